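import numpy as np
import pytest

from plaquekit import (
    PhantomConfig,
    build_feature_table,
    generate_dataset,
    otsu_segment,
    preprocess_image,
)


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def small_batch(phantom_config):
    """24 phantoms (8 per stage) with truth masks, plus preprocessed images."""
    records = generate_dataset(
        phantom_config, {"EFS": 8, "EF": 8, "AA": 8}, seed=42
    )
    processed = [preprocess_image(r.image) for r in records]
    return records, processed


@pytest.fixture(scope="session")
def small_feature_table(small_batch):
    """Feature panel of the small batch: Otsu masks from the enhanced images,
    intensities measured on the acquired images."""
    records, processed = small_batch
    masks = [otsu_segment(img)[1] for img in processed]
    return build_feature_table(records, masks)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The full phantom staging study: 150 images/stage through the pipeline.

    Generated once per session and shared by the acceptance checks.
    """
    from plaquekit.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("study")
    cfg = PhantomConfig()
    records = generate_dataset(cfg, {"EFS": 150, "EF": 150, "AA": 150}, seed=101)
    pipeline_cfg = PipelineConfig(segmenters=("otsu",), seed=7, save_masks=False)
    summary = run_pipeline(records, pipeline_cfg, out_dir=str(out))
    return {"summary": summary, "out_dir": str(out), "records": records}
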