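"""End-to-end orchestration: preprocess → segment (×4) → features → select (×2) → classify (×3).

``run_pipeline`` drives the whole staging study over a manifest (or an
in-memory list of records), writing every intermediate artifact — masks, Dice
scores on a seeded per-stage subset, feature tables, selection results,
per-classifier evaluation reports — plus a top-level summary CSV over the
(segmenter × selector × classifier) cross product.  The run is a pure
function of (input records, config, seed): the same seed reproduces the
summary bit for bit.

Feature refinement is computed from the full labelled feature table (class
means over the whole dataset), as in the staging study; classifier tuning
and the held-out evaluation use the seeded 60/20/20 stratified split.

Per-image failures (unreadable files, empty masks) are quarantined and
logged in ``errors.csv`` rather than aborting the batch.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import asdict, dataclass, field

import imageio.v3 as iio
import joblib
import numpy as np
import pandas as pd
import yaml

from .classify import CLASS_ORDER, TunedClassifier, evaluate, split_dataset
from .features import (
    FEATURE_NAMES,
    GLCMConfig,
    build_feature_table,
    extract_all,
    write_feature_table,
)
from .phantom import PlaqueRecord, read_manifest
from .preprocessing import preprocess_image
from .segmentation import dice, otsu_segment, segment, trace_reference
from .selection import SelectionResult, cv_select, ftf_select

__all__ = ["PipelineConfig", "run_pipeline", "classify_single", "save_bundle", "load_bundle"]

_SEED_MOD = 2**31 - 1


def _derive_seed(seed: int, tag: str) -> int:
    """Stable per-stage seed derived from the global seed and a stage tag."""
    return (int(seed) * 1000003 + zlib.crc32(tag.encode())) % _SEED_MOD


@dataclass
class PipelineConfig:
    """All knobs of the staging pipeline, mirroring the study's stated values."""

    # preprocessing
    low_fraction: float = 0.01
    high_fraction: float = 0.01
    sharpen_radius: float = 1.5
    sharpen_amount: float = 0.8
    # segmentation
    segmenters: tuple[str, ...] = ("otsu", "ifct", "mcw", "kms")
    segmenter_params: dict = field(default_factory=dict)
    # features
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    # selection
    cv_threshold_pct: float = 8.0
    ftf_top_k: int = 15
    ftf_bins: int = 10
    # classification
    classifiers: tuple[str, ...] = ("knn", "dt", "mcsvm")
    tuning_budget: int = 30
    cv_folds: int = 10
    train_frac: float = 0.6
    test_frac: float = 0.2
    val_frac: float = 0.2
    # evaluation
    dice_subset_per_group: int = 50
    trace_iters: int = 40
    save_masks: bool = True
    seed: int = 7

    def to_yaml(self, path: str) -> None:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        payload = plain(asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "glcm" in payload and isinstance(payload["glcm"], dict):
            g = payload["glcm"]
            if "angles" in g:
                g["angles"] = tuple(g["angles"])
            payload["glcm"] = GLCMConfig(**g)
        if "segmenters" in payload:
            payload["segmenters"] = tuple(payload["segmenters"])
        if "classifiers" in payload:
            payload["classifiers"] = tuple(payload["classifiers"])
        return cls(**payload)


def _foreground_significant(img: np.ndarray, mask: np.ndarray, z: float = 4.0) -> bool:
    """Does the masked foreground rise meaningfully above the background?

    Uses robust background statistics (median and MAD) so a plaque-free
    noise field is not mistaken for plaque.
    """
    img = np.asarray(img).astype(np.float64)
    med = np.median(img)
    sigma = 1.4826 * np.median(np.abs(img - med))
    if sigma == 0:
        sigma = max(img.std(), 1e-9)
    return float(img[mask].mean() - med) > z * sigma


def _segment_one(img: np.ndarray, method: str, config: PipelineConfig) -> np.ndarray:
    params = dict(config.segmenter_params.get(method, {}))
    if method == "kms" and "seed" not in params:
        params["seed"] = _derive_seed(config.seed, "kms")
    return segment(img, method=method, **params)


def _reference_mask(record: PlaqueRecord, img: np.ndarray, config: PipelineConfig):
    """Ground truth for Dice: the phantom truth mask, else a traced contour."""
    if record.truth_mask is not None:
        return record.truth_mask
    try:
        _, init = otsu_segment(img)
    except ValueError:
        return None
    if not init.any():
        return None
    from scipy.ndimage import binary_dilation

    init = binary_dilation(init, iterations=2)
    return trace_reference(img, init, n_iter=config.trace_iters)


def run_pipeline(
    records_or_manifest,
    config: PipelineConfig | None = None,
    out_dir: str = "plaquekit_run",
) -> pd.DataFrame:
    """Run the full staging study; returns the summary table (also written to disk)."""
    config = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    config.to_yaml(os.path.join(out_dir, "config.yaml"))

    if isinstance(records_or_manifest, (str, os.PathLike)):
        records = read_manifest(str(records_or_manifest))
    else:
        records = list(records_or_manifest)

    errors: list[dict] = []
    processed: list[tuple[PlaqueRecord, np.ndarray]] = []
    for rec in records:
        try:
            img = preprocess_image(
                rec.image,
                low_fraction=config.low_fraction,
                high_fraction=config.high_fraction,
                radius=config.sharpen_radius,
                amount=config.sharpen_amount,
                bit_depth=rec.bit_depth,
            )
            processed.append((rec, img))
        except Exception as exc:  # quarantine, keep the batch running
            errors.append({"id": rec.id, "stage": "preprocess", "error": str(exc)})
    if not processed:
        raise ValueError("no usable input records")

    summary_rows = []
    for method in config.segmenters:
        mdir = os.path.join(out_dir, method)
        os.makedirs(mdir, exist_ok=True)
        masks: list[np.ndarray | None] = []
        for rec, img in processed:
            try:
                mask = _segment_one(img, method, config)
            except Exception as exc:
                errors.append({"id": rec.id, "stage": f"segment:{method}", "error": str(exc)})
                mask = None
            masks.append(mask)
            if config.save_masks and mask is not None:
                iio.imwrite(
                    os.path.join(mdir, f"{rec.id}_mask.png"),
                    mask.astype(np.uint8) * 255,
                )

        # Dice against reference masks on a seeded subset per stage
        dice_rows = []
        rng = np.random.default_rng(_derive_seed(config.seed, f"dice:{method}"))
        by_stage: dict[str, list[int]] = {}
        for idx, (rec, _) in enumerate(processed):
            if rec.label is not None and masks[idx] is not None:
                by_stage.setdefault(rec.label.value, []).append(idx)
        for stage, idxs in sorted(by_stage.items()):
            take = min(config.dice_subset_per_group, len(idxs))
            chosen = rng.choice(idxs, size=take, replace=False)
            for idx in sorted(chosen):
                rec, img = processed[idx]
                ref = _reference_mask(rec, img, config)
                if ref is None:
                    continue
                dice_rows.append(
                    {"id": rec.id, "method": method, "label": stage,
                     "dice": dice(masks[idx], ref)}
                )
        dice_df = pd.DataFrame(dice_rows, columns=["id", "method", "label", "dice"])
        dice_df.to_csv(os.path.join(mdir, "dice.csv"), index=False)

        # masks come from the enhanced images, but the morphology panel is
        # measured on the acquired intensities: contrast stretching is a
        # per-image display normalization that would erase the absolute
        # intensity differences between stages
        usable = [(rec, m) for (rec, img), m in zip(processed, masks)
                  if m is not None and m.any() and rec.label is not None]
        table = build_feature_table(
            [r for r, _ in usable], [m for _, m in usable], config.glcm
        )
        write_feature_table(table, os.path.join(mdir, "features.csv"))
        if table.empty or table["label"].nunique() < len(CLASS_ORDER):
            errors.append({"id": "", "stage": f"features:{method}",
                           "error": "not all classes usable; skipping classification"})
            continue

        selections = {
            "cv": cv_select(table, threshold_pct=config.cv_threshold_pct),
            "ftf": ftf_select(table, k=config.ftf_top_k, n_bins=config.ftf_bins),
        }
        for name, sel in selections.items():
            sel.to_json(os.path.join(mdir, f"selection_{name}.json"))
            sel.to_csv(os.path.join(mdir, f"selection_{name}.csv"))

        train, test, val = split_dataset(
            table, config.train_frac, config.test_frac, config.val_frac,
            seed=_derive_seed(config.seed, f"split:{method}"),
        )
        for sel_name, sel in selections.items():
            cols = sel.retained
            if not cols:
                continue
            for algo in config.classifiers:
                clf = TunedClassifier(
                    algorithm=algo,
                    budget=config.tuning_budget,
                    cv_folds=config.cv_folds,
                    seed=_derive_seed(config.seed, f"tune:{method}:{sel_name}:{algo}"),
                )
                clf.fit(train[cols].to_numpy(), train["label"].to_numpy())
                report = evaluate(clf, test[cols].to_numpy(), test["label"].to_numpy())
                rpath = os.path.join(mdir, f"report_{sel_name}_{algo}.json")
                with open(rpath, "w") as fh:
                    json.dump(report.to_dict(), fh, indent=2)
                pd.DataFrame(
                    [{"params": json.dumps(p, sort_keys=True), "cv_loss": l}
                     for p, l in clf.cv_results_]
                ).to_csv(os.path.join(mdir, f"tuning_{sel_name}_{algo}.csv"), index=False)
                row = {
                    "segmenter": method,
                    "selector": sel_name,
                    "classifier": algo,
                    "n_features": len(cols),
                    "dice_mean": float(dice_df["dice"].mean()) if len(dice_df) else np.nan,
                    "macro_accuracy": report.macro["accuracy"],
                    "overall_accuracy": report.macro["overall_accuracy"],
                    "generalization_error": report.generalization_error,
                }
                for lab in CLASS_ORDER:
                    row[f"accuracy_{lab}"] = report.per_class.get(lab, {}).get("accuracy", np.nan)
                summary_rows.append(row)

    pd.DataFrame(errors).to_csv(os.path.join(out_dir, "errors.csv"), index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(os.path.join(out_dir, "summary.csv"), index=False, float_format="%.10g")
    return summary


# ---------------------------------------------------------------------------
# single-image inference
# ---------------------------------------------------------------------------

def save_bundle(path: str, *, config: PipelineConfig, segmenter: str,
                selection: SelectionResult, model: TunedClassifier) -> None:
    """Persist everything needed for single-image inference."""
    joblib.dump(
        {"config": config, "segmenter": segmenter, "selection": selection,
         "model": model},
        path,
    )


def load_bundle(path: str) -> dict:
    return joblib.load(path)


def classify_single(image: np.ndarray, bundle: dict) -> tuple[str | None, dict]:
    """Stage one image through a trained bundle.

    Returns ``(label, features)``; the label is ``None`` when segmentation
    finds no plaque ("no plaque detected") — either an empty mask, or a
    foreground whose intensity does not rise meaningfully above the
    background (a threshold always splits something, even pure noise).
    """
    config: PipelineConfig = bundle["config"]
    raw = np.asarray(image)
    img = preprocess_image(
        raw,
        low_fraction=config.low_fraction,
        high_fraction=config.high_fraction,
        radius=config.sharpen_radius,
        amount=config.sharpen_amount,
    )
    try:
        mask = _segment_one(img, bundle["segmenter"], config)
    except ValueError:
        return None, {}
    if not mask.any() or not _foreground_significant(raw, mask):
        return None, {}
    feats = extract_all(raw, mask, config.glcm)
    cols = bundle["selection"].retained
    X = np.asarray([[feats[c] for c in cols]])
    label = str(bundle["model"].predict(X)[0])
    return label, feats
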