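"""The 27-feature morphology panel of a segmented plaque.

Six first-order statistics of the masked intensity histogram, four shape
descriptors of the mask, and seventeen co-occurrence texture statistics
(see :mod:`plaquekit.texture`), in a fixed canonical order.

Conventions for degenerate inputs: a zero-variance region has skewness and
kurtosis 0; kurtosis is otherwise the non-excess (Pearson) standardized
fourth moment, so a normal distribution scores 3.  Correlation-type texture
statistics fall back to 0 on degenerate co-occurrence matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.measure import perimeter as _sk_perimeter
from sklearn.base import BaseEstimator, TransformerMixin

from .phantom import PlaqueRecord, StageLabel
from .segmentation import label_components, segment
from .texture import TEXTURE_NAMES, masked_texture_features

__all__ = [
    "FOS_NAMES",
    "SHAPE_NAMES",
    "TEXTURE_NAMES",
    "FEATURE_NAMES",
    "GLCMConfig",
    "extract_fos",
    "extract_shape",
    "extract_texture",
    "extract_all",
    "build_feature_table",
    "write_feature_table",
    "read_feature_table",
    "PlaqueSegmenter",
    "PlaqueFeatureExtractor",
]

FOS_NAMES = (
    "mean_intensity",
    "n_objects",
    "skewness",
    "kurtosis",
    "std_dev",
    "integrated_density",
)
SHAPE_NAMES = ("area", "circularity", "perimeter", "extent")
#: Canonical order of the full 27-feature panel.
FEATURE_NAMES = FOS_NAMES + SHAPE_NAMES + TEXTURE_NAMES
assert len(FEATURE_NAMES) == 27


@dataclass(frozen=True)
class GLCMConfig:
    """Settings of the windowed co-occurrence analysis.

    ``window_size`` must be odd; ``distance`` and ``angles`` define the pixel
    offsets; ``n_gray_levels`` is the equal-width re-quantization of the
    image's intensity range before accumulation.  Features are computed per
    offset and averaged over offsets.
    """

    window_size: int = 9
    distance: int = 1
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    n_gray_levels: int = 32
    symmetric: bool = True

    def validate(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if not self.angles:
            raise ValueError("at least one offset angle is required")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")


def _masked_values(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise ValueError("mask must match image dimensions")
    if not mask.any():
        raise ValueError("mask is empty")
    return img[mask].astype(np.float64)


def extract_fos(img: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """First-order statistics of the masked intensities.

    ``n_objects`` counts the 8-connected components of the mask (the number
    of distinct lipid-cell clusters); ``integrated_density`` is the plain sum
    of masked intensities.
    """
    vals = _masked_values(img, mask)
    _, n_objects = label_components(mask, connectivity=8)
    var = vals.var()  # population variance, for the standardized moments
    if var > 0:
        skew = float(stats.skew(vals, bias=True))
        kurt = float(stats.kurtosis(vals, fisher=False, bias=True))
    else:
        skew = 0.0
        kurt = 0.0
    std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return {
        "mean_intensity": float(vals.mean()),
        "n_objects": float(n_objects),
        "skewness": skew,
        "kurtosis": kurt,
        "std_dev": std,
        "integrated_density": float(vals.sum()),
    }


def extract_shape(mask: np.ndarray) -> dict[str, float]:
    """Shape descriptors of the mask union.

    area = pixel count; perimeter = weighted boundary-segment estimate over
    all components; circularity = 4*pi*area / perimeter**2; extent = area
    over the bounding-box area of the union.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    area = float(mask.sum())
    perim = float(_sk_perimeter(mask, neighborhood=4))
    circularity = float(4.0 * np.pi * area / perim**2) if perim > 0 else 0.0
    ys, xs = np.nonzero(mask)
    bbox_area = float((ys.max() - ys.min() + 1) * (xs.max() - xs.min() + 1))
    return {
        "area": area,
        "circularity": circularity,
        "perimeter": perim,
        "extent": area / bbox_area,
    }


def extract_texture(
    img: np.ndarray, mask: np.ndarray, cfg: GLCMConfig | None = None
) -> dict[str, float]:
    """Window-averaged co-occurrence texture statistics over the mask."""
    cfg = cfg or GLCMConfig()
    cfg.validate()
    values = masked_texture_features(
        img,
        mask,
        window_size=cfg.window_size,
        levels=cfg.n_gray_levels,
        distance=cfg.distance,
        angles=cfg.angles,
    )
    return dict(zip(TEXTURE_NAMES, map(float, values)))


def extract_all(
    img: np.ndarray, mask: np.ndarray, cfg: GLCMConfig | None = None
) -> dict[str, float]:
    """The full 27-value panel in canonical order."""
    out = {}
    out.update(extract_fos(img, mask))
    out.update(extract_shape(mask))
    out.update(extract_texture(img, mask, cfg))
    return {name: out[name] for name in FEATURE_NAMES}


def build_feature_table(
    records: Sequence[PlaqueRecord],
    masks: Sequence[np.ndarray],
    cfg: GLCMConfig | None = None,
    on_empty: str = "skip",
) -> pd.DataFrame:
    """Feature table (columns: id, label, then the 27 features) over records.

    Records whose mask is empty are skipped (``on_empty="skip"``) or raise
    (``on_empty="raise"``).
    """
    rows = []
    for rec, mask in zip(records, masks):
        if mask is None or not np.asarray(mask).any():
            if on_empty == "raise":
                raise ValueError(f"empty mask for record {rec.id}")
            continue
        row = {"id": rec.id, "label": rec.label.value if rec.label else ""}
        row.update(extract_all(rec.image, mask, cfg))
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "label", *FEATURE_NAMES])


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    # default float repr is shortest-roundtrip, so the CSV is lossless
    table.to_csv(path, index=False)


def read_feature_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str, "label": str})
    missing = [c for c in ("id", "label", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# sklearn-style transformers so the image chain composes into a Pipeline
# ---------------------------------------------------------------------------

class PlaqueSegmenter(BaseEstimator, TransformerMixin):
    """Stateless transformer mapping a list of images to a list of masks.

    ``method`` is one of ``otsu``/``ifct``/``mcw``/``kms``; ``params`` are
    forwarded to the underlying segmenter.
    """

    def __init__(self, method: str = "otsu", params: dict | None = None):
        self.method = method
        self.params = params

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        params = self.params or {}
        return [segment(np.asarray(img), method=self.method, **params) for img in X]


class PlaqueFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping ``(image, mask)`` pairs to the 27-feature matrix."""

    def __init__(self, glcm: GLCMConfig | None = None):
        self.glcm = glcm

    def fit(self, X, y=None):
        self.feature_names_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        rows = [
            [extract_all(img, mask, self.glcm)[name] for name in FEATURE_NAMES]
            for img, mask in X
        ]
        return np.asarray(rows, dtype=np.float64)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
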