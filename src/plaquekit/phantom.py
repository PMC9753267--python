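"""Synthetic CARS-like foam-cell phantoms with ground-truth masks and stage labels.

Atherosclerotic plaque imaged by CARS microscopy appears as bright clusters of
lipid-laden foam cells over a dim, noisy background.  The three disease stages
modelled here differ in how those clusters look:

* **EFS** (early fatty streak development): many small, dim blobs scattered
  across the field — confluent but sparse early lipid pools.
* **EF** (early fibroatheroma): intermediate-size blobs gathered into a couple
  of loose pools; a per-image mixture of immature (dim) and mature (bright)
  foam-cell clusters gives EF the most asymmetric (skewed, heavy-tailed)
  intensity distribution of the three stages.
* **AA** (advancing atheroma): few large, bright, strongly overlapping blobs
  forming one dense, compact accumulation.

Each blob is an isotropic Gaussian-profile disc (hard support at two standard
deviations); blob signals add, then Poisson shot noise and Gaussian read noise
are applied and the result is clipped to the representable integer range.  The
union of blob supports is recorded as the ground-truth mask.

Generation is a pure function of ``(config, stage, seed)``.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "StageLabel",
    "StageParams",
    "PhantomConfig",
    "PlaqueRecord",
    "generate_phantom",
    "generate_dataset",
    "write_dataset",
    "read_manifest",
    "STUDY_CLASS_SIZES",
]

#: Per-stage image counts of the reference rabbit-model cohort the phantom emulates.
STUDY_CLASS_SIZES: dict[str, int] = {"EFS": 214, "EF": 134, "AA": 218}

_SEED_MOD = 2**31 - 1


class StageLabel(str, enum.Enum):
    """The three plaque stages, ordered by disease progression."""

    EFS = "EFS"
    EF = "EF"
    AA = "AA"

    def __lt__(self, other: "StageLabel") -> bool:  # progression order
        order = [StageLabel.EFS, StageLabel.EF, StageLabel.AA]
        if not isinstance(other, StageLabel):
            return NotImplemented
        return order.index(self) < order.index(other)

    @classmethod
    def coerce(cls, value: "StageLabel | str") -> "StageLabel":
        if isinstance(value, StageLabel):
            return value
        try:
            return cls(str(value).upper())
        except ValueError as exc:
            raise ValueError(
                f"invalid stage {value!r}; expected one of EFS, EF, AA"
            ) from exc


@dataclass(frozen=True)
class StageParams:
    """Blob statistics for one stage.

    Radii are in pixels; amplitudes in raw intensity units (signal above
    background before noise).  ``bright_*`` fields, when set, switch the blob
    amplitude to a two-population mixture: each blob is drawn from the bright
    population with a per-image probability sampled uniformly from
    ``bright_frac_range``.  ``n_cluster_centers == 0`` scatters blob centres
    uniformly; otherwise blobs fall normally (sd ``cluster_spread``) around
    that many uniformly placed cluster centres.
    """

    n_blobs_mean: float
    n_blobs_sd: float
    radius_mean: float
    radius_image_sd: float  # image-to-image spread of the mean radius
    radius_blob_sd: float  # blob-to-blob spread within an image
    amp_mean: float
    amp_sd: float
    n_cluster_centers: int = 0
    cluster_spread: float = 0.0
    bright_frac_range: tuple[float, float] | None = None
    bright_amp_mean: float | None = None
    bright_amp_sd: float | None = None

    def expected_amplitude(self) -> float:
        """Expected blob amplitude, accounting for the bright/dim mixture."""
        if self.bright_frac_range is None:
            return self.amp_mean
        f = 0.5 * (self.bright_frac_range[0] + self.bright_frac_range[1])
        assert self.bright_amp_mean is not None
        return (1.0 - f) * self.amp_mean + f * self.bright_amp_mean

    def validate(self) -> None:
        if self.n_blobs_mean < 0 or self.n_blobs_sd < 0:
            raise ValueError("blob counts must be nonnegative")
        if self.radius_mean < 0 or self.radius_image_sd < 0 or self.radius_blob_sd < 0:
            raise ValueError("blob radii must be nonnegative")
        if self.amp_mean < 0 or self.amp_sd < 0:
            raise ValueError("blob amplitudes must be nonnegative")
        if self.bright_frac_range is not None:
            lo, hi = self.bright_frac_range
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("bright_frac_range must lie within [0, 1]")
            if self.bright_amp_mean is None:
                raise ValueError("bright mixture requires bright_amp_mean")


def _default_stages() -> dict[StageLabel, StageParams]:
    return {
        StageLabel.EFS: StageParams(
            n_blobs_mean=25, n_blobs_sd=5,
            radius_mean=4.0, radius_image_sd=0.8, radius_blob_sd=0.8,
            amp_mean=12000.0, amp_sd=1500.0,
            n_cluster_centers=0,
        ),
        StageLabel.EF: StageParams(
            n_blobs_mean=18, n_blobs_sd=4,
            radius_mean=7.0, radius_image_sd=1.5, radius_blob_sd=0.8,
            amp_mean=14000.0, amp_sd=1500.0,
            n_cluster_centers=2, cluster_spread=18.0,
            bright_frac_range=(0.1, 0.9),
            bright_amp_mean=30000.0, bright_amp_sd=2000.0,
        ),
        StageLabel.AA: StageParams(
            n_blobs_mean=14, n_blobs_sd=3,
            radius_mean=11.0, radius_image_sd=1.5, radius_blob_sd=1.0,
            amp_mean=32000.0, amp_sd=2500.0,
            n_cluster_centers=1, cluster_spread=14.0,
        ),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, noise and per-stage blob distributions of the generator.

    The defaults constitute the "strong separation" preset: class-mean
    intensity, integrated density and area differ well beyond the 8%
    interclass coefficient of variation used downstream for feature
    refinement, while EF remains the hardest class because of its mixture
    construction.
    """

    image_height: int = 128
    image_width: int = 128
    bit_depth: int = 16
    background_level: float = 1500.0
    read_noise_sd: float = 300.0
    shot_noise: bool = True
    random_seed: int = 0
    stages: Mapping[StageLabel, StageParams] = field(default_factory=_default_stages)

    @classmethod
    def strong_separation(cls, **overrides) -> "PhantomConfig":
        """The default, strongly class-separated preset."""
        return cls(**overrides)

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.bit_depth <= 0:
            raise ValueError("bit depth must be positive")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("background and noise levels must be nonnegative")
        for stage in StageLabel:
            if stage not in self.stages:
                raise ValueError(f"missing stage parameters for {stage.value}")
            self.stages[stage].validate()
        amps = [self.stages[s].expected_amplitude() for s in
                (StageLabel.EFS, StageLabel.EF, StageLabel.AA)]
        if not (amps[0] < amps[1] < amps[2]):
            raise ValueError(
                "expected foreground amplitude must be strictly ordered EFS < EF < AA"
            )

    def with_stage(self, stage: StageLabel, **changes) -> "PhantomConfig":
        stages = dict(self.stages)
        stages[stage] = replace(stages[stage], **changes)
        return replace(self, stages=stages)


@dataclass
class PlaqueRecord:
    """One sample: image, optional ground-truth mask, optional stage label."""

    id: str
    image: np.ndarray
    truth_mask: np.ndarray | None = None
    label: StageLabel | None = None
    bit_depth: int = 16
    path: str | None = None
    mask_path: str | None = None

    def __post_init__(self) -> None:
        if self.truth_mask is not None and self.truth_mask.shape != self.image.shape:
            raise ValueError("image and truth_mask must have identical dimensions")


def _int_dtype(bit_depth: int) -> np.dtype:
    if bit_depth <= 8:
        return np.dtype(np.uint8)
    if bit_depth <= 16:
        return np.dtype(np.uint16)
    return np.dtype(np.uint32)


def generate_phantom(
    config: PhantomConfig,
    stage: StageLabel | str,
    seed: int,
    record_id: str | None = None,
) -> PlaqueRecord:
    """Draw one phantom image for ``stage``.

    Deterministic: the same ``(config, stage, seed)`` reproduces the image and
    mask bit for bit.
    """
    stage = StageLabel.coerce(stage)
    config.validate()
    params = config.stages[stage]
    rng = np.random.default_rng(seed)
    h, w = config.image_height, config.image_width

    n_blobs = max(0, int(round(rng.normal(params.n_blobs_mean, params.n_blobs_sd))))

    signal = np.zeros((h, w), dtype=np.float64)
    mask = np.zeros((h, w), dtype=bool)

    # blob centres: uniform scatter or clustered around a few centres
    if params.n_cluster_centers > 0 and n_blobs > 0:
        centers = rng.uniform(
            [0.2 * h, 0.2 * w], [0.8 * h, 0.8 * w],
            size=(params.n_cluster_centers, 2),
        )
        which = rng.integers(0, params.n_cluster_centers, size=n_blobs)
        pos = centers[which] + rng.normal(0.0, params.cluster_spread, size=(n_blobs, 2))
    else:
        pos = rng.uniform([0.0, 0.0], [h, w], size=(n_blobs, 2))
    pos = np.clip(pos, 0, [h - 1, w - 1])

    radius_image = max(2.0, rng.normal(params.radius_mean, params.radius_image_sd))
    radii = np.clip(
        rng.normal(radius_image, params.radius_blob_sd, size=n_blobs), 2.0, None
    )

    if params.bright_frac_range is not None:
        f = rng.uniform(*params.bright_frac_range)
        bright = rng.random(n_blobs) < f
        amps = np.where(
            bright,
            rng.normal(params.bright_amp_mean, params.bright_amp_sd, size=n_blobs),
            rng.normal(params.amp_mean, params.amp_sd, size=n_blobs),
        )
    else:
        amps = rng.normal(params.amp_mean, params.amp_sd, size=n_blobs)
    amps = np.clip(amps, 0.0, None)

    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx), r, amp in zip(pos, radii, amps):
        sigma = r / 2.0  # hard support at 2 sigma = r
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        d2 = (yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2
        support = d2 <= r * r
        signal[y0:y1, x0:x1] += np.where(
            support, amp * np.exp(-d2 / (2.0 * sigma * sigma)), 0.0
        )
        mask[y0:y1, x0:x1] |= support

    signal += config.background_level
    if config.shot_noise:
        signal = rng.poisson(np.clip(signal, 0.0, None)).astype(np.float64)
    if config.read_noise_sd > 0:
        signal += rng.normal(0.0, config.read_noise_sd, size=signal.shape)

    image = np.clip(np.rint(signal), 0, config.max_value).astype(_int_dtype(config.bit_depth))
    rid = record_id if record_id is not None else f"{stage.value}-{seed:010d}"
    return PlaqueRecord(
        id=rid, image=image, truth_mask=mask, label=stage, bit_depth=config.bit_depth
    )


def generate_dataset(
    config: PhantomConfig,
    n_per_stage: Mapping[StageLabel | str, int],
    seed: int | None = None,
) -> list[PlaqueRecord]:
    """Generate a labelled phantom dataset, shuffled reproducibly from ``seed``."""
    config.validate()
    counts = {StageLabel.coerce(k): int(v) for k, v in n_per_stage.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("per-stage counts must be nonnegative")
    if seed is None:
        seed = config.random_seed
    rng = np.random.default_rng(seed)
    records: list[PlaqueRecord] = []
    for stage in (StageLabel.EFS, StageLabel.EF, StageLabel.AA):
        n = counts.get(stage, 0)
        child_seeds = rng.integers(0, _SEED_MOD, size=n)
        for i, child in enumerate(child_seeds):
            records.append(
                generate_phantom(
                    config, stage, int(child), record_id=f"{stage.value}-{i:04d}"
                )
            )
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def write_dataset(records: Sequence[PlaqueRecord], out_dir: str) -> str:
    """Write images (16-bit TIFF), masks (8-bit PNG) and a CSV manifest.

    Returns the manifest path.  Manifest columns: id, path, mask_path, label.
    """
    os.makedirs(out_dir, exist_ok=True)
    img_dir = os.path.join(out_dir, "images")
    mask_dir = os.path.join(out_dir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    rows = []
    for rec in records:
        path = os.path.join(img_dir, f"{rec.id}.tif")
        tifffile.imwrite(path, rec.image)
        mask_path = ""
        if rec.truth_mask is not None:
            os.makedirs(mask_dir, exist_ok=True)
            mask_path = os.path.join(mask_dir, f"{rec.id}.png")
            iio.imwrite(mask_path, (rec.truth_mask.astype(np.uint8) * 255))
        rows.append(
            {
                "id": rec.id,
                "path": path,
                "mask_path": mask_path,
                "label": rec.label.value if rec.label is not None else "",
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(manifest_path: str) -> list[PlaqueRecord]:
    """Load records listed in a manifest CSV (id, path, mask_path, label)."""
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        image = tifffile.imread(row["path"]) if row["path"].endswith((".tif", ".tiff")) \
            else iio.imread(row["path"])
        image = np.asarray(image)
        mask = None
        if row.get("mask_path", ""):
            mask = np.asarray(iio.imread(row["mask_path"])) > 0
        label = StageLabel.coerce(row["label"]) if row.get("label", "") else None
        bit_depth = 16 if image.dtype.itemsize >= 2 else 8
        records.append(
            PlaqueRecord(
                id=row["id"], image=image, truth_mask=mask, label=label,
                bit_depth=bit_depth, path=row["path"],
                mask_path=row.get("mask_path") or None,
            )
        )
    return records
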