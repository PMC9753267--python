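"""Four parallel plaque segmenters, an active-contour reference tracer, and Dice.

The segmenters isolate bright foam-cell clusters (plaque) from the dim
background; mask polarity is foreground = plaque = high intensity throughout.

* ``otsu_segment`` — global histogram threshold maximizing between-class
  variance (the Otsu criterion, computed here explicitly over the binned
  histogram so the threshold is an exact argmax over all split points).
* ``ifct_segment`` — independent foam-cell thresholding: a permissive global
  seed threshold proposes candidate clusters, and each candidate's bounding
  region is then re-thresholded with its own local Otsu, so dim clusters are
  segmented independently of bright ones.
* ``mcw_segment`` — marker-controlled watershed on the gradient magnitude,
  with foreground markers at regional maxima of the smoothed image and a
  background marker from low-intensity pixels.
* ``kms_segment`` — k-means clustering of per-pixel Gabor filter-bank
  magnitude responses plus intensity; clusters brighter than the image mean
  are called plaque.

``trace_reference`` evolves a Chan–Vese-type active contour from an initial
mask, standing in for manual boundary tracing when no ground truth exists.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gabor, sobel
from skimage.measure import label as _sk_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import morphological_chan_vese, watershed
from sklearn.cluster import KMeans

__all__ = [
    "otsu_threshold",
    "otsu_segment",
    "ifct_segment",
    "mcw_segment",
    "kms_segment",
    "trace_reference",
    "dice",
    "label_components",
    "SEGMENTERS",
    "segment",
]


# ---------------------------------------------------------------------------
# Otsu thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(img: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's optimal threshold over an ``n_bins`` equal-width histogram.

    Returns the intensity maximizing the between-class variance
    ``w0 * w1 * (mu0 - mu1)**2`` over all histogram split points; the
    threshold is the centre of the last bin assigned to the background class.

    Raises ``ValueError`` for a constant image (no split exists).
    """
    img = np.asarray(img)
    vals = img.ravel().astype(np.float64)
    if vals.size == 0:
        raise ValueError("empty image")
    vmin, vmax = vals.min(), vals.max()
    if vmin == vmax:
        raise ValueError("constant image: no Otsu threshold exists")
    counts, edges = np.histogram(vals, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])

    p = counts / counts.sum()
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (mu_total - m) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-np.inf)  # a split needs both classes
    idx = int(np.argmax(sigma_b))
    return float(centers[idx])


def otsu_segment(img: np.ndarray, n_bins: int = 256) -> tuple[float, np.ndarray]:
    """Global Otsu segmentation; the mask marks pixels strictly above threshold."""
    t = otsu_threshold(img, n_bins=n_bins)
    return t, np.asarray(img) > t


# ---------------------------------------------------------------------------
# Independent foam cell thresholding (IFCT)
# ---------------------------------------------------------------------------

def ifct_segment(
    img: np.ndarray,
    candidate_quantile: float = 0.75,
    min_area: int = 10,
    n_bins: int = 256,
    min_peak_z: float = 4.0,
) -> np.ndarray:
    """Independent foam-cell thresholding.

    A permissive global seed threshold at ``candidate_quantile`` proposes
    candidate clusters; each candidate's bounding region is re-segmented with
    a local Otsu threshold computed from that region alone, and the per-region
    masks are unioned.  Components smaller than ``min_area`` are discarded,
    as are candidates whose peak does not rise meaningfully above the
    background (robust z-score below ``min_peak_z``) — a quantile seed
    threshold always marks something, even on a plaque-free noise field.
    An image with no surviving candidates yields an empty mask.
    """
    img = np.asarray(img)
    if not (0.0 < candidate_quantile < 1.0):
        raise ValueError("candidate_quantile must lie in (0, 1)")
    med = np.median(img)
    sigma = 1.4826 * np.median(np.abs(img.astype(np.float64) - med))
    seed_thr = np.quantile(img, candidate_quantile)
    candidates = img > seed_thr
    labels, n = ndi.label(candidates, structure=np.ones((3, 3), dtype=int))
    out = np.zeros(img.shape, dtype=bool)
    if n == 0:
        return out
    for sl in ndi.find_objects(labels):
        if sl is None:
            continue
        region = img[sl]
        if sigma > 0 and (region.max() - med) < min_peak_z * sigma:
            continue  # indistinguishable from background noise
        if region.min() == region.max():
            # no local contrast: keep the seed-threshold pixels as-is
            out[sl] |= candidates[sl]
            continue
        local_thr = otsu_threshold(region, n_bins=n_bins)
        out[sl] |= region > local_thr
    if min_area > 1:
        out = remove_small_objects(out, max_size=min_area - 1, connectivity=2)
    return out


# ---------------------------------------------------------------------------
# Marker-controlled watershed (MCW)
# ---------------------------------------------------------------------------

def mcw_segment(
    img: np.ndarray,
    marker_min_distance: int = 8,
    min_area: int = 10,
    smoothing_sigma: float = 2.0,
    return_basins: bool = False,
) -> np.ndarray:
    """Marker-controlled watershed on the gradient magnitude.

    Foreground markers are the regional maxima of the Gaussian-smoothed image
    separated by at least ``marker_min_distance`` pixels; pixels at or below
    the global Otsu threshold form the background region and are never
    claimed.  The watershed floods the gradient magnitude within the
    above-threshold support, so ridges of the gradient trace the boundaries
    between touching foam-cell clusters without the background leaking into
    the dim skirt of a cluster.  The mask is the union of the resulting
    catchment basins, small objects removed.  A constant image yields an
    empty mask.

    With ``return_basins=True`` the labelled catchment basins are returned
    instead of their union (0 = background, one label per marker).
    """
    img = np.asarray(img).astype(np.float64)
    if img.min() == img.max():
        empty = np.zeros(img.shape, dtype=np.int32 if return_basins else bool)
        return empty
    smoothed = ndi.gaussian_filter(img, sigma=smoothing_sigma)
    thr = otsu_threshold(img)
    support = img > thr
    if not support.any():
        return np.zeros(img.shape, dtype=bool)
    peaks = peak_local_max(
        smoothed, min_distance=marker_min_distance, threshold_abs=thr,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    next_label = 2
    for y, x in peaks:
        if support[y, x]:
            markers[y, x] = next_label
            next_label += 1
    # every support component needs at least one marker
    comp, n_comp = ndi.label(support, structure=np.ones((3, 3), dtype=int))
    marked = set(np.unique(comp[markers > 1])) - {0}
    for c in range(1, n_comp + 1):
        if c not in marked:
            inside = comp == c
            flat = np.argmax(np.where(inside, smoothed, -np.inf))
            markers[np.unravel_index(flat, img.shape)] = next_label
            next_label += 1
    gradient = sobel(smoothed)
    basins = watershed(gradient, markers=markers, mask=support)
    if return_basins:
        return np.where(basins > 1, basins - 1, 0).astype(np.int32)
    mask = basins > 1
    if min_area > 1:
        mask = remove_small_objects(mask, max_size=min_area - 1, connectivity=2)
    return mask


# ---------------------------------------------------------------------------
# Gabor + k-means segmentation (KMS)
# ---------------------------------------------------------------------------

def kms_segment(
    img: np.ndarray,
    gabor_frequencies: tuple[float, ...] = (0.05, 0.1, 0.2),
    gabor_orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    k: int = 2,
    seed: int = 0,
    smoothing_sigma: float = 3.0,
    intensity_weight: float = 2.5,
) -> np.ndarray:
    """Texture segmentation by k-means over Gabor magnitude responses.

    The per-pixel feature vector stacks the Gaussian-smoothed magnitude of
    every (frequency x orientation) Gabor response with the pixel intensity.
    Channels are standardized; the intensity channel is then up-weighted by
    ``intensity_weight`` so that cluster assignment stays anchored to the
    CARS signal brightness while the filter bank refines boundaries (with
    unit weight the twelve texture channels swamp intensity and their
    spatial support smears small clusters).  After seeded k-means, clusters
    whose mean raw intensity exceeds the overall image mean are called
    plaque.
    """
    img = np.asarray(img).astype(np.float64)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(gabor_frequencies) == 0 or len(gabor_orientations) == 0:
        raise ValueError("Gabor filter bank must be non-empty")
    scale = img.max() if img.max() > 0 else 1.0
    norm = img / scale
    feats = []
    for f in gabor_frequencies:
        for theta_deg in gabor_orientations:
            real, imag = gabor(norm, frequency=f, theta=np.deg2rad(theta_deg))
            mag = np.hypot(real, imag)
            feats.append(ndi.gaussian_filter(mag, sigma=smoothing_sigma))
    feats.append(norm)
    X = np.stack([f.ravel() for f in feats], axis=1)
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("k exceeds the number of distinct feature vectors")
    # standardize features so intensity does not dominate the distance
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    Xs[:, -1] *= intensity_weight
    km = KMeans(n_clusters=k, n_init=4, random_state=int(seed) % _SEED_MOD)
    assign = km.fit_predict(Xs).reshape(img.shape)
    overall_mean = img.mean()
    mask = np.zeros(img.shape, dtype=bool)
    for c in range(k):
        sel = assign == c
        if img[sel].mean() > overall_mean:
            mask |= sel
    return mask


_SEED_MOD = 2**31 - 1


# ---------------------------------------------------------------------------
# Active-contour reference tracing and evaluation
# ---------------------------------------------------------------------------

def trace_reference(img: np.ndarray, init_mask: np.ndarray, n_iter: int = 50) -> np.ndarray:
    """Region-based (Chan–Vese-type) active-contour evolution of ``init_mask``.

    With ``n_iter == 0`` the initial mask is returned unchanged.  Raises for
    an empty initial mask.
    """
    img = np.asarray(img).astype(np.float64)
    init_mask = np.asarray(init_mask).astype(bool)
    if init_mask.shape != img.shape:
        raise ValueError("init_mask must match image dimensions")
    if not init_mask.any():
        raise ValueError("init_mask must be non-empty")
    if n_iter == 0:
        return init_mask.copy()
    out = morphological_chan_vese(
        img, num_iter=int(n_iter), init_level_set=init_mask.astype(np.int8),
        smoothing=1,
    )
    return out.astype(bool)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; 1.0 when both masks are empty."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("masks must have identical dimensions")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def label_components(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Connected-component labelling; ``connectivity`` is 4 or 8."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask).astype(bool)
    labels, n = _sk_label(
        mask, connectivity=1 if connectivity == 4 else 2, return_num=True
    )
    return labels, int(n)


def _otsu_mask(img, **kw):
    return otsu_segment(img, **kw)[1]


#: Registry of the four segmenters keyed by their short names.
SEGMENTERS = {
    "otsu": _otsu_mask,
    "ifct": ifct_segment,
    "mcw": mcw_segment,
    "kms": kms_segment,
}


def segment(img: np.ndarray, method: str = "otsu", **params) -> np.ndarray:
    """Dispatch to one of the four segmenters by name (otsu/ifct/mcw/kms)."""
    try:
        fn = SEGMENTERS[method]
    except KeyError as exc:
        raise ValueError(f"unknown segmentation method {method!r}") from exc
    return fn(img, **params)
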