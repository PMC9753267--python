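"""Gray-level co-occurrence matrices and the 17 Haralick texture statistics.

A co-occurrence matrix ``P(i, j)`` holds the probability that a pixel pair at
a fixed spatial offset takes quantized gray levels ``(i, j)``.  Accumulation
is symmetric (every pair is counted in both directions), so ``P`` is a
symmetric probability matrix.  From ``P`` and its marginal, sum (``i+j``) and
difference (``|i-j|``) distributions, seventeen standard second-order texture
statistics are derived.  All logarithms are natural with the ``0 log 0 = 0``
convention; gray-level indices are 1-based in the moment-type statistics
(autocorrelation, cluster shade/prominence, sum average, ...), matching the
classical formulations.

For masked texture extraction, a ``window_size x window_size`` window is slid
over every pixel whose centre lies in the mask (the image is mirror-padded at
its borders).  Per window the 17 statistics are computed at each offset and
averaged over offsets; the final value of each statistic is its mean over all
in-mask window centres.  The engine vectorizes this over thousands of windows
at once.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "TEXTURE_NAMES",
    "quantize",
    "angle_to_offset",
    "compute_glcm",
    "haralick_features",
    "masked_texture_features",
]

#: Canonical order of the 17 texture statistics.
TEXTURE_NAMES = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "dissimilarity",
    "energy",
    "entropy",
    "imc1",
    "imc2",
    "max_probability",
    "sum_average",
    "sum_entropy",
    "sum_of_squares_variance",
    "sum_variance",
    "homogeneity",
)

_EPS = 1e-12


def quantize(img: np.ndarray, levels: int = 32) -> np.ndarray:
    """Equal-width re-binning of an intensity image to ``levels`` gray levels.

    Bins span the image's own min–max range; a constant image maps to level 0.
    """
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    img = np.asarray(img).astype(np.float64)
    vmin, vmax = img.min(), img.max()
    if vmax <= vmin:
        return np.zeros(img.shape, dtype=np.int64)
    q = np.floor((img - vmin) / (vmax - vmin) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def angle_to_offset(distance: int, angle_deg: float) -> tuple[int, int]:
    """Map a (distance, angle) pair to a row/column pixel offset.

    Angles follow the usual GLCM convention: 0° → east, 45° → north-east,
    90° → north, 135° → north-west (rows increase downwards).
    """
    table = {0.0: (0, 1), 45.0: (-1, 1), 90.0: (-1, 0), 135.0: (-1, -1)}
    try:
        dy, dx = table[float(angle_deg) % 180.0]
    except KeyError as exc:
        raise ValueError(f"unsupported GLCM angle {angle_deg}") from exc
    return dy * distance, dx * distance


def compute_glcm(
    window: np.ndarray,
    offset: tuple[int, int] = (0, 1),
    levels: int = 32,
    symmetric: bool = True,
) -> np.ndarray:
    """Co-occurrence matrix of a quantized window at one pixel offset.

    ``window`` must already hold integer gray levels in ``[0, levels)``;
    ``offset`` is a ``(row, col)`` displacement (see ``angle_to_offset``).
    The matrix is normalized to sum to 1.  Raises if the window is smaller
    than the offset reach.
    """
    q = np.asarray(window)
    if q.ndim != 2:
        raise ValueError("window must be 2-D")
    if q.min() < 0 or q.max() >= levels:
        raise ValueError("window must be quantized to [0, levels)")
    dy, dx = offset
    h, w = q.shape
    if h <= abs(dy) or w <= abs(dx):
        raise ValueError("window smaller than the offset reach")
    a = q[max(0, -dy): h - max(0, dy), max(0, -dx): w - max(0, dx)]
    b = q[max(0, dy): h - max(0, -dy), max(0, dx): w - max(0, -dx)]
    P = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(P, (a.ravel(), b.ravel()), 1.0)
    if symmetric:
        P = P + P.T
    total = P.sum()
    if total > 0:
        P /= total
    return P


def _plogp(p: np.ndarray, axis=None) -> np.ndarray:
    """``sum(p * log(p))`` with the 0 log 0 = 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    return t.sum(axis=axis)


def haralick_features(P: np.ndarray) -> np.ndarray:
    """The 17 texture statistics of one or a stack of co-occurrence matrices.

    ``P`` has shape ``(L, L)`` or ``(n, L, L)`` with each matrix summing to 1.
    Returns an array of shape ``(17,)`` or ``(n, 17)`` in ``TEXTURE_NAMES``
    order.  Degenerate matrices (zero marginal variance or entropy) yield the
    documented limits: correlation 0, IMC1 0, IMC2 0.
    """
    P = np.asarray(P, dtype=np.float64)
    single = P.ndim == 2
    if single:
        P = P[None]
    n, L, L2 = P.shape
    if L != L2:
        raise ValueError("co-occurrence matrices must be square")

    I = np.arange(1, L + 1, dtype=np.float64)  # 1-based gray levels
    ii = I[:, None] * np.ones((1, L))
    jj = ii.T

    px = P.sum(axis=2)  # (n, L)
    py = P.sum(axis=1)
    mux = px @ I
    muy = py @ I
    varx = px @ (I**2) - mux**2
    vary = py @ (I**2) - muy**2
    sigx = np.sqrt(np.clip(varx, 0.0, None))
    sigy = np.sqrt(np.clip(vary, 0.0, None))

    # sum (i+j) and difference |i-j| distributions
    Pf = P[:, :, ::-1]
    psum = np.stack(
        [np.trace(Pf, offset=o, axis1=1, axis2=2) for o in range(L - 1, -L, -1)],
        axis=1,
    )  # (n, 2L-1), entry k corresponds to i + j = k + 2 (1-based levels)
    ksum = np.arange(2, 2 * L + 1, dtype=np.float64)
    pdiff = np.empty((n, L))
    pdiff[:, 0] = np.trace(P, axis1=1, axis2=2)
    for d in range(1, L):
        pdiff[:, d] = np.trace(P, offset=d, axis1=1, axis2=2) + np.trace(
            P, offset=-d, axis1=1, axis2=2
        )
    # (symmetric P makes the two traces equal; summing keeps this general)

    w_contrast = (ii - jj) ** 2
    w_dissim = np.abs(ii - jj)
    w_homog = 1.0 / (1.0 + (ii - jj) ** 2)
    w_auto = ii * jj

    autocorrelation = np.einsum("nij,ij->n", P, w_auto)
    contrast = np.einsum("nij,ij->n", P, w_contrast)
    dissimilarity = np.einsum("nij,ij->n", P, w_dissim)
    homogeneity = np.einsum("nij,ij->n", P, w_homog)
    energy = np.einsum("nij,nij->n", P, P)
    entropy = -_plogp(P, axis=(1, 2))
    max_probability = P.max(axis=(1, 2))

    # cluster shade/prominence are central moments of u = i + j about
    # m = mux + muy; expand binomially over the sum distribution
    m1 = (psum * ksum).sum(axis=1)
    m2 = (psum * ksum**2).sum(axis=1)
    m3 = (psum * ksum**3).sum(axis=1)
    m4 = (psum * ksum**4).sum(axis=1)
    mu_u = mux + muy
    cluster_shade = m3 - 3 * mu_u * m2 + 3 * mu_u**2 * m1 - mu_u**3
    cluster_prominence = m4 - 4 * mu_u * m3 + 6 * mu_u**2 * m2 - 4 * mu_u**3 * m1 + mu_u**4

    cov = autocorrelation - mux * muy
    denom = sigx * sigy
    correlation = np.where(denom > _EPS, cov / np.where(denom > _EPS, denom, 1.0), 0.0)

    sum_average = m1
    sum_entropy = -_plogp(psum, axis=1)
    sum_variance = m2 - m1**2
    difference_entropy = -_plogp(pdiff, axis=1)
    sum_of_squares_variance = varx

    hx = -_plogp(px, axis=1)
    hy = -_plogp(py, axis=1)
    # HXY1 = -sum P log(px py) and HXY2 = -sum px py log(px py) both reduce
    # to HX + HY, since P and the product measure share their marginals
    hxy1 = hx + hy
    hxy2 = hx + hy
    hmax = np.maximum(hx, hy)
    imc1 = np.where(hmax > _EPS, (entropy - hxy1) / np.where(hmax > _EPS, hmax, 1.0), 0.0)
    imc2 = np.sqrt(np.clip(1.0 - np.exp(-2.0 * (hxy2 - entropy)), 0.0, None))
    imc2 = np.where(hmax > _EPS, imc2, 0.0)

    out = np.stack(
        [
            autocorrelation,
            cluster_prominence,
            cluster_shade,
            contrast,
            correlation,
            difference_entropy,
            dissimilarity,
            energy,
            entropy,
            imc1,
            imc2,
            max_probability,
            sum_average,
            sum_entropy,
            sum_of_squares_variance,
            sum_variance,
            homogeneity,
        ],
        axis=1,
    )
    return out[0] if single else out


def masked_texture_features(
    img: np.ndarray,
    mask: np.ndarray,
    window_size: int = 9,
    levels: int = 32,
    distance: int = 1,
    angles: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    chunk: int = 4096,
) -> np.ndarray:
    """Window-averaged texture statistics over a masked region.

    Slides a ``window_size``-square window over every in-mask pixel (image
    mirror-padded at the borders), computes the 17 statistics at each offset
    per window, averages them over the offsets, and returns the mean over all
    window centres (shape ``(17,)``, ``TEXTURE_NAMES`` order).
    """
    img = np.asarray(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise ValueError("mask must match image dimensions")
    if not mask.any():
        raise ValueError("mask is empty")
    if window_size < 3 or window_size % 2 == 0:
        raise ValueError("window_size must be odd and >= 3")
    half = window_size // 2
    q = np.pad(quantize(img, levels), half, mode="reflect")
    ys, xs = np.nonzero(mask)
    n = ys.size

    totals = np.zeros(len(TEXTURE_NAMES), dtype=np.float64)
    offsets = [angle_to_offset(distance, a) for a in angles]
    for start in range(0, n, chunk):
        cy = ys[start:start + chunk]
        cx = xs[start:start + chunk]
        m = cy.size
        acc = np.zeros((m, len(TEXTURE_NAMES)), dtype=np.float64)
        for dy, dx in offsets:
            hh = window_size - abs(dy)
            ww = window_size - abs(dx)
            # anchor map of pair codes: pairs (p, p+offset) both inside image
            a = q[max(0, -dy): q.shape[0] - max(0, dy),
                  max(0, -dx): q.shape[1] - max(0, dx)]
            b = q[max(0, dy): q.shape[0] - max(0, -dy),
                  max(0, dx): q.shape[1] - max(0, -dx)]
            codes = a * levels + b
            # for a window centred at padded (cy+half, cx+half) the valid
            # anchors form an (hh, ww) block starting at (cy, cx) in code space
            blocks = sliding_window_view(codes, (hh, ww))[cy, cx].reshape(m, hh * ww)
            flat = (np.arange(m)[:, None] * (levels * levels) + blocks).ravel()
            counts = np.bincount(flat, minlength=m * levels * levels).astype(np.float64)
            P = counts.reshape(m, levels, levels)
            P = P + P.transpose(0, 2, 1)  # symmetric accumulation
            P /= P.sum(axis=(1, 2), keepdims=True)
            acc += haralick_features(P)
        acc /= len(offsets)
        totals += acc.sum(axis=0)
    return totals / n
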