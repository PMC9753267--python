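"""Independent brute-force reference implementations used only by the tests.

Each oracle deliberately avoids the code paths of the package: explicit
double loops, exhaustive enumeration and direct formula evaluation, so that
agreement with the vectorized implementations is meaningful.
"""

import numpy as np


def exhaustive_otsu(values, n_bins=256):
    """Best threshold by directly partitioning the binned pixel multiset.

    Enumerates every histogram split point, computes the two-class weights
    and means from the raw values assigned to each side, and returns the
    centre of the split bin maximizing the between-class variance.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    assert vmax > vmin
    edges = np.linspace(vmin, vmax, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # assign each value to its bin, as np.histogram does
    bins = np.minimum(np.searchsorted(edges, values, side="right") - 1, n_bins - 1)
    best_sigma, best_thr = -1.0, None
    for split in range(n_bins - 1):  # classes: bins <= split / bins > split
        lo = values[bins <= split]
        hi = values[bins > split]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / values.size
        w1 = 1.0 - w0
        # class means over bin centres, mirroring the histogram formulation
        mu0 = centers[bins[bins <= split]].mean()
        mu1 = centers[bins[bins > split]].mean()
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_thr = sigma, centers[split]
    return best_thr


def naive_haralick(P):
    """The 17 texture statistics by direct double-loop formula evaluation."""
    P = np.asarray(P, dtype=float)
    L = P.shape[0]
    I = np.arange(1, L + 1, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((px * I).sum())
    muy = float((py * I).sum())
    sigx = float(np.sqrt((px * (I - mux) ** 2).sum()))
    sigy = float(np.sqrt((py * (I - muy) ** 2).sum()))

    auto = contrast = dissim = homog = energy = entropy = 0.0
    shade = prom = cov = 0.0
    maxp = 0.0
    psum = np.zeros(2 * L - 1)
    pdiff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            a, b = i + 1.0, j + 1.0
            auto += a * b * p
            contrast += (a - b) ** 2 * p
            dissim += abs(a - b) * p
            homog += p / (1.0 + (a - b) ** 2)
            energy += p * p
            if p > 0:
                entropy -= p * np.log(p)
            shade += (a + b - mux - muy) ** 3 * p
            prom += (a + b - mux - muy) ** 4 * p
            cov += (a - mux) * (b - muy) * p
            maxp = max(maxp, p)
            psum[int(a + b) - 2] += p
            pdiff[abs(i - j)] += p
    correlation = cov / (sigx * sigy) if sigx * sigy > 1e-12 else 0.0
    ks = np.arange(2, 2 * L + 1, dtype=float)
    sum_average = float((ks * psum).sum())
    sum_entropy = -sum(p * np.log(p) for p in psum if p > 0)
    sum_variance = float(((ks - sum_average) ** 2 * psum).sum())
    diff_entropy = -sum(p * np.log(p) for p in pdiff if p > 0)
    ssv = float((px * (I - mux) ** 2).sum())
    hx = -sum(p * np.log(p) for p in px if p > 0)
    hy = -sum(p * np.log(p) for p in py if p > 0)
    hxy1 = hxy2 = 0.0
    for i in range(L):
        for j in range(L):
            q = px[i] * py[j]
            if q > 0:
                hxy1 += -P[i, j] * np.log(q)
                hxy2 += -q * np.log(q)
    hmax = max(hx, hy)
    imc1 = (entropy - hxy1) / hmax if hmax > 1e-12 else 0.0
    imc2 = (
        float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))
        if hmax > 1e-12
        else 0.0
    )
    return np.array([
        auto, prom, shade, contrast, correlation, diff_entropy, dissim,
        energy, entropy, imc1, imc2, maxp, sum_average, sum_entropy, ssv,
        sum_variance, homog,
    ])


def naive_glcm(window, offset, levels):
    """Symmetric co-occurrence counting by explicit pair enumeration."""
    q = np.asarray(window)
    dy, dx = offset
    h, w = q.shape
    P = np.zeros((levels, levels))
    for y in range(h):
        for x in range(w):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w:
                P[q[y, x], q[yy, xx]] += 1
                P[q[yy, xx], q[y, x]] += 1
    if P.sum() > 0:
        P /= P.sum()
    return P


def naive_chi2(bins, labels):
    """Chi-square statistic of a contingency table by direct formula."""
    bins = np.asarray(bins)
    labels = np.asarray(labels)
    bvals = np.unique(bins)
    lvals = np.unique(labels)
    n = bins.size
    stat = 0.0
    for b in bvals:
        for l in lvals:
            observed = float(np.sum((bins == b) & (labels == l)))
            expected = float(np.sum(bins == b) * np.sum(labels == l)) / n
            if expected > 0:
                stat += (observed - expected) ** 2 / expected
    return stat


def boundary_walk_perimeter(mask):
    """Crude contour-length estimate by walking 8-connected boundary pixels.

    For every boundary pixel, adds the distance to the next boundary pixel
    along the contour (1 for axial steps, sqrt(2) for diagonal steps).
    Suitable only as an independent ~10% sanity bound on smooth shapes.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    padded = np.zeros((h + 2, w + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    boundary = set()
    for y in range(1, h + 1):
        for x in range(1, w + 1):
            if padded[y, x] and not (
                padded[y - 1, x] and padded[y + 1, x]
                and padded[y, x - 1] and padded[y, x + 1]
            ):
                boundary.add((y, x))
    if not boundary:
        return 0.0
    # greedy walk over the boundary set
    length = 0.0
    start = min(boundary)
    current = start
    visited = {start}
    steps = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    while True:
        nxt = None
        for dy, dx in steps:
            cand = (current[0] + dy, current[1] + dx)
            if cand in boundary and cand not in visited:
                nxt = cand
                length += np.hypot(dy, dx)
                break
        if nxt is None:
            length += np.hypot(start[0] - current[0], start[1] - current[1])
            break
        visited.add(nxt)
        current = nxt
    return length


def gaussian_blur_reference(img, sigma, truncate=4.0):
    """Separable Gaussian convolution with reflect padding, built from scratch."""
    img = np.asarray(img, dtype=float)
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()

    def conv_axis(a, axis):
        a = np.moveaxis(a, axis, 0)
        padded = np.concatenate([a[radius - 1::-1], a, a[:-radius - 1:-1]], axis=0)
        out = np.empty_like(a)
        for i in range(a.shape[0]):
            window = padded[i:i + 2 * radius + 1]
            out[i] = np.tensordot(kernel, window, axes=(0, 0))
        return np.moveaxis(out, 0, axis)

    return conv_axis(conv_axis(img, 0), 1)


def metrics_from_confusion(cm, labels):
    """Per-class accuracy/precision/recall/F1 by direct formula evaluation."""
    cm = np.asarray(cm, dtype=float)
    out = {}
    for i, lab in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        rec = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[lab] = {"accuracy": rec, "precision": prec, "recall": rec, "f1": f1}
    return out
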