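import numpy as np
import pytest
from skimage.filters import threshold_otsu as sk_threshold_otsu

from plaquekit import (
    dice,
    generate_phantom,
    ifct_segment,
    kms_segment,
    label_components,
    mcw_segment,
    otsu_segment,
    otsu_threshold,
    preprocess_image,
    trace_reference,
)

from oracles import exhaustive_otsu


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def test_otsu_two_valued_image():
    img = np.concatenate([np.full(50, 10), np.full(50, 200)]).reshape(10, 10)
    thr, mask = otsu_segment(img)
    assert 10 < thr < 200
    assert np.array_equal(mask, img == 200)


def test_otsu_small_multiset_matches_exhaustive_search():
    img = np.array([[1, 1, 2], [8, 9, 9]])
    thr = otsu_threshold(img)
    assert thr == pytest.approx(exhaustive_otsu(img))
    _, mask = otsu_segment(img)
    assert np.array_equal(mask, img > thr)


def test_otsu_matches_exhaustive_oracle_on_random_images():
    rng = np.random.default_rng(0)
    for _ in range(100):
        img = rng.integers(0, 4000, size=(16, 16))
        assert otsu_threshold(img) == pytest.approx(exhaustive_otsu(img))


def test_otsu_agrees_with_skimage_within_one_bin():
    rng = np.random.default_rng(1)
    for _ in range(20):
        img = rng.normal(20000, 4000, size=(32, 32)).clip(0, 65535)
        img[8:16, 8:16] += 25000
        bin_width = (img.max() - img.min()) / 256
        assert abs(otsu_threshold(img) - sk_threshold_otsu(img)) <= bin_width


def test_otsu_separates_two_gaussians_with_low_error():
    rng = np.random.default_rng(2)
    n = 10_000
    lo = rng.normal(1000, 500, n)
    hi = rng.normal(40000, 500, n)
    img = np.concatenate([lo, hi]).clip(0, 65535).reshape(200, 100)
    truth = np.concatenate([np.zeros(n, bool), np.ones(n, bool)]).reshape(200, 100)
    _, mask = otsu_segment(img)
    assert (mask != truth).mean() < 0.01


def test_otsu_constant_image_raises():
    with pytest.raises(ValueError):
        otsu_threshold(np.full((8, 8), 7))


# ---------------------------------------------------------------------------
# IFCT
# ---------------------------------------------------------------------------

def _blob(shape, cy, cx, r, amp):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return np.where(d2 <= r * r, amp, 0.0)


def test_ifct_segments_dim_blob_missed_by_global_otsu():
    """Two blobs at 60000 and 8000 on background 500: global Otsu keeps only
    the bright one; IFCT re-thresholds each candidate locally and finds both."""
    rng = np.random.default_rng(3)
    img = np.full((80, 80), 500.0) + rng.normal(0, 50, (80, 80))
    img += _blob((80, 80), 20, 20, 8, 60000) + _blob((80, 80), 60, 60, 8, 8000)
    img = img.clip(0, 65535)
    _, global_mask = otsu_segment(img)
    _, n_global = label_components(global_mask, 8)
    assert n_global == 1  # the dim blob is lost globally
    mask = ifct_segment(img, candidate_quantile=0.9, min_area=10)
    _, n = label_components(mask, 8)
    assert n == 2


def test_ifct_blank_image_gives_empty_mask():
    rng = np.random.default_rng(4)
    img = (1500 + rng.normal(0, 300, (64, 64))).clip(0, 65535)
    assert not ifct_segment(img).any()


def test_ifct_invalid_quantile_rejected():
    with pytest.raises(ValueError):
        ifct_segment(np.zeros((8, 8)), candidate_quantile=1.5)


# ---------------------------------------------------------------------------
# MCW
# ---------------------------------------------------------------------------

def test_mcw_recovers_single_blob(phantom_config):
    rec = generate_phantom(phantom_config.with_stage("AA", n_blobs_mean=1,
                                                     n_blobs_sd=0), "AA", 11)
    img = preprocess_image(rec.image)
    mask = mcw_segment(img)
    assert dice(mask, rec.truth_mask) >= 0.8


def test_mcw_splits_twin_peaks():
    rng = np.random.default_rng(5)
    img = np.full((60, 60), 1000.0) + rng.normal(0, 100, (60, 60))
    yy, xx = np.mgrid[0:60, 0:60]
    for cx in (22, 38):
        d2 = (yy - 30) ** 2 + (xx - cx) ** 2
        img += 30000 * np.exp(-d2 / (2 * 5.0**2))
    img = img.clip(0, 65535)
    basins = mcw_segment(img, marker_min_distance=5, return_basins=True)
    labels = set(np.unique(basins)) - {0}
    assert len(labels) >= 2  # the overlapping blobs end in separate basins
    mask = mcw_segment(img, marker_min_distance=5)
    assert mask.any()


def test_mcw_constant_image_empty():
    assert not mcw_segment(np.full((32, 32), 9)).any()


# ---------------------------------------------------------------------------
# KMS
# ---------------------------------------------------------------------------

def test_kms_deterministic_and_accurate(phantom_config):
    rec = generate_phantom(phantom_config, "AA", 21)
    img = preprocess_image(rec.image)
    a = kms_segment(img, seed=3)
    b = kms_segment(img, seed=3)
    assert np.array_equal(a, b)
    assert dice(a, rec.truth_mask) >= 0.8


def test_kms_k1_degenerate_and_bad_k_rejected():
    rng = np.random.default_rng(6)
    img = rng.integers(0, 65536, (32, 32)).astype(float)
    mask = kms_segment(img, k=1, seed=0)
    assert mask.all() or not mask.any()
    with pytest.raises(ValueError):
        kms_segment(np.zeros((4, 4)), k=30, seed=0)


# ---------------------------------------------------------------------------
# Active contour reference, Dice, labelling
# ---------------------------------------------------------------------------

def _sharp_disc(shape=(96, 96), r=20, amp=40000, bg=2000, seed=0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    truth = (yy - shape[0] // 2) ** 2 + (xx - shape[1] // 2) ** 2 <= r * r
    rng = np.random.default_rng(seed)
    img = np.where(truth, amp, bg) + rng.normal(0, 300, shape)
    return img.clip(0, 65535).astype(np.uint16), truth


def test_trace_reference_contracts_to_sharp_boundary():
    from scipy.ndimage import binary_dilation

    img, truth = _sharp_disc()
    init = binary_dilation(truth, iterations=4)
    out = trace_reference(img, init, n_iter=60)
    assert dice(out, truth) >= 0.95


def test_trace_reference_fixed_point_and_degenerate_cases():
    img, truth = _sharp_disc(seed=1)
    out = trace_reference(img, truth, n_iter=30)
    assert dice(out, truth) >= 0.99
    assert np.array_equal(trace_reference(img, truth, n_iter=0), truth)
    with pytest.raises(ValueError):
        trace_reference(img, np.zeros_like(truth), n_iter=5)


def test_dice_closed_forms_and_errors():
    a = np.zeros((10, 10), bool)
    a[:5] = True
    assert dice(a, a) == 1.0
    b = np.zeros((10, 10), bool)
    b[5:] = True
    assert dice(a, b) == 0.0
    c = np.zeros((10, 10), bool)
    c[:, :5] = True  # |a|=|b|=50, overlap 25 -> 2*25/100
    assert dice(a, c) == pytest.approx(0.5)
    assert dice(np.zeros((3, 3), bool), np.zeros((3, 3), bool)) == 1.0
    with pytest.raises(ValueError):
        dice(a, np.zeros((5, 5), bool))


def test_dice_symmetric_and_bounded():
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = rng.random((12, 12)) > 0.6
        b = rng.random((12, 12)) > 0.6
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)


def test_label_components_connectivity():
    empty = np.zeros((6, 6), bool)
    assert label_components(empty, 8)[1] == 0
    squares = np.zeros((10, 10), bool)
    for off in (0, 4, 8):
        squares[off:off + 2, off:off + 2] = True
    assert label_components(squares, 8)[1] == 3
    diag = np.zeros((4, 4), bool)
    diag[1, 1] = diag[2, 2] = True
    assert label_components(diag, 8)[1] == 1
    assert label_components(diag, 4)[1] == 2
    with pytest.raises(ValueError):
        label_components(diag, 6)


def test_segmenters_mean_dice_on_strong_separation_preset(phantom_config):
    """Otsu, MCW and KMS all reach mean Dice >= 0.7 over >= 50 phantoms."""
    from plaquekit import generate_dataset, segment

    records = generate_dataset(phantom_config, {"EFS": 17, "EF": 17, "AA": 17},
                               seed=77)
    scores = {m: [] for m in ("otsu", "mcw", "kms")}
    for rec in records:
        img = preprocess_image(rec.image)
        for m in scores:
            kwargs = {"seed": 0} if m == "kms" else {}
            mask = segment(img, method=m, **kwargs)
            scores[m].append(dice(mask, rec.truth_mask))
    for m, vals in scores.items():
        assert len(vals) >= 50
        assert np.mean(vals) >= 0.7, f"{m} mean Dice {np.mean(vals):.3f}"
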