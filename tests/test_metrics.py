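"""Metric implementations against brute-force evaluations of their formulas."""

import math
import warnings

import numpy as np
import pytest

from ossr.metrics import (MetricConfig, evaluate_pairs, nmi, psnr, rmse,
                          slice_metrics, ssim, to_metric_scale)


# ---------------------------------------------------------------- oracles

def brute_rmse(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return math.sqrt(total / a.size)


def brute_ssim(a, b, w=7, L=255.0, k1=0.01, k2=0.03):
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    n = w * w
    vals = []
    for i in range(a.shape[0] - w + 1):
        for j in range(a.shape[1] - w + 1):
            wa = a[i:i + w, j:j + w].ravel()
            wb = b[i:i + w, j:j + w].ravel()
            ua, ub = wa.mean(), wb.mean()
            va = ((wa - ua) ** 2).sum() / (n - 1)
            vb = ((wb - ub) ** 2).sum() / (n - 1)
            vab = ((wa - ua) * (wb - ub)).sum() / (n - 1)
            vals.append(((2 * ua * ub + c1) * (2 * vab + c2))
                        / ((ua ** 2 + ub ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


def brute_nmi(a, b, bins, lo, hi, variant):
    joint = np.zeros((bins, bins))
    scale = bins / (hi - lo)
    for x, y in zip(a.ravel(), b.ravel()):
        bi = min(int((x - lo) * scale), bins - 1)
        bj = min(int((y - lo) * scale), bins - 1)
        joint[bi, bj] += 1
    p = joint / joint.sum()

    def ent(q):
        q = q[q > 0]
        return -(q * np.log(q)).sum()

    hx, hy, hxy = ent(p.sum(1)), ent(p.sum(0)), ent(p.ravel())
    if variant == "studholme":
        return (hx + hy) / hxy
    return 2 * (hx + hy - hxy) / (hx + hy)


# ------------------------------------------------------------- unit tests

def test_rmse_closed_forms():
    a = np.zeros((2, 2))
    b = np.array([[3.0, 4.0], [0.0, 0.0]])
    assert rmse(a, b) == pytest.approx(2.5)
    assert rmse(a, a) == 0.0
    assert rmse(a, a + 7.0) == pytest.approx(7.0)


def test_rmse_shape_mismatch():
    with pytest.raises(ValueError):
        rmse(np.zeros((2, 2)), np.zeros((3, 3)))


def test_psnr_identities():
    a = np.zeros((4, 4))
    b = a + 255.0
    assert psnr(a, b, 255.0) == pytest.approx(0.0)          # rmse == L
    c = a + 10.0
    d = a + 5.0
    assert psnr(a, d, 255.0) - psnr(a, c, 255.0) == pytest.approx(
        20 * math.log10(2))                                 # halving rmse: +6.02 dB
    with pytest.warns(RuntimeWarning):
        assert psnr(a, a) == math.inf


def test_ssim_identical_and_symmetric(rng):
    a = rng.uniform(0, 255, (16, 16))
    b = rng.uniform(0, 255, (16, 16))
    assert ssim(a, a) == pytest.approx(1.0)
    assert ssim(a, b) == pytest.approx(ssim(b, a), rel=1e-12)


def test_ssim_constant_images_closed_form():
    # constant 0 vs constant L: luminance term only, C1/(L^2+C1)
    L = 255.0
    a = np.zeros((8, 8))
    b = np.full((8, 8), L)
    expect = (0.01 * L) ** 2 / (L ** 2 + (0.01 * L) ** 2)
    assert ssim(a, b) == pytest.approx(expect, rel=1e-12)
    assert expect == pytest.approx(9.999e-5, rel=1e-3)


def test_ssim_rejects_window_larger_than_image():
    with pytest.raises(ValueError):
        ssim(np.zeros((4, 4)), np.zeros((4, 4)))


def test_metrics_match_brute_force_on_random_grids(rng):
    for _ in range(5):
        a = rng.uniform(0, 255, (8, 8))
        b = a + rng.normal(0, 20, (8, 8))
        assert rmse(a, b) == pytest.approx(brute_rmse(a, b), rel=1e-9)
        assert ssim(a, b) == pytest.approx(brute_ssim(a, b), rel=1e-9)
        assert psnr(a, b) == pytest.approx(
            20 * math.log10(255.0) - 20 * math.log10(rmse(a, b)), rel=1e-12)
        bc = np.clip(b, 0.0, 255.0)  # histogram range is the display range
        cfg = MetricConfig(nmi_bins=8)
        assert nmi(a, bc, cfg) == pytest.approx(
            brute_nmi(a, bc, 8, 0.0, 255.0, "symmetric_uncertainty"), rel=1e-9)
        scfg = MetricConfig(nmi_bins=8, nmi_variant="studholme")
        assert nmi(a, bc, scfg) == pytest.approx(
            brute_nmi(a, bc, 8, 0.0, 255.0, "studholme"), rel=1e-9)


def test_ssim_agrees_with_skimage(rng):
    from skimage.metrics import structural_similarity

    a = rng.uniform(0, 255, (32, 32))
    b = np.clip(a + rng.normal(0, 15, a.shape), 0, 255)
    ref = structural_similarity(a, b, win_size=7, data_range=255.0,
                                gaussian_weights=False)
    assert ssim(a, b) == pytest.approx(ref, rel=1e-7)


def test_nmi_studholme_agrees_with_skimage(rng):
    from skimage.metrics import normalized_mutual_information

    a = rng.integers(0, 256, (64, 64)).astype(float)
    b = np.clip(a + rng.normal(0, 30, a.shape), 0, 255)
    cfg = MetricConfig(nmi_bins=64, nmi_variant="studholme")
    ref = normalized_mutual_information(
        np.clip((a / 4).astype(int), 0, 63), np.clip((b / 4).astype(int), 0, 63),
        bins=64)
    assert nmi(a, b, cfg) == pytest.approx(ref, rel=2e-2)


def test_nmi_ideal_and_independent(rng):
    a = rng.integers(0, 256, (64, 64)).astype(float)
    assert nmi(a, a) == pytest.approx(1.0)
    assert nmi(a, a, MetricConfig(nmi_variant="studholme")) == pytest.approx(2.0)
    b = rng.integers(0, 256, (64, 64)).astype(float)  # independent
    assert nmi(a, b, MetricConfig(nmi_bins=8)) < 0.05


def test_nmi_invariant_under_monotone_relabeling(rng):
    cfg = MetricConfig(nmi_bins=8)
    a = rng.integers(0, 8, (32, 32)).astype(float) * 32.0   # bin centers
    b = rng.integers(0, 8, (32, 32)).astype(float) * 32.0
    base = nmi(a, b, cfg)
    # strictly monotone relabeling keeping one value per histogram bin
    new_centers = np.array([0.0, 40.0, 72.0, 104.0, 136.0, 168.0, 200.0, 248.0])
    relabeled = new_centers[(a / 32.0).astype(int)]
    assert nmi(relabeled, b, cfg) == pytest.approx(base, rel=1e-12)


def test_nmi_decreases_with_added_noise(rng):
    a = rng.integers(0, 256, (64, 64)).astype(float)
    cfg = MetricConfig(nmi_bins=16)
    vals = [nmi(a, np.clip(a + rng.normal(0, s, a.shape), 0, 255), cfg)
            for s in (5, 20, 60)]
    assert vals[0] > vals[1] > vals[2]


def test_nmi_constant_image_degenerate():
    a = np.zeros((8, 8))
    with pytest.warns(RuntimeWarning):
        assert nmi(a, a) == 1.0
    with pytest.warns(RuntimeWarning):
        assert nmi(a, np.arange(64, dtype=float).reshape(8, 8)) == 0.0


def test_evaluate_pairs_aggregation():
    target = np.zeros((8, 8), dtype=int)
    # per-slice RMSE on the metric scale is |c|*255/65025 for constant offset c
    def img(c):
        return np.full((8, 8), c, dtype=int)

    entries = [
        ("p1", 0, "M", img(255), target),   # metric-scale rmse 1
        ("p1", 1, "M", img(765), target),   # 3
        ("p2", 0, "M", img(1275), target),  # 5
        ("p2", 1, "M", img(1785), target),  # 7
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant images: degenerate nmi
        report = evaluate_pairs(entries)
    means = report.rows.groupby("patient_id")["rmse"].mean()
    assert means["p1"] == pytest.approx(2.0)
    assert means["p2"] == pytest.approx(6.0)
    assert report.summary.loc["M", ("rmse", "mean")] == pytest.approx(4.0)
    assert len(report.rows) == 4


def test_evaluate_pairs_flags_missing_output():
    target = np.zeros((8, 8), dtype=int)
    entries = [("p", 0, "M", np.ones((8, 8), dtype=int), target),
               ("p", 1, "M", None, target)]
    with pytest.warns(RuntimeWarning):
        report = evaluate_pairs(entries)
    assert report.rows["missing"].sum() == 1
    assert len(report.rows) == 2


def test_slice_metrics_ideal_values(phantom_pair):
    img = phantom_pair.pair.planct_reg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = slice_metrics(img, img)
    assert vals["rmse"] == 0.0
    assert vals["psnr"] == math.inf
    assert vals["ssim"] == pytest.approx(1.0)
    assert vals["nmi"] == pytest.approx(1.0)


def test_metric_scale_rescaling():
    img = np.array([[0, 65025]], dtype=int)
    assert to_metric_scale(img).tolist() == [[0.0, 255.0]]
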