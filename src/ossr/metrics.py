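"""Image-similarity metrics (RMSE, PSNR, SSIM, NMI) and the per-patient report.

All four metrics are evaluated on the display images rescaled from
``[0, 65025]`` to ``[0, 255]`` (real-valued, no re-rounding) with dynamic
range ``L = 255``.  This dialect reproduces the internal RMSE↔PSNR relation of
the reported patient means (``20·log10(255/11.70) = 26.77 dB`` against a mean
PSNR of 26.85).

NMI defaults to the symmetric-uncertainty normalisation
``2·I(A;B)/(H(A)+H(B)) ∈ [0,1]``; the Studholme variant
``(H(A)+H(B))/H(A,B) ∈ [1,2]`` is selectable.  Joint histograms are binned
over the fixed display range, not per-image extrema, so values are comparable
across methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .gradation import DISPLAY_MAX

#: display-to-metric rescale: [0, 65025] -> [0, 255]
METRIC_SCALE = 255.0


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class MetricConfig:
    psnr_max: float = 255.0
    ssim_window: int = 7
    ssim_k1: float = 0.01
    ssim_k2: float = 0.03
    ssim_gaussian: bool = False  # alternative 11x11 Gaussian (sigma 1.5) dialect
    nmi_bins: int = 256
    nmi_variant: str = "symmetric_uncertainty"  # or "studholme"

    def __post_init__(self) -> None:
        if self.psnr_max <= 0:
            raise MetricError("psnr_max must be > 0")
        if self.ssim_window < 3 or self.ssim_window % 2 == 0:
            raise MetricError("ssim_window must be odd and >= 3")
        if self.nmi_bins < 2:
            raise MetricError("nmi_bins must be >= 2")
        if self.nmi_variant not in ("symmetric_uncertainty", "studholme"):
            raise MetricError(f"unknown nmi_variant {self.nmi_variant!r}")


def to_metric_scale(img: np.ndarray) -> np.ndarray:
    """Rescale a display image to the [0, 255] metric scale (float, no rounding)."""
    return np.asarray(img, dtype=np.float64) * (METRIC_SCALE / DISPLAY_MAX)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise MetricError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square difference: sqrt(mean((a-b)^2))."""
    a, b = _check_shapes(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a: np.ndarray, b: np.ndarray, max_value: float = METRIC_SCALE) -> float:
    """Peak signal-to-noise ratio in dB: ``20·log10(L / rmse)``.

    Identical images yield ``inf`` (flagged by a warning).
    """
    r = rmse(a, b)
    if r == 0.0:
        warnings.warn("psnr of identical images is infinite", RuntimeWarning,
                      stacklevel=2)
        return math.inf
    return 20.0 * math.log10(max_value / r)


def ssim(a: np.ndarray, b: np.ndarray, cfg: MetricConfig | None = None) -> float:
    """Mean local structural similarity over sliding windows.

    Uniform window (default 7x7), unbiased covariance, stabilizers
    ``C1=(k1·L)^2`` and ``C2=(k2·L)^2``; symmetric in its arguments and 1.0
    iff the images are identical.
    """
    cfg = cfg or MetricConfig()
    a, b = _check_shapes(a, b)
    if cfg.ssim_gaussian:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5, win_size=11,
            use_sample_covariance=False, data_range=cfg.psnr_max))
    w = cfg.ssim_window
    if min(a.shape) < w:
        raise MetricError(f"image side smaller than ssim_window={w}")
    L = cfg.psnr_max
    c1, c2 = (cfg.ssim_k1 * L) ** 2, (cfg.ssim_k2 * L) ** 2
    n = w * w
    cov_norm = n / (n - 1)  # unbiased

    wa = sliding_window_view(a, (w, w)).reshape(-1, n)
    wb = sliding_window_view(b, (w, w)).reshape(-1, n)
    ua, ub = wa.mean(axis=1), wb.mean(axis=1)
    va = cov_norm * (np.mean(wa * wa, axis=1) - ua * ua)
    vb = cov_norm * (np.mean(wb * wb, axis=1) - ub * ub)
    vab = cov_norm * (np.mean(wa * wb, axis=1) - ua * ub)
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / ((ua * ua + ub * ub + c1) * (va + vb + c2))
    return float(s.mean())


def _joint_histogram(a: np.ndarray, b: np.ndarray, bins: int,
                     value_range: tuple[float, float]) -> np.ndarray:
    h, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins,
                             range=[value_range, value_range])
    return h


def nmi(a: np.ndarray, b: np.ndarray, cfg: MetricConfig | None = None,
        value_range: tuple[float, float] = (0.0, METRIC_SCALE)) -> float:
    """Normalized mutual information from a joint histogram over the fixed range.

    ``symmetric_uncertainty``: ``2·I/(H(A)+H(B))`` in [0, 1];
    ``studholme``: ``(H(A)+H(B))/H(A,B)`` in [1, 2].
    A constant image has zero entropy; that degenerate case returns the ideal
    value when the images are identical, else the minimal one, with a warning.
    """
    cfg = cfg or MetricConfig()
    a, b = _check_shapes(a, b)
    joint = _joint_histogram(a, b, cfg.nmi_bins, value_range)
    pxy = joint / joint.sum()
    px, py = pxy.sum(axis=1), pxy.sum(axis=0)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))

    hx, hy, hxy = entropy(px), entropy(py), entropy(pxy.ravel())
    if hx == 0.0 or hy == 0.0:
        warnings.warn("constant image in nmi: zero marginal entropy",
                      RuntimeWarning, stacklevel=2)
        same = np.array_equal(a, b)
        if cfg.nmi_variant == "symmetric_uncertainty":
            return 1.0 if same else 0.0
        return 2.0 if same else 1.0
    mi = hx + hy - hxy
    if cfg.nmi_variant == "symmetric_uncertainty":
        return float(2.0 * mi / (hx + hy))
    return float((hx + hy) / hxy)


_METRIC_COLUMNS = ["nmi", "rmse", "psnr", "ssim"]


def slice_metrics(output: np.ndarray, target: np.ndarray,
                  cfg: MetricConfig | None = None) -> dict[str, float]:
    """All four metrics of one method output against its registered target."""
    cfg = cfg or MetricConfig()
    a = to_metric_scale(output)
    b = to_metric_scale(target)
    return {
        "nmi": nmi(a, b, cfg),
        "rmse": rmse(a, b),
        "psnr": psnr(a, b, cfg.psnr_max),
        "ssim": ssim(a, b, cfg),
    }


@dataclass
class MetricReport:
    """Long-format per-slice rows plus per-patient and per-method summaries."""

    rows: pd.DataFrame        # patient_id, slice_index, method, nmi, rmse, psnr, ssim
    per_patient: pd.DataFrame  # method x patient means/SDs
    summary: pd.DataFrame      # per-method grand mean +/- SD over patients


def evaluate_pairs(entries, cfg: MetricConfig | None = None) -> MetricReport:
    """Evaluate method outputs against their registered planning-CT targets.

    ``entries`` is an iterable of records ``(patient_id, slice_index, method,
    output_image, target_image)``; an entry with ``output_image is None`` is
    recorded as missing and excluded from aggregates with a warning.
    """
    cfg = cfg or MetricConfig()
    records = []
    for patient_id, slice_index, method, output, target in entries:
        if output is None:
            warnings.warn(
                f"missing output for {patient_id}/{slice_index}/{method}; "
                "excluded from aggregates", RuntimeWarning, stacklevel=2)
            records.append({"patient_id": patient_id, "slice_index": slice_index,
                            "method": method, "missing": True,
                            **{m: np.nan for m in _METRIC_COLUMNS}})
            continue
        vals = slice_metrics(output, target, cfg)
        records.append({"patient_id": patient_id, "slice_index": slice_index,
                        "method": method, "missing": False, **vals})
    rows = pd.DataFrame.from_records(records)
    ok = rows[~rows["missing"]]
    per_patient = (ok.groupby(["method", "patient_id"])[_METRIC_COLUMNS]
                     .agg(["mean", "std"]))
    patient_means = ok.groupby(["method", "patient_id"])[_METRIC_COLUMNS].mean()
    summary = patient_means.groupby("method").agg(["mean", "std", "min", "max"])
    return MetricReport(rows=rows, per_patient=per_patient, summary=summary)
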