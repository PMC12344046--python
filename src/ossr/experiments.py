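"""Reproducible desk-scale studies on the synthetic phantom suite.

These drive the package end to end under fixed seeds: the improvement study
mirrors the per-image evaluation protocol (one network per pair, metrics of
each method against the registered planning-CT target, per-image improvement
counts), and the registration study measures recovery of a known smooth
deformation.  Problem sizes are chosen so each study runs in minutes on one
CPU; see the methods note for what this does and does not show.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .gradation import DEFAULT_WINDOW, ct_to_display
from .metrics import MetricConfig, nmi, rmse, slice_metrics, to_metric_scale
from .phantom import (DegradationSpec, PhantomSpec, make_dataset, make_phantom,
                      smooth_sinusoid_field, warp_ct)
from .registration import (RegistrationConfig, invert_displacement_field,
                           mean_endpoint_error, register_deformable)
from .simplenet import NetworkConfig
from .train import (TrainingConfig, enhance, scaled_network_config,
                    scaled_training_config)
from .tvd import TVDConfig, tv_denoise


@dataclass
class ImprovementStudy:
    rows: list[dict]          # per pair: metrics of CBCT / TVD / OSSR vs target
    n_pairs: int

    def improved_count(self, method: str, metric: str) -> int:
        """Pairs on which ``method`` beats the raw CBCT on ``metric``."""
        better = 0
        for row in self.rows:
            a, b = row[method][metric], row["CBCT"][metric]
            if metric == "rmse":
                better += a < b
            else:
                better += a > b
        return better

    def mean(self, method: str, metric: str) -> float:
        return float(np.mean([row[method][metric] for row in self.rows]))


def improvement_study(n_pairs: int = 10, master_seed: int = 0,
                      net_cfg: NetworkConfig | None = None,
                      train_cfg: TrainingConfig | None = None,
                      tvd_cfg: TVDConfig | None = None,
                      metric_cfg: MetricConfig | None = None,
                      phantom_spec: PhantomSpec | None = None,
                      degradation_spec: DegradationSpec | None = None
                      ) -> ImprovementStudy:
    """Train one network per phantom pair and score every method per image.

    Defaults: 128×128 phantoms with the default degradation, the desk-scale
    network (32 channels) and training preset, per-pair seed
    ``master_seed + index``.
    """
    net_cfg = net_cfg or scaled_network_config()
    base_tcfg = train_cfg or scaled_training_config()
    tvd_cfg = tvd_cfg or TVDConfig()
    metric_cfg = metric_cfg or MetricConfig()
    pairs = make_dataset(n_pairs, phantom_spec, degradation_spec, master_seed)
    rows = []
    for pp in pairs:
        tcfg = dataclasses.replace(base_tcfg, seed=master_seed + pp.pair.slice_index)
        sr = enhance(pp.pair, net_cfg, tcfg)
        den = tv_denoise(pp.pair.cbct, tvd_cfg)
        target = pp.pair.planct_reg
        rows.append({
            "pair": pp.pair.slice_index,
            "CBCT": slice_metrics(pp.pair.cbct, target, metric_cfg),
            "TVD": slice_metrics(den, target, metric_cfg),
            "OSSR": slice_metrics(sr, target, metric_cfg),
        })
    return ImprovementStudy(rows=rows, n_pairs=n_pairs)


@dataclass
class RegistrationStudy:
    mean_epe: float           # px, whole image
    mean_epe_body: float      # px, inside the body ellipse
    nmi_before: float
    nmi_after: float
    rmse_before: float
    rmse_after: float


def registration_recovery(seed: int = 0, size: int = 128, amplitude: float = 3.0,
                          period: float = 64.0,
                          reg_cfg: RegistrationConfig | None = None
                          ) -> RegistrationStudy:
    """Warp a phantom by a known smooth sinusoidal field and recover it.

    The recovered field is compared with the numerical inverse of the
    generating field (registration undoes the warp, so the inverse is the
    ground truth for it).
    """
    from .phantom import phantom_masks

    spec = PhantomSpec(seed=seed)
    spec = dataclasses.replace(spec, size=size)
    clean = make_phantom(spec)
    fixed = ct_to_display(clean, DEFAULT_WINDOW)
    rng = np.random.default_rng(seed + 1)
    phase = tuple(rng.uniform(0, 2 * np.pi, 2))
    field = smooth_sinusoid_field(size, amplitude, period, phase)
    moving = ct_to_display(warp_ct(clean, field), DEFAULT_WINDOW)
    truth = invert_displacement_field(field)
    warped, recovered, _ = register_deformable(fixed, moving, reg_cfg)
    body = phantom_masks(spec)["body"]
    a = to_metric_scale(fixed)
    return RegistrationStudy(
        mean_epe=mean_endpoint_error(recovered, truth),
        mean_epe_body=mean_endpoint_error(recovered, truth, mask=body),
        nmi_before=nmi(to_metric_scale(moving), a),
        nmi_after=nmi(to_metric_scale(warped), a),
        rmse_before=rmse(to_metric_scale(moving), a),
        rmse_after=rmse(to_metric_scale(warped), a),
    )
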