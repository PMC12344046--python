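"""One-shot training and self-ensemble inference.

One SimpleNet is trained per slice pair, on nothing but augmented crops of
that pair: each step draws a random rotation (0°/90°/180°/270°), an optional
left–right flip, and a random crop, applies the identical transform to the
CBCT input and the registered planning-CT target, and takes one Adam step on
the mean squared error between network output and target.  No downscaling is
applied anywhere — the low-/high-quality roles are played by the two
modalities themselves.

The learning rate starts at 1e-3 and follows a plateau rule: periodically a
straight line is fitted to the recent (period-averaged) losses; when the
residual standard deviation exceeds the predicted decrease over the window,
the rate is divided by 10.  Training stops when the next division would fall
below 1e-6 (or at ``max_steps``).  After each division the recorded-loss
window restarts so one plateau triggers one division, not a cascade.

Inference fuses the eight square symmetries of the trained network: the
slice is transformed by every rotation/flip combination, passed through the
network, transformed back, and the per-pixel median of the eight aligned
outputs is taken.  The fused output is therefore equivariant under the
dihedral group of the square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gradation import denormalize, normalize
from .phantom import SlicePair
from .simplenet import (NetworkConfig, NetworkParams, backward,
                        forward_with_cache, init_params)


class TrainingError(RuntimeError):
    pass


class TrainingAborted(TrainingError):
    """Non-finite loss encountered; carries the trace so far."""

    def __init__(self, message: str, trace: "TrainingTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class TrainingConfig:
    initial_lr: float = 1e-3
    min_lr: float = 1e-6
    lr_divisor: float = 10.0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    crop_size: int = 128
    batch_size: int = 1
    check_period: int = 60   # steps between schedule evaluations
    fit_window: int = 5      # number of recorded (period-averaged) losses in the fit
    slope_std_factor: float = 1.0
    max_steps: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_lr < self.initial_lr):
            raise ValueError("need 0 < min_lr < initial_lr")
        if self.lr_divisor <= 1:
            raise ValueError("lr_divisor must be > 1")
        if self.crop_size < 1 or self.check_period < 1 or self.fit_window < 2:
            raise ValueError("invalid schedule constants")


def scaled_training_config(seed: int = 0, **overrides) -> TrainingConfig:
    """Desk-scale preset: 48-px crops, 20-step checks, at most 600 steps."""
    kw = dict(crop_size=48, check_period=20, fit_window=5, max_steps=600, seed=seed)
    kw.update(overrides)
    return TrainingConfig(**kw)


def scaled_network_config(**overrides) -> NetworkConfig:
    """Desk-scale preset: 32 channels instead of 128."""
    kw = dict(channels=32)
    kw.update(overrides)
    return NetworkConfig(**kw)


@dataclass
class TrainingTrace:
    losses: list[float] = field(default_factory=list)       # per step
    lrs: list[float] = field(default_factory=list)          # per step
    recorded: list[float] = field(default_factory=list)     # period-averaged losses
    events: list[tuple[int, float, float]] = field(default_factory=list)
    termination: str = "running"

    @property
    def lr(self) -> float:
        return self.lrs[-1] if self.lrs else float("nan")


@dataclass(frozen=True)
class AugmentedSample:
    rotation_quarter_turns: int
    lr_flip: bool
    crop_origin: tuple[int, int]
    input_patch: np.ndarray
    target_patch: np.ndarray


def apply_dihedral(img: np.ndarray, k: int, flip: bool) -> np.ndarray:
    """Rotate by ``k`` quarter turns, then optionally flip left–right."""
    out = np.rot90(img, k)
    return np.fliplr(out) if flip else out


def invert_dihedral(img: np.ndarray, k: int, flip: bool) -> np.ndarray:
    out = np.fliplr(img) if flip else img
    return np.rot90(out, -k)


def sample_augmentation(rng: np.random.Generator, pair: SlicePair,
                        crop_size: int) -> AugmentedSample:
    """One random (rotation, flip, crop) applied identically to both images.

    Rotation is uniform over the four quarter turns, the flip is a fair coin,
    and the crop origin is uniform over every placement that keeps the crop
    inside the transformed image.
    """
    cbct_n = normalize(pair.cbct)
    plan_n = normalize(pair.planct_reg)
    k = int(rng.integers(4))
    flip = bool(rng.integers(2))
    a = apply_dihedral(cbct_n, k, flip)
    b = apply_dihedral(plan_n, k, flip)
    h, w = a.shape
    if crop_size > min(h, w):
        raise ValueError(f"crop_size {crop_size} exceeds image sides {a.shape}")
    r0 = int(rng.integers(h - crop_size + 1))
    c0 = int(rng.integers(w - crop_size + 1))
    return AugmentedSample(
        rotation_quarter_turns=k, lr_flip=flip, crop_origin=(r0, c0),
        input_patch=a[r0:r0 + crop_size, c0:c0 + crop_size],
        target_patch=b[r0:r0 + crop_size, c0:c0 + crop_size])


def lr_schedule_step(trace: TrainingTrace, cfg: TrainingConfig) -> str:
    """Plateau decision from the recorded losses: keep | divide | terminate.

    A least-squares line is fitted to the last ``fit_window`` recorded losses;
    with ``s = |slope|·fit_window`` (predicted decrease over the window) and
    ``σ`` the residual standard deviation, ``σ > slope_std_factor·s`` triggers
    a division.  If the divided rate would undercut ``min_lr``, training
    terminates instead.
    """
    rec = trace.recorded
    if len(rec) < max(2, cfg.fit_window):
        return "keep"
    y = np.asarray(rec[-cfg.fit_window:], dtype=np.float64)
    x = np.arange(len(y), dtype=np.float64)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sigma = float(resid.std())
    s = abs(float(slope)) * cfg.fit_window
    if sigma <= cfg.slope_std_factor * s:
        return "keep"
    lr = trace.lr if np.isfinite(trace.lr) else cfg.initial_lr
    if lr / cfg.lr_divisor < cfg.min_lr * (1 - 1e-9):
        return "terminate"
    return "divide"


class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainingConfig):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float):
        c = self.cfg
        self.t += 1
        b1t = 1 - c.beta1 ** self.t
        b2t = 1 - c.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= c.beta1
            m += (1 - c.beta1) * g
            v *= c.beta2
            v += (1 - c.beta2) * (g * g)
            p -= (lr * (m / b1t) / (np.sqrt(v / b2t) + c.eps)).astype(p.dtype)


def train_one_shot(pair: SlicePair,
                   net_cfg: NetworkConfig | None = None,
                   train_cfg: TrainingConfig | None = None
                   ) -> tuple[NetworkParams, TrainingTrace]:
    """Train one SimpleNet on one slice pair; returns parameters and trace."""
    net_cfg = net_cfg or NetworkConfig()
    cfg = train_cfg or TrainingConfig()
    side = min(pair.cbct.shape)
    crop = cfg.crop_size
    if crop > side:
        import warnings
        warnings.warn(f"crop_size {crop} larger than image side {side}; "
                      "using the full side", RuntimeWarning, stacklevel=2)
        crop = side
    rng = np.random.default_rng(cfg.seed)
    params = init_params(net_cfg, seed=cfg.seed)
    flat = params.flat()
    adam = _Adam(flat, cfg)
    trace = TrainingTrace()
    lr = cfg.initial_lr
    nw = len(params.weights)
    for step in range(1, cfg.max_steps + 1):
        # accumulate over the (usually singleton) batch
        gw = [np.zeros_like(w) for w in params.weights]
        gb = [np.zeros_like(b) for b in params.biases]
        loss = 0.0
        for _ in range(cfg.batch_size):
            s = sample_augmentation(rng, pair, crop)
            y, cache = forward_with_cache(params, s.input_patch)
            diff = y - s.target_patch
            loss += float(np.mean(diff * diff))
            dws, dbs = backward(params, cache, 2.0 * diff / diff.size)
            for i in range(nw):
                gw[i] += dws[i]
                gb[i] += dbs[i]
        loss /= cfg.batch_size
        if cfg.batch_size > 1:
            for i in range(nw):
                gw[i] /= cfg.batch_size
                gb[i] /= cfg.batch_size
        if not np.isfinite(loss):
            trace.termination = "aborted_nonfinite_loss"
            raise TrainingAborted(f"non-finite loss at step {step}", trace)
        adam.step(flat, gw + gb, lr)
        trace.losses.append(loss)
        trace.lrs.append(lr)
        if step % cfg.check_period == 0:
            trace.recorded.append(
                float(np.mean(trace.losses[-cfg.check_period:])))
            decision = lr_schedule_step(trace, cfg)
            if decision == "divide":
                new_lr = lr / cfg.lr_divisor
                trace.events.append((step, lr, new_lr))
                lr = new_lr
                trace.recorded.clear()  # one plateau, one division
            elif decision == "terminate":
                trace.termination = "lr_floor"
                break
    if trace.termination == "running":
        trace.termination = "max_steps"
    return params, trace


#: the eight symmetries of the square, as (quarter_turns, lr_flip)
DIHEDRAL_GROUP = [(k, f) for f in (False, True) for k in range(4)]


def self_ensemble_infer(params: NetworkParams, cbct: np.ndarray) -> np.ndarray:
    """Median fusion of the network over the 8 square symmetries.

    Requires a square input (quarter-turn rotations must stay on one grid).
    The median of eight values is the mean of the 4th and 5th order statistics.
    """
    cbct = np.asarray(cbct)
    if cbct.ndim != 2 or cbct.shape[0] != cbct.shape[1]:
        raise ValueError("self-ensemble inference requires a square image "
                         f"(got {cbct.shape}): 90-degree rotations must "
                         "preserve the grid")
    x = normalize(cbct)
    outs = []
    for k, flip in DIHEDRAL_GROUP:
        y, _ = forward_with_cache(params, apply_dihedral(x, k, flip),
                                  keep_cache=False)
        outs.append(invert_dihedral(y, k, flip))
    fused = np.median(np.stack(outs), axis=0)
    return denormalize(fused)


@dataclass
class EnhanceResult:
    sr: np.ndarray
    params: NetworkParams
    trace: TrainingTrace


def enhance(pair: SlicePair,
            net_cfg: NetworkConfig | None = None,
            train_cfg: TrainingConfig | None = None,
            details: bool = False):
    """Full one-shot enhancement of one slice pair.

    Trains an independent network on the pair, then applies self-ensemble
    inference to the full CBCT slice.  Returns the enhanced display image, or
    an :class:`EnhanceResult` when ``details`` is true.
    """
    params, trace = train_one_shot(pair, net_cfg, train_cfg)
    sr = self_ensemble_infer(params, pair.cbct)
    if details:
        return EnhanceResult(sr=sr, params=params, trace=trace)
    return sr
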