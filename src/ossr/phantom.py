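"""Synthetic paired pelvic phantoms: clean planning-CT-like slices and CBCT-like degradations.

The private patient data behind the method cannot be redistributed, so the
package ships a generator producing slice pairs with known ground truth:

* ``make_phantom``     — a piecewise-smooth CT-number image (air background at
  −1000 HU, water-density body ellipse, bone ring, bladder- and rectum-like
  structures) with mild per-seed shape jitter so pairs differ slice to slice.
* ``degrade_to_cbct``  — adds the hallmarks of cone-beam acquisition: a
  low-frequency cupping/shading field, angular streaks through the body
  center, additive Gaussian noise, and blur; optionally a smooth deformation
  to exercise registration.
* ``make_dataset``     — windowed ``SlicePair`` objects plus retained ground
  truth (clean image, true deformation field).

Everything is a pure function of its spec including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .gradation import DEFAULT_WINDOW, WindowSettings, ct_to_display

HU_AIR = -1000.0
HU_SOFT_CLIP = (-1100.0, 1700.0)


class PhantomSpecError(ValueError):
    pass


@dataclass(frozen=True)
class Structure:
    """One elliptical structure: center/size as fractions of the body semi-axes."""

    name: str
    center: tuple[float, float]     # (row, col) offset from body center, fraction of semi-axes
    semi_axes: tuple[float, float]  # fraction of body semi-axes
    ct_number: float                # HU
    ring_width: float = 0.0         # >0: annulus of this fractional width instead of a disc


def default_structures() -> tuple[Structure, ...]:
    """Pelvis-like content: iliac bone ring, bladder, gas-filled rectum."""
    return (
        Structure("bone_ring", (0.0, 0.0), (0.92, 0.92), 700.0, ring_width=0.10),
        Structure("bladder", (-0.25, 0.0), (0.30, 0.34), 30.0),
        Structure("rectum", (0.38, 0.0), (0.16, 0.18), -950.0),
        Structure("muscle_l", (0.15, -0.52), (0.22, 0.18), 55.0),
        Structure("muscle_r", (0.15, 0.52), (0.22, 0.18), 55.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 128
    body_axes: tuple[float, float] = (0.42, 0.46)  # semi-axes, fraction of side
    structures: tuple[Structure, ...] = field(default_factory=default_structures)
    texture_amplitude: float = 25.0  # HU, smooth soft-tissue inhomogeneity
    jitter: float = 0.04             # per-seed fractional jitter of structure geometry
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 16:
            raise PhantomSpecError("size must be >= 16")
        for s in self.structures:
            if not (-1000.0 <= s.ct_number <= 1600.0):
                raise PhantomSpecError(f"CT number of {s.name} outside [-1000, 1600]")
            reach = max(abs(s.center[0]) + s.semi_axes[0],
                        abs(s.center[1]) + s.semi_axes[1])
            if reach > 1.001:
                raise PhantomSpecError(f"structure {s.name} extends outside the body")


@dataclass(frozen=True)
class DegradationSpec:
    shading_amplitude: float = 60.0  # HU, low-frequency cupping
    streak_count: int = 12
    streak_amplitude: float = 40.0   # HU
    noise_sigma: float = 20.0        # HU, additive Gaussian
    blur_sigma: float = 0.8          # px
    deform_amplitude: float = 0.0    # px, smooth misalignment of the clean image
    deform_period: float = 64.0      # px, wavelength of the misalignment field
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shading_amplitude", "streak_amplitude", "noise_sigma",
                     "blur_sigma", "deform_amplitude"):
            if getattr(self, name) < 0:
                raise PhantomSpecError(f"{name} must be >= 0")


@dataclass
class SlicePair:
    """Registered (CBCT, planning-CT) display-image pair for one slice."""

    cbct: np.ndarray
    planct_reg: np.ndarray
    patient_id: str = "phantom"
    slice_index: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cbct = np.asarray(self.cbct)
        self.planct_reg = np.asarray(self.planct_reg)
        if self.cbct.shape != self.planct_reg.shape:
            raise ValueError("cbct and planct_reg must share the CBCT grid shape")


@dataclass
class PhantomPair:
    """A SlicePair plus the generator's ground truth."""

    pair: SlicePair
    clean_ct: np.ndarray                  # HU, before degradation
    degraded_ct: np.ndarray               # HU
    clean_display: np.ndarray             # windowed clean image (== planct_reg if undeformed)
    planct_unregistered: np.ndarray       # windowed deformed clean image (misaligned PlanCT)
    true_field: np.ndarray | None         # (H, W, 2) px displacement, None if undeformed
    window: WindowSettings
    seed: int


def _ellipse_mask(size: int, center: tuple[float, float],
                  semi_axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = (rr - center[0]) / semi_axes[0]
    dc = (cc - center[1]) / semi_axes[1]
    return dr * dr + dc * dc <= 1.0


def phantom_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Region masks used by :func:`make_phantom` (exposed for tests)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    c0 = ((n - 1) / 2.0, (n - 1) / 2.0)
    body_ax = (spec.body_axes[0] * n, spec.body_axes[1] * n)
    masks = {"body": _ellipse_mask(n, c0, body_ax)}
    for s in spec.structures:
        j = 1.0 + spec.jitter * rng.standard_normal(4)
        ctr = (c0[0] + s.center[0] * body_ax[0] * j[0],
               c0[1] + s.center[1] * body_ax[1] * j[1])
        ax = (max(1.0, s.semi_axes[0] * body_ax[0] * j[2]),
              max(1.0, s.semi_axes[1] * body_ax[1] * j[3]))
        outer = _ellipse_mask(n, ctr, ax)
        if s.ring_width > 0:
            inner = _ellipse_mask(n, ctr, (ax[0] * (1 - s.ring_width),
                                           ax[1] * (1 - s.ring_width)))
            masks[s.name] = outer & ~inner & masks["body"]
        else:
            masks[s.name] = outer & masks["body"]
    return masks


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic piecewise-smooth CT-number image (HU) for one slice."""
    rng = np.random.default_rng(spec.seed)
    masks = phantom_masks(spec)
    img = np.full((spec.size, spec.size), HU_AIR, dtype=np.float64)
    img[masks["body"]] = 0.0
    for s in spec.structures:
        img[masks[s.name]] = s.ct_number
    if spec.texture_amplitude > 0:
        # smooth soft-tissue inhomogeneity inside the body, away from bone/air
        tex = gaussian_filter(rng.standard_normal(img.shape), spec.size / 18.0)
        tex *= spec.texture_amplitude / max(tex.std(), 1e-12)
        soft = masks["body"].copy()
        for s in spec.structures:
            if s.ct_number > 300 or s.ct_number < -500:
                soft &= ~masks[s.name]
        img[soft] += tex[soft]
    return img


def _shading_field(size: int, amplitude: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    c = (size - 1) / 2.0
    r2 = ((rr - c) ** 2 + (cc - c) ** 2) / (c * c)
    # cupping: center depressed, periphery raised
    return amplitude * (r2 - 0.5)


def _streak_field(size: int, count: int, amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Sparse angular comb of straight lines through the image center with a
    Hann radial taper — streak-like without a full forward projector."""
    if count == 0 or amplitude == 0:
        return np.zeros((size, size))
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    c = (size - 1) / 2.0
    dr, dc = rr - c, cc - c
    radius = np.hypot(dr, dc)
    taper = 0.5 * (1 + np.cos(np.pi * np.clip(radius / c, 0, 1)))  # Hann, 1 at center
    field = np.zeros((size, size))
    angles = rng.uniform(0, np.pi, size=count)
    signs = rng.choice([-1.0, 1.0], size=count)
    widths = rng.uniform(0.7, 1.6, size=count)
    for theta, sign, w in zip(angles, signs, widths):
        # perpendicular distance to a line through the center at angle theta
        d = np.abs(dr * np.cos(theta) - dc * np.sin(theta))
        field += sign * np.exp(-0.5 * (d / w) ** 2)
    return amplitude * taper * field / max(count ** 0.5, 1.0)


def smooth_sinusoid_field(size: int, amplitude: float, period: float,
                          phase: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Smooth (H, W, 2) displacement field, peak magnitude per axis = amplitude px."""
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    k = 2 * np.pi / period
    dy = amplitude * np.sin(k * cc + phase[0]) * np.cos(k * rr / 2 + phase[1])
    dx = amplitude * np.cos(k * rr + phase[1]) * np.sin(k * cc / 2 + phase[0])
    return np.stack([dy, dx], axis=-1)


def warp_ct(img: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Backward-warp a CT-number image by a (H, W, 2) px displacement field."""
    rr, cc = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(np.float64)
    coords = np.stack([rr + field[..., 0], cc + field[..., 1]])
    return map_coordinates(img, coords, order=1, mode="nearest")


def degrade_to_cbct(clean: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """CBCT-like degradation of a clean CT-number image.

    clean + shading + streaks + noise, then blur; values clamped to
    [-1100, 1700] HU.  All-zero amplitudes reproduce the input exactly.
    """
    rng = np.random.default_rng(spec.seed)
    size = clean.shape[0]
    out = clean.astype(np.float64).copy()
    identity = (spec.shading_amplitude == 0 and spec.streak_amplitude == 0
                and spec.noise_sigma == 0 and spec.blur_sigma == 0)
    if identity:
        return out
    if spec.shading_amplitude > 0:
        out += _shading_field(size, spec.shading_amplitude)
    out += _streak_field(size, spec.streak_count, spec.streak_amplitude, rng)
    if spec.noise_sigma > 0:
        out += spec.noise_sigma * rng.standard_normal(out.shape)
    if spec.blur_sigma > 0:
        out = gaussian_filter(out, spec.blur_sigma)
    return np.clip(out, *HU_SOFT_CLIP)


def make_pair(index: int, phantom_spec: PhantomSpec, degradation_spec: DegradationSpec,
              master_seed: int, window: WindowSettings = DEFAULT_WINDOW) -> PhantomPair:
    """One phantom pair with seed ``master_seed + index``."""
    seed = int(master_seed) + int(index)
    pspec = replace(phantom_spec, seed=seed)
    dspec = replace(degradation_spec, seed=seed + 10_000)
    clean = make_phantom(pspec)
    degraded = degrade_to_cbct(clean, dspec)
    clean_disp = ct_to_display(clean, window)
    cbct_disp = ct_to_display(degraded, window)
    if dspec.deform_amplitude > 0:
        rng = np.random.default_rng(seed + 20_000)
        phase = tuple(rng.uniform(0, 2 * np.pi, 2))
        field = smooth_sinusoid_field(pspec.size, dspec.deform_amplitude,
                                      dspec.deform_period, phase)
        moved = warp_ct(clean, field)
        planct_unreg = ct_to_display(moved, window)
    else:
        field = None
        planct_unreg = clean_disp
    pair = SlicePair(cbct=cbct_disp, planct_reg=clean_disp,
                     patient_id="phantom", slice_index=index,
                     provenance={"seed": seed, "deformed": field is not None})
    return PhantomPair(pair=pair, clean_ct=clean, degraded_ct=degraded,
                       clean_display=clean_disp, planct_unregistered=planct_unreg,
                       true_field=field, window=window, seed=seed)


def make_dataset(n_pairs: int,
                 phantom_spec: PhantomSpec | None = None,
                 degradation_spec: DegradationSpec | None = None,
                 master_seed: int = 0,
                 window: WindowSettings = DEFAULT_WINDOW) -> list[PhantomPair]:
    """``n_pairs`` reproducible phantom pairs with per-pair derived seeds."""
    if n_pairs < 1:
        raise PhantomSpecError("n_pairs must be >= 1")
    pspec = phantom_spec or PhantomSpec()
    dspec = degradation_spec or DegradationSpec()
    return [make_pair(i, pspec, dspec, master_seed, window) for i in range(n_pairs)]
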