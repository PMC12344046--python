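"""Augmentation sampling, the plateau learning-rate rule, one-shot training,
and the geometric self-ensemble."""

import dataclasses

import numpy as np
import pytest

from ossr.gradation import DISPLAY_MAX, normalize
from ossr.phantom import SlicePair
from ossr.simplenet import NetworkConfig, init_params
from ossr.train import (DIHEDRAL_GROUP, TrainingConfig, TrainingTrace,
                        apply_dihedral, invert_dihedral, lr_schedule_step,
                        sample_augmentation, self_ensemble_infer,
                        train_one_shot)


# ------------------------------------------------------------ augmentation

def test_augmentation_applies_same_transform_to_both(rng, phantom_pair):
    pair = phantom_pair.pair
    for _ in range(20):
        s = sample_augmentation(rng, pair, 48)
        k, f, (r0, c0) = s.rotation_quarter_turns, s.lr_flip, s.crop_origin
        a = apply_dihedral(normalize(pair.cbct), k, f)[r0:r0 + 48, c0:c0 + 48]
        b = apply_dihedral(normalize(pair.planct_reg), k, f)[r0:r0 + 48, c0:c0 + 48]
        assert np.array_equal(s.input_patch, a)
        assert np.array_equal(s.target_patch, b)
        assert s.input_patch.shape == (48, 48)


def test_augmentation_full_side_crop_forces_origin(rng, phantom_pair):
    s = sample_augmentation(rng, phantom_pair.pair, phantom_pair.pair.cbct.shape[0])
    assert s.crop_origin == (0, 0)


def test_augmentation_rejects_oversized_crop(rng, phantom_pair):
    with pytest.raises(ValueError):
        sample_augmentation(rng, phantom_pair.pair, 1000)


def test_augmentation_uniform_over_dihedral_group(phantom_pair):
    """Each of the 8 (rotation, flip) combinations at ~1/8 over 8000 draws."""
    rng = np.random.default_rng(42)
    counts = {}
    n = 8000
    for _ in range(n):
        s = sample_augmentation(rng, phantom_pair.pair, 32)
        key = (s.rotation_quarter_turns, s.lr_flip)
        counts[key] = counts.get(key, 0) + 1
    assert len(counts) == 8
    p = 1 / 8
    bound = 3 * np.sqrt(n * p * (1 - p))  # 3-sigma binomial bound
    for c in counts.values():
        assert abs(c - n * p) < bound


# ---------------------------------------------------------------- schedule

def _trace_with(recorded, lr):
    t = TrainingTrace()
    t.recorded = list(recorded)
    t.lrs = [lr]
    return t


def test_schedule_keeps_on_noiseless_decreasing_line():
    cfg = TrainingConfig(fit_window=5)
    t = _trace_with([1.0, 0.8, 0.6, 0.4, 0.2], 1e-3)
    assert lr_schedule_step(t, cfg) == "keep"


def test_schedule_divides_on_noisy_plateau():
    cfg = TrainingConfig(fit_window=5)
    t = _trace_with([0.50, 0.52, 0.49, 0.51, 0.50], 1e-3)
    assert lr_schedule_step(t, cfg) == "divide"


def test_schedule_terminates_at_lr_floor():
    cfg = TrainingConfig(fit_window=5)
    plateau = [0.50, 0.52, 0.49, 0.51, 0.50]
    lr = cfg.initial_lr
    path = [lr]
    for _ in range(10):
        d = lr_schedule_step(_trace_with(plateau, lr), cfg)
        if d == "terminate":
            break
        assert d == "divide"
        lr /= cfg.lr_divisor
        path.append(lr)
    else:
        pytest.fail("schedule never terminated")
    assert path == pytest.approx([1e-3, 1e-4, 1e-5, 1e-6])


def test_schedule_keeps_with_too_few_points():
    cfg = TrainingConfig(fit_window=5)
    assert lr_schedule_step(_trace_with([1.0], 1e-3), cfg) == "keep"


# ---------------------------------------------------------------- training

def test_training_deterministic_and_lr_monotone(small_pair, tiny_net_cfg,
                                                tiny_train_cfg):
    p1, t1 = train_one_shot(small_pair.pair, tiny_net_cfg, tiny_train_cfg)
    p2, t2 = train_one_shot(small_pair.pair, tiny_net_cfg, tiny_train_cfg)
    assert t1.losses == t2.losses
    assert t1.lrs == t2.lrs
    assert all(np.array_equal(a, b) for a, b in zip(p1.flat(), p2.flat()))
    lrs = np.array(t1.lrs)
    assert np.all(np.diff(lrs) <= 0)
    for _, old, new in t1.events:
        assert new == pytest.approx(old / 10)
    assert t1.termination in ("lr_floor", "max_steps")


def test_training_loss_decreases(small_pair, tiny_net_cfg):
    cfg = TrainingConfig(crop_size=32, check_period=10, fit_window=3,
                         max_steps=150, seed=1)
    _, trace = train_one_shot(small_pair.pair, tiny_net_cfg, cfg)
    early = np.mean(trace.losses[:10])
    late = np.mean(trace.losses[-10:])
    assert late < early


def test_training_crop_degenerates_to_side_with_warning(tiny_net_cfg):
    rng = np.random.default_rng(0)
    img = rng.integers(0, DISPLAY_MAX, (40, 40))
    pair = SlicePair(cbct=img, planct_reg=img)
    cfg = TrainingConfig(crop_size=128, check_period=10, fit_window=3,
                         max_steps=5, seed=0)
    with pytest.warns(RuntimeWarning, match="crop_size"):
        _, trace = train_one_shot(pair, tiny_net_cfg, cfg)
    assert len(trace.losses) == 5


# ------------------------------------------------------------ self-ensemble

def test_dihedral_transforms_invert():
    rng = np.random.default_rng(3)
    x = rng.uniform(size=(16, 16))
    assert len(DIHEDRAL_GROUP) == 8
    for k, f in DIHEDRAL_GROUP:
        assert np.array_equal(invert_dihedral(apply_dihedral(x, k, f), k, f), x)


def test_identity_network_ensemble_returns_input(rng):
    params = init_params(NetworkConfig(channels=8), zero=True)
    img = rng.integers(0, DISPLAY_MAX + 1, (32, 32))
    assert np.array_equal(self_ensemble_infer(params, img), img)


def test_even_count_median_is_mean_of_middle_two():
    stack = np.arange(1, 9, dtype=float).reshape(8, 1, 1)
    assert np.median(stack, axis=0)[0, 0] == pytest.approx(4.5)


def test_ensemble_requires_square_input(rng):
    params = init_params(NetworkConfig(channels=8), seed=0)
    with pytest.raises(ValueError, match="square"):
        self_ensemble_infer(params, rng.integers(0, 10, (16, 20)))


def test_ensemble_d4_equivariance(rng):
    """Fusing over the full group commutes with any group element."""
    params = init_params(NetworkConfig(channels=8), seed=9)
    img = rng.integers(0, DISPLAY_MAX + 1, (32, 32))
    base = self_ensemble_infer(params, img)
    for k, f in DIHEDRAL_GROUP:
        lhs = self_ensemble_infer(params, apply_dihedral(img, k, f))
        rhs = apply_dihedral(base, k, f)
        # float32 conv sums differ across orientations; allow 1 display unit
        assert np.max(np.abs(lhs.astype(int) - rhs.astype(int))) <= 1
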