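"""Hill-type isometric force, joint torques, and kinematic-noise propagation.

Isometric musculotendon force combines an activation-scaled active
force-length factor with a passive elastic factor:

    F(L) = u * F_max * F_a(L_norm) + F_maxpass * F_P(L)
    F_a  = 2.5 * L_norm - 1.25 * L_norm^2
    F_P  = (exp(2 (L - L_pass) / (L_max - L_min)) - 1) / (e - 1)  for L > L_pass
           0                                                      otherwise

with ``L_norm = (L - L_min) / (L_max - L_min)`` clamped to [0, 1],
``F_maxpass = 0.1 F_max`` and passive slack length ``L_pass = 0.9 L_max``.
The torque at each actuated DOF is the moment arm times the force:
``tau_i = mu_i * F(L)``.

The perturbation experiment propagates kinematic estimation errors into
kinetics: at every test-grid posture, normally distributed noise is added
to the *kinematic values* (length sd = level × ROM length range, samples
clamped into [L_min, L_max]; per-DOF moment-arm sd = 10 × level × that
DOF's maximum |M|, unclamped — moment-arm errors are not physically
bounded), and the resulting force/torque deviations are normalized to each
muscle's reference force/torque range over the grid.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HillParams:
    """Hill-model scalars for one muscle.

    ``f_max`` peak active force (N); activation ``u`` in [0, 1] (1 =
    maximal isometric contraction); ``l_min``/``l_max`` shortest/longest
    musculotendon length over the ROM (mm).  Derived: passive scale
    ``f_maxpass = 0.1 f_max`` and slack length ``l_pass = 0.9 l_max``.
    """

    f_max: float
    l_min: float
    l_max: float
    u: float = 1.0

    def __post_init__(self):
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        if not self.l_min < self.l_max:
            raise ValueError("need l_min < l_max")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("activation u must be in [0, 1]")
        if not self.l_min < self.l_pass:
            raise ValueError("l_pass must exceed l_min (lengths too close to 0?)")

    @property
    def f_maxpass(self) -> float:
        return 0.1 * self.f_max

    @property
    def l_pass(self) -> float:
        return 0.9 * self.l_max


def active_force_factor(l_norm) -> np.ndarray | float:
    """Active force-length factor ``2.5 l - 1.25 l^2`` on normalized length
    clamped to [0, 1]; 0 at slack, 1.25 at maximal length."""
    l = np.clip(np.asarray(l_norm, dtype=float), 0.0, 1.0)
    out = 2.5 * l - 1.25 * l * l
    return float(out) if out.ndim == 0 else out


def passive_force_factor(L, l_pass: float, l_max: float, l_min: float):
    """Passive elastic factor: 0 up to the slack length, then exponential;
    continuous at ``l_pass`` and equal to 1 when ``L - l_pass`` is half the
    length range."""
    if not l_max > l_min:
        raise ValueError("need l_max > l_min")
    L = np.asarray(L, dtype=float)
    z = 2.0 * (L - l_pass) / (l_max - l_min)
    out = np.where(L > l_pass, (np.expm1(z)) / (math.e - 1.0), 0.0)
    return float(out) if out.ndim == 0 else out


def muscle_force(u: float, L, params: HillParams) -> np.ndarray | float:
    """Isometric force (N) at length ``L`` (mm) and activation ``u``."""
    L = np.asarray(L, dtype=float)
    l_norm = (L - params.l_min) / (params.l_max - params.l_min)
    out = np.asarray(
        u * params.f_max * active_force_factor(l_norm)
        + params.f_maxpass
        * passive_force_factor(L, params.l_pass, params.l_max, params.l_min)
    )
    return float(out) if out.ndim == 0 else out


def joint_torques(M, F) -> np.ndarray:
    """Torques (N·mm) at each actuated DOF: ``tau_i = mu_i * F``.

    ``M`` may be a d-vector (one posture) or an N x d matrix; ``F`` a scalar
    or N-vector.
    """
    M = np.asarray(M, dtype=float)
    F = np.asarray(F, dtype=float)
    if M.ndim == 1:
        return M * F
    return M * F[:, None]


@dataclass(frozen=True)
class PerturbationConfig:
    """Design of the noise-propagation experiment.

    ``noise_levels`` are fractions of the length range of motion, in
    percent; ``sets_per_posture`` noisy draws are taken per posture;
    moment-arm noise is ``moment_multiplier`` times larger than length
    noise (relative to each DOF's maximum |M|).
    """

    noise_levels: Tuple[float, ...] = (0.1, 1.0, 10.0, 20.0)
    sets_per_posture: int = 10
    moment_multiplier: float = 10.0
    u: float = 1.0
    f_max: float = 100.0

    def __post_init__(self):
        if any(lv < 0 for lv in self.noise_levels):
            raise ValueError("noise levels must be >= 0")
        if self.moment_multiplier <= 0 or self.sets_per_posture < 1:
            raise ValueError("invalid perturbation design")


@dataclass(frozen=True)
class PerturbationRow:
    """Pooled error statistics for one noise level."""

    noise_level: float
    force_error_mean: float
    force_error_iqr: float
    torque_error_mean: float
    torque_error_iqr: float
    n_force_samples: int
    n_torque_samples: int


def _iqr(x: np.ndarray) -> float:
    return float(np.subtract(*np.percentile(x, [75, 25])))


def perturbation_experiment(
    muscles: Sequence, config: PerturbationConfig, seed,
    grid_points: int = 8,
) -> List[PerturbationRow]:
    """Propagate kinematic noise through the Hill model for a muscle set.

    ``muscles`` is a sequence of objects exposing length/moment-arm
    evaluation over a posture grid: either fitted
    :class:`~polymuscle.fitting.MuscleModel` instances or fixture
    :class:`~polymuscle.arm_fixture.ArmMuscle` oracles.  For every muscle,
    reference forces and torques are computed on its ``grid_points``-per-DOF
    test grid; each noise level then draws ``sets_per_posture`` noisy
    kinematic samples per posture and the force/torque deviations are
    normalized to the muscle's reference force/torque range.  Deterministic
    per seed; muscles with a degenerate (zero) force or torque range are
    skipped with a warning.
    """
    from .arm_fixture import ArmMuscle
    from .fitting import MuscleModel
    from .geometry import DofSpec, make_test_grid
    from .terms import evaluate

    rng = np.random.default_rng(seed)
    per_level_force: Dict[float, List[np.ndarray]] = {
        lv: [] for lv in config.noise_levels
    }
    per_level_torque: Dict[float, List[np.ndarray]] = {
        lv: [] for lv in config.noise_levels
    }

    for mus in muscles:
        if isinstance(mus, MuscleModel):
            dofs = [DofSpec(lbl, rom) for lbl, rom in zip(mus.dof_labels, mus.roms)]
            X = make_test_grid(dofs, points=grid_points)
            L = evaluate(mus.L, X)
            M = np.stack([evaluate(p, X) for p in mus.M], axis=1)
            name = mus.name
        elif isinstance(mus, ArmMuscle):
            X = make_test_grid(mus.oracle.dofs, points=grid_points)
            L = np.asarray(mus.oracle.length_fn(X), dtype=float)
            M = np.stack(
                [np.asarray(fn(X), dtype=float) for fn in mus.oracle.moment_fns],
                axis=1,
            )
            name = mus.name
        else:
            raise TypeError(f"unsupported muscle object {type(mus)!r}")

        l_min, l_max = float(np.min(L)), float(np.max(L))
        if l_max - l_min <= 0:
            logger.warning("muscle %s has zero length range; skipped", name)
            continue
        params = HillParams(config.f_max, l_min, l_max, u=config.u)
        F_ref = muscle_force(config.u, L, params)
        tau_ref = joint_torques(M, F_ref)
        f_range = float(np.ptp(F_ref))
        tau_range = np.ptp(tau_ref, axis=0)
        if f_range <= 0 or np.any(tau_range <= 0):
            logger.warning("muscle %s has degenerate force/torque range; skipped",
                           name)
            continue
        m_max = np.max(np.abs(M), axis=0)

        for lv in config.noise_levels:
            sd_l = lv / 100.0 * (l_max - l_min)
            sd_m = config.moment_multiplier * lv / 100.0 * m_max
            f_errs, t_errs = [], []
            for _ in range(config.sets_per_posture):
                L_noisy = L + rng.normal(0.0, sd_l, size=L.shape) if sd_l > 0 else L.copy()
                np.clip(L_noisy, l_min, l_max, out=L_noisy)
                M_noisy = M + rng.normal(0.0, 1.0, size=M.shape) * sd_m
                F = muscle_force(config.u, L_noisy, params)
                tau = joint_torques(M_noisy, F)
                f_errs.append(np.abs(F - F_ref) / f_range)
                t_errs.append(np.abs(tau - tau_ref) / tau_range)
            per_level_force[lv].append(np.concatenate(f_errs))
            per_level_torque[lv].append(
                np.concatenate([t.ravel() for t in t_errs])
            )

    if not any(per_level_force[lv] for lv in config.noise_levels):
        raise ValueError("no usable muscles in the perturbation experiment")

    rows = []
    for lv in config.noise_levels:
        fe = np.concatenate(per_level_force[lv])
        te = np.concatenate(per_level_torque[lv])
        rows.append(
            PerturbationRow(
                noise_level=lv,
                force_error_mean=float(100.0 * np.mean(fe)),
                force_error_iqr=float(100.0 * _iqr(fe)),
                torque_error_mean=float(100.0 * np.mean(te)),
                torque_error_iqr=float(100.0 * _iqr(te)),
                n_force_samples=int(fe.size),
                n_torque_samples=int(te.size),
            )
        )
    return rows
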