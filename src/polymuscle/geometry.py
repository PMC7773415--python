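"""Synthetic muscle-geometry oracles and posture-grid sampling.

This module stands in for a geometric musculoskeletal model: it generates
smooth posture-dependent muscle length functions with analytically
consistent moment arms (``M_i = dL/dx_i``) and samples them on the uniform
posture grids used for fitting (9 points per DOF, range-of-motion endpoints
included) and testing (8 points per DOF, placed at the midpoints of the
9-point nodes, hence strictly interior and maximally far from the fit
samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Sequence, Tuple

import numpy as np

from . import terms as ta
from .terms import PolynomialModel, canonical_term, differentiate, evaluate


@dataclass(frozen=True)
class DofSpec:
    """One rotational degree of freedom: a label and its range of motion.

    Labels follow the ``<limb>_<joint>_<min>_<max>`` convention, e.g.
    ``ra_wr_s_p`` for right-arm wrist supination(-)/pronation(+); angles are
    radians.
    """

    label: str
    rom: Tuple[float, float]

    def __post_init__(self):
        lo, hi = self.rom
        if not lo < hi:
            raise ValueError(f"{self.label}: ROM min {lo} must be < max {hi}")
        object.__setattr__(self, "rom", (float(lo), float(hi)))


@dataclass(frozen=True)
class MuscleGeometryOracle:
    """Ground-truth muscle geometry: length and per-DOF moment-arm functions.

    The moment arms are the analytic partial derivatives of the length
    function, so sampled datasets are internally consistent by construction.
    ``ground_truth`` holds the underlying length polynomial when the oracle
    is polynomial (the structure-recovery reference); it is ``None`` when a
    non-polynomial perturbation is active.
    """

    dofs: Tuple[DofSpec, ...]
    length_fn: Callable[[np.ndarray], np.ndarray]
    moment_fns: Tuple[Callable[[np.ndarray], np.ndarray], ...]
    ground_truth: PolynomialModel | None = None

    @property
    def dimension(self) -> int:
        return len(self.dofs)

    @property
    def dof_labels(self) -> Tuple[str, ...]:
        return tuple(d.label for d in self.dofs)


@dataclass(frozen=True)
class GridDataset:
    """Sampled posture grid with measured lengths and moment arms.

    ``postures`` is N x d (radians), ``lengths`` N (mm), ``moments`` N x d
    (mm, one column per spanned DOF).
    """

    postures: np.ndarray
    lengths: np.ndarray
    moments: np.ndarray
    dof_labels: Tuple[str, ...]
    roms: Tuple[Tuple[float, float], ...]
    grid_points_per_dof: int | None = None

    def __post_init__(self):
        P = np.asarray(self.postures, dtype=float)
        L = np.asarray(self.lengths, dtype=float)
        M = np.asarray(self.moments, dtype=float)
        if P.ndim != 2 or L.shape != (P.shape[0],) or M.shape != P.shape:
            raise ValueError("inconsistent dataset shapes")
        object.__setattr__(self, "postures", P)
        object.__setattr__(self, "lengths", L)
        object.__setattr__(self, "moments", M)

    @property
    def n(self) -> int:
        return self.postures.shape[0]

    @property
    def dimension(self) -> int:
        return self.postures.shape[1]


def make_grid(dofs: Sequence[DofSpec], points: int = 9) -> np.ndarray:
    """Uniform Cartesian posture grid including both ROM endpoints.

    Rows: ``points ** d`` postures; per-DOF nodes at 0%, ..., 100% of ROM.
    """
    if points < 2:
        raise ValueError("need at least 2 grid points per DOF")
    axes = [np.linspace(d.rom[0], d.rom[1], points) for d in dofs]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def make_test_grid(dofs: Sequence[DofSpec], points: int = 8) -> np.ndarray:
    """Test grid interleaved with the fit grid.

    Per-DOF nodes are the ``points`` midpoints of adjacent nodes of the
    ``points + 1``-node uniform grid, i.e. for the default 8-point grid the
    midpoints of the 9-point fit grid: 6.25%, 18.75%, ..., 93.75% of ROM —
    strictly interior to the ROM and as far as possible from the fit samples.
    """
    axes = []
    for d in dofs:
        ref = np.linspace(d.rom[0], d.rom[1], points + 1)
        axes.append(0.5 * (ref[:-1] + ref[1:]))
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def _default_roms(d: int) -> List[Tuple[float, float]]:
    # generic joint ROMs, ~±90° for the first DOF then narrowing
    base = [(-np.pi / 2, np.pi / 2), (-1.2, 1.2), (-1.0, 1.0),
            (-0.9, 0.9), (-0.8, 0.8), (-0.7, 0.7)]
    return [base[i % len(base)] for i in range(d)]


def synth_muscle(
    d: int,
    n_terms: int,
    seed,
    dofs: Sequence[DofSpec] | None = None,
    rho: int = 5,
    wobble: float = 0.0,
) -> MuscleGeometryOracle:
    """Draw a random smooth muscle-geometry oracle.

    The ground truth is a sparse polynomial length function of degree
    ``<= rho`` with ``n_terms`` non-intercept terms.  Term coefficients are
    drawn relative to the ROM extent, then jointly rescaled so the length
    excursion over the ROM falls in a physiological 30–80 mm band with the
    shortest length in the 50–100 mm band — which also keeps the shortest
    length below the Hill passive slack length 0.9 * L_max.  Moment arms
    are the analytic partial derivatives of the length.

    ``wobble`` adds a smooth non-polynomial component
    ``A * sin(w . x + phi)`` (amplitude ``A = wobble`` mm) with matching
    analytic derivatives, for exercising the approximation regime where no
    finite polynomial is exact.

    Reproducible: the same ``seed`` yields the same oracle.
    """
    if not 1 <= d <= 6:
        raise ValueError("d must be in [1, 6]")
    rng = np.random.default_rng(seed)
    if dofs is None:
        dofs = [DofSpec(f"dof_{i + 1}", rom) for i, rom in enumerate(_default_roms(d))]
    dofs = tuple(dofs)
    if len(dofs) != d:
        raise ValueError("len(dofs) must equal d")

    pool = sorted(ta.full_structure(d, rho) - {ta.INTERCEPT},
                  key=lambda t: (len(t), t))
    n_terms = min(n_terms, len(pool))
    chosen = [pool[i] for i in rng.choice(len(pool), size=n_terms, replace=False)]

    r_max = max(max(abs(lo), abs(hi)) for lo, hi in (dd.rom for dd in dofs))
    coeffs = {}
    for term in chosen:
        scale = rng.uniform(5.0, 25.0) * rng.choice([-1.0, 1.0])
        coeffs[term] = scale / max(r_max, 1e-6) ** len(term)

    # calibrate excursion and baseline on a coarse ROM grid
    labels = tuple(dd.label for dd in dofs)
    shape = PolynomialModel(d, coeffs, labels)
    calib = make_grid(dofs, points=5)
    vals = evaluate(shape, calib)
    excursion = float(np.ptp(vals))
    if excursion > 1e-9:
        factor = rng.uniform(30.0, 80.0) / excursion
        coeffs = {t: c * factor for t, c in coeffs.items()}
        shortest = float(np.min(vals)) * factor
    else:
        shortest = 0.0
    coeffs[ta.INTERCEPT] = rng.uniform(50.0, 100.0) - shortest
    truth = PolynomialModel(d, coeffs, labels)
    dL = [differentiate(truth, i) for i in range(1, d + 1)]

    if wobble > 0.0:
        w = rng.uniform(0.5, 1.5, size=d)
        phi = rng.uniform(0.0, 2 * np.pi)

        def length_fn(X, _t=truth, _w=w, _phi=phi, _A=wobble):
            X = np.atleast_2d(np.asarray(X, dtype=float))
            return evaluate(_t, X) + _A * np.sin(X @ _w + _phi)

        def make_moment(i):
            def moment_fn(X, _p=dL[i - 1], _w=w, _phi=phi, _A=wobble):
                X = np.atleast_2d(np.asarray(X, dtype=float))
                return evaluate(_p, X) + _A * _w[i - 1] * np.cos(X @ _w + _phi)
            return moment_fn

        return MuscleGeometryOracle(
            dofs, length_fn, tuple(make_moment(i) for i in range(1, d + 1)),
            ground_truth=None,
        )

    def length_fn(X, _t=truth):
        return evaluate(_t, np.atleast_2d(np.asarray(X, dtype=float)))

    def make_moment(i):
        def moment_fn(X, _p=dL[i - 1]):
            return evaluate(_p, np.atleast_2d(np.asarray(X, dtype=float)))
        return moment_fn

    return MuscleGeometryOracle(
        dofs, length_fn, tuple(make_moment(i) for i in range(1, d + 1)),
        ground_truth=truth,
    )


def sample_dataset(oracle: MuscleGeometryOracle, postures: np.ndarray,
                   grid_points_per_dof: int | None = None) -> GridDataset:
    """Evaluate the oracle's length and all moment arms at every posture."""
    P = np.atleast_2d(np.asarray(postures, dtype=float))
    if P.shape[0] == 0:
        return GridDataset(
            P.reshape(0, oracle.dimension), np.zeros(0),
            np.zeros((0, oracle.dimension)), oracle.dof_labels,
            tuple(d.rom for d in oracle.dofs), grid_points_per_dof,
        )
    L = np.asarray(oracle.length_fn(P), dtype=float)
    M = np.stack([np.asarray(fn(P), dtype=float) for fn in oracle.moment_fns],
                 axis=1)
    if not (np.all(np.isfinite(L)) and np.all(np.isfinite(M))):
        raise ValueError("oracle produced non-finite values")
    return GridDataset(P, L, M, oracle.dof_labels,
                       tuple(d.rom for d in oracle.dofs), grid_points_per_dof)
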