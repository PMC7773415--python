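"""Autogenerating polynomial search: least squares, AICc, constraint loop.

The search approximates a muscle's length ``L(x)`` and its moment arms
``{M_i(x)}`` by sparse polynomials whose term sets are grown one term at a
time (forward stepwise selection).  Candidate structures are scored with
the small-sample corrected Akaike information criterion

    AICc = 2k + 2N ln(sigma) + 2k(k+1)/(N - k - 1)

where ``k`` is the number of coefficients (intercept included), ``N`` the
number of grid samples and ``sigma`` the normalized RMS residual (lengths
normalized by their range over the fit grid, each moment arm by its maximum
magnitude).  A term is accepted only if it lowers the function's AICc, so
the criterion itself stops the expansion before overfitting.

In *constrained* mode each iteration additionally imposes the differential
relationship ``M_i = dL/dx_i`` on the term sets: moment-arm structures are
integrated into the length structure, and all moment-arm structures are
re-derived from it, after which every coefficient set is refit
independently by least squares.  The returned model then satisfies
``structure(M_i) == structure(dL/dx_i)`` exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import terms as ta
from .geometry import GridDataset
from .terms import (
    PolynomialModel,
    Structure,
    design_matrix,
    differentiate_structure,
    integrate_structure,
    union_structures,
)

logger = logging.getLogger(__name__)

#: Default maximum power of the length polynomial.
RHO_L = 5
#: Default maximum power of the moment-arm polynomials.
RHO_M = 4

_NORMALIZER_FLOOR = 1e-12

#: Normalized RMS below this is numerically a perfect fit; without the
#: floor, double-precision noise (~1e-14) keeps "improving" AICc after an
#: exact fit and drags superfluous terms in.
SIGMA_PERFECT = 1e-9


@dataclass(frozen=True)
class MuscleModel:
    """A fitted muscle: one length polynomial and one moment-arm polynomial
    per spanned DOF, with ROM and normalization constants.

    ``l_range`` is the spread of measured lengths over the fit grid (mm) and
    ``m_max[i]`` the maximum absolute measured moment arm of DOF ``i+1``;
    these are the constants used to normalize residuals during the search.
    """

    name: str
    dof_labels: Tuple[str, ...]
    roms: Tuple[Tuple[float, float], ...]
    L: PolynomialModel
    M: Tuple[PolynomialModel, ...]
    l_range: float
    m_max: Tuple[float, ...]
    mode: str = "unconstrained"
    rho_l: int = RHO_L
    rho_m: int = RHO_M

    @property
    def dimension(self) -> int:
        return len(self.dof_labels)

    def is_consistent(self) -> bool:
        """True when every moment-arm structure equals the structure of the
        corresponding partial derivative of the length polynomial."""
        return all(
            self.M[i - 1].structure == differentiate_structure(self.L.structure, i)
            for i in range(1, self.dimension + 1)
        )


@dataclass
class IterationRecord:
    """One search iteration: per-function accepted AICc / normalized RMS
    (percent) and the term accepted for each function (None if frozen)."""

    iteration: int
    aicc: Dict[str, float]
    rms_percent: Dict[str, float]
    added: Dict[str, object]


@dataclass
class FitReport:
    """Per-iteration trace of the search plus the stop reason."""

    function_names: List[str]
    iterations: List[IterationRecord] = field(default_factory=list)
    stop_reason: str = ""

    def aicc_trace(self, name: str) -> List[float]:
        return [it.aicc[name] for it in self.iterations if name in it.aicc]

    def rms_trace(self, name: str) -> List[float]:
        return [it.rms_percent[name] for it in self.iterations
                if name in it.rms_percent]


def fit_coefficients(
    structure: Structure, postures: np.ndarray, targets: np.ndarray
) -> Tuple[Dict[ta.TermKey, float], float]:
    """Least-squares coefficients of ``structure`` on the given samples.

    Returns the coefficient map and the RMS residual (same units as
    ``targets``).  Rank-deficient designs fall back to the minimum-norm
    solution with a warning.  The empty structure is the zero model.
    """
    X = np.atleast_2d(np.asarray(postures, dtype=float))
    y = np.asarray(targets, dtype=float)
    terms = sorted(structure, key=lambda t: (len(t), t))
    if not terms:
        return {}, float(np.sqrt(np.mean(y**2))) if y.size else 0.0
    if X.shape[0] < len(terms):
        raise ValueError(
            f"{X.shape[0]} samples cannot identify {len(terms)} coefficients"
        )
    A = design_matrix(terms, X)
    coef, _res, rank, _sv = np.linalg.lstsq(A, y)
    if rank < len(terms):
        logger.warning(
            "rank-deficient design (rank %d < %d terms); minimum-norm solution",
            rank, len(terms),
        )
    resid = y - A @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    return dict(zip(terms, (float(c) for c in coef))), rms


def aicc(k: int, N: int, sigma: float) -> float:
    """Corrected Akaike information criterion for a fit with ``k``
    coefficients, ``N`` samples and normalized RMS residual ``sigma``.

    ``sigma <= 0`` (perfect fit) returns ``-inf`` so it wins any comparison;
    ``N <= k + 1`` returns ``+inf`` so under-determined candidates lose.
    """
    if N <= k + 1:
        return math.inf
    if sigma <= 0.0:
        return -math.inf
    return 2 * k + 2 * N * math.log(sigma) + 2 * k * (k + 1) / (N - k - 1)


def _score(structure: Structure, X: np.ndarray, y: np.ndarray,
           normalizer: float) -> Tuple[float, float]:
    """(AICc, normalized RMS) of a structure fit on (X, y)."""
    try:
        _coeffs, rms = fit_coefficients(structure, X, y)
    except ValueError:
        return math.inf, math.inf
    sigma = rms / normalizer
    if sigma < SIGMA_PERFECT:
        return -math.inf, sigma
    return aicc(len(structure), X.shape[0], sigma), sigma


def select_term(
    current: Structure, postures: np.ndarray, targets: np.ndarray,
    normalizer: float, rho: int, d: int,
) -> Tuple[Structure, float]:
    """Best one-term expansion of ``current`` by AICc.

    Fits every candidate from :func:`~polymuscle.terms.expand_candidates`
    and returns the argmin-AICc structure with its AICc; the current
    structure is returned when no candidate improves on it.  Ties are broken
    toward the lowest-degree, lexicographically smallest added term (the
    candidate list is ordered that way, and only strict improvement
    replaces the incumbent best).
    """
    X = np.atleast_2d(np.asarray(postures, dtype=float))
    current_aicc, _ = _score(current, X, targets, normalizer)
    best_struct, best_aicc = current, current_aicc
    for cand in ta.expand_candidates(current, rho, d):
        cand_aicc, _ = _score(cand, X, targets, normalizer)
        if cand_aicc < best_aicc:
            best_struct, best_aicc = cand, cand_aicc
    return best_struct, best_aicc


def _normalizers(dataset: GridDataset) -> Tuple[float, List[float]]:
    l_range = float(np.ptp(dataset.lengths))
    if l_range < _NORMALIZER_FLOOR:
        logger.warning("length range ~0 over fit grid; normalizer set to 1 mm")
        l_range = 1.0
    m_max = []
    for i in range(dataset.dimension):
        m = float(np.max(np.abs(dataset.moments[:, i])))
        if m < _NORMALIZER_FLOOR:
            logger.warning(
                "moment arm %s ~0 over fit grid; normalizer set to 1 mm",
                dataset.dof_labels[i],
            )
            m = 1.0
        m_max.append(m)
    return l_range, m_max


def apply_constraint(
    L_structure: Structure,
    M_structures: Sequence[Structure],
    dataset: GridDataset,
    rho_l: int = RHO_L,
) -> Tuple[PolynomialModel, List[PolynomialModel]]:
    """Impose ``M_i = dL/dx_i`` on the term sets and refit coefficients.

    Steps: (1) integrate each moment-arm structure over its own DOF to get
    intermediate length structures; (2) union them all into the length
    structure; (3) re-derive every moment-arm structure by differentiating
    the new length structure; (4) re-estimate every coefficient set
    independently by least squares on the original dataset.
    """
    d = dataset.dimension
    intermediates = [
        integrate_structure(M_structures[i - 1], i, rho_max=rho_l)
        for i in range(1, d + 1)
    ]
    L_new = union_structures([L_structure, *intermediates])
    M_new = [differentiate_structure(L_new, i) for i in range(1, d + 1)]

    L_coeffs, _ = fit_coefficients(L_new, dataset.postures, dataset.lengths)
    L_poly = PolynomialModel(d, L_coeffs, dataset.dof_labels)
    M_polys = []
    for i in range(1, d + 1):
        c, _ = fit_coefficients(M_new[i - 1], dataset.postures,
                                dataset.moments[:, i - 1])
        M_polys.append(PolynomialModel(d, c, dataset.dof_labels))
    return L_poly, M_polys


def _prune_negligible(
    structure: Structure, X: np.ndarray, y: np.ndarray, normalizer: float,
    rel_tol: float = 1e-7,
) -> Structure:
    """Drop terms whose fitted contribution is numerically zero.

    A structure is defined by its *non-zero* coefficients; greedy expansion
    can pick up a term that later turns redundant once the true terms are
    in, leaving it with a coefficient at floating-point-noise level.  A
    term is dropped when ``|coef| * max|column|`` over the grid is below
    ``rel_tol`` times the target's normalization scale — far below any
    physically meaningful contribution.
    """
    return structure - _negligible_terms(structure, X, y, normalizer, rel_tol)


def _negligible_terms(
    structure: Structure, X: np.ndarray, y: np.ndarray, normalizer: float,
    rel_tol: float = 1e-7,
) -> frozenset:
    coeffs, _ = fit_coefficients(structure, X, y)
    if not coeffs:
        return frozenset()
    terms = sorted(coeffs, key=lambda t: (len(t), t))
    A = design_matrix(terms, X)
    col_max = np.max(np.abs(A), axis=0)
    return frozenset(
        t for t, cm in zip(terms, col_max)
        if abs(coeffs[t]) * cm < rel_tol * normalizer
    )


def _fit(
    dataset: GridDataset,
    rho_l: int,
    rho_m: int,
    constrained: bool,
    name: str,
    max_iterations: int,
) -> Tuple[MuscleModel, FitReport]:
    d = dataset.dimension
    X = dataset.postures
    l_range, m_max = _normalizers(dataset)

    # function index 0 = length, 1..d = moment arms
    fn_names = ["L"] + [f"M_{lbl}" for lbl in dataset.dof_labels]
    targets = [dataset.lengths] + [dataset.moments[:, i] for i in range(d)]
    normalizers = [l_range] + m_max
    rhos = [rho_l] + [rho_m] * d

    structures: List[Structure] = [frozenset() for _ in fn_names]
    frozen = [False] * len(fn_names)
    # first comparison is against the zero model L = 0, M_i = 0
    best_aicc = [
        _score(frozenset(), X, y, nrm)[0] for y, nrm in zip(targets, normalizers)
    ]
    report = FitReport(function_names=fn_names)

    for iteration in range(1, max_iterations + 1):
        added: Dict[str, object] = {}
        improved = False
        for j, fname in enumerate(fn_names):
            if frozen[j]:
                continue
            cand, cand_aicc = select_term(
                structures[j], X, targets[j], normalizers[j], rhos[j], d
            )
            # accept only strict improvement over the best AICc seen for
            # this function; keeps the accepted trace non-increasing and
            # guarantees termination
            if cand != structures[j] and cand_aicc < best_aicc[j]:
                added[fname] = next(iter(cand - structures[j]))
                structures[j] = cand
                best_aicc[j] = cand_aicc
                improved = True
            else:
                frozen[j] = True

        if constrained:
            L_poly, M_polys = apply_constraint(
                structures[0], structures[1:], dataset, rho_l=rho_l
            )
            structures = [L_poly.structure] + [m.structure for m in M_polys]

        rec_aicc, rec_rms = {}, {}
        for j, fname in enumerate(fn_names):
            a, sigma = _score(structures[j], X, targets[j], normalizers[j])
            rec_aicc[fname] = min(a, best_aicc[j])
            best_aicc[j] = rec_aicc[fname]
            rec_rms[fname] = 100.0 * sigma
        report.iterations.append(
            IterationRecord(iteration, rec_aicc, rec_rms, added)
        )

        if not improved:
            report.stop_reason = "no AICc improvement for any function"
            break
        if all(frozen):
            report.stop_reason = "all functions frozen"
            break
    else:
        report.stop_reason = f"iteration cap {max_iterations} reached"

    if constrained:
        # prune numerically-zero terms without breaking the derivative
        # constraint: an L term goes only if it is negligible in L and its
        # derivative image is negligible in every moment arm it feeds
        L_struct = structures[0]
        neg_L = _negligible_terms(L_struct, X, dataset.lengths, l_range)
        neg_M = [
            _negligible_terms(
                differentiate_structure(L_struct, i), X,
                dataset.moments[:, i - 1], m_max[i - 1],
            )
            for i in range(1, d + 1)
        ]
        pruned = set()
        for t in neg_L:
            images_ok = True
            for i in set(t):
                reduced = list(t)
                reduced.remove(i)
                if tuple(reduced) not in neg_M[i - 1]:
                    images_ok = False
                    break
            if images_ok:
                pruned.add(t)
        L_struct = L_struct - pruned
        L_coeffs, _ = fit_coefficients(L_struct, X, dataset.lengths)
        L_poly = PolynomialModel(d, L_coeffs, dataset.dof_labels)
        M_polys = []
        for i in range(1, d + 1):
            c, _ = fit_coefficients(
                differentiate_structure(L_struct, i), X,
                dataset.moments[:, i - 1],
            )
            M_polys.append(PolynomialModel(d, c, dataset.dof_labels))
    else:
        L_struct = _prune_negligible(structures[0], X, dataset.lengths, l_range)
        L_coeffs, _ = fit_coefficients(L_struct, X, dataset.lengths)
        L_poly = PolynomialModel(d, L_coeffs, dataset.dof_labels)
        M_polys = []
        for i in range(1, d + 1):
            struct = _prune_negligible(
                structures[i], X, dataset.moments[:, i - 1], m_max[i - 1]
            )
            c, _ = fit_coefficients(struct, X, dataset.moments[:, i - 1])
            M_polys.append(PolynomialModel(d, c, dataset.dof_labels))

    model = MuscleModel(
        name=name,
        dof_labels=dataset.dof_labels,
        roms=dataset.roms,
        L=L_poly,
        M=tuple(M_polys),
        l_range=l_range,
        m_max=tuple(m_max),
        mode="constrained" if constrained else "unconstrained",
        rho_l=rho_l,
        rho_m=rho_m,
    )
    return model, report


def fit_unconstrained(
    dataset: GridDataset, rho_l: int = RHO_L, rho_m: int = RHO_M,
    name: str = "muscle", max_iterations: int = 200,
) -> Tuple[MuscleModel, FitReport]:
    """Independent forward selection for the length and each moment arm.

    Each function grows by at most one term per iteration and freezes when
    its best candidate no longer lowers its AICc; the search ends when all
    functions are frozen.
    """
    return _fit(dataset, rho_l, rho_m, False, name, max_iterations)


def fit_constrained(
    dataset: GridDataset, rho_l: int = RHO_L, rho_m: int = RHO_M,
    name: str = "muscle", max_iterations: int = 200,
) -> Tuple[MuscleModel, FitReport]:
    """Forward selection with the length/moment-arm differential constraint
    applied (and all coefficients refit) after every expansion step.

    The returned model always satisfies
    ``structure(M_i) == structure(dL/dx_i)``.
    """
    return _fit(dataset, rho_l, rho_m, True, name, max_iterations)
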