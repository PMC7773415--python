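"""Canonical algebra of sparse multivariate polynomial terms (K-notation).

A musculotendon length surface ``L(x)`` over joint angles ``x`` (radians) is
represented as a sparse polynomial

    f(x) = a + sum_terms  K_{i1..ip} * x_{i1} * ... * x_{ip}

where each term is identified by the non-decreasing tuple of 1-based DOF
indices it multiplies: ``x1^2 * x2`` is the term ``(1, 1, 2)`` (written
``K112``).  Sorting the indices makes the representation unique — ``K121``
and ``K211`` collapse onto ``K112``.  The intercept ``a`` is the empty
tuple and participates in structures like any other term.

A *structure* is the set of terms present in a polynomial, irrespective of
coefficient values; structures are what the forward-selection search and the
similarity index operate on.  Coefficients are plain scalars in mm (lengths
and moment arms); angles are in radians.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np

logger = logging.getLogger(__name__)

#: Maximum total power of any term handled by the algebra.
RHO_MAX = 5

TermKey = Tuple[int, ...]
Structure = frozenset  # frozenset[TermKey]

#: The intercept term ``a``.
INTERCEPT: TermKey = ()


def canonical_term(indices: Iterable[int], d: int | None = None) -> TermKey:
    """Return the canonical (sorted) K-notation key for a product of DOFs.

    Parameters
    ----------
    indices
        1-based DOF indices, one per factor; ``(1, 2, 1)`` means
        ``x1 * x2 * x1``.  The empty sequence is the intercept.
    d
        Optional dimensionality; when given, indices must lie in ``[1, d]``.

    ``canonical_term`` is idempotent and permutation-invariant:
    ``(1, 2, 1) -> (1, 1, 2)``.
    """
    key = tuple(sorted(int(i) for i in indices))
    for i in key:
        if i < 1 or (d is not None and i > d):
            raise ValueError(f"DOF index {i} outside [1, {d}]")
    if len(key) > RHO_MAX:
        raise ValueError(f"term degree {len(key)} exceeds maximum power {RHO_MAX}")
    return key


def term_degree(term: TermKey) -> int:
    return len(term)


def structure(terms: Iterable[Iterable[int]], d: int | None = None) -> Structure:
    """Build a structure (set of canonical terms) from raw index tuples."""
    return frozenset(canonical_term(t, d) for t in terms)


def full_structure(d: int, rho: int) -> Structure:
    """All terms of a full ``d``-variable polynomial of power ``rho``,
    intercept included.  Its size is C(d + rho, rho)."""
    terms = [INTERCEPT]
    for p in range(1, rho + 1):
        terms.extend(combinations_with_replacement(range(1, d + 1), p))
    return frozenset(terms)


def full_size(d: int, rho: int) -> int:
    """Number of terms of the full polynomial: binomial(d + rho, rho)."""
    return math.comb(d + rho, rho)


def union_structures(structs: Sequence[Structure]) -> Structure:
    """Set union of term structures (step 2 of the constraint algorithm)."""
    out: frozenset = frozenset()
    for s in structs:
        out = out | s
    return out


def expand_candidates(P: Structure, rho: int, d: int) -> list[Structure]:
    """One-term expansions of structure ``P``.

    Returns one candidate per term of the full degree-``rho`` polynomial that
    is absent from ``P`` (the intercept counts as a term), each candidate
    being ``P`` plus that term.  The list is ordered by (degree, lexicographic
    index tuple) of the added term so that downstream tie-breaking is
    deterministic.  Empty when ``P`` is already full.
    """
    missing = sorted(full_structure(d, rho) - P, key=lambda t: (len(t), t))
    return [P | {t} for t in missing]


def power_signature(term: TermKey) -> Tuple[int, ...]:
    """Multiset of per-variable exponents of a term, sorted ascending.

    ``x1^2 * x2`` (term ``(1, 1, 2)``) has signature ``(1, 2)``.  The
    signature forgets *which* DOFs a term involves and keeps only the powers,
    which is the basis of the muscle-invariant representation.  The intercept
    carries no signature.
    """
    if len(term) == 0:
        raise ValueError("the intercept has no power signature")
    return tuple(sorted(Counter(term).values()))


def all_power_signatures(rho: int = RHO_MAX) -> set:
    """Distinct power signatures of terms with total degree 1..rho.

    For ``rho = 5`` these are the 18 integer partitions of 1 through 5.
    """
    sigs = set()
    for p in range(1, rho + 1):
        # partitions of p == signatures of degree-p terms
        for term in combinations_with_replacement(range(1, p + 1), p):
            if len(term) == p:
                try:
                    sigs.add(power_signature(canonical_term(term)))
                except ValueError:
                    pass
    # the loop above enumerates terms over p variables, degree exactly p,
    # which realizes every partition of p
    return {s for s in sigs}


@dataclass(frozen=True)
class PolynomialModel:
    """A polynomial structure with one scalar coefficient per term.

    Attributes
    ----------
    dimension
        Number of DOFs ``d`` the polynomial is defined over.
    coefficients
        Mapping from canonical :data:`TermKey` to its scalar coefficient
        (mm for lengths and moment arms).
    dof_labels
        Optional names of the DOFs, index ``i`` labelling ``x_i``.
    """

    dimension: int
    coefficients: Mapping[TermKey, float] = field(default_factory=dict)
    dof_labels: Tuple[str, ...] | None = None

    def __post_init__(self):
        canon: Dict[TermKey, float] = {}
        for term, c in self.coefficients.items():
            canon[canonical_term(term, self.dimension)] = float(c)
        object.__setattr__(self, "coefficients", canon)
        if self.dof_labels is not None:
            labels = tuple(self.dof_labels)
            if len(labels) != self.dimension:
                raise ValueError("dof_labels length must equal dimension")
            object.__setattr__(self, "dof_labels", labels)

    @property
    def structure(self) -> Structure:
        return frozenset(self.coefficients)

    @property
    def n_terms(self) -> int:
        return len(self.coefficients)

    def sorted_terms(self) -> list[TermKey]:
        return sorted(self.coefficients, key=lambda t: (len(t), t))

    def __call__(self, x) -> float | np.ndarray:
        return evaluate(self, x)


def design_matrix(terms: Sequence[TermKey], X: np.ndarray) -> np.ndarray:
    """Columns of monomial values for each term at each posture row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = np.empty((X.shape[0], len(terms)))
    for j, term in enumerate(terms):
        col = np.ones(X.shape[0])
        for i in term:
            col = col * X[:, i - 1]
        cols[:, j] = col
    return cols


def evaluate(poly: PolynomialModel, x) -> float | np.ndarray:
    """Evaluate a polynomial at one posture (1-D) or many (N x d).

    Exact for polynomial inputs; the empty polynomial evaluates to 0.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != poly.dimension:
        raise ValueError(
            f"posture has {X.shape[1]} coordinates, polynomial has "
            f"dimension {poly.dimension}"
        )
    if not poly.coefficients:
        out = np.zeros(X.shape[0])
    else:
        terms = poly.sorted_terms()
        coeffs = np.array([poly.coefficients[t] for t in terms])
        out = design_matrix(terms, X) @ coeffs
    return float(out[0]) if single else out


def differentiate(poly: PolynomialModel, dof: int) -> PolynomialModel:
    """Analytic partial derivative with respect to ``x_dof``.

    Term-wise power rule: a term containing ``dof`` with multiplicity ``m``
    maps to the term with one copy removed, coefficient scaled by ``m``;
    terms without ``dof`` vanish.  By the moment-arm convention used
    throughout, ``M_i = dL/dx_i``.
    """
    if dof < 1 or dof > poly.dimension:
        raise ValueError(f"DOF {dof} outside [1, {poly.dimension}]")
    out: Dict[TermKey, float] = {}
    for term, c in poly.coefficients.items():
        m = term.count(dof)
        if m == 0:
            continue
        reduced = list(term)
        reduced.remove(dof)
        key = tuple(reduced)
        out[key] = out.get(key, 0.0) + m * c
    return PolynomialModel(poly.dimension, out, poly.dof_labels)


def integrate(poly: PolynomialModel, dof: int, rho_max: int = RHO_MAX) -> PolynomialModel:
    """Term-wise antiderivative in ``x_dof`` plus a free constant term.

    A term with multiplicity ``m`` of ``dof`` maps to the term with one copy
    added, coefficient divided by ``m + 1``.  The constant of integration is
    represented by an intercept term with coefficient 0 (its value is always
    re-estimated by least squares afterwards).  A term whose degree would
    exceed ``rho_max`` is dropped with a warning; with moment-arm power
    capped at 4 and lengths at 5 this never triggers in the standard search.
    """
    if dof < 1 or dof > poly.dimension:
        raise ValueError(f"DOF {dof} outside [1, {poly.dimension}]")
    out: Dict[TermKey, float] = {INTERCEPT: 0.0}
    for term, c in poly.coefficients.items():
        if len(term) + 1 > rho_max:
            logger.warning(
                "integration of term %s over x%d exceeds max power %d; dropped",
                term, dof, rho_max,
            )
            continue
        m = term.count(dof)
        key = canonical_term(term + (dof,))
        out[key] = out.get(key, 0.0) + c / (m + 1)
    return PolynomialModel(poly.dimension, out, poly.dof_labels)


def differentiate_structure(S: Structure, dof: int) -> Structure:
    """Structure of the partial derivative: drop one copy of ``dof`` from
    each term containing it; other terms vanish."""
    out = set()
    for term in S:
        if dof in term:
            reduced = list(term)
            reduced.remove(dof)
            out.add(tuple(reduced))
    return frozenset(out)


def integrate_structure(S: Structure, dof: int, rho_max: int = RHO_MAX) -> Structure:
    """Structure of the antiderivative in ``dof``, including the free
    constant of integration (intercept)."""
    out = {INTERCEPT}
    for term in S:
        if len(term) + 1 > rho_max:
            logger.warning(
                "integration of term %s over x%d exceeds max power %d; dropped",
                term, dof, rho_max,
            )
            continue
        out.add(canonical_term(term + (dof,)))
    return frozenset(out)


def term_label(term: TermKey) -> str:
    """Human-readable K-notation, e.g. ``(1, 1, 2) -> 'K112'``, ``() -> 'a'``."""
    return "a" if len(term) == 0 else "K" + "".join(str(i) for i in term)
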