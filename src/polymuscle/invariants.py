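"""Structural and functional analysis of fitted polynomials.

Two complementary views of a muscle's polynomial:

* the **similarity index** compares two term *structures* —
  ``SI = 100 * N_C / (N_ANC + N_BNC + N_C)`` with ``N_C`` shared terms and
  ``N_ANC``/``N_BNC`` terms unique to either side;
* the **muscle invariant** is an 18-dimensional unit vector built from the
  *coefficients*: for each power signature (multiset of per-variable
  exponents, e.g. ``x1*x2^2 -> (1, 2)``) it sums the absolute coefficients
  of all terms with that signature, then normalizes to unit length.  The
  signature forgets DOF identity, so invariants can be compared between
  muscles that span entirely different joints.

Euclidean distances between invariants feed average-linkage hierarchical
clustering and PCA, and two pair-construction procedures test whether
anatomical (shared-DOF) and functional (shared-category) relationships are
reflected in invariant space.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .terms import PolynomialModel, Structure, power_signature

logger = logging.getLogger(__name__)

#: Ordering of the 18 power signatures along the invariant axes
#: (v1 .. v18).  Note this is the ordering used for the invariant vector
#: throughout; a tabulated index that lists the single-variable powers
#: first — (1), (2), ..., (1,1), (1,2), ... — is a different, conflicting
#: convention and is NOT used here (under that ordering the worked example
#: below would not land on v9/v12/v16).
SIGNATURE_ORDER: Tuple[Tuple[int, ...], ...] = (
    (1, 1, 1, 1, 1),
    (1, 1, 1, 1),
    (1, 1, 1, 2),
    (1, 1, 1),
    (1, 1, 2),
    (1, 1, 3),
    (1, 1),
    (1, 2, 2),
    (1, 2),       # v9:  e.g. x1*x2^2 and x1^2*x2
    (1, 3),
    (1, 4),
    (1,),         # v12: linear terms
    (2, 2),
    (2, 3),
    (2,),
    (3,),         # v16: cubic single-variable terms
    (4,),
    (5,),
)
_SIG_INDEX = {s: i for i, s in enumerate(SIGNATURE_ORDER)}

N_SIGNATURES = len(SIGNATURE_ORDER)


def similarity_index(A: Structure, B: Structure) -> float:
    """Percentage of shared terms between two polynomial structures.

    100% for identical structures, 0% for disjoint ones; symmetric.  Two
    empty structures are identical by convention (logged).
    """
    A, B = frozenset(A), frozenset(B)
    if not A and not B:
        logger.info("similarity of two empty structures defined as 100%%")
        return 100.0
    n_c = len(A & B)
    n_anc = len(A - B)
    n_bnc = len(B - A)
    return 100.0 * n_c / (n_anc + n_bnc + n_c)


def invariant_vector(L: PolynomialModel) -> np.ndarray:
    """18-dimensional unit muscle invariant of a length polynomial.

    Sums ``|coefficient|`` over all terms sharing each power signature
    (intercept excluded), then normalizes to unit Euclidean length.  The
    zero polynomial maps to the zero vector with a warning.
    """
    v = np.zeros(N_SIGNATURES)
    for term, c in L.coefficients.items():
        if len(term) == 0:
            continue
        v[_SIG_INDEX[power_signature(term)]] += abs(c)
    norm = np.linalg.norm(v)
    if norm == 0:
        logger.warning("zero polynomial has a zero invariant vector")
        return v
    return v / norm


@dataclass(frozen=True)
class InvariantGeometry:
    """Pairwise distances, average-linkage tree and PCA of invariants."""

    labels: Tuple[str, ...]
    distance_matrix: np.ndarray      # n x n Euclidean, symmetric, zero diag
    linkage: np.ndarray              # scipy average-linkage matrix
    pca_scores: np.ndarray           # n x 2 projection
    explained_variance: Tuple[float, float]


def invariant_distances(
    vectors: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
) -> InvariantGeometry:
    """Euclidean distance matrix, average-linkage dendrogram and 2-component
    PCA of a collection of muscle invariants."""
    if isinstance(vectors, Mapping):
        labels = tuple(vectors)
        V = np.stack([vectors[k] for k in labels])
    else:
        V = np.stack(list(vectors))
        labels = tuple(labels) if labels is not None else tuple(
            f"m{i}" for i in range(V.shape[0])
        )
    if V.shape[0] < 2:
        raise ValueError("need at least 2 invariant vectors")
    condensed = pdist(V, metric="euclidean")
    Z = hierarchy.linkage(condensed, method="average")
    n_comp = min(2, V.shape[0] - 1, V.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(V)
    evr = tuple(float(r) for r in pca.explained_variance_ratio_)
    if len(evr) < 2:
        evr = (evr[0], 0.0)
        scores = np.column_stack([scores, np.zeros(V.shape[0])])
    return InvariantGeometry(labels, squareform(condensed), Z, scores, evr)


@dataclass(frozen=True)
class PairedGroupTest:
    """Result of a with-group vs without-group invariant-distance test.

    ``differences`` holds every (with-pair distance − without-pair distance)
    for without-pairs sharing one muscle with the with-pair, built per
    DOF (or per DOF × category cell).  A negative median difference means
    with-group pairs are closer together.
    """

    with_distances: np.ndarray
    without_distances: np.ndarray
    differences: np.ndarray
    median_difference: float
    fraction_negative: float
    mannwhitney_u: float
    mannwhitney_p: float
    sign_test_p: float
    normality_p_with: float
    normality_p_without: float
    alpha: float

    @property
    def significant(self) -> bool:
        return self.sign_test_p < self.alpha and self.mannwhitney_p < self.alpha


_PHALANGEAL = re.compile(r"^(?P<joint>mcp|pip|dip)[2-5]$")


def pool_phalangeal(label: str) -> str:
    """Pool MCP/PIP/DIP labels across fingers 2-5.

    ``ra_mcp3_f_e -> ra_mcp_f_e`` etc.; the same joint level on different
    fingers is treated as one DOF for pair construction (fingers share
    geometry and the model has no intrinsic hand muscles to distinguish
    them).  Other labels pass through unchanged.
    """
    parts = label.split("_")
    if len(parts) >= 2:
        m = _PHALANGEAL.match(parts[1])
        if m:
            parts[1] = m.group("joint")
    return "_".join(parts)


def _pooled_incidence(
    dof_incidence: Mapping[str, Sequence[str]], pool
) -> Dict[str, frozenset]:
    if pool is None:
        pool = lambda s: s  # noqa: E731
    return {m: frozenset(pool(l) for l in dofs)
            for m, dofs in dof_incidence.items()}


def _dist(vectors: Mapping[str, np.ndarray], a: str, b: str) -> float:
    return float(np.linalg.norm(vectors[a] - vectors[b]))


def _difference_population(
    with_pairs: List[Tuple[str, str]],
    without_pairs: List[Tuple[str, str]],
    vectors: Mapping[str, np.ndarray],
) -> List[float]:
    diffs = []
    for a, b in with_pairs:
        w = _dist(vectors, a, b)
        for c, e in without_pairs:
            if len({a, b} & {c, e}) == 1:
                diffs.append(w - _dist(vectors, c, e))
    return diffs


def _run_tests(
    with_d: np.ndarray, without_d: np.ndarray, diffs: np.ndarray, alpha: float
) -> PairedGroupTest:
    def safe_normaltest(x):
        return float(stats.normaltest(x).pvalue) if x.size >= 20 else float("nan")

    u_res = stats.mannwhitneyu(with_d, without_d, alternative="less")
    nz = diffs[diffs != 0]
    if nz.size:
        # one-sided sign test: are with-pairs systematically closer
        # (median difference < 0)?
        sign_p = float(
            stats.binomtest(int(np.sum(nz < 0)), nz.size, 0.5,
                            alternative="greater").pvalue
        )
    else:
        sign_p = 1.0
    return PairedGroupTest(
        with_distances=with_d,
        without_distances=without_d,
        differences=diffs,
        median_difference=float(np.median(diffs)) if diffs.size else 0.0,
        fraction_negative=float(np.mean(diffs < 0)) if diffs.size else 0.0,
        mannwhitney_u=float(u_res.statistic),
        mannwhitney_p=float(u_res.pvalue),
        sign_test_p=sign_p,
        normality_p_with=safe_normaltest(with_d),
        normality_p_without=safe_normaltest(without_d),
        alpha=alpha,
    )


def shared_dof_test(
    vectors: Mapping[str, np.ndarray],
    dof_incidence: Mapping[str, Sequence[str]],
    alpha: float = 0.01,
    pool=pool_phalangeal,
) -> PairedGroupTest:
    """Do muscles sharing a DOF sit closer together in invariant space?

    For every (pooled) DOF, pairs of muscles that both actuate it form the
    with-group and pairs with exactly one actuating muscle form the
    without-group; each pair is selected once per DOF (the same pair may
    recur at another DOF).  The difference population subtracts every
    without-pair distance sharing one muscle with a with-pair from that
    with-pair's distance, within the same DOF.  Reports a one-tailed
    Mann-Whitney U (with < without), a one-sided sign test of the
    difference population against zero median, and D'Agostino normality
    checks of both groups.
    """
    inc = _pooled_incidence(dof_incidence, pool)
    muscles = sorted(vectors)
    all_dofs = sorted(set().union(*inc.values()))
    with_d: List[float] = []
    without_d: List[float] = []
    diffs: List[float] = []
    usable = 0
    for dof in all_dofs:
        members = [m for m in muscles if dof in inc[m]]
        others = [m for m in muscles if dof not in inc[m]]
        if len(members) < 2 or not others:
            continue
        usable += 1
        wp = list(combinations(members, 2))
        op = [(a, b) for a in members for b in others]
        with_d += [_dist(vectors, a, b) for a, b in wp]
        without_d += [_dist(vectors, a, b) for a, b in op]
        diffs += _difference_population(wp, op, vectors)
    if usable < 2:
        raise ValueError("need at least 2 DOFs with >=2 actuating muscles")
    return _run_tests(
        np.asarray(with_d), np.asarray(without_d), np.asarray(diffs), alpha
    )


def shared_function_test(
    vectors: Mapping[str, np.ndarray],
    categories: Mapping[str, str],
    dof_incidence: Mapping[str, Sequence[str]],
    alpha: float = 0.01,
    pool=pool_phalangeal,
) -> PairedGroupTest:
    """Does shared function separate muscles beyond shared anatomy?

    Pairs are conditioned on actuating the same (pooled) DOF, then split by
    whether the two muscles belong to the same functional category; pairs
    are selected once per DOF × category cell.  Cells with fewer than two
    same-category muscles at a DOF are skipped (logged).  Tests as in
    :func:`shared_dof_test`.
    """
    missing = [m for m in vectors if m not in categories]
    if missing:
        raise ValueError(f"no category for muscles: {missing}")
    inc = _pooled_incidence(dof_incidence, pool)
    muscles = sorted(vectors)
    all_dofs = sorted(set().union(*inc.values()))
    with_d: List[float] = []
    without_d: List[float] = []
    diffs: List[float] = []
    for dof in all_dofs:
        members = [m for m in muscles if dof in inc[m]]
        cats_here = sorted({categories[m] for m in members})
        for cat in cats_here:
            same = [m for m in members if categories[m] == cat]
            other = [m for m in members if categories[m] != cat]
            if len(same) < 2:
                logger.info("DOF %s category %r has <2 muscles; skipped",
                            dof, cat)
                continue
            if not other:
                continue
            wp = list(combinations(same, 2))
            op = [(a, b) for a in same for b in other]
            with_d += [_dist(vectors, a, b) for a, b in wp]
            without_d += [_dist(vectors, a, b) for a, b in op]
            diffs += _difference_population(wp, op, vectors)
    if not with_d or not without_d:
        raise ValueError(
            "no usable DOF x category cells (single category everywhere?)"
        )
    return _run_tests(
        np.asarray(with_d), np.asarray(without_d), np.asarray(diffs), alpha
    )
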