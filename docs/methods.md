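# Methods

## The surrogate model

A musculotendon actuator spanning `d` joint DOFs is described by two
coupled kinematic quantities over the posture vector `x = (x1, …, xd)`
(radians): the musculotendon length `L(x)` (mm) and one moment arm
`M_i(x)` (mm) per spanned DOF.  Both are approximated by sparse
multivariate polynomials

    f(x) = a + Σ K_{i1..ip} · x_{i1} · … · x_{ip}

where each term is identified by the non-decreasing tuple of DOF indices
it multiplies (K-notation: `x1²x2 → K112`).  Sorting makes the
representation canonical; the intercept `a` is the empty tuple and is
treated as an ordinary term during selection.  A *structure* is the set of
terms with non-zero coefficients, independent of their values.

Maximum total power is ρ = 5 for lengths and ρ = 4 for moment arms, so
that differentiation and integration map the two families onto each other
without truncation.  (Integration that would exceed ρ = 5 drops the
offending term with a logged warning; it cannot occur under the default
power caps.)

The moment-arm convention used throughout is `M_i = ∂L/∂x_i`, with no
sign flip.  Which sign convention a lab uses is immaterial here as long
as the data are internally consistent; the synthetic oracles generate
moment arms as exact analytic partials of the length, so the convention
holds by construction.

## Term selection

Coefficients for a fixed structure are estimated by linear least squares
(`numpy.linalg.lstsq`, i.e. a pseudoinverse; rank-deficient designs fall
back to the minimum-norm solution with a warning).  Structures are grown
by forward stepwise selection scored with the small-sample-corrected
Akaike information criterion

    AICc = 2k + 2N·ln(σ) + 2k(k+1)/(N − k − 1)

with `k` the number of coefficients (intercept included), `N` the number
of grid samples, and `σ` the *normalized* RMS residual: length residuals
are divided by the length range over the fit grid, each moment arm's by
its maximum magnitude.  Normalization puts all functions of a muscle on a
common error scale so their AICc values are comparable across DOFs.

Each iteration expands every still-active function by at most one term:
all one-term extensions of the current structure (drawn from the full
degree-ρ polynomial, intercept included) are fitted and the AICc argmin is
taken.  The candidate list is ordered by (degree, lexicographic index
tuple) and only strict improvement replaces the incumbent, so ties break
deterministically toward simpler terms.  The first iteration scores
against the zero model `L = 0, M_i = 0`.  A function freezes when its best
candidate no longer lowers its AICc; the loop ends when every function is
frozen.

Numerical choices:

* **Perfect-fit floor.**  A normalized RMS below 1e-9 is treated as an
  exact fit (AICc = −∞).  Without the floor, double-precision noise
  (~1e-14) keeps "improving" `ln σ` after the target is already exactly
  represented and drags arbitrary extra terms in.
* **Zero-coefficient pruning.**  Greedy expansion can accept a term that
  later turns redundant once the true terms arrive, leaving it with a
  coefficient at floating-point-noise level.  Because a structure is
  defined by its non-zero coefficients, the final refit drops terms whose
  fitted contribution (|coef| × max |monomial| over the grid) is below
  1e-7 of the function's normalization scale, then refits.  In
  constrained mode a length term is dropped only when it is negligible in
  `L` *and* its derivative image is negligible in every moment arm it
  feeds, so pruning never breaks the differential constraint.
* **Degenerate targets.**  A constant-length muscle has zero length range;
  its normalizer falls back to 1 mm (logged) so the constant fit is still
  scored, and the search correctly returns the intercept-only structure.

## The differential constraint

Moment arms are partial derivatives of length, so the two families of
polynomials are not independent.  In constrained mode, after each
expansion step the term sets are made mutually consistent:

1. integrate each `M_i` structure over its own DOF (adding the free
   constant of integration);
2. union the results into the `L` structure;
3. re-derive every `M_i` structure as the analytic derivative of the new
   `L` structure;
4. refit every coefficient set independently by least squares on the
   original dataset.

Coefficients of `L` and of each `M_i` are *not* shared — only the term
sets are linked.  The returned model always satisfies
`structure(M_i) = structure(∂L/∂x_i)` exactly (checked symbolically in the
tests).  Two readings of the loop's stopping rule were possible; this
implementation freezes each function individually, accepting a candidate
only when it beats the best AICc that function has seen.  That makes the
accepted AICc trace non-increasing by construction and guarantees
termination, since structures grow monotonically and are bounded by the
full polynomial.  Whether the post-constraint refit should couple length
and moment-arm information was left open; independent per-target least
squares was chosen as the simpler, better-conditioned option.

## Synthetic geometry

No geometric musculoskeletal model is bundled; the generator emulates one.
`synth_muscle` draws a sparse ground-truth length polynomial (degree ≤ 5)
over the muscle's DOFs and derives moment arms analytically, so sampled
datasets are internally consistent and structure recovery is a
well-defined target.  Coefficients are scaled relative to the ROM extent
and then jointly calibrated so the length excursion over the ROM falls in
30–80 mm with the shortest length in 50–100 mm — physiologically plausible
for forearm muscles and guaranteeing the Hill passive-slack inequality
`L_min < 0.9·L_max`.  An optional `wobble` adds a smooth sinusoidal
component (with matching analytic derivatives) to exercise the regime
where no finite polynomial is exact; by Taylor's theorem the polynomial
search still approximates it, and differentiation amplifies the
non-polynomial residual, which is why moment arms fit worse than lengths.

What the generator does **not** emulate: wrapping-surface and via-point
geometry, path discontinuities (muscles slipping off wrapping surfaces),
measurement noise structure of real motion-capture pipelines, and
inter-muscle correlations of real anatomy.  Passing tests therefore
demonstrate the correctness and statistical behaviour of the *method*, not
the error levels attainable on any particular anatomical model.

Posture grids: fitting uses a uniform 9-point grid per DOF including both
ROM endpoints (9^d postures); testing uses the 8 midpoints of adjacent
9-grid nodes (8^d postures), strictly interior and maximally far from the
fit samples.

### The 33-muscle arm fixture

`arm_fixture` names 33 synthetic actuators over 18 DOFs (wrist
pronation-supination and extension-flexion, four thumb joints, MCP/PIP/DIP
of fingers 2–5), tagged with seven functional categories (wrist
supinators, pronators, extensors, flexors; finger flexors, extensors;
thumb muscles).  The muscle → DOF incidence is a plausible anatomical
assignment constrained so the per-muscle DOF counts are exactly
[5, 7, 7, 12, 1, 1] muscles spanning 1–6 DOFs — the unique distribution
for which the roster totals 674,937 fit-grid postures, 348,136 test-grid
postures, and 3,481,360 / 19,450,000 perturbation length / moment-arm
samples at 10 draws per posture.  Per-muscle polynomial sizes grow
linearly with DOF count (≈ 7 terms per DOF) to mirror how selected
structures scale.  The incidence is synthetic and documented as such in
the module.

## Validation metrics

Errors are normalized RMS percentages (residual RMS over the length range
or the maximum |M|).  Outliers among absolute errors are screened with the
maximum-expected-error threshold `MEE = mean + (1/α)·sd`; α = 0.1 places
the cut 10 standard deviations out, which by Chebyshev's inequality
excludes at most 1% of *any* distribution (1 − 1/k² = 0.99 at k = 10) —
appropriate because fit-error distributions are heavy-tailed and
non-normal.  The rule is applied to absolute errors pooled per quantity
(lengths vs moment arms) across muscles.

The complexity analysis regresses selected term count on spanned DOF count
with a linear and a free two-parameter exponential fit
(`y = b·exp(c·x)`, seeded from a log-linear fit and refined by
least squares).  Before the final fits, muscles whose residuals exceed
median + 1.5·IQR under **both** preliminary fits are removed (Tukey's
rule); requiring both keeps the screen conservative.  Correlation p-values
come from the t distribution of the Pearson correlation.  Relative
complexity is the share of the full parameter space used:
`100·n_terms/C(d+ρ, ρ)` (intercept counted; e.g. 3 of 6 terms of a full
2-variable power-2 polynomial = 50%).

## Invariants and structure/function analysis

The similarity index compares two structures:
`SI = 100·N_C/(N_ANC + N_BNC + N_C)` with `N_C` shared and
`N_ANC`/`N_BNC` unique terms.  Two empty structures are defined as
identical (SI = 100, logged).

The muscle invariant maps a length polynomial onto the 18 power
signatures — the integer partitions of 1…5, i.e. multisets of
per-variable exponents (`x1x2² → (1,2)`) — by summing |coefficient| per
signature (intercept excluded) and normalizing to unit length.  Two
orderings of the 18 signatures circulate: the tabulated index that lists
single-variable powers first, and the ordered list
`[(1,1,1,1,1), (1,1,1,1), (1,1,1,2), (1,1,1), (1,1,2), (1,1,3), (1,1),
(1,2,2), (1,2), (1,3), (1,4), (1), (2,2), (2,3), (2), (3), (4), (5)]`.
They conflict; this package uses the latter throughout (it is the one
consistent with the v9 = (1,2), v12 = (1), v16 = (3) worked example), and
the conflict is recorded here rather than silently reconciled.

Invariant geometry uses Euclidean distances, average-linkage hierarchical
clustering (SciPy) with Newick export (scikit-bio), and 2-component PCA
(scikit-learn) with explained-variance fractions.

Two pair-construction procedures test what the invariants encode, with
phalangeal DOFs (MCP/PIP/DIP) pooled across fingers 2–5:

* **shared-DOF test** — per pooled DOF, pairs of muscles both actuating it
  vs pairs with exactly one; pairs are selected once per DOF, so a pair
  recurring at several DOFs is counted at each (the counting rule is
  exposed via the `pool` parameter rather than asserted, since several
  de-duplication conventions are defensible).  The difference population
  subtracts, within a DOF, every without-pair distance sharing one muscle
  from each with-pair distance.
* **shared-function test** — pairs conditioned on actuating the same
  pooled DOF, split by functional-category match, selected once per
  DOF × category cell; cells with fewer than two same-category muscles
  are skipped with a log message.

Both report D'Agostino normality of the two distance groups (sample size
permitting), a one-tailed Mann-Whitney U (with-group stochastically
smaller), and a one-sided sign test of the difference population against
zero median (`binomtest` on the negative count — chosen over the signed
rank test because no symmetry is assumed), all at α = 0.01.

## Hill-type mechanics and noise propagation

Isometric force:  `F = u·F_max·F_a + 0.1·F_max·F_P` with
`F_a = 2.5·L_norm − 1.25·L_norm²` (clamped `L_norm ∈ [0,1]`; peaks at
1.25) and passive factor 0 below the slack length `L_pass = 0.9·L_max`,
then `(exp(2(L − L_pass)/(L_max − L_min)) − 1)/(e − 1)`.  Activation
defaults to u = 1 (maximal isometric contraction); `F_max` defaults to
100 N and cancels out of all normalized error statistics.  Torque per DOF
is `τ_i = M_i·F`.

The perturbation protocol adds noise to the *kinematic values* (not the
joint angles — noise magnitudes are specified as fractions of the
kinematic ranges, which only makes sense on the values themselves): per
posture of the 8-point grid, 10 draws of
`L' = clip(L + N(0, level·ΔL), L_min, L_max)` and
`M_i' = M_i + N(0, 10·level·max|M_i|)`, at levels 0.1, 1, 10 and 20% —
the lowest matching typical surrogate fit errors, the highest matching
kinematic errors without data-driven calibration.  Lengths are clamped to
the ROM (muscle excursion is physically bounded); moment-arm noise is not
clamped (moment-arm errors are unbounded).  The moment-arm noise scale is
per-DOF (that DOF's max |M|) rather than muscle-global; this was an open
choice and is flagged for sensitivity analysis.  Force and torque
deviations are normalized to each muscle's reference range over the grid;
muscles with a degenerate range are skipped with a warning.  Reported
statistics are the pooled mean and IQR per noise level.  The printed
values depend on the synthetic muscle set; the validated claims are the
orderings (errors grow monotonically with level; torque errors exceed
force errors from 1% on; near-linear growth at small noise).

## Problem sizes

The test suite and examples run at desk scale by choice of fixture size:
structure-recovery and search tests use muscles of d ≤ 4 on 9-point grids
(up to 6,561 postures), constraint and greedy-optimality checks use 5-point
grids, the perturbation study uses the d ≤ 2 fixture muscles on 8-point
grids, and the complexity regression fits two muscles per d ∈ {1..4}.
Full-roster totals (674,937 postures etc.) are verified combinatorially
from the DOF incidence rather than by materializing the d = 6 grids, whose
fitting cost grows steeply with dimensionality.

## Known limitations

* Forward selection is greedy: one term per function per iteration, no
  backward elimination.  On small samples AICc may stop before an exact
  representation (correctly, by its own trade-off).  A two-term variant
  is out of scope.
* Only monomial bases are supported; periodic or sigmoidal geometry would
  be better served by trigonometric/exponential terms.
* The statistical pair tests reuse muscles across pairs, so the
  difference-population samples are not independent; the sign test is
  used descriptively, as in the analysis it mirrors.
* The arm fixture's DOF incidence and geometry are synthetic; none of the
  fixture's numeric results characterize any real anatomical model.
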