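"""How polynomial size scales with the number of DOFs a muscle spans.

Fits fixture muscles spanning 1-4 DOFs and regresses selected term count
on DOF count.  A full degree-5 polynomial grows combinatorially
(C(d+5, 5): 6, 21, 56, 126, ... terms) but the AICc-selected structures
grow far more slowly, so their relative complexity (share of the full
parameter space) falls with d.
"""

import numpy as np

from polymuscle import (
    complexity_regression,
    fit_constrained,
    fixture_arm_model,
    full_size,
    make_grid,
    relative_complexity,
    sample_dataset,
)

roster = fixture_arm_model(seed=1)
picked = []
for d in (1, 2, 3, 4):
    picked += [m for m in roster if m.oracle.dimension == d][:2]

term_counts, dof_counts = [], []
for muscle in picked:
    grid = make_grid(muscle.oracle.dofs, points=9 if muscle.oracle.dimension < 4 else 7)
    dataset = sample_dataset(muscle.oracle, grid)
    model, _ = fit_constrained(dataset, name=muscle.name)
    n = model.L.n_terms
    term_counts.append(n)
    dof_counts.append(muscle.oracle.dimension)
    rel = relative_complexity(n, muscle.oracle.dimension, 5)
    print(f"{muscle.name:7s} d={muscle.oracle.dimension}  "
          f"{n:3d} terms of {full_size(muscle.oracle.dimension, 5):3d} "
          f"({rel:.1f}% of the parameter space)")

fit = complexity_regression(term_counts, dof_counts)
slope, icpt = fit.linear
print(f"\nlinear fit: terms = {slope:.2f} * d + {icpt:.2f}  (r = {fit.linear_r:.3f})")
print("relative complexity falls with d — the structure search defeats the "
      "combinatorial growth of the full polynomial.")
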