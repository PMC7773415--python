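"""The length/moment-arm differential constraint on a worked example.

A muscle's moment arm about DOF i is the partial derivative of its length:
M_i = dL/dx_i.  Starting from L = 2 x1 x2^2, M1 = 3 x1^3 + 2 and
M2 = 5 x1 x2, the constraint integrates each moment arm, unions the
results into L, and re-derives both moment-arm structures — making the
three functions structurally consistent.
"""

from polymuscle import apply_constraint, make_grid, sample_dataset, synth_muscle
from polymuscle.terms import structure, term_label


def show(name, terms):
    print(f"{name}: ({', '.join(term_label(t) for t in sorted(terms, key=lambda t: (len(t), t)))})")


L0 = structure([(1, 2, 2)])              # 2 x1 x2^2
M1 = structure([(), (1, 1, 1)])          # 3 x1^3 + 2
M2 = structure([(1, 2)])                 # 5 x1 x2
show("initial L ", L0)
show("initial M1", M1)
show("initial M2", M2)

# any 2-DOF dataset supplies the grid the coefficients are refit on
oracle = synth_muscle(d=2, n_terms=4, seed=0)
dataset = sample_dataset(oracle, make_grid(oracle.dofs, points=9))
L, M = apply_constraint(L0, [M1, M2], dataset)

print("\nafter the constraint:")
show("L ", L.structure)    # (a, K1, K122, K1111)
show("M1", M[0].structure)  # (a, K22, K111) = dL/dx1
show("M2", M[1].structure)  # (K12)          = dL/dx2

# The moment-arm structures are now exactly the analytic derivatives of
# the length structure; the coefficients are refit independently by least
# squares on the dataset.
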