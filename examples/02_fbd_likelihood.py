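"""Evaluate the fossilised birth-death skyline likelihood by hand.

Builds a tiny 2-fossil tree, shows the two auxiliary functions p(t)
(probability a lineage leaves no sampled descendants) and q(t) (the
edge factor), and the resulting log density of the tree.
"""

from paleosky import (
    BDSKYParams,
    edge_factor,
    fbd_log_likelihood,
    make_time_grid,
    no_sample_prob,
)
from paleosky.core import Node, TimeTree

grid = make_time_grid([66.0])
params = BDSKYParams(origin_age=25.0, lam=(0.15,), mu=(0.05,), psi=(0.1,))

for t in (0.0, 5.0, 25.0):
    print(f"t={t:5.1f}  p={no_sample_prob(t, params, grid):.4f}  "
          f"log q={edge_factor(t, params, grid, log=True):+.4f}")

tree = TimeTree(
    Node(age=10.0, children=[Node(age=2.0, label="F1"), Node(age=4.5, label="F2")]),
    origin_age=25.0,
)
print("log L =", round(fbd_log_likelihood(tree, params, grid), 4))
# p(0) = 1 with rho = 0 (a lineage reaching the reference age unseen is
# never sampled there); p falls with depth because older lineages have
# more chances to leave fossils. The log-likelihood combines one
# speciation, two fossil tips and the >=1-fossil conditioning.
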