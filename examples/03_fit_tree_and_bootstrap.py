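"""ML tree estimation with bootstrap support on a small simulated dataset.

The search is neighbor joining on pairwise ML distances followed by NNI
hill climbing; support is the percentage of bootstrap replicate trees
containing each bipartition of the point estimate.
"""

import numpy as np

from regraft import (
    SubstitutionModel,
    bootstrap_support,
    ml_tree,
    random_tree,
    robinson_foulds,
    simulate_alignment,
    write_newick,
)

rng = np.random.default_rng(7)
model = SubstitutionModel.wag(alpha=0.8, p_inv=0.1)
labels = [f"t{i:02d}" for i in range(12)]
true = random_tree(labels, rng, branch_length=lambda: float(rng.uniform(0.05, 0.3)))
aln = simulate_alignment(true, model, 500, seed=3)

tree, lnl = ml_tree(aln, model)
print(f"ML tree lnL = {lnl:.2f}; RF distance to the generating tree = "
      f"{robinson_foulds(tree, true)}")

support = bootstrap_support(aln, model, replicates=50, seed=1, tree=tree)
sups = sorted(
    v.support for v in support.edges() if v.children and v.support is not None
)
print("bootstrap support per internal edge (%):", [int(s) for s in sups])
print(write_newick(support, support=True))
# High support on every internal edge means the 500 simulated columns carry
# enough signal to resolve this 12-taxon topology unambiguously.
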