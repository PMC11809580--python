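"""AU and SH topology tests on per-site log-likelihoods.

Simulates strong-signal data on a known tree, then asks whether a
nearest-neighbor-interchange of the true topology can be rejected.  Both
tests resample per-site log-likelihoods (RELL); the AU test additionally
fits the rejection probability across bootstrap scales, making it less
conservative than SH.  A p-value below 0.05 rejects the tested topology.
"""

import numpy as np

from treestab import SubstModel, assess_significance
from treestab.synthdata import sample_tree, simulate_alignment

model = SubstModel.jc69()
rng = np.random.default_rng(3)
tree = sample_tree(8, rng)
for eid in tree.internal_edges():
    tree.edges[eid].length = max(tree.edges[eid].length, 0.1)
aln = simulate_alignment(tree, model, 2000, rng)

wrong = tree.nni_neighbors(tree.internal_edges()[0])[0]
au_p, sh_p = assess_significance(wrong, tree, aln, model, B=1000, seed=1)
print(f"testing an NNI-perturbed topology against the truth "
      f"({aln.n_taxa} taxa, {aln.n_sites} sites):")
print(f"  AU p = {au_p:.4f}   SH p = {sh_p:.4f}")
print("  -> the perturbed topology is "
      + ("rejected" if au_p < 0.05 else "not rejected")
      + " at the 0.05 level; strong data discriminate single NNI moves.")
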