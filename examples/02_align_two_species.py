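"""Align two synthetic species networks and recover the hidden orthology.

Generates a twin network pair (a shared core with 5% rewiring noise plus
species-specific genes), reveals half of the true gene correspondence as
anchors, cross-trains the two autoencoders into a joint latent space, and
asks where the *held-out* true pairs rank in the cross-species score matrix.
"""

import numpy as np
from scipy.stats import mannwhitneyu

from etna.align import fit_joint, score_matrix
from etna.graph_io import anchors_from_pairs
from etna.synthetic import TWIN_PRESETS, generate_network_pair

netA, netB, truth = generate_network_pair(seed=7, **TWIN_PRESETS["twin"])
anchors = anchors_from_pairs(truth.anchors, netA, netB)
held = truth.held_out_pairs()
print(f"species A: {netA.n} genes; species B: {netB.n} genes; "
      f"{len(anchors)} ortholog anchors; {len(held)} held-out true pairs")

joint = fit_joint(netA, netB, anchors, blocks=10, seed=7)
print(f"final block losses: {joint.log[-1]}")

S = score_matrix(joint)
ridx = {g: i for i, g in enumerate(S.row_ids)}
cidx = {g: i for i, g in enumerate(S.col_ids)}
allv = S.values.ravel()
true_scores = np.array([S.values[ridx[a], cidx[b]] for a, b in held])
percentiles = [(allv < s).mean() * 100 for s in true_scores]
rng = np.random.default_rng(0)
rand = allv[rng.choice(allv.size, 5000, replace=False)]
p = mannwhitneyu(true_scores, rand, alternative="greater").pvalue

print(f"median percentile of held-out true pairs: {np.median(percentiles):.1f}")
print(f"one-sided rank-sum p (true pairs > random pairs): {p:.2g}")
print("A median percentile above 90 means the joint embedding places a "
      "typical unseen ortholog pair in the top tenth of all cross-species "
      "gene pairs, from topology and anchors alone.")
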