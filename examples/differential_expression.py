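"""Permutation-FDR differential expression on a spiked count matrix.

Simulates a negative-binomial RNA-seq count matrix (3 control vs 3 treated
samples, 10% of genes truly regulated 4-fold), applies the CPM expression
filter (cpm > 1 in >= 2 samples of one group), and runs the two-tailed
permutation-FDR Student's t test (FDR < 0.05, up to 250 randomizations) on
log2(cpm + 1).
"""

import numpy as np

from retinakit import degstats, synth

counts, labels, is_de = synth.simulate_counts(
    n_genes=4000, group_sizes=(3, 3), frac_de=0.1, effect_log2=2.0, seed=7
)
kept = degstats.filter_genes(counts, labels, min_cpm=1.0, min_samples=2)
print(f"expression filter: kept {len(kept)} of {len(counts)} genes")

logmat = np.log2(degstats.cpm(kept) + 1.0)
result = degstats.perm_fdr_ttest(logmat, labels, n_perm=250, fdr=0.05, seed=11)

sig = result.table["significant"]
truth = np.asarray(is_de)[[counts.index.get_loc(g) for g in kept.index]]
tp = int((sig & truth).sum())
fp = int((sig & ~truth).sum())
print(f"|t| threshold   : {result.threshold:.2f} ({result.n_perm} permutations)")
print(f"significant set : {int(sig.sum())} genes ({tp} truly regulated, {fp} false)")
print(f"recall          : {tp / truth.sum():.2f}")
print(f"realized FDR    : {fp / max(1, int(sig.sum())):.3f} (target 0.05)")
print(
    "\nThe threshold is the smallest |t| whose permutation-estimated FDR "
    "stays below the target; the realized FDR against the generator's truth "
    "labels should sit near that target."
)
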