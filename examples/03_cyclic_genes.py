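"""Rank genes by the significance of their cyclic trend over phase.

Fits circularized quadratic trend-filter curves to each gene, builds a
permutation null from one well-detected gene, and prints the ranked report
plus the enrichment of significant genes in the planted cyclic set.

Gene expression is taken on the normalized (Gaussian) scale here so that
null genes are exactly independent of phase. With count-scale data and only
a few dozen genes, CPM compositionality couples every gene to the cyclic
mass — an effect that vanishes at genome scale but would dominate a toy
panel this small.
"""

from cyclephase import simulate as sim
from cyclephase.trend import enrichment_odds_ratio, permutation_test

truth = sim.make_truth(n_cells=120, n_genes=30, n_cyclic=6, seed=4)
normalized, _ = sim.simulate_cyclic_expression(truth)
theta = truth.cells["theta_true"].to_numpy()

report = permutation_test(
    normalized, theta, B=100, seed=4,
    gene_ids=truth.genes.gene_id.tolist(), n_lambda=15,
)
print(report.head(8).to_string(index=False))

hits = report[report.empirical_p <= 1 / 101].gene_id.tolist()
planted = truth.genes[truth.genes.is_cyclic].gene_id.tolist()
odds, p = enrichment_odds_ratio(hits, planted, truth.genes.gene_id.tolist())
print(f"\n{len(hits)} genes at the minimum attainable p = 1/101")
print(f"enrichment in the planted cyclic set: OR = {odds:.1f}, exact p = {p:.2e}")
# The planted cyclic genes hit the permutation floor while null genes spread
# over larger p-values; the odds ratio quantifies the overlap between the
# significant set and the planted set.
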