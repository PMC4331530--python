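"""Leave-one-out benchmark: dual flow versus its one-sided components.

Generates the default synthetic benchmark (2000 nodes, 5 diseases x 6
genes), runs leave-one-out cross-validation with chromosome-local 100-gene
candidate lists for each prioritization strategy, and prints the two
enrichment summaries and the AUC.  Enrichment is 50/r for a test gene
ranked r-th; score 1 averages all trials, score 2 only trials whose test
gene is on the network.
"""

from dualflow import PropagationConfig, SyntheticSpec, generate, loocv, partition_genes

spec = SyntheticSpec(seed=0)
net, gene_map, essentials, positions = generate(spec)
disease = {g for genes in gene_map.values() for g in genes}
part = partition_genes(net, disease, essentials)
config = PropagationConfig(alpha=0.5, normalization="pump")

print(f"benchmark: {net.n_nodes} nodes, {len(gene_map)} diseases, "
      f"{sum(len(v) for v in gene_map.values())} disease genes\n")
print(f"{'strategy':>8}  {'score 1':>8}  {'score 2':>8}  {'AUC':>6}")
for mode in ("np_e", "np_d", "np_de"):
    report = loocv(gene_map, net, part, config, positions=positions, mode=mode)
    print(f"{mode:>8}  {report.score1:>8.3f}  {report.score2:>8.3f}  {report.auc:>6.3f}")

print(
    "\nThe dual-flow strategy (np_de) should match or beat positive-only"
    "\npropagation (np_d) and far exceed the negative-only baseline (np_e)."
)
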