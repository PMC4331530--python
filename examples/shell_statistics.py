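"""Shell-proportion analysis: disease genes avoid the essential core.

Generates a synthetic interaction network with planted disease modules and
an interconnected essential core, then compares the proportion of
non-disease essential proteins (E-) in the n-th BFS shell of non-essential
disease proteins (D-) against other proteins (O).  Smaller D- medians with
small rank-sum p-values mean disease genes sit farther from essentials —
the topological signal the dual-flow prior exploits.
"""

from dualflow import (
    SyntheticSpec,
    compare_classes,
    generate,
    partition_genes,
    shell_proportions,
)

spec = SyntheticSpec(seed=0)
net, gene_map, essentials, _positions = generate(spec)
disease = {g for genes in gene_map.values() for g in genes}
part = partition_genes(net, disease, essentials)
print(f"network: {net.n_nodes} nodes, {net.n_edges} edges; classes {part.counts(net)}")

print(f"\n{'n':>2}  {'Md(D-)':>8}  {'Md(O)':>8}  {'rank-sum p':>12}")
for n in range(1, 7):
    p_d = shell_proportions(net, part, "D-", n)
    p_o = shell_proportions(net, part, "O", n)
    if p_d.size == 0 or p_o.size == 0:
        break
    c = compare_classes(p_d, p_o, n=n, class_a="D-", class_b="O")
    print(f"{n:>2}  {100 * c.median_a:>7.2f}%  {100 * c.median_b:>7.2f}%  {c.p_value:>12.3e}")

print(
    "\nMedians are the percentage of E- proteins among exact-distance-n"
    "\nneighbours; D- below O at mid-range n reproduces the planted structure."
)
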