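# dualflow

Dual-flow network propagation for disease-gene prioritization on
protein–protein interaction (PPI) networks.

## The problem

Given a hereditary disease with a handful of verified disease genes,
network-based gene prioritization ranks candidate genes by their proximity
to the known disease genes in a PPI network.  Global diffusion methods
(random walk with restart, network propagation) do this well, but they
share a failure mode: a high-degree **non-disease hub** that happens to
interact with several known disease proteins collects a large share of the
diffused flow and is mistaken for a disease gene.  Such hubs are very often
essential (housekeeping) proteins — and, empirically, disease proteins are
*not* well connected to essential proteins.  `dualflow` exploits that
observation: known disease genes inject **positive** flow, non-disease
essential genes inject **negative** flow, and candidates are ranked by
their steady-state **net** flow, so essential-adjacent hubs are drained
while genuine disease-module members stay on top.

## The model

Let G = (V, L) be the undirected PPI network with adjacency matrix A and
degrees k(x), and let W be the degree-normalized operator (default: each
node pumps its flow in equal parts to its neighbours, W = A D⁻¹).
Propagation iterates

    F(t+1) = (1 − α) W F(t) + α Y,      F(1) = Y,

with restart weight α ∈ (0, 1] and prior vector Y.  The fixed point is

    F(∞) = α (I − (1 − α) W)⁻¹ Y  =  S Y.

Three priors are supported, with T_h the training disease genes of disease
h and E⁻ the essential-not-disease genes:

| strategy | prior Y | ranks by |
|----------|---------|----------|
| `np_d`   | +1/\|T_h\| on each training gene | similarity to disease genes |
| `np_e`   | −1/\|E⁻\| on each E⁻ gene | dissimilarity to essential genes |
| `np_de`  | both sides, equal total positive and negative flow | net flow F(∞)(x) = (1/\|T_h\|)Σ_{y∈T_h} S(x,y) − (1/\|E⁻\|)Σ_{y∈E⁻} S(x,y) |

The companion topology analysis computes, for each node i, the BFS shells
Q_i^n (nodes at shortest-path distance exactly n) and the proportion
p_i^n = |Q_i^n ∩ E⁻| / |Q_i^n| of essential proteins in each shell, and
compares the medians of these proportions between non-essential disease
proteins (D⁻) and other proteins (O) with a two-sided rank-sum test.

Evaluation follows the standard leave-one-out protocol: each disease gene
is held out in turn, re-ranked among its 100 genomically nearest
same-chromosome genes, and scored 50/r for rank r (off-network test genes:
rank 100, score 0.5); ROC/AUC treats prioritization as classification at a
rank threshold.

## Worked example

`examples/prioritize_decoy_hub.py` builds an 11-node toy network in which
disease genes `a`,`b` train the prior, `c` is the held-out disease gene,
and the hub `e` touches both training genes plus a clique of essential
proteins:

```
NP_D ranking (top 4 of 9 candidates):
  rank 1: e   net flow +0.1511  <- non-disease decoy hub
  rank 2: c   net flow +0.0642  <- held-out disease gene
  ...
NP_DE ranking (top 4 of 9 candidates):
  rank 1: c   net flow +0.0602  <- held-out disease gene
  rank 2: e   net flow +0.0486  <- non-disease decoy hub
```

Positive-only propagation mistakes the essential-adjacent hub for a disease
gene; the dual-flow prior reverses the order.  The other examples print the
shell-statistics table (D⁻ medians below O at mid-range n with rank-sum
p ≪ 0.05 on the planted benchmark) and the LOOCV benchmark summary, where
the mean enrichment score 2 on the default 2000-node instance is 46.7 for
`np_de` and `np_d` versus 5.6 for `np_e`, with AUC 0.999 versus 0.780.

A thin CLI mirrors the library:

```sh
dualflow simulate --out-dir fixtures/
dualflow prioritize --network fixtures/edges.tsv --disease-genes d.txt \
    --essential-genes fixtures/essentials.txt --mode np_de --out ranks.tsv
dualflow shells --network fixtures/edges.tsv --disease-genes d.txt \
    --essential-genes fixtures/essentials.txt --classes D-,O --out shells.tsv
dualflow evaluate --network fixtures/edges.tsv --associations fixtures/associations.tsv \
    --essential-genes fixtures/essentials.txt --positions fixtures/positions.tsv \
    --mode np_de --report report.json
```

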