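# Methods

## Propagation model

`dualflow` ranks candidate disease genes by the steady state of a linear
diffusion on an undirected, unweighted PPI network,

    F(t+1) = (1 − α) W F(t) + α Y,    F(1) = Y,
    F(∞)   = α (I − (1 − α) W)⁻¹ Y,

where Y is a signed prior and W a degree-normalized operator.  The model
assumes (i) functional similarity decays along interaction paths, so a
gene's disease relevance is a weighted sum of all walks to prior genes;
(ii) essential (housekeeping) genes are informative *negative* anchors,
because disease proteins are depleted around the essential core; and
(iii) edge confidence beyond a load-time threshold carries no information
(the graph is binarized).

### Operator orientation

The update can be read three ways, and the choice matters on heterogeneous
degrees:

- **pump** (default): node x sends F(x)/k(x) along each incident edge;
  as a matrix, W = A D⁻¹ (column-stochastic off isolated nodes).  This
  conserves total flow on graphs without isolated nodes, which matches the
  narrative of positive and negative flows competing for territory.
- **average**: the new value at x is the mean of its neighbours' values
  (W = D⁻¹ A).
- **symmetric**: W = D⁻¹ᐟ² A D⁻¹ᐟ², the common choice in the propagation
  literature; spectrum in [−1, 1].

All three have operator norm ≤ 1, so (I − (1−α)W) is invertible for every
α ∈ (0, 1] and the fixed point always exists; isolated nodes pump nothing
and retain αY.  The orientation of the published method is ambiguous
between the first two readings; pump is the default here because it
conserves flow, and the others are selectable per run.

A consequence worth knowing: under **pump**, wiring the essential core more
densely *raises* a decoy hub's net score (each essential's outgoing flow is
split over more edges, so less negative flow reaches the hub), whereas
under **average** a denser core makes essentials mutually more negative and
monotonically drains hubs attached to them.  The negative-flow drain
mechanism is therefore normalization-dependent; the test suite exercises
the monotone version under `average`.

### Parameters

| parameter | default | meaning |
|-----------|---------|---------|
| α | 0.5 | restart weight: share of the prior re-injected each step.  **The source method does not state its α**; 0.5 is this package's choice and results should be read as α-dependent. |
| normalization | pump | operator orientation, above |
| prior_mode | normalized | `normalized`: +1/\|T_h\| and −1/\|E⁻\| per gene, so each side totals one unit — the operational scoring definition.  `unit`: literal ±1 per gene.  The two differ only by per-side scaling; for `np_de` the balance of the two sides (and hence the ranking) can differ, and both are provided because the published description supports both readings. |
| solver | auto | sparse direct factorization up to 20 000 nodes, fixed-point iteration above |
| tolerance | 1e−8 | L1 change between successive iterates at which iteration stops |
| max_iterations | 10 000 | iteration cap; exceeding it raises a convergence error with the residual |

Genes supplied on both the positive and negative side keep the positive
assignment with a warning (by construction E⁻ excludes disease genes, so
this only happens with inconsistent user input).  Scoring runs on the full
loaded graph by default; restriction to the largest connected component is
opt-in, since the published workflow reports component sizes but never
states that scoring was restricted to one.

## Shell statistics

For node i, shell Q_i^n holds the nodes at shortest-path distance exactly
n (BFS layering; unreachable nodes excluded).  The statistic is
p_i^n = |Q_i^n ∩ E⁻| / |Q_i^n|, collected over a node class and compared
between classes by a two-sided Wilcoxon rank-sum test.  Nodes with an empty
shell n are excluded from the collection rather than counted as zero —
counting them as 0 would drag medians down exactly where shells become
sparse and make high-n comparisons meaningless.  For combined sample sizes
≤ 12 the p-value comes from exhaustive enumeration of the rank-sum null
(midranks under ties); above that, from the tie-corrected normal
approximation with continuity correction.  At combined size 12 the largest
possible gap between the two is below 0.02 for tie-free data (computed by
enumerating the null distribution); for smaller or heavily tied samples the
normal approximation can be off by far more, which is why the exact path
exists.

## Evaluation protocol

Leave-one-out: every disease with m ≥ 2 genes contributes m trials; in each,
the held-out gene is ranked among a candidate list of up to 100 genes —
itself plus the 99 same-chromosome genes nearest by absolute coordinate
difference (the coordinate is a single per-gene position; users may supply
starts or midpoints).  Enrichment is 50/r for rank r; ties rank last within
their group; an off-network test gene gets rank 100 and score 0.5.
*Score 1* averages all trials of a disease, *score 2* only on-network
trials; overall figures average per-disease means (disease as the unit).
The negative set E⁻ is fixed from the full disease annotation and not
recomputed per fold — the held-out gene is a known disease gene in this
setting, so it never becomes a negative anchor.

ROC analysis excludes off-network trials.  The published description of
specificity is internally inconsistent (it defines the term twice); this
package follows the rank-threshold convention of the LOOCV literature:
at threshold t, sensitivity is the fraction of test genes ranked ≤ t and
the false-positive rate is the per-trial fraction of decoy candidates
ranked ≤ t, averaged over trials; AUC is the trapezoidal integral.  This
is an interpretation, recorded here rather than silently resolved.

When no position table is supplied, candidate lists are the test gene plus
99 decoys drawn uniformly (seeded) from non-disease network genes — a
documented deviation that enables position-free runs; chromosome-local
lists are the faithful protocol.

## Synthetic benchmark generator

The generator emulates the topology the method assumes, not any real
database: a connected preferential-attachment base graph (scale-free-like,
attachment 1 ⇒ sparse with a wide distance distribution), essential genes
drawn with probability proportional to degree (hub-enriched without
monopolising every hub) and interconnected by extra pairwise edges
(probability 0.05), disease modules of 6 genes planted on nodes at hop
distance ≥ 4 from every essential and interlinked by a cycle plus random
extra pairs (probability 0.6), and decoy hubs wired to at least half of one
module and ≥ 3 essentials.  Positions assign genes to ~17 synthetic
chromosomes in blocks of 120, so chromosome-local candidate lists hold 100
genes.  Defaults (2000 nodes, 5 diseases × 6 genes, 150 essentials) are the
package's standard benchmark conditions.

The essential standoff is the deliberate design choice here.  D⁻ shell
proportions are essentially the O curve shifted right by the standoff: if
disease modules merely avoid *direct* essential contact, their essential
mass arrives one shell late and overshoots O wherever the O curve has
peaked, inverting the real-data pattern at mid n.  A standoff of 4 on a
sparse base keeps D⁻ below O through shells 2–4, which is the planted
analogue of the real finding.  What the generator does **not** emulate:
realistic degree-distribution exponents, edge confidence scores, overlap
between disease and essential annotations (E ∩ D is empty by construction),
multi-disease genes, and false-positive/false-negative interactions.
Passing tests on this benchmark show the machinery and the direction of the
planted signal, not effect sizes on real PPI data.

## Numerical choices

- Direct solves use sparse LU (`scipy.sparse.linalg.spsolve`) on
  I − (1−α)W; iterative solves start from F(1) = Y and stop when the L1
  change ≤ tolerance.  The two agree within 10× tolerance (tested).
- Ranks are 1-based descending; every member of a tie group gets the
  group's worst rank, so a test gene tied with others is ranked last among
  them.  Off-network candidates share the overall worst rank.
- Candidate-list distance ties at the inclusion boundary break by
  identifier order, making lists deterministic.
- Largest-component ties break by lexicographically smallest member set.
- All generator and decoy-sampling randomness flows from explicit integer
  seeds; identical seeds give byte-identical outputs.

## Known limitations

- Unweighted propagation only; edge confidences are used solely for
  load-time thresholding (0.4 is the conventional cutoff for STRING-style
  scores).
- No identifier mapping: gene/protein IDs are opaque case-sensitive
  strings and must already be consistent across inputs.
- α, the operator orientation, and the prior scaling of the published
  results are unknown; conclusions that depend on them should be checked
  across the provided options.
- The dense similarity matrix S is exposed for analysis but is O(|V|²)
  and refused above 5000 nodes; scoring paths never materialise it.
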