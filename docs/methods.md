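# Methods

## Model

`targo` ranks genes for a phenotype or disease term by biased random-walk
propagation over a merged gene interaction network, followed by a
trust-based refinement and a reliability filter.

**Transition operator.** The merged network (protein–protein
interactions, curated pathway edges, co-expression edges) is represented
by the row-stochastic operator Pr = H + D: the hyperlink matrix H places
1/out-degree(i) on each outgoing neighbor of gene i, and the dangling
matrix D replaces the row of every gene with no outgoing edges by the
uniform distribution 1/n over all n genes. Edges reported by several
sources collapse to one directed edge before out-degrees are taken, so
multiply-reported interactions do not dilute the transition
probabilities. PPI and co-expression edges are treated as symmetric
(expanded to both directions); pathway edges keep their file direction;
the symmetric set is configurable. Self-loops are dropped: a gene feeding
probability back to itself would inflate its own rank, and the
1/out-degree formulation describes flow to *other* genes.

**Topic-sensitive PageRank (TSPR).** For a term with signature gene set
t_j, the personalization vector pa holds 1/|t_j| on each signature gene
present in the network and 0 elsewhere (|t_j| is counted after network
restriction so pa sums to exactly 1). The TSPR score vector is the unique
fixed point of

    x ← d · x · Pr + (1 − d) · pa,

a probability distribution over genes. The damping factor d (default
0.85) is the probability of following an interaction edge rather than
teleporting to a signature gene. Note the dangling correction teleports
uniformly (1/n), not to pa — a deliberate property of the D construction
above, diverging from personalized-PageRank variants that send dangling
mass to the teleport vector.

**Good seeds and TrustRank.** The good seeds of a term are the signature
genes that also rank inside the top `seed_k` TSPR scores (default 3000;
boundary ties broken by gene identifier so the pool has exactly `seed_k`
members). The seed vector gd is uniform 1/|good seeds| on that
intersection, and TrustRank is the same fixed point with gd in place of
pa. Because the seeds are restricted to independently corroborated,
highly ranked genes, TrustRank concentrates probability on the part of
the network reachable from trustworthy evidence and suppresses genes
whose TSPR rank came from unrelated regions.

**Spam mass.** Per gene, spammass = 1 − TrustRank/TSPR. Negative values
mean the gene's rank is elevated by the good seeds (reliable); positive
values mean it is elevated by unrelated genes. Where TSPR = 0 the ratio
is undefined and the value is reported as NaN, never silently 0; such
genes are exempt from the spam-mass filter. The filter, when enabled,
*demotes* genes with spammass above the cutoff (default 0) below all
retained genes rather than removing them, keeping the output a full
permutation of the gene universe.

**Term filter.** Only terms with strictly more than `min_support`
(default 10) signature genes present in the network are ranked — a
literal "more than 10" reading, configurable.

**Multi-phenotype selection.** For a user panel of terms, a gene is
"top-ranked" in a term when its TrustRank rank is within `top_fraction`
(default 0.05) of that term's gene list. The 2×2 table per gene — panel
terms vs. background terms, top-ranked vs. not — is tested one-sided for
enrichment with the Fisher exact test; Benjamini–Hochberg q-values
control the FDR and genes with q below the threshold (default 0.01) are
selected. The table construction and the one-sided alternative are the
minimal operationalization of "enriched among the selected phenotypes";
both the cutoff and the threshold are exposed.

## Numerical choices

* Power iteration starts at the teleport vector, iterates to an L1 change
  below 1e-10, caps at 200 iterations; non-convergence logs a warning and
  returns the best iterate with a flag (both stationary vectors exist and
  are unique for 0 ≤ d < 1, so this only guards extreme configs).
  d = 0 is accepted as a degenerate configuration whose fixed point is
  the teleport vector itself; it is useful for testing limits.
* The result is renormalized to unit mass once after convergence to
  absorb accumulated floating-point drift.
* All rankings are ordinal with ties broken by gene identifier, and node
  order is lexicographic, so identical inputs give bitwise-identical
  outputs.
* Dense linear solves of (I − d·Prᵀ)x = (1 − d)·v serve as the
  independent oracle for the iterative solvers in the test suite (n ≤ 20).

## Evaluation machinery

ROC/AUC against known gene–term association labels is computed by
default *within* the top-`top_n` (100) sublist of the ranking — the list
of candidates a screening project would actually take forward; labels
outside the sublist are ignored. The alternative reading (full labeled
ranking) is available as `scope="full"`. AUC is the trapezoid-rule area,
identical to the Mann–Whitney probability with ties counted one half;
sublists lacking a class yield an undefined (flagged) AUC. The
hub-degree diagnostic reports the per-term Pearson correlation between
TrustRank score and total degree (distinct neighbors after
symmetrization) and the fraction of terms below a threshold (0.6);
zero-variance terms are flagged undefined and excluded from the
denominator. A damping sweep utility recomputes mean TrustRank AUC over
a d-grid.

## Synthetic benchmark

The generator emulates the pipeline's three inputs with planted ground
truth. A base graph (Erdős–Rényi, mean degree 6; or Barabási–Albert,
m = 3, whose heavy-tailed degrees make the hub diagnostic meaningful)
is overlaid with per-term modules: 20 signature genes plus a fringe of
10 associated neighbors, wired pairwise with probability 0.3. Benchmark
defaults are 500 genes and 30 terms — large enough for stable AUC
estimates, small enough for seconds-scale runs — plus 5 dangling nodes,
3 explicit hubs, 3 deliberately sub-threshold terms (8 genes), and 100
edges shared by all three provenance files. Labels mark the associated
genes, optionally flipped at a noise rate (default 0). Optionally a set
of panel genes is planted into the signatures of the first `panel_terms`
terms and kept out of hubs and all background modules, so the Fisher
panel selection has an exact expected answer.

At this scale the published seed pool (`seed_k = 3000`, about 18% of a
~16k-gene network) exceeds the network size and makes TrustRank
trivially identical to TSPR; benchmark runs therefore use
`seed_k = 100`, the same fraction of 500 genes. Under zero label noise
all signature genes rank inside that pool, the good seeds coincide with
the supported signature, and TrustRank equals TSPR exactly — the
refinement only separates from TSPR when some signature genes rank
poorly (noise, weak wiring, small pools).

What the benchmark does **not** emulate: realistic pathway topology,
degree-correlated annotation bias, overlapping term hierarchies, or
namespace mismatches between sources. Passing benchmark tests shows the
machinery recovers planted signal under its own assumptions, not that
the published database-scale accuracies transfer.

## Known limitations

* Inputs must share one gene namespace; no orthology or identifier
  mapping is performed.
* The spam-mass filter threshold and the "top-ranked" cutoff of the panel
  selection have no canonical published values; defaults (0 and 0.05) are
  design choices exposed in the configuration.
* Negative-label definitions for real corpora (all unannotated genes vs.
  matched samples) change AUC materially; the evaluation takes labels as
  given.
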