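# targo

Gene prioritization for phenotype and disease terms by network
propagation. Given a merged gene interaction network (protein–protein
interactions, curated pathways, co-expression) and a signature gene set
per term, `targo` ranks every gene in the network by:

1. **Topic-sensitive PageRank (TSPR)** — the stationary distribution of
   `x ← d·x·Pr + (1−d)·pa`, where `Pr` is the row-stochastic transition
   operator (1/out-degree hyperlink matrix, dangling rows uniform at
   1/n), `pa` places 1/|t_j| on the term's signature genes, and
   `d = 0.85` is the damping factor;
2. **TrustRank** — the same fixed point re-seeded from the *good seeds*,
   the signature genes that also rank inside the top-`seed_k` TSPR
   scores, which suppresses genes whose rank came from unrelated parts
   of the network;
3. **Spam mass** — `1 − TrustRank/TSPR` per gene; negative values mean
   the gene is supported by good seeds, positive values mean it is
   propped up by unrelated genes and can be demoted by a filter;
4. **Multi-phenotype selection** — for a user panel of terms, a one-sided
   Fisher exact test on top-ranked status (panel vs. background terms)
   with Benjamini–Hochberg FDR control (default q < 0.01) pinpoints the
   genes shared across the panel, e.g. candidate knockout targets for a
   mouse model of a multi-phenotype condition.

The audience is anyone triaging candidate genes against a phenotype:
mouse-model designers picking knockout targets, or analysts ranking
disease genes on an interaction network. A synthetic benchmark module
with planted modules, hubs, dangling nodes and label noise makes the
whole pipeline testable offline.

## Worked example

Generate a 500-gene benchmark, rank one term, and evaluate against the
planted associations:

```python
from pathlib import Path
from targo import (assemble_network, build_transition_operator,
                   load_signatures, filter_terms, rank_term, RankingConfig)
from targo.synthetic import SyntheticSpec, simulate, load_labels
from targo.evaluation import evaluate_roc

data = simulate(SyntheticSpec(seed=42), Path("demo"))
net = assemble_network(data.edge_files)
op = build_transition_operator(net)
sigs = filter_terms(load_signatures(data.gmt_path), net)
res = rank_term(net, op, sigs[0], RankingConfig(seed_k=100))
print(res.table.head(5).round(5))

labels = load_labels(data.label_path)
y = labels[labels.term_id == sigs[0].term_id].set_index("gene")["label"]
rep = evaluate_roc(res.table["trust_score"], y, top_n=100)
print(f"top-100 TrustRank AUC = {rep.auc:.3f}")
```

prints

```
       tspr_score  trust_score  spammass  tspr_rank  trust_rank  is_signature
gene
g0017     0.01492      0.01492       0.0          1           1          True
g0155     0.01386      0.01386       0.0          2           2          True
g0293     0.01375      0.01375       0.0          3           3          True
g0100     0.01371      0.01371       0.0          4           4          True
g0257     0.01325      0.01325       0.0          5           5          True
top-100 TrustRank AUC = 0.940
```

The top of the list is the planted signature module (all
`is_signature`), each gene holding ~1.4% of the stationary probability;
spam mass 0 means TrustRank and TSPR agree — here every signature gene
made it into the seed pool, so the two teleport vectors coincide. The
AUC of 0.94 says a planted associated gene outranks a non-associated one
94% of the time within the top-100 candidates.

The same workflow is available from the shell:

```sh
targo simulate --seed 42 --out demo
targo rank --edges demo/edges_ppi.tsv:ppi --edges demo/edges_pathway.tsv:pathway \
           --edges demo/edges_coexpression.tsv:coexpression \
           --gmt demo/signatures.gmt --seed-k 100 --out demo/ranks
targo evaluate --ranks demo/ranks/ranks.tsv --labels demo/labels.tsv \
           --top-n 100 --out demo/eval
targo select --ranks demo/ranks/ranks.tsv --panel panel.txt \
           --top-fraction 0.05 --fdr 0.01 --out demo/selection.tsv
targo sweep-d --edges demo/edges_ppi.tsv:ppi ... --grid 0.1,0.5,0.85 \
           --labels demo/labels.tsv --out demo/sweep.tsv
```

Every run writes a `manifest.json` with resolved parameters and input
digests.

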