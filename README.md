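# credence

Evidence-weighted gene list and gene-pair list analysis with
Dempster–Shafer belief management.

Exploratory genomics rarely rests on one database: a candidate gene list is
assembled from literature-mining p-values, interaction article counts,
ortholog percent identities and expression direction calls, all of varying
reliability. `credence` keeps every result row annotated with its evidence
and turns those heterogeneous scores — plus the analyst's own trust in each
source — into a single *combined credibility* per row, so lists can be
queried, enriched, combined and re-ranked without losing track of why each
entry is believed. All data sources are local flat files (ontology OBO,
annotation/interaction/ortholog/coordinate/expression TSVs), and a
deterministic synthetic-data generator plants known structure in every
format so each analysis stage can be validated against ground truth.

## The belief model

Evidence quality is a credibility c ∈ (−1, 1): −1 perfect disbelief, 0
neutral, +1 perfect belief (default 0.5). Each credibility maps onto a
basic probability assignment m over the frame Θ = {T, F}, with focal
elements {T}, {F} and the uncertain set {T, F}:

- c ≥ 0: m({T}) = c, m({T,F}) = 1 − c
- c < 0: m({F}) = −c, m({T,F}) = 1 + c

Independent pieces of evidence combine by Dempster's orthogonal sum,

  m(A) = K · Σ_{X∩Y=A} m₁(X)·m₂(Y),  K⁻¹ = Σ_{X∩Y≠∅} m₁(X)·m₂(Y),

with log K quantifying the conflict between the two assignments. A row's
combined credibility is Bel({T}) of the fold over one mass per evidence
source, one for the score credibility, and one for the size-of-group
credibility when present; it always lies in [0, 1]. Raw source scores are
normalised onto a "bigger is more significant" axis (−log₁₀ p for
p-values), partitioned with a 1-D Gaussian mixture (model size by BIC), and
each partition carries a user-adjustable credibility. Per-row feedback
nudges a source's global credibility through five learning rates
(+0.030, +0.015, 0, −0.015, −0.030).

On top of this sit four enrichment statistics (term-for-term and
parent-child union/intersection hypergeometric tests over an ontology DAG
with true-path closure, a disease-hierarchy variant, an exact sign test for
expression direction, and a Monte-Carlo span test for chromosomal
proximity), a list algebra (union / intersect / difference / translate /
extract), workflow persistence as versioned XML, and an interolog pipeline
that predicts unreported interactions by transferring interactions through
orthologs in other species.

## Worked example: interolog prediction

`examples/04_interolog_prediction.py` recreates the Mediator-complex
walkthrough on the synthetic tables — start from fly MED26 (gene 43816),
hop to its human ortholog (9441), collect the human partners, hop back
through orthology, and subtract what fly databases already report:

```
known fly interactions of the input: [(43816, 39995)]
predicted-only pairs (3):
  43816 - 37109 belief=0.875 evidence=['orthologs', 'mimi']
  43816 - 34577 belief=0.875 evidence=['orthologs', 'mimi']
  43816 - 35210 belief=0.875 evidence=['orthologs', 'mimi']
planted truth: [[43816, 34577], [43816, 35210], [43816, 37109]]
```

All three planted partners (the fly orthologs of human MED4, MED16 and
MED17) are recovered; the candidate that was already a known fly
interaction was removed by the undirected difference. The 0.875 belief is
the Dempster combination of three neutral-default (0.5) credibilities — the
orthology evidence, the interaction evidence, and the score credibility —
i.e. 1 − 0.5³.

The same run is available from the shell:

```sh
credence --seed 1 synth --out fixtures/
credence interolog --genes fixtures/input_genes.txt \
    --query-species 7227 --via 9606 \
    --orthologs fixtures/orthologs.tsv \
    --interactions fixtures/interactions.tsv \
    --out predicted.csv
```

Every operation is also a CLI subcommand (`credence --help`); lists pass
between subcommands as saved XML workflow-node files, so a multi-step
pipeline can be driven entirely from the shell. The other examples show the
belief engine, term enrichment and the list algebra.

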