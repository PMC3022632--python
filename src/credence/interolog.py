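"""Interolog prediction: transfer interactions across species via orthology.

An *interolog* is an interaction inferred in a query species because the
orthologs of the two genes interact in another (via) species.  The pipeline
chains the primitive operations: map the input genes into each via species,
collect the via-species interactions of those orthologs, translate back
through orthology, pool the candidates over all via species, and finally
subtract the interactions already known in the query species — leaving only
predictions.  Interactions are physical and symmetric, so the final
subtraction matches pairs in either orientation by default.

Belief propagates through the chain automatically: each predicted pair's
combined credibility is the Dempster combination of the orthology rows
(percent-identity evidence, both hops) and the via-species interaction row
(article-count evidence), under the current source credibilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import io as data_io
from . import setops
from .model import GeneList, GenePairList, SourceRegistry

__all__ = ["InterologConfig", "known_interactions", "predict_interologs"]


@dataclass(frozen=True)
class InterologConfig:
    """Parameters of an interolog run.

    ``via_species`` are the species whose known interactions are transferred
    into ``query_species``; the query species itself may not appear among
    them.  ``undirected_matching`` controls how candidate pairs are matched
    against known interactions in the final subtraction (on by default,
    since physical interactions are symmetric).
    """

    query_species: int
    via_species: tuple[int, ...]
    undirected_matching: bool = True

    def __post_init__(self) -> None:
        if self.query_species in self.via_species:
            raise ValueError("query species cannot be one of the via species")
        if not self.via_species:
            raise ValueError("at least one via species is required")


def known_interactions(
    genes: GeneList,
    interactions: data_io.SourceTable,
    *,
    registry: SourceRegistry | None = None,
) -> GenePairList:
    """Known interactions of the input genes in their own species.

    Thin alias of the interaction query, recorded as the pipeline's
    known-set step for provenance.
    """
    out = data_io.query_interactions(
        genes, interactions, registry=registry, name=f"{genes.name} known"
    )
    return out


def predict_interologs(
    genes: GeneList,
    cfg: InterologConfig,
    orthologs: data_io.SourceTable,
    interactions: data_io.SourceTable,
    *,
    registry: SourceRegistry | None = None,
) -> GenePairList:
    """Predict unreported interactions in the query species.

    For each via species v: (1) find orthologs of the input genes in v,
    (2) collect v-internal interactions of those orthologs, (3) translate
    input->ortholog with ortholog->interactant to get input->v-interactant,
    (4) map the v-interactants back to the query species and translate
    again, yielding candidate query-species pairs.  Candidates are pooled
    over via species (a pair found via two species carries both evidence
    chains, Dempster-combined), then interactions already known for the
    input genes are removed.  A via species with no orthologs of the input
    contributes nothing (reported as a notice).
    """
    candidates: GenePairList | None = None
    for v in cfg.via_species:
        orth_out = data_io.query_orthologs(
            genes, v, orthologs, registry=registry, name=f"{genes.name}->%d" % v
        )
        if not orth_out.entries:
            warnings.warn(
                f"via species {v} has no orthologs of the input; skipped",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        via_genes = setops.extract_column(orth_out, "output", registry=registry)
        via_inter = data_io.query_interactions(via_genes, interactions, registry=registry)
        if not via_inter.entries:
            continue
        hop1 = setops.translate(orth_out, via_inter, registry=registry)
        partners = setops.extract_column(hop1, "output", registry=registry)
        back = data_io.query_orthologs(
            partners, cfg.query_species, orthologs, registry=registry
        )
        if not back.entries:
            continue
        hop2 = setops.translate(hop1, back, registry=registry)
        candidates = (
            hop2
            if candidates is None
            else setops.union([candidates, hop2], registry=registry)
        )
    if candidates is None:
        out = GenePairList(
            f"{genes.name} predicted",
            cfg.query_species,
            cfg.query_species,
            genes.provenance,
        )
        return out
    known = known_interactions(genes, interactions, registry=registry)
    predicted = setops.difference(
        candidates,
        known,
        undirected=cfg.undirected_matching,
        name=f"{genes.name} predicted",
        registry=registry,
    )
    # self-check: by construction no prediction may coincide with a known pair
    known_keys = {
        frozenset(k) if cfg.undirected_matching else k for k in known.entries
    }
    for key in predicted.entries:
        kk = frozenset(key) if cfg.undirected_matching else key
        assert kk not in known_keys, f"predicted pair {key} is already known"
    return predicted
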