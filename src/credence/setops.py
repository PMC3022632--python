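"""List algebra over gene lists and gene-pair lists.

Union, intersection and difference act on the key sets (gene id, or the
ordered pair of ids); evidence from coinciding rows is concatenated and
deduplicated by source, and combined credibilities are refreshed over the
merged evidence.  ``translate`` is the relational join that turns an A-B
pair list and a B-C pair list into A-C — the workhorse for ortholog-hopping
pipelines — and propagates belief by Dempster-combining the two supporting
rows.  Pairs are ordered by default (column 1 = input, column 2 =
discovered); symmetric-interaction semantics are available through the
``undirected`` flag on ``difference``.
"""

from __future__ import annotations

import datetime
from typing import Iterable, Sequence

from . import belief
from .model import (
    CredibilityState,
    EvidenceItem,
    Gene,
    GeneList,
    GeneListEntry,
    GenePairEntry,
    GenePairList,
    Provenance,
    SourceRegistry,
    merge_evidence,
)

__all__ = [
    "difference",
    "extract_column",
    "extract_rows",
    "intersect",
    "translate",
    "union",
]


def _check_compatible(lists: Sequence) -> None:
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    first = lists[0]
    for other in lists[1:]:
        if other.kind != first.kind:
            raise ValueError(f"kind mismatch: {first.kind} vs {other.kind}")
        if first.kind == "gene_list":
            if other.species != first.species:
                raise ValueError(
                    f"species mismatch: {first.species} vs {other.species}"
                )
        else:
            if (other.input_species, other.output_species) != (
                first.input_species,
                first.output_species,
            ):
                raise ValueError("pair-list species signatures differ")


def _fresh_like(template, name: str, operation: str, parents: tuple[str, ...]):
    prov = Provenance("setops", datetime.date.today(), operation, parents)
    if template.kind == "gene_list":
        return GeneList(name, template.species, prov)
    return GenePairList(name, template.input_species, template.output_species, prov)


def _copy_entry(entry):
    cred = CredibilityState(
        entry.credibility.source_credibility,
        entry.credibility.score_credibility,
        entry.credibility.group_credibility,
        entry.credibility.combined,
    )
    if isinstance(entry, GeneListEntry):
        return GeneListEntry(entry.gene, list(entry.evidence), cred)
    return GenePairEntry(entry.input_gene, entry.output_gene, list(entry.evidence), cred)


def union(lists: Sequence, *, name: str | None = None, registry: SourceRegistry | None = None):
    """Rows present in any input list; evidence merged across lists."""
    _check_compatible(lists)
    out = _fresh_like(
        lists[0],
        name or " | ".join(l.name for l in lists),
        "union",
        tuple(l.name for l in lists),
    )
    for lst in lists:
        for entry in lst:
            out.add_entry(_copy_entry(entry), registry)
    out.recompute_combined(registry)
    return out


def intersect(lists: Sequence, *, name: str | None = None, registry: SourceRegistry | None = None):
    """Rows present in every input list; evidence merged across lists.

    Because every surviving row accumulates the evidence of all the lists it
    appeared in, its combined belief is at least its best single-list belief
    whenever all component credibilities are nonnegative.
    """
    _check_compatible(lists)
    common = set(lists[0].entries)
    for lst in lists[1:]:
        common &= set(lst.entries)
    out = _fresh_like(
        lists[0],
        name or " & ".join(l.name for l in lists),
        "intersect",
        tuple(l.name for l in lists),
    )
    for lst in lists:
        for key, entry in lst.entries.items():
            if key in common:
                out.add_entry(_copy_entry(entry), registry)
    out.recompute_combined(registry)
    return out


def _undirected_key(key):
    return frozenset(key) if isinstance(key, tuple) else key


def difference(
    superset,
    other,
    *,
    undirected: bool = False,
    name: str | None = None,
    registry: SourceRegistry | None = None,
):
    """Rows of ``superset`` whose key is absent from ``other``.

    Exactly two lists.  Pair keys match on the ordered pair by default;
    ``undirected=True`` treats (a, b) and (b, a) as the same interaction.
    """
    _check_compatible([superset, other])
    keyfn = _undirected_key if undirected else (lambda k: k)
    drop = {keyfn(k) for k in other.entries}
    out = _fresh_like(
        superset,
        name or f"{superset.name} - {other.name}",
        "difference",
        (superset.name, other.name),
    )
    for key, entry in superset.entries.items():
        if keyfn(key) not in drop:
            out.add_entry(_copy_entry(entry), registry)
    return out


def translate(
    ab: GenePairList,
    bc: GenePairList,
    *,
    name: str | None = None,
    registry: SourceRegistry | None = None,
) -> GenePairList:
    """Join A-B with B-C on the shared middle gene, producing A-C.

    The output column of ``ab`` must carry the same species as the input
    column of ``bc``.  Each output pair's belief is the Dempster combination
    of the combined credibilities of the two supporting rows (folded across
    all supporting middle genes when several paths produce the same pair);
    evidence items from both rows ride along.
    """
    if ab.output_species != bc.input_species:
        raise ValueError(
            f"cannot translate: output species {ab.output_species} != "
            f"input species {bc.input_species}"
        )
    prov = Provenance(
        "setops", datetime.date.today(), "translate", (ab.name, bc.name)
    )
    out = GenePairList(
        name or f"{ab.name} . {bc.name}",
        ab.input_species,
        bc.output_species,
        prov,
    )
    by_middle: dict[int, list[GenePairEntry]] = {}
    for e in bc:
        by_middle.setdefault(e.input_gene.id, []).append(e)
    support: dict[tuple[int, int], list[float]] = {}
    for e_ab in ab:
        for e_bc in by_middle.get(e_ab.output_gene.id, ()):
            key = (e_ab.input_gene.id, e_bc.output_gene.id)
            entry = out.entries.get(key)
            if entry is None:
                entry = GenePairEntry(
                    e_ab.input_gene,
                    e_bc.output_gene,
                    merge_evidence(e_ab.evidence, e_bc.evidence),
                )
                out.entries[key] = entry
                support[key] = []
            else:
                entry.evidence = merge_evidence(
                    entry.evidence, merge_evidence(e_ab.evidence, e_bc.evidence)
                )
            support[key].append(e_ab.credibility.combined)
            support[key].append(e_bc.credibility.combined)
    for key, creds in support.items():
        # combined beliefs are in [0, 1); fold them through the orthogonal sum
        safe = [min(c, belief.CRED_CLAMP) for c in creds]
        out.entries[key].credibility.combined = belief.combined_credibility(safe)
    return out


def extract_column(
    pairs: GenePairList,
    column: str,
    rows: Iterable | None = None,
    *,
    name: str | None = None,
    registry: SourceRegistry | None = None,
) -> GeneList:
    """Collapse one column of a pair list into a deduplicated gene list.

    ``column`` is ``"input"`` or ``"output"``; ``rows`` optionally restricts
    to a selection of pair keys.  Evidence from all contributing rows is
    carried over and merged.
    """
    if column not in ("input", "output"):
        raise ValueError(f"column must be 'input' or 'output', not {column!r}")
    species = pairs.input_species if column == "input" else pairs.output_species
    prov = Provenance(
        "setops", datetime.date.today(), f"extract_column[{column}]", (pairs.name,)
    )
    out = GeneList(name or f"{pairs.name}[{column}]", species, prov)
    selected = set(rows) if rows is not None else None
    for key, entry in pairs.entries.items():
        if selected is not None and key not in selected:
            continue
        gene = entry.input_gene if column == "input" else entry.output_gene
        out.add_entry(GeneListEntry(gene, list(entry.evidence)), registry)
    out.recompute_combined(registry)
    return out


def extract_rows(
    source,
    selection,
    *,
    name: str | None = None,
    species: int | None = None,
    gene_lookup: dict[int, Gene] | None = None,
    registry: SourceRegistry | None = None,
):
    """Select rows into a new list.

    For gene or pair lists, ``selection`` is an iterable of keys (or None
    for all rows) and the result is a same-kind list with fresh provenance.
    For a sequence of enrichment results, ``selection`` indexes the groups;
    the result is the deduplicated union of their member genes, each gene
    carrying its group's p-value as evidence (``species`` required,
    ``gene_lookup`` optionally supplying symbols).
    """
    if hasattr(source, "entries"):
        keys = set(selection) if selection is not None else set(source.entries)
        out = _fresh_like(
            source, name or f"{source.name}[rows]", "extract_rows", (source.name,)
        )
        for key, entry in source.entries.items():
            if key in keys:
                out.add_entry(_copy_entry(entry), registry)
        return out

    # enrichment-results source
    if species is None:
        raise ValueError("species is required when extracting from enrichment results")
    results = list(source)
    idx = set(selection) if selection is not None else set(range(len(results)))
    prov = Provenance("setops", datetime.date.today(), "extract_rows", ())
    out = GeneList(name or "enrichment[rows]", species, prov)
    today = datetime.date.today()
    for i, res in enumerate(results):
        if i not in idx:
            continue
        for gid in sorted(res.member_genes):
            gene = (gene_lookup or {}).get(gid, Gene(gid, species))
            ev = EvidenceItem(f"enrichment:{res.term}", res.p_value, "p_value", today)
            out.add_entry(GeneListEntry(gene, [ev]), registry)
    out.recompute_combined(registry)
    return out
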