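"""Evidence-annotated gene lists and gene-pair lists.

These are the universal currency between every operation in the package: a
list row carries the gene (or ordered gene pair), the evidence items each
source contributed, and a credibility state whose *combined* value is the
Dempster-Shafer belief in the row.  Genes are identified by stable integer
IDs (NCBI style), which are the common denominator across all adapters.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from . import belief

__all__ = [
    "CredibilityState",
    "DEFAULT_CREDIBILITY",
    "DEFAULT_SCORE",
    "EvidenceItem",
    "Gene",
    "GeneList",
    "GeneListEntry",
    "GenePairEntry",
    "GenePairList",
    "Provenance",
    "SourceRegistry",
    "merge_term_results",
    "new_list",
    "sort_entries",
]

SCORE_KINDS = frozenset(
    {"p_value", "article_count", "percent_identity", "expression_net", "default"}
)
#: neutral stand-in p-value for sources that attach no score of their own
DEFAULT_SCORE = 0.05
#: default credibility assigned to every score and source
DEFAULT_CREDIBILITY = 0.5


@dataclass(frozen=True)
class Gene:
    """A gene: stable integer ID, display symbol, species taxonomy ID."""

    id: int
    species: int
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValueError(f"gene id must be a positive integer, got {self.id!r}")
        if self.species <= 0:
            raise ValueError(f"species taxonomy id must be positive, got {self.species!r}")


@dataclass(frozen=True)
class EvidenceItem:
    """One source's score for one row, with its acquisition date."""

    source: str
    score_from_source: float
    score_kind: str
    acquired: datetime.date

    def __post_init__(self) -> None:
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(f"unknown score kind {self.score_kind!r}")
        s = self.score_from_source
        if self.score_kind in ("p_value", "default") and not 0.0 < s <= 1.0:
            raise ValueError(f"p-value score must be in (0, 1], got {s!r}")
        if self.score_kind == "article_count" and (s < 0 or s != int(s)):
            raise ValueError(f"article count must be a nonnegative integer, got {s!r}")
        if self.score_kind == "percent_identity" and not 0.0 <= s <= 100.0:
            raise ValueError(f"percent identity must be in [0, 100], got {s!r}")


def _check_cred(name: str, c: float) -> None:
    if not -1.0 < c < 1.0:
        raise ValueError(f"{name} {c!r} outside the open interval (-1, 1)")


@dataclass
class CredibilityState:
    """The user-adjustable credibility components of one row.

    ``source_credibility`` mirrors the (first) source's registry value for
    display; ``score_credibility`` comes from the partition scheme or user
    grading; ``group_credibility`` is set for enrichment groups only.  The
    ``combined`` value is Bel({T}) of the orthogonal sum over all components
    and always lies in [0, 1].
    """

    source_credibility: float = DEFAULT_CREDIBILITY
    score_credibility: float = DEFAULT_CREDIBILITY
    group_credibility: float | None = None
    combined: float = 0.0

    def __post_init__(self) -> None:
        _check_cred("source credibility", self.source_credibility)
        _check_cred("score credibility", self.score_credibility)
        if self.group_credibility is not None:
            _check_cred("group credibility", self.group_credibility)
        if not 0.0 <= self.combined <= 1.0:
            raise ValueError(f"combined credibility {self.combined!r} outside [0, 1]")


@dataclass
class SourceRegistry:
    """Per-source credibilities plus the feedback learning rates.

    The five learning rates map to the five feedback positions from
    strongest agreement to strongest disagreement; the middle (neutral)
    position must have rate zero.
    """

    credibilities: dict[str, float] = field(default_factory=dict)
    learning_rates: tuple[float, ...] = (0.030, 0.015, 0.0, -0.015, -0.030)

    def __post_init__(self) -> None:
        if len(self.learning_rates) != 5:
            raise ValueError("exactly five learning rates are required")
        if self.learning_rates[2] != 0.0:
            raise ValueError("the neutral (third) learning rate must be 0")
        for c in self.credibilities.values():
            _check_cred("source credibility", c)

    def get(self, source: str) -> float:
        return self.credibilities.get(source, DEFAULT_CREDIBILITY)

    def register(self, source: str, credibility: float = DEFAULT_CREDIBILITY) -> None:
        _check_cred("source credibility", credibility)
        self.credibilities[source] = credibility


@dataclass(frozen=True)
class Provenance:
    """How a list came to be: source, acquisition date, operation, parents."""

    source_name: str
    acquired: datetime.date
    operation: str
    parent_list_names: tuple[str, ...] = ()


def _entry_combined(entry, registry: SourceRegistry | None) -> float:
    reg = registry or _DEFAULT_REGISTRY
    creds = [reg.get(ev.source) for ev in entry.evidence]
    creds.append(entry.credibility.score_credibility)
    if entry.credibility.group_credibility is not None:
        creds.append(entry.credibility.group_credibility)
    return belief.combined_credibility(creds)


_DEFAULT_REGISTRY = SourceRegistry()


@dataclass
class GeneListEntry:
    """One row of a gene list: the gene, its evidence, its credibility."""

    gene: Gene
    evidence: list[EvidenceItem]
    credibility: CredibilityState = field(default_factory=CredibilityState)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("an entry needs at least one evidence item")
        sources = [ev.source for ev in self.evidence]
        if len(sources) != len(set(sources)):
            raise ValueError("evidence sources within an entry must be distinct")

    @property
    def key(self) -> int:
        return self.gene.id


@dataclass
class GenePairEntry:
    """One row of a pair list: input gene, discovered gene, evidence."""

    input_gene: Gene
    output_gene: Gene
    evidence: list[EvidenceItem]
    credibility: CredibilityState = field(default_factory=CredibilityState)

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("an entry needs at least one evidence item")
        sources = [ev.source for ev in self.evidence]
        if len(sources) != len(set(sources)):
            raise ValueError("evidence sources within an entry must be distinct")

    @property
    def key(self) -> tuple[int, int]:
        return (self.input_gene.id, self.output_gene.id)


class _ListBase:
    """Shared behaviour of gene lists and gene-pair lists."""

    def __init__(self, name: str, provenance: Provenance) -> None:
        self.name = name
        self.provenance = provenance
        self.entries: dict = {}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator:
        return iter(self.entries.values())

    def __contains__(self, key) -> bool:
        return key in self.entries

    def recompute_combined(self, registry: SourceRegistry | None = None) -> None:
        """Refresh every row's combined credibility from its components."""
        for entry in self.entries.values():
            reg = registry or _DEFAULT_REGISTRY
            entry.credibility.source_credibility = reg.get(entry.evidence[0].source)
            entry.credibility.combined = _entry_combined(entry, registry)

    def add_entry(self, entry, registry: SourceRegistry | None = None) -> None:
        """Insert an entry, merging evidence if its key already exists."""
        key = entry.key
        if key in self.entries:
            existing = self.entries[key]
            existing.evidence = merge_evidence(existing.evidence, entry.evidence)
            existing.credibility.combined = _entry_combined(existing, registry)
        else:
            entry.credibility.combined = _entry_combined(entry, registry)
            self.entries[key] = entry


class GeneList(_ListBase):
    """A named, species-homogeneous set of evidence-annotated genes."""

    kind = "gene_list"

    def __init__(self, name: str, species: int, provenance: Provenance) -> None:
        super().__init__(name, provenance)
        self.species = species

    def add_entry(self, entry: GeneListEntry, registry=None) -> None:
        if entry.gene.species != self.species:
            raise ValueError(
                f"gene {entry.gene.id} has species {entry.gene.species}, "
                f"list {self.name!r} is species {self.species}"
            )
        super().add_entry(entry, registry)

    def gene_ids(self) -> set[int]:
        return set(self.entries)

    def genes(self) -> list[Gene]:
        return [e.gene for e in self.entries.values()]


class GenePairList(_ListBase):
    """Ordered gene pairs: input genes in column 1, discovered in column 2.

    Each column carries its own species so cross-species (ortholog) pair
    lists are first-class.
    """

    kind = "gene_pair_list"

    def __init__(
        self,
        name: str,
        input_species: int,
        output_species: int,
        provenance: Provenance,
    ) -> None:
        super().__init__(name, provenance)
        self.input_species = input_species
        self.output_species = output_species

    def add_entry(self, entry: GenePairEntry, registry=None) -> None:
        if entry.input_gene.species != self.input_species:
            raise ValueError(
                f"input gene {entry.input_gene.id} has species "
                f"{entry.input_gene.species}, column 1 is species {self.input_species}"
            )
        if entry.output_gene.species != self.output_species:
            raise ValueError(
                f"output gene {entry.output_gene.id} has species "
                f"{entry.output_gene.species}, column 2 is species {self.output_species}"
            )
        super().add_entry(entry, registry)

    def pair_keys(self) -> set[tuple[int, int]]:
        return set(self.entries)


def _more_significant(a: EvidenceItem, b: EvidenceItem) -> EvidenceItem:
    """Of two items from the same source, keep the more significant score."""
    if a.score_kind in ("p_value", "default"):
        return a if a.score_from_source <= b.score_from_source else b
    return a if a.score_from_source >= b.score_from_source else b


def merge_evidence(
    first: Iterable[EvidenceItem], second: Iterable[EvidenceItem]
) -> list[EvidenceItem]:
    """Concatenate evidence, deduplicating by source.

    Distinct sources concatenate in first-seen order; a source appearing
    twice keeps its more significant score (smaller p, larger count).
    """
    out: dict[str, EvidenceItem] = {}
    for ev in list(first) + list(second):
        if ev.source in out:
            out[ev.source] = _more_significant(out[ev.source], ev)
        else:
            out[ev.source] = ev
    return list(out.values())


def new_list(
    name: str,
    species: int,
    genes: Iterable[Gene],
    *,
    acquired: datetime.date | None = None,
    source: str = "import",
    registry: SourceRegistry | None = None,
) -> GeneList:
    """Build a fresh gene list from bare genes.

    Every entry receives one neutral evidence item (kind ``default``, score
    0.05 — the stand-in p-value convention for unscored sources) and default
    credibilities.  Duplicate genes collapse to one entry.
    """
    acquired = acquired or datetime.date.today()
    lst = GeneList(name, species, Provenance(source, acquired, "import"))
    for g in genes:
        if g.species != species:
            raise ValueError(
                f"gene {g.id} has species {g.species}, expected {species}"
            )
        lst.add_entry(
            GeneListEntry(
                gene=g,
                evidence=[EvidenceItem(source, DEFAULT_SCORE, "default", acquired)],
            ),
            registry,
        )
    return lst


def merge_term_results(
    focused: GeneList, general: GeneList, *, registry: SourceRegistry | None = None
) -> GeneList:
    """Merge a focused (p-value bearing) and a general term-query result.

    The union of genes is kept.  A gene found by both sources keeps the
    focused source's p-value as its score and lists both sources as
    evidence; a gene only the general source returned carries the default
    score 0.05.
    """
    if focused.species != general.species:
        raise ValueError(
            f"species mismatch: {focused.species} vs {general.species}"
        )
    prov = Provenance(
        source_name=f"{focused.provenance.source_name}+{general.provenance.source_name}",
        acquired=max(focused.provenance.acquired, general.provenance.acquired),
        operation="merge_term_results",
        parent_list_names=(focused.name, general.name),
    )
    out = GeneList(focused.name, focused.species, prov)
    for entry in focused:
        out.add_entry(
            GeneListEntry(entry.gene, list(entry.evidence), _copy_cred(entry)),
            registry,
        )
    for entry in general:
        if entry.gene.id in out.entries:
            merged = out.entries[entry.gene.id]
            # focused p-value wins; the general source is recorded as evidence
            merged.evidence = merge_evidence(merged.evidence, entry.evidence)
            merged.credibility.combined = _entry_combined(merged, registry)
        else:
            out.add_entry(
                GeneListEntry(entry.gene, list(entry.evidence), _copy_cred(entry)),
                registry,
            )
    return out


def _copy_cred(entry) -> CredibilityState:
    c = entry.credibility
    return CredibilityState(
        c.source_credibility, c.score_credibility, c.group_credibility, c.combined
    )


_SORT_KEYS = ("combined_credibility", "score", "gene_symbol", "source")


def sort_entries(lst, key: str):
    """Reorder a list's rows.

    ``combined_credibility`` and ``score`` sort most significant first;
    ``gene_symbol`` and ``source`` sort alphabetically.  The sort is stable:
    rows with equal keys keep their original relative order.
    """
    if key not in _SORT_KEYS:
        raise ValueError(f"unknown sort key {key!r}; choose from {_SORT_KEYS}")

    if key == "combined_credibility":
        keyfunc = lambda e: -e.credibility.combined
    elif key == "score":
        def keyfunc(e):
            ev = e.evidence[0]
            return -float(
                belief.normalize_scores([ev.score_from_source], ev.score_kind)[0]
            )
    elif key == "gene_symbol":
        keyfunc = lambda e: (
            e.gene.symbol if hasattr(e, "gene") else e.input_gene.symbol
        )
    else:  # source
        keyfunc = lambda e: e.evidence[0].source

    ordered = sorted(lst.entries.values(), key=keyfunc)
    lst.entries = {e.key: e for e in ordered}
    return lst
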