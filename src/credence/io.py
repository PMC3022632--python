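"""Flat-file adapters and workflow persistence.

Every external data source is a local table: an OBO ontology, a GAF-like
annotation TSV, interaction / ortholog / coordinate / expression TSVs and a
term-to-gene table with p-values.  Each table carries an acquisition date
(from a ``# acquired: YYYY-MM-DD`` header comment, defaulting to today) so
provenance semantics survive without any network access.  Malformed lines
are collected into a per-table error report with line numbers rather than
aborting the load.

Workflows — saved lists, operation records and their lineage — persist as a
versioned XML document whose save -> load round trip is lossless for list
contents, evidence, credibilities, partition schemes and provenance dates.
"""

from __future__ import annotations

import datetime
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

import networkx as nx
import obonet
import pandas as pd

from . import belief
from .model import (
    CredibilityState,
    DEFAULT_SCORE,
    EvidenceItem,
    Gene,
    GeneList,
    GeneListEntry,
    GenePairEntry,
    GenePairList,
    Provenance,
    SourceRegistry,
    merge_term_results,
    new_list,
)
from .enrichment import TermGraph

__all__ = [
    "SourceTable",
    "Workflow",
    "export_csv",
    "import_ids",
    "load_list",
    "load_workflow",
    "query_interactions",
    "query_orthologs",
    "query_term_to_genes",
    "read_annotations",
    "read_coordinates",
    "read_expression",
    "read_interactions",
    "read_obo",
    "read_orthologs",
    "read_term_genes",
    "save_list",
    "save_workflow",
]

SCHEMA_VERSION = "1.0"

TABLE_KINDS = (
    "term_gene_pvalue",
    "term_gene_plain",
    "interaction",
    "ortholog",
    "coordinates",
    "expression",
    "ontology",
)


@dataclass
class SourceTable:
    """A typed local table standing in for one web data source."""

    name: str
    kind: str
    df: pd.DataFrame
    acquired: datetime.date
    errors: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise ValueError(f"unknown table kind {self.kind!r}")


_ACQUIRED_RE = re.compile(r"#\s*acquired:\s*(\d{4}-\d{2}-\d{2})")


def _read_lines(path) -> tuple[list[tuple[int, list[str]]], datetime.date]:
    acquired = datetime.date.today()
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = _ACQUIRED_RE.match(line)
                if m:
                    acquired = datetime.date.fromisoformat(m.group(1))
                continue
            rows.append((lineno, line.split("\t")))
    return rows, acquired


def _load_table(path, kind, columns, parsers) -> SourceTable:
    rows, acquired = _read_lines(path)
    records, errors, seen = [], [], {}
    for lineno, fields in rows:
        if len(fields) < len(columns):
            errors.append(f"line {lineno}: expected {len(columns)} columns, got {len(fields)}")
            continue
        try:
            rec = tuple(p(f) for p, f in zip(parsers, fields))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {lineno}: {exc}")
            continue
        if rec in seen:
            seen[rec] += 1
            continue
        seen[rec] = 1
        records.append(rec)
    df = pd.DataFrame(records, columns=columns)
    ndup = sum(c - 1 for c in seen.values() if c > 1)
    if ndup:
        warnings.warn(
            f"{path}: {ndup} duplicate rows collapsed", RuntimeWarning, stacklevel=3
        )
    return SourceTable(Path(path).stem, kind, df, acquired, errors)


def _bool(s: str) -> bool:
    if s.lower() in ("1", "true", "yes", "y"):
        return True
    if s.lower() in ("0", "false", "no", "n"):
        return False
    raise ValueError(f"not a boolean flag: {s!r}")


def read_interactions(path) -> SourceTable:
    """gene_a <TAB> gene_b <TAB> source <TAB> article_count.

    Self-interactions are kept but flagged in the error report.
    """
    t = _load_table(
        path,
        "interaction",
        ["gene_a", "gene_b", "source", "article_count"],
        [int, int, str, int],
    )
    for r in t.df.itertuples():
        if r.gene_a == r.gene_b:
            t.errors.append(f"self-interaction kept: {r.gene_a}-{r.gene_b}")
    return t


def read_orthologs(path) -> SourceTable:
    """gene_a <TAB> tax_a <TAB> gene_b <TAB> tax_b <TAB> percent_identity."""
    return _load_table(
        path,
        "ortholog",
        ["gene_a", "tax_a", "gene_b", "tax_b", "percent_identity"],
        [int, int, int, int, float],
    )


def read_expression(path) -> SourceTable:
    """gene <TAB> condition <TAB> n_up <TAB> n_down."""
    return _load_table(
        path,
        "expression",
        ["gene", "condition", "n_up", "n_down"],
        [int, str, int, int],
    )


def read_term_genes(path, *, plain: bool = False) -> SourceTable:
    """term <TAB> gene_id <TAB> p_value <TAB> is_disease (focused table) or
    term <TAB> gene_id <TAB> is_disease (plain/general table)."""
    if plain:
        return _load_table(
            path, "term_gene_plain", ["term", "gene", "is_disease"], [str, int, _bool]
        )
    return _load_table(
        path,
        "term_gene_pvalue",
        ["term", "gene", "p_value", "is_disease"],
        [str, int, float, _bool],
    )


def read_coordinates(path) -> SourceTable:
    """Gene start coordinates, 0-based half-open internally.

    Two layouts are accepted: a gene TSV ``gene <TAB> chrom <TAB> start
    [<TAB> symbol]`` with 1-based starts (converted on read), or BED
    ``chrom <TAB> start <TAB> end <TAB> gene`` kept 0-based as-is.  The
    layout is detected per line by whether the first column is an integer
    gene id.
    """
    rows, acquired = _read_lines(path)
    records, errors = [], []
    for lineno, fields in rows:
        try:
            if fields[0].lstrip("-").isdigit():  # gene TSV, 1-based
                gene, chrom, start = int(fields[0]), fields[1], int(fields[2])
                if start < 1:
                    raise ValueError(f"1-based start must be >= 1, got {start}")
                symbol = fields[3] if len(fields) > 3 else ""
                records.append((gene, chrom, start - 1, symbol))
            else:  # BED3+name, 0-based
                chrom, start, _end, gene = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    int(fields[3]),
                )
                records.append((gene, chrom, start, ""))
        except (ValueError, IndexError) as exc:
            errors.append(f"line {lineno}: {exc}")
    df = pd.DataFrame(records, columns=["gene", "chrom", "start", "symbol"])
    df = df.drop_duplicates(subset=["gene"])
    return SourceTable(Path(path).stem, "coordinates", df, acquired, errors)


def read_obo(path) -> TermGraph:
    """Load an OBO ontology, keeping only is_a edges (child -> parent).

    Other relationship types (part_of etc.) are dropped with a count
    warning; a cycle in the is_a graph is a hard error naming one member.
    """
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    names = {}
    dropped = 0
    for node, data in multi.nodes(data=True):
        g.add_node(node)
        names[node] = data.get("name", node)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
        else:
            dropped += 1
    if dropped:
        warnings.warn(
            f"{dropped} non-is_a relationships dropped from {path}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"is_a cycle in {path} through term {cycle[0][0]!r}")
    return TermGraph(g, names=names)


def read_annotations(path, graph: TermGraph) -> TermGraph:
    """gene_id <TAB> term_id <TAB> evidence_code, applied to a term graph.

    Returns a new TermGraph with true-path closure applied; rows annotating
    unknown terms are reported (with line numbers) and dropped.
    """
    rows, _acquired = _read_lines(path)
    records, bad = [], []
    for lineno, fields in rows:
        if len(fields) < 3:
            bad.append(f"line {lineno}: expected 3 columns")
            continue
        try:
            gid = int(fields[0])
        except ValueError:
            bad.append(f"line {lineno}: bad gene id {fields[0]!r}")
            continue
        if fields[1] not in graph.graph:
            bad.append(f"line {lineno}: unknown term {fields[1]!r}")
            continue
        records.append((gid, fields[1], fields[2]))
    if bad:
        warnings.warn(
            f"{path}: {len(bad)} annotation rows dropped ({bad[:3]} ...)",
            RuntimeWarning,
            stacklevel=2,
        )
    out = TermGraph(graph.graph, names=dict(graph.names))
    out.raw_annotations = records
    out._close()
    return out


# ---------------------------------------------------------------------------
# queries against local tables


def query_term_to_genes(
    term: str,
    focused: SourceTable,
    general: SourceTable,
    *,
    species: int,
    mode: str = "general",
    registry: SourceRegistry | None = None,
) -> GeneList:
    """Term -> gene list from a focused (p-value) and a general source.

    Terms match exactly but case-insensitively.  The focused source's
    p-value is kept when both sources return a gene; genes only the general
    source returned carry the default score 0.05.  ``disease_only``
    restricts the general table to rows flagged as disease terms.
    """
    if mode not in ("disease_only", "general"):
        raise ValueError(f"unknown query mode {mode!r}")
    t = term.lower()
    fdf = focused.df[focused.df["term"].str.lower() == t]
    gdf = general.df[general.df["term"].str.lower() == t]
    if mode == "disease_only":
        gdf = gdf[gdf["is_disease"]]

    flist = GeneList(
        f"{term} [{focused.name}]",
        species,
        Provenance(focused.name, focused.acquired, "query_term_to_genes"),
    )
    for r in fdf.itertuples():
        flist.add_entry(
            GeneListEntry(
                Gene(int(r.gene), species),
                [EvidenceItem(focused.name, float(r.p_value), "p_value", focused.acquired)],
            ),
            registry,
        )
    glist = GeneList(
        f"{term} [{general.name}]",
        species,
        Provenance(general.name, general.acquired, "query_term_to_genes"),
    )
    for r in gdf.itertuples():
        glist.add_entry(
            GeneListEntry(
                Gene(int(r.gene), species),
                [EvidenceItem(general.name, DEFAULT_SCORE, "default", general.acquired)],
            ),
            registry,
        )
    if not flist.entries and not glist.entries:
        warnings.warn(
            f"term {term!r} absent from both sources", RuntimeWarning, stacklevel=2
        )
    merged = merge_term_results(flist, glist, registry=registry)
    merged.name = term
    return merged


def query_interactions(
    genes: GeneList,
    interactions: SourceTable,
    *,
    registry: SourceRegistry | None = None,
    name: str | None = None,
) -> GenePairList:
    """Gene list -> interacting pair list from a local interaction table.

    Partners are looked up in both columns of the (symmetric) table; the
    score is the supporting article count, and a pair reported by several
    sources carries one evidence item per source.
    """
    prov = Provenance(
        interactions.name,
        interactions.acquired,
        "query_interactions",
        (genes.name,),
    )
    out = GenePairList(
        name or f"{genes.name} interactions",
        genes.species,
        genes.species,
        prov,
    )
    df = interactions.df
    lookup = {e.gene.id: e.gene for e in genes}
    for gid, gene in sorted(lookup.items()):
        hits = df[(df["gene_a"] == gid) | (df["gene_b"] == gid)]
        for r in hits.itertuples():
            partner = int(r.gene_b) if int(r.gene_a) == gid else int(r.gene_a)
            out.add_entry(
                GenePairEntry(
                    gene,
                    Gene(partner, genes.species),
                    [
                        EvidenceItem(
                            str(r.source),
                            int(r.article_count),
                            "article_count",
                            interactions.acquired,
                        )
                    ],
                ),
                registry,
            )
    return out


def query_orthologs(
    genes: GeneList,
    target_species: int,
    orthologs: SourceTable,
    *,
    registry: SourceRegistry | None = None,
    name: str | None = None,
) -> GenePairList:
    """Gene list -> orthologous pair list into a target species.

    The ortholog table is searched in both orientations; the score is the
    percent identity between the two orthologs.  Genes without an ortholog
    are simply absent from the result.
    """
    prov = Provenance(
        orthologs.name, orthologs.acquired, "query_orthologs", (genes.name,)
    )
    out = GenePairList(
        name or f"{genes.name} orthologs({target_species})",
        genes.species,
        target_species,
        prov,
    )
    df = orthologs.df
    for entry in genes:
        gid, sp = entry.gene.id, entry.gene.species
        fwd = df[(df["gene_a"] == gid) & (df["tax_a"] == sp) & (df["tax_b"] == target_species)]
        rev = df[(df["gene_b"] == gid) & (df["tax_b"] == sp) & (df["tax_a"] == target_species)]
        for r in fwd.itertuples():
            out.add_entry(
                GenePairEntry(
                    entry.gene,
                    Gene(int(r.gene_b), target_species),
                    [
                        EvidenceItem(
                            orthologs.name,
                            float(r.percent_identity),
                            "percent_identity",
                            orthologs.acquired,
                        )
                    ],
                ),
                registry,
            )
        for r in rev.itertuples():
            out.add_entry(
                GenePairEntry(
                    entry.gene,
                    Gene(int(r.gene_a), target_species),
                    [
                        EvidenceItem(
                            orthologs.name,
                            float(r.percent_identity),
                            "percent_identity",
                            orthologs.acquired,
                        )
                    ],
                ),
                registry,
            )
    return out


# ---------------------------------------------------------------------------
# workflow XML


@dataclass
class Workflow:
    """Saved lists, partition schemes and operation records with lineage."""

    nodes: dict[str, object] = field(default_factory=dict)
    edges: list[tuple[str, str]] = field(default_factory=list)

    def add(self, name: str, payload, parents: tuple[str, ...] = ()) -> None:
        if name in self.nodes:
            raise ValueError(f"duplicate workflow node {name!r}")
        for p in parents:
            if p not in self.nodes:
                raise ValueError(f"unknown parent node {p!r}")
        self.nodes[name] = payload
        for p in parents:
            self.edges.append((p, name))


def _evidence_el(ev: EvidenceItem) -> ET.Element:
    return ET.Element(
        "evidence",
        source=ev.source,
        score=repr(ev.score_from_source),
        kind=ev.score_kind,
        acquired=ev.acquired.isoformat(),
    )


def _cred_el(c: CredibilityState) -> ET.Element:
    attrs = {
        "source": repr(c.source_credibility),
        "score": repr(c.score_credibility),
        "combined": repr(c.combined),
    }
    if c.group_credibility is not None:
        attrs["group"] = repr(c.group_credibility)
    return ET.Element("credibility", attrs)


def _prov_el(p: Provenance) -> ET.Element:
    el = ET.Element(
        "provenance",
        source=p.source_name,
        acquired=p.acquired.isoformat(),
        operation=p.operation,
    )
    for parent in p.parent_list_names:
        ET.SubElement(el, "parent", name=parent)
    return el


def _gene_attrs(g: Gene) -> dict[str, str]:
    return {"id": str(g.id), "species": str(g.species), "symbol": g.symbol}


def _list_to_el(lst) -> ET.Element:
    if lst.kind == "gene_list":
        el = ET.Element("gene_list", name=lst.name, species=str(lst.species))
    else:
        el = ET.Element(
            "gene_pair_list",
            name=lst.name,
            input_species=str(lst.input_species),
            output_species=str(lst.output_species),
        )
    el.append(_prov_el(lst.provenance))
    for entry in lst:
        e = ET.SubElement(el, "entry")
        if lst.kind == "gene_list":
            ET.SubElement(e, "gene", _gene_attrs(entry.gene))
        else:
            ET.SubElement(e, "input_gene", _gene_attrs(entry.input_gene))
            ET.SubElement(e, "output_gene", _gene_attrs(entry.output_gene))
        e.append(_cred_el(entry.credibility))
        for ev in entry.evidence:
            e.append(_evidence_el(ev))
    return el


def _el_to_gene(el: ET.Element) -> Gene:
    return Gene(int(el.get("id")), int(el.get("species")), el.get("symbol", ""))


def _el_to_evidence(el: ET.Element) -> EvidenceItem:
    return EvidenceItem(
        el.get("source"),
        float(el.get("score")),
        el.get("kind"),
        datetime.date.fromisoformat(el.get("acquired")),
    )


def _el_to_cred(el: ET.Element) -> CredibilityState:
    group = el.get("group")
    return CredibilityState(
        float(el.get("source")),
        float(el.get("score")),
        float(group) if group is not None else None,
        float(el.get("combined")),
    )


def _el_to_prov(el: ET.Element) -> Provenance:
    return Provenance(
        el.get("source"),
        datetime.date.fromisoformat(el.get("acquired")),
        el.get("operation"),
        tuple(p.get("name") for p in el.findall("parent")),
    )


def _el_to_list(el: ET.Element):
    prov = _el_to_prov(el.find("provenance"))
    if el.tag == "gene_list":
        lst = GeneList(el.get("name"), int(el.get("species")), prov)
        for e in el.findall("entry"):
            entry = GeneListEntry(
                _el_to_gene(e.find("gene")),
                [_el_to_evidence(ev) for ev in e.findall("evidence")],
                _el_to_cred(e.find("credibility")),
            )
            lst.entries[entry.key] = entry
    else:
        lst = GenePairList(
            el.get("name"),
            int(el.get("input_species")),
            int(el.get("output_species")),
            prov,
        )
        for e in el.findall("entry"):
            entry = GenePairEntry(
                _el_to_gene(e.find("input_gene")),
                _el_to_gene(e.find("output_gene")),
                [_el_to_evidence(ev) for ev in e.findall("evidence")],
                _el_to_cred(e.find("credibility")),
            )
            lst.entries[entry.key] = entry
    return lst


def _scheme_to_el(s: belief.PartitionScheme) -> ET.Element:
    return ET.Element(
        "partition_scheme",
        boundaries=",".join(repr(b) for b in s.boundaries),
        credibilities=",".join(repr(c) for c in s.credibilities),
    )


def _el_to_scheme(el: ET.Element) -> belief.PartitionScheme:
    btxt = el.get("boundaries")
    boundaries = tuple(float(x) for x in btxt.split(",")) if btxt else ()
    creds = tuple(float(x) for x in el.get("credibilities").split(","))
    return belief.PartitionScheme(boundaries, creds)


def save_workflow(wf: Workflow, path) -> None:
    """Serialise a workflow as schema-versioned XML."""
    root = ET.Element("workflow", schema=SCHEMA_VERSION)
    for name in sorted(wf.nodes):  # key order normalised
        payload = wf.nodes[name]
        node = ET.SubElement(root, "node", name=name)
        if isinstance(payload, (GeneList, GenePairList)):
            node.append(_list_to_el(payload))
        elif isinstance(payload, belief.PartitionScheme):
            node.append(_scheme_to_el(payload))
        elif isinstance(payload, dict):  # operation record
            op = ET.SubElement(node, "operation")
            for k, v in sorted(payload.items()):
                ET.SubElement(op, "param", key=str(k), value=str(v))
        else:
            raise TypeError(f"cannot serialise workflow node of type {type(payload)}")
    for parent, child in wf.edges:
        ET.SubElement(root, "edge", parent=parent, child=child)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def load_workflow(path) -> Workflow:
    """Load a workflow XML file, validating schema version and lineage."""
    root = ET.parse(path).getroot()
    version = root.get("schema")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported workflow schema version {version!r} "
            f"(this build reads {SCHEMA_VERSION})"
        )
    wf = Workflow()
    for node in root.findall("node"):
        name = node.get("name")
        child = list(node)[0]
        if child.tag in ("gene_list", "gene_pair_list"):
            wf.nodes[name] = _el_to_list(child)
        elif child.tag == "partition_scheme":
            wf.nodes[name] = _el_to_scheme(child)
        elif child.tag == "operation":
            wf.nodes[name] = {
                p.get("key"): p.get("value") for p in child.findall("param")
            }
        else:
            raise ValueError(f"unknown node payload {child.tag!r}")
    for edge in root.findall("edge"):
        parent, child = edge.get("parent"), edge.get("child")
        if parent not in wf.nodes or child not in wf.nodes:
            raise ValueError(f"dangling workflow edge {parent!r} -> {child!r}")
        wf.edges.append((parent, child))
    return wf


def save_list(lst, path) -> None:
    """Save a single list as a one-node workflow file."""
    wf = Workflow()
    wf.add(lst.name, lst)
    save_workflow(wf, path)


def load_list(path):
    """Load the single list from a one-node workflow file."""
    wf = load_workflow(path)
    lists = [v for v in wf.nodes.values() if isinstance(v, (GeneList, GenePairList))]
    if len(lists) != 1:
        raise ValueError(f"{path} holds {len(lists)} lists, expected exactly 1")
    return lists[0]


# ---------------------------------------------------------------------------
# CSV export / plain-ID import


def export_csv(lst, path) -> None:
    """Flatten a list to CSV (one row per entry, evidence joined by ';')."""
    rows = []
    for entry in lst:
        common = {
            "scores": ";".join(repr(ev.score_from_source) for ev in entry.evidence),
            "kinds": ";".join(ev.score_kind for ev in entry.evidence),
            "sources": ";".join(ev.source for ev in entry.evidence),
            "source_credibility": entry.credibility.source_credibility,
            "score_credibility": entry.credibility.score_credibility,
            "combined_credibility": entry.credibility.combined,
        }
        if lst.kind == "gene_list":
            rows.append(
                {"gene_id": entry.gene.id, "symbol": entry.gene.symbol, **common}
            )
        else:
            rows.append(
                {
                    "input_gene_id": entry.input_gene.id,
                    "input_symbol": entry.input_gene.symbol,
                    "output_gene_id": entry.output_gene.id,
                    "output_symbol": entry.output_gene.symbol,
                    **common,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def import_ids(
    path,
    species: int,
    *,
    symbol_map: dict[str, int] | None = None,
    name: str | None = None,
    registry: SourceRegistry | None = None,
) -> GeneList:
    """Import a plain ID list (one integer id or symbol per line).

    Symbols resolve through ``symbol_map`` (typically built from the
    coordinate or annotation tables); unresolvable lines are reported in a
    warning and skipped.
    """
    genes, unresolved = [], []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            token = raw.strip()
            if not token or token.startswith("#"):
                continue
            if token.isdigit():
                genes.append(Gene(int(token), species))
            elif symbol_map and token in symbol_map:
                genes.append(Gene(symbol_map[token], species, token))
            else:
                unresolved.append(token)
    if unresolved:
        warnings.warn(
            f"{len(unresolved)} identifiers could not be resolved and were "
            f"skipped: {unresolved[:10]}",
            RuntimeWarning,
            stacklevel=2,
        )
    return new_list(name or Path(path).stem, species, genes, registry=registry)
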