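"""Deterministic synthetic fixtures for every adapter format.

The generator writes a coherent little two-species world — an ontology with
a planted over-represented term, coordinates with a planted chromosomal
cluster, expression skewed under one condition, term-to-gene tables for the
term query, and ortholog/interaction tables containing a planted interolog
triangle modelled on the fly/human Mediator-complex MED26 case (fly MED26,
NCBI gene 43816, orthologous to human MED26, 9441, whose human partners
MED4/MED16/MED17 have fly orthologs with which no fly interaction is on
record).  Gene IDs for the fly partner orthologs are synthetic stand-ins.
Every planted truth is recorded in a machine-readable manifest, and the
same seed always reproduces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["FixtureSpec", "generate", "manifest", "PRESETS"]

ACQUIRED = "2010-12-30"  # fixed provenance date stamped into every table

# -- planted interolog triangle (human IDs real, fly partner IDs synthetic) --
FLY, HUMAN = 7227, 9606
FLY_MED26, HUMAN_MED26 = 43816, 9441
HUMAN_PARTNERS = {"MED4": 29079, "MED16": 10025, "MED17": 9440, "MED31": 51003}
FLY_ORTHOLOGS = {29079: 35210, 10025: 34577, 9440: 37109, 51003: 39995}
#: the MED31 edge is already known in fly, so it must NOT be predicted
FLY_KNOWN_PARTNER = 39995

PLANTED_TERM = "T:0111"

_OBO_EDGES = [
    ("T:0010", "T:0001"),
    ("T:0020", "T:0001"),
    ("T:0011", "T:0010"),
    ("T:0012", "T:0010"),
    ("T:0021", "T:0020"),
    ("T:0022", "T:0020"),
    ("T:0111", "T:0011"),
    ("T:0111", "T:0012"),
    ("T:0112", "T:0011"),
    ("T:0121", "T:0021"),
    ("T:0122", "T:0021"),
    ("T:0122", "T:0022"),
]
_TERM_NAMES = {
    "T:0001": "biological process root",
    "T:0010": "metabolic process",
    "T:0020": "signaling",
    "T:0011": "DNA repair",
    "T:0012": "chromatin organization",
    "T:0021": "kinase cascade",
    "T:0022": "stress response",
    "T:0111": "mismatch repair",
    "T:0112": "base excision repair",
    "T:0121": "MAPK cascade",
    "T:0122": "oxidative stress response",
}
_BACKGROUND_TERMS = ["T:0112", "T:0121", "T:0122", "T:0011", "T:0012", "T:0021", "T:0022"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic world.

    Defaults are the fixture-scale study conditions used throughout the
    test suite: a 60-gene annotated population with a 10-gene study set of
    which 80% carry the planted term, a 5-gene cluster within 200 kb on a
    1,000-gene chromosome, and a sparse interaction background (expected
    degree well under 3) so the planted signal dominates.
    """

    seed: int = 1
    n_population: int = 60
    study_size: int = 10
    planted_effect: float = 0.8
    annotation_density: float = 0.15
    cluster_chrom: str = "2L"
    cluster_size: int = 5
    cluster_span_bp: int = 200_000
    n_chrom_genes: int = 1_000
    chrom_length_bp: int = 20_000_000
    n_background_genes: int = 40
    background_interactions: int = 20
    expression_condition: str = "hypoxia"


PRESETS = {
    "med26": FixtureSpec(),
    "enrichment": FixtureSpec(),
    "proximity": FixtureSpec(),
}


def _write(path: Path, lines: list[str]) -> None:
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _obo_lines() -> list[str]:
    lines = ["format-version: 1.2", "ontology: synthetic-fixture", ""]
    parents: dict[str, list[str]] = {}
    for child, parent in _OBO_EDGES:
        parents.setdefault(child, []).append(parent)
    for term in sorted(_TERM_NAMES):
        lines += ["[Term]", f"id: {term}", f"name: {_TERM_NAMES[term]}"]
        for p in parents.get(term, []):
            lines.append(f"is_a: {p} ! {_TERM_NAMES[p]}")
        lines.append("")
    return lines[:-1]


def generate(spec: FixtureSpec, outdir) -> dict:
    """Write every fixture file into ``outdir`` and return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    header = f"# acquired: {ACQUIRED}"

    # ---- ontology + annotations with a planted enriched term -------------
    population = list(range(1001, 1001 + spec.n_population))
    study = sorted(rng.choice(population, size=spec.study_size, replace=False).tolist())
    n_hit = max(2, int(round(spec.planted_effect * spec.study_size)))
    planted_hits = study[:n_hit]
    non_study = sorted(set(population) - set(study))
    planted_extra = sorted(
        rng.choice(non_study, size=2, replace=False).tolist()
    )
    ann_rows: list[tuple[int, str, str]] = []
    for g in planted_hits + planted_extra:
        ann_rows.append((g, PLANTED_TERM, "EXP"))
    # both parents of the planted term share a pool of direct annotations so
    # that the parent-child conditioning sets properly exceed the term itself
    shared_parent = sorted(rng.choice(non_study, size=15, replace=False).tolist())
    for g in shared_parent:
        ann_rows.append((g, "T:0011", "EXP"))
        ann_rows.append((g, "T:0012", "EXP"))
    for g in population:
        n_terms = rng.integers(1, 3)
        terms = rng.choice(_BACKGROUND_TERMS, size=n_terms, replace=False)
        for t in terms:
            if rng.random() < spec.annotation_density * 4:
                code = "IEA" if rng.random() < 0.3 else "EXP"
                ann_rows.append((g, str(t), code))
    ann_rows = sorted(set(ann_rows))
    _write(out / "ontology.obo", _obo_lines())
    _write(
        out / "annotations.tsv",
        [header] + [f"{g}\t{t}\t{c}" for g, t, c in ann_rows],
    )

    # ---- coordinates with a planted cluster ------------------------------
    coords: list[tuple[int, str, int]] = []
    bg_starts = sorted(
        rng.choice(
            spec.chrom_length_bp,
            size=spec.n_chrom_genes - spec.cluster_size,
            replace=False,
        ).tolist()
    )
    for i, s in enumerate(bg_starts):
        coords.append((3001 + i, spec.cluster_chrom, int(s)))
    base = int(rng.integers(1_000_000, spec.chrom_length_bp - 1_000_000))
    offsets = np.sort(
        rng.choice(spec.cluster_span_bp, size=spec.cluster_size, replace=False)
    )
    cluster_genes = list(range(2001, 2001 + spec.cluster_size))
    for g, off in zip(cluster_genes, offsets):
        coords.append((g, spec.cluster_chrom, base + int(off)))
    # a second chromosome with three widely scattered study genes
    scatter_genes = [5001, 5002, 5003]
    for g, s in zip(scatter_genes, (1_000_000, 8_000_000, 15_000_000)):
        coords.append((g, "3R", s))
    for i in range(200):
        coords.append((5101 + i, "3R", int(rng.integers(spec.chrom_length_bp))))
    coords.sort()
    cluster_starts = [s for g, c, s in coords if g in cluster_genes]
    _write(
        out / "coords.tsv",
        [header] + [f"{g}\t{c}\t{s + 1}" for g, c, s in coords],  # 1-based file
    )

    # ---- expression skewed for the study set -----------------------------
    expr_rows = []
    for g in study:
        n_up = int(rng.integers(4, 9))
        n_down = int(rng.integers(0, max(1, n_up - 1)))
        expr_rows.append((g, spec.expression_condition, n_up, n_down))
    for g in non_study:
        n_up = int(rng.integers(0, 4))
        n_down = int(rng.integers(0, 4))
        expr_rows.append((g, spec.expression_condition, n_up, n_down))
    for g in population:
        expr_rows.append((g, "control", int(rng.integers(0, 4)), int(rng.integers(0, 4))))
    expr_rows.sort(key=lambda r: (r[1], r[0]))
    _write(
        out / "expression.tsv",
        [header] + [f"{g}\t{c}\t{u}\t{d}" for g, c, u, d in expr_rows],
    )

    # ---- term-to-gene tables for the term query --------------------------
    focused_genes = population[:5]
    general_genes = population[2:8]
    focused_rows = [
        (
            "neoplasms",
            g,
            float(np.round(10 ** rng.uniform(-4, -2), 6)),
            True,
        )
        for g in focused_genes
    ]
    _write(
        out / "term_genes_focused.tsv",
        [header] + [f"{t}\t{g}\t{p:g}\ttrue" for t, g, p, _ in focused_rows],
    )
    general_lines = [f"neoplasms\t{g}\ttrue" for g in general_genes]
    general_lines += [f"kinase activity\t{g}\tfalse" for g in population[10:14]]
    _write(out / "term_genes_general.tsv", [header] + general_lines)

    # ---- orthologs and interactions with the planted triangle -----------
    orth_rows = [(FLY_MED26, FLY, HUMAN_MED26, HUMAN, 78.0)]
    for h, f in sorted(FLY_ORTHOLOGS.items()):
        orth_rows.append((f, FLY, h, HUMAN, float(np.round(rng.uniform(55, 90), 1))))
    fly_bg = list(range(70001, 70001 + spec.n_background_genes))
    human_bg = list(range(80001, 80001 + spec.n_background_genes))
    for f, h in zip(fly_bg[: spec.n_background_genes // 2], human_bg):
        orth_rows.append((f, FLY, h, HUMAN, float(np.round(rng.uniform(40, 95), 1))))

    inter_rows = []
    for name, h in sorted(HUMAN_PARTNERS.items()):
        inter_rows.append((HUMAN_MED26, h, "mimi", int(rng.integers(1, 6))))
    inter_rows.append((FLY_MED26, FLY_KNOWN_PARTNER, "mimi", 2))
    # sparse background interactions among background genes only
    for _ in range(spec.background_interactions):
        a, b = rng.choice(fly_bg, size=2, replace=False)
        inter_rows.append((int(a), int(b), "ncbi", int(rng.integers(1, 4))))
        a, b = rng.choice(human_bg, size=2, replace=False)
        inter_rows.append((int(a), int(b), "ncbi", int(rng.integers(1, 4))))
    inter_rows = sorted(set(inter_rows))
    _write(
        out / "orthologs.tsv",
        [header] + [f"{a}\t{ta}\t{b}\t{tb}\t{p:g}" for a, ta, b, tb, p in orth_rows],
    )
    _write(
        out / "interactions.tsv",
        [header] + [f"{a}\t{b}\t{s}\t{n}" for a, b, s, n in inter_rows],
    )
    _write(out / "input_genes.txt", [str(FLY_MED26)])

    planted_pairs = sorted(
        [FLY_MED26, FLY_ORTHOLOGS[h]] for h in HUMAN_PARTNERS.values()
        if FLY_ORTHOLOGS[h] != FLY_KNOWN_PARTNER
    )
    man = {
        "seed": spec.seed,
        "acquired": ACQUIRED,
        "species": {"query": FLY, "via": HUMAN},
        "files": sorted(
            p.name for p in out.iterdir() if p.name != "manifest.json"
        ),
        "planted_term": PLANTED_TERM,
        "population": population,
        "study_genes": study,
        "planted_term_study_hits": planted_hits,
        "planted_term_extra_genes": planted_extra,
        "planted_cluster": {
            "chrom": spec.cluster_chrom,
            "genes": cluster_genes,
            "starts_0based": cluster_starts,
            "span_bp": max(cluster_starts) - min(cluster_starts),
            "window_bp": spec.cluster_span_bp,
        },
        "proximity_study_genes": sorted(cluster_genes + scatter_genes),
        "expression_condition": spec.expression_condition,
        "term_query": {
            "term": "neoplasms",
            "focused_genes": focused_genes,
            "general_genes": general_genes,
            "overlap_genes": sorted(set(focused_genes) & set(general_genes)),
        },
        "input_gene": FLY_MED26,
        "planted_interologs": planted_pairs,
        "known_pairs": [[FLY_MED26, FLY_KNOWN_PARTNER]],
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(man, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return man


def manifest(outdir) -> dict:
    """Load the planted-truth manifest written by :func:`generate`."""
    path = Path(outdir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest in {outdir}")
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
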