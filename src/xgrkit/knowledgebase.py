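"""Plain-text knowledgebases: ontologies, gene networks, LD panels and evidence datasets.

Every resource is loaded from flat, diff-able text files (GMT for gene sets,
TSV for everything else; lines starting with ``#`` are ignored).  Gene
identifiers are opaque, case-sensitive symbols — no alias resolution is
attempted.  One consistent genome build per run is assumed throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("xgrkit")

#: Named confidence tiers for functional-interaction networks and the minimum
#: edge weight each one keeps.
TIER_THRESHOLDS: dict[str, float] = {"highest": 0.9, "high": 0.7, "medium": 0.4}

INTERVAL_KINDS = frozenset({"pchic", "abc"})
QTL_KINDS = frozenset({"eqtl", "pqtl"})


class KnowledgebaseError(ValueError):
    """Raised for malformed or inconsistent knowledgebase files."""


# ---------------------------------------------------------------------------
# Ontologies
# ---------------------------------------------------------------------------

@dataclass
class Ontology:
    """Term definitions, an optional term DAG, and gene annotations.

    ``direct`` maps each term to the genes annotated to it explicitly;
    ``propagated`` holds the annotation index after applying the true-path
    rule (a gene annotated to a term is implicitly annotated to every
    ancestor).  On a flat ontology the two coincide.
    """

    terms: dict[str, tuple[str, str]]          # term_id -> (name, namespace)
    direct: dict[str, frozenset[str]]          # term_id -> direct gene set
    dag_edges: set[tuple[str, str]] = field(default_factory=set)  # (child, parent)
    propagated: dict[str, set[str]] = field(default_factory=dict)

    @property
    def annotations(self) -> dict[str, set[str]]:
        """Direct gene -> term index (inverse of ``direct``)."""
        idx: dict[str, set[str]] = {}
        for term, genes in self.direct.items():
            for g in genes:
                idx.setdefault(g, set()).add(term)
        return idx

    def annotated_genes(self) -> set[str]:
        """All genes carrying at least one propagated annotation."""
        out: set[str] = set()
        for genes in self.propagated.values():
            out |= genes
        return out


def load_gmt(path: str | Path) -> Ontology:
    """Load a flat ontology from a GMT file (term, description, genes...).

    Duplicate genes within a line are deduplicated; duplicate term lines are
    merged by union.  Raises :class:`KnowledgebaseError` on lines with fewer
    than three tab-separated fields or on an empty file.
    """
    path = Path(path)
    terms: dict[str, tuple[str, str]] = {}
    direct: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            term_id, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if term_id in direct:
                direct[term_id] = direct[term_id] | genes
            else:
                terms[term_id] = (name, "")
                direct[term_id] = genes
    if not terms:
        raise KnowledgebaseError(f"{path}: empty GMT file")
    ont = Ontology(terms=terms, direct=direct)
    ont.propagated = {t: set(g) for t, g in direct.items()}
    return ont


def write_gmt(ont: Ontology, path: str | Path) -> None:
    """Write direct annotations back out as GMT, terms and genes sorted."""
    with open(path, "w") as fh:
        for term in sorted(ont.terms):
            name = ont.terms[term][0]
            genes = "\t".join(sorted(ont.direct[term]))
            fh.write(f"{term}\t{name}\t{genes}\n")


def attach_dag(ont: Ontology, edges: Iterable[tuple[str, str]]) -> Ontology:
    """Attach (child, parent) term edges to an ontology, checking acyclicity.

    Returns a new ontology whose propagated index is reset to the direct
    annotations; call :func:`propagate_annotations` afterwards to apply the
    true-path rule.
    """
    edge_set = set(edges)
    for child, parent in edge_set:
        for t in (child, parent):
            if t not in ont.terms:
                raise KnowledgebaseError(f"DAG references unknown term {t!r}")
    g = nx.DiGraph(edge_set)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        chain = " -> ".join(u for u, _ in cycle) + f" -> {cycle[0][0]}"
        raise KnowledgebaseError(f"term DAG contains a cycle: {chain}")
    return replace(
        ont,
        dag_edges=edge_set,
        propagated={t: set(g_) for t, g_ in ont.direct.items()},
    )


def propagate_annotations(ont: Ontology) -> Ontology:
    """Apply the true-path rule: each term inherits its descendants' genes.

    propagated[parent] = direct[parent] ∪ ⋃ propagated[children].  Idempotent,
    because propagation always restarts from the direct annotations.
    """
    g = nx.DiGraph()
    g.add_nodes_from(ont.terms)
    g.add_edges_from(ont.dag_edges)  # child -> parent
    propagated: dict[str, set[str]] = {}
    for term in nx.topological_sort(g):  # children before parents
        genes = set(ont.direct.get(term, ()))
        for child in g.predecessors(term):
            genes |= propagated[child]
        propagated[term] = genes
    return replace(ont, propagated=propagated)


def load_dag_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Read term DAG edges from a two-column TSV (child, parent)."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: expected 2 fields (child, parent)"
                )
            edges.append((fields[0], fields[1]))
    return edges


# ---------------------------------------------------------------------------
# Gene networks
# ---------------------------------------------------------------------------

@dataclass
class GeneNetwork:
    """Undirected weighted gene network with a confidence-tier provenance.

    Edges are stored canonically with ``gene_a < gene_b`` and weights in
    [0, 1]; self-loops are never kept and duplicate edges collapse to the
    maximum weight.
    """

    edges: dict[tuple[str, str], float]
    tier: str = "custom"
    threshold: float = 0.0

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def edge_set(self) -> set[tuple[str, str, float]]:
        return {(a, b, w) for (a, b), w in self.edges.items()}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=w)
        return g


def _tier_threshold(tier: str | float) -> tuple[str, float]:
    if isinstance(tier, str) and tier in TIER_THRESHOLDS:
        return tier, TIER_THRESHOLDS[tier]
    try:
        thr = float(tier)
    except (TypeError, ValueError):
        raise KnowledgebaseError(
            f"unknown confidence tier {tier!r}; expected one of "
            f"{sorted(TIER_THRESHOLDS)} or a numeric threshold"
        ) from None
    if not 0.0 <= thr <= 1.0:
        raise KnowledgebaseError(f"custom confidence threshold {thr} outside [0, 1]")
    return "custom", thr


def _add_edge(edges: dict[tuple[str, str], float], a: str, b: str, w: float) -> None:
    if a == b:
        return
    key = (a, b) if a < b else (b, a)
    if w > edges.get(key, -1.0):
        edges[key] = w


def load_network(path: str | Path, tier: str | float = "high") -> GeneNetwork:
    """Load a weighted edge-list TSV (gene_a, gene_b, weight), tier-filtered.

    Edges below the tier threshold are dropped; self-loops are dropped;
    duplicates (in either orientation) collapse keeping the maximum weight.
    """
    tier_name, thr = _tier_threshold(tier)
    path = Path(path)
    edges: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: expected 3 fields (gene_a, gene_b, weight)"
                )
            a, b = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: non-numeric weight {fields[2]!r}"
                ) from None
            if not 0.0 <= w <= 1.0:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: weight {w} outside [0, 1]"
                )
            if w < thr:
                continue
            _add_edge(edges, a, b, w)
    return GeneNetwork(edges=edges, tier=tier_name, threshold=thr)


def merge_pathway_networks(
    pathways: Sequence[Iterable[tuple]],
) -> GeneNetwork:
    """Merge per-pathway edge sets into one gene network.

    Each pathway is an iterable of ``(gene_a, gene_b)`` or
    ``(gene_a, gene_b, weight)`` edges; unweighted edges default to 1.0.
    Duplicate edges across pathways collapse keeping the maximum weight.
    An empty pathway list yields an empty network.
    """
    edges: dict[tuple[str, str], float] = {}
    for pathway in pathways:
        for edge in pathway:
            if len(edge) == 2:
                a, b = edge
                w = 1.0
            else:
                a, b, w = edge[0], edge[1], float(edge[2])
            if not 0.0 <= w <= 1.0:
                raise KnowledgebaseError(f"pathway edge weight {w} outside [0, 1]")
            _add_edge(edges, a, b, w)
    return GeneNetwork(edges=edges, tier="custom", threshold=0.0)


# ---------------------------------------------------------------------------
# LD panels
# ---------------------------------------------------------------------------

@dataclass
class LDPanel:
    """Directed seed -> proxy r² lookup plus proxy genomic coordinates."""

    pairs: dict[str, set[tuple[str, float]]]
    coords: dict[str, tuple[str, int]] = field(default_factory=dict)
    population_tag: str = "unspecified"

    def proxies(self, seed: str, r2_min: float) -> list[tuple[str, float]]:
        return sorted(
            (p, r2) for p, r2 in self.pairs.get(seed, ()) if r2 >= r2_min
        )


def empty_ld_panel() -> LDPanel:
    return LDPanel(pairs={}, coords={}, population_tag="none")


def load_ld_panel(path: str | Path, population_tag: str = "unspecified") -> LDPanel:
    """Load an LD panel TSV: seed, proxy, r2 [, proxy_chrom, proxy_pos].

    The two coordinate columns let downstream SNP expansion place proxies on
    the genome; when absent the proxy is kept but cannot feed proximity or
    interval evidence.
    """
    path = Path(path)
    pairs: dict[str, set[tuple[str, float]]] = {}
    coords: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: expected >=3 fields (seed, proxy, r2)"
                )
            seed, proxy = fields[0], fields[1]
            try:
                r2 = float(fields[2])
            except ValueError:
                raise KnowledgebaseError(
                    f"{path}: line {lineno}: non-numeric r2 {fields[2]!r}"
                ) from None
            if not 0.0 <= r2 <= 1.0:
                raise KnowledgebaseError(f"{path}: line {lineno}: r2 {r2} outside [0, 1]")
            pairs.setdefault(seed, set()).add((proxy, r2))
            if len(fields) >= 5:
                coords[proxy] = (fields[3], int(fields[4]))
    return LDPanel(pairs=pairs, coords=coords, population_tag=population_tag)


# ---------------------------------------------------------------------------
# Evidence datasets (entity -> gene)
# ---------------------------------------------------------------------------

@dataclass
class EvidenceDataset:
    """One entity→gene evidence resource.

    kind 'pchic'/'abc': table columns (chrom, start, end, gene, strength),
    0-based half-open intervals.  kind 'eqtl'/'pqtl': columns (rsid, gene,
    weight) with weight in (0, 1].  kind 'proximity': a gene TSS table with
    columns (gene, chrom, tss, strand).
    """

    kind: str
    table: pd.DataFrame
    label: str = ""


def load_interval_dataset(
    path: str | Path, kind: str, label: str = ""
) -> EvidenceDataset:
    """Load a BED-like interval→gene TSV (chrom, start, end, gene, strength)."""
    if kind not in INTERVAL_KINDS:
        raise KnowledgebaseError(f"interval dataset kind must be in {sorted(INTERVAL_KINDS)}")
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene", "strength"],
        dtype={"chrom": str, "start": int, "end": int, "gene": str, "strength": float},
    )
    if df.empty:
        raise KnowledgebaseError(f"{path}: empty {kind} dataset")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise KnowledgebaseError(f"{path}: row {bad}: start >= end")
    if (df["strength"] < 0).any():
        raise KnowledgebaseError(f"{path}: negative interaction strength")
    if (df["gene"].astype(str).str.len() == 0).any() or df["gene"].isna().any():
        raise KnowledgebaseError(f"{path}: empty gene symbol")
    return EvidenceDataset(kind=kind, table=df, label=label or Path(path).stem)


def load_qtl_dataset(path: str | Path, kind: str, label: str = "") -> EvidenceDataset:
    """Load a SNP→gene QTL TSV (rsid, gene, weight)."""
    if kind not in QTL_KINDS:
        raise KnowledgebaseError(f"QTL dataset kind must be in {sorted(QTL_KINDS)}")
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["rsid", "gene", "weight"],
        dtype={"rsid": str, "gene": str, "weight": float},
    )
    if df.empty:
        raise KnowledgebaseError(f"{path}: empty {kind} dataset")
    if ((df["weight"] <= 0) | (df["weight"] > 1)).any():
        raise KnowledgebaseError(f"{path}: QTL weight outside (0, 1]")
    if (df["gene"].astype(str).str.len() == 0).any() or df["gene"].isna().any():
        raise KnowledgebaseError(f"{path}: empty gene symbol")
    return EvidenceDataset(kind=kind, table=df, label=label or Path(path).stem)


def load_tss_table(path: str | Path) -> EvidenceDataset:
    """Load a gene TSS table (gene, chrom, tss, strand) for proximity linking."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["gene", "chrom", "tss", "strand"],
        dtype={"gene": str, "chrom": str, "tss": int, "strand": str},
    )
    if df.empty:
        raise KnowledgebaseError(f"{path}: empty TSS table")
    if (df["tss"] < 1).any():
        raise KnowledgebaseError(f"{path}: TSS positions must be >= 1 (1-based)")
    if (df["gene"].astype(str).str.len() == 0).any() or df["gene"].isna().any():
        raise KnowledgebaseError(f"{path}: empty gene symbol")
    return EvidenceDataset(kind="proximity", table=df, label=Path(path).stem)
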