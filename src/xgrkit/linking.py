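"""SNP / genomic-region to candidate-gene linking with per-evidence provenance.

Input SNPs are thresholded on significance and expanded through an LD panel;
SNPs and regions are then linked to genes by genomic proximity to a TSS,
by interval overlap against chromatin-interaction (PCHi-C) or enhancer–gene
(ABC) maps, and — for SNPs — by e/pQTL membership.  Per-gene evidence is
combined additively into a raw score and rescaled to a 1–10 display score.

Coordinate conventions: SNP positions are 1-based; regions and evidence
intervals are 0-based half-open (BED).  A SNP at position p occupies the
half-open interval [p-1, p).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .knowledgebase import EvidenceDataset, LDPanel

logger = logging.getLogger("xgrkit")

#: Cap on -log10(p) when converting seed significance into a score factor.
LOG10P_CAP = 10.0


class LinkingError(ValueError):
    pass


@dataclass(frozen=True)
class SNPRecord:
    rsid: str
    chrom: str
    pos: int  # 1-based
    pvalue: float
    seed: str | None = None  # originating input SNP for LD proxies

    @property
    def entity_id(self) -> str:
        return self.rsid

    @property
    def seed_id(self) -> str:
        return self.seed if self.seed is not None else self.rsid


@dataclass(frozen=True)
class GenomicRegion:
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise LinkingError(f"region {self.chrom}:{self.start}-{self.end}: start >= end")

    @property
    def entity_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def seed_id(self) -> str:
        return self.entity_id


@dataclass(frozen=True)
class LinkEvidence:
    entity_id: str
    seed_entity_id: str
    gene_symbol: str
    dataset_kind: str  # proximity | pchic | eqtl | pqtl | abc
    raw_weight: float  # in [0, 1]


@dataclass
class LinkedGene:
    gene_symbol: str
    raw_score: float
    display_score: float  # in [1, 10]
    evidence: list[LinkEvidence] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Input readers
# ---------------------------------------------------------------------------

def read_snp_table(path: str | Path) -> list[SNPRecord]:
    """Read rsid/chrom/pos/pvalue TSV; duplicate rsids keep the smallest p."""
    best: dict[str, SNPRecord] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise LinkingError(
                    f"{path}: line {lineno}: expected 4 fields (rsid, chrom, pos, pvalue)"
                )
            rsid, chrom = fields[0], fields[1]
            pos, p = int(fields[2]), float(fields[3])
            if pos < 1:
                raise LinkingError(f"{path}: line {lineno}: position must be >= 1")
            if not 0.0 < p <= 1.0:
                raise LinkingError(f"{path}: line {lineno}: p-value {p} outside (0, 1]")
            rec = SNPRecord(rsid=rsid, chrom=chrom, pos=pos, pvalue=p)
            if rsid not in best or p < best[rsid].pvalue:
                best[rsid] = rec
    return sorted(best.values(), key=lambda s: (s.chrom, s.pos, s.rsid))


def read_regions_bed(path: str | Path) -> list[GenomicRegion]:
    """Read 3- or 4-column BED (chrom, start, end [, score])."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LinkingError(f"{path}: line {lineno}: expected >=3 BED fields")
            score = float(fields[3]) if len(fields) >= 4 and fields[3] != "." else None
            regions.append(GenomicRegion(
                chrom=fields[0], start=int(fields[1]), end=int(fields[2]), score=score,
            ))
    return regions


# ---------------------------------------------------------------------------
# SNP thresholding and LD expansion
# ---------------------------------------------------------------------------

def filter_and_expand_snps(
    snps: Sequence[SNPRecord],
    panel: LDPanel,
    p_threshold: float = 5e-8,
    r2_min: float = 0.8,
) -> list[SNPRecord]:
    """Keep genome-wide significant SNPs and add their LD proxies.

    Input SNPs with p < ``p_threshold`` are kept as seeds; every panel proxy
    with r² >= ``r2_min`` of a kept seed is added, inheriting the seed's
    p-value and recording the seed's rsid.  A proxy reachable from several
    seeds keeps the most significant one.  Proxies whose coordinates are
    absent from the panel are kept without coordinates (chrom '', pos 1) and
    logged; they can still feed QTL evidence.
    """
    # dedup rsids keeping min p (input invariant)
    dedup: dict[str, SNPRecord] = {}
    for s in snps:
        if s.rsid not in dedup or s.pvalue < dedup[s.rsid].pvalue:
            dedup[s.rsid] = s
    seeds = [s for s in dedup.values() if s.pvalue < p_threshold]
    if not seeds:
        raise LinkingError(
            f"no input SNP passes p < {p_threshold:g}; "
            "relax it with --p-threshold"
        )
    logger.info("SNP filter: %d/%d SNPs pass p < %g", len(seeds), len(dedup), p_threshold)
    out: dict[str, SNPRecord] = {
        s.rsid: SNPRecord(s.rsid, s.chrom, s.pos, s.pvalue, seed=s.rsid) for s in seeds
    }
    n_missing_coords = 0
    for seed in sorted(seeds, key=lambda s: (s.pvalue, s.rsid)):
        for proxy, r2 in panel.proxies(seed.rsid, r2_min):
            if proxy in out and out[proxy].pvalue <= seed.pvalue:
                continue  # already carried by an equal-or-better seed (or is one)
            chrom, pos = panel.coords.get(proxy, ("", 1))
            if proxy not in panel.coords:
                n_missing_coords += 1
            out[proxy] = SNPRecord(proxy, chrom, pos, seed.pvalue, seed=seed.rsid)
    n_proxies = len(out) - len(seeds)
    logger.info("LD expansion: added %d proxies at r2 >= %g", n_proxies, r2_min)
    if n_missing_coords:
        logger.warning("LD expansion: %d proxies lack panel coordinates", n_missing_coords)
    return sorted(out.values(), key=lambda s: (s.chrom, s.pos, s.rsid))


# ---------------------------------------------------------------------------
# Evidence generators
# ---------------------------------------------------------------------------

def _region_tss_distance(start: int, end: int, tss: int) -> int:
    """Distance (bp) from 0-based half-open [start, end) to a 1-based TSS."""
    t0 = tss - 1
    if start <= t0 < end:
        return 0
    return start - t0 if t0 < start else t0 - (end - 1)


def link_by_proximity(
    entities: Sequence[SNPRecord | GenomicRegion],
    tss: EvidenceDataset,
    window: int = 50_000,
) -> list[LinkEvidence]:
    """Link entities to genes whose TSS lies strictly within ``window`` bp.

    Weight decays linearly with distance, 1 − d/W; boundary entities at
    exactly d = W get weight 0 and are not reported.  Entities on
    chromosomes absent from the TSS table yield no evidence (logged).
    """
    if tss.kind != "proximity":
        raise LinkingError("link_by_proximity requires a TSS (proximity) dataset")
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, sub in tss.table.groupby("chrom", sort=True):
        sub = sub.sort_values(["tss", "gene"], kind="stable")
        by_chrom[str(chrom)] = (sub["tss"].to_numpy(), sub["gene"].tolist())
    evidence: list[LinkEvidence] = []
    unknown_chroms: set[str] = set()
    for ent in entities:
        if ent.chrom not in by_chrom:
            if ent.chrom:
                unknown_chroms.add(ent.chrom)
            continue
        positions, genes = by_chrom[ent.chrom]
        if isinstance(ent, SNPRecord):
            lo_q, hi_q = ent.pos - window, ent.pos + window
        else:
            lo_q, hi_q = ent.start + 1 - window, ent.end + window
        i0 = int(np.searchsorted(positions, lo_q, side="left"))
        i1 = int(np.searchsorted(positions, hi_q, side="right"))
        best: dict[str, float] = {}
        for j in range(i0, i1):
            t = int(positions[j])
            if isinstance(ent, SNPRecord):
                d = abs(ent.pos - t)
            else:
                d = _region_tss_distance(ent.start, ent.end, t)
            if d >= window:
                continue
            w = 1.0 - d / window
            g = genes[j]
            if w > best.get(g, 0.0):
                best[g] = w
        for g in sorted(best):
            evidence.append(LinkEvidence(
                entity_id=ent.entity_id, seed_entity_id=ent.seed_id,
                gene_symbol=g, dataset_kind="proximity", raw_weight=best[g],
            ))
    if unknown_chroms:
        logger.info("proximity: %d entity chromosome(s) absent from TSS table: %s",
                    len(unknown_chroms), ",".join(sorted(unknown_chroms)))
    return evidence


def link_by_interval_map(
    entities: Sequence[SNPRecord | GenomicRegion],
    dataset: EvidenceDataset,
) -> list[LinkEvidence]:
    """Link entities overlapping interval→gene evidence (PCHi-C / ABC maps).

    Overlap uses half-open semantics; SNPs are 1-bp intervals [pos−1, pos).
    Raw weight is the interval strength divided by the dataset-wide maximum;
    several intervals hitting the same (entity, gene) keep the maximum.
    """
    if dataset.kind not in ("pchic", "abc"):
        raise LinkingError("interval linking requires a pchic or abc dataset")
    max_strength = float(dataset.table["strength"].max())
    if max_strength <= 0.0:
        raise LinkingError(f"dataset {dataset.label or dataset.kind}: all strengths are zero")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in dataset.table.groupby("chrom", sort=False):
        tree = IntervalTree()
        for start, end, gene, strength in zip(
            sub["start"], sub["end"], sub["gene"], sub["strength"]
        ):
            tree.addi(int(start), int(end), (str(gene), float(strength)))
        trees[str(chrom)] = tree
    evidence: list[LinkEvidence] = []
    for ent in entities:
        tree = trees.get(ent.chrom)
        if tree is None:
            continue
        if isinstance(ent, SNPRecord):
            hits = tree.overlap(ent.pos - 1, ent.pos)
        else:
            hits = tree.overlap(ent.start, ent.end)
        best: dict[str, float] = {}
        for iv in hits:
            gene, strength = iv.data
            w = strength / max_strength
            if w > best.get(gene, -1.0):
                best[gene] = w
        for g in sorted(best):
            evidence.append(LinkEvidence(
                entity_id=ent.entity_id, seed_entity_id=ent.seed_id,
                gene_symbol=g, dataset_kind=dataset.kind, raw_weight=best[g],
            ))
    return evidence


def link_by_qtl(
    snps: Sequence[SNPRecord], dataset: EvidenceDataset
) -> list[LinkEvidence]:
    """Join input/proxy SNPs against an e/pQTL table on rsid."""
    if dataset.kind not in ("eqtl", "pqtl"):
        raise LinkingError("QTL linking requires an eqtl or pqtl dataset")
    rows: dict[str, list[tuple[str, float]]] = {}
    for rsid, gene, w in zip(
        dataset.table["rsid"], dataset.table["gene"], dataset.table["weight"]
    ):
        rows.setdefault(str(rsid), []).append((str(gene), float(w)))
    evidence: list[LinkEvidence] = []
    for snp in snps:
        for gene, w in sorted(rows.get(snp.rsid, ())):
            evidence.append(LinkEvidence(
                entity_id=snp.rsid, seed_entity_id=snp.seed_id,
                gene_symbol=gene, dataset_kind=dataset.kind, raw_weight=w,
            ))
    return evidence


# ---------------------------------------------------------------------------
# Score combination
# ---------------------------------------------------------------------------

def _significance_factor(p: float) -> float:
    return min(-math.log10(p), LOG10P_CAP) / LOG10P_CAP


def combine_scores(
    evidence: Sequence[LinkEvidence],
    snp_pvalues: Mapping[str, float] | None = None,
    pool: str = "sum",
) -> list[LinkedGene]:
    """Aggregate per-evidence contributions into 1–10 gene display scores.

    Each evidence row contributes c = raw_weight × s, where s is the capped
    −log10(p) of the originating seed SNP scaled to [0, 1] (s = 1 for region
    evidence).  ``pool='sum'`` adds all contributions per gene;
    ``pool='max'`` keeps, per (gene, dataset_kind), only the strongest
    contribution before summing across kinds.  Raw scores rescale linearly
    to [1, 10]; when all raw scores tie, every gene displays 10.
    """
    if pool not in ("sum", "max"):
        raise LinkingError(f"unknown pooling mode {pool!r}")
    if not evidence:
        return []
    per_gene: dict[str, list[LinkEvidence]] = {}
    for ev in evidence:
        per_gene.setdefault(ev.gene_symbol, []).append(ev)

    def contribution(ev: LinkEvidence) -> float:
        if snp_pvalues is not None and ev.seed_entity_id in snp_pvalues:
            s = _significance_factor(snp_pvalues[ev.seed_entity_id])
        else:
            s = 1.0
        return ev.raw_weight * s

    raw: dict[str, float] = {}
    for gene, evs in per_gene.items():
        if pool == "sum":
            raw[gene] = sum(contribution(e) for e in evs)
        else:
            by_kind: dict[str, float] = {}
            for e in evs:
                c = contribution(e)
                if c > by_kind.get(e.dataset_kind, -1.0):
                    by_kind[e.dataset_kind] = c
            raw[gene] = sum(by_kind.values())
    lo, hi = min(raw.values()), max(raw.values())
    out: list[LinkedGene] = []
    for gene in sorted(raw, key=lambda g: (-raw[g], g)):
        if hi == lo:
            disp = 10.0
        else:
            disp = 1.0 + 9.0 * (raw[gene] - lo) / (hi - lo)
        evs = sorted(per_gene[gene],
                     key=lambda e: (e.gene_symbol, e.dataset_kind, e.entity_id))
        out.append(LinkedGene(gene_symbol=gene, raw_score=raw[gene],
                              display_score=disp, evidence=evs))
    return out
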