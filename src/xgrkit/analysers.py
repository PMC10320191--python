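"""End-to-end analyser pipelines and their table writers.

Six analysers cover the two analysis families over three input entities:

* EAG / EAS / EAR — ontology enrichment for input genes, or for the genes
  linked from input SNPs / genomic regions;
* SAG / SAS / SAR — gene-subnetwork identification from gene-level summary
  data, or from linked-gene scores derived from SNPs / regions.

Each pipeline composes the library modules (knowledgebase → linking →
enrichment / subnetwork) and writes plain TSV/JSON outputs; the CLI adds no
values of its own.  All randomness flows through the configured seed, and
tables are written with fixed number formatting so a fixed-seed run is
byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import enrichment as enr
from . import knowledgebase as kb
from . import linking as lk
from . import subnetwork as sn

logger = logging.getLogger("xgrkit")

ANALYSERS = ("eag", "eas", "ear", "sag", "sas", "sar")


class ConfigError(ValueError):
    pass


@dataclass
class AnalyserConfig:
    analyser: str
    input_path: str
    out_dir: str
    # knowledgebase paths
    ontology: str | None = None
    dag: str | None = None
    network: str | None = None
    tier: str = "high"
    ld: str | None = None
    no_ld: bool = False
    tss: str | None = None
    pchic: tuple[str, ...] = ()
    eqtl: tuple[str, ...] = ()
    pqtl: tuple[str, ...] = ()
    abc: tuple[str, ...] = ()
    # statistical parameters
    p_threshold: float = 5e-8
    r2_min: float = 0.8
    window: int = 50_000
    min_term: int = 10
    max_term: int = 2000
    min_overlap: int = 3
    universe_mode: str = "annotated"
    universe_file: str | None = None
    no_propagation: bool = False
    fdr_scope: str = "tested"
    pool: str = "sum"
    # subnetwork parameters
    target_n: int = 10
    tol: int | None = None
    permutations: int = 100
    seed: int = 1

    def validate(self) -> None:
        if self.analyser not in ANALYSERS:
            raise ConfigError(f"unknown analyser {self.analyser!r}")
        needs_ontology = self.analyser in ("eag", "eas", "ear")
        if needs_ontology and not self.ontology:
            raise ConfigError(f"{self.analyser} requires --ontology")
        if self.analyser in ("sag", "sas", "sar") and not self.network:
            raise ConfigError(f"{self.analyser} requires --network")
        if self.analyser in ("eas", "sas"):
            if not (self.ld or self.no_ld):
                raise ConfigError(f"{self.analyser} requires --ld or --no-ld")
            if not (self.tss or self.pchic or self.eqtl or self.pqtl):
                raise ConfigError(f"{self.analyser} requires at least one evidence "
                                  "dataset (--tss/--pchic/--eqtl/--pqtl)")
        if self.analyser in ("ear", "sar"):
            if not (self.tss or self.pchic or self.abc):
                raise ConfigError(f"{self.analyser} requires at least one evidence "
                                  "dataset (--tss/--pchic/--abc)")


# ---------------------------------------------------------------------------
# small input readers
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line (first column if tab-separated)."""
    genes: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            genes.append(line.split("\t")[0])
    return genes


def read_gene_summary(path: str | Path) -> dict[str, float]:
    """Gene-level summary TSV (gene, pvalue); duplicates keep the smallest p."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ConfigError(f"{path}: line {lineno}: expected gene<TAB>pvalue")
            gene, p = fields[0], float(fields[1])
            if gene not in out or p < out[gene]:
                out[gene] = p
    return out


# ---------------------------------------------------------------------------
# writers (fixed formatting for byte-reproducibility)
# ---------------------------------------------------------------------------

def _f(x: float) -> str:
    return f"{x:.6g}"


def write_enrichment(results: Sequence[enr.EnrichmentResult], out_dir: Path) -> Path:
    path = out_dir / "enrichment.tsv"
    header = ("term_id\tname\tk\tK\tn\tN\tzscore\todds_ratio\tci_low\tci_high"
              "\tpvalue\tfdr\tmembers")
    lines = [header]
    for r in results:
        lines.append("\t".join([
            r.term_id, r.term_name, str(r.k), str(r.K), str(r.n), str(r.N),
            _f(r.zscore), _f(r.odds_ratio), _f(r.ci_low), _f(r.ci_high),
            _f(r.pvalue), _f(r.fdr), ",".join(r.members),
        ]))
    path.write_text("".join(l + "\n" for l in lines))
    (out_dir / "enrichment.json").write_text(json.dumps([
        {
            "term_id": r.term_id, "name": r.term_name,
            "k": r.k, "K": r.K, "n": r.n, "N": r.N,
            "zscore": float(_f(r.zscore)), "odds_ratio": float(_f(r.odds_ratio)),
            "ci_low": float(_f(r.ci_low)), "ci_high": float(_f(r.ci_high)),
            "pvalue": float(_f(r.pvalue)), "fdr": float(_f(r.fdr)),
            "members": r.members,
        }
        for r in results
    ], indent=2) + "\n")
    return path


def write_linked_genes(linked: Sequence[lk.LinkedGene], out_dir: Path) -> tuple[Path, Path]:
    genes_path = out_dir / "linked_genes.tsv"
    lines = ["gene\traw_score\tdisplay_score\tn_evidence"]
    for g in linked:
        lines.append(f"{g.gene_symbol}\t{_f(g.raw_score)}\t{_f(g.display_score)}"
                     f"\t{len(g.evidence)}")
    genes_path.write_text("".join(l + "\n" for l in lines))
    ev_path = out_dir / "evidence.tsv"
    lines = ["entity\tseed\tgene\tdataset_kind\traw_weight"]
    for g in linked:
        for e in g.evidence:
            lines.append(f"{e.entity_id}\t{e.seed_entity_id}\t{e.gene_symbol}"
                         f"\t{e.dataset_kind}\t{_f(e.raw_weight)}")
    ev_path.write_text("".join(l + "\n" for l in lines))
    return genes_path, ev_path


def write_subnetwork(
    sub: sn.Subnetwork,
    scores: Sequence[sn.NodeScore],
    net: kb.GeneNetwork,
    out_dir: Path,
    significance: dict[str, float] | None = None,
    B: int = 0,
    seed: int | None = None,
) -> Path:
    x = {s.gene_symbol: s.x for s in scores}
    lines = ["gene\tx\tprize\tis_seed\tsignificance"]
    for g in sorted(sub.nodes):
        xi = x.get(g, 0.0)
        prize = xi - sub.lambda_final
        sig = significance.get(g) if significance else None
        lines.append(f"{g}\t{_f(xi)}\t{_f(prize)}\t{int(prize > 0)}"
                     f"\t{_f(sig) if sig is not None else 'NA'}")
    (out_dir / "subnetwork_nodes.tsv").write_text("".join(l + "\n" for l in lines))
    lines = ["gene_a\tgene_b\tweight"]
    for a, b in sorted(sub.edges):
        lines.append(f"{a}\t{b}\t{_f(net.edges[(a, b)])}")
    (out_dir / "subnetwork_edges.tsv").write_text("".join(l + "\n" for l in lines))
    summary = {
        "n_nodes": sub.size,
        "n_edges": len(sub.edges),
        "objective": float(_f(sub.objective)),
        "lambda_final": float(_f(sub.lambda_final)),
        "empirical_p": sub.empirical_p,
        "permutations": B,
        "seed": seed,
    }
    path = out_dir / "subnetwork_summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# shared pipeline pieces
# ---------------------------------------------------------------------------

def _load_ontology(cfg: AnalyserConfig) -> kb.Ontology:
    ont = kb.load_gmt(cfg.ontology)
    if cfg.dag:
        ont = kb.attach_dag(ont, kb.load_dag_tsv(cfg.dag))
    if not cfg.no_propagation:
        ont = kb.propagate_annotations(ont)
    return ont


def _enrich(cfg: AnalyserConfig, genes: Sequence[str], ont: kb.Ontology):
    custom = read_gene_list(cfg.universe_file) if cfg.universe_file else None
    mode = "custom" if custom is not None else cfg.universe_mode
    return enr.run_enrichment(
        genes, ont,
        min_term=cfg.min_term, max_term=cfg.max_term, min_overlap=cfg.min_overlap,
        universe_mode=mode, custom_universe=custom, fdr_scope=cfg.fdr_scope,
    )


def _link_snps(cfg: AnalyserConfig) -> tuple[list[lk.LinkedGene], dict[str, float]]:
    snps = lk.read_snp_table(cfg.input_path)
    panel = kb.load_ld_panel(cfg.ld) if cfg.ld else kb.empty_ld_panel()
    expanded = lk.filter_and_expand_snps(snps, panel, cfg.p_threshold, cfg.r2_min)
    evidence: list[lk.LinkEvidence] = []
    if cfg.tss:
        evidence += lk.link_by_proximity(expanded, kb.load_tss_table(cfg.tss), cfg.window)
    for path in cfg.pchic:
        evidence += lk.link_by_interval_map(expanded, kb.load_interval_dataset(path, "pchic"))
    for path in cfg.eqtl:
        evidence += lk.link_by_qtl(expanded, kb.load_qtl_dataset(path, "eqtl"))
    for path in cfg.pqtl:
        evidence += lk.link_by_qtl(expanded, kb.load_qtl_dataset(path, "pqtl"))
    seed_p: dict[str, float] = {}
    for s in expanded:
        if s.seed_id == s.rsid:
            seed_p[s.rsid] = min(s.pvalue, seed_p.get(s.rsid, 1.0))
    linked = lk.combine_scores(evidence, snp_pvalues=seed_p, pool=cfg.pool)
    logger.info("linking: %d evidence rows -> %d linked genes", len(evidence), len(linked))
    return linked, seed_p


def _link_regions(cfg: AnalyserConfig) -> list[lk.LinkedGene]:
    regions = lk.read_regions_bed(cfg.input_path)
    evidence: list[lk.LinkEvidence] = []
    if cfg.tss:
        evidence += lk.link_by_proximity(regions, kb.load_tss_table(cfg.tss), cfg.window)
    for path in cfg.pchic:
        evidence += lk.link_by_interval_map(regions, kb.load_interval_dataset(path, "pchic"))
    for path in cfg.abc:
        evidence += lk.link_by_interval_map(regions, kb.load_interval_dataset(path, "abc"))
    linked = lk.combine_scores(evidence, snp_pvalues=None, pool=cfg.pool)
    logger.info("linking: %d evidence rows -> %d linked genes", len(evidence), len(linked))
    return linked


def _subnetwork(cfg: AnalyserConfig, scores: list[sn.NodeScore], out_dir: Path,
                significance: dict[str, float] | None = None) -> sn.Subnetwork:
    net = kb.load_network(cfg.network, cfg.tier)
    sub = sn.search_subnetwork(net, scores, cfg.target_n, tol=cfg.tol)
    p, _null = sn.permutation_significance(
        net, scores, sub, B=cfg.permutations, seed=cfg.seed,
        target_n=cfg.target_n, tol=cfg.tol,
    )
    sub.empirical_p = p
    sub.permutations_used = cfg.permutations
    write_subnetwork(sub, scores, net, out_dir, significance=significance,
                     B=cfg.permutations, seed=cfg.seed)
    return sub


# ---------------------------------------------------------------------------
# the six analysers
# ---------------------------------------------------------------------------

def run_eag(cfg: AnalyserConfig) -> list[enr.EnrichmentResult]:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ont = _load_ontology(cfg)
    genes = read_gene_list(cfg.input_path)
    logger.info("EAG: %d input genes", len(genes))
    results = _enrich(cfg, genes, ont)
    write_enrichment(results, out_dir)
    return results


def run_eas(cfg: AnalyserConfig) -> list[enr.EnrichmentResult]:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    linked, _seed_p = _link_snps(cfg)
    write_linked_genes(linked, out_dir)
    ont = _load_ontology(cfg)
    results = _enrich(cfg, [g.gene_symbol for g in linked], ont)
    write_enrichment(results, out_dir)
    return results


def run_ear(cfg: AnalyserConfig) -> list[enr.EnrichmentResult]:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    linked = _link_regions(cfg)
    write_linked_genes(linked, out_dir)
    ont = _load_ontology(cfg)
    results = _enrich(cfg, [g.gene_symbol for g in linked], ont)
    write_enrichment(results, out_dir)
    return results


def run_sag(cfg: AnalyserConfig) -> sn.Subnetwork:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pvalues = read_gene_summary(cfg.input_path)
    scores = sn.scores_from_pvalues(pvalues)
    logger.info("SAG: %d scored genes", len(scores))
    return _subnetwork(cfg, scores, out_dir, significance=pvalues)


def run_sas(cfg: AnalyserConfig) -> sn.Subnetwork:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    linked, _seed_p = _link_snps(cfg)
    write_linked_genes(linked, out_dir)
    scores = [sn.NodeScore(g.gene_symbol, g.display_score) for g in linked]
    sig = {g.gene_symbol: g.display_score for g in linked}
    return _subnetwork(cfg, scores, out_dir, significance=sig)


def run_sar(cfg: AnalyserConfig) -> sn.Subnetwork:
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    linked = _link_regions(cfg)
    write_linked_genes(linked, out_dir)
    scores = [sn.NodeScore(g.gene_symbol, g.display_score) for g in linked]
    sig = {g.gene_symbol: g.display_score for g in linked}
    return _subnetwork(cfg, scores, out_dir, significance=sig)


RUNNERS = {
    "eag": run_eag, "eas": run_eas, "ear": run_ear,
    "sag": run_sag, "sas": run_sas, "sar": run_sar,
}


def run(cfg: AnalyserConfig):
    """Dispatch a configured analyser run."""
    cfg.validate()
    return RUNNERS[cfg.analyser](cfg)
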