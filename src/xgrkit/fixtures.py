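"""Synthetic knowledgebase and input bundles for end-to-end testing.

`generate_fixtures` lays out a toy single-chromosome genome (gene TSSs on a
100 kb grid, about average human gene density), an annotated ontology with
one designated plantable term, a
preferential-attachment gene network carrying a dense planted module, LD
blocks, and proximity/PCHi-C/ABC/e-pQTL evidence maps, together with analyser
inputs in which the planted signal is embedded:

* a gene list enriched for the planted term (30 planted + 30 background genes),
* gene-level p-values peaking on the planted network module,
* SNPs reaching genome-wide significance only near planted-term gene TSSs,
* regions overlapping the enhancer/PCHi-C intervals of those genes.

Everything is written as sorted, fixed-format text so regeneration from the
same seed is byte-identical.  A `manifest.json` records the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np


class FixtureError(ValueError):
    pass


@dataclass
class FixtureBundle:
    out_dir: Path
    files: dict[str, Path]
    manifest: dict

    def path(self, key: str) -> Path:
        return self.files[key]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _write_lines(path: Path, lines: list[str]) -> None:
    path.write_text("".join(line + "\n" for line in lines))


def generate_fixtures(
    out_dir: str | Path,
    seed: int,
    genes: int = 2000,
    terms: int = 50,
    snps: int = 200,
    regions: int = 120,
    ld_block: int = 4,
    module: int = 10,
    network_nodes: int = 100,
    n_signal_genes: int = 20,
) -> FixtureBundle:
    """Write a mutually consistent synthetic knowledgebase + input bundle.

    Sizes default to the study conditions used throughout the test-suite
    benchmarks: a 2,000-gene universe annotated by 50 terms of 20–200 genes,
    a 100-gene network with a 10-gene planted module, 200 input SNPs with
    4-proxy LD blocks, and 120 input regions.
    """
    if module > network_nodes or network_nodes > genes:
        raise FixtureError("inconsistent sizes: require module <= network_nodes <= genes")
    if terms < 6 or genes < 300:
        raise FixtureError("need at least 6 terms and 300 genes")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    files: dict[str, Path] = {}

    # ---- toy genome: genes on a 100 kb TSS grid along one chromosome ------
    # (~1 gene per 100 kb mirrors average human gene density, so the default
    # 50 kb proximity window links a SNP to its own locus, not a whole block)
    gene_ids = [f"G{i:04d}" for i in range(1, genes + 1)]
    tss = {g: 100_000 * (i + 1) for i, g in enumerate(gene_ids)}
    strand = {g: "+" if i % 2 == 0 else "-" for i, g in enumerate(gene_ids)}
    chrom = "chr1"
    chrom_len = 100_000 * (genes + 2)
    files["tss"] = out_dir / "tss.tsv"
    _write_lines(files["tss"], [f"{g}\t{chrom}\t{tss[g]}\t{strand[g]}" for g in gene_ids])

    # ---- ontology: 50 terms, sizes 20-200, one plantable leaf term --------
    term_ids = [f"T{i:03d}" for i in range(1, terms + 1)]
    sizes = rng.integers(20, 201, size=terms)
    planted_idx = 5
    sizes[planted_idx] = max(int(sizes[planted_idx]), 40)
    members: dict[str, list[str]] = {}
    for t, size in zip(term_ids, sizes):
        members[t] = sorted(rng.choice(gene_ids, size=int(size), replace=False))
    planted_term = term_ids[planted_idx]
    planted_genes = members[planted_term]
    files["gmt"] = out_dir / "ontology.gmt"
    _write_lines(files["gmt"],
                 [f"{t}\tsynthetic term {t}\t" + "\t".join(members[t]) for t in term_ids])
    # shallow DAG: terms beyond the first five may point at one of five roots;
    # only index >= 5 terms are children, so the planted term stays a leaf
    dag_lines = []
    for i in range(5, terms):
        if rng.random() < 0.4:
            parent = term_ids[int(rng.integers(0, 5))]
            dag_lines.append(f"{term_ids[i]}\t{parent}")
    files["dag"] = out_dir / "dag.tsv"
    _write_lines(files["dag"], dag_lines)
    annotated = sorted(set().union(*members.values()))

    # ---- network: preferential attachment + dense planted module ----------
    net_genes = sorted(rng.choice(annotated, size=network_nodes, replace=False))
    module_genes = sorted(rng.choice(net_genes, size=module, replace=False))
    background = [g for g in net_genes if g not in set(module_genes)]
    ba = nx.barabasi_albert_graph(len(background), 2, seed=int(rng.integers(2**31)))
    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a < b else (b, a))

    for u, v in ba.edges():
        add(background[u], background[v])
    for i in range(len(module_genes) - 1):          # spanning path keeps it connected
        add(module_genes[i], module_genes[i + 1])
    for i in range(len(module_genes)):
        for j in range(i + 1, len(module_genes)):
            if rng.random() < 0.6:
                add(module_genes[i], module_genes[j])
    for _ in range(2):                              # bridge module into the main graph
        add(module_genes[int(rng.integers(0, module))],
            background[int(rng.integers(0, len(background)))])
    sorted_edges = sorted(edges)
    weights = rng.uniform(0.7, 0.999, size=len(sorted_edges))
    files["network"] = out_dir / "network.tsv"
    _write_lines(files["network"],
                 [f"{a}\t{b}\t{_fmt(w)}" for (a, b), w in zip(sorted_edges, weights)])

    # ---- SNP input: significant SNPs near planted-term gene TSSs ----------
    signal_genes = sorted(rng.choice(planted_genes, size=min(n_signal_genes, len(planted_genes)),
                                     replace=False))
    snp_rows: list[tuple[str, str, int, float]] = []
    for i, g in enumerate(signal_genes):
        pos = tss[g] + int(rng.integers(-10_000, 10_001))
        p = 10.0 ** -float(rng.uniform(9, 12))
        snp_rows.append((f"rsS{i + 1:04d}", chrom, max(pos, 1), p))
    n_bg = max(0, snps - len(signal_genes))
    for i in range(n_bg):
        pos = int(rng.integers(1, chrom_len))
        p = 10.0 ** -float(rng.uniform(0, 6))  # never below the 5e-8 threshold
        snp_rows.append((f"rsB{i + 1:04d}", chrom, pos, p))
    files["snps"] = out_dir / "snps.tsv"
    _write_lines(files["snps"],
                 [f"{r}\t{c}\t{p}\t{_fmt(pv)}" for r, c, p, pv in snp_rows])

    # ---- LD panel: proxy blocks around half of the significant SNPs -------
    ld_lines: list[str] = []
    ld_blocks: dict[str, list[str]] = {}
    for r, c, pos, _pv in snp_rows[: len(signal_genes)]:
        if rng.random() < 0.5:
            proxies = []
            for j in range(ld_block):
                prx = f"rsP{r[3:]}_{j + 1}"
                ppos = max(1, pos + int(rng.integers(-30_000, 30_001)))
                r2 = float(rng.uniform(0.5, 1.0))
                ld_lines.append(f"{r}\t{prx}\t{_fmt(r2)}\t{c}\t{ppos}")
                proxies.append(prx)
            ld_blocks[r] = proxies
    files["ld"] = out_dir / "ld.tsv"
    _write_lines(files["ld"], ld_lines)

    # ---- evidence datasets -------------------------------------------------
    # PCHi-C: promoter-interacting windows; guaranteed for signal genes
    pchic_lines: list[str] = []
    covered_pchic = sorted(set(signal_genes)
                           | {g for g in gene_ids if rng.random() < 0.4})
    for g in covered_pchic:
        start = max(0, tss[g] - 12_000)
        end = tss[g] + 12_000
        pchic_lines.append(f"{chrom}\t{start}\t{end}\t{g}\t{_fmt(rng.uniform(1, 10))}")
    files["pchic"] = out_dir / "pchic.tsv"
    _write_lines(files["pchic"], pchic_lines)
    # ABC enhancer-gene map: downstream enhancer windows
    abc_lines: list[str] = []
    covered_abc = sorted(set(signal_genes)
                         | {g for g in gene_ids if rng.random() < 0.3})
    for g in covered_abc:
        start = tss[g] + 4_000
        end = tss[g] + 9_000
        abc_lines.append(f"{chrom}\t{start}\t{end}\t{g}\t{_fmt(rng.uniform(0.5, 5))}")
    files["abc"] = out_dir / "abc.tsv"
    _write_lines(files["abc"], abc_lines)
    # eQTL: most significant SNPs regulate their gene; plus random background rows
    eqtl_lines: list[str] = []
    for (r, _c, _p, _pv), g in zip(snp_rows[: len(signal_genes)], signal_genes):
        if rng.random() < 0.7:
            eqtl_lines.append(f"{r}\t{g}\t{_fmt(rng.uniform(0.2, 1.0))}")
    for _ in range(100):
        r = snp_rows[int(rng.integers(0, len(snp_rows)))][0]
        g = gene_ids[int(rng.integers(0, genes))]
        eqtl_lines.append(f"{r}\t{g}\t{_fmt(rng.uniform(0.05, 1.0))}")
    files["eqtl"] = out_dir / "eqtl.tsv"
    _write_lines(files["eqtl"], sorted(set(eqtl_lines)))
    # pQTL: a sparse protein-level subset
    pqtl_lines = []
    for (r, _c, _p, _pv), g in zip(snp_rows[: len(signal_genes)], signal_genes):
        if rng.random() < 0.2:
            pqtl_lines.append(f"{r}\t{g}\t{_fmt(rng.uniform(0.2, 1.0))}")
    files["pqtl"] = out_dir / "pqtl.tsv"
    _write_lines(files["pqtl"], sorted(set(pqtl_lines)))

    # ---- analyser inputs ---------------------------------------------------
    pool = [g for g in annotated if g not in set(planted_genes)]
    input_genes = sorted(rng.choice(planted_genes, size=30, replace=False).tolist()
                         + rng.choice(pool, size=30, replace=False).tolist())
    files["genes"] = out_dir / "genes.txt"
    _write_lines(files["genes"], input_genes)

    gene_summary = []
    for g in net_genes:
        if g in set(module_genes):
            p = 10.0 ** -float(rng.uniform(6, 8))
        else:
            p = float(rng.uniform(0.05, 1.0))
        gene_summary.append(f"{g}\t{_fmt(p)}")
    files["gene_summary"] = out_dir / "gene_summary.tsv"
    _write_lines(files["gene_summary"], gene_summary)

    region_rows: list[tuple[str, int, int]] = []
    for g in signal_genes:                       # overlap the ABC enhancer window
        region_rows.append((chrom, tss[g] + 5_000, tss[g] + 7_000))
    for _ in range(max(0, regions - len(signal_genes))):
        start = int(rng.integers(0, chrom_len - 2_000))
        region_rows.append((chrom, start, start + 2_000))
    files["regions"] = out_dir / "regions.bed"
    _write_lines(files["regions"], [f"{c}\t{s}\t{e}" for c, s, e in region_rows])

    manifest = {
        "seed": int(seed),
        "chrom": chrom,
        "planted_term": planted_term,
        "planted_genes": planted_genes,
        "signal_genes": signal_genes,
        "module_genes": module_genes,
        "network_genes": net_genes,
        "ld_blocks": ld_blocks,
        "sizes": {
            "genes": genes, "terms": terms, "snps": snps, "regions": regions,
            "ld_block": ld_block, "module": module, "network_nodes": network_nodes,
        },
        "files": {k: p.name for k, p in files.items()},
    }
    files["manifest"] = out_dir / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return FixtureBundle(out_dir=out_dir, files=files, manifest=manifest)
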