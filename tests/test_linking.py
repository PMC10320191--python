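import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xgrkit.knowledgebase import EvidenceDataset, LDPanel, empty_ld_panel
from xgrkit.linking import (
    GenomicRegion,
    LinkEvidence,
    LinkingError,
    SNPRecord,
    combine_scores,
    filter_and_expand_snps,
    link_by_interval_map,
    link_by_proximity,
    link_by_qtl,
    read_snp_table,
)


def snp(rsid, pos, p=1e-9, chrom="chr1", seed=None):
    return SNPRecord(rsid=rsid, chrom=chrom, pos=pos, pvalue=p, seed=seed)


def tss_dataset(rows):
    df = pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])
    return EvidenceDataset(kind="proximity", table=df)


def interval_dataset(rows, kind="pchic"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "strength"])
    return EvidenceDataset(kind=kind, table=df)


def qtl_dataset(rows, kind="eqtl"):
    df = pd.DataFrame(rows, columns=["rsid", "gene", "weight"])
    return EvidenceDataset(kind=kind, table=df)


class TestSNPInput:
    def test_duplicate_rsids_keep_smallest_p(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("rs1\tchr1\t100\t0.5\nrs1\tchr1\t100\t0.01\n")
        recs = read_snp_table(p)
        assert len(recs) == 1 and recs[0].pvalue == 0.01


class TestFilterAndExpand:
    def test_empty_panel_returns_thresholded_input(self):
        snps = [snp("rs1", 10, 1e-9), snp("rs2", 20, 0.5)]
        out = filter_and_expand_snps(snps, empty_ld_panel())
        assert [s.rsid for s in out] == ["rs1"]
        assert out[0].seed_id == "rs1"

    def test_r2_threshold_and_pvalue_inheritance(self):
        panel = LDPanel(
            pairs={"rs1": {("rs2", 0.9), ("rs3", 0.5)}},
            coords={"rs2": ("chr1", 50), "rs3": ("chr1", 60)},
        )
        out = filter_and_expand_snps([snp("rs1", 10, 1e-9)], panel)
        by_id = {s.rsid: s for s in out}
        assert set(by_id) == {"rs1", "rs2"}
        assert by_id["rs2"].pvalue == 1e-9 and by_id["rs2"].seed_id == "rs1"

    def test_multi_seed_proxy_keeps_most_significant_seed(self):
        panel = LDPanel(
            pairs={"rs1": {("rsP", 0.9)}, "rs2": {("rsP", 0.95)}},
            coords={"rsP": ("chr1", 5)},
        )
        out = filter_and_expand_snps([snp("rs1", 10, 1e-9), snp("rs2", 20, 1e-12)], panel)
        by_id = {s.rsid: s for s in out}
        assert by_id["rsP"].seed_id == "rs2" and by_id["rsP"].pvalue == 1e-12

    def test_no_passing_snp_advises_threshold_flag(self):
        with pytest.raises(LinkingError, match="--p-threshold"):
            filter_and_expand_snps([snp("rs1", 10, 0.5)], empty_ld_panel())

    def test_matches_brute_force_set_construction(self):
        rng = np.random.default_rng(17)
        snps, pairs, coords = [], {}, {}
        for i in range(100):
            p = 10.0 ** -float(rng.uniform(2, 12))
            snps.append(snp(f"rs{i:03d}", int(rng.integers(1, 10**6)), p))
        for i in range(100):
            if rng.random() < 0.5:
                proxies = set()
                for j in range(3):
                    name = f"px{i:03d}_{j}"
                    proxies.add((name, float(rng.uniform(0.3, 1.0))))
                    coords[name] = ("chr1", int(rng.integers(1, 10**6)))
                pairs[f"rs{i:03d}"] = proxies
        panel = LDPanel(pairs=pairs, coords=coords)
        out = {s.rsid for s in filter_and_expand_snps(snps, panel)}
        passing = {s.rsid for s in snps if s.pvalue < 5e-8}
        expected = set(passing)
        for seed_id in passing:
            expected |= {p for p, r2 in pairs.get(seed_id, ()) if r2 >= 0.8}
        assert out == expected

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(23)
        snps = [snp(f"rs{i}", i + 1, 10.0 ** -float(rng.uniform(2, 10))) for i in range(50)]
        pairs = {f"rs{i}": {(f"px{i}", float(rng.uniform()))} for i in range(50)}
        coords = {f"px{i}": ("chr1", 10 * i + 5) for i in range(50)}
        panel = LDPanel(pairs=pairs, coords=coords)
        base = {s.rsid for s in filter_and_expand_snps(snps, panel, 5e-8, 0.8)}
        looser_r2 = {s.rsid for s in filter_and_expand_snps(snps, panel, 5e-8, 0.5)}
        looser_p = {s.rsid for s in filter_and_expand_snps(snps, panel, 1e-4, 0.8)}
        assert base <= looser_r2 and base <= looser_p


class TestProximity:
    TSS = [("GA", "chr1", 100_000, "+"), ("GB", "chr1", 160_000, "-"),
           ("GC", "chr2", 100_000, "+")]

    def test_snp_at_tss_gets_weight_one(self):
        ev = link_by_proximity([snp("rs1", 100_000)], tss_dataset(self.TSS))
        assert [(e.gene_symbol, e.raw_weight) for e in ev] == [("GA", 1.0)]

    def test_snp_at_window_boundary_is_dropped(self):
        ev = link_by_proximity([snp("rs1", 150_000)], tss_dataset(self.TSS), window=50_000)
        # GA at exactly d=W excluded; GB at d=10_000 kept
        assert [(e.gene_symbol, e.raw_weight) for e in ev] == [("GB", 0.8)]

    def test_region_containing_tss_has_distance_zero(self):
        region = GenomicRegion("chr1", 99_000, 101_000)
        ev = link_by_proximity([region], tss_dataset(self.TSS))
        ga = [e for e in ev if e.gene_symbol == "GA"]
        assert ga[0].raw_weight == 1.0

    def test_unknown_chromosome_yields_no_evidence(self):
        ev = link_by_proximity([snp("rs1", 100_000, chrom="chrX")], tss_dataset(self.TSS))
        assert ev == []

    def test_matches_quadratic_scan_oracle(self):
        rng = np.random.default_rng(31)
        genes = [(f"G{i:03d}", f"chr{rng.integers(1, 3)}", int(rng.integers(1, 10**6)), "+")
                 for i in range(100)]
        snps = [snp(f"rs{i:03d}", int(rng.integers(1, 10**6)),
                    chrom=f"chr{rng.integers(1, 3)}") for i in range(200)]
        W = 50_000
        ev = link_by_proximity(snps, tss_dataset(genes), window=W)
        got = {(e.entity_id, e.gene_symbol): e.raw_weight for e in ev}
        expected = {}
        for s in snps:
            for g, chrom, t, _ in genes:
                if chrom != s.chrom:
                    continue
                d = abs(s.pos - t)
                if d < W:
                    w = 1 - d / W
                    key = (s.rsid, g)
                    expected[key] = max(expected.get(key, 0.0), w)
        assert got.keys() == expected.keys()
        for key in expected:
            assert got[key] == pytest.approx(expected[key])


class TestIntervalMap:
    def test_region_identical_to_interval_links_gene(self):
        ds = interval_dataset([("chr1", 100, 200, "GA", 5.0), ("chr1", 0, 50, "GB", 10.0)])
        ev = link_by_interval_map([GenomicRegion("chr1", 100, 200)], ds)
        assert [(e.gene_symbol, e.raw_weight) for e in ev] == [("GA", 0.5)]

    def test_half_open_boundary_no_overlap(self):
        ds = interval_dataset([("chr1", 200, 300, "GA", 1.0)])
        assert link_by_interval_map([GenomicRegion("chr1", 100, 200)], ds) == []

    def test_snp_is_one_bp_interval(self):
        ds = interval_dataset([("chr1", 99, 100, "GA", 1.0)])
        assert len(link_by_interval_map([snp("rs1", 100)], ds)) == 1
        assert link_by_interval_map([snp("rs1", 101)], ds) == []

    def test_all_zero_strengths_is_error(self):
        ds = interval_dataset([("chr1", 0, 10, "GA", 0.0)])
        with pytest.raises(LinkingError, match="zero"):
            link_by_interval_map([GenomicRegion("chr1", 0, 10)], ds)

    def test_matches_quadratic_scan_oracle(self):
        rng = np.random.default_rng(37)
        rows = []
        for i in range(300):
            start = int(rng.integers(0, 10**6))
            rows.append(("chr1", start, start + int(rng.integers(1, 5000)),
                         f"G{rng.integers(50):03d}", float(rng.uniform(0.1, 10))))
        ds = interval_dataset(rows)
        regions = []
        for _ in range(500):
            start = int(rng.integers(0, 10**6))
            regions.append(GenomicRegion("chr1", start, start + int(rng.integers(1, 5000))))
        ev = link_by_interval_map(regions, ds)
        got = {(e.entity_id, e.gene_symbol): e.raw_weight for e in ev}
        max_s = max(r[4] for r in rows)
        expected = {}
        for reg in regions:
            for chrom, s0, e0, g, strength in rows:
                if s0 < reg.end and reg.start < e0:  # half-open intersection
                    key = (reg.entity_id, g)
                    expected[key] = max(expected.get(key, 0.0), strength / max_s)
        assert got.keys() == expected.keys()
        for key in expected:
            assert got[key] == pytest.approx(expected[key])

    def test_shift_invariance_of_evidence(self):
        rows = [("chr1", 100, 300, "GA", 2.0), ("chr1", 400, 600, "GB", 4.0)]
        regions = [GenomicRegion("chr1", 250, 450)]
        base = link_by_interval_map(regions, interval_dataset(rows))
        shift = 10_000
        rows2 = [(c, s + shift, e + shift, g, st_) for c, s, e, g, st_ in rows]
        regions2 = [GenomicRegion("chr1", 250 + shift, 450 + shift)]
        shifted = link_by_interval_map(regions2, interval_dataset(rows2))
        assert [(e.gene_symbol, e.dataset_kind, e.raw_weight) for e in base] == \
               [(e.gene_symbol, e.dataset_kind, e.raw_weight) for e in shifted]


class TestQTL:
    def test_absent_snp_yields_no_evidence(self):
        ds = qtl_dataset([("rs9", "GA", 0.5)])
        assert link_by_qtl([snp("rs1", 10)], ds) == []

    def test_one_snp_two_genes_two_rows(self):
        ds = qtl_dataset([("rs1", "GA", 0.5), ("rs1", "GB", 0.7)])
        ev = link_by_qtl([snp("rs1", 10)], ds)
        assert [(e.gene_symbol, e.raw_weight) for e in ev] == [("GA", 0.5), ("GB", 0.7)]

    def test_matches_relational_join_oracle(self):
        rng = np.random.default_rng(41)
        rows = [(f"rs{rng.integers(40):02d}", f"G{rng.integers(30):02d}",
                 float(rng.uniform(0.05, 1))) for _ in range(150)]
        ds = qtl_dataset(rows)
        snps = [snp(f"rs{i:02d}", i + 1) for i in range(0, 40, 2)]
        ev = link_by_qtl(snps, ds)
        got = sorted((e.entity_id, e.gene_symbol, e.raw_weight) for e in ev)
        rsids = {s.rsid for s in snps}
        expected = sorted((r, g, w) for r, g, w in rows if r in rsids)
        assert got == expected


class TestCombineScores:
    def region_ev(self, gene, weight, entity="chr1:0-10", kind="abc"):
        return LinkEvidence(entity_id=entity, seed_entity_id=entity,
                            gene_symbol=gene, dataset_kind=kind, raw_weight=weight)

    def test_single_gene_displays_ten(self):
        out = combine_scores([self.region_ev("GA", 0.4)])
        assert out[0].display_score == 10.0

    def test_linear_rescale_arithmetic(self):
        evidence = []
        for gene, count in (("GA", 2), ("GB", 4), ("GC", 6)):
            evidence += [self.region_ev(gene, 1.0, entity=f"chr1:{i}-{i+1}")
                         for i in range(count)]
        out = {g.gene_symbol: g.display_score for g in combine_scores(evidence)}
        assert out == pytest.approx({"GA": 1.0, "GB": 5.5, "GC": 10.0})

    def test_tied_raw_scores_all_display_ten(self):
        ev = [self.region_ev("GA", 0.5), self.region_ev("GB", 0.5)]
        out = combine_scores(ev)
        assert all(g.display_score == 10.0 for g in out)

    def test_snp_significance_factor_caps_at_ten(self):
        ev = [LinkEvidence("rs1", "rs1", "GA", "eqtl", 1.0),
              LinkEvidence("rs2", "rs2", "GB", "eqtl", 1.0)]
        out = combine_scores(ev, snp_pvalues={"rs1": 1e-20, "rs2": 1e-5})
        raw = {g.gene_symbol: g.raw_score for g in out}
        assert raw["GA"] == pytest.approx(1.0)   # capped at -log10 p = 10
        assert raw["GB"] == pytest.approx(0.5)

    def test_adding_evidence_never_decreases_raw_scores(self):
        rng = np.random.default_rng(43)
        base = [self.region_ev(f"G{rng.integers(5)}", float(rng.uniform(0.1, 1)),
                               entity=f"chr1:{i}-{i+1}") for i in range(20)]
        extra = [self.region_ev(f"G{rng.integers(5)}", float(rng.uniform(0.1, 1)),
                                entity=f"chr1:{i+100}-{i+101}", kind="pchic")
                 for i in range(10)]
        before = {g.gene_symbol: g.raw_score for g in combine_scores(base)}
        after = {g.gene_symbol: g.raw_score for g in combine_scores(base + extra)}
        for gene, score in before.items():
            assert after[gene] >= score - 1e-12

    def test_max_pooling_keeps_strongest_per_kind(self):
        ev = [self.region_ev("GA", 0.2), self.region_ev("GA", 0.9),
              self.region_ev("GA", 0.5, kind="pchic")]
        summed = combine_scores(ev, pool="sum")[0].raw_score
        pooled = combine_scores(ev, pool="max")[0].raw_score
        assert summed == pytest.approx(1.6)
        assert pooled == pytest.approx(1.4)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(
        st.tuples(st.sampled_from(["GA", "GB", "GC", "GD"]),
                  st.floats(min_value=0.0, max_value=1.0),
                  st.floats(min_value=1e-30, max_value=1.0)),
        min_size=1, max_size=25,
    ))
    def test_display_scores_always_in_1_10(self, rows):
        evidence = [LinkEvidence(f"rs{i}", f"rs{i}", g, "eqtl", w)
                    for i, (g, w, _p) in enumerate(rows)]
        pvals = {f"rs{i}": p for i, (_g, _w, p) in enumerate(rows)}
        for pool in ("sum", "max"):
            for g in combine_scores(evidence, snp_pvalues=pvals, pool=pool):
                assert 1.0 <= g.display_score <= 10.0 + 1e-12
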