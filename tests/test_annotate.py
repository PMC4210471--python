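"""Annotation orchestration, numeric summaries, percentiles and reports."""

import csv

import numpy as np
import pytest

from conftest import random_instance
from varsweep.annotate import (
    JobConfig,
    dedup_unique_loci,
    generate_job_id,
    percentile_rank,
    run_annotation,
    summarize_numeric,
    write_table,
)
from varsweep.errors import ConfigError
from varsweep.feature_store import ValueDistribution
from varsweep.simulate import GenomeModel, simulate_feature, simulate_variants
from varsweep.sweep import brute_force_join
from varsweep.variant_io import VariantList, make_variant, parse_variants


def _dist(values):
    arr = np.sort(np.asarray(values, dtype=np.float64))
    return ValueDistribution(values=arr, n=arr.size)


class TestPercentileRank:
    @pytest.mark.parametrize("dist,m,expected", [
        ([10, 20, 30, 40], 40, 87.5),     # (3 + 0.5) / 4
        ([10, 20, 30, 40], 5, 0.0),       # below all values
        (list(range(1, 101)), 50, 49.5),  # (49 + 0.5) / 100
        ([7, 7, 7], 7, 50.0),             # all tied: mid-rank centre
        ([1, 2, 3], 10, 100.0),
    ])
    def test_mid_rank_formula(self, dist, m, expected):
        assert percentile_rank(m, _dist(dist)) == pytest.approx(expected)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ConfigError):
            percentile_rank(1.0, _dist([]))

    def test_bounds_and_monotonicity(self):
        rng = np.random.default_rng(0)
        dist = _dist(rng.uniform(0, 1, 500))
        prev = -1.0
        for m in np.linspace(-0.5, 1.5, 41):
            p = percentile_rank(float(m), dist)
            assert 0.0 <= p <= 100.0
            assert p >= prev
            prev = p


class TestSummarizeNumeric:
    def test_unweighted_mean(self):
        m, _ = summarize_numeric([2.0, 4.0], _dist([1, 2, 3, 4]))
        assert m == 3.0

    def test_single_region_identity(self):
        m, p = summarize_numeric([7.5], _dist([5.0, 7.5, 10.0]))
        assert m == 7.5
        assert p == pytest.approx(50.0)

    def test_empty_region_set_is_contract_violation(self):
        with pytest.raises(ValueError):
            summarize_numeric([], _dist([1.0]))


class TestDedup:
    def test_empty(self):
        assert dedup_unique_loci(VariantList([]))[0] == 0

    def test_same_locus_twice(self):
        vl = VariantList([make_variant("chr1", 5), make_variant("chr1", 5)])
        n, dd = dedup_unique_loci(vl)
        assert n == 1 and len(dd) == 1

    def test_distinct_chromosomes_not_merged(self):
        vl = VariantList([make_variant("chr1", 5), make_variant("chr2", 5)])
        assert dedup_unique_loci(vl)[0] == 2


class TestJobConfig:
    def test_window_cap(self):
        JobConfig(window=1_000_000)
        with pytest.raises(ConfigError):
            JobConfig(window=1_000_001)
        with pytest.raises(ConfigError):
            JobConfig(window=-1)

    def test_no_stores_selected(self):
        with pytest.raises(ConfigError):
            run_annotation(VariantList([make_variant("chr1", 5)]), [], JobConfig())


class TestRunAnnotation:
    def test_one_variant_two_stores_one_overlapping(self, store_factory):
        vl = parse_variants("chr1 101\n")  # point 100
        numeric = store_factory([("chr1", 90, 110, 5.0), ("chr1", 500, 600, 1.0)],
                                name="signal")
        categorical = store_factory([("chr1", 500, 600, "state")], name="states",
                                    value_type="categorical")
        table = run_annotation(vl, [numeric, categorical], JobConfig(window=0))
        assert len(table.records) == 1
        rec = table.record_for(0, "signal")
        assert rec.count == 1 and rec.mean == 5.0
        assert rec.percentile == pytest.approx(75.0)  # 5.0 among {1.0, 5.0}
        assert table.record_for(0, "states") is None

    def test_disjoint_chromosomes_warn_but_succeed(self, store_factory):
        vl = parse_variants("chr9 50\n")
        st = store_factory([("chr1", 1, 2, 1.0)])
        with pytest.warns(UserWarning, match="no chromosome"):
            table = run_annotation(vl, [st], JobConfig())
        assert len(table.records) == 0

    def test_exact_rows_subset_of_windowed_rows(self, tmp_path):
        gm = GenomeModel.toy(n_chrom=2, length=100_000)
        vl = simulate_variants(150, gm, seed=21)
        from varsweep.feature_store import build_store
        st = build_store(simulate_feature(120, (5, 200), (0.0, 1.0), gm, seed=22),
                         "f", "numeric", tmp_path / "f.vasf")
        t0 = run_annotation(vl, [st], JobConfig(window=0))
        t100 = run_annotation(vl, [st], JobConfig(window=100))
        assert set(t0.records) <= set(t100.records)
        for key, rec in t0.records.items():
            assert rec.count <= t100.records[key].count

    @pytest.mark.parametrize("w", [0, 100])
    def test_end_to_end_matches_brute_force(self, tmp_path, w):
        gm = GenomeModel.toy(n_chrom=2, length=50_000)
        vl = simulate_variants(200, gm, seed=31)
        regions = simulate_feature(150, (2, 120), (0.0, 10.0), gm, seed=32)
        from varsweep.feature_store import build_store
        st = build_store(regions, "f", "numeric", tmp_path / f"f{w}.vasf")
        table = run_annotation(vl, [st], JobConfig(window=w))

        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        regions_sorted = {c: sorted(rs, key=lambda r: (r.start, r.end))
                          for c, rs in by_chrom.items()}
        oracle = brute_force_join(vl.points_by_chrom(), regions_sorted, w)
        # (variant input index -> overlap count) must agree with the oracle
        expected_counts = {}
        for chrom, vi, ri in oracle.pair_set():
            input_i = vl.indices_for(chrom)[vi]
            expected_counts[input_i] = expected_counts.get(input_i, 0) + 1
        got_counts = {i: rec.count for (i, _), rec in table.records.items()}
        assert got_counts == expected_counts
        # means must match a naive recomputation from the oracle's overlaps
        for chrom in regions_sorted:
            for vi in range(len(vl.indices_for(chrom))):
                ris = oracle.regions_for(chrom, vi)
                if not ris:
                    continue
                input_i = vl.indices_for(chrom)[vi]
                naive = np.mean([np.float32(regions_sorted[chrom][ri].value)
                                 for ri in ris])
                assert table.records[(input_i, "f")].mean == pytest.approx(
                    float(naive), rel=1e-6)


class TestWriteTable:
    def _tiny_table(self, store_factory):
        vl = parse_variants("chr1 101\nchr1 901\n")
        st = store_factory([("chr1", 90, 110, 5.0), ("chr1", 95, 105, 7.0)],
                           name="sig")
        return run_annotation(vl, [st], JobConfig())

    def test_tsv_layout_and_blanks(self, store_factory, tmp_path):
        table = self._tiny_table(store_factory)
        path = tmp_path / "out.tsv"
        write_table(table, str(path))
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["chrom", "pos", "ref", "alt",
                                        "sig:count", "sig:value", "sig:percentile"]
        row1 = lines[1].split("\t")
        assert row1[:2] == ["chr1", "101"] and row1[4] == "2" and row1[5] == "6"
        # second variant overlapped nothing: present but blank
        assert lines[2].split("\t")[4:] == ["", "", ""]

    def test_tsv_round_trip(self, store_factory, tmp_path):
        table = self._tiny_table(store_factory)
        path = tmp_path / "out.tsv"
        write_table(table, str(path))
        with open(path, newline="") as f:
            cells = list(csv.reader(f, delimiter="\t"))
        path2 = tmp_path / "out2.tsv"
        with open(path2, "w", newline="") as f:
            csv.writer(f, delimiter="\t", lineterminator="\n").writerows(cells)
        assert path.read_bytes() == path2.read_bytes()

    def test_deterministic_bytes(self, store_factory, tmp_path):
        table = self._tiny_table(store_factory)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_table(table, str(p1))
        write_table(table, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_table_is_header_only(self, store_factory, tmp_path):
        vl = parse_variants("chr5 10\n")
        st = store_factory([("chr5", 100, 200, 1.0)], name="s")
        table = run_annotation(vl, [st], JobConfig())
        path = tmp_path / "e.tsv"
        write_table(table, str(path))
        assert len(path.read_text().splitlines()) == 2  # header + blank row

    def test_spreadsheet_same_cells(self, store_factory, tmp_path):
        from openpyxl import load_workbook

        table = self._tiny_table(store_factory)
        xlsx = tmp_path / "out.xlsx"
        write_table(table, str(xlsx), format="spreadsheet")
        ws = load_workbook(xlsx).active
        assert [c.value for c in ws[1]][:4] == ["chrom", "pos", "ref", "alt"]
        assert ws.cell(row=2, column=5).value == "2"


class TestJobId:
    def test_is_512_bits_of_lowercase_hex(self):
        jid = generate_job_id()
        assert len(jid) == 128
        assert set(jid) <= set("0123456789abcdef")
        assert len(bytes.fromhex(jid)) * 8 == 512

    def test_successive_ids_distinct(self):
        assert generate_job_id() != generate_job_id()
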