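"""Sync parsing, filtering, and frequency conventions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from evoltraj import (
    Locus,
    SampleMeta,
    SnpTable,
    filter_snps,
    frequencies,
    read_snp_table,
    read_sync,
    write_snp_table,
    write_sync,
)
from evoltraj.snp_io import SyncParseError

from conftest import make_table


def _metas(k):
    return [
        SampleMeta(f"s{j}", "A2C", 1, float(j), timepoint=f"t{j}") for j in range(k)
    ]


class TestReadSync:
    def test_global_minor_rule(self, tmp_path):
        # A totals 18 vs T totals 2: T is the global minor even though
        # sample 1 is pure A
        p = tmp_path / "x.sync"
        p.write_text("2L\t5\tA\t10:0:0:0:0:0\t8:2:0:0:0:0\n")
        t = read_sync(p, _metas(2))
        assert t.n_loci == 1
        assert t.loci[0].minor_base == "T" and t.loci[0].major_base == "A"
        assert t.minor[0].tolist() == [0, 2]
        assert t.coverage[0].tolist() == [10, 10]

    def test_tie_breaks_lexicographically(self, tmp_path):
        p = tmp_path / "x.sync"
        p.write_text("2L\t5\tA\t5:0:5:0:0:0\n")  # A=5, C=5
        t = read_sync(p, _metas(1))
        assert t.loci[0].minor_base == "A"

    def test_triallelic_site_dropped(self, tmp_path):
        p = tmp_path / "x.sync"
        p.write_text("2L\t5\tA\t5:0:3:2:0:0\n")
        assert read_sync(p, _metas(1)).n_loci == 0

    def test_monomorphic_site_not_a_snp(self, tmp_path):
        p = tmp_path / "x.sync"
        p.write_text("2L\t5\tA\t9:0:0:0:0:0\n")
        assert read_sync(p, _metas(1)).n_loci == 0

    @pytest.mark.parametrize(
        "line", ["2L\t5\tA\t10:0:0:0", "2L\t5\tA\tx:0:0:0:0:0", "2L\t5\tA"]
    )
    def test_malformed_line_names_location(self, tmp_path, line):
        p = tmp_path / "x.sync"
        p.write_text(line + "\n")
        with pytest.raises(SyncParseError, match="line 1"):
            read_sync(p, _metas(1))

    def test_n_and_deletion_columns_ignored(self, tmp_path):
        p = tmp_path / "x.sync"
        p.write_text("3R\t42\tG\t0:3:0:7:5:2\n")
        t = read_sync(p, _metas(1))
        assert t.coverage[0, 0] == 10  # N=5 and del=2 excluded
        assert t.loci[0].minor_base == "T"


@st.composite
def snp_tables(draw):
    n_loci = draw(st.integers(1, 5))
    n_samples = draw(st.integers(1, 4))
    loci, minor, cov = [], [], []
    bases = ["A", "T", "C", "G"]
    for i in range(n_loci):
        mb, Mb = draw(st.permutations(bases))[:2]
        m = draw(
            st.lists(st.integers(0, 30), min_size=n_samples, max_size=n_samples)
        )
        extra = draw(
            st.lists(st.integers(0, 30), min_size=n_samples, max_size=n_samples)
        )
        c = [mi + mi + e + 1 for mi, e in zip(m, extra)]  # strict minor < major
        if sum(m) == 0:
            m[0], c[0] = 1, max(c[0], 3)  # both alleles must segregate
        loci.append(Locus("2L", i + 1, mb, Mb))
        minor.append(m)
        cov.append(c)
    samples = _metas(n_samples)
    return SnpTable(loci, samples, np.array(minor), np.array(cov))


class TestWriteSync:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(snp_tables())
    def test_round_trip_is_identity_on_matrices(self, tmp_path_factory, table):
        p = tmp_path_factory.mktemp("sync") / "t.sync"
        write_sync(table, p)
        back = read_sync(p, list(table.samples))
        assert back.n_loci == table.n_loci
        np.testing.assert_array_equal(back.minor, table.minor)
        np.testing.assert_array_equal(back.coverage, table.coverage)
        assert [l.minor_base for l in back.loci] == [
            l.minor_base for l in table.loci
        ]

    def test_empty_table_round_trips(self, tmp_path):
        t = SnpTable([], _metas(2), np.zeros((0, 2)), np.zeros((0, 2)))
        p = tmp_path / "e.sync"
        write_sync(t, p)
        assert p.read_text() == ""
        assert read_sync(p, _metas(2)).n_loci == 0

    def test_zero_coverage_cell_round_trips(self, tmp_path):
        t = make_table([[0, 3]], [[0, 10]])
        p = tmp_path / "z.sync"
        write_sync(t, p)
        back = read_sync(p, _metas(2))
        np.testing.assert_array_equal(back.minor, t.minor)
        np.testing.assert_array_equal(back.coverage, t.coverage)


class TestFilterSnps:
    def test_low_coverage_in_one_sample_removes_locus(self):
        t = make_table([[5, 5], [5, 5]], [[19, 100], [100, 100]])
        f = filter_snps(t, min_cov=20, min_maf=0.0)
        assert f.n_loci == 1 and f.loci[0].pos == t.loci[1].pos

    def test_maf_boundary_inclusive(self):
        # pooled 4/200 = 0.02 exactly: retained
        t = make_table([[2, 2], [1, 0]], [[100, 100], [100, 100]])
        f = filter_snps(t, min_cov=20, min_maf=0.02)
        assert f.n_loci == 1 and f.loci[0].pos == t.loci[0].pos

    def test_hand_computed_pooled_frequencies(self):
        # pooled MAFs: 0.01, 0.02, 0.3, 0.5, 0.0 -> 3 loci survive
        minor = [[1, 1], [2, 2], [30, 30], [50, 50], [0, 0]]
        cov = [[100, 100]] * 5
        f = filter_snps(make_table(minor, cov), min_cov=20, min_maf=0.02)
        assert f.n_loci == 3
        assert [l.pos for l in f.loci] == [101, 102, 103]

    def test_idempotent(self):
        t = make_table([[1, 1], [30, 30]], [[100, 100], [100, 100]])
        once = filter_snps(t)
        twice = filter_snps(once)
        np.testing.assert_array_equal(once.minor, twice.minor)
        assert [l.pos for l in once.loci] == [l.pos for l in twice.loci]

    def test_invalid_maf_rejected(self):
        t = make_table([[1]], [[30]])
        with pytest.raises(ValueError, match="min_maf"):
            filter_snps(t, min_maf=0.7)

    def test_chrom4_exclusion(self):
        loci = [Locus("4", 1, "T", "A"), Locus("X", 1, "T", "A")]
        t = SnpTable(loci, _metas(1), [[30], [30]], [[100], [100]])
        f = filter_snps(t, exclude_chrom4=True)
        assert [l.chrom for l in f.loci] == ["X"]


class TestFrequencies:
    @pytest.mark.parametrize(
        "minor,cov,pc,expected",
        [(10, 100, 0, 0.1), (0, 90, 1, 1 / 92), (50, 50, 1, 51 / 52)],
    )
    def test_formula(self, minor, cov, pc, expected):
        t = make_table([[minor]], [[cov]])
        assert frequencies(t, pc)[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_pseudocount_bounds(self):
        t = make_table([[0, 50]], [[90, 50]])
        f0 = frequencies(t, 0)
        assert np.all((f0 >= 0) & (f0 <= 1))
        f1 = frequencies(t, 1)
        assert np.all((f1 > 0) & (f1 < 1))

    def test_zero_coverage_error_lists_site(self):
        t = make_table([[0]], [[0]])
        with pytest.raises(ValueError, match="2L:100"):
            frequencies(t, 0)


class TestTabularDialect:
    def test_round_trip(self, tmp_path, sim_default):
        t = sim_default.table
        write_snp_table(t, tmp_path / "t.tsv", tmp_path / "d.tsv")
        back = read_snp_table(tmp_path / "t.tsv", tmp_path / "d.tsv")
        np.testing.assert_array_equal(back.minor, t.minor)
        np.testing.assert_array_equal(back.coverage, t.coverage)
        assert back.samples == t.samples
        assert back.loci == t.loci


class TestValidation:
    def test_locus_invariants(self):
        with pytest.raises(ValueError):
            Locus("2L", 0, "T", "A")
        with pytest.raises(ValueError):
            Locus("2L", 5, "A", "A")
        with pytest.raises(ValueError):
            Locus("5", 5, "T", "A")

    def test_matrix_bounds(self):
        with pytest.raises(ValueError, match="minor <= coverage"):
            make_table([[5]], [[4]])

    def test_global_minor_rule_after_read(self, tmp_path, sim_default):
        write_sync(sim_default.table, tmp_path / "s.sync")
        t = read_sync(tmp_path / "s.sync", list(sim_default.table.samples))
        assert np.all(
            2 * t.minor.sum(axis=1) <= t.coverage.sum(axis=1)
        )
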