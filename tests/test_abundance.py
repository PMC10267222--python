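"""Unit tests for the abundance container, IO, and filtering rules."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mucocosm import abundance
from mucocosm.abundance import (AbundanceTable, aggregate_taxon,
                                collapse_technical, detect, parse_fraction,
                                prevalence_filter, read_abundance_table,
                                richness, write_abundance_table)


def long_frame(rows):
    cols = ["sample_id", "condition", "passage", "bio_rep", "tech_rep",
            "strain_id", "rel_abundance", "h_coverage"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def small_tsv(tmp_path):
    df = long_frame([
        ["s1", "mucin-carrier", 1, 1, 1, "A", 0.6, 0.9],
        ["s1", "mucin-carrier", 1, 1, 1, "B", 0.4, 0.8],
    ])
    path = tmp_path / "ab.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


class TestIO:
    def test_read_small(self, small_tsv):
        t = read_abundance_table(small_tsv)
        assert t.rel_abundance["s1"].sum() == pytest.approx(1.0)
        assert t.samples.loc["s1", "condition"] == "mucin-carrier"

    def test_negative_abundance_names_row(self, tmp_path):
        df = long_frame([["s1", "x", 1, 1, 1, "A", -0.1, 0.5]])
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="row 2"):
            read_abundance_table(p)

    def test_duplicate_rows_rejected(self, tmp_path):
        df = long_frame([["s1", "x", 1, 1, 1, "A", 0.2, 0.5],
                         ["s1", "x", 1, 1, 1, "A", 0.3, 0.5]])
        p = tmp_path / "dup.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_abundance_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "mis.tsv"
        pd.DataFrame({"sample_id": ["s"], "strain_id": ["A"]}).to_csv(
            p, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_abundance_table(p)

    def test_round_trip(self, small_tsv, tmp_path):
        t = read_abundance_table(small_tsv)
        out = tmp_path / "rt.tsv"
        write_abundance_table(t, out)
        t2 = read_abundance_table(out)
        pd.testing.assert_frame_equal(t.rel_abundance, t2.rel_abundance)
        pd.testing.assert_frame_equal(t.h_coverage, t2.h_coverage)


class TestCollapse:
    def make(self, values_by_tech):
        n_tech = len(values_by_tech)
        ra = pd.DataFrame(
            {f"s{t}": vals for t, vals in enumerate(values_by_tech)},
            index=["A", "B", "C"][: len(values_by_tech[0])])
        meta = pd.DataFrame({
            "condition": "mucin-carrier", "passage": 1, "bio_rep": 1,
            "tech_rep": list(range(n_tech))}, index=ra.columns)
        return AbundanceTable(ra, ra.where(ra == 0, 0.9), meta, sum_slack=10)

    def test_median_of_three(self):
        t = self.make([[0.1], [0.2], [0.9]])
        c = collapse_technical(t)
        assert c.rel_abundance.iloc[0, 0] == pytest.approx(0.2)

    def test_singleton_passthrough(self):
        t = self.make([[0.3, 0.4]])
        c = collapse_technical(t)
        assert np.allclose(c.rel_abundance.iloc[:, 0], [0.3, 0.4])

    def test_hand_medians_three_strains(self):
        vals = [[0.5, 0.2, 0.3], [0.4, 0.35, 0.25], [0.1, 0.5, 0.4]]
        t = self.make(vals)
        c = collapse_technical(t)
        expect = np.median(np.array(vals), axis=0)
        assert np.allclose(c.rel_abundance.iloc[:, 0], expect)

    def test_bio_reps_kept_separate(self):
        ra = pd.DataFrame({"s0": [0.5], "s1": [0.7]}, index=["A"])
        meta = pd.DataFrame({"condition": "c", "passage": 1,
                             "bio_rep": [1, 2], "tech_rep": 1},
                            index=ra.columns)
        t = AbundanceTable(ra, ra * 0 + 0.9, meta)
        assert collapse_technical(t).rel_abundance.shape[1] == 2


class TestDetect:
    def make_single(self, a, h):
        ra = pd.DataFrame({"s": [a]}, index=["A"])
        hc = pd.DataFrame({"s": [h]}, index=["A"])
        meta = pd.DataFrame({"condition": ["x"]}, index=["s"])
        return AbundanceTable(ra, hc, meta)

    @pytest.mark.parametrize("a,h,present", [
        (2e-6, 0.02, True),    # exceeds both cutoffs
        (2e-6, 0.01, False),   # coverage exactly at the bound: absent
        (1e-6, 0.02, False),   # abundance exactly at the bound: absent
        (0.0, 0.5, False),
    ])
    def test_threshold_boundaries(self, a, h, present):
        t = self.make_single(a, h)
        assert bool(detect(t).iloc[0, 0]) is present

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_thresholds(self, ma, mc):
        rng = np.random.default_rng(0)
        ra = pd.DataFrame(rng.uniform(0, 0.5, (5, 3)) / 5,
                          index=list("ABCDE"), columns=["s1", "s2", "s3"])
        hc = pd.DataFrame(rng.uniform(0, 1, (5, 3)),
                          index=ra.index, columns=ra.columns)
        meta = pd.DataFrame({"condition": "x"}, index=ra.columns)
        t = AbundanceTable(ra, hc, meta, sum_slack=10)
        base = detect(t, 0.0, 0.0)
        stricter = detect(t, ma, mc)
        assert not (stricter & ~base).any().any()


class TestRichness:
    def test_all_true(self):
        p = pd.DataFrame(True, index=range(10), columns=list("wxyz"))
        assert (richness(p) == 10).all()

    def test_identity(self):
        p = pd.DataFrame(np.eye(3, dtype=bool), columns=list("abc"))
        assert (richness(p) == 1).all()

    def test_group_medians_reproduce_planted_gap(self):
        # carrier samples detect 20 strains, no-carrier 12
        p = pd.DataFrame(False, index=range(30),
                         columns=[f"c{i}" for i in range(4)] +
                                 [f"n{i}" for i in range(4)])
        p.iloc[:20, :4] = True
        p.iloc[:12, 4:] = True
        groups = {c: ("carrier" if c.startswith("c") else "none")
                  for c in p.columns}
        _, med = richness(p, groups)
        assert med["carrier"] - med["none"] == 8


class TestPrevalence:
    def make(self, n_samples, n_hit, strain="A"):
        vals = [2e-4 if i < n_hit else 0.0 for i in range(n_samples)]
        ra = pd.DataFrame([vals], index=[strain],
                          columns=[f"s{i}" for i in range(n_samples)])
        meta = pd.DataFrame({"condition": "x"}, index=ra.columns)
        return AbundanceTable(ra, ra * 0 + 0.5, meta)

    def test_required_count_at_study_scale(self):
        assert math.ceil(0.10 * 270) == 27
        t = self.make(270, 27)
        assert prevalence_filter(t) == ["A"]

    def test_boundary_26_of_270_excluded(self):
        t = self.make(270, 26)
        assert prevalence_filter(t) == []

    def test_one_of_ten_included(self):
        t = self.make(10, 1)
        assert prevalence_filter(t) == ["A"]

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        ra = pd.DataFrame(rng.uniform(0, 2e-4, (6, 20)) / 6,
                          index=list("ABCDEF"),
                          columns=[f"s{i}" for i in range(20)])
        meta = pd.DataFrame({"condition": "x"}, index=ra.columns)
        t = AbundanceTable(ra, ra * 0 + 0.5, meta)
        kept = prevalence_filter(t)
        shuffled = t.subset_samples(list(rng.permutation(t.sample_ids)))
        assert set(prevalence_filter(shuffled)) == set(kept)

    def test_empty_table_rejected(self):
        ra = pd.DataFrame(index=["A"])
        meta = pd.DataFrame({"condition": []}, index=ra.columns)
        t = AbundanceTable(ra, ra.copy(), meta)
        with pytest.raises(ValueError, match="empty"):
            prevalence_filter(t)


class TestAggregateTaxon:
    def make(self):
        ra = pd.DataFrame({"s1": [0.3, 0.2, 0.5]}, index=["A", "B", "C"])
        meta = pd.DataFrame({"condition": ["x"]}, index=["s1"])
        return AbundanceTable(ra, ra * 0 + 0.5, meta)

    def test_same_phylum_sums(self):
        tax = pd.DataFrame({"phylum": ["P1", "P1", "P2"]},
                           index=["A", "B", "C"])
        agg = aggregate_taxon(self.make(), tax)
        assert agg.rel_abundance.loc["P1", "s1"] == pytest.approx(0.5)

    def test_totals_preserved(self):
        tax = pd.DataFrame({"phylum": ["P1", "P2", "P2"]},
                           index=["A", "B", "C"])
        t = self.make()
        agg = aggregate_taxon(t, tax)
        assert agg.rel_abundance.sum().sum() == pytest.approx(
            t.rel_abundance.sum().sum())

    def test_unmapped_strain_rejected(self):
        tax = pd.DataFrame({"phylum": ["P1"]}, index=["A"])
        with pytest.raises(KeyError, match="B"):
            aggregate_taxon(self.make(), tax)


@pytest.mark.parametrize("raw,expected", [
    ("0.01%", 1e-4), ("1%", 0.01), ("0.0001%", 1e-6), (0.05, 0.05),
    ("0.05", 0.05),
])
def test_parse_fraction(raw, expected):
    assert parse_fraction(raw) == pytest.approx(expected)
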