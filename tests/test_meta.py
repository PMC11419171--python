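import numpy as np
import pandas as pd
import pytest

from endosubtypes.assoc import LocusSet
from endosubtypes.meta import (dl_meta, format_count_percent, meta_analyze,
                               negative_control, significance_summary)


class TestDlMeta:
    def test_zero_heterogeneity_closed_form(self):
        m = dl_meta([0.5, 0.5], [0.1, 0.1])
        assert m.Q == pytest.approx(0.0)
        assert m.tau2 == 0.0
        assert m.beta == pytest.approx(0.5)
        assert m.se == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)

    def test_equals_fixed_effect_when_q_small(self, rng):
        """DL collapses to inverse-variance fixed effect when Q <= k-1."""
        checked = 0
        for _ in range(400):
            k = rng.integers(2, 7)
            ses = rng.uniform(0.05, 0.5, k)
            betas = rng.normal(0.2, 0.02, k)
            w = 1 / ses ** 2
            b_fe = np.sum(w * betas) / np.sum(w)
            Q = np.sum(w * (betas - b_fe) ** 2)
            m = dl_meta(betas, ses)
            if Q <= k - 1:
                checked += 1
                assert m.tau2 == 0.0
                assert m.beta == pytest.approx(b_fe, abs=1e-12)
                assert m.se == pytest.approx(np.sqrt(1 / np.sum(w)), abs=1e-12)
            else:
                assert m.tau2 > 0
                assert m.se >= np.sqrt(1 / np.sum(w)) - 1e-12
        assert checked > 50

    def test_hand_computed_heterogeneous_example(self):
        # two studies with opposite large effects, se = 0.1 each:
        # w = 100 each, b_FE = 0, Q = 100*(1^2+1^2) = 200,
        # tau2 = (200-1)/(200 - 20000/200) = 199/100 = 1.99
        m = dl_meta([1.0, -1.0], [0.1, 0.1])
        assert m.Q == pytest.approx(200.0)
        assert m.tau2 == pytest.approx(1.99)
        assert m.beta == pytest.approx(0.0, abs=1e-12)
        assert m.se == pytest.approx(np.sqrt((0.01 + 1.99) / 2), abs=1e-9)
        assert m.se > 0.1 / np.sqrt(2)  # wider than fixed effect

    def test_single_stratum_passthrough(self):
        m = dl_meta([0.3], [0.15])
        assert (m.beta, m.se, m.k_strata) == (0.3, 0.15, 1)

    def test_all_missing_flagged(self):
        m = dl_meta([np.nan], [np.nan])
        assert m.k_strata == 0 and np.isnan(m.p)

    def test_meta_analyze_groups_and_counts(self):
        df = pd.DataFrame({
            "variant": ["v"] * 2, "phenotype": ["a"] * 2,
            "stratum": ["s1", "s2"], "beta": [0.5, 0.5], "se": [0.1, 0.1],
            "n_case": [10, 20], "n_control": [100, 200],
        })
        out = meta_analyze(df)
        assert len(out) == 1
        assert out.loc[0, "n_case"] == 30
        assert out.loc[0, "k_strata"] == 2


class TestNegativeControl:
    def test_sizes_preserved_per_dataset(self, rng):
        idx = pd.Index([f"s{i}" for i in range(120)])
        labels = pd.Series(rng.integers(0, 5, 120), index=idx)
        datasets = pd.Series(np.r_[["A"] * 60, ["B"] * 60], index=idx)
        perm = negative_control(labels, datasets, seed=1)
        for d in ("A", "B"):
            sel = datasets == d
            assert (np.bincount(perm[sel], minlength=5)
                    == np.bincount(labels[sel], minlength=5)).all()

    def test_seeds_differ_assignments_not_sizes(self, rng):
        idx = pd.Index([f"s{i}" for i in range(200)])
        labels = pd.Series(rng.integers(0, 5, 200), index=idx)
        a = negative_control(labels, seed=1)
        b = negative_control(labels, seed=2)
        assert not (a == b).all()
        assert sorted(a) == sorted(b)


def _locus_set(n=39):
    rows = [(f"locus_{i}", f"rs{i}", f"rs{i}", "1", 100 + i, 1.0, 0)
            for i in range(n)]
    return LocusSet(pd.DataFrame(rows, columns=[
        "locus_label", "lead_rsid", "rsid", "chrom", "pos", "r2", "distance"]))


class TestSignificanceSummary:
    def test_seventeen_of_39_formatting(self):
        ls = _locus_set()
        p = [1e-6] * 17 + [0.5] * 22
        meta = pd.DataFrame({"variant": [f"rs{i}" for i in range(39)],
                             "phenotype": "positive_control", "p": p})
        s = significance_summary(meta, ls).set_index("phenotype")
        row = s.loc["positive_control"]
        assert row["bonferroni_significant"] == 17
        assert row["significant_fraction"] == "17 / 39 (44%)"

    def test_thresholds_strict(self):
        ls = _locus_set(2)
        meta = pd.DataFrame({
            "variant": ["rs0", "rs1"], "phenotype": "positive_control",
            "p": [0.05 / 39, 0.05 / 39 - 1e-12],
        })
        s = significance_summary(meta, ls)
        assert s.loc[0, "bonferroni_significant"] == 1  # only the strict <

    def test_locus_p_is_min_over_tags(self):
        rows = [("L", "lead", "lead", "1", 100, 1.0, 0),
                ("L", "lead", "tag", "1", 200, 0.5, 100)]
        ls = LocusSet(pd.DataFrame(rows, columns=[
            "locus_label", "lead_rsid", "rsid", "chrom", "pos", "r2",
            "distance"]))
        meta = pd.DataFrame({"variant": ["lead", "tag"],
                             "phenotype": "positive_control",
                             "p": [0.5, 1e-9]})
        s = significance_summary(meta, ls, bonferroni_n=39)
        assert s.loc[0, "genome_wide_significant"] == 1

    def test_stronger_than_baseline_counts(self):
        ls = _locus_set(3)
        meta = pd.DataFrame({
            "variant": ["rs0", "rs1", "rs2"] * 2,
            "phenotype": ["positive_control"] * 3 + ["cluster_1"] * 3,
            "p": [0.01, 0.2, 0.3, 0.001, 0.5, 0.1],
        })
        s = significance_summary(meta, ls).set_index("phenotype")
        assert s.loc["cluster_1", "stronger_than_positive_control"] == 2

    def test_missing_positive_control_warns(self):
        ls = _locus_set(2)
        meta = pd.DataFrame({"variant": ["rs0", "rs1"], "phenotype": "c",
                             "p": [0.5, 0.5]})
        with pytest.warns(UserWarning, match="positive control"):
            s = significance_summary(meta, ls)
        assert np.isnan(s.loc[0, "stronger_than_positive_control"])

    def test_empty_results_zero_counts(self):
        ls = _locus_set(2)
        meta = pd.DataFrame({"variant": ["rs0"],
                             "phenotype": "positive_control",
                             "p": [np.nan]})
        s = significance_summary(meta, ls)
        assert s.loc[0, "loci_tested"] == 0
        assert s.loc[0, "bonferroni_significant"] == 0


class TestReportFormatting:
    @pytest.mark.parametrize("count,total,digits,expected", [
        (441, 4078, 1, "441 (10.8%)"),
        (686, 4078, 1, "686 (16.8%)"),
        (1151, 4078, 1, "1,151 (28.2%)"),
        (796, 4078, 1, "796 (19.5%)"),
        (1004, 4078, 1, "1,004 (24.6%)"),
    ])
    def test_count_percent_cells(self, count, total, digits, expected):
        assert format_count_percent(count, total, digits) == expected
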