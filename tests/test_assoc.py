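import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endosubtypes.assoc import (GenotypeMatrix, LogisticNull, compute_pcs,
                                ld_expand, logistic_assoc,
                                run_stratified_assoc)


def _gm(dosages, chrom=None, pos=None, rsids=None):
    dosages = np.asarray(dosages, float)
    n, v = dosages.shape
    rsids = rsids or [f"v{j}" for j in range(v)]
    variants = pd.DataFrame({
        "rsid": rsids,
        "chrom": chrom or ["1"] * v,
        "pos": pos or list(range(1, v + 1)),
        "ref": "A", "alt": "G", "locus_label": rsids,
    })
    return GenotypeMatrix(np.array([f"s{i}" for i in range(n)], object),
                          variants, dosages)


class TestComputePcs:
    def test_pc1_separates_divergent_ancestries(self, rng):
        n = 200
        maf_a = rng.uniform(0.05, 0.2, 100)
        maf_b = maf_a + 0.3  # systematic frequency divergence
        G = np.vstack([rng.binomial(2, maf_a, (n, 100)),
                       rng.binomial(2, maf_b, (n, 100))]).astype(float)
        pcs = compute_pcs(_gm(G), 4)
        group = np.r_[np.zeros(n), np.ones(n)]
        r = np.corrcoef(pcs[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_orthogonal_and_deterministic_for_duplicates(self, rng):
        G = rng.binomial(2, 0.3, (50, 10)).astype(float)
        G[10] = G[11]  # duplicated subjects
        pcs = compute_pcs(_gm(G), 4)
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(gram)).max()
        np.testing.assert_allclose(pcs[10], pcs[11], atol=1e-10)

    def test_too_few_variants_rejected(self, rng):
        G = rng.binomial(2, 0.3, (30, 2)).astype(float)
        with pytest.raises(ValueError, match="non-monomorphic"):
            compute_pcs(_gm(G), 4)


class TestLdExpand:
    def test_duplicate_in_perfect_ld_included(self, rng):
        g = rng.binomial(2, 0.3, 200).astype(float)
        G = np.c_[g, g, rng.binomial(2, 0.3, 200)]
        gm = _gm(G, pos=[100, 200, 300])
        ls = ld_expand(gm, ["v0"], window=500_000, r2_min=0.1)
        members = ls.members("v0")
        assert "v1" in members  # r2 = 1
        row = ls.table[ls.table["rsid"] == "v1"].iloc[0]
        assert row["r2"] == pytest.approx(1.0)

    def test_independent_variant_excluded(self, rng):
        g = rng.binomial(2, 0.3, 5000).astype(float)
        indep = rng.binomial(2, 0.3, 5000).astype(float)
        gm = _gm(np.c_[g, indep], pos=[100, 200])
        ls = ld_expand(gm, ["v0"])
        assert ls.members("v0") == ["v0"]  # r2 ~ 0 < 0.1

    def test_window_boundary_strict(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        gm = _gm(np.c_[g, g, g], pos=[1, 1 + 500_000, 1 + 499_999])
        ls = ld_expand(gm, ["v0"], window=500_000)
        members = ls.members("v0")
        assert "v2" in members       # distance 499,999 < window
        assert "v1" not in members   # distance 500,000 excluded (strict <)

    def test_other_chromosome_excluded(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        gm = _gm(np.c_[g, g], chrom=["1", "2"], pos=[100, 200])
        assert ld_expand(gm, ["v0"]).members("v0") == ["v0"]

    def test_r2_allele_flip_invariant(self, rng):
        g = rng.binomial(2, 0.3, 300).astype(float)
        noisy = g.copy()
        noisy[:30] = rng.binomial(2, 0.3, 30)
        gm1 = _gm(np.c_[g, noisy], pos=[100, 200])
        gm2 = _gm(np.c_[g, 2 - noisy], pos=[100, 200])
        r2_1 = ld_expand(gm1, ["v0"]).table.set_index("rsid").loc["v1", "r2"]
        r2_2 = ld_expand(gm2, ["v0"]).table.set_index("rsid").loc["v1", "r2"]
        assert r2_1 == pytest.approx(r2_2, abs=1e-12)

    def test_monomorphic_lead_warns_lead_only(self, rng):
        G = np.c_[np.zeros(100), rng.binomial(2, 0.3, 100)].astype(float)
        gm = _gm(G, pos=[100, 200])
        with pytest.warns(UserWarning, match="monomorphic"):
            ls = ld_expand(gm, ["v0"])
        assert ls.members("v0") == ["v0"]


class TestLogisticAssoc:
    def test_null_uniform_p(self, rng):
        n_case, n_ctrl = 400, 1200
        y = np.r_[np.ones(n_case), np.zeros(n_ctrl)]
        age = rng.normal(50, 10, len(y))
        null = LogisticNull(y, age[:, None])
        G = rng.binomial(2, 0.3, (len(y), 500)).astype(float)
        U, V = null.score_test(G)
        p = stats.chi2.sf(U ** 2 / V, 1)
        assert 0.02 < (p < 0.05).mean() < 0.09
        # score-test p matches the likelihood-ratio p at these sizes
        import statsmodels.api as sm
        j = int(np.argmin(p))
        X0 = np.c_[np.ones(len(y)), age]
        ll0 = sm.Logit(y, X0).fit(disp=0).llf
        ll1 = sm.Logit(y, np.c_[X0, G[:, j]]).fit(disp=0).llf
        p_lrt = stats.chi2.sf(2 * (ll1 - ll0), 1)
        assert p[j] == pytest.approx(p_lrt, rel=0.15)

    def test_effect_recovery(self, rng):
        y = np.r_[np.ones(800), np.zeros(2400)]
        w = np.array([0.49, 0.42 * 1.5, 0.09 * 2.25])
        w /= w.sum()
        betas = []
        for _ in range(20):
            g = np.r_[rng.choice([0, 1, 2], 800, p=w),
                      rng.binomial(2, 0.3, 2400)].astype(float)
            betas.append(logistic_assoc(g, y, beta_method="full")["beta"])
        assert np.median(betas) == pytest.approx(np.log(1.5), rel=0.2)

    def test_constant_dosage_skipped(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        res = logistic_assoc(np.ones(20), y)
        assert "monomorphic" in res["note"]
        assert np.isnan(res["p"])

    def test_spa_close_to_normal_when_balanced(self, rng):
        y = np.r_[np.ones(500), np.zeros(500)]
        g = rng.binomial(2, 0.3, 1000).astype(float)
        res_n = logistic_assoc(g, y)
        res_s = logistic_assoc(g, y, spa=True)
        assert res_s["p"] == pytest.approx(res_n["p"], rel=0.2)


class TestRunStratified:
    def test_bookkeeping_counts(self, planted_cohort):
        b = planted_cohort
        sub = b.truth.subtype
        phenos = {f"cluster_{k}": sub.index[sub == k].tolist()
                  for k in range(5)}
        phenos["positive_control"] = sub.index[sub >= 0].tolist()
        controls = sub.index[sub < 0].tolist()
        res = run_stratified_assoc(b.genotypes, b.subjects, phenos, controls,
                                   test_rsids=["rs0"])
        # per stratum, cluster case counts partition the positive control
        for stratum, part in res.groupby("stratum"):
            p = part.set_index("phenotype")
            total = sum(p.loc[f"cluster_{k}", "n_case"] for k in range(5)
                        if f"cluster_{k}" in p.index)
            assert total == p.loc["positive_control", "n_case"]
        # <= phenotypes x strata rows for the single variant
        assert len(res) <= 6 * 2

    def test_subtype_specific_signal_strongest_in_own_cluster(self, planted_cohort):
        b = planted_cohort
        sub = b.truth.subtype
        phenos = {f"cluster_{k}": sub.index[sub == k].tolist() for k in range(5)}
        res = run_stratified_assoc(b.genotypes, b.subjects, phenos,
                                   sub.index[sub < 0].tolist(),
                                   test_rsids=["rs1"])
        from endosubtypes.meta import meta_analyze
        m = meta_analyze(res).set_index("phenotype")["p"]
        assert m.idxmin() == "cluster_0"

    def test_empty_phenotype_rejected(self, planted_cohort):
        b = planted_cohort
        sub = b.truth.subtype
        with pytest.raises(ValueError, match="no cases"):
            run_stratified_assoc(b.genotypes, b.subjects, {"empty": []},
                                 sub.index[sub < 0].tolist())
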