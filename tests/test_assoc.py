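"""QC, LD tagging, regression, SKAT, thresholds, power and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hearvar.assoc import (
    GenotypeMatrix,
    assoc_additive,
    bonferroni,
    enrich_fisher_fdr,
    fit_interaction,
    greedy_tag,
    hwe_chi2_p,
    ld_r2,
    power_variance_explained,
    skat_test,
    snp_qc,
)


def make_gm(dosages, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{j}" for j in range(m)],
            "chrom": ["chr1"] * m,
            "pos": pos or [(j + 1) * 100 for j in range(m)],
        }
    )
    return GenotypeMatrix([f"i{k}" for k in range(n)], snps, dosages)


class TestHweAndQc:
    def test_perfect_hwe_retained(self):
        # genotype counts (25, 50, 25): chi-square 0
        col = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        assert hwe_chi2_p(col) == pytest.approx(1.0)

    def test_hand_computed_chi_square(self):
        # counts (30, 40, 30) at n=100: expected (25, 50, 25), chi2 = 4.0
        col = np.repeat([0.0, 1.0, 2.0], [30, 40, 30])
        assert hwe_chi2_p(col) == pytest.approx(sps.chi2.sf(4.0, 1))
        assert hwe_chi2_p(col) == pytest.approx(0.0455, abs=2e-4)

    def test_low_maf_removed_and_hwe_kept_at_5e7(self):
        rng = np.random.default_rng(0)
        n = 200
        common = rng.binomial(2, 0.3, (n, 1)).astype(float)
        rare = rng.binomial(2, 0.04, (n, 1)).astype(float)
        hwe_dev = np.repeat([0.0, 1.0, 2.0], [60, 80, 60])[:, None]  # chi2=8, p~0.005 >> 5e-7
        gm = make_gm(np.hstack([common, rare, hwe_dev]))
        out = snp_qc(gm)
        kept = set(out.snps["snp_id"])
        assert "rs1" not in kept  # MAF < 5%
        assert "rs2" in kept  # HWE deviation above the 5e-7 bar survives
        assert "rs0" in kept

    def test_high_missingness_removed(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.3, (200, 20)).astype(float)
        g[:30, 1] = np.nan  # 15% missing SNP; per-sample missingness only 5%
        out = snp_qc(make_gm(g))
        kept = set(out.snps["snp_id"])
        assert "rs1" not in kept and "rs0" in kept

    def test_empty_result_is_error(self):
        g = np.tile([0.0, 0.0, 1.0], (30, 1)).T.reshape(30, 3)[:, :1]  # near-monomorphic
        gm = make_gm(np.zeros((30, 1)))
        with pytest.raises(ValueError, match="no SNPs survive"):
            snp_qc(gm)


class TestLd:
    def test_duplicate_snp(self):
        x = np.array([0.0, 1, 2, 0, 1, 2])
        assert ld_r2(x, x) == pytest.approx(1.0)

    def test_hand_pearson(self):
        x = np.array([0.0, 1, 2, 0])
        y = np.array([0.0, 1, 2, 2])
        assert ld_r2(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_zero_variance_undefined(self):
        assert np.isnan(ld_r2(np.ones(5), np.array([0.0, 1, 2, 1, 0])))

    def test_null_expectation_one_over_n(self):
        rng = np.random.default_rng(7)
        n, reps = 10_000, 200
        vals = []
        for _ in range(reps):
            a = rng.binomial(2, 0.4, n).astype(float)
            b = rng.binomial(2, 0.4, n).astype(float)
            vals.append(ld_r2(a, b))
        # E[r^2] under independence ~ 1/n; MC error ~ (1/n)/sqrt(reps)
        assert np.mean(vals) == pytest.approx(1 / n, abs=4e-5)


class TestGreedyTag:
    def test_all_independent_all_tags(self):
        rng = np.random.default_rng(3)
        gm = make_gm(rng.binomial(2, 0.4, (500, 5)).astype(float))
        assert greedy_tag(gm) == [0, 1, 2, 3, 4]

    def test_duplicate_pair_one_tag(self):
        rng = np.random.default_rng(4)
        a = rng.binomial(2, 0.4, 200).astype(float)
        gm = make_gm(np.column_stack([a, a]))
        assert len(greedy_tag(gm)) == 1

    def test_chain_covered_by_middle_snp(self):
        # r2(1,2) and r2(2,3) high, r2(1,3) lower: the hub tags everything
        rng = np.random.default_rng(5)
        b = rng.binomial(2, 0.5, 4000).astype(float)
        flip = rng.random(4000) < 0.05
        a = np.where(flip, 2 - b, b)
        flip2 = rng.random(4000) < 0.05
        c = np.where(flip2, 2 - b, b)
        gm = make_gm(np.column_stack([a, b, c]))
        r12, r23, r13 = ld_r2(a, b), ld_r2(b, c), ld_r2(a, c)
        assert r12 >= 0.8 and r23 >= 0.8 and r13 < 0.8
        assert greedy_tag(gm) == [1]

    def test_coverage_property_post_hoc(self):
        rng = np.random.default_rng(6)
        base = rng.binomial(2, 0.4, (300, 4)).astype(float)
        extra = base[:, [0, 2]].copy()
        noise = rng.random((300, 2)) < 0.03
        extra = np.where(noise, 2 - extra, extra)
        gm = make_gm(np.hstack([base, extra]))
        tags = greedy_tag(gm)
        m = gm.dosages.shape[1]
        for j in range(m):
            if j in tags:
                continue
            assert any(ld_r2(gm.dosages[:, j], gm.dosages[:, t]) >= 0.8 for t in tags)
        for t1 in tags:
            for t2 in tags:
                if t1 < t2:
                    assert ld_r2(gm.dosages[:, t1], gm.dosages[:, t2]) < 0.8


class TestAdditiveAssociation:
    def test_noiseless_linear_exact(self):
        g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1, 2, 1, 0, 2])
        y = 2 + 3 * g
        res = assoc_additive(y, g)
        assert res.beta == pytest.approx(3.0, abs=1e-10)

    def test_constant_dosage_error(self):
        with pytest.raises(ValueError, match="constant dosage"):
            assoc_additive(np.arange(12, dtype=float), np.ones(12))

    def test_logistic_recovers_direction(self):
        rng = np.random.default_rng(8)
        n = 2000
        g = rng.binomial(2, 0.3, n).astype(float)
        p = 1 / (1 + np.exp(-(-1 + 0.8 * g)))
        y = (rng.random(n) < p).astype(float)
        res = assoc_additive(y, g, trait_kind="binary")
        assert res.beta == pytest.approx(0.8, abs=0.25)
        assert res.p < 1e-6

    def test_perfect_separation_flagged(self):
        g = np.repeat([0.0, 2.0], 10)
        y = np.repeat([0.0, 1.0], 10)
        res = assoc_additive(y, g, trait_kind="binary")
        assert res.flagged == "perfect_separation"
        assert np.isnan(res.p)


class TestInteraction:
    def test_noiseless_exact_coefficients(self):
        rng = np.random.default_rng(9)
        n = 50
        g = rng.binomial(2, 0.4, n).astype(float)
        c = rng.normal(10, 3, n)
        y = 1 + 0.5 * g + 0.2 * c + 0.3 * g * c
        fit = fit_interaction(y, g, c)
        assert (fit.b0, fit.b1, fit.b2, fit.b3) == pytest.approx((1, 0.5, 0.2, 0.3), abs=1e-9)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(10)
        n = 300
        g = rng.binomial(2, 0.3, n).astype(float)
        c = rng.normal(5, 2, n)
        y = 2 - 0.4 * g + 0.1 * c + 0.25 * g * c + rng.standard_normal(n)
        fit = fit_interaction(y, g, c)
        X = np.column_stack([np.ones(n), g, c, g * c])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert (fit.b0, fit.b1, fit.b2, fit.b3) == pytest.approx(tuple(beta), abs=1e-8)

    def test_collinear_design_named(self):
        n = 40
        g = np.tile([0.0, 1, 2, 1], 10)
        c = np.zeros(n)  # zero-variance covariate: COV1 collinear with intercept
        y = np.arange(n, dtype=float)
        with pytest.raises(ValueError, match="collinear"):
            fit_interaction(y, g, c)

    def test_type_i_error_calibrated_small(self):
        rng = np.random.default_rng(11)
        n, reps = 400, 400
        rejections = 0
        for _ in range(reps):
            g = rng.binomial(2, 0.3, n).astype(float)
            c = rng.normal(10, 3, n)
            y = 1 + 0.5 * g + 0.2 * c + rng.standard_normal(n)  # b3 = 0
            if fit_interaction(y, g, c).p_interaction < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


class TestSkat:
    def test_single_variant_reduces_to_score_test(self):
        rng = np.random.default_rng(12)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.15 * g + rng.standard_normal(n)
        res = skat_test(y, g[:, None], weights="flat")
        # independent oracle: score test of the slope from first principles
        r = y - y.mean()
        gc = g - g.mean()
        sigma2 = float(r @ r) / (n - 1)
        stat = float(g @ r) ** 2 / (sigma2 * float(gc @ gc))
        p_score = sps.chi2.sf(stat, df=1)
        assert res.p == pytest.approx(p_score, abs=1e-3)
        assert res.method == "liu"

    def test_with_covariates_null_model(self):
        rng = np.random.default_rng(13)
        n = 400
        cov = rng.normal(0, 1, n)
        y = 2 + 1.5 * cov + rng.standard_normal(n)
        G = rng.binomial(2, 0.1, (n, 10)).astype(float)
        res = skat_test(y, G, covariates=cov)
        assert 0 < res.p <= 1
        assert res.n_variants == 10

    def test_all_zero_genotypes_error(self):
        with pytest.raises(ValueError, match="polymorphic"):
            skat_test(np.random.default_rng(0).standard_normal(100), np.zeros((100, 5)))

    def test_small_sample_uses_permutation(self):
        rng = np.random.default_rng(14)
        n = 30
        G = rng.binomial(2, 0.3, (n, 4)).astype(float)
        y = rng.standard_normal(n)
        res = skat_test(y, G, seed=5, n_perm=500)
        assert res.method == "permutation"
        assert 0 < res.p <= 1
        # seeded: reproducible
        assert skat_test(y, G, seed=5, n_perm=500).p == res.p

    def test_maf_subsetting(self):
        rng = np.random.default_rng(15)
        n = 600
        rare = rng.binomial(2, 0.005, (n, 5)).astype(float)
        common = rng.binomial(2, 0.3, (n, 5)).astype(float)
        G = np.hstack([rare, common])
        y = rng.standard_normal(n)
        res_rare = skat_test(y, G, maf_range=(0.0, 0.01))
        res_common = skat_test(y, G, maf_range=(0.05, 0.5))
        assert res_rare.n_variants <= 5
        assert res_common.n_variants == 5

    def test_detects_planted_burden(self):
        rng = np.random.default_rng(16)
        n = 800
        G = rng.binomial(2, 0.05, (n, 15)).astype(float)
        y = G[:, :8].sum(axis=1) * 0.5 + rng.standard_normal(n)
        assert skat_test(y, G).p < 1e-4


class TestBonferroni:
    @pytest.mark.parametrize(
        "n_tests,printed,half_ulp",
        [
            (635, 7.87e-5, 5e-8),  # 127 SNPs x 5 phenotypes
            (15, 0.0033, 5e-5),  # 5 traits x 3 variant subsets
            (36, 0.0014, 5e-5),  # 12 SNPs x 3 outcomes
            (488205, 1.02e-7, 5e-10),  # genome-wide interaction scan
        ],
    )
    def test_published_thresholds(self, n_tests, printed, half_ulp):
        """alpha / n_tests agrees with each printed threshold to its printed
        precision."""
        assert abs(bonferroni(n_tests) - printed) <= half_ulp

    def test_monotone_and_identity(self):
        assert bonferroni(1) == 0.05
        vals = [bonferroni(k) for k in range(1, 50)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            bonferroni(0)


class TestPower:
    def test_limits(self):
        assert power_variance_explained(100, 0.1, 1.0) == pytest.approx(1.0)
        assert power_variance_explained(100, 0.0, 0.05) == 0.05

    def test_monotone_in_n(self):
        p1 = power_variance_explained(500, 0.01, 1e-4)
        p2 = power_variance_explained(5000, 0.01, 1e-4)
        assert p2 > p1

    def test_analytic_matches_simulation(self):
        analytic = power_variance_explained(500, 0.02, 0.01)
        sim = power_variance_explained(500, 0.02, 0.01, method="simulation", seed=1, n_reps=3000)
        assert sim == pytest.approx(analytic, abs=0.025)


class TestEnrichment:
    def test_hypergeometric_tail_equality(self):
        # 2x2 (8,2; 10,80): one-sided Fisher equals the hypergeometric tail
        hits = {f"h{i}" for i in range(10)}
        others = {f"o{i}" for i in range(90)}
        bg = hits | others
        term = {f"h{i}" for i in range(8)} | {f"o{i}" for i in range(10)}
        df = enrich_fisher_fdr(hits, bg, {"T": term})
        expected = sps.hypergeom.sf(7, 100, 18, 10)
        assert df.loc[0, "p"] == pytest.approx(expected)
        assert df.loc[0, "q"] == pytest.approx(expected)  # single term: q = p

    def test_exact_hit_set_is_most_enriched(self):
        hits = {f"h{i}" for i in range(6)}
        bg = hits | {f"o{i}" for i in range(200)}
        terms = {
            "exact": set(hits),
            "diffuse": {f"o{i}" for i in range(50)} | {"h0"},
            "unrelated": {f"o{i}" for i in range(50, 90)},
        }
        df = enrich_fisher_fdr(hits, bg, terms)
        assert df.loc[0, "term"] == "exact"

    def test_bh_monotone_in_p(self):
        rng = np.random.default_rng(17)
        bg = {f"g{i}" for i in range(300)}
        hits = set(rng.choice(sorted(bg), 30, replace=False))
        terms = {
            f"t{k}": set(rng.choice(sorted(bg), rng.integers(10, 60), replace=False))
            for k in range(12)
        }
        df = enrich_fisher_fdr(hits, bg, terms)
        assert (df["p"].diff().dropna() >= -1e-12).all()
        assert (df["q"].diff().dropna() >= -1e-12).all()

    def test_hits_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            enrich_fisher_fdr({"x"}, {"y"}, {"t": {"y"}})
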