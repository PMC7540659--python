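import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cagewas.mixed_models import (
    BivariateModel,
    fit_bivariate,
    group_genotype_regression,
    lrt_covariance,
    scan_bivariate,
    scan_model1,
    variance_explained,
)
from cagewas.mixed_models.emreml import ResidualGroup, em_reml
from cagewas.traits import IndividualPhenotypes

from tests._cage_sim import build_cage_population, draw_cage_trait
from tests.test_mixed_models_uni import sim_individual


class TestEffectFormula:
    def test_zero_covariance_zero_effect(self):
        pop = build_cage_population(1, cages_per_batch=8, n_snps=3)
        cp = draw_cage_trait(pop)
        model = BivariateModel.from_cage(
            cp, pop["caged"], pop["A"], pop["genotyped"], trait="y"
        )
        rows = [list(pop["G"].sample_ids).index(a) for a in model.genotyped_ids]
        fit = model.fit(pop["G"].values[rows, 0], null=True)
        assert fit.alpha == 0.0

    def test_half_frequency(self):
        # alpha = g12 / (2 f (1-f)): f = 0.5, g12 = 0.5 -> 1.0
        assert 0.5 / (2 * 0.5 * 0.5) == pytest.approx(1.0)

    def test_printed_effect_inverts(self):
        # published effect/MAF pair: alpha 0.52 at f 0.42 implies
        # g12 = 0.52 * 2*0.42*0.58 = 0.2533; formula round-trips
        g12 = 0.52 * 2 * 0.42 * 0.58
        assert g12 == pytest.approx(0.2533, abs=1e-4)
        assert g12 / (2 * 0.42 * 0.58) == pytest.approx(0.52)

    def test_fixed_snp_rejected(self):
        pop = build_cage_population(2, cages_per_batch=8, n_snps=3)
        cp = draw_cage_trait(pop)
        model = BivariateModel.from_cage(
            cp, pop["caged"], pop["A"], pop["genotyped"], trait="y"
        )
        with pytest.raises(ValueError, match="fixed"):
            model.fit(np.full(len(model.genotyped_ids), 2.0))


class TestEmBehaviour:
    def test_loglik_monotone_every_iteration(self):
        pop = build_cage_population(3, cages_per_batch=10, n_snps=5)
        cp = draw_cage_trait(pop)
        model = BivariateModel.from_cage(
            cp, pop["caged"], pop["A"], pop["genotyped"], trait="y"
        )
        rows = [list(pop["G"].sample_ids).index(a) for a in model.genotyped_ids]
        for j in range(pop["G"].n_snps):
            fit = model.fit(pop["G"].values[rows, j])
            diffs = np.diff(fit.loglik_path)
            assert (diffs > -1e-8).all(), f"loglik decreased at SNP {j}"

    def test_nonconvergence_flagged_not_raised(self):
        pop = build_cage_population(4, cages_per_batch=8, n_snps=2)
        cp = draw_cage_trait(pop)
        model = BivariateModel.from_cage(
            cp, pop["caged"], pop["A"], pop["genotyped"], trait="y",
            em_max_iter=3,
        )
        rows = [list(pop["G"].sample_ids).index(a) for a in model.genotyped_ids]
        fit = model.fit(pop["G"].values[rows, 0])
        assert not fit.converged

    def test_allele_content_heritability_near_one(self):
        # error-free genotypes: fitted h2 of allele content >= 0.9
        pop = build_cage_population(5, cages_per_batch=20, n_snps=10,
                                    fraction_genotyped=0.5)
        cp = draw_cage_trait(pop)
        model = BivariateModel.from_cage(
            cp, pop["caged"], pop["A"], pop["genotyped"], trait="y"
        )
        rows = [list(pop["G"].sample_ids).index(a) for a in model.genotyped_ids]
        h2 = []
        for j in range(10):
            y2 = pop["G"].values[rows, j]
            f2 = model.fit_null_trait2(y2, np.ones(len(y2), dtype=bool))
            h2.append(f2.theta["a2"] / (f2.theta["a2"] + f2.theta["e2"]))
        assert np.median(h2) >= 0.9

    def test_group_mean_residual_contract(self):
        """Doubling every group size N halves the residual contribution:
        the restricted likelihood profile satisfies
        ll(theta; weights 2w) = ll(theta/2; weights w) exactly."""
        rng = np.random.default_rng(0)
        y = rng.normal(10.0, 2.0, 6)
        X = np.ones((6, 1))
        idx = np.arange(6)

        def profile(theta, w):
            return em_reml(
                y, X, [], [ResidualGroup("e", idx, w * np.ones(6))],
                theta0={"e": theta}, max_iter=1,
            ).loglik_path[0]

        for theta in (1.0, 3.7, 9.2):
            assert profile(theta, 2.0) == pytest.approx(
                profile(theta / 2.0, 1.0), abs=1e-10
            )
        # and the fitted residual variance doubles with the weights
        f1 = em_reml(y, X, [], [ResidualGroup("e", idx, np.ones(6))],
                     theta0={"e": 1.0}, max_iter=500)
        f2 = em_reml(y, X, [], [ResidualGroup("e", idx, 2 * np.ones(6))],
                     theta0={"e": 1.0}, max_iter=500)
        assert f2.theta["e"] == pytest.approx(2 * f1.theta["e"], rel=1e-5)
        # the doubled variance exactly compensates the doubled weights
        assert f2.loglik == pytest.approx(f1.loglik, abs=1e-8)


class TestEquivalenceSmall:
    def test_complete_data_matches_emmax(self):
        """On complete data (every phenotyped animal genotyped, individual
        records, genotypes gene-dropped through the pedigree so allele
        content is heritable) the bivariate scan tracks the EMMAX scan —
        small-scale version of the equivalence theorem; the full-strength
        check at the stated tolerances lives in the acceptance suite."""
        import warnings

        from cagewas.simdata import (
            SimConfig,
            draw_breeding_values,
            simulate_trait_records,
        )

        pop = build_cage_population(13, cages_per_batch=14, n_batches=3,
                                    n_snps=20)
        caged, ped, A, G = pop["caged"], pop["pedigree"], pop["A"], pop["G"]
        rng = np.random.default_rng(131)
        cfg = SimConfig(sigma2_cage=4.0, sigma2_litter=10.0,
                        sigma2_e_adg=44.0, seed=0)
        bv = draw_breeding_values(ped, np.array([[16.0]]), rng,
                                  inbreeding=A.inbreeding)
        gidx = {a: i for i, a in enumerate(G.sample_ids)}
        g = G.values[:, 4]
        f = np.nanmean(g) / 2.0
        causal = 6.0 * np.array([g[gidx[a]] - 2 * f for a in caged["animal"]])
        adg, _ = simulate_trait_records(caged, bv, ped.animal, cfg, rng,
                                        causal_values=causal)
        frame = caged.copy()
        frame["adg"] = adg
        pheno = IndividualPhenotypes(frame)

        emmax = scan_model1(pheno, G, pop["snp_map"], A, mode="emmax")
        model = BivariateModel.from_individual(
            pheno, A, list(frame["animal"]), trait="adg"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bivar = scan_bivariate(model, G, pop["snp_map"], trait="adg")
        merged = emmax.merge(bivar, on="snp_id", suffixes=("_em", "_bi"))
        # both engines rank the causal SNP first
        assert merged.sort_values("lrt_em")["snp_id"].iloc[-1] == "snp5"
        assert merged.sort_values("lrt_bi")["snp_id"].iloc[-1] == "snp5"
        # its effect estimates agree (per-SNP REML scatter is O(n^-1/2),
        # so ~30% at this n; the acceptance run shows the full-scale value)
        row = merged[merged["snp_id"] == "snp5"].iloc[0]
        assert row["effect_bi"] == pytest.approx(row["effect_em"], rel=0.3)
        # effects of clearly associated SNPs agree in sign
        strong = merged[merged["lrt_em"] > 4]
        assert (
            np.sign(strong["effect_em"]) == np.sign(strong["effect_bi"])
        ).all()
        corr = np.corrcoef(merged["lrt_em"], merged["lrt_bi"])[0, 1]
        assert corr >= 0.9


class TestRecoverySmall:
    def test_median_alpha_recovers_truth(self):
        """Reduced-replicate version of the recovery criterion: enough
        cages/genotyped relatives that the allele-content model is
        informative; the 100-replicate 15% check is in the acceptance
        suite."""
        pop = build_cage_population(55, cages_per_batch=40, n_batches=3,
                                    n_snps=60, fraction_genotyped=0.3)
        G = pop["G"]
        row_of = {a: i for i, a in enumerate(G.sample_ids)}
        rows = [row_of[str(a)] for a in pop["genotyped"]]
        freqs = G.values[rows, :].mean(axis=0) / 2.0
        candidates = np.argsort(np.abs(freqs - 0.3))[:12]
        sd = np.sqrt(16.0 + 10.0 + 44.0)
        alpha_true = 0.5 * sd
        estimates = []
        for rep in range(12):
            snp = int(candidates[rep])
            cp = draw_cage_trait(pop, causal_snp=snp, causal_alpha=alpha_true,
                                 seed=100 + rep)
            model = BivariateModel.from_cage(
                cp, pop["caged"], pop["A"], pop["genotyped"], trait="y",
                em_ll_tol=1e-7,
            )
            fit = model.fit(G.values[rows, snp])
            estimates.append(fit.alpha)
        med = float(np.median(estimates))
        assert med == pytest.approx(alpha_true, rel=0.5)


class TestWrapperAndScan:
    def test_fit_bivariate_wrapper_individual(self, rng):
        pheno, snp, A = sim_individual(60, rng)
        fit = fit_bivariate(
            pheno, snp, A, list(pheno.frame["animal"]), trait="adg"
        )
        assert np.isfinite(fit.loglik)
        assert np.isfinite(fit.alpha)

    def test_fit_bivariate_wrapper_cage(self):
        pop = build_cage_population(7, cages_per_batch=8, n_snps=4)
        cp = draw_cage_trait(pop)
        rows = [
            list(pop["G"].sample_ids).index(str(a)) for a in pop["genotyped"]
        ]
        fit = fit_bivariate(
            cp,
            pop["G"].values[rows, 1],
            pop["A"],
            pop["genotyped"],
            trait="y",
            individual_meta=pop["caged"],
        )
        assert np.isfinite(fit.loglik)

    def test_scan_output_schema(self):
        pop = build_cage_population(8, cages_per_batch=8, n_snps=4)
        cp = draw_cage_trait(pop)
        model = BivariateModel.from_cage(
            cp, pop["caged"], pop["A"], pop["genotyped"], trait="y"
        )
        rec = scan_bivariate(model, pop["G"], pop["snp_map"], trait="y")
        assert {"snp_id", "chromosome", "position_bp", "effect", "lrt", "p",
                "method", "trait", "maf"} <= set(rec.columns)
        assert (rec["method"] == "bivar").all()
        assert ((rec["p"] >= 0) & (rec["p"] <= 1)).all()


class TestVarianceExplained:
    def test_published_worked_example(self):
        # 2*0.42*0.58*0.52^2 / 0.2 = 0.659 -> ~66%
        v = variance_explained(0.52, 0.42, 0.2)
        assert v == pytest.approx(0.659, abs=0.001)

    def test_zero_effect(self):
        assert variance_explained(0.0, 0.3, 1.0) == 0.0

    def test_adg_band_example(self):
        # strongest growth-trait SNP: 2*0.39*0.61*3.68^2/77.6 ~ 8.3%,
        # inside the printed 5-8% band within rounding
        v = variance_explained(3.68, 0.39, 77.6)
        assert v == pytest.approx(0.083, abs=0.001)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            variance_explained(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            variance_explained(1.0, 0.5, 0.0)


class TestGroupGenotypeRegression:
    def test_constant_genotype_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            group_genotype_regression([1.0, 2.0, 3.0], [1.0, 1.0, 1.0])

    def test_exact_linear_recovered(self):
        x = np.array([0.2, 0.5, 0.9, 1.4, 1.8])
        y = 2.0 + 0.25 * x
        slope, se, p = group_genotype_regression(y, x)
        assert slope == pytest.approx(0.25, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_cage_mean_genotype_helper(self):
        from cagewas.mixed_models.common import cage_mean_genotype

        pop = build_cage_population(9, cages_per_batch=8, n_snps=3)
        cp = draw_cage_trait(pop)
        G_sub = pop["G"].subset(
            samples=np.array(
                [list(pop["G"].sample_ids).index(str(a))
                 for a in pop["genotyped"]]
            )
        )
        x = cage_mean_genotype(cp, G_sub, "snp1")
        assert len(x) == len(cp.frame)
        # hand-check one cage
        cage0 = cp.frame["cage"].iloc[0]
        members = [a for a in cp.members[cage0] if a in set(pop["genotyped"])]
        col = {a: G_sub.values[i, 0] for i, a in enumerate(G_sub.sample_ids)}
        assert x[0] == pytest.approx(np.mean([col[a] for a in members]))
        # detectably related to the trait machinery end to end
        slope, se, p = group_genotype_regression(cp.frame["y"], x)
        assert np.isfinite(slope) and np.isfinite(p)

    def test_matches_statsmodels_oracle(self, rng):
        x = rng.uniform(0, 2, 99)
        y = 2.8 + 0.2 * x + rng.normal(0, 0.1, 99)
        slope, se, p = group_genotype_regression(y, x)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert slope == pytest.approx(ols.params[1], rel=1e-10)
        assert se == pytest.approx(ols.bse[1], rel=1e-10)
        assert p == pytest.approx(ols.pvalues[1], rel=1e-8)
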