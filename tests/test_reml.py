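"""REML engine: oracles, invariances, recovery at small scale."""

import numpy as np
import pandas as pd
import pytest

from abaqg import (
    AnimalModelREML,
    DesignSpec,
    MissingnessSpec,
    PedigreeError,
    fit_reml,
    pedigree_from_frame,
    profile_loglik,
    simulate_population,
)
from abaqg.reml import ModelError, assemble_mme
from conftest import fully_observed


def founders_data():
    ped = pedigree_from_frame(
        pd.DataFrame(
            {"id": ["a", "b", "c"], "sire": ["0"] * 3, "dam": ["0"] * 3}
        )
    )
    data = pd.DataFrame({"id": ["a", "b", "c"], "y": [1.0, 2.0, 3.0]})
    return data, ped


class TestAssembly:
    def test_dimension_founders_univariate(self):
        data, ped = founders_data()
        C, rhs = assemble_mme(
            data, ped, "y", {"G": [[1.0]], "E": [[1.0]]}
        )
        # 3 animal equations + 1 fixed (intercept; no sex column)
        assert C.shape == (4, 4)
        assert rhs.shape == (4,)

    def test_vanishing_additive_variance_shrinks_blup_to_zero(self):
        data, ped = founders_data()
        from scipy.sparse.linalg import spsolve

        C, rhs = assemble_mme(
            data, ped, "y", {"G": [[1e-10]], "E": [[1.0]]}
        )
        sol = spsolve(C.tocsc(), rhs)
        assert np.abs(sol[:3]).max() < 1e-8

    def test_unbalanced_bivariate_block_sizes(self, small_design):
        data = small_design.phenotypes.copy()
        keep = data.sample(n=60, random_state=0).index
        data.loc[~data.index.isin(keep), "Mw"] = np.nan
        fit = fit_reml(
            data, small_design.pedigree, traits=["Tww", "Mw"], max_iter=3
        )
        assert fit.n_records["Mw"] == data.Mw.notna().sum()
        assert fit.n_records["Tww"] == data.Tww.notna().sum()
        assert fit.n_records["Tww"] > 3 * fit.n_records["Mw"]

    def test_phenotyped_individual_missing_from_pedigree_fatal(self):
        data, ped = founders_data()
        data.loc[1, "id"] = "ghost"
        with pytest.raises(PedigreeError, match="ghost"):
            fit_reml(data, ped, traits=["y"], max_iter=2)


class TestOracles:
    def test_reml_matches_dense_grid_argmax(self, sl30_population):
        """Optimum of the sparse-MME AI-REML fit coincides with the
        brute-force dense restricted-likelihood grid."""
        pop = sl30_population
        sub_ids = pop.phenotypes["id"].iloc[:200]
        data = pop.phenotypes[pop.phenotypes.id.isin(sub_ids)]
        fit = fit_reml(data, pop.pedigree, traits=["SL_30"])
        vp = fit.gcov[0, 0] + fit.ecov[0, 0]
        h2s = np.linspace(0.02, 0.95, 32)
        curve = profile_loglik(
            data, pop.pedigree, "SL_30", [(h * vp, (1 - h) * vp) for h in h2s]
        )
        best = curve.loglik.idxmax()
        assert abs(h2s[best] - fit.h2[0]) <= (h2s[1] - h2s[0])
        # and the MME likelihood value itself agrees with the dense formula
        at_opt = profile_loglik(
            data, pop.pedigree, "SL_30", [(fit.gcov[0, 0], fit.ecov[0, 0])]
        )
        assert at_opt.loglik[0] == pytest.approx(fit.loglik, abs=1e-6)

    def test_likelihood_at_truth_not_above_optimum(self, sl30_population):
        pop = sl30_population
        data = pop.phenotypes[pop.phenotypes.id.isin(pop.phenotypes.id.iloc[:200])]
        fit = fit_reml(data, pop.pedigree, traits=["SL_30"])
        tr = pop.params.traits[0]
        at_truth = profile_loglik(
            data, pop.pedigree, "SL_30", [(tr.sigma_a2, tr.sigma_e2)]
        )
        assert at_truth.loglik[0] <= fit.loglik + 1e-8

    def test_grid_of_one_point(self, sl30_population):
        pop = sl30_population
        data = pop.phenotypes[pop.phenotypes.id.isin(pop.phenotypes.id.iloc[:50])]
        curve = profile_loglik(data, pop.pedigree, "SL_30", [(5.0, 10.0)])
        assert len(curve) == 1

    def test_dense_oracle_refuses_large_n(self, sl30_population):
        pop = sl30_population
        with pytest.raises(ModelError, match="500"):
            profile_loglik(pop.phenotypes, pop.pedigree, "SL_30", [(1.0, 1.0)])

    def test_half_sib_anova_agreement(self):
        """On a balanced nested design, REML agrees with the closed-form
        nested ANOVA method-of-moments decomposition."""
        diffs = []
        n_off, n_dps = 10, 2
        for seed in (31, 32, 33):
            spec = DesignSpec(
                n_sires=30, n_dams=60, n_families=60,
                offspring_per_family=n_off, seed=seed,
            )
            pop = simulate_population(
                spec, traits=["SL_30"], seed=seed, miss=fully_observed()
            )
            data = pop.phenotypes
            fit = fit_reml(data, pop.pedigree, traits=["SL_30"])

            # nested ANOVA oracle: sires / dams-within-sires / within
            d = data.copy()
            d["sire"] = d.family.str.split("x").str[0]
            d["r"] = (
                d.SL_30 - d.groupby("sex").SL_30.transform("mean")
            ).to_numpy()
            gm = d.r.mean()
            sire_means = d.groupby("sire").r.mean()
            fam_means = d.groupby("family").r.mean()
            fam_sire = fam_means.index.str.split("x").str[0]
            ms_sire = (
                n_off * n_dps * ((sire_means - gm) ** 2).sum()
                / (len(sire_means) - 1)
            )
            ms_fam = (
                n_off
                * (
                    (fam_means.to_numpy() - sire_means.loc[fam_sire].to_numpy())
                    ** 2
                ).sum()
                / (len(fam_means) - len(sire_means))
            )
            ms_within = ((d.r - fam_means.loc[d.family].to_numpy()) ** 2).sum() / (
                len(d) - len(fam_means)
            )
            var_sire = (ms_sire - ms_fam) / (n_off * n_dps)
            var_fam = (ms_fam - ms_within) / n_off
            h2_anova = 4 * var_sire / (var_sire + var_fam + ms_within)
            diffs.append(fit.h2[0] - h2_anova)
        assert abs(np.mean(diffs)) < 0.08

    def test_null_recovery(self):
        """With sigma_a2 = 0 truth the REML estimate collapses to the
        boundary in almost all replicates."""
        from abaqg.simulate import Trait, TraitParams

        tr = Trait("y", 0.0, sigma_a2=0.0, sigma_e2=1.0)
        params = TraitParams([tr], np.eye(1), np.eye(1))
        hits = 0
        reps = 6
        for s in range(reps):
            pop = simulate_population(
                DesignSpec(20, 30, 34, 15, seed=100 + s),
                params=params, miss=fully_observed(), seed=100 + s,
            )
            fit = fit_reml(pop.phenotypes, pop.pedigree, traits=["y"])
            if fit.h2[0] < 0.05:
                hits += 1
        assert hits >= reps - 1


class TestProperties:
    def test_em_loglik_monotone(self, sl30_population):
        pop = sl30_population
        data = pop.phenotypes[pop.phenotypes.id.isin(pop.phenotypes.id.iloc[:250])]
        est = AnimalModelREML(traits=["SL_30"])
        from abaqg.reml import _MME

        mme = _MME(data, pop.pedigree, ["SL_30"], False)
        rng = np.random.default_rng(0)
        v = np.nanvar(data.SL_30.to_numpy())
        G0, E0 = np.array([[0.8 * v]]), np.array([[0.2 * v]])
        state = mme.factorize(G0, E0, None)
        lls = [state.loglik]
        for _ in range(12):
            G0, E0, _f = est._em_step(state, True, rng)
            state = mme.factorize(G0, E0, None)
            lls.append(state.loglik)
        assert np.all(np.diff(lls) > -1e-9)

    def test_scale_equivariance(self, sl30_population):
        pop = sl30_population
        data = pop.phenotypes[pop.phenotypes.id.isin(pop.phenotypes.id.iloc[:400])].copy()
        fit1 = fit_reml(data, pop.pedigree, traits=["SL_30"])
        k = 3.7
        data["SL_30"] = data["SL_30"] * k
        fit2 = fit_reml(data, pop.pedigree, traits=["SL_30"])
        assert fit2.gcov[0, 0] == pytest.approx(k**2 * fit1.gcov[0, 0], rel=1e-3)
        assert fit2.h2[0] == pytest.approx(fit1.h2[0], abs=1e-4)

    def test_row_order_and_relabeling_invariance(self, sl30_population):
        pop = sl30_population
        data = pop.phenotypes[pop.phenotypes.id.isin(pop.phenotypes.id.iloc[:300])]
        fit1 = fit_reml(data, pop.pedigree, traits=["SL_30"])
        shuffled = data.sample(frac=1.0, random_state=3)
        fit2 = fit_reml(shuffled, pop.pedigree, traits=["SL_30"])
        assert fit2.h2[0] == pytest.approx(fit1.h2[0], abs=1e-6)
        # consistent relabeling of individual ids
        mapping = {i: f"z{k}" for k, i in enumerate(pop.pedigree.ids)}
        pedf = pop.pedigree.to_frame()
        for col in ("id", "sire", "dam"):
            pedf[col] = pedf[col].map(lambda v: mapping.get(v, "0"))
        relabeled_ped = pedigree_from_frame(pedf)
        data3 = data.copy()
        data3["id"] = data3["id"].map(mapping)
        fit3 = fit_reml(data3, relabeled_ped, traits=["SL_30"])
        assert fit3.h2[0] == pytest.approx(fit1.h2[0], abs=1e-6)

    def test_bivariate_with_zero_cross_covariances_matches_univariate(
        self, small_design
    ):
        data = small_design.phenotypes
        ped = small_design.pedigree
        f_t = fit_reml(data, ped, traits=["SL_30"])
        f_w = fit_reml(data, ped, traits=["Tww"])
        f_b = fit_reml(
            data, ped, traits=["SL_30", "Tww"], diagonal_covariances=True
        )
        assert f_b.gcov[0, 0] == pytest.approx(f_t.gcov[0, 0], rel=1e-4)
        assert f_b.gcov[1, 1] == pytest.approx(f_w.gcov[0, 0], rel=1e-4)
        assert f_b.ecov[1, 1] == pytest.approx(f_w.ecov[0, 0], rel=1e-4)
        assert f_b.gcov[0, 1] == 0.0

    def test_sklearn_estimator_surface(self, sl30_population):
        from sklearn.base import clone

        pop = sl30_population
        data = pop.phenotypes[pop.phenotypes.id.isin(pop.phenotypes.id.iloc[:150])]
        est = AnimalModelREML(traits=["SL_30"], max_iter=50)
        est2 = clone(est).set_params(seed=1)
        est2.fit(data, pop.pedigree)
        assert hasattr(est2, "gcov_") and hasattr(est2, "loglik_")
        assert est2.fit_.traits == ["SL_30"]
        assert est.get_params()["max_iter"] == 50

    def test_se_shrinks_with_sample_size(self):
        from abaqg.genpar import se_delta

        fits = []
        for off, seed in ((6, 41), (24, 42)):
            pop = simulate_population(
                DesignSpec(20, 30, 34, off, seed=seed),
                traits=["SL_30"], seed=seed, miss=fully_observed(),
            )
            fits.append(fit_reml(pop.phenotypes, pop.pedigree, traits=["SL_30"]))
        se_small = se_delta(fits[0], "h2:SL_30")
        se_large = se_delta(fits[1], "h2:SL_30")
        assert se_large < se_small
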