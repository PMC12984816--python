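"""Design generation, breeding-value recursion, phenotype simulation."""

import numpy as np
import pandas as pd
import pytest

from abaqg import (
    DesignError,
    DesignSpec,
    MissingnessSpec,
    OrdinalSpec,
    Trait,
    TraitParams,
    build_A,
    family_structure,
    generate_design,
    simulate_breeding_values,
    simulate_population,
)
from abaqg.calibration import default_calibration, solve_category_probs
from abaqg.simulate import MeatSubsample
from conftest import fully_observed


class TestDesign:
    @pytest.mark.parametrize(
        "spec, families, sires, dams",
        [
            (DesignSpec(), 141, 81, 124),
            (DesignSpec(2, 4, 4, 5), 4, 2, 4),
            (DesignSpec(3, 3, 3, 5), 3, 3, 3),
        ],
    )
    def test_family_counts(self, spec, families, sires, dams):
        fm = family_structure(generate_design(spec))
        assert (fm.n_families, fm.n_sires, fm.n_dams) == (families, sires, dams)

    def test_each_sire_at_most_two_dams(self):
        ped = generate_design(DesignSpec(2, 4, 4, 5))
        fm = family_structure(ped)
        per_sire = (
            fm.families_frame()["family"].str.split("x").str[0].value_counts()
        )
        assert (per_sire == 2).all()

    def test_monogamous_design_has_no_half_sibs(self):
        ped = generate_design(DesignSpec(3, 3, 3, 4))
        A = build_A(ped).values
        offspring = [k for k in range(len(ped)) if ped.sire[k] >= 0]
        sub = A[np.ix_(offspring, offspring)]
        np.fill_diagonal(sub, 0.0)
        assert set(np.unique(np.round(sub, 12))).issubset({0.0, 0.5})

    @pytest.mark.parametrize(
        "spec",
        [
            DesignSpec(n_sires=2, n_dams=4, n_families=5),
            DesignSpec(n_sires=5, n_dams=9, n_families=8),
            DesignSpec(n_sires=3, n_dams=1, n_families=3),
        ],
    )
    def test_infeasible_designs_fatal(self, spec):
        with pytest.raises(DesignError):
            generate_design(spec)

    def test_sex_frequencies(self):
        ped = generate_design(DesignSpec(seed=3))
        offspring = ped.sex[ped.sire >= 0]
        freq = pd.Series(offspring).value_counts(normalize=True)
        assert freq["F"] == pytest.approx(0.520, abs=0.02)
        assert freq["U"] == pytest.approx(0.111, abs=0.02)


def one_trait_params(sigma_a2=1.0, sigma_e2=1.0, sigma_f2=0.0, mean=0.0):
    tr = Trait("y", mean=mean, sigma_a2=sigma_a2, sigma_e2=sigma_e2,
               sigma_f2=sigma_f2)
    return TraitParams(traits=[tr], r_g=np.eye(1), r_e=np.eye(1))


class TestBreedingValues:
    def test_zero_additive_variance_gives_zero_values(self, rng):
        ped = generate_design(DesignSpec(4, 6, 7, 5, seed=1))
        a = simulate_breeding_values(ped, one_trait_params(sigma_a2=0.0), rng)
        assert np.all(a == 0)

    def test_covariance_matches_dense_A_oracle(self):
        """Empirical covariance of replicate draws converges to A (the
        direct MVN covariance), validating the Mendelian-sampling
        recursion against the tabular relationship matrix."""
        ped = generate_design(DesignSpec(6, 9, 10, 8, seed=2))
        A = build_A(ped).values
        rng = np.random.default_rng(77)
        params = one_trait_params(sigma_a2=1.0, sigma_e2=1.0)
        draws = np.stack(
            [simulate_breeding_values(ped, params, rng)[:, 0] for _ in range(600)]
        )
        emp = draws.T @ draws / len(draws)
        err = np.abs(emp - A)
        assert err.mean() < 0.05
        assert err.max() < 0.35

    def test_full_and_half_sib_covariance(self):
        spec = DesignSpec(20, 30, 34, 20, seed=5)
        ped = generate_design(spec)
        rng = np.random.default_rng(11)
        params = one_trait_params(sigma_a2=1.0, sigma_e2=0.5)
        fs, hs = [], []
        fm = family_structure(ped)
        fam = fm.family_of.to_numpy()
        sire = fm.sire_of.to_numpy()
        for _ in range(40):
            a = simulate_breeding_values(ped, params, rng)[:, 0]
            for f in fm.family_sizes.index[:10]:
                members = np.flatnonzero(fam == f)
                fs.append(a[members[0]] * a[members[1]])
            seen = {}
            for k in np.flatnonzero(sire != ""):
                s = sire[k]
                if s in seen and fam[seen[s]] != fam[k]:
                    hs.append(a[seen[s]] * a[k])
                else:
                    seen.setdefault(s, k)
        assert np.mean(fs) == pytest.approx(0.5, abs=0.1)
        assert np.mean(hs) == pytest.approx(0.25, abs=0.1)

    def test_cross_trait_genetic_correlation(self, rng):
        t1 = Trait("u", 0.0, 1.0, 0.5)
        t2 = Trait("v", 0.0, 1.0, 0.5)
        params = TraitParams(
            traits=[t1, t2],
            r_g=np.array([[1.0, 0.9], [0.9, 1.0]]),
            r_e=np.eye(2),
        )
        ped = generate_design(DesignSpec(20, 30, 34, 30, seed=6))
        a = simulate_breeding_values(ped, params, rng)
        r = np.corrcoef(a[:, 0], a[:, 1])[0, 1]
        assert r == pytest.approx(0.9, abs=0.03)

    def test_non_psd_correlation_fatal(self, rng):
        t1 = Trait("u", 0.0, 1.0, 0.5)
        t2 = Trait("v", 0.0, 1.0, 0.5)
        t3 = Trait("w", 0.0, 1.0, 0.5)
        bad = np.array([[1, 0.9, -0.9], [0.9, 1, 0.9], [-0.9, 0.9, 1.0]])
        params = TraitParams(traits=[t1, t2, t3], r_g=bad, r_e=np.eye(3))
        ped = generate_design(DesignSpec(2, 3, 3, 4, seed=0))
        with pytest.raises(ValueError, match="PSD|eigenvalue"):
            simulate_breeding_values(ped, params, rng)


class TestPhenotypes:
    def test_all_variances_zero_yields_the_mean(self):
        tr = Trait("y", mean=5.0, sigma_a2=0.0, sigma_e2=1e-12)
        params = TraitParams([tr], np.eye(1), np.eye(1))
        spec = DesignSpec(3, 5, 6, 10, seed=4)
        pop = simulate_population(
            spec, params=params, miss=fully_observed(), seed=4
        )
        assert pop.phenotypes["y"].to_numpy() == pytest.approx(5.0, abs=1e-4)

    def test_seeded_runs_are_identical(self, tmp_path):
        spec = DesignSpec(6, 9, 10, 8, seed=12)
        p1 = simulate_population(spec, seed=12, miss=fully_observed())
        p2 = simulate_population(spec, seed=12, miss=fully_observed())
        assert p1.phenotypes.equals(p2.phenotypes)
        p1.write(tmp_path / "a")
        p2.write(tmp_path / "b")
        assert (tmp_path / "a" / "phenotypes.csv").read_bytes() == (
            tmp_path / "b" / "phenotypes.csv"
        ).read_bytes()

    def test_death_hides_everything_but_survival(self):
        pop = simulate_population(DesignSpec(seed=2), seed=2)
        ph = pop.phenotypes
        dead = ph[ph.survival == 0]
        traits = [c for c in ph.columns if c not in ("id", "family", "sex", "survival")]
        assert dead[traits].isna().all().all()
        # conservation: family sizes sum to the tagged total
        fm = family_structure(pop.pedigree)
        assert fm.family_sizes.sum() == len(ph)

    def test_meat_subsample_size_and_stratification(self):
        pop = simulate_population(DesignSpec(seed=8), seed=8)
        ph = pop.phenotypes
        meat = ph[ph.My.notna()]
        assert len(meat) == 680
        per_fam = meat.family.value_counts()
        assert len(per_fam) == 30
        assert per_fam.between(20, 25).all()
        assert (meat.survival == 1).all()
        # composite: yield is exactly Mw / Tww (where Tww was recorded)
        both = meat[meat.Tww.notna()]
        assert both.My.to_numpy() == pytest.approx(
            (both.Mw / both.Tww).to_numpy()
        )

    def test_full_sib_phenotypic_covariance_with_common_environment(self):
        tr = Trait.from_moments("y", 0.0, 1.0, h2=0.4, c2=0.2)
        params = TraitParams([tr], np.eye(1), np.eye(1))
        spec = DesignSpec(30, 45, 50, 24, seed=3)
        products = []
        for s in range(6):
            pop = simulate_population(
                DesignSpec(30, 45, 50, 24, seed=s),
                params=params, miss=fully_observed(), seed=s,
            )
            ph = pop.phenotypes
            for f, grp in ph.groupby("family"):
                y = grp["y"].to_numpy()
                # disjoint full-sib pairs -> independent products
                products.extend(y[0::2][: len(y) // 2] * y[1::2])
        expected = 0.5 * tr.sigma_a2 + tr.sigma_f2
        assert np.mean(products) == pytest.approx(expected, abs=0.06)


class TestCalibration:
    def test_category_prob_solver_matches_moments(self):
        p = solve_category_probs(1.42, 0.64)
        scores = np.arange(1, 5)
        assert p.sum() == pytest.approx(1.0)
        assert (p * scores).sum() == pytest.approx(1.42)
        assert np.sqrt((p * scores**2).sum() - 1.42**2) == pytest.approx(0.64)
        assert p.argmax() == 0

    def test_category_prob_solver_rejects_impossible_moments(self):
        with pytest.raises(ValueError):
            solve_category_probs(1.05, 1.4)

    def test_default_parameter_set(self):
        params, ordinal, miss = default_calibration()
        sl30 = params.traits[params.index("SL_30")]
        assert sl30.mean == 76.68
        assert sl30.h2 == pytest.approx(0.48)
        tww = params.traits[params.index("Tww")]
        assert tww.phenotypic_var == pytest.approx(14.6**2)
        fc = params.traits[params.index("Fc")]
        # standard sire-dam latent heritability at the generating truth
        ss = fc.sigma_a2 / 4
        assert 2 * (2 * ss) / (2 * ss + fc.sigma_f2 + 1) == pytest.approx(0.46)
        # residual of a sire-dam decomposition is exactly 1
        assert fc.sigma_e2 + fc.sigma_a2 / 2 == pytest.approx(1.0)
        assert np.all(np.diff(ordinal.cutpoints) > 0)
        # printed correlations survive the PSD completion untouched
        assert params.r_g[params.index("Tww"), params.index("Mw")] == 0.92
        assert params.r_g[params.index("SL_30"), params.index("Tww")] == 0.90
        assert np.linalg.eigvalsh(params.r_g).min() > -1e-10
        assert np.linalg.eigvalsh(params.r_e).min() > -1e-10
        assert miss.survival_rate == pytest.approx(0.7984, abs=1e-4)

    def test_default_moments_one_simulation(self):
        pop = simulate_population(DesignSpec(seed=17), seed=17)
        from abaqg.pipeline import descriptive_stats

        d = descriptive_stats(pop.phenotypes)
        assert d.loc["SL_30", "mean"] == pytest.approx(76.68, abs=0.8)
        assert d.loc["SL_30", "SD"] == pytest.approx(5.34, abs=0.25)
        assert d.loc["Fc", "min"] == 1.0
        assert d.loc["Fc", "max"] == 4.0
        fc = pop.phenotypes.Fc.dropna()
        assert fc.value_counts().idxmax() == 1.0
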