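"""Sampler correctness: diagnostics, priors, recovery on simple designs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from ivfjoint.cohort import Cohort, EmptyCohortError
from ivfjoint.inference import (DegenerateDataError, FitConfig,
                                PosteriorSamples, build_priors,
                                combine_separate_fits, fit_joint,
                                fit_separate, split_rhat,
                                summarise_posterior)
from ivfjoint.model import SubmodelSpec, pretreatment_specs

from conftest import make_cohort


def intercept_specs():
    return {o: SubmodelSpec(o, ()) for o in "OMEFDL"}


def flat_cohort(n, seed, p_lbe=0.32, p_det=0.5):
    """Cohort where every cycle reaches transfer: isolates the probit
    submodels with known Bernoulli outcomes."""
    rng = np.random.default_rng(seed)
    ids = np.array([f"c{i}" for i in range(n)], dtype=object)
    cyc = pd.DataFrame({
        "cycle_id": ids,
        "age": 33.0, "partner_age": 35.0, "attempt": "1",
        "n_oocytes": pd.array(rng.poisson(5.0, n) + 2, dtype="Int64"),
        "mixed": pd.array(np.ones(n, dtype=int), dtype="Int64"),
        "n_embryos": pd.array(np.full(n, 2), dtype="Int64"),
        "transferred": pd.array(np.ones(n, dtype=int), dtype="Int64"),
        "det": pd.array(rng.binomial(1, p_det, n), dtype="Int64"),
        "lbe": pd.array(rng.binomial(1, p_lbe, n), dtype="Int64"),
    })
    emb = pd.DataFrame({
        "cycle_id": np.repeat(ids, 2),
        "evenness": pd.array(rng.integers(1, 5, 2 * n), dtype="Int64"),
        "fragmentation": pd.array(rng.integers(1, 5, 2 * n),
                                  dtype="Int64"),
        "icsi": pd.array(rng.integers(0, 2, 2 * n), dtype="Int64"),
    })
    return Cohort(cyc, emb)


class TestPriors:
    def test_probit_coefficients_weakly_informative(self):
        pr = build_priors()
        assert pr.sd_beta["L"] == 2.0 and pr.sd_beta["D"] == 2.0

    def test_count_coefficients_effectively_flat(self):
        pr = build_priors()
        assert pr.sd_beta["O"] == 1000.0 and pr.sd_alpha == 1000.0

    def test_latent_sd_half_cauchy_scale(self):
        assert build_priors().theta_scale == 2.5

    def test_lkj_shape_uniform(self):
        assert build_priors().lkj_shape == 1.0


class TestSplitRhat:
    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 2000))
        assert 0.99 < split_rhat(x) < 1.01

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 500))
        x[1] += 10
        assert split_rhat(x) > 1.1

    def test_constant_chains_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero within-chain"):
            assert np.isnan(split_rhat(np.ones((2, 100))))

    def test_matches_arviz(self):
        import arviz
        rng = np.random.default_rng(2)
        x = np.cumsum(rng.standard_normal((3, 400)), axis=1) * 0.05 \
            + rng.standard_normal((3, 400))
        ours = split_rhat(x)
        ref = float(np.asarray(
            arviz.rhat(arviz.convert_to_dataset(x))["x"]))
        assert ours == pytest.approx(ref, abs=0.01)


class TestSummaries:
    def test_median_and_interval_are_percentiles(self):
        # a PosteriorSamples built by hand with known draws
        rng = np.random.default_rng(3)
        draws = {f"beta_{o}": rng.standard_normal((2, 300, 1))
                 for o in "OMDL"}
        draws["beta_E"] = rng.standard_normal((2, 300, 3))
        draws["beta_F"] = rng.standard_normal((2, 300, 3))
        draws["alpha_E"] = np.sort(rng.standard_normal((2, 300, 3)), -1)
        draws["alpha_F"] = np.sort(rng.standard_normal((2, 300, 3)), -1)
        draws["theta"] = np.abs(rng.standard_normal((2, 300, 4)))
        draws["eta"] = np.zeros((2, 300, 15))
        sp = intercept_specs()
        post = PosteriorSamples(draws, sp, None, tuple("OMEFDL"))
        tab = summarise_posterior(post).set_index("parameter")
        flat = draws["beta_O"].reshape(-1)
        assert tab.loc["beta_O[intercept]", "median"] == \
            pytest.approx(np.percentile(flat, 50))
        assert tab.loc["beta_O[intercept]", "lower95"] == \
            pytest.approx(np.percentile(flat, 2.5))

    def test_standardised_coefficient_converted_per_unit(self):
        rng = np.random.default_rng(4)
        sp = {o: SubmodelSpec(o, ("age",) if o == "O" else ())
              for o in "OMEFDL"}
        draws = {f"beta_{o}": rng.standard_normal((2, 200, 1))
                 for o in "MDL"}
        draws["beta_O"] = np.stack([np.zeros((200, 2))] * 2)
        draws["beta_O"][:, :, 1] = -0.20
        draws["beta_E"] = np.zeros((2, 200, 0))
        draws["beta_F"] = np.zeros((2, 200, 0))
        draws["alpha_E"] = np.tile([-1.0, 0.0, 1.0], (2, 200, 1))
        draws["alpha_F"] = np.tile([-1.0, 0.0, 1.0], (2, 200, 1))
        draws["theta"] = np.ones((2, 200, 4))
        draws["eta"] = np.zeros((2, 200, 15))
        scaling = {"age": {"mean": 33.0, "sd": 5.0}}
        post = PosteriorSamples(draws, sp, scaling, tuple("OMEFDL"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-draw rhat NaNs
            tab = post.summary(original_scale=True).set_index("parameter")
        assert tab.loc["beta_O[age]", "median"] == pytest.approx(-0.04)


class TestSeparateFits:
    def test_probit_intercept_recovery(self):
        """Intercept-only probit: posterior median of Phi(b0) must sit
        inside a binomial confidence band around the empirical rate."""
        cohort = flat_cohort(2500, seed=5, p_lbe=0.32)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_separate(cohort, intercept_specs(),
                               FitConfig(chains=2, iterations=400, seed=1),
                               outcomes=("L",))["L"]
        b0 = np.median(fit.stacked("beta_L")[:, 0])
        emp = (cohort.cycles["lbe"] == 1).mean()
        se = np.sqrt(emp * (1 - emp) / cohort.n_cycles)
        assert abs(ndtr(b0) - emp) < 3 * se

    def test_poisson_intercept_recovery(self):
        cohort = make_cohort(400, seed=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_separate(cohort, pretreatment_specs(),
                               FitConfig(chains=2, iterations=500, seed=2),
                               outcomes=("O",))["O"]
        tab = fit.summary().set_index("parameter")
        assert tab.loc["beta_O[intercept]", "lower95"] < 2.10 \
            < tab.loc["beta_O[intercept]", "upper95"]
        assert tab.loc["beta_O[age]", "lower95"] < -0.04 \
            < tab.loc["beta_O[age]", "upper95"]

    def test_grading_fit_ignores_downstream_columns(self):
        """Permuting live-birth outcomes must leave the evenness fit
        untouched (separate submodels are independent)."""
        cohort = make_cohort(200, seed=7)
        cyc = cohort.cycles.copy()
        tr = cyc.index[(cyc["transferred"] == 1).fillna(False)]
        rng = np.random.default_rng(0)
        cyc.loc[tr, "lbe"] = cyc.loc[tr, "lbe"].sample(
            frac=1.0, random_state=1).to_numpy()
        shuffled = Cohort(cyc, cohort.embryos,
                          cohort.covariate_scaling)
        cfg = FitConfig(chains=2, iterations=150, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_separate(cohort, pretreatment_specs(), cfg,
                             outcomes=("E",))["E"]
            b = fit_separate(shuffled, pretreatment_specs(), cfg,
                             outcomes=("E",))["E"]
        assert np.array_equal(a.draws["beta_E"], b.draws["beta_E"])
        assert np.array_equal(a.draws["alpha_E"], b.draws["alpha_E"])


class TestJointFit:
    def test_smoke_and_structure(self):
        cohort = make_cohort(120, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_joint(cohort, pretreatment_specs(),
                             FitConfig(chains=2, iterations=150, seed=4))
        assert post.n_chains == 2 and post.n_draws == 150
        params = post.parameters_at(0)
        params.validate()  # ordered thresholds, positive SDs, PD matrix
        assert set(post.diagnostics["rhat"])

    def test_draws_satisfy_parameter_invariants(self):
        cohort = make_cohort(120, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit_joint(cohort, pretreatment_specs(),
                             FitConfig(chains=2, iterations=100, seed=5))
        assert np.all(post.draws["theta"] > 0)
        assert np.all(np.diff(post.draws["alpha_E"], axis=-1) > 0)
        assert np.all(np.diff(post.draws["alpha_F"], axis=-1) > 0)
        for i in range(0, post.n_chains * post.n_draws, 37):
            post.parameters_at(i).validate()

    def test_empty_cohort_rejected(self, specs):
        with pytest.raises(EmptyCohortError):
            fit_joint(Cohort.from_records([], []), specs,
                      FitConfig(chains=2, iterations=10))

    def test_degenerate_outcome_rejected(self):
        cohort = make_cohort(60, seed=10)
        cyc = cohort.cycles.copy()
        tr = (cyc["transferred"] == 1).fillna(False)
        cyc.loc[tr, "lbe"] = 0  # no live birth anywhere: L unfittable
        with pytest.raises(DegenerateDataError, match="single class"):
            fit_joint(Cohort(cyc, cohort.embryos,
                             cohort.covariate_scaling),
                      pretreatment_specs(),
                      FitConfig(chains=2, iterations=10))

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="chains"):
            FitConfig(chains=1)


def test_combine_separate_layout():
    cohort = make_cohort(100, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = fit_separate(cohort, pretreatment_specs(),
                            FitConfig(chains=2, iterations=100, seed=6))
    post = combine_separate_fits(fits)
    assert np.all(post.draws["eta"] == 0)
    params = post.parameters_at(3)
    params.validate()


def test_posterior_save_load_roundtrip(tmp_path):
    cohort = make_cohort(100, seed=12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit_joint(cohort, pretreatment_specs(),
                         FitConfig(chains=2, iterations=80, seed=7))
    post.save(tmp_path / "p")
    back = PosteriorSamples.load(tmp_path / "p")
    assert np.allclose(back.draws["beta_O"], post.draws["beta_O"])
    assert back.specs["O"].covariates == post.specs["O"].covariates
    assert back.covariate_scaling.keys() == post.covariate_scaling.keys()
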