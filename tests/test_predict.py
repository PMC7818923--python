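"""Sequential prediction: failure propagation, denominators, closed forms."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import poisson

from ivfjoint.inference import posterior_from_parameters
from ivfjoint.model import ModelParameters, SubmodelSpec, dynamic_specs
from ivfjoint.predict import (joint_event_probability, predict_dynamic,
                              predict_pretreatment, predictive_intervals)


def intercept_specs():
    return {o: SubmodelSpec(o, ()) for o in "OMEFDL"}


def make_post(beta_O=2.09, beta_M=-1.0, beta_D=0.1, beta_L=-0.46,
              theta=(1e-6,) * 4, eta=None, n_draws=200):
    params = ModelParameters(
        beta_O=[beta_O], beta_M=[beta_M], beta_E=[], beta_F=[],
        beta_D=[beta_D], beta_L=[beta_L],
        alpha_E=[-4.35, -1.38, 1.33], alpha_F=[-5.11, -2.44, -0.33],
        theta=list(theta),
        eta=np.zeros(15) if eta is None else eta)
    return posterior_from_parameters(params, intercept_specs(), None,
                                     n_draws=n_draws)


NOCOV = {"age": [33.0]}


class TestPretreatment:
    def test_forced_failure_propagates(self):
        post = make_post(beta_O=-30.0)
        d = predict_pretreatment(post, NOCOV, n_draws=300, seed=0)
        assert np.all(d.outcomes["y_O"] == 0)
        assert np.all(np.isnan(d.outcomes["lbe"]))
        lbe = np.nan_to_num(d.outcomes["lbe"], nan=0.0)
        assert lbe.mean() == 0.0  # P(live birth per cycle started) = 0

    def test_chain_product_closed_form(self):
        """Without latent noise, P(live birth per cycle started) equals
        the analytic product P(reach transfer) * Phi(beta_L), with
        P(reach transfer) from truncated-Poisson zero probabilities."""
        bO, bM, bL = 2.0, -1.1, -0.46
        post = make_post(beta_O=bO, beta_M=bM, beta_L=bL)
        cov = {"age": np.zeros(2000)}
        d = predict_pretreatment(post, cov, n_draws=100, seed=1)
        lam_o = np.exp(bO)
        ks = np.arange(1, 200)
        pk = poisson.pmf(ks, lam_o)
        mu = ks * np.exp(bM)
        # embryo count is Poisson truncated at the oocyte count, so
        # P(0 embryos | k oocytes) = e^{-mu} / F(k; mu)
        p0_trunc = poisson.pmf(0, mu) / poisson.cdf(ks, mu)
        p_transfer = float(np.sum(pk * (1 - p0_trunc)))
        p_lbe = p_transfer * ndtr(bL)
        lbe = np.nan_to_num(d.outcomes["lbe"], nan=0.0)
        n = lbe.size
        assert abs(lbe.mean() - p_lbe) < 3 * np.sqrt(p_lbe * (1 - p_lbe)
                                                     / n)

    def test_latent_inclusion_inflates_variance(self):
        cov = {"age": np.zeros(400)}
        post = make_post(theta=(0.5, 0.3, 0.8, 0.9))
        with_z = predict_pretreatment(post, cov, n_draws=250,
                                      latents_included=True, seed=2)
        without = predict_pretreatment(post, cov, n_draws=250,
                                       latents_included=False, seed=2)
        v1 = np.var(with_z.outcomes["y_O"])
        v0 = np.var(without.outcomes["y_O"])
        # law of total variance: lognormal mixing adds strictly to the
        # Poisson variance
        assert v1 > v0 * 1.1

    def test_outcome_covariate_rejected(self):
        post = make_post()
        with pytest.raises(ValueError, match="dynamic"):
            predict_pretreatment(post, {"age": [33.0],
                                        "n_oocytes": [9.0]})

    def test_funnel_invariant_all_modes(self):
        post = make_post(theta=(0.5, 0.3, 0.8, 0.9),
                         eta=np.r_[np.zeros(14), 0.2])
        for latents in (True, False):
            d = predict_pretreatment(post, {"age": np.zeros(100)},
                                     n_draws=150,
                                     latents_included=latents, seed=3)
            assert d.check_funnel()

    def test_denominator_conservation_exact(self):
        """P(event per cycle started) = P(reach stage) * P(event|reached),
        as an exact identity on draw counts."""
        post = make_post(theta=(0.5, 0.3, 0.8, 0.9))
        d = predict_pretreatment(post, {"age": np.zeros(300)},
                                 n_draws=200, seed=4)
        lbe = d.outcomes["lbe"]
        reached = ~np.isnan(lbe)
        n_total = lbe.size
        n_events = np.nansum(lbe)
        p_started = n_events / n_total
        p_cond = n_events / reached.sum()
        p_reach = reached.sum() / n_total
        assert p_started == pytest.approx(p_reach * p_cond, abs=1e-15)


class TestDynamic:
    def dynamic_post(self, fert_coef_L=0.8):
        specs = dynamic_specs()
        params = ModelParameters(
            beta_O=[2.09, -0.04, 0.01, 0.06, 0.14, 0.04],
            beta_M=[-1.0, 0.02, 0.0],
            beta_E=[0.0, 0.01, -0.27, 0.09, -0.16],
            beta_F=[-0.03, 0.01, -0.33, 0.22, -0.30],
            beta_D=[0.13, 0.02, -0.01, 0.23, 0.44, 0.60, -0.06, -0.02,
                    -0.14, -0.12],
            beta_L=[-0.49, -0.02, -0.01, 0.04, fert_coef_L, 0.07, 0.04,
                    0.11],
            alpha_E=[-4.35, -1.38, 1.33], alpha_F=[-5.11, -2.44, -0.33],
            theta=[0.5, 0.3, 0.8, 0.9], eta=np.zeros(15))
        scaling = {"age": {"mean": 33.0, "sd": 1.0},
                   "partner_age": {"mean": 35.5, "sd": 1.0},
                   "n_oocytes": {"mean": 9.0, "sd": 5.0},
                   "fert_rate": {"mean": 0.4, "sd": 0.25},
                   "mean_evenness": {"mean": 2.8, "sd": 0.7},
                   "mean_fragmentation": {"mean": 3.2, "sd": 0.7}}
        return posterior_from_parameters(params, specs, scaling,
                                         n_draws=150)

    BASE = {"age": [33.0], "partner_age": [35.5], "attempt": ["1"],
            "icsi": [1.0]}

    def test_observed_zero_oocytes_fails_everything(self):
        post = self.dynamic_post()
        d = predict_dynamic(post, self.BASE, {"n_oocytes": 0},
                            n_draws=100, seed=5)
        assert np.all(d.outcomes["y_O"] == 0)
        for key in ("y_M", "transferred", "det", "lbe"):
            assert np.all(np.isnan(d.outcomes[key]))

    def test_prefix_gap_rejected(self):
        post = self.dynamic_post()
        with pytest.raises(ValueError, match="gap"):
            predict_dynamic(post, self.BASE, {"n_embryos": 3})

    def test_split_grade_pair_rejected(self):
        post = self.dynamic_post()
        with pytest.raises(ValueError, match="together"):
            predict_dynamic(post, self.BASE,
                            {"n_oocytes": 9, "n_embryos": 3,
                             "mean_evenness": 2.5})

    def test_pretreatment_fit_cannot_condition(self):
        post = make_post()
        with pytest.raises(ValueError, match="dynamic-setting"):
            predict_dynamic(post, NOCOV, {"n_oocytes": 9})

    def test_upstream_fixed_at_observed_values(self):
        post = self.dynamic_post()
        obs = {"n_oocytes": 9, "n_embryos": 3,
               "mean_evenness": 3.0, "mean_fragmentation": 3.0, "det": 1}
        d = predict_dynamic(post, self.BASE, obs, n_draws=100, seed=6)
        assert np.all(d.outcomes["y_O"] == 9)
        assert np.all(d.outcomes["y_M"] == 3)
        assert np.all(d.outcomes["det"] == 1)
        assert np.var(d.outcomes["y_O"]) == 0

    def test_fertilisation_rate_effect_sign(self):
        """A positive live-birth coefficient on the fertilisation rate
        must push predicted LBE up as the observed rate rises."""
        post = self.dynamic_post(fert_coef_L=0.8)
        lo = predict_dynamic(post, self.BASE,
                             {"n_oocytes": 10, "n_embryos": 1},
                             n_draws=400, latents_included=False, seed=7)
        hi = predict_dynamic(post, self.BASE,
                             {"n_oocytes": 10, "n_embryos": 9},
                             n_draws=400, latents_included=False, seed=7)
        p_lo = np.nanmean(lo.outcomes["lbe"])
        p_hi = np.nanmean(hi.outcomes["lbe"])
        assert p_hi > p_lo


class TestIntervalsAndEvents:
    def test_degenerate_draws_equal_percentiles(self):
        post = make_post(beta_O=-30.0)
        d = predict_pretreatment(post, NOCOV, n_draws=50, seed=8)
        tab = predictive_intervals(d, outcomes=("y_O",))
        assert tab["p2.5"].iloc[0] == tab["p50"].iloc[0] \
            == tab["p97.5"].iloc[0] == 0.0

    def test_poisson_quantiles_recovered(self):
        lam = np.exp(2.09)
        post = make_post()
        d = predict_pretreatment(post, {"age": np.zeros(100)},
                                 n_draws=150, latents_included=False,
                                 seed=9)
        tab = predictive_intervals(d, outcomes=("y_O",))
        for col, q in (("p2.5", 0.025), ("p50", 0.5), ("p97.5", 0.975)):
            med = np.median(tab[col])
            assert abs(med - poisson.ppf(q, lam)) <= 1.0

    def test_denominator_switch_affects_lbe_not_oocytes(self):
        post = make_post(theta=(0.5, 0.3, 0.8, 0.9))
        d1 = predict_pretreatment(post, {"age": np.zeros(200)},
                                  n_draws=150, seed=10,
                                  denominator="per_cycle_started")
        d2 = predict_pretreatment(post, {"age": np.zeros(200)},
                                  n_draws=150, seed=10,
                                  denominator="per_stage_reached")
        t1 = predictive_intervals(d1).set_index(["cycle_id", "outcome"])
        t2 = predictive_intervals(d2).set_index(["cycle_id", "outcome"])
        y1 = t1.xs("y_O", level="outcome")
        y2 = t2.xs("y_O", level="outcome")
        assert np.allclose(y1.to_numpy(), y2.to_numpy())
        l1 = np.nanmean(t1.xs("lbe", level="outcome")["p50"])
        l2 = np.nanmean(t2.xs("lbe", level="outcome")["p50"])
        assert not np.isclose(l1, l2) or (l1 == 0 and l2 == 0)

    def test_empty_draws_rejected(self):
        post = make_post()
        d = predict_pretreatment(post, NOCOV, n_draws=10, seed=11)
        d.draw_index = d.draw_index[:0]
        with pytest.raises(ValueError, match="empty"):
            predictive_intervals(d)

    def test_false_predicate_degenerate(self):
        post = make_post()
        d = predict_pretreatment(post, {"age": np.zeros(50)},
                                 n_draws=100, seed=12)
        res = joint_event_probability(
            d, lambda o: np.zeros_like(o["y_O"], dtype=bool))
        assert res.estimate == res.lower95 == res.upper95 == 0.0

    def test_safe_stimulation_matches_poisson_cdf(self):
        lam = np.exp(2.09)
        post = make_post()
        d = predict_pretreatment(post, {"age": np.zeros(500)},
                                 n_draws=200, latents_included=False,
                                 seed=13)
        res = joint_event_probability(d, lambda o: o["y_O"] < 15)
        p = poisson.cdf(14, lam)
        n = 500 * 200
        assert abs(res.estimate - p) < 4 * np.sqrt(p * (1 - p) / n)
        assert res.lower95 <= res.estimate <= res.upper95

    def test_frechet_upper_bound(self):
        post = make_post(theta=(0.5, 0.3, 0.8, 0.9),
                         eta=np.r_[np.zeros(14), 0.2])
        for seed in (14, 15, 16):
            d = predict_pretreatment(post, {"age": np.zeros(200)},
                                     n_draws=150, seed=seed)
            both = joint_event_probability(
                d, lambda o: (o["y_O"] < 15) & (o["lbe"] == 1)).estimate
            pa = joint_event_probability(d, lambda o: o["y_O"] < 15)
            pb = joint_event_probability(d, lambda o: o["lbe"] == 1)
            assert both <= min(pa.estimate, pb.estimate) + 1e-12
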