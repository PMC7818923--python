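"""Sequential, denominator-aware prediction from posterior draws.

Predictions are posterior-predictive simulations of whole cycles: for each
retained posterior draw the cycle is simulated forward through the same
generative chain as the synthetic-cohort module, so failure propagates
deterministically — a patient predicted to have no oocytes has no embryos,
no grades, no transfer and no live birth in that draw, never an imputed
value. Two accounting conventions are supported: *per cycle started*
(upstream failure counts as a non-event downstream — the treatment-policy
reading) and *per stage reached* (conditional on getting there). Embryo
grades are only ever summarised conditional on at least one embryo
existing.

Latent variables may be drawn from their fitted multivariate-normal
distribution (``latents_included=True``) or set to zero (marginal
prediction at the linear-predictor scale, without integrating the random
effects); both modes are first-class and the caller chooses. In dynamic
prediction the observed upstream outcomes are plugged into downstream
linear predictors as covariates; the latents of the remaining stages are
*not* filtered on the observed outcomes — conditioning flows through the
covariates only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .inference import PosteriorSamples
from .model import DYNAMIC_SOURCE, build_latent_covariance
from .simulate import simulate_stages

_STAGE_CHAIN = (("n_oocytes",), ("n_embryos",),
                ("mean_evenness", "mean_fragmentation"), ("det",))

OUTCOME_KEYS = ("y_O", "y_M", "transferred", "det", "lbe",
                "even_one", "frag_one", "mean_evenness",
                "mean_fragmentation")


@dataclass
class PredictiveDraws:
    """Simulated cycle outcomes: arrays of shape (n_patients, n_draws).

    NaN marks a stage never reached in that draw. Columns are aligned to
    posterior draws (``draw_index``), one simulation per posterior draw
    per patient, so cohort-level proportions per column are draws from the
    posterior distribution of the predicted cohort fraction.
    """

    outcomes: dict
    patient_ids: list
    draw_index: np.ndarray
    latents_included: bool
    denominator: str = "per_cycle_started"

    @property
    def n_patients(self):
        return len(self.patient_ids)

    @property
    def n_draws(self):
        return len(self.draw_index)

    def check_funnel(self) -> bool:
        """True when every draw respects the stage funnel."""
        o = self.outcomes
        lbe1 = o["lbe"] == 1
        tr1 = o["transferred"] == 1
        emb1 = o["y_M"] >= 1
        oo1 = o["y_O"] >= 1
        return bool(np.all(~lbe1 | tr1) and np.all(~tr1 | emb1)
                    and np.all(~emb1 | oo1))


def _covariate_table(new_covariates):
    if isinstance(new_covariates, pd.DataFrame):
        tab = {k: new_covariates[k].to_numpy() for k in
               new_covariates.columns}
    else:
        tab = {k: np.atleast_1d(np.asarray(v))
               for k, v in dict(new_covariates).items()}
    n = max(len(v) for v in tab.values())
    return {k: np.broadcast_to(v, (n,)).copy() for k, v in tab.items()}, n


def _draw_indices(samples, n_draws, rng):
    total = samples.n_chains * samples.n_draws
    if n_draws >= total:
        return np.arange(total)
    # evenly thin the stacked draws; deterministic given n_draws
    return np.linspace(0, total - 1, n_draws).astype(int)


def _simulate(samples, values, n_pat, n_draws, latents_included, rng,
              observed=None, transfer_prob=1.0):
    idx = _draw_indices(samples, n_draws, rng)
    out = {k: np.full((n_pat, len(idx)), np.nan) for k in OUTCOME_KEYS}
    for col, s in enumerate(idx):
        params = samples.parameters_at(s)
        if latents_included:
            sigma = build_latent_covariance(params.theta, params.eta)
            z = rng.multivariate_normal(np.zeros(6), sigma, size=n_pat,
                                        method="cholesky")
        else:
            z = np.zeros((n_pat, 6))
        sim = simulate_stages(params, samples.specs,
                              samples.covariate_scaling, values, z, rng,
                              transfer_prob=transfer_prob,
                              observed=observed)
        for k in OUTCOME_KEYS:
            out[k][:, col] = sim[k]
    return out, idx


def predict_pretreatment(samples: PosteriorSamples, new_covariates,
                         n_draws=500, latents_included=True, seed=0,
                         denominator="per_cycle_started",
                         transfer_prob=1.0) -> PredictiveDraws:
    """Whole-cycle posterior-predictive simulation from baseline covariates.

    ``new_covariates`` holds only pre-treatment fields (age, partner_age,
    attempt, icsi); supplying outcome covariates is an error — that is the
    dynamic setting.
    """
    tab, n_pat = _covariate_table(new_covariates)
    bad = sorted(set(tab) & set(DYNAMIC_SOURCE))
    if bad:
        raise ValueError(
            f"covariates {bad} are treatment outcomes; use "
            "predict_dynamic for conditioning on accrued stages")
    ids = list(tab.pop("cycle_id", range(1, n_pat + 1)))
    rng = np.random.default_rng(seed)
    out, idx = _simulate(samples, tab, n_pat, n_draws, latents_included,
                         rng, transfer_prob=transfer_prob)
    return PredictiveDraws(out, ids, idx, latents_included, denominator)


def predict_dynamic(samples: PosteriorSamples, new_covariates,
                    observed_upstream: dict, n_draws=500,
                    latents_included=True, seed=0,
                    denominator="per_cycle_started") -> PredictiveDraws:
    """Predict the remaining stages given observed upstream outcomes.

    ``observed_upstream`` must be a stage-consistent prefix — any of
    ``n_oocytes``; plus ``n_embryos``; plus both mean grades; plus
    ``det`` — with no gaps. The fitted model must be a dynamic-setting fit
    whose submodels take the observed outcomes as covariates; observed
    stages are fixed at their values in the output and drive downstream
    linear predictors.
    """
    observed = dict(observed_upstream)
    seen_end = False
    for group in _STAGE_CHAIN:
        has = [g in observed for g in group]
        if any(has) and not all(has):
            raise ValueError(f"outcome group {group} must be observed "
                             "together")
        if all(has):
            if seen_end:
                raise ValueError(
                    "observed_upstream has a gap: "
                    f"{group} observed but an earlier stage is not")
        else:
            seen_end = True
    if not observed:
        raise ValueError("no upstream outcomes supplied; use "
                         "predict_pretreatment")
    used = {c for s in samples.specs.values() for c in s.covariates}
    missing = [k for k in observed if k in DYNAMIC_SOURCE
               and k not in used]
    if missing:
        raise ValueError(
            f"fit does not use {missing} as covariates; a dynamic-setting "
            "fit is required to condition on observed outcomes")
    tab, n_pat = _covariate_table(new_covariates)
    ids = list(tab.pop("cycle_id", range(1, n_pat + 1)))
    rng = np.random.default_rng(seed)
    out, idx = _simulate(samples, tab, n_pat, n_draws, latents_included,
                         rng, observed=observed)
    return PredictiveDraws(out, ids, idx, latents_included, denominator)


def _apply_denominator(draws: PredictiveDraws, key):
    """Outcome draws under the declared accounting convention.

    Per cycle started, pre-transfer failure is a zero count / non-event;
    grades stay conditional on embryos existing in both conventions.
    """
    x = draws.outcomes[key].copy()
    if key in ("even_one", "frag_one", "mean_evenness",
               "mean_fragmentation"):
        return x
    if draws.denominator == "per_cycle_started":
        return np.nan_to_num(x, nan=0.0)
    return x


def predictive_intervals(draws: PredictiveDraws,
                         outcomes=("y_O", "y_M", "even_one", "frag_one",
                                   "det", "lbe")) -> pd.DataFrame:
    """Per-patient 2.5/50/97.5 predictive percentiles per outcome."""
    if draws.n_draws == 0:
        raise ValueError("empty predictive draws")
    rows = []
    for key in outcomes:
        vals = _apply_denominator(draws, key)
        with np.errstate(all="ignore"):
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                q = np.nanpercentile(vals, [2.5, 50, 97.5], axis=1)
        for i, pid in enumerate(draws.patient_ids):
            rows.append({"cycle_id": pid, "outcome": key,
                         "p2.5": q[0, i], "p50": q[1, i],
                         "p97.5": q[2, i]})
    return pd.DataFrame(rows)


@dataclass
class JointEventResult:
    estimate: float
    lower95: float
    upper95: float


def joint_event_probability(draws: PredictiveDraws,
                            predicate: Callable) -> JointEventResult:
    """Probability that a whole-cycle predicate holds, with 95% interval.

    ``predicate`` receives the outcome-array dict and returns a boolean
    (n_patients, n_draws) array; stages never reached are NaN, so
    comparisons there evaluate False — a failed stage is a non-event. The
    interval is the 2.5/97.5 percentile of the predicted cohort proportion
    across posterior draws (columns), the posterior-predictive construction
    used for joint-event statements like "fewer than 15 oocytes and a live
    birth".
    """
    with np.errstate(invalid="ignore"):
        ev = np.asarray(predicate(draws.outcomes), dtype=bool)
    if ev.shape != (draws.n_patients, draws.n_draws):
        raise ValueError("predicate must return an (n_patients, n_draws) "
                         "boolean array")
    frac = ev.mean(axis=0)
    lo, hi = np.percentile(frac, [2.5, 97.5])
    return JointEventResult(float(ev.mean()), float(lo), float(hi))
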