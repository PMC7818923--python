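"""Synthetic IVF cohorts drawn from the full generative model.

The generator runs the joint model forwards, cycle by cycle: draw baseline
covariates, draw the 6-d latent vector, then walk the treatment funnel —
oocyte count, fertilisation (offset-Poisson, truncated so embryos never
exceed oocytes), per-embryo ordinal grades, transfer, DET and live birth
via the probit sign rule. A cycle failing at any stage leaves every
downstream outcome undefined, so generated cohorts always satisfy the
funnel invariants and carry the missing-by-design pattern the sequential
prediction machinery relies on.

Default regression coefficients are the point estimates of the fitted
pre-treatment joint model reported for the motivating clinic cohort (2,962
cycles); default covariate distributions match that cohort's baseline
table (median age 33, partner 35, 72% first attempts, ...). The latent
SDs/correlations were not reported — the defaults theta = (0.5, 0.3, 0.8,
0.9), eta = 0 except a 0.2 DET-live-birth correlation, are placeholders
chosen to give realistic overdispersion, NOT estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, validate
from .design import design_from_values
from .model import (ModelParameters, SubmodelSpec, build_latent_covariance,
                    ordinal_category_probs, pretreatment_specs)

# Upper bound on log Poisson rates: overflow guard only, far above any
# clinically plausible oocyte/embryo count.
_MAX_LOG_RATE = 13.8  # rate <= ~1e6


def default_parameters() -> ModelParameters:
    """Point parameters of the fitted pre-treatment joint model.

    Coefficients are per-unit (ages in years, centred at the default
    covariate means; see ``default_scaling``). Latent SDs / correlations
    are documented placeholders, not estimates.
    """
    return ModelParameters(
        beta_O=[2.10, -0.04, 0.01, 0.06, 0.14, 0.04],
        beta_M=[-0.95, 0.02, -0.00],
        beta_E=[0.00, 0.01, -0.27],
        beta_F=[-0.03, 0.01, -0.33],
        beta_D=[0.13, 0.02, -0.01, 0.23, 0.44, 0.60],
        beta_L=[-0.49, -0.02, -0.01],
        alpha_E=[-4.35, -1.38, 1.33],
        alpha_F=[-5.11, -2.44, -0.33],
        theta=[0.5, 0.3, 0.8, 0.9],
        eta=[0.0] * 14 + [0.2],
    )


def default_scaling() -> dict:
    """Centring (SD 1) at the design means, so coefficients stay per-year."""
    return {"age": {"mean": 33.0, "sd": 1.0},
            "partner_age": {"mean": 35.5, "sd": 1.0}}


@dataclass
class CovariateModel:
    """Baseline covariate distributions, matched to the clinic cohort's
    summary table: ages are rounded truncated normals, attempt number a
    four-category draw (4th/5th pooled), ICSI a cycle-level coin flip."""

    age_mean: float = 33.0
    age_sd: float = 4.4
    age_range: tuple = (21.0, 43.0)
    partner_age_mean: float = 35.5
    partner_age_sd: float = 5.2
    partner_age_range: tuple = (19.0, 72.0)
    attempt_probs: tuple = (0.7198, 0.2225, 0.0496, 0.0081)
    icsi_prob: float = 0.5

    def draw(self, n, rng):
        def trunc(mean, sd, lo, hi):
            x = rng.normal(mean, sd, size=n)
            bad = (x < lo) | (x > hi)
            while bad.any():
                x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
                bad = (x < lo) | (x > hi)
            return np.round(x)

        p = np.asarray(self.attempt_probs, dtype=float)
        p = p / p.sum()
        cats = np.array(["1", "2", "3", "4-5"], dtype=object)
        return {
            "age": trunc(self.age_mean, self.age_sd, *self.age_range),
            "partner_age": trunc(self.partner_age_mean, self.partner_age_sd,
                                 *self.partner_age_range),
            "attempt": cats[rng.choice(4, size=n, p=p)],
            "icsi": rng.binomial(1, self.icsi_prob, size=n).astype(float),
        }


@dataclass
class GeneratorConfig:
    """Everything needed to simulate a cohort reproducibly."""

    n_cycles: int
    params: ModelParameters = field(default_factory=default_parameters)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    scaling: dict = field(default_factory=default_scaling)
    specs: Optional[dict] = None          # default: pre-treatment specs
    transfer_prob: float = 1.0            # thinning of embryo->transfer
    seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.specs is None:
            self.specs = pretreatment_specs()

    def to_yaml(self, path):
        doc = {
            "n_cycles": int(self.n_cycles),
            "params": self.params.to_dict(),
            "covariate_model": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.covariate_model).items()},
            "scaling": self.scaling,
            "specs": {o: list(s.covariates) for o, s in self.specs.items()},
            "transfer_prob": float(self.transfer_prob),
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cm = doc.get("covariate_model", {})
        for k in ("age_range", "partner_age_range", "attempt_probs"):
            if k in cm:
                cm[k] = tuple(cm[k])
        specs = doc.get("specs")
        if specs is not None:
            specs = {o: SubmodelSpec(o, tuple(c)) for o, c in specs.items()}
        return cls(
            n_cycles=doc["n_cycles"],
            params=ModelParameters.from_dict(doc["params"]),
            covariate_model=CovariateModel(**cm),
            scaling=doc.get("scaling", default_scaling()),
            specs=specs,
            transfer_prob=doc.get("transfer_prob", 1.0),
            seed=doc.get("seed", 0),
        )


def _truncated_poisson(rate, upper, rng, max_tries=200):
    """Poisson draws conditioned on <= upper (element-wise rejection)."""
    y = rng.poisson(rate)
    bad = y > upper
    tries = 0
    while bad.any() and tries < max_tries:
        y[bad] = rng.poisson(rate[bad])
        bad = y > upper
        tries += 1
    y[bad] = upper[bad]  # pathological rates only; clamp rather than hang
    return y


def _draw_grades(probs, rng):
    """Categorical grade draws (1-4) from an (n, 4) probability array."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    return 1 + (u[:, None] > cum[:, :3]).sum(axis=1)


def simulate_stages(params, specs, scaling, values, z, rng,
                    transfer_prob=1.0, observed=None):
    """Run the sequential generative chain for a batch of cycles.

    ``values`` maps baseline covariate names to (n,) arrays; ``z`` is the
    (n, 6) latent matrix. ``observed`` optionally fixes a stage-consistent
    prefix of outcomes (dynamic prediction): any of ``n_oocytes``,
    ``n_embryos``, ``mean_evenness``+``mean_fragmentation``, ``det``; fixed
    stages are not simulated and feed downstream dynamic covariates.

    Returns a dict of (n,) float arrays (NaN = stage not reached):
    ``y_O, mixed, y_M, transferred, det, lbe, mean_evenness,
    mean_fragmentation, even_one, frag_one`` plus the per-embryo arrays
    ``embryo_parent, evenness, fragmentation``. ``even_one``/``frag_one``
    are one hypothetical embryo's grades per cycle with embryos.
    """
    observed = dict(observed or {})
    n = len(z)
    values = dict(values)

    def X(outcome, n_rows=n):
        return design_from_values(specs[outcome], values, scaling,
                                  n_rows=n_rows)

    # --- stimulation ---
    if "n_oocytes" in observed:
        y_o = np.broadcast_to(
            np.asarray(observed["n_oocytes"], dtype=float), (n,)).copy()
    else:
        lp = np.minimum(X("O") @ params.beta_O + z[:, 0], _MAX_LOG_RATE)
        y_o = rng.poisson(np.exp(lp)).astype(float)
    has_oo = y_o >= 1
    mixed = np.where(has_oo, 1.0, np.nan)
    values["n_oocytes"] = y_o

    # --- fertilisation ---
    y_m = np.full(n, np.nan)
    if "n_embryos" in observed:
        y_m[has_oo] = np.broadcast_to(
            np.asarray(observed["n_embryos"], dtype=float), (n,))[has_oo]
    elif has_oo.any():
        lp = (np.log(np.maximum(y_o, 1.0)) + X("M") @ params.beta_M
              + z[:, 1])
        lp = np.minimum(lp, _MAX_LOG_RATE)
        y_m[has_oo] = _truncated_poisson(
            np.exp(lp[has_oo]), y_o[has_oo], rng)
    has_emb = y_m >= 1
    values["fert_rate"] = np.where(has_oo, y_m / np.maximum(y_o, 1.0),
                                   np.nan)

    # --- embryo grading ---
    mean_e = np.full(n, np.nan)
    mean_f = np.full(n, np.nan)
    even_one = np.full(n, np.nan)
    frag_one = np.full(n, np.nan)
    parent = np.zeros(0, dtype=int)
    grades_e = np.zeros(0, dtype=int)
    grades_f = np.zeros(0, dtype=int)
    if "mean_evenness" in observed:
        mean_e[has_emb] = np.broadcast_to(
            np.asarray(observed["mean_evenness"], dtype=float), (n,))[has_emb]
        mean_f[has_emb] = np.broadcast_to(
            np.asarray(observed["mean_fragmentation"], dtype=float),
            (n,))[has_emb]
    elif has_emb.any():
        counts = y_m.copy()
        counts[~has_emb] = 0
        counts = counts.astype(int)
        parent = np.repeat(np.arange(n), counts)
        lp_e = X("E") @ params.beta_E + z[:, 2]
        lp_f = X("F") @ params.beta_F + z[:, 3]
        ones = np.ones((len(parent), 1))
        pe = ordinal_category_probs(params.alpha_E, ones, [0.0],
                                    lp_e[parent])
        pf = ordinal_category_probs(params.alpha_F, ones, [0.0],
                                    lp_f[parent])
        grades_e = _draw_grades(pe, rng)
        grades_f = _draw_grades(pf, rng)
        sums_e = np.bincount(parent, weights=grades_e, minlength=n)
        sums_f = np.bincount(parent, weights=grades_f, minlength=n)
        with np.errstate(invalid="ignore"):
            mean_e = np.where(has_emb, sums_e / np.maximum(y_m, 1.0), np.nan)
            mean_f = np.where(has_emb, sums_f / np.maximum(y_m, 1.0), np.nan)
        # one hypothetical embryo's grade per cycle with embryos
        onesn = np.ones((n, 1))
        pe1 = ordinal_category_probs(params.alpha_E, onesn, [0.0], lp_e)
        pf1 = ordinal_category_probs(params.alpha_F, onesn, [0.0], lp_f)
        ge1 = _draw_grades(pe1, rng).astype(float)
        gf1 = _draw_grades(pf1, rng).astype(float)
        even_one = np.where(has_emb, ge1, np.nan)
        frag_one = np.where(has_emb, gf1, np.nan)
    values["mean_evenness"] = mean_e
    values["mean_fragmentation"] = mean_f

    # --- transfer decision ---
    if "det" in observed:
        transferred = np.where(has_emb, 1.0, np.nan)
    else:
        thin = (rng.random(n) < transfer_prob) if transfer_prob < 1.0 \
            else np.ones(n, dtype=bool)
        transferred = np.where(has_emb, (thin & has_emb).astype(float),
                               np.nan)
    is_tr = transferred == 1

    # --- DET (sign rule; a single embryo forces a single transfer) ---
    det = np.full(n, np.nan)
    if "det" in observed:
        det[is_tr] = np.broadcast_to(
            np.asarray(observed["det"], dtype=float), (n,))[is_tr]
    elif is_tr.any():
        ystar = X("D") @ params.beta_D + z[:, 4]
        det[is_tr] = (ystar[is_tr] >= 0).astype(float)
        det[is_tr & (y_m == 1)] = 0.0
    values["det"] = det

    # --- live birth ---
    lbe = np.full(n, np.nan)
    if is_tr.any():
        ystar = X("L") @ params.beta_L + z[:, 5]
        lbe[is_tr] = (ystar[is_tr] >= 0).astype(float)

    return {
        "y_O": y_o, "mixed": mixed, "y_M": y_m, "transferred": transferred,
        "det": det, "lbe": lbe, "mean_evenness": mean_e,
        "mean_fragmentation": mean_f, "even_one": even_one,
        "frag_one": frag_one, "embryo_parent": parent,
        "evenness": grades_e, "fragmentation": grades_f,
    }


def simulate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a full cohort from the generative model (bit-reproducible).

    The default transfer rule is deterministic (every cycle with at least
    one embryo proceeds to transfer); ``transfer_prob < 1`` thins the
    embryo-to-transfer transition to emulate the observed gap between
    cycles with embryos and transfer procedures.
    """
    params = config.params
    params.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cycles
    if n == 0:
        return Cohort.from_records([], [],
                                   covariate_scaling=dict(config.scaling))
    values = config.covariate_model.draw(n, rng)
    sigma = build_latent_covariance(params.theta, params.eta)
    z = rng.multivariate_normal(np.zeros(6), sigma, size=n,
                                method="cholesky")
    sim = simulate_stages(params, config.specs, config.scaling, values, z,
                          rng, transfer_prob=config.transfer_prob)

    ids = np.array([str(i) for i in range(1, n + 1)], dtype=object)

    def as_int64(x):
        return pd.array(x, dtype="Int64")

    cyc = pd.DataFrame({
        "cycle_id": ids,
        "age": values["age"].astype(float),
        "partner_age": values["partner_age"].astype(float),
        "attempt": pd.Series(values["attempt"], dtype=object).astype(str),
        "n_oocytes": as_int64(sim["y_O"].astype(int)),
        "mixed": as_int64(np.round(sim["mixed"])),
        "n_embryos": as_int64(np.round(sim["y_M"])),
        "transferred": as_int64(np.round(sim["transferred"])),
        "det": as_int64(np.round(sim["det"])),
        "lbe": as_int64(np.round(sim["lbe"])),
    })
    parent = sim["embryo_parent"]
    emb = pd.DataFrame({
        "cycle_id": ids[parent] if len(parent) else np.array([], dtype=str),
        "evenness": as_int64(sim["evenness"]),
        "fragmentation": as_int64(sim["fragmentation"]),
        "icsi": as_int64(values["icsi"][parent].astype(int)
                         if len(parent) else []),
    })
    cohort = Cohort(cyc, emb, covariate_scaling=dict(config.scaling))
    validate(cohort)
    return cohort
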