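"""MCMC fitting of the joint model and the separate-model baselines.

No external probabilistic-programming backend is assumed: the module
implements a blocked Gibbs/Metropolis sampler targeting the posterior
implied by the submodel likelihoods and the default priors —

* normal(0, 1000^2) on the count/ordinal regression coefficients and the
  ordinal thresholds (effectively flat);
* normal(0, 2^2) on the probit (DET, live birth) coefficients, weakly
  informative because the probit latent variance is pinned at 1;
* half-Cauchy(0, 2.5) on the free latent SDs theta;
* LKJ(1) — uniform over valid correlation matrices — on the latent
  correlations, with the probit variances fixed at 1.

Update scheme per iteration: the probit blocks use Albert–Chib data
augmentation (truncated-normal draws of the latent utilities, conjugate
normal draws of their coefficients, conditioned on the remaining latent
components through the multivariate-normal conditionals); the Poisson and
cumulative-logit coefficient blocks use adaptive random-walk Metropolis
with an empirical-covariance proposal learned during warmup; the patient
latents are updated with per-patient random-walk Metropolis, vectorised
across patients; theta moves on the log scale and each free correlation by
scalar Metropolis with positive-definiteness rejection (the LKJ(1) prior
is flat over the valid set).

The probit likelihood contract is the data-augmentation route: z_D and
z_L are sampled explicitly and the observed indicators follow the
deterministic sign rule. Tests verify its agreement with the analytic
marginalisation route evaluated by the likelihood module.

Separate-model baselines reuse the same machinery with a single outcome
active: a Poisson/offset-Poisson model with a lognormal random intercept,
a cumulative-logit model with a patient random intercept, or (for DET and
live birth) an exact Bayesian probit regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .cohort import Cohort, EmptyCohortError
from .design import compute_scaling, cycle_design, embryo_design
from .model import ETA_PAIRS, ModelParameters, OUTCOMES, OUTCOME_INDEX

_COUNT_ORDINAL = ("O", "M", "E", "F")
_PROBIT = ("D", "L")


class DegenerateDataError(ValueError):
    """An active outcome shows no variation, so its submodel is unfittable."""


@dataclass
class PriorSpec:
    """Prior hyperparameters (defaults as documented in the module)."""

    sd_beta: dict = field(default_factory=lambda: {
        "O": 1000.0, "M": 1000.0, "E": 1000.0, "F": 1000.0,
        "D": 2.0, "L": 2.0})
    sd_alpha: float = 1000.0
    theta_scale: float = 2.5
    lkj_shape: float = 1.0


def build_priors(specs=None) -> PriorSpec:
    """Default prior specification for a given submodel layout."""
    return PriorSpec()


@dataclass
class FitConfig:
    """Sampler configuration.

    ``iterations`` counts post-warmup draws per chain; warmup adds
    ``warmup_frac`` of that on top (adaptation happens only there).
    ``fix_eta`` freezes the latent correlations (e.g. at zero, which
    factorises the joint model); ``None`` samples them under LKJ(1).
    """

    mode: str = "joint"                  # "joint" | "separate"
    setting: str = "pretreatment"        # "pretreatment" | "dynamic"
    chains: int = 3
    iterations: int = 1000
    warmup_frac: float = 1.0
    seed: int = 0
    prior: PriorSpec = field(default_factory=PriorSpec)
    fix_eta: Optional[np.ndarray] = None
    rhat_threshold: float = 1.05
    save_latents: bool = False

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for the "
                             "convergence diagnostic")


class PosteriorSamples:
    """Per-chain posterior draws plus the metadata needed to reuse them.

    ``draws`` maps block names (``beta_O`` ... ``alpha_F``, ``theta``,
    ``eta``) to arrays of shape (chains, iterations, dim). The covariate
    scaling and submodel specs used in fitting travel with the draws so
    predictions evaluate linear predictors on the identical scale.
    """

    def __init__(self, draws, specs, covariate_scaling, active,
                 diagnostics=None):
        self.draws = draws
        self.specs = specs
        self.covariate_scaling = covariate_scaling
        self.active = tuple(active)
        self.diagnostics = diagnostics or {}

    @property
    def n_chains(self):
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self):
        return next(iter(self.draws.values())).shape[1]

    def stacked(self, name):
        a = self.draws[name]
        if a.shape[-1] == 0:
            return np.zeros((a.shape[0] * a.shape[1], 0))
        return a.reshape(-1, a.shape[-1])

    def scalar_draws(self):
        """Yield (name, (chains, iterations) array) per scalar parameter.

        Placeholder blocks of inactive outcomes (separate fits) and frozen
        correlation entries are skipped.
        """
        for name, arr in self.draws.items():
            if name.startswith(("beta_", "alpha_")) \
                    and name.split("_")[-1] not in self.active:
                continue
            if name == "theta":
                for i, o in enumerate(("O", "M", "E", "F")):
                    if o in self.active:
                        yield f"theta_{o}", arr[:, :, i]
                continue
            if name == "eta":
                if np.ptp(arr) == 0:  # frozen correlations
                    continue
                for m, (i, j) in enumerate(ETA_PAIRS):
                    if np.ptp(arr[:, :, m]) > 0:
                        yield (f"eta_{OUTCOMES[i]}{OUTCOMES[j]}",
                               arr[:, :, m])
                continue
            labels = self._labels(name)
            for k, lab in enumerate(labels):
                yield lab, arr[:, :, k]

    def _labels(self, name):
        dim = self.draws[name].shape[-1]
        if name.startswith("beta_"):
            out = name[5:]
            cols = self.specs[out].column_names
            if len(cols) != dim:  # placeholder block of an inactive outcome
                return [f"{name}[{k}]" for k in range(dim)]
            return [f"{name}[{c}]" for c in cols]
        if name.startswith("alpha_"):
            return [f"{name}[{k}]" for k in (1, 2, 3)]
        if name == "theta":
            return [f"theta_{o}" for o in ("O", "M", "E", "F")]
        if name == "eta":
            return [f"eta_{OUTCOMES[i]}{OUTCOMES[j]}" for i, j in ETA_PAIRS]
        return [f"{name}[{k}]" for k in range(
            self.draws[name].shape[-1])]

    def rhat(self) -> dict:
        return {lab: split_rhat(arr) for lab, arr in self.scalar_draws()}

    def parameters_at(self, index) -> ModelParameters:
        """ModelParameters for one stacked draw (standardised scale)."""
        kw = {}
        for name in ("beta_O", "beta_M", "beta_E", "beta_F", "beta_D",
                     "beta_L", "alpha_E", "alpha_F", "theta", "eta"):
            kw[name] = self.stacked(name)[index]
        return ModelParameters(**kw)

    def summary(self, original_scale=True) -> pd.DataFrame:
        return summarise_posterior(self, self.covariate_scaling
                                   if original_scale else None)

    def save(self, prefix):
        """Write draws to ``<prefix>.npz`` and metadata to
        ``<prefix>.json``."""
        import json
        np.savez_compressed(f"{prefix}.npz", **self.draws)
        meta = {
            "specs": {o: list(s.covariates)
                      for o, s in self.specs.items()},
            "covariate_scaling": self.covariate_scaling,
            "active": list(self.active),
            "rhat": {k: (None if not np.isfinite(v) else float(v))
                     for k, v in self.diagnostics.get("rhat", {}).items()},
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix):
        import json
        from .model import SubmodelSpec
        with np.load(f"{prefix}.npz") as z:
            draws = {k: z[k] for k in z.files}
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        specs = {o: SubmodelSpec(o, tuple(c))
                 for o, c in meta["specs"].items()}
        return cls(draws, specs, meta["covariate_scaling"],
                   meta["active"],
                   diagnostics={"rhat": meta.get("rhat", {})})


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    Each chain is split in half; R-hat compares between- and within-half
    variances. Constant chains yield NaN with a warning (zero variance
    leaves the diagnostic undefined).
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains >= 2, draws) array")
    n = x.shape[1] // 2
    if n < 2:
        raise ValueError("need at least 4 draws per chain")
    halves = np.vstack([x[:, :n], x[:, n:2 * n]])
    w = halves.var(axis=1, ddof=1).mean()
    if w == 0:
        warnings.warn("zero within-chain variance; R-hat undefined")
        return float("nan")
    b = n * halves.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def summarise_posterior(samples: PosteriorSamples,
                        covariate_scaling=None) -> pd.DataFrame:
    """Posterior medians and central 95% intervals per scalar parameter.

    When a covariate scaling is supplied, coefficients of standardised
    continuous covariates are divided by the covariate SD, i.e. reported
    per original unit (per year of age, etc.).
    """
    rh = samples.rhat()
    rows = []
    for lab, arr in samples.scalar_draws():
        v = arr.reshape(-1).astype(float)
        scale = 1.0
        if covariate_scaling and "[" in lab:
            col = lab[lab.index("[") + 1:-1]
            base = col  # design column name == covariate name for continuous
            if base in covariate_scaling:
                scale = 1.0 / covariate_scaling[base]["sd"]
        v = v * scale
        lo, med, hi = np.percentile(v, [2.5, 50, 97.5])
        rows.append({"parameter": lab, "median": med, "lower95": lo,
                     "upper95": hi, "rhat": rh[lab]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Data preparation


class _ModelData:
    """Cohort flattened into the arrays the sampler consumes."""

    def __init__(self, cohort: Cohort, specs: dict, active,
                 scaling=None):
        if cohort.n_cycles == 0:
            raise EmptyCohortError("cannot fit to an empty cohort")
        self.specs = specs
        self.active = tuple(active)
        self.scaling = scaling if scaling is not None \
            else compute_scaling(cohort)
        cyc = cohort.cycles
        self.n = len(cyc)
        self.y_O = cyc["n_oocytes"].to_numpy(dtype=float)
        self.mixed = (cyc["mixed"] == 1).to_numpy(dtype=bool,
                                                  na_value=False)
        self.y_M = cyc["n_embryos"].astype(float).to_numpy(
            na_value=np.nan)
        self.transferred = (cyc["transferred"] == 1).to_numpy(
            dtype=bool, na_value=False)
        self.y_D = cyc["det"].astype(float).to_numpy(na_value=np.nan)
        self.y_L = cyc["lbe"].astype(float).to_numpy(na_value=np.nan)

        self.X = {}
        for o in ("O", "M", "D", "L"):
            if o in active:
                self.X[o] = cycle_design(cohort, specs[o], self.scaling)
        self.grades = {}
        if "E" in active or "F" in active:
            for o, col in (("E", "evenness"), ("F", "fragmentation")):
                if o not in active:
                    continue
                X, parent = embryo_design(cohort, specs[o], self.scaling)
                self.X[o] = X
                self.parent = parent
                self.grades[o] = cohort.embryos[col].to_numpy(dtype=int)
            self.has_emb = np.zeros(self.n, dtype=bool)
            if cohort.n_embryos:
                self.has_emb[np.unique(self.parent)] = True
        else:
            self.parent = np.zeros(0, dtype=int)
            self.has_emb = np.zeros(self.n, dtype=bool)
        # NaN guard: design rows only matter inside each submodel's mask
        for o in self.X:
            mask = self.lik_mask(o)
            if np.isnan(self.X[o][mask] if o not in ("E", "F")
                        else self.X[o]).any():
                raise ValueError(
                    f"design matrix for submodel {o} contains undefined "
                    "covariates inside its fitting population")
        self._check_degenerate()

    def lik_mask(self, outcome):
        if outcome == "O":
            return np.ones(self.n, dtype=bool)
        if outcome == "M":
            return self.mixed
        if outcome in ("E", "F"):
            return self.has_emb
        return self.transferred

    def _check_degenerate(self):
        for o in self.active:
            if o == "O" and np.ptp(self.y_O) == 0:
                raise DegenerateDataError("no variation in oocyte counts")
            if o == "M" and (not self.mixed.any()
                             or np.ptp(self.y_M[self.mixed]) == 0):
                raise DegenerateDataError("no variation in embryo counts")
            if o in ("E", "F") and (o not in self.grades
                                    or len(np.unique(self.grades[o])) < 2):
                raise DegenerateDataError(f"no variation in {o} grades")
            if o in _PROBIT:
                y = self.y_D if o == "D" else self.y_L
                vals = np.unique(y[self.transferred])
                if len(vals) < 2:
                    raise DegenerateDataError(
                        f"outcome {o} shows a single class among "
                        "transferred cycles")


# ---------------------------------------------------------------------------
# The sampler


class _BlockSampler:
    def __init__(self, data: _ModelData, prior: PriorSpec, fix_eta=None):
        self.d = data
        self.prior = prior
        self.fix_eta = None if fix_eta is None \
            else np.asarray(fix_eta, dtype=float)
        self.act_idx = [OUTCOME_INDEX[o] for o in data.active]
        self.free_theta = [i for i, o in enumerate(_COUNT_ORDINAL)
                           if o in data.active]
        # eta indices whose both endpoints are active (only those matter)
        self.free_eta = [m for m, (i, j) in enumerate(ETA_PAIRS)
                         if i in self.act_idx and j in self.act_idx]

    # --- likelihood pieces (per patient, conditional on latents) ---

    def _ll_O(self, beta, z_col):
        lp = self.d.X["O"] @ beta + z_col
        return self.d.y_O * lp - np.exp(np.minimum(lp, 50.0))

    def _ll_M(self, beta, z_col):
        out = np.zeros(self.d.n)
        m = self.d.mixed
        lp = (np.log(self.d.y_O[m]) + self.d.X["M"][m] @ beta + z_col[m])
        out[m] = self.d.y_M[m] * lp - np.exp(np.minimum(lp, 50.0))
        return out

    def _ll_ordinal(self, outcome, beta, alpha, z_col):
        """Per-patient sums of embryo ordinal log-probabilities."""
        lp = self.d.X[outcome] @ beta + z_col[self.d.parent]
        per_embryo = _ordinal_logpmf(self.d.grades[outcome], alpha, lp)
        return np.bincount(self.d.parent, weights=per_embryo,
                           minlength=self.d.n)

    def _ll_outcome(self, o, state, z_col=None):
        z = state["z"]
        if o == "O":
            return self._ll_O(state["beta"]["O"],
                              z[:, 0] if z_col is None else z_col)
        if o == "M":
            return self._ll_M(state["beta"]["M"],
                              z[:, 1] if z_col is None else z_col)
        c = OUTCOME_INDEX[o]
        return self._ll_ordinal(o, state["beta"][o], state["alpha"][o],
                                z[:, c] if z_col is None else z_col)

    # --- covariance bookkeeping ---

    def _sigma_act(self, theta, eta):
        sd = np.concatenate([theta, [1.0, 1.0]])
        corr = np.eye(6)
        for m, (i, j) in enumerate(ETA_PAIRS):
            corr[i, j] = corr[j, i] = eta[m]
        sig = corr * np.outer(sd, sd)
        return sig[np.ix_(self.act_idx, self.act_idx)]

    def _refresh_cov(self, state):
        sig = self._sigma_act(state["theta"], state["eta"])
        state["sigma_act"] = sig
        state["lambda_act"] = np.linalg.inv(sig)
        sign, logdet = np.linalg.slogdet(sig)
        state["logdet_act"] = logdet

    def _cond(self, state, o):
        """Conditional N(mu, s2) of component o's latent given the rest."""
        pos = self.act_idx.index(OUTCOME_INDEX[o])
        lam = state["lambda_act"]
        z = state["z"][:, self.act_idx]
        prec = lam[pos, pos]
        s2 = 1.0 / prec
        mu = -(z @ lam[:, pos] - z[:, pos] * prec) * s2
        return mu, s2

    def _z_prior_loglik(self, state, sigma=None, logdet=None):
        z = state["z"][:, self.act_idx]
        if sigma is None:
            lam, logdet = state["lambda_act"], state["logdet_act"]
        else:
            lam = np.linalg.inv(sigma)
            _, logdet = np.linalg.slogdet(sigma)
        quad = float(np.sum((z @ lam) * z))
        return -0.5 * (self.d.n * logdet + quad)

    # --- updates ---

    def _update_z_mh(self, o, state, rng, steps, adapt, it):
        c = OUTCOME_INDEX[o]
        mu, s2 = self._cond(state, o)
        sd = np.sqrt(s2)
        mask = self.d.lik_mask(o)
        z = state["z"]
        # exact conditional-prior draw where the outcome carries no data
        free = ~mask
        if free.any():
            z[free, c] = mu[free] + sd * rng.standard_normal(int(free.sum()))
        if not mask.any():
            return
        cur = z[:, c].copy()
        prop = cur + steps[o] * rng.standard_normal(self.d.n)
        ll_cur = self._ll_outcome(o, state)
        ll_prop = self._ll_outcome(o, state, z_col=prop)
        logr = (ll_prop - ll_cur
                - 0.5 * ((prop - mu) ** 2 - (cur - mu) ** 2) / s2)
        acc = (np.log(rng.random(self.d.n)) < logr) & mask
        z[acc, c] = prop[acc]
        if adapt:
            rate = float(acc[mask].mean())
            steps[o] *= np.exp(self._gamma(it) * (rate - 0.44))

    def _update_probit(self, o, state, rng):
        """Albert–Chib: truncated-normal utilities, conjugate coefficients."""
        c = OUTCOME_INDEX[o]
        z = state["z"]
        mu, s2 = self._cond(state, o)
        sd = np.sqrt(s2)
        tr = self.d.transferred
        free = ~tr
        if free.any():
            z[free, c] = mu[free] + sd * rng.standard_normal(int(free.sum()))
        if not tr.any():
            return
        X = self.d.X[o][tr]
        beta = state["beta"][o]
        y = (self.d.y_D if o == "D" else self.d.y_L)[tr]
        m = X @ beta + mu[tr]
        a = ndtr(-m / sd)  # P(utility < 0)
        u01 = rng.random(int(tr.sum()))
        p = np.where(y == 1, a + u01 * (1 - a), u01 * a)
        p = np.clip(p, 1e-15, 1 - 1e-15)
        u = m + sd * ndtri(p)
        # conjugate draw of beta given utilities
        resid = u - mu[tr]
        prior_prec = 1.0 / self.prior.sd_beta[o] ** 2
        A = X.T @ X / s2 + prior_prec * np.eye(X.shape[1])
        b = X.T @ resid / s2
        L = np.linalg.cholesky(A)
        mean = np.linalg.solve(A, b)
        beta_new = mean + np.linalg.solve(
            L.T, rng.standard_normal(X.shape[1]))
        state["beta"][o] = beta_new
        z[tr, c] = u - X @ beta_new

    def _update_beta_block(self, o, state, rng, blocks, adapt, it):
        blk = blocks[o]
        cur = np.concatenate([state["beta"][o], state["alpha"][o]]) \
            if o in ("E", "F") else state["beta"][o].copy()
        prop = cur + blk["scale"] * (blk["chol"] @
                                     rng.standard_normal(len(cur)))
        p = len(state["beta"][o])
        if o in ("E", "F"):
            alpha_prop = prop[p:]
            if np.any(np.diff(alpha_prop) <= 0):
                self._adapt_block(blk, 0.0, adapt, it, cur)
                return
            beta_prop = prop[:p]
        else:
            beta_prop, alpha_prop = prop, None
        ll_cur = float(self._ll_outcome(o, state).sum())
        st2 = {"beta": dict(state["beta"]), "alpha": dict(state["alpha"]),
               "z": state["z"]}
        st2["beta"][o] = beta_prop
        if alpha_prop is not None:
            st2["alpha"][o] = alpha_prop
        ll_prop = float(self._ll_outcome(o, st2).sum())
        sd_b = self.prior.sd_beta[o]
        lp_cur = -0.5 * np.sum(state["beta"][o] ** 2) / sd_b ** 2
        lp_prop = -0.5 * np.sum(beta_prop ** 2) / sd_b ** 2
        if alpha_prop is not None:
            lp_cur += -0.5 * np.sum(
                state["alpha"][o] ** 2) / self.prior.sd_alpha ** 2
            lp_prop += -0.5 * np.sum(alpha_prop ** 2) / self.prior.sd_alpha ** 2
        logr = ll_prop - ll_cur + lp_prop - lp_cur
        if np.log(rng.random()) < logr:
            state["beta"][o] = beta_prop
            if alpha_prop is not None:
                state["alpha"][o] = alpha_prop
            self._adapt_block(blk, 1.0, adapt, it, prop)
        else:
            self._adapt_block(blk, 0.0, adapt, it, cur)

    def _update_beta_scalar(self, o, state, rng, steps, adapt, it):
        """Component-wise refinement pass; helps sparse dummy columns."""
        p = len(state["beta"][o])
        ll_cur = float(self._ll_outcome(o, state).sum())
        sd_b = self.prior.sd_beta[o]
        for k in range(p):
            key = f"{o}[{k}]"
            step = steps.setdefault(key, 0.1)
            beta_prop = state["beta"][o].copy()
            beta_prop[k] += step * rng.standard_normal()
            st2 = {"beta": dict(state["beta"]),
                   "alpha": state["alpha"], "z": state["z"]}
            st2["beta"][o] = beta_prop
            ll_prop = float(self._ll_outcome(o, st2).sum())
            logr = (ll_prop - ll_cur
                    - 0.5 * (beta_prop[k] ** 2
                             - state["beta"][o][k] ** 2) / sd_b ** 2)
            acc = np.log(rng.random()) < logr
            if acc:
                state["beta"][o] = beta_prop
                ll_cur = ll_prop
            if adapt:
                steps[key] *= np.exp(self._gamma(it) * (float(acc) - 0.44))

    def _update_recenter(self, o, state, rng, steps, adapt, it):
        """Shift the intercept (or thresholds) against the latent column.

        The move leaves the data likelihood invariant, so the acceptance
        ratio involves only the latent MVN prior and the coefficient
        prior; it decorrelates the slowest posterior direction (overall
        level vs. latent mean).
        """
        c = OUTCOME_INDEX[o]
        key = f"shift_{o}"
        step = steps.setdefault(key, 0.1)
        delta = step * rng.standard_normal()
        z_prior_cur = self._z_prior_loglik(state)
        zc = state["z"][:, c].copy()
        state["z"][:, c] = zc + delta
        z_prior_prop = self._z_prior_loglik(state)
        if o in ("E", "F"):
            # likelihood uses alpha_k - x.beta - z: shift both alpha and z
            lp_cur = -0.5 * np.sum(
                state["alpha"][o] ** 2) / self.prior.sd_alpha ** 2
            alpha_prop = state["alpha"][o] + delta
            lp_prop = -0.5 * np.sum(alpha_prop ** 2) / self.prior.sd_alpha ** 2
        else:
            sd_b = self.prior.sd_beta[o]
            b0 = state["beta"][o][0]
            lp_cur = -0.5 * b0 ** 2 / sd_b ** 2
            lp_prop = -0.5 * (b0 - delta) ** 2 / sd_b ** 2
        logr = z_prior_prop - z_prior_cur + lp_prop - lp_cur
        acc = np.log(rng.random()) < logr
        if acc:
            if o in ("E", "F"):
                state["alpha"][o] = state["alpha"][o] + delta
            else:
                state["beta"][o] = state["beta"][o].copy()
                state["beta"][o][0] -= delta
        else:
            state["z"][:, c] = zc
        if adapt:
            steps[key] *= np.exp(self._gamma(it) * (float(acc) - 0.44))

    def _update_rescale(self, o, state, rng, steps, adapt, it):
        """Joint multiplicative move on (theta_c, z_c).

        Scaling both the latent SD and the whole latent column explores the
        funnel-shaped (theta, z) geometry that single-site updates traverse
        slowly. Acceptance uses the data likelihood, the latent MVN prior,
        the half-Cauchy prior and the a^(n+1) Jacobian of the scaling map.
        """
        i = _COUNT_ORDINAL.index(o)
        c = OUTCOME_INDEX[o]
        key = f"rescale_{o}"
        step = steps.setdefault(key, 0.1)
        a = np.exp(step * rng.standard_normal())
        theta_prop = state["theta"].copy()
        theta_prop[i] *= a
        sigma_new = self._sigma_act(theta_prop, state["eta"])
        ll_cur = float(self._ll_outcome(o, state).sum())
        zp_cur = self._z_prior_loglik(state)
        zc = state["z"][:, c].copy()
        state["z"][:, c] = zc * a
        ll_prop = float(self._ll_outcome(o, state).sum())
        zp_prop = self._z_prior_loglik(state, sigma=sigma_new)

        def lp(t):
            return -np.log1p((t / self.prior.theta_scale) ** 2)

        logr = (ll_prop - ll_cur + zp_prop - zp_cur
                + lp(theta_prop[i]) - lp(state["theta"][i])
                + (self.d.n + 1) * np.log(a))
        acc = np.log(rng.random()) < logr
        if acc:
            state["theta"] = theta_prop
            self._refresh_cov(state)
        else:
            state["z"][:, c] = zc
        if adapt:
            steps[key] *= np.exp(self._gamma(it) * (float(acc) - 0.3))

    def _adapt_block(self, blk, acc, adapt, it, value):
        if not adapt:
            return
        blk["scale"] *= np.exp(self._gamma(it) * (acc - 0.28))
        blk["history"].append(np.array(value))
        if len(blk["history"]) >= 100 and len(blk["history"]) % 25 == 0:
            h = np.array(blk["history"][-400:])
            cov = np.cov(h.T) + 1e-9 * np.eye(h.shape[1])
            try:
                blk["chol"] = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def _update_theta(self, state, rng, steps, adapt, it):
        for i in self.free_theta:
            cur = state["theta"][i]
            prop = cur * np.exp(steps[f"theta_{i}"] *
                                rng.standard_normal())
            sig_prop = state["theta"].copy()
            sig_prop[i] = prop
            try:
                sigma_new = self._sigma_act(sig_prop, state["eta"])
                np.linalg.cholesky(sigma_new)
            except np.linalg.LinAlgError:
                continue
            ll_cur = self._z_prior_loglik(state)
            ll_prop = self._z_prior_loglik(state, sigma=sigma_new)
            # half-Cauchy(2.5) with log-scale Jacobian
            def lp(t):
                return -np.log1p((t / self.prior.theta_scale) ** 2) \
                    + np.log(t)
            logr = ll_prop - ll_cur + lp(prop) - lp(cur)
            acc = np.log(rng.random()) < logr
            if acc:
                state["theta"] = sig_prop
                self._refresh_cov(state)
            if adapt:
                steps[f"theta_{i}"] *= np.exp(
                    self._gamma(it) * (float(acc) - 0.44))

    def _update_eta(self, state, rng, steps, adapt, it):
        if self.fix_eta is not None:
            return
        for m in self.free_eta:
            cur = state["eta"][m]
            prop = cur + steps[f"eta_{m}"] * rng.standard_normal()
            if not -1 < prop < 1:
                continue
            eta_new = state["eta"].copy()
            eta_new[m] = prop
            try:
                sigma_new = self._sigma_act(state["theta"], eta_new)
                np.linalg.cholesky(sigma_new)
            except np.linalg.LinAlgError:
                continue
            ll_cur = self._z_prior_loglik(state)
            ll_prop = self._z_prior_loglik(state, sigma=sigma_new)
            acc = np.log(rng.random()) < ll_prop - ll_cur  # LKJ(1): flat
            if acc:
                state["eta"] = eta_new
                self._refresh_cov(state)
            if adapt:
                steps[f"eta_{m}"] *= np.exp(
                    self._gamma(it) * (float(acc) - 0.44))

    @staticmethod
    def _gamma(it):
        return min(0.25, 2.0 / (1.0 + it) ** 0.6)

    # --- initialisation and main loop ---

    def _init_state(self, rng):
        d = self.d
        beta, alpha = {}, {}
        for o in d.active:
            p = d.X[o].shape[1]
            b = 0.01 * rng.standard_normal(p)
            if o == "O":
                b[0] += np.log(d.y_O.mean() + 0.5)
            elif o == "M":
                b[0] += np.log(max(np.nansum(d.y_M) /
                                   max(d.y_O[d.mixed].sum(), 1.0), 1e-3))
            elif o in _PROBIT:
                y = (d.y_D if o == "D" else d.y_L)[d.transferred]
                b[0] += float(ndtri(np.clip(y.mean(), 0.02, 0.98)))
            beta[o] = b
            if o in ("E", "F"):
                g = d.grades[o]
                cum = np.clip(np.cumsum(np.bincount(
                    g, minlength=5)[1:4]) / len(g), 0.02, 0.98)
                cum = np.maximum.accumulate(cum + np.arange(3) * 1e-3)
                alpha[o] = np.log(cum / (1 - cum))
        for o in ("E", "F"):
            alpha.setdefault(o, np.array([-1.0, 0.0, 1.0]))
            beta.setdefault(o, np.zeros(0))
        theta = np.full(4, 0.5)
        eta = (self.fix_eta.copy() if self.fix_eta is not None
               else np.zeros(15))
        state = {"beta": beta, "alpha": alpha, "theta": theta, "eta": eta,
                 "z": np.zeros((d.n, 6))}
        self._refresh_cov(state)
        return state

    def run(self, n_iter, n_warmup, seed, save_latents=False):
        rng = np.random.default_rng(seed)
        state = self._init_state(rng)
        d = self.d
        steps = {o: 0.5 for o in d.active if o in _COUNT_ORDINAL}
        for i in self.free_theta:
            steps[f"theta_{i}"] = 0.3
        for m in self.free_eta:
            steps[f"eta_{m}"] = 0.1
        blocks = {}
        for o in d.active:
            if o in _PROBIT:
                continue
            dim = d.X[o].shape[1] + (3 if o in ("E", "F") else 0)
            blocks[o] = {"scale": 0.1 / np.sqrt(dim),
                         "chol": np.eye(dim), "history": []}
        store = {"beta": {o: [] for o in d.active},
                 "alpha": {o: [] for o in ("E", "F") if o in d.active},
                 "theta": [], "eta": [], "z": []}
        total = n_warmup + n_iter
        for it in range(total):
            adapt = it < n_warmup
            for o in d.active:
                if o in _COUNT_ORDINAL:
                    self._update_z_mh(o, state, rng, steps, adapt, it)
            for o in d.active:
                if o in _PROBIT:
                    # several cheap sub-draws decorrelate the (utility,
                    # coefficient) pair, whose Gibbs coupling is the only
                    # source of autocorrelation in the probit blocks
                    for _ in range(5):
                        self._update_probit(o, state, rng)
            for o in d.active:
                if o in _COUNT_ORDINAL:
                    self._update_beta_block(o, state, rng, blocks, adapt,
                                            it)
                    self._update_beta_scalar(o, state, rng, steps, adapt,
                                             it)
                    self._update_recenter(o, state, rng, steps, adapt, it)
            if self.free_theta:
                self._update_theta(state, rng, steps, adapt, it)
                for i in self.free_theta:
                    self._update_rescale(_COUNT_ORDINAL[i], state, rng,
                                         steps, adapt, it)
            self._update_eta(state, rng, steps, adapt, it)
            if it >= n_warmup:
                for o in d.active:
                    store["beta"][o].append(state["beta"][o].copy())
                for o in store["alpha"]:
                    store["alpha"][o].append(state["alpha"][o].copy())
                store["theta"].append(state["theta"].copy())
                store["eta"].append(state["eta"].copy())
                if save_latents:
                    store["z"].append(state["z"].copy())
        return store


def _ordinal_logpmf(grades, alpha, linpred):
    from scipy.special import expit
    gam = expit(np.asarray(alpha) - linpred[:, None])
    full = np.concatenate([np.zeros((len(linpred), 1)), gam,
                           np.ones((len(linpred), 1))], axis=1)
    p = np.diff(full, axis=1)
    chosen = p[np.arange(len(grades)), np.asarray(grades) - 1]
    return np.log(np.maximum(chosen, 1e-300))


# ---------------------------------------------------------------------------
# Public fitting interface


def _collect(stores, data, config):
    """Assemble per-chain stores into a PosteriorSamples."""
    draws = {}
    n_chains = len(stores)
    n_draws = len(stores[0]["theta"])
    for o in OUTCOMES:
        key = f"beta_{o}"
        if o in data.active:
            draws[key] = np.stack([np.array(s["beta"][o]) for s in stores])
        else:
            draws[key] = np.zeros((n_chains, n_draws, 1))
    for o in ("E", "F"):
        key = f"alpha_{o}"
        if o in data.active:
            draws[key] = np.stack([np.array(s["alpha"][o])
                                   for s in stores])
        else:
            draws[key] = np.tile(np.array([-1.0, 0.0, 1.0]),
                                 (n_chains, n_draws, 1))
    draws["theta"] = np.stack([np.array(s["theta"]) for s in stores])
    draws["eta"] = np.stack([np.array(s["eta"]) for s in stores])
    specs = {o: data.specs[o] for o in data.specs}
    post = PosteriorSamples(draws, specs, data.scaling, data.active)
    rh = {lab: split_rhat(arr) for lab, arr in post.scalar_draws()}
    post.diagnostics["rhat"] = rh
    bad = {k: v for k, v in rh.items()
           if np.isfinite(v) and v > config.rhat_threshold}
    post.diagnostics["converged"] = not bad
    if bad:
        warnings.warn(
            "convergence flagged: R-hat above "
            f"{config.rhat_threshold} for {sorted(bad)}")
    return post


def _run_fit(cohort, specs, config, active):
    data = _ModelData(cohort, specs, active)
    sampler = _BlockSampler(data, config.prior, fix_eta=config.fix_eta)
    n_warmup = max(int(config.iterations * config.warmup_frac), 50)
    root = np.random.default_rng(config.seed)
    chain_seeds = root.integers(0, 2 ** 31 - 1, size=config.chains)
    stores = [sampler.run(config.iterations, n_warmup, int(s),
                          save_latents=config.save_latents)
              for s in chain_seeds]
    return _collect(stores, data, config)


def fit_joint(cohort: Cohort, specs: dict, config: FitConfig
              ) -> PosteriorSamples:
    """Fit the six-submodel joint model by MCMC.

    All six outcomes share the 6-d latent vector; correlations are sampled
    under LKJ(1) unless ``config.fix_eta`` freezes them. Latents of
    unreached stages carry prior-only contributions. Non-convergence
    (any R-hat above the threshold) is flagged with a warning, never
    silently accepted.
    """
    return _run_fit(cohort, specs, config, active=tuple(OUTCOMES))


def fit_separate(cohort: Cohort, specs: dict, config: FitConfig,
                 outcomes=OUTCOMES) -> dict:
    """Fit the six baseline submodels independently.

    Returns a dict outcome -> PosteriorSamples: Poisson (O) and
    offset-Poisson (M) with lognormal random intercepts, cumulative-logit
    models with patient random intercepts (E, F), and exact probit
    regressions (D, L — the unit-variance latent makes the separate model
    a plain probit).
    """
    out = {}
    for k, o in enumerate(outcomes):
        sub = FitConfig(mode="separate", setting=config.setting,
                        chains=config.chains,
                        iterations=config.iterations,
                        warmup_frac=config.warmup_frac,
                        seed=config.seed + 1000 * (k + 1),
                        prior=config.prior, fix_eta=np.zeros(15),
                        rhat_threshold=config.rhat_threshold,
                        save_latents=config.save_latents)
        out[o] = _run_fit(cohort, specs, sub, active=(o,))
    return out


def combine_separate_fits(fits: dict) -> PosteriorSamples:
    """Merge six separate fits into one joint-layout PosteriorSamples.

    Draws are aligned by index across the independent fits (their
    posteriors are independent, so any pairing is valid); correlations are
    zero by construction.
    """
    first = fits["O"]
    n_chains, n_draws = first.n_chains, first.n_draws
    draws = {}
    for o in OUTCOMES:
        draws[f"beta_{o}"] = fits[o].draws[f"beta_{o}"]
    for o in ("E", "F"):
        draws[f"alpha_{o}"] = fits[o].draws[f"alpha_{o}"]
    theta = np.zeros((n_chains, n_draws, 4))
    for i, o in enumerate(_COUNT_ORDINAL):
        theta[:, :, i] = fits[o].draws["theta"][:, :, i]
    draws["theta"] = theta
    draws["eta"] = np.zeros((n_chains, n_draws, 15))
    specs = {o: fits[o].specs[o] for o in OUTCOMES}
    return PosteriorSamples(draws, specs, first.covariate_scaling,
                            tuple(OUTCOMES))


def posterior_from_parameters(params: ModelParameters, specs: dict,
                              scaling, n_draws=1) -> PosteriorSamples:
    """Degenerate PosteriorSamples concentrated at one parameter point.

    Lets the prediction machinery run with known (e.g. generating)
    parameters; draws are exact copies.
    """
    draws = {}
    for name in ("beta_O", "beta_M", "beta_E", "beta_F", "beta_D",
                 "beta_L", "alpha_E", "alpha_F", "theta", "eta"):
        v = np.asarray(getattr(params, name), dtype=float)
        draws[name] = np.tile(v, (2, n_draws, 1))
    return PosteriorSamples(draws, specs, scaling, tuple(OUTCOMES))


def check_dynamic_precision(joint_fit: PosteriorSamples,
                            separate_fits: dict, factor=5.0):
    """Warn when joint dynamic outcome-covariate coefficients are grossly
    less precise than their separate-fit counterparts (a known behaviour
    of the dynamic joint model, accepted rather than treated as error)."""
    from .model import DYNAMIC_SOURCE
    flagged = []
    sd_j = {lab: arr.std() for lab, arr in joint_fit.scalar_draws()}
    for o, fit in separate_fits.items():
        for lab, arr in fit.scalar_draws():
            col = lab[lab.index("[") + 1:-1] if "[" in lab else ""
            if col in DYNAMIC_SOURCE and lab in sd_j:
                if sd_j[lab] > factor * arr.std():
                    flagged.append(lab)
    if flagged:
        warnings.warn(
            "joint dynamic fit is markedly less precise than the separate "
            f"fits for {sorted(set(flagged))}")
    return flagged
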