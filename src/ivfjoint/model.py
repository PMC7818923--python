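"""Submodel link functions and parameter containers for the joint model.

Six sequential outcomes are modelled per cycle, indexed in temporal order:

====  =========================  ==========================================
code  outcome                    submodel family
====  =========================  ==========================================
O     oocyte count               Poisson, log link, latent intercept z_O
M     embryo (fertilised) count  Poisson, log(oocytes) offset, latent z_M
E     embryo cell evenness       cumulative logit (grades 1-4), latent z_E
F     embryo fragmentation       cumulative logit (grades 1-4), latent z_F
D     double embryo transfer     latent probit, unit error variance
L     live birth event           latent probit, unit error variance
====  =========================  ==========================================

The per-cycle latent vector z = (z_O, z_M, z_E, z_F, z_D, z_L) is
multivariate normal with mean zero; the first four components have free
standard deviations theta while the probit components are pinned at unit
variance, which makes the marginal D and L submodels exactly probit
regressions. Fifteen correlations eta (row-wise upper triangle in outcome
order) tie the submodels together; setting them to zero factorises the
joint model into six independent regressions.

For the two ordinal submodels the linear predictor enters the cumulative
logits with a negative sign, so a positive coefficient shifts probability
mass towards *higher* grades.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, ndtr

OUTCOMES = ("O", "M", "E", "F", "D", "L")
OUTCOME_INDEX = {o: i for i, o in enumerate(OUTCOMES)}

# Temporal stage of each outcome; E and F are coincident.
STAGE = {"O": 0, "M": 1, "E": 2, "F": 2, "D": 3, "L": 4}

# Row-wise upper-triangle order of the 15 correlations.
ETA_PAIRS = [(i, j) for i in range(6) for j in range(i + 1, 6)]

BASELINE_COVARIATES = ("age", "partner_age", "attempt", "icsi")
# Dynamic covariates and the outcome whose realisation defines them.
DYNAMIC_SOURCE = {
    "n_oocytes": "O",
    "fert_rate": "M",
    "mean_evenness": "E",
    "mean_fragmentation": "F",
    "det": "D",
}


@dataclass(frozen=True)
class SubmodelSpec:
    """Covariate list for one submodel (intercept implicit, first).

    Dynamic covariates must be temporally upstream of the outcome; the two
    coincident grading scales may not predict each other, and ``icsi`` is
    an embryo-level covariate admitted only in the grading submodels.
    """

    outcome: str
    covariates: tuple = ()

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        for cov in self.covariates:
            if cov in BASELINE_COVARIATES:
                if cov == "icsi" and self.outcome not in ("E", "F"):
                    raise ValueError(
                        "icsi is an embryo-level covariate; only the "
                        "grading submodels may use it")
                continue
            if cov not in DYNAMIC_SOURCE:
                raise ValueError(f"unknown covariate {cov!r}")
            if STAGE[DYNAMIC_SOURCE[cov]] >= STAGE[self.outcome]:
                raise ValueError(
                    f"covariate {cov!r} is not upstream of outcome "
                    f"{self.outcome!r}")

    @property
    def has_intercept(self):
        """Ordinal submodels carry no intercept: the three thresholds
        absorb it."""
        return self.outcome not in ("E", "F")

    @property
    def column_names(self):
        """Expanded design-column names, intercept (if any) first."""
        cols = ["intercept"] if self.has_intercept else []
        for cov in self.covariates:
            if cov == "attempt":
                cols += ["attempt_2", "attempt_3", "attempt_4_5"]
            else:
                cols.append(cov)
        return cols


def pretreatment_specs() -> dict:
    """Default pre-treatment covariate sets (baseline information only)."""
    return {
        "O": SubmodelSpec("O", ("age", "partner_age", "attempt")),
        "M": SubmodelSpec("M", ("age", "partner_age")),
        "E": SubmodelSpec("E", ("age", "partner_age", "icsi")),
        "F": SubmodelSpec("F", ("age", "partner_age", "icsi")),
        "D": SubmodelSpec("D", ("age", "partner_age", "attempt")),
        "L": SubmodelSpec("L", ("age", "partner_age")),
    }


def dynamic_specs() -> dict:
    """Default dynamic covariate sets: upstream outcomes feed downstream
    submodels (oocyte count and fertilisation rate into the grading
    submodels; those plus mean grades into DET; all of them plus DET into
    the live-birth submodel)."""
    return {
        "O": SubmodelSpec("O", ("age", "partner_age", "attempt")),
        "M": SubmodelSpec("M", ("age", "partner_age")),
        "E": SubmodelSpec("E", ("age", "partner_age", "icsi",
                                "n_oocytes", "fert_rate")),
        "F": SubmodelSpec("F", ("age", "partner_age", "icsi",
                                "n_oocytes", "fert_rate")),
        "D": SubmodelSpec("D", ("age", "partner_age", "attempt",
                                "n_oocytes", "fert_rate",
                                "mean_evenness", "mean_fragmentation")),
        "L": SubmodelSpec("L", ("age", "partner_age",
                                "n_oocytes", "fert_rate",
                                "mean_evenness", "mean_fragmentation",
                                "det")),
    }


@dataclass
class ModelParameters:
    """All regression coefficients, thresholds and latent (co)variances.

    Coefficient vectors are aligned to their SubmodelSpec column order
    (intercept first). ``theta`` holds the four free latent SDs
    (O, M, E, F); ``eta`` the 15 correlations in row-wise upper-triangle
    order O,M,E,F,D,L.
    """

    beta_O: np.ndarray
    beta_M: np.ndarray
    beta_E: np.ndarray
    beta_F: np.ndarray
    beta_D: np.ndarray
    beta_L: np.ndarray
    alpha_E: np.ndarray
    alpha_F: np.ndarray
    theta: np.ndarray = field(default_factory=lambda: np.ones(4))
    eta: np.ndarray = field(default_factory=lambda: np.zeros(15))

    def __post_init__(self):
        for name in ("beta_O", "beta_M", "beta_E", "beta_F", "beta_D",
                     "beta_L", "alpha_E", "alpha_F", "theta", "eta"):
            setattr(self, name, np.atleast_1d(
                np.asarray(getattr(self, name), dtype=float)))

    def beta(self, outcome: str) -> np.ndarray:
        return getattr(self, f"beta_{outcome}")

    def alpha(self, outcome: str) -> np.ndarray:
        return getattr(self, f"alpha_{outcome}")

    def validate(self) -> None:
        for name in ("alpha_E", "alpha_F"):
            a = getattr(self, name)
            if len(a) != 3 or np.any(np.diff(a) <= 0):
                raise ValueError(f"{name} must be 3 strictly increasing "
                                 f"thresholds, got {a}")
        if len(self.theta) != 4 or np.any(self.theta <= 0):
            raise ValueError("theta must be 4 positive SDs")
        if len(self.eta) != 15 or np.any(np.abs(self.eta) >= 1):
            raise ValueError("eta must be 15 correlations in (-1, 1)")
        build_latent_covariance(self.theta, self.eta)  # PD check

    def latent_covariance(self) -> np.ndarray:
        return build_latent_covariance(self.theta, self.eta)

    def copy(self) -> "ModelParameters":
        return replace(self, **{
            k: np.array(getattr(self, k)) for k in (
                "beta_O", "beta_M", "beta_E", "beta_F", "beta_D", "beta_L",
                "alpha_E", "alpha_F", "theta", "eta")})

    def to_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)).tolist() for k in (
            "beta_O", "beta_M", "beta_E", "beta_F", "beta_D", "beta_L",
            "alpha_E", "alpha_F", "theta", "eta")}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**{k: np.asarray(v, dtype=float) for k, v in d.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class LatentVector:
    """One cycle's 6-d latent draw (z_O, z_M, z_E, z_F, z_D, z_L)."""

    z_O: float = 0.0
    z_M: float = 0.0
    z_E: float = 0.0
    z_F: float = 0.0
    z_D: float = 0.0
    z_L: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.z_O, self.z_M, self.z_E, self.z_F,
                         self.z_D, self.z_L])


# ---------------------------------------------------------------------------
# Link functions


def _check_dims(x_row, beta):
    x = np.asarray(x_row, dtype=float)
    b = np.asarray(beta, dtype=float)
    if x.shape[-1] != b.shape[0]:
        raise ValueError(
            f"covariate row has {x.shape[-1]} entries but beta has "
            f"{b.shape[0]}")
    return x, b


def oocyte_log_rate(x_row, beta, z):
    """Log Poisson rate for the oocyte count: x.beta + z_O.

    The latent intercept z_O captures between-patient overdispersion in
    oocyte yield relative to a plain Poisson model.
    """
    x, b = _check_dims(x_row, beta)
    return x @ b + z


def fert_log_rate(n_oocytes, x_row, beta, z):
    """Log Poisson rate for the embryo count: log(oocytes) + x.beta + z_M.

    The oocyte count enters as an offset, so exp(x.beta + z) is a per-oocyte
    fertilisation rate. Cycles without mixed oocytes are outside this
    submodel; unmixed oocytes are treated as unable to fertilise, so the
    offset uses the full retrieved count.
    """
    n = np.asarray(n_oocytes, dtype=float)
    if np.any(n < 1):
        raise ValueError("fertilisation submodel requires n_oocytes >= 1")
    x, b = _check_dims(x_row, beta)
    return np.log(n) + x @ b + z


def ordinal_cumulative_probs(alpha, linpred):
    """gamma_k = logit^{-1}(alpha_k - linpred) for k = 1..3."""
    a = np.asarray(alpha, dtype=float)
    if len(a) != 3 or np.any(np.diff(a) <= 0):
        raise ValueError(f"thresholds must be strictly increasing, got {a}")
    lp = np.asarray(linpred, dtype=float)
    return expit(a - lp[..., None])


def ordinal_category_probs(alpha, x_row, beta, z):
    """Probabilities of grades 1..4 under the cumulative logit submodel.

    The linear predictor x.beta + z enters with a negative sign against the
    thresholds, so positive effects move mass to higher grades. Returns an
    array with last dimension 4 summing to one.
    """
    x, b = _check_dims(x_row, beta)
    gam = ordinal_cumulative_probs(alpha, x @ b + z)
    full = np.concatenate([np.zeros_like(gam[..., :1]), gam,
                           np.ones_like(gam[..., :1])], axis=-1)
    return np.diff(full, axis=-1)


def probit_success_prob(x_row, beta, z):
    """Success probability for a latent-probit outcome (DET or LBE).

    With a numeric latent ``z`` the outcome is deterministic: success iff
    x.beta + z >= 0 (returns 0.0 or 1.0). With ``z="marginal"`` the unit
    normal latent is integrated out, giving the probit probability
    Phi(x.beta).
    """
    x, b = _check_dims(x_row, beta)
    lp = x @ b
    if isinstance(z, str):
        if z != "marginal":
            raise ValueError("z must be numeric or 'marginal'")
        return ndtr(lp)
    return (lp + np.asarray(z, dtype=float) >= 0).astype(float)


# ---------------------------------------------------------------------------
# Latent covariance


def build_latent_covariance(theta, eta) -> np.ndarray:
    """Assemble the 6x6 latent covariance from 4 SDs and 15 correlations.

    Diagonal (theta_O^2, theta_M^2, theta_E^2, theta_F^2, 1, 1); entry
    (i, j) is eta_m sd_i sd_j with unit SD for the probit components. The
    matrix is validated symmetric positive definite via Cholesky — the 15
    correlations are jointly constrained and an invalid combination is an
    error, never silently repaired.
    """
    th = np.asarray(theta, dtype=float)
    et = np.asarray(eta, dtype=float)
    if len(th) != 4 or np.any(th <= 0):
        raise ValueError("theta must be 4 positive SDs")
    if len(et) != 15 or np.any(np.abs(et) >= 1):
        raise ValueError("eta must be 15 correlations in (-1, 1)")
    sd = np.concatenate([th, [1.0, 1.0]])
    corr = np.eye(6)
    for m, (i, j) in enumerate(ETA_PAIRS):
        corr[i, j] = corr[j, i] = et[m]
    sigma = corr * np.outer(sd, sd)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ValueError(
            "latent covariance is not positive definite for the given "
            "correlations") from None
    return sigma


def conditional_latent_distribution(sigma, observed_idx, observed_vals):
    """Condition a zero-mean MVN on a subset of its components.

    Returns ``(mean, cov)`` of the remaining components (in ascending index
    order) given the observed ones. Used both to integrate probit latents
    given the others and to propagate latents of unreached stages.
    """
    sigma = np.asarray(sigma, dtype=float)
    p = sigma.shape[0]
    obs = list(observed_idx)
    if len(set(obs)) != len(obs):
        raise ValueError("observed_idx contains duplicates")
    if not set(obs) <= set(range(p)) or len(obs) >= p:
        raise ValueError("observed_idx must be a strict subset of indices")
    rest = [i for i in range(p) if i not in obs]
    if not obs:
        return np.zeros(len(rest)), sigma[np.ix_(rest, rest)]
    v = np.asarray(observed_vals, dtype=float)
    s_oo = sigma[np.ix_(obs, obs)]
    s_ro = sigma[np.ix_(rest, obs)]
    try:
        gain = np.linalg.solve(s_oo, s_ro.T).T
    except np.linalg.LinAlgError:
        raise ValueError("conditioning block is singular") from None
    mean = gain @ v
    cov = sigma[np.ix_(rest, rest)] - gain @ s_ro.T
    return mean, cov
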