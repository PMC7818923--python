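"""Joint log-likelihood given latents, and latent-integrated likelihoods.

``joint_log_likelihood`` evaluates the data log-density of a cohort
conditional on each cycle's 6-d latent vector. Stages a cycle never
reached contribute nothing: a patient who drops out of the cycle simply
leaves every downstream submodel.

The two probit outcomes admit two evaluation modes, matching the two ways
a sampler may treat their latents:

* ``probit="marginal"`` — z_D and z_L are integrated out analytically
  given the four count/ordinal latents, using the conditional normal
  distribution. With a single probit outcome observed the term is
  log Phi(+/- (x.beta + mu_cond) / sd_cond); with both observed it is the
  corresponding bivariate normal orthant probability (which factorises
  into the two Phi terms whenever the residual D-L correlation is zero).
* ``probit="augmented"`` — the supplied z_D, z_L are taken at face value
  and the outcome is the deterministic sign of x.beta + z, contributing
  log 1 or log 0.

``gh_marginal_loglik`` integrates the latents out of a single cycle's
likelihood with Gauss-Hermite quadrature over the count/ordinal latent
dimensions (the probit dimensions are handled exactly through the
conditional normal CDF, since quadrature converges poorly against their
discontinuous indicator). It serves as a slow, independent route to the
marginal likelihood for validation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import multivariate_normal, norm

from .cohort import Cohort
from .design import cycle_design, embryo_design
from .model import (ModelParameters, OUTCOME_INDEX,
                    conditional_latent_distribution, ordinal_category_probs)

_NUMERIC = ("O", "M", "E", "F")


def _poisson_logpmf(y, log_rate):
    return y * log_rate - np.exp(log_rate) - gammaln(y + 1.0)


def _ordinal_loglik(grades, alpha, linpred):
    p = ordinal_category_probs(alpha, np.ones((len(grades), 1)),
                               np.zeros(1), linpred)
    chosen = p[np.arange(len(grades)), np.asarray(grades, dtype=int) - 1]
    return np.log(np.maximum(chosen, 1e-300))


def _probit_pair_logprob(sigma, z_numeric, lp_D, lp_L, y_D, y_L):
    """log P(y_D, y_L | z_O..z_F) with z_D, z_L integrated analytically."""
    mean, cov = conditional_latent_distribution(sigma, [0, 1, 2, 3],
                                                z_numeric)
    terms = []
    obs = []
    if y_D is not None:
        obs.append((lp_D + mean[0], np.sqrt(cov[0, 0]), int(y_D), 0))
    if y_L is not None:
        obs.append((lp_L + mean[1], np.sqrt(cov[1, 1]), int(y_L), 1))
    if not obs:
        return 0.0
    if len(obs) == 1:
        m, s, y, _ = obs[0]
        return norm.logcdf((m if y == 1 else -m) / s)
    rho = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
    if abs(rho) < 1e-12:
        return sum(norm.logcdf((m if y == 1 else -m) / s)
                   for m, s, y, _ in obs)
    # Orthant probability of the correlated pair: flip signs so both
    # events read "standardised latent <= bound".
    signs = np.array([1.0 if y == 1 else -1.0 for _, _, y, _ in obs])
    bounds = np.array([m / s for m, s, _, _ in obs]) * signs
    r = rho * signs[0] * signs[1]
    p = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]]).cdf(bounds)
    return float(np.log(np.maximum(p, 1e-300)))


def _latents_array(latents, n):
    if hasattr(latents, "as_array"):
        latents = [latents]
    if isinstance(latents, (list, tuple)):
        latents = np.vstack([z.as_array() if hasattr(z, "as_array")
                             else np.asarray(z, dtype=float)
                             for z in latents])
    z = np.asarray(latents, dtype=float)
    if z.shape != (n, 6):
        raise ValueError(
            f"need one 6-d latent vector per cycle: expected shape "
            f"({n}, 6), got {z.shape}")
    return z


def joint_log_likelihood(cohort: Cohort, params: ModelParameters, latents,
                         specs: dict, probit="marginal") -> float:
    """Sum of all submodel log-likelihood contributions given the latents.

    ``latents`` is an (n_cycles, 6) array (or list of LatentVector) in
    cohort row order. Unreached stages contribute nothing, and no latent
    prior density is included — this is the data density conditional on z.
    """
    cyc = cohort.cycles
    n = len(cyc)
    z = _latents_array(latents, n)
    scaling = cohort.covariate_scaling
    total = 0.0

    y_o = cyc["n_oocytes"].to_numpy(dtype=float)
    X_O = cycle_design(cohort, specs["O"], scaling)
    total += float(np.sum(_poisson_logpmf(
        y_o, X_O @ params.beta_O + z[:, 0])))

    mixed = (cyc["mixed"] == 1).to_numpy(dtype=bool, na_value=False)
    if mixed.any():
        y_m = cyc["n_embryos"].astype(float).to_numpy(na_value=np.nan)
        X_M = cycle_design(cohort, specs["M"], scaling)
        lr = (np.log(y_o[mixed]) + X_M[mixed] @ params.beta_M
              + z[mixed, 1])
        total += float(np.sum(_poisson_logpmf(y_m[mixed], lr)))

    if cohort.n_embryos:
        for out, col in (("E", "evenness"), ("F", "fragmentation")):
            X, parent = embryo_design(cohort, specs[out], scaling)
            lp = X @ params.beta(out) + z[parent, OUTCOME_INDEX[out]]
            total += float(np.sum(_ordinal_loglik(
                cohort.embryos[col].to_numpy(dtype=int),
                params.alpha(out), lp)))

    transferred = (cyc["transferred"] == 1).to_numpy(dtype=bool,
                                                     na_value=False)
    if transferred.any():
        X_D = cycle_design(cohort, specs["D"], scaling)
        X_L = cycle_design(cohort, specs["L"], scaling)
        lp_D = X_D @ params.beta_D
        lp_L = X_L @ params.beta_L
        y_d = cyc["det"].astype(float).to_numpy(na_value=np.nan)
        y_l = cyc["lbe"].astype(float).to_numpy(na_value=np.nan)
        if probit == "augmented":
            sign_d = np.where(y_d[transferred] == 1, 1.0, -1.0)
            sign_l = np.where(y_l[transferred] == 1, 1.0, -1.0)
            ok = ((sign_d * (lp_D[transferred] + z[transferred, 4]) >= 0)
                  & (sign_l * (lp_L[transferred] + z[transferred, 5]) >= 0))
            total += 0.0 if ok.all() else -np.inf
        elif probit == "marginal":
            sigma = params.latent_covariance()
            for j in np.flatnonzero(transferred):
                total += _probit_pair_logprob(
                    sigma, z[j, :4], lp_D[j], lp_L[j],
                    int(y_d[j]), int(y_l[j]))
        else:
            raise ValueError("probit must be 'marginal' or 'augmented'")
    return total


def gh_marginal_loglik(params: ModelParameters, specs: dict,
                       covariates: dict, y: dict, scaling=None,
                       n_nodes=40) -> float:
    """Latent-integrated log-likelihood of one cycle's observed outcomes.

    ``y`` maps outcome codes to observations: counts for ``O``/``M``,
    lists of grades for ``E``/``F``, 0/1 for ``D``/``L``; outcomes absent
    from ``y`` are treated as unreached. Gauss-Hermite quadrature (default
    40 nodes per dimension) runs over the active count/ordinal latent
    dimensions, transformed through the Cholesky factor of their covariance
    block; active probit outcomes are integrated exactly via the
    conditional normal CDF given each quadrature point.
    """
    sigma = params.latent_covariance()
    active_num = [o for o in _NUMERIC if o in y]
    idx = [OUTCOME_INDEX[o] for o in active_num]
    d = len(idx)

    from .design import design_from_values
    X = {o: design_from_values(specs[o], covariates, scaling, n_rows=1)[0]
         for o in y}

    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    if d:
        grids = np.meshgrid(*([nodes] * d), indexing="ij")
        u = np.sqrt(2.0) * np.column_stack([g.ravel() for g in grids])
        w = np.ones(u.shape[0])
        for k in range(d):
            w *= np.tile(
                np.repeat(weights, n_nodes ** (d - 1 - k)),
                n_nodes ** k) / np.sqrt(np.pi)
        L = np.linalg.cholesky(sigma[np.ix_(idx, idx)])
        zpts = u @ L.T                       # (Q, d) latent draws
    else:
        zpts = np.zeros((1, 0))
        w = np.ones(1)

    loglik_pts = np.zeros(zpts.shape[0])
    for k, o in enumerate(active_num):
        lp = float(X[o] @ params.beta(o))
        if o == "O":
            loglik_pts += _poisson_logpmf(float(y["O"]), lp + zpts[:, k])
        elif o == "M":
            lr = np.log(float(y["O"])) + lp + zpts[:, k]
            loglik_pts += _poisson_logpmf(float(y["M"]), lr)
        else:
            grades = np.atleast_1d(y[o]).astype(int)
            for g in grades:
                p = ordinal_category_probs(
                    params.alpha(o), np.ones(1), np.zeros(1),
                    lp + zpts[:, k])[..., g - 1]
                loglik_pts += np.log(np.maximum(p, 1e-300))

    if "D" in y or "L" in y:
        # Conditional of (z_D, z_L) given the active numeric latents only:
        # inactive numeric latents are marginalised (they carry no data).
        sub = idx + [4, 5]
        sig_sub = sigma[np.ix_(sub, sub)]
        lp_D = float(X["D"] @ params.beta_D) if "D" in y else 0.0
        lp_L = float(X["L"] @ params.beta_L) if "L" in y else 0.0
        if d:
            A = sig_sub[:d, :d]
            B = sig_sub[:d, d:]
            gain = np.linalg.solve(A, B).T          # (2, d)
            cond_cov = sig_sub[d:, d:] - gain @ B
            means = zpts @ gain.T                   # (Q, 2)
        else:
            cond_cov = sig_sub
            means = np.zeros((zpts.shape[0], 2))
        obs = []
        if "D" in y:
            obs.append((lp_D, 0, int(y["D"])))
        if "L" in y:
            obs.append((lp_L, 1, int(y["L"])))
        rho = cond_cov[0, 1] / np.sqrt(cond_cov[0, 0] * cond_cov[1, 1])
        if len(obs) < 2 or abs(rho) < 1e-12:
            for lp, k, yv in obs:
                s = np.sqrt(cond_cov[k, k])
                sign = 1.0 if yv == 1 else -1.0
                loglik_pts += norm.logcdf(sign * (lp + means[:, k]) / s)
        else:
            signs = np.array([1.0 if yv == 1 else -1.0
                              for _, _, yv in obs])
            r = float(rho * signs[0] * signs[1])
            mvn = multivariate_normal(mean=[0, 0],
                                      cov=[[1, r], [r, 1]])
            bounds = np.column_stack([
                signs[k] * (obs[k][0] + means[:, obs[k][1]])
                / np.sqrt(cond_cov[obs[k][1], obs[k][1]])
                for k in range(2)])
            p = mvn.cdf(bounds)
            loglik_pts += np.log(np.maximum(np.atleast_1d(p), 1e-300))

    m = np.max(loglik_pts)
    return float(m + np.log(np.sum(w * np.exp(loglik_pts - m))))

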