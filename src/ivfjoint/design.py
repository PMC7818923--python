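"""Design matrices for the six submodels.

Continuous covariates (ages and, in the dynamic setting, upstream outcome
summaries) are standardised by a stored per-covariate ``(mean, sd)``; the
scaling travels with the cohort so that fitted coefficients, simulated
cohorts and prediction requests all evaluate linear predictors on the same
scale. Attempt number is a four-category factor (first attempt reference,
4th/5th pooled) entering as dummies; ICSI and DET are plain 0/1 columns.

Dynamic outcome covariates are defined as: ``n_oocytes`` the realised
oocyte count; ``fert_rate`` the per-oocyte fertilisation rate y_M / y_O;
``mean_evenness`` / ``mean_fragmentation`` the patient's embryo grades
averaged over all her gradable embryos.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort
from .model import SubmodelSpec

CONTINUOUS = ("age", "partner_age", "n_oocytes", "fert_rate",
              "mean_evenness", "mean_fragmentation")

_ATTEMPT_DUMMIES = {"1": (0, 0, 0), "2": (1, 0, 0),
                    "3": (0, 1, 0), "4-5": (0, 0, 1)}


def scale_of(scaling, name):
    if scaling and name in scaling:
        s = scaling[name]
        return float(s["mean"]), float(s["sd"])
    return 0.0, 1.0


def compute_scaling(cohort: Cohort, names=CONTINUOUS) -> dict:
    """Mean/SD per continuous covariate over the cycles where it is defined."""
    values = cycle_covariate_values(cohort, scaling=None)
    out = {}
    for name in names:
        if name not in values:
            continue
        v = np.asarray(values[name], dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        sd = float(np.std(v))
        out[name] = {"mean": float(np.mean(v)),
                     "sd": sd if sd > 0 else 1.0}
    return out


def cycle_covariate_values(cohort: Cohort, scaling="cohort") -> dict:
    """Raw (unscaled) covariate arrays per cycle, dynamic ones included.

    Dynamic covariates are NaN for cycles that never defined them (e.g. the
    fertilisation rate of a cycle whose oocytes were not mixed); such
    cycles are outside every submodel that would use the covariate.
    """
    cyc = cohort.cycles
    n = len(cyc)
    y_o = cyc["n_oocytes"].astype(float).to_numpy()
    y_m = cyc["n_embryos"].astype(float).to_numpy(na_value=np.nan)
    values = {
        "age": cyc["age"].to_numpy(dtype=float),
        "partner_age": cyc["partner_age"].to_numpy(dtype=float),
        "attempt": cyc["attempt"].to_numpy(),
        "n_oocytes": y_o,
        "fert_rate": np.where(y_o > 0, y_m / np.maximum(y_o, 1.0), np.nan),
        "det": cyc["det"].astype(float).to_numpy(na_value=np.nan),
    }
    if cohort.n_embryos:
        grp = cohort.embryos.groupby("cycle_id")[["evenness", "fragmentation"]]
        means = grp.mean().reindex(cyc["cycle_id"]).to_numpy(dtype=float)
        values["mean_evenness"] = means[:, 0]
        values["mean_fragmentation"] = means[:, 1]
    else:
        values["mean_evenness"] = np.full(n, np.nan)
        values["mean_fragmentation"] = np.full(n, np.nan)
    return values


def design_from_values(spec: SubmodelSpec, values: dict, scaling=None,
                       n_rows=None) -> np.ndarray:
    """Assemble the (n, p) design matrix for one submodel.

    ``values`` maps covariate names to scalars or (n,) arrays on the raw
    scale; continuous columns are standardised with ``scaling``. The
    intercept column comes first (ordinal submodels have none — their
    thresholds absorb it).
    """
    if n_rows is None:
        n_rows = 1
        for cov in spec.covariates:
            v = np.atleast_1d(np.asarray(values[cov]))
            n_rows = max(n_rows, v.shape[0])
    cols = [np.ones(n_rows)] if spec.has_intercept else []
    for cov in spec.covariates:
        if cov not in values:
            raise KeyError(
                f"covariate {cov!r} required by the {spec.outcome} submodel "
                "is not available")
        v = values[cov]
        if cov == "attempt":
            a = np.broadcast_to(np.atleast_1d(np.asarray(v, dtype=object)),
                                (n_rows,))
            dummies = np.array([_ATTEMPT_DUMMIES[str(x)] for x in a],
                               dtype=float)
            cols.extend(dummies.T)
        else:
            arr = np.broadcast_to(
                np.atleast_1d(np.asarray(v, dtype=float)), (n_rows,)).copy()
            if cov in CONTINUOUS:
                m, s = scale_of(scaling, cov)
                arr = (arr - m) / s
            cols.append(arr)
    if not cols:
        return np.zeros((n_rows, 0))
    return np.column_stack(cols)


def cycle_design(cohort: Cohort, spec: SubmodelSpec,
                 scaling=None) -> np.ndarray:
    """Design matrix with one row per cycle (submodels O, M, D, L)."""
    if spec.outcome in ("E", "F"):
        raise ValueError("grading submodels are embryo-level; use "
                         "embryo_design")
    values = cycle_covariate_values(cohort)
    return design_from_values(spec, values, scaling, n_rows=cohort.n_cycles)


def embryo_design(cohort: Cohort, spec: SubmodelSpec, scaling=None):
    """Design matrix with one row per embryo, plus the parent-cycle index.

    Cycle-level covariates are broadcast to the embryos; ``icsi`` comes
    from the embryo table.
    """
    cyc_values = cycle_covariate_values(cohort)
    idx = pd.Index(cohort.cycles["cycle_id"])
    parent = idx.get_indexer(cohort.embryos["cycle_id"])
    values = {}
    for cov in spec.covariates:
        if cov == "icsi":
            values[cov] = cohort.embryos["icsi"].to_numpy(dtype=float)
        else:
            v = np.asarray(cyc_values[cov])
            values[cov] = v[parent]
    X = design_from_values(spec, values, scaling,
                           n_rows=cohort.n_embryos)
    return X, parent
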