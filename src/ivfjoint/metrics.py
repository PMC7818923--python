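"""Performance metrics and calibration data for sequential predictions.

Count and ordinal outcomes are scored by root mean squared error (grades
treated as equally spaced integers 1-4, point prediction the
posterior-predictive median by default); the two binary outcomes (DET,
live birth) by the Brier score and the rank-based (Mann-Whitney) AUC with
a DeLong 95% confidence interval. Brier and AUC are computed over the
cycles that reached embryo transfer — the population their submodels are
fitted to — and every report records the denominator used.

In-sample evaluation (scoring the training cohort) is permitted but always
labelled as such: it demonstrates mean calibration machinery, not
validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .cohort import Cohort
from .predict import PredictiveDraws, _apply_denominator


def _paired(predicted, observed):
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must be aligned")
    keep = np.isfinite(p) & np.isfinite(o)
    return p[keep], o[keep]


def rmse(predicted, observed) -> float:
    """Root mean squared error over the defined (stage-reached) pairs."""
    p, o = _paired(predicted, observed)
    if len(p) == 0:
        raise ValueError("no defined prediction/observation pairs")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def brier(predicted_prob, observed_binary) -> float:
    """Mean squared difference between probability and 0/1 outcome."""
    p, o = _paired(predicted_prob, observed_binary)
    if len(p) == 0:
        raise ValueError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - o) ** 2))


def auc(predicted_prob, observed_binary):
    """Mann-Whitney AUC with a DeLong 95% confidence interval.

    Ties are handled by midranks. Requires both classes present.
    Returns ``(auc, lower95, upper95)``.
    """
    p, o = _paired(predicted_prob, observed_binary)
    pos = p[o == 1]
    neg = p[o == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUC requires both outcome classes")
    all_ranks = rankdata(np.concatenate([pos, neg]))
    a = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong structural components
    v10 = (all_ranks[:m] - rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[m:] - rankdata(neg)) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zq = norm.ppf(0.975)
    return (float(a), float(max(a - zq * se, 0.0)),
            float(min(a + zq * se, 1.0)))


@dataclass
class MetricReport:
    """Per-outcome metrics plus the metadata needed to interpret them."""

    rmse: dict = field(default_factory=dict)      # outcome -> value
    brier: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)       # outcome -> (a, lo, hi)
    mode: str = ""
    setting: str = ""
    denominator: str = "per_transfer"
    n: int = 0
    in_sample: bool = True

    def validate(self):
        for v in self.rmse.values():
            assert v >= 0
        for v in self.brier.values():
            assert 0 <= v <= 1
        for a, lo, hi in self.auc.values():
            assert 0 <= lo <= a <= hi <= 1

    def to_json(self, path):
        doc = {"rmse": self.rmse, "brier": self.brier,
               "auc": {k: list(v) for k, v in self.auc.items()},
               "mode": self.mode, "setting": self.setting,
               "denominator": self.denominator, "n": self.n,
               "in_sample": self.in_sample}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            doc = json.load(fh)
        doc["auc"] = {k: tuple(v) for k, v in doc["auc"].items()}
        return cls(**doc)


_OUTCOME_KEY = {"n_oocytes": "y_O", "n_embryos": "y_M",
                "evenness": "even_one", "fragmentation": "frag_one",
                "det": "det", "lbe": "lbe"}


def _point_predictions(draws: PredictiveDraws, key, point="median"):
    vals = _apply_denominator(draws, key)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN rows yield NaN points
        if key in ("det", "lbe"):
            return np.nanmean(vals, axis=1)
        if point == "mean":
            return np.nanmean(vals, axis=1)
        return np.nanmedian(vals, axis=1)


def _align(draws: PredictiveDraws, cohort: Cohort):
    ids = pd.Index([str(i) for i in draws.patient_ids])
    pos = pd.Index(cohort.cycles["cycle_id"]).get_indexer(ids)
    if (pos >= 0).sum() == 0:
        raise ValueError("no overlap between predicted and observed cycles")
    keep = pos >= 0
    return np.flatnonzero(keep), pos[keep]


def evaluate_predictions(draws: PredictiveDraws, cohort: Cohort,
                         mode="", setting="", point="median",
                         in_sample=True) -> MetricReport:
    """Score predictive draws against a cohort's observed outcomes.

    RMSE for the oocyte count, embryo count and the two grading scales
    (embryo-level, grades numeric 1-4); Brier and DeLong-interval AUC for
    DET and live birth over transfer-reaching cycles.
    """
    rows, pos = _align(draws, cohort)
    cyc = cohort.cycles.iloc[pos]
    report = MetricReport(mode=mode, setting=setting, n=len(pos),
                          in_sample=in_sample)
    obs_counts = {
        "n_oocytes": cyc["n_oocytes"].to_numpy(dtype=float),
        "n_embryos": cyc["n_embryos"].astype(float).to_numpy(
            na_value=np.nan),
    }
    if draws.denominator == "per_cycle_started":
        obs_counts["n_embryos"] = np.nan_to_num(obs_counts["n_embryos"],
                                                nan=0.0)
    for name in ("n_oocytes", "n_embryos"):
        pred = _point_predictions(draws, _OUTCOME_KEY[name], point)[rows]
        try:
            report.rmse[name] = rmse(pred, obs_counts[name])
        except ValueError:
            pass
    # grading scales: per-embryo observed grades vs the cycle's
    # posterior-predictive median grade for a hypothetical embryo
    if cohort.n_embryos:
        parent = pd.Index(cohort.cycles["cycle_id"]).get_indexer(
            cohort.embryos["cycle_id"])
        row_of_cycle = np.full(cohort.n_cycles, -1)
        row_of_cycle[pos] = rows
        emb_rows = row_of_cycle[parent]
        ok = emb_rows >= 0
        for name, col in (("evenness", "evenness"),
                          ("fragmentation", "fragmentation")):
            pred_cycle = _point_predictions(draws, _OUTCOME_KEY[name],
                                            point)
            pred = pred_cycle[emb_rows[ok]]
            obs = cohort.embryos[col].to_numpy(dtype=float)[ok]
            try:
                report.rmse[name] = rmse(pred, obs)
            except ValueError:
                pass
    # binary outcomes, per transfer procedure
    tr = (cyc["transferred"] == 1).to_numpy(dtype=bool, na_value=False)
    for name in ("det", "lbe"):
        obs = cyc[name].astype(float).to_numpy(na_value=np.nan)[tr]
        prob = np.nanmean(draws.outcomes[_OUTCOME_KEY[name]][rows],
                          axis=1)[tr] if tr.any() else np.array([])
        try:
            report.brier[name] = brier(prob, obs)
            report.auc[name] = auc(prob, obs)
        except ValueError:
            pass
    report.validate()
    return report


def calibration_data(draws: PredictiveDraws, observed: Cohort,
                     outcome="n_oocytes", in_sample=True) -> pd.DataFrame:
    """Per-cycle predictive percentiles joined to the observed response.

    The layout backs interval-versus-observed calibration plots: one row
    per cycle with the 2.5/50/97.5 predictive percentiles, the observed
    value and an ``in_sample`` label (scoring the training data does not
    constitute validation). Grade outcomes compare the observed per-cycle
    mean grade against the predictive mean-grade distribution.
    """
    key = {"n_oocytes": "y_O", "n_embryos": "y_M",
           "evenness": "mean_evenness", "fragmentation":
           "mean_fragmentation", "det": "det", "lbe": "lbe"}[outcome]
    rows, pos = _align(draws, observed)
    cyc = observed.cycles.iloc[pos]
    if outcome in ("evenness", "fragmentation"):
        col = {"evenness": "evenness",
               "fragmentation": "fragmentation"}[outcome]
        if observed.n_embryos == 0:
            raise ValueError("cohort has no embryos to calibrate against")
        means = observed.embryos.groupby("cycle_id")[col].mean()
        obs = means.reindex(cyc["cycle_id"]).to_numpy(dtype=float)
    else:
        colname = {"n_oocytes": "n_oocytes", "n_embryos": "n_embryos",
                   "det": "det", "lbe": "lbe"}[outcome]
        obs = cyc[colname].astype(float).to_numpy(na_value=np.nan)
        if draws.denominator == "per_cycle_started" \
                and outcome != "n_oocytes":
            obs = np.nan_to_num(obs, nan=0.0)
    vals = _apply_denominator(draws, key)[rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q = np.nanpercentile(vals, [2.5, 50, 97.5], axis=1)
    return pd.DataFrame({
        "cycle_id": cyc["cycle_id"].to_numpy(),
        "observed": obs,
        "p2.5": q[0], "p50": q[1], "p97.5": q[2],
        "in_sample": in_sample,
    })


def plot_calibration(table: pd.DataFrame, path, title=""):
    """Minimal interval-vs-observed calibration figure (PNG export)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    t = table.sort_values("p50").reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(t))
    ax.fill_between(x, t["p2.5"], t["p97.5"], alpha=0.3,
                    label="95% predictive interval")
    ax.plot(x, t["p50"], lw=1, label="predictive median")
    ax.plot(x, t["observed"], ".", ms=3, alpha=0.6, label="observed")
    ax.set_xlabel("cycles (sorted by predictive median)")
    ax.set_title(title + (" (in-sample)" if t["in_sample"].all() else ""))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
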