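"""Domain types, CSV I/O and validation for two-level IVF cohorts.

An IVF cohort is stored as two tidy tables. The *cycle* table has one row
per initiated treatment cycle and records the patient's baseline covariates
together with the sequential stage outcomes: the oocyte (egg) count from
ovarian stimulation, whether oocytes were mixed/injected with sperm, the
number of gradable embryos obtained, and — for cycles reaching embryo
transfer — the double-embryo-transfer (DET) and live-birth-event (LBE)
indicators. The *embryo* table has one row per gradable embryo with its two
ordinal quality grades (cell evenness and degree of fragmentation, each
1-4) and the fertilisation-method flag (ICSI: sperm injected into egg).

Treatment may fail at any stage, in which case downstream outcomes are
*undefined* — not zero. The distinction is load-bearing for sequential
prediction denominators, so undefined values are held as missing values in
memory and as empty fields on disk; an observed zero is written as ``0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CYCLE_COLUMNS = [
    "cycle_id", "age", "partner_age", "attempt", "n_oocytes",
    "mixed", "n_embryos", "transferred", "det", "lbe",
]
EMBRYO_COLUMNS = ["cycle_id", "evenness", "fragmentation", "icsi"]

ATTEMPT_CATEGORIES = ("1", "2", "3", "4-5")


class CohortError(ValueError):
    """Base class for cohort schema / invariant failures."""


class SchemaError(CohortError):
    """A column is missing or a cell violates its declared type/range."""


class InvariantError(CohortError):
    """Tables are well-typed but violate a structural invariant."""


class EmptyCohortError(CohortError):
    """An operation requiring data was given an empty cohort."""


@dataclass
class Embryo:
    """One gradable embryo: ordinal grades (1-4) and fertilisation method."""

    cycle_id: str
    evenness: int
    fragmentation: int
    icsi: int


@dataclass
class PatientCycle:
    """One treatment cycle's covariates and stage-wise outcomes.

    Downstream fields are ``None`` when the stage was never reached:
    ``mixed`` is undefined when no oocytes were obtained; ``n_embryos``,
    ``transferred`` are undefined unless oocytes were mixed; ``det`` and
    ``lbe`` are defined if and only if the cycle reached embryo transfer.
    """

    cycle_id: str
    age: float
    partner_age: float
    attempt: str
    n_oocytes: int
    mixed: Optional[int] = None
    n_embryos: Optional[int] = None
    transferred: Optional[int] = None
    det: Optional[int] = None
    lbe: Optional[int] = None


@dataclass
class Cohort:
    """Validated two-table cohort plus the covariate scaling in force.

    ``covariate_scaling`` maps a continuous covariate name to the
    ``(mean, sd)`` pair used to standardise it wherever model linear
    predictors are evaluated; ``None`` until a generator or a fit sets it.
    """

    cycles: pd.DataFrame
    embryos: pd.DataFrame
    covariate_scaling: Optional[dict] = field(default=None)

    @classmethod
    def from_records(cls, cycles, embryos, covariate_scaling=None,
                     validate_cohort=True):
        """Build a cohort from iterables of PatientCycle / Embryo records."""
        cyc = pd.DataFrame(
            [vars(c) for c in cycles], columns=CYCLE_COLUMNS)
        emb = pd.DataFrame(
            [vars(e) for e in embryos], columns=EMBRYO_COLUMNS)
        cohort = cls(_coerce_cycles(cyc), _coerce_embryos(emb),
                     covariate_scaling)
        if validate_cohort:
            validate(cohort)
        return cohort

    @property
    def n_cycles(self):
        return len(self.cycles)

    @property
    def n_embryos(self):
        return len(self.embryos)

    def equals(self, other: "Cohort") -> bool:
        return (self.cycles.reset_index(drop=True).equals(
                    other.cycles.reset_index(drop=True))
                and self.embryos.reset_index(drop=True).equals(
                    other.embryos.reset_index(drop=True)))


def _fail(kind, table, row_id, message):
    raise kind(f"{table} row {row_id!r}: {message}")


def _to_nullable_int(frame, table, col, lo=None, hi=None):
    raw = frame[col]
    out = pd.array([pd.NA] * len(raw), dtype="Int64")
    for i, v in enumerate(raw):
        if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
            continue
        if isinstance(v, str):
            v = v.strip()
            if v == "":
                continue
            if v == ".":
                _fail(SchemaError, table, frame["cycle_id"].iloc[i],
                      f"'{col}' uses '.' as a missing marker; "
                      "empty field required")
        try:
            f = float(v)
        except (TypeError, ValueError):
            _fail(SchemaError, table, frame["cycle_id"].iloc[i],
                  f"'{col}' value {v!r} is not numeric")
        if f != int(f):
            _fail(SchemaError, table, frame["cycle_id"].iloc[i],
                  f"'{col}' value {v!r} is not an integer")
        iv = int(f)
        if (lo is not None and iv < lo) or (hi is not None and iv > hi):
            _fail(SchemaError, table, frame["cycle_id"].iloc[i],
                  f"'{col}' value {iv} outside [{lo}, {hi}]")
        out[i] = iv
    return out


def _to_float(frame, table, col):
    raw = frame[col]
    out = np.full(len(raw), np.nan)
    for i, v in enumerate(raw):
        if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            _fail(SchemaError, table, frame["cycle_id"].iloc[i],
                  f"'{col}' is missing")
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            _fail(SchemaError, table, frame["cycle_id"].iloc[i],
                  f"'{col}' value {v!r} is not numeric")
    return out


def _coerce_cycles(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CYCLE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"cycles table missing columns: {missing}")
    out = pd.DataFrame(index=range(len(frame)))
    out["cycle_id"] = frame["cycle_id"].astype(str)
    tmp = frame.copy()
    tmp["cycle_id"] = out["cycle_id"]
    out["age"] = _to_float(tmp, "cycles", "age")
    out["partner_age"] = _to_float(tmp, "cycles", "partner_age")
    # Attempts beyond the 3rd are pooled at read time (sparse categories).
    att = []
    for i, v in enumerate(tmp["attempt"]):
        s = str(v).strip()
        if s in ("4", "5", "4-5"):
            s = "4-5"
        if s not in ATTEMPT_CATEGORIES:
            _fail(SchemaError, "cycles", out["cycle_id"].iloc[i],
                  f"'attempt' value {v!r} not in {ATTEMPT_CATEGORIES}")
        att.append(s)
    out["attempt"] = att
    out["n_oocytes"] = _to_nullable_int(tmp, "cycles", "n_oocytes", lo=0)
    for col in ("mixed", "transferred", "det", "lbe"):
        out[col] = _to_nullable_int(tmp, "cycles", col, lo=0, hi=1)
    out["n_embryos"] = _to_nullable_int(tmp, "cycles", "n_embryos", lo=0)
    out = out[CYCLE_COLUMNS]
    if out["n_oocytes"].isna().any():
        bad = out.loc[out["n_oocytes"].isna(), "cycle_id"].iloc[0]
        _fail(SchemaError, "cycles", bad, "'n_oocytes' is missing")
    return out


def _coerce_embryos(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EMBRYO_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"embryos table missing columns: {missing}")
    out = pd.DataFrame(index=range(len(frame)))
    out["cycle_id"] = frame["cycle_id"].astype(str)
    tmp = frame.copy()
    tmp["cycle_id"] = out["cycle_id"]
    for col, hi in (("evenness", 4), ("fragmentation", 4), ("icsi", 1)):
        vals = _to_nullable_int(tmp, "embryos", col, lo=0 if hi == 1 else 1,
                                hi=hi)
        if vals.isna().any():
            bad = out["cycle_id"][np.asarray(vals.isna())].iloc[0]
            _fail(SchemaError, "embryos", bad,
                  f"'{col}' is missing for a gradable embryo")
        out[col] = vals
    return out[EMBRYO_COLUMNS]


def validate(cohort: Cohort) -> None:
    """Check referential integrity and the stage-funnel invariants.

    Raises :class:`InvariantError` naming the first offending row.
    """
    cyc, emb = cohort.cycles, cohort.embryos
    if cyc["cycle_id"].duplicated().any():
        dup = cyc.loc[cyc["cycle_id"].duplicated(), "cycle_id"].iloc[0]
        _fail(InvariantError, "cycles", dup, "duplicate cycle_id")
    known = set(cyc["cycle_id"])
    unknown = ~emb["cycle_id"].isin(known)
    if unknown.any():
        _fail(InvariantError, "embryos", emb.loc[unknown, "cycle_id"].iloc[0],
              "embryo refers to unknown cycle_id")

    emb_counts = emb.groupby("cycle_id").size()
    n_emb_rows = emb_counts.reindex(cyc["cycle_id"]).fillna(0) \
        .to_numpy(dtype=int)

    def first_bad(mask, message):
        m = np.asarray(mask, dtype=bool)
        if m.any():
            _fail(InvariantError, "cycles",
                  cyc["cycle_id"].iloc[int(np.argmax(m))], message)

    mixed1 = (cyc["mixed"] == 1).to_numpy(dtype=bool, na_value=False)
    for col in ("n_embryos", "transferred", "det", "lbe"):
        defined = cyc[col].notna().to_numpy()
        first_bad(~mixed1 & defined,
                  f"'{col}' defined although mixed is undefined or 0")
    first_bad(~mixed1 & (n_emb_rows > 0),
              "embryo rows present although oocytes were not mixed")

    n_oo = cyc["n_oocytes"].to_numpy(dtype=float)
    n_em = cyc["n_embryos"].astype(float).to_numpy(na_value=np.nan)
    first_bad(mixed1 & (n_oo < 1), "mixed=1 requires at least one oocyte")
    first_bad(mixed1 & np.isnan(n_em), "mixed=1 but n_embryos undefined")
    with np.errstate(invalid="ignore"):
        first_bad(mixed1 & (n_em > n_oo), "n_embryos > n_oocytes")
        first_bad(mixed1 & ~np.isnan(n_em) & (n_emb_rows != n_em),
                  "n_embryos does not match the number of embryo rows")

    tr_def = cyc["transferred"].notna().to_numpy()
    tr1 = (cyc["transferred"] == 1).to_numpy(dtype=bool, na_value=False)
    det_def = cyc["det"].notna().to_numpy()
    lbe_def = cyc["lbe"].notna().to_numpy()
    first_bad(mixed1 & ~tr_def & (det_def | lbe_def),
              "det/lbe defined although transferred is undefined")
    with np.errstate(invalid="ignore"):
        first_bad(tr1 & ~(n_em >= 1), "transferred=1 with no embryos")
    first_bad(tr1 & ~det_def, "transferred=1 but 'det' undefined")
    first_bad(tr1 & ~lbe_def, "transferred=1 but 'lbe' undefined")
    first_bad(tr_def & ~tr1 & det_def, "'det' defined although transferred=0")
    first_bad(tr_def & ~tr1 & lbe_def, "'lbe' defined although transferred=0")
    det1 = (cyc["det"] == 1).to_numpy(dtype=bool, na_value=False)
    with np.errstate(invalid="ignore"):
        first_bad(det1 & ~(n_em >= 2), "det=1 with n_embryos<2")

    # Stage funnel: lbe=1 <= transferred <= (>=1 embryo) <= mixed <= cycles.
    counts = funnel_counts(cohort)
    keys = ["cycles", "mixed", "with_embryos", "transferred", "live_births"]
    vals = [counts[k] for k in keys]
    if any(a < b for a, b in zip(vals, vals[1:])):
        raise InvariantError(f"stage funnel not monotone: {counts}")


def funnel_counts(cohort: Cohort) -> dict:
    cyc = cohort.cycles
    return {
        "cycles": len(cyc),
        "mixed": int((cyc["mixed"] == 1).sum()),
        "with_embryos": int((cyc["n_embryos"] >= 1).sum()),
        "transferred": int((cyc["transferred"] == 1).sum()),
        "live_births": int((cyc["lbe"] == 1).sum()),
    }


def read_cohort(cycle_path, embryo_path) -> Cohort:
    """Read and validate a cohort from its two CSV files.

    Empty fields are the only recognised missing-value marker (a stage not
    reached); ``"."`` is rejected, and ``0`` always means an observed zero.
    """
    cyc = pd.read_csv(cycle_path, dtype=str, keep_default_na=False)
    emb = pd.read_csv(embryo_path, dtype=str, keep_default_na=False)
    cyc = cyc.replace({"": None})
    emb = emb.replace({"": None})
    cohort = Cohort(_coerce_cycles(cyc), _coerce_embryos(emb))
    validate(cohort)
    return cohort


def write_cohort(cohort: Cohort, cycle_path, embryo_path) -> None:
    """Write the two CSV tables; undefined cells become empty fields.

    Round-trip contract: ``read_cohort`` on the written files reproduces
    the cohort exactly, including the missingness pattern.
    """
    cohort.cycles.to_csv(cycle_path, index=False, na_rep="")
    cohort.embryos.to_csv(embryo_path, index=False, na_rep="")


def _five_number(x) -> dict:
    x = np.asarray(x, dtype=float)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "min": float(np.min(x)), "max": float(np.max(x))}


def summarise_cohort(cohort: Cohort) -> dict:
    """Cohort characteristics in the layout of a clinical baseline table.

    Returns counts of cycles started / cycles with mixing / gradable
    embryos / transfer procedures, five-number summaries of ages and of
    per-cycle oocyte and embryo counts, the attempt-number breakdown, and
    DET / LBE frequencies per transfer procedure.
    """
    if cohort.n_cycles == 0:
        raise EmptyCohortError("cannot summarise an empty cohort")
    cyc = cohort.cycles
    n_tr = int((cyc["transferred"] == 1).sum())
    att = {c: int((cyc["attempt"] == c).sum()) for c in ATTEMPT_CATEGORIES}
    emb_per_cycle = cyc["n_embryos"].fillna(0).astype(int).to_numpy()
    out = {
        "n_cycles": len(cyc),
        "n_mixed": int((cyc["mixed"] == 1).sum()),
        "n_gradable_embryos": cohort.n_embryos,
        "n_transfers": n_tr,
        "age": _five_number(cyc["age"]),
        "partner_age": _five_number(cyc["partner_age"]),
        "attempt": {k: {"count": v, "prop": v / len(cyc)}
                    for k, v in att.items()},
        "oocytes_per_cycle": _five_number(cyc["n_oocytes"].astype(int)),
        "embryos_per_cycle": _five_number(emb_per_cycle),
    }
    if n_tr:
        det1 = int((cyc["det"] == 1).sum())
        lbe1 = int((cyc["lbe"] == 1).sum())
        out["det_per_transfer"] = {
            "single": {"count": n_tr - det1, "prop": (n_tr - det1) / n_tr},
            "double": {"count": det1, "prop": det1 / n_tr},
        }
        out["lbe_per_transfer"] = {
            "no": {"count": n_tr - lbe1, "prop": (n_tr - lbe1) / n_tr},
            "yes": {"count": lbe1, "prop": lbe1 / n_tr},
        }
    else:
        out["det_per_transfer"] = None
        out["lbe_per_transfer"] = None
    return out


def summary_frame(summary: dict) -> pd.DataFrame:
    """Flatten a summarise_cohort dict into a two-column display table."""
    rows = []

    def fmt5(d):
        return (f"{d['median']:g} ({d['q1']:g} to {d['q3']:g}; "
                f"range {d['min']:g} to {d['max']:g})")

    rows.append(("No of cycles started", summary["n_cycles"]))
    rows.append(("No of cycles where eggs mixed with sperm",
                 summary["n_mixed"]))
    rows.append(("No of gradable embryos", summary["n_gradable_embryos"]))
    rows.append(("Number of embryo transfer procedures",
                 summary["n_transfers"]))
    rows.append(("Age (years)", fmt5(summary["age"])))
    rows.append(("Partner age (years)", fmt5(summary["partner_age"])))
    for k, v in summary["attempt"].items():
        rows.append((f"Attempt number {k}",
                     f"{v['count']} ({100 * v['prop']:.0f}%)"))
    rows.append(("Oocytes per cycle started",
                 fmt5(summary["oocytes_per_cycle"])))
    rows.append(("Gradable embryos per cycle started",
                 fmt5(summary["embryos_per_cycle"])))
    if summary["det_per_transfer"] is not None:
        for lab, key in (("1", "single"), ("2", "double")):
            v = summary["det_per_transfer"][key]
            rows.append((f"Embryos transferred per procedure: {lab}",
                         f"{v['count']} ({100 * v['prop']:.0f}%)"))
        for lab in ("no", "yes"):
            v = summary["lbe_per_transfer"][lab]
            rows.append((f"Live birth event per transfer: {lab}",
                         f"{v['count']} ({100 * v['prop']:.0f}%)"))
    return pd.DataFrame(rows, columns=["variable", "summary"])
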