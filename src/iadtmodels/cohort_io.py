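"""Patient-cohort containers, CSV round-trip, preprocessing and exclusion.

A cohort is a long-format CSV with one row per PSA draw:

    patient_id, time_days, psa_ugL, on_treatment[, psa_err][, label]

The per-patient treatment schedule is derived from maximal runs of
``on_treatment == 1``, with run boundaries placed at the midpoint between
adjacent samples whose flags differ (exact clinical switch dates are not in
the data model).

Preprocessing applies the assay detection floor (PSA below 0.1 µg/L set to
0.1 µg/L) and assigns measurement errors, either uniformly at the maximal
assay error e_max = 0.1 µg/L or with the peak-referenced declining-relevance
weights (which combine magnitudes on different scales and are therefore
guarded by a positive floor — retained as specified rather than silently
redefined).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedule import TreatmentInterval, TreatmentSchedule

__all__ = [
    "PatientRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "preprocess",
    "exclusion_filter",
    "DETECTION_FLOOR",
    "E_MAX",
]

DETECTION_FLOOR = 0.1   # µg/L, assay detection threshold
E_MAX = 0.1             # µg/L, maximal per-point PSA error
_ERR_FLOOR = 0.01       # µg/L, positivity guard for peak-referenced weights

LABELS = ("omega", "not_omega", "unknown")  # Ω (relapsing) / ¬Ω / unknown


@dataclass
class PatientRecord:
    """One patient's PSA series with errors, flags and derived schedule."""

    patient_id: str
    times: np.ndarray       # days, strictly increasing
    psa: np.ndarray         # µg/L
    errors: np.ndarray      # µg/L, > 0
    on_flag: np.ndarray     # per-point {0, 1}
    label: str = "unknown"
    schedule: TreatmentSchedule = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.psa = np.asarray(self.psa, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        self.on_flag = np.asarray(self.on_flag, dtype=int)
        n = self.times.size
        if not (self.psa.size == self.errors.size == self.on_flag.size == n):
            raise ValueError(f"{self.patient_id}: ragged record arrays")
        if n and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.patient_id}: times not strictly increasing")
        if np.any(self.errors <= 0):
            raise ValueError(f"{self.patient_id}: nonpositive PSA errors")
        if self.label not in LABELS:
            raise ValueError(f"{self.patient_id}: unknown label {self.label!r}")
        if self.schedule is None:
            self.schedule = schedule_from_flags(
                self.patient_id, self.times, self.on_flag
            )

    @property
    def n_points(self) -> int:
        return self.times.size


def schedule_from_flags(patient_id, times, on_flag) -> TreatmentSchedule:
    """Derive on-intervals from per-sample flags (midpoint boundaries)."""
    times = np.asarray(times, dtype=float)
    on = np.asarray(on_flag, dtype=int)
    if times.size == 0:
        raise ValueError("cannot derive a schedule from an empty record")
    t_min, t_max = float(times[0]), float(times[-1])
    if t_min == t_max:
        t_max = t_min + 1.0
    bounds = []
    start = t_min if on[0] else None
    for k in range(1, times.size):
        if on[k] != on[k - 1]:
            mid = 0.5 * (times[k - 1] + times[k])
            if on[k]:  # off → on
                start = mid
            else:      # on → off
                bounds.append(TreatmentInterval(start, mid))
                start = None
    if start is not None:
        bounds.append(TreatmentInterval(start, t_max))
    return TreatmentSchedule(tuple(bounds), t_min=t_min, t_max=t_max,
                             patient_id=str(patient_id))


@dataclass
class Cohort:
    records: list[PatientRecord]
    provenance: dict = field(default_factory=dict)
    ground_truth: dict | None = None  # generator metadata, when synthetic

    def __post_init__(self):
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in cohort")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for r in self.records:
            frames.append(pd.DataFrame({
                "patient_id": r.patient_id,
                "time_days": r.times,
                "psa_ugL": r.psa,
                "on_treatment": r.on_flag,
                "psa_err": r.errors,
                "label": r.label,
            }))
        if not frames:
            return pd.DataFrame(columns=[
                "patient_id", "time_days", "psa_ugL", "on_treatment",
                "psa_err", "label",
            ])
        return pd.concat(frames, ignore_index=True)


_KNOWN_COLS = {"patient_id", "time_days", "psa_ugL", "on_treatment",
               "psa_err", "label"}
_REQUIRED_COLS = {"patient_id", "time_days", "psa_ugL", "on_treatment"}


def read_cohort(path) -> Cohort:
    """Parse a long-format cohort CSV into records with derived schedules."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return Cohort(records=[], provenance={"source": str(path), "filters": []})
    if df.empty:
        return Cohort(records=[], provenance={"source": str(path), "filters": []})
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    extra = set(df.columns) - _KNOWN_COLS
    if extra:
        warnings.warn(f"ignoring unknown cohort columns: {sorted(extra)}",
                      UserWarning, stacklevel=2)
    if df.duplicated(subset=["patient_id", "time_days"]).any():
        dup = df[df.duplicated(subset=["patient_id", "time_days"])]
        raise ValueError(
            "duplicated (patient_id, time_days) rows, first: "
            f"{dup.iloc[0].to_dict()}"
        )
    records = []
    for pid, g in df.groupby("patient_id", sort=False):
        g = g.sort_values("time_days")
        errors = (g["psa_err"].to_numpy(float) if "psa_err" in g
                  else np.full(len(g), E_MAX))
        label = "unknown"
        if "label" in g:
            vals = set(g["label"].astype(str))
            if len(vals) == 1:
                label = vals.pop()
                if label not in LABELS:
                    label = "unknown"
        records.append(PatientRecord(
            patient_id=str(pid),
            times=g["time_days"].to_numpy(float),
            psa=g["psa_ugL"].to_numpy(float),
            errors=errors,
            on_flag=g["on_treatment"].to_numpy(int),
            label=label,
        ))
    return Cohort(records=records,
                  provenance={"source": str(path), "filters": []})


def write_cohort(cohort: Cohort, path) -> None:
    cohort.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(record: PatientRecord, floor: float = DETECTION_FLOOR,
               e_max: float = E_MAX, error_mode: str = "uniform") -> PatientRecord:
    """Apply the detection floor and assign per-point PSA errors.

    ``uniform`` sets every error to e_max.  ``peak_weighted`` implements the
    declining-relevance weighting referenced to the last PSA peak (ĉ, t̂):
    e_i = |c_i − ĉ| at t = t̂ and e_i = |ĉ| − |t̂ − t_i| + |c_i| elsewhere,
    floored at 0.01 µg/L.
    """
    psa = np.maximum(record.psa, floor)
    if error_mode == "uniform":
        errors = np.full(psa.size, e_max)
    elif error_mode == "peak_weighted":
        i_hat = int(np.argmax(psa))            # last peak: argmax, last if tied
        ties = np.flatnonzero(psa == psa[i_hat])
        i_hat = int(ties[-1])
        c_hat, t_hat = psa[i_hat], record.times[i_hat]
        errors = np.abs(c_hat) - np.abs(t_hat - record.times) + np.abs(psa)
        errors[i_hat] = abs(psa[i_hat] - c_hat)
        errors = np.maximum(errors, _ERR_FLOOR)
    else:
        raise ValueError(f"unknown error_mode {error_mode!r}")
    return replace(record, psa=psa, errors=errors)


# ---------------------------------------------------------------------------
# exclusion filters
# ---------------------------------------------------------------------------

def fluctuation_statistic(record: PatientRecord, kind: str = "range") -> float:
    """PSA fluctuation summary used by the exclusion filter.

    ``range``: max − min of the PSA series (µg/L) — a patient whose whole
    excursion stays inside the natural day-to-day variability band is
    considered non-pathological.  ``max_daily_change``: max over consecutive
    samples of |ΔPSA|/Δt (µg/L/day).
    """
    if record.n_points < 2:
        return 0.0
    if kind == "range":
        return float(record.psa.max() - record.psa.min())
    if kind == "max_daily_change":
        return float(np.max(np.abs(np.diff(record.psa)) / np.diff(record.times)))
    raise ValueError(f"unknown fluctuation statistic {kind!r}")


def exclusion_filter(
    cohort: Cohort,
    fluct_min: float = 2.0,
    min_points: int | None = None,
    statistic: str = "range",
) -> Cohort:
    """Drop non-informative patients, logging each exclusion with a reason.

    Excluded are patients whose PSA fluctuation statistic is below
    ``fluct_min`` (default 2.0 µg/L: the natural variability scale of serum
    PSA) and patients with fewer than ``min_points`` samples (default
    ceil(sqrt(N)) with N the pre-filter cohort size — the Poisson-noise
    floor on the sample count).  Idempotent: the point threshold is frozen
    into the output provenance so re-filtering changes nothing.
    """
    prior_filters = list(cohort.provenance.get("filters", []))
    if min_points is None:
        frozen = cohort.provenance.get("min_points_rule")
        min_points = (int(frozen) if frozen is not None
                      else math.ceil(math.sqrt(len(cohort))))
    kept, log = [], []
    for r in cohort.records:
        stat = fluctuation_statistic(r, kind=statistic)
        if stat < fluct_min:
            log.append({"patient_id": r.patient_id, "reason": "fluctuation",
                        "statistic": stat, "threshold": fluct_min})
            continue
        if r.n_points < min_points:
            log.append({"patient_id": r.patient_id, "reason": "too_few_points",
                        "n_points": int(r.n_points), "threshold": min_points})
            continue
        kept.append(r)
    prov = dict(cohort.provenance)
    prov["filters"] = prior_filters + log
    prov["min_points_rule"] = min_points
    return Cohort(records=kept, provenance=prov,
                  ground_truth=cohort.ground_truth)


def write_filter_log(cohort: Cohort, path) -> None:
    """Exclusion log as JSON lines."""
    with open(path, "w") as fh:
        for entry in cohort.provenance.get("filters", []):
            fh.write(json.dumps(entry) + "\n")
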