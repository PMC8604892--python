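"""Patient-specific treatment schedules.

Intermittent androgen-deprivation therapy alternates on-treatment cycles
``τ_i = [start_i, end_i)`` with off-treatment gaps.  A schedule carries the
control function ``u(t) ∈ {0, 1}`` (1 while on treatment) that forces every
model right-hand side, plus the observation window ``[t_min, t_max]``.

Times are in days throughout; week-denominated clinical statistics are
converted with a factor of 7 before they reach this module.

The on-interval convention is half-open ``[start, end)`` so that abutting
on/off blocks tile the time axis without double counting; a sample taken
exactly on a switch day is therefore attributed to the phase that starts
that day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["TreatmentInterval", "TreatmentSchedule"]


@dataclass(frozen=True)
class TreatmentInterval:
    """One on-treatment cycle ``[start, end)`` in days."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start) and np.isfinite(self.end)):
            raise ValueError("interval endpoints must be finite")
        if self.start < 0:
            raise ValueError("interval start must be >= 0")
        if not self.start < self.end:
            raise ValueError(
                f"interval start must precede end, got [{self.start}, {self.end})"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TreatmentSchedule:
    """Ordered, disjoint on-treatment intervals inside ``[t_min, t_max]``."""

    intervals: tuple[TreatmentInterval, ...]
    t_min: float
    t_max: float
    patient_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "intervals",
            tuple(
                iv if isinstance(iv, TreatmentInterval) else TreatmentInterval(*iv)
                for iv in self.intervals
            ),
        )
        if not self.t_min < self.t_max:
            raise ValueError("t_min must precede t_max")
        prev_end = -np.inf
        for iv in self.intervals:
            if iv.start < prev_end:
                raise ValueError("treatment intervals must be sorted and disjoint")
            prev_end = iv.end
            if iv.start < self.t_min or iv.end > self.t_max:
                raise ValueError(
                    f"interval [{iv.start}, {iv.end}) outside [{self.t_min}, {self.t_max}]"
                )

    # -- control function -------------------------------------------------

    def indicator(self, t):
        """Evaluate the control function u(t): 1 on-treatment, 0 off.

        Accepts scalars or arrays; raises for times outside the observation
        window.
        """
        arr = np.asarray(t, dtype=float)
        if np.any(arr < self.t_min) or np.any(arr > self.t_max):
            raise ValueError(
                f"time outside schedule domain [{self.t_min}, {self.t_max}]"
            )
        out = np.zeros_like(arr, dtype=int)
        for iv in self.intervals:
            out |= (arr >= iv.start) & (arr < iv.end)
        return int(out) if np.isscalar(t) or arr.ndim == 0 else out

    def __call__(self, t):
        return self.indicator(t)

    # -- derived quantities ------------------------------------------------

    @property
    def n_cycles(self) -> int:
        return len(self.intervals)

    @property
    def on_duration(self) -> float:
        """Total on-treatment time (sum of interval lengths), days."""
        return float(sum(iv.duration for iv in self.intervals))

    def switch_times(self, clip: bool = True) -> np.ndarray:
        """Interval boundaries, for piecewise ODE integration.

        With ``clip`` (default) boundaries coinciding with t_min/t_max are
        dropped so the result partitions the open window.
        """
        pts = []
        for iv in self.intervals:
            pts.extend((iv.start, iv.end))
        out = np.array(sorted(set(pts)), dtype=float)
        if clip:
            out = out[(out > self.t_min) & (out < self.t_max)]
        return out

    def segments(self) -> list[tuple[float, float, int]]:
        """Maximal constant-u pieces ``(t0, t1, u)`` covering [t_min, t_max]."""
        knots = np.concatenate(
            ([self.t_min], self.switch_times(), [self.t_max])
        )
        segs = []
        for a, b in zip(knots[:-1], knots[1:]):
            segs.append((float(a), float(b), self.indicator(a)))
        return segs

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "t_min": self.t_min,
            "t_max": self.t_max,
            "intervals": [[iv.start, iv.end] for iv in self.intervals],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentSchedule":
        return cls(
            intervals=tuple(TreatmentInterval(a, b) for a, b in d["intervals"]),
            t_min=float(d["t_min"]),
            t_max=float(d["t_max"]),
            patient_id=d.get("patient_id"),
        )

    @classmethod
    def from_json(cls, path) -> "TreatmentSchedule":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_durations(
        cls,
        t_min: float,
        on_off_days: Sequence[tuple[float, float]],
        patient_id: str | None = None,
    ) -> "TreatmentSchedule":
        """Build an alternating schedule from (on, off) day pairs."""
        t = t_min
        ivs = []
        for on_d, off_d in on_off_days:
            ivs.append(TreatmentInterval(t, t + on_d))
            t += on_d + off_d
        return cls(tuple(ivs), t_min=t_min, t_max=t, patient_id=patient_id)
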