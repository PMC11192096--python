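"""Discrete threat-timing schedules and their hazard algebra.

A threat-anticipation trial delivers an aversive event (a shock) at one
discrete timepoint drawn from a probability mass function (pmf) over trial
seconds.  Two descriptions of the same schedule behave very differently as
the trial unfolds:

* ``P(Threat)`` -- the marginal pmf, fixed before the trial starts;
* the *hazard rate* ``h(t) = p(t) / (1 - sum_{s<t} p(s))`` -- the
  probability of the shock arriving *now* given that it has not arrived
  yet.

For a certain countdown (all mass on the final second) both descriptions
coincide at the end of the trial and the hazards sum to exactly 1.  For a
temporally uncertain schedule the hazard climbs as safe seconds pass: the
uniform four-step schedule ``[.25, .25, .25, .25]`` has hazards
``.25, 1/3, .5, 1`` whose sum (the *cumulative hazard*) is about 2.08.
That dissociation between marginal probability and hazard is the quantity
this package manipulates and measures.

This module provides the schedule container, validation, the
survival/hazard/cumulative-hazard transform, and JSON/CSV round-trip IO.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np

#: Absolute tolerance for requiring a pmf to sum to one.
PMF_TOL = 1e-9


class ScheduleValidationError(ValueError):
    """Base class for every threat-schedule validation failure."""


class NegativeMassError(ScheduleValidationError):
    """Some probability mass is negative."""


class ImproperMassError(ScheduleValidationError):
    """The pmf does not sum to one within :data:`PMF_TOL`."""


class UnsortedTimepointsError(ScheduleValidationError):
    """Timepoints are not strictly increasing."""


class LengthMismatchError(ScheduleValidationError):
    """``timepoints`` and ``pmf`` have different lengths."""


def _as_float_array(values: Iterable[float]) -> np.ndarray:
    return np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)


@dataclass(frozen=True)
class ThreatSchedule:
    """A discrete distribution of shock time over trial seconds.

    Parameters
    ----------
    timepoints
        0-based integer trial seconds, strictly increasing.  Timepoint
        ``t`` means "during second ``t``" at 1-second resolution.
    pmf
        Probability that the shock lands at each timepoint.  A proper
        schedule sums to one: every trial ends in a shock.
    label
        Free-text name, e.g. ``"early-threat"``.
    """

    timepoints: np.ndarray
    pmf: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints",
                           np.asarray(self.timepoints, dtype=int))
        object.__setattr__(self, "pmf", _as_float_array(self.pmf))

    def __len__(self) -> int:
        return len(self.timepoints)

    @property
    def last_support(self) -> int:
        """Last timepoint carrying positive mass."""
        nz = np.nonzero(self.pmf)[0]
        if len(nz) == 0:
            raise ImproperMassError("schedule carries no mass")
        return int(self.timepoints[nz[-1]])


@dataclass(frozen=True)
class HazardProfile:
    """Survival, hazard and cumulative hazard derived from a schedule.

    The profile is truncated at the last support point of the pmf: once
    survival reaches zero the hazard is undefined and is not emitted.
    """

    timepoints: np.ndarray
    survival: np.ndarray
    hazard: np.ndarray
    cumulative_hazard: np.ndarray

    def hazard_at(self, t: int) -> float:
        """Hazard at timepoint ``t`` (0 before support, error after it)."""
        idx = np.searchsorted(self.timepoints, t)
        if idx >= len(self.timepoints) or self.timepoints[idx] != t:
            raise ValueError(
                f"hazard undefined at t={t}: profile covers "
                f"[{self.timepoints[0]}, {self.timepoints[-1]}]")
        return float(self.hazard[idx])


def validate_schedule(schedule: ThreatSchedule) -> ThreatSchedule:
    """Check schedule invariants, returning the schedule unchanged.

    Raises
    ------
    LengthMismatchError, UnsortedTimepointsError, NegativeMassError,
    ImproperMassError
        One distinct error per violated invariant.
    """
    if len(schedule.timepoints) != len(schedule.pmf):
        raise LengthMismatchError(
            f"{len(schedule.timepoints)} timepoints vs {len(schedule.pmf)} masses")
    if len(schedule.timepoints) == 0:
        raise ImproperMassError("empty schedule")
    if np.any(np.diff(schedule.timepoints) <= 0):
        raise UnsortedTimepointsError("timepoints must be strictly increasing")
    if np.any(schedule.pmf < 0):
        raise NegativeMassError(f"negative mass in {schedule.pmf}")
    total = float(schedule.pmf.sum())
    if abs(total - 1.0) > PMF_TOL:
        raise ImproperMassError(f"pmf sums to {total!r}, not 1")
    return schedule


def hazard_rate(schedule: ThreatSchedule) -> HazardProfile:
    """Survival, per-timepoint hazard and cumulative hazard of a schedule.

    ``hazard[i] = pmf[i] / (1 - sum_{j<i} pmf[j])``.  Survival is computed
    as the tail mass at-or-after each timepoint, which makes the hazard at
    the last support point exactly 1 in floating point.  The profile stops
    at the last support point; beyond it survival is zero and the hazard
    undefined.
    """
    validate_schedule(schedule)
    pmf = schedule.pmf
    last = int(np.nonzero(pmf)[0][-1])
    p = pmf[: last + 1]
    # P(no shock before t) = mass at or after t, for a proper pmf
    survival = np.cumsum(pmf[::-1])[::-1][: last + 1]
    hazard = np.clip(p / survival, 0.0, 1.0)
    return HazardProfile(
        timepoints=schedule.timepoints[: last + 1].copy(),
        survival=survival,
        hazard=hazard,
        cumulative_hazard=np.cumsum(hazard),
    )


def cumulative_hazard(schedule: ThreatSchedule) -> float:
    """Sum of the hazard over the schedule's support, at full precision.

    Equals 1 for a point mass and strictly exceeds 1 for any schedule
    spreading mass over two or more timepoints (25/12 = 2.0833... for the
    uniform four-step example).
    """
    return float(hazard_rate(schedule).cumulative_hazard[-1])


def expected_shock_time(schedule: ThreatSchedule) -> float:
    """pmf-weighted mean shock time in seconds."""
    validate_schedule(schedule)
    return float(np.dot(schedule.timepoints, schedule.pmf))


def round_printed(values: Union[float, np.ndarray], ndigits: int = 2):
    """Round to display precision (2 decimals by default).

    Hazard tables in print are usually shown at two decimals, e.g. 1/3 as
    ``.33``; full precision is kept everywhere else in this package.
    """
    return np.round(values, ndigits)


def printed_cumulative_hazard(schedule: ThreatSchedule, ndigits: int = 2) -> float:
    """Cumulative hazard as it would be printed: round addends, then sum.

    For the uniform four-step schedule this gives
    ``.25 + .33 + .5 + 1 = 2.08`` whereas the full-precision sum is
    2.0833...; the difference is purely display rounding of the addends.
    """
    prof = hazard_rate(schedule)
    return float(np.sum(round_printed(prof.hazard, ndigits)))


# ---------------------------------------------------------------------------
# IO: JSON object {label, timepoints, pmf} and 2-column CSV
# ---------------------------------------------------------------------------

def schedule_to_json(schedule: ThreatSchedule) -> dict:
    validate_schedule(schedule)
    return {
        "label": schedule.label,
        "timepoints": [int(t) for t in schedule.timepoints],
        "pmf": [float(p) for p in schedule.pmf],
    }


def schedule_from_json(obj: dict) -> ThreatSchedule:
    return validate_schedule(ThreatSchedule(
        timepoints=obj["timepoints"], pmf=obj["pmf"], label=obj.get("label", "")))


def save_schedule(schedule: ThreatSchedule, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        lines = ["timepoint,probability"]
        lines += [f"{int(t)},{float(p)!r}" for t, p in
                  zip(schedule.timepoints, schedule.pmf)]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(json.dumps(schedule_to_json(schedule), indent=1) + "\n")


def load_schedule(path: Union[str, Path], label: str = "") -> ThreatSchedule:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        rows = [line.split(",") for line in
                path.read_text().strip().splitlines()[1:]]
        tp = [int(r[0]) for r in rows]
        pmf = [float(r[1]) for r in rows]
        return validate_schedule(ThreatSchedule(tp, pmf, label=label))
    return schedule_from_json(json.loads(path.read_text()))
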