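"""Condition constructors for threat-anticipation paradigms.

Classic designs contrast a *certain* countdown (shock at a known final
second) with an *uncertain* one (shock time spread over the trial).  The
two differ both in marginal probability P(Threat) and in hazard rate, so
the designs confound them.  The matched early-/late-threat pair built by
:func:`design_matched_pair` removes the confound: both 30-second
conditions carry identical P(Threat) through a middle window (seconds
6-25 by default), yet the early condition -- having already spent part of
its mass before the window -- has a strictly higher hazard at every
matched second and a higher cumulative hazard overall.

The dominance is algebraic, not numeric luck: with equal window pmfs
``q_t`` and pre-window mass ``a > 0`` spent only by the early schedule,
survival inside the window satisfies ``S_early(t) = S_late(t) - a``, so
``q_t / S_early(t) > q_t / S_late(t)`` wherever ``q_t > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .schedules import (
    PMF_TOL,
    ThreatSchedule,
    cumulative_hazard,
    expected_shock_time,
    hazard_rate,
    validate_schedule,
)


class InfeasibleDesignError(ValueError):
    """Requested mass allocation cannot form a valid condition pair."""


@dataclass(frozen=True)
class ConditionPair:
    """Early-/late-threat schedules plus their matched window.

    Invariants (verified by :func:`verify_pair`):

    * identical pmf at every second of ``matched_window`` (inclusive);
    * early hazard strictly above late hazard throughout the window;
    * early cumulative hazard above late over the full trial.
    """

    early: ThreatSchedule
    late: ThreatSchedule
    matched_window: Tuple[int, int]
    trial_length_s: int


@dataclass(frozen=True)
class DesignReport:
    """Outcome of checking a :class:`ConditionPair` against its contract."""

    matched_ok: bool
    dominance_ok: bool
    cumulative_ok: bool
    expected_times: Tuple[float, float]
    hazard_gap: np.ndarray  # early - late hazard at each matched second

    @property
    def ok(self) -> bool:
        return self.matched_ok and self.dominance_ok and self.cumulative_ok

    def to_json(self) -> dict:
        return {
            "matched_ok": bool(self.matched_ok),
            "dominance_ok": bool(self.dominance_ok),
            "cumulative_ok": bool(self.cumulative_ok),
            "expected_times": {"early_s": self.expected_times[0],
                               "late_s": self.expected_times[1]},
            "hazard_gap": [float(g) for g in self.hazard_gap],
        }


def make_certain_countdown(length_s: int, label: str = "certain") -> ThreatSchedule:
    """Point mass at the final second: hazard 0 everywhere then 1."""
    if length_s < 1:
        raise InfeasibleDesignError(f"length must be >= 1, got {length_s}")
    pmf = np.zeros(length_s)
    pmf[-1] = 1.0
    return ThreatSchedule(np.arange(length_s), pmf, label=label)


def make_uniform_uncertain(length_s: int, label: str = "uncertain") -> ThreatSchedule:
    """Equal chance of the shock at any second of the trial."""
    if length_s < 1:
        raise InfeasibleDesignError(f"length must be >= 1, got {length_s}")
    return ThreatSchedule(np.arange(length_s),
                          np.full(length_s, 1.0 / length_s), label=label)


def make_npu_schedules(cue_len_s: int,
                       block_len_s: int) -> Tuple[ThreatSchedule, ThreatSchedule]:
    """Predictable/unpredictable block pair in the style of the NPU task.

    The predictable block shocks exactly at the end of its cue; the
    unpredictable block can shock at any second.  Both live on the same
    block-length grid, so ``(k, k)`` reduces exactly to the
    certain-vs-uniform countdown pair.
    """
    if cue_len_s < 1 or block_len_s < 1:
        raise InfeasibleDesignError("cue and block lengths must be >= 1")
    if cue_len_s > block_len_s:
        raise InfeasibleDesignError(
            f"cue ({cue_len_s}s) cannot outlast block ({block_len_s}s)")
    pmf = np.zeros(block_len_s)
    pmf[cue_len_s - 1] = 1.0
    predictable = ThreatSchedule(np.arange(block_len_s), pmf, label="predictable")
    unpredictable = make_uniform_uncertain(block_len_s, label="unpredictable")
    return predictable, unpredictable


def _window_weights(start: int, end: int, tilt: float) -> np.ndarray:
    """Shared within-window pmf shape: uniform with an optional linear tilt.

    Weights are proportional to ``1 + tilt * (t - mid)``; ``tilt`` must
    keep every weight positive, i.e. ``|tilt| < 2 / (end - start)`` for a
    window of more than one second.
    """
    t = np.arange(start, end + 1, dtype=float)
    mid = (start + end) / 2.0
    w = 1.0 + tilt * (t - mid)
    if np.any(w <= 0):
        raise InfeasibleDesignError(
            f"window tilt {tilt} produces non-positive weights")
    return w / w.sum()


# Defaults give expected shock times of 9.50 s (early) and 19.00 s (late)
# on the 30-s trial with the 6-25 s matched window; see docs/methods.md.
DEFAULT_WINDOW_MASS = 0.62
DEFAULT_EARLY_PRE_MASS = 0.38
DEFAULT_WINDOW_TILT = -0.05142


def design_matched_pair(trial_length_s: int = 30,
                        matched_window: Sequence[int] = (6, 25),
                        window_mass: float = DEFAULT_WINDOW_MASS,
                        early_pre_mass: float = DEFAULT_EARLY_PRE_MASS,
                        window_tilt: float = DEFAULT_WINDOW_TILT,
                        ) -> ConditionPair:
    """Build a P(Threat)-matched, hazard-dissociated early/late pair.

    Both schedules share ``window_mass`` of probability inside
    ``matched_window`` with an identical (uniform or linearly tilted)
    shape.  The early schedule spends ``early_pre_mass`` uniformly before
    the window (any remainder after it); the late schedule places all of
    its off-window mass uniformly after the window.  Any strictly
    positive ``early_pre_mass`` yields strict hazard dominance inside the
    window.

    Raises
    ------
    InfeasibleDesignError
        If masses do not fit in [0, 1], the window does not fit in the
        trial, or mass is requested in an empty pre/post region.
    """
    start, end = int(matched_window[0]), int(matched_window[1])
    if not (0 <= start <= end < trial_length_s):
        raise InfeasibleDesignError(
            f"window [{start}, {end}] must lie inside the {trial_length_s}-s trial")
    if not (0.0 < window_mass <= 1.0):
        raise InfeasibleDesignError(f"window_mass {window_mass} outside (0, 1]")
    if early_pre_mass < 0 or early_pre_mass > 1.0 - window_mass + PMF_TOL:
        raise InfeasibleDesignError(
            f"early_pre_mass {early_pre_mass} incompatible with "
            f"window_mass {window_mass}")
    early_post_mass = max(0.0, 1.0 - window_mass - early_pre_mass)
    late_post_mass = 1.0 - window_mass
    if early_pre_mass > PMF_TOL and start == 0:
        raise InfeasibleDesignError("pre-window region is empty (window starts at 0)")
    n_post = trial_length_s - 1 - end
    if (late_post_mass > PMF_TOL or early_post_mass > PMF_TOL) and n_post == 0:
        raise InfeasibleDesignError("post-window region is empty (window ends the trial)")

    grid = np.arange(trial_length_s)
    window = _window_weights(start, end, window_tilt) * window_mass

    early = np.zeros(trial_length_s)
    late = np.zeros(trial_length_s)
    early[start:end + 1] = window
    late[start:end + 1] = window
    if early_pre_mass > 0:
        early[:start] = early_pre_mass / start
    if early_post_mass > 0:
        early[end + 1:] = early_post_mass / n_post
    if late_post_mass > 0:
        late[end + 1:] = late_post_mass / n_post

    pair = ConditionPair(
        early=validate_schedule(ThreatSchedule(grid, early, label="early-threat")),
        late=validate_schedule(ThreatSchedule(grid, late, label="late-threat")),
        matched_window=(start, end),
        trial_length_s=trial_length_s,
    )
    return pair


def verify_pair(pair: ConditionPair) -> DesignReport:
    """Check each pair invariant independently and report hazard gaps."""
    if len(pair.early) != len(pair.late):
        raise InfeasibleDesignError("early/late trial lengths differ")
    validate_schedule(pair.early)
    validate_schedule(pair.late)
    start, end = pair.matched_window
    window = slice(start, end + 1)

    matched_ok = bool(np.all(
        np.abs(pair.early.pmf[window] - pair.late.pmf[window]) <= PMF_TOL))

    prof_e = hazard_rate(pair.early)
    prof_l = hazard_rate(pair.late)
    n_e, n_l = len(prof_e.hazard), len(prof_l.hazard)
    if n_e <= end or n_l <= end:
        # a schedule exhausted before the window's end: hazard undefined there
        dominance_ok = False
        upto = min(n_e, n_l, end + 1)
        gap = prof_e.hazard[start:upto] - prof_l.hazard[start:upto]
    else:
        gap = prof_e.hazard[window] - prof_l.hazard[window]
        dominance_ok = bool(np.all(gap > 0))

    cumulative_ok = cumulative_hazard(pair.early) > cumulative_hazard(pair.late)
    return DesignReport(
        matched_ok=matched_ok,
        dominance_ok=dominance_ok,
        cumulative_ok=cumulative_ok,
        expected_times=(expected_shock_time(pair.early),
                        expected_shock_time(pair.late)),
        hazard_gap=np.asarray(gap),
    )
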