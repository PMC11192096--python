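"""Synthetic cohort of threat-learning, reward-foraging agents.

Each agent first experiences a block of unavoidable shocks per condition
and builds a smoothed empirical histogram of shock times (its *learned*
schedule).  In the testing phase the agent earns 1 cent for every safe
second but may escape; escape at second ``t`` is a per-second Bernoulli
draw with probability ``logistic(alpha + beta * signal(t))``, where the
signal is read off the agent's learned schedule either as the hazard rate
(*hazard tracker*) or as the marginal probability P(Threat)
(*probability tracker*).  The tracker dichotomy is the model-based
dissociation at the heart of the paradigm: with P(Threat) matched across
conditions inside the window, probability trackers behave identically
there while hazard trackers avoid the early-threat condition.

Fear/anxiety ratings are a noisy affine read-out of the tracked signal on
a 0-10 scale, and the end-of-study forced choice picks the condition
whose mean experienced signal was higher (plus judgment noise).

Everything downstream consumes the flat ``TrialRecord`` table this module
emits; one master seed fixes the entire cohort byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import ConditionPair
from .schedules import ThreatSchedule, hazard_rate, validate_schedule

CONDITIONS = ("early", "late")

#: Column order of the trial-record table (and its CSV serialization).
RECORD_COLUMNS = [
    "participant_id", "trial_index", "condition", "phase", "outcome",
    "event_time_s", "earnings_cents", "rating", "rating_time_s",
]


@dataclass(frozen=True)
class AgentParams:
    """Policy and rating parameters of one synthetic participant."""

    id: int
    tracker: str = "hazard"              # 'hazard' | 'probability'
    escape_intercept: float = -5.8       # log-odds of escape at zero signal
    escape_slope: float = 22.0           # log-odds per unit signal
    rating_gain: float = 10.0            # rating units per unit signal
    rating_noise_sd: float = 1.0         # rating units
    smoothing: float = 0.5               # pseudo-count per bin for learning

    def __post_init__(self) -> None:
        if self.tracker not in ("hazard", "probability"):
            raise ValueError(f"unknown tracker {self.tracker!r}")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be >= 0")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")


@dataclass
class AgentState:
    """Learned schedule estimate and shock tally, per condition."""

    estimates: Dict[str, ThreatSchedule] = field(default_factory=dict)
    shocks_received: Dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class TrialRecord:
    """One trial's outcome; the row format of every analysis input."""

    participant_id: int
    trial_index: int
    condition: str
    phase: str          # 'learning' | 'testing' | 'final'
    outcome: str        # 'shock' | 'escape'
    event_time_s: int
    earnings_cents: int
    rating: Optional[float] = None
    rating_time_s: Optional[int] = None


@dataclass(frozen=True)
class AgentPopulation:
    """Sampling distribution of agent parameters across a cohort.

    Defaults describe a hazard-tracking cohort whose escape policy is
    nearly silent at low hazard but engages steeply as the hazard climbs,
    producing earnable-second losses concentrated in the early-threat
    condition; see docs/methods.md for the rationale behind each value.
    """

    tracker: str = "hazard"
    escape_intercept_mean: float = -5.8
    escape_intercept_sd: float = 0.3
    escape_slope_mean: float = 22.0
    escape_slope_sd: float = 1.5
    rating_gain_mean: float = 10.0
    rating_gain_sd: float = 1.5
    rating_noise_sd: float = 1.0
    smoothing: float = 0.5

    def sample(self, n: int, rng: np.random.Generator) -> List[AgentParams]:
        alphas = rng.normal(self.escape_intercept_mean, self.escape_intercept_sd, n)
        betas = np.maximum(0.0, rng.normal(self.escape_slope_mean,
                                           self.escape_slope_sd, n))
        gains = np.maximum(0.0, rng.normal(self.rating_gain_mean,
                                           self.rating_gain_sd, n))
        return [AgentParams(id=i, tracker=self.tracker,
                            escape_intercept=float(alphas[i]),
                            escape_slope=float(betas[i]),
                            rating_gain=float(gains[i]),
                            rating_noise_sd=self.rating_noise_sd,
                            smoothing=self.smoothing)
                for i in range(n)]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _estimate_from_counts(schedule: ThreatSchedule, counts: np.ndarray,
                          smoothing: float) -> ThreatSchedule:
    total = counts.sum() + smoothing * len(counts)
    pmf = (counts + smoothing) / total
    return ThreatSchedule(schedule.timepoints.copy(), pmf, label="estimate")


def simulate_learning(agent: AgentParams, schedule: ThreatSchedule,
                      n_trials: int = 50, rng=None, condition: str = "early",
                      state: Optional[AgentState] = None,
                      ) -> Tuple[AgentState, List[TrialRecord]]:
    """Expose an agent to ``n_trials`` unavoidable shocks from ``schedule``.

    Shock times are i.i.d. draws from the schedule pmf; the learned
    estimate is the normalized count histogram plus ``smoothing``
    pseudo-counts per bin.  Every record has outcome ``'shock'`` and zero
    earnings: the learning phase pays nothing and cannot be escaped.
    """
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    validate_schedule(schedule)
    rng = _as_rng(rng)
    times = rng.choice(schedule.timepoints, size=n_trials, p=schedule.pmf)
    counts = np.zeros(len(schedule), dtype=float)
    idx = np.searchsorted(schedule.timepoints, times)
    np.add.at(counts, idx, 1.0)

    if state is None:
        state = AgentState()
    state.estimates[condition] = _estimate_from_counts(schedule, counts,
                                                       agent.smoothing)
    state.shocks_received[condition] = (
        state.shocks_received.get(condition, 0) + n_trials)
    records = [TrialRecord(agent.id, k, condition, "learning", "shock",
                           int(t), 0) for k, t in enumerate(times)]
    return state, records


def signal_vector(estimate: ThreatSchedule, tracker: str) -> np.ndarray:
    """Tracked signal at every grid second of the learned schedule.

    Hazard trackers read the learned hazard rate (0 after the estimate's
    support is exhausted -- no perceived threat remains); probability
    trackers read the learned pmf directly.
    """
    if tracker == "probability":
        return estimate.pmf.copy()
    out = np.zeros(len(estimate))
    prof = hazard_rate(estimate)
    out[: len(prof.hazard)] = prof.hazard
    return out


def escape_signal(state: AgentState, tracker: str, t: int,
                  condition: str = "early") -> float:
    """The quantity the agent's escape policy responds to at second ``t``."""
    estimate = state.estimates[condition]
    if t < int(estimate.timepoints[0]) or t > int(estimate.timepoints[-1]):
        raise ValueError(f"t={t} outside the trial grid")
    idx = int(np.searchsorted(estimate.timepoints, t))
    return float(signal_vector(estimate, tracker)[idx])


def escape_probability_vector(agent: AgentParams,
                              estimate: ThreatSchedule) -> np.ndarray:
    """Per-second escape probability implied by the agent's policy."""
    sig = signal_vector(estimate, agent.tracker)
    return expit(agent.escape_intercept + agent.escape_slope * sig)


def _simulate_testing_rows(true_hazard: np.ndarray, escape_prob: np.ndarray,
                           rng: np.random.Generator
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized competing-risks walk over trial seconds.

    ``true_hazard`` and ``escape_prob`` are (n_trials, T).  Within each
    second the escape decision is evaluated first -- escaping is
    anticipatory, a choice made before the shock of that second can land
    -- and only then does the shock resolve with the true hazard.  A flat
    policy with per-second escape probability ``p`` on a certain
    ``T``-second countdown therefore escapes with probability
    ``1 - (1-p)^T``.  Returns outcome codes (1 = shock, 0 = escape) and
    event times.  A proper true pmf guarantees an event by the last
    support second; as a numerical backstop any straggler is recorded as
    a shock at the final second.
    """
    n, T = true_hazard.shape
    outcome = np.ones(n, dtype=int)
    etime = np.full(n, T - 1, dtype=int)
    alive = np.ones(n, dtype=bool)
    for t in range(T):
        if not alive.any():
            break
        u_escape = rng.random(n)
        u_shock = rng.random(n)
        escaped = alive & (u_escape < escape_prob[:, t])
        shocked = alive & ~escaped & (u_shock < true_hazard[:, t])
        etime[shocked | escaped] = t
        outcome[escaped] = 0
        alive &= ~(shocked | escaped)
    return outcome, etime


def simulate_testing_trial(agent: AgentParams, state: AgentState,
                           true_schedule: ThreatSchedule,
                           condition: str = "early",
                           reward_rate_cents_per_s: int = 1,
                           rng=None, trial_index: int = 0) -> TrialRecord:
    """One testing trial: earn ``reward_rate`` per safe second, escape or be shocked."""
    validate_schedule(true_schedule)
    rng = _as_rng(rng)
    prof = hazard_rate(true_schedule)
    T = len(true_schedule)
    hz = np.zeros(T)
    hz[: len(prof.hazard)] = prof.hazard
    ep = escape_probability_vector(agent, state.estimates[condition])
    outcome, etime = _simulate_testing_rows(hz[None, :], ep[None, :], rng)
    t = int(etime[0])
    return TrialRecord(agent.id, trial_index, condition, "testing",
                       "shock" if outcome[0] else "escape", t,
                       int(t * reward_rate_cents_per_s))


def generate_rating(agent: AgentParams, signal: float, rng=None) -> float:
    """Noisy affine read-out of the tracked signal, clipped to the 0-10 scale."""
    rng = _as_rng(rng)
    raw = agent.rating_gain * signal + rng.normal(0.0, agent.rating_noise_sd)
    return float(np.clip(raw, 0.0, 10.0))


@dataclass
class CohortResult:
    """Full record set of a simulated study."""

    records: pd.DataFrame        # one TrialRecord per row
    forced_choice: pd.DataFrame  # participant_id, choice
    agents: List[AgentParams]
    pair: ConditionPair


def simulate_cohort(pair: ConditionPair,
                    n_participants: int = 42,
                    population: Optional[AgentPopulation] = None,
                    n_learning: int = 50,
                    n_testing_per_condition: int = 25,
                    rating_every: int = 5,
                    reward_rate_cents_per_s: int = 1,
                    rng=None) -> CohortResult:
    """Simulate the full within-subject study for a cohort of agents.

    Per participant: ``n_learning`` unavoidable shocks in each condition
    (pseudo-randomized order), ``n_testing_per_condition`` testing trials
    per condition interleaved in a shuffled order, an in-trial
    fear/anxiety rating on every ``rating_every``-th testing trial of
    each condition (prompted at a uniformly drawn second of the trial),
    one final unavoidable 30-s trial per condition with a post-trial
    rating, and a forced choice of the more anxiogenic condition.

    One ``rng`` seed reproduces the record tables byte-for-byte.
    """
    if population is None:
        population = AgentPopulation()
    rng = _as_rng(rng)
    agents = population.sample(n_participants, rng)
    T = pair.trial_length_s
    true = {"early": pair.early, "late": pair.late}
    true_hazard = {}
    for cond, sched in true.items():
        prof = hazard_rate(sched)
        hz = np.zeros(T)
        hz[: len(prof.hazard)] = prof.hazard
        true_hazard[cond] = hz

    rows: List[tuple] = []
    choices: List[tuple] = []
    for agent in agents:
        state = AgentState()
        trial_index = 0

        # ---- learning phase: pseudo-randomized interleaving of conditions
        learn_times = {cond: rng.choice(true[cond].timepoints, size=n_learning,
                                        p=true[cond].pmf)
                       for cond in CONDITIONS}
        order = np.repeat([0, 1], n_learning)
        rng.shuffle(order)
        seen = {c: 0 for c in CONDITIONS}
        for o in order:
            cond = CONDITIONS[o]
            t = int(learn_times[cond][seen[cond]])
            seen[cond] += 1
            rows.append((agent.id, trial_index, cond, "learning", "shock",
                         t, 0, np.nan, np.nan))
            trial_index += 1
        for cond in CONDITIONS:
            counts = np.zeros(T)
            idx = np.searchsorted(true[cond].timepoints, learn_times[cond])
            np.add.at(counts, idx, 1.0)
            state.estimates[cond] = _estimate_from_counts(true[cond], counts,
                                                          agent.smoothing)
            state.shocks_received[cond] = n_learning

        sig = {cond: signal_vector(state.estimates[cond], agent.tracker)
               for cond in CONDITIONS}
        escp = {cond: expit(agent.escape_intercept + agent.escape_slope * sig[cond])
                for cond in CONDITIONS}

        # ---- testing phase: all trials of both conditions, shuffled order
        out = {}
        for cond in CONDITIONS:
            hz = np.broadcast_to(true_hazard[cond],
                                 (n_testing_per_condition, T))
            ep = np.broadcast_to(escp[cond], (n_testing_per_condition, T))
            out[cond] = _simulate_testing_rows(np.ascontiguousarray(hz),
                                               np.ascontiguousarray(ep), rng)
        torder = np.repeat([0, 1], n_testing_per_condition)
        rng.shuffle(torder)
        within = {c: 0 for c in CONDITIONS}
        for o in torder:
            cond = CONDITIONS[o]
            k = within[cond]
            within[cond] += 1
            oc, et = out[cond][0][k], int(out[cond][1][k])
            rating = np.nan
            rating_t = np.nan
            if k % rating_every == 0:
                rating_t = int(rng.integers(0, et + 1))
                rating = generate_rating(agent, float(sig[cond][rating_t]), rng)
            rows.append((agent.id, trial_index, cond, "testing",
                         "shock" if oc else "escape", et,
                         int(et * reward_rate_cents_per_s), rating, rating_t))
            trial_index += 1

        # ---- final unavoidable trial per condition, rated afterwards
        for cond in CONDITIONS:
            t = int(rng.choice(true[cond].timepoints, p=true[cond].pmf))
            mean_sig = float(sig[cond][: t + 1].mean())
            rating = generate_rating(agent, mean_sig, rng)
            rows.append((agent.id, trial_index, cond, "final", "shock",
                         t, 0, rating, t))
            trial_index += 1

        # ---- forced choice: condition with the higher mean experienced
        # signal, blurred by judgment noise.  The end-of-study judgment
        # aggregates over every trial experienced in a condition, so its
        # noise is one rating's noise shrunk by sqrt(trials experienced).
        n_exp = n_learning + n_testing_per_condition
        score = {}
        for cond in CONDITIONS:
            lived = np.concatenate([learn_times[cond],
                                    out[cond][1]]).astype(int)
            csum = np.cumsum(sig[cond])
            mean_exp = float(csum[lived].sum() / (lived + 1).sum())
            noise = rng.normal(0.0, agent.rating_noise_sd / np.sqrt(n_exp))
            score[cond] = agent.rating_gain * mean_exp + noise
        choices.append((agent.id,
                        "early" if score["early"] > score["late"] else "late"))

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    forced = pd.DataFrame(choices, columns=["participant_id", "choice"])
    return CohortResult(records=records, forced_choice=forced,
                        agents=agents, pair=pair)
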