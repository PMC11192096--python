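"""Avoidance and fear/anxiety analyses over trial-record tables.

The testing phase is treated as a survival problem in which the event of
interest is the *escape decision* and a delivered shock censors the
escape time: a shocked trial tells us only that the participant had not
yet chosen to escape.  On top of the product-limit estimator and the
log-rank test, the battery covers epoch-wise avoidance proportions,
per-participant earnings, the association between self-reported
fear/anxiety and the schedule's hazard (or marginal probability), the
end-of-study forced choice, and the final unavoidable-trial ratings.

Rating effects use a two-stage summary-statistics model: an ordinary
least-squares fit per subject (rating on regressor, plus a
shocks-received covariate), then a one-sample t-test of the subject
slopes against zero.  For balanced designs this is the classic
alternative to a mixed-effects model and keeps every step explicit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .design import ConditionPair
from .schedules import hazard_rate

DEFAULT_EPOCHS: Tuple[Tuple[int, int], ...] = ((6, 10), (11, 15), (16, 20), (21, 25))


# ---------------------------------------------------------------------------
# Survival of escape behavior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate of 'still in the trial, not yet escaped'."""

    times: np.ndarray       # distinct event/censor times, ascending
    at_risk: np.ndarray     # trials still at risk entering each time
    events: np.ndarray      # escapes at each time
    censored: np.ndarray    # shocks at each time
    survival: np.ndarray    # S(t) just after each time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "at_risk": self.at_risk,
                             "events": self.events, "censored": self.censored,
                             "survival": self.survival})


def _testing(records: pd.DataFrame) -> pd.DataFrame:
    out = records[records["phase"] == "testing"]
    if out.empty:
        raise ValueError("no testing-phase records")
    return out


def kaplan_meier(records: pd.DataFrame, condition: Optional[str] = None
                 ) -> SurvivalCurve:
    """Kaplan-Meier curve of escape times, shocks censoring at their times.

    Standard product-limit convention: at a tied time, events are counted
    before censorings.  With no censoring the curve reduces exactly to
    the empirical survival function of the escape times.
    """
    df = _testing(records)
    if condition is not None:
        df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError(f"no testing records for condition {condition!r}")
    t = df["event_time_s"].to_numpy()
    escape = (df["outcome"] == "escape").to_numpy()

    times = np.unique(t)
    n = len(t)
    at_risk = np.empty(len(times), dtype=int)
    events = np.empty(len(times), dtype=int)
    censored = np.empty(len(times), dtype=int)
    surv = np.empty(len(times))
    s = 1.0
    removed = 0
    for i, ti in enumerate(times):
        here = t == ti
        d = int(np.sum(here & escape))
        c = int(np.sum(here & ~escape))
        r = n - removed
        at_risk[i] = r
        events[i] = d
        censored[i] = c
        if d:
            s *= 1.0 - d / r
        surv[i] = s
        removed += d + c
    return SurvivalCurve(times=times, at_risk=at_risk, events=events,
                         censored=censored, survival=surv)


def log_rank(records_early: pd.DataFrame, records_late: pd.DataFrame
             ) -> Tuple[float, float]:
    """Two-group log-rank test of escape hazards (df = 1).

    Observed-minus-expected escape counts accumulated over the pooled
    event times with the hypergeometric variance; identical groups give a
    statistic of exactly 0, and the statistic is symmetric in the group
    labels.
    """
    frames = []
    for g, df in enumerate((_testing(records_early), _testing(records_late))):
        frames.append(pd.DataFrame({
            "t": df["event_time_s"].to_numpy(),
            "e": (df["outcome"] == "escape").to_numpy(),
            "g": g}))
    pooled = pd.concat(frames, ignore_index=True)
    for g in (0, 1):
        if not pooled.loc[pooled["g"] == g, "e"].any():
            raise ValueError(f"group {g} has zero escape events")

    t = pooled["t"].to_numpy()
    e = pooled["e"].to_numpy()
    g = pooled["g"].to_numpy()
    o_minus_e = 0.0
    var = 0.0
    for ti in np.unique(t[e]):
        at_risk = t >= ti
        n_total = int(at_risk.sum())
        n0 = int((at_risk & (g == 0)).sum())
        d_total = int((e & (t == ti)).sum())
        d0 = int((e & (t == ti) & (g == 0)).sum())
        exp0 = d_total * n0 / n_total
        o_minus_e += d0 - exp0
        if n_total > 1:
            var += (d_total * (n0 / n_total) * (1 - n0 / n_total)
                    * (n_total - d_total) / (n_total - 1))
    chi2 = 0.0 if var == 0 else o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return float(chi2), p


# ---------------------------------------------------------------------------
# Epoch-wise avoidance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EpochStats:
    """Escape-given-entry proportions for one trial epoch, by condition."""

    start: int
    end: int
    prop_early: np.ndarray   # per-participant proportions (entrants only)
    prop_late: np.ndarray
    t_stat: float
    p_value: float

    @property
    def mean_early(self) -> float:
        return float(np.mean(self.prop_early)) if len(self.prop_early) else np.nan

    @property
    def mean_late(self) -> float:
        return float(np.mean(self.prop_late)) if len(self.prop_late) else np.nan


def epoch_avoidance(records: pd.DataFrame,
                    epochs: Sequence[Sequence[int]] = DEFAULT_EPOCHS
                    ) -> List[EpochStats]:
    """Per-epoch escape proportions and early-vs-late t-tests.

    A trial *enters* an epoch if it has not ended before the epoch's
    first second; it counts as an escape for that epoch if it ends in an
    escape at a second inside the epoch.  Each participant contributes
    one proportion per condition per epoch (provided at least one of
    their trials entered); conditions are compared with an
    independent-samples t-test.
    """
    df = _testing(records)
    out = []
    for start, end in epochs:
        entered = df[df["event_time_s"] >= start]
        if entered.empty:
            raise ValueError(f"no trial enters epoch [{start}, {end}]")
        esc = ((entered["outcome"] == "escape")
               & (entered["event_time_s"] <= end))
        grouped = (entered.assign(esc=esc)
                   .groupby(["condition", "participant_id"])["esc"]
                   .mean())
        props = {cond: grouped.get(cond, pd.Series(dtype=float)).to_numpy()
                 for cond in ("early", "late")}
        pe, pl = props["early"], props["late"]
        if len(pe) < 2 or len(pl) < 2:
            t_stat, p_val = np.nan, np.nan  # too few entrants to compare
        elif (np.var(pe) == 0 and np.var(pl) == 0
                and pe.mean() == pl.mean()):
            t_stat, p_val = 0.0, 1.0  # degenerate identical groups
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tt = stats.ttest_ind(pe, pl)
            t_stat, p_val = float(tt.statistic), float(tt.pvalue)
        out.append(EpochStats(start=int(start), end=int(end),
                              prop_early=pe, prop_late=pl,
                              t_stat=t_stat, p_value=p_val))
    return out


# ---------------------------------------------------------------------------
# Earnings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EarningsResult:
    mean_early: float
    mean_late: float
    pct_difference: float    # 100 * (late - early) / late
    t_stat: float
    p_value: float
    per_participant: pd.DataFrame


def earnings_comparison(records: pd.DataFrame) -> EarningsResult:
    """Per-participant mean testing earnings, early vs late, paired t-test."""
    df = _testing(records)
    table = (df.groupby(["participant_id", "condition"])["earnings_cents"]
             .mean().unstack("condition"))
    if table.isna().any().any() or table.shape[1] < 2:
        missing = table.index[table.isna().any(axis=1)].tolist()
        raise ValueError(f"participants missing a condition: {missing}")
    early = table["early"].to_numpy()
    late = table["late"].to_numpy()
    mean_early = float(early.mean())
    mean_late = float(late.mean())
    diff = early - late
    if np.all(diff == diff[0]):
        # constant paired difference: 0 -> null; nonzero -> infinitely strong
        t_stat = 0.0 if diff[0] == 0 else float(np.sign(diff[0]) * np.inf)
        p = 1.0 if diff[0] == 0 else 0.0
    else:
        tt = stats.ttest_rel(early, late)
        t_stat, p = float(tt.statistic), float(tt.pvalue)
    pct = 100.0 * (mean_late - mean_early) / mean_late if mean_late else 0.0
    return EarningsResult(mean_early=mean_early, mean_late=mean_late,
                          pct_difference=float(pct), t_stat=t_stat, p_value=p,
                          per_participant=table)


# ---------------------------------------------------------------------------
# Rating association (two-stage summary statistics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationResult:
    regressor: str
    slopes: np.ndarray       # one OLS slope per retained subject
    t_stat: float
    p_value: float
    n_subjects: int
    n_dropped: int


def _regressor_lookup(pair: ConditionPair, regressor: str) -> Dict[str, np.ndarray]:
    """Per-condition regressor value at every grid second of the trial."""
    out = {}
    for cond, sched in (("early", pair.early), ("late", pair.late)):
        if regressor == "probability":
            out[cond] = sched.pmf.copy()
        elif regressor == "hazard":
            vec = np.zeros(len(sched))
            prof = hazard_rate(sched)
            vec[: len(prof.hazard)] = prof.hazard
            out[cond] = vec
        else:
            raise ValueError(f"unknown regressor {regressor!r}")
    return out


def _shocks_before(records: pd.DataFrame) -> pd.Series:
    """Shocks received in the same condition before each trial (chronological)."""
    df = records.sort_values(["participant_id", "trial_index"])
    is_shock = (df["outcome"] == "shock").astype(int)
    cum = (is_shock.groupby([df["participant_id"], df["condition"]])
           .cumsum() - is_shock)
    return cum.reindex(records.index)


def rating_association(records: pd.DataFrame, pair: ConditionPair,
                       regressor: str = "hazard",
                       include_shock_covariate: bool = True,
                       include_condition: bool = False,
                       min_obs: int = 3) -> AssociationResult:
    """Association between in-trial fear/anxiety ratings and the schedule.

    Stage 1 fits, per subject, an OLS of rating on the regressor (the
    condition's *true* hazard rate or P(Threat) at the rated second) plus
    the number of shocks received so far in that condition and,
    optionally, an early-condition indicator.  Stage 2 tests the subject
    slopes against zero with a one-sample t.  Subjects with fewer than
    ``min_obs`` rated trials are dropped with a warning.
    """
    df = _testing(records)
    rated = df[df["rating"].notna() & df["rating_time_s"].notna()].copy()
    if rated.empty:
        raise ValueError("no rated testing trials")
    lookup = _regressor_lookup(pair, regressor)
    x = np.array([lookup[c][int(t)] for c, t in
                  zip(rated["condition"], rated["rating_time_s"])])
    rated["x"] = x
    rated["shocks_before"] = _shocks_before(records).loc[rated.index]

    slopes = []
    dropped = 0
    for pid, sub in rated.groupby("participant_id"):
        if len(sub) < min_obs:
            warnings.warn(f"participant {pid}: only {len(sub)} rated trials, dropped")
            dropped += 1
            continue
        cols = [np.ones(len(sub)), sub["x"].to_numpy()]
        if include_shock_covariate:
            cols.append(sub["shocks_before"].to_numpy(dtype=float))
        if include_condition:
            cols.append((sub["condition"] == "early").to_numpy(dtype=float))
        X = np.column_stack(cols)
        beta, *_ = np.linalg.lstsq(X, sub["rating"].to_numpy(), rcond=None)
        slopes.append(beta[1])
    if not slopes:
        raise ValueError("no subject had enough rated trials")
    slopes = np.asarray(slopes)
    if np.allclose(slopes, slopes[0]):
        # degenerate noiseless case: identical slopes, t undefined or infinite
        t_stat = np.inf if slopes[0] != 0 else 0.0
        p = 0.0 if slopes[0] != 0 else 1.0
    else:
        tt = stats.ttest_1samp(slopes, 0.0)
        t_stat, p = float(tt.statistic), float(tt.pvalue)
    return AssociationResult(regressor=regressor, slopes=slopes,
                             t_stat=t_stat, p_value=p,
                             n_subjects=len(slopes), n_dropped=dropped)


# ---------------------------------------------------------------------------
# Forced choice and final-trial ratings
# ---------------------------------------------------------------------------

def exact_binomial_p(k: int, n: int) -> float:
    """Exact two-sided binomial test against 0.5: min(1, 2 x smaller tail)."""
    if n < 1:
        raise ValueError("empty input")
    lower = sum(comb(n, i) for i in range(0, k + 1))
    upper = sum(comb(n, i) for i in range(k, n + 1))
    tail = min(lower, upper) / 2 ** n
    return float(min(1.0, 2.0 * tail))


def forced_choice_test(choices: Sequence[str]) -> Tuple[int, int, float]:
    """Count of 'early' choices and the exact two-sided binomial p-value."""
    choices = list(choices)
    if not choices:
        raise ValueError("empty choice list")
    k = sum(c == "early" for c in choices)
    n = len(choices)
    return k, n, exact_binomial_p(k, n)


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_max_n: int = 12) -> Tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney U for the first sample), midrank ties.

    Exact permutation p-value (all ``C(n, nx)`` label assignments of the
    pooled midranks) when the total sample size is at most
    ``exact_max_n``; otherwise the tie-corrected normal approximation.
    Two-sided either way, measured as ``P(|U - mu| >= |u - mu|)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mu = nx * ny / 2.0

    if nx + ny <= exact_max_n:
        stat_all = []
        idx = range(nx + ny)
        base = nx * (nx + 1) / 2
        for combo in itertools.combinations(idx, nx):
            stat_all.append(ranks[list(combo)].sum() - base)
        stat_all = np.asarray(stat_all)
        p = float(np.mean(np.abs(stat_all - mu) >= np.abs(u - mu) - 1e-12))
        return u, min(1.0, p)

    _, counts = np.unique(pooled, return_counts=True)
    n = nx + ny
    tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (u - mu) / np.sqrt(sigma2)
    return u, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class FinalTrialResult:
    u_stat: float
    p_value: float
    resid_u_stat: float
    resid_p_value: float
    mean_diff: float         # early - late mean rating
    resid_mean_diff: float


def final_trial_comparison(records: pd.DataFrame) -> FinalTrialResult:
    """Early-vs-late ratings of the final unavoidable trials.

    Rank-sum on the raw ratings, then again on ratings residualized (by
    pooled OLS) for the cumulative number of shocks received in that
    condition over the whole study -- the shock count is a potential
    confound since the early condition also shocks more often before
    late trial seconds.
    """
    final = records[records["phase"] == "final"]
    if final.empty or final["rating"].isna().any():
        raise ValueError("missing final-trial ratings")
    shocks = (records[records["outcome"] == "shock"]
              .groupby(["participant_id", "condition"]).size())
    key = list(zip(final["participant_id"], final["condition"]))
    n_shocks = np.array([shocks.get(k, 0) for k in key], dtype=float)
    ratings = final["rating"].to_numpy()
    X = np.column_stack([np.ones(len(final)), n_shocks])
    beta, *_ = np.linalg.lstsq(X, ratings, rcond=None)
    resid = ratings - X @ beta

    is_early = (final["condition"] == "early").to_numpy()
    u, p = rank_sum_test(ratings[is_early], ratings[~is_early])
    ru, rp = rank_sum_test(resid[is_early], resid[~is_early])
    return FinalTrialResult(
        u_stat=u, p_value=p, resid_u_stat=ru, resid_p_value=rp,
        mean_diff=float(ratings[is_early].mean() - ratings[~is_early].mean()),
        resid_mean_diff=float(resid[is_early].mean() - resid[~is_early].mean()))


# ---------------------------------------------------------------------------
# Full battery
# ---------------------------------------------------------------------------

def analyze_all(records: pd.DataFrame, forced_choice: pd.DataFrame,
                pair: ConditionPair,
                epochs: Sequence[Sequence[int]] = DEFAULT_EPOCHS) -> dict:
    """Run every analysis and return a JSON-ready report dictionary."""
    df = _testing(records)
    early = records[records["condition"] == "early"]
    late = records[records["condition"] == "late"]
    km = {cond: kaplan_meier(records, cond).to_frame().to_dict("list")
          for cond in ("early", "late")}
    chi2, p_lr = log_rank(early, late)
    ep = epoch_avoidance(records, epochs)
    earn = earnings_comparison(records)
    assoc_h = rating_association(records, pair, "hazard")
    assoc_p = rating_association(records, pair, "probability")
    k, n, p_fc = forced_choice_test(forced_choice["choice"])
    ft = final_trial_comparison(records)
    return {
        "survival": km,
        "log_rank": {"chi2": chi2, "p": p_lr},
        "epochs": [{"start": e.start, "end": e.end,
                    "mean_early": e.mean_early, "mean_late": e.mean_late,
                    "t": e.t_stat, "p": e.p_value} for e in ep],
        "earnings": {"mean_early_cents": earn.mean_early,
                     "mean_late_cents": earn.mean_late,
                     "pct_difference": earn.pct_difference,
                     "t": earn.t_stat, "p": earn.p_value},
        "rating_association": {
            "hazard": {"mean_slope": float(np.mean(assoc_h.slopes)),
                       "t": assoc_h.t_stat, "p": assoc_h.p_value,
                       "n_subjects": assoc_h.n_subjects},
            "probability": {"mean_slope": float(np.mean(assoc_p.slopes)),
                            "t": assoc_p.t_stat, "p": assoc_p.p_value,
                            "n_subjects": assoc_p.n_subjects},
        },
        "forced_choice": {"k_early": k, "n": n, "p": p_fc},
        "final_trial": {"u": ft.u_stat, "p": ft.p_value,
                        "resid_u": ft.resid_u_stat, "resid_p": ft.resid_p_value,
                        "mean_diff": ft.mean_diff,
                        "resid_mean_diff": ft.resid_mean_diff},
    }
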