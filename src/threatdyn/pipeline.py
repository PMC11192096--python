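"""End-to-end orchestration: design -> simulate -> analyze, reproducibly.

A single :class:`RunConfig` (YAML on disk) holds every design, cohort and
analysis parameter plus one master seed; child seeds for each stage are
derived from it with :class:`numpy.random.SeedSequence`, so a config file
fully determines every artifact the run writes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .analysis import DEFAULT_EPOCHS, analyze_all
from .cohort import AgentPopulation, CohortResult, simulate_cohort
from .design import (ConditionPair, DEFAULT_EARLY_PRE_MASS,
                     DEFAULT_WINDOW_MASS, DEFAULT_WINDOW_TILT,
                     design_matched_pair, verify_pair)
from .schedules import schedule_to_json

logger = logging.getLogger("threatdyn")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class DesignConfig:
    trial_length_s: int = 30
    matched_window: Tuple[int, int] = (6, 25)
    window_mass: float = DEFAULT_WINDOW_MASS
    early_pre_mass: float = DEFAULT_EARLY_PRE_MASS
    window_tilt: float = DEFAULT_WINDOW_TILT


@dataclass
class CohortConfig:
    n_participants: int = 42
    n_learning: int = 50
    n_testing_per_condition: int = 25
    rating_every: int = 5
    reward_rate_cents_per_s: int = 1
    population: AgentPopulation = field(default_factory=AgentPopulation)


@dataclass
class AnalysisConfig:
    epochs: Tuple[Tuple[int, int], ...] = DEFAULT_EPOCHS
    alpha: float = 0.05


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs/default"
    design: DesignConfig = field(default_factory=DesignConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())),
                              sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, obj: dict) -> "RunConfig":
        obj = dict(obj)
        design = DesignConfig(**obj.pop("design", {}))
        cohort_d = dict(obj.pop("cohort", {}))
        pop = AgentPopulation(**cohort_d.pop("population", {}))
        cohort = CohortConfig(population=pop, **cohort_d)
        analysis_d = dict(obj.pop("analysis", {}))
        if "epochs" in analysis_d:
            analysis_d["epochs"] = tuple(tuple(e) for e in analysis_d["epochs"])
        analysis = AnalysisConfig(**analysis_d)
        cfg = cls(design=design, cohort=cohort, analysis=analysis, **obj)
        cfg.design.matched_window = tuple(cfg.design.matched_window)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _child_seeds(master: int, n: int) -> List[int]:
    """Derive reproducible per-stage seeds (< 2**31) from the master seed."""
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def build_pair(cfg: DesignConfig) -> ConditionPair:
    return design_matched_pair(
        trial_length_s=cfg.trial_length_s,
        matched_window=cfg.matched_window,
        window_mass=cfg.window_mass,
        early_pre_mass=cfg.early_pre_mass,
        window_tilt=cfg.window_tilt)


def run_cohort(config: RunConfig, pair: Optional[ConditionPair] = None
               ) -> CohortResult:
    if pair is None:
        pair = build_pair(config.design)
    (cohort_seed,) = _child_seeds(config.seed, 1)
    c = config.cohort
    return simulate_cohort(
        pair,
        n_participants=c.n_participants,
        population=c.population,
        n_learning=c.n_learning,
        n_testing_per_condition=c.n_testing_per_condition,
        rating_every=c.rating_every,
        reward_rate_cents_per_s=c.reward_rate_cents_per_s,
        rng=cohort_seed)


def pair_to_json(pair: ConditionPair) -> dict:
    report = verify_pair(pair)
    return {
        "trial_length_s": pair.trial_length_s,
        "matched_window": list(pair.matched_window),
        "early": schedule_to_json(pair.early),
        "late": schedule_to_json(pair.late),
        "report": report.to_json(),
    }


def pair_from_json(obj: dict) -> ConditionPair:
    from .schedules import schedule_from_json
    return ConditionPair(
        early=schedule_from_json(obj["early"]),
        late=schedule_from_json(obj["late"]),
        matched_window=tuple(obj["matched_window"]),
        trial_length_s=int(obj["trial_length_s"]))


def run_all(config: RunConfig) -> dict:
    """design -> simulate -> analyze; write every artifact under outdir.

    Writes ``pair.json``, ``trials.csv``, ``forced_choice.csv``,
    ``report.json`` and ``run.log``.  Returns the report dictionary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"threatdyn {__version__} | numpy {np.__version__}",
        f"config sha256[:16] = {config.config_hash}",
        "--- config ---",
        config.to_yaml().rstrip(),
        "--------------",
    ]

    try:
        pair = build_pair(config.design)
        report_design = verify_pair(pair)
        (outdir / "pair.json").write_text(
            json.dumps(pair_to_json(pair), indent=1) + "\n")
        log_lines.append(f"design: ok={report_design.ok} "
                         f"expected_times={report_design.expected_times}")
    except Exception as exc:  # noqa: BLE001 - stage tagging
        raise PipelineStageError("design", exc) from exc

    try:
        cohort = run_cohort(config, pair)
        cohort.records.to_csv(outdir / "trials.csv", index=False)
        cohort.forced_choice.to_csv(outdir / "forced_choice.csv", index=False)
        log_lines.append(f"simulate: {len(cohort.records)} trial records, "
                         f"{len(cohort.forced_choice)} forced choices")
    except Exception as exc:
        raise PipelineStageError("simulate", exc) from exc

    try:
        report = analyze_all(cohort.records, cohort.forced_choice, pair,
                             epochs=config.analysis.epochs)
        report["config_hash"] = config.config_hash
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, default=float) + "\n")
        log_lines.append("analyze: report.json written")
    except Exception as exc:
        raise PipelineStageError("analyze", exc) from exc

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
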