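"""Run configuration, validation, and result serialization.

A run is described by a small YAML mapping (all keys optional except the
simulation id) and resolves to a fully seeded, reproducible cohort run::

    simulation: sim5        # sim1 .. sim6
    seed: 1                 # master seed for the whole cohort
    subjects: 10
    trials: 300
    out: results/
    model:                  # ModelConfig fields except n_events
      learning_rate: 0.1
      discount: 0.95
    response:               # ResponseConfig fields
      noise_sd: 0.1
    task:                   # generator-specific keyword arguments
      stop_rate: 0.25

Unknown keys raise an error naming them; range violations surface the
offending field through the dataclass validators. Every CSV written by
:func:`run_simulation` starts with a comment line carrying the hash of the
resolved configuration (read back with ``pandas.read_csv(..., comment='#')``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from prosim.core_model import ModelConfig
from prosim.experiments import (
    CohortConfig,
    log_to_frame,
    run_sim1,
    run_sim2,
    run_sim3,
    run_sim4,
    run_sim5,
    run_sim6,
    run_subject,
)
from prosim.response_control import ResponseConfig
from prosim.tasks import (
    gen_cued_stroop,
    gen_expect_reward,
    gen_flanker_frequency,
    gen_item_stroop,
    gen_mmn,
    gen_stop_signal,
)

__all__ = ["RunConfig", "load_config", "run_simulation", "SIMULATIONS"]

SIMULATIONS = ("sim1", "sim2", "sim3", "sim4", "sim5", "sim6")

_DEFAULT_TRIALS = {
    "sim1": 300, "sim2": 200, "sim3": 200, "sim4": 300, "sim5": 300,
    "sim6": 200,
}

_TOP_KEYS = {"simulation", "seed", "subjects", "trials", "out", "model",
             "response", "task", "trace"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """A fully resolved simulation run."""

    simulation: str
    seed: int = 0
    subjects: int = 10
    trials: int | None = None
    out: str = "results"
    model: dict[str, Any] = dataclasses.field(default_factory=dict)
    response: dict[str, Any] = dataclasses.field(default_factory=dict)
    task: dict[str, Any] = dataclasses.field(default_factory=dict)
    trace: bool = False

    def __post_init__(self) -> None:
        if self.simulation not in SIMULATIONS:
            raise ValueError(
                f"simulation must be one of {SIMULATIONS}, got {self.simulation!r}"
            )
        if self.subjects < 1:
            raise ValueError("subjects must be >= 1")
        if self.trials is not None and self.trials < 1:
            raise ValueError("trials must be >= 1")
        # validate nested sections eagerly so errors name the field
        ModelConfig(n_events=1, **self.model)
        ResponseConfig(**self.response)

    @property
    def n_trials(self) -> int:
        return self.trials if self.trials is not None else _DEFAULT_TRIALS[self.simulation]

    def resolved(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["trials"] = self.n_trials
        return out

    @property
    def hash(self) -> str:
        """Digest of the scientific run parameters.

        Excludes ``out`` and ``trace``, which affect where and how much is
        written but not what is computed.
        """
        payload = self.resolved()
        payload.pop("out", None)
        payload.pop("trace", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys (top level or in the model/response sections) raise a
    ValueError listing them. ``overrides`` take precedence over file values
    (used by the command line for ``--seed`` etc.).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, fields in (
        ("model", {f.name for f in dataclasses.fields(ModelConfig)} - {"n_events"}),
        ("response", {f.name for f in dataclasses.fields(ResponseConfig)}),
    ):
        extra = set(raw.get(section) or {}) - fields
        if extra:
            raise ValueError(f"unknown keys in {section!r} section: {sorted(extra)}")
    raw.update(overrides)
    return RunConfig(**raw)


def _probe_schedule(cfg: RunConfig):
    """One-trial schedule used to size the model and dump traces."""
    gen: dict[str, Callable] = {
        "sim1": lambda **kw: gen_flanker_frequency(
            kw.pop("condition", "frequent-congruent"), n_trials=1, seed=0, **kw
        ),
        "sim2": lambda **kw: gen_item_stroop(
            kw.pop("experiment", 1), n_trials=1, seed=0, **kw
        ),
        "sim3": lambda **kw: gen_mmn(n_repetitions=1, seed=0, **kw),
        "sim4": lambda **kw: gen_cued_stroop(n_trials=1, seed=0, **kw),
        "sim5": lambda **kw: gen_stop_signal(n_trials=1, seed=0, **kw),
        "sim6": lambda **kw: gen_expect_reward(n_trials=1, seed=0, **kw),
    }
    return gen[cfg.simulation](**dict(cfg.task))


def _model_cfg(cfg: RunConfig) -> ModelConfig | None:
    if not cfg.model:
        return None  # let each runner pick its documented default
    probe = _probe_schedule(cfg)
    return ModelConfig(n_events=len(probe.catalog), **cfg.model)


def _write_csv(frame: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash: {cfg_hash}\n")
        frame.to_csv(fh, index=False)


def run_simulation(cfg: RunConfig) -> list[Path]:
    """Execute a configured cohort run and write its summary CSVs.

    Writes one CSV per figure panel, a copy of the resolved configuration,
    a plain-text log with seed provenance, and (with ``trace``) an
    iteration-level dump for the first subject. Returns the written paths.
    """
    out_dir = Path(cfg.out)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = CohortConfig(
        n_subjects=cfg.subjects, n_trials=cfg.n_trials, master_seed=cfg.seed
    )
    model_cfg = _model_cfg(cfg)
    response_cfg = ResponseConfig(**cfg.response) if cfg.response else None

    results: dict[str, pd.DataFrame]
    if cfg.simulation == "sim1":
        results = {"sim1_summary": run_sim1(cohort, model_cfg, response_cfg)}
    elif cfg.simulation == "sim2":
        results = {"sim2_summary": run_sim2(cohort, model_cfg, response_cfg)}
    elif cfg.simulation == "sim3":
        r = run_sim3(cohort, model_cfg)
        results = {"sim3_summary": r["summary"], "sim3_timecourse": r["timecourse"]}
    elif cfg.simulation == "sim4":
        r = run_sim4(cohort, model_cfg, response_cfg)
        results = {
            "sim4_cue": r["cue"], "sim4_task20": r["task20"],
            "sim4_task100": r["task100"],
        }
    elif cfg.simulation == "sim5":
        results = {"sim5_summary": run_sim5(cohort, model_cfg, response_cfg)}
    else:
        results = {"sim6_units": run_sim6(cohort, model_cfg)}

    written: list[Path] = []
    for name, frame in results.items():
        path = out_dir / f"{name}.csv"
        _write_csv(frame, path, cfg.hash)
        written.append(path)

    if cfg.trace:
        log = _trace_subject(cfg)
        path = out_dir / f"{cfg.simulation}_trace_subject0.csv"
        _write_csv(log, path, cfg.hash)
        written.append(path)

    resolved_path = out_dir / f"{cfg.simulation}_config.yaml"
    resolved_path.write_text(
        yaml.safe_dump({"config_hash": cfg.hash, **cfg.resolved()}, sort_keys=True)
    )
    written.append(resolved_path)

    log_path = out_dir / f"{cfg.simulation}_run.log"
    log_path.write_text(
        "\n".join(
            [
                f"simulation: {cfg.simulation}",
                f"master_seed: {cfg.seed}",
                f"subjects: {cfg.subjects}",
                f"trials: {cfg.n_trials}",
                f"config_hash: {cfg.hash}",
                "",
            ]
        )
    )
    written.append(log_path)
    return written


def _trace_subject(cfg: RunConfig) -> pd.DataFrame:
    """Iteration-level dump of subject 0 under the configured parameters."""
    gen: dict[str, Callable] = {
        "sim1": lambda kw: gen_flanker_frequency(
            kw.pop("condition", "frequent-congruent"), cfg.n_trials, cfg.seed, **kw
        ),
        "sim2": lambda kw: gen_item_stroop(
            kw.pop("experiment", 1), cfg.n_trials, cfg.seed, **kw
        ),
        "sim3": lambda kw: gen_mmn(n_repetitions=cfg.n_trials, seed=cfg.seed, **kw),
        "sim4": lambda kw: gen_cued_stroop(cfg.n_trials, cfg.seed, **kw),
        "sim5": lambda kw: gen_stop_signal(cfg.n_trials, cfg.seed, **kw),
        "sim6": lambda kw: gen_expect_reward(cfg.n_trials, cfg.seed, **kw),
    }
    sched = gen[cfg.simulation](dict(cfg.task))
    model_cfg = (
        ModelConfig(n_events=len(sched.catalog), **cfg.model) if cfg.model else None
    )
    response_cfg = ResponseConfig(**cfg.response) if cfg.response else ResponseConfig(
        sr_scale=0.0 if sched.lesioned else 1.0
    )
    log = run_subject(sched, model_cfg, response_cfg, cfg.seed)
    return log_to_frame(log)
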