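"""End-to-end orchestration: simulate -> condition -> features -> train -> evaluate.

One master seed fans out to named substreams (simulation, splitting, model
initialisation) so stages can be re-run in isolation reproducibly and the
whole pipeline is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import EvaluationReport, run_loso_experiment, run_pooled_experiment
from .features import CalibrationCurve, default_calibration_curve, extract_features_table
from .fusion import MLPConfig
from .preprocess import PreprocConfig
from .signal_model import Dataset, ValidationError, validate_session, write_dataset_manifest, write_session
from .synthesize import SimulationConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "make_quickstart_fixture", "extract_cohort_features", "stage_seeds"]

log = logging.getLogger("dualppg")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive named per-stage seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(3)
    return {
        "simulate": int(state[0] % (2**31)),
        "split": int(state[1] % (2**31)),
        "model": int(state[2] % (2**31)),
    }


@dataclass
class PipelineConfig:
    """Nested stage configs plus orchestration options."""

    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(
        n_subjects=6, sessions_per_subject=4, session_duration=120.0))
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    mlp: MLPConfig = field(default_factory=lambda: MLPConfig(max_epochs=150, early_stop_patience=15))
    min_beats: int = 5
    targets: tuple[str, ...] = ("SBP", "DBP")
    eval_mode: str = "loso"  # or "pooled"
    seed: int = 0
    out_dir: str | None = None
    write_sessions: bool = False

    def validate(self) -> None:
        self.sim.validate()
        self.preproc.validate()
        self.mlp.validate()
        if self.eval_mode not in ("loso", "pooled"):
            raise ValidationError(f"unknown eval_mode {self.eval_mode!r}")
        for t in self.targets:
            if t not in ("SBP", "DBP"):
                raise ValidationError(f"unknown target {t!r}")

    # ---- JSON round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sim": dict(self.sim.__dict__),
            "preproc": dict(self.preproc.__dict__),
            "mlp": {**self.mlp.__dict__, "hidden_sizes": list(self.mlp.hidden_sizes)},
            "min_beats": self.min_beats,
            "targets": list(self.targets),
            "eval_mode": self.eval_mode,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "write_sessions": self.write_sessions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "sim" in d:
            cfg.sim = SimulationConfig(**d["sim"])
        if "preproc" in d:
            cfg.preproc = PreprocConfig(**d["preproc"])
        if "mlp" in d:
            m = dict(d["mlp"])
            if "hidden_sizes" in m:
                m["hidden_sizes"] = tuple(m["hidden_sizes"])
            cfg.mlp = MLPConfig(**m)
        for key in ("min_beats", "eval_mode", "seed", "out_dir", "write_sessions"):
            if key in d:
                setattr(cfg, key, d[key])
        if "targets" in d:
            cfg.targets = tuple(d["targets"])
        return cfg


def extract_cohort_features(
    dataset: Dataset,
    preproc: PreprocConfig | None = None,
    curve: CalibrationCurve | None = None,
    min_beats: int = 5,
) -> pd.DataFrame:
    """Window-feature table of a whole cohort, with per-session counters logged."""
    frames = []
    for session in dataset:
        df = extract_features_table(session, preproc, curve, min_beats=min_beats)
        n_invalid = int((~df["valid"].astype(bool)).sum()) if len(df) else 0
        log.debug("session %s: %d windows, %d rejected", session.session_id, len(df), n_invalid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> dict[str, EvaluationReport]:
    """Run every stage and return one evaluation report per target.

    When ``config.out_dir`` is set, the feature table, the per-target report
    JSONs, and (optionally) the simulated session directories are written
    there.  Idempotent per (config, seed).
    """
    config.validate()
    seeds = stage_seeds(config.seed)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    sim_cfg = replace(config.sim, seed=seeds["simulate"])
    dataset, truths = generate_cohort(sim_cfg)
    log.info("simulate: %d sessions in %.1f s", len(dataset), time.time() - t0)
    for session in dataset:
        problems = validate_session(session, sim_cfg.ppg_rate, sim_cfg.iface_rate)
        if problems:
            raise ValidationError(f"simulate stage produced invalid session: {problems}")
    if out and config.write_sessions:
        rows = []
        for session in dataset:
            p = out / "sessions" / session.session_id
            write_session(session, p)
            rows.append((session.session_id, session.profile.subject_id, str(p)))
        write_dataset_manifest(rows, out / "manifest.csv")

    t0 = time.time()
    curve = default_calibration_curve(v_sat=sim_cfg.v_sat, p0=sim_cfg.p0)
    features = extract_cohort_features(dataset, config.preproc, curve, config.min_beats)
    n_rej = int((~features["valid"].astype(bool)).sum())
    log.info(
        "features: %d windows (%d rejected) in %.1f s", len(features), n_rej, time.time() - t0
    )
    if out:
        features.to_csv(out / "features.csv", index=False)

    reports: dict[str, EvaluationReport] = {}
    for target in config.targets:
        t0 = time.time()
        mlp_cfg = replace(config.mlp, seed=seeds["model"])
        if config.eval_mode == "loso":
            rep = run_loso_experiment(features, target, mlp_cfg, seed=seeds["split"])
        else:
            rep = run_pooled_experiment(features, target, mlp_cfg, seed=seeds["split"])
        log.info(
            "%s %s: ME %.2f, SD %.2f mmHg (n=%d) in %.1f s",
            config.eval_mode, target, rep.stats.me, rep.stats.sd, rep.stats.n, time.time() - t0,
        )
        reports[target] = rep
        if out:
            (out / f"report_{target.lower()}.json").write_text(
                json.dumps({"schema_version": 1, **rep.to_dict()}, indent=1)
            )
    return reports


def make_quickstart_fixture(out_dir: str | Path, seed: int = 0) -> Path:
    """Write a tiny cohort (2 subjects x 2 x 60 s) plus a matching config file.

    Used by the documentation walkthroughs; builds in seconds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = SimulationConfig(n_subjects=2, sessions_per_subject=2, session_duration=60.0, seed=seed)
    dataset, _ = generate_cohort(sim)
    rows = []
    for session in dataset:
        problems = validate_session(session)
        if problems:
            raise ValidationError(f"fixture session invalid: {problems}")
        p = out / "sessions" / session.session_id
        write_session(session, p)
        rows.append((session.session_id, session.profile.subject_id, str(p)))
    write_dataset_manifest(rows, out / "manifest.csv")
    cfg = PipelineConfig(sim=sim, seed=seed, out_dir=str(out))
    (out / "config.json").write_text(json.dumps(cfg.to_dict(), indent=1))
    return out
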