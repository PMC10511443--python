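"""Evaluation protocols and agreement statistics for BP estimates.

Supports the two split protocols used to judge cross-subject generalization —
leave-one-subject-out (every subject in turn is the unseen test case; 85/15
train/validation split of the remaining subjects' sessions) and a pooled
70/15/15 session-level split — and the standard agreement statistics: mean
error and standard deviation of (estimate − reference), Bland–Altman limits
of agreement ``[mu − 1.96 sigma, mu + 1.96 sigma]``, the AAMI accuracy
criterion (|ME| < 5 mmHg and SD < 8 mmHg, strict), and BHS cumulative-error
grading (A–D from the percentages of absolute errors within 5/10/15 mmHg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import DBP_FEATURES, SBP_FEATURES
from .fusion import MLPConfig, TrainedModel, predict_bp, train_model
from .signal_model import Dataset, ValidationError

__all__ = [
    "SplitPlan",
    "Fold",
    "ErrorStats",
    "BlandAltman",
    "BHSGrade",
    "EvaluationReport",
    "loso_folds",
    "pooled_split",
    "compute_error_stats",
    "bland_altman_limits",
    "aami_check",
    "bhs_grade",
    "run_loso_experiment",
    "run_pooled_experiment",
]

#: BHS protocol grading table: cumulative % of |error| <= 5 / 10 / 15 mmHg.
BHS_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass(frozen=True)
class Fold:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def violations(self) -> list[str]:
        sets = [set(self.train), set(self.val), set(self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            return ["fold: train/val/test session sets overlap"]
        return []


@dataclass
class SplitPlan:
    mode: str  # "loso" or "pooled"
    folds: list[Fold]
    seed: int


def _session_index(dataset: Dataset | Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    if isinstance(dataset, Dataset):
        return dataset.session_index()
    return [(str(a), str(b)) for a, b in dataset]


def loso_folds(
    dataset: Dataset | Sequence[tuple[str, str]],
    val_fraction: float = 0.15,
    seed: int = 0,
) -> SplitPlan:
    """Leave-one-subject-out plan: one fold per subject.

    Each fold tests on all sessions of one subject; the remaining subjects'
    sessions are shuffled by ``seed`` and split 85/15 into train and
    validation at session level.
    """
    index = _session_index(dataset)
    subjects: dict[str, list[str]] = {}
    for sid, subj in index:
        subjects.setdefault(subj, []).append(sid)
    if len(subjects) < 2:
        raise ValidationError("LOSO requires at least 2 subjects")
    rng = np.random.Generator(np.random.PCG64(seed))
    folds = []
    for subj in subjects:
        test = tuple(subjects[subj])
        rest = [sid for s, sids in subjects.items() if s != subj for sid in sids]
        order = rng.permutation(len(rest))
        n_val = int(round(val_fraction * len(rest)))
        val = tuple(rest[i] for i in order[:n_val])
        train = tuple(rest[i] for i in order[n_val:])
        folds.append(Fold(train=train, val=val, test=test))
    return SplitPlan(mode="loso", folds=folds, seed=seed)


def pooled_split(
    dataset: Dataset | Sequence[tuple[str, str]],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """Single 70/15/15 session-level split (subjects shared across sets)."""
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValidationError("split fractions must sum to 1")
    index = _session_index(dataset)
    ids = [sid for sid, _ in index]
    if len(ids) < 7:
        raise ValidationError("pooled split requires at least 7 sessions")
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(len(ids))
    n_train = int(round(fractions[0] * len(ids)))
    n_val = int(round(fractions[1] * len(ids)))
    train = tuple(ids[i] for i in order[:n_train])
    val = tuple(ids[i] for i in order[n_train : n_train + n_val])
    test = tuple(ids[i] for i in order[n_train + n_val :])
    return SplitPlan(mode="pooled", folds=[Fold(train=train, val=val, test=test)], seed=seed)


# --------------------------------------------------------------------------
# Agreement statistics
# --------------------------------------------------------------------------

@dataclass
class ErrorStats:
    """Mean error and sample standard deviation of (estimate − reference)."""

    me: float
    sd: float
    n: int


@dataclass
class BlandAltman:
    mu: float
    sigma: float
    loa_lower: float
    loa_upper: float


@dataclass
class BHSGrade:
    grade: str
    pct_le5: float
    pct_le10: float
    pct_le15: float


@dataclass
class EvaluationReport:
    """Full assessment of one target's estimates against cuff references."""

    target: str
    stats: ErrorStats
    bland_altman: BlandAltman
    aami_pass: bool
    bhs: BHSGrade
    per_subject: dict[str, ErrorStats] = field(default_factory=dict)
    per_fold: list[dict] = field(default_factory=list)
    baseline: ErrorStats | None = None  # train-mean predictor, same protocol
    errors: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "target": self.target,
            "me": self.stats.me,
            "sd": self.stats.sd,
            "n": self.stats.n,
            "loa_lower": self.bland_altman.loa_lower,
            "loa_upper": self.bland_altman.loa_upper,
            "aami_pass": self.aami_pass,
            "bhs_grade": self.bhs.grade,
            "bhs_pct_le5": self.bhs.pct_le5,
            "bhs_pct_le10": self.bhs.pct_le10,
            "bhs_pct_le15": self.bhs.pct_le15,
            "per_subject": {
                k: {"me": v.me, "sd": v.sd, "n": v.n} for k, v in self.per_subject.items()
            },
            "per_fold": self.per_fold,
        }
        if self.baseline is not None:
            d["baseline_me"] = self.baseline.me
            d["baseline_sd"] = self.baseline.sd
        return d


def compute_error_stats(estimates: np.ndarray, references: np.ndarray) -> ErrorStats:
    """ME = mean(est − ref); SD with the n−1 denominator."""
    est = np.asarray(estimates, dtype=np.float64).ravel()
    ref = np.asarray(references, dtype=np.float64).ravel()
    if est.size != ref.size:
        raise ValidationError("estimate and reference vectors differ in length")
    if est.size < 2:
        raise ValidationError("need at least 2 pairs for error statistics")
    err = est - ref
    return ErrorStats(me=float(err.mean()), sd=float(err.std(ddof=1)), n=est.size)


def bland_altman_limits(me: float, sd: float) -> BlandAltman:
    """Limits of agreement ``[mu − 1.96 sigma, mu + 1.96 sigma]``, exact."""
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    return BlandAltman(
        mu=me, sigma=sd, loa_lower=me - 1.96 * sd, loa_upper=me + 1.96 * sd
    )


def aami_check(stats: ErrorStats) -> bool:
    """AAMI accuracy: |ME| < 5 mmHg and SD < 8 mmHg (strict; ties fail)."""
    return abs(stats.me) < 5.0 and stats.sd < 8.0


def bhs_grade(errors: np.ndarray) -> BHSGrade:
    """BHS cumulative-error grade from a vector of errors (mmHg)."""
    err = np.abs(np.asarray(errors, dtype=np.float64).ravel())
    if err.size < 1:
        raise ValidationError("need at least 1 error for BHS grading")
    pct = tuple(100.0 * float(np.mean(err <= t)) for t in (5.0, 10.0, 15.0))
    grade = "D"
    for g in ("C", "B", "A"):  # strongest grade whose thresholds are all met
        if all(p >= t for p, t in zip(pct, BHS_THRESHOLDS[g])):
            grade = g
    return BHSGrade(grade=grade, pct_le5=pct[0], pct_le10=pct[1], pct_le15=pct[2])


def _report_from_errors(
    target: str,
    estimates: np.ndarray,
    references: np.ndarray,
    subjects: np.ndarray,
    per_fold: list[dict],
    baseline_errors: np.ndarray | None,
) -> EvaluationReport:
    stats = compute_error_stats(estimates, references)
    errors = np.asarray(estimates) - np.asarray(references)
    per_subject = {}
    for subj in pd.unique(subjects):
        mask = subjects == subj
        if mask.sum() >= 2:
            per_subject[str(subj)] = compute_error_stats(
                np.asarray(estimates)[mask], np.asarray(references)[mask]
            )
    baseline = None
    if baseline_errors is not None:
        baseline = ErrorStats(
            me=float(np.mean(baseline_errors)),
            sd=float(np.std(baseline_errors, ddof=1)),
            n=baseline_errors.size,
        )
    return EvaluationReport(
        target=target,
        stats=stats,
        bland_altman=bland_altman_limits(stats.me, stats.sd),
        aami_pass=aami_check(stats),
        bhs=bhs_grade(errors),
        per_subject=per_subject,
        per_fold=per_fold,
        baseline=baseline,
        errors=errors,
    )


# --------------------------------------------------------------------------
# Experiment drivers
# --------------------------------------------------------------------------

def _target_columns(target: str, feature_names: Sequence[str] | None) -> list[str]:
    if feature_names is not None:
        return list(feature_names)
    return list(SBP_FEATURES if target == "SBP" else DBP_FEATURES)


def _prepare(features: pd.DataFrame, target: str, cols: list[str]):
    df = features[features["valid"].astype(bool)].copy()
    ycol = "sbp_ref" if target == "SBP" else "dbp_ref"
    needed = cols + [ycol, "session_id", "subject_id"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table lacks columns: {missing}")
    df = df.dropna(subset=cols + [ycol])
    return df, ycol


def _run_plan(
    features: pd.DataFrame,
    target: str,
    plan: SplitPlan,
    mlp_cfg: MLPConfig,
    feature_names: Sequence[str] | None = None,
) -> EvaluationReport:
    cols = _target_columns(target, feature_names)
    df, ycol = _prepare(features, target, cols)
    all_est, all_ref, all_subj = [], [], []
    base_err = []
    per_fold = []
    for i, fold in enumerate(plan.folds):
        tr = df[df["session_id"].isin(fold.train)]
        va = df[df["session_id"].isin(fold.val)]
        te = df[df["session_id"].isin(fold.test)]
        if len(tr) < 2 or len(va) < 1 or len(te) < 2:
            raise ValidationError(f"fold {i}: too few rows (train {len(tr)}, val {len(va)}, test {len(te)})")
        # a feature that is constant across this fold's training rows carries
        # no information here and would break z-scoring; drop it for the fold
        tr_mat = tr[cols].to_numpy()
        fold_cols = [c for c, sd in zip(cols, tr_mat.std(axis=0)) if sd > 0]
        cfg = MLPConfig(**{**mlp_cfg.__dict__, "seed": mlp_cfg.seed + i})
        model = train_model(
            tr[fold_cols].to_numpy(), tr[ycol].to_numpy(),
            va[fold_cols].to_numpy(), va[ycol].to_numpy(),
            cfg, target=target, feature_names=tuple(fold_cols),
        )
        est = predict_bp(model, te[fold_cols].to_numpy())
        ref = te[ycol].to_numpy()
        all_est.append(est)
        all_ref.append(ref)
        all_subj.append(te["subject_id"].to_numpy())
        base_err.append(float(tr[ycol].mean()) - ref)
        fstats = compute_error_stats(est, ref)
        per_fold.append(
            {
                "fold": i,
                "test_subjects": sorted(set(te["subject_id"])),
                "me": fstats.me,
                "sd": fstats.sd,
                "n": fstats.n,
                "epochs_run": len(model.history["val_loss"]),
                "best_val_mse": float(min(model.history["val_loss"])),
                "dropped_features": [c for c in cols if c not in fold_cols],
            }
        )
    return _report_from_errors(
        target,
        np.concatenate(all_est),
        np.concatenate(all_ref),
        np.concatenate(all_subj),
        per_fold,
        np.concatenate(base_err),
    )


def run_loso_experiment(
    features: pd.DataFrame,
    target: str,
    mlp_cfg: MLPConfig | None = None,
    seed: int = 0,
    val_fraction: float = 0.15,
    feature_names: Sequence[str] | None = None,
) -> EvaluationReport:
    """Train one model per left-out subject and pool test errors across folds.

    Errors from all folds are concatenated before ME/SD (a single pooled
    scatter, not fold-averaged statistics).  The report also carries the
    train-mean baseline predictor evaluated under the identical protocol.
    Deterministic per (features, seed).
    """
    mlp_cfg = mlp_cfg or MLPConfig()
    index = list(dict.fromkeys(zip(features["session_id"], features["subject_id"])))
    plan = loso_folds(index, val_fraction=val_fraction, seed=seed)
    return _run_plan(features, target, plan, mlp_cfg, feature_names)


def run_pooled_experiment(
    features: pd.DataFrame,
    target: str,
    mlp_cfg: MLPConfig | None = None,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> EvaluationReport:
    """Single pooled 70/15/15 split experiment (subjects shared across sets)."""
    mlp_cfg = mlp_cfg or MLPConfig()
    index = list(dict.fromkeys(zip(features["session_id"], features["subject_id"])))
    plan = pooled_split(index, seed=seed)
    return _run_plan(features, target, plan, mlp_cfg, feature_names)
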