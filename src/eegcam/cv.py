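"""Leave-p%-subjects-out cross-validation (LPSO-CV).

The protocol trains only on the non-carrier (N) and single-risk (A+P-)
groups: each of the 100 seeded iterations (seeds 42..141 by default) holds
out a stratified random p% of subjects per group for validation, trains the
CNN on the remaining subjects' trials, scores validation ROC AUC / Cohen's
kappa / sensitivity (positive class = A+P-), and then applies the trained
model post hoc to every trial of the held-out dual-risk group (A+P+),
recording its sensitivity as the generalization measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .metrics import cohen_kappa, roc_auc, sensitivity
from .model import ModelConfig, ModelParams, build_model, predict_log_probs
from .synth import Dataset, HELDOUT_GROUP, RISK_GROUP, TRAINING_GROUPS
from .training import TrainConfig, train_model

logger = logging.getLogger(__name__)

TASK_CONDITIONS = ("ALL", "MSIT", "STMT")


@dataclass(frozen=True)
class CVConfig:
    n_iterations: int = 100
    seed_start: int = 42
    seed_end: int = 141
    heldout_fraction: float = 0.20
    training_groups: Tuple[str, str] = TRAINING_GROUPS
    test_group: str = HELDOUT_GROUP
    task_filter: str = "ALL"

    def __post_init__(self) -> None:
        if self.seed_end - self.seed_start + 1 != self.n_iterations:
            raise ValueError("seed range must contain exactly n_iterations seeds")
        if not (0.0 < self.heldout_fraction < 1.0):
            raise ValueError("heldout_fraction must be in (0, 1)")
        if self.task_filter not in TASK_CONDITIONS:
            raise ValueError(f"task_filter must be one of {TASK_CONDITIONS}")

    @property
    def seeds(self) -> range:
        return range(self.seed_start, self.seed_end + 1)


@dataclass(frozen=True)
class Split:
    train_subjects: Tuple[str, ...]
    val_subjects: Tuple[str, ...]


@dataclass
class FoldResult:
    seed: int
    task_condition: str
    val_roc_auc: float
    val_kappa: float
    val_sensitivity: float
    test_sensitivity: float
    n_train_trials: int = 0
    n_val_trials: int = 0
    stop_epoch: int = 0
    valid: bool = True


@dataclass
class SummaryTable:
    """Mean and sample SD per metric, per task condition."""

    table: pd.DataFrame  # index metric, columns MultiIndex (condition, stat)
    n_folds: Dict[str, int]


def split_subjects(dataset: Dataset, p: float, seed: int,
                   groups: Sequence[str] = TRAINING_GROUPS) -> Split:
    """Stratified subject-level split: round(p * group size), minimum 1, per group."""
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    rng = default_rng(seed)
    train: List[str] = []
    val: List[str] = []
    for g in groups:
        ids = sorted(s.subject_id for s in dataset.subjects_in_group(g))
        if len(ids) < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects to split")
        n_val = max(1, int(round(p * len(ids))))
        if n_val >= len(ids):
            raise ValueError(f"p={p} leaves no training subjects in group {g!r}")
        perm = rng.permutation(len(ids))
        val.extend(ids[i] for i in perm[:n_val])
        train.extend(ids[i] for i in perm[n_val:])
    return Split(tuple(sorted(train)), tuple(sorted(val)))


def _stack(epochs) -> Tuple[np.ndarray, np.ndarray]:
    """Trials -> (X, y) with y = 1 for the risk group, 0 otherwise."""
    X = np.stack([ep.data for ep in epochs])
    y = np.array([1 if ep.group == RISK_GROUP else 0 for ep in epochs], dtype=int)
    return X, y


def evaluate_heldout_group(trained: ModelParams, dataset: Dataset,
                           group: str = HELDOUT_GROUP,
                           task: str = "ALL") -> float:
    """Fraction of the group's trials predicted as the risk class."""
    eps = dataset.epochs(groups=(group,), task=task)
    if not eps:
        raise ValueError(f"no trials for held-out group {group!r}")
    X = np.stack([ep.data for ep in eps])
    preds = predict_log_probs(trained, X).argmax(axis=1)
    return float((preds == 1).mean())


def run_fold(dataset: Dataset, model_cfg: ModelConfig, train_cfg: TrainConfig,
             cv_cfg: CVConfig, seed: int,
             return_params: bool = False):
    """One LPSO-CV iteration for a single seed.

    The fold seed drives three independent sub-seeds (split, weight init,
    batch shuffle).
    """
    sub = [int(s.generate_state(1)[0] % 2 ** 31)
           for s in SeedSequence(seed).spawn(3)]
    split_seed, init_seed, shuffle_seed = sub
    split = split_subjects(dataset, cv_cfg.heldout_fraction, split_seed,
                           groups=cv_cfg.training_groups)
    assert not set(split.train_subjects) & set(split.val_subjects)

    task = cv_cfg.task_filter
    train_eps = dataset.epochs(groups=cv_cfg.training_groups,
                               subject_ids=split.train_subjects, task=task)
    val_eps = dataset.epochs(groups=cv_cfg.training_groups,
                             subject_ids=split.val_subjects, task=task)
    if not train_eps or not val_eps:
        raise ValueError(f"task filter {task!r} selects no trials")
    X_tr, y_tr = _stack(train_eps)
    X_va, y_va = _stack(val_eps)

    fold = FoldResult(seed=seed, task_condition=task, val_roc_auc=np.nan,
                      val_kappa=np.nan, val_sensitivity=np.nan,
                      test_sensitivity=np.nan, n_train_trials=len(X_tr),
                      n_val_trials=len(X_va))
    if len(np.unique(y_va)) < 2:
        logger.warning("seed %d: single-class validation set; fold flagged invalid",
                       seed)
        fold.valid = False
        return (fold, None) if return_params else fold

    from dataclasses import replace as _replace
    params = build_model(_replace(model_cfg, init_seed=init_seed))
    trained, hist = train_model(params, X_tr, y_tr, X_va, y_va, train_cfg,
                                seed=shuffle_seed)
    fold.stop_epoch = hist.stop_epoch

    log_p = predict_log_probs(trained, X_va)
    risk_scores = np.exp(log_p[:, 1])
    preds = log_p.argmax(axis=1)
    fold.val_roc_auc = roc_auc(risk_scores, y_va)
    fold.val_kappa = cohen_kappa(preds, y_va)
    fold.val_sensitivity = sensitivity(preds, y_va)
    fold.test_sensitivity = evaluate_heldout_group(
        trained, dataset, cv_cfg.test_group, task=task)
    return (fold, trained) if return_params else fold


def run_lpso_cv(dataset: Dataset, model_cfg: ModelConfig, train_cfg: TrainConfig,
                cv_cfg: CVConfig, progress: bool = False) -> List[FoldResult]:
    """All seeded iterations; invalid folds are recorded, never dropped."""
    for g in cv_cfg.training_groups:
        if not dataset.subjects_in_group(g):
            raise ValueError(f"dataset is missing training group {g!r}")
    results: List[FoldResult] = []
    for seed in cv_cfg.seeds:
        fold = run_fold(dataset, model_cfg, train_cfg, cv_cfg, seed)
        if progress:
            logger.info("seed %d: AUC=%.3f kappa=%.3f", seed,
                        fold.val_roc_auc, fold.val_kappa)
        results.append(fold)
    return results


METRIC_COLUMNS = ("val_roc_auc", "val_kappa", "val_sensitivity", "test_sensitivity")


def results_frame(results: Sequence[FoldResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def summarize_folds(results: Sequence[FoldResult]) -> SummaryTable:
    """Mean +/- sample SD (n-1; 0 for a single fold) by task condition."""
    valid = [r for r in results if r.valid]
    if not valid:
        raise ValueError("no valid folds to summarize")
    df = results_frame(valid)
    rows = {}
    n_folds = {}
    for cond, sub in df.groupby("task_condition"):
        n_folds[cond] = len(sub)
        for m in METRIC_COLUMNS:
            vals = sub[m].to_numpy(dtype=float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows[(cond, m)] = (float(np.mean(vals)), sd)
    conditions = sorted(n_folds)
    table = pd.DataFrame(
        {(c, stat): [rows[(c, m)][i] for m in METRIC_COLUMNS]
         for c in conditions for i, stat in enumerate(("mean", "sd"))},
        index=list(METRIC_COLUMNS))
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return SummaryTable(table=table, n_folds=n_folds)


def format_summary(summary: SummaryTable) -> str:
    """Human-readable summary mirroring the metric x condition layout."""
    lines = []
    conds = list(summary.table.columns.levels[0])
    header = "metric".ljust(18) + "".join(c.rjust(20) for c in conds)
    lines.append(header)
    for m in summary.table.index:
        cells = []
        for c in conds:
            mean = summary.table.loc[m, (c, "mean")]
            sd = summary.table.loc[m, (c, "sd")]
            cells.append(f"{mean:.4f} +/- {sd:.4f}".rjust(20))
        lines.append(m.ljust(18) + "".join(cells))
    lines.append("folds: " + ", ".join(f"{c}={summary.n_folds[c]}" for c in conds))
    return "\n".join(lines)
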