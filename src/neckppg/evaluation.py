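"""Confusion metrics, the repeated-randomization experiment driver,
best-model selection and the selection-frequency report.

One experiment repetition = build a balanced labelled table, partition
it subject-safely, then on the training side rank features (chi-square),
grid-search hyperparameters on the top-30 set, run forward selection at
the chosen (C, gamma), refit on all training data, and evaluate on the
held-out side.  Repetitions differ only in the randomization of the
partition/balancing stage; all randomness derives from a single
experiment seed plus the (W, Thd, repetition) coordinates.

The best artifacts model is the (W, Thd) pair maximizing mean accuracy;
the best apnea model maximizes mean F1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .io import Cohort, ValidationError
from .model import (
    RbfSvmClassifier,
    SvmConfig,
    TrainedModel,
    loso_grid_search,
    partition_leave_30pct_subjects,
    partition_recording_thirds,
    split_by_plan,
    train_svm_rbf,
)
from .selection import TOP_K, chi2_rank, forward_select
from .windowing import build_feature_table, extract_cohort_features

logger = logging.getLogger(__name__)

METRIC_NAMES = ("ACC", "SE", "SP", "precision", "F1")

#: Balanced per-class cap applied by the experiment driver (runtime bound
#: for the synthetic harness; None disables).
DEFAULT_MAX_PER_CLASS = 1000


@dataclass
class Metrics:
    """Confusion counts and the five derived percentages.

    Counts may be non-integer means over repetitions; undefined ratios
    (zero denominators) are NaN.
    """

    TP: float
    TN: float
    FP: float
    FN: float
    ACC: float = field(init=False)
    SE: float = field(init=False)
    SP: float = field(init=False)
    precision: float = field(init=False)
    F1: float = field(init=False)

    def __post_init__(self) -> None:
        tp, tn, fp, fn = self.TP, self.TN, self.FP, self.FN
        self.ACC = _ratio(tp + tn, tp + tn + fp + fn)
        self.SE = _ratio(tp, tp + fn)
        self.SP = _ratio(tn, tn + fp)
        self.precision = _ratio(tp, tp + fp)
        if np.isnan(self.precision) or np.isnan(self.SE) or self.precision + self.SE == 0:
            self.F1 = float("nan")
        else:
            self.F1 = 2 * self.precision * self.SE / (self.precision + self.SE)

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "ACC": self.ACC, "SE": self.SE, "SP": self.SP,
            "precision": self.precision, "F1": self.F1,
        }


def _ratio(num: float, den: float) -> float:
    if den == 0:
        logger.warning("undefined metric (zero denominator)")
        return float("nan")
    return 100.0 * num / den


def compute_metrics(y_true, y_pred) -> Metrics:
    """Confusion metrics from +/-1 label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    return Metrics(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


@dataclass
class RepetitionResult:
    repetition: int
    metrics: Metrics
    config: SvmConfig
    selected_features: list[str]


@dataclass
class ExperimentResult:
    """Aggregated outcome for one task over the (W, Thd) grid."""

    task: str
    results: dict[tuple[float, float], list[RepetitionResult]]
    failures: dict[tuple[float, float], int]

    def metric_table(self) -> pd.DataFrame:
        """Per-repetition metric rows, one per (W, Thd, repetition)."""
        rows = []
        for (W, thd), reps in sorted(self.results.items()):
            for r in reps:
                row = {"task": self.task, "W": W, "Thd": thd, "repetition": r.repetition}
                row.update(r.metrics.as_dict())
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Mean and std per metric per (W, Thd), plus mean counts."""
        table = self.metric_table()
        rows = []
        for (W, thd), sub in table.groupby(["W", "Thd"]):
            row = {"task": self.task, "W": W, "Thd": thd, "n_effective": len(sub)}
            for m in ("TP", "TN", "FP", "FN"):
                row[f"{m}_mean"] = float(sub[m].mean())
            for m in METRIC_NAMES:
                vals = sub[m].dropna()
                row[f"{m}_mean"] = float(vals.mean()) if len(vals) else float("nan")
                row[f"{m}_std"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
                if len(vals) < len(sub):
                    logger.info(
                        "%d undefined %s values excluded from aggregation",
                        len(sub) - len(vals), m,
                    )
            rows.append(row)
        return pd.DataFrame(rows)

    def best_model(self) -> tuple[float, float]:
        """(W, Thd) maximizing mean ACC (artifacts) or mean F1 (apnea)."""
        crit = "F1_mean" if self.task == "apnea" else "ACC_mean"
        summ = self.summary()
        best = summ.loc[summ[crit].idxmax()]
        return float(best["W"]), float(best["Thd"])

    def selection_frequencies(self, W: float, thd: float) -> pd.DataFrame:
        reps = self.results[(W, thd)]
        counts = {name: 0 for name in FEATURE_NAMES}
        for r in reps:
            for name in r.selected_features:
                counts[name] += 1
        n = max(len(reps), 1)
        df = pd.DataFrame(
            {
                "feature": list(counts),
                "frequency_pct": [100.0 * c / n for c in counts.values()],
            }
        )
        return df.sort_values(
            ["frequency_pct", "feature"], ascending=[False, True]
        ).reset_index(drop=True)


def derive_rep_seed(seed: int, W: float, thd: float, repetition: int) -> int:
    """Deterministic per-repetition seed below 2^31."""
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(int(round(W * 10)), int(round(thd * 100)), repetition)
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_single_repetition(
    table: pd.DataFrame,
    task: str,
    repetition: int,
    seed: int,
) -> RepetitionResult:
    """Partition -> rank -> tune -> select -> refit -> test, once."""
    if task == "artifacts":
        plan = partition_leave_30pct_subjects(
            sorted(table["subject"].unique()), seed=seed, repetition=repetition
        )
        train, test = split_by_plan(table, plan, level="subject")
    else:
        plan = partition_recording_thirds(table, repetition)
        train, test = split_by_plan(table, plan, level="window")

    if train.empty or test.empty:
        raise ValidationError("empty train or test side after partition")

    ranking = chi2_rank(train)
    base = ranking.top(TOP_K)
    cfg = loso_grid_search(train, task, base)
    subset = forward_select(
        ranking, train,
        model_factory=lambda: RbfSvmClassifier(C=cfg.C, gamma=cfg.gamma),
    )
    clf = train_svm_rbf(train[subset.features], train["label"].to_numpy(), cfg)
    model = TrainedModel(config=cfg, selected_features=subset.features, classifier=clf)
    pred = model.predict(test)
    metrics = compute_metrics(test["label"].to_numpy(), pred)
    return RepetitionResult(
        repetition=repetition,
        metrics=metrics,
        config=cfg,
        selected_features=list(subset.features),
    )


def run_repeated_experiment(
    cohort: Cohort,
    task: str,
    W_list=(6,),
    thd_list=(0.2,),
    n_reps: int = 30,
    seed: int = 0,
    max_per_class: int | None = DEFAULT_MAX_PER_CLASS,
    features_by_W: dict[float, pd.DataFrame] | None = None,
) -> ExperimentResult:
    """The repeated-randomization experiment over a (W, Thd) grid.

    Failed repetitions (e.g. a partition segment losing a class) are
    recorded and skipped; more than 20% failures for a combination is an
    error.  ``features_by_W`` lets callers reuse label-free feature
    tables across tasks and thresholds.
    """
    results: dict[tuple[float, float], list[RepetitionResult]] = {}
    failures: dict[tuple[float, float], int] = {}
    features_by_W = dict(features_by_W or {})
    for W in W_list:
        if float(W) not in features_by_W:
            rec_ids = None
            if task == "apnea":
                rec_ids = [r.recording_id for r in cohort.by_scenario("breath_hold")]
            features_by_W[float(W)] = extract_cohort_features(
                cohort, float(W), recordings=rec_ids
            )
        for thd in thd_list:
            key = (float(W), float(thd))
            results[key] = []
            failures[key] = 0
            for rep in range(n_reps):
                rep_seed = derive_rep_seed(seed, W, thd, rep)
                try:
                    table = build_feature_table(
                        cohort, task, float(W), float(thd), seed=rep_seed,
                        features=features_by_W[float(W)],
                        max_per_class=max_per_class,
                    )
                    res = run_single_repetition(table, task, rep, rep_seed)
                except ValidationError as exc:
                    failures[key] += 1
                    logger.warning(
                        "repetition %d failed (task=%s W=%s Thd=%s): %s",
                        rep, task, W, thd, exc,
                    )
                    continue
                results[key].append(res)
            if failures[key] > 0.2 * n_reps:
                raise ValidationError(
                    f"more than 20% of repetitions failed for task={task}, "
                    f"W={W}, Thd={thd}"
                )
    return ExperimentResult(task=task, results=results, failures=failures)


def selection_frequency_report(
    result: ExperimentResult, W: float | None = None, thd: float | None = None
) -> pd.DataFrame:
    """51-row feature-selection frequency table, sorted descending.

    Defaults to the best (W, Thd) model of the experiment.
    """
    if W is None or thd is None:
        W, thd = result.best_model()
    return result.selection_frequencies(float(W), float(thd))


def write_experiment_outputs(result: ExperimentResult, out_dir) -> None:
    """Write metrics_by_model.csv, selection_frequency.csv, best_models.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.metric_table().to_csv(out / "metrics_by_model.csv", index=False)
    result.summary().to_csv(out / "metrics_summary.csv", index=False)
    selection_frequency_report(result).to_csv(
        out / "selection_frequency.csv", index=False
    )
    W, thd = result.best_model()
    summ = result.summary()
    best_row = summ[(summ["W"] == W) & (summ["Thd"] == thd)].iloc[0]
    with open(out / "best_models.json", "w") as fh:
        json.dump(
            {
                "task": result.task,
                "best_W": W,
                "best_Thd": thd,
                "criterion": "F1" if result.task == "apnea" else "ACC",
                "metrics_mean": {m: best_row[f"{m}_mean"] for m in METRIC_NAMES},
                "metrics_std": {m: best_row[f"{m}_std"] for m in METRIC_NAMES},
            },
            fh,
            indent=1,
        )
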