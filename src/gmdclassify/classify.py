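"""Repeated train/test-split classification of psychosis groups vs controls.

The engine draws, per iteration, a balanced training sample (default 88 cases
per group, the control draw shared across the scheme's three binary models),
fits one L2-penalized logistic model per psychosis group vs CON, and
evaluates on the full held-out complement: balanced accuracy on the model's
own group + controls, and psychosis-label ("transfer") rates on the other two
groups' held-out cases. Across iterations it forms equal-tail percentile
intervals (default level 99.17%) and tests them against nominal chance (50%).
A model is *specific* when its own group is classified above chance while
neither out-group transfer rate is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .masking import FeatureMatrix
from .synthetic import BIOTYPE_GROUPS, CONTROL_GROUP, DIAGNOSIS_GROUPS

SCHEME_GROUPS = {"biotype": BIOTYPE_GROUPS, "diagnosis": DIAGNOSIS_GROUPS}
SCHEME_COLUMNS = {"biotype": "biotype", "diagnosis": "diagnosis"}

#: Metric keys carried per model in reports.
OVERALL_BALANCED = "overall_balanced"
OVERALL_POOLED = "overall_pooled"
OWN_GROUP = "own_group"
CON_GROUP = "con"


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the repeated-split pipeline (defaults = study conditions)."""

    n_train_per_group: int = 88
    n_iterations: int = 1000
    ci_level: float = 0.9917
    chance_level: float = 0.5
    l2_cost: float = 1.0
    decision_threshold: float = 0.5
    master_seed: int = 0
    solver_tol: float = 1e-6
    collect_weights: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_train_per_group < 1:
            raise ValueError("n_train_per_group must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.l2_cost <= 0:
            raise ValueError("l2_cost must be positive")


@dataclass
class TrainedBinaryModel:
    """One fitted psychosis-group-vs-CON logistic model."""

    weights: np.ndarray
    intercept: float
    positive_class: str
    negative_class: str = CONTROL_GROUP

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.isfinite(self.weights).all() or not np.isfinite(self.intercept):
            raise ValueError("model parameters must be finite")


@dataclass
class SplitPlan:
    """Per-iteration train/test indices per group, reproducible from a seed."""

    iterations: list  # list of dict group -> (train_idx, test_idx)
    scheme: str
    master_seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


@dataclass
class IterationRecord:
    """All metrics of one iteration: per model, rates and subject evidence."""

    iteration: int
    metrics: dict  # model -> {sensitivity, specificity, balanced, pooled}
    outgroup_rates: dict  # model -> {other_group: rate}
    evidence: dict  # model -> pd.Series indexed by subject_id (all test cases)


@dataclass
class IntervalEntry:
    mean: float
    lo: float
    hi: float
    above_chance: bool

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "lo": self.lo,
            "hi": self.hi,
            "above_chance": self.above_chance,
        }


@dataclass
class ModelSummary:
    model: str
    entries: dict  # metric/out-group name -> IntervalEntry
    specific: bool


@dataclass
class SpecificityReport:
    scheme: str
    ci_level: float
    chance_level: float
    n_iterations: int
    models: dict  # model label -> ModelSummary

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "ci_level": self.ci_level,
            "chance_level": self.chance_level,
            "n_iterations": self.n_iterations,
            "models": {
                m: {
                    "specific": s.specific,
                    "entries": {k: e.as_dict() for k, e in s.entries.items()},
                }
                for m, s in self.models.items()
            },
        }


# ---------------------------------------------------------------------------
# split planning


def _iteration_rng(master_seed: int, iteration: int) -> np.random.Generator:
    """Documented counter scheme: stream i is seeded by [master_seed, 3, i]."""
    return np.random.default_rng([int(master_seed), 3, int(iteration)])


def plan_splits(
    subject_table: pd.DataFrame, scheme: str, config: PipelineConfig
) -> SplitPlan:
    """Draw per-iteration balanced training samples and complement test sets.

    Each in-scheme group (three psychosis groups plus CON) contributes exactly
    ``n_train_per_group`` training cases, sampled without replacement; every
    remaining subject of every group is a test case. The other labeling
    scheme plays no role in case selection.
    """
    if scheme not in SCHEME_GROUPS:
        raise ValueError(f"unknown scheme {scheme!r}")
    column = SCHEME_COLUMNS[scheme]
    groups = [*SCHEME_GROUPS[scheme], CONTROL_GROUP]
    group_indices = {}
    for g in groups:
        idx = np.flatnonzero((subject_table[column] == g).to_numpy())
        if len(idx) < config.n_train_per_group + 1:
            raise ValueError(
                f"group {g!r} has {len(idx)} subjects; needs more than "
                f"n_train_per_group={config.n_train_per_group} to leave test cases"
            )
        group_indices[g] = idx

    iterations = []
    for it in range(config.n_iterations):
        rng = _iteration_rng(config.master_seed, it)
        split = {}
        for g in groups:
            idx = group_indices[g]
            train = np.sort(rng.choice(idx, size=config.n_train_per_group, replace=False))
            test = np.setdiff1d(idx, train)
            split[g] = (train, test)
        iterations.append(split)
    return SplitPlan(iterations=iterations, scheme=scheme, master_seed=config.master_seed)


# ---------------------------------------------------------------------------
# model fitting and metrics


def train_binary_model(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    positive_class: str | None = None,
) -> TrainedBinaryModel:
    """Fit the L2-regularized logistic model (cost C, unpenalized intercept).

    Minimizes ``C * sum_i log(1 + exp(-y_i (w.x_i + b))) + ||w||^2 / 2`` with
    a deterministic quasi-Newton solver; the gradient norm at the solution is
    below the configured tolerance.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    if np.all(X == X.ravel()[0]):
        raise ValueError("degenerate features: all-constant training matrix")
    if positive_class is None:
        non_con = [c for c in classes if c != CONTROL_GROUP]
        positive_class = non_con[0] if non_con else classes[1]
    negative_class = [c for c in classes if c != positive_class][0]

    clf = LogisticRegression(
        C=config.l2_cost,
        solver="lbfgs",
        tol=config.solver_tol,
        max_iter=2000,
        fit_intercept=True,
    )
    clf.fit(X, (y == positive_class).astype(int))
    return TrainedBinaryModel(
        weights=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        positive_class=str(positive_class),
        negative_class=str(negative_class),
    )


def predict_evidence(model: TrainedBinaryModel, features: np.ndarray) -> np.ndarray:
    """Predicted probability of the psychosis (positive) class per subject."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model ({model.weights.shape[0]})"
        )
    return expit(X @ model.weights + model.intercept)


def balanced_accuracy(
    truth: np.ndarray, predicted_labels: np.ndarray, positive_class=None
) -> float:
    """(sensitivity + specificity) / 2 for a binary labeling."""
    truth = np.asarray(truth)
    pred = np.asarray(predicted_labels)
    if truth.shape != pred.shape:
        raise ValueError("truth and predictions must align")
    classes = np.unique(truth)
    if len(classes) != 2:
        raise ValueError("balanced accuracy needs both classes present in truth")
    if positive_class is None:
        non_con = [c for c in classes if c != CONTROL_GROUP]
        positive_class = non_con[0] if non_con else classes[1]
    pos = truth == positive_class
    sensitivity = float(np.mean(pred[pos] == truth[pos]))
    specificity = float(np.mean(pred[~pos] == truth[~pos]))
    return 0.5 * (sensitivity + specificity)


def outgroup_rate(
    model: TrainedBinaryModel,
    outgroup_features: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
) -> float:
    """Fraction of out-group cases the model labels as its psychosis group.

    Evidence exactly at the decision threshold counts as a control label (tie
    rule), so only strictly-greater evidence enters the numerator.
    """
    X = np.asarray(outgroup_features, dtype=float)
    if X.size == 0:
        raise ValueError("out-group feature matrix is empty")
    ev = predict_evidence(model, X)
    return float(np.mean(ev > config.decision_threshold))


def percentile_interval(values, level: float) -> tuple[float, float]:
    """Equal-tail empirical percentile interval with linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("percentile interval needs at least 2 values")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# full scheme run


def _evaluate_iteration(
    features: np.ndarray,
    labels: np.ndarray,
    subject_ids: np.ndarray,
    split: dict,
    model_groups: list,
    scheme_groups: list,
    config: PipelineConfig,
) -> tuple[IterationRecord, dict]:
    con_train, _ = split[CONTROL_GROUP]
    all_test = np.concatenate([split[g][1] for g in [*scheme_groups, CONTROL_GROUP]])
    metrics, rates, evidence, weights = {}, {}, {}, {}
    for g in model_groups:
        g_train, g_test = split[g]
        train_idx = np.concatenate([g_train, con_train])
        model = train_binary_model(
            features[train_idx],
            np.where(np.isin(train_idx, g_train), g, CONTROL_GROUP),
            config,
            positive_class=g,
        )
        ev_all = predict_evidence(model, features[all_test])
        ev = pd.Series(ev_all, index=subject_ids[all_test])
        psychosis_call = ev_all > config.decision_threshold

        pos_in_test = np.isin(all_test, g_test)
        con_in_test = np.isin(all_test, split[CONTROL_GROUP][1])
        sens = float(np.mean(psychosis_call[pos_in_test]))
        spec = float(np.mean(~psychosis_call[con_in_test]))
        n_pos, n_con = int(pos_in_test.sum()), int(con_in_test.sum())
        pooled = (sens * n_pos + spec * n_con) / (n_pos + n_con)
        metrics[g] = {
            "sensitivity": sens,
            "specificity": spec,
            "balanced": 0.5 * (sens + spec),
            "pooled": pooled,
        }
        rates[g] = {}
        for other in scheme_groups:
            if other == g:
                continue
            other_in_test = np.isin(all_test, split[other][1])
            rates[g][other] = float(np.mean(psychosis_call[other_in_test]))
        evidence[g] = ev
        if config.collect_weights:
            weights[g] = model.weights
    record = IterationRecord(
        iteration=-1, metrics=metrics, outgroup_rates=rates, evidence=evidence
    )
    return record, weights


def run_scheme(
    features: FeatureMatrix,
    subject_table: pd.DataFrame,
    scheme: str,
    config: PipelineConfig,
    groups: list | None = None,
) -> tuple[SpecificityReport, list, dict]:
    """Run the full repeated-split analysis for one categorization scheme.

    Returns ``(report, iteration_records, weights)`` where ``weights`` maps
    each model to an (n_iterations x n_voxels) array (empty dict when weight
    collection is disabled). ``groups`` restricts which binary models are fit
    (split planning always covers the whole scheme so draws are identical
    whether one or all models run).
    """
    if list(subject_table["subject_id"]) != list(features.subject_ids):
        raise ValueError("subject table and feature matrix must align by subject_id")
    plan = plan_splits(subject_table, scheme, config)
    scheme_groups = list(SCHEME_GROUPS[scheme])
    psych_groups = scheme_groups if groups is None else list(groups)
    labels = subject_table[SCHEME_COLUMNS[scheme]].to_numpy()
    subject_ids = subject_table["subject_id"].to_numpy()

    records: list[IterationRecord] = []
    weight_rows = {g: [] for g in psych_groups} if config.collect_weights else {}
    for it, split in enumerate(plan.iterations):
        record, weights = _evaluate_iteration(
            features.values, labels, subject_ids, split, psych_groups, scheme_groups, config
        )
        record.iteration = it
        records.append(record)
        for g, w in weights.items():
            weight_rows[g].append(w)

    report = summarize_records(records, scheme, config, psych_groups)
    weights_out = {g: np.asarray(rows) for g, rows in weight_rows.items()}
    return report, records, weights_out


def summarize_records(
    records: list,
    scheme: str,
    config: PipelineConfig,
    psych_groups: list | None = None,
) -> SpecificityReport:
    """Aggregate iteration records into interval summaries and verdicts."""
    if psych_groups is None:
        psych_groups = list(records[0].metrics.keys())

    def entry(values) -> IntervalEntry:
        lo, hi = percentile_interval(values, config.ci_level)
        return IntervalEntry(
            mean=float(np.mean(values)),
            lo=lo,
            hi=hi,
            above_chance=bool(lo > config.chance_level),
        )

    models = {}
    for g in psych_groups:
        entries = {
            OVERALL_BALANCED: entry([r.metrics[g]["balanced"] for r in records]),
            OVERALL_POOLED: entry([r.metrics[g]["pooled"] for r in records]),
            OWN_GROUP: entry([r.metrics[g]["sensitivity"] for r in records]),
            CON_GROUP: entry([r.metrics[g]["specificity"] for r in records]),
        }
        for other in records[0].outgroup_rates[g]:
            entries[f"transfer_{other}"] = entry(
                [r.outgroup_rates[g][other] for r in records]
            )
        specific = assess_specificity(
            entries[OWN_GROUP],
            {k: v for k, v in entries.items() if k.startswith("transfer_")},
        )
        models[g] = ModelSummary(model=g, entries=entries, specific=specific)
    return SpecificityReport(
        scheme=scheme,
        ci_level=config.ci_level,
        chance_level=config.chance_level,
        n_iterations=len(records),
        models=models,
    )


def assess_specificity(own_group: IntervalEntry, outgroups: dict) -> bool:
    """Specific iff own-group accuracy is above chance and no transfer rate is."""
    if own_group is None or not outgroups:
        raise ValueError("own-group and out-group interval entries are required")
    if not own_group.above_chance:
        return False
    return not any(e.above_chance for e in outgroups.values())


# ---------------------------------------------------------------------------
# tabular export


def evidence_table(records: list) -> pd.DataFrame:
    """Long table (iteration, model, subject_id, evidence) over all records."""
    rows = []
    for r in records:
        for model, series in r.evidence.items():
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": r.iteration,
                        "model": model,
                        "subject_id": series.index,
                        "evidence": series.to_numpy(),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def metrics_table(records: list) -> pd.DataFrame:
    """Long table (iteration, model, metric, value) of accuracies and rates."""
    rows = []
    for r in records:
        for model, m in r.metrics.items():
            for metric, value in m.items():
                rows.append((r.iteration, model, metric, value))
            for other, rate in r.outgroup_rates[model].items():
                rows.append((r.iteration, model, f"transfer_{other}", rate))
    return pd.DataFrame(rows, columns=["iteration", "model", "metric", "value"])
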