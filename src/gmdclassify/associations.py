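"""Brain-behavior association stage: evidence-by-group interaction regressions.

For each clinical/biomarker outcome and each repeated-split iteration, an OLS
regression predicts the outcome from seven terms: the (mean-centered) B1-model
classifier evidence over the iteration's full test sample, three dummy-coded
group indicators against the CON reference, and the three evidence-by-group
interactions. The per-term unstandardized coefficients are collected across
iterations; a term is flagged significant when the equal-tail 95% percentile
interval of its coefficients excludes zero. A significant evidence main
effect with non-significant interactions is the signature of a group-invariant
brain-behavior link.

Multi-measure inputs (eye-movement, EEG panels) are reduced beforehand by a
PCA of their correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import percentile_interval
from .synthetic import BIOTYPE_GROUPS, CONTROL_GROUP

DESIGN_COLUMNS = (
    "intercept",
    "evidence",
    "d_B1",
    "d_B2",
    "d_B3",
    "evidence_x_B1",
    "evidence_x_B2",
    "evidence_x_B3",
)


@dataclass(frozen=True)
class RegressionSpec:
    """Layout of the 7-predictor interaction regression."""

    reference_group: str = CONTROL_GROUP
    groups: tuple = BIOTYPE_GROUPS
    interval_level: float = 0.95
    standardize_outcomes: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.interval_level < 1.0):
            raise ValueError("interval_level must lie in (0, 1)")

    @property
    def column_names(self) -> tuple:
        names = ["intercept", "evidence"]
        names += [f"d_{g}" for g in self.groups]
        names += [f"evidence_x_{g}" for g in self.groups]
        return tuple(names)


@dataclass
class AssociationSummary:
    """Per outcome x term coefficient intervals across iterations."""

    table: pd.DataFrame  # columns: outcome, term, mean, lo, hi, significant
    interval_level: float
    n_iterations: int

    def significant_terms(self, outcome: str) -> list:
        t = self.table
        sel = t[(t["outcome"] == outcome) & t["significant"]]
        return list(sel["term"])

    def coefficient(self, outcome: str, term: str) -> pd.Series:
        t = self.table
        row = t[(t["outcome"] == outcome) & (t["term"] == term)]
        if len(row) != 1:
            raise KeyError((outcome, term))
        return row.iloc[0]


# ---------------------------------------------------------------------------
# PCA reduction


def reduce_pca(measures, n_components: int):
    """Correlation-matrix PCA of a multi-measure panel.

    Rows with any missing value are excluded before fitting; their scores are
    NaN. Inputs are z-scored, components ordered by decreasing eigenvalue,
    and each component's sign is fixed so that its largest-|loading| measure
    loads positively. Returns ``(scores, loadings, explained_ratio)`` with
    ``scores`` an (n_rows x n_components) array and ``loadings`` the
    (n_measures x n_components) eigenvector matrix.
    """
    X = np.asarray(measures, dtype=float)
    if X.ndim != 2:
        raise ValueError("measure matrix must be 2D")
    n_measures = X.shape[1]
    if n_components > n_measures:
        raise ValueError("n_components exceeds the number of measures")
    complete = ~np.isnan(X).any(axis=1)
    Xc = X[complete]
    if Xc.shape[0] < 2:
        raise ValueError("need at least 2 complete rows for PCA")
    mean = Xc.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant measure column; correlation PCA undefined")
    Z = (Xc - mean) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    rank = int(np.sum(eigval > 1e-10))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    loadings = eigvec[:, :n_components]
    for k in range(n_components):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = np.full((X.shape[0], n_components), np.nan)
    scores[complete] = Z @ loadings
    explained = eigval[:n_components] / eigval.sum()
    return scores, loadings, explained


# ---------------------------------------------------------------------------
# design and fit


def build_design(evidence, groups, spec: RegressionSpec = RegressionSpec()):
    """Assemble the interaction design matrix for one regression.

    ``evidence`` is centered on its mean over the supplied rows (callers do
    listwise deletion first, so the centering mean is the analysis-sample
    mean). Reference-group rows carry zeros in all dummy and interaction
    columns. Returns ``(X, column_names)``.
    """
    ev = np.asarray(evidence, dtype=float)
    groups = np.asarray(groups)
    if ev.shape[0] != groups.shape[0]:
        raise ValueError("evidence and groups must align")
    known = set(spec.groups) | {spec.reference_group}
    unknown = sorted(set(groups) - known)
    if unknown:
        raise ValueError(f"unknown group labels: {unknown}")
    centered = ev - ev.mean()
    cols = [np.ones_like(centered), centered]
    for g in spec.groups:
        cols.append((groups == g).astype(float))
    for g in spec.groups:
        cols.append(centered * (groups == g))
    return np.column_stack(cols), spec.column_names


def fit_ols(design: np.ndarray, outcome: np.ndarray) -> np.ndarray:
    """Least-squares coefficients from the normal equations."""
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and outcome must align")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} columns)"
        )
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    return b


# ---------------------------------------------------------------------------
# iteration loop


def run_associations(
    evidence: pd.DataFrame,
    clinical: pd.DataFrame,
    spec: RegressionSpec = RegressionSpec(),
    model: str = "B1",
    outcomes: list | None = None,
    group_column: str = "biotype",
) -> AssociationSummary:
    """Regress each outcome on classifier evidence, per iteration, and pool.

    ``evidence`` is the long table produced by the classification stage
    (columns: iteration, model, subject_id, evidence); ``clinical`` carries
    subject_id, the group label column and outcome columns. Missing outcome
    values are removed listwise per outcome per iteration; evidence centering
    happens after deletion inside :func:`build_design`.
    """
    ev = evidence[evidence["model"] == model]
    if ev.empty:
        raise ValueError(f"no evidence rows for model {model!r}")
    if outcomes is None:
        reserved = {"subject_id", group_column, "biotype", "diagnosis"}
        outcomes = [c for c in clinical.columns if c not in reserved]
    clin = clinical.set_index("subject_id")
    for outcome in outcomes:
        present = clin.groupby(group_column)[outcome].apply(lambda s: s.notna().any())
        if not present.all():
            empty = list(present.index[~present])
            raise ValueError(f"outcome {outcome!r} entirely missing for groups {empty}")

    if spec.standardize_outcomes:
        clin = clin.copy()
        for outcome in outcomes:
            col = clin[outcome]
            clin[outcome] = (col - col.mean()) / col.std(ddof=1)

    coeffs: dict = {o: [] for o in outcomes}
    for _, ev_it in ev.groupby("iteration", sort=True):
        sub = clin.loc[ev_it["subject_id"]]
        groups = sub[group_column].to_numpy()
        ev_values = ev_it["evidence"].to_numpy()
        for outcome in outcomes:
            y = sub[outcome].to_numpy(dtype=float)
            keep = ~np.isnan(y)
            X, names = build_design(ev_values[keep], groups[keep], spec)
            coeffs[outcome].append(fit_ols(X, y[keep]))

    rows = []
    n_iter = len(next(iter(coeffs.values())))
    for outcome in outcomes:
        B = np.asarray(coeffs[outcome])
        for j, term in enumerate(spec.column_names):
            vals = B[:, j]
            if n_iter >= 2:
                lo, hi = percentile_interval(vals, spec.interval_level)
            else:
                lo = hi = float(vals[0])
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "mean": float(vals.mean()),
                    "lo": lo,
                    "hi": hi,
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
    return AssociationSummary(
        table=pd.DataFrame(rows), interval_level=spec.interval_level, n_iterations=n_iter
    )
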