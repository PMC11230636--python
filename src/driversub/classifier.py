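"""Subtype classification panel and evaluation.

Panel selection proceeds in three nested stages: (1) differential
expression between the subtypes at strict thresholds (BH-adjusted
p < 0.001, |log2FC| > 1); (2) a mean-interval filter keeping only genes
whose per-subtype intervals [mu - sigma, mu + sigma] are disjoint
(sample sd, closed intervals — a shared endpoint counts as overlap);
(3) elastic-net-regularized logistic regression over a cross-validated
regularization path, the panel being the genes with nonzero coefficients.
The panel then feeds a maximum-margin classifier (soft-margin SVM by
default) trained on a stratified 70/30 split with grid-searched
hyperparameters and evaluated with ACC, SEN, SPE and MCC:

    ACC = (TP+TN)/(TP+TN+FP+FN)   SEN = TP/(TP+FN)   SPE = TN/(TN+FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

The positive class is the last subtype in sorted label order (CLASS B for
a two-class run). MCC is reported on its natural [-1, 1] scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import ddg as _ddg
from .types import OmicsMatrix

logger = logging.getLogger(__name__)

PANEL_P_CUT = 1e-3
PANEL_FC_CUT = 1.0
TRAIN_FRAC = 0.7
DEFAULT_C_GRID = (100.0, 10.0, 1.0, 0.1, 0.01)
DEFAULT_SVM_GRID = {"C": [0.1, 1.0, 10.0, 100.0]}


@dataclass
class ClassifierMetrics:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def acc(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")

    @property
    def sen(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def spe(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def mcc(self) -> float:
        denom = (
            (self.tp + self.fn)
            * (self.tn + self.fp)
            * (self.tp + self.fp)
            * (self.tn + self.fn)
        )
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / np.sqrt(denom)

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ClassifierMetrics":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "TN": self.tn,
            "FP": self.fp,
            "FN": self.fn,
            "ACC": self.acc,
            "SEN": self.sen,
            "SPE": self.spe,
            "MCC": self.mcc,
        }


def _split_groups(expr: pd.DataFrame, assignment: pd.Series):
    samples = [s for s in expr.columns if s in assignment.index]
    labels = assignment.loc[samples]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two subtypes required, got {groups}")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"subtype {g} has fewer than 2 samples")
    return samples, labels, groups


def select_candidates(
    expr_tpm: OmicsMatrix,
    assignment: pd.Series,
    p_cut: float = PANEL_P_CUT,
    fc_cut: float = PANEL_FC_CUT,
) -> list[str]:
    """Differentially expressed genes between the two subtypes at the
    stricter classifier thresholds (reuses the tumor/normal DE machinery)."""
    samples, labels, groups = _split_groups(expr_tpm.data, assignment)
    g0 = [s for s in samples if labels[s] == groups[0]]
    g1 = [s for s in samples if labels[s] == groups[1]]
    res = _ddg.differential_expression(
        OmicsMatrix("mrna_tpm", expr_tpm.data[g1]),
        OmicsMatrix("mrna_tpm", expr_tpm.data[g0]),
        fc_cut=fc_cut,
        p_cut=p_cut,
    )
    return [r.gene_id for r in res if r.is_deg]


def subtype_mean_intervals(
    log_expr: pd.DataFrame, labels: pd.Series, groups: Sequence[str]
) -> dict:
    """Per-gene, per-subtype (mu, sigma) with sample sd (ddof=1)."""
    out = {}
    for gene in log_expr.index:
        per = {}
        for g in groups:
            vals = log_expr.loc[gene, labels.index[labels == g]].to_numpy(dtype=float)
            per[g] = (float(vals.mean()), float(vals.std(ddof=1)))
        out[gene] = per
    return out


def mean_interval_filter(
    expr_tpm: OmicsMatrix, assignment: pd.Series, candidates: Sequence[str]
) -> list[str]:
    """Keep candidates whose subtype intervals [mu - sigma, mu + sigma] are
    disjoint (computed on log2(x+1) expression; closed intervals, so a
    shared endpoint counts as overlap)."""
    if not candidates:
        raise ValueError("no candidate genes to filter")
    samples, labels, groups = _split_groups(expr_tpm.data, assignment)
    log_expr = np.log2(expr_tpm.data.loc[list(candidates), samples] + 1.0)
    intervals = subtype_mean_intervals(log_expr, labels, groups)
    kept = []
    for gene in candidates:
        (m0, s0), (m1, s1) = intervals[gene][groups[0]], intervals[gene][groups[1]]
        lo0, hi0 = m0 - s0, m0 + s0
        lo1, hi1 = m1 - s1, m1 + s1
        if hi0 < lo1 or hi1 < lo0:  # strictly disjoint closed intervals
            kept.append(gene)
    return kept


def sparse_panel_selection(
    expr_tpm: OmicsMatrix,
    assignment: pd.Series,
    interval_pass: Sequence[str],
    l1_ratio: float = 0.5,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    cv: int = 5,
    seed: int = 0,
) -> list[str]:
    """Elastic-net logistic regression panel over a regularization path.

    The inverse penalty C is chosen by stratified cross-validated accuracy;
    ties go to the least-regularized C (the elastic net's grouping effect
    then keeps correlated informative genes together). Panel = genes with
    nonzero coefficients; if every C zeroes all coefficients the full
    interval-pass set is returned with a warning.
    """
    if len(interval_pass) < 2:
        raise ValueError("need at least 2 interval-pass genes")
    samples, labels, groups = _split_groups(expr_tpm.data, assignment)
    x = np.log2(expr_tpm.data.loc[list(interval_pass), samples].T + 1.0).to_numpy()
    x = StandardScaler().fit_transform(x)
    y = (labels.loc[samples] == groups[1]).to_numpy().astype(int)
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    best_c, best_score = None, -np.inf
    for c in sorted(c_grid, reverse=True):  # largest C first: ties keep it
        model = LogisticRegression(
            solver="saga", l1_ratio=l1_ratio, C=c, max_iter=5000, random_state=seed
        )
        score = cross_val_score(model, x, y, cv=skf, scoring="accuracy").mean()
        if score > best_score:
            best_score, best_c = score, c
    final = LogisticRegression(
        solver="saga", l1_ratio=l1_ratio, C=best_c, max_iter=5000, random_state=seed
    ).fit(x, y)
    nonzero = np.flatnonzero(np.abs(final.coef_[0]) > 0)
    if nonzero.size == 0:
        logger.warning("elastic net zeroed every coefficient; panel falls back to "
                       "the full interval-pass set")
        return list(interval_pass)
    return [interval_pass[i] for i in nonzero]


@dataclass
class SubtypeClassifier:
    """Trained subtype model: panel genes, training-set standardization and
    the fitted maximum-margin backend."""

    panel_genes: list
    scaler: StandardScaler
    model: object
    groups: list  # [negative, positive] label names
    intervals: dict = field(default_factory=dict)

    def _transform(self, expr: pd.DataFrame) -> np.ndarray:
        missing = [g for g in self.panel_genes if g not in expr.index]
        if missing:
            raise ValueError(f"profiles missing panel gene(s): {', '.join(missing)}")
        x = np.log2(expr.loc[self.panel_genes].T.to_numpy(dtype=float) + 1.0)
        return self.scaler.transform(x)

    def predict(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Labels and continuous decision scores for feature x sample profiles."""
        x = self._transform(expr)
        pred = self.model.predict(x)
        score = self.model.decision_function(x)
        labels = [self.groups[int(p)] for p in pred]
        return pd.DataFrame(
            {"sample_id": list(expr.columns), "label": labels, "score": score}
        )


def train_and_evaluate(
    expr_tpm: OmicsMatrix,
    assignment: pd.Series,
    panel: Sequence[str],
    train_frac: float = TRAIN_FRAC,
    seed: int = 0,
    backend: Optional[object] = None,
    param_grid: Optional[dict] = None,
    cv: int = 5,
):
    """Train the panel classifier on a stratified split and evaluate held-out.

    Hyperparameters are grid-searched with stratified CV on the training
    split only; the held-out fraction (1 - train_frac) yields the
    ClassifierMetrics. Returns ``(SubtypeClassifier, ClassifierMetrics,
    held_out_predictions)``.
    """
    if not panel:
        raise ValueError("empty panel")
    samples, labels, groups = _split_groups(expr_tpm.data, assignment)
    x_all = np.log2(expr_tpm.data.loc[list(panel), samples].T.to_numpy(dtype=float) + 1.0)
    y_all = (labels.loc[samples] == groups[1]).to_numpy().astype(int)
    idx = np.arange(len(samples))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_frac, stratify=y_all, random_state=seed
    )
    if len(np.unique(y_all[train_idx])) < 2:
        raise ValueError("a class is absent from the training split")
    scaler = StandardScaler().fit(x_all[train_idx])
    x_train = scaler.transform(x_all[train_idx])
    x_test = scaler.transform(x_all[test_idx])
    if backend is None:
        backend = SVC(kernel="linear")
    grid = param_grid if param_grid is not None else DEFAULT_SVM_GRID
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    search = GridSearchCV(backend, grid, cv=skf, scoring="accuracy")
    search.fit(x_train, y_all[train_idx])
    model = search.best_estimator_

    log_expr = np.log2(expr_tpm.data.loc[list(panel), samples] + 1.0)
    clf = SubtypeClassifier(
        panel_genes=list(panel),
        scaler=scaler,
        model=model,
        groups=list(groups),
        intervals=subtype_mean_intervals(log_expr, labels, groups),
    )
    y_pred = model.predict(x_test)
    metrics = ClassifierMetrics.from_predictions(y_all[test_idx], y_pred, positive=1)
    held_out = pd.DataFrame(
        {
            "sample_id": [samples[i] for i in test_idx],
            "true": [groups[v] for v in y_all[test_idx]],
            "predicted": [groups[v] for v in y_pred],
            "score": model.decision_function(x_test),
        }
    )
    return clf, metrics, held_out


def build_panel_and_classifier(
    expr_tpm: OmicsMatrix,
    assignment: pd.Series,
    p_cut: float = PANEL_P_CUT,
    fc_cut: float = PANEL_FC_CUT,
    l1_ratio: float = 0.5,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    train_frac: float = TRAIN_FRAC,
    seed: int = 0,
):
    """Candidates -> interval filter -> sparse panel -> trained classifier.

    Returns ``(selection_dict, classifier, metrics)`` where the selection
    dict records the nested gene lists (panel <= interval_pass <=
    candidates, asserted).
    """
    candidates = select_candidates(expr_tpm, assignment, p_cut=p_cut, fc_cut=fc_cut)
    if not candidates:
        raise ValueError("no candidate genes passed the differential filter")
    interval_pass = mean_interval_filter(expr_tpm, assignment, candidates)
    if len(interval_pass) < 2:
        logger.warning("interval filter left %d gene(s); using candidates", len(interval_pass))
        interval_pass = candidates
    panel = sparse_panel_selection(
        expr_tpm, assignment, interval_pass, l1_ratio=l1_ratio, c_grid=c_grid, seed=seed
    )
    assert set(panel) <= set(interval_pass) <= set(candidates)
    clf, metrics, held_out = train_and_evaluate(
        expr_tpm, assignment, panel, train_frac=train_frac, seed=seed
    )
    selection = {
        "candidate_genes": candidates,
        "interval_pass_genes": interval_pass,
        "panel_genes": panel,
    }
    return selection, clf, metrics, held_out


def predict_subtype(clf: SubtypeClassifier, expr: pd.DataFrame) -> pd.DataFrame:
    """Apply a trained classifier to new feature x sample expression profiles."""
    return clf.predict(expr)


def pseudobulk(cell_by_gene: pd.DataFrame, cell_to_sample: Mapping[str, str]) -> pd.DataFrame:
    """Per-sample pseudo-bulk: sum single-cell expression across each
    sample's cells. Returns a gene x sample matrix."""
    unmapped = [c for c in cell_by_gene.index if c not in cell_to_sample]
    if unmapped:
        raise ValueError(f"unmapped cell(s): {', '.join(map(str, unmapped[:5]))}")
    groups = pd.Series({c: cell_to_sample[c] for c in cell_by_gene.index})
    bulk = cell_by_gene.groupby(groups).sum()
    return bulk.T.sort_index(axis=1)
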