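"""Validation protocols and classification metrics.

Three protocols evaluate the base models and their ensemble:

- SCT  (self-consistency): train and evaluate on the full dataset — an
  overfitting/memorization diagnostic, not a generalization claim;
- IST  (independent set): one stratified, seeded 80/20 split;
- 10-FCVT: stratified 10-fold cross-validation, per-fold metrics plus their
  mean.

Metrics follow the standard confusion-matrix formulas with the mutated
class positive:

    Sn  = TP / (TP + FN)                 (sensitivity / recall)
    Sp  = TN / (TN + FP)                 (specificity)
    Acc = (TP + TN) / (TP + FP + FN + TN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A zero factor in the MCC denominator yields MCC = 0 with a ``degenerate``
flag.  ROC curves and AUC come from sklearn (trapezoidal rule over distinct
score thresholds); the test suite cross-checks AUC against an independent
pairwise-comparison estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .datagen import LabeledDataset
from .ensemble import DECISION_THRESHOLD, derive_weights, ensemble_scores
from .errors import ParameterError, StratificationError
from .features import HahnParams, MomentFeaturizer
from .models import (
    MODEL_NAMES,
    ModelSpec,
    build_estimator,
    default_spec,
    tokens_from_sequences,
)

PROTOCOLS = ("SCT", "IST", "10-FCVT")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = mutated."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Metrics of one model under one protocol (optionally one fold)."""

    model: str
    protocol: str
    acc: float
    sn: float
    sp: float
    mcc: float
    auc: float | None = None
    cm: ConfusionMatrix | None = None
    degenerate_mcc: bool = False
    fold: int | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "protocol": self.protocol,
            "acc": self.acc,
            "sn": self.sn,
            "sp": self.sp,
            "mcc": self.mcc,
            "auc": self.auc,
            "degenerate_mcc": self.degenerate_mcc,
        }
        if self.fold is not None:
            d["fold"] = self.fold
        if self.cm is not None:
            d["confusion"] = {
                "tp": self.cm.tp, "tn": self.cm.tn,
                "fp": self.cm.fp, "fn": self.cm.fn,
            }
        return d


def confusion_matrix(truth, predicted) -> ConfusionMatrix:
    """Count agreement between binary truth and predictions (positive = 1)."""
    t = np.asarray(truth).astype(np.int64)
    p = np.asarray(predicted).astype(np.int64)
    if t.shape != p.shape:
        raise ParameterError(f"length mismatch: truth {t.shape} vs pred {p.shape}")
    return ConfusionMatrix(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def classification_metrics(
    cm: ConfusionMatrix, model: str = "", protocol: str = ""
) -> MetricsReport:
    """Acc/Sn/Sp/MCC from a confusion matrix, by the formulas above.

    Sn (resp. Sp) is reported as 0 when no positives (negatives) were
    evaluated; a zero MCC denominator factor yields MCC = 0 with the
    ``degenerate_mcc`` flag set.
    """
    if cm.total == 0:
        raise ParameterError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    acc = (tp + tn) / cm.total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsReport(
        model=model, protocol=protocol,
        acc=acc, sn=sn, sp=sp, mcc=mcc, cm=cm, degenerate_mcc=degenerate,
    )


def roc_auc(truth, scores) -> tuple[np.ndarray, float]:
    """ROC points (fpr, tpr) at every distinct threshold and trapezoidal AUC."""
    t = np.asarray(truth).astype(np.int64)
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ParameterError("truth and scores differ in length")
    if len(np.unique(t)) < 2:
        raise ParameterError("AUC undefined: truth contains a single class")
    fpr, tpr, _ = roc_curve(t, s)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def stratified_folds(y, k: int, seed: int) -> np.ndarray:
    """Per-sample fold index in [0, k), stratified by class, seeded.

    Folds partition the data with sizes differing by at most one and
    per-fold class ratios within one sample of the global ratio (the
    StratifiedKFold contract).  A fold missing a class raises.
    """
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.full(len(y), -1, dtype=np.int64)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[val_idx] = fold
        if len(np.unique(y[val_idx])) < 2:
            raise StratificationError(f"fold {fold} lost a class")
    return assignment


# ---------------------------------------------------------------------------
# Protocol runner


@dataclass
class ProtocolResult:
    """All reports of one protocol run (base models + ensemble)."""

    protocol: str
    seed: int
    reports: list[MetricsReport]
    per_fold: list[MetricsReport] = field(default_factory=list)
    weights: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)  # model -> [[fpr, tpr], ...]

    def report(self, model: str) -> MetricsReport:
        for r in self.reports:
            if r.model == model:
                return r
        raise KeyError(model)


def _fit_and_score(specs, X_train, y_train, X_eval, epochs=None):
    """Fit every base spec on the training portion; score train and eval."""
    fitted, train_scores, eval_scores = [], [], []
    for spec in specs:
        overrides = {} if epochs is None else {"epochs": epochs}
        est = build_estimator(spec, **overrides)
        est.fit(X_train, y_train)
        fitted.append(est)
        train_scores.append(est.predict_scores(X_train))
        eval_scores.append(est.predict_scores(X_eval))
    return fitted, train_scores, eval_scores


def _evaluate_split(specs, X_train, y_train, X_eval, y_eval, protocol,
                    epochs=None, fold=None):
    """Reports for the three base models and the EDLM on one train/eval split.

    Ensemble weights are proportional to each base model's accuracy on the
    *training* portion (training-data-only rule; for SCT the training
    portion is the full set).
    """
    _, train_scores, eval_scores = _fit_and_score(
        specs, X_train, y_train, X_eval, epochs
    )
    train_accs = [
        float((((s >= DECISION_THRESHOLD).astype(int)) == y_train).mean())
        for s in train_scores
    ]
    weights = derive_weights(train_accs)
    reports, rocs = [], {}
    for spec, scores in zip(specs, eval_scores):
        cm = confusion_matrix(y_eval, (scores >= DECISION_THRESHOLD).astype(int))
        rep = classification_metrics(cm, model=spec.name, protocol=protocol)
        points, rep.auc = roc_auc(y_eval, scores)
        rep.fold = fold
        rocs[spec.name] = points
        reports.append(rep)
    pred = ensemble_scores(eval_scores, weights)
    cm = confusion_matrix(y_eval, pred.labels)
    rep = classification_metrics(cm, model="EDLM", protocol=protocol)
    points, rep.auc = roc_auc(y_eval, pred.scores)
    rep.fold = fold
    rocs["EDLM"] = points
    reports.append(rep)
    return reports, weights, rocs


def run_protocol(
    protocol: str,
    dataset: LabeledDataset,
    specs: Sequence[ModelSpec] | None = None,
    seed: int = 0,
    hahn_params: HahnParams = HahnParams(),
    epochs: int | None = None,
    test_fraction: float = 0.2,
    n_folds: int = 10,
) -> ProtocolResult:
    """Run one validation protocol over a labeled dataset.

    Features are extracted once (they are label- and fold-independent); all
    label-dependent fitting — feature standardization inside each estimator,
    model weights, ensemble weights — uses only the training portion of each
    split or fold.  Identical arguments yield identical results.
    """
    if protocol not in PROTOCOLS:
        raise ParameterError(f"unknown protocol {protocol!r}; expected {PROTOCOLS}")
    if specs is None:
        specs = [default_spec(name, seed=seed + i) for i, name in enumerate(MODEL_NAMES)]
    y = dataset.labels()
    if len(np.unique(y)) < 2:
        raise StratificationError("dataset must contain both classes")

    token_mode = any(s.input_mode == "token_sequence" for s in specs)
    if token_mode:
        X = tokens_from_sequences(dataset.sequences, specs[0].fixed_length)
    else:
        X = MomentFeaturizer(hahn_params.a, hahn_params.b).fit_transform(
            dataset.sequences
        )

    if protocol == "SCT":
        reports, weights, rocs = _evaluate_split(
            specs, X, y, X, y, protocol, epochs=epochs
        )
        return ProtocolResult(
            protocol, seed, reports,
            weights={"all": list(weights.w)}, roc={k: v.tolist() for k, v in rocs.items()},
        )

    if protocol == "IST":
        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, test_size=test_fraction, stratify=y, random_state=seed
        )
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            raise StratificationError("80/20 split lost a class")
        reports, weights, rocs = _evaluate_split(
            specs, X[train_idx], y[train_idx], X[test_idx], y[test_idx],
            protocol, epochs=epochs,
        )
        return ProtocolResult(
            protocol, seed, reports,
            weights={"all": list(weights.w)}, roc={k: v.tolist() for k, v in rocs.items()},
        )

    # 10-FCVT
    assignment = stratified_folds(y, n_folds, seed)
    per_fold: list[MetricsReport] = []
    fold_weights: dict = {}
    for fold in range(n_folds):
        val = assignment == fold
        train = ~val
        reports, weights, _ = _evaluate_split(
            specs, X[train], y[train], X[val], y[val],
            protocol, epochs=epochs, fold=fold,
        )
        per_fold.extend(reports)
        fold_weights[str(fold)] = list(weights.w)
    mean_reports = []
    model_names = [s.name for s in specs] + ["EDLM"]
    for name in model_names:
        rs = [r for r in per_fold if r.model == name]
        mean_reports.append(
            MetricsReport(
                model=name, protocol=protocol,
                acc=float(np.mean([r.acc for r in rs])),
                sn=float(np.mean([r.sn for r in rs])),
                sp=float(np.mean([r.sp for r in rs])),
                mcc=float(np.mean([r.mcc for r in rs])),
                auc=float(np.mean([r.auc for r in rs])),
            )
        )
    return ProtocolResult(protocol, seed, mean_reports, per_fold=per_fold,
                          weights=fold_weights)
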