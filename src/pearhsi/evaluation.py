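"""Quality indices, regression/classification metrics and cross-validation.

The composite maturity index is the firmness to soluble-solids ratio

    FSR = FI / SSC

with FI in newtons and SSC in percent.  Regression models are scored by
R^2 = 1 - SS_res/SS_tot, RMSE, and the residual prediction deviation
RPD = SD(y_ref)/RMSE.  With the population SD convention (divide by n,
the same variance entering SS_tot) the identity RPD = 1/sqrt(1 - R^2)
holds exactly; an RPD above 2.5 conventionally signals a reliable model.
Classification uses a leakage-free stratified five-fold protocol: every
preprocessing step (scaling, feature elimination) is fitted on each fold's
training portion only, and accuracy/precision/recall/F1 are computed from
the predictions aggregated across folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .baselines import BaselineSpec, fit_baseline
from .errors import ContractError
from .table import STAGES, SpectrumTable

__all__ = [
    "QualityRecord",
    "RegressionReport",
    "ClassificationReport",
    "FoldScheme",
    "fsr",
    "regression_report",
    "percent_change",
    "stage_summary",
    "make_folds",
    "crossval_classify",
]


@dataclass(frozen=True)
class QualityRecord:
    """Per-fruit reference values: FI (N), SSC (%), FSR, maturity stage."""

    FI: float
    SSC: float
    FSR: float
    stage: str

    def __post_init__(self) -> None:
        if self.FI <= 0 or self.SSC <= 0:
            raise ContractError("FI and SSC must be positive")
        if abs(self.FSR - self.FI / self.SSC) > 1e-9:
            raise ContractError("FSR must equal FI/SSC")
        if self.stage not in STAGES:
            raise ContractError(f"unknown stage {self.stage!r}")


def fsr(FI: float | np.ndarray, SSC: float | np.ndarray) -> float | np.ndarray:
    """Firmness to soluble-solids ratio FI/SSC (dimensionless)."""
    SSC_arr = np.asarray(SSC, dtype=float)
    if np.any(SSC_arr <= 0):
        raise ContractError("SSC must be positive")
    out = np.asarray(FI, dtype=float) / SSC_arr
    return float(out) if out.ndim == 0 else out


@dataclass
class RegressionReport:
    set_id: str
    r2: float
    rmse: float
    rpd: float
    n: int
    rpd_overflow: bool = False

    def to_dict(self) -> dict:
        return {
            "set": self.set_id,
            "R2": self.r2,
            "RMSE": self.rmse,
            "RPD": None if self.rpd_overflow else self.rpd,
            "RPD_overflow": self.rpd_overflow,
            "n": self.n,
        }


def regression_report(y_ref, y_pred, set_id: str = "prediction",
                      sd_convention: str = "population") -> RegressionReport:
    """R^2, RMSE and RPD for one evaluation set.

    ``sd_convention='population'`` (default) divides the reference variance by
    n so that RPD = 1/sqrt(1 - R^2) exactly; ``'sample'`` uses n-1.
    """
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_ref) != len(y_pred):
        raise ContractError("reference and prediction lengths differ")
    if len(y_ref) < 2:
        raise ContractError("need at least 2 samples")
    ss_tot = float(np.sum((y_ref - y_ref.mean()) ** 2))
    if ss_tot == 0:
        raise ContractError("reference values have zero variance")
    ss_res = float(np.sum((y_ref - y_pred) ** 2))
    rmse = math.sqrt(ss_res / len(y_ref))
    r2 = 1.0 - ss_res / ss_tot
    ddof = 0 if sd_convention == "population" else 1
    sd = float(np.std(y_ref, ddof=ddof))
    overflow = rmse == 0.0
    rpd = math.inf if overflow else sd / rmse
    return RegressionReport(set_id, r2, rmse, rpd, len(y_ref), overflow)


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100*(after-before)/before, rounded to one
    decimal half-away-from-zero (presentation convention)."""
    if before == 0:
        raise ContractError("percent change undefined for before == 0")
    raw = 100.0 * (after - before) / before
    return math.copysign(math.floor(abs(raw) * 10 + 0.5) / 10, raw)


def stage_summary(records: list[QualityRecord]) -> pd.DataFrame:
    """Per-stage min/max/mean/SD table for FI, SSC and FSR, ordered P1..P5.

    SD is the sample standard deviation (n-1); stages with a single record
    report SD as missing.
    """
    if not records:
        raise ContractError("no records")
    df = pd.DataFrame(
        {"stage": [r.stage for r in records], "FI": [r.FI for r in records],
         "SSC": [r.SSC for r in records], "FSR": [r.FSR for r in records]})
    rows = []
    for stage in STAGES:
        sub = df[df["stage"] == stage]
        if sub.empty:
            continue
        for index in ("FI", "SSC", "FSR"):
            vals = sub[index].to_numpy()
            rows.append({
                "stage": stage, "index": index, "n": len(vals),
                "min": vals.min(), "max": vals.max(), "mean": vals.mean(),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)


@dataclass
class FoldScheme:
    """Stratified k-fold index partition."""

    folds: list[np.ndarray]
    stratified: bool
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.folds)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ContractError("folds overlap")


def make_folds(labels: np.ndarray, k: int = 5, seed: int = 2,
               stratified: bool = True) -> FoldScheme:
    labels = np.asarray(labels)
    if k < 2:
        raise ContractError("k must be >= 2")
    if stratified:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in skf.split(np.zeros(len(labels)), labels)]
    else:
        rng = np.random.default_rng(seed)
        folds = [np.sort(f) for f in np.array_split(rng.permutation(len(labels)), k)]
    return FoldScheme(folds=folds, stratified=stratified, seed=seed)


@dataclass
class ClassificationReport:
    classes: list[str]
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_fold_accuracy: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy_pct": self.accuracy,
            "precision_pct": self.precision,
            "recall_pct": self.recall,
            "f1_pct": self.f1,
            "per_fold_accuracy_pct": self.per_fold_accuracy,
            "n": self.n,
        }


def classification_report_from_predictions(y_true, y_pred,
                                           classes=None) -> ClassificationReport:
    """Confusion matrix and macro-averaged metrics, in percent."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        conf[index[t], index[p]] += 1
    n = conf.sum()
    accuracy = 100.0 * np.trace(conf) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.diag(conf) / conf.sum(axis=0)
        rec = np.diag(conf) / conf.sum(axis=1)
    prec = np.nan_to_num(prec)
    rec = np.nan_to_num(rec)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return ClassificationReport(
        classes=[str(c) for c in classes], confusion=conf,
        accuracy=accuracy, precision=100.0 * prec.mean(),
        recall=100.0 * rec.mean(), f1=100.0 * f1.mean())


def crossval_classify(spec: BaselineSpec, table: SpectrumTable | np.ndarray,
                      labels: np.ndarray, scheme: FoldScheme) -> ClassificationReport:
    """Leakage-free cross-validated classification.

    The entire pipeline named by ``spec`` — including standardization and any
    feature elimination — is refitted from scratch on each fold's training
    portion; metrics come from predictions aggregated over all folds.
    """
    X = table.spectra if isinstance(table, SpectrumTable) else np.asarray(table)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    n = len(labels)
    all_idx = np.concatenate(scheme.folds)
    if len(all_idx) != n or set(all_idx.tolist()) != set(range(n)):
        raise ContractError("fold scheme does not cover the samples exactly")
    y_pred = np.empty(n, dtype=labels.dtype)
    per_fold = []
    for test_idx in scheme.folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train_labels = labels[train_mask]
        if set(classes) - set(np.unique(train_labels)):
            raise ContractError("a class is absent from a training fold")
        model = fit_baseline(spec, X[train_mask], train_labels)
        pred = model.predict(X[test_idx])
        y_pred[test_idx] = pred
        per_fold.append(100.0 * float(np.mean(pred == labels[test_idx])))
    report = classification_report_from_predictions(labels, y_pred, classes)
    report.per_fold_accuracy = per_fold
    return report
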