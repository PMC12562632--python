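"""Classical chemometric regressors and maturity classifiers.

Regression: partial least squares (PLSR), RBF support-vector regression
(C=90, gamma=1) and principal-component regression (10 components).
Classification: PLS-DA (PLS on one-hot class indicators + argmax), RBF SVM
(C=10, gamma='scale') and LDA coupled with recursive feature elimination.
All models are deterministic functions of the training data and their
hyperparameters; scale-sensitive models standardize bands internally, the
projection models are centred only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .errors import ContractError
from .table import SpectrumTable

__all__ = [
    "BaselineSpec",
    "FittedRegressor",
    "FittedClassifier",
    "fit_plsr",
    "fit_svr",
    "fit_pcr",
    "fit_plsda",
    "fit_svm_classifier",
    "fit_lda_rfe",
    "fit_baseline",
    "select_latent_variables",
]


@dataclass
class BaselineSpec:
    """Method id plus hyperparameters; defaults follow the study settings."""

    method: str
    params: dict = field(default_factory=dict)

    _DEFAULTS = {
        "plsr": {"n_latent": 10},
        "svr": {"C": 90.0, "gamma": 1.0},
        "pcr": {"n_components": 10},
        "plsda": {"n_latent": 10},
        "svm": {"C": 10.0, "gamma": "scale"},
        "lda_rfe": {"n_features": 40, "step_fraction": 0.1},
    }

    def __post_init__(self) -> None:
        if self.method not in self._DEFAULTS:
            raise ContractError(f"unknown baseline method {self.method!r}")
        self.params = {**self._DEFAULTS[self.method], **self.params}


def _xy(train: SpectrumTable | np.ndarray, target: str | np.ndarray | None):
    if isinstance(train, SpectrumTable):
        X = train.spectra
        y = train.target_values(target) if isinstance(target, str) else np.asarray(target)
    else:
        X = np.asarray(train, dtype=float)
        y = np.asarray(target)
    return X, y


class FittedRegressor:
    """Uniform predict() facade over the sklearn estimators."""

    def __init__(self, method: str, pipeline, params: dict):
        self.method = method
        self._pipeline = pipeline
        self.params = params

    def predict(self, data: SpectrumTable | np.ndarray) -> np.ndarray:
        X = data.spectra if isinstance(data, SpectrumTable) else np.asarray(data)
        return np.asarray(self._pipeline.predict(X)).ravel()


class FittedClassifier:
    def __init__(self, method: str, predict_fn, params: dict,
                 classes: np.ndarray, selected_bands: np.ndarray | None = None):
        self.method = method
        self._predict_fn = predict_fn
        self.params = params
        self.classes = classes
        self.selected_bands = selected_bands

    def predict(self, data: SpectrumTable | np.ndarray) -> np.ndarray:
        X = data.spectra if isinstance(data, SpectrumTable) else np.asarray(data)
        return self._predict_fn(X)


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def fit_plsr(train, target, n_latent: int = 10) -> FittedRegressor:
    """Partial least squares regression; latent variables maximize the
    X-y covariance.  The fitted model is linear in the original bands."""
    X, y = _xy(train, target)
    max_lv = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_latent <= max_lv:
        raise ContractError(f"n_latent must be in [1, {max_lv}]")
    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(X, y.reshape(-1, 1))
    return FittedRegressor("plsr", pls, {"n_latent": n_latent})


def fit_svr(train, target, C: float = 90.0, gamma: float = 1.0) -> FittedRegressor:
    """RBF support-vector regression with the study's penalty/kernel setting.

    Bands are standardized inside the pipeline (SVR is scale-sensitive)."""
    X, y = _xy(train, target)
    if X.shape[0] < 2:
        raise ContractError("SVR needs at least 2 training samples")
    from sklearn.pipeline import make_pipeline

    pipe = make_pipeline(StandardScaler(), SVR(C=C, gamma=gamma, kernel="rbf"))
    pipe.fit(X, y)
    return FittedRegressor("svr", pipe, {"C": C, "gamma": gamma})


class _PCRPipeline:
    """PCA scores + least squares, with a deterministic component-sign fix
    (largest-magnitude loading made positive)."""

    def __init__(self, n_components: int):
        self.n_components = n_components

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_PCRPipeline":
        self.pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = self.pca.fit_transform(X)
        comp = self.pca.components_
        signs = np.sign(comp[np.arange(comp.shape[0]),
                             np.argmax(np.abs(comp), axis=1)])
        signs[signs == 0] = 1.0
        self.pca.components_ = comp * signs[:, None]
        scores = scores * signs[None, :]
        self.reg = LinearRegression().fit(scores, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.reg.predict(self.pca.transform(X))


def fit_pcr(train, target, n_components: int = 10) -> FittedRegressor:
    X, y = _xy(train, target)
    max_pc = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_pc:
        raise ContractError(f"n_components must be in [1, {max_pc}]")
    return FittedRegressor("pcr", _PCRPipeline(n_components).fit(X, y),
                           {"n_components": n_components})


def select_latent_variables(X: np.ndarray, y: np.ndarray, max_lv: int = 20,
                            k: int = 5, seed: int = 2) -> int:
    """Choose the PLS latent-variable count by internal k-fold CV RMSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_lv = min(max_lv, X.shape[1], int(X.shape[0] * (k - 1) / k) - 1)
    cv = KFold(n_splits=k, shuffle=True, random_state=seed)
    best_lv, best_rmse = 1, np.inf
    for lv in range(1, max_lv + 1):
        sq = 0.0
        for tr, te in cv.split(X):
            m = PLSRegression(n_components=lv, scale=False).fit(X[tr], y[tr, None])
            sq += float(np.sum((m.predict(X[te]).ravel() - y[te]) ** 2))
        rmse = np.sqrt(sq / len(y))
        if rmse < best_rmse - 1e-12:
            best_rmse, best_lv = rmse, lv
    return best_lv


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _check_classes(labels: np.ndarray) -> np.ndarray:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ContractError("classification needs at least 2 classes")
    return classes


def fit_plsda(train, stage_labels, n_latent: int = 10) -> FittedClassifier:
    """PLS-DA: PLS regression on one-hot class indicators, argmax decision.
    Bands are standardized so the decision is invariant to common rescaling."""
    X, labels = _xy(train, stage_labels)
    classes = _check_classes(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    max_lv = min(X.shape[0] - 1, X.shape[1])
    n_latent = min(n_latent, max_lv)
    scaler = StandardScaler().fit(X)
    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(scaler.transform(X), Y)

    def predict_fn(Xq: np.ndarray) -> np.ndarray:
        scores = pls.predict(scaler.transform(Xq))
        return classes[np.argmax(scores, axis=1)]

    return FittedClassifier("plsda", predict_fn, {"n_latent": n_latent}, classes)


def fit_svm_classifier(train, labels, C: float = 10.0,
                       gamma: str | float = "scale") -> FittedClassifier:
    X, y = _xy(train, labels)
    classes = _check_classes(y)
    from sklearn.pipeline import make_pipeline

    pipe = make_pipeline(StandardScaler(), SVC(C=C, gamma=gamma, kernel="rbf"))
    pipe.fit(X, y)
    return FittedClassifier("svm", lambda Xq: pipe.predict(Xq),
                            {"C": C, "gamma": gamma}, classes)


def fit_lda_rfe(train, labels, n_features: int = 40,
                step_fraction: float = 0.1) -> FittedClassifier:
    """LDA with recursive feature elimination.

    Each round fits LDA on the surviving standardized bands, ranks bands by
    the aggregate absolute discriminant coefficient across class functions,
    and drops the lowest-ranked ``step_fraction`` of the remainder until
    ``n_features`` survive.  Returns the final model plus the selected band
    indices.
    """
    X, y = _xy(train, labels)
    classes = _check_classes(y)
    if n_features < len(classes) - 1:
        raise ContractError("n_features must be >= n_classes - 1")
    if n_features > X.shape[1]:
        raise ContractError("n_features exceeds band count")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    surviving = np.arange(X.shape[1])
    while len(surviving) > n_features:
        lda = LinearDiscriminantAnalysis().fit(Xs[:, surviving], y)
        importance = np.abs(lda.coef_).sum(axis=0)
        n_drop = min(max(1, int(np.floor(step_fraction * len(surviving)))),
                     len(surviving) - n_features)
        # stable ranking: lowest importance dropped, ties resolved to lower index
        order = np.argsort(importance, kind="stable")
        drop = set(order[:n_drop].tolist())
        surviving = np.array([b for i, b in enumerate(surviving) if i not in drop])
    final = LinearDiscriminantAnalysis().fit(Xs[:, surviving], y)

    def predict_fn(Xq: np.ndarray) -> np.ndarray:
        return final.predict(scaler.transform(Xq)[:, surviving])

    return FittedClassifier("lda_rfe", predict_fn,
                            {"n_features": n_features, "step_fraction": step_fraction},
                            classes, selected_bands=surviving)


def fit_baseline(spec: BaselineSpec, train, target_or_labels):
    """Dispatch on a :class:`BaselineSpec`; returns a fitted model."""
    m, p = spec.method, spec.params
    if m == "plsr":
        return fit_plsr(train, target_or_labels, p["n_latent"])
    if m == "svr":
        return fit_svr(train, target_or_labels, p["C"], p["gamma"])
    if m == "pcr":
        return fit_pcr(train, target_or_labels, p["n_components"])
    if m == "plsda":
        return fit_plsda(train, target_or_labels, p["n_latent"])
    if m == "svm":
        return fit_svm_classifier(train, target_or_labels, p["C"], p["gamma"])
    if m == "lda_rfe":
        return fit_lda_rfe(train, target_or_labels, p["n_features"], p["step_fraction"])
    raise ContractError(f"unknown method {m!r}")
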