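"""Training, prediction and persistence for the deep spectral regressors.

Spectra are standardized per band with calibration-set statistics (stored in
the fitted artifact and re-applied at predict time); optimization is Adam on
mean squared error with mini-batches drawn without replacement in a seeded
shuffle each epoch.  "Iterations" are epochs over the calibration set.  Early
stopping, when enabled, holds out a fraction of the calibration samples,
tracks validation MSE each epoch and restores the best parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ..errors import ContractError, DivergenceError
from ..table import SpectrumTable
from .layers import DTYPE, Adam, BatchNorm1d, Module
from .models import MSCNN, MSCNNLSTM, MSCNNConfig, ResNet18_1D

__all__ = [
    "EarlyStoppingConfig",
    "TrainConfig",
    "PredictorGraph",
    "build_mscnn",
    "build_mscnn_lstm",
    "build_resnet18_1d",
    "default_train_config",
    "train_regressor",
    "predict",
    "save_model",
    "load_model",
]

ARCHITECTURES = ("mscnn", "mscnn_lstm", "resnet18_1d")


@dataclass
class EarlyStoppingConfig:
    enabled: bool = False
    patience: int = 50
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction <= 0.5:
            raise ContractError("validation fraction must be in (0, 0.5]")
        if self.patience < 1:
            raise ContractError("patience must be >= 1")


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_iterations: int = 1000
    early_stopping: EarlyStoppingConfig = field(default_factory=EarlyStoppingConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.max_iterations < 0:
            raise ContractError("hyperparameters must be positive")


def default_train_config(architecture: str, seed: int = 0) -> TrainConfig:
    """Published training budgets: ResNet18 500 epochs with early stopping,
    the multiscale models 1000 epochs."""
    if architecture == "resnet18_1d":
        return TrainConfig(max_iterations=500, seed=seed,
                           early_stopping=EarlyStoppingConfig(enabled=True))
    return TrainConfig(max_iterations=1000, seed=seed)


@dataclass
class PredictorGraph:
    """A (possibly fitted) deep regressor plus its preprocessing state."""

    architecture: str
    model: Module
    config: dict
    fitted: bool = False
    band_mean: np.ndarray | None = None
    band_std: np.ndarray | None = None
    y_mean: float = 0.0
    y_std: float = 1.0
    target: str | None = None
    history: dict = field(default_factory=dict)

    @property
    def input_length(self) -> int:
        return int(self.config["input_length"])

    def n_parameters(self) -> int:
        return self.model.n_parameters()


def build_mscnn(cfg: MSCNNConfig | None = None) -> PredictorGraph:
    cfg = cfg or MSCNNConfig()
    model = MSCNN(cfg)
    return PredictorGraph("mscnn", model, cfg.to_dict())


def build_mscnn_lstm(cfg: MSCNNConfig | None = None, hidden: int = 128) -> PredictorGraph:
    cfg = cfg or MSCNNConfig()
    model = MSCNNLSTM(cfg, hidden=hidden)
    config = cfg.to_dict()
    config["lstm_hidden"] = hidden
    return PredictorGraph("mscnn_lstm", model, config)


def build_resnet18_1d(input_length: int = 421, seed: int = 0) -> PredictorGraph:
    model = ResNet18_1D(input_length, seed=seed)
    return PredictorGraph("resnet18_1d", model,
                          {"input_length": input_length, "seed": seed})


def _as_xy(train: SpectrumTable | tuple[np.ndarray, np.ndarray],
           target: str | None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(train, SpectrumTable):
        if target is None:
            raise ContractError("a target column name is required with a table")
        return train.spectra, train.target_values(target)
    X, y = train
    return np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel()


def _snapshot(model: Module) -> list[np.ndarray]:
    return [p.value.copy() for p in model.parameters()]


def _restore(model: Module, values: list[np.ndarray]) -> None:
    for p, v in zip(model.parameters(), values):
        p.value[...] = v


def train_regressor(
    graph: PredictorGraph,
    train: SpectrumTable | tuple[np.ndarray, np.ndarray],
    target: str | None = None,
    cfg: TrainConfig | None = None,
) -> PredictorGraph:
    """Fit ``graph`` in place with Adam on MSE; returns the fitted graph.

    The per-epoch training loss (and validation loss under early stopping)
    is stored in ``graph.history``.  Deterministic for a fixed seed on a
    single thread.
    """
    cfg = cfg or default_train_config(graph.architecture)
    X, y = _as_xy(train, target)
    if X.shape[0] == 0:
        raise ContractError("training set is empty")
    if X.shape[1] != graph.input_length:
        raise ContractError(
            f"band count {X.shape[1]} does not match model input "
            f"{graph.input_length}")

    graph.band_mean = X.mean(axis=0)
    std = X.std(axis=0)
    graph.band_std = np.where(std == 0, 1.0, std)
    Xs = ((X - graph.band_mean) / graph.band_std).astype(DTYPE)
    # the response is standardized for optimization (network outputs start
    # near the target mean) and de-standardized at predict time; recorded
    # losses are rescaled back to squared target units
    graph.y_mean = float(np.mean(y))
    y_sd = float(np.std(y))
    graph.y_std = y_sd if y_sd > 0 else 1.0
    ys = ((np.asarray(y, dtype=float) - graph.y_mean) / graph.y_std).astype(DTYPE)

    rng = np.random.default_rng(cfg.seed)
    es = cfg.early_stopping
    if es.enabled and len(ys) >= 10:
        n_val = max(1, int(round(len(ys) * es.validation_fraction)))
        perm = rng.permutation(len(ys))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_val, y_val = Xs[val_idx], ys[val_idx]
        Xs, ys = Xs[tr_idx], ys[tr_idx]
    else:
        X_val = y_val = None

    model = graph.model
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = len(ys)
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    stall = 0

    for epoch in range(cfg.max_iterations):
        model.set_training(True)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = Xs[idx], ys[idx]
            opt.zero_grad()
            pred = model(xb)
            resid = pred - yb
            loss = float(np.mean(resid * resid))
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}", epoch)
            epoch_loss += loss * len(idx)
            if cfg.learning_rate > 0:
                model.backward((2.0 / len(idx)) * resid)
                opt.step()
        train_losses.append(epoch_loss / n)

        if X_val is not None:
            model.set_training(False)
            vp = model(X_val)
            vloss = float(np.mean((vp - y_val) ** 2))
            val_losses.append(vloss)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best_params = _snapshot(model)
                stall = 0
            else:
                stall += 1
                if stall >= es.patience:
                    break

    if best_params is not None:
        _restore(model, best_params)
    model.set_training(False)
    graph.fitted = True
    graph.target = target if isinstance(train, SpectrumTable) else target
    scale = graph.y_std ** 2
    graph.history = {
        "train_loss": [v * scale for v in train_losses],
        "val_loss": [v * scale for v in val_losses],
        "epochs_run": len(train_losses),
        "config": {
            "learning_rate": cfg.learning_rate,
            "batch_size": cfg.batch_size,
            "max_iterations": cfg.max_iterations,
            "early_stopping": vars(es) | {},
            "seed": cfg.seed,
        },
    }
    return graph


def predict(graph: PredictorGraph, data: SpectrumTable | np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Per-sample predictions in target units; batch-size independent."""
    if not graph.fitted:
        raise ContractError("predict called on an unfitted graph")
    X = data.spectra if isinstance(data, SpectrumTable) else np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[1] != graph.input_length:
        raise ContractError(
            f"band count {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"model input {graph.input_length}")
    Xs = ((X - graph.band_mean) / graph.band_std).astype(DTYPE)
    graph.model.set_training(False)
    preds = [graph.model(Xs[i:i + batch_size]) for i in range(0, len(Xs), batch_size)]
    return np.concatenate(preds).astype(float) * graph.y_std + graph.y_mean


# ---------------------------------------------------------------------------
# Artifact persistence: parameter store + config echo + standardization
# ---------------------------------------------------------------------------


def _bn_modules(model: Module) -> list[BatchNorm1d]:
    found: list[BatchNorm1d] = []

    def walk(m: Module) -> None:
        for attr in m.__dict__.values():
            if isinstance(attr, BatchNorm1d):
                found.append(attr)
            elif isinstance(attr, Module):
                walk(attr)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        if isinstance(item, BatchNorm1d):
                            found.append(item)
                        else:
                            walk(item)
        if isinstance(m, BatchNorm1d) and m not in found:
            found.append(m)

    walk(model)
    return found


def save_model(graph: PredictorGraph, out_dir: str | Path) -> Path:
    """Write a model artifact directory: params.npz + config.yaml."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    arrays = {f"p_{i:04d}": p.value for i, p in enumerate(graph.model.parameters())}
    for i, bn in enumerate(_bn_modules(graph.model)):
        arrays[f"rm_{i:04d}"] = bn.running_mean
        arrays[f"rv_{i:04d}"] = bn.running_var
    if graph.band_mean is not None:
        arrays["band_mean"] = graph.band_mean
        arrays["band_std"] = graph.band_std
        arrays["y_scale"] = np.array([graph.y_mean, graph.y_std])
    np.savez(out_dir / "params.npz", **arrays)
    meta = {
        "architecture": graph.architecture,
        "config": graph.config,
        "fitted": bool(graph.fitted),
        "target": graph.target,
        "history": {k: v for k, v in graph.history.items() if k != "val_loss"}
        | {"val_loss": graph.history.get("val_loss", [])},
    }
    (out_dir / "config.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return out_dir


def _rebuild(architecture: str, config: dict) -> PredictorGraph:
    if architecture == "resnet18_1d":
        return build_resnet18_1d(config["input_length"], seed=config.get("seed", 0))
    from .models import BranchSpec

    cfg = MSCNNConfig(
        input_length=config["input_length"],
        branches=tuple(BranchSpec(**b) for b in config["branches"]),
        pool_kernel=config["pool_kernel"],
        pool_stride=config["pool_stride"],
        hidden=config["hidden"],
        fusion_init=config["fusion_init"],
        seed=config["seed"],
    )
    if architecture == "mscnn":
        return build_mscnn(cfg)
    if architecture == "mscnn_lstm":
        return build_mscnn_lstm(cfg, hidden=config.get("lstm_hidden", 128))
    raise ContractError(f"unknown architecture {architecture!r}")


def load_model(model_dir: str | Path) -> PredictorGraph:
    model_dir = Path(model_dir)
    meta = yaml.safe_load((model_dir / "config.yaml").read_text())
    graph = _rebuild(meta["architecture"], meta["config"])
    with np.load(model_dir / "params.npz") as arrays:
        for i, p in enumerate(graph.model.parameters()):
            p.value[...] = arrays[f"p_{i:04d}"]
        for i, bn in enumerate(_bn_modules(graph.model)):
            bn.running_mean[...] = arrays[f"rm_{i:04d}"]
            bn.running_var[...] = arrays[f"rv_{i:04d}"]
        if "band_mean" in arrays:
            graph.band_mean = arrays["band_mean"]
            graph.band_std = arrays["band_std"]
            if "y_scale" in arrays:
                graph.y_mean, graph.y_std = (float(v) for v in arrays["y_scale"])
    graph.fitted = bool(meta.get("fitted", False))
    graph.target = meta.get("target")
    graph.history = meta.get("history", {})
    graph.model.set_training(False)
    return graph
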