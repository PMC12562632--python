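"""Pixel-wise quality maps: apply a fitted regressor to every pixel spectrum.

Each in-region pixel of a calibrated, band-truncated cube is pushed through
the model's standardization and forward pass, yielding a spatial map of the
predicted quality index (FI, SSC or FSR) that is rendered with a continuous
blue-to-red palette.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib import cm

from .errors import ContractError
from .hypercube import Hypercube
from .nn.train import PredictorGraph
from .nn.train import predict as nn_predict

__all__ = ["PredictionMap", "pixelwise_predict", "render_map", "map_to_rgba",
           "centered_rectangle"]


@dataclass
class PredictionMap:
    """Spatial prediction in target units; NaN marks out-of-region pixels."""

    values: np.ndarray
    region: np.ndarray  # boolean mask actually predicted
    target: str
    model_id: str

    def region_values(self) -> np.ndarray:
        return self.values[self.region]


def _predict_fn(model):
    if isinstance(model, PredictorGraph):
        return (lambda X: nn_predict(model, X)), model.input_length, model.architecture
    if hasattr(model, "predict"):
        return (lambda X: np.asarray(model.predict(X)).ravel()), None, getattr(
            model, "method", type(model).__name__)
    raise ContractError("model must be a PredictorGraph or expose .predict")


def centered_rectangle(shape: tuple[int, int], height: int, width: int
                       ) -> tuple[int, int, int, int]:
    """(row0, col0, height, width) of a centred rectangle, e.g. the study's
    90 x 60 px evaluation region."""
    rows, cols = shape
    if height > rows or width > cols:
        raise ContractError("rectangle exceeds image bounds")
    return (rows - height) // 2, (cols - width) // 2, height, width


def pixelwise_predict(cube: Hypercube, model,
                      region: tuple[int, int, int, int] | np.ndarray | None = None,
                      target: str = "", chunk_size: int = 4096) -> PredictionMap:
    """Predict the quality index for every pixel spectrum inside ``region``.

    ``region`` is a (row0, col0, height, width) rectangle, a boolean mask, or
    None for the whole frame.  The cube must already be reflectance-calibrated
    and truncated to the model's expected band count.  Pixels are processed in
    row-major chunks; results are chunking-independent.
    """
    fn, expected, model_id = _predict_fn(model)
    if expected is not None and cube.n_bands != expected:
        raise ContractError(
            f"cube has {cube.n_bands} bands, model expects {expected}")
    rows, cols, b = cube.shape
    if region is None:
        mask = np.ones((rows, cols), dtype=bool)
    elif isinstance(region, np.ndarray):
        mask = np.asarray(region, dtype=bool)
        if mask.shape != (rows, cols):
            raise ContractError("region mask shape must match cube spatial shape")
    else:
        r0, c0, h, w = region
        if r0 < 0 or c0 < 0 or r0 + h > rows or c0 + w > cols:
            raise ContractError("rectangle region exceeds cube bounds")
        mask = np.zeros((rows, cols), dtype=bool)
        mask[r0:r0 + h, c0:c0 + w] = True

    pixels = cube.data[mask]  # (n_pix, bands), row-major order
    preds = np.concatenate([
        fn(pixels[i:i + chunk_size]) for i in range(0, len(pixels), chunk_size)
    ]) if len(pixels) else np.empty(0)
    values = np.full((rows, cols), np.nan)
    values[mask] = preds
    return PredictionMap(values=values, region=mask, target=target, model_id=model_id)


def map_to_rgba(pmap: PredictionMap, color_scale: tuple[float, float],
                palette: str = "coolwarm") -> np.ndarray:
    """Deterministic RGBA array for the map: values clipped to the scale,
    normalized, and passed through the named colormap; out-of-region pixels
    are transparent."""
    lo, hi = color_scale
    if not lo < hi:
        raise ContractError("color scale must satisfy lo < hi")
    norm = np.clip((pmap.values - lo) / (hi - lo), 0.0, 1.0)
    rgba = matplotlib.colormaps[palette](np.nan_to_num(norm, nan=0.0))
    rgba[..., 3] = np.where(pmap.region, 1.0, 0.0)
    return rgba


def default_scale(pmap: PredictionMap) -> tuple[float, float]:
    """1st-99th percentile of the in-region values."""
    vals = pmap.region_values()
    lo, hi = np.percentile(vals, [1, 99])
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    return float(lo), float(hi)


def render_map(pmap: PredictionMap, out_path: str | Path,
               color_scale: tuple[float, float] | None = None,
               palette: str = "coolwarm", dpi: int = 120) -> Path:
    """Write a PNG of the prediction map with a colorbar.

    Bytes are deterministic for fixed inputs (fixed dpi, no timestamps).
    """
    scale = color_scale if color_scale is not None else default_scale(pmap)
    rgba = map_to_rgba(pmap, scale, palette)
    fig, ax = plt.subplots(figsize=(5, 4), dpi=dpi)
    ax.imshow(rgba, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    title = pmap.target or "prediction"
    ax.set_title(f"{title} ({pmap.model_id})")
    sm = cm.ScalarMappable(cmap=palette,
                           norm=matplotlib.colors.Normalize(*scale))
    fig.colorbar(sm, ax=ax, shrink=0.85)
    out_path = Path(out_path)
    fig.savefig(out_path, format="png", metadata={"Software": "pearhsi"})
    plt.close(fig)
    return out_path
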