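"""SPXY calibration/prediction partitioning with per-stage stratification.

SPXY extends Kennard-Stone sample selection to a joint distance over spectra
(X) and response (y): each pairwise distance is the Euclidean X-distance and
the absolute y-difference, both normalized by their respective maxima, summed.
Selection starts from the most distant pair and greedily adds the sample whose
minimum distance to the selected set is largest, yielding a calibration set
that spans both spectral and response space.  The split is run independently
within each maturity stage so both sets represent every stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ContractError, DegenerateDistanceError
from .table import STAGES, SpectrumTable

__all__ = [
    "SplitAssignment",
    "spxy_joint_distance",
    "spxy_select",
    "stratified_spxy_split",
    "random_split",
]


@dataclass
class SplitAssignment:
    """Disjoint calibration/prediction index lists covering the input table."""

    calibration_indices: list[int]
    prediction_indices: list[int]
    per_stratum_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cal, pred = set(self.calibration_indices), set(self.prediction_indices)
        if cal & pred:
            raise ContractError("calibration and prediction sets overlap")

    @property
    def n_total(self) -> int:
        return len(self.calibration_indices) + len(self.prediction_indices)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "calibration_indices": list(map(int, self.calibration_indices)),
            "prediction_indices": list(map(int, self.prediction_indices)),
            "per_stratum_counts": {k: list(v) for k, v in self.per_stratum_counts.items()},
            "config": self.config,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitAssignment":
        payload = json.loads(Path(path).read_text())
        return cls(
            calibration_indices=payload["calibration_indices"],
            prediction_indices=payload["prediction_indices"],
            per_stratum_counts={k: tuple(v) for k, v in payload.get("per_stratum_counts", {}).items()},
            config=payload.get("config", {}),
        )


def spxy_joint_distance(X: np.ndarray, y: np.ndarray | None = None) -> np.ndarray:
    """Symmetric joint X+y distance matrix, entries in [0, 2].

    d(i,j) = dX(i,j)/max dX + |y_i - y_j|/max |dy|.  With ``y=None`` the
    y-term is dropped (pure Kennard-Stone distance, entries in [0, 1]).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ContractError("X must be 2-D with at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ContractError("X must be finite")
    dx = squareform(pdist(X, metric="euclidean"))
    dx_max = dx.max()
    if dx_max == 0:
        raise DegenerateDistanceError("all samples have identical spectra")
    d = dx / dx_max
    if y is not None:
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ContractError("y length must match X rows")
        if not np.all(np.isfinite(y)):
            raise ContractError("y must be finite")
        dy = np.abs(y[:, None] - y[None, :])
        dy_max = dy.max()
        if dy_max == 0:
            raise DegenerateDistanceError("all samples have identical response")
        d = d + dy / dy_max
    return d


def spxy_select(D: np.ndarray, n_cal: int) -> list[int]:
    """Greedy max-min selection of ``n_cal`` indices from a distance matrix.

    The first two picks are the globally most distant pair; every later pick
    maximizes the minimum distance to the already-selected set.  Ties are
    broken toward the lowest index, so the result is fully deterministic.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape != (n, n):
        raise ContractError("D must be square")
    if not 2 <= n_cal <= n:
        raise ContractError(f"need 2 <= n_cal <= {n}, got {n_cal}")
    # most distant pair, lowest (i, j) on ties via C-order argmax
    i, j = np.unravel_index(np.argmax(D), D.shape)
    selected = [min(i, j), max(i, j)] if i != j else [int(i), int((i + 1) % n)]
    min_dist = np.minimum(D[selected[0]], D[selected[1]])
    chosen = np.zeros(n, dtype=bool)
    chosen[selected] = True
    while len(selected) < n_cal:
        masked = np.where(chosen, -np.inf, min_dist)
        nxt = int(np.argmax(masked))  # argmax returns the first max: lowest index
        selected.append(nxt)
        chosen[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])
    return selected


def _stratum_n_cal(sizes: list[int], cal: int, pred: int) -> list[int]:
    """Per-stratum calibration counts: banker's rounding, last stratum adjusted
    so the totals match the global ratio exactly."""
    frac = cal / (cal + pred)
    total = sum(sizes)
    target_total = int(np.round(total * frac))
    counts = [int(np.round(s * frac)) for s in sizes]
    counts[-1] += target_total - sum(counts)
    counts[-1] = min(max(counts[-1], 0), sizes[-1])
    return counts


def stratified_spxy_split(
    table: SpectrumTable,
    ratio: tuple[int, int] = (4, 1),
    seed: int = 2,
    target: str | None = "FI",
) -> SplitAssignment:
    """SPXY split run independently within each maturity stage.

    ``seed`` governs only a pre-selection shuffle of within-stratum sample
    order (which fixes tie resolution); the max-min selection itself is
    deterministic.  ``target`` names the response column joined into the SPXY
    distance; ``None`` uses the X-only Kennard-Stone distance.  One shared
    split serves all downstream models.
    """
    cal, pred = ratio
    if cal <= 0 or pred < 0:
        raise ContractError("ratio parts must be positive (prediction may be 0)")
    if table.stage is None:
        strata = {"all": np.arange(table.n_samples)}
    else:
        strata = {s: np.flatnonzero(table.stage == s) for s in STAGES
                  if np.any(table.stage == s)}
    sizes = [len(v) for v in strata.values()]
    if any(s < 2 for s in sizes):
        raise ContractError("every stratum needs at least 2 samples")
    n_cals = _stratum_n_cal(sizes, cal, pred)

    y_all = table.target_values(target) if target is not None else None
    rng = np.random.default_rng(seed)
    cal_idx: list[int] = []
    pred_idx: list[int] = []
    per_stratum: dict[str, tuple[int, int]] = {}
    for (stage, idx), n_cal in zip(strata.items(), n_cals):
        order = rng.permutation(len(idx))
        idx = idx[order]
        if n_cal >= len(idx):
            sel = list(range(len(idx)))
        elif n_cal < 2:
            sel = list(range(n_cal))  # degenerate ratios: keep leading samples
        else:
            D = spxy_joint_distance(
                table.spectra[idx], None if y_all is None else y_all[idx]
            )
            sel = spxy_select(D, n_cal)
        sel_mask = np.zeros(len(idx), dtype=bool)
        sel_mask[sel] = True
        stage_cal = sorted(int(i) for i in idx[sel_mask])
        stage_pred = sorted(int(i) for i in idx[~sel_mask])
        cal_idx.extend(stage_cal)
        pred_idx.extend(stage_pred)
        per_stratum[stage] = (len(stage_cal), len(stage_pred))

    return SplitAssignment(
        calibration_indices=cal_idx,
        prediction_indices=pred_idx,
        per_stratum_counts=per_stratum,
        config={"method": "spxy", "ratio": list(ratio), "seed": seed, "target": target},
    )


def random_split(table: SpectrumTable, ratio: tuple[int, int] = (4, 1),
                 seed: int = 2) -> SplitAssignment:
    """Seeded uniform split (convenience fallback, stratified when possible)."""
    cal, pred = ratio
    rng = np.random.default_rng(seed)
    if table.stage is None:
        strata = {"all": np.arange(table.n_samples)}
    else:
        strata = {s: np.flatnonzero(table.stage == s) for s in STAGES
                  if np.any(table.stage == s)}
    n_cals = _stratum_n_cal([len(v) for v in strata.values()], cal, pred)
    cal_idx: list[int] = []
    pred_idx: list[int] = []
    per_stratum: dict[str, tuple[int, int]] = {}
    for (stage, idx), n_cal in zip(strata.items(), n_cals):
        idx = rng.permutation(idx)
        cal_s = sorted(int(i) for i in idx[:n_cal])
        pred_s = sorted(int(i) for i in idx[n_cal:])
        cal_idx.extend(cal_s)
        pred_idx.extend(pred_s)
        per_stratum[stage] = (len(cal_s), len(pred_s))
    return SplitAssignment(cal_idx, pred_idx, per_stratum,
                           {"method": "random", "ratio": list(ratio), "seed": seed})
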