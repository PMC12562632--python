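"""Tabular spectra: N samples x B bands with quality targets and stage labels.

The on-disk form is a delimited text table with header
``id,stage,FI,SSC,FSR,wl_<nm>,...`` — one row per fruit, reflectance per band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = ["SpectrumTable", "truncate_bands", "STAGES", "TARGET_COLUMNS"]

STAGES = ("P1", "P2", "P3", "P4", "P5")
TARGET_COLUMNS = ("FI", "SSC", "FSR")


@dataclass
class SpectrumTable:
    """Reflectance spectra with optional per-sample quality targets.

    Parameters
    ----------
    spectra : (N, B) array of reflectance, clipped to [0, reflectance_max].
    wavelengths : length-B band centres in nm, strictly increasing.
    sample_ids : length-N identifiers.
    targets : optional DataFrame with columns FI (N), SSC (%), FSR.
    stage : optional length-N array of maturity labels P1..P5.
    """

    spectra: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    targets: pd.DataFrame | None = None
    stage: np.ndarray | None = None
    reflectance_max: float = 1.2

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.ndim != 2:
            raise ContractError("spectra must be a 2-D (samples x bands) array")
        n, b = self.spectra.shape
        if len(self.wavelengths) != b:
            raise ContractError("wavelength vector must match band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ContractError("wavelengths must be strictly increasing")
        if np.isnan(self.spectra).any():
            raise ContractError("spectra contain NaN")
        self.spectra = np.clip(self.spectra, 0.0, self.reflectance_max)
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ContractError("sample_ids length must match sample count")
        if self.stage is not None:
            self.stage = np.asarray(self.stage, dtype=object)
            if len(self.stage) != n:
                raise ContractError("stage labels must match sample count")
            bad = set(self.stage) - set(STAGES)
            if bad:
                raise ContractError(f"unknown stage labels: {sorted(bad)}")
        if self.targets is not None:
            if len(self.targets) != n:
                raise ContractError("targets must match sample count")
            self.targets = self.targets.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]

    def target_values(self, target: str) -> np.ndarray:
        if self.targets is None or target not in self.targets:
            raise ContractError(f"table has no target column {target!r}")
        return self.targets[target].to_numpy(dtype=float)

    def subset(self, indices: np.ndarray | list[int]) -> "SpectrumTable":
        idx = np.asarray(indices, dtype=int)
        return SpectrumTable(
            spectra=self.spectra[idx],
            wavelengths=self.wavelengths.copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            targets=None if self.targets is None else self.targets.iloc[idx],
            stage=None if self.stage is None else self.stage[idx],
            reflectance_max=self.reflectance_max,
        )

    # -- delimited-text round trip ------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, object] = {"id": self.sample_ids}
        cols["stage"] = self.stage if self.stage is not None else [""] * self.n_samples
        for t in TARGET_COLUMNS:
            if self.targets is not None and t in self.targets:
                cols[t] = self.targets[t].to_numpy()
            else:
                cols[t] = np.full(self.n_samples, np.nan)
        df = pd.DataFrame(cols)
        wl_cols = pd.DataFrame(
            self.spectra, columns=[f"wl_{w:.4f}" for w in self.wavelengths]
        )
        return pd.concat([df, wl_cols], axis=1)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False, float_format="%.6g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectrumTable":
        df = pd.read_csv(path)
        wl_cols = [c for c in df.columns if c.startswith("wl_")]
        if not wl_cols:
            raise ContractError(f"{path}: no wl_<nm> spectral columns found")
        wavelengths = np.array([float(c[3:]) for c in wl_cols])
        targets = df[list(TARGET_COLUMNS)] if set(TARGET_COLUMNS) <= set(df.columns) else None
        if targets is not None and targets.isna().all().all():
            targets = None
        stage = None
        if "stage" in df.columns and df["stage"].notna().all():
            vals = df["stage"].astype(str).to_numpy()
            if all(v in STAGES for v in vals):
                stage = vals
        return cls(
            spectra=df[wl_cols].to_numpy(dtype=float),
            wavelengths=wavelengths,
            sample_ids=[str(s) for s in df["id"]],
            targets=targets,
            stage=stage,
        )


def truncate_bands(table: SpectrumTable, lo_nm: float, hi_nm: float) -> SpectrumTable:
    """Retain the bands with lo_nm <= wavelength <= hi_nm (both inclusive).

    The study restricts analysis to 950-1650 nm, discarding noisy detector
    edges; on the package's fixed instrument grid that window holds exactly
    421 bands.  Idempotent for a fixed window.
    """
    if not lo_nm < hi_nm:
        raise ContractError("require lo_nm < hi_nm")
    keep = (table.wavelengths >= lo_nm) & (table.wavelengths <= hi_nm)
    if not keep.any():
        raise ContractError(f"no bands inside [{lo_nm}, {hi_nm}] nm")
    return SpectrumTable(
        spectra=table.spectra[:, keep],
        wavelengths=table.wavelengths[keep],
        sample_ids=list(table.sample_ids),
        targets=table.targets,
        stage=table.stage,
        reflectance_max=table.reflectance_max,
    )
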