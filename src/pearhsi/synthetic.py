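"""Synthetic pear spectra, quality records and hypercubes.

The generator emulates the study design end to end: 600 fruit across five
maturity stages (120 each) whose firmness (FI) and soluble solid content
(SSC) follow stage-specific truncated normal distributions with a negative
FI-SSC coupling, and whose 512-band reflectance spectra carry the absorption
features seen in pear tissue — O-H related dips at 970 and 1450 nm, a weak
N-H dip near 1080 nm, C-H dips at 1200 nm (tied to sugar content) and
1270 nm — on a smooth scattering baseline whose level and slope track
firmness.  Truncating the fixed instrument grid to 950-1650 nm leaves
exactly 421 bands, the pipeline's working dimension.

The spectral coupling is phenomenological, not radiative transfer: its only
contract is that the statistical and geometric structure the analysis
pipeline assumes (stage separability, monotone band-depth/target coupling,
calibration-recoverable cubes) actually holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, truncnorm

from .errors import ContractError
from .evaluation import QualityRecord
from .hypercube import CalibrationPair, Hypercube
from .table import STAGES, SpectrumTable, truncate_bands

__all__ = [
    "StageParams",
    "GeneratorConfig",
    "TABLE1_PARAMS",
    "wavelength_grid",
    "sample_quality",
    "spectrum_from_quality",
    "generate_dataset",
    "generate_cube",
]

# Per-stage (mean, SD, min, max) of the destructive reference measurements.
TABLE1_PARAMS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "P1": {"FI": (13.98, 1.24, 10.97, 16.63), "SSC": (9.13, 0.84, 7.13, 12.10)},
    "P2": {"FI": (11.42, 0.99, 9.58, 14.09), "SSC": (12.87, 0.82, 10.23, 14.53)},
    "P3": {"FI": (10.09, 0.88, 7.99, 12.13), "SSC": (14.55, 0.93, 12.00, 17.00)},
    "P4": {"FI": (8.43, 0.76, 6.90, 10.42), "SSC": (13.22, 1.02, 10.80, 15.10)},
    "P5": {"FI": (8.03, 0.75, 6.75, 9.55), "SSC": (12.51, 0.99, 10.37, 14.50)},
}


@dataclass
class StageParams:
    """Distributional targets per stage and index; defaults are the study's
    reference statistics."""

    table: dict[str, dict[str, tuple[float, float, float, float]]] = field(
        default_factory=lambda: {s: dict(v) for s, v in TABLE1_PARAMS.items()})

    def __post_init__(self) -> None:
        for stage, indices in self.table.items():
            for index, (mean, sd, lo, hi) in indices.items():
                if not (lo <= mean <= hi):
                    raise ContractError(f"{stage}/{index}: need min <= mean <= max")
                if sd <= 0:
                    raise ContractError(f"{stage}/{index}: SD must be positive")


def wavelength_grid() -> np.ndarray:
    """Fixed 512-point instrument grid spanning 900-1700 nm.

    421 uniformly spaced points cover [950, 1650] inclusive (spacing
    700/420 nm); 45 points pad below 950 and 46 above 1650, so band
    truncation to the effective analysis window retains exactly 421 bands.
    """
    lower = np.linspace(900.0, 950.0, 46)[:-1]
    inner = np.linspace(950.0, 1650.0, 421)
    upper = np.linspace(1650.0, 1700.0, 47)[1:]
    return np.concatenate([lower, inner, upper])


@dataclass
class GeneratorConfig:
    """Spectral coupling and sampling parameters.

    Band model: Gaussian dips at the named absorption centres; the 1200 nm
    depth grows with SSC, the 1450 nm depth with a stage-linked moisture
    proxy, and the smooth baseline's level and slope track FI.  ``noise_sd``
    is additive i.i.d. reflectance noise per band.
    """

    n_per_stage: int = 120
    noise_sd: float = 0.008
    fi_ssc_corr: float = -0.3
    # absorption centres (nm) -> (depth intercept, width sigma nm)
    fixed_dips: dict[float, tuple[float, float]] = field(default_factory=lambda: {
        970.0: (0.060, 20.0), 1080.0: (0.030, 18.0), 1270.0: (0.050, 22.0)})
    # per-stage depth multipliers (P1..P5) for each fixed dip: maturation
    # rescales the fixed absorbers along independent, partly non-monotone
    # trajectories, so the five stage-mean spectra span a non-degenerate
    # simplex in band space (as mixtures of real absorbers do)
    stage_profiles: dict[float, tuple[float, ...]] = field(default_factory=lambda: {
        970.0: (1.00, 1.12, 1.28, 1.48, 1.72),
        1080.0: (1.00, 1.40, 0.85, 1.45, 0.75),
        1270.0: (1.00, 0.70, 1.30, 1.35, 0.75)})
    ssc_dip_center: float = 1200.0
    ssc_dip_sigma: float = 35.0
    ssc_dip_per_pct: float = 0.015       # dip depth per % SSC
    moisture_dip_center: float = 1450.0
    moisture_dip_sigma: float = 45.0
    moisture_dip_base: float = 0.05
    moisture_dip_per_stage: float = 0.03  # depth step per maturity stage
    moisture_center_shift: float = 5.0    # nm shift of the water band per stage
    stage_jitter_sd: float = 0.06         # within-stage maturity-continuum spread
    fi_level_ref: float = 11.0            # N, coupling pivot
    base_level: float = 0.78
    fi_level_coeff: float = 0.010         # reflectance per N
    base_slope: float = -0.02
    fi_slope_coeff: float = -0.006        # slope change per N
    clip: tuple[float, float] = (0.01, 1.0)
    seed: int = 2

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ContractError("noise SD must be >= 0")
        if self.n_per_stage < 1:
            raise ContractError("n_per_stage must be >= 1")


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lo: float,
                   hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def sample_quality(stage: str, n: int, params: StageParams | None = None,
                   seed: int | np.random.Generator = 0,
                   corr: float = -0.3) -> list[QualityRecord]:
    """Draw n quality records for one stage.

    FI and SSC follow truncated normals with the stage's (mean, SD, min, max)
    joined through a Gaussian copula with correlation ``corr`` (firmer fruit
    tend to be less sweet); sampling is exact inverse-CDF, no rejection.
    FSR is computed per record.
    """
    if n < 1:
        raise ContractError("n must be >= 1")
    params = params or StageParams()
    if stage not in params.table:
        raise ContractError(f"unknown stage {stage!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov = np.array([[1.0, corr], [corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    u = norm.cdf(z)
    fi = _truncnorm_ppf(u[:, 0], *params.table[stage]["FI"])
    ssc = _truncnorm_ppf(u[:, 1], *params.table[stage]["SSC"])
    return [QualityRecord(FI=float(f), SSC=float(s), FSR=float(f / s), stage=stage)
            for f, s in zip(fi, ssc)]


def _spectra_batch(fi: np.ndarray, ssc: np.ndarray, stage_idx: np.ndarray,
                   cfg: GeneratorConfig, rng: np.random.Generator | None,
                   wavelengths: np.ndarray) -> np.ndarray:
    """Vectorized reflectance synthesis: (N,) quality arrays -> (N, B)."""
    wl = wavelengths[None, :]
    fi = np.asarray(fi, dtype=float)[:, None]
    ssc = np.asarray(ssc, dtype=float)[:, None]
    stage_idx = np.asarray(stage_idx, dtype=float)[:, None]

    u = (wl - 1300.0) / 350.0
    level = cfg.base_level + cfg.fi_level_coeff * (fi - cfg.fi_level_ref)
    slope = cfg.base_slope + cfg.fi_slope_coeff * (fi - cfg.fi_level_ref)
    refl = level + slope * u

    if rng is not None and cfg.stage_jitter_sd > 0:
        stage_pos = stage_idx + cfg.stage_jitter_sd * rng.standard_normal(fi.shape)
    else:
        stage_pos = stage_idx
    grid = np.arange(5.0)
    for center, (depth, sigma) in cfg.fixed_dips.items():
        profile = cfg.stage_profiles.get(center)
        if profile is not None:
            mult = np.interp(stage_pos.ravel(), grid, profile)[:, None]
        else:
            mult = 1.0
        refl = refl - depth * mult * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    ssc_depth = cfg.ssc_dip_per_pct * ssc
    refl = refl - ssc_depth * np.exp(
        -0.5 * ((wl - cfg.ssc_dip_center) / cfg.ssc_dip_sigma) ** 2)
    # the 1450 nm O-H combination band deepens linearly with maturity and
    # drifts slightly to longer wavelengths as the moisture state changes
    moist_depth = cfg.moisture_dip_base + cfg.moisture_dip_per_stage * stage_pos
    moist_center = cfg.moisture_dip_center + cfg.moisture_center_shift * stage_pos
    refl = refl - moist_depth * np.exp(
        -0.5 * ((wl - moist_center) / cfg.moisture_dip_sigma) ** 2)

    if rng is not None and cfg.noise_sd > 0:
        refl = refl + cfg.noise_sd * rng.standard_normal(refl.shape)
    return np.clip(refl, cfg.clip[0], cfg.clip[1])


def spectrum_from_quality(record: QualityRecord, cfg: GeneratorConfig | None = None,
                          seed: int | np.random.Generator | None = 0,
                          truncated: bool = True) -> np.ndarray:
    """Reflectance spectrum for one fruit: 421 bands (950-1650 nm) by default,
    or the full 512-band raw grid with ``truncated=False``.

    ``seed=None`` disables noise and stage jitter, making the map from
    (FI, SSC, stage) to spectrum deterministic.
    """
    cfg = cfg or GeneratorConfig()
    rng = None
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    wl = wavelength_grid()
    spec = _spectra_batch(
        np.array([record.FI]), np.array([record.SSC]),
        np.array([STAGES.index(record.stage)]), cfg, rng, wl)[0]
    if truncated:
        keep = (wl >= 950.0) & (wl <= 1650.0)
        return spec[keep]
    return spec


def generate_dataset(cfg: GeneratorConfig | None = None,
                     params: StageParams | None = None,
                     seed: int | None = None,
                     truncated: bool = True) -> SpectrumTable:
    """Full study-design table: 5 stages x n_per_stage rows with targets.

    Reproducible per seed (``None`` uses ``cfg.seed``).  Bands are truncated
    to the 421-band analysis window unless ``truncated=False``.
    """
    cfg = cfg or GeneratorConfig()
    params = params or StageParams()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    wl = wavelength_grid()
    records: list[QualityRecord] = []
    for stage in STAGES:
        records.extend(sample_quality(stage, cfg.n_per_stage, params, rng,
                                      corr=cfg.fi_ssc_corr))
    fi = np.array([r.FI for r in records])
    ssc = np.array([r.SSC for r in records])
    stage_idx = np.array([STAGES.index(r.stage) for r in records])
    spectra = _spectra_batch(fi, ssc, stage_idx, cfg, rng, wl)
    import pandas as pd

    table = SpectrumTable(
        spectra=spectra,
        wavelengths=wl,
        sample_ids=[f"{r.stage}_{i % cfg.n_per_stage:03d}" for i, r in enumerate(records)],
        targets=pd.DataFrame({"FI": fi, "SSC": ssc, "FSR": fi / ssc}),
        stage=np.array([r.stage for r in records], dtype=object),
    )
    if truncated:
        table = truncate_bands(table, 950.0, 1650.0)
    return table


def generate_cube(stage: str, size: tuple[int, int] = (128, 96),
                  cfg: GeneratorConfig | None = None, seed: int = 0):
    """Raw hypercube + calibration pair + ground-truth quality maps.

    An elliptical "fruit" occupies the frame centre; per-pixel FI and SSC
    vary smoothly (radial softening plus a low-frequency lobe), spectra come
    from the same band model as the tabular generator, and the raw digital
    numbers are constructed so whiteboard correction recovers the intended
    reflectance exactly.  Returns ``(raw, pair, truth)`` where ``truth`` has
    per-pixel FI/SSC/FSR maps (NaN off-fruit) and the fruit mask.
    """
    rows, cols = size
    if rows < 100 or cols < 70:
        raise ContractError("cube must be at least 100 x 70 pixels")
    cfg = cfg or GeneratorConfig()
    params = StageParams()
    if stage not in params.table:
        raise ContractError(f"unknown stage {stage!r}")
    rng = np.random.default_rng(seed)
    wl = wavelength_grid()
    b = len(wl)

    cr, cc = (rows - 1) / 2.0, (cols - 1) / 2.0
    a_ax, b_ax = rows * 0.42, cols * 0.42
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    rho2 = ((r - cr) / a_ax) ** 2 + ((c - cc) / b_ax) ** 2
    mask = rho2 <= 1.0

    fi_mean, fi_sd = params.table[stage]["FI"][:2]
    ssc_mean, ssc_sd = params.table[stage]["SSC"][:2]
    lobe = np.sin(2 * np.pi * (r - cr) / rows) * np.cos(np.pi * (c - cc) / cols)
    fi_map = np.where(mask, fi_mean + fi_sd * (0.6 * (1 - rho2) - 0.3 + 0.4 * lobe), np.nan)
    ssc_map = np.where(mask, ssc_mean + ssc_sd * (0.5 * rho2 - 0.25 - 0.4 * lobe), np.nan)
    fsr_map = fi_map / ssc_map

    refl = np.empty((rows, cols, b))
    # background: flat grey panel, no absorption features
    refl[...] = 0.25
    idx = np.flatnonzero(mask.ravel())
    spectra = _spectra_batch(
        fi_map.ravel()[idx], ssc_map.ravel()[idx],
        np.full(len(idx), STAGES.index(stage), dtype=float), cfg, rng, wl)
    flat = refl.reshape(-1, b)
    flat[idx] = spectra
    refl = flat.reshape(rows, cols, b)

    white = np.full((rows, cols, b), 3600.0)
    dark = np.full((rows, cols, b), 120.0)
    raw = dark + refl * (white - dark)
    meta = {"stage": stage, "synthetic": "true"}
    pair = CalibrationPair(
        white=Hypercube(white, wl, {"frame": "white"}),
        dark=Hypercube(dark, wl, {"frame": "dark"}),
    )
    truth = {"FI": fi_map, "SSC": ssc_map, "FSR": fsr_map, "mask": mask}
    return Hypercube(raw, wl, meta), pair, truth
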