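"""Synthetic fermentation-broth NIR data generator.

Emulates the statistical structure of in-tank transflectance NIR
monitoring of a two-stage vinegar fermentation:

* **Kinetics** — each analyte follows a two-phase trajectory over 28
  days with an instantaneous state jump when wine is added to the
  fermenter on day 6 (acetic acid dips by dilution and then climbs past
  4 %w/v; ethanol is replenished and then oxidized away).  Phases are
  logistic segments pinned to their endpoint values.  Sampling is three
  scans a day.  Per-sample multiplicative jitter (default 1.5 % RSD,
  the order of the reference methods' precision) and a per-batch gain
  emulate reference-analysis and batch-to-batch variation; values are
  clipped to the calibration ranges the trajectories are built for.

* **Spectra** — Beer-Lambert mixing on the instrument grid: a strong
  water background (bands near 6,900 and 5,150 cm^-1) plus each
  analyte's concentration times a pure-component spectrum built from
  Gaussian bands.  Band centers default to wavenumbers diagnostic for
  each analyte so that planted-truth recovery has a ground truth.

* **Scatter** — the broth is turbid, so every spectrum gets its own
  multiplicative gain, additive offset, and linear baseline tilt, plus
  i.i.d. per-point noise.  With scatter and noise disabled the
  concentration-to-spectrum map is exactly linear.

Everything is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra_io import ROLE_CALIBRATION, ROLE_PREDICTION, SpectralDataset, WavenumberGrid

__all__ = [
    "ANALYTES",
    "CALIBRATION_RANGES",
    "AnalyteKinetics",
    "FermentationSimConfig",
    "PureComponentBand",
    "ScatterNoiseModel",
    "default_analyte_bands",
    "default_water_bands",
    "simulate_profiles",
    "simulate_dataset",
    "make_paper_scale_splits",
    "make_planted_dataset",
]

#: Analytes and their units.
ANALYTES = {
    "acetic_acid": "%w/v",
    "ethanol": "%v/v",
    "tss": "degBrix",
    "caffeic_acid": "ug/mL",
    "gallic_acid": "ug/mL",
    "tannic_acid": "ug/mL",
}

#: Calibration-set concentration ranges the kinetics are built to cover.
CALIBRATION_RANGES = {
    "acetic_acid": (4.69e-2, 4.24),
    "ethanol": (5.00e-3, 7.00),
    "tss": (7.90, 10.80),
    "caffeic_acid": (1.23, 7.46),
    "gallic_acid": (3.46, 5.98),
    "tannic_acid": (138.82, 288.30),
}


@dataclass(frozen=True)
class AnalyteKinetics:
    """Two-phase logistic trajectory with a jump at wine addition.

    Phase 1 runs from ``start`` at day 0 to ``end_phase1`` at the wine
    addition day; the level then jumps to ``jump_to`` (equal to
    ``end_phase1`` for analytes without a jump) and relaxes to
    ``final`` by the last day.  ``mid``/``rate`` set each logistic
    segment's midpoint (days) and steepness (1/day).
    """

    start: float
    end_phase1: float
    jump_to: float
    final: float
    mid1: float = 3.0
    rate1: float = 1.0
    mid2: float = 16.0
    rate2: float = 0.4


_DEFAULT_KINETICS = {
    "acetic_acid": AnalyteKinetics(0.05, 1.12, 0.39, 4.17, mid1=3.0, rate1=1.4, mid2=17.0, rate2=0.5),
    "ethanol": AnalyteKinetics(6.50, 0.46, 5.02, 0.39, mid1=3.0, rate1=1.5, mid2=15.0, rate2=0.45),
    "tss": AnalyteKinetics(7.97, 8.30, 9.20, 9.80, mid1=3.0, rate1=1.0, mid2=15.0, rate2=0.35),
    "caffeic_acid": AnalyteKinetics(1.45, 2.20, 2.20, 6.51, mid1=3.0, rate1=0.8, mid2=16.0, rate2=0.30),
    "gallic_acid": AnalyteKinetics(5.35, 5.10, 5.10, 4.62, mid1=3.0, rate1=0.8, mid2=15.0, rate2=0.25),
    "tannic_acid": AnalyteKinetics(145.0, 160.0, 160.0, 200.55, mid1=3.0, rate1=0.8, mid2=16.0, rate2=0.30),
}


@dataclass(frozen=True)
class FermentationSimConfig:
    """Study design and noise levels for the fermentation simulator."""

    days: int = 28
    scans_per_day: int = 3
    wine_addition_day: float = 6.0
    kinetics: dict = field(default_factory=lambda: dict(_DEFAULT_KINETICS))
    jitter_rsd: float = 0.015  # per-sample multiplicative jitter (relative sd)
    batch_effect_sd: float = 0.02  # per-batch multiplicative gain spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.days <= 0 or self.scans_per_day <= 0:
            raise ValueError("days and scans_per_day must be positive")
        if not 0 < self.wine_addition_day < self.days:
            raise ValueError("wine_addition_day must fall inside the run")


@dataclass(frozen=True)
class PureComponentBand:
    """Gaussian absorption band: center (cm^-1), sigma (cm^-1), AU per unit concentration."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if not math.isfinite(self.amplitude):
            raise ValueError("band amplitude must be finite")


@dataclass(frozen=True)
class ScatterNoiseModel:
    """Per-sample scatter (gain/offset/tilt) and per-point noise levels.

    ``noise_sd`` is the absorbance noise at A = 0.  With
    ``photometric=True`` (default) the per-point noise grows as
    10**A with the local absorbance (detector noise is roughly constant
    in transmittance, so absorbance noise explodes in the near-opaque
    water bands); the exponent is capped at A = 2.  Set it to False for
    homoscedastic noise.
    """

    multiplicative_sd: float = 0.05
    offset_sd: float = 0.02
    slope_sd: float = 0.01
    noise_sd: float = 0.002
    photometric: bool = True

    def __post_init__(self) -> None:
        for name in ("multiplicative_sd", "offset_sd", "slope_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "ScatterNoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, photometric=False)


def default_water_bands() -> list[PureComponentBand]:
    """Water-dominated broth background (AU, not per concentration)."""
    return [
        PureComponentBand(6900.0, 190.0, 0.95),
        PureComponentBand(5150.0, 140.0, 1.25),
        PureComponentBand(8500.0, 420.0, 0.12),
        PureComponentBand(6000.0, 300.0, 0.07),
        PureComponentBand(5600.0, 250.0, 0.06),
        PureComponentBand(7500.0, 2600.0, 0.25),  # broad baseline
    ]


def default_analyte_bands() -> dict[str, list[PureComponentBand]]:
    """Pure-component bands at wavenumbers diagnostic for each analyte."""

    def bands(centers, width, amplitude):
        return [PureComponentBand(c, width, amplitude) for c in centers]

    return {
        "acetic_acid": bands([7192, 6664, 5440, 5336, 4376], 25.0, 0.012),
        "ethanol": bands([6744, 5328, 5032, 4656, 4384], 25.0, 0.008),
        "tss": bands([6664, 6600, 5352, 4712, 4480], 25.0, 0.020),
        "caffeic_acid": bands([8424, 6304, 5936, 5600, 4384], 40.0, 0.008),
        "gallic_acid": bands([6360, 5344, 4528, 4352], 25.0, 0.010),
        "tannic_acid": bands([10560, 7656, 6368, 5528, 4400], 40.0, 2.5e-4),
    }


def default_interferent_bands() -> dict[str, list[PureComponentBand]]:
    """Spectra of unmodelled broth constituents (concentrations in [0, 1]).

    ``biomass`` stands in for the acetic-acid bacteria whose cell
    membranes absorb across the CH/CONH/lipid regions; ``metabolite``
    for the pool of minor fermentation products.  Both vary from sample
    to sample but are not reference-analyzed, so a calibration must
    either span them (full-spectrum PLS) or avoid them (selection).
    """
    return {
        "biomass": [
            PureComponentBand(6600.0, 60.0, 0.040),
            PureComponentBand(5800.0, 60.0, 0.040),
            PureComponentBand(4900.0, 50.0, 0.035),
            PureComponentBand(4300.0, 50.0, 0.035),
        ],
        "metabolite": [
            PureComponentBand(7000.0, 50.0, 0.030),
            PureComponentBand(6200.0, 50.0, 0.030),
            PureComponentBand(5500.0, 50.0, 0.025),
            PureComponentBand(4500.0, 50.0, 0.025),
        ],
    }


def _interferent_profiles(t: np.ndarray, days: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-sample concentrations of the unmodelled constituents.

    Biomass follows logistic growth with multiplicative fluctuation;
    the metabolite pool drifts along a smooth random two-harmonic path.
    """
    growth = 1.0 / (1.0 + np.exp(-0.4 * (t - 10.0)))
    biomass = growth * (1.0 + 0.2 * rng.standard_normal(t.size))
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    metabolite = (
        0.5
        + 0.3 * np.sin(2 * np.pi * t / days + phase1)
        + 0.15 * np.sin(4 * np.pi * t / days + phase2)
        + 0.1 * rng.standard_normal(t.size)
    )
    return {"biomass": np.clip(biomass, 0.0, None), "metabolite": np.clip(metabolite, 0.0, None)}


def _segment(t: np.ndarray, lo_t: float, hi_t: float, lo_v: float, hi_v: float, mid: float, rate: float) -> np.ndarray:
    """Logistic segment renormalized to pass exactly through its endpoints."""
    sig = lambda u: 1.0 / (1.0 + np.exp(-rate * (u - mid)))
    s0, s1 = sig(np.array([lo_t])), sig(np.array([hi_t]))
    frac = (sig(t) - s0) / (s1 - s0)
    return lo_v + (hi_v - lo_v) * frac


def trajectory(kin: AnalyteKinetics, t: np.ndarray, wine_day: float, days: float) -> np.ndarray:
    """Noise-free concentration trajectory at times ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    first = t < wine_day
    out[first] = _segment(t[first], 0.0, wine_day, kin.start, kin.end_phase1, kin.mid1, kin.rate1)
    out[~first] = _segment(t[~first], wine_day, days, kin.jump_to, kin.final, kin.mid2, kin.rate2)
    return out


def simulate_profiles(
    config: FermentationSimConfig,
    batch: str = "B1",
    rng: np.random.Generator | None = None,
    batch_gain: dict | None = None,
) -> pd.DataFrame:
    """Per-sample analyte concentrations with timestamps for one batch.

    Returns a frame with ``time_days``, ``batch`` and one column per
    analyte.  Deterministic given the config seed (or the generator
    passed in).  Values are clipped to the calibration ranges.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.days * config.scans_per_day + 1
    t = np.linspace(0.0, float(config.days), n)
    data = {"time_days": t, "batch": np.repeat(batch, n)}
    for analyte, kin in config.kinetics.items():
        clean = trajectory(kin, t, config.wine_addition_day, float(config.days))
        gain = batch_gain.get(analyte, 1.0) if batch_gain else 1.0
        jitter = 1.0 + config.jitter_rsd * rng.standard_normal(n)
        values = clean * gain * jitter
        lo, hi = CALIBRATION_RANGES.get(analyte, (0.0, np.inf))
        data[analyte] = np.clip(values, lo, hi)
    for name, values in _interferent_profiles(t, float(config.days), rng).items():
        data[name] = values
    return pd.DataFrame(data)


def _pure_spectrum(bands: list[PureComponentBand], grid: WavenumberGrid) -> np.ndarray:
    nu = grid.values
    out = np.zeros(grid.count)
    for band in bands:
        if not grid.last <= band.center <= grid.first:
            raise ValueError(f"band center {band.center} cm^-1 outside the grid span")
        out += band.amplitude * np.exp(-0.5 * ((nu - band.center) / band.width) ** 2)
    return out


def simulate_dataset(
    profiles: pd.DataFrame,
    bands: dict[str, list[PureComponentBand]],
    water_bands: list[PureComponentBand],
    scatter: ScatterNoiseModel,
    grid: WavenumberGrid,
    seed: int,
    role: str = ROLE_CALIBRATION,
    interferent_bands: dict[str, list[PureComponentBand]] | None = None,
) -> SpectralDataset:
    """Beer-Lambert mixture spectra plus per-sample scatter and noise.

    ``absorbance = gain * (water + sum_k c_k * pure_k) + offset +
    slope * nu_scaled + noise`` with ``nu_scaled`` the wavenumber mapped
    to [-1, 1].  ``interferent_bands`` name profile columns that absorb
    but are excluded from the reference table (unmodelled broth
    constituents).
    """
    rng = np.random.default_rng(seed)
    analytes = [c for c in profiles.columns if c in bands]
    n = len(profiles)
    water = _pure_spectrum(water_bands, grid) if water_bands else np.zeros(grid.count)
    clean = np.tile(water, (n, 1))
    for analyte in analytes:
        pure = _pure_spectrum(bands[analyte], grid)
        clean += np.outer(profiles[analyte].to_numpy(dtype=float), pure)
    for name, ibands in (interferent_bands or {}).items():
        if name in profiles.columns:
            pure = _pure_spectrum(ibands, grid)
            clean += np.outer(profiles[name].to_numpy(dtype=float), pure)
    gain = 1.0 + scatter.multiplicative_sd * rng.standard_normal(n)
    offset = scatter.offset_sd * rng.standard_normal(n)
    slope = scatter.slope_sd * rng.standard_normal(n)
    nu_scaled = (grid.values - grid.values.mean()) / ((grid.first - grid.last) / 2.0)
    signal = gain[:, None] * clean
    if scatter.photometric:
        noise_scale = scatter.noise_sd * 10.0 ** np.clip(signal, 0.0, 2.0)
    else:
        noise_scale = scatter.noise_sd
    absorbance = (
        signal
        + offset[:, None]
        + np.outer(slope, nu_scaled)
        + noise_scale * rng.standard_normal((n, grid.count))
    )
    batch = (
        profiles["batch"].to_numpy(dtype=object)
        if "batch" in profiles
        else np.repeat("B1", n)
    )
    return SpectralDataset(
        grid=grid,
        absorbance=absorbance,
        references=profiles[analytes].reset_index(drop=True).astype(float),
        batch=batch,
        role=np.repeat(role, n),
    )


def _stride_indices(n: int, k: int) -> np.ndarray:
    """k uniformly strided indices out of n (first and last included)."""
    return np.round(np.linspace(0, n - 1, k)).astype(int)


def make_paper_scale_splits(
    config: FermentationSimConfig | None = None,
    seed: int = 0,
    scatter: ScatterNoiseModel | None = None,
    bands: dict[str, list[PureComponentBand]] | None = None,
    water_bands: list[PureComponentBand] | None = None,
    grid: WavenumberGrid | None = None,
    interferent_bands: dict[str, list[PureComponentBand]] | None = None,
) -> SpectralDataset:
    """Study-sized dataset: 162 calibration samples from two batches
    plus 30 prediction samples from a third, independent batch.

    Each batch is a full 28-day, thrice-daily fermentation run,
    subsampled by uniform stride to the target count (81 + 81 / 30).
    Prediction-set analyte values are clipped into the calibration
    set's per-analyte range, matching an external validation batch
    chosen inside the calibrated domain.
    """
    config = config or FermentationSimConfig()
    scatter = scatter if scatter is not None else ScatterNoiseModel()
    bands = bands or default_analyte_bands()
    water_bands = default_water_bands() if water_bands is None else water_bands
    grid = grid or WavenumberGrid.default()
    if interferent_bands is None:
        interferent_bands = default_interferent_bands()
    root = np.random.SeedSequence(seed)
    prof_seeds = root.spawn(4)

    frames = []
    for b, (name, count) in enumerate([("cal1", 81), ("cal2", 81), ("pred", 30)]):
        rng = np.random.default_rng(prof_seeds[b])
        if name == "pred":
            gains = {a: 1.0 for a in config.kinetics}
        else:
            gains = {a: 1.0 + config.batch_effect_sd * rng.standard_normal() for a in config.kinetics}
        profile = simulate_profiles(config, batch=name, rng=rng, batch_gain=gains)
        frames.append(profile.iloc[_stride_indices(len(profile), count)].reset_index(drop=True))

    cal = pd.concat(frames[:2], ignore_index=True)
    pred = frames[2]
    for analyte in config.kinetics:
        lo, hi = cal[analyte].min(), cal[analyte].max()
        pred[analyte] = pred[analyte].clip(lo, hi)

    spectra_seed = int(np.random.default_rng(prof_seeds[3]).integers(0, 2**31 - 2))
    cal_ds = simulate_dataset(
        cal, bands, water_bands, scatter, grid, seed=spectra_seed,
        role=ROLE_CALIBRATION, interferent_bands=interferent_bands,
    )
    pred_ds = simulate_dataset(
        pred, bands, water_bands, scatter, grid, seed=spectra_seed + 1,
        role=ROLE_PREDICTION, interferent_bands=interferent_bands,
    )
    return SpectralDataset(
        grid=grid,
        absorbance=np.vstack([cal_ds.absorbance, pred_ds.absorbance]),
        references=pd.concat([cal_ds.references, pred_ds.references], ignore_index=True),
        batch=np.concatenate([cal_ds.batch, pred_ds.batch]),
        role=np.concatenate([cal_ds.role, pred_ds.role]),
    )


def make_planted_dataset(
    n_cal: int = 40,
    n_pred: int = 20,
    n_variables: int = 50,
    n_informative: int = 3,
    seed: int = 0,
    noise_sd: float = 0.0,
):
    """Planted-truth regression data for selection-recovery experiments.

    The response is an exact (optionally lightly noised) linear
    function of ``n_informative`` randomly placed columns; all other
    columns are pure noise.  Returns
    ``(X_cal, y_cal, X_pred, y_pred, planted_indices)``.
    """
    rng = np.random.default_rng(seed)
    planted = np.sort(rng.choice(n_variables, size=n_informative, replace=False))
    beta = rng.uniform(1.0, 2.0, size=n_informative) * rng.choice([-1.0, 1.0], size=n_informative)
    X_cal = rng.standard_normal((n_cal, n_variables))
    X_pred = rng.standard_normal((n_pred, n_variables))
    y_cal = X_cal[:, planted] @ beta + noise_sd * rng.standard_normal(n_cal)
    y_pred = X_pred[:, planted] @ beta + noise_sd * rng.standard_normal(n_pred)
    return X_cal, y_cal, X_pred, y_pred, planted
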