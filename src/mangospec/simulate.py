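"""Synthetic mango quality records and NIR spectra for end-to-end testing.

No measurement data accompany the study design this package targets, so this
module generates datasets with the same statistical structure: a drop-test
design (heights 0.5/1.0/1.5 m plus an undamaged control, observation days
1/3/5, 20 fruits per group), per-group attribute distributions matching the
published group means and standard deviations, and absorbance spectra on the
256-band 900-1700 nm instrument grid built from known physics:

* broad water bands near 970 and 1450 nm, a starch/sugar band near 1190 nm;
* water-band depth decreasing with drop height (bruised tissue absorbs less);
* sugar-band depth affine in TSS, the 1450 nm O-H band affine in TA, and the
  baseline slope affine in firmness;
* multiplicative scatter (random per-sample slope/offset) plus additive
  per-band noise.

Ground-truth band centres and attribute coefficients are carried alongside
the data so recovery tests can check that the chemometric chain finds them.
All randomness flows from a single seed; a fixed seed reproduces the dataset
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .hsi_io import (
    Hypercube,
    ReferenceFrames,
    RoiMask,
    Spectrum,
    WavelengthGrid,
    absorbance_to_reflectance,
    default_grid,
)
from .preprocess import SpectraMatrix
from .quality import QualityRecord, ripening_index

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "TABLE_STATS",
    "simulate_quality",
    "simulate_spectrum",
    "simulate_cube",
    "generate_dataset",
]

# Published per-group attribute statistics: (height m, day) ->
# {attribute: (mean, sd)}.  Firmness in N, TSS in degrees Brix, TA in
# percent citric acid, chroma as CIE delta-b*.
TABLE_STATS: dict[tuple[float, int], dict[str, tuple[float, float]]] = {
    (0.5, 1): {"firmness": (48.79, 7.09), "tss": (10.05, 1.01),
               "ta": (1.99, 0.16), "chroma": (38.03, 9.86)},
    (0.5, 3): {"firmness": (40.85, 6.42), "tss": (11.27, 1.16),
               "ta": (1.59, 0.42), "chroma": (47.66, 5.86)},
    (0.5, 5): {"firmness": (35.31, 5.94), "tss": (11.31, 1.33),
               "ta": (1.26, 0.15), "chroma": (51.71, 4.00)},
    (1.0, 1): {"firmness": (44.16, 7.11), "tss": (10.54, 0.51),
               "ta": (1.89, 0.17), "chroma": (46.25, 8.38)},
    (1.0, 3): {"firmness": (37.40, 7.31), "tss": (11.76, 1.12),
               "ta": (1.40, 0.11), "chroma": (49.22, 4.95)},
    (1.0, 5): {"firmness": (30.32, 5.28), "tss": (12.46, 0.85),
               "ta": (0.94, 0.19), "chroma": (54.52, 5.01)},
    (1.5, 1): {"firmness": (40.51, 6.19), "tss": (11.19, 0.60),
               "ta": (1.71, 0.14), "chroma": (50.92, 5.83)},
    (1.5, 3): {"firmness": (35.66, 6.24), "tss": (11.87, 0.91),
               "ta": (1.12, 0.18), "chroma": (52.24, 4.45)},
    (1.5, 5): {"firmness": (27.72, 4.08), "tss": (13.20, 2.11),
               "ta": (0.35, 0.13), "chroma": (56.51, 2.79)},
}

_ATTRS = ("firmness", "tss", "ta", "chroma")

# Attribute correlation structure (firmness, tss, ta, chroma): ripening
# physiology couples softening with sugar accumulation and acid loss.  The
# published table gives marginals only; these correlations are a simulation
# choice, documented in the methods note.
_CORR = np.array(
    [
        [1.0, -0.5, 0.5, 0.0],
        [-0.5, 1.0, 0.0, 0.0],
        [0.5, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


def _control_stats() -> dict[tuple[float, int], dict[str, tuple[float, float]]]:
    """Control-group statistics: 0.5 m means pulled halfway back to day 1.

    Undamaged fruit ripens in the same direction but more slowly; no control
    table is published, so the control mean for day d is the day-1 mean of
    the gentlest drop plus half its day trend.  Synthetic-only construction.
    """
    out = {}
    for d in (1, 3, 5):
        base = TABLE_STATS[(0.5, 1)]
        trend = TABLE_STATS[(0.5, d)]
        out[(0.0, d)] = {
            a: (base[a][0] + 0.5 * (trend[a][0] - base[a][0]), trend[a][1])
            for a in _ATTRS
        }
    return out


@dataclass(frozen=True)
class SimConfig:
    """Study design, attribute statistics and the spectral forward model."""

    heights: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)   # 0 = control
    days: tuple[int, ...] = (1, 3, 5)
    n_fruits: int = 20
    stats: dict = field(
        default_factory=lambda: {**TABLE_STATS, **_control_stats()}
    )
    # spectral forward model ------------------------------------------------
    band_centers: tuple[float, ...] = (970.0, 1190.0, 1450.0)   # nm
    band_widths: tuple[float, ...] = (45.0, 15.0, 55.0)         # Gaussian sigma, nm
    depth_970: tuple[float, float] = (0.50, -0.01)    # base, per-metre height slope
    depth_1190: tuple[float, float] = (0.30, 0.02)    # base, per-Brix TSS slope
    depth_1450: tuple[float, float, float] = (0.60, 0.02, -0.01)  # base, TA, height
    baseline: tuple[float, float] = (0.35, 0.003)     # level base, per-N firmness
    baseline_slope: tuple[float, float] = (0.03, 0.0007)  # tilt base, per-N firmness
    # bruise-severity signature: browning / water redistribution in damaged
    # tissue adds a broad absorption whose amplitude grows as the fruit's
    # ripening index falls (more advanced ripening = more severe damage).
    # Severe bruising is threshold-like (cell rupture), so a second, sharper
    # component switches on as RPI crosses into the seriously-damaged range.
    damage_band: tuple[float, float] = (1350.0, 60.0)   # center, sigma (nm)
    damage_coeff: tuple[float, float] = (7.0, 0.02)     # RPI pivot, AU per RPI unit
    rupture_coeff: tuple[float, float, float] = (5.0, 0.06, 0.10)
    # rupture logistic: (RPI midpoint, width, amplitude AU)
    scatter_slope_sd: float = 0.05    # multiplicative scatter, per sample
    scatter_offset_sd: float = 0.02   # additive scatter offset, AU
    noise_sd: float = 0.002           # additive per-band noise, AU (ROI mean)
    pixel_noise_sd: float = 0.5       # per-pixel reflectance noise, %R (cubes)
    seed: int = 0

    def grid(self) -> WavelengthGrid:
        return default_grid()


@dataclass
class SyntheticDataset:
    """Quality records with matched spectra plus generator ground truth."""

    records: list[QualityRecord]
    spectra: SpectraMatrix
    ground_truth: dict


def simulate_quality(cfg: SimConfig = SimConfig(),
                     rng: np.random.Generator | None = None) -> list[QualityRecord]:
    """Draw per-fruit quality attributes group by group.

    Within each (height, day) group the four attributes are jointly normal
    with the configured means/sds and the ripening correlation structure,
    truncated at physical bounds (firmness, TSS positive; TA >= 0.05%).
    RPI and the damage label are derived per fruit.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    records: list[QualityRecord] = []
    for height in cfg.heights:
        for day in cfg.days:
            key = (height, day)
            if key not in cfg.stats:
                raise KeyError(f"no attribute statistics for group {key}")
            stats = cfg.stats[key]
            mean = np.array([stats[a][0] for a in _ATTRS])
            sd = np.array([stats[a][1] for a in _ATTRS])
            if np.all(sd == 0):
                draws = np.tile(mean, (cfg.n_fruits, 1))
            else:
                cov = _CORR * np.outer(sd, sd)
                draws = rng.multivariate_normal(mean, cov, size=cfg.n_fruits,
                                                method="svd")
            # physical truncation
            draws[:, 0] = np.maximum(draws[:, 0], 1.0)    # firmness
            draws[:, 1] = np.maximum(draws[:, 1], 1.0)    # tss
            draws[:, 2] = np.maximum(draws[:, 2], 0.05)   # ta
            for j in range(cfg.n_fruits):
                f, tss, ta, chroma = draws[j]
                records.append(
                    QualityRecord(
                        fruit_id=f"h{height:g}_d{day}_{j:03d}",
                        drop_height=height,
                        day=day,
                        firmness=float(f),
                        tss=float(tss),
                        ta=float(ta),
                        chroma=float(chroma),
                    )
                )
    return records


def _latent_spectrum(record: QualityRecord, cfg: SimConfig,
                     wl: np.ndarray) -> np.ndarray:
    """Noise-free absorbance: baseline plus attribute-driven Gaussian bands."""
    x = (wl - 1300.0) / 400.0       # normalised axis, roughly [-1, 1]
    level = cfg.baseline[0] + cfg.baseline[1] * (record.firmness - 40.0)
    tilt = cfg.baseline_slope[0] + cfg.baseline_slope[1] * (record.firmness - 40.0)
    spec = level + tilt * x
    depths = (
        cfg.depth_970[0] + cfg.depth_970[1] * record.drop_height,
        cfg.depth_1190[0] + cfg.depth_1190[1] * record.tss,
        cfg.depth_1450[0] + cfg.depth_1450[1] * record.ta
        + cfg.depth_1450[2] * record.drop_height,
    )
    for depth, mu, sigma in zip(depths, cfg.band_centers, cfg.band_widths):
        spec = spec + depth * np.exp(-0.5 * ((wl - mu) / sigma) ** 2)
    if record.rpi is not None:
        pivot, coeff = cfg.damage_coeff
        mid, width, boost = cfg.rupture_coeff
        amp = coeff * (pivot - record.rpi)
        if boost:
            amp += boost / (1.0 + np.exp((record.rpi - mid) / width))
        mu, sigma = cfg.damage_band
        spec = spec + amp * np.exp(-0.5 * ((wl - mu) / sigma) ** 2)
    return spec


def simulate_spectrum(record: QualityRecord, cfg: SimConfig = SimConfig(),
                      rng: np.random.Generator | None = None) -> Spectrum:
    """One absorbance spectrum: latent bands, then scatter and noise."""
    rng = rng or np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    latent = _latent_spectrum(record, cfg, grid.values)
    slope = rng.normal(1.0, cfg.scatter_slope_sd) if cfg.scatter_slope_sd else 1.0
    offset = rng.normal(0.0, cfg.scatter_offset_sd) if cfg.scatter_offset_sd else 0.0
    noisy = slope * latent + offset
    if cfg.noise_sd:
        noisy = noisy + rng.normal(0.0, cfg.noise_sd, size=grid.count)
    return Spectrum(sample_id=record.fruit_id, grid=grid, values=noisy,
                    kind="absorbance")


def simulate_cube(
    record: QualityRecord,
    cfg: SimConfig = SimConfig(),
    shape: tuple[int, int] = (32, 32),
    rng: np.random.Generator | None = None,
) -> tuple[Hypercube, ReferenceFrames, RoiMask]:
    """Small raw cube + reference frames + elliptical bruise ROI for one fruit.

    The fruit's latent absorbance spectrum is converted to percent
    reflectance, perturbed per pixel, and pushed through the affine
    instrument model raw = B + R/100 * (W - B) with smooth per-line white
    and dark frames.  Calibrating with the emitted frames and averaging over
    the emitted mask recovers the spectrum up to pixel noise / sqrt(ROI size).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    lines, samples = shape
    grid = cfg.grid()
    p = grid.count

    latent_A = _latent_spectrum(record, cfg, grid.values)
    refl = absorbance_to_reflectance(latent_A)          # %R, bruise tissue
    refl_bg = 0.7 * refl + 8.0                          # surrounding flesh

    s_axis = np.linspace(-1, 1, samples)[:, None]
    w_axis = np.linspace(-1, 1, p)[None, :]
    white = 3000.0 * (0.9 + 0.05 * (1 - s_axis**2)) * (1.0 - 0.08 * w_axis**2)
    dark = 120.0 + 10.0 * (1 - s_axis**2) + 0.0 * w_axis

    ly, lx = np.mgrid[0:lines, 0:samples]
    cy, cx = (lines - 1) / 2.0, (samples - 1) / 2.0
    mask = (((ly - cy) / (lines / 4.0)) ** 2
            + ((lx - cx) / (samples / 4.0)) ** 2) <= 1.0
    if not mask.any():
        raise ValueError("ROI ellipse does not cover any pixel")

    R = np.where(mask[:, :, None], refl[None, None, :], refl_bg[None, None, :])
    if cfg.pixel_noise_sd:
        R = R + rng.normal(0.0, cfg.pixel_noise_sd, size=R.shape)
    raw = dark[None, :, :] + R / 100.0 * (white - dark)[None, :, :]
    cube = Hypercube(raw, grid, kind="raw", cube_id=record.fruit_id)
    return cube, ReferenceFrames(white=white, dark=dark), RoiMask(mask, "bruise")


def generate_dataset(cfg: SimConfig = SimConfig()) -> SyntheticDataset:
    """Full synthetic study: records plus one spectrum per fruit."""
    rng = np.random.default_rng(cfg.seed)
    records = simulate_quality(cfg, rng)
    grid = cfg.grid()
    values = np.empty((len(records), grid.count))
    for i, rec in enumerate(records):
        values[i] = simulate_spectrum(rec, cfg, rng).values
    spectra = SpectraMatrix(
        [r.fruit_id for r in records], grid, values, provenance="raw"
    )
    truth = {
        "band_centers_nm": list(cfg.band_centers),
        "band_widths_nm": list(cfg.band_widths),
        "depth_970": list(cfg.depth_970),
        "depth_1190": list(cfg.depth_1190),
        "depth_1450": list(cfg.depth_1450),
        "baseline": list(cfg.baseline),
        "baseline_slope": list(cfg.baseline_slope),
        "attribute_bands": {"tss": 1190.0, "ta": 1450.0},
    }
    return SyntheticDataset(records=records, spectra=spectra, ground_truth=truth)
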