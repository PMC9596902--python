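"""Synthetic cadaver cohorts with known ground truth.

The generator emulates the statistical structure the calibration
pipeline assumes, so every downstream operation can be tested against a
known generative model:

* nested sampling design — cadavers, left/right knees, three joint
  surfaces per knee with a 9/8/2 femur/tibia/patella site split
  (19 locations per knee);
* a latent degeneration severity per location in [0, 1], built from
  nested random intercepts (cadaver, knee, surface) plus site-level
  variation on a logit scale, shifted so that mildly degenerated
  locations dominate (right-skewed, clearly non-normal score
  distributions);
* reference properties as monotone maps of severity into their valid
  ranges — Safranin-O optical density decreasing into [0.2, 1.5],
  ICRS/OARSI/Mankin increasing into [0,4]/[0,6]/[0,13] — plus bounded
  observation noise;
* absorbance spectra on the merged two-spectrometer grid, composed from
  a fixed library of Gaussian absorption bands (water near 1.40 and
  1.90 μm, matrix bands between 0.8 and 1.8 μm) whose amplitudes are
  linear in severity, a per-spectrum multiplicative scatter factor and
  additive detector noise (10 co-added acquisitions per recorded
  spectrum);
* a poor-contact contamination mechanism for ex vivo arthroscopic
  spectra: a contaminated spectrum gains an amplified water band at
  1.40 μm (saline between probe and cartilage) and extra scatter.

The ground truth (severity, contamination flags, band model) is returned
alongside the dataset and is never consumed by the pipeline under test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectral_data import (
    META_COLUMNS,
    SpectralDataset,
    Spectrum,
    make_nir_grid,
    make_vis_grid,
    merged_grid,
)

logger = logging.getLogger(__name__)

SITES_PER_SURFACE = {"femur": 9, "tibia": 8, "patella": 2}

#: fixed, versioned band library: (centre μm, width μm, base amplitude,
#: severity slope).  Water bands grow with degeneration (tissue water
#: increases as the collagen/PG matrix degrades); matrix bands shrink.
BAND_LIBRARY: tuple[tuple[float, float, float, float], ...] = (
    (1.40, 0.055, 0.35, 0.25),   # water 1st overtone
    (1.90, 0.100, 0.55, 0.30),   # water combination band
    (0.91, 0.045, 0.18, -0.10),  # CH/collagen overtone
    (1.18, 0.060, 0.22, -0.14),  # matrix band
    (1.45, 0.050, 0.12, -0.08),  # matrix shoulder under the water band
    (1.73, 0.060, 0.20, -0.12),  # CH combination
)

WATER_PEAK_INDEX = 0  # index of the 1.40 μm band in BAND_LIBRARY


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; defaults mirror the emulated study design."""

    n_cadavers: int = 9
    sites_per_surface: tuple[int, int, int] = (9, 8, 2)  # femur, tibia, patella
    replicates_ex_vivo: int = 15
    replicates_in_vitro: int = 3
    noise_sd: float = 0.010          # additive detector noise per acquisition, AU
    coadds: int = 10                 # acquisitions averaged per recorded spectrum
    cadaver_sd: float = 0.55         # latent-severity random intercepts (logit scale)
    knee_sd: float = 0.25
    surface_sd: float = 0.35
    site_sd: float = 0.80
    severity_shift: float = -0.8     # logit-scale shift → right-skewed severities
    scatter_sd: float = 0.06         # log-scale multiplicative scatter, in vitro
    ex_vivo_scatter_sd: float = 0.12  # extra log-scatter for arthroscopic spectra
    contamination_rate: float = 0.30  # fraction of ex vivo spectra with poor contact
    contamination_strength: float = 0.8  # mean added 1.40 μm band amplitude, AU
    water_peak_center: float = 1.40
    merge_cut: float = 1.05
    reference_noise: tuple[float, float, float, float] = (0.05, 0.15, 0.25, 0.50)
    integer_scores: bool = False     # stress-test mode: round histologic scores
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contamination_rate < 1:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.n_cadavers < 1:
            raise ValueError("n_cadavers must be ≥ 1")
        for sd in (self.noise_sd, self.cadaver_sd, self.knee_sd, self.surface_sd,
                   self.site_sd, self.scatter_sd, self.ex_vivo_scatter_sd):
            if sd < 0:
                raise ValueError("standard deviations must be ≥ 0")
        if min(self.sites_per_surface) < 1:
            raise ValueError("site counts must be ≥ 1")


@dataclass
class GroundTruth:
    """Generative state stored alongside a cohort; not pipeline input."""

    severity: pd.DataFrame           # location columns + 'severity'
    contaminated: np.ndarray         # bool per spectrum row (dataset order; in vitro rows False)
    band_library: tuple = BAND_LIBRARY
    variance_components: dict[str, float] = field(default_factory=dict)


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def clean_spectrum(wl: np.ndarray, severity: float) -> np.ndarray:
    """Noise-free absorbance for one location: baseline + band library."""
    out = 0.30 + 0.20 * (wl - wl[0]) / (wl[-1] - wl[0])
    for center, width, base, slope in BAND_LIBRARY:
        out = out + (base + slope * severity) * _gaussian(wl, center, width)
    return out


def contaminate(spectrum: Spectrum, strength: float,
                rng: np.random.Generator | None = None,
                scatter_sd: float = 0.2,
                water_peak_center: float = 1.40) -> Spectrum:
    """Apply the poor-contact mechanism to one spectrum.

    Adds a ``strength``-scaled Gaussian water band at the 1.40 μm centre
    and rescales by an extra multiplicative scatter draw (identity when
    ``rng`` is None).  Absorbance at the water peak strictly increases
    for ``strength > 0``.
    """
    if strength < 0:
        raise ValueError("strength must be ≥ 0")
    wl = spectrum.grid.values
    scatter = 1.0 if rng is None else float(np.exp(rng.normal(0.0, scatter_sd)))
    absorbance = scatter * (spectrum.absorbance + strength * _gaussian(wl, water_peak_center, 0.05))
    return Spectrum(grid=spectrum.grid, absorbance=absorbance,
                    location=spectrum.location, replicate=spectrum.replicate,
                    setting=spectrum.setting)


def _severity_table(params: SynthParams, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counts = dict(zip(("femur", "tibia", "patella"), params.sites_per_surface))
    for c in range(params.n_cadavers):
        cid = f"C{c + 1:02d}"
        u_c = rng.normal(0.0, params.cadaver_sd)
        for knee in ("left", "right"):
            u_k = rng.normal(0.0, params.knee_sd)
            for surface in ("femur", "tibia", "patella"):
                u_s = rng.normal(0.0, params.surface_sd)
                for site in range(1, counts[surface] + 1):
                    latent = (params.severity_shift + u_c + u_k + u_s
                              + rng.normal(0.0, params.site_sd))
                    rows.append({
                        "cadaver_id": cid, "knee_side": knee, "surface": surface,
                        "site_index": site, "severity": 1.0 / (1.0 + np.exp(-latent)),
                    })
    return pd.DataFrame(rows)


def _references(severity: pd.DataFrame, params: SynthParams,
                rng: np.random.Generator) -> pd.DataFrame:
    s = severity["severity"].to_numpy()
    n = len(s)
    sd_pg, sd_icrs, sd_oarsi, sd_mankin = params.reference_noise
    refs = severity[["cadaver_id", "knee_side", "surface", "site_index"]].copy()
    refs["pg_od"] = np.clip(1.5 - 1.3 * s + rng.normal(0, sd_pg, n), 0.2, 1.5)
    refs["icrs"] = np.clip(4.0 * s + rng.normal(0, sd_icrs, n), 0.0, 4.0)
    refs["oarsi"] = np.clip(6.0 * s + rng.normal(0, sd_oarsi, n), 0.0, 6.0)
    refs["mankin"] = np.clip(13.0 * s + rng.normal(0, sd_mankin, n), 0.0, 13.0)
    if params.integer_scores:
        for col in ("icrs", "oarsi", "mankin"):
            refs[col] = refs[col].round()
    return refs


def simulate_cohort(params: SynthParams) -> tuple[SpectralDataset, GroundTruth]:
    """Generate a full synthetic cohort; deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    grid = merged_grid(make_vis_grid(), make_nir_grid(), params.merge_cut)
    wl = grid.values
    severity = _severity_table(params, rng)
    refs = _references(severity, params, rng)

    noise_sd_eff = params.noise_sd / np.sqrt(params.coadds)
    meta_rows: list[dict] = []
    spectra: list[np.ndarray] = []
    contaminated: list[bool] = []

    for _, loc in severity.iterrows():
        clean = clean_spectrum(wl, loc["severity"])
        base_meta = {k: loc[k] for k in ("cadaver_id", "knee_side", "surface", "site_index")}
        # in vitro: goniometer-fixed plug, reliable probe contact
        for rep in range(1, params.replicates_in_vitro + 1):
            scatter = np.exp(rng.normal(0.0, params.scatter_sd))
            trace = scatter * clean + rng.normal(0.0, noise_sd_eff, len(wl))
            meta_rows.append({**base_meta, "replicate": rep, "setting": "in_vitro"})
            spectra.append(trace)
            contaminated.append(False)
        # ex vivo: arthroscopic acquisition, contact not guaranteed
        for rep in range(1, params.replicates_ex_vivo + 1):
            scatter = np.exp(rng.normal(0.0, np.hypot(params.scatter_sd,
                                                      params.ex_vivo_scatter_sd)))
            trace = scatter * clean + rng.normal(0.0, noise_sd_eff, len(wl))
            is_bad = bool(rng.random() < params.contamination_rate)
            if is_bad:
                strength = params.contamination_strength * np.exp(rng.normal(0.0, 0.3))
                extra = np.exp(rng.normal(0.0, 0.2))
                trace = extra * (trace + strength * _gaussian(wl, params.water_peak_center, 0.05))
            meta_rows.append({**base_meta, "replicate": rep, "setting": "ex_vivo"})
            spectra.append(trace)
            contaminated.append(is_bad)

    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    dataset = SpectralDataset(
        grid=grid, meta=meta, absorbance=np.vstack(spectra), references=refs,
        provenance={"generator": "cartigrade.synthetic_cohort", "seed": params.seed,
                    "n_cadavers": params.n_cadavers,
                    "contamination_rate": params.contamination_rate},
    )
    truth = GroundTruth(
        severity=severity,
        contaminated=np.asarray(contaminated, dtype=bool),
        variance_components={
            "cadaver": params.cadaver_sd ** 2, "knee": params.knee_sd ** 2,
            "surface": params.surface_sd ** 2, "site": params.site_sd ** 2,
        },
    )
    return dataset, truth


def ex_vivo_contamination_flags(dataset: SpectralDataset, truth: GroundTruth) -> np.ndarray:
    """Contamination flags restricted to the ex vivo rows of a cohort."""
    mask = (dataset.meta["setting"] == "ex_vivo").to_numpy()
    return truth.contaminated[mask]
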