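"""Spectral preprocessing operators and the candidate-pipeline grid.

Each candidate pipeline is a ``PreprocessConfig``: a scatter-correction
choice (none, SNV, or localized SNV with a given window), a third-degree
Savitzky–Golay filter with derivative order 0/1/2 and an odd window, and
a set of retained wavelength intervals.  Operators are applied in the
fixed order scatter correction → SG filter → trim; trimming last keeps
derivative edge artifacts away from the interior of the retained bands.

The default search grid is the Cartesian product of 8 scatter options
(none, SNV, LSNV windows 2,4,…,12), 3 derivative orders, the 22 odd SG
windows 5..47, and 4 region sets — 2112 configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectral_data import CartigradeError, SpectralDataset, Spectrum, WavelengthGrid

logger = logging.getLogger(__name__)

LSNV_WINDOWS = (2, 4, 6, 8, 10, 12)
SG_WINDOWS = tuple(range(5, 48, 2))
SG_DERIVS = (0, 1, 2)

#: the four candidate retained-region sets (μm)
RANGE_SETS: tuple[tuple[tuple[float, float], ...], ...] = (
    ((0.70, 1.90),),
    ((0.75, 1.85),),
    ((0.70, 1.375), (1.525, 1.90)),
    ((0.75, 1.375), (1.525, 1.85)),
)


class DegenerateSpectrumError(CartigradeError):
    """A spectrum (or segment) has zero variance where variance is required."""


class EmptySelectionError(CartigradeError):
    """Trimming removed every wavelength."""


@dataclass(frozen=True)
class PreprocessConfig:
    """One point of the preprocessing search grid."""

    scatter: str = "none"  # none | snv | lsnv
    lsnv_window: int | None = None
    sg_deriv: int = 0
    sg_window: int = 5
    sg_degree: int = 3
    ranges: tuple[tuple[float, float], ...] = RANGE_SETS[0]

    def __post_init__(self) -> None:
        if self.scatter not in ("none", "snv", "lsnv"):
            raise ValueError(f"unknown scatter option {self.scatter!r}")
        if self.scatter == "lsnv":
            if self.lsnv_window not in LSNV_WINDOWS:
                raise ValueError(f"lsnv window must be one of {LSNV_WINDOWS}")
        elif self.lsnv_window is not None:
            raise ValueError("lsnv_window only applies when scatter='lsnv'")
        if self.sg_deriv not in SG_DERIVS:
            raise ValueError("sg_deriv must be 0, 1 or 2")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_degree:
            raise ValueError("sg_window must be odd and > sg_degree")
        ranges = tuple((float(lo), float(hi)) for lo, hi in self.ranges)
        object.__setattr__(self, "ranges", ranges)
        for lo, hi in ranges:
            if not lo < hi:
                raise ValueError(f"range ({lo}, {hi}) is not increasing")
        for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
            if lo2 <= hi:
                raise ValueError("ranges must be non-overlapping and increasing")

    def describe(self) -> str:
        scatter = self.scatter if self.scatter != "lsnv" else f"lsnv{self.lsnv_window}"
        bands = "+".join(f"{lo:g}-{hi:g}" for lo, hi in self.ranges)
        return f"{scatter}|d{self.sg_deriv}w{self.sg_window}|{bands}"


@dataclass(frozen=True)
class PipelineGrid:
    """Deterministically ordered, duplicate-free collection of configs."""

    configs: tuple[PreprocessConfig, ...]

    def __post_init__(self) -> None:
        if len(set(self.configs)) != len(self.configs):
            raise ValueError("duplicate configs in grid")

    def __len__(self) -> int:
        return len(self.configs)

    def __iter__(self):
        return iter(self.configs)


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------


def savitzky_golay(absorbance: np.ndarray, window: int, deriv: int, degree: int = 3) -> np.ndarray:
    """Savitzky–Golay smoothing / derivative filter.

    Derivatives are expressed per grid step (``delta=1``).  At the edges
    the polynomial is fitted over the first/last full window and
    evaluated at the edge positions (one-sided fit, no padding).  Accepts
    a vector or a (n_spectra × n_wavelengths) matrix.
    """
    absorbance = np.asarray(absorbance, dtype=float)
    if window % 2 == 0 or window <= degree:
        raise ValueError(f"window must be odd and > degree, got window={window} degree={degree}")
    if absorbance.shape[-1] < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(absorbance, window, degree, deriv=deriv, delta=1.0,
                         axis=-1, mode="interp")


def snv(absorbance: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum (x − mean) / sample std."""
    absorbance = np.asarray(absorbance, dtype=float)
    mean = absorbance.mean(axis=-1, keepdims=True)
    std = absorbance.std(axis=-1, keepdims=True, ddof=1)
    if np.any(std <= 0) or not np.all(np.isfinite(std)):
        raise DegenerateSpectrumError("constant spectrum: SNV undefined (zero variance)")
    return (absorbance - mean) / std


def lsnv(absorbance: np.ndarray, window: int) -> np.ndarray:
    """Localized SNV: SNV applied within contiguous disjoint segments.

    The spectrum is split into consecutive segments of ``window`` points;
    a short remainder is attached to the final segment.  With
    ``window >= len(spectrum)`` this reduces exactly to plain SNV.
    """
    absorbance = np.asarray(absorbance, dtype=float)
    n = absorbance.shape[-1]
    if window < 2:
        raise ValueError("lsnv window must be ≥ 2")
    if n < 2:
        raise ValueError("spectrum too short for LSNV")
    if window >= n:
        return snv(absorbance)
    starts = list(range(0, n - n % window, window))
    out = np.empty_like(absorbance)
    for i, s in enumerate(starts):
        e = s + window if i < len(starts) - 1 else n  # remainder joins last segment
        seg = absorbance[..., s:e]
        std = seg.std(axis=-1, keepdims=True, ddof=1)
        if np.any(std <= 0):
            raise DegenerateSpectrumError(f"locally constant segment {i} ({s}:{e}): LSNV undefined")
        out[..., s:e] = (seg - seg.mean(axis=-1, keepdims=True)) / std
    return out


def trim_mask(grid: WavelengthGrid, ranges: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Boolean mask of wavelengths inside the closed intervals."""
    wl = grid.values
    mask = np.zeros(len(wl), dtype=bool)
    for lo, hi in ranges:
        mask |= (wl >= lo - 1e-12) & (wl <= hi + 1e-12)
    return mask


def trim_regions(spectrum: Spectrum, ranges) -> Spectrum:
    """Retain exactly the wavelengths inside the closed intervals."""
    ranges = tuple((float(lo), float(hi)) for lo, hi in ranges)
    mask = trim_mask(spectrum.grid, ranges)
    if not mask.any():
        raise EmptySelectionError(f"ranges {ranges} select no wavelengths")
    grid = WavelengthGrid(spectrum.grid.values[mask], spectrum.grid.resolution)
    return replace(spectrum, grid=grid, absorbance=spectrum.absorbance[mask])


# ---------------------------------------------------------------------------
# pipeline application
# ---------------------------------------------------------------------------


def apply_config_matrix(
    absorbance: np.ndarray, grid: WavelengthGrid, config: PreprocessConfig
) -> tuple[np.ndarray, WavelengthGrid]:
    """Run one config on a spectra matrix: scatter → SG filter → trim."""
    x = np.asarray(absorbance, dtype=float)
    if config.scatter == "snv":
        x = snv(x)
    elif config.scatter == "lsnv":
        x = lsnv(x, config.lsnv_window)
    x = savitzky_golay(x, config.sg_window, config.sg_deriv, config.sg_degree)
    mask = trim_mask(grid, config.ranges)
    if not mask.any():
        raise EmptySelectionError(f"ranges {config.ranges} select no wavelengths")
    out_grid = WavelengthGrid(grid.values[mask], grid.resolution)
    return x[..., mask], out_grid


def apply_config(dataset: SpectralDataset, config: PreprocessConfig) -> SpectralDataset:
    """Preprocess every spectrum of a dataset; metadata is untouched."""
    try:
        matrix, grid = apply_config_matrix(dataset.absorbance, dataset.grid, config)
    except DegenerateSpectrumError:
        # rerun row-wise to attach the offending spectrum's identity
        for i in range(dataset.n_spectra):
            try:
                apply_config_matrix(dataset.absorbance[i], dataset.grid, config)
            except DegenerateSpectrumError as exc:
                label = dataset.location_labels().iloc[i]
                raise DegenerateSpectrumError(f"spectrum {label} (row {i}): {exc}") from exc
        raise
    return SpectralDataset(
        grid=grid,
        meta=dataset.meta.copy(),
        absorbance=matrix,
        references=dataset.references,
        provenance=dict(dataset.provenance),
    )


# ---------------------------------------------------------------------------
# grid enumeration and named presets
# ---------------------------------------------------------------------------


def enumerate_grid(
    scatter_options=None, deriv_options=SG_DERIVS, window_options=SG_WINDOWS,
    range_options=RANGE_SETS,
) -> PipelineGrid:
    """Cartesian product of the option axes in deterministic order.

    ``scatter_options`` entries are ``"none"``, ``"snv"`` or
    ``("lsnv", window)``; the default covers none + SNV + the six LSNV
    windows.  Duplicate options are dropped with a warning.
    """
    if scatter_options is None:
        scatter_options = ["none", "snv"] + [("lsnv", w) for w in LSNV_WINDOWS]

    def dedup(name, opts):
        seen, out = set(), []
        for o in opts:
            key = tuple(o) if isinstance(o, (list, tuple)) else o
            if key in seen:
                logger.warning("duplicate %s option %r dropped", name, o)
                continue
            seen.add(key)
            out.append(o)
        if not out:
            raise ValueError(f"no {name} options supplied")
        return out

    scatter_options = dedup("scatter", scatter_options)
    deriv_options = dedup("deriv", deriv_options)
    window_options = dedup("window", window_options)
    range_options = dedup("range", [tuple(map(tuple, r)) for r in range_options])

    configs = []
    for sc in scatter_options:
        if isinstance(sc, (list, tuple)):
            scatter, lsnv_window = sc
        else:
            scatter, lsnv_window = sc, None
        for ranges in range_options:
            for deriv in deriv_options:
                for window in window_options:
                    configs.append(PreprocessConfig(
                        scatter=scatter, lsnv_window=lsnv_window, sg_deriv=deriv,
                        sg_window=window, ranges=ranges,
                    ))
    return PipelineGrid(tuple(configs))


def _preset(lsnv_window, deriv, window, ranges) -> PreprocessConfig:
    return PreprocessConfig(scatter="lsnv", lsnv_window=lsnv_window,
                            sg_deriv=deriv, sg_window=window, ranges=ranges)


#: optimal published pipelines for the regression models, keyed by property
REGRESSION_PRESETS: dict[str, PreprocessConfig] = {
    "pg_od": _preset(10, 1, 23, RANGE_SETS[0]),
    "icrs": _preset(6, 2, 15, RANGE_SETS[2]),
    "oarsi": _preset(2, 0, 47, RANGE_SETS[2]),
    "mankin": _preset(6, 2, 15, RANGE_SETS[2]),
}

#: optimal published pipelines for the poor-contact classifiers
CLASSIFIER_PRESETS: dict[str, PreprocessConfig] = {
    "pg_od": _preset(6, 0, 35, RANGE_SETS[2]),
    "icrs": _preset(2, 0, 7, RANGE_SETS[3]),
    "oarsi": _preset(4, 0, 11, RANGE_SETS[3]),
    "mankin": _preset(6, 0, 31, RANGE_SETS[0]),
}
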