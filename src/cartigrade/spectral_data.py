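"""Core data model and I/O for NIR cartilage spectra.

Spectra are absorbance traces on a wavelength grid (μm) with nested
provenance metadata: cadaver → knee side → joint surface → measurement
site, plus a replicate index and an acquisition setting (``in_vitro``
plug measurement or ``ex_vivo`` arthroscopic measurement).  Reference
measurements (Safranin-O optical density ∼ proteoglycan content and
three histologic scores) exist once per measurement location.

Wavelengths are stored in μm everywhere.  Two acquisition grids occur in
practice: a silicon-detector range 0.35–1.10 μm at 0.6 nm resolution and
an InGaAs range 1.00–2.50 μm at 6.4 nm resolution; ``downsample_and_merge``
joins them on the coarse grid.

Storage dialect
---------------
``csv`` format writes three sidecar files from one base path:

* ``<base>.spectra.csv`` — wide table, metadata columns
  (cadaver_id, knee_side, surface, site_index, replicate, setting)
  followed by one column per wavelength, header = wavelength in μm
  (shortest decimal string that round-trips the double);
* ``<base>.references.csv`` — one row per location
  (cadaver_id, knee_side, surface, site_index, pg_od, icrs, oarsi, mankin);
* ``<base>.provenance.json`` — free-text provenance plus the nominal grid
  resolution.

``json`` format stores the same content in a single JSON document.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ["cadaver_id", "knee_side", "surface", "site_index", "replicate", "setting"]
LOCATION_COLUMNS = ["cadaver_id", "knee_side", "surface", "site_index"]
REFERENCE_PROPERTIES = ["pg_od", "icrs", "oarsi", "mankin"]

KNEE_SIDES = ("left", "right")
SURFACES = ("femur", "tibia", "patella")
SETTINGS = ("in_vitro", "ex_vivo")

#: nominal acquisition grids, μm
VIS_RANGE = (0.35, 1.10)
VIS_STEP = 0.0006
NIR_RANGE = (1.00, 2.50)
NIR_STEP = 0.0064
#: score/OD validity ranges
REFERENCE_RANGES = {"pg_od": (0.0, np.inf), "icrs": (0.0, 4.0), "oarsi": (0.0, 6.0), "mankin": (0.0, 13.0)}


class CartigradeError(Exception):
    """Base class for all package errors."""


class ValidationError(CartigradeError):
    """A container violated one of its invariants."""


class ParseError(CartigradeError):
    """A file could not be parsed under the documented dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in μm with a nominal step."""

    values: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size == 0:
            raise ValidationError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(values) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing with no duplicates")
        if values[0] < 0.35 - 1e-9 or values[-1] > 2.50 + 1e-9:
            raise ValidationError("wavelengths must lie within [0.35, 2.50] μm")

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.values, other.values)

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((len(self.values), float(self.values[0]), float(self.values[-1])))


@dataclass(frozen=True, order=True)
class LocationKey:
    """One measurement location in the cadaver/knee/surface/site nesting."""

    cadaver_id: str
    knee_side: str
    surface: str
    site_index: int

    def __post_init__(self) -> None:
        if self.knee_side not in KNEE_SIDES:
            raise ValidationError(f"knee_side must be one of {KNEE_SIDES}, got {self.knee_side!r}")
        if self.surface not in SURFACES:
            raise ValidationError(f"surface must be one of {SURFACES}, got {self.surface!r}")
        if self.site_index < 1:
            raise ValidationError("site_index must be ≥ 1")

    def label(self) -> str:
        return f"{self.cadaver_id}/{self.knee_side}/{self.surface}/{self.site_index}"


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace aligned to a wavelength grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    location: LocationKey
    replicate: int = 1
    setting: str = "in_vitro"

    def __post_init__(self) -> None:
        absorbance = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "absorbance", absorbance)
        if absorbance.shape != (len(self.grid),):
            raise ValidationError("absorbance length must equal grid length")
        if not np.all(np.isfinite(absorbance)):
            raise ValidationError("absorbance values must be finite")
        if self.replicate < 1:
            raise ValidationError("replicate index must be ≥ 1")
        if self.setting not in SETTINGS:
            raise ValidationError(f"setting must be one of {SETTINGS}")


@dataclass(frozen=True)
class ReferenceRecord:
    """Reference measurements for one location.

    Scores may be non-integer: each is an average over sections and
    assessors.
    """

    location: LocationKey
    pg_od: float
    icrs: float
    oarsi: float
    mankin: float

    def __post_init__(self) -> None:
        if not self.pg_od > 0:
            raise ValidationError("pg_od must be > 0")
        for name, (lo, hi) in REFERENCE_RANGES.items():
            value = getattr(self, name)
            if not (lo <= value <= hi):
                raise ValidationError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass
class SpectralDataset:
    """Tabular spectra collection with per-location references.

    Internally the spectra live in a wide layout: ``meta`` (one row per
    spectrum, columns ``META_COLUMNS``) aligned row-wise with the
    ``absorbance`` matrix (n_spectra × n_wavelengths).  ``references``
    has one row per location.
    """

    grid: WavelengthGrid
    meta: pd.DataFrame
    absorbance: np.ndarray
    references: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.meta = self.meta.reset_index(drop=True)
        self.references = self.references.reset_index(drop=True)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if list(self.meta.columns) != META_COLUMNS:
            raise ValidationError(f"meta columns must be {META_COLUMNS}")
        if self.absorbance.shape != (len(self.meta), len(self.grid)):
            raise ValidationError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{len(self.meta)} spectra × {len(self.grid)} wavelengths"
            )
        bad = np.flatnonzero(~np.isfinite(self.absorbance).all(axis=1))
        if bad.size:
            raise ValidationError(f"non-finite absorbance in spectrum row(s) {bad.tolist()}")
        missing = set(self.reference_columns()) - set(self.references.columns)
        if missing:
            raise ValidationError(f"references missing columns {sorted(missing)}")
        # every spectrum location must appear in references (or be flagged)
        if len(self.meta):
            spec_locs = set(map(tuple, self.meta[LOCATION_COLUMNS].itertuples(index=False)))
            ref_locs = set(map(tuple, self.references[LOCATION_COLUMNS].itertuples(index=False)))
            orphans = spec_locs - ref_locs
            if orphans and not self.provenance.get("reference_missing_ok", False):
                raise ValidationError(
                    f"{len(orphans)} spectrum location(s) have no reference record; "
                    "set provenance['reference_missing_ok']=True to allow"
                )

    @staticmethod
    def reference_columns() -> list[str]:
        return LOCATION_COLUMNS + REFERENCE_PROPERTIES

    # -- accessors ----------------------------------------------------------

    @property
    def n_spectra(self) -> int:
        return len(self.meta)

    def location_labels(self) -> pd.Series:
        m = self.meta
        return (
            m["cadaver_id"].astype(str)
            + "/" + m["knee_side"].astype(str)
            + "/" + m["surface"].astype(str)
            + "/" + m["site_index"].astype(str)
        )

    def iter_spectra(self) -> Iterator[Spectrum]:
        for i, row in self.meta.iterrows():
            yield Spectrum(
                grid=self.grid,
                absorbance=self.absorbance[i],
                location=LocationKey(
                    str(row["cadaver_id"]), row["knee_side"], row["surface"], int(row["site_index"])
                ),
                replicate=int(row["replicate"]),
                setting=row["setting"],
            )

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Row subset of the spectra; references and grid are shared."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectralDataset(
            grid=self.grid,
            meta=self.meta.iloc[idx].reset_index(drop=True),
            absorbance=self.absorbance[idx],
            references=self.references,
            provenance=dict(self.provenance),
        )

    def select_setting(self, setting: str) -> "SpectralDataset":
        return self.subset((self.meta["setting"] == setting).to_numpy())

    def cadaver_ids(self) -> list[str]:
        return sorted(self.meta["cadaver_id"].astype(str).unique())

    def average_replicates(self, setting: str | None = None) -> "SpectralDataset":
        """Collapse replicate spectra to one mean spectrum per location.

        References exist once per location, so calibration treats the
        location as the observational unit; replicate traces are averaged
        before modelling.
        """
        ds = self if setting is None else self.select_setting(setting)
        if not len(ds.meta):
            return ds
        groups = ds.meta.groupby(LOCATION_COLUMNS, sort=True).indices
        rows, mats = [], []
        for key in sorted(groups):
            idx = groups[key]
            rows.append(dict(zip(LOCATION_COLUMNS, key), replicate=1,
                             setting=ds.meta["setting"].iloc[idx[0]]))
            mats.append(ds.absorbance[idx].mean(axis=0))
        return SpectralDataset(
            grid=ds.grid,
            meta=pd.DataFrame(rows, columns=META_COLUMNS),
            absorbance=np.vstack(mats),
            references=ds.references,
            provenance=dict(ds.provenance),
        )

    def reference_frame(self) -> pd.DataFrame:
        """References indexed like ``meta`` rows (merge on location)."""
        return self.meta[LOCATION_COLUMNS].merge(self.references, on=LOCATION_COLUMNS, how="left")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        a, b = _sorted_refs(self.references), _sorted_refs(other.references)
        return (
            self.grid == other.grid
            and self.meta.equals(other.meta)
            and np.allclose(self.absorbance, other.absorbance, rtol=1e-12, atol=1e-12)
            and a[LOCATION_COLUMNS].equals(b[LOCATION_COLUMNS])
            and np.allclose(a[REFERENCE_PROPERTIES], b[REFERENCE_PROPERTIES],
                            rtol=1e-12, atol=1e-12)
        )


def _sorted_refs(refs: pd.DataFrame) -> pd.DataFrame:
    cols = SpectralDataset.reference_columns()
    return refs[cols].sort_values(LOCATION_COLUMNS).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _csv_base(path: Path) -> str:
    """Base path shared by the three csv-dialect files."""
    s = str(path)
    for suffix in (".spectra.csv", ".references.csv", ".provenance.json", ".csv"):
        if s.endswith(suffix):
            return s[: -len(suffix)]
    return s


def _wavelength_header(grid: WavelengthGrid) -> list[str]:
    # repr gives the shortest decimal string that round-trips the double
    return [repr(float(w)) for w in grid.values]


def _parse_wavelength_columns(columns: list[str]) -> np.ndarray:
    values = []
    for col in columns:
        try:
            values.append(float(col))
        except ValueError:
            raise ParseError(f"wavelength column {col!r} is not numeric") from None
    return np.asarray(values)


def _grid_from_header(columns: list[str], resolution: float | None) -> tuple[WavelengthGrid, np.ndarray]:
    """Parse wavelength header; auto-sort unsorted columns with a warning.

    Returns the grid and the permutation applied to the columns.
    """
    values = _parse_wavelength_columns(columns)
    order = np.arange(len(values))
    if np.any(np.diff(values) <= 0):
        if len(np.unique(values)) != len(values):
            raise ParseError("duplicate wavelength columns in header")
        logger.warning("wavelength columns not sorted; auto-sorting")
        order = np.argsort(values)
        values = values[order]
    if resolution is None:
        resolution = float(np.median(np.diff(values))) if len(values) > 1 else 0.0
    return WavelengthGrid(values, resolution), order


def write_dataset(dataset: SpectralDataset, path: str | Path, format: str = "csv") -> None:
    """Serialize a dataset under the documented dialect."""
    dataset.validate()
    path = Path(path)
    if format == "csv":
        base = _csv_base(path)
        wide = pd.concat(
            [dataset.meta, pd.DataFrame(dataset.absorbance, columns=_wavelength_header(dataset.grid))],
            axis=1,
        )
        wide.to_csv(f"{base}.spectra.csv", index=False)
        dataset.references[dataset.reference_columns()].to_csv(f"{base}.references.csv", index=False)
        sidecar = {"provenance": dataset.provenance, "resolution_um": dataset.grid.resolution}
        Path(f"{base}.provenance.json").write_text(json.dumps(sidecar, indent=2))
    elif format == "json":
        doc = {
            "wavelengths_um": dataset.grid.values.tolist(),
            "resolution_um": dataset.grid.resolution,
            "meta": dataset.meta.to_dict(orient="list"),
            "absorbance": dataset.absorbance.tolist(),
            "references": dataset.references[dataset.reference_columns()].to_dict(orient="list"),
            "provenance": dataset.provenance,
        }
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path: str | Path, format: str = "csv") -> SpectralDataset:
    """Load a dataset written by :func:`write_dataset`."""
    path = Path(path)
    if format == "csv":
        base = _csv_base(path)
        spectra_path = Path(f"{base}.spectra.csv")
        if not spectra_path.exists():
            raise FileNotFoundError(spectra_path)
        wide = pd.read_csv(spectra_path, dtype={"cadaver_id": str})
        for col in META_COLUMNS:
            if col not in wide.columns:
                raise ParseError(f"missing metadata column {col!r}")
        wl_cols = [c for c in wide.columns if c not in META_COLUMNS]
        grid, order = _grid_from_header(wl_cols, None)
        absorbance = wide[wl_cols].to_numpy(dtype=float)[:, order]
        refs = pd.read_csv(f"{base}.references.csv", dtype={"cadaver_id": str})
        provenance = {}
        sidecar_path = Path(f"{base}.provenance.json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            provenance = sidecar.get("provenance", {})
            grid = WavelengthGrid(grid.values, sidecar.get("resolution_um", grid.resolution))
        meta = wide[META_COLUMNS]
    elif format == "json":
        doc = json.loads(Path(path).read_text())
        grid, order = _grid_from_header([repr(float(v)) for v in doc["wavelengths_um"]],
                                        doc.get("resolution_um"))
        absorbance = np.asarray(doc["absorbance"], dtype=float)
        if absorbance.ndim == 1:
            absorbance = absorbance.reshape(0, len(grid))
        absorbance = absorbance[:, order]
        meta = pd.DataFrame(doc["meta"], columns=META_COLUMNS)
        meta["cadaver_id"] = meta["cadaver_id"].astype(str)
        refs = pd.DataFrame(doc["references"], columns=SpectralDataset.reference_columns())
        refs["cadaver_id"] = refs["cadaver_id"].astype(str)
        provenance = doc.get("provenance", {})
    else:
        raise ValueError(f"unknown format {format!r}")
    return SpectralDataset(grid=grid, meta=meta, absorbance=absorbance,
                           references=refs, provenance=provenance)


# ---------------------------------------------------------------------------
# two-spectrometer merge
# ---------------------------------------------------------------------------


def make_vis_grid() -> WavelengthGrid:
    """0.35–1.10 μm at 0.6 nm (silicon-detector spectrometer)."""
    n = int(round((VIS_RANGE[1] - VIS_RANGE[0]) / VIS_STEP)) + 1
    return WavelengthGrid(VIS_RANGE[0] + VIS_STEP * np.arange(n), VIS_STEP)


def make_nir_grid() -> WavelengthGrid:
    """1.00–2.50 μm at 6.4 nm (InGaAs spectrometer)."""
    n = int(np.floor((NIR_RANGE[1] - NIR_RANGE[0]) / NIR_STEP + 1e-9)) + 1
    return WavelengthGrid(NIR_RANGE[0] + NIR_STEP * np.arange(n), NIR_STEP)


def merged_grid(vis: WavelengthGrid, nir: WavelengthGrid, cut: float = 1.05) -> WavelengthGrid:
    """Coarse-resolution grid spanning both spectrometers.

    Below ``cut`` the grid marches from the visible-range start at the
    coarse (NIR) step; at and above ``cut`` the native NIR grid points are
    kept.  The junction gap may be shorter than one step, never longer.
    """
    step = nir.resolution
    low = vis.values[0] + step * np.arange(int(np.ceil((cut - vis.values[0]) / step)) + 1)
    low = low[(low < cut) & (low <= vis.values[-1] + 1e-12)]
    high = nir.values[nir.values >= cut - 1e-12]
    return WavelengthGrid(np.concatenate([low, high]), step)


def downsample_and_merge(vis: Spectrum, nir: Spectrum, cut: float = 1.05) -> Spectrum:
    """Join the fine visible-range trace and the coarse NIR trace.

    The visible trace is linearly interpolated onto the coarse grid below
    ``cut``; NIR samples at/above ``cut`` are kept verbatim.  ``cut`` must
    lie in the spectrometer overlap [1.00, 1.10] μm.
    """
    if (vis.location, vis.replicate, vis.setting) != (nir.location, nir.replicate, nir.setting):
        raise ValidationError("vis and nir spectra must share location, replicate and setting")
    if not (1.00 <= cut <= 1.10):
        raise ValueError(f"cut={cut} μm outside the spectrometer overlap [1.00, 1.10] μm")
    grid = merged_grid(vis.grid, nir.grid, cut)
    low_mask = grid.values < cut
    out = np.empty(len(grid))
    out[low_mask] = np.interp(grid.values[low_mask], vis.grid.values, vis.absorbance)
    out[~low_mask] = nir.absorbance[nir.grid.values >= cut - 1e-12]
    return replace(vis, grid=grid, absorbance=out)
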