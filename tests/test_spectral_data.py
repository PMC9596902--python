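"""Data model, I/O dialect and two-spectrometer merging."""

import numpy as np
import pandas as pd
import pytest

import cartigrade as cg
from cartigrade.spectral_data import (
    META_COLUMNS,
    ParseError,
    ValidationError,
    make_nir_grid,
    make_vis_grid,
    merged_grid,
)


def _mini_dataset(n_cadavers=2, n_wl=12):
    wl = np.linspace(0.70, 1.90, n_wl)
    grid = cg.WavelengthGrid(wl, float(wl[1] - wl[0]))
    rows, spectra, refs = [], [], []
    rng = np.random.default_rng(0)
    for c in range(n_cadavers):
        cid = f"C{c + 1:02d}"
        for rep in (1, 2):
            rows.append({"cadaver_id": cid, "knee_side": "left", "surface": "femur",
                         "site_index": 1, "replicate": rep, "setting": "in_vitro"})
            spectra.append(rng.normal(0.5, 0.1, n_wl))
        refs.append({"cadaver_id": cid, "knee_side": "left", "surface": "femur",
                     "site_index": 1, "pg_od": 0.8, "icrs": 1.5, "oarsi": 2.0,
                     "mankin": 4.0})
    return cg.SpectralDataset(grid=grid, meta=pd.DataFrame(rows, columns=META_COLUMNS),
                              absorbance=np.vstack(spectra),
                              references=pd.DataFrame(refs),
                              provenance={"note": "fixture"})


class TestGridAndTypes:
    def test_grid_must_increase(self):
        with pytest.raises(ValidationError):
            cg.WavelengthGrid(np.array([0.5, 0.5, 0.6]), 0.1)

    def test_grid_bounds(self):
        with pytest.raises(ValidationError):
            cg.WavelengthGrid(np.array([0.1, 0.5]), 0.4)

    def test_location_key_validation(self):
        with pytest.raises(ValidationError):
            cg.LocationKey("C01", "left", "humerus", 1)
        with pytest.raises(ValidationError):
            cg.LocationKey("C01", "left", "femur", 0)

    def test_reference_ranges(self):
        loc = cg.LocationKey("C01", "left", "femur", 1)
        with pytest.raises(ValidationError):
            cg.ReferenceRecord(loc, pg_od=0.5, icrs=5.0, oarsi=1.0, mankin=2.0)
        rec = cg.ReferenceRecord(loc, pg_od=0.5, icrs=2.5, oarsi=1.0, mankin=2.0)
        assert rec.icrs == 2.5  # assessor-averaged scores may be non-integer

    def test_spectrum_alignment(self):
        grid = cg.WavelengthGrid(np.linspace(0.7, 1.9, 5), 0.3)
        loc = cg.LocationKey("C01", "left", "femur", 1)
        with pytest.raises(ValidationError):
            cg.Spectrum(grid, np.ones(4), loc)
        with pytest.raises(ValidationError):
            cg.Spectrum(grid, np.array([1, 2, np.nan, 4, 5.0]), loc)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_round_trip(self, tmp_path, fmt):
        ds = _mini_dataset()
        path = tmp_path / ("d.json" if fmt == "json" else "d")
        cg.write_dataset(ds, path, format=fmt)
        back = cg.read_dataset(path, format=fmt)
        assert back == ds

    def test_round_trip_random_cohort(self, tmp_path, tiny_cohort):
        ds, _ = tiny_cohort
        sub = ds.subset(np.arange(0, ds.n_spectra, 37))  # thin out for speed
        cg.write_dataset(sub, tmp_path / "c", format="csv")
        assert cg.read_dataset(tmp_path / "c", format="csv") == sub

    def test_empty_spectra_collection(self, tmp_path):
        ds = _mini_dataset()
        empty = ds.subset(np.zeros(ds.n_spectra, dtype=bool))
        cg.write_dataset(empty, tmp_path / "e", format="csv")
        back = cg.read_dataset(tmp_path / "e", format="csv")
        assert back.n_spectra == 0
        assert back.grid == ds.grid

    def test_cadaver_count_preserved(self, tmp_path):
        ds = _mini_dataset(n_cadavers=2)
        cg.write_dataset(ds, tmp_path / "two", format="csv")
        wide = pd.read_csv(tmp_path / "two.spectra.csv")
        assert wide["cadaver_id"].nunique() == 2

    def test_nan_cell_rejected(self, tmp_path):
        ds = _mini_dataset()
        cg.write_dataset(ds, tmp_path / "bad", format="csv")
        wide = pd.read_csv(tmp_path / "bad.spectra.csv")
        wide.iloc[2, len(META_COLUMNS) + 3] = np.nan
        wide.to_csv(tmp_path / "bad.spectra.csv", index=False)
        with pytest.raises(ValidationError, match=r"row\(s\) \[2\]"):
            cg.read_dataset(tmp_path / "bad", format="csv")

    def test_unsorted_wavelengths_auto_sorted(self, tmp_path, caplog):
        ds = _mini_dataset()
        cg.write_dataset(ds, tmp_path / "u", format="csv")
        wide = pd.read_csv(tmp_path / "u.spectra.csv")
        cols = list(wide.columns)
        wl = cols[len(META_COLUMNS):]
        wide = wide[cols[: len(META_COLUMNS)] + wl[::-1]]
        wide.to_csv(tmp_path / "u.spectra.csv", index=False)
        with caplog.at_level("WARNING"):
            back = cg.read_dataset(tmp_path / "u", format="csv")
        assert "auto-sorting" in caplog.text
        assert back == ds

    def test_malformed_header_names_column(self, tmp_path):
        ds = _mini_dataset()
        cg.write_dataset(ds, tmp_path / "m", format="csv")
        wide = pd.read_csv(tmp_path / "m.spectra.csv")
        wide = wide.rename(columns={wide.columns[-1]: "not-a-wavelength"})
        wide.to_csv(tmp_path / "m.spectra.csv", index=False)
        with pytest.raises(ParseError, match="not-a-wavelength"):
            cg.read_dataset(tmp_path / "m", format="csv")


class TestMerge:
    def _pair(self, vis_fn, nir_fn):
        vis_grid, nir_grid = make_vis_grid(), make_nir_grid()
        loc = cg.LocationKey("C01", "left", "femur", 1)
        vis = cg.Spectrum(vis_grid, vis_fn(vis_grid.values), loc)
        nir = cg.Spectrum(nir_grid, nir_fn(nir_grid.values), loc)
        return vis, nir

    def test_linear_ramp_exact(self):
        # linear interpolation reproduces affine functions exactly
        f = lambda wl: 0.2 + 0.7 * wl
        vis, nir = self._pair(f, f)
        merged = cg.downsample_and_merge(vis, nir, cut=1.05)
        np.testing.assert_allclose(merged.absorbance, f(merged.grid.values), atol=1e-12)

    def test_constant_stays_constant(self):
        vis, nir = self._pair(lambda w: np.full_like(w, 0.4), lambda w: np.full_like(w, 0.4))
        merged = cg.downsample_and_merge(vis, nir)
        np.testing.assert_allclose(merged.absorbance, 0.4)

    def test_point_count_matches_enumeration(self):
        # independent brute-force enumeration of the documented grid rule
        cut = 1.05
        low = []
        w, k = 0.35, 0
        while True:
            w = 0.35 + k * 0.0064
            if w >= cut or w > 1.10 + 1e-12:
                break
            low.append(w)
            k += 1
        nir = make_nir_grid().values
        high = [w for w in nir if w >= cut - 1e-12]
        expected = len(low) + len(high)
        vis, nirs = self._pair(lambda w: w, lambda w: w)
        merged = cg.downsample_and_merge(vis, nirs, cut=cut)
        assert len(merged.grid) == expected == 337

    @pytest.mark.parametrize("cut", [1.00, 1.03, 1.05, 1.10])
    def test_merge_never_extrapolates(self, cut):
        vis, nir = self._pair(np.sin, np.cos)
        merged = cg.downsample_and_merge(vis, nir, cut=cut)
        assert merged.grid.values[0] >= vis.grid.values[0] - 1e-12
        assert merged.grid.values[-1] <= nir.grid.values[-1] + 1e-12
        assert np.all(np.diff(merged.grid.values) > 0)

    def test_idempotent_on_coarse_input(self):
        nir_grid = make_nir_grid()
        loc = cg.LocationKey("C01", "left", "femur", 1)
        coarse = cg.Spectrum(nir_grid, np.sin(5 * nir_grid.values), loc)
        merged = cg.downsample_and_merge(coarse, coarse, cut=1.05)
        # every retained wavelength keeps its original value
        common = np.isin(merged.grid.values, nir_grid.values)
        orig = {w: a for w, a in zip(nir_grid.values, coarse.absorbance)}
        for w, a in zip(merged.grid.values[common], merged.absorbance[common]):
            assert a == pytest.approx(orig[w], abs=1e-12)

    def test_metadata_mismatch_rejected(self):
        vis, nir = self._pair(lambda w: w, lambda w: w)
        other = cg.Spectrum(nir.grid, nir.absorbance,
                            cg.LocationKey("C02", "left", "femur", 1))
        with pytest.raises(ValidationError):
            cg.downsample_and_merge(vis, other)

    def test_cut_outside_overlap_rejected(self):
        vis, nir = self._pair(lambda w: w, lambda w: w)
        with pytest.raises(ValueError):
            cg.downsample_and_merge(vis, nir, cut=1.2)


class TestDatasetAccessors:
    def test_average_replicates_one_row_per_location(self, tiny_cohort):
        ds, _ = tiny_cohort
        avg = ds.average_replicates("in_vitro")
        assert len(avg.meta) == len(ds.references)
        assert avg.meta.duplicated(subset=["cadaver_id", "knee_side", "surface",
                                           "site_index"]).sum() == 0

    def test_subset_preserves_grid_and_refs(self, tiny_cohort):
        ds, _ = tiny_cohort
        sub = ds.subset(np.arange(10))
        assert sub.n_spectra == 10
        assert sub.grid == ds.grid
        assert len(sub.references) == len(ds.references)
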