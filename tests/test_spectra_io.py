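"""Spectral containers, file readers, stitching, resampling, calibration."""

import numpy as np
import pandas as pd
import pytest
from numpy.testing import assert_allclose, assert_array_equal

from leafspec.io import (
    load_set,
    preprocess_raw,
    read_panel_csv,
    read_spectrum_file,
    resample_1nm,
    stitch,
    to_absolute,
    write_spectrum_csv,
)
from leafspec.spectra import (
    GRID,
    CoverageError,
    PanelCalibration,
    ParseError,
    RawSpectrum,
    Spectrum,
    SpectrumMeta,
    SpectrumSet,
    StitchError,
)

from conftest import make_flat


def _three_segment_raw(v_vnir=0.4, v_swir1=0.4, v_swir2=0.4, meta=None):
    vnir = np.arange(350.0, 1000.0 + 0.1, 1.5)
    swir1 = np.arange(1000.0, 1890.0 + 0.1, 3.8)
    swir2 = np.arange(1890.0, 2500.0 + 0.1, 2.5)
    return RawSpectrum(
        segments=(
            ("VNIR", vnir, np.full(vnir.size, v_vnir)),
            ("SWIR1", swir1, np.full(swir1.size, v_swir1)),
            ("SWIR2", swir2, np.full(swir2.size, v_swir2)),
        ),
        meta=meta or SpectrumMeta(),
    )


class TestReaders:
    def test_svc_three_segment_file_recovers_instrument_ranges(self, tmp_path):
        lines = ["/* leaf clip spectrum */", "treatment = eCO2",
                 "tree_id = E1-T1", "date = 2023-07-25", "leaf_index = 3"]
        for seg in (np.arange(350.0, 1000.1, 1.5),
                    np.arange(1000.0, 1890.1, 3.8),
                    np.arange(1890.0, 2500.1, 2.5)):
            lines += [f"{w:.1f} 0.42" for w in seg]
        f = tmp_path / "leaf.sig"
        f.write_text("\n".join(lines))
        raw = read_spectrum_file(f)
        dets = [s[0] for s in raw.segments]
        assert dets == ["VNIR", "SWIR1", "SWIR2"]
        assert raw.segments[0][1][0] == 350.0
        assert raw.segments[0][1][-1] == pytest.approx(1000.0, abs=1.5)
        assert raw.segments[1][1][0] == 1000.0
        assert raw.segments[2][1][-1] == pytest.approx(2500.0, abs=2.5)
        assert raw.meta.treatment == "eCO2"
        assert raw.meta.leaf_index == 3

    def test_csv_roundtrip_preserves_data_and_metadata(self, tmp_path):
        wl = np.arange(350.0, 2500.1, 1.0)
        vals = 0.2 + 0.1 * np.sin(wl / 200.0)
        raw = RawSpectrum(
            segments=(("VNIR", wl[wl < 1000], vals[wl < 1000]),
                      ("SWIR1", wl[(wl >= 1000) & (wl < 1890)],
                       vals[(wl >= 1000) & (wl < 1890)]),
                      ("SWIR2", wl[wl >= 1890], vals[wl >= 1890])),
            meta=SpectrumMeta(treatment="aCO2", tree_id="A1-T1",
                              date="2023-07-25", leaf_index=1),
        )
        f = tmp_path / "leaf.csv"
        write_spectrum_csv(raw, f)
        back = read_spectrum_file(f, dialect="csv")
        wl2 = np.concatenate([s[1] for s in back.segments])
        vals2 = np.concatenate([s[2] for s in back.segments])
        assert_array_equal(wl2, wl)
        assert_array_equal(vals2, vals)
        assert back.meta.treatment == "aCO2"
        assert back.meta.leaf_index == 1

    def test_duplicate_wavelength_is_a_parse_error_naming_it(self, tmp_path):
        rows = [f"{w:.1f},0.3" for w in np.arange(350.0, 2500.1, 1.0)]
        rows.insert(151, "500.0,0.31")  # duplicates the 500.0 row
        f = tmp_path / "dup.csv"
        f.write_text("wavelength_nm,reflectance\n" + "\n".join(rows))
        with pytest.raises(ParseError, match="500"):
            read_spectrum_file(f, dialect="csv")

    def test_unknown_dialect_rejected(self, tmp_path):
        f = tmp_path / "x.csv"
        f.write_text("wavelength_nm,reflectance\n400,0.5\n")
        with pytest.raises(ParseError, match="dialect"):
            read_spectrum_file(f, dialect="bsq")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_spectrum_file("/nonexistent/leaf.sig")


class TestStitch:
    def test_consistent_overlap_is_policy_invariant(self):
        vnir = np.arange(350.0, 1005.1, 1.5)
        swir1 = np.arange(995.0, 1890.1, 3.8)
        swir2 = np.arange(1890.0, 2500.1, 2.5)
        raw = RawSpectrum(segments=(
            ("VNIR", vnir, np.full(vnir.size, 0.4)),
            ("SWIR1", swir1, np.full(swir1.size, 0.4)),
            ("SWIR2", swir2, np.full(swir2.size, 0.4)),
        ))
        for policy in ("cut", "rescale"):
            wl, vals = stitch(raw, policy=policy)
            assert_allclose(vals, 0.4, rtol=0, atol=1e-15)

    def test_rescale_jump_correction_factor(self):
        # VNIR 0.40 / SWIR1 0.50 overlapping on [995, 1005]:
        # SWIR1 is rescaled by 0.4/0.5 = 0.8, giving a continuous 0.40
        vnir = np.arange(350.0, 1005.1, 1.5)
        swir1 = np.arange(995.0, 1890.1, 3.8)
        raw = RawSpectrum(segments=(
            ("VNIR", vnir, np.full(vnir.size, 0.40)),
            ("SWIR1", swir1, np.full(swir1.size, 0.50)),
        ))
        wl, vals = stitch(raw, policy="rescale")
        assert_allclose(vals, 0.40, rtol=0, atol=1e-15)
        # default policy keeps the detector step
        _, vals_cut = stitch(raw, policy="cut")
        assert vals_cut[wl < 1000].max() == pytest.approx(0.40)
        assert vals_cut[wl >= 1000].min() == pytest.approx(0.50)

    def test_three_segments_span_full_range_without_duplicates(self):
        wl, vals = stitch(_three_segment_raw())
        assert wl[0] == 350.0
        assert wl[-1] >= 2495.0
        assert np.all(np.diff(wl) > 0)

    def test_gap_between_segments_errors(self):
        vnir = np.arange(350.0, 980.1, 1.5)
        swir1 = np.arange(1000.0, 1890.1, 3.8)
        raw = RawSpectrum(segments=(
            ("VNIR", vnir, np.full(vnir.size, 0.4)),
            ("SWIR1", swir1, np.full(swir1.size, 0.4)),
        ))
        with pytest.raises(StitchError, match="gap"):
            stitch(raw)

    def test_unknown_policy_errors(self):
        with pytest.raises(StitchError, match="policy"):
            stitch(_three_segment_raw(), policy="average")


class TestResample:
    def test_identity_on_integer_grid(self):
        vals = 0.2 + 0.05 * np.cos(GRID / 100.0)
        out = resample_1nm((GRID.astype(float), vals))
        assert_allclose(out.reflectance, vals, rtol=0, atol=0)

    def test_linear_midpoint(self):
        wl = np.array([350.0, 400.0, 402.0, 2500.0])
        vals = np.array([0.1, 0.1, 0.3, 0.3])
        out = resample_1nm((wl, vals))
        assert out.reflectance[401 - 350] == pytest.approx(0.2)

    def test_native_spacing_yields_2151_points(self):
        out = resample_1nm(stitch(_three_segment_raw()))
        assert out.reflectance.shape == (2151,)
        assert out.grid[0] == 350 and out.grid[-1] == 2500

    def test_short_coverage_errors(self):
        wl = np.arange(360.0, 2500.1, 1.0)
        with pytest.raises(CoverageError, match="starts"):
            resample_1nm((wl, np.full(wl.size, 0.3)))
        wl = np.arange(350.0, 2490.1, 1.0)
        with pytest.raises(CoverageError, match="ends"):
            resample_1nm((wl, np.full(wl.size, 0.3)))

    def test_idempotent(self):
        out1 = resample_1nm(stitch(_three_segment_raw(0.3, 0.45, 0.2)))
        out2 = resample_1nm((out1.grid.astype(float), out1.reflectance))
        assert_array_equal(out1.reflectance, out2.reflectance)

    def test_constant_preserved_through_full_chain(self):
        for policy in ("cut", "rescale"):
            out = resample_1nm(stitch(_three_segment_raw(0.37, 0.37, 0.37),
                                      policy=policy))
            assert_allclose(out.reflectance, 0.37, rtol=0, atol=1e-14)


class TestPanel:
    def test_identity_panel_is_a_noop(self, flat_spectrum):
        panel = PanelCalibration(np.array([350.0, 2500.0]), np.array([1.0, 1.0]))
        out = to_absolute(flat_spectrum, panel)
        assert_array_equal(out.reflectance, flat_spectrum.reflectance)

    def test_constant_panel_scales(self):
        panel = PanelCalibration(np.array([350.0, 2500.0]),
                                 np.array([0.98, 0.98]))
        out = to_absolute(make_flat(0.5), panel)
        assert_allclose(out.reflectance, 0.49, rtol=0, atol=1e-15)

    def test_elementwise_ratio_recovers_panel_curve(self):
        wl = np.linspace(350.0, 2500.0, 20)
        pr = 0.95 + 0.05 * np.sin(wl / 300.0)
        panel = PanelCalibration(wl, pr)
        spec = make_flat(0.5)
        out = to_absolute(spec, panel)
        assert_allclose(out.reflectance / spec.reflectance, panel.on_grid(),
                        rtol=1e-12)

    def test_nonpositive_panel_rejected(self):
        with pytest.raises(ValueError, match="panel reflectance"):
            PanelCalibration(np.array([350.0, 2500.0]), np.array([0.0, 0.9]))

    def test_panel_must_cover_grid(self):
        with pytest.raises(CoverageError):
            PanelCalibration(np.array([400.0, 2500.0]), np.array([0.9, 0.9]))

    def test_panel_csv_reader(self, tmp_path):
        f = tmp_path / "panel.csv"
        pd.DataFrame({"wavelength_nm": [350.0, 2500.0],
                      "panel_reflectance": [0.97, 0.99]}).to_csv(f, index=False)
        panel = read_panel_csv(f)
        assert panel.panel_reflectance[0] == 0.97


class TestMetadataAndSets:
    def test_meta_preserved_through_preprocessing(self):
        meta = SpectrumMeta(treatment="eCO2", array_id="E1", tree_id="E1-T2",
                            date="2023-08-10", leaf_index=7)
        panel = PanelCalibration(np.array([350.0, 2500.0]),
                                 np.array([0.99, 0.99]))
        out = preprocess_raw(_three_segment_raw(meta=meta), panel=panel)
        assert out.meta == meta

    def test_over_unity_values_flagged_not_destroyed(self):
        refl = np.full(GRID.size, 0.5)
        refl[1000] = 1.2
        s = Spectrum(refl)
        assert s.over_unity
        assert s.reflectance[1000] == 1.2

    def test_values_clipped_to_bounds(self):
        refl = np.full(GRID.size, 0.5)
        refl[0], refl[1] = -0.1, 2.0
        s = Spectrum(refl)
        assert s.reflectance[0] == 0.0
        assert s.reflectance[1] == 1.5

    def test_duplicate_leaf_key_rejected(self):
        meta = SpectrumMeta(treatment="aCO2", tree_id="T1",
                            date="2023-07-25", leaf_index=1)
        s = make_flat(0.3).with_meta(tree_id="T1", date="2023-07-25",
                                     leaf_index=1, treatment="aCO2")
        with pytest.raises(ValueError, match="duplicate"):
            SpectrumSet([s, Spectrum(s.reflectance, meta)])

    def test_wide_csv_roundtrip(self, tmp_path, tiny_campaign):
        f = tmp_path / "wide.csv"
        tiny_campaign.to_csv(f)
        back = SpectrumSet.from_csv(f)
        assert len(back) == len(tiny_campaign)
        assert np.max(np.abs(back.to_matrix() - tiny_campaign.to_matrix())) <= 1e-9
        assert back.meta_frame()["tree_id"].equals(
            tiny_campaign.meta_frame()["tree_id"])


class TestLoadSet:
    def _write_campaign(self, tmp_path, n=12):
        rows = []
        wl = np.arange(350.0, 2500.1, 1.0)
        for i in range(n):
            trt = "aCO2" if i % 2 == 0 else "eCO2"
            fname = f"leaf_{i}.csv"
            vals = np.full(wl.size, 0.3 + 0.01 * i)
            pd.DataFrame({"wavelength_nm": wl, "reflectance": vals}).to_csv(
                tmp_path / fname, index=False)
            rows.append({"path": fname, "treatment": trt,
                         "array_id": "A1" if trt == "aCO2" else "E1",
                         "tree_id": f"{trt[:1]}-T{i}", "date": "2023-07-25",
                         "leaf_index": 1})
        manifest = tmp_path / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    def test_manifest_load_counts(self, tmp_path):
        manifest = self._write_campaign(tmp_path)
        sset = load_set(manifest)
        assert len(sset) == 12
        assert sset.treatment_counts() == {"aCO2": 6, "eCO2": 6}

    def test_empty_manifest_errors(self, tmp_path):
        f = tmp_path / "manifest.csv"
        f.write_text("path,treatment,array_id,tree_id,date,leaf_index\n")
        with pytest.raises(ParseError, match="empty"):
            load_set(f)

    def test_missing_metadata_lists_files(self, tmp_path):
        manifest = self._write_campaign(tmp_path, n=3)
        df = pd.read_csv(manifest)
        df.loc[1, "treatment"] = None
        df.to_csv(manifest, index=False)
        with pytest.raises(ParseError, match="leaf_1.csv"):
            load_set(manifest)
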