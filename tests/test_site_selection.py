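"""Blob segmentation, probe-site picking, difference spectra, analyte matching."""

import numpy as np
import pytest

from pascan.acquisition import InstrumentConfig, PAImage, Spectrum, raster_scan
from pascan.site_selection import (
    difference_spectrum,
    match_analyte,
    monitor_secretion,
    segment_blobs,
    select_probe_sites,
)
from pascan.synthetic_skin import (
    Pore,
    SkinMap,
    component_spectrum,
    generate_skin_map,
)


def make_image(values, pitch=44.0):
    return PAImage(values=np.asarray(values, float), pixel_pitch=pitch,
                   origin=(0.0, 0.0), wavenumber=1040.0)


def gaussian_blob(shape, row, col, amp, sigma=1.5):
    r, c = np.mgrid[0: shape[0], 0: shape[1]]
    return amp * np.exp(-((r - row) ** 2 + (c - col) ** 2) / (2 * sigma**2))


class TestSegmentBlobs:
    def test_constant_image_has_no_blobs(self):
        blobs = segment_blobs(make_image(np.full((30, 30), 7.0)))
        assert blobs.n_blobs == 0

    def test_single_blob_centroid_recovered(self, rng):
        bg = rng.normal(100.0, 2.0, (30, 30))
        mad = np.median(np.abs(bg - np.median(bg)))
        img = make_image(bg + gaussian_blob((30, 30), 12, 17, amp=10 * mad / 0.1))
        blobs = segment_blobs(img)
        assert blobs.n_blobs == 1
        r, c = blobs.summaries[0].centroid_px
        assert abs(r - 12) <= 1.0 and abs(c - 17) <= 1.0

    def test_two_separated_blobs(self, rng):
        bg = rng.normal(100.0, 2.0, (30, 30))
        img = make_image(
            bg
            + gaussian_blob((30, 30), 7, 7, amp=80.0)
            + gaussian_blob((30, 30), 22, 22, amp=80.0)
        )
        assert segment_blobs(img).n_blobs == 2

    def test_non_finite_image_rejected(self):
        bad = np.full((5, 5), 1.0)
        bad[2, 2] = np.nan
        with pytest.raises(ValueError):
            segment_blobs(make_image(bad))


class TestSelectProbeSites:
    def test_unique_extrema_returned(self, rng):
        v = rng.normal(100.0, 0.5, (20, 20))
        v[5, 6] = 201.0   # two-pixel blob so it survives the area filter
        v[5, 7] = 200.0
        v[14, 3] = 10.0
        img = make_image(v)
        sel = select_probe_sites(img, segment_blobs(img))
        assert sel.bright_px == (5, 6)
        assert sel.dark_px == (14, 3)
        assert not sel.degenerate

    def test_all_equal_image_degenerate_tie_break(self):
        img = make_image(np.full((10, 10), 3.0))
        sel = select_probe_sites(img, segment_blobs(img))
        assert sel.dark_px == (0, 0) and sel.bright_px == (0, 0)
        assert sel.degenerate

    def test_dark_site_lands_on_valley_floor(self):
        """On a noiseless ridge+pore map the darkest eligible point must sit
        in a valley (low ridge height) of the ground truth."""
        skin = generate_skin_map(seed=8, secretion_noise=0.0)
        config = InstrumentConfig(noise_sigma=0.0)
        img = raster_scan(skin, t=60.0, config=config, seed=0)
        sel = select_probe_sites(img, segment_blobs(img))
        assert float(skin.ridge_height(*sel.dark_um)) < 0.2

    def test_dark_site_respects_blob_exclusion(self, rng):
        v = rng.normal(100.0, 1.0, (20, 20))
        v[10, 10] = 300.0  # blob
        v[10, 12] = 50.0   # minimum 2 px from the blob: excluded
        v[0, 0] = 60.0
        img = make_image(v)
        blobs = segment_blobs(img, min_area=1)
        sel = select_probe_sites(img, blobs, d_min=3.0)
        assert sel.dark_px != (10, 12)

    def test_blob_centroids_near_true_pores(self):
        """Every detected blob lies within one beam diameter of a real pore."""
        skin = generate_skin_map(seed=8, secretion_noise=0.0)
        config = InstrumentConfig(noise_sigma=0.0)
        img = raster_scan(skin, t=120.0, config=config, seed=0)
        blobs = segment_blobs(img)
        assert blobs.n_blobs >= 1
        for summary in blobs.summaries:
            bx, by = summary.centroid_um
            d = min(np.hypot(bx - p.x, by - p.y) for p in skin.pores)
            assert d <= config.beam_diameter


class TestDifferenceSpectrum:
    def test_identical_spectra_cancel(self, grid):
        s = Spectrum(grid=grid, values=np.linspace(1, 2, len(grid)))
        assert np.all(difference_spectrum(s, s).values == 0.0)

    def test_antisymmetry(self, grid, rng):
        a = Spectrum(grid=grid, values=rng.random(len(grid)))
        b = Spectrum(grid=grid, values=rng.random(len(grid)))
        assert np.allclose(
            difference_spectrum(a, b).values, -difference_spectrum(b, a).values
        )

    def test_grid_and_state_mismatch_rejected(self, grid):
        from pascan.synthetic_skin import make_wavenumber_grid

        other = make_wavenumber_grid(950.0, 1240.0, 2.76)
        a = Spectrum(grid=grid, values=np.ones(len(grid)))
        b = Spectrum(grid=other, values=np.ones(len(other)))
        with pytest.raises(ValueError):
            difference_spectrum(a, b)
        c = Spectrum(grid=grid, values=np.ones(len(grid)), normalized=True)
        with pytest.raises(ValueError):
            difference_spectrum(a, c)

    def test_bright_minus_dark_recovers_lactate(self, grid, rng):
        lactate = component_spectrum("sodium_lactate", grid).values
        dark = rng.random(len(grid))
        bright = dark + 0.8 * lactate
        diff = difference_spectrum(
            Spectrum(grid=grid, values=bright), Spectrum(grid=grid, values=dark)
        )
        dc = diff.values - diff.values.mean()
        lc = lactate - lactate.mean()
        corr = dc @ lc / (np.linalg.norm(dc) * np.linalg.norm(lc))
        assert corr > 0.999


class TestMatchAnalyte:
    def library(self, grid):
        return [component_spectrum(a, grid) for a in ("glucose", "sodium_lactate", "skin_baseline")]

    def test_exact_lactate_scores_one(self, grid):
        lactate = component_spectrum("sodium_lactate", grid)
        match = match_analyte(Spectrum(grid=grid, values=lactate.values), self.library(grid))
        assert match.best == "sodium_lactate"
        assert match.scores["sodium_lactate"] == pytest.approx(1.0)

    def test_zero_variance_reports_no_match(self, grid):
        match = match_analyte(
            Spectrum(grid=grid, values=np.full(len(grid), 2.0)), self.library(grid)
        )
        assert match.best is None
        assert all(np.isnan(v) for v in match.scores.values())

    def test_flat_library_spectrum_scores_zero(self, grid, rng):
        from pascan.synthetic_skin import ComponentSpectrum

        flat = ComponentSpectrum("flat", grid, np.full(len(grid), 3.0))
        match = match_analyte(
            Spectrum(grid=grid, values=rng.random(len(grid))), [flat]
        )
        assert match.scores["flat"] == 0.0

    def test_empty_library_rejected(self, grid):
        with pytest.raises(ValueError):
            match_analyte(Spectrum(grid=grid, values=np.ones(len(grid))), [])


class TestMonitorSecretion:
    def quiet(self):
        return InstrumentConfig(noise_sigma=0.0)

    def secreting_map(self):
        return SkinMap(
            extent=(1500.0, 1500.0),
            ridge_period=450.0,
            coupling_floor=1.0,
            pores=(Pore(x=750.0, y=750.0, s_max=1.2, tau=15.0),),
            concentrations={"skin_baseline": 1.0},
            secretion_noise=0.0,
        )

    def test_nonsecreting_site_is_constant(self, grid):
        skin = SkinMap(
            extent=(1500.0, 1500.0), ridge_period=450.0, coupling_floor=1.0,
            concentrations={"skin_baseline": 1.0}, secretion_noise=0.0,
        )
        series = monitor_secretion(
            skin, (700.0, 700.0), [0.0, 30.0, 60.0, 120.0], grid, self.quiet(), seed=0
        )
        for values in series.channels.values():
            assert np.allclose(values, values[0], rtol=1e-9)

    def test_secreting_site_rises_concavely(self, grid):
        series = monitor_secretion(
            self.secreting_map(), (750.0, 750.0),
            np.linspace(0.0, 120.0, 13), grid, self.quiet(), seed=0,
        )
        for values in series.channels.values():
            assert np.all(np.diff(values) > 0)
            assert np.all(np.diff(values, 2) < 0)

    def test_saturated_after_about_one_hour(self, grid):
        series = monitor_secretion(
            self.secreting_map(), (750.0, 750.0), [60.0, 240.0], grid, self.quiet(), seed=0
        )
        for values in series.channels.values():
            assert values[0] >= 0.98 * values[1]

    def test_marker_channels_near_1070_and_1140(self, grid):
        series = monitor_secretion(
            self.secreting_map(), (750.0, 750.0), [10.0], grid, self.quiet(), seed=0
        )
        channels = sorted(series.channels)
        assert abs(channels[0] - 1070.0) <= grid.step
        assert abs(channels[1] - 1140.0) <= grid.step

    def test_unsorted_times_rejected(self, grid):
        with pytest.raises(ValueError):
            monitor_secretion(
                self.secreting_map(), (750.0, 750.0), [10.0, 5.0], grid, self.quiet()
            )
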