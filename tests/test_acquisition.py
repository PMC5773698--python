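"""Instrument forward model: beam, raster scans, spectra, resonance, accounting."""

import math

import numpy as np
import pytest

from pascan.acquisition import (
    InstrumentConfig,
    acquire_spectrum,
    beam_kernel,
    cell_gain,
    laser_accounting,
    normalize_by_pulse_energy,
    raster_scan,
    resolution_contrast,
)
from pascan.synthetic_skin import Pore, SkinMap, make_wavenumber_grid


def uniform_map(level=1.0, extent=(1500.0, 1500.0)):
    """Spatially uniform absorber: full coupling, no ridge contrast, no pores."""
    return SkinMap(
        extent=extent,
        ridge_period=450.0,
        coupling_floor=1.0,
        concentrations={"skin_baseline": level},
        spectra_bands={"skin_baseline": ((1100.0, 120.0, 1.0),)},
        secretion_noise=0.0,
    )


class TestBeamKernel:
    def test_sums_to_one(self, quiet_instrument):
        k = beam_kernel(quiet_instrument, 44.0)
        assert abs(k.weights.sum() - 1.0) < 1e-9

    def test_point_symmetry(self, quiet_instrument):
        k = beam_kernel(quiet_instrument, 44.0)
        assert np.allclose(k.weights, k.weights[::-1, ::-1])

    def test_fwhm_matches_gaussian_closed_form(self, quiet_instrument):
        """90 um 1/e^2 diameter -> FWHM = 90 sqrt(ln2 / 2) ~ 52.99 um."""
        k = beam_kernel(quiet_instrument, 0.25)
        center = k.weights.shape[0] // 2
        profile = k.weights[center]
        half = profile.max() / 2.0
        above = k.offsets[profile >= half]
        fwhm = above.max() - above.min()
        assert fwhm == pytest.approx(90.0 * math.sqrt(math.log(2) / 2.0), abs=0.6)

    def test_coarse_pitch_warns(self, quiet_instrument):
        with pytest.warns(UserWarning, match="undersamples"):
            beam_kernel(quiet_instrument, 200.0)


class TestRasterScan:
    def test_uniform_map_gives_uniform_image(self, quiet_instrument):
        img = raster_scan(uniform_map(), t=0.0, config=quiet_instrument, seed=0)
        assert np.allclose(img.values, img.values[0, 0], rtol=1e-9)

    def test_field_of_view_printed_as_1p3_mm(self, quiet_instrument):
        img = raster_scan(uniform_map(), t=0.0, config=quiet_instrument, seed=0)
        assert img.field_of_view_mm == pytest.approx(1.32)
        assert round(img.field_of_view_mm, 1) == 1.3

    def test_saturated_pore_is_image_maximum(self, quiet_instrument):
        pore = Pore(x=750.0, y=700.0, s_max=1.5, tau=15.0)
        skin = SkinMap(
            extent=(1500.0, 1500.0),
            ridge_period=450.0,
            coupling_floor=1.0,
            pores=(pore,),
            concentrations={"skin_baseline": 1.0},
            secretion_noise=0.0,
        )
        img = raster_scan(skin, t=300.0, config=quiet_instrument, seed=0)
        row, col = np.unravel_index(np.argmax(img.values), img.values.shape)
        x, y = img.pixel_center_um(row, col)
        assert abs(x - pore.x) <= img.pixel_pitch
        assert abs(y - pore.y) <= img.pixel_pitch

    def test_matches_per_pixel_convolution_oracle(self, quiet_instrument):
        """Vectorized scan equals an explicit per-pixel kernel sum on a toy map."""
        config = InstrumentConfig(n_pixels=10, noise_sigma=0.0)
        skin = SkinMap(
            extent=(800.0, 800.0),
            ridge_period=300.0,
            pores=(Pore(x=400.0, y=380.0, s_max=1.0, tau=10.0),),
            secretion_noise=0.0,
        )
        img = raster_scan(skin, t=60.0, config=config, seed=0)
        kernel = beam_kernel(config, config.step)
        origin = img.origin
        gain = cell_gain(config.rep_rate, config)
        energy = float(config.pulse_energy(img.wavenumber)[0])
        oracle = np.empty_like(img.values)
        for i in range(config.n_pixels):
            for j in range(config.n_pixels):
                cx = origin[0] + config.step * (j + 0.5)
                cy = origin[1] + config.step * (i + 0.5)
                acc = 0.0
                for a, dy in enumerate(kernel.offsets):
                    for b, dx in enumerate(kernel.offsets):
                        val = skin.absorption(cx + dx, cy + dy, [img.wavenumber], 60.0)
                        acc += kernel.weights[a, b] * float(val[0])
                oracle[i, j] = gain * energy * acc
        assert np.allclose(img.values, oracle, rtol=1e-6)

    def test_map_must_cover_scan_field(self, quiet_instrument):
        with pytest.raises(ValueError, match="cover"):
            raster_scan(uniform_map(extent=(800.0, 800.0)), t=0.0, config=quiet_instrument)

    def test_wavenumber_outside_tuning_range_rejected(self, quiet_instrument):
        with pytest.raises(ValueError, match="tuning range"):
            raster_scan(uniform_map(), t=0.0, wavenumber=2000.0, config=quiet_instrument)


class TestResolutionTarget:
    def test_wide_lines_fully_resolved(self, quiet_instrument):
        assert resolution_contrast(900.0, quiet_instrument) > 0.95

    def test_90um_lines_resolved_at_contrast_criterion(self, quiet_instrument):
        assert resolution_contrast(90.0, quiet_instrument) >= 0.10

    def test_lines_much_finer_than_beam_wash_out(self, quiet_instrument):
        assert resolution_contrast(9.0, quiet_instrument) < 0.05

    def test_contrast_monotone_in_line_width(self, quiet_instrument):
        widths = [10.0, 30.0, 90.0, 300.0]
        contrasts = [resolution_contrast(w, quiet_instrument) for w in widths]
        assert all(a <= b for a, b in zip(contrasts, contrasts[1:]))

    def test_nonpositive_width_rejected(self, quiet_instrument):
        with pytest.raises(ValueError):
            resolution_contrast(0.0, quiet_instrument)


class TestSpectralAcquisition:
    def test_zero_absorbers_zero_noise_gives_zero_spectrum(self, grid, quiet_instrument):
        skin = uniform_map(level=0.0)
        spec = acquire_spectrum(skin, (750.0, 750.0), 0.0, grid, quiet_instrument, seed=0)
        assert np.all(spec.values == 0.0)

    def test_linear_in_concentration_and_pulse_energy(self, grid, quiet_instrument):
        pos = (750.0, 750.0)
        s1 = acquire_spectrum(uniform_map(1.0), pos, 0.0, grid, quiet_instrument, 0)
        s2 = acquire_spectrum(uniform_map(2.0), pos, 0.0, grid, quiet_instrument, 0)
        assert np.allclose(s2.values, 2.0 * s1.values, rtol=1e-12)
        doubled = InstrumentConfig(noise_sigma=0.0, pulse_energy_peak_nj=2 * 44.2)
        s3 = acquire_spectrum(uniform_map(1.0), pos, 0.0, grid, doubled, 0)
        assert np.allclose(s3.values, 2.0 * s1.values, rtol=1e-12)

    def test_position_outside_map_rejected(self, grid, quiet_instrument):
        with pytest.raises(ValueError, match="outside"):
            acquire_spectrum(uniform_map(), (5000.0, 0.0), 0.0, grid, quiet_instrument)


class TestPulseEnergyNormalization:
    def test_flat_energy_curve_leaves_spectrum_unchanged(self, grid, quiet_instrument):
        flat = InstrumentConfig(
            noise_sigma=0.0,
            pulse_energy_table=((900.0, 1250.0), (1.0, 1.0)),
        )
        spec = acquire_spectrum(uniform_map(), (750.0, 750.0), 0.0, grid, flat, 0)
        norm = normalize_by_pulse_energy(spec, flat)
        assert np.allclose(norm.values, spec.values)
        assert norm.normalized and not spec.normalized

    def test_uniform_absorber_normalizes_flat(self, grid, quiet_instrument):
        """A wavenumber-flat absorber: the raw spectrum is the energy curve,
        so normalization must return a flat line."""
        skin = SkinMap(
            extent=(1500.0, 1500.0),
            ridge_period=450.0,
            coupling_floor=1.0,
            concentrations={"flat": 1.0},
            spectra_bands={"flat": ((1100.0, 1e7, 1.0),)},
            secretion_noise=0.0,
        )
        spec = acquire_spectrum(skin, (750.0, 750.0), 0.0, grid, quiet_instrument, 0)
        norm = normalize_by_pulse_energy(spec, quiet_instrument)
        assert np.allclose(norm.values, norm.values[0], rtol=1e-9)

    def test_double_normalization_rejected(self, grid, quiet_instrument):
        spec = acquire_spectrum(uniform_map(), (750.0, 750.0), 0.0, grid, quiet_instrument, 0)
        norm = normalize_by_pulse_energy(spec, quiet_instrument)
        with pytest.raises(ValueError, match="already"):
            normalize_by_pulse_energy(norm, quiet_instrument)

    def test_nonpositive_energy_rejected(self, grid, quiet_instrument):
        bad = InstrumentConfig(
            noise_sigma=0.0, pulse_energy_table=((900.0, 1250.0), (0.0, 0.0))
        )
        spec = acquire_spectrum(uniform_map(), (750.0, 750.0), 0.0, grid, quiet_instrument, 0)
        with pytest.raises(ValueError, match="positive"):
            normalize_by_pulse_energy(spec, bad)


class TestCellResonance:
    def test_peak_at_resonance(self):
        config = InstrumentConfig()
        freqs = np.linspace(30e3, 65e3, 2001)
        gains = [cell_gain(float(f), config) for f in freqs]
        assert freqs[int(np.argmax(gains))] == pytest.approx(47_500.0, abs=20)

    def test_half_power_full_width(self):
        """Q = 17 at 47.5 kHz -> half-power full width 47500/17 ~ 2794 Hz."""
        config = InstrumentConfig()
        hwhm = 47_500.0 / (2 * 17.0)
        assert cell_gain(47_500.0 + hwhm, config) == pytest.approx(17.0 / 2.0)
        assert cell_gain(47_500.0 - hwhm, config) == pytest.approx(17.0 / 2.0)

    def test_near_resonance_symmetry(self):
        config = InstrumentConfig()
        for delta in (500.0, 2000.0, 4750.0):
            up = cell_gain(47_500.0 + delta, config)
            down = cell_gain(47_500.0 - delta, config)
            assert up == pytest.approx(down, rel=0.01)

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            cell_gain(0.0)


class TestLaserAccounting:
    def test_pulse_and_power_bookkeeping(self):
        acc = laser_accounting(InstrumentConfig())
        assert acc["pulses_per_tc"] == 1425
        assert round(acc["avg_power_mW"], 1) == 2.1
        assert acc["peak_power_mW"] == pytest.approx(88.4)
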