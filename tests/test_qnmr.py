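"""Lorentzian integration, SNR and internal-standard quantification."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dtsq.doe import AcquisitionSettings
from dtsq.qnmr import (
    PeakModel,
    QuantSetup,
    Spectrum,
    SpectrumError,
    accuracy_index,
    fit_and_integrate,
    quantify,
    quantify_spectrum,
    resolution_index,
    snr,
)
from dtsq.synthetic import VirtualInstrumentConfig, simulate_spectrum

FREQ = 500.13


def lorentz_spectrum(peaks, noise_sd=0.0, seed=0, n=16384, ppm_max=11.0, sw=12.016):
    ppm = np.linspace(ppm_max, ppm_max - sw, n)
    y = np.zeros(n)
    for c, h, w_hz in peaks:
        hw = w_hz / FREQ / 2
        y += h * hw**2 / ((ppm - c) ** 2 + hw**2)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, n)
    return Spectrum(ppm, y, {"frequency_mhz": FREQ})


def test_axis_must_be_uniform_and_descending():
    with pytest.raises(SpectrumError):
        Spectrum(np.linspace(0, 10, 50), np.zeros(50))
    bad = np.concatenate([np.linspace(10, 5, 25), np.linspace(4, 0, 25)])
    with pytest.raises(SpectrumError):
        Spectrum(bad, np.zeros(50))


def test_window_outside_axis_rejected():
    spec = lorentz_spectrum([(8.11, 100, 0.8)])
    with pytest.raises(SpectrumError):
        spec.window(40.0, 41.0)


def test_single_lorentzian_area_recovered_on_noiseless_data():
    h, w = 123.0, 0.7
    spec = lorentz_spectrum([(8.11, h, w)])
    peaks, total, _ = fit_and_integrate(spec, (7.9, 8.3), 1)
    assert total == pytest.approx(h * math.pi * w / 2, rel=1e-6)
    assert peaks[0].center_ppm == pytest.approx(8.11, abs=1e-6)
    assert peaks[0].fwhm_hz == pytest.approx(w, rel=1e-6)


def test_overlapping_doublet_resolved_on_noiseless_data():
    spec = lorentz_spectrum([(1.62, 80.0, 0.9), (1.68, 50.0, 0.9)])
    peaks, _, _ = fit_and_integrate(spec, (1.45, 1.85), 2, centers=[1.62, 1.68])
    a1, a2 = peaks[0].area, peaks[1].area
    assert a1 == pytest.approx(80.0 * math.pi * 0.9 / 2, rel=1e-4)
    assert a2 == pytest.approx(50.0 * math.pi * 0.9 / 2, rel=1e-4)


def test_area_error_below_one_percent_at_snr_1000():
    h, w = 100.0, 0.8
    true_area = h * math.pi * w / 2
    errors = []
    for seed in range(25):
        spec = lorentz_spectrum([(8.11, h, w)], noise_sd=h / 2000, seed=seed)
        _, total, _ = fit_and_integrate(spec, (7.9, 8.3), 1)
        errors.append(abs(total - true_area) / true_area)
    assert max(errors) < 0.01


def test_fit_conserves_area_across_window_partitions():
    spec = lorentz_spectrum([(1.62, 80, 0.9), (1.68, 50, 0.9), (8.11, 120, 0.8)])
    _, a_ts, _ = fit_and_integrate(spec, (1.3, 2.0), 2, centers=[1.62, 1.68])
    _, a_dmt, _ = fit_and_integrate(spec, (7.9, 8.3), 1, centers=[8.11])
    _, a_all, _ = fit_and_integrate(spec, (1.3, 8.3), 3, centers=[1.62, 1.68, 8.11])
    assert a_all == pytest.approx(a_ts + a_dmt, rel=1e-3)


def test_snr_by_construction_and_scale_invariance():
    h = 1000.0
    sd = 0.5
    spec = lorentz_spectrum([(8.11, h, 0.8)], noise_sd=sd, seed=4)
    peaks, _, _ = fit_and_integrate(spec, (7.9, 8.3), 1)
    value = snr(spec, peaks[0], (9.5, 10.0))
    assert value == pytest.approx(h / (2 * sd), rel=0.1)
    doubled = Spectrum(spec.ppm, 2 * spec.intensity, spec.meta)
    peaks2, _, _ = fit_and_integrate(doubled, (7.9, 8.3), 1)
    assert snr(doubled, peaks2[0], (9.5, 10.0)) == pytest.approx(value, rel=1e-6)


def test_snr_undefined_on_noiseless_spectrum():
    spec = lorentz_spectrum([(8.11, 10, 0.8)])
    peaks, _, _ = fit_and_integrate(spec, (7.9, 8.3), 1)
    flat = spec.intensity.copy()
    flat[spec.ppm > 9.0] = 0.0  # strictly silent noise region
    with pytest.raises(SpectrumError, match="noise"):
        snr(Spectrum(spec.ppm, flat, spec.meta), peaks[0], (9.5, 10.0))


def test_quadrupling_scans_doubles_snr():
    def measure(ns):
        cfg = VirtualInstrumentConfig(
            seed=8, acquisition=AcquisitionSettings(NS=ns))
        return quantify_spectrum(simulate_spectrum(cfg)).snr

    assert measure(128) / measure(32) == pytest.approx(2.0, rel=0.15)


def test_equal_areas_give_four_thirds_of_standard_concentration():
    assert quantify(1.0, 1.0) == pytest.approx(1.9467, abs=5e-5)
    assert quantify(0.0, 1.0) == 0.0
    with pytest.raises(SpectrumError):
        quantify(1.0, 0.0)


@given(c=st.floats(1e-3, 1e3), a=st.floats(1e-3, 1e3))
def test_quantification_homogeneity_and_linearity(c, a):
    base = quantify(a, 2.0)
    assert quantify(c * a, c * 2.0) == pytest.approx(base, rel=1e-9)
    assert quantify(3 * a, 2.0) == pytest.approx(3 * base, rel=1e-9)
    setup = QuantSetup(m_dmt=2.92)  # doubling the standard doubles the result
    assert quantify(a, 2.0, setup) == pytest.approx(2 * base, rel=1e-9)


@pytest.mark.parametrize("measured,true,expected",
                         [(5.05, 5.00, 1.0), (5.00, 5.00, 0.0)])
def test_accuracy_index_examples(measured, true, expected):
    assert accuracy_index(measured, true) == pytest.approx(expected)


def test_resolution_index_round_trip_and_monotonicity():
    spec = lorentz_spectrum([(1.68, 60, 0.7)])
    peaks, _, _ = fit_and_integrate(spec, (1.5, 1.85), 1)
    assert resolution_index(peaks[0]) == pytest.approx(0.7, rel=1e-5)
    wider = lorentz_spectrum([(1.68, 60, 1.2)])
    peaks_w, _, _ = fit_and_integrate(wider, (1.5, 1.85), 1)
    assert resolution_index(peaks_w[0]) > resolution_index(peaks[0])


def test_peak_model_area_identity():
    p = PeakModel(8.11, 40.0, 0.9)
    assert p.area == pytest.approx(40.0 * math.pi * 0.9 / 2)
    with pytest.raises(SpectrumError):
        PeakModel(8.11, 40.0, 0.0)


def test_overlapping_quant_windows_rejected():
    with pytest.raises(SpectrumError, match="overlap"):
        QuantSetup(dmt_window=(1.5, 8.2), ts_window=(1.45, 1.85))


@pytest.mark.parametrize("m_true", [0.5, 2.5, 5.0])
def test_end_to_end_round_trip_within_two_percent(m_true):
    """Full pipeline (simulate -> fit -> quantify) at the study's sample
    levels recovers the true concentration within 2% at SNR >= 1000."""
    cfg = VirtualInstrumentConfig(m_ts=m_true, seed=17)
    result = quantify_spectrum(simulate_spectrum(cfg))
    assert result.snr >= 1000
    assert accuracy_index(result.m_ts, m_true) < 2.0


def test_spectrum_csv_round_trip(tmp_path):
    cfg = VirtualInstrumentConfig(seed=3, acquisition=AcquisitionSettings(TD=8192))
    spec = simulate_spectrum(cfg)
    path = tmp_path / "spectrum.csv"
    spec.to_csv(path)
    loaded = Spectrum.from_csv(path)
    assert loaded.meta["NS"] == 32
    assert np.allclose(loaded.intensity, spec.intensity, atol=1e-6)
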