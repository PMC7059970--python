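"""Measurement layer: spectra, bursts, wavelets, phase coupling."""

import numpy as np
import pytest

from striatal_rhythms import DEFAULT_BANDS, BandDefinition
from striatal_rhythms.analysis import (burst_stats, detect_spikes,
                                       multitaper_psd, phase_modulation,
                                       spectrogram, surrogate_lfp,
                                       wavelet_band_trace)


FS = 1000.0


def test_band_definition_validation():
    with pytest.raises(ValueError):
        BandDefinition("bad", 10.0, 5.0)
    with pytest.raises(ValueError):
        BandDefinition("bad", 0.0, 5.0)


# ---------------------------------------------------------------- spikes

def test_detect_spikes_cases():
    t = np.arange(0, 1000.0, 0.1)
    assert detect_spikes(np.full(t.size, -70.0), time=t).size == 0
    # 40 Hz template train
    v = np.full(t.size, -70.0)
    for onset in np.arange(10.0, 1000.0, 25.0):
        idx = int(onset / 0.1)
        v[idx:idx + 10] = 20.0
    spikes = detect_spikes(v, time=t)
    assert spikes.size == len(np.arange(10.0, 1000.0, 25.0))
    assert detect_spikes(v, time=t, threshold=50.0).size == 0
    with pytest.raises(ValueError):
        detect_spikes(v, time=np.cumsum(np.random.default_rng(0).random(t.size)))
    with pytest.raises(ValueError):
        detect_spikes(v)


def test_detect_spikes_refractory():
    t = np.arange(0, 100.0, 0.1)
    v = -70.0 + 80.0 * (np.sin(2 * np.pi * 0.5 * t / 1.0) > 0.99)
    dense = detect_spikes(v, time=t, refractory=0.0)
    sparse = detect_spikes(v, time=t, refractory=5.0)
    assert sparse.size <= dense.size
    assert np.all(np.diff(sparse) >= 5.0)


# ---------------------------------------------------------------- PSD

def test_multitaper_sinusoid_peak():
    t = np.arange(0, 4.0, 1 / FS)
    x = np.sin(2 * np.pi * 60.0 * t)
    summary = multitaper_psd(x, FS)
    peak = summary.peak("gamma_wide")
    df = FS / x.size
    assert abs(peak.frequency - 60.0) <= 2.0 + df


def test_multitaper_white_noise_flat():
    rng = np.random.default_rng(0)
    x = rng.standard_normal(8000)
    summary = multitaper_psd(x, FS)
    for name, peak in summary.band_peaks.items():
        assert peak.peak_power < 5.0 * peak.band_median


@pytest.mark.parametrize("make", [
    lambda t, rng: np.sin(2 * np.pi * 23.0 * t),
    lambda t, rng: rng.standard_normal(t.size),
    lambda t, rng: np.sin(2 * np.pi * 3.0 * t) * (1 + 0.5 * rng.standard_normal(t.size)),
])
def test_multitaper_parseval(make):
    rng = np.random.default_rng(1)
    t = np.arange(0, 5.0, 1 / FS)
    x = make(t, rng)
    summary = multitaper_psd(x, FS)
    total = summary.psd.sum() * FS / x.size
    assert total == pytest.approx(np.var(x), rel=0.05)


def test_multitaper_psd_nonnegative_and_peaks_in_band():
    rng = np.random.default_rng(2)
    x = rng.standard_normal(4000) + np.sin(2 * np.pi * 15 * np.arange(4000) / FS)
    summary = multitaper_psd(x, FS)
    assert np.all(summary.psd >= 0)
    for name, peak in summary.band_peaks.items():
        band = DEFAULT_BANDS[name]
        assert band.f_lo <= peak.frequency <= band.f_hi


def test_multitaper_rejects_short_series():
    with pytest.raises(ValueError):
        multitaper_psd(np.zeros(5), FS)


def test_detector_psd_coherence():
    """A regular spike train's PSD fundamental matches its rate."""
    rate = 40.0
    t = np.arange(0, 4000.0, 1.0 / 10.0)  # ms, 10 kHz
    v = np.full(t.size, -70.0)
    for onset in np.arange(5.0, 4000.0, 1000.0 / rate):
        idx = int(onset * 10)
        v[idx:idx + 15] = 30.0
    spikes = detect_spikes(v, time=t)
    measured_rate = (spikes.size - 1) / ((spikes[-1] - spikes[0]) / 1000.0)
    summary = multitaper_psd(v - v.mean(), 10_000.0,
                             bands={"fund": BandDefinition("fund", 20.0, 60.0)})
    df = 10_000.0 / v.size
    assert abs(summary.peak("fund").frequency - measured_rate) <= df + 2.0


# ---------------------------------------------------------------- spectrogram

def test_spectrogram_stationary_and_switching():
    t = np.arange(0, 4.0, 1 / FS)
    x = np.sin(2 * np.pi * 20.0 * t)
    times, freqs, S = spectrogram(x, FS, window_ms=500.0, step_ms=100.0)
    ridge = freqs[S.argmax(axis=0)]
    assert np.all(np.abs(ridge - 20.0) < 4.0)

    x2 = np.concatenate([np.sin(2 * np.pi * 20.0 * t[:2000]),
                         np.sin(2 * np.pi * 80.0 * t[:2000])])
    times, freqs, S = spectrogram(x2, FS, window_ms=400.0, step_ms=100.0)
    ridge = freqs[S.argmax(axis=0)]
    early = ridge[times < 1500.0]
    late = ridge[times > 2500.0]
    assert np.all(np.abs(early - 20.0) < 6.0)
    assert np.all(np.abs(late - 80.0) < 6.0)
    with pytest.raises(ValueError):
        spectrogram(x, FS, window_ms=0.0, step_ms=10.0)
    with pytest.raises(ValueError):
        spectrogram(x[:100], FS, window_ms=500.0, step_ms=10.0)


# ---------------------------------------------------------------- bursts

def test_burst_stats_triplets():
    bursts = [np.array([0.0, 10.0, 20.0]) + k * 500.0 for k in range(6)]
    spikes = np.concatenate(bursts)
    stats = burst_stats(spikes, max_intraburst_isi=25.0)
    assert stats.n_bursts == 6
    assert stats.intraburst_rate == pytest.approx(100.0)
    assert stats.interburst_freq == pytest.approx(2.0)
    assert stats.spikes_per_burst == [3] * 6


def test_burst_stats_tonic_flagged():
    spikes = np.arange(0.0, 1000.0, 20.0)  # 50 Hz, threshold 25 ms
    stats = burst_stats(spikes, max_intraburst_isi=25.0)
    assert stats.n_bursts == 1
    assert stats.tonic
    assert np.isnan(stats.interburst_freq)
    assert stats.intraburst_rate == pytest.approx(50.0)


def test_burst_stats_empty_and_unsorted():
    stats = burst_stats(np.array([]))
    assert stats.n_bursts == 0
    with pytest.raises(ValueError):
        burst_stats(np.array([10.0, 5.0]))


# ---------------------------------------------------------------- wavelets

def test_wavelet_band_envelope_in_vs_out_of_band():
    t = np.arange(0, 4.0, 1 / FS)
    band = DEFAULT_BANDS["beta"]
    x_in = np.sin(2 * np.pi * 19.0 * t)
    x_out = np.sin(2 * np.pi * 70.0 * t)
    _, env_in = wavelet_band_trace(x_in, FS, band)
    _, env_out = wavelet_band_trace(x_out, FS, band)
    mid = slice(500, -500)
    assert env_in[mid].std() / env_in[mid].mean() < 0.1  # ~constant
    assert env_out[mid].mean() < 0.05 * env_in[mid].mean()
    with pytest.raises(ValueError):
        wavelet_band_trace(x_in, FS, BandDefinition("uhf", 100.0, 600.0))


# ---------------------------------------------------------------- coupling

def test_phase_modulation_flat_envelope_needs_variance():
    slow = np.sin(2 * np.pi * 3.0 * np.arange(0, 4.0, 1 / FS))
    with pytest.raises(ValueError):
        phase_modulation(slow, np.ones(slow.size))


def test_phase_modulation_detects_coupling():
    t = np.arange(0, 10.0, 1 / FS)
    slow = np.cos(2 * np.pi * 3.0 * t)
    rng = np.random.default_rng(3)
    env_coupled = 1.0 + slow  # maximal at phase 0
    phase, depth = phase_modulation(slow, env_coupled)
    assert abs(phase) < 0.2
    assert depth > 0.3
    env_flat = 1.0 + 0.5 * rng.random(t.size)
    _, depth_flat = phase_modulation(slow, env_flat)
    assert depth_flat < 0.05


# ---------------------------------------------------------------- LFP

def test_surrogate_lfp_linearity_and_selectors(tiny_combined):
    res = tiny_combined
    t, lfp_all = surrogate_lfp(res, "all")
    _, lfp_fsi = surrogate_lfp(res, "fsi")
    _, lfp_spn = surrogate_lfp(res, "spn")
    assert lfp_all == pytest.approx(lfp_fsi + lfp_spn)
    _, d1 = surrogate_lfp(res, "d1")
    _, d2 = surrogate_lfp(res, "d2")
    assert lfp_spn == pytest.approx(d1 + d2)
    _, fsi_part = surrogate_lfp(res, "fsi", indices=[0, 1])
    _, fsi_rest = surrogate_lfp(res, "fsi", indices=[2, 3, 4])
    assert lfp_fsi == pytest.approx(fsi_part + fsi_rest)
    # source split partitions the SPN currents
    _, from_fsi = surrogate_lfp(res, "spn", source="fsi")
    _, from_spn = surrogate_lfp(res, "spn", source="spn")
    assert lfp_spn == pytest.approx(from_fsi + from_spn)
    assert np.all(t >= res.settings.t_transient)
    with pytest.raises(ValueError):
        surrogate_lfp(res, "cortex")
    with pytest.raises(ValueError):
        surrogate_lfp(res, "fsi", indices=[])


def test_surrogate_lfp_zero_when_conductances_zero():
    from striatal_rhythms import (IntegrationSettings, NetworkSpec, NoiseSpec,
                                  SynapseParams, simulate)
    spec = NetworkSpec(n_fsi=3, n_d1=3, n_d2=3)
    settings = IntegrationSettings(t_total=200.0, t_transient=50.0, seed=0)
    syn = SynapseParams(g_fsi_fsi=0.0, g_fsi_spn=0.0, g_spn_spn=0.0, g_gj=0.0)
    res = simulate(spec, "high", settings, NoiseSpec(), synapse=syn)
    _, lfp = surrogate_lfp(res, "all")
    assert np.allclose(lfp, 0.0)
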