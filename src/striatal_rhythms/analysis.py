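"""Measurement layer: spikes, surrogate LFP, spectra, bursts, coupling.

The observables mirror standard practice for this kind of circuit model:
the surrogate local field potential is the sum of GABA_A synaptic currents
over a chosen population; spectra are Thomson multitaper estimates (DPSS
tapers, time-bandwidth 4, 7 tapers by default) of de-meaned traces; burst
structure is segmented by an interspike-interval threshold separating
gamma-rate intraburst intervals from delta/theta interburst gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
import scipy.signal
from scipy.signal.windows import dpss

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "SpectralSummary",
    "BurstStats",
    "detect_spikes",
    "surrogate_lfp",
    "multitaper_psd",
    "spectrogram",
    "burst_stats",
    "minimum_firing_rate",
    "wavelet_band_trace",
    "phase_modulation",
    "band_interactions",
    "packet_interactions",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError("require 0 < f_lo < f_hi")


DEFAULT_BANDS = {
    "delta_theta": BandDefinition("delta_theta", 1.0, 10.0),
    "beta": BandDefinition("beta", 8.0, 30.0),
    "low_gamma": BandDefinition("low_gamma", 40.0, 60.0),
    "high_gamma": BandDefinition("high_gamma", 60.0, 100.0),
    "gamma_wide": BandDefinition("gamma_wide", 40.0, 100.0),
}


@dataclass
class BandPeak:
    """Peak location and power of a PSD restricted to one band."""

    frequency: float      # Hz, argmax within the band
    peak_power: float
    band_power: float     # integral of the PSD over the band
    band_median: float    # median PSD value within the band


@dataclass
class SpectralSummary:
    """Multitaper PSD plus per-band peak statistics."""

    frequencies: np.ndarray
    psd: np.ndarray
    band_peaks: dict
    meta: dict = field(default_factory=dict)

    def peak(self, band: str) -> BandPeak:
        return self.band_peaks[band]


@dataclass
class BurstStats:
    """Burst segmentation of a spike train.

    ``intraburst_rate`` is the mean instantaneous rate over within-burst
    intervals; ``interburst_freq`` the reciprocal of the mean burst-onset
    interval.  ``tonic`` flags trains in which a single group covers every
    spike, leaving the interburst frequency undefined.
    """

    n_bursts: int
    intraburst_rate: float    # Hz, mean instantaneous (nan if no such ISI)
    interburst_freq: float    # Hz (nan if fewer than two bursts)
    min_rate: float = float("nan")  # Hz, minimal instantaneous within-burst rate
    spikes_per_burst: list = field(default_factory=list)
    tonic: bool = False


def detect_spikes(voltage, time=None, fs=None, threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Upward threshold crossings separated by a refractory window.

    Provide either a uniform ``time`` grid (ms) or a sampling rate ``fs``
    (Hz).  Returns spike times in ms.
    """
    v = np.asarray(voltage, dtype=float)
    if time is not None:
        t = np.asarray(time, dtype=float)
        dt = np.diff(t)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time grid must be uniform")
    elif fs is not None:
        t = np.arange(v.size) * (1000.0 / fs)
    else:
        raise ValueError("provide time or fs")
    crossings = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    spikes = []
    last = -np.inf
    for idx in crossings:
        if t[idx] - last >= refractory:
            spikes.append(t[idx])
            last = t[idx]
    return np.asarray(spikes)


def surrogate_lfp(result, population: str = "all", indices=None,
                  trim_transient: bool = True, source: str = "all"):
    """Summed GABA_A synaptic current of the selected cells.

    ``population`` selects 'fsi', 'd1', 'd2', 'spn' or 'all'; ``indices``
    optionally restricts to cell indices within that population.
    ``source`` filters SPN input currents by their presynaptic origin
    ('all', 'fsi' or 'spn'), which separates the FSI-driven gamma packets
    from the SPN-internal beta currents.  Returns (time_ms, lfp); with
    ``trim_transient`` the initial settling window is excluded, since the
    network is only stationary afterwards.
    """
    if source not in ("all", "fsi", "spn"):
        raise ValueError(f"unknown source {source!r}")
    if source == "all":
        spn_traces = result.spn_syn_current
    elif source == "fsi":
        spn_traces = result.spn_syn_fsi_source
    else:
        spn_traces = result.spn_syn_spn_source
    parts = []
    if population in ("fsi", "all") and source in ("all", "fsi"):
        parts.append(result.fsi_syn_current)
    if population in ("d1", "spn", "all"):
        parts.append(spn_traces[result.d1_slice])
    if population in ("d2", "spn", "all"):
        parts.append(spn_traces[result.d2_slice])
    if population not in ("fsi", "d1", "d2", "spn", "all"):
        raise ValueError(f"unknown population {population!r}")
    traces = np.concatenate(parts, axis=0) if parts else np.zeros((0, 0))
    if indices is not None:
        traces = traces[np.asarray(indices, dtype=np.intp)]
    if traces.shape[0] == 0:
        raise ValueError("empty population selection")
    lfp = traces.sum(axis=0)
    time = result.time
    if trim_transient:
        mask = result.analysis_mask
        return time[mask], lfp[mask]
    return time, lfp


def multitaper_psd(series, fs: float, time_bandwidth: float = 4.0,
                   n_tapers: int = 7, bands=None,
                   demean: bool = True) -> SpectralSummary:
    """Thomson multitaper PSD with per-band peak extraction.

    The PSD is the average of ``n_tapers`` DPSS-tapered one-sided
    periodograms of the de-meaned series; total power integrates to the
    series variance (Parseval).  Band peaks are the argmax of the PSD
    restricted to each band.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 2 * n_tapers:
        raise ValueError("series too short for the requested tapers")
    if demean:
        x = x - x.mean()
    tapers = dpss(n, time_bandwidth, Kmax=n_tapers, sym=False)
    tapers = tapers / np.sqrt(np.sum(tapers ** 2, axis=1, keepdims=True))
    spectra = np.abs(np.fft.rfft(tapers * x[None, :], axis=1)) ** 2 / fs
    psd = spectra.mean(axis=0)
    # one-sided scaling (DC and Nyquist counted once)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    bands = bands if bands is not None else DEFAULT_BANDS
    df = fs / n
    peaks = {}
    for name, band in bands.items():
        sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
        if not np.any(sel):
            continue
        sub = psd[sel]
        fsub = freqs[sel]
        imax = int(np.argmax(sub))
        peaks[name] = BandPeak(frequency=float(fsub[imax]),
                               peak_power=float(sub[imax]),
                               band_power=float(sub.sum() * df),
                               band_median=float(np.median(sub)))
    return SpectralSummary(frequencies=freqs, psd=psd, band_peaks=peaks,
                           meta={"time_bandwidth": time_bandwidth,
                                 "n_tapers": n_tapers, "fs": fs, "n": n})


def spectrogram(series, fs: float, window_ms: float, step_ms: float,
                time_bandwidth: float = 2.5, n_tapers: int = 4):
    """Sliding-window multitaper PSD.

    Returns (window-centre times in ms, frequencies, PSD matrix with shape
    (n_freqs, n_windows)).
    """
    x = np.asarray(series, dtype=float)
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window and step must be positive")
    w = int(round(window_ms * fs / 1000.0))
    s = int(round(step_ms * fs / 1000.0))
    if w > x.size:
        raise ValueError("window longer than series")
    starts = np.arange(0, x.size - w + 1, max(s, 1))
    cols = []
    for st in starts:
        summary = multitaper_psd(x[st:st + w], fs,
                                 time_bandwidth=time_bandwidth,
                                 n_tapers=n_tapers, bands={})
        cols.append(summary.psd)
    freqs = np.fft.rfftfreq(w, d=1.0 / fs)
    t_centers = (starts + w / 2.0) * 1000.0 / fs
    return t_centers, freqs, np.array(cols).T


def burst_stats(spike_times, max_intraburst_isi: float = 25.0) -> BurstStats:
    """Group a sorted spike train into bursts by an ISI threshold.

    Consecutive spikes closer than ``max_intraburst_isi`` ms belong to the
    same burst (the default 25 ms keeps within-burst rates at or above
    40 Hz, an order of magnitude faster than delta/theta interburst gaps).
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return BurstStats(n_bursts=0, intraburst_rate=np.nan,
                          interburst_freq=np.nan)
    if np.any(np.diff(t) < 0):
        raise ValueError("spike times must be sorted")
    isi = np.diff(t)
    breaks = np.flatnonzero(isi > max_intraburst_isi)
    onsets = np.concatenate([[0], breaks + 1])
    bounds = np.concatenate([onsets, [t.size]])
    counts = np.diff(bounds).tolist()
    intra = isi[isi <= max_intraburst_isi]
    intraburst = np.mean(1000.0 / intra) if intra.size else np.nan
    min_rate = 1000.0 / intra.max() if intra.size else np.nan
    if onsets.size >= 2:
        interburst = 1000.0 / np.diff(t[onsets]).mean()
        tonic = False
    else:
        interburst = np.nan
        tonic = t.size > 1
    return BurstStats(n_bursts=int(onsets.size), intraburst_rate=float(intraburst),
                      interburst_freq=float(interburst), min_rate=float(min_rate),
                      spikes_per_burst=counts, tonic=tonic)


def minimum_firing_rate(i_app_grid, fsi=None, t_total: float = 3000.0,
                        t_transient: float = 500.0, dt: float = 0.01,
                        max_intraburst_isi: float = 25.0,
                        return_details: bool = False):
    """Firing rate of a noise-free FSI at the smallest drive that sustains it.

    Simulates a single two-compartment FSI for each applied current on the
    grid (no noise, no synapses) and reports, at the smallest current with
    sustained spiking after the transient, the minimal instantaneous
    firing rate: the reciprocal of the longest interspike interval within
    a burst (for bursting cells) or of the longest interval overall (for
    tonic cells).  This is the rate floor below which the cell never
    fires.  Raises if no grid point spikes.
    """
    from .engine import IntegrationSettings, NoiseSpec, simulate
    from .network import NetworkSpec, dopamine_condition

    spec = NetworkSpec(n_fsi=1, n_d1=0, n_d2=0, seed=0)
    settings = IntegrationSettings(dt=dt, t_total=t_total,
                                   t_transient=t_transient, seed=0)
    for i_app in np.sort(np.asarray(i_app_grid, dtype=float)):
        cond = dopamine_condition("baseline", I_app_fsi=float(i_app))
        result = simulate(spec, cond, settings, NoiseSpec.off(), fsi=fsi)
        spikes = result.fsi_spikes[0]
        spikes = spikes[spikes >= t_transient]
        sustained = (spikes.size >= 4
                     and spikes.size and spikes[-1] >= t_total - 1000.0)
        if not sustained:
            continue
        stats = burst_stats(spikes, max_intraburst_isi=max_intraburst_isi)
        if np.isfinite(stats.min_rate):
            rate = stats.min_rate
        else:
            rate = 1000.0 / np.diff(spikes).max()
        if return_details:
            return {"rate": float(rate), "i_app": float(i_app),
                    "bursting": not stats.tonic and stats.n_bursts > 1,
                    "stats": stats}
        return float(rate)
    raise ValueError("no sustained spiking anywhere on the I_app grid")


def wavelet_band_trace(series, fs: float, band: BandDefinition,
                       n_scales: int = 16, wavelet: str = "cmor1.5-1.0"):
    """Band-limited reconstruction and amplitude envelope via the CWT.

    Complex Morlet coefficients are computed on a grid of scales spanning
    the band; the filtered trace is the mean real part across scales and
    the envelope the magnitude of the mean complex coefficient.
    """
    x = np.asarray(series, dtype=float)
    nyquist = fs / 2.0
    if band.f_hi > nyquist:
        raise ValueError("band extends above the Nyquist frequency")
    freqs = np.linspace(band.f_lo, band.f_hi, n_scales)
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(x - x.mean(), scales, wavelet,
                         sampling_period=1.0 / fs)
    mean_coef = coeffs.mean(axis=0)
    return np.real(mean_coef), np.abs(mean_coef)


def phase_modulation(slow_trace, fast_envelope):
    """Phase-amplitude coupling of a fast envelope to a slow rhythm.

    The slow trace (already band-limited) supplies an instantaneous Hilbert
    phase; the modulation is summarised by the envelope-weighted mean
    resultant vector: ``depth`` in [0, 1] and the preferred phase in rad
    (0 = slow-rhythm peak).
    """
    slow = np.asarray(slow_trace, dtype=float)
    env = np.asarray(fast_envelope, dtype=float)
    if slow.shape != env.shape:
        raise ValueError("series must share one time grid")
    if np.allclose(env.std(), 0.0):
        raise ValueError("degenerate (zero-variance) envelope")
    phase = np.angle(scipy.signal.hilbert(slow - slow.mean()))
    weights = env / env.sum()
    resultant = np.sum(weights * np.exp(1j * phase))
    return float(np.angle(resultant)), float(np.abs(resultant))


def band_interactions(series, fs: float, bands=None,
                      slow_band: str = "delta_theta",
                      beta_band: str = "beta",
                      gamma_band: str = "gamma_wide") -> dict:
    """Beta/gamma envelope correlation and slow-phase coupling of one trace.

    Returns the Pearson correlation between the beta and gamma amplitude
    envelopes, and the coupling (depth, preferred phase) of the gamma
    envelope to the slow-band rhythm.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    slow_filt, _ = wavelet_band_trace(series, fs, bands[slow_band])
    _, beta_env = wavelet_band_trace(series, fs, bands[beta_band])
    _, gamma_env = wavelet_band_trace(series, fs, bands[gamma_band])
    # trim CWT edge effects (one slow-band period each side, but always
    # keep at least a one-second interior on short traces)
    n = len(beta_env)
    edge = min(int(fs / bands[slow_band].f_lo), max((n - int(fs)) // 2, 0))
    sl = slice(edge, n - edge)
    corr = float(np.corrcoef(beta_env[sl], gamma_env[sl])[0, 1])
    phase, depth = phase_modulation(slow_filt[sl], gamma_env[sl])
    return {"beta_gamma_corr": corr, "gamma_slow_phase": phase,
            "gamma_slow_depth": depth}


def packet_interactions(result, bands=None) -> dict:
    """Gamma/beta packet alternation in a combined FSI-SPN simulation.

    The gamma rhythm lives in the FSI-generated currents and the beta
    rhythm in the SPN-internal inhibition, so the gamma envelope is taken
    from the FSI-population surrogate LFP and the beta envelope from the
    SPN-sourced currents onto SPNs.  Returns the envelope correlation and
    the coupling of the gamma envelope to the FSI-LFP delta/theta phase.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    fs = result.settings.sampling_rate
    _, lfp_f = surrogate_lfp(result, "fsi")
    _, lfp_s = surrogate_lfp(result, "spn", source="spn")
    slow_filt, _ = wavelet_band_trace(lfp_f, fs, bands["delta_theta"])
    _, gamma_env = wavelet_band_trace(lfp_f, fs, bands["gamma_wide"])
    _, beta_env = wavelet_band_trace(lfp_s, fs, bands["beta"])
    n = len(beta_env)
    edge = min(int(fs / bands["delta_theta"].f_lo), max((n - int(fs)) // 2, 0))
    sl = slice(edge, n - edge)
    corr = float(np.corrcoef(beta_env[sl], gamma_env[sl])[0, 1])
    phase, depth = phase_modulation(slow_filt[sl], gamma_env[sl])
    return {"beta_gamma_corr": corr, "gamma_slow_phase": phase,
            "gamma_slow_depth": depth}
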