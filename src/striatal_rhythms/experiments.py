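"""Scripted, seeded experiment recipes for the main network conditions.

Each experiment is a pure function of (configuration, seed list): the
FSI-only and SPN-only networks and the combined microcircuit are run under
baseline or high dopaminergic tone, analysed (surrogate-LFP and
mean-voltage spectra, burst statistics, envelope interactions) and
summarised as tidy records.  Heterogeneity and assembly-pulse protocols
reproduce the corresponding robustness and motor-program experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import analysis
from .engine import IntegrationSettings, NoiseSpec, SimulationResult, simulate
from .network import NetworkSpec, dopamine_condition

__all__ = [
    "ExperimentRecipe",
    "PulseProtocol",
    "make_fixture",
    "condition_summary",
    "run_condition_experiment",
    "heterogeneity_sweep",
    "assembly_pulse_experiment",
    "pairwise_synchrony",
]

_SCALES = {
    # population sizes, duration, transient, pinned base seed
    "tiny": dict(n_fsi=5, n_d1=10, n_d2=10, t_total=500.0,
                 t_transient=100.0, seed=101),
    "small": dict(n_fsi=20, n_d1=40, n_d2=40, t_total=2000.0,
                  t_transient=500.0, seed=202),
    "full": dict(n_fsi=50, n_d1=100, n_d2=100, t_total=4000.0,
                 t_transient=1000.0, seed=303),
}


def make_fixture(scale: str = "tiny") -> dict:
    """Pinned configuration set for a given problem scale.

    ``tiny`` (5 FSI / 10+10 SPN, 0.5 s) serves unit tests, ``small``
    (20 / 40+40, 2 s) integration tests, and ``full`` (50 / 100+100,
    4 s) the full-scale experiments.  Two calls with the same scale return
    identical configurations.
    """
    if scale not in _SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(_SCALES)}")
    c = _SCALES[scale]
    return {
        "spec": NetworkSpec(n_fsi=c["n_fsi"], n_d1=c["n_d1"], n_d2=c["n_d2"]),
        "settings": IntegrationSettings(t_total=c["t_total"],
                                        t_transient=c["t_transient"],
                                        seed=c["seed"]),
        "noise": NoiseSpec(),
    }


@dataclass
class ExperimentRecipe:
    """A named, fully-resolved experiment plan."""

    name: str
    populations: str = "combined"      # fsi_only | spn_only | combined
    condition: str = "baseline"
    scale: str = "full"
    n_seeds: int = 5
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.populations not in ("fsi_only", "spn_only", "combined"):
            raise ValueError(f"unknown population set {self.populations!r}")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


def _population_spec(populations: str, spec: NetworkSpec) -> NetworkSpec:
    if populations == "fsi_only":
        return replace(spec, n_d1=0, n_d2=0)
    if populations == "spn_only":
        return replace(spec, n_fsi=0)
    if populations == "combined":
        return spec
    raise ValueError(f"unknown population set {populations!r}")


def condition_summary(result: SimulationResult) -> dict:
    """Band peaks, rates, and power ratios of one simulation.

    For FSI populations the surrogate LFP (summed GABA_A currents onto
    FSIs) supplies the gamma and delta/theta peaks; the ratio of the
    delta/theta peak power to the band median measures whether a
    low-frequency peak is present at all.  Per-cell FSI voltage spectra
    (variance-normalised before averaging) give the corresponding
    single-cell ratio.  SPN subpopulations are summarised by the beta peak
    of their mean voltage.
    """
    fs = result.settings.sampling_rate
    mask = result.analysis_mask
    out: dict = {"fsi_rate": result.firing_rate("fsi") if result.spec.n_fsi else np.nan}

    if result.spec.n_fsi:
        _, lfp = analysis.surrogate_lfp(result, "fsi")
        psd = analysis.multitaper_psd(lfp, fs)
        out["gamma_peak_lfp"] = psd.peak("gamma_wide").frequency
        dt_peak = psd.peak("delta_theta")
        out["delta_theta_peak_lfp"] = dt_peak.frequency
        out["delta_theta_ratio_lfp"] = dt_peak.peak_power / dt_peak.band_median
        # average variance-normalised per-cell voltage PSD
        cell_psds = []
        for i in range(result.spec.n_fsi):
            v = result.fsi_v_soma[i, mask]
            if v.std() == 0:
                continue
            s = analysis.multitaper_psd(v / v.std(), fs)
            cell_psds.append((s.frequencies, s.psd))
        if cell_psds:
            freqs = cell_psds[0][0]
            mean_psd = np.mean([p for _, p in cell_psds], axis=0)
            sel = (freqs >= 1.0) & (freqs <= 10.0)
            out["delta_theta_ratio_cells"] = float(
                mean_psd[sel].max() / np.median(mean_psd[sel]))

    for pop in ("d1", "d2"):
        n = result.spec.n_d1 if pop == "d1" else result.spec.n_d2
        if not n:
            continue
        v = result.mean_voltage(pop)[mask]
        psd = analysis.multitaper_psd(v, fs)
        out[f"beta_peak_{pop}"] = psd.peak("beta").frequency
        out[f"{pop}_rate"] = result.firing_rate(pop)
    return out


def run_condition_experiment(populations: str, condition: str,
                             scale: str = "full", seeds=(1, 2, 3, 4, 5),
                             overrides: dict | None = None,
                             return_results: bool = False,
                             summary_fn=condition_summary) -> dict:
    """Run one population set under one dopamine condition across seeds.

    Returns {'per_seed': DataFrame, 'median': dict}; with
    ``return_results`` the raw `SimulationResult` objects are kept under
    'results' for downstream envelope or raster analyses.
    """
    fx = make_fixture(scale)
    spec = _population_spec(populations, fx["spec"])
    records, results = [], []
    for seed in seeds:
        settings = replace(fx["settings"], seed=int(seed))
        result = simulate(spec, condition, settings, fx["noise"],
                          overrides=overrides)
        row = {"seed": int(seed)}
        row.update(summary_fn(result))
        records.append(row)
        if return_results:
            results.append(result)
    per_seed = pd.DataFrame.from_records(records)
    median = per_seed.drop(columns="seed").median(numeric_only=True).to_dict()
    out = {"per_seed": per_seed, "median": median,
           "populations": populations, "condition": condition}
    if return_results:
        out["results"] = results
    return out


def heterogeneity_sweep(parameter: str, h_grid, condition: str,
                        scale: str = "small", seeds=(1, 2, 3)) -> pd.DataFrame:
    """Band summaries of the FSI network as parameter spread h grows.

    ``parameter`` is one of {'g_L', 'g_D', 'I_app'}; per-cell values are
    drawn uniformly from [default (1-h), default (1+h)], so h = 0 is the
    homogeneous network and h = 1 spans zero to twice the default.  The
    summary observable is the FSI network mean voltage.
    """
    if parameter not in ("g_L", "g_D", "I_app"):
        raise ValueError("parameter must be one of g_L, g_D, I_app")
    fx = make_fixture(scale)
    spec = _population_spec("fsi_only", fx["spec"])
    records = []
    for h in h_grid:
        if not 0.0 <= h <= 1.0:
            raise ValueError("heterogeneity spread must lie in [0, 1]")
        for seed in seeds:
            settings = replace(fx["settings"], seed=int(seed))
            result = simulate(spec, condition, settings, fx["noise"],
                              heterogeneity={parameter: float(h)})
            fs = result.settings.sampling_rate
            v = result.mean_voltage("fsi")[result.analysis_mask]
            psd = analysis.multitaper_psd(v, fs)
            records.append({
                "parameter": parameter, "h": float(h), "seed": int(seed),
                "gamma_peak": psd.peak("gamma_wide").frequency,
                "gamma_power": psd.peak("gamma_wide").band_power,
                "delta_theta_peak": psd.peak("delta_theta").frequency,
                "delta_theta_power": psd.peak("delta_theta").band_power,
                "fsi_rate": result.firing_rate("fsi"),
            })
    return pd.DataFrame.from_records(records)


@dataclass
class PulseProtocol:
    """Timed excitatory current pulses to SPN assemblies.

    ``targets`` are (lo, hi) index ranges into the D1 population, paired
    with ``onsets`` in ms.  The default reproduces the two-assembly
    protocol: a 20 ms pulse to cells 50-100 at 1680 ms, then to cells
    25-75 at 2080 ms.
    """

    targets: tuple = ((50, 100), (25, 75))
    onsets: tuple = (1680.0, 2080.0)
    duration: float = 20.0      # ms
    amplitude: float = 5.0      # uA/cm^2

    def pulses(self, n_d1: int) -> list:
        out = []
        for (lo, hi), t_on in zip(self.targets, self.onsets):
            if not 0 <= lo <= hi <= n_d1:
                raise ValueError("pulse target range outside the D1 population")
            out.append((t_on, self.duration, self.amplitude, lo, hi))
        return out


def pairwise_synchrony(spike_trains, t_lo: float, t_hi: float,
                       window: float = 5.0) -> float:
    """Mean normalised pairwise spike coincidence within [t_lo, t_hi).

    For each cell pair the number of spike pairs closer than ``window`` ms
    is normalised by the geometric mean spike count; pairs in which either
    cell is silent contribute zero.  Returns nan if fewer than two cells
    spike.
    """
    trains = [np.asarray(s)[(np.asarray(s) >= t_lo) & (np.asarray(s) < t_hi)]
              for s in spike_trains]
    n = len(trains)
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = trains[i], trains[j]
            if a.size == 0 or b.size == 0:
                vals.append(0.0)
                continue
            coincidences = np.sum(np.abs(a[:, None] - b[None, :]) < window)
            vals.append(coincidences / np.sqrt(a.size * b.size))
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def assembly_pulse_experiment(protocol: PulseProtocol | None = None,
                              with_fsi: bool = True, scale: str = "full",
                              seed: int = 0,
                              post_window: float = 200.0) -> dict:
    """Assembly switching under pulsed input, with or without FSI input.

    Runs the high-dopamine D1 subnetwork (plus the FSI network when
    ``with_fsi``) with the two-assembly pulse protocol and reports, for
    each assembly, the pairwise spike synchrony in the ``post_window`` ms
    after each pulse.  With FSIs the delta/theta-periodic inhibition
    terminates assembly-1 activity before the second pulse; without them
    its beta-rhythmic firing persists.
    """
    protocol = protocol or PulseProtocol()
    fx = make_fixture(scale)
    spec = replace(fx["spec"], n_d2=0)
    if not with_fsi:
        spec = replace(spec, n_fsi=0)
    settings = replace(fx["settings"], seed=int(seed))
    if settings.t_total < max(protocol.onsets) + 2 * post_window:
        settings = replace(settings,
                           t_total=max(protocol.onsets) + 2 * post_window)
    result = simulate(spec, "high", settings, fx["noise"],
                      pulses=protocol.pulses(spec.n_d1))
    d1 = result.spikes("d1")
    assemblies = [list(range(lo, hi)) for lo, hi in protocol.targets]
    out = {"with_fsi": with_fsi, "result": result}
    for k, (cells, t_on) in enumerate(zip(assemblies, protocol.onsets), 1):
        trains = [d1[c] for c in cells]
        out[f"assembly{k}_post_sync"] = pairwise_synchrony(
            trains, t_on, t_on + post_window)
    # persistence of assembly 1 after the *second* pulse
    t2 = protocol.onsets[1]
    out["assembly1_persistence"] = pairwise_synchrony(
        [d1[c] for c in assemblies[0]], t2, t2 + post_window)
    out["assembly1_rate_after_pulse2"] = float(np.mean(
        [np.count_nonzero((s >= t2) & (s < t2 + post_window))
         for s in (d1[c] for c in assemblies[0])]) / (post_window / 1000.0))
    return out
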