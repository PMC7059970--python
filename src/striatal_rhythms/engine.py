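"""Fixed-step RK4 integration of the coupled microcircuit.

`simulate` assembles a network from a `NetworkSpec` and a `DACondition`,
draws initial conditions and noise from a seeded RNG hierarchy, and runs
the numba kernel at dt = 0.01 ms.  Everything is reproducible bit-for-bit
from (configuration, seed).

Noise model
-----------
Each FSI dendrite receives an independent homogeneous Poisson input
(default 100 events/s).  Each event injects, by default, a single-step
rectangular current pulse of configurable amplitude; a one-sided
exponential kernel is available as an option.  Each SPN receives additive
Gaussian noise of mean zero and standard deviation one, scaled by
``amplitude * dt`` per step, with a switch for
``amplitude * sqrt(dt)`` scaling.  Noise stays on during the transient;
analysis discards the first ``t_transient`` ms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.signal

from . import _kernels
from .cells import FSIParams, SPNParams, fsi_steady_gates, spn_steady_gates
from .network import (NetworkSpec, ConnectivityMatrices, SynapseParams,
                      DACondition, build_connectivity, dopamine_condition)

__all__ = [
    "IntegrationSettings",
    "NoiseSpec",
    "SimulationResult",
    "IntegrationError",
    "rk4_step",
    "poisson_drive",
    "simulate",
    "sweep",
]

#: Default Poisson event amplitude (uA/cm^2) for the single-step
#: rectangular kernel.  Calibrated once so that a single low-dopamine FSI
#: (I_app = 7 uA/cm^2) receiving 500 events/s bursts at a theta-range
#: interburst frequency; see docs/methods.md.
DEFAULT_POISSON_AMPLITUDE = 240.0


@dataclass
class IntegrationSettings:
    """Integrator configuration (times in ms)."""

    dt: float = 0.01
    t_total: float = 4000.0
    t_transient: float = 1000.0   # flagged for analysis, still recorded
    record_stride: int = 20       # output decimation of the dt grid
    seed: int = 0                 # master seed

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.t_transient < self.t_total:
            raise ValueError("t_transient must be smaller than t_total")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))

    @property
    def sampling_rate(self) -> float:
        """Output sampling rate in Hz."""
        return 1000.0 / (self.dt * self.record_stride)


@dataclass
class NoiseSpec:
    """Stochastic drive configuration."""

    fsi_poisson_rate: float = 100.0          # events/s per FSI
    fsi_poisson_amplitude: float = DEFAULT_POISSON_AMPLITUDE  # uA/cm^2
    fsi_poisson_kernel: str = "rect"         # "rect" | "exp"
    fsi_poisson_tau: float = 1.0             # ms, exp-kernel decay
    spn_gauss_mean: float = 0.0
    spn_gauss_sd: float = 1.0
    spn_gauss_amplitude: float = 4.0         # scaled by dt (literal form)
    spn_gauss_sqrt_dt: bool = False          # sqrt(dt) scaling instead

    def __post_init__(self) -> None:
        if self.fsi_poisson_rate < 0:
            raise ValueError("Poisson rate must be >= 0")
        if self.spn_gauss_sd < 0:
            raise ValueError("Gaussian sd must be >= 0")
        if self.fsi_poisson_kernel not in ("rect", "exp"):
            raise ValueError("kernel must be 'rect' or 'exp'")

    @classmethod
    def off(cls) -> "NoiseSpec":
        return cls(fsi_poisson_rate=0.0, spn_gauss_amplitude=0.0)


class IntegrationError(RuntimeError):
    """Raised when the integration blows up or a gate leaves [0, 1]."""


@dataclass
class SimulationResult:
    """Recorded trajectory of one network simulation.

    Trace arrays are (n_cells, n_samples) on the decimated time grid; SPN
    rows are ordered D1 first, then D2.  Spike times (ms) are detected
    online at full integrator resolution.
    """

    time: np.ndarray
    fsi_v_soma: np.ndarray
    fsi_v_dend: np.ndarray
    spn_v: np.ndarray
    fsi_syn_current: np.ndarray
    spn_syn_fsi_source: np.ndarray   # FSI-sourced GABA currents onto SPNs
    spn_syn_spn_source: np.ndarray   # SPN-sourced GABA currents onto SPNs
    fsi_spikes: list
    spn_spikes: list
    spec: NetworkSpec
    condition: DACondition
    settings: IntegrationSettings
    noise: NoiseSpec
    synapse: SynapseParams
    fsi_params: FSIParams
    spn_params: SPNParams
    connectivity: ConnectivityMatrices
    meta: dict = field(default_factory=dict)

    @property
    def spn_syn_current(self) -> np.ndarray:
        """Total GABA_A current onto each SPN (both presynaptic sources)."""
        return self.spn_syn_fsi_source + self.spn_syn_spn_source

    @property
    def n_d1(self) -> int:
        return self.spec.n_d1

    @property
    def d1_slice(self) -> slice:
        return slice(0, self.spec.n_d1)

    @property
    def d2_slice(self) -> slice:
        return slice(self.spec.n_d1, self.spec.n_spn)

    @property
    def analysis_mask(self) -> np.ndarray:
        """Samples after the transient window."""
        return self.time >= self.settings.t_transient

    def mean_voltage(self, population: str) -> np.ndarray:
        """Population mean voltage trace ('fsi', 'fsi_dend', 'd1', 'd2', 'spn')."""
        if population == "fsi":
            return self.fsi_v_soma.mean(axis=0)
        if population == "fsi_dend":
            return self.fsi_v_dend.mean(axis=0)
        if population == "d1":
            return self.spn_v[self.d1_slice].mean(axis=0)
        if population == "d2":
            return self.spn_v[self.d2_slice].mean(axis=0)
        if population == "spn":
            return self.spn_v.mean(axis=0)
        raise ValueError(f"unknown population {population!r}")

    def spikes(self, population: str) -> list:
        if population == "fsi":
            return self.fsi_spikes
        if population == "d1":
            return self.spn_spikes[self.d1_slice]
        if population == "d2":
            return self.spn_spikes[self.d2_slice]
        if population == "spn":
            return self.spn_spikes
        raise ValueError(f"unknown population {population!r}")

    def firing_rate(self, population: str, after_transient: bool = True) -> float:
        """Mean per-cell firing rate in Hz."""
        spikes = self.spikes(population)
        if not len(spikes):
            return 0.0
        t0 = self.settings.t_transient if after_transient else 0.0
        window = (self.settings.t_total - t0) / 1000.0
        counts = [np.count_nonzero(s >= t0) for s in spikes]
        return float(np.mean(counts) / window)


def rk4_step(y, f, dt):
    """One classical RK4 update of ``y`` under ``dy/dt = f(y)``."""
    y = np.asarray(y, dtype=float)
    k1 = np.asarray(f(y))
    k2 = np.asarray(f(y + 0.5 * dt * k1))
    k3 = np.asarray(f(y + 0.5 * dt * k2))
    k4 = np.asarray(f(y + dt * k3))
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def poisson_drive(rate: float, amplitude: float, kernel: str, dt: float,
                  duration: float, rng) -> np.ndarray:
    """Per-step current trace of a Poisson event drive.

    ``rate`` is in events/s, ``dt`` and ``duration`` in ms.  The "rect"
    kernel injects ``amplitude`` for the single step containing each event;
    the "exp" kernel convolves events with a one-sided exponential of 1 ms
    decay (peak ``amplitude``).
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    n = int(round(duration / dt))
    counts = rng.poisson(rate * dt * 1e-3, size=n).astype(float)
    if kernel == "rect":
        return amplitude * counts
    if kernel == "exp":
        decay = np.exp(-dt / 1.0)
        return scipy.signal.lfilter([amplitude], [1.0, -decay], counts)
    raise ValueError(f"unknown kernel {kernel!r}")


def _derive_seeds(master: int) -> dict:
    """Independent child seeds for connectivity, ICs, noise, heterogeneity."""
    ss = np.random.SeedSequence(master)
    conn, init, noise, het = ss.spawn(4)
    return {
        "connectivity": int(conn.generate_state(1)[0] % (2 ** 31 - 1)),
        "init": int(init.generate_state(1)[0] % (2 ** 31 - 1)),
        "noise": int(noise.generate_state(1)[0] % (2 ** 31 - 1)),
        "heterogeneity": int(het.generate_state(1)[0] % (2 ** 31 - 1)),
    }


def _apply_overrides(objs: dict, overrides: dict) -> dict:
    """Apply {'namespace.field': value} overrides via dataclasses.replace."""
    objs = dict(objs)
    for path, value in (overrides or {}).items():
        ns, _, fname = path.partition(".")
        if ns not in objs or not fname:
            raise KeyError(f"cannot resolve override path {path!r}")
        if not any(f.name == fname for f in dataclasses.fields(objs[ns])):
            raise KeyError(f"cannot resolve override path {path!r}")
        objs[ns] = replace(objs[ns], **{fname: value})
    return objs


def simulate(spec: NetworkSpec, condition: DACondition | str,
             settings: IntegrationSettings, noise: NoiseSpec | None = None,
             *, fsi: FSIParams | None = None, spn: SPNParams | None = None,
             synapse: SynapseParams | None = None,
             connectivity: ConnectivityMatrices | None = None,
             heterogeneity: dict | None = None,
             pulses=(), overrides: dict | None = None,
             spike_threshold: float = 0.0,
             refractory: float = 2.0) -> SimulationResult:
    """Run one network simulation and return the recorded trajectory.

    ``heterogeneity`` maps FSI parameter names in {'g_L', 'g_D', 'g_Na',
    'g_K', 'I_app'} to a spread h in [0, 1]; per-cell values are drawn
    uniformly from [default (1 - h), default (1 + h)].  ``pulses`` is a
    sequence of (t_on_ms, duration_ms, amplitude, lo, hi) extra current
    steps applied to SPN indices [lo, hi).  ``overrides`` remaps individual
    fields by dotted path, e.g. {'synapse.tau_i': 8.0}.
    """
    if isinstance(condition, str):
        condition = dopamine_condition(condition)
    noise = noise if noise is not None else NoiseSpec()
    fsi = fsi if fsi is not None else FSIParams()
    spn = spn if spn is not None else SPNParams()
    if synapse is None:
        synapse = SynapseParams.for_condition(condition, spec.n_d1, spec.n_d2)

    objs = _apply_overrides(
        {"spec": spec, "condition": condition, "settings": settings,
         "noise": noise, "fsi": fsi, "spn": spn, "synapse": synapse},
        overrides)
    spec, condition, settings = objs["spec"], objs["condition"], objs["settings"]
    noise, fsi, spn, synapse = (objs["noise"], objs["fsi"], objs["spn"],
                                objs["synapse"])

    seeds = _derive_seeds(settings.seed)
    if connectivity is None:
        conn_spec = spec if spec.seed is not None else replace(
            spec, seed=seeds["connectivity"])
        connectivity = build_connectivity(conn_spec)

    nf, nd1, nd2 = spec.n_fsi, spec.n_d1, spec.n_d2
    ns = nd1 + nd2

    W_ff = np.ascontiguousarray(connectivity.fsi_inh_adj, dtype=np.float64)
    W_fs = np.ascontiguousarray(connectivity.fsi_spn_adj, dtype=np.float64)
    W_ss = np.ascontiguousarray(connectivity.spn_spn_adj, dtype=np.float64)
    G_adj = np.ascontiguousarray(connectivity.gj_adj, dtype=np.float64)
    gj_deg = G_adj.sum(axis=1)

    # per-cell FSI conductances and drives, with optional heterogeneity
    het = dict(heterogeneity or {})
    rng_het = np.random.default_rng(seeds["heterogeneity"])

    def het_factor(name: str, n: int) -> np.ndarray:
        h = float(het.get(name, 0.0))
        if not 0.0 <= h <= 1.0:
            raise ValueError("heterogeneity spread must lie in [0, 1]")
        if h == 0.0:
            return np.ones(n)
        return rng_het.uniform(1.0 - h, 1.0 + h, size=n)

    gna_f = fsi.g_Na * het_factor("g_Na", nf)
    gk_f = fsi.g_K * het_factor("g_K", nf)
    gl_f = fsi.g_L * het_factor("g_L", nf)
    gd_f = fsi.g_D * het_factor("g_D", nf)
    I_app_f = condition.I_app_fsi * het_factor("I_app", nf)
    I_app_spn = np.concatenate([np.full(nd1, condition.I_app_d1),
                                np.full(nd2, condition.I_app_d2)])
    I_app_spn = I_app_spn + noise.spn_gauss_mean  # noise mean folds into drive

    P = np.zeros(_kernels.N_PARAMS)
    P[_kernels.CM_F] = fsi.c_m
    P[_kernels.ENA_F] = fsi.E_Na
    P[_kernels.EK_F] = fsi.E_K
    P[_kernels.EL_F] = fsi.E_L
    P[_kernels.TAU_A] = fsi.tau_a
    P[_kernels.TAU_B] = fsi.tau_b
    P[_kernels.DSCALE] = fsi.dendrite_scale
    P[_kernels.GC] = fsi.g_compartment
    P[_kernels.CM_S] = spn.c_m
    P[_kernels.GNA_S] = spn.g_Na
    P[_kernels.GK_S] = spn.g_K
    P[_kernels.GL_S] = spn.g_L
    P[_kernels.GM_S] = spn.g_M
    P[_kernels.ENA_S] = spn.E_Na
    P[_kernels.EK_S] = spn.E_K
    P[_kernels.EL_S] = spn.E_L
    P[_kernels.QS] = spn.qs
    P[_kernels.G_FF] = synapse.g_fsi_fsi
    P[_kernels.G_FS] = synapse.g_fsi_spn
    P[_kernels.G_SS] = synapse.g_spn_spn
    P[_kernels.E_I] = synapse.E_i
    P[_kernels.TAU_I] = synapse.tau_i
    P[_kernels.TAU_R] = synapse.tau_r
    P[_kernels.G_GJ] = synapse.g_gj

    # initial conditions: per-cell uniform voltage, gates at steady state
    rng_init = np.random.default_rng(seeds["init"])
    y0 = np.zeros(_kernels.state_size(nf, ns))
    v0_f = rng_init.uniform(-90.0, -50.0, size=nf)
    for i in range(nf):
        h, n, a, b = fsi_steady_gates(v0_f[i])
        y0[i] = v0_f[i]
        y0[nf + i], y0[2 * nf + i] = h, n
        y0[3 * nf + i], y0[4 * nf + i] = a, b
        y0[5 * nf + i] = v0_f[i]
        y0[6 * nf + i], y0[7 * nf + i] = h, n
        y0[8 * nf + i], y0[9 * nf + i] = a, b
    # SPNs start near their quiescent resting state (~ -63 mV).  The SPN
    # is bistable around baseline drive: hyperpolarised initial conditions
    # deactivate the M-current and rebound onto the spiking attractor, so a
    # wide initial spread would ignite self-sustained firing that the
    # quiescent baseline network must not show.  The 0.8 mV jitter stays
    # inside the quiescent basin while desynchronising the population.
    o = 10 * nf
    v0_s = rng_init.uniform(-63.5, -62.7, size=ns)
    qs = spn.qs
    for j in range(ns):
        m, h, n, w = spn_steady_gates(v0_s[j], qs)
        y0[o + j] = v0_s[j]
        y0[o + ns + j], y0[o + 2 * ns + j] = m, h
        y0[o + 3 * ns + j], y0[o + 4 * ns + j] = n, w
    # GABA gates start closed

    pulses = list(pulses)
    pulse_t0 = np.array([p[0] for p in pulses], dtype=np.float64)
    pulse_t1 = np.array([p[0] + p[1] for p in pulses], dtype=np.float64)
    pulse_amp = np.array([p[2] for p in pulses], dtype=np.float64)
    pulse_lo = np.array([p[3] for p in pulses], dtype=np.int64)
    pulse_hi = np.array([p[4] for p in pulses], dtype=np.int64)
    for p in pulses:
        if not (0 <= p[3] <= p[4] <= ns):
            raise ValueError("pulse target range outside SPN population")
        if not 0.0 <= p[0] <= settings.t_total:
            raise ValueError("pulse onset outside the simulation window")

    n_steps = settings.n_steps
    max_spikes = int(settings.t_total / 2.5) + 16
    noise_decay = float(np.exp(-settings.dt / noise.fsi_poisson_tau))
    kernel_flag = 0 if noise.fsi_poisson_kernel == "rect" else 1
    is_gate = _kernels.gate_mask(nf, ns)

    out = _kernels.run_network(
        y0, nf, nd1, nd2, W_ff, W_fs, W_ss, G_adj, gj_deg,
        gna_f, gk_f, gl_f, gd_f, P, I_app_f, I_app_spn,
        settings.dt, n_steps, settings.record_stride,
        noise.fsi_poisson_rate, noise.fsi_poisson_amplitude,
        kernel_flag, noise_decay,
        noise.spn_gauss_amplitude * noise.spn_gauss_sd,
        noise.spn_gauss_sqrt_dt,
        pulse_t0, pulse_t1, pulse_amp, pulse_lo, pulse_hi,
        spike_threshold, refractory, max_spikes,
        is_gate, seeds["noise"])
    (status, bad_index, bad_step, rec_t, rec_vs, rec_vd, rec_vspn,
     rec_isyn_f, rec_isyn_s_fsi, rec_isyn_s_spn,
     spk_t_f, spk_n_f, spk_t_s, spk_n_s, _y) = out

    if status == _kernels.STATUS_NONFINITE:
        raise IntegrationError(
            f"non-finite state component {bad_index} at step {bad_step} "
            f"(t = {bad_step * settings.dt:.2f} ms)")
    if status == _kernels.STATUS_GATE_OVERSHOOT:
        raise IntegrationError(
            f"gating variable (state component {bad_index}) left [0, 1] "
            f"by more than {_kernels.GATE_CLAMP_TOL} at step {bad_step}; "
            "reduce dt")
    if status == _kernels.STATUS_SPIKE_OVERFLOW:
        raise IntegrationError("per-cell spike buffer overflow")

    fsi_spikes = [spk_t_f[i, :spk_n_f[i]].copy() for i in range(nf)]
    spn_spikes = [spk_t_s[j, :spk_n_s[j]].copy() for j in range(ns)]

    return SimulationResult(
        time=rec_t, fsi_v_soma=rec_vs, fsi_v_dend=rec_vd, spn_v=rec_vspn,
        fsi_syn_current=rec_isyn_f, spn_syn_fsi_source=rec_isyn_s_fsi,
        spn_syn_spn_source=rec_isyn_s_spn,
        fsi_spikes=fsi_spikes, spn_spikes=spn_spikes,
        spec=spec, condition=condition, settings=settings, noise=noise,
        synapse=synapse, fsi_params=fsi, spn_params=spn,
        connectivity=connectivity,
        meta={"seeds": seeds, "heterogeneity": het})


def _default_summary(result: SimulationResult) -> dict:
    summary = {"fsi_rate": result.firing_rate("fsi")}
    if result.spec.n_spn:
        summary["d1_rate"] = result.firing_rate("d1")
        summary["d2_rate"] = result.firing_rate("d2")
    return summary


def sweep(base: dict, path: str, values, n_repeats: int = 1,
          seeds=None, summary_fn=None) -> pd.DataFrame:
    """Run `simulate` over a parameter grid and tabulate summaries.

    ``base`` holds keyword arguments for `simulate` (at least ``spec``,
    ``condition`` and ``settings``); ``path`` is a dotted override path
    such as ``'fsi.g_D'`` or ``'noise.fsi_poisson_rate'``.  Each value is
    run ``n_repeats`` times with seeds taken from ``seeds`` (default
    0..n_repeats-1), and ``summary_fn(result)`` rows are collected into a
    tidy long-format frame.  Identical (value, seed) pairs reproduce
    identical summaries.
    """
    summary_fn = summary_fn or _default_summary
    if seeds is None:
        seeds = list(range(n_repeats))
    if len(seeds) != n_repeats:
        raise ValueError("seeds must match n_repeats")
    records = []
    for value in values:
        for rep, seed in zip(range(n_repeats), seeds):
            kwargs = dict(base)
            overrides = dict(kwargs.pop("overrides", None) or {})
            overrides[path] = value
            kwargs["settings"] = replace(kwargs["settings"], seed=seed)
            result = simulate(overrides=overrides, **kwargs)
            row = {"parameter": path, "value": value,
                   "repeat": rep, "seed": seed}
            row.update(summary_fn(result))
            records.append(row)
    columns = ["parameter", "value", "repeat", "seed"]
    if records:
        extra = [k for k in records[0] if k not in columns]
        return pd.DataFrame.from_records(records, columns=columns + extra)
    return pd.DataFrame(columns=columns)
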