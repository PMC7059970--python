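"""Single-cell dynamics of the striatal microcircuit model.

Two cell types are implemented as Hodgkin-Huxley-type conductance models:

* the striatal fast-spiking interneuron (FSI), a two-compartment
  (soma + dendrite) cell with fast Na, fast K (n^2), leak, and a
  fast-activating/slowly-inactivating D-type potassium current whose slow
  inactivation (tau_b = 150 ms) produces stuttering/bursting and a minimum
  firing rate in the gamma range;

* the striatal spiny projection neuron (SPN), a single-compartment cell
  with fast Na, fast K (n^4), leak, and a slow non-inactivating M-type
  potassium current whose ~50 ms rebound timescale underlies beta
  rhythmicity.  M-current kinetics, originally characterised at 23 degC,
  are scaled to body temperature by a Q10 factor.

All voltages are in mV, currents in uA/cm^2, conductances in mS/cm^2,
capacitances in mF/cm^2 (so dV/dt comes out in mV/ms), and time constants
in ms.  The gating-rate functions are written once as numba-compiled
scalar kernels; the network integration engine and the pure-Python
conveniences below share them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "FSIParams",
    "SPNParams",
    "FSICellState",
    "SPNCellState",
    "qs_factor",
    "fsi_gating_rates",
    "spn_gating_rates",
    "fsi_rhs",
    "spn_rhs",
    "compartment_currents",
    "fsi_steady_gates",
    "spn_steady_gates",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class FSIParams:
    """Parameters of the two-compartment fast-spiking interneuron.

    Dendritic conductances are ``dendrite_scale`` times the somatic values;
    the two compartments are coupled bidirectionally with conductance
    ``g_compartment``.
    """

    c_m: float = 1.0          # mF/cm^2
    g_Na: float = 112.5       # mS/cm^2
    g_K: float = 225.0
    g_L: float = 0.25
    g_D: float = 6.0
    E_Na: float = 50.0        # mV
    E_K: float = -90.0
    E_L: float = -70.0
    tau_a: float = 2.0        # ms, D-current activation
    tau_b: float = 150.0      # ms, D-current inactivation
    dendrite_scale: float = 0.1
    g_compartment: float = 0.5  # mS/cm^2, soma<->dendrite coupling

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K", "g_L", "g_D", "g_compartment", "c_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.dendrite_scale <= 1.0:
            raise ValueError("dendrite_scale must lie in (0, 1]")
        if self.tau_a <= 0 or self.tau_b <= 0:
            raise ValueError("tau_a and tau_b must be positive")


@dataclass
class SPNParams:
    """Parameters of the single-compartment spiny projection neuron."""

    c_m: float = 1.0
    g_Na: float = 100.0
    g_K: float = 80.0
    g_L: float = 0.1
    g_M: float = 1.25
    E_Na: float = 50.0
    E_K: float = -100.0
    E_L: float = -67.0
    Q10: float = 2.3
    T_body: float = 37.0      # degC
    T_ref: float = 23.0       # degC

    def __post_init__(self) -> None:
        for name in ("g_Na", "g_K", "g_L", "g_M", "c_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Q10 <= 0:
            raise ValueError("Q10 must be positive")

    @property
    def qs(self) -> float:
        """Temperature scaling factor applied to the M-current rates."""
        return qs_factor(self.Q10, self.T_body, self.T_ref)


def qs_factor(q10: float, t_body: float, t_ref: float) -> float:
    """Q10 temperature scaling, ``q10 ** ((t_body - t_ref) / 10)``.

    With the default Q10 = 2.3 and a 23 -> 37 degC correction this equals
    2.3 ** 1.4 = 3.209.
    """
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    return float(q10) ** ((float(t_body) - float(t_ref)) / 10.0)


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------

@dataclass
class FSICellState:
    """State of one FSI: compartment voltages plus gating variables.

    Na activation is instantaneous (m = m_inf(V)) and therefore not a state
    variable; each compartment carries h (Na inactivation), n (K
    activation), and a, b (D-current activation/inactivation).
    """

    V_soma: float
    V_dend: float
    h_soma: float
    n_soma: float
    a_soma: float
    b_soma: float
    h_dend: float
    n_dend: float
    a_dend: float
    b_dend: float

    def gates(self) -> np.ndarray:
        return np.array([self.h_soma, self.n_soma, self.a_soma, self.b_soma,
                         self.h_dend, self.n_dend, self.a_dend, self.b_dend])


@dataclass
class SPNCellState:
    """State of one SPN: voltage plus m, h (Na), n (K), w (M-current)."""

    V: float
    m: float
    h: float
    n: float
    w: float

    def gates(self) -> np.ndarray:
        return np.array([self.m, self.h, self.n, self.w])


# --------------------------------------------------------------------------
# FSI gating kernels (steady states / time constants)
# --------------------------------------------------------------------------

@njit(cache=True)
def fsi_m_inf(v):
    return 1.0 / (1.0 + np.exp(-(v + 24.0) / 11.5))


@njit(cache=True)
def fsi_h_inf(v):
    return 1.0 / (1.0 + np.exp((v + 58.3) / 6.7))


@njit(cache=True)
def fsi_tau_h(v):
    return 0.5 + 14.0 / (1.0 + np.exp((v + 60.0) / 12.0))


@njit(cache=True)
def fsi_n_inf(v):
    return 1.0 / (1.0 + np.exp(-(v + 12.4) / 6.8))


@njit(cache=True)
def fsi_tau_n(v):
    return (0.087 + 11.4 / (1.0 + np.exp((v + 14.6) / 8.6))) * (
        0.087 + 11.4 / (1.0 + np.exp(-(v - 1.3) / 18.7)))


@njit(cache=True)
def fsi_a_inf(v):
    return 1.0 / (1.0 + np.exp(-(v + 50.0) / 20.0))


@njit(cache=True)
def fsi_b_inf(v):
    return 1.0 / (1.0 + np.exp((v + 70.0) / 6.0))


def fsi_gating_rates(v: float) -> dict:
    """Steady states and time constants of the FSI gates at voltage ``v``.

    Returns m_inf, h_inf, tau_h, n_inf, tau_n, a_inf, b_inf.  Na activation
    is treated as instantaneous, so no tau_m is defined; the D-current
    gates relax with the fixed constants tau_a and tau_b.
    """
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    return {
        "m_inf": float(fsi_m_inf(v)),
        "h_inf": float(fsi_h_inf(v)),
        "tau_h": float(fsi_tau_h(v)),
        "n_inf": float(fsi_n_inf(v)),
        "tau_n": float(fsi_tau_n(v)),
        "a_inf": float(fsi_a_inf(v)),
        "b_inf": float(fsi_b_inf(v)),
    }


# --------------------------------------------------------------------------
# SPN rate kernels (alpha/beta form, removable singularities guarded)
# --------------------------------------------------------------------------

@njit(cache=True)
def _lin_sig(x, s):
    """x / (1 - exp(-x/s)), with its analytic limit s at x = 0."""
    if abs(x) < 1e-6:
        return s
    return x / (1.0 - np.exp(-x / s))


@njit(cache=True)
def spn_alpha_m(v):
    return 0.32 * _lin_sig(v + 54.0, 4.0)


@njit(cache=True)
def spn_beta_m(v):
    return 0.28 * _lin_sig(-(v + 27.0), 5.0)


@njit(cache=True)
def spn_alpha_h(v):
    return 0.128 * np.exp(-(v + 50.0) / 18.0)


@njit(cache=True)
def spn_beta_h(v):
    return 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))


@njit(cache=True)
def spn_alpha_n(v):
    return 0.032 * _lin_sig(v + 52.0, 5.0)


@njit(cache=True)
def spn_beta_n(v):
    return 0.5 * np.exp(-(v + 57.0) / 40.0)


@njit(cache=True)
def spn_alpha_w(v, qs):
    return qs * 1e-4 * _lin_sig(v + 30.0, 9.0)


@njit(cache=True)
def spn_beta_w(v, qs):
    return qs * 1e-4 * _lin_sig(-(v + 30.0), 9.0)


def spn_gating_rates(v: float, qs: float = 3.209) -> dict:
    """Opening/closing rates of all SPN gates at voltage ``v``.

    The M-current rates are multiplied by the temperature factor ``qs``;
    with qs = 1 they reduce to the 23 degC kinetics.  Removable
    singularities (V = -54, -52, -27, -30) are evaluated by their analytic
    limits.
    """
    if not math.isfinite(v):
        raise ValueError("voltage must be finite")
    if qs <= 0:
        raise ValueError("qs must be positive")
    return {
        "alpha_m": float(spn_alpha_m(v)),
        "beta_m": float(spn_beta_m(v)),
        "alpha_h": float(spn_alpha_h(v)),
        "beta_h": float(spn_beta_h(v)),
        "alpha_n": float(spn_alpha_n(v)),
        "beta_n": float(spn_beta_n(v)),
        "alpha_w": float(spn_alpha_w(v, qs)),
        "beta_w": float(spn_beta_w(v, qs)),
    }


# --------------------------------------------------------------------------
# steady-state gate initialisation
# --------------------------------------------------------------------------

def fsi_steady_gates(v: float) -> tuple[float, float, float, float]:
    """(h, n, a, b) at their voltage-clamped steady state."""
    return (float(fsi_h_inf(v)), float(fsi_n_inf(v)),
            float(fsi_a_inf(v)), float(fsi_b_inf(v)))


def spn_steady_gates(v: float, qs: float) -> tuple[float, float, float, float]:
    """(m, h, n, w) at their voltage-clamped steady state."""
    am, bm = spn_alpha_m(v), spn_beta_m(v)
    ah, bh = spn_alpha_h(v), spn_beta_h(v)
    an, bn = spn_alpha_n(v), spn_beta_n(v)
    aw, bw = spn_alpha_w(v, qs), spn_beta_w(v, qs)
    return (am / (am + bm), ah / (ah + bh), an / (an + bn), aw / (aw + bw))


# --------------------------------------------------------------------------
# right-hand sides (single-cell convenience layer)
# --------------------------------------------------------------------------

def compartment_currents(state: FSICellState, params: FSIParams) -> tuple[float, float]:
    """(I_ds, I_sd): dendrite->soma and soma->dendrite coupling currents.

    The two are equal and opposite by construction.
    """
    i_ds = params.g_compartment * (state.V_dend - state.V_soma)
    return i_ds, -i_ds


def _fsi_membrane_current(v, h, n, a, b, scale, p: FSIParams) -> float:
    """Total outward intrinsic current of one FSI compartment."""
    m = fsi_m_inf(v)
    i_na = scale * p.g_Na * m ** 3 * h * (v - p.E_Na)
    i_k = scale * p.g_K * n ** 2 * (v - p.E_K)
    i_d = scale * p.g_D * a ** 3 * b * (v - p.E_K)
    i_l = scale * p.g_L * (v - p.E_L)
    return i_na + i_k + i_d + i_l


def fsi_rhs(state: FSICellState, params: FSIParams,
            I_syn_soma: float = 0.0, I_syn_dend: float = 0.0,
            I_ext: float = 0.0) -> FSICellState:
    """Time derivative of a single FSI.

    ``I_syn_soma`` is the outward GABA_A current on the soma (somato-somatic
    synapses), ``I_syn_dend`` an outward current on the dendrite (e.g. the
    negated gap-junction input), and ``I_ext`` the external drive, which
    enters the dendritic compartment.  Dendritic conductances are
    ``dendrite_scale`` times the somatic ones.
    """
    p = params
    i_ds, i_sd = compartment_currents(state, p)
    dv_s = (-_fsi_membrane_current(state.V_soma, state.h_soma, state.n_soma,
                                   state.a_soma, state.b_soma, 1.0, p)
            - I_syn_soma + i_ds) / p.c_m
    dv_d = (-_fsi_membrane_current(state.V_dend, state.h_dend, state.n_dend,
                                   state.a_dend, state.b_dend,
                                   p.dendrite_scale, p)
            - I_syn_dend + I_ext + i_sd) / p.c_m

    def gate_derivs(v, h, n, a, b):
        dh = (fsi_h_inf(v) - h) / fsi_tau_h(v)
        dn = (fsi_n_inf(v) - n) / fsi_tau_n(v)
        da = (fsi_a_inf(v) - a) / p.tau_a
        db = (fsi_b_inf(v) - b) / p.tau_b
        return dh, dn, da, db

    dh_s, dn_s, da_s, db_s = gate_derivs(state.V_soma, state.h_soma,
                                         state.n_soma, state.a_soma,
                                         state.b_soma)
    dh_d, dn_d, da_d, db_d = gate_derivs(state.V_dend, state.h_dend,
                                         state.n_dend, state.a_dend,
                                         state.b_dend)
    return FSICellState(dv_s, dv_d, dh_s, dn_s, da_s, db_s,
                        dh_d, dn_d, da_d, db_d)


def spn_rhs(state: SPNCellState, params: SPNParams,
            I_syn: float = 0.0, I_app: float = 0.0) -> SPNCellState:
    """Time derivative of a single SPN.

    Na has three activation and one inactivation gate, K four activation
    gates, the M-current a single activation gate; ``I_syn`` is the outward
    synaptic current and ``I_app`` the applied drive.
    """
    p = params
    v = state.V
    qs = p.qs
    i_na = p.g_Na * state.m ** 3 * state.h * (v - p.E_Na)
    i_k = p.g_K * state.n ** 4 * (v - p.E_K)
    i_m = p.g_M * state.w * (v - p.E_K)
    i_l = p.g_L * (v - p.E_L)
    dv = (-(i_na + i_k + i_m + i_l) - I_syn + I_app) / p.c_m
    dm = spn_alpha_m(v) * (1.0 - state.m) - spn_beta_m(v) * state.m
    dh = spn_alpha_h(v) * (1.0 - state.h) - spn_beta_h(v) * state.h
    dn = spn_alpha_n(v) * (1.0 - state.n) - spn_beta_n(v) * state.n
    dw = spn_alpha_w(v, qs) * (1.0 - state.w) - spn_beta_w(v, qs) * state.w
    return SPNCellState(dv, dm, dh, dn, dw)
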