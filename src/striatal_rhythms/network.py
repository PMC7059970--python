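"""Populations, random connectivity, and coupling currents.

The microcircuit contains one FSI population and two SPN subpopulations
(D1- and D2-receptor expressing).  FSIs are coupled by dendro-dendritic
gap junctions and somato-somatic GABA_A synapses, project to both SPN
subpopulations, and receive no feedback.  SPNs inhibit all other SPNs of
the same subtype; there is no D1<->D2 coupling.

Dopaminergic tone is encoded as a parameter bundle (`DACondition`): high
dopamine depolarises FSIs, doubles their gap-junction conductance, weakens
FSI-FSI inhibition, and shifts D1/D2 excitability apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkSpec",
    "ConnectivityMatrices",
    "SynapseParams",
    "DACondition",
    "build_connectivity",
    "dopamine_condition",
    "gaba_gate_rhs",
    "synaptic_current",
    "gap_junction_currents",
    "connectivity_to_edge_list",
    "connectivity_from_edge_list",
]


@dataclass
class NetworkSpec:
    """Population sizes and connection probabilities of the microcircuit."""

    n_fsi: int = 50
    n_d1: int = 100
    n_d2: int = 100
    p_fsi_gj: float = 0.33      # gap junction per unordered FSI pair
    p_fsi_inh: float = 0.58     # inhibitory synapse per unordered FSI pair
    p_fsi_spn: float = 0.375    # per directed FSI->SPN edge
    p_spn_spn: float = 1.0      # within-subpopulation SPN->SPN
    seed: int | None = None     # connectivity RNG seed
    #: How the per-pair inhibitory probability is realised:
    #: 'pair_single'  - one synapse per connected pair, direction random
    #:                  (an unordered pair carries *a* synapse);
    #: 'reciprocal'   - one draw per pair creates both directions;
    #: 'directed'     - independent draw per directed edge.
    fsi_inh_mode: str = "pair_single"

    def __post_init__(self) -> None:
        for name in ("p_fsi_gj", "p_fsi_inh", "p_fsi_spn", "p_spn_spn"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fsi_inh_mode not in ("pair_single", "reciprocal", "directed"):
            raise ValueError(f"unknown fsi_inh_mode {self.fsi_inh_mode!r}")
        for name in ("n_fsi", "n_d1", "n_d2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_spn(self) -> int:
        return self.n_d1 + self.n_d2


@dataclass
class ConnectivityMatrices:
    """Realised 0/1 adjacency, indexed [pre, post].

    ``gj_adj`` is symmetric with zero diagonal; ``spn_spn_adj`` is block
    structured (no D1<->D2 entries, no autapses).  SPN indices run D1 first,
    then D2.
    """

    gj_adj: np.ndarray         # (n_fsi, n_fsi)
    fsi_inh_adj: np.ndarray    # (n_fsi, n_fsi)
    fsi_spn_adj: np.ndarray    # (n_fsi, n_spn)
    spn_spn_adj: np.ndarray    # (n_spn, n_spn)
    n_d1: int = 0

    def __post_init__(self) -> None:
        if not np.array_equal(self.gj_adj, self.gj_adj.T):
            raise ValueError("gap-junction adjacency must be symmetric")
        for a in (self.gj_adj, self.fsi_inh_adj, self.spn_spn_adj):
            if a.size and np.any(np.diag(a) != 0):
                raise ValueError("adjacency diagonals must be zero")
        nd1 = self.n_d1
        if self.spn_spn_adj.size and np.any(self.spn_spn_adj[:nd1, nd1:]):
            raise ValueError("no D1<->D2 connections allowed")


def build_connectivity(spec: NetworkSpec) -> ConnectivityMatrices:
    """Draw the random adjacency for a network specification.

    Gap junctions are drawn once per unordered FSI pair (undirected).
    FSI-FSI inhibitory synapses follow ``spec.fsi_inh_mode``: by default
    each connected pair carries a single synapse whose direction is chosen
    at random; 'reciprocal' and 'directed' realisations are available for
    sensitivity checks.  FSI->SPN edges are
    independent per (FSI, SPN) pair; SPN->SPN connectivity is all-to-all
    within each subpopulation at the default probability 1, excluding
    autapses and any D1<->D2 edge.  Identical (spec, seed) give identical
    matrices.
    """
    rng = np.random.default_rng(spec.seed)
    nf, nd1, nd2 = spec.n_fsi, spec.n_d1, spec.n_d2
    ns = nd1 + nd2

    gj = np.zeros((nf, nf), dtype=np.int8)
    inh = np.zeros((nf, nf), dtype=np.int8)
    iu = np.triu_indices(nf, k=1)
    if iu[0].size:
        gj[iu] = rng.random(iu[0].size) < spec.p_fsi_gj
        gj |= gj.T
        if spec.fsi_inh_mode == "pair_single":
            has = rng.random(iu[0].size) < spec.p_fsi_inh
            forward = rng.random(iu[0].size) < 0.5
            inh[iu[0][has & forward], iu[1][has & forward]] = 1
            inh[iu[1][has & ~forward], iu[0][has & ~forward]] = 1
        elif spec.fsi_inh_mode == "reciprocal":
            inh[iu] = rng.random(iu[0].size) < spec.p_fsi_inh
            inh |= inh.T
        else:  # independent per directed edge
            mask = rng.random((nf, nf)) < spec.p_fsi_inh
            np.fill_diagonal(mask, False)
            inh = mask.astype(np.int8)

    fsi_spn = (rng.random((nf, ns)) < spec.p_fsi_spn).astype(np.int8)

    spn_spn = np.zeros((ns, ns), dtype=np.int8)
    for lo, hi in ((0, nd1), (nd1, ns)):
        block = (rng.random((hi - lo, hi - lo)) < spec.p_spn_spn).astype(np.int8)
        spn_spn[lo:hi, lo:hi] = block
    np.fill_diagonal(spn_spn, 0)

    _flag_connection_counts(spec, gj, inh, fsi_spn)
    return ConnectivityMatrices(gj, inh, fsi_spn, spn_spn, n_d1=nd1)


def _flag_connection_counts(spec, gj, inh, fsi_spn) -> None:
    """Warn (never fail) if realised edge counts are >4 binomial SD out."""
    n_pairs = spec.n_fsi * (spec.n_fsi - 1) / 2
    if spec.fsi_inh_mode == "pair_single":
        inh_count, inh_n = inh.sum(), n_pairs
    elif spec.fsi_inh_mode == "reciprocal":
        inh_count, inh_n = np.triu(inh, 1).sum(), n_pairs
    else:
        inh_count, inh_n = inh.sum(), 2 * n_pairs
    checks = [
        ("gap junctions", np.triu(gj, 1).sum(), n_pairs, spec.p_fsi_gj),
        ("FSI inhibitory synapses", inh_count, inh_n, spec.p_fsi_inh),
        ("FSI->SPN edges", fsi_spn.sum(),
         spec.n_fsi * spec.n_spn, spec.p_fsi_spn),
    ]
    for name, count, n, p in checks:
        sd = np.sqrt(max(n * p * (1 - p), 1e-12))
        if n > 0 and abs(count - n * p) > 4 * sd:
            warnings.warn(
                f"realised {name} count {count} deviates from expectation "
                f"{n * p:.1f} by more than 4 binomial SD", stacklevel=3)


@dataclass
class SynapseParams:
    """GABA_A and gap-junction coupling parameters.

    ``g_fsi_spn`` and ``g_spn_spn`` are the per-synapse conductances after
    normalising the total budgets (0.6 and 0.1 mS/cm^2) by the number of
    SPNs in the target subpopulation, preserving the ~6:1 strength ratio of
    FSI->SPN over SPN->SPN inhibition at any population size.  The FSI-FSI
    conductance is not size-normalised.
    """

    g_fsi_fsi: float = 0.1    # mS/cm^2 (dopamine-dependent)
    g_fsi_spn: float = 0.006  # = 0.6 / n_spn_targets at n = 100
    g_spn_spn: float = 0.001  # = 0.1 / n_spn at n = 100
    tau_i: float = 13.0       # ms, GABA_A decay
    tau_r: float = 0.25       # ms, rise (FSI-sourced synapses)
    E_i: float = -80.0        # mV
    g_gj: float = 0.15        # mS/cm^2 (dopamine-dependent)

    def __post_init__(self) -> None:
        for name in ("g_fsi_fsi", "g_fsi_spn", "g_spn_spn", "g_gj"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.tau_i > self.tau_r > 0:
            raise ValueError("require tau_i > tau_r > 0")

    @classmethod
    def for_condition(cls, condition: "DACondition",
                      n_d1: int = 100, n_d2: int = 100) -> "SynapseParams":
        """Synapse bundle for a dopamine condition and SPN population size."""
        n = max(n_d1, 1)  # per-subpopulation normalisation (equal sizes)
        return cls(g_fsi_fsi=condition.g_fsi_fsi,
                   g_fsi_spn=0.6 / n, g_spn_spn=0.1 / n,
                   g_gj=condition.g_gj)


@dataclass
class DACondition:
    """Dopaminergic tone as a parameter bundle.

    ``baseline`` and ``high`` differ in exactly five fields: FSI tonic
    drive, gap-junction conductance, FSI-FSI inhibitory conductance, and
    the D1/D2 applied currents.
    """

    label: str
    I_app_fsi: float   # uA/cm^2
    g_gj: float        # mS/cm^2
    g_fsi_fsi: float   # mS/cm^2
    I_app_d1: float    # uA/cm^2
    I_app_d2: float    # uA/cm^2


_DA_TABLE = {
    "baseline": DACondition("baseline", I_app_fsi=7.0, g_gj=0.15,
                            g_fsi_fsi=0.1, I_app_d1=1.19, I_app_d2=1.19),
    "high": DACondition("high", I_app_fsi=14.0, g_gj=0.3,
                        g_fsi_fsi=0.005, I_app_d1=1.29, I_app_d2=1.09),
}


def dopamine_condition(label: str, **overrides) -> DACondition:
    """Return the parameter bundle for ``baseline`` or ``high`` dopamine.

    Individual fields may be overridden by keyword.
    """
    if label not in _DA_TABLE:
        raise ValueError(f"unknown dopamine condition {label!r}; "
                         f"choose from {sorted(_DA_TABLE)}")
    cond = _DA_TABLE[label]
    return replace(cond, **overrides) if overrides else replace(cond)


# --------------------------------------------------------------------------
# coupling currents (reference implementations; the engine kernel mirrors
# these formulas)
# --------------------------------------------------------------------------

def gaba_gate_rhs(S, V_pre, kind: str, params: SynapseParams):
    """dS/dt of a GABA_A gate driven by the presynaptic voltage.

    SPN-sourced synapses open at rate 2 (1 + tanh(V/4)); FSI-sourced
    synapses open at rate (1/tau_r)(1 + tanh(V/10)).  Both close with the
    common decay constant tau_i.
    """
    S = np.asarray(S, dtype=float)
    V_pre = np.asarray(V_pre, dtype=float)
    if kind == "spn-source":
        g_open = 2.0 * (1.0 + np.tanh(V_pre / 4.0))
    elif kind == "fsi-source":
        g_open = (1.0 + np.tanh(V_pre / 10.0)) / params.tau_r
    else:
        raise ValueError(f"unknown synapse kind {kind!r}")
    return g_open * (1.0 - S) - S / params.tau_i


def synaptic_current(S: np.ndarray, adjacency: np.ndarray, g: float,
                     V_post: np.ndarray, E_i: float) -> np.ndarray:
    """Per-postsynaptic-cell GABA_A current g * (sum_pre S) * (V_post - E_i).

    ``S`` holds one gate per presynaptic cell; ``adjacency[pre, post]``
    selects which gates reach which target.
    """
    S = np.asarray(S, dtype=float)
    V_post = np.asarray(V_post, dtype=float)
    adjacency = np.asarray(adjacency)
    if adjacency.shape != (S.shape[0], V_post.shape[0]):
        raise ValueError("adjacency shape inconsistent with S / V_post")
    return g * (S @ adjacency) * (V_post - E_i)


def gap_junction_currents(V_dend: np.ndarray, gj_adj: np.ndarray,
                          g_gj: float) -> np.ndarray:
    """Per-FSI dendritic gap-junction current sum_j g_gj (V_dj - V_di).

    Positive values depolarise cell i.  The network-wide sum is zero by
    antisymmetry.
    """
    V_dend = np.asarray(V_dend, dtype=float)
    gj_adj = np.asarray(gj_adj)
    if not np.array_equal(gj_adj, gj_adj.T):
        raise ValueError("gap-junction adjacency must be symmetric")
    deg = gj_adj.sum(axis=1)
    return g_gj * (gj_adj.astype(float) @ V_dend - deg * V_dend)


# --------------------------------------------------------------------------
# edge-list round trip (for exact re-runs)
# --------------------------------------------------------------------------

_EDGE_TYPES = ("gap_junction", "fsi_fsi_inh", "fsi_spn_inh", "spn_spn_inh")


def connectivity_to_edge_list(conn: ConnectivityMatrices,
                              syn: SynapseParams) -> list[tuple]:
    """Flatten adjacency to (pre_id, post_id, type, conductance) rows.

    Gap junctions, being undirected, are listed once per pair (pre < post).
    """
    rows = []
    pre, post = np.nonzero(np.triu(conn.gj_adj, 1))
    rows += [(int(i), int(j), "gap_junction", syn.g_gj) for i, j in zip(pre, post)]
    for adj, kind, g in ((conn.fsi_inh_adj, "fsi_fsi_inh", syn.g_fsi_fsi),
                         (conn.fsi_spn_adj, "fsi_spn_inh", syn.g_fsi_spn),
                         (conn.spn_spn_adj, "spn_spn_inh", syn.g_spn_spn)):
        pre, post = np.nonzero(adj)
        rows += [(int(i), int(j), kind, g) for i, j in zip(pre, post)]
    return rows


def save_edge_list(path, conn: ConnectivityMatrices, syn: SynapseParams) -> None:
    with open(path, "w") as fh:
        fh.write("pre_id\tpost_id\ttype\tconductance\n")
        for pre, post, kind, g in connectivity_to_edge_list(conn, syn):
            fh.write(f"{pre}\t{post}\t{kind}\t{g:.9g}\n")


def connectivity_from_edge_list(rows, n_fsi: int, n_d1: int,
                                n_d2: int) -> ConnectivityMatrices:
    """Rebuild adjacency matrices from edge-list rows."""
    ns = n_d1 + n_d2
    gj = np.zeros((n_fsi, n_fsi), dtype=np.int8)
    inh = np.zeros((n_fsi, n_fsi), dtype=np.int8)
    fsi_spn = np.zeros((n_fsi, ns), dtype=np.int8)
    spn_spn = np.zeros((ns, ns), dtype=np.int8)
    for pre, post, kind, _g in rows:
        if kind == "gap_junction":
            gj[pre, post] = gj[post, pre] = 1
        elif kind == "fsi_fsi_inh":
            inh[pre, post] = 1
        elif kind == "fsi_spn_inh":
            fsi_spn[pre, post] = 1
        elif kind == "spn_spn_inh":
            spn_spn[pre, post] = 1
        else:
            raise ValueError(f"unknown edge type {kind!r}")
    return ConnectivityMatrices(gj, inh, fsi_spn, spn_spn, n_d1=n_d1)


def load_edge_list(path, n_fsi: int, n_d1: int, n_d2: int) -> ConnectivityMatrices:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pre_id"):
            raise ValueError("missing edge-list header")
        for line in fh:
            pre, post, kind, g = line.rstrip("\n").split("\t")
            rows.append((int(pre), int(post), kind, float(g)))
    return connectivity_from_edge_list(rows, n_fsi, n_d1, n_d2)
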