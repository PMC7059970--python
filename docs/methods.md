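# Model and methods

## The circuit

The package simulates a striatal microcircuit of two cell classes under
two dopaminergic conditions.

**Fast-spiking interneurons (FSIs)** are two-compartment (soma +
dendrite) Hodgkin-Huxley cells with fast sodium (m³h, instantaneous
activation), fast potassium (n²), leak, and a fast-activating,
slowly-inactivating D-type potassium current (a³b, τ_a = 2 ms, τ_b =
150 ms, ḡ_D = 6 mS/cm²).  Slow D-current inactivation makes the cell
stutter: γ-rate spike bursts separated by δ-rate quiescent gaps, with a
minimum within-burst firing rate around 40 Hz.  Dendritic conductances
are 1/10 of somatic values; the compartments are coupled at 0.5 mS/cm².
External drive (tonic + Poisson noise) enters the dendrite; GABA_A
inhibition from other FSIs arrives at the soma (somato-somatic
synapses); gap junctions couple dendrites (dendro-dendritic).

**Spiny projection neurons (SPNs)** are single-compartment cells with
fast sodium (m³h), fast potassium (n⁴), leak, and a slow
non-inactivating M-type potassium current (one gate, ḡ_M =
1.25 mS/cm²).  M-current kinetics are scaled from their 23 °C reference
to 37 °C by Qs = Q10^1.4 = 3.209 (Q10 = 2.3).  The rebound timescale of
the M-current (~50–80 ms at subthreshold voltages) sets a β-band
resonance; networks of mutually inhibiting SPNs turn it into a
population β rhythm.

**Synapses.** GABA_A gates depend only on the presynaptic voltage, so
one gate per source cell serves all of its targets.  SPN-sourced gates
open at rate 2(1 + tanh(V/4)) and FSI-sourced gates at
(1/τ_r)(1 + tanh(V/10)) with τ_r = 0.25 ms; both decay with τ_i = 13 ms
and reverse at −80 mV.  FSI→SPN and SPN→SPN conductances are normalised
by the number of SPNs in the target subpopulation (0.6/n and 0.1/n),
preserving their ~6:1 ratio; FSI-FSI conductance is not normalised.
Gap junctions are linear ohmic couplings g_GJ (V_dj − V_di).

**Connectivity.** Within the 50-FSI population each unordered pair has
an independent 33 % chance of a gap junction and an independent 58 %
chance of an inhibitory synapse.  The inhibitory draw realises *one*
synapse per connected pair with random direction (`fsi_inh_mode=
"pair_single"`), which is the literal reading of "a somato-somatic
synapse" per pair; reciprocal-pair and independent-directed-edge
realisations are available as options.  This choice matters: with
reciprocal pairs (twice the synapse count) the baseline network γ falls
to ~46 Hz and FSI firing collapses below 1 Hz, inconsistent with the
~60 Hz γ this circuit is known to produce; the single-synapse reading
restores it.  Each FSI→SPN edge is drawn independently at 37.5 %
(expected in-degree 18.75); SPNs are connected all-to-all within their
D1/D2 subpopulation, with no autapses and no D1↔D2 coupling, and there
is no SPN→FSI feedback.

**Dopamine** is a five-field parameter bundle.  Baseline: FSI drive
7 µA/cm², g_GJ 0.15, FSI-FSI inhibition 0.1, D1 = D2 drive 1.19.  High:
FSI drive 14, g_GJ 0.3, inhibition 0.005, D1 1.29, D2 1.09.

## Integration and noise

The full coupled system (all compartments, all gates, one GABA gate per
source cell) is advanced by classical fixed-step RK4 at dt = 0.01 ms in
a numba-compiled kernel.  Noise is redrawn once per step and held
constant across the four stages.  Output is decimated to 5 kHz; spikes
are detected online at full resolution (upward crossing of 0 mV, 2 ms
refractory).

Gates may overshoot [0, 1] by integrator rounding; overshoots up to
10⁻⁶ are clamped silently and anything larger aborts the run as an
instability.  (A far stricter clamp threshold would abort healthy
trajectories: RK4 at this step size produces overshoots well above
10⁻¹² around spikes.)

**FSI Poisson drive.** Each FSI dendrite receives an independent
homogeneous Poisson stream (default 100 events/s).  Each event injects
a single-step rectangular current pulse; a one-sided exponential kernel
(1 ms decay) is available.  The event amplitude is not a published
quantity; it was fixed once by the single-cell calibration that a
baseline-drive FSI (7 µA/cm²) receiving 500 events/s bursts at a
θ-range interburst frequency.  Amplitude 240 µA/cm² (charge
2.4 nA·ms/cm² per event, i.e. a ~2.4 mV dendritic kick) yields
5.2–5.8 Hz interburst frequency there, and was frozen before any
network-level analysis.  Strong noise (7000 events/s) then degrades
single-cell low-frequency rhythmicity, as it should.

**SPN Gaussian noise.** Additive current noise of mean zero and unit
standard deviation with per-step amplitude 4·δt (0.04 µA/cm² at the
default step), implemented literally.  The printed form is
dimensionally odd, so a √δt switch is provided; it is off by default
because any interpretation that makes the noise substantially larger
(4·√δt ≈ 0.4, or 4 µA/cm²) ignites spontaneous spiking in the isolated
baseline SPN network, which must stay quiescent.

**Initial conditions.** FSI voltages start uniformly in [−90, −50] mV
with gates at their voltage-clamped steady state.  SPNs start in
[−63.5, −62.7] mV — near their resting state — for a dynamical reason:
the SPN is bistable around baseline drive.  A quiescent state (in fact
a subthreshold M-current limit cycle, which is what produces the
subthreshold low-β oscillation of the non-firing network) coexists with
a rebound-driven spiking limit cycle, and the quiescent basin measured
in the (V₀, steady-gates) slice at I = 1.19 µA/cm² is only ≈[−63.6,
−62.6] mV.  Hyperpolarised starts deactivate the M-current and rebound
onto the spiking attractor, igniting self-sustained network firing that
the quiescent baseline condition must not show.  The 0.8 mV jitter
desynchronises the population while staying inside the basin.

## Observables

The **surrogate LFP** is the sum of GABA_A synaptic currents over a
selected population, evaluated after a 1000 ms transient.  Currents
onto SPNs are recorded separately by presynaptic source (FSI-sourced vs
SPN-sourced), because the FSI-driven γ packets otherwise mask the weaker
SPN-internal β currents in envelope analyses.

Spectra are Thomson **multitaper** estimates: 7 DPSS tapers at
time-bandwidth 4 on de-meaned traces, one-sided, normalised so total
power equals the series variance (Parseval, within 5 %).  Band peaks
are the argmax of the PSD restricted to δ/θ 1–10 Hz, β 8–30 Hz, low γ
40–60 Hz, high γ 60–100 Hz, wide γ 40–100 Hz.  Spectrograms are
sliding-window multitaper estimates.

**Burst statistics** segment a spike train at a 25 ms interspike
threshold (within-burst rates ≥ 40 Hz, an order of magnitude above
δ/θ gaps).  `intraburst_rate` is the mean instantaneous within-burst
rate; `min_rate` the reciprocal of the longest within-burst interval.
The **minimum firing rate** of a cell is reported as `min_rate` at the
smallest drive that sustains spiking — the rate floor below which the
cell never fires, which is the quantity the stuttering-FSI literature
plots (the mean within-burst rate sits a few Hz above it).

**Band-limited traces and envelopes** come from a complex-Morlet CWT
averaged over scales spanning the band.  Phase-amplitude coupling is
the envelope-weighted mean resultant of the slow-band Hilbert phase
(depth ∈ [0, 1]).  For combined networks, `packet_interactions` takes
the γ envelope from the FSI-population LFP and the β envelope from the
SPN-sourced currents, the population-specific surrogates in which each
rhythm is generated.

## Problem sizes and experiment defaults

Fixture scales: `tiny` (5 FSI / 10+10 SPN, 0.5 s) for unit tests,
`small` (20 / 40+40, 2 s) for integration-level checks, `full`
(50 / 100+100, ≥4 s) for the full-scale experiments.  Both the test
suite and `scripts/acceptance.py` measure network spectra on a 3 s
post-transient window (0.33 Hz resolution), five seeds per condition.
Heterogeneity sweeps draw per-cell values uniformly from
[default·(1−h), default·(1+h)].  The assembly-pulse protocol delivers
20 ms, 5 µA/cm² pulses to D1 cells 50–100 at 1680 ms and cells 25–75 at
2080 ms; assembly coherence is the mean pairwise count of spike
coincidences within 5 ms, normalised by geometric-mean spike count,
over a 200 ms post-pulse window.

## What the model reproduces, and known gaps

At the printed parameters the implementation reproduces: the single-FSI
regimes (low-γ bursts at 8 µA/cm², high-γ bursts at 20, δ interburst
rhythm, ~41 Hz minimum rate at rheobase with g_D = 6, tonic firing with
g_D = 0); the dopamine switch of the 50-FSI network (baseline: ~56 Hz
γ without network δ/θ; high: ~75 Hz γ nested in a ~3 Hz δ/θ with
strong phase modulation); the quiescent baseline SPN network with
subthreshold low-β and the ~20 Hz β of the excited D1 network; and, in
the combined circuit, paradoxical excitation of SPNs at baseline,
~19 Hz D1 β at high dopamine, and δ/θ-timed anticorrelated alternation
of FSI-γ and SPN-β packets.

Known quantitative gaps, stable across seeds and robust to the
admissible noise settings:

* With g_D = 0 the noise-free two-compartment FSI has a hard (class-2)
  firing onset at ≈17 Hz rather than a rate continuously approaching
  zero; the "no minimum rate" description may reflect noise-graded
  onset or the single-compartment predecessor model.
* At baseline the δ/θ rhythmicity of *individual* FSI voltages is weak:
  the per-cell δ/θ peak-to-band-median ratio sits near the same ~3
  threshold as the (correctly flat) LFP, rather than clearly above it.
  Baseline cells here fire sparse noise-gated doublets at ~2 Hz, too
  irregularly to build a sharp single-cell δ/θ peak.
* SPN β at subthreshold drives in the combined circuit runs ~2–4 Hz
  low: baseline SPN β ≈ 12 Hz (vs ~15) and high-dopamine D2 β ≈ 10–14
  Hz (vs ~15), while the suprathreshold D1 β (~19–20 Hz) is on target.
  The β pacing of subthreshold SPNs depends on the density of FSI
  rebound kicks; baseline FSI firing here is ~2 Hz, sparser than the
  raster figures of the original circuit suggest, and no printed
  parameter we varied within its stated meaning closes the gap.

The synthetic conditions emulate tonic + Poisson background input and
stationary dopaminergic tone; they contain no structured cortical
input, no distance-dependent connectivity, and unrealistically high
FSI:SPN ratios (as in the source model), so passing tests demonstrate
internal consistency of the mechanism, not in vivo fidelity.

## Numerical notes

RK4 self-convergence on the noise-free FSI is fourth order (log-log
slope of max-voltage error vs dt within [3.5, 4.5]).  Removable
singularities of the SPN rate functions (V = −54, −52, −27, −30 mV) are
evaluated by their analytic limits inside a 10⁻⁶ mV guard.  Simulations
are bitwise reproducible from (configuration, seed): a master seed
spawns independent streams for connectivity, initial conditions, noise
and heterogeneity.  All-to-all SPN blocks exclude autapses.  Empty
populations (FSI-only or SPN-only networks) are first-class.
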