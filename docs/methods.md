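# Methods

`okrsim` simulates the cerebellar corticonuclear microcomplex that
underlies gain adaptation of the optokinetic response (OKR), at a level
of detail sufficient to watch posttraining memory consolidation unfold:
fast acquisition at cortical parallel-fiber → Purkinje-cell (PF–PC)
synapses, and slow transfer to nuclear mossy-fiber → vestibular-nucleus
(MF–VN) synapses. This note records the model, the parameters that
matter, the numerical choices, and what the desk-scale emulation does
and does not show.

## Circuit and membrane model

The reference circuit is 1 mm³ of cerebellar cortex plus its target
nucleus: 1,048,576 granule cells (GR) on a 1024×1024 grid, 1024 Golgi
cells (GO, 32×32), 16 Purkinje cells (PC), 16 basket cells (BS), one
inferior-olive cell (IO) and one vestibular-nucleus cell (VN). Granule
cells are partitioned into clusters in register with the GO grid; every
GR of a cluster shares the same Golgi afferents, while each GR receives
its own four private mossy fibers. Parallel fibers contact every GO, PC
and BS (full fan-in). A single climbing fiber (CF), carrying retinal
slip, reaches all 16 PCs; all PCs inhibit the VN; a pool of mossy fibers
drives the VN directly.

Each neuron is a conductance-based leaky integrate-and-fire unit

    C du/dt = −g_leak (u − E_leak) − g_AMPA (u − E_ex) − g_NMDA (u − E_ex)
              − g_GABA (u − E_inh) − g_ahp (u − E_ahp) + I_ext ,

with per-type constants from the standard parameter table shipped in
`okrsim/data/parameters.yaml` (units mV, pF, nS, nA, ms). The NMDA
conductance is voltage-independent (no Mg²⁺ block). A spike is emitted
when `u` crosses `θ_spike`; on spike the after-hyperpolarization
conductance is set to its peak (saturating, not additive) and decays
with `τ_ahp`, and the membrane is hard-reset to `E_leak`. The hard reset
is the package default because with the table's AHP peaks (0.1 nS for
PC and BS against >100 nS of synaptic drive) the AHP alone cannot
repolarize a tonically driven cell: without a reset, PC/BS/VN lock at
the 1-ms sampling ceiling of 1000 spikes/s and the circuit degenerates.
The no-reset variant remains available (`NetworkConfig(hard_reset=False)`)
for comparison.

Synaptic conductances are causal exponential-kernel convolutions of
weighted presynaptic spike trains (single- or double-exponential kernels
per target type and receptor), implemented as one recursive decay
accumulator per kernel component. Conductance summation is linear, so it
may be partitioned over the presynaptic population and reduced by
addition; `split_reduce_check` exposes this as a correctness property
(the full-scale ancestor of this code path is a multi-device reduction).
Internal spikes reach their targets with a uniform one-step (1 ms)
bookkeeping latency; external Poisson inputs act within their own step.
Parallel fibers conduct at ~0.24 m/s, i.e. ≤ 4.2 ms across 1 mm —
negligible against the 50-ms plasticity window — so no transmission
delays are modeled (`pf_delay_estimate` documents the arithmetic).

## Stimulus and protocol

During training, the optokinetic stimulus and retinal slip are
inhomogeneous Poisson trains with rate `f(t) = mean·(1 + sin 2πt/T)`,
`T = 6 s` (MF mean 15 spikes/s; CF mean 1.5 spikes/s). At rest both
fire homogeneously (5 and 1 spikes/s). Discretization is Bernoulli per
1-ms step with `p = f(t)·dt` (small-p bias < 2% at 30 spikes/s). The
protocol repeats daily 1-h training (600 cycles) plus 23-h rest for five
days; 4.32 × 10⁸ ms of simulated time uncompressed. OKR gain is read
out per day from 10 probe cycles before and after training: VN spikes
are folded modulo T into a 100-ms histogram and fitted with
`B + A·cos(2πt/T + φ)` by closed-form least squares on cosine/sine
regressors; the amplitude `A` is the gain, `B` the baseline.

## Plasticity

**Cortical site (PF–PC).** Each synapse carries a weight `w` (init 1)
relaxing with `τ_w = 20 min` toward `1 + x`, where the internal variable
`x` (init 0) relaxes to 0 with `τ_x = 240 min` and receives
spike-driven impulses: a CF spike depresses `x` by `ltd_step` for every
PF spike of that synapse within the preceding 50-ms eligibility window
(n spikes ⇒ n·`ltd_step`), and each PF spike potentiates `x` by
`ltp_step`. The eligibility ring holds exactly 50 one-ms samples
(current step plus 49), so each PF spike is eligible for exactly 50
subsequent CF steps. The published parameter table lists the pair
(0.005, 0.1); as labeled, the potentiation drive would exceed the
depression drive ~260-fold under any stationary spike statistics and
the weight could only rise during training. With the two constants in
the transposed roles — `ltd_step = 0.1` per windowed coincidence,
`ltp_step = 0.005` per PF spike — the rest state satisfies the exact
stationarity identity

    ltp_step = ltd_step × (50 ms window) × (1 spikes/s rest CF rate),

independent of the PF rate, and training (CF at 1.5 spikes/s, in-phase
modulation) is net-depressing. We take that identity as decisive and
default to the transposed assignment. The as-printed "literal" form
(`w` relaxing toward `x`, hence draining to 0 at rest) and a
rate-scaled impulse variant (impulses divided by `τ_x`) are selectable
for comparison.

**Nuclear site (MF–VN).** The engine uses the simplified form
`τ_v dv/dt = w_c − w(t)` with `w(t)` the population-average PF–PC
weight and `w_c = 1`: cortical depression slowly potentiates the
nuclear weight — the memory-transfer mechanism. The full
thresholded-Hebbian form, `τ_v dv/dt = −v⟨MF⟩ + ⟨MF(VN − θ)⟩` with
tumbling 6-s window averages and `θ` a running (exponential) average of
the VN rate over ~10 windows, is implemented and unit-tested;
activities enter it in spikes/s. `τ_v` is not stated in the reference
material; the default is 3 days. A faster value (0.25 day) was
evaluated and rejected: it drives the VN baseline from ~49 to ~250
spikes/s over five days through the VN's steep drive–rate curve,
contradicting the observed stationary 30–50 spikes/s baseline.

The effective synaptic weight of a PF on a PC is the pathway base
(0.00075) times `w_ij`; of a pooled MF on the VN, the base (0.2) times
`v`. With one climbing fiber shared by all PCs and full PF fan-in, the
per-PC weight rows evolve identically; the engine therefore stores one
logical row (the class supports per-PC CF flags for the general case).
Plasticity uses forward Euler at 1 ms (its time constants are ≥ seconds
even compressed); membranes use RK2.

## Time compression (κ)

Protocol durations and the slow plasticity constants (`τ_w`, `τ_x`,
`τ_v`, and the windowed averages of the full nuclear rule) divide by κ;
fast membrane/synapse dynamics and the 6-s stimulus period are
untouched. Because the plasticity rules are linear time-invariant
filters, rescaling the slow constants with the schedule preserves the
*expected* weight trajectories against protocol phase. What compression
cannot preserve is the event statistics: a κ=600 training phase is a
single 6-s stimulus cycle (~9 CF events), so the per-day depression
dose carries the Poisson and network-state variability that 600 cycles
would average away. Consequences observed at κ=600 (4096 GR, five
days): per-day dips of the mean PF–PC weight range 0.6–9%; day-end `v`
rises overall but can stall on a near-zero-dose day; the within-day
gain increment inherits the dose noise and shows no detectable upward
trend across five days, although its driver (`v` accumulation) is
present. Probe phases are *fully frozen* plasticity interludes
(impulses and relaxation): compressed, a 60-s probe is comparable to
the compressed `τ_x`, and letting relaxation run during measurement
would erase the just-acquired depression — an artifact of κ, not of the
model. Probes therefore take zero time on the consolidation clock, and
the 24 h/κ day consists of training + rest exactly.

## Desk-scale calibration

Three structural choices are not fixed by the published tables and were
calibrated once against published operating characteristics:

- **Golgi neighborhood** (`go_neighborhood`, default 1): each cluster is
  inhibited by its nearest Golgi cell. With four shared afferents the
  granule layer is inhibited to 0.38 spikes/s and plasticity is starved
  of coincidences; with one, granule cells fire ~1.8 spikes/s with
  clear stimulus modulation (~0–3.6 spikes/s over the cycle).
- **Scale compensation** (`scale_compensation`, default on): at N
  granule cells the feedforward PF readout weights (GR→PC, GR→BS) are
  multiplied by 1,048,576/N so the expected summed PF drive is
  scale-invariant. The recurrent GR→GO weight is *not* compensated:
  multiplying it quantizes single GR spikes into a 256-fold Golgi
  drive, which keeps every GO tonically primed (3-mV threshold gap,
  170-ms NMDA tail) and locks the granule layer silent. The recurrent
  loop's operating point is governed by its stability boundary, not its
  mean drive.
- **VN mossy-fiber pool** (`n_mf_vn_pool`): the VN fan-in is
  anatomically unconstrained here; it is calibrated per scale so the
  pretraining VN baseline sits in the physiological 30–50 spikes/s
  band — 78 fibers at 4096 GR, 44 at 16,384 GR, log-interpolated
  between (the granular operating point, hence the Purkinje rate and VN
  inhibition, is not fully scale-invariant). Measured baselines: 43–54
  spikes/s across seeds and both scales.

## Numerics

- Membranes: explicit second-order Runge-Kutta (Heun) at Δt = 1 ms,
  synaptic conductances held constant within a step. When the summed
  conductance makes `g·Δt/C` exceed 1 (Golgi cells under parallel-fiber
  surges reach hundreds of nS; the explicit stability limit is 2) the
  step is subdivided into equal RK2 substeps. In the non-stiff regime
  this is plain RK2 and exhibits the expected second-order convergence.
- Spike handling: threshold crossing at step end; AHP saturates at its
  peak; hard reset to `E_leak` (default; configurable).
- Accumulator updates, plasticity relaxation and the weight clip at 0
  are the only nonlinearities outside threshold crossing; plasticity is
  otherwise linear, and the test suite checks superposition exactly.
- All randomness flows from named, seeded streams (GR mossy fibers, CF,
  VN pool) spawned from one master seed; identical configuration and
  seed give byte-identical outputs, and full simulation state
  (membranes, accumulators, plasticity, stream positions, input-buffer
  remainder) can be checkpointed and resumed exactly.

## Reproducibility index

Granule-cell pattern reproducibility across stimulus cycles is
quantified by convolving each cell's spikes with a causal exponential
(τ = 8.3 ms, the AMPA PF-EPSP time constant) and comparing successive
cycles:

    R(t) = Σ_j z_j⁽ⁱ⁾ z_j⁽ⁱ⁺¹⁾ / (Σ_j z_j⁽ⁱ⁾ · Σ_j z_j⁽ⁱ⁺¹⁾) ,

summarized as mean ± sd over successive-cycle pairs. As printed, the
product-of-sums denominator yields R = 1/N for N identical uniform
cells and pins R ≈ 1/N for cells with private noise regardless of
pattern quality; a cosine normalization (root of summed squares) is
available behind a switch. Neither form depends on the *number* of
cells at fixed per-cell statistics, so the benefit of a large granular
layer is assessed on the population signal: N·R (product form, equal
recorded subsets) is the cycle-to-cycle correlation ratio of the
population-summed EPSP trace, and rises with network size (measured
0.975 at 4096 GR vs 0.918 at 400 GR) because private mossy-fiber noise
averages out of the summed parallel-fiber signal.

## What the desk-scale emulation shows — and does not

Shown at 4096–16,384 GR with κ = 600: the published structural
arithmetic (counts, cycles, durations, delays); stimulus statistics;
the pretraining VN operating band; per-day cortical dip-and-recovery;
nuclear weight accumulation across days; rising pretraining gain; and
the scale advantage of the granular layer for signal transmission. Not
shown: the growing within-day gain increment (dose noise at one
training cycle per compressed day, see above); absolute wall-clock
performance of the original multi-device implementation (out of scope);
and any claim about biological parameter values beyond the shipped
table. Granule rates at desk scale (~1.8 spikes/s) sit below the
full-scale design point, a consequence of the recurrent loop's scale
sensitivity; the feedforward readout is compensated, the loop is not.

## Problem sizes used

Unit and property tests run at 256–4096 granule cells with seconds of
simulated time. The consolidation demonstration runs 5 compressed days
at 4096 GR (κ = 600; ≈ 1.3 × 10⁶ steps); the pretraining baseline
measurement runs 10 probe cycles at 16,384 GR; the full-scale builder
(1,048,576 GR) is constructed, not integrated.
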