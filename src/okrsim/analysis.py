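"""Measurement procedures: OKR gain and granule-cell reproducibility.

OKR gain. The modulation amplitude of the vestibular-nucleus firing rate
is the model's readout of OKR gain: spikes from the probe cycles are
folded modulo the 6-s stimulus period into a 100-ms-bin histogram and fit
with ``B + A cos(2*pi*t/T + phi)`` by closed-form linear least squares on
cosine/sine regressors (A = sqrt(a^2 + b^2) >= 0); ``A`` is the gain and
``B`` the baseline rate.

Reproducibility. To quantify how reliably the granule-cell population
re-encodes the same stimulus across cycles despite Poisson input noise,
each cell's spikes are convolved with a causal exponential (tau = 8.3 ms,
the AMPA-receptor PF-EPSP time constant), giving per-cycle traces
``z_j(t)``, and successive cycles are compared by the index

    R(t) = sum_j z_j^(i) z_j^(i+1) / (sum_j z_j^(i) * sum_j z_j^(i+1)),

summarized as mean +/- sd over pairs of successive cycles. The printed
product-of-sums denominator gives R = 1/N for N identical uniform cells;
a cosine-similarity normalization (root of summed squares) is available
behind ``normalization="cosine"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

EPSP_TAU_MS = 8.3


@dataclass
class GainMeasurement:
    """Cosine-fit summary of one probe measurement."""

    amplitude: float  # spikes/s, >= 0
    baseline: float  # spikes/s
    phase_offset: float  # radians, fit is B + A*cos(2*pi*t/T + phase)
    histogram: np.ndarray = field(repr=False, default=None)  # spikes/s per bin
    bin_ms: float = 100.0
    period_s: float = 6.0
    n_cycles: int = 0
    day: int | None = None
    phase: str | None = None  # pre | post


def measure_gain(
    spike_times_ms,
    n_cycles: int,
    period_s: float = 6.0,
    bin_ms: float = 100.0,
    t0_ms: float = 0.0,
) -> GainMeasurement:
    """OKR gain from VN spike times over ``n_cycles`` probe cycles.

    Spikes are folded modulo the stimulus period before binning
    (equivalent to fitting all cycles jointly at fixed period). An empty
    spike set yields amplitude 0 with a warning.
    """
    if n_cycles < 1:
        raise ValueError("need at least one full cycle")
    period_ms = period_s * 1000.0
    n_bins = period_ms / bin_ms
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin width must divide the stimulus period")
    n_bins = int(round(n_bins))
    spikes = np.asarray(spike_times_ms, dtype=float)
    if spikes.size == 0:
        warnings.warn("no spikes: amplitude set to 0", stacklevel=2)
        hist = np.zeros(n_bins)
        return GainMeasurement(0.0, 0.0, 0.0, hist, bin_ms, period_s, n_cycles)
    folded = np.mod(spikes - t0_ms, period_ms)
    counts, _ = np.histogram(folded, bins=n_bins, range=(0.0, period_ms))
    rate = counts / (n_cycles * bin_ms / 1000.0)  # spikes/s per bin
    centers = (np.arange(n_bins) + 0.5) * bin_ms
    theta = 2.0 * np.pi * centers / period_ms
    X = np.column_stack([np.ones(n_bins), np.cos(theta), np.sin(theta)])
    beta, *_ = np.linalg.lstsq(X, rate, rcond=None)
    b0, a, b = beta
    amplitude = float(np.hypot(a, b))
    phase = float(np.arctan2(-b, a))  # a cos + b sin = A cos(theta + phase)
    return GainMeasurement(amplitude, float(b0), phase, rate, bin_ms, period_s, n_cycles)


def fit_cosine(histogram_rate, period_s: float = 6.0, bin_ms: float = 100.0):
    """Closed-form cosine fit of an already-binned rate histogram.

    Returns (amplitude, baseline, phase). Exact on noiseless cosines.
    """
    rate = np.asarray(histogram_rate, dtype=float)
    n_bins = rate.shape[0]
    centers = (np.arange(n_bins) + 0.5) * bin_ms
    theta = 2.0 * np.pi * centers / (period_s * 1000.0)
    X = np.column_stack([np.ones(n_bins), np.cos(theta), np.sin(theta)])
    b0, a, b = np.linalg.lstsq(X, rate, rcond=None)[0]
    return float(np.hypot(a, b)), float(b0), float(np.arctan2(-b, a))


def epsp_trace(
    spike_times_ms,
    duration_ms: float,
    tau_ms: float = EPSP_TAU_MS,
    dt_ms: float = 1.0,
    t0_ms: float = 0.0,
) -> np.ndarray:
    """Causal exponential convolution of one spike train.

    ``z(t) = sum_f exp(-(t - t_f)/tau)`` for ``t >= t_f``; computed by the
    same recursive decay accumulation as the synaptic kernels. Sampled at
    step times; a spike contributes 1 at its own step.
    """
    if tau_ms <= 0:
        raise ValueError("tau must be > 0")
    n_steps = int(round(duration_ms / dt_ms))
    counts = np.zeros(n_steps)
    spikes = np.asarray(spike_times_ms, dtype=float) - t0_ms
    idx = np.floor(spikes / dt_ms + 1e-9).astype(int)
    idx = idx[(idx >= 0) & (idx < n_steps)]
    np.add.at(counts, idx, 1.0)
    decay = np.exp(-dt_ms / tau_ms)
    z = np.empty(n_steps)
    acc = 0.0
    for t in range(n_steps):
        acc = acc * decay + counts[t]
        z[t] = acc
    return z


def epsp_traces(
    trains: list, duration_ms: float, tau_ms: float = EPSP_TAU_MS,
    dt_ms: float = 1.0, t0_ms: float = 0.0,
) -> np.ndarray:
    """Stacked traces, shape (n_cells, n_steps). Vectorized over cells."""
    n_steps = int(round(duration_ms / dt_ms))
    counts = np.zeros((len(trains), n_steps))
    for j, spikes in enumerate(trains):
        s = np.asarray(spikes, dtype=float) - t0_ms
        idx = np.floor(s / dt_ms + 1e-9).astype(int)
        idx = idx[(idx >= 0) & (idx < n_steps)]
        np.add.at(counts[j], idx, 1.0)
    decay = np.exp(-dt_ms / tau_ms)
    z = np.empty_like(counts)
    acc = np.zeros(len(trains))
    for t in range(n_steps):
        acc = acc * decay + counts[:, t]
        z[:, t] = acc
    return z


def reproducibility_index(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    normalization: str = "product",
) -> np.ndarray:
    """Reproducibility index R(t) between two cycles' trace stacks.

    ``traces_a``/``traces_b`` are (n_cells, n_steps) EPSP traces of the
    same cells on two successive stimulus cycles. ``normalization``:
    "product" is the printed product-of-sums denominator; "cosine" uses
    sqrt(sum z^2) * sqrt(sum z'^2). Time points with a zero denominator
    are returned as NaN.
    """
    a = np.asarray(traces_a, dtype=float)
    b = np.asarray(traces_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("both cycles must have the same cell count and length")
    num = (a * b).sum(axis=0)
    if normalization == "product":
        den = a.sum(axis=0) * b.sum(axis=0)
    elif normalization == "cosine":
        den = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    else:
        raise ValueError("normalization must be 'product' or 'cosine'")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r


@dataclass
class ReproducibilityResult:
    """Mean +/- sd of R(t) over successive-cycle pairs."""

    mean: np.ndarray
    sd: np.ndarray
    n_pairs: int
    tau_ms: float = EPSP_TAU_MS
    normalization: str = "product"

    @property
    def grand_mean(self) -> float:
        return float(np.nanmean(self.mean))


def reproducibility_over_cycles(
    trains_per_cell: list,
    cycle_ms: float,
    n_cycles: int,
    tau_ms: float = EPSP_TAU_MS,
    dt_ms: float = 1.0,
    normalization: str = "product",
    t0_ms: float = 0.0,
) -> ReproducibilityResult:
    """R(t) statistics from whole-run spike trains of many cells.

    Each cell's train is cut into ``n_cycles`` consecutive cycles of
    ``cycle_ms``; R(t) is computed for each of the ``n_cycles - 1`` pairs
    of successive cycles and summarized across pairs (NaN-aware).
    Traces are built per cycle, so EPSPs do not leak across cycle
    boundaries.
    """
    if n_cycles < 2:
        raise ValueError("need at least two cycles")
    per_cycle = []
    for i in range(n_cycles):
        start = t0_ms + i * cycle_ms
        cut = [
            np.asarray(s, dtype=float)[
                (np.asarray(s, dtype=float) >= start)
                & (np.asarray(s, dtype=float) < start + cycle_ms)
            ]
            for s in trains_per_cell
        ]
        per_cycle.append(epsp_traces(cut, cycle_ms, tau_ms, dt_ms, t0_ms=start))
    rs = [
        reproducibility_index(per_cycle[i], per_cycle[i + 1], normalization)
        for i in range(n_cycles - 1)
    ]
    rs = np.stack(rs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(rs, axis=0)
        sd = np.nanstd(rs, axis=0, ddof=1) if rs.shape[0] > 1 else np.zeros_like(mean)
    return ReproducibilityResult(mean, sd, rs.shape[0], tau_ms, normalization)
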