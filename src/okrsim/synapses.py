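"""Exponential synaptic-conductance kernels as recursive decay accumulators.

The conductance of receptor type ``x`` on a target neuron is the
convolution of weighted presynaptic spike trains with a causal single- or
double-exponential kernel,

    g_x(t) = gbar_x * sum_j w_j * sum_f exp_x(t - t_f) * Theta(t - t_f),

where ``exp_x(t) = sum_c k_c * exp(-t / tau_c)``. Because the kernel is a
sum of exponentials the convolution reduces to one recursive accumulator
per component: each step the accumulator decays by ``exp(-dt/tau_c)`` and
is incremented by ``k_c`` times the summed spike weight. The calculation
is linear in the presynaptic spikes, so it can be split over arbitrary
partitions of the presynaptic population and reduced by summation — a
property exposed here as a test utility (`split_reduce_check`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KernelSpec:
    """A synaptic kernel: list of ``(coefficient, tau_ms)`` components."""

    components: tuple[tuple[float, float], ...]
    receptor: str = ""

    def __post_init__(self):
        if not self.components:
            raise ValueError("kernel needs at least one component")
        for coeff, tau in self.components:
            if coeff <= 0 or tau <= 0:
                raise ValueError("kernel coefficients and taus must be > 0")

    @classmethod
    def from_list(cls, comps, receptor: str = "") -> "KernelSpec":
        return cls(tuple((float(c), float(t)) for c, t in comps), receptor)

    def evaluate(self, t_ms) -> np.ndarray:
        """Kernel value ``sum_c k_c exp(-t/tau_c)`` for ``t >= 0`` (0 before)."""
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        mask = t >= 0
        for coeff, tau in self.components:
            out = out + np.where(mask, coeff * np.exp(-np.clip(t, 0, None) / tau), 0.0)
        return out

    @property
    def peak(self) -> float:
        """Value at t -> 0+ (sum of coefficients)."""
        return sum(c for c, _ in self.components)

    def integral_ms(self) -> float:
        """Time integral ``sum_c k_c tau_c`` in ms (used for rate estimates)."""
        return sum(c * t for c, t in self.components)


class ConductanceState:
    """Recursive accumulators for one projection's kernel.

    Holds one trace per (kernel component, target); the dimensionless
    total is multiplied by the postsynaptic peak conductance by the caller.
    """

    def __init__(
        self, kernel: KernelSpec, n_targets: int, dt_ms: float = 1.0,
        validate: bool = True,
    ):
        self.kernel = kernel
        self.n_targets = int(n_targets)
        self.dt_ms = float(dt_ms)
        self.validate = bool(validate)
        self._coeffs = np.array([c for c, _ in kernel.components])[:, None]
        self._decay = np.exp(
            -dt_ms / np.array([t for _, t in kernel.components])
        )[:, None]
        self.a = np.zeros((len(kernel.components), self.n_targets))

    def decay_and_inject(self, weighted_spike_sum=None) -> None:
        """One step: decay every component, then add the weighted spike sum.

        ``weighted_spike_sum`` is the per-target sum of (weight x spike)
        for spikes landing this step; scalar values broadcast over targets.
        Negative sums are rejected (weights are nonnegative by
        construction; the engine skips this check in its hot loop via
        ``validate=False``).
        """
        self.a *= self._decay
        if weighted_spike_sum is None:
            return
        w = np.asarray(weighted_spike_sum, dtype=float)
        if self.validate and np.any(w < 0):
            raise ValueError("negative spike weights rejected")
        if w.ndim == 0 and float(w) == 0.0:
            return
        self.a += self._coeffs * w

    def total(self) -> np.ndarray:
        """Dimensionless conductance trace per target (>= 0)."""
        return self.a.sum(axis=0)

    def get_state(self) -> np.ndarray:
        return self.a.copy()

    def set_state(self, a: np.ndarray) -> None:
        self.a[...] = a


def direct_convolution(
    spike_weights: np.ndarray, kernel: KernelSpec, dt_ms: float = 1.0
) -> np.ndarray:
    """O(T^2) brute-force conductance trace for oracle checks.

    ``spike_weights[t]`` is the summed spike weight injected at step ``t``;
    returns the trace sampled at step times (injection included at its own
    step, matching `ConductanceState`).
    """
    spike_weights = np.asarray(spike_weights, dtype=float)
    n = spike_weights.shape[0]
    t = np.arange(n) * dt_ms
    out = np.zeros(n)
    for f in np.flatnonzero(spike_weights):
        out[f:] += spike_weights[f] * kernel.evaluate(t[f:] - t[f])
    return out


def split_reduce_check(
    spikes: np.ndarray,
    weights: np.ndarray,
    kernel: KernelSpec,
    n_partitions: int,
    dt_ms: float = 1.0,
):
    """Partition the presynaptic population, accumulate per partition, reduce.

    ``spikes`` is a (T, N) 0/1 array, ``weights`` the per-presynaptic-cell
    weights. Returns ``(partials, reduced, single)`` where ``partials`` is
    (n_partitions, T), ``reduced = partials.sum(0)`` and ``single`` is the
    one-pass accumulation over the whole population. Linearity of the
    kernel convolution guarantees ``reduced == single`` up to float
    rounding; this mirrors the multi-device split-reduction used to sum
    parallel-fiber input at full scale, kept here purely as a correctness
    property.
    """
    spikes = np.asarray(spikes)
    weights = np.asarray(weights, dtype=float)
    n_steps, n_pre = spikes.shape
    if n_pre % n_partitions:
        raise ValueError("n_partitions must divide the presynaptic population")
    part = n_pre // n_partitions
    partials = np.empty((n_partitions, n_steps))
    for k in range(n_partitions):
        sl = slice(k * part, (k + 1) * part)
        acc = ConductanceState(kernel, 1, dt_ms)
        for t in range(n_steps):
            acc.decay_and_inject(float(spikes[t, sl] @ weights[sl]))
            partials[k, t] = acc.total()[0]
    single = np.empty(n_steps)
    acc = ConductanceState(kernel, 1, dt_ms)
    for t in range(n_steps):
        acc.decay_and_inject(float(spikes[t] @ weights))
        single[t] = acc.total()[0]
    return partials, partials.sum(axis=0), single
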