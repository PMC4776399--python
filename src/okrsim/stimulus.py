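"""Mossy-fiber and climbing-fiber input generation and protocol scheduling.

During optokinetic training the visual-world velocity is encoded as
inhomogeneous Poisson spike trains whose rate follows the sinusoidal
stimulus, ``f(t) = mean * (1 + sin(2*pi*t/T))`` with period ``T = 6 s``
(mossy fibers: mean 15 spikes/s; climbing fiber, carrying retinal slip:
mean 1.5 spikes/s). At rest both fibers fire homogeneously (5 and
1 spikes/s). The multi-day protocol alternates daily training with rest;
an optional time-compression factor ``kappa`` divides the protocol
durations (and, elsewhere, the slow plasticity time constants) so that the
consolidation dynamics replay at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: default stimulus parameters (spikes/s, seconds)
MF_TRAIN_MEAN = 15.0
CF_TRAIN_MEAN = 1.5
MF_REST_MEAN = 5.0
CF_REST_MEAN = 1.0
PERIOD_S = 6.0

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class RateLaw:
    """Firing-rate law of a Poisson fiber.

    ``mode="training"`` gives ``mean_rate * (1 + sin(2*pi*t/T))``;
    ``mode="rest"`` gives the constant ``mean_rate``.
    """

    mode: str
    mean_rate: float
    period_s: float = PERIOD_S

    def __post_init__(self):
        if self.mode not in ("training", "rest"):
            raise ValueError(f"unknown rate-law mode {self.mode!r}")
        if self.mean_rate < 0:
            raise ValueError("mean_rate must be >= 0")
        if self.period_s <= 0:
            raise ValueError("period must be > 0")

    @property
    def period_ms(self) -> float:
        return self.period_s * 1000.0

    def rate(self, t_ms):
        """Instantaneous rate in spikes/s at time ``t_ms`` (scalar or array)."""
        t = np.asarray(t_ms, dtype=float)
        if np.any(t < 0):
            raise ValueError("negative time rejected")
        if self.mode == "rest":
            return np.broadcast_to(np.float64(self.mean_rate), t.shape)[()] + 0.0 \
                if t.shape else float(self.mean_rate)
        out = self.mean_rate * (1.0 + np.sin(2.0 * np.pi * t / self.period_ms))
        return out if t.shape else float(out)


def instantaneous_rate(law: RateLaw, t_ms) -> float:
    """Functional alias for :meth:`RateLaw.rate`."""
    return law.rate(t_ms)


def mf_training_law() -> RateLaw:
    return RateLaw("training", MF_TRAIN_MEAN)


def cf_training_law() -> RateLaw:
    return RateLaw("training", CF_TRAIN_MEAN)


def mf_rest_law() -> RateLaw:
    return RateLaw("rest", MF_REST_MEAN)


def cf_rest_law() -> RateLaw:
    return RateLaw("rest", CF_REST_MEAN)


def spike_probabilities(law: RateLaw, t_ms, dt_ms: float = 1.0) -> np.ndarray:
    """Per-step Bernoulli spike probabilities ``f(t) * dt``.

    Raises if any probability exceeds 1 (invalid rate/step combination).
    """
    p = np.asarray(law.rate(t_ms), dtype=float) * dt_ms / 1000.0
    if np.any(p > 1.0):
        raise ValueError(
            f"f(t)*dt exceeds 1 for law {law.mode}/{law.mean_rate} at dt={dt_ms} ms"
        )
    return p


def sample_poisson(
    law: RateLaw,
    duration_ms: float,
    dt_ms: float = 1.0,
    n_trains: int = 1,
    rng: np.random.Generator | int | None = None,
) -> list[np.ndarray]:
    """Sample independent Poisson spike trains under ``law``.

    Discretization is Bernoulli per ``dt_ms`` step with probability
    ``f(t) * dt`` (at 1-ms resolution the small-p bias is < 2% at
    30 spikes/s). Identical seeds give identical output.

    Returns a list of ``n_trains`` arrays of spike times in ms (step start
    times).
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    if dt_ms <= 0:
        raise ValueError("dt must be > 0")
    rng = np.random.default_rng(rng)
    n_steps = int(round(duration_ms / dt_ms))
    times = np.arange(n_steps) * dt_ms
    p = spike_probabilities(law, times, dt_ms)
    trains: list[list[np.ndarray]] = [[] for _ in range(n_trains)]
    block = max(1, int(4_000_000 // max(n_trains, 1)))
    for start in range(0, n_steps, block):
        stop = min(start + block, n_steps)
        hits = rng.random((stop - start, n_trains)) < p[start:stop, None]
        step_idx, train_idx = np.nonzero(hits)
        order = np.argsort(train_idx, kind="stable")
        train_idx = train_idx[order]
        step_times = times[start:stop][step_idx[order]]
        bounds = np.searchsorted(train_idx, np.arange(n_trains + 1))
        for j in range(n_trains):
            seg = step_times[bounds[j]:bounds[j + 1]]
            if seg.size:
                trains[j].append(seg)
    return [
        np.concatenate(parts) if parts else np.empty(0, dtype=float)
        for parts in trains
    ]


@dataclass(frozen=True)
class Protocol:
    """Multi-day training/rest schedule.

    Durations are given at natural (uncompressed) scale in seconds;
    ``kappa`` compresses them. ``train_s + rest_s`` must equal 24 h so the
    compressed day is exactly ``24 h / kappa``. Probe phases (10 stimulus
    cycles before and after each training session, used for the gain
    measurement) are extra measurement interludes: plasticity is frozen
    during them by default and they do not count against the 24-h day.
    """

    n_days: int = 5
    train_s: float = 3600.0
    rest_s: float = SECONDS_PER_DAY - 3600.0
    probe_cycles: int = 10
    dt_ms: float = 1.0
    kappa: float = 1.0
    period_s: float = PERIOD_S
    freeze_plasticity_in_probe: bool = True
    strict_day: bool = True

    def __post_init__(self):
        if self.n_days < 1 or self.probe_cycles < 0:
            raise ValueError("n_days >= 1 and probe_cycles >= 0 required")
        if self.kappa < 1:
            raise ValueError("compression factor kappa must be >= 1")
        if self.dt_ms <= 0 or self.period_s <= 0:
            raise ValueError("dt and period must be > 0")
        if self.strict_day and abs(self.train_s + self.rest_s - SECONDS_PER_DAY) > 1e-6:
            raise ValueError("train_s + rest_s must equal 24 h (set strict_day=False to override)")

    @property
    def train_ms(self) -> float:
        return self.train_s * 1000.0 / self.kappa

    @property
    def rest_ms(self) -> float:
        return self.rest_s * 1000.0 / self.kappa

    @property
    def probe_ms(self) -> float:
        return self.probe_cycles * self.period_s * 1000.0

    @property
    def train_cycles(self) -> int:
        return int(self.train_ms // (self.period_s * 1000.0))


@dataclass(frozen=True)
class Phase:
    """One contiguous schedule segment."""

    name: str  # pre_probe | train | post_probe | rest
    day: int  # 1-based
    start_ms: int
    duration_ms: int
    mf_law: RateLaw
    cf_law: RateLaw
    plasticity_on: bool
    n_cycles: int = 0

    @property
    def end_ms(self) -> int:
        return self.start_ms + self.duration_ms


def build_schedule(protocol: Protocol) -> list[Phase]:
    """Expand a protocol into an ordered, gapless list of phases.

    Per day: pre-probe, training, post-probe, rest. Training cycle counts
    are ``floor(train duration / T)``; a warning is emitted when the period
    does not divide the training duration. All phase boundaries are integer
    multiples of ``dt``.
    """
    dt = protocol.dt_ms
    t_ms = protocol.period_s * 1000.0

    def steps(ms: float) -> int:
        n = int(round(ms / dt))
        if abs(n * dt - ms) > 1e-9 * max(1.0, ms):
            raise ValueError(f"phase duration {ms} ms is not a multiple of dt={dt} ms")
        return n

    train_ms = protocol.train_ms
    if train_ms % t_ms > 1e-9 and abs(train_ms % t_ms - t_ms) > 1e-9:
        warnings.warn(
            "stimulus period does not divide the training duration; "
            "cycle count truncated to whole cycles",
            stacklevel=2,
        )
    mf_tr, cf_tr = mf_training_law(), cf_training_law()
    mf_re, cf_re = mf_rest_law(), cf_rest_law()

    phases: list[Phase] = []
    cursor = 0
    for day in range(1, protocol.n_days + 1):
        probe_steps = steps(protocol.probe_ms)
        for name in ("pre_probe", "train", "post_probe", "rest"):
            if name in ("pre_probe", "post_probe"):
                if probe_steps == 0:
                    continue
                dur, mf, cf = probe_steps, mf_tr, cf_tr
                plast = not protocol.freeze_plasticity_in_probe
                cyc = protocol.probe_cycles
            elif name == "train":
                dur, mf, cf = steps(train_ms), mf_tr, cf_tr
                plast, cyc = True, protocol.train_cycles
            else:
                dur, mf, cf = steps(protocol.rest_ms), mf_re, cf_re
                plast, cyc = True, 0
            phases.append(
                Phase(name, day, int(cursor * dt), int(dur * dt), mf, cf, plast, cyc)
            )
            cursor += dur
    return phases


def schedule_duration_ms(phases: list[Phase]) -> int:
    """Total scheduled duration; phases are guaranteed gapless."""
    return phases[-1].end_ms if phases else 0


def consolidation_duration_ms(protocol: Protocol) -> float:
    """Duration spent on the consolidation clock (train + rest, no probes)."""
    return protocol.n_days * (protocol.train_ms + protocol.rest_ms)
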