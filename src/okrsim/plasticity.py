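"""Synaptic plasticity: cortical PF-PC LTD/LTP and nuclear MF-VN transfer.

Cortical site (parallel fiber -> Purkinje cell). Each synapse carries a
weight multiplier ``w_ij`` relaxing with time constant ``tau_w`` toward a
drive set by an internal variable ``x_ij`` (itself relaxing to rest with
the slower ``tau_x``):

    tau_w dw/dt = -(w - baseline) + x
    tau_x dx/dt = -x   (+ spike-driven impulses)

A climbing-fiber spike depresses ``x`` by ``ltd_step`` for every PF spike
of that synapse in the preceding 50-ms eligibility window (n spikes => n
times the step); every PF spike potentiates ``x`` by ``ltp_step``. In the
default *deviation* form the baseline is 1 and ``x`` is the deviation
from rest, so with no stimulation weights return spontaneously to their
initial value; the *literal* form (baseline 0, w relaxes toward x) is
available for comparison. The default step sizes satisfy
``ltp_step = ltd_step * window * (rest CF rate)`` which makes the rest
state exactly stationary in expectation regardless of the PF rate.

Nuclear site (mossy fiber -> vestibular nucleus). The weight ``v``
integrates the cortical state: in the simplified form

    tau_v dv/dt = w_c - w(t)

with ``w(t)`` the population-average PF-PC weight — LTD in the cortex
(w < w_c) slowly potentiates the nuclear weight, transferring the learned
gain. The full thresholded-Hebbian form based on windowed MF/VN activity
averages is also provided.

Under time compression the caller divides ``tau_w``, ``tau_x`` and
``tau_v`` by kappa along with the protocol durations; the rules are
linear time-invariant filters, so this rescaling preserves the weight
trajectories against protocol phase.
"""

from __future__ import annotations

import numpy as np


class PfPcPlasticity:
    """State and update of all PF-PC synapses of one microcomplex.

    Parameters
    ----------
    n_pf : int
        Number of parallel fibers (granule cells).
    n_pc : int
        Number of Purkinje-cell rows. With a single climbing fiber shared
        by all PCs and full PF fan-in every row evolves identically, so
        the engine uses ``n_pc=1``; the class supports per-PC climbing
        fiber flags for the general case.
    tau_w_ms, tau_x_ms : float
        Relaxation constants (compressed values if running under kappa).
    ltd_step, ltp_step : float
        Impulse sizes of the eligibility-gated depression and of the
        per-PF-spike potentiation.
    window_ms : float
        LTD eligibility window; ``dt`` must divide it. The ring buffer
        holds exactly ``window_ms/dt`` samples (the current step plus the
        49 preceding at defaults), so each PF spike is eligible for
        exactly 50 subsequent climbing-fiber steps.
    form : {"deviation", "literal"}
        Baseline convention, see module docstring.
    impulse : {"jump", "rate"}
        "jump": x changes by the full step per event. "rate": impulses are
        scaled by dt/tau_x, i.e. the spike indicators are read as drive
        terms of the relaxation ODE.
    w_min : float or None
        Lower clip for w (None disables clipping, used by linearity
        tests).
    """

    def __init__(
        self,
        n_pf: int,
        n_pc: int = 1,
        *,
        tau_w_ms: float = 20.0 * 60_000.0,
        tau_x_ms: float = 240.0 * 60_000.0,
        ltd_step: float = 0.1,
        ltp_step: float = 0.005,
        window_ms: float = 50.0,
        dt_ms: float = 1.0,
        form: str = "deviation",
        impulse: str = "jump",
        w_init: float = 1.0,
        x_init: float = 0.0,
        w_min: float | None = 0.0,
    ):
        if form not in ("deviation", "literal"):
            raise ValueError("form must be 'deviation' or 'literal'")
        if impulse not in ("jump", "rate"):
            raise ValueError("impulse must be 'jump' or 'rate'")
        n_slots = window_ms / dt_ms
        if abs(n_slots - round(n_slots)) > 1e-9 or round(n_slots) < 1:
            raise ValueError("dt must divide the LTD window")
        self.n_pf, self.n_pc = int(n_pf), int(n_pc)
        self.tau_w_ms, self.tau_x_ms = float(tau_w_ms), float(tau_x_ms)
        self.ltd_step, self.ltp_step = float(ltd_step), float(ltp_step)
        self.dt_ms = float(dt_ms)
        self.form, self.impulse = form, impulse
        self.w_min = w_min
        self.baseline = 1.0 if form == "deviation" else 0.0
        self.w = np.full((self.n_pc, self.n_pf), float(w_init))
        self.x = np.full((self.n_pc, self.n_pf), float(x_init))
        self._ring = np.zeros((int(round(n_slots)), self.n_pf), dtype=np.int32)
        self._counts = np.zeros(self.n_pf, dtype=np.int64)
        self._head = 0

    @property
    def window_counts(self) -> np.ndarray:
        """Per-PF spike count over the current eligibility window."""
        return self._counts.copy()

    def step(self, pf_spikes, cf_spike) -> None:
        """Advance one dt given this step's PF spike flags and CF spike(s).

        ``pf_spikes``: bool/int array (n_pf,); ``cf_spike``: scalar flag
        shared by all PC rows, or an (n_pc,) array of per-row flags.
        """
        pf = np.asarray(pf_spikes)
        if pf.dtype != np.int32:
            pf = pf.astype(np.int32)
        # roll the eligibility window so it includes the current step
        self._counts += pf - self._ring[self._head]
        self._ring[self._head] = pf
        self._head = (self._head + 1) % self._ring.shape[0]

        dt = self.dt_ms
        cf = np.asarray(cf_spike)
        scale = 1.0 if self.impulse == "jump" else dt / self.tau_x_ms
        # relaxation (forward Euler; tau_x >> dt)
        self.x -= (dt / self.tau_x_ms) * self.x
        if pf.any():
            self.x += (scale * self.ltp_step) * pf
        if cf.any():
            dec = (scale * self.ltd_step) * self._counts
            if cf.ndim == 0:
                self.x -= dec
            else:
                self.x -= dec * cf.astype(float)[:, None]
        self.w += (dt / self.tau_w_ms) * ((self.baseline + self.x) - self.w)
        if self.w_min is not None:
            np.clip(self.w, self.w_min, None, out=self.w)

    def relax(self, n_steps: int = 1) -> None:
        """Advance the intrinsic relaxation only (no spikes, frozen window).

        Used when plasticity impulses are gated off but the slow
        relaxation should continue.
        """
        for _ in range(int(n_steps)):
            self.x -= (self.dt_ms / self.tau_x_ms) * self.x
            self.w += (self.dt_ms / self.tau_w_ms) * ((self.baseline + self.x) - self.w)
        if self.w_min is not None:
            np.clip(self.w, self.w_min, None, out=self.w)

    def reset_window(self) -> None:
        """Clear the eligibility window (e.g. at a phase boundary)."""
        self._ring[...] = 0
        self._counts[...] = 0
        self._head = 0

    def mean_weight(self) -> float:
        """Arithmetic mean of w over all (PC, PF) pairs."""
        return float(self.w.mean())

    def get_state(self) -> dict:
        return {
            "w": self.w.copy(),
            "x": self.x.copy(),
            "ring": self._ring.copy(),
            "counts": self._counts.copy(),
            "head": self._head,
        }

    def set_state(self, state: dict) -> None:
        self.w[...] = state["w"]
        self.x[...] = state["x"]
        self._ring[...] = state["ring"]
        self._counts[...] = state["counts"]
        self._head = int(state["head"])


def mean_pf_weight(state: PfPcPlasticity | np.ndarray) -> float:
    """Population-average PF-PC weight."""
    if isinstance(state, PfPcPlasticity):
        return state.mean_weight()
    return float(np.asarray(state).mean())


class MfVnPlasticity:
    """Simplified nuclear-weight dynamics ``tau_v dv/dt = w_c - w(t)``.

    ``w(t)`` is the population-average cortical weight; cortical LTD
    (w < w_c) drives nuclear LTP. v is clipped at 0.
    """

    def __init__(self, tau_v_ms: float, w_c: float = 1.0, v_init: float = 1.0, dt_ms: float = 1.0):
        self.tau_v_ms = float(tau_v_ms)
        self.w_c = float(w_c)
        self.v = float(v_init)
        self.dt_ms = float(dt_ms)

    def step(self, w_mean: float, dt_ms: float | None = None) -> float:
        dt = self.dt_ms if dt_ms is None else dt_ms
        self.v += dt * (self.w_c - w_mean) / self.tau_v_ms
        if self.v < 0.0:
            self.v = 0.0
        return self.v

    def get_state(self) -> dict:
        return {"v": self.v}

    def set_state(self, state: dict) -> None:
        self.v = float(state["v"])


class MfVnPlasticityFull:
    """Thresholded-Hebbian nuclear rule on windowed activity averages.

    Per completed averaging window (default 6 s, one stimulus cycle):

        tau_v dv/dt = -v <MF> + <MF (VN - theta)>

    with ``<.>`` the window average of the per-ms activities (spikes/s)
    and ``theta`` a running average of the VN activity across windows —
    the sliding LTP/LTD threshold: the synapse potentiates only when the
    VN is driven above its own recent history. Updates are applied in one
    Euler step per window (tumbling windows).
    """

    def __init__(
        self,
        tau_v_ms: float,
        window_ms: float = 6000.0,
        v_init: float = 1.0,
        theta_windows: int = 10,
        dt_ms: float = 1.0,
    ):
        self.tau_v_ms = float(tau_v_ms)
        self.window_ms = float(window_ms)
        self.v = float(v_init)
        self.dt_ms = float(dt_ms)
        self.theta: float | None = None
        # EMA factor: theta forgets over ~theta_windows windows
        self._theta_keep = float(np.exp(-1.0 / theta_windows))
        self._n = 0
        self._sum_mf = 0.0
        self._sum_vn = 0.0
        self._sum_mfvn = 0.0
        self._steps_per_window = int(round(self.window_ms / self.dt_ms))

    def accumulate(self, mf_rate: float, vn_rate: float) -> float:
        """Feed one dt of MF and VN activity (spikes/s); update v when a
        window completes. Returns the current v."""
        self._sum_mf += mf_rate
        self._sum_vn += vn_rate
        self._sum_mfvn += mf_rate * vn_rate
        self._n += 1
        if self._n >= self._steps_per_window:
            self._close_window()
        return self.v

    def _close_window(self) -> None:
        n = self._n
        m_mf = self._sum_mf / n
        m_vn = self._sum_vn / n
        m_mfvn = self._sum_mfvn / n
        if self.theta is None:
            self.theta = m_vn
        hebb = m_mfvn - self.theta * m_mf
        self.v += (self.window_ms / self.tau_v_ms) * (-self.v * m_mf + hebb)
        if self.v < 0.0:
            self.v = 0.0
        self.theta = self._theta_keep * self.theta + (1.0 - self._theta_keep) * m_vn
        self._n = 0
        self._sum_mf = self._sum_vn = self._sum_mfvn = 0.0
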