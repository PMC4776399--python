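"""Conductance-based leaky integrate-and-fire populations.

Membrane dynamics per neuron:

    C du/dt = -g_leak (u - E_leak) - g_AMPA(t) (u - E_ex)
              - g_NMDA(t) (u - E_ex) - g_GABA(t) (u - E_inh)
              - g_ahp(t) (u - E_ahp) + I_ext,

integrated by second-order Runge-Kutta (Heun) at dt = 1 ms with the
synaptic conductances held constant across the substeps of one step. The
NMDA conductance is voltage-independent (no Mg block). A spike is emitted
whenever u crosses theta_spike; repolarization is driven by the
after-hyperpolarization conductance, which is set to its peak on each
spike (saturating, not additive) and decays exponentially with tau_ahp.
An optional hard reset of u to E_leak after a spike is available for
robustness experiments.

Units: mV, pF, nS, pA internally (external currents are stored in nA and
converted); 1 nS x 1 mV = 1 pA, so du/dt in mV/ms = pA / pF.
"""

from __future__ import annotations

import numpy as np

from .params import CellParams


class NumericalBlowup(RuntimeError):
    """Raised when a membrane potential becomes non-finite."""


#: largest g*dt/C an RK2 substep may take (stability limit is 2.0)
_RK2_LAMBDA_MAX = 1.0


def rk2_membrane_step(u, g_total, drive, C, dt_ms):
    """One Heun step of the linear membrane ODE ``C du/dt = -g u + D``.

    ``g_total`` (nS) and ``drive`` (pA) are held constant over the step.
    When the step is stiff (``g*dt/C`` beyond the explicit stability
    region — e.g. Golgi cells under a strong parallel-fiber surge, whose
    summed conductance can reach hundreds of nS) the step is subdivided
    into equal RK2 substeps, still with conductances held constant; for
    the non-stiff case this is a plain single RK2 step.
    """
    lam = dt_ms * float(np.max(g_total)) / C
    n_sub = max(1, int(np.ceil(lam / _RK2_LAMBDA_MAX)))
    h = dt_ms / n_sub
    for _ in range(n_sub):
        k1 = (drive - g_total * u) / C
        u1 = u + h * k1
        k2 = (drive - g_total * u1) / C
        u = u + 0.5 * h * (k1 + k2)
    return u


class Population:
    """State and one-step dynamics of one cell type.

    Attributes
    ----------
    u : ndarray
        Membrane potentials (mV), initialized at E_leak.
    g_ahp : ndarray
        AHP conductance state (nS).
    spiked : ndarray of bool
        Spike flags of the most recent step.
    last_spike_ms : ndarray
        Time of each neuron's most recent spike (-inf before any).
    """

    def __init__(
        self,
        params: CellParams,
        n: int,
        dt_ms: float = 1.0,
        hard_reset: bool = False,
    ):
        self.params = params
        self.n = int(n)
        self.dt_ms = float(dt_ms)
        self.hard_reset = bool(hard_reset)
        self.u = np.full(self.n, params.E_leak, dtype=float)
        self.g_ahp = np.zeros(self.n)
        self.spiked = np.zeros(self.n, dtype=bool)
        self.last_spike_ms = np.full(self.n, -np.inf)
        self.spike_total = 0
        self._ahp_decay = float(np.exp(-self.dt_ms / params.tau_ahp))

    def decay_ahp(self) -> None:
        """Exponential AHP decay over one step (no spike handling)."""
        self.g_ahp *= self._ahp_decay

    def step(self, g_ampa=None, g_nmda=None, g_gaba=None, t_ms: float = 0.0) -> np.ndarray:
        """Advance one dt: AHP decay, RK2 membrane update, spike detection.

        Synaptic conductances are per-neuron arrays or scalars in nS
        (already scaled by the receptor peak conductance); ``None`` means
        the pathway is absent. Returns the boolean spike flags. On spike
        the AHP conductance is set to its peak; membrane potential is
        left to repolarize through the AHP unless ``hard_reset`` is
        enabled.
        """
        p = self.params
        self.decay_ahp()
        g_total = p.g_leak + self.g_ahp
        drive = p.g_leak * p.E_leak + self.g_ahp * p.E_ahp + p.I_ext_pA
        if g_ampa is not None:
            g_total = g_total + g_ampa
            if p.E_ex != 0.0:
                drive = drive + g_ampa * p.E_ex
        if g_nmda is not None:
            g_total = g_total + g_nmda
            if p.E_ex != 0.0:
                drive = drive + g_nmda * p.E_ex
        if g_gaba is not None:
            if p.g_inh is None:
                raise ValueError(f"{p.name} has no inhibitory pathway")
            g_total = g_total + g_gaba
            drive = drive + g_gaba * p.E_inh
        self.u = rk2_membrane_step(self.u, g_total, drive, p.C, self.dt_ms)
        spiked = self.u >= p.theta_spike
        self.spiked = spiked
        if spiked.any():
            self.g_ahp[spiked] = p.g_ahp
            self.last_spike_ms[spiked] = t_ms
            if self.hard_reset:
                self.u[spiked] = p.E_leak
            self.spike_total += int(spiked.sum())
        return spiked

    def check_finite(self) -> None:
        if not np.isfinite(self.u).all():
            raise NumericalBlowup(
                f"non-finite membrane potential in population {self.params.name}"
            )

    def get_state(self) -> dict:
        return {
            "u": self.u.copy(),
            "g_ahp": self.g_ahp.copy(),
            "spiked": self.spiked.copy(),
            "last_spike_ms": self.last_spike_ms.copy(),
            "spike_total": self.spike_total,
        }

    def set_state(self, state: dict) -> None:
        self.u[...] = state["u"]
        self.g_ahp[...] = state["g_ahp"]
        self.spiked[...] = state["spiked"]
        self.last_spike_ms[...] = state["last_spike_ms"]
        self.spike_total = int(state["spike_total"])
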