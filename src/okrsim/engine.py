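"""Simulation orchestration: per-step update loop and protocol execution.

Update order within one 1-ms step (fixed; the model has no transmission
delays, so a uniform one-step bookkeeping latency applies to all
*internal* pathways, while external Poisson inputs — mossy fibers and the
climbing fiber — act within their own step):

1. sample external inputs from the current phase's rate laws,
2. decay every conductance accumulator and inject this step's external
   spikes plus the previous step's internal spikes,
3. advance all membranes one second-order Runge-Kutta step,
4. detect threshold crossings (spikes) and engage the AHP,
5. apply plasticity updates (PF-PC eligibility rule, nuclear transfer),
6. record spikes and weight traces.

Probe phases freeze the plasticity state completely (impulses and
relaxation): under time compression a 60-s probe is comparable to the
compressed cortical relaxation constants, so a running clock during
measurement would erase the just-acquired learning — frozen probes are
measurement interludes that take zero time on the consolidation clock.

All randomness is drawn from named seeded streams (granule-cell mossy
fibers, climbing fiber, nuclear mossy-fiber pool), so identical
(config, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .analysis import GainMeasurement, measure_gain
from .network import Network, NetworkConfig, build
from .neurons import NumericalBlowup
from .params import ParameterSet
from .plasticity import MfVnPlasticity, PfPcPlasticity
from .stimulus import (
    Phase,
    Protocol,
    build_schedule,
    mf_training_law,
    cf_training_law,
    spike_probabilities,
)

_FINITE_CHECK_EVERY = 1024


@dataclass
class Results:
    """Bundle of recorded outputs of one simulation run."""

    gains: pd.DataFrame  # day, phase, amplitude, baseline, phase_offset
    weights: pd.DataFrame  # time_ms, mean_w, v
    vn_spikes: pd.DataFrame  # time_ms, population, neuron_index
    gr_spikes: pd.DataFrame  # subset spikes during probes (may be empty)
    spike_totals: dict
    manifest: dict

    def save(self, outdir: str) -> None:
        """Write delimited-text tables plus a JSON manifest."""
        os.makedirs(outdir, exist_ok=True)
        self.gains.to_csv(os.path.join(outdir, "gains.csv"), index=False)
        self.weights.to_csv(os.path.join(outdir, "weights.csv"), index=False)
        self.vn_spikes.to_csv(os.path.join(outdir, "spikes_VN.csv"), index=False)
        if len(self.gr_spikes):
            self.gr_spikes.to_csv(os.path.join(outdir, "spikes_GR.csv"), index=False)
        manifest = dict(self.manifest)
        manifest["spike_totals"] = {k: int(v) for k, v in self.spike_totals.items()}
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)


class Simulation:
    """One runnable instance: network + protocol/schedule + seeded streams.

    Parameters
    ----------
    network : Network
        Built network (any scale).
    protocol : Protocol
        Day schedule; its ``kappa`` also rescales the slow plasticity
        time constants (``tau_w``, ``tau_x``, ``tau_v``) — the plasticity
        rules are linear time-invariant filters, so compressing schedule
        and slow constants together preserves the weight trajectories
        against protocol phase.
    seed : int
        Master seed; per-purpose streams are spawned from it.
    schedule : list of Phase, optional
        Override the protocol-derived schedule (used for probe-only runs).
    plasticity_enabled : bool
        Master switch (False freezes both sites for control runs).
    record_gr_subset : int
        If > 0, record spikes of that many evenly spaced granule cells
        during probe phases (for reproducibility analysis).
    weight_stride_ms : float
        Sampling stride of the (mean_w, v) trace.
    """

    def __init__(
        self,
        network: Network,
        protocol: Protocol,
        seed: int,
        schedule: list[Phase] | None = None,
        plasticity_enabled: bool = True,
        record_gr_subset: int = 0,
        weight_stride_ms: float = 100.0,
    ):
        self.net = network
        self.protocol = protocol
        self.seed = int(seed)
        self.schedule = schedule if schedule is not None else build_schedule(protocol)
        self.plasticity_enabled = bool(plasticity_enabled)
        self.dt = protocol.dt_ms
        cfg = network.config
        if cfg.n_bs != cfg.n_pc:
            raise ValueError("engine pairs basket cells to Purkinje cells one-to-one")

        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        self.rng_mf = np.random.default_rng(kids[0])
        self.rng_cf = np.random.default_rng(kids[1])
        self.rng_vnpool = np.random.default_rng(kids[2])

        learn = network.params.learning
        kappa = protocol.kappa
        self.pfpc = PfPcPlasticity(
            n_pf=cfg.n_gr,
            n_pc=1,  # one shared climbing fiber => identical PC rows
            tau_w_ms=learn.tau_w_ms / kappa,
            tau_x_ms=learn.tau_x_ms / kappa,
            ltd_step=learn.ltd_step_per_coincidence,
            ltp_step=learn.ltp_step_per_spike,
            window_ms=learn.ltd_window_ms,
            dt_ms=self.dt,
            w_init=learn.w_init,
            x_init=learn.x_init,
        )
        self.mfvn = MfVnPlasticity(
            tau_v_ms=learn.tau_v_ms / kappa,
            w_c=learn.w_c,
            v_init=learn.v_init,
            dt_ms=self.dt,
        )

        from .synapses import ConductanceState, KernelSpec

        kern = network.params.kernels
        mk = lambda cell, rec, n: ConductanceState(
            KernelSpec.from_list(kern[cell][rec], rec), n, self.dt, validate=False
        )
        self.acc = {
            "GR_ampa": mk("GR", "ampa", cfg.n_gr),
            "GR_nmda": mk("GR", "nmda", cfg.n_gr),
            "GR_gaba": mk("GR", "gaba", cfg.n_clusters),  # cluster-shared
            "GO_ampa": mk("GO", "ampa", cfg.n_go),
            "GO_nmda": mk("GO", "nmda", cfg.n_go),
            "PC_ampa": mk("PC", "ampa", cfg.n_pc),
            "PC_gaba": mk("PC", "gaba", cfg.n_pc),
            "BS_ampa": mk("BS", "ampa", cfg.n_bs),
            "VN_ampa": mk("VN", "ampa", cfg.n_vn),
            "VN_nmda": mk("VN", "nmda", cfg.n_vn),
            "VN_gaba": mk("VN", "gaba", cfg.n_vn),
            "IO_ampa": mk("IO", "ampa", cfg.n_io),
        }

        # previous-step internal spikes (one-step synaptic latency)
        self._prev_gr_idx = np.empty(0, dtype=np.int64)
        self._prev_n_gr = 0
        self._prev_go_spiked = np.zeros(cfg.n_go, dtype=bool)
        self._prev_bs_spiked = np.zeros(cfg.n_bs, dtype=bool)
        self._prev_n_pc = 0

        # schedule cursor
        self.phase_idx = 0
        self.phase_step = 0
        self.t_step = 0

        # input block buffers
        self._buf: dict | None = None
        self._buf_pos = 0

        # recorders
        self.weight_stride = max(1, int(round(weight_stride_ms / self.dt)))
        self._weight_rows: list[tuple] = []
        self._vn_spike_times: list[float] = []
        self._gr_rows: list[tuple] = []  # (time_ms, cell_index)
        n_sub = min(record_gr_subset, cfg.n_gr)
        self.gr_subset = (
            np.unique(np.linspace(0, cfg.n_gr - 1, n_sub).astype(np.int64))
            if n_sub > 0
            else np.empty(0, dtype=np.int64)
        )

    # ------------------------------------------------------------------ #
    # stepping

    def _fill_buffer(self, phase: Phase, phase_len: int) -> None:
        cfg = self.net.config
        block = max(1, int(2_000_000 // max(cfg.n_gr, 1)))
        n = min(block, phase_len - self.phase_step)
        t_local = (self.phase_step + np.arange(n)) * self.dt
        p_mf = spike_probabilities(phase.mf_law, t_local, self.dt)
        p_cf = spike_probabilities(phase.cf_law, t_local, self.dt)
        p_mf_col = np.atleast_1d(p_mf)[:, None]
        # per-GR count of its n_mf private fibers firing this step:
        # Binomial(n_mf, p) drawn as summed Bernoulli fields (faster than
        # the generic binomial sampler for small n_mf)
        counts = np.zeros((n, cfg.n_gr))
        for _ in range(cfg.n_mf_per_gr):
            counts += self.rng_mf.random((n, cfg.n_gr)) < p_mf_col
        self._buf = {
            "mf_counts": counts,
            "cf": self.rng_cf.random(n) < np.atleast_1d(p_cf),
            "vn_pool": self.rng_vnpool.binomial(
                cfg.n_mf_vn_pool, np.atleast_1d(p_mf)
            ).astype(np.float64),
            "n": n,
        }
        self._buf_pos = 0

    def _step_one(self, phase: Phase) -> None:
        net, cfg, acc = self.net, self.net.config, self.acc
        w = net.weights
        pops = net.populations
        cells = net.params.cells
        i = self._buf_pos
        mf_counts = self._buf["mf_counts"][i]
        cf = bool(self._buf["cf"][i])
        vn_pool = self._buf["vn_pool"][i]
        t_ms = self.t_step * self.dt

        # --- synaptic accumulators (decay + inject) ---
        mf_gr = w["MF->GR"] * mf_counts
        acc["GR_ampa"].decay_and_inject(mf_gr)
        acc["GR_nmda"].decay_and_inject(mf_gr)
        go_counts = self._prev_go_spiked[net.go_afferents].sum(axis=1)
        acc["GR_gaba"].decay_and_inject(w["GO->GR"] * go_counts)

        gr_go = w["GR->GO"] * self._prev_n_gr
        acc["GO_ampa"].decay_and_inject(gr_go)
        acc["GO_nmda"].decay_and_inject(gr_go)

        pf_sum = self.pfpc.w[:, self._prev_gr_idx].sum(axis=1)
        pf_pc = w["GR->PC"] * (pf_sum[0] if pf_sum.shape[0] == 1 else pf_sum)
        acc["PC_ampa"].decay_and_inject(pf_pc + w["IO->PC"] * cf)
        acc["PC_gaba"].decay_and_inject(w["BS->PC"] * self._prev_bs_spiked.astype(float))

        acc["BS_ampa"].decay_and_inject(w["GR->BS"] * self._prev_n_gr)

        mf_vn = w["MF->VN"] * self.mfvn.v * vn_pool
        acc["VN_ampa"].decay_and_inject(mf_vn)
        acc["VN_nmda"].decay_and_inject(mf_vn)
        acc["VN_gaba"].decay_and_inject(w["PC->VN"] * self._prev_n_pc)

        acc["IO_ampa"].decay_and_inject(1.0 * cf)

        # --- membranes ---
        gr = pops["GR"]
        p = cells["GR"]
        gr.step(
            g_ampa=p.g_ampa * acc["GR_ampa"].total(),
            g_nmda=p.g_nmda * acc["GR_nmda"].total(),
            g_gaba=p.g_inh * acc["GR_gaba"].total()[net.cluster_of_gr],
            t_ms=t_ms,
        )
        go = pops["GO"]
        p = cells["GO"]
        go.step(
            g_ampa=p.g_ampa * acc["GO_ampa"].total(),
            g_nmda=p.g_nmda * acc["GO_nmda"].total(),
            t_ms=t_ms,
        )
        pc = pops["PC"]
        p = cells["PC"]
        pc.step(
            g_ampa=p.g_ampa * acc["PC_ampa"].total(),
            g_gaba=p.g_inh * acc["PC_gaba"].total(),
            t_ms=t_ms,
        )
        bs = pops["BS"]
        p = cells["BS"]
        bs.step(g_ampa=p.g_ampa * acc["BS_ampa"].total(), t_ms=t_ms)
        vn = pops["VN"]
        p = cells["VN"]
        vn.step(
            g_ampa=p.g_ampa * acc["VN_ampa"].total(),
            g_nmda=p.g_nmda * acc["VN_nmda"].total(),
            g_gaba=p.g_inh * acc["VN_gaba"].total(),
            t_ms=t_ms,
        )
        io = pops["IO"]
        p = cells["IO"]
        io.step(g_ampa=p.g_ampa * acc["IO_ampa"].total(), t_ms=t_ms)

        # --- plasticity ---
        plast_on = phase.plasticity_on and self.plasticity_enabled
        if plast_on:
            self.pfpc.step(gr.spiked, cf)
            self.mfvn.step(self.pfpc.mean_weight())

        # --- bookkeeping for next step's injections ---
        self._prev_gr_idx = np.flatnonzero(gr.spiked)
        self._prev_n_gr = self._prev_gr_idx.size
        self._prev_go_spiked = go.spiked
        self._prev_bs_spiked = bs.spiked
        self._prev_n_pc = int(pc.spiked.sum())

        # --- recording ---
        if self.t_step % self.weight_stride == 0:
            self._weight_rows.append((t_ms, self.pfpc.mean_weight(), self.mfvn.v))
        if phase.name in ("pre_probe", "post_probe"):
            if vn.spiked[0]:
                self._vn_spike_times.append(t_ms)
            if self.gr_subset.size:
                hit = np.flatnonzero(gr.spiked[self.gr_subset])
                for j in hit:
                    self._gr_rows.append((t_ms, int(self.gr_subset[j])))

        self._buf_pos += 1
        self.t_step += 1
        self.phase_step += 1
        if self.t_step % _FINITE_CHECK_EVERY == 0:
            self._check_finite()

    def _check_finite(self) -> None:
        for name, pop in self.net.populations.items():
            try:
                pop.check_finite()
            except NumericalBlowup as exc:
                raise NumericalBlowup(f"{exc} at step {self.t_step}") from exc

    def advance(self, n_steps: int) -> int:
        """Advance up to ``n_steps`` (stops at the end of the schedule)."""
        done = 0
        while done < n_steps and self.phase_idx < len(self.schedule):
            phase = self.schedule[self.phase_idx]
            phase_len = int(round(phase.duration_ms / self.dt))
            if self.phase_step == 0:
                self.pfpc.reset_window()
                self._buf = None
            if self._buf is None or self._buf_pos >= self._buf["n"]:
                self._fill_buffer(phase, phase_len)
            take = min(
                n_steps - done,
                self._buf["n"] - self._buf_pos,
                phase_len - self.phase_step,
            )
            for _ in range(take):
                self._step_one(phase)
            done += take
            if self.phase_step >= phase_len:
                self.phase_idx += 1
                self.phase_step = 0
                self._buf = None
        return done

    @property
    def total_steps(self) -> int:
        return int(round(sum(ph.duration_ms for ph in self.schedule) / self.dt))

    def run(self, progress: bool = False) -> Results:
        """Execute the full schedule and assemble the results bundle."""
        remaining = self.total_steps - self.t_step
        while remaining > 0:
            chunk = min(remaining, 100_000)
            stepped = self.advance(chunk)
            remaining -= stepped
            if stepped == 0:
                break
            if progress:
                ph = self.schedule[min(self.phase_idx, len(self.schedule) - 1)]
                print(
                    f"[okrsim] t={self.t_step * self.dt / 1000.0:.1f}s "
                    f"day {ph.day} {ph.name} mean_w={self.pfpc.mean_weight():.4f} "
                    f"v={self.mfvn.v:.4f}",
                    flush=True,
                )
        self._check_finite()
        return self._collect()

    run_protocol = run

    # ------------------------------------------------------------------ #
    # results

    def _collect(self) -> Results:
        vn_t = np.asarray(self._vn_spike_times)
        rows = []
        for ph in self.schedule:
            if ph.name not in ("pre_probe", "post_probe") or ph.n_cycles < 1:
                continue
            sel = vn_t[(vn_t >= ph.start_ms) & (vn_t < ph.end_ms)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                g = measure_gain(
                    sel,
                    n_cycles=ph.n_cycles,
                    period_s=self.protocol.period_s,
                    t0_ms=ph.start_ms,
                )
            rows.append(
                {
                    "day": ph.day,
                    "phase": "pre" if ph.name == "pre_probe" else "post",
                    "amplitude": g.amplitude,
                    "baseline": g.baseline,
                    "phase_offset": g.phase_offset,
                    "n_spikes": int(sel.size),
                }
            )
        gains = pd.DataFrame(rows, columns=["day", "phase", "amplitude", "baseline", "phase_offset", "n_spikes"])
        weights = pd.DataFrame(self._weight_rows, columns=["time_ms", "mean_w", "v"])
        vn_spikes = pd.DataFrame(
            {"time_ms": vn_t, "population": "VN", "neuron_index": 0}
        )
        gr_spikes = pd.DataFrame(self._gr_rows, columns=["time_ms", "neuron_index"])
        if len(gr_spikes):
            gr_spikes.insert(1, "population", "GR")
        manifest = {
            "package_version": _pkg_version,
            "seed": self.seed,
            "kappa": self.protocol.kappa,
            "n_days": self.protocol.n_days,
            "dt_ms": self.dt,
            "network": self.net.describe(),
            "plasticity_enabled": self.plasticity_enabled,
            "final_mean_w": self.pfpc.mean_weight(),
            "final_v": self.mfvn.v,
        }
        totals = {name: pop.spike_total for name, pop in self.net.populations.items()}
        return Results(gains, weights, vn_spikes, gr_spikes, totals, manifest)

    # ------------------------------------------------------------------ #
    # checkpointing

    def get_state(self) -> dict:
        """Full dynamic state (membranes, accumulators, plasticity, rng
        stream positions, cursor, input buffers, recorder buffers)."""
        return {
            "pops": {k: p.get_state() for k, p in self.net.populations.items()},
            "acc": {k: a.get_state() for k, a in self.acc.items()},
            "pfpc": self.pfpc.get_state(),
            "mfvn": self.mfvn.get_state(),
            "rng": {
                "mf": self.rng_mf.bit_generator.state,
                "cf": self.rng_cf.bit_generator.state,
                "vn": self.rng_vnpool.bit_generator.state,
            },
            "cursor": (self.phase_idx, self.phase_step, self.t_step),
            "prev": (
                self._prev_gr_idx.copy(),
                self._prev_n_gr,
                self._prev_go_spiked.copy(),
                self._prev_bs_spiked.copy(),
                self._prev_n_pc,
            ),
            "buf": None
            if self._buf is None
            else ({k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in self._buf.items()}, self._buf_pos),
            "recorders": (
                list(self._weight_rows),
                list(self._vn_spike_times),
                list(self._gr_rows),
            ),
        }

    def set_state(self, state: dict) -> None:
        for k, p in self.net.populations.items():
            p.set_state(state["pops"][k])
        for k, a in self.acc.items():
            a.set_state(state["acc"][k])
        self.pfpc.set_state(state["pfpc"])
        self.mfvn.set_state(state["mfvn"])
        self.rng_mf.bit_generator.state = state["rng"]["mf"]
        self.rng_cf.bit_generator.state = state["rng"]["cf"]
        self.rng_vnpool.bit_generator.state = state["rng"]["vn"]
        self.phase_idx, self.phase_step, self.t_step = state["cursor"]
        (
            self._prev_gr_idx,
            self._prev_n_gr,
            self._prev_go_spiked,
            self._prev_bs_spiked,
            self._prev_n_pc,
        ) = (
            state["prev"][0].copy(),
            state["prev"][1],
            state["prev"][2].copy(),
            state["prev"][3].copy(),
            state["prev"][4],
        )
        if state["buf"] is None:
            self._buf, self._buf_pos = None, 0
        else:
            buf, pos = state["buf"]
            self._buf = {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in buf.items()}
            self._buf_pos = pos
        wr, vt, gr = state["recorders"]
        self._weight_rows = list(wr)
        self._vn_spike_times = list(vt)
        self._gr_rows = list(gr)


def probe_run(
    network: Network,
    n_cycles: int,
    seed: int,
    record_gr_subset: int = 0,
    kappa: float = 1.0,
) -> Results:
    """Run only a probe (training stimulus, plasticity frozen) and measure.

    Used for baseline gain measurements and reproducibility analyses on
    an untrained (or externally prepared) network.
    """
    protocol = Protocol(n_days=1, probe_cycles=n_cycles, kappa=kappa)
    period_ms = protocol.period_s * 1000.0
    phase = Phase(
        name="pre_probe",
        day=1,
        start_ms=0,
        duration_ms=int(n_cycles * period_ms),
        mf_law=mf_training_law(),
        cf_law=cf_training_law(),
        plasticity_on=False,
        n_cycles=n_cycles,
    )
    sim = Simulation(
        network,
        protocol,
        seed,
        schedule=[phase],
        record_gr_subset=record_gr_subset,
    )
    return sim.run()
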