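"""Default parameter tables for the corticonuclear microcomplex model.

The defaults are shipped as a versioned YAML data file
(``okrsim/data/parameters.yaml``) holding, per cell type, the electrical
constants of the conductance-based integrate-and-fire unit, the synaptic
kernel shapes per receptor, the base weight of every pathway, and the
learning-rule constants. ``load_parameters`` returns them as plain
dataclasses; callers may override individual entries via nested dicts.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources

import yaml

CELL_TYPES = ("GR", "GO", "PC", "BS", "VN", "IO")


@dataclass(frozen=True)
class CellParams:
    """Electrical constants of one cell type (mV, pF, nS, nA, ms).

    ``None`` for a conductance peak means the cell type has no such
    pathway and the builder must not create one.
    """

    name: str
    theta_spike: float
    C: float
    g_leak: float
    E_leak: float
    g_ampa: float
    E_ex: float
    g_ahp: float
    E_ahp: float
    tau_ahp: float
    g_nmda: float | None = None
    g_inh: float | None = None
    E_inh: float | None = None
    I_ext: float | None = None

    @property
    def I_ext_pA(self) -> float:
        """External current in pA (stored in nA)."""
        return 0.0 if self.I_ext is None else self.I_ext * 1000.0


@dataclass(frozen=True)
class LearningParams:
    """Constants of the PF-PC and MF-VN plasticity rules.

    ``ltd_step_per_coincidence`` is the decrement of the internal LTD
    variable per (PF spike in the 50-ms window, CF spike) pair;
    ``ltp_step_per_spike`` is the increment per lone PF spike. The pair is
    chosen so that spontaneous rest input (CF at 1 spikes/s) leaves the
    cortical weight stationary in expectation:
    ``ltp_step = ltd_step * window * rest CF rate``.
    """

    tau_w_min: float = 20.0
    tau_x_min: float = 240.0
    ltd_step_per_coincidence: float = 0.1
    ltp_step_per_spike: float = 0.005
    ltd_window_ms: float = 50.0
    mfvn_window_s: float = 6.0
    w_init: float = 1.0
    x_init: float = 0.0
    v_init: float = 1.0
    w_c: float = 1.0
    tau_v_days: float = 3.0

    @property
    def tau_w_ms(self) -> float:
        return self.tau_w_min * 60_000.0

    @property
    def tau_x_ms(self) -> float:
        return self.tau_x_min * 60_000.0

    @property
    def tau_v_ms(self) -> float:
        return self.tau_v_days * 86_400_000.0


@dataclass
class ParameterSet:
    """Complete default parameter bundle."""

    cells: dict[str, CellParams]
    kernels: dict[str, dict[str, list[tuple[float, float]]]]
    weights: dict[str, float]
    learning: LearningParams
    schema_version: int = 1


def _deep_update(base: dict, overrides: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in overrides.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def _raw_defaults() -> dict:
    text = resources.files("okrsim.data").joinpath("parameters.yaml").read_text()
    return yaml.safe_load(text)


def load_parameters(overrides: dict | None = None) -> ParameterSet:
    """Load the default parameter set, optionally overriding entries.

    Parameters
    ----------
    overrides
        Nested dict mirroring the YAML structure, e.g.
        ``{"cells": {"VN": {"I_ext": 0.9}}, "weights": {"MF->VN": 0.1}}``.
    """
    raw = _raw_defaults()
    if overrides:
        raw = _deep_update(raw, overrides)
    cells = {
        name: CellParams(name=name, **vals) for name, vals in raw["cells"].items()
    }
    kernels = {
        name: {rec: [tuple(map(float, c)) for c in comps] for rec, comps in recs.items()}
        for name, recs in raw["kernels"].items()
    }
    learn_raw = dict(raw["learning"])
    learning = LearningParams(**learn_raw)
    return ParameterSet(
        cells=cells,
        kernels=kernels,
        weights={k: float(v) for k, v in raw["weights"].items()},
        learning=learning,
        schema_version=int(raw.get("schema_version", 1)),
    )
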