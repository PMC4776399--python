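"""YAML run configuration: scale, protocol, compression, seeds, overrides.

A run config is a small YAML document, e.g.::

    network:
      gr_side: 64          # 64x64 granule cells (cluster side inferred)
      scale_compensation: true
    protocol:
      n_days: 5
      kappa: 600
      probe_cycles: 10
    seed: 1
    record_gr_subset: 0
    parameter_overrides: {}   # nested, mirrors parameters.yaml

Anything omitted falls back to the defaults of the corresponding
dataclass; ``network.gr_side`` omitted means the full 1024x1024 scale.
"""

from __future__ import annotations

import yaml

from .network import Network, NetworkConfig
from .params import load_parameters
from .stimulus import Protocol


def default_config() -> dict:
    return {
        "network": {"gr_side": 64, "scale_compensation": True},
        "protocol": {"n_days": 5, "kappa": 600.0, "probe_cycles": 10},
        "seed": 1,
        "record_gr_subset": 0,
        "weight_stride_ms": 100.0,
        "parameter_overrides": {},
    }


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = default_config()
    for key, val in cfg.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def save_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def network_from_config(cfg: dict) -> Network:
    net_cfg = dict(cfg.get("network", {}))
    gr_side = net_cfg.pop("gr_side", None)
    cluster_side = net_cfg.pop("cluster_side", None)
    params = load_parameters(cfg.get("parameter_overrides") or None)
    if gr_side is None:
        config = NetworkConfig(**net_cfg)
    else:
        config = NetworkConfig.reduced(gr_side, cluster_side, **net_cfg)
    return Network(config, params, seed=cfg.get("seed"))


def protocol_from_config(cfg: dict) -> Protocol:
    return Protocol(**cfg.get("protocol", {}))
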