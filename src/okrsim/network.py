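"""Construction of the corticonuclear network at full or reduced scale.

The reference circuit models 1 mm^3 of cerebellar cortex plus its target
nucleus: 1,048,576 granule cells (GR, a 1024x1024 grid), 1024 Golgi cells
(GO, 32x32), 16 Purkinje cells (PC), 16 basket cells (BS), one inferior
olive neuron (IO) and one vestibular nucleus neuron (VN). Granule cells
are partitioned into clusters aligned with the GO grid; all GRs of a
cluster share the same Golgi afferents (short dendrites), while each GR
receives its own 4 private mossy-fiber trains. Parallel fibers (GR axons)
contact every GO, PC and BS (full fan-in). The single climbing fiber
drives all PCs; all PCs inhibit the VN; a configurable mossy-fiber pool
excites the VN directly.

At reduced granule-cell counts, optional scale compensation multiplies
the GR-outgoing weights by (1,048,576 / N) so the expected summed
parallel-fiber drive onto each target is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .neurons import Population
from .params import ParameterSet, load_parameters

FULL_GR_COUNT = 1024 * 1024
PF_CONDUCTION_VELOCITY_M_S = 0.24


@dataclass(frozen=True)
class NetworkConfig:
    """Geometry, counts and weight options of one network instance.

    The GR grid must factor exactly as (GO grid) x (cluster size),
    element-wise. ``go_neighborhood`` is the number of Golgi afferents per
    granule-cell cluster (the cluster's own GO plus its nearest toroidal
    neighbors on the GO grid).
    """

    gr_grid: tuple[int, int] = (1024, 1024)
    go_grid: tuple[int, int] = (32, 32)
    cluster_size: tuple[int, int] = (32, 32)
    n_pc: int = 16
    n_bs: int = 16
    n_vn: int = 1
    n_io: int = 1
    n_mf_per_gr: int = 4
    n_mf_vn_pool: int = 100
    go_neighborhood: int = 1
    scale_compensation: bool = True
    hard_reset: bool = True
    weight_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        gr, go, cl = self.gr_grid, self.go_grid, self.cluster_size
        if any(v < 1 for v in (*gr, *go, *cl)):
            raise ValueError("grid dimensions must be >= 1")
        if gr[0] != go[0] * cl[0] or gr[1] != go[1] * cl[1]:
            raise ValueError(
                f"gr_grid {gr} must equal go_grid {go} x cluster_size {cl} element-wise"
            )
        for name in ("n_pc", "n_bs", "n_vn", "n_io", "n_mf_per_gr", "n_mf_vn_pool"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 1 <= self.go_neighborhood <= go[0] * go[1]:
            raise ValueError("go_neighborhood out of range")

    @property
    def n_gr(self) -> int:
        return self.gr_grid[0] * self.gr_grid[1]

    @property
    def n_go(self) -> int:
        return self.go_grid[0] * self.go_grid[1]

    @property
    def n_clusters(self) -> int:
        # clusters are in 1:1 registration with the GO grid
        return self.n_go

    @classmethod
    def reduced(cls, gr_side: int, cluster_side: int | None = None, **kw) -> "NetworkConfig":
        """Square reduced-scale config with ``gr_side x gr_side`` GRs.

        The cluster side defaults to ``min(32, gr_side)`` capped so that at
        least 4 clusters exist where possible. Unless given explicitly,
        the VN mossy-fiber pool is set from the per-scale calibration
        (:func:`vn_pool_for_scale`).
        """
        if cluster_side is None:
            cluster_side = min(32, gr_side)
            while cluster_side > 1 and (gr_side // cluster_side) < 2:
                cluster_side //= 2
        if gr_side % cluster_side:
            raise ValueError("cluster side must divide the GR side")
        go_side = gr_side // cluster_side
        kw.setdefault("n_mf_vn_pool", vn_pool_for_scale(gr_side * gr_side))
        return cls(
            gr_grid=(gr_side, gr_side),
            go_grid=(go_side, go_side),
            cluster_size=(cluster_side, cluster_side),
            **kw,
        )


#: Calibrated VN mossy-fiber pool sizes per granule-cell count. The VN
#: fan-in is the model's one free structural parameter (anatomically
#: unconstrained here); it is calibrated so that the pretraining VN
#: baseline rate sits in its physiological 30-50 spikes/s operating
#: range. The required pool shifts with network scale because the
#: granular-layer operating point (hence Purkinje rate, hence VN
#: inhibition) is not fully scale-invariant.
_VN_POOL_ANCHORS = {4096: 78, 16384: 44}


def vn_pool_for_scale(n_gr: int) -> int:
    """VN mossy-fiber pool size for a given granule-cell count.

    Log-linear interpolation between the calibrated anchors in
    :data:`_VN_POOL_ANCHORS`, clamped to the nearest anchor outside the
    calibrated range.
    """
    if n_gr <= 0:
        raise ValueError("n_gr must be positive")
    pts = sorted(_VN_POOL_ANCHORS.items())
    x = np.log2(float(n_gr))
    xs = [np.log2(float(k)) for k, _ in pts]
    ys = [float(v) for _, v in pts]
    return int(round(float(np.interp(x, xs, ys))))


#: pathways rescaled by default when compensating a reduced GR count.
#: The feedforward parallel-fiber readouts (PC, BS) are compensated so
#: their expected summed drive is scale-invariant; the recurrent GR->GO
#: loop is not: multiplying per-spike Golgi drive by the compensation
#: factor quantizes the loop input so coarsely that a single granule-cell
#: spike keeps every Golgi cell tonically primed (3-mV threshold gap,
#: 170-ms NMDA tail) and the granular layer locks silent. The loop's
#: operating point is set by its stability boundary, not its mean drive,
#: so the recurrent weight is left at its full-scale value.
SCALE_COMPENSATED_PATHWAYS = ("GR->PC", "GR->BS")


def scale_compensate(
    config: NetworkConfig,
    weights: dict[str, float],
    pathways: tuple[str, ...] = SCALE_COMPENSATED_PATHWAYS,
) -> dict[str, float]:
    """Rescale GR-outgoing weights for a reduced granule-cell count.

    Multiplies the listed pathways by (full count / N) so the expected
    summed parallel-fiber conductance onto each target at a fixed per-GR
    rate matches the full-scale network. See
    :data:`SCALE_COMPENSATED_PATHWAYS` for why the recurrent GR->GO
    pathway is excluded by default (pass it explicitly to include it).
    """
    n = config.n_gr
    if n == 0:
        raise ValueError("empty granule-cell population")
    factor = FULL_GR_COUNT / n
    out = dict(weights)
    for key in pathways:
        out[key] = out[key] * factor
    return out


def pf_delay_estimate(length_mm: float, velocity_m_s: float = PF_CONDUCTION_VELOCITY_M_S) -> float:
    """Parallel-fiber conduction delay in ms, rounded to one decimal.

    With the measured PF conduction velocity of 0.24 m/s a 1-mm fiber
    accrues at most ~4.2 ms — small against the 50-ms LTD eligibility
    window, which is why the model omits transmission delays. This helper
    only documents that choice.
    """
    if length_mm < 0:
        raise ValueError("length must be >= 0")
    if velocity_m_s <= 0:
        raise ValueError("velocity must be > 0")
    return round(length_mm / velocity_m_s, 1)


def _cluster_map(config: NetworkConfig) -> np.ndarray:
    """Row-major GR index -> cluster index (0-based)."""
    rows, cols = config.gr_grid
    crows, ccols = config.cluster_size
    r = np.arange(rows)[:, None] // crows
    c = np.arange(cols)[None, :] // ccols
    return (r * config.go_grid[1] + c).ravel().astype(np.int64)


def _go_afferents(config: NetworkConfig) -> np.ndarray:
    """Per-cluster Golgi afferent lists, shape (n_clusters, go_neighborhood).

    Each cluster is inhibited by the GO at its own grid position plus its
    nearest neighbors under toroidal distance on the GO grid; ties are
    broken by (row offset, column offset) lexicographic order so the
    wiring is deterministic.
    """
    grows, gcols = config.go_grid
    k = config.go_neighborhood
    # candidate offsets sorted by toroidal distance then lexicographically
    offs = [
        (dr, dc)
        for dr in range(-(grows // 2), (grows + 1) // 2)
        for dc in range(-(gcols // 2), (gcols + 1) // 2)
    ]
    offs.sort(key=lambda o: (o[0] * o[0] + o[1] * o[1], o[0], o[1]))
    offs = np.array(offs[:k])
    rr = np.arange(grows)[:, None]
    cc = np.arange(gcols)[None, :]
    aff = np.empty((grows, gcols, k), dtype=np.int64)
    for i, (dr, dc) in enumerate(offs):
        aff[:, :, i] = ((rr + dr) % grows) * gcols + (cc + dc) % gcols
    return aff.reshape(config.n_clusters, k)


class Network:
    """Populations plus structured wiring of one microcomplex instance.

    Wiring is deterministic given the config (the seed is retained in the
    manifest for provenance; all run-time randomness lives in the input
    spike trains, not the anatomy).
    """

    def __init__(self, config: NetworkConfig, params: ParameterSet, seed: int | None = None):
        self.config = config
        self.params = params
        self.seed = seed
        dt = 1.0
        hr = config.hard_reset
        self.populations: dict[str, Population] = {
            "GR": Population(params.cells["GR"], config.n_gr, dt, hr),
            "GO": Population(params.cells["GO"], config.n_go, dt, hr),
            "PC": Population(params.cells["PC"], config.n_pc, dt, hr),
            "BS": Population(params.cells["BS"], config.n_bs, dt, hr),
            "VN": Population(params.cells["VN"], config.n_vn, dt, hr),
            "IO": Population(params.cells["IO"], config.n_io, dt, hr),
        }
        self.cluster_of_gr = _cluster_map(config)
        self.go_afferents = _go_afferents(config)
        weights = dict(params.weights)
        weights.update(config.weight_overrides)
        if config.scale_compensation:
            weights = scale_compensate(config, weights)
        self.weights = weights

    @property
    def counts(self) -> dict[str, int]:
        return {name: pop.n for name, pop in self.populations.items()}

    def describe(self) -> dict:
        """Structured description (counts, grids, weights) for provenance."""
        c = self.config
        return {
            "counts": self.counts,
            "gr_grid": list(c.gr_grid),
            "go_grid": list(c.go_grid),
            "cluster_size": list(c.cluster_size),
            "n_mf_per_gr": c.n_mf_per_gr,
            "n_mf_vn_pool": c.n_mf_vn_pool,
            "go_neighborhood": c.go_neighborhood,
            "scale_compensation": c.scale_compensation,
            "hard_reset": c.hard_reset,
            "weights": {k: float(v) for k, v in self.weights.items()},
            "seed": self.seed,
        }


def build(
    config: NetworkConfig | None = None,
    seed: int | None = None,
    params: ParameterSet | None = None,
) -> Network:
    """Build a network at the configured scale (defaults: full scale)."""
    config = config or NetworkConfig()
    params = params or load_parameters()
    return Network(config, params, seed)
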