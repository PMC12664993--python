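"""Global gating statistics: per-subunit ECD twist and β-expansion.

The ECD twist of one subunit is the dihedral angle among four Cα centers of
mass: (a) the subunit's ECD, (b) the ECD of all five subunits, (c) the TMD
of all five subunits, (d) the subunit's TMD. β-expansion is the distance
between the subunit's β1 and β10 Cα centers of mass. Both are invariant
under rigid motion of the whole frame, so no pre-alignment is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import center_of_mass, dihedral
from .model_io import DomainScheme, StructureModel, Trajectory, select

__all__ = ["MetricSeries", "MetricSummary", "ecd_twist", "beta_expansion", "summarize",
           "trajectory_metric_table"]


@dataclass
class MetricSeries:
    """Per-(replicate, frame, chain) scalar values of one named metric."""

    metric_name: str
    units: str  # "degrees" or "A"
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["replicate", "time_ns", "chain", "value"]))

    def __post_init__(self) -> None:
        vals = self.table["value"].to_numpy(dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("metric series must contain finite values only")

    @property
    def values(self) -> np.ndarray:
        return self.table["value"].to_numpy(dtype=float)


@dataclass
class MetricSummary:
    """Pooled median and extrema; ``range`` is max − min exactly."""

    metric_name: str
    units: str
    median: float
    min: float
    max: float
    n: int

    @property
    def range(self) -> float:
        return self.max - self.min


def _block_com(model: StructureModel, chain: str, rng: tuple[int, int],
               coverage_floor: float = 0.8) -> np.ndarray | None:
    sel = select(model, chain, rng, atom_filter="ca_only", coverage_floor=coverage_floor)
    if len(sel) == 0:
        return None
    return center_of_mass(model.xyz[sel.indices])


def ecd_twist(model: StructureModel, scheme: DomainScheme | None = None,
              coverage_floor: float = 0.8) -> dict[str, float]:
    """Per-chain ECD twist in degrees.

    Returns a mapping chain id → twist; a chain whose ECD or TMD block falls
    below the coverage floor maps to NaN rather than raising.
    """
    scheme = scheme or DomainScheme()
    model.require_pentamer()
    chains = model.assembly_chains
    ecd_coms = {c: _block_com(model, c, scheme.ecd_twist, coverage_floor) for c in chains}
    tmd_coms = {c: _block_com(model, c, scheme.tmd_twist, coverage_floor) for c in chains}
    # "all subunits" = full-pentamer Cα COM, including the chain under evaluation
    ecd_all_pts = [
        model.xyz[select(model, c, scheme.ecd_twist, "ca_only", coverage_floor).indices]
        for c in chains if ecd_coms[c] is not None
    ]
    tmd_all_pts = [
        model.xyz[select(model, c, scheme.tmd_twist, "ca_only", coverage_floor).indices]
        for c in chains if tmd_coms[c] is not None
    ]
    if not ecd_all_pts or not tmd_all_pts:
        return {c: math.nan for c in chains}
    ecd_all = center_of_mass(np.vstack(ecd_all_pts))
    tmd_all = center_of_mass(np.vstack(tmd_all_pts))
    out: dict[str, float] = {}
    for c in chains:
        if ecd_coms[c] is None or tmd_coms[c] is None:
            out[c] = math.nan
            continue
        out[c] = dihedral(ecd_coms[c], ecd_all, tmd_all, tmd_coms[c])
    return out


def beta_expansion(model: StructureModel, scheme: DomainScheme | None = None,
                   coverage_floor: float = 0.8) -> dict[str, float]:
    """Per-chain β1–β10 Cα COM distance in Å (NaN on coverage failure)."""
    scheme = scheme or DomainScheme()
    model.require_pentamer()
    out: dict[str, float] = {}
    for c in model.assembly_chains:
        com1 = _block_com(model, c, scheme.beta1, coverage_floor)
        com10 = _block_com(model, c, scheme.beta10, coverage_floor)
        if com1 is None or com10 is None:
            out[c] = math.nan
        else:
            out[c] = float(np.linalg.norm(com10 - com1))
    return out


_METRIC_FUNCS = {"ecd_twist": (ecd_twist, "degrees"), "beta_expansion": (beta_expansion, "A")}


def trajectory_metric_table(trajs: Trajectory | list[Trajectory], metric: str,
                            scheme: DomainScheme | None = None) -> MetricSeries:
    """Evaluate ``ecd_twist`` or ``beta_expansion`` over every frame of one or
    more replicate trajectories, as a long-format :class:`MetricSeries`."""
    if metric not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_FUNCS)}")
    func, units = _METRIC_FUNCS[metric]
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    rows = []
    for traj in trajs:
        for i in range(traj.n_frames):
            per_chain = func(traj.frame_model(i), scheme)
            for chain, val in per_chain.items():
                if math.isfinite(val):
                    rows.append((traj.replicate_id, traj.times[i], chain, val))
    table = pd.DataFrame(rows, columns=["replicate", "time_ns", "chain", "value"])
    return MetricSeries(metric_name=metric, units=units, table=table)


def summarize(series: MetricSeries, pool_by: list[str] | None = None
              ) -> MetricSummary | dict[tuple, MetricSummary]:
    """Median/min/max/range over pooled values.

    With ``pool_by=None`` everything (all chains, frames, replicates) is
    pooled into one summary — the single-number-per-condition convention.
    Otherwise one summary per group key (e.g. ``["replicate"]``).
    """
    if len(series.table) == 0:
        raise ValueError("cannot summarize an empty metric series")

    def _one(vals: np.ndarray) -> MetricSummary:
        return MetricSummary(
            metric_name=series.metric_name, units=series.units,
            median=float(np.median(vals)), min=float(vals.min()),
            max=float(vals.max()), n=len(vals),
        )

    if not pool_by:
        return _one(series.values)
    out = {}
    for key, grp in series.table.groupby(pool_by):
        out[key if isinstance(key, tuple) else (key,)] = _one(grp["value"].to_numpy(dtype=float))
    return out
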