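"""NTD lobe rigid-body tracking through TMD-aligned trajectories.

Frames are first superposed on the reference's TMD Cα atoms, removing
whole-channel drift; each lobe's Cα COM is then followed per frame, giving a
displacement from its frame-0 position ("initial pose") plus a (radial, z)
decomposition relative to the fixed pore axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gating import MetricSeries, MetricSummary, summarize
from .geometry import PoreAxis, center_of_mass, estimate_axis, superpose
from .model_io import DomainScheme, StructureModel, Trajectory, select

__all__ = ["LobeTrace", "align_trajectory", "pore_axis_from_model", "lobe_trace",
           "displacement_summary"]


@dataclass
class LobeTrace:
    """Per-frame COM track of one NTD lobe of one chain (post-alignment)."""

    chain: str
    lobe: str  # "NTD1" or "NTD2"
    replicate_id: str
    times: np.ndarray  # ns
    com: np.ndarray  # (F, 3) Å
    displacement: np.ndarray  # (F,) Å from frame-0 COM
    radial: np.ndarray  # (F,) Å from pore axis
    z: np.ndarray  # (F,) Å along axis
    flagged: bool = False

    @property
    def start(self) -> tuple[float, float]:
        """Starting (radial, z) position, the 'black bead' of a trace plot."""
        return float(self.radial[0]), float(self.z[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": self.replicate_id, "time_ns": self.times,
            "chain": self.chain, "lobe": self.lobe,
            "displacement": self.displacement, "radial": self.radial, "z": self.z,
        })


def align_trajectory(traj: Trajectory, reference: StructureModel,
                     scheme: DomainScheme | None = None) -> Trajectory:
    """Superpose every frame onto the reference's TMD Cα set.

    The alignment selection (default residues 328–639) must resolve to the
    same residue correspondence in topology and reference.
    """
    scheme = scheme or DomainScheme()
    ref_sels = {}
    top_sels = {}
    for chain in reference.assembly_chains:
        ref_sels[chain] = select(reference, chain, scheme.tmd_align, "ca_only")
        top_sels[chain] = select(traj.topology, chain, scheme.tmd_align, "ca_only")
        ref_res = reference.res_seq[ref_sels[chain].indices]
        top_res = traj.topology.res_seq[top_sels[chain].indices]
        if len(ref_res) != len(top_res) or not np.array_equal(ref_res, top_res):
            raise ValueError(
                f"alignment correspondence mismatch on chain {chain}: "
                f"reference resolves {len(ref_res)} Cα, topology {len(top_res)}"
            )
    ref_idx = np.concatenate([ref_sels[c].indices for c in reference.assembly_chains])
    top_idx = np.concatenate([top_sels[c].indices for c in reference.assembly_chains])
    ref_xyz = reference.xyz[ref_idx]
    aligned = np.empty_like(traj.frames)
    for i in range(traj.n_frames):
        transform, _ = superpose(traj.frames[i][top_idx], ref_xyz)
        aligned[i] = transform.apply(traj.frames[i])
    return Trajectory(topology=traj.topology, frames=aligned, times=traj.times,
                      replicate_id=traj.replicate_id)


def pore_axis_from_model(model: StructureModel, scheme: DomainScheme | None = None) -> PoreAxis:
    """C5 pore axis of a pentamer from its TMD Cα ring, oriented toward the NTD."""
    scheme = scheme or DomainScheme()
    model.require_pentamer()
    idx, chains = [], []
    for chain in model.assembly_chains:
        sel = select(model, chain, scheme.tmd_twist, "ca_only")
        idx.append(sel.indices)
        chains.extend([chain] * len(sel))
    coords = model.xyz[np.concatenate(idx)]
    ntd_idx = []
    for chain in model.assembly_chains:
        sel = select(model, chain, scheme.ntd_track, "ca_only")
        if len(sel):
            ntd_idx.append(sel.indices)
    toward = center_of_mass(model.xyz[np.concatenate(ntd_idx)]) if ntd_idx else None
    return estimate_axis(coords, np.array(chains), toward=toward)


def lobe_trace(aligned: Trajectory, chain: str, lobe: str,
               lobe_range: tuple[int, int], axis: PoreAxis,
               coverage_floor: float = 0.8) -> LobeTrace:
    """Track one lobe's Cα COM through an aligned trajectory.

    Displacement is measured from the frame-0 COM (the initial pose after
    alignment), not from any deposited model.
    """
    sel = select(aligned.topology, chain, lobe_range, "ca_only", coverage_floor)
    if len(sel) == 0:
        raise ValueError(f"lobe range {lobe_range} resolves no Cα on chain {chain}")
    coms = np.array([center_of_mass(aligned.frames[i][sel.indices])
                     for i in range(aligned.n_frames)])
    displacement = np.linalg.norm(coms - coms[0], axis=1)
    radial, z = axis.decompose(coms)
    return LobeTrace(chain=chain, lobe=lobe, replicate_id=aligned.replicate_id,
                     times=aligned.times, com=coms, displacement=displacement,
                     radial=radial, z=z, flagged=sel.flagged)


def displacement_summary(traces: list[LobeTrace]) -> dict[str, MetricSummary]:
    """Pooled COM-displacement summary per lobe, across chains, frames and
    replicates (the raincloud statistic: single-point COM RMSD equals its
    displacement magnitude)."""
    if not traces:
        raise ValueError("no traces to summarize")
    out: dict[str, MetricSummary] = {}
    for lobe in sorted({t.lobe for t in traces}):
        rows = []
        for t in traces:
            if t.lobe != lobe:
                continue
            rows.append(pd.DataFrame({
                "replicate": t.replicate_id, "time_ns": t.times,
                "chain": t.chain, "value": t.displacement,
            }))
        series = MetricSeries(metric_name=f"{lobe}_com_displacement", units="A",
                              table=pd.concat(rows, ignore_index=True))
        out[lobe] = summarize(series)
    return out
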