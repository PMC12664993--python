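"""Pipeline orchestration: run the full analysis on a model or trajectories
and write a reproducible report bundle (tabular files + JSON summary).

Every run writes its resolved configuration next to its outputs, and the
JSON summary records the package version plus input checksums, so a
replication run is auditable. Condition labels are free strings carried
verbatim to every output row.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gating import summarize, trajectory_metric_table
from .ions import (DEFAULT_SITE_DEFINITIONS, classify_sites, coordination_shell,
                   find_ions, max_coordination_distance, residence,
                   residence_summary)
from .model_io import DomainScheme, StructureModel, Trajectory
from .pore import PoreProfile, annotate_primes, pore_radius_profile, profile_stats
from .tracking import (align_trajectory, displacement_summary, lobe_trace,
                       pore_axis_from_model)

__all__ = ["RunConfig", "run_structure_analysis", "run_trajectory_analysis"]


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    output_dir: str | Path
    condition: str = "custom"  # e.g. with_calcium / no_calcium_sym / no_calcium_asym
    scheme: DomainScheme = field(default_factory=DomainScheme)
    seed: int = 0
    metrics: tuple[str, ...] = ("twist", "expansion", "pore", "ions")
    ion_cutoff: float = 3.5
    residence_threshold: float = 5.0
    input_paths: tuple[str, ...] = ()

    def resolved(self) -> dict:
        return {
            "condition": self.condition,
            "seed": self.seed,
            "metrics": list(self.metrics),
            "ion_cutoff": self.ion_cutoff,
            "residence_threshold": self.residence_threshold,
            "input_paths": list(self.input_paths),
            "scheme": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in vars(self.scheme).items()
            },
            "version": __version__,
        }


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()[:16]


def _write_sidecar(config: RunConfig, outdir: Path, extra: dict) -> None:
    payload = config.resolved()
    payload["inputs_sha256"] = {str(p): _checksum(p) for p in config.input_paths
                                if Path(p).exists()}
    payload.update(extra)
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_structure_analysis(model: StructureModel, config: RunConfig) -> dict:
    """Per-chain twist/expansion, pore profile with prime annotations and
    per-ion coordination tables for a single model."""
    from .gating import beta_expansion, ecd_twist

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    model.require_pentamer()
    scheme = config.scheme
    summary: dict = {"condition": config.condition}

    rows = []
    if "twist" in config.metrics:
        for chain, val in ecd_twist(model, scheme).items():
            rows.append((config.condition, chain, "ecd_twist", val, "degrees"))
    if "expansion" in config.metrics:
        for chain, val in beta_expansion(model, scheme).items():
            rows.append((config.condition, chain, "beta_expansion", val, "A"))
    metrics = pd.DataFrame(rows, columns=["condition", "chain", "metric", "value", "units"])
    metrics.to_csv(outdir / "structure_metrics.tsv", sep="\t", index=False)
    for metric in metrics["metric"].unique():
        vals = metrics.loc[metrics.metric == metric, "value"].to_numpy(dtype=float)
        summary[metric] = {"mean": float(np.nanmean(vals)),
                           "per_chain": [float(v) for v in vals]}

    if "pore" in config.metrics:
        axis = pore_axis_from_model(model, scheme)
        profile = pore_radius_profile(model, axis, scheme=scheme)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile = annotate_primes(profile, scheme, model, axis)
        profile.to_frame().to_csv(outdir / "pore_profile.tsv", sep="\t", index=False)
        summary["pore"] = {
            "min_radius": float(profile.radius.min()),
            "primes": {lab: {"z": z, "radius": profile.radius_at(z)}
                       for lab, z in profile.annotations.items()},
        }

    if "ions" in config.metrics:
        ions = find_ions(model)
        contacts = {ion: coordination_shell(model, ion, cutoff=config.ion_cutoff)
                    for ion in ions}
        labels = classify_sites(contacts, DEFAULT_SITE_DEFINITIONS)
        ion_rows = []
        for ion, cset in contacts.items():
            for c in cset:
                ion_rows.append((config.condition, ion, labels[ion], c.chain, c.res_seq,
                                 c.res_name, c.atom_name, c.partner_class, c.distance))
        pd.DataFrame(ion_rows, columns=[
            "condition", "ion_id", "site", "chain", "res_seq", "res_name",
            "atom_name", "partner_class", "distance"]
        ).to_csv(outdir / "ion_contacts.tsv", sep="\t", index=False)
        per_site: dict[str, list[float]] = {}
        for ion, cset in contacts.items():
            if cset and not labels[ion].startswith("unassigned"):
                per_site.setdefault(labels[ion], []).append(
                    max_coordination_distance(cset))
        summary["ion_sites"] = {
            "n_ions": len(ions),
            "assignments": labels,
            "max_distance_per_site": {k: max(v) for k, v in sorted(per_site.items())},
        }
        if not ions:
            summary["ion_sites"]["notice"] = "no ions present in model"

    _write_sidecar(config, outdir, {"mode": "structure"})
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_trajectory_analysis(trajs: list[Trajectory], reference: StructureModel,
                            config: RunConfig) -> dict:
    """Aligned-trajectory pipeline: gating metrics per frame, lobe traces,
    pooled summaries, pore-profile statistics and ion residence."""
    if not trajs:
        raise ValueError("at least one replicate trajectory required")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = config.scheme
    reference.require_pentamer()
    aligned = [align_trajectory(t, reference, scheme) for t in trajs]
    axis = pore_axis_from_model(reference, scheme)
    summary: dict = {"condition": config.condition,
                     "n_replicates": len(trajs),
                     "n_frames": [t.n_frames for t in trajs]}

    tables = []
    for metric in ("ecd_twist", "beta_expansion"):
        toggle = "twist" if metric == "ecd_twist" else "expansion"
        if toggle not in config.metrics:
            continue
        series = trajectory_metric_table(aligned, metric, scheme)
        tab = series.table.copy()
        tab.insert(0, "condition", config.condition)
        tab["metric"] = metric
        tab["units"] = series.units
        tables.append(tab)
        pooled = summarize(series)
        per_rep = summarize(series, pool_by=["replicate"])
        summary[metric] = {
            "median": pooled.median, "min": pooled.min, "max": pooled.max,
            "range": pooled.range,
            "range_per_replicate": {k[0]: v.range for k, v in per_rep.items()},
        }
    if tables:
        pd.concat(tables, ignore_index=True).to_csv(
            outdir / "trajectory_metrics.tsv", sep="\t", index=False)

    lobes = []
    for lobe, rng in (("NTD1", scheme.ntd1), ("NTD2", scheme.ntd2)):
        if rng is None:
            continue
        for traj in aligned:
            for chain in reference.assembly_chains:
                lobes.append(lobe_trace(traj, chain, lobe, rng, axis))
    if lobes:
        pd.concat([t.to_frame() for t in lobes], ignore_index=True).to_csv(
            outdir / "lobe_traces.tsv", sep="\t", index=False)
        summary["lobe_displacement"] = {
            lobe: {"median": s.median, "max": s.max, "range": s.range}
            for lobe, s in displacement_summary(lobes).items()}

    if "pore" in config.metrics:
        profiles = [pore_radius_profile(t.frame_model(i), axis, scheme=scheme)
                    for t in aligned for i in range(t.n_frames)]
        stats = profile_stats(profiles)
        stats.to_csv(outdir / "pore_profile_stats.tsv", sep="\t", index=False)
        summary["pore"] = {"min_radius_mean": float(stats["radius_mean"].min())}

    if "ions" in config.metrics:
        ions = find_ions(reference)
        site_contacts = {ion: coordination_shell(reference, ion, config.ion_cutoff)
                         for ion in ions}
        labels = classify_sites(site_contacts, DEFAULT_SITE_DEFINITIONS)
        res_series = []
        for traj in aligned:
            for ion in ions:
                res_series.append(residence(traj, ion, config.residence_threshold,
                                            site_label=labels.get(ion, "unassigned")))
        if res_series:
            tab = residence_summary(res_series)
            tab.to_csv(outdir / "residence_summary.tsv", sep="\t", index=False)
            per_site = {}
            for site, grp in tab.groupby("site"):
                per_site[site] = {
                    "chains_bound_at_end": int(grp["bound_at_end"].sum()),
                    "n_tracked": len(grp),
                    "mean_bound_fraction": float(grp["bound_fraction"].mean()),
                }
            summary["residence"] = per_site

    _write_sidecar(config, outdir, {"mode": "trajectory"})
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
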