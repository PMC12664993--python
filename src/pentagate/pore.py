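"""Sphere-probe pore radius profiling along the channel axis.

At each axial sample z the profile reports the radius of the largest probe
sphere centred in the plane through z that touches no atom's van der Waals
surface: radius(c) = min_i (|c − x_i| − r_vdw,i), maximised over in-plane
centre positions c. The search is 2-D per slice (the pore is axis-aligned
after TMD alignment): a coarse in-plane grid seeds a Nelder–Mead refinement,
which handles the non-smooth maximin objective reliably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .geometry import PoreAxis, center_of_mass
from .model_io import DomainScheme, StructureModel, select

__all__ = ["VdwTable", "PoreProfile", "BONDI_VDW", "pore_radius_profile",
           "annotate_primes", "profile_stats"]

# Bondi-type van der Waals radii (Å) for the elements that occur in protein
# heavy atoms and common hetero species.
BONDI_VDW: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "CA": 2.31, "ZN": 1.39, "FE": 2.00,
}


@dataclass
class VdwTable:
    """Element → van der Waals radius (Å); unknown elements fall back to
    ``default`` so an exotic hetero atom never crashes a profile."""

    radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_VDW))
    default: float = 1.70

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii.values()) or self.default <= 0:
            raise ValueError("van der Waals radii must be positive")

    def lookup(self, elements: np.ndarray) -> np.ndarray:
        return np.array([self.radii.get(str(e).upper(), self.default) for e in elements])


@dataclass
class PoreProfile:
    """Radius profile of one frame: per-z radius plus prime annotations."""

    z: np.ndarray  # (M,) Å along the pore axis
    radius: np.ndarray  # (M,) Å, ≥ 0 where bounded
    capped: np.ndarray  # (M,) bool, True where the probe escaped (radius at cap)
    annotations: dict[str, float] = field(default_factory=dict)  # prime label -> z

    def __post_init__(self) -> None:
        if np.any(self.radius < 0):
            raise ValueError("pore radius must be non-negative")

    def radius_at(self, z: float) -> float:
        """Linear interpolation of the profile at axial coordinate ``z``."""
        return float(np.interp(z, self.z, self.radius))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.z, "radius": self.radius, "capped": self.capped})


def _slice_radius(xy_atoms: np.ndarray, dz: np.ndarray, vdw: np.ndarray,
                  cap: float, search_radius: float, grid_step: float = 0.5,
                  ) -> tuple[float, bool]:
    """Largest inscribed probe radius in one z-slice.

    ``xy_atoms``: in-plane atom offsets from the axis; ``dz``: axial offsets
    from the slice plane. Distances to atom centres are 3-D, so atoms off the
    plane still bound the probe correctly. The probe centre is confined to a
    disc of ``search_radius`` around the axis so that an open geometry does
    not let the probe escape sideways out of the pore.
    """

    def neg_radius(c: np.ndarray) -> float:
        if np.linalg.norm(c) > search_radius:
            return np.inf
        d = np.sqrt(((xy_atoms - c) ** 2).sum(axis=1) + dz ** 2) - vdw
        return -d.min()

    # coarse grid seed centred on the axis, confined to the search disc
    n = int(np.ceil(search_radius / grid_step))
    ax = np.arange(-n, n + 1) * grid_step
    gx, gy = np.meshgrid(ax, ax)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    centers = centers[np.linalg.norm(centers, axis=1) <= search_radius]
    d3 = np.sqrt(
        ((centers[:, None, :] - xy_atoms[None, :, :]) ** 2).sum(axis=2) + dz[None, :] ** 2
    ) - vdw[None, :]
    slice_min = d3.min(axis=1)
    seed = centers[slice_min.argmax()]
    res = minimize(neg_radius, seed, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    best = max(-res.fun if np.isfinite(res.fun) else -np.inf, slice_min.max())
    if best >= cap:
        return cap, True
    return max(float(best), 0.0), False


def pore_radius_profile(
    frame: StructureModel,
    axis: PoreAxis,
    lining: np.ndarray | None = None,
    vdw: VdwTable | None = None,
    z_window: tuple[float, float] | None = None,
    z_step: float = 0.5,
    cap_radius: float = 10.0,
    cylinder_radius: float = 15.0,
    search_radius: float = 5.0,
    scheme: DomainScheme | None = None,
) -> PoreProfile:
    """Pore radius profile of one frame along ``axis``.

    ``lining`` is an atom index array; by default all protein heavy atoms
    within ``cylinder_radius`` of the axis. ``z_window`` defaults to the
    axial extent of the TMD Cα selection. Slices where no atom bounds the
    probe are capped at ``cap_radius`` and flagged.
    """
    vdw = vdw or VdwTable()
    scheme = scheme or DomainScheme()
    if lining is None:
        mask = (~frame.is_hetero) & (frame.element != "H") & (frame.element != "D")
        lining = np.nonzero(mask)[0]
    lining = np.asarray(lining, dtype=int)
    if lining.size == 0:
        raise ValueError("empty lining selection")
    radial, zcoord = axis.decompose(frame.xyz[lining])
    keep = radial <= cylinder_radius
    lining, radial, zcoord = lining[keep], radial[keep], zcoord[keep]
    if lining.size == 0:
        raise ValueError(f"no lining atoms within {cylinder_radius} Å of the axis")

    if z_window is None:
        tmd_z = []
        for chain in frame.assembly_chains:
            sel = select(frame, chain, scheme.tmd_twist, "ca_only")
            if len(sel):
                _, zc = axis.decompose(frame.xyz[sel.indices])
                tmd_z.append(zc)
        if tmd_z:
            allz = np.concatenate(tmd_z)
            z_window = (float(allz.min()), float(allz.max()))
        else:
            z_window = (float(zcoord.min()), float(zcoord.max()))

    # orthonormal in-plane basis for the slice coordinates
    d = axis.direction
    seed = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    rel = frame.xyz[lining] - axis.origin
    xy = np.column_stack([rel @ e1, rel @ e2])
    radii_vdw = vdw.lookup(frame.element[lining])

    zs = np.arange(z_window[0], z_window[1] + 0.5 * z_step, z_step)
    radius = np.empty(len(zs))
    capped = np.zeros(len(zs), dtype=bool)
    reach = cap_radius + search_radius + radii_vdw.max()
    for k, z0 in enumerate(zs):
        # atoms farther than the probe's reach along z can never bind it
        near = np.abs(zcoord - z0) <= reach
        if not near.any():
            radius[k], capped[k] = cap_radius, True
            continue
        radius[k], capped[k] = _slice_radius(xy[near], zcoord[near] - z0,
                                             radii_vdw[near], cap_radius, search_radius)
    if capped.any():
        warnings.warn(f"{capped.sum()} of {len(zs)} slices unbounded; radius capped "
                      f"at {cap_radius} Å", stacklevel=2)
    return PoreProfile(z=zs, radius=radius, capped=capped)


def annotate_primes(profile: PoreProfile, scheme: DomainScheme,
                    frame: StructureModel, axis: PoreAxis) -> PoreProfile:
    """Attach prime-position (2′, 9′, 16′ …) axial coordinates to a profile.

    The z of each prime is the axial coordinate of the Cα COM of the five
    corresponding residues. Without a ``prime_map`` the profile is returned
    unchanged with a warning.
    """
    if not scheme.prime_map:
        warnings.warn("no prime_map configured; skipping prime annotation", stacklevel=2)
        return profile
    for label, res in scheme.prime_map.items():
        coms = []
        for chain in frame.assembly_chains:
            sel = select(frame, chain, (res, res), "ca_only", coverage_floor=0.0)
            if len(sel):
                coms.append(frame.xyz[sel.indices].mean(axis=0))
        if len(coms) < 5:
            warnings.warn(f"prime {label}: residue {res} resolved in only "
                          f"{len(coms)}/5 chains", stacklevel=2)
        if coms:
            _, z = axis.decompose(center_of_mass(np.array(coms)))
            profile.annotations[label] = float(z)
    return profile


def profile_stats(profiles: list[PoreProfile]) -> pd.DataFrame:
    """Pointwise mean and SEM (sample SD/√n) across per-frame profiles.

    Profiles must share a common z grid (they do when produced by
    :func:`pore_radius_profile` with one axis and window).
    """
    if not profiles:
        raise ValueError("at least one profile required")
    z0 = profiles[0].z
    for p in profiles[1:]:
        if len(p.z) != len(z0) or not np.allclose(p.z, z0):
            raise ValueError("profiles must share a common z grid")
    stack = np.vstack([p.radius for p in profiles])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return pd.DataFrame({"z": z0, "radius_mean": mean, "radius_sem": sem})
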