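"""Geometric primitives: centers of mass, dihedrals, superposition, pore axis.

All angles are degrees, all lengths Å. The dihedral follows the IUPAC sign
convention: looking along b→c, a clockwise rotation carrying the projection
of a onto the projection of d is positive; values lie in (−180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "PoreAxis",
    "center_of_mass",
    "dihedral",
    "superpose",
    "estimate_axis",
]


@dataclass
class RigidTransform:
    """Proper rigid-body motion x ↦ R x + t."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class PoreAxis:
    """Channel axis: origin plus unit direction, +direction toward the NTD side."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("axis direction must be non-zero")
        self.direction = d / n

    def decompose(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (radial distance from axis, signed axial coordinate z)."""
        rel = np.atleast_2d(np.asarray(points, dtype=float) - self.origin)
        z = rel @ self.direction
        radial = np.linalg.norm(rel - np.outer(z, self.direction), axis=-1)
        if np.asarray(points).ndim == 1:
            return radial[0], z[0]
        return radial, z


def center_of_mass(
    xyz: np.ndarray,
    weighting: str = "uniform",
    elements: np.ndarray | None = None,
) -> np.ndarray:
    """Centroid (uniform) or mass-weighted center of an atom set.

    Uniform weighting reproduces the Cα-COM definition exactly; mass
    weighting uses standard atomic weights and requires ``elements``.
    """
    xyz = np.asarray(xyz, dtype=float)
    if xyz.size == 0:
        raise ValueError("center of mass of an empty atom set is undefined")
    xyz = np.atleast_2d(xyz)
    if weighting == "uniform":
        return xyz.mean(axis=0)
    if weighting == "mass":
        if elements is None:
            raise ValueError("mass weighting requires element symbols")
        w = np.array([gemmi.Element(str(e)).weight for e in elements], dtype=float)
        return (xyz * w[:, None]).sum(axis=0) / w.sum()
    raise ValueError(f"unknown weighting {weighting!r}")


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Dihedral angle a–b–c–d in degrees, IUPAC sign, in (−180, 180]."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b0 = a - b
    b1 = c - b
    b2 = d - c
    n1 = np.linalg.norm(b1)
    if n1 < 1e-12:
        raise ValueError("degenerate dihedral: b and c coincide")
    b1 = b1 / n1
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    if np.linalg.norm(v) < 1e-12 or np.linalg.norm(w) < 1e-12:
        raise ValueError("degenerate dihedral: colinear points")
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang <= -180.0 else float(ang)


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Ordered one-to-one correspondence is assumed (Kabsch). The rotation is
    constrained proper (no reflections). Returns the transform and the
    post-fit RMSD in Å.
    """
    mobile = np.atleast_2d(np.asarray(mobile, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    if mobile.shape[0] < 3:
        raise ValueError("superposition requires at least 3 points")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - cr, mobile - cm)
    rmat = rot.as_matrix()
    transform = RigidTransform(rotation=rmat, translation=cr - rmat @ cm)
    rmsd = rssd / np.sqrt(mobile.shape[0])
    return transform, float(rmsd)


def estimate_axis(
    coords: np.ndarray,
    chains: np.ndarray,
    toward: np.ndarray | None = None,
) -> PoreAxis:
    """Estimate the C5 pore axis from a TMD selection spanning all 5 chains.

    The five per-chain centroids of a C5-arranged selection form a planar
    ring; the axis is the smallest-spread principal direction of those five
    points (the ring-plane normal), through the centroid of the whole
    selection. Working on chain centroids rather than raw atoms makes the
    estimate independent of the selection's axial extent. ``toward``
    (typically the NTD Cα centroid) fixes the sign so +direction points from
    the TMD toward the periplasmic NTD side; without it, the sign is aligned
    with +z.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    chains = np.asarray(chains)
    uniq = np.unique(chains)
    if len(uniq) < 5:
        raise ValueError("axis estimation requires a selection spanning all 5 chains")
    chain_coms = np.array([coords[chains == c].mean(axis=0) for c in uniq])
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(chain_coms - chain_coms.mean(axis=0), full_matrices=False)
    direction = vt[-1]  # smallest singular value: the ring-plane normal
    if toward is not None:
        if (np.asarray(toward, dtype=float) - centroid) @ direction < 0:
            direction = -direction
    elif direction[2] < 0:
        direction = -direction
    return PoreAxis(origin=centroid, direction=direction)
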