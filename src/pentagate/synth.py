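"""Synthetic pentamer and trajectory generator with exact ground truth.

Builds an idealized C5-symmetric pentamer of Cα pseudo-atoms in four stacked
domain blocks per subunit (NTD1, NTD2, ECD, TMD), with the residue numbering
of the default domain scheme so every selection resolves at coverage 1.0.
The construction makes the analysis metrics exact at zero noise:

* ECD twist — each chain's ECD-block center of mass is placed at the
  azimuth of its TMD-block center of mass plus the target twist, which is
  exactly what the four-COM dihedral measures (and what pins the global
  sign convention of the twist).
* β-expansion — the β1 cluster COM and the β10 COM (whose last residue, the
  ECD→TMD transition residue, lives in the TMD block) are placed exactly
  ``beta_sep`` apart, via a small fixed-point solve that keeps the ECD-COM
  azimuth constraint simultaneously exact.
* Pore radius — the TMD is a stack of 25 dense rings (25 atoms each) whose
  ring radii realize ``pore_radius_by_z`` plus the carbon van der Waals
  radius, so the sphere-probe profile recovers the requested radii.
* Ion sites — each requested site archetype gets an ion plus a shell of
  correctly named O atoms at the requested shell radius, so coordination
  analysis and site classification have exact expectations.

Trajectories apply scripted rigid events (lobe/ECD/chain/ion translations
and rotations about the pore axis) cumulatively on top of the base model,
plus seeded isotropic Gaussian noise; the applied per-frame offsets are
returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import DomainScheme, StructureModel, Trajectory

__all__ = ["PentamerSpec", "MotionEvent", "build_pentamer", "build_trajectory",
           "CHAIN_IDS"]

CHAIN_IDS = ["A", "B", "C", "D", "E"]

_CA_VDW = 1.70  # carbon vdW radius used when converting pore radii to ring radii

# residues that carry coordination-shell oxygens keep their real identity;
# everything else is alanine
_RES_NAMES = {76: "ASP", 77: "PRO", 123: "ASP", 124: "ASP", 126: "GLY",
              128: "GLY", 129: "TYR", 347: "GLU", 434: "PRO", 436: "PHE",
              476: "GLN", 477: "LEU", 478: "GLY", 480: "GLU"}

# site archetype -> (ion res_seq, local ion position, [(res_seq, atom_name), ...])
_SITE_ARCHETYPES: dict[str, tuple[int, tuple[float, float, float],
                                  list[tuple[int, str]]]] = {
    "Site1": (701, (10.0, -6.0, 88.0),
              [(76, "OD1"), (77, "O"), (123, "OD1"), (123, "O"),
               (124, "OD1"), (129, "O")]),
    "Site2": (702, (16.0, 6.0, 92.0),
              [(124, "O"), (126, "O"), (128, "O")]),
    "Site3": (703, (17.0, -5.0, 55.0),
              [(347, "OE1"), (434, "O"), (436, "O"), (477, "O")]),
    "Site4": (704, (19.0, 4.0, 60.0),
              [(480, "OE1"), (476, "O"), (478, "O")]),
}

_SHELL_DIRECTIONS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
], dtype=float)

_N_RINGS = 25
_RING_DZ = 1.6
_TMD_Z_TOP = (_N_RINGS - 1) * _RING_DZ  # 38.4 Å


def _default_pore_profile() -> list[tuple[float, float]]:
    # modest inner-end constriction (1.5 Å at the intracellular mouth)
    # widening toward the extracellular side
    return [(0.0, 1.5), (10.0, 2.5), (25.0, 3.0), (_TMD_Z_TOP, 3.5)]


@dataclass
class PentamerSpec:
    """Ground-truth parameters of a synthetic pentamer.

    ``twist_deg`` and ``beta_sep`` are recovered exactly (noise 0) by
    :func:`pentagate.gating.ecd_twist` / ``beta_expansion``. Shell radii in
    ``ion_sites`` are the exact ion–oxygen distances of each site archetype.
    ``lobe_offsets`` maps (chain, lobe) to a rigid 3-vector applied to that
    lobe's atoms.
    """

    twist_deg: float = -26.0
    beta_sep: float = 12.0
    pore_radius_by_z: list[tuple[float, float]] = field(default_factory=_default_pore_profile)
    lobe_offsets: dict[tuple[str, str], tuple[float, float, float]] = field(default_factory=dict)
    ion_sites: dict[str, float] = field(default_factory=lambda: {
        "Site1": 2.4, "Site2": 2.85, "Site3": 2.5, "Site4": 2.75})
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for _, r in self.pore_radius_by_z):
            raise ValueError("pore radii must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for (chain, lobe) in self.lobe_offsets:
            if chain not in CHAIN_IDS or lobe not in ("NTD1", "NTD2"):
                raise ValueError(f"unknown lobe-offset target ({chain!r}, {lobe!r})")
        for label in self.ion_sites:
            if label not in _SITE_ARCHETYPES:
                raise ValueError(f"unknown ion site archetype {label!r}")

    def scheme(self) -> DomainScheme:
        """Domain scheme matching the generator's numbering, with the lobe
        split and a prime map for the pore-lining ring residues."""
        return DomainScheme(
            ntd1=(35, 115), ntd2=(116, 195),
            prime_map={"2'": 637, "9'": 630, "16'": 623},
        )


def _rot_z(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _fibonacci_ball(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    """Deterministic quasi-uniform cloud of n points in a ball."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    zfrac = 1.0 - 2.0 * (i + 0.5) / n
    r_sph = radius * ((i + 0.5) / n) ** (1.0 / 3.0)
    rho = np.sqrt(np.clip(1.0 - zfrac**2, 0.0, 1.0))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), zfrac]) * r_sph[:, None]
    return pts + center


def _octahedral_cluster(center: np.ndarray, n: int, radius: float) -> np.ndarray:
    """n ≤ 6 points from the octahedral directions; any antipodal-complete
    prefix sums to zero, so 2/4/6-point clusters have their COM at center."""
    return center + radius * _SHELL_DIRECTIONS[:n]


def _azimuth(p: np.ndarray) -> float:
    return float(np.degrees(np.arctan2(p[1], p[0])))


def _wrap(deg: float) -> float:
    return (deg + 180.0) % 360.0 - 180.0


class _ChainAtoms:
    """Accumulator for one chain's records."""

    def __init__(self) -> None:
        self.rows: list[tuple[int, str, str, str, bool, np.ndarray]] = []

    def add(self, res_seq: int, atom_name: str, element: str, pos: np.ndarray,
            res_name: str | None = None, hetero: bool = False) -> None:
        name = res_name or _RES_NAMES.get(res_seq, "ALA")
        self.rows.append((res_seq, name, atom_name, element, hetero, np.asarray(pos, float)))

    def sorted_rows(self):
        # protein records in residue order; hetero ions (res_seq ≥ 700) land last
        return sorted(self.rows, key=lambda r: (r[4], r[0]))


def _build_chain0(spec: PentamerSpec) -> _ChainAtoms:
    atoms = _ChainAtoms()

    # --- TMD: residues 515..639 in 25 rings of 5, top (515) to bottom (639)
    zs = [_TMD_Z_TOP - m * _RING_DZ for m in range(_N_RINGS)]
    ctrl = np.array(spec.pore_radius_by_z)
    order = np.argsort(ctrl[:, 0])
    ring_radii = np.interp(zs, ctrl[order, 0], ctrl[order, 1]) + _CA_VDW
    tmd_xyz: dict[int, np.ndarray] = {}
    for m in range(_N_RINGS):
        for j in range(5):
            res = 515 + 5 * m + j
            ang = np.radians((j - 2) * 14.4)
            pos = np.array([ring_radii[m] * np.cos(ang), ring_radii[m] * np.sin(ang), zs[m]])
            tmd_xyz[res] = pos
            atoms.add(res, "CA", "C", pos)

    # azimuth of the TMD-twist block COM fixes where the ECD must sit
    tmd_com = np.mean([tmd_xyz[r] for r in range(515, 637)], axis=0)
    target_azimuth = _azimuth(tmd_com) + spec.twist_deg
    a515 = tmd_xyz[515]

    # --- ECD local template (azimuth ≈ 0): generic spiral + β1 cluster
    generic_res = list(range(328, 340)) + list(range(346, 511))
    g = len(generic_res)
    i = np.arange(g, dtype=float)
    ang = 2.39996322972865332 * i
    loc_generic = np.column_stack([
        15.0 + 3.0 * np.cos(ang), 3.0 * np.sin(ang), 48.0 + 22.0 * i / g])
    q1_loc = np.array([14.0, 0.0, 52.0])
    loc_beta1 = _octahedral_cluster(q1_loc, 6, 1.5)
    v = np.array([0.3, 0.0, -1.0])
    p10_loc = q1_loc + spec.beta_sep * v / np.linalg.norm(v)

    # fixed-point solve: rotate the template by delta about z so that the
    # ECD-twist-range COM (which includes the a515-coupled β10 atoms) lands
    # at the target azimuth
    def ecd_range_com(delta: float) -> np.ndarray:
        rot = _rot_z(delta)
        q10c = (5.0 * rot @ p10_loc - a515) / 4.0
        total = (rot @ loc_generic.T).T.sum(axis=0) + (rot @ loc_beta1.T).T.sum(axis=0)
        total = total + 3.0 * q10c  # residues 511-513 sit at q10c
        return total / (g + 6 + 3)

    delta = target_azimuth
    for _ in range(60):
        err = _wrap(target_azimuth - _azimuth(ecd_range_com(delta)))
        delta += err
        if abs(err) < 1e-13:
            break

    rot = _rot_z(delta)
    for res, pos in zip(generic_res, (rot @ loc_generic.T).T):
        atoms.add(res, "CA", "C", pos)
    for res, pos in zip(range(340, 346), (rot @ loc_beta1.T).T):
        atoms.add(res, "CA", "C", pos)
    q10c = (5.0 * rot @ p10_loc - a515) / 4.0
    tri = np.array([[1.2, 0.0, 0.0], [-0.6, 1.0392, 0.0], [-0.6, -1.0392, 0.0]])
    for res, off in zip((511, 512, 513), tri):  # equilateral, sums to zero
        atoms.add(res, "CA", "C", q10c + off)
    atoms.add(514, "CA", "C", q10c)

    # --- NTD lobes: compact balls above the ECD
    for res, pos in zip(range(35, 116),
                        _fibonacci_ball(81, 4.0, np.array([12.0, 0.0, 88.0]))):
        atoms.add(res, "CA", "C", pos)
    for res, pos in zip(range(116, 196),
                        _fibonacci_ball(80, 4.0, np.array([18.0, 0.0, 98.0]))):
        atoms.add(res, "CA", "C", pos)

    # --- ion sites: ion + correctly named O shell at the requested radius
    for label, shell_r in spec.ion_sites.items():
        ion_seq, ion_pos, partners = _SITE_ARCHETYPES[label]
        ion_pos = np.asarray(ion_pos, float)
        atoms.add(ion_seq, "CA", "CA", ion_pos, res_name="CA", hetero=True)
        for k, (res, aname) in enumerate(partners):
            atoms.add(res, aname, "O", ion_pos + shell_r * _SHELL_DIRECTIONS[k])
    return atoms


def build_pentamer(spec: PentamerSpec) -> StructureModel:
    """Build the C5 pentamer; chains B–E are 72° rotations of chain A."""
    chain0 = _build_chain0(spec)
    chain_ids, res_seq, res_name, atom_name, element, het, xyz = [], [], [], [], [], [], []
    for k, cid in enumerate(CHAIN_IDS):
        rot = _rot_z(72.0 * k)
        for seq, rname, aname, elem, hetero, pos in chain0.sorted_rows():
            p = rot @ pos
            lobe = None
            if 35 <= seq <= 115 and not hetero:
                lobe = (cid, "NTD1")
            elif 116 <= seq <= 195 and not hetero:
                lobe = (cid, "NTD2")
            if lobe in spec.lobe_offsets:
                p = p + np.asarray(spec.lobe_offsets[lobe], float)
            chain_ids.append(cid)
            res_seq.append(seq)
            res_name.append(rname)
            atom_name.append(aname)
            element.append(elem)
            het.append(hetero)
            xyz.append(p)
    xyz_arr = np.array(xyz)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        xyz_arr = xyz_arr + rng.normal(0.0, spec.noise_sigma, xyz_arr.shape)
    return StructureModel(
        chain_ids=np.array(chain_ids), res_seq=np.array(res_seq, dtype=int),
        res_name=np.array(res_name), atom_name=np.array(atom_name),
        element=np.array(element), xyz=xyz_arr, is_hetero=np.array(het, dtype=bool),
        title="synthetic pentamer", assembly_chains=list(CHAIN_IDS),
    )


@dataclass
class MotionEvent:
    """A rigid event applied from ``frame`` onward (cumulative).

    ``target``: ("NTD1"|"NTD2"|"ECD"|"chain", chain id) or ("ion", ion id
    like "A/701"). ``translation`` is a 3-vector in Å; ``rotate_z_deg``
    rotates the target's atoms about the pore (z) axis — applying the same
    ECD rotation to all five chains shifts every chain's twist by exactly
    that angle (a single-chain rotation also perturbs the pentamer ECD COM,
    so its twist shift is only approximate).
    """

    frame: int
    target: tuple[str, str]
    translation: tuple[float, float, float] | None = None
    rotate_z_deg: float | None = None


def _target_mask(model: StructureModel, target: tuple[str, str]) -> np.ndarray:
    kind, who = target
    if kind == "ion":
        chain, _, seq = who.partition("/")
        mask = (model.chain_ids == chain) & (model.res_seq == int(seq)) & model.is_hetero
    else:
        ranges = {"NTD1": (35, 115), "NTD2": (116, 195), "ECD": (328, 514),
                  "chain": (0, 10**6)}
        if kind not in ranges:
            raise ValueError(f"unknown motion target kind {kind!r}")
        lo, hi = ranges[kind]
        mask = (model.chain_ids == who) & (model.res_seq >= lo) & (model.res_seq <= hi)
        if kind != "chain":
            mask &= ~model.is_hetero
    if not mask.any():
        raise ValueError(f"motion target {target} matches no atoms")
    return mask


def build_trajectory(
    spec: PentamerSpec,
    n_frames: int,
    script: list[MotionEvent] | None = None,
    dt_ns: float = 1.0,
    replicate_id: str = "rep1",
) -> tuple[Trajectory, dict[tuple[str, str], np.ndarray]]:
    """Multi-frame trajectory from the base pentamer plus scripted events.

    Returns the trajectory and a ground-truth map target → (n_frames, 3)
    cumulative translation applied per frame (rotations are exact by
    construction and not tabulated as offsets). Frame noise is seeded from
    ``spec.seed`` and independent of the base-model noise.
    """
    script = script or []
    base = build_pentamer(spec)
    for ev in script:
        if not (0 <= ev.frame < n_frames):
            raise ValueError(f"event frame {ev.frame} outside trajectory length {n_frames}")
        _target_mask(base, ev.target)  # validate targets up front
    rng = np.random.default_rng(spec.seed + 1)
    current = base.xyz.copy()
    frames = np.empty((n_frames, base.n_atoms, 3))
    offsets: dict[tuple[str, str], np.ndarray] = {
        ev.target: np.zeros((n_frames, 3)) for ev in script}
    running: dict[tuple[str, str], np.ndarray] = {
        ev.target: np.zeros(3) for ev in script}
    for f in range(n_frames):
        for ev in script:
            if ev.frame != f:
                continue
            mask = _target_mask(base, ev.target)
            if ev.rotate_z_deg is not None:
                current[mask] = (current[mask] @ _rot_z(ev.rotate_z_deg).T)
            if ev.translation is not None:
                t = np.asarray(ev.translation, float)
                current[mask] = current[mask] + t
                running[ev.target] = running[ev.target] + t
        for tgt, cum in running.items():
            offsets[tgt][f] = cum
        noise = rng.normal(0.0, spec.noise_sigma, current.shape) if spec.noise_sigma > 0 \
            else 0.0
        frames[f] = current + noise
    times = dt_ns * np.arange(n_frames, dtype=float)
    traj = Trajectory(topology=base, frames=frames, times=times, replicate_id=replicate_id)
    return traj, offsets
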