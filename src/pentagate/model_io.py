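"""Structural model and trajectory I/O with author-numbered residue selection.

Models are read with gemmi (PDB and mmCIF) into a flat, array-backed
:class:`StructureModel`; trajectories are read with MDAnalysis from any
(topology, coordinates) pair its readers support (multi-model PDB, XTC and
DCD are the documented combinations). All residue selection is by *author*
numbering, because every residue identifier used in the analyses (e.g.
Asp76, Glu347, the 328–639 alignment range) is an author number; mmCIF
``label_seq_id`` is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "StructureModel",
    "Trajectory",
    "DomainScheme",
    "Selection",
    "SelectionError",
    "FormatError",
    "read_structure",
    "write_structure",
    "select",
    "read_trajectory",
    "write_trajectory",
    "load_scheme",
]


class FormatError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a residue-range selection matches nothing."""


@dataclass
class StructureModel:
    """A structural model as parallel per-atom arrays (coordinates in Å).

    ``res_seq`` carries author residue numbering. Hetero records (ions,
    waters, lipids) are retained with ``is_hetero`` set.
    """

    chain_ids: np.ndarray  # (N,) str
    res_seq: np.ndarray  # (N,) int, author numbering
    res_name: np.ndarray  # (N,) str
    atom_name: np.ndarray  # (N,) str
    element: np.ndarray  # (N,) str
    xyz: np.ndarray  # (N, 3) float, Å
    is_hetero: np.ndarray  # (N,) bool
    title: str = ""
    assembly_chains: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (N, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("all atom coordinates must be finite")
        for name in ("chain_ids", "res_seq", "res_name", "atom_name", "element", "is_hetero"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != self.n_atoms:
                raise ValueError(f"{name} length {arr.shape[0]} != atom count {self.n_atoms}")
            setattr(self, name, arr)
        if not self.assembly_chains:
            seen: list[str] = []
            for c, het in zip(self.chain_ids, self.is_hetero):
                if not het and c not in seen:
                    seen.append(str(c))
            self.assembly_chains = seen

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[0]

    def require_pentamer(self) -> None:
        """Enforce the five-chain assembly contract at analysis entry."""
        if len(self.assembly_chains) != 5:
            raise ValueError(
                f"pentamer analysis requires exactly 5 protein chains, "
                f"found {len(self.assembly_chains)}: {self.assembly_chains}"
            )

    def with_xyz(self, xyz: np.ndarray) -> "StructureModel":
        return replace(self, xyz=np.asarray(xyz, dtype=float))


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å) over a fixed topology, times in ns."""

    topology: StructureModel
    frames: np.ndarray  # (F, N, 3)
    times: np.ndarray  # (F,), ns
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.times.shape[0] != self.frames.shape[0]:
            raise ValueError("one time stamp per frame required")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_model(self, i: int) -> StructureModel:
        """Topology with the coordinates of frame ``i``."""
        return self.topology.with_xyz(self.frames[i])


# Default residue ranges for the DeCLIC-style domain scheme. The alignment
# range (328–639) deliberately overlaps the ECD-twist range (328–513) while
# the twist's TMD block starts at 515; residues 514 and 637–639 belong to no
# twist block. This is kept verbatim.
_DEFAULT_RANGES = {
    "ntd_track": (35, 195),
    "ecd_twist": (328, 513),
    "tmd_twist": (515, 636),
    "tmd_align": (328, 639),
    "beta1": (340, 345),
    "beta10": (511, 515),
}


@dataclass
class DomainScheme:
    """Named residue-range selections per structural role.

    Ranges are inclusive (start, stop) author-numbered pairs. ``ntd1``/
    ``ntd2`` have no default: the two-lobe split is not part of the scheme
    conventions and must be supplied for lobe tracking. ``prime_map`` maps a
    pore-lining prime index (e.g. ``"2'"``) to a residue number; it has no
    default either.
    """

    ntd_track: tuple[int, int] = _DEFAULT_RANGES["ntd_track"]
    ecd_twist: tuple[int, int] = _DEFAULT_RANGES["ecd_twist"]
    tmd_twist: tuple[int, int] = _DEFAULT_RANGES["tmd_twist"]
    tmd_align: tuple[int, int] = _DEFAULT_RANGES["tmd_align"]
    beta1: tuple[int, int] = _DEFAULT_RANGES["beta1"]
    beta10: tuple[int, int] = _DEFAULT_RANGES["beta10"]
    ntd1: tuple[int, int] | None = None
    ntd2: tuple[int, int] | None = None
    prime_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("ntd_track", "ecd_twist", "tmd_twist", "tmd_align", "beta1", "beta10"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"range {name} is empty: ({lo}, {hi})")
            setattr(self, name, (int(lo), int(hi)))
        b1 = set(range(self.beta1[0], self.beta1[1] + 1))
        b10 = set(range(self.beta10[0], self.beta10[1] + 1))
        if b1 & b10:
            raise ValueError("beta1 and beta10 ranges must be disjoint")
        tmd = set(range(self.tmd_twist[0], self.tmd_twist[1] + 1)) | set(
            range(self.tmd_align[0], self.tmd_align[1] + 1)
        )
        for label, res in self.prime_map.items():
            if int(res) not in tmd:
                raise ValueError(f"prime position {label} -> {res} lies outside the TMD ranges")

    def range_for(self, role: str) -> tuple[int, int]:
        rng = getattr(self, role, None)
        if rng is None:
            raise ValueError(f"scheme has no range configured for role {role!r}")
        return rng


def load_scheme(path: str | Path) -> DomainScheme:
    """Load a :class:`DomainScheme` from a YAML file.

    Keys mirror the dataclass fields; ranges are two-element lists.
    Unspecified keys keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key, val in raw.items():
        if key == "prime_map":
            kwargs[key] = {str(k): int(v) for k, v in val.items()}
        elif val is not None:
            kwargs[key] = (int(val[0]), int(val[1]))
    return DomainScheme(**kwargs)


# --- structure reading -----------------------------------------------------


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # sniff: mmCIF files start with data_ blocks
    with open(path) as fh:
        head = fh.read(2048)
    return "mmcif" if head.lstrip().startswith(("data_", "#")) else "pdb"


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a model from PDB or mmCIF, preserving author numbering.

    Alternate locations: altloc ``A`` or blank is kept, others dropped.
    Hydrogens are retained (filtering happens at selection time).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    st.setup_entities()
    chain_ids, res_seq, res_name, atom_name, element, xyz, het = [], [], [], [], [], [], []
    model = st[0]
    for chain in model:
        for residue in chain:
            info = gemmi.find_tabulated_residue(residue.name)
            is_aa = info.is_amino_acid() if info is not None else False
            is_het = residue.het_flag == "H" or not is_aa
            for atom in residue:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                chain_ids.append(chain.name)
                res_seq.append(residue.seqid.num)
                res_name.append(residue.name)
                atom_name.append(atom.name)
                element.append(atom.element.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                het.append(is_het)
    if not chain_ids:
        raise FormatError(f"{path}: no atoms parsed")
    het_arr = np.array(het, dtype=bool)
    if het_arr.all():
        raise FormatError(f"{path}: model contains zero protein atoms")
    return StructureModel(
        chain_ids=np.array(chain_ids),
        res_seq=np.array(res_seq, dtype=int),
        res_name=np.array(res_name),
        atom_name=np.array(atom_name),
        element=np.array(element),
        xyz=np.array(xyz, dtype=float),
        is_hetero=het_arr,
        title=st.name or "",
    )


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.title or "model"
    gm = gemmi.Model("1")
    for cid in dict.fromkeys(str(c) for c in model.chain_ids):
        chain = gemmi.Chain(cid)
        mask = model.chain_ids == cid
        idx = np.nonzero(mask)[0]
        current = None
        res = None
        for i in idx:
            key = (int(model.res_seq[i]), str(model.res_name[i]))
            if key != current:
                if res is not None:
                    chain.add_residue(res)
                res = gemmi.Residue()
                res.seqid = gemmi.SeqId(key[0], " ")
                res.name = key[1]
                res.het_flag = "H" if model.is_hetero[i] else "A"
                current = key
            atom = gemmi.Atom()
            atom.name = str(model.atom_name[i])
            atom.element = gemmi.Element(str(model.element[i]))
            atom.pos = gemmi.Position(*model.xyz[i])
            res.add_atom(atom)
        if res is not None:
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write a model as PDB or mmCIF (by extension when ``auto``)."""
    path = Path(path)
    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(model)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# --- selection -------------------------------------------------------------


@dataclass
class Selection:
    """Atom indices matched by a residue-range query, with coverage report.

    ``coverage`` = matched residues / residues in the requested range.
    ``flagged`` is set when coverage falls below the floor (missing residues
    are tolerated: deposited models omit disordered stretches).
    """

    indices: np.ndarray
    coverage: float
    flagged: bool

    def __len__(self) -> int:
        return len(self.indices)


def select(
    model: StructureModel,
    chain: str,
    range: tuple[int, int],
    atom_filter: str = "ca_only",
    coverage_floor: float = 0.8,
) -> Selection:
    """Select atoms of ``chain`` with author residue numbers in ``range``.

    ``atom_filter``: ``ca_only`` (protein Cα), ``heavy`` (non-hydrogen) or
    ``all``. Zero matches raise :class:`SelectionError` unless the range
    itself resolves no residues at all, which returns an empty, flagged
    selection with coverage 0 (the missing-loop case).
    """
    lo, hi = int(range[0]), int(range[1])
    if hi < lo:
        raise ValueError(f"empty residue range ({lo}, {hi})")
    in_chain = model.chain_ids == chain
    if not in_chain.any():
        raise SelectionError(f"chain {chain!r} not present in model")
    in_range = in_chain & (model.res_seq >= lo) & (model.res_seq <= hi) & ~model.is_hetero
    if atom_filter == "ca_only":
        mask = in_range & (model.atom_name == "CA")
    elif atom_filter == "heavy":
        mask = in_range & (model.element != "H") & (model.element != "D")
    elif atom_filter == "all":
        mask = in_range
    else:
        raise ValueError(f"unknown atom_filter {atom_filter!r}")

    matched_residues = np.unique(model.res_seq[mask])
    coverage = len(matched_residues) / (hi - lo + 1)
    flagged = coverage < coverage_floor
    if mask.sum() == 0:
        if not in_range.any():
            warnings.warn(
                f"chain {chain} residues {lo}-{hi}: no residues resolved (coverage 0)",
                stacklevel=2,
            )
            return Selection(indices=np.array([], dtype=int), coverage=0.0, flagged=True)
        raise SelectionError(
            f"chain {chain} residues {lo}-{hi}: residues present but no atoms "
            f"match filter {atom_filter!r}"
        )
    if flagged:
        warnings.warn(
            f"chain {chain} residues {lo}-{hi}: coverage {coverage:.2f} below "
            f"floor {coverage_floor:.2f}",
            stacklevel=2,
        )
    # indices sorted by (res_seq, atom order) so selections are invariant to
    # atom record order within a chain
    idx = np.nonzero(mask)[0]
    order = np.argsort(model.res_seq[idx], kind="stable")
    return Selection(indices=idx[order], coverage=coverage, flagged=flagged)


# --- trajectories ----------------------------------------------------------


def read_trajectory(
    topology: str | Path,
    coords: str | Path,
    replicate_id: str | None = None,
) -> Trajectory:
    """Read a trajectory with MDAnalysis from a (topology, coordinates) pair.

    Any reader pair MDAnalysis supports works; multi-model PDB, XTC+PDB and
    DCD+PDB are the documented combinations. Times are converted to ns; when
    the format carries no time information, frames are stamped 0, 1, 2, … ns.
    """
    import MDAnalysis as mda

    top_model = read_structure(topology)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            universe = mda.Universe(str(topology), str(coords))
    except Exception as exc:  # MDAnalysis raises assorted types
        raise FormatError(f"cannot read trajectory {coords}: {exc}") from exc
    n_traj = len(universe.atoms)
    if n_traj != top_model.n_atoms:
        raise ValueError(
            f"atom-count mismatch: topology has {top_model.n_atoms} atoms, "
            f"trajectory frames have {n_traj}"
        )
    frames, times = [], []
    for ts in universe.trajectory:
        frames.append(universe.atoms.positions.astype(float).copy())
        times.append(float(ts.time) / 1000.0)  # ps -> ns
    times_arr = np.asarray(times)
    if len(times_arr) > 1 and not np.all(np.diff(times_arr) > 0):
        times_arr = np.arange(len(frames), dtype=float)
    return Trajectory(
        topology=top_model,
        frames=np.asarray(frames),
        times=times_arr,
        replicate_id=replicate_id or Path(coords).stem,
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (text, readable by MDAnalysis)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"MODEL     {i + 1:4d}\n")
            fh.write(_pdb_atom_records(traj.topology.with_xyz(traj.frames[i])))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def _pdb_atom_records(model: StructureModel) -> str:
    lines = []
    serial = 1
    for i in range(model.n_atoms):
        record = "HETATM" if model.is_hetero[i] else "ATOM  "
        name = str(model.atom_name[i])
        # PDB atom-name column convention: element right-aligned in cols 13-14
        name_fmt = f" {name:<3s}" if len(name) < 4 and len(str(model.element[i])) == 1 else f"{name:<4s}"
        x, y, z = model.xyz[i]
        lines.append(
            f"{record}{serial:5d} {name_fmt} {str(model.res_name[i]):<3s} "
            f"{str(model.chain_ids[i]):1s}{int(model.res_seq[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{str(model.element[i]):>2s}\n"
        )
        serial = min(serial + 1, 99999)
    return "".join(lines)
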