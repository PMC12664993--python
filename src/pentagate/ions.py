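"""Cation coordination-shell analysis, site classification and residence.

Four calcium-site archetypes are shipped as defaults, defined by their
coordinating partners:

* Site 1 — acidic side chains of Asp76, Asp123, Asp124 plus backbone
  carbonyls of Pro77, Asp123, Tyr129 (NTD1 jelly-roll, tight shell).
* Site 2 — backbone carbonyls of Asp124, Gly126, Gly128 (looser NTD shell).
* Site 3 — acidic side chain of Glu347 plus backbone carbonyls of Pro434,
  Phe436 and loop-F Leu477 (ECD subunit interface).
* Site 4 — side chain of Glu480 plus backbone carbonyls of Gln476 and
  Gly478, all in loop F (limited coordination).

Classification here is purely geometric; it does not attempt to distinguish
a calcium ion from a water molecule in a weak shell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model_io import StructureModel, Trajectory

__all__ = [
    "CoordinationContact", "SiteDefinition", "ResidenceSeries",
    "DEFAULT_SITE_DEFINITIONS", "find_ions", "coordination_shell",
    "classify_sites", "max_coordination_distance", "residence",
    "load_site_definitions",
]

# atoms considered coordinating donors/acceptors: oxygen always, nitrogen optionally
_BACKBONE_O = "O"


@dataclass(frozen=True)
class CoordinationContact:
    """One ion–partner contact with its heavy-atom distance in Å."""

    ion_id: str
    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    distance: float
    partner_class: str  # sidechain_O | backbone_carbonyl_O | water_O | other

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("contact distance must be positive")


@dataclass
class SiteDefinition:
    """A named coordination-site archetype.

    ``partners`` is a set of (residue name, author residue offset key,
    partner class) requirements; an ion matches when at least
    ``match_threshold`` of them are present in its shell.
    """

    label: str
    partners: list[tuple[str, int, str]]  # (res_name, res_seq, partner_class)
    match_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.partners:
            raise ValueError(f"site {self.label}: required partners must be non-empty")

    def matched_fraction(self, contacts: list[CoordinationContact]) -> float:
        have = {(c.res_name, c.res_seq, c.partner_class) for c in contacts}
        hits = sum(1 for p in self.partners if (p[0], p[1], p[2]) in have)
        return hits / len(self.partners)


DEFAULT_SITE_DEFINITIONS: list[SiteDefinition] = [
    SiteDefinition("Site1", [
        ("ASP", 76, "sidechain_O"), ("ASP", 123, "sidechain_O"), ("ASP", 124, "sidechain_O"),
        ("PRO", 77, "backbone_carbonyl_O"), ("ASP", 123, "backbone_carbonyl_O"),
        ("TYR", 129, "backbone_carbonyl_O"),
    ]),
    SiteDefinition("Site2", [
        ("ASP", 124, "backbone_carbonyl_O"), ("GLY", 126, "backbone_carbonyl_O"),
        ("GLY", 128, "backbone_carbonyl_O"),
    ]),
    SiteDefinition("Site3", [
        ("GLU", 347, "sidechain_O"),
        ("PRO", 434, "backbone_carbonyl_O"), ("PHE", 436, "backbone_carbonyl_O"),
        ("LEU", 477, "backbone_carbonyl_O"),
    ]),
    SiteDefinition("Site4", [
        ("GLU", 480, "sidechain_O"),
        ("GLN", 476, "backbone_carbonyl_O"), ("GLY", 478, "backbone_carbonyl_O"),
    ]),
]


def load_site_definitions(path) -> list[SiteDefinition]:
    """Load site definitions from YAML: label → {partners: [[res_name,
    res_seq, class], ...], match_threshold: float}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = []
    for label, body in raw.items():
        out.append(SiteDefinition(
            label=label,
            partners=[(str(p[0]).upper(), int(p[1]), str(p[2])) for p in body["partners"]],
            match_threshold=float(body.get("match_threshold", 0.5)),
        ))
    return out


@dataclass
class ResidenceSeries:
    """Per-frame ion displacement from its initial pose, with bound flags."""

    ion_id: str
    times: np.ndarray
    displacement: np.ndarray  # Å from frame-0 position, in the aligned frame
    threshold: float
    site_label: str = "unassigned"

    @property
    def bound(self) -> np.ndarray:
        return self.displacement < self.threshold

    @property
    def bound_fraction(self) -> float:
        return float(self.bound.mean())

    @property
    def bound_at_end(self) -> bool:
        return bool(self.bound[-1])


_ION_ELEMENTS = {"CA", "MG", "NA", "K", "ZN", "SR", "BA", "MN", "FE", "CU", "CD"}


def find_ions(model: StructureModel, element: str | None = "Ca") -> dict[str, int]:
    """Map ion id (``chain/res_seq``) → atom index for hetero monatomic ions."""
    out: dict[str, int] = {}
    want = element.upper() if element else None
    for i in range(model.n_atoms):
        if not model.is_hetero[i]:
            continue
        el = str(model.element[i]).upper()
        if el not in _ION_ELEMENTS:
            continue
        if want and el != want:
            continue
        out[f"{model.chain_ids[i]}/{int(model.res_seq[i])}"] = i
    return out


def _ion_index(model: StructureModel, ion_id: str | int) -> int:
    if isinstance(ion_id, (int, np.integer)):
        return int(ion_id)
    ions = find_ions(model, element=None)
    if ion_id not in ions:
        raise KeyError(f"unknown ion id {ion_id!r}; known: {sorted(ions)}")
    return ions[ion_id]


def _classify_partner(res_name: str, atom_name: str, is_hetero: bool) -> str:
    if res_name in ("HOH", "WAT", "TIP", "TIP3") and atom_name.startswith("O"):
        return "water_O"
    if is_hetero:
        return "other"
    if atom_name == _BACKBONE_O:
        return "backbone_carbonyl_O"
    if atom_name.startswith("O"):
        return "sidechain_O"
    return "other"


def coordination_shell(model: StructureModel, ion_id: str | int,
                       cutoff: float = 3.5, include_n: bool = False,
                       ) -> list[CoordinationContact]:
    """All O (optionally N) heavy atoms within ``cutoff`` Å of the ion.

    Contacts are sorted by (distance, chain, res_seq, atom_name) so output
    order is deterministic even for equidistant partners.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    idx = _ion_index(model, ion_id)
    label = ion_id if isinstance(ion_id, str) else f"{model.chain_ids[idx]}/{int(model.res_seq[idx])}"
    pos = model.xyz[idx]
    elements = np.char.upper(model.element.astype(str))
    wanted = elements == "O"
    if include_n:
        wanted |= elements == "N"
    wanted[idx] = False
    dist = np.linalg.norm(model.xyz - pos, axis=1)
    hits = np.nonzero(wanted & (dist <= cutoff))[0]
    contacts = [
        CoordinationContact(
            ion_id=str(label),
            chain=str(model.chain_ids[i]),
            res_seq=int(model.res_seq[i]),
            res_name=str(model.res_name[i]),
            atom_name=str(model.atom_name[i]),
            distance=float(dist[i]),
            partner_class=_classify_partner(str(model.res_name[i]),
                                            str(model.atom_name[i]),
                                            bool(model.is_hetero[i])),
        )
        for i in hits
    ]
    contacts.sort(key=lambda c: (c.distance, c.chain, c.res_seq, c.atom_name))
    return contacts


def classify_sites(contacts_per_ion: dict[str, list[CoordinationContact]],
                   definitions: list[SiteDefinition] | None = None,
                   ) -> dict[str, str]:
    """Assign each ion to the best-matching site definition.

    The ion gets the label with the highest matched fraction above that
    definition's threshold; no match → ``"unassigned"``; an exact tie →
    both labels joined with ``|`` and a tie flag in the label.
    """
    definitions = definitions or DEFAULT_SITE_DEFINITIONS
    out: dict[str, str] = {}
    for ion, contacts in contacts_per_ion.items():
        scored = [(d.matched_fraction(contacts), d.label) for d in definitions]
        eligible = [(f, lab) for f, lab in scored
                    if f >= next(d.match_threshold for d in definitions if d.label == lab)]
        if not eligible:
            out[ion] = "unassigned"
            continue
        best = max(f for f, _ in eligible)
        winners = sorted(lab for f, lab in eligible if f == best)
        out[ion] = winners[0] if len(winners) == 1 else "|".join(winners) + " (tie)"
    return out


def max_coordination_distance(contacts: list[CoordinationContact],
                              partners: list[tuple[str, int]] | None = None) -> float:
    """Maximum heavy-atom distance over the named (res_name, res_seq)
    partners, or over all contacts when ``partners`` is None."""
    if partners is None:
        if not contacts:
            raise ValueError("no contacts")
        return max(c.distance for c in contacts)
    want = {(str(r).upper(), int(s)) for r, s in partners}
    have = {(c.res_name, c.res_seq) for c in contacts}
    missing = want - have
    if missing:
        raise ValueError(f"named partners absent from shell: {sorted(missing)}")
    return max(c.distance for c in contacts if (c.res_name, c.res_seq) in want)


def residence(aligned: Trajectory, ion_id: str | int, threshold: float = 5.0,
              site_label: str = "unassigned") -> ResidenceSeries:
    """Track an ion's displacement from its initial pose through an aligned
    trajectory; the ion counts as bound while displacement < ``threshold``.

    Displacement is measured in the TMD-aligned frame so whole-channel drift
    does not register as unbinding.
    """
    idx = _ion_index(aligned.topology, ion_id)
    pos = aligned.frames[:, idx, :]
    displacement = np.linalg.norm(pos - pos[0], axis=1)
    label = ion_id if isinstance(ion_id, str) else (
        f"{aligned.topology.chain_ids[idx]}/{int(aligned.topology.res_seq[idx])}")
    return ResidenceSeries(ion_id=str(label), times=aligned.times,
                           displacement=displacement, threshold=threshold,
                           site_label=site_label)


def residence_summary(series_list: list[ResidenceSeries]) -> pd.DataFrame:
    """One row per ion: site, bound fraction and bound-at-end flag."""
    rows = [{
        "ion_id": s.ion_id, "site": s.site_label,
        "bound_fraction": s.bound_fraction, "bound_at_end": s.bound_at_end,
        "max_displacement": float(s.displacement.max()),
    } for s in series_list]
    return pd.DataFrame(rows)
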