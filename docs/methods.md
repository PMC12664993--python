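# Methods

## Scope and model

The package treats a pLGIC pentamer as five chains of author-numbered
residues carrying Cα coordinates (plus hetero records for ions, waters and
lipids), and derives four families of conformational observables: global
gating coordinates (ECD twist, β-expansion), NTD lobe rigid-body traces,
a sphere-probe pore-radius profile, and cation coordination/residence
statistics. All selection is by author residue numbering, because that is
the numbering in which the DeCLIC domain boundaries and binding-site
residues are conventionally cited; mmCIF `label_seq_id` is ignored.

The default domain scheme is: NTD 35–195, ECD twist block 328–513, TMD
twist block 515–636, TMD alignment range 328–639, β1 340–345, β10 511–515.
These ranges are kept verbatim even though they are not mutually consistent
as a partition (residue 514 and 637–639 belong to no twist block, β10
straddles the ECD/TMD boundary); "fixing" them would change the metrics.
The NTD1/NTD2 lobe split and the prime-position map are deliberately
config-mandatory for real structures — there is no canonical default — and
the synthetic generator supplies its own (NTD1 35–115, NTD2 116–195;
2′ → 637).

## Gating coordinates

ECD twist of chain *c* is the IUPAC-sign dihedral among four Cα centroids:
the chain's ECD, the pentamer ECD, the pentamer TMD, and the chain's TMD.
On an ideal C5 assembly both pentamer centroids lie on the symmetry axis,
and the dihedral reduces exactly to the azimuthal offset between the
chain's ECD and TMD centroids about that axis; this identity is what the
generator uses to impose a target twist, and it pins the global sign
convention once (a negative twist is the direction observed in the
calcium-bound closed state). Note that the IUPAC dihedral is *symmetric*
under full point reversal (d,c,b,a), which the property suite asserts.

Centroids are uniform-weighted: on Cα-only selections uniform and
mass weighting coincide, and uniform weighting reproduces the "Cα COM"
definition exactly. Mass weighting (standard atomic weights via gemmi) is
available for mixed-atom sets.

Both gating coordinates are invariant under rigid motion of a frame, so
they are computed on raw frames without pre-alignment. "Range" summaries
are max − min over all chains, frames and replicates pooled per condition
(one number per condition); per-replicate ranges are emitted alongside,
since pooling conventions differ between studies.

## Trajectory alignment and lobe tracking

Frames are superposed on the reference's TMD Cα atoms (default 328–639,
all five chains) by proper-rotation Kabsch (scipy `align_vectors`; the
independent cross-check in the tests is MDAnalysis `rotation_matrix`).
Lobe displacement is measured from the frame-0 COM of each replicate — the
"initial pose" after equilibration — rather than from a deposited model.
COM RMSD of a single-point lobe COM equals its displacement magnitude,
which is the statistic summarized. The pore axis is estimated once from
the alignment reference and reused for every frame, so (radial, z) traces
share a fixed frame of reference.

The C5 axis estimate fits the plane through the five per-chain centroids
of the TMD selection and takes its normal (smallest principal direction of
those five points). Working on chain centroids rather than raw atoms makes
the estimate independent of whether the selection is a thin ring or a tall
cylinder; the sign is fixed toward the NTD-side Cα centroid.

## Pore profiling

At each axial sample z the profile reports the radius of the largest
sphere centred in the plane through z that touches no van der Waals
surface: a maximin objective over in-plane centre positions, evaluated
with full 3-D distances so atoms off the slice plane bound the probe
correctly. The search is a coarse in-plane grid (0.5 Å) seeding a
Nelder–Mead refinement, with the centre confined to a 5 Å disc about the
axis so the probe cannot escape sideways through an open wall; slices with
no bounding atom are capped (default 10 Å) and flagged. The in-test oracle
is an exhaustive 0.05 Å grid search. Default lining is all protein heavy
atoms within 15 Å of the axis (not M2-only, which would be fragile to
missing atoms); the vdW table is Bondi-type, recorded in config, hydrogens
excluded by default. z-step defaults to 0.5 Å over the TMD Cα extent.

## Ion analysis

Coordination shells collect O (optionally N) atoms within 3.5 Å of an ion
— a deliberately generous cutoff; the per-site distance bounds quoted for
DeCLIC (2.4–3.1 Å) are assertions about results, not detection parameters.
Contacts are classified geometrically (backbone carbonyl ⇔ protein atom
named `O`; other O names are side-chain; waters separate) and matched
against shipped site definitions: Site 1 (Asp76/Asp123/Asp124 side chains
+ Pro77/Asp123/Tyr129 carbonyls), Site 2 (Asp124/Gly126/Gly128 carbonyls),
Site 3 (Glu347 side chain + Pro434/Phe436/Leu477 carbonyls), Site 4
(Glu480 side chain + Gln476/Gly478 carbonyls). The default match threshold
of 0.5 lets the loosely coordinated Sites 2/4 classify from partial
shells. Classification is geometric only — it does not attempt to decide
whether a weak density is calcium or water.

Residence uses the TMD-aligned frame (whole-channel drift must not count
as unbinding): an ion is bound while its displacement from its frame-0
pose stays below 5 Å. Whether the "chains bound at end" count is taken per
replicate or pooled is not standardized; the report emits per-replicate
flags, and the acceptance script counts a chain as bound only if it stayed
bound in every replicate (the stricter reading).

## Synthetic generator

The generator emulates the DeCLIC architecture as Cα pseudo-atoms: a TMD
of 25 stacked 25-atom rings (ring radius = target pore radius + 1.7 Å
carbon vdW radius, realizing a piecewise-linear radius profile with a
1.5 Å inner-end constriction by default), an ECD blob containing the β1
cluster, NTD lobes as compact balls, and ion sites as correctly named O
shells at exact radii (defaults 2.4/2.85/2.5/2.75 Å for Sites 1–4,
mirroring tight versus loose coordination). The target twist is imposed by
placing each chain's ECD centroid at its TMD centroid azimuth plus the
target angle; because the β10 range ends on the ECD→TMD transition residue
(515, which lives in the topmost TMD ring and does not rotate with the
ECD), a small fixed-point solve places the β10 atoms so the azimuth
constraint and the exact β1–β10 separation hold simultaneously. Default state parameters are the
calcium-bound closed state: twist −26°, β-separation 12 Å.

Trajectories apply scripted rigid events (lobe/ECD/chain/ion translations,
rotations about the pore axis) cumulatively, plus seeded isotropic
Gaussian noise per atom per frame. The generator reproduces everything the
metrics measure but none of the physics that produces it: no correlated
thermal modes, no force field, no solvent, full-occupancy single-conformer
sites, and lobe "motion" as instantaneous jumps. Passing tests therefore
demonstrate that the measurement pipeline is exact and invariant where it
should be — not that real DeCLIC trajectories behave any particular way.

## Numerical choices

* Superposition requires ≥3 points and constrains the rotation proper
  (no reflections). Post-fit RMSD is reported.
* Dihedrals are undefined within 1e-12 of colinearity and raise.
* Missing residues inside a selection range produce a coverage fraction
  and a warning below the 0.8 floor, not an error; per-chain metric values
  become NaN on coverage failure rather than crashing the frame.
* Coordination contacts are sorted by (distance, chain, residue, atom
  name) so equidistant shells are deterministic.
* Trajectory times are converted ps → ns from the reader; formats without
  time stamps get 1 ns/frame indices. Times must be strictly increasing.
* PDB output carries 1e-3 Å precision; round-trip tests use that bound.

## Acceptance-script problem sizes

The acceptance script uses 4 replicates × 12 frames per condition at
0.15 Å thermal noise, sizes at which every scripted amplitude is resolved
well above the noise floor of a Cα-COM (σ/√81 ≈ 0.02 Å) while the whole
run completes in seconds. Scripted amplitudes are the study conditions
themselves (−26° state twist, −7°/−12° untwisting contrasts, 13/25 Å NTD1
excursions, one-of-five-chain ion escape).

## Known limitations

* The pore probe search is 2-D per slice; a strongly tilted or kinked
  channel would need tunnel tracing, which is out of scope.
* Site classification keys on residue identity and number; homologs with
  shifted numbering need custom site definitions (YAML-loadable).
* `estimate_axis` assumes an approximately C5 assembly; it is not a
  general symmetry detector.
* Ion residence requires the ion to exist in the topology for all frames;
  grand-canonical setups are not supported.
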