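# Methods

This note documents the models, conventions and numerical choices behind
`cnascreen`, in the order a screening campaign uses them.

## Structures, numbering and formats

All residue ranges are author numbering (PDB `resSeq` plus insertion
code), 1-based and inclusive at both ends, and nothing is ever
renumbered — split boundaries for deposited domains are quoted in author
numbering and the toolkit must match them literally.  Single structures
are the first MODEL of a PDB file; multiple MODELs are a trajectory and
must be read as one.  Alternate locations collapse to the
highest-occupancy conformer (ties: lexicographically first altloc).
Waters and common ions are dropped by default (`keep_solvent=True`
retains them); HETATM amino acids such as selenomethionine are kept and
map to their standard one-letter codes.  Written PDB output stores
coordinates to the format's 3 decimals and separates chains with TER
records; re-reading reproduces a model to that precision.  Multi-model
PDB is the contractual trajectory format; anything else should be
converted before analysis.

## Isopeptide triad detection

Detection is purely geometric, on heavy atoms (crystal structures lack
hydrogens).  A reactive Lys is any Lys whose NZ lies within
`proximal_max` (default 4.0 Å) of an Asn/Asp CG; the nearest such
acceptor is paired with it (ties broken by lower residue number, one
acceptor per Lys, so output is deterministic).  The nearest Glu CD or
Asp CG within `catalytic_max` (default 5.0 Å) of NZ is attached as the
catalytic residue, absent if none.  Bonds at NZ–CG ≤ `covalent_max`
(default 1.8 Å) are *covalent* — deposited formed bonds sit near
1.3–1.4 Å — otherwise *proximal* (a reaction-competent pose).  The
defaults separate those two populations cleanly and are all
user-configurable; a Lys with a truncated side chain (no NZ) is skipped
with a logged warning rather than failing the whole structure.

## Split design and validation

A split specification is four author numbers on one chain:
`catcher_first ≤ catcher_last < tag_first ≤ tag_last`.  The deleted
linker region is always derived as `catcher_last+1 … tag_first−1` —
single source of truth, never user-supplied — so
`|catcher| + |deleted| + |tag| = |parent range|` holds identically.
Validation enforces the Spy-like topology used throughout: reactive Lys
and catalytic residue in the catcher, acceptor in the tag, no triad
member deleted.  An N-terminal-tag (Snoop-like) split is rejected with
an explicit message rather than silently mis-assembled.  The catcher
becomes chain `C` and the tag chain `T`, keeping author numbers.

Terminal caps (ACE before the N-terminus, NME after the C-terminus) are
placed deterministically from ideal internal coordinates off the
terminal backbone (C–N 1.33 Å, C=O 1.23 Å, C–CH3 1.50 Å).  Simulation
preparation software would normally do this; deterministic placement
makes the outputs testable.  Newly created split termini stay ionic
(charged), matching how such systems are simulated.

Variants edit construct sequences: an N-terminal extension (literal or
an author-numbered range read off the parent), and at most one
C-terminal edit per variant (truncation or literal replacement).
Point mutants are given in author numbering as `X<num>Y` with the
wild-type letter checked.  Fusion constructs concatenate named parts
from an editable FASTA library; reports echo per-part spans and an
8-hex-digit checksum so masses are traceable to the exact part
sequences.  Masses are average (not monoisotopic), matching gel-based
"approx. kDa" statements.

The shipped part library contains the canonical published sequences of
the pQE-9-style His6 leader (MRGSHHHHHHGS), the HA tag, the GSGSGSG and
GSGESG linkers, mature E. coli maltose binding protein (370 aa,
40.71 kDa) and mCherry (236 aa, 26.72 kDa).  Where a campaign needs a
specific catcher/tag sequence that is not available, synthetic
stand-ins of the correct length can be drawn from average amino-acid
background frequencies (`random_protein_sequence`); mass checks with
such stand-ins test the assembly arithmetic and the authentic dominant
parts, not the exact residue composition of the variable segment.

The MD-preparation recipe is a YAML document recording the standard
explicit-solvent protocol for these systems: truncated-octahedral TIP3P
box with a 10 Å margin, monovalent-ion neutralization, three-step
minimization, heating to 310 K in three restraint stages
(5 kcal mol⁻¹ Å⁻² all-protein for 0.1 ns, backbone-CA-only for 0.4 ns,
unrestrained for 0.5 ns), then 200 ns NPT production at a 2 fs timestep
with bonds to hydrogen constrained.  Split systems are prepared
*without* the isopeptide bond (`isopeptide_bond_present: false`),
mimicking the initial recognition stage in which the tag binds the
catcher in a reaction-competent but unbonded pose; intact domains keep
the bond.

## Sequence screen

Candidate divergence uses a global Needleman–Wunsch alignment under
BLOSUM62 with gap open 10 and extend 0.5; identity is 100 × identical
columns over the alignment length excluding terminal gap overhangs
(`shorter_sequence` is available as an alternative denominator).  These
conventions are echoed in every identity matrix so the < 30 % screen is
reproducible; symmetry is guaranteed by canonicalizing argument order
before aligning.  A pair passes the screen iff its identity is strictly
below the threshold.

## Trajectory metrics

**Superposition/RMSD.**  Kabsch superposition via SVD with the
determinant correction, so the rotation is always proper; degenerate
(collinear or < 3-atom) selections are rejected.  The core-region RMSD
series uses frame 0 (the initial structure) as reference, superposes
each frame on the core backbone {N, CA, C, O} and evaluates the RMSD
over the same atoms.  The built-in core table lists the rigid
secondary-structure windows of the four candidate systems
(3phs 167–207, 4oq1 183–223, 3kptN 186–225, 3kptC 429–469).  For
comparing two *different* domains, residue correspondence comes from a
global sequence alignment and the RMSD from a Kabsch fit over the
aligned backbones.

**Van-der-Waals energy.**  The 12-6 form
`E = Σ ε_ij[(R_min,ij/r)¹² − 2(R_min,ij/r)⁶]` over all tag×catcher atom
pairs, no distance cutoff (the systems are small), deterministic sorted
summation for bit-stable results.  The shipped parameter table is a
minimal per-element set of AMBER-like protein values
(ε, R_min/2: C 0.086/1.908; N 0.170/1.824; O 0.210/1.6612; S 0.250/2.0;
H 0.0157/0.6); a user table can be substituted, and reports always name
the table.  Absolute reproduction of published energies would require
the full force-field atom typing; the toolkit's comparisons are
within-toolkit (intact domain vs split system), which is how the metric
is actually used.  For the intact domain, atom pairs connected by ≤ 3
covalent bonds across the catcher/tag junction are excluded (standard
1-2/1-3; 1-4 pairs are included at full weight, stated here and in
reports); bonds are inferred from heavy-atom distances < 1.9 Å (1.3 Å
to hydrogen).  Split systems have no covalent connection and no
exclusions.

**β-sheet hydrogen bonds.**  Reference pairs are all (tag N, catcher O)
and (catcher N, tag O) backbone pairs with N···O ≤ 3.5 Å in the
reference structure, each atom used at most once per direction (nearest
wins).  The per-frame series is the plain N···O distance; a frozen
trajectory reproduces the reference distance exactly — the series mean
short-circuits to the constant for a zero-spread series, avoiding
summation round-off in that degenerate case.

**Secondary structure.**  A Kabsch–Sander-style assignment: amide
hydrogens are rebuilt from ideal geometry (1.0 Å from N along the
preceding carbonyl C→O direction reversed; proline and chain starts
cannot donate), backbone H-bonds are scored with the electrostatic
energy `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol and
accepted below −0.5 kcal/mol, parallel/antiparallel bridge patterns are
chained into ladders, and ladder residues are labelled E.  Two
deliberate conventions: ladders merge bridges whose indices differ by
up to 2 on both strands (bulge-tolerant; strict single-step chaining
would leave alternating-bridge ladders as isolated B bridges), and
helix labels (H) require two consecutive i→i+4 bonds.  β-sheet content
of a range is the percentage of E labels, reported rounded to integer
percent — the granularity at which such estimates are quoted.

**Contacts.**  A frame is "in contact" if any heavy-atom tag×catcher
pair is within 4.5 Å; the contact fraction over frames is the proxy for
tag dissociation.

## Screening verdicts

With both trajectories present, the verdict is, in precedence order:
*dissociated* if the split system's contact fraction is below 0.95;
else *destabilized* if its mean core RMSD exceeds the domain's by more
than 1.0 Å, or its mean tag–catcher vdW energy retains less than half
of the domain's (energies are negative; "retains less" means a mean
above `0.5 × domain mean`); else *comparable*.  The underlying
published judgement is qualitative ("similar RMSD", "no dissociation");
these numeric defaults are explicit, conservative stand-ins, echoed in
every report, and changing them never alters the metric values.  A
failing system is reported with its error and does not abort the other
systems in a campaign.

## Synthetic fixtures

Fixtures exist to test measurement code, not to simulate physics.  The
two-strand fixture emulates the parallel pairing of the first and last
β-strand: two extended strands on a 3.5 Å-per-residue grid, chain `C`
(catcher) and chain `T` (tag), with a backbone H-bond ladder whose
designated N···O pairs sit at *exactly* the declared distance — the
acceptor carbonyls are tilted to achieve this, a metrology choice, and
the bridge pattern is laid out so the Kabsch–Sander assignment
recognizes the pairing and labels the inner residues E.  Planted triads
place the Lys NZ at exactly the declared distance from the Asn CG, side
chains straddling the inter-strand midpoint to stay clear of backbone
atoms; placement is deterministic and clash-free by construction.
Jitter trajectories add i.i.d. Gaussian noise (frame 0 unperturbed);
drift trajectories translate the tag chain by `i × drift_vector` in
frame i, emulating dissociation, and the expected contact-frame count
is computed in closed form from the same construction.  The synthetic
parent domain is a hairpin (outbound strand at y = 0, return strand at
y = −6.5 Å) spanning a split's author-numbered range, so a late residue
(the acceptor) lies spatially close to an early one (the reactive Lys);
the 6.5 Å separation keeps the bound-pose tag–catcher vdW energy
attractive.  The catalytic carboxylate is placed directly in range of
NZ even where the schematic fold puts the Glu backbone far away — the
side chain is stretched, which detection (reading only atom positions)
does not mind.  All fixtures are bit-reproducible given their spec and
seed, from a single seeded generator.

What the fixtures do **not** emulate: real side-chain packing,
solvation, force-field energetics, and the loop-length diversity of
real CnaB domains.  Passing fixture tests therefore demonstrates that
the *measurements* are correct, not that any particular real domain is
a good split candidate; conclusions about real systems require real
structures and real trajectories.

## Problem sizes and defaults in the shipped checks

The test suite and the acceptance script run at desk scale by design:
oracle suites use 100 random point sets / 100 lattice-based
Lennard-Jones systems of up to 100 atoms; trajectory fixtures use
8-residue strands with 20–200 frames; screening demonstrations use the
4oq1 split specification with 25-frame jitter/drift trajectories.
These sizes exercise every code path while keeping the whole suite in
seconds.  Benchmarks against deposited structures (mutual < 30 %
identity, 1.8–2.2 Å cross-domain backbone RMSD, seven β-strands in the
template domain, 43 % sheet content of the 4oq1 catcher range) require
the real PDB entries, which are not redistributed; supply them under
`data/pdb/` to run that check.

## Known limitations

* Secondary-structure assignment is a Kabsch–Sander-style
  reimplementation with the bulge-tolerant ladder convention described
  above; counts of very short or highly irregular strands can differ
  from other DSSP implementations by a segment.
* The per-element LJ table is intentionally minimal; energies are
  meaningful for within-toolkit comparison, not as absolute force-field
  values.
* mmCIF input, crystallographic symmetry expansion and hydrogen-aware
  analyses are out of scope; structures come in as fixed-column PDB.
* Split-site proposal is not automated: split boundaries remain user
  input, as in the screening protocol the toolkit implements.
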