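# Methods

## Scope and model

`pepkit` treats a peptide as an ordered multiset of monomers plus an
explicit bond table, not as an opaque molecule. Every construct the
notation can express — linear chains, caps, branches, disulfide and
head-to-tail macrocycles across one or several chains — flows through the
same pipeline: notation → resolved sequence → molecular graph → 2D layout
/ secondary-structure prediction → restrained 3D conformer → exports.

## Monomer dictionary

A monomer is a molecular fragment whose attachment points are dummy atoms
numbered by R-group: R1 the backbone amine, R2 the backbone carboxyl,
R3+ side-chain attachments. Each R-group records a leaving group (H for
amines/thiols, OH for carboxyls) that is deleted when the R-group bonds
and *retained* otherwise; retaining R2's OH is what makes a free
C-terminus a carboxylic acid. Supported leaving groups are H and OH —
enough for amide, disulfide and ester-free peptide chemistry; other
fragments are rejected at ingestion rather than guessed at.

Natural-analog assignment prefers an explicit annotation; otherwise a
Morgan fingerprint (radius 2, 2048 bits) Tanimoto comparison against the
20 standard residues is used, accepting the best hit at ≥ 0.5 and falling
back to alanine. Placeholders are stripped (replaced by H) before
fingerprinting so the comparison sees plausible free monomers. Ties take
the alphabetically first letter, making the assignment deterministic.

PDB residue codes come from a bundled chemical-component-dictionary table
where available (the 20 standard residues, ACE, NH2, AIB). Unknown
monomers get a code derived from a SHA-256 hash of the monomer name over
the [A-Z0-9]^3 space with linear probing against the already-allocated
set. A hash instead of a random draw trades the documented "random but
unique" behaviour for reproducibility: the same library always yields
the same codes, which keeps PDB output byte-stable under a fixed seed.

## Notation

The BILN grammar implemented: chains split on `.`, monomers on `-`,
trailing `(n,i)` groups parsed as bond annotations; whitespace around
separators is tolerated on input and never emitted. A bond id must occur
exactly twice, anywhere in the string. Monomer symbols may not contain
`-` or `.` (the separators); no escaping mechanism is provided.

HELM support is the peptide subset: `PEPTIDEk{...}` polymers with `.`
separators and bracketed multi-character symbols, one `$`-delimited
connections section (`PEPTIDEa,PEPTIDEb,p1:Ri-p2:Rj`), empty group and
annotation sections, and the literal `V2.0` suffix. Connection bond ids
are renumbered 1..k in order of appearance on conversion — ids are
arbitrary labels; only the pairing is information.

## Sequence resolution

Backbone bonds are created right-to-left-neighbor within each chain:
R2(i)→R1(i+1) for amino acids, a cap using its single R-group on either
side. Caps are only legal at chain termini. Annotated bonds consume the
R-groups their `(n,i)` pairs name; a slot claimed twice (backbone +
annotation, or two annotations) is a hard error. Whatever R-group is left
unclaimed is scheduled for capping by its leaving group. All bonds formed
between monomers are single bonds, which covers the amide, disulfide and
thioether linkages the notation is used for.

### Atom naming

Heavy atoms are named per residue: N, CA, C, O (OXT for the capping
oxygen of a free C-terminus), then a breadth-first walk from CA assigns
greek letters by distance (B, G, D, E, Z, H) with branch numbers when a
level holds several atoms. Branch numbering is deterministic: numbers
propagate along branches (CD1 → CE1); a level whose atoms inherit
distinct parent numbers keeps them; a single atom closing a ring between
symmetry-equivalent branches stays unnumbered (Phe/Tyr CZ) while an
asymmetric closure inherits the smaller branch number (Trp CH2);
otherwise atoms are ranked by subtree size, atomic number, bond order to
parent and adjacency to already-numbered atoms. Side-chain dummy atoms
whose leaving group is OH are walked as the oxygen they become, which is
how Asp/Glu get OD2/OE2. The scheme reproduces the PDB v3 heavy-atom
names of all twenty standard residues (the table in
`pepkit.naming.STANDARD_HEAVY_ATOM_NAMES` is asserted in the tests).
Hydrogens inherit their parent's suffix: HB2/HB3 on a methylene,
HB1-3 on a methyl, HG1 on OG1, H on a mid-chain amide nitrogen, H1-H3 on
a free N-terminal amine. Atoms the walk cannot reach (e.g. an N-methyl
carbon) get element+counter names, with CN reserved for the N-methyl
case.

## Molecule assembly

Monomers are inserted in global index order; bonds are added between
attachment atoms after all atoms exist; placeholder dummies are then
deleted (H leaving group) or mutated into a real oxygen (OH), and the
result is sanitized. Stereochemistry comes exclusively from the monomer
structures — assembly neither creates nor destroys stereocenters. A
radical left by bad leaving-group bookkeeping or a sanitization failure
aborts with the offending monomer named where it can be attributed.

### 2D layout

*Standard* mode delegates to the toolkit's CoordGen layout, which is
deterministic and handles macrocycles well.

*Extended* mode pins backbone atoms (N, CA, C per residue; the cap
attachment atom) to an ideal zig-zag and lets the depictor place the rest.
The zig-zag uses a 150° backbone angle: shallow enough that a proline
pyrrolidine — whose pentagon edge leaves CA 108° off the CA–N axis —
clears the pinned carbonyls on one side (at the conventional 120° the
pentagon edge passes 12° ≈ 0.3 bond lengths from the carbonyl, a
guaranteed clash). Proline rings are re-placed explicitly on the regular
pentagon through CA and N, on whichever side has more clearance.
Remaining clashes are resolved by reflecting side chains across their
CA–CB axis (the 2D analog of rotating the CA–CB torsion), greedily, up
to 50 rounds; if a clash below δ_min survives, best-effort coordinates
are kept under a warning. δ_min defaults to half the median 2D bond
length. Peptides whose annotated bonds close a macrocycle cannot be
drawn extended; they fall back to the standard layout with a warning.

## Secondary-structure prediction

The score of two equal-length fragments is
S_AB = score_AB / √(score_AA·score_BB) with score_XY the position-wise
substitution-matrix sum; gaps are never allowed, so a shorter query
slides over a longer entry and vice versa. The matrix is a parameter and
defaults to BLOSUM62 — a structure-aware matrix from the same standard
collection can be substituted without code changes, and keeping a single
well-known default makes every test value reproducible. The threshold
defaults to 0.65, the midpoint of the 0.6–0.7 band in which retrieval is
useful; raising it can only remove hits (asserted as a property).

Each retained window votes its annotation onto the query positions it
covers, one vote per hit by default (score-weighted voting is available
but off, since equal weighting is the simpler assumption and the tested
behaviour). Position ties resolve by the fixed priority
H > E > G > T > S > B > `-`, putting the categories that drive 3D
restraints first. Positions with no votes stay `-`; sub-threshold hits
contribute nothing at all. Queries outside 5–20 residues warn but run.

## Synthetic reference data

The bundled reference database stands in for a curated set of bioactive
peptide conformations. It contains 50 unique random sequences of 5–30
residues over the 20 standard letters; annotation strings are built from
category runs — helix runs of at least 5, strand runs of at least 3,
short coil filler — drawn at 30% helix / 10% strand / 60% coil, matching
the composition reported for such curated sets. Everything regenerates
byte-identically from (spec, seed); the default seed is 2023.

What passing against this database shows: the matching, voting and
restraint machinery is correct (self-retrieval is exact, oracle
equivalence holds). What it does not show: predictive accuracy on real
peptides, which depends on a database of real conformations the package
deliberately does not ship. The loader accepts any TSV or annotated
FASTA with equal-length (sequence, annotation) pairs, so a real database
drops in unchanged.

## 3D conformers

Helix runs of ≥ 5 residues over {H, G} with at least as many H as G are
restrained with O(i)–N(i+4) ∈ [2.7, 3.3] Å (the backbone hydrogen-bond
donor–acceptor distance) and CA(i)–CA(i+4) ∈ [5.8, 6.6] Å (one helical
turn); standalone 3/10 runs are left unrestrained (conservative: the
category is rare and its ideal geometry differs). Strand runs of ≥ 3 E
residues get CA(i)–CA(i+2) ∈ [6.2, 7.2] Å, the spacing of an extended
strand; inter-strand pairing is not restrained because a category string
cannot say which strands pair. All values live in `RestraintConfig`.

Restraints are injected into the default distance-geometry bounds matrix
by *clamping*: new lower = max(default, ours), new upper = min(default,
ours), so injection can only tighten; an infeasible clamp (lower above
upper, e.g. a window below the van-der-Waals floor) is an error rather
than a silent loosening. After triangle smoothing, embedding uses
ETKDGv3 with a caller-supplied seed; random initial coordinates are used
for molecules above 200 atoms (and on retries), where the default
eigenvalue start frequently fails. Up to 3 attempts with consecutive
seeds are made before an error carrying diagnostics.

Minimization (MMFF94 when parameterized, UFF otherwise; 500 iterations)
holds each restraint window with a flat-bottomed harmonic constraint at
force constant 500 kcal·mol⁻¹·Å⁻²: an unrestrained relaxation of a
distance-geometry helix reliably unfolds it, and 100 kcal·mol⁻¹·Å⁻²
proved too weak to hold every window on some starts. Identical inputs
and seed give bit-identical coordinates.

Geometry checking widens each window by −0.5/+0.3 Å to absorb
minimization drift before declaring a restraint violated, and reports
backbone φ/ψ per residue alongside.

The pipeline is intended for peptides up to ~20 residues; beyond that,
distance geometry plus category-string restraints is the wrong tool and
dedicated protein-structure methods should be used.

## PDB output

The writer emits ATOM (standard residues) / HETATM (everything else)
records with residue codes, chain letters A, B, ... per notation chain,
per-chain residue numbering, IUPAC atom names (names shorter than four
characters start in column 14), occupancy 1.00, B-factor 0.00, element
symbols, TER after each chain, CONECT in both directions for each
annotated bond (backbone connectivity is implied by residue order), and
END. Output parses with Biopython's PDB reader, asserted in the tests.

## Problem sizes used in the test suite

The suite and the acceptance script run entirely on generated inputs:
the 25-monomer library, the 50-entry synthetic database, the six printed
notation examples, peptides up to 20 residues and ~330 atoms for
embedding. These sizes exercise every code path (multi-chain, macrocycle,
cap, non-natural residue) while keeping a full run near half a minute.

## Known limitations

* Leaving groups beyond H/OH are rejected, not modeled.
* No protonation-state or tautomer enumeration; histidine is fixed in the
  ND1-H tautomer the library encodes.
* Extended 2D layout of macrocyclic peptides falls back to the standard
  depiction.
* β-sheet restraints are intra-strand only.
* The similarity matrix default (BLOSUM62) is a general-purpose choice; a
  structure-fitted matrix may retrieve better on real data.
* Conformer output is a single restrained conformer, not an ensemble, and
  carries no energy ranking.
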