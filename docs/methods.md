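# Methods

This note documents the models, conventions and numerical choices behind
tcrface, and what the synthetic fixtures do and do not establish about real
structures.

## Structure model and file handling

Coordinate files (PDB/mmCIF, parsed via gemmi) are reduced at read time to
heavy atoms of the 20 standard amino acids: hydrogens, waters, ions and
ligands are dropped, because every implemented analysis is protein-protein
and heavy-atom based. Residue identity is the author's chain id, residue
number and insertion code, kept verbatim — no renumbering — so that residue
labels in reports match the labels crystallographers use. Alternate
locations are resolved per atom-name group to the highest-occupancy
conformer, ties going to the first conformer in the file; this never
increases the atom count. The PDB writer stores per-atom confidence in the
B-factor column, multiplying by 100 when the values are on a 0–1 scale so
pLDDT round-trips on the conventional 0–100 scale.

Chain roles (TCR α/β, MHC heavy, β2m, peptide), CDR/HV4 loop intervals and
the conserved variable-domain disulfide cysteines come from a JSON config,
never from sequence analysis. Default loop intervals follow IMGT-style
bounds (CDR1 27–38, CDR2 56–65, HV4 81–86, CDR3 105–117) but are always
overridable: loop definitions differ between numbering schemes, and a
published contact table's loop assignment cannot generally be recovered
from coordinates alone, so the config is authoritative.

## Contacts

A contact is any heavy-atom pair across the two binding partners at
distance ≤ 4.0 Å (inclusive), the common crystallographic convention for
interface contact accounting. Each pair counts once; polar classification
reassigns a subset of pairs, it never adds or removes them, so
|vdw| + |hbond| + |saltbridge| equals the contact count.

Because the structures carry no hydrogens, hydrogen bonds and salt bridges
use heavy-atom distance criteria without angle terms: a salt bridge is a
basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2; His ND1/NE2) within
4.0 Å of an acidic carboxylate oxygen (Asp OD1/OD2; Glu OE1/OE2); a
hydrogen bond is a donor-capable N/O within 3.5 Å of an acceptor-capable
N/O, salt bridges taking precedence. Both cutoffs are parameters. These are
deliberately simple, explicit and testable criteria; angle-aware detection
would require placed hydrogens, which is out of scope.

Contact tables mirror the eight-loop layout (CDR1/CDR2/HV4/CDR3 × two
chains) with targets peptide and MHC. Percentages are integers,
`round(100·count/total)` rounded half away from zero; this rule reproduces
every recomputable percentage in the published table this layout mirrors.
Two text-level percentages in that source disagree with their own printed
counts (90/128 printed as 71% where the arithmetic gives 70.3%; 36/46
printed as 79% where the arithmetic gives 78.3%); `chain_share` reports the
arithmetic value (70, 78) rather than chasing the typo. Framework (non-CDR)
TCR contacts are reported in their own row rather than dropped: the
published tables have none, but synthetic or unusual inputs may.

SASA is a deterministic Shrake–Rupley implementation: each atom's sphere is
expanded by the 1.4 Å probe and sampled with a Fibonacci lattice (default
960 points; fixed, so results are bit-reproducible), and the unoccluded
fraction scales the expanded-sphere area. Radii are a fixed Bondi-style
heavy-atom set (C 1.70, N 1.55, O 1.52, S 1.80 Å, …) shipped in
`tcrface/sasa.py`. Accuracy is validated against closed forms (isolated
sphere, two-sphere spherical caps) and cross-checked against biotite's
independent implementation; with 960 points per atom the per-structure
totals agree to well under 2%. Peptide burial computes the peptide's SASA
twice — in the TCR-deleted pMHC subcomplex and in the full complex — and
reports the difference and its percentage of the free value. Adding
occluders can only bury surface, so bsa ≥ 0 holds exactly, sampling
included.

## Docking geometry

Published crossing/incident-angle tools differ in their anchor choices and
are not restated in enough detail to clone; the constructions here are
fixed and documented so the numbers are reproducible:

- **TCR axis**: from the Vα to the Vβ intrachain-disulfide centroid (mean
  of the two Cys Sγ atoms, Cβ when Sγ is absent) — the same spheres
  conventionally drawn as axis markers on TCR–pMHC figures.
- **Groove axis**: first principal component of peptide Cα positions,
  oriented from N to C terminus. **Origin**: the peptide Cα centroid.
- **Platform normal**: least principal component of the MHC α1α2 Cα cloud
  (optionally restricted by `mhc_platform_range`, e.g. residues 1–180 for a
  real class I heavy chain), oriented toward the TCR centroid. Principal
  components are robust to both the synthetic slab fixtures and real
  platforms, unlike helix-subset fits.
- **Crossing angle** = planar angle between TCR axis and groove axis after
  projecting both into the platform plane, folded into [0°, 180°);
  **incident angle** = 90° minus the TCR-axis/normal angle, folded into
  [0°, 90°]; **peptide shift** = scalar projection of the disulfide-centroid
  midpoint (relative to the groove origin) onto the groove axis, negative
  toward the N terminus. The folding conventions make small printed values
  (tens of degrees, a few Å) representable without sign ambiguity.

All three descriptors are invariant under global rigid motion (tested to
1e-6). Superposition is closed-form Kabsch (SVD with determinant
correction); collinear point sets are rejected as ill-defined.

RMSD profiling superposes the unbound structure onto the bound one over the
backbone of the fit selection (e.g. the MHC), then reports per-residue
backbone and all-heavy-atom RMSD with **no further fitting**, plus pooled
summaries — the standard way of asking how much a peptide moved upon TCR
engagement. CDR RMSD fits on the variable-domain framework (non-CDR)
backbone and pools over CDR residues. Residue correspondence uses author
numbering when the chains share it (and amino acids agree); otherwise
identical-length, identical-sequence chains pair positionally; anything
else errors with the unmatched residues listed, never a silent guess.

## Model accuracy

fnat counts residue-level native contacts (any heavy-atom pair ≤ 5.0 Å),
distinct from the 4.0 Å atomic-contact tables; the two cutoffs live in
separate parameter types to prevent cross-talk. Interface residues for
I-RMSD carry any heavy atom within 10.0 Å of the partner; the metric
superposes model onto reference over the paired interface backbone and
reports that selection's RMSD. L-RMSD fits on the receptor backbone and
reports ligand backbone RMSD. Receptor/ligand default to pMHC/TCR
(overridable). β2m, when present in both structures, joins the receptor
superposition but never the interface definition, since predicted models
are often built from the α1α2 platform only. DockQ combines the three
metrics with the standard constants d1 = 1.5 Å, d2 = 8.5 Å; CAPRI tiers use
the usual fnat/RMSD thresholds with boundary values inclusive (a model at
fnat 0.5 with I-RMSD 1.0 Å is High). DockQ is affine in fnat at fixed
RMSDs, so the formula can be inverted in closed form to recover the fnat
implied by a published (I-RMSD, L-RMSD, DockQ) row — useful as a
consistency check when the models themselves are not distributed.

Fewer than 50% pairable reference interface residues is an error rather
than a silently truncated metric.

## Confidence and triage

Residue pLDDT is the unweighted mean of the residue's heavy-atom values;
per-atom confidence is ingested from the B-factor column or a sidecar TSV,
never recomputed. Scale is auto-detected per structure: a maximum ≤ 1.0
means a 0–1 scale, rescaled ×100. I-pLDDT averages residue pLDDT over
interface residues — the 4 Å heavy-atom rule, pooled over **both** partners
(the definition is side-symmetric; a side-restricted variant exists behind
a flag). An empty interface is an error, not zero. Triage uses strict
inequalities (model confidence > 0.875, I-pLDDT > 87.5): boundary-exact
scores fail. The I-pLDDT threshold is treated as a single number on the
0–100 scale even where sources quote it as 0.875. Ranking is by model
confidence, descending, ties broken lexicographically by model id so
reports are deterministic.

## Synthetic fixtures

The generator builds geometric idealizations, not proteins: a poly-alanine
10-mer peptide spaced 3.5 Å per residue along the groove axis; an MHC
platform of two wall rows (y = ±6 Å) and a floor sheet (z = −3.5 Å) whose
Cα covariance makes the plane normal exact; a β2m blob below the floor; and
two TCR domain clusters 20 Å apart whose Cys-pair Sγ atoms average exactly
to the domain centroids. The TCR axis direction and midpoint are computed
from the requested (crossing, incident, shift), so at zero noise the
geometry module recovers the parameters exactly; the acceptance sweep holds
to 0.5°/0.2 Å over 210 grid points including the published 28°/5° and
28°/7° combinations. Optional CDR "loops" hang 4.2 Å above the peptide and
walls to guarantee a nonempty 4 Å interface for contact, burial and
I-pLDDT analyses. Default TCR height is 16 Å above the groove; incident
angles above 60° are rejected as geometrically infeasible (the domains
would enter the platform).

Decoys apply an exactly known rigid transform (rotation about the moved
subset's centroid, then translation) to the TCR or the whole complex, so
L-RMSD for pure ligand translations equals |t| exactly and rotation decoys
have closed-form RMSDs. Confidence assignment draws per-atom values from
Normal(mean, sd) clipped to [0, 100] with separate interface and
non-interface means. Ensembles displace each residue rigidly by its
amplitude in a seeded random direction, so per-residue RMSD equals the
amplitude exactly when the fit selection is unperturbed. All randomness
flows from explicit integer seeds recorded in output metadata; equal seeds
give bit-identical coordinates.

**What passing does and does not show.** The fixtures exercise every metric
on inputs with known ground truth, so they establish correctness of the
geometry, contact accounting, grading and triage arithmetic. They do not
establish agreement with any particular deposited structure: absolute
published values that require real coordinates (raw contact counts, the
28°/5°/7° angles on the crystal structures, the 273 Å² burial, the
0.53/0.62 Å CDR RMSDs, absolute I-RMSD/L-RMSD of real predicted models) are
validated only at the level of formula consistency and parameter recovery.
Fixtures have no side-chain rotamers, no sequence realism and no packing
forces; SASA and polar-contact results on them are internally consistent
but not biophysically meaningful magnitudes.

## Problem sizes and determinism

The default fixture has ~450 heavy atoms; the analysis scripts use a
210-point geometry grid, 10-member ensembles and a 7-point decoy series,
sizes chosen so the full analysis set and test suite run in well under a
minute on one core while exercising every code path. SASA uses 960 sample
points per atom by default (5000 in the spherical-cap oracle test). All
tests are seeded; hypothesis property tests run with fixed example counts.
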