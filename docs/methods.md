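# Methods

This note records the models behind each analysis stage, the parameters
that matter, the numerical conventions, and what the synthetic fixtures
do and do not establish.

## Structure model and parsing

Coordinate files are read with gemmi and reduced to a plain
chains → residues → atoms model keyed by *author* identifiers (auth chain
id, auth_seq_id, insertion code), because sites in the literature are
cited in author numbering (G148, Q109, CLA807).  Policy on read: model 1
only; atoms with zero occupancy dropped; alternate locations resolved to
the highest-occupancy conformer with ties broken by the lexicographically
smaller altloc; hydrogens stripped (deposited cryo-EM models are
heavy-atom — hydrogens appear only as refinement artifacts, and all
distance criteria here are heavy-atom criteria).  Coordinates stay in the
file's frame; nothing is re-centered.

Residues are classified into functional categories by a component table
(CLA → chlorophyll *a*, CHL → chlorophyll *b*, BCR/LUT/XAT/NEX →
carotenoid subtypes, PQN → quinone, SF4 → Fe₄S₄ cluster, HOH → water, a
six-code lipid list LMG/LMU/LHG/SQD/DGD/PG).  Amino acids are recognised
through gemmi's tabulated residue dictionary; anything else falls back to
*other*, and the census reports unclassified hetero codes so the table
can be extended per deposition — lipid and detergent codes vary between
entries, which is why the table is configuration rather than a constant.

## Inventory

Counts are per residue (one HOH residue = one water molecule; one SF4 =
one cluster).  "Protein subunits" is operationalised as polymer chains
holding at least one amino-acid residue.  Two pigment sums are reported
because the four-class sum (Chl a + Chl b + β-carotene + lutein) is the
conventional whole-complex pigment total while violaxanthin and
neoxanthin are sometimes included and sometimes not; reporting both
removes the ambiguity.  The model-to-model comparison walks paired chains
site by site (auth_seq_id + insertion code) and lists every site whose
component assignment differs or exists in only one model; waters are
excluded since their numbering is not stable across depositions.

## Membrane frame and TM helices

The membrane normal is the eigenvector of the smallest eigenvalue of the
covariance of chlorophyll Mg positions, origin at their centroid — the
chlorophyll layer of a light-harvesting complex is parallel to the
membrane, so its thin direction is the normal.  At least 10 chlorophylls
are required; pigment-poor models must supply a frame explicitly.  Sign
convention: the first chain's first CA projects non-negatively.  The
estimate degrades gracefully: on a jittered slab of ~120 chlorophylls
with ±4 Å thickness the recovered normal is within 1° of truth
(tested); error grows as the slab thickens or the pigment count drops.

Helix detection is pure CA geometry, chosen because deposited models
carry no hydrogens for DSSP-style assignment: residue *i* is helical iff
|CA(i)−CA(i+3)| ∈ [4.5, 6.0] Å and |CA(i)−CA(i+4)| ∈ [5.7, 7.0] Å
(evaluated only where i…i+4 are contiguous in author numbering); maximal
runs of ≥ 10 marked residues become segments; single-residue holes are
bridged, but numbering gaps > 1 (modelling gaps) split segments.  A
segment is transmembrane iff its terminal CA projections straddle the
midplane and span ≥ 15 Å along the normal (min_span and the 15 Å default
half-thickness match a thylakoid hydrophobic core; both configurable).
There is no community-standard TM-helix counting convention, so counts on
real depositions carry a few-helix tolerance by construction.

## Mg coordination and hydration

Axial ligands are N/O/S heavy atoms of *other* residues within 2.9 Å of
the Mg (axial Mg–O/N bonds are 2.0–2.6 Å; 2.9 absorbs coordinate error
at ~2–2.5 Å resolution).  The site's own atoms — in particular the four
tetrapyrrole nitrogens — are never ligands; coordination number is
4 + |axial ligands|.  Ligands are classified as protein backbone
(N/CA/C/O/OXT) vs side chain, water, lipid (ester/galactosyl oxygens do
ligate Mg), pigment, other.  Hydration class is anhydrous / mono- /
di-hydrated by the axial water count, and the per-type census reports the
fraction of Chl *a* and Chl *b* sites with ≥ 1 axial water plus their
b : a ratio (undefined and flagged when a type is absent or the Chl *a*
fraction is zero).

Hydrogen bonds use a hydrogen-free geometric criterion (coordinates lack
hydrogens; no criterion is standard enough to assume): donors are N atoms
and hydroxyl oxygens (OG/OG1/OH) plus water O; acceptors are O atoms and
His ring N; a bond requires donor–acceptor distance ≤ 3.5 Å and
antecedent–donor–acceptor angle ≥ 90°, where the antecedent is the
donor's nearest bonded heavy atom.  Water donors are exempt from the
angle term (no antecedent).  Each bond is reported once; O–O pairs where
either oxygen could donate carry an ambiguous-roles flag rather than a
guessed assignment.

## Excitation-pathway network

Nodes are chlorophyll Mg atoms; an edge exists iff the Mg–Mg distance is
≤ the cutoff, default 23 Å, with the threshold closed (a pair at exactly
23.0 Å is connected).  Mg–Mg centre distance is the metric — not minimal
ring–ring distance — matching how such maps are drawn.  Edge width
weight is the linear ramp cutoff − distance.  Edges are flagged
inter-subunit (different chains) and inter-group (different monomers
under a chain → group mapping).  "Most likely inter-subunit pathway" is
operationalised as the minimum-distance edge per chain pair; distance is
the only criterion (no orientation factors, no excitonic couplings — by
design this module stops at geometry).  The KD-tree implementation is
required, and tested, to be identical to the all-pairs O(n²) scan.

## Interface analysis

A residue contact is any heavy-atom pair ≤ 4.0 Å (standard van der Waals
contact distance) between residues of two disjoint groups; hydrogen
bonds re-use the criterion above; a cofactor bridge is a non-protein,
non-water residue in contact with both groups within the same cutoff.  A
cofactor whose own chain belongs to one group may still bridge (the
report records which convention fired), since cofactor chain assignment
varies between depositions.  Analyses of a soluble partner's binding
interface (e.g. an electron-donor protein against the lumenal face) use
these same operations with the partner as one group — there is no
bespoke stage.  Sequence-window composition (count + positions of a
residue type in an inclusive author-numbering window) covers
charge-patch arguments such as lysine clusters.

## Superposition and clashes

Kabsch: closed-form SVD solution for the proper rotation minimising CA
RMSD over a chain pairing matched by author numbering; the reflection
branch is corrected via the determinant sign, and degenerate inputs
(< 3 pairs, collinear point sets) raise rather than return garbage.
Clashes: distance < r₁ + r₂ − tolerance (strict), radii C 1.70, N 1.55,
O 1.52, S 1.80, Mg 1.73, Fe 1.56 Å, fallback 1.70, tolerance 0.4 Å.  A
chain pair "would clash" when ≥ 10 atom pairs clash — the threshold
separates genuine overlap from grazing surfaces and is configurable.
Overlap analysis anchors a reference complex on part of a host via a
user-supplied chain pairing (cross-entry chain naming is inconsistent, so
the pairing is explicit input, not inference) and counts clashes between
chosen probe chains of the superposed reference and chosen host chains.

## Rigid-body ensemble

The two halves of a dimer are treated as rigid bodies; the moving group
is rotated about a pivot by a random axis (uniform on the sphere) and a
random angle (uniform on [0, max_angle], default 13° — the scale of
monomer–monomer rocking in flexible photosynthetic dimers), optionally
with isotropic coordinate noise.  This sampling is uniform in axis and
angle, *not* Haar-uniform on SO(3); the quantity of interest is the
angular bound, which this parameterisation makes explicit.  The default
pivot is the centroid of moving-group atoms within 8 Å of the static
group — the natural hinge of an interface-mediated rocking motion.
Read-outs: per-conformer distances for chosen site pairs with 0.5 Å-bin
histograms; PCA over flattened moving-group CA coordinates (per-atom
centred, eigenvalues by SVD of the centred data matrix), with the top-3
variance fraction reported because rigid rotations about a fixed point
span a three-parameter manifold; and recovery of the angular bound by
re-deriving each conformer's rotation with the package's own Kabsch
about the pivot and taking the maximum angle — exact at zero noise, and
within 10 % of the simulated bound at 1,000 conformers (tested).  The
ensemble is a simulation stand-in for motions that, in experiments, are
measured from particle images; recovery on the simulation validates the
estimator, not any particular experimental value.

## Synthetic fixtures

The generator emulates exactly the features the analyses consume: ideal
α-helices (rise 1.5 Å, 100°/residue, CA radius 2.3 Å) crossing a ±15 Å
slab, one chain each; minimal chlorophylls (Mg + NA/NB/NC/ND at 2.05 Å +
four methine carbons, no phytol tail) with legal component codes;
carotenoid and lipid stand-ins as short carbon chains; axial waters at
2.2 Å along the ring normal for a designated fraction of each
chlorophyll type (defaults 0.2 for Chl *a*, 0.8 for Chl *b*, making the
b : a hydration ratio exactly 4 — the regime where water
preferentially accompanies Chl *b*).  The C2 dimer is an exact 180°
rotation about z, with a planted interface: symmetric
backbone-carbonyl→hydroxyl hydrogen-bond pair, a symmetric amide pair,
one lipid whose ends touch a chlorophyll and a carotenoid across the
axis, and one cross-monomer chlorophyll pair at a chosen Mg–Mg distance
(default 15 Å).  Bulk chlorophylls are kept > 16 Å from the C2 axis so
their mirror images sit > 23 Å away and the planted pair is the *only*
inter-group edge.  Every manifest entry is computed by brute-force scans
inside the generator, independent of the analysis code it tests, on
coordinates frozen at mmCIF precision (10⁻³ Å) so that manifests match a
re-parse bit for bit.  Generation is deterministic: same spec + seed →
byte-identical files.

What passing on fixtures does *not* show: the fixtures have no real
chemistry (no phytol tails, schematic backbone geometry, no density-based
ambiguity), so they validate geometry, bookkeeping and thresholds — not
pigment identification, model building, or behaviour on noisy real
coordinates.  Checks against deposited reference structures exist
separately and run when the files are present locally.

## Problem sizes and determinism

Default test and acceptance conditions: fixtures with 4 helices × 24
residues and 10 + 10 chlorophylls per monomer; 1,000 random
configurations of 12 chlorophylls for the network oracle; 1,000
conformers for ensemble recovery; 120-site slab for normal recovery.
These sizes make the full suite run in well under a minute while leaving
every statistical criterion comfortably determined.  All randomness goes
through numpy Generators seeded explicitly; the acceptance script derives
every seed from its --seed argument.

## Known limitations

* TM-helix counting has no canonical convention; counts on real models
  are tolerance-bounded, not exact.
* The hydrogen-bond criterion is heavy-atom geometric; protonation
  states and bifurcated bonds are out of scope.
* The network is distance-only: no Förster rates, orientation factors or
  coupling energies.
* Assemblies are used as deposited — no symmetry expansion from
  crystallographic/point-group operators.
* The ensemble's pivot approximates an interface hinge; experimentally
  observed pivot points of any particular complex are not reproduced
  from coordinates alone.
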