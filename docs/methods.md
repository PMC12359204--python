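# Methods

`lanthimodel` models the solution-state conformational ensembles of
lanthipeptides: ribosomally synthesized peptides whose serine/threonine
residues are dehydrated (to dehydroalanine, Dha, and dehydrobutyrine, Dhb)
and then cyclized by cysteine thiols into lanthionine and
methyllanthionine thioether rings.  The package covers the whole desk-scale
workflow — topology description, conformer generation with ring closure,
ensemble-averaged NOE fitting, and atropisomer filtering — with a
simplified, declared score function in place of a full molecular-mechanics
force field.

## Topology model

A peptide is a sequence of residue specs (canonical L-amino acids,
D-amino acids by their PDB component codes, Dha/Dhb with sp2 alpha carbons,
and 2-aminobutanoic acid for methyllanthionine donors) plus a list of
rings, each a donor (formerly dehydrated) position and an acceptor
(cysteine-derived) position with a ring type and a bridge-chirality label
(default DL, the most common configuration; the label is carried, not
enforced geometrically, because ring stereochemistry depends on the
maturation enzyme and substrate).  Invariants: a residue may appear at most
once as donor and once as acceptor, and no residue may carry two thioether
bonds.  Ring *spans* are the inclusive sequence intervals between donor and
acceptor; pairs of rings are classified as adjacent (disjoint spans),
nested (strict containment) or overlapping (interleaved).  A ring is
"helix-compatible" when its acceptor lies three or four residues past the
donor — roughly one helical turn.

## Conformer geometry

Conformers use a reduced atom set: backbone N, H, CA, HA, C, O per residue,
CB for non-glycine residues, the beta-methyl CG for Dhb/Abu/Thr-derived
residues and SG for cysteines.  This is sufficient for ring geometry and
for the NOE-active protons (amide H, alpha H, methyl pseudoatoms); larger
sidechains are deliberately truncated at CB.  Chains are built by NeRF
internal-coordinate extension with ideal (Engh–Huber-class) bond lengths
and angles, trans peptide bonds, and chirality carried by the sign of the
C–N–CA–CB branch torsion (+122.5° for L, −122.5° for D).  Dha/Dhb get
planar sp2 geometry at CA (120° angles, CB anti to C, no HA); Dhb's methyl
is placed Z (cis to N), the configuration produced by anti dehydration of
threonine.

### Thioether crosslink

The closed ring is described by the C–S bond (donor CB to acceptor SG,
target 1.81 Å), two flanking angles (CA–CB–SG 109.5°, CB–SG–CB 98°),
three dihedrals across the bond region, and — for methyllanthionine — an
improper dihedral at the bridge carbon plus two methyl angles.  These
targets are standard thioether values exposed as configurable data, not
fitted constants; users with force-field-derived numbers can substitute
them.  `measure_crosslink` reports each term's deviation and a weighted
quadratic penalty; the default weights (bond 100 Å⁻², angles 0.02 deg⁻²,
dihedrals 0.002 deg⁻²) make a 0.05 Å bond error comparable to a ~3.5°
angle error, keeping bond closure dominant.

### Ring closure

Closure is cyclic coordinate descent (CCD) over the torsions inside the
ring span — donor ψ, interior φ/ψ, acceptor φ, plus the acceptor χ1 — each
set in turn to the angle minimizing a normalized bond + flanking-angle
objective (coarse 5° scan then bounded 1-D refinement).  Torsion rotations
are exact rigid rotations of the downstream atoms, so bond lengths and
angles are untouched by construction, and torsions outside the span never
change.  Because coordinate-wise descent can stall with the bond formed
but the angles strained, a joint Powell polish over all span torsions runs
when CCD stops improving.  Success requires a C–S gap below 0.02 Å and
flanking angles within 5°.  Rings spanning fewer than three residues have
no interior torsion and are rejected.  With multiple rings, closure
orderings are tried over permutations of the ring list (capped at 24,
randomly subsampled beyond four rings).

### Superposition

Kabsch SVD superposition with the determinant correction (proper rotations
only).  "Backbone" means N, CA, C.  Ring RMSD uses backbone atoms of the
ring span plus donor/acceptor CB and the acceptor SG, superposed on that
same set — the atom set is a documented choice, configurable in code.
Reference conventions: model 1 for deposited NMR ensembles, the
lowest-scoring member for generated ensembles.

## Torsion potentials

Backbone (φ, ψ) preferences are periodic grid tables (15° spacing) with a
disallowed mask; scoring is periodic bilinear interpolation, sampling
draws an allowed cell with Boltzmann weight exp(−E/T) (default T = 1 in
table units) and jitters uniformly within the cell, so masked cells have
exactly zero probability.  Shipped tables are qualitative analytic
surfaces (regenerable with `scripts/make_rama_tables.py`): a general
canonical map (alpha, beta, ppII and a weak left-handed alpha basin),
a symmetrized glycine map, a C2-symmetric Dha map reflecting the planar
sp2 alpha carbon, and a Dhb map equal to Dha plus a steric penalty where
the Z gamma-methyl approaches the backbone — making Dhb's allowed region a
strict subset of Dha's by construction.  Energies are meaningful up to an
additive constant and a temperature factor.  D-residues score through the
(φ, ψ) → (−φ, −ψ) mirrored general table.  Quantum-chemistry-derived
tables can be dropped in using the same text format.

## Pool generation and the simplified score

The unstructured pipeline draws every residue's (φ, ψ) from its table,
builds the chain, closes each ring (trying ring orderings), drops models
whose rings cannot close, and sorts survivors by score.  The helical
pipeline perturbs a user-supplied start structure with the refinement
machinery at elevated move magnitudes and re-closes rings afterwards.

The score is a declared simplified potential, not a transferable force
field: soft-sphere clash repulsion (onset 2.8 Å heavy–heavy, 2.0 Å with
hydrogen, residue separation ≥ 2, thioether-bonded pairs exempt), the
torsion-table energies, a geometric backbone hydrogen-bond reward
(H···O < 2.5 Å, N–H···O > 120°, −1 each), and the crosslink penalty.
Refinement is Metropolis Monte Carlo with *small* moves (one torsion,
σ = 3°) and *shear* moves (compensating φ(r)/−ψ(r−1) pair, which limits
lever-arm motion), a burn-in phase then a production phase, returning the
best production conformer; moves opening any C–S gap beyond 0.5 Å are
rejected outright.  Fragment insertion and backrub moves of cluster-scale
protocols are deliberately replaced by the small/shear move set — the
largest declared simplification — because fragment libraries are
orthogonal to the ensemble-fitting method itself.  Default schedule sizes
are desk-scale (500 models, 100 + 400 steps); `FAITHFUL_SCHEDULE` records
the published protocol sizes (150,000–200,000 models, 1000 burn-in + 9000
production, top 2.5% carried forward) for cluster runs.

## NOE restraints and ensemble averaging

A restraint couples two possibly ambiguous proton groups with an observed
distance.  Within one conformer an ambiguous pair collapses by the r⁻⁶
*sum* over cross-pairs (the pseudoatom convention, which shortens
multi-proton distances); across an ensemble of N equally populated members
the averaged distance is the r⁻⁶ *mean*:

    d* = ( (1/N) Σᵢ dᵢ⁻⁶ )^(−1/6)

Short distances in any one member dominate d* — the mechanism by which a
flexible ensemble can satisfy restraints no single conformer can.  The sum
vs mean distinction is explicit in code.  Upper-limit restraints score
one-sided residuals max(0, d* − d_obs); a strict symmetric mode is
available because literature protocols differ.  The ensemble score is the
plain sum of squared residuals, with no normalization by restraint count.
Pseudoatom expansion (methyls, glycine QA) ships as a data table over the
reduced atom set; methyl pseudoatoms map to the methyl carbon.

## Ensemble selection

Selection is a Metropolis Monte Carlo over ensemble membership: start from
a random set (default 20), propose add / remove / swap moves (uniform over
move types, then uniform over eligible members/non-members), reject moves
leaving the size window (default 10–30), accept by the Boltzmann criterion,
and return the lowest-scoring state visited over the run (default 500,000
steps).  Per-conformer effective distances never change during the search,
so they are precomputed into a pool × restraint matrix and the r⁻⁶ sums
updated incrementally per move.  The acceptance temperature is not pinned
by published protocols; it defaults to 1.0 in score units (Å²) and should
be scanned (0.01–1) when the restraint count or noise level changes
materially.  Repeating a conformer to up-weight it is supported behind
`allow_duplicates` (default off).  If chemical shifts are supplied, the
squared deviation of the ensemble-*mean* predicted shift from the observed
shift (shifts average linearly, unlike NOEs) is added, restricted to
positions whose residue and both neighbors are canonical — where empirical
shift predictors are trustworthy.

Two cross-checks frame the stochastic search: `exhaustive_select`
enumerates all subsets (bounded at 10⁶) as a small-instance oracle, and
`select_by_filter` implements the alternative deterministic path — keep
the 200 structures agreeing best with the NOEs individually, then the 20
lowest-energy of those (ties broken by stable input order).

## Atropisomer classification

Overlapping-ring lanthipeptides can be kinetically trapped in
non-interconvertible classes.  A probe quad is three alpha carbons (a
plane) plus a fourth on another loop; the sign of
(probe − p1)·((p2 − p1)×(p3 − p1)) is invariant under proper rigid motion
and negated by mirroring, so a vector of probe signs partitions a pool
into classes.  Probes with |signed distance| < 0.1 Å are degenerate and
raise rather than guess.  Filtering keeps an explicit reference class or
the majority class (ties raise, requiring an explicit choice).  Probe
selection is structural judgement: `suggest_probes` (cross-ring heuristic)
and `ring_probe` (intra-span quad, the sensitive detector for mirror-flip
fixtures) are starting points only.

## Synthetic fixtures

The default synthetic peptide is 15 residues with two adjacent lanthionine
rings and one Dha — small enough for exhaustive selection oracles, rich
enough to exercise ring logic.  The central fixture plants two
Ramachandran-sampled, ring-closed states (pairwise backbone RMSD > 1 Å),
hides them among 40 decoys (25° torsion-noise perturbations of the states,
re-closed), and computes 50 NOE observations from the equal-weight r⁻⁶
mixture of the states with 0.1 Å Gaussian noise (floored at 0.5 Å), over
amide/alpha-proton and methyl-pseudoatom pairs with mixture distances in
the observable 1.8–7 Å window.  Ring-flip fixtures reflect a ring's span
atoms through the span's best-fit plane: reflection is an isometry of the
span, so ring closure is preserved and the flip is an exact involution,
while chirality-sensitive probe signs flip; the peptide bond at the span
boundary inherits a small seam strain, acceptable in a classification
fixture.  Every fixture is a pure function of (recipe, seed).

What the fixtures do *not* emulate: real NOE peak lists (no assignment
ambiguity beyond pseudoatoms, no spin diffusion), real conformational
energetics (decoys are geometric, not thermodynamic), sidechain packing,
or solvent.  Passing the recovery tests shows the selection machinery is
correct and well-conditioned at realistic noise, not that the simplified
score ranks real lanthipeptide conformers like a molecular-mechanics
force field would.

## Numerical choices and problem sizes

All angles are degrees at interfaces, radians internally; coordinates are
Å; residue numbering is 1-based everywhere.  Closure tolerance 0.02 Å /
5°; clash onsets 2.8/2.0 Å; degenerate-probe tolerance 0.1 Å; exhaustive
enumeration bound 10⁶ subsets; selection and sampling are driven by a
single NumPy generator per run, making every stage bit-reproducible from
(config, seed).  The test-suite and acceptance-script problem sizes —
pools of a dozen for selector-vs-oracle checks, a 42-member pool for
two-state recovery, 20,000-step selection runs — are the package's chosen
desk-scale study conditions; the published cluster-scale schedule is
preserved as a preset, not exercised by the tests.

## Known limitations

- The score function is a ranking device for pool assembly; its energies
  are not comparable across topologies and have no physical units.
- Ring closure optimizes bond and flanking angles; the crosslink dihedral
  preferences act only softly through the score, so closed rings sample
  dihedrals more broadly than a force-field ensemble would.
- Dha/Dhb tables are qualitative; substitute QM-derived tables for
  production work on real peptides.
- Proline is treated as a generic residue (no ring, no phi restriction)
  beyond lacking an amide proton.
- Chemical-shift support is a scoring hook; the package does not predict
  shifts.
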