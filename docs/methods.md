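# Methods

`conformap` implements the geometric analysis used to characterise how a
mutation re-arranges a two-domain, autoinhibited protein — the archetype
being an AKT-family kinase whose pleckstrin-homology (PH) domain packs
against the kinase domain in the closed state, occluding the
activation-loop phosphosite (T308 in AKT1), and whose in-frame
duplications in the PH domain force an open, "PH-out" conformation.  All
operators are purely geometric: they take structures and conformational
ensembles as given and measure contacts, distances, displacement, and
exposure.  No energies are computed and no dynamics are simulated.

## Structures and ensembles

Structures are ordered heavy-atom lists in author residue numbering
(1-based, insertion codes as composite keys); residues are addressed the
way the literature addresses them, with no renumbering.  A multi-model
PDB file is read as an ensemble of congruent frames and stands in for an
MD trajectory.  Alternate locations resolve to the highest-occupancy
conformer (ties keep the first).  Hydrogens are not added; all analysis
defaults are heavy-atom-only, and the hydrogen-bond angle test activates
only when a file carries explicit hydrogens.  Only the 20 standard amino
acids enter sequence-derived operations and RSA normalisation; other
residues are flagged and carried with raw values.

## Residue correspondence across alleles

An in-frame tandem duplication of residues `s..e` maps wild-type residue
`i` to `i` for `i <= e` and to `i + (e - s + 1)` afterwards; mutant
residues `e+1 .. e+L` are the new copy, unmapped on the wild-type side.
The first copy keeps wild-type identity — for tandem duplications the
choice of which copy is "the" wild-type residue is biologically
arbitrary, and both conventions give identical index shifts outside the
block; keeping the first copy minimises the shift of downstream
residues.  For arbitrary in-frame events the map comes from global
Needleman–Wunsch alignment (Gotoh, affine gaps; defaults +1/-1 match/
mismatch, gap open -4, extend -1 with a length-k gap costing
`open + k*extend`).  Traceback tie-breaking is fixed — diagonal, then
gap-in-b, then gap-in-a — which places tied gaps leftmost, so results
are deterministic.  The alignment scores are conventional choices (the
source analyses place insertions by construction, not by alignment) and
are exposed in `AlignmentParams`.

## Superposition, time-averaging, displacement

Rigid superposition is the least-squares Kabsch fit (via scipy's
`Rotation.align_vectors`, proper rotation enforced; the residual is
recomputed from the fitted transform in float64, so exact matches report
RMSD at machine precision).  Time-averaged structures are per-atom
Cartesian means after superposing every frame onto a reference frame on
C-alpha atoms — matching the behaviour of the standard "average
structure" utilities; no internal-coordinate averaging is attempted, so
very large intra-ensemble rotations would blur averages (the synthetic
jitter is kept small).

Per-residue displacement between alleles requires choosing the rigid
frame the displacement is measured *in*.  The default superposes the
mutant onto the wild type using mapped C-alpha atoms of the domain the
perturbation is not expected to move (the kinase domain in the AKT
configuration; domain A in the synthetic study), because a PH-domain
insertion perturbs the PH domain and linker.  The frame is configurable
and recorded in output metadata.  Displacement is the distance between
representative atoms — C-alpha by default, side-chain centroid as an
option for side-chain reorientation questions.  Two modes exist: measure
on time-averaged structures (default), or per frame and then average;
the per-frame mode is upward-biased by thermal scatter, which is why it
is not the default.

## Interface contacts, hydrogen bonds, distance maps

A hydrophobic interface pair is two residues, one per domain, both in the
hydrophobic set, with at least 6 carbon–carbon contacts within 4.0 Å.
The hydrophobic set is {ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO, CYS} —
a side-chain-based choice consistent with the interface residues named
in the AKT literature (L52, W80, L321) — and is configurable.  All
carbons count by default, backbone included, because the criterion is
stated over "carbon atoms" rather than side-chain carbons; a
side-chain-only switch is provided since the pair count can shift under
either reading.

Hydrogen bonds use a simple geometric criterion: N/O atoms of different
residues within 3.5 Å, plus a D–H⋯A angle ≥ 120° when explicit hydrogens
exist.  This is a deliberate, documented substitution for
geometry-family-specific detectors in interactive modelling tools whose
exact parameter families are not reproducible from their defaults; for
presence/absence diffs of designated bonds the simple criterion is
sufficient and transparent.

Distance maps are inter-residue distances over a selection (C-alpha
metric for maps — cheap and standard; minimum-heavy-atom for contact
logic and clustering, where the criterion demands atoms).  The
distance-difference map between alleles is `d_mut(map(i), map(j)) -
d_wt(i, j)` over mapped residues: internal distances only, hence exactly
invariant to rigid motions of either input, and antisymmetric under
swapping the alleles.  Its domain-block summary (mean intra-A, intra-B,
cross) is the compact signature of interface opening: cross-block
positive, intra blocks ~0.

The per-pair separation report gives, for each interface pair discovered
on the wild type, the distance between representative positions
(side-chain heavy-atom centroid by default) in each time-averaged
structure and the change; "RMS distance" over a pair set is reported as
the RMS aggregate of the per-pair values.  Pairs touching unmapped
residues are flagged rather than dropped.

## Solvent accessibility

Shrake–Rupley quadrature: per atom, test points on a deterministic
Fibonacci lattice (960 points default) over the solvent-expanded sphere
(van der Waals radius + 1.4 Å water probe); a point is accessible iff
outside every neighbour's expanded sphere.  An isolated atom gets
exactly its analytic sphere area for any lattice size, which anchors the
quadrature; doubling the lattice moves totals by well under 2%.  Radii:
C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å (configurable).
Relative solvent accessibility divides residue SASA by the theoretical
maximum per residue type (Tien-style Gly-X-Gly table) and is reported
both raw and in decile bins; RSA may exceed 1 in extended conformations
and then reports the top bin unclamped.

This structure-based RSA replaces the sequence-based neural predictor
used in the original analysis workflow: a predictor's weights are not a
geometric object, while the burial question ("is the phosphosite caged
by the partner domain?") is.  Consequently exact bin values from
predictor-based reports are not expected to reproduce; the meaningful,
tested statement is the qualitative one — a caged residue gains at least
two exposure deciles when the interface opens.

## Model gating and 3D mutation clustering

TM-score over mapped C-alpha pairs: `TM = (1/L) Σ 1/(1 + (d_i/d0)^2)`
with `d0 = 1.24 (L-15)^{1/3} - 1.8`, floored at 0.5 Å for short chains.
Because the compared models are alleles of one protein, the residue
correspondence is known (from the mapping layer) and only the
superposition is optimised: iterated Kabsch fits on shrinking inlier
sets (inlier cutoff `max(d0+1, 3.5)` Å), started from the full set and
two half-fragments, keeping the best score — the standard score-
maximisation heuristic without the alignment search, which is not needed
here.  Identical structures score exactly 1.

The TM-score → p-value conversion is a right-tail extreme-value null for
unrelated structure pairs: `p = 1 - exp(-exp(-(tm - 0.1512)/0.0242))`,
the asymptotic parametrisation of the random-pair TM-score distribution
(it reproduces the conventional reading that TM ≈ 0.17 is chance-level
and TM = 0.5 has p ~ 5e-7).  The function is a pluggable component with
a contract (continuous, in [0,1], strictly decreasing in TM at fixed
length, defined for chains of length ≥ 22); any finer length dependence
can be swapped in without touching the gate.  Multiple-testing
correction is Benjamini–Hochberg (Q values — FDR control is what
"Q value" reporting implies), with the gate at q < 0.05.

Proximity clustering of mutated residues builds the graph of pairs
within the cutoff (5 Å default) under the minimum-heavy-atom metric (the
most permissive reading of "physically adjacent"; C-alpha optional).
Component linkage (default) takes connected components; clique linkage
reads "within 5 Å of one another" literally as maximal all-pairs cliques
and resolves overlaps into a partition by greedily peeling the largest
maximal clique, ties broken toward the lexicographically smallest member
set — deterministic, and every output is a genuine partition with
singletons retained.  Increasing the cutoff only coarsens component-
linkage clusters.

## The synthetic study conditions

The generator builds the study's inputs at desk scale, with every
feature known by construction:

- **Closed toy**: two compact domains of 50 residues each on a 6 Å
  lattice (5×5 per layer), joined by an 8-residue linker arced away from
  the interface.  Residues carry N, CA, C, O plus 1–4 schematic
  side-chain carbons (hydrophobic residues ≥ 3).  Six designated
  leucine-like contact pairs face each other across the interface at a
  3.5 Å carbon gap — nine qualifying carbon pairs each, while every
  non-designed cross-domain atom pair stays beyond ~5 Å — so interface
  detection must return exactly the designed set.  One designated
  cross-interface hydrogen bond (amide N donor to carbonyl O acceptor at
  2.9 Å) bridges the domains.  One marker residue (the T308 analogue)
  sits at the centre of domain B's interface face inside a 24-carbon
  cage at 3.9 Å: domain A contributes the 16 interface-side directions,
  domain B's own neighbours the 8 rear ones, so the closed-form RSA is
  < 0.03 and opening the interface frees two-thirds of the sphere
  (RSA ≈ 0.4, a 4-decile gain).  In the real protein the lost
  stabilising bond is intra-PH (re-localisation of Q79 away from N53);
  a rigid toy cannot re-localise a side chain within a domain, so the
  designated bond spans the interface instead — the same observable
  (a named bond present in closed, absent in open), produced by the
  mechanism the toy can represent.
- **Open conformer**: rigid translation of domain B plus the distal half
  of the linker (default 12 Å along the interface normal), so every
  domain-B residue's true displacement is exactly the translation
  magnitude.  Moves that bring atoms within 1 Å of the fixed region
  raise a warning (the transform is deterministic, so there is nothing
  to re-randomise; the caller picks a different translation).
- **Duplication**: a 10-residue block (domain-A interior, residues
  30–39 in the fixtures) copied in tandem with a ~2.3 Å offset along the
  local chain direction; mapped residues keep their coordinates exactly,
  so the duplication alone contributes nothing to the distance-difference
  map.
- **Ensembles**: each frame is a small random rigid motion of the mean
  (rotation sd 2°, translation sd 0.5 Å) plus i.i.d. Gaussian
  per-coordinate noise (sd 0.5 Å), 500 frames for the recovery study —
  chosen so the time-averaged mean is accurate to ~0.02 Å per coordinate
  and the ±0.2 Å displacement-recovery tolerance is meaningful rather
  than slack.  Everything is a pure function of spec + seed.

What the toy does *not* emulate: correlated breathing modes and
anharmonic dynamics (noise is isotropic and independent), physical
side-chain rotamers, solvent, or any force field.  Passing the recovery
tests therefore demonstrates that the *analysis operators* measure what
they claim on inputs with known truth — not that a real trajectory would
show these magnitudes.

## Numerical choices

- PDB coordinates quantise at 3 decimals; round-trips are exact after the
  first quantisation.
- Traceback, clique-peeling, and output orderings are all explicitly
  tie-broken, so every result is deterministic given inputs and seed.
- Superposition requires ≥ 3 non-collinear points; mirror-image cases
  are resolved to proper rotations (det +1).
- Degenerate inputs fail loudly with the offending residue/model/line
  named: missing C-alpha under the C-alpha metric, incongruent ensemble
  models, unmapped residues in an explicit selection, coordinates
  exceeding the PDB field width.

## Known limitations

- The hydrogen-bond criterion is distance-dominated for hydrogen-free
  structures and will count close covalent-adjacent N/O pairs in dense
  schematic geometries; designated-bond diffs are unaffected.
- TM-score superposition optimisation is a heuristic; it never scores
  below the plain full-set fit but is not guaranteed globally optimal.
- The p-value null uses constant EVD parameters rather than a
  length-resolved table; it is used as a monotone gate, not as a
  calibrated tail probability.
- Structure-based RSA on modelled structures need not match
  predictor-based RSA values; only bin *shifts* are interpreted.
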