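# Methods

## Problem and approach

Cofolded protein–glycan models carry no chemistry beyond atom names and
coordinates, and the predictors that produce them are known to hallucinate
stereochemically impossible carbohydrates.  `glycancheck` therefore treats
validation as a pure geometry problem: every judgement is made against a
built-in per-monosaccharide reference dictionary, never against an
experimental structure.  A model passes only if every sugar unit is
simultaneously clean under all six detectors.

The pipeline per model: parse (mmCIF/PDB via gemmi, first model only,
highest-occupancy altloc) → infer covalent bonds from distances → identify
sugar units by CCD code → assemble the glycosidic tree → run the six
detectors per unit plus the reducing-end check per tree → emit a
deterministic report.

## Bond inference

Atoms i, j are bonded iff d(i,j) ≤ (r_cov(i)+r_cov(j))·(1+t) with
covalent radii C 0.76, N 0.71, O 0.66, S 1.05 Å (1.10 Å fallback) and
t = 0.25.  This tolerance passes ideal single bonds (longest relevant:
C–C 1.52 Å vs cutoff 1.90 Å) while rejecting ring-diagonal distances
(≥ 2.3 Å in a chair).  Pairs under 0.5 Å are treated as modelling clashes:
no bond, a warning instead.  Hydrogens are ignored throughout (cofolding
outputs are heavy-atom); `infer_bonds(..., include_hydrogens=True)` exists
for completeness.  Bonds below the pair-type double-bond floor are marked
`SUSPECT_DOUBLE` at inference time; whether they are *errors* is decided
by the detector, which exempts bonds the dictionary itself holds short
(N-acetyl C=O at 1.21 Å and its amide C–N at 1.35 Å, the sialic-acid
carboxylate, the AC1 cyclohexene C=C).

## Reference dictionary

One entry per CCD code: ring atom order (ring oxygen first), anomeric
carbon and oxygen, heavy-atom bond list, stereocenter definitions, and a
chair recipe from which ideal Cartesian coordinates are **generated at
load time** — the package ships no coordinates.  The recipe:

* **Ring.**  Six atoms on a closed cyclic polygon whose in-plane side
  lengths reproduce the ideal ring bonds exactly (ring C–C 1.52 Å,
  C–O 1.43 Å; the circumradius is solved by 1-D root finding), with
  alternating out-of-plane displacements z = ±0.25 Å.  This yields
  Q = √6·0.25 ≈ 0.61 Å and ring torsions alternating around ±60°, i.e. an
  ideal chair.  A parity flag selects the chair form: θ ≈ 0° (⁴C₁ for
  D-aldopyranoses) or θ ≈ 180° (¹C₄ for α-L-fucose; the ²C₅ chair of
  sialic acid under its O6,C2..C6 ring ordering).
* **First substituent shell.**  Each ring carbon's heavy substituent takes
  the axial or equatorial tetrahedral direction (109.47° to both ring
  neighbours) recorded per sugar.  These axial/equatorial flags, together
  with the chair parity, encode the full stereochemistry — they were
  derived once from the PDB Chemical Component Dictionary ideal
  coordinates and frozen into `data/sugars.yaml`; the test suite
  re-verifies every resulting chiral-volume sign against the CCD copy
  bundled with biotite.
* **Outer shells.**  Hydroxymethyl arms, N-acetyl groups, the sialic-acid
  glycerol tail and carboxylate, and the AC1 aminocyclohexene ring are
  placed by z-matrix rows (bond, angle, torsion) tabulated in the data
  file.  The AC1 carbocycle is built as an open chain whose tabulated
  torsions close the ring to its ideal 1.50 Å bond.

Ideal bond lengths and angles used by the improper detector are measured
from these generated coordinates, which makes the dictionary its own
negative control: a structure built from `ideal_coords` must produce zero
flags, and the loader refuses any entry whose generated geometry
contradicts its recorded stereo signs or has a degenerate center.

Stereocenters are defined by a fixed four-name substituent order
(ring-predecessor, ring-successor, exocyclic substituent(s), and the
center itself standing in for the implicit hydrogen when only three heavy
substituents exist).  On ideal geometry |V| ≈ 0.43 Å³ for ordinary centers
and ≈ 1.6 Å³ for the quaternary-like sialic-acid C2; the degeneracy
threshold of 0.1 Å³ therefore separates flattened centers (|V| → 0) from
meaningful handedness with a wide margin, and flattened centers are
deliberately routed to the planarity/improper logic instead of chirality.

## Detector thresholds

All tunables live in `DetectorConfig` (YAML-loadable); defaults sit midway
between ideal values and clearly-corrupted ones:

| parameter | default | ideal value | corrupted regime |
|---|---|---|---|
| degenerate \|V\| | 0.1 Å³ | ≈ 0.43 Å³ | 0 when flattened |
| C–C / C–O / C–N floors | 1.42 / 1.32 / 1.37 Å | 1.52 / 1.43 / 1.47 Å | 1.2–1.39 Å |
| planar Q ceiling | 0.25 Å | 0.61 Å (chair) | ≈ 0 |
| planar atom rule | ≥ 3 atoms > 0.5 Å | — | 4–7 atoms move 0.5–1.5 Å on flattening |
| aromatic Q / mean bond | 0.15 Å / 1.45 Å | 0.61 / 1.49 Å | ≈ 0 / 1.39 Å |
| improper bond / angle / RMSD | 0.25 Å / 20° / 0.6 Å | 0 | 0.35 Å+ / 35°+ / 0.7 Å+ |

Flags are additive — violations co-occur freely, as they do in real
cofolding output — with two principled exclusions: a bond already flagged
`DOUBLE_BOND` is omitted from the improper bond scan (no double counting),
and the whole-unit RMSD criterion is skipped for units already flagged
`PLANAR_RING` (flattening inevitably leaves RMSD ≈ 0.65–0.75 Å against the
chair; improper is defined as *residual* error).  Likewise the RMSD is
computed on chirality-normalised coordinates: detected stereocenter flips
are rotated back first, so one flipped N-acetyl arm is not also counted as
an improper distortion.  Stereocenters with a missing substituent atom are
skipped with a warning, never guessed.

The per-model verdict is FAIL on ≥ 1 flag of any category in any unit.
Aggregation counts categories per model (once per category regardless of
how many units are affected) with a per-unit companion table, since both
accountings are of interest; percentages are rounded half-up to one
decimal.

## Glycan tree

Glycosidic edges are anomeric-carbon → bridging-oxygen → acceptor-carbon
paths over the inferred bonds; the anomeric carbon is always taken from
the dictionary (C1; C2 for SIA), never re-derived, so distorted rings
remain analysable.  Edges must form a forest; each component's unique unit
with a free anomeric carbon is its reducing end.  An anomeric carbon
bridging to two different units is reported as an ambiguity error.  A
glycan covalently attached to protein has no free reducing end and is
excluded from the reducing-end check (with a warning).  α/β labels on
edges come from the donor's dictionary anomer and are reported only, never
used to gate detection.

## Synthetic generator

The generator is the package's stand-in for the study's raw cofolding
outputs, at desk scale.  `build_glycan` docks each donor unit onto its
acceptor hydroxyl with ideal bridge geometry (C–O 1.43 Å, C–O–C 117°,
φ = −60°, ψ = 120°, a fallback ψ×φ grid on steric clashes < 2 Å); the
donor's anomeric oxygen is consumed.  Eight library compositions cover all
nine sugars (lactose, lacto-N-neotetraose, 3'-sialyllactose, Lewis-x, the
blood-group-A trisaccharide, a cellobiose-type and a chitobiose-type
disaccharide, and an acarbose fragment for AC1), emulating the ligand
diversity of a protein–glycan benchmark set.

Corruption operators plant one error class each, at default magnitudes
chosen clearly supra-threshold so acceptance is not threshold-marginal
(sign flips are binary; flatten to Q ≈ 0; aromatize to 1.39 Å ring bonds;
shorten to 1.33 Å; stretch by +0.35 Å; delete the reducing-end oxygen;
seeded jitter for below-threshold noise).  A `MARGINAL_MAGNITUDES` table
at ≈ 1.1× threshold supports sensitivity studies.  Two design points:

* **Flips are proper rotations.**  A stereocenter flip rotates each
  exocyclic branch onto the mirror image of its attachment direction.  A
  literal reflection would enantiomerise everything inside the branch;
  the rotation inverts only the target center, preserves all bond lengths,
  and is an involution.
* **Branches follow the model bond graph.**  An edit at an anchor carrying
  a glycosidic bridge moves the downstream unit rigidly instead of
  severing the linkage.  The benchmark picker additionally rejects any
  candidate whose rigid-body edit would change covalent topology (branch
  collisions), so each planted model carries exactly its labelled error.

Aromatization genuinely plants sub-floor C–C ring bonds, so its label set
is {PLANAR_RING, AROMATIC_RING, DOUBLE_BOND} — the same co-occurrence seen
in real flattened-ring output.  The default benchmark mix (clean 0.15,
chirality 0.40, double-bond 0.15, planar 0.10, aromatic 0.08, improper
0.05, missing-atom 0.07) mirrors the observed ranking of cofolding failure
modes, with chirality dominant.

Randomness: a single master seed; per-model generators are split off it
with `SeedSequence(entropy=seed, spawn_key=(i,))`, so any subset of a
suite is reproducible in isolation and regeneration is byte-identical.

### What the generator does and does not emulate

It emulates the *error signatures* (their geometry, magnitudes and
co-occurrence) on clean chair-conformation scaffolds.  It does not emulate
protein context, conformational ensembles, correlated multi-residue
distortions, partial/marginal errors, or coordinate noise at experimental
levels.  Passing the suite therefore demonstrates that the detectors
recover each error class with correct attribution under unambiguous
conditions; on real cofolding output, threshold-marginal distortions will
divide pass/fail differently as the configurable thresholds are moved, and
the qualitative error classes — not the exact percentages — are the robust
output.

## Numerical choices

Cremer–Pople: mean-centred positions, plane normal from the weighted
sine/cosine sums, q₂/q₃ from the standard projections, Q = √(q₂²+q₃²),
θ = atan2(q₂, q₃) ∈ [0°, 180°]; coplanarity tolerance 1e-6 Å; conformer
labels are coarse bins relative to the fixed O-first ring order.
Superposition is Kabsch with the determinant sign correction (proper
rotations only).  Collinear plane fits, duplicate ring atoms, and
antiparallel rotation targets raise explicit geometry errors.  Reports are
sorted (unit, category, atoms) and magnitudes rounded to 4 decimals so
repeated runs are byte-identical.

## Known limitations

* Furanoses and 5-membered rings are out of scope; the supported sugars
  are all pyranoses (plus AC1's carbocycle, handled as an exocyclic
  substituent).
* Sulfated and phosphorylated sugars are not in the v1 dictionary; the
  YAML schema accepts user entries (e.g. MAN, BMA, GLA, XYP) without code
  changes, given ring order, chair recipe and stereo signs.
* Bond inference cannot see a bond whose atoms were placed > 25 % beyond
  covalent reach; such units surface through the improper detector's bond
  scan instead of the tree.
* NMR-style multi-model files: first model only; no symmetry expansion.
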