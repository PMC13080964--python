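# glycancheck

Reference-free stereochemical validation of glycan 3D models.

Deep-learning cofolding predictors (AlphaFold 3-class tools, Boltz-1x, and
BondedAtomPairs-style inputs) routinely emit carbohydrate ligands with
chemistry that cannot exist: inverted stereocenters, ring bonds compressed
to double-bond lengths, pyranose rings flattened into benzene-like
hexagons, grossly distorted monosaccharide geometry, and a systematically
deleted reducing-end anomeric oxygen.  Until now such errors have been
found by manual inspection.  `glycancheck` automates that inspection: it
classifies six error categories directly from 3D coordinates, using only a
built-in per-monosaccharide dictionary as reference — no experimental
structure required.  It is aimed at structural bioinformaticians and
glycoscientists who need to screen cofolding outputs at scale.

## The checks

For every sugar residue (supported CCD codes: A2G, AC1, BGC, FUC, GAL,
GLC, NAG, NDG, SIA; the dictionary is extensible via a YAML data file):

| Category | Criterion (defaults) |
|---|---|
| `CHIRALITY` | sign of the chiral volume V = ((**r**₁−**r**₄)·((**r**₂−**r**₄)×(**r**₃−**r**₄)))/6 at a stereocenter contradicts the dictionary, with \|V\| ≥ 0.1 Å³ |
| `DOUBLE_BOND` | an intra-unit bond below its single-bond floor (C–C < 1.42 Å, C–O < 1.32 Å, C–N < 1.37 Å), excluding dictionary carbonyls/amides/carboxylates |
| `PLANAR_RING` | Cremer–Pople amplitude Q < 0.25 Å **and** ≥ 3 atoms > 0.5 Å from the ideal unit after proper-rotation superposition |
| `AROMATIC_RING` | Q < 0.15 Å **and** mean intra-ring bond < 1.45 Å |
| `IMPROPER` | residual geometry errors: bond \|Δ\| > 0.25 Å, angle \|Δ\| > 20°, whole-unit RMSD > 0.6 Å, or a missing non-terminal heavy atom |
| `MISSING_ATOM` | the reducing-end anomeric oxygen (O1; O2 for sialic acids) is absent — the BondedAtomPairs artefact |

Ring puckering uses the standard Cremer–Pople coordinates (Q, θ, φ) with
the ring oxygen first in the atom ordering, so θ ≈ 0° is the ⁴C₁ chair of
a D-aldopyranose; Q = √6·z₀ for an alternating ±z₀ chair.  Chirality is
judged by signed tetrahedral volumes in a fixed dictionary substituent
order, and superpositions minimise over **proper** rotations only, so
handedness can never be "fixed" by a reflection.  All thresholds are
configurable (`DetectorConfig`, YAML-loadable).

A synthetic module builds ideal chair-conformation glycans from internal
coordinates and injects each error class at controlled magnitude with
ground-truth labels, so every detector is verified end-to-end without any
external data.

## Worked example

```python
from glycancheck import (GLYCAN_LIBRARY, build_glycan, corrupt,
                         CorruptionSpec, CorruptionOp, validate_model)

model = build_glycan(GLYCAN_LIBRARY["sialyllactose"])       # SIAα2→3GALβ1→4GLC
bad, labels = corrupt(model, CorruptionSpec((
    CorruptionOp(1, "flip_stereocenter", {"center": "C2"}), # epimerize GAL C2
    CorruptionOp(0, "delete_atom", {"name": "O1"}),         # BAP-style deletion
)))
report = validate_model(bad, model_id="sialyllactose_demo")
print(report.verdict, f"({len(report.flags)} flags over {report.n_units} units)")
for f in report.flags:
    print(f"  {f.category.value:12s} {f.unit_id:10s} atoms={','.join(f.atoms):6s} magnitude={f.magnitude:.3f}")
```

prints

```
FAIL (2 flags over 3 units)
  MISSING_ATOM G:1:GLC    atoms=O1     magnitude=0.000
  CHIRALITY    G:2:GAL    atoms=C2     magnitude=0.429
```

Both injected errors are recovered and attributed to the right unit and
atoms; the untouched SIA unit carries no flags.  The `magnitude` is
category-specific: here the absolute chiral volume (Å³) at the flipped
center, comfortably above the 0.1 Å³ degeneracy threshold.

The same pipeline is available from a shell:

```sh
glycancheck synth --n 100 --seed 42 --out suite/        # labelled benchmark
glycancheck validate suite/*.pdb --out reports/         # per-model JSON reports
glycancheck aggregate reports/ --out summary            # pass/fail + per-category tables
```

`aggregate` reports per-model category percentages (a model counts once
per category), a per-unit companion count, and a per-sugar × per-category
incidence matrix; with a condition manifest CSV
(`file,tool,notation,cofold_type,seed,ligand`) it also breaks results down
per modelling tool / input notation / cofolding type.

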