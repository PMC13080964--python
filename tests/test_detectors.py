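"""The six error detectors and the per-model orchestrator."""

import numpy as np
import pytest

from glycancheck.detectors import (
    DetectorConfig,
    detect_aromatic_ring,
    detect_chirality,
    detect_double_bonds,
    detect_improper,
    detect_planar_ring,
    validate_model,
)
from glycancheck.flags import ErrorCategory
from glycancheck.graph import identify_sugar_units
from glycancheck.reference import get_entry
from glycancheck.structure import (
    AtomRecord,
    ResidueRecord,
    StructureModel,
    infer_bonds,
)
from glycancheck.synthetic import (
    GLYCAN_LIBRARY,
    CorruptionOp,
    CorruptionSpec,
    build_glycan,
    corrupt,
)


def unit_model(code, coords=None, drop=()):
    entry = get_entry(code)
    coords = coords or entry.ideal_coords
    atoms = [
        AtomRecord(n, n[0], np.asarray(coords[n], float).copy(), ("A", 1, ""), True)
        for n in entry.atom_names
        if n in coords and n not in drop
    ]
    m = StructureModel(residues=[ResidueRecord(code, ("A", 1, ""), atoms)])
    infer_bonds(m)
    return m


def the_unit(model, dictionary):
    (unit,) = identify_sugar_units(model, dictionary)
    return unit


class TestChirality:
    def test_ideal_unit_clean(self, dictionary):
        unit = the_unit(unit_model("GAL"), dictionary)
        assert detect_chirality(unit) == []

    def test_single_flip_attributed_to_center(self, dictionary):
        model = unit_model("GAL")
        model, _ = corrupt(model, CorruptionSpec((CorruptionOp(0, "flip_stereocenter", {"center": "C4"}),)), dictionary)
        unit = the_unit(model, dictionary)
        flags = detect_chirality(unit)
        assert len(flags) == 1
        assert flags[0].atoms == ("C4",)
        assert flags[0].magnitude > 0.3

    def test_fully_mirrored_unit_flags_every_center(self, dictionary):
        e = get_entry("GAL")
        mirrored = {n: p * np.array([-1.0, 1.0, 1.0]) for n, p in e.ideal_coords.items()}
        unit = the_unit(unit_model("GAL", coords=mirrored), dictionary)
        flags = detect_chirality(unit)
        assert {f.atoms[0] for f in flags} == {"C1", "C2", "C3", "C4", "C5"}

    def test_flattened_center_skipped_as_degenerate(self, dictionary):
        e = get_entry("GAL")
        coords = {n: p.copy() for n, p in e.ideal_coords.items()}
        # project O4 into the plane of C3, C5, C4 -> |V| < 0.1 at C4
        c, a, b = coords["C4"], coords["C3"], coords["C5"]
        n = np.cross(a - c, b - c)
        n /= np.linalg.norm(n)
        u = coords["O4"] - c
        coords["O4"] = c + u - n * (u @ n)
        unit = the_unit(unit_model("GAL", coords=coords), dictionary)
        assert all(f.atoms != ("C4",) for f in detect_chirality(unit))

    def test_missing_substituent_skips_center_with_warning(self, dictionary):
        model = unit_model("GAL", drop=("O4",))
        unit = the_unit(model, dictionary)
        flags = detect_chirality(unit)
        assert all(f.atoms != ("C4",) for f in flags)
        assert any("C4" in w for w in unit.warnings)


class TestDoubleBonds:
    def test_nag_carbonyl_sanctioned(self, dictionary):
        model = unit_model("NAG")
        unit = the_unit(model, dictionary)
        assert detect_double_bonds(unit, model.bonds) == []

    def test_compressed_ring_bond_flagged_with_magnitude(self, dictionary):
        model = unit_model("GAL")
        model, _ = corrupt(
            model,
            CorruptionSpec((CorruptionOp(0, "shorten_bond", {"pair": ["C2", "C3"], "length": 1.33}),)),
            dictionary,
        )
        unit = the_unit(model, dictionary)
        flags = detect_double_bonds(unit, model.bonds)
        assert len(flags) == 1
        assert flags[0].atoms == ("C2", "C3")
        assert flags[0].magnitude == pytest.approx(1.33, abs=0.01)

    def test_ideal_unit_clean(self, dictionary):
        model = unit_model("GAL")
        assert detect_double_bonds(the_unit(model, dictionary), model.bonds) == []

    def test_sia_carboxylate_and_amide_sanctioned(self, dictionary):
        model = unit_model("SIA")
        assert detect_double_bonds(the_unit(model, dictionary), model.bonds) == []


class TestRings:
    def test_ideal_chair_not_planar(self, dictionary):
        unit = the_unit(unit_model("GAL"), dictionary)
        assert detect_planar_ring(unit) is None
        assert detect_aromatic_ring(unit) is None

    def test_flattened_ring_planar_only(self, dictionary):
        model = unit_model("GAL")
        model, _ = corrupt(model, CorruptionSpec((CorruptionOp(0, "flatten_ring", {}),)), dictionary)
        unit = the_unit(model, dictionary)
        planar = detect_planar_ring(unit)
        assert planar is not None
        assert planar.magnitude < 0.05
        assert detect_aromatic_ring(unit) is None  # ideal-length flat ring, mean ~1.49

    def test_aromatized_ring_flags_both(self, dictionary):
        model = unit_model("GAL")
        model, _ = corrupt(model, CorruptionSpec((CorruptionOp(0, "aromatize_ring", {"target": 1.39}),)), dictionary)
        unit = the_unit(model, dictionary)
        assert detect_planar_ring(unit) is not None
        aro = detect_aromatic_ring(unit)
        assert aro is not None
        assert "1.390" in aro.detail

    def test_half_chair_above_threshold_unflagged(self, dictionary):
        e = get_entry("GAL")
        coords = {n: p.copy() for n, p in e.ideal_coords.items()}
        ring = np.array([coords[a] for a in e.ring_atoms])
        centroid = ring.mean(axis=0)
        from glycancheck.geometry import best_fit_plane, cremer_pople

        _, normal, _ = best_fit_plane(ring)
        # damp out-of-plane components until Q ~ 0.35 (above the 0.25 cutoff)
        for scale in np.linspace(1.0, 0.3, 50):
            trial = centroid + (ring - centroid) - (1 - scale) * np.outer((ring - centroid) @ normal, normal)
            if cremer_pople(trial).Q < 0.36:
                break
        for i, a in enumerate(e.ring_atoms):
            coords[a] = trial[i]
        unit = the_unit(unit_model("GAL", coords=coords), dictionary)
        q = cremer_pople(np.array([coords[a] for a in e.ring_atoms])).Q
        assert 0.25 < q < 0.4
        assert detect_planar_ring(unit) is None


class TestImproper:
    def test_ideal_sia_clean(self, dictionary):
        unit = the_unit(unit_model("SIA"), dictionary)
        assert detect_improper(unit) == []

    def test_stretched_bond_magnitude(self, dictionary):
        model = unit_model("GAL")
        model, _ = corrupt(
            model,
            CorruptionSpec((CorruptionOp(0, "stretch_bond", {"pair": ["C5", "C6"], "length": 1.85}),)),
            dictionary,
        )
        unit = the_unit(model, dictionary)
        flags = detect_improper(unit)
        bond_flags = [f for f in flags if f.atoms == ("C5", "C6")]
        assert len(bond_flags) == 1
        assert bond_flags[0].magnitude == pytest.approx(1.85 - 1.52, abs=0.02)

    def test_torsioned_sia_tail_angle_flagged(self, dictionary):
        e = get_entry("SIA")
        coords = {n: p.copy() for n, p in e.ideal_coords.items()}
        # bend the glycerol tail: rotate everything beyond C7 to open C6-C7-C8
        c6, c7, c8 = coords["C6"], coords["C7"], coords["C8"]
        # rotate the C8 branch about the normal of the C6-C7-C8 plane
        n = np.cross(c6 - c7, c8 - c7)
        n /= np.linalg.norm(n)
        theta = np.radians(35.0)
        k = np.array([[0, -n[2], n[1]], [n[2], 0, -n[0]], [-n[1], n[0], 0]])
        rot = np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)
        for name in ("C8", "C9", "O8", "O9"):
            coords[name] = c7 + rot @ (coords[name] - c7)
        unit = the_unit(unit_model("SIA", coords=coords), dictionary)
        flags = detect_improper(unit)
        assert any(f.atoms == ("C6", "C7", "C8") for f in flags)

    def test_missing_nonterminal_atom_flagged(self, dictionary):
        model = unit_model("GAL", drop=("O3",))
        unit = the_unit(model, dictionary)
        flags = detect_improper(unit)
        assert any(f.atoms == ("O3",) and "absent" in f.detail for f in flags)

    def test_double_bond_pairs_excluded_from_scan(self, dictionary):
        model = unit_model("GAL")
        model, _ = corrupt(
            model,
            CorruptionSpec((CorruptionOp(0, "shorten_bond", {"pair": ["C2", "C3"], "length": 1.33}),)),
            dictionary,
        )
        unit = the_unit(model, dictionary)
        flags = detect_improper(unit, exclude_bonds={("C2", "C3")})
        assert all(f.atoms != ("C2", "C3") for f in flags)


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = DetectorConfig(planar_q_max=0.3)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert DetectorConfig.from_yaml(path) == cfg

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("not_a_threshold: 1\n")
        with pytest.raises(ValueError, match="not_a_threshold"):
            DetectorConfig.from_yaml(path)

    def test_thresholds_are_live(self, dictionary):
        """A stricter amplitude cutoff reclassifies an ideal chair."""
        model = unit_model("GAL")
        unit = the_unit(model, dictionary)
        strict = DetectorConfig(planar_q_max=0.7, planar_min_atoms=0)
        assert detect_planar_ring(unit, config=strict) is not None


class TestValidateModel:
    def test_clean_lactose_passes(self, lactose_model, dictionary):
        report = validate_model(lactose_model, dictionary)
        assert report.verdict == "PASS"
        assert report.flags == []
        assert report.n_units == 2

    def test_injected_flip_yields_single_attributed_flag(self, lactose_model, dictionary):
        model, labels = corrupt(
            lactose_model,
            CorruptionSpec((CorruptionOp(0, "flip_stereocenter", {"center": "C2"}),)),
            dictionary,
        )
        report = validate_model(model, dictionary)
        assert report.verdict == "FAIL"
        assert len(report.flags) == 1
        flag = report.flags[0]
        assert flag.category is ErrorCategory.CHIRALITY
        assert flag.unit_id == labels[0].unit_id
        assert flag.atoms == ("C2",)

    def test_spec_flip_through_glycosidic_anchor(self, lactose_model, dictionary):
        """Flipping GLC C4 carries the whole GAL branch along; only the C4
        chirality flag must appear."""
        model, _ = corrupt(
            lactose_model,
            CorruptionSpec((CorruptionOp(0, "flip_stereocenter", {"center": "C4"}),)),
            dictionary,
        )
        report = validate_model(model, dictionary)
        assert [(f.category, f.atoms) for f in report.flags] == [(ErrorCategory.CHIRALITY, ("C4",))]

    def test_aromatized_plus_deleted_o1_category_superset(self, lactose_model, dictionary):
        model, _ = corrupt(
            lactose_model,
            CorruptionSpec(
                (
                    CorruptionOp(0, "aromatize_ring", {"target": 1.39}),
                    CorruptionOp(0, "delete_atom", {"name": "O1"}),
                )
            ),
            dictionary,
        )
        report = validate_model(model, dictionary)
        cats = report.categories
        assert {ErrorCategory.PLANAR_RING, ErrorCategory.AROMATIC_RING, ErrorCategory.MISSING_ATOM} <= cats

    def test_no_glycan_model_reports_status(self, dictionary):
        m = StructureModel(
            residues=[ResidueRecord("ALA", ("A", 1, ""), [AtomRecord("CA", "C", np.zeros(3), ("A", 1, ""), False)])]
        )
        report = validate_model(m, dictionary)
        assert report.status == "no glycan found"
        assert report.verdict == "PASS"
        assert report.n_units == 0

    def test_report_deterministic(self, lactose_model, dictionary):
        model, _ = corrupt(
            lactose_model,
            CorruptionSpec((CorruptionOp(1, "aromatize_ring", {"target": 1.39}),)),
            dictionary,
        )
        r1 = validate_model(model, dictionary, model_id="m")
        r2 = validate_model(model, dictionary, model_id="m")
        assert r1.to_json() == r2.to_json()
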