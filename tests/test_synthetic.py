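"""Synthetic builder and corruptor: negative controls, closure, determinism."""

import json
import os

import numpy as np
import pytest

from glycancheck.detectors import validate_model
from glycancheck.exceptions import BuildError
from glycancheck.geometry import cremer_pople
from glycancheck.graph import identify_sugar_units
from glycancheck.reference import get_entry
from glycancheck.structure import parse_structure
from glycancheck.synthetic import (
    DEFAULT_MIX,
    GLYCAN_LIBRARY,
    CorruptionOp,
    CorruptionSpec,
    GlycanSpec,
    Linkage,
    build_glycan,
    build_ideal_unit,
    corrupt,
    generate_benchmark_suite,
)


class TestBuildIdealUnit:
    def test_bgc_chair_parameters(self):
        coords = build_ideal_unit("BGC", "4C1")
        e = get_entry("BGC")
        ring = np.array([coords[a] for a in e.ring_atoms])
        ps = cremer_pople(ring)
        assert 0.5 <= ps.Q <= 0.65
        assert ps.theta < 15.0
        for (a, b), ideal in e.ideal_bonds.items():
            got = float(np.linalg.norm(coords[a] - coords[b]))
            assert got == pytest.approx(ideal, abs=0.01)

    def test_gal_signs_differ_from_bgc_only_at_c4(self):
        gal_e, bgc_e = get_entry("GAL"), get_entry("BGC")
        gal = build_ideal_unit("GAL")
        bgc = build_ideal_unit("BGC")
        diffs = []
        for sg, sb in zip(gal_e.stereocenters, bgc_e.stereocenters):
            vg = np.sign(gal_e.stereo_volume(gal, sg))
            vb = np.sign(bgc_e.stereo_volume(bgc, sb))
            if vg != vb:
                diffs.append(sg.center)
        assert diffs == ["C4"]

    def test_fuc_native_chair_is_inverted(self):
        coords = build_ideal_unit("FUC", "1C4")
        e = get_entry("FUC")
        ps = cremer_pople(np.array([coords[a] for a in e.ring_atoms]))
        assert ps.theta > 165.0

    def test_ring_flip_preserves_stereo_signs(self):
        e = get_entry("BGC")
        flipped = build_ideal_unit("BGC", "1C4")
        ps = cremer_pople(np.array([flipped[a] for a in e.ring_atoms]))
        assert ps.theta > 165.0
        for sc in e.stereocenters:
            assert np.sign(e.stereo_volume(flipped, sc)) == sc.expected_sign

    def test_unsupported_conformer_rejected(self):
        with pytest.raises(BuildError, match="conformer"):
            build_ideal_unit("BGC", "3S1")


class TestBuildGlycan:
    @pytest.mark.parametrize("name", sorted(GLYCAN_LIBRARY))
    def test_library_negative_controls(self, dictionary, name):
        model = build_glycan(GLYCAN_LIBRARY[name], dictionary)
        report = validate_model(model, dictionary, model_id=name)
        assert report.verdict == "PASS", report.flags

    def test_lactose_structure(self, lactose_model):
        assert len(lactose_model.residues) == 2
        inter = [
            b
            for b in lactose_model.bonds
            if b.atom_a.residue_key != b.atom_b.residue_key
        ]
        assert len(inter) == 1  # one glycosidic bridge
        assert {inter[0].atom_a.name, inter[0].atom_b.name} == {"C1", "O4"}

    def test_donor_anomeric_oxygen_consumed(self, lactose_model):
        gal = next(r for r in lactose_model.residues if r.ccd_code == "GAL")
        assert gal.atom("O1") is None

    def test_duplicate_acceptor_site_rejected(self):
        spec = GlycanSpec(
            ("GLC", "GAL", "GAL"),
            (Linkage(1, 0, 4, "beta"), Linkage(2, 0, 4, "beta")),
        )
        with pytest.raises(BuildError, match="claimed twice"):
            build_glycan(spec)

    def test_anomer_mismatch_rejected(self):
        spec = GlycanSpec(("GLC", "GAL"), (Linkage(1, 0, 4, "alpha"),))
        with pytest.raises(BuildError, match="contradicts"):
            build_glycan(spec)

    def test_invalid_acceptor_position_rejected(self):
        spec = GlycanSpec(("GLC", "GAL"), (Linkage(1, 0, 9, "beta"),))
        with pytest.raises(BuildError, match="O9"):
            build_glycan(spec)


class TestCorrupt:
    def test_flip_is_involution(self, lactose_model, dictionary):
        op = CorruptionSpec((CorruptionOp(1, "flip_stereocenter", {"center": "C3"}),))
        once, _ = corrupt(lactose_model, op, dictionary)
        twice, _ = corrupt(once, op, dictionary)
        for r0, r1 in zip(lactose_model.residues, twice.residues):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                assert np.allclose(a0.pos, a1.pos, atol=1e-6)

    def test_flip_preserves_bond_lengths(self, lactose_model, dictionary):
        op = CorruptionSpec((CorruptionOp(0, "flip_stereocenter", {"center": "C2"}),))
        model, _ = corrupt(lactose_model, op, dictionary)
        e = get_entry("GLC")
        res = model.residues[0]
        for (a, b), ideal in e.ideal_bonds.items():
            aa, bb = res.atom(a), res.atom(b)
            if aa is None or bb is None:
                continue
            assert float(np.linalg.norm(aa.pos - bb.pos)) == pytest.approx(ideal, abs=0.01)

    def test_flip_missing_substituent_rejected(self, lactose_model, dictionary):
        # donor GAL lost its O1 to the linkage, so C1 cannot be flipped
        with pytest.raises(BuildError, match="missing"):
            corrupt(
                lactose_model,
                CorruptionSpec((CorruptionOp(1, "flip_stereocenter", {"center": "C1"}),)),
                dictionary,
            )

    def test_jitter_below_threshold_and_reproducible(self, lactose_model, dictionary):
        op = CorruptionSpec((CorruptionOp(0, "jitter", {"sigma": 0.01, "seed": 7}),))
        m1, labels = corrupt(lactose_model, op, dictionary)
        m2, _ = corrupt(lactose_model, op, dictionary)
        assert labels[0].categories == ()
        assert validate_model(m1, dictionary).verdict == "PASS"
        for r1, r2 in zip(m1.residues, m2.residues):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.array_equal(a1.pos, a2.pos)

    def test_jitter_requires_seed(self, lactose_model, dictionary):
        with pytest.raises(BuildError, match="seed"):
            corrupt(
                lactose_model,
                CorruptionSpec((CorruptionOp(0, "jitter", {"sigma": 0.01}),)),
                dictionary,
            )

    def test_deleting_reducing_end_oxygen_changes_only_that_flag(
        self, dictionary
    ):
        """The reducing-end deletion artefact must be surgically detectable:
        exactly one new MISSING_ATOM flag, nothing else, on every glycan."""
        for name, spec in GLYCAN_LIBRARY.items():
            clean = build_glycan(spec, dictionary)
            base = validate_model(clean, dictionary, model_id=name)
            units = identify_sugar_units(clean, dictionary)
            root = units[0]  # spec order puts the reducing end first
            oxy = root.anomeric_oxygen
            model, _ = corrupt(
                clean, CorruptionSpec((CorruptionOp(0, "delete_atom", {"name": oxy}),)), dictionary
            )
            report = validate_model(model, dictionary, model_id=name)
            new = [f for f in report.flags if f not in base.flags]
            assert len(new) == 1, (name, report.flags)
            assert new[0].category.value == "MISSING_ATOM"
            assert new[0].atoms == (oxy,)

    @pytest.mark.parametrize(
        "op_name,params,expected",
        [
            ("flip_stereocenter", {"center": "C2"}, {"CHIRALITY"}),
            ("shorten_bond", {"pair": ["C2", "C3"], "length": 1.33}, {"DOUBLE_BOND"}),
            ("flatten_ring", {}, {"PLANAR_RING"}),
            (
                "aromatize_ring",
                {"target": 1.39},
                {"PLANAR_RING", "AROMATIC_RING", "DOUBLE_BOND"},
            ),
            ("stretch_bond", {"pair": ["C5", "C6"]}, {"IMPROPER"}),
            ("delete_atom", {"name": "O1"}, {"MISSING_ATOM"}),
        ],
    )
    def test_closed_loop_per_op(self, lactose_model, dictionary, op_name, params, expected):
        model, labels = corrupt(
            lactose_model, CorruptionSpec((CorruptionOp(0, op_name, params),)), dictionary
        )
        assert {c.value for c in labels[0].categories} == expected
        report = validate_model(model, dictionary)
        on_unit = {f.category.value for f in report.flags if f.unit_id == labels[0].unit_id}
        off_unit = [f for f in report.flags if f.unit_id != labels[0].unit_id]
        assert on_unit == expected
        assert off_unit == []


class TestBenchmarkSuite:
    def test_all_clean_mix_passes(self, tmp_path, dictionary):
        mix = {k: (1.0 if k == "clean" else 0.0) for k in DEFAULT_MIX}
        manifest = generate_benchmark_suite(tmp_path / "s", 8, mix=mix, master_seed=11)
        for fname, info in manifest["models"].items():
            assert info["class"] == "clean"
            model = parse_structure(tmp_path / "s" / fname)
            assert validate_model(model, dictionary).verdict == "PASS"

    def test_manifest_counts_are_self_consistent(self, tmp_path):
        manifest = generate_benchmark_suite(tmp_path / "s", 30, master_seed=5)
        assert len(manifest["models"]) == 30
        classes = {info["class"] for info in manifest["models"].values()}
        assert classes <= set(DEFAULT_MIX)
        for info in manifest["models"].values():
            if info["class"] == "clean":
                assert info["labels"] == []
            else:
                assert len(info["labels"]) == 1

    def test_same_seed_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_benchmark_suite(d1, 10, master_seed=42)
        generate_benchmark_suite(d2, 10, master_seed=42)
        files1 = sorted(os.listdir(d1))
        assert files1 == sorted(os.listdir(d2))
        for f in files1:
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_mix_must_sum_to_one(self, tmp_path):
        with pytest.raises(BuildError, match="sum"):
            generate_benchmark_suite(tmp_path / "s", 2, mix={"clean": 0.5})
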