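"""The six-category stereochemical error classification.

Each detector inspects one sugar unit against its reference-dictionary
entry and emits :class:`~glycancheck.flags.ErrorFlag` objects:

CHIRALITY
    A stereocenter whose observed chiral-volume sign contradicts the
    dictionary.  Centers flattened below the degeneracy threshold carry
    no meaningful handedness and are left to the planarity/improper logic.
DOUBLE_BOND
    An intra-unit bond shortened below its pair-type single-bond floor
    (C-C 1.42, C-O 1.32, C-N 1.37 A), excluding bonds the dictionary
    itself holds short (N-acetyl carbonyl and amide, carboxylates, the
    AC1 cyclohexene).
PLANAR_RING
    Puckering amplitude collapsed (Q < 0.25 A) together with at least
    three atoms displaced > 0.5 A from the ideal unit after superposition.
AROMATIC_RING
    Benzene-like ring: near-flat (Q < 0.15 A) with mean intra-ring bond
    length < 1.45 A.  Reported independently of PLANAR_RING; the two
    co-occur by construction for truly aromatized rings.
IMPROPER
    Geometry wrong in ways not captured above: a bond length off by more
    than 0.25 A, a bond angle off by more than 20 deg, whole-unit RMSD to
    the ideal unit above 0.6 A (after undoing detected chirality flips, so
    one flipped branch is not double-counted), or a missing non-terminal
    heavy atom.
MISSING_ATOM
    The reducing-end anomeric oxygen is absent (emitted by the tree-level
    reducing-end check, not per unit).

All thresholds are configurable through :class:`DetectorConfig`; flags are
additive (violations co-occur freely), with the single exception that a
bond already flagged DOUBLE_BOND is omitted from the improper bond scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from .exceptions import GeometryError
from .flags import ErrorCategory, ErrorFlag
from .geometry import angle, cremer_pople, superpose_rmsd
from ._stereo import flip_rotation
from .graph import GlycanTree, SugarUnit, build_glycan_tree, check_reducing_end, identify_sugar_units
from .reference import DEGENERATE_VOLUME, ReferenceDictionary, ReferenceEntry, default_dictionary
from .structure import BondRecord, StructureModel, infer_bonds

__all__ = [
    "DetectorConfig",
    "ValidationReport",
    "detect_aromatic_ring",
    "detect_chirality",
    "detect_double_bonds",
    "detect_improper",
    "detect_planar_ring",
    "validate_model",
]


@dataclass(frozen=True)
class DetectorConfig:
    """All detector thresholds (defaults match the package's calibration)."""

    #: |V| below which a stereocenter is degenerate, A^3
    degenerate_volume: float = DEGENERATE_VOLUME
    #: observed-length floors for single bonds, A
    double_bond_cc: float = 1.42
    double_bond_co: float = 1.32
    double_bond_cn: float = 1.37
    #: planar-ring: amplitude ceiling (A), per-atom deviation (A), atom count
    planar_q_max: float = 0.25
    planar_atom_deviation: float = 0.5
    planar_min_atoms: int = 3
    #: aromatic-ring: amplitude ceiling (A) and mean ring bond ceiling (A)
    aromatic_q_max: float = 0.15
    aromatic_mean_bond_max: float = 1.45
    #: improper: bond (A), angle (deg) and whole-unit RMSD (A) tolerances
    improper_bond_tol: float = 0.25
    improper_angle_tol: float = 20.0
    improper_rmsd_max: float = 0.6
    #: covalent-radius tolerance used for bond inference
    bond_tolerance: float = 0.25

    def pair_threshold(self, elem_a: str, elem_b: str) -> float | None:
        pair = tuple(sorted((elem_a, elem_b)))
        return {
            ("C", "C"): self.double_bond_cc,
            ("C", "O"): self.double_bond_co,
            ("C", "N"): self.double_bond_cn,
        }.get(pair)

    @classmethod
    def from_yaml(cls, path) -> "DetectorConfig":
        """Load thresholds from a flat key-value YAML file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; known: {sorted(known)}")
        return replace(cls(), **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)


def _intra_unit_bonds(unit: SugarUnit, bonds: list[BondRecord]) -> list[BondRecord]:
    key = unit.residue.residue_key
    return [b for b in bonds if b.atom_a.residue_key == key and b.atom_b.residue_key == key]


def detect_chirality(
    unit: SugarUnit, entry: ReferenceEntry | None = None, config: DetectorConfig | None = None
) -> list[ErrorFlag]:
    """CHIRALITY flags for stereocenters with inverted chiral-volume sign.

    Centers with |V| below the degeneracy threshold are skipped here
    (flattened geometry has no handedness to judge); centers with a
    missing substituent atom are skipped and noted as unit warnings.
    """
    entry = entry or unit.entry
    config = config or DetectorConfig()
    coords = unit.coords
    out: list[ErrorFlag] = []
    for sc in entry.stereocenters:
        if any(n not in coords for n in sc.substituent_order):
            unit.warnings.append(
                f"{unit.unit_id}: stereocenter {sc.center} skipped (substituent atom missing)"
            )
            continue
        v = entry.stereo_volume(coords, sc)
        if abs(v) < config.degenerate_volume:
            continue
        sign = 1 if v > 0 else -1
        if sign != sc.expected_sign:
            out.append(
                ErrorFlag(
                    category=ErrorCategory.CHIRALITY,
                    unit_id=unit.unit_id,
                    ccd_code=unit.ccd_code,
                    atoms=(sc.center,),
                    magnitude=abs(v),
                    detail=(
                        f"chiral volume {v:+.3f} A^3 over {'-'.join(sc.substituent_order)}, "
                        f"expected sign {sc.expected_sign:+d}"
                    ),
                )
            )
    return out


def detect_double_bonds(
    unit: SugarUnit, bonds: list[BondRecord], config: DetectorConfig | None = None
) -> list[ErrorFlag]:
    """DOUBLE_BOND flags for intra-unit bonds below their pair-type floor.

    Dictionary-sanctioned short bonds -- any bond whose ideal length is
    itself below the floor (carbonyls, amides, carboxylates, the AC1 ene
    bond) -- are excluded.
    """
    config = config or DetectorConfig()
    entry = unit.entry
    out: list[ErrorFlag] = []
    for b in _intra_unit_bonds(unit, bonds):
        threshold = config.pair_threshold(b.atom_a.element, b.atom_b.element)
        if threshold is None or b.length >= threshold:
            continue
        pair = tuple(sorted((b.atom_a.name, b.atom_b.name)))
        ideal = entry.ideal_bonds.get(pair)
        if ideal is not None and ideal < threshold:
            continue  # sanctioned: the dictionary itself holds this bond short
        out.append(
            ErrorFlag(
                category=ErrorCategory.DOUBLE_BOND,
                unit_id=unit.unit_id,
                ccd_code=unit.ccd_code,
                atoms=pair,
                magnitude=b.length,
                detail=f"bond {pair[0]}-{pair[1]} at {b.length:.2f} A (< {threshold:.2f} A floor)",
            )
        )
    return out


def _superpose_deviations(
    unit: SugarUnit, coords: dict[str, np.ndarray]
) -> tuple[dict[str, float], float] | None:
    """Per-atom deviations and RMSD vs the ideal unit (proper rotations only)."""
    entry = unit.entry
    common = [n for n in entry.atom_names if n in coords]
    if len(common) < 3:
        return None
    obs = np.array([coords[n] for n in common])
    ref = np.array([entry.ideal_coords[n] for n in common])
    rmsd, rot, trans = superpose_rmsd(obs, ref)
    moved = obs @ rot.T + trans
    dev = np.linalg.norm(moved - ref, axis=1)
    return dict(zip(common, dev.tolist())), rmsd


def detect_planar_ring(
    unit: SugarUnit, config: DetectorConfig | None = None
) -> ErrorFlag | None:
    """PLANAR_RING flag for a collapsed ring with broad geometric deviation.

    Fires iff the puckering amplitude drops below ``planar_q_max`` AND at
    least ``planar_min_atoms`` atoms sit further than
    ``planar_atom_deviation`` from the ideal unit after superposition.
    """
    config = config or DetectorConfig()
    ring = unit.ring_coords()
    if ring is None:
        unit.warnings.append(f"{unit.unit_id}: ring incomplete; planarity not assessed")
        return None
    q = cremer_pople(ring).Q
    if q >= config.planar_q_max:
        return None
    res = _superpose_deviations(unit, unit.coords)
    if res is None:
        return None
    deviations, _ = res
    off = sorted(n for n, d in deviations.items() if d > config.planar_atom_deviation)
    if len(off) < config.planar_min_atoms:
        return None
    return ErrorFlag(
        category=ErrorCategory.PLANAR_RING,
        unit_id=unit.unit_id,
        ccd_code=unit.ccd_code,
        atoms=tuple(unit.ring_atoms),
        magnitude=q,
        detail=f"Q={q:.3f} A; {len(off)} atoms deviate > {config.planar_atom_deviation} A: {', '.join(off)}",
    )


def detect_aromatic_ring(
    unit: SugarUnit, bonds: list[BondRecord] | None = None, config: DetectorConfig | None = None
) -> ErrorFlag | None:
    """AROMATIC_RING flag: near-flat ring with shortened ring bonds.

    Assessed from ring coordinates directly (consecutive ring-atom
    distances), independent of -- and freely co-occurring with -- the
    planar-ring classification.
    """
    config = config or DetectorConfig()
    ring = unit.ring_coords()
    if ring is None:
        return None
    q = cremer_pople(ring).Q
    if q >= config.aromatic_q_max:
        return None
    lengths = [float(np.linalg.norm(ring[(i + 1) % 6] - ring[i])) for i in range(6)]
    mean_len = float(np.mean(lengths))
    if mean_len >= config.aromatic_mean_bond_max:
        return None
    return ErrorFlag(
        category=ErrorCategory.AROMATIC_RING,
        unit_id=unit.unit_id,
        ccd_code=unit.ccd_code,
        atoms=tuple(unit.ring_atoms),
        magnitude=q,
        detail=f"Q={q:.3f} A, mean ring bond {mean_len:.3f} A",
    )


def _chirality_normalized_coords(
    unit: SugarUnit, chirality_flags: list[ErrorFlag]
) -> dict[str, np.ndarray]:
    """Coordinates with detected stereocenter flips undone.

    Rotates each flagged center's exocyclic branches back onto their
    mirrored attachment directions (the flip construction is an
    involution), so the improper scan judges residual geometry rather
    than re-counting the chirality error.
    """
    coords = {n: p.copy() for n, p in unit.coords.items()}
    entry = unit.entry
    flagged = {f.atoms[0] for f in chirality_flags if f.unit_id == unit.unit_id}
    for sc in entry.stereocenters:
        if sc.center not in flagged:
            continue
        a, b = sc.substituent_order[0], sc.substituent_order[1]
        if a not in coords or b not in coords or sc.center not in coords:
            continue
        for name, branch in zip(sc.substituent_order[2:], entry.stereo_branches(sc)):
            if name == sc.center or name not in coords:
                continue
            try:
                rot = flip_rotation(coords[sc.center], coords[a], coords[b], coords[name])
            except GeometryError:
                continue
            for n in branch:
                if n in coords:
                    coords[n] = coords[sc.center] + rot @ (coords[n] - coords[sc.center])
    return coords


def detect_improper(
    unit: SugarUnit,
    entry: ReferenceEntry | None = None,
    config: DetectorConfig | None = None,
    exclude_bonds: set[tuple[str, str]] | None = None,
    chirality_flags: list[ErrorFlag] | None = None,
    skip_rmsd: bool = False,
) -> list[ErrorFlag]:
    """IMPROPER flags for residual geometry errors.

    ``exclude_bonds`` (sorted atom-name pairs) removes bonds already
    flagged DOUBLE_BOND from the length scan; ``chirality_flags`` lets the
    RMSD criterion undo detected stereocenter flips first; ``skip_rmsd``
    disables the whole-unit RMSD criterion (used when the unit is already
    flagged PLANAR_RING, whose geometry change the RMSD would re-count).
    """
    entry = entry or unit.entry
    config = config or DetectorConfig()
    exclude_bonds = exclude_bonds or set()
    coords = unit.coords
    out: list[ErrorFlag] = []

    def _flag(atoms, magnitude, detail):
        out.append(
            ErrorFlag(
                category=ErrorCategory.IMPROPER,
                unit_id=unit.unit_id,
                ccd_code=unit.ccd_code,
                atoms=tuple(atoms),
                magnitude=magnitude,
                detail=detail,
            )
        )

    for (a, b), ideal in sorted(entry.ideal_bonds.items()):
        if (a, b) in exclude_bonds or a not in coords or b not in coords:
            continue
        obs = float(np.linalg.norm(coords[a] - coords[b]))
        dev = abs(obs - ideal)
        if dev > config.improper_bond_tol:
            _flag((a, b), dev, f"bond {a}-{b} {obs:.2f} A vs ideal {ideal:.2f} A")

    for (a, b, c), ideal in sorted(entry.ideal_angles.items()):
        if any(n not in coords for n in (a, b, c)):
            continue
        obs = angle(coords[a], coords[b], coords[c])
        dev = abs(obs - ideal)
        if dev > config.improper_angle_tol:
            _flag((a, b, c), dev, f"angle {a}-{b}-{c} {obs:.1f} deg vs ideal {ideal:.1f} deg")

    res = None
    if not skip_rmsd:
        norm_coords = _chirality_normalized_coords(unit, chirality_flags or [])
        res = _superpose_deviations(unit, norm_coords)
    if res is not None:
        _, rmsd = res
        if rmsd > config.improper_rmsd_max:
            _flag(
                tuple(sorted(n for n in entry.atom_names if n in coords)),
                rmsd,
                f"whole-unit RMSD {rmsd:.2f} A vs ideal geometry",
            )

    for name in sorted(unit.missing_atoms):
        if name == entry.anomeric_oxygen:
            continue  # consumed by a linkage or the reducing-end check's business
        _flag((name,), 0.0, f"dictionary heavy atom {name} absent (non-terminal)")
    return out


@dataclass
class ValidationReport:
    """All flags for one model plus verdict and condition metadata."""

    model_id: str
    flags: list[ErrorFlag]
    n_units: int
    condition: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    status: str = "ok"  # "ok" | "no glycan found"

    @property
    def verdict(self) -> str:
        return "PASS" if not self.flags else "FAIL"

    @property
    def categories(self) -> set[ErrorCategory]:
        return {f.category for f in self.flags}

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "status": self.status,
            "verdict": self.verdict,
            "n_units": self.n_units,
            "condition": dict(sorted(self.condition.items())),
            "flags": [f.to_dict() for f in self.flags],
            "warnings": list(self.warnings),
        }

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        kw.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kw)


def _sort_key(flag: ErrorFlag):
    order = list(ErrorCategory)
    return (flag.unit_id, order.index(flag.category), flag.atoms)


def validate_model(
    model: StructureModel,
    dictionary: ReferenceDictionary | None = None,
    config: DetectorConfig | None = None,
    model_id: str | None = None,
    condition: dict[str, str] | None = None,
) -> ValidationReport:
    """Run the full per-model pipeline and return its report.

    Identifies sugar units, assembles the glycan tree, applies all six
    detectors to every unit plus the reducing-end check per tree, and
    returns a deterministic report whose verdict is PASS iff no flag of
    any category was raised.
    """
    dictionary = dictionary or default_dictionary()
    config = config or DetectorConfig()
    if model_id is None:
        model_id = model.source_path or "model"
    if not model.bonds:
        infer_bonds(model, tolerance=config.bond_tolerance)
    units = identify_sugar_units(model, dictionary)
    if not units:
        return ValidationReport(
            model_id=model_id,
            flags=[],
            n_units=0,
            condition=condition or {},
            warnings=list(model.warnings),
            status="no glycan found",
        )
    tree = build_glycan_tree(units, model.bonds)
    flags: list[ErrorFlag] = []
    for unit in units:
        chir = detect_chirality(unit, config=config)
        dbl = detect_double_bonds(unit, model.bonds, config=config)
        flagged_pairs = {f.atoms for f in dbl}
        planar = detect_planar_ring(unit, config=config)
        aromatic = detect_aromatic_ring(unit, model.bonds, config=config)
        improper = detect_improper(
            unit,
            config=config,
            exclude_bonds=flagged_pairs,
            chirality_flags=chir,
            skip_rmsd=planar is not None,
        )
        flags.extend(chir)
        flags.extend(dbl)
        if planar:
            flags.append(planar)
        if aromatic:
            flags.append(aromatic)
        flags.extend(improper)
    flags.extend(check_reducing_end(tree))
    flags.sort(key=_sort_key)
    warnings = list(model.warnings) + tree.warnings + [w for u in units for w in u.warnings]
    return ValidationReport(
        model_id=model_id,
        flags=flags,
        n_units=len(units),
        condition=condition or {},
        warnings=warnings,
    )
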