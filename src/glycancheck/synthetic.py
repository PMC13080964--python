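"""Synthetic glycan builder and corruptor.

Stands in for the study's raw cofolding outputs: builds ideal
chair-conformation glycans from internal coordinates and injects each
error class at controlled magnitude with machine-readable ground-truth
labels, so every detector is verifiable without external data.

* :func:`build_ideal_unit` -- one ideal monosaccharide (ring torsions
  alternating around +/-60 deg, dictionary bond lengths).
* :func:`build_glycan` -- a whole oligosaccharide from a
  :class:`GlycanSpec`: units placed with C-O-C bridge geometry (C-O
  1.43 A, C-O-C 117 deg, phi/psi defaults -60/120 deg with a fallback
  grid on clashes), the donor's anomeric oxygen consumed by each linkage,
  exactly one reducing end.
* :func:`corrupt` -- applies :class:`CorruptionOp` edits (stereocenter
  flip, ring flattening/aromatization, bond shortening/stretching, atom
  deletion, coordinate jitter) and emits one ground-truth label per op.
  Edits trace substituent branches on the model's inferred bond graph, so
  an edit at an anchor carrying a glycosidic bridge moves the downstream
  unit rigidly instead of severing the linkage.
* :func:`generate_benchmark_suite` -- a reproducible labelled directory
  of models emulating the study's evaluation at desk scale.

Corruption magnitudes default to clearly supra-threshold values (flatten
to Q ~ 0; aromatize to 1.39 A ring bonds; shorten to 1.33 A; stretch by
+0.35 A) so that detection is not threshold-marginal; ``MARGINAL``
magnitudes at ~1.1x threshold are provided for sensitivity studies.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import BuildError
from .flags import ErrorCategory
from .geometry import place_zmatrix_atom, superpose_rmsd
from ._builder import build_chair_ring, build_unit_coords
from ._stereo import flip_rotation
from .reference import ReferenceDictionary, ReferenceEntry, default_dictionary
from .structure import AtomRecord, ResidueRecord, StructureModel, infer_bonds, write_structure

__all__ = [
    "CorruptionOp",
    "CorruptionSpec",
    "GlycanSpec",
    "GroundTruthLabel",
    "GLYCAN_LIBRARY",
    "DEFAULT_MIX",
    "Linkage",
    "build_glycan",
    "build_ideal_unit",
    "corrupt",
    "generate_benchmark_suite",
]

#: Glycosidic bridge geometry defaults.
BRIDGE_CO = 1.43  # C1'-O bridge bond, A
BRIDGE_ANGLE = 117.0  # C-O-C angle, deg
PHI_DEFAULT = -60.0  # O5'-C1'-On-Cn
PSI_DEFAULT = 120.0  # C1'-On-Cn-(ring neighbour)
PSI_FALLBACK = (120.0, -120.0, 60.0, -60.0, 180.0, 90.0, -90.0)
PHI_FALLBACK = (-60.0, 60.0, 180.0)
CLASH_DISTANCE = 2.0

#: Supra-threshold corruption magnitudes (defaults).
DEFAULT_MAGNITUDES = {
    "shorten_bond": 1.33,  # target length, A (C-C floor is 1.42)
    "aromatize_ring": 1.39,  # target ring bond length, A
    "stretch_bond": 0.35,  # added length, A (improper floor is 0.25)
}

#: Threshold-marginal magnitudes (~1.1x each detector threshold).
MARGINAL_MAGNITUDES = {
    "shorten_bond": 1.42 / 1.1,
    "aromatize_ring": 1.45 * 0.96,
    "stretch_bond": 0.25 * 1.1,
}


@dataclass(frozen=True)
class Linkage:
    donor: int  # index into GlycanSpec.units (provides the anomeric carbon)
    acceptor: int
    position: int  # acceptor hydroxyl position n (bridge oxygen On)
    anomer: str | None = None  # "alpha"/"beta"; validated against the donor code


@dataclass(frozen=True)
class GlycanSpec:
    """Composition of a synthetic glycan: CCD codes plus linkage tree."""

    units: tuple[str, ...]
    linkages: tuple[Linkage, ...] = ()
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "units", tuple(self.units))
        object.__setattr__(
            self,
            "linkages",
            tuple(l if isinstance(l, Linkage) else Linkage(*l) for l in self.linkages),
        )


@dataclass(frozen=True)
class CorruptionOp:
    """One corruption: operation name, target unit, parameters."""

    unit_index: int
    name: str  # flip_stereocenter | flatten_ring | aromatize_ring |
    #            shorten_bond | stretch_bond | delete_atom | jitter
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CorruptionSpec:
    ops: tuple[CorruptionOp, ...]

    def __post_init__(self):
        object.__setattr__(
            self, "ops", tuple(o if isinstance(o, CorruptionOp) else CorruptionOp(*o) for o in self.ops)
        )


@dataclass(frozen=True)
class GroundTruthLabel:
    """Expected detector outcome of one corruption op."""

    op_name: str
    unit_index: int
    unit_id: str
    ccd_code: str
    categories: tuple[ErrorCategory, ...]
    atoms: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "op": self.op_name,
            "unit_index": self.unit_index,
            "unit": self.unit_id,
            "ccd_code": self.ccd_code,
            "categories": [c.value for c in self.categories],
            "atoms": list(self.atoms),
        }


#: Benchmark glycan compositions assembled from the nine supported sugars.
GLYCAN_LIBRARY: dict[str, GlycanSpec] = {
    "lactose": GlycanSpec(("GLC", "GAL"), (Linkage(1, 0, 4, "beta"),), name="lactose"),
    "lnnt": GlycanSpec(
        ("GLC", "GAL", "NAG", "GAL"),
        (Linkage(1, 0, 4, "beta"), Linkage(2, 1, 3, "beta"), Linkage(3, 2, 4, "beta")),
        name="lnnt",
    ),
    "sialyllactose": GlycanSpec(
        ("GLC", "GAL", "SIA"),
        (Linkage(1, 0, 4, "beta"), Linkage(2, 1, 3, "alpha")),
        name="sialyllactose",
    ),
    "lewis_x": GlycanSpec(
        ("NAG", "GAL", "FUC"),
        (Linkage(1, 0, 4, "beta"), Linkage(2, 0, 3, "alpha")),
        name="lewis_x",
    ),
    "blood_group_a": GlycanSpec(
        ("GAL", "A2G", "FUC"),
        (Linkage(1, 0, 3, "alpha"), Linkage(2, 0, 2, "alpha")),
        name="blood_group_a",
    ),
    "cellobiose": GlycanSpec(("GLC", "BGC"), (Linkage(1, 0, 4, "beta"),), name="cellobiose"),
    "chitobiose": GlycanSpec(("NAG", "NDG"), (Linkage(1, 0, 4, "alpha"),), name="chitobiose"),
    "acarviosin": GlycanSpec(("GLC", "AC1"), (Linkage(1, 0, 4, "alpha"),), name="acarviosin"),
}

#: Default per-model corruption mix for benchmark suites.  Mirrors the
#: observed ranking of cofolding failure modes: chirality errors dominate,
#: followed by artificial double bonds, ring flattening/aromatization,
#: reducing-end atom loss and improper geometry, plus a clean fraction.
DEFAULT_MIX: dict[str, float] = {
    "clean": 0.15,
    "chirality": 0.40,
    "double_bond": 0.15,
    "planar_ring": 0.10,
    "aromatic_ring": 0.08,
    "improper": 0.05,
    "missing_atom": 0.07,
}


def build_ideal_unit(ccd_code: str, conformer: str | None = None, dictionary=None) -> dict[str, np.ndarray]:
    """Ideal heavy-atom coordinates of one monosaccharide.

    ``conformer`` may be the entry's native chair (default) or its
    ring-flipped form; any other label raises.
    """
    dictionary = dictionary or default_dictionary()
    entry = dictionary.get_entry(ccd_code)
    if conformer is None or conformer == entry.chair:
        return {k: v.copy() for k, v in entry.ideal_coords.items()}
    return build_unit_coords(entry.raw, conformer)


def _validate_spec(spec: GlycanSpec, dictionary: ReferenceDictionary) -> int:
    n = len(spec.units)
    if n == 0:
        raise BuildError("empty glycan spec")
    donors = set()
    used_acceptor_sites: set[tuple[int, int]] = set()
    for l in spec.linkages:
        if not (0 <= l.donor < n and 0 <= l.acceptor < n) or l.donor == l.acceptor:
            raise BuildError(f"linkage {l} references invalid unit indices")
        if l.donor in donors:
            raise BuildError(f"unit {l.donor} is donor in two linkages (anomeric carbon reused)")
        donors.add(l.donor)
        site = (l.acceptor, l.position)
        if site in used_acceptor_sites:
            raise BuildError(f"acceptor oxygen O{l.position} of unit {l.acceptor} claimed twice")
        used_acceptor_sites.add(site)
        acc_entry = dictionary.get_entry(spec.units[l.acceptor])
        oname = f"O{l.position}"
        if oname not in acc_entry.atom_names or oname == acc_entry.anomeric_oxygen or oname == acc_entry.ring_atoms[0]:
            raise BuildError(
                f"unit {l.acceptor} ({acc_entry.ccd_code}) has no linkable hydroxyl O{l.position}"
            )
        donor_entry = dictionary.get_entry(spec.units[l.donor])
        if l.anomer is not None:
            norm = {"a": "alpha", "b": "beta"}.get(l.anomer, l.anomer)
            if norm != donor_entry.anomer:
                raise BuildError(
                    f"linkage anomer {l.anomer!r} contradicts donor {donor_entry.ccd_code} "
                    f"({donor_entry.anomer})"
                )
    roots = [i for i in range(n) if i not in donors]
    if not roots:
        raise BuildError("linkages form a cycle: no unit with a free anomeric carbon")
    children: dict[int, list[int]] = {}
    for l in spec.linkages:
        children.setdefault(l.acceptor, []).append(l.donor)
    seen = set(roots)
    stack = list(roots)
    while stack:
        cur = stack.pop()
        for nxt in children.get(cur, []):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    if len(seen) != n:
        raise BuildError("linkages contain a cycle or disconnected donor loop")
    if len(roots) > 1 and spec.linkages:
        raise BuildError(f"spec has {len(roots)} reducing ends; expected a single tree")
    return roots[0]


def _near_set(entry: ReferenceEntry, center: str, shells: int = 2) -> set[str]:
    near = {center}
    for _ in range(shells):
        near |= {n for a in list(near) for n in entry.neighbors(a)}
    return near


def build_glycan(spec: GlycanSpec, dictionary: ReferenceDictionary | None = None) -> StructureModel:
    """Assemble a synthetic oligosaccharide model from a :class:`GlycanSpec`.

    Units are placed reducing-end first; each donor is rigidly docked onto
    its acceptor's hydroxyl oxygen with ideal bridge geometry, trying a
    fallback psi/phi grid if a placement clashes (< 2 A between non-bonded
    inter-unit atoms).  The donor's own anomeric oxygen is consumed by the
    linkage.  Residues are numbered 1..n on chain G in spec order.
    """
    dictionary = dictionary or default_dictionary()
    root = _validate_spec(spec, dictionary)
    entries = [dictionary.get_entry(code) for code in spec.units]
    placed: dict[int, dict[str, np.ndarray]] = {
        root: build_ideal_unit(spec.units[root], dictionary=dictionary)
    }

    by_acceptor: dict[int, list[Linkage]] = {}
    for l in spec.linkages:
        by_acceptor.setdefault(l.acceptor, []).append(l)
    queue = [root]
    while queue:
        acc_idx = queue.pop(0)
        acc_entry = entries[acc_idx]
        acc_coords = placed[acc_idx]
        for link in sorted(by_acceptor.get(acc_idx, []), key=lambda l: l.position):
            donor_entry = entries[link.donor]
            local = build_ideal_unit(spec.units[link.donor], dictionary=dictionary)
            oname = f"O{link.position}"
            cname = f"C{link.position}"
            if cname not in acc_coords:
                raise BuildError(f"acceptor {acc_entry.ccd_code} lacks carbon {cname}")
            ring_nbrs = [a for a in acc_entry.neighbors(cname) if a in acc_entry.ring_atoms]
            if not ring_nbrs:
                raise BuildError(f"no ring neighbour for torsion reference at {cname}")
            tors_ref = sorted(ring_nbrs, key=acc_entry.ring_atoms.index)[0]

            ac = donor_entry.anomeric_carbon
            ao = donor_entry.anomeric_oxygen
            ring_o = donor_entry.ring_atoms[0]
            d_co = float(np.linalg.norm(local[ac] - local[ao]))
            d_ring = float(np.linalg.norm(local[ac] - local[ring_o]))
            ang_oco = 109.47

            src = np.array([local[ac], local[ring_o], local[ao]])
            success = False
            for psi, phi in [(p, f) for f in PHI_FALLBACK for p in PSI_FALLBACK]:
                c1_t = place_zmatrix_atom(
                    acc_coords[oname], acc_coords[cname], acc_coords[tors_ref],
                    d_co, BRIDGE_ANGLE, psi,
                )
                o5_t = place_zmatrix_atom(
                    c1_t, acc_coords[oname], acc_coords[cname], d_ring, ang_oco, phi
                )
                dst = np.array([c1_t, o5_t, acc_coords[oname]])
                _, rot, trans = superpose_rmsd(src, dst)
                moved = {
                    name: pos @ rot.T + trans for name, pos in local.items() if name != ao
                }
                donor_near = _near_set(donor_entry, ac)
                acc_near = _near_set(acc_entry, oname)
                clash = False
                for other_idx, other_coords in placed.items():
                    for dn, dp in moved.items():
                        for on, op_ in other_coords.items():
                            if other_idx == acc_idx and dn in donor_near and on in acc_near:
                                continue
                            if float(np.linalg.norm(dp - op_)) < CLASH_DISTANCE:
                                clash = True
                                break
                        if clash:
                            break
                    if clash:
                        break
                if not clash:
                    placed[link.donor] = moved
                    success = True
                    break
            if not success:
                raise BuildError(
                    f"cannot place {donor_entry.ccd_code} onto {acc_entry.ccd_code} O{link.position} "
                    f"without clashes (tried psi x phi = {PSI_FALLBACK} x {PHI_FALLBACK})"
                )
            queue.append(link.donor)

    residues = []
    for i, code in enumerate(spec.units):
        entry = entries[i]
        key = ("G", i + 1, "")
        coords = placed[i]
        atoms = [
            AtomRecord(name=n, element=n[0], pos=np.asarray(coords[n], float), residue_key=key, het_flag=True)
            for n in entry.atom_names
            if n in coords
        ]
        residues.append(ResidueRecord(code, key, atoms))
    model = StructureModel(residues=residues)
    infer_bonds(model)
    return model


# ---------------------------------------------------------------------------
# corruption operators


def _sugar_residues(model: StructureModel, dictionary: ReferenceDictionary) -> list[ResidueRecord]:
    return [r for r in model.residues if r.ccd_code in dictionary]


class _ModelEditor:
    """Mutable view of a model for corruption ops.

    Holds the bond-graph adjacency of the *clean* model so that branch
    traversal can follow glycosidic bridges across residues.  Atom
    positions are edited in place (the position arrays are shared with
    the model's records).
    """

    def __init__(self, model: StructureModel, dictionary: ReferenceDictionary):
        self.model = model
        self.dictionary = dictionary
        if not model.bonds:
            infer_bonds(model)
        self.adj: dict[int, list[AtomRecord]] = {}
        for b in model.bonds:
            self.adj.setdefault(id(b.atom_a), []).append(b.atom_b)
            self.adj.setdefault(id(b.atom_b), []).append(b.atom_a)

    def branch(self, start: AtomRecord, blocked: list[AtomRecord]) -> list[AtomRecord]:
        blocked_ids = {id(x) for x in blocked}
        seen = {id(start)}
        out = [start]
        stack = [start]
        while stack:
            cur = stack.pop()
            for nxt in self.adj.get(id(cur), []):
                if id(nxt) not in seen and id(nxt) not in blocked_ids:
                    seen.add(id(nxt))
                    out.append(nxt)
                    stack.append(nxt)
        return out

    def remove_atom(self, res: ResidueRecord, atom: AtomRecord) -> None:
        res.atoms = [a for a in res.atoms if a is not atom]
        for nbr in self.adj.pop(id(atom), []):
            self.adj[id(nbr)] = [a for a in self.adj[id(nbr)] if a is not atom]


def _require_atom(res: ResidueRecord, name: str) -> AtomRecord:
    atom = res.atom(name)
    if atom is None:
        raise BuildError(f"atom {name!r} missing from {res.ccd_code} {res.residue_key}")
    return atom


def _op_flip_stereocenter(ed: _ModelEditor, res, entry, params):
    center = params["center"]
    sc = next((s for s in entry.stereocenters if s.center == center), None)
    if sc is None:
        raise BuildError(f"{entry.ccd_code} has no stereocenter {center!r}")
    c = _require_atom(res, center)
    a = _require_atom(res, sc.substituent_order[0])
    b = _require_atom(res, sc.substituent_order[1])
    subs = [n for n in sc.substituent_order[2:] if n != center]
    if not subs:
        raise BuildError(f"stereocenter {center} has no exocyclic substituent to flip")
    for name in subs:
        s = _require_atom(res, name)
        rot = flip_rotation(c.pos, a.pos, b.pos, s.pos)
        for atom in ed.branch(s, blocked=[c]):
            atom.pos[:] = c.pos + rot @ (atom.pos - c.pos)
    return (ErrorCategory.CHIRALITY,), (center,)


def _planar_ring_target(entry, ring_atoms: list[AtomRecord], bond_length: float | None) -> np.ndarray:
    """Ideally planar hexagon (ideal or rescaled bond lengths) fitted onto
    the current ring positions."""
    names = [a.name for a in ring_atoms]
    if bond_length is None:
        lengths = [
            entry.ideal_bonds[tuple(sorted((names[i], names[(i + 1) % 6])))] for i in range(6)
        ]
    else:
        lengths = [bond_length] * 6
    flat = build_chair_ring(lengths, parity=+1, z0=0.0)
    obs = np.array([a.pos for a in ring_atoms])
    _, rot, trans = superpose_rmsd(flat, obs)
    return flat @ rot.T + trans


def _reseat_ring(ed: _ModelEditor, res, entry, new_ring: np.ndarray) -> None:
    """Set ring atoms to ``new_ring`` and move every substituent branch
    rigidly with its anchor's (prev, anchor, next) local frame."""
    ring_atoms = [_require_atom(res, n) for n in entry.ring_atoms]
    ring_ids = set(map(id, ring_atoms))
    old_pos = [a.pos.copy() for a in ring_atoms]
    moves: list[tuple[AtomRecord, np.ndarray]] = []
    for i, anchor in enumerate(ring_atoms):
        exo = [n for n in ed.adj.get(id(anchor), []) if id(n) not in ring_ids]
        if not exo:
            continue
        old_tri = np.array([old_pos[i - 1], old_pos[i], old_pos[(i + 1) % 6]])
        new_tri = np.array([new_ring[i - 1], new_ring[i], new_ring[(i + 1) % 6]])
        _, rot, trans = superpose_rmsd(old_tri, new_tri)
        for nbr in exo:
            for atom in ed.branch(nbr, blocked=ring_atoms):
                moves.append((atom, atom.pos @ rot.T + trans))
    for atom, pos in moves:
        atom.pos[:] = pos
    for i, atom in enumerate(ring_atoms):
        atom.pos[:] = new_ring[i]


def _op_flatten_ring(ed, res, entry, params):
    ring = [_require_atom(res, n) for n in entry.ring_atoms]
    _reseat_ring(ed, res, entry, _planar_ring_target(entry, ring, None))
    return (ErrorCategory.PLANAR_RING,), tuple(entry.ring_atoms)


def _op_aromatize_ring(ed, res, entry, params):
    target = float(params.get("target", DEFAULT_MAGNITUDES["aromatize_ring"]))
    ring = [_require_atom(res, n) for n in entry.ring_atoms]
    _reseat_ring(ed, res, entry, _planar_ring_target(entry, ring, target))
    cats = [ErrorCategory.PLANAR_RING, ErrorCategory.AROMATIC_RING]
    if target < 1.42:  # genuinely plants sub-floor C-C ring bonds as well
        cats.append(ErrorCategory.DOUBLE_BOND)
    return tuple(cats), tuple(entry.ring_atoms)


def _resize_bond(ed: _ModelEditor, res, entry, a_name: str, b_name: str, new_length: float):
    a = _require_atom(res, a_name)
    b = _require_atom(res, b_name)
    ring = set(entry.ring_atoms)
    if a_name in ring and b_name in ring:
        blocked = [_require_atom(res, n) for n in ring if n != b_name]
    else:
        blocked = [a]
    moving = ed.branch(b, blocked=blocked)
    if any(x is a for x in moving):
        raise BuildError(f"bond {a_name}-{b_name} closes a non-ring cycle; cannot resize")
    axis = b.pos - a.pos
    old = float(np.linalg.norm(axis))
    shift = (new_length - old) * axis / old
    for atom in moving:
        atom.pos[:] = atom.pos + shift


def _op_shorten_bond(ed, res, entry, params):
    a, b = params["pair"]
    target = float(params.get("length", DEFAULT_MAGNITUDES["shorten_bond"]))
    _resize_bond(ed, res, entry, a, b, target)
    return (ErrorCategory.DOUBLE_BOND,), tuple(sorted((a, b)))


def _op_stretch_bond(ed, res, entry, params):
    a, b = params["pair"]
    pair = tuple(sorted((a, b)))
    ideal = entry.ideal_bonds.get(pair)
    if ideal is None:
        raise BuildError(f"{entry.ccd_code}: {a}-{b} is not a dictionary bond")
    target = params.get("length")
    if target is None:
        target = ideal + DEFAULT_MAGNITUDES["stretch_bond"]
    _resize_bond(ed, res, entry, a, b, float(target))
    return (ErrorCategory.IMPROPER,), pair


def _op_delete_atom(ed, res, entry, params):
    name = params["name"]
    atom = _require_atom(res, name)
    ed.remove_atom(res, atom)
    cat = (
        ErrorCategory.MISSING_ATOM
        if name == entry.anomeric_oxygen
        else ErrorCategory.IMPROPER
    )
    return (cat,), (name,)


def _op_jitter(ed, res, entry, params):
    sigma = float(params["sigma"])
    seed = params.get("seed")
    if seed is None:
        raise BuildError("jitter requires an explicit seed")
    rng = np.random.default_rng(int(seed))
    atoms = sorted(res.atoms, key=lambda a: a.name)
    noise = rng.normal(scale=sigma, size=(len(atoms), 3))
    for atom, dx in zip(atoms, noise):
        atom.pos[:] = atom.pos + dx
    return (), tuple()


_OPS = {
    "flip_stereocenter": _op_flip_stereocenter,
    "flatten_ring": _op_flatten_ring,
    "aromatize_ring": _op_aromatize_ring,
    "shorten_bond": _op_shorten_bond,
    "stretch_bond": _op_stretch_bond,
    "delete_atom": _op_delete_atom,
    "jitter": _op_jitter,
}


def corrupt(
    model: StructureModel,
    spec: CorruptionSpec,
    dictionary: ReferenceDictionary | None = None,
) -> tuple[StructureModel, list[GroundTruthLabel]]:
    """Apply corruption ops to a copy of ``model``; emit labels 1:1 with ops.

    Stereocenter flips preserve all bond lengths and are involutions;
    flattening/aromatization replaces the ring with a fitted planar
    hexagon and re-seats substituent branches rigidly with their anchor's
    local frame; jitter adds seeded isotropic Gaussian noise.  Bonds are
    re-inferred on the corrupted coordinates before returning.
    """
    dictionary = dictionary or default_dictionary()
    new_model = StructureModel(
        residues=[
            ResidueRecord(
                r.ccd_code,
                r.residue_key,
                [AtomRecord(a.name, a.element, a.pos.copy(), a.residue_key, a.het_flag) for a in r.atoms],
            )
            for r in model.residues
        ],
        source_path=model.source_path,
        format=model.format,
    )
    infer_bonds(new_model)
    ed = _ModelEditor(new_model, dictionary)
    sugars = _sugar_residues(new_model, dictionary)
    labels: list[GroundTruthLabel] = []
    for op in spec.ops:
        if not (0 <= op.unit_index < len(sugars)):
            raise BuildError(
                f"corruption references unit {op.unit_index}; model has {len(sugars)} sugars"
            )
        if op.name not in _OPS:
            raise BuildError(f"unknown corruption op {op.name!r}")
        res = sugars[op.unit_index]
        entry = dictionary.get_entry(res.ccd_code)
        categories, atoms = _OPS[op.name](ed, res, entry, op.params)
        chain, num, icode = res.residue_key
        labels.append(
            GroundTruthLabel(
                op_name=op.name,
                unit_index=op.unit_index,
                unit_id=f"{chain}:{num}{icode}:{res.ccd_code}",
                ccd_code=res.ccd_code,
                categories=categories,
                atoms=atoms,
            )
        )
    infer_bonds(new_model)
    return new_model, labels


# ---------------------------------------------------------------------------
# benchmark suite generation


def _model_rng(master_seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(index,))
    )


def _bridging_atoms(model: StructureModel, res: ResidueRecord) -> set[str]:
    """Names of this residue's atoms bonded to another residue."""
    out = set()
    for b in model.bonds:
        ka, kb = b.atom_a.residue_key, b.atom_b.residue_key
        if ka == res.residue_key and kb != ka:
            out.add(b.atom_a.name)
        elif kb == res.residue_key and ka != kb:
            out.add(b.atom_b.name)
    return out


def _eligible_flip_centers(entry: ReferenceEntry, res: ResidueRecord, bridging: set[str]) -> list[str]:
    """Stereocenters whose flip stays inside the unit and moves no other
    stereocenter's atoms (used by the benchmark generator for clean,
    single-label injections)."""
    present = {a.name for a in res.atoms}
    centers = []
    all_centers = {sc.center for sc in entry.stereocenters}
    for sc in entry.stereocenters:
        if any(n not in present for n in sc.substituent_order):
            continue
        branch_union: set[str] = set()
        for br in entry.stereo_branches(sc):
            branch_union |= br
        if branch_union & (all_centers - {sc.center}):
            continue
        if branch_union & bridging or sc.center in bridging:
            continue
        centers.append(sc.center)
    return centers


def _bond_topology(model: StructureModel) -> set[tuple]:
    out = set()
    for b in model.bonds:
        ka = (b.atom_a.residue_key, b.atom_a.name)
        kb = (b.atom_b.residue_key, b.atom_b.name)
        out.add((ka, kb) if ka <= kb else (kb, ka))
    return out


def _topology_preserved(clean: StructureModel, corrupted: StructureModel) -> bool:
    """True iff the corruption changed no covalent connectivity beyond atom
    removal: no new contacts short enough to look bonded, no severed
    linkages.  Used to reject candidate corruptions whose rigid-body edits
    would collide branches (an op must plant exactly its own signature)."""
    present = {(a.residue_key, a.name) for a in corrupted.atoms()}
    before = {
        pair for pair in _bond_topology(clean) if pair[0] in present and pair[1] in present
    }
    after = _bond_topology(corrupted)
    return before == after


def _candidate_ops(
    kind: str,
    model: StructureModel,
    spec: GlycanSpec,
    dictionary: ReferenceDictionary,
    rng: np.random.Generator,
) -> list[CorruptionOp]:
    sugars = _sugar_residues(model, dictionary)
    donors = {l.donor for l in spec.linkages}
    root = next(i for i in range(len(spec.units)) if i not in donors)
    candidates: list[CorruptionOp] = []
    for idx in list(rng.permutation(len(sugars))):
        res = sugars[int(idx)]
        idx = int(idx)
        entry = dictionary.get_entry(res.ccd_code)
        present = {a.name for a in res.atoms}
        bridging = _bridging_atoms(model, res)
        if kind == "chirality":
            centers = _eligible_flip_centers(entry, res, bridging)
            for c in rng.permutation(centers):
                candidates.append(CorruptionOp(idx, "flip_stereocenter", {"center": str(c)}))
        elif kind == "double_bond":
            ring = entry.ring_atoms
            cc = [
                (ring[i], ring[(i + 1) % 6])
                for i in range(6)
                if ring[i].startswith("C") and ring[(i + 1) % 6].startswith("C")
                and ring[i] in present and ring[(i + 1) % 6] in present
            ]
            for pair in [cc[int(j)] for j in rng.permutation(len(cc))]:
                candidates.append(
                    CorruptionOp(
                        idx,
                        "shorten_bond",
                        {"pair": list(pair), "length": DEFAULT_MAGNITUDES["shorten_bond"]},
                    )
                )
        elif kind == "planar_ring":
            if all(a in present for a in entry.ring_atoms):
                candidates.append(CorruptionOp(idx, "flatten_ring", {}))
        elif kind == "aromatic_ring":
            if all(a in present for a in entry.ring_atoms):
                candidates.append(
                    CorruptionOp(idx, "aromatize_ring", {"target": DEFAULT_MAGNITUDES["aromatize_ring"]})
                )
        elif kind == "improper":
            subs = [
                (anchor, s["atom"])
                for anchor, lst in sorted(entry.raw.get("ring_substituents", {}).items())
                for s in lst
                if anchor in present and s["atom"] in present and s["atom"] not in bridging
            ]
            for anchor, atom in [subs[int(j)] for j in rng.permutation(len(subs))]:
                candidates.append(CorruptionOp(idx, "stretch_bond", {"pair": [anchor, atom]}))
        elif kind == "missing_atom":
            if idx == root and entry.anomeric_oxygen in present:
                candidates.append(CorruptionOp(idx, "delete_atom", {"name": entry.anomeric_oxygen}))
        else:
            raise BuildError(f"unknown corruption kind {kind!r}")
    return candidates


def _pick_corruption(
    kind: str,
    model: StructureModel,
    spec: GlycanSpec,
    dictionary: ReferenceDictionary,
    rng: np.random.Generator,
) -> CorruptionOp:
    """First candidate op (in seeded random order) whose rigid-body edit
    leaves the covalent topology intact (no branch collisions)."""
    for op in _candidate_ops(kind, model, spec, dictionary, rng):
        corrupted, _ = corrupt(model, CorruptionSpec((op,)), dictionary)
        if _topology_preserved(model, corrupted):
            return op
    raise BuildError(f"no eligible target for corruption kind {kind!r} in {spec.name or spec.units}")


def generate_benchmark_suite(
    out_dir,
    n_models: int,
    mix: dict[str, float] | None = None,
    master_seed: int = 0,
    dictionary: ReferenceDictionary | None = None,
    file_format: str = "pdb",
) -> dict:
    """Write a labelled benchmark suite of synthetic glycan models.

    Each model draws a composition from :data:`GLYCAN_LIBRARY` and a
    corruption class from ``mix`` (default :data:`DEFAULT_MIX`), both from
    a per-model generator split deterministically off ``master_seed``;
    regenerating with the same seed is byte-identical.  Returns the
    manifest (also written to ``manifest.json``): per file, the glycan,
    the corruption class and the ground-truth labels.
    """
    dictionary = dictionary or default_dictionary()
    mix = dict(mix or DEFAULT_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-6:
        raise BuildError(f"mix proportions sum to {total}, expected 1.0")
    kinds = sorted(mix)
    probs = np.array([mix[k] for k in kinds])
    os.makedirs(str(out_dir), exist_ok=True)
    lib_names = sorted(GLYCAN_LIBRARY)
    manifest: dict = {
        "master_seed": int(master_seed),
        "n_models": int(n_models),
        "mix": {k: float(v) for k, v in sorted(mix.items())},
        "models": {},
    }
    for i in range(n_models):
        rng = _model_rng(master_seed, i)
        glycan_name = lib_names[int(rng.integers(len(lib_names)))]
        gspec = GLYCAN_LIBRARY[glycan_name]
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        model = build_glycan(gspec, dictionary)
        if kind == "clean":
            labels: list[GroundTruthLabel] = []
        else:
            op = _pick_corruption(kind, model, gspec, dictionary, rng)
            model, labels = corrupt(model, CorruptionSpec((op,)), dictionary)
        fname = f"model_{i:04d}.{file_format}"
        write_structure(model, os.path.join(str(out_dir), fname), file_format)
        manifest["models"][fname] = {
            "glycan": glycan_name,
            "class": kind,
            "labels": [lab.to_dict() for lab in labels],
        }
    with open(os.path.join(str(out_dir), "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
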