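"""Structure input/output and geometric bond inference.

Reads and writes protein-glycan 3D models in mmCIF and PDB dialects
(via gemmi) into a uniform in-memory model, and infers covalent bonds
from interatomic distances and covalent radii.  Cofolding outputs carry
no CONECT/chem-comp bond records, so distance-based inference is the
only connectivity source the detectors can rely on -- which is also what
makes artificially shortened bonds visible.

Only the first model of a multi-model file is read.  Alternate locations
are collapsed to the highest-occupancy conformer (first wins on a tie).
Unknown mmCIF categories (predicted aligned error tables etc.) are
skipped silently by the parser.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from enum import Enum

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .exceptions import FormatError, ParseError

__all__ = [
    "AtomRecord",
    "BondOrder",
    "BondRecord",
    "ResidueRecord",
    "StructureFormat",
    "StructureModel",
    "infer_bonds",
    "parse_structure",
    "write_structure",
]

#: Covalent radii in Angstrom (heavy atoms relevant to glycans; fallback for
#: anything else).  Values fixed in-code by design.
COVALENT_RADII = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05}
FALLBACK_RADIUS = 1.10

#: Below this distance two atoms are treated as a clash artefact, not a bond.
CLASH_DISTANCE = 0.5

#: Pair-type thresholds (Angstrom) below which a single bond looks like a
#: double bond.  Keys are sorted element pairs.
DOUBLE_BOND_THRESHOLDS = {("C", "C"): 1.42, ("C", "O"): 1.32, ("C", "N"): 1.37}


class StructureFormat(str, Enum):
    MMCIF = "mmcif"
    PDB = "pdb"


class BondOrder(str, Enum):
    SINGLE = "SINGLE"
    SUSPECT_DOUBLE = "SUSPECT_DOUBLE"


@dataclass(frozen=True)
class AtomRecord:
    """One atom: CCD-convention name, element, position (A), residue key."""

    name: str
    element: str
    pos: np.ndarray
    residue_key: tuple[str, int, str]  # (chain id, residue number, insertion code)
    het_flag: bool

    def __repr__(self) -> str:  # keep arrays out of reprs
        x, y, z = self.pos
        return f"AtomRecord({self.name} {self.element} ({x:.3f},{y:.3f},{z:.3f}) {self.residue_key})"


@dataclass
class ResidueRecord:
    ccd_code: str
    residue_key: tuple[str, int, str]
    atoms: list[AtomRecord]

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]


@dataclass(frozen=True)
class BondRecord:
    """An inferred covalent bond; symmetric in its two atoms."""

    atom_a: AtomRecord
    atom_b: AtomRecord
    length: float
    inferred_order: BondOrder

    def involves(self, atom: AtomRecord) -> bool:
        return atom is self.atom_a or atom is self.atom_b

    def other(self, atom: AtomRecord) -> AtomRecord:
        return self.atom_b if atom is self.atom_a else self.atom_a


@dataclass
class StructureModel:
    residues: list[ResidueRecord]
    bonds: list[BondRecord] = field(default_factory=list)
    source_path: str | None = None
    format: StructureFormat | None = None
    warnings: list[str] = field(default_factory=list)

    def atoms(self) -> list[AtomRecord]:
        return [a for r in self.residues for a in r.atoms]

    def residue(self, key: tuple[str, int, str]) -> ResidueRecord | None:
        for r in self.residues:
            if r.residue_key == key:
                return r
        return None


def _detect_format(path: str) -> StructureFormat:
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".pdb", ".ent"):
        return StructureFormat.PDB
    if ext in (".cif", ".mmcif"):
        return StructureFormat.MMCIF
    # content sniff: mmCIF files start with "data_" blocks
    try:
        with open(path, "rb") as fh:
            head = fh.read(4096).decode("utf-8", "replace")
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    for line in head.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if s.startswith("data_"):
            return StructureFormat.MMCIF
        if s[:6].rstrip() in ("ATOM", "HETATM", "HEADER", "REMARK", "CRYST1", "MODEL", "TITLE", "HET"):
            return StructureFormat.PDB
        break
    raise FormatError(f"cannot determine structure format of {path}")


def parse_structure(path, format: StructureFormat | str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    ``format`` is auto-detected from the extension (and, failing that, the
    content) when not given.  All ATOM/HETATM records of the first model
    are kept; residues are grouped by (chain, residue number, insertion
    code); alternate locations collapse to the highest-occupancy copy.
    """
    if not os.path.exists(str(path)):
        raise ParseError(f"no such file: {path}")
    fmt = StructureFormat(format) if format is not None else _detect_format(str(path))
    gemmi_fmt = gemmi.CoorFormat.Pdb if fmt is StructureFormat.PDB else gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=gemmi_fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"failed to parse {path} as {fmt.value}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no coordinate model found")

    model = StructureModel(residues=[], source_path=str(path), format=fmt)
    if len(st) > 1:
        model.warnings.append(f"multi-model file: using first of {len(st)} models")
    for chain in st[0]:
        for res in chain:
            key = (chain.name, res.seqid.num, res.seqid.icode.strip() or "")
            het = res.het_flag != "A"
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            atoms = []
            for at in res:
                if by_name.get(at.name) is not at:
                    continue
                elem = at.element.name.upper() if at.element else ""
                if not elem:
                    raise ParseError(f"{path}: atom {at.name} in {res.name} {key} lacks an element")
                atoms.append(
                    AtomRecord(
                        name=at.name,
                        element=elem,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z], dtype=float),
                        residue_key=key,
                        het_flag=het,
                    )
                )
            if atoms:
                model.residues.append(ResidueRecord(res.name.upper(), key, atoms))
    if not model.residues:
        raise ParseError(f"{path}: no atoms found")
    return model


def write_structure(model: StructureModel, path, format: StructureFormat | str | None = None) -> None:
    """Write ``model`` to ``path`` as PDB or mmCIF.

    Round-trips losslessly through :func:`parse_structure` for atom names,
    residue keys and coordinates (to the 1e-3 A precision of the formats).
    """
    fmt = StructureFormat(format) if format is not None else _detect_format_for_write(str(path))
    for atom in model.atoms():
        if not atom.element:
            raise FormatError(f"atom {atom.name} in {atom.residue_key} has no element; cannot write")
    n_atoms = sum(len(r.atoms) for r in model.residues)
    if fmt is StructureFormat.PDB and n_atoms > 99999:
        raise FormatError(
            f"{n_atoms} atoms exceed the 99999-atom PDB serial limit; write mmCIF instead"
        )

    st = gemmi.Structure()
    st.name = os.path.splitext(os.path.basename(str(path)))[0]
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in model.residues:
        chain_id, seqnum, icode = res.residue_key
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        gres = gemmi.Residue()
        gres.name = res.ccd_code
        gres.seqid = gemmi.SeqId(seqnum, icode or " ")
        gres.het_flag = "H" if (res.atoms and res.atoms[0].het_flag) else "A"
        for atom in res.atoms:
            gat = gemmi.Atom()
            gat.name = atom.name
            gat.element = gemmi.Element(atom.element.capitalize())
            gat.pos = gemmi.Position(*atom.pos)
            gat.occ = 1.0
            gres.add_atom(gat)
        chains[chain_id].add_residue(gres)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    if fmt is StructureFormat.PDB:
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def _detect_format_for_write(path: str) -> StructureFormat:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        return StructureFormat.PDB
    if ext in (".cif", ".mmcif"):
        return StructureFormat.MMCIF
    raise FormatError(f"cannot infer output format from {path!r}; pass format= explicitly")


def infer_bonds(
    model: StructureModel,
    tolerance: float = 0.25,
    include_hydrogens: bool = False,
) -> list[BondRecord]:
    """Distance-based covalent bond inference.

    Atoms i, j are bonded iff ``d(i, j) <= (r_cov(i) + r_cov(j)) * (1 +
    tolerance)``.  Hydrogens are ignored unless ``include_hydrogens`` is
    set (cofolding outputs are heavy-atom only).  Pairs closer than 0.5 A
    are treated as modelling clashes: the bond is suppressed and a warning
    attached to the model.  The result is also stored on ``model.bonds``.

    A bond whose length falls below its pair-type double-bond threshold is
    marked ``SUSPECT_DOUBLE``; interpretation (including dictionary-
    sanctioned carbonyls) is left to the detectors.
    """
    atoms = [
        a
        for a in model.atoms()
        if include_hydrogens or a.element not in ("H", "D")
    ]
    bonds: list[BondRecord] = []
    if len(atoms) >= 2:
        coords = np.array([a.pos for a in atoms])
        if not np.all(np.isfinite(coords)):
            raise ParseError("non-finite coordinates; cannot infer bonds")
        radii = np.array([COVALENT_RADII.get(a.element, FALLBACK_RADIUS) for a in atoms])
        max_cut = 2.0 * radii.max() * (1.0 + tolerance)
        tree = cKDTree(coords)
        for i, j in sorted(tree.query_pairs(max_cut)):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            cutoff = (radii[i] + radii[j]) * (1.0 + tolerance)
            if d > cutoff:
                continue
            if d < CLASH_DISTANCE:
                model.warnings.append(
                    f"clash: {atoms[i].name}{atoms[i].residue_key} -- "
                    f"{atoms[j].name}{atoms[j].residue_key} at {d:.2f} A; bond suppressed"
                )
                continue
            pair = tuple(sorted((atoms[i].element, atoms[j].element)))
            threshold = DOUBLE_BOND_THRESHOLDS.get(pair)
            order = (
                BondOrder.SUSPECT_DOUBLE
                if threshold is not None and d < threshold
                else BondOrder.SINGLE
            )
            bonds.append(BondRecord(atoms[i], atoms[j], d, order))
    model.bonds = bonds
    return bonds
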