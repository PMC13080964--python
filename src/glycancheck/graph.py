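"""Glycan graph extraction: sugar units, glycosidic edges, reducing end.

Sugar residues are identified purely by CCD code against the reference
dictionary (no chemical perception), their ring and anomeric atoms
resolved by dictionary atom names, and the oligosaccharide tree assembled
from inferred bonds: each glycosidic linkage is an anomeric-carbon ->
bridging-oxygen -> acceptor-carbon path.  In a well-formed tree exactly
one unit per connected component keeps a free anomeric carbon -- the
reducing end, whose anomeric oxygen is the terminal atom systematically
deleted by the BondedAtomPairs input protocol.

The anomeric carbon is taken from the dictionary (C1; C2 for sialic
acids), never re-derived chemically, so the assignment is robust to the
very distortions being detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import LinkageError
from .flags import ErrorCategory, ErrorFlag
from .reference import ReferenceDictionary, ReferenceEntry, default_dictionary
from .structure import AtomRecord, BondRecord, ResidueRecord, StructureModel

__all__ = [
    "GlycanTree",
    "GlycosidicEdge",
    "SugarUnit",
    "build_glycan_tree",
    "check_reducing_end",
    "identify_sugar_units",
]

#: Residue codes skipped silently (solvent, standard amino acids, ions).
_NON_SUGAR_SILENT = {
    "HOH", "WAT", "DOD",
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
    "NA", "CL", "MG", "CA", "ZN", "K", "MN", "FE", "SO4", "PO4", "GOL", "EDO",
}

_GREEK = {"alpha": "α", "beta": "β"}


@dataclass
class SugarUnit:
    """One monosaccharide residue resolved against the dictionary."""

    residue: ResidueRecord
    entry: ReferenceEntry
    ring_atoms: tuple[str, ...]
    ring_complete: bool
    present_atoms: frozenset[str]
    missing_atoms: frozenset[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def ccd_code(self) -> str:
        return self.entry.ccd_code

    @property
    def unit_id(self) -> str:
        chain, num, icode = self.residue.residue_key
        return f"{chain}:{num}{icode}:{self.ccd_code}"

    @property
    def anomeric_carbon(self) -> str:
        return self.entry.anomeric_carbon

    @property
    def anomeric_oxygen(self) -> str:
        return self.entry.anomeric_oxygen

    @property
    def coords(self) -> dict[str, np.ndarray]:
        return {a.name: a.pos for a in self.residue.atoms}

    def ring_coords(self) -> np.ndarray | None:
        """Ordered ring coordinates, or None if the ring is unresolved."""
        pos = self.coords
        if all(a in pos for a in self.ring_atoms):
            return np.array([pos[a] for a in self.ring_atoms])
        return None

    def stereocenters(self):
        return self.entry.stereocenters


def identify_sugar_units(
    model: StructureModel, dictionary: ReferenceDictionary | None = None
) -> list[SugarUnit]:
    """One :class:`SugarUnit` per residue whose CCD code is in the dictionary.

    Atoms are matched by name; ``missing_atoms`` records dictionary heavy
    atoms absent from the model.  A unit with fewer than four named ring
    atoms is flagged ring-incomplete but kept.  Unknown HETATM codes are
    recorded as warnings on the model (solvent and standard residues are
    skipped silently).
    """
    dictionary = dictionary or default_dictionary()
    units: list[SugarUnit] = []
    for res in model.residues:
        if res.ccd_code not in dictionary:
            if res.ccd_code not in _NON_SUGAR_SILENT and any(a.het_flag for a in res.atoms):
                model.warnings.append(f"unknown residue code {res.ccd_code} at {res.residue_key}: skipped")
            continue
        entry = dictionary.get_entry(res.ccd_code)
        present = frozenset(a.name for a in res.atoms if a.element not in ("H", "D"))
        missing = frozenset(n for n in entry.atom_names if n not in present)
        ring = entry.ring_atoms
        n_ring_present = sum(1 for a in ring if a in present)
        unit = SugarUnit(
            residue=res,
            entry=entry,
            ring_atoms=ring,
            ring_complete=n_ring_present == len(ring),
            present_atoms=present,
            missing_atoms=missing,
        )
        if n_ring_present < 4:
            unit.warnings.append(
                f"{unit.unit_id}: only {n_ring_present}/6 ring atoms present; ring-incomplete"
            )
        elif not unit.ring_complete:
            unit.warnings.append(f"{unit.unit_id}: ring atoms missing: "
                                 f"{sorted(set(ring) - present)}")
        units.append(unit)
    return units


@dataclass(frozen=True)
class GlycosidicEdge:
    """Donor anomeric carbon -> bridging oxygen -> acceptor linkage."""

    donor: SugarUnit
    acceptor: SugarUnit
    acceptor_atom: str  # name of the bridging oxygen (on the acceptor side)
    linkage_label: str


@dataclass
class GlycanTree:
    units: list[SugarUnit]
    edges: list[GlycosidicEdge]
    reducing_ends: list[SugarUnit]
    warnings: list[str] = field(default_factory=list)

    @property
    def reducing_end(self) -> SugarUnit | None:
        return self.reducing_ends[0] if self.reducing_ends else None


def _linkage_label(donor: SugarUnit, acceptor: SugarUnit, bridge_name: str) -> str:
    anomer = _GREEK.get(donor.entry.anomer, donor.entry.anomer)
    donor_pos = donor.anomeric_carbon.lstrip("C")
    acc_pos = bridge_name.lstrip("O") or "?"
    return f"{donor.ccd_code}{anomer}{donor_pos}→{acc_pos}{acceptor.ccd_code}"


def build_glycan_tree(units: list[SugarUnit], bonds: list[BondRecord]) -> GlycanTree:
    """Assemble glycosidic edges and assign reducing ends.

    An edge is recorded when a unit's anomeric carbon reaches another
    unit's carbon through exactly one bridging oxygen.  An anomeric carbon
    bridging to two different units is ambiguous and rejected.  Cycles are
    rejected (edges must form a forest).  A unit whose anomeric carbon is
    covalently attached to a non-sugar residue (protein-linked glycan) has
    no free reducing end and is excluded from reducing-end assignment.
    """
    atom_to_unit: dict[int, SugarUnit] = {}
    for u in units:
        for a in u.residue.atoms:
            atom_to_unit[id(a)] = u
    adj: dict[int, list[BondRecord]] = {}
    for b in bonds:
        adj.setdefault(id(b.atom_a), []).append(b)
        adj.setdefault(id(b.atom_b), []).append(b)

    edges: list[GlycosidicEdge] = []
    warnings: list[str] = []
    protein_linked: set[str] = set()
    donors: set[str] = set()
    for u in units:
        ac = u.residue.atom(u.anomeric_carbon)
        if ac is None:
            continue
        ring_oxygen = u.ring_atoms[0]
        candidates: list[tuple[AtomRecord, SugarUnit, AtomRecord]] = []
        for b in adj.get(id(ac), []):
            o = b.other(ac)
            if o.element != "O":
                # direct hetero attachment (e.g. ASN ND2) to something outside
                if o.element == "N" and atom_to_unit.get(id(o)) is None:
                    protein_linked.add(u.unit_id)
                continue
            o_unit = atom_to_unit.get(id(o))
            if o_unit is u and o.name in (ring_oxygen, u.anomeric_oxygen):
                if o.name == u.anomeric_oxygen:
                    # donor-side anomeric oxygen may itself bridge onward
                    for b2 in adj.get(id(o), []):
                        c2 = b2.other(o)
                        if c2 is ac or c2.element != "C":
                            continue
                        tgt = atom_to_unit.get(id(c2))
                        if tgt is not None and tgt is not u:
                            candidates.append((o, tgt, c2))
                        elif tgt is None:
                            protein_linked.add(u.unit_id)
                continue
            if o_unit is None:
                protein_linked.add(u.unit_id)
                continue
            if o_unit is not u:
                candidates.append((o, o_unit, o))
        targets = {c[1].unit_id for c in candidates}
        if len(targets) > 1:
            raise LinkageError(
                f"anomeric carbon of {u.unit_id} bridges to multiple units: {sorted(targets)}"
            )
        if candidates:
            bridge, acceptor, _ = candidates[0]
            edges.append(
                GlycosidicEdge(
                    donor=u,
                    acceptor=acceptor,
                    acceptor_atom=bridge.name,
                    linkage_label=_linkage_label(u, acceptor, bridge.name),
                )
            )
            donors.add(u.unit_id)

    g = nx.Graph()
    g.add_nodes_from(u.unit_id for u in units)
    g.add_edges_from((e.donor.unit_id, e.acceptor.unit_id) for e in edges)
    # count logical edges (a simple Graph would collapse a 2-unit cycle)
    if len(edges) > len(g.nodes) - nx.number_connected_components(g):
        raise LinkageError("glycosidic edges contain a cycle; expected a forest")

    by_id = {u.unit_id: u for u in units}
    reducing_ends: list[SugarUnit] = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        free = sorted(
            uid for uid in comp if uid not in donors and uid not in protein_linked
        )
        if len(free) == 1:
            reducing_ends.append(by_id[free[0]])
        elif len(free) == 0:
            warnings.append(
                f"component {sorted(comp)}: no free reducing end (cyclic or protein-linked)"
            )
        else:
            # disconnected free units in one component cannot happen in a tree;
            # multiple free units means missing linkage evidence
            for uid in free:
                reducing_ends.append(by_id[uid])
            if len(comp) > 1:
                warnings.append(
                    f"component {sorted(comp)}: {len(free)} units with free anomeric carbon"
                )
    return GlycanTree(units=list(units), edges=edges, reducing_ends=reducing_ends, warnings=warnings)


def check_reducing_end(tree: GlycanTree) -> list[ErrorFlag]:
    """Flag reducing-end units whose anomeric oxygen is absent.

    Returns one MISSING_ATOM flag per reducing end lacking its dictionary
    anomeric oxygen (O1 for aldopyranoses, O2 for sialic acids) -- the
    systematic terminal-atom deletion artefact of BondedAtomPairs inputs.
    An input with no reducing end (cyclic or fully protein-linked) is not
    checked; the tree carries a warning instead.
    """
    flags: list[ErrorFlag] = []
    for unit in tree.reducing_ends:
        o = unit.anomeric_oxygen
        if o in unit.missing_atoms:
            flags.append(
                ErrorFlag(
                    category=ErrorCategory.MISSING_ATOM,
                    unit_id=unit.unit_id,
                    ccd_code=unit.ccd_code,
                    atoms=(o,),
                    magnitude=0.0,
                    detail=f"reducing-end anomeric oxygen {o} absent",
                )
            )
    return flags
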