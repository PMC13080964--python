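"""Internal-coordinate construction of ideal monosaccharide geometry.

The reference dictionary does not ship Cartesian coordinates; it ships a
chair recipe (ring bond lengths, puckering parity, axial/equatorial flags
for the first substituent shell) plus a z-matrix for everything further
out.  This module turns that recipe into coordinates:

* The six ring atoms are placed on a closed cyclic polygon whose projected
  side lengths reproduce the ideal ring bond lengths exactly, with
  alternating out-of-plane displacements ``z = +/- z0`` (z0 = 0.25 A by
  default, giving a chair with Q = sqrt(6) * z0 ~ 0.61 A and ring torsions
  alternating around +/-55 deg).
* Each ring carbon's heavy substituent is placed on one of the two
  remaining tetrahedral directions (axial or equatorial, per the
  dictionary flags).
* Remaining atoms (O6 arms, N-acetyl groups, the sialic-acid glycerol tail
  and carboxylate, the AC1 cyclohexene ring) follow z-matrix rows whose
  internal coordinates are tabulated in the dictionary data file.

The construction is fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .exceptions import BuildError, GeometryError
from .geometry import place_zmatrix_atom

__all__ = ["build_chair_ring", "build_unit_coords", "tetrahedral_directions"]

#: Out-of-plane half-amplitude of the ideal chair (Angstrom).
CHAIR_Z0 = 0.25

#: Ideal tetrahedral angle (degrees).
TETRAHEDRAL = 109.47122


def build_chair_ring(bond_lengths, parity: int, z0: float = CHAIR_Z0) -> np.ndarray:
    """Six chair-ring positions with exact consecutive bond lengths.

    ``bond_lengths[i]`` is the ideal length of the bond ring[i]-ring[i+1]
    (cyclic).  ``parity`` (+1 or -1) selects which alternation phase the
    out-of-plane displacements take, i.e. which of the two chair forms is
    built.  The in-plane projection is a cyclic polygon inscribed in a
    circle whose radius is solved so the hexagon closes exactly.
    """
    lengths = np.asarray(bond_lengths, dtype=float)
    if lengths.shape != (6,):
        raise BuildError(f"need 6 ring bond lengths, got {lengths.shape}")
    if parity not in (+1, -1):
        raise BuildError(f"chair parity must be +1 or -1, got {parity}")
    proj = lengths**2 - (2.0 * z0) ** 2
    if np.any(proj <= 0):
        raise BuildError("chair amplitude too large for the given bond lengths")
    d = np.sqrt(proj)

    def closure(radius: float) -> float:
        return float(np.sum(2.0 * np.arcsin(d / (2.0 * radius))) - 2.0 * np.pi)

    lo = float(d.max()) / 2.0 + 1e-9
    hi = float(d.sum())  # generous upper bound; closure(hi) < 0
    radius = brentq(closure, lo, hi, xtol=1e-12)
    central = 2.0 * np.arcsin(d / (2.0 * radius))
    # vertex i sits at the cumulative angle of the preceding sides
    angles = np.concatenate([[0.0], np.cumsum(central[:-1])])
    ring = np.column_stack(
        [
            radius * np.cos(angles),
            radius * np.sin(angles),
            -parity * z0 * (-1.0) ** np.arange(6),
        ]
    )
    return ring


def tetrahedral_directions(center, neighbor_a, neighbor_b) -> tuple[np.ndarray, np.ndarray]:
    """The two unit directions completing a tetrahedron at ``center``.

    Given the two ring-neighbour bond directions, returns ``(d_plus,
    d_minus)``, each making the ideal tetrahedral angle with both
    neighbours.  ``d_plus`` has positive component along the local
    ``u x v`` axis.
    """
    c = np.asarray(center, dtype=float)
    u = np.asarray(neighbor_a, dtype=float) - c
    v = np.asarray(neighbor_b, dtype=float) - c
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    bisector = -(u + v)
    nb = np.linalg.norm(bisector)
    if nb < 1e-9:
        raise GeometryError("linear ring-neighbour geometry at substituent center")
    p = bisector / nb
    axis = np.cross(u, v)
    na = np.linalg.norm(axis)
    if na < 1e-9:
        raise GeometryError("collinear ring neighbours at substituent center")
    b = axis / na
    target = np.cos(np.radians(TETRAHEDRAL))
    alpha = target / np.dot(p, u)
    alpha = np.clip(alpha, -1.0, 1.0)
    beta = np.sqrt(max(0.0, 1.0 - alpha * alpha))
    return alpha * p + beta * b, alpha * p - beta * b


def _ring_normal(ring: np.ndarray) -> np.ndarray:
    """Mean-plane normal oriented by the ring traversal (right-hand rule)."""
    centred = ring - ring.mean(axis=0)
    j = np.arange(6)
    rp = (centred * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (centred * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    return n / np.linalg.norm(n)


def build_unit_coords(entry_data: dict, conformer: str | None = None) -> dict[str, np.ndarray]:
    """Build ideal heavy-atom coordinates for one dictionary entry.

    ``entry_data`` is the raw mapping from the dictionary data file.
    ``conformer`` may name the entry's native chair or its ring-flipped
    form; flipping swaps every axial/equatorial flag so the same
    stereoisomer is produced in the other chair.
    """
    ring_names: list[str] = list(entry_data["ring"])
    native = entry_data["chair"]
    flipped = entry_data.get("chair_flipped", native)
    if conformer is None:
        conformer = native
    if conformer == native:
        parity, swap = int(entry_data["chair_parity"]), False
    elif conformer == flipped and flipped != native:
        parity, swap = -int(entry_data["chair_parity"]), True
    else:
        raise BuildError(
            f"unsupported conformer {conformer!r} for {entry_data.get('ccd_code', '?')}; "
            f"supported: {native!r}, {flipped!r}"
        )

    ring_bonds = [float(x) for x in entry_data["ring_bond_lengths"]]
    ring = build_chair_ring(ring_bonds, parity)
    coords: dict[str, np.ndarray] = {name: ring[i] for i, name in enumerate(ring_names)}
    normal = _ring_normal(ring)

    for anchor, subs in entry_data.get("ring_substituents", {}).items():
        i = ring_names.index(anchor)
        prev_atom = ring[(i - 1) % 6]
        next_atom = ring[(i + 1) % 6]
        d_plus, d_minus = tetrahedral_directions(ring[i], prev_atom, next_atom)
        if abs(np.dot(d_plus, normal)) >= abs(np.dot(d_minus, normal)):
            axial, equatorial = d_plus, d_minus
        else:
            axial, equatorial = d_minus, d_plus
        for sub in subs:
            orient = sub["orient"]
            if swap:
                orient = {"ax": "eq", "eq": "ax"}[orient]
            direction = axial if orient == "ax" else equatorial
            coords[sub["atom"]] = ring[i] + float(sub["length"]) * direction

    for row in entry_data.get("zmatrix", []):
        name, p_bond, p_angle, p_torsion, r, theta, tau = row
        for ref in (p_bond, p_angle, p_torsion):
            if ref not in coords:
                raise BuildError(f"z-matrix reference {ref!r} not yet placed for {name!r}")
        coords[name] = place_zmatrix_atom(
            coords[p_bond], coords[p_angle], coords[p_torsion], float(r), float(theta), float(tau)
        )
    return coords
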