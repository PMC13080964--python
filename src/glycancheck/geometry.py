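"""Pure geometry primitives.

Everything the error detectors rely on lives here: distances, angles,
dihedrals, the signed chiral (tetrahedral) volume, least-squares plane
fitting, Cremer-Pople ring-puckering coordinates, and proper-rotation
(Kabsch) superposition.  All functions are stateless and operate on plain
numpy arrays of shape (3,) or (n, 3), in Angstrom.

Conventions
-----------
* Cremer-Pople coordinates are computed for six-membered rings given in
  covalent order.  The package-wide convention puts the ring oxygen first
  (O5, C1, ..., C5 for aldopyranoses; O6, C2, ..., C6 for sialic acids), so
  theta ~ 0 deg corresponds to the 4C1 chair of a D-aldopyranose and
  theta ~ 180 deg to 1C4 (for sialic acids the theta ~ 180 deg chair is the
  one written 2C5 in carbohydrate nomenclature; the label bins here are
  relative to the fixed ring order, not to IUPAC locants).
* Chirality never survives an improper transform: ``superpose_rmsd``
  minimises over proper rotations only, so enantiomers keep a strictly
  positive residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError

__all__ = [
    "PuckerState",
    "angle",
    "best_fit_plane",
    "chiral_volume",
    "cremer_pople",
    "dihedral",
    "place_zmatrix_atom",
    "reflect_through_plane",
    "superpose_rmsd",
]

#: Amplitude below which a ring counts as numerically coplanar (Angstrom).
PLANAR_Q_TOL = 1e-6


@dataclass(frozen=True)
class PuckerState:
    """Cremer-Pople puckering state of a six-membered ring.

    Attributes
    ----------
    Q : float
        Total puckering amplitude in Angstrom; 0 for a coplanar ring.
    theta : float
        Polar angle in degrees, [0, 180]; ~0 or ~180 for chairs, ~90 for
        boats and twist-boats.
    phi : float
        Azimuthal (pseudorotation) angle in degrees, [0, 360).
    conformer_label : str
        Coarse conformer bin under the package ring-order convention.
    """

    Q: float
    theta: float
    phi: float
    conformer_label: str


def _as_points(points, min_n: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if pts.shape[0] < min_n:
        raise GeometryError(f"need at least {min_n} points, got {pts.shape[0]}")
    if not np.all(np.isfinite(pts)):
        raise GeometryError("non-finite coordinates")
    return pts


def chiral_volume(p1, p2, p3, p4) -> float:
    """Signed tetrahedral volume of four points, in cubic Angstrom.

    Returns ``((p1 - p4) . ((p2 - p4) x (p3 - p4))) / 6``.  The sign encodes
    handedness of the substituent arrangement: it is antisymmetric under
    swapping any two points and negated by mirror reflection.  Coplanar
    input returns 0.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    return float(np.dot(p1 - p4, np.cross(p2 - p4, p3 - p4))) / 6.0


def angle(a, b, c) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise GeometryError("zero-length bond vector in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral(a, b, c, d) -> float:
    """Torsion angle a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    return float(np.degrees(np.arctan2(y, x)))


def best_fit_plane(points) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through ``points``.

    Returns ``(centroid, unit_normal, rms)`` where ``rms`` is the
    root-mean-square point-plane distance.  Raises :class:`GeometryError`
    for fewer than three points or collinear input.
    """
    pts = _as_points(points, 3)
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    # collinear: only one significant singular value
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("collinear points: plane is not defined")
    normal = vt[2]
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return centroid, normal, rms


def _pucker_label(Q: float, theta: float) -> str:
    if Q < PLANAR_Q_TOL:
        return "planar"
    if theta < 30.0:
        return "4C1"
    if theta > 150.0:
        return "1C4"
    if theta < 60.0 or theta > 120.0:
        return "half-chair"
    return "boat/twist-boat"


def cremer_pople(ring_coords) -> PuckerState:
    """Cremer-Pople puckering coordinates of a six-membered ring.

    ``ring_coords`` must hold exactly six positions in covalent order
    starting at the dictionary origin atom (ring oxygen).  Q is invariant
    under rigid motion; theta/phi depend on the ring ordering convention.
    """
    pts = _as_points(ring_coords, 6)
    if pts.shape[0] != 6:
        raise GeometryError(f"cremer_pople needs exactly 6 ring atoms, got {pts.shape[0]}")
    for i in range(6):
        for j in range(i + 1, 6):
            if np.linalg.norm(pts[i] - pts[j]) < 1e-6:
                raise GeometryError("duplicate ring atom positions")
    centred = pts - pts.mean(axis=0)
    j = np.arange(6)
    rp = (centred * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    rpp = (centred * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("degenerate ring geometry (no mean plane)")
    n /= norm
    z = centred @ n
    q2c = np.sqrt(2.0 / 6.0) * (z * np.cos(4 * np.pi * j / 6)).sum()
    q2s = -np.sqrt(2.0 / 6.0) * (z * np.sin(4 * np.pi * j / 6)).sum()
    q3 = np.sqrt(1.0 / 6.0) * (z * (-1.0) ** j).sum()
    q2 = float(np.hypot(q2c, q2s))
    Q = float(np.hypot(q2, q3))
    theta = float(np.degrees(np.arctan2(q2, q3)))
    phi = float(np.degrees(np.arctan2(q2s, q2c)) % 360.0)
    return PuckerState(Q=Q, theta=theta, phi=phi, conformer_label=_pucker_label(Q, theta))


def superpose_rmsd(coords_a, coords_b) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum RMSD of paired point sets over proper rotations + translations.

    Returns ``(rmsd, rotation, translation)`` such that
    ``coords_a @ rotation.T + translation`` best matches ``coords_b``.
    Reflections are excluded: mirror-image sets keep a positive residual,
    which is what lets chirality survive superposition.
    """
    a = _as_points(coords_a, 3)
    b = _as_points(coords_b, 3)
    if a.shape != b.shape:
        raise GeometryError(f"point-set length mismatch: {a.shape[0]} vs {b.shape[0]}")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = a0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b0) ** 2, axis=1))))
    trans = cb - ca @ rot.T
    return rmsd, rot, trans


def place_zmatrix_atom(p_bond, p_angle, p_torsion, r: float, theta: float, tau: float) -> np.ndarray:
    """Place an atom from internal coordinates (NeRF construction).

    The new atom sits at distance ``r`` (Angstrom) from ``p_bond``, with
    angle ``theta`` (degrees) at ``p_bond`` relative to ``p_angle``, and
    torsion ``tau`` (degrees) about the ``p_angle``-``p_bond`` axis relative
    to ``p_torsion``.
    """
    a = np.asarray(p_torsion, dtype=float)
    b = np.asarray(p_angle, dtype=float)
    c = np.asarray(p_bond, dtype=float)
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < 1e-9:
        raise GeometryError("coincident reference atoms in z-matrix placement")
    bc /= nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise GeometryError("collinear reference atoms in z-matrix placement")
    n /= nn
    m = np.cross(n, bc)
    th = np.radians(theta)
    ta = np.radians(tau)
    d = np.array(
        [
            -r * np.cos(th),
            r * np.sin(th) * np.cos(ta),
            -r * np.sin(th) * np.sin(ta),
        ]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d


def rotation_between(u, v) -> np.ndarray:
    """Proper rotation matrix taking direction ``u`` onto direction ``v``.

    Rodrigues construction about the ``u x v`` axis.  Antiparallel input
    is rejected (the rotation is then not unique).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        raise GeometryError("antiparallel directions: rotation is not unique")
    axis /= s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    theta = np.arctan2(s, c)
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def reflect_through_plane(points, plane_point, normal) -> np.ndarray:
    """Mirror ``points`` through the plane with unit ``normal`` at ``plane_point``."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    p0 = np.asarray(plane_point, dtype=float)
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = (pts - p0) @ n
    return pts - 2.0 * d[:, None] * n
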