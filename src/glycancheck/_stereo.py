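"""Shared stereocenter-flip construction.

A flip moves each exocyclic substituent branch of a stereocenter onto the
mirror image of its attachment direction (mirrored through the plane of
the center and its two in-ring neighbours) by a *proper rotation* about
the center.  This inverts the chiral-volume sign at the center while
preserving every bond length and the internal handedness of the moved
branch, and it is an involution: applying it twice restores the input.
"""

from __future__ import annotations

import numpy as np

from .geometry import rotation_between

__all__ = ["flip_rotation"]


def flip_rotation(center, plane_a, plane_b, substituent) -> np.ndarray:
    """Rotation matrix (about ``center``) flipping the substituent direction.

    ``plane_a``/``plane_b`` are the positions of the center's two in-ring
    neighbours; the substituent's bond direction is mirrored through the
    plane they span with the center, and the unique shortest proper
    rotation taking the old direction to the mirrored one is returned.
    """
    center = np.asarray(center, dtype=float)
    n = np.cross(np.asarray(plane_a, float) - center, np.asarray(plane_b, float) - center)
    n = n / np.linalg.norm(n)
    u = np.asarray(substituent, float) - center
    u_mirror = u - 2.0 * float(u @ n) * n
    return rotation_between(u, u_mirror)
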