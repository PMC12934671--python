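"""Torsion angles, Ramachandran regions, rotamer bins and small geometric helpers.

All angles are in degrees on the interval (-180, 180]; all distances in
Angstroms.  The Ramachandran regions used here are the three broad boxes
that appear in the activity criteria:

* ``A`` (alpha):        phi in (-180, 0),  psi in (-100, 50]
* ``B`` (beta):         phi in (-180, 0),  psi in (50, 180]  (psi = -180 wraps to 180)
* ``L`` (left-handed):  phi in (0, 180],   psi in (-50, 100]

The boxes are written with open bounds; for a deterministic partition we
close A at psi = 50 and L at phi = 180 / psi = 100, and treat psi = -180 as
180 so that B absorbs the wraparound.  Everything not in A/B/L is ``other``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryError",
    "DihedralSet",
    "dihedral",
    "rama_region",
    "chi1_minus",
    "rotamer_word",
    "min_pair_distance",
    "virtual_cbeta",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (coincident or colinear points)."""


@dataclass(frozen=True)
class DihedralSet:
    """Backbone phi/psi and side-chain chi1 for one residue; ``None`` when unmeasurable."""

    phi: float | None = None
    psi: float | None = None
    chi1: float | None = None


def _wrap_angle(deg: float) -> float:
    """Map an angle to (-180, 180]."""
    a = math.fmod(deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Positive when, looking down the p2->p3 bond, the far bond (p3->p4) is
    rotated clockwise from the near bond (p2->p1).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) < 1e-9 or np.linalg.norm(b2) < 1e-9 or np.linalg.norm(b3) < 1e-9:
        raise GeometryError("coincident consecutive points in torsion")
    if np.linalg.norm(np.cross(b1, b2)) < 1e-9 or np.linalg.norm(np.cross(b2, b3)) < 1e-9:
        raise GeometryError("colinear bond vectors in torsion")
    # project the outer bonds onto the plane normal to the central bond
    b2u = b2 / np.linalg.norm(b2)
    v = -b1 - np.dot(-b1, b2u) * b2u
    w = b3 - np.dot(b3, b2u) * b2u
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b2u, v), w))
    return _wrap_angle(math.degrees(math.atan2(y, x)))


def rama_region(phi: float | None, psi: float | None) -> str:
    """Region label {'A','B','L','other','none'} for a phi/psi pair."""
    if phi is None or psi is None:
        return "none"
    if not (math.isfinite(phi) and math.isfinite(psi)):
        return "none"
    phi = _wrap_angle(phi)
    psi = _wrap_angle(psi)
    if psi == -180.0:  # wraparound: treat as +180 for the B box
        psi = 180.0
    if -180.0 < phi < 0.0:
        if -100.0 < psi <= 50.0:
            return "A"
        if 50.0 < psi <= 180.0:
            return "B"
    elif 0.0 < phi <= 180.0:
        if -50.0 < psi <= 100.0:
            return "L"
    return "other"


def chi1_minus(chi1: float | None) -> bool | None:
    """True iff chi1 is in the gauche-minus bin (-120, 0); ``None`` when chi1 is absent."""
    if chi1 is None or not math.isfinite(chi1):
        return None
    c = _wrap_angle(chi1)
    return -120.0 < c < 0.0


def rotamer_word(chi1: float | None) -> str | None:
    """'minus' for chi1 in (-120,0), 'plus' for (0,120), else 'trans'; None if absent."""
    if chi1 is None or not math.isfinite(chi1):
        return None
    c = _wrap_angle(chi1)
    if -120.0 < c < 0.0:
        return "minus"
    if 0.0 < c < 120.0:
        return "plus"
    return "trans"


def min_pair_distance(atoms_a, atoms_b) -> float | None:
    """Minimum Euclidean distance across the Cartesian product of two position sets.

    Accepts iterables of 3-vectors; returns ``None`` when either set is
    empty (missing-atom propagation).
    """
    a = np.asarray(list(atoms_a), dtype=float)
    b = np.asarray(list(atoms_b), dtype=float)
    if a.size == 0 or b.size == 0:
        return None
    a = a.reshape(-1, 3)
    b = b.reshape(-1, 3)
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def virtual_cbeta(n, ca, c) -> np.ndarray:
    """Ideal C-beta position from the backbone N/CA/C triad (used when Gly has no CB).

    Standard tetrahedral construction with L-chirality (~1.53 A from CA);
    equivariant under rigid transforms because it is built from the
    inter-atom vectors and their cross product.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    b = ca - n
    cv = c - ca
    if np.linalg.norm(b) < 1e-9 or np.linalg.norm(cv) < 1e-9:
        raise GeometryError("degenerate backbone triad")
    a = np.cross(b, cv)
    if np.linalg.norm(a) < 1e-9:
        raise GeometryError("colinear backbone triad")
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cv + ca
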