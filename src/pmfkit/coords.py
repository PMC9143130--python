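"""Scalar reaction coordinates over Cartesian frames.

Three kinds drive the scans, biases and analyses:

* ``distance`` — d(a, b) in Å;
* ``antisymmetric`` — d(a, b) − d(c, d), the breaking-minus-forming
  combination used for proton transfer and ring-opening coordinates, so a
  reactant state evaluates negative;
* ``dihedral`` — signed torsion in degrees, IUPAC sign convention (positive
  clockwise looking from a to b along the b→c axis), range (−180, 180].

``gradient`` returns the analytic derivative with respect to every atom's
Cartesian position (zero rows for uninvolved atoms); dihedral gradients are
in degrees/Å to stay consistent with ``evaluate``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import CoordinateFrame

__all__ = ["ReactionCoordinate", "distance_rc", "antisymmetric_rc", "dihedral_rc",
           "evaluate", "gradient"]

_KINDS = {"distance": 2, "antisymmetric": 4, "dihedral": 4}


@dataclass(frozen=True)
class ReactionCoordinate:
    kind: str
    indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        if len(self.indices) != _KINDS[self.kind]:
            raise ValueError(
                f"{self.kind} needs {_KINDS[self.kind]} atom indices, "
                f"got {len(self.indices)}"
            )
        if self.kind == "antisymmetric":
            # pairs (a,b) and (c,d) may share an atom, but each pair must
            # be a genuine distance
            a, b, c, d = self.indices
            if a == b or c == d:
                raise ValueError("degenerate distance pair in antisymmetric coordinate")
        elif len(set(self.indices)) != len(self.indices):
            raise ValueError("atom indices must be distinct")
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))

    def evaluate(self, frame: CoordinateFrame | np.ndarray) -> float:
        return evaluate(self, frame)

    def gradient(self, frame: CoordinateFrame | np.ndarray) -> np.ndarray:
        return gradient(self, frame)


def distance_rc(a: int, b: int, label: str = "") -> ReactionCoordinate:
    return ReactionCoordinate("distance", (a, b), label or f"d({a},{b})")


def antisymmetric_rc(a: int, b: int, c: int, d: int, label: str = "") -> ReactionCoordinate:
    """Breaking-minus-forming combination d(a,b) − d(c,d)."""
    return ReactionCoordinate(
        "antisymmetric", (a, b, c, d), label or f"asym(d({a},{b}),d({c},{d}))"
    )


def dihedral_rc(a: int, b: int, c: int, d: int, label: str = "") -> ReactionCoordinate:
    return ReactionCoordinate("dihedral", (a, b, c, d), label or f"dih({a},{b},{c},{d})")


def _coords(frame) -> np.ndarray:
    if isinstance(frame, CoordinateFrame):
        return frame.coords
    return np.asarray(frame, dtype=float)


def _check_indices(rc: ReactionCoordinate, n: int) -> None:
    for i in rc.indices:
        if not 0 <= i < n:
            raise IndexError(f"coordinate index {i} outside frame of {n} atoms")


def _dist(x: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(x[i] - x[j]))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion in degrees, IUPAC convention, range (−180, 180]."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        raise ValueError("degenerate geometry: collinear atoms in dihedral")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def evaluate(rc: ReactionCoordinate, frame) -> float:
    """Evaluate a coordinate on a frame (Å for distances, degrees for dihedrals)."""
    x = _coords(frame)
    _check_indices(rc, len(x))
    if rc.kind == "distance":
        a, b = rc.indices
        return _dist(x, a, b)
    if rc.kind == "antisymmetric":
        a, b, c, d = rc.indices
        return _dist(x, a, b) - _dist(x, c, d)
    a, b, c, d = rc.indices
    return dihedral_angle(x[a], x[b], x[c], x[d])


def _distance_grad(x: np.ndarray, i: int, j: int, out: np.ndarray, sign: float = 1.0):
    r = x[i] - x[j]
    norm = np.linalg.norm(r)
    if norm < 1e-12:
        raise ValueError(f"degenerate geometry: atoms {i} and {j} coincide")
    u = r / norm
    out[i] += sign * u
    out[j] -= sign * u


def gradient(rc: ReactionCoordinate, frame) -> np.ndarray:
    """Analytic ∂ξ/∂r, shape (n_atoms, 3); rows of uninvolved atoms are zero."""
    x = _coords(frame)
    _check_indices(rc, len(x))
    g = np.zeros_like(x)
    if rc.kind == "distance":
        a, b = rc.indices
        _distance_grad(x, a, b, g)
        return g
    if rc.kind == "antisymmetric":
        a, b, c, d = rc.indices
        _distance_grad(x, a, b, g, +1.0)
        _distance_grad(x, c, d, g, -1.0)
        return g
    return _dihedral_gradient(x, rc.indices)


def _dihedral_gradient(x: np.ndarray, idx) -> np.ndarray:
    """Closed-form torsion gradient (degrees/Å), zero-sum by construction."""
    a, b, c, d = idx
    b1 = x[b] - x[a]
    b2 = x[c] - x[b]
    b3 = x[d] - x[c]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    nb2 = float(np.linalg.norm(b2))
    if n1sq < 1e-24 or n2sq < 1e-24 or nb2 < 1e-12:
        raise ValueError("degenerate geometry in dihedral gradient")
    ga = -(nb2 / n1sq) * n1
    gd = (nb2 / n2sq) * n2
    p = float(np.dot(b1, b2)) / nb2**2
    q = float(np.dot(b3, b2)) / nb2**2
    gb = -(1.0 + p) * ga + q * gd
    gc = p * ga - (1.0 + q) * gd
    g = np.zeros_like(x)
    deg = 180.0 / math.pi
    g[a] = deg * ga
    g[b] = deg * gb
    g[c] = deg * gc
    g[d] = deg * gd
    return g
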