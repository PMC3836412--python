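"""Geometric primitives: internal-coordinate measurement, NeRF construction,
Kabsch superposition and symmetry-aware RMSD.

All angles are in degrees; torsions follow the IUPAC convention (cis = 0,
sign by the right-hand rule about the central bond) on (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .topology import (
    AUX_TORSIONS,
    CANONICAL_ATOMS,
    ConformerRecord,
    GlutamateTopology,
    IncompleteConformerError,
    InternalCoordinateSet,
    canonical_key,
    wrap_angle,
)


class GeometryError(ValueError):
    """Degenerate geometry (collinear frame, zero-length arm, ...)."""


def bond_length(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance |p - q| in Å."""
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


def bond_angle(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    """Angle p-q-r at vertex q, in [0, 180] degrees."""
    u = np.asarray(p, float) - np.asarray(q, float)
    v = np.asarray(r, float) - np.asarray(q, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("zero-length arm in bond angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral_angle(p: np.ndarray, q: np.ndarray, r: np.ndarray,
                   s: np.ndarray) -> float:
    """Signed torsion p-q-r-s about the q->r axis, degrees in (-180, 180]."""
    p, q, r, s = (np.asarray(x, float) for x in (p, q, r, s))
    b0 = p - q
    b1 = r - q
    b2 = s - r
    nb1 = np.linalg.norm(b1)
    if nb1 < 1e-12:
        raise GeometryError("coincident axis atoms in dihedral")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise GeometryError("collinear atoms in dihedral")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(math.degrees(math.atan2(y, x)))


# ---------------------------------------------------------------------------
# Internal coordinates <-> Cartesian
# ---------------------------------------------------------------------------

#: Z-matrix construction table: (atom, bond ref A, angle ref B, torsion ref C).
#: Atom placement order is fixed; every reference precedes its dependants.
#: The CB row is an improper torsion (N is not bonded to C): its sign fixes
#: the CA chirality independently of the carboxyl torsion theta.
ZMATRIX: tuple[tuple[str, str | None, str | None, str | None], ...] = (
    ("N", None, None, None),
    ("CA", "N", None, None),
    ("C", "CA", "N", None),
    ("O1", "C", "CA", "N"),
    ("O2", "C", "CA", "N"),
    ("CB", "CA", "C", "N"),
    ("CG", "CB", "CA", "N"),
    ("CD", "CG", "CB", "CA"),
    ("OE1", "CD", "CG", "CB"),
    ("OE2", "CD", "CG", "CB"),
)


def _zmatrix_keys():
    """(atom, bond key, angle key, torsion key) for rows with full references."""
    rows = []
    for atom, a, b, c in ZMATRIX:
        bond = canonical_key((a, atom)) if a else None
        ang = canonical_key((atom, a, b)) if b else None
        tor = canonical_key((atom, a, b, c)) if c else None
        rows.append((atom, a, b, c, bond, ang, tor))
    return rows


_ZROWS = _zmatrix_keys()


def internal_coordinates(conf: ConformerRecord,
                         topo: GlutamateTopology) -> InternalCoordinateSet:
    """Measure every bond, angle and torsion of the topology (plus the
    auxiliary construction torsions) on one conformer."""
    atoms = conf.atoms
    for name in topo.atom_names:
        if name not in atoms:
            raise IncompleteConformerError(
                f"{conf.conformer_id}: missing atom {name}")
    bonds = {canonical_key(b): bond_length(atoms[b[0]], atoms[b[1]])
             for b in topo.bonds}
    angles = {canonical_key(a): bond_angle(atoms[a[0]], atoms[a[1]], atoms[a[2]])
              for a in topo.angles}
    torsions: dict[tuple, float] = {}
    for quad in list(topo.torsions.values()) + list(AUX_TORSIONS):
        torsions[canonical_key(quad)] = dihedral_angle(
            atoms[quad[0]], atoms[quad[1]], atoms[quad[2]], atoms[quad[3]])
    return InternalCoordinateSet(bonds, angles, torsions)


def _place_nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to ``a`` given angle D-a-b and torsion D-a-b-c."""
    if not 0.0 < angle_deg < 180.0:
        raise GeometryError(f"degenerate construction angle {angle_deg:.3f}")
    th = math.radians(angle_deg)
    ph = math.radians(torsion_deg)
    d_local = np.array([-bond * math.cos(th),
                        bond * math.sin(th) * math.cos(ph),
                        bond * math.sin(th) * math.sin(ph)])
    ab = a - b
    nab = np.linalg.norm(ab)
    if nab < 1e-12:
        raise GeometryError("coincident frame atoms")
    ab /= nab
    n = np.cross(b - c, ab)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear construction frame")
    n /= nn
    m = np.cross(n, ab)
    rot = np.column_stack([ab, m, n])
    return a + rot @ d_local


def build_cartesian(topo: GlutamateTopology,
                    ics: InternalCoordinateSet,
                    conformer_id: str = "built",
                    source: str = "theoretical") -> ConformerRecord:
    """Reconstruct Cartesian coordinates from internal coordinates.

    Placement frame: N at the origin, CA on +x, C in the xy-plane with
    positive y.  Measuring the result reproduces ``ics`` to ~1e-6.
    """
    pos: dict[str, np.ndarray] = {}
    for atom, a, b, c, bond_k, ang_k, tor_k in _ZROWS:
        if a is None:
            pos[atom] = np.zeros(3)
        elif b is None:
            pos[atom] = np.array([ics.bond_lengths[bond_k], 0.0, 0.0])
        elif c is None:
            ang = ics.bond_angles[ang_k]
            if not 0.0 < ang < 180.0:
                raise GeometryError(f"degenerate angle {ang_k}")
            th = math.radians(ang)
            r = ics.bond_lengths[bond_k]
            pos[atom] = pos[a] + r * np.array([-math.cos(th), math.sin(th), 0.0])
        else:
            pos[atom] = _place_nerf(pos[a], pos[b], pos[c],
                                    ics.bond_lengths[bond_k],
                                    ics.bond_angles[ang_k],
                                    ics.torsions[tor_k])
    return ConformerRecord(conformer_id=conformer_id, source=source, atoms=pos)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    """Optimal proper rigid transform x -> rotation @ x + translation."""
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def _check_nondegenerate(x: np.ndarray) -> None:
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear or coincident) atom subset")


def kabsch_superpose(moving: ConformerRecord, target: ConformerRecord,
                     subset: Iterable[str] | None = None) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation of ``moving`` onto
    ``target`` over the given atom subset (default: all heavy atoms).

    Reflections are excluded so chirality is preserved.
    """
    names = tuple(subset) if subset is not None else CANONICAL_ATOMS
    if len(names) < 3:
        raise GeometryError("superposition needs at least 3 atoms")
    p = moving.coords(names)
    q = target.coords(names)
    _check_nondegenerate(p)
    _check_nondegenerate(q)
    return kabsch_points(p, q)


def kabsch_points(p: np.ndarray, q: np.ndarray) -> SuperpositionResult:
    """Kabsch on raw point arrays (rows correspond)."""
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = qc - rot @ pc
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _swap_labelings(swaps: Sequence[tuple[str, str]]):
    """All relabelings generated by the independent transpositions."""
    labelings = [{}]
    for a, b in swaps:
        labelings = [dict(m) for m in labelings] + [
            {**m, a: b, b: a} for m in labelings]
    return labelings


def rmsd_symmetric(a: ConformerRecord, b: ConformerRecord,
                   subset: Iterable[str] | None = None,
                   use_swaps: bool = True,
                   swaps: Sequence[tuple[str, str]] | None = None) -> float:
    """Superposition-minimised RMSD between two conformers.

    With ``use_swaps`` the minimum over the carboxylate oxygen relabelings
    (O1<->O2, OE1<->OE2) is returned, treating the chemically equivalent
    oxygens as indistinguishable.  Symmetric in its arguments.
    """
    names = tuple(subset) if subset is not None else CANONICAL_ATOMS
    if swaps is None:
        swaps = (("O1", "O2"), ("OE1", "OE2"))
    labelings = _swap_labelings(swaps) if use_swaps else [{}]
    best = math.inf
    pa = a.coords(names)
    _check_nondegenerate(pa)
    for lab in labelings:
        renamed = tuple(lab.get(n, n) for n in names)
        pb = b.coords(renamed)
        best = min(best, kabsch_points(pb, pa).rmsd)
    return best


def superpose_onto(moving: ConformerRecord, target: ConformerRecord,
                   subset: Iterable[str] | None = None) -> ConformerRecord:
    """Return a copy of ``moving`` rigidly transformed onto ``target``."""
    res = kabsch_superpose(moving, target, subset)
    return moving.transformed(res.rotation, res.translation)
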