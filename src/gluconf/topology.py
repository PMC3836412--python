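"""Canonical glutamate topology, conformer records and internal coordinates.

The heavy-atom skeleton of L-glutamate is a tree of 10 atoms::

            O1  O2              OE1  OE2
             \\  /                 \\  /
      N ----- CA ----- CB -- CG -- CD
              |
              C (carboxyl carbon, bonded to O1/O2)

Naming follows the convention used in the crystallographic reporting of the
ligand: the main-chain carboxylate oxygens are ``O1``/``O2`` (wwPDB ``O`` and
``OXT``), the side-chain carboxylate oxygens are ``OE1``/``OE2``.

Internal coordinates are stored keyed by atom-name tuples.  A tuple and its
reversal denote the same measurement, so keys are canonicalised to the
lexicographically smaller orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

CANONICAL_ATOMS: tuple[str, ...] = (
    "N", "CA", "C", "O1", "O2", "CB", "CG", "CD", "OE1", "OE2",
)

ELEMENTS: dict[str, str] = {
    "N": "N", "CA": "C", "C": "C", "O1": "O", "O2": "O",
    "CB": "C", "CG": "C", "CD": "C", "OE1": "O", "OE2": "O",
}

BONDS: tuple[tuple[str, str], ...] = (
    ("N", "CA"), ("CA", "C"), ("C", "O1"), ("C", "O2"), ("CA", "CB"),
    ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2"),
)

ANGLES: tuple[tuple[str, str, str], ...] = (
    ("N", "CA", "C"), ("CA", "C", "O1"), ("CA", "C", "O2"),
    ("C", "CA", "CB"), ("CA", "CB", "CG"), ("CB", "CG", "CD"),
    ("CG", "CD", "OE1"), ("CG", "CD", "OE2"),
)

#: Named torsions.  ``chi1``..``chi3`` are the side-chain dihedrals; ``theta``
#: is the main-chain carboxyl torsion N-CA-C-O1, the single rotatable
#: main-chain degree of freedom of the free amino acid (phi/psi do not exist
#: without peptide neighbours).
TORSIONS: dict[str, tuple[str, str, str, str]] = {
    "chi1": ("N", "CA", "CB", "CG"),
    "chi2": ("CA", "CB", "CG", "CD"),
    "chi3": ("CB", "CG", "CD", "OE1"),
    "theta": ("N", "CA", "C", "O1"),
}

#: Auxiliary dihedrals completing the 3N-6 internal-coordinate set: the
#: second oxygen of each carboxylate and the improper fixing CA chirality.
AUX_TORSIONS: tuple[tuple[str, str, str, str], ...] = (
    ("N", "CA", "C", "O2"),
    ("CB", "CG", "CD", "OE2"),
    ("CB", "CA", "C", "N"),   # improper; sign encodes L/D at CA
)

SYMMETRY_SWAPS: tuple[tuple[str, str], ...] = (("O1", "O2"), ("OE1", "OE2"))
MAIN_CHAIN: tuple[str, ...] = ("N", "CA", "C")
#: Atom subset used for the "main-chain RMSD" reported for the experimental
#: clusters: backbone plus the alpha-carboxylate oxygens.
MAIN_CHAIN_REPORT: tuple[str, ...] = ("N", "CA", "C", "O1", "O2")

#: Signed volume det(N-CA, C-CA, CB-CA) is positive for L-amino acids.
L_CHIRAL_SIGN = 1.0

#: Default value (deg) of the improper torsion CB-CA-C-N placing CB at a
#: near-tetrahedral position with L configuration at CA.
IDEAL_IMPROPER_CB = 122.0

# ---------------------------------------------------------------------------
# Reference geometry statistics (crystallographic ensemble, n = 22)
# ---------------------------------------------------------------------------

#: Bond-length mean and SD (Å) measured across the receptor-bound ensemble.
EXPERIMENTAL_BOND_STATS: dict[tuple[str, str], tuple[float, float]] = {
    ("N", "CA"): (1.491, 0.010),
    ("CA", "C"): (1.524, 0.008),
    ("C", "O1"): (1.245, 0.010),
    ("C", "O2"): (1.247, 0.006),
    ("CA", "CB"): (1.535, 0.010),
    ("CB", "CG"): (1.523, 0.011),
    ("CG", "CD"): (1.525, 0.013),
    ("CD", "OE1"): (1.250, 0.009),
    ("CD", "OE2"): (1.254, 0.010),
}

#: Bond-angle mean and SD (degrees) across the receptor-bound ensemble.
EXPERIMENTAL_ANGLE_STATS: dict[tuple[str, str, str], tuple[float, float]] = {
    ("N", "CA", "C"): (111.063, 1.478),
    ("CA", "C", "O1"): (118.796, 1.044),
    ("CA", "C", "O2"): (118.565, 1.558),
    ("C", "CA", "CB"): (110.027, 0.813),
    ("CA", "CB", "CG"): (114.447, 0.984),
    ("CB", "CG", "CD"): (112.999, 0.970),
    ("CG", "CD", "OE1"): (118.545, 1.146),
    ("CG", "CD", "OE2"): (119.017, 1.402),
}

#: Average bond lengths (Å) over the relaxed vacuum conformer database; used
#: as ideal bond lengths for template construction and as harmonic r0.
IDEAL_BOND_LENGTHS: dict[tuple[str, str], float] = {
    ("CA", "C"): 1.552,
    ("N", "CA"): 1.501,
    ("CA", "CB"): 1.538,
    ("CB", "CG"): 1.535,
    ("CG", "CD"): 1.530,
    ("C", "O1"): 1.266,
    ("C", "O2"): 1.266,
    ("CD", "OE1"): 1.267,
    ("CD", "OE2"): 1.267,
}

#: Ideal angles (deg) = ensemble averages; harmonic theta0.
IDEAL_BOND_ANGLES: dict[tuple[str, str, str], float] = {
    k: v[0] for k, v in EXPERIMENTAL_ANGLE_STATS.items()
}


def canonical_key(key: Sequence[str]) -> tuple[str, ...]:
    """Canonicalise an internal-coordinate key (a tuple equals its reversal)."""
    t = tuple(key)
    r = t[::-1]
    return t if t <= r else r


def _bond_graph() -> dict[str, set[str]]:
    g: dict[str, set[str]] = {a: set() for a in CANONICAL_ATOMS}
    for a, b in BONDS:
        g[a].add(b)
        g[b].add(a)
    return g


def bond_separation() -> dict[frozenset, int]:
    """Graph distance (number of bonds) between every heavy-atom pair."""
    g = _bond_graph()
    dist: dict[frozenset, int] = {}
    for src in CANONICAL_ATOMS:
        seen = {src: 0}
        queue = [src]
        while queue:
            cur = queue.pop(0)
            for nb in g[cur]:
                if nb not in seen:
                    seen[nb] = seen[cur] + 1
                    queue.append(nb)
        for atom, d in seen.items():
            dist[frozenset((src, atom))] = d
    return dist


@dataclass(frozen=True)
class GlutamateTopology:
    """Connectivity, named torsions and symmetry of the glutamate heavy atoms."""

    atom_names: tuple[str, ...] = CANONICAL_ATOMS
    bonds: tuple[tuple[str, str], ...] = BONDS
    angles: tuple[tuple[str, str, str], ...] = ANGLES
    torsions: Mapping[str, tuple[str, str, str, str]] = field(
        default_factory=lambda: dict(TORSIONS))
    symmetry_swaps: tuple[tuple[str, str], ...] = SYMMETRY_SWAPS
    main_chain: tuple[str, ...] = MAIN_CHAIN

    def validate(self) -> None:
        g = {a: set() for a in self.atom_names}
        for a, b in self.bonds:
            g[a].add(b)
            g[b].add(a)
        # connected + acyclic tree: |E| = |V|-1 and all reachable
        if len(self.bonds) != len(self.atom_names) - 1:
            raise ValueError("bond graph is not a tree")
        seen = {self.atom_names[0]}
        stack = [self.atom_names[0]]
        while stack:
            for nb in g[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if seen != set(self.atom_names):
            raise ValueError("bond graph is not connected")
        bonded = {frozenset(b) for b in self.bonds}
        for name, quad in self.torsions.items():
            for a, b in zip(quad, quad[1:]):
                if frozenset((a, b)) not in bonded:
                    raise ValueError(f"torsion {name} is not a bonded path")


DEFAULT_TOPOLOGY = GlutamateTopology()
DEFAULT_TOPOLOGY.validate()


class IncompleteConformerError(ValueError):
    """A conformer is missing required heavy atoms."""


@dataclass
class ConformerRecord:
    """One glutamate conformation: id, provenance and heavy-atom coordinates (Å)."""

    conformer_id: str
    source: str  # experimental | theoretical | synthetic
    atoms: dict[str, np.ndarray]
    provenance: str = ""
    hydrogens: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float) for k, v in self.atoms.items()}

    def coords(self, subset: Iterable[str] | None = None) -> np.ndarray:
        names = tuple(subset) if subset is not None else CANONICAL_ATOMS
        try:
            return np.array([self.atoms[n] for n in names], dtype=float)
        except KeyError as exc:
            raise IncompleteConformerError(
                f"{self.conformer_id}: missing atom {exc.args[0]}") from exc

    def validate(self) -> None:
        missing = [a for a in CANONICAL_ATOMS if a not in self.atoms]
        if missing:
            raise IncompleteConformerError(
                f"{self.conformer_id}: missing atoms {missing}")
        xyz = self.coords()
        if not np.all(np.isfinite(xyz)):
            raise ValueError(f"{self.conformer_id}: non-finite coordinates")
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 0.5:
            raise ValueError(
                f"{self.conformer_id}: atoms closer than 0.5 Å "
                f"(min pairwise distance {d.min():.3f})")
        if self.chiral_volume() * L_CHIRAL_SIGN <= 0:
            raise ValueError(f"{self.conformer_id}: CA chirality is not L")

    def chiral_volume(self) -> float:
        """Signed volume det(N-CA, C-CA, CB-CA); positive for L."""
        ca = self.atoms["CA"]
        v = np.cross(self.atoms["N"] - ca, self.atoms["C"] - ca)
        return float(np.dot(v, self.atoms["CB"] - ca))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray,
                    conformer_id: str | None = None) -> "ConformerRecord":
        atoms = {k: rotation @ v + translation for k, v in self.atoms.items()}
        return ConformerRecord(
            conformer_id=conformer_id or self.conformer_id,
            source=self.source, atoms=atoms, provenance=self.provenance)

    def copy(self) -> "ConformerRecord":
        return ConformerRecord(self.conformer_id, self.source,
                               {k: v.copy() for k, v in self.atoms.items()},
                               self.provenance,
                               {k: v.copy() for k, v in self.hydrogens.items()})


@dataclass
class InternalCoordinateSet:
    """Bond lengths (Å), bond angles (deg) and torsions (deg) of one conformer.

    Torsions are stored in the IUPAC sign convention on (-180, 180].
    """

    bond_lengths: dict[tuple[str, str], float]
    bond_angles: dict[tuple[str, str, str], float]
    torsions: dict[tuple[str, str, str, str], float]

    def get_torsion(self, key: Sequence[str]) -> float:
        return self.torsions[canonical_key(key)]

    def set_torsion(self, key: Sequence[str], value: float) -> None:
        self.torsions[canonical_key(key)] = wrap_angle(value)

    def get_angle(self, key: Sequence[str]) -> float:
        return self.bond_angles[canonical_key(key)]

    def get_bond(self, key: Sequence[str]) -> float:
        return self.bond_lengths[canonical_key(key)]

    def validate(self) -> None:
        for k, v in self.bond_lengths.items():
            if not 0.8 < v < 2.0:
                raise ValueError(f"bond {k} length {v:.3f} Å outside (0.8, 2)")
        for k, v in self.bond_angles.items():
            if not 0.0 < v < 180.0:
                raise ValueError(f"angle {k} = {v:.2f} outside (0, 180)")
        for k, v in self.torsions.items():
            if not -180.0 < v <= 180.0:
                raise ValueError(f"torsion {k} = {v:.2f} outside (-180, 180]")

    def copy(self) -> "InternalCoordinateSet":
        return InternalCoordinateSet(dict(self.bond_lengths),
                                     dict(self.bond_angles),
                                     dict(self.torsions))


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    w = math.fmod(deg, 360.0)
    if w <= -180.0:
        w += 360.0
    elif w > 180.0:
        w -= 360.0
    return w
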