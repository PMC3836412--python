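"""Systematic torsion-grid conformer search for glutamate in vacuum.

The search enumerates a regular grid over the rotatable torsions
(chi1, chi2, chi3 and the main-chain carboxyl torsion theta), locally
minimises a transparent molecular-mechanics energy in torsion space,
eliminates duplicates by symmetric RMSD, ranks by energy, groups by
single-linkage similarity, detects intramolecular N-H...O hydrogen bonds
and classifies each conformer as extended or rounded.

The energy is a fixed-parameter vacuum force field::

    E = sum_bonds  k_b (r - r0)^2
      + sum_angles k_a (theta - theta0)^2
      + sum_{pairs >= 3 bonds apart} [ 4 eps_ij ((s_ij/r)^12 - (s_ij/r)^6)
                                       + 332.0637 q_i q_j / (D r) ]

with 1-4 pairs scaled by ``scale_14`` and Lorentz-Berthelot combining.
Equilibrium values default to the ensemble-average geometry of the relaxed
conformer database (bond lengths) and of the crystallographic ensemble
(angles).  The default species is the vacuum anion (both carboxylates
deprotonated, ammonium protonated, net charge -1); a zwitterion-like
neutral-side-chain variant is available.  Bonds and angles are frozen at
their template values during the scan, so the torsional preferences are
driven entirely by the nonbonded terms.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize as scipy_minimize

from . import topology as _topo
from .geometry import (
    GeometryError,
    _place_nerf,
    bond_angle,
    build_cartesian,
    internal_coordinates,
    rmsd_symmetric,
)
from .topology import (
    CANONICAL_ATOMS,
    ConformerRecord,
    DEFAULT_TOPOLOGY,
    ELEMENTS,
    GlutamateTopology,
    InternalCoordinateSet,
    bond_separation,
    canonical_key,
    wrap_angle,
)

logger = logging.getLogger(__name__)

COULOMB_CONSTANT = 332.0637  # kcal mol^-1 Å e^-2
MIN_PAIR_DISTANCE = 0.1      # Å; closer pairs are clamped with a warning

#: Lennard-Jones parameters per element: sigma (Å), epsilon (kcal/mol).
LJ_BY_ELEMENT: dict[str, tuple[float, float]] = {
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
}

#: Partial charges (e) for the vacuum anion: ammonium +1 collapsed onto N,
#: each carboxylate carries -1 split as C +0.70 / O -0.85, -0.85.
CHARGES_ANION: dict[str, float] = {
    "N": 1.00, "CA": 0.0, "CB": 0.0, "CG": 0.0,
    "C": 0.70, "O1": -0.85, "O2": -0.85,
    "CD": 0.70, "OE1": -0.85, "OE2": -0.85,
}

#: Neutral (protonated) side-chain carboxyl variant; net charge 0.
CHARGES_ZWITTERION: dict[str, float] = {
    "N": 1.00, "CA": 0.0, "CB": 0.0, "CG": 0.0,
    "C": 0.70, "O1": -0.85, "O2": -0.85,
    "CD": 0.60, "OE1": -0.30, "OE2": -0.30,
}


@dataclass
class EnergyParameters:
    """Force-field parameters for the vacuum molecular-mechanics energy."""

    bond_r0: dict[tuple[str, str], float] = field(
        default_factory=lambda: {canonical_key(k): v
                                 for k, v in _topo.IDEAL_BOND_LENGTHS.items()})
    bond_k: float = 300.0          # kcal mol^-1 Å^-2
    angle_theta0: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: {canonical_key(k): v
                                 for k, v in _topo.IDEAL_BOND_ANGLES.items()})
    angle_k: float = 0.02          # kcal mol^-1 deg^-2 (~65 per rad^2)
    charges: dict[str, float] = field(default_factory=lambda: dict(CHARGES_ANION))
    lj: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {n: LJ_BY_ELEMENT[ELEMENTS[n]]
                                 for n in CANONICAL_ATOMS})
    scale_14: float = 0.5
    dielectric: float = 1.0
    net_charge: float = -1.0

    @classmethod
    def anionic(cls) -> "EnergyParameters":
        return cls()

    @classmethod
    def zwitterionic(cls) -> "EnergyParameters":
        return cls(charges=dict(CHARGES_ZWITTERION), net_charge=0.0)

    def validate(self) -> None:
        total = sum(self.charges[n] for n in CANONICAL_ATOMS)
        if abs(total - self.net_charge) > 1e-9:
            raise ValueError(
                f"total charge {total:+.3f} != declared species charge "
                f"{self.net_charge:+.3f}")
        if self.bond_k <= 0 or self.angle_k <= 0:
            raise ValueError("force constants must be positive")
        for n, (s, e) in self.lj.items():
            if s <= 0 or e <= 0:
                raise ValueError(f"LJ parameters for {n} must be positive")

    def digest(self) -> str:
        payload = repr(sorted(self.__dict__.items(), key=lambda kv: kv[0]))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ScanConfig:
    """Configuration of the systematic torsion scan."""

    torsion_names: tuple[str, ...] = ("chi1", "chi2", "chi3", "theta")
    step: float = 30.0             # degrees
    dedup_rmsd: float = 0.1        # Å
    group_rmsd: float = 0.5        # Å
    min_tol: float = 1e-6          # kcal/mol gradient tolerance
    max_iter: int = 200
    seed: int = 0
    rounded_threshold: float = 4.0  # Å, N...OE distance for shape label

    def validate(self, topo: GlutamateTopology = DEFAULT_TOPOLOGY) -> None:
        if self.step <= 0 or abs(360.0 / self.step - round(360.0 / self.step)) > 1e-9:
            raise ValueError(f"step {self.step} must divide 360")
        if not 0 < self.dedup_rmsd < self.group_rmsd:
            raise ValueError("require 0 < dedup_rmsd < group_rmsd")
        for name in self.torsion_names:
            if name not in topo.torsions:
                raise ValueError(f"unknown torsion {name!r}")

    def grid_axis(self) -> list[float]:
        n = int(round(360.0 / self.step))
        return [-180.0 + self.step * i for i in range(n)]


#: Carboxylate partner torsions that must co-rotate with a scanned torsion
#: to keep the group planar: scanned name -> (partner aux quadruple).
_COUPLED_AUX: dict[str, tuple[str, str, str, str]] = {
    "theta": ("N", "CA", "C", "O2"),
    "chi3": ("CB", "CG", "CD", "OE2"),
}


def set_scanned_torsions(ics: InternalCoordinateSet,
                         values: dict[str, float],
                         topo: GlutamateTopology = DEFAULT_TOPOLOGY) -> None:
    """Set named torsions in-place, co-rotating the second carboxylate oxygen
    so the group geometry (the O-C-O plane) is preserved."""
    for name, value in values.items():
        quad = topo.torsions[name]
        old = ics.get_torsion(quad)
        ics.set_torsion(quad, value)
        if name in _COUPLED_AUX:
            aux = _COUPLED_AUX[name]
            offset = wrap_angle(ics.get_torsion(aux) - old)
            ics.set_torsion(aux, value + offset)


# ---------------------------------------------------------------------------
# Energy
# ---------------------------------------------------------------------------

def _nonbonded_pairs(params: EnergyParameters,
                     topo: GlutamateTopology) -> list[tuple[int, int, float, float, float]]:
    """Precomputed (i, j, coulomb coefficient, LJ A, LJ B) for pairs at least
    three bonds apart; 1-4 pairs carry the scale factor."""
    sep = bond_separation()
    names = topo.atom_names
    pairs = []
    for i, j in itertools.combinations(range(len(names)), 2):
        d = sep[frozenset((names[i], names[j]))]
        if d < 3:
            continue
        scale = params.scale_14 if d == 3 else 1.0
        qi, qj = params.charges[names[i]], params.charges[names[j]]
        si, ei = params.lj[names[i]]
        sj, ej = params.lj[names[j]]
        sig = 0.5 * (si + sj)
        eps = math.sqrt(ei * ej)
        a = scale * 4.0 * eps * sig ** 12
        b = scale * 4.0 * eps * sig ** 6
        c = scale * COULOMB_CONSTANT * qi * qj / params.dielectric
        pairs.append((i, j, c, a, b))
    return pairs


def _nonbonded_energy(coords: Sequence[Sequence[float]],
                      pairs: Sequence[tuple[int, int, float, float, float]]) -> float:
    e = 0.0
    clamped = False
    for i, j, c, a, b in pairs:
        xi, yi, zi = coords[i]
        xj, yj, zj = coords[j]
        r2 = (xi - xj) ** 2 + (yi - yj) ** 2 + (zi - zj) ** 2
        if r2 < MIN_PAIR_DISTANCE ** 2:
            r2 = MIN_PAIR_DISTANCE ** 2
            clamped = True
        inv6 = 1.0 / (r2 * r2 * r2)
        e += (a * inv6 - b) * inv6 + c / math.sqrt(r2)
    if clamped:
        warnings.warn("overlapping atoms clamped to 0.1 Å in nonbonded energy",
                      stacklevel=3)
    return e


def mm_energy(conf: ConformerRecord,
              params: EnergyParameters | None = None,
              topo: GlutamateTopology = DEFAULT_TOPOLOGY) -> float:
    """Vacuum molecular-mechanics energy (kcal/mol) of one conformer."""
    params = params or EnergyParameters.anionic()
    atoms = conf.atoms
    e = 0.0
    for a, b in topo.bonds:
        r = math.dist(atoms[a], atoms[b])
        e += params.bond_k * (r - params.bond_r0[canonical_key((a, b))]) ** 2
    for tri in topo.angles:
        th = bond_angle(atoms[tri[0]], atoms[tri[1]], atoms[tri[2]])
        e += params.angle_k * (th - params.angle_theta0[canonical_key(tri)]) ** 2
    idx = {n: i for i, n in enumerate(topo.atom_names)}
    coords = [tuple(atoms[n]) for n in topo.atom_names]
    e += _nonbonded_energy(coords, _nonbonded_pairs(params, topo))
    return e


class TorsionEnergyModel:
    """Fast energy-as-a-function-of-torsions for a frozen bond/angle template.

    Bond lengths and angles are fixed at the template values, so the bonded
    energy is a constant and only the nonbonded terms respond to the scanned
    torsions.  Coordinates are rebuilt with a scalar NeRF chain, which keeps
    a single energy evaluation cheap enough for exhaustive grid work.
    """

    def __init__(self, template_ics: InternalCoordinateSet,
                 params: EnergyParameters | None = None,
                 torsion_names: Sequence[str] = ("chi1", "chi2", "chi3", "theta"),
                 topo: GlutamateTopology = DEFAULT_TOPOLOGY):
        self.params = params or EnergyParameters.anionic()
        self.params.validate()
        self.topo = topo
        self.torsion_names = tuple(torsion_names)
        self.template = template_ics.copy()
        self.pairs = _nonbonded_pairs(self.params, topo)
        self._compile()
        ref = build_cartesian(topo, self.template)
        self.bonded_constant = mm_energy(ref, self.params, topo) - \
            _nonbonded_energy([tuple(ref.atoms[n]) for n in topo.atom_names],
                              self.pairs)

    def _compile(self) -> None:
        from .geometry import ZMATRIX
        ics = self.template
        scanned = {canonical_key(self.topo.torsions[n]): i
                   for i, n in enumerate(self.torsion_names)}
        coupled = {}
        for name, aux in _COUPLED_AUX.items():
            if name in self.torsion_names:
                named_key = canonical_key(self.topo.torsions[name])
                aux_key = canonical_key(aux)
                offset = wrap_angle(ics.torsions[aux_key] - ics.torsions[named_key])
                coupled[aux_key] = (scanned[named_key], math.radians(offset))
        self._index = {n: i for i, n in enumerate(self.topo.atom_names)}
        rows = []
        for atom, a, b, c in ZMATRIX:
            if a is None:
                rows.append(("origin", self._index[atom]))
            elif b is None:
                rows.append(("axis", self._index[atom],
                             ics.bond_lengths[canonical_key((a, atom))]))
            elif c is None:
                r = ics.bond_lengths[canonical_key((a, atom))]
                th = math.radians(ics.bond_angles[canonical_key((atom, a, b))])
                rows.append(("plane", self._index[atom], self._index[a],
                             -r * math.cos(th), r * math.sin(th)))
            else:
                r = ics.bond_lengths[canonical_key((a, atom))]
                th = math.radians(ics.bond_angles[canonical_key((atom, a, b))])
                tor_key = canonical_key((atom, a, b, c))
                if tor_key in scanned:
                    driver = (scanned[tor_key], 0.0)
                elif tor_key in coupled:
                    driver = coupled[tor_key]
                else:
                    driver = (None, math.radians(ics.torsions[tor_key]))
                rows.append(("nerf", self._index[atom], self._index[a],
                             self._index[b], self._index[c],
                             -r * math.cos(th), r * math.sin(th), driver))
        self._rows = rows

    def coordinates(self, torsions_deg: Sequence[float]) -> list[tuple[float, float, float]]:
        """Cartesian coordinates (template frame) for scanned torsion values."""
        phi = [math.radians(t) for t in torsions_deg]
        pos: list[tuple[float, float, float]] = [(0.0, 0.0, 0.0)] * 10
        for row in self._rows:
            kind = row[0]
            if kind == "origin":
                pos[row[1]] = (0.0, 0.0, 0.0)
            elif kind == "axis":
                pos[row[1]] = (row[2], 0.0, 0.0)
            elif kind == "plane":
                _, di, ai, dx, dy = row
                ax, ay, az = pos[ai]
                pos[di] = (ax + dx, ay + dy, az)
            else:
                _, di, ai, bi, ci, dpar, dperp, (free, off) = row
                ph = off if free is None else phi[free] + off
                ax, ay, az = pos[ai]
                bx, by, bz = pos[bi]
                cx, cy, cz = pos[ci]
                abx, aby, abz = ax - bx, ay - by, az - bz
                nab = math.sqrt(abx * abx + aby * aby + abz * abz)
                abx, aby, abz = abx / nab, aby / nab, abz / nab
                bcx, bcy, bcz = bx - cx, by - cy, bz - cz
                nx = bcy * abz - bcz * aby
                ny = bcz * abx - bcx * abz
                nz = bcx * aby - bcy * abx
                nn = math.sqrt(nx * nx + ny * ny + nz * nz)
                nx, ny, nz = nx / nn, ny / nn, nz / nn
                mx = ny * abz - nz * aby
                my = nz * abx - nx * abz
                mz = nx * aby - ny * abx
                cph, sph = math.cos(ph), math.sin(ph)
                ux = dpar * abx + dperp * (cph * mx + sph * nx)
                uy = dpar * aby + dperp * (cph * my + sph * ny)
                uz = dpar * abz + dperp * (cph * mz + sph * nz)
                pos[di] = (ax + ux, ay + uy, az + uz)
        return pos

    def energy(self, torsions_deg: Sequence[float]) -> float:
        """Total energy (kcal/mol) at the given scanned torsions."""
        return self.bonded_constant + _nonbonded_energy(
            self.coordinates(torsions_deg), self.pairs)

    def conformer(self, torsions_deg: Sequence[float],
                  conformer_id: str = "scan",
                  source: str = "theoretical") -> ConformerRecord:
        pos = self.coordinates(torsions_deg)
        atoms = {n: np.array(pos[self._index[n]]) for n in self.topo.atom_names}
        return ConformerRecord(conformer_id=conformer_id, source=source,
                               atoms=atoms)


# ---------------------------------------------------------------------------
# Grid enumeration, minimisation, deduplication
# ---------------------------------------------------------------------------

def enumerate_torsion_grid(template: ConformerRecord,
                           cfg: ScanConfig,
                           topo: GlutamateTopology = DEFAULT_TOPOLOGY,
                           ) -> Iterator[tuple[tuple[float, ...], ConformerRecord]]:
    """Yield ``(torsion vector, conformer)`` over the full regular grid.

    Exactly ``(360/step)^k`` conformers in lexicographic axis order, each
    axis running -180, -180+step, ..., 180-step.  All non-scanned internal
    coordinates stay at the template values.
    """
    cfg.validate(topo)
    ics = internal_coordinates(template, topo)
    axis = cfg.grid_axis()
    counter = 0
    for combo in itertools.product(axis, repeat=len(cfg.torsion_names)):
        work = ics.copy()
        set_scanned_torsions(work, dict(zip(cfg.torsion_names, combo)), topo)
        counter += 1
        yield combo, build_cartesian(topo, work,
                                     conformer_id=f"grid-{counter:06d}")


@dataclass
class MinimizationResult:
    conformer: ConformerRecord
    energy: float
    torsions: tuple[float, ...]
    converged: bool
    n_iter: int


def minimize_torsions(conf: ConformerRecord,
                      params: EnergyParameters | None = None,
                      cfg: ScanConfig | None = None,
                      topo: GlutamateTopology = DEFAULT_TOPOLOGY,
                      model: TorsionEnergyModel | None = None) -> MinimizationResult:
    """Deterministic local minimisation over the scanned torsions only.

    Bond lengths and angles are frozen at the conformer's own values; the
    returned energy never exceeds the input energy.
    """
    cfg = cfg or ScanConfig()
    if model is None:
        model = TorsionEnergyModel(internal_coordinates(conf, topo), params,
                                   cfg.torsion_names, topo)
        x0 = [internal_coordinates(conf, topo).get_torsion(topo.torsions[n])
              for n in cfg.torsion_names]
    else:
        ics = internal_coordinates(conf, topo)
        x0 = [ics.get_torsion(topo.torsions[n]) for n in cfg.torsion_names]
    x, e, nit, ok = _minimize_model(model, x0, cfg)
    out = model.conformer(x, conformer_id=f"{conf.conformer_id}-min")
    return MinimizationResult(conformer=out, energy=e,
                              torsions=tuple(wrap_angle(v) for v in x),
                              converged=ok, n_iter=nit)


def _minimize_model(model: TorsionEnergyModel, x0: Sequence[float],
                    cfg: ScanConfig) -> tuple[list[float], float, int, bool]:
    e0 = model.energy(x0)
    res = scipy_minimize(model.energy, np.asarray(x0, float),
                         method="L-BFGS-B",
                         options={"maxiter": cfg.max_iter,
                                  "ftol": 1e-12,
                                  "gtol": cfg.min_tol})
    if res.fun <= e0:
        return list(res.x), float(res.fun), int(res.nit), bool(res.success)
    return list(x0), e0, 0, True  # already at (numerical) minimum


def deduplicate(items: Sequence[tuple[ConformerRecord, float]],
                dedup_rmsd: float = 0.1,
                use_swaps: bool = True) -> list[tuple[ConformerRecord, float]]:
    """Greedy duplicate elimination in ascending energy order.

    A conformer is kept iff its symmetric all-heavy-atom RMSD to every
    already-kept conformer exceeds ``dedup_rmsd``.  Idempotent.
    """
    ordered = sorted(items, key=lambda t: t[1])
    kept: list[tuple[ConformerRecord, float]] = []
    for conf, e in ordered:
        if all(rmsd_symmetric(conf, k, use_swaps=use_swaps) > dedup_rmsd
               for k, _ in kept):
            kept.append((conf, e))
    return kept


# ---------------------------------------------------------------------------
# Hydrogen bonds and shape
# ---------------------------------------------------------------------------

AMMONIUM_NH = 1.01          # Å
AMMONIUM_ANGLE = 109.47     # deg, H-N-CA
HBOND_ACCEPTORS = ("O1", "O2", "OE1", "OE2")


def place_ammonium_hydrogens(conf: ConformerRecord) -> dict[str, np.ndarray]:
    """Geometric ammonium hydrogens: N-H 1.01 Å, tetrahedral, staggered with
    respect to the CA substituents (H-N-CA-C dihedrals 60, 180, -60)."""
    n, ca, c = conf.atoms["N"], conf.atoms["CA"], conf.atoms["C"]
    out = {}
    for i, phi in enumerate((60.0, 180.0, -60.0), start=1):
        out[f"H{i}"] = _place_nerf(n, ca, c, AMMONIUM_NH, AMMONIUM_ANGLE, phi)
    return out


@dataclass
class HydrogenBond:
    donor: str
    hydrogen: str
    acceptor: str
    distance_ha: float   # H...O, Å
    angle_dha: float     # N-H...O, deg


def detect_hbond(conf: ConformerRecord,
                 distance_cutoff: float = 2.5,
                 angle_min: float = 120.0) -> list[HydrogenBond]:
    """Intramolecular N-H...O contacts of the ammonium group.

    Hydrogens are placed geometrically (they never enter RMSD or bonded
    energy terms); a contact is reported when d(H...O) <= cutoff and the
    N-H...O angle is >= ``angle_min``.
    """
    hydrogens = place_ammonium_hydrogens(conf)
    n = conf.atoms["N"]
    found = []
    for hname, h in hydrogens.items():
        for acc in HBOND_ACCEPTORS:
            o = conf.atoms[acc]
            d = float(np.linalg.norm(h - o))
            if d > distance_cutoff:
                continue
            ang = bond_angle(n, h, o)
            if ang >= angle_min:
                found.append(HydrogenBond("N", hname, acc, d, ang))
    return found


def classify_shape(conf: ConformerRecord, threshold: float = 4.0) -> str:
    """``rounded`` iff the ammonium nitrogen approaches a side-chain
    carboxylate oxygen (min N...OE distance < threshold), else ``extended``."""
    d = min(float(np.linalg.norm(conf.atoms["N"] - conf.atoms[o]))
            for o in ("OE1", "OE2"))
    return "rounded" if d < threshold else "extended"


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class DatabaseRecord:
    conformer: ConformerRecord
    torsions: dict[str, float]
    energy: float
    shape: str
    group: int
    hbonds: list[HydrogenBond] = field(default_factory=list)


@dataclass
class ConformerDatabase:
    """Minimised unique conformers with energies, groups and shape labels."""

    records: list[DatabaseRecord]
    grid_energies: pd.DataFrame
    stats: pd.DataFrame
    config: ScanConfig
    n_grid: int
    provenance: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rec in enumerate(self.records, start=1):
            row = {"conformer_id": rec.conformer.conformer_id, "rank": i}
            row.update({n: rec.torsions[n] for n in self.config.torsion_names})
            row.update({"energy_kcal_mol": rec.energy, "shape": rec.shape,
                        "group": rec.group, "n_hbonds": len(rec.hbonds)})
            rows.append(row)
        return pd.DataFrame(rows)


def _collapse_minima(results: list[tuple[tuple[float, ...], float]],
                     resolution: float = 0.05
                     ) -> list[tuple[tuple[float, ...], float]]:
    """Merge minimisation endpoints that are the same stationary point up to
    ``resolution`` degrees, keeping the lowest energy representative."""
    best: dict[tuple[int, ...], tuple[tuple[float, ...], float]] = {}
    for tors, e in results:
        key = tuple(int(round(((t + 180.0) % 360.0) / resolution))
                    for t in tors)
        cur = best.get(key)
        if cur is None or e < cur[1]:
            best[key] = (tors, e)
    return sorted(best.values(), key=lambda t: (t[1], t[0]))


def run_conformer_pipeline(cfg: ScanConfig | None = None,
                           params: EnergyParameters | None = None,
                           topo: GlutamateTopology = DEFAULT_TOPOLOGY,
                           template: ConformerRecord | None = None,
                           ) -> ConformerDatabase:
    """Grid scan -> local minimisation -> dedup -> energy ranking -> grouping
    -> shape/H-bond annotation.  Fully deterministic for a given config."""
    from .synthetic import ideal_template
    from .ensemble import cluster_threshold, descriptive_stats, pairwise_rmsd_matrix

    cfg = cfg or ScanConfig()
    cfg.validate(topo)
    params = params or EnergyParameters.anionic()
    params.validate()
    template = template or ideal_template()
    model = TorsionEnergyModel(internal_coordinates(template, topo), params,
                               cfg.torsion_names, topo)
    axis = cfg.grid_axis()
    grid = list(itertools.product(axis, repeat=len(cfg.torsion_names)))
    logger.info("scanning %d grid points over %s",
                len(grid), ",".join(cfg.torsion_names))

    grid_rows = []
    minima: list[tuple[tuple[float, ...], float]] = []
    for point in grid:
        e_grid = model.energy(point)
        grid_rows.append((*point, e_grid))
        x, e, _, _ = _minimize_model(model, point, cfg)
        minima.append((tuple(wrap_angle(v) for v in x), e))
    grid_df = pd.DataFrame(grid_rows,
                           columns=[*cfg.torsion_names, "energy_kcal_mol"])

    unique = _collapse_minima(minima)
    candidates = [(model.conformer(t, conformer_id=f"min-{i:04d}"), e)
                  for i, (t, e) in enumerate(unique, start=1)]
    kept = deduplicate(candidates, cfg.dedup_rmsd, use_swaps=True)

    confs = [c for c, _ in kept]
    for i, c in enumerate(confs, start=1):
        c.conformer_id = f"VAC-{i}"
    if len(confs) > 1:
        mat = pairwise_rmsd_matrix(confs, use_swaps=True)
        assignment = cluster_threshold(mat, tau=cfg.group_rmsd, linkage="single")
        # groups re-indexed so group 1 holds the lowest-energy conformer
        order: dict[int, int] = {}
        for c, _ in kept:
            lab = assignment.labels[c.conformer_id]
            if lab not in order:
                order[lab] = len(order) + 1
        labels = {cid: order[lab] for cid, lab in assignment.labels.items()}
    else:
        labels = {confs[0].conformer_id: 1}

    records = []
    for conf, e in kept:
        ics = internal_coordinates(conf, topo)
        tors = {n: ics.get_torsion(topo.torsions[n]) for n in topo.torsions}
        records.append(DatabaseRecord(
            conformer=conf, torsions=tors, energy=e,
            shape=classify_shape(conf, cfg.rounded_threshold),
            group=labels[conf.conformer_id],
            hbonds=detect_hbond(conf)))

    stats = descriptive_stats([internal_coordinates(c, topo) for c in confs],
                              topo=topo)
    return ConformerDatabase(records=records, grid_energies=grid_df,
                             stats=stats, config=cfg, n_grid=len(grid),
                             provenance=f"params:{params.digest()}")
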