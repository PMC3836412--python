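"""Ensemble-level analysis: descriptive statistics of internal coordinates,
pairwise RMSD matrices, iterative multiple alignment and threshold
clustering.

Statistics follow the conventions of small-sample crystallographic ensemble
reporting: sample SD (n-1 denominator) and the variation coefficient
VC% = 100*SD/mean for bond lengths and angles.  Torsions are circular
variables, so their mean and SD are circular and VC is not applicable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import circmean, circstd

from .geometry import kabsch_points, rmsd_symmetric
from .topology import (
    CANONICAL_ATOMS,
    ConformerRecord,
    GlutamateTopology,
    InternalCoordinateSet,
    TORSIONS,
    canonical_key,
)


def _variable_key(name: str):
    """Resolve a variable name ('CB-CG', 'CB-CG-CD' or 'chi1') to an IC key."""
    if name in TORSIONS:
        return canonical_key(TORSIONS[name]), "torsion"
    parts = tuple(name.split("-"))
    if len(parts) == 2:
        return canonical_key(parts), "bond"
    if len(parts) == 3:
        return canonical_key(parts), "angle"
    if len(parts) == 4:
        return canonical_key(parts), "torsion"
    raise KeyError(f"unrecognised variable name {name!r}")


def _lookup(ics: InternalCoordinateSet, key, kind: str) -> float:
    store = {"bond": ics.bond_lengths, "angle": ics.bond_angles,
             "torsion": ics.torsions}[kind]
    return store[key]


def default_variables(topo: GlutamateTopology) -> list[str]:
    names = ["-".join(b) for b in topo.bonds]
    names += ["-".join(a) for a in topo.angles]
    names += list(topo.torsions)
    return names


def descriptive_stats(ensemble: Sequence[InternalCoordinateSet],
                      variables: Iterable[str] | None = None,
                      topo: GlutamateTopology | None = None) -> pd.DataFrame:
    """Per-variable mean, sample SD, min, max and VC% across an ensemble.

    Returns a DataFrame indexed by variable name with columns
    ``kind, n, mean, sd, min, max, vc_percent``.  For torsions the mean and
    SD are circular and ``vc_percent`` is NaN.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    if variables is None:
        from .topology import DEFAULT_TOPOLOGY
        variables = default_variables(topo or DEFAULT_TOPOLOGY)
    rows = []
    for name in variables:
        key, kind = _variable_key(name)
        vals = np.array([_lookup(ics, key, kind) for ics in ensemble])
        n = len(vals)
        if kind == "torsion":
            mean = float(circmean(vals, high=180.0, low=-180.0))
            sd = float(circstd(vals, high=180.0, low=-180.0)) if n > 1 else 0.0
            vc = math.nan
        else:
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            vc = 100.0 * sd / mean if mean > 0 else math.nan
        rows.append({"variable": name, "kind": kind, "n": n, "mean": mean,
                     "sd": sd, "min": float(vals.min()),
                     "max": float(vals.max()), "vc_percent": vc})
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# Pairwise RMSD and clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(confs: Sequence[ConformerRecord],
                         subset: Iterable[str] | None = None,
                         use_swaps: bool = False) -> pd.DataFrame:
    """Symmetric matrix of superposition-minimised RMSD values (Å)."""
    if len(confs) < 2:
        raise ValueError("need at least two conformers")
    ids = [c.conformer_id for c in confs]
    n = len(confs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = rmsd_symmetric(confs[i], confs[j], subset, use_swaps)
            except Exception as exc:
                raise RuntimeError(
                    f"RMSD failed for pair ({ids[i]}, {ids[j]}): {exc}") from exc
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class ClusterAssignment:
    """Threshold-clustering result over a conformer ensemble."""
    labels: dict[str, int]
    centers: dict[int, str]
    intra_rmsd: dict[int, float]
    inter_center_rmsd: pd.DataFrame
    linkage: str = "single"
    tau: float = 1.0


def cluster_threshold(matrix: pd.DataFrame | np.ndarray,
                      ids: Sequence[str] | None = None,
                      tau: float = 1.0,
                      linkage: str = "single") -> ClusterAssignment:
    """Agglomerative clustering of an RMSD matrix cut at distance ``tau``.

    Cluster indices are contiguous from 1, ordered by decreasing size (ties
    by smallest member id).  The center of each cluster is its medoid: the
    member minimising mean RMSD to co-members, ties broken by id.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if isinstance(matrix, pd.DataFrame):
        if ids is None:
            ids = list(matrix.index)
        matrix = matrix.to_numpy()
    if ids is None:
        ids = [str(i) for i in range(len(matrix))]
    mat = np.asarray(matrix, dtype=float)
    if mat.shape[0] != mat.shape[1] or mat.shape[0] != len(ids):
        raise ValueError("matrix/id dimension mismatch")
    if len(ids) == 1:
        raw = np.array([1])
    else:
        z = scipy_linkage(squareform(mat, checks=False), method=linkage)
        raw = fcluster(z, t=tau, criterion="distance")
    # relabel: decreasing size, ties by smallest member id
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(raw):
        groups.setdefault(int(lab), []).append(idx)
    ordered = sorted(groups.values(),
                     key=lambda mem: (-len(mem), min(ids[i] for i in mem)))
    labels: dict[str, int] = {}
    centers: dict[int, str] = {}
    intra: dict[int, float] = {}
    for ci, members in enumerate(ordered, start=1):
        for i in members:
            labels[ids[i]] = ci
        sub = mat[np.ix_(members, members)]
        mean_to_others = sub.mean(axis=1)
        order = sorted(range(len(members)),
                       key=lambda k: (mean_to_others[k], ids[members[k]]))
        medoid_local = order[0]
        medoid = members[medoid_local]
        centers[ci] = ids[medoid]
        # mean over all members incl. the medoid itself (zero term)
        intra[ci] = float(np.mean(mat[medoid, members]))
    k = len(ordered)
    inter = np.zeros((k, k))
    for a in range(1, k + 1):
        for b in range(1, k + 1):
            ia = ids.index(centers[a])
            ib = ids.index(centers[b])
            inter[a - 1, b - 1] = mat[ia, ib]
    inter_df = pd.DataFrame(inter, index=range(1, k + 1), columns=range(1, k + 1))
    return ClusterAssignment(labels=labels, centers=centers, intra_rmsd=intra,
                             inter_center_rmsd=inter_df,
                             linkage=linkage, tau=tau)


def cluster_summary(assignment: ClusterAssignment,
                    matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster report: size, medoid, intra-RMSD and center-to-center RMSD."""
    rows = []
    clusters = sorted(assignment.centers)
    for ci in clusters:
        members = [cid for cid, lab in assignment.labels.items() if lab == ci]
        row = {"cluster": ci, "size": len(members),
               "medoid": assignment.centers[ci],
               "intra_rmsd": assignment.intra_rmsd[ci],
               "members": ";".join(sorted(members))}
        for cj in clusters:
            row[f"rmsd_to_center_{cj}"] = float(
                assignment.inter_center_rmsd.loc[ci, cj])
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


# ---------------------------------------------------------------------------
# Iterative multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    aligned: list[ConformerRecord]
    mean_coords: np.ndarray
    iterations: int
    converged: bool
    subset: tuple[str, ...] = field(default_factory=tuple)


def iterative_mean_alignment(confs: Sequence[ConformerRecord],
                             subset: Iterable[str] | None = None,
                             tol: float = 1e-6,
                             max_iter: int = 100) -> AlignmentResult:
    """Align an ensemble into a common frame by iterating superposition onto
    the evolving coordinate mean.

    The reference starts as the first conformer; each round superposes every
    conformer onto the reference and replaces it with the coordinate mean,
    until the mean moves by less than ``tol`` (RMSD) or ``max_iter`` is hit
    (flagged, not raised).
    """
    if len(confs) < 2:
        raise ValueError("need at least two conformers to align")
    names = tuple(subset) if subset is not None else CANONICAL_ATOMS
    coords = np.array([c.coords(names) for c in confs])
    ref = coords[0].copy()
    converged = False
    iterations = 0
    transforms = [None] * len(confs)
    for iterations in range(1, max_iter + 1):
        new = np.empty_like(coords)
        for i in range(len(confs)):
            res = kabsch_points(coords[i], ref)
            transforms[i] = res
            new[i] = coords[i] @ res.rotation.T + res.translation
        mean = new.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((mean - ref) ** 2, axis=1))))
        ref = mean
        if shift < tol:
            converged = True
            break
    aligned = [c.transformed(t.rotation, t.translation)
               for c, t in zip(confs, transforms)]
    return AlignmentResult(aligned=aligned, mean_coords=ref,
                           iterations=iterations, converged=converged,
                           subset=names)
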