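"""Roster and regression analysis of the receptor-bound glutamate ensemble.

The 22 receptor-bound glutamate molecules come from 13 crystal structures of
ionotropic (GluR0/2/5/6) and metabotropic (mGluR1) glutamate receptor
ligand-binding domains.  PDB coordinate files are not bundled; download them
from the wwPDB (https://files.rcsb.org/download/<ID>.pdb) into a local
directory and point :func:`load_reference_ensemble` at it.
"""

from __future__ import annotations

from pathlib import Path

from .ensemble import cluster_threshold, pairwise_rmsd_matrix
from .structure_io import read_pdb_file
from .topology import MAIN_CHAIN_REPORT, ConformerRecord

#: conformer id -> (receptor subunit, receptor class) for the 22-member
#: receptor-bound ensemble.  Classes: "i" ionotropic, "m" metabotropic.
REFERENCE_ROSTER: dict[str, tuple[str, str]] = {
    "1FTJ-274": ("GluR2", "i"), "1FTJ-275": ("GluR2", "i"),
    "1FTJ-276": ("GluR2", "i"),
    "2CMO-274": ("GluR2", "i"), "2CMO-275": ("GluR2", "i"),
    "1TXF-111": ("GluR5", "i"),
    "1YCJ-998": ("GluR5", "i"), "1YCJ-999": ("GluR5", "i"),
    "2F36-501": ("GluR5", "i"), "2F36-502": ("GluR5", "i"),
    "2F36-503": ("GluR5", "i"), "2F36-504": ("GluR5", "i"),
    "1S50-999": ("GluR6", "i"),
    "1S7Y-551": ("GluR6", "i"), "1S7Y-552": ("GluR6", "i"),
    "2A5S-1001": ("GluR6", "i"),
    "1US4-131": ("GluR0", "i"), "1US5-1313": ("GluR0", "i"),
    "1II5-999": ("GluR0", "i"),
    "1EWK-701": ("mGluR1", "m"), "1EWK-702": ("mGluR1", "m"),
    "1ISR-1001": ("mGluR1", "m"),
}

PDB_IDS: tuple[str, ...] = tuple(sorted({k.split("-")[0]
                                         for k in REFERENCE_ROSTER}))


def load_reference_ensemble(data_dir: str | Path) -> list[ConformerRecord]:
    """Extract the 22 roster conformers from locally supplied PDB files.

    ``data_dir`` must contain ``<ID>.pdb`` for each entry in :data:`PDB_IDS`.
    Raises ``FileNotFoundError`` if any file is missing.
    """
    data_dir = Path(data_dir)
    confs: dict[str, ConformerRecord] = {}
    for pdb_id in PDB_IDS:
        path = data_dir / f"{pdb_id}.pdb"
        if not path.exists():
            path = data_dir / f"{pdb_id.lower()}.pdb"
        if not path.exists():
            raise FileNotFoundError(f"missing coordinate file for {pdb_id}")
        for conf in read_pdb_file(path, pdb_id):
            confs[conf.conformer_id] = conf
    missing = [cid for cid in REFERENCE_ROSTER if cid not in confs]
    if missing:
        raise ValueError(f"roster conformers not found: {missing}")
    return [confs[cid] for cid in REFERENCE_ROSTER]


def reference_cluster_analysis(confs: list[ConformerRecord],
                               tau: float = 1.0):
    """Main-chain-metric clustering of the reference ensemble.

    Returns ``(assignment, matrix)`` with the metric used for the bound
    ensemble: superposition on all heavy atoms, RMSD reported over the
    main-chain subset (N, CA, C, O1, O2), deposited oxygen names kept.
    """
    matrix = pairwise_rmsd_matrix(confs, subset=MAIN_CHAIN_REPORT,
                                  use_swaps=False)
    assignment = cluster_threshold(matrix, tau=tau, linkage="single")
    return assignment, matrix
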