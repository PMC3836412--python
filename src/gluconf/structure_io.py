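"""Reading and writing glutamate conformers in PDB and CSV form.

Extraction pulls every complete glutamate residue (bound ligand or free
residue) out of a crystal-structure PDB file, normalises the wwPDB atom
names (``O``/``OXT``) to the carboxylate convention used throughout this
package (``O1``/``O2``), and resolves alternate locations by occupancy.

Multi-model conformer sets written by this module carry a
``REMARK 300 CONFORMER_ID`` line per model so that conformer identifiers
survive a round trip exactly.
"""

from __future__ import annotations

import io
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import gemmi
import numpy as np
import pandas as pd

from .topology import CANONICAL_ATOMS, ELEMENTS, ConformerRecord

logger = logging.getLogger(__name__)

_REMARK_ID = re.compile(r"^REMARK 300 CONFORMER_ID\s+(\d+)\s+(\S+)")

#: Raw PDB name -> canonical name.  Canonical names map to themselves.
NAME_ALIASES: dict[str, str] = {
    "O": "O1", "OXT": "O2", "OT1": "O1", "OT2": "O2",
    "1OE": "OE1", "2OE": "OE2",
    **{n: n for n in CANONICAL_ATOMS},
}


class PdbParseError(ValueError):
    """A coordinate line could not be parsed; message names the line."""


class AtomNameConflictError(ValueError):
    """Two raw atom names normalise to the same canonical name."""


def normalize_atom_names(raw: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Map raw PDB atom names to canonical glutamate heavy-atom names.

    Unknown heavy-atom names are dropped with a warning; hydrogens are
    dropped silently.  Two raw names resolving to the same canonical name
    raise :class:`AtomNameConflictError`.
    """
    out: dict[str, np.ndarray] = {}
    origin: dict[str, str] = {}
    for name, pos in raw.items():
        key = name.strip().upper()
        if key not in NAME_ALIASES:
            if key.startswith("H") or (key[:1].isdigit() and "H" in key):
                continue
            logger.warning("dropping unknown atom name %r", name)
            continue
        canon = NAME_ALIASES[key]
        if canon in out:
            raise AtomNameConflictError(
                f"atom names {origin[canon]!r} and {name!r} both map to {canon}")
        out[canon] = np.asarray(pos, dtype=float)
        origin[canon] = name
    return out


def _validate_coordinate_lines(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise PdbParseError(f"line {lineno}: truncated coordinate line")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise PdbParseError(
                    f"line {lineno}: malformed coordinate field: {exc}") from exc


def _select_altloc(atom_sites: list[tuple[str, float, np.ndarray]]) -> np.ndarray:
    """Keep the highest-occupancy alternate location; ties break alphabetically."""
    return sorted(atom_sites, key=lambda t: (-t[1], t[0] or "A"))[0][2]


def parse_pdb_conformers(pdb_text: str, pdb_id: str,
                         residue_name: str = "GLU",
                         source: str = "experimental") -> list[ConformerRecord]:
    """Extract complete glutamate conformers from a PDB coordinate file.

    One :class:`ConformerRecord` is returned per glutamate residue with the
    full 10-heavy-atom set after name normalisation; incomplete residues are
    skipped with a logged warning.  Conformer ids are ``<pdb_id>-<seq>``.
    """
    _validate_coordinate_lines(pdb_text)
    id_by_model: dict[int, str] = {}
    for line in pdb_text.splitlines():
        m = _REMARK_ID.match(line)
        if m:
            id_by_model[int(m.group(1))] = m.group(2)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(f"PDB parsing failed: {exc}") from exc

    out: list[ConformerRecord] = []
    seen: set[str] = set()
    multi_model = len(st) > 1
    for model_idx, model in enumerate(st, start=1):
        for chain in model:
            for res in chain:
                if res.name.strip() != residue_name:
                    continue
                sites: dict[str, list[tuple[str, float, np.ndarray]]] = {}
                for atom in res:
                    sites.setdefault(atom.name.strip(), []).append(
                        (atom.altloc or "", atom.occ, np.array(atom.pos.tolist())))
                raw = {name: _select_altloc(alts) for name, alts in sites.items()}
                atoms = normalize_atom_names(raw)
                missing = [a for a in CANONICAL_ATOMS if a not in atoms]
                if missing:
                    logger.warning(
                        "%s %s %s/%d: skipping, missing heavy atoms %s",
                        pdb_id, residue_name, chain.name, res.seqid.num, missing)
                    continue
                cid = id_by_model.get(model_idx, f"{pdb_id}-{res.seqid.num}")
                if cid in seen:
                    cid = f"{cid}.m{model_idx}" if multi_model \
                        else f"{cid}.{chain.name}"
                seen.add(cid)
                out.append(ConformerRecord(
                    conformer_id=cid, source=source,
                    atoms={n: atoms[n] for n in CANONICAL_ATOMS},
                    provenance=f"{pdb_id} chain {chain.name} "
                               f"{residue_name} {res.seqid.num}"))
    return out


def read_pdb_file(path: str | Path, pdb_id: str | None = None,
                  **kwargs) -> list[ConformerRecord]:
    path = Path(path)
    if pdb_id is None:
        pdb_id = path.stem.upper()
    return parse_pdb_conformers(path.read_text(), pdb_id, **kwargs)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _residue_seq(conf: ConformerRecord, fallback: int) -> int:
    tail = conf.conformer_id.rsplit("-", 1)[-1].split(".")[0]
    try:
        return int(tail)
    except ValueError:
        return fallback


def _pdb_string(confs: Sequence[ConformerRecord]) -> str:
    st = gemmi.Structure()
    st.name = "gluconf conformer set"
    seen_seq: set[int] = set()
    for i, conf in enumerate(confs, start=1):
        model = gemmi.Model(i)
        chain = gemmi.Chain("A")
        res = gemmi.Residue()
        res.name = "GLU"
        seq = _residue_seq(conf, i)
        if seq in seen_seq:
            seq = max(seen_seq) + 1
        seen_seq.add(seq)
        res.seqid = gemmi.SeqId(seq, " ")
        res.het_flag = "H"
        for name in CANONICAL_ATOMS:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(ELEMENTS[name])
            x, y, z = conf.atoms[name]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    remarks = "".join(
        f"REMARK 300 CONFORMER_ID {i} {c.conformer_id}\n"
        for i, c in enumerate(confs, start=1))
    return remarks + st.make_pdb_string()


def conformer_frame(confs: Sequence[ConformerRecord]) -> pd.DataFrame:
    """One row per conformer: id, source and 30 coordinate columns."""
    rows = []
    for conf in confs:
        row: dict[str, object] = {"conformer_id": conf.conformer_id,
                                  "source": conf.source}
        for name in CANONICAL_ATOMS:
            for ax, v in zip("xyz", conf.atoms[name]):
                row[f"{name}_{ax}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_conformer_set(confs: Sequence[ConformerRecord],
                        sink: str | Path | TextIO,
                        fmt: str = "pdb",
                        header: str | None = None) -> None:
    """Write a conformer set as a multi-model PDB or a CSV table.

    PDB output uses one MODEL block per conformer with canonical atom names
    and round-trips through :func:`parse_pdb_conformers` to within the PDB
    fixed-width precision (1e-3 Å), with conformer ids preserved exactly.
    """
    if not confs:
        raise ValueError("cannot write an empty conformer set")
    if fmt == "pdb":
        text = _pdb_string(confs)
        if header:
            text = "".join(f"REMARK 299 {line}\n"
                           for line in header.splitlines()) + text
    elif fmt == "csv":
        buf = io.StringIO()
        if header:
            buf.write("".join(f"# {line}\n" for line in header.splitlines()))
        conformer_frame(confs).to_csv(buf, index=False)
        text = buf.getvalue()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text)
    else:
        sink.write(text)
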