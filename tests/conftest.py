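import numpy as np
import pytest

from gluconf.geometry import build_cartesian
from gluconf.search import set_scanned_torsions
from gluconf.synthetic import ideal_template, template_internal_coordinates
from gluconf.topology import DEFAULT_TOPOLOGY


@pytest.fixture(scope="session")
def topo():
    return DEFAULT_TOPOLOGY


@pytest.fixture()
def template():
    return ideal_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def conformer_at(torsions: dict, conformer_id: str = "conf"):
    """Template conformer with the given named torsions set."""
    ics = template_internal_coordinates()
    set_scanned_torsions(ics, torsions)
    return build_cartesian(DEFAULT_TOPOLOGY, ics, conformer_id=conformer_id)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def toy_pdb_block(positions: dict, res_seq: int = 274, chain: str = "A",
                  alt_loc: str = " ", occupancy: float = 1.0,
                  res_name: str = "GLU", record: str = "HETATM",
                  start_serial: int = 1) -> str:
    """Hand-written fixed-column PDB coordinate block."""
    elements = {"N": "N", "O": "O"}
    lines = []
    for i, (name, pos) in enumerate(positions.items()):
        el = elements.get(name[0], "C")
        x, y, z = pos
        lines.append(
            f"{record:<6s}{start_serial + i:5d} {name:<4s}{alt_loc}"
            f"{res_name:<3s} {chain}{res_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}"
            f"          {el:>2s}")
    return "\n".join(lines) + "\n"
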