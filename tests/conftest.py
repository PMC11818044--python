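import numpy as np
import pytest


def pdb_atom_line(serial: int, name: str, resname: str, resseq: int,
                  xyz, bfac: float = 0.0, chain: str = "A") -> str:
    return (f"ATOM  {serial:5d}  {name:<3s}{resname:>4s} {chain}"
            f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{bfac:6.2f}           C\n")


@pytest.fixture
def toy_pdb(tmp_path):
    """Three ALA residues with CB atoms at (0,0,0), (0,0,5), (0,0,20)."""
    path = tmp_path / "toy.pdb"
    lines = [
        pdb_atom_line(1, "CA", "ALA", 1, (0.5, 0, 0)),
        pdb_atom_line(2, "CB", "ALA", 1, (0, 0, 0)),
        pdb_atom_line(3, "CA", "ALA", 2, (0.5, 0, 5)),
        pdb_atom_line(4, "CB", "ALA", 2, (0, 0, 5)),
        pdb_atom_line(5, "CA", "ALA", 3, (0.5, 0, 20)),
        pdb_atom_line(6, "CB", "ALA", 3, (0, 0, 20)),
    ]
    path.write_text("".join(lines) + "END\n")
    return path


@pytest.fixture
def random_coords():
    def make(n, seed=0, scale=20.0):
        return np.random.default_rng(seed).uniform(-scale, scale, size=(n, 3))
    return make
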