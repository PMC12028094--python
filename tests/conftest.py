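import numpy as np
import pytest

from pbflex.geometry import DihedralSeries
from pbflex.synthetic import (
    ensemble_from_dihedrals,
    helix_dihedrals,
    strand_dihedrals,
)


def repetitive_series(maker, n_residues=12, n_frames=1):
    phi, psi = maker(n_residues)
    return DihedralSeries(
        phi=np.tile(phi, (n_frames, 1)),
        psi=np.tile(psi, (n_frames, 1)),
        resids=np.arange(1, n_residues + 1),
    )


@pytest.fixture
def helix_series():
    return repetitive_series(helix_dihedrals, n_residues=12, n_frames=3)


@pytest.fixture
def strand_series():
    return repetitive_series(strand_dihedrals, n_residues=12, n_frames=3)


@pytest.fixture
def helix_ensemble():
    """3 identical frames of an ideal 12-residue helix backbone."""
    return ensemble_from_dihedrals(repetitive_series(helix_dihedrals, 12, 3))


def pdb_atom_line(serial, name, resname, chain, resid, xyz, b=0.0, occ=1.0,
                  element=None, record="ATOM"):
    element = element or name.strip()[0]
    name_field = f" {name:<3s}" if len(name) < 4 else name
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:>5d} {name_field:<4s} {resname:<3s} {chain}"
        f"{resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def make_pdb(tmp_path):
    def _write(lines, fname="input.pdb"):
        path = tmp_path / fname
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
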