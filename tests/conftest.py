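"""Shared fixtures: reference rate constants and programmatic toy structures."""

from __future__ import annotations

import numpy as np
import pytest

from tightbind.datasets import KINETIC_CONSTANTS
from tightbind.kinetic_models import RateParameters
from tightbind.structure_io import AtomRecord, StructureModel
from tightbind.synthetic_assay import builtin_designs


def make_atom(
    name: str,
    element: str,
    x: float,
    y: float,
    z: float,
    chain: str = "A",
    resnum: int = 1,
    resname: str = "GLY",
    **kwargs,
) -> AtomRecord:
    return AtomRecord(chain, resnum, "", resname, name, element, x, y, z, **kwargs)


def chain_of_cas(chain: str, coords: np.ndarray, resname: str = "ALA") -> list[AtomRecord]:
    return [
        make_atom("CA", "C", *c, chain=chain, resnum=i + 1, resname=resname)
        for i, c in enumerate(np.asarray(coords, dtype=float))
    ]


@pytest.fixture
def plasmin_rates() -> RateParameters:
    r = KINETIC_CONSTANTS[("textilinin-1", "plasmin")]
    return RateParameters(k_on=r.k_on.value, k_off=r.k_off.value)


@pytest.fixture
def plasmin_design():
    return builtin_designs()["plasmin"]


@pytest.fixture
def toy_complex_pair():
    """Two copies of a synthetic protease-inhibitor complex whose inhibitor
    copies differ by an exact 8 degree rotation about their centroid, with
    the whole second complex additionally moved rigidly."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(7)
    prot = rng.normal(size=(40, 3)) * 8
    inh = rng.normal(size=(20, 3)) * 4 + np.array([15.0, 0.0, 0.0])
    c1 = StructureModel(chain_of_cas("E", prot) + chain_of_cas("I", inh), "complex1")

    global_rot = Rotation.from_euler("xyz", [0.5, -0.2, 1.0]).as_matrix()
    global_t = np.array([3.0, -5.0, 2.0])
    axis = np.array([1.0, 2.0, 0.5])
    axis /= np.linalg.norm(axis)
    extra = Rotation.from_rotvec(np.deg2rad(8.0) * axis).as_matrix()
    centroid = inh.mean(axis=0)
    inh2 = (inh - centroid) @ extra.T + centroid
    c2 = StructureModel(
        chain_of_cas("E", prot @ global_rot.T + global_t)
        + chain_of_cas("I", inh2 @ global_rot.T + global_t),
        "complex2",
    )
    return c1, c2


TINY_PDB = """\
HEADER    TOY FIXTURE
ATOM      1  N   SER A  17      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  SER A  17      10.500   5.000  -5.800  1.00 10.00           C
ATOM      3  OG  SER A  17       9.000   4.500  -7.100  1.00 10.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA ASER A   1       1.000   0.000   0.000  0.60 10.00           C
ATOM      3  CA BSER A   1       2.000   0.000   0.000  0.40 10.00           C
ATOM      4  CB ASER A   1       3.000   0.000   0.000  0.50 10.00           C
ATOM      5  CB BSER A   1       4.000   0.000   0.000  0.50 10.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path
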