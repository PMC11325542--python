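import math

import numpy as np
import pytest

from hispi import synthetic_data as sd
from hispi.structure_io import Atom, Residue, Structure


@pytest.fixture
def his_template():
    return sd.make_residue_template("HIS")


@pytest.fixture
def phe_template():
    return sd.make_residue_template("PHE")


@pytest.fixture
def mining_fixture():
    """Manifest + structure with one designed His–Phe pair, a six-His tag and
    a Zn-bound His (4 Å)."""
    manifest = sd.FixtureManifest(
        aromatic_pairs=[sd.AromaticPairSpec("HIS", "PHE", 3.8, 10.0, 70.0)],
        his_tag_runs=[6],
        metal_his=[("ZN", 4.0)],
    )
    structure, echo = sd.make_fixture_structure(manifest)
    return manifest, structure, echo


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion construction)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def transform(residue: Residue, rot: np.ndarray, shift: np.ndarray) -> Residue:
    return sd._transform_residue(residue, rot, np.asarray(shift, dtype=float))


def hexagon_residue(name="PHE", chain="A", seq=1, side=1.39, z=0.0) -> Residue:
    """Perfect benzene ring in the z-plane (no CB)."""
    radius = side / (2 * math.sin(math.pi / 6))
    names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    atoms = [
        Atom(
            name=n,
            element="C",
            coords=np.array(
                [radius * math.cos(2 * math.pi * i / 6), radius * math.sin(2 * math.pi * i / 6), z]
            ),
        )
        for i, n in enumerate(names)
    ]
    return Residue(chain_id=chain, seq_number=seq, name=name, atoms=atoms)
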