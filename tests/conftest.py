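"""Shared builders for synthetic structures used across the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from chw.structure import Atom, Residue, StructureModel, WaterSite

AA3 = {
    "A": "ALA", "G": "GLY", "N": "ASN", "P": "PRO", "L": "LEU", "S": "SER",
    "T": "THR", "V": "VAL", "R": "ARG", "M": "MET", "D": "ASP", "E": "GLU",
    "Q": "GLN", "K": "LYS", "F": "PHE", "W": "TRP", "Y": "TYR", "I": "ILE",
    "H": "HIS", "C": "CYS",
}


def make_water(x, y, z, number=1, label=None, b=30.0, chain="W"):
    atom = Atom(
        element="O", name="O", alt_loc="", coords=np.array([x, y, z], dtype=float),
        b_factor=b, occupancy=1.0, residue_name="HOH", residue_number=number,
        insertion_code="", chain_id=chain, is_hetero=True, is_water=True,
    )
    return WaterSite(oxygen=atom, label=label)


def make_chain(sequence, chain_id="A", start=1, jitter=0.0, seed=0):
    """Cα trace along a loose helix; Asn residues get a side-chain ND2."""
    rng = np.random.default_rng(seed)
    residues = []
    for i, c in enumerate(sequence):
        num = start + i
        th = 0.6 * i
        pos = np.array([5 * np.cos(th), 5 * np.sin(th), 1.5 * i])
        if jitter:
            pos = pos + rng.normal(0, jitter, 3)
        name = AA3[c]
        atoms = [
            Atom("C", "CA", "", pos, 20.0, 1.0, name, num, "", chain_id, False, False)
        ]
        if c == "N":
            atoms.append(
                Atom("N", "ND2", "", pos + np.array([1.2, 0.0, 0.0]), 20.0, 1.0,
                     name, num, "", chain_id, False, False)
            )
        residues.append(Residue(name, num, "", chain_id, atoms))
    return residues


def make_model(sequence="GAVL", chain_id="A", start=1, waters=(), identifier="toy",
               **chain_kwargs):
    model = StructureModel(identifier=identifier)
    model.chains[chain_id] = make_chain(sequence, chain_id, start=start, **chain_kwargs)
    model.waters = list(waters)
    return model


@pytest.fixture
def rigid_transform():
    """A fixed proper rigid transform (rotation matrix, translation)."""
    from chw._geom import random_rotation

    rng = np.random.default_rng(1234)
    return random_rotation(rng), np.array([3.0, -2.0, 7.5])


@pytest.fixture
def hourglass_model():
    """Toy hourglass pore: min ring radius 3.45 Å at z=0 → min diameter 3.5 Å."""
    from chw.synth import PoreSpec, make_toy_pore

    spec = PoreSpec(radius_profile=lambda z: 3.45 + 0.012 * z * z, z_range=(-15, 15))
    return make_toy_pore(spec)
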