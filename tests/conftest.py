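"""Shared fixtures: tiny hand-built structures and the synthetic fixture set."""
from __future__ import annotations

import numpy as np
import pytest

from hingemd import HingeModelParams, write_fixture_set
from hingemd.structure_io import Atom, Structure, Trajectory


def make_ca_atom(serial, residue, xyz, name="CA", resname="GLY", chain="A"):
    return Atom(serial, name, residue, resname, chain,
                np.asarray(xyz, dtype=float), element="C")


def make_ca_structure(coords, residue_numbers=None, resnames=None):
    """C-alpha-only Structure from an (n, 3) array."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if residue_numbers is None:
        residue_numbers = range(1, n + 1)
    if resnames is None:
        resnames = ["GLY"] * n
    atoms = [
        make_ca_atom(i + 1, r, coords[i], resname=resnames[i])
        for i, r in enumerate(residue_numbers)
    ]
    return Structure(atoms)


def make_trajectory(frames, residue_numbers=None, resnames=None, dt_ns=0.1):
    frames = np.asarray(frames, dtype=float)
    top = make_ca_structure(frames[0], residue_numbers, resnames)
    return Trajectory(top, frames, dt_ns=dt_ns)


@pytest.fixture(scope="session")
def default_params():
    return HingeModelParams()


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory, default_params):
    """The canonical synthetic fixture set (400-frame trajectories)."""
    out = tmp_path_factory.mktemp("fixtures")
    return write_fixture_set(out, default_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
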