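"""Shared fixtures: tiny hand-built systems with fully known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from lipocontact.core import Atom, Segment, Topology, Trajectory
from lipocontact.selection import AtomSelection
from lipocontact.synthetic import SyntheticSystemSpec, build_toy_system


def make_topology(specs: list[tuple]) -> Topology:
    """Build a Topology from (name, element, resid, resname, chain, segment)."""
    atoms = [
        Atom(i, name, element, resid, resname, chain, Segment(segment))
        for i, (name, element, resid, resname, chain, segment) in enumerate(specs)
    ]
    return Topology(atoms)


@pytest.fixture
def pair_system():
    """One receptor atom at the origin, one ligand bead, position per frame."""
    topo = make_topology(
        [
            ("CA", "C", 172, "LEU", "A", "protein"),
            ("c1", "C", 901, "LIG", "L", "ligand"),
        ]
    )

    def build(distances, spacing_ns=0.1):
        frames = np.zeros((len(distances), 2, 3))
        frames[:, 1, 0] = distances
        return Trajectory(topo, frames, np.arange(len(distances)) * spacing_ns)

    return topo, build


@pytest.fixture
def groove_spec():
    return SyntheticSystemSpec(chains=(6,), n_frames=100, rng_seed=7)


@pytest.fixture
def groove_system(groove_spec):
    return build_toy_system(groove_spec)


def selection_of(topology, indices, expr="manual"):
    return AtomSelection(topology, np.asarray(indices), expr)
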