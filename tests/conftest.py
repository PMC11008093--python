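"""Shared fixtures and brute-force oracles."""

import numpy as np
import pytest

import memwrap as mw
from memwrap.state import SystemState


def brute_force_pairs(pos, box, cutoff):
    """O(N^2) minimum-image pair scan (oracle for neighbor searches)."""
    pos = np.asarray(pos, dtype=float)
    box = np.asarray(box, dtype=float)
    n = len(pos)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            if d @ d < cutoff * cutoff:
                out.add((i, j))
    return out


def brute_force_lr_edges(state, cutoff):
    """O(N^2) ligand/receptor adjacency (oracle for binding graphs)."""
    edges = set()
    for li in state.ligand_indices:
        for ri in state.receptor_indices:
            d = state.positions[li] - state.positions[ri]
            d -= state.box * np.round(d / state.box)
            if np.sqrt(d @ d) < cutoff:
                edges.add((int(li), int(ri)))
    return edges


def gas_state(n, box_edge, rng, species=None, min_sep=0.9):
    """Random non-overlapping bead gas in a cubic box (no topology)."""
    box = np.array([box_edge] * 3, dtype=float)
    pos = []
    while len(pos) < n:
        cand = rng.random(3) * box_edge
        ok = True
        for p in pos:
            d = cand - p
            d -= box * np.round(d / box)
            if d @ d < min_sep ** 2:
                ok = False
                break
        if ok:
            pos.append(cand)
    pos = np.array(pos)
    sp = (np.zeros(n, dtype=np.int64) if species is None
          else np.asarray(species, dtype=np.int64))
    return SystemState(pos, np.zeros((n, 3)), sp, box,
                       np.empty((0, 2)), np.empty(0), np.empty((0, 3)))


@pytest.fixture(scope="session")
def ff_pair():
    return mw.ForceField.default(lr_mode="pair")


@pytest.fixture(scope="session")
def ff_bond():
    return mw.ForceField.default(lr_mode="bond")


@pytest.fixture()
def small_membrane():
    state = mw.build_membrane(
        mw.MembraneSpec(n_lipids=72, receptor_fraction=0.5, seed=4))
    mw.thermalize(state, 1.0, np.random.default_rng(5))
    return state
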