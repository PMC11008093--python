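"""Valence-limited dynamic ligand-receptor bonds.

The valence-limiting scheme replaces the unrestricted ligand-receptor pair
potential with explicit bonds that are created and destroyed during the
run.  Once per timestep:

1. every live bond whose minimum-image length exceeds the rupture length
   (default ``1.5 sigma``, where the well still holds 1.25 epsilon at the
   default depth) is removed;
2. every unbound ligand/receptor pair within the formation radius
   (default ``2 sigma``) is visited in seeded random order and forms a bond
   with probability ``p_form`` (default 0.5), provided both partners are
   still below the valence cap (default 1 per ligand and per receptor).

Rupture is checked before formation, so a bond created at a separation in
``(r_break, r_form]`` survives until at least the next step's check.  The
random visiting order means no spatial bias decides which receptor wins a
contested ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .forcefield import LigandReceptorParams
from .state import SystemState

__all__ = ["BondEvent", "BondEventLog", "update_bonds", "binding_graph"]


@dataclass(frozen=True)
class BondEvent:
    """One bond creation or rupture."""

    time: float
    ligand: int
    receptor: int
    event: str          # "formed" | "broken"
    separation: float


@dataclass
class BondEventLog:
    """Chronological record of all bond events in a run."""

    events: List[BondEvent] = field(default_factory=list)

    def append(self, ev: BondEvent) -> None:
        self.events.append(ev)

    def count(self, kind: str) -> int:
        return sum(1 for ev in self.events if ev.event == kind)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tligand\treceptor\tevent\tr\n")
            for ev in self.events:
                fh.write(f"{ev.time:.6g}\t{ev.ligand}\t{ev.receptor}\t"
                         f"{ev.event}\t{ev.separation:.6g}\n")

    def __len__(self) -> int:
        return len(self.events)


def _candidate_pairs_kdtree(state: SystemState, r_form: float):
    """All ligand/receptor-head index pairs within ``r_form`` (KD-tree)."""
    lig = state.ligand_indices
    rec = state.receptor_indices
    if lig.size == 0 or rec.size == 0:
        return (np.empty(0, dtype=np.int64),) * 2
    box = state.box
    pl = state.positions[lig] % box
    pr = state.positions[rec] % box
    tl = cKDTree(pl, boxsize=box)
    tr = cKDTree(pr, boxsize=box)
    pairs = tl.query_ball_tree(tr, r_form)
    li, ri = [], []
    for a, partners in enumerate(pairs):
        for b in partners:
            li.append(lig[a])
            ri.append(rec[b])
    return np.asarray(li, dtype=np.int64), np.asarray(ri, dtype=np.int64)


def update_bonds(
    state: SystemState,
    p: LigandReceptorParams,
    rng: np.random.Generator,
    candidates: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    log: Optional[BondEventLog] = None,
) -> int:
    """One per-timestep bond update (rupture, then stochastic formation).

    ``candidates`` may supply precomputed ligand/receptor index pairs known
    to include every pair within ``p.r_form`` (e.g. from the engine's
    neighbor list); if omitted they are found with a KD-tree query.
    Mutates ``state.dyn_lig``/``state.dyn_rec`` and returns the net change
    in the number of live bonds.  Events are appended to ``log`` if given.
    """
    pos = state.positions
    box = state.box
    n = state.n_beads
    changed = 0

    # rupture pass
    if state.n_dynamic_bonds:
        d = _kernels.pair_distances(pos, box, state.dyn_lig, state.dyn_rec)
        broken = d > p.r_break
        if np.any(broken):
            if log is not None:
                for k in np.flatnonzero(broken):
                    log.append(BondEvent(state.time, int(state.dyn_lig[k]),
                                         int(state.dyn_rec[k]), "broken",
                                         float(d[k])))
            changed -= int(np.count_nonzero(broken))
            keep = ~broken
            state.dyn_lig = state.dyn_lig[keep]
            state.dyn_rec = state.dyn_rec[keep]

    # formation pass
    if candidates is None:
        cl, cr = _candidate_pairs_kdtree(state, p.r_form)
    else:
        cl, cr = candidates
    if cl.size:
        d = _kernels.pair_distances(pos, box, cl, cr)
        live_keys = np.sort(state.dyn_lig * n + state.dyn_rec)
        idx = _kernels.candidate_filter(d, p.r_form, cl, cr, live_keys, n)
        if idx.size:
            order = rng.permutation(idx.size)
            idx = idx[order]
            lig_count = np.zeros(n, dtype=np.int64)
            rec_count = np.zeros(n, dtype=np.int64)
            np.add.at(lig_count, state.dyn_lig, 1)
            np.add.at(rec_count, state.dyn_rec, 1)
            u = rng.random(idx.size)
            acc = _kernels.form_bonds(cl[idx], cr[idx], u, p.p_form,
                                      lig_count, rec_count, p.valence_cap)
            if acc.size:
                new_l = cl[idx[acc]]
                new_r = cr[idx[acc]]
                if log is not None:
                    for k in range(acc.size):
                        log.append(BondEvent(state.time, int(new_l[k]),
                                             int(new_r[k]), "formed",
                                             float(d[idx[acc[k]]])))
                state.dyn_lig = np.concatenate([state.dyn_lig, new_l])
                state.dyn_rec = np.concatenate([state.dyn_rec, new_r])
                changed += int(acc.size)
    return changed


def binding_graph(
    state: SystemState,
    p: LigandReceptorParams,
    criterion: Optional[str] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Bipartite ligand-receptor binding edges of a frame.

    ``criterion`` defaults to the coupling mode of ``p``: in bond mode the
    live bond set is returned; in pair (distance) mode all ligand/receptor
    pairs with minimum-image separation below the interaction support
    ``r_c_LR + w_c_LR`` are returned.  Edges are parallel arrays of bead
    indices (ligand, receptor).
    """
    if criterion is None:
        criterion = p.mode
    if criterion == "bond":
        return state.dyn_lig.copy(), state.dyn_rec.copy()
    if criterion != "pair":
        raise ValueError(f"unknown binding criterion {criterion!r}")
    return _candidate_pairs_kdtree(state, p.r_cut)


def check_valence_cap(state: SystemState, cap: int) -> bool:
    """True if no ligand or receptor exceeds ``cap`` simultaneous bonds."""
    if state.n_dynamic_bonds == 0:
        return True
    _, cl = np.unique(state.dyn_lig, return_counts=True)
    _, cr = np.unique(state.dyn_rec, return_counts=True)
    return bool(cl.max(initial=0) <= cap and cr.max(initial=0) <= cap)
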