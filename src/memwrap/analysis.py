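"""Measurements: valency, wrapping time, percent error, membrane observables.

The central observable is the ligand valency X: the number of receptors
simultaneously bound to one ligand.  A frame's mean valency is the number
of binding edges divided by the total ligand count, and the reported X is
the unweighted average of frame means over the window starting 100 tau
after the nanoparticle is completely wrapped (so the value describes the
equilibrated, fully wrapped particle).

Wrapping is detected operationally: the first time the bound-ligand
fraction reaches a threshold (default 0.95) and stays there for a dwell
time (default 10 tau).  The wrapping-time discrepancy between the
unrestricted pair-potential scheme (NV, no valence limit) and the
valence-limited bond scheme (IV, imposed valency 1) is summarized as

    percent error = 100 * (T_u^NV - T_u^IV) / T_u^IV .
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .bond_dynamics import binding_graph
from .forcefield import LigandReceptorParams
from .state import SystemState

__all__ = [
    "ValencyTimeSeries", "WrappingReport", "ligand_valency",
    "valency_series", "time_averaged_valency", "wrapping_time",
    "percent_error", "valency_from_energy", "area_per_lipid",
    "predicted_box_edge",
]

NOT_WRAPPED = float("nan")

#: post-wrap equilibration discarded before averaging valency (tau)
DEFAULT_EQUILIBRATION = 100.0


@dataclass
class ValencyTimeSeries:
    """Per-frame ligand binding statistics of one run."""

    time: np.ndarray              # frame times (tau)
    counts: np.ndarray            # (n_frames, n_ligands) receptors per ligand

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts)

    @property
    def frame_mean(self) -> np.ndarray:
        """Mean receptors per ligand of each frame (edges / N_L)."""
        return self.counts.mean(axis=1)

    @property
    def bound_fraction(self) -> np.ndarray:
        """Fraction of ligands with at least one bound receptor, per frame."""
        return (self.counts > 0).mean(axis=1)


def ligand_valency(state: SystemState, p: LigandReceptorParams,
                   criterion: Optional[str] = None):
    """Per-ligand receptor counts and their mean for a single frame."""
    lig = state.ligand_indices
    if lig.size == 0:
        raise ValueError("frame contains no ligands")
    el, _ = binding_graph(state, p, criterion)
    pos_in_lig = np.full(state.n_beads, -1, dtype=np.int64)
    pos_in_lig[lig] = np.arange(lig.size)
    counts = np.zeros(lig.size, dtype=np.int64)
    if el.size:
        np.add.at(counts, pos_in_lig[el], 1)
    return counts, float(counts.mean())


def valency_series(sampler) -> ValencyTimeSeries:
    """Package a :class:`~memwrap.observers.ValencySampler` into a series."""
    if not sampler.time:
        raise ValueError("sampler holds no frames")
    return ValencyTimeSeries(np.asarray(sampler.time),
                             np.vstack(sampler.counts))


def time_averaged_valency(series: ValencyTimeSeries, wrap_time: float,
                          equilibration: float = DEFAULT_EQUILIBRATION) -> float:
    """Window-averaged valency X after wrapping plus an equilibration time.

    The unweighted mean of frame means over all frames with
    ``t >= wrap_time + equilibration``; raises if the trajectory does not
    extend past that point.
    """
    t0 = wrap_time + equilibration
    mask = series.time >= t0
    if not np.any(mask):
        raise ValueError(
            f"no frames at t >= {t0:.1f} tau; trajectory too short for the "
            "post-wrap averaging window")
    return float(series.frame_mean[mask].mean())


def wrapping_time(series: ValencyTimeSeries, threshold: float = 0.95,
                  dwell: float = 10.0) -> float:
    """First time the bound-ligand fraction reaches and holds the threshold.

    The fraction must stay at or above ``threshold`` for every sampled
    frame within ``dwell`` tau.  Returns NaN if the system never wraps
    (callers must check with :func:`numpy.isnan`; unwrapped runs are never
    silently averaged).
    """
    frac = series.bound_fraction
    t = series.time
    above = frac >= threshold
    for k in np.flatnonzero(above):
        window = (t >= t[k]) & (t <= t[k] + dwell)
        if np.all(above[window]):
            return float(t[k])
    return NOT_WRAPPED


def percent_error(tu_nv: float, tu_iv: float) -> float:
    """Wrapping-time percent error of the valence-unlimited scheme.

    ``100 * (T_u^NV - T_u^IV) / T_u^IV``; positive when the unrestricted
    pair potential wraps more slowly than the valence-limited reference.
    """
    if not tu_iv > 0:
        raise ValueError("reference wrapping time must be positive")
    return 100.0 * (tu_nv - tu_iv) / tu_iv


@dataclass
class WrappingReport:
    """Wrapping times of matched replicate pairs and their percent errors.

    ``tu_nv``/``tu_iv`` are per-replicate wrapping times of the
    valence-unlimited and imposed-valence runs.  Replicates in which either
    run failed to wrap are flagged and excluded from the mean, never
    silently averaged.
    """

    tu_nv: List[float] = field(default_factory=list)
    tu_iv: List[float] = field(default_factory=list)

    def add(self, tu_nv: float, tu_iv: float) -> None:
        self.tu_nv.append(tu_nv)
        self.tu_iv.append(tu_iv)

    @property
    def wrapped_mask(self) -> np.ndarray:
        a = np.asarray(self.tu_nv)
        b = np.asarray(self.tu_iv)
        return ~(np.isnan(a) | np.isnan(b))

    @property
    def n_unwrapped(self) -> int:
        return int(np.count_nonzero(~self.wrapped_mask))

    def percent_errors(self) -> np.ndarray:
        m = self.wrapped_mask
        a = np.asarray(self.tu_nv)[m]
        b = np.asarray(self.tu_iv)[m]
        return np.array([percent_error(x, y) for x, y in zip(a, b)])

    def summary(self) -> dict:
        pe = self.percent_errors()
        return {
            "n_replicates": len(self.tu_nv),
            "n_unwrapped": self.n_unwrapped,
            "mean_percent_error": float(pe.mean()) if pe.size else float("nan"),
            "std_percent_error": float(pe.std(ddof=1)) if pe.size > 1 else 0.0,
        }


def valency_from_energy(u_pair: float, u_bond: float, eps_lr: float,
                        n_ligands: int) -> float:
    """Energy-difference valency diagnostic.

    For two otherwise identical fully wrapped systems, the potential-energy
    difference divided by the total well depth approximates how many extra
    full-depth receptors each ligand holds in the pair-potential run; the
    +1 accounts for the one bond per ligand the valence-limited system
    itself has.  A coarse diagnostic, not a ground-truth measurement.
    """
    if n_ligands <= 0:
        raise ValueError("n_ligands must be positive")
    if eps_lr == 0:
        raise ValueError("eps_lr must be nonzero")
    return (u_bond - u_pair) / (eps_lr * n_ligands) + 1.0


def area_per_lipid(lx, ly, n_lipids: int, window: Optional[slice] = None) -> float:
    """Mean projected area per lipid, ``<Lx*Ly> / (n_lipids/2)``."""
    lx = np.asarray(lx, dtype=float)
    ly = np.asarray(ly, dtype=float)
    if window is not None:
        lx = lx[window]
        ly = ly[window]
    return float(np.mean(lx * ly) / (n_lipids / 2))


def predicted_box_edge(apl: float, n_lipids: int) -> float:
    """Equilibrated edge of a square membrane of ``n_lipids`` at that area."""
    return float(np.sqrt(apl * n_lipids / 2))
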