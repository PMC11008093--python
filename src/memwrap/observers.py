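"""Observer hooks collected during a run (thermo, valency, trajectory)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from . import _kernels
from .lammps_io import write_xyz_frame

__all__ = ["ThermoLog", "ValencySampler", "TrajectoryRecorder", "XYZWriter"]


@dataclass
class ThermoLog:
    """Samples time, temperature, energies, lateral pressure and box edge."""

    interval: int = 100
    time: List[float] = field(default_factory=list)
    temperature: List[float] = field(default_factory=list)
    potential: List[float] = field(default_factory=list)
    kinetic: List[float] = field(default_factory=list)
    lateral_pressure: List[float] = field(default_factory=list)
    lx: List[float] = field(default_factory=list)
    ly: List[float] = field(default_factory=list)

    def __call__(self, sim) -> None:
        self.time.append(sim.state.time)
        self.temperature.append(sim.temperature())
        self.potential.append(sim.potential_energy)
        self.kinetic.append(sim.kinetic_energy())
        self.lateral_pressure.append(sim.lateral_pressure())
        self.lx.append(float(sim.state.box[0]))
        self.ly.append(float(sim.state.box[1]))

    def arrays(self) -> dict:
        return {k: np.asarray(getattr(self, k)) for k in
                ("time", "temperature", "potential", "kinetic",
                 "lateral_pressure", "lx", "ly")}

    def write_tsv(self, path) -> None:
        cols = self.arrays()
        keys = list(cols)
        with open(path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for row in zip(*(cols[k] for k in keys)):
                fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")


class ValencySampler:
    """Per-frame ligand binding counts under the run's own coupling mode.

    In bond mode counts come from the live bond set; in pair mode from the
    distance criterion (separation below the interaction support), using
    the engine's ligand/receptor candidate list so sampling stays cheap.
    """

    def __init__(self, interval: int = 100):
        self.interval = interval
        self.time: List[float] = []
        self.counts: List[np.ndarray] = []
        self._lig: Optional[np.ndarray] = None

    def __call__(self, sim) -> None:
        st = sim.state
        if self._lig is None:
            self._lig = st.ligand_indices
        lig = self._lig
        counts = np.zeros(lig.size, dtype=np.int32)
        pos_in_lig = np.full(st.n_beads, -1, dtype=np.int64)
        pos_in_lig[lig] = np.arange(lig.size)
        if sim.ff.lr.mode == "bond":
            np.add.at(counts, pos_in_lig[st.dyn_lig], 1)
        else:
            cl, cr = sim._cand_l, sim._cand_r
            if cl.size:
                d = _kernels.pair_distances(st.positions, st.box, cl, cr)
                bound = cl[d < sim.ff.lr.r_cut]
                np.add.at(counts, pos_in_lig[bound], 1)
        self.time.append(st.time)
        self.counts.append(counts)

    @property
    def ligands(self) -> np.ndarray:
        return self._lig if self._lig is not None else np.empty(0, np.int64)


@dataclass
class TrajectoryRecorder:
    """Keeps (time, positions, box) frames in memory."""

    interval: int = 1000
    time: List[float] = field(default_factory=list)
    positions: List[np.ndarray] = field(default_factory=list)
    box: List[np.ndarray] = field(default_factory=list)

    def __call__(self, sim) -> None:
        self.time.append(sim.state.time)
        self.positions.append(sim.state.positions.copy())
        self.box.append(sim.state.box.copy())

    def __len__(self) -> int:
        return len(self.time)


class XYZWriter:
    """Streams frames to an XYZ trajectory file."""

    def __init__(self, path, interval: int = 1000):
        self.interval = interval
        self._fh = open(path, "w")

    def __call__(self, sim) -> None:
        write_xyz_frame(self._fh, sim.state)

    def close(self) -> None:
        self._fh.close()
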