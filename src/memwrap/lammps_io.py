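"""Readers and writers for engine-standard text formats.

Built systems can be exported as a LAMMPS data file (atoms, bonds, angles,
masses, box) so they can also be run in the reference MD engine, and read
back for cross-validation.  Trajectories are written as XYZ or LAMMPS-dump
text.
"""

from __future__ import annotations

import numpy as np

from .species import SPECIES_SYMBOLS
from .state import SystemState

__all__ = ["write_data_file", "read_data_file", "write_xyz_frame",
           "write_dump_frame"]


def write_data_file(path, state: SystemState, comment: str = "memwrap system"):
    """Write the full topology in LAMMPS data format (atom_style angle).

    Species are mapped to atom types 1..5; bead masses are taken from the
    state (all 1 m by default).  Molecule ids group the three beads of each
    lipid; every nanoparticle bead shares one molecule id.
    """
    n = state.n_beads
    nb = len(state.bonds)
    na = len(state.angles)
    mol = np.zeros(n, dtype=int)
    for lip in range(state.n_lipids):
        mol[3 * lip:3 * lip + 3] = lip + 1
    if state.body is not None:
        mol[state.body.indices] = state.n_lipids + 1

    lines = [f"# {comment}", ""]
    lines.append(f"{n} atoms")
    lines.append(f"{nb} bonds")
    lines.append(f"{na} angles")
    lines.append("")
    lines.append("5 atom types")
    lines.append("2 bond types")
    lines.append("1 angle types")
    lines.append("")
    lines.append(f"0.0 {state.box[0]:.10g} xlo xhi")
    lines.append(f"0.0 {state.box[1]:.10g} ylo yhi")
    lines.append(f"0.0 {state.box[2]:.10g} zlo zhi")
    lines.append("")
    lines.append("Masses")
    lines.append("")
    for t in range(5):
        m = state.masses[state.species == t]
        lines.append(f"{t + 1} {m[0] if m.size else 1.0:.10g}")
    lines.append("")
    lines.append("Atoms")
    lines.append("")
    for i in range(n):
        x, y, z = state.positions[i]
        lines.append(f"{i + 1} {mol[i]} {state.species[i] + 1} "
                     f"{x:.10g} {y:.10g} {z:.10g}")
    if nb:
        lines.append("")
        lines.append("Bonds")
        lines.append("")
        for k, (i, j) in enumerate(state.bonds):
            lines.append(f"{k + 1} {state.bond_types[k] + 1} {i + 1} {j + 1}")
    if na:
        lines.append("")
        lines.append("Angles")
        lines.append("")
        for k, (i, j, l) in enumerate(state.angles):
            lines.append(f"{k + 1} 1 {i + 1} {j + 1} {l + 1}")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_data_file(path) -> SystemState:
    """Read a data file written by :func:`write_data_file`.

    Restores positions, species, box and static topology (rigid-body and
    dynamic-bond information is not part of the format).
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    header = {}
    box = np.zeros(3)
    section = None
    atoms = {}
    bonds = []
    angles = []
    masses_by_type = {}
    for line in raw:
        stripped = line.split("#")[0].strip()
        if not stripped:
            continue
        toks = stripped.split()
        if toks[-1] in ("atoms", "bonds", "angles") and len(toks) == 2:
            header[toks[-1]] = int(toks[0])
            continue
        if stripped.endswith(("xlo xhi", "ylo yhi", "zlo zhi")):
            axis = {"xlo": 0, "ylo": 1, "zlo": 2}[toks[2]]
            box[axis] = float(toks[1]) - float(toks[0])
            continue
        if stripped.endswith("types"):
            continue
        if stripped in ("Masses", "Atoms", "Bonds", "Angles", "Velocities"):
            section = stripped
            continue
        if section == "Masses":
            masses_by_type[int(toks[0])] = float(toks[1])
        elif section == "Atoms":
            i = int(toks[0])
            atoms[i] = (int(toks[2]) - 1,
                        (float(toks[3]), float(toks[4]), float(toks[5])))
        elif section == "Bonds":
            bonds.append((int(toks[1]) - 1, int(toks[2]) - 1, int(toks[3]) - 1))
        elif section == "Angles":
            angles.append((int(toks[2]) - 1, int(toks[3]) - 1, int(toks[4]) - 1))

    n = header["atoms"]
    pos = np.empty((n, 3))
    species = np.empty(n, dtype=np.int64)
    for i in range(1, n + 1):
        sp, xyz = atoms[i]
        species[i - 1] = sp
        pos[i - 1] = xyz
    bonds_arr = np.array([(i, j) for _, i, j in bonds], dtype=np.int64).reshape(-1, 2)
    btypes = np.array([t for t, _, _ in bonds], dtype=np.int64)
    angles_arr = np.array(angles, dtype=np.int64).reshape(-1, 3)
    masses = np.array([masses_by_type.get(int(s) + 1, 1.0) for s in species])
    n_lipids = len(angles)
    return SystemState(pos, np.zeros((n, 3)), species, box, bonds_arr, btypes,
                       angles_arr, masses, n_lipids=n_lipids)


def write_xyz_frame(fh, state: SystemState, comment: str = ""):
    """Append one frame in extended-XYZ form (species letter + coordinates)."""
    fh.write(f"{state.n_beads}\n")
    fh.write(f"t={state.time:.4f} box={state.box[0]:.6g},"
             f"{state.box[1]:.6g},{state.box[2]:.6g} {comment}\n")
    for sp, (x, y, z) in zip(state.species, state.positions):
        fh.write(f"{SPECIES_SYMBOLS[int(sp)]} {x:.6f} {y:.6f} {z:.6f}\n")


def write_dump_frame(fh, state: SystemState, timestep: int):
    """Append one frame in LAMMPS dump (id type x y z) text format."""
    fh.write("ITEM: TIMESTEP\n")
    fh.write(f"{timestep}\n")
    fh.write("ITEM: NUMBER OF ATOMS\n")
    fh.write(f"{state.n_beads}\n")
    fh.write("ITEM: BOX BOUNDS pp pp pp\n")
    for k in range(3):
        fh.write(f"0.0 {state.box[k]:.10g}\n")
    fh.write("ITEM: ATOMS id type x y z\n")
    for i, (sp, (x, y, z)) in enumerate(zip(state.species, state.positions)):
        fh.write(f"{i + 1} {int(sp) + 1} {x:.6f} {y:.6f} {z:.6f}\n")
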