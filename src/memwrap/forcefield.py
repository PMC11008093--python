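"""Interaction potentials of the coarse-grained membrane / nanoparticle model.

The model is the three-bead implicit-solvent lipid of Cooke and Deserno:
one head bead and two tail beads per lipid, connected by FENE bonds and
straightened by a harmonic angle.  Excluded volume between all beads is a
WCA (purely repulsive, truncated-shifted Lennard-Jones) potential; bilayer
cohesion comes from a broad cosine-squared attraction between tail beads.
Ligand-receptor adhesion reuses the same cosine-squared form, scaled to a
much shorter range (width ``0.45 sigma``) and, by default, a well depth of
``20 epsilon``.

Every potential is provided as an energy/force pair of closed-form
functions plus parameter dataclasses, and the ligand-receptor potential can
be exported as a tabulated bond (r, U, F) table in the text format used by
standard MD engines.

Units are reduced throughout: energies in epsilon, lengths in sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .species import HEAD, LIGAND, N_SPECIES, NP_SURFACE, RECEPTOR_HEAD, TAIL

__all__ = [
    "WCAParams",
    "FENEParams",
    "AngleParams",
    "CosineAttractionParams",
    "LigandReceptorParams",
    "ForceField",
    "wca_energy",
    "wca_force",
    "fene_energy",
    "fene_force",
    "angle_energy",
    "cosine_attraction_energy",
    "cosine_attraction_force",
    "ligand_receptor_energy",
    "ligand_receptor_force",
    "tabulate_bond_potential",
    "write_lammps_table",
    "OverstretchedBondError",
]

#: WCA cutoff factor: the potential is truncated at its minimum, 2^(1/6) b.
WCA_CUT = 2.0 ** (1.0 / 6.0)


class OverstretchedBondError(RuntimeError):
    """A FENE bond reached or exceeded its maximum extension R0."""


def _as_array(r):
    arr = np.asarray(r, dtype=float)
    return arr, arr.ndim == 0


def _maybe_scalar(out, scalar):
    return float(out) if scalar else out


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WCAParams:
    """Purely repulsive excluded-volume interaction.

    ``b`` sets the effective bead diameter; the cutoff is pinned to the
    potential minimum ``r_c = 2^(1/6) b`` so energy and force vanish
    continuously there.
    """

    epsilon: float = 1.0
    b: float = 1.0

    @property
    def r_c(self) -> float:
        return WCA_CUT * self.b


@dataclass(frozen=True)
class FENEParams:
    """Finitely extensible nonlinear elastic bond.

    The attractive logarithmic branch diverges at the maximum extension
    ``R0``; short-range repulsion is the WCA term folded into the bond, as
    in the standard MD-engine convention for FENE bonds.
    """

    K1: float = 30.0
    R0: float = 1.5
    wca: WCAParams = field(default_factory=WCAParams)


@dataclass(frozen=True)
class AngleParams:
    """Harmonic angle ``U = K2 (theta - theta0)^2`` (K2 in epsilon/rad^2)."""

    K2: float = 10.0
    theta0: float = math.pi


@dataclass(frozen=True)
class CosineAttractionParams:
    """Broad cosine-squared attraction.

    Flat at depth ``-epsilon`` up to ``r_c``, decaying smoothly to zero at
    ``r_c + w_c``.  The width ``w_c`` tunes membrane fluidity at fixed
    temperature.
    """

    epsilon: float = 1.0
    r_c: float = WCA_CUT
    w_c: float = 1.5

    def __post_init__(self):
        if self.w_c <= 0:
            raise ValueError(f"cosine attraction width must be positive, got {self.w_c}")

    @property
    def r_cut(self) -> float:
        """Outer cutoff ``r_c + w_c`` (support of the interaction)."""
        return self.r_c + self.w_c


@dataclass(frozen=True)
class LigandReceptorParams:
    """Ligand-receptor coupling: shared potential, two coupling modes.

    The potential is a short-ranged cosine-squared well (onset at the WCA
    minimum ``2^(1/6) sigma``, width ``0.45 sigma``, default depth
    ``20 epsilon``).  In ``pair`` mode it acts between every
    ligand/receptor-head pair, so nothing limits how many receptors
    crowd one ligand.  In ``bond`` mode the identical potential is applied
    only through explicit bonds that form stochastically (probability
    ``p_form`` per step once a free pair comes within ``r_form``) and
    rupture when stretched beyond ``r_break``; at the default depth the
    energy still stored at rupture is 1.25 epsilon.  ``valence_cap`` bounds
    the simultaneous bonds per ligand and per receptor.
    """

    epsilon_LR: float = 20.0
    r_c_LR: float = WCA_CUT
    w_c_LR: float = 0.45
    r_form: float = 2.0
    p_form: float = 0.5
    r_break: float = 1.5
    valence_cap: int = 1
    mode: str = "pair"

    def __post_init__(self):
        if self.mode not in ("pair", "bond"):
            raise ValueError(f"mode must be 'pair' or 'bond', got {self.mode!r}")
        if self.r_break >= self.r_form:
            raise ValueError("rupture length must be below the formation search radius")
        if self.valence_cap < 1:
            raise ValueError("valence_cap must be at least 1")

    @property
    def r_cut(self) -> float:
        """Support of the attraction, ``r_c_LR + w_c_LR``."""
        return self.r_c_LR + self.w_c_LR

    def as_cosine(self) -> CosineAttractionParams:
        return CosineAttractionParams(self.epsilon_LR, self.r_c_LR, self.w_c_LR)


# ---------------------------------------------------------------------------
# closed-form energies and forces
# ---------------------------------------------------------------------------

def wca_energy(r, p: WCAParams):
    """WCA energy: ``4 eps [(b/r)^12 - (b/r)^6] + eps`` below ``r_c``, else 0."""
    arr, scalar = _as_array(r)
    if np.any(arr <= 0):
        raise ValueError("WCA energy undefined for nonpositive separation")
    sr6 = (p.b / arr) ** 6
    u = 4.0 * p.epsilon * (sr6 * sr6 - sr6) + p.epsilon
    out = np.where(arr < p.r_c, u, 0.0)
    return _maybe_scalar(out, scalar)


def wca_force(r, p: WCAParams):
    """Radial force ``F = -dU/dr`` of the WCA potential (positive = repulsive)."""
    arr, scalar = _as_array(r)
    if np.any(arr <= 0):
        raise ValueError("WCA force undefined for nonpositive separation")
    sr6 = (p.b / arr) ** 6
    f = 24.0 * p.epsilon * (2.0 * sr6 * sr6 - sr6) / arr
    out = np.where(arr < p.r_c, f, 0.0)
    return _maybe_scalar(out, scalar)


def fene_energy(r, p: FENEParams):
    """FENE bond energy: log branch plus the folded-in WCA repulsion.

    Raises :class:`OverstretchedBondError` at or beyond ``R0``.
    """
    arr, scalar = _as_array(r)
    if np.any(arr <= 0):
        raise ValueError("FENE energy undefined for nonpositive separation")
    if np.any(arr >= p.R0):
        raise OverstretchedBondError(
            f"bond length {np.max(arr):.4f} sigma >= maximum extension {p.R0} sigma"
        )
    x = (arr / p.R0) ** 2
    u = -0.5 * p.K1 * p.R0 ** 2 * np.log(1.0 - x)
    u = u + wca_energy(arr, p.wca)
    return _maybe_scalar(u, scalar)


def fene_force(r, p: FENEParams):
    """Radial force of the FENE bond (negative = restoring pull)."""
    arr, scalar = _as_array(r)
    if np.any(arr <= 0):
        raise ValueError("FENE force undefined for nonpositive separation")
    if np.any(arr >= p.R0):
        raise OverstretchedBondError(
            f"bond length {np.max(arr):.4f} sigma >= maximum extension {p.R0} sigma"
        )
    x = (arr / p.R0) ** 2
    f = -p.K1 * arr / (1.0 - x)
    f = f + wca_force(arr, p.wca)
    return _maybe_scalar(f, scalar)


def angle_energy(theta, p: AngleParams):
    """Harmonic angle energy ``K2 (theta - theta0)^2``."""
    arr, scalar = _as_array(theta)
    out = p.K2 * (arr - p.theta0) ** 2
    return _maybe_scalar(out, scalar)


def cosine_attraction_energy(r, p: CosineAttractionParams):
    """Cosine-squared attraction: ``-eps`` plateau, smooth decay over ``w_c``."""
    arr, scalar = _as_array(r)
    if np.any(arr <= 0):
        raise ValueError("cosine attraction undefined for nonpositive separation")
    z = np.pi * (arr - p.r_c) / (2.0 * p.w_c)
    decay = -p.epsilon * np.cos(np.clip(z, 0.0, np.pi / 2)) ** 2
    out = np.where(arr <= p.r_c, -p.epsilon, np.where(arr < p.r_cut, decay, 0.0))
    return _maybe_scalar(out, scalar)


def cosine_attraction_force(r, p: CosineAttractionParams):
    """Radial force of the cosine attraction (negative = attractive pull)."""
    arr, scalar = _as_array(r)
    if np.any(arr <= 0):
        raise ValueError("cosine attraction undefined for nonpositive separation")
    z = np.pi * (arr - p.r_c) / (2.0 * p.w_c)
    f = -p.epsilon * np.pi * np.sin(2.0 * np.clip(z, 0.0, np.pi / 2)) / (2.0 * p.w_c)
    out = np.where((arr > p.r_c) & (arr < p.r_cut), f, 0.0)
    return _maybe_scalar(out, scalar)


def ligand_receptor_energy(r, p: LigandReceptorParams):
    """Ligand-receptor energy; the same function serves pair and bond mode."""
    return cosine_attraction_energy(r, p.as_cosine())


def ligand_receptor_force(r, p: LigandReceptorParams):
    """Radial ligand-receptor force; identical in pair and bond mode."""
    return cosine_attraction_force(r, p.as_cosine())


# ---------------------------------------------------------------------------
# tabulation
# ---------------------------------------------------------------------------

def tabulate_bond_potential(p: LigandReceptorParams, n_points: int = 2000):
    """Tabulate the ligand-receptor potential on an even grid over (0, r_form].

    Returns ``(r, U, F)`` arrays with the force from the analytic
    derivative (not a finite difference).  Beyond the support of the
    attraction the bond contributes zero energy and force, so a bond
    created near the formation radius exerts nothing until it shortens
    into range.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    r = np.linspace(p.r_form / n_points, p.r_form, n_points)
    u = np.asarray(ligand_receptor_energy(r, p))
    f = np.asarray(ligand_receptor_force(r, p))
    return r, u, f


def write_lammps_table(path, r, u, f, keyword: str = "LR_BOND", comment: str = "",
                       pair_style: bool = False):
    """Write an (index, r, energy, force) table in the MD-engine text format.

    With ``pair_style=True`` the header's ``N`` line carries the ``R lo hi``
    range annotation used by tabulated pair styles; otherwise the plain bond
    table header is written.
    """
    r = np.asarray(r)
    n = r.size
    lines = []
    if comment:
        lines.append(f"# {comment}")
    lines.append(f"{keyword}")
    if pair_style:
        lines.append(f"N {n} R {r[0]:.10g} {r[-1]:.10g}")
    else:
        lines.append(f"N {n}")
    lines.append("")
    for i in range(n):
        lines.append(f"{i + 1} {r[i]:.10g} {u[i]:.10g} {f[i]:.10g}")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# assembled force field
# ---------------------------------------------------------------------------

#: static bond types
BOND_HEAD_TAIL = 0
BOND_TAIL_TAIL = 1


@dataclass(frozen=True)
class ForceField:
    """All interaction parameters of the membrane + nanoparticle system.

    Excluded volume: WCA with ``b = 0.95 sigma`` for every pair except
    tail-tail, which uses ``b = 1.0 sigma`` (the original head/tail sizing
    that yields a tension-free flat bilayer).  Nanoparticle surface beads
    (plain and ligand) repel everything with the same ``b = 0.95 sigma``.
    Tail-tail pairs additionally attract through the broad cosine well.
    Ligand/receptor-head pairs attract via the scaled cosine well when the
    coupling mode is ``pair``; in ``bond`` mode the identical potential acts
    only through explicit dynamic bonds.
    """

    b_head: float = 0.95
    b_tail: float = 1.0
    wca_epsilon: float = 1.0
    tail_attraction: CosineAttractionParams = field(
        default_factory=lambda: CosineAttractionParams(1.0, WCA_CUT * 1.0, 1.5))
    fene_head_tail: FENEParams = field(
        default_factory=lambda: FENEParams(30.0, 1.5, WCAParams(1.0, 0.95)))
    fene_tail_tail: FENEParams = field(
        default_factory=lambda: FENEParams(30.0, 1.5, WCAParams(1.0, 1.0)))
    angle: AngleParams = field(default_factory=AngleParams)
    lr: LigandReceptorParams = field(default_factory=LigandReceptorParams)

    @classmethod
    def default(cls, lr_mode: str = "pair", epsilon_LR: float = 20.0,
                w_c: float = 1.5) -> "ForceField":
        """Standard parameterization with a chosen coupling mode and depth."""
        return cls(
            tail_attraction=CosineAttractionParams(1.0, WCA_CUT * 1.0, w_c),
            lr=LigandReceptorParams(epsilon_LR=epsilon_LR, mode=lr_mode),
        )

    def with_lr(self, **kwargs) -> "ForceField":
        """Copy of the force field with modified ligand-receptor parameters."""
        return replace(self, lr=replace(self.lr, **kwargs))

    @property
    def max_cutoff(self) -> float:
        """Largest interaction/search radius (sets the neighbor-list cutoff)."""
        return max(self.tail_attraction.r_cut, self.lr.r_cut, self.lr.r_form,
                   WCA_CUT * max(self.b_head, self.b_tail))

    def wca_b_matrix(self) -> np.ndarray:
        b = np.full((N_SPECIES, N_SPECIES), self.b_head)
        b[TAIL, TAIL] = self.b_tail
        return b

    def pair_cutoffs(self) -> np.ndarray:
        """Interaction/search support per species pair (for neighbor lists).

        Tail-tail pairs need the broad attraction's support; ligand/receptor
        pairs the larger of the short attraction's support and the bond
        formation radius; every other pair only its WCA cutoff.
        """
        c = WCA_CUT * self.wca_b_matrix()
        c[TAIL, TAIL] = max(c[TAIL, TAIL], self.tail_attraction.r_cut)
        lr_reach = max(self.lr.r_cut, self.lr.r_form)
        for s1, s2 in ((RECEPTOR_HEAD, LIGAND), (LIGAND, RECEPTOR_HEAD)):
            c[s1, s2] = max(c[s1, s2], lr_reach)
        return c

    def tables(self) -> dict:
        """Dense per-species-pair parameter tables for the force kernels.

        The cosine attractions are stored as energies on a uniform r^2 grid
        together with the per-interval F/r that is the exact negative
        gradient of the interpolated energy (conservative by construction).
        """
        b = self.wca_b_matrix()
        wca_b2 = b * b
        wca_rc2 = (WCA_CUT * b) ** 2
        wca_eps = np.full((N_SPECIES, N_SPECIES), self.wca_epsilon)

        # The cosine attractions are tabulated per species pair on a uniform
        # r^2 grid (linear interpolation of U and F/r), which removes the
        # per-pair transcendentals from the force kernel.  2048 nodes keep
        # the interpolation error below ~1e-5 epsilon.
        K = 4096
        cos_rc2 = np.zeros((N_SPECIES, N_SPECIES))
        cos_scale = np.zeros((N_SPECIES, N_SPECIES))
        cos_u = np.zeros((N_SPECIES, N_SPECIES, K))
        cos_fr = np.zeros((N_SPECIES, N_SPECIES, K))
        attractions = [((TAIL, TAIL),) + (self.tail_attraction,)]
        if self.lr.mode == "pair":
            lr_cos = self.lr.as_cosine()
            attractions.append(((RECEPTOR_HEAD, LIGAND), lr_cos))
            attractions.append(((LIGAND, RECEPTOR_HEAD), lr_cos))
        for (s1, s2), cp in attractions:
            rc2 = cp.r_cut ** 2
            scale = (K - 1) / rc2
            r2 = np.arange(K) / scale
            r = np.sqrt(np.maximum(r2, 1e-20))
            u = np.asarray(cosine_attraction_energy(np.maximum(r, 1e-10), cp))
            u[-1] = 0.0
            # F/r per interval as the exact negative gradient of the
            # linear-in-r^2 energy interpolant, so the kernel forces are
            # exactly conservative
            fr = np.zeros(K)
            fr[:-1] = -2.0 * scale * np.diff(u)
            cos_rc2[s1, s2] = rc2
            cos_scale[s1, s2] = scale
            cos_u[s1, s2] = u
            cos_fr[s1, s2] = fr

        fene = (self.fene_head_tail, self.fene_tail_tail)
        return {
            "wca_eps": wca_eps, "wca_b2": wca_b2, "wca_rc2": wca_rc2,
            "cos_rc2": cos_rc2, "cos_scale": cos_scale,
            "cos_u": cos_u, "cos_fr": cos_fr,
            "fene_K": np.array([p.K1 for p in fene]),
            "fene_R0": np.array([p.R0 for p in fene]),
            "fene_eps": np.array([p.wca.epsilon for p in fene]),
            "fene_b2": np.array([p.wca.b ** 2 for p in fene]),
            "angle_K": self.angle.K2,
            "angle_theta0": self.angle.theta0,
            "lr_eps": self.lr.epsilon_LR,
            "lr_rc": self.lr.r_c_LR,
            "lr_wc": self.lr.w_c_LR,
        }
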