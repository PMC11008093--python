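"""Reduced (Lennard-Jones) units and the calibration used for reporting.

All quantities in the package are expressed in reduced units: energy in
``epsilon``, length in ``sigma``, time in ``tau`` and mass in ``m``.  The
membrane calibration adopted for reporting alongside reduced units is
``sigma = 0.9 nm`` and ``tau = 1 ns`` (obtained by matching bilayer
thickness and in-plane lipid diffusion of comparable coarse-grained
membranes).  The calibration is a convenience for presentation only; no
computation in the package depends on it.
"""

SIGMA_NM: float = 0.9
"""Length calibration: one sigma in nanometres."""

TAU_NS: float = 1.0
"""Time calibration: one tau in nanoseconds."""


def sigma_to_nm(x: float) -> float:
    """Convert a length in sigma to nanometres."""
    return x * SIGMA_NM


def nm_to_sigma(x: float) -> float:
    """Convert a length in nanometres to sigma."""
    return x / SIGMA_NM


def tau_to_ns(t: float) -> float:
    """Convert a time in tau to nanoseconds."""
    return t * TAU_NS


def ns_to_tau(t: float) -> float:
    """Convert a time in nanoseconds to tau."""
    return t / TAU_NS
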