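"""Unit conventions and physical constants.

All model energies are wavenumbers (cm^-1), times are femtoseconds unless a
function says otherwise (fitted lifetimes are reported in picoseconds).
Wavenumbers convert to angular frequency through 2*pi*c with c in cm/fs, so a
coherence at ``w`` cm^-1 evolves as ``exp(-1j * w * TWO_PI_C * t_fs)``.
"""

from __future__ import annotations

import numpy as np

#: speed of light in cm / fs
C_CM_PER_FS: float = 2.99792458e-5

#: converts cm^-1 to angular frequency in rad / fs
TWO_PI_C: float = 2.0 * np.pi * C_CM_PER_FS

#: Boltzmann constant in cm^-1 / K
KB_CM_PER_K: float = 0.695034800


def cm_to_angfs(wavenumber: float | np.ndarray) -> float | np.ndarray:
    """Convert an energy in cm^-1 to an angular frequency in rad/fs."""
    return np.asarray(wavenumber) * TWO_PI_C


def thermal_energy(temperature_k: float) -> float:
    """k_B * T in cm^-1."""
    return KB_CM_PER_K * temperature_k
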