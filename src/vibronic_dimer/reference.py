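"""Reference parameterization: the BChl 3-4 heterodimer of the FMO complex.

The two lowest-energy, relatively strongly coupled bacteriochlorophylls of
the Fenna-Matthews-Olson antenna define the canonical parameter set used
throughout: site coupling J0 = -53.5 cm^-1, site-energy gap 110 cm^-1,
optical transition at 12210 cm^-1, one 117 cm^-1 mode with Huang-Rhys factor
0.05 per pigment, Qy axes spanning 107.2 deg, an overdamped bath with
Lambda = 130 cm^-1 and lambda = 35 cm^-1 at 77 K, and Gaussian gap disorder
of 80 cm^-1 FWHM.

The dipole *vectors* are oriented at 72.8 deg (the supplement of the
107.2 deg axis angle): the orientation sign of a Qy vector is conventional,
and this choice makes the dipole inner product sign-consistent with the sign
convention of J0, i.e. the lower state of a mixed pair borrows intensity
constructively.  See docs/methods.md.
"""

from __future__ import annotations

from .bath import BathSpec
from .model import DimerSpec

SITE_ENERGY: float = 12210.0        # cm^-1
COUPLING_J0: float = -53.5          # cm^-1
GAP_DE0: float = 110.0              # cm^-1
MODE_FREQUENCY: float = 117.0       # cm^-1 (alternative studied case: 185)
HUANG_RHYS: float = 0.05
AXIS_ANGLE: float = 107.2           # deg, angle between the Qy axes
DIPOLE_VECTOR_ANGLE: float = 180.0 - AXIS_ANGLE  # deg, between dipole vectors

DISORDER_FWHM: float = 80.0         # cm^-1, Gaussian disorder of the gap
DISORDER_SAMPLES: int = 2000
DISORDER_SEED: int = 20130619


def reference_dimer(
    gap: float = GAP_DE0,
    coupling: float = COUPLING_J0,
    mode_frequency: float = MODE_FREQUENCY,
    huang_rhys: float = HUANG_RHYS,
    n_quanta: int = 1,
) -> DimerSpec:
    """The reference heterodimer, optionally with single parameters changed."""
    return DimerSpec.from_parameters(
        site_energy=SITE_ENERGY,
        gap=gap,
        coupling=coupling,
        mode_frequency=mode_frequency,
        huang_rhys=huang_rhys,
        dipole_angle=DIPOLE_VECTOR_ANGLE,
        n_quanta=n_quanta,
    )


def reference_bath() -> BathSpec:
    return BathSpec(
        debye_frequency=130.0,
        reorganization_energy=35.0,
        temperature=77.0,
        n_matsubara=100,
    )
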