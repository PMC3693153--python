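"""Non-rephasing third-order response on the diagonal of the 2D spectrum.

Only the two non-rephasing Liouville pathways that oscillate during the
population time t2 are propagated:

* R1 -- stimulated emission through an excited-state (vibronic) coherence
  rho_{alpha beta}.  On a diagonal peak the t1 and t3 optical coherences both
  evolve at the alpha line, so the signal is separable:
  ``S(w1, t2) = pref * D_alpha(w1)^2 * exp(-(i w_ab + Gamma_ab) t2)``.
* R4 -- ground-state bleach through the vibrational coherence between
  |g_0> and |g_nu> on pigment 1; both optical coherences evolve at the beta
  line and the t2 oscillation sits exactly at nu * omega0 with no decay.

``D(w)`` is the half-Fourier transform of the optical-coherence propagator
``exp(-i w_line t - p g(t))`` where p scales the bath lineshape by the squared
electronic site participations of the eigenstate (partial exchange
narrowing).  Delta-pulse (impulsive) excitation is assumed throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .bath import LineshapeTable, RateMatrix, coherence_dephasing
from .model import DimerSpec, Eigensystem, MonomerSpec, TransitionDipoleSet, dipole_prefactor, monomer_prefactor
from .units import TWO_PI_C

__all__ = [
    "PathwaySpec",
    "PathwaySignal",
    "half_fourier",
    "fourier_amplitude",
    "response_R1",
    "response_R4",
    "monomer_reference_signal",
    "peak_position_table",
    "PeakPosition",
]


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------

def half_fourier(exponent: np.ndarray, t: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """``int_0^T exp(exponent(t) + i omega t) dt`` on a sampled exponent.

    Exponential-segment (Filon-type) rule: on each interval the full complex
    exponent is taken linear, which integrates exactly; the rule is therefore
    exact to machine precision for piecewise-exponential integrands (e.g. the
    Markovian limit) and highly accurate for smooth lineshape exponents.
    ``omega`` in cm^-1; ``t`` uniform or not, in fs.

    Raises if the sampling cannot resolve the phase (Nyquist violation).
    """
    t = np.asarray(t, float)
    w = np.asarray(omega, float) * TWO_PI_C
    exponent = np.asarray(exponent, complex)
    dt = np.diff(t)
    phase_step = np.abs(
        np.imag(np.diff(exponent))[None, :] + w[:, None] * dt[None, :]
    )
    if np.any(phase_step >= np.pi):
        raise ValueError(
            "time grid too coarse to resolve the maximum oscillation frequency "
            "(phase advances by >= pi within one step)"
        )
    phi = exponent[None, :] + 1j * w[:, None] * t[None, :]
    dphi = np.diff(phi, axis=1)
    small = np.abs(dphi) < 1e-8
    safe = np.where(small, 1.0, dphi)
    ratio = np.where(small, 1.0 + dphi / 2.0, np.expm1(np.where(small, 0.0, dphi)) / safe)
    return np.sum(np.exp(phi[:, :-1]) * ratio * dt[None, :], axis=1)


def _simpson_weights(t: np.ndarray) -> np.ndarray:
    n = len(t)
    h = t[1] - t[0]
    if not np.allclose(np.diff(t), h):
        raise ValueError("uniform grid required")
    if n % 2 == 1:
        w = np.ones(n)
        w[1:-1:2], w[2:-1:2] = 4.0, 2.0
        return w * h / 3.0
    # even count: Simpson on the first n-1 points + trapezoid on the last step
    w = np.zeros(n)
    w[: n - 1] = _simpson_weights(t[: n - 1])
    w[n - 2] += h / 2.0
    w[n - 1] += h / 2.0
    return w


def fourier_amplitude(
    response: np.ndarray,
    t1: np.ndarray,
    t3: np.ndarray,
    omega1: np.ndarray,
    omega3: np.ndarray | None = None,
) -> np.ndarray:
    """Double half-Fourier transform of a sampled response R(t1, t3).

    Linear in the input (composite-Simpson quadrature against
    ``exp(i w1 t1 + i w3 t3)``); frequencies in cm^-1.  With
    ``omega3=None`` the diagonal cut omega3 = omega1 is returned as a
    1-D array; otherwise the full (omega1, omega3) map.

    The caller must supply time grids fine enough for the carrier
    frequencies present in ``response``; grids must be uniform.
    """
    r = np.asarray(response, complex)
    if r.shape != (len(t1), len(t3)):
        raise ValueError("response shape must be (len(t1), len(t3))")
    w1 = _simpson_weights(np.asarray(t1, float))
    w3 = _simpson_weights(np.asarray(t3, float))
    e1 = np.exp(1j * np.outer(np.asarray(omega1, float) * TWO_PI_C, t1)) * w1  # (n1, nt1)
    if omega3 is None:
        e3 = np.exp(1j * np.outer(np.asarray(omega1, float) * TWO_PI_C, t3)) * w3
        return np.einsum("wi,ij,wj->w", e1, r, e3)
    e3 = np.exp(1j * np.outer(np.asarray(omega3, float) * TWO_PI_C, t3)) * w3
    return e1 @ r @ e3.T


# ---------------------------------------------------------------------------
# pathway containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwaySpec:
    """Which pathway to evaluate and on which grids.

    ``pair`` holds zero-based eigenstate indices (alpha, beta); ``nu`` the
    ground-manifold vibrational index of pigment 1 involved in the optical
    transitions.  ``omega1`` is the excitation-frequency grid of the diagonal
    cut (cm^-1), ``t2`` the population-time grid (fs).
    """

    pathway: Literal["R1", "R4"]
    pair: tuple[int, int]
    omega1: np.ndarray
    t2: np.ndarray
    nu: int = 0
    dephasing_mode: str = "pair"

    def __post_init__(self) -> None:
        if self.pathway not in ("R1", "R4"):
            raise ValueError(f"unknown pathway {self.pathway!r}")


@dataclass
class PathwaySignal:
    """Complex diagonal-cut amplitude S(omega1, t2) of one Liouville pathway."""

    omega1: np.ndarray
    t2: np.ndarray
    amplitude: np.ndarray  # (n_omega1, n_t2), complex
    pathway: str
    pair: tuple[int, int]
    nu: int = 0
    disorder: str = "single"
    meta: dict = field(default_factory=dict)

    def initial_peak(self) -> tuple[float, float]:
        """(omega1 at the t2=0 amplitude maximum, that amplitude)."""
        a0 = np.abs(self.amplitude[:, 0])
        i = int(np.argmax(a0))
        return float(self.omega1[i]), float(a0[i])

    def trace(self, omega1: float | None = None) -> np.ndarray:
        """Complex t2 trace at a given omega1 (default: t2=0 peak position)."""
        if omega1 is None:
            i = int(np.argmax(np.abs(self.amplitude[:, 0])))
        else:
            i = int(np.argmin(np.abs(self.omega1 - omega1)))
        return self.amplitude[i]


def _participation_scale(eig: Eigensystem, alpha: int) -> float:
    p = eig.site_participation(alpha)
    return float(np.sum(p * p))


def _optical_line(
    eig: Eigensystem, alpha: int, table: LineshapeTable, omega1: np.ndarray
) -> np.ndarray:
    p = _participation_scale(eig, alpha)
    exponent = -1j * eig.energies[alpha] * TWO_PI_C * table.t - p * table.g
    return half_fourier(exponent, table.t, omega1)


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------

def response_R1(
    eig: Eigensystem,
    dipoles: TransitionDipoleSet,
    lineshapes: LineshapeTable,
    rates: RateMatrix,
    spec: PathwaySpec,
) -> PathwaySignal:
    """Excited-state (vibronic) coherence contribution of pathway R1.

    Diagonal peak at the alpha line; t2 oscillation at w_ab = E_a - E_b with
    relaxation-induced dephasing Gamma_ab.  With the bath removed the t2
    dependence is strictly periodic; at J = 0 the pigment-1 pathway reduces
    exactly to the monomer reference signal.
    """
    a, b = spec.pair
    if a == b:
        raise ValueError("R1 oscillatory pathway needs two distinct eigenstates")
    pref = dipole_prefactor(eig, dipoles, "R1", a, b, spec.nu)
    gamma = coherence_dephasing(rates, a, b, mode=spec.dephasing_mode)
    d = _optical_line(eig, a, lineshapes, spec.omega1)
    w_ab = (eig.energies[a] - eig.energies[b]) * TWO_PI_C
    prop = np.exp((-1j * w_ab - gamma) * np.asarray(spec.t2, float))
    return PathwaySignal(
        omega1=np.asarray(spec.omega1, float),
        t2=np.asarray(spec.t2, float),
        amplitude=pref * (d * d)[:, None] * prop[None, :],
        pathway="R1",
        pair=(a, b),
        nu=spec.nu,
        meta={"gamma_fs": gamma, "omega_ab_cm": (eig.energies[a] - eig.energies[b])},
    )


def response_R4(
    eig: Eigensystem,
    dipoles: TransitionDipoleSet,
    lineshapes: LineshapeTable,
    spec: PathwaySpec,
    mode_frequency: float,
) -> PathwaySignal:
    """Ground-state vibrational coherence contribution of pathway R4.

    Both optical coherences evolve at the beta line; during t2 the ground
    manifold holds the |g_nu><g_0| coherence, which oscillates at exactly
    nu * omega0 and does not decay (the intramolecular mode is undamped).
    """
    if spec.nu < 1:
        raise ValueError(
            "R4 carries no ground-state coherence for nu = 0; use nu >= 1"
        )
    _, b = spec.pair
    pref = dipole_prefactor(eig, dipoles, "R4", b, b, spec.nu)
    d = _optical_line(eig, b, lineshapes, spec.omega1)
    w_g = spec.nu * mode_frequency * TWO_PI_C
    prop = np.exp(-1j * w_g * np.asarray(spec.t2, float))
    return PathwaySignal(
        omega1=np.asarray(spec.omega1, float),
        t2=np.asarray(spec.t2, float),
        amplitude=pref * (d * d)[:, None] * prop[None, :],
        pathway="R4",
        pair=(b, b),
        nu=spec.nu,
        meta={"omega_t2_cm": spec.nu * mode_frequency},
    )


def monomer_reference_signal(
    monomer: MonomerSpec,
    lineshapes: LineshapeTable,
    omega1: np.ndarray,
    t2: np.ndarray,
) -> PathwaySignal:
    """Vibrational-coherence signal of the isolated pigment.

    The denominator of every enhancement ratio: pre-factor
    mu^4 FC00^2 FC01^2 (3/15), optical coherences at the 0-0 line with the
    full lineshape, non-decaying t2 oscillation at omega0.
    """
    pref = monomer_prefactor(monomer)
    if pref == 0.0:
        raise ValueError("monomer reference vanishes for S = 0")
    exponent = -1j * monomer.site_energy * TWO_PI_C * lineshapes.t - lineshapes.g
    d = half_fourier(exponent, lineshapes.t, np.asarray(omega1, float))
    # rho_{e0 e1} coherence: E_{e0} - E_{e1} = -omega0
    w0 = monomer.mode.frequency * TWO_PI_C
    prop = np.exp(1j * w0 * np.asarray(t2, float))
    return PathwaySignal(
        omega1=np.asarray(omega1, float),
        t2=np.asarray(t2, float),
        amplitude=pref * (d * d)[:, None] * prop[None, :],
        pathway="R1",
        pair=(0, 1),
        nu=0,
        meta={"monomer": True, "omega_t2_cm": monomer.mode.frequency},
    )


# ---------------------------------------------------------------------------
# peak-position bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakPosition:
    omega1: float
    omega3: float
    t2_frequency: float
    oscillating: bool
    manifold: str  # "excited" or "ground"


def peak_position_table(
    pathway: str,
    alpha: int,
    beta: int,
    nu: int,
    eig: Eigensystem,
    mode_frequency: float,
) -> PeakPosition:
    """Expected 2D peak coordinates and t2 oscillation class of a pathway.

    Bookkeeping for all four pathways (R2/R3 positions are recorded even
    though only the non-rephasing pair is propagated).  Excited-state
    pathways (R1/R2) oscillate at w_ab; ground-state pathways (R3/R4) at
    nu * omega0 and are static for nu = 0.
    """
    e = eig.energies
    w0 = mode_frequency
    w_ab = abs(float(e[alpha] - e[beta]))
    if pathway == "R1":
        return PeakPosition(float(e[alpha]), float(e[alpha] - nu * w0), w_ab,
                            alpha != beta, "excited")
    if pathway == "R2":
        return PeakPosition(float(e[beta]), float(e[alpha] - nu * w0), w_ab,
                            alpha != beta, "excited")
    if pathway == "R4":
        return PeakPosition(float(e[beta]), float(e[beta] - 0 * w0), nu * w0,
                            nu >= 1, "ground")
    if pathway == "R3":
        return PeakPosition(float(e[alpha]), float(e[beta] - nu * w0), nu * w0,
                            nu >= 1, "ground")
    raise ValueError(f"unknown pathway {pathway!r}")
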