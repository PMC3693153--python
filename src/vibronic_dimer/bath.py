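"""Overdamped Brownian oscillator bath: lineshape function and Redfield rates.

The protein environment couples linearly to the electronic excitation of each
pigment (site-diagonal coupling, statistically independent and identical
baths).  The intramolecular mode is explicitly part of the system and is not
damped by the bath, so purely vibrational coherences do not dephase.

The energy-gap correlation function is the overdamped Brownian oscillator
with Debye frequency Lambda and reorganization energy lambda; the same
correlation function provides the second-cumulant lineshape g(t) for the
optical coherences and, through its Fourier transform, the Redfield
population-transfer rates between vibronic eigenstates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import Eigensystem
from .units import KB_CM_PER_K, TWO_PI_C

__all__ = [
    "BathSpec",
    "LineshapeTable",
    "RateMatrix",
    "spectral_density",
    "lineshape_g",
    "rate_kernel",
    "redfield_rates",
    "coherence_dephasing",
]


@dataclass(frozen=True)
class BathSpec:
    """Overdamped Brownian oscillator bath parameters.

    Parameters
    ----------
    debye_frequency : float
        Inverse bath correlation time Lambda in cm^-1.
    reorganization_energy : float
        Reorganization energy lambda in cm^-1 (Stokes shift = 2 lambda).
    temperature : float
        Temperature in kelvin.
    n_matsubara : int
        Initial number of Matsubara terms in g(t); extended automatically if
        the sum has not converged.
    """

    debye_frequency: float = 130.0
    reorganization_energy: float = 35.0
    temperature: float = 77.0
    n_matsubara: int = 100

    def __post_init__(self) -> None:
        if self.debye_frequency <= 0 or self.reorganization_energy <= 0:
            raise ValueError("Lambda and lambda must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_matsubara < 1:
            raise ValueError("n_matsubara must be >= 1")

    @property
    def thermal_energy(self) -> float:
        """k_B T in cm^-1."""
        return KB_CM_PER_K * self.temperature


def spectral_density(omega: float | np.ndarray, bath: BathSpec) -> float | np.ndarray:
    """Odd spectral density C''(omega) = 2 lambda Lambda omega / (omega^2 + Lambda^2).

    ``omega`` and the returned value are in cm^-1; the maximum value, reached
    at omega = Lambda, equals lambda.
    """
    w = np.asarray(omega, float)
    lam, big = bath.reorganization_energy, bath.debye_frequency
    out = 2.0 * lam * big * w / (w * w + big * big)
    return float(out) if np.isscalar(omega) else out


def _matsubara_sum(t: np.ndarray, bath: BathSpec, n_terms: int) -> np.ndarray:
    """Matsubara part of g(t), explicit terms plus an analytic tail.

    The sum over frequencies nu_n = 2 pi n kT converges only as 1/n if
    truncated; beyond ``n_terms`` the exp(-nu t) contribution is negligible
    and the remaining (nu t - 1) part is summed in closed form with digamma
    functions, so the result is converged for any moderate truncation.
    """
    from scipy.special import digamma

    lam_r = bath.reorganization_energy * TWO_PI_C
    big_r = bath.debye_frequency * TWO_PI_C
    kt_r = bath.thermal_energy * TWO_PI_C
    c = 2.0 * np.pi * kt_r
    acc = np.zeros_like(t, dtype=float)
    for n in range(1, n_terms + 1):
        nu = c * n
        acc += (np.exp(-nu * t) + nu * t - 1.0) / (nu * (nu * nu - big_r * big_r))
    a = big_r / c
    np1 = n_terms + 1
    # sum_{n>N} 1/(nu^2 - Lambda^2) and 1/(nu (nu^2 - Lambda^2))
    s2 = (digamma(np1 + a) - digamma(np1 - a)) / (2.0 * a * c * c)
    s3 = (digamma(np1) - 0.5 * (digamma(np1 - a) + digamma(np1 + a))) / (
        a * a * c * c * c
    )
    # dropped exp(-nu t) terms: modelled as s3 * exp(-r t) with the rate
    # r = s2/s3 chosen so the correction vanishes quadratically at t = 0
    acc += t * s2 - s3 + s3 * np.exp(-(s2 / s3) * t)
    return 4.0 * lam_r * big_r * kt_r * acc


def lineshape_g(t: np.ndarray, bath: BathSpec, rtol: float = 1e-6) -> np.ndarray:
    """Second-cumulant lineshape function g(t) of the overdamped bath.

    ``t`` in fs (non-negative).  g(0) = 0, g'(0) = 0; at long times
    Re g grows linearly (homogeneous dephasing) and Im g -> -lambda * t in
    angular-frequency units.  The Matsubara series is extended automatically
    (with a warning) until the last doubling changes the result by less than
    ``rtol``.
    """
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("g(t) is evaluated for t >= 0 only")
    lam_r = bath.reorganization_energy * TWO_PI_C
    big_r = bath.debye_frequency * TWO_PI_C
    x = bath.debye_frequency / (2.0 * bath.thermal_energy)  # hbar Lambda / 2 kT
    h = np.exp(-big_r * t) + big_r * t - 1.0
    g = (lam_r / big_r) / np.tan(x) * h - 1j * (lam_r / big_r) * h
    n = bath.n_matsubara
    mats = _matsubara_sum(t, bath, n)
    for _ in range(6):
        more = _matsubara_sum(t, bath, 2 * n)
        tol = rtol * np.abs(g + more) + 1e-9
        if np.all(np.abs(more - mats) <= tol):
            mats = more
            break
        warnings.warn(
            f"Matsubara series not converged with {n} terms; extending",
            stacklevel=2,
        )
        n *= 2
        mats = more
    return g + mats


@dataclass(frozen=True)
class LineshapeTable:
    """Tabulated g(t) with its generating bath."""

    t: np.ndarray
    g: np.ndarray
    bath: BathSpec

    @classmethod
    def compute(cls, t: np.ndarray, bath: BathSpec) -> "LineshapeTable":
        return cls(t=np.asarray(t, float), g=lineshape_g(t, bath), bath=bath)


def rate_kernel(omega: float | np.ndarray, bath: BathSpec) -> float | np.ndarray:
    """Thermally weighted rate kernel C~(omega) in fs^-1.

    The full Fourier transform of the bath correlation function,
    (1 + coth(omega / 2 kT)) C''(omega), converted to fs^-1; omega in cm^-1.
    Positive omega is downhill.  The omega -> 0 limit is 4 lambda kT / Lambda.
    """
    w = np.asarray(omega, float)
    kt = bath.thermal_energy
    small = np.abs(w) < 1e-8
    ws = np.where(small, 1.0, w)
    cpp = spectral_density(ws, bath)
    out = (1.0 + 1.0 / np.tanh(ws / (2.0 * kt))) * cpp * TWO_PI_C
    limit = 4.0 * bath.reorganization_energy * kt / bath.debye_frequency * TWO_PI_C
    out = np.where(small, limit, out)
    return float(out) if np.isscalar(omega) else out


@dataclass(frozen=True)
class RateMatrix:
    """Redfield population rates and their eigenstate energies.

    ``rates[a, b]`` is the population-transfer rate a -> b in fs^-1.
    """

    rates: np.ndarray
    energies: np.ndarray

    @property
    def depopulation(self) -> np.ndarray:
        """Total depopulation rate of each eigenstate, fs^-1."""
        return self.rates.sum(axis=1)


def redfield_rates(eig: Eigensystem, bath: BathSpec) -> RateMatrix:
    """Secular Redfield population-transfer rates between vibronic eigenstates.

    The bath couples to the electronic site populations only, so the coupling
    operator of site n is the projector onto the basis states with pigment n
    excited.  k_{a->b} = sum_n |<a|K_n|b>|^2 C~(E_a - E_b); detailed balance
    k_{a->b} / k_{b->a} = exp((E_a - E_b)/kT) holds by construction.
    """
    c = eig.coefficients
    sites = np.array([b.site for b in eig.basis])
    n = eig.n_states
    k = np.zeros((n, n))
    for site in (1, 2):
        block = c[sites == site, :]
        ks = block.T @ block  # <a|K_site|b>
        k += ks * ks
    dw = eig.energies[:, None] - eig.energies[None, :]
    k = k * rate_kernel(dw, bath)
    np.fill_diagonal(k, 0.0)
    return RateMatrix(rates=k, energies=np.asarray(eig.energies, float))


def coherence_dephasing(
    rates: RateMatrix, alpha: int, beta: int, mode: str = "pair"
) -> float:
    """Relaxation-induced dephasing rate of the coherence rho_{alpha beta}, fs^-1.

    ``mode='pair'`` (default) counts population exchange between the two
    states carrying the coherence, Gamma = (k_{a->b} + k_{b->a}) / 2; this is
    exact for an isolated pair and yields the picosecond coherence
    lifetimes characteristic of the reference dimer.  ``mode='total'`` uses the
    total-depopulation form Gamma = (sum_g k_{a->g} + sum_g k_{b->g}) / 2.
    Pure dephasing of the t2 coherence is excluded by construction, and
    ground-state vibrational coherences do not decay at all.
    """
    if alpha == beta:
        raise ValueError("dephasing is defined for a coherence between distinct states")
    if mode == "pair":
        return 0.5 * float(rates.rates[alpha, beta] + rates.rates[beta, alpha])
    if mode == "total":
        dep = rates.depopulation
        return 0.5 * float(dep[alpha] + dep[beta])
    raise ValueError(f"unknown dephasing mode {mode!r}")
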