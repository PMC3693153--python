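"""Vibronic-exciton model of a two-pigment aggregate.

Each pigment carries one optical transition and one intramolecular harmonic
mode (frequency ``omega0``, Huang-Rhys factor ``S``).  In the one-particle
approximation the singly-excited manifold is spanned by states in which the
electronically excited pigment holds 0..n_quanta vibrational quanta while the
other pigment stays in its vibrational ground state.  Excitonic coupling J
mixes these states with Franck-Condon scaled matrix elements
``V = J * FC(0,nu) * FC(0,nu')`` and lends transition-dipole strength from the
strong zero-phonon transitions to the weak vibronic ones (intensity
borrowing).

This module builds and diagonalizes the excited-state Hamiltonian, computes
eigenstate transition dipoles, the local-vibrational-character measure chi of
a coherence, and the isotropically averaged dipole pre-factors of the
four-wave-mixing pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import eval_genlaguerre

__all__ = [
    "VibrationalMode",
    "MonomerSpec",
    "DimerSpec",
    "BasisState",
    "Eigensystem",
    "TransitionDipoleSet",
    "franck_condon",
    "build_excited_hamiltonian",
    "diagonalize",
    "vibrational_character",
    "eigen_transition_dipoles",
    "orientation_factor",
    "isotropic_pathway_average",
    "dipole_prefactor",
    "monomer_prefactor",
    "prefactor_enhancement",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VibrationalMode:
    """A single displaced harmonic mode.

    Parameters
    ----------
    frequency : float
        Mode wavenumber omega0 in cm^-1 (must be positive).
    huang_rhys : float
        Dimensionless Huang-Rhys factor S = d**2 / 2 for the dimensionless
        displacement d between the ground- and excited-state surfaces.
    n_quanta : int
        Number of explicitly treated excited vibrational levels (>= 1).
    """

    frequency: float
    huang_rhys: float
    n_quanta: int = 1

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError(f"mode frequency must be positive, got {self.frequency}")
        if self.huang_rhys < 0:
            raise ValueError(f"Huang-Rhys factor must be >= 0, got {self.huang_rhys}")
        if self.n_quanta < 1:
            raise ValueError(f"n_quanta must be >= 1, got {self.n_quanta}")

    @property
    def displacement(self) -> float:
        """Dimensionless surface displacement d = sqrt(2 S)."""
        return math.sqrt(2.0 * self.huang_rhys)


@dataclass(frozen=True)
class MonomerSpec:
    """One pigment: site energy, transition dipole and its local mode."""

    site_energy: float
    mode: VibrationalMode
    dipole_length: float = 1.0
    dipole_direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.dipole_length < 0:
            raise ValueError("dipole_length must be >= 0")
        n = float(np.linalg.norm(self.dipole_direction))
        if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValueError("dipole_direction must be a unit vector")

    @property
    def dipole_vector(self) -> np.ndarray:
        return self.dipole_length * np.asarray(self.dipole_direction, float)


@dataclass(frozen=True)
class DimerSpec:
    """Two coupled pigments.

    ``gap`` and ``dipole_angle`` are derived from the monomers so the
    invariants (gap = E2 - E1, angle from the direction vectors) hold by
    construction.  Note the dipole *vector* orientations matter: the model is
    invariant under flipping the sign of the site-2 excited states, which
    maps (J, theta) to (-J, 180 deg - theta); only the relative sign of the
    coupling and of the dipole inner product is physical.
    """

    monomer1: MonomerSpec
    monomer2: MonomerSpec
    coupling: float

    @property
    def gap(self) -> float:
        """Site-energy gap Delta E = E_2 - E_1 in cm^-1."""
        return self.monomer2.site_energy - self.monomer1.site_energy

    @property
    def dipole_angle(self) -> float:
        """Angle between the two dipole direction vectors, degrees in [0, 180]."""
        c = float(
            np.dot(self.monomer1.dipole_direction, self.monomer2.dipole_direction)
        )
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    def with_gap(self, gap: float) -> "DimerSpec":
        """Copy of this dimer with the site-2 energy moved to E_1 + gap."""
        m2 = replace(self.monomer2, site_energy=self.monomer1.site_energy + gap)
        return replace(self, monomer2=m2)

    def with_mode_frequency(self, omega0: float) -> "DimerSpec":
        """Copy with the mode frequency changed on both pigments."""
        def upd(m: MonomerSpec) -> MonomerSpec:
            return replace(m, mode=replace(m.mode, frequency=omega0))
        return replace(self, monomer1=upd(self.monomer1), monomer2=upd(self.monomer2))

    def with_coupling(self, coupling: float) -> "DimerSpec":
        return replace(self, coupling=coupling)

    @classmethod
    def from_parameters(
        cls,
        site_energy: float,
        gap: float,
        coupling: float,
        mode_frequency: float,
        huang_rhys: float,
        dipole_angle: float,
        n_quanta: int = 1,
        dipole_length: float = 1.0,
    ) -> "DimerSpec":
        """Build a dimer from scalar parameters.

        ``dipole_angle`` is the angle (degrees) between the dipole *vectors*;
        monomer 1 points along x, monomer 2 in the xy plane.
        """
        if not 0.0 <= dipole_angle <= 180.0:
            raise ValueError("dipole_angle must lie in [0, 180] degrees")
        mode = VibrationalMode(mode_frequency, huang_rhys, n_quanta)
        th = math.radians(dipole_angle)
        m1 = MonomerSpec(site_energy, mode, dipole_length, (1.0, 0.0, 0.0))
        m2 = MonomerSpec(
            site_energy + gap, mode, dipole_length,
            (math.cos(th), math.sin(th), 0.0),
        )
        return cls(m1, m2, coupling)


@dataclass(frozen=True)
class BasisState:
    """One-particle basis state of the singly-excited manifold.

    ``site`` is the electronically excited pigment (1 or 2) and ``quanta``
    the vibrational level of that pigment; the other pigment is pinned to its
    vibrational ground state.
    """

    site: int
    quanta: int

    def __post_init__(self) -> None:
        if self.site not in (1, 2):
            raise ValueError("site must be 1 or 2")
        if self.quanta < 0:
            raise ValueError("quanta must be >= 0")

    @property
    def label(self) -> str:
        if self.site == 1:
            return f"|e{self.quanta} g0>"
        return f"|g0 e{self.quanta}>"


def excited_basis(n_quanta: int) -> list[BasisState]:
    """Ordered one-particle basis: site-1 block then site-2 block, quanta ascending."""
    return [BasisState(1, v) for v in range(n_quanta + 1)] + [
        BasisState(2, v) for v in range(n_quanta + 1)
    ]


@dataclass(frozen=True)
class Eigensystem:
    """Eigenstates of the excited-state Hamiltonian.

    ``coefficients[:, alpha]`` holds the expansion of eigenstate ``alpha``
    (zero-based, energies ascending) over ``basis``.
    """

    energies: np.ndarray
    coefficients: np.ndarray
    basis: tuple[BasisState, ...]

    @property
    def n_states(self) -> int:
        return len(self.energies)

    def weight(self, alpha: int, state: BasisState) -> float:
        """|c|^2 of ``state`` in eigenstate ``alpha``."""
        i = self.basis.index(state)
        return float(self.coefficients[i, alpha] ** 2)

    def site_participation(self, alpha: int) -> np.ndarray:
        """Total electronic weight of each site (length-2 array summing to 1)."""
        sites = np.array([b.site for b in self.basis])
        c2 = self.coefficients[:, alpha] ** 2
        return np.array([c2[sites == 1].sum(), c2[sites == 2].sum()])


@dataclass(frozen=True)
class TransitionDipoleSet:
    """Transition dipole vectors mu_{alpha, g_nu}.

    ``vectors[alpha, nu]`` is the 3-vector for the transition from the ground
    manifold state with ``nu`` vibrational quanta on pigment 1 (the other
    pigment in its vibrational ground state) to excited eigenstate ``alpha``.
    """

    vectors: np.ndarray  # (n_states, n_quanta + 1, 3)

    def length(self, alpha: int, nu: int = 0) -> float:
        return float(np.linalg.norm(self.vectors[alpha, nu]))

    def angle_deg(self, alpha: int, beta: int, nu_a: int = 0, nu_b: int = 0) -> float:
        """Angle between mu_{alpha, g nu_a} and mu_{beta, g nu_b} in degrees."""
        a, b = self.vectors[alpha, nu_a], self.vectors[beta, nu_b]
        la, lb = np.linalg.norm(a), np.linalg.norm(b)
        if la == 0 or lb == 0:
            raise ValueError("angle undefined for a vanishing transition dipole")
        c = float(np.dot(a, b) / (la * lb))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))


# ---------------------------------------------------------------------------
# Franck-Condon factors
# ---------------------------------------------------------------------------

def franck_condon(huang_rhys: float, nu_g: int, nu_e: int) -> float:
    """Signed overlap <g_{nu_g} | e_{nu_e}> of displaced harmonic oscillators.

    The two surfaces share the mode frequency and are displaced by
    d = sqrt(2 S).  The sign convention fixes FC(0, nu_e) >= 0, so e.g.
    FC(0,0) = exp(-S/2), FC(0,1) = sqrt(S) exp(-S/2) and
    FC(1,1) = (1 - S) exp(-S/2); only squared magnitudes enter observables.
    """
    if huang_rhys < 0:
        raise ValueError("huang_rhys must be >= 0")
    if nu_g < 0 or nu_e < 0:
        raise ValueError("vibrational quantum numbers must be >= 0")
    s = float(huang_rhys)
    a = math.sqrt(s)
    m, n = int(nu_g), int(nu_e)
    if m >= n:
        pref = math.sqrt(math.factorial(n) / math.factorial(m)) * (-a) ** (m - n)
        lag = eval_genlaguerre(n, m - n, s)
    else:
        pref = math.sqrt(math.factorial(m) / math.factorial(n)) * a ** (n - m)
        lag = eval_genlaguerre(m, n - m, s)
    return float(pref * math.exp(-s / 2.0) * lag)


# ---------------------------------------------------------------------------
# Hamiltonian and diagonalization
# ---------------------------------------------------------------------------

def build_excited_hamiltonian(dimer: DimerSpec) -> tuple[np.ndarray, list[BasisState]]:
    """Excited-state Hamiltonian in the one-particle basis (cm^-1).

    Diagonal entries are E_site + nu * omega0; the inter-site block carries
    V_{nu nu'} = J * FC(0, nu) * FC(0, nu').
    """
    m1, m2 = dimer.monomer1, dimer.monomer2
    nq = m1.mode.n_quanta
    if m2.mode.n_quanta != nq:
        raise ValueError("both monomers must use the same number of quanta")
    basis = excited_basis(nq)
    nb = nq + 1
    h = np.zeros((2 * nb, 2 * nb))
    for v in range(nb):
        h[v, v] = m1.site_energy + v * m1.mode.frequency
        h[nb + v, nb + v] = m2.site_energy + v * m2.mode.frequency
    fc1 = [franck_condon(m1.mode.huang_rhys, 0, v) for v in range(nb)]
    fc2 = [franck_condon(m2.mode.huang_rhys, 0, v) for v in range(nb)]
    for i in range(nb):
        for j in range(nb):
            h[i, nb + j] = dimer.coupling * fc1[i] * fc2[j]
            h[nb + j, i] = h[i, nb + j]
    return h, basis


def diagonalize(
    h: np.ndarray, basis: list[BasisState] | None = None
) -> Eigensystem:
    """Diagonalize a Hermitian Hamiltonian into an :class:`Eigensystem`.

    Eigenvalues ascend; each eigenvector's largest-magnitude component is made
    positive.  Exactly degenerate eigenvalues are ordered by the index of the
    dominant basis state, which makes the decomposition deterministic (the
    composition at an exact degeneracy remains basis-convention dependent).
    """
    h = np.asarray(h, float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("Hamiltonian must be a square matrix")
    if not np.allclose(h, h.T, atol=1e-9):
        raise ValueError("Hamiltonian must be Hermitian")
    w, v = np.linalg.eigh(h)
    # tie-break exact degeneracies by dominant basis-state index
    order = np.arange(len(w))
    i = 0
    while i < len(w):
        j = i
        while j + 1 < len(w) and abs(w[j + 1] - w[i]) < 1e-9:
            j += 1
        if j > i:
            block = order[i : j + 1]
            dom = [int(np.argmax(np.abs(v[:, k]))) for k in block]
            order[i : j + 1] = block[np.argsort(dom, kind="stable")]
        i = j + 1
    w, v = w[order], v[:, order]
    sgn = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    sgn[sgn == 0] = 1.0
    v = v * sgn
    if basis is None:
        basis = excited_basis(h.shape[0] // 2 - 1)
    return Eigensystem(energies=w, coefficients=v, basis=tuple(basis))


def diagonalize_dimer(dimer: DimerSpec) -> Eigensystem:
    """Convenience: build and diagonalize the excited-state Hamiltonian."""
    return diagonalize(*build_excited_hamiltonian(dimer))


# ---------------------------------------------------------------------------
# vibrational character
# ---------------------------------------------------------------------------

def vibrational_character(eig: Eigensystem, alpha: int, beta: int) -> float:
    """Local vibrational character chi of the coherence rho_{alpha beta}.

    chi = |c^a_{e0g0}|^2 |c^b_{e1g0}|^2 + |c^a_{e1g0}|^2 |c^b_{e0g0}|^2 is the
    joint probability that the pair of eigenstates realizes the zero- and
    one-phonon states of pigment 1 (in either assignment).  chi = 1 for the
    pure local pair; chi > 0.5 is read as prevailingly vibrational.  It is a
    property of the Hamiltonian only and does not evolve in time.
    """
    if alpha == beta:
        raise ValueError("chi is defined for a coherence between distinct states")
    e0, e1 = BasisState(1, 0), BasisState(1, 1)
    return (
        eig.weight(alpha, e0) * eig.weight(beta, e1)
        + eig.weight(alpha, e1) * eig.weight(beta, e0)
    )


# ---------------------------------------------------------------------------
# transition dipoles and pre-factors
# ---------------------------------------------------------------------------

def eigen_transition_dipoles(eig: Eigensystem, dimer: DimerSpec) -> TransitionDipoleSet:
    """Transition dipoles from |g_nu g_0> (quanta on pigment 1) to each eigenstate.

    Under the Condon approximation every vibronic transition on a pigment
    shares that pigment's electronic dipole vector, scaled by the vibrational
    overlap.  A site-2 component contributes only for nu = 0 because exciting
    pigment 2 cannot change pigment 1's vibrational state (one-particle
    basis orthogonality).
    """
    m1, m2 = dimer.monomer1, dimer.monomer2
    nq = m1.mode.n_quanta
    u1, u2 = m1.dipole_vector, m2.dipole_vector
    n_states = eig.n_states
    out = np.zeros((n_states, nq + 1, 3))
    for alpha in range(n_states):
        for nu in range(nq + 1):
            vec = np.zeros(3)
            for i, b in enumerate(eig.basis):
                c = eig.coefficients[i, alpha]
                if b.site == 1:
                    vec += c * franck_condon(m1.mode.huang_rhys, nu, b.quanta) * u1
                elif nu == 0:
                    vec += c * franck_condon(m2.mode.huang_rhys, 0, b.quanta) * u2
            out[alpha, nu] = vec
    return TransitionDipoleSet(vectors=out)


def orientation_factor(theta_deg: float) -> float:
    """Isotropic four-pulse (all-parallel) orientation factor (1 + 2 cos^2 theta)/15.

    ``theta_deg`` is the angle between the two distinct transition dipoles of
    a mu_a^2 mu_b^2 pathway; parallel dipoles give 3/15 = <cos^4> = 1/5.
    """
    c = math.cos(math.radians(theta_deg))
    return (1.0 + 2.0 * c * c) / 15.0


def isotropic_pathway_average(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> float:
    """Isotropic average <(a.e)(b.e)(c.e)(d.e)> for four parallel pulse polarizations.

    Equals [(a.b)(c.d) + (a.c)(b.d) + (a.d)(b.c)] / 15 and is symmetric under
    any permutation of the four interaction dipoles.
    """
    return float(
        np.dot(a, b) * np.dot(c, d)
        + np.dot(a, c) * np.dot(b, d)
        + np.dot(a, d) * np.dot(b, c)
    ) / 15.0


def dipole_prefactor(
    eig: Eigensystem,
    dipoles: TransitionDipoleSet,
    pathway: str,
    alpha: int,
    beta: int,
    nu: int = 0,
) -> float:
    """Orientationally averaged dipole pre-factor of a non-rephasing pathway.

    R1 (stimulated emission, excited-state coherence rho_{alpha beta}) uses the
    interaction sequence (mu_{alpha,g0}, mu_{beta,g0}, mu_{beta,g nu},
    mu_{alpha,g nu}); R4 (ground-state bleach through the g_nu vibrational
    coherence) uses (mu_{alpha,g0}, mu_{alpha,g nu}, mu_{beta,g nu},
    mu_{beta,g0}).  The two sequences contain the same dipoles, so matched R1
    and R4 labels give identical pre-factors for nu > 0.
    """
    if pathway not in ("R1", "R4"):
        raise ValueError(f"unknown pathway {pathway!r}; expected 'R1' or 'R4'")
    nq = dipoles.vectors.shape[1] - 1
    if not 0 <= nu <= nq:
        raise ValueError(f"nu={nu} outside the explicit ground-state levels (0..{nq})")
    ag0, bg0 = dipoles.vectors[alpha, 0], dipoles.vectors[beta, 0]
    agn, bgn = dipoles.vectors[alpha, nu], dipoles.vectors[beta, nu]
    if pathway == "R1":
        return isotropic_pathway_average(ag0, bg0, bgn, agn)
    return isotropic_pathway_average(ag0, agn, bgn, bg0)


def monomer_prefactor(monomer: MonomerSpec) -> float:
    """Pre-factor of the vibrational (0-1) coherence on an isolated pigment.

    mu^4 FC(0,0)^2 FC(0,1)^2 (3/15): the reference against which dimer
    pre-factors are measured.
    """
    s = monomer.mode.huang_rhys
    f0 = franck_condon(s, 0, 0)
    f1 = franck_condon(s, 0, 1)
    return monomer.dipole_length ** 4 * f0 * f0 * f1 * f1 * (3.0 / 15.0)


def prefactor_enhancement(
    dimer: DimerSpec,
    pathway: str,
    alpha: int,
    beta: int,
    nu: int = 0,
) -> float:
    """Dimer pathway pre-factor relative to the monomer-1 vibrational reference."""
    ref = monomer_prefactor(dimer.monomer1)
    if ref == 0.0:
        raise ValueError(
            "monomer vibrational pre-factor vanishes (S = 0); ratio undefined"
        )
    eig = diagonalize_dimer(dimer)
    dip = eigen_transition_dipoles(eig, dimer)
    return dipole_prefactor(eig, dip, pathway, alpha, beta, nu) / ref
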