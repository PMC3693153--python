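"""Hamiltonian construction, Franck-Condon factors, chi and dipole pre-factors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import hermite

from vibronic_dimer import (
    BasisState,
    DimerSpec,
    Eigensystem,
    MonomerSpec,
    VibrationalMode,
    build_excited_hamiltonian,
    diagonalize,
    diagonalize_dimer,
    dipole_prefactor,
    eigen_transition_dipoles,
    franck_condon,
    monomer_prefactor,
    orientation_factor,
    prefactor_enhancement,
    vibrational_character,
)
from vibronic_dimer.model import excited_basis

S = 0.05


def fc_quadrature(s: float, m: int, n: int) -> float:
    """Independent oracle: overlap of displaced harmonic wavefunctions."""
    d = math.sqrt(2.0 * s)

    def psi(k, x):
        norm = 1.0 / math.sqrt(2.0**k * math.factorial(k) * math.sqrt(math.pi))
        return norm * hermite(k)(x) * np.exp(-x * x / 2.0)

    val, _ = quad(lambda x: psi(m, x) * psi(n, x - d), -12, 12, limit=200)
    return val


class TestFranckCondon:
    @pytest.mark.parametrize(
        "m,n,expected",
        [
            (0, 0, math.exp(-S / 2)),
            (0, 1, math.sqrt(S) * math.exp(-S / 2)),
            (1, 1, (1 - S) * math.exp(-S / 2)),
            (0, 2, S / math.sqrt(2) * math.exp(-S / 2)),
        ],
    )
    def test_closed_forms(self, m, n, expected):
        assert franck_condon(S, m, n) == pytest.approx(expected, rel=1e-12)

    def test_no_displacement_orthogonality(self):
        assert franck_condon(0.0, 0, 1) == 0.0
        assert franck_condon(0.0, 2, 2) == 1.0

    @pytest.mark.parametrize("m,n", [(0, 0), (0, 1), (1, 0), (1, 1), (2, 1)])
    def test_against_numerical_quadrature(self, m, n):
        got = franck_condon(S, m, n)
        assert abs(got) == pytest.approx(abs(fc_quadrature(S, m, n)), abs=1e-10)

    def test_sign_convention(self):
        # 0 -> nu overlaps positive; 1 -> 0 picks up the displaced-node sign
        assert franck_condon(S, 0, 1) > 0
        assert franck_condon(S, 1, 0) < 0

    def test_completeness(self):
        total = sum(franck_condon(S, 0, n) ** 2 for n in range(21))
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("bad", [(-0.1, 0, 0), (S, -1, 0), (S, 0, -2)])
    def test_domain_errors(self, bad):
        s, m, n = bad
        with pytest.raises(ValueError):
            franck_condon(s, m, n)


def make_dimer(gap=110.0, coupling=-53.5, omega0=117.0, s=S, angle=72.8, nq=1):
    return DimerSpec.from_parameters(
        site_energy=12210.0, gap=gap, coupling=coupling, mode_frequency=omega0,
        huang_rhys=s, dipole_angle=angle, n_quanta=nq,
    )


class TestHamiltonian:
    def test_uncoupled_eigenvalues_exact(self):
        h, _ = build_excited_hamiltonian(make_dimer(coupling=0.0))
        w = np.sort(np.linalg.eigvalsh(h))
        e = 12210.0
        assert np.allclose(w, [e, e + 110, e + 117, e + 227], atol=1e-10)

    def test_coupling_element_franck_condon_scaled(self):
        h, basis = build_excited_hamiltonian(make_dimer())
        i = basis.index(BasisState(1, 0))
        j = basis.index(BasisState(2, 0))
        assert h[i, j] == pytest.approx(-53.5 * math.exp(-S), rel=1e-12)  # -50.89
        assert h[i, j] == pytest.approx(-50.89, abs=0.01)
        assert np.allclose(h, h.T)

    def test_resonant_block_splitting(self):
        # exact resonance Delta E = omega0: the isolated {|e1 g0>, |g0 e0>}
        # block splits by 2 |J FC0 FC1|
        f0 = franck_condon(S, 0, 0)
        f1 = franck_condon(S, 0, 1)
        v = -53.5 * f0 * f1
        block = np.array([[12327.0, v], [v, 12327.0]])
        w = np.linalg.eigvalsh(block)
        assert w[1] - w[0] == pytest.approx(2 * abs(v), rel=1e-12)
        assert w[1] - w[0] == pytest.approx(22.8, abs=0.1)

    def test_two_level_mixing_angle_oracle(self):
        # analytic two-level formulas for an isolated resonant pair
        e1, e2, v = 100.0, 140.0, -11.4
        block = np.array([[e1, v], [v, e2]])
        eig = diagonalize(block, basis=excited_basis(0))
        theta = 0.5 * math.atan(2 * v / (e1 - e2))
        mean, half = (e1 + e2) / 2, math.hypot((e1 - e2) / 2, v)
        assert eig.energies[0] == pytest.approx(mean - half, abs=1e-8)
        assert eig.energies[1] == pytest.approx(mean + half, abs=1e-8)
        c = np.abs(eig.coefficients)
        assert c[0, 0] == pytest.approx(abs(math.cos(theta)), abs=1e-8)
        assert c[1, 0] == pytest.approx(abs(math.sin(theta)), abs=1e-8)


class TestDiagonalize:
    def test_identity_like_permutation(self):
        h = np.diag([3.0, 1.0, 2.0, 4.0])
        eig = diagonalize(h)
        assert np.allclose(eig.energies, [1, 2, 3, 4])
        assert np.allclose(np.abs(eig.coefficients).sum(axis=0), 1.0)

    def test_non_hermitian_rejected(self):
        with pytest.raises(ValueError):
            diagonalize(np.array([[0.0, 1.0], [0.0, 0.0]]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_orthonormality_and_trace(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 4))
        h = (a + a.T) / 2
        eig = diagonalize(h)
        c = eig.coefficients
        assert np.linalg.norm(c.T @ c - np.eye(4)) < 1e-10
        assert np.sum(eig.energies) == pytest.approx(np.trace(h), rel=1e-12)
        assert np.all(np.diff(eig.energies) >= -1e-12)

    def test_sign_convention_deterministic(self):
        eig = diagonalize_dimer(make_dimer())
        for a in range(4):
            col = eig.coefficients[:, a]
            assert col[np.argmax(np.abs(col))] > 0

    def test_reference_composition(self):
        # state 2 is dominated by the one-phonon site-1 excitation, state 3
        # by the zero-phonon site-2 excitation
        eig = diagonalize_dimer(make_dimer())
        assert np.argmax(eig.coefficients[:, 1] ** 2) == 1  # |e1 g0>
        assert np.argmax(eig.coefficients[:, 2] ** 2) == 2  # |g0 e0>


class TestVibrationalCharacter:
    def test_pure_local_pair_is_one(self):
        eig = diagonalize_dimer(make_dimer(coupling=0.0, gap=150.0))
        # states 1, 2 are exactly |e0 g0>, |e1 g0>
        assert vibrational_character(eig, 0, 1) == pytest.approx(1.0, abs=1e-12)

    def test_equal_mixture_is_half(self):
        c = np.array(
            [[1 / math.sqrt(2), 1 / math.sqrt(2)], [1 / math.sqrt(2), -1 / math.sqrt(2)]]
        )
        eig = Eigensystem(
            energies=np.array([0.0, 1.0]),
            coefficients=c,
            basis=(BasisState(1, 0), BasisState(1, 1)),
        )
        assert vibrational_character(eig, 0, 1) == pytest.approx(0.5)

    def test_mean_composition_arithmetic(self):
        # plugging the disorder-averaged weights (0.85, 0.64, 0.00, 0.08)
        # into the definition classifies rho_12 as prevailingly vibrational
        chi = 0.85 * 0.64 + 0.00 * 0.08
        assert chi == pytest.approx(0.544)
        assert chi > 0.5

    def test_same_state_rejected(self):
        eig = diagonalize_dimer(make_dimer())
        with pytest.raises(ValueError):
            vibrational_character(eig, 1, 1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 4))
        eig = diagonalize((a + a.T) / 2)
        for i in range(4):
            for j in range(i + 1, 4):
                chi = vibrational_character(eig, i, j)
                assert 0.0 <= chi <= 1.0
                assert chi == pytest.approx(vibrational_character(eig, j, i))


class TestTransitionDipoles:
    def test_uncoupled_lengths_reduce_to_monomer(self):
        d = make_dimer(coupling=0.0, gap=150.0)
        eig = diagonalize_dimer(d)
        dip = eigen_transition_dipoles(eig, d)
        assert dip.length(0, 0) == pytest.approx(franck_condon(S, 0, 0), rel=1e-10)
        assert dip.length(1, 0) == pytest.approx(franck_condon(S, 0, 1), rel=1e-10)

    def test_site2_cannot_change_site1_vibration(self):
        d = make_dimer(coupling=0.0, gap=150.0)
        eig = diagonalize_dimer(d)
        dip = eigen_transition_dipoles(eig, d)
        # states 3, 4 are the site-2 excitations: no |g1 g0> transition
        assert dip.length(2, 1) == pytest.approx(0.0, abs=1e-14)
        assert dip.length(3, 1) == pytest.approx(0.0, abs=1e-14)

    def test_intensity_borrowing_at_reference(self):
        d = make_dimer()
        eig = diagonalize_dimer(d)
        dip = eigen_transition_dipoles(eig, d)
        uncoupled = franck_condon(S, 0, 1)  # 0-1 strength without mixing
        assert dip.length(1, 0) ** 2 > uncoupled**2

    def test_lengths_invariant_under_global_rotation(self):
        d = make_dimer()
        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        mode = d.monomer1.mode

        def rot(m: MonomerSpec) -> MonomerSpec:
            vec = q @ np.asarray(m.dipole_direction)
            return MonomerSpec(m.site_energy, mode, m.dipole_length, tuple(vec))

        d2 = DimerSpec(rot(d.monomer1), rot(d.monomer2), d.coupling)
        e1, e2 = diagonalize_dimer(d), diagonalize_dimer(d2)
        p1 = eigen_transition_dipoles(e1, d)
        p2 = eigen_transition_dipoles(e2, d2)
        for a in range(4):
            assert p1.length(a, 0) == pytest.approx(p2.length(a, 0), rel=1e-9)


class TestOrientationFactor:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 0.2), (90.0, 1.0 / 15.0), (107.2, 0.0783), (72.8, 0.0783)],
    )
    def test_values(self, theta, expected):
        assert orientation_factor(theta) == pytest.approx(expected, abs=5e-5)


class TestDipolePrefactor:
    def test_monomer_limit_closed_form(self):
        d = make_dimer(coupling=0.0, gap=150.0)
        eig = diagonalize_dimer(d)
        dip = eigen_transition_dipoles(eig, d)
        got = dipole_prefactor(eig, dip, "R1", 0, 1, nu=0)
        f0, f1 = franck_condon(S, 0, 0), franck_condon(S, 0, 1)
        assert got == pytest.approx(f0**2 * f1**2 * (3 / 15), rel=1e-10)
        assert got == pytest.approx(monomer_prefactor(d.monomer1), rel=1e-10)

    def test_r1_r4_prefactor_equality_for_nu1(self):
        d = make_dimer(gap=95.0)
        eig = diagonalize_dimer(d)
        dip = eigen_transition_dipoles(eig, d)
        for a, b in [(0, 1), (0, 2), (1, 2)]:
            r1 = dipole_prefactor(eig, dip, "R1", a, b, nu=1)
            r4 = dipole_prefactor(eig, dip, "R4", a, b, nu=1)
            assert r1 == pytest.approx(r4, rel=1e-12)

    def test_maximal_mixing_saturation(self):
        # toy limit: site-2 transition forbidden, resonant electronic mixing;
        # the coherence pre-factor saturates at mu^4/4 times the parallel
        # orientation factor
        mode = VibrationalMode(117.0, 1e-12)
        m1 = MonomerSpec(12210.0, mode, 1.0, (1.0, 0.0, 0.0))
        m2 = MonomerSpec(12210.0, mode, 0.0, (0.0, 1.0, 0.0))
        d = DimerSpec(m1, m2, -50.0)
        eig = diagonalize_dimer(d)
        dip = eigen_transition_dipoles(eig, d)
        got = dipole_prefactor(eig, dip, "R1", 0, 1, nu=0)
        assert got == pytest.approx(0.25 * 0.2, rel=1e-6)

    def test_unknown_pathway_rejected(self):
        d = make_dimer()
        eig = diagonalize_dimer(d)
        dip = eigen_transition_dipoles(eig, d)
        with pytest.raises(ValueError):
            dipole_prefactor(eig, dip, "R2", 0, 1)
        with pytest.raises(ValueError):
            dipole_prefactor(eig, dip, "R1", 0, 1, nu=5)


class TestPrefactorEnhancement:
    def test_decoupled_ratio_is_one(self):
        # J = 0 with the vibrational pair as the two lowest states
        d = make_dimer(coupling=0.0, gap=150.0)
        assert prefactor_enhancement(d, "R1", 0, 1) == pytest.approx(1.0, rel=1e-10)

    def test_decoupling_limit_smooth(self):
        vals = [
            prefactor_enhancement(make_dimer(coupling=j, gap=150.0), "R1", 0, 1)
            for j in (-10.0, -1.0, -0.1)
        ]
        assert abs(vals[-1] - 1.0) < 5e-3  # dipole borrowing is linear in J
        assert abs(vals[0] - 1.0) > abs(vals[1] - 1.0) > abs(vals[2] - 1.0)

    def test_zero_huang_rhys_rejected(self):
        d = make_dimer(s=0.0)
        with pytest.raises(ValueError):
            prefactor_enhancement(d, "R1", 0, 1)


class TestSpecs:
    def test_gap_and_angle_derived(self):
        d = make_dimer(gap=110.0, angle=72.8)
        assert d.gap == pytest.approx(110.0)
        assert d.dipole_angle == pytest.approx(72.8)
        assert d.with_gap(95.0).gap == pytest.approx(95.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            VibrationalMode(-5.0, 0.05)
        with pytest.raises(ValueError):
            VibrationalMode(117.0, -0.1)
        with pytest.raises(ValueError):
            VibrationalMode(117.0, 0.05, 0)
        with pytest.raises(ValueError):
            MonomerSpec(12210.0, VibrationalMode(117.0, 0.05), 1.0, (1.0, 1.0, 0.0))
        with pytest.raises(ValueError):
            make_dimer(angle=200.0)
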