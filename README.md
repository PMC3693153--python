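# vibronic-dimer

Vibronic-exciton modelling of a coupled pigment dimer and of the coherences
it produces in two-dimensional (2D) electronic spectra.

Long-lived oscillations in the 2D spectra of photosynthetic antennae such as
the Fenna–Matthews–Olson (FMO) complex have been attributed to excitonic
mixing between electronic excitations and weak intramolecular vibrations:
the mixing lends transition-dipole strength from strong zero-phonon
transitions to nearly forbidden vibronic ones ("intensity borrowing") and
thereby amplifies both excited-state vibronic coherences and ground-state
vibrational coherences.  This package implements that analysis end to end
for a heterodimer patterned on BChls 3–4 of FMO, for anyone who wants to
explore when the enhancement is large, how long the coherences live, and how
the two coherence types can be told apart.

## What it computes

* **Model** — one-particle vibronic Hamiltonian (site energies E and E+ΔE,
  coupling J, one mode ω₀ with Huang–Rhys factor S per pigment), with
  Franck–Condon scaled coupling V_νν' = J·FC₀ν·FC₀ν'; eigenstates, their
  transition dipoles μ_{α,gν}, and the local-vibrational-character measure
  χ_αβ = |c^α_{e₀g₀}|²|c^β_{e₁g₀}|² + |c^α_{e₁g₀}|²|c^β_{e₀g₀}|²
  of a coherence ρ_αβ (χ > ½ ⇒ prevailingly vibrational).
* **Pre-factors** — isotropically averaged four-pulse dipole pre-factors of
  the non-rephasing Liouville pathways, and their enhancement over the
  monomer vibrational reference μ⁴FC₀₀²FC₀₁²(1+2cos²θ)/15.
* **Signals** — diagonal-cut amplitudes S(ω₁,t₂) of pathway R1 (stimulated
  emission through the vibronic coherence, oscillating at ω_αβ and dephased
  by Redfield population exchange) and R4 (ground-state bleach through the
  vibrational coherence, oscillating at exactly ω₀ with no decay), with
  overdamped-Brownian-oscillator lineshapes (Λ = 130 cm⁻¹, λ = 35 cm⁻¹,
  77 K) and Gaussian static disorder of the site-energy gap (80 cm⁻¹ FWHM).
* **Analysis** — disorder-averaged eigenstate composition tables, χ
  thresholds over the gap axis, absorption-maximum location, relative
  amplitudes A_r versus the monomer, damped-cosine fits of t₂ traces
  (frequency and lifetime), and sweeps over ΔE, J and ω₀.

See `docs/methods.md` for the model equations, conventions and limitations.

## Worked example

```python
import numpy as np
from vibronic_dimer import (
    fixtures, diagonalize_dimer, vibrational_character, prefactor_enhancement,
    averaged_dimer_signals, averaged_monomer_signal, relative_amplitude,
    find_absorption_maximum, fit_damped_cosine,
)

fx = fixtures()["reference"]          # J = -53.5, gap 110, omega0 117 cm^-1
eig = diagonalize_dimer(fx.dimer)
print("eigenenergies (cm^-1, relative):", np.round(eig.energies - eig.energies[0], 1))
print("chi_12 =", round(vibrational_character(eig, 0, 1), 3))
print("pre-factor enhancement (1,2):", round(prefactor_enhancement(fx.dimer, "R1", 0, 1), 2))

om = np.arange(11900.0, 12650.0, 3.0)
t2 = np.arange(0.0, 2001.0, 10.0)
s1, s4, beta = averaged_dimer_signals(fx.dimer, fx.bath, fx.disorder, om, t2)
mono = averaged_monomer_signal(fx.dimer, fx.bath, fx.disorder, om, t2)
w_opt = find_absorption_maximum(s1)
fit = fit_damped_cosine(t2, np.real(s1.trace(w_opt)))
print(f"omega_opt = {w_opt:.0f} cm^-1, A_r(R1) = {relative_amplitude(s1, mono).value:.1f}, "
      f"A_r(R4) = {relative_amplitude(s4, mono).value:.1f}")
print(f"fitted frequency = {fit.frequency:.1f} cm^-1, lifetime = {fit.lifetime_ps:.2f} ps")
```

prints

```
eigenenergies (cm^-1, relative): [  0.  131.7 156.2 248.2]
chi_12 = 0.655
pre-factor enhancement (1,2): 2.66
omega_opt = 12160 cm^-1, A_r(R1) = 20.0, A_r(R4) = 6.7
fitted frequency = 130.2 cm^-1, lifetime = 1.02 ps
```

Reading this: at the reference gap the second eigenstate sits 131.7 cm⁻¹
above the first and the ρ₁₂ coherence is 65% local-vibrational (χ = 0.655 >
0.5).  Averaged over disorder, the R1 signal at its optimal excitation
frequency (12160 cm⁻¹, the lower exciton line) starts twenty times stronger
than the same vibrational coherence in an isolated pigment, oscillates at
130 cm⁻¹ — shifted off the 117 cm⁻¹ mode by the excitonic mixing — and
survives for about a picosecond, while the ground-state R4 signal is
enhanced ~7× and never decays.  The frequency shift and the decay are the
observables that distinguish the two coherence types.

## Command line

Every driver reads a YAML config (all keys optional; defaults are the
reference parameterization) and writes TSV tables plus a JSON manifest:

```
vibronic-dimer thresholds            # chi crossings along the gap axis
vibronic-dimer prefactor-sweep       # enhancement + chi vs gap
vibronic-dimer composition           # disorder-averaged composition
vibronic-dimer trace                 # R1/R4 signals and the omega_opt trace
vibronic-dimer fit                   # damped-cosine fit of the R1 trace
vibronic-dimer mode-sweep            # enhancement/lifetime vs omega0
vibronic-dimer reproduce prefactor-gap   # data behind the headline results
```

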