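# Methods

## Model

Two coupled pigments (a heterodimer abstracted from bacteriochlorophylls 3
and 4 of the FMO antenna) each carry one optical transition and one
intramolecular harmonic mode of frequency ω₀ with Huang–Rhys factor S
(surface displacement d = √(2S), identical on both pigments).  In the
one-particle approximation the singly-excited manifold is spanned by
|e_ν g₀⟩ and |g₀ e_ν'⟩ with ν ≤ ν_max: the electronically unexcited pigment
is pinned to its vibrational ground state.  This truncation is exact for the
diagonal-peak pathways studied here, because a state reached from the global
ground state by one optical interaction cannot carry a vibrational quantum
on the other pigment.

With basis order (|e₀g₀⟩, |e₁g₀⟩, |g₀e₀⟩, |g₀e₁⟩) for ν_max = 1 the
excited-manifold Hamiltonian has diagonal (E, E+ω₀, E+ΔE, E+ΔE+ω₀) and
inter-site elements V_νν' = J·FC₍₀ν₎·FC₍₀ν'₎, where FC₍mn₎ = ⟨g_m|e_n⟩ is
the displaced-oscillator Franck–Condon overlap (closed form via associated
Laguerre polynomials; sign convention FC₍₀ν₎ ≥ 0, fixed so coefficient signs
are reproducible).  Eigenstates |α⟩ = Σ c^α_i |i⟩ are numbered by increasing
energy; each eigenvector's largest component is made positive, and exact
degeneracies are ordered by dominant basis index (the composition at an
exact degeneracy is basis-convention dependent and documented as such).

**Vibrational character.**  For the coherence ρ_αβ the measure
χ_αβ = |c^α_{e₀g₀}|²|c^β_{e₁g₀}|² + |c^α_{e₁g₀}|²|c^β_{e₀g₀}|² is the joint
probability that the pair realizes the zero- and one-phonon states of
pigment 1.  χ = 1 for the pure local pair, ½ for 50/50 mixtures; χ > ½ is
read as "prevailingly vibrational".  χ depends only on the Hamiltonian and
does not evolve in time.

**Transition dipoles and intensity borrowing.**  Under the Condon
approximation μ_{α,gν} = Σ_ν' c^α_{e_ν' g₀} FC₍ν ν'₎ μ̂₁μ₁ + δ_ν0 Σ_ν'
c^α_{g₀ e_ν'} FC₍0 ν'₎ μ̂₂μ₂.  Mixing of the weak one-phonon transition
(∝ √S) with the allowed zero-phonon transition of the partner pigment lends
it intensity — the enhancement mechanism at the heart of the analysis.

**Dipole orientation convention.**  The Qy axes of the two pigments span
107.2° (crystal-structure value).  An axis does not fix the sign of a dipole
vector, and the model is gauge-invariant under flipping the site-2 basis
sign, which maps (J, θ_vec) → (−J, 180°−θ_vec): only the relative sign of J
and μ̂₁·μ̂₂ is physical.  With the adopted J₀ = −53.5 cm⁻¹ the vector angle
must be 72.8° (the supplement of the axis angle) for the lower state of a
mixed pair to borrow constructively, which is the configuration that
produces the enhancement resonance at ΔE ≈ ω₀.  The reference fixture uses
exactly this orientation; the orientation factor (1+2cos²θ)/15 is unchanged
by the convention since cos²(72.8°) = cos²(107.2°).

## Bath, lineshape and dephasing

The protein bath couples linearly and site-diagonally to the electronic
excitations (independent, identical baths per pigment; the explicit mode is
undamped, so purely vibrational coherences never decay).  The spectral
density is the overdamped Brownian oscillator C''(ω) = 2λΛω/(ω²+Λ²) with
Λ = 130 cm⁻¹, λ = 35 cm⁻¹ at T = 77 K.

The second-cumulant lineshape g(t) uses the standard pole expansion
(resonant Debye term plus Matsubara series).  The Matsubara tail is summed
in closed form with digamma functions — the raw series converges only as
1/n — and the dropped exp(−ν_n t) terms are modelled by a single
exponential whose rate makes the correction vanish quadratically at t = 0;
the result is verified against brute-force frequency-domain quadrature to
better than 10⁻⁴ relative.  Optical coherences of eigenstate α are damped
by g_α(t) = (P₁(α)² + P₂(α)²)·g(t) with P_n the electronic site
participations: delocalized states feel partial exchange narrowing because
only electronic populations couple to the bath.

Population transfer between eigenstates follows secular Redfield theory,
k_{a→b} = Σ_n |⟨a|K_n|b⟩|² (1+coth(ω_ab/2k_BT)) C''(ω_ab) (converted to
fs⁻¹), with K_n the projector onto site-n excited basis states; detailed
balance holds by construction.

**Relaxation-induced dephasing.**  The t₂ coherence ρ_αβ decays at
Γ_αβ = ½(k_{α→β} + k_{β→α}) — the population exchange *within* the pair,
which is the exact secular result for an isolated two-level pair.  The
alternative that also counts transfer to third states,
Γ = ½(Σ_γ k_{α→γ} + Σ_γ k_{β→γ}), is available as `mode="total"`.  The
within-pair form is the default because it reproduces the behavior
established for this system — a fitted ρ₁₂ lifetime slightly above 1 ps at ω₀ = 117 cm⁻¹
and the disappearance of >1 ps vibronic coherences above ω₀ ≈ 120 cm⁻¹ —
whereas the total-depopulation form halves the lifetime (≈0.55 ps) through
the near-degenerate 2↔3 exchange.  This is a genuine modelling choice with a
factor-two consequence; both forms are exposed and the sensitivity is worth
remembering when transferring the numbers to other parameter regimes.

## Non-rephasing diagonal signals

Delta-pulse (impulsive) excitation; only the two non-rephasing pathways
that oscillate in t₂ on the diagonal are propagated.  Excited-state
absorption does not reach the diagonal without explicit transport and is
omitted.  For the diagonal peak of the (α,β) coherence both optical
coherences evolve at the *same* line, so the signal separates:

* R1 (stimulated emission, vibronic coherence):
  S(ω₁,t₂) = A·D_α(ω₁)² · exp(−(iω_αβ + Γ_αβ) t₂), peak at the α line;
  A = |μ_{α,g0}|²|μ_{β,g0}|²(1+2cos²θ_αβ)/15.
* R4 (ground-state bleach, vibrational coherence, ν = 1):
  S(ω₁,t₂) = A·D_β(ω₁)² · exp(−iω₀t₂) with no decay, peak at the β line;
  A = |μ_{β,g0}|²|μ_{β,g1}|²(1+2cos²θ)/15.

D(ω) is the half-Fourier transform of exp(−iω_line t − g_α(t)), evaluated by
an exponential-segment (Filon-type) quadrature that is exact for piecewise
exponential integrands — the Markovian limit reproduces the analytic complex
Lorentzian to machine precision.  This reconstruction places the optimal
excitation frequencies at 12160 (R1) and 12296 cm⁻¹ (R4) for the reference
ensemble, i.e. at the strong lower-exciton line and at the vibronic β line
respectively.  The t₂ propagator carries no additional lineshape damping
beyond Γ_αβ.  Fuller treatments that retain lineshape cross terms between
the three time intervals add mixing-dependent amplitude that this separable
form misses, so single-realization resonance contrasts are conservative
here while ensemble-level quantities are robust.

**Monomer reference.**  All enhancement ratios are measured against the
vibrational coherence of isolated pigment 1: pre-factor
μ⁴FC₍₀₀₎²FC₍₀₁₎²·(3/15), optical coherences at the 0-0 line with the full
g(t), non-decaying t₂ oscillation at ω₀, and the same 80 cm⁻¹ FWHM Gaussian
disorder applied to its transition energy.  Broadening the reference is
essential to the absolute scale of the computed enhancements (≈20× for R1):
an unbroadened monomer line would cap them near 5.6.

## Disorder ensemble

Static disorder is sampled on the site-energy *gap*: ΔE ~ N(110 cm⁻¹,
80 cm⁻¹ FWHM), site-1 energy fixed, n = 2000 seeded realizations (standard
errors on the composition table < 0.005).  Composition tables average |c|²
with states numbered by energy within each realization — this matches the disorder-averaged
compositions established for these parameters (0.85/0.64/0.29/0.36); maximal-overlap tracking to the zero-disorder eigenvectors is
available (`ordering="overlap"`) and is the right choice when following one
coherence smoothly through a parameter sweep.  Signal ensembles fix the
coherence partner β by the dominant |e₁g₀⟩ character at the ensemble center
(β = 2 below the eigenstate-reordering mode frequency ≈135 cm⁻¹, β = 3
above).  The production ensemble path batches diagonalization, dipoles,
rates and the line quadrature (rotating-frame composite Simpson, phase per
step ≲ 0.4 rad) across all realizations; it is cross-checked against the
per-realization response functions to 0.5% in the tests.

What the generator does *not* emulate: correlated inter-site disorder,
disorder on the coupling or mode frequency, and site-1 energy disorder in
the dimer (the gap-sampling convention keeps the lower exciton line
artificially narrow relative to a fully site-disordered aggregate).  Tests
passing under this ensemble therefore validate the mechanism and its
parameter dependence, not absolute spectra of real FMO.

## Fits and derived quantities

t₂ traces (real part at ω₁ = ω_opt, the argmax of the initial-amplitude
diagonal cut with parabolic refinement) are fitted with a single
exponentially damped cosine A·e^(−t/τ)·cos(ωt+φ)+c, initialized from the
FFT peak; fits with τ > 50 ps are flagged non-decaying.  Synthetic-data
recovery is verified across ω ∈ [80,250] cm⁻¹ × τ ∈ [0.3,3] ps (ω within
1 cm⁻¹, τ within 10%).  Relative amplitudes A_r read the dimer envelope at
its first maximum after t' (local maxima with ≥1% prominence; a monotone
envelope reads at t' itself) against the monomer's global maximum.
Character thresholds (χ = 0.5 crossings, χ₁₂ = χ₁₃ equality) are located by
coarse scan plus Brent bisection to 0.1 cm⁻¹.

Default grids: t₁ ∈ [0,2] ps step 4 fs, t₂ ∈ [0,2] ps step 10 fs, ω₁ ∈
[11900,12650] cm⁻¹ step 3 cm⁻¹; mode-frequency sweeps use a 10 cm⁻¹ grid at
600 realizations per point.  These resolve the 117 cm⁻¹ mode (285 fs
period), the ~1 ps lifetimes, and the ~60 cm⁻¹ homogeneous linewidths, and
keep a full ensemble under a second of computation.

## Known limitations

* The separable propagator reconstruction reproduces every ensemble-level
  headline number except the R4 initial enhancement, which comes out ≈6.5
  rather than the literature ≈5, and it underestimates single-realization
  resonance contrast in the off-resonant (ω₀ = 185 cm⁻¹) case.
* The (1,3) pre-factor enhancement reaches ≈2.6 near the upper edge of its
  prevailingly-vibrational window versus a literature bound of 2.
* Secular Redfield is questionable for the near-degenerate 2↔3 pair at the
  reference gap (level spacing comparable to the rates); non-secular or
  modified-Redfield treatments are out of scope.
* ν_max = 1 by default (justified by S = 0.05); the basis builder accepts
  larger ν_max but the headline pathways only address the ν ≤ 1 levels.
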