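# Methods

## Physical model and assumptions

The package treats an array of N chromophores in the single-excitation
manifold. |A⟩ denotes chromophore A excited with all others in the ground
state; off-diagonal electronic couplings V_AB are assumed weak, so transfer
rates are second order in V (Fermi's golden rule) and coherences between
sites are discarded — populations obey a Pauli master equation. Each site
couples linearly to its own harmonic bath, characterized by a spectral
density J_A(ω) ≥ 0 tabulated on a dense frequency grid; baths on different
sites are uncorrelated. Energy flow into the environment is resolved by
reweighting the golden-rule time integral with the mode response factor
cos(ωt) − i coth(βħω/2) sin(ωt), which yields the dissipative potential
I_BA(ω) and from it mode- and frequency-resolved dissipation rate
constants. The framework conserves energy and satisfies detailed balance
exactly at the level of the defining integrals (see "Exact identities").

Conventions: energies and frequencies in cm⁻¹ (a mode of frequency ω
carries energy ω), time in fs, ħ = 5308.8 cm⁻¹·fs, k_B = 0.695035 cm⁻¹/K.
The reorganization energy is Λ = ∫ J(ω)/ω dω with no 1/π prefactor, and the
synthetic densities are generated in the same convention so their Λ values
are analytic by construction.

## Exact identities used as correctness anchors

Two identities pin all ħ placements and sign conventions, and the test
suite uses both as oracles:

1. **Marcus limit.** In the classical high-temperature regime the rate
   integral is dominated by short times, where Re g ≈ Λ k_B T t²/ħ² and
   Im g = O(t³); the explicit phase factor exp[−it(E_B−E_A+Λ_A+Λ_B)/ħ] then
   supplies the full reorganization shift and the rate reduces to
   (2π/ħ)|V|²(4πΛk_BT)^(−1/2) exp[−(E_B−E_A+Λ)²/(4Λk_BT)]. The
   implementation reproduces this within a few percent at 600 K on a Drude
   bath (the residual is the genuine quantum correction).

2. **Pairwise energy sum rule.** Using
   ∫(J/ω)[cos ωt − i coth sin ωt]dω = Λ − iħ ġ(t) and integrating the
   dissipative-potential integral by parts, one finds
   (2V²/ħ²)∫dω [J_A/ω + J_B/ω] I_BA(ω) = K_BA (E_A − E_B) **exactly, with
   bare site energies** (the boundary term is purely imaginary and drops
   under the real part). Consequently d/dt ∫E_Tot dω = −Σ_A E_A Ṗ_A and the
   accumulated total dissipation equals the electronic energy released at
   every time. The numerical residual of this identity (quadrature only) is
   ~10⁻⁵ relative.

A corollary worth knowing: for a *symmetric* pair (equal energies,
identical baths) I_BA(ω) vanishes pointwise, not merely in the weighted
integral — no frequency does net work over a completed symmetric transfer.

## Numerical scheme

- **Frequency integrals** (Λ, σ_slow, g(t), mode weights): composite
  trapezoid on the tabulated grid. ω → 0 limits of J/ω, J/ω² integrands are
  filled analytically from the slope of J (all are finite for ohmic-like
  densities); coth(x) uses the series 1/x + x/3 below x = 10⁻³ and
  saturates to 1 above x = 20.
- **Line-broadening functions** g(t) are evaluated on the uniform rate
  grid with a half-angle phasor recursion
  (1 − cos x = 2 sin²(x/2), sin x = 2 sin(x/2)cos(x/2)), re-synchronized
  with an exact complex exponential every `block_size` steps. The
  half-angle form avoids the short-time cancellation of 1 − cos and keeps
  Re g accurate at machine precision; results are independent of
  `block_size` to ~10⁻¹² relative. g is computed once per chromophore and
  reused across the entire disorder ensemble.
- **Rate and dissipative-potential time integrals**: trapezoid with fixed
  step Δt = 0.5 fs to a fixed horizon T_max (default 30 ps). A fixed
  horizon keeps ensemble runs deterministic; if the pairwise dephasing
  envelope |exp(−g_A−g_B)| at T_max exceeds 10⁻⁶, a warning (single run) or
  a hard ConvergenceError (ensemble) is raised instead of silently
  extending the grid. Because site-energy disorder only changes phase
  factors, the envelope check made once covers every realization.
- **Shared-cache rate evaluation.** For an ensemble, the per-pair
  dephasing factors, trapezoid weights and the (mode × time) trigonometric
  kernels are precomputed; each realization then costs one phase-factor
  evaluation per ordered pair plus two real matrix products. This is what
  makes 10³–10⁴ realizations affordable.
- **Discretization** of J_fast into n equally spaced modes (default 4000)
  assigns each mode the bin integral of J/ω, computed as differences of
  the cumulative trapezoid with interpolated bin edges, so Σ_j λ_j
  telescopes to Λ_fast exactly (rounding only).
- **Population propagation**: fixed-step RK4 with Δt = 0.5 fs. Because the
  dissipation function is linear in the populations, the accumulated
  dissipation E_A(ω,t) is obtained from running trapezoid integrals
  Q_A(t) = ∫P_A dt′ accumulated at full step resolution; snapshots between
  stored steps interpolate Q linearly. E is reported as a density per unit
  frequency on the mode grid, keeping the mode-resolved and
  frequency-resolved views consistent.
- **Splitting** J = J_slow + J_fast uses S(ω,ω*) = [1−(ω/ω*)²]² below ω*
  (C¹ at the cutoff). A double-subtraction (Sterbenz) construction makes
  J_slow + J_fast reproduce the parent density bit-exactly at every grid
  point. Default ω* = 20 cm⁻¹; a warning is issued if any chromophore's
  slow fraction exceeds 5 % of Λ, the selection criterion for the cutoff.

## Static disorder

The slow bath enters as quasi-static Gaussian noise on the site energies
with per-site width σ_slow = [∫ J_slow coth(βω/2) dω]^½, which reduces to
the classical (2 Λ_slow k_B T)^½. The ħ-placement here follows the
convention that reproduces that classical limit. Draws are independent
across sites and realizations (no cross-site correlation is assumed);
couplings are not modulated. Each draw is keyed on
(seed, realization_index) through a SeedSequence, realizations are
processed in fixed 25-realization blocks and block sums are reduced in
block order, so results are byte-identical for any worker count.
Ensemble means are arithmetic; the per-site frequency-integrated final
dissipation carries a standard error over realizations. Energy
conservation under disorder is checked against the ensemble mean of
Σ_A E′_A [P_A(0) − P_A(t_end)] evaluated with each realization's perturbed
energies.

## Synthetic environments and the built-in 7-site model

The generator emulates the shape of bacteriochlorophyll-specific
environments: a Drude background J_D = (2/π)λ_D γ_D ω/(ω²+γ_D²) for the
protein (default γ_D = 106 cm⁻¹, a 50 fs correlation time) plus underdamped
Brownian-oscillator peaks (2/π)λ_k γ_k ω ω_k²/[(ω²−ω_k²)²+γ_k²ω²], each
contributing exactly λ_k to Λ. The Drude part is renormalized for the
finite tabulation range (0, ω_max] (division by (2/π)·arctan(ω_max/γ_D)) so
the analytic Λ contract holds within 1 % on the default grid
(ω_max = 2000 cm⁻¹, 20,000 points — ≥50 points across a 5 cm⁻¹ peak).

The built-in model combines the 7-site Adolphs–Renger bacteriochlorophyll
Hamiltonian (stored as a versioned TSV fixture with provenance comments;
diagonal relative to the lowest site, since only differences enter) with
per-site recipes: mildly site-dependent backgrounds (λ_D = 32–38 cm⁻¹), a
shared in-plane-breathing peak at 200 cm⁻¹ (λ = 20, γ = 5), and a
far-detuned 1500 cm⁻¹ peak (λ = 15, γ = 10). At 300 K and ω* = 20 cm⁻¹ the
slow fractions are 3.1–3.4 % and σ_slow ≈ 30 cm⁻¹. Excitation starts on the
chlorosome-proximal site (Bchl1); a second preset starts on Bchl6 as a
robustness variant.

What the synthetic densities deliberately do **not** reproduce: the
10⁻⁴ cm⁻¹ frequency resolution and the 20+ vibrational features per pigment
of spectral densities derived from molecular dynamics, anharmonicity, or
correlated inter-site fluctuations. Passing tests therefore demonstrate the
correctness and thermodynamic consistency of the machinery and the
qualitative FMO phenomenology (low-frequency dominance, 200 cm⁻¹ channel,
transient energy borrowing on the uphill first hop, Bchl1 as net absorber
and Bchl3 as dominant dissipator), not quantitative agreement with any
particular measured complex.

## Problem sizes

Production defaults are Δt = 0.5 fs, T_max = 30 ps, 4000 modes, 5 ps of
dynamics with snapshots at 40/200/600/5000 fs, and 10,000 realizations.
The bundled example, the test suite and the acceptance script run the
7-site ensemble at 200 realizations, 500 modes and a 2 ps rate horizon —
with the synthetic peak widths (γ ≥ 5 cm⁻¹) the dephasing envelope at 2 ps
is far below the 10⁻⁶ criterion, and 200 realizations put standard errors
well below the effects being tested. The 30 ps horizon of the production
default serves much sharper spectral features than the synthetic recipes
contain.

## Known limitations

- Golden-rule (weak-coupling) rates: no coherent site–site dynamics, no
  higher-order corrections; accuracy degrades for strong electronic
  coupling or very slow baths.
- The Markovian master equation with frozen-disorder correction captures
  slow-bath effects only statistically; individual slow modes never
  exchange energy dynamically (their share of Λ is kept below 5 % by the
  cutoff criterion).
- Per-atom or spatially resolved energy flow, time-dependent Hamiltonians
  and anharmonic baths are out of scope.
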