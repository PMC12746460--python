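# dissipath

Frequency-, mode-, chromophore- and time-resolved **dissipation pathways** of
excitonic energy transfer in structured harmonic environments, for people who
want to know not just *how fast* an exciton hops between chromophores but
*where the released energy goes* — into which molecule's bath, into which
vibrational frequency, and when.

The motivating systems are pigment–protein complexes such as the
Fenna–Matthews–Olson (FMO) complex of green sulfur bacteria, where a photon's
excess energy is funneled from an antenna toward a reaction center while the
protein and the intramolecular vibrations of each bacteriochlorophyll absorb
(or transiently supply) the difference. A built-in 7-site FMO-like model with
synthetic, chromophore-specific structured spectral densities makes every
stage runnable out of the box.

## The model

Each chromophore *A* carries a localized excited state |A⟩ with site energy
E_A, electronic couplings V_AB, and a local harmonic bath described by a
spectral density J_A(ω). Populations follow the Pauli master equation

    dP_A/dt = Σ_B [ −K_BA P_A + K_AB P_B ]

with second-order (Fermi golden rule) rate constants

    K_BA = (2|V_AB|²/ħ²) Re ∫₀^∞ dt exp[−it(E_B−E_A+Λ_A+Λ_B)/ħ] exp[−g_A(t)−g_B(t)]

where Λ_A = ∫ J_A(ω)/ω dω is the reorganization energy and g_A(t) the complex
line-broadening function of bath A. The same integrand, reweighted by
cos(ωt) − i coth(βħω/2) sin(ωt), yields the **dissipative potential**
I_BA(ω): the energy a bath mode at frequency ω absorbs per unit
reorganization energy during the A→B transfer. From it follow mode-resolved
dissipation rate constants K^Aj_BA = (2|V_AB|²/ħ²) λ_Aj I_BA(ω_Aj),
dissipative spectral densities J^A_BA(ω) = (2|V_AB|²/ħ²)[J_A(ω)/ω] I_BA(ω),
the dissipation function D_A(ω,t) and its time integral E_A(ω,t), the
accumulated frequency-resolved dissipation per chromophore. These quantities
satisfy detailed balance and an exact pairwise energy sum rule
∫dω [J_A/ω + J_B/ω] I_BA · (2V²/ħ²) = K_BA (E_A − E_B), so the total
accumulated dissipation always equals the electronic energy released.

Non-Markovian low-frequency bath modes are handled by splitting each J(ω)
at a cutoff ω* (default 20 cm⁻¹, chosen so the slow part carries <5 % of Λ)
with the smooth weight S = [1−(ω/ω*)²]² and treating the slow part as frozen
Gaussian site-energy disorder of width σ_slow² = ∫ J_slow(ω) coth(βω/2) dω,
averaged over an ensemble of realizations that all share the (expensive)
fast-bath quantities.

Units throughout: energies and frequencies in cm⁻¹, time in fs
(ħ = 5308.8 cm⁻¹·fs, k_B = 0.695035 cm⁻¹/K).

## Worked example

A scaled-down 7-site run (200 disorder realizations, 500 modes, 2 ps rate
horizon — about 30 s on one core; the production defaults are 4000 modes,
30 ps and 10,000 realizations):

```bash
$ dissipath validate examples/fmo_quick.yaml
site           Lambda  Lambda_slow  slow_frac    sigma
Bchl1          66.956       2.1083      3.15%   29.653
Bchl2          67.956       2.1736      3.20%   30.109
...

$ dissipath simulate examples/fmo_quick.yaml --output fmo_quick_result.h5
wrote fmo_quick_result.h5
  Bchl1: accumulated dissipation -34.606 cm^-1
  Bchl2: accumulated dissipation +21.205 cm^-1
  Bchl3: accumulated dissipation +54.924 cm^-1
  Bchl4: accumulated dissipation +13.503 cm^-1
  Bchl5: accumulated dissipation +7.076 cm^-1
  Bchl6: accumulated dissipation -3.477 cm^-1
  Bchl7: accumulated dissipation +3.688 cm^-1
  total: +62.312 cm^-1
```

Reading: starting from Bchl1, the exciton relaxes toward Bchl3/Bchl4 and the
baths collectively absorb 62.3 cm⁻¹ — the electronic energy released. The
*negative* Bchl1 entry means its bath supplies energy throughout: the first
hop (Bchl1→Bchl2) is uphill and must be thermally activated, so the complex
borrows energy from the environment before netting dissipation (the total
accumulated dissipation at 40 fs is −25 cm⁻¹).

```bash
$ dissipath band-summary fmo_quick_result.h5 --edges 0,800,2000
band (cm^-1)          Bchl1      Bchl2      Bchl3   ...      total
[     0,   800)   -34.6061   +21.2008   +54.9198   ...   +62.3040
[   800,  2000)    -0.0003    +0.0039    +0.0042   ...    +0.0081
```

Modes above 800 cm⁻¹ contribute ~0.01 % of the dissipation despite carrying
real reorganization energy (each synthetic density has a 1500 cm⁻¹ peak with
λ = 15 cm⁻¹): they are far detuned from every electronic energy gap. The
dominant channel is the shared 200 cm⁻¹ peak, near-resonant with the gaps.

The same pipeline is scriptable:

```python
from dissipath import RunConfig, Simulation
result = Simulation(RunConfig(temperature_K=300.0, preset="fmo7",
                              n_modes=500, t_max_rate_fs=2000.0,
                              n_realizations=200, seed=1)).run()
print(result.ensemble.mean_field.frequency_integral())  # (site, snapshot)
```

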