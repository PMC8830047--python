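# corevib

Vibronically resolved X-ray absorption (XANES) and X-ray photoelectron
(XPS) spectra of molecules, computed from ground-state harmonic data and
per-state electronic-structure results — within the displaced harmonic
oscillator (DHO) model and beyond it (Duschinsky rotation and linear
Herzberg–Teller corrections) — plus a chunked active-space iteration scheme
for accumulating core-excited states over a pluggable electronic-structure
backend.

The package is aimed at spectroscopists and quantum chemists who already
have (or mock) core-excited/core-ionized state data — vertical energies,
Cartesian gradients at the ground-state minimum, transition dipoles or
Dyson norms, core-hole lifetimes — and want reproducible vibronic spectra
without re-running the electronic-structure engine.  The multireference
calculation itself (RASSCF/RASPT2 or any other method) is out of scope:
it is consumed as input data through a documented YAML bundle schema, or
emulated by the packaged synthetic fixtures.

## The model

For a final electronic state whose potential surface is the ground-state
harmonic well rigidly displaced (the DHO assumption), the Cartesian energy
gradient **g** of that state at the ground-state minimum fixes everything.
With mass-weighted normal modes *L_k* and frequencies ω_k (atomic units):

- per-mode gradient: g_k = L_k · M^(−1/2) **g** (translations/rotations
  projected out in the Eckart frame),
- dimensionless displacement: Δ_k = −g_k / ω_k^(3/2),
- Huang–Rhys factor: S_k = Δ_k²/2 = g_k² / (2ω_k³),
- reorganization energy: λ = Σ_k S_k ħω_k, 0-0 energy: E₀₀ = E_vert − λ.

At 0 K the absorption is the multi-mode Poisson progression
I(n₁,n₂,…) = I₀ · Π_k e^(−S_k) S_k^(n_k)/n_k! at E₀₀ + Σ_k n_k ħω_k, with
I₀ = |μ|² (XANES) or the Dyson norm (XPS, sudden approximation).  Each line
is dressed with a Lorentzian of FWHM Γ = ħ/τ from the core-hole lifetime τ
plus an instrument Gaussian; an equivalent time-domain
(generating-function) route is implemented and tested against the
sum-over-states route.  Beyond the DHO, excited-state frequencies and mode
mixing enter through the Duschinsky relation Q′ = J Q + K, with
multidimensional Franck–Condon overlaps ⟨0|n′⟩ from a Doktorov-class
recursion and Herzberg–Teller intensities
|μ₀⟨0|n′⟩ + Σ_k (∂μ/∂q_k)⟨0|q_k|n′⟩|², all validated against explicit
numerical quadrature.

Spectrum assembly mirrors standard core-level practice: bound states below
the ionization threshold get full lineshapes, states above it are rendered
as sticks; XPS spectra are normalized so the most intense band equals 1;
gas-phase conformers are averaged with Boltzmann weights exp(−ΔG/RT).

## Worked example

`examples/01_dho_xanes.py` builds a three-mode synthetic molecule with
prescribed Huang–Rhys factors and assembles its XANES band:

```
transition: 1s -> pi* (three-mode)   E_vert = 290.000 eV
lifetime 2.0 fs -> Lorentzian FWHM 0.3291 eV
  mode 1:   600.0 cm^-1   S = 0.300   lambda =   22.3 meV
  mode 2:  1200.0 cm^-1   S = 0.500   lambda =   74.4 meV
  mode 3:  2400.0 cm^-1   S = 0.150   lambda =   44.6 meV
total reorganization lambda = 0.1413 eV
0-0 energy E_00 = E_vert - lambda = 289.8587 eV
504 Franck-Condon lines; intensity-weighted mean 290.0000 eV (= E_vert, the vibronic sum rule)
lifetime-broadened band maxima (eV): 289.930
```

The recovered S_k are exactly the requested ones (the generator solves the
inverse problem), the intensity-weighted mean of the sticks equals the
vertical energy — the Poisson mean sum rule — and the single broadened
maximum sits between E₀₀ and E_vert because the 2 fs lifetime merges the
progression.  The other examples cover XPS with conformer averaging
(`02`), the DHO → +Duschinsky → +Herzberg–Teller ladder in which the third
vibronic band splits into two sub-peaks (`03`), and the active-space
iterator on a toy configuration model (`04`).

A thin CLI wraps the same library calls:

```
corevib synth --preset formaldehyde-like -o ch2o.yaml
corevib xanes ch2o.yaml --model fcht --grid 283:290:0.005 -o ch2o_xanes.tsv
```

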