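# Methods

## Scope and model

`corevib` simulates vibronically resolved core-level spectra (XANES, XPS)
at 0 K from (a) a ground-state harmonic model — geometry, masses,
frequencies, normal modes — and (b) per-electronic-state records: vertical
energy, Cartesian gradient at the ground-state minimum, transition dipole
(absorption) or Dyson norm (ionization), core-hole lifetime, and optionally
an excited-state harmonic model.  The electronic-structure calculation that
produces these inputs is deliberately outside the package; any engine that
can emit them (directly or through the YAML bundle schema in
`corevib.qm_io`) can drive the simulator.

The baseline vibronic model is the displaced harmonic oscillator (DHO):
initial and final potential surfaces are identical harmonic wells differing
only in equilibrium position.  Its single input per mode is the projected
gradient g_k, giving Δ_k = −g_k/ω_k^{3/2}, S_k = Δ_k²/2,
λ_k = S_k ħω_k and E₀₀ = E_vert − λ.  The sign convention (negative
gradient → positive displacement) matters only once Herzberg–Teller
cross-terms appear; it is fixed here and used consistently by the
synthetic generator and the Duschinsky module.

## Units and constants

All internal computation uses Hartree atomic units; I/O uses eV, cm⁻¹, fs,
Å and amu.  Constants are pinned in `corevib.constants` (1 Hartree =
27.211386 eV, 1 eV = 8065.544 cm⁻¹, ħ = 0.6582120 eV·fs,
R = 8.314462 J mol⁻¹ K⁻¹) so that every number in the test suite is
reproducible from one table.  Dimensionless mode coordinates
q_k = √(ω_k) Q_k are used for both the Duschinsky shift vector K and the
transition-dipole derivatives ∂μ/∂q_k — stating this once removes the
classic silent-√2 ambiguity between codes.

## Gradient projection

Gradients from electronic-structure codes carry small translational and
rotational contaminations (especially when computed by finite differences).
Before mode projection the mass-weighted gradient is cleaned with an
Eckart-frame projector built from the three translations and up to three
infinitesimal rotations about the center of mass (null rotations dropped by
SVD, which also handles linear molecules).  Which cleanup the reference
workflows used is generally unreported; the projector choice is this
package's own and is covered by a rotation-invariance test (reorganization
energies invariant to 1e-9 eV under random rigid rotations of geometry,
modes and gradient jointly).

## Lineshapes

Two equivalent routes produce broadened spectra:

* **Sum over states.**  Multi-mode Poisson sticks, truncated per mode once
  the cumulative Poisson weight reaches (1−ε)^(1/M) (default ε = 1e-4),
  then padded by three further quanta so that the discarded tail is
  negligible in the first moment as well as the zeroth; hard cap 50 quanta
  per mode; lexicographic enumeration order for determinism.  Sticks are
  convolved with a normalized Voigt evaluated through the complex error
  function (`scipy.special.voigt_profile`), which degrades exactly to the
  Gaussian/Lorentzian limits — no numerical convolution grid error.
* **Time domain.**  σ(E) ∝ Re ∫₀^∞ dθ e^{i(E−E₀₀)θ}
  exp[−Σ_k S_k(1−e^{−iħω_kθ})] e^{−Γθ/2} e^{−σ²θ²/2} with θ = t/ħ,
  sampled so the Nyquist range covers the largest energy offset on the
  requested grid and the correlation function has decayed below 1e-9,
  evaluated by FFT and interpolated onto the grid.  Small negative ringing
  (≪ machine-level of the peak) is clipped.

Route equivalence is enforced at relative L∞ < 1e-3 on three-mode
fixtures.  A grid step coarser than one fifth of the total width is
rejected rather than silently aliased.  Moments use the Poisson identities
mean = E₀₀ + λ = E_vert and variance = Σ_k S_k (ħω_k)² as validation
instruments.

No ω or E prefactor multiplies the intensities: spectra are reported in
relative units and routinely normalized, so any prefactor convention would
be invisible; recording the choice keeps comparisons reproducible.

Only the vibrational ground state is populated initially (0 K): the modes
that matter at core edges (> 1000 cm⁻¹) are thermally unpopulated at
relevant temperatures.  Hot bands and temperature-dependent lineshapes are
out of scope.

## Beyond the DHO

With excited-state harmonic data present, the package builds
Q′ = J Q + shift with J = L′ᵀL after mass-weighted Kabsch (Eckart)
alignment of the two geometries — whether reference implementations apply
axis switching before building J is usually unstated; alignment is applied
here and recorded as a package decision.  K is reported as the
dimensionless ground-state-mode position of the excited-state minimum, so
for J = I and equal frequencies S_k = K_k²/2 exactly.

Franck–Condon overlaps ⟨0|n′⟩ are generated by a Gaussian
generating-function recursion (Doktorov-class, as used by dedicated FC
codes): writing the overlap integrand as a Gaussian times Hermite
polynomials, the Hermite three-term recurrence plus Gaussian integration by
parts yields a two-term recursion over excited-state quanta; the same
table gives ⟨0|q_k|n′⟩ through the Gaussian first-moment identity, and
Herzberg–Teller intensities follow as |μ₀⟨0|n′⟩ + Σ_k ∂μ/∂q_k ⟨0|q_k|n′⟩|².
The correctness contract is *quadrature equivalence*: every overlap and HT
matrix element for ≤ 2-mode fixtures must match dense numerical quadrature
of explicit harmonic-oscillator wavefunctions to 1e-8 (the oracle lives in
the test suite and the acceptance script and shares no code with the
recursion).  Closed-form anchors: the Poisson limit for J = I with equal
frequencies, and |⟨0|0′⟩|² = 2√2/3 for a single mode with ω′ = 2ω.

The dense overlap table grows combinatorially; beyond 10 mixed modes the
module refuses and a block-diagonal treatment of J is required.  Quadratic
Herzberg–Teller terms and finite-temperature Duschinsky spectra are out of
scope.

When a distinct excited-state well exists, the band origin also acquires a
zero-point correction ΔZPE = ½ Σ_k ħ(ω′_k − ω_k), positive when the final
well stiffens (the mechanism behind, e.g., blue-shifted ionization
thresholds).  Excited- and ground-state modes are paired by
maximum-overlap assignment of mass-weighted mode vectors, falling back to
sorted-frequency order with a warning when the best overlap drops below
0.5 — mode pairing between states is itself an under-specified operation
and this greedy criterion is a deliberate, simple choice.

## Spectrum assembly

XANES: states below the ionization threshold contribute broadened vibronic
envelopes, each with its own lifetime Lorentzian Γ = ħ/τ; states above it
appear as sticks only (they are shorter-lived and continuum-broadened in
ways no bound-state lineshape captures), with an opt-in wider Lorentzian
for continuum-like display.  XPS: envelopes are scaled by Dyson norms
(sudden approximation), optionally ΔZPE-shifted, and the assembled
spectrum is normalized to unit maximum — matching the convention of
scaling to the most intense measured band; XANES is left unnormalized by
default.  Conformer averaging uses weights exp(−ΔG/RT); both the raw
ratio relative to the reference conformer and the normalized fractions are
returned, because "population percentages" in the literature often mean
the former (for ΔG = 6.535 kJ/mol at 473 K the ratio is 0.190 ≈ 20% while
the two-state fraction is 0.160).  Rigid shifts are available, logged in
metadata, and default to zero.

## Synthetic fixtures

`corevib.synthetic` solves the inverse problem: given target Huang–Rhys
factors it builds the mode-space gradient g_k = ω_k^{3/2}√(2S_k) and embeds
it in a Cartesian frame of unit-mass pseudo-atoms at seeded random
non-collinear positions.  Collinear embeddings would make the rotational
part of the Eckart space degenerate about the molecular axis, so
non-collinear placement is used even though it costs one extra atom of
bookkeeping; the embedding is non-physical by construction — only
mode-space quantities matter downstream.  Excited-state models realizing a
planned Duschinsky transform (per-mode frequency scaling, pairwise mixing
angle, displacement) and per-mode transition-dipole derivatives can be
attached.  What the generator does *not* emulate: real electronic-structure
energetics, anharmonicity, mode-mixing beyond one rotation plane, state
couplings.  Passing tests therefore demonstrate the correctness of the
vibronic machinery on exactly-harmonic inputs, not the fidelity of any
quantum-chemistry method.

The `formaldehyde-like` preset uses the C=O and C–H symmetric stretch
frequencies (1753 and 2970 cm⁻¹) with S = (0.9, 0.1), a 20° mixing angle
and excited-state frequency scales (0.95, 0.80), chosen so that the
qualitative beyond-DHO phenomenon — the third vibronic band splitting into
a pair of sub-peaks once frequency change and mode mixing are enabled —
appears at a 0.04 eV Lorentzian + 0.05 eV Gaussian analysis broadening.
The preset lifetime (4 fs) represents the fast end of typical
second-row-element core-hole lifetimes (1–4 fs).

The toy configuration model (`ToyElectronicModel`) has one core→virtual
configuration per virtual orbital, a symmetric coupling matrix, and exact
states by dense diagonalization; with block-diagonal couplings aligned to
the iteration chunks the chunked accumulation must reproduce the full-space
result exactly, which is the iterator's acceptance property.

## Active-space iteration

The iterator is orchestration and bookkeeping around a pure backend
contract (core id, occupied ids, virtual ids → states with energies,
intensities, dominant-configuration labels).  Virtuals are consumed in
energy-ordered chunks of n; the minimal-active-space virtuals (typically
the LUMO) join every computation, so their states are recomputed each
iteration and removed by duplicate matching — identity is label equality
plus energy agreement within a tolerance (1e-6 eV for the toy backend;
a looser 0.05 eV preset is appropriate for real-data noise).  How
shake-up duplicates should be matched when their dominant configuration
drifts between chunks is genuinely open; label matching is the implemented
default.  Convergence is declared when an iteration contributes no new
post-dedup state inside the energy window of interest.  Orbital
rotation/locking between iterations is a backend responsibility and is
modeled as set bookkeeping only.  The scheme ignores couplings between
states computed in different iterations by construction — hence exactness
for block-diagonal couplings and approximation otherwise.

## Numerical choices and problem sizes

* Mode-vector orthonormality (mass-weighted metric) enforced to 1e-6 on
  read, after renormalization; re-validation is idempotent.
* Duschinsky recursion: dense table, lexicographic fill; singular
  transformation matrices rejected via sign of the log-determinant.
* Voigt via complex error function; degenerate (zero-width) profiles are
  an error rather than a delta-function surprise.
* Dedup tie-break: earliest iteration wins, then input order.
* Test and acceptance problem sizes — 200 random Poisson fixtures, 50
  moment fixtures, 3 route-equivalence fixtures, 2 quadrature fixtures at
  nmax 4 on 401² grids, 5 recovery fixtures, a 7-orbital toy model — keep
  the full suite under half a minute while exercising every code path;
  they are the package's chosen verification sizes, not statistical
  samples.

## Known limitations

Dissociative or strongly anharmonic final-state surfaces break the DHO
assumption (the classic failure cases at, e.g., fluorine K-edges); the
package does not treat them but flags modes whose reorganization energy
exceeds a configurable threshold as "DHO-suspect" diagnostics.  Initial
vibrational temperature, RIXS/resonant-emission lineshapes, edge-jump and
semicontinuum backgrounds, and automatic selection of occupied orbitals
for the iterator are all out of scope.
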