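"""XPS of two gas-phase conformers, Boltzmann-averaged at 473 K.

Each conformer contributes a Dyson-norm-weighted vibronic envelope at its
core-electron binding energy; the populations follow from the Gibbs
free-energy difference (6.535 kJ/mol, the value for the two most populated
glycine conformers at the sublimation temperature).
"""

import numpy as np

import corevib as cv
from corevib import assembly, lineshape, synthetic

GRID = lineshape.make_grid(402.0, 410.0, 0.01)
BROADENING = cv.BroadeningSpec(gaussian_fwhm=0.3)


def conformer_bundle(vertical_ip, seed):
    spec = synthetic.FixtureSpec(
        n_modes=2, frequencies=(900.0, 1650.0), target_huang_rhys=(0.25, 0.45),
        vertical_energy=vertical_ip, lifetime=3.0, kind="core-cation", seed=seed,
    )
    return synthetic.make_bundle(spec)


spec_a = assembly.assemble_xps(conformer_bundle(405.0, seed=1), BROADENING, GRID, normalize=False)
spec_b = assembly.assemble_xps(conformer_bundle(406.1, seed=2), BROADENING, GRID, normalize=False)

ratios, fractions = assembly.boltzmann_weights([0.0, 6.535], temperature=473.0)
print(f"Boltzmann ratio B/A  = {ratios[1]:.3f}  (~{100 * ratios[1]:.0f}% of A's population)")
print(f"normalized fractions = A {fractions[0]:.3f} / B {fractions[1]:.3f}")

combined = assembly.normalize_max(assembly.combine_conformers([spec_a, spec_b], fractions))
peaks = lineshape.count_peaks(combined, min_rel_height=0.02)
print("averaged N 1s XPS band maxima (eV):", ", ".join(f"{p:.2f}" for p in peaks))
print("the minority conformer appears as the weak high-binding-energy shoulder;")
print("the spectrum is normalized so the most intense band equals 1.")
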