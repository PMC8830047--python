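"""XANES/XPS assembly, IP-threshold rendering, Boltzmann conformer averaging."""

import numpy as np
import pytest

import corevib as cv
from corevib import assembly, dho, lineshape, synthetic


GRID = lineshape.make_grid(282.0, 298.0, 0.01)
BR = cv.BroadeningSpec(gaussian_fwhm=0.2)


def xanes_bundle(vertical=288.0, s=0.0, ip=None, extra_states=()):
    b = synthetic.make_bundle(
        synthetic.FixtureSpec(1, (1200.0,), (s,), vertical_energy=vertical, lifetime=2.0, seed=13)
    )
    return cv.CalculationBundle(b.harmonic, b.states + tuple(extra_states), ip_threshold=ip)


def test_single_undisplaced_state_is_one_lorentzian_band():
    b = xanes_bundle(s=0.0)
    spec, sticks = assembly.assemble_xanes(b, "dho", BR, GRID)
    assert len(sticks) == 0
    peaks = lineshape.count_peaks(spec)
    assert len(peaks) == 1
    assert peaks[0] == pytest.approx(288.0, abs=2 * spec.step)


def test_states_straddling_ip_are_partitioned():
    b0 = xanes_bundle(s=0.2)
    above = cv.ElectronicStateRecord(
        label="above-IP", kind="core-excited", vertical_energy=294.0,
        gradient=np.zeros(3 * b0.harmonic.n_atoms), lifetime=1.0, tdm=[0.0, 0.0, 1.0],
    )
    b = cv.CalculationBundle(b0.harmonic, b0.states + (above,), ip_threshold=291.0)
    spec, sticks = assembly.assemble_xanes(b, "dho", BR, GRID)
    # grid holds only the sub-IP state's intensity
    below_only, _ = assembly.assemble_xanes(
        cv.CalculationBundle(b0.harmonic, b0.states), "dho", BR, GRID
    )
    assert np.allclose(spec.intensity, below_only.intensity, rtol=1e-12)
    # stick list holds exactly the supra-IP line
    assert len(sticks) == 1
    assert sticks.energies[0] == pytest.approx(294.0)
    assert all("above-IP" in l for l in sticks.labels)


def test_assembly_is_additive_over_states():
    b0 = xanes_bundle(s=0.3)
    doubled = cv.CalculationBundle(b0.harmonic, b0.states + b0.states)
    one, _ = assembly.assemble_xanes(b0, "dho", BR, GRID)
    two, _ = assembly.assemble_xanes(doubled, "dho", BR, GRID)
    assert np.allclose(two.intensity, 2 * one.intensity, rtol=1e-12)


def test_empty_assembly_raises():
    b0 = xanes_bundle(s=0.0)
    cation = cv.ElectronicStateRecord(
        label="ion", kind="core-cation", vertical_energy=293.0,
        gradient=np.zeros(3 * b0.harmonic.n_atoms), lifetime=2.0, dyson_norm=0.9,
    )
    with pytest.raises(cv.ConsistencyError):
        assembly.assemble_xanes(cv.CalculationBundle(b0.harmonic, (cation,)), "dho", BR, GRID)
    with pytest.raises(cv.ConsistencyError):
        assembly.assemble_xps(b0, BR, GRID)


def cation_bundle(dysons=(1.0,), verticals=(405.0,), s=0.0):
    b = synthetic.make_bundle(
        synthetic.FixtureSpec(1, (1200.0,), (s,), vertical_energy=verticals[0],
                              lifetime=2.0, kind="core-cation", seed=14)
    )
    states = []
    for dn, ev in zip(dysons, verticals):
        s0 = b.states[0]
        states.append(cv.ElectronicStateRecord(
            label=f"ip-{ev}", kind="core-cation", vertical_energy=ev,
            gradient=s0.gradient, lifetime=s0.lifetime, dyson_norm=dn,
        ))
    return cv.CalculationBundle(b.harmonic, tuple(states))


XPS_GRID = lineshape.make_grid(398.0, 414.0, 0.01)


def test_xps_single_state_unit_height():
    spec = assembly.assemble_xps(cation_bundle(), BR, XPS_GRID)
    assert spec.intensity.max() == pytest.approx(1.0)
    peaks = lineshape.count_peaks(spec)
    assert len(peaks) == 1 and peaks[0] == pytest.approx(405.0, abs=2 * spec.step)


def test_xps_dyson_scaling_and_normalization():
    b = cation_bundle(dysons=(1.0, 0.5), verticals=(404.0, 409.0))
    br = cv.BroadeningSpec(gaussian_fwhm=0.2, profile="gaussian")
    raw = assembly.assemble_xps(b, br, XPS_GRID, normalize=False)
    i1 = raw.intensity[np.argmin(np.abs(raw.grid - 404.0))]
    i2 = raw.intensity[np.argmin(np.abs(raw.grid - 409.0))]
    assert i1 / i2 == pytest.approx(2.0, rel=1e-3)
    normed = assembly.assemble_xps(b, BR, XPS_GRID)
    assert normed.intensity.max() == pytest.approx(1.0)


def test_xps_band_mean_equals_vertical_ip():
    """Moment rule survives assembly: envelope mean = vertical binding energy."""
    spec = assembly.assemble_xps(
        cation_bundle(s=0.6),
        cv.BroadeningSpec(gaussian_fwhm=0.2, profile="gaussian"),
        XPS_GRID,
        epsilon=1e-9,
    )
    _, mean, _ = lineshape.spectral_moments(spec)
    assert mean == pytest.approx(405.0, abs=5e-4)


def test_boltzmann_weight_of_glycine_b_conformer():
    """dG = 6.535 kJ/mol at 473 K gives a ~19% raw ratio, i.e. the 'about
    20%' population quoted for gas-phase conformer B."""
    ratios, fractions = assembly.boltzmann_weights([0.0, 6.535], 473.0)
    assert ratios[1] == pytest.approx(0.190, abs=5e-4)
    assert round(100 * ratios[1], -1) == 20.0
    assert fractions[1] == pytest.approx(ratios[1] / (1 + ratios[1]), rel=1e-12)


def test_boltzmann_limits():
    _, f_eq = assembly.boltzmann_weights([0.0, 0.0], 300.0)
    assert np.allclose(f_eq, [0.5, 0.5])
    _, f_hot = assembly.boltzmann_weights([0.0, 50.0], 1e9)
    assert np.allclose(f_hot, [0.5, 0.5], atol=1e-6)
    with pytest.raises(cv.ConsistencyError):
        assembly.boltzmann_weights([0.0], -1.0)


def test_combine_conformers_linearity():
    a, _ = assembly.assemble_xanes(xanes_bundle(vertical=287.0, s=0.2), "dho", BR, GRID)
    b, _ = assembly.assemble_xanes(xanes_bundle(vertical=289.0, s=0.1), "dho", BR, GRID)
    w = (0.8, 0.2)
    comb = assembly.combine_conformers([a, b], w)
    assert comb.integral() == pytest.approx(w[0] * a.integral() + w[1] * b.integral(), rel=1e-9)
    only_a = assembly.combine_conformers([a, b], (1.0, 0.0))
    assert np.allclose(only_a.intensity, a.intensity)
    same = assembly.combine_conformers([a, a], (0.3, 0.7))
    assert np.allclose(same.intensity, a.intensity)


def test_combine_conformers_validation():
    a, _ = assembly.assemble_xanes(xanes_bundle(), "dho", BR, GRID)
    other = cv.GridSpectrum(lineshape.make_grid(0.0, 1.0, 0.01), np.zeros(101))
    with pytest.raises(cv.ConsistencyError):
        assembly.combine_conformers([a, other], (0.5, 0.5))
    with pytest.raises(cv.ConsistencyError):
        assembly.combine_conformers([a, a], (0.5, 0.2))


def test_shift_is_invertible_and_exact_on_sticks():
    spec, _ = assembly.assemble_xanes(xanes_bundle(s=0.3), "dho", BR, GRID)
    assert assembly.apply_shift(spec, 0.0) is spec
    back = assembly.apply_shift(assembly.apply_shift(spec, 0.1), -0.1)
    inner = slice(50, -50)
    assert np.allclose(back.intensity[inner], spec.intensity[inner], atol=2e-3 * spec.intensity.max())
    sticks = cv.StickSpectrum([288.0], [1.0], ("a",))
    moved = assembly.apply_shift(sticks, 0.1)
    assert moved.energies[0] == 288.1
    assert moved.intensities[0] == 1.0


def test_normalization_idempotent_and_scale_invariant():
    spec, _ = assembly.assemble_xanes(xanes_bundle(s=0.3), "dho", BR, GRID)
    n1 = assembly.normalize_max(spec)
    n2 = assembly.normalize_max(n1)
    assert np.allclose(n1.intensity, n2.intensity)
    scaled = spec.with_intensity(spec.intensity * 37.0)
    assert np.allclose(assembly.normalize_max(scaled).intensity, n1.intensity)


def test_model_level_beyond_dho_requires_es_harmonic():
    with pytest.raises(cv.ConsistencyError):
        assembly.assemble_xanes(xanes_bundle(), "duschinsky", BR, GRID)


def test_fcht_assembly_runs_on_preset():
    b = synthetic.make_bundle(synthetic.preset_spec("formaldehyde-like"))
    grid = lineshape.make_grid(283.0, 290.0, 0.01)
    spec, _ = assembly.assemble_xanes(b, "fcht", BR, grid)
    assert spec.integral() > 0
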