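"""Duschinsky rotation, multidimensional FC integrals, Herzberg-Teller terms.

Every overlap and HT matrix element is checked against the quadrature
oracle (explicit harmonic-oscillator wavefunctions on dense grids)."""

import itertools
import math

import numpy as np
import pytest

import corevib as cv
from corevib import dho, duschinsky, lineshape, synthetic


def two_mode_transform(angle_deg=25.0, scales=(1.1, 0.9), s_target=(0.4, 0.1)):
    spec = synthetic.FixtureSpec(
        n_modes=2, frequencies=(1753.0, 2970.0), target_huang_rhys=s_target,
        duschinsky_angle=math.radians(angle_deg), es_frequency_scale=scales, seed=4,
    )
    b = synthetic.make_bundle(spec)
    return duschinsky.build_duschinsky(b.harmonic, b.states[0].es_harmonic)


def test_identical_models_give_identity_transform():
    b = synthetic.make_bundle(synthetic.FixtureSpec(2, (800.0, 1600.0), (0.2, 0.3), seed=1))
    tr = duschinsky.build_duschinsky(b.harmonic, b.harmonic)
    assert np.allclose(tr.J, np.eye(2), atol=1e-12)
    assert np.allclose(tr.K, 0.0, atol=1e-12)


def test_pure_displacement_recovered_in_shift_vector():
    spec = synthetic.FixtureSpec(
        2, (800.0, 1600.0), (0.32, 0.0), es_frequency_scale=(1.0, 1.0), seed=6
    )
    b = synthetic.make_bundle(spec)
    tr = duschinsky.build_duschinsky(b.harmonic, b.states[0].es_harmonic)
    assert np.allclose(tr.J, np.eye(2), atol=1e-9)
    assert tr.K[0] == pytest.approx(-math.sqrt(2 * 0.32), abs=1e-9)
    assert tr.K[1] == pytest.approx(0.0, abs=1e-9)


def test_planned_rotation_angle_recovered():
    tr = two_mode_transform(angle_deg=30.0, scales=(1.0, 1.0), s_target=(0.0, 0.0))
    angle = math.degrees(math.atan2(tr.J[1, 0], tr.J[0, 0]))
    assert angle == pytest.approx(30.0, abs=1e-8)
    assert tr.orthogonality_deviation < 1e-10


def test_atom_mismatch_rejected():
    b1 = synthetic.make_bundle(synthetic.FixtureSpec(1, (800.0,), (0.1,), seed=1))
    b2 = synthetic.make_bundle(synthetic.FixtureSpec(4, (500.0, 800.0, 1200.0, 1600.0), (0.1,) * 4, seed=1))
    with pytest.raises(cv.ConsistencyError):
        duschinsky.build_duschinsky(b1.harmonic, b2.harmonic)


def test_identity_transform_reduces_to_poisson():
    """J = I, equal frequencies: |<0|n'>|^2 are the Poisson factors of
    S = K^2/2 per mode."""
    k = np.array([-1.0, 0.6])
    tr = cv.DuschinskyTransform(np.eye(2), k, np.array([1000.0, 2000.0]), np.array([1000.0, 2000.0]))
    tab = duschinsky.fc_integrals(tr, 10)
    s = k**2 / 2
    for n1, n2 in itertools.product(range(6), repeat=2):
        expected = (
            math.exp(-s[0]) * s[0]**n1 / math.factorial(n1)
            * math.exp(-s[1]) * s[1]**n2 / math.factorial(n2)
        )
        assert tab.overlaps[n1, n2] ** 2 == pytest.approx(expected, rel=1e-10, abs=1e-300)


def test_frequency_doubling_closed_form():
    """1 mode, w' = 2w, no shift: |<0|0'>|^2 = 2 sqrt(2)/3."""
    tr = cv.DuschinskyTransform(np.eye(1), np.zeros(1), np.array([1000.0]), np.array([2000.0]))
    tab = duschinsky.fc_integrals(tr, 8)
    assert tab.overlaps[(0,)] ** 2 == pytest.approx(2 * math.sqrt(2) / 3, rel=1e-12)
    # odd levels are dark without displacement
    assert tab.overlaps[(1,)] == pytest.approx(0.0, abs=1e-12)


def test_mixed_two_mode_overlaps_match_quadrature(quad_oracle):
    tr = two_mode_transform()
    tab = duschinsky.fc_integrals(tr, 4)
    for quanta in itertools.product(range(5), repeat=2):
        ref = quad_oracle(tr, quanta)
        assert tab.overlaps[quanta] == pytest.approx(ref, abs=1e-8)


def test_ht_matrix_elements_match_quadrature(quad_oracle):
    tr = two_mode_transform(angle_deg=35.0, scales=(0.9, 1.15), s_target=(0.5, 0.2))
    tab = duschinsky.fc_integrals(tr, 3)
    for k in range(2):
        for quanta in itertools.product(range(4), repeat=2):
            ref = quad_oracle(tr, quanta, q_mode=k)
            assert tab.q_overlaps[(k,) + quanta] == pytest.approx(ref, abs=1e-8)


def test_single_mode_displaced_ht_matches_quadrature(quad_oracle):
    tr = cv.DuschinskyTransform(np.eye(1), np.array([0.9]), np.array([1400.0]), np.array([1700.0]))
    tab = duschinsky.fc_integrals(tr, 8)
    for n in range(8):
        assert tab.overlaps[(n,)] == pytest.approx(quad_oracle(tr, (n,)), abs=1e-8)
        assert tab.q_overlaps[(0, n)] == pytest.approx(quad_oracle(tr, (n,), q_mode=0), abs=1e-8)


def test_overlap_completeness_monotone():
    tr = two_mode_transform()
    comps = [duschinsky.fc_integrals(tr, n).completeness() for n in (2, 4, 6, 8)]
    assert all(b >= a - 1e-15 for a, b in zip(comps, comps[1:]))
    assert comps[-1] >= 0.999


def test_condon_reduction_reproduces_fc_sticks():
    """dmu = 0, J = I, matched frequencies: line-for-line agreement with the
    Poisson stick generator."""
    freqs = np.array([1100.0, 2100.0])
    s = np.array([0.45, 0.2])
    lam = float((s * freqs / 8065.544).sum())
    p = cv.DHOParameters(freqs, np.sqrt(2 * s), s, s * freqs / 8065.544,
                         lam, 290.0, 290.0 - lam)
    ref = lineshape.fc_sticks(p, 1.0, epsilon=1e-10)
    tr = duschinsky.dho_transform(p)
    got = duschinsky.fcht_sticks(
        tr, cv.HTExpansion([1.0, 0.0, 0.0], np.zeros((2, 3))), p.adiabatic_energy_ev, 12
    )
    ref_map = {round(e, 9): i for e, i in zip(ref.energies, ref.intensities)}
    for e, i in zip(got.energies, got.intensities):
        key = min(ref_map, key=lambda k: abs(k - e))
        if abs(key - e) < 1e-10:
            assert i == pytest.approx(ref_map[key], rel=1e-10, abs=1e-13)


def test_pure_ht_line_carries_half_dmu_squared():
    """mu0 = 0, undisplaced single mode: only the 0->1 line is bright, with
    intensity |dmu|^2/2 (since <0|q|1> = 1/sqrt(2))."""
    tr = cv.DuschinskyTransform(np.eye(1), np.zeros(1), np.array([1500.0]), np.array([1500.0]))
    ht = cv.HTExpansion([0.0, 0.0, 0.0], [[0.3, 0.0, 0.0]])
    sticks = duschinsky.fcht_sticks(tr, ht, 290.0, 6)
    bright = {lab: i for lab, i in zip(sticks.labels, sticks.intensities) if i > 1e-20}
    assert set(bright) == {"v1'^1"}
    assert bright["v1'^1"] == pytest.approx(0.3**2 / 2, rel=1e-12)


def test_generic_ht_intensities_match_quadrature(quad_oracle):
    """1-mode displaced, frequency-shifted case: full FCHT line intensities
    against quadrature of mu(q) psi_0 psi_n integrals."""
    tr = cv.DuschinskyTransform(np.eye(1), np.array([-0.8]), np.array([1300.0]), np.array([1560.0]))
    mu0 = np.array([0.9, 0.1, 0.0])
    dmu = np.array([[0.25, -0.05, 0.0]])
    sticks = duschinsky.fcht_sticks(tr, cv.HTExpansion(mu0, dmu), 290.0, 6)
    for n in range(7):
        amp = mu0 * quad_oracle(tr, (n,)) + dmu[0] * quad_oracle(tr, (n,), q_mode=0)
        expected = float(amp @ amp)
        assert sticks.intensities[n] == pytest.approx(expected, abs=1e-8)


def test_mode_cap_enforced():
    n = duschinsky.MAX_MIXED_MODES + 1
    tr = cv.DuschinskyTransform(
        np.eye(n), np.zeros(n), np.full(n, 1000.0), np.full(n, 1000.0)
    )
    with pytest.raises(cv.CorevibError):
        duschinsky.fc_integrals(tr, 2)


def test_third_band_splits_with_frequency_change_and_mixing():
    """Formaldehyde-like two-mode fixture (1753 + 2970 cm^-1): the third
    vibronic band of the DHO spectrum becomes a pair of sub-peaks once
    excited-state frequency change and Duschinsky mixing are enabled."""
    b = synthetic.make_bundle(synthetic.preset_spec("formaldehyde-like"))
    state = b.states[0]
    p = dho.dho_from_state(b.harmonic, state)
    e00 = p.adiabatic_energy_ev
    br = cv.BroadeningSpec(lorentzian_fwhm=0.04, gaussian_fwhm=0.05)
    grid = lineshape.make_grid(e00 - 0.8, e00 + 2.0, 0.002)

    g_dho = lineshape.broaden_sticks(lineshape.fc_sticks(p, state.intensity0), br, grid)
    tr = duschinsky.build_duschinsky(b.harmonic, state.es_harmonic)
    e00_b = e00 + dho.zpe_shift(b.harmonic, state.es_harmonic)
    g_bey = lineshape.broaden_sticks(
        duschinsky.duschinsky_sticks(tr, state.intensity0, e00_b, 10), br, grid
    )
    window = (e00 + 0.30, e00 + 0.52)
    assert len(lineshape.count_peaks(g_dho, window)) == 1
    assert len(lineshape.count_peaks(g_bey, window)) == 2
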