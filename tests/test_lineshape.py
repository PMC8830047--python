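"""Franck-Condon progressions, broadening, moments and route equivalence."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import corevib as cv
from corevib import dho, lineshape, synthetic
from corevib.constants import CM_PER_EV


def make_dho(freqs_cm1, huang_rhys, e_vert=290.0):
    freqs = np.asarray(freqs_cm1, dtype=float)
    s = np.asarray(huang_rhys, dtype=float)
    lam = s * freqs / CM_PER_EV
    return cv.DHOParameters(
        frequencies=freqs,
        displacements=np.sqrt(2 * s),
        huang_rhys=s,
        reorg_ev=lam,
        total_reorg_ev=float(lam.sum()),
        vertical_energy_ev=e_vert,
        adiabatic_energy_ev=e_vert - float(lam.sum()),
    )


def test_undisplaced_transition_is_a_single_line():
    p = make_dho([1500.0], [0.0])
    sticks = lineshape.fc_sticks(p, 0.7)
    assert len(sticks) == 1
    assert sticks.energies[0] == p.adiabatic_energy_ev
    assert sticks.intensities[0] == 0.7
    assert sticks.labels[0] == "0-0"


def test_single_mode_poisson_ratios():
    p = make_dho([1500.0], [0.5])
    sticks = lineshape.fc_sticks(p, 1.0)
    i00 = sticks.intensities[0]
    assert i00 == pytest.approx(math.exp(-0.5), rel=1e-12)
    assert sticks.intensities[1] / i00 == pytest.approx(0.5, rel=1e-12)


def test_two_mode_sticks_match_brute_force_enumeration():
    """Independent oracle: direct double loop over quanta up to 20."""
    p = make_dho([900.0, 1600.0], [0.3, 0.7])
    eps = 1e-4
    sticks = lineshape.fc_sticks(p, 1.0, epsilon=eps)
    assert sticks.total_intensity() >= 1.0 - 2 * eps

    hw = p.frequencies / CM_PER_EV
    oracle = {}
    for n1, n2 in itertools.product(range(21), repeat=2):
        w = (
            math.exp(-0.3) * 0.3**n1 / math.factorial(n1)
            * math.exp(-0.7) * 0.7**n2 / math.factorial(n2)
        )
        oracle[(n1, n2)] = (p.adiabatic_energy_ev + n1 * hw[0] + n2 * hw[1], w)

    matched = 0
    for e, i in zip(sticks.energies, sticks.intensities):
        key = min(oracle, key=lambda k: abs(oracle[k][0] - e))
        assert i == pytest.approx(oracle[key][1], rel=1e-12, abs=1e-300)
        matched += 1
    assert matched == len(sticks)
    # line count: every oracle line above the truncation floor must be present
    kept = sum(1 for e, w in oracle.values() if w > 1e-3)
    assert len(sticks) >= kept


@given(
    s=st.lists(st.floats(0.0, 3.0), min_size=1, max_size=4),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_fc_sum_rules_property(s, seed):
    """Total weight -> intensity0 and mean -> E_vert for random DHOs."""
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(300.0, 3200.0, size=len(s))
    p = make_dho(freqs, s)
    sticks = lineshape.fc_sticks(p, 1.0, epsilon=1e-8)
    assert sticks.total_intensity() >= 1.0 - 2e-8
    m0, mean, var = lineshape.spectral_moments(sticks)
    assert mean == pytest.approx(p.vertical_energy_ev, abs=1e-9)
    hw = freqs / CM_PER_EV
    assert var == pytest.approx(float(np.sum(np.array(s) * hw**2)), abs=1e-9)


def test_moments_of_single_stick():
    sticks = cv.StickSpectrum([288.5], [2.0])
    m0, mean, var = lineshape.spectral_moments(sticks)
    assert (m0, mean, var) == (2.0, 288.5, 0.0)


def test_moments_reject_empty_spectrum():
    with pytest.raises(cv.ConsistencyError):
        lineshape.spectral_moments(cv.StickSpectrum([1.0], [0.0]))


def test_gaussian_peak_height_and_area():
    grid = lineshape.make_grid(280.0, 300.0, 0.005)
    br = cv.BroadeningSpec(gaussian_fwhm=0.2, profile="gaussian")
    spec = lineshape.broaden_sticks(cv.StickSpectrum([290.0], [1.0]), br, grid)
    sigma = 0.2 / 2.3548200450309493
    assert sigma == pytest.approx(0.0849, abs=1e-4)
    assert spec.intensity.max() == pytest.approx(1.0 / (sigma * math.sqrt(2 * math.pi)), rel=1e-4)
    assert spec.integral() == pytest.approx(1.0, abs=1e-6)


def test_broadening_is_linear():
    grid = lineshape.make_grid(285.0, 295.0, 0.01)
    br = cv.BroadeningSpec(lorentzian_fwhm=0.3)
    s1 = cv.StickSpectrum([289.0], [0.6])
    s2 = cv.StickSpectrum([291.0], [1.1])
    both = cv.StickSpectrum([289.0, 291.0], [0.6, 1.1])
    y = lineshape.broaden_sticks(both, br, grid).intensity
    y12 = (
        lineshape.broaden_sticks(s1, br, grid).intensity
        + lineshape.broaden_sticks(s2, br, grid).intensity
    )
    assert np.allclose(y, y12, rtol=1e-12)


def test_voigt_with_zero_gaussian_equals_lorentzian():
    grid = lineshape.make_grid(285.0, 295.0, 0.01)
    sticks = cv.StickSpectrum([290.0], [1.0])
    v = lineshape.broaden_sticks(sticks, cv.BroadeningSpec(lorentzian_fwhm=0.4, profile="voigt"), grid)
    l = lineshape.broaden_sticks(sticks, cv.BroadeningSpec(lorentzian_fwhm=0.4, profile="lorentzian"), grid)
    assert np.allclose(v.intensity, l.intensity, atol=1e-10)


def test_zeroth_moment_preserved_by_broadening():
    p = make_dho([1200.0], [0.8], e_vert=290.0)
    sticks = lineshape.fc_sticks(p, 1.0, epsilon=1e-8)
    width = 0.25
    grid = lineshape.make_grid(
        sticks.energies.min() - 20 * width, sticks.energies.max() + 20 * width, 0.01
    )
    spec = lineshape.broaden_sticks(sticks, cv.BroadeningSpec(gaussian_fwhm=width), grid)
    assert spec.integral() == pytest.approx(sticks.total_intensity(), rel=1e-6)


def test_coarse_grid_is_rejected():
    p = make_dho([1200.0], [0.2])
    grid = lineshape.make_grid(285.0, 295.0, 0.2)
    with pytest.raises(cv.ConsistencyError):
        lineshape.broaden_sticks(lineshape.fc_sticks(p, 1.0), cv.BroadeningSpec(lorentzian_fwhm=0.3), grid)
    with pytest.raises(cv.ConsistencyError):
        lineshape.timedomain_spectrum(p, 1.0, cv.BroadeningSpec(lorentzian_fwhm=0.3), grid)


def test_timedomain_lorentzian_limit():
    """S = 0: pure Lorentzian at E_00 with peak height 2/(pi*Gamma)."""
    p = make_dho([1500.0], [0.0], e_vert=290.0)
    gamma = 0.3
    grid = lineshape.make_grid(285.0, 295.0, 0.005)
    spec = lineshape.timedomain_spectrum(
        p, 1.0, cv.BroadeningSpec(lorentzian_fwhm=gamma, profile="lorentzian"), grid
    )
    ipk = int(np.argmax(spec.intensity))
    assert spec.grid[ipk] == pytest.approx(290.0, abs=2 * spec.step)
    assert spec.intensity[ipk] == pytest.approx(2.0 / (math.pi * gamma), rel=1e-3)


@pytest.mark.parametrize("profile, lor, gau", [
    ("lorentzian", 0.25, 0.0),
    ("voigt", 0.15, 0.1),
    ("gaussian", 0.0, 0.2),
])
def test_route_equivalence_time_vs_sum_over_states(profile, lor, gau):
    """FFT of the correlation function agrees with broadened sticks."""
    p = make_dho([600.0, 1200.0, 2400.0], [0.3, 0.5, 0.15], e_vert=290.0)
    br = cv.BroadeningSpec(lorentzian_fwhm=lor, gaussian_fwhm=gau, profile=profile)
    grid = lineshape.make_grid(p.adiabatic_energy_ev - 2.0, p.vertical_energy_ev + 3.0, 0.01)
    ref = lineshape.broaden_sticks(lineshape.fc_sticks(p, 1.0, epsilon=1e-10), br, grid)
    td = lineshape.timedomain_spectrum(p, 1.0, br, grid)
    err = np.abs(ref.intensity - td.intensity).max() / ref.intensity.max()
    assert err < 1e-3


def test_small_damping_approaches_stick_positions():
    p = make_dho([1500.0], [0.6], e_vert=290.0)
    br = cv.BroadeningSpec(lorentzian_fwhm=0.02, profile="lorentzian")
    grid = lineshape.make_grid(p.adiabatic_energy_ev - 0.5, p.adiabatic_energy_ev + 1.0, 0.002)
    spec = lineshape.timedomain_spectrum(p, 1.0, br, grid)
    peaks = lineshape.count_peaks(spec, min_rel_height=0.05)
    sticks = lineshape.fc_sticks(p, 1.0)
    for pk in peaks:
        assert np.abs(sticks.energies - pk).min() < 2 * spec.step
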