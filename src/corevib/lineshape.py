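"""Vibronic lineshapes at 0 K: Franck-Condon stick spectra, lifetime and
instrument broadening, and the equivalent time-domain (cumulant) route.

For a displaced harmonic oscillator with Huang-Rhys factors S_k the 0 K
absorption is a multi-mode Poisson progression,

    I(n1, n2, ...) = I0 * prod_k exp(-S_k) S_k^{n_k} / n_k!

at energies E_00 + sum_k n_k hbar*omega_k.  The same spectrum follows from
the Fourier transform of the second-order cumulant response

    sigma(E) ~ I0 * Re INT_0^inf dt e^{i(E-E_00)t/hbar}
               exp[-sum_k S_k (1 - e^{-i omega_k t})] D(t)

with D(t) the lifetime/instrument damping; both routes are implemented and
tested against each other.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import voigt_profile

from .constants import FWHM_TO_SIGMA, cm1_to_ev
from .models import (
    BroadeningSpec,
    ConsistencyError,
    CorevibError,
    DHOParameters,
    GridSpectrum,
    StickSpectrum,
)

__all__ = [
    "fc_sticks",
    "broaden_sticks",
    "timedomain_spectrum",
    "spectral_moments",
    "make_grid",
    "parse_grid",
]

#: hard per-mode cap on vibrational quanta (determinism of truncation)
PER_MODE_CAP = 50
#: maximum number of enumerated lines before refusing
MAX_LINES = 2_000_000


#: quanta kept past the cumulative-weight cutoff, so the discarded tail is
#: negligible in the first spectral moment as well as the zeroth
TAIL_PAD = 3


def _poisson_weights(s: float, eps_mode: float) -> np.ndarray:
    """Poisson factors e^-s s^n/n! for n = 0..nmax, truncated TAIL_PAD quanta
    after the cumulative weight reaches 1 - eps_mode (hard cap PER_MODE_CAP)."""
    if s == 0.0:
        return np.array([1.0])
    w = [math.exp(-s)]
    cum = w[0]
    n = 0
    while cum < 1.0 - eps_mode and n < PER_MODE_CAP:
        n += 1
        w.append(w[-1] * s / n)
        cum += w[-1]
    for _ in range(TAIL_PAD):
        if n >= PER_MODE_CAP or w[-1] == 0.0:
            break
        n += 1
        w.append(w[-1] * s / n)
    return np.array(w)


def fc_sticks(
    dho: DHOParameters,
    intensity0: float = 1.0,
    epsilon: float = 1e-4,
) -> StickSpectrum:
    """0 K Franck-Condon stick spectrum of a DHO transition.

    Truncation: each mode keeps quanta until its own cumulative Poisson
    weight reaches (1 - epsilon)^(1/M), so the retained total weight is at
    least 1 - epsilon; lines are enumerated in lexicographic quantum-number
    order.  ``intensity0`` is |mu|^2 or a Dyson norm; no energy prefactor is
    applied.
    """
    if intensity0 < 0:
        raise ConsistencyError("intensity0 must be >= 0")
    m = dho.n_modes
    hw = cm1_to_ev(dho.frequencies)
    if m == 0:
        return StickSpectrum([dho.adiabatic_energy_ev], [intensity0], ("0-0",))
    eps_mode = 1.0 - (1.0 - epsilon) ** (1.0 / m)
    per_mode = [_poisson_weights(float(s), eps_mode) for s in dho.huang_rhys]

    n_lines = math.prod(len(w) for w in per_mode)
    if n_lines > MAX_LINES:
        raise CorevibError(
            f"{n_lines} Franck-Condon lines exceed the enumeration limit; "
            "raise epsilon or reduce the mode count"
        )
    energies = np.empty(n_lines)
    intens = np.empty(n_lines)
    labels = []
    for i, quanta in enumerate(itertools.product(*(range(len(w)) for w in per_mode))):
        energies[i] = dho.adiabatic_energy_ev + sum(n * w for n, w in zip(quanta, hw))
        intens[i] = intensity0 * math.prod(per_mode[k][n] for k, n in enumerate(quanta))
        labels.append(_quanta_label(quanta))
    return StickSpectrum(energies, intens, tuple(labels))


def _quanta_label(quanta) -> str:
    if not any(quanta):
        return "0-0"
    return "+".join(f"v{k + 1}^{n}" for k, n in enumerate(quanta) if n)


def _profile(x: np.ndarray, broadening: BroadeningSpec) -> np.ndarray:
    """Unit-area line profile on offsets x (eV)."""
    sigma = broadening.gaussian_fwhm / FWHM_TO_SIGMA
    gamma = broadening.lorentzian_fwhm / 2.0
    if broadening.profile == "lorentzian":
        sigma = 0.0
    elif broadening.profile == "gaussian":
        gamma = 0.0
    if sigma == 0.0 and gamma == 0.0:
        raise ConsistencyError("degenerate profile: both widths are zero")
    # complex-error-function Voigt; exact Gaussian/Lorentzian limits built in
    return voigt_profile(x, sigma, gamma)


def _check_grid_step(grid: np.ndarray, broadening: BroadeningSpec):
    step = float(grid[1] - grid[0])
    width = broadening.effective_width
    if width <= 0:
        raise ConsistencyError("broadening requires a positive width")
    if step > width / 5.0:
        raise ConsistencyError(
            f"grid step {step:.3g} eV too coarse for width {width:.3g} eV "
            "(need step <= width/5)"
        )


def broaden_sticks(
    sticks: StickSpectrum,
    broadening: BroadeningSpec,
    grid: np.ndarray,
) -> GridSpectrum:
    """Convolve a stick spectrum with a normalized Lorentzian/Gaussian/Voigt
    profile on a uniform grid.  The zeroth moment is preserved as long as the
    grid spans the lines by many widths."""
    grid = np.asarray(grid, dtype=float)
    _check_grid_step(grid, broadening)
    y = np.zeros_like(grid)
    chunk = max(1, int(5e6 / max(grid.size, 1)))
    for i in range(0, len(sticks), chunk):
        e = sticks.energies[i : i + chunk]
        w = sticks.intensities[i : i + chunk]
        y += (w[:, None] * _profile(grid[None, :] - e[:, None], broadening)).sum(axis=0)
    return GridSpectrum(grid, y, {"broadening": broadening, "route": "sum-over-states"})


#: cap on FFT length in the time-domain route
_MAX_FFT = 1 << 23


def timedomain_spectrum(
    dho: DHOParameters,
    intensity0: float,
    broadening: BroadeningSpec,
    grid: np.ndarray,
) -> GridSpectrum:
    """DHO absorption through the time-domain (generating-function) route.

    The correlation function exp[-sum_k S_k (1 - e^{-i omega_k t})], damped
    by the Lorentzian/Gaussian factors, is sampled on a uniform time grid and
    Fourier transformed (FFT); the result is interpolated onto the requested
    energy grid.  Each vibronic line integrates to its Poisson weight.
    """
    grid = np.asarray(grid, dtype=float)
    _check_grid_step(grid, broadening)

    gamma = broadening.lorentzian_fwhm          # eV (FWHM)
    sigma = broadening.gaussian_fwhm / FWHM_TO_SIGMA
    if broadening.profile == "lorentzian":
        sigma = 0.0
    elif broadening.profile == "gaussian":
        gamma = 0.0

    hw = cm1_to_ev(dho.frequencies)             # hbar*omega_k in eV
    e00 = dho.adiabatic_energy_ev

    # theta = t/hbar in 1/eV.  Nyquist must cover the largest energy offset.
    off_max = float(np.abs(grid - e00).max()) + 10.0 * broadening.effective_width + hw.sum()
    dtheta = math.pi / off_max
    # long enough for the damping to die out, fine enough to resolve the grid
    theta_damp = []
    if gamma > 0:
        theta_damp.append(2.0 * math.log(1e9) / gamma)
    if sigma > 0:
        theta_damp.append(math.sqrt(2.0 * math.log(1e9)) / sigma)
    if not theta_damp:
        raise ConsistencyError("selected profile leaves no active damping channel")
    theta_max = min(theta_damp)
    de_target = min(grid[1] - grid[0], broadening.effective_width / 4.0) / 4.0
    n = max(theta_max / dtheta, 2.0 * math.pi / (de_target * dtheta))
    nfft = 1 << max(8, math.ceil(math.log2(n)))
    if nfft > _MAX_FFT:
        raise CorevibError("time-domain discretization too large; widen the broadening or coarsen the grid")

    theta = dtheta * np.arange(nfft)
    phase = np.exp(-1j * np.outer(theta, hw))
    f = np.exp((dho.huang_rhys[None, :] * (phase - 1.0)).sum(axis=1))
    f *= np.exp(-0.5 * gamma * theta) * np.exp(-0.5 * (sigma * theta) ** 2)

    big_f = nfft * np.fft.ifft(f)               # sum_j f_j e^{+i 2pi jk/N}
    sig = (dtheta / math.pi) * (big_f.real - 0.5 * f[0].real)
    de = 2.0 * math.pi / (nfft * dtheta)
    offsets = np.fft.fftshift(np.fft.fftfreq(nfft, d=1.0 / (nfft * de)))
    sig = np.fft.fftshift(sig)

    y = intensity0 * np.interp(grid - e00, offsets, sig)
    y = np.clip(y, 0.0, None)                   # FFT ringing below machine-level
    return GridSpectrum(grid, y, {"broadening": broadening, "route": "time-domain"})


def spectral_moments(
    spectrum: Union[StickSpectrum, GridSpectrum],
) -> tuple:
    """(M0, intensity-weighted mean energy, variance).

    For FC sticks of a DHO these obey the Poisson sum rules
    mean = E_00 + lambda = E_vert and variance = sum_k S_k (hbar*omega_k)^2.
    """
    if isinstance(spectrum, StickSpectrum):
        w = spectrum.intensities
        e = spectrum.energies
        m0 = float(w.sum())
    else:
        w = spectrum.intensity
        e = spectrum.grid
        m0 = float(np.trapezoid(w, e))
    if m0 <= 0:
        raise ConsistencyError("zero-intensity spectrum has no moments")
    if isinstance(spectrum, StickSpectrum):
        mean = float((w * e).sum() / m0)
        var = float((w * (e - mean) ** 2).sum() / m0)
    else:
        mean = float(np.trapezoid(w * e, e) / m0)
        var = float(np.trapezoid(w * (e - mean) ** 2, e) / m0)
    return m0, mean, var


def count_peaks(
    spectrum: GridSpectrum,
    window: Optional[tuple] = None,
    min_rel_height: float = 0.05,
    order: int = 5,
) -> list:
    """Energies of local maxima of a broadened spectrum.

    A point is a peak when it exceeds its ``order`` neighbours on both sides
    and its height is at least ``min_rel_height`` of the global maximum;
    ``window`` restricts the result to an (lo, hi) energy interval.  Used
    for qualitative band-structure assertions (e.g. whether a vibronic band
    is split in two sub-peaks)."""
    from scipy.signal import argrelmax

    idx = argrelmax(spectrum.intensity, order=order)[0]
    floor = min_rel_height * spectrum.intensity.max()
    peaks = [float(spectrum.grid[i]) for i in idx if spectrum.intensity[i] >= floor]
    if window is not None:
        lo, hi = window
        peaks = [p for p in peaks if lo <= p <= hi]
    return peaks


def make_grid(start: float, stop: float, step: float) -> np.ndarray:
    """Uniform energy grid [start, stop] with the given step (eV)."""
    if step <= 0 or stop <= start:
        raise ConsistencyError("grid requires stop > start and step > 0")
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def parse_grid(spec: str) -> np.ndarray:
    """Parse a 'start:stop:step' grid specification in eV."""
    try:
        start, stop, step = (float(x) for x in spec.split(":"))
    except ValueError as exc:
        raise ConsistencyError(f"bad grid spec {spec!r}; expected start:stop:step") from exc
    return make_grid(start, stop, step)
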