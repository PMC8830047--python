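"""Compose per-state vibronic spectra into full XANES and XPS traces.

Rendering follows the conventions of core-level work: bound core-excited
states below the ionization threshold are drawn with their full broadened
lineshape, states above the threshold (short-lived, continuum-coupled) are
reported as sticks only; XPS envelopes are scaled by Dyson norms and
normalized so the most intense band reaches 1; coexisting gas-phase
conformers are averaged with Boltzmann weights.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .constants import GAS_CONSTANT_J_MOL_K
from .dho import dho_from_state, lifetime_to_fwhm, zpe_shift
from .duschinsky import build_duschinsky, duschinsky_sticks, fcht_sticks
from .lineshape import broaden_sticks, fc_sticks
from .models import (
    BroadeningSpec,
    CalculationBundle,
    ConsistencyError,
    CorevibError,
    ElectronicStateRecord,
    GridSpectrum,
    HTExpansion,
    KIND_CORE_CATION,
    KIND_CORE_EXCITED,
    StickSpectrum,
)

__all__ = [
    "assemble_xanes",
    "assemble_xps",
    "boltzmann_weights",
    "combine_conformers",
    "apply_shift",
    "normalize_max",
    "MODEL_LEVELS",
]

MODEL_LEVELS = ("dho", "duschinsky", "fcht")


def _state_sticks(
    bundle: CalculationBundle,
    state: ElectronicStateRecord,
    model_level: str,
    nmax: int,
    epsilon: float,
) -> StickSpectrum:
    """Vibronic sticks of one state at the requested model level."""
    dho = dho_from_state(bundle.harmonic, state)
    if model_level == "dho":
        sticks = fc_sticks(dho, state.intensity0, epsilon)
    else:
        if state.es_harmonic is None:
            raise ConsistencyError(
                f"state {state.label!r}: model level {model_level!r} requires "
                "excited-state harmonic data (es_harmonic)"
            )
        transform = build_duschinsky(bundle.harmonic, state.es_harmonic)
        # 0-0 energy: vertical minus reorganization, plus the zero-point
        # change of the distinct excited-state well
        e00 = dho.adiabatic_energy_ev + zpe_shift(bundle.harmonic, state.es_harmonic)
        if model_level == "duschinsky":
            sticks = duschinsky_sticks(transform, state.intensity0, e00, nmax)
        elif model_level == "fcht":
            if state.kind != KIND_CORE_EXCITED:
                raise ConsistencyError("Herzberg-Teller terms require a transition dipole")
            dmu = state.tdm_derivatives
            if dmu is None:
                dmu = np.zeros((dho.n_modes, 3))
            ht = HTExpansion(state.tdm, dmu)
            sticks = fcht_sticks(transform, ht, e00, nmax)
        else:
            raise ConsistencyError(f"unknown model level {model_level!r}; use {MODEL_LEVELS}")
    labels = tuple(f"{state.label} | {l}" for l in sticks.labels)
    return StickSpectrum(sticks.energies, sticks.intensities, labels)


def assemble_xanes(
    bundle: CalculationBundle,
    model_level: str = "dho",
    broadening: BroadeningSpec = BroadeningSpec(),
    grid: Optional[np.ndarray] = None,
    nmax: int = 8,
    epsilon: float = 1e-4,
    broaden_above_ip: Optional[float] = None,
) -> Tuple[GridSpectrum, StickSpectrum]:
    """XANES from the core-excited states of a bundle.

    States with vertical energy below ``bundle.ip_threshold`` contribute
    broadened vibronic envelopes (each with its own lifetime Lorentzian);
    states above it are returned in the stick list only, unless
    ``broaden_above_ip`` supplies a Lorentzian FWHM (eV) for continuum-like
    display.  With no threshold every state is broadened.

    Returns the broadened spectrum and the supra-threshold stick list.
    """
    if grid is None:
        raise ConsistencyError("an energy grid is required")
    states = bundle.select(KIND_CORE_EXCITED)
    if not states:
        raise ConsistencyError("bundle has no core-excited states")
    ip = bundle.ip_threshold

    total = np.zeros_like(np.asarray(grid, dtype=float))
    out_grid = None
    supra: list = []
    any_below = False
    for state in states:
        sticks = _state_sticks(bundle, state, model_level, nmax, epsilon)
        below = ip is None or state.vertical_energy < ip
        if below:
            any_below = True
            spec = broaden_sticks(
                sticks, broadening.with_lorentzian(lifetime_to_fwhm(state.lifetime)), grid
            )
            total += spec.intensity
            out_grid = spec.grid
        else:
            supra.append(sticks)
            if broaden_above_ip is not None:
                spec = broaden_sticks(sticks, broadening.with_lorentzian(broaden_above_ip), grid)
                total += spec.intensity
                out_grid = spec.grid
    supra_sticks = StickSpectrum.concatenate(supra)
    if not any_below and len(supra_sticks) == 0:
        raise CorevibError("empty spectrum: no states below the IP threshold and no sticks")
    if out_grid is None:
        out_grid = np.asarray(grid, dtype=float)
    meta = {"kind": "xanes", "model_level": model_level, "ip_threshold": ip}
    return GridSpectrum(out_grid, total, meta), supra_sticks


def assemble_xps(
    bundle: CalculationBundle,
    broadening: BroadeningSpec = BroadeningSpec(),
    grid: Optional[np.ndarray] = None,
    epsilon: float = 1e-4,
    include_zpe: bool = True,
    normalize: bool = True,
) -> GridSpectrum:
    """XPS from the core-cation states of a bundle.

    Each cation state contributes a DHO vibronic envelope at its binding
    energy, scaled by its Dyson norm (sudden approximation).  When
    excited-state harmonic data are present the band origin is shifted by
    the zero-point-energy change of the cation well.  The assembled spectrum
    is normalized so its maximum equals 1 (matching the convention of
    scaling to the most intense experimental band); disable with
    ``normalize=False``.
    """
    if grid is None:
        raise ConsistencyError("an energy grid is required")
    states = bundle.select(KIND_CORE_CATION)
    if not states:
        raise ConsistencyError("bundle has no core-cation states (XPS needs Dyson norms)")
    total = np.zeros_like(np.asarray(grid, dtype=float))
    out_grid = None
    for state in states:
        dho = dho_from_state(bundle.harmonic, state)
        sticks = fc_sticks(dho, state.dyson_norm, epsilon)
        if include_zpe and state.es_harmonic is not None:
            sticks = sticks.shifted(zpe_shift(bundle.harmonic, state.es_harmonic))
        spec = broaden_sticks(
            sticks, broadening.with_lorentzian(lifetime_to_fwhm(state.lifetime)), grid
        )
        total += spec.intensity
        out_grid = spec.grid
    result = GridSpectrum(out_grid, total, {"kind": "xps", "normalized": normalize})
    if normalize:
        result = normalize_max(result)
    return result


def normalize_max(spectrum: GridSpectrum) -> GridSpectrum:
    """Scale so the maximum intensity equals 1.  Idempotent."""
    peak = float(spectrum.intensity.max())
    if peak <= 0:
        raise ConsistencyError("cannot normalize an all-zero spectrum")
    return spectrum.with_intensity(spectrum.intensity / peak, normalized=True)


def boltzmann_weights(
    delta_g_kjmol: Sequence[float],
    temperature: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Boltzmann conformer weights from Gibbs free energies.

    ``delta_g_kjmol`` lists each conformer's free energy (kJ/mol) relative
    to the reference conformer at 0.  Returns ``(ratios, fractions)``:
    ratios r_i = exp(-dG_i / RT) relative to the reference, and normalized
    populations r_i / sum_j r_j.
    """
    if not temperature > 0:
        raise ConsistencyError("temperature must be positive")
    dg = np.asarray(delta_g_kjmol, dtype=float) * 1e3      # J/mol
    ratios = np.exp(-dg / (GAS_CONSTANT_J_MOL_K * temperature))
    return ratios, ratios / ratios.sum()


def combine_conformers(
    spectra: Sequence[GridSpectrum],
    weights: Sequence[float],
) -> GridSpectrum:
    """Pointwise population-weighted sum of per-conformer spectra on one grid."""
    if len(spectra) != len(weights):
        raise ConsistencyError("one weight per spectrum required")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-8:
        raise ConsistencyError("weights must sum to 1")
    ref = spectra[0]
    total = np.zeros_like(ref.intensity)
    for sp, wi in zip(spectra, w):
        if sp.grid.shape != ref.grid.shape or not np.allclose(sp.grid, ref.grid, rtol=1e-12):
            raise ConsistencyError("conformer spectra must share an identical grid")
        total += wi * sp.intensity
    return GridSpectrum(ref.grid, total, {"kind": "conformer-average", "weights": w.tolist()})


def apply_shift(
    spectrum: Union[GridSpectrum, StickSpectrum],
    shift_ev: float = 0.0,
) -> Union[GridSpectrum, StickSpectrum]:
    """Rigid energy shift, recorded in metadata.  Stick energies translate
    exactly; grid spectra are re-interpolated onto their original axis.
    The default 0 leaves the spectrum untouched (headline comparisons are
    made unshifted)."""
    if isinstance(spectrum, StickSpectrum):
        return spectrum.shifted(shift_ev)
    if shift_ev == 0.0:
        return spectrum
    y = np.interp(spectrum.grid - shift_ev, spectrum.grid, spectrum.intensity, left=0.0, right=0.0)
    prev = float(spectrum.metadata.get("shift_ev", 0.0))
    return spectrum.with_intensity(y, shift_ev=prev + shift_ev)
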