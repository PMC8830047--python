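"""Domain types: harmonic models, electronic-state records, spectra.

All energies stored in the units named by the field (eV, cm^-1, fs, Angstrom,
amu, Hartree/Bohr for gradients); conversion to atomic units happens inside
the computational modules, never at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .constants import AMU_TO_ME, BOHR_ANGSTROM

__all__ = [
    "CorevibError",
    "FormatError",
    "ConsistencyError",
    "HarmonicModel",
    "ElectronicStateRecord",
    "CalculationBundle",
    "DHOParameters",
    "DuschinskyTransform",
    "HTExpansion",
    "StickSpectrum",
    "GridSpectrum",
    "BroadeningSpec",
]


class CorevibError(Exception):
    """Base class for all package errors."""


class FormatError(CorevibError):
    """A file or schema could not be parsed."""


class ConsistencyError(CorevibError):
    """Parsed data violates a physical or structural invariant."""


@dataclass(frozen=True)
class HarmonicModel:
    """Harmonic description of one electronic state.

    Parameters
    ----------
    atom_symbols : element labels, length N.
    masses : atomic masses in amu, length N, all positive.
    geometry : Cartesian coordinates in Angstrom, shape (N, 3).
    frequencies : harmonic wavenumbers in cm^-1, length M, all positive.
    mode_vectors : Cartesian displacement vectors, shape (M, N, 3).  They are
        re-orthonormalized in the mass-weighted metric on validation; a
        writer that already stores mass-weighted vectors should divide them
        by sqrt(m) per atom before constructing the model (see
        ``qm_io.read_molden_frequencies(mass_weighted=True)``).
    linear_flag : True for linear molecules (3N-5 internal modes).
    """

    atom_symbols: tuple
    masses: np.ndarray
    geometry: np.ndarray
    frequencies: np.ndarray
    mode_vectors: np.ndarray
    linear_flag: bool = False

    # orthonormality tolerance in the mass-weighted metric
    ORTHO_TOL = 1e-6

    def __post_init__(self):
        object.__setattr__(self, "atom_symbols", tuple(self.atom_symbols))
        for name in ("masses", "geometry", "frequencies", "mode_vectors"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.atom_symbols)
        if self.masses.shape != (n,):
            raise ConsistencyError(f"masses shape {self.masses.shape} != ({n},)")
        if np.any(self.masses <= 0):
            raise ConsistencyError("all atomic masses must be positive")
        if self.geometry.shape != (n, 3):
            raise ConsistencyError(f"geometry shape {self.geometry.shape} != ({n}, 3)")
        m = self.frequencies.shape[0]
        if np.any(self.frequencies <= 0):
            raise ConsistencyError(
                "zero or imaginary (negative) frequencies are not allowed; "
                "drop them explicitly on read if intended"
            )
        max_modes = 3 * n - 5 if self.linear_flag else 3 * n - 6
        if m > max(max_modes, 0):
            raise ConsistencyError(f"{m} modes exceeds 3N-{5 if self.linear_flag else 6} = {max_modes}")
        if self.mode_vectors.shape != (m, n, 3):
            raise ConsistencyError(
                f"mode_vectors shape {self.mode_vectors.shape} != ({m}, {n}, 3)"
            )
        object.__setattr__(self, "mode_vectors", self._orthonormalized())

    def _orthonormalized(self) -> np.ndarray:
        """Renormalize Cartesian modes in the mass-weighted metric; verify
        pairwise orthogonality to ORTHO_TOL.  Idempotent."""
        sqm = np.sqrt(self.masses * AMU_TO_ME)[None, :, None]
        mw = self.mode_vectors * sqm                       # (M, N, 3) mass-weighted
        flat = mw.reshape(len(self.frequencies), -1)
        norms = np.linalg.norm(flat, axis=1)
        if np.any(norms == 0):
            raise ConsistencyError("zero-norm mode vector")
        flat = flat / norms[:, None]
        gram = flat @ flat.T
        off = np.abs(gram - np.eye(len(gram))).max() if len(gram) else 0.0
        if off > self.ORTHO_TOL:
            raise ConsistencyError(
                f"mode vectors not orthonormal in the mass-weighted metric "
                f"(max deviation {off:.2e} > {self.ORTHO_TOL})"
            )
        return (flat.reshape(mw.shape) / sqm)

    # -- derived quantities used throughout --------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atom_symbols)

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    def mass_weighted_modes(self) -> np.ndarray:
        """Orthonormal mass-weighted mode matrix L, shape (3N, M)."""
        sqm = np.sqrt(self.masses * AMU_TO_ME)[None, :, None]
        mw = (self.mode_vectors * sqm).reshape(self.n_modes, -1)
        mw /= np.linalg.norm(mw, axis=1)[:, None]
        return mw.T

    def geometry_bohr(self) -> np.ndarray:
        return self.geometry / BOHR_ANGSTROM


KIND_CORE_EXCITED = "core-excited"
KIND_CORE_CATION = "core-cation"


@dataclass(frozen=True)
class ElectronicStateRecord:
    """One final electronic state: a core-excited state (XANES) carrying a
    transition dipole, or a core-cation state (XPS) carrying a Dyson norm."""

    label: str
    kind: str
    vertical_energy: float          # eV, relative to the neutral ground state
    gradient: np.ndarray            # Hartree/Bohr, length 3N
    lifetime: float                 # fs
    tdm: Optional[np.ndarray] = None          # a.u., 3-vector (core-excited)
    dyson_norm: Optional[float] = None        # in [0, 1]  (core-cation)
    es_harmonic: Optional[HarmonicModel] = None
    tdm_derivatives: Optional[np.ndarray] = None   # (M, 3) a.u. per dimensionless coord

    def __post_init__(self):
        if self.kind not in (KIND_CORE_EXCITED, KIND_CORE_CATION):
            raise ConsistencyError(f"unknown state kind {self.kind!r}")
        if self.vertical_energy <= 0:
            raise ConsistencyError("vertical energy must be positive")
        if self.lifetime <= 0:
            raise ConsistencyError("lifetime must be positive")
        object.__setattr__(self, "gradient", np.asarray(self.gradient, dtype=float).ravel())
        if self.kind == KIND_CORE_EXCITED:
            if self.tdm is None or self.dyson_norm is not None:
                raise ConsistencyError("core-excited states carry a tdm and no dyson_norm")
            object.__setattr__(self, "tdm", np.asarray(self.tdm, dtype=float).reshape(3))
        else:
            if self.dyson_norm is None or self.tdm is not None:
                raise ConsistencyError("core-cation states carry a dyson_norm and no tdm")
            if not (0.0 <= self.dyson_norm <= 1.0):
                raise ConsistencyError("dyson_norm must lie in [0, 1]")
        if self.tdm_derivatives is not None:
            object.__setattr__(
                self, "tdm_derivatives",
                np.asarray(self.tdm_derivatives, dtype=float).reshape(-1, 3),
            )

    @property
    def intensity0(self) -> float:
        """Condon intensity: |mu|^2 for absorption, Dyson norm for ionization."""
        if self.kind == KIND_CORE_EXCITED:
            return float(np.dot(self.tdm, self.tdm))
        return float(self.dyson_norm)


@dataclass(frozen=True)
class CalculationBundle:
    """Everything needed to simulate one molecule/conformer."""

    harmonic: HarmonicModel
    states: tuple
    ip_threshold: Optional[float] = None       # eV
    conformer_label: str = ""
    delta_g: Optional[float] = None            # kJ/mol vs reference conformer
    temperature: Optional[float] = None        # K

    def __post_init__(self):
        object.__setattr__(self, "states", tuple(self.states))
        if not self.states:
            raise ConsistencyError("bundle must contain at least one electronic state")
        n3 = 3 * self.harmonic.n_atoms
        for s in self.states:
            if s.gradient.shape != (n3,):
                raise ConsistencyError(
                    f"state {s.label!r}: gradient length {s.gradient.size} != 3N = {n3}"
                )
        if self.ip_threshold is not None:
            evs = [s.vertical_energy for s in self.states]
            if not (min(evs) - 50.0 <= self.ip_threshold <= max(evs) + 50.0):
                raise ConsistencyError(
                    "ip_threshold lies further than 50 eV from every state energy"
                )

    def select(self, kind: str) -> tuple:
        return tuple(s for s in self.states if s.kind == kind)


@dataclass(frozen=True)
class DHOParameters:
    """Displaced-harmonic-oscillator parameters of one electronic transition.

    Per mode: dimensionless displacement Delta_k, Huang-Rhys factor
    S_k = Delta_k^2/2, reorganization energy lambda_k = S_k * hbar*omega_k.
    E_00 = E_vert - lambda.
    """

    frequencies: np.ndarray        # cm^-1
    displacements: np.ndarray      # dimensionless, signed
    huang_rhys: np.ndarray         # dimensionless
    reorg_ev: np.ndarray           # eV per mode
    total_reorg_ev: float
    vertical_energy_ev: float
    adiabatic_energy_ev: float     # E_00

    def __post_init__(self):
        for name in ("frequencies", "displacements", "huang_rhys", "reorg_ev"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.allclose(self.huang_rhys, self.displacements**2 / 2.0, rtol=1e-12, atol=1e-300):
            raise ConsistencyError("S_k != Delta_k^2 / 2")
        if abs(self.total_reorg_ev - self.reorg_ev.sum()) > 1e-9 * max(1.0, abs(self.total_reorg_ev)):
            raise ConsistencyError("total reorganization != sum of per-mode terms")
        if self.adiabatic_energy_ev > self.vertical_energy_ev + 1e-12:
            raise ConsistencyError("E_00 must not exceed E_vert")

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class DuschinskyTransform:
    """Linear map between ground- and excited-state normal coordinates:
    Q' = J Q + shift, reported as (J, K) with K the dimensionless
    ground-state-mode displacement of the excited-state minimum."""

    J: np.ndarray                  # (M, M), ES modes in terms of GS modes
    K: np.ndarray                  # (M,), dimensionless GS-mode coordinates
    gs_frequencies: np.ndarray     # cm^-1
    es_frequencies: np.ndarray     # cm^-1
    orthogonality_deviation: float = 0.0

    def __post_init__(self):
        for name in ("J", "K", "gs_frequencies", "es_frequencies"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not np.all(np.isfinite(self.K)):
            raise ConsistencyError("non-finite Duschinsky shift vector")
        if self.J.shape != (len(self.es_frequencies), len(self.gs_frequencies)):
            raise ConsistencyError("J shape inconsistent with frequency sets")

    @property
    def n_modes(self) -> int:
        return len(self.gs_frequencies)


@dataclass(frozen=True)
class HTExpansion:
    """Linear (Herzberg-Teller) expansion of the transition dipole:
    mu(q) = mu0 + sum_k dmu_k q_k in dimensionless ground-state coordinates."""

    mu0: np.ndarray                # (3,) a.u.
    dmu: np.ndarray                # (M, 3) a.u. per dimensionless coordinate

    def __post_init__(self):
        object.__setattr__(self, "mu0", np.asarray(self.mu0, dtype=float).reshape(3))
        object.__setattr__(self, "dmu", np.asarray(self.dmu, dtype=float).reshape(-1, 3))
        if not (np.all(np.isfinite(self.mu0)) and np.all(np.isfinite(self.dmu))):
            raise ConsistencyError("non-finite transition dipole expansion")


@dataclass(frozen=True)
class StickSpectrum:
    """Discrete vibronic lines with parent-state labels."""

    energies: np.ndarray           # eV
    intensities: np.ndarray        # >= 0, dimensionless
    labels: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "energies", np.asarray(self.energies, dtype=float).ravel())
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float).ravel())
        if self.energies.shape != self.intensities.shape:
            raise ConsistencyError("energies and intensities differ in length")
        if not np.all(np.isfinite(self.energies)):
            raise ConsistencyError("non-finite stick energy")
        if np.any(self.intensities < 0):
            raise ConsistencyError("negative stick intensity")
        labels = tuple(self.labels) if self.labels else ("",) * len(self.energies)
        if len(labels) != len(self.energies):
            raise ConsistencyError("label count mismatch")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.energies)

    def total_intensity(self) -> float:
        return float(self.intensities.sum())

    def shifted(self, de: float) -> "StickSpectrum":
        return StickSpectrum(self.energies + de, self.intensities, self.labels)

    def scaled(self, c: float) -> "StickSpectrum":
        return StickSpectrum(self.energies, self.intensities * c, self.labels)

    @staticmethod
    def concatenate(parts: Sequence["StickSpectrum"]) -> "StickSpectrum":
        parts = [p for p in parts if len(p)]
        if not parts:
            return StickSpectrum(np.empty(0), np.empty(0))
        return StickSpectrum(
            np.concatenate([p.energies for p in parts]),
            np.concatenate([p.intensities for p in parts]),
            tuple(l for p in parts for l in p.labels),
        )


@dataclass(frozen=True)
class GridSpectrum:
    """Intensity on a uniform energy grid."""

    grid: np.ndarray               # eV, strictly increasing, uniform step
    intensity: np.ndarray          # >= 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float).ravel())
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float).ravel())
        if self.grid.size < 2:
            raise ConsistencyError("grid needs at least two points")
        steps = np.diff(self.grid)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9):
            raise ConsistencyError("grid must be strictly increasing with uniform step")
        if self.intensity.shape != self.grid.shape:
            raise ConsistencyError("grid and intensity differ in length")
        if np.any(self.intensity < 0):
            raise ConsistencyError("negative grid intensity")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.grid))

    def with_intensity(self, y: np.ndarray, **meta) -> "GridSpectrum":
        md = dict(self.metadata)
        md.update(meta)
        return GridSpectrum(self.grid, y, md)


PROFILES = ("lorentzian", "gaussian", "voigt")


@dataclass(frozen=True)
class BroadeningSpec:
    """Lorentzian width from the core-hole lifetime; Gaussian width for
    instrument response and unresolved structure."""

    lorentzian_fwhm: float = 0.0   # eV
    gaussian_fwhm: float = 0.0     # eV
    profile: str = "voigt"

    def __post_init__(self):
        if self.lorentzian_fwhm < 0 or self.gaussian_fwhm < 0:
            raise ConsistencyError("broadening widths must be >= 0")
        if self.profile not in PROFILES:
            raise ConsistencyError(f"profile must be one of {PROFILES}")

    def with_lorentzian(self, fwhm: float) -> "BroadeningSpec":
        return replace(self, lorentzian_fwhm=fwhm)

    @property
    def effective_width(self) -> float:
        return self.lorentzian_fwhm + self.gaussian_fwhm
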