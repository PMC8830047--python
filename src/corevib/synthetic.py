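"""Synthetic fixtures with known ground truth.

Two generators live here: harmonic bundles constructed backwards from
prescribed Huang-Rhys factors (the inverse problem of ``dho``), and toy
configuration-interaction models for exercising the active-space iterator
without a quantum-chemistry engine.  All pseudo-randomness in the package is
confined to this module; every science module is deterministic.

The Cartesian embedding uses pseudo-atoms with unit masses at seeded random
(non-collinear) positions: only mode-space quantities matter downstream, so
the embedding is deliberately non-physical.  Non-collinear positions keep
the full 6-dimensional translation/rotation space non-degenerate, which the
rigid-rotation invariance checks rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import AMU_TO_ME, BOHR_ANGSTROM, cm1_to_hartree
from .models import (
    CalculationBundle,
    ConsistencyError,
    ElectronicStateRecord,
    HarmonicModel,
    KIND_CORE_CATION,
    KIND_CORE_EXCITED,
)

__all__ = [
    "FixtureSpec",
    "make_bundle",
    "ToyElectronicModel",
    "make_toy_model",
    "PRESETS",
    "preset_spec",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic harmonic bundle with exact DHO ground truth."""

    n_modes: int
    frequencies: Sequence[float]                 # cm^-1
    target_huang_rhys: Sequence[float]           # dimensionless, >= 0
    vertical_energy: float = 290.0               # eV
    lifetime: float = 4.0                        # fs
    kind: str = KIND_CORE_EXCITED
    ht_derivatives: Optional[Sequence[float]] = None   # |dmu_k|, a.u./dimensionless q
    duschinsky_angle: Optional[float] = None     # rad, mixes the first mode pair
    es_frequency_scale: Optional[Sequence[float]] = None
    seed: int = 0
    label: str = "1s -> synthetic"

    def __post_init__(self):
        if len(self.frequencies) != self.n_modes or len(self.target_huang_rhys) != self.n_modes:
            raise ConsistencyError("frequencies and target_huang_rhys must have n_modes entries")
        if any(f <= 0 for f in self.frequencies):
            raise ConsistencyError("frequencies must be positive")
        if any(s < 0 for s in self.target_huang_rhys):
            raise ConsistencyError("Huang-Rhys factors must be >= 0")


def _internal_basis(rng: np.random.Generator, geometry_bohr: np.ndarray, n_modes: int) -> np.ndarray:
    """Seeded orthonormal basis (3N, M) of the internal (Eckart-orthogonal)
    subspace for unit-mass pseudo-atoms."""
    n = len(geometry_bohr)
    com = geometry_bohr.mean(axis=0)
    r = geometry_bohr - com
    ext = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        ext.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        ext.append(np.cross(np.broadcast_to(e, (n, 3)), r).ravel())
    ext = np.array(ext).T
    q_ext, s, _ = np.linalg.svd(ext, full_matrices=False)
    q_ext = q_ext[:, s > 1e-10]
    proj = np.eye(3 * n) - q_ext @ q_ext.T

    raw = proj @ rng.standard_normal((3 * n, n_modes))
    q, r_tri = np.linalg.qr(raw)
    q *= np.sign(np.diag(r_tri))                 # deterministic sign convention
    if np.abs(np.diag(r_tri)).min() < 1e-8:
        raise ConsistencyError("degenerate random basis; change the seed")
    return q


def make_bundle(spec: FixtureSpec) -> CalculationBundle:
    """Build a bundle whose gradient reproduces ``target_huang_rhys`` exactly.

    Inverse construction in atomic units: the mode-space gradient
    g_k = omega_k^(3/2) * sqrt(2 S_k) yields Delta_k = -sqrt(2 S_k), hence
    S_k on the forward pass through ``dho.project_gradient`` +
    ``dho.dho_parameters``.  The gradient is embedded in a synthetic
    Cartesian frame of unit-mass pseudo-atoms.  Deterministic given the seed.
    """
    m = spec.n_modes
    n_atoms = max(3, math.ceil((m + 6) / 3))
    if m > 3 * n_atoms - 6:
        raise ConsistencyError("n_modes exceeds 3N-6 for the generated atom count")
    rng = np.random.default_rng(spec.seed)
    geometry_bohr = 2.0 * rng.standard_normal((n_atoms, 3))
    masses = np.ones(n_atoms)
    basis = _internal_basis(rng, geometry_bohr, m)   # mass-weighted == Cartesian here

    freqs = np.asarray(spec.frequencies, dtype=float)
    s_target = np.asarray(spec.target_huang_rhys, dtype=float)
    omega = cm1_to_hartree(freqs)
    g_mode = omega**1.5 * np.sqrt(2.0 * s_target)    # atomic units, mass-weighted

    sqm = math.sqrt(1.0 * AMU_TO_ME)
    gradient = sqm * (basis @ g_mode)                # Hartree/Bohr, Cartesian

    model = HarmonicModel(
        atom_symbols=("X",) * n_atoms,
        masses=masses,
        geometry=geometry_bohr * BOHR_ANGSTROM,
        frequencies=freqs,
        mode_vectors=basis.T.reshape(m, n_atoms, 3),
        linear_flag=False,
    )

    tdm_dir = rng.standard_normal(3)
    tdm_dir /= np.linalg.norm(tdm_dir)

    es_harmonic = None
    if spec.duschinsky_angle is not None or spec.es_frequency_scale is not None:
        es_harmonic = _excited_model(model, basis, omega, s_target, spec)

    dmu = None
    if spec.ht_derivatives is not None:
        mags = np.asarray(spec.ht_derivatives, dtype=float)
        if mags.shape != (m,):
            raise ConsistencyError("one HT derivative magnitude per mode required")
        dmu = mags[:, None] * tdm_dir[None, :]

    common = dict(
        label=spec.label,
        vertical_energy=spec.vertical_energy,
        gradient=gradient,
        lifetime=spec.lifetime,
        es_harmonic=es_harmonic,
        tdm_derivatives=dmu,
    )
    if spec.kind == KIND_CORE_EXCITED:
        state = ElectronicStateRecord(kind=KIND_CORE_EXCITED, tdm=tdm_dir, **common)
    elif spec.kind == KIND_CORE_CATION:
        state = ElectronicStateRecord(kind=KIND_CORE_CATION, dyson_norm=1.0, **common)
    else:
        raise ConsistencyError(f"unknown state kind {spec.kind!r}")
    return CalculationBundle(harmonic=model, states=(state,), conformer_label="synthetic")


def _excited_model(model, basis, omega, s_target, spec) -> HarmonicModel:
    """Excited-state harmonic model realizing the planned Duschinsky
    transform: frequencies scaled per mode, the first mode pair mixed by the
    requested angle, equilibrium displaced by Delta_k = -sqrt(2 S_k)."""
    m = spec.n_modes
    scale = np.ones(m) if spec.es_frequency_scale is None else np.asarray(spec.es_frequency_scale, float)
    if scale.shape != (m,):
        raise ConsistencyError("one frequency scale per mode required")
    rot = np.eye(m)
    if spec.duschinsky_angle is not None:
        if m < 2:
            raise ConsistencyError("mode mixing needs at least two modes")
        th = float(spec.duschinsky_angle)
        rot[0, 0] = rot[1, 1] = math.cos(th)
        rot[0, 1] = -math.sin(th)
        rot[1, 0] = math.sin(th)
    # L' = L R^T so that J = L'^T L = R
    basis_es = basis @ rot.T
    delta = -np.sqrt(2.0 * s_target)
    dx = (basis @ (delta / np.sqrt(omega))) / math.sqrt(1.0 * AMU_TO_ME)  # Bohr
    geom_es = model.geometry + dx.reshape(-1, 3) * BOHR_ANGSTROM
    return HarmonicModel(
        atom_symbols=model.atom_symbols,
        masses=model.masses,
        geometry=geom_es,
        frequencies=model.frequencies * scale,
        mode_vectors=basis_es.T.reshape(m, model.n_atoms, 3),
        linear_flag=False,
    )


# ---------------------------------------------------------------------------
# toy configuration model for the active-space iterator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyElectronicModel:
    """Synthetic configuration-space oracle: one core->virtual configuration
    per virtual orbital, with a symmetric coupling matrix.  Exact states come
    from dense diagonalization of the full configuration Hamiltonian; the
    chunked iterator sees only sub-blocks, so with block-diagonal couplings
    the two routes agree exactly."""

    core_energy: float                    # eV (core -> LUMO reference gap)
    orbital_energies: np.ndarray          # eV per virtual, ascending
    couplings: np.ndarray                 # symmetric (n, n), eV
    tdm_rule: np.ndarray                  # per-orbital transition-dipole magnitude
    occupied_ids: tuple = ("homo",)
    core_id: str = "1s"
    window: tuple = (0.0, np.inf)         # eV interval of interest

    def __post_init__(self):
        object.__setattr__(self, "orbital_energies", np.asarray(self.orbital_energies, float))
        object.__setattr__(self, "couplings", np.asarray(self.couplings, float))
        object.__setattr__(self, "tdm_rule", np.asarray(self.tdm_rule, float))
        n = len(self.orbital_energies)
        if np.any(np.diff(np.sort(self.orbital_energies)) < 0):
            raise ConsistencyError("orbital energies must sort ascending")
        if self.couplings.shape != (n, n) or not np.allclose(self.couplings, self.couplings.T):
            raise ConsistencyError("coupling matrix must be symmetric (n, n)")
        if self.tdm_rule.shape != (n,):
            raise ConsistencyError("one tdm magnitude per virtual orbital")

    @property
    def n_virtuals(self) -> int:
        return len(self.orbital_energies)

    def virtual_ids(self) -> tuple:
        return tuple(range(self.n_virtuals))

    def config_energies(self, virtuals: Sequence[int]) -> np.ndarray:
        return self.core_energy + self.orbital_energies[list(virtuals)]

    def solve(self, virtuals: Sequence[int]):
        """Diagonalize the configuration Hamiltonian restricted to the given
        virtual orbitals.  Returns (energies eV, intensities, labels), the
        label naming the dominant configuration."""
        virtuals = sorted(set(int(v) for v in virtuals))
        if not virtuals:
            raise ConsistencyError("empty virtual set")
        idx = np.array(virtuals)
        h = np.diag(self.config_energies(idx)) + self.couplings[np.ix_(idx, idx)]
        evals, evecs = np.linalg.eigh(h)
        mu = self.tdm_rule[idx]
        intensities = (evecs.T @ mu) ** 2
        labels = tuple(
            f"{self.core_id}->v{idx[int(np.argmax(np.abs(evecs[:, i])))]}"
            for i in range(len(evals))
        )
        return evals, intensities, labels

    def solve_full(self):
        return self.solve(self.virtual_ids())


def make_toy_model(
    n_virtuals: int,
    coupling_scale: float = 0.0,
    seed: int = 0,
    block_size=None,
    core_energy: float = 287.0,
    spacing: float = 1.0,
    window: tuple = (0.0, np.inf),
) -> ToyElectronicModel:
    """Reproducible toy model.  With ``coupling_scale = 0`` the exact state
    energies equal the diagonal configuration energies.  With ``block_size``
    set (an int, or a sequence of per-block sizes), couplings between
    different energy-ordered blocks are zeroed, making the chunked iteration
    exact."""
    if n_virtuals < 1:
        raise ConsistencyError("need at least one virtual orbital")
    rng = np.random.default_rng(seed)
    eps = spacing * np.arange(1, n_virtuals + 1) + 0.1 * spacing * rng.random(n_virtuals)
    eps = np.sort(eps)
    w = coupling_scale * rng.standard_normal((n_virtuals, n_virtuals))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    if block_size is not None:
        if np.isscalar(block_size):
            blocks = np.arange(n_virtuals) // int(block_size)
        else:
            blocks = np.empty(n_virtuals, dtype=int)
            start = 0
            for bi, size in enumerate(block_size):
                blocks[start : start + int(size)] = bi
                start += int(size)
            if start != n_virtuals:
                raise ConsistencyError("block sizes must sum to n_virtuals")
        w *= blocks[:, None] == blocks[None, :]
    mu = 0.5 + rng.random(n_virtuals)
    return ToyElectronicModel(
        core_energy=core_energy,
        orbital_energies=eps,
        couplings=w,
        tdm_rule=mu,
        window=window,
    )


# ---------------------------------------------------------------------------
# named presets
# ---------------------------------------------------------------------------

PRESETS = {
    # three displaced modes spanning low/mid/high wavenumbers
    "three-mode-dho": FixtureSpec(
        n_modes=3,
        frequencies=(600.0, 1200.0, 2400.0),
        target_huang_rhys=(0.3, 0.5, 0.15),
        vertical_energy=290.0,
        lifetime=2.0,
        seed=11,
        label="1s -> pi* (three-mode)",
    ),
    # C=O and C-H symmetric stretches of the formaldehyde 1s_C -> pi*
    # transition; excited-state frequency change plus mode mixing splits the
    # third vibronic band in two sub-peaks
    "formaldehyde-like": FixtureSpec(
        n_modes=2,
        frequencies=(1753.0, 2970.0),
        target_huang_rhys=(0.9, 0.1),
        vertical_energy=286.0,
        lifetime=4.0,
        ht_derivatives=(0.05, 0.02),
        duschinsky_angle=math.radians(20.0),
        es_frequency_scale=(0.95, 0.80),
        seed=5,
        label="1s_C -> pi*",
    ),
}


def preset_spec(name: str, seed: Optional[int] = None) -> FixtureSpec:
    """Look up a named fixture preset, optionally overriding the seed."""
    if name not in PRESETS:
        raise ConsistencyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[name]
    if seed is not None:
        spec = FixtureSpec(**{**spec.__dict__, "seed": seed})
    return spec
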