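"""Displaced-harmonic-oscillator parameters from excited-state gradients.

The DHO model assumes ground and final electronic states share identical
harmonic wells that differ only in equilibrium position.  The Cartesian
energy gradient of the final state, evaluated at the ground-state minimum,
then determines the dimensionless displacement of every normal mode:

    Delta_k = -g_k / omega_k^(3/2)      (atomic units, hbar = 1)
    S_k     = Delta_k^2 / 2 = g_k^2 / (2 omega_k^3)
    lam_k   = S_k * hbar*omega_k
    E_00    = E_vert - sum_k lam_k

where g_k is the gradient projected onto mass-weighted normal mode k.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np

from .constants import AMU_TO_ME, HARTREE_EV, HBAR_EV_FS, cm1_to_ev, cm1_to_hartree
from .models import ConsistencyError, DHOParameters, HarmonicModel

__all__ = [
    "project_gradient",
    "dho_parameters",
    "dho_from_state",
    "zpe_shift",
    "lifetime_to_fwhm",
    "trans_rot_projector",
    "flag_dho_suspect",
]


def trans_rot_projector(model: HarmonicModel) -> np.ndarray:
    """Projector (3N x 3N) onto the internal subspace of mass-weighted
    displacement space: rigid translations and infinitesimal rotations about
    the center of mass are projected out (Eckart conditions)."""
    n = model.n_atoms
    m_me = model.masses * AMU_TO_ME
    sqm = np.sqrt(m_me)
    geom = model.geometry_bohr()
    com = (m_me[:, None] * geom).sum(axis=0) / m_me.sum()
    r = geom - com

    vecs = []
    for ax in range(3):                       # translations
        t = np.zeros((n, 3))
        t[:, ax] = sqm
        vecs.append(t.ravel())
    for ax in range(3):                       # rotations
        e = np.zeros(3)
        e[ax] = 1.0
        rot = np.cross(np.broadcast_to(e, (n, 3)), r) * sqm[:, None]
        vecs.append(rot.ravel())

    basis = np.array(vecs).T                  # (3N, 6)
    # orthonormalize, dropping null rotations (linear molecules, single atoms)
    q, s, _ = np.linalg.svd(basis, full_matrices=False)
    keep = s > 1e-10 * max(s.max(), 1.0)
    q = q[:, keep]
    return np.eye(3 * n) - q @ q.T


def project_gradient(gradient: np.ndarray, model: HarmonicModel) -> np.ndarray:
    """Project a Cartesian gradient (Hartree/Bohr, length 3N) onto the
    mass-weighted normal modes, returning per-mode gradients g_k in atomic
    units.  Translational/rotational contamination is removed first."""
    gradient = np.asarray(gradient, dtype=float).ravel()
    n3 = 3 * model.n_atoms
    if gradient.shape != (n3,):
        raise ConsistencyError(f"gradient length {gradient.size} != 3N = {n3}")
    sqm = np.sqrt(np.repeat(model.masses * AMU_TO_ME, 3))
    g_mw = gradient / sqm                     # mass-weighted gradient
    g_clean = trans_rot_projector(model) @ g_mw
    return model.mass_weighted_modes().T @ g_clean


def dho_parameters(
    mode_gradients: np.ndarray,
    model: HarmonicModel,
    vertical_energy_ev: float,
) -> DHOParameters:
    """DHO parameters from per-mode gradients (atomic units) as produced by
    :func:`project_gradient`."""
    g = np.asarray(mode_gradients, dtype=float).ravel()
    if g.shape != (model.n_modes,):
        raise ConsistencyError("one gradient component per mode required")
    omega = cm1_to_hartree(model.frequencies)
    if np.any(omega <= 0):
        raise ConsistencyError("nonpositive frequency")
    delta = -g / omega**1.5
    s = delta**2 / 2.0
    lam_ev = g**2 / (2.0 * omega**2) * HARTREE_EV
    total = float(lam_ev.sum())
    return DHOParameters(
        frequencies=model.frequencies.copy(),
        displacements=delta,
        huang_rhys=s,
        reorg_ev=lam_ev,
        total_reorg_ev=total,
        vertical_energy_ev=float(vertical_energy_ev),
        adiabatic_energy_ev=float(vertical_energy_ev) - total,
    )


def dho_from_state(model: HarmonicModel, state) -> DHOParameters:
    """Convenience: Cartesian gradient of an ElectronicStateRecord straight
    to DHO parameters."""
    g = project_gradient(state.gradient, model)
    return dho_parameters(g, model, state.vertical_energy)


def _match_modes(gs: HarmonicModel, es: HarmonicModel) -> np.ndarray:
    """Pair ES modes with GS modes by maximum overlap of mass-weighted mode
    vectors (greedy assignment); warn on ambiguous (<0.5) overlaps and fall
    back to sorted-frequency order when shapes make overlap meaningless."""
    if gs.n_atoms != es.n_atoms:
        raise ConsistencyError("mode matching requires identical atom counts")
    lg = gs.mass_weighted_modes()
    le = es.mass_weighted_modes()
    if lg.shape != le.shape:
        raise ConsistencyError("mode-count mismatch between state harmonic models")
    overlap = np.abs(le.T @ lg)               # (M_es, M_gs)
    m = overlap.shape[0]
    order = np.full(m, -1)
    cost = overlap.copy()
    for _ in range(m):
        i, j = np.unravel_index(np.argmax(cost), cost.shape)
        order[i] = j
        if overlap[i, j] < 0.5:
            warnings.warn(
                f"ambiguous mode match (overlap {overlap[i, j]:.2f}) between "
                f"ES mode {i} and GS mode {j}; falling back to frequency order",
                stacklevel=3,
            )
            return np.argsort(np.argsort(es.frequencies))[np.argsort(gs.frequencies)]
        cost[i, :] = -1.0
        cost[:, j] = -1.0
    return order


def zpe_shift(gs: HarmonicModel, es: HarmonicModel, match: Optional[np.ndarray] = None) -> float:
    """Zero-point-energy difference in eV:

        dZPE = 1/2 * sum_k hbar*(omega'_k - omega_k)

    positive when the final-state well stiffens.  ES modes are paired with
    GS modes by maximum mode-vector overlap unless an explicit matching map
    (ES index -> GS index) is supplied."""
    if es.n_modes != gs.n_modes:
        raise ConsistencyError("mode-count mismatch; supply an explicit matching map")
    if match is None:
        match = _match_modes(gs, es)
    diff = cm1_to_ev(es.frequencies) - cm1_to_ev(gs.frequencies[match])
    return float(0.5 * diff.sum())


def lifetime_to_fwhm(tau_fs: float) -> float:
    """Lorentzian FWHM (eV) from a core-hole lifetime (fs): Gamma = hbar/tau."""
    if not tau_fs > 0:
        raise ConsistencyError("lifetime must be positive")
    return HBAR_EV_FS / tau_fs


def flag_dho_suspect(dho: DHOParameters, reorg_threshold_ev: float = 0.5) -> np.ndarray:
    """Indices of modes whose reorganization energy exceeds the threshold.

    Large per-mode reorganization energies signal strongly displaced,
    potentially anharmonic or dissociative coordinates for which the
    identical-well assumption is unreliable; such modes are reported as
    diagnostics rather than treated."""
    return np.flatnonzero(dho.reorg_ev > reorg_threshold_ev)
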