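"""Beyond-DHO intensities: Duschinsky-rotated Franck-Condon integrals and
linear Herzberg-Teller corrections.

The excited-state normal coordinates are related to the ground-state ones by
Q' = J Q + shift with J = L'^T L in mass-weighted coordinates.  Overlaps of
the ground vibrational state |0> with excited-state levels |n'> are obtained
from a Gaussian generating-function recursion (the Doktorov-class scheme
used by Franck-Condon codes): writing the overlap integrand as a Gaussian
times Hermite polynomials,

    T(n) = INT dQ exp(-1/2 Q^T M Q + c^T Q + const) prod_k H_{n_k}(x_k(Q)),

the Hermite three-term recurrence plus Gaussian integration by parts gives

    T(n + 1_k) = b_k T(n) + sum_m n_m (A_{km} - 2 delta_{km}) T(n - 1_m)

with M = G + J^T G' J, c = -J^T G' d, B = sqrt(G') J, b = 2(B M^-1 c + d'),
A = 4 B M^-1 B^T, d' the dimensionless excited-state shift.  The same table
yields the Herzberg-Teller matrix elements <0| q_k |n'> through the Gaussian
first-moment identity.  Everything is validated against explicit numerical
quadrature of harmonic-oscillator wavefunctions in the test suite.

Conventions (the single largest source of silent sqrt(2) bugs, so stated
once): K and the transition-dipole derivatives dmu are both expressed in
dimensionless ground-state normal coordinates q_k = sqrt(omega_k) Q_k
(atomic units, hbar = 1).  K is the position of the excited-state minimum;
for J = I and equal frequencies, S_k = K_k^2 / 2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .constants import AMU_TO_ME, BOHR_ANGSTROM, cm1_to_ev, cm1_to_hartree
from .models import (
    ConsistencyError,
    CorevibError,
    DHOParameters,
    DuschinskyTransform,
    HarmonicModel,
    HTExpansion,
    StickSpectrum,
)

__all__ = [
    "build_duschinsky",
    "dho_transform",
    "fc_integrals",
    "DuschinskyIntegrals",
    "fcht_sticks",
    "duschinsky_sticks",
]

#: combinatorial guard: beyond this many mixed modes the dense overlap table
#: is not tractable; block-diagonal treatment of J is required instead.
MAX_MIXED_MODES = 10


def _kabsch(p: np.ndarray, q: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted rotation matrix R minimizing sum w |p - q R^T|^2."""
    h = (w[:, None] * q).T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def build_duschinsky(gs: HarmonicModel, es: HarmonicModel) -> DuschinskyTransform:
    """Duschinsky transform linking ground- and excited-state modes.

    The excited-state geometry and mode vectors are first Eckart-aligned
    (mass-weighted Kabsch rotation onto the ground-state frame, centers of
    mass superimposed); then J = L'^T L and K is the mass-weighted geometry
    difference projected on the ground-state modes and nondimensionalized.
    """
    if gs.atom_symbols != es.atom_symbols or not np.allclose(gs.masses, es.masses):
        raise ConsistencyError("ground and excited harmonic models must share atoms/masses")
    m_me = gs.masses * AMU_TO_ME
    xg = gs.geometry_bohr()
    xe = es.geometry_bohr()
    cg = (m_me[:, None] * xg).sum(0) / m_me.sum()
    ce = (m_me[:, None] * xe).sum(0) / m_me.sum()
    rot = _kabsch(xg - cg, xe - ce, m_me)
    xe_al = (xe - ce) @ rot.T + cg
    es_al = HarmonicModel(
        es.atom_symbols, es.masses, xe_al * BOHR_ANGSTROM,
        es.frequencies, es.mode_vectors @ rot.T, es.linear_flag,
    )

    lg = gs.mass_weighted_modes()            # (3N, M)
    le = es_al.mass_weighted_modes()
    j = le.T @ lg
    dev = float(np.abs(j @ j.T - np.eye(len(j))).max())

    dx_mw = (np.sqrt(m_me)[:, None] * (xe_al - xg)).ravel()
    q_star = lg.T @ dx_mw                    # GS mass-weighted coords of ES minimum
    k = np.sqrt(cm1_to_hartree(gs.frequencies)) * q_star
    return DuschinskyTransform(j, k, gs.frequencies.copy(), es.frequencies.copy(), dev)


def dho_transform(dho: DHOParameters) -> DuschinskyTransform:
    """The identity-mixing transform equivalent to a DHO: J = I, K = Delta,
    identical frequency sets."""
    m = dho.n_modes
    return DuschinskyTransform(
        np.eye(m), dho.displacements.copy(),
        dho.frequencies.copy(), dho.frequencies.copy(), 0.0,
    )


@dataclass(frozen=True)
class DuschinskyIntegrals:
    """Tabulated overlaps of the ground vibrational state with excited-state
    levels up to nmax quanta per mode.

    ``overlaps[n1, n2, ...]`` is the signed overlap <0|n'>;
    ``q_overlaps[k, n1, n2, ...]`` is <0| q_k |n'> with q_k the k-th
    dimensionless ground-state coordinate.
    """

    nmax: tuple
    overlaps: np.ndarray
    q_overlaps: np.ndarray
    es_frequencies: np.ndarray     # cm^-1

    def completeness(self) -> float:
        """sum |<0|n'>|^2; approaches 1 as nmax grows."""
        return float((self.overlaps**2).sum())

    def indices(self):
        return itertools.product(*(range(n + 1) for n in self.nmax))


def fc_integrals(
    transform: DuschinskyTransform,
    nmax: Union[int, Sequence[int]] = 8,
) -> DuschinskyIntegrals:
    """Recursively generate <0|n'> and <0|q_k|n'> up to nmax quanta per mode."""
    m = transform.n_modes
    if m > MAX_MIXED_MODES:
        raise CorevibError(
            f"{m} mixed modes exceed the dense-table limit ({MAX_MIXED_MODES}); "
            "apply a block-diagonal approximation to J"
        )
    if np.isscalar(nmax):
        nmax = (int(nmax),) * m
    nmax = tuple(int(n) for n in nmax)
    if len(nmax) != m:
        raise ConsistencyError("one nmax per mode required")

    w = cm1_to_hartree(transform.gs_frequencies)
    wp = cm1_to_hartree(transform.es_frequencies)
    if np.any(w <= 0) or np.any(wp <= 0):
        raise ConsistencyError("nonpositive frequency in Duschinsky transform")
    j = transform.J
    # ES coordinates of the GS minimum: Q' = J Q + d with d = -J Q*,
    # Q* = K / sqrt(omega) the ES minimum in GS mass-weighted coordinates.
    d = -j @ (transform.K / np.sqrt(w))

    gamma = np.diag(w)
    gamma_p = np.diag(wp)
    mmat = gamma + j.T @ gamma_p @ j
    sign, logdet = np.linalg.slogdet(mmat)
    if sign <= 0:
        raise ConsistencyError("singular Duschinsky transformation matrix")
    minv = np.linalg.inv(mmat)
    c = -j.T @ gamma_p @ d
    b_mat = np.sqrt(wp)[:, None] * j          # B = sqrt(G') J
    delta = np.sqrt(wp) * d                   # dimensionless ES shift

    b = 2.0 * (b_mat @ minv @ c + delta)
    a = 4.0 * b_mat @ minv @ b_mat.T

    t0 = math.exp(
        0.5 * m * math.log(2.0 * math.pi) - 0.5 * logdet
        + 0.5 * float(c @ minv @ c) - 0.5 * float(d @ gamma_p @ d)
    )
    pref = math.exp(0.25 * float(np.log(w).sum() + np.log(wp).sum()) - 0.5 * m * math.log(math.pi))

    shape = tuple(n + 1 for n in nmax)
    t = np.zeros(shape)
    t[(0,) * m] = t0
    # lexicographic fill: every index depends only on smaller indices
    for idx in itertools.product(*(range(s) for s in shape)):
        if not any(idx):
            continue
        k = next(i for i, n in enumerate(idx) if n)
        prev = list(idx)
        prev[k] -= 1                          # recursion advanced along mode k
        val = b[k] * t[tuple(prev)]
        for mm in range(m):
            if prev[mm] > 0:
                pp = list(prev)
                pp[mm] -= 1
                coeff = a[k, mm] - (2.0 if mm == k else 0.0)
                val += prev[mm] * coeff * t[tuple(pp)]
        t[idx] = val

    norm = np.ones(shape)
    for k in range(m):
        fac = np.array([math.sqrt((2.0**n) * math.factorial(n)) for n in range(shape[k])])
        norm *= fac.reshape([-1 if i == k else 1 for i in range(m)])
    overlaps = pref * t / norm

    # <0| q_k |n'> from the Gaussian first moment of Q, q = sqrt(omega) Q:
    # INT Q w F = M^-1 (c T(n) + 2 sum_m n_m B_m. T(n - 1_m))
    minv_c = minv @ c
    minv_bt = minv @ b_mat.T
    q_t = np.zeros((m,) + shape)
    for idx in itertools.product(*(range(s) for s in shape)):
        acc = minv_c * t[idx]
        for mm in range(m):
            if idx[mm] > 0:
                pp = list(idx)
                pp[mm] -= 1
                acc = acc + 2.0 * idx[mm] * minv_bt[:, mm] * t[tuple(pp)]
        q_t[(slice(None),) + idx] = acc
    q_overlaps = np.sqrt(w)[:, None].reshape((m,) + (1,) * m) * pref * q_t / norm[None]

    return DuschinskyIntegrals(nmax, overlaps, q_overlaps, transform.es_frequencies.copy())


def fcht_sticks(
    transform: DuschinskyTransform,
    ht: Optional[HTExpansion],
    e00_ev: float,
    nmax: Union[int, Sequence[int]] = 8,
    intensity0: Optional[float] = None,
) -> StickSpectrum:
    """Vibronic sticks including Duschinsky rotation and, when ``ht`` is
    given, linear Herzberg-Teller intensity borrowing:

        I(n') = | mu0 <0|n'> + sum_k dmu_k <0|q_k|n'> |^2

    at energies E_00 + sum_k n'_k hbar*omega'_k.  With ``ht=None`` the Condon
    intensities ``intensity0 * <0|n'>^2`` are produced instead.
    """
    table = fc_integrals(transform, nmax)
    hw = cm1_to_ev(transform.es_frequencies)
    energies, intens, labels = [], [], []
    for idx in table.indices():
        ov = table.overlaps[idx]
        if ht is None:
            inten = (1.0 if intensity0 is None else intensity0) * ov * ov
        else:
            amp = ht.mu0 * ov
            for k in range(transform.n_modes):
                amp = amp + ht.dmu[k] * table.q_overlaps[(k,) + idx]
            inten = float(amp @ amp)
        energies.append(e00_ev + float(np.dot(idx, hw)))
        intens.append(inten)
        labels.append(_label(idx))
    return StickSpectrum(np.array(energies), np.array(intens), tuple(labels))


def duschinsky_sticks(
    transform: DuschinskyTransform,
    intensity0: float,
    e00_ev: float,
    nmax: Union[int, Sequence[int]] = 8,
) -> StickSpectrum:
    """Condon-level sticks with Duschinsky rotation (no HT terms)."""
    return fcht_sticks(transform, None, e00_ev, nmax, intensity0=intensity0)


def _label(quanta) -> str:
    if not any(quanta):
        return "0-0"
    return "+".join(f"v{k + 1}'^{n}" for k, n in enumerate(quanta) if n)
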