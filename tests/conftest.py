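"""Shared fixtures and independent oracles for the test suite.

The quadrature oracle evaluates vibrational overlap integrals by explicit
numerical integration of harmonic-oscillator wavefunctions on dense grids
(1 or 2 modes); it shares no code with the recursion it checks.
"""

import math

import numpy as np
import pytest
from scipy.special import eval_hermite

from corevib.constants import CM_PER_EV, HARTREE_EV

CM1_TO_AU = 1.0 / (CM_PER_EV * HARTREE_EV)


def quadrature_overlap(transform, quanta, q_mode=None, npts=401, lim=9.0):
    """<0 | n'> (or <0| q_k |n'> when q_mode is given) by dense quadrature.

    Wavefunctions are written in ground-state mass-weighted coordinates Q;
    the excited-state coordinates are Q' = J Q + d with d = -J K/sqrt(w).
    Supports 1 or 2 modes.
    """
    wg = np.asarray(transform.gs_frequencies) * CM1_TO_AU
    we = np.asarray(transform.es_frequencies) * CM1_TO_AU
    j = transform.J
    d = -j @ (transform.K / np.sqrt(wg))
    m = len(wg)
    axes = [np.linspace(-lim / math.sqrt(w), lim / math.sqrt(w), npts) for w in wg]
    if m == 1:
        grids = [axes[0]]
        measure = axes[0][1] - axes[0][0]
    elif m == 2:
        g1, g2 = np.meshgrid(axes[0], axes[1], indexing="ij")
        grids = [g1, g2]
        measure = (axes[0][1] - axes[0][0]) * (axes[1][1] - axes[1][0])
    else:
        raise ValueError("oracle supports 1 or 2 modes")

    q = np.stack(grids)
    psi0 = np.prod([(wg[k] / math.pi) ** 0.25 * np.exp(-0.5 * wg[k] * q[k] ** 2) for k in range(m)], axis=0)
    qp = np.einsum("ij,j...->i...", j, q) + d.reshape((m,) + (1,) * (q.ndim - 1))
    x = np.sqrt(we).reshape((m,) + (1,) * (q.ndim - 1)) * qp
    psin = np.prod([(we[k] / math.pi) ** 0.25 * np.exp(-0.5 * x[k] ** 2) for k in range(m)], axis=0)
    for k, nk in enumerate(quanta):
        psin = psin * eval_hermite(nk, x[k]) / math.sqrt(2.0**nk * math.factorial(nk))
    integrand = psi0 * psin
    if q_mode is not None:
        integrand = integrand * math.sqrt(wg[q_mode]) * q[q_mode]
    return float(integrand.sum() * measure)


@pytest.fixture
def quad_oracle():
    return quadrature_overlap


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
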