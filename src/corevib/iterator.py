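"""Divide-and-conquer accumulation of core-excited states over
virtual-orbital chunks.

Full multiconfigurational treatment of many core-excited states is limited
by active-space size.  The iterative scheme keeps a minimal active space
(core orbital + a few occupied + the lowest virtual) fixed, adds small
energy-ordered chunks of n further virtual orbitals, computes the states of
each enlarged space through a pluggable backend, and accumulates spectra
over iterations.  States recomputed at every step (e.g. the core->LUMO line
and its shake-up satellites) are removed by label/energy duplicate matching
before summation; iteration stops once a step contributes no new state
inside the energy window of interest.  The scheme ignores couplings between
states computed in different iterations, so with a block-diagonal
interaction it is exact — the property the test suite verifies against
single-shot full-space diagonalization.

The backend contract is a single pure function: given the core orbital, the
occupied set and a list of virtual orbitals, return (energies, intensities,
dominant-configuration labels).  A real multireference engine is one
backend; :class:`corevib.synthetic.ToyElectronicModel` provides another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .models import ConsistencyError, CorevibError, StickSpectrum

__all__ = [
    "OrbitalPool",
    "StateRecord",
    "IterationResult",
    "plan_chunks",
    "run_iteration",
    "dedup_states",
    "check_convergence",
    "iterate_active_space",
    "ToyBackend",
    "states_to_sticks",
]


@dataclass(frozen=True)
class OrbitalPool:
    """Virtual-orbital pool to be consumed in energy-ordered chunks.

    ``minas_virtual_ids`` are the virtuals of the minimal active space
    (typically the LUMO); they take part in every iteration and are not
    chunked."""

    core_id: str
    occupied_ids: tuple
    virtual_ids: tuple
    orbital_energies: dict            # id -> eV
    minas_virtual_ids: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "occupied_ids", tuple(self.occupied_ids))
        object.__setattr__(self, "virtual_ids", tuple(self.virtual_ids))
        object.__setattr__(self, "minas_virtual_ids", tuple(self.minas_virtual_ids))
        ids = self.virtual_ids + self.minas_virtual_ids
        if len(set(ids)) != len(ids):
            raise ConsistencyError("orbital ids must be unique")
        if not self.virtual_ids:
            raise ConsistencyError("virtual orbital pool is empty")
        missing = [v for v in ids if v not in self.orbital_energies]
        if missing:
            raise ConsistencyError(f"no orbital energy for {missing}")


@dataclass(frozen=True)
class StateRecord:
    """One electronic state produced by a backend call."""

    energy: float                     # eV
    intensity: float
    label: str                        # dominant-configuration tag
    iteration: int = 0
    chunk: tuple = ()


@dataclass(frozen=True)
class IterationResult:
    index: int
    chunk: tuple
    states: tuple                     # StateRecord, this iteration (pre-dedup)
    duplicates_removed: int
    new_in_window: int

    def __post_init__(self):
        if self.duplicates_removed < 0:
            raise ConsistencyError("duplicates_removed must be >= 0")
        if not all(np.isfinite(s.energy) for s in self.states):
            raise ConsistencyError("non-finite state energy")


def plan_chunks(pool: OrbitalPool, n: int) -> List[tuple]:
    """Partition the pool's virtuals into energy-ordered chunks of size n
    (the last may be smaller).  Deterministic."""
    if n < 1:
        raise ConsistencyError("chunk size must be >= 1")
    ordered = sorted(pool.virtual_ids, key=lambda v: (pool.orbital_energies[v], str(v)))
    return [tuple(ordered[i : i + n]) for i in range(0, len(ordered), n)]


def run_iteration(
    backend: Callable,
    pool: OrbitalPool,
    chunk: Sequence,
    index: int = 0,
) -> IterationResult:
    """Invoke the backend once on minAS + chunk and tag the states with
    their provenance."""
    chunk = tuple(chunk)
    virtuals = tuple(pool.minas_virtual_ids) + chunk
    try:
        energies, intensities, labels = backend(pool.core_id, pool.occupied_ids, virtuals)
    except Exception as exc:  # surface with chunk context
        raise CorevibError(f"backend failed on chunk {chunk} (iteration {index}): {exc}") from exc
    states = tuple(
        StateRecord(float(e), float(i), str(l), iteration=index, chunk=chunk)
        for e, i, l in zip(energies, intensities, labels)
    )
    return IterationResult(index, chunk, states, duplicates_removed=0, new_in_window=0)


def dedup_states(states: Sequence[StateRecord], energy_tol: float = 1e-6) -> List[StateRecord]:
    """Remove recomputed states: among states sharing a dominant-configuration
    label with energies within ``energy_tol`` eV, keep the first occurrence
    (earliest iteration, then input order)."""
    kept: List[StateRecord] = []
    for s in sorted(states, key=lambda s: (s.iteration,)):
        dup = any(
            s.label == k.label and abs(s.energy - k.energy) <= energy_tol for k in kept
        )
        if not dup:
            kept.append(s)
    return kept


def check_convergence(latest: IterationResult, window: Tuple[float, float]) -> bool:
    """True when the latest iteration contributed no new (post-dedup) state
    inside the energy window."""
    lo, hi = window
    if not lo < hi:
        raise ConsistencyError("malformed energy window")
    return latest.new_in_window == 0


@dataclass
class IterationLog:
    """Accumulated outcome of an active-space iteration run."""

    results: List[IterationResult] = field(default_factory=list)
    states: List[StateRecord] = field(default_factory=list)   # deduplicated
    converged_at: Optional[int] = None

    def lines(self) -> List[str]:
        out = []
        for r in self.results:
            out.append(
                f"iter {r.index}: chunk={r.chunk} states={len(r.states)} "
                f"dups_removed={r.duplicates_removed} new_in_window={r.new_in_window}"
            )
        if self.converged_at is not None:
            out.append(f"converged at iteration {self.converged_at}")
        return out


def iterate_active_space(
    backend: Callable,
    pool: OrbitalPool,
    chunk_size: int,
    window: Tuple[float, float] = (0.0, np.inf),
    energy_tol: float = 1e-6,
    stop_on_convergence: bool = False,
) -> IterationLog:
    """Run the chunked accumulation over the whole pool.

    Each chunk is computed once, duplicates against the accumulated state
    list are removed, and the per-iteration count of new in-window states is
    logged.  With ``stop_on_convergence`` the loop ends at the first
    iteration contributing nothing new inside the window.
    """
    log = IterationLog()
    lo, hi = window
    for index, chunk in enumerate(plan_chunks(pool, chunk_size)):
        result = run_iteration(backend, pool, chunk, index)
        merged = dedup_states(list(log.states) + list(result.states), energy_tol)
        # accumulated states are already deduplicated and precede this
        # iteration, so the tail of `merged` is exactly the new states
        new_states = merged[len(log.states):]
        dups = len(result.states) - len(new_states)
        new_in_window = sum(1 for s in new_states if lo <= s.energy <= hi)
        result = IterationResult(index, result.chunk, result.states, dups, new_in_window)
        log.results.append(result)
        log.states = merged
        if check_convergence(result, window) and log.converged_at is None:
            log.converged_at = index
            if stop_on_convergence:
                break
    return log


class ToyBackend:
    """Backend over a :class:`corevib.synthetic.ToyElectronicModel`."""

    def __init__(self, model):
        self.model = model

    def __call__(self, core_id, occupied_ids, virtual_ids):
        idx = [int(str(v).lstrip("v")) for v in virtual_ids]
        return self.model.solve(idx)


def states_to_sticks(states: Sequence[StateRecord]) -> StickSpectrum:
    """Accumulated states as a stick spectrum for hand-off to assembly."""
    if not states:
        return StickSpectrum(np.empty(0), np.empty(0))
    return StickSpectrum(
        np.array([s.energy for s in states]),
        np.array([s.intensity for s in states]),
        tuple(s.label for s in states),
    )
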