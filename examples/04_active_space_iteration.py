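"""Chunked active-space accumulation of core-excited states.

A toy configuration model stands in for the multireference engine: one
core->virtual configuration per virtual orbital with block-diagonal
couplings.  The iterator keeps the minimal active space (core + HOMO +
LUMO) fixed, adds two virtual orbitals per step, removes the recomputed
core->LUMO state, and stops contributing new states once the window of
interest is exhausted.  With block-diagonal couplings the accumulated
result equals single-shot diagonalization of the full space.
"""

import numpy as np

from corevib import iterator, synthetic

model = synthetic.make_toy_model(
    n_virtuals=7, coupling_scale=0.5, seed=31, block_size=(1, 2, 2, 2)
)
energies = {v: float(model.config_energies([v])[0]) for v in range(7)}
pool = iterator.OrbitalPool(
    core_id="1s", occupied_ids=("homo",),
    virtual_ids=tuple(range(1, 7)),      # six virtuals, chunked in pairs
    orbital_energies=energies,
    minas_virtual_ids=(0,),              # the LUMO stays in every iteration
)

log = iterator.iterate_active_space(
    iterator.ToyBackend(model), pool, chunk_size=2, window=(287.0, 296.0)
)
for line in log.lines():
    print(line)

full_e, full_i, _ = model.solve_full()
acc = sorted((s.energy, s.intensity) for s in log.states)
err = max(
    abs(a - b) for pa, pb in zip(acc, sorted(zip(full_e, full_i))) for a, b in zip(pa, pb)
)
print(f"accumulated {len(log.states)} states over {len(log.results)} iterations")
print(f"max |chunked - full-space| deviation: {err:.2e}")
print("duplicates removed are the core->LUMO state recomputed in every chunk;")
print("zero deviation shows the scheme is exact for block-diagonal couplings.")
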