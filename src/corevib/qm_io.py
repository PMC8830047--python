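"""Read/write harmonic data, calculation bundles and spectra.

Supported formats:

* Molden frequency files ([FREQ], [FR-COORD], [FR-NORM-COORD] sections) for
  ground- or excited-state harmonic data.
* A versioned YAML bundle schema (documented in :data:`BUNDLE_SCHEMA_DOC`)
  holding one molecule/conformer: harmonic block, electronic-state records,
  optional IP threshold and thermochemistry metadata.
* Tab-separated spectrum files: two columns for grids, three (energy,
  intensity, label) for sticks.

All values round-trip losslessly (floats are written with 17 significant
digits).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .constants import BOHR_ANGSTROM, HARTREE_EV
from .models import (
    CalculationBundle,
    ConsistencyError,
    ElectronicStateRecord,
    FormatError,
    GridSpectrum,
    HarmonicModel,
    StickSpectrum,
)

__all__ = [
    "read_molden_frequencies",
    "write_molden",
    "read_bundle",
    "write_bundle",
    "write_spectrum",
    "read_spectrum",
    "ATOMIC_MASSES",
]

#: standard atomic weights (amu) for the elements this package meets in
#: practice; "X" is the unit-mass pseudo-atom of the synthetic fixtures.
ATOMIC_MASSES = {
    "X": 1.0, "H": 1.00794, "He": 4.002602, "Li": 6.941, "Be": 9.012182,
    "B": 10.811, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403,
    "Ne": 20.1797, "Na": 22.98977, "Mg": 24.305, "Al": 26.981538,
    "Si": 28.0855, "P": 30.973762, "S": 32.065, "Cl": 35.453, "Ar": 39.948,
}

BUNDLE_SCHEMA_VERSION = 1

BUNDLE_SCHEMA_DOC = """\
corevib bundle schema, version 1 (YAML):

corevib_bundle: 1
units:
  energy: eV | hartree          # vertical energies and ip_threshold
harmonic:                       # ground-state harmonic block
  atoms: [C, O, ...]
  masses_amu: [...]             # optional; element table used when absent
  geometry_angstrom: [[x, y, z], ...]
  frequencies_cm1: [...]
  modes: [[[dx, dy, dz], ...], ...]   # Cartesian displacements per mode
  linear: false
states:
  - label: "1s_C -> pi*"
    kind: core-excited | core-cation
    vertical_energy: ...        # in `units.energy`
    gradient: [...]             # Hartree/Bohr, length 3N
    lifetime_fs: ...
    tdm: [x, y, z]              # a.u.; core-excited only
    dyson_norm: ...             # [0, 1]; core-cation only
    tdm_derivatives: [[...], ...]    # optional, (n_modes, 3)
    es_harmonic: {...}          # optional, same layout as `harmonic`
ip_threshold: ...               # optional, in `units.energy`
conformer_label: ""             # optional
delta_g_kjmol: ...              # optional, vs reference conformer
temperature_K: ...              # optional
"""


# ---------------------------------------------------------------------------
# Molden frequency files
# ---------------------------------------------------------------------------


def _molden_sections(text: str) -> dict:
    sections: dict = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            current = line.split("]")[0].lstrip("[").strip().upper()
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    return sections


def _collinear(geometry: np.ndarray, tol: float = 1e-8) -> bool:
    if len(geometry) < 3:
        return True
    rel = geometry - geometry[0]
    return np.linalg.matrix_rank(rel, tol=max(tol, tol * np.abs(rel).max())) < 2


def read_molden_frequencies(
    path,
    masses: Optional[np.ndarray] = None,
    mass_weighted: bool = False,
    drop_nonpositive: bool = False,
) -> HarmonicModel:
    """Parse the [FREQ]/[FR-COORD]/[FR-NORM-COORD] sections of a Molden file.

    Parameters
    ----------
    masses : amu per atom; looked up from the element table when omitted.
    mass_weighted : set True for Molden dialects that store mass-weighted
        rather than Cartesian mode vectors (they are divided by sqrt(m)
        before validation).
    drop_nonpositive : silently drop zero/imaginary (negative) frequencies
        and their modes instead of raising.
    """
    text = Path(path).read_text()
    sections = _molden_sections(text)
    for req in ("FREQ", "FR-COORD", "FR-NORM-COORD"):
        if req not in sections:
            raise FormatError(f"missing Molden section [{req}] in {path}")

    freqs = np.array([float(l.split()[0]) for l in sections["FREQ"]])

    symbols, coords = [], []
    for line in sections["FR-COORD"]:
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"bad [FR-COORD] line: {line!r}")
        symbols.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[1:4]])
    geometry = np.array(coords) * BOHR_ANGSTROM     # Molden FR-COORD is in Bohr
    n = len(symbols)

    modes, current = [], None
    for line in sections["FR-NORM-COORD"]:
        low = line.lower()
        if low.startswith("vibration"):
            current = []
            modes.append(current)
        else:
            if current is None:
                raise FormatError("[FR-NORM-COORD] data before any 'vibration' header")
            current.append([float(x) for x in line.split()[:3]])
    if len(modes) != len(freqs):
        raise FormatError(f"{len(modes)} mode blocks for {len(freqs)} frequencies")
    for i, mode in enumerate(modes):
        if len(mode) != n:
            raise FormatError(f"mode {i + 1} has {len(mode)} atom rows, expected {n}")
    vecs = np.array(modes)

    if drop_nonpositive:
        keep = freqs > 0
        freqs, vecs = freqs[keep], vecs[keep]

    if masses is None:
        try:
            masses = np.array([ATOMIC_MASSES[s] for s in symbols])
        except KeyError as exc:
            raise FormatError(f"no tabulated mass for element {exc.args[0]!r}; pass masses=") from None
    masses = np.asarray(masses, dtype=float)
    if mass_weighted:
        vecs = vecs / np.sqrt(masses)[None, :, None]

    return HarmonicModel(
        atom_symbols=tuple(symbols),
        masses=masses,
        geometry=geometry,
        frequencies=freqs,
        mode_vectors=vecs,
        linear_flag=_collinear(geometry),
    )


def write_molden(model: HarmonicModel, path) -> None:
    """Write a Molden frequency file (Cartesian mode vectors, Bohr coords)."""
    buf = io.StringIO()
    buf.write("[Molden Format]\n[FREQ]\n")
    for f in model.frequencies:
        buf.write(f" {f:.10f}\n")
    buf.write("[FR-COORD]\n")
    for sym, xyz in zip(model.atom_symbols, model.geometry_bohr()):
        buf.write(f" {sym} {xyz[0]:.12f} {xyz[1]:.12f} {xyz[2]:.12f}\n")
    buf.write("[FR-NORM-COORD]\n")
    for k, vec in enumerate(model.mode_vectors, start=1):
        buf.write(f" vibration {k}\n")
        for row in vec:
            buf.write(f"  {row[0]:.12f} {row[1]:.12f} {row[2]:.12f}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# YAML bundles
# ---------------------------------------------------------------------------


def _harmonic_to_dict(model: HarmonicModel) -> dict:
    return {
        "atoms": list(model.atom_symbols),
        "masses_amu": model.masses.tolist(),
        "geometry_angstrom": model.geometry.tolist(),
        "frequencies_cm1": model.frequencies.tolist(),
        "modes": model.mode_vectors.tolist(),
        "linear": bool(model.linear_flag),
    }


def _harmonic_from_dict(d: dict) -> HarmonicModel:
    try:
        atoms = tuple(d["atoms"])
        masses = d.get("masses_amu")
        if masses is None:
            masses = [ATOMIC_MASSES[str(s).capitalize()] for s in atoms]
        return HarmonicModel(
            atom_symbols=atoms,
            masses=np.asarray(masses, float),
            geometry=np.asarray(d["geometry_angstrom"], float),
            frequencies=np.asarray(d["frequencies_cm1"], float),
            mode_vectors=np.asarray(d["modes"], float),
            linear_flag=bool(d.get("linear", False)),
        )
    except KeyError as exc:
        raise FormatError(f"harmonic block missing key {exc.args[0]!r}") from None


_ENERGY_UNITS = {"ev": 1.0, "hartree": HARTREE_EV}


def read_bundle(path) -> CalculationBundle:
    """Read and validate a YAML calculation bundle (schema version 1).

    Energies tagged ``units.energy: hartree`` are converted to eV on read;
    unknown unit tags are an error.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "corevib_bundle" not in doc:
        raise FormatError(f"{path} is not a corevib bundle")
    if int(doc["corevib_bundle"]) != BUNDLE_SCHEMA_VERSION:
        raise FormatError(f"unsupported bundle schema version {doc['corevib_bundle']}")
    unit = str(doc.get("units", {}).get("energy", "eV")).lower()
    if unit not in _ENERGY_UNITS:
        raise FormatError(f"unknown energy unit tag {unit!r} (use eV or hartree)")
    to_ev = _ENERGY_UNITS[unit]

    if "harmonic" not in doc or "states" not in doc:
        raise FormatError("bundle requires 'harmonic' and 'states' blocks")
    harmonic = _harmonic_from_dict(doc["harmonic"])

    states = []
    for sd in doc["states"]:
        es = sd.get("es_harmonic")
        states.append(
            ElectronicStateRecord(
                label=str(sd.get("label", "")),
                kind=str(sd["kind"]),
                vertical_energy=float(sd["vertical_energy"]) * to_ev,
                gradient=np.asarray(sd["gradient"], float),
                lifetime=float(sd["lifetime_fs"]),
                tdm=None if sd.get("tdm") is None else np.asarray(sd["tdm"], float),
                dyson_norm=None if sd.get("dyson_norm") is None else float(sd["dyson_norm"]),
                es_harmonic=None if es is None else _harmonic_from_dict(es),
                tdm_derivatives=None
                if sd.get("tdm_derivatives") is None
                else np.asarray(sd["tdm_derivatives"], float),
            )
        )

    ip = doc.get("ip_threshold")
    return CalculationBundle(
        harmonic=harmonic,
        states=tuple(states),
        ip_threshold=None if ip is None else float(ip) * to_ev,
        conformer_label=str(doc.get("conformer_label", "")),
        delta_g=None if doc.get("delta_g_kjmol") is None else float(doc["delta_g_kjmol"]),
        temperature=None if doc.get("temperature_K") is None else float(doc["temperature_K"]),
    )


def write_bundle(bundle: CalculationBundle, path) -> None:
    """Serialize a bundle to the versioned YAML schema (energies in eV)."""
    doc: dict = {
        "corevib_bundle": BUNDLE_SCHEMA_VERSION,
        "units": {"energy": "eV"},
        "harmonic": _harmonic_to_dict(bundle.harmonic),
        "states": [],
    }
    for s in bundle.states:
        sd = {
            "label": s.label,
            "kind": s.kind,
            "vertical_energy": float(s.vertical_energy),
            "gradient": s.gradient.tolist(),
            "lifetime_fs": float(s.lifetime),
        }
        if s.tdm is not None:
            sd["tdm"] = s.tdm.tolist()
        if s.dyson_norm is not None:
            sd["dyson_norm"] = float(s.dyson_norm)
        if s.tdm_derivatives is not None:
            sd["tdm_derivatives"] = s.tdm_derivatives.tolist()
        if s.es_harmonic is not None:
            sd["es_harmonic"] = _harmonic_to_dict(s.es_harmonic)
        doc["states"].append(sd)
    if bundle.ip_threshold is not None:
        doc["ip_threshold"] = float(bundle.ip_threshold)
    if bundle.conformer_label:
        doc["conformer_label"] = bundle.conformer_label
    if bundle.delta_g is not None:
        doc["delta_g_kjmol"] = float(bundle.delta_g)
    if bundle.temperature is not None:
        doc["temperature_K"] = float(bundle.temperature)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, default_flow_style=None, sort_keys=False, width=100)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def write_spectrum(spectrum: Union[GridSpectrum, StickSpectrum], path) -> None:
    """Write a spectrum as TSV: '# corevib grid' header + two columns, or
    '# corevib sticks' header + energy/intensity/label columns."""
    buf = io.StringIO()
    if isinstance(spectrum, GridSpectrum):
        if not np.all(np.isfinite(spectrum.intensity)):
            raise ConsistencyError("non-finite intensity")
        buf.write("# corevib grid\n# energy_eV\tintensity\n")
        for e, y in zip(spectrum.grid, spectrum.intensity):
            buf.write(f"{e:.17g}\t{y:.17g}\n")
    elif isinstance(spectrum, StickSpectrum):
        buf.write("# corevib sticks\n# energy_eV\tintensity\tlabel\n")
        for e, y, lab in zip(spectrum.energies, spectrum.intensities, spectrum.labels):
            buf.write(f"{e:.17g}\t{y:.17g}\t{lab}\n")
    else:
        raise ConsistencyError(f"cannot write {type(spectrum).__name__}")
    Path(path).write_text(buf.getvalue())


def read_spectrum(path) -> Union[GridSpectrum, StickSpectrum]:
    """Read a TSV spectrum written by :func:`write_spectrum`."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# corevib"):
        raise FormatError(f"{path} is not a corevib spectrum file")
    kind = lines[0].split()[-1]
    rows = [l for l in lines if l and not l.startswith("#")]
    if kind == "grid":
        data = np.array([[float(x) for x in r.split("\t")] for r in rows])
        return GridSpectrum(data[:, 0], data[:, 1])
    if kind == "sticks":
        energies, intens, labels = [], [], []
        for r in rows:
            parts = r.split("\t")
            energies.append(float(parts[0]))
            intens.append(float(parts[1]))
            labels.append(parts[2] if len(parts) > 2 else "")
        return StickSpectrum(np.array(energies), np.array(intens), tuple(labels))
    raise FormatError(f"unknown spectrum kind {kind!r}")
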