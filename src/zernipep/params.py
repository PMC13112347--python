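"""Loaders for the shipped plain-text parameter tables.

Two tables ship with the package under ``zernipep/data``:

* ``nonbonded_heavy_v1.txt`` — per-(residue, atom) Lennard-Jones well depth
  ε (kcal/mol), Rmin/2 (Å) and partial charge (e) for the heavy atoms of
  the 20 standard amino acids, with hydrogen charges absorbed into their
  parent heavy atoms so heavy-atom structures keep integer residue charges.
* ``hydropathy_kyte_doolittle.txt`` — the default hydropathy scale.

Both formats are whitespace-delimited text so users can substitute their
own files (e.g. a different force field or a custom hydropathy scale).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .errors import ConfigurationError

_STANDARD_RESIDUES = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()


def _data_text(filename: str) -> str:
    return resources.files("zernipep.data").joinpath(filename).read_text()


def parse_parameter_table(text: str) -> dict:
    """Parse 'residue atom epsilon rmin_half charge' lines into a dict."""
    table: dict[tuple[str, str], tuple[float, float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, eps, rmin_half, charge = line.split()
        table[(res, atom)] = (float(eps), float(rmin_half), float(charge))
    return table


@lru_cache(maxsize=1)
def default_parameter_table() -> dict:
    """Shipped nonbonded table, with an OXT alias mapped to carbonyl O."""
    table = parse_parameter_table(_data_text("nonbonded_heavy_v1.txt"))
    for res in _STANDARD_RESIDUES:
        o_entry = table[(res, "O")]
        table.setdefault((res, "OXT"), o_entry)
    return table


def parse_hydropathy_scale(text: str) -> dict:
    """Parse 'residue index' lines into a residue_type -> float map."""
    scale: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, value = line.split()
        scale[res] = float(value)
    return scale


@lru_cache(maxsize=1)
def default_hydropathy_scale() -> dict:
    scale = parse_hydropathy_scale(_data_text("hydropathy_kyte_doolittle.txt"))
    missing = set(_STANDARD_RESIDUES) - set(scale)
    if missing:
        raise ConfigurationError(
            f"hydropathy scale misses residues: {sorted(missing)}"
        )
    return scale
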