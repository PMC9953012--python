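"""Loaders for the shipped, editable data tables.

``vdw_radii``: Bondi van der Waals radii by element (Angstroms).
``reference_areas``: per-residue total reference surface areas A_i (Angstroms^2),
literature-standard theoretical maximum accessible surface areas.
``kd_hydropathy``: Kyte-Doolittle hydropathy by 1-letter amino-acid code.
``moieties``: chemical-moiety membership of side-chain heavy atoms; backbone
atoms (N, CA, C, O, OXT) always form the residue's backbone moiety.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("thermadapt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


@lru_cache(maxsize=None)
def vdw_radii() -> dict[str, float]:
    df = _read("vdw_radii.tsv")
    return dict(zip(df["element"], df["radius"].astype(float)))


@lru_cache(maxsize=None)
def reference_areas() -> dict[str, float]:
    df = _read("reference_areas.tsv")
    return dict(zip(df["residue"], df["area"].astype(float)))


@lru_cache(maxsize=None)
def kd_hydropathy() -> dict[str, float]:
    df = _read("kd_hydropathy.tsv")
    return dict(zip(df["aa"], df["kd"].astype(float)))


_BACKBONE = ("N", "CA", "C", "O", "OXT")


@lru_cache(maxsize=None)
def moiety_table() -> dict[tuple[str, str], str]:
    """Map (residue_name, atom_name) -> moiety label within the residue."""
    df = _read("moieties.tsv")
    table: dict[tuple[str, str], str] = {}
    residues = set(df["residue"]) | {"GLY"}
    for res in residues:
        for atom in _BACKBONE:
            table[(res, atom)] = "bb"
    for _, row in df.iterrows():
        table[(row["residue"], row["atom"])] = row["moiety"]
    return table
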