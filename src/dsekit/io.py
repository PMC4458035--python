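"""Tabular I/O for the shared experiment tables.

All tables are UTF-8 CSV with one header row; the field delimiter defaults
to a comma and can be overridden (``dialect``).  Missing values are written
as ``NA`` and read back from either ``NA`` or an empty cell.

Schemas
-------
pedigree.csv    id,parent_id,generation,family,population,background
phenotypes.csv  progenitor_id,plant_index,year,block,flowering_raw,flowering_tt
bands.csv       progenitor_id,marker,system,state   (state in {1,0,NA})
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .pedigree import DIGESTION_SYSTEMS, POPULATIONS, Pedigree, Progenitor

NA_VALUES = ["", "NA"]

PEDIGREE_COLUMNS = ["id", "parent_id", "generation", "family", "population",
                    "background"]
PHENOTYPE_COLUMNS = ["progenitor_id", "plant_index", "year", "block",
                     "flowering_raw", "flowering_tt"]
BAND_COLUMNS = ["progenitor_id", "marker", "system", "state"]


class TableFormatError(ValueError):
    """Raised when a CSV does not match its expected schema."""


def _read_csv(path: str, columns: list[str], sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=NA_VALUES)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    return df[columns]


def _to_int(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    try:
        return df[col].astype(int)
    except (TypeError, ValueError):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        line = int(bad[0]) + 2 if len(bad) else "?"
        raise TableFormatError(
            f"{path}: non-integer value in column {col!r} at line {line}")


def read_pedigree(path: str, sep: str = ",") -> Pedigree:
    df = _read_csv(path, PEDIGREE_COLUMNS, sep)
    progenitors = []
    for i, row in df.iterrows():
        pop = row["population"]
        if pop not in POPULATIONS:
            raise TableFormatError(
                f"{path}: unknown population {pop!r} at line {i + 2}")
        progenitors.append(Progenitor(
            id=str(row["id"]),
            parent_id=None if pd.isna(row["parent_id"]) else str(row["parent_id"]),
            generation=int(_to_int(df, "generation", path)[i]),
            family=str(row["family"]),
            population=pop,
            background=str(row["background"]),
        ))
    return Pedigree(progenitors)


def write_pedigree(pedigree: Pedigree, path: str, sep: str = ",") -> None:
    df = pedigree_to_frame(pedigree)
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


def pedigree_to_frame(pedigree: Pedigree) -> pd.DataFrame:
    rows = [{"id": p.id, "parent_id": p.parent_id, "generation": p.generation,
             "family": p.family, "population": p.population,
             "background": p.background}
            for p in pedigree.topological_order()]
    return pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)


def read_phenotypes(path: str, sep: str = ",") -> pd.DataFrame:
    df = _read_csv(path, PHENOTYPE_COLUMNS, sep)
    out = pd.DataFrame({
        "progenitor_id": df["progenitor_id"].astype(str),
        "plant_index": _to_int(df, "plant_index", path),
        "year": _to_int(df, "year", path),
        "block": df["block"].astype(str),
        "flowering_raw": pd.to_numeric(df["flowering_raw"], errors="coerce"),
        "flowering_tt": pd.to_numeric(df["flowering_tt"], errors="coerce"),
    })
    if (out["flowering_tt"].dropna() < 0).any():
        raise TableFormatError(f"{path}: negative thermal time")
    return out


def write_phenotypes(df: pd.DataFrame, path: str, sep: str = ",") -> None:
    df[PHENOTYPE_COLUMNS].to_csv(path, sep=sep, index=False, na_rep="NA")


def read_bands(path: str, sep: str = ",") -> pd.DataFrame:
    """Band-phenotype matrix in long form; ``state`` is 1/0/NaN (float)."""
    df = _read_csv(path, BAND_COLUMNS, sep)
    state = pd.to_numeric(df["state"], errors="coerce")
    bad = state.dropna()[~state.dropna().isin([0.0, 1.0])]
    if len(bad):
        raise TableFormatError(
            f"{path}: band state must be 0, 1 or NA (line {int(bad.index[0]) + 2})")
    unknown = df["system"].dropna()[~df["system"].isin(DIGESTION_SYSTEMS)]
    if len(unknown):
        raise TableFormatError(
            f"{path}: unknown digestion system {unknown.iloc[0]!r}")
    return pd.DataFrame({
        "progenitor_id": df["progenitor_id"].astype(str),
        "marker": df["marker"].astype(str),
        "system": df["system"].astype(str),
        "state": state,
    })


def write_bands(df: pd.DataFrame, path: str, sep: str = ",") -> None:
    out = df[BAND_COLUMNS].copy()
    out["state"] = out["state"].map(
        lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep=sep, index=False, na_rep="NA")


def band_matrix(bands: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-form bands to a progenitor x marker matrix of 0/1/NaN."""
    return bands.pivot_table(index="progenitor_id", columns="marker",
                             values="state", aggfunc="first", dropna=False)


def read_tables(paths: dict[str, str], dialect: str = ","
                ) -> tuple[Pedigree, pd.DataFrame, pd.DataFrame]:
    """Read the three experiment tables.

    ``paths`` maps ``{"pedigree": ..., "phenotypes": ..., "bands": ...}`` to
    file paths; ``dialect`` is the field delimiter.
    """
    for key in ("pedigree", "phenotypes", "bands"):
        if key not in paths:
            raise KeyError(f"read_tables: missing path for {key!r}")
        if not os.path.exists(paths[key]):
            raise FileNotFoundError(paths[key])
    return (read_pedigree(paths["pedigree"], sep=dialect),
            read_phenotypes(paths["phenotypes"], sep=dialect),
            read_bands(paths["bands"], sep=dialect))


def write_tables(pedigree: Pedigree, phenotypes: pd.DataFrame,
                 bands: pd.DataFrame, directory: str,
                 dialect: str = ",") -> dict[str, str]:
    os.makedirs(directory, exist_ok=True)
    paths = {
        "pedigree": os.path.join(directory, "pedigree.csv"),
        "phenotypes": os.path.join(directory, "phenotypes.csv"),
        "bands": os.path.join(directory, "bands.csv"),
    }
    write_pedigree(pedigree, paths["pedigree"], sep=dialect)
    write_phenotypes(phenotypes, paths["phenotypes"], sep=dialect)
    write_bands(bands, paths["bands"], sep=dialect)
    return paths
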