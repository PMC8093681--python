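"""Read, rank and report empirical community abundance tables.

Tables are delimited text (CSV/TSV) with one row per species: species name,
genus, foraging guild and abundance, plus an optional precomputed rank
column.  Species sharing genus and guild form the similarity groups of the
randomization test; tied abundances share a competition ("min") rank exactly
as published tables do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .rad_analysis import RankedCommunity, rad_to_frame
from .rank_test import GroupAssignment, RankTestResult

__all__ = [
    "CommunityTable", "SchemaError", "TableParseError", "EmptyCommunityError",
    "DEFAULT_COLUMNS", "read_community_table", "write_community_table",
    "rank_with_ties", "write_report",
]

DEFAULT_COLUMNS = {"species": "species", "genus": "genus",
                   "guild": "guild", "abundance": "abundance", "rank": "rank"}


class SchemaError(ValueError):
    """A required column is missing or a species name is duplicated."""


class TableParseError(ValueError):
    """A cell could not be parsed (message carries the row number)."""


class EmptyCommunityError(ValueError):
    """No species with positive abundance to rank."""


@dataclass(frozen=True)
class CommunityTable:
    """Validated community abundance table.

    ``data`` holds columns species, genus, guild, abundance (and rank when
    supplied).  Zero-abundance rows are retained but flagged in
    ``zero_abundance`` and excluded from ranking.
    """

    data: pd.DataFrame

    @property
    def species(self) -> np.ndarray:
        return self.data["species"].to_numpy()

    @property
    def zero_abundance(self) -> np.ndarray:
        return (self.data["abundance"] <= 0).to_numpy()

    @property
    def has_ranks(self) -> bool:
        return "rank" in self.data.columns


def _validate_frame(df: pd.DataFrame, columns: Mapping[str, str]) -> pd.DataFrame:
    colmap = {**DEFAULT_COLUMNS, **(columns or {})}
    rename = {}
    for canonical in ("species", "genus", "guild", "abundance"):
        name = colmap[canonical]
        if name not in df.columns:
            raise SchemaError(f"missing required column {name!r}")
        rename[name] = canonical
    if colmap["rank"] in df.columns:
        rename[colmap["rank"]] = "rank"
    df = df.rename(columns=rename)
    keep = [c for c in ("species", "genus", "guild", "abundance", "rank")
            if c in df.columns]
    df = df[keep].copy()

    abund = pd.to_numeric(df["abundance"], errors="coerce")
    if abund.isna().any():
        row = int(np.flatnonzero(abund.isna().to_numpy())[0])
        raise TableParseError(f"non-numeric abundance in data row {row + 1}")
    df["abundance"] = abund.astype(float)
    if (df["abundance"] < 0).any():
        row = int(np.flatnonzero((df["abundance"] < 0).to_numpy())[0])
        raise TableParseError(f"negative abundance in data row {row + 1}")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].iloc[0]
        raise SchemaError(f"duplicate species name {dup!r}")
    df["species"] = df["species"].astype(str)
    df["genus"] = df["genus"].astype(str)
    df["guild"] = df["guild"].astype(str)
    return df.reset_index(drop=True)


def read_community_table(path, dialect: str | None = None,
                         columns: Mapping[str, str] | None = None
                         ) -> CommunityTable:
    """Read a CSV/TSV community table (UTF-8, header row required).

    ``dialect`` forces 'csv' or 'tsv'; by default the delimiter follows the
    file suffix (.tsv/.tab -> tab, otherwise comma).  ``columns`` remaps
    non-default column names.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    return CommunityTable(_validate_frame(df, columns or {}))


def write_community_table(table: CommunityTable, path) -> None:
    """Write the table back to delimited text (suffix chooses the delimiter)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table.data.to_csv(path, sep=sep, index=False)


def rank_with_ties(table: CommunityTable,
                   exclude: Iterable[str] = ()) -> tuple[RankedCommunity,
                                                         GroupAssignment]:
    """Rank a community table and derive its genus x guild groups.

    Species named in ``exclude`` and zero-abundance rows are dropped before
    ranking; the remainder get competition ("min") ranks by descending
    abundance unless the table carries a precomputed rank column, which is
    preserved verbatim.  Frequencies are abundances normalized to sum 1 and
    the group key is the (genus, guild) pair.
    """
    df = table.data
    excl = set(exclude)
    unknown = excl - set(df["species"])
    if unknown:
        raise KeyError(f"cannot exclude unknown species {sorted(unknown)}")
    df = df[~df["species"].isin(excl) & (df["abundance"] > 0)]
    if df.empty:
        raise EmptyCommunityError("no species with positive abundance")
    df = df.sort_values("abundance", ascending=False, kind="stable")

    abund = df["abundance"].to_numpy(dtype=float)
    if "rank" in df.columns and df["rank"].notna().all() and not excl:
        ranks = pd.to_numeric(df["rank"]).to_numpy().astype(int)
    else:
        ranks = rankdata(-abund, method="min").astype(int)
    freq = abund / abund.sum()
    keys = list(zip(df["genus"], df["guild"]))
    groups = GroupAssignment(dict(zip(df["species"], keys)))
    group_key = np.empty(len(df), dtype=object)
    group_key[:] = keys
    rad = RankedCommunity(
        species_id=df["species"].to_numpy(),
        frequency=freq, rank=ranks, group_key=group_key)
    return rad, groups


def _package_version() -> str:
    try:
        return version("radlabel")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        return "unknown"


def write_report(result: RankTestResult, rad: RankedCommunity, path,
                 rad_path=None, extra: Mapping | None = None) -> None:
    """Write a JSON test report plus a delimited RAD table.

    The report carries the observed indices, all probabilities, significance
    marks, seed, trial count and software version; identical inputs produce
    byte-identical files.  ``rad_path`` defaults to the report path with a
    ``.rad.csv`` suffix.
    """
    path = Path(path)
    if rad_path is None:
        rad_path = path.with_suffix(".rad.csv")
    payload = {"software": "radlabel", "version": _package_version(),
               **result.to_dict()}
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
    rad_to_frame(rad).to_csv(rad_path, index=False)
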