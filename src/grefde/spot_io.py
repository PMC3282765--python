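"""Spot-level array tables, design tables and result tables.

The shared data model for the whole pipeline: spot-level two-channel
intensities (cDNA = Cy3 sample channel, gDNA = Cy5 genomic-DNA common
reference) with print-tip grid coordinates, gene identifiers, within-array
duplicate indices and a fixed-arity tuple of Boolean quality indicators,
grouped into replicate arrays per strain.

Files are plain tab-separated text with a one-line header (a GPR-like
dialect).  Column names are configurable through a dialect mapping so that
exports from different quantification packages can be ingested.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotRecord",
    "ArraySet",
    "GrefdeError",
    "FormatError",
    "ConsistencyError",
    "DesignError",
    "InputError",
    "ConfigError",
    "SPOT_COLUMNS",
    "STRAINS",
    "read_spot_tables",
    "write_spot_tables",
    "read_design",
    "write_de_table",
    "read_de_table",
]


class GrefdeError(Exception):
    """Base class for all package errors."""


class FormatError(GrefdeError):
    """A file does not conform to the expected tabular dialect."""


class ConsistencyError(GrefdeError):
    """Data violate a structural invariant (e.g. unequal duplicate counts)."""


class DesignError(GrefdeError):
    """The design table is invalid or inconsistent with the spot tables."""


class InputError(GrefdeError):
    """Invalid values passed to a computation."""


class ConfigError(GrefdeError):
    """Invalid configuration."""


#: canonical spot-table column names (indicators follow as ind1..indK)
SPOT_COLUMNS = [
    "block",
    "row",
    "col",
    "gene_id",
    "duplicate_index",
    "fg_cdna",
    "bg_cdna",
    "fg_gdna",
    "bg_gdna",
]

#: strain labels of the three-condition design (A = wild type M145,
#: B and C = the two regulator deletion mutants)
STRAINS = ("A", "B", "C")

#: built-in dialects: mapping canonical name -> file column name
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {c: c for c in SPOT_COLUMNS},
}


@dataclasses.dataclass(frozen=True)
class SpotRecord:
    """One spot of a two-channel array."""

    array_id: str
    block: int
    row: int
    col: int
    gene_id: str
    duplicate_index: int
    fg_cdna: float
    bg_cdna: float
    fg_gdna: float
    bg_gdna: float
    indicators: tuple[bool, ...] = ()


@dataclasses.dataclass
class ArraySet:
    """A collection of replicate arrays plus their design.

    Parameters
    ----------
    spots
        Long table with one row per spot and columns ``array_id`` +
        :data:`SPOT_COLUMNS` + ``ind1..indK`` Boolean indicator columns.
    design
        One row per array: ``array_id``, ``strain``, ``replicate``.
    duplicate_arity
        Number of spots per gene on each array.
    """

    spots: pd.DataFrame
    design: pd.DataFrame
    duplicate_arity: int

    @property
    def array_ids(self) -> list[str]:
        return list(self.design["array_id"])

    @property
    def n_indicators(self) -> int:
        return len(self.indicator_columns)

    @property
    def indicator_columns(self) -> list[str]:
        return [c for c in self.spots.columns if c.startswith("ind")]

    def validate(self) -> "ArraySet":
        """Check the structural invariants; raise on violation."""
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise FormatError(f"spot table is missing columns: {missing}")
        _check_design(self.design)
        spot_ids = set(self.spots["array_id"].unique())
        design_ids = set(self.design["array_id"])
        if spot_ids != design_ids:
            raise DesignError(
                "array_id mismatch between spots and design: "
                f"only in spots {sorted(spot_ids - design_ids)}, "
                f"only in design {sorted(design_ids - spot_ids)}"
            )
        fg = self.spots[["fg_cdna", "bg_cdna", "fg_gdna", "bg_gdna"]].to_numpy(float)
        if not np.all(np.isfinite(fg)) or (fg < 0).any():
            raise InputError("intensities must be finite and >= 0")
        # unique grid coordinate per array
        dup_pos = self.spots.duplicated(["array_id", "block", "row", "col"])
        if dup_pos.any():
            bad = self.spots.loc[dup_pos, ["array_id", "block", "row", "col"]].iloc[0]
            raise ConsistencyError(f"duplicate grid position: {bad.to_dict()}")
        # constant duplicate arity for every gene on every array
        counts = self.spots.groupby(["array_id", "gene_id"], sort=False).size()
        if counts.nunique() != 1 or counts.iloc[0] != self.duplicate_arity:
            bad = counts[counts != self.duplicate_arity]
            raise ConsistencyError(
                "genes with inconsistent duplicate counts, e.g. "
                f"{bad.index[0]}: {int(bad.iloc[0])} spots "
                f"(expected {self.duplicate_arity})"
            )
        return self


def _check_design(design: pd.DataFrame) -> None:
    for col in ("array_id", "strain", "replicate"):
        if col not in design.columns:
            raise FormatError(f"design table is missing column: {col}")
    bad = set(design["strain"]) - set(STRAINS)
    if bad:
        raise DesignError(f"unknown strain labels: {sorted(bad)}")
    if design.duplicated(["strain", "replicate"]).any():
        raise DesignError("(strain, replicate) pairs must be unique")
    if design["array_id"].duplicated().any():
        raise DesignError("array_id values must be unique")


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", comment="#", dtype={"array_id": str, "strain": str})
    _check_design(design)
    return design.reset_index(drop=True)


def read_spot_tables(
    paths: Sequence[str | os.PathLike],
    design_path: str | os.PathLike,
    dialect: str | Mapping[str, str] = "generic",
) -> ArraySet:
    """Read per-array spot tables plus a design table into an :class:`ArraySet`.

    ``array_id`` is taken from each file's stem and must appear in the
    design.  Indicator columns are any columns named ``ind1..indK`` (after
    dialect renaming) and are parsed, in declared order, as Booleans.
    """
    if isinstance(dialect, str):
        try:
            mapping = DIALECTS[dialect]
        except KeyError:
            raise ConfigError(f"unknown dialect: {dialect!r}") from None
    else:
        mapping = dict(dialect)
    rename = {v: k for k, v in mapping.items()}

    design = read_design(design_path)
    frames = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.rename(columns=rename)
        missing = [c for c in SPOT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing column(s) {missing}")
        df.insert(0, "array_id", path.stem)
        frames.append(df)
    spots = pd.concat(frames, ignore_index=True)
    ind_cols = [c for c in spots.columns if c.startswith("ind")]
    for c in ind_cols:
        spots[c] = spots[c].astype(int).astype(bool)
    counts = spots.groupby(["array_id", "gene_id"], sort=False).size()
    if counts.nunique() != 1:
        per_gene = counts.reset_index(name="n")
        bad = per_gene.loc[per_gene["n"] != per_gene["n"].mode()[0]].iloc[0]
        raise ConsistencyError(
            f"gene {bad['gene_id']!r} has {bad['n']} spots on array "
            f"{bad['array_id']!r}; duplicate arity must be constant"
        )
    arity = int(counts.iloc[0])
    aset = ArraySet(spots=spots, design=design, duplicate_arity=arity)
    return aset.validate()


def write_spot_tables(
    arrayset: ArraySet, directory: str | os.PathLike
) -> tuple[list[Path], Path]:
    """Write one TSV per array plus ``design.tsv``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    cols = SPOT_COLUMNS + arrayset.indicator_columns
    for array_id, sub in arrayset.spots.groupby("array_id", sort=False):
        out = sub[cols].copy()
        for c in arrayset.indicator_columns:
            out[c] = out[c].astype(int)
        path = directory / f"{array_id}.tsv"
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")
        paths.append(path)
    design_path = directory / "design.tsv"
    arrayset.design.to_csv(design_path, sep="\t", index=False)
    return paths, design_path


# ---------------------------------------------------------------------------
# result tables

DE_TABLE_COLUMNS = [
    "gene_id",
    "Mc_BvA", "p_BvA", "fdr_BvA", "pfp_up_BvA", "pfp_down_BvA", "SS_BvA",
    "Mc_CvA", "p_CvA", "fdr_CvA", "pfp_up_CvA", "pfp_down_CvA", "SS_CvA",
]


def write_de_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the per-gene differential-transcription table.

    One row per gene with Mc, raw and FDR-adjusted p-values, the two
    directional rank-product pfp values and the combined significance call,
    for both mutant-vs-wild-type contrasts.  Rows are ordered by gene_id.
    """
    missing = [c for c in DE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"result table is missing columns: {missing}")
    out = table[DE_TABLE_COLUMNS].sort_values("gene_id").copy()
    for c in ("SS_BvA", "SS_CvA"):
        out[c] = out[c].astype(bool).astype(int)
    try:
        out.to_csv(path, sep="\t", index=False, float_format="%.6f")
    except OSError as exc:
        raise GrefdeError(f"cannot write result table to {path}: {exc}") from exc


def read_de_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in DE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    for c in ("SS_BvA", "SS_CvA"):
        df[c] = df[c].astype(bool)
    return df
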