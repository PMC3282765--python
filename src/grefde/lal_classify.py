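"""Classification of LuxR-family regulators into putative LAL members.

LAL regulators (Large ATP-binding regulators of the LuxR family) combine
three features: unusually large protein size, an N-terminal ATP/GTP-binding
domain recognizable by the Walker A motif, and a C-terminal LuxR-type
helix-turn-helix (HTH) DNA-binding domain.  Given an annotation table of
LuxR-family proteins (gene, protein length, motif flags) the classifier
applies::

    is_lal = has_hth AND has_atp_motif AND length_aa >= min_length

with ``min_length`` defaulting to 700 aa, which cleanly separates the known
S. coelicolor LuxR-family inventory (a 606-aa ATPase-motif protein is
excluded, the shortest true LAL at 780 aa is included).  A bundled
transcription of that 23-protein inventory ships with the package.

A simple Walker A scanner (G-x(4)-GK[ST] by default) is provided for
de-novo protein sequences.
"""

from __future__ import annotations

import dataclasses
import re
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .spot_io import ConfigError, InputError

__all__ = [
    "RegulatorRecord",
    "classify_regulators",
    "scan_walker_a",
    "load_luxr_table",
    "DEFAULT_MIN_LENGTH",
    "WALKER_A_PATTERN",
]

DEFAULT_MIN_LENGTH = 700
WALKER_A_PATTERN = r"G.{4}GK[ST]"
_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclasses.dataclass
class RegulatorRecord:
    """One LuxR-family regulator annotation."""

    gene_id: str
    length_aa: int
    has_atp_motif: bool
    has_hth: bool = True
    is_lal: bool | None = None


def load_luxr_table() -> pd.DataFrame:
    """The bundled 23-entry S. coelicolor LuxR-family annotation table.

    Columns: gene_id, length_aa, atp_motif, hth, lal (the published
    putative-LAL assignment, kept for verification).
    """
    with resources.files("grefde.data").joinpath("luxr_regulators.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for c in ("atp_motif", "hth", "lal"):
        df[c] = df[c].astype(bool)
    return df


def classify_regulators(
    records: pd.DataFrame | Iterable[RegulatorRecord],
    min_length: int = DEFAULT_MIN_LENGTH,
) -> tuple[pd.DataFrame, dict]:
    """Apply the LAL rule to an annotation table.

    Accepts a DataFrame with columns gene_id, length_aa, atp_motif and
    optionally hth (assumed True when absent, as LuxR-family inputs carry
    the HTH by construction), or an iterable of :class:`RegulatorRecord`.
    Returns the classified table (with ``is_lal``) and counts
    ``{"n_total", "n_lal"}``.  Classification is monotone in length.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "length_aa": r.length_aa,
                    "atp_motif": r.has_atp_motif,
                    "hth": r.has_hth,
                }
                for r in records
            ]
        )
    for c in ("gene_id", "length_aa", "atp_motif"):
        if c not in df.columns:
            raise InputError(f"annotation table is missing column: {c}")
    if (df["length_aa"] <= 0).any():
        raise InputError("protein lengths must be positive")
    if "hth" not in df.columns:
        df["hth"] = True
    df["is_lal"] = (
        df["hth"].astype(bool)
        & df["atp_motif"].astype(bool)
        & (df["length_aa"] >= min_length)
    )
    counts = {"n_total": int(len(df)), "n_lal": int(df["is_lal"].sum())}
    return df, counts


def scan_walker_a(
    protein_sequence: str, pattern: str = WALKER_A_PATTERN
) -> tuple[bool, list[int]]:
    """Scan a protein sequence for the Walker A (P-loop) motif.

    Returns (found, 1-based start positions of every, possibly overlapping,
    match).  The pattern is a configurable regular expression over the
    20-letter amino-acid alphabet.
    """
    if not pattern:
        raise ConfigError("empty Walker A pattern")
    seq = protein_sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise InputError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    positions = [m.start() + 1 for m in re.finditer(f"(?={pattern})", seq)]
    return bool(positions), positions
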