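"""Combined significance calls, summary counts and gene-set Mc profiles.

A gene is called statistically significant (SS) in a contrast when the
FDR-adjusted moderated-t p-value is below alpha, OR when both the
rank-product pfp (of the direction matching the sign of Mc) and the raw
p-value are below alpha.  The per-gene decision table feeds the
differential-transcription result tables; gene-set profiles report the
per-gene and mean Mc of a named set (e.g. phosphate-starvation-response
genes or the actinorhodin cluster) per contrast, together with how many
members pass a relaxed uncorrected-p criterion.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spot_io import InputError
from .linear_model import GenewiseFit, EBayesParams
from .rank_products import RPResult

__all__ = [
    "DecisionTable",
    "GeneSetProfile",
    "decide_significance",
    "count_differential",
    "gene_set_profile",
    "assemble_de_table",
]


@dataclasses.dataclass
class DecisionTable:
    """Per-gene, per-contrast SS calls.

    ``table`` columns per contrast ``<c>``: ``SS_<c>`` (bool),
    ``basis_<c>`` in {FDR, RP, both, none}, plus the Mc / p / fdr / pfp
    inputs the rule used.
    """

    table: pd.DataFrame
    contrasts: tuple[str, ...]
    alpha: float


def decide_significance(
    fit: GenewiseFit,
    ebayes: EBayesParams,
    rp: Mapping[str, RPResult],
    alpha: float = 0.05,
) -> DecisionTable:
    """Apply the combined rule: SS iff fdr < alpha or (pfp < alpha and
    p_raw < alpha), with pfp taken from the direction matching sign(Mc)."""
    genes = fit.table.index
    for c, res in rp.items():
        extra = res.table.index.symmetric_difference(genes)
        if len(extra):
            raise InputError(
                f"gene universes differ for contrast {c}: "
                f"{list(extra[:5])}{'...' if len(extra) > 5 else ''}"
            )
    out = pd.DataFrame(index=genes)
    contrasts = tuple(c for c in fit.contrasts if c in rp)
    if not contrasts:
        raise InputError("no contrast is shared between the fit and rank products")
    for c in contrasts:
        mc = fit.table[f"Mc_{c}"]
        p = ebayes.table[f"p_{c}"]
        fdr = ebayes.table[f"fdr_{c}"]
        rpt = rp[c].table.reindex(genes)
        pfp = pd.Series(
            np.where(mc >= 0, rpt["pfp_up"], rpt["pfp_down"]), index=genes
        )
        fdr_hit = fdr < alpha
        rp_hit = (pfp < alpha) & (p < alpha)
        ss = (fdr_hit | rp_hit).fillna(False)
        basis = np.select(
            [fdr_hit & rp_hit, fdr_hit, rp_hit],
            ["both", "FDR", "RP"],
            default="none",
        )
        out[f"Mc_{c}"] = mc
        out[f"p_{c}"] = p
        out[f"fdr_{c}"] = fdr
        out[f"pfp_{c}"] = pfp
        out[f"SS_{c}"] = ss.astype(bool)
        out[f"basis_{c}"] = basis
    return DecisionTable(table=out, contrasts=contrasts, alpha=alpha)


def count_differential(decisions: DecisionTable) -> dict:
    """Summary counts: SS per contrast, union, intersection, and how many
    intersection genes have sign-consistent Mc in both contrasts."""
    t = decisions.table
    cs = decisions.contrasts
    ss = {c: t[f"SS_{c}"].astype(bool) for c in cs}
    summary = {f"n_{c}": int(ss[c].sum()) for c in cs}
    union = np.logical_or.reduce([ss[c].to_numpy() for c in cs])
    inter = np.logical_and.reduce([ss[c].to_numpy() for c in cs])
    summary["n_union"] = int(union.sum())
    summary["n_intersection"] = int(inter.sum())
    if len(cs) >= 2 and inter.any():
        signs = np.stack([np.sign(t.loc[inter, f"Mc_{c}"].to_numpy()) for c in cs])
        agree = (signs == signs[0]).all(axis=0)
        summary["n_intersection_sign_agree"] = int(agree.sum())
    else:
        summary["n_intersection_sign_agree"] = 0
    return summary


@dataclasses.dataclass
class GeneSetProfile:
    """Per-gene and mean Mc of a gene set, with the relaxed-criterion count."""

    name: str
    genes: list[str]
    unknown_genes: list[str]
    table: pd.DataFrame                # per-gene Mc and p per contrast
    mean_mc: pd.Series                 # contrast -> mean Mc (missing excluded)
    n_used: pd.Series                  # contrast -> genes contributing to mean
    relaxed_alpha: float
    relaxed_pass: pd.Series            # contrast -> count with p_raw < relaxed_alpha
    relaxed_genes: dict[str, list[str]]


def gene_set_profile(
    fit: GenewiseFit,
    ebayes: EBayesParams,
    gene_set: Sequence[str],
    name: str = "gene_set",
    relaxed_alpha: float = 0.05,
) -> GeneSetProfile:
    """Mc profile of a gene set: per-gene values, arithmetic mean per
    contrast, and the members passing the relaxed uncorrected-p criterion."""
    gene_set = list(gene_set)
    if not gene_set:
        raise InputError("gene set is empty")
    known = [g for g in gene_set if g in fit.table.index]
    unknown = [g for g in gene_set if g not in fit.table.index]
    if not known:
        raise InputError(f"no resolvable genes in set {name!r}")
    cols = {}
    for c in fit.contrasts:
        cols[f"Mc_{c}"] = fit.table.loc[known, f"Mc_{c}"]
        cols[f"p_{c}"] = ebayes.table.loc[known, f"p_{c}"]
    table = pd.DataFrame(cols, index=pd.Index(known, name="gene_id"))
    mean_mc = pd.Series(
        {c: table[f"Mc_{c}"].mean() for c in fit.contrasts}, name="mean_Mc"
    )
    n_used = pd.Series(
        {c: int(table[f"Mc_{c}"].notna().sum()) for c in fit.contrasts}, name="n_used"
    )
    relaxed = {
        c: [g for g in known if table.loc[g, f"p_{c}"] < relaxed_alpha]
        for c in fit.contrasts
    }
    relaxed_pass = pd.Series(
        {c: len(relaxed[c]) for c in fit.contrasts}, name="relaxed_pass"
    )
    return GeneSetProfile(
        name=name,
        genes=known,
        unknown_genes=unknown,
        table=table,
        mean_mc=mean_mc,
        n_used=n_used,
        relaxed_alpha=relaxed_alpha,
        relaxed_pass=relaxed_pass,
        relaxed_genes=relaxed,
    )


def assemble_de_table(
    fit: GenewiseFit,
    ebayes: EBayesParams,
    rp: Mapping[str, RPResult],
    decisions: DecisionTable,
) -> pd.DataFrame:
    """Build the per-gene result table for :func:`grefde.spot_io.write_de_table`."""
    genes = fit.table.index
    out = pd.DataFrame({"gene_id": genes})
    out = out.set_index("gene_id")
    for c in decisions.contrasts:
        rpt = rp[c].table.reindex(genes)
        out[f"Mc_{c}"] = fit.table[f"Mc_{c}"]
        out[f"p_{c}"] = ebayes.table[f"p_{c}"]
        out[f"fdr_{c}"] = ebayes.table[f"fdr_{c}"]
        out[f"pfp_up_{c}"] = rpt["pfp_up"]
        out[f"pfp_down_{c}"] = rpt["pfp_down"]
        out[f"SS_{c}"] = decisions.table[f"SS_{c}"]
    return out.reset_index()
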