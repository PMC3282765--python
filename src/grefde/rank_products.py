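"""Rank products with permutation-based pfp (proportion of false positives).

A non-parametric complement to the moderated t: for an unpaired two-class
comparison, all pairwise fold changes between mutant and wild-type
replicates are formed (K = nB x nA columns of duplicate-averaged Mg
differences), genes are ranked within each column, and the rank product of
a gene is the geometric mean of its ranks over the columns.  Consistently
up-regulated genes have small RP_up (rank 1 = largest fold change) and
consistently down-regulated genes small RP_down.

Significance is calibrated against a permutation null in which each
column's ranks are an independent uniform permutation of 1..G: the
permutation p-value of a gene is the (add-one smoothed) fraction of null
rank products at or below its observed one, and
pfp(g) = p(g) * G / rank_of_RP(g) estimates the expected proportion of
false positives among all genes called at g's level.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .spot_io import DesignError, InputError
from .normalization import NormalizedSet

__all__ = [
    "RPResult",
    "pairwise_fold_changes",
    "rank_product_statistic",
    "estimate_pfp",
    "rank_product_analysis",
]


@dataclasses.dataclass
class RPResult:
    """Rank products and their permutation calibration for one contrast.

    ``table`` columns: RP_up, RP_down, p_up, p_down, pfp_up, pfp_down.
    """

    contrast: str
    table: pd.DataFrame
    K: int
    n_perm: int
    seed: int | None


def pairwise_fold_changes(
    normalized: NormalizedSet, contrast: str
) -> pd.DataFrame:
    """All mutant-vs-wild-type replicate differences of duplicate-averaged Mg.

    ``contrast`` is e.g. ``"BvA"``.  Returns a genes x K frame,
    K = n_mutant_reps x n_wt_reps; entry (g, (i, j)) = Mg(mutant rep i)
    - Mg(WT rep j), duplicates averaged within array.  Missing values are
    allowed and propagate.
    """
    mut, ref = contrast.split("v")
    design = normalized.design
    mut_ids = list(design.loc[design["strain"] == mut, "array_id"])
    ref_ids = list(design.loc[design["strain"] == ref, "array_id"])
    if not mut_ids or not ref_ids:
        raise DesignError(f"contrast {contrast!r}: empty strain group")
    avg = (
        normalized.spots.groupby(["gene_id", "array_id"], sort=False)["Mg"]
        .mean()
        .unstack("array_id")
    )
    cols = {}
    for i, mid in enumerate(mut_ids, start=1):
        for j, rid in enumerate(ref_ids, start=1):
            cols[f"{mid}-{rid}"] = avg[mid] - avg[rid]
    return pd.DataFrame(cols, index=avg.index)


def rank_product_statistic(fc: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(RP_up, RP_down) per gene: geometric mean of per-column ranks.

    Rank 1 = most up-regulated (descending order) for RP_up, most
    down-regulated for RP_down; ties get average ranks; missing entries are
    skipped (geometric mean over observed columns only).  Genes missing in
    every column get NaN.
    """
    x = np.asarray(fc, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InputError("fold-change matrix must have >= 2 genes")
    logs_up = np.full(x.shape, np.nan)
    logs_down = np.full(x.shape, np.nan)
    for k in range(x.shape[1]):
        col = x[:, k]
        ok = np.isfinite(col)
        if not ok.any():
            continue
        ranks_down = stats.rankdata(col[ok])          # ascending: 1 = most down
        nk = ok.sum()
        logs_down[ok, k] = np.log(ranks_down)
        logs_up[ok, k] = np.log(nk + 1 - ranks_down)  # descending ranks
    with np.errstate(invalid="ignore"):
        rp_up = np.exp(np.nanmean(logs_up, axis=1))
        rp_down = np.exp(np.nanmean(logs_down, axis=1))
    return rp_up, rp_down


def _null_rp(G: int, K: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Null rank products: independent uniform rank permutations per column."""
    out = np.empty(G * n_perm)
    for b in range(n_perm):
        logs = np.zeros(G)
        for _ in range(K):
            ranks = rng.permutation(G) + 1
            logs += np.log(ranks)
        out[b * G : (b + 1) * G] = np.exp(logs / K)
    return out


def estimate_pfp(
    rp_up: np.ndarray,
    rp_down: np.ndarray,
    K: int,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation p-values and pfp for both directions.

    p(g) = (#null RP <= RP(g) + 1) / (G*n_perm + 1) against a shared null
    sample of G*n_perm rank products (the null distribution is identical
    for the two directions); pfp(g) = p(g) * G / rank_of_RP(g) within each
    direction.  Fully reproducible from ``seed``.
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    rp_up = np.asarray(rp_up, float)
    rp_down = np.asarray(rp_down, float)
    G = rp_up.size
    rng = np.random.default_rng(seed)
    null = np.sort(_null_rp(G, K, n_perm, rng))

    def direction(rp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = np.full(G, np.nan)
        pfp = np.full(G, np.nan)
        ok = np.isfinite(rp)
        counts = np.searchsorted(null, rp[ok], side="right")
        p[ok] = (counts + 1.0) / (null.size + 1.0)
        ranks = stats.rankdata(rp[ok], method="average")
        pfp[ok] = p[ok] * ok.sum() / ranks
        return p, pfp

    p_up, pfp_up = direction(rp_up)
    p_down, pfp_down = direction(rp_down)
    return pd.DataFrame(
        {
            "RP_up": rp_up,
            "RP_down": rp_down,
            "p_up": p_up,
            "p_down": p_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
        }
    )


def _rp_fast(fc: np.ndarray, G: int) -> tuple[np.ndarray, np.ndarray]:
    """Rank products of a complete (no-missing) fold-change matrix."""
    ranks = stats.rankdata(fc, axis=0)
    rp_down = np.exp(np.log(ranks).mean(axis=1))
    rp_up = np.exp(np.log(G + 1 - ranks).mean(axis=1))
    return rp_up, rp_down


def estimate_pfp_label_permutation(
    normalized: NormalizedSet,
    contrast: str,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation p-values and pfp with a sample-label null.

    Each permutation reassigns the strain labels among the contrast's
    arrays, rebuilds the all-pairs fold-change matrix and recomputes the
    rank products; this preserves the dependence between the K = nB x nA
    columns (which share arrays) that the independent rank-permutation null
    of :func:`estimate_pfp` ignores.  Null rank products of both directions
    are pooled (the label null is direction-symmetric).
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    mut, ref = contrast.split("v")
    design = normalized.design
    ids = list(
        design.loc[design["strain"].isin([mut, ref])].sort_values(
            ["strain", "replicate"]
        )["array_id"]
    )
    n_mut = int((design["strain"] == mut).sum())
    if n_mut == 0 or len(ids) == n_mut:
        raise DesignError(f"contrast {contrast!r}: empty strain group")
    avg = (
        normalized.spots.groupby(["gene_id", "array_id"], sort=False)["Mg"]
        .mean()
        .unstack("array_id")
    )
    fc = pairwise_fold_changes(normalized, contrast)
    rp_up, rp_down = rank_product_statistic(fc)

    x = avg[ids].to_numpy(float)
    G = x.shape[0]
    K = n_mut * (len(ids) - n_mut)
    rng = np.random.default_rng(seed)
    null = np.empty(2 * G * n_perm)
    for b in range(n_perm):
        perm = rng.permutation(len(ids))
        xm = x[:, perm[:n_mut]]
        xr = x[:, perm[n_mut:]]
        fcn = (xm[:, :, None] - xr[:, None, :]).reshape(G, K)
        if np.isnan(fcn).any():
            u, d = rank_product_statistic(fcn)
        else:
            u, d = _rp_fast(fcn, G)
        null[2 * b * G : (2 * b + 1) * G] = u
        null[(2 * b + 1) * G : (2 * b + 2) * G] = d
    null.sort()

    def direction(rp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = np.full(G, np.nan)
        pfp = np.full(G, np.nan)
        ok = np.isfinite(rp)
        counts = np.searchsorted(null, rp[ok], side="right")
        p[ok] = (counts + 1.0) / (null.size + 1.0)
        ranks = stats.rankdata(rp[ok], method="average")
        pfp[ok] = p[ok] * ok.sum() / ranks
        return p, pfp

    p_up, pfp_up = direction(rp_up)
    p_down, pfp_down = direction(rp_down)
    return pd.DataFrame(
        {
            "RP_up": rp_up,
            "RP_down": rp_down,
            "p_up": p_up,
            "p_down": p_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
        },
        index=fc.index,
    )


def rank_product_analysis(
    normalized: NormalizedSet,
    contrast: str,
    n_perm: int = 1000,
    seed: int | None = None,
    null: str = "label",
) -> RPResult:
    """Full rank-product analysis of one contrast.

    ``null`` selects the permutation scheme: ``"label"`` (default)
    reassigns strain labels among the contrast's arrays, preserving the
    dependence between the pairwise fold-change columns; ``"rank"`` uses
    independent uniform rank permutations per column (anticonservative for
    the all-pairs unpaired construction, but the classical definition).
    """
    fc = pairwise_fold_changes(normalized, contrast)
    if null == "label":
        table = estimate_pfp_label_permutation(
            normalized, contrast, n_perm=n_perm, seed=seed
        )
    elif null == "rank":
        rp_up, rp_down = rank_product_statistic(fc)
        table = estimate_pfp(rp_up, rp_down, K=fc.shape[1], n_perm=n_perm, seed=seed)
        table.index = fc.index
    else:
        raise InputError(f"unknown null scheme: {null!r}")
    return RPResult(
        contrast=contrast, table=table, K=fc.shape[1], n_perm=n_perm, seed=seed
    )
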