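"""Genewise weighted linear models with duplicate-spot correlation,
empirical-Bayes moderated t-statistics and Benjamini-Hochberg FDR.

For each gene the normalized log-ratios Mg are regressed on strain
indicators by generalized least squares.  Observation weights are the
product of spot-quality and array weights, and the two duplicate spots of a
gene on one array share an exchangeable correlation rho (estimated by
pooling genewise Pearson correlations on the Fisher-z scale).  Contrasts
are mutant minus wild type: Mc_BvA = mean_B - mean_A, Mc_CvA = mean_C -
mean_A, so genes transcribed more strongly in a mutant have positive Mc.

Genewise residual variances are shrunk toward a common prior: the prior
degrees of freedom d0 and prior variance s0^2 are estimated by moment
matching on log s^2 (digamma/trigamma equations), the posterior variance is
s~2 = (d0*s0^2 + df*s^2)/(d0 + df), and the moderated t statistic
t~ = Mc/(u*s~) (u the unscaled standard error) is referred to a
t-distribution with d0 + df degrees of freedom.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .spot_io import InputError
from .normalization import NormalizedSet

__all__ = [
    "CorrelationEstimate",
    "GenewiseFit",
    "EBayesParams",
    "estimate_duplicate_correlation",
    "fit_genewise",
    "ebayes_moderate",
    "bh_adjust",
    "trigamma_inverse",
]


@dataclasses.dataclass
class CorrelationEstimate:
    """Pooled inter-duplicate correlation."""

    rho: float
    gene_correlations: pd.Series
    n_genes_used: int


@dataclasses.dataclass
class GenewiseFit:
    """Per-gene contrast estimates and residual variances.

    ``table`` columns: per contrast ``Mc_<c>``, ``stderr_<c>``,
    ``unscaled_<c>`` (standard error per unit residual sd), plus ``s2``,
    ``df_residual`` and ``n_obs``.  Index: gene_id.
    """

    table: pd.DataFrame
    contrasts: tuple[str, ...]
    rho: float


@dataclasses.dataclass
class EBayesParams:
    """Empirical-Bayes hyperparameters and moderated statistics.

    ``table`` columns: ``s2_post`` plus per contrast ``t_<c>``, ``p_<c>``,
    ``fdr_<c>``.  ``d0`` may be +inf (complete shrinkage to s0^2).
    """

    d0: float
    s02: float
    table: pd.DataFrame
    contrasts: tuple[str, ...]


def _gene_cube(normalized: NormalizedSet):
    """Stack Mg into a (genes, arrays, duplicates) cube in design order."""
    design = normalized.design
    array_ids = list(design["array_id"])
    df = normalized.spots
    genes = pd.Index(pd.unique(df["gene_id"]), name="gene_id")
    g = genes.get_indexer(df["gene_id"])
    a = pd.Index(array_ids).get_indexer(df["array_id"])
    d = df["duplicate_index"].to_numpy(int) - 1
    arity = int(d.max()) + 1
    cube = np.full((len(genes), len(array_ids), arity), np.nan)
    cube[g, a, d] = df["Mg"].to_numpy(float)
    return genes, array_ids, cube


def estimate_duplicate_correlation(
    normalized: NormalizedSet, trim: float = 0.15, min_arrays: int = 3
) -> CorrelationEstimate:
    """Pooled within-array duplicate correlation of residual Mg.

    Per gene, the strain-and-duplicate means are removed and the Pearson
    correlation between the two duplicates' residuals is computed across
    arrays; genewise correlations are pooled by a trimmed mean on the
    Fisher-z (atanh) scale and transformed back.
    """
    if normalized.duplicate_arity != 2:
        raise InputError("duplicate correlation requires duplicate_arity = 2")
    design = normalized.design
    if len(design) < min_arrays:
        raise InputError(f"needs >= {min_arrays} arrays")
    genes, array_ids, cube = _gene_cube(normalized)
    strain_of = pd.Index(array_ids).map(
        design.set_index("array_id")["strain"]
    ).to_numpy()
    resid = cube.copy()
    for s in np.unique(strain_of):
        sel = strain_of == s
        with np.errstate(invalid="ignore"):
            resid[:, sel, :] -= np.nanmean(cube[:, sel, :], axis=1, keepdims=True)
    r1, r2 = resid[:, :, 0], resid[:, :, 1]
    ok = np.isfinite(r1) & np.isfinite(r2)
    n = ok.sum(axis=1)
    r1 = np.where(ok, r1, 0.0)
    r2 = np.where(ok, r2, 0.0)
    sxy = (r1 * r2).sum(axis=1)
    sxx = (r1 * r1).sum(axis=1)
    syy = (r2 * r2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = sxy / np.sqrt(sxx * syy)
    usable = (n >= min_arrays) & np.isfinite(corr)
    corr_used = np.clip(corr[usable], -0.9999, 0.9999)
    if corr_used.size == 0:
        raise InputError("no genes usable for correlation estimation")
    z = np.arctanh(corr_used)
    rho = float(np.tanh(stats.trim_mean(z, trim)))
    return CorrelationEstimate(
        rho=rho,
        gene_correlations=pd.Series(corr, index=genes, name="rho_gene"),
        n_genes_used=int(usable.sum()),
    )


def fit_genewise(
    normalized: NormalizedSet,
    spot_weights=None,
    array_weights=None,
    rho: float = 0.0,
) -> GenewiseFit:
    """Genewise GLS of Mg on strain indicators.

    ``spot_weights`` aligns with ``normalized.spots`` rows (default all 1);
    ``array_weights`` is a mapping/Series array_id -> weight (default 1).
    Duplicate spots of one gene on one array share correlation ``rho``;
    observation variances are proportional to 1/(spot_weight*array_weight).
    Estimates are invariant to a common rescaling of all weights.
    """
    if not -1 < rho < 1:
        raise InputError("rho must lie in (-1, 1)")
    design = normalized.design
    genes, array_ids, cube = _gene_cube(normalized)
    n_genes, n_arrays, arity = cube.shape
    if arity > 2:
        raise InputError("only duplicate_arity <= 2 designs are supported")

    w = np.ones(len(normalized.spots)) if spot_weights is None else np.asarray(
        spot_weights, float
    )
    wcube = np.zeros((n_genes, n_arrays, arity))
    df = normalized.spots
    g = genes.get_indexer(df["gene_id"])
    a = pd.Index(array_ids).get_indexer(df["array_id"])
    d = df["duplicate_index"].to_numpy(int) - 1
    wcube[g, a, d] = w
    if array_weights is not None:
        aw = pd.Series(array_weights).reindex(array_ids).to_numpy(float)
        wcube *= aw[None, :, None]

    mask = np.isfinite(cube) & (wcube > 0)
    y = np.where(mask, cube, 0.0)
    u = np.where(mask, wcube, 0.0)

    if arity == 2:
        both = mask[:, :, 0] & mask[:, :, 1]
        sq = np.sqrt(u[:, :, 0] * u[:, :, 1])
        denom = 1.0 - rho * rho
        # 1' Sigma^-1 1 and 1' Sigma^-1 y per (gene, array) pair block
        info_pair = np.where(
            both,
            (u[:, :, 0] + u[:, :, 1] - 2 * rho * sq) / denom,
            u[:, :, 0] + u[:, :, 1],
        )
        proj_pair = np.where(
            both,
            (
                y[:, :, 0] * (u[:, :, 0] - rho * sq)
                + y[:, :, 1] * (u[:, :, 1] - rho * sq)
            )
            / denom,
            u[:, :, 0] * y[:, :, 0] + u[:, :, 1] * y[:, :, 1],
        )
    else:
        info_pair = u[:, :, 0]
        proj_pair = u[:, :, 0] * y[:, :, 0]

    strain_of = pd.Index(array_ids).map(
        design.set_index("array_id")["strain"]
    ).to_numpy()
    strains = [s for s in ("A", "B", "C") if s in set(strain_of)]
    if "A" not in strains or len(strains) < 2:
        raise InputError("design must contain strain A and at least one mutant")
    info = {}
    beta = {}
    arrays_with_data = {}
    for s in strains:
        sel = strain_of == s
        info_s = info_pair[:, sel].sum(axis=1)
        proj_s = proj_pair[:, sel].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta[s] = np.where(info_s > 0, proj_s / np.maximum(info_s, 1e-300), np.nan)
        info[s] = info_s
        arrays_with_data[s] = (mask[:, sel].any(axis=2)).sum(axis=1)

    # residual quadratic form
    mu = np.zeros((n_genes, n_arrays))
    for s in strains:
        sel = strain_of == s
        mu[:, sel] = beta[s][:, None]
    r = np.where(mask, cube - mu[:, :, None], 0.0)
    if arity == 2:
        quad = np.where(
            both,
            (
                u[:, :, 0] * r[:, :, 0] ** 2
                - 2 * rho * sq * r[:, :, 0] * r[:, :, 1]
                + u[:, :, 1] * r[:, :, 1] ** 2
            )
            / denom,
            u[:, :, 0] * r[:, :, 0] ** 2 + u[:, :, 1] * r[:, :, 1] ** 2,
        )
    else:
        quad = u[:, :, 0] * r[:, :, 0] ** 2
    quad_total = np.nansum(quad, axis=1)
    n_obs = mask.sum(axis=(1, 2))
    n_strains_present = np.stack(
        [info[s] > 0 for s in strains], axis=1
    ).sum(axis=1)
    df_resid = np.maximum(n_obs - n_strains_present, 0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(df_resid > 0, quad_total / np.maximum(df_resid, 1), np.nan)

    out = pd.DataFrame(index=genes)
    contrasts = tuple(f"{s}vA" for s in strains if s != "A")
    for c in contrasts:
        s = c[0]
        informative = (arrays_with_data.get("A", 0) >= 2) & (
            arrays_with_data[s] >= 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            mc = np.where(informative, beta[s] - beta["A"], np.nan)
            unscaled = np.where(
                informative, np.sqrt(1.0 / info[s] + 1.0 / info["A"]), np.nan
            )
        out[f"Mc_{c}"] = mc
        out[f"unscaled_{c}"] = unscaled
        out[f"stderr_{c}"] = unscaled * np.sqrt(s2)
    out["s2"] = s2
    out["df_residual"] = df_resid
    out["n_obs"] = n_obs
    return GenewiseFit(table=out, contrasts=contrasts, rho=rho)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if -dif / x < tol:
            break
    return x


def ebayes_moderate(
    fit: GenewiseFit,
    d0: float | None = None,
    s02: float | None = None,
) -> EBayesParams:
    """Moderate genewise variances and compute moderated t / p / FDR.

    Hyperparameters (d0, s0^2) are estimated by moment matching on
    log s^2 unless forced via the keyword arguments (d0=0 gives ordinary
    t-statistics; d0=inf gives fully pooled variances).  Genes with missing
    s^2 or df <= 0 are excluded from hyperparameter estimation but retained
    with missing statistics.
    """
    tbl = fit.table
    s2 = tbl["s2"].to_numpy(float)
    dfr = tbl["df_residual"].to_numpy(float)
    usable = np.isfinite(s2) & (s2 > 0) & (dfr > 0)
    if d0 is None or s02 is None:
        if usable.sum() < 50:
            raise InputError("hyperparameter estimation needs >= 50 usable genes")
        d0_est, s02_est = _fit_f_dist(s2[usable], dfr[usable])
        if d0 is None:
            d0 = d0_est
        if s02 is None:
            s02 = s02_est

    s2_post = np.full_like(s2, np.nan)
    if math.isinf(d0):
        s2_post[usable] = s02
        df_total = np.full_like(dfr, np.inf)
    elif d0 == 0:
        s2_post[usable] = s2[usable]
        df_total = dfr
    else:
        s2_post[usable] = (d0 * s02 + dfr[usable] * s2[usable]) / (d0 + dfr[usable])
        df_total = d0 + dfr

    out = pd.DataFrame(index=tbl.index)
    out["s2_post"] = s2_post
    for c in fit.contrasts:
        mc = tbl[f"Mc_{c}"].to_numpy(float)
        unscaled = tbl[f"unscaled_{c}"].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mc / (unscaled * np.sqrt(s2_post))
        p = np.full_like(t, np.nan)
        fin = np.isfinite(t)
        if math.isinf(d0):
            p[fin] = 2.0 * stats.norm.sf(np.abs(t[fin]))
        else:
            p[fin] = 2.0 * stats.t.sf(np.abs(t[fin]), df_total[fin])
        out[f"t_{c}"] = t
        out[f"p_{c}"] = p
        out[f"fdr_{c}"] = bh_adjust(p)
    return EBayesParams(d0=float(d0), s02=float(s02), table=out, contrasts=fit.contrasts)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled F prior to genewise variances (log-scale)."""
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = np.sum((e - emean) ** 2) / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s02 = math.exp(
            emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return d0, s02


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} (m/j) p_(j), capped at 1, in the original order.
    Missing values are passed through and do not count toward m.
    """
    p = np.asarray(p, float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out
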