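"""Within-array normalization: M/A values, print-tip correction, global loess.

For each spot the log-ratio M = log2(cDNA/gDNA) and average intensity
A = 0.5*log2(cDNA*gDNA) are computed, optionally after background
subtraction.  Each array is then normalized in a fixed order: first the
per-print-tip weighted median of M is subtracted (removes pin-specific
offsets), then a global loess fit of M on A is subtracted (removes the
smooth intensity-dependent dye bias).  The result is the normalized
log-ratio Mg, proportional to transcript abundance under the genomic-DNA
common-reference design.

Normalization is strictly per-array: no information crosses arrays.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .spot_io import ArraySet, ConfigError, InputError, SpotRecord

__all__ = [
    "NormalizedArray",
    "NormalizedSet",
    "compute_m_a",
    "weighted_median",
    "print_tip_weighted_median",
    "loess_fit",
    "global_loess",
    "normalize_array",
    "normalize_set",
]


class DegenerateGroupError(InputError):
    """A print-tip group has no usable spots or weights."""


class InsufficientDataError(InputError):
    """Too few non-missing spots for a smooth fit."""


@dataclasses.dataclass
class NormalizedArray:
    """Per-spot normalized values of one array.

    ``spots`` carries gene_id, duplicate_index, block (tip), A, Mg and,
    for diagnostics, the raw M.  Spots failing the background policy are
    kept with Mg = NaN (missing), never dropped.
    """

    array_id: str
    spots: pd.DataFrame
    tip_medians: pd.Series        # fitted weighted median per block
    loess_grid: pd.DataFrame      # A grid and fitted dye-bias curve


@dataclasses.dataclass
class NormalizedSet:
    """Normalized arrays in design order, as one long table."""

    spots: pd.DataFrame           # array_id, gene_id, duplicate_index, block, A, Mg, flag?
    design: pd.DataFrame
    duplicate_arity: int
    arrays: list[NormalizedArray] = dataclasses.field(default_factory=list)


def compute_m_a(
    fg_cdna,
    fg_gdna,
    bg_cdna=None,
    bg_gdna=None,
    background_mode: str = "none",
    eps: float = 0.5,
):
    """Compute (M, A) from foreground/background intensities.

    ``background_mode='none'`` uses foregrounds as-is; any operand <= 0
    yields a missing (NaN) result.  ``'subtract'`` replaces each foreground
    by max(fg - bg, eps) before taking logs.  Accepts scalars, arrays or a
    :class:`~grefde.spot_io.SpotRecord`.
    """
    if isinstance(fg_cdna, SpotRecord):
        spot = fg_cdna
        return compute_m_a(
            spot.fg_cdna, spot.fg_gdna, spot.bg_cdna, spot.bg_gdna,
            background_mode=background_mode, eps=eps,
        )
    if background_mode not in ("none", "subtract"):
        raise ConfigError(f"unknown background mode: {background_mode!r}")
    cy3 = np.asarray(fg_cdna, float)
    cy5 = np.asarray(fg_gdna, float)
    if (cy3 < 0).any() or (cy5 < 0).any():
        raise InputError("negative foreground intensities")
    if background_mode == "subtract":
        if bg_cdna is None or bg_gdna is None:
            raise InputError("background subtraction requires bg intensities")
        cy3 = np.maximum(cy3 - np.asarray(bg_cdna, float), eps)
        cy5 = np.maximum(cy5 - np.asarray(bg_gdna, float), eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where((cy3 > 0) & (cy5 > 0), np.log2(cy3) - np.log2(cy5), np.nan)
        a = np.where((cy3 > 0) & (cy5 > 0), 0.5 * (np.log2(cy3) + np.log2(cy5)), np.nan)
    if m.ndim == 0:
        return float(m), float(a)
    return m, a


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value at which the cumulative normalized weight reaches 0.5
    over value-sorted observations (lower value taken at an exact 0.5 tie)."""
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    ok = np.isfinite(values) & np.isfinite(weights) & (weights > 0)
    if not ok.any():
        raise DegenerateGroupError("no positive weights in group")
    v = values[ok]
    w = weights[ok]
    order = np.argsort(v, kind="stable")
    v = v[order]
    cum = np.cumsum(w[order]) / w.sum()
    idx = int(np.searchsorted(cum, 0.5, side="left"))
    return float(v[idx])


def print_tip_weighted_median(values, weights=None) -> np.ndarray:
    """Centre one print-tip group: M - weighted_median(M; w).

    The weighted median of the output is 0 to machine tolerance.
    """
    values = np.asarray(values, float)
    if weights is None:
        weights = np.ones_like(values)
    return values - weighted_median(values, weights)


def _local_linear(x0: float, x: np.ndarray, y: np.ndarray, w: np.ndarray, k: int) -> float:
    """Weighted local-linear fit at x0 using the k nearest x (x sorted)."""
    n = x.size
    i = int(np.searchsorted(x, x0))
    lo = max(0, min(i - k // 2, n - k))
    hi = lo + k
    xs, ys, ws = x[lo:hi], y[lo:hi], w[lo:hi]
    d = np.abs(xs - x0)
    dmax = d.max()
    if dmax <= 0:
        tri = np.ones_like(d)
    else:
        tri = (1.0 - (d / dmax) ** 3) ** 3
    wt = tri * ws
    sw = wt.sum()
    if sw <= 0:
        return np.nan
    xm = (wt * xs).sum() / sw
    ym = (wt * ys).sum() / sw
    sxx = (wt * (xs - xm) ** 2).sum()
    if sxx <= 0:
        return ym
    beta = (wt * (xs - xm) * (ys - ym)).sum() / sxx
    return ym + beta * (x0 - xm)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    span: float = 0.3,
    iterations: int = 3,
    max_eval: int = 200,
) -> np.ndarray:
    """Weighted local-linear loess fit of y on x, evaluated at every x.

    Tricube distance kernel over the nearest span*n points, with prior
    observation weights multiplied in and bisquare robustifying iterations.
    For large inputs the curve is fitted on a quantile grid of ``max_eval``
    points and linearly interpolated (the usual delta shortcut).
    Returns fitted values aligned with x; NaN where x or y is missing.
    """
    if not 0 < span <= 1:
        raise ConfigError("span must lie in (0, 1]")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if weights is None:
        weights = np.ones_like(x)
    w = np.asarray(weights, float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(w) & (w >= 0)
    n = int(ok.sum())
    if n < 10:
        raise InsufficientDataError(f"loess requires >= 10 points, got {n}")
    order = np.argsort(x[ok], kind="stable")
    xs = x[ok][order]
    ys = y[ok][order]
    ws = w[ok][order]
    k = max(int(np.ceil(span * n)), 2)
    if n <= max_eval:
        eval_idx = np.arange(n)
    else:
        eval_idx = np.unique(np.linspace(0, n - 1, max_eval).round().astype(int))
    rob = np.ones(n)
    for it in range(max(iterations, 0) + 1):
        fit_grid = np.array(
            [_local_linear(xs[i], xs, ys, ws * rob, k) for i in eval_idx]
        )
        fitted = np.interp(xs, xs[eval_idx], fit_grid)
        if it == max(iterations, 0):
            break
        resid = ys - fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = np.clip(resid / (6.0 * s), -1, 1)
        rob = (1.0 - u**2) ** 2
    out = np.full(x.shape, np.nan)
    idx_ok = np.flatnonzero(ok)
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    out[idx_ok] = fitted[inv]
    return out


def global_loess(
    m: np.ndarray,
    a: np.ndarray,
    weights: np.ndarray | None = None,
    span: float = 0.3,
    iterations: int = 3,
) -> np.ndarray:
    """Mg = M - loess(M ~ A); missing values propagate."""
    fitted = loess_fit(a, m, weights=weights, span=span, iterations=iterations)
    return np.asarray(m, float) - fitted


def normalize_array(
    spots: pd.DataFrame,
    weights: np.ndarray | None = None,
    background_mode: str = "none",
    span: float = 0.3,
    iterations: int = 3,
    eps: float = 0.5,
) -> NormalizedArray:
    """Normalize one array: M/A, per-tip weighted median, then global loess.

    ``spots`` is the per-array slice of an :class:`ArraySet` spot table.
    ``weights`` are per-spot prior weights for the median and loess fits
    (default: all 1).  The fitted tip medians and the loess curve are kept
    for diagnostics.
    """
    array_id = str(spots["array_id"].iloc[0]) if "array_id" in spots else ""
    m, a = compute_m_a(
        spots["fg_cdna"].to_numpy(),
        spots["fg_gdna"].to_numpy(),
        spots["bg_cdna"].to_numpy() if "bg_cdna" in spots else None,
        spots["bg_gdna"].to_numpy() if "bg_gdna" in spots else None,
        background_mode=background_mode,
        eps=eps,
    )
    if weights is None:
        weights = np.ones(len(spots))
    weights = np.asarray(weights, float)
    block = spots["block"].to_numpy()
    m_tip = np.array(m, float)
    tip_medians = {}
    for b in np.unique(block):
        sel = block == b
        usable = sel & np.isfinite(m) & (weights > 0)
        if not usable.any():
            raise DegenerateGroupError(f"print-tip block {b} has no usable spots")
        med = weighted_median(m[sel], weights[sel])
        tip_medians[int(b)] = med
        m_tip[sel] = m[sel] - med
    fitted = loess_fit(a, m_tip, weights=weights, span=span, iterations=iterations)
    mg = m_tip - fitted
    carry = ["gene_id", "duplicate_index", "block", "row", "col"]
    if "flag" in spots.columns:
        carry.append("flag")
    out = spots[carry].copy()
    out.insert(0, "array_id", array_id)
    out["A"] = a
    out["M_raw"] = m
    out["M_tip"] = m_tip
    out["Mg"] = mg
    grid_order = np.argsort(a[np.isfinite(a)])
    a_sorted = a[np.isfinite(a)][grid_order]
    f_sorted = fitted[np.isfinite(a)][grid_order]
    loess_grid = pd.DataFrame({"A": a_sorted, "fit": f_sorted})
    return NormalizedArray(
        array_id=array_id,
        spots=out,
        tip_medians=pd.Series(tip_medians, name="tip_median"),
        loess_grid=loess_grid,
    )


def normalize_set(
    arrayset: ArraySet,
    weights: pd.Series | np.ndarray | None = None,
    background_mode: str = "none",
    span: float = 0.3,
    iterations: int = 3,
) -> NormalizedSet:
    """Normalize every array of an :class:`ArraySet` independently.

    ``weights``, if given, must align with ``arrayset.spots`` rows.
    """
    if weights is not None:
        weights = np.asarray(weights, float)
        if weights.shape[0] != len(arrayset.spots):
            raise InputError("weights must align with the spot table rows")
    arrays = []
    frames = []
    for array_id in arrayset.array_ids:
        sel = (arrayset.spots["array_id"] == array_id).to_numpy()
        sub = arrayset.spots.loc[sel]
        w = weights[sel] if weights is not None else None
        na = normalize_array(
            sub, weights=w, background_mode=background_mode,
            span=span, iterations=iterations,
        )
        arrays.append(na)
        frames.append(na.spots)
    spots = pd.concat(frames, ignore_index=True)
    return NormalizedSet(
        spots=spots,
        design=arrayset.design.copy(),
        duplicate_arity=arrayset.duplicate_arity,
        arrays=arrays,
    )
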