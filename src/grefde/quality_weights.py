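"""Spot-quality flags, per-flag spot weights and empirical array weights.

The quantification software attaches a tuple of Boolean quality indicators
to every spot.  An ordered, first-match rule table maps indicator
combinations to a quality flag (best quality = 1.00; other labels are
arbitrary positive reals).  Spot weights are then estimated from the data:
spots that are more reproducible across biological replicates carry more
information, so the mean across-replicate variance of Mg is computed per
flag group and the weight of a flag is the normalized inverse of that mean
variance (max weight = 1).

Array weights capture whole-hybridization quality: per-array residual
variance factors are estimated by an iterative moment scheme from the
genewise strain-means model, and the weight of an array is the normalized
inverse of its variance factor (mean weight = 1).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .spot_io import ConfigError, InputError
from .normalization import NormalizedSet

__all__ = [
    "FlagRule",
    "FlagRuleTable",
    "WeightTable",
    "ArrayWeightSet",
    "DEFAULT_FLAG_RULES",
    "assign_flags",
    "estimate_spot_weights",
    "estimate_array_weights",
]

# wildcard marker in indicator patterns
WILD = None


@dataclasses.dataclass(frozen=True)
class FlagRule:
    """One rule: indicator pattern (True/False/None=wildcard) -> flag label."""

    pattern: tuple[bool | None, ...]
    flag: float

    def __post_init__(self):
        if self.flag <= 0:
            raise ConfigError("flag labels must be positive")


@dataclasses.dataclass(frozen=True)
class FlagRuleTable:
    """Ordered first-match rules plus a default flag for unmatched patterns."""

    rules: tuple[FlagRule, ...]
    default_flag: float

    def __post_init__(self):
        if not self.rules:
            raise ConfigError("at least one flag rule is required")
        arities = {len(r.pattern) for r in self.rules}
        if len(arities) != 1:
            raise ConfigError("all rule patterns must have the same arity")

    @property
    def arity(self) -> int:
        return len(self.rules[0].pattern)

    @classmethod
    def from_yaml(cls, path) -> "FlagRuleTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rules = tuple(
            FlagRule(pattern=_parse_pattern(item["pattern"]), flag=float(item["flag"]))
            for item in doc["rules"]
        )
        return cls(rules=rules, default_flag=float(doc.get("default_flag", rules[-1].flag)))


def _parse_pattern(pattern) -> tuple[bool | None, ...]:
    """Accept '1*10'-style strings or lists of true/false/null."""
    if isinstance(pattern, str):
        table = {"1": True, "T": True, "0": False, "F": False, "*": WILD}
        try:
            return tuple(table[ch.upper()] for ch in pattern)
        except KeyError as exc:
            raise ConfigError(f"bad pattern character in {pattern!r}") from exc
    return tuple(None if p is None else bool(p) for p in pattern)


#: default rule table, matching the indicator patterns the synthetic
#: generator emits (spot found, above background, not saturated, uniform)
DEFAULT_FLAG_RULES = FlagRuleTable(
    rules=(
        FlagRule((True, True, True, True), 1.00),
        FlagRule((True, True, True, False), 0.5),
        FlagRule((True, False, WILD, WILD), 0.1),
    ),
    default_flag=0.1,
)


def assign_flags(indicators, rules: FlagRuleTable = DEFAULT_FLAG_RULES) -> np.ndarray:
    """Map each spot's Boolean indicator tuple to a quality flag.

    ``indicators`` is an (n_spots, arity) Boolean array (or DataFrame of
    indicator columns).  First matching rule wins; unmatched spots get the
    default flag.  Pure function of (indicators, rules).
    """
    ind = np.asarray(indicators, dtype=bool)
    if ind.ndim != 2 or ind.shape[1] != rules.arity:
        raise ConfigError(
            f"indicator arity {ind.shape[-1] if ind.ndim == 2 else '?'} "
            f"does not match rule arity {rules.arity}"
        )
    flags = np.full(ind.shape[0], rules.default_flag, float)
    unassigned = np.ones(ind.shape[0], dtype=bool)
    for rule in rules.rules:
        match = unassigned.copy()
        for k, want in enumerate(rule.pattern):
            if want is WILD:
                continue
            match &= ind[:, k] == want
        flags[match] = rule.flag
        unassigned &= ~match
    return flags


@dataclasses.dataclass
class WeightTable:
    """Per-flag spot weights: normalized inverse of the mean across-replicate
    variance of Mg within each flag group (max weight = 1)."""

    table: pd.DataFrame  # index: flag label; columns: weight, mean_variance, n_spots
    default_flag: float

    def weight_of(self, flags) -> np.ndarray:
        w = self.table["weight"]
        default = w.loc[self.default_flag] if self.default_flag in w.index else 1.0
        return w.reindex(np.asarray(flags, float)).fillna(default).to_numpy()


def estimate_spot_weights(
    normalized: NormalizedSet,
    flags,
    min_count: int = 30,
    default_flag: float = 1.0,
) -> WeightTable:
    """Estimate per-flag spot weights from replicate reproducibility.

    For each physical spot position (gene, duplicate) the variance of Mg is
    computed across the replicate arrays of each strain; every spot inherits
    its position's within-strain variance, variances are grouped by the
    spot's flag (which pools across strains by simple averaging), and the
    weight of a flag is the inverse of its mean variance, normalized so the
    best group has weight 1.  Flag groups with fewer than ``min_count``
    spots inherit the default flag's weight.
    """
    df = normalized.spots[["array_id", "gene_id", "duplicate_index", "Mg"]].copy()
    df["flag"] = np.asarray(flags, float)
    df = df.merge(normalized.design[["array_id", "strain"]], on="array_id", how="left")
    reps = normalized.design.groupby("strain").size()
    if (reps < 2).any():
        raise InputError("spot-weight estimation needs >= 2 replicates per strain")
    grp = df.groupby(["strain", "gene_id", "duplicate_index"], sort=False)["Mg"]
    df["pos_var"] = grp.transform("var")

    ok = df["pos_var"].notna()
    by_flag = df.loc[ok].groupby("flag")
    mean_var = by_flag["pos_var"].mean()
    counts = by_flag.size()
    if mean_var.isna().all():
        raise InputError("all flag groups have missing variances")

    inv = 1.0 / mean_var
    big = counts[counts >= min_count].index
    if len(big) == 0:
        big = counts.index
    weights = inv / inv.loc[big].max()
    if default_flag in weights.index:
        fallback = weights.loc[default_flag]
    else:
        fallback = 1.0
    weights.loc[~weights.index.isin(big)] = fallback
    table = pd.DataFrame(
        {"weight": weights, "mean_variance": mean_var, "n_spots": counts}
    ).sort_index(ascending=False)
    return WeightTable(table=table, default_flag=default_flag)


@dataclasses.dataclass
class ArrayWeightSet:
    """Per-array weights (inverse variance factors, mean-normalized to 1)."""

    weights: pd.Series       # index array_id, mean exactly 1
    gamma: pd.Series         # estimated per-array variance factors
    iterations: int
    converged: bool

    def weight_of(self, array_ids) -> np.ndarray:
        return self.weights.reindex(np.asarray(array_ids)).to_numpy()


def estimate_array_weights(
    normalized: NormalizedSet,
    spot_weights=None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> ArrayWeightSet:
    """Estimate empirical array weights from genewise residuals.

    Iterative moment scheme: fit genewise strain means with the current
    weights, update each array's variance factor gamma_j as the
    leverage-corrected mean of standardized squared residuals on that array,
    and repeat until the factors stabilize.  weight_j = 1/gamma_j,
    mean-normalized to 1.  Returns the last iterate with ``converged=False``
    if ``max_iter`` is exhausted.
    """
    design = normalized.design
    if len(design) < 3:
        raise InputError("array-weight estimation needs >= 3 arrays")
    df = normalized.spots[["array_id", "gene_id", "Mg"]].copy()
    df = df.merge(design[["array_id", "strain"]], on="array_id", how="left")
    df = df[df["Mg"].notna()]
    w = np.ones(len(df)) if spot_weights is None else np.asarray(spot_weights, float)[
        normalized.spots["Mg"].notna().to_numpy()
    ]

    array_ids = list(design["array_id"])
    arr_code = pd.Categorical(df["array_id"], categories=array_ids).codes
    grp_code, _ = pd.factorize(
        df["gene_id"].astype(str) + "\x00" + df["strain"].astype(str), sort=False
    )
    gene_code, _ = pd.factorize(df["gene_id"], sort=False)
    y = df["Mg"].to_numpy(float)
    n_arrays = len(array_ids)
    n_groups = grp_code.max() + 1
    n_genes = gene_code.max() + 1

    # residual df per gene: obs - strains with data
    obs_per_gene = np.bincount(gene_code, minlength=n_genes)
    groups_per_gene = np.zeros(n_genes)
    first = pd.DataFrame({"gene": gene_code, "grp": grp_code}).drop_duplicates()
    np.add.at(groups_per_gene, first["gene"].to_numpy(), 1)
    df_gene = obs_per_gene - groups_per_gene
    usable_gene = df_gene > 0

    gamma = np.ones(n_arrays)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = w / gamma[arr_code]
        su = np.bincount(grp_code, weights=u, minlength=n_groups)
        suy = np.bincount(grp_code, weights=u * y, minlength=n_groups)
        mu = suy / su
        r = y - mu[grp_code]
        h = u / su[grp_code]
        # genewise scale given gamma
        q_gene = np.bincount(gene_code, weights=u * r * r, minlength=n_genes)
        sigma2 = np.full(n_genes, np.nan)
        sigma2[usable_gene] = q_gene[usable_gene] / df_gene[usable_gene]
        valid = usable_gene[gene_code] & (sigma2[gene_code] > 0)
        z = np.zeros(len(y))
        z[valid] = w[valid] * r[valid] ** 2 / sigma2[gene_code[valid]]
        num = np.bincount(arr_code[valid], weights=z[valid], minlength=n_arrays)
        den = np.bincount(
            arr_code[valid], weights=(1.0 - h[valid]), minlength=n_arrays
        )
        new_gamma = np.where(den > 0, num / np.maximum(den, 1e-12), 1.0)
        new_gamma = np.maximum(new_gamma, 1e-8)
        new_gamma = new_gamma / new_gamma.mean()
        delta = np.max(np.abs(new_gamma - gamma))
        gamma = new_gamma
        if delta < tol:
            converged = True
            break
    weights = 1.0 / gamma
    weights = weights / weights.mean()
    return ArrayWeightSet(
        weights=pd.Series(weights, index=array_ids, name="array_weight"),
        gamma=pd.Series(gamma, index=array_ids, name="gamma"),
        iterations=it,
        converged=converged,
    )
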