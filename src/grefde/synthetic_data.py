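"""Synthetic two-colour arrays with a genomic-DNA common reference.

Generates :class:`~grefde.spot_io.ArraySet` instances with the statistical
structure the downstream analysis assumes, plus the ground truth needed for
recovery tests:

* three strains (A = wild type, B and C = regulator deletion mutants),
  five biological replicates each, duplicated probes per gene;
* a Cy5 genomic-DNA channel whose expectation for a gene is constant across
  arrays (the common-reference property) and a Cy3 cDNA channel carrying
  the strain effects;
* a smooth intensity-dependent dye bias (recoverable by loess), additive
  per-print-tip offsets (recoverable by per-block median correction);
* per-spot quality flags with flag-dependent noise multipliers, drawn per
  physical spot position so that a position keeps its flag across replicate
  hybridizations (print-run artefacts);
* within-array duplicate spots correlated through a shared gene-by-array
  latent term (exchangeable correlation rho);
* designed differentially transcribed gene sets: an up-regulated
  "PHO-like" set (25 genes) and a down-regulated "act-like" set (13 genes),
  with per-contrast effect sizes.

All noise lives on the log2 (M) scale: the cDNA channel is constructed as
gDNA x 2^M, which keeps the flag multipliers directly interpretable as
M-scale standard-deviation factors.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spot_io import ArraySet, ConfigError, STRAINS

__all__ = ["SimConfig", "GroundTruth", "default_config", "simulate_experiment",
           "FLAG_INDICATOR_PATTERNS"]

#: canonical indicator patterns emitted for each quality flag
#: (four Booleans: spot found, signal above background, not saturated,
#: uniform feature)
FLAG_INDICATOR_PATTERNS: dict[float, tuple[bool, bool, bool, bool]] = {
    1.00: (True, True, True, True),
    0.5: (True, True, True, False),
    0.1: (True, False, True, True),
}


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults mirror the study design: 3 strains x 5 biological replicates,
    duplicated probes, 8 print-tip groups, baseline M noise 0.25 (log2
    units), duplicate correlation 0.6, and the (p, multiplier) flag model
    {1.00: (0.85, x1), 0.5: (0.10, x2), 0.1: (0.05, x4)}.
    """

    n_genes: int = 1000
    duplicate_arity: int = 2
    n_tips: int = 8
    strains: tuple[str, ...] = STRAINS
    n_reps: int = 5
    seed: int = 0
    # intensity model (A axis)
    sigma_capture: float = 0.8     # lognormal sd of per-gene capture efficiency
    sigma_expr: float = 1.0        # lognormal sd of per-gene base expression
    sigma_scale: float = 0.2       # lognormal sd of per-array gDNA scale
    base_intensity: float = 1000.0
    # artefacts injected into M
    dye_bias_coeffs: tuple[float, float, float, float] = (0.2, 0.1, 0.0, 0.025)
    tip_offsets: tuple[float, ...] | None = None  # None -> linspace(-0.3, 0.3)
    # noise model
    noise_sd: float = 0.25
    flag_model: tuple[tuple[float, float, float], ...] = (
        (1.00, 0.85, 1.0),
        (0.5, 0.10, 2.0),
        (0.1, 0.05, 4.0),
    )
    array_var_factors: tuple[float, ...] | None = None  # None -> all 1
    dup_correlation: float = 0.6
    # designed differential transcription (gene indices into 0..n_genes-1)
    de_up_genes: tuple[int, ...] = ()
    de_up_effects: Mapping[str, tuple[float, ...]] | None = None
    de_down_genes: tuple[int, ...] = ()
    de_down_effects: Mapping[str, tuple[float, ...]] | None = None

    def validate(self) -> "SimConfig":
        probs = [p for _, p, _ in self.flag_model]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError("flag_model probabilities must sum to 1")
        if self.noise_sd < 0 or self.sigma_capture <= 0 or self.sigma_expr <= 0:
            raise ConfigError("all scale parameters must be positive")
        if not -1 < self.dup_correlation < 1:
            raise ConfigError("dup_correlation must lie in (-1, 1)")
        for idx in (*self.de_up_genes, *self.de_down_genes):
            if not 0 <= idx < self.n_genes:
                raise ConfigError(f"DE gene index out of range: {idx}")
        if set(self.de_up_genes) & set(self.de_down_genes):
            raise ConfigError("up- and down-regulated gene sets must be disjoint")
        if self.tip_offsets is not None and len(self.tip_offsets) != self.n_tips:
            raise ConfigError("tip_offsets length must equal n_tips")
        n_arrays = len(self.strains) * self.n_reps
        if self.array_var_factors is not None and len(self.array_var_factors) != n_arrays:
            raise ConfigError("array_var_factors length must equal the array count")
        return self

    @property
    def mutant_strains(self) -> tuple[str, ...]:
        return tuple(s for s in self.strains if s != "A")

    @property
    def contrasts(self) -> tuple[str, ...]:
        return tuple(f"{s}vA" for s in self.mutant_strains)


@dataclasses.dataclass
class GroundTruth:
    """What the generator injected, for recovery tests."""

    gene_ids: list[str]
    true_mc: pd.DataFrame            # gene_id x contrast, log2 mutant - WT
    position_flags: np.ndarray       # flag label per physical spot position
    array_var_factors: np.ndarray    # per array, design order
    rho: float
    de_up_genes: list[str]
    de_down_genes: list[str]


def default_config(seed: int) -> SimConfig:
    """Study-shaped defaults: 25 up-regulated PHO-like genes with per-contrast
    effects uniform in [+1, +3] and 13 down-regulated act-like genes with
    effects uniform in [-1.5, -0.5], present in both mutant contrasts."""
    rng = np.random.default_rng(seed)
    n_genes = 1000
    idx = rng.choice(n_genes, size=25 + 13, replace=False)
    up = tuple(int(i) for i in np.sort(idx[:25]))
    down = tuple(int(i) for i in np.sort(idx[25:]))
    up_eff = {c: tuple(rng.uniform(1.0, 3.0, size=25)) for c in ("BvA", "CvA")}
    down_eff = {c: tuple(rng.uniform(-1.5, -0.5, size=13)) for c in ("BvA", "CvA")}
    return SimConfig(
        n_genes=n_genes,
        seed=seed,
        de_up_genes=up,
        de_up_effects=up_eff,
        de_down_genes=down,
        de_down_effects=down_eff,
    ).validate()


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _layout(n_positions: int, n_tips: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign positions to (block, row, col); contiguous blocks of equal size."""
    per_tip = math.ceil(n_positions / n_tips)
    pos = np.arange(n_positions)
    block = pos // per_tip + 1
    within = pos % per_tip
    ncol = math.ceil(math.sqrt(per_tip))
    row = within // ncol + 1
    col = within % ncol + 1
    return block, row, col


def simulate_experiment(config: SimConfig) -> tuple[ArraySet, GroundTruth]:
    """Generate one full experiment; bitwise-reproducible from the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    arity = config.duplicate_arity
    n_pos = n * arity
    gene_ids = _gene_ids(n)
    strains = list(config.strains)
    design = pd.DataFrame(
        [
            {"array_id": f"{s}{r}", "strain": s, "replicate": r}
            for s in strains
            for r in range(1, config.n_reps + 1)
        ]
    )
    n_arrays = len(design)

    # --- gene-level brightness (enters BOTH channels: abundance relative to
    # the single-copy gDNA reference is a gene-level constant, absorbed into
    # the baseline so that null M is centred at 0)
    capture = rng.lognormal(0.0, config.sigma_capture, size=n)
    base_expr = rng.lognormal(0.0, config.sigma_expr, size=n)
    level = config.base_intensity * capture * base_expr  # per gene

    # --- strain effects (log2): Mc per contrast for DE genes, 0 elsewhere
    delta = {s: np.zeros(n) for s in strains}
    true_mc = pd.DataFrame(0.0, index=gene_ids, columns=list(config.contrasts))
    for genes, effects in (
        (config.de_up_genes, config.de_up_effects),
        (config.de_down_genes, config.de_down_effects),
    ):
        if not genes:
            continue
        if effects is None:
            raise ConfigError("DE gene set given without effect sizes")
        for contrast, eff in effects.items():
            strain = contrast[0]
            if strain not in delta:
                raise ConfigError(f"contrast {contrast!r} names unknown strain")
            if len(eff) != len(genes):
                raise ConfigError("effect-size vector length mismatch")
            delta[strain][list(genes)] += np.asarray(eff, float)
            true_mc.loc[np.asarray(gene_ids)[list(genes)], contrast] += np.asarray(eff)

    # --- spot geometry and per-position quality flags (print-run artefacts:
    # a position keeps its flag across all hybridizations)
    block, row, col = _layout(n_pos, config.n_tips)
    if config.tip_offsets is None:
        tip_offsets = np.linspace(-0.3, 0.3, config.n_tips)
    else:
        tip_offsets = np.asarray(config.tip_offsets, float)
    flag_labels = np.array([f for f, _, _ in config.flag_model])
    flag_probs = np.array([p for _, p, _ in config.flag_model])
    flag_mults = np.array([m for _, _, m in config.flag_model])
    flag_idx = rng.choice(len(flag_labels), size=n_pos, p=flag_probs)
    position_flags = flag_labels[flag_idx]
    position_mults = flag_mults[flag_idx]

    # position -> gene: duplicate 1 occupies positions 0..n-1, duplicate 2
    # occupies n..2n-1 (the two duplicates of a gene sit in different blocks)
    gene_of_pos = np.tile(np.arange(n), arity)
    dup_of_pos = np.repeat(np.arange(1, arity + 1), n)

    if config.array_var_factors is None:
        var_factors = np.ones(n_arrays)
    else:
        var_factors = np.asarray(config.array_var_factors, float)
    scale = rng.lognormal(0.0, config.sigma_scale, size=n_arrays)

    rho = config.dup_correlation
    c0, c1, c2, c3 = config.dye_bias_coeffs

    frames = []
    for j, (_, arr) in enumerate(design.iterrows()):
        strain = arr["strain"]
        # clean per-position A (log2 of the geometric-mean intensity)
        a_clean = np.log2(level[gene_of_pos] * scale[j])
        a_std = (a_clean - a_clean.mean()) / a_clean.std()
        dye = c0 + c1 * a_std + c2 * a_std**2 + c3 * a_std**3
        # shared gene-by-array latent (induces duplicate correlation rho)
        z_gene = rng.normal(size=n)
        eps = rng.normal(size=n_pos)
        sd_spot = config.noise_sd * position_mults * math.sqrt(var_factors[j])
        noise = sd_spot * (
            math.sqrt(rho) * z_gene[gene_of_pos] + math.sqrt(1.0 - rho) * eps
        )
        m = delta[strain][gene_of_pos] + dye + tip_offsets[block - 1] + noise
        gdna_noise = 2.0 ** rng.normal(0.0, 0.1, size=n_pos)
        fg_gdna = level[gene_of_pos] * scale[j] * gdna_noise
        fg_cdna = fg_gdna * 2.0**m
        bg = rng.lognormal(math.log(20.0), 0.3, size=(2, n_pos))
        df = pd.DataFrame(
            {
                "array_id": arr["array_id"],
                "block": block,
                "row": row,
                "col": col,
                "gene_id": np.asarray(gene_ids)[gene_of_pos],
                "duplicate_index": dup_of_pos,
                "fg_cdna": fg_cdna,
                "bg_cdna": bg[0],
                "fg_gdna": fg_gdna,
                "bg_gdna": bg[1],
            }
        )
        patterns = np.array(
            [FLAG_INDICATOR_PATTERNS[float(f)] for f in flag_labels], dtype=bool
        )
        ind = patterns[flag_idx]
        for k in range(ind.shape[1]):
            df[f"ind{k + 1}"] = ind[:, k]
        frames.append(df)

    spots = pd.concat(frames, ignore_index=True)
    aset = ArraySet(spots=spots, design=design, duplicate_arity=arity).validate()
    truth = GroundTruth(
        gene_ids=gene_ids,
        true_mc=true_mc,
        position_flags=position_flags,
        array_var_factors=var_factors,
        rho=rho,
        de_up_genes=[gene_ids[i] for i in config.de_up_genes],
        de_down_genes=[gene_ids[i] for i in config.de_down_genes],
    )
    return aset, truth
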