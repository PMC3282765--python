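"""End-to-end orchestration: simulate/import -> normalize -> weights ->
fit -> rank products -> decide -> profiles, from a single config.

Every stage writes a plain TSV into the output directory and the run ends
with a JSON manifest recording parameters, seeds and row counts, so a rerun
with an identical config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import spot_io
from .spot_io import ArraySet, ConfigError, GrefdeError
from .synthetic_data import SimConfig, default_config, simulate_experiment
from .normalization import NormalizedSet, normalize_set
from .quality_weights import (
    DEFAULT_FLAG_RULES,
    FlagRuleTable,
    assign_flags,
    estimate_array_weights,
    estimate_spot_weights,
)
from .linear_model import (
    ebayes_moderate,
    estimate_duplicate_correlation,
    fit_genewise,
)
from .rank_products import rank_product_analysis
from .significance import (
    assemble_de_table,
    count_differential,
    decide_significance,
    gene_set_profile,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("grefde")

STAGES = (
    "input",
    "normalize",
    "weights",
    "fit",
    "rankprod",
    "decide",
    "profile",
)


@dataclasses.dataclass
class PipelineConfig:
    """One run's parameters.

    Exactly one of ``input_paths`` (spot tables + design) or ``simulate``
    must be given.  ``simulate`` is either a :class:`SimConfig` or True to
    use the study-shaped defaults with ``seed``.
    """

    out_dir: str
    seed: int = 0
    input_paths: Sequence[str] | None = None
    design_path: str | None = None
    dialect: str = "generic"
    simulate: SimConfig | bool | None = None
    background_mode: str = "none"
    span: float = 0.3
    flag_rules_path: str | None = None
    rho: float | str = "auto"
    alpha: float = 0.05
    n_perm: int = 1000
    gene_sets: Mapping[str, Sequence[str] | str] | None = None
    relaxed_alpha: float = 0.05
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        has_input = self.input_paths is not None
        has_sim = bool(self.simulate)
        if has_input == has_sim:
            raise ConfigError(
                "exactly one of input_paths or simulate must be configured"
            )
        if has_input and self.design_path is None:
            raise ConfigError("input_paths requires design_path")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        sim = doc.pop("simulate", None)
        if isinstance(sim, dict):
            sim = SimConfig(**{**sim, "seed": sim.get("seed", doc.get("seed", 0))})
        return cls(**doc, simulate=sim).validate()


@dataclasses.dataclass
class PipelineResult:
    manifest: dict
    arrayset: ArraySet
    normalized: NormalizedSet
    decisions: "pd.DataFrame"
    out_dir: Path


def _load_gene_set(source) -> list[str]:
    if isinstance(source, (list, tuple)):
        return [str(g) for g in source]
    path = Path(source)
    return [
        line.strip()
        for line in path.read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; abort with the stage name on error."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
    )
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    log.addHandler(fh)
    manifest: dict = {
        "seed": config.seed,
        "parameters": {
            "background_mode": config.background_mode,
            "span": config.span,
            "rho": config.rho,
            "alpha": config.alpha,
            "n_perm": config.n_perm,
        },
        "stages": [],
    }
    stage = "input"
    try:
        # ------------------------------------------------------- input
        gene_sets: dict[str, list[str]] = {}
        if config.simulate:
            sim = (
                config.simulate
                if isinstance(config.simulate, SimConfig)
                else default_config(config.seed)
            )
            arrayset, truth = simulate_experiment(sim)
            truth.true_mc.rename_axis("gene_id").to_csv(
                out_dir / "truth.tsv", sep="\t", float_format="%.6f"
            )
            if truth.de_up_genes:
                gene_sets["pho_like"] = truth.de_up_genes
            if truth.de_down_genes:
                gene_sets["act_like"] = truth.de_down_genes
            manifest["parameters"]["sim_seed"] = sim.seed
        else:
            arrayset = spot_io.read_spot_tables(
                config.input_paths, config.design_path, dialect=config.dialect
            )
        if config.gene_sets:
            for name, source in config.gene_sets.items():
                gene_sets[name] = _load_gene_set(source)
        spot_io.write_spot_tables(arrayset, out_dir / "arrays")
        manifest["stages"].append(
            {"stage": stage, "n_arrays": len(arrayset.design),
             "n_spots": len(arrayset.spots)}
        )
        log.info("input: %d arrays, %d spots", len(arrayset.design), len(arrayset.spots))

        # --------------------------------------------------- flag rules
        stage = "normalize"
        if config.flag_rules_path is not None:
            rules_path = Path(config.flag_rules_path)
            if not rules_path.exists():
                raise ConfigError(f"flag rules file not found: {rules_path}")
            rules = FlagRuleTable.from_yaml(rules_path)
        else:
            rules = DEFAULT_FLAG_RULES
        flags = assign_flags(
            arrayset.spots[arrayset.indicator_columns].to_numpy(bool), rules
        )
        arrayset.spots = arrayset.spots.copy()
        arrayset.spots["flag"] = flags
        normalized = normalize_set(
            arrayset, background_mode=config.background_mode, span=config.span
        )
        normalized.spots.to_csv(
            out_dir / "normalized.tsv", sep="\t", index=False, float_format="%.6f"
        )
        diag = pd.concat(
            [
                na.tip_medians.rename_axis("block").reset_index().assign(
                    array_id=na.array_id
                )
                for na in normalized.arrays
            ],
            ignore_index=True,
        )
        diag.to_csv(out_dir / "tip_medians.tsv", sep="\t", index=False,
                    float_format="%.6f")
        manifest["stages"].append(
            {"stage": stage, "n_rows": len(normalized.spots)}
        )
        log.info("normalize: %d spots", len(normalized.spots))

        # ------------------------------------------------------ weights
        stage = "weights"
        flags_norm = normalized.spots["flag"].to_numpy(float)
        weight_table = estimate_spot_weights(normalized, flags_norm)
        spot_w = weight_table.weight_of(flags_norm)
        array_w = estimate_array_weights(normalized, spot_w)
        weight_table.table.rename_axis("flag").to_csv(
            out_dir / "spot_weights.tsv", sep="\t", float_format="%.6f"
        )
        array_w.weights.rename_axis("array_id").to_frame().assign(
            gamma=array_w.gamma
        ).to_csv(out_dir / "array_weights.tsv", sep="\t", float_format="%.6f")
        manifest["stages"].append(
            {
                "stage": stage,
                "n_flags": len(weight_table.table),
                "array_weight_iterations": array_w.iterations,
                "array_weight_converged": array_w.converged,
            }
        )
        log.info("weights: %d flag groups", len(weight_table.table))

        # ---------------------------------------------------------- fit
        stage = "fit"
        if config.rho == "auto":
            corr = estimate_duplicate_correlation(normalized)
            rho = corr.rho
        else:
            rho = float(config.rho)
        fit = fit_genewise(
            normalized, spot_weights=spot_w, array_weights=array_w.weights, rho=rho
        )
        eb = ebayes_moderate(fit)
        manifest["stages"].append(
            {"stage": stage, "rho": rho, "d0": eb.d0, "s02": eb.s02,
             "n_genes": len(fit.table)}
        )
        log.info("fit: rho=%.3f d0=%.2f s02=%.4f", rho, eb.d0, eb.s02)

        # ----------------------------------------------------- rankprod
        stage = "rankprod"
        rp = {}
        for i, c in enumerate(fit.contrasts):
            rp[c] = rank_product_analysis(
                normalized, c, n_perm=config.n_perm, seed=config.seed + 1000 + i
            )
            rp[c].table.rename_axis("gene_id").to_csv(
                out_dir / f"rp_{c}.tsv", sep="\t", float_format="%.6g"
            )
        manifest["stages"].append(
            {"stage": stage, "n_perm": config.n_perm,
             "contrasts": list(fit.contrasts)}
        )
        log.info("rankprod: %s", ", ".join(fit.contrasts))

        # ------------------------------------------------------- decide
        stage = "decide"
        decisions = decide_significance(fit, eb, rp, alpha=config.alpha)
        de_table = assemble_de_table(fit, eb, rp, decisions)
        spot_io.write_de_table(de_table, out_dir / "decisions.tsv")
        summary = count_differential(decisions)
        manifest["stages"].append({"stage": stage, **summary})
        log.info("decide: %s", summary)

        # ------------------------------------------------------ profile
        stage = "profile"
        profiles = {}
        prof_rows = []
        for name, members in gene_sets.items():
            prof = gene_set_profile(
                fit, eb, members, name=name, relaxed_alpha=config.relaxed_alpha
            )
            profiles[name] = prof
            prof.table.reset_index().assign(set=name).to_csv(
                out_dir / f"profile_{name}.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
            prof_rows.append(
                {
                    "set": name,
                    "n_genes": len(prof.genes),
                    **{f"mean_Mc_{c}": prof.mean_mc[c] for c in fit.contrasts},
                    **{f"relaxed_pass_{c}": int(prof.relaxed_pass[c])
                       for c in fit.contrasts},
                }
            )
        manifest["stages"].append({"stage": stage, "sets": prof_rows})
        log.info("profile: %d gene sets", len(profiles))

        manifest["n_stages"] = len(manifest["stages"])
        with open(out_dir / "manifest.json", "w") as out:
            json.dump(manifest, out, indent=2, sort_keys=True)
        return PipelineResult(
            manifest=manifest,
            arrayset=arrayset,
            normalized=normalized,
            decisions=de_table,
            out_dir=out_dir,
        )
    except GrefdeError as exc:
        raise GrefdeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
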