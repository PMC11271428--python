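"""End-to-end orchestration: one call from a MET table to the full results
bundle (ANOVA, genetic parameters, stability indices, AMMI, GGE, BLUP
statistics and the cross-method concordance), plus the on-disk writer used
by the command-line interface."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ammi import ammi_decompose, asv
from .anova import (
    DEFAULT_K_INTENSITY,
    individual_anova,
    homogeneity_check,
    joint_anova,
    selective_accuracy,
    ss_shares,
    trait_summary,
)
from .blup import composite_score, fit_blups, hmgv, performance_stability_quadrants, waasb
from .compare import build_rank_matrix, pca_group_methods, spearman_matrix, stability_concept_classification
from .data import METTable, cell_means, read_met_table, validate_balance
from .errors import MetstabError
from .gge import environment_metrics, gge_decompose, which_won_where
from .indices import environmental_index, stability_table
from .scott_knott import scott_knott
from .simulate import SyntheticConfig, generate_met


@dataclass
class RunConfig:
    """Settings for one pipeline run (CLI flags mirror these fields)."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    traits: list[str] = field(default_factory=list)
    alpha_scott_knott: float = 0.05
    alpha_confidence: float = 0.25
    k_intensity: float = DEFAULT_K_INTENSITY
    svp: str = "environment"
    variance_mode: str = "component_sum"
    n_method_groups: int = 4
    output_dir: str = "metstab_results"
    seed: int = 0

    def load(self) -> METTable:
        if self.input_path is not None:
            return read_met_table(self.input_path)
        if self.synthetic is not None:
            return generate_met(self.synthetic.with_seed(self.seed))
        raise MetstabError("RunConfig needs either input_path or a synthetic config")


def analyze_trait(
    met: METTable,
    trait: str,
    alpha_scott_knott: float = 0.05,
    alpha_confidence: float = 0.25,
    k_intensity: float = DEFAULT_K_INTENSITY,
    svp: str = "environment",
    variance_mode: str = "component_sum",
    n_method_groups: int = 4,
) -> dict:
    """Run the complete analysis chain for one trait; returns a results dict."""
    report = validate_balance(met, trait)
    summary = trait_summary(met, trait, variance_mode, k_intensity)
    anova = summary["anova"]
    cells = summary["cells"]
    reps = report.reps_per_cell

    individuals = [individual_anova(met, trait, env) for env in cells.environments]
    homogeneity = homogeneity_check(individuals)

    ms_error = anova.ms("residual")
    grouping = scott_knott(
        dict(zip(cells.genotypes, cells.genotype_means)),
        ms_error,
        int(anova.row("residual")["df"]),
        reps * cells.n_environments,
        alpha_scott_knott,
    )

    ammi_res = ammi_decompose(cells)
    asv_table = asv(ammi_res)
    gge_res = gge_decompose(cells, svp)
    www = which_won_where(gge_res)
    env_metrics = environment_metrics(gge_res)

    blup_res = fit_blups(met, trait, variance_mode)
    hmgv_table = hmgv(blup_res)
    waasb_table = waasb(blup_res)
    means = pd.Series(cells.genotype_means, index=list(cells.genotypes), name="mean")
    quadrants = performance_stability_quadrants(waasb_table, means)
    composite = composite_score(means, waasb_table["waasb"])

    indices = stability_table(met, cells, trait, ms_error, reps, alpha_confidence)
    values = indices.copy()
    values["asv"] = asv_table.frame["asv"]
    values["waasb"] = waasb_table["waasb"]
    values["hmgv"] = hmgv_table["hmgv"]
    values["gge"] = gge_res.genotype_scores[:, 1]  # PC2 marker, stability axis
    rank_matrix = build_rank_matrix(values)
    concord = spearman_matrix(rank_matrix.ranks)
    grouping_methods = pca_group_methods(concord["rho"], n_method_groups)
    concepts = stability_concept_classification(
        grouping_methods.groups, concord["rho"]["mean"]
    )

    return {
        "trait": trait,
        "anova": anova,
        "homogeneity": homogeneity,
        "selective_accuracy": selective_accuracy(anova),
        "ss_shares": ss_shares(anova),
        "components": summary["components"],
        "parameters": summary["parameters"],
        "cells": cells,
        "scott_knott": grouping,
        "ammi": ammi_res,
        "asv": asv_table,
        "gge": gge_res,
        "which_won_where": www,
        "environment_metrics": env_metrics,
        "environmental_index": environmental_index(cells),
        "blup": blup_res,
        "hmgv": hmgv_table,
        "waasb": waasb_table,
        "quadrants": quadrants,
        "composite": composite,
        "indices": values,
        "rank_matrix": rank_matrix,
        "spearman": concord,
        "method_groups": grouping_methods,
        "method_concepts": concepts,
    }


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_results(results: dict, outdir: Path) -> None:
    trait = results["trait"]

    def sub(name: str) -> Path:
        d = outdir / name
        d.mkdir(parents=True, exist_ok=True)
        return d

    results["anova"].frame.to_csv(sub("anova") / f"{trait}_joint_anova.csv", index=False)
    pd.DataFrame([results["homogeneity"]]).to_csv(
        sub("anova") / f"{trait}_homogeneity.csv", index=False
    )
    gp = {**results["components"].as_dict(), **results["parameters"].as_dict(),
          "selective_accuracy": results["selective_accuracy"], **results["ss_shares"]}
    with open(sub("genetic_parameters") / f"{trait}_parameters.json", "w") as fh:
        json.dump(gp, fh, indent=2)

    letters = results["scott_knott"].letters
    means = pd.DataFrame(
        {"mean": results["cells"].genotype_means,
         "group": [letters[g] for g in results["cells"].genotypes]},
        index=list(results["cells"].genotypes),
    )
    means.to_csv(sub("anova") / f"{trait}_means_scott_knott.csv")

    results["indices"].to_csv(sub("stability") / f"{trait}_indices.csv")
    results["environmental_index"].to_csv(sub("stability") / f"{trait}_environment_index.csv")
    results["rank_matrix"].display.to_csv(sub("comparison") / f"{trait}_ranks.csv")

    results["ammi"].scores_frame().to_csv(sub("ammi") / f"{trait}_scores.csv")
    results["asv"].frame.to_csv(sub("ammi") / f"{trait}_asv.csv")
    results["gge"].biplot_frame().to_csv(sub("gge") / f"{trait}_biplot.csv")
    results["environment_metrics"].frame.to_csv(sub("gge") / f"{trait}_environment_metrics.csv")
    www = results["which_won_where"]
    with open(sub("gge") / f"{trait}_which_won_where.json", "w") as fh:
        json.dump(
            {"hull_vertices": www.hull_vertices, "winners": www.winners,
             "mega_environments": [{"winner": g, "environments": e} for g, e in www.mega_environments]},
            fh, indent=2,
        )

    results["blup"].genotypic_values_frame().to_csv(sub("blup") / f"{trait}_genotypic_values.csv")
    blup_stats = pd.concat(
        [results["hmgv"].add_prefix("hmgv_"), results["waasb"].add_prefix("waasb_"),
         results["quadrants"], results["composite"]], axis=1
    )
    blup_stats.to_csv(sub("blup") / f"{trait}_hmgv_waasb.csv")

    results["spearman"]["rho"].to_csv(sub("comparison") / f"{trait}_spearman.csv")
    results["spearman"]["stars"].to_csv(sub("comparison") / f"{trait}_spearman_stars.csv")
    mg = results["method_groups"]
    loadings = mg.pca_loadings.copy()
    loadings["group"] = mg.groups
    loadings["concept"] = results["method_concepts"]
    loadings.to_csv(sub("comparison") / f"{trait}_method_groups.csv")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the results bundle to disk.

    Returns {trait: results dict}; writes a manifest recording the
    configuration, package version and a hash of every output file.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    met = config.load()
    traits = config.traits or met.traits
    all_results = {}
    for trait in traits:
        try:
            results = analyze_trait(
                met, trait,
                config.alpha_scott_knott, config.alpha_confidence, config.k_intensity,
                config.svp, config.variance_mode, config.n_method_groups,
            )
            _write_results(results, outdir)
            all_results[trait] = results
        except MetstabError as exc:
            (outdir / f"FAILED_{trait}").write_text(str(exc))
            raise
    manifest = {
        "package": "metstab",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "traits": list(traits),
        "config": {
            k: (asdict(v) if isinstance(v, SyntheticConfig) else v)
            for k, v in asdict(config).items()
        },
        "outputs": _hash_outputs(outdir),
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return all_results


def _hash_outputs(outdir: Path) -> dict:
    hashes = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            hashes[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    return hashes
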