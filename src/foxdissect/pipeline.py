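"""End-to-end orchestration of the transcriptomic dissection pipeline.

classify -> differential expression (all configured contrasts) ->
regulation calls -> set summaries -> direction-distribution tests ->
sample distances / PCA, with every stage's output written as diff-able
TSV/JSON under one output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import foxdissect
from foxdissect.classify import classify_replicates, compute_size_factors
from foxdissect.de import Contrast, estimate_dispersions, wald_test
from foxdissect.io import CountMatrix
from foxdissect.regulation import (call_mutant_status, call_regulated, summarize_sets)
from foxdissect.stats import (DirectionSplit, direction_distribution_test,
                              hierarchical_cluster, pca_summary, rlog_like,
                              sample_distances)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Contrast layout and thresholds for one pipeline run.

    ``lineage_contrast`` is the ex vivo lineage comparison (A, B), e.g.
    ``("naive_th", "treg")``; ``factor_contrast`` the transduction
    comparison, e.g. ``("control", "foxp3")``; ``mutants`` the mutant
    condition names, each compared against the factor condition.
    """

    lineage_contrast: tuple[str, str] = ("naive_th", "treg")
    factor_contrast: tuple[str, str] = ("control", "foxp3")
    mutants: list[str] = field(default_factory=list)
    alpha: float = 0.05
    fdr_class: float = 0.05
    shrinkage_prior_sd: float = 2.0
    seed: int = 0
    out_dir: str | None = None

    def validate(self, cm: CountMatrix) -> None:
        if not (0 < self.alpha < 1 and 0 < self.fdr_class < 1):
            raise ValueError("alpha and fdr_class must be in (0, 1)")
        known = set(cm.conditions)
        for c in (*self.lineage_contrast, *self.factor_contrast, *self.mutants):
            if c not in known:
                raise ValueError(f"configuration error: condition {c!r} not in metadata")


def run_pipeline(cm: CountMatrix, config: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the result bundle."""
    config.validate(cm)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    log.info("classify: fdr=%s seed=%s", config.fdr_class, config.seed)
    classes, fits, bounds, fpkm = classify_replicates(cm, fdr=config.fdr_class,
                                                      seed=config.seed)

    sf = compute_size_factors(cm)
    disp = estimate_dispersions(cm, sf)
    contrasts = {
        "lineage": Contrast(*config.lineage_contrast),
        "factor": Contrast(*config.factor_contrast),
    }
    factor_cond = config.factor_contrast[1]
    for m in config.mutants:
        contrasts[f"mutant_{m}"] = Contrast(factor_cond, m)

    de_results = {}
    for name, con in contrasts.items():
        log.info("de: %s (%s vs %s)", name, con.condition_A, con.condition_B)
        de_results[name] = wald_test(cm, sf, con, disp,
                                     shrinkage_prior_sd=config.shrinkage_prior_sd)

    regulation = call_regulated(de_results["lineage"], de_results["factor"],
                                classes, cm, alpha=config.alpha)
    for m in config.mutants:
        call_mutant_status(regulation, m, de_results[f"mutant_{m}"], alpha=config.alpha)
    summary = summarize_sets(regulation)

    n_up, n_down = summary["n_up"], summary["n_down"]
    tests = {}
    if n_up + n_down > 0:
        # split of the whole regulated set against an even null
        tests["up_down_split_p"] = direction_distribution_test(
            DirectionSplit(n_up, n_down, 1, 2))
        for m in config.mutants:
            mm = summary["mutants"][m]
            if mm["dysregulated"] > 0:
                tests[f"direction_p_{m}"] = direction_distribution_test(
                    DirectionSplit(mm["dysregulated_up"], mm["dysregulated_down"],
                                   n_up, n_up + n_down))

    reg_genes = list(regulation.regulated_genes)
    bundle = {
        "params": {
            "version": foxdissect.__version__,
            "alpha": config.alpha,
            "fdr_class": config.fdr_class,
            "shrinkage_prior_sd": config.shrinkage_prior_sd,
            "seed": config.seed,
        },
        "summary": summary,
        "direction_tests": tests,
    }
    if len(reg_genes) >= 2:
        expr = rlog_like(cm.counts[cm.sample_ids].div(sf, axis=1)).loc[reg_genes]
        dist = sample_distances(expr)
        scores, frac = pca_summary(expr)
        merge = hierarchical_cluster(dist)
        bundle["pca_variance_fractions"] = [round(float(f), 6) for f in frac]
        if out_dir:
            dist.round(6).to_csv(out_dir / "sample_distances.tsv", sep="\t")
            scores.round(6).to_csv(out_dir / "pca_scores.tsv", sep="\t")
            np.savetxt(out_dir / "linkage.tsv", merge, delimiter="\t", fmt="%.6g")

    if out_dir:
        classes.to_csv(out_dir / "classes.tsv", sep="\t", index_label="gene")
        for name, de in de_results.items():
            de.table.round(6).to_csv(out_dir / f"de_{name}.tsv", sep="\t",
                                     index_label="gene")
        regulation.table.to_csv(out_dir / "regulation.tsv", sep="\t",
                                index_label="gene")
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(bundle, fh, indent=1, sort_keys=True)

    bundle["_regulation"] = regulation
    bundle["_de"] = de_results
    bundle["_classes"] = classes
    return bundle
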