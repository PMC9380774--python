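"""End-to-end orchestration: simulate -> normalize -> test -> interference -> profiles.

A single TOML file configures every stage; one global seed deterministically
derives per-stage seeds, so identical config + seed gives byte-identical
summaries.  Stage outputs are written as plain-text tables next to a
machine-readable ``report.json``.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

from . import __version__
from .annotation import write_gff3
from .coverage import mean_coverage, smooth_and_bin, write_bedgraph
from .counts import write_counts
from .diffexpr import DifferentialExpression
from .interference import (
    anticorrelation,
    classify_orientation,
    opposite_strand_pairs,
    orientation_chi2,
    window_pairs,
)
from .normalization import spikein_size_factors
from .profiles import (
    cluster_partner_stats,
    convergent_pair_matrix,
    kmeans_cluster,
    metagene_average,
    metagene_matrix,
)
from .simulate import (
    MINUS_AUXIN,
    PLUS_AUXIN,
    SimulationConfig,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "diffexpr", "interference", "profiles")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    simulate: dict[str, Any] = field(default_factory=dict)
    diffexpr: dict[str, Any] = field(default_factory=lambda: {"alpha": 0.05})
    interference: dict[str, Any] = field(
        default_factory=lambda: {"window": 1000, "corr": "pearson"}
    )
    profiles: dict[str, Any] = field(
        default_factory=lambda: {"k": 4, "flank": 500, "min_dist": 200}
    )

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        bad_stages = set(cfg.stages) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stage(s): {sorted(bad_stages)}")
        return cfg

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulate)
        params.setdefault("seed", stage_seed(self.seed, "simulate"))
        known = {f.name for f in fields(SimulationConfig)}
        unknown = set(params) - known
        if unknown:
            raise ValueError(f"unknown [simulate] key(s): {sorted(unknown)}")
        if "gene_length_range" in params:
            params["gene_length_range"] = tuple(params["gene_length_range"])
        if "intergap_distribution" in params:
            params["intergap_distribution"] = tuple(params["intergap_distribution"])
        return SimulationConfig(**params)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Any]:
    """Run enabled stages and return (and write) the summary report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"version": __version__, "seed": config.seed}

    current = "simulate"
    try:
        if not config.stages.get("simulate", True):
            raise ValueError("pipeline currently requires the simulate stage")
        sim_cfg = config.simulation_config()
        annotation, expected, table, observed = simulate_dataset(sim_cfg)
        write_gff3(annotation, outdir / "annotation.gff3")
        write_counts(table, outdir / "counts.tsv")
        for cond, (cov, truth) in expected.items():
            truth.table.to_csv(outdir / f"truth_{_slug(cond)}.tsv", sep="\t")
        report["simulate"] = {
            "n_genes": sim_cfg.n_genes,
            "n_samples": len(table.samples),
            "conditions": sim_cfg.conditions,
        }

        # condition-pooled CPM coverage used by interference and profiles
        cond_cov = {}
        for cond in sim_cfg.conditions:
            pooled = mean_coverage(
                [observed[s] for s in table.condition_samples(cond)]
            )
            cond_cov[cond] = smooth_and_bin(pooled, sim_cfg.bin_size, 2 * sim_cfg.bin_size)
            write_bedgraph(cond_cov[cond], outdir / f"coverage_{_slug(cond)}")

        treated, control = PLUS_AUXIN, MINUS_AUXIN
        if treated not in sim_cfg.conditions or control not in sim_cfg.conditions:
            control, treated = sim_cfg.conditions[:2]

        current = "normalize"
        if config.stages.get("normalize", True):
            factors = spikein_size_factors(table)
            table = table.with_size_factors(factors)
            factors.to_csv(outdir / "size_factors.tsv", sep="\t")
            report["normalize"] = {
                "method": "spikein-median-ratio",
                "size_factors": {s: round(float(v), 6) for s, v in factors.items()},
            }

        current = "diffexpr"
        deresult = None
        if config.stages.get("diffexpr", True):
            model = DifferentialExpression(table, treated=treated, control=control)
            deresult = model.fit(alpha=float(config.diffexpr.get("alpha", 0.05)))
            deresult.to_tsv(outdir / "de_results.tsv")
            report["diffexpr"] = {
                "alpha": deresult.alpha,
                "n_up": deresult.n_up(),
                "n_down": deresult.n_down(),
            }

        current = "interference"
        if config.stages.get("interference", True) and deresult is not None:
            gene_pairs = opposite_strand_pairs(deresult, annotation, cond_cov)
            gene_pairs.pairs.to_csv(outdir / "gene_strand_pairs.tsv", sep="\t")
            method = config.interference.get("corr", "pearson")
            r_gene, p_gene = anticorrelation(gene_pairs, method=method)
            tiles = window_pairs(
                cond_cov, treated, control,
                window=int(config.interference.get("window", 1000)),
            )
            tiles.pairs.to_csv(outdir / "window_strand_pairs.tsv", sep="\t", index=False)
            r_win, p_win = anticorrelation(tiles, method=method)
            classes = classify_orientation(annotation)
            chi2_res = orientation_chi2(deresult.direction, classes)
            chi2_res.observed.to_csv(outdir / "orientation_contingency.tsv", sep="\t")
            chi2_res.residuals.to_csv(outdir / "orientation_residuals.tsv", sep="\t")
            report["interference"] = {
                "gene_pair_r": round(r_gene, 6),
                "gene_pair_p": float(f"{p_gene:.6g}"),
                "window_pair_r": round(r_win, 6),
                "window_pair_p": float(f"{p_win:.6g}"),
                "chi2": round(chi2_res.chi2, 6),
                "chi2_dof": chi2_res.dof,
                "chi2_p": float(f"{chi2_res.p_value:.6g}"),
            }

        current = "profiles"
        if config.stages.get("profiles", True) and deresult is not None:
            flank = int(config.profiles.get("flank", 500))
            min_dist = int(config.profiles.get("min_dist", 200))
            k = int(config.profiles.get("k", 4))
            meta_curves = {}
            biological = [g for g in annotation if g.chrom != "spikein"]
            for cond in (control, treated):
                mat = metagene_matrix(
                    cond_cov[cond], annotation, flank=flank,
                    min_neighbor_distance=min_dist, genes=biological,
                )
                avg = metagene_average(mat)
                avg.to_csv(outdir / f"metagene_{_slug(cond)}.tsv", sep="\t", index=False)
                meta_curves[cond] = avg
            pair_mat, kept_pairs = convergent_pair_matrix(cond_cov, annotation, flank=flank)
            clusters = kmeans_cluster(
                pair_mat, k=min(k, max(1, len(kept_pairs))),
                seed=stage_seed(config.seed, "profiles"),
            )
            clusters.assignments.to_csv(outdir / "pair_clusters.tsv", sep="\t")
            box, tests = cluster_partner_stats(deresult, kept_pairs, clusters.assignments)
            box.to_csv(outdir / "cluster_boxstats.tsv", sep="\t", index=False)
            tests.to_csv(outdir / "cluster_ttests.tsv", sep="\t", index=False)
            report["profiles"] = {
                "n_metagene_genes": int(meta_curves[treated]["n"].max()),
                "n_convergent_pairs": len(kept_pairs),
                "k": clusters.k,
                "cluster_sizes": {
                    str(c): int(n) for c, n in clusters.cluster_sizes.items()
                },
                "wcss": round(clusters.wcss, 6),
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _slug(condition: str) -> str:
    return condition.replace("+", "plus_").replace("-", "minus_").strip("_")
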