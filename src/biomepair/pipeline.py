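"""End-to-end orchestration of the paired-cohort analysis.

Stages run in a fixed order — load, depth filter, diversity, ordination,
differential abundance, correlation screen, random forest, field effect —
each writing machine-readable artifacts (TSV/JSON) into the output
directory.  Identical config and master seed give byte-identical outputs:
every stochastic stage consumes a named substream derived from the master
seed, and nothing time- or host-dependent is written.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as bio_io
from .core import PairedCohort, ValidationError, filter_low_depth_pairs, merge_genus_tables
from .diversity import bray_curtis, pcoa, sample_diversity, unweighted_unifrac, upgma_dendrogram
from .rf import (
    RFConfig,
    bootstrap_632plus,
    field_effect_test,
    fit_rf,
    vote_fraction_differences,
)
from .stats import correlation_screen, diversity_comparison, per_taxon_differential

logger = logging.getLogger("biomepair")

__version__ = "0.1.0"


def substream_seed(master_seed: int, name: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the master seed."""
    h = 2166136261
    for ch in f"{master_seed}:{name}".encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h % (2**31 - 1)


@dataclass
class PipelineConfig:
    bacteria_path: Optional[str] = None
    fungi_path: Optional[str] = None
    metadata_path: Optional[str] = None
    tree_path: Optional[str] = None
    out_dir: str = "biomepair_out"
    min_reads: int = 50
    alpha: float = 0.05
    master_seed: int = 0
    rf: RFConfig = field(default_factory=RFConfig)
    run_ordination: bool = True
    run_differential: bool = True
    run_correlation: bool = True
    run_rf: bool = True
    run_bootstrap: bool = False
    field_grouping: str = "t_stage"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass
class RunReport:
    version: str
    config: dict
    stages: dict[str, dict]  # stage name -> summary
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _stage(report: RunReport, name: str, **summary) -> None:
    report.stages[name] = {"status": "complete", **summary}
    logger.info("[%s] complete: %s", name, summary)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: PipelineConfig, cohort: Optional[PairedCohort] = None) -> RunReport:
    """Execute the full analysis; returns the run report (also written to
    ``report.json`` in the output directory).

    A pre-built cohort may be passed directly (e.g. fresh from the
    simulator); otherwise the three TSV paths in the config are loaded.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_echo = dataclasses.asdict(config)
    config_echo.pop("out_dir")  # run-local, not an analysis parameter
    report = RunReport(
        version=__version__,
        config=config_echo,
        stages={},
        warnings=[],
    )
    stage = "load"
    try:
        if cohort is None:
            from .core import build_cohort

            bacteria = bio_io.read_abundance_tsv(config.bacteria_path, "bacteria")
            fungi = bio_io.read_abundance_tsv(config.fungi_path, "fungi")
            metadata = bio_io.read_metadata_tsv(config.metadata_path)
            cohort = build_cohort(bacteria, fungi, metadata)
        _stage(report, "load", n_pairs=cohort.n_pairs, n_samples=len(cohort.paired_samples))

        stage = "filter"
        cohort, removed = filter_low_depth_pairs(cohort, min_reads=config.min_reads)
        if removed:
            report.warnings.append(
                f"removed {len(removed)} pairs below {config.min_reads} bacterial reads: {removed}"
            )
        _stage(report, "filter", n_pairs=cohort.n_pairs, removed_pairs=removed)

        stage = "diversity"
        div_rows = []
        meta = cohort.metadata_frame()
        for kingdom in ("bacteria", "fungi"):
            div = sample_diversity(cohort.table(kingdom))
            for sid, h, s in zip(div.sample_ids, div.shannon, div.richness):
                div_rows.append(
                    {
                        "sample_id": sid,
                        "kingdom": kingdom,
                        "tissue": meta.loc[sid, "tissue"],
                        "shannon": h,
                        "richness": int(s),
                    }
                )
        pd.DataFrame(div_rows).to_csv(out / "diversity.tsv", sep="\t", index=False)
        div_tests = []
        for metric in ("shannon", "richness"):
            for res in diversity_comparison(cohort, metric=metric):
                div_tests.append(dataclasses.asdict(res))
        _write_json(out / "diversity_tests.json", div_tests)
        _stage(report, "diversity", tests=len(div_tests))

        if config.run_ordination:
            stage = "ordination"
            tree = None
            if config.tree_path:
                import skbio

                tree = skbio.TreeNode.read(config.tree_path)
            ord_summaries = {}
            for kingdom in ("bacteria", "fungi"):
                dm = bray_curtis(cohort.table(kingdom))
                bio_io.write_distance_tsv(dm, out / f"braycurtis_{kingdom}.tsv")
                k = min(2, len(dm.sample_ids) - 1)
                ordn = pcoa(dm, k=k)
                pd.DataFrame(
                    ordn.coordinates,
                    index=ordn.sample_ids,
                    columns=[f"PCo{i + 1}" for i in range(k)],
                ).to_csv(out / f"pcoa_braycurtis_{kingdom}.tsv", sep="\t")
                newick, _ = upgma_dendrogram(dm)
                (out / f"upgma_{kingdom}.nwk").write_text(newick + "\n")
                ord_summaries[kingdom] = {
                    "variance_explained": [float(v) for v in ordn.proportion_explained]
                }
                if tree is not None and kingdom == "bacteria":
                    udm = unweighted_unifrac(cohort.table(kingdom), tree)
                    bio_io.write_distance_tsv(udm, out / f"unifrac_{kingdom}.tsv")
            _stage(report, "ordination", **ord_summaries)

        n_sig_genus = None
        if config.run_differential:
            stage = "differential"
            diff_summary = {}
            for rank in ("phylum", "genus"):
                results = per_taxon_differential(cohort, rank=rank)
                rows = [
                    {
                        "taxon_id": r.lineage.taxon_id,
                        "kingdom": r.lineage.kingdom,
                        "phylum": r.lineage.phylum,
                        "genus": r.lineage.genus,
                        "mean_tumor": r.group_means.get("tumor"),
                        "mean_nontumor": r.group_means.get("nontumor"),
                        "h": r.h_statistic,
                        "p_raw": r.p_raw,
                        "p_adjusted": r.p_adjusted,
                        "direction": r.direction,
                    }
                    for r in results
                ]
                pd.DataFrame(rows).to_csv(out / f"differential_{rank}.tsv", sep="\t", index=False)
                n_sig = sum(r.p_adjusted < config.alpha for r in results)
                diff_summary[rank] = {"tested": len(results), "significant": n_sig}
                if rank == "genus":
                    n_sig_genus = n_sig
            _stage(report, "differential", **diff_summary)

        if config.run_correlation:
            stage = "correlation"
            corr_summary = {}
            for scope in ("intra-bacteria", "intra-fungi", "inter-kingdom"):
                res = correlation_screen(cohort, tissue="tumor", scope=scope)
                tidy = res.tidy()
                tidy.to_csv(out / f"correlation_{scope}.tsv", sep="\t", index=False)
                corr_summary[scope] = {
                    "pairs": int(len(tidy)),
                    "significant": int((tidy["p_adjusted"] < config.alpha).sum()),
                }
            _stage(report, "correlation", **corr_summary)

        fit = None
        if config.run_rf:
            stage = "rf"
            features, _ = merge_genus_tables(cohort)
            labels = meta.loc[features.index, "tissue"].to_numpy()
            rf_cfg = RFConfig(**{**vars(config.rf), "seed": substream_seed(config.master_seed, "rf")})
            fit = fit_rf(features, labels, rf_cfg, compute_importance=True)
            fit.votes().rename("vote_fraction").to_csv(out / "votes.tsv", sep="\t")
            fit.importance.rename("mean_decrease_accuracy").sort_values(
                ascending=False
            ).to_csv(out / "importance.tsv", sep="\t")
            _write_json(
                out / "rf_fit.json",
                {"oob_error": fit.oob_error, "n_features": len(fit.feature_names)},
            )
            _stage(report, "rf", oob_error=fit.oob_error, n_features=len(fit.feature_names))

            if config.run_bootstrap:
                stage = "bootstrap"
                boot_cfg = RFConfig(
                    **{**vars(config.rf), "seed": substream_seed(config.master_seed, "bootstrap")}
                )
                ev = bootstrap_632plus(features, labels, boot_cfg, with_selection=False)
                _write_json(
                    out / "bootstrap_632plus.json",
                    {
                        "err_apparent": ev.err_apparent,
                        "err_loo_bootstrap": ev.err_loo_bootstrap,
                        "gamma": ev.gamma,
                        "relative_overfitting": ev.relative_overfitting,
                        "weight": ev.weight,
                        "err_632plus": ev.err_632plus,
                    },
                )
                _stage(report, "bootstrap", err_632plus=ev.err_632plus)

            stage = "field_effect"
            vd = vote_fraction_differences(fit, cohort)
            vd.frame().to_csv(out / "vote_differences.tsv", sep="\t", index=False)
            try:
                fe = field_effect_test(vd, cohort, grouping=config.field_grouping)
                _write_json(
                    out / "field_effect.json",
                    {
                        "grouping": fe.grouping,
                        "group_means": fe.group_means,
                        "group_sizes": fe.group_sizes,
                        "statistic": fe.statistic,
                        "p_value": fe.p_value,
                        "method": fe.method,
                    },
                )
                _stage(
                    report,
                    "field_effect",
                    group_means=fe.group_means,
                    p_value=fe.p_value,
                    mean_d=float(np.mean(vd.d)),
                )
            except ValidationError as exc:
                report.warnings.append(f"field_effect skipped: {exc}")
                report.stages["field_effect"] = {"status": "skipped", "reason": str(exc)}
    except ValidationError as exc:
        report.stages[stage] = {"status": "failed", "error": str(exc)}
        (out / "report.json").write_text(report.to_json() + "\n")
        raise ValidationError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(report.to_json() + "\n")
    (out / "report.md").write_text(render_report(report))
    return report


def render_report(report: RunReport) -> str:
    """Human-readable markdown mirroring the analysis order."""
    lines = [
        "# Paired-cohort microbiome analysis report",
        "",
        f"Pipeline version {report.version}, master seed "
        f"{report.config.get('master_seed')}.",
        "",
    ]
    titles = {
        "load": "Cohort",
        "filter": "Depth filtering",
        "diversity": "Diversity and richness",
        "ordination": "Ordination and clustering",
        "differential": "Differential abundance",
        "correlation": "Correlation screens",
        "rf": "Random-forest classification",
        "bootstrap": "0.632+ bootstrap error",
        "field_effect": "Paired vote-fraction differences",
    }
    for name, title in titles.items():
        if name not in report.stages:
            continue
        info = report.stages[name]
        lines.append(f"## {title}")
        lines.append("")
        status = info.get("status", "complete")
        if status != "complete":
            lines.append(f"_{status}_: {info.get('reason', info.get('error', ''))}")
            lines.append("")
            continue
        for key, val in sorted(info.items()):
            if key == "status":
                continue
            lines.append(f"- {key}: {val}")
        lines.append("")
    if report.warnings:
        lines.append("## Warnings")
        lines.append("")
        lines.extend(f"- {w}" for w in report.warnings)
        lines.append("")
    return "\n".join(lines)
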