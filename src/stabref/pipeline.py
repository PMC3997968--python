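"""End-to-end orchestration of the discovery and validation arms.

``run_discovery`` takes a raw count table through normalization,
slope-1 fold changes, stability filtering per condition, cross-condition
intersection and abundance tiering.  ``run_validation`` takes Cq panels
and dilution series through replicate collapse, efficiency fitting,
efficiency-corrected relative quantification and the full geNorm suite.
Both write TSV/JSON reports plus a manifest (config snapshot, seed, stage
timings, output checksums) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import genorm, io as sio, qpcr, seq_stability as seq
from .config import Config

logger = logging.getLogger("stabref")

__all__ = ["DiscoveryResult", "ValidationResult", "run_discovery", "run_validation"]


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _staged(stage: str, timings: dict, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        out = fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc
    timings[stage] = time.perf_counter() - t0
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, inputs: dict, config: Config, timings: dict) -> None:
    outputs = {
        p.name: _sha256(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "inputs": inputs,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_timings_s": {k: round(v, 6) for k, v in timings.items()},
        "output_sha256": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class DiscoveryResult:
    normalized: seq.NormalizedCountMatrix
    reports: dict[str, seq.StabilityReport]
    intersection: seq.ConditionIntersection
    tiers: dict[str, dict[str, frozenset[str]]]  # per condition


def run_discovery(
    counts: seq.RawCountMatrix | str | Path,
    config: Config = Config(),
    out_dir: str | Path | None = None,
) -> DiscoveryResult:
    """Count table → normalized matrix → per-condition stable sets →
    intersection → abundance tiers, with reports written under ``out_dir``."""
    timings: dict[str, float] = {}
    inputs: dict = {}
    if not isinstance(counts, seq.RawCountMatrix):
        path = Path(counts)
        inputs["count_table"] = {"path": str(path), "sha256": _sha256(path)}
        counts = _staged(
            "read_counts", timings, sio.read_count_table, path, config.decimal_comma
        )
    norm = _staged("normalize", timings, seq.normalize_counts, counts, config.pseudocount)
    design = config.resolve_comparisons(norm.sample_ids)

    reports: dict[str, seq.StabilityReport] = {}
    for condition, pairs in design.items():
        report = _staged(
            f"filter[{condition}]",
            timings,
            seq.filter_stable,
            norm,
            pairs,
            config.var_threshold_pct,
            config.min_reads,
            config.variation_metric,
            condition,
        )
        logger.info(
            "condition %s: %d/%d miRNAs stable (threshold %.3g%%, floor %.3g reads)",
            condition, len(report.passed), len(norm.mirna_ids),
            config.var_threshold_pct, config.min_reads,
        )
        reports[condition] = report

    if len(reports) >= 2:
        intersection = _staged("intersect", timings, seq.intersect_conditions, reports)
    else:
        only = next(iter(reports.values()))
        intersection = seq.ConditionIntersection(
            per_condition={c: r.passed for c, r in reports.items()},
            all_conditions=only.passed,
            venn_partition={next(iter(reports)): only.passed},
        )
    logger.info("stable in all conditions: %d miRNAs", len(intersection.all_conditions))

    tiers = {
        condition: _staged(
            f"tier[{condition}]",
            timings,
            seq.tier_by_abundance,
            norm,
            sorted(reports[condition].passed),
            config.tier_boundaries,
            sorted({s for pair in design[condition] for s in pair}),
        )
        for condition in reports
        if reports[condition].passed
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for condition, report in reports.items():
            sio.write_stability_report(
                report, out / f"stability_{condition}.tsv", out / f"stability_{condition}.json"
            )
        sio.write_intersection(intersection, out / "venn.tsv", out / "venn.json")
        (out / "tiers.json").write_text(
            json.dumps(
                {c: {t: sorted(m) for t, m in tmap.items()} for c, tmap in tiers.items()},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        _write_manifest(out, inputs, config, timings)
    return DiscoveryResult(
        normalized=norm, reports=reports, intersection=intersection, tiers=tiers
    )


@dataclass(frozen=True)
class ValidationResult:
    efficiencies: dict[str, qpcr.EfficiencyFit]
    quantities: qpcr.RelativeQuantityMatrix
    ranking: genorm.StabilityRanking
    v_series: genorm.PairwiseVariationSeries
    m_final: pd.Series  # stage-0 M per gene
    m_pass: pd.Series
    cv: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "efficiency_pct": {g: f.efficiency_pct for g, f in self.efficiencies.items()},
            "r_squared": {g: f.r_squared for g, f in self.efficiencies.items()},
            "m_values": {k: float(v) for k, v in self.m_final.items()},
            "m_pass": {k: bool(v) for k, v in self.m_pass.items()},
            "m_by_stage": [
                {k: float(v) for k, v in stage.items()} for stage in self.ranking.m_by_stage
            ],
            "exclusion_order": list(self.ranking.exclusion_order),
            "final_pair": list(self.ranking.final_pair),
            "v_values": {str(n): v for n, v in self.v_series.v_values.items()},
            "recommended_n": self.v_series.recommended_n,
            "cv": {k: float(v) for k, v in self.cv.items()},
        }


def run_validation(
    cq: qpcr.CqPanel | str | Path,
    dilutions: Mapping[str, qpcr.DilutionSeries] | str | Path,
    config: Config = Config(),
    out_dir: str | Path | None = None,
) -> ValidationResult:
    """Cq panel + dilution series → efficiencies → relative quantities →
    geNorm M/V/CV report."""
    timings: dict[str, float] = {}
    inputs: dict = {}
    if not isinstance(cq, qpcr.CqPanel):
        path = Path(cq)
        inputs["cq_table"] = {"path": str(path), "sha256": _sha256(path)}
        cq = _staged("read_cq", timings, sio.read_cq_table, path)
    if not isinstance(dilutions, Mapping):
        path = Path(dilutions)
        inputs["dilution_table"] = {"path": str(path), "sha256": _sha256(path)}
        dilutions = _staged("read_dilutions", timings, sio.read_dilution_table, path)

    panel_genes = set(cq.genes)
    dilution_genes = set(dilutions)
    if not panel_genes <= dilution_genes:
        raise StageError(
            "gene_coverage",
            ValueError(f"Cq genes without dilution series: {sorted(panel_genes - dilution_genes)}"),
        )

    collapsed = _staged("collapse_replicates", timings, qpcr.collapse_replicates, cq)
    fits = {
        g: _staged(f"fit_efficiency[{g}]", timings, qpcr.fit_efficiency,
                   dilutions[g], config.min_dilutions)
        for g in sorted(panel_genes)
    }
    rq = _staged(
        "relative_quantities", timings, qpcr.relative_quantities, collapsed, fits, config.ref_cq
    )
    ranking = _staged("stepwise_rank", timings, genorm.stepwise_rank, rq)
    v_series = _staged(
        "pairwise_variation", timings, genorm.pairwise_variation, rq, ranking, config.v_cutoff
    )
    m_final = ranking.m_by_stage[0]
    m_pass = genorm.classify_m(m_final, config.m_cutoff)
    nf = genorm.normalization_factor(rq, ranking.ranked[: v_series.recommended_n])
    cv = _staged("cv", timings, genorm.coefficient_of_variation, rq, nf)
    logger.info(
        "geNorm: final pair %s, recommended_n=%d, %d/%d genes below M cut-off %.2f",
        ranking.final_pair, v_series.recommended_n, int(m_pass.sum()), len(m_pass),
        config.m_cutoff,
    )

    result = ValidationResult(
        efficiencies=fits, quantities=rq, ranking=ranking, v_series=v_series,
        m_final=m_final, m_pass=m_pass, cv=cv,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sio.write_efficiency_table(fits, out / "efficiencies.csv")
        sio.write_quantity_matrix(rq, out / "relative_quantities.tsv")
        (out / "genorm.json").write_text(json.dumps(result.to_json_dict(), indent=2) + "\n")
        if config.make_plots:
            from .plotting import plot_m_series, plot_v_series

            plot_m_series(ranking, out / "m_values.svg")
            plot_v_series(v_series, out / "v_series.svg")
        _write_manifest(out, inputs, config, timings)
    return result
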