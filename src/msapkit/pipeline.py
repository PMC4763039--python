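"""Pipeline orchestration: score, compare, test and report from one config.

The pipeline composes the module operations with no hidden state: its
output equals calling :func:`msapkit.scoring.summarize_sample`,
:func:`msapkit.patterns.summarize_comparison` and
:func:`msapkit.stats.pearson_chi_square` by hand.  The report carries a
provenance block (input paths and checksums, config, seed, package
version) from which every number is recomputable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Union

import yaml

from . import __version__
from .bisulfite import call_methylation, methylation_percentage, read_locus_fasta
from .core import BandMatrix, BandMatrixError, parse_sample_label, read_band_matrix
from .patterns import ComparisonSummary, summarize_comparison
from .scoring import MethylationSummary, pool_summaries, round_half_up, summarize_sample
from .stats import ContingencyResult, ContingencyTable, pearson_chi_square

__all__ = ["AnalysisReport", "run_pipeline", "reproduce_study_tables"]


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class AnalysisReport:
    """Machine-readable result of one pipeline run."""

    summaries: List[MethylationSummary]
    pooled: List[MethylationSummary]
    comparisons: List[ComparisonSummary]
    chi_square: Dict[str, ContingencyResult]
    bisulfite: Dict[str, dict]
    provenance: Dict[str, object]

    def to_dict(self) -> dict:
        def summary_row(s: MethylationSummary) -> dict:
            return {
                "label": s.label,
                "n_I": s.n_I, "n_II": s.n_II, "n_III": s.n_III, "n_IV": s.n_IV,
                "n_total": s.n_total,
                "pct_total_methylation": s.pct_total_methylation,
                "pct_fully_methylated": s.pct_fully_methylated,
                "pct_hemi_methylated": s.pct_hemi_methylated,
                "rounded": s.rounded(),
            }

        def comparison_row(c: ComparisonSummary) -> dict:
            return {
                "label": c.label,
                "control": c.control_sample,
                "treatment": c.treatment_sample,
                "n_class": c.n_class,
                "n_group": c.n_group,
                "n_total": c.n_total,
                "pct_group": c.pct_group,
                "pct_group_rounded": c.pct_group_rounded(),
            }

        return {
            "summaries": [summary_row(s) for s in self.summaries],
            "pooled": [summary_row(s) for s in self.pooled],
            "comparisons": [comparison_row(c) for c in self.comparisons],
            "chi_square": {
                name: {
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_value": r.p_value,
                    "statistic_rounded": round_half_up(r.statistic, 2),
                    "p_value_rounded": round_half_up(r.p_value, 3),
                    "dropped": r.dropped,
                }
                for name, r in self.chi_square.items()
            },
            "bisulfite": self.bisulfite,
            "provenance": self.provenance,
        }

    def write_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")


def _load_config(config: Union[str, dict]) -> dict:
    if isinstance(config, dict):
        return dict(config)
    with open(config, "r", encoding="utf-8") as handle:
        loaded = yaml.safe_load(handle)
    if not isinstance(loaded, dict):
        raise ValueError("pipeline config must be a mapping")
    loaded.setdefault("_config_path", str(config))
    return loaded


def _condition_pools(
    summaries: List[MethylationSummary],
) -> List[MethylationSummary]:
    by_condition: Dict[str, List[MethylationSummary]] = {}
    for summary in summaries:
        try:
            label = parse_sample_label(summary.label)
        except ValueError:
            continue
        by_condition.setdefault(label.condition, []).append(summary)
    return [
        pool_summaries(members, condition)
        for condition, members in by_condition.items()
        if members
    ]


def _stage_chi_square(
    summaries: List[MethylationSummary],
) -> Dict[str, ContingencyResult]:
    """Band-type x condition chi-square per stage (and pooled) for every
    stage observed under both conditions."""
    labelled: Dict[str, Dict[str, MethylationSummary]] = {}
    for summary in summaries:
        try:
            label = parse_sample_label(summary.label)
        except ValueError:
            continue
        labelled.setdefault(label.stage, {})[label.condition] = summary

    def table(pairs: List[MethylationSummary]) -> ContingencyTable:
        return ContingencyTable(
            row_labels=["I", "II", "III", "IV"],
            col_labels=[s.label for s in pairs],
            cells=[[s.n_I for s in pairs], [s.n_II for s in pairs],
                   [s.n_III for s in pairs], [s.n_IV for s in pairs]],
        )

    results: Dict[str, ContingencyResult] = {}
    complete = {
        stage: conds for stage, conds in labelled.items()
        if set(conds) == {"high_chill", "low_chill"}
    }
    for stage, conds in complete.items():
        results[stage] = pearson_chi_square(
            table([conds["high_chill"], conds["low_chill"]])
        )
    if len(complete) > 1:
        pools = _condition_pools(
            [s for conds in complete.values() for s in conds.values()]
        )
        pools.sort(key=lambda s: s.label)  # high_chill before low_chill
        if len(pools) == 2:
            results["pooled"] = pearson_chi_square(table(pools))
    return results


def _bisulfite_block(fasta_path: str) -> Dict[str, dict]:
    out: Dict[str, dict] = {}
    for locus, records in read_locus_fasta(fasta_path).items():
        refs = records.get("ref")
        if not refs:
            raise ValueError(f"locus {locus!r}: no reference record (sample field 'ref')")
        reference = refs[0]
        per_sample: Dict[str, dict] = {}
        for sample, clones in records.items():
            if sample == "ref":
                continue
            calls = []
            for clone in clones:
                calls.extend(call_methylation(reference, clone))
            summary = methylation_percentage(calls)
            per_sample[sample] = {
                "n_clones": len(clones),
                "n_methylated": summary.n_methylated,
                "n_total": summary.n_total,
                "n_undetermined": summary.n_undetermined,
                "n_ambiguous": summary.n_ambiguous,
                "pct_methylated": summary.pct_methylated,
                "pct_by_context": summary.pct_by_context(),
            }
        out[locus] = per_sample
    return out


def run_pipeline(config: Union[str, dict]) -> AnalysisReport:
    """Run score -> compare -> test from a config mapping or YAML path.

    Config keys: ``matrix`` (band-matrix TSV, required), ``comparisons``
    (list of ``{control, treatment}`` pairs), ``exclude_samples`` (ids to
    score around but not report, e.g. simulation anchors), ``bisulfite``
    (``{fasta: path}``), ``seed``.  Sample ids following the
    ``<stage><H|L>`` convention are pooled by condition and tested per
    stage automatically.  Fails before producing output when a comparison
    names an unknown sample.
    """
    cfg = _load_config(config)
    matrix_path = cfg.get("matrix")
    if not matrix_path:
        raise ValueError("config must name a band matrix under 'matrix'")
    matrix = read_band_matrix(matrix_path)
    matrix.require_complete()
    exclude = set(cfg.get("exclude_samples", []))
    comparisons_cfg = cfg.get("comparisons", [])
    for pair in comparisons_cfg:
        for role in ("control", "treatment"):
            if pair[role] not in matrix.samples:
                raise BandMatrixError(
                    f"comparison names unknown sample {pair[role]!r}"
                )
    report_samples = [s for s in matrix.samples if s not in exclude]
    summaries = [summarize_sample(matrix, s) for s in report_samples]
    pooled = _condition_pools(summaries)
    chi_square = _stage_chi_square(summaries)
    comparisons = [
        summarize_comparison(matrix, pair["control"], pair["treatment"])
        for pair in comparisons_cfg
    ]
    bisulfite: Dict[str, dict] = {}
    if cfg.get("bisulfite"):
        bisulfite = _bisulfite_block(cfg["bisulfite"]["fasta"])
    inputs = {"matrix": {"path": str(matrix_path), "sha256": _sha256(str(matrix_path))}}
    if cfg.get("bisulfite"):
        fasta = cfg["bisulfite"]["fasta"]
        inputs["bisulfite_fasta"] = {"path": str(fasta), "sha256": _sha256(str(fasta))}
    provenance = {
        "inputs": inputs,
        "config": {k: v for k, v in cfg.items() if k != "_config_path"},
        "config_path": cfg.get("_config_path"),
        "seed": cfg.get("seed"),
        "version": __version__,
    }
    return AnalysisReport(summaries, pooled, comparisons, chi_square, bisulfite, provenance)


def reproduce_study_tables() -> dict:
    """Recompute the study's summary tables from the packaged count
    fixtures, end-to-end through the matrix-level pipeline.

    Each sample's (and each comparison's) counts are expanded into a
    synthetic band matrix, scored or classified by the ordinary operations,
    pooled by condition and chi-square tested.  Returns a dict with
    ``summaries`` (per sample), ``pooled`` (per condition),
    ``chi_square`` (per stage and pooled) and ``comparisons``.
    """
    from . import datasets

    summaries = {
        sample: summarize_sample(datasets.sample_band_matrix(sample), sample)
        for sample in datasets.SAMPLES
    }
    pooled = {
        condition: pool_summaries(
            [summaries[s] for s in datasets.SAMPLES if s.endswith(suffix)], condition
        )
        for condition, suffix in (("high_chill", "H"), ("low_chill", "L"))
    }
    chi_square = {
        stage: pearson_chi_square(datasets.band_type_contingency(stage))
        for stage in (*datasets.STAGES, "pooled")
    }
    comparisons = {}
    for name in datasets.COMPARISONS:
        treatment, control = name.split("-vs-")
        comparisons[name] = summarize_comparison(
            datasets.comparison_band_matrix(name), control, treatment
        )
    return {
        "summaries": summaries,
        "pooled": pooled,
        "chi_square": chi_square,
        "comparisons": comparisons,
    }
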