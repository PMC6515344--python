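"""End-to-end orchestration: simulate -> quantify -> qPCR -> biomarker.

`run_pipeline` executes the whole analysis on a simulated cohort (or on
user-supplied tables for the individual stages, via the CLI), writes
every intermediate and final table as TSV, and emits a JSON run
manifest (config snapshot, seed, file digests, per-stage row counts)
plus a human-readable markdown report. A fixed config and seed
reproduce every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from circlin import biomarker as bm
from circlin import io as cio
from circlin import quant, stats
from circlin.simulate import (
    DEFAULT_SPLICING_EVENTS,
    SimulationConfig,
    simulate_cohort,
    simulate_ct_matrix,
    simulate_splicing_table,
)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_from_dict(d: dict) -> SimulationConfig:
    sim = dict(d.get("simulation", {}))
    if "lib_size_range" in sim:
        sim["lib_size_range"] = tuple(sim["lib_size_range"])
    return SimulationConfig(**sim)


def run_pipeline(
    config: SimulationConfig | dict | None = None,
    out_dir: str | Path = "circlin_run",
    seed: int | None = None,
    q: float = 0.01,
    min_presence: float = 0.7,
    presence_mode: str = "either",
    n_null_targets: int = 4,
) -> dict:
    """Run the full simulated-cohort analysis into ``out_dir``.

    Stages: cohort simulation; per-million normalization and presence
    filtering of back-splice counts; circular-to-linear ratio matrix
    with candidate intersection; qPCR simulation for the planted genes
    plus ``n_null_targets`` unmodulated genes; differential circular
    fractions (two-group tests, two-stage FDR at ``q``); score, per
    feature and score ROC; correlations with MRC and splicing
    covariates; MIRS stage comparison. Returns a results dict and
    writes tables, ``manifest.json`` and ``report.md``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts_log: dict[str, int] = {}

    # --- stage: simulate ------------------------------------------------
    try:
        if config is None:
            config = SimulationConfig()
        elif isinstance(config, dict):
            config = _config_from_dict(config)
        if seed is not None:
            config = dataclasses.replace(config, seed=int(seed))
        bs_table, linear, metadata, truth = simulate_cohort(config)
    except Exception as exc:
        raise StageError(f"simulate: {exc}") from exc
    counts_log["events_simulated"] = len(bs_table.events)
    cio.write_junction_counts(bs_table, out / "backsplice_counts.tsv")
    cio.write_linear_junctions(linear, out / "linear_junctions.tsv")
    cio.write_metadata(metadata, out / "metadata.tsv")

    # --- stage: quantify ------------------------------------------------
    try:
        filtered = quant.presence_filter(bs_table, metadata, min_presence, presence_mode)
        norm = quant.normalize_per_million(filtered)
        linear_norm = quant.normalize_linear_per_million(linear, norm.lib_sizes)
        rmat = quant.ratio_matrix(norm, linear_norm, metadata)
    except Exception as exc:
        raise StageError(f"quantify: {exc}") from exc
    counts_log["events_after_filter"] = len(filtered.events)
    counts_log["events_removed"] = len(bs_table.events) - len(filtered.events)

    # candidate intersection: the qPCR validation panel (planted genes
    # plus unmodulated ones), expressed as gene-level candidates
    tp = sorted(truth.true_positive_ids)
    nulls = [g for g in truth.baseline_expression.index if g not in truth.true_positive_ids]
    targets = tp + nulls[: n_null_targets]
    candidates, _ = quant.intersect_candidates(filtered.events, set(targets))
    counts_log["candidate_events"] = len(candidates)

    ratio_summary = rmat.summaries.copy()
    ratio_summary["high_ratio"] = ratio_summary[["mean_case", "mean_control"]].max(axis=1) > 0.5
    counts_log["events_ratio_gt_0p5"] = int(ratio_summary["high_ratio"].sum())
    cio.write_results(ratio_summary, out / "ratio_summary.tsv", index=True)
    cio.write_results(rmat.values, out / "ratio_matrix.tsv", index=True)

    # --- stage: qpcr ----------------------------------------------------
    try:
        ct = simulate_ct_matrix(config, truth, targets)
        cio.write_ct_table(ct, out / "ct_table.tsv")
        fractions = stats.circ_fraction(ct)
        frac_matrix = fractions.pivot(index="target_id", columns="sample_id",
                                      values="log2_fraction")
        diff = stats.differential_analysis(frac_matrix, metadata, q=q)
    except Exception as exc:
        raise StageError(f"qpcr: {exc}") from exc
    counts_log["features_tested"] = len(diff)
    counts_log["features_significant"] = int(diff["q_flag"].sum())
    cio.write_results(diff, out / "differential.tsv")

    # --- stage: biomarker ----------------------------------------------
    try:
        significant = list(diff.loc[diff["q_flag"], "feature_id"])
        results: dict = {
            "config": dataclasses.asdict(config),
            "counts": counts_log,
            "true_positive_ids": tp,
            "significant_features": significant,
        }
        splicing = simulate_splicing_table(config, truth, DEFAULT_SPLICING_EVENTS)
        cio.write_splicing_table(splicing, out / "splicing_table.tsv")
        splice_pct = bm.exon_exclusion_percent(splicing)
        if significant:
            score = bm.circ_lin_score(frac_matrix, significant, metadata)
            roc_rows = []
            for fid in significant:
                feat_curve = bm.roc_auc(frac_matrix.loc[fid].dropna(), metadata)
                roc_rows.append({"feature_id": fid, "auc": feat_curve.auc,
                                 "n_case": feat_curve.n_pos, "n_control": feat_curve.n_neg})
            score_curve = bm.roc_auc(score.scores, metadata)
            roc_rows.append({"feature_id": "circ_lin_score", "auc": score_curve.auc,
                             "n_case": score_curve.n_pos, "n_control": score_curve.n_neg})
            roc_table = pd.DataFrame(roc_rows)
            cio.write_results(roc_table, out / "roc_auc.tsv")
            cio.write_results(
                pd.DataFrame({"threshold": score_curve.thresholds,
                              "sensitivity": score_curve.sensitivity,
                              "specificity": score_curve.specificity}),
                out / "roc_curve_score.tsv",
            )

            covariates = metadata.set_index("sample_id")[["mrc_megascore"]].astype(float)
            spl_wide = splice_pct.pivot(index="sample_id", columns="event_name",
                                        values="percent")
            covariates = covariates.join(spl_wide)
            value_rows = frac_matrix.loc[significant].copy()
            value_rows.loc["circ_lin_score"] = score.scores
            correlations = bm.correlate_with_covariates(value_rows, covariates)
            cio.write_results(correlations, out / "correlations.tsv")
            mirs = bm.mirs_group_compare(score.scores, metadata)
            cio.write_results(score.scores.rename("score").to_frame(), out / "score.tsv",
                              index=True)
            results.update(
                score_auc=score_curve.auc,
                feature_aucs={r["feature_id"]: r["auc"] for r in roc_rows},
                mirs_compare=mirs,
                correlations=correlations,
            )
        else:
            logger.info("run_pipeline: no significant features; score not computed")
            results.update(score_auc=None, feature_aucs={}, mirs_compare=None,
                           correlations=None)
    except Exception as exc:
        raise StageError(f"biomarker: {exc}") from exc

    # --- manifest and report -------------------------------------------
    manifest = {
        "tool": "circlin",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stage_counts": counts_log,
        "files": {p.name: _digest(p) for p in sorted(out.glob("*.tsv"))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    (out / "report.md").write_text(render_report(results))
    results["manifest"] = manifest
    return results


def render_report(results: dict) -> str:
    """Human-readable markdown summary of one pipeline run."""
    c = results["counts"]
    lines = [
        "# circlin run report",
        "",
        "## RNA-seq arm",
        f"- back-splice events simulated: {c['events_simulated']}",
        f"- events surviving the presence filter: {c['events_after_filter']} "
        f"(removed: {c['events_removed']})",
        f"- candidate-panel events: {c['candidate_events']}",
        f"- events with circular-to-linear ratio > 0.5: {c['events_ratio_gt_0p5']}",
        "",
        "## qPCR arm",
        f"- circular fractions tested: {c['features_tested']}",
        f"- significant at the FDR cut-off: {c['features_significant']}",
    ]
    if results.get("score_auc") is None:
        lines += ["", "no significant features; score not computed"]
    else:
        lines += ["", "## Biomarker"]
        for fid, auc in results["feature_aucs"].items():
            lines.append(f"- AUC[{fid}] = {auc:.3f}")
        mirs = results["mirs_compare"]
        lines += [
            f"- MIRS high (4-5) vs low (1-3) score means: "
            f"{mirs['mean_high']:.3f} vs {mirs['mean_low']:.3f} (p = {mirs['p_value']:.3g})",
            "",
            "## Correlations",
        ]
        corr = results["correlations"]
        for _, row in corr.iterrows():
            if row["flag"] == "ok":
                lines.append(
                    f"- {row['feature_id']} vs {row['covariate']}: "
                    f"r = {row['r']:.3f}, p = {row['p_value']:.3g}, n = {row['n']}"
                )
            else:
                lines.append(
                    f"- {row['feature_id']} vs {row['covariate']}: {row['flag']} (n = {row['n']})"
                )
    return "\n".join(lines) + "\n"
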