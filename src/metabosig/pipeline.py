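"""End-to-end orchestration: preprocess -> differential -> enrichment -> network.

``run_pipeline`` executes the full stage sequence per tissue from a
:class:`RunConfig`, writes every figure-ready table as TSV plus one JSON
run summary (counts, thresholds, seeds, versions), and is byte-identical
under re-runs with the same config.  ``make_report`` renders a
human-readable markdown summary from a completed run directory.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, differential, enrichment, io, network, preprocess

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class TissueInput:
    matrix: str
    metadata: str
    exclude: tuple = ()


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Inputs, thresholds and seeds for one full pipeline run."""

    tissues: dict  # tissue -> TissueInput
    annotations: str
    outdir: str
    edges: str | None = None
    p_threshold: float = differential.P_THRESHOLD
    fc_threshold: float = differential.FC_THRESHOLD
    zscore_threshold: float = enrichment.ZSCORE_THRESHOLD
    ev_threshold: float = enrichment.EV_THRESHOLD
    min_dms: int = enrichment.MIN_DMS
    zscore_denominator: str = "sqrt"
    min_edge_score: int = network.HIGH_CONFIDENCE
    top_hubs: int = network.TOP_K
    msea_n_perm: int = 1000
    msea_seed: int = 17
    min_observed: int = 2

    def __post_init__(self) -> None:
        for name in ("p_threshold", "fc_threshold", "zscore_threshold", "ev_threshold"):
            if getattr(self, name) <= 0:
                raise io.StudyValidationError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        tissues = {
            t: TissueInput(
                matrix=v["matrix"],
                metadata=v["metadata"],
                exclude=tuple(v.get("exclude", ())),
            )
            for t, v in d.pop("tissues").items()
        }
        return cls(tissues=tissues, **d)

    def thresholds(self) -> dict:
        return {
            "p_threshold": self.p_threshold,
            "fc_threshold": self.fc_threshold,
            "zscore_threshold": self.zscore_threshold,
            "ev_threshold": self.ev_threshold,
            "min_dms": self.min_dms,
            "zscore_denominator": self.zscore_denominator,
            "min_edge_score": self.min_edge_score,
            "top_hubs": self.top_hubs,
            "msea_n_perm": self.msea_n_perm,
            "msea_seed": self.msea_seed,
            "min_observed": self.min_observed,
        }


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and tissue."""


def _stage(name: str, tissue: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed for tissue {tissue!r}: {exc}") from exc
    logger.info("stage %s (%s): %.2fs", name, tissue, time.perf_counter() - t0)
    return result


def run_tissue(
    config: RunConfig, tissue: str, annotations: pd.DataFrame, edges: pd.DataFrame | None, outdir: Path
) -> dict:
    """All per-tissue stages; writes artifacts and returns summary counts."""
    ti = config.tissues[tissue]
    tdir = outdir / tissue
    tdir.mkdir(parents=True, exist_ok=True)

    study = _stage("read", tissue, io.read_peak_area_study, ti.matrix, ti.metadata, tissue)
    study = _stage("exclusions", tissue, io.apply_exclusions, study, ti.exclude)
    norm = _stage("preprocess", tissue, preprocess.normalize, study, config.min_observed)
    io.write_table(norm.imputed, tdir / "normalized.tsv")
    io.write_table(norm.imputed_mask.astype(int), tdir / "imputed_mask.tsv")

    results = _stage(
        "differential", tissue, differential.run_differential,
        norm, config.p_threshold, config.fc_threshold,
    )
    io.write_table(results, tdir / "dms.tsv")
    volcano = pd.DataFrame(
        {
            "log2_fold_change": results["log2_fold_change"],
            "neg_log10_p": -np.log10(results["p_value"].clip(lower=1e-300)),
            "direction": results["direction"],
            "is_dm": results["is_dm"],
        }
    )
    io.write_table(volcano, tdir / "volcano.tsv")
    dm_ids, summary = differential.call_dms(results, tissue, config.p_threshold, config.fc_threshold)

    scores, variances = _stage("pca", tissue, differential.pca_overview, norm.logged)
    io.write_table(scores, tdir / "pca_scores.tsv")
    io.write_table(
        pd.DataFrame(
            {"explained_variance": variances},
            index=pd.Index(scores.columns, name="component"),
        ),
        tdir / "pca_variance.tsv",
    )

    leaf_order = None
    if len(dm_ids) >= 2:
        _, leaf_order = _stage(
            "clustering", tissue, differential.hierarchical_clustering, norm.logged.loc[dm_ids]
        )

    pathways = _stage(
        "pathway_scores", tissue, enrichment.score_all_pathways,
        results, annotations,
        config.zscore_threshold, config.ev_threshold, config.min_dms, config.zscore_denominator,
    )
    io.write_table(pathways, tdir / "pathways.tsv")
    if not pathways.empty:
        quadrant = pathways[["enrichment_value", "zscore", "k", "is_signature"]].copy()
        quadrant["abs_zscore"] = quadrant["zscore"].abs()
        io.write_table(quadrant, tdir / "quadrant.tsv")

    sets = enrichment.pathway_sets(annotations, background=results.index)
    msea_table = _stage(
        "msea", tissue, enrichment.msea,
        enrichment.rank_statistic(results), sets,
        config.msea_n_perm, config.msea_seed, 1.0, dm_ids,
    )
    io.write_table(msea_table, tdir / "msea.tsv")

    n_hub_nodes = 0
    if edges is not None and dm_ids:
        subnet = _stage("network", tissue, network.build_subnetwork, dm_ids, edges, config.min_edge_score)
        hubs = network.rank_hubs(subnet, top_k=config.top_hubs)
        if not hubs.empty:
            hubs = network.annotate_hub_directions(hubs, results)
        io.write_table(hubs, tdir / "hubs.tsv")
        network.export_graph(subnet, tdir / "network_edges.tsv", tdir / "network_nodes.tsv")
        n_hub_nodes = subnet.n_nodes

    return {
        "summary": summary.as_dict(),
        "excluded_samples": sorted(study.excluded_samples),
        "n_per_group": {g: int(c) for g, c in study.group.value_counts().items()},
        "dropped_metabolites": list(norm.dropped_metabolites),
        "n_imputed_cells": int(norm.imputed_mask.to_numpy().sum()),
        "n_signature_pathways": int(pathways["is_signature"].sum()) if not pathways.empty else 0,
        "n_network_nodes": n_hub_nodes,
        "sample_leaf_order": leaf_order,
        "detected_ids": list(results.index),
        "dm_ids": dm_ids,
        "msea_table": msea_table,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage for every tissue and write the run summary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = io.read_annotations(config.annotations)
    edges = io.read_edge_list(config.edges) if config.edges else None

    per_tissue = {}
    for tissue in config.tissues:
        per_tissue[tissue] = run_tissue(config, tissue, annotations, edges, outdir)

    summary = {
        "version": __version__,
        "thresholds": config.thresholds(),
        "tissues": {
            t: {k: v for k, v in r.items() if k not in ("detected_ids", "dm_ids", "msea_table")}
            for t, r in per_tissue.items()
        },
    }
    if len(per_tissue) >= 2:
        detected = {t: set(r["detected_ids"]) for t, r in per_tissue.items()}
        dms = {t: set(r["dm_ids"]) for t, r in per_tissue.items()}
        summary["venn_detected"] = differential.venn_counts(detected)
        summary["venn_dms"] = differential.venn_counts(dms)
        comparison = enrichment.compare_tissues(
            {t: r["msea_table"] for t, r in per_tissue.items()}, min_dms=config.min_dms
        )
        io.write_table(comparison, outdir / "msea_comparison.tsv")
    io.write_json(summary, outdir / "summary.json")
    return outdir


def make_report(run_dir, top_n: int = 5) -> str:
    """Render a markdown report from a completed run directory.

    Top-ranked DMs are ordered by absolute fold change (descending) then
    p-value (ascending).  An incomplete run lists the missing artifacts
    instead of failing.
    """
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise io.StudyValidationError(f"no summary.json under {run_dir}")
    summary = io.read_json(summary_path)
    lines = ["# Metabolomic pipeline report", ""]
    missing = []
    for tissue, info in summary["tissues"].items():
        s = info["summary"]
        lines += [
            f"## {tissue}",
            "",
            f"- detected metabolites: {s['n_detected']}",
            f"- differential metabolites: {s['n_dm']} "
            f"({s['n_up']} up, {s['n_down']} down; {s['pct_dm']}% of detected)",
            f"- samples per group: {info['n_per_group']}"
            + (f"; excluded: {info['excluded_samples']}" if info["excluded_samples"] else ""),
        ]
        dms_path = run_dir / tissue / "dms.tsv"
        if dms_path.exists():
            results = io.read_table(dms_path)
            results["is_dm"] = results["is_dm"].astype(bool)
            dms = results.loc[results["is_dm"]]
            if len(dms):
                top = dms.sort_values(
                    ["abs_fold_change", "p_value"], ascending=[False, True]
                ).head(top_n)
                lines.append(f"- top-ranked DMs (by abs fold change, then p):")
                for mid, row in top.iterrows():
                    lines.append(
                        f"    - {mid}: FC {row['fold_change']:.3g}, "
                        f"p {row['p_value']:.3g}, {row['direction']}"
                    )
            else:
                lines.append("- no differential metabolites at the configured cutoffs")
        else:
            missing.append(str(dms_path))
        pw_path = run_dir / tissue / "pathways.tsv"
        if pw_path.exists():
            pathways = io.read_table(pw_path)
            if not pathways.empty:
                sig = pathways.loc[pathways["is_signature"].astype(bool)]
                if len(sig):
                    lines.append("- signature pathways (|zscore| and EV above cutoffs, >=min DMs):")
                    for sub, row in sig.sort_values("zscore", ascending=False).iterrows():
                        lines.append(
                            f"    - {sub}: {int(row['k'])} DMs, zscore {row['zscore']:.2f}, "
                            f"EV {row['enrichment_value']:.2f}"
                        )
                else:
                    lines.append("- no signature pathways")
        else:
            missing.append(str(pw_path))
        hubs_path = run_dir / tissue / "hubs.tsv"
        if hubs_path.exists():
            hubs = io.read_table(hubs_path)
            top_hubs = hubs.loc[hubs["is_top"].astype(bool)] if len(hubs) else hubs
            if len(top_hubs):
                lines.append("- top metabolite hubs (betweenness):")
                for mid, row in top_hubs.iterrows():
                    lines.append(
                        f"    - {mid}: betweenness {row['betweenness']:.3g}, "
                        f"degree {int(row['degree'])}"
                        + (f", {row['direction']}" if "direction" in hubs.columns else "")
                    )
        lines.append("")
    if "venn_dms" in summary:
        lines += ["## Cross-tissue overlap (DMs)", ""]
        for region, count in sorted(summary["venn_dms"].items()):
            lines.append(f"- {region}: {count}")
        lines.append("")
    if missing:
        lines += ["## Missing artifacts", ""] + [f"- {m}" for m in missing]
    report = "\n".join(lines).rstrip() + "\n"
    (run_dir / "report.md").write_text(report, encoding="utf-8")
    return report
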