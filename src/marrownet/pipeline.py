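"""Pipeline orchestration: simulate → preprocess → univariate → multilevel →
correlate → network → report, as one reproducible, seeded run.

Every stage writes its artifacts under the run directory and records a
manifest entry (parameters, record counts); identical configuration and
seed give byte-identical numerical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    AnnotationMap,
    ConcentrationTable,
    read_annotation,
    read_concentration_table,
    write_annotation,
    write_concentration_table,
    write_network,
)
from .correlation import correlation_matrix, threshold_counts
from .experiments import recovery_config
from .multilevel import mpca, mplsda, permutation_validate
from .network import (
    EDGE_AMINO,
    EDGE_LIPID,
    aracne_prune,
    build_relevance_network,
    component_summary,
    connected_components,
    enrichment_test,
    fdr_retain,
)
from .panels import panel_annotation
from .preprocess import glog_transform, pqn_normalize, suggest_glog_lambda
from .synthetic import generate_cohort
from .univariate import comparison_frame, compartment_comparison, paired_differences, ratio_features

log = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "univariate", "multilevel", "correlate", "network", "report")


@dataclass
class RunConfig:
    """Full parameterization of a pipeline run.

    Every stochastic stage has an explicit seed derived from ``seed``;
    the config round-trips losslessly through YAML.
    """

    seed: int = 1
    n_patients: int = 10
    missing_rate: float = 0.05
    planted: bool = True
    days: tuple = (0, 29)
    fdr_admit: float = 0.5
    fdr_retain: float = 0.01
    min_nonzero: int = 5
    estimator: str = "spearman"
    n_perm: int = 99
    n_lv: int = 2
    pqn: bool = False
    glog: bool = True
    census_thresholds: tuple = (0.75, 0.85, 0.93)
    input_table: str | None = None  # path; None → simulate
    input_annotation: str | None = None
    stages: tuple = STAGES

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["days"] = list(self.days)
        payload["census_thresholds"] = list(self.census_thresholds)
        payload["stages"] = list(self.stages)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        for key in ("days", "census_thresholds", "stages"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=list)),
        "stages": [],
    }
    state: dict = {}
    try:
        for stage in cfg.stages:
            record = _STAGE_FUNCS[stage](cfg, out, state)
            manifest["stages"].append({"stage": stage, **record})
    except Exception as exc:  # record the failure point, then re-raise
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(out / "manifest.json", manifest)
        raise
    _write_json(out / "manifest.json", manifest)
    return manifest


# -- stages ---------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> dict:
    if cfg.input_table:
        table = read_concentration_table(cfg.input_table)
        ann = read_annotation(cfg.input_annotation) if cfg.input_annotation else None
        source = "loaded"
    else:
        cohort_cfg = recovery_config(cfg.seed, planted=cfg.planted, missing_rate=cfg.missing_rate)
        cohort_cfg.n_patients = cfg.n_patients
        table = generate_cohort(cohort_cfg)
        ann = AnnotationMap(panel_annotation(cohort_cfg.panel))
        source = "simulated"
    if ann is None:
        raise ValueError("an annotation map is required (input_annotation)")
    ann.require_cover(table.metabolites)
    write_concentration_table(table, out / "cohort.tsv")
    write_annotation(ann, out / "annotation.tsv")
    state["table"], state["ann"] = table, ann
    return {
        "source": source,
        "n_samples": table.n_samples,
        "n_metabolites": len(table.metabolites),
        "n_missing": table.n_missing,
    }


def _stage_preprocess(cfg: RunConfig, out: Path, state: dict) -> dict:
    """Per-day feature matrices for the multivariate stage (PQN + glog)."""
    table: ConcentrationTable = state["table"]
    matrices = {}
    record: dict = {"pqn": cfg.pqn, "glog": cfg.glog}
    for day in cfg.days:
        bm = table.values_at("BM", day)
        pb = table.values_at("PB", day)
        patients = bm.index.intersection(pb.index)
        stacked = pd.concat([bm.loc[patients], pb.loc[patients]], axis=0)
        stacked.index = pd.Index(
            [f"{p}:BM" for p in patients] + [f"{p}:PB" for p in patients], name="sample"
        )
        stacked = stacked.dropna(axis=1)  # multivariate models need complete columns
        if cfg.pqn:
            stacked, factors = pqn_normalize(stacked)
            record[f"day{day}_median_dilution"] = float(np.median(factors))
        if cfg.glog:
            lam = suggest_glog_lambda(stacked)
            stacked = glog_transform(stacked, lam)
            record[f"day{day}_glog_lambda"] = lam
        stacked.to_csv(out / f"features_day{day}.tsv", sep="\t")
        matrices[day] = stacked
    state["feature_matrices"] = matrices
    record["n_complete_features"] = {int(d): int(m.shape[1]) for d, m in matrices.items()}
    return record


def _stage_univariate(cfg: RunConfig, out: Path, state: dict) -> dict:
    table: ConcentrationTable = state["table"]
    record = {}
    state["univariate"] = {}
    for day in cfg.days:
        results = compartment_comparison(table, day)
        diffs = paired_differences(table, day)
        frame = comparison_frame(results)
        frame["mean_difference"] = frame["metabolite"].map(diffs.mean_difference)
        frame["mean_fold"] = frame["metabolite"].map(diffs.mean_fold)
        frame.to_csv(out / f"univariate_day{day}.tsv", sep="\t", index=False)
        state["univariate"][day] = frame
        record[f"day{day}_tested"] = len(frame)
        record[f"day{day}_pfdr_lt_10"] = int((frame["q"] < 0.10).sum())
        record[f"day{day}_pfdr_lt_5"] = int((frame["q"] < 0.05).sum())
    ratios = ratio_features(table)
    ratios.reset_index().to_csv(out / "ratio_features.tsv", sep="\t", index=False)
    state["ratios"] = ratios
    record["ratio_features"] = list(ratios.columns)
    return record


def _stage_multilevel(cfg: RunConfig, out: Path, state: dict) -> dict:
    day = cfg.days[0]
    matrix = state["feature_matrices"][day]
    subjects = [s.split(":")[0] for s in matrix.index]
    labels = [s.split(":")[1] for s in matrix.index]
    pca = mpca(matrix.to_numpy(), subjects, k=min(cfg.n_lv, 2))
    plsda = mplsda(matrix.to_numpy(), subjects, labels, n_lv=cfg.n_lv)
    perm_p = permutation_validate(
        matrix.to_numpy(), subjects, labels, n_perm=cfg.n_perm, seed=cfg.seed, n_lv=cfg.n_lv
    )
    scores = pd.DataFrame(
        pca.scores, index=matrix.index,
        columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])],
    )
    scores.to_csv(out / f"mpca_scores_day{day}.tsv", sep="\t")
    metrics = {
        "day": int(day),
        "mpca_variance_pct": [float(v) for v in pca.variance_fraction],
        "plsda_x_variance_pct": [float(v) for v in plsda.x_variance_pct],
        "plsda_sensitivity_pct": plsda.sensitivity,
        "plsda_specificity_pct": plsda.specificity,
        "permutation_p": perm_p,
        "n_permutations": cfg.n_perm,
    }
    _write_json(out / "multilevel.json", metrics)
    state["multilevel"] = metrics
    return metrics


def _stage_correlate(cfg: RunConfig, out: Path, state: dict) -> dict:
    table: ConcentrationTable = state["table"]
    day = cfg.days[0]
    censuses = {}
    for space in ("BM", "PB", "diff"):
        if space == "diff":
            values = paired_differences(table, day).differences
        else:
            values = table.values_at(space, day)
        corr = correlation_matrix(values)
        corr.r.to_csv(out / f"correlation_{space}_day{day}.tsv", sep="\t")
        censuses[space] = {
            str(k): v for k, v in threshold_counts(corr, cfg.census_thresholds).items()
        }
    _write_json(out / "census.json", {"day": int(day), "censuses": censuses})
    state["census"] = censuses
    return {"day": int(day), "censuses": censuses}


def _stage_network(cfg: RunConfig, out: Path, state: dict) -> dict:
    table: ConcentrationTable = state["table"]
    ann: AnnotationMap = state["ann"]
    record: dict = {}
    nets = {}
    summaries = {}
    for day in cfg.days:
        diffs = paired_differences(table, day).differences
        net = build_relevance_network(
            diffs, ann, fdr_admit=cfg.fdr_admit, min_nonzero=cfg.min_nonzero,
            estimator=cfg.estimator, provenance={"space": "BM_minus_PB", "day": int(day)},
        )
        nets[day] = net
        pruned = fdr_retain(aracne_prune(net), fdr=cfg.fdr_retain)
        write_network(net, out / f"network_day{day}.graphml", "graphml")
        write_network(net, out / f"network_day{day}_edges.tsv", "edge_tsv")
        write_network(pruned, out / f"network_day{day}_pruned_edges.tsv", "edge_tsv")
        comps = connected_components(pruned, min_nodes=4)
        summaries[day] = {
            "relevance_edges": net.n_edges,
            "pruned_edges": pruned.n_edges,
            "components": [dataclasses.asdict(component_summary(c)) for c in comps],
        }
        record[f"day{day}_edges_admitted"] = net.n_edges
        record[f"day{day}_edges_after_aracne_fdr"] = pruned.n_edges
    enrichments = {}
    for day, group in ((cfg.days[0], EDGE_LIPID), (cfg.days[-1], EDGE_AMINO)):
        try:
            res = enrichment_test(nets[day], group)
            enrichments[f"{group}_day{day}"] = dataclasses.asdict(res)
        except ValueError as exc:
            enrichments[f"{group}_day{day}"] = {"error": str(exc)}
    if len(cfg.days) > 1:
        try:
            res = enrichment_test(
                nets[cfg.days[0]], EDGE_LIPID,
                versus="same_class_other_network", other=nets[cfg.days[-1]],
            )
            enrichments["lipid_cross_day"] = dataclasses.asdict(res)
        except ValueError as exc:
            enrichments["lipid_cross_day"] = {"error": str(exc)}
    payload = {"components": summaries, "enrichment": enrichments}
    _write_json(out / "network_summary.json", payload)
    state["network"] = payload
    return record


def _stage_report(cfg: RunConfig, out: Path, state: dict) -> dict:
    path = out / "report.md"
    path.write_text(render_report(out))
    return {"report": str(path)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "univariate": _stage_univariate,
    "multilevel": _stage_multilevel,
    "correlate": _stage_correlate,
    "network": _stage_network,
    "report": _stage_report,
}


def render_report(run_dir) -> str:
    """Compose the human-readable run summary from stage artifacts.

    Idempotent: re-rendering from the same run directory gives the same
    document. Missing stages are flagged rather than omitted.
    """
    run_dir = Path(run_dir)
    lines = ["# Paired compartment metabolomics run report", ""]

    def _load(name):
        p = run_dir / name
        return json.loads(p.read_text()) if p.exists() else None

    manifest = _load("manifest.json")
    if manifest:
        lines += [f"Package version {manifest['version']}; seed {manifest['config']['seed']}.", ""]
        if "failed_stage" in manifest:
            lines += [f"**Run failed at stage `{manifest['failed_stage']}`:** {manifest['error']}", ""]

    lines.append("## Compartment comparison")
    uni_files = sorted(run_dir.glob("univariate_day*.tsv"))
    if not uni_files:
        lines.append("_univariate stage output missing_")
    for f in uni_files:
        frame = pd.read_csv(f, sep="\t")
        day = f.stem.replace("univariate_day", "")
        n5 = int((frame["q"] < 0.05).sum())
        n10 = int((frame["q"] < 0.10).sum())
        lines += [
            f"### Day {day}",
            f"{len(frame)} metabolites tested; {n10} at pFDR<10% ({n5} at pFDR<5%).",
            "",
            "```",
            frame.sort_values("q").head(10).to_string(index=False),
            "```",
            "",
        ]
    ratio_file = run_dir / "ratio_features.tsv"
    if ratio_file.exists():
        ratios = pd.read_csv(ratio_file, sep="\t")
        derived = [c for c in ratios.columns if c not in ("patient_id", "compartment", "day")]
        lines += ["Derived ratio features: " + (", ".join(derived) if derived else "none"), ""]

    lines.append("## Multilevel models")
    metrics = _load("multilevel.json")
    if metrics:
        var = ", ".join(f"{v:.2f}%" for v in metrics["mpca_variance_pct"])
        lines += [
            f"mPCA variance captured: {var}.",
            f"mPLS-DA permutation p = {metrics['permutation_p']:.4g} "
            f"({metrics['n_permutations']} permutations); "
            f"CV sensitivity {metrics['plsda_sensitivity_pct']:.0f}%, "
            f"specificity {metrics['plsda_specificity_pct']:.0f}%.",
            "",
        ]
    else:
        lines.append("_multilevel stage output missing_")

    lines.append("## Correlation census")
    census = _load("census.json")
    if census:
        for space, counts in census["censuses"].items():
            pretty = ", ".join(f"|r|>{k}: {v}" for k, v in counts.items())
            lines.append(f"- {space} (day {census['day']}): {pretty}")
        lines.append("")
    else:
        lines.append("_correlation stage output missing_")

    lines.append("## Network analysis")
    network = _load("network_summary.json")
    if network:
        for day, summary in network["components"].items():
            lines.append(
                f"- Day {day}: {summary['relevance_edges']} relevance edges, "
                f"{summary['pruned_edges']} after ARACNE + FDR retention."
            )
            if summary["components"]:
                for comp in summary["components"]:
                    lines.append(
                        f"    - component: {comp['n_nodes']} nodes, {comp['n_edges']} edges, "
                        f"<R²>={comp['mean_r2']:.2f}, <p>={comp['mean_p']:.3g}, "
                        f"<MI>={comp['mean_mi']:.2f}"
                    )
            else:
                lines.append("    - 0 components with more than three nodes (0 edges)")
        lines.append("")
        lines.append("### Enrichment")
        for name, res in network["enrichment"].items():
            if "error" in res:
                lines.append(f"- {name}: not testable ({res['error']})")
            else:
                lines.append(
                    f"- {name}: U={res['u_statistic']:.1f}, p={res['p']:.3g}, "
                    f"smaller edge p-values in: {res['direction']} "
                    f"(n={res['n_group']} vs {res['n_other']})"
                )
    else:
        lines.append("_network stage output missing_")
    lines.append("")
    return "\n".join(lines)
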