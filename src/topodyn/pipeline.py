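"""Seed-deterministic pipeline orchestration over a timecourse bundle.

Stages run in dependency order (simulate -> compartments -> tads -> loops ->
hubs -> communities -> enrich -> compare); every output file is listed in a
manifest with its stage, parameters, and content hash.  All thresholds
default to the analysis' standard values (20 kb boundary tolerance, 10 kb
TSS window, 30 kb / 3 kb / 5-feet / 30 kb hub parameters, 1 CPM expression
cutoff, Mahalanobis distance > 1, normalized rank < 0.05, FDR 0.05, 100
shuffles, 1000 permutations).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compartments as cp
from . import concordance as cc
from . import enrichment_stats as es
from . import gene_networks as gn
from . import loops_hubs as lh
from . import tads as td
from .genome_model import filter_expressed_genes
from .synthetic_data import SimulationSpec, TimecourseBundle, simulate_timecourse, write_bundle

__all__ = ["PipelineConfig", "PipelineError", "run_all", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "compartments",
    "tads",
    "loops",
    "hubs",
    "communities",
    "enrich",
    "compare",
)


@dataclass
class PipelineConfig:
    outdir: str = "topodyn_out"
    seed: int = 0
    resolution_matrix: int = 10_000
    resolution_pc1: int = 50_000
    boundary_tolerance: int = 20_000
    tss_window: int = 10_000
    hub_window: int = 30_000
    hub_step: int = 3_000
    hub_min_feet: int = 5
    hub_stitch_gap: int = 30_000
    cpm_threshold: float = 1.0
    md_threshold: float = 1.0
    rank_level: float = 0.05
    fdr: float = 0.05
    n_shuffles: int = 100
    n_permutations: int = 1000
    insulation_window_bins: int = 10
    min_prominence: float = 0.25
    pseudocount: float = 1.0
    min_clique_size: int = 3
    saddle_quantiles: int = 40
    saddle_corner: int = 5
    simulation: dict = field(default_factory=dict)

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) is None:
                raise ValueError(f"config field {f.name!r} missing")
        self.spec()  # raises on inconsistent simulation overrides

    def spec(self) -> SimulationSpec:
        sim = dict(self.simulation)
        if "chromsizes" in sim:
            sim["chromsizes"] = {str(k): int(v) for k, v in sim["chromsizes"].items()}
        if "timepoints" in sim:
            sim["timepoints"] = tuple(sim["timepoints"])
        spec = SimulationSpec(
            resolution_matrix=self.resolution_matrix,
            resolution_pc1=self.resolution_pc1,
            seed=self.seed,
            **sim,
        )
        spec.validate()
        return spec

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")
    return path


# ---------------------------------------------------------------------------
# Stage implementations (each returns the list of files it wrote)


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> tuple[TimecourseBundle, list]:
    bundle = simulate_timecourse(cfg.spec())
    files = write_bundle(bundle, outdir / "bundle")
    return bundle, files


def stage_compartments(bundle: TimecourseBundle, cfg: PipelineConfig, outdir: Path) -> tuple[dict, list]:
    d = outdir / "compartments"
    d.mkdir(parents=True, exist_ok=True)
    files = []
    called = {
        tp: cp.call_compartments_bundle(
            bundle.matrices[tp], bundle.gene_density, cfg.resolution_pc1
        )
        for tp in bundle.timepoints
    }
    for tp, track in called.items():
        p = d / f"pc1_called_{tp}.bedgraph"
        track.to_bedgraph(p)
        files.append(p)
    tracks = [called[tp] for tp in bundle.timepoints]
    labels, switches, n_withheld = cp.classify_track_trajectories(tracks)
    rows = []
    for chrom, lab in labels.items():
        for i, l in enumerate(lab):
            rows.append(
                (chrom, i * cfg.resolution_pc1, (i + 1) * cfg.resolution_pc1,
                 l if l is not None else "NA", switches[chrom][i])
            )
    files.append(_write_df(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "switch_timepoint"]),
        d / "trajectory_labels.tsv",
    ))
    summary, hist = cp.switch_mass_summary(labels, switches, cfg.resolution_pc1)
    files.append(_write_df(summary, d / "switch_mass.tsv"))
    files.append(_write_df(hist.rename("n_bins").reset_index(), d / "switch_histogram.tsv"))

    first_tp = bundle.timepoints[0]
    coarse = {
        c: m.rebin(cfg.resolution_pc1) for c, m in bundle.matrices[first_tp].items()
    }
    sad = cp.saddle(coarse, called[first_tp], cfg.saddle_quantiles, cfg.saddle_corner)
    files.append(_write_df(
        pd.DataFrame([{"aa": sad.aa, "bb": sad.bb, "ab": sad.ab}]), d / "saddle_strength.tsv"
    ))
    md_track, flags = cp.mahalanobis_change(tracks, cfg.md_threshold)
    p = d / "mahalanobis.bedgraph"
    md_track.to_bedgraph(p)
    files.append(p)

    expressed, _ = filter_expressed_genes(bundle.genes, bundle.expression, cfg.cpm_threshold)
    r, pval, n, dropped = cp.correlate_compartment_expression(
        called, bundle.expression, bundle.genes, expressed.df["id"],
        bundle.timepoints[0], bundle.timepoints[-1], cfg.pseudocount,
    )
    files.append(_write_df(
        pd.DataFrame([{"spearman_r": r, "p": pval, "n_genes": n, "n_dropped": dropped}]),
        d / "compartment_expression.tsv",
    ))
    results = {"called": called, "labels": labels, "switches": switches,
               "summary": summary, "saddle": sad, "n_withheld": n_withheld}
    return results, files


def stage_tads(bundle: TimecourseBundle, cfg: PipelineConfig, outdir: Path) -> tuple[dict, list]:
    d = outdir / "tads"
    d.mkdir(parents=True, exist_ok=True)
    files = []
    boundary_sets = {}
    tad_sets = {}
    for tp in bundle.timepoints:
        frames = []
        tframes = []
        for chrom, mat in bundle.matrices[tp].items():
            is_vals = td.insulation_track(mat, cfg.insulation_window_bins, log_normalize=True)
            bset = td.call_boundaries_from_insulation(
                is_vals, cfg.min_prominence, chrom, cfg.resolution_matrix, bundle.chromsizes
            )
            frames.append(bset.df)
            tset = td.tads_from_boundaries(bset, chrom, bundle.chromsizes[chrom], bundle.chromsizes)
            tframes.append(tset.df)
        from .genome_model import IntervalSet

        boundary_sets[tp] = IntervalSet(pd.concat(frames, ignore_index=True))
        tad_sets[tp] = IntervalSet(pd.concat(tframes, ignore_index=True))
        p = d / f"boundaries_called_{tp}.bed"
        boundary_sets[tp].to_bed(p)
        files.append(p)
        p = d / f"tads_called_{tp}.bed"
        tad_sets[tp].to_bed(p)
        files.append(p)
    dynamics, n_dup = td.classify_boundary_dynamics(boundary_sets, cfg.boundary_tolerance)
    files.append(_write_df(dynamics, d / "boundary_dynamics.tsv"))

    first_tp = bundle.timepoints[0]
    ds_frames = []
    pair_frames = []
    cliques_all = []
    tad_offset = 0
    tads_first = tad_sets[first_tp]
    for chrom, mat in bundle.matrices[first_tp].items():
        ds_frames.append(td.domain_score(mat, tads_first))
        pairs = td.significant_tad_pairs(mat, tads_first, cfg.fdr)
        sig = pairs[pairs["significant"]]
        edges = [
            (tad_offset + int(a), tad_offset + int(b))
            for a, b in zip(sig["tad_a"], sig["tad_b"])
        ]
        cliques_all.extend(td.find_tad_cliques(edges, cfg.min_clique_size))
        pairs = pairs.assign(chrom=chrom)
        pair_frames.append(pairs)
        tad_offset += int((tads_first.df["chrom"] == chrom).sum())
    files.append(_write_df(pd.concat(ds_frames, ignore_index=True), d / "domain_scores.tsv"))
    files.append(_write_df(pd.concat(pair_frames, ignore_index=True), d / "tad_pairs.tsv"))
    clique_df = pd.DataFrame(
        [(i, ",".join(map(str, c)), len(c)) for i, c in enumerate(cliques_all)],
        columns=["clique_id", "tad_ids", "size"],
    )
    files.append(_write_df(clique_df, d / "cliques.tsv"))
    n_tads = len(tads_first)
    nulls = td.shuffle_cliques(cliques_all, list(range(n_tads)), cfg.n_shuffles, cfg.seed) if cliques_all else []
    expressed, _ = filter_expressed_genes(bundle.genes, bundle.expression, cfg.cpm_threshold)
    marker_ids = set(bundle.truth["markers"]["gene_id"]) if "markers" in bundle.truth else set()
    gene_sets = {
        "expressed": expressed.df["id"].tolist(),
        "markers": sorted(marker_ids & set(expressed.df["id"])),
    }
    if cliques_all:
        stats_df = td.clique_gene_stats(cliques_all, nulls, tads_first, bundle.genes, gene_sets)
        files.append(_write_df(stats_df, d / "clique_gene_stats.tsv"))
    comp = td.assign_tad_compartment(tads_first, bundle.pc1[first_tp])
    files.append(_write_df(comp, d / "tad_compartments.tsv"))
    results = {"boundaries": boundary_sets, "tads": tad_sets, "dynamics": dynamics,
               "cliques": cliques_all}
    return results, files


def stage_loops(bundle: TimecourseBundle, cfg: PipelineConfig, outdir: Path) -> tuple[dict, list]:
    d = outdir / "loops"
    d.mkdir(parents=True, exist_ok=True)
    files = []
    union, hist = lh.merge_loops_across_timepoints(bundle.loops, cfg.resolution_matrix)
    files.append(_write_df(union, d / "loop_union.tsv"))
    files.append(_write_df(hist.rename("n_loops").reset_index(), d / "loop_sharing.tsv"))
    first_lp = bundle.loop_timepoints[0]
    nulls = lh.shuffle_loops(bundle.loops[first_lp], bundle.chromsizes, cfg.n_shuffles, cfg.seed)
    nulls[0].to_bedpe(d / "null_loops_rep0.bedpe")
    files.append(d / "null_loops_rep0.bedpe")
    return {"union": union, "null_loops": nulls}, files


def stage_hubs(bundle: TimecourseBundle, cfg: PipelineConfig, outdir: Path) -> tuple[dict, list]:
    d = outdir / "hubs"
    d.mkdir(parents=True, exist_ok=True)
    files = []
    hubs = lh.call_hubs(
        bundle.loops, bundle.chromsizes, cfg.hub_window, cfg.hub_step,
        cfg.hub_min_feet, cfg.hub_stitch_gap,
    )
    hubs = hubs.copy()
    hubs["dynamics"] = lh.hub_dynamics_table(hubs, bundle.loop_timepoints)
    trend = lh.hub_pc1_trend_table(hubs, {tp: bundle.pc1[tp] for tp in bundle.timepoints})
    hubs["pc1_trend"] = trend
    files.append(_write_df(hubs, d / "hubs.tsv"))
    return {"hubs": hubs}, files


def stage_communities(bundle: TimecourseBundle, cfg: PipelineConfig, outdir: Path) -> tuple[dict, list]:
    d = outdir / "communities"
    d.mkdir(parents=True, exist_ok=True)
    files = []
    expressed, _ = filter_expressed_genes(bundle.genes, bundle.expression, cfg.cpm_threshold)
    first_lp = bundle.loop_timepoints[0]
    comms = gn.build_gene_communities(expressed, bundle.loops[first_lp])
    marker_ids = set(bundle.truth["markers"]["gene_id"]) if "markers" in bundle.truth else set()
    per, summary = gn.community_stats(comms, {"markers": marker_ids})
    files.append(_write_df(per, d / "communities.tsv"))
    files.append(_write_df(summary, d / "community_stats.tsv"))
    return {"communities": comms, "summary": summary}, files


def stage_enrich(bundle: TimecourseBundle, cfg: PipelineConfig, outdir: Path) -> tuple[dict, list]:
    d = outdir / "enrich"
    d.mkdir(parents=True, exist_ok=True)
    files = []
    expressed, _ = filter_expressed_genes(bundle.genes, bundle.expression, cfg.cpm_threshold)
    first_tp = bundle.timepoints[0]
    frames = []
    for chrom, mat in bundle.matrices[first_tp].items():
        sub = expressed.df[expressed.df["chrom"] == chrom]
        tss_bins = (sub["tss"] // cfg.resolution_matrix).tolist()
        res = es.tss_contact_enrichment(
            mat, tss_bins, cfg.n_permutations, cfg.seed, cfg.rank_level
        )
        res.insert(0, "gene_id", sub["id"].to_numpy())
        res.insert(0, "chrom", chrom)
        frames.append(res)
    tss_df = pd.concat(frames, ignore_index=True)
    files.append(_write_df(tss_df, d / "tss_enrichment.tsv"))

    first_lp = bundle.loop_timepoints[0]
    nulls = lh.shuffle_loops(bundle.loops[first_lp], bundle.chromsizes, 20, cfg.seed)
    annot = es.loop_annotation_enrichment(bundle.loops[first_lp], expressed, nulls)
    files.append(_write_df(annot, d / "loop_annotation.tsv"))

    called = {
        tp: cp.call_compartments_bundle(
            bundle.matrices[tp], bundle.gene_density, cfg.resolution_pc1
        )
        for tp in bundle.timepoints
    }
    labels, _, _ = cp.classify_track_trajectories([called[tp] for tp in bundle.timepoints])
    marker_ids = bundle.truth["markers"]["gene_id"].tolist() if "markers" in bundle.truth else []
    switch_rows = []
    if marker_ids:
        for target in ("stable_AtoB", "stable_BtoA"):
            perm = es.gene_set_switch_enrichment(
                marker_ids, labels, bundle.genes, cfg.resolution_pc1, target,
                cfg.n_shuffles, cfg.seed, cfg.rank_level,
            )
            switch_rows.append(
                (target, perm.observed, perm.null.mean(), perm.null.std(ddof=1),
                 perm.z, perm.normalized_rank, perm.significant)
            )
    switch_df = pd.DataFrame(
        switch_rows,
        columns=["label", "observed_pct", "null_mean", "null_sd", "z", "rank", "significant"],
    )
    files.append(_write_df(switch_df, d / "switch_enrichment.tsv"))
    return {"tss": tss_df, "switch": switch_df}, files


def stage_compare(bundle: TimecourseBundle, cfg: PipelineConfig, outdir: Path) -> tuple[dict, list]:
    d = outdir / "compare"
    d.mkdir(parents=True, exist_ok=True)
    files = []
    rows = []
    tps = bundle.timepoints
    for a, b in zip(tps[:-1], tps[1:]):
        res = cc.scc_genomewide(bundle.matrices[a], bundle.matrices[b])
        rows.append((a, b, res.mean))
    files.append(_write_df(pd.DataFrame(rows, columns=["tp_a", "tp_b", "scc"]), d / "scc.tsv"))
    conc = cc.compartment_concordance(bundle.pc1[tps[0]], bundle.pc1[tps[-1]], bundle.genes)
    recall = cc.boundary_recall(
        bundle.boundaries[tps[0]], bundle.boundaries[tps[-1]], cfg.boundary_tolerance
    )
    pairs = cc.intra_tad_gene_pair_concordance(
        bundle.tads[tps[0]], bundle.tads[tps[-1]], bundle.genes
    )
    files.append(_write_df(
        pd.DataFrame([
            {"metric": "compartment_bin_pct", "value": conc["bin_pct"]},
            {"metric": "compartment_gene_pct", "value": conc.get("gene_pct", np.nan)},
            {"metric": "boundary_recall_pct", "value": recall},
            {"metric": "intra_tad_pair_pct", "value": pairs["pct"]},
        ]),
        d / "concordance.tsv",
    ))
    return {"scc": rows, "concordance": conc}, files


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(cfg), "stages": []}
    bundle = None
    results: dict = {}

    def record(stage: str, files) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "files": [
                    {"path": str(Path(f).relative_to(outdir)), "sha256": _sha256(Path(f))}
                    for f in files
                ],
            }
        )

    stage_funcs = {
        "compartments": stage_compartments,
        "tads": stage_tads,
        "loops": stage_loops,
        "hubs": stage_hubs,
        "communities": stage_communities,
        "enrich": stage_enrich,
        "compare": stage_compare,
    }
    try:
        bundle, files = stage_simulate(cfg, outdir)
        record("simulate", files)
    except Exception as exc:  # noqa: BLE001
        _dump_manifest(manifest, outdir)
        raise PipelineError("simulate", exc) from exc
    for stage in STAGES[1:]:
        try:
            res, files = stage_funcs[stage](bundle, cfg, outdir)
            results[stage] = res
            record(stage, files)
        except Exception as exc:  # noqa: BLE001
            _dump_manifest(manifest, outdir)
            raise PipelineError(stage, exc) from exc
    _dump_manifest(manifest, outdir)
    results["manifest"] = manifest
    results["bundle"] = bundle
    return results


def _dump_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
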