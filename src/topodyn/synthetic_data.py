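"""Synthetic Hi-C timecourse generator with planted, recoverable structure.

The generator emulates the statistical structure of a multi-timepoint bulk
Hi-C + RNA-seq differentiation study on a desk-scale toy genome:

* power-law distance decay ``P(s) ~ s^-alpha`` with Poisson counting noise;
* a checkerboard compartment modulation organised in megabase blocks, with
  planted stable A-to-B / B-to-A switches and fully dynamic blocks;
* block-diagonal TAD enrichment on a partition that respects compartment
  block edges (as in real genomes, where compartment transitions coincide
  with domain boundaries), with planted gained and lost boundaries;
* focal loop peaks, including planted loop-foot clusters (hubs) with
  stable / gained / lost presence profiles, background loops, and chains of
  loops linking marker genes into planted gene communities;
* an expression table whose marker-gene log2 CPM follows
  ``beta * delta-PC1 + noise`` while all other genes are pure noise.

Every planted event is recorded in a truth table so recovery tests can score
precision and recall.  All randomness is derived from ``spec.seed`` through
numpy ``SeedSequence`` streams keyed by (timepoint, chromosome), so the same
spec always yields the same bundle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_model import (
    BinnedTrack,
    ChromSizes,
    ContactMatrix,
    GeneCatalog,
    IntervalSet,
    LoopSet,
    read_chrom_sizes,
    read_expression,
)

__all__ = [
    "SimulationSpec",
    "TimecourseBundle",
    "simulate_contact_map",
    "simulate_timecourse",
    "write_bundle",
    "read_bundle",
]


def _default_chromsizes() -> ChromSizes:
    return {"chr1": 20_000_000, "chr2": 20_000_000}


@dataclass
class SimulationSpec:
    """All knobs of the generator; defaults define the standard toy study.

    The toy genome is 2 chromosomes x 20 Mb, binned at 10 kb for matrices and
    50 kb for compartment scores, observed at five timepoints with loops at
    the first four (mirroring a differentiation timecourse where the last
    sample lacks loop calls).
    """

    timepoints: tuple = ("D60", "D70", "D90", "D120", "D200")
    n_loop_timepoints: int = 4
    chromsizes: ChromSizes = field(default_factory=_default_chromsizes)
    resolution_matrix: int = 10_000
    resolution_pc1: int = 50_000
    decay_exponent: float = 1.0
    depth: float = 60.0  # expected count on the first off-diagonal
    compartment_amplitude: float = 0.4
    tad_strength: float = 1.0
    loop_boost: float = 3.0
    block_size: int = 1_000_000
    n_atob_blocks: int = 2  # per chromosome
    n_btoa_blocks: int = 2
    n_dynamic_blocks: int = 1
    tad_split_range: tuple = (40, 60)  # interior boundary offset, matrix bins
    n_gained_boundaries: int = 4  # per chromosome
    n_lost_boundaries: int = 4
    n_hubs_stable: int = 2  # per chromosome
    n_hubs_gained: int = 2
    n_hubs_lost: int = 2
    hub_feet: int = 6
    n_background_loops: int = 150  # per chromosome
    background_presence_prob: float = 0.7
    n_genes_per_chrom: int = 250
    markers_per_switch_block: int = 5
    gene_a_bias: float = 0.75
    silent_gene_frac: float = 0.1
    beta: float = 1.0
    expression_noise_sd: float = 0.25
    n_replicates: int = 2
    pc1_amplitude: float = 1.0
    pc1_jitter_sd: float = 0.05
    max_bins: int = 4000
    seed: int = 0

    @property
    def loop_timepoints(self) -> tuple:
        return tuple(self.timepoints[: self.n_loop_timepoints])

    def validate(self) -> None:
        if self.decay_exponent <= 0:
            raise ValueError("decay exponent must be positive")
        if self.hub_feet < 5:
            raise ValueError("planted hubs need at least 5 feet")
        if self.n_loop_timepoints < 2 or self.n_loop_timepoints > len(self.timepoints):
            raise ValueError("loop timepoints must cover 2..n_timepoints")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        for chrom, size in self.chromsizes.items():
            n = size // self.resolution_matrix
            if n > self.max_bins:
                raise ValueError(f"{chrom}: {n} bins exceeds cap {self.max_bins}")
            if size % self.block_size:
                raise ValueError(f"{chrom}: size must be a multiple of block_size")
        if self.block_size % self.resolution_pc1 or self.block_size % self.resolution_matrix:
            raise ValueError("block_size must be a multiple of both resolutions")
        if not np.isfinite(self.beta) or not np.isfinite(self.expression_noise_sd):
            raise ValueError("beta and noise SD must be finite")


@dataclass
class TimecourseBundle:
    """Aligned multi-timepoint bundle of matrices, tracks, intervals and truth."""

    spec: SimulationSpec
    timepoints: tuple
    loop_timepoints: tuple
    chromsizes: ChromSizes
    matrices: dict  # {tp: {chrom: ContactMatrix}}
    pc1: dict  # {tp: BinnedTrack}, planted ground-truth compartment score
    boundaries: dict  # {tp: IntervalSet}
    tads: dict  # {tp: IntervalSet}
    loops: dict  # {tp: LoopSet}, loop timepoints only
    genes: GeneCatalog
    expression: pd.DataFrame
    gene_density: BinnedTrack  # TSS count per PC1 bin, used to orient PC1 signs
    truth: dict  # name -> DataFrame


# ---------------------------------------------------------------------------
# Planted layout (deterministic given spec.seed and chromosome)


class _ChromPlan:
    """Planted structure for one chromosome, shared by all timepoints."""

    def __init__(self, spec: SimulationSpec, chrom: str, chrom_idx: int):
        self.chrom = chrom
        size = spec.chromsizes[chrom]
        self.n_bins = size // spec.resolution_matrix
        self.block_bins = spec.block_size // spec.resolution_matrix
        self.n_blocks = size // spec.block_size
        n_tp = len(spec.timepoints)
        rng = np.random.default_rng([spec.seed, 101, chrom_idx])

        # -- compartment blocks: alternating base signs, planted switches
        base_sign = np.where(np.arange(self.n_blocks) % 2 == 0, 1, -1)
        interior = np.arange(1, self.n_blocks - 1)
        even_int = interior[base_sign[interior] > 0]
        odd_int = interior[base_sign[interior] < 0]
        atob = rng.choice(even_int, spec.n_atob_blocks, replace=False)
        btoa = rng.choice(odd_int, spec.n_btoa_blocks, replace=False)
        remaining = np.setdiff1d(interior, np.concatenate([atob, btoa]))
        dyn = rng.choice(remaining, spec.n_dynamic_blocks, replace=False)
        self.block_sign = np.repeat(base_sign[:, None], n_tp, axis=1)
        self.block_label = np.array(
            ["stable_A" if s > 0 else "stable_B" for s in base_sign], dtype=object
        )
        self.block_switch = np.full(self.n_blocks, -1)
        for b in atob:
            k = int(rng.integers(1, n_tp))
            self.block_sign[b] = np.where(np.arange(n_tp) < k, 1, -1)
            self.block_label[b] = "stable_AtoB"
            self.block_switch[b] = k
        for b in btoa:
            k = int(rng.integers(1, n_tp))
            self.block_sign[b] = np.where(np.arange(n_tp) < k, -1, 1)
            self.block_label[b] = "stable_BtoA"
            self.block_switch[b] = k
        for b in dyn:
            s0 = int(rng.choice([-1, 1]))
            self.block_sign[b] = s0 * np.where(np.arange(n_tp) % 2 == 0, 1, -1)
            self.block_label[b] = "dynamic"

        # -- TAD boundaries: block edges are stable boundaries; each block is
        # split once internally; gained/lost events modify interior splits
        lo, hi = spec.tad_split_range
        splits = {
            b: b * self.block_bins + int(rng.integers(lo, hi + 1))
            for b in range(self.n_blocks)
        }
        edge_bounds = [b * self.block_bins for b in range(1, self.n_blocks)]
        stable = sorted(edge_bounds + list(splits.values()))
        blocks_for_events = rng.permutation(np.arange(self.n_blocks))
        lost_blocks = blocks_for_events[: spec.n_lost_boundaries]
        gain_blocks = blocks_for_events[
            spec.n_lost_boundaries : spec.n_lost_boundaries + spec.n_gained_boundaries
        ]
        self.lost_boundaries = {}  # bin -> loss timepoint index
        for b in lost_blocks:
            pos = splits[b]
            stable.remove(pos)
            self.lost_boundaries[pos] = int(rng.integers(1, n_tp))
        self.gained_boundaries = {}  # bin -> gain timepoint index
        for b in gain_blocks:
            start = b * self.block_bins
            split = splits[b]
            # split the larger half of the block, >=10 bins from other bounds
            halves = [(start, split), (split, start + self.block_bins)]
            seg = max(halves, key=lambda h: h[1] - h[0])
            pos = int(rng.integers(seg[0] + 10, seg[1] - 9))
            self.gained_boundaries[pos] = int(rng.integers(1, n_tp))
        self.stable_boundaries = stable

        # -- loop hubs: clusters of >=5 near feet within 3 matrix bins
        n_ltp = spec.n_loop_timepoints
        n_hubs = spec.n_hubs_stable + spec.n_hubs_gained + spec.n_hubs_lost
        # one anchor per slot, jittered; the margin keeps every hub's far
        # feet (reach <= anchor + ~170 bins) clear of the next hub's cluster
        lo, hi = 100, self.n_bins - 300
        margin = 180
        slot = (hi - lo) // max(n_hubs, 1)
        if slot < margin:
            raise ValueError(
                f"{chrom}: too small for {n_hubs} planted hubs at this resolution"
            )
        anchors = [
            lo + k * slot + int(rng.integers(0, slot - margin + 1))
            for k in range(n_hubs)
        ]
        labels = (
            ["stable"] * spec.n_hubs_stable
            + ["gained"] * spec.n_hubs_gained
            + ["lost"] * spec.n_hubs_lost
        )
        self.hubs = []  # (anchor, label, event, presence, loops[(abin,bbin)])
        for anchor, label in zip(anchors, labels):
            if label == "stable":
                event, presence = -1, np.ones(n_ltp, bool)
            elif label == "gained":
                event = int(rng.integers(1, n_ltp))
                presence = np.arange(n_ltp) >= event
            else:
                event = int(rng.integers(1, n_ltp))
                presence = np.arange(n_ltp) < event
            feet = []
            for f in range(spec.hub_feet):
                near = anchor + int(rng.integers(0, 3))
                far = anchor + 50 + 20 * f + int(rng.integers(0, 8))
                feet.append((near, far))
            self.hubs.append((anchor, label, event, presence, feet))

        # -- background loops with per-timepoint presence.  Non-hub feet are
        # capped at 4 per 30 kb window so that only planted clusters ever
        # reach the hub threshold: the truth table must enumerate every
        # hub-grade cluster.
        foot_load = np.zeros(self.n_bins, dtype=int)
        for _anchor, _label, _event, _presence, feet in self.hubs:
            for _near, far in feet:
                foot_load[far] += 1
        # community-chain feet (placed later, deterministically) count too
        res = spec.resolution_matrix
        switch_blocks_pre = sorted(np.concatenate([atob, btoa]).tolist())
        for b in switch_blocks_pre:
            for m in range(spec.markers_per_switch_block):
                start = b * spec.block_size + 100_000 + m * 160_000
                w = 2 if 0 < m < spec.markers_per_switch_block - 1 else 1
                foot_load[start // res] += w

        # keep background feet out of the stitched-hub footprint so a hub's
        # planted absence at a timepoint cannot be masked by background feet
        forbidden = np.zeros(self.n_bins, dtype=bool)
        for anchor in anchors:
            forbidden[max(0, anchor - 5) : min(self.n_bins, anchor + 9)] = True

        def _cap_ok(*positions: int) -> bool:
            if any(forbidden[x] for x in positions):
                return False
            tmp = foot_load.copy()
            for x in positions:
                tmp[x] += 1
            for x in positions:
                for w0 in range(max(0, x - 3), min(x + 1, self.n_bins - 3)):
                    if tmp[w0 : w0 + 4].sum() > 4:
                        return False
            return True

        self.background = []
        for _ in range(spec.n_background_loops):
            for _attempt in range(100):
                a = int(rng.integers(0, self.n_bins - 250))
                b = a + int(rng.integers(20, 200))
                if _cap_ok(a, b):
                    break
            else:
                continue
            foot_load[a] += 1
            foot_load[b] += 1
            presence = rng.random(n_ltp) < spec.background_presence_prob
            if not presence.any():
                presence[int(rng.integers(0, n_ltp))] = True
            self.background.append((a, b, presence))

        # -- genes: markers in switching blocks (chained into communities),
        # background genes biased toward stable-A blocks
        res = spec.resolution_matrix
        self.markers = []  # (gene rows), one chain per switching block
        self.community_loops = []  # (abin, bbin, community_id)
        self.communities = []  # (community_id, [gene ids])
        switch_blocks = sorted(np.concatenate([atob, btoa]).tolist())
        gid = 0
        for ci, b in enumerate(switch_blocks):
            members = []
            starts = []
            for m in range(spec.markers_per_switch_block):
                start = b * spec.block_size + 100_000 + m * 160_000
                gene_id = f"M{chrom}_{gid:03d}"
                gid += 1
                self.markers.append(
                    dict(
                        id=gene_id,
                        chrom=chrom,
                        start=start,
                        end=start + 20_000,
                        strand="+" if rng.random() < 0.5 else "-",
                        biotype="protein_coding",
                        block=b,
                    )
                )
                members.append(gene_id)
                starts.append(start)
            for m in range(len(starts) - 1):
                self.community_loops.append(
                    (starts[m] // res, starts[m + 1] // res, f"{chrom}_c{ci}")
                )
            self.communities.append((f"{chrom}_c{ci}", members))

        n_background_genes = spec.n_genes_per_chrom - len(self.markers)
        slot_starts = np.arange(5_000, size - 60_000, 50_000)
        slot_blocks = slot_starts // spec.block_size
        weights = np.where(base_sign[slot_blocks] > 0, spec.gene_a_bias, 1 - spec.gene_a_bias)
        weights = weights / weights.sum()
        chosen = rng.choice(len(slot_starts), n_background_genes, replace=False, p=weights)
        ncrna_pool = ["lncRNA", "miRNA", "snoRNA", "snRNA"]
        self.background_genes = []
        for i, s in enumerate(np.sort(slot_starts[chosen])):
            length = int(rng.integers(5_000, 40_000))
            bio = (
                "protein_coding"
                if rng.random() < 0.85
                else ncrna_pool[int(rng.integers(0, len(ncrna_pool)))]
            )
            self.background_genes.append(
                dict(
                    id=f"G{chrom}_{i:04d}",
                    chrom=chrom,
                    start=int(s),
                    end=int(s) + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=bio,
                )
            )
        n_silent = int(round(spec.silent_gene_frac * len(self.background_genes)))
        silent_idx = rng.choice(len(self.background_genes), n_silent, replace=False)
        self.silent_ids = {self.background_genes[i]["id"] for i in silent_idx}

    # -- per-timepoint derived structure

    def boundaries_at(self, tp_idx: int) -> list[int]:
        bounds = list(self.stable_boundaries)
        bounds += [p for p, k in self.lost_boundaries.items() if tp_idx < k]
        bounds += [p for p, k in self.gained_boundaries.items() if tp_idx >= k]
        return sorted(bounds)

    def tad_id_per_bin(self, tp_idx: int) -> np.ndarray:
        edges = [0] + self.boundaries_at(tp_idx) + [self.n_bins]
        tad_id = np.empty(self.n_bins, dtype=np.int32)
        for t, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
            tad_id[a:b] = t
        return tad_id

    def sign_per_bin(self, tp_idx: int, resolution: int, block_size: int) -> np.ndarray:
        per_block = block_size // resolution
        return np.repeat(self.block_sign[:, tp_idx], per_block).astype(float)

    def loops_at(self, loop_tp_idx: int) -> list[tuple]:
        out = []
        for _anchor, _label, _event, presence, feet in self.hubs:
            if presence[loop_tp_idx]:
                out.extend(feet)
        out.extend((a, b) for a, b, pres in self.background if pres[loop_tp_idx])
        out.extend((a, b) for a, b, _cid in self.community_loops)
        return out


def _plans(spec: SimulationSpec) -> dict:
    return {
        chrom: _ChromPlan(spec, chrom, ci)
        for ci, chrom in enumerate(spec.chromsizes)
    }


# ---------------------------------------------------------------------------
# Contact maps


_DECAY_CACHE: dict = {}


def _decay_matrix(n: int, alpha: float) -> np.ndarray:
    key = (n, alpha)
    if key not in _DECAY_CACHE:
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        _DECAY_CACHE.clear()  # keep at most one cached size
        _DECAY_CACHE[key] = (dist + 1.0) ** (-alpha)
    return _DECAY_CACHE[key]


def expected_contact_map(
    spec: SimulationSpec, plan: _ChromPlan, tp_idx: int, with_loops: bool = True
) -> np.ndarray:
    """Noise-free expected count matrix for one chromosome and timepoint."""
    n = plan.n_bins
    e = spec.depth * _decay_matrix(n, spec.decay_exponent).copy()
    sign = plan.sign_per_bin(tp_idx, spec.resolution_matrix, spec.block_size)
    a = spec.compartment_amplitude
    e *= np.where(sign[:, None] == sign[None, :], 1 + a, 1 - a)
    tad = plan.tad_id_per_bin(tp_idx)
    e *= np.where(tad[:, None] == tad[None, :], 1 + spec.tad_strength, 1.0)
    if with_loops and tp_idx < spec.n_loop_timepoints:
        for i, j in plan.loops_at(tp_idx):
            e[i, j] *= 1 + spec.loop_boost
            e[j, i] = e[i, j]
    return e


def simulate_contact_map(
    spec: SimulationSpec,
    timepoint: str,
    chrom: str,
    _plan_cache: dict | None = None,
) -> ContactMatrix:
    """Poisson-sampled symmetric contact matrix; deterministic in spec.seed."""
    spec.validate()
    plans = _plan_cache if _plan_cache is not None else _plans(spec)
    plan = plans[chrom]
    tp_idx = spec.timepoints.index(timepoint)
    chrom_idx = list(spec.chromsizes).index(chrom)
    e = expected_contact_map(spec, plan, tp_idx)
    rng = np.random.default_rng([spec.seed, 202, tp_idx, chrom_idx])
    upper = np.triu(rng.poisson(e)).astype(float)
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(chrom, spec.resolution_matrix, counts)


# ---------------------------------------------------------------------------
# Full bundle


def simulate_timecourse(spec: SimulationSpec) -> TimecourseBundle:
    spec.validate()
    plans = _plans(spec)
    n_tp = len(spec.timepoints)
    res = spec.resolution_matrix
    res_pc1 = spec.resolution_pc1
    per_block_pc1 = spec.block_size // res_pc1

    matrices = {
        tp: {
            chrom: simulate_contact_map(spec, tp, chrom, plans)
            for chrom in spec.chromsizes
        }
        for tp in spec.timepoints
    }

    # planted PC1 tracks (block sign * amplitude + small jitter, sign-safe)
    pc1 = {}
    for t, tp in enumerate(spec.timepoints):
        values = {}
        for ci, (chrom, plan) in enumerate(plans.items()):
            rng = np.random.default_rng([spec.seed, 303, t, ci])
            sign = np.repeat(plan.block_sign[:, t], per_block_pc1).astype(float)
            jitter = rng.normal(0, spec.pc1_jitter_sd, sign.size)
            jitter = np.clip(jitter, -0.5 * spec.pc1_amplitude, 0.5 * spec.pc1_amplitude)
            values[chrom] = sign * spec.pc1_amplitude + sign * np.abs(jitter)
        pc1[tp] = BinnedTrack(res_pc1, values, spec.chromsizes)

    # boundary / TAD interval sets per timepoint
    boundaries = {}
    tads = {}
    for t, tp in enumerate(spec.timepoints):
        brows, trows = [], []
        for chrom, plan in plans.items():
            bounds = plan.boundaries_at(t)
            for pos in bounds:
                brows.append((chrom, pos * res, (pos + 1) * res))
            edges = [0] + bounds + [plan.n_bins]
            for a, b in zip(edges[:-1], edges[1:]):
                trows.append((chrom, a * res, b * res))
        boundaries[tp] = IntervalSet(
            pd.DataFrame(brows, columns=["chrom", "start", "end"]), spec.chromsizes
        )
        tads[tp] = IntervalSet(
            pd.DataFrame(trows, columns=["chrom", "start", "end"]), spec.chromsizes
        )

    # loop sets per loop timepoint
    loops = {}
    for lt, tp in enumerate(spec.loop_timepoints):
        rows = []
        for chrom, plan in plans.items():
            for a, b in plan.loops_at(lt):
                rows.append((chrom, a * res, (a + 1) * res, b * res, (b + 1) * res))
        loops[tp] = LoopSet(
            pd.DataFrame(rows, columns=["chrom", "startA", "endA", "startB", "endB"])
        )

    # gene catalog, density, expression
    gene_rows = []
    for chrom, plan in plans.items():
        gene_rows += [dict(r) for r in plan.markers]
        gene_rows += [dict(r) for r in plan.background_genes]
    gdf = pd.DataFrame(gene_rows)
    genes = GeneCatalog(gdf[GeneCatalog.COLUMNS], spec.chromsizes)

    density_vals = {}
    for chrom, size in spec.chromsizes.items():
        nb = size // res_pc1
        vec = np.zeros(nb)
        sub = genes.df[genes.df["chrom"] == chrom]
        np.add.at(vec, (sub["tss"].to_numpy() // res_pc1).astype(int), 1.0)
        density_vals[chrom] = vec
    gene_density = BinnedTrack(res_pc1, density_vals, spec.chromsizes)

    expr_rng = np.random.default_rng([spec.seed, 404])
    marker_block = {}
    silent = set()
    for chrom, plan in plans.items():
        silent |= plan.silent_ids
        for r in plan.markers:
            marker_block[r["id"]] = (chrom, r["block"])
    sample_cols = [
        f"{tp}_{r + 1}" for tp in spec.timepoints for r in range(spec.n_replicates)
    ]
    log2cpm = np.empty((len(genes), n_tp * spec.n_replicates))
    ids = genes.df["id"].tolist()
    base = np.where(
        [g in silent for g in ids],
        expr_rng.uniform(0.1, 0.8, len(ids)),
        expr_rng.uniform(1.5, 6.0, len(ids)),
    )
    amp = spec.pc1_amplitude
    for gi, gid in enumerate(ids):
        for t in range(n_tp):
            mu = base[gi]
            if gid in marker_block:
                chrom, b = marker_block[gid]
                s = plans[chrom].block_sign[b]
                mu = base[gi] + spec.beta * amp * (s[t] - s[0])
            for r in range(spec.n_replicates):
                log2cpm[gi, t * spec.n_replicates + r] = mu + expr_rng.normal(
                    0, spec.expression_noise_sd
                )
    cpm = np.clip(2.0**log2cpm - 1.0, 0, None)
    expression = pd.DataFrame(cpm, index=pd.Index(ids, name="gene_id"), columns=sample_cols)

    truth = _truth_tables(spec, plans)
    return TimecourseBundle(
        spec=spec,
        timepoints=tuple(spec.timepoints),
        loop_timepoints=spec.loop_timepoints,
        chromsizes=dict(spec.chromsizes),
        matrices=matrices,
        pc1=pc1,
        boundaries=boundaries,
        tads=tads,
        loops=loops,
        genes=genes,
        expression=expression,
        gene_density=gene_density,
        truth=truth,
    )


def _truth_tables(spec: SimulationSpec, plans: Mapping[str, _ChromPlan]) -> dict:
    res = spec.resolution_matrix
    res_pc1 = spec.resolution_pc1
    per_block_pc1 = spec.block_size // res_pc1

    comp = []
    for chrom, plan in plans.items():
        for b in range(plan.n_blocks):
            for k in range(per_block_pc1):
                bin_i = b * per_block_pc1 + k
                comp.append(
                    (
                        chrom,
                        bin_i,
                        bin_i * res_pc1,
                        (bin_i + 1) * res_pc1,
                        plan.block_label[b],
                        plan.block_switch[b],
                    )
                )
    comp_df = pd.DataFrame(
        comp, columns=["chrom", "bin", "start", "end", "label", "switch_interval"]
    )

    bnd = []
    for chrom, plan in plans.items():
        for pos in plan.stable_boundaries:
            bnd.append((chrom, pos, pos * res + res // 2, "stable", -1))
        for pos, k in plan.gained_boundaries.items():
            bnd.append((chrom, pos, pos * res + res // 2, "gained", k))
        for pos, k in plan.lost_boundaries.items():
            bnd.append((chrom, pos, pos * res + res // 2, "lost", k))
    bnd_df = pd.DataFrame(
        bnd, columns=["chrom", "bin", "midpoint", "kind", "event_timepoint"]
    )

    hubs = []
    for chrom, plan in plans.items():
        for anchor, label, event, presence, feet in plan.hubs:
            near = [f[0] for f in feet]
            hubs.append(
                (
                    chrom,
                    min(near) * res,
                    (max(near) + 1) * res,
                    label,
                    event,
                    "".join("1" if p else "0" for p in presence),
                )
            )
    hub_df = pd.DataFrame(
        hubs, columns=["chrom", "start", "end", "label", "event_timepoint", "presence"]
    )

    markers = []
    for chrom, plan in plans.items():
        for r in plan.markers:
            markers.append((r["id"], chrom, r["block"], spec.beta))
    marker_df = pd.DataFrame(markers, columns=["gene_id", "chrom", "block", "beta"])

    comms = []
    for chrom, plan in plans.items():
        for cid, members in plan.communities:
            comms.append((cid, chrom, ",".join(members), len(members)))
    comm_df = pd.DataFrame(comms, columns=["community_id", "chrom", "gene_ids", "n_genes"])

    return {
        "compartments": comp_df,
        "boundaries": bnd_df,
        "hubs": hub_df,
        "markers": marker_df,
        "communities": comm_df,
    }


# ---------------------------------------------------------------------------
# On-disk bundle (plain-text formats only)


def write_bundle(bundle: TimecourseBundle, outdir) -> list:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(path):
        written.append(str(path))
        return path

    with open(_w(outdir / "chrom.sizes"), "w") as fh:
        for c, s in bundle.chromsizes.items():
            fh.write(f"{c}\t{s}\n")
    with open(_w(outdir / "timepoints.txt"), "w") as fh:
        fh.write("\t".join(bundle.timepoints) + "\n")
        fh.write("\t".join(bundle.loop_timepoints) + "\n")
    for tp in bundle.timepoints:
        for chrom, mat in bundle.matrices[tp].items():
            mat.write_triplets(_w(outdir / f"matrix_{tp}_{chrom}.txt"))
        bundle.pc1[tp].to_bedgraph(_w(outdir / f"pc1_{tp}.bedgraph"))
        bundle.boundaries[tp].to_bed(_w(outdir / f"boundaries_{tp}.bed"))
        bundle.tads[tp].to_bed(_w(outdir / f"tads_{tp}.bed"))
    for tp in bundle.loop_timepoints:
        bundle.loops[tp].to_bedpe(_w(outdir / f"loops_{tp}.bedpe"))
    bundle.genes.to_tsv(_w(outdir / "genes.tsv"))
    bundle.expression.to_csv(_w(outdir / "expression.tsv"), sep="\t")
    bundle.gene_density.to_bedgraph(_w(outdir / "gene_density.bedgraph"))
    for name, df in bundle.truth.items():
        df.to_csv(_w(outdir / f"truth_{name}.tsv"), sep="\t", index=False)
    return written


def read_bundle(indir, spec: SimulationSpec | None = None) -> TimecourseBundle:
    indir = Path(indir)
    chromsizes = read_chrom_sizes(indir / "chrom.sizes")
    with open(indir / "timepoints.txt") as fh:
        timepoints = tuple(fh.readline().split())
        loop_timepoints = tuple(fh.readline().split())
    spec = spec or SimulationSpec(
        timepoints=timepoints,
        n_loop_timepoints=len(loop_timepoints),
        chromsizes=chromsizes,
    )
    matrices = {
        tp: {
            chrom: ContactMatrix.read_triplets(indir / f"matrix_{tp}_{chrom}.txt")
            for chrom in chromsizes
        }
        for tp in timepoints
    }
    res_pc1 = spec.resolution_pc1
    pc1 = {
        tp: BinnedTrack.from_bedgraph(indir / f"pc1_{tp}.bedgraph", res_pc1, chromsizes)
        for tp in timepoints
    }
    boundaries = {
        tp: IntervalSet.from_bed(indir / f"boundaries_{tp}.bed", chromsizes)
        for tp in timepoints
    }
    tads = {
        tp: IntervalSet.from_bed(indir / f"tads_{tp}.bed", chromsizes)
        for tp in timepoints
    }
    loops = {
        tp: LoopSet.from_bedpe(indir / f"loops_{tp}.bedpe") for tp in loop_timepoints
    }
    genes = GeneCatalog.from_tsv(indir / "genes.tsv", chromsizes)
    expression = read_expression(indir / "expression.tsv")
    gene_density = BinnedTrack.from_bedgraph(
        indir / "gene_density.bedgraph", res_pc1, chromsizes
    )
    truth = {}
    for name in ("compartments", "boundaries", "hubs", "markers", "communities"):
        p = indir / f"truth_{name}.tsv"
        if p.exists():
            truth[name] = pd.read_csv(p, sep="\t")
    return TimecourseBundle(
        spec=spec,
        timepoints=timepoints,
        loop_timepoints=loop_timepoints,
        chromsizes=chromsizes,
        matrices=matrices,
        pc1=pc1,
        boundaries=boundaries,
        tads=tads,
        loops=loops,
        genes=genes,
        expression=expression,
        gene_density=gene_density,
        truth=truth,
    )
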