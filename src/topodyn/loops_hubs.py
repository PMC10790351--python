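"""Loop-set comparison, loop shuffling, loop-hub calling and hub dynamics.

A hub is a genomic region densely covered by loop feet: sliding 30 kb
windows (3 kb step) with at least 5 overlapping feet are stitched (gaps up
to 30 kb), the stitched regions are merged across timepoints, and a merged
region counts as present at a timepoint when at least 5 feet cover it
there.  Feet are counted as occurrences: a loop whose two feet fall in the
same window contributes 2.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import BinnedTrack, ChromSizes, IntervalSet, LoopSet

__all__ = [
    "merge_loops_across_timepoints",
    "shuffle_loops",
    "call_hubs",
    "classify_hub_dynamics",
    "classify_hub_pc1_trend",
    "hub_feature_overlap",
]

HUB_DYNAMICS_LABELS = ("stable", "gained", "lost", "other")
PC1_TREND_LABELS = ("stable_increase", "stable_decrease", "other")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_loops_across_timepoints(
    loop_sets: Mapping[str, LoopSet],
    resolution: int,
    anchor_tolerance: int = 1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Union loop list with per-timepoint presence.

    Loops are matched when both feet fall within ``anchor_tolerance`` bins of
    each other (transitive: matching is by connected components, so chains of
    pairwise matches collapse into one union loop).  Returns the union frame
    (feet of the first-seen member; ``present_<tp>`` boolean columns;
    ``n_timepoints``) and the histogram of loops present in exactly k
    timepoints.
    """
    timepoints = list(loop_sets)
    if len(timepoints) < 2:
        raise ValueError("need >=2 loop sets")
    frames = []
    for t, tp in enumerate(timepoints):
        df = loop_sets[tp].df.copy()
        df["tp"] = t
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    pooled["abin"] = pooled["startA"] // resolution
    pooled["bbin"] = pooled["startB"] // resolution
    pooled = pooled.sort_values(["chrom", "abin", "bbin"], kind="stable").reset_index(
        drop=True
    )
    uf = _UnionFind(len(pooled))
    chroms = pooled["chrom"].to_numpy()
    abins = pooled["abin"].to_numpy()
    bbins = pooled["bbin"].to_numpy()
    tol = anchor_tolerance
    for i in range(len(pooled)):
        j = i + 1
        while j < len(pooled) and chroms[j] == chroms[i] and abins[j] - abins[i] <= tol:
            if abs(bbins[j] - bbins[i]) <= tol:
                uf.union(i, j)
            j += 1
    roots = np.array([uf.find(i) for i in range(len(pooled))])
    rows = []
    for root in pd.unique(roots):
        members = pooled[roots == root]
        first = members.iloc[0]
        presence = np.zeros(len(timepoints), dtype=bool)
        presence[members["tp"].unique()] = True
        rows.append(
            [first["chrom"], first["startA"], first["endA"], first["startB"], first["endB"]]
            + presence.tolist()
            + [int(presence.sum())]
        )
    cols = ["chrom", "startA", "endA", "startB", "endB"] + [
        f"present_{tp}" for tp in timepoints
    ] + ["n_timepoints"]
    union = pd.DataFrame(rows, columns=cols)
    hist = union["n_timepoints"].value_counts().sort_index()
    hist.index.name = "n_timepoints"
    return union, hist


def shuffle_loops(
    loops: LoopSet,
    chromsizes: ChromSizes,
    n: int = 100,
    seed: int = 0,
) -> list[LoopSet]:
    """Random loop placements preserving foot widths and foot-to-foot span.

    Each null loop keeps its chromosome; the pair is translated to a uniform
    random position within bounds.  Loops whose span exceeds the chromosome
    are dropped with a warning.  Seed-deterministic (per-replicate streams).
    """
    df = loops.df
    w_a = (df["endA"] - df["startA"]).to_numpy()
    w_b = (df["endB"] - df["startB"]).to_numpy()
    span = (df["startB"] - df["startA"]).to_numpy()
    sizes = df["chrom"].map(chromsizes).to_numpy()
    max_start = sizes - span - w_b
    droppable = max_start < 0
    if droppable.any():
        warnings.warn(f"{int(droppable.sum())} loops longer than their chromosome dropped")
    out = []
    for rep in range(n):
        rng = np.random.default_rng([seed, rep])
        new_a = rng.integers(0, max_start.clip(min=0) + 1)
        sub = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "startA": new_a,
                "endA": new_a + w_a,
                "startB": new_a + span,
                "endB": new_a + span + w_b,
            }
        )[~droppable]
        out.append(LoopSet(sub))
    return out


# ---------------------------------------------------------------------------
# Hubs


def _window_foot_counts(
    feet: pd.DataFrame, chrom_size: int, window: int, step: int
) -> np.ndarray:
    """Feet-occurrence count per sliding window (windows tile from 0)."""
    n_win = -(-chrom_size // step)  # every start < chrom_size; partial windows kept
    delta = np.zeros(n_win + 1)
    for s, e in zip(feet["start"].to_numpy(), feet["end"].to_numpy()):
        # windows [w*step, w*step+window) overlapping [s, e) by >=1 bp
        lo = max(0, (s - window) // step + 1)
        hi = min(n_win - 1, (e - 1) // step)
        if hi >= lo:
            delta[lo] += 1
            delta[hi + 1] -= 1
    return np.cumsum(delta[:-1])


def _stitch(
    retained_windows: np.ndarray, chrom_size: int, window: int, step: int, gap: int
) -> list[tuple[int, int]]:
    """Merge retained windows allowing up to ``gap`` bp between them."""
    regions: list[list[int]] = []
    for w in retained_windows:
        s = int(w * step)
        e = int(min(s + window, chrom_size))
        if regions and s - regions[-1][1] <= gap:
            regions[-1][1] = max(regions[-1][1], e)
        else:
            regions.append([s, e])
    return [(s, e) for s, e in regions]


def _merge_union(regions: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Plain interval union (>=1 bp overlap required to merge)."""
    out: list[list] = []
    for chrom, s, e in sorted(regions):
        if out and out[-1][0] == chrom and s < out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([chrom, s, e])
    return [tuple(r) for r in out]


def _count_feet_in_regions(
    feet: pd.DataFrame, regions: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    counts = np.zeros(len(regions), dtype=int)
    by_chrom = dict(tuple(feet.groupby("chrom", sort=False)))
    for i, (chrom, s, e) in enumerate(regions):
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        counts[i] = int(
            ((sub["start"].to_numpy() < e) & (sub["end"].to_numpy() > s)).sum()
        )
    return counts


def call_hubs(
    loop_sets: Mapping[str, LoopSet],
    chromsizes: ChromSizes,
    window: int = 30_000,
    step: int = 3_000,
    min_feet: int = 5,
    stitch_gap: int = 30_000,
) -> pd.DataFrame:
    """Loop-foot hubs from per-timepoint loop sets.

    Returns a frame with (chrom, start, end), per-timepoint foot coverage
    ``coverage_<tp>`` and presence ``present_<tp>`` (coverage >= min_feet,
    inclusive).
    """
    timepoints = list(loop_sets)
    feet_by_tp = {tp: loop_sets[tp].feet().df for tp in timepoints}
    per_tp_regions: list[tuple[str, int, int]] = []
    for tp in timepoints:
        feet = feet_by_tp[tp]
        for chrom, size in chromsizes.items():
            sub = feet[feet["chrom"] == chrom]
            if sub.empty:
                continue
            counts = _window_foot_counts(sub, size, window, step)
            retained = np.flatnonzero(counts >= min_feet)
            for s, e in _stitch(retained, size, window, step, stitch_gap):
                per_tp_regions.append((chrom, s, e))
    merged = _merge_union(per_tp_regions)
    if not merged:
        cols = ["chrom", "start", "end"]
        for tp in timepoints:
            cols += [f"coverage_{tp}", f"present_{tp}"]
        return pd.DataFrame(columns=cols)
    out = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    for tp in timepoints:
        cov = _count_feet_in_regions(feet_by_tp[tp], merged)
        out[f"coverage_{tp}"] = cov
        out[f"present_{tp}"] = cov >= min_feet
    return out


def classify_hub_dynamics(presence: Sequence[bool]) -> str:
    """stable / gained / lost / other from a hub presence vector.

    gained: absent at the first timepoint, present at the last, and never
    absent again once present; lost: the mirror; stable: always present.
    """
    p = np.asarray(presence, dtype=bool)
    if p.all():
        return "stable"
    if p.any() and not p[0] and p[-1]:
        first = int(np.argmax(p))
        if p[first:].all():
            return "gained"
    if p[0] and not p[-1]:
        first_zero = int(np.argmax(~p))
        if not p[first_zero:].any():
            return "lost"
    return "other"


def hub_dynamics_table(hubs: pd.DataFrame, timepoints: Sequence[str]) -> pd.Series:
    cols = [f"present_{tp}" for tp in timepoints]
    return hubs[cols].apply(lambda r: classify_hub_dynamics(r.to_numpy()), axis=1)


def classify_hub_pc1_trend(means: Sequence[float]) -> str | None:
    """Label the per-timepoint mean PC1 at a hub.

    stable_increase: the last value exceeds the first and every later
    timepoint is >= every earlier one (monotone non-decreasing);
    stable_decrease is the mirror; anything else is other.  Returns None
    when any mean is missing.
    """
    v = np.asarray(means, dtype=float)
    if not np.all(np.isfinite(v)):
        return None
    d = np.diff(v)
    if v[-1] > v[0] and (d >= 0).all():
        return "stable_increase"
    if v[-1] < v[0] and (d <= 0).all():
        return "stable_decrease"
    return "other"


def hub_pc1_means(
    hubs: pd.DataFrame, pc1_tracks: Mapping[str, BinnedTrack]
) -> pd.DataFrame:
    """Coverage-weighted mean PC1 over each hub interval, per timepoint."""
    out = {}
    for tp, track in pc1_tracks.items():
        res = track.resolution
        vals = []
        for row in hubs.itertuples(index=False):
            vec = track.values.get(row.chrom)
            if vec is None:
                vals.append(np.nan)
                continue
            b0 = row.start // res
            b1 = -(-row.end // res)
            w, v = [], []
            for b in range(b0, min(b1, len(vec))):
                if not np.isfinite(vec[b]):
                    continue
                ov = min(row.end, (b + 1) * res) - max(row.start, b * res)
                w.append(ov)
                v.append(vec[b])
            vals.append(float(np.average(v, weights=w)) if w else np.nan)
        out[tp] = vals
    return pd.DataFrame(out, index=hubs.index)


def hub_pc1_trend_table(
    hubs: pd.DataFrame, pc1_tracks: Mapping[str, BinnedTrack]
) -> pd.Series:
    means = hub_pc1_means(hubs, pc1_tracks)
    return means.apply(lambda r: classify_hub_pc1_trend(r.to_numpy()), axis=1)


def hub_feature_overlap(
    hubs: pd.DataFrame,
    features: IntervalSet,
    timepoints: Sequence[str],
    n_quartiles: int = 4,
) -> pd.DataFrame:
    """Fraction of (score-quartiled) features overlapped by >=1 present hub.

    Quartile 1 holds the lowest-scoring features.  Without scores all
    features form a single group (quartile 0).
    """
    fdf = features.df.reset_index(drop=True)
    if fdf["score"].notna().all() and len(fdf) >= n_quartiles:
        quart = pd.qcut(fdf["score"].rank(method="first"), n_quartiles, labels=False) + 1
    else:
        quart = pd.Series(0, index=fdf.index)
    rows = []
    for tp in timepoints:
        present = hubs[hubs[f"present_{tp}"]] if f"present_{tp}" in hubs else hubs
        by_chrom = dict(tuple(present.groupby("chrom", sort=False)))
        hit = np.zeros(len(fdf), dtype=bool)
        for i, row in enumerate(fdf.itertuples(index=False)):
            sub = by_chrom.get(row.chrom)
            if sub is None:
                continue
            hit[i] = bool(
                ((sub["start"].to_numpy() < row.end) & (sub["end"].to_numpy() > row.start)).any()
            )
        for q in sorted(quart.unique()):
            mask = (quart == q).to_numpy()
            rows.append((tp, int(q), float(hit[mask].mean()) if mask.any() else np.nan))
    return pd.DataFrame(rows, columns=["timepoint", "quartile", "fraction_overlapped"])
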