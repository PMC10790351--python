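"""A/B compartment scores, trajectory classes, saddle strength, and
compartment-expression coupling.

The compartment score (PC1) is the first principal component of the Pearson
correlation matrix of the distance-normalised (observed/expected) contact
map, computed on 100 kb sliding windows advanced in 50 kb steps and oriented
so that it correlates positively with a reference track (gene density), the
convention under which gene-dense active chromatin is "A" (PC1 > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import BinnedTrack, ContactMatrix, GeneCatalog

__all__ = [
    "TRAJECTORY_LABELS",
    "SaddleResult",
    "observed_over_expected",
    "call_compartments",
    "call_compartments_bundle",
    "classify_bin_trajectory",
    "classify_track_trajectories",
    "switch_mass_summary",
    "saddle",
    "mahalanobis_change",
    "correlate_compartment_expression",
    "rank_monotone_expression",
    "de_overlap_with_switches",
    "genes_to_bins",
]

TRAJECTORY_LABELS = ("stable_A", "stable_B", "stable_AtoB", "stable_BtoA", "dynamic")


def observed_over_expected(counts: np.ndarray, valid: np.ndarray | None = None):
    """O/E matrix with the expected value at each distance = diagonal mean.

    Bins flagged invalid (or with zero marginal) are excluded from the
    expected-value estimate and set to NaN in the output.
    """
    n = counts.shape[0]
    if valid is None:
        valid = counts.sum(axis=0) > 0
    expected = np.full(n, np.nan)
    vmask = np.outer(valid, valid)
    for d in range(n):
        diag = np.diagonal(counts, d)
        keep = np.diagonal(vmask, d)
        if keep.any():
            expected[d] = diag[keep].mean()
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = counts / expected[dist]
    oe[~vmask] = np.nan
    return oe, expected


def call_compartments(
    matrix: ContactMatrix,
    reference: np.ndarray,
    resolution_pc1: int | None = None,
    window_bins: int = 2,
) -> np.ndarray:
    """Compartment score for one chromosome.

    The matrix is aggregated to the PC1 resolution (the 50 kb step), the O/E
    map is averaged over ``window_bins``-wide sliding windows (100 kb windows
    at the default step), and PC1 of the Pearson correlation matrix is
    extracted and sign-oriented against ``reference`` (one value per PC1 bin,
    e.g. gene density).  Unscorable bins are NaN.
    """
    if resolution_pc1 is not None and resolution_pc1 != matrix.resolution:
        matrix = matrix.rebin(resolution_pc1)
    counts = matrix.counts
    n = counts.shape[0]
    out = np.full(n, np.nan)
    if n < 4 * window_bins:
        warnings.warn(f"{matrix.chrom}: too short for compartment calling")
        return out
    valid = counts.sum(axis=0) > 0
    if valid.sum() < 4 * window_bins:
        warnings.warn(f"{matrix.chrom}: insufficient coverage")
        return out
    oe, _ = observed_over_expected(counts, valid)
    sub = oe[np.ix_(valid, valid)]
    # sparse long-range diagonals can be entirely empty; O/E there is
    # uninformative, so fill with the neutral value before correlating
    sub = np.where(np.isfinite(sub), sub, 1.0)
    if window_bins > 1:
        m = sub.shape[0]
        k = window_bins
        cs = np.cumsum(np.cumsum(np.pad(sub, ((1, 0), (1, 0))), axis=0), axis=1)
        mm = m - k + 1
        sm = (
            cs[k : k + mm, k : k + mm]
            - cs[0:mm, k : k + mm]
            - cs[k : k + mm, 0:mm]
            + cs[0:mm, 0:mm]
        ) / (k * k)
        sub = sm  # one value per step; the final partial windows are dropped
        scored = np.flatnonzero(valid)[:mm]
    else:
        scored = np.flatnonzero(valid)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    if not np.all(np.isfinite(corr)):
        warnings.warn(f"{matrix.chrom}: degenerate correlation matrix")
        return out
    evals, evecs = np.linalg.eigh(corr)
    pc1 = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    ref = np.asarray(reference, dtype=float)[scored]
    ok = np.isfinite(ref)
    if ok.sum() >= 2 and np.std(pc1[ok]) > 0 and np.std(ref[ok]) > 0:
        r = np.corrcoef(pc1[ok], ref[ok])[0, 1]
        if r < 0:
            pc1 = -pc1
    out[scored] = pc1
    return out


def call_compartments_bundle(
    matrices: Mapping[str, ContactMatrix],
    reference: BinnedTrack,
    resolution_pc1: int,
    window_bins: int = 2,
) -> BinnedTrack:
    """Compartment track over all chromosomes of one timepoint."""
    values = {
        chrom: call_compartments(
            mat, reference.values[chrom], resolution_pc1, window_bins
        )
        for chrom, mat in matrices.items()
    }
    return BinnedTrack(resolution_pc1, values, reference.chromsizes)


# ---------------------------------------------------------------------------
# Trajectory classification


def classify_bin_trajectory(values: Sequence[float]) -> tuple[str | None, int | None]:
    """Label a per-bin PC1 trajectory by its sign-switch count.

    Returns ``(label, switch_interval)``; ``switch_interval`` is the index of
    the timepoint at which the single switch first takes effect (switching
    labels only).  Exact zeros carry the previous sign; leading zeros are
    dropped.  Any missing value withholds the label (``(None, None)``).
    """
    vals = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vals)):
        return None, None
    signs: list[int] = []
    idxs: list[int] = []
    prev = 0
    for i, v in enumerate(vals):
        s = int(np.sign(v)) or prev
        if s == 0:
            continue  # leading zero
        signs.append(s)
        idxs.append(i)
        prev = s
    if not signs:
        return None, None
    arr = np.array(signs)
    changes = np.flatnonzero(arr[1:] != arr[:-1])
    if changes.size == 0:
        return ("stable_A" if arr[0] > 0 else "stable_B"), None
    if changes.size == 1:
        k = idxs[changes[0] + 1]
        return ("stable_AtoB" if arr[0] > 0 else "stable_BtoA"), k
    return "dynamic", None


def classify_track_trajectories(
    tracks: Sequence[BinnedTrack],
) -> tuple[dict, dict, int]:
    """Per-bin labels across chromosomes.

    Returns ``(labels, switch_intervals, n_withheld)`` where each dict maps
    chromosome to an object/int array (label None / interval -1 where
    withheld).
    """
    chroms = list(tracks[0].values)
    labels: dict = {}
    switches: dict = {}
    n_withheld = 0
    for chrom in chroms:
        stack = np.stack([t.values[chrom] for t in tracks], axis=1)
        lab = np.empty(stack.shape[0], dtype=object)
        sw = np.full(stack.shape[0], -1)
        for i in range(stack.shape[0]):
            label, k = classify_bin_trajectory(stack[i])
            lab[i] = label
            if label is None:
                n_withheld += 1
            if k is not None:
                sw[i] = k
        labels[chrom] = lab
        switches[chrom] = sw
    return labels, switches, n_withheld


def switch_mass_summary(
    labels: Mapping[str, np.ndarray],
    switch_intervals: Mapping[str, np.ndarray],
    bin_size: int,
) -> tuple[pd.DataFrame, pd.Series]:
    """Genomic mass (Mb) per trajectory label and switch-timepoint histogram."""
    all_labels = np.concatenate([labels[c] for c in labels])
    all_sw = np.concatenate([switch_intervals[c] for c in switch_intervals])
    rows = []
    for lab in TRAJECTORY_LABELS:
        n = int((all_labels == lab).sum())
        rows.append((lab, n, n * bin_size / 1e6))
    summary = pd.DataFrame(rows, columns=["label", "n_bins", "mb"])
    hist = pd.Series(all_sw[all_sw >= 0]).value_counts().sort_index()
    hist.index.name = "switch_timepoint"
    return summary, hist


# ---------------------------------------------------------------------------
# Saddle


@dataclass
class SaddleResult:
    """Quantile-sorted mean O/E matrix with corner-block strengths.

    Bins are sorted by PC1 ascending, so the B-most quantile is row 0; the
    BB corner is the top-left ``corner x corner`` block of ``matrix`` and AA
    the bottom-right.  ``ab`` averages the two heterotypic corners.
    """

    matrix: np.ndarray
    aa: float
    bb: float
    ab: float
    n_quantiles: int
    corner: int
    arms: list


def saddle(
    matrices: Mapping[str, ContactMatrix] | ContactMatrix,
    pc1: BinnedTrack | np.ndarray,
    n_quantiles: int = 40,
    corner: int = 5,
) -> SaddleResult:
    """Saddle matrix: mean O/E between PC1-quantile bin groups.

    Each chromosome (arm) is processed separately; the per-arm saddle
    matrices are averaged.  Arms with fewer scored bins than ``n_quantiles``
    are skipped with a warning.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = {matrices.chrom: matrices}
        pc1_vals = {list(matrices)[0]: np.asarray(pc1, dtype=float)}
    else:
        pc1_vals = pc1.values if isinstance(pc1, BinnedTrack) else pc1
    per_arm = []
    arms = []
    for chrom, mat in matrices.items():
        vec = np.asarray(pc1_vals[chrom], dtype=float)
        if len(vec) != mat.n_bins:
            raise ValueError(f"{chrom}: PC1 and matrix binnings differ")
        valid = (mat.counts.sum(axis=0) > 0) & np.isfinite(vec)
        if valid.sum() < n_quantiles:
            warnings.warn(f"{chrom}: fewer scored bins than quantiles; skipped")
            continue
        oe, _ = observed_over_expected(mat.counts, valid)
        order = np.flatnonzero(valid)[np.argsort(vec[valid], kind="stable")]
        groups = np.array_split(order, n_quantiles)
        s = np.full((n_quantiles, n_quantiles), np.nan)
        for a in range(n_quantiles):
            for b in range(a, n_quantiles):
                block = oe[np.ix_(groups[a], groups[b])]
                m = np.nanmean(block) if np.isfinite(block).any() else np.nan
                s[a, b] = m
                s[b, a] = m
        per_arm.append(s)
        arms.append(chrom)
    if not per_arm:
        raise ValueError("no arm had enough scored bins")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_s = np.nanmean(np.stack(per_arm), axis=0)
    c = corner
    bb = float(np.nanmean(mean_s[:c, :c]))
    aa = float(np.nanmean(mean_s[-c:, -c:]))
    ab = float(
        np.nanmean([np.nanmean(mean_s[:c, -c:]), np.nanmean(mean_s[-c:, :c])])
    )
    return SaddleResult(mean_s, aa, bb, ab, n_quantiles, corner, arms)


# ---------------------------------------------------------------------------
# Mahalanobis change detection


def mahalanobis_change(
    tracks: Sequence[BinnedTrack],
    threshold: float = 1.0,
) -> tuple[BinnedTrack, dict]:
    """Per-bin Mahalanobis distance of the multi-timepoint PC1 vector.

    The mean and covariance are estimated over all scored bins genome-wide;
    the covariance diagonal is regularised by ``1e-8 * trace / dim``.  Bins
    with any missing value are excluded.  Returns the MD track and a dict of
    boolean flag vectors (MD > threshold).
    """
    if len(tracks) < 2:
        raise ValueError("need at least two timepoints")
    chroms = list(tracks[0].values)
    stacks = {c: np.stack([t.values[c] for t in tracks], axis=1) for c in chroms}
    complete = {c: np.all(np.isfinite(s), axis=1) for c, s in stacks.items()}
    x = np.concatenate([stacks[c][complete[c]] for c in chroms], axis=0)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("too few complete bins to estimate covariance")
    mu = x.mean(axis=0)
    sigma = np.cov(x, rowvar=False)
    dim = sigma.shape[0]
    sigma = sigma + np.eye(dim) * (1e-8 * np.trace(sigma) / dim)
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance singular after regularization") from exc
    md_vals = {}
    flags = {}
    for c in chroms:
        md = np.full(stacks[c].shape[0], np.nan)
        d = stacks[c][complete[c]] - mu
        md[complete[c]] = np.sqrt(np.einsum("ij,jk,ik->i", d, sigma_inv, d))
        md_vals[c] = md
        flags[c] = md > threshold
    track = BinnedTrack(tracks[0].resolution, md_vals, tracks[0].chromsizes)
    return track, flags


# ---------------------------------------------------------------------------
# Compartment-expression coupling


def genes_to_bins(genes: GeneCatalog, track: BinnedTrack) -> pd.DataFrame:
    """Map each gene's TSS to its track bin; adds columns (bin, chrom)."""
    df = genes.df[["id", "chrom", "tss"]].copy()
    df["bin"] = df["tss"] // track.resolution
    return df


def correlate_compartment_expression(
    pc1_tracks: Mapping[str, BinnedTrack],
    expression: pd.DataFrame,
    genes: GeneCatalog,
    gene_ids: Iterable[str],
    t_ref: str,
    t_cmp: str,
    pseudocount: float = 1.0,
):
    """Spearman correlation of delta-PC1 vs delta-log2(CPM) over a gene set.

    delta-PC1 is PC1(t_cmp) - PC1(t_ref) at the TSS bin; delta-expression is
    the change in mean log2(CPM + pseudocount) between the two timepoints.
    Genes in unscored bins are dropped (counted); <10 mapped genes is an
    error.
    """
    from .genome_model import parse_sample_groups

    gene_ids = list(gene_ids)
    sub = genes.subset(gene_ids)
    track_ref, track_cmp = pc1_tracks[t_ref], pc1_tracks[t_cmp]
    groups = parse_sample_groups(expression.columns)
    dpc1, dexpr = [], []
    n_dropped = 0
    for row in sub.df.itertuples(index=False):
        if row.id not in expression.index:
            n_dropped += 1
            continue
        b = row.tss // track_ref.resolution
        v_ref = track_ref.values[row.chrom][b]
        v_cmp = track_cmp.values[row.chrom][b]
        if not (np.isfinite(v_ref) and np.isfinite(v_cmp)):
            n_dropped += 1
            continue
        e = expression.loc[row.id]
        l_ref = np.log2(e[groups[t_ref]].to_numpy(dtype=float) + pseudocount).mean()
        l_cmp = np.log2(e[groups[t_cmp]].to_numpy(dtype=float) + pseudocount).mean()
        dpc1.append(v_cmp - v_ref)
        dexpr.append(l_cmp - l_ref)
    if len(dpc1) < 10:
        raise ValueError(f"only {len(dpc1)} genes mapped; need >=10")
    r, p = stats.spearmanr(dpc1, dexpr)
    return float(r), float(p), len(dpc1), n_dropped


def rank_monotone_expression(
    expression: pd.DataFrame,
    timepoints: Sequence[str],
    frac: float = 0.10,
    pseudocount: float = 1.0,
) -> tuple[list, list]:
    """Top/bottom deciles of monotone genes ranked by last/first CPM ratio.

    A gene is eligible if its mean CPM is monotone non-decreasing or
    non-increasing across all consecutive timepoints.  Eligible genes are
    ranked by (last + pc) / (first + pc); the top and bottom ``frac``
    fractions are returned.
    """
    if len(timepoints) < 3:
        raise ValueError("need >=3 timepoints")
    from .genome_model import parse_sample_groups

    groups = parse_sample_groups(expression.columns)
    means = pd.DataFrame(
        {tp: expression[groups[tp]].mean(axis=1) for tp in timepoints}
    )
    diffs = means.to_numpy()[:, 1:] - means.to_numpy()[:, :-1]
    inc = (diffs >= 0).all(axis=1)
    dec = (diffs <= 0).all(axis=1)
    eligible = inc | dec
    if not eligible.any():
        warnings.warn("no monotone genes")
        return [], []
    sub = means[eligible]
    ratio = (sub[timepoints[-1]] + pseudocount) / (sub[timepoints[0]] + pseudocount)
    order = ratio.sort_values(ascending=False, kind="stable")
    k = int(np.ceil(frac * len(order)))
    top = order.index[:k].tolist()
    bottom = order.index[-k:].tolist() if k else []
    return top, bottom


def de_overlap_with_switches(
    de_up: Iterable[str],
    de_down: Iterable[str],
    labels: Mapping[str, np.ndarray],
    genes: GeneCatalog,
    resolution: int,
) -> pd.DataFrame:
    """Counts of DE genes whose TSS falls in each trajectory-label class."""
    counts = {lab: {"up": 0, "down": 0} for lab in TRAJECTORY_LABELS}
    lookup = genes.df.set_index("id")
    for direction, ids in (("up", de_up), ("down", de_down)):
        for gid in ids:
            if gid not in lookup.index:
                continue
            row = lookup.loc[gid]
            lab_vec = labels.get(row["chrom"])
            if lab_vec is None:
                continue
            b = int(row["tss"]) // resolution
            if b >= len(lab_vec):
                continue
            lab = lab_vec[b]
            if lab is not None:
                counts[lab][direction] += 1
    return pd.DataFrame(counts).T.rename_axis("label")
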