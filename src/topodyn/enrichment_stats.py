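"""Permutation and shuffle-null enrichment statistics.

All permutation operations derive per-replicate random streams from the
master seed by replicate index, so results are seed-deterministic and
independent of any parallel scheduling.  Normalised ranks are always
``(r + 1) / (n + 1)`` with ``r`` the number of null values at least as large
as the observed one, so a rank is never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import ChromSizes, ContactMatrix, GeneCatalog, IntervalSet, LoopSet, overlap_join

__all__ = [
    "PermutationResult",
    "tss_contact_enrichment",
    "annotation_classes",
    "loop_annotation_enrichment",
    "gene_set_switch_enrichment",
    "interval_class_composition",
]


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    normalized_rank: float
    enrichment_ratio: float
    significant: bool
    level: float

    @classmethod
    def from_null(cls, observed: float, null: np.ndarray, level: float = 0.05):
        null = np.asarray(null, dtype=float)
        r = int((null >= observed).sum())
        rank = (r + 1) / (len(null) + 1)
        mean = null.mean() if len(null) else np.nan
        ratio = observed / mean if mean else np.nan
        return cls(float(observed), null, rank, float(ratio), rank < level, level)

    @property
    def z(self) -> float:
        sd = self.null.std(ddof=1) if len(self.null) > 1 else np.nan
        return (self.observed - self.null.mean()) / sd if sd else np.nan


def tss_contact_enrichment(
    matrix: ContactMatrix,
    tss_bins: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
    level: float = 0.05,
    window: int = 0,
) -> pd.DataFrame:
    """Per-gene permutation test of cis contact counts at the TSS bin.

    The statistic is the row sum of the TSS bin (diagonal excluded; with
    ``window`` k > 0, the sum over rows within +-k bins).  Null values are
    the same statistic at ``n_perm`` bins drawn uniformly from the same
    chromosome (bins with zero marginal excluded from the pool; drawn
    without replacement when the pool holds >= 2 n_perm bins, otherwise with
    replacement, flagged).
    """
    c = matrix.counts
    n = matrix.n_bins
    rowsum = c.sum(axis=1) - np.diagonal(c)
    if window > 0:
        k = window
        padded = np.pad(rowsum, k)
        stat = np.array([padded[i : i + 2 * k + 1].sum() for i in range(n)])
    else:
        stat = rowsum
    pool = np.flatnonzero(rowsum > 0)
    cols = [
        "bin", "observed", "null_mean", "null_sd", "ratio", "rank",
        "significant", "with_replacement",
    ]
    if pool.size == 0:
        warnings.warn(f"{matrix.chrom}: all-zero matrix; enrichment undefined")
        return pd.DataFrame(
            [
                (b, 0.0, np.nan, np.nan, np.nan, np.nan, False, False)
                for b in tss_bins
            ],
            columns=cols,
        )
    with_replacement = pool.size < 2 * n_perm
    if with_replacement:
        warnings.warn(
            f"{matrix.chrom}: pool of {pool.size} bins < 2*{n_perm}; sampling with replacement"
        )
    rows = []
    for gi, b in enumerate(tss_bins):
        rng = np.random.default_rng([seed, gi])
        gene_pool = pool[pool != b]  # the focal bin never enters its own null
        if with_replacement or gene_pool.size < n_perm:
            draw = rng.choice(gene_pool, n_perm, replace=True)
        else:
            draw = rng.choice(gene_pool, n_perm, replace=False)
        null = stat[draw]
        obs = stat[b]
        if obs == 0 and null.mean() == 0:
            warnings.warn(f"bin {b}: degenerate all-zero statistic")
            rows.append((b, 0.0, 0.0, 0.0, np.nan, np.nan, False, with_replacement))
            continue
        res = PermutationResult.from_null(obs, null, level)
        rows.append(
            (
                b,
                res.observed,
                float(null.mean()),
                float(null.std(ddof=1)),
                res.enrichment_ratio,
                res.normalized_rank,
                res.significant,
                with_replacement,
            )
        )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Loop / annotation enrichment


def annotation_classes(
    genes: GeneCatalog, promoter_pad: int = 2_000
) -> dict[str, pd.DataFrame]:
    """Priority-ordered annotation classes built from a gene catalog.

    promoter = TSS +- promoter_pad; gene_body = the full gene interval.  A
    foot is assigned the first class it overlaps; the fallback class is
    "intergenic".
    """
    g = genes.df
    promoter = pd.DataFrame(
        {
            "chrom": g["chrom"],
            "start": (g["tss"] - promoter_pad).clip(lower=0),
            "end": g["tss"] + promoter_pad + 1,
        }
    )
    body = g[["chrom", "start", "end"]].copy()
    return {"promoter": promoter, "gene_body": body}


def _classify_feet(feet: pd.DataFrame, classes: Mapping[str, pd.DataFrame]) -> pd.Series:
    label = pd.Series("intergenic", index=feet.index)
    unassigned = pd.Series(True, index=feet.index)
    for name, intervals in classes.items():
        if not unassigned.any():
            break
        hits = overlap_join(feet, intervals)
        idx = feet.index[pd.unique(hits["index_a"])] if len(hits) else []
        for i in idx:
            if unassigned[i]:
                label[i] = name
                unassigned[i] = False
    return label


def loop_annotation_enrichment(
    loops: LoopSet,
    expressed_genes: GeneCatalog,
    null_loop_sets: Sequence[LoopSet],
    classes: Mapping[str, pd.DataFrame] | None = None,
    promoter_pad: int = 2_000,
) -> pd.DataFrame:
    """log2 enrichment of unique gene/annotation pairs over shuffle nulls.

    For each loop with a foot in an expressed gene body, the opposite foot is
    annotated by the priority classes; the statistic is the number of unique
    (gene, class) pairs over the number of annotated feet.  Enrichment per
    class is log2(observed statistic / mean null statistic); classes absent
    from every null are flagged undefined.
    """
    if classes is None:
        classes = annotation_classes(expressed_genes, promoter_pad)

    def stats_for(ls: LoopSet) -> dict[str, float]:
        df = ls.df.reset_index(drop=True)
        gene_iv = expressed_genes.df[["chrom", "start", "end"]].reset_index(drop=True)
        foot_a = df[["chrom", "startA", "endA"]].rename(columns={"startA": "start", "endA": "end"})
        foot_b = df[["chrom", "startB", "endB"]].rename(columns={"startB": "start", "endB": "end"})
        ga = overlap_join(foot_a, gene_iv)
        gb = overlap_join(foot_b, gene_iv)
        gene_ids = expressed_genes.df["id"].to_numpy()
        # pairs: (gene at one foot, class of the other foot)
        other_feet = []
        pair_genes = []
        for hits, other in ((ga, foot_b), (gb, foot_a)):
            for li, gi in zip(hits["index_a"], hits["index_b"]):
                other_feet.append(other.iloc[li])
                pair_genes.append(gene_ids[gi])
        if not other_feet:
            return {"__total__": 0.0}
        of = pd.DataFrame(other_feet).reset_index(drop=True)
        labels = _classify_feet(of, classes)
        pairs = pd.DataFrame({"gene": pair_genes, "class": labels.to_numpy()})
        total = float(len(of))
        out = {"__total__": total}
        for cls_name, sub in pairs.groupby("class"):
            out[cls_name] = len(sub.drop_duplicates()) / total
        return out

    obs = stats_for(loops)
    nulls = [stats_for(ls) for ls in null_loop_sets]
    class_names = sorted(
        (set(obs) | set().union(*map(set, nulls))) - {"__total__"}
    ) if nulls else sorted(set(obs) - {"__total__"})
    rows = []
    for name in class_names:
        o = obs.get(name, 0.0)
        nv = np.array([d.get(name, 0.0) for d in nulls])
        null_mean = nv.mean() if len(nv) else np.nan
        if null_mean == 0 or not np.isfinite(null_mean):
            rows.append((name, o, null_mean, np.nan, True))
        else:
            rows.append((name, o, null_mean, float(np.log2(o / null_mean)) if o > 0 else -np.inf, False))
    return pd.DataFrame(
        rows, columns=["class", "observed", "null_mean", "log2_enrichment", "undefined"]
    )


# ---------------------------------------------------------------------------
# Gene-set compartment-switch enrichment


def gene_set_switch_enrichment(
    gene_ids: Iterable[str],
    labels: Mapping[str, np.ndarray],
    genes: GeneCatalog,
    resolution: int,
    target_label: str,
    n_shuffles: int = 100,
    seed: int = 0,
    level: float = 0.05,
) -> PermutationResult:
    """Observed % of a gene set in a trajectory class vs genome-wide shuffles.

    The null permutes the bin-label vector across the whole genome (labels
    pooled over chromosomes); genes keep their TSS bins.  Gene sets smaller
    than 10 mapped genes raise an error.
    """
    lookup = genes.df.set_index("id")
    chroms = list(labels)
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += len(labels[c])
    pooled = np.concatenate([labels[c] for c in chroms])
    flat_bins = []
    for gid in gene_ids:
        if gid not in lookup.index:
            continue
        row = lookup.loc[gid]
        if row["chrom"] not in offsets:
            continue
        b = int(row["tss"]) // resolution
        if b >= len(labels[row["chrom"]]):
            continue
        idx = offsets[row["chrom"]] + b
        if pooled[idx] is not None:
            flat_bins.append(idx)
    if len(flat_bins) < 10:
        raise ValueError(f"gene set maps to only {len(flat_bins)} labeled bins; need >=10")
    flat_bins = np.asarray(flat_bins)
    observed = 100.0 * float((pooled[flat_bins] == target_label).mean())
    null = np.empty(n_shuffles)
    for rep in range(n_shuffles):
        rng = np.random.default_rng([seed, rep])
        perm = pooled[rng.permutation(len(pooled))]
        null[rep] = 100.0 * float((perm[flat_bins] == target_label).mean())
    return PermutationResult.from_null(observed, null, level)


# ---------------------------------------------------------------------------
# Interval class composition


def _overlap_bp(regions: pd.DataFrame, intervals: pd.DataFrame) -> int:
    hits = overlap_join(regions, intervals)
    total = 0
    for a, b in zip(hits["index_a"], hits["index_b"]):
        ra = regions.iloc[a]
        rb = intervals.iloc[b]
        total += min(ra["end"], rb["end"]) - max(ra["start"], rb["start"])
    return int(total)


def _merge_frame(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        cur = None
        for row in sub.itertuples(index=False):
            if cur is not None and row.start <= cur[2]:
                cur[2] = max(cur[2], row.end)
            else:
                if cur is not None:
                    rows.append(tuple(cur))
                cur = [chrom, row.start, row.end]
        if cur is not None:
            rows.append(tuple(cur))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def interval_class_composition(
    regions: IntervalSet,
    class_intervals: Mapping[str, IntervalSet],
    chromsizes: ChromSizes,
) -> pd.DataFrame:
    """Fraction of region bp covered by each class, vs genome background.

    Regions are merged (union) before measuring so overlaps do not inflate
    the denominator.  Classes are taken as given: if classes overlap each
    other, their fractions double-count and the output flags it.
    """
    merged = _merge_frame(regions.df[["chrom", "start", "end"]])
    region_bp = int((merged["end"] - merged["start"]).sum())
    genome_bp = int(sum(chromsizes.values()))
    rows = []
    total_frac = 0.0
    for name, cls in class_intervals.items():
        cdf = cls.df[["chrom", "start", "end"]]
        ov = _overlap_bp(merged, cdf) if region_bp else 0
        frac = ov / region_bp if region_bp else np.nan
        bg = int((cdf["end"] - cdf["start"]).sum()) / genome_bp
        total_frac += frac if np.isfinite(frac) else 0.0
        rows.append((name, frac, bg))
    out = pd.DataFrame(rows, columns=["class", "region_fraction", "genome_fraction"])
    out.attrs["double_counted"] = bool(total_frac > 1 + 1e-9)
    if out.attrs["double_counted"]:
        warnings.warn("class intervals overlap: fractions double-count")
    return out
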