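"""Cross-sample similarity: SCC, compartment concordance, boundary recall,
intra-TAD gene-pair recapture.

SCC is the stratum-adjusted correlation coefficient: per-distance-stratum
Pearson correlations combined with weights ``w_k = N_k * sd(A_k) * sd(B_k)``,
computed per chromosome and averaged across chromosomes.  Smoothing (2D mean
filter) is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .genome_model import BinnedTrack, ContactMatrix, GeneCatalog, IntervalSet

__all__ = [
    "SccResult",
    "scc",
    "scc_genomewide",
    "compartment_concordance",
    "boundary_recall",
    "intra_tad_gene_pair_concordance",
]


@dataclass
class SccResult:
    per_chrom: dict
    mean: float
    max_dist_bins: int
    smooth_h: int
    n_skipped_strata: int = 0


def scc(
    matrix_a: ContactMatrix,
    matrix_b: ContactMatrix,
    max_dist_bins: int | None = None,
    smooth_h: int = 0,
) -> tuple[float, int]:
    """Stratum-adjusted correlation between two same-chromosome matrices.

    Strata are diagonals k = 1 .. max_dist_bins (default: 5 Mb worth of
    bins).  Zero-variance strata are skipped and counted.  Returns
    (scc, n_skipped).
    """
    if matrix_a.chrom != matrix_b.chrom or matrix_a.resolution != matrix_b.resolution:
        raise ValueError("matrices must share chromosome and resolution")
    if matrix_a.n_bins != matrix_b.n_bins:
        raise ValueError("matrices must share shape")
    if max_dist_bins is None:
        max_dist_bins = max(1, 5_000_000 // matrix_a.resolution)
    a, b = matrix_a.counts, matrix_b.counts
    if smooth_h > 0:
        size = 2 * smooth_h + 1
        a = ndimage.uniform_filter(a, size=size, mode="constant")
        b = ndimage.uniform_filter(b, size=size, mode="constant")
    num = 0.0
    den = 0.0
    n_skipped = 0
    n = matrix_a.n_bins
    for k in range(1, min(max_dist_bins, n - 1) + 1):
        va = np.diagonal(a, k)
        vb = np.diagonal(b, k)
        sa, sb = va.std(), vb.std()
        if sa == 0 or sb == 0:
            n_skipped += 1
            continue
        r = np.corrcoef(va, vb)[0, 1]
        w = len(va) * sa * sb
        num += w * r
        den += w
    if den == 0:
        raise ValueError("no usable strata")
    return float(num / den), n_skipped


def scc_genomewide(
    matrices_a: Mapping[str, ContactMatrix],
    matrices_b: Mapping[str, ContactMatrix],
    max_dist_bins: int | None = None,
    smooth_h: int = 0,
) -> SccResult:
    """SCC per chromosome, then the unweighted mean across chromosomes."""
    per = {}
    skipped = 0
    for chrom in matrices_a:
        rho, sk = scc(matrices_a[chrom], matrices_b[chrom], max_dist_bins, smooth_h)
        per[chrom] = rho
        skipped += sk
    md = max_dist_bins if max_dist_bins is not None else -1
    return SccResult(per, float(np.mean(list(per.values()))), md, smooth_h, skipped)


def compartment_concordance(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    genes: GeneCatalog | None = None,
) -> dict:
    """% of pairwise-complete bins (and optionally genes) with matching sign."""
    if track_a.resolution != track_b.resolution:
        raise ValueError("tracks must share resolution")
    n_match = 0
    n_total = 0
    for chrom in track_a.values:
        if chrom not in track_b.values:
            continue
        va, vb = track_a.values[chrom], track_b.values[chrom]
        ok = np.isfinite(va) & np.isfinite(vb)
        n_total += int(ok.sum())
        n_match += int((np.sign(va[ok]) == np.sign(vb[ok])).sum())
    if n_total == 0:
        raise ValueError("no pairwise-complete bins")
    out = {"bin_pct": 100.0 * n_match / n_total, "n_bins": n_total}
    if genes is not None:
        gm = gt = 0
        res = track_a.resolution
        for row in genes.df.itertuples(index=False):
            va = track_a.values.get(row.chrom)
            vb = track_b.values.get(row.chrom)
            if va is None or vb is None:
                continue
            b = row.tss // res
            if b >= len(va) or not (np.isfinite(va[b]) and np.isfinite(vb[b])):
                continue
            gt += 1
            gm += int(np.sign(va[b]) == np.sign(vb[b]))
        out["gene_pct"] = 100.0 * gm / gt if gt else np.nan
        out["n_genes"] = gt
    return out


def boundary_recall(
    query: IntervalSet,
    reference: IntervalSet,
    tolerance: int = 20_000,
) -> float:
    """% of reference boundaries with a query boundary within +-tolerance.

    Distances are midpoint-to-midpoint; the tolerance is inclusive.
    """
    if len(reference) == 0:
        raise ValueError("empty reference boundary set")
    q_by_chrom = {
        chrom: np.sort(sub[["start", "end"]].mean(axis=1).to_numpy())
        for chrom, sub in query.df.groupby("chrom", sort=False)
    }
    hit = 0
    for row in reference.df.itertuples(index=False):
        mids = q_by_chrom.get(row.chrom)
        if mids is None or mids.size == 0:
            continue
        m = 0.5 * (row.start + row.end)
        i = np.searchsorted(mids, m)
        d = min(
            abs(m - mids[i - 1]) if i > 0 else np.inf,
            abs(mids[i] - m) if i < mids.size else np.inf,
        )
        if d <= tolerance:
            hit += 1
    return 100.0 * hit / len(reference)


def _tss_tad_index(genes: GeneCatalog, tads: IntervalSet, gene_ids) -> dict:
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub.index.to_numpy())
        for chrom, sub in tads.df.groupby("chrom", sort=False)
    }
    lookup = genes.df.set_index("id")
    out = {}
    for gid in gene_ids:
        if gid not in lookup.index:
            continue
        row = lookup.loc[gid]
        entry = by_chrom.get(row["chrom"])
        if entry is None:
            continue
        starts, ends, idx = entry
        i = np.searchsorted(starts, row["tss"], side="right") - 1
        if i >= 0 and row["tss"] < ends[i]:
            out[gid] = int(idx[i])
    return out


def intra_tad_gene_pair_concordance(
    tads_query: IntervalSet,
    tads_reference: IntervalSet,
    genes: GeneCatalog,
    gene_ids: Iterable[str] | None = None,
) -> dict:
    """% of reference intra-TAD gene pairs that also share a query TAD.

    Reference pairs are unordered gene pairs whose TSS share a reference
    TAD; a pair is preserved when both TSS also share a query TAD.
    """
    ids = list(gene_ids) if gene_ids is not None else genes.df["id"].tolist()
    ref = _tss_tad_index(genes, tads_reference, ids)
    qry = _tss_tad_index(genes, tads_query, ids)
    ref_groups: dict[int, list] = {}
    for gid, t in ref.items():
        ref_groups.setdefault(t, []).append(gid)
    n_pairs = 0
    n_preserved = 0
    for members in ref_groups.values():
        m = len(members)
        if m < 2:
            continue
        n_pairs += m * (m - 1) // 2
        q_counts: dict[int, int] = {}
        for gid in members:
            qt = qry.get(gid)
            if qt is not None:
                q_counts[qt] = q_counts.get(qt, 0) + 1
        n_preserved += sum(c * (c - 1) // 2 for c in q_counts.values())
    if n_pairs == 0:
        warnings.warn("no reference intra-TAD gene pairs")
        return {"pct": np.nan, "n_pairs": 0, "n_preserved": 0}
    return {
        "pct": 100.0 * n_preserved / n_pairs,
        "n_pairs": n_pairs,
        "n_preserved": n_preserved,
    }
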