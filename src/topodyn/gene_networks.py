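"""Loop-mediated gene communities.

A community is a connected component of the graph whose nodes are gene
bodies and loop feet, with edges for gene-gene body overlap, gene-foot
overlap, and the two feet of each loop.  Components with at least two loci
(genes + feet) are retained; components containing no genes are kept in the
object model but excluded from gene-size statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .genome_model import GeneCatalog, IntervalSet, LoopSet, overlap_join

__all__ = ["GeneCommunity", "build_gene_communities", "community_stats"]


@dataclass
class GeneCommunity:
    id: int
    chrom: str
    genes: list
    n_feet: int
    loops: list  # row indices into the loop set
    start: int
    end: int

    @property
    def n_loci(self) -> int:
        return len(self.genes) + self.n_feet


def build_gene_communities(
    genes: GeneCatalog,
    loops: LoopSet,
) -> list[GeneCommunity]:
    """Connected components over gene bodies and loop feet.

    ``genes`` should already be restricted to the expressed set for the
    timepoint under analysis.  Overlap means >=1 bp of gene-body overlap
    (not TSS-only).  Community ids are assigned in (chrom, min start) order.
    """
    g = nx.Graph()
    gdf = genes.df.reset_index(drop=True)
    gene_nodes = [f"g:{gid}" for gid in gdf["id"]]
    g.add_nodes_from(gene_nodes)
    feet = loops.feet().df  # rows 0..n-1 = foot A of each loop, n..2n-1 = foot B
    n_loops = len(loops)
    for li in range(n_loops):
        g.add_edge(f"f:{li}:A", f"f:{li}:B")

    gene_iv = gdf[["chrom", "start", "end"]]
    gg = overlap_join(gene_iv, gene_iv)
    for a, b in zip(gg["index_a"], gg["index_b"]):
        if a < b:
            g.add_edge(gene_nodes[a], gene_nodes[b])
    # feet().df is sorted; rebuild unsorted foot frame to keep loop indexing
    foot_rows = []
    ldf = loops.df
    for li in range(n_loops):
        foot_rows.append((ldf.at[li, "chrom"], ldf.at[li, "startA"], ldf.at[li, "endA"], li, "A"))
        foot_rows.append((ldf.at[li, "chrom"], ldf.at[li, "startB"], ldf.at[li, "endB"], li, "B"))
    foot_df = pd.DataFrame(foot_rows, columns=["chrom", "start", "end", "loop", "side"])
    gf = overlap_join(gene_iv, foot_df)
    for a, b in zip(gf["index_a"], gf["index_b"]):
        g.add_edge(gene_nodes[a], f"f:{foot_df.at[b, 'loop']}:{foot_df.at[b, 'side']}")

    gene_pos = gdf.set_index("id")[["chrom", "start", "end"]]
    comms = []
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        gene_ids = [m[2:] for m in members if m.startswith("g:")]
        loop_ids = sorted({int(m.split(":")[1]) for m in members if m.startswith("f:")})
        spans = []
        chroms = set()
        for gid in gene_ids:
            r = gene_pos.loc[gid]
            spans.append((int(r["start"]), int(r["end"])))
            chroms.add(r["chrom"])
        for li in loop_ids:
            spans.append((int(ldf.at[li, "startA"]), int(ldf.at[li, "endB"])))
            chroms.add(ldf.at[li, "chrom"])
        start = min(s for s, _ in spans)
        end = max(e for _, e in spans)
        n_feet = sum(1 for m in members if m.startswith("f:"))
        comms.append((sorted(chroms)[0], start, end, gene_ids, n_feet, loop_ids))
    comms.sort(key=lambda c: (c[0], c[1]))
    return [
        GeneCommunity(i, chrom, sorted(gene_ids), n_feet, loop_ids, start, end)
        for i, (chrom, start, end, gene_ids, n_feet, loop_ids) in enumerate(comms)
    ]


def community_stats(
    communities: Iterable[GeneCommunity],
    gene_sets: Mapping[str, Iterable[str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-community sizes plus gene-set split summaries.

    The split compares communities containing >=1 member of a gene set with
    those containing none; gene-size statistics exclude communities made of
    loop feet only.
    """
    rows = [
        (c.id, c.chrom, c.start, c.end, len(c.genes), c.n_feet, c.n_loci)
        for c in communities
    ]
    per = pd.DataFrame(
        rows, columns=["community_id", "chrom", "start", "end", "n_genes", "n_feet", "n_loci"]
    )
    summaries = []
    with_genes = [c for c in communities if c.genes]
    for name, ids in (gene_sets or {}).items():
        ids = set(ids)
        inside = [len(c.genes) for c in with_genes if ids & set(c.genes)]
        outside = [len(c.genes) for c in with_genes if not (ids & set(c.genes))]

        def _mean_se(v):
            if not v:
                return np.nan, np.nan
            a = np.asarray(v, dtype=float)
            se = a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else np.nan
            return float(a.mean()), float(se)

        m_in, se_in = _mean_se(inside)
        m_out, se_out = _mean_se(outside)
        summaries.append((name, len(inside), m_in, se_in, len(outside), m_out, se_out))
    summary = pd.DataFrame(
        summaries,
        columns=[
            "gene_set",
            "n_with",
            "mean_size_with",
            "se_with",
            "n_without",
            "mean_size_without",
            "se_without",
        ],
    )
    return per, summary
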