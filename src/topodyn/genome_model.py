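"""Core genomic data containers and plain-text I/O.

All coordinates are 0-based half-open throughout the package.  BED and BEDPE
are read natively under that convention; bedGraph spans are likewise treated
as 0-based half-open.  Strand is carried only for TSS computation — every
overlap operation is strand-blind.

Containers are thin wrappers around pandas DataFrames / numpy arrays so that
downstream modules can use vectorised operations directly.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ChromSizes",
    "GenomicInterval",
    "IntervalSet",
    "BinnedTrack",
    "ContactMatrix",
    "GeneCatalog",
    "LoopSet",
    "read_chrom_sizes",
    "read_intervals",
    "read_expression",
    "parse_sample_groups",
    "filter_expressed_genes",
    "overlap_join",
]

# Ordered chromosome-name -> size (bp) mapping.
ChromSizes = dict


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str = "."
    score: float = math.nan

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def __len__(self) -> int:
        return self.end - self.start


_INTERVAL_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class IntervalSet:
    """An ordered collection of genomic intervals backed by a DataFrame.

    The frame always carries columns (chrom, start, end, name, score, strand);
    missing BED fields are filled with defaults.  Order is canonical:
    (chrom, start, end).
    """

    def __init__(self, df: pd.DataFrame, chromsizes: Mapping[str, int] | None = None):
        df = df.copy()
        for col, default in (("name", None), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_INTERVAL_COLS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if (df["end"] <= df["start"]).any():
            raise ValueError("interval end must exceed start")
        if chromsizes is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in chromsizes:
                    raise ValueError(f"chromosome {chrom!r} absent from size table")
                if (sub["end"] > chromsizes[chrom]).any():
                    raise ValueError(f"interval beyond end of {chrom}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom,
                int(row.start),
                int(row.end),
                row.name,
                row.strand if isinstance(row.strand, str) else ".",
                row.score if row.score == row.score else math.nan,
            )

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.df["start"].to_numpy() + self.df["end"].to_numpy())

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        chromsizes: Mapping[str, int] | None = None,
    ) -> "IntervalSet":
        rows = [r if len(r) >= 3 else tuple(r) for r in records]
        df = pd.DataFrame(rows, columns=_INTERVAL_COLS[: len(rows[0])] if rows else _INTERVAL_COLS[:3])
        return cls(df, chromsizes)

    def to_bed(self, path) -> None:
        df = self.df.copy()
        has_extra = df["name"].notna().any() or df["score"].notna().any() or (
            df["strand"] != "."
        ).any()
        if has_extra:
            out = df.fillna({"name": ".", "score": 0.0})
            out.to_csv(path, sep="\t", header=False, index=False)
        else:
            df[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, chromsizes: Mapping[str, int] | None = None) -> "IntervalSet":
        rows = []
        for lineno, fields in _iter_table(path):
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                rec = {
                    "chrom": fields[0],
                    "start": int(fields[1]),
                    "end": int(fields[2]),
                }
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if len(fields) > 3:
                rec["name"] = None if fields[3] == "." else fields[3]
            if len(fields) > 4:
                rec["score"] = float(fields[4])
            if len(fields) > 5:
                rec["strand"] = fields[5]
            rows.append(rec)
        df = pd.DataFrame(rows, columns=_INTERVAL_COLS[:3] + [c for c in _INTERVAL_COLS[3:] if rows and c in rows[0]])
        if not rows:
            df = pd.DataFrame(columns=_INTERVAL_COLS[:3])
        return cls(df, chromsizes)


class BinnedTrack:
    """Per-bin scalar signal on a fixed uniform genome binning.

    ``values[chrom]`` is a float vector of length ``ceil(size / resolution)``;
    NaN marks unscorable bins.
    """

    def __init__(
        self,
        resolution: int,
        values: Mapping[str, np.ndarray],
        chromsizes: Mapping[str, int] | None = None,
    ):
        self.resolution = int(resolution)
        self.values = {c: np.asarray(v, dtype=float) for c, v in values.items()}
        self.chromsizes = dict(chromsizes) if chromsizes is not None else {
            c: len(v) * self.resolution for c, v in self.values.items()
        }
        for chrom, vec in self.values.items():
            expect = -(-self.chromsizes[chrom] // self.resolution)
            if len(vec) != expect:
                raise ValueError(
                    f"{chrom}: track length {len(vec)} != ceil(size/res) {expect}"
                )

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def bin_of(self, chrom: str, pos: int) -> int:
        return int(pos) // self.resolution

    def at(self, chrom: str, pos: int) -> float:
        return float(self.values[chrom][self.bin_of(chrom, pos)])

    def stacked(self) -> np.ndarray:
        """All values concatenated in chromosome order."""
        return np.concatenate([self.values[c] for c in self.values])

    def to_bedgraph(self, path, skip_missing: bool = True) -> None:
        with open(path, "w") as fh:
            for chrom, vec in self.values.items():
                size = self.chromsizes[chrom]
                for i, v in enumerate(vec):
                    if skip_missing and not np.isfinite(v):
                        continue
                    start = i * self.resolution
                    end = min(start + self.resolution, size)
                    val = v if np.isfinite(v) else math.nan
                    fh.write(f"{chrom}\t{start}\t{end}\t{val:.10g}\n")

    @classmethod
    def from_bedgraph(
        cls,
        path,
        resolution: int,
        chromsizes: Mapping[str, int],
    ) -> "BinnedTrack":
        values = {
            c: np.full(-(-s // resolution), np.nan) for c, s in chromsizes.items()
        }
        for lineno, fields in _iter_table(path):
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in values:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            size = chromsizes[chrom]
            clipped_end = min(start + resolution, size)
            if start % resolution != 0 or end != clipped_end:
                raise FormatError(
                    f"{path}:{lineno}: span [{start},{end}) off the {resolution}-bp grid"
                )
            values[chrom][start // resolution] = val
        return cls(resolution, values, chromsizes)


class ContactMatrix:
    """Symmetric non-negative binned contact counts for one chromosome."""

    def __init__(
        self,
        chrom: str,
        resolution: int,
        counts: np.ndarray,
        balanced: bool = False,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("contact matrix must be square")
        diff = counts - counts.T
        if diff.size and float(np.abs(diff).max()) > 1e-9:
            raise ValueError("contact matrix must be symmetric")
        if counts.size and np.nanmin(counts) < 0:
            raise ValueError("contact matrix must be non-negative")
        self.chrom = chrom
        self.resolution = int(resolution)
        self.counts = counts
        self.balanced = bool(balanced)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def rebin(self, new_resolution: int) -> "ContactMatrix":
        """Aggregate counts into coarser bins (new resolution must be a multiple)."""
        f, rem = divmod(new_resolution, self.resolution)
        if rem or f < 1:
            raise ValueError("new resolution must be a positive multiple")
        n = self.n_bins
        m = -(-n // f)
        pad = m * f - n
        c = np.pad(self.counts, ((0, pad), (0, pad)))
        coarse = c.reshape(m, f, m, f).sum(axis=(1, 3))
        return ContactMatrix(self.chrom, new_resolution, coarse, self.balanced)

    def write_triplets(self, path) -> None:
        i, j = np.nonzero(np.triu(self.counts))
        with open(path, "w") as fh:
            fh.write(
                f"#chrom={self.chrom}\tresolution={self.resolution}\t"
                f"nbins={self.n_bins}\tbalanced={int(self.balanced)}\n"
            )
            for a, b in zip(i, j):
                fh.write(f"{a}\t{b}\t{self.counts[a, b]:.10g}\n")

    @classmethod
    def read_triplets(cls, path) -> "ContactMatrix":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise FormatError(f"{path}:1: missing triplet header line")
            meta = dict(kv.split("=", 1) for kv in header[1:].split())
            n = int(meta["nbins"])
            counts = np.zeros((n, n))
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                try:
                    a_s, b_s, v_s = line.split()
                    a, b, v = int(a_s), int(b_s), float(v_s)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: malformed triplet") from None
                counts[a, b] = v
                counts[b, a] = v
        return cls(meta["chrom"], int(meta["resolution"]), counts, bool(int(meta.get("balanced", "0"))))


_NCRNA_BIOTYPES = frozenset(
    {
        "miRNA",
        "miscRNA",
        "rRNA",
        "snRNA",
        "snoRNA",
        "vault_RNA",
        "lncRNA",
        "scRNA",
        "sRNA",
        "scaRNA",
    }
)
_BIOTYPES = _NCRNA_BIOTYPES | {"protein_coding"}


class GeneCatalog:
    """Gene annotations: id, interval, strand, biotype; strand-aware TSS.

    TSS is the 5' end of the gene body: ``start`` on the + strand and
    ``end - 1`` on the − strand (unstranded genes are treated as +).
    """

    COLUMNS = ["id", "chrom", "start", "end", "strand", "biotype"]

    def __init__(self, df: pd.DataFrame, chromsizes: Mapping[str, int] | None = None):
        df = df[self.COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["end"] <= df["start"]).any():
            raise ValueError("gene end must exceed start")
        bad = set(df["biotype"]) - _BIOTYPES
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")
        if df["id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if chromsizes is not None:
            missing = set(df["chrom"]) - set(chromsizes)
            if missing:
                raise ValueError(f"chromosomes absent from size table: {sorted(missing)}")
        df["tss"] = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, ids: Iterable[str]) -> "GeneCatalog":
        ids = set(ids)
        return GeneCatalog(self.df[self.df["id"].isin(ids)].drop(columns="tss"))

    def is_ncrna(self) -> pd.Series:
        return self.df["biotype"].isin(_NCRNA_BIOTYPES)

    def to_tsv(self, path) -> None:
        self.df[self.COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, chromsizes: Mapping[str, int] | None = None) -> "GeneCatalog":
        return cls(pd.read_csv(path, sep="\t"), chromsizes)


_LOOP_COLS = ["chrom", "startA", "endA", "startB", "endB", "score"]


class LoopSet:
    """Cis chromatin loops: two anchor intervals ("feet") per loop.

    Feet are stored in canonical order (``startA <= startB``); trans pairs are
    rejected at construction.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "score" not in df.columns:
            df["score"] = np.nan
        df = df[_LOOP_COLS]
        for c in ("startA", "endA", "startB", "endB"):
            df[c] = df[c].astype(np.int64)
        if ((df["endA"] <= df["startA"]) | (df["endB"] <= df["startB"])).any():
            raise ValueError("loop foot end must exceed start")
        # canonical foot ordering
        swap = df["startB"] < df["startA"]
        if swap.any():
            a = df.loc[swap, ["startA", "endA"]].to_numpy()
            df.loc[swap, ["startA", "endA"]] = df.loc[swap, ["startB", "endB"]].to_numpy()
            df.loc[swap, ["startB", "endB"]] = a
        self.df = df.sort_values(["chrom", "startA", "startB"], kind="stable").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def feet(self) -> IntervalSet:
        """Both feet of every loop as one interval set (occurrences kept)."""
        a = self.df[["chrom", "startA", "endA"]].rename(
            columns={"startA": "start", "endA": "end"}
        )
        b = self.df[["chrom", "startB", "endB"]].rename(
            columns={"startB": "start", "endB": "end"}
        )
        return IntervalSet(pd.concat([a, b], ignore_index=True))

    def to_bedpe(self, path) -> None:
        df = self.df
        out = pd.DataFrame(
            {
                "chrom1": df["chrom"],
                "start1": df["startA"],
                "end1": df["endA"],
                "chrom2": df["chrom"],
                "start2": df["startB"],
                "end2": df["endB"],
            }
        )
        if df["score"].notna().any():
            out["name"] = "."
            out["score"] = df["score"].fillna(0.0)
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bedpe(cls, path) -> "LoopSet":
        rows = []
        for lineno, f in _iter_table(path):
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE needs >=6 columns")
            if f[0] != f[3]:
                raise FormatError(
                    f"{path}:{lineno}: trans loop {f[0]}/{f[3]} not supported"
                )
            try:
                rec = {
                    "chrom": f[0],
                    "startA": int(f[1]),
                    "endA": int(f[2]),
                    "startB": int(f[4]),
                    "endB": int(f[5]),
                }
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if len(f) >= 8:
                try:
                    rec["score"] = float(f[7])
                except ValueError:
                    pass
            rows.append(rec)
        if not rows:
            return cls(pd.DataFrame(columns=_LOOP_COLS))
        return cls(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Readers


def _iter_table(path):
    """Yield (lineno, fields) for non-comment, non-blank lines of a text table."""
    if isinstance(path, io.IOBase):
        fh = path
        close = False
    else:
        fh = open(path)
        close = True
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t") if "\t" in line else line.split()
    finally:
        if close:
            fh.close()


def read_chrom_sizes(path) -> ChromSizes:
    sizes: ChromSizes = {}
    for lineno, f in _iter_table(path):
        if len(f) < 2:
            raise FormatError(f"{path}:{lineno}: chrom-size table needs 2 columns")
        sizes[f[0]] = int(f[1])
    return sizes


def read_intervals(
    path,
    format: str,
    chromsizes: Mapping[str, int] | None = None,
    resolution: int | None = None,
):
    """Dispatching reader for BED / BEDPE / bedGraph / gene TSV inputs."""
    fmt = format.lower()
    if fmt == "bed":
        return IntervalSet.from_bed(path, chromsizes)
    if fmt == "bedpe":
        return LoopSet.from_bedpe(path)
    if fmt == "bedgraph":
        if resolution is None or chromsizes is None:
            raise ValueError("bedGraph conversion needs resolution and chromsizes")
        return BinnedTrack.from_bedgraph(path, resolution, chromsizes)
    if fmt == "tsv":
        return GeneCatalog.from_tsv(path, chromsizes)
    raise ValueError(f"unknown format {format!r}")


def read_expression(path) -> pd.DataFrame:
    """Expression table: first column gene id, remaining columns CPM samples."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def parse_sample_groups(columns: Iterable[str]) -> dict[str, list[str]]:
    """Group ``<timepoint>_<rep>`` sample columns by timepoint, order-preserving."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        tp = col.rsplit("_", 1)[0] if "_" in col else col
        groups.setdefault(tp, []).append(col)
    return groups


def filter_expressed_genes(
    genes: GeneCatalog,
    expression: pd.DataFrame,
    cpm_threshold: float = 1.0,
) -> tuple[GeneCatalog, int]:
    """Expressed genes: CPM >= threshold in all replicates of >=1 timepoint.

    Genes absent from the expression table are excluded; the count of such
    genes is returned alongside the filtered catalog.
    """
    groups = parse_sample_groups(expression.columns)
    if not groups:
        raise ValueError("expression table has no sample columns")
    present = genes.df["id"].isin(expression.index)
    n_missing = int((~present).sum())
    expr = expression.loc[genes.df.loc[present, "id"]]
    ok = np.zeros(len(expr), dtype=bool)
    for cols in groups.values():
        ok |= (expr[cols].to_numpy() >= cpm_threshold).all(axis=1)
    kept = set(expr.index[ok])
    return genes.subset(kept), n_missing


# ---------------------------------------------------------------------------
# Interval arithmetic


def overlap_join(
    set_a: IntervalSet | pd.DataFrame,
    set_b: IntervalSet | pd.DataFrame,
    max_gap: int = 0,
) -> pd.DataFrame:
    """All pairs overlapping by >=1 bp after symmetric extension by ``max_gap``.

    Returns a frame with columns (index_a, index_b) referring to row positions
    in the canonical order of each input, sorted by the A interval's
    (chrom, start) then the B interval's start.  Strand-blind.
    """
    df_a = set_a.df if isinstance(set_a, IntervalSet) else set_a
    df_b = set_b.df if isinstance(set_b, IntervalSet) else set_b
    out_a: list[np.ndarray] = []
    out_b: list[np.ndarray] = []
    b_by_chrom = dict(tuple(df_b.groupby("chrom", sort=False)))
    for chrom, sub_a in df_a.groupby("chrom", sort=False):
        sub_b = b_by_chrom.get(chrom)
        if sub_b is None:
            continue
        # both sides are extended symmetrically by max_gap, so the slack
        # between the raw intervals is 2*max_gap; fold it onto B
        b_start = sub_b["start"].to_numpy() - 2 * max_gap
        b_end = sub_b["end"].to_numpy() + 2 * max_gap
        b_idx = sub_b.index.to_numpy()
        order = np.argsort(b_start, kind="stable")
        b_start_s, b_end_s, b_idx_s = b_start[order], b_end[order], b_idx[order]
        # running max of interval ends lets us prune the left side of the sweep
        b_end_cummax = np.maximum.accumulate(b_end_s)
        for ia, a_start, a_end in zip(
            sub_a.index.to_numpy(),
            sub_a["start"].to_numpy(),
            sub_a["end"].to_numpy(),
        ):
            hi = np.searchsorted(b_start_s, a_end, side="left")
            lo = np.searchsorted(b_end_cummax[:hi], a_start, side="right")
            if lo >= hi:
                continue
            cand = slice(lo, hi)
            mask = b_end_s[cand] > a_start
            hits = b_idx_s[cand][mask]
            if hits.size:
                out_a.append(np.full(hits.size, ia))
                out_b.append(np.sort(hits))
    if not out_a:
        return pd.DataFrame(columns=["index_a", "index_b"], dtype=np.int64)
    res = pd.DataFrame(
        {"index_a": np.concatenate(out_a), "index_b": np.concatenate(out_b)}
    )
    return res.reset_index(drop=True)
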