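"""Genome layout, bin tables, and readers/writers for the pipeline's on-disk formats.

Coordinates are 0-based half-open everywhere, matching the BED family of
formats. Bin tables tile each chromosome with fixed-size bins; the last bin
per chromosome may be short and is flagged so scoring code can exclude it.

On-disk formats handled here:

* chrom-sizes: two-column TSV (chromosome, length), optional centromere BED
* contacts: bin-pair triplet TSV (chrom1, start1, chrom2, start2, count)
  with a header line naming bin size and assembly
* bedGraph (chrom, start, end, value)
* BED3 / BED6 intervals, genes as stranded BED6
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError

__all__ = [
    "GenomeLayout",
    "BinTable",
    "GenomicInterval",
    "make_bin_table",
    "read_chromsizes",
    "write_chromsizes",
    "read_bed",
    "write_bed",
    "read_genes",
    "read_bedgraph",
    "write_bedgraph",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidParameterError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise InvalidParameterError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths and optional centromere intervals.

    Parameters
    ----------
    chromosomes
        Ordered chromosome names; order fixes the global bin ordering.
    lengths
        Chromosome lengths in base pairs, keyed by name.
    centromeres
        Optional per-chromosome ``(start, end)`` centromere interval in bp.
    """

    chromosomes: tuple[str, ...]
    lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise InvalidParameterError("chromosome names must be unique")
        for name in self.chromosomes:
            if name not in self.lengths:
                raise InvalidParameterError(f"no length for chromosome {name!r}")
            if self.lengths[name] <= 0:
                raise InvalidParameterError(f"chromosome {name!r} has non-positive length")
        for name, (c0, c1) in self.centromeres.items():
            if name not in self.lengths:
                raise InvalidParameterError(f"centromere on unknown chromosome {name!r}")
            if not (0 <= c0 < c1 <= self.lengths[name]):
                raise InvalidParameterError(
                    f"centromere [{c0}, {c1}) outside chromosome {name!r}"
                )

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    @property
    def total_length(self) -> int:
        return sum(self.lengths[c] for c in self.chromosomes)

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.lengths:
            raise InvalidParameterError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.lengths[iv.chrom]:
            raise InvalidParameterError(
                f"interval end {iv.end} beyond chromosome {iv.chrom!r} "
                f"length {self.lengths[iv.chrom]}"
            )


class BinTable:
    """Fixed-size genomic bins tiling a :class:`GenomeLayout`.

    Bins are 0-based half-open, tile each chromosome without gaps or
    overlaps, and carry a dense global index 0..N-1 in (chromosome order,
    start order). The last bin of a chromosome may be shorter than
    ``bin_size``.
    """

    def __init__(self, layout: GenomeLayout, bin_size: int):
        if bin_size <= 0:
            raise InvalidParameterError(f"bin_size must be positive, got {bin_size}")
        self.layout = layout
        self.bin_size = int(bin_size)
        chroms, starts, ends = [], [], []
        offsets = {}
        n = 0
        for chrom in layout.chromosomes:
            length = layout.lengths[chrom]
            s = np.arange(0, length, bin_size, dtype=np.int64)
            e = np.minimum(s + bin_size, length)
            chroms.extend([chrom] * len(s))
            starts.append(s)
            ends.append(e)
            offsets[chrom] = (n, n + len(s))
            n += len(s)
        self._offsets = offsets
        self.df = pd.DataFrame(
            {
                "chrom": pd.Categorical(chroms, categories=list(layout.chromosomes)),
                "start": np.concatenate(starts),
                "end": np.concatenate(ends),
            }
        )
        # short terminal bins are flagged so edge-sensitive scores can skip them
        self.df["short"] = (self.df["end"] - self.df["start"]) != bin_size

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinTable)
            and self.bin_size == other.bin_size
            and self.layout == other.layout
        )

    def n_bins(self, chrom: str) -> int:
        lo, hi = self._offsets[chrom]
        return hi - lo

    def chrom_range(self, chrom: str) -> tuple[int, int]:
        """Global-index half-open range of a chromosome's bins."""
        return self._offsets[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Local bin index (within chromosome) containing position ``pos``."""
        if chrom not in self.layout.lengths:
            raise InvalidParameterError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.layout.lengths[chrom]:
            raise InvalidParameterError(f"position {pos} outside chromosome {chrom!r}")
        return int(pos // self.bin_size)

    def global_index(self, chrom: str, pos: int) -> int:
        return self._offsets[chrom][0] + self.bin_index(chrom, pos)

    def bin_midpoints(self, chrom: str) -> np.ndarray:
        lo, hi = self._offsets[chrom]
        sub = self.df.iloc[lo:hi]
        return ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)


def make_bin_table(layout: GenomeLayout, bin_size: int) -> BinTable:
    """Tile ``layout`` with ``bin_size``-bp bins.

    The number of bins per chromosome is ``ceil(length / bin_size)``; the
    final bin of each chromosome is truncated at the chromosome end.
    """
    return BinTable(layout, bin_size)


# ---------------------------------------------------------------------------
# chrom-sizes and centromeres


def read_chromsizes(path, centromere_bed=None) -> GenomeLayout:
    """Read a two-column chrom-sizes file, optionally with a centromere BED."""
    chroms, lengths = [], {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError("expected 'chrom<TAB>length'", i, path)
            try:
                length = int(parts[1])
            except ValueError:
                raise FormatError(f"length {parts[1]!r} is not an integer", i, path)
            chroms.append(parts[0])
            lengths[parts[0]] = length
    centromeres = {}
    if centromere_bed is not None:
        cen = read_bed(centromere_bed)
        for row in cen.itertuples():
            centromeres[row.chrom] = (int(row.start), int(row.end))
    return GenomeLayout(tuple(chroms), lengths, centromeres)


def write_chromsizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom in layout.chromosomes:
            fh.write(f"{chrom}\t{layout.lengths[chrom]}\n")


# ---------------------------------------------------------------------------
# BED / bedGraph


def _parse_int(token: str, what: str, i: int, path) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{what} {token!r} is not an integer", i, path)


def read_bed(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame (chrom, start, end[, name, score, strand]).

    Intervals are validated against ``layout`` when given; malformed lines
    raise :class:`FormatError` naming the line.
    """
    rows = []
    ncols = 3
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError("BED line has fewer than 3 fields", i, path)
            chrom = parts[0]
            start = _parse_int(parts[1], "start", i, path)
            end = _parse_int(parts[2], "end", i, path)
            if start >= end:
                raise FormatError(f"start {start} >= end {end}", i, path)
            if layout is not None:
                if chrom not in layout:
                    raise FormatError(f"unknown chromosome {chrom!r}", i, path)
                if end > layout.lengths[chrom]:
                    raise FormatError(
                        f"interval end {end} beyond chromosome length "
                        f"{layout.lengths[chrom]}",
                        i,
                        path,
                    )
            row = [chrom, start, end]
            if len(parts) >= 6:
                if parts[5] not in ("+", "-", "."):
                    raise FormatError(f"bad strand {parts[5]!r}", i, path)
                row += [parts[3], float(parts[4]), parts[5]]
                ncols = 6
            rows.append(row)
    if ncols == 6:
        return pd.DataFrame(rows, columns=BED_COLUMNS)
    return pd.DataFrame(rows, columns=BED_COLUMNS[:3])


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED3 or BED6 DataFrame (column subset decides the dialect)."""
    cols = [c for c in BED_COLUMNS if c in df.columns]
    out = df[cols].copy()
    with open(path, "w") as fh:
        for row in out.itertuples(index=False):
            fh.write("\t".join(_bed_token(v) for v in row) + "\n")


def _bed_token(v) -> str:
    if isinstance(v, float):
        return repr(v) if not v.is_integer() else str(int(v))
    return str(v)


def read_genes(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read genes as stranded BED6; a missing or '.' strand is an error."""
    df = read_bed(path, layout)
    if "strand" not in df.columns:
        raise FormatError("gene BED must have 6 columns including strand", path=path)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(
            f"{int(bad.sum())} gene(s) without explicit +/- strand", path=path
        )
    return df


def read_bedgraph(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Read bedGraph into a DataFrame (chrom, start, end, value)."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError("bedGraph line must have 4 fields", i, path)
            chrom = parts[0]
            start = _parse_int(parts[1], "start", i, path)
            end = _parse_int(parts[2], "end", i, path)
            try:
                value = float(parts[3])
            except ValueError:
                raise FormatError(f"value {parts[3]!r} is not numeric", i, path)
            if start >= end:
                raise FormatError(f"start {start} >= end {end}", i, path)
            if layout is not None:
                if chrom not in layout:
                    raise FormatError(f"unknown chromosome {chrom!r}", i, path)
                if end > layout.lengths[chrom]:
                    raise FormatError("interval end beyond chromosome length", i, path)
            rows.append((chrom, start, end, value))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for row in df[["chrom", "start", "end", "value"]].itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{float(row.value)!r}\n")


def coverage_to_bedgraph(chrom: str, cov: np.ndarray) -> pd.DataFrame:
    """Run-length encode a per-base coverage array, dropping zero runs."""
    cov = np.asarray(cov)
    if len(cov) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    change = np.flatnonzero(np.diff(cov) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [len(cov)]])
    vals = cov[starts]
    keep = vals != 0
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts[keep],
            "end": ends[keep],
            "value": vals[keep].astype(float),
        }
    )


def bedgraph_to_coverage(df: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    """Expand a bedGraph DataFrame back into a dense per-base array."""
    cov = np.zeros(length)
    sub = df[df["chrom"] == chrom]
    for row in sub.itertuples(index=False):
        cov[row.start : row.end] = row.value
    return cov
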