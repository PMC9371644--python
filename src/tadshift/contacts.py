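"""Sparse-on-disk, dense-in-memory Hi-C contact maps over a uniform bin table.

Cis (intra-chromosomal) matrices are symmetric per chromosome; only the
upper triangle is stored on disk. Trans (inter-chromosomal) matrices are
rectangular per ordered chromosome pair. The on-disk interchange is a
bin-pair triplet TSV::

    # tadshift-contacts bin_size=40000 assembly=sim
    chrA	0	chrA	40000	17
    chrA	0	chrB	0	2

Dense per-chromosome arrays are the working representation: at the bin
sizes this pipeline uses (40 kb boundaries, 500 kb compartments, 4 Mb
trans) a chromosome is at most a few thousand bins.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError, InvalidParameterError
from .genome_io import BinTable

__all__ = ["ContactMap", "read_contacts", "write_contacts"]


class ContactMap:
    """Per-chromosome cis and per-pair trans contact matrices.

    Attributes
    ----------
    bins : BinTable
        The uniform binning both axes of every matrix refer to.
    cis : dict[str, np.ndarray]
        Symmetric ``(n, n)`` count matrix per chromosome.
    trans : dict[tuple[str, str], np.ndarray]
        Rectangular ``(n1, n2)`` matrix per chromosome pair, keyed with the
        chromosomes in layout order.
    """

    def __init__(self, bins: BinTable):
        self.bins = bins
        self.cis: dict[str, np.ndarray] = {}
        self.trans: dict[tuple[str, str], np.ndarray] = {}
        # per-chromosome validity mask set by balancing (True = usable bin)
        self.cis_mask: dict[str, np.ndarray] = {}

    @classmethod
    def zeros(cls, bins: BinTable, with_trans: bool = False) -> "ContactMap":
        cm = cls(bins)
        chroms = bins.layout.chromosomes
        for c in chroms:
            cm.cis[c] = np.zeros((bins.n_bins(c), bins.n_bins(c)))
        if with_trans:
            for i, c1 in enumerate(chroms):
                for c2 in chroms[i + 1 :]:
                    cm.trans[(c1, c2)] = np.zeros((bins.n_bins(c1), bins.n_bins(c2)))
        return cm

    def set_cis(self, chrom: str, matrix: np.ndarray) -> None:
        n = self.bins.n_bins(chrom)
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (n, n):
            raise InvalidParameterError(
                f"cis matrix for {chrom!r} must be ({n}, {n}), got {matrix.shape}"
            )
        if not np.allclose(matrix, matrix.T):
            raise InvalidParameterError(f"cis matrix for {chrom!r} is not symmetric")
        self.cis[chrom] = matrix

    def set_trans(self, chrom1: str, chrom2: str, matrix: np.ndarray) -> None:
        key, matrix = self._ordered(chrom1, chrom2, np.asarray(matrix, dtype=float))
        n1 = self.bins.n_bins(key[0])
        n2 = self.bins.n_bins(key[1])
        if matrix.shape != (n1, n2):
            raise InvalidParameterError(
                f"trans matrix for {key} must be ({n1}, {n2}), got {matrix.shape}"
            )
        self.trans[key] = matrix

    def _ordered(self, c1: str, c2: str, matrix=None):
        order = {c: i for i, c in enumerate(self.bins.layout.chromosomes)}
        if c1 not in order or c2 not in order:
            raise InvalidParameterError(f"unknown chromosome in pair ({c1!r}, {c2!r})")
        if order[c1] <= order[c2]:
            return (c1, c2), matrix
        return (c2, c1), (matrix.T if matrix is not None else None)

    def get_trans(self, chrom1: str, chrom2: str) -> np.ndarray:
        key, _ = self._ordered(chrom1, chrom2)
        m = self.trans[key]
        return m if key == (chrom1, chrom2) else m.T

    @property
    def total_cis(self) -> float:
        # each off-diagonal contact counted once
        return sum(np.triu(m).sum() for m in self.cis.values())

    @property
    def total_trans(self) -> float:
        return sum(m.sum() for m in self.trans.values())

    def scaled(self, factor: float) -> "ContactMap":
        out = ContactMap(self.bins)
        out.cis = {c: m * factor for c, m in self.cis.items()}
        out.trans = {k: m * factor for k, m in self.trans.items()}
        return out


def write_contacts(cmap: ContactMap, path, assembly: str = "unknown") -> None:
    """Write a ContactMap as a bin-pair triplet TSV (upper triangle for cis)."""
    bins = cmap.bins
    bs = bins.bin_size
    with open(path, "w") as fh:
        fh.write(f"# tadshift-contacts bin_size={bs} assembly={assembly}\n")
        for chrom in bins.layout.chromosomes:
            if chrom not in cmap.cis:
                continue
            m = cmap.cis[chrom]
            iu, ju = np.nonzero(np.triu(m))
            for i, j in zip(iu, ju):
                fh.write(f"{chrom}\t{i * bs}\t{chrom}\t{j * bs}\t{float(m[i, j])!r}\n")
        for (c1, c2), m in sorted(
            cmap.trans.items(),
            key=lambda kv: (
                bins.layout.chromosomes.index(kv[0][0]),
                bins.layout.chromosomes.index(kv[0][1]),
            ),
        ):
            iu, ju = np.nonzero(m)
            for i, j in zip(iu, ju):
                fh.write(f"{c1}\t{i * bs}\t{c2}\t{j * bs}\t{float(m[i, j])!r}\n")


def read_contacts(path, bins: BinTable) -> ContactMap:
    """Read a bin-pair triplet TSV into a ContactMap.

    Coordinates must sit on the bin grid of ``bins``; cis symmetry is
    enforced by mirroring the stored upper triangle.
    """
    cmap = ContactMap.zeros(bins, with_trans=True)
    bs = bins.bin_size
    layout = bins.layout
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError("triplet line must have 5 fields", ln, path)
            c1, s1, c2, s2, count = parts
            for c in (c1, c2):
                if c not in layout:
                    raise FormatError(f"unknown chromosome {c!r}", ln, path)
            try:
                s1, s2 = int(s1), int(s2)
                count = float(count)
            except ValueError:
                raise FormatError("non-numeric coordinate or count", ln, path)
            for c, s in ((c1, s1), (c2, s2)):
                if s % bs != 0:
                    raise FormatError(
                        f"coordinate {s} not on the {bs}-bp bin grid", ln, path
                    )
                if s >= layout.lengths[c]:
                    raise FormatError(
                        f"coordinate {s} beyond chromosome {c!r}", ln, path
                    )
            i, j = s1 // bs, s2 // bs
            if c1 == c2:
                cmap.cis[c1][i, j] += count
                if i != j:
                    cmap.cis[c1][j, i] += count
            else:
                order = layout.chromosomes.index
                if order(c1) <= order(c2):
                    cmap.trans[(c1, c2)][i, j] += count
                else:
                    cmap.trans[(c2, c1)][j, i] += count
    return cmap
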