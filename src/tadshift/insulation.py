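"""Insulation scoring and TAD-boundary calling on cis contact maps.

The insulation score of bin *i* at window *w* (in bins) is the mean
normalized contact count over the square of bin pairs spanning *i*::

    s_raw(i) = mean{ M[u, v] : i - w <= u < i < v <= i + w }

log2-scaled against the chromosome-wide mean of s_raw over valid bins, so
a score of 0 is "averagely insulated" and strong boundaries are deep
negative local minima. Bins within *w* bins of a chromosome edge are
masked. Boundaries are local minima of the track with a minimum
prominence, plateaus resolved to their leftmost bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .contacts import ContactMap
from .errors import ConvergenceError, InvalidParameterError
from .genome_io import BinTable

__all__ = [
    "InsulationTrack",
    "Boundary",
    "balance",
    "balance_matrix",
    "insulation_score",
    "call_boundaries",
    "merge_boundary_calls",
    "score_boundaries_across_samples",
]


# ---------------------------------------------------------------------------
# matrix balancing


def balance(
    matrix: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 2000,
    min_nnz: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Iteratively balance a symmetric nonnegative matrix (Sinkhorn/ICE).

    Rows/columns with fewer than ``min_nnz`` nonzero entries are masked and
    excluded. On return all unmasked row sums agree to relative tolerance
    ``tol``; masked rows/columns are NaN.

    Returns (balanced matrix, boolean valid mask).
    Raises :class:`ConvergenceError` if the tolerance is not reached.
    """
    m = np.asarray(matrix, dtype=float)
    if (m < 0).any():
        raise InvalidParameterError("contact matrix has negative counts")
    n = m.shape[0]
    valid = (m != 0).sum(axis=1) >= max(min_nnz, 1)
    out = np.full_like(m, np.nan)
    if valid.sum() == 0:
        return out, valid
    sub = m[np.ix_(valid, valid)].copy()
    bias = np.ones(sub.shape[0])
    for it in range(max_iter):
        cur = sub / np.outer(bias, bias)
        rs = cur.sum(axis=1)
        target = rs.mean()
        if target == 0:
            break
        if np.max(np.abs(rs / target - 1.0)) < tol:
            balanced = cur / target * cur.shape[0]  # mean row sum == n_valid
            out[np.ix_(valid, valid)] = balanced
            return out, valid
        bias *= np.sqrt(rs / target)
    raise ConvergenceError("matrix balancing did not converge", max_iter)


def balance_matrix(
    cmap: ContactMap, tol: float = 1e-5, max_iter: int = 2000, min_nnz: int = 1
) -> ContactMap:
    """Balance every cis matrix of a ContactMap; masks stored on the result."""
    out = ContactMap(cmap.bins)
    for chrom, m in cmap.cis.items():
        balanced, valid = balance(m, tol=tol, max_iter=max_iter, min_nnz=min_nnz)
        out.cis[chrom] = balanced
        out.cis_mask[chrom] = valid
    out.trans = dict(cmap.trans)
    return out


# ---------------------------------------------------------------------------
# insulation track


@dataclass
class InsulationTrack:
    """Per-bin insulation scores (log2) with a validity mask."""

    bins: BinTable
    window: int  # base pairs
    scores: dict  # chrom -> float array (NaN on invalid bins)
    valid: dict  # chrom -> bool array

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for chrom in self.bins.layout.chromosomes:
            lo, hi = self.bins.chrom_range(chrom)
            sub = self.bins.df.iloc[lo:hi]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": sub["start"].to_numpy(),
                        "end": sub["end"].to_numpy(),
                        "value": self.scores[chrom],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_bedgraph_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[np.isfinite(df["value"])].reset_index(drop=True)


def _window_mean_square(m: np.ndarray, w: int) -> np.ndarray:
    """Mean of M over the crossing square for each bin, NaN-aware.

    For bin i the square is rows [i-w, i) x cols (i, i+w]; computed with
    summed-area tables so the whole track is O(n^2) once.
    """
    n = m.shape[0]
    out = np.full(n, np.nan)
    for i in range(w, n - w):
        sub = m[i - w : i, i + 1 : i + w + 1]
        finite = np.isfinite(sub)
        c = finite.sum()
        if c > 0:
            out[i] = sub[finite].sum() / c
    return out


def insulation_score(
    cmap: ContactMap, window: int, balanced: bool = True
) -> InsulationTrack:
    """Compute the insulation track at ``window`` bp on every chromosome.

    ``cmap`` should normally be a balanced map (see :func:`balance_matrix`);
    pass ``balanced=False`` to score raw counts. The window must be an
    integer multiple of the bin size and span at least two bins.
    """
    bins = cmap.bins
    bs = bins.bin_size
    if window % bs != 0:
        raise InvalidParameterError(
            f"window {window} is not a multiple of the bin size {bs}"
        )
    w = window // bs
    if w < 2:
        raise InvalidParameterError(f"window must span >= 2 bins, got {w}")
    scores, valid = {}, {}
    for chrom in bins.layout.chromosomes:
        if chrom not in cmap.cis:
            continue
        m = cmap.cis[chrom]
        n = m.shape[0]
        if n < 2 * w + 1:
            warnings.warn(
                f"chromosome {chrom!r} shorter than 2*window+1 bins; track masked"
            )
            scores[chrom] = np.full(n, np.nan)
            valid[chrom] = np.zeros(n, dtype=bool)
            continue
        mask = cmap.cis_mask.get(chrom)
        mm = m.copy()
        if mask is not None:
            mm[~mask, :] = np.nan
            mm[:, ~mask] = np.nan
        s_raw = _window_mean_square(mm, w)
        ok = np.isfinite(s_raw)
        if mask is not None:
            ok &= mask
        if not ok.any():
            scores[chrom] = np.full(n, np.nan)
            valid[chrom] = ok
            continue
        # floor zeros at half the smallest positive value so contact-free
        # boundaries stay finite and callable
        positive = s_raw[ok & (s_raw > 0)]
        floor = positive.min() / 2.0 if len(positive) else 1.0
        s_adj = np.where(ok & (s_raw <= 0), floor, s_raw)
        mean = s_adj[ok].mean()
        track = np.full(n, np.nan)
        track[ok] = np.log2(s_adj[ok] / mean)
        scores[chrom] = track
        valid[chrom] = ok
    return InsulationTrack(bins=bins, window=window, scores=scores, valid=valid)


# ---------------------------------------------------------------------------
# boundary calling


@dataclass(frozen=True)
class Boundary:
    """A called TAD boundary at a local insulation minimum."""

    chrom: str
    bin: int  # local bin index on its chromosome
    midpoint: int  # bp
    score: float
    prominence: float

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.bin)


def call_boundaries(track: InsulationTrack, prominence_min: float = 0.1) -> list[Boundary]:
    """Call boundaries as prominent local minima of the insulation track.

    A boundary bin is strictly lower than both flanking valid scores
    (plateaus collapse to their leftmost bin) and has prominence at least
    ``prominence_min`` (log2 units). Returned sorted by genomic position.
    """
    out: list[Boundary] = []
    for chrom in track.bins.layout.chromosomes:
        if chrom not in track.scores:
            continue
        s = track.scores[chrom]
        v = track.valid[chrom]
        mids = track.bins.bin_midpoints(chrom)
        # process each contiguous valid segment separately
        idx = np.flatnonzero(v)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        segments = np.split(idx, breaks + 1)
        for seg in segments:
            if len(seg) < 3:
                continue
            y = -s[seg]
            peaks, props = find_peaks(y, prominence=prominence_min, plateau_size=(1, None))
            for k, p in enumerate(peaks):
                left = int(props["left_edges"][k])  # leftmost bin of a plateau
                b = int(seg[left])
                out.append(
                    Boundary(
                        chrom=chrom,
                        bin=b,
                        midpoint=int(mids[b]),
                        score=float(s[b]),
                        prominence=float(props["prominences"][k]),
                    )
                )
    out.sort(key=lambda b: (track.bins.layout.chromosomes.index(b.chrom), b.bin))
    return out


def merge_boundary_calls(
    calls: list[list[Boundary]], within_bins: int = 1
) -> list[Boundary]:
    """Union-merge boundary calls from several samples.

    Boundaries within ``within_bins`` bins of each other collapse to the
    one with the lower insulation score.
    """
    pooled = sorted(
        (b for lst in calls for b in lst), key=lambda b: (b.chrom, b.bin, b.score)
    )
    merged: list[Boundary] = []
    for b in pooled:
        if merged and merged[-1].chrom == b.chrom and b.bin - merged[-1].bin <= within_bins:
            if b.score < merged[-1].score:
                merged[-1] = b
            continue
        merged.append(b)
    return merged


def score_boundaries_across_samples(
    boundaries: list[Boundary], tracks: dict[str, InsulationTrack]
) -> pd.DataFrame:
    """Annotate a fixed boundary set with its score in every sample.

    Rows are boundaries (indexed ``chrom:bin``), columns samples. A bin
    masked in some sample yields NaN there, never zero.
    """
    rows = {}
    for b in boundaries:
        vals = {}
        for sample, track in tracks.items():
            s = track.scores.get(b.chrom)
            ok = track.valid.get(b.chrom)
            if s is None or not ok[b.bin]:
                vals[sample] = np.nan
            else:
                vals[sample] = float(s[b.bin])
        rows[f"{b.chrom}:{b.bin}"] = vals
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(tracks))
    df.insert(0, "chrom", [b.chrom for b in boundaries])
    df.insert(1, "bin", [b.bin for b in boundaries])
    df.insert(2, "midpoint", [b.midpoint for b in boundaries])
    return df
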