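"""Nascent-transcription (PRO-seq) analytics.

Coverage is per-base and stranded: ``{strand: {chrom: float array}}``.
The central statistic is the promoter-proximal pausing index

    PI = (pause reads / pause length) / (body reads / body length)

with a TSS-anchored, strand-aware pause window (default TSS-50 to TSS+300
in the direction of transcription) and the gene body from the pause
window's downstream edge to the TES. Differential pausing between
conditions uses Fisher's exact test on replicate-summed pause/body
counts, BH-corrected.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .errors import InvalidParameterError
from .genome_io import (
    GenomeLayout,
    bedgraph_to_coverage,
    coverage_to_bedgraph,
    read_bedgraph,
    write_bedgraph,
)

__all__ = [
    "write_coverage",
    "read_coverage",
    "boundary_transcription",
    "pause_body_counts",
    "pausing_index",
    "pausing_table",
    "differential_pausing",
    "deregulated_boundary_enrichment",
    "fraction_boundary_transcripts",
]

DEFAULT_PAUSE_OFFSET = (-50, 300)
MIN_BODY_READS = 10
MIN_BODY_LENGTH = 100


def write_coverage(cov: dict, prefix) -> tuple[Path, Path]:
    """Write stranded coverage as two bedGraph files (<prefix>.plus/.minus.bedgraph)."""
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        frames = [
            coverage_to_bedgraph(chrom, arr) for chrom, arr in cov[strand].items()
        ]
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "start", "end", "value"]
        )
        path = Path(f"{prefix}.{tag}.bedgraph")
        write_bedgraph(df, path)
        paths.append(path)
    return tuple(paths)


def read_coverage(prefix, layout: GenomeLayout) -> dict:
    cov = {}
    for strand, tag in (("+", "plus"), ("-", "minus")):
        df = read_bedgraph(Path(f"{prefix}.{tag}.bedgraph"), layout)
        cov[strand] = {
            c: bedgraph_to_coverage(df, c, layout.lengths[c])
            for c in layout.chromosomes
        }
    return cov


# ---------------------------------------------------------------------------
# boundary-centered profiles


def boundary_transcription(
    cov: dict,
    boundaries,
    flank: int = 200_000,
    n_bins: int = 41,
) -> np.ndarray:
    """Strand-summed coverage binned over +-``flank`` around boundary midpoints.

    Returns an ``(n_boundaries, n_bins)`` matrix of mean per-base coverage
    per profile bin; positions beyond the chromosome are treated as zero.
    ``boundaries`` is any iterable with ``chrom`` and ``midpoint``
    attributes.
    """
    edges = np.linspace(-flank, flank, n_bins + 1).astype(int)
    blist = list(boundaries)
    out = np.zeros((len(blist), n_bins))
    for bi, b in enumerate(blist):
        plus = cov["+"].get(b.chrom)
        minus = cov["-"].get(b.chrom)
        if plus is None:
            continue
        length = len(plus)
        for k in range(n_bins):
            lo = b.midpoint + edges[k]
            hi = b.midpoint + edges[k + 1]
            lo_c, hi_c = max(lo, 0), min(hi, length)
            if hi_c <= lo_c:
                continue
            total = plus[lo_c:hi_c].sum() + minus[lo_c:hi_c].sum()
            out[bi, k] = total / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# pausing index


def _windows(start, end, strand, pause_offset):
    lo, hi = pause_offset
    if strand == "+":
        pause = (start + lo, start + hi)
        body = (start + hi, end)
    elif strand == "-":
        pause = (end - hi, end - lo)
        body = (start, end - hi)
    else:
        raise InvalidParameterError(f"gene strand must be + or -, got {strand!r}")
    return pause, body


def pause_body_counts(
    cov: dict,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    pause_offset: tuple[int, int] = DEFAULT_PAUSE_OFFSET,
) -> tuple[float, int, float, int]:
    """(pause reads, pause length, body reads, body length) for one gene."""
    (p0, p1), (b0, b1) = _windows(start, end, strand, pause_offset)
    arr = cov[strand][chrom]
    n = len(arr)
    p0c, p1c = max(p0, 0), min(p1, n)
    b0c, b1c = max(b0, 0), min(b1, n)
    pause = float(arr[p0c:p1c].sum()) if p1c > p0c else 0.0
    body = float(arr[b0c:b1c].sum()) if b1c > b0c else 0.0
    return pause, max(p1 - p0, 0), body, max(b1 - b0, 0)


def pausing_index(
    cov: dict,
    chrom: str,
    start: int,
    end: int,
    strand: str,
    pause_offset: tuple[int, int] = DEFAULT_PAUSE_OFFSET,
    min_body_reads: int = MIN_BODY_READS,
) -> float:
    """Pausing index for one gene; NaN when the body is under-covered."""
    pause, plen, body, blen = pause_body_counts(cov, chrom, start, end, strand, pause_offset)
    if blen <= 0 or plen <= 0 or body < min_body_reads:
        return float("nan")
    return (pause / plen) / (body / blen)


def pausing_table(
    cov: dict,
    genes: pd.DataFrame,
    pause_offset: tuple[int, int] = DEFAULT_PAUSE_OFFSET,
    min_body_reads: int = MIN_BODY_READS,
    min_body_length: int = MIN_BODY_LENGTH,
) -> pd.DataFrame:
    """Per-gene pause/body counts and PI; skipped genes carry a reason code.

    ``genes`` is a BED6-like frame (chrom, start, end, name, score,
    strand). Reason codes: ``ok``, ``too_short`` (body shorter than
    ``min_body_length``), ``low_body`` (body reads below threshold).
    """
    rows = []
    for g in genes.itertuples(index=False):
        pause, plen, body, blen = pause_body_counts(
            cov, g.chrom, g.start, g.end, g.strand, pause_offset
        )
        if blen < min_body_length:
            reason, pi = "too_short", float("nan")
        elif body < min_body_reads:
            reason, pi = "low_body", float("nan")
        else:
            reason = "ok"
            pi = (pause / plen) / (body / blen)
        rows.append((g.name, g.chrom, g.start, g.end, g.strand,
                     pause, plen, body, blen, pi, reason))
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "start", "end", "strand",
                 "pause_reads", "pause_len", "body_reads", "body_len", "pi", "reason"],
    )


def differential_pausing(
    control_tables: list[pd.DataFrame],
    treated_tables: list[pd.DataFrame],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact test of pause-vs-body counts, control vs treated.

    Replicate tables (from :func:`pausing_table`) are summed per gene; per
    gene the 2x2 table [[pause_ctrl, body_ctrl], [pause_trt, body_trt]]
    is tested two-sided, BH-corrected, and classified ``more_paused`` /
    ``less_paused`` / ``unchanged`` by the direction of the PI change at
    q < ``q_threshold``.
    """
    def summed(tables):
        cat = pd.concat(tables, ignore_index=True)
        agg = cat.groupby("gene", sort=False).agg(
            pause=("pause_reads", "sum"),
            body=("body_reads", "sum"),
            pause_len=("pause_len", "first"),
            body_len=("body_len", "first"),
        )
        return agg

    ctrl = summed(control_tables)
    trt = summed(treated_tables)
    genes = ctrl.index.intersection(trt.index)
    rows = []
    for g in genes:
        pc, bc = ctrl.loc[g, "pause"], ctrl.loc[g, "body"]
        pt, bt = trt.loc[g, "pause"], trt.loc[g, "body"]
        plen, blen = ctrl.loc[g, "pause_len"], ctrl.loc[g, "body_len"]
        table = np.round([[pc, bc], [pt, bt]]).astype(int)
        if table.sum() == 0 or blen == 0:
            rows.append((g, np.nan, np.nan, np.nan, 1.0))
            continue
        pi_c = (pc / plen) / (bc / blen) if bc > 0 else np.nan
        pi_t = (pt / plen) / (bt / blen) if bt > 0 else np.nan
        _, p = scipy.stats.fisher_exact(table, alternative="two-sided")
        rows.append((g, pi_c, pi_t, pi_t - pi_c if np.isfinite(pi_c) and np.isfinite(pi_t) else np.nan, p))
    out = pd.DataFrame(rows, columns=["gene", "pi_control", "pi_treated", "delta_pi", "p"])
    _, q, _, _ = multipletests(out["p"].fillna(1.0), method="fdr_bh")
    out["q"] = q
    cls = np.full(len(out), "unchanged", dtype=object)
    sig = (out["q"] < q_threshold) & out["delta_pi"].notna()
    cls[sig & (out["delta_pi"] > 0)] = "more_paused"
    cls[sig & (out["delta_pi"] < 0)] = "less_paused"
    out["class"] = cls
    return out


# ---------------------------------------------------------------------------
# boundary-overlap enrichment


def _midpoint_in_regions(items: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    mids = ((items["start"] + items["end"]) // 2).to_numpy()
    chroms = items["chrom"].to_numpy()
    hit = np.zeros(len(items), dtype=bool)
    for r in regions.itertuples(index=False):
        hit |= (chroms == r.chrom) & (mids >= r.start) & (mids < r.end)
    return hit


def deregulated_boundary_enrichment(
    genes: pd.DataFrame,
    hds_regions: pd.DataFrame,
    unaffected_regions: pd.DataFrame,
) -> float:
    """Size-normalized enrichment of a gene class on HDS vs unaffected regions.

    enrichment = (genes with midpoint in HDS regions / HDS span in Mb)
               / (genes with midpoint in unaffected regions / unaffected span in Mb)
    """
    hds_mb = (hds_regions["end"] - hds_regions["start"]).sum() / 1e6
    un_mb = (unaffected_regions["end"] - unaffected_regions["start"]).sum() / 1e6
    if hds_mb <= 0 or un_mb <= 0:
        raise InvalidParameterError("both region sets must have positive total span")
    n_hds = int(_midpoint_in_regions(genes, hds_regions).sum())
    n_un = int(_midpoint_in_regions(genes, unaffected_regions).sum())
    if n_un == 0:
        return float("inf") if n_hds > 0 else float("nan")
    return (n_hds / hds_mb) / (n_un / un_mb)


def fraction_boundary_transcripts(
    transcripts: pd.DataFrame,
    hds_regions: pd.DataFrame,
    all_boundary_regions: pd.DataFrame,
) -> float:
    """Fraction of boundary-overlapping transcripts on HDS boundaries.

    A transcript overlaps a boundary region when its midpoint falls inside
    it; the fraction is HDS-overlapping over all boundary-overlapping
    transcripts (0 when none overlap any boundary).
    """
    on_boundary = _midpoint_in_regions(transcripts, all_boundary_regions)
    if not on_boundary.any():
        return 0.0
    on_hds = _midpoint_in_regions(transcripts, hds_regions)
    return float((on_boundary & on_hds).sum() / on_boundary.sum())
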