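"""Genomic clustering of HDS boundaries and trans-contact aggregation.

Condensate-sensitive (HDS) boundaries cluster along chromosomes; this
module finds those clusters with a gap-threshold sweep, aggregates
interchromosomal contacts over 4-Mb bins grouped by their HDS-boundary
count, runs the total-boundary confounder check, and measures how strongly
ubiquitously-expressed (housekeeping) genes concentrate on cluster spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .errors import InvalidParameterError
from .genome_io import BinTable, GenomeLayout
from .insulation import Boundary

__all__ = [
    "filter_centromeric",
    "ClusterTable",
    "cluster_boundaries",
    "trans_aggregate",
    "control_total_boundaries",
    "housekeeping_enrichment",
    "housekeeping_genes",
]

CENTROMERE_EXCLUSION = 1_000_000  # bp; boundaries closer than this are dropped


def filter_centromeric(
    boundaries: list[Boundary],
    layout: GenomeLayout,
    distance: int = CENTROMERE_EXCLUSION,
) -> list[Boundary]:
    """Drop boundaries whose midpoint lies within ``distance`` of a centromere.

    The comparison is strict: a boundary exactly ``distance`` bp from the
    centromere edge is retained. Chromosomes without an annotated
    centromere pass through unchanged.
    """
    out = []
    for b in boundaries:
        cen = layout.centromeres.get(b.chrom)
        if cen is None:
            out.append(b)
            continue
        c0, c1 = cen
        gap = max(c0 - b.midpoint, b.midpoint - c1, 0)
        if gap >= distance and not (c0 <= b.midpoint < c1):
            out.append(b)
    return out


@dataclass
class ClusterTable:
    """Maximal runs of HDS boundaries with member counts and spans."""

    clusters: pd.DataFrame  # cluster_id, chrom, start, end, n_members, members
    singletons: list  # Boundary objects not in any cluster
    gap: int

    def summary(self) -> dict:
        n_clustered = int(self.clusters["n_members"].sum()) if len(self.clusters) else 0
        n_total = n_clustered + len(self.singletons)
        sizes = self.clusters["n_members"]
        return {
            "n_clusters": len(self.clusters),
            "n_boundaries": n_total,
            "mean_size": float(sizes.mean()) if len(sizes) else float("nan"),
            "min_size": int(sizes.min()) if len(sizes) else 0,
            "max_size": int(sizes.max()) if len(sizes) else 0,
            "clustered_fraction": n_clustered / n_total if n_total else float("nan"),
        }

    def spans(self) -> pd.DataFrame:
        return self.clusters[["chrom", "start", "end"]].copy()

    def total_span(self) -> int:
        if not len(self.clusters):
            return 0
        return int((self.clusters["end"] - self.clusters["start"]).sum())


def cluster_boundaries(hds_boundaries: list[Boundary], gap: int = 2_000_000) -> ClusterTable:
    """Single linear sweep merging consecutive boundaries with gap <= threshold.

    A cluster needs at least two members; lone boundaries are reported as
    singletons. Cluster spans run from the first to the last member
    midpoint.
    """
    by_chrom: dict[str, list[Boundary]] = {}
    for b in hds_boundaries:
        by_chrom.setdefault(b.chrom, []).append(b)
    rows, singletons = [], []
    cid = 0
    for chrom in sorted(by_chrom):
        bl = sorted(by_chrom[chrom], key=lambda b: b.midpoint)
        run = [bl[0]]
        for b in bl[1:]:
            if b.midpoint - run[-1].midpoint <= gap:
                run.append(b)
            else:
                cid = _flush_run(run, rows, singletons, cid, chrom)
                run = [b]
        cid = _flush_run(run, rows, singletons, cid, chrom)
    clusters = pd.DataFrame(
        rows, columns=["cluster_id", "chrom", "start", "end", "n_members", "members"]
    )
    return ClusterTable(clusters=clusters, singletons=singletons, gap=gap)


def _flush_run(run, rows, singletons, cid, chrom):
    if len(run) >= 2:
        rows.append(
            (
                cid,
                chrom,
                run[0].midpoint,
                run[-1].midpoint,
                len(run),
                [b.key for b in run],
            )
        )
        return cid + 1
    singletons.extend(run)
    return cid


# ---------------------------------------------------------------------------
# trans aggregation


def _hds_counts_per_bin(bins: BinTable, boundaries: list[Boundary]) -> dict:
    counts = {c: np.zeros(bins.n_bins(c), dtype=int) for c in bins.layout.chromosomes}
    for b in boundaries:
        counts[b.chrom][b.midpoint // bins.bin_size] += 1
    return counts


def _group_of(count: int, groups: tuple[int, ...]) -> int:
    """Index of the group a count falls in; last group is open-ended."""
    for gi in range(len(groups) - 1, -1, -1):
        if count >= groups[gi]:
            return gi
    return 0


def group_label(gi: int, groups: tuple[int, ...]) -> str:
    return f"{groups[gi]}+" if gi == len(groups) - 1 else str(groups[gi])


def trans_aggregate(
    cmap: ContactMap,
    hds_boundaries: list[Boundary],
    groups: tuple[int, ...] = (0, 1, 2, 3),
    bin_size: int = 4_000_000,
    mode: str = "pair",
    condition: str | None = None,
) -> pd.DataFrame:
    """Mean normalized trans contacts grouped by per-bin HDS-boundary count.

    Counts are scaled to counts-per-million (each sample's trans total
    becomes 1e6). Every 4-Mb bin gets the number of HDS boundaries whose
    midpoint it contains and a group per ``groups`` (last group
    open-ended). With ``mode="pair"`` (default) a group's value is the
    mean CPM over interchromosomal bin pairs whose BOTH bins fall in that
    group; ``mode="single"`` averages over all trans pairs involving at
    least one group bin.
    """
    bins = cmap.bins
    if bins.bin_size != bin_size:
        raise InvalidParameterError(
            f"trans aggregation expects {bin_size}-bp bins, map has {bins.bin_size}"
        )
    if mode not in ("pair", "single"):
        raise InvalidParameterError(f"mode must be 'pair' or 'single', got {mode!r}")
    total = cmap.total_trans
    if total <= 0:
        raise InvalidParameterError("trans map has zero total counts")
    cpm_factor = 1e6 / total
    hds = _hds_counts_per_bin(bins, hds_boundaries)
    # bins with no trans coverage at all (unmappable/absent) leave the groups
    coverage = {c: np.zeros(bins.n_bins(c)) for c in bins.layout.chromosomes}
    for (c1, c2), m in cmap.trans.items():
        coverage[c1] += m.sum(axis=1)
        coverage[c2] += m.sum(axis=0)
    group_idx = {
        c: np.where(
            coverage[c] > 0,
            np.array([_group_of(k, groups) for k in hds[c]]),
            -1,
        )
        for c in hds
    }
    ng = len(groups)
    sums = np.zeros((ng,))
    npairs = np.zeros((ng,), dtype=int)
    for (c1, c2), m in cmap.trans.items():
        g1 = group_idx[c1]
        g2 = group_idx[c2]
        for gi in range(ng):
            if mode == "pair":
                sel = np.ix_(g1 == gi, g2 == gi)
                sums[gi] += m[sel].sum()
                npairs[gi] += (g1 == gi).sum() * (g2 == gi).sum()
            else:
                row = m[g1 == gi, :]
                col = m[:, g2 == gi]
                sums[gi] += row.sum() + col.sum()
                npairs[gi] += row.size + col.size
    with np.errstate(invalid="ignore"):
        means = np.where(npairs > 0, sums * cpm_factor / np.maximum(npairs, 1), np.nan)
    return pd.DataFrame(
        {
            "group": [group_label(gi, groups) for gi in range(ng)],
            "hds_min": list(groups),
            "mean_cpm": means,
            "n_pairs": npairs,
            "condition": condition,
        }
    )


def control_total_boundaries(
    bins: BinTable,
    all_boundaries: list[Boundary],
    hds_boundaries: list[Boundary],
    groups: tuple[int, ...] = (0, 1, 2, 3),
) -> pd.DataFrame:
    """Total-boundary counts per HDS-count group (confounder check).

    For each group of bins (by HDS-boundary count), summarizes the
    distribution of TOTAL boundary counts, to verify that trans-contact
    differences between groups are not explained by overall boundary
    density.
    """
    hds = _hds_counts_per_bin(bins, hds_boundaries)
    tot = _hds_counts_per_bin(bins, all_boundaries)
    rows = []
    for c in bins.layout.chromosomes:
        for k in range(bins.n_bins(c)):
            rows.append((group_label(_group_of(hds[c][k], groups), groups), tot[c][k]))
    df = pd.DataFrame(rows, columns=["group", "total_boundaries"])
    return (
        df.groupby("group", sort=False)["total_boundaries"]
        .agg(n_bins="size", mean="mean", std="std")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# housekeeping enrichment


def housekeeping_genes(expression: pd.DataFrame, top_fraction: float = 0.01) -> list[str]:
    """Genes in the top ``top_fraction`` by expression in EVERY tissue.

    ``expression`` is gene-by-tissue. The housekeeping set is the
    intersection of the per-tissue top lists.
    """
    if not 0 < top_fraction <= 0.5:
        raise InvalidParameterError(
            f"top_fraction must be in (0, 0.5], got {top_fraction}"
        )
    if expression.shape[1] < 2:
        raise InvalidParameterError("need >= 2 tissues")
    k = max(1, int(np.ceil(top_fraction * len(expression))))
    sets = []
    for col in expression.columns:
        sets.append(set(expression[col].nlargest(k).index))
    return sorted(set.intersection(*sets))


def housekeeping_enrichment(
    expression: pd.DataFrame,
    genes: pd.DataFrame,
    cluster_spans: pd.DataFrame,
    layout: GenomeLayout,
    top_fraction: float = 0.01,
) -> dict:
    """Density enrichment of housekeeping genes on cluster spans.

    ``genes`` is a BED6-like frame (chrom, start, end, name, ...); a gene
    belongs to a cluster when its midpoint falls inside a span. The
    enrichment is (housekeeping genes per Mb inside spans) / (per Mb
    outside). Returns a dict with the ratio, the housekeeping set size and
    the genomic fraction covered by clusters; an empty housekeeping
    intersection yields enrichment NaN with ``defined=False``.
    """
    hk = housekeeping_genes(expression, top_fraction)
    span_bp = int((cluster_spans["end"] - cluster_spans["start"]).sum())
    genome_bp = layout.total_length
    frac = span_bp / genome_bp
    result = {
        "n_housekeeping": len(hk),
        "cluster_fraction": frac,
        "defined": bool(hk) and 0 < span_bp < genome_bp,
    }
    if not result["defined"]:
        result["enrichment"] = float("nan")
        result["n_inside"] = 0
        return result
    sub = genes.set_index("name").loc[[g for g in hk if g in set(genes["name"])]]
    mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
    chroms = sub["chrom"].to_numpy()
    inside = np.zeros(len(sub), dtype=bool)
    for row in cluster_spans.itertuples(index=False):
        inside |= (chroms == row.chrom) & (mids >= row.start) & (mids < row.end)
    n_in = int(inside.sum())
    n_out = len(sub) - n_in
    dens_in = n_in / (span_bp / 1e6)
    dens_out = n_out / ((genome_bp - span_bp) / 1e6)
    result["n_inside"] = n_in
    result["enrichment"] = dens_in / dens_out if dens_out > 0 else float("inf")
    return result
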