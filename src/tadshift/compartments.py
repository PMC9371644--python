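"""A/B compartment analysis at coarse (500-kb) resolution.

Per chromosome, the contact matrix is distance-normalized (observed over
the per-diagonal expected), converted to a Pearson correlation matrix over
valid bins, and the leading eigenvector (PC1) of that correlation matrix
gives the compartment profile. The eigenvector sign is arbitrary, so it is
oriented to correlate positively with a caller-supplied anchor track
(gene density in real data; the planted compartment profile in
simulations). Bins with PC1 > 0 are labelled A, the rest B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .differential import boundary_shift_test
from .errors import InvalidParameterError
from .genome_io import BinTable
from statsmodels.stats.multitest import multipletests

__all__ = ["CompartmentTrack", "compartment_pc1", "differential_compartments"]

MIN_VALID_BINS = 10


@dataclass
class CompartmentTrack:
    """Per-bin PC1 values and A/B labels; NaN PC1 marks masked bins."""

    bins: BinTable
    pc1: dict  # chrom -> float array, unit norm over valid bins
    orientation_anchor: str = "anchor"

    def labels(self, chrom: str) -> np.ndarray:
        v = self.pc1[chrom]
        lab = np.full(len(v), None, dtype=object)
        lab[np.isfinite(v) & (v > 0)] = "A"
        lab[np.isfinite(v) & (v <= 0)] = "B"
        return lab

    def to_bedgraph_frame(self) -> pd.DataFrame:
        frames = []
        for chrom in self.bins.layout.chromosomes:
            if chrom not in self.pc1:
                continue
            lo, hi = self.bins.chrom_range(chrom)
            sub = self.bins.df.iloc[lo:hi]
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": sub["start"].to_numpy(),
                        "end": sub["end"].to_numpy(),
                        "value": self.pc1[chrom],
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        return df[np.isfinite(df["value"])].reset_index(drop=True)


def _observed_over_expected(m: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """O/E over valid bins; expected = per-diagonal mean across valid pairs."""
    n = m.shape[0]
    oe = np.full_like(m, np.nan, dtype=float)
    pairmask = np.outer(valid, valid)
    for d in range(n):
        idx = np.arange(n - d)
        vals = m[idx, idx + d]
        ok = pairmask[idx, idx + d]
        if not ok.any():
            continue
        exp = vals[ok].mean()
        if exp <= 0:
            continue
        oe[idx, idx + d] = vals / exp
        oe[idx + d, idx] = vals / exp
    return oe


def compartment_pc1(cmap: ContactMap, orientation: dict) -> CompartmentTrack:
    """Compartment PC1 per chromosome from a coarse cis ContactMap.

    ``orientation`` maps chromosome -> per-bin anchor values used only to
    fix the eigenvector sign (PC1 is flipped so its correlation with the
    anchor is nonnegative). Chromosomes with fewer than 10 valid bins are
    skipped with a warning.
    """
    bins = cmap.bins
    pc1 = {}
    for chrom in bins.layout.chromosomes:
        if chrom not in cmap.cis:
            continue
        m = cmap.cis[chrom]
        n = m.shape[0]
        valid = cmap.cis_mask.get(chrom, m.sum(axis=1) > 0).copy()
        track = np.full(n, np.nan)
        if valid.sum() < MIN_VALID_BINS:
            warnings.warn(
                f"chromosome {chrom!r}: only {int(valid.sum())} valid bins; skipped"
            )
            pc1[chrom] = track
            continue
        oe = _observed_over_expected(m, valid)
        sub = oe[np.ix_(valid, valid)]
        # rows without variance cannot enter a correlation matrix
        sd = np.nanstd(sub, axis=1)
        keep = np.isfinite(sd) & (sd > 0)
        if keep.sum() < MIN_VALID_BINS:
            warnings.warn(f"chromosome {chrom!r}: too few variable bins; skipped")
            pc1[chrom] = track
            continue
        sub = sub[np.ix_(keep, keep)]
        corr = np.corrcoef(sub)
        evals, evecs = np.linalg.eigh(corr)
        vec = evecs[:, -1]  # leading eigenvector, unit norm
        anchor = np.asarray(orientation[chrom], dtype=float)
        if len(anchor) != n:
            raise InvalidParameterError(
                f"orientation track for {chrom!r} has length {len(anchor)}, expected {n}"
            )
        sel = np.flatnonzero(valid)[keep]
        a = anchor[sel]
        if np.std(a) > 0 and np.std(vec) > 0:
            if np.corrcoef(vec, a)[0, 1] < 0:
                vec = -vec
        track[sel] = vec
        pc1[chrom] = track
    return CompartmentTrack(bins=bins, pc1=pc1)


def differential_compartments(
    tracks: dict[str, list[CompartmentTrack]],
    control: str,
    treated: str,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-bin differential PC1 between two conditions with replicates.

    Uses the same Gaussian replicate test as differential boundary
    insulation, BH-corrected across bins. A bin is ``switched`` when it is
    significant at ``fdr`` AND the condition mean PC1 changes sign
    (crosses the A/B divide).
    """
    def stack(cond: str) -> pd.DataFrame:
        cols = {}
        for r, tr in enumerate(tracks[cond]):
            vals = np.concatenate(
                [tr.pc1[c] for c in tr.bins.layout.chromosomes if c in tr.pc1]
            )
            cols[f"{cond}_{r}"] = vals
        return pd.DataFrame(cols)

    ctrl = stack(control)
    trt = stack(treated)
    scores = pd.concat([ctrl, trt], axis=1)
    table = boundary_shift_test(scores, list(ctrl.columns), list(trt.columns))
    bins0 = tracks[control][0].bins
    chroms = np.concatenate(
        [
            np.repeat(c, bins0.n_bins(c))
            for c in bins0.layout.chromosomes
            if c in tracks[control][0].pc1
        ]
    )
    local = np.concatenate(
        [
            np.arange(bins0.n_bins(c))
            for c in bins0.layout.chromosomes
            if c in tracks[control][0].pc1
        ]
    )
    table.insert(0, "chrom", chroms)
    table.insert(1, "bin", local)
    table["q"] = np.nan
    tested = table["p"].notna()
    if tested.any():
        _, q, _, _ = multipletests(table.loc[tested, "p"], method="fdr_bh")
        table.loc[tested, "q"] = q
    table["significant"] = tested & (table["q"] < fdr)
    table["switched"] = table["significant"] & (
        np.sign(table["mean_control"]) != np.sign(table["mean_treated"])
    )
    return table
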