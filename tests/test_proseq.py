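import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from math import comb

import scipy.stats

from tadshift.genome_io import GenomeLayout
from tadshift.insulation import Boundary
from tadshift.proseq import (
    boundary_transcription,
    deregulated_boundary_enrichment,
    differential_pausing,
    fraction_boundary_transcripts,
    pause_body_counts,
    pausing_index,
    pausing_table,
    read_coverage,
    write_coverage,
)
from tadshift.simulate import GeneSpec, SimulationConfig, simulate_proseq


def _cov(length=100_000, chrom="c"):
    return {"+": {chrom: np.zeros(length)}, "-": {chrom: np.zeros(length)}}


class TestPausingIndex:
    def test_equal_densities_give_unity(self):
        cov = _cov()
        cov["+"]["c"][9_950:10_300] = 2.0  # pause window of a gene at 10k
        cov["+"]["c"][10_300:30_000] = 2.0
        pi = pausing_index(cov, "c", 10_000, 30_000, "+")
        assert pi == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        """50 reads over 350 bp pause vs 100 reads over 5000 bp body."""
        cov = _cov()
        cov["+"]["c"][9_950:10_300] = 50 / 350
        cov["+"]["c"][10_300:15_300] = 100 / 5_000
        pi = pausing_index(cov, "c", 10_000, 15_300, "+")
        assert pi == pytest.approx((50 / 350) / (100 / 5000))
        assert pi == pytest.approx(7.142857142857143)

    def test_matches_per_base_tally(self, rng):
        """Formula equals a brute-force per-base tally on random coverage."""
        for _ in range(20):
            cov = _cov()
            arr = cov["+"]["c"]
            arr[:] = rng.poisson(0.5, len(arr))
            start, end = 20_000, 20_000 + int(rng.integers(2_000, 50_000))
            pause, plen, body, blen = pause_body_counts(cov, "c", start, end, "+")
            assert pause == sum(arr[i] for i in range(start - 50, start + 300))
            assert body == sum(arr[i] for i in range(start + 300, end))
            assert (plen, blen) == (350, end - start - 300)

    def test_strand_mirror_invariance(self, rng):
        arr = rng.poisson(1.0, 40_000).astype(float)
        L = 40_000
        cov_f = _cov(L)
        cov_f["+"]["c"][:] = arr
        cov_r = _cov(L)
        cov_r["-"]["c"][:] = arr[::-1]
        pi_f = pausing_index(cov_f, "c", 5_000, 35_000, "+")
        pi_r = pausing_index(cov_r, "c", L - 35_000, L - 5_000, "-")
        assert pi_f == pytest.approx(pi_r)

    def test_low_body_reads_undefined(self):
        cov = _cov()
        cov["+"]["c"][9_950:10_300] = 1.0
        assert np.isnan(pausing_index(cov, "c", 10_000, 30_000, "+"))

    def test_table_reason_codes(self):
        cov = _cov()
        genes = pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "start": [10_000, 50_000],
                "end": [10_350, 90_000],
                "name": ["short", "quiet"],
                "score": [0.0, 0.0],
                "strand": ["+", "+"],
            }
        )
        out = pausing_table(cov, genes).set_index("gene")
        assert out.loc["short", "reason"] == "too_short"
        assert out.loc["quiet", "reason"] == "low_body"


def _fisher_enumeration_oracle(table):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total


class TestDifferentialPausing:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene", "chrom", "start", "end", "strand",
                     "pause_reads", "pause_len", "body_reads", "body_len",
                     "pi", "reason"],
        )

    def test_fisher_matches_enumeration(self):
        table = [[10, 90], [40, 60]]
        _, p_scipy = scipy.stats.fisher_exact(table)
        assert p_scipy == pytest.approx(_fisher_enumeration_oracle(table), rel=1e-9)

    def test_fisher_symmetric_under_row_and_column_swap(self):
        t = np.array([[10, 90], [40, 60]])
        _, p1 = scipy.stats.fisher_exact(t)
        _, p2 = scipy.stats.fisher_exact(t[::-1, ::-1])
        assert p1 == pytest.approx(p2)

    def test_identical_counts_unchanged(self):
        row = ("g", "c", 0, 10_000, "+", 50.0, 350, 100.0, 9_700, 1.0, "ok")
        ctrl = [self._table([row]), self._table([row])]
        trt = [self._table([row]), self._table([row])]
        out = differential_pausing(ctrl, trt)
        assert out.loc[0, "p"] == pytest.approx(1.0)
        assert out.loc[0, "class"] == "unchanged"

    def test_recovery_of_designated_paused_set(self):
        """Raised f_pause genes are recovered with high sensitivity, low FDR."""
        layout = GenomeLayout(("c",), {"c": 10_000_000})
        genes, raised = [], set()
        for i in range(60):
            start = 30_000 + i * 160_000
            f_treated = 0.5 if i % 4 == 0 else 0.25
            if i % 4 == 0:
                raised.add(f"g{i}")
            genes.append(
                GeneSpec(f"g{i}", "c", start, start + 20_000, "+", 100.0,
                         {"control": 0.25, "treated": f_treated})
            )
        cfg = SimulationConfig(
            seed=11, layout=layout, bin_size=40_000, boundaries=(),
            conditions=(("control", 0.0), ("treated", 0.0)),
            genes=tuple(genes), proseq_depth=3e5,
        )
        gdf = pd.DataFrame(
            {"chrom": "c", "start": [g.start for g in genes],
             "end": [g.end for g in genes], "name": [g.name for g in genes],
             "score": 0.0, "strand": "+"}
        )
        tables = {}
        for cond in ("control", "treated"):
            tables[cond] = [
                pausing_table(simulate_proseq(cfg, cond, r), gdf) for r in range(2)
            ]
        out = differential_pausing(tables["control"], tables["treated"])
        called = set(out.loc[out["class"] == "more_paused", "gene"])
        tp = len(called & raised)
        fp = len(called - raised)
        assert tp / len(raised) >= 0.8
        assert fp / max(len(called), 1) <= 0.1

    def test_pi_monotone_in_pause_fraction(self):
        """Estimated PI tracks the multinomial closed form across f_pause."""
        layout = GenomeLayout(("c",), {"c": 200_000})
        pis, expected = [], []
        for f in (0.1, 0.3, 0.5, 0.7):
            gene = GeneSpec("g", "c", 50_000, 90_000, "+", 1.0, {"control": f})
            cfg = SimulationConfig(
                seed=4, layout=layout, bin_size=40_000, boundaries=(),
                conditions=(("control", 0.0),), genes=(gene,), proseq_depth=2e5,
            )
            cov = simulate_proseq(cfg, "control", 0)
            pis.append(pausing_index(cov, "c", 50_000, 90_000, "+"))
            blen = 40_000 - 300
            expected.append((f / 350) / ((1 - f) / blen))
        assert all(np.diff(pis) > 0)
        for got, exp in zip(pis, expected):
            assert got == pytest.approx(exp, rel=0.05)


class TestBoundaryProfiles:
    def test_zero_coverage_zero_matrix(self):
        cov = _cov(1_000_000)
        b = [Boundary("c", 10, 420_000, -1.0, 0.5)]
        out = boundary_transcription(cov, b, flank=100_000, n_bins=11)
        assert out.shape == (1, 11)
        assert (out == 0).all()

    def test_single_read_lands_in_center_bin(self):
        cov = _cov(1_000_000)
        cov["+"]["c"][420_000] = 1.0
        b = [Boundary("c", 10, 420_000, -1.0, 0.5)]
        out = boundary_transcription(cov, b, flank=100_000, n_bins=11)
        assert np.flatnonzero(out[0]) == [5]

    def test_hds_profile_exceeds_unaffected(self, demo):
        cov = simulate_proseq(demo, "control", 0)
        hds, rest = [], []
        for b in demo.boundaries:
            bb = Boundary(b.chrom, b.position // 40_000, b.position, -1.0, 0.5)
            (hds if b.hds else rest).append(bb)
        p_hds = boundary_transcription(cov, hds, flank=60_000, n_bins=5).mean(axis=0)
        p_rest = boundary_transcription(cov, rest, flank=60_000, n_bins=5).mean(axis=0)
        assert p_hds[2] > p_rest[2]


class TestRegionEnrichment:
    def _regions(self, spans):
        return pd.DataFrame(
            {"chrom": "c", "start": [s for s, _ in spans], "end": [e for _, e in spans]}
        )

    def _genes(self, positions):
        return pd.DataFrame(
            {"chrom": "c", "start": positions, "end": [p + 1_000 for p in positions],
             "name": [f"g{i}" for i in range(len(positions))]}
        )

    def test_direct_arithmetic(self):
        """10 genes in 10 Mb HDS vs 20 genes in 40 Mb unaffected -> 2.0."""
        hds = self._regions([(0, 10_000_000)])
        una = self._regions([(20_000_000, 60_000_000)])
        genes = self._genes(
            [i * 1_000_000 + 1000 for i in range(10)]
            + [20_000_000 + i * 2_000_000 + 1000 for i in range(20)]
        )
        assert deregulated_boundary_enrichment(genes, hds, una) == pytest.approx(2.0)

    def test_label_swap_inverts_ratio(self):
        hds = self._regions([(0, 10_000_000)])
        una = self._regions([(20_000_000, 60_000_000)])
        genes = self._genes([1_000, 21_000_000, 25_000_000])
        a = deregulated_boundary_enrichment(genes, hds, una)
        b = deregulated_boundary_enrichment(genes, una, hds)
        assert a == pytest.approx(1 / b)


class TestBoundaryTranscriptFraction:
    def test_edge_cases(self):
        allb = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1_000_000]})
        none_hds = allb.iloc[:0]
        tx = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [200]})
        assert fraction_boundary_transcripts(tx, none_hds, allb) == 0.0
        assert fraction_boundary_transcripts(tx, allb, allb) == 1.0

    def test_proportional_to_span_share(self, rng):
        n = 5_000
        pos = rng.integers(0, 10_000_000, n)
        tx = pd.DataFrame({"chrom": "c", "start": pos, "end": pos + 10})
        allb = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10_000_000]})
        hds = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [3_000_000]})
        frac = fraction_boundary_transcripts(tx, hds, allb)
        assert frac == pytest.approx(0.3, abs=0.03)


def test_coverage_round_trip(tmp_path, rng):
    layout = GenomeLayout(("c",), {"c": 50_000})
    cov = {"+": {"c": rng.poisson(0.2, 50_000).astype(float)},
           "-": {"c": rng.poisson(0.2, 50_000).astype(float)}}
    write_coverage(cov, tmp_path / "x")
    back = read_coverage(tmp_path / "x", layout)
    for s in "+-":
        np.testing.assert_array_equal(cov[s]["c"], back[s]["c"])
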