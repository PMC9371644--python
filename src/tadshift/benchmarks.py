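"""Recovery and calibration experiments on the bundled synthetic conditions.

Each function regenerates its inputs from a seed, runs the corresponding
analysis path end to end, and returns the measured quantity. They back
both the acceptance checks and the reproducibility script; problem sizes
are chosen so the whole battery runs in a few minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .compartments import compartment_pc1
from .differential import (
    boundary_shift_glm,
    boundary_shift_test,
    classify_boundaries,
)
from .insulation import balance_matrix, call_boundaries, insulation_score
from .proseq import pausing_index, pausing_table, differential_pausing
from .simulate import (
    demo_config,
    simulate_cis,
    simulate_compartment_cis,
    simulate_proseq,
    simulate_trans,
)
from .spatial import cluster_boundaries, filter_centromeric, trans_aggregate

WINDOW = 480_000
PROMINENCE = 0.1


def boundary_recovery(seed: int, window: int = WINDOW) -> dict:
    """Fraction of planted boundaries recovered within +-1 bin (demo genome)."""
    cfg = demo_config(seed)
    cmap = simulate_cis(cfg, "control", 0)
    track = insulation_score(balance_matrix(cmap), window)
    called = call_boundaries(track, PROMINENCE)
    called_set = {(b.chrom, b.bin) for b in called}
    hits = 0
    for b in cfg.boundaries:
        bbin = b.position // cfg.bin_size
        if any((b.chrom, bbin + d) in called_set for d in (-1, 0, 1)):
            hits += 1
    return {
        "recovered_fraction": hits / len(cfg.boundaries),
        "n_planted": len(cfg.boundaries),
        "n_called": len(called),
    }


def null_calibration(
    seed: int, n_runs: int = 200, n_boundaries: int = 5000, sigma: float = 0.05
) -> dict:
    """Type-I calibration of the boundary test under the no-effect null.

    Draws replicate insulation scores with pure Gaussian noise (no
    condition effect) and measures the raw p < 0.05 rate plus the fraction
    of runs with zero HDS calls after BH at q < 0.05.
    """
    rng = np.random.default_rng([seed, 31])
    n_sig = 0
    n_total = 0
    zero_hds_runs = 0
    for _ in range(n_runs):
        scores = pd.DataFrame(
            rng.normal(-1.0, sigma, size=(n_boundaries, 4)),
            columns=["c0", "c1", "t0", "t1"],
        )
        res = boundary_shift_test(scores, ["c0", "c1"], ["t0", "t1"])
        n_sig += int((res["p"] < 0.05).sum())
        n_total += int(res["p"].notna().sum())
        out = classify_boundaries(res, 0.05)
        if (out["class"] == "HDS").sum() == 0:
            zero_hds_runs += 1
    return {
        "p_rate": n_sig / n_total,
        "n_tests": n_total,
        "zero_hds_fraction": zero_hds_runs / n_runs,
        "n_runs": n_runs,
    }


def differential_power(seed: int, n_genomes: int = 6, window: int = WINDOW) -> dict:
    """Sensitivity and empirical FDR of HDS detection through the full path.

    Each genome: simulate control and 5-min treatment (2 replicates each),
    balance, score insulation, call boundaries on pooled control, test,
    classify. A called HDS boundary within +-1 bin of a planted weakened
    boundary is a true positive.
    """
    tp = fp = n_true = 0
    for g in range(n_genomes):
        cfg = demo_config(seed + 1000 + g)
        maps = {}
        for cond in ("control", "HD_5min"):
            for rep in range(2):
                maps[f"{cond}.{rep}"] = simulate_cis(cfg, cond, rep)
        pooled = maps["control.0"]
        pooled_sum = {
            c: maps["control.0"].cis[c] + maps["control.1"].cis[c]
            for c in pooled.cis
        }
        ref = simulate_cis(cfg, "control", 0)  # container reuse
        ref.cis = pooled_sum
        ref_track = insulation_score(balance_matrix(ref), window)
        boundaries = call_boundaries(ref_track, PROMINENCE)
        tracks = {
            name: insulation_score(balance_matrix(m), window)
            for name, m in maps.items()
        }
        from .insulation import score_boundaries_across_samples

        scores = score_boundaries_across_samples(boundaries, tracks)
        res = boundary_shift_test(
            scores, ["control.0", "control.1"], ["HD_5min.0", "HD_5min.1"]
        )
        out = classify_boundaries(res, 0.05)
        planted = {
            (b.chrom, b.position // cfg.bin_size)
            for b in cfg.boundaries
            if b.hds
        }
        n_true += len(planted)
        called_rows = scores[(out["class"] == "HDS").to_numpy()]
        called = set(zip(called_rows["chrom"], called_rows["bin"]))
        matched_planted = {
            (c, b)
            for c, b in planted
            if any((c, b + d) in called for d in (-1, 0, 1))
        }
        tp += len(matched_planted)
        fp += sum(
            not any((c, b + d) in planted for d in (-1, 0, 1)) for c, b in called
        )
    n_called = tp + fp
    return {
        "sensitivity": tp / n_true,
        "fdr": fp / n_called if n_called else 0.0,
        "n_true": n_true,
        "n_called": n_called,
    }


def glm_t_equivalence(seed: int, n: int = 1000) -> dict:
    """Max relative p-value disagreement between the GLM and pooled-t routes."""
    import scipy.stats

    rng = np.random.default_rng([seed, 47])
    worst = 0.0
    for _ in range(n):
        a = rng.normal(size=2)
        b = rng.normal(size=2)
        _, _, p_glm = boundary_shift_glm(a, b)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t = (b.mean() - a.mean()) / np.sqrt(sp2)
        p_ref = 2 * scipy.stats.t.sf(abs(t), 2)
        worst = max(worst, abs(p_glm - p_ref) / p_ref)
    return {"max_rel_diff": worst, "n": n}


def compartment_recovery(seed: int) -> dict:
    """Fraction of valid 500-kb bins whose PC1 sign matches the planted profile."""
    cfg = demo_config(seed)
    cmap = simulate_compartment_cis(cfg, "control", 0)
    spec = cfg.compartments
    anchor = {c: spec.signs[c] for c in cfg.layout.chromosomes}
    track = compartment_pc1(cmap, anchor)
    hits = total = 0
    for c in cfg.layout.chromosomes:
        v = track.pc1[c]
        ok = np.isfinite(v)
        s = np.sign(np.asarray(spec.signs[c]))[ok]
        hits += int((np.sign(v[ok]) == s).sum())
        total += int(ok.sum())
    return {"sign_accuracy": hits / total, "n_bins": total}


def trans_enrichment_recovery(seed: int) -> dict:
    """Top/bottom group CPM ratio on the demo trans maps and monotonicity."""
    cfg = demo_config(seed)
    from .insulation import Boundary

    hds = [
        Boundary(b.chrom, b.position // cfg.bin_size, b.position, -1.0, 1.0)
        for b in cfg.boundaries
        if b.hds
    ]
    cmap = simulate_trans(cfg, "control", 0)
    out = trans_aggregate(cmap, hds, groups=(0, 1, 2, 3),
                          bin_size=cfg.trans_bin_size)
    occupied = out.dropna(subset=["mean_cpm"])
    means = occupied["mean_cpm"].to_numpy()
    return {
        "top_bottom_ratio": float(means[-1] / means[0]),
        "monotone": bool((np.diff(means) > 0).all()),
        "n_groups": len(occupied),
    }


def cluster_statistics(seed: int, gap: int = 2_000_000) -> dict:
    """HDS-cluster descriptives on the demo ground truth."""
    cfg = demo_config(seed)
    from .insulation import Boundary

    hds = [
        Boundary(b.chrom, b.position // cfg.bin_size, b.position, -1.0, 1.0)
        for b in cfg.boundaries
        if b.hds
    ]
    hds = filter_centromeric(hds, cfg.layout)
    table = cluster_boundaries(hds, gap=gap)
    s = table.summary()
    s["hds_fraction"] = sum(b.hds for b in cfg.boundaries) / len(cfg.boundaries)
    return s


def pausing_recovery(seed: int) -> dict:
    """PI closed-form agreement across an f_pause sweep plus the demo PI call."""
    cfg = demo_config(seed)
    cov = simulate_proseq(cfg, "control", 0)
    genes = pd.DataFrame(
        {"chrom": [g.chrom for g in cfg.genes], "start": [g.start for g in cfg.genes],
         "end": [g.end for g in cfg.genes], "name": [g.name for g in cfg.genes],
         "score": 0.0, "strand": [g.strand for g in cfg.genes]}
    )
    tables = {
        cond: [pausing_table(simulate_proseq(cfg, cond, r), genes) for r in range(2)]
        for cond in ("control", "HD_5min")
    }
    diff = differential_pausing(tables["control"], tables["HD_5min"])
    raised = {
        g.name for g in cfg.genes if g.pause_fraction.get("HD_5min", 0) > 0.25
    }
    called = set(diff.loc[diff["class"] == "more_paused", "gene"])
    tp = len(called & raised)
    fp = len(called - raised)
    # closed-form check on one deeply covered gene
    ok = tables["control"][0].set_index("gene")
    rel_err = []
    for g in cfg.genes:
        if g.name not in ok.index or ok.loc[g.name, "reason"] != "ok":
            continue
        row = ok.loc[g.name]
        if row["body_reads"] < 500:
            continue
        f = g.pause_fraction["control"]
        expected = (f / row["pause_len"]) / ((1 - f) / row["body_len"])
        rel_err.append(abs(row["pi"] / expected - 1))
    return {
        "sensitivity": tp / len(raised) if raised else float("nan"),
        "false_discovery": fp / max(len(called), 1),
        "n_raised": len(raised),
        "median_pi_rel_err": float(np.median(rel_err)),
        "n_checked": len(rel_err),
    }
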