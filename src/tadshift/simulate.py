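"""Multi-condition, multi-replicate synthetic Hi-C / PRO-seq / expression data.

The generator emulates a condensate-perturbation experiment: a genome
partitioned into TADs by boundaries of varying permeability; a treatment
that transiently weakens a designated ("HDS", hexanediol-sensitive) subset
of boundaries and then recovers over a time-course; replicate-level Poisson
sequencing noise; enriched trans contacts between designated cluster bins;
and nascent-transcription profiles with a tunable promoter-proximal pause
peak.

Generative model
----------------
Cis contacts, chromosome with bins i, j (i <= j)::

    E[i, j] = D * (1 + |i - j|)**(-alpha)
                * tau**[i, j in same TAD]
                * prod(pi_eff(b) for boundaries b strictly between i and j)

with D set so the expected total equals the configured per-chromosome
depth, and observed counts drawn Poisson(E) on the upper triangle then
mirrored. A boundary's effective permeability under condition c with
weakening factor w_c is ``pi + w_c * (1 - pi)`` for HDS boundaries and
``pi`` otherwise, so w_c = 0 is the control and w_c = 1 erases the
boundary.

Trans contacts between 4-Mb bins: ``E = lambda_trans * eps_eff`` when both
bins belong to the cluster-bin set, ``lambda_trans`` otherwise, with
``eps_eff = 1 + (eps - 1) * (1 - w_c)`` so treatment relaxes the
enrichment toward 1.

PRO-seq: each gene receives a Poisson total proportional to its expression;
a fraction ``f_pause`` of reads lands uniformly in the TSS-anchored pause
window (strand-aware) and the rest uniformly over the gene body.

Randomness: every (condition, replicate, data-kind) triple gets its own
stream derived from the master seed, so adding a replicate or condition
never perturbs the draws of existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .errors import InvalidParameterError
from .genome_io import BinTable, GenomeLayout, make_bin_table

__all__ = [
    "BoundarySpec",
    "GeneSpec",
    "CompartmentSpec",
    "SimulationConfig",
    "demo_config",
    "simulate_cis",
    "expected_cis",
    "simulate_trans",
    "expected_trans",
    "simulate_compartment_cis",
    "simulate_proseq",
    "simulate_expression",
    "ground_truth_tables",
]

# stream tags keep cis / trans / proseq / expression draws independent
_STREAM_CIS, _STREAM_TRANS, _STREAM_PROSEQ, _STREAM_EXPR, _STREAM_COMP = 1, 2, 3, 4, 5


def _label_key(label: str) -> int:
    digest = hashlib.sha256(label.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _rng(seed: int, stream: int, condition: str, replicate: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream, _label_key(condition), replicate])


@dataclass(frozen=True)
class BoundarySpec:
    """A planted TAD boundary: position in bp, permeability, HDS flag."""

    chrom: str
    position: int
    permeability: float
    hds: bool = False

    def __post_init__(self):
        if not 0.0 <= self.permeability <= 1.0:
            raise InvalidParameterError(
                f"permeability must be in [0, 1], got {self.permeability}"
            )


@dataclass(frozen=True)
class GeneSpec:
    """A gene with a relative expression level and per-condition pause fraction."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    expression: float
    pause_fraction: dict  # condition label -> f_pause in [0, 1)
    housekeeping: bool = False


@dataclass(frozen=True)
class CompartmentSpec:
    """Checkerboard A/B structure for 500-kb compartment simulations.

    ``signs`` holds the planted per-bin compartment sign (+1 = A, -1 = B)
    per chromosome at ``bin_size`` resolution; ``strength`` scales the
    checkerboard modulation ``(1 + strength * s_i * s_j)`` of expected
    counts. ``flips`` lists (chrom, bin) signs flipped under a condition.
    """

    bin_size: int
    signs: dict
    strength: float = 0.4
    depth: float = 2e6
    flips: dict = field(default_factory=dict)  # condition label -> [(chrom, bin)]

    def condition_signs(self, chrom: str, condition: str) -> np.ndarray:
        s = np.array(self.signs[chrom], dtype=float).copy()
        for c, b in self.flips.get(condition, []):
            if c == chrom:
                s[b] = -s[b]
        return s


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic perturbation experiment."""

    seed: int
    layout: GenomeLayout
    bin_size: int
    boundaries: tuple[BoundarySpec, ...]
    # ordered (label, weakening factor w_c); w_c = 0 is the control analog
    conditions: tuple[tuple[str, float], ...]
    n_replicates: int = 2
    alpha: float = 1.0
    tau: float = 1.5
    cis_depth: float = 1e6  # expected cis contacts per chromosome per replicate
    trans_bin_size: int = 4_000_000
    trans_rate: float = 5_000.0  # baseline expected count per trans bin pair
    trans_epsilon: float = 2.0
    cluster_bins: frozenset | None = None  # {(chrom, bin index at trans_bin_size)}
    genes: tuple[GeneSpec, ...] = ()
    proseq_depth: float = 1e6  # expected total PRO-seq reads per replicate
    pause_offset: tuple[int, int] = (-50, 300)  # pause window rel. TSS, tx direction
    compartments: CompartmentSpec | None = None
    n_tissues: int = 54
    expression_sigma: float = 1.0

    def __post_init__(self):
        if self.alpha <= 0:
            raise InvalidParameterError(f"decay exponent alpha must be > 0, got {self.alpha}")
        if self.tau < 1:
            raise InvalidParameterError(f"intra-TAD boost tau must be >= 1, got {self.tau}")
        if self.trans_epsilon < 1:
            raise InvalidParameterError("trans enrichment epsilon must be >= 1")
        for label, w in self.conditions:
            if not 0.0 <= w <= 1.0:
                raise InvalidParameterError(
                    f"weakening factor for {label!r} must be in [0, 1], got {w}"
                )

    def weakening(self, condition: str) -> float:
        for label, w in self.conditions:
            if label == condition:
                return w
        raise InvalidParameterError(f"unknown condition {condition!r}")

    @property
    def condition_labels(self) -> list[str]:
        return [label for label, _ in self.conditions]

    @property
    def control(self) -> str:
        return self.conditions[0][0]

    def effective_permeability(self, b: BoundarySpec, condition: str) -> float:
        w = self.weakening(condition)
        if b.hds:
            return b.permeability + w * (1.0 - b.permeability)
        return b.permeability

    def bin_table(self) -> BinTable:
        return make_bin_table(self.layout, self.bin_size)

    def trans_bin_table(self) -> BinTable:
        return make_bin_table(self.layout, self.trans_bin_size)

    def resolved_cluster_bins(self) -> frozenset:
        """Cluster-bin set; defaults to 4-Mb bins holding >= 2 HDS boundaries."""
        if self.cluster_bins is not None:
            return self.cluster_bins
        counts: dict[tuple[str, int], int] = {}
        for b in self.boundaries:
            if b.hds:
                key = (b.chrom, b.position // self.trans_bin_size)
                counts[key] = counts.get(key, 0) + 1
        return frozenset(k for k, v in counts.items() if v >= 2)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# cis


def _boundary_bins(config: SimulationConfig, chrom: str) -> list[tuple[int, float, bool]]:
    out = []
    for b in config.boundaries:
        if b.chrom == chrom:
            out.append((b.position // config.bin_size, b.permeability, b.hds))
    return sorted(out)


def expected_cis(config: SimulationConfig, condition: str, chrom: str) -> np.ndarray:
    """Closed-form expected cis matrix for one chromosome (noise-free)."""
    bins = config.bin_table()
    n = bins.n_bins(chrom)
    blist = _boundary_bins(config, chrom)
    # cumulative log-permeability and zero-count up to each bin; a boundary
    # at bin b separates i < b <= j
    log_cum = np.zeros(n)
    zero_cum = np.zeros(n, dtype=int)
    tad_id = np.zeros(n, dtype=int)
    for bbin, pi, hds in blist:
        spec = BoundarySpec(chrom, bbin * config.bin_size, pi, hds)
        pi_eff = config.effective_permeability(spec, condition)
        if bbin >= n:
            continue
        if pi_eff == 0.0:
            zero_cum[bbin:] += 1
        else:
            log_cum[bbin:] += np.log(pi_eff)
        tad_id[bbin:] += 1
    i = np.arange(n)
    dist = np.abs(i[:, None] - i[None, :])
    log_perm = log_cum[None, :] - log_cum[:, None]  # valid for i <= j
    log_perm = np.where(i[:, None] <= i[None, :], log_perm, log_perm.T)
    zeros = np.abs(zero_cum[None, :] - zero_cum[:, None])
    factor = np.where(zeros > 0, 0.0, np.exp(log_perm))
    same_tad = tad_id[:, None] == tad_id[None, :]
    e = (1.0 + dist) ** (-config.alpha) * np.where(same_tad, config.tau, 1.0) * factor
    total = np.triu(e).sum()
    return e * (config.cis_depth / total)


def simulate_cis(config: SimulationConfig, condition: str, replicate: int) -> ContactMap:
    """Draw one replicate cis contact map (Poisson noise on the expected map)."""
    rng = _rng(config.seed, _STREAM_CIS, condition, replicate)
    bins = config.bin_table()
    cmap = ContactMap(bins)
    for chrom in config.layout.chromosomes:
        e = expected_cis(config, condition, chrom)
        upper = np.triu(rng.poisson(e).astype(float))
        cmap.cis[chrom] = upper + np.triu(upper, 1).T
    return cmap


# ---------------------------------------------------------------------------
# trans


def expected_trans(
    config: SimulationConfig, condition: str, chrom1: str, chrom2: str
) -> np.ndarray:
    """Closed-form expected trans matrix for an ordered chromosome pair."""
    bins = config.trans_bin_table()
    cluster = config.resolved_cluster_bins()
    w = config.weakening(condition)
    eps_eff = 1.0 + (config.trans_epsilon - 1.0) * (1.0 - w)
    in1 = np.array([(chrom1, i) in cluster for i in range(bins.n_bins(chrom1))])
    in2 = np.array([(chrom2, j) in cluster for j in range(bins.n_bins(chrom2))])
    both = in1[:, None] & in2[None, :]
    return config.trans_rate * np.where(both, eps_eff, 1.0)


def simulate_trans(config: SimulationConfig, condition: str, replicate: int) -> ContactMap:
    """Draw one replicate of all interchromosomal 4-Mb contact matrices."""
    rng = _rng(config.seed, _STREAM_TRANS, condition, replicate)
    bins = config.trans_bin_table()
    cmap = ContactMap(bins)
    chroms = config.layout.chromosomes
    for a, c1 in enumerate(chroms):
        for c2 in chroms[a + 1 :]:
            e = expected_trans(config, condition, c1, c2)
            cmap.trans[(c1, c2)] = rng.poisson(e).astype(float)
    return cmap


# ---------------------------------------------------------------------------
# compartments


def simulate_compartment_cis(
    config: SimulationConfig, condition: str, replicate: int
) -> ContactMap:
    """Draw a coarse cis map with planted checkerboard A/B structure.

    Expected counts follow the distance decay modulated by
    ``(1 + strength * s_i * s_j)`` where ``s`` is the planted sign vector
    (possibly flipped for this condition).
    """
    if config.compartments is None:
        raise InvalidParameterError("config has no compartment specification")
    spec = config.compartments
    rng = _rng(config.seed, _STREAM_COMP, condition, replicate)
    bins = make_bin_table(config.layout, spec.bin_size)
    cmap = ContactMap(bins)
    for chrom in config.layout.chromosomes:
        n = bins.n_bins(chrom)
        s = spec.condition_signs(chrom, condition)
        if len(s) != n:
            raise InvalidParameterError(
                f"compartment signs for {chrom!r} have length {len(s)}, expected {n}"
            )
        i = np.arange(n)
        dist = np.abs(i[:, None] - i[None, :])
        e = (1.0 + dist) ** (-config.alpha) * (1.0 + spec.strength * np.outer(s, s))
        e *= spec.depth / np.triu(e).sum()
        upper = np.triu(rng.poisson(e).astype(float))
        cmap.cis[chrom] = upper + np.triu(upper, 1).T
    return cmap


# ---------------------------------------------------------------------------
# PRO-seq


def pause_body_windows(
    gene: GeneSpec, pause_offset: tuple[int, int] = (-50, 300)
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Strand-aware pause and body windows in genome coordinates.

    The pause window spans ``pause_offset`` around the TSS in the direction
    of transcription; the body runs from the pause window's downstream edge
    to the TES.
    """
    lo, hi = pause_offset
    if gene.strand == "+":
        tss = gene.start
        pause = (tss + lo, tss + hi)
        body = (tss + hi, gene.end)
    else:
        tss = gene.end
        pause = (tss - hi, tss - lo)
        body = (gene.start, tss - hi)
    return pause, body


def simulate_proseq(config: SimulationConfig, condition: str, replicate: int) -> dict:
    """Simulate stranded per-base nascent coverage.

    Returns ``{strand: {chrom: per-base float array}}``. Per gene the read
    total is Poisson with mean proportional to expression; reads fall
    uniformly in the pause window with probability ``f_pause`` and
    uniformly over the body otherwise.
    """
    rng = _rng(config.seed, _STREAM_PROSEQ, condition, replicate)
    cov = {
        strand: {c: np.zeros(config.layout.lengths[c]) for c in config.layout.chromosomes}
        for strand in "+-"
    }
    if not config.genes:
        return cov
    total_expr = sum(g.expression for g in config.genes)
    for gene in config.genes:
        mean_reads = config.proseq_depth * gene.expression / total_expr
        n_reads = rng.poisson(mean_reads)
        if n_reads == 0:
            continue
        f = gene.pause_fraction.get(condition, 0.0)
        (p0, p1), (b0, b1) = pause_body_windows(gene, config.pause_offset)
        length = config.layout.lengths[gene.chrom]
        p0, p1 = max(p0, 0), min(p1, length)
        b0, b1 = max(b0, 0), min(b1, length)
        n_pause = rng.binomial(n_reads, f)
        arr = cov[gene.strand][gene.chrom]
        if n_pause and p1 > p0:
            pos = rng.integers(p0, p1, size=n_pause)
            np.add.at(arr, pos, 1.0)
        n_body = n_reads - n_pause
        if n_body and b1 > b0:
            pos = rng.integers(b0, b1, size=n_body)
            np.add.at(arr, pos, 1.0)
    return cov


# ---------------------------------------------------------------------------
# expression


def simulate_expression(config: SimulationConfig) -> pd.DataFrame:
    """Gene-by-tissue log-normal expression table.

    Housekeeping genes draw from a high-mean, low-variance log-normal in
    every tissue; other genes from a lower-mean log-normal, independently
    per tissue.
    """
    rng = _rng(config.seed, _STREAM_EXPR, "expression", 0)
    tissues = [f"tissue_{t:02d}" for t in range(config.n_tissues)]
    data = {}
    for gene in config.genes:
        if gene.housekeeping:
            vals = rng.lognormal(np.log(1e5), 0.15, size=config.n_tissues)
        else:
            base = np.log(gene.expression * 10.0)
            vals = rng.lognormal(base, config.expression_sigma, size=config.n_tissues)
        data[gene.name] = vals
    return pd.DataFrame.from_dict(data, orient="index", columns=tissues)


# ---------------------------------------------------------------------------
# ground truth + demo configuration


def ground_truth_tables(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Boundary and gene ground-truth tables for benchmarking recovery."""
    btab = pd.DataFrame(
        [
            {
                "chrom": b.chrom,
                "position": b.position,
                "bin": b.position // config.bin_size,
                "permeability": b.permeability,
                "hds": b.hds,
            }
            for b in config.boundaries
        ]
    )
    rows = []
    for g in config.genes:
        row = {
            "gene": g.name,
            "chrom": g.chrom,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "expression": g.expression,
            "housekeeping": g.housekeeping,
        }
        for label in config.condition_labels:
            row[f"f_pause.{label}"] = g.pause_fraction.get(label, 0.0)
        rows.append(row)
    return btab, pd.DataFrame(rows)


_DEMO_BOUNDARIES = {
    # chrom: [(position Mb, permeability, hds)]
    "chrA": [
        (1.2, 0.40, False),
        (2.8, 0.15, False),
        (4.4, 0.20, True),
        (5.8, 0.20, True),
        (7.2, 0.30, False),
        (8.6, 0.10, False),
        (12.4, 0.50, False),
        (14.0, 0.25, False),
        (16.4, 0.35, False),
        (18.0, 0.15, False),
    ],
    "chrB": [
        (1.6, 0.30, False),
        (3.2, 0.20, False),
        (4.8, 0.45, False),
        (6.4, 0.10, False),
        (8.0, 0.25, False),
        (11.6, 0.50, False),
        (12.4, 0.20, True),
        (13.8, 0.20, True),
        (16.8, 0.35, False),
        (18.4, 0.15, False),
    ],
}

# treatment weakens HDS boundaries at 5 min then recovers by 3 h
_DEMO_SCHEDULE = (
    ("control", 0.0),
    ("HD_5min", 0.5),
    ("HD_30min", 0.25),
    ("HD_3h", 0.0),
)


def _demo_genes(layout: GenomeLayout, boundaries, cluster_spans, rng) -> tuple[GeneSpec, ...]:
    genes = []
    idx = 0
    hds_positions = {(b.chrom, b.position) for b in boundaries if b.hds}
    # boundary-proximal genes: one per boundary, straddling its midpoint;
    # genes at HDS boundaries are more highly expressed and gain pausing
    # under treatment (the designated paused set)
    for b in boundaries:
        length = int(rng.integers(8_000, 24_000))
        start = b.position - length // 2
        strand = "+" if rng.random() < 0.5 else "-"
        hds = (b.chrom, b.position) in hds_positions
        expr = float(rng.lognormal(np.log(300.0 if hds else 100.0), 0.3))
        pause = {"control": 0.25, "HD_5min": 0.5 if hds else 0.25,
                 "HD_30min": 0.35 if hds else 0.25, "HD_3h": 0.25}
        genes.append(
            GeneSpec(f"gene_{idx:03d}", b.chrom, start, start + length, strand,
                     expr, pause, housekeeping=False)
        )
        idx += 1
    # background genes scattered away from boundaries
    for chrom in layout.chromosomes:
        for _ in range(40):
            length = int(rng.integers(4_000, 30_000))
            start = int(rng.integers(0, layout.lengths[chrom] - length))
            strand = "+" if rng.random() < 0.5 else "-"
            expr = float(rng.lognormal(np.log(60.0), 0.8))
            pause = {c: 0.25 for c, _ in _DEMO_SCHEDULE}
            genes.append(
                GeneSpec(f"gene_{idx:03d}", chrom, start, start + length, strand,
                         expr, pause, housekeeping=False)
            )
            idx += 1
    # housekeeping genes, preferentially inside cluster spans
    for k in range(5):
        length = int(rng.integers(6_000, 16_000))
        if rng.random() < 0.8 and cluster_spans:
            chrom, lo, hi = cluster_spans[int(rng.integers(0, len(cluster_spans)))]
            start = int(rng.integers(lo, max(lo + 1, hi - length)))
        else:
            chrom = layout.chromosomes[int(rng.integers(0, len(layout.chromosomes)))]
            start = int(rng.integers(0, layout.lengths[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        pause = {c: 0.25 for c, _ in _DEMO_SCHEDULE}
        genes.append(
            GeneSpec(f"hk_{k:02d}", chrom, start, start + length, strand,
                     2000.0, pause, housekeeping=True)
        )
        idx += 1
    return tuple(genes)


def demo_config(seed: int = 0) -> SimulationConfig:
    """The bundled demo experiment: 2 chromosomes x 20 Mb at 40-kb bins.

    Twenty planted boundaries (permeabilities 0.10-0.50), four of them HDS
    (20%), arranged as one two-boundary cluster per chromosome inside a
    single 4-Mb bin; a four-point treatment/recovery schedule with two
    replicates per condition; ~1e6 cis contacts per chromosome per
    replicate; trans enrichment epsilon = 2 between cluster bins; ~1e6
    PRO-seq reads per replicate; checkerboard compartments at 500 kb.
    """
    layout = GenomeLayout(
        ("chrA", "chrB"),
        {"chrA": 20_000_000, "chrB": 20_000_000},
        centromeres={"chrA": (9_800_000, 10_200_000), "chrB": (9_800_000, 10_200_000)},
    )
    boundaries = tuple(
        BoundarySpec(chrom, int(mb * 1e6), pi, hds)
        for chrom, lst in _DEMO_BOUNDARIES.items()
        for mb, pi, hds in lst
    )
    # cluster spans (for housekeeping placement): HDS cluster extents +- 0.5 Mb
    cluster_spans = [("chrA", 3_900_000, 6_300_000), ("chrB", 11_900_000, 14_300_000)]
    gene_rng = np.random.default_rng([seed, 99])
    genes = _demo_genes(layout, boundaries, cluster_spans, gene_rng)
    signs = {
        c: np.repeat([1, -1], 5)[np.arange(40) % 10] * 1.0 for c in layout.chromosomes
    }
    compartments = CompartmentSpec(bin_size=500_000, signs=signs, strength=0.4, depth=2e6)
    return SimulationConfig(
        seed=seed,
        layout=layout,
        bin_size=40_000,
        boundaries=boundaries,
        conditions=_DEMO_SCHEDULE,
        n_replicates=2,
        alpha=1.0,
        tau=1.5,
        cis_depth=1e6,
        trans_rate=5_000.0,
        trans_epsilon=2.0,
        genes=genes,
        proseq_depth=1e6,
        compartments=compartments,
    )
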