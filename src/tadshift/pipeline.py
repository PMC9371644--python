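"""End-to-end workflow: simulate -> balance -> insulation -> boundaries ->
differential -> compartments -> clusters -> trans-agg -> pausing -> enrichment.

Every stage reads and writes the open on-disk formats of
:mod:`tadshift.genome_io`, so stages interoperate with external tools and
can be re-run individually. A JSON run manifest records parameters, seeds
and output checksums per stage; a stage is skipped on re-run when its
parameter/upstream signature is unchanged and its outputs still exist, so
changing e.g. the insulation window recomputes only downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compartments import compartment_pc1, differential_compartments
from .contacts import read_contacts, write_contacts
from .differential import (
    class_counts,
    differential_boundary_table,
    overlap_timepoints,
)
from .errors import DependencyError, InvalidParameterError
from .genome_io import write_bed, write_bedgraph, write_chromsizes
from .insulation import (
    balance_matrix,
    call_boundaries,
    insulation_score,
    score_boundaries_across_samples,
)
from .proseq import (
    differential_pausing,
    fraction_boundary_transcripts,
    pausing_table,
    write_coverage,
    read_coverage,
    deregulated_boundary_enrichment,
)
from .simulate import (
    SimulationConfig,
    demo_config,
    ground_truth_tables,
    simulate_cis,
    simulate_compartment_cis,
    simulate_proseq,
    simulate_trans,
    simulate_expression,
)
from .spatial import (
    cluster_boundaries,
    control_total_boundaries,
    filter_centromeric,
    housekeeping_enrichment,
    trans_aggregate,
)

log = logging.getLogger("tadshift")

STAGES = [
    "simulate",
    "balance",
    "insulation",
    "boundaries",
    "diff-boundaries",
    "compartments",
    "clusters",
    "trans-agg",
    "pausing",
    "enrichment",
]


@dataclass
class RunConfig:
    """Pipeline parameters; unknown keys in a config file are rejected."""

    seed: int = 0
    outdir: str = "tadshift_run"
    window: int = 480_000
    prominence: float = 0.1
    fdr: float = 0.05
    cluster_gap: int = 2_000_000
    trans_groups: tuple = (0, 1, 2, 3)
    pause_offset: tuple = (-50, 300)
    min_body_reads: int = 10
    top_fraction: float = 0.05
    boundary_region_flank: int = 40_000
    balance_tol: float = 1e-5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("trans_groups", "pause_offset"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def stage_params(self, stage: str) -> dict:
        relevant = {
            "simulate": ["seed"],
            "balance": ["balance_tol"],
            "insulation": ["window"],
            "boundaries": ["prominence"],
            "diff-boundaries": ["fdr"],
            "compartments": ["fdr"],
            "clusters": ["cluster_gap"],
            "trans-agg": ["trans_groups"],
            "pausing": ["pause_offset", "min_body_reads", "fdr"],
            "enrichment": ["top_fraction", "boundary_region_flank"],
        }[stage]
        d = asdict(self)
        return {k: d[k] for k in relevant}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-stage signatures and output checksums, persisted as JSON."""

    def __init__(self, path: Path):
        self.path = path
        if path.exists():
            self.data = json.loads(path.read_text())
        else:
            self.data = {"version": __version__, "stages": {}}

    def save(self):
        self.data["version"] = __version__
        self.path.write_text(json.dumps(self.data, indent=2, default=str))

    def signature(self, stage: str, params: dict, upstream: list[str]) -> str:
        payload = {
            "params": params,
            "upstream": {s: self.data["stages"].get(s, {}).get("signature") for s in upstream},
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()

    def is_current(self, stage: str, signature: str) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec or rec.get("signature") != signature:
            return False
        return all(Path(p).exists() for p in rec.get("outputs", {}))

    def record(self, stage: str, signature: str, params: dict, outputs: list[Path]):
        self.data["stages"][stage] = {
            "signature": signature,
            "params": params,
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }
        self.save()

    def require(self, stage: str):
        if stage not in self.data["stages"]:
            raise DependencyError(
                f"stage {stage!r} has not been run; required intermediate missing"
            )


_UPSTREAM = {
    "simulate": [],
    "balance": ["simulate"],
    "insulation": ["balance"],
    "boundaries": ["insulation"],
    "diff-boundaries": ["boundaries", "insulation"],
    "compartments": ["simulate"],
    "clusters": ["diff-boundaries"],
    "trans-agg": ["simulate", "diff-boundaries"],
    "pausing": ["simulate"],
    "enrichment": ["simulate", "clusters", "pausing", "diff-boundaries"],
}


class Pipeline:
    """Stateful runner binding a RunConfig, a simulation and an output tree."""

    def __init__(self, run: RunConfig, sim: SimulationConfig | None = None):
        self.run = run
        self.sim = sim if sim is not None else demo_config(run.seed)
        self.outdir = Path(run.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = Manifest(self.outdir / "manifest.json")

    # -- helpers ----------------------------------------------------------
    @property
    def samples(self) -> list[tuple[str, int]]:
        return [
            (cond, rep)
            for cond in self.sim.condition_labels
            for rep in range(self.sim.n_replicates)
        ]

    def sample_name(self, cond: str, rep: int) -> str:
        return f"{cond}.rep{rep}"

    def _stage(self, stage: str) -> tuple[str, bool]:
        params = self.run.stage_params(stage)
        for up in _UPSTREAM[stage]:
            self.manifest.require(up)
        sig = self.manifest.signature(stage, params, _UPSTREAM[stage])
        return sig, self.manifest.is_current(stage, sig)

    def _done(self, stage: str, sig: str, outputs: list[Path]):
        self.manifest.record(stage, sig, self.run.stage_params(stage), outputs)
        log.info("stage %s: wrote %d output file(s)", stage, len(outputs))

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> list[Path]:
        sig, current = self._stage("simulate")
        if current:
            log.info("stage simulate: up to date, skipping")
            return []
        out = []
        d = self.outdir
        write_chromsizes(self.sim.layout, d / "genome.chrom.sizes")
        out.append(d / "genome.chrom.sizes")
        cen = pd.DataFrame(
            [
                {"chrom": c, "start": s, "end": e}
                for c, (s, e) in self.sim.layout.centromeres.items()
            ]
        )
        if len(cen):
            write_bed(cen, d / "centromeres.bed")
            out.append(d / "centromeres.bed")
        for cond, rep in self.samples:
            name = self.sample_name(cond, rep)
            cis = simulate_cis(self.sim, cond, rep)
            write_contacts(cis, d / f"cis.{name}.tsv", assembly="sim")
            out.append(d / f"cis.{name}.tsv")
            trans = simulate_trans(self.sim, cond, rep)
            write_contacts(trans, d / f"trans.{name}.tsv", assembly="sim")
            out.append(d / f"trans.{name}.tsv")
            if self.sim.compartments is not None:
                comp = simulate_compartment_cis(self.sim, cond, rep)
                write_contacts(comp, d / f"comp.{name}.tsv", assembly="sim")
                out.append(d / f"comp.{name}.tsv")
            cov = simulate_proseq(self.sim, cond, rep)
            out.extend(write_coverage(cov, d / f"proseq.{name}"))
        expr = simulate_expression(self.sim)
        expr.to_csv(d / "expression.tsv", sep="\t")
        out.append(d / "expression.tsv")
        genes = pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.sim.genes],
                "start": [g.start for g in self.sim.genes],
                "end": [g.end for g in self.sim.genes],
                "name": [g.name for g in self.sim.genes],
                "score": [g.expression for g in self.sim.genes],
                "strand": [g.strand for g in self.sim.genes],
            }
        )
        write_bed(genes, d / "genes.bed")
        out.append(d / "genes.bed")
        btruth, gtruth = ground_truth_tables(self.sim)
        btruth.to_csv(d / "truth.boundaries.tsv", sep="\t", index=False)
        gtruth.to_csv(d / "truth.genes.tsv", sep="\t", index=False)
        out += [d / "truth.boundaries.tsv", d / "truth.genes.tsv"]
        self._done("simulate", sig, out)
        return out

    def stage_balance(self) -> list[Path]:
        sig, current = self._stage("balance")
        if current:
            log.info("stage balance: up to date, skipping")
            return []
        bins = self.sim.bin_table()
        out = []
        for cond, rep in self.samples:
            name = self.sample_name(cond, rep)
            cmap = read_contacts(self.outdir / f"cis.{name}.tsv", bins)
            bal = balance_matrix(cmap, tol=self.run.balance_tol)
            # store NaN-masked balanced values as triplets with mask sidecar
            for chrom in bal.cis:
                bal.cis[chrom] = np.nan_to_num(bal.cis[chrom])
            write_contacts(bal, self.outdir / f"balanced.{name}.tsv", assembly="sim")
            out.append(self.outdir / f"balanced.{name}.tsv")
        self._done("balance", sig, out)
        return out

    def _balanced_maps(self):
        bins = self.sim.bin_table()
        maps = {}
        for cond, rep in self.samples:
            name = self.sample_name(cond, rep)
            path = self.outdir / f"balanced.{name}.tsv"
            if not path.exists():
                raise DependencyError("stage 'balance' output missing; run balance first")
            cmap = read_contacts(path, bins)
            for chrom in cmap.cis:
                cmap.cis_mask[chrom] = cmap.cis[chrom].sum(axis=1) > 0
            maps[name] = cmap
        return maps

    def stage_insulation(self) -> list[Path]:
        sig, current = self._stage("insulation")
        if current:
            log.info("stage insulation: up to date, skipping")
            return []
        out = []
        for name, cmap in self._balanced_maps().items():
            track = insulation_score(cmap, self.run.window)
            write_bedgraph(track.to_bedgraph_frame(), self.outdir / f"insulation.{name}.bedgraph")
            out.append(self.outdir / f"insulation.{name}.bedgraph")
        self._done("insulation", sig, out)
        return out

    def _tracks(self):
        maps = self._balanced_maps()
        return {name: insulation_score(cmap, self.run.window) for name, cmap in maps.items()}

    def _reference_boundaries(self, tracks):
        control = self.sim.control
        ctrl_names = [self.sample_name(control, r) for r in range(self.sim.n_replicates)]
        bins = self.sim.bin_table()
        pooled = read_contacts(self.outdir / f"cis.{ctrl_names[0]}.tsv", bins)
        for name in ctrl_names[1:]:
            other = read_contacts(self.outdir / f"cis.{name}.tsv", bins)
            for chrom in pooled.cis:
                pooled.cis[chrom] += other.cis[chrom]
        bal = balance_matrix(pooled, tol=self.run.balance_tol)
        track = insulation_score(bal, self.run.window)
        return call_boundaries(track, self.run.prominence)

    def stage_boundaries(self) -> list[Path]:
        sig, current = self._stage("boundaries")
        if current:
            log.info("stage boundaries: up to date, skipping")
            return []
        tracks = self._tracks()
        boundaries = self._reference_boundaries(tracks)
        df = pd.DataFrame(
            {
                "chrom": [b.chrom for b in boundaries],
                "start": [b.midpoint - self.sim.bin_size // 2 for b in boundaries],
                "end": [b.midpoint + self.sim.bin_size // 2 for b in boundaries],
                "name": [f"{b.chrom}:{b.bin}" for b in boundaries],
                "score": [b.score for b in boundaries],
                "strand": ["." for b in boundaries],
            }
        )
        write_bed(df, self.outdir / "boundaries.bed")
        scores = score_boundaries_across_samples(boundaries, tracks)
        scores.to_csv(self.outdir / "boundary_scores.tsv", sep="\t")
        sheet = pd.DataFrame(
            [
                {"sample": self.sample_name(c, r), "condition": c, "replicate": r}
                for c, r in self.samples
            ]
        )
        sheet.to_csv(self.outdir / "samples.tsv", sep="\t", index=False)
        out = [
            self.outdir / "boundaries.bed",
            self.outdir / "boundary_scores.tsv",
            self.outdir / "samples.tsv",
        ]
        self._done("boundaries", sig, out)
        return out

    def stage_diff_boundaries(self) -> list[Path]:
        sig, current = self._stage("diff-boundaries")
        if current:
            log.info("stage diff-boundaries: up to date, skipping")
            return []
        scores = pd.read_csv(self.outdir / "boundary_scores.tsv", sep="\t", index_col=0)
        sheet = pd.read_csv(self.outdir / "samples.tsv", sep="\t")
        control = self.sim.control
        out = []
        hds_sets = {}
        for cond in self.sim.condition_labels:
            if cond == control:
                continue
            table = differential_boundary_table(scores, sheet, control, cond, self.run.fdr)
            table.to_csv(self.outdir / f"diff.{cond}.tsv", sep="\t")
            out.append(self.outdir / f"diff.{cond}.tsv")
            hds_sets[cond] = set(table.index[table["class"] == "HDS"])
            for cls in ("HDS", "unaffected"):
                sub = table[table["class"] == cls]
                bed = pd.DataFrame(
                    {
                        "chrom": sub["chrom"],
                        "start": sub["midpoint"] - self.sim.bin_size // 2,
                        "end": sub["midpoint"] + self.sim.bin_size // 2,
                        "name": sub.index,
                        "score": sub["delta"],
                        "strand": ".",
                    }
                )
                write_bed(bed, self.outdir / f"boundaries.{cond}.{cls}.bed")
                out.append(self.outdir / f"boundaries.{cond}.{cls}.bed")
        overlaps = overlap_timepoints(hds_sets)
        (self.outdir / "hds_overlaps.json").write_text(
            json.dumps({"|".join(k): v for k, v in overlaps.items()}, indent=2)
        )
        out.append(self.outdir / "hds_overlaps.json")
        self._done("diff-boundaries", sig, out)
        return out

    def stage_compartments(self) -> list[Path]:
        sig, current = self._stage("compartments")
        if current:
            log.info("stage compartments: up to date, skipping")
            return []
        if self.sim.compartments is None:
            self._done("compartments", sig, [])
            return []
        from .genome_io import make_bin_table

        spec = self.sim.compartments
        bins = make_bin_table(self.sim.layout, spec.bin_size)
        control = self.sim.control
        anchor = {c: spec.condition_signs(c, control) for c in self.sim.layout.chromosomes}
        tracks = {}
        out = []
        for cond in self.sim.condition_labels:
            reps = []
            for rep in range(self.sim.n_replicates):
                name = self.sample_name(cond, rep)
                cmap = read_contacts(self.outdir / f"comp.{name}.tsv", bins)
                track = compartment_pc1(cmap, anchor)
                write_bedgraph(
                    track.to_bedgraph_frame(), self.outdir / f"pc1.{name}.bedgraph"
                )
                out.append(self.outdir / f"pc1.{name}.bedgraph")
                reps.append(track)
            tracks[cond] = reps
        for cond in self.sim.condition_labels:
            if cond == control:
                continue
            table = differential_compartments(tracks, control, cond, self.run.fdr)
            table.to_csv(self.outdir / f"diff_compartments.{cond}.tsv", sep="\t", index=False)
            out.append(self.outdir / f"diff_compartments.{cond}.tsv")
        self._done("compartments", sig, out)
        return out

    def _hds_boundaries(self, cond=None):
        from .genome_io import read_bed

        cond = cond or self.sim.condition_labels[1]
        bed = read_bed(self.outdir / f"boundaries.{cond}.HDS.bed")
        from .insulation import Boundary

        out = []
        for row in bed.itertuples(index=False):
            mid = (row.start + row.end) // 2
            out.append(
                Boundary(
                    chrom=row.chrom,
                    bin=int(mid // self.sim.bin_size),
                    midpoint=int(mid),
                    score=float(row.score),
                    prominence=0.0,
                )
            )
        return out

    def _all_boundaries(self):
        from .genome_io import read_bed
        from .insulation import Boundary

        bed = read_bed(self.outdir / "boundaries.bed")
        out = []
        for row in bed.itertuples(index=False):
            mid = (row.start + row.end) // 2
            out.append(
                Boundary(row.chrom, int(mid // self.sim.bin_size), int(mid),
                         float(row.score), 0.0)
            )
        return out

    def stage_clusters(self) -> list[Path]:
        sig, current = self._stage("clusters")
        if current:
            log.info("stage clusters: up to date, skipping")
            return []
        hds = filter_centromeric(self._hds_boundaries(), self.sim.layout)
        table = cluster_boundaries(hds, gap=self.run.cluster_gap)
        bed = pd.DataFrame(
            {
                "chrom": table.clusters["chrom"],
                "start": table.clusters["start"],
                "end": table.clusters["end"],
                "name": table.clusters["n_members"].astype(str),
                "score": table.clusters["n_members"].astype(float),
                "strand": ".",
            }
        )
        write_bed(bed, self.outdir / "clusters.bed")
        (self.outdir / "cluster_summary.json").write_text(
            json.dumps(table.summary(), indent=2)
        )
        out = [self.outdir / "clusters.bed", self.outdir / "cluster_summary.json"]
        self._done("clusters", sig, out)
        return out

    def stage_trans_agg(self) -> list[Path]:
        sig, current = self._stage("trans-agg")
        if current:
            log.info("stage trans-agg: up to date, skipping")
            return []
        bins = self.sim.trans_bin_table()
        hds = self._hds_boundaries()
        frames = []
        for cond in self.sim.condition_labels:
            for rep in range(self.sim.n_replicates):
                name = self.sample_name(cond, rep)
                cmap = read_contacts(self.outdir / f"trans.{name}.tsv", bins)
                agg = trans_aggregate(
                    cmap, hds, groups=self.run.trans_groups,
                    bin_size=self.sim.trans_bin_size, condition=name,
                )
                frames.append(agg)
        agg_all = pd.concat(frames, ignore_index=True)
        agg_all.to_csv(self.outdir / "trans_aggregate.tsv", sep="\t", index=False)
        ctrl = control_total_boundaries(bins, self._all_boundaries(), hds,
                                        groups=self.run.trans_groups)
        ctrl.to_csv(self.outdir / "trans_total_boundary_control.tsv", sep="\t", index=False)
        out = [
            self.outdir / "trans_aggregate.tsv",
            self.outdir / "trans_total_boundary_control.tsv",
        ]
        self._done("trans-agg", sig, out)
        return out

    def stage_pausing(self) -> list[Path]:
        sig, current = self._stage("pausing")
        if current:
            log.info("stage pausing: up to date, skipping")
            return []
        from .genome_io import read_genes

        genes = read_genes(self.outdir / "genes.bed", self.sim.layout)
        out = []
        tables = {}
        for cond in self.sim.condition_labels:
            reps = []
            for rep in range(self.sim.n_replicates):
                name = self.sample_name(cond, rep)
                cov = read_coverage(self.outdir / f"proseq.{name}", self.sim.layout)
                tab = pausing_table(
                    cov, genes, pause_offset=self.run.pause_offset,
                    min_body_reads=self.run.min_body_reads,
                )
                tab.to_csv(self.outdir / f"pausing.{name}.tsv", sep="\t", index=False)
                out.append(self.outdir / f"pausing.{name}.tsv")
                reps.append(tab)
            tables[cond] = reps
        control = self.sim.control
        treated = self.sim.condition_labels[1]
        diff = differential_pausing(tables[control], tables[treated], self.run.fdr)
        diff.to_csv(self.outdir / "diff_pausing.tsv", sep="\t", index=False)
        out.append(self.outdir / "diff_pausing.tsv")
        self._done("pausing", sig, out)
        return out

    def stage_enrichment(self) -> list[Path]:
        sig, current = self._stage("enrichment")
        if current:
            log.info("stage enrichment: up to date, skipping")
            return []
        from .genome_io import read_bed, read_genes

        flank = self.run.boundary_region_flank
        genes = read_genes(self.outdir / "genes.bed", self.sim.layout)
        expr = pd.read_csv(self.outdir / "expression.tsv", sep="\t", index_col=0)
        clusters = read_bed(self.outdir / "clusters.bed")
        hk = housekeeping_enrichment(
            expr, genes, clusters, self.sim.layout, top_fraction=self.run.top_fraction
        )
        hds = self._hds_boundaries()
        allb = self._all_boundaries()
        hds_keys = {b.key for b in hds}
        unaff = [b for b in allb if b.key not in hds_keys]

        def regions(blist):
            return pd.DataFrame(
                {
                    "chrom": [b.chrom for b in blist],
                    "start": [max(b.midpoint - flank, 0) for b in blist],
                    "end": [b.midpoint + flank for b in blist],
                }
            )

        diff = pd.read_csv(self.outdir / "diff_pausing.tsv", sep="\t")
        gmeta = genes.set_index("name")
        result = {"housekeeping": hk}
        for cls in ("more_paused", "less_paused"):
            names = diff.loc[diff["class"] == cls, "gene"]
            sub = gmeta.loc[[n for n in names if n in gmeta.index]].reset_index()
            if len(sub) and len(hds) and len(unaff):
                enr = deregulated_boundary_enrichment(sub, regions(hds), regions(unaff))
            else:
                enr = float("nan")
            result[f"enrichment_{cls}"] = enr
        all_regions = regions(allb)
        result["fraction_hds_transcripts"] = fraction_boundary_transcripts(
            genes, regions(hds), all_regions
        )
        (self.outdir / "enrichment.json").write_text(json.dumps(result, indent=2))
        out = [self.outdir / "enrichment.json"]
        self._done("enrichment", sig, out)
        return out

    # -- driver -----------------------------------------------------------
    def run_all(self) -> Path:
        for stage in STAGES:
            self.run_stage(stage)
        return self.manifest.path

    def run_stage(self, stage: str):
        fn = {
            "simulate": self.stage_simulate,
            "balance": self.stage_balance,
            "insulation": self.stage_insulation,
            "boundaries": self.stage_boundaries,
            "diff-boundaries": self.stage_diff_boundaries,
            "compartments": self.stage_compartments,
            "clusters": self.stage_clusters,
            "trans-agg": self.stage_trans_agg,
            "pausing": self.stage_pausing,
            "enrichment": self.stage_enrichment,
        }[stage]
        log.info("running stage %s", stage)
        return fn()


def run_pipeline(run: RunConfig, sim: SimulationConfig | None = None) -> Path:
    """Execute the full workflow; returns the manifest path."""
    return Pipeline(run, sim).run_all()
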