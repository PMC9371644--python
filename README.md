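# tadshift

Detection of condensate-sensitive TAD boundaries from perturbation Hi-C.

Topologically associated domains (TADs) partition chromosomes into
self-interacting blocks separated by boundaries. A subset of boundaries
depends on weak hydrophobic interactions of the kind that hold
biomolecular condensates together: brief treatment with 1,6-hexanediol
(1,6-HD) transiently weakens their insulation, while an inert isomer
(2,5-HD) does not. `tadshift` implements the computational chain needed to
find and characterize these hexanediol-sensitive ("HDS") boundaries:

* **Insulation scoring and boundary calling.** For bin *i* at window *w*
  (in bins), the insulation score is

  `s(i) = log2( mean{ M[u,v] : i−w ≤ u < i < v ≤ i+w } / ⟨s_raw⟩_chrom )`

  computed on an iteratively balanced contact matrix; TAD boundaries are
  prominent local minima of the track.
* **Differential boundary insulation.** Per boundary, a Gaussian
  identity-link GLM `score ~ condition` (equivalently the pooled
  two-sample t-test) with Benjamini–Hochberg FDR control; a boundary is
  HDS when q < 0.05 and the insulation shift Δ (treated − control) is
  positive, i.e. the boundary weakened.
* **A/B compartments.** PC1 of the Pearson correlation of the
  distance-normalized (O/E) 500-kb matrix, sign-anchored, with per-bin
  differential compartment calls.
* **Spatial organisation.** Centromere-proximal filtering, gap-threshold
  clustering of HDS boundaries, counts-per-million aggregation of
  interchromosomal contacts over 4-Mb bins grouped by HDS-boundary
  count, and housekeeping-gene enrichment on cluster spans.
* **Nascent transcription (PRO-seq).** Boundary-centered coverage
  profiles, the promoter-proximal pausing index
  `PI = (pause reads / pause bp) / (body reads / body bp)`, differential
  pausing via Fisher's exact test, and size-normalized enrichment of
  deregulated genes on HDS vs unaffected boundary regions.
* **A ground-truth simulator.** Multi-condition, multi-replicate
  synthetic Hi-C (distance decay, TADs with per-boundary permeability, a
  treatment/recovery schedule weakening HDS boundaries), trans maps with
  cluster-bin enrichment, stranded PRO-seq coverage with tunable pause
  fractions, and gene-by-tissue expression tables — all with known ground
  truth, so every analysis stage can be benchmarked for recovery and
  calibration.

## Worked example

Run the bundled demo experiment (2 chromosomes × 20 Mb at 40-kb bins, 20
planted boundaries of permeability 0.10–0.50, four of them HDS, a
four-point treatment/recovery schedule, two replicates per condition):

```
tadshift all --outdir run1 --seed 7
```

This writes every intermediate in open text formats (triplet contact
TSVs, bedGraph tracks, BED boundary/cluster files, TSV tables) plus a
run manifest. Key results from this run:

* `diff.HD_5min.tsv` — per-boundary differential table. Class counts:
  **4 HDS, 21 unaffected**; the HDS calls are `chrA:109, chrA:145,
  chrB:310, chrB:344`, exactly the four boundaries the simulator weakened
  (planted at bins 110, 145, 310, 345; calls may sit one bin off).
* `cluster_summary.json` —
  `{"n_clusters": 2, "mean_size": 2.0, "clustered_fraction": 1.0}`: both
  HDS pairs form one cluster per chromosome, as planted.
* `trans_aggregate.tsv` — mean trans CPM by HDS-count group; the
  group-2 / group-0 ratio is ≈ 2, the planted trans enrichment.
* `enrichment.json` — housekeeping genes are ~9-fold denser on HDS
  cluster spans than outside (the generator places 80% of them there).

Because the insulation window (480 kb), boundary prominence (0.1),
FDR (0.05), cluster gap (2 Mb) and pause windows (−50/+300 bp) are all
configurable, each stage can also be run alone, e.g.
`tadshift insulation --outdir run1 --window 400000` recomputes the
insulation stage and everything downstream, leaving simulation and
balancing untouched.

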