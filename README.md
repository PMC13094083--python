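# dualcut

Simulation and quantification of CRISPR/Cas9 **dual-gRNA structural editing
outcomes** — chromosomal inversions, large inter-cut deletions, and small
indels — as measured in transient plant-protoplast experiments.

When Cas9 is delivered with two gRNAs targeting one chromosome (a *fixed*
internal-reference site plus a *variable* site at a chosen distance), the
intervening segment can re-ligate in place (perfectly or with small indel
scars), invert, or be deleted. `dualcut` provides a ground-truthed generative
simulator of these outcomes and of the three assays used to count them, plus
the estimators that turn each assay's raw output back into frequencies:

- **`dualcut.editsim`** — per-cell transfection, per-allele cutting and
  repair; emits crystal-digital-PCR droplet panels, short amplicon reads
  around each cut site, and full-interval long amplicon reads, all with
  recorded truth labels.
- **`dualcut.cdpcr`** — genome-copy accounting from DNA mass
  (copies = m·N_A / (G·w̄), with G the genome size in bp and w̄ = 659.928 Da
  per base pair), analysed-volume fraction from valid 0.59 nL partitions,
  double-positive droplet counting in two probe channels, and the per-genome
  inversion frequency (direct counting, with an optional Poisson
  multi-occupancy correction).
- **`dualcut.amplicon`** — affine-gap global alignment of amplicon reads; a
  read is mutated iff an insertion/deletion intersects the ±4 bp-buffered
  2-nt cut window; negative-control event subtraction.
- **`dualcut.junctions`** — grep-style classification of long reads by exact
  16 bp flank pairs spaced ~60 bp around each junction, tolerating 0–80 bp
  inserts; labels wild-type, (complete) inversion, deletion, other; unique
  events deduplicated by junction signature.
- **`dualcut.refnorm`** — internal-reference normalisation: each sample's
  frequencies are rescaled by (mean fixed-site frequency / its own
  fixed-site frequency), removing shared transfection/expression variation;
  experiment-level reports (frequency vs interval size, vs gRNA efficiency,
  deletion:inversion ratios, cross-method concordance).

## Worked example

```python
from dualcut import *

locus = make_locus(interval_bp=1000, margin=200, seed=7)
model = OutcomeModel(p_transfect=0.4, p_cut_fixed=0.45, p_cut_var=0.35,
                     p_inv=0.05, p_del=0.20, p_perfect=0.25)
truth = simulate_sample(locus, model, n_cells=100_000, seed=11)

mass = 5.0e5 / genome_copies(1.0)          # grams giving 5e5 genome copies
panel, _ = emit_droplet_panel(truth, dna_mass_g=mass, n_droplets=25_000, seed=12)
res = quantify(panel, mass, cfg=CdpcrRunConfig(poisson_corrected=True))

reads = emit_long_reads(truth, locus, ReadSimConfig(coverage=20_000, seed=13))
summary = classify_readset(reads, build_queries(locus))
```

printed output:

```
allele classes: {'wild_type': 171279, 'indel_fixed_only': 13646, 'indel_var_only': 9810,
                 'indel_both': 2033, 'inversion': 614, 'deletion': 2618}
true junction-carrier fraction: 0.3070%
valid droplets: 23993, double positive: 798
analysed fraction: 0.566, analysed genomes: 283,117
estimated inversion frequency: 0.2867% (QC pass: True)
long-read labels: {'wild_type': 18346, 'inversion': 3, 'complete_inversion': 49,
                   'deletion': 249, 'other': 1353}
deletion:inversion ratio: 4.79
```

Reading this: of 200,000 simulated alleles, 0.307% carry an inversion
junction. The cdPCR pipeline captures 56.6% of the loaded volume in valid
droplets and estimates 0.287% — one panel's Poisson counting noise around
the truth (averaging panels converges on 0.307%). The long-read caller
recovers the inversion and deletion channels at their simulated proportions;
with the default per-base error rate, reads whose exact 16 bp flanks are hit
by an error fall into `other` rather than being mislabelled (see
`docs/methods.md` for the (1−e)³² per-junction recall bound). With
error-free reads the caller agrees with the generative truth on every read.

A `dualcut` console script exposes the same steps
(`simulate`, `quantify-cdpcr`, `call-indels`, `call-junctions`, `normalise`,
`report`); see `dualcut --help`.

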