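# Methods

## Generative model of dual-cut editing

A sample is a pool of `n_cells` diploid cells. The construct (Cas9 + both
gRNAs on one plasmid) reaches a cell with probability `p_transfect`; because
delivery is per plasmid, transfection is drawn per cell and shared by both
alleles, while all subsequent events are drawn independently per allele.
Within a transfected cell each allele is cleaved at the fixed site with
probability `p_cut_fixed` and at the variable site with `p_cut_var`
(conditionally independent). Repair is resolved per allele:

- **both sites cut** — inversion with `p_inv`, inter-cut deletion with
  `p_del`, perfect re-ligation with `p_perfect`, and with the remaining mass
  re-ligation leaving indel scars at one or both junctions. The scar
  placement splits fixed-only / variable-only / both with weights
  q(1−q) : (1−q)q : q² (renormalised), where q = `p_indel_single`.
- **one site cut** — perfect repair or an indel scar
  (probability `p_indel_single`, default 0.5).
- **no cut / untransfected** — wild type.

This structure makes the expected frequency of every edited class linear in
`p_transfect` (the premise of reference normalisation) and makes inversions
and deletions structurally impossible when either cut probability is zero.
Closed form used in tests: the inversion-allele fraction is
`p_transfect · p_cut_fixed · p_cut_var · p_inv`.

Scar sizes come from `indel_size_dist`: point masses at −3/−6/−9 bp
(microhomology-mediated deletions dominate imperfect repair at these sites,
with −3 most common) plus a geometric insertion tail from +1 bp, truncated
at +80 bp. Rearrangement junctions draw insert lengths from
`junction_insert_dist` (80% exact joins, geometric tail to 80 bp).
Both defaults are deliberately confined to the envelope the junction scanner
admits, so that on error-free reads the caller and the generator agree
read-for-read; distributions with support up to 200 bp (e.g. a ~193 bp
templated-insertion class) are accepted and simply reduce caller recall, as
they would in a real experiment. Every drawn scar and insert is stored per
allele, so resampling an allele during read emission always reproduces the
same molecule.

## Measurement models

**cdPCR droplets.** The loaded DNA mass implies
`copies = m·N_A/(G·w̄)` genome copies (tomato defaults G = 1.179×10⁹ bp,
w̄ = 659.928 Da; 1 ng ≈ 774 copies). Each of the `n_droplets` fixed-volume
partitions (0.59 nL) captures inversion-junction genomes as
Poisson(λ·f) with λ = copies·v_droplet/v_loaded and f the carrier fraction;
a droplet with ≥ 1 junction genome emits high signal in both probe channels
(Gaussian around 5000 a.u., σ=250), others background (500 a.u., σ=60), and
a configurable fraction (default 4%) is flagged volume-invalid. An
alternative `occupancy="multinomial"` mode scatters exactly `round(copies)`
molecules, conserving counts — useful for deterministic edge cases. The
spectrally clean two-channel model deliberately omits crosstalk/spillover
compensation, which belongs to instrument calibration, not to the counting
statistics this package studies.

**Short amplicons.** A window of `read_length` bases (default 200) centred
on the cut is emitted per read, drawn from allele classes proportional to
their counts. By default alleles carrying an inversion or deletion yield no
product for the wild-type-orientation primer pair (their junction removes a
primer site), so indel frequencies are computed over amplifiable alleles;
`rearranged_dropout=False` instead emits the junction-spanning product
window, exposing the bias this assumption hides. Sequencing error is
per-base substitution (default 10⁻³) plus rare 1 bp indels (10⁻⁴/base); no
homopolymer or quality model — the estimators consume base identities only.

**Long amplicons.** The full molecule between the outer primers is emitted
per read — wild-type order, the inverted internal segment with its junction
inserts, or the fused deletion product — in random orientation. Intervals
above `long_read_ceiling_bp` (default 5,000) raise an explicit error:
multi-kilobase-plus intervals are not amplicon-sequenceable and the droplet
assay is the appropriate instrument there.

## Estimators

**cdPCR quantification.** Valid droplets × 0.59 nL over the loaded volume
gives the analysed fraction; times loaded copies, the analysed genomes.
Double positives require both channels above threshold; volume-invalid
droplets are excluded outright. Samples with < 18,000 valid partitions fail
QC (frequency still reported, flagged). The default estimator divides the
raw double-positive count by analysed genomes. At high loading this is
biased low: with λ genomes per droplet and carrier fraction f, the
double-positive probability is 1−exp(−λf), so direct counting recovers
f·(1−e^{−λf})/(λf). At the recovery tests' operating point (5×10⁵ copies in
25,000 droplets, λ≈11.8, f≈1%) that is a ~6% deficit — larger than the
Monte-Carlo error of the test. `poisson_corrected=True` replaces the count
with −ln(1−p̂)·n_valid, which is unbiased for any occupancy, and is what the
recovery tests and the acceptance script use; the default stays at direct
counting, the assay's customary arithmetic.

**Amplicon indel calling.** Reads are globally aligned to the reference
amplicon with affine gaps (match +2, mismatch −2, open −6, extend −1); the
first optimal alignment reported by Biopython's `PairwiseAligner` is taken,
making event coordinates deterministic. The cut window is the two
nucleotides flanking the blunt cut extended by `cut_buffer_bp = 4` on each
side, i.e. positions `[cut−4, cut+5]`; a deletion qualifies when its span
intersects the window, an insertion when its anchor lies in `[cut−5, cut+5]`
(the inserted bases sit between anchor and anchor+1). Substitutions never
qualify — enlarging the buffer therefore can only add qualifying reads
(monotonicity property). Reads shorter than 30% of the reference are
discarded. Control subtraction works on event classes (kind, position,
size): a class whose pooled negative-control frequency reaches 50% of its
sample frequency is treated as background (pre-existing variation or PCR
artefact) and removed before the frequency is recomputed; this explicit
filter stands in for AmpliCan-style control normalisation, whose exact
behaviour is not re-specified here, and its threshold is configurable.
Identical read sequences are aligned once and cached.

**Junction calling.** For each cut (0-based split c) the flanks are
`seg[c−46:c−30]` and `seg[c+30:c+46]` (16 bp each, inner edges 30 bp from
the break). Inversion borders reuse these flanks with the interval-side one
reverse-complemented; the deletion junction fuses the two outer flanks.
A query matches when left flank and right flank occur with 0–140 bases
between them (nominal 60 bp spacing + up to 80 bp insert) — so an 80 bp
junction insert is the largest still called, and small break-site deletions
shrink the gap without escaping the window. Reads are scanned on both
strands (long-amplicon orientation is random; forward-only scanning would
halve frequencies) with exact matching, mirroring a literal grep. Label
precedence: both inversion borders → `complete_inversion`; one →
`inversion`; deletion junction → `deletion`; both wild-type junctions →
`wild_type`; anything else — including chimeric reads matching inversion
and deletion queries — → `other`. Per-junction recall under per-base error
e is bounded by (1−e)³² (two exact 16-mers), (1−e)⁶⁴ for labels needing two
junctions; an error-hit read falls to `other` rather than being mislabelled.
Unique events deduplicate on the exact inter-flank sequence per junction,
canonicalised across strands.

**Reference normalisation.** The normalisation factor is
mean(fixed-site frequency over non-control, normalisable samples) divided
by the sample's own fixed-site frequency, applied multiplicatively to the
variable-site and rearrangement frequencies. The mean is taken per
replicate with equal weight (a per-construct-mean weighting is equally
defensible; per-replicate is implemented). Samples with zero fixed-site
frequency (inactive reference) are excluded and flagged rather than
normalised. Exact algebraic properties, all asserted in tests: the
normalised fixed-site frequency is the mean, identically across samples
(fixpoint); within-sample ratios are preserved; and with the reference mean
pinned externally (`normalise(..., mean_fixed=...)`) the normalised values
are exactly invariant to per-sample scaling constants. With the mean
recomputed from the scaled table, all normalised values instead move by the
single common factor by which the mean itself moved — the invariance is
per-sample-effect removal, not absolute-scale rigidity. Normalised values
may exceed 1 on pathological input and are reported unclamped with the
understanding that the scale is relative.

## What the simulator does and does not establish

Passing recovery tests shows the estimators are consistent for data
generated under this model: independent alleles, spectrally clean droplet
channels, uniform amplification across amplifiable alleles, uniform
per-base error. Real data add PCR efficiency differences between product
sizes, chimera formation, droplet volume dispersion, probe cross-talk, and
locus-specific repair biases, none of which are modelled; results on
synthetic data bound estimator error, not assay error. Organellar DNA
inflating the mass-derived genome count (which would deflate absolute
frequencies) is likewise out of scope.

## Problem sizes and numerics

Recovery runs use 10 panels of 25,000 droplets at 5×10⁵ copies, long-read
sets of 2–5×10⁴ reads over 10 seeds, and allele pools of 1–2×10⁵ — sizes at
which Monte-Carlo standard errors are a few percent of the measured
quantities, so three-standard-error acceptance bands are meaningful.
Every stochastic operation takes an explicit seed (no global RNG state);
identical seeds give byte-identical outputs. Probability vectors are
validated to sum to one within 1e−9; analysed volume is validated against
loaded volume; degenerate inputs (zero analysed genomes, empty read sets,
all-control tables, all-positive panels under Poisson correction) raise
explicit errors rather than returning NaN.

## Known limitations

- Exact flank matching makes junction recall sensitive to the per-base
  error rate; a ≤1-mismatch-per-flank mode is a natural extension and is
  deliberately not the default (it changes unique-event dedup semantics).
- The amplicon indel caller reports events from a single best alignment;
  indels in repetitive contexts can shift coordinates between equally
  scoring placements (deterministically, but not necessarily leftmost).
- Deletion detection in long reads uses the single fused outer-flank
  junction; deletions larger than the amplicon or nested rearrangements are
  out of scope, as are duplications and translocations.
- The cdPCR model assumes the junction-carrier fraction is small enough
  that both-border probes co-occupy droplets only via a true inversion
  junction; single-border artefacts are not simulated.
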