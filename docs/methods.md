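# Methods

This note documents the models and procedures implemented in cracflow, the
parameter choices that matter, and what validation on synthetic data does and
does not establish.

## Problem setting

A UV-crosslinking experiment (CRAC/CLIP family) on a chromatin protein with
an RNA-binding domain yields strand-specific per-nucleotide coverage of the
RNA the protein touched *in vivo*, together with a non-crosslinked control, an
RNAPII CRAC track that reports transcription, and ChIP tracks that report
chromatin occupancy. Two questions drive the analysis: *which* transcripts
does the protein bind specifically, and *when* — during transcription
(signal tracks RNAPII on the nascent chain) or after it (signal reflects
mature-mRNA abundance instead). The pipeline answers the first with a
spike-calibrated enrichment filter and the second with position-resolved
metagene profiles and a per-gene ratio classifier.

## Normalization

Between-sample recovery in crosslinking experiments varies for reasons
unrelated to biology (crosslinking efficiency, purification yield, library
depth). A fixed proportion of cells from a second species ("spike-in"),
carrying an equivalently tagged protein and purified together with the
sample, provides reads whose count is proportional to that recovery. Scale
factors are `reference / spike_reads` with the reference taken as the
**median spike count across the samples in the sheet** — symmetric and
robust to one bad library, rather than privileging a designated reference
sample. The reference is recorded in the output metadata.

One consequence worth stating: jointly rescaling one sample's track and
spike count leaves its normalized signal exactly unchanged *provided the
rescaling does not change which sample defines the median*. The invariance
is exact for scalings that keep the sample on the same side of the median
(the validation scales the largest-spike sample upward).

Depth-only scalings (RPM, per-10-million) are provided for ChIP-style tracks
where no spike is available.

The >5-fold enrichment filter is applied to spike-normalized signals, with a
pseudocount applied as `max(No-CL, 1)` and a strict inequality. Applying the
filter after normalization (rather than to raw counts) makes the call
independent of library size; the pseudocount convention preserves the
intuitive arithmetic for non-zero controls (12 vs 2 → fold 6).

## Weighted poly(A) site

Because most genes use several poly(A) addition sites, anchoring 3′-end
aggregate profiles on any single annotated end smears the region of
interest. Each gene's anchor is instead the intensity-weighted mean site
position, `wPAS = Σ posᵢ wᵢ / Σ wᵢ`, computed from a 3′-end-sequencing
intensity table. Weights are used as given (linear, no transform). The
anchor is rounded half-away-from-zero to an integer coordinate; zero total
weight or a negative weight is an error naming the gene.

## Metagene profiles

Profiles are anchored (TSS or wPAS) rather than length-scaled: the features
of interest here — a recruitment lag in nt, a peak a fixed distance before
the poly(A) site — live on an absolute nucleotide scale. Each gene's window
is extracted 5′→3′ (minus-strand genes reversed), optionally clipped to the
gene body, optionally divided by the gene's own mean over in-gene window
positions (`mean_of_window`) so that profile shape is not dominated by
expression, then averaged per bin across genes with the per-bin gene count
as denominator. Defaults: 10-nt bins, TSS −200/+1500, wPAS −500/+300, and a
minimum gene length of 1000 nt for cohort profiles so that 3′ features do
not intrude into 5′ windows (a >1500 bp cohort is conventional for
ChIP-style profiles). Bins with no contributing gene are **missing, not
zero** — zeros would fabricate signal decay.

`profile_ratio` divides two structurally identical profiles bin-wise;
`peak3_equivalence` compares mutant vs WT mean signal over the bins in
`[−window, 0)` before the wPAS (default 50 nt, covering the 3′ peak located
~25 nt upstream) and attaches a percentile bootstrap CI over genes,
resampling each cohort independently. For genotype comparisons the inputs
are spike-normalized but *not* per-gene normalized — per-gene normalization
would divide out exactly the genotype difference under test.

Size-matched control cohorts (e.g. non-coding RNAs vs length-matched ORFs)
use greedy nearest-length matching without replacement, discarding pairs
with relative length difference above a tolerance (default 20%). Greedy
matching is a bijection onto a subset of the control pool and is close to
the optimal assignment on average, though individual adversarial instances
can exceed twice the optimal mean gap; for cohort-level profile comparisons
the average behavior is what matters.

## Ratio-distribution classifier

Per-gene ratios of crosslink signal to RNAPII signal (or to ChIP) are
analyzed as **log10** values: the underlying signals span orders of
magnitude and a mode/symmetry analysis is only meaningful on the log scale.
Genes with denominator below a floor (default 1 normalized read) or zero
numerator are excluded and counted.

If binding were purely co-transcriptional, these ratios would form one
homogeneous distribution. The observed signature of a second,
post-transcriptionally bound class is right-tail excess: the distribution's
mean > median > mode. The classifier formalizes the "symmetric shaded area
around the mode" reading of such a histogram:

* **Mode** — from the Freedman–Diaconis histogram's maximal-count bin (ties
  broken toward the median), deterministically refined by a three-bin moving
  average of counts followed by the classical grouped-data parabolic
  interpolation around the maximal bin. The refinement matters: the raw
  center of a flat-topped histogram is only accurate to about one bin width,
  which propagates doubled into the tail threshold below.
* **Symmetric core** — the left flank is assumed purely co-transcriptional,
  so the core half-width is the robust left reach `d = mode − Q₀.₀₁`
  (percentile configurable), mirrored to the right. `core_fraction` is the
  mass in `[mode − d, mode + d]` (closed interval); `tail_threshold =
  mode + d`. A mode at or below the reference quantile (e.g. a point mass)
  is a pathological-distribution error.
* **Labels** — genes above the threshold are `post_txn_tail`, below the
  mirrored lower edge `below_core`, otherwise `core`. A gene exactly at the
  threshold is core.

This mirrored-percentile rule is one explicit, testable formalization of a
"symmetric core" — chosen for determinism and affine equivariance (shifting
all ratios by a constant shifts mode/median/mean/threshold by it and leaves
core fraction and tail membership unchanged; this is a tested invariant).

Distribution comparisons (WT vs mutant) report the difference of medians
with a bootstrap CI plus a two-sample Mann–Whitney statistic, reported
descriptively (it tests stochastic ordering, not shift size). Cross-assay
agreement is the r² of an ordinary least-squares regression of log10
signals, with the two-sided p-value of the zero-slope test; r² is symmetric
under exchange of axes.

## The synthetic-data generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline is validated by parameter recovery. Per gene (local
coordinate x, 5′→3′; e = expression in expected reads/nt):

* **RNAPII**: `e · shape(x)` with a linear entry ramp over 50 nt, flat body,
  and a linear decline by 90% over the final 10% of the gene — polymerase
  signal falls steeply approaching the poly(A) region.
* **Crosslinked signal (CL)**, multiplied overall by a per-gene
  crosslinking-propensity factor (log-normal, log10 sd ≈ 0.2 — RNAs differ
  in crosslinkability):
  * *co-transcriptional term*: the gene's RNAPII expectation shifted
    downstream by `set1_lag_nt` (default 150 nt, inside the 100–250 nt range
    where the relative signal builds up), damped by `exp(−(x − lag)/1500)`.
    The slow exponential release term reflects the protein's 5′-weighted
    association with the nascent transcript (the mutant loses signal
    preferentially 5′) and makes the lag identifiable: a pure shift would
    leave the profile ratio exactly flat past lag+ramp, so the argmax of a
    noisy ratio would be uniform over the plateau rather than at the
    build-up point. Setting `set1_release_decay_nt = None` recovers the pure
    shift-only construction. In the YF/AA-like mutant this term is
    multiplied by `yfaa_5prime_factor` (default 0.3).
  * *3′ term*: a Gaussian bump (σ = 25 nt) centred 25 nt upstream of the
    true wPAS with amplitude 3.5·e, **identical in both genotypes** — the
    defining property of the 3′ peak is its insensitivity to the RNA-binding
    mutation. The amplitude and the sharp polymerase decline were chosen by
    forward expectation calculation so that the pre-wPAS window is dominated
    by this genotype-shared term (expected mutant/WT window ratio ≈ 0.95)
    while the genome-wide mutant ratio shift remains below −0.3 log10 —
    i.e. so the generator reproduces both qualitative phenomena the analysis
    is meant to detect.
  * *post-transcriptional term*: for a random gene subset (default fraction
    0.35, chosen so the symmetric core comes out near the ~63% seen in real
    data), `multiplier · e` over **exonic positions only** — mature-mRNA
    binding excludes introns. Multipliers are log-normal with median 8 and
    log-sd 0.5, floored at 1.5; non-members have multiplier 1 (recorded in
    the truth table).
* **No-CL control**: uniform Poisson background (0.2 reads/nt).
* **ChIP IP**: RNAPII shifted 3′ by 50 nt, scaled per gene by a ChIP
  efficiency factor; input is uniform. ChIP is unstranded, so the simulator
  deposits IP signal on the gene's own strand and quantification offers a
  both-strands mode.
* **Spike-in and recovery**: each sample has a global log-normal recovery
  factor (log-sd 0.2) multiplying its whole track; spike reads are
  `Binomial(10⁶, 0.005 · recovery)`. Spike normalization is thereby
  *meaningful* in the simulation: it cancels a real sample-level factor up
  to binomial noise (~1.4%), instead of injecting noise.

Counts are Poisson per nucleotide; `total_mapped` is defined as track sum
plus spike reads, so reads are allocated, never resampled. Gene lengths are
log-normal (median ~1400 nt, typical for yeast mRNAs, min 400), expression
log-normal (mean 30 reads/nt — deep coverage, so per-gene Poisson noise is
small relative to biological variation), 1–4 poly(A) sites per gene in the
final 10% with Dirichlet weights, and a 5% intron probability (mRNAs only,
5′-proximal, as in budding yeast). All randomness derives from one root
seed through labelled substreams; identical configurations are bit-identical.

### What the generator does not emulate

No read-level artifacts (PCR duplicates, mappability, barcode structure —
the pipeline starts from aligned coverage); no antisense or overlapping
transcription; no correlation between expression and gene length or class;
no sequence-dependent crosslinking hotspots within a gene (the propensity
factor is per-gene, so within-gene profiles are smoother than real CRAC
data); the spike genome is represented only by read counts, not a track.
Consequently, passing recovery tests shows the estimators are correct under
the stated statistical model, not that real libraries satisfy that model —
in particular, real per-nucleotide CRAC signal is far spikier, so real
profile ratios need the same cohort averaging but may need wider windows.

## Numerical and procedural choices

* Coordinates are 0-based half-open throughout; GFF3 converted on read.
  Chromosome lengths come from a UCSC-style `chrom.sizes` file.
* wPAS anchors round half away from zero; metagene windows must be
  divisible by the bin size.
* The lag readout isolates the co-transcriptional construction
  (post-transcriptional fraction set to 0 for that scenario): mature-RNA
  binding adds ratio signal directly at the TSS, where the polymerase ramp
  is near zero, and would swamp the build-up of interest. On real data the
  equivalent move is profiling the classifier's core genes only.
* Bootstrap CIs are percentile intervals (2.5/97.5) over genes or samples;
  all bootstrap and simulation RNGs are seeded.
* Degenerate inputs raise user-facing errors naming the offending gene,
  sample, file or line: zero poly(A) weight, zero spike count under spike
  normalization, empty cohorts, all-identical ratio distributions,
  overlapping bedGraph intervals, intervals past the declared chromosome
  end.
* Problem sizes used by the validation runs: 10⁴ random tables for the wPAS
  oracle; 200 features for the quantification oracle; 200 genes for the lag
  cohort; 2000 genes for distribution-shape, mutant-shift and 3′-peak
  statistics; 3000 genes for two-population recovery (the tail threshold is
  twice as sensitive to mode error as the mode itself, and the histogram
  mode sharpens as n^(1/3)). The demo pipeline uses 200 genes.

## Known limitations

* The symmetric-core rule assumes the left flank is purely
  co-transcriptional; a population with *depleted* RNA binding would bias
  the core width.
* The histogram mode, even refined, carries bin-scale uncertainty; with
  fewer than ~500 genes the median−mode gap is unreliable.
* Greedy size matching is not optimal-assignment matching (see above).
* The enrichment filter uses gene-level sums; it has no concept of local
  peaks, and a gene with one strong site and a long silent body is treated
  the same as uniform binding. Per-nucleotide crosslink-site calling is out
  of scope.
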