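# cracflow

Analysis pipeline for quantifying where a chromatin protein binds nascent and
mature RNA, built around UV-crosslinking (CRAC/CLIP-style) and ChIP coverage
tracks. The motivating system is the budding-yeast H3K4 methyltransferase
Set1/COMPASS, whose double RNA-recognition motif (dRRM) binds RNA *in vivo*:
the pipeline separates the co-transcriptional component of that binding
(tracking RNAPII on nascent transcripts) from a post-transcriptional component
(binding to mature mRNA), and localizes binding along transcription units.

## What it computes

Given strand-specific per-nucleotide coverage tracks (bedGraph pairs) for a
crosslinked sample (CL), a non-crosslinked control (No-CL), an RNAPII CRAC
reference and optional ChIP IP/input, plus an annotation and a poly(A)-site
intensity table:

* **Spike-in normalization** — each sample is scaled by
  `reference / spike_reads`, where the spike reads come from a second species
  added in fixed proportion before crosslinking and the reference is the
  median spike count across samples. RPM and per-10M scalings are available
  for ChIP-style tracks.
* **Crosslink-enrichment filter** — per gene, `fold = CL / max(No-CL, 1)` on
  spike-normalized sums; genes with `fold > 5` (strict) are called
  high-confidence RNA-binding targets.
* **Weighted poly(A) site (wPAS)** — most genes use several poly(A) sites, so
  3′-anchored aggregation uses the intensity-weighted mean position
  `wPAS = Σᵢ posᵢ·wᵢ / Σᵢ wᵢ` per gene.
* **Metagene profiles** — cohort-averaged signal anchored on the TSS or the
  wPAS, strand-flipped to 5′→3′, optionally per-gene normalized, with
  missing (out-of-gene) bins reported as missing rather than zero; plus
  bin-wise profile ratios, greedy size-matched control cohorts and a
  bootstrap comparison of WT vs mutant signal in the pre-wPAS window.
* **Ratio-distribution classifier** — per-gene `log10(CL / RNAPII)` ratios
  are summarized by mode (refined Freedman–Diaconis histogram mode), median
  and mean; the symmetric core around the mode is mirrored from the robust
  left reach `d = mode − Q₀.₀₁`, and genes above `mode + d` form the
  post-transcriptional tail. Cross-assay agreement is reported as the r² of
  a least-squares regression in log space.

A fully tested synthetic-data generator produces annotation, tracks, spike
counts, poly(A) tables and a ground-truth table with the statistical
structure this analysis assumes (RNAPII 5′ ramp and 3′ decline, lagged
crosslink signal, mutant-insensitive 3′ peak, post-transcriptional gene
class, spike-in recovery variation), so every stage can be validated by
parameter recovery.

## Worked example

The shipped demo configuration simulates a 200-gene, seven-sample dataset
and runs every stage:

```
cracflow run --config configs/demo.yaml --outdir runs/demo
```

which prints (stderr shows per-stage logs; stdout the run summary):

```json
{
  "core_fraction": 0.6446700507614214,
  "mean": 0.19531325957297394,
  "median": -0.002533579549722678,
  "mode": -0.1267378598439613,
  "n_genes": 197,
  "n_high_confidence_wt": 197,
  "n_tail": 68,
  "peak3_mut_wt_ratio": 0.9552554811629957,
  "set1_vs_rnapii_r2": 0.4001934658045944,
  "yfaa_median_shift": -0.3544456238830548
}
```

Reading this: 197/200 simulated genes pass the >5-fold crosslink filter; the
log10 CL/RNAPII ratio distribution is right-skewed (mean 0.195 > median
−0.003 > mode −0.127), with 64% of genes in the symmetric core around the
mode and 68 genes in the post-transcriptional tail; the mutant/WT signal
ratio in the 50 nt upstream of the wPAS is 0.96 (the 3′ peak does not depend
on the RNA-binding domain), while the mutant's ratio distribution as a whole
shifts down by 0.35 log10 units — the co-transcriptional component is lost,
the 3′/post-transcriptional one is not.

Outputs land under `runs/demo/`: `scale_factors.tsv`, `signal_tables.tsv`,
`enrichment.tsv`, `wpas.tsv`, `metagene_tss.tsv`, `metagene_wpas.tsv`,
`peak3_equivalence.json`, `classification.tsv`,
`classification_summary.json` and a `manifest.json` with parameters and
output hashes; reruns with the same seed are byte-identical.

The individual stages are also available as subcommands (`simulate`,
`quantify`, `enrich`, `wpas`, `metagene`, `classify`, `correlate`,
`compare`) and as library functions (`import cracflow`).

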