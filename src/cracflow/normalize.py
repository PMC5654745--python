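"""Spike-in / depth normalization, per-feature quantification and the
crosslink-enrichment filter.

Normalization methods
---------------------
spike
    ``scale = reference / spike_reads`` with the reference being the median
    spike count across the samples in the sheet. Spike-in reads come from a
    second species added in fixed proportion before crosslinking, so they
    calibrate between-sample recovery independently of the transcriptome.
rpm
    Reads per million mapped: ``scale = 1e6 / total_mapped``.
per10m
    Normalization to 10 million mapped reads: ``scale = 1e7 / total_mapped``
    (the convention used for browser tracks).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import CoverageTrack, CracflowError, Feature

SIGNAL_COLUMNS = ("raw_signal", "normalized_signal", "scale_factor", "sample_id")

_METHODS = ("spike", "rpm", "per10m")


@dataclass
class ScaleFactors:
    """Per-sample scale factors under one normalization method."""

    method: str
    factors: pd.Series  # index: sample_id
    reference_spike: float | None = None  # median spike count (spike method)

    def factor(self, sample_id: str) -> float:
        if sample_id not in self.factors.index:
            raise CracflowError(f"no scale factor for sample {sample_id!r}")
        return float(self.factors.loc[sample_id])


def compute_scale_factors(sample_sheet: pd.DataFrame, method: str = "spike") -> ScaleFactors:
    """Scale factors for every sample in the sheet.

    For the spike method the reference is the median ``spike_reads`` across
    samples; a zero spike count is an error naming the sample.
    """
    method = method.lower()
    if method not in _METHODS:
        raise CracflowError(f"unknown normalization method {method!r}")
    sheet = sample_sheet.set_index("sample_id") if "sample_id" in sample_sheet.columns \
        else sample_sheet
    if method == "spike":
        spikes = sheet["spike_reads"].astype(float)
        zero = spikes[spikes <= 0]
        if len(zero):
            raise CracflowError(
                f"spike normalization requires spike_reads > 0; "
                f"sample {zero.index[0]!r} has {int(zero.iloc[0])}"
            )
        reference = float(spikes.median())
        return ScaleFactors("spike", reference / spikes, reference_spike=reference)
    total = sheet["total_mapped"].astype(float)
    if (total <= 0).any():
        bad = total[total <= 0].index[0]
        raise CracflowError(f"sample {bad!r} has non-positive total_mapped")
    scale = (1e6 if method == "rpm" else 1e7) / total
    return ScaleFactors(method, scale)


def quantify_feature(track: CoverageTrack, feature: Feature, mode: str = "sense") -> float:
    """Sum of per-nucleotide signal over the feature interval.

    ``mode`` selects the strand: "sense" (the feature's strand), "antisense"
    (the opposite strand) or "both" (sum of both, for unstranded assays such
    as ChIP).
    """
    if feature.chrom not in track.chrom_sizes:
        raise CracflowError(
            f"chromosome {feature.chrom!r} missing from track {track.sample_id!r}"
        )
    if mode == "sense":
        strands = [feature.strand]
    elif mode == "antisense":
        strands = ["+" if feature.strand == "-" else "-"]
    elif mode == "both":
        strands = ["+", "-"]
    else:
        raise CracflowError(f"unknown quantification mode {mode!r}")
    return float(sum(
        track.vector(feature.chrom, s)[feature.start:feature.end].sum()
        for s in strands
    ))


def quantify_features(
    track: CoverageTrack,
    features: list[Feature],
    mode: str = "sense",
    scale_factor: float = 1.0,
) -> pd.DataFrame:
    """Per-gene signal table: raw and normalized sums for one sample.

    Returns a DataFrame indexed by gene_id with columns
    :data:`SIGNAL_COLUMNS`; ``normalized_signal = raw_signal * scale_factor``.
    """
    raw = np.array([quantify_feature(track, f, mode) for f in features])
    return pd.DataFrame(
        {
            "raw_signal": raw,
            "normalized_signal": raw * scale_factor,
            "scale_factor": scale_factor,
            "sample_id": track.sample_id,
        },
        index=pd.Index([f.gene_id for f in features], name="gene_id"),
    )


def call_high_confidence(
    cl_table: pd.DataFrame,
    nocl_table: pd.DataFrame,
    fold_threshold: float = 5.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Crosslink-enrichment filter: CL signal > ``fold_threshold`` x No-CL.

    Both tables must be normalized by the same method over the same gene
    universe. The fold change is ``cl / max(nocl, pseudocount)`` and the call
    uses a strict inequality; genes failing the filter are retained with
    ``high_confidence = False``.
    """
    genes = cl_table.index.intersection(nocl_table.index)
    if genes.empty:
        raise CracflowError("CL and No-CL tables share no genes")
    cl = cl_table.loc[genes, "normalized_signal"].astype(float)
    nocl = nocl_table.loc[genes, "normalized_signal"].astype(float)
    if (cl < 0).any() or (nocl < 0).any():
        raise CracflowError("negative normalized signal in enrichment input")
    fold = cl / np.maximum(nocl, pseudocount)
    return pd.DataFrame({
        "cl_signal": cl,
        "nocl_signal": nocl,
        "fold": fold,
        "high_confidence": fold > fold_threshold,
    })


@dataclass
class RatioTable:
    """Per-gene log10 ratios of two normalized signal tables."""

    ratios: pd.Series  # index gene_id, values log10(num/den)
    n_excluded_denominator: int
    n_excluded_numerator: int


def ratio_table(
    numerator_table: pd.DataFrame,
    denominator_table: pd.DataFrame,
    min_denominator: float = 1.0,
) -> RatioTable:
    """log10(numerator / denominator) per gene.

    Genes with denominator below ``min_denominator`` or zero numerator are
    excluded and counted. Tables must be normalized by the same method.
    """
    genes = numerator_table.index.intersection(denominator_table.index)
    if genes.empty:
        raise CracflowError("ratio tables share no genes")
    num = numerator_table.loc[genes, "normalized_signal"].astype(float)
    den = denominator_table.loc[genes, "normalized_signal"].astype(float)
    den_ok = den >= min_denominator
    num_ok = num > 0
    keep = den_ok & num_ok
    ratios = np.log10(num[keep] / den[keep])
    ratios.name = "log10_ratio"
    return RatioTable(
        ratios=ratios,
        n_excluded_denominator=int((~den_ok).sum()),
        n_excluded_numerator=int((den_ok & ~num_ok).sum()),
    )
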