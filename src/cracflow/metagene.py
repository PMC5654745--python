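"""Anchored metagene (aggregate) profiles and profile comparisons.

A metagene profile averages a coverage track over a cohort of genes aligned
on a common anchor (TSS or wPAS), oriented 5'->3' so minus-strand genes are
reversed. Positions beyond a gene's extent can be clipped; per-gene
normalization (dividing by the gene's own mean over in-gene window positions)
removes expression differences so the profile reflects shape only. Bins with
no contributing gene are reported as missing (NaN), never as zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CoverageTrack, CracflowError, Feature

logger = logging.getLogger(__name__)

ANCHORS = ("TSS", "wPAS")
PER_GENE_NORMS = ("none", "mean_of_window", "rpm_only")


@dataclass
class MetageneProfile:
    """Aggregate profile over a gene cohort.

    ``values[k]`` is the mean over contributing genes of the per-gene mean
    signal in bin ``k``; ``n_genes_per_bin[k]`` counts the contributing genes.
    ``gene_values`` keeps the per-gene binned matrix (genes x bins, NaN where
    a gene does not cover a bin) so that gene-level resampling (bootstrap)
    remains possible downstream.
    """

    anchor: str
    upstream: int
    downstream: int
    bin_size: int
    values: np.ndarray
    n_genes_per_bin: np.ndarray
    per_gene_norm: str
    cohort: str = ""
    gene_ids: list[str] = field(default_factory=list)
    gene_values: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return (self.upstream + self.downstream) // self.bin_size

    @property
    def bin_centers(self) -> np.ndarray:
        """Bin centers in nt relative to the anchor (negative = upstream)."""
        k = np.arange(self.n_bins)
        return -self.upstream + (k + 0.5) * self.bin_size

    def compatible(self, other: "MetageneProfile") -> bool:
        return (
            self.anchor == other.anchor
            and self.upstream == other.upstream
            and self.downstream == other.downstream
            and self.bin_size == other.bin_size
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "value": self.values,
            "n_genes": self.n_genes_per_bin,
        })


def _anchor_position(f: Feature, anchor: str, wpas: pd.DataFrame | None) -> int | None:
    if anchor == "TSS":
        return f.tss
    if wpas is None or f.gene_id not in wpas.index:
        return None
    return int(wpas.at[f.gene_id, "wpas_anchor"])


def metagene_profile(
    track: CoverageTrack,
    features: list[Feature],
    anchor: str = "TSS",
    window: tuple[int, int] = (200, 1500),
    bin_size: int = 10,
    per_gene_norm: str = "mean_of_window",
    min_length: int = 0,
    clip_to_gene: bool = True,
    wpas: pd.DataFrame | None = None,
    cohort: str = "",
) -> MetageneProfile:
    """Build an anchored metagene profile of ``track`` over ``features``.

    Parameters
    ----------
    anchor
        "TSS" or "wPAS" (the latter requires a ``wpas`` table from
        :func:`cracflow.wpas.compute_wpas`; genes without a wPAS are skipped
        with a warning).
    window
        (upstream_nt, downstream_nt) around the anchor; must be divisible by
        ``bin_size``.
    per_gene_norm
        "none"/"rpm_only" (use track values as given) or "mean_of_window"
        (divide each gene by its mean over in-gene window positions).
    min_length
        Genes shorter than this are excluded from the cohort.
    clip_to_gene
        Exclude window positions outside [start, end).
    """
    if anchor not in ANCHORS:
        raise CracflowError(f"unknown anchor {anchor!r}")
    if per_gene_norm not in PER_GENE_NORMS:
        raise CracflowError(f"unknown per-gene normalization {per_gene_norm!r}")
    up, down = int(window[0]), int(window[1])
    if (up + down) % bin_size != 0 or up + down <= 0:
        raise CracflowError("window span must be a positive multiple of bin_size")
    cohort_feats = [f for f in features if f.length >= min_length]
    if not cohort_feats:
        raise CracflowError("empty cohort after min_length filter")

    n_bins = (up + down) // bin_size
    offsets = np.arange(-up, down)
    bin_of = (offsets + up) // bin_size
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    n_skipped = 0
    for f in cohort_feats:
        apos = _anchor_position(f, anchor, wpas)
        if apos is None:
            n_skipped += 1
            continue
        sign = 1 if f.strand == "+" else -1
        gpos = apos + sign * offsets
        chrom_len = track.chrom_sizes.get(f.chrom)
        if chrom_len is None:
            raise CracflowError(f"chromosome {f.chrom!r} missing from track")
        valid = (gpos >= 0) & (gpos < chrom_len)
        in_gene = (gpos >= f.start) & (gpos < f.end)
        if clip_to_gene:
            valid &= in_gene
        vec = track.vector(f.chrom, f.strand)
        vals = np.full(len(offsets), np.nan)
        vals[valid] = vec[gpos[valid]]
        if per_gene_norm == "mean_of_window":
            denom_vals = vals[valid & in_gene]
            denom = np.nanmean(denom_vals) if len(denom_vals) else np.nan
            if not np.isfinite(denom) or denom <= 0:
                n_skipped += 1
                continue
            vals = vals / denom
        # per-gene bin means
        binned = np.full(n_bins, np.nan)
        for k in range(n_bins):
            seg = vals[bin_of == k]
            good = ~np.isnan(seg)
            if good.any():
                binned[k] = seg[good].mean()
        rows.append(binned)
        gene_ids.append(f.gene_id)
    if n_skipped:
        logger.warning("metagene: skipped %d gene(s) (missing wPAS or zero norm)",
                       n_skipped)
    if not rows:
        raise CracflowError("no genes contributed to the metagene profile")
    mat = np.vstack(rows)
    n_per_bin = (~np.isnan(mat)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        values = np.where(n_per_bin > 0, np.nansum(mat, axis=0) /
                          np.maximum(n_per_bin, 1), np.nan)
    return MetageneProfile(
        anchor=anchor, upstream=up, downstream=down, bin_size=bin_size,
        values=values, n_genes_per_bin=n_per_bin, per_gene_norm=per_gene_norm,
        cohort=cohort, gene_ids=gene_ids, gene_values=mat,
    )


def profile_ratio(
    profile_a: MetageneProfile,
    profile_b: MetageneProfile,
    min_denominator_bin: float = 0.0,
) -> np.ndarray:
    """Bin-wise ``a / b``; bins where ``b`` is missing or below
    ``min_denominator_bin`` (or zero) are NaN."""
    if not profile_a.compatible(profile_b):
        raise CracflowError("profiles have different anchor/window/bin structure")
    a, b = profile_a.values, profile_b.values
    out = np.full_like(a, np.nan)
    ok = np.isfinite(a) & np.isfinite(b) & (b > 0) & (b >= min_denominator_bin)
    out[ok] = a[ok] / b[ok]
    return out


@dataclass
class SizeMatchResult:
    pairs: list[tuple[Feature, Feature]]
    matched_fraction: float


def size_match(
    cohort_a: list[Feature],
    cohort_b: list[Feature],
    tolerance_fraction: float = 0.2,
) -> SizeMatchResult:
    """Greedy nearest-length matching of cohort A to cohort B, no replacement.

    A genes are processed in order of increasing length; each takes the
    unmatched B gene of closest length. Pairs whose length difference exceeds
    ``tolerance_fraction * len(a)`` are discarded. Zero matches is an error.
    """
    if not cohort_a or not cohort_b:
        raise CracflowError("size_match requires two non-empty cohorts")
    remaining = sorted(cohort_b, key=lambda f: f.length)
    pairs: list[tuple[Feature, Feature]] = []
    for fa in sorted(cohort_a, key=lambda f: f.length):
        best_i = min(range(len(remaining)),
                     key=lambda i: abs(remaining[i].length - fa.length))
        fb = remaining[best_i]
        if abs(fb.length - fa.length) <= tolerance_fraction * fa.length:
            pairs.append((fa, fb))
            remaining.pop(best_i)
        if not remaining:
            break
    if not pairs:
        raise CracflowError(
            "size_match found no pairs within tolerance; increase tolerance_fraction"
        )
    return SizeMatchResult(pairs=pairs,
                           matched_fraction=len(pairs) / len(cohort_a))


@dataclass
class Peak3Equivalence:
    """Mutant/WT signal ratio in the pre-wPAS window, with a gene bootstrap CI."""

    ratio: float
    ci_low: float
    ci_high: float
    window_nt: int
    n_genes_wt: int
    n_genes_mut: int


def peak3_equivalence(
    profile_wt: MetageneProfile,
    profile_mut: MetageneProfile,
    wpas_window: int = 50,
    n_boot: int = 1000,
    random_state: int | np.random.Generator = 0,
) -> Peak3Equivalence:
    """Compare mutant vs WT signal in the window just upstream of the wPAS.

    Both profiles must be wPAS-anchored with identical structure and carry
    per-gene matrices. The statistic is mean(mut)/mean(wt) over bins whose
    centers fall in [-wpas_window, 0); the CI is a percentile bootstrap over
    genes, resampling each cohort independently.
    """
    if not profile_wt.compatible(profile_mut):
        raise CracflowError("profiles have different anchor/window/bin structure")
    if profile_wt.anchor != "wPAS":
        raise CracflowError("peak3_equivalence requires wPAS-anchored profiles")
    if profile_wt.gene_values is None or profile_mut.gene_values is None:
        raise CracflowError("profiles lack per-gene matrices")
    centers = profile_wt.bin_centers
    sel = (centers >= -wpas_window) & (centers < 0)
    if not sel.any():
        raise CracflowError("no bins inside the pre-wPAS window")
    wt = profile_wt.gene_values[:, sel]
    mut = profile_mut.gene_values[:, sel]

    def _mean(mat: np.ndarray) -> float:
        return float(np.nanmean(mat))

    ratio = _mean(mut) / _mean(wt)
    rng = (random_state if isinstance(random_state, np.random.Generator)
           else np.random.default_rng(random_state))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        iw = rng.integers(0, wt.shape[0], wt.shape[0])
        im = rng.integers(0, mut.shape[0], mut.shape[0])
        boots[b] = _mean(mut[im]) / _mean(wt[iw])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return Peak3Equivalence(
        ratio=ratio, ci_low=float(lo), ci_high=float(hi),
        window_nt=wpas_window,
        n_genes_wt=wt.shape[0], n_genes_mut=mut.shape[0],
    )


def plot_profile(profiles: dict[str, MetageneProfile], path) -> None:
    """Basic line plot of one or more compatible profiles."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, prof in profiles.items():
        ax.plot(prof.bin_centers, prof.values, label=label)
    first = next(iter(profiles.values()))
    ax.set_xlabel(f"position relative to {first.anchor} (nt)")
    ax.set_ylabel("mean signal")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
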