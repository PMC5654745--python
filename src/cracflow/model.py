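"""Shared genomic data model.

All coordinates are 0-based, half-open ([start, end)), matching BED/bedGraph.
GFF3 input is converted on read. Strands are "+" and "-"; minus-strand signal
is stored as non-negative values in its own per-strand vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

FEATURE_CLASSES = ("mRNA", "CUT", "SUT", "snRNA", "snoRNA", "ORF")
CONDITIONS = ("CRAC_CL", "CRAC_NoCL", "RNAPII_CRAC", "ChIP_IP", "ChIP_input")
GENOTYPES = ("WT", "YF_AA", "other")
STRANDS = ("+", "-")


class CracflowError(Exception):
    """Base class for user-facing errors (bad input, bad parameters)."""


class FormatError(CracflowError):
    """A file does not parse in its declared dialect."""


@dataclass(frozen=True)
class Feature:
    """A stranded genomic interval with a class label.

    Parameters
    ----------
    gene_id
        Unique identifier within an annotation.
    chrom, start, end
        Location, 0-based half-open.
    strand
        "+" or "-".
    feature_class
        One of :data:`FEATURE_CLASSES` (mRNA, CUT, SUT, snRNA, snoRNA, ORF).
    introns
        Optional (start, end) sub-intervals strictly inside [start, end),
        pairwise non-overlapping. Genomic coordinates, not transcript-relative.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    introns: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CracflowError(
                f"feature {self.gene_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise CracflowError(f"feature {self.gene_id!r}: bad strand {self.strand!r}")
        if self.feature_class not in FEATURE_CLASSES:
            raise CracflowError(
                f"feature {self.gene_id!r}: unknown feature class "
                f"{self.feature_class!r} (expected one of {FEATURE_CLASSES})"
            )
        introns = tuple(sorted((int(a), int(b)) for a, b in self.introns))
        object.__setattr__(self, "introns", introns)
        prev_end = self.start
        for a, b in introns:
            if not (self.start < a < b < self.end):
                raise CracflowError(
                    f"feature {self.gene_id!r}: intron [{a}, {b}) not strictly "
                    f"inside [{self.start}, {self.end})"
                )
            if a < prev_end:
                raise CracflowError(f"feature {self.gene_id!r}: overlapping introns")
            prev_end = b

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    def exons(self) -> list[tuple[int, int]]:
        """Exonic sub-intervals (gene minus introns), genomic coordinates."""
        out: list[tuple[int, int]] = []
        pos = self.start
        for a, b in self.introns:
            if a > pos:
                out.append((pos, a))
            pos = b
        if pos < self.end:
            out.append((pos, self.end))
        return out

    def local_to_genomic(self, x: int) -> int:
        """Map a transcript-oriented offset (0 = TSS) to a genomic position."""
        return self.start + x if self.strand == "+" else self.end - 1 - x

    def genomic_to_local(self, pos: int) -> int:
        return pos - self.start if self.strand == "+" else self.end - 1 - pos


@dataclass(eq=False)
class CoverageTrack:
    """Per-chromosome, per-strand dense signal with sample metadata.

    ``data`` maps (chrom, strand) to a non-negative float vector whose length
    equals ``chrom_sizes[chrom]``. Missing (chrom, strand) combinations are
    treated as all-zero.
    """

    sample_id: str
    chrom_sizes: dict[str, int]
    data: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    condition: str = "CRAC_CL"
    genotype: str = "WT"
    total_mapped: int = 0
    spike_reads: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise CracflowError(f"unknown condition {self.condition!r}")
        if self.genotype not in GENOTYPES:
            raise CracflowError(f"unknown genotype {self.genotype!r}")
        if self.spike_reads < 0 or self.total_mapped < self.spike_reads:
            raise CracflowError(
                f"sample {self.sample_id!r}: require total_mapped >= spike_reads >= 0"
            )
        for (chrom, strand), vec in self.data.items():
            if strand not in STRANDS:
                raise CracflowError(f"bad strand key {strand!r}")
            if chrom not in self.chrom_sizes:
                raise CracflowError(f"chromosome {chrom!r} not in chrom_sizes")
            if len(vec) != self.chrom_sizes[chrom]:
                raise CracflowError(
                    f"sample {self.sample_id!r}: vector length {len(vec)} != "
                    f"declared length {self.chrom_sizes[chrom]} for {chrom!r}"
                )
            if np.any(vec < 0):
                raise CracflowError(
                    f"sample {self.sample_id!r}: negative signal on {chrom}{strand}"
                )

    def vector(self, chrom: str, strand: str) -> np.ndarray:
        """Dense signal for one chromosome strand (zeros if absent)."""
        if chrom not in self.chrom_sizes:
            raise CracflowError(f"chromosome {chrom!r} not in track {self.sample_id!r}")
        key = (chrom, strand)
        if key not in self.data:
            return np.zeros(self.chrom_sizes[chrom])
        return self.data[key]

    def total_signal(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        """A copy with every value multiplied by ``factor`` (metadata kept)."""
        if factor <= 0:
            raise CracflowError("scale factor must be > 0")
        new = replace(self)
        new.data = {k: v * factor for k, v in self.data.items()}
        return new


@dataclass
class PolyASiteTable:
    """Per-gene poly(A) addition sites with intensities.

    ``sites[gene_id]`` is a list of (genomic position, weight) pairs. Every
    gene must carry at least one site and positive total weight.
    """

    sites: dict[str, list[tuple[int, float]]]

    def __post_init__(self) -> None:
        for gene, lst in self.sites.items():
            if not lst:
                raise CracflowError(f"gene {gene!r}: poly(A) table entry has no sites")
            total = 0.0
            for pos, w in lst:
                if w < 0:
                    raise CracflowError(f"gene {gene!r}: negative poly(A) weight {w}")
                total += w
            if total <= 0:
                raise CracflowError(f"gene {gene!r}: total poly(A) weight is zero")

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sites
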