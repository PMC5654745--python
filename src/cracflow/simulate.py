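"""Synthetic CRAC/ChIP dataset generator with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a chromatin methyltransferase that binds nascent RNA:

* RNAPII occupancy with a short 5' entry ramp, a flat body and a linear
  decline over the final 10% of each transcription unit;
* a crosslinked (CL) RNA-binding signal whose co-transcriptional component
  follows RNAPII with a downstream lag of ~100-250 nt and releases slowly
  along the transcript;
* a genotype-independent 3' signal peak just upstream of the weighted
  poly(A) site;
* a minority gene class with excess, exon-restricted (mature-RNA,
  post-transcriptional) binding;
* an RNA-binding-mutant condition (YF/AA-like) in which only the
  co-transcriptional component is attenuated;
* a non-crosslinked control that is uniform background;
* ChIP IP occupancy slightly 3'-shifted from RNAPII plus a uniform input;
* spike-in reads from a dedicated spike genome, represented by per-sample
  read counts.

Counts are Poisson per nucleotide. All randomness flows from ``SimConfig.seed``
through per-track substreams, so identical configs give bit-identical output.
"""
from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CoverageTrack, CracflowError, Feature, PolyASiteTable
from .io import (
    write_annotation_bed,
    write_bedgraph_pair,
    write_chrom_sizes,
    write_pa_table,
)
from .wpas import round_half_away

ExpectationMap = dict[tuple[str, str], np.ndarray]

#: columns of the ground-truth table (one row per gene)
TRUTH_COLUMNS = (
    "gene_id", "expression", "crosslink_efficiency", "chip_efficiency",
    "is_post_txn", "post_txn_multiplier", "true_wpas",
)


@dataclass
class SimConfig:
    """Parameters of the synthetic dataset.

    Lengths are nucleotides, rates are expected reads per nucleotide.
    ``mean_expression`` sets sequencing depth: it is the mean per-nucleotide
    expected RNAPII read count across genes.
    """

    seed: int = 0
    n_genes: int = 500
    n_chroms: int = 4
    chrom_length: int | None = None  # None: auto-size to fit the genes
    # gene lengths: log-normal, median exp(gene_length_log_mean)
    gene_length_log_mean: float = 7.244  # median ~1400 nt
    gene_length_log_sd: float = 0.45
    min_gene_length: int = 400
    intergenic_gap: int = 200
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "mRNA": 0.75, "CUT": 0.08, "SUT": 0.07,
            "snRNA": 0.02, "snoRNA": 0.03, "ORF": 0.05,
        }
    )
    intron_probability: float = 0.05  # mRNA only
    intron_length_range: tuple[int, int] = (60, 400)
    # expression and depth
    expression_log_sd: float = 1.0
    mean_expression: float = 30.0
    # RNAPII shape
    pol_entry_ramp_nt: int = 50
    pol_3prime_decline_fraction: float = 0.9
    # Set1-like CL signal
    set1_lag_nt: int = 150
    set1_release_decay_nt: float | None = 1500.0  # None: pure shift, no release
    peak3_offset_nt: int = 25
    peak3_width_nt: int = 25
    peak3_amplitude: float = 3.5
    post_txn_fraction: float = 0.35
    post_txn_multiplier_log_median: float = 2.079  # ln 8
    post_txn_multiplier_log_sd: float = 0.5
    crosslink_jitter_log_sd: float = 0.46  # ~0.2 in log10
    yfaa_5prime_factor: float = 0.3
    background_rate: float = 0.2  # No-CL, reads/nt
    # spike-in and per-sample recovery
    spike_read_fraction: float = 0.005
    spike_depth: int = 1_000_000
    sample_recovery_log_sd: float = 0.2
    # ChIP
    chip_3prime_shift_nt: int = 50
    chip_efficiency_log_sd: float = 0.3
    chip_input_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("intron_probability", "post_txn_fraction",
                     "spike_read_fraction", "pol_3prime_decline_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CracflowError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.yfaa_5prime_factor <= 1.0:
            raise CracflowError("yfaa_5prime_factor must be in (0, 1]")
        if self.set1_lag_nt < 0:
            raise CracflowError("set1_lag_nt must be >= 0")
        if self.mean_expression <= 0 or self.spike_depth <= 0:
            raise CracflowError("depth parameters must be > 0")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-6:
            raise CracflowError(f"class proportions sum to {total}, not 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intron_length_range"] = list(self.intron_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise CracflowError(f"unknown simulation keys: {sorted(unknown)}")
        d = dict(d)
        if "intron_length_range" in d:
            d["intron_length_range"] = tuple(d["intron_length_range"])
        return cls(**d)


def _rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic substream keyed by (root seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# annotation, poly(A) sites, truth
# ---------------------------------------------------------------------------

def simulate_annotation(
    config: SimConfig,
) -> tuple[list[Feature], PolyASiteTable, pd.DataFrame]:
    """Place non-overlapping genes on synthetic chromosomes on both strands.

    Returns (features, poly(A) table, truth table). Each gene receives 1-4
    poly(A) sites within its final 10% with Dirichlet-distributed weights;
    ``true_wpas`` is the intensity-weighted average site rounded to an integer
    coordinate. The truth table (a DataFrame indexed by gene_id, columns
    :data:`TRUTH_COLUMNS`) records expression, per-gene efficiency factors and
    post-transcriptional class membership.
    """
    rng = _rng(config.seed, "annotation")
    lengths = np.maximum(
        rng.lognormal(config.gene_length_log_mean, config.gene_length_log_sd,
                      config.n_genes).astype(int),
        config.min_gene_length,
    )
    classes = rng.choice(
        list(config.class_proportions), size=config.n_genes,
        p=list(config.class_proportions.values()),
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)

    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    features: list[Feature] = []
    truth_rows = []
    pa_sites: dict[str, list[tuple[int, float]]] = {}

    cursor = config.intergenic_gap
    chrom_idx = 0
    chrom_sizes: dict[str, int] = {}
    n_on_chrom = 0
    for g in range(config.n_genes):
        length = int(lengths[g])
        if n_on_chrom >= per_chrom:
            chrom_sizes[f"chr{chrom_idx + 1}"] = cursor
            chrom_idx += 1
            cursor = config.intergenic_gap
            n_on_chrom = 0
        chrom = f"chr{chrom_idx + 1}"
        start, end = cursor, cursor + length
        if config.chrom_length is not None and end + config.intergenic_gap > config.chrom_length:
            raise CracflowError(
                f"genome too small to place {config.n_genes} genes: gene {g} "
                f"would end at {end} on {chrom} (length {config.chrom_length}); "
                "increase chrom_length or n_chroms"
            )
        cursor = end + config.intergenic_gap
        n_on_chrom += 1
        gene_id = f"g{g + 1:05d}"
        strand = str(strands[g])
        fclass = str(classes[g])

        introns: tuple[tuple[int, int], ...] = ()
        if fclass == "mRNA" and rng.random() < config.intron_probability:
            lo, hi = config.intron_length_range
            ilen = int(rng.integers(lo, min(hi, max(lo + 1, length // 3)) + 1))
            # introns are 5'-proximal, as in budding yeast
            max_off = max(51, length - ilen - 50)
            off = int(rng.integers(50, max_off))
            if strand == "+":
                introns = ((start + off, start + off + ilen),)
            else:
                introns = ((end - off - ilen, end - off),)
        feat = Feature(gene_id, chrom, start, end, strand, fclass, introns)
        features.append(feat)

        # poly(A) sites in the final 10% of the gene on its strand
        window = max(4, length // 10)
        k = int(rng.integers(1, 5))
        offs = np.sort(rng.choice(window, size=min(k, window), replace=False))
        if strand == "+":
            positions = end - window + offs
        else:
            positions = start + window - 1 - offs
        weights = rng.dirichlet(np.ones(len(positions))) * 1000.0
        pa_sites[gene_id] = [
            (int(p), float(w)) for p, w in zip(positions, weights)
        ]
        wpas_real = float(np.average(positions, weights=weights))
        expression = config.mean_expression * float(
            rng.lognormal(-config.expression_log_sd**2 / 2, config.expression_log_sd)
        )
        is_post = bool(rng.random() < config.post_txn_fraction)
        multiplier = (
            max(float(rng.lognormal(config.post_txn_multiplier_log_median,
                                    config.post_txn_multiplier_log_sd)), 1.5)
            if is_post else 1.0
        )
        truth_rows.append({
            "gene_id": gene_id,
            "expression": expression,
            "crosslink_efficiency": float(
                rng.lognormal(-config.crosslink_jitter_log_sd**2 / 2,
                              config.crosslink_jitter_log_sd)
            ),
            "chip_efficiency": float(
                rng.lognormal(-config.chip_efficiency_log_sd**2 / 2,
                              config.chip_efficiency_log_sd)
            ),
            "is_post_txn": is_post,
            "post_txn_multiplier": multiplier,
            "true_wpas": int(round_half_away(wpas_real)),
        })
    chrom_sizes[f"chr{chrom_idx + 1}"] = cursor
    if config.chrom_length is not None:
        chrom_sizes = {c: config.chrom_length for c in chrom_sizes}

    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    truth.attrs["chrom_sizes"] = chrom_sizes
    return features, PolyASiteTable(sites=pa_sites), truth


def chrom_sizes_of(features: list[Feature], truth: pd.DataFrame | None = None,
                   margin: int = 200) -> dict[str, int]:
    """Chromosome sizes: from the truth table if available, else from extents."""
    if truth is not None and "chrom_sizes" in truth.attrs:
        return dict(truth.attrs["chrom_sizes"])
    sizes: dict[str, int] = {}
    for f in features:
        sizes[f.chrom] = max(sizes.get(f.chrom, 0), f.end + margin)
    return sizes


# ---------------------------------------------------------------------------
# expectation models
# ---------------------------------------------------------------------------

def pol_local_shape(length: int, config: SimConfig) -> np.ndarray:
    """RNAPII occupancy shape over gene-local coordinates, values in [0, 1].

    Linear entry ramp over ``pol_entry_ramp_nt``, flat body, linear decline by
    ``pol_3prime_decline_fraction`` over the final 10% of the gene.
    """
    x = np.arange(length, dtype=float)
    shape = np.ones(length)
    ramp = min(config.pol_entry_ramp_nt, length)
    if ramp > 0:
        shape[:ramp] = (x[:ramp] + 1.0) / ramp
    decline = max(1, length // 10)
    d = config.pol_3prime_decline_fraction
    if d > 0:
        i = np.arange(decline, dtype=float)
        shape[length - decline:] *= 1.0 - d * (i + 1.0) / decline
    return shape


def expected_rnapii(
    features: list[Feature], truth: pd.DataFrame, config: SimConfig
) -> ExpectationMap:
    """Noise-free expected RNAPII CRAC coverage per (chrom, strand)."""
    sizes = chrom_sizes_of(features, truth)
    exp: ExpectationMap = {(c, s): np.zeros(n) for c, n in sizes.items() for s in "+-"}
    for f in features:
        e = float(truth.at[f.gene_id, "expression"])
        local = e * pol_local_shape(f.length, config)
        _add_local(exp[(f.chrom, f.strand)], f, local)
    return exp


def _add_local(vec: np.ndarray, f: Feature, local: np.ndarray) -> None:
    """Add a gene-local (5'->3') profile into a genomic strand vector."""
    if f.strand == "+":
        vec[f.start:f.end] += local
    else:
        vec[f.start:f.end] += local[::-1]


def _extract_local(vec: np.ndarray, f: Feature) -> np.ndarray:
    seg = vec[f.start:f.end]
    return seg.copy() if f.strand == "+" else seg[::-1].copy()


def expected_set1_cl(
    features: list[Feature],
    rnapii_expectation: ExpectationMap,
    truth: pd.DataFrame,
    config: SimConfig,
    genotype: str,
) -> ExpectationMap:
    """Noise-free expected CL coverage for the RNA-binding protein.

    Per gene (local coordinates, 5'->3'):

    * co-transcriptional term: the gene's RNAPII expectation shifted
      downstream by ``set1_lag_nt`` and, when ``set1_release_decay_nt`` is
      set, damped by ``exp(-(x - lag)/decay)`` (slow release of the protein
      along the transcript); attenuated by ``yfaa_5prime_factor`` in the
      YF/AA genotype;
    * 3' term: a Gaussian bump of width ``peak3_width_nt`` centred
      ``peak3_offset_nt`` upstream of the true wPAS, amplitude
      ``peak3_amplitude * expression`` — identical in both genotypes;
    * post-transcriptional term: ``post_txn_multiplier * expression`` over
      exonic positions only, for post-transcriptional genes — identical in
      both genotypes.

    The whole expectation is multiplied by the gene's crosslink efficiency.
    """
    if genotype not in ("WT", "YF_AA"):
        raise CracflowError(f"unknown genotype {genotype!r}")
    sizes = {c: len(v) for (c, s), v in rnapii_expectation.items()}
    exp: ExpectationMap = {(c, s): np.zeros(n) for c, n in sizes.items() for s in "+-"}
    lag = config.set1_lag_nt
    factor = config.yfaa_5prime_factor if genotype == "YF_AA" else 1.0
    for f in features:
        e = float(truth.at[f.gene_id, "expression"])
        eff = float(truth.at[f.gene_id, "crosslink_efficiency"])
        pol_local = _extract_local(rnapii_expectation[(f.chrom, f.strand)], f)
        length = f.length
        co = np.zeros(length)
        if lag < length:
            co[lag:] = pol_local[: length - lag]
            if config.set1_release_decay_nt:
                co[lag:] *= np.exp(
                    -np.arange(length - lag) / config.set1_release_decay_nt
                )
        co *= factor

        w_local = f.genomic_to_local(int(truth.at[f.gene_id, "true_wpas"]))
        center = w_local - config.peak3_offset_nt
        x = np.arange(length, dtype=float)
        bump = config.peak3_amplitude * e * np.exp(
            -((x - center) ** 2) / (2.0 * config.peak3_width_nt**2)
        )

        post = np.zeros(length)
        if bool(truth.at[f.gene_id, "is_post_txn"]):
            mult = float(truth.at[f.gene_id, "post_txn_multiplier"])
            post[:] = mult * e
            for a, b in f.introns:  # mature RNA: exons only
                la, lb = sorted((f.genomic_to_local(a), f.genomic_to_local(b - 1)))
                post[la:lb + 1] = 0.0

        _add_local(exp[(f.chrom, f.strand)], f, eff * (co + bump + post))
    return exp


def expected_chip_ip(
    features: list[Feature],
    rnapii_expectation: ExpectationMap,
    truth: pd.DataFrame,
    config: SimConfig,
) -> ExpectationMap:
    """Expected ChIP IP coverage: RNAPII shifted 3' by ``chip_3prime_shift_nt``,
    scaled per gene by its ChIP efficiency. Deposited on the gene's strand
    (ChIP is unstranded; see docs)."""
    sizes = {c: len(v) for (c, s), v in rnapii_expectation.items()}
    exp: ExpectationMap = {(c, s): np.zeros(n) for c, n in sizes.items() for s in "+-"}
    s = config.chip_3prime_shift_nt
    for f in features:
        eff = float(truth.at[f.gene_id, "chip_efficiency"])
        pol_local = _extract_local(rnapii_expectation[(f.chrom, f.strand)], f)
        ip = np.zeros(f.length)
        if s < f.length:
            ip[s:] = pol_local[: f.length - s]
        _add_local(exp[(f.chrom, f.strand)], f, eff * ip)
    return exp


# ---------------------------------------------------------------------------
# track sampling
# ---------------------------------------------------------------------------

def sample_recovery(config: SimConfig, sample_id: str) -> float:
    """Global recovery/efficiency factor of one sample (log-normal, mean 1).

    The factor scales the whole library — both the genome track and the
    spike-in reads — which is exactly the between-sample variation spike
    normalization is meant to cancel.
    """
    if config.sample_recovery_log_sd <= 0:
        return 1.0
    rng = _rng(config.seed, f"recovery:{sample_id}")
    return float(rng.lognormal(-config.sample_recovery_log_sd**2 / 2,
                               config.sample_recovery_log_sd))


def simulate_spike_counts(
    config: SimConfig, sample_id: str, depth: int | None = None
) -> int:
    """Spike-genome read count for one sample.

    ``spike_reads ~ Binomial(depth, spike_read_fraction * recovery)`` where
    the recovery factor is the sample's global efficiency (see
    :func:`sample_recovery`). Deterministic in (seed, sample_id, depth).
    """
    rng = _rng(config.seed, f"spike:{sample_id}")
    depth = config.spike_depth if depth is None else depth
    p = min(1.0, config.spike_read_fraction * sample_recovery(config, sample_id))
    return int(rng.binomial(depth, p))


def _sample_track(
    expectation: ExpectationMap,
    config: SimConfig,
    sample_id: str,
    condition: str,
    genotype: str,
) -> CoverageTrack:
    rng = _rng(config.seed, f"track:{sample_id}")
    recovery = sample_recovery(config, sample_id)
    data = {k: rng.poisson(v * recovery).astype(float)
            for k, v in sorted(expectation.items())}
    spike = simulate_spike_counts(config, sample_id)
    total = int(sum(v.sum() for v in data.values())) + spike
    sizes = {c: len(v) for (c, s), v in expectation.items()}
    return CoverageTrack(
        sample_id=sample_id, chrom_sizes=sizes, data=data,
        condition=condition, genotype=genotype,
        total_mapped=total, spike_reads=spike,
    )


def simulate_rnapii_track(
    annotation: list[Feature], truth: pd.DataFrame, config: SimConfig,
    sample_id: str = "rnapii_wt",
) -> CoverageTrack:
    """Poisson-sampled RNAPII CRAC track."""
    return _sample_track(
        expected_rnapii(annotation, truth, config), config,
        sample_id, "RNAPII_CRAC", "WT",
    )


def _uniform_expectation(sizes: dict[str, int], rate: float) -> ExpectationMap:
    return {(c, s): np.full(n, rate) for c, n in sizes.items() for s in "+-"}


def simulate_set1_tracks(
    annotation: list[Feature],
    rnapii_expectation: ExpectationMap,
    truth: pd.DataFrame,
    config: SimConfig,
    genotype: str = "WT",
) -> tuple[CoverageTrack, CoverageTrack]:
    """Crosslinked and non-crosslinked tracks for one genotype.

    CL is Poisson around :func:`expected_set1_cl`; No-CL is uniform Poisson
    background at ``background_rate``.
    """
    tag = genotype.lower()
    cl = _sample_track(
        expected_set1_cl(annotation, rnapii_expectation, truth, config, genotype),
        config, f"set1_{tag}_cl", "CRAC_CL", genotype,
    )
    sizes = {c: len(v) for (c, s), v in rnapii_expectation.items()}
    nocl = _sample_track(
        _uniform_expectation(sizes, config.background_rate),
        config, f"set1_{tag}_nocl", "CRAC_NoCL", genotype,
    )
    return cl, nocl


def simulate_chip_tracks(
    annotation: list[Feature],
    rnapii_expectation: ExpectationMap,
    truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[CoverageTrack, CoverageTrack]:
    """ChIP IP and input tracks (input is uniform, split across strands)."""
    ip = _sample_track(
        expected_chip_ip(annotation, rnapii_expectation, truth, config),
        config, "chip_ip_wt", "ChIP_IP", "WT",
    )
    sizes = {c: len(v) for (c, s), v in rnapii_expectation.items()}
    inp = _sample_track(
        _uniform_expectation(sizes, config.chip_input_rate / 2.0),
        config, "chip_input_wt", "ChIP_input", "WT",
    )
    return ip, inp


# ---------------------------------------------------------------------------
# dataset assembly and writing
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    features: list[Feature]
    pa_table: PolyASiteTable
    truth: pd.DataFrame
    tracks: dict[str, CoverageTrack]
    chrom_sizes: dict[str, int]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate the full seven-sample dataset in memory."""
    features, pa_table, truth = simulate_annotation(config)
    pol_exp = expected_rnapii(features, truth, config)
    tracks: dict[str, CoverageTrack] = {}
    tracks["rnapii_wt"] = simulate_rnapii_track(features, truth, config)
    for genotype in ("WT", "YF_AA"):
        cl, nocl = simulate_set1_tracks(features, pol_exp, truth, config, genotype)
        tracks[cl.sample_id] = cl
        tracks[nocl.sample_id] = nocl
    ip, inp = simulate_chip_tracks(features, pol_exp, truth, config)
    tracks[ip.sample_id] = ip
    tracks[inp.sample_id] = inp
    return SimulatedDataset(
        config=config, features=features, pa_table=pa_table, truth=truth,
        tracks=tracks, chrom_sizes=chrom_sizes_of(features, truth),
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated dataset as the pipeline's on-disk input formats.

    Emits chrom.sizes, annotation.bed, pa_sites.tsv, truth.tsv, samples.tsv
    and one bedGraph pair per sample under ``tracks/``. Returns the paths.
    Sample-sheet track paths are relative to ``outdir``.
    """
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes(ds.chrom_sizes, paths["chrom_sizes"])
    paths["annotation"] = outdir / "annotation.bed"
    write_annotation_bed(ds.features, paths["annotation"])
    paths["pa_table"] = outdir / "pa_sites.tsv"
    write_pa_table(ds.pa_table, paths["pa_table"])
    paths["truth"] = outdir / "truth.tsv"
    ds.truth.reset_index().to_csv(
        paths["truth"], sep="\t", index=False, float_format="%.10g"
    )

    rows = []
    for sample_id, track in ds.tracks.items():
        rel_plus = f"tracks/{sample_id}.plus.bedgraph"
        rel_minus = f"tracks/{sample_id}.minus.bedgraph"
        write_bedgraph_pair(track, outdir / rel_plus, outdir / rel_minus)
        rows.append({
            "sample_id": sample_id,
            "condition": track.condition,
            "genotype": track.genotype,
            "total_mapped": track.total_mapped,
            "spike_reads": track.spike_reads,
            "path_plus": rel_plus,
            "path_minus": rel_minus,
        })
    paths["sample_sheet"] = outdir / "samples.tsv"
    pd.DataFrame(rows).to_csv(paths["sample_sheet"], sep="\t", index=False)
    return paths
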