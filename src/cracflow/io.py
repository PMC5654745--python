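"""Readers and writers for the standard text formats the pipeline touches.

Formats
-------
* annotation: BED6 (name field ``gene_id|class``; rows with class ``intron``
  and name ``gene_id|intron`` attach introns to ``gene_id``) or GFF3 (column 3
  is the feature class; ``ID=`` gives the gene id; ``intron`` rows attach via
  ``Parent=``). GFF3 1-based closed coordinates are converted to 0-based
  half-open on read.
* coverage: strand-specific 4-column bedGraph pairs
  (``*.plus.bedgraph`` / ``*.minus.bedgraph``), minus-strand values stored
  non-negative; chromosome lengths come from a UCSC-style ``chrom.sizes`` TSV.
* sample sheet: TSV with columns sample_id, condition, genotype, total_mapped,
  spike_reads, path_plus, path_minus.
* poly(A) table: TSV with columns gene_id, position, weight.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    CoverageTrack,
    CracflowError,
    Feature,
    FormatError,
    PolyASiteTable,
)

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "condition",
    "genotype",
    "total_mapped",
    "spike_reads",
    "path_plus",
    "path_minus",
)


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column UCSC-style chrom.sizes file."""
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}: line {i}: expected 'chrom<TAB>size'")
        try:
            sizes[parts[0]] = int(parts[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: non-integer size") from exc
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{c}\t{n}\n" for c, n in sizes.items())
    )


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _parse_bed6(path: Path) -> list[Feature]:
    raw: dict[str, dict] = {}
    introns: dict[str, list[tuple[int, int]]] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 6:
            raise FormatError(f"{path}: line {i}: BED6 needs 6 columns, got {len(parts)}")
        chrom, start_s, end_s, name, _score, strand = parts[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: non-integer coordinates") from exc
        if "|" not in name:
            raise FormatError(
                f"{path}: line {i}: BED name field must be 'gene_id|class', got {name!r}"
            )
        gene_id, fclass = name.rsplit("|", 1)
        if fclass == "intron":
            introns.setdefault(gene_id, []).append((start, end))
            continue
        if gene_id in raw:
            raise FormatError(f"{path}: line {i}: duplicate gene_id {gene_id!r}")
        raw[gene_id] = dict(
            gene_id=gene_id, chrom=chrom, start=start, end=end,
            strand=strand, feature_class=fclass, line=i,
        )
    return _assemble_features(raw, introns, path)


def _parse_gff3(path: Path) -> list[Feature]:
    raw: dict[str, dict] = {}
    introns: dict[str, list[tuple[int, int]]] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 9:
            raise FormatError(f"{path}: line {i}: GFF3 needs 9 columns, got {len(parts)}")
        chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = parts
        try:
            # GFF3 is 1-based closed; internal model is 0-based half-open.
            start, end = int(start_s) - 1, int(end_s)
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: non-integer coordinates") from exc
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
        )
        if ftype == "intron":
            parent = attr.get("Parent")
            if parent is None:
                raise FormatError(f"{path}: line {i}: intron without Parent attribute")
            introns.setdefault(parent, []).append((start, end))
            continue
        gene_id = attr.get("ID")
        if gene_id is None:
            raise FormatError(f"{path}: line {i}: feature without ID attribute")
        if gene_id in raw:
            raise FormatError(f"{path}: line {i}: duplicate gene_id {gene_id!r}")
        raw[gene_id] = dict(
            gene_id=gene_id, chrom=chrom, start=start, end=end,
            strand=strand, feature_class=ftype, line=i,
        )
    return _assemble_features(raw, introns, path)


def _assemble_features(
    raw: dict[str, dict], introns: dict[str, list], path: Path
) -> list[Feature]:
    for gene_id in introns:
        if gene_id not in raw:
            logger.warning("%s: introns for unknown gene %r ignored", path, gene_id)
    feats = []
    for gene_id, d in raw.items():
        line = d.pop("line")
        try:
            feats.append(Feature(**d, introns=tuple(introns.get(gene_id, ()))))
        except CracflowError as exc:
            raise FormatError(f"{path}: line {line}: {exc}") from exc
    return feats


def read_annotation(path: str | Path, fmt: str | None = None) -> list[Feature]:
    """Read a BED6 or GFF3 annotation into a list of :class:`Feature`.

    ``fmt`` is "bed6" or "gff3"; by default it is inferred from the file
    extension. An empty file yields an empty list with a logged warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed6"
    fmt = fmt.lower()
    if fmt not in {"bed6", "gff3"}:
        raise CracflowError(f"unknown annotation format {fmt!r}")
    feats = _parse_gff3(path) if fmt == "gff3" else _parse_bed6(path)
    if not feats:
        logger.warning("%s: annotation is empty", path)
    return feats


def write_annotation_bed(features: list[Feature], path: str | Path) -> None:
    """Write features (and their introns) as BED6 with 'gene|class' names."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.gene_id}|{f.feature_class}"
                f"\t0\t{f.strand}\n"
            )
            for a, b in f.introns:
                fh.write(f"{f.chrom}\t{a}\t{b}\t{f.gene_id}|intron\t0\t{f.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def _read_bedgraph_vectors(
    path: Path, chrom_sizes: dict[str, int]
) -> dict[str, np.ndarray]:
    vecs = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    starts: dict[str, list] = {c: [] for c in chrom_sizes}
    ends: dict[str, list] = {c: [] for c in chrom_sizes}
    vals: dict[str, list] = {c: [] for c in chrom_sizes}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}: line {i}: bedGraph needs 4 columns")
        chrom = parts[0]
        try:
            s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: malformed record") from exc
        if chrom not in chrom_sizes:
            raise FormatError(f"{path}: line {i}: unknown chromosome {chrom!r}")
        if not (0 <= s < e):
            raise FormatError(f"{path}: line {i}: bad interval [{s}, {e})")
        if e > chrom_sizes[chrom]:
            raise FormatError(
                f"{path}: line {i}: interval end {e} exceeds declared length "
                f"{chrom_sizes[chrom]} of {chrom!r}"
            )
        if v < 0:
            raise FormatError(f"{path}: line {i}: negative value {v}")
        starts[chrom].append(s)
        ends[chrom].append(e)
        vals[chrom].append(v)
    for chrom in chrom_sizes:
        if not starts[chrom]:
            continue
        s = np.asarray(starts[chrom], dtype=np.int64)
        e = np.asarray(ends[chrom], dtype=np.int64)
        v = np.asarray(vals[chrom])
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if np.any(s[1:] < e[:-1]):
            j = int(np.flatnonzero(s[1:] < e[:-1])[0])
            raise FormatError(
                f"{path}: overlapping intervals on {chrom!r} near position {int(s[j + 1])}"
            )
        lens = e - s
        # scatter run values into the dense vector without a Python loop
        offsets = np.repeat(s - np.concatenate(([0], np.cumsum(lens)[:-1])), lens)
        idx = offsets + np.arange(lens.sum())
        vecs[chrom][idx] = np.repeat(v, lens)
    return vecs


def read_bedgraph_pair(
    path_plus: str | Path,
    path_minus: str | Path,
    chrom_sizes: dict[str, int],
    *,
    sample_id: str = "sample",
    condition: str = "CRAC_CL",
    genotype: str = "WT",
    total_mapped: int = 0,
    spike_reads: int = 0,
) -> CoverageTrack:
    """Read a strand-specific bedGraph pair into a dense :class:`CoverageTrack`.

    Positions not covered by any record are zero. Sample metadata is supplied
    by the caller (normally from the sample sheet), not by the track files.
    """
    data: dict[tuple[str, str], np.ndarray] = {}
    for strand, p in (("+", Path(path_plus)), ("-", Path(path_minus))):
        for chrom, vec in _read_bedgraph_vectors(p, chrom_sizes).items():
            data[(chrom, strand)] = vec
    return CoverageTrack(
        sample_id=sample_id,
        chrom_sizes=dict(chrom_sizes),
        data=data,
        condition=condition,
        genotype=genotype,
        total_mapped=total_mapped,
        spike_reads=spike_reads,
    )


def _write_bedgraph_vector(fh, chrom: str, vec: np.ndarray, scale: float) -> None:
    if len(vec) == 0:
        return
    # run-length encode; zero runs omitted
    change = np.flatnonzero(np.diff(vec)) + 1
    bounds = np.concatenate(([0], change, [len(vec)]))
    for s, e in zip(bounds[:-1], bounds[1:]):
        v = vec[s]
        if v != 0:
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v * scale:.10g}\n")


def write_bedgraph_pair(
    track: CoverageTrack,
    path_plus: str | Path,
    path_minus: str | Path,
    scale: float = 1.0,
) -> None:
    """Write a track as a strand-specific bedGraph pair.

    Runs of equal value are merged into maximal intervals, values are
    multiplied by ``scale`` and zero runs are omitted.
    """
    if scale <= 0:
        raise CracflowError("scale must be > 0")
    for strand, path in (("+", path_plus), ("-", path_minus)):
        with open(path, "w") as fh:
            for chrom in track.chrom_sizes:
                key = (chrom, strand)
                if key in track.data:
                    _write_bedgraph_vector(fh, chrom, track.data[key], scale)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_pa_table(
    path: str | Path, annotation: list[Feature] | None = None
) -> PolyASiteTable:
    """Read a TSV of poly(A) sites (columns gene_id, position, weight).

    Gene ids absent from ``annotation`` (when given) are kept with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "position", "weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if (df["weight"] < 0).any():
        bad = df.loc[df["weight"] < 0].iloc[0]
        raise FormatError(
            f"{path}: negative weight {bad['weight']} for gene {bad['gene_id']!r}"
        )
    if annotation is not None:
        known = {f.gene_id for f in annotation}
        unknown = sorted(set(df["gene_id"]) - known)
        if unknown:
            logger.warning(
                "%s: %d gene_id(s) absent from annotation (kept): %s%s",
                path, len(unknown), ", ".join(unknown[:5]),
                "..." if len(unknown) > 5 else "",
            )
    sites: dict[str, list[tuple[int, float]]] = {}
    for gene_id, pos, w in zip(df["gene_id"], df["position"], df["weight"]):
        sites.setdefault(str(gene_id), []).append((int(pos), float(w)))
    return PolyASiteTable(sites=sites)


def write_pa_table(table: PolyASiteTable, path: str | Path) -> None:
    rows = [
        (g, p, w) for g, lst in table.sites.items() for p, w in lst
    ]
    pd.DataFrame(rows, columns=["gene_id", "position", "weight"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the sample sheet TSV; see :data:`SAMPLE_SHEET_COLUMNS`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: sample sheet missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    return df


def load_track(
    row: pd.Series, chrom_sizes: dict[str, int], base_dir: str | Path | None = None
) -> CoverageTrack:
    """Load one sample-sheet row into a :class:`CoverageTrack`.

    Relative track paths are resolved against ``base_dir`` (typically the
    directory containing the sample sheet).
    """
    def _resolve(p: str) -> Path:
        p = Path(p)
        if not p.is_absolute() and base_dir is not None:
            p = Path(base_dir) / p
        return p

    return read_bedgraph_pair(
        _resolve(row["path_plus"]),
        _resolve(row["path_minus"]),
        chrom_sizes,
        sample_id=str(row["sample_id"]),
        condition=str(row["condition"]),
        genotype=str(row["genotype"]),
        total_mapped=int(row["total_mapped"]),
        spike_reads=int(row["spike_reads"]),
    )
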