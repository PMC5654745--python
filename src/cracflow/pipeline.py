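"""End-to-end driver: simulate -> normalize -> quantify -> enrich -> wpas ->
metagene -> classify, with a reproducibility manifest.

All randomness flows from one root seed; rerunning an identical configuration
reproduces byte-identical outputs (TSV/JSON text, fixed float formats, no
timestamps). Each stage failure is re-raised as :class:`StageError` naming
the stage and the offending input.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import metagene as _metagene
from . import normalize as _normalize
from .io import load_track, read_annotation, read_chrom_sizes, read_pa_table, read_sample_sheet
from .model import CoverageTrack, CracflowError, Feature
from .simulate import SimConfig, simulate_dataset, write_dataset
from .wpas import compute_wpas

logger = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "quantify", "enrich", "wpas", "metagene", "classify")

_FLOAT_FMT = "%.8g"


class StageError(CracflowError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat run configuration; unknown keys are treated as simulator fields."""

    seed: int = 0
    outdir: str = "runs/out"
    simulate_input: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # paths, used when simulate_input is False (relative to the config file)
    annotation: str | None = None
    chrom_sizes: str | None = None
    sample_sheet: str | None = None
    pa_table: str | None = None
    # analysis parameters
    normalization: str = "spike"
    fold_threshold: float = 5.0
    pseudocount: float = 1.0
    min_denominator: float = 1.0
    tss_window: tuple[int, int] = (200, 1500)
    wpas_window: tuple[int, int] = (500, 300)
    bin_size: int = 10
    min_length: int = 1000
    peak3_window: int = 50
    left_quantile: float = 0.01
    n_boot: int = 1000

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        own = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        kwargs = {k: d.pop(k) for k in list(d) if k in own}
        sim_d = dict(d)  # every remaining key must be a simulator field
        sim_d.setdefault("seed", kwargs.get("seed", 0))
        kwargs["sim"] = SimConfig.from_dict(sim_d)
        for key in ("tss_window", "wpas_window"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls.from_dict(data)
        base = Path(path).parent
        for key in ("annotation", "chrom_sizes", "sample_sheet", "pa_table"):
            v = getattr(cfg, key)
            if v is not None and not Path(v).is_absolute():
                setattr(cfg, key, str(base / v))
        return cfg

    def manifest_params(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # run location must not affect the manifest bytes
        d["tss_window"] = list(self.tss_window)
        d["wpas_window"] = list(self.wpas_window)
        return d


@dataclass
class RunReport:
    outdir: Path
    manifest: dict
    summary: dict


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _find_sample(sheet: pd.DataFrame, condition: str, genotype: str) -> str | None:
    m = sheet[(sheet["condition"] == condition) & (sheet["genotype"] == genotype)]
    return None if m.empty else str(m["sample_id"].iloc[0])


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage, writing outputs and ``manifest.json`` under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_stages: list[dict] = []
    summary: dict = {}

    def record(stage: str, outputs: list[Path]) -> None:
        manifest_stages.append({
            "name": stage,
            "outputs": [str(p.relative_to(outdir)) for p in outputs],
            "sha256": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        })

    # -- stage 1: simulate (or point at user inputs) -------------------------
    stage = "simulate"
    try:
        if config.simulate_input:
            sim_cfg = config.sim.replace(seed=config.sim.seed)
            ds = simulate_dataset(sim_cfg)
            input_dir = outdir / "inputs"
            paths = write_dataset(ds, input_dir)
            annotation_path = paths["annotation"]
            sizes_path = paths["chrom_sizes"]
            sheet_path = paths["sample_sheet"]
            pa_path = paths["pa_table"]
            record(stage, sorted(input_dir.rglob("*.tsv"))
                   + [paths["annotation"], paths["chrom_sizes"]])
        else:
            for key in ("annotation", "chrom_sizes", "sample_sheet", "pa_table"):
                v = getattr(config, key)
                if v is None or not Path(v).exists():
                    raise CracflowError(f"missing input {key}: {v}")
            annotation_path = Path(config.annotation)
            sizes_path = Path(config.chrom_sizes)
            sheet_path = Path(config.sample_sheet)
            pa_path = Path(config.pa_table)
            record(stage, [])
    except CracflowError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- stage 2: normalize (scale factors) ----------------------------------
    stage = "normalize"
    try:
        features = read_annotation(annotation_path)
        chrom_sizes = read_chrom_sizes(sizes_path)
        sheet = read_sample_sheet(sheet_path)
        factors = _normalize.compute_scale_factors(sheet, config.normalization)
        sf = factors.factors.rename("scale_factor").to_frame()
        sf["method"] = factors.method
        out = outdir / "scale_factors.tsv"
        _write_tsv(sf, out)
        record(stage, [out])
    except CracflowError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- stage 3: quantify ----------------------------------------------------
    stage = "quantify"
    tracks: dict[str, CoverageTrack] = {}
    tables: dict[str, pd.DataFrame] = {}
    try:
        base_dir = sheet_path.parent
        for _, row in sheet.iterrows():
            try:
                track = load_track(row, chrom_sizes, base_dir)
            except (OSError, CracflowError) as exc:
                raise CracflowError(
                    f"cannot load track for sample {row['sample_id']!r} "
                    f"({row['path_plus']}, {row['path_minus']}): {exc}"
                ) from exc
            tracks[track.sample_id] = track
            mode = "both" if track.condition.startswith("ChIP") else "sense"
            tables[track.sample_id] = _normalize.quantify_features(
                track, features, mode=mode,
                scale_factor=factors.factor(track.sample_id),
            )
        long = pd.concat(tables.values()).reset_index()
        out = outdir / "signal_tables.tsv"
        _write_tsv(long, out, index=False)
        record(stage, [out])
    except CracflowError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- stage 4: enrich ------------------------------------------------------
    stage = "enrich"
    try:
        frames = []
        for genotype in sorted(sheet["genotype"].unique()):
            cl = _find_sample(sheet, "CRAC_CL", genotype)
            nocl = _find_sample(sheet, "CRAC_NoCL", genotype)
            if cl is None or nocl is None:
                continue
            enr = _normalize.call_high_confidence(
                tables[cl], tables[nocl],
                fold_threshold=config.fold_threshold,
                pseudocount=config.pseudocount,
            )
            enr.insert(0, "genotype", genotype)
            frames.append(enr)
        if not frames:
            raise CracflowError("no CL/No-CL sample pair found in the sheet")
        enrichment = pd.concat(frames)
        out = outdir / "enrichment.tsv"
        _write_tsv(enrichment, out)
        record(stage, [out])
        wt_enr = enrichment[enrichment["genotype"] == "WT"]
        summary["n_high_confidence_wt"] = int(wt_enr["high_confidence"].sum())
    except CracflowError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- stage 5: wpas --------------------------------------------------------
    stage = "wpas"
    try:
        pa = read_pa_table(pa_path, annotation=features)
        wpas_table = compute_wpas(pa)
        out = outdir / "wpas.tsv"
        _write_tsv(wpas_table, out)
        record(stage, [out])
    except CracflowError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- stage 6: metagene ----------------------------------------------------
    stage = "metagene"
    try:
        roles = {
            "set1_wt": _find_sample(sheet, "CRAC_CL", "WT"),
            "set1_yfaa": _find_sample(sheet, "CRAC_CL", "YF_AA"),
            "rnapii": _find_sample(sheet, "RNAPII_CRAC", "WT"),
        }
        outputs = []
        profiles_by_anchor: dict[str, dict[str, _metagene.MetageneProfile]] = {}
        for anchor, window in (("TSS", config.tss_window), ("wPAS", config.wpas_window)):
            profiles = {}
            for role, sample_id in roles.items():
                if sample_id is None:
                    continue
                track = tracks[sample_id].scaled(factors.factor(sample_id))
                profiles[role] = _metagene.metagene_profile(
                    track, features, anchor=anchor, window=window,
                    bin_size=config.bin_size, per_gene_norm="none",
                    min_length=config.min_length,
                    clip_to_gene=(anchor == "TSS"),
                    wpas=wpas_table, cohort=f"len>={config.min_length}",
                )
            if not profiles:
                raise CracflowError("no CRAC samples available for metagene profiles")
            profiles_by_anchor[anchor] = profiles
            wide = pd.DataFrame(
                {"bin_center": next(iter(profiles.values())).bin_centers}
            )
            for role, prof in profiles.items():
                wide[role] = prof.values
                wide[f"{role}_n_genes"] = prof.n_genes_per_bin
            if "set1_wt" in profiles and "rnapii" in profiles:
                wide["set1_rnapii_ratio"] = _metagene.profile_ratio(
                    profiles["set1_wt"], profiles["rnapii"]
                )
            out = outdir / f"metagene_{anchor.lower()}.tsv"
            _write_tsv(wide, out, index=False)
            outputs.append(out)
        wprofiles = profiles_by_anchor.get("wPAS", {})
        if "set1_wt" in wprofiles and "set1_yfaa" in wprofiles:
            eq = _metagene.peak3_equivalence(
                wprofiles["set1_wt"], wprofiles["set1_yfaa"],
                wpas_window=config.peak3_window, n_boot=config.n_boot,
                random_state=np.random.default_rng(config.seed),
            )
            peak3 = {
                "mut_wt_ratio": eq.ratio,
                "ci_low": eq.ci_low, "ci_high": eq.ci_high,
                "window_nt": eq.window_nt,
                "n_genes_wt": eq.n_genes_wt, "n_genes_mut": eq.n_genes_mut,
            }
            out = outdir / "peak3_equivalence.json"
            _write_json(peak3, out)
            outputs.append(out)
            summary["peak3_mut_wt_ratio"] = eq.ratio
        record(stage, outputs)
    except CracflowError as exc:
        raise StageError(stage, str(exc)) from exc

    # -- stage 7: classify ----------------------------------------------------
    stage = "classify"
    try:
        if roles["set1_wt"] is None or roles["rnapii"] is None:
            raise CracflowError("classification needs a WT CRAC_CL and an RNAPII sample")
        wt_hc = wt_enr[wt_enr["high_confidence"]].index
        num = tables[roles["set1_wt"]].loc[
            tables[roles["set1_wt"]].index.intersection(wt_hc)
        ]
        rt = _normalize.ratio_table(
            num, tables[roles["rnapii"]], min_denominator=config.min_denominator
        )
        dist = _classify.analyze_ratio_distribution(
            rt.ratios, left_quantile=config.left_quantile
        )
        labels = _classify.classify_tail(dist, annotation=features)
        out_labels = outdir / "classification.tsv"
        _write_tsv(labels, out_labels)
        corr = _classify.correlate_signals(
            tables[roles["set1_wt"]]["normalized_signal"],
            tables[roles["rnapii"]]["normalized_signal"],
        )
        class_summary = {
            "mode": dist.summary.mode,
            "median": dist.summary.median,
            "mean": dist.summary.mean,
            "core_fraction": dist.core_fraction,
            "tail_threshold": dist.tail_threshold,
            "n_genes": int(len(dist.ratios)),
            "n_tail": int(len(dist.tail_genes)),
            "n_excluded_denominator": rt.n_excluded_denominator,
            "n_excluded_numerator": rt.n_excluded_numerator,
            "set1_vs_rnapii_r2": corr.r2,
            "set1_vs_rnapii_p": corr.p_value,
        }
        if roles["set1_yfaa"] is not None:
            rt_yf = _normalize.ratio_table(
                tables[roles["set1_yfaa"]], tables[roles["rnapii"]],
                min_denominator=config.min_denominator,
            )
            shift = _classify.compare_distributions(
                rt.ratios, rt_yf.ratios, n_boot=config.n_boot,
                random_state=np.random.default_rng(config.seed + 1),
            )
            class_summary["yfaa_median_shift"] = shift.median_shift
            class_summary["yfaa_shift_ci"] = [shift.ci_low, shift.ci_high]
        out_summary = outdir / "classification_summary.json"
        _write_json(class_summary, out_summary)
        record(stage, [out_labels, out_summary])
        summary.update(class_summary)
    except CracflowError as exc:
        raise StageError(stage, str(exc)) from exc

    from . import __version__

    manifest = {
        "package": "cracflow",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.manifest_params(),
        "stages": manifest_stages,
    }
    _write_json(manifest, outdir / "manifest.json")
    logger.info("pipeline finished: %d stages, outputs in %s",
                len(manifest_stages), outdir)
    return RunReport(outdir=outdir, manifest=manifest, summary=summary)
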