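"""One-shot pipeline: configuration, validation, and the end-to-end run.

A single YAML config selects either a simulation block (the default:
generate the annotated toy genome and every signal track) or explicit
input paths, plus the analysis parameters. Unknown keys are rejected
before any computation. A run emits normalized tracks, the element-class
summary, metagene tables, the length-scan window tables with the
crossover estimate, transcription-stratified scans, the 3' mark-gain
table, Pol2 concordance fits, and a manifest recording version, seed and
config hash; every stage is logged with counts.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Gene, Track
from . import io_formats, synthetic, turnover, elements, metagene, windows, marks_pol2
from .synthetic import (
    WT, MUTANT, GenomeSpec, TurnoverModel, MarkModel, Pol2Model,
    generate_annotation, simulate_turnover, simulate_marks, simulate_pol2,
    expression_table,
)

log = logging.getLogger("h3turnover")


@dataclass(frozen=True)
class AnalysisParams:
    """Window sizes and thresholds; defaults follow the analysis design
    (500 bp end/TSS windows, 200 bp ARS window, 30-bin metagene,
    k = 80/50/20 gene windows)."""

    end_window_bp: int = 500
    tss_window_bp: int = 500
    ars_window_bp: int = 200
    length_k: int = 80
    strata_k: int = 80
    mark_k: int = 50
    expression_k: int = 20
    # None -> persist for a full window of genes (m = length_k); sliding
    # windows are strongly autocorrelated, so shorter runs misfire on noise
    m_consecutive: Optional[int] = None
    delta_threshold: Optional[float] = None
    length_breaks: tuple = (1000, 2000)


@dataclass(frozen=True)
class InputPaths:
    """Precomputed inputs (used instead of simulation when given)."""

    genes_bed: str = ""
    ars_bed: str = ""
    turnover_wt: tuple = ()
    turnover_mutant: tuple = ()
    scale: str = "log2"


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    turnover_model: TurnoverModel = field(default_factory=TurnoverModel)
    mark_model: MarkModel = field(default_factory=MarkModel)
    pol2_model: Pol2Model = field(default_factory=Pol2Model)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    inputs: Optional[InputPaths] = None


class ConfigError(ValueError):
    pass


def _build(cls, mapping: Mapping[str, Any], context: str):
    if mapping is None:
        mapping = {}
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


_SECTIONS = {
    "genome": GenomeSpec,
    "turnover_model": TurnoverModel,
    "mark_model": MarkModel,
    "pol2_model": Pol2Model,
    "analysis": AnalysisParams,
    "inputs": InputPaths,
}


def config_from_mapping(raw: Mapping[str, Any]) -> PipelineConfig:
    raw = dict(raw or {})
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"config: unknown keys {sorted(unknown)}")
    kwargs: Dict[str, Any] = {"seed": int(raw.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        if name == "inputs":
            kwargs[name] = _build(cls, raw[name], name) if name in raw else None
        else:
            kwargs[name] = _build(cls, raw.get(name, {}), name)
    return PipelineConfig(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_mapping(raw or {})


def config_hash(config: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    canonical = json.dumps(enc(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _averaged_turnover(genes, probes, model, genotype, seed) -> Track:
    reps = simulate_turnover(genes, probes, model, genotype, _derive_seed(seed, f"turnover-{genotype}"))
    normalized = [turnover.normalize_track(t) for t in reps]
    # re-center after averaging so the emitted track keeps a zero median
    return turnover.normalize_track(turnover.average_replicates(normalized))


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage and write the result tables under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stages = []

    def stage(name, **counts):
        log.info("stage %s: %s", name, counts)
        stages.append({"stage": name, **counts})

    try:
        params = config.analysis
        simulated = config.inputs is None or not config.inputs.genes_bed
        if simulated:
            genes, ars, probes = generate_annotation(
                config.genome, _derive_seed(config.seed, "annotation")
            )
            io_formats.write_intervals(genes, out / "genes.bed")
            io_formats.write_intervals(ars, out / "ars.bed")
            stage("annotation", n_genes=len(genes), n_ars=len(ars), n_probes=len(probes))
            tracks = {
                g: _averaged_turnover(genes, probes, config.turnover_model, g, config.seed)
                for g in (WT, MUTANT)
            }
            marks = {
                g: simulate_marks(
                    genes, probes, config.mark_model, g, _derive_seed(config.seed, f"marks-{g}")
                )
                for g in (WT, MUTANT)
            }
            pol2_wt, pol2_mut = simulate_pol2(
                genes, probes, config.pol2_model, _derive_seed(config.seed, "pol2")
            )
            expression = expression_table(genes, pol2_wt, _derive_seed(config.seed, "expression"))
        else:
            genes = io_formats.read_intervals(config.inputs.genes_bed)
            ars = (
                io_formats.read_intervals(config.inputs.ars_bed, as_genes=False)
                if config.inputs.ars_bed
                else []
            )
            stage("annotation", n_genes=len(genes), n_ars=len(ars))
            tracks = {}
            for g, paths in ((WT, config.inputs.turnover_wt), (MUTANT, config.inputs.turnover_mutant)):
                if not paths:
                    raise ConfigError(f"inputs: no turnover tracks for genotype {g!r}")
                reps = [
                    io_formats.read_signal(p, channel="turnover", genotype=g, replicate=i + 1)
                    for i, p in enumerate(paths)
                ]
                normalized = [turnover.normalize_track(t) for t in reps]
                tracks[g] = turnover.average_replicates(normalized)
            probes = [
                synthetic.Interval(r.chrom, int(r.start), int(r.end))
                for r in tracks[WT].data.itertuples(index=False)
            ]
            marks = None
            pol2_wt = pol2_mut = None
            expression = None

        for g, t in tracks.items():
            io_formats.write_signal(t, out / f"turnover_{g}.bedgraph")
        stage("normalize", n_probes=len(tracks[WT].data))

        classes = elements.classify_probes(
            probes, genes, ars,
            end_window=params.end_window_bp,
            tss_window=params.tss_window_bp,
            ars_window=params.ars_window_bp,
        )
        for g, t in tracks.items():
            io_formats.write_table(
                elements.class_summary(classes, t, probes), out / f"class_summary_{g}.tsv"
            )
        stage("classify", n_probes=len(classes))

        for g, t in tracks.items():
            profile = metagene.aggregate_metagene(t, genes)
            io_formats.write_table(profile.to_frame(), out / f"metagene_turnover_{g}.tsv")
        if marks is not None:
            for g, (k4, k36) in marks.items():
                for name, t in (("k4me3", k4), ("k36me3", k36)):
                    profile = metagene.aggregate_metagene(t, genes)
                    io_formats.write_table(profile.to_frame(), out / f"metagene_{name}_{g}.tsv")
        stage("metagene", n_genes=len(genes))

        end_stats = {
            end: {
                g: windows.end_table(t, genes, end, params.end_window_bp)
                for g, t in tracks.items()
            }
            for end in (windows.FIVE_PRIME, windows.THREE_PRIME)
        }
        crossover = {}
        for end, stats in end_stats.items():
            series = windows.window_scan(stats, k=params.length_k)
            io_formats.write_table(series.frame, out / f"lengthscan_{end}.tsv")
            est = windows.estimate_crossover(
                series.column(f"mean_{WT}"),
                series.column(f"mean_{MUTANT}"),
                delta_threshold=params.delta_threshold,
                m_consecutive=params.m_consecutive or params.length_k,
            )
            crossover[end] = est
        io_formats.write_table(
            pd.DataFrame(
                {"end": list(crossover), "crossover_length_bp": [crossover[e] for e in crossover]}
            ),
            out / "crossover.tsv",
        )
        stage("lengthscan", windows_per_series=series.n_windows, **{
            f"crossover_{e}": (v if v is not None else "none") for e, v in crossover.items()
        })

        if pol2_wt is not None:
            summaries = marks_pol2.pol2_summaries(pol2_wt, pol2_mut, genes, params.end_window_bp)
            io_formats.write_table(summaries, out / "pol2_summaries.tsv")
            fits = []
            for fld in ("mean", "five_prime_bias"):
                slope, intercept, r = marks_pol2.concordance_slope(summaries, fld)
                fits.append({"field": fld, "slope": slope, "intercept": intercept, "r": r})
            io_formats.write_table(pd.DataFrame(fits), out / "pol2_concordance.tsv")
            stage("pol2bias", n_genes=len(summaries))

            covariate = summaries.set_index("id")["mean_wt"]
            strata = windows.stratified_scan(
                end_stats[windows.THREE_PRIME][WT],
                end_stats[windows.THREE_PRIME][MUTANT],
                covariate,
                k=min(params.strata_k, max(2, len(covariate) // 3)),
            )
            stacked = pd.concat(
                [s.frame.assign(tertile=name) for name, s in strata.items()],
                ignore_index=True,
            )
            io_formats.write_table(stacked, out / "stratified_three_prime.tsv")
            stage("stratified", n_strata=len(strata))

        if marks is not None:
            gain = marks_pol2.three_prime_gain(
                marks[WT][1], marks[MUTANT][1], genes,
                window_bp=params.end_window_bp, length_breaks=params.length_breaks,
            )
            io_formats.write_table(gain, out / "k36_three_prime_gain.tsv")
            k36_3p = windows.end_table(marks[WT][1], genes, windows.THREE_PRIME, 1000)
            smooth = windows.moving_average_vs(
                k36_3p["length"], k36_3p["value"], k=params.mark_k, ids=k36_3p["id"]
            )
            io_formats.write_table(smooth, out / "k36_three_prime_vs_length.tsv")
            stage("modscan", n_classes=len(gain))

        if expression is not None:
            smooth = windows.moving_average_vs(
                expression["length"], expression["expression_log2fc"],
                k=params.expression_k, ids=expression["id"],
            )
            io_formats.write_table(smooth, out / "expression_vs_length.tsv")
            stage("expression", n_genes=len(expression))

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_sha256": config_hash(config),
            "stages": stages,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
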