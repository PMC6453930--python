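"""Pipeline configuration and the end-to-end driver.

A :class:`PipelineConfig` round-trips losslessly through YAML, rejects
unknown keys, and toggles the stages simulate -> align -> call -> windows ->
dmr. :func:`run_pipeline` executes the toggled stages into an artifact
directory and writes a manifest (package version, full parameter set, seed,
input checksums) so a rerun reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import mossmeth
from mossmeth import io as mio
from mossmeth.simulate import (
    SimConfig,
    GenotypeEffect,
    simulate_genome,
    simulate_methylome,
    simulate_bisulfite_reads,
)
from mossmeth.align import ConvertedIndex, align, pileup
from mossmeth.calls import call_single_c, context_table, genome_average, NoDataError
from mossmeth.windows import window_methylation, call_dmrs

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "align", "call", "windows", "dmr")


class ConfigError(ValueError):
    pass


def _check_keys(section: str, given: dict, allowed: set[str]):
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {section}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "mossmeth_out"
    log_level: str = "INFO"
    stages: dict = field(
        default_factory=lambda: {name: True for name in _STAGES}
    )
    sim: dict = field(default_factory=dict)
    base_levels: dict = field(default_factory=lambda: {"CG": 0.8, "CHG": 0.7,
                                                       "CHH": 0.2})
    genotypes: list = field(default_factory=lambda: [{"name": "wt"}])
    align: dict = field(default_factory=lambda: {"k": 20, "max_mismatches": 2})
    windows: dict = field(default_factory=lambda: {"window_size": 50})
    dmr: dict = field(
        default_factory=lambda: {"context": "CHH", "min_fraction": 0.1,
                                 "min_informative": 10, "alpha": 0.05}
    )
    inputs: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        _check_keys("config", data, {f.name for f in dataclasses.fields(cls)})
        cfg = cls(**data)
        _check_keys("stages", cfg.stages, set(_STAGES))
        sim_allowed = {f.name for f in dataclasses.fields(SimConfig)}
        _check_keys("sim", cfg.sim, sim_allowed)
        _check_keys("align", cfg.align, {"k", "max_mismatches"})
        _check_keys("windows", cfg.windows, {"window_size"})
        _check_keys("dmr", cfg.dmr,
                    {"context", "min_fraction", "min_informative", "alpha"})
        _check_keys("inputs", cfg.inputs, {"genome", "reads", "pileup"})
        geno_allowed = {f.name for f in dataclasses.fields(GenotypeEffect)}
        for g in cfg.genotypes:
            _check_keys(f"genotype {g.get('name', '?')}", g, geno_allowed)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the toggled stages and return the artifact directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {name: config.stages.get(name, True) for name in _STAGES}
    sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
    genotypes = [dict(g) for g in config.genotypes]
    names = [g.get("name", f"g{i}") for i, g in enumerate(genotypes)]
    summary: dict = {"genome_averages": {}, "dmrs": {}}
    manifest: dict = {
        "package": "mossmeth",
        "version": mossmeth.__version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "inputs": {},
        "outputs": {},
    }

    try:
        stage = "simulate"
        if stages["simulate"]:
            genome, annotations, tracks = simulate_genome(sim_cfg)
            mio.write_fasta(genome, out / "genome.fa")
            mio.write_gff3(annotations, out / "annotations.gff3")
            for feature in tracks.features:
                mio.write_bedgraph(tracks, feature, out / f"track_{feature}.bedgraph")
            ctx = context_table(genome)
            wt_model = simulate_methylome(
                genome, annotations, tracks, base_levels=config.base_levels, ctx=ctx
            )
            readsets = {}
            for i, g in enumerate(genotypes):
                effect = GenotypeEffect(**g)
                model = (
                    wt_model
                    if effect == GenotypeEffect(name=effect.name)
                    else simulate_methylome(
                        genome, annotations, tracks, effect=effect,
                        base_levels=config.base_levels, ctx=ctx,
                    )
                )
                rs = simulate_bisulfite_reads(
                    genome, model, sim_cfg, seed=config.seed + 1000 * (i + 1)
                )
                mio.write_fastq(rs, out / f"reads_{effect.name}.fastq")
                mio.write_truth_sidecar(rs, out / f"truth_{effect.name}.tsv")
                readsets[effect.name] = rs
                logger.info("simulate: %s -> %d reads", effect.name, len(rs))
        else:
            genome = mio.read_fasta(config.inputs["genome"])
            ctx = context_table(genome)
            readsets = {
                name: None for name in names
            }

        stage = "align"
        pileups = {}
        if stages["align"]:
            index = ConvertedIndex(genome, k=int(config.align.get("k", 20)))
            for name in names:
                rs = readsets[name]
                reads = (
                    list(rs)
                    if rs is not None
                    else mio.read_fastq(config.inputs["reads"][name])
                )
                alns, stats_ = align(
                    reads, index,
                    max_mismatches=int(config.align.get("max_mismatches", 2)),
                )
                pile = pileup(alns, dict(reads), genome)
                mio.write_pileup(pile, out / f"pileup_{name}.tsv")
                pileups[name] = pile
                logger.info(
                    "align: %s usable=%d multimapped=%d unaligned=%d",
                    name, stats_.n_usable, stats_.n_multimapped, stats_.n_unaligned,
                )
        else:
            for name in names:
                pileups[name] = mio.read_pileup(config.inputs["pileup"][name])

        stage = "call"
        callsets = {}
        if stages["call"]:
            for name in names:
                calls = call_single_c(pileups[name], genome, ctx=ctx)
                mio.write_single_c(calls, out / f"singlec_{name}.tsv")
                callsets[name] = calls
                averages = {}
                for context in ("CG", "CHG", "CHH"):
                    try:
                        averages[context] = genome_average(calls, context)
                    except NoDataError:
                        averages[context] = None
                summary["genome_averages"][name] = averages
                logger.info("call: %s -> %d cytosines", name, len(calls))

        stage = "windows"
        wtabs = {}
        if stages["windows"] and callsets:
            wsize = int(config.windows.get("window_size", 50))
            dmr_ctx = config.dmr.get("context", "CHH")
            for name in names:
                wtabs[name] = window_methylation(callsets[name], wsize, dmr_ctx)
                mio.write_w50(wtabs[name], out / f"w50_{dmr_ctx}_{name}.tsv")
                logger.info("windows: %s -> %d windows", name, len(wtabs[name]))

        stage = "dmr"
        if stages["dmr"] and len(wtabs) >= 2:
            ref = names[0]
            for name in names[1:]:
                result = call_dmrs(
                    wtabs[ref], wtabs[name],
                    min_fraction=float(config.dmr.get("min_fraction", 0.1)),
                    min_informative=int(config.dmr.get("min_informative", 10)),
                    alpha=float(config.dmr.get("alpha", 0.05)),
                )
                mio.write_dmr_bed(
                    result.records, out / f"dmrs_{ref}_vs_{name}.bed",
                    window_size=int(config.windows.get("window_size", 50)),
                )
                summary["dmrs"][name] = {
                    "tested": len(result.tested),
                    "dmrs": len(result.records),
                    "hypo": result.n_hypo,
                    "hyper": result.n_hyper,
                }
                logger.info(
                    "dmr: %s vs %s -> %d DMRs (%d hypo / %d hyper)",
                    ref, name, len(result.records), result.n_hypo, result.n_hyper,
                )
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    for section, paths in config.inputs.items():
        if isinstance(paths, dict):
            manifest["inputs"][section] = {
                k: _sha256(Path(p)) for k, p in paths.items()
            }
        else:
            manifest["inputs"][section] = _sha256(Path(paths))
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
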