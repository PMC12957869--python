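"""Umbrella pipeline: (simulate) -> decode -> quantify -> narrow.

``PipelineConfig`` is a plain dataclass loadable from YAML; each stage
logs its inputs and output sizes, writes its artifacts under the output
directory, and any failure propagates as an exception carrying stage
context.  Reruns with identical config and seed produce byte-identical
artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import io
from .codes import BarcodePool
from .enrich import NarrowingParams, narrow_pool
from .errors import BcscreenError
from .quantify import normalized_accumulation, summarize_by_group
from .readproc import ReadLayout, count_reads
from .simulate import ErrorModel, SampleSpec, ScreenScenario, simulate_screen

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    pool: Optional[str] = None
    samples: Optional[str] = None
    fastq_dir: Optional[str] = None
    outdir: str = "bcscreen_out"
    clamp: str = ""
    barcode_length: int = 12
    umi_length: int = 12
    max_clamp_edits: int = 1
    barcode_slack: int = 3
    umi_method: str = "directional"
    fold_window: tuple = (0.8, 1.2)
    alpha: float = 0.05
    require_significance: bool = False
    scope: str = "pooled"
    simulate: Optional[dict] = None  # scenario spec; replaces fastq_dir
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise BcscreenError(f"unknown config key(s): {sorted(unknown)}")
        if "fold_window" in raw:
            raw["fold_window"] = tuple(raw["fold_window"])
        return cls(**raw)

    def layout(self) -> ReadLayout:
        return ReadLayout(
            clamp=self.clamp,
            barcode_length=self.barcode_length,
            umi_length=self.umi_length,
            max_clamp_edits=self.max_clamp_edits,
            barcode_slack=self.barcode_slack,
        )


def scenario_from_config(config: PipelineConfig, pool: BarcodePool) -> ScreenScenario:
    spec = config.simulate or {}
    samples = [
        SampleSpec(
            sample_id=s["sample_id"],
            group=s["group"],
            is_input_pool=bool(s.get("is_input_pool", False)),
            depth=int(s.get("depth", 10000)),
        )
        for s in spec.get("samples", [])
    ]
    effects = {
        (e["group"], int(e["barcode_id"])): float(e["fold"])
        for e in spec.get("effects", [])
    }
    em = spec.get("error_model", {})
    layout = config.layout()
    if spec.get("fixed_prefix"):
        layout = ReadLayout(
            clamp=layout.clamp,
            barcode_length=layout.barcode_length,
            umi_length=layout.umi_length,
            max_clamp_edits=layout.max_clamp_edits,
            barcode_slack=layout.barcode_slack,
            fixed_prefix=spec["fixed_prefix"],
        )
    return ScreenScenario(
        pool=pool,
        layout=layout,
        samples=samples,
        enrichment_effects=effects,
        pcr_duplication=float(spec.get("pcr_duplication", 1.0)),
        error_model=ErrorModel(
            substitution_rate=float(em.get("substitution_rate", 0.0)),
            insertion_rate=float(em.get("insertion_rate", 0.0)),
            deletion_rate=float(em.get("deletion_rate", 0.0)),
        ),
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    if config.pool is None:
        raise BcscreenError("config must reference a pool file")
    pool = io.read_pool(config.pool)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage=load_pool n=%d d_min=%d", len(pool), pool.d_min)

    if config.simulate is not None:
        scenario = scenario_from_config(config, pool)
        simdir = outdir / "simdata"
        screen = simulate_screen(scenario, outdir=simdir)
        logger.info("stage=simulate samples=%d", len(screen.reads))
        samples = screen.sample_sheet
        fastq_dir = simdir
    else:
        if config.samples is None or config.fastq_dir is None:
            raise BcscreenError(
                "config must give samples + fastq_dir, or a simulate block"
            )
        samples = io.read_sample_sheet(config.samples)
        fastq_dir = Path(config.fastq_dir)
        if not fastq_dir.is_dir():
            raise BcscreenError(f"fastq directory not found: {fastq_dir}")

    layout = config.layout()
    counts_dir = outdir / "counts"
    for sid in samples["sample_id"]:
        fq = fastq_dir / f"{sid}.fastq"
        if not fq.exists():
            fq = fastq_dir / f"{sid}.fastq.gz"
        if not fq.exists():
            raise BcscreenError(f"missing FASTQ for sample {sid} in {fastq_dir}")
        bc = count_reads(fq, pool, layout, sample_id=sid,
                         umi_method=config.umi_method)
        io.write_counts(bc, counts_dir, pool)
        logger.info("stage=decode sample=%s reads=%d assigned=%d",
                    sid, bc.n_reads, bc.qc["assigned"])

    matrix = io.read_counts_dir(counts_dir, samples)
    table = normalized_accumulation(matrix)
    io.write_accumulation(table, outdir / "accumulation.tsv")
    summarize_by_group(table).to_csv(
        outdir / "group_summary.tsv", sep="\t", index=False, float_format="%.6g"
    )
    logger.info("stage=quantify barcodes=%d flagged=%d",
                table.values.shape[0], len(table.flagged))

    params = NarrowingParams(
        fold_window=tuple(config.fold_window),
        alpha=config.alpha,
        scope=config.scope,
        require_significance=config.require_significance,
    )
    results, kept = narrow_pool(table, params, pool=pool)
    io.write_narrowing_report(results, outdir / "narrowing_report.tsv")
    io.write_pool(kept, outdir / "kept_pool.tsv")
    logger.info("stage=narrow kept=%d excluded=%d",
                len(kept), len(results) - len(kept))
    return outdir
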