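"""Synthetic screen simulator with known ground truth.

Emulates a pooled barcode screen: molecules are drawn multinomially from
a per-sample barcode abundance vector (optionally perturbed by planted
enrichment/depletion folds in non-input samples), each molecule receives
a random UMI at reverse transcription, PCR replicates each molecule a
geometric number of times, and reads — fixed_prefix + barcode + clamp +
UMI — are corrupted by independent per-base substitution/insertion/
deletion errors.  Everything is reproducible from the scenario seed; the
per-sample RNG is derived from (seed, sample index), so a sample's reads
do not depend on which other samples are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .codes import BarcodePool
from .errors import BcscreenError
from .readproc import ReadLayout

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base sequencing-error rates."""

    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    quality_char: str = "I"

    def __post_init__(self):
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r < 1:
                raise BcscreenError("error rates must lie in [0, 1)")

    @property
    def is_null(self) -> bool:
        return (
            self.substitution_rate == 0
            and self.insertion_rate == 0
            and self.deletion_rate == 0
        )


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    group: str
    is_input_pool: bool
    depth: int  # molecules sampled (reads when pcr_duplication == 1)
    true_abundance: Optional[Sequence[float]] = None


@dataclass
class ScreenScenario:
    """Complete specification of a simulated screen."""

    pool: BarcodePool
    layout: ReadLayout
    samples: List[SampleSpec]
    enrichment_effects: Mapping[Tuple[str, int], float] = field(default_factory=dict)
    pcr_duplication: float = 1.0
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def __post_init__(self):
        if not self.samples:
            raise BcscreenError("scenario needs at least one sample")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise BcscreenError("duplicate sample ids in scenario")
        if self.pcr_duplication < 1:
            raise BcscreenError("pcr_duplication must be >= 1")
        for s in self.samples:
            if s.depth < 1:
                raise BcscreenError(f"sample {s.sample_id}: depth must be >= 1")
            if s.true_abundance is not None:
                a = np.asarray(s.true_abundance, dtype=float)
                if a.size != len(self.pool) or a.min() < 0 or not np.isclose(a.sum(), 1):
                    raise BcscreenError(
                        f"sample {s.sample_id}: abundance must be a probability "
                        f"vector over {len(self.pool)} barcodes"
                    )
        for (group, bid), fold in self.enrichment_effects.items():
            if fold <= 0:
                raise BcscreenError(f"effect fold for {(group, bid)} must be > 0")
            if bid not in self.pool.ids:
                raise BcscreenError(f"effect references unknown barcode {bid}")

    def sample_sheet(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "is_input_pool": [int(s.is_input_pool) for s in self.samples],
                "replicate": list(range(1, len(self.samples) + 1)),
            }
        )

    def effective_abundance(self, spec: SampleSpec) -> np.ndarray:
        """Effect-adjusted, renormalized abundance for one sample."""
        base = (
            np.full(len(self.pool), 1.0 / len(self.pool))
            if spec.true_abundance is None
            else np.asarray(spec.true_abundance, dtype=float)
        )
        if spec.is_input_pool or not self.enrichment_effects:
            return base / base.sum()
        adj = base.copy()
        for idx, bid in enumerate(self.pool.ids):
            fold = self.enrichment_effects.get((spec.group, bid))
            if fold is not None:
                adj[idx] *= fold
        return adj / adj.sum()


def _rng_for(scenario: ScreenScenario, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=(sample_index,))
    )


def _corrupt(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = []
    for b in arr:
        if model.deletion_rate and rng.random() < model.deletion_rate:
            continue
        if model.insertion_rate and rng.random() < model.insertion_rate:
            out.append(_BASES[rng.integers(4)])
        if model.substitution_rate and rng.random() < model.substitution_rate:
            cur = b
            while cur == b:
                cur = _BASES[rng.integers(4)]
            out.append(cur)
        else:
            out.append(b)
    return bytes(out).decode("ascii")


def _random_umis(n: int, length: int, rng: np.random.Generator) -> List[str]:
    codes = rng.integers(0, 4, size=(n, length))
    return [_BASES[row].tobytes().decode("ascii") for row in codes]


def simulate_reads(
    scenario: ScreenScenario, sample_id: str
) -> Tuple[List[Tuple[str, str, str]], pd.DataFrame]:
    """Simulate one sample; returns (FASTQ records, ground-truth table).

    Records are (name, sequence, quality) tuples; the truth table has one
    row per barcode with molecule and read counts.
    """
    index = next(
        (i for i, s in enumerate(scenario.samples) if s.sample_id == sample_id),
        None,
    )
    if index is None:
        raise BcscreenError(f"unknown sample {sample_id!r}")
    spec = scenario.samples[index]
    rng = _rng_for(scenario, index)
    probs = scenario.effective_abundance(spec)
    mol_counts = rng.multinomial(spec.depth, probs)
    layout = scenario.layout
    prefix = layout.fixed_prefix or ""
    model = scenario.error_model
    records: List[Tuple[str, str, str]] = []
    read_counts = np.zeros(len(scenario.pool), dtype=np.int64)
    for idx, barcode in enumerate(scenario.pool):
        n_mol = int(mol_counts[idx])
        if n_mol == 0:
            continue
        umis = _random_umis(n_mol, layout.umi_length, rng)
        if scenario.pcr_duplication > 1:
            dups = rng.geometric(1.0 / scenario.pcr_duplication, size=n_mol)
        else:
            dups = np.ones(n_mol, dtype=np.int64)
        template = prefix + barcode.sequence + layout.clamp
        for m in range(n_mol):
            base_read = template + umis[m]
            for d in range(int(dups[m])):
                read = base_read if model.is_null else _corrupt(base_read, model, rng)
                name = f"{sample_id}:bc{barcode.id}:m{m}:d{d}"
                records.append((name, read, model.quality_char * len(read)))
        read_counts[idx] = dups.sum()
    truth = pd.DataFrame(
        {
            "sample_id": sample_id,
            "barcode_id": list(scenario.pool.ids),
            "molecules": mol_counts.astype(int),
            "reads": read_counts,
        }
    )
    return records, truth


@dataclass
class SimulatedScreen:
    scenario: ScreenScenario
    reads: Dict[str, List[Tuple[str, str, str]]]
    truth: pd.DataFrame
    sample_sheet: pd.DataFrame
    fastq_paths: Dict[str, Path] = field(default_factory=dict)


def simulate_screen(
    scenario: ScreenScenario, outdir: Optional[Path] = None
) -> SimulatedScreen:
    """Simulate every sample; optionally write FASTQ + TSV artifacts.

    Enrichment effects apply only to non-input samples.  With an
    ``outdir``, writes <sample_id>.fastq, sample_sheet.tsv and
    ground_truth.tsv.
    """
    if not any(s.is_input_pool for s in scenario.samples):
        raise BcscreenError("scenario needs at least one input-pool sample")
    reads = {}
    truths = []
    for spec in scenario.samples:
        recs, truth = simulate_reads(scenario, spec.sample_id)
        reads[spec.sample_id] = recs
        truths.append(truth)
    screen = SimulatedScreen(
        scenario=scenario,
        reads=reads,
        truth=pd.concat(truths, ignore_index=True),
        sample_sheet=scenario.sample_sheet(),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid, recs in reads.items():
            path = outdir / f"{sid}.fastq"
            with open(path, "w") as fh:
                for name, seq, qual in recs:
                    fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            screen.fastq_paths[sid] = path
        screen.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
        screen.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return screen
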