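"""Readers and writers for pool, sample-sheet, counts and report files.

All tabular artifacts are TSV (UTF-8, LF, newline-terminated) written
with deterministic ordering so reruns are byte-identical.  Pools round-
trip losslessly through FASTA (record id ``bc<rank>``) or TSV (columns
id, sequence[, mean_pairwise_distance]); the pool's minimum pairwise
distance is recomputed on load and checked against any declared value.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codes import (
    BarcodePool,
    mean_pairwise_distance,
    pool_min_distance,
    validate_dna,
)
from .errors import (
    BcscreenError,
    InvalidAlphabetError,
    PoolIntegrityError,
    SampleSheetError,
)
from .quantify import SAMPLE_COLUMNS, AccumulationTable, CountMatrix

_FASTA_EXT = {".fa", ".fasta", ".fna"}


def _parse_id(name: str, fallback: int) -> int:
    if name.startswith("bc"):
        try:
            return int(name[2:])
        except ValueError:
            pass
    return fallback


def read_pool(path, d_min: Optional[int] = None) -> BarcodePool:
    """Load a barcode pool from FASTA or TSV.

    The minimum pairwise distance is recomputed; if a declared
    ``d_min`` (argument, or TSV ``# d_min=`` header comment) exceeds
    the recomputed value, loading fails with an integrity error.
    """
    path = Path(path)
    declared = d_min
    ids: List[int] = []
    seqs: List[str] = []
    if path.suffix.lower() in _FASTA_EXT:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            try:
                seqs.append(validate_dna(str(rec.seq)))
            except InvalidAlphabetError as exc:
                raise PoolIntegrityError(
                    f"{path}: record {rec.id!r}: {exc}"
                ) from exc
            ids.append(_parse_id(rec.id, i))
    else:
        with open(path) as fh:
            header: Optional[List[str]] = None
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("d_min=") and declared is None:
                            declared = int(tok.split("=", 1)[1])
                    continue
                parts = line.split("\t")
                if header is None:
                    header = parts
                    if "sequence" not in header or "id" not in header:
                        raise PoolIntegrityError(
                            f"{path}:{lineno}: TSV pool needs 'id' and "
                            f"'sequence' columns"
                        )
                    continue
                row = dict(zip(header, parts))
                try:
                    seqs.append(validate_dna(row["sequence"]))
                except InvalidAlphabetError as exc:
                    raise PoolIntegrityError(f"{path}:{lineno}: {exc}") from exc
                ids.append(_parse_id(row["id"], len(ids) + 1))
    if not seqs:
        raise PoolIntegrityError(f"{path}: no barcodes found")
    pool = BarcodePool.from_sequences(seqs, d_min=declared or 0, ids=ids)
    if len(pool) >= 2:
        actual = pool_min_distance(pool)
        if declared is not None and actual < declared:
            raise PoolIntegrityError(
                f"{path}: recomputed minimum distance {actual} violates "
                f"declared d_min={declared}"
            )
        pool.d_min = declared if declared is not None else actual
    return pool


def write_pool(pool: BarcodePool, path, with_distances: bool = False) -> None:
    """Write a pool as FASTA (by extension) or TSV, in generation order."""
    path = Path(path)
    if path.suffix.lower() in _FASTA_EXT:
        records = [
            SeqRecord(Seq(b.sequence), id=f"bc{b.id}", description="")
            for b in pool
        ]
        SeqIO.write(records, str(path), "fasta")
        return
    with open(path, "w") as fh:
        fh.write(f"# length={pool.length} d_min={pool.d_min} "
                 f"filters={','.join(sorted(pool.filters_applied)) or '-'}\n")
        if with_distances and len(pool) >= 2:
            means = mean_pairwise_distance(pool)
            fh.write("id\tsequence\tmean_pairwise_distance\n")
            for b, m in zip(pool, means):
                fh.write(f"bc{b.id}\t{b.sequence}\t{m:.6f}\n")
        else:
            fh.write("id\tsequence\n")
            for b in pool:
                fh.write(f"bc{b.id}\t{b.sequence}\n")


def read_sample_sheet(path) -> pd.DataFrame:
    """Validated sample sheet: sample_id, group, is_input_pool, replicate."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSheetError(f"{path}: missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise SampleSheetError(f"{path}: duplicate sample_id(s) {dupes}")
    truthy = {"1": True, "true": True, "0": False, "false": False}
    flags = df["is_input_pool"].str.lower().map(truthy)
    if flags.isna().any():
        raise SampleSheetError(
            f"{path}: is_input_pool must be one of 0/1/true/false"
        )
    df["is_input_pool"] = flags
    if not flags.any():
        import warnings

        warnings.warn(f"{path}: no sample is flagged is_input_pool")
    return df


def write_counts(counts, outdir, pool: Optional[BarcodePool] = None) -> Path:
    """Write one sample's counts and QC TSVs; returns the counts path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts_path = outdir / f"{counts.sample_id}.counts.tsv"
    counts.to_frame(pool).to_csv(counts_path, sep="\t", index=False)
    counts.qc_frame().to_csv(
        outdir / f"{counts.sample_id}.qc.tsv", sep="\t", index=False
    )
    return counts_path


def read_counts_dir(counts_dir, samples: pd.DataFrame) -> CountMatrix:
    """Assemble a CountMatrix from per-sample ``<id>.counts.tsv`` files."""
    counts_dir = Path(counts_dir)
    cols = {}
    for sid in samples["sample_id"]:
        path = counts_dir / f"{sid}.counts.tsv"
        if not path.exists():
            raise BcscreenError(f"missing counts file {path}")
        df = pd.read_csv(path, sep="\t")
        cols[sid] = df.set_index("barcode_id")["umi_count"]
    counts = pd.DataFrame(cols).fillna(0).astype("int64")
    counts.index.name = "barcode_id"
    return CountMatrix(counts=counts.sort_index(),
                       samples=samples.set_index("sample_id"))


def write_accumulation(table: AccumulationTable, path) -> None:
    long = table.to_long()
    long = long.sort_values(["barcode_id", "sample_id"]).reset_index(drop=True)
    long.to_csv(path, sep="\t", index=False)


def write_narrowing_report(results, path) -> None:
    rows = pd.DataFrame([r.__dict__ for r in results])
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")
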