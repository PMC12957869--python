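"""Normalized accumulation, group summaries, profile correlation, tropism.

A barcode's read fraction in a sample is its UMI-collapsed count divided
by the sample's total barcode counts.  Normalized accumulation (NA)
divides each output-sample fraction by the mean fraction of that barcode
across the uninjected input-pool samples, so NA = 1 means the barcode
accumulated in proportion to its representation in the injected library.
Barcodes absent from every input sample have no defined NA; they are
flagged and excluded from downstream statistics rather than rescued with
a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .errors import (
    BcscreenError,
    EmptySampleError,
    MissingInputPoolError,
)

SAMPLE_COLUMNS = ("sample_id", "group", "is_input_pool", "replicate")


@dataclass
class CountMatrix:
    """UMI-collapsed counts (barcodes x samples) plus sample metadata.

    ``counts``: DataFrame indexed by barcode_id with sample_id columns.
    ``samples``: DataFrame indexed by sample_id with columns group,
    is_input_pool (bool) and replicate.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            self.samples = self.samples.loc[list(self.counts.columns)]
        if (self.counts.values < 0).any():
            raise BcscreenError("counts must be non-negative")
        if not self.samples["is_input_pool"].any():
            raise MissingInputPoolError(
                "at least one sample must be flagged is_input_pool"
            )

    @property
    def input_samples(self) -> pd.Index:
        return self.samples.index[self.samples["is_input_pool"].astype(bool)]

    @property
    def output_samples(self) -> pd.Index:
        return self.samples.index[~self.samples["is_input_pool"].astype(bool)]

    @classmethod
    def from_barcode_counts(cls, counts_list, samples: pd.DataFrame,
                            use: str = "umi") -> "CountMatrix":
        """Assemble from per-sample ``BarcodeCounts`` (use='umi' or 'raw')."""
        cols = {}
        for bc in counts_list:
            src = bc.umi_collapsed if use == "umi" else bc.raw
            cols[bc.sample_id] = pd.Series(src, dtype="int64")
        counts = pd.DataFrame(cols).fillna(0).astype("int64")
        counts.index.name = "barcode_id"
        counts = counts.sort_index()
        samples = samples.set_index("sample_id") if "sample_id" in samples else samples
        return cls(counts=counts[list(samples.index)], samples=samples)


@dataclass
class AccumulationTable:
    """Per-barcode, per-sample normalized accumulation.

    ``values`` covers all samples (input ones included, where mean NA is
    1 per barcode by construction) for the unflagged barcodes;
    ``flagged`` lists barcodes with zero mean input fraction, which
    carry no accumulation values.
    """

    values: pd.DataFrame
    input_mean_fraction: pd.Series
    flagged: pd.Index
    samples: pd.DataFrame

    @property
    def output_values(self) -> pd.DataFrame:
        out = self.samples.index[~self.samples["is_input_pool"].astype(bool)]
        return self.values[list(out)]

    def to_long(self) -> pd.DataFrame:
        long = (
            self.values.rename_axis("barcode_id")
            .reset_index()
            .melt(id_vars="barcode_id", var_name="sample_id",
                  value_name="normalized_accumulation")
        )
        meta = self.samples.reset_index().rename(
            columns={self.samples.index.name or "index": "sample_id"}
        )
        return long.merge(meta[["sample_id", "group", "is_input_pool"]],
                          on="sample_id")


def read_fractions(counts) -> np.ndarray:
    """Within-sample read fractions: count_i / sum(counts)."""
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise BcscreenError("read_fractions expects a single sample vector")
    total = arr.sum()
    if total <= 0:
        raise EmptySampleError("sample has no positive counts")
    return arr / total


def normalized_accumulation(matrix: CountMatrix) -> AccumulationTable:
    """Output read fractions divided by mean input-pool read fractions."""
    inputs = matrix.input_samples
    if len(inputs) == 0:
        raise MissingInputPoolError("no input-pool samples present")
    frac = matrix.counts.apply(lambda col: read_fractions(col), axis=0)
    frac = pd.DataFrame(frac, index=matrix.counts.index,
                        columns=matrix.counts.columns, dtype=float)
    input_mean = frac[list(inputs)].mean(axis=1)
    flagged = matrix.counts.index[input_mean <= 0]
    keep = matrix.counts.index.difference(flagged, sort=False)
    values = frac.loc[keep].div(input_mean.loc[keep], axis=0)
    return AccumulationTable(
        values=values,
        input_mean_fraction=input_mean,
        flagged=flagged,
        samples=matrix.samples,
    )


def summarize_by_group(
    table: AccumulationTable, grouping: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Per-barcode, per-group mean and standard deviation of NA.

    ``grouping`` maps sample_id -> group label; defaults to the sample
    metadata's ``group`` column.  Dispersion is the sample standard
    deviation (ddof=1; NaN for single-sample groups).
    """
    groups = _resolve_grouping(table, grouping)
    rows = []
    for group, sample_ids in groups.items():
        if not sample_ids:
            continue
        block = table.values[sample_ids]
        rows.append(
            pd.DataFrame(
                {
                    "barcode_id": table.values.index,
                    "group": group,
                    "mean_na": block.mean(axis=1).values,
                    "sd_na": block.std(axis=1, ddof=1).values,
                    "n_samples": len(sample_ids),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _resolve_grouping(table, grouping) -> Dict[str, list]:
    if grouping is None:
        grouping = table.samples["group"].to_dict()
    missing = [s for s in table.values.columns if s not in grouping]
    if missing:
        raise BcscreenError(f"samples without a group mapping: {missing}")
    groups: Dict[str, list] = {}
    for s in table.values.columns:
        groups.setdefault(grouping[s], []).append(s)
    return groups


def correlate_profiles(
    table: AccumulationTable, grouping: Optional[Mapping[str, str]] = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-group mean NA profiles.

    Correlations are taken across barcodes between the group-mean NA
    vectors; a zero-variance profile yields NaN against every other
    group.
    """
    summary = summarize_by_group(table, grouping)
    wide = summary.pivot(index="barcode_id", columns="group", values="mean_na")
    if wide.shape[0] < 3:
        raise BcscreenError("profile correlation needs >= 3 barcodes")
    corr = wide.corr(method="pearson")
    # an (effectively) constant profile has no defined correlation;
    # without the guard, float residuals of order 1e-16 (e.g. the input
    # group, whose mean NA is identically 1) would correlate as noise
    degenerate = wide.std(axis=0) <= 1e-9 * wide.abs().mean(axis=0).clip(lower=1)
    corr.loc[degenerate, :] = np.nan
    corr.loc[:, degenerate] = np.nan
    corr.index.name = corr.columns.name = "group"
    np.fill_diagonal(corr.values, 1.0)
    return corr


@dataclass(frozen=True)
class OrganSignal:
    """Luminescence readout used for organ-tropism classification."""

    spleen_signal: float
    liver_signal: float
    baseline_ratio: float

    def __post_init__(self):
        if self.spleen_signal <= 0 or self.liver_signal <= 0:
            raise BcscreenError("organ signals must be positive")
        if self.baseline_ratio <= 0:
            raise BcscreenError("baseline ratio must be positive")


def classify_tropism(signal: OrganSignal) -> str:
    """Spleen- vs liver-tropic by the spleen:liver ratio against baseline.

    A treatment whose spleen:liver ratio exceeds the negative-control
    baseline is spleen-tropic; otherwise (equality included) it is
    liver-tropic.
    """
    ratio = signal.spleen_signal / signal.liver_signal
    return "spleen-tropic" if ratio > signal.baseline_ratio else "liver-tropic"
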