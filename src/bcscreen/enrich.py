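"""Enrichment statistics and pool narrowing.

Barcodes whose normalized accumulation (NA) deviates from unity behave
differently from the pool average — suggestive of unwanted interactions
with cellular machinery (e.g. differential miRNA binding within the
barcode region) — and are removed before the pool is used to label
treatments.  Exclusion is driven by the +/-20% effect-size rule: a
barcode whose mean NA falls outside the inclusive fold window
[0.8, 1.2] is excluded as enriched or depleted.  A Wilcoxon rank-sum
test of each barcode's NA values against all other barcodes' values
(normal approximation with continuity correction, mid-ranks and tie
correction) with Benjamini-Hochberg FDR control is computed and
reported alongside; ``require_significance`` switches to the
conjunctive rule (deviation AND q < alpha).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codes import BarcodePool
from .errors import BcscreenError
from .quantify import AccumulationTable

KEEP = "keep"
EXCLUDE = "exclude"
ENRICHED = "enriched"
DEPLETED = "depleted"
NONE = "none"


@dataclass(frozen=True)
class NarrowingParams:
    """Pool-narrowing parameters.

    ``fold_window``: inclusive NA interval regarded as unbiased
    (default [0.8, 1.2], the +/-20% rule).  ``alpha``: FDR level for
    reporting.  ``scope``: 'pooled' pools NA values across all non-input
    samples; 'per-group' excludes a barcode deviating in any group.
    ``require_significance``: also require BH q < alpha for exclusion.
    """

    fold_window: Tuple[float, float] = (0.8, 1.2)
    alpha: float = 0.05
    scope: str = "pooled"
    require_significance: bool = False

    def __post_init__(self):
        lo, hi = self.fold_window
        if not (0 < lo < 1 < hi):
            raise BcscreenError("fold window must satisfy 0 < lower < 1 < upper")
        if not 0 < self.alpha < 1:
            raise BcscreenError("alpha must be in (0, 1)")
        if self.scope not in ("pooled", "per-group"):
            raise BcscreenError("scope must be 'pooled' or 'per-group'")


@dataclass
class EnrichmentResult:
    barcode_id: int
    mean_na: float
    fold_deviation: float  # mean NA relative to 1
    z_statistic: float
    p_value: float
    q_value: float
    decision: str
    reason: str


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test, normal approximation.

    Mid-ranks for ties; tie-corrected variance
    Var(U) = (n1*n2/12) * [(N+1) - sum(t^3 - t) / (N*(N-1))];
    continuity correction of 0.5 toward the null mean n1*n2/2.
    Returns (z, p).  Fully tied data degenerate to (0, 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise BcscreenError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts.astype(float) ** 3 - tie_counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return 0.0, 1.0
    diff = u - mean_u
    if diff > 0:
        diff -= 0.5
    elif diff < 0:
        diff += 0.5
    z = diff / np.sqrt(var_u)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(z), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise BcscreenError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def narrow_pool(
    table: AccumulationTable,
    params: NarrowingParams = NarrowingParams(),
    pool: Optional[BarcodePool] = None,
) -> Tuple[List[EnrichmentResult], object]:
    """Exclude barcodes with biased accumulation; return results + kept set.

    For each barcode, x = its NA values over the scope's samples and
    y = the NA values of all other barcodes over those samples feed the
    rank-sum test; q-values are BH-adjusted across barcodes.  Exclusion
    is decided by the fold window on the mean NA (per group in
    'per-group' scope), optionally conjunctive with q < alpha.  Returns
    (results, kept) where kept is a BarcodePool subset when ``pool`` is
    given, else the list of kept barcode ids.  Barcodes flagged for zero
    input fraction are dropped entirely (no defined NA).
    """
    values = table.output_values
    if values.shape[0] < 2:
        raise BcscreenError("narrowing needs at least 2 barcodes")
    if values.shape[1] < 2:
        raise BcscreenError("narrowing needs at least 2 samples in scope")
    lo, hi = params.fold_window
    mat = values.to_numpy(dtype=float)
    barcode_ids = list(values.index)
    n_bc = len(barcode_ids)
    zs = np.empty(n_bc)
    ps = np.empty(n_bc)
    flat = mat.ravel()
    ncol = mat.shape[1]
    for i in range(n_bc):
        x = mat[i]
        y = np.delete(flat, slice(i * ncol, (i + 1) * ncol))
        zs[i], ps[i] = wilcoxon_rank_sum(x, y)
    qs = bh_adjust(ps)
    means = mat.mean(axis=1)

    if params.scope == "per-group":
        groups = table.samples.loc[list(values.columns), "group"]
        gmeans = values.T.groupby(groups.values).mean().T.to_numpy()  # bc x grp
        above = (gmeans > hi).any(axis=1)
        below = (gmeans < lo).any(axis=1)
        # high in one group and low in another: report the direction of
        # the larger absolute log-fold deviation
        logm = np.abs(np.log(gmeans.clip(min=1e-300)))
        worst = gmeans[np.arange(n_bc), logm.argmax(axis=1)]
        deviating_high = above & (~below | (worst > 1))
        deviating_low = below & ~deviating_high
    else:
        deviating_high = means > hi
        deviating_low = means < lo

    results: List[EnrichmentResult] = []
    kept_ids: List[int] = []
    for i, bid in enumerate(barcode_ids):
        if deviating_high[i]:
            reason = ENRICHED
        elif deviating_low[i]:
            reason = DEPLETED
        else:
            reason = NONE
        if reason != NONE and params.require_significance and qs[i] >= params.alpha:
            reason = NONE
        decision = EXCLUDE if reason != NONE else KEEP
        if decision == KEEP:
            kept_ids.append(bid)
        results.append(
            EnrichmentResult(
                barcode_id=bid,
                mean_na=float(means[i]),
                fold_deviation=float(means[i] - 1.0),
                z_statistic=float(zs[i]),
                p_value=float(ps[i]),
                q_value=float(qs[i]),
                decision=decision,
                reason=reason,
            )
        )
    kept = pool.subset(kept_ids) if pool is not None else kept_ids
    return results, kept


def results_frame(results: List[EnrichmentResult]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in results])
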