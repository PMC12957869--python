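"""Read decoding: clamp anchoring, barcode assignment, UMI collapse.

A sequenced read traverses (5'→3' in pipeline orientation) an optional
fixed prefix (the tail of the 3' UTR), the 12-nt barcode, the clamp (the
fixed spacer between barcode and poly(A) tail that the RT oligo primes
on), and the 12-nt UMI added at reverse transcription.  The clamp is the
anchoring landmark: it is located by approximate sliding alignment, the
barcode window is read off 5' of it and the UMI 3' of it.

Decoding is anchored at the clamp-proximal end of the barcode window:
the embedded distance between a candidate barcode and the window is the
minimum over the final DP row computed on the reversed pair, so the
barcode must abut the clamp while its far end may float into the slack
bases.  A window is assigned to the unique candidate within the code's
correction radius floor((d_min-1)/2); ties are reported as ambiguous and
discarded rather than resolved arbitrarily.  When the fixed sequence
upstream of the barcode is known, the window's residual 5' bases are
scored against it, which removes the rare shifted-alignment ties the
non-metric sequence-Levenshtein function admits.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .codes import BarcodePool, reverse_complement, validate_dna
from .errors import BcscreenError, InvalidAlphabetError

logger = logging.getLogger(__name__)

# DecodedRead / QC statuses
ASSIGNED = "assigned"
CLAMP_NOT_FOUND = "clamp_not_found"
TOO_FAR = "too_far"
AMBIGUOUS = "ambiguous"
MALFORMED = "malformed"
STATUSES = (ASSIGNED, CLAMP_NOT_FOUND, TOO_FAR, AMBIGUOUS, MALFORMED)


@dataclass(frozen=True)
class ReadLayout:
    """Structural description of a read: [prefix] barcode clamp UMI."""

    clamp: str
    barcode_length: int = 12
    umi_length: int = 12
    max_clamp_edits: int = 1
    barcode_slack: int = 3
    fixed_prefix: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "clamp", validate_dna(self.clamp))
        if self.fixed_prefix is not None:
            object.__setattr__(self, "fixed_prefix", validate_dna(self.fixed_prefix))
        if len(self.clamp) < 6:
            raise ValueError("clamp must be at least 6 nt to anchor reliably")
        if self.barcode_length < 1:
            raise ValueError("barcode_length must be >= 1")
        if self.umi_length < 0:
            raise ValueError("umi_length must be >= 0")
        if self.max_clamp_edits < 0 or self.barcode_slack < 0:
            raise ValueError("max_clamp_edits and barcode_slack must be >= 0")


@dataclass(frozen=True)
class DecodedRead:
    status: str
    barcode_id: Optional[int] = None
    umi: Optional[str] = None
    distance: Optional[int] = None


@dataclass
class BarcodeCounts:
    """Per-sample decoding result: raw and UMI-collapsed counts plus QC."""

    sample_id: str
    raw: Dict[int, int] = field(default_factory=dict)
    umi_collapsed: Dict[int, int] = field(default_factory=dict)
    qc: Dict[str, int] = field(default_factory=lambda: {s: 0 for s in STATUSES})
    n_reads: int = 0

    def to_frame(self, pool: Optional[BarcodePool] = None) -> pd.DataFrame:
        ids = pool.ids if pool is not None else sorted(self.raw)
        return pd.DataFrame(
            {
                "barcode_id": list(ids),
                "raw_reads": [self.raw.get(i, 0) for i in ids],
                "umi_count": [self.umi_collapsed.get(i, 0) for i in ids],
            }
        )

    def qc_frame(self) -> pd.DataFrame:
        total = max(self.n_reads, 1)
        return pd.DataFrame(
            {
                "status": list(STATUSES),
                "count": [self.qc[s] for s in STATUSES],
                "fraction": [self.qc[s] / total for s in STATUSES],
            }
        )


def find_clamp(read: str, layout: ReadLayout) -> Optional[int]:
    """Leftmost position where the clamp matches with <= max_clamp_edits."""
    start, _end, _ed = _find_clamp_span(read, layout)
    return None if start < 0 else start


def _find_clamp_span(read: str, layout: ReadLayout) -> Tuple[int, int, int]:
    if not read:
        raise BcscreenError("empty read")
    # exact-match fast path: edit count dominates, so a leftmost exact
    # occurrence is always the best alignment
    pos = read.find(layout.clamp)
    if pos >= 0:
        return pos, pos + len(layout.clamp), 0
    enc = _kernels.encode(read)
    cl = _kernels.encode(layout.clamp)
    start, end, ed = _kernels.find_clamp(enc, cl, layout.max_clamp_edits)
    return int(start), int(end), int(ed)


@dataclass(frozen=True)
class Extraction:
    status: str
    window: Optional[str] = None
    umi: Optional[str] = None


def extract(read: str, layout: ReadLayout) -> Extraction:
    """Cut the barcode window and UMI out of a read by clamp anchoring.

    The window is the (barcode_length + barcode_slack) bases immediately
    5' of the clamp (truncated at the read start); the UMI is the
    umi_length bases immediately 3' of the clamp alignment.
    """
    read = validate_dna(read, allow_n=True)
    start, end, _ed = _find_clamp_span(read, layout)
    if start < 0:
        return Extraction(CLAMP_NOT_FOUND)
    if start < layout.barcode_length - layout.barcode_slack:
        return Extraction(MALFORMED)
    if len(read) - end < layout.umi_length:
        return Extraction(MALFORMED)
    wstart = max(0, start - layout.barcode_length - layout.barcode_slack)
    window = read[wstart:start]
    umi = read[end : end + layout.umi_length] if layout.umi_length else ""
    return Extraction("ok", window=window, umi=umi)


def correction_radius(pool: BarcodePool) -> int:
    return max((pool.d_min - 1) // 2, 0)


def _pool_rev_matrix(pool: BarcodePool) -> np.ndarray:
    return pool.matrix()[:, ::-1].copy()


def _exact_index(pool: BarcodePool) -> Dict[str, int]:
    return {b.sequence: b.id for b in pool}


_NO_CTX = np.zeros(0, dtype=np.uint8)


def _context_rev(upstream: Optional[str]) -> tuple:
    if upstream:
        return _kernels.encode(validate_dna(upstream, allow_n=True))[::-1].copy(), True
    return _NO_CTX, False


def decode_barcode(
    window: str,
    pool: BarcodePool,
    radius: Optional[int] = None,
    upstream: Optional[str] = None,
) -> DecodedRead:
    """Assign a barcode window to its pool barcode with error correction.

    The embedded distance anchors the barcode at the clamp-proximal
    (right) end of the window; assignment requires a unique minimum
    within the correction radius.  When the fixed sequence upstream of
    the barcode is known (``upstream``), the slack bases of the window
    are scored against it, which resolves rare alignment ties between
    a shifted impostor barcode and the true one.
    """
    if len(pool) == 0:
        raise BcscreenError("cannot decode against an empty pool")
    if radius is None:
        radius = correction_radius(pool)
    window = validate_dna(window, allow_n=True)
    exact = _exact_index(pool)
    bid = exact.get(window[-pool.length:]) if len(window) >= pool.length else None
    if bid is not None:
        return DecodedRead(ASSIGNED, barcode_id=bid, distance=0)
    w_rev = _kernels.encode(window)[::-1].copy()
    ctx, use_ctx = _context_rev(upstream)
    besti, best, nbest = _kernels.decode_window(
        _pool_rev_matrix(pool), w_rev, radius, ctx, use_ctx
    )
    return _interpret(pool, int(besti), int(best), int(nbest), radius)


def _interpret(pool, besti, best, nbest, radius):
    if best > radius:
        return DecodedRead(TOO_FAR, distance=None)
    if nbest > 1:
        return DecodedRead(AMBIGUOUS, distance=best)
    return DecodedRead(ASSIGNED, barcode_id=pool.barcodes[besti].id, distance=best)


def decode_windows_batch(windows, pool: BarcodePool,
                         radius: Optional[int] = None,
                         upstream: Optional[str] = None) -> list:
    """Vectorized decode of many barcode windows against one pool."""
    if radius is None:
        radius = correction_radius(pool)
    windows = [validate_dna(w, allow_n=True) for w in windows]
    n = len(windows)
    if n == 0:
        return []
    exact = _exact_index(pool)
    bl = pool.length
    maxlen = max(len(w) for w in windows)
    wins = np.zeros((n, maxlen), dtype=np.uint8)
    wlens = np.empty(n, dtype=np.int64)
    for i, w in enumerate(windows):
        enc = _kernels.encode(w)[::-1]
        wins[i, : len(w)] = enc
        wlens[i] = len(w)
    out_idx = np.empty(n, dtype=np.int64)
    out_d = np.empty(n, dtype=np.int64)
    out_n = np.empty(n, dtype=np.int64)
    ctx, use_ctx = _context_rev(upstream)
    _kernels.decode_windows(_pool_rev_matrix(pool), wins, wlens, radius,
                            ctx, use_ctx, out_idx, out_d, out_n)
    results = []
    for i, w in enumerate(windows):
        bid = exact.get(w[-bl:]) if len(w) >= bl else None
        if bid is not None:
            results.append(DecodedRead(ASSIGNED, barcode_id=bid, distance=0))
        else:
            results.append(
                _interpret(pool, int(out_idx[i]), int(out_d[i]),
                           int(out_n[i]), radius)
            )
    return results


def collapse_umis(umis, method: str = "directional") -> int:
    """Count distinct molecules from a multiset of same-length UMIs.

    ``directional``: network-based collapse in which UMI u absorbs
    Hamming-1 neighbour v when count(u) >= 2*count(v) - 1; the result is
    the number of cluster roots.  ``unique``: number of distinct UMIs.
    Deterministic: UMIs are processed in descending count, ties broken
    lexicographically.
    """
    counts = umis if isinstance(umis, Counter) else Counter(umis)
    if not counts:
        return 0
    lengths = {len(u) for u in counts}
    if len(lengths) != 1:
        raise BcscreenError(f"mixed UMI lengths: {sorted(lengths)}")
    if method == "unique":
        return len(counts)
    if method != "directional":
        raise ValueError(f"unknown UMI method {method!r}")
    if len(counts) == 1:
        return 1
    # Hamming-1 neighbourhood via single-position wildcard buckets
    buckets = defaultdict(list)
    for u in counts:
        for i in range(len(u)):
            buckets[(i, u[:i], u[i + 1 :])].append(u)
    neighbours = {u: set() for u in counts}
    for bucket in buckets.values():
        for i, u in enumerate(bucket):
            for v in bucket[i + 1 :]:
                neighbours[u].add(v)
                neighbours[v].add(u)
    order = sorted(counts, key=lambda u: (-counts[u], u))
    visited = set()
    n_clusters = 0
    for root in order:
        if root in visited:
            continue
        n_clusters += 1
        stack = [root]
        visited.add(root)
        while stack:
            u = stack.pop()
            for v in sorted(neighbours[u]):
                if v not in visited and counts[u] >= 2 * counts[v] - 1:
                    visited.add(v)
                    stack.append(v)
    return n_clusters


def _iter_fastq(source) -> Iterator[Tuple[str, str, int]]:
    """Yield (name, sequence, n_malformed_skipped) from a FASTQ source.

    Tolerant record-group reader: a structurally broken record is skipped
    (reported via the third tuple element accumulated by the caller)
    and processing continues — required because decoding must degrade
    gracefully on truncated files.
    """
    if isinstance(source, (str, Path)):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:
            yield from _iter_fastq(fh)
        return
    while True:
        header = source.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header.startswith("@"):
            logger.warning("skipping malformed FASTQ record at %r", header[:40])
            yield "", "", 1
            continue
        seq = source.readline().rstrip("\n")
        plus = source.readline().rstrip("\n")
        qual = source.readline().rstrip("\n")
        if not plus.startswith("+") or len(qual) != len(seq) or not seq:
            logger.warning("skipping malformed FASTQ record %r", header[:40])
            yield "", "", 1
            continue
        yield header[1:].split()[0], seq, 0


def count_reads(
    fastq,
    pool: BarcodePool,
    layout: ReadLayout,
    sample_id: str = "sample",
    umi_method: str = "directional",
    reverse_complement_reads: bool = False,
) -> BarcodeCounts:
    """Decode a per-sample FASTQ stream into barcode counts.

    ``fastq`` may be a path (optionally .gz), an open text handle, or an
    iterable of sequence strings.  Streaming: memory is proportional to
    the number of barcodes times distinct UMIs, not the file size.
    """
    if len(pool) == 0:
        raise BcscreenError("cannot decode against an empty pool")
    radius = correction_radius(pool)
    pool_rev = _pool_rev_matrix(pool)
    ctx, use_ctx = _context_rev(layout.fixed_prefix)
    exact = {b.sequence: b.id for b in pool}
    bl = pool.length
    counts = BarcodeCounts(sample_id=sample_id)
    umi_sets: Dict[int, Counter] = defaultdict(Counter)
    raw: Dict[int, int] = defaultdict(int)

    if isinstance(fastq, (str, Path)) or hasattr(fastq, "readline"):
        records: Iterable[Tuple[str, str, int]] = _iter_fastq(fastq)
    else:
        records = ((f"read{i}", s, 0) for i, s in enumerate(fastq))

    for _name, seq, bad in records:
        counts.n_reads += 1
        if bad:
            counts.qc[MALFORMED] += 1
            continue
        seq = seq.upper()
        if reverse_complement_reads:
            seq = reverse_complement(seq)
        try:
            ext = extract(seq, layout)
        except InvalidAlphabetError:
            counts.qc[MALFORMED] += 1
            continue
        if ext.status != "ok":
            counts.qc[ext.status] += 1
            continue
        window = ext.window
        # exact fast path: the clamp-adjacent 12-mer is a pool barcode
        bid = exact.get(window[-bl:]) if len(window) >= bl else None
        if bid is not None:
            dec = DecodedRead(ASSIGNED, barcode_id=bid, distance=0)
        else:
            w_rev = _kernels.encode(window)[::-1].copy()
            besti, best, nbest = _kernels.decode_window(pool_rev, w_rev,
                                                        radius, ctx, use_ctx)
            dec = _interpret(pool, int(besti), int(best), int(nbest), radius)
        counts.qc[dec.status] += 1
        if dec.status != ASSIGNED:
            continue
        raw[dec.barcode_id] += 1
        if layout.umi_length and "N" not in ext.umi:
            umi_sets[dec.barcode_id][ext.umi] += 1

    counts.raw = dict(raw)
    if layout.umi_length:
        counts.umi_collapsed = {
            bid: collapse_umis(c, method=umi_method) for bid, c in umi_sets.items()
        }
    else:
        counts.umi_collapsed = dict(raw)
    return counts
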