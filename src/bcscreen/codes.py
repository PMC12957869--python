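"""Error-correcting DNA barcode design under the sequence-Levenshtein metric.

Barcodes destined for amplicon sequencing sit inside longer DNA, so an
insertion or deletion near the barcode boundary drags flanking bases into
the sequenced window.  The sequence-Levenshtein distance accounts for
this by taking the minimum over the entire last row *and* last column of
the unit-cost edit-distance matrix, i.e. the cheapest edit script that
may leave either word unfinished at its right boundary.  A code with
minimum pairwise distance d detects up to d-1 edits and corrects
floor((d-1)/2) of them even in an embedded context.

Pools are built with a greedy lexicographic closure: scan all 4**L words
in A<C<G<T order, drop words failing composition filters (homopolymer
triplets, GC content outside 40-60%, self-complementarity), and accept a
word iff it keeps the pool's minimum distance.  The construction is
deterministic, so a pool is fully specified by (length, d_min, filters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .errors import InsufficientPoolError, InvalidAlphabetError

ALL_FILTERS = ("triplet", "gc", "selfcomp")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def validate_dna(seq: str, allow_n: bool = False) -> str:
    """Return the uppercase sequence, rejecting non-ACGT(N) characters."""
    if not seq:
        raise InvalidAlphabetError("empty sequence")
    up = seq.upper()
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(up) - allowed
    if bad:
        raise InvalidAlphabetError(
            f"invalid character(s) {sorted(bad)} in sequence {seq!r}"
        )
    return up


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Barcode:
    """A fixed-length DNA barcode; ``id`` is its 1-based generation rank."""

    id: int
    sequence: str


@dataclass(frozen=True)
class CodeGuarantee:
    detectable_errors: int
    correctable_errors: int


@dataclass
class BarcodePool:
    """An ordered barcode set with a declared minimum pairwise distance."""

    barcodes: Tuple[Barcode, ...]
    length: int
    d_min: int
    filters_applied: frozenset = frozenset()
    _matrix: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.barcodes = tuple(self.barcodes)
        seqs = [b.sequence for b in self.barcodes]
        if len(set(seqs)) != len(seqs):
            raise InvalidAlphabetError("pool contains duplicate sequences")
        for s in seqs:
            if len(s) != self.length:
                raise InvalidAlphabetError(
                    f"barcode {s!r} does not have declared length {self.length}"
                )
            validate_dna(s)

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self) -> Iterator[Barcode]:
        return iter(self.barcodes)

    @property
    def sequences(self) -> Tuple[str, ...]:
        return tuple(b.sequence for b in self.barcodes)

    @property
    def ids(self) -> Tuple[int, ...]:
        return tuple(b.id for b in self.barcodes)

    def matrix(self) -> np.ndarray:
        """uint8-encoded (n, length) matrix, cached."""
        if self._matrix is None:
            self._matrix = np.vstack([_kernels.encode(s) for s in self.sequences])
        return self._matrix

    def subset(self, ids: Iterable[int]) -> "BarcodePool":
        wanted = set(ids)
        kept = tuple(b for b in self.barcodes if b.id in wanted)
        return replace(self, barcodes=kept, _matrix=None)

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[str],
        d_min: int = 0,
        ids: Optional[Sequence[int]] = None,
        filters_applied: Iterable[str] = (),
    ) -> "BarcodePool":
        sequences = [validate_dna(s) for s in sequences]
        if not sequences:
            raise InsufficientPoolError("cannot build a pool from zero sequences")
        if ids is None:
            ids = range(1, len(sequences) + 1)
        barcodes = tuple(Barcode(i, s) for i, s in zip(ids, sequences))
        return cls(
            barcodes=barcodes,
            length=len(sequences[0]),
            d_min=d_min,
            filters_applied=frozenset(filters_applied),
        )


def sl_distance(a: str, b: str) -> int:
    """Sequence-Levenshtein distance between two DNA strings.

    Minimum over the last row and last column of the Levenshtein DP
    matrix; symmetric, and never larger than the plain Levenshtein
    distance.
    """
    ea = _kernels.encode(validate_dna(a))
    eb = _kernels.encode(validate_dna(b))
    return int(_kernels.sl_distance_arr(ea, eb))


def passes_composition_filters(
    seq: str, filters: Iterable[str] = ALL_FILTERS
) -> Tuple[bool, Optional[str]]:
    """Check composition filters; returns (ok, first_failing_filter).

    Filters: ``triplet`` (no homopolymer run of length >= 3), ``gc``
    (GC fraction within [0.4, 0.6] inclusive), ``selfcomp`` (sequence is
    not its own reverse complement).
    """
    seq = validate_dna(seq)
    filters = set(filters)
    unknown = filters - set(ALL_FILTERS)
    if unknown:
        raise ValueError(f"unknown filter(s): {sorted(unknown)}")
    if "triplet" in filters:
        for i in range(len(seq) - 2):
            if seq[i] == seq[i + 1] == seq[i + 2]:
                return False, "triplet"
    if "gc" in filters:
        gc = sum(c in "GC" for c in seq)
        # integer comparison of gc/len against [0.4, 0.6], both inclusive
        if 10 * gc < 4 * len(seq) or 10 * gc > 6 * len(seq):
            return False, "gc"
    if "selfcomp" in filters:
        if seq == reverse_complement(seq):
            return False, "selfcomp"
    return True, None


def conway_generate(
    length: int = 12,
    d_min: int = 4,
    filters: Iterable[str] = ALL_FILTERS,
    stop_after: Optional[int] = None,
) -> BarcodePool:
    """Generate a barcode pool by greedy lexicographic closure.

    Enumerates all ``4**length`` words in A<C<G<T order, skips words
    failing the composition ``filters``, and accepts a word iff its
    sequence-Levenshtein distance to every previously accepted word is
    at least ``d_min``.  ``stop_after`` truncates generation once that
    many barcodes are accepted (the result is a prefix of the full
    pool).  Deterministic: identical parameters give identical pools.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    filters = frozenset(filters)
    unknown = filters - set(ALL_FILTERS)
    if unknown:
        raise ValueError(f"unknown filter(s): {sorted(unknown)}")
    stop = int(stop_after) if stop_after else 0
    cap = stop if stop > 0 else 4096
    while True:
        mat, n, exhausted = _kernels.conway_closure(
            length,
            d_min,
            "triplet" in filters,
            "gc" in filters,
            "selfcomp" in filters,
            stop,
            cap,
        )
        if exhausted:
            break
        cap *= 4
    barcodes = tuple(
        Barcode(i + 1, _kernels.decode(mat[i])) for i in range(n)
    )
    return BarcodePool(
        barcodes=barcodes, length=length, d_min=d_min, filters_applied=filters
    )


def mean_pairwise_distance(pool: BarcodePool) -> np.ndarray:
    """Per-barcode mean sequence-Levenshtein distance to all other barcodes."""
    if len(pool) < 2:
        raise InsufficientPoolError("mean pairwise distance needs >= 2 barcodes")
    return _kernels.pairwise_mean_distance(pool.matrix())


def pool_min_distance(pool: BarcodePool) -> int:
    """Minimum sequence-Levenshtein distance over all unordered pairs."""
    if len(pool) < 2:
        raise InsufficientPoolError("pool minimum distance needs >= 2 barcodes")
    return int(_kernels.pairwise_min_distance(pool.matrix()))


def select_top_k(pool: BarcodePool, k: int) -> BarcodePool:
    """Keep the ``k`` barcodes with greatest mean pairwise distance.

    Means are computed against the full input pool; ties break by
    lexicographic sequence order (earlier wins).  Output preserves ids
    and the original generation order.
    """
    if not 1 <= k <= len(pool):
        raise InsufficientPoolError(
            f"k={k} out of range for pool of size {len(pool)}"
        )
    means = mean_pairwise_distance(pool)
    order = sorted(
        range(len(pool)), key=lambda i: (-means[i], pool.barcodes[i].sequence)
    )
    chosen = set(order[:k])
    kept = tuple(b for i, b in enumerate(pool.barcodes) if i in chosen)
    return replace(pool, barcodes=kept, _matrix=None)


def code_guarantees(d_min: int) -> CodeGuarantee:
    """Detection/correction guarantees of a distance-``d_min`` code."""
    if d_min < 1:
        raise ValueError("d_min must be >= 1")
    return CodeGuarantee(
        detectable_errors=d_min - 1, correctable_errors=(d_min - 1) // 2
    )
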