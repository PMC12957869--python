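"""Read decoding: clamp anchoring, extraction, correction, UMI collapse."""

import io as _io
import itertools
from collections import Counter

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcscreen import (
    BarcodePool,
    collapse_umis,
    count_reads,
    decode_barcode,
    extract,
    find_clamp,
)
from bcscreen.errors import BcscreenError
from bcscreen.readproc import (
    AMBIGUOUS,
    ASSIGNED,
    CLAMP_NOT_FOUND,
    MALFORMED,
    TOO_FAR,
)
from conftest import CLAMP, PREFIX

UMI = "ACGTACGTACGT"


def make_read(barcode: str, prefix=PREFIX, clamp=CLAMP, umi=UMI) -> str:
    return prefix + barcode + clamp + umi


class TestFindClamp:
    def test_exact_clamp_position(self, pool20, layout):
        read = make_read(pool20.barcodes[0].sequence, prefix="")
        assert find_clamp(read, layout) == layout.barcode_length

    def test_one_substitution_still_found(self, pool20, layout):
        bc = pool20.barcodes[0].sequence
        mut = "A" if CLAMP[5] != "A" else "C"
        read = PREFIX + bc + CLAMP[:5] + mut + CLAMP[6:] + UMI
        assert find_clamp(read, layout) == len(PREFIX) + 12

    def test_absent_clamp_not_found(self, layout):
        assert find_clamp("ACGT" * 12, layout) is None

    def test_two_edits_not_found_at_max_one(self, layout):
        broken = "AA" + CLAMP[2:]
        read = PREFIX + "ACACACACACAC" + broken + UMI
        assert find_clamp(read, layout) is None


class TestExtract:
    def test_window_and_umi_dimensions(self, pool20, layout):
        read = make_read(pool20.barcodes[0].sequence)
        ext = extract(read, layout)
        assert ext.status == "ok"
        assert len(ext.window) == layout.barcode_length + layout.barcode_slack
        assert ext.umi == UMI

    def test_window_truncated_at_read_start(self, pool20, layout):
        read = make_read(pool20.barcodes[0].sequence, prefix="GG")
        ext = extract(read, layout)
        assert ext.status == "ok"
        assert ext.window == "GG" + pool20.barcodes[0].sequence

    def test_upstream_deletion_absorbed_by_slack(self, pool20, layout):
        bc = pool20.barcodes[0]
        read = make_read(bc.sequence, prefix=PREFIX[:-1])
        ext = extract(read, layout)
        assert ext.window.endswith(bc.sequence)
        assert decode_barcode(ext.window, pool20).barcode_id == bc.id

    def test_short_umi_is_malformed(self, pool20, layout):
        read = PREFIX + pool20.barcodes[0].sequence + CLAMP + "ACGTA"
        assert extract(read, layout).status == MALFORMED

    def test_too_few_bases_before_clamp_is_malformed(self, pool20, layout):
        read = "ACGT" + CLAMP + UMI  # 4 < barcode_length - slack = 9
        assert extract(read, layout).status == MALFORMED

    def test_missing_clamp_status(self, layout):
        assert extract("ACGT" * 12, layout).status == CLAMP_NOT_FOUND


def single_edits(seq):
    """All single-base substitutions, insertions and deletions of seq."""
    for i, c in enumerate(seq):
        for x in "ACGT":
            if x != c:
                yield seq[:i] + x + seq[i + 1 :]
        yield seq[:i] + seq[i + 1 :]
    for i in range(len(seq) + 1):
        for x in "ACGT":
            yield seq[:i] + x + seq[i:]


class TestDecodeBarcode:
    def test_exact_window(self, pool20):
        bc = pool20.barcodes[7]
        dec = decode_barcode(bc.sequence, pool20)
        assert (dec.status, dec.barcode_id, dec.distance) == (ASSIGNED, bc.id, 0)

    def test_single_substitution_corrected(self, pool20):
        bc = pool20.barcodes[3]
        mut = ("A" if bc.sequence[4] != "A" else "T")
        window = bc.sequence[:4] + mut + bc.sequence[5:]
        dec = decode_barcode(window, pool20)
        assert (dec.status, dec.barcode_id, dec.distance) == (ASSIGNED, bc.id, 1)

    def test_far_window_unassigned(self, pool20):
        # maximally GC-poor window violates every pool barcode's GC content
        dec = decode_barcode("ATATATATATATATA", pool20)
        assert dec.status == TOO_FAR
        assert dec.barcode_id is None

    def test_tie_reported_ambiguous(self):
        pool = BarcodePool.from_sequences(
            ["AAAACCCCGGGG", "AAAACCCCGGGT"], d_min=4
        )
        dec = decode_barcode("AAAACCCCGGGC", pool)
        assert dec.status == AMBIGUOUS

    def test_n_in_window_counts_as_mismatch(self, pool20):
        bc = pool20.barcodes[0]
        window = "N" + bc.sequence[1:]
        dec = decode_barcode(window, pool20)
        assert (dec.status, dec.barcode_id, dec.distance) == (ASSIGNED, bc.id, 1)

    def test_empty_pool_rejected(self, pool20):
        with pytest.raises(BcscreenError):
            decode_barcode("ACGT", BarcodePool.from_sequences(["ACGT"]).subset([]))


def directional_oracle(counts: Counter) -> int:
    """Cluster-count oracle via explicit graph reachability (networkx)."""
    g = nx.DiGraph()
    g.add_nodes_from(counts)
    for u, v in itertools.permutations(counts, 2):
        if sum(a != b for a, b in zip(u, v)) == 1 and counts[u] >= 2 * counts[v] - 1:
            g.add_edge(u, v)
    unassigned = set(counts)
    clusters = 0
    for node in sorted(counts, key=lambda u: (-counts[u], u)):
        if node not in unassigned:
            continue
        clusters += 1
        sub = g.subgraph(unassigned)
        unassigned -= {node} | nx.descendants(sub, node)
    return clusters


class TestCollapseUmis:
    @pytest.mark.parametrize(
        "umis,expected",
        [
            (["AAAA"] * 10, 1),
            (["AAAA"] * 10 + ["AAAT"], 1),  # 10 >= 2*1 - 1 absorbs the error
            (["AAAA"] * 5 + ["TTTT"] * 5, 2),  # Hamming 4: disconnected
            (["AAAA", "AAAT"], 1),  # equal singletons: 1 >= 2*1 - 1 holds
            (["AAAA"] * 2 + ["AAAT"] * 2, 2),  # 2 < 2*2 - 1: no absorption
        ],
    )
    def test_reference_multisets(self, umis, expected):
        assert collapse_umis(umis) == expected

    def test_unique_method(self):
        assert collapse_umis(["AAAA"] * 3 + ["AAAT"], method="unique") == 2

    def test_mixed_lengths_rejected(self):
        with pytest.raises(BcscreenError):
            collapse_umis(["AAAA", "AAA"])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.text("ACGT", min_size=4, max_size=4),
                      st.integers(min_value=1, max_value=20)),
            min_size=1,
            max_size=6,
        )
    )
    def test_matches_reachability_oracle(self, items):
        counts = Counter()
        for umi, n in items:
            counts[umi] += n
        assert collapse_umis(counts) == directional_oracle(counts)


class TestCountReads:
    @staticmethod
    def _umi(k: int) -> str:
        # doubled base-4 digits: distinct UMIs at pairwise Hamming >= 2,
        # so the directional collapse cannot merge them
        return "".join("ACGT"[(k >> (2 * p)) & 3] * 2 for p in range(6))

    def test_error_free_round_trip(self, pool20, layout):
        reads = []
        truth = Counter()
        k = 0
        for bc in pool20:
            for _ in range(20):
                reads.append(make_read(bc.sequence, umi=self._umi(k)))
                truth[bc.id] += 1
                k += 1
        counts = count_reads(reads, pool20, layout)
        assert counts.raw == dict(truth)
        assert counts.umi_collapsed == dict(truth)  # all UMIs distinct
        assert counts.qc[ASSIGNED] == len(reads)

    def test_pcr_duplicates_collapse_to_molecules(self, pool20, layout):
        bc = pool20.barcodes[0]
        umis = ["AAAACCCCGGGG", "TTTTGGGGCCCC", "ACACACGTGTGT"]
        reads = [make_read(bc.sequence, umi=u) for u in umis for _ in range(5)]
        counts = count_reads(reads, pool20, layout)
        assert counts.raw == {bc.id: 15}
        assert counts.umi_collapsed == {bc.id: 3}

    def test_destroyed_clamp_tallied(self, pool20, layout):
        good = [make_read(b.sequence) for b in pool20]
        bad = ["ACGT" * 12] * 5
        counts = count_reads(good + bad, pool20, layout)
        assert counts.qc[CLAMP_NOT_FOUND] == 5
        assert counts.qc[ASSIGNED] == len(good)
        assert sum(counts.qc.values()) == counts.n_reads

    def test_umi_with_n_excluded_from_collapse(self, pool20, layout):
        bc = pool20.barcodes[0]
        reads = [make_read(bc.sequence, umi="NCGTACGTACGT"),
                 make_read(bc.sequence, umi="ACGTACGTACGT")]
        counts = count_reads(reads, pool20, layout)
        assert counts.raw == {bc.id: 2}
        assert counts.umi_collapsed == {bc.id: 1}

    def test_malformed_fastq_record_skipped(self, pool20, layout):
        good = make_read(pool20.barcodes[0].sequence)
        fastq = (
            f"@ok\n{good}\n+\n{'I' * len(good)}\n"
            "not-a-header\n"
            f"@ok2\n{good}\n+\n{'I' * len(good)}\n"
        )
        counts = count_reads(_io.StringIO(fastq), pool20, layout)
        assert counts.qc[MALFORMED] == 1
        assert counts.raw == {pool20.barcodes[0].id: 2}

    def test_exhaustive_single_error_decoding_sample(self, pool20, layout):
        """Every single edit inside the barcode decodes to its source."""
        for bc in pool20.barcodes[:5]:
            for mutant in single_edits(bc.sequence):
                ext = extract(make_read(mutant), layout)
                assert ext.status == "ok"
                dec = decode_barcode(ext.window, pool20)
                assert dec.status == ASSIGNED and dec.barcode_id == bc.id
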