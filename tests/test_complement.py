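"""k-mer enumeration, mismatch-tolerant both-strand mapping, and region merging."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasmap import (
    TranscriptRecord,
    enumerate_kmers,
    filter_antisense,
    hamming_match,
    map_pool,
    merge_regions,
    reverse_complement,
)
from pasmap.complement import MatchHit

from oracles import hits_as_set, scan_pair_python, scan_pool


def _rec(seq, tx_id="t1"):
    return TranscriptRecord(tx_id, tx_id, "lncRNA", seq)


def _random_pool(rng, n_seqs, min_len, max_len, prefix="s"):
    return [
        _rec(
            "".join(rng.choice("ACGT") for _ in range(rng.randint(min_len, max_len))),
            f"{prefix}{i}",
        )
        for i in range(n_seqs)
    ]


class TestEnumerateKmers:
    def test_count_is_length_minus_k_plus_one(self):
        entries = enumerate_kmers("A" * 1000, 19)
        assert len(entries) == 982
        assert [e.offset for e in entries[:3]] == [0, 1, 2]

    def test_k_equal_to_length_gives_single_entry(self):
        entries = enumerate_kmers("ACGTACGT", 8)
        assert len(entries) == 1 and entries[0].kmer == "ACGTACGT"

    def test_k_larger_than_length_is_error(self):
        with pytest.raises(ValueError):
            enumerate_kmers("ACGT", 5)

    def test_ambiguous_kmers_emitted_but_flagged(self):
        entries = enumerate_kmers("ACGTNACGT", 4)
        assert len(entries) == 6
        flags = [e.matchable for e in entries]
        # windows overlapping the N (offsets 1..4) are unmatchable
        assert flags == [True, False, False, False, False, True]


class TestHammingMatch:
    def test_exact_antisense_match(self):
        target = _rec("C" * 30 + reverse_complement("ATGATGATGATGATGATGA") + "C" * 30)
        hits = hamming_match("ATGATGATGATGATGATGA", target, max_mm=0, query_id="q")
        assert len(hits) == 1
        h = hits[0]
        assert (h.strand, h.target_start, h.target_end, h.mismatches) == ("-", 30, 49, 0)

    def test_three_mismatches_not_reported_at_max_two(self):
        base = "ATGATGATGATGATGATGA"
        mutated = "CCC" + base[3:]
        target = _rec("G" * 20 + mutated + "G" * 20)
        hits = hamming_match(base, target, max_mm=2)
        assert all(not (h.strand == "+" and h.target_start == 20) for h in hits)
        hits3 = hamming_match(base, target, max_mm=3)
        assert any(h.strand == "+" and h.target_start == 20 and h.mismatches == 3
                   for h in hits3)

    def test_ambiguous_kmer_never_matches(self):
        target = _rec("ACGT" * 20)
        assert hamming_match("ACGTNACGTNACGTNACGT", target, max_mm=2) == []

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=25)
    def test_equals_python_oracle_on_random_target(self, seed):
        rng = random.Random(seed)
        kmer = "".join(rng.choice("ACGT") for _ in range(19))
        target = _rec("".join(rng.choice("ACGT") for _ in range(500)))
        hits = hamming_match(kmer, target, max_mm=2, query_id="q")
        got = {(h.target_start, h.strand, h.mismatches) for h in hits}
        expected = {
            (tstart, strand, mm)
            for (_, tstart, strand, mm) in scan_pair_python(kmer, target.sequence, 19, 2)
        }
        assert got == expected


class TestMapPool:
    def test_matches_pure_python_oracle_on_tiny_pool(self):
        rng = random.Random(11)
        pool = _random_pool(rng, 2, 40, 60)
        hits = map_pool(pool, k_values=[19, 22], max_mm=2)
        assert hits_as_set(hits) == scan_pool(pool, [19, 22], 2, engine="python")

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_matches_numpy_oracle_on_random_pools(self, seed):
        rng = random.Random(seed)
        pool = _random_pool(rng, rng.randint(2, 4), 60, 250)
        mm = rng.randint(0, 2)
        ks = [19, 22, 25]
        hits = map_pool(pool, k_values=ks, max_mm=mm)
        assert hits_as_set(hits) == scan_pool(pool, ks, mm)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=10, deadline=None)
    def test_hit_sets_monotone_in_max_mismatch(self, seed):
        rng = random.Random(seed)
        pool = _random_pool(rng, 3, 80, 200)
        previous = set()
        for mm in (0, 1, 2):
            current = hits_as_set(
                h for h in map_pool(pool, k_values=[19], max_mm=mm) if True
            )
            keys = {t[:5] for t in current}  # drop mismatch count for containment
            prev_keys = {t[:5] for t in previous}
            assert prev_keys <= keys
            previous = current

    def test_antisense_symmetry_at_zero_mismatches(self):
        block = "ATCGGATTACAGGATCCAGATTACA"  # 25 nt
        # A-flanks on both sides cannot pair with each other (A pairs with T)
        a = _rec("A" * 40 + block + "A" * 40, "A")
        b = _rec("A" * 25 + reverse_complement(block) + "A" * 25, "B")
        hits = filter_antisense(map_pool([a, b], k_values=[19], max_mm=0))
        forward = {(h.query_offset, h.target_start) for h in hits if h.query_id == "A"}
        backward = {(h.target_start, h.query_offset) for h in hits if h.query_id == "B"}
        assert forward and forward == backward

    def test_planted_25mer_yields_nested_hits_for_every_k(self):
        block = "ATCGGATTACAGGATCCAGATTACA"
        a = _rec("A" * 40 + block + "A" * 40, "A")
        b = _rec("A" * 30 + reverse_complement(block) + "A" * 30, "B")
        hits = filter_antisense(map_pool([a, b], k_values=range(19, 26), max_mm=0))
        per_k = {}
        for h in hits:
            if h.query_id == "A":
                per_k.setdefault(h.k, 0)
                per_k[h.k] += 1
        assert per_k == {k: 25 - k + 1 for k in range(19, 26)}

    def test_include_self_reports_hairpin(self):
        stem = "ATCGGATTACAGGATCCAGATTACA"
        seq = "G" * 30 + stem + "T" * 10 + reverse_complement(stem) + "G" * 30
        rec = _rec(seq, "hp")
        assert filter_antisense(map_pool([rec], k_values=[25], max_mm=0,
                                         include_self=True))
        with pytest.raises(ValueError, match="empty pool|duplicate"):
            map_pool([], k_values=[19], max_mm=0)

    def test_trivial_self_sense_match_always_excluded(self):
        rec = _rec("ACGT" * 20, "solo")
        hits = map_pool([rec], k_values=[19], max_mm=0, include_self=True)
        assert all(
            not (h.strand == "+" and h.target_start == h.query_offset) for h in hits
        )

    def test_duplicate_ids_rejected(self):
        pool = [_rec("ACGT" * 10, "x"), _rec("TTTT" * 10, "x")]
        with pytest.raises(ValueError, match="duplicate"):
            map_pool(pool)


class TestFilterAntisense:
    def _mixed(self):
        return [
            MatchHit("q", 0, "t", 0, 19, "+", 0, 19),
            MatchHit("q", 1, "t", 5, 24, "-", 1, 19),
            MatchHit("q", 2, "t", 9, 28, "-", 2, 19),
        ]

    def test_keeps_only_minus_strand_in_order(self):
        kept = filter_antisense(self._mixed())
        assert [h.query_offset for h in kept] == [1, 2]
        assert all(h.strand == "-" for h in kept)

    def test_all_plus_gives_empty(self):
        assert filter_antisense([MatchHit("q", 0, "t", 0, 19, "+", 0, 19)]) == []

    def test_idempotent(self):
        once = filter_antisense(self._mixed())
        assert filter_antisense(once) == once


class TestMergeRegions:
    def _hit(self, start, end, q="q", t="t", mm=0):
        return MatchHit(q, 0, t, start, end, "-", mm, end - start)

    def test_overlapping_hits_merge(self):
        regions = merge_regions([self._hit(10, 29), self._hit(15, 34, mm=2)])
        assert len(regions) == 1
        r = regions[0]
        assert (r.target_start, r.target_end, r.support, r.min_mismatches) == (10, 34, 2, 0)

    def test_book_ended_hits_merge(self):
        regions = merge_regions([self._hit(10, 29), self._hit(29, 48)])
        assert len(regions) == 1 and regions[0].target_end == 48

    def test_disjoint_hits_stay_separate(self):
        regions = merge_regions([self._hit(10, 29), self._hit(40, 59)])
        assert [(r.target_start, r.target_end) for r in regions] == [(10, 29), (40, 59)]

    def test_pairs_kept_apart_and_sorted(self):
        regions = merge_regions(
            [self._hit(50, 69, q="q2"), self._hit(10, 29), self._hit(5, 24, t="s")]
        )
        assert [(r.query_id, r.target_id, r.target_start) for r in regions] == [
            ("q", "s", 5),
            ("q", "t", 10),
            ("q2", "t", 50),
        ]
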