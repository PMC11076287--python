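"""Search-set filtering, terminal-window PAS scanning, and variant assignment."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasmap import (
    PASHit,
    assign_pas,
    count_tandem,
    filter_search_set,
    scan_pas_window,
)

from oracles import find_hexamers_bruteforce


def _seq_with_window(window: str, total_len: int = 300, fill: str = "C") -> str:
    assert len(window) == 50
    return fill * (total_len - 50) + window


class TestFilterSearchSet:
    def test_short_transcript_excluded(self, make_record):
        rec = make_record("A" * 150)
        kept, excluded = filter_search_set([rec])
        assert kept == []
        assert excluded[0].reason == "short"
        assert excluded[0].excluded and excluded[0].n_total_hits == 0

    def test_boundary_length_exactly_min_len_excluded(self, make_record):
        # "greater than 200 nucleotides": 200 itself does not pass
        kept, excluded = filter_search_set([make_record("A" * 200)])
        assert kept == [] and excluded[0].reason == "short"
        kept, excluded = filter_search_set([make_record("A" * 201)])
        assert len(kept) == 1 and excluded == []

    def test_ambiguous_base_in_terminal_window_excluded(self, make_record):
        seq = "A" * 290 + "N" + "A" * 9  # N at position length-10
        kept, excluded = filter_search_set([make_record(seq)])
        assert kept == [] and excluded[0].reason == "ambiguous_window"

    def test_ambiguous_base_outside_windows_kept(self, make_record):
        seq = "A" * 5 + "N" + "A" * 294
        kept, excluded = filter_search_set([make_record(seq)])
        assert len(kept) == 1 and excluded == []

    def test_ambiguous_downstream_window_excluded(self, make_record):
        rec = make_record("A" * 300)
        kept, excluded = filter_search_set(
            [rec], downstream_windows={rec.transcript_id: "A" * 20 + "N" + "A" * 29}
        )
        assert kept == [] and excluded[0].reason == "ambiguous_window"

    def test_window_larger_than_min_len_is_config_error(self, make_record):
        with pytest.raises(ValueError, match="window"):
            filter_search_set([make_record("A" * 300)], min_len=40, window=50)


class TestScanPasWindow:
    def test_single_planted_consensus(self, default_table):
        seq = "C" * 60 + "AATAAA" + "C" * 10
        hits = scan_pas_window(seq, default_table)
        assert [(h.hexamer, h.offset_from_3prime) for h in hits] == [("AATAAA", 10)]

    def test_hexamer_must_lie_fully_inside_window(self, default_table):
        # L=100, window=50: starts < 50 leave a base outside the window
        inside = "C" * 50 + "AATAAA" + "C" * 44
        assert len(scan_pas_window(inside, default_table)) == 1
        straddling = "C" * 49 + "AATAAA" + "C" * 45
        assert scan_pas_window(straddling, default_table) == []

    def test_overlapping_occurrences_all_reported(self, default_table):
        seq = _seq_with_window("AATAAATAAA".ljust(50, "C"))
        hits = scan_pas_window(seq, default_table)
        consensus = [h for h in hits if h.hexamer == "AATAAA"]
        assert len(consensus) == 2  # starts 0 and 4 of the window

    def test_sequence_shorter_than_window_rejected(self, default_table):
        with pytest.raises(ValueError, match="shorter"):
            scan_pas_window("ACGT" * 10, default_table)

    def test_ambiguous_window_rejected(self, default_table):
        with pytest.raises(ValueError, match="ambiguous"):
            scan_pas_window("C" * 60 + "N" + "C" * 10, default_table)

    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    @settings(derandomize=True, max_examples=300)
    def test_equals_bruteforce_on_random_sequences(self, default_table, seed):
        rng = random.Random(seed)
        L = rng.randint(50, 5000)
        seq = "".join(rng.choice("ACGT") for _ in range(min(L, 400)))
        seq = seq * (L // len(seq) + 1)
        seq = seq[:L]
        hits = scan_pas_window(seq, default_table)
        got = {(h.hexamer, h.offset_from_3prime) for h in hits}
        expected = find_hexamers_bruteforce(seq, default_table.hexamers, 50)
        assert got == expected

    @given(
        seq=st.text(alphabet="ACGT", min_size=50, max_size=200),
        prefix=st.text(alphabet="ACGT", min_size=0, max_size=100),
    )
    @settings(derandomize=True, max_examples=100)
    def test_prepending_5prime_bases_preserves_offsets(self, default_table, seq, prefix):
        base = {(h.hexamer, h.offset_from_3prime) for h in scan_pas_window(seq, default_table)}
        extended = {
            (h.hexamer, h.offset_from_3prime)
            for h in scan_pas_window(prefix + seq, default_table)
        }
        assert base == extended


class TestAssignPas:
    def test_consensus_beats_variant(self, default_table):
        hits = [PASHit("tx1", "ATTAAA", 20), PASHit("tx1", "AATAAA", 5)]
        call = assign_pas(hits, default_table)
        assert call.assigned_variant == "AATAAA"
        assert call.n_distinct_variants == 2 and call.n_total_hits == 2

    def test_no_hits_gives_none(self, default_table):
        call = assign_pas([], default_table, transcript_id="tx1")
        assert call.assigned_variant is None
        assert call.n_distinct_variants == 0 and call.n_total_hits == 0

    def test_equal_distance_broken_by_usage_rank(self, default_table):
        # ATTAAA (rank 2) and TATAAA (rank 3) are both one substitution away
        hits = [PASHit("tx1", "TATAAA", 8), PASHit("tx1", "ATTAAA", 30)]
        assert assign_pas(hits, default_table).assigned_variant == "ATTAAA"

    def test_permutation_invariant(self, default_table):
        import itertools

        hits = [
            PASHit("tx1", "AATAAA", 3),
            PASHit("tx1", "ATTAAA", 12),
            PASHit("tx1", "AAGAAA", 25),
        ]
        variants = {
            assign_pas(list(p), default_table).assigned_variant
            for p in itertools.permutations(hits)
        }
        assert variants == {"AATAAA"}

    def test_unknown_hexamer_is_error(self, default_table):
        with pytest.raises(ValueError, match="not in variant table"):
            assign_pas([PASHit("tx1", "CCCCCC", 0)], default_table)

    def test_hits_from_multiple_transcripts_rejected(self, default_table):
        hits = [PASHit("tx1", "AATAAA", 0), PASHit("tx2", "AATAAA", 0)]
        with pytest.raises(ValueError, match="multiple transcripts"):
            assign_pas(hits, default_table)


class TestCountTandem:
    def test_single_hit_not_tandem(self):
        assert count_tandem([PASHit("t", "AATAAA", 5)]) == 1

    def test_three_distinct_offsets(self):
        hits = [PASHit("t", "AATAAA", o) for o in (5, 15, 25)]
        assert count_tandem(hits) == 3

    def test_overlapping_hits_counted_separately(self, default_table):
        # AATAAATAAA: two overlapping consensus occurrences at distinct starts
        seq = _seq_with_window("AATAAATAAA".ljust(50, "C"))
        hits = scan_pas_window(seq, default_table)
        assert count_tandem(hits) == len({h.offset_from_3prime for h in hits})
        assert count_tandem(hits) >= 2
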