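"""Mismatch-tolerant k-mer mapping for antisense complementarity among lncRNAs.

Every k-mer of each query sequence (k typically 19-25, sliding window, all
L - k + 1 of them) is compared against every position of every other pool
sequence on both strands, counting full-length Hamming mismatches (no
indels).  Antisense hits — the query fragment matching the reverse
complement of the target sense strand — indicate RNA:RNA base-pairing
potential; overlapping antisense hits are merged into complementary regions.

The all-pairs mismatch counts are computed by accumulating a base-equality
matrix along its diagonals, which gives every (query offset, target offset)
alignment in one vectorized pass per k.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .seqio import TranscriptRecord

Strand = Literal["+", "-"]

# Base codes: A,C,G,T -> 0..3 so that complement(c) = 3 - c; anything else is
# unmatchable (codes chosen so query 254 never equals target 255).
_ENCODE = np.full(256, 254, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rc_codes(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, np.uint8(255))[::-1]


@dataclass(frozen=True)
class KmerEntry:
    query_id: str
    offset: int  # 0-based start within the query
    kmer: str
    matchable: bool  # False when the k-mer contains a non-ACGT base


@dataclass(frozen=True)
class KmerDataset:
    """All k-mers of one length drawn from a set of query sequences."""

    k: int
    entries: tuple[KmerEntry, ...]


@dataclass(frozen=True)
class MatchHit:
    """One k-mer-to-target alignment.

    Coordinates are 0-based half-open on the *target sense strand*; strand
    '-' means the k-mer matches the reverse complement of that substring.
    """

    query_id: str
    query_offset: int
    target_id: str
    target_start: int
    target_end: int
    strand: Strand
    mismatches: int
    k: int


@dataclass(frozen=True)
class ComplementRegion:
    """Union of overlapping/book-ended antisense hits for one (query, target) pair."""

    query_id: str
    target_id: str
    target_start: int
    target_end: int
    support: int
    min_mismatches: int


def enumerate_kmers(seq: str, k: int, query_id: str = "") -> list[KmerEntry]:
    """All L - k + 1 contiguous k-mers, offsets consecutive from 0.

    k-mers containing ambiguity codes are emitted but flagged unmatchable.
    """
    L = len(seq)
    if k < 1 or k > L:
        raise ValueError(f"k={k} invalid for sequence of length {L}")
    acgt = frozenset("ACGT")
    return [
        KmerEntry(query_id, i, seq[i : i + k], set(seq[i : i + k]) <= acgt)
        for i in range(L - k + 1)
    ]


def build_kmer_dataset(records: Sequence[TranscriptRecord], k: int) -> KmerDataset:
    entries: list[KmerEntry] = []
    for rec in records:
        if len(rec) >= k:
            entries.extend(enumerate_kmers(rec.sequence, k, rec.transcript_id))
    return KmerDataset(k, tuple(entries))


def _mismatch_matrix(q: np.ndarray, t: np.ndarray, k: int) -> np.ndarray:
    """Hamming mismatch counts for every (query offset, target offset) pair.

    Entry [i, j] is the mismatch count of q[i:i+k] vs t[j:j+k]; computed by
    summing the equality matrix over the k diagonals of the alignment.
    """
    nq, nt = len(q) - k + 1, len(t) - k + 1
    eq = q[:, None] == t[None, :]
    acc = np.zeros((nq, nt), dtype=np.int16)
    for a in range(k):
        acc += eq[a : a + nq, a : a + nt]
    return (k - acc).astype(np.int16)


def _pair_hits(
    q_codes: np.ndarray,
    t_codes: np.ndarray,
    k: int,
    max_mm: int,
) -> list[tuple[int, int, Strand, int]]:
    """(query_offset, target_sense_start, strand, mismatches) for one pair and k."""
    Lq, Lt = len(q_codes), len(t_codes)
    if k > Lq or k > Lt:
        return []
    out: list[tuple[int, int, Strand, int]] = []

    mm = _mismatch_matrix(q_codes, t_codes, k)
    for i, j in zip(*np.nonzero(mm <= max_mm)):
        out.append((int(i), int(j), "+", int(mm[i, j])))

    mm_rc = _mismatch_matrix(q_codes, _rc_codes(t_codes), k)
    for i, jr in zip(*np.nonzero(mm_rc <= max_mm)):
        # position jr on the reverse strand maps to sense start Lt - jr - k
        out.append((int(i), int(Lt - jr - k), "-", int(mm_rc[i, jr])))
    return out


def hamming_match(
    kmer: str,
    target: TranscriptRecord,
    max_mm: int,
    query_id: str = "",
    query_offset: int = 0,
) -> list[MatchHit]:
    """All positions of ``target`` (both strands) within ``max_mm`` of ``kmer``.

    Full-length Hamming distance, no indels; a '-' hit means the k-mer
    matches the reverse complement of the reported sense-strand substring.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    k = len(kmer)
    q = encode(kmer)
    if (q > 3).any():
        return []  # unmatchable k-mer
    hits = [
        MatchHit(
            query_id=query_id,
            query_offset=query_offset + qoff,
            target_id=target.transcript_id,
            target_start=start,
            target_end=start + k,
            strand=strand,
            mismatches=mm,
            k=k,
        )
        for qoff, start, strand, mm in _pair_hits(q, encode(target.sequence), k, max_mm)
    ]
    hits.sort(key=lambda h: (h.strand, h.target_start))
    return hits


def map_pool(
    pool: Sequence[TranscriptRecord],
    k_values: Iterable[int] = range(19, 26),
    max_mm: int = 2,
    include_self: bool = False,
) -> list[MatchHit]:
    """Map every k-mer of every pool sequence against the whole pool.

    Self-pairs are excluded unless ``include_self``; the degenerate exact
    sense self-match of a k-mer at its own coordinates is always excluded.
    Unmatchable k-mers (ambiguity codes) never produce hits.  Output order is
    deterministic: (query, target, k, strand, target_start, query_offset).
    """
    ids = [r.transcript_id for r in pool]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate transcript ids in pool")
    if not pool:
        raise ValueError("empty pool")
    k_values = sorted(set(k_values))
    if not k_values:
        raise ValueError("no k values supplied")

    codes = {r.transcript_id: encode(r.sequence) for r in pool}
    # offsets whose k-mer contains an ambiguous base, per (id, k)
    hits: list[MatchHit] = []
    for query in pool:
        q_codes = codes[query.transcript_id]
        q_bad = q_codes > 3
        for target in pool:
            if target.transcript_id == query.transcript_id and not include_self:
                continue
            t_codes = codes[target.transcript_id]
            for k in k_values:
                if k > len(q_codes) or k > len(t_codes):
                    continue
                if q_bad.any():
                    bad_counts = np.convolve(q_bad.astype(int), np.ones(k, int), "valid")
                else:
                    bad_counts = None
                for qoff, start, strand, mm in _pair_hits(q_codes, t_codes, k, max_mm):
                    if bad_counts is not None and bad_counts[qoff] > 0:
                        continue  # k-mer spans an ambiguity code: unmatchable
                    if (
                        target.transcript_id == query.transcript_id
                        and strand == "+"
                        and start == qoff
                    ):
                        continue  # trivial self sense-match at own coordinates
                    hits.append(
                        MatchHit(
                            query_id=query.transcript_id,
                            query_offset=qoff,
                            target_id=target.transcript_id,
                            target_start=start,
                            target_end=start + k,
                            strand=strand,
                            mismatches=mm,
                            k=k,
                        )
                    )
    hits.sort(
        key=lambda h: (
            h.query_id,
            h.target_id,
            h.k,
            h.strand,
            h.target_start,
            h.query_offset,
        )
    )
    return hits


def filter_antisense(hits: Iterable[MatchHit]) -> list[MatchHit]:
    """Keep exactly the '-' (antisense) hits, order preserved; idempotent."""
    return [h for h in hits if h.strand == "-"]


def merge_regions(hits: Iterable[MatchHit]) -> list[ComplementRegion]:
    """Merge overlapping/book-ended hit intervals per (query, target) pair.

    Intended for antisense-filtered hits.  Book-ended means gap 0 (end of one
    interval equals start of the next).  Output sorted by (query, target,
    start); each region records its supporting hit count and the minimum
    mismatch count among supporters.
    """
    by_pair: dict[tuple[str, str], list[MatchHit]] = {}
    for h in hits:
        by_pair.setdefault((h.query_id, h.target_id), []).append(h)

    regions: list[ComplementRegion] = []
    for (qid, tid), pair_hits in sorted(by_pair.items()):
        pair_hits.sort(key=lambda h: (h.target_start, h.target_end))
        cur_start, cur_end = pair_hits[0].target_start, pair_hits[0].target_end
        cur_support, cur_mm = 1, pair_hits[0].mismatches
        for h in pair_hits[1:]:
            if h.target_start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, h.target_end)
                cur_support += 1
                cur_mm = min(cur_mm, h.mismatches)
            else:
                regions.append(
                    ComplementRegion(qid, tid, cur_start, cur_end, cur_support, cur_mm)
                )
                cur_start, cur_end = h.target_start, h.target_end
                cur_support, cur_mm = 1, h.mismatches
        regions.append(
            ComplementRegion(qid, tid, cur_start, cur_end, cur_support, cur_mm)
        )
    return regions
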