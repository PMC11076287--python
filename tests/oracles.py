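"""Independent reference implementations used to check the package.

Everything here is written from the definitions (per-position Hamming
counting, per-start substring comparison) without reusing the package's
scanning code, so agreement is a genuine two-route check.  The numpy variant
compares one k-mer at a time against a window view of the target, unlike the
production scanner's all-pairs diagonal accumulation.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def scan_pair_python(
    qseq: str, tseq: str, k: int, max_mm: int
) -> set[tuple[int, int, str, int]]:
    """Pure-Python all-positions both-strands scan: {(qoff, tstart, strand, mm)}."""
    out = set()
    rc_t = rc(tseq)
    Lt = len(tseq)
    for qoff in range(len(qseq) - k + 1):
        kmer = qseq[qoff : qoff + k]
        if set(kmer) - set("ACGT"):
            continue
        for tstart in range(Lt - k + 1):
            mm = hamming(kmer, tseq[tstart : tstart + k])
            if mm <= max_mm:
                out.add((qoff, tstart, "+", mm))
        for jr in range(Lt - k + 1):
            mm = hamming(kmer, rc_t[jr : jr + k])
            if mm <= max_mm:
                out.add((qoff, Lt - jr - k, "-", mm))
    return out


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def _enc(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def scan_pair_numpy(
    qseq: str, tseq: str, k: int, max_mm: int
) -> set[tuple[int, int, str, int]]:
    """Per-k-mer numpy scan (windowed target view), same output convention."""
    out: set[tuple[int, int, str, int]] = set()
    if len(qseq) < k or len(tseq) < k:
        return out
    t = np.lib.stride_tricks.sliding_window_view(_enc(tseq), k)
    t_rc = np.lib.stride_tricks.sliding_window_view(_enc(rc(tseq)), k)
    Lt = len(tseq)
    for qoff in range(len(qseq) - k + 1):
        kmer = qseq[qoff : qoff + k]
        if set(kmer) - set("ACGT"):
            continue
        kv = _enc(kmer)
        for tstart in np.nonzero((t != kv).sum(axis=1) <= max_mm)[0]:
            out.add((qoff, int(tstart), "+", int((t[tstart] != kv).sum())))
        for jr in np.nonzero((t_rc != kv).sum(axis=1) <= max_mm)[0]:
            out.add((qoff, int(Lt - int(jr) - k), "-", int((t_rc[jr] != kv).sum())))
    return out


def scan_pool(
    pool, k_values, max_mm: int, include_self: bool = False, engine: str = "numpy"
) -> set[tuple[str, int, str, int, str, int, int]]:
    """Oracle pool scan with the same exclusion rules as the production mapper.

    Returns {(query_id, qoff, target_id, tstart, strand, mm, k)}.
    """
    scan = scan_pair_numpy if engine == "numpy" else scan_pair_python
    out = set()
    for query in pool:
        for target in pool:
            if query.transcript_id == target.transcript_id and not include_self:
                continue
            for k in k_values:
                if k > len(query.sequence) or k > len(target.sequence):
                    continue
                for qoff, tstart, strand, mm in scan(
                    query.sequence, target.sequence, k, max_mm
                ):
                    if (
                        query.transcript_id == target.transcript_id
                        and strand == "+"
                        and qoff == tstart
                    ):
                        continue
                    out.add(
                        (
                            query.transcript_id,
                            qoff,
                            target.transcript_id,
                            tstart,
                            strand,
                            mm,
                            k,
                        )
                    )
    return out


def hits_as_set(hits) -> set[tuple[str, int, str, int, str, int, int]]:
    """Project production MatchHit objects onto the oracle tuple convention."""
    return {
        (h.query_id, h.query_offset, h.target_id, h.target_start, h.strand,
         h.mismatches, h.k)
        for h in hits
    }


def find_hexamers_bruteforce(seq: str, hexamers, window: int) -> set[tuple[str, int]]:
    """{(hexamer, offset_from_3prime)} by checking every start in the last window."""
    L = len(seq)
    out = set()
    for start in range(max(0, L - window), L - 6 + 1):
        sub = seq[start : start + 6]
        if sub in set(hexamers):
            out.add((sub, L - (start + 6)))
    return out
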