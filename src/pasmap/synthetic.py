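"""Seeded synthetic data with ground truth for every pipeline stage.

Two generators are provided.  The transcript generator emulates the
statistical structure of the PAS survey: two gene classes, i.i.d. background
at a chosen base composition, one PAS hexamer per transcript planted inside
the terminal 50-nt window at per-variant rates, a downstream window with a
DSE planted at its own rate, and optional ambiguity injection to exercise
the search-set filter.  The pool generator emulates pairwise antisense
complementarity: reverse-complement blocks copied between pool sequences
with an exact (not maximum) number of substitutions.

Unplanted structure is rejection-sampled away: terminal windows of
"unplanted" transcripts contain no table hexamer at all, downstream windows
of DSE-negative transcripts contain no pattern match, and pool backgrounds
contain no accidental >=19-mer antisense match at <= 2 mismatches (verified
with a windowed brute-force check that is independent of the production
scanner).  Every generator is driven by a single integer seed; no global
random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dse_scan import DSEPattern, SequenceLogo, build_dse_pattern
from .pas_scan import PASVariantTable
from .seqio import TranscriptRecord, reverse_complement

_BASES = "ACGT"
_MAX_ATTEMPTS = 1000


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_seq(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(4, size=length, p=probs)
    return "".join(_BASES[i] for i in idx)


def _comp_probs(base_composition: dict[str, float]) -> np.ndarray:
    probs = np.array([base_composition[b] for b in _BASES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-6 or (probs < 0).any():
        raise ValueError("base composition must be a distribution over A,C,G,T")
    return probs


# ---------------------------------------------------------------------------
# transcripts with planted PAS / DSE motifs


@dataclass
class TranscriptSynthConfig:
    """Study conditions for the synthetic PAS/DSE transcript sets.

    ``pas_rates`` maps gene class -> {hexamer: probability}; with the
    remaining probability a transcript carries no planted PAS (and its
    terminal window is guaranteed free of every table hexamer).  Defaults
    emulate the headline prevalences of the fly transcriptome survey this
    package reproduces: consensus AATAAA in 60% of protein-coding genes and
    23% of lncRNA genes, with a smaller share of single-substitution
    variants in both classes.
    """

    seed: int
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"mRNA": 2000, "lncRNA": 2000}
    )
    length_range: tuple[int, int] = (400, 1500)
    base_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29}
    )
    pas_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "mRNA": {"AATAAA": 0.60, "ATTAAA": 0.12, "TATAAA": 0.05},
            "lncRNA": {"AATAAA": 0.23, "ATTAAA": 0.08, "TATAAA": 0.05},
        }
    )
    dse_rate: float = 0.60
    ambiguous_rate: float = 0.0
    window: int = 50
    downstream_window: int = 50
    variant_table: Optional[PASVariantTable] = None
    dse_pattern: Optional[DSEPattern] = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid length range {self.length_range}")
        if lo < self.window:
            raise ValueError("minimum length must cover the search window")
        for rates in self.pas_rates.values():
            if any(not (0 <= r <= 1) for r in rates.values()) or sum(rates.values()) > 1:
                raise ValueError("per-variant rates must lie in [0,1] and sum to <= 1")
        if not (0 <= self.dse_rate <= 1 and 0 <= self.ambiguous_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


def _window_free_of_hexamers(window: str, hexamers: Sequence[str]) -> bool:
    return not any(h in window for h in hexamers)


def _hexamer_occurrences(window: str, hexamers: Sequence[str]) -> set[tuple[str, int]]:
    occ = set()
    for h in hexamers:
        start = window.find(h)
        while start != -1:
            occ.add((h, start))
            start = window.find(h, start + 1)
    return occ


def _pattern_matches(window: str, pattern: DSEPattern) -> list[int]:
    m = len(pattern)
    return [
        s
        for s in range(len(window) - m + 1)
        if all(window[s + i] in pattern.allowed[i] for i in range(m))
    ]


def _sample_window(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    hexamers: Sequence[str],
    plant: Optional[str],
) -> tuple[str, int]:
    """A window containing exactly the planted hexamer (or none at all)."""
    for _ in range(_MAX_ATTEMPTS):
        window = _random_seq(rng, length, probs)
        if plant is None:
            if _window_free_of_hexamers(window, hexamers):
                return window, -1
            continue
        pos = int(rng.integers(0, length - len(plant) + 1))
        planted = window[:pos] + plant + window[pos + len(plant) :]
        if _hexamer_occurrences(planted, hexamers) == {(plant, pos)}:
            return planted, pos
    raise RuntimeError(
        "window rejection sampling failed; lower the motif density or GC content"
    )


def _sample_dse_window(
    rng: np.random.Generator,
    length: int,
    probs: np.ndarray,
    pattern: DSEPattern,
    plant: bool,
) -> tuple[str, int]:
    m = len(pattern)
    for _ in range(_MAX_ATTEMPTS):
        window = _random_seq(rng, length, probs)
        if not _pattern_matches(window, pattern):
            if not plant:
                return window, -1
            pos = int(rng.integers(0, length - m + 1))
            motif = "".join(
                sorted(pattern.allowed[i])[int(rng.integers(0, len(pattern.allowed[i])))]
                for i in range(m)
            )
            planted = window[:pos] + motif + window[pos + m :]
            if _pattern_matches(planted, pattern):
                return planted, pos
    raise RuntimeError(
        "DSE window rejection sampling failed; loosen the pattern or composition"
    )


def generate_transcripts(
    config: TranscriptSynthConfig,
) -> tuple[list[TranscriptRecord], pd.DataFrame, dict[str, str]]:
    """Synthesize transcripts + truth ledger + downstream windows.

    Returns ``(records, truth, downstream_windows)``.  The truth frame has
    one row per record: planted variant ('' if none), its window position,
    DSE planting, ambiguity injection, and whether the record is short.
    Deterministic given the config seed.
    """
    rng = _rng(config.seed)
    probs = _comp_probs(config.base_composition)
    table = config.variant_table or PASVariantTable.default()
    pattern = config.dse_pattern or build_dse_pattern(SequenceLogo.default())
    hexamers = table.hexamers

    records: list[TranscriptRecord] = []
    truth_rows = []
    downstream: dict[str, str] = {}
    counter = 0
    for gene_class in sorted(config.n_per_class):
        rates = config.pas_rates.get(gene_class, {})
        variants = sorted(rates)
        cum = np.cumsum([rates[v] for v in variants])
        for _ in range(config.n_per_class[gene_class]):
            counter += 1
            tx_id = f"T{counter:05d}"
            gene_id = f"G{counter:05d}"
            L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))

            u = rng.random()
            planted: Optional[str] = None
            for v, edge in zip(variants, cum):
                if u < edge:
                    planted = v
                    break

            body = _random_seq(rng, L - config.window, probs)
            window, pos_in_window = _sample_window(
                rng, config.window, probs, hexamers, planted
            )
            dse_plant = bool(rng.random() < config.dse_rate)
            ds_window, dse_pos = _sample_dse_window(
                rng, config.downstream_window, probs, pattern, dse_plant
            )

            ambiguous = bool(rng.random() < config.ambiguous_rate)
            if ambiguous:
                n_pos = int(rng.integers(0, config.window))
                window = window[:n_pos] + "N" + window[n_pos + 1 :]

            records.append(
                TranscriptRecord(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    gene_class=gene_class,  # type: ignore[arg-type]
                    sequence=body + window,
                )
            )
            downstream[tx_id] = ds_window
            truth_rows.append(
                {
                    "transcript_id": tx_id,
                    "gene_id": gene_id,
                    "gene_class": gene_class,
                    "length": L,
                    "planted_variant": planted or "",
                    "planted_window_start": pos_in_window,
                    "dse_planted": dse_plant,
                    "dse_start": dse_pos,
                    "ambiguous": ambiguous,
                    "short": L <= 200,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return records, truth, downstream


# ---------------------------------------------------------------------------
# lncRNA pools with planted antisense blocks


def mutate_block(block: str, d: int, seed) -> str:
    """Substitute exactly ``d`` positions, each to a different base.

    The result is at Hamming distance exactly ``d`` from the input (``d`` is
    exact, not a maximum).  ``seed`` may be an int or a Generator.
    """
    if d < 0:
        raise ValueError("mismatch count must be >= 0")
    if d > len(block):
        raise ValueError(f"cannot place {d} mismatches in a block of length {len(block)}")
    rng = _rng(seed)
    positions = rng.choice(len(block), size=d, replace=False)
    chars = list(block)
    for p in positions:
        alternatives = [b for b in _BASES if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


@dataclass(frozen=True)
class PlantedBlock:
    """One reverse-complement block copied from a query into a target."""

    query_index: int
    target_index: int
    length: int  # in [19, 60]
    mismatches: int  # exact substitution count, 0-2
    target_pos: int
    query_pos: Optional[int] = None  # random if omitted

    def __post_init__(self) -> None:
        if not (19 <= self.length <= 60):
            raise ValueError("planted block length must be in [19, 60]")
        if self.mismatches not in (0, 1, 2):
            raise ValueError("planted mismatch count must be 0, 1 or 2")


@dataclass
class PoolSynthConfig:
    seed: int
    n_sequences: int = 4
    length_range: tuple[int, int] = (300, 600)
    base_composition: dict[str, float] = field(
        default_factory=lambda: {"A": 0.29, "C": 0.21, "G": 0.21, "T": 0.29}
    )
    planted_blocks: list[PlantedBlock] = field(default_factory=list)
    id_prefix: str = "lnc"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_sequences < 1:
            raise ValueError("pool must contain at least one sequence")
        for b in self.planted_blocks:
            for idx in (b.query_index, b.target_index):
                if not (0 <= idx < self.n_sequences):
                    raise ValueError(f"block index {idx} outside pool")
            if b.query_index == b.target_index:
                raise ValueError("planted blocks must link two distinct sequences")


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i


def _enc(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _antisense_hit_starts(
    query: str, target: str, k: int = 19, max_mm: int = 2
) -> list[tuple[int, int]]:
    """Brute-force (query_offset, target_sense_start) antisense matches.

    Window-by-window Hamming counting against the reverse-complemented
    target; independent of the production diagonal-sum scanner and used only
    to certify generated backgrounds.
    """
    if len(query) < k or len(target) < k:
        return []
    q = np.lib.stride_tricks.sliding_window_view(_enc(query), k)
    rc_t = _enc(reverse_complement(target))
    t = np.lib.stride_tricks.sliding_window_view(rc_t, k)
    Lt = len(target)
    out = []
    for i in range(q.shape[0]):  # per-k-mer scan keeps memory flat
        mm = (t != q[i]).sum(axis=1)
        for jr in np.nonzero(mm <= max_mm)[0]:
            out.append((i, int(Lt - int(jr) - k)))
    return out


def generate_complement_pool(
    config: PoolSynthConfig,
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Synthesize a sequence pool with planted antisense blocks + truth ledger.

    Each planted block writes ``mutate_block(rc(query block), d)`` into its
    target.  The background is rejection-sampled so that no unplanned
    antisense 19-mer match at <= 2 mismatches exists between any pair, both
    before and after planting; failure after the attempt bound raises with a
    hint to use longer sequences or a lower-GC composition.
    """
    rng = _rng(config.seed)
    probs = _comp_probs(config.base_composition)
    lo, hi = config.length_range

    for attempt in range(_MAX_ATTEMPTS):
        lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_sequences)]
        for b in config.planted_blocks:
            if b.target_pos + b.length > lengths[b.target_index]:
                raise ValueError(
                    f"planted block (len {b.length} at {b.target_pos}) does not fit "
                    f"in target sequence of length {lengths[b.target_index]}"
                )
            if b.query_pos is not None and b.query_pos + b.length > lengths[b.query_index]:
                raise ValueError("planted block does not fit in query sequence")
        seqs = [_random_seq(rng, L, probs) for L in lengths]

        # clean background: no accidental antisense match between any pair
        clean = True
        for i in range(len(seqs)):
            for j in range(len(seqs)):
                if i != j and _antisense_hit_starts(seqs[i], seqs[j]):
                    clean = False
                    break
            if not clean:
                break
        if not clean:
            continue

        # plant blocks; target regions must not collide
        used: dict[int, list[tuple[int, int]]] = {}
        qpos: list[int] = []
        ok = True
        for b in config.planted_blocks:
            q0 = (
                b.query_pos
                if b.query_pos is not None
                else int(rng.integers(0, lengths[b.query_index] - b.length + 1))
            )
            qpos.append(q0)
            for s, e in used.get(b.target_index, []):
                if not (b.target_pos + b.length <= s or e <= b.target_pos):
                    raise ValueError("planted blocks overlap on a target sequence")
            used.setdefault(b.target_index, []).append(
                (b.target_pos, b.target_pos + b.length)
            )
            block = seqs[b.query_index][q0 : q0 + b.length]
            payload = mutate_block(reverse_complement(block), b.mismatches, rng)
            t = seqs[b.target_index]
            t = t[: b.target_pos] + payload + t[b.target_pos + b.length :]
            # guard bases: the target base flanking the payload must not
            # complement the adjacent query base, so the match footprint is
            # exactly the planted interval
            qseq = seqs[b.query_index]
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            own = (b.target_pos, b.target_pos + b.length)
            for t_idx, q_idx in (
                (b.target_pos - 1, q0 + b.length),
                (b.target_pos + b.length, q0 - 1),
            ):
                if not (0 <= t_idx < len(t) and 0 <= q_idx < len(qseq)):
                    continue
                if any(
                    s <= t_idx < e
                    for s, e in used.get(b.target_index, [])
                    if (s, e) != own
                ):
                    continue  # inside another planted block: leave untouched
                paired = comp[qseq[q_idx]]
                if t[t_idx] == paired:
                    choices = [x for x in _BASES if x != paired]
                    t = t[:t_idx] + choices[int(rng.integers(0, 3))] + t[t_idx + 1 :]
            seqs[b.target_index] = t

        # post-plant audit: every antisense hit must touch a planted footprint
        allowed: dict[tuple[int, int], list[tuple[int, int]]] = {}
        for bi, b in enumerate(config.planted_blocks):
            allowed.setdefault((b.query_index, b.target_index), []).append(
                (b.target_pos, b.target_pos + b.length)
            )
            allowed.setdefault((b.target_index, b.query_index), []).append(
                (qpos[bi], qpos[bi] + b.length)
            )
        for i in range(len(seqs)):
            for j in range(len(seqs)):
                if i == j:
                    continue
                for _, tstart in _antisense_hit_starts(seqs[i], seqs[j]):
                    spans = allowed.get((i, j), [])
                    if not any(tstart < e and tstart + 19 > s for s, e in spans):
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue

        records = [
            TranscriptRecord(
                transcript_id=f"{config.id_prefix}{i + 1:03d}",
                gene_id=f"{config.id_prefix}{i + 1:03d}",
                gene_class="lncRNA",
                sequence=seq,
            )
            for i, seq in enumerate(seqs)
        ]
        truth = pd.DataFrame(
            [
                {
                    "block_id": bi,
                    "query_id": records[b.query_index].transcript_id,
                    "target_id": records[b.target_index].transcript_id,
                    "query_start": qpos[bi],
                    "target_start": b.target_pos,
                    "length": b.length,
                    "mismatches": b.mismatches,
                }
                for bi, b in enumerate(config.planted_blocks)
            ],
            columns=[
                "block_id",
                "query_id",
                "target_id",
                "query_start",
                "target_start",
                "length",
                "mismatches",
            ],
        )
        return records, truth

    raise RuntimeError(
        "pool rejection sampling failed after "
        f"{_MAX_ATTEMPTS} attempts; try longer sequences or lower GC content"
    )
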