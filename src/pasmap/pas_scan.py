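"""Polyadenylation-signal (PAS) hexamer scanning of transcript 3' ends.

The search set is filtered to transcripts longer than a minimum length whose
terminal search window (and, when available, genomic downstream window)
contains only unambiguous bases.  The last ``window`` nucleotides of each
surviving transcript are scanned on the sense strand for every hexamer in a
variant table; when several variants are found, the one closest to the
AATAAA consensus wins, with usage rank breaking ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from .seqio import GeneClass, TranscriptRecord

CONSENSUS = "AATAAA"

ExclusionReason = Literal["short", "ambiguous_window", "none"]

_ACGT = set("ACGT")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class PASVariant:
    hexamer: str
    consensus_distance: int
    usage_rank: int


class PASVariantTable:
    """Ordered table of PAS hexamer variants.

    Entries are held sorted by (consensus distance, usage rank); that pair is
    also the assignment key.  The consensus AATAAA must be present with
    distance 0 and rank 1.
    """

    def __init__(self, variants: Sequence[PASVariant]):
        hexamers = [v.hexamer for v in variants]
        if len(set(hexamers)) != len(hexamers):
            raise ValueError("duplicate hexamers in PAS variant table")
        for v in variants:
            if len(v.hexamer) != 6 or set(v.hexamer) - _ACGT:
                raise ValueError(f"invalid hexamer {v.hexamer!r}")
            if v.consensus_distance != hamming(v.hexamer, CONSENSUS):
                raise ValueError(
                    f"{v.hexamer}: stated consensus distance {v.consensus_distance} "
                    f"!= actual {hamming(v.hexamer, CONSENSUS)}"
                )
        by_hex = {v.hexamer: v for v in variants}
        consensus = by_hex.get(CONSENSUS)
        if consensus is None or consensus.usage_rank != 1:
            raise ValueError("table must contain AATAAA with usage rank 1")
        self._variants = sorted(
            variants, key=lambda v: (v.consensus_distance, v.usage_rank)
        )
        self._by_hex = by_hex

    @classmethod
    def from_ranks(cls, ranked_hexamers: Sequence[str]) -> "PASVariantTable":
        """Build a table from hexamers listed in usage order (rank 1 first)."""
        return cls(
            [
                PASVariant(h, hamming(h, CONSENSUS), rank)
                for rank, h in enumerate(ranked_hexamers, start=1)
            ]
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PASVariantTable":
        """Read a two-column delimited file (hexamer, usage_rank); '#' comments."""
        entries: list[tuple[int, str]] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.replace(",", "\t").split()
                hexamer, rank = parts[0].upper(), int(parts[1])
                entries.append((rank, hexamer))
        entries.sort()
        return cls(
            [PASVariant(h, hamming(h, CONSENSUS), rank) for rank, h in entries]
        )

    @classmethod
    def default(cls) -> "PASVariantTable":
        """The packaged default: AATAAA plus ranked single-substitution variants."""
        with resources.as_file(
            resources.files("pasmap.data").joinpath("pas_variants.tsv")
        ) as p:
            return cls.from_file(p)

    def __iter__(self):
        return iter(self._variants)

    def __len__(self) -> int:
        return len(self._variants)

    def __contains__(self, hexamer: str) -> bool:
        return hexamer in self._by_hex

    @property
    def hexamers(self) -> list[str]:
        return [v.hexamer for v in self._variants]

    def key(self, hexamer: str) -> tuple[int, int]:
        """(consensus_distance, usage_rank) assignment key for a table hexamer."""
        try:
            v = self._by_hex[hexamer]
        except KeyError:
            raise ValueError(f"hexamer {hexamer!r} not in variant table") from None
        return (v.consensus_distance, v.usage_rank)


@dataclass(frozen=True)
class PASHit:
    """One hexamer occurrence inside a transcript's terminal search window.

    ``offset_from_3prime`` is the distance from the hexamer's last base to
    the transcript's last base (0 = hexamer flush with the 3' end).
    """

    transcript_id: str
    hexamer: str
    offset_from_3prime: int


@dataclass
class TranscriptPASCall:
    transcript_id: str
    gene_id: str
    gene_class: Optional[GeneClass]
    assigned_variant: Optional[str]  # None = no PAS found
    n_distinct_variants: int = 0
    n_total_hits: int = 0
    excluded: bool = False
    reason: ExclusionReason = "none"
    hits: list[PASHit] = field(default_factory=list)


def filter_search_set(
    records: Iterable[TranscriptRecord],
    min_len: int = 200,
    window: int = 50,
    downstream_windows: Optional[dict[str, str]] = None,
) -> tuple[list[TranscriptRecord], list[TranscriptPASCall]]:
    """Split records into (kept, excluded-with-reason).

    Kept records are strictly longer than ``min_len`` and carry only
    {A,C,G,T} in the terminal ``window`` bases and — when a downstream window
    is supplied for the transcript — in that downstream window too.
    """
    if window > min_len:
        raise ValueError(
            f"search window ({window}) larger than minimum length ({min_len})"
        )
    kept: list[TranscriptRecord] = []
    excluded: list[TranscriptPASCall] = []
    for rec in records:
        reason: ExclusionReason = "none"
        if len(rec) <= min_len:
            reason = "short"
        else:
            terminal = rec.sequence[-window:]
            if set(terminal) - _ACGT:
                reason = "ambiguous_window"
            elif downstream_windows is not None and rec.transcript_id in downstream_windows:
                if set(downstream_windows[rec.transcript_id]) - _ACGT:
                    reason = "ambiguous_window"
        if reason == "none":
            kept.append(rec)
        else:
            excluded.append(
                TranscriptPASCall(
                    transcript_id=rec.transcript_id,
                    gene_id=rec.gene_id,
                    gene_class=rec.gene_class,
                    assigned_variant=None,
                    excluded=True,
                    reason=reason,
                )
            )
    return kept, excluded


def scan_pas_window(
    seq: str,
    table: PASVariantTable,
    window: int = 50,
    transcript_id: str = "",
) -> list[PASHit]:
    """All occurrences of all table hexamers fully inside the last ``window`` bases.

    Overlapping occurrences are all reported; only the sense strand is
    searched.  Hits are returned sorted by position (5'->3'), then hexamer.
    """
    L = len(seq)
    if L < window:
        raise ValueError(f"sequence length {L} shorter than window {window}")
    region = seq[L - window :]
    if set(region) - _ACGT:
        raise ValueError("ambiguous bases in search window; filter first")
    hits = []
    for variant in table:
        start = region.find(variant.hexamer)
        while start != -1:
            abs_start = (L - window) + start
            hits.append(
                PASHit(
                    transcript_id=transcript_id,
                    hexamer=variant.hexamer,
                    offset_from_3prime=L - (abs_start + 6),
                )
            )
            start = region.find(variant.hexamer, start + 1)
    hits.sort(key=lambda h: (-h.offset_from_3prime, h.hexamer))
    return hits


def assign_pas(
    hits: Sequence[PASHit],
    table: PASVariantTable,
    *,
    transcript_id: str = "",
    gene_id: str = "",
    gene_class: Optional[GeneClass] = None,
) -> TranscriptPASCall:
    """Collapse one transcript's hits to a single PAS call.

    With no hits the call is None (no PAS).  Otherwise the assigned variant
    minimizes (consensus distance, usage rank): among multiple detected
    signals only the closest to consensus is counted, and the more commonly
    used variant wins among equally distant ones.  Order of ``hits`` is
    irrelevant.
    """
    if not hits:
        return TranscriptPASCall(
            transcript_id=transcript_id,
            gene_id=gene_id,
            gene_class=gene_class,
            assigned_variant=None,
        )
    tx_ids = {h.transcript_id for h in hits if h.transcript_id}
    if len(tx_ids) > 1:
        raise ValueError(f"hits span multiple transcripts: {sorted(tx_ids)}")
    if not transcript_id and tx_ids:
        transcript_id = tx_ids.pop()
    best = min((h.hexamer for h in hits), key=table.key)
    return TranscriptPASCall(
        transcript_id=transcript_id,
        gene_id=gene_id,
        gene_class=gene_class,
        assigned_variant=best,
        n_distinct_variants=len({h.hexamer for h in hits}),
        n_total_hits=len(hits),
        hits=list(hits),
    )


def count_tandem(hits: Sequence[PASHit]) -> int:
    """Number of distinct hit positions in one transcript's window.

    A transcript is "tandem" when this count is >= 2; overlapping hexamers at
    different starts count separately.
    """
    return len({h.offset_from_3prime for h in hits})


def call_transcripts(
    records: Iterable[TranscriptRecord],
    table: Optional[PASVariantTable] = None,
    min_len: int = 200,
    window: int = 50,
    downstream_windows: Optional[dict[str, str]] = None,
) -> list[TranscriptPASCall]:
    """Filter -> scan -> assign for a whole transcript set.

    Returns one call per input record; excluded records carry their exclusion
    reason and no hits.
    """
    if table is None:
        table = PASVariantTable.default()
    kept, excluded = filter_search_set(
        records, min_len=min_len, window=window, downstream_windows=downstream_windows
    )
    calls = list(excluded)
    for rec in kept:
        hits = scan_pas_window(
            rec.sequence, table, window=window, transcript_id=rec.transcript_id
        )
        calls.append(
            assign_pas(
                hits,
                table,
                transcript_id=rec.transcript_id,
                gene_id=rec.gene_id,
                gene_class=rec.gene_class,
            )
        )
    return calls
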