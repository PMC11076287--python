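"""Downstream sequence element (DSE) matching from a thresholded frequency logo.

A DSE logo (per-position nucleotide frequencies) is converted into a hard
pattern: position *i* allows exactly the bases whose frequency at *i* is at
or above the threshold (default 10%).  A window matches at a start when every
pattern position is satisfied — no log-odds scoring, by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pas_scan import TranscriptPASCall
from .seqio import AmbiguousSequenceError

_BASES = ("A", "C", "G", "T")
_ACGT = set(_BASES)


@dataclass(frozen=True)
class SequenceLogo:
    """Per-position base frequencies of a motif; each row sums to 1."""

    frequencies: tuple[tuple[float, float, float, float], ...]  # rows = positions, cols = A,C,G,T

    def __post_init__(self) -> None:
        if len(self.frequencies) < 1:
            raise ValueError("logo must have at least one position")
        for i, row in enumerate(self.frequencies):
            if any(f < 0 or f > 1 for f in row):
                raise ValueError(f"logo position {i}: frequencies outside [0,1]")
            if abs(sum(row) - 1.0) > 1e-6:
                raise ValueError(f"logo position {i}: frequencies sum to {sum(row)}")

    def __len__(self) -> int:
        return len(self.frequencies)

    @classmethod
    def from_array(cls, mat) -> "SequenceLogo":
        arr = np.asarray(mat, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("logo matrix must have shape (positions, 4)")
        return cls(tuple(tuple(row) for row in arr))

    @classmethod
    def from_file(cls, path: str | Path) -> "SequenceLogo":
        """Read a 4-column (A C G T) delimited matrix; '#' lines are comments."""
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                vals = [float(x) for x in line.replace(",", "\t").split()]
                if len(vals) != 4:
                    raise ValueError(f"expected 4 frequencies per row, got {len(vals)}")
                rows.append(tuple(vals))
        return cls(tuple(rows))

    @classmethod
    def default(cls) -> "SequenceLogo":
        """Packaged synthetic U/G-rich stand-in logo (see its file header)."""
        with resources.as_file(
            resources.files("pasmap.data").joinpath("dse_logo_synthetic.tsv")
        ) as p:
            return cls.from_file(p)


@dataclass(frozen=True)
class DSEPattern:
    """Per-position allowed-base sets derived from a logo at a threshold."""

    allowed: tuple[frozenset[str], ...]
    threshold: float

    def __len__(self) -> int:
        return len(self.allowed)

    def matches_at(self, window: str, start: int) -> bool:
        return all(
            window[start + i] in self.allowed[i] for i in range(len(self.allowed))
        )


@dataclass(frozen=True)
class DSEHit:
    transcript_id: str
    start: int  # 0-based offset within the downstream window
    matched: str


def build_dse_pattern(logo: SequenceLogo, threshold: float = 0.10) -> DSEPattern:
    """Pattern position *i* allows exactly {b : frequency(i, b) >= threshold}."""
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    allowed = []
    for i, row in enumerate(logo.frequencies):
        bases = frozenset(b for b, f in zip(_BASES, row) if f >= threshold)
        if not bases:
            raise ValueError(
                f"no base reaches threshold {threshold} at logo position {i}"
            )
        allowed.append(bases)
    return DSEPattern(tuple(allowed), threshold)


def scan_dse(
    window_seq: str, pattern: DSEPattern, transcript_id: str = ""
) -> list[DSEHit]:
    """All starts where the window satisfies every pattern position.

    Windows containing ambiguity codes are rejected (mirrors the search-set
    ambiguity filter) by raising :class:`AmbiguousSequenceError`.
    """
    bad = set(window_seq) - _ACGT
    if bad:
        raise AmbiguousSequenceError(
            f"{transcript_id or 'window'}: ambiguous bases {sorted(bad)} in DSE window"
        )
    m = len(pattern)
    if m > len(window_seq):
        raise ValueError(
            f"pattern length {m} exceeds window length {len(window_seq)}"
        )
    hits = []
    for s in range(len(window_seq) - m + 1):
        if pattern.matches_at(window_seq, s):
            hits.append(DSEHit(transcript_id, s, window_seq[s : s + m]))
    return hits


def pas_dse_cooccurrence(
    calls: Sequence[TranscriptPASCall],
    dse_counts: dict[str, int],
) -> pd.DataFrame:
    """Per gene class, the 2x2 table of (PAS assigned) x (>=1 DSE hit).

    ``dse_counts`` maps transcript id -> number of DSE hits and must cover
    exactly the non-excluded transcripts in ``calls``.
    """
    included = [c for c in calls if not c.excluded]
    call_ids = {c.transcript_id for c in included}
    if call_ids != set(dse_counts):
        missing = call_ids - set(dse_counts)
        extra = set(dse_counts) - call_ids
        raise ValueError(
            f"transcript universe mismatch: missing DSE counts for {sorted(missing)[:5]}, "
            f"unknown ids {sorted(extra)[:5]}"
        )
    rows = []
    for gene_class in sorted({c.gene_class for c in included if c.gene_class}):
        sub = [c for c in included if c.gene_class == gene_class]
        n_pp = sum(
            1 for c in sub if c.assigned_variant and dse_counts[c.transcript_id] > 0
        )
        n_pn = sum(
            1 for c in sub if c.assigned_variant and dse_counts[c.transcript_id] == 0
        )
        n_np = sum(
            1 for c in sub if not c.assigned_variant and dse_counts[c.transcript_id] > 0
        )
        n_nn = sum(
            1
            for c in sub
            if not c.assigned_variant and dse_counts[c.transcript_id] == 0
        )
        n = len(sub)
        rows.append(
            {
                "gene_class": gene_class,
                "n": n,
                "pas_and_dse": n_pp,
                "pas_only": n_pn,
                "dse_only": n_np,
                "neither": n_nn,
                "rate_pas": (n_pp + n_pn) / n if n else float("nan"),
                "rate_dse": (n_pp + n_np) / n if n else float("nan"),
                "rate_joint": n_pp / n if n else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_class",
            "n",
            "pas_and_dse",
            "pas_only",
            "dse_only",
            "neither",
            "rate_pas",
            "rate_dse",
            "rate_joint",
        ],
    )
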