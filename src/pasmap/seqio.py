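"""FASTA input, strand-aware genomic windows, and BED output.

Transcript FASTA files come either with plain headers (first whitespace token
is the transcript id) or with FlyBase-style ``key=value;`` annotation fields,
from which the parent gene id and the genomic location are recovered.  All
coordinates are held 0-based half-open internally; FlyBase 1-based inclusive
header locations are converted on parse.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Optional

from Bio import SeqIO

GeneClass = Literal["mRNA", "lncRNA"]

# Full IUPAC nucleotide complement (uppercase only; records are uppercased on read).
_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")
_IUPAC = set("ACGTUNRYSWKMBDHV")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed; names the offending line."""


class AmbiguousSequenceError(ValueError):
    """A sequence window contains a base outside {A,C,G,T} where none is allowed."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome with strand."""

    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptRecord:
    """One transcript sequence with gene identity and optional genomic location."""

    transcript_id: str
    gene_id: str
    gene_class: GeneClass
    sequence: str
    location: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.transcript_id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValueError(
                f"{self.transcript_id}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class GenomeSequence:
    """Chromosome-name -> sequence map with bounds-checked slicing."""

    def __init__(self, chroms: dict[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        chroms = {}
        with _open_maybe_gzip(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                chroms[rec.id] = str(rec.seq)
        return cls(chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def chrom_length(self, chrom: str) -> int:
        return len(self._fetch_chrom(chrom))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return genome[start:end) on the plus strand; out-of-range is an error."""
        seq = self._fetch_chrom(chrom)
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"range {start}-{end} outside chromosome {chrom} (length {len(seq)})"
            )
        return seq[start:end]

    def _fetch_chrom(self, chrom: str) -> str:
        try:
            return self._chroms[chrom]
        except KeyError:
            raise ValueError(f"chromosome {chrom!r} not present in genome") from None


class DownstreamWindow(NamedTuple):
    """A genomic window 3' of a transcript, in transcript reading orientation."""

    sequence: str
    truncated: bool


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet (N maps to N)."""
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


# FlyBase-style location field, e.g.
#   loc=2L:7529..9484
#   loc=X:complement(1234..5678)
#   loc=3R:join(10..20,30..40)  /  loc=3R:complement(join(...))
_LOC_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<spec>.+)$")
_SPAN_RE = re.compile(r"(\d+)\.\.(\d+)")


def _parse_flybase_header(description: str) -> tuple[Optional[str], Optional[GenomicInterval]]:
    """Extract (gene_id, location) from FlyBase ``key=value;`` header fields."""
    fields: dict[str, str] = {}
    for chunk in description.split(";"):
        chunk = chunk.strip()
        if "=" in chunk:
            key, _, value = chunk.partition("=")
            key = key.strip()
            if " " in key:  # first chunk carries the record id before the key
                key = key.split()[-1]
            fields[key] = value.strip()

    gene_id = None
    parent = fields.get("parent")
    if parent:
        for token in parent.split(","):
            token = token.strip()
            if token.startswith("FBgn"):
                gene_id = token
                break
        else:
            gene_id = parent.split(",")[0].strip()

    location = None
    loc = fields.get("loc")
    if loc:
        m = _LOC_RE.match(loc)
        if m is None:
            raise FastaParseError(f"cannot parse loc field {loc!r}")
        spec = m.group("spec")
        strand: Literal["+", "-"] = "-" if spec.startswith("complement(") else "+"
        spans = [(int(a), int(b)) for a, b in _SPAN_RE.findall(spec)]
        if not spans:
            raise FastaParseError(f"no coordinates in loc field {loc!r}")
        start_1b = min(a for a, _ in spans)
        end_1b = max(b for _, b in spans)
        # 1-based inclusive -> 0-based half-open
        location = GenomicInterval(m.group("chrom"), start_1b - 1, end_1b, strand)
    return gene_id, location


def read_transcript_fasta(
    path: str | Path,
    gene_class: GeneClass,
    header_dialect: Literal["flybase", "plain"] = "plain",
) -> list[TranscriptRecord]:
    """Read a transcript FASTA into :class:`TranscriptRecord` objects.

    With ``header_dialect="flybase"`` the parent gene id and the genomic
    location (including strand, from ``complement(...)``) are parsed from the
    annotation fields; with ``"plain"`` the gene id equals the transcript id
    and no location is attached.  Duplicate transcript ids are an error.
    """
    if header_dialect not in ("flybase", "plain"):
        raise ValueError(f"unknown header dialect {header_dialect!r}")

    with _open_maybe_gzip(path) as handle:
        # Light well-formedness check: first non-blank line must be a header.
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header, got {line[:40]!r}"
                    )
                break

    records: list[TranscriptRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate transcript id {rec.id!r} in {path}")
            seen.add(rec.id)
            gene_id, location = (None, None)
            if header_dialect == "flybase":
                gene_id, location = _parse_flybase_header(rec.description)
            records.append(
                TranscriptRecord(
                    transcript_id=rec.id,
                    gene_id=gene_id or rec.id,
                    gene_class=gene_class,
                    sequence=str(rec.seq),
                    location=location,
                )
            )
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.transcript_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def extract_downstream_window(
    genome: GenomeSequence, tx_loc: GenomicInterval, n: int = 50
) -> DownstreamWindow:
    """Genomic window of length ``n`` immediately 3' of a transcript.

    Plus strand: genome[end, end+n); minus strand: reverse complement of
    genome[start-n, start).  Returned in transcript reading orientation.  If
    fewer than ``n`` bases remain before the chromosome edge the window is
    truncated and flagged, never silently dropped.
    """
    if n < 1:
        raise ValueError("window length must be >= 1")
    chrom_len = genome.chrom_length(tx_loc.chrom)
    if tx_loc.end > chrom_len:
        raise ValueError(
            f"interval end {tx_loc.end} beyond chromosome {tx_loc.chrom} "
            f"(length {chrom_len})"
        )
    if tx_loc.strand == "+":
        stop = min(tx_loc.end + n, chrom_len)
        seq = genome.fetch(tx_loc.chrom, tx_loc.end, stop)
        return DownstreamWindow(seq, truncated=len(seq) < n)
    start = max(tx_loc.start - n, 0)
    seq = genome.fetch(tx_loc.chrom, start, tx_loc.start)
    return DownstreamWindow(reverse_complement(seq), truncated=len(seq) < n)


def write_bed(hits: Iterable, path: str | Path) -> None:
    """Serialize hits as BED6 with deterministic (target, start, name) ordering.

    Accepts :class:`~pasmap.complement.MatchHit` objects (name rendered as
    ``queryID|k|mm``, score = mismatch count) or any record with ``chrom``,
    ``start``, ``end`` and optional ``name``/``score``/``strand`` attributes.
    """
    lines = []
    for h in hits:
        if hasattr(h, "target_id"):  # MatchHit
            lines.append(
                (
                    h.target_id,
                    h.target_start,
                    h.target_end,
                    f"{h.query_id}|{h.k}|{h.mismatches}",
                    h.mismatches,
                    h.strand,
                )
            )
        else:
            lines.append(
                (
                    h.chrom,
                    h.start,
                    h.end,
                    getattr(h, "name", "."),
                    getattr(h, "score", 0),
                    getattr(h, "strand", "+"),
                )
            )
    lines.sort(key=lambda t: (t[0], t[1], t[3]))
    with open(path, "w") as out:
        for chrom, start, end, name, score, strand in lines:
            out.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


@dataclass(frozen=True)
class BedLine:
    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str


def read_bed(path: str | Path) -> list[BedLine]:
    """Minimal BED6 reader (round-trip counterpart of :func:`write_bed`)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start, end, name, score, strand = line.split("\t")
            out.append(BedLine(chrom, int(start), int(end), name, int(score), strand))
    return out
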