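"""Aggregation of PAS calls, DSE hits and complementary regions into summary tables.

Per-gene-class PAS percentages follow an explicit transcript-to-gene
reduction: a gene is represented by its best transcript call, using the same
(consensus distance, usage rank) key as single-transcript assignment.
Percentage denominators are the genes that survive the search-set filters.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from .complement import ComplementRegion
from .pas_scan import PASVariantTable, TranscriptPASCall


@dataclass
class ClassSummary:
    """Fig-style per-class PAS summary: exclusive per-variant gene percentages."""

    gene_class: str
    n_genes_searched: int
    variant_counts: dict[str, int]
    variant_percents: dict[str, float]
    percent_no_pas: float
    percent_tandem: float
    percent_with_dse: Optional[float] = None


_NONE_KEY = (10**6, 10**6)  # sorts after every real variant


def _gene_reduce(
    calls: Sequence[TranscriptPASCall], table: PASVariantTable
) -> dict[str, TranscriptPASCall]:
    """Best-transcript reduction: per gene keep the call minimizing the
    (consensus distance, usage rank) key; no-PAS calls sort last."""

    def call_key(c: TranscriptPASCall):
        if c.assigned_variant is None:
            return _NONE_KEY
        return table.key(c.assigned_variant)

    best: dict[str, TranscriptPASCall] = {}
    for c in sorted(calls, key=lambda c: c.transcript_id):
        if c.excluded:
            continue
        prev = best.get(c.gene_id)
        if prev is None or call_key(c) < call_key(prev):
            best[c.gene_id] = c
    return best


def summarize_pas_by_class(
    calls: Sequence[TranscriptPASCall],
    table: Optional[PASVariantTable] = None,
    dse_counts: Optional[dict[str, int]] = None,
    gene_reduction: Literal["best_transcript"] = "best_transcript",
    precision: int = 1,
) -> list[ClassSummary]:
    """Reduce calls to genes and report exclusive per-variant percentages.

    The denominator is the number of genes with at least one transcript
    passing the filters.  Per-variant percentages plus the no-PAS percentage
    sum to 100 (exclusive assignment).  ``dse_counts`` (transcript id -> DSE
    hit count) enables the percent-with-DSE column, evaluated on each gene's
    representative transcript.
    """
    if gene_reduction != "best_transcript":
        raise ValueError(f"unknown gene reduction {gene_reduction!r}")
    if table is None:
        table = PASVariantTable.default()
    if not any(not c.excluded for c in calls):
        raise ValueError("no transcripts survive filtering; nothing to summarize")

    summaries = []
    classes = sorted({c.gene_class for c in calls if c.gene_class is not None})
    for gene_class in classes:
        class_calls = [c for c in calls if c.gene_class == gene_class]
        best = _gene_reduce(class_calls, table)
        n = len(best)
        if n == 0:
            continue
        counts = {hexamer: 0 for hexamer in table.hexamers}
        n_none = 0
        n_tandem = 0
        n_dse = 0
        for call in best.values():
            if call.assigned_variant is None:
                n_none += 1
            else:
                counts[call.assigned_variant] += 1
            if call.n_total_hits >= 2:
                n_tandem += 1
            if dse_counts is not None and dse_counts.get(call.transcript_id, 0) > 0:
                n_dse += 1
        summaries.append(
            ClassSummary(
                gene_class=gene_class,
                n_genes_searched=n,
                variant_counts=counts,
                variant_percents={
                    h: round(100.0 * c / n, precision) for h, c in counts.items()
                },
                percent_no_pas=round(100.0 * n_none / n, precision),
                percent_tandem=round(100.0 * n_tandem / n, precision),
                percent_with_dse=(
                    round(100.0 * n_dse / n, precision) if dse_counts is not None else None
                ),
            )
        )
    return summaries


def class_summary_frame(summaries: Sequence[ClassSummary]) -> pd.DataFrame:
    """Long-format table: one row per (gene class, variant-or-none)."""
    rows = []
    for s in summaries:
        for hexamer, count in s.variant_counts.items():
            rows.append(
                {
                    "gene_class": s.gene_class,
                    "category": hexamer,
                    "n_genes": count,
                    "percent": s.variant_percents[hexamer],
                }
            )
        rows.append(
            {
                "gene_class": s.gene_class,
                "category": "none",
                "n_genes": s.n_genes_searched
                - sum(s.variant_counts.values()),
                "percent": s.percent_no_pas,
            }
        )
    return pd.DataFrame(rows, columns=["gene_class", "category", "n_genes", "percent"])


def calls_frame(calls: Sequence[TranscriptPASCall]) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": c.transcript_id,
            "gene_id": c.gene_id,
            "gene_class": c.gene_class or "",
            "assigned_variant": c.assigned_variant or "none",
            "n_distinct_variants": c.n_distinct_variants,
            "n_total_hits": c.n_total_hits,
            "excluded": c.excluded,
            "reason": c.reason,
        }
        for c in sorted(calls, key=lambda c: c.transcript_id)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "gene_id",
            "gene_class",
            "assigned_variant",
            "n_distinct_variants",
            "n_total_hits",
            "excluded",
            "reason",
        ],
    )


def summarize_interactors(regions: Iterable[ComplementRegion]) -> pd.DataFrame:
    """One row per ordered (query, target) pair with >= 1 complementary region.

    ``total_bp`` sums region lengths; rows sorted by region count descending,
    then pair ids for determinism.
    """
    agg: dict[tuple[str, str], dict] = {}
    for r in regions:
        key = (r.query_id, r.target_id)
        entry = agg.setdefault(
            key, {"n_regions": 0, "total_bp": 0, "min_mismatches": r.min_mismatches}
        )
        entry["n_regions"] += 1
        entry["total_bp"] += r.target_end - r.target_start
        entry["min_mismatches"] = min(entry["min_mismatches"], r.min_mismatches)
    rows = [
        {
            "query_id": q,
            "target_id": t,
            "n_regions": e["n_regions"],
            "total_bp": e["total_bp"],
            "min_mismatches": e["min_mismatches"],
        }
        for (q, t), e in agg.items()
    ]
    df = pd.DataFrame(
        rows, columns=["query_id", "target_id", "n_regions", "total_bp", "min_mismatches"]
    )
    if len(df):
        df = df.sort_values(
            ["n_regions", "query_id", "target_id"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return df


def render_report(
    tables: dict[str, pd.DataFrame],
    outdir: str | Path,
    parameters: Optional[dict] = None,
    seed: Optional[int] = None,
) -> list[Path]:
    """Write each table as TSV plus a plain-text run log; deterministic bytes.

    The log records the parameter set, seed, row counts and library versions
    so that two runs with identical logs imply identical outputs.
    """
    import numpy as np

    import pasmap

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = outdir / f"{name}.tsv"
        tables[name].to_csv(path, sep="\t", index=False)
        written.append(path)
    log = outdir / "run_log.txt"
    with open(log, "w") as fh:
        fh.write("pasmap run log\n")
        fh.write(f"pasmap_version: {pasmap.__version__}\n")
        fh.write(
            f"python: {sys.version_info.major}.{sys.version_info.minor}."
            f"{sys.version_info.micro}\n"
        )
        fh.write(f"numpy: {np.__version__}\npandas: {pd.__version__}\n")
        fh.write(f"seed: {seed if seed is not None else 'none'}\n")
        for key in sorted(parameters or {}):
            fh.write(f"param {key}: {(parameters or {})[key]}\n")
        for name in sorted(tables):
            fh.write(f"table {name}: {len(tables[name])} rows\n")
    written.append(log)
    return written
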