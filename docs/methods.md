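# Methods

## PAS identification

**Search set.** Transcripts enter the search only if strictly longer than
`min_len` (default 200 nt — the conventional length floor for lncRNAs) and
if their search windows contain only `{A,C,G,T}`. Two windows count: the
terminal window (last `window` nt of the transcript, default 50) and, when
genomic locations and a genome are available, the 50-nt downstream window.
Excluded records are returned with a reason (`short` or `ambiguous_window`)
rather than dropped silently, so denominators stay auditable.

**Scanning.** The terminal window is scanned on the sense strand for every
hexamer in the PAS variant table; all occurrences at all starts are
reported, overlapping ones included, and a hexamer must lie *fully* inside
the window (the strictest reading of a "last 50 nt" search). Hit positions
are recorded as the distance from the hexamer's last base to the
transcript's last base, which makes them invariant under 5′ extension — a
property test in the suite.

**Assignment.** A transcript with no hits has no PAS. Otherwise the
assigned variant minimizes the pair *(Hamming distance to AATAAA, usage
rank)*, lexicographically. This single rule realizes both conventions found
in practice — "closest to consensus wins" and "most used variant wins" —
which agree whenever the consensus is present; the usage rank only breaks
ties among equally distant variants. Assignment is order-invariant by
construction.

**Variant table.** The packaged default (`data/pas_variants.tsv`) is the
consensus plus the eleven single-substitution variants in the descending
usage order reported by large-scale poly(A)-site surveys. The table is
configuration, not code: any two-column (hexamer, usage_rank) file can be
substituted, and the consensus must appear with rank 1.

**Gene reduction.** Figures of the "percent of genes with signal X" kind
need one call per gene. A gene is represented by its best transcript call
under the same lexicographic key (no-PAS calls sort last). The percentage
denominator is the number of genes with at least one transcript surviving
the filters — not all annotated genes — since filtering precedes searching.
Per-variant percentages plus the no-PAS percentage sum to 100 by
construction (exclusive assignment); values are rounded to one decimal.

**Tandem signals.** A transcript's tandem count is its number of distinct
hit positions in the window; ≥ 2 counts as tandem. Overlapping occurrences
at different starts count separately.

## DSE matching

A DSE frequency logo (rows = positions, columns = A,C,G,T, each row summing
to 1 ± 1e-6) is converted to a hard pattern at a threshold (default 0.10):
position *i* allows exactly the bases with frequency ≥ threshold there. A
position where no base reaches the threshold is a configuration error and
is reported by index. Matching is all-or-nothing across the pattern length
at every start of the downstream window — no log-odds or information
weighting, because the procedure being reproduced is a hard character-class
match. Lowering the threshold can only grow the allowed sets, so hit sets
are monotone in the threshold (property-tested). Windows containing
ambiguity codes are rejected with the same reason the PAS filter uses.

The packaged logo (`data/dse_logo_synthetic.tsv`) is a **synthetic** U/G-rich
matrix with the qualitative shape of published DSE logos; it exists so the
pipeline runs end to end out of the box. Real analyses should supply the
position-frequency matrix of a published logo via `--logo`.

## Antisense k-mer mapping

**Semantics.** For every ordered (query, target) pair, every query k-mer is
aligned at every target position on both strands; the distance is
full-length Hamming (no indels). A `-` (antisense) hit means the k-mer
equals the reverse complement of the target sense substring within the
mismatch budget — the configuration with RNA:RNA pairing potential.
Coordinates are always reported 0-based half-open on the target sense
strand. k-mers containing ambiguity codes never match; an ambiguous base in
a target window simply counts as a mismatch at that position.

**Exclusions.** Self-pairs are skipped unless requested; the degenerate
exact sense self-match of a k-mer at its own coordinates is always removed
(it is an artifact of querying a pool that contains the query). Hairpin
(antisense self) matches are reported when self-mapping is enabled.

**Implementation and verification.** Mismatch counts for all (query offset,
target offset) pairs are obtained by accumulating the base-equality matrix
of the two sequences along its k diagonals — one vectorized pass per k,
O(Lq·Lt·k) with small constants and O(Lq·Lt) memory, comfortably fast at
the desk scale the method targets (pools of tens of sequences, kilobase
lengths; no genome-scale indexing is attempted). The scanner is checked
against two independently written oracles: a pure-Python per-position
counter and a per-k-mer numpy window comparison. Agreement is exact over
hundreds of random pools and is the primary gate of the acceptance suite.

**Regions and interactors.** Antisense hits for a (query, target) pair are
merged when their target intervals overlap or are book-ended (gap 0),
keeping the supporting hit count and the minimum mismatch count. The
interactor table aggregates regions per ordered pair (region count, summed
bp, best mismatch count), sorted by region count. Note that with a mismatch
budget m > 0, merged regions can extend a few bases past a planted or
biological duplex core: flanking windows that overhang the core by up to m
coincidentally pairing bases still pass the budget. This is inherent to
fixed-budget Hamming matching, not an artifact.

## Synthetic data

**Transcripts.** Background sequence is i.i.d. at a configurable base
composition (default A/T 0.29, C/G 0.21 — fly-like AT richness). Each
record draws at most one PAS variant from the per-class planting rates and
carries it at a uniform position fully inside the terminal 50-nt window.
The rest of that window is rejection-sampled to contain *no* table hexamer,
and the post-plant window is re-checked so the planted occurrence is the
only one — truth labels are therefore exact, not probabilistic. Downstream
windows are built the same way against the DSE pattern, with a planted
match at rate `dse_rate` (default 0.60). An optional ambiguity-injection
rate places an `N` in the terminal window to exercise the filter. Defaults
are the study conditions the package reproduces: 2000 genes per class,
consensus prevalence 0.60 (mRNA) and 0.23 (lncRNA) plus smaller
single-substitution shares (0.12/0.05 and 0.08/0.05) so both classes retain
a realistic degenerate-variant fraction.

**Pools.** Planted blocks copy `mutate_block(rc(query block), d)` into the
target at a stated position, where `mutate_block` substitutes exactly `d`
positions (exact, not a maximum). Backgrounds are rejection-sampled (bounded
at 1000 attempts) so no unplanned ≥ 19-mer antisense match at ≤ 2
mismatches exists between any pair, certified with the brute-force checker,
and re-audited after planting. Two numerical details make truth coordinates
exact: (i) the target base flanking each payload is re-sampled if it would
complement the adjacent query base, so zero-mismatch footprints cannot
extend past the planted interval; (ii) blocks may not overlap on a target.
A block of length > k with d > 0 legitimately yields some sub-k windows at
fewer than d mismatches (windows that dodge the substituted positions);
found-iff-budget guarantees are therefore stated for blocks of length k.

**What the generators do not emulate.** Real transcriptomes have
non-i.i.d. composition (isochores, repeats, UTR biases), genes with many
isoforms, and correlated PAS/DSE occurrence; the generators plant
independently and one-variant-per-record. Passing recovery tests therefore
demonstrates correctness of the scanning/assignment machinery under known
truth, not field performance on FlyBase annotation — the pipeline accepts
the real bulk files (flybase header dialect, genome-derived downstream
windows) for that purpose.

## Determinism and numerical choices

Every generator takes a mandatory integer seed driving a single
`numpy.random.Generator`; no global state. Reports are byte-deterministic:
tables are written in sorted order and the run log records parameters,
seed, row counts and library versions. Coordinates are 0-based half-open
everywhere, including BED output; FlyBase 1-based inclusive header
locations are converted on parse, and `complement(...)`/`join(...)` forms
are reduced to the spanning interval with the stated strand. Truncated
downstream windows at chromosome edges are returned flagged rather than
dropped. CLI defaults equal the standard study constants (window 50,
min_len 200, threshold 0.10, k 19–25, mismatches ≤ 2) but are all
overridable, which is what lets the test suite run scaled-down cases
through the same code paths.

## Problem sizes used in the checks

The acceptance suite runs the mapper-vs-oracle comparison on 200 random
pools of 2–5 sequences × 60–300 nt (k ∈ {19, 22, 25}, mismatches 0–2),
planted-block recovery on 100 seeded replicates, and the PAS pipeline on
2000 synthetic transcripts per class; `scripts/acceptance.py` recomputes
the same quantities from scratch under a user-supplied seed. These sizes
give exact oracle agreement and ~1% binomial resolution on recovered rates.

## Known limitations

- No gapped alignment or thermodynamic duplex scoring; complementarity is
  purely Hamming-based, as specified.
- The DSE stage requires genomic locations; transcripts without a location
  (plain headers) are summarized without DSE columns.
- The packaged DSE logo is a synthetic stand-in; per-gene DSE conclusions
  require the real matrix.
- Gene reduction assumes the best-transcript rule; if a study defines a
  canonical transcript per gene, pre-filter to those transcripts instead.
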