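# Methods

## Problem setting

`varsweep` integrates a list of genetic variants (SNVs, insertions,
deletions, or bare genomic locations) with genome-wide feature tracks.
Each track is a set of intervals carrying either a numeric signal (coverage,
conservation score) or a categorical label (chromatin state, catalog
membership). The questions answered per variant are: which regions of each
feature overlap it (exactly, or within a flanking window), what is the mean
signal around it, and how does that mean rank among all of the feature's
regions genome-wide.

## Coordinates and variant representation

All internal coordinates are 0-based with half-open intervals `[start, end)`
(the BED convention); VCF and whitespace-list positions are read as 1-based
and converted on parse. Each variant is reduced to one representative point:

* SNV, insertion, bare location: the exact 0-based position `pos − 1`.
* Deletion with reference allele spanning `[s, s + |ref|)`: the floor
  mid-point `(2s + |ref| − 1) // 2`. Floor is an arbitrary but deterministic
  choice between the two central bases of even-length deletions.

Classification is purely by allele lengths: equal single bases → SNV, longer
alternate → insertion, longer reference → deletion, no alleles → point-only.
Multi-allelic VCF records contribute their first ALT only; the remaining
alleles would at most move the classification, never the position, and
keeping one record per input line keeps the input-row/output-row
correspondence trivial.

## The transfer codec

A variant list is reduced to per-chromosome sorted arrays of points. Each
array is stored as one absolute value followed by deltas, all as unsigned
LEB128 varints; the payload carries a 9-byte header plus, per chromosome, a
length-prefixed name and a u64 count. Sorted uniform positions on a human
chromosome have mean gap ≈ 1 kb, so deltas fit in 1–2 varint bytes and
3 × 10⁶ variants encode to ≈ 5.7 MB. The format guarantees
`size ≤ 16 + Σ_c (2 + |name_c| + 8 + 5·n_c)` bytes (a varint of a < 2³⁵
value takes at most 5 bytes); the encoder asserts this bound on every call.
Decoding is the exact inverse on locations; alleles are deliberately not
carried (annotation needs only points), so a decoded list is point-only.

## The feature store

Tracks are imported from BED 3–5 / bedGraph text and written to a binary
file: fixed 12-byte records (u32 start, u32 end, f32 value or u32 label
index) sorted by chromosome (lexicographic) and `(start, end)` within, a
directory mapping each chromosome to the byte offset of its first record,
and — for numeric tracks — a footer holding the sorted array of all region
values. Scanning one chromosome seeks to its offset and reads exactly its
records; a read counter on the store lets tests assert that no preceding
records are touched. Overlapping and nested regions are stored as-is, never
merged: real tracks (peak calls from multiple experiments) overlap, and the
sweep's active set handles them naturally. Values are quantized to f32 by
the record format; the value distribution is stored from the same f32
values so percentile queries are self-consistent. Coordinates must fit u32,
which covers every human chromosome. Pointers are chromosome-level only;
finer intra-chromosome bins would only matter when a single chromosome scan
dominates, which at the supported scales it does not.

## Sweep-line joins

Both integration modes are sort-merge scans over one chromosome at a time.
Events are the region starts/ends plus either variant points (exact mode)
or window starts/ends (window mode, window `[max(0, p − w), p + w + 1)`,
flank `w` ∈ [0, 1 Mb] per side). Ties at one coordinate resolve as

    region end < window end < region start < variant point / window start

which is exactly the half-open convention: an interval ending at `c` is
closed before anything starting at `c` opens, and a region starting at `c`
annotates a point at `c`. The scan keeps identity-keyed active sets (a
strict FIFO queue would fail on nested regions, which close in non-FIFO
order). Each region and each window is inserted and removed exactly once —
the joins expose these counters, and tests assert insertions = #regions
(+ #variants in window mode) on every instance. Event order is obtained by
`lexsort` over the concatenated event arrays; given per-chromosome sorted
inputs this is a merge of four sorted streams, and the subsequent pass is
linear. Pair discovery in window mode can happen at either the window-start
or the region-start event; the variant map stores pairs with set semantics
so no pair is double-reported.

Chromosome names are matched after normalizing both sides to the `chr`
prefix; `1` and `chr1` in the same input is rejected as ambiguous rather
than silently merged mid-sort.

## Summaries and the report

For each (variant, feature) with ≥ 1 overlapping region: the count, and for
numeric features the **unweighted** arithmetic mean `m` of the overlapping
region values — each region counts once regardless of its width or how much
of it the window covers (a base-pair-weighted mean would be the natural
alternative; unweighted was chosen as the simplest reading of "average value
of the regions around the variant") — and the mid-rank percentile
`p = 100·(C_lt + ½·C_eq)/N` of `m` in the feature's genome-wide value
multiset. Mid-rank is symmetric (`p(median) = 50` for odd `N`), handles
ties, and stays strictly inside [0, 100] for values inside the range.
The TSV report has one row per input variant in input order — variants with
no overlaps anywhere appear as blank rows so the user can see they were
processed — and one `count / value / percentile` column group per feature in
selection order. Numeric cells use `%.6g`. An Excel rendering with the same
cells is available. Jobs can be tagged with a 512-bit identifier (128 hex
characters from the OS CSPRNG), the access token under which results are
filed; the library never deletes results.

## Synthetic data

The generators define the conditions under which the package is tested:

* `GenomeModel.human_scale()` — 24 chromosomes with GRCh37 lengths
  (≈ 3.1 Gb). Used for codec-size measurements, where what matters is the
  coordinate magnitude and gap distribution, not sequence content.
* `GenomeModel.toy()` — small genomes for join logic.
* `simulate_variants(n, gm, seed)` — points uniform over the genome
  (per-chromosome multinomial by length). Uniformity is the conservative
  choice for codec size: real variants cluster, clustering shrinks deltas,
  so uniform placement upper-bounds realistic payloads.
* `simulate_feature` — uniform region starts, uniform lengths, uniform
  values or uniform labels, overlaps allowed, clipped at chromosome ends.
* `planted_instance` — slot-isolated variant/region pairs with a
  known-by-construction answer set (pitch `3·(w + max_len + 10)` guarantees
  windows cannot reach a neighbouring slot's region).

What the generators do **not** emulate: linkage structure, allele
frequencies, realistic signal shapes (peaks, domains), clustered hotspots,
or chromosome-specific density differences. Passing tests therefore
demonstrate algorithmic correctness (joins equal to an all-pairs oracle,
exact accounting, format round trips) and size behaviour at realistic
coordinate magnitudes — not biological fidelity of annotations.

The one real-data fixture is the list of 31 clinically flagged variant rows
(21 unique GRCh37 loci) published for five Personal Genome Project
participants, used as an end-to-end exact-location annotation check.

## Problem sizes and numerical choices

The test suite and acceptance script use: 3 × 10⁶ variants for the codec
size measurement; 1,000 variants × 500 regions × 100+ seeded instances with
flanks `w ∈ {0, 10, 1000}` for oracle equivalence; 40k→80k variants with
20k→40k regions for the soft scaling check (doubling must stay under 3×,
measured as best-of-three to damp timer noise); 100 random lists for codec
round-trips. These sizes make the whole suite run in well under a minute
per property while exercising every code path at non-trivial density.

Degenerate inputs: empty variant lists, empty stores and absent chromosomes
all produce empty-but-valid results; zero-width regions are rejected at
import; windows are clipped at coordinate 0 but not at chromosome right
ends (the store carries no chromosome lengths, and right overhang cannot
change overlap results).

## Known limitations

* No bigWig/bigBed/tabix ingestion; convert to BED/bedGraph text upstream.
* The store is uncompressed fixed-width records; it trades disk for seek
  simplicity.
* The flank `w` is per side; a "window of 100 bp" in the per-side sense is
  201 bp of total width. Callers wanting total-width semantics should pass
  `w = width // 2`.
* Percentiles compare a *mean* against the distribution of *single region
  values*; for multi-region windows this is a summary convention, not a
  calibrated statistic.
* The value distribution is the exact sorted array; at extreme region
  counts a quantile sketch would be the natural replacement (acceptable if
  it stays within ±0.1 percentile of exact).
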