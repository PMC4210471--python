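# varsweep

Annotating a whole-genome list of genetic variants — often millions of loci
from one sequenced sample — against tens of genome-wide feature tracks
(histone marks, open chromatin, chromatin states, conservation, variant
catalogs) runs into two practical walls: the variant list itself is hundreds
of megabytes of repetitive text, and a naive interval join between millions
of points and millions of regions is slow when done through generic
tree-indexed queries. `varsweep` is a small toolkit that attacks both with
two ideas:

1. **A compact location codec.** A variant list is reduced to per-chromosome
   arrays of sorted 0-based locations, each array stored as one absolute
   position followed by successive deltas in unsigned LEB128 varints.
   Chromosome names, alleles and genotype columns are dropped. Three million
   uniformly placed human-genome variants encode to about 5.7 MB.

2. **Sweep-line (sort-merge) joins.** Feature tracks are imported once into a
   sorted binary store with a per-chromosome pointer directory, so reading
   one chromosome is a seek, not a scan. Variants and regions are then merged
   in a single coordinated pass per chromosome. Two modes exist:
   *exact-location* — a variant's representative point `p` (exact position
   for an SNV or insertion, floor mid-point of the deleted span for a
   deletion) matches region `[s, e)` iff `s ≤ p < e` — and
   *flanking-window* — the window `[max(0, p−w), p+w+1)` (flank `w` up to
   1 Mb per side) must intersect the region. The scan maintains a *feature
   queue* of currently open regions and, in window mode, a *variant queue* of
   open windows; every region and every window enters and leaves its queue
   exactly once, so the join is linear in the sorted input size.

For numeric features each annotated variant additionally gets the unweighted
mean `m` of the overlapping region values and the mid-rank percentile
`p = 100·(C_lt + ½·C_eq)/N` of `m` among all `N` region values of that
feature genome-wide.

## Worked example

```sh
# a tiny cohort: 60 SNVs and a coverage track on a 2-chromosome toy genome
python - <<'EOF'
from varsweep.simulate import *
gm = GenomeModel.toy(n_chrom=2, length=20_000)
open("variants.vcf", "w").write(variants_to_vcf(simulate_variants(60, gm, seed=1, alleles=True)))
open("track.bedgraph", "w").write(regions_to_bed(simulate_feature(50, (5, 200), (0.0, 9.0), gm, seed=2)))
EOF

varsweep pack variants.vcf -o payload.vasc
varsweep mkstore track.bedgraph --name cov --type numeric -o cov.vasf
varsweep annotate payload.vasc --store cov.vasf --window 100 -o out.tsv
```

which prints

```
packed 60 variants on 2 chromosomes into 144 bytes
stored 50 regions of 'cov' (numeric) on 2 chromosomes
annotated 23/60 variants with 1 features -> out.tsv
```

`payload.vasc` holds the 60 locations in 144 bytes (the VCF is 1.4 kB; at
3 million real-genome variants the ratio is hundreds of megabytes down to
~5.7 MB). `out.tsv` has one row per input variant and a three-column group
for the `cov` feature; rows look like

```
chrom	pos	ref	alt	cov:count	cov:value	cov:percentile
chr1	2489					
chr1	5140			1	6.23266	75
chr1	5464			2	5.08817	62
```

The variant at chr1:2489 overlapped nothing within ±100 bp — it is reported
blank, not dropped. At chr1:5140 one stored region overlaps the window; its
value 6.23 sits at the 75th percentile of all 50 region values of this
track. At chr1:5464 two regions overlap and their unweighted mean is 5.09
(62nd percentile). (Annotating `variants.vcf` directly instead of the
packed payload gives the same feature columns plus the ref/alt cells.)

The same pipeline is available as a library (`parse_variants`,
`compress_variants`, `build_store`, `run_annotation`, `write_table`), and
`varsweep.datasets.pgp_reported_variants()` carries a real worked example:
31 clinically flagged variant rows published for five Personal Genome
Project participants (21 unique GRCh37 loci), which the test suite annotates
end to end.

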