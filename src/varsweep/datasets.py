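"""Small published datasets used in worked examples and tests.

The Personal Genome Project (PGP, https://my.pgp-hms.org/) publishes whole
genome variant lists together with reports flagging variants of clinical
importance.  ``pgp_reported_variants`` returns the published loci of the
likely-pathogenic and rare pathogenic variants reported for five PGP
participants — 31 report rows over 21 unique genomic loci (GRCh37), since
several loci recur across participants.  This tiny list is useful as an
end-to-end smoke test: annotating the participants' loci against a store
built from any catalog that covers these positions must hit every one.
"""

from __future__ import annotations

from varsweep.variant_io import VariantList, make_variant

# (sample, variant label, chrom, 1-based GRCh37 position, dbSNP id, importance)
PGP_REPORTED_VARIANTS: tuple[tuple[str, str, str, int, str, str], ...] = (
    ("hu47A9D1", "APOA5-S19W", "chr11", 116662407, "rs3135506", "Low"),
    ("hu47A9D1", "APOE-C130R", "chr19", 45411941, "rs429358", "High"),
    ("hu47A9D1", "MBL2-G54D", "chr10", 54531235, "rs1800450", "Low"),
    ("hu47A9D1", "MBL2-R52C", "chr10", 54531242, "rs5030737", "Low"),
    ("hu47A9D1", "MTRR-I49M", "chr5", 7870973, "rs1801394", "Low"),
    ("hu47A9D1", "MYO7A-R302H", "chr11", 76869378, "rs41298135", "High"),
    ("hu47A9D1", "rs5186", "chr3", 148459988, "rs5186", "Low"),
    ("hu7DA960", "AMPD1-Q12X", "chr11", 115236057, "rs17602729", "Low"),
    ("hu7DA960", "KCNE1-D85N", "chr21", 35821680, "N/A", "High"),
    ("hu7DA960", "KRT5-G138E", "chr12", 52913668, "rs11170164", "Low"),
    ("hu7DA960", "MBL2-G54D", "chr10", 54531235, "rs1800450", "Low"),
    ("hu7DA960", "rs5186", "chr3", 148459988, "rs5186", "Low"),
    ("hu8D40D6", "APOE-C130R", "chr19", 45411941, "rs429358", "High"),
    ("hu8D40D6", "HFE-S65C", "chr6", 26091185, "N/A", "Low"),
    ("hu8D40D6", "MTRR-I49M", "chr5", 7870973, "rs1801394", "Low"),
    ("hu8D40D6", "PRPH-D141Y", "chr12", 49689404, "rs58599399", "High"),
    ("hu8D40D6", "RPF1-A91V", "chr10", 72360387, "rs35947132", "Low"),
    ("hu8D40D6", "SERPINA1-E288V", "chr14", 94847262, "rs17580", "Low"),
    ("hu998A3D", "BTD-D444H", "chr3", 15686693, "rs13078881", "Low"),
    ("hu998A3D", "C3-R102G", "chr19", 6718387, "rs2230199", "Moderate"),
    ("hu998A3D", "COL4A1-Q1334H", "chr13", 110818598, "rs3742207", "Low"),
    ("hu998A3D", "HFE-S65C", "chr6", 26091185, "N/A", "Low"),
    ("hu998A3D", "MTRR-I49M", "chr5", 7870973, "rs1801394", "Low"),
    ("hu998A3D", "rs5186", "chr3", 148459988, "rs5186", "Low"),
    ("hu998A3D", "SERPINA1-E366K", "chr14", 94844947, "rs28929474", "High"),
    ("hgD53911", "COL4A1-Q1334H", "chr13", 110818598, "rs3742207", "Low"),
    ("hgD53911", "MTRR-I49M", "chr5", 7870973, "rs1801394", "Low"),
    ("hgD53911", "PKD1-R4276W", "chr16", 2139814, "rs114251396", "High"),
    ("hgD53911", "rs5186", "chr3", 148459988, "rs5186", "Low"),
    ("hgD53911", "SCNN1G-E197K", "chr16", 23200963, "rs5738", "Low"),
    ("hgD53911", "VWF-R854Q", "chr12", 6143978, "rs41276738", "Moderate"),
)


def pgp_reported_variants() -> VariantList:
    """The 31 reported PGP variant rows as a point-only variant list.

    Rows keep report order; the same locus may appear for several samples,
    so deduplication (``dedup_unique_loci``) yields 21 unique loci.
    """
    return VariantList([make_variant(chrom, pos)
                        for _, _, chrom, pos, _, _ in PGP_REPORTED_VARIANTS])
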