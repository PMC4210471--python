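"""Synthetic genomes, variant lists and feature tracks for testing.

Everything here is seeded and deterministic: a fixed seed reproduces the
same instance across runs and platforms.  Two genome models cover the two
testing regimes: a human-scale 24-chromosome model whose coordinate
magnitudes exercise the varint codec realistically, and tiny toy genomes for
join-logic tests.  ``planted_instance`` builds variant/region sets with a
known-by-construction answer set, replacing hand-drawn join examples.

Generators can also emit VCF, whitespace-list and bedGraph/BED text so tests
exercise the real parsers, not just in-memory paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from varsweep.feature_store import FeatureRegion
from varsweep.sweep import normalize_chrom
from varsweep.variant_io import Variant, VariantList, make_variant

# GRCh37 chromosome lengths: realistic coordinate magnitudes for size tests
_HG19_LENGTHS = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560, "chrY": 59373566,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names and lengths of a (possibly toy) genome."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    @classmethod
    def human_scale(cls) -> "GenomeModel":
        """24 chromosomes with GRCh37 lengths (~3.1 Gb)."""
        return cls(dict(_HG19_LENGTHS))

    @classmethod
    def toy(cls, n_chrom: int = 2, length: int = 10_000) -> "GenomeModel":
        return cls({f"chr{i + 1}": length for i in range(n_chrom)})


def simulate_variants(n: int, gm: GenomeModel, seed: int,
                      alleles: bool = False) -> VariantList:
    """``n`` variant points uniform over the genome, sorted per chromosome.

    Points are allocated to chromosomes proportionally to length
    (multinomial) and drawn uniformly within each.  With ``alleles=True``
    each variant becomes an SNV with random distinct ref/alt bases, so the
    list survives a round trip through VCF text.
    """
    if n < 0:
        raise ValueError(f"variant count {n} negative")
    rng = np.random.default_rng(seed)
    chroms = gm.chromosomes
    lens = np.array([gm.lengths[c] for c in chroms], dtype=np.float64)
    counts = rng.multinomial(n, lens / lens.sum())
    if not alleles:
        points = {c: np.sort(rng.integers(0, gm.lengths[c], size=int(k)))
                  for c, k in zip(chroms, counts) if k}
        return VariantList.from_points(points)
    variants: list[Variant] = []
    for c, k in zip(chroms, counts):
        pts = np.sort(rng.integers(0, gm.lengths[c], size=int(k)))
        ref_idx = rng.integers(0, 4, size=int(k))
        refs = _BASES[ref_idx]
        alts = _BASES[(ref_idx + rng.integers(1, 4, size=int(k))) % 4]
        for p, r, a in zip(pts, refs, alts):
            variants.append(make_variant(c, int(p) + 1, str(r), str(a)))
    return VariantList(variants)


def simulate_feature(n_regions: int, length_law: tuple[int, int],
                     value_law, gm: GenomeModel, seed: int) -> list[FeatureRegion]:
    """``n_regions`` random regions, possibly overlapping, clipped to bounds.

    ``length_law`` is a uniform (min, max) region length with min >= 1.
    ``value_law`` is either a uniform numeric (lo, hi) pair or a sequence of
    labels to draw from.
    """
    if n_regions < 0:
        raise ValueError(f"region count {n_regions} negative")
    lmin, lmax = length_law
    if lmin < 1 or lmax < lmin:
        raise ValueError(f"invalid length law ({lmin}, {lmax})")
    numeric = (len(value_law) == 2
               and all(isinstance(x, (int, float)) and not isinstance(x, bool)
                       for x in value_law))
    rng = np.random.default_rng(seed)
    chroms = gm.chromosomes
    lens = np.array([gm.lengths[c] for c in chroms], dtype=np.float64)
    counts = rng.multinomial(n_regions, lens / lens.sum())
    regions: list[FeatureRegion] = []
    for c, k in zip(chroms, counts):
        k = int(k)
        clen = gm.lengths[c]
        starts = rng.integers(0, clen, size=k)
        lengths = rng.integers(lmin, lmax + 1, size=k)
        ends = np.minimum(starts + lengths, clen)
        starts = np.minimum(starts, ends - 1)  # keep width >= 1 at the edge
        if numeric:
            lo, hi = value_law
            values = rng.uniform(lo, hi, size=k)
        else:
            values = rng.choice(np.asarray(list(value_law), dtype=object), size=k)
        for s, e, v in zip(starts, ends, values):
            regions.append(FeatureRegion(chrom=c, start=int(s), end=int(e),
                                         value=float(v) if numeric else str(v)))
    return regions


@dataclass(frozen=True)
class PlantedInstance:
    """A join instance whose answer set is known by construction.

    ``expected_pairs`` holds ``(chrom, variant point, region start, region
    end)`` tuples — exactly the pairs any correct join must return for flank
    ``w``.  All planted loci are unique, so coordinates identify pairs.
    """

    variants: VariantList
    regions: list[FeatureRegion]
    w: int
    expected_pairs: frozenset[tuple[str, int, int, int]]


def pairs_as_coords(vmap, variants_by_chrom, regions_by_chrom) -> frozenset:
    """Convert a VariantMap keyed by indices into coordinate-identified pairs."""
    out = set()
    for chrom, vi, ri in vmap.pair_set():
        p = int(variants_by_chrom[chrom][vi])
        r = regions_by_chrom[chrom][ri]
        out.add((chrom, p, int(r.start), int(r.end)))
    return frozenset(out)


def planted_instance(k_overlaps: int, k_nonoverlaps: int, w: int,
                     gm: GenomeModel, seed: int,
                     max_region_len: int = 50) -> PlantedInstance:
    """Build ``k_overlaps`` guaranteed hits and ``k_nonoverlaps`` guaranteed misses.

    The genome is divided into slots of pitch ``3 * (w + max_region_len +
    10)`` so that windows from one slot can never reach another slot's
    region.  A hit slot places the variant point inside its region; a miss
    slot places it more than ``w`` bases beyond the region end.
    """
    if k_overlaps < 0 or k_nonoverlaps < 0:
        raise ValueError("plant counts must be non-negative")
    rng = np.random.default_rng(seed)
    pitch = 3 * (w + max_region_len + 10)
    slots: list[tuple[str, int]] = []
    need = k_overlaps + k_nonoverlaps
    for c in gm.chromosomes:
        for i in range(gm.lengths[c] // pitch):
            slots.append((c, i * pitch))
            if len(slots) >= need:
                break
        if len(slots) >= need:
            break
    if len(slots) < need:
        raise ValueError(
            f"genome too small: {len(slots)} slots of pitch {pitch} for "
            f"{need} plants")
    kinds = np.array([True] * k_overlaps + [False] * k_nonoverlaps)
    rng.shuffle(kinds)

    variants: list[Variant] = []
    regions: list[FeatureRegion] = []
    expected: set[tuple[str, int, int, int]] = set()
    for (chrom, base), is_hit in zip(slots, kinds):
        length = int(rng.integers(1, max_region_len + 1))
        start = base + w + 1 + int(rng.integers(0, 5))
        end = start + length
        regions.append(FeatureRegion(chrom=chrom, start=start, end=end, value=1.0))
        if is_hit:
            point = int(rng.integers(start, end))
            expected.add((normalize_chrom(chrom), point, start, end))
        else:
            point = end + w + int(rng.integers(1, 6))
        variants.append(make_variant(chrom, point + 1))
    return PlantedInstance(variants=VariantList(variants), regions=regions,
                           w=w, expected_pairs=frozenset(expected))


# ---------------------------------------------------------------------------
# text emitters, so fixtures can exercise the real parsers

def variants_to_vcf(vl: VariantList) -> str:
    lines = ["##fileformat=VCFv4.2",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for v in vl:
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref or '.'}\t{v.alt or '.'}"
                     "\t.\t.\t.")
    return "\n".join(lines) + "\n"


def variants_to_list(vl: VariantList) -> str:
    lines = []
    for v in vl:
        fields = [v.chrom, str(v.pos)]
        if v.ref or v.alt:
            fields += [v.ref or ".", v.alt or "."]
        lines.append(" ".join(fields))
    return "\n".join(lines) + "\n"


def regions_to_bed(regions: Sequence[FeatureRegion]) -> str:
    """bedGraph-style 4-column text (numeric values) or BED4 (labels)."""
    lines = []
    for r in regions:
        val = f"{r.value:.6g}" if isinstance(r.value, float) else r.value
        lines.append(f"{r.chrom}\t{r.start}\t{r.end}\t{val}")
    return "\n".join(lines) + "\n"
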