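"""Linear-time sort-merge (sweep-line) joins of variant points with regions.

Two integration modes are provided.  *Exact-location* (:func:`point_join`)
annotates a variant with every region containing its representative point.
*Flanking-window* (:func:`window_join`) annotates a variant with every region
overlapping the window of ±w bases around its point, capturing nearby loci in
genetic linkage.

Both run a single coordinated scan over the sorted inputs of one chromosome.
The scan maintains two active sets: the *feature queue* of regions whose
interval is currently open, and (window mode only) the *variant queue* of
variants whose window is currently open.  The event actions are:

exact-location mode
    * variant point: annotate the variant with every region in the feature
      queue
    * region start: add the region to the feature queue
    * region end: remove the region from the feature queue

flanking-window mode
    * window start: add the variant to the variant queue and annotate it with
      every region in the feature queue
    * window end: remove the variant from the variant queue
    * region start: add the region to the feature queue and annotate every
      variant in the variant queue with it
    * region end: remove the region from the feature queue

All intervals are half-open ``[start, end)`` and a variant point occupies
``[p, p+1)``.  Ties at one coordinate resolve in the order region end <
window end < region start < variant point / window start, which encodes the
half-open convention: a region ending at *c* never annotates anything
starting at *c*, while a region starting at *c* always annotates a variant
point at *c*.

Each region enters and leaves the feature queue exactly once and each
variant is visited once, so a join costs one pass over the merged event
sequence — linear in variants + regions once the inputs are sorted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from varsweep.errors import SweepError

MAX_WINDOW = 1_000_000

# event-type priorities at equal coordinates
_PRI_REGION_END = 0
_PRI_WINDOW_END = 1
_PRI_REGION_START = 2
_PRI_VARIANT_POINT = 3  # also the window-start priority


def normalize_chrom(name: str) -> str:
    """Normalize a chromosome name to the ``chr``-prefixed convention."""
    return name if name.startswith("chr") else "chr" + name


@dataclass
class SweepStats:
    """Instrumentation counters for one join (summed over chromosomes)."""

    feature_insertions: int = 0
    feature_removals: int = 0
    variant_insertions: int = 0
    variant_removals: int = 0


class VariantMap:
    """The join result: variant -> set of annotating regions.

    Variants and regions are identified by ``(chromosome, index)`` where the
    index refers to the position in the per-chromosome sorted input
    sequences.  Pair membership uses set semantics, so each (variant,
    region) pair appears at most once regardless of discovery order.
    """

    def __init__(self) -> None:
        self._pairs: dict[tuple[str, int], set[int]] = {}
        self.stats = SweepStats()

    def add(self, chrom: str, vi: int, ri: int) -> None:
        self._pairs.setdefault((chrom, vi), set()).add(ri)

    def regions_for(self, chrom: str, vi: int) -> frozenset[int]:
        return frozenset(self._pairs.get((chrom, vi), ()))

    def pair_set(self) -> frozenset[tuple[str, int, int]]:
        return frozenset((c, vi, ri)
                         for (c, vi), ris in self._pairs.items() for ri in ris)

    def npairs(self) -> int:
        return sum(len(ris) for ris in self._pairs.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantMap):
            return NotImplemented
        return self.pair_set() == other.pair_set()

    def __len__(self) -> int:
        return len(self._pairs)

    def __repr__(self) -> str:
        return f"VariantMap({self.npairs()} pairs over {len(self)} variants)"


# ---------------------------------------------------------------------------
# input normalization

def _region_arrays(regions) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a per-chromosome region sequence to (starts, ends) arrays."""
    if isinstance(regions, tuple) and len(regions) >= 2 and \
            isinstance(regions[0], np.ndarray):
        starts = np.asarray(regions[0], dtype=np.int64)
        ends = np.asarray(regions[1], dtype=np.int64)
    else:
        regions = list(regions)
        if regions and hasattr(regions[0], "start"):
            starts = np.fromiter((r.start for r in regions), dtype=np.int64,
                                 count=len(regions))
            ends = np.fromiter((r.end for r in regions), dtype=np.int64,
                               count=len(regions))
        else:
            starts = np.fromiter((r[0] for r in regions), dtype=np.int64,
                                 count=len(regions))
            ends = np.fromiter((r[1] for r in regions), dtype=np.int64,
                               count=len(regions))
    return starts, ends


def _normalize_keys(mapping: Mapping[str, object], what: str) -> dict[str, object]:
    out: dict[str, object] = {}
    for name, val in mapping.items():
        key = normalize_chrom(name)
        if key in out:
            raise SweepError(
                f"{what} chromosome names {name!r} and {key!r} collide after "
                "chr-prefix normalization; merge them upstream")
        out[key] = val
    return out


def _check_sorted(arr: np.ndarray, what: str, chrom: str) -> None:
    if arr.size > 1 and np.any(arr[1:] < arr[:-1]):
        raise SweepError(f"{what} on {chrom} are not sorted; sweep precondition violated")


# ---------------------------------------------------------------------------
# joins

def point_join(variants: Mapping[str, Sequence[int] | np.ndarray],
               regions: Mapping[str, object]) -> VariantMap:
    """Exact-location join: variant v matches region r iff r.start <= p < r.end.

    Both inputs are per-chromosome mappings; variant points and region starts
    must be sorted ascending within each chromosome.  Chromosome names on the
    two sides are matched after ``chr``-prefix normalization.
    """
    vmap = VariantMap()
    var_by_chrom = _normalize_keys(variants, "variant")
    reg_by_chrom = _normalize_keys(regions, "region")
    for chrom in sorted(set(var_by_chrom) & set(reg_by_chrom)):
        points = np.asarray(var_by_chrom[chrom], dtype=np.int64)
        starts, ends = _region_arrays(reg_by_chrom[chrom])
        _check_sorted(points, "variant points", chrom)
        _check_sorted(starts, "region starts", chrom)
        _sweep_chrom(vmap, chrom, points, starts, ends, window=None)
    # account for regions on chromosomes with no variants: they are never
    # scanned, which is exactly the saving the directory pointers buy us
    return vmap


def window_join(variants: Mapping[str, Sequence[int] | np.ndarray],
                regions: Mapping[str, object], w: int) -> VariantMap:
    """Flanking-window join with flank ``w`` bases per side.

    The window of a variant at point p is ``[max(0, p-w), p+w+1)``; variant v
    matches region r iff the window overlaps ``[r.start, r.end)``.  ``w`` must
    lie in ``[0, 1_000_000]`` (flanks up to 1 Mb per side).
    """
    if not (0 <= w <= MAX_WINDOW):
        raise SweepError(f"flank size {w} outside [0, {MAX_WINDOW}]")
    vmap = VariantMap()
    var_by_chrom = _normalize_keys(variants, "variant")
    reg_by_chrom = _normalize_keys(regions, "region")
    for chrom in sorted(set(var_by_chrom) & set(reg_by_chrom)):
        points = np.asarray(var_by_chrom[chrom], dtype=np.int64)
        starts, ends = _region_arrays(reg_by_chrom[chrom])
        _check_sorted(points, "variant points", chrom)
        _check_sorted(starts, "region starts", chrom)
        _sweep_chrom(vmap, chrom, points, starts, ends, window=int(w))
    return vmap


def _sweep_chrom(vmap: VariantMap, chrom: str, points: np.ndarray,
                 starts: np.ndarray, ends: np.ndarray, window: int | None) -> None:
    """One chromosome's sweep; ``window=None`` selects exact-location mode."""
    nv, nr = points.size, starts.size
    if nv == 0 or nr == 0:
        return
    if window is None:
        coords = np.concatenate([ends, starts, points])
        pris = np.concatenate([
            np.full(nr, _PRI_REGION_END, np.int8),
            np.full(nr, _PRI_REGION_START, np.int8),
            np.full(nv, _PRI_VARIANT_POINT, np.int8),
        ])
    else:
        wstarts = np.maximum(points - window, 0)
        wends = points + window + 1
        coords = np.concatenate([ends, wends, starts, wstarts])
        pris = np.concatenate([
            np.full(nr, _PRI_REGION_END, np.int8),
            np.full(nv, _PRI_WINDOW_END, np.int8),
            np.full(nr, _PRI_REGION_START, np.int8),
            np.full(nv, _PRI_VARIANT_POINT, np.int8),
        ])
    if window is None:
        ids = np.concatenate([np.arange(nr), np.arange(nr), np.arange(nv)])
    else:
        ids = np.concatenate([np.arange(nr), np.arange(nv),
                              np.arange(nr), np.arange(nv)])
    order = np.lexsort((pris, coords))

    stats = vmap.stats
    feature_queue: set[int] = set()
    variant_queue: set[int] = set()
    add = vmap.add
    for k in order:
        pri = pris[k]
        ident = int(ids[k])
        if pri == _PRI_REGION_END:
            feature_queue.discard(ident)
            stats.feature_removals += 1
        elif pri == _PRI_REGION_START:
            feature_queue.add(ident)
            stats.feature_insertions += 1
            if window is not None:
                for vi in variant_queue:
                    add(chrom, vi, ident)
        elif pri == _PRI_WINDOW_END:
            variant_queue.discard(ident)
            stats.variant_removals += 1
        else:  # variant point / window start
            if window is not None:
                variant_queue.add(ident)
                stats.variant_insertions += 1
            for ri in feature_queue:
                add(chrom, ident, ri)


def brute_force_join(variants: Mapping[str, Sequence[int] | np.ndarray],
                     regions: Mapping[str, object], w: int = 0) -> VariantMap:
    """Quadratic all-pairs overlap oracle; definitionally correct reference.

    For every (variant, region) pair on one chromosome the pair is included
    iff the variant's window ``[max(0, p-w), p+w+1)`` intersects the region
    ``[start, end)``.  Needs no sorted inputs; used to verify the sweeps.
    """
    if w < 0:
        raise SweepError(f"flank size {w} negative")
    vmap = VariantMap()
    var_by_chrom = _normalize_keys(variants, "variant")
    reg_by_chrom = _normalize_keys(regions, "region")
    for chrom in sorted(set(var_by_chrom) & set(reg_by_chrom)):
        points = np.asarray(var_by_chrom[chrom], dtype=np.int64)
        starts, ends = _region_arrays(reg_by_chrom[chrom])
        if points.size == 0 or starts.size == 0:
            continue
        ws = np.maximum(points - w, 0)
        we = points + w + 1
        hit = (ws[:, None] < ends[None, :]) & (we[:, None] > starts[None, :])
        for vi, ri in zip(*np.nonzero(hit)):
            vmap.add(chrom, int(vi), int(ri))
    return vmap
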