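"""End-to-end annotation: join variants with feature stores and report.

For each selected feature store the variant list is joined per chromosome —
exact-location when the flanking window is 0, flanking-window otherwise —
and every variant/region hit becomes one report record.  Numeric features
are summarized per variant by the unweighted mean of the overlapping region
values and by that mean's mid-rank percentile among all region values of the
feature, genome-wide; categorical features report their labels.  The table
has one row per input variant (input order preserved) and one column group
per feature (selection order preserved); variants with no overlap for a
feature show blank cells, so a processed-but-unannotated variant is visible
rather than dropped.
"""

from __future__ import annotations

import csv
import secrets
import warnings
from dataclasses import dataclass, field

import numpy as np

from varsweep.errors import ConfigError
from varsweep.feature_store import CATEGORICAL, NUMERIC, FeatureStore, ValueDistribution
from varsweep.sweep import MAX_WINDOW, normalize_chrom, point_join, window_join
from varsweep.variant_io import Variant, VariantList


@dataclass(frozen=True)
class JobConfig:
    """Configuration of one annotation job.

    ``window`` is the flank in bases per side (0 = exact-location mode),
    capped at 1 Mb.  ``output`` is where :func:`write_table` puts the table;
    ``label`` is an optional free-text job label.
    """

    window: int = 0
    output: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.window <= MAX_WINDOW):
            raise ConfigError(
                f"flanking window {self.window} outside [0, {MAX_WINDOW}] bp")


@dataclass(frozen=True)
class AnnotationRecord:
    """One (variant, feature) result with at least one overlapping region."""

    variant: Variant
    feature: str
    count: int
    labels: tuple[str, ...] = ()
    mean: float | None = None
    percentile: float | None = None


@dataclass
class AnnotationTable:
    """All annotation records of a job, plus the full processed variant list."""

    variants: list[Variant]
    features: list[str]
    records: dict[tuple[int, str], AnnotationRecord] = field(default_factory=dict)

    def record_for(self, variant_index: int, feature: str) -> AnnotationRecord | None:
        return self.records.get((variant_index, feature))

    def rows(self) -> list[AnnotationRecord]:
        """Records in (input variant order, feature selection order)."""
        out = []
        for i in range(len(self.variants)):
            for f in self.features:
                rec = self.records.get((i, f))
                if rec is not None:
                    out.append(rec)
        return out


def percentile_rank(m: float, dist: ValueDistribution) -> float:
    """Mid-rank percentile of ``m`` in a sorted value multiset.

    ``p = 100 * (C_lt + 0.5 * C_eq) / N`` where ``C_lt`` values are strictly
    below ``m`` and ``C_eq`` equal it; ties count half, so p is symmetric
    and always inside [0, 100].
    """
    if dist.n == 0:
        raise ConfigError("percentile undefined on an empty value distribution")
    lo = int(np.searchsorted(dist.values, m, side="left"))
    hi = int(np.searchsorted(dist.values, m, side="right"))
    return 100.0 * (lo + 0.5 * (hi - lo)) / dist.n


def summarize_numeric(values, dist: ValueDistribution) -> tuple[float, float]:
    """Mean of the overlapping region values and its genome-wide percentile."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("summarize_numeric requires at least one overlapping region")
    m = float(values.mean())
    return m, percentile_rank(m, dist)


def dedup_unique_loci(vl: VariantList) -> tuple[int, VariantList]:
    """Count distinct (chromosome, point) loci; also return the deduplicated list.

    The first occurrence of each locus (input order) is kept.
    """
    seen: set[tuple[str, int]] = set()
    kept = []
    for v in vl:
        key = (v.chrom, v.point)
        if key not in seen:
            seen.add(key)
            kept.append(v)
    return len(seen), VariantList(kept)


def run_annotation(vl: VariantList, stores: list[FeatureStore],
                   cfg: JobConfig) -> AnnotationTable:
    """Annotate every variant of ``vl`` against every store in ``stores``.

    Chromosome names are matched after ``chr``-prefix normalization, and only
    the chromosomes shared with the variant list are scanned from each store
    (the store's directory pointers make that a seek, not a scan).  A store
    sharing no chromosome with the variant list triggers a warning; its
    column group stays blank.
    """
    if not stores:
        raise ConfigError("at least one feature store must be selected")
    names = [s.name for s in stores]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate feature names among selected stores: {names}")

    # per-chromosome sorted points + back-references to input order,
    # keyed by normalized chromosome name
    points_by_key: dict[str, np.ndarray] = {}
    vidx_by_key: dict[str, list[int]] = {}
    for chrom in vl.chromosomes:
        key = normalize_chrom(chrom)
        idx = vl.indices_for(chrom)
        pts = np.fromiter((vl.variants[i].point for i in idx), dtype=np.int64,
                          count=len(idx))
        if key in points_by_key:  # "1" and "chr1" both present: merge and re-sort
            pts = np.concatenate([points_by_key[key], pts])
            idx = vidx_by_key[key] + idx
            order = np.argsort(pts, kind="stable")
            pts = pts[order]
            idx = [idx[j] for j in order]
        points_by_key[key] = pts
        vidx_by_key[key] = idx

    table = AnnotationTable(variants=list(vl.variants), features=names)
    for store in stores:
        store_chroms = {normalize_chrom(c): c for c in store.chromosomes}
        shared = set(points_by_key) & set(store_chroms)
        if not shared:
            warnings.warn(
                f"feature {store.name!r} shares no chromosome with the variant "
                "list; its annotations will be empty", stacklevel=2)
            continue
        regions = {}
        values = {}
        for key in shared:
            starts, ends, vals = store.scan_arrays(store_chroms[key])
            regions[key] = (starts, ends)
            values[key] = vals
        variants = {key: points_by_key[key] for key in shared}
        if cfg.window == 0:
            vmap = point_join(variants, regions)
        else:
            vmap = window_join(variants, regions, cfg.window)
        dist = store.value_distribution() if store.value_type == NUMERIC else None
        for key in sorted(shared):
            for vi in range(len(vidx_by_key[key])):
                ris = sorted(vmap.regions_for(key, vi))
                if not ris:
                    continue
                input_i = vidx_by_key[key][vi]
                variant = vl.variants[input_i]
                if store.value_type == NUMERIC:
                    m, p = summarize_numeric(values[key][ris], dist)
                    rec = AnnotationRecord(variant=variant, feature=store.name,
                                           count=len(ris), mean=m, percentile=p)
                else:
                    labels = tuple(dict.fromkeys(str(values[key][ri])
                                                 for ri in ris))
                    rec = AnnotationRecord(variant=variant, feature=store.name,
                                           count=len(ris), labels=labels)
                table.records[(input_i, store.name)] = rec
    return table


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_table(t: AnnotationTable, path: str, format: str = "tsv") -> None:
    """Write the annotation table as TSV or an Excel spreadsheet.

    TSV dialect: UTF-8, tab separator, ``\\n`` line ends, mandatory header.
    Columns: chrom, pos, ref, alt, then per feature F the group ``F:count``,
    ``F:value``, ``F:percentile``.  Cells are blank where a variant has no
    overlap with a feature (and the percentile cell is blank for categorical
    features).
    """
    header = ["chrom", "pos", "ref", "alt"]
    for f in t.features:
        header += [f"{f}:count", f"{f}:value", f"{f}:percentile"]
    rows: list[list[str]] = []
    for i, v in enumerate(t.variants):
        row = [v.chrom, str(v.pos), v.ref, v.alt]
        for f in t.features:
            rec = t.records.get((i, f))
            if rec is None:
                row += ["", "", ""]
            elif rec.mean is not None:
                row += [str(rec.count), _fmt(rec.mean),
                        _fmt(rec.percentile) if rec.percentile is not None else ""]
            else:
                row += [str(rec.count), ",".join(rec.labels), ""]
        rows.append(row)

    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as out:
            writer = csv.writer(out, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)
    elif format == "spreadsheet":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "annotations"
        ws.append(header)
        for row in rows:
            ws.append(row)
        wb.save(path)
    else:
        raise ConfigError(f"unknown table format {format!r}")


def generate_job_id() -> str:
    """A unique 512-bit job identifier as 128 lowercase hex characters.

    Drawn from the OS cryptographic entropy source; collisions between
    independently generated identifiers are cryptographically negligible.
    """
    return secrets.token_hex(64)
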