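"""Indexed on-disk store for genomic feature tracks.

A feature track is a set of genomic regions, each carrying either a numeric
signal value (e.g. histone-mark coverage) or a categorical label (e.g. a
chromatin state).  For integration with variant lists the regions are sorted
by genomic location and written to a binary file together with a chromosome
directory: one pointer per chromosome giving the byte offset of its first
record, so a scan of one chromosome seeks straight to it and never touches
the records of preceding chromosomes.

Numeric stores additionally persist the sorted array of all region values,
so a window-mean around a variant can be placed as a percentile among all
genomic regions of the feature.

File layout (little-endian throughout)::

    magic "VASF" | version u8
    metadata: u16 name length, name UTF-8 | value type u8 (0 numeric,
              1 categorical) | string table: u32 label count, per label
              u16 length + UTF-8 bytes (empty for numeric stores)
    directory: u32 chromosome count; per chromosome: u8 name length, name,
              u64 byte offset of first record, u64 record count
    records:  per chromosome, sorted by (start, end): u32 start, u32 end,
              f32 value (numeric) or u32 label index (categorical)
    footer:   numeric stores only: u64 N, N sorted f32 values
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from varsweep.errors import RecordError, StoreError

MAGIC = b"VASF"
VERSION = 1

NUMERIC = "numeric"
CATEGORICAL = "categorical"

_MAX_COORD = 2 ** 32 - 1
_REC_DTYPE = np.dtype([("start", "<u4"), ("end", "<u4"), ("value", "<f4")])
_REC_DTYPE_CAT = np.dtype([("start", "<u4"), ("end", "<u4"), ("label", "<u4")])


@dataclass(frozen=True, slots=True)
class FeatureRegion:
    """One half-open genomic interval ``[start, end)`` carrying a value."""

    chrom: str
    start: int
    end: int
    value: float | str


@dataclass(frozen=True)
class ValueDistribution:
    """Exact sorted multiset of all numeric region values of a store."""

    values: np.ndarray  # sorted ascending, float64
    n: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))


def import_bed(stream: Iterable[str] | str,
               value_column: int | None = None) -> Iterator[FeatureRegion]:
    """Yield regions from BED 3-5 column or bedGraph-style 4-column text.

    ``value_column`` designates the 0-based column holding a numeric value
    (3 for bedGraph, 4 for BED score); without it the name column (3), if
    present, becomes a categorical label, and bare 3-column lines get the
    constant label ``"present"``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            fields = line.split()
        if len(fields) < 3:
            raise RecordError("expected at least chrom, start, end", lineno)
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise RecordError(f"non-integer interval {fields[1]!r}..{fields[2]!r}",
                              lineno) from None
        if start < 0:
            raise RecordError(f"negative start {start}", lineno)
        if start >= end:
            raise RecordError(f"empty or inverted interval [{start}, {end})", lineno)
        value: float | str
        if value_column is not None:
            if value_column >= len(fields):
                raise RecordError(f"value column {value_column} missing", lineno)
            try:
                value = float(fields[value_column])
            except ValueError:
                raise RecordError(
                    f"non-numeric value {fields[value_column]!r}", lineno) from None
        elif len(fields) > 3:
            value = fields[3]
        else:
            value = "present"
        yield FeatureRegion(chrom=chrom, start=start, end=end, value=value)


def _write_str(out, s: str, width: int) -> None:
    b = s.encode("utf-8")
    if len(b) >= 2 ** (8 * width):
        raise StoreError(f"string too long for {width}-byte length field: {s!r}")
    out.write(len(b).to_bytes(width, "little"))
    out.write(b)


def build_store(regions: Iterable[FeatureRegion], name: str, value_type: str,
                path: str | os.PathLike) -> "FeatureStore":
    """Sort regions, write the indexed binary store at ``path`` and open it.

    Regions may arrive unsorted and may mutually overlap; overlaps are
    preserved as-is (the sweep's active set handles them), only the order is
    normalized: chromosomes lexicographically, records by ``(start, end)``
    within each chromosome.  An empty region sequence yields a valid empty
    store.
    """
    if value_type not in (NUMERIC, CATEGORICAL):
        raise StoreError(f"unknown value type {value_type!r}")
    by_chrom: dict[str, list[FeatureRegion]] = {}
    all_values: list[float] = []
    labels: set[str] = set()
    for r in regions:
        if r.start < 0 or r.start >= r.end:
            raise StoreError(f"invalid interval [{r.start}, {r.end}) on {r.chrom}")
        if r.end > _MAX_COORD:
            raise StoreError(f"coordinate {r.end} exceeds u32 range")
        if value_type == NUMERIC:
            if isinstance(r.value, str):
                raise StoreError(
                    f"categorical label {r.value!r} in numeric store {name!r}")
            all_values.append(float(r.value))
        else:
            if not isinstance(r.value, str):
                raise StoreError(
                    f"numeric value {r.value!r} in categorical store {name!r}")
            labels.add(r.value)
        by_chrom.setdefault(r.chrom, []).append(r)

    label_list = sorted(labels)
    label_index = {lab: i for i, lab in enumerate(label_list)}

    meta = io.BytesIO()
    meta.write(MAGIC)
    meta.write(bytes([VERSION]))
    _write_str(meta, name, 2)
    meta.write(bytes([0 if value_type == NUMERIC else 1]))
    meta.write(len(label_list).to_bytes(4, "little"))
    for lab in label_list:
        _write_str(meta, lab, 2)

    chroms = sorted(by_chrom)
    dir_size = 4 + sum(1 + len(c.encode("utf-8")) + 8 + 8 for c in chroms)
    rec_size = _REC_DTYPE.itemsize
    offset = meta.tell() + dir_size

    directory = io.BytesIO()
    directory.write(len(chroms).to_bytes(4, "little"))
    blocks: list[bytes] = []
    for chrom in chroms:
        recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        arr = np.empty(len(recs), dtype=_REC_DTYPE if value_type == NUMERIC
                       else _REC_DTYPE_CAT)
        arr["start"] = [r.start for r in recs]
        arr["end"] = [r.end for r in recs]
        if value_type == NUMERIC:
            arr["value"] = [float(r.value) for r in recs]
        else:
            arr["label"] = [label_index[r.value] for r in recs]
        block = arr.tobytes()
        _write_str(directory, chrom, 1)
        directory.write(offset.to_bytes(8, "little"))
        directory.write(len(recs).to_bytes(8, "little"))
        blocks.append(block)
        offset += len(block)
    assert directory.tell() == dir_size

    with open(path, "wb") as out:
        out.write(meta.getvalue())
        out.write(directory.getvalue())
        for block in blocks:
            out.write(block)
        if value_type == NUMERIC:
            vals = np.sort(np.asarray(all_values, dtype=np.float32))
            out.write(len(vals).to_bytes(8, "little"))
            out.write(vals.astype("<f4").tobytes())
    return FeatureStore(path)


class FeatureStore:
    """An open, read-only handle on an indexed feature-track file.

    ``records_read`` counts the records decoded since opening; tests use it
    to assert that per-chromosome scans really seek instead of scanning from
    the start of the file.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self.records_read = 0
        with open(self.path, "rb") as f:
            data = f.read()
        buf = memoryview(data)
        if bytes(buf[:4]) != MAGIC:
            raise StoreError(f"bad magic {bytes(buf[:4])!r} in {self.path}")
        if buf[4] != VERSION:
            raise StoreError(f"unsupported store version {buf[4]}")
        off = 5
        namelen = int.from_bytes(buf[off:off + 2], "little"); off += 2
        self.name = bytes(buf[off:off + namelen]).decode("utf-8"); off += namelen
        self.value_type = NUMERIC if buf[off] == 0 else CATEGORICAL; off += 1
        nlabels = int.from_bytes(buf[off:off + 4], "little"); off += 4
        self.labels: list[str] = []
        for _ in range(nlabels):
            n = int.from_bytes(buf[off:off + 2], "little"); off += 2
            self.labels.append(bytes(buf[off:off + n]).decode("utf-8")); off += n
        nchrom = int.from_bytes(buf[off:off + 4], "little"); off += 4
        self._directory: dict[str, tuple[int, int]] = {}
        self._chrom_order: list[str] = []
        for _ in range(nchrom):
            n = buf[off]; off += 1
            cname = bytes(buf[off:off + n]).decode("utf-8"); off += n
            coffset = int.from_bytes(buf[off:off + 8], "little"); off += 8
            count = int.from_bytes(buf[off:off + 8], "little"); off += 8
            self._directory[cname] = (coffset, count)
            self._chrom_order.append(cname)
        self._data = data
        self._records_end = off + sum(c * _REC_DTYPE.itemsize
                                      for _, c in self._directory.values())
        self._dist: ValueDistribution | None = None
        if self.value_type == NUMERIC:
            foff = self._records_end
            n = int.from_bytes(buf[foff:foff + 8], "little")
            vals = np.frombuffer(data, dtype="<f4", count=n, offset=foff + 8)
            self._dist = ValueDistribution(values=vals.astype(np.float64), n=n)

    # -- directory ---------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_order)

    @property
    def directory(self) -> dict[str, tuple[int, int]]:
        """Mapping chromosome -> (byte offset, record count)."""
        return dict(self._directory)

    @property
    def total_records(self) -> int:
        return sum(c for _, c in self._directory.values())

    # -- scanning ----------------------------------------------------------

    def scan_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return this chromosome's sorted ``(starts, ends, values)`` arrays.

        Reads begin at the directory offset for ``chrom``; an absent
        chromosome yields empty arrays.  ``values`` is float64 for numeric
        stores and an object array of labels for categorical stores.
        """
        entry = self._directory.get(chrom)
        if entry is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty.copy(), np.empty(0, dtype=object)
        offset, count = entry
        dtype = _REC_DTYPE if self.value_type == NUMERIC else _REC_DTYPE_CAT
        arr = np.frombuffer(self._data, dtype=dtype, count=count, offset=offset)
        self.records_read += count
        starts = arr["start"].astype(np.int64)
        ends = arr["end"].astype(np.int64)
        if self.value_type == NUMERIC:
            values = arr["value"].astype(np.float64)
        else:
            labels = np.asarray(self.labels, dtype=object)
            values = labels[arr["label"]] if count else np.empty(0, dtype=object)
        return starts, ends, values

    def scan_regions(self, chrom: str) -> Iterator[FeatureRegion]:
        """Yield this chromosome's records in (start, end) order."""
        starts, ends, values = self.scan_arrays(chrom)
        for s, e, v in zip(starts, ends, values):
            yield FeatureRegion(chrom=chrom, start=int(s), end=int(e),
                                value=v if isinstance(v, str) else float(v))

    def scan_all(self) -> Iterator[FeatureRegion]:
        """Full sequential scan: concatenation of per-chromosome scans."""
        for chrom in self._chrom_order:
            yield from self.scan_regions(chrom)

    # -- value distribution ------------------------------------------------

    def value_distribution(self) -> ValueDistribution:
        """The sorted multiset of all region values (numeric stores only)."""
        if self.value_type != NUMERIC:
            raise StoreError(
                f"value distribution unsupported on categorical store {self.name!r}")
        assert self._dist is not None
        return self._dist


def scan_regions(store: FeatureStore, chrom: str) -> Iterator[FeatureRegion]:
    """Module-level convenience alias for :meth:`FeatureStore.scan_regions`."""
    return store.scan_regions(chrom)


def value_distribution(store: FeatureStore) -> ValueDistribution:
    """Module-level convenience alias for :meth:`FeatureStore.value_distribution`."""
    return store.value_distribution()
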