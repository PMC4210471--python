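"""Variant-list parsing, classification and the compact transfer codec.

Variant lists arrive as VCF or whitespace-delimited text.  Each record is
classified (SNV / insertion / deletion / point-only) and reduced to a single
representative genome coordinate: the exact location for an SNV or an
insertion, the mid-point of the deleted span for a deletion.  Internally all
coordinates are 0-based; text inputs are read as 1-based and converted on
parse.

For transfer, a variant list is reduced to per-chromosome arrays of
locations: within each chromosome the first location is stored as an absolute
unsigned LEB128 varint and every subsequent location as the delta to its
predecessor.  Repetitive text (chromosome names, alleles, genotypes) is
dropped entirely, so a multi-million-variant list compresses to a few
megabytes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from varsweep.errors import CodecError, CorruptPayloadError, FormatError, VariantParseError

MAGIC = b"VASC"
VERSION = 1

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"
POINT_ONLY = "point-only"


@dataclass(frozen=True, slots=True)
class Variant:
    """One input locus.

    ``pos`` is the 1-based position as parsed from the input; ``point`` is
    the 0-based representative coordinate used by all downstream joins.
    ``ref``/``alt`` are empty strings for bare location lists.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str
    point: int


def classify(ref: str, alt: str) -> str:
    """Classify a record from its alleles.

    SNV if both alleles are single bases, insertion if the alternate is
    longer, deletion if the reference is longer, point-only if no alleles
    were given at all.
    """
    if not ref and not alt:
        return POINT_ONLY
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(alt) > len(ref):
        return INSERTION
    return DELETION


def representative_point(v: Variant) -> int:
    """Return the 0-based representative coordinate of a variant.

    SNVs, insertions and point-only records map to their exact (0-based)
    location.  A deletion spanning the 0-based half-open interval
    ``[s, s + |ref|)`` maps to the floor mid-point of the deleted span,
    ``(s + s + |ref| - 1) // 2``.
    """
    s = v.pos - 1
    if v.kind == DELETION:
        return (s + s + len(v.ref) - 1) // 2
    return s


def make_variant(chrom: str, pos: int, ref: str = "", alt: str = "") -> Variant:
    """Build a classified :class:`Variant` from parsed fields (1-based pos)."""
    kind = classify(ref, alt)
    v = Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, kind=kind, point=0)
    point = representative_point(v)
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, kind=kind, point=point)


class VariantList:
    """A variant list with per-chromosome point-sorted views.

    Variants are kept in input order (``variants``); per-chromosome index
    arrays sorted (stably) by representative point provide the sorted views
    the sweep joins require.  Ties at the same point keep input order.
    """

    def __init__(self, variants: Sequence[Variant]):
        self.variants: list[Variant] = list(variants)
        by_chrom: dict[str, list[int]] = {}
        for i, v in enumerate(self.variants):
            by_chrom.setdefault(v.chrom, []).append(i)
        self._by_chrom: dict[str, list[int]] = {}
        for chrom, idx in by_chrom.items():
            pts = np.fromiter((self.variants[i].point for i in idx), dtype=np.int64,
                              count=len(idx))
            order = np.argsort(pts, kind="stable")
            self._by_chrom[chrom] = [idx[j] for j in order]

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def indices_for(self, chrom: str) -> list[int]:
        """Input-order indices of this chromosome's variants, sorted by point."""
        return self._by_chrom.get(chrom, [])

    def variants_for(self, chrom: str) -> list[Variant]:
        return [self.variants[i] for i in self.indices_for(chrom)]

    def points_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted 0-based point arrays, one per chromosome."""
        return {
            chrom: np.fromiter((self.variants[i].point for i in idx), dtype=np.int64,
                               count=len(idx))
            for chrom, idx in self._by_chrom.items()
        }

    @classmethod
    def from_points(cls, points_by_chrom: Mapping[str, Sequence[int]]) -> "VariantList":
        """Build a point-only list from per-chromosome 0-based coordinates."""
        variants = []
        for chrom in sorted(points_by_chrom):
            for p in points_by_chrom[chrom]:
                p = int(p)
                variants.append(Variant(chrom=chrom, pos=p + 1, ref="", alt="",
                                        kind=POINT_ONLY, point=p))
        return cls(variants)


@dataclass(frozen=True)
class CompressedVariants:
    """The opaque transfer payload plus its chromosome directory.

    ``directory`` holds ``(chromosome name, variant count, byte offset)``
    triples; the offset points at the chromosome's block inside ``payload``.
    """

    payload: bytes
    directory: tuple[tuple[str, int, int], ...]

    def __len__(self) -> int:
        return len(self.payload)


# ---------------------------------------------------------------------------
# parsing

def _detect_format(lines: list[tuple[int, str]], header_said_vcf: bool) -> str:
    if header_said_vcf:
        return "vcf"
    for _, line in lines:
        # VCF body lines carry at least CHROM POS ID REF ALT
        if len(line.split("\t")) >= 5:
            return "vcf"
        return "list"
    return "list"


def _norm_allele(a: str) -> str:
    return "" if a in (".", "") else a


def parse_variants(stream: Iterable[str] | str, format_hint: str = "auto",
                   on_error: str = "raise") -> VariantList:
    """Parse a variant list from VCF or whitespace-delimited text.

    Parameters
    ----------
    stream:
        An iterable of lines (an open text file works) or a single string.
    format_hint:
        ``"vcf"``, ``"list"``, or ``"auto"``.  In auto mode the format is
        detected from a ``##fileformat=VCF`` header line or, failing that,
        from the column count of the first data line.
    on_error:
        ``"raise"`` (default) aborts on the first malformed record with a
        :class:`~varsweep.errors.VariantParseError` naming the line;
        ``"skip"`` drops malformed records.

    Header and comment lines (leading ``#``) are skipped.  Multi-allelic VCF
    records contribute only their first ALT allele.
    """
    if format_hint not in ("vcf", "list", "auto"):
        raise FormatError(f"unknown format hint {format_hint!r}")
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    header_said_vcf = False
    data_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("##fileformat=VCF"):
                header_said_vcf = True
            continue
        data_lines.append((lineno, line))

    fmt = format_hint if format_hint != "auto" else _detect_format(data_lines, header_said_vcf)

    variants: list[Variant] = []
    for lineno, line in data_lines:
        try:
            if fmt == "vcf":
                fields = line.split("\t")
                if len(fields) < 5:
                    raise VariantParseError(
                        f"VCF record has {len(fields)} columns, expected >= 5", lineno)
                chrom, pos_s, _id, ref, alt = fields[:5]
                ref = _norm_allele(ref)
                alt = _norm_allele(alt.split(",")[0])
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise VariantParseError(
                        f"expected at least chrom and position, got {len(fields)} columns",
                        lineno)
                chrom, pos_s = fields[0], fields[1]
                ref = _norm_allele(fields[2]) if len(fields) > 2 else ""
                alt = _norm_allele(fields[3]) if len(fields) > 3 else ""
            try:
                pos = int(pos_s)
            except ValueError:
                raise VariantParseError(f"non-integer position {pos_s!r}", lineno) from None
            if pos < 1:
                raise VariantParseError(f"position {pos} < 1", lineno)
            variants.append(make_variant(chrom, pos, ref, alt))
        except VariantParseError:
            if on_error == "raise":
                raise
    return VariantList(variants)


# ---------------------------------------------------------------------------
# codec

def _encode_uleb128_array(values: np.ndarray) -> bytes:
    """Vectorized unsigned LEB128 encoding of a non-negative integer array."""
    v = np.ascontiguousarray(values, dtype=np.uint64)
    if v.size == 0:
        return b""
    seven = np.uint64(7)
    nbytes = np.ones(v.shape, dtype=np.int64)
    t = v >> seven
    while True:
        nz = t != 0
        if not nz.any():
            break
        nbytes += nz
        t >>= seven
    starts = np.zeros(v.size, dtype=np.int64)
    np.cumsum(nbytes[:-1], out=starts[1:])
    out = np.zeros(int(starts[-1] + nbytes[-1]), dtype=np.uint8)
    idx = np.arange(v.size)
    rem = v.copy()
    k = 0
    while idx.size:
        more = rem >> seven
        cont = more != 0
        byte = (rem & np.uint64(0x7F)).astype(np.uint8)
        byte[cont] |= 0x80
        out[starts[idx] + k] = byte
        idx = idx[cont]
        rem = more[cont]
        k += 1
    return out.tobytes()


def _decode_uleb128(buf: memoryview, offset: int, count: int) -> tuple[np.ndarray, int]:
    """Decode ``count`` unsigned LEB128 varints starting at ``offset``."""
    values = np.empty(count, dtype=np.uint64)
    n = len(buf)
    for i in range(count):
        result = 0
        shift = 0
        while True:
            if offset >= n:
                raise CorruptPayloadError("payload truncated mid-varint", offset)
            b = buf[offset]
            offset += 1
            result |= (b & 0x7F) << shift
            if not (b & 0x80):
                break
            shift += 7
            if shift > 63:
                raise CorruptPayloadError("varint overflows 64 bits", offset)
        values[i] = result
    return values, offset


def compress_variants(vl: VariantList) -> CompressedVariants:
    """Encode a variant list's locations into the compact transfer payload.

    Layout (all multi-byte integers little-endian): magic ``VASC``, version
    byte, u32 chromosome count, then per chromosome (lexicographic name
    order): u8 name length, UTF-8 name, u64 location count, and the sorted
    0-based locations as unsigned LEB128 varints — the first absolute, the
    rest deltas to the predecessor.  Only locations survive; alleles and any
    other record text are dropped.
    """
    parts = [MAGIC, bytes([VERSION])]
    chroms = vl.chromosomes
    parts.append(len(chroms).to_bytes(4, "little"))
    directory = []
    offset = 4 + 1 + 4
    points = vl.points_by_chrom()
    bound = 16
    for chrom in chroms:
        name = chrom.encode("utf-8")
        if len(name) > 255:
            raise CodecError(f"chromosome name longer than 255 bytes: {chrom!r}")
        pts = points[chrom]
        deltas = np.empty_like(pts)
        if pts.size:
            deltas[0] = pts[0]
            np.subtract(pts[1:], pts[:-1], out=deltas[1:])
        body = _encode_uleb128_array(deltas)
        block = b"".join([bytes([len(name)]), name,
                          int(pts.size).to_bytes(8, "little"), body])
        directory.append((chrom, int(pts.size), offset))
        parts.append(block)
        offset += len(block)
        bound += 2 + len(name) + 8 + 5 * pts.size
    payload = b"".join(parts)
    # size guarantee of the format: varints for human-scale coordinates
    # never exceed 5 bytes, headers are covered by the constant terms
    assert len(payload) <= bound, "codec produced payload above its size bound"
    return CompressedVariants(payload=payload, directory=tuple(directory))


def decompress_variants(cv: CompressedVariants | bytes) -> VariantList:
    """Decode a compact payload back into a (point-only) variant list.

    Exact inverse of :func:`compress_variants` on locations.  Raises
    :class:`~varsweep.errors.FormatError` on a bad magic or version and
    :class:`~varsweep.errors.CorruptPayloadError` (naming the byte offset)
    on truncation; no partial result is ever returned.
    """
    payload = cv.payload if isinstance(cv, CompressedVariants) else bytes(cv)
    buf = memoryview(payload)
    if len(buf) < 9:
        raise CorruptPayloadError("payload shorter than fixed header", len(buf))
    if bytes(buf[:4]) != MAGIC:
        raise FormatError(f"bad magic {bytes(buf[:4])!r}, expected {MAGIC!r}")
    if buf[4] != VERSION:
        raise FormatError(f"unsupported payload version {buf[4]}")
    nchrom = int.from_bytes(buf[5:9], "little")
    offset = 9
    points: dict[str, np.ndarray] = {}
    for _ in range(nchrom):
        if offset >= len(buf):
            raise CorruptPayloadError("payload truncated before chromosome entry", offset)
        namelen = buf[offset]
        offset += 1
        if offset + namelen + 8 > len(buf):
            raise CorruptPayloadError("payload truncated inside chromosome header", offset)
        name = bytes(buf[offset:offset + namelen]).decode("utf-8")
        offset += namelen
        count = int.from_bytes(buf[offset:offset + 8], "little")
        offset += 8
        deltas, offset = _decode_uleb128(buf, offset, count)
        points[name] = np.cumsum(deltas.astype(np.int64)) if count else np.empty(0, np.int64)
    if offset != len(buf):
        raise CorruptPayloadError("trailing bytes after last chromosome block", offset)
    return VariantList.from_points(points)
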