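"""Tabix (.tbi) index parsing, evaluation, and construction.

A Tabix index maps a genomic region to the minimal set of compressed-file
chunks that can contain overlapping records.  It combines:

* a 5-level hierarchical binning scheme (min interval 2^14 bp, bin ids
  0..37448) assigning each record to the smallest bin containing it, with a
  list of (virtual offset begin, end) chunks per bin; and
* a linear index with one virtual offset per 16,384-bp window: the file
  position of the first record that could overlap that window, used to
  discard chunks of large bins that end before the query region's window.

All coordinates in this module are 0-based half-open; conversion from
1-based inclusive user regions happens once, in :mod:`variome.source`.
"""

from __future__ import annotations

import gzip
import io
import struct
from dataclasses import dataclass, field

from . import bgzf
from .errors import ArgumentError, FormatError

MAGIC = b"TBI\x01"

#: Linear-index window shift (16 kb windows).
LINEAR_SHIFT = 14
#: Number of binning levels (root..leaf) and the maximum bin id + 1.
N_LEVELS = 6
MAX_BIN = 37449  # ((1 << 18) - 1) // 7 + 4681 + 1 == bins over 5 levels
MAX_COORD = 1 << 29

#: Tabix preset: generic / SAM / VCF flags for the ``format`` header field.
FMT_GENERIC, FMT_SAM, FMT_VCF = 0, 1, 2


@dataclass(frozen=True)
class Chunk:
    """A [beg, end) span of the compressed file, in packed virtual offsets."""

    beg: int
    end: int


@dataclass
class TabixHeader:
    n_ref: int
    format: int = FMT_VCF
    col_seq: int = 1
    col_beg: int = 2
    col_end: int = 0
    meta_char: int = ord("#")
    skip: int = 0
    names: list[str] = field(default_factory=list)


@dataclass
class TabixIndex:
    header: TabixHeader
    bins: list[dict[int, list[Chunk]]]  # per contig: bin id -> chunks
    linear: list[list[int]]  # per contig: virtual offset per 16-kb window

    def __post_init__(self) -> None:
        self._name_to_id = {name: i for i, name in enumerate(self.header.names)}

    def contig_id(self, name: str) -> int | None:
        return self._name_to_id.get(name)

    @property
    def names(self) -> list[str]:
        return self.header.names


def reg2bin(beg: int, end: int) -> int:
    """Smallest bin fully containing the 0-based half-open interval [beg, end)."""
    _check_interval(beg, end)
    end -= 1
    if beg >> 14 == end >> 14:
        return ((1 << 15) - 1) // 7 + (beg >> 14)
    if beg >> 17 == end >> 17:
        return ((1 << 12) - 1) // 7 + (beg >> 17)
    if beg >> 20 == end >> 20:
        return ((1 << 9) - 1) // 7 + (beg >> 20)
    if beg >> 23 == end >> 23:
        return ((1 << 6) - 1) // 7 + (beg >> 23)
    if beg >> 26 == end >> 26:
        return ((1 << 3) - 1) // 7 + (beg >> 26)
    return 0


def reg2bins(beg: int, end: int) -> list[int]:
    """All bins whose spans overlap [beg, end), ascending."""
    _check_interval(beg, end)
    end -= 1
    bins = [0]
    for offset, shift in ((1, 26), (9, 23), (73, 20), (585, 17), (4681, 14)):
        bins.extend(range(offset + (beg >> shift), offset + (end >> shift) + 1))
    return bins


def _check_interval(beg: int, end: int) -> None:
    if not 0 <= beg < end <= MAX_COORD:
        raise ArgumentError(f"invalid interval [{beg}, {end}) for tabix binning")


def parse_index(raw: bytes) -> TabixIndex:
    """Parse gzip/BGZF-compressed .tbi bytes into a :class:`TabixIndex`."""
    try:
        body = gzip.decompress(raw)
    except (OSError, EOFError) as exc:
        raise FormatError(f"index is not gzip-compressed: {exc}") from exc
    if body[:4] == b"CSI\x01":
        raise FormatError("CSI indexes are not supported; a .tbi Tabix index is required")
    if body[:4] != MAGIC:
        raise FormatError(f"bad tabix magic {body[:4]!r}; expected {MAGIC!r}")
    buf = io.BytesIO(body[4:])

    def read(fmt: str):
        size = struct.calcsize(fmt)
        data = buf.read(size)
        if len(data) < size:
            raise FormatError("truncated tabix index body")
        return struct.unpack(fmt, data)

    n_ref, fmt, col_seq, col_beg, col_end, meta, skip, l_nm = read("<8i")
    names_blob = buf.read(l_nm)
    if len(names_blob) < l_nm:
        raise FormatError("truncated tabix contig name block")
    names = [n.decode() for n in names_blob.split(b"\x00") if n]
    if len(names) != n_ref:
        raise FormatError(f"tabix header declares {n_ref} contigs but names {len(names)}")
    header = TabixHeader(n_ref, fmt, col_seq, col_beg, col_end, meta, skip, names)
    bins: list[dict[int, list[Chunk]]] = []
    linear: list[list[int]] = []
    for _ in range(n_ref):
        (n_bin,) = read("<i")
        bin_map: dict[int, list[Chunk]] = {}
        for _ in range(n_bin):
            bin_id, n_chunk = read("<Ii")
            chunks = []
            for _ in range(n_chunk):
                cbeg, cend = read("<QQ")
                chunks.append(Chunk(cbeg, cend))
            bin_map[bin_id] = chunks
        (n_intv,) = read("<i")
        ioff = list(read(f"<{n_intv}Q")) if n_intv else []
        bins.append(bin_map)
        linear.append(ioff)
    return TabixIndex(header=header, bins=bins, linear=linear)


def query_chunks(index: TabixIndex, contig: str, beg: int, end: int) -> list[Chunk] | None:
    """Minimal merged chunk list for [beg, end) on ``contig``.

    Returns ``None`` when the contig is absent from the index (the caller
    decides whether that is an error); an empty list when the contig exists
    but no chunk can overlap the region.
    """
    cid = index.contig_id(contig)
    if cid is None:
        return None
    bin_map = index.bins[cid]
    ioff = index.linear[cid]
    window = beg >> LINEAR_SHIFT
    if ioff:
        min_off = ioff[window] if window < len(ioff) else ioff[-1]
    else:
        min_off = 0
    chunks = [
        c
        for b in reg2bins(beg, end)
        for c in bin_map.get(b, ())
        if c.end > min_off
    ]
    chunks.sort(key=lambda c: (c.beg, c.end))
    merged: list[Chunk] = []
    for c in chunks:
        if merged and c.beg <= merged[-1].end:
            if c.end > merged[-1].end:
                merged[-1] = Chunk(merged[-1].beg, c.end)
        else:
            merged.append(Chunk(c.beg, c.end))
    return merged


def write_index(
    records,
    names: list[str],
    header: TabixHeader | None = None,
) -> bytes:
    """Build .tbi bytes from sorted record spans.

    ``records`` iterates ``(contig, beg, end, vo_start, vo_end)`` with 0-based
    half-open coordinates and packed virtual offsets, sorted by
    (position of contig in ``names``, beg).  Raises on unsorted input, naming
    the offending record.
    """
    order = {name: i for i, name in enumerate(names)}
    bins: list[dict[int, list[Chunk]]] = [dict() for _ in names]
    linear: list[dict[int, int]] = [dict() for _ in names]
    prev = (-1, -1)
    for contig, beg, end, vo_start, vo_end in records:
        if contig not in order:
            raise ArgumentError(f"record contig {contig!r} not in declared contig order")
        cid = order[contig]
        if (cid, beg) < prev:
            raise ArgumentError(
                f"unsorted input at record {contig}:{beg + 1} (previous contig id "
                f"{prev[0]}, position {prev[1] + 1})"
            )
        prev = (cid, beg)
        b = reg2bin(beg, end)
        chunk_list = bins[cid].setdefault(b, [])
        if chunk_list and vo_start <= chunk_list[-1].end:
            chunk_list[-1] = Chunk(chunk_list[-1].beg, max(chunk_list[-1].end, vo_end))
        else:
            chunk_list.append(Chunk(vo_start, vo_end))
        lin = linear[cid]
        for w in range(beg >> LINEAR_SHIFT, ((end - 1) >> LINEAR_SHIFT) + 1):
            if w not in lin or vo_start < lin[w]:
                lin[w] = min(lin.get(w, vo_start), vo_start)

    hdr = header or TabixHeader(n_ref=len(names), names=list(names))
    hdr.n_ref = len(names)
    hdr.names = list(names)

    out = io.BytesIO()
    out.write(MAGIC)
    names_blob = b"".join(n.encode() + b"\x00" for n in names)
    out.write(
        struct.pack(
            "<8i",
            hdr.n_ref,
            hdr.format,
            hdr.col_seq,
            hdr.col_beg,
            hdr.col_end,
            hdr.meta_char,
            hdr.skip,
            len(names_blob),
        )
    )
    out.write(names_blob)
    for cid in range(len(names)):
        bin_map = bins[cid]
        out.write(struct.pack("<i", len(bin_map)))
        for bin_id in sorted(bin_map):
            chunks = bin_map[bin_id]
            out.write(struct.pack("<Ii", bin_id, len(chunks)))
            for c in chunks:
                out.write(struct.pack("<QQ", c.beg, c.end))
        lin = linear[cid]
        n_intv = (max(lin) + 1) if lin else 0
        ioff = []
        last = 0
        for w in range(n_intv):
            if w in lin:
                last = lin[w]
            ioff.append(last)
        # enforce the non-decreasing invariant (records sorted by beg can
        # still leave a later window pointing earlier via long spans)
        for i in range(1, n_intv):
            if ioff[i] < ioff[i - 1]:
                ioff[i] = ioff[i - 1]
        out.write(struct.pack("<i", n_intv))
        if n_intv:
            out.write(struct.pack(f"<{n_intv}Q", *ioff))
    return bgzf.write_stream(out.getvalue())
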