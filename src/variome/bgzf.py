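"""BGZF (blocked gzip) reading and writing with virtual file offsets.

BGZF is a series of <= 64 KiB gzip members, each carrying its compressed
size in a ``BC`` extra subfield, so any block can be located and inflated
without touching the rest of the stream.  A *virtual offset* packs the
compressed byte offset of a block (high 48 bits) with the byte offset into
its decompressed payload (low 16 bits); ordering of packed values equals
lexicographic ordering of the pairs.  This is the random-access primitive
underneath Tabix region queries.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import Iterator

from .errors import ArgumentError, CorruptionError, FormatError

#: Maximum payload per block; keeps the compressed block under 65536 bytes
#: even for incompressible data (htslib convention).
BLOCK_PAYLOAD_LIMIT = 65280

#: The canonical 28-byte BGZF end-of-file marker (an empty block).
EOF_MARKER = bytes.fromhex(
    "1f8b08040000000000ff0600424302001b0003000000000000000000"
)

_GZIP_MAGIC = b"\x1f\x8b"
_FLG_FEXTRA = 0x04


def pack_virtual_offset(coffset: int, uoffset: int) -> int:
    """Pack (compressed offset, intra-block offset) into a 64-bit integer."""
    if not 0 <= uoffset < 65536:
        raise ArgumentError(f"uoffset out of range [0, 65536): {uoffset}")
    if not 0 <= coffset < 1 << 48:
        raise ArgumentError(f"coffset out of range [0, 2^48): {coffset}")
    return (coffset << 16) | uoffset


def unpack_virtual_offset(voffset: int) -> tuple[int, int]:
    """Split a packed virtual offset into (coffset, uoffset)."""
    if not 0 <= voffset < 1 << 64:
        raise ArgumentError(f"virtual offset out of range: {voffset}")
    return voffset >> 16, voffset & 0xFFFF


@dataclass(frozen=True)
class BgzfBlock:
    """One decoded BGZF block."""

    compressed_size: int  # bytes on disk, header + deflate data + footer
    payload: bytes  # decompressed content

    def __len__(self) -> int:
        return len(self.payload)


def _parse_bsize(header12: bytes, extra: bytes, offset: int) -> int:
    """Extract BSIZE from the FEXTRA subfields; raise if the BC field is absent."""
    i = 0
    while i + 4 <= len(extra):
        si1, si2, slen = extra[i], extra[i + 1], struct.unpack_from("<H", extra, i + 2)[0]
        if si1 == 66 and si2 == 67:  # 'B','C'
            if slen != 2:
                raise FormatError(f"bad BC subfield length {slen} at offset {offset}")
            return struct.unpack_from("<H", extra, i + 4)[0]
        i += 4 + slen
    raise FormatError(
        f"gzip member at offset {offset} lacks the BGZF 'BC' extra subfield "
        "(plain gzip is not randomly accessible; recompress with bgzip)"
    )


def read_block(source, offset: int, check_crc: bool = True) -> BgzfBlock:
    """Read and inflate the BGZF block starting at compressed byte ``offset``.

    ``source`` is any object with ``read(offset, length) -> bytes``.  Exactly
    the block's declared BSIZE+1 bytes are requested from the source.
    """
    header = source.read(offset, 12)
    if len(header) < 12:
        raise FormatError(f"truncated BGZF block header at offset {offset}")
    if header[:2] != _GZIP_MAGIC:
        raise FormatError(f"no gzip magic at offset {offset}: not a BGZF block start")
    flg = header[3]
    if not flg & _FLG_FEXTRA:
        raise FormatError(
            f"gzip member at offset {offset} has no FEXTRA field: plain gzip, not BGZF"
        )
    xlen = struct.unpack_from("<H", header, 10)[0]
    extra = source.read(offset + 12, xlen)
    if len(extra) < xlen:
        raise FormatError(f"truncated FEXTRA field at offset {offset}")
    bsize = _parse_bsize(header, extra, offset)
    compressed_size = bsize + 1
    body = source.read(offset + 12 + xlen, compressed_size - 12 - xlen)
    if len(body) < compressed_size - 12 - xlen:
        raise FormatError(f"truncated BGZF block body at offset {offset}")
    cdata, footer = body[:-8], body[-8:]
    crc32, isize = struct.unpack("<II", footer)
    try:
        payload = zlib.decompress(cdata, wbits=-15)
    except zlib.error as exc:
        raise CorruptionError(f"deflate failure in block at offset {offset}: {exc}") from exc
    if len(payload) != isize:
        raise CorruptionError(
            f"block at offset {offset}: declared ISIZE {isize} != payload {len(payload)}"
        )
    if check_crc and zlib.crc32(payload) != crc32:
        raise CorruptionError(f"CRC mismatch in block at offset {offset}")
    return BgzfBlock(compressed_size=compressed_size, payload=payload)


def iter_blocks(source, offset: int = 0, check_crc: bool = True) -> Iterator[tuple[int, BgzfBlock]]:
    """Yield (compressed offset, block) for every block from ``offset`` to EOF."""
    size = source.size()
    while offset < size:
        block = read_block(source, offset, check_crc=check_crc)
        yield offset, block
        offset += block.compressed_size


def read_range(
    source,
    begin: int,
    end: int,
    check_crc: bool = True,
    block_cache: dict | None = None,
) -> bytes:
    """Decompress exactly the bytes from virtual offset ``begin`` to ``end``.

    Both bounds are packed virtual offsets; ``begin`` inclusive, ``end``
    exclusive.  Blocks are read lazily, so the compressed bytes touched are
    bounded by the chunk's span plus one block.  An optional ``block_cache``
    maps compressed offset -> payload and is consulted before the source.
    """
    if begin > end:
        raise ArgumentError(f"begin virtual offset {begin} > end {end}")
    if begin == end:
        return b""
    coff, uoff = unpack_virtual_offset(begin)
    end_coff, end_uoff = unpack_virtual_offset(end)
    parts: list[bytes] = []
    while True:
        if block_cache is not None and coff in block_cache:
            payload, csize = block_cache[coff]
        else:
            block = read_block(source, coff, check_crc=check_crc)
            payload, csize = block.payload, block.compressed_size
            if block_cache is not None:
                block_cache[coff] = (payload, csize)
        if coff < end_coff:
            parts.append(payload[uoff:])
            coff += csize
            uoff = 0
            if coff == end_coff and end_uoff == 0:
                break
        else:  # coff == end_coff
            parts.append(payload[uoff:end_uoff])
            break
    return b"".join(parts)


def _deflate(data: bytes, level: int = 6) -> bytes:
    co = zlib.compressobj(level, zlib.DEFLATED, -15)
    return co.compress(data) + co.flush()


def compress_block(payload: bytes, level: int = 6) -> bytes:
    """Serialize one payload (<= BLOCK_PAYLOAD_LIMIT bytes) as a BGZF block."""
    if len(payload) > BLOCK_PAYLOAD_LIMIT:
        raise ArgumentError(f"payload exceeds block limit: {len(payload)}")
    cdata = _deflate(payload, level)
    bsize = len(cdata) + 12 + 6 + 8  # header + FEXTRA(BC) + footer
    if bsize > 65536:
        # Incompressible payload; store uncompressed-ish at level 0.
        cdata = _deflate(payload, 0)
        bsize = len(cdata) + 12 + 6 + 8
    header = (
        _GZIP_MAGIC
        + b"\x08\x04"  # CM=deflate, FLG=FEXTRA
        + b"\x00\x00\x00\x00"  # MTIME
        + b"\x00\xff"  # XFL, OS=unknown
        + struct.pack("<H", 6)  # XLEN
        + b"BC"
        + struct.pack("<HH", 2, bsize - 1)
    )
    footer = struct.pack("<II", zlib.crc32(payload), len(payload))
    return header + cdata + footer


class BgzfWriter:
    """Incremental BGZF writer that tracks virtual offsets as it goes.

    Used by the fixture generator and index builder: call
    :meth:`tell_virtual` immediately before/after writing a record to obtain
    the virtual offsets the Tabix index needs.
    """

    def __init__(self, block_payload_limit: int = BLOCK_PAYLOAD_LIMIT, level: int = 6):
        if block_payload_limit > BLOCK_PAYLOAD_LIMIT or block_payload_limit < 1:
            raise ArgumentError(f"invalid block payload limit {block_payload_limit}")
        self._limit = block_payload_limit
        self._level = level
        self._buffer = bytearray()
        self._chunks: list[bytes] = []
        self._coffset = 0  # compressed bytes flushed so far

    def tell_virtual(self) -> int:
        return pack_virtual_offset(self._coffset, len(self._buffer))

    def write(self, data: bytes) -> None:
        self._buffer.extend(data)
        while len(self._buffer) >= self._limit:
            self._flush_block(self._limit)

    def _flush_block(self, n: int) -> None:
        block = compress_block(bytes(self._buffer[:n]), self._level)
        del self._buffer[:n]
        self._chunks.append(block)
        self._coffset += len(block)

    def finish(self) -> bytes:
        while self._buffer:
            self._flush_block(min(len(self._buffer), self._limit))
        self._chunks.append(EOF_MARKER)
        out = b"".join(self._chunks)
        self._chunks = [out]  # idempotent-ish: keep result
        return out


def write_stream(
    payload: bytes, block_payload_limit: int = BLOCK_PAYLOAD_LIMIT, level: int = 6
) -> bytes:
    """Compress ``payload`` into a BGZF stream ending with the EOF marker."""
    writer = BgzfWriter(block_payload_limit, level)
    writer.write(payload)
    return writer.finish()


def is_bgzf(head: bytes) -> bool:
    """Heuristic check on the first bytes of a file: gzip magic + BC subfield."""
    if len(head) < 18 or head[:2] != _GZIP_MAGIC or not head[3] & _FLG_FEXTRA:
        return False
    xlen = struct.unpack_from("<H", head, 10)[0]
    extra = head[12 : 12 + xlen]
    i = 0
    while i + 4 <= len(extra):
        if extra[i] == 66 and extra[i + 1] == 67:
            return True
        i += 4 + struct.unpack_from("<H", extra, i + 2)[0]
    return False


def decompress_all(source, check_crc: bool = True) -> bytes:
    """Inflate an entire BGZF stream (used for full-scan oracles and tools)."""
    return b"".join(block.payload for _, block in iter_blocks(source, check_crc=check_crc))
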