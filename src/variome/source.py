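"""Byte-range sources and the genome session.

A :class:`ByteRangeSource` abstracts "read ``length`` bytes at ``offset``"
over a local file or an HTTP(S) server that honors Range requests, with an
instrumented ``bytes_fetched`` counter so partial-fetch behaviour is
measurable.  :class:`GenomeSession` composes a source with the Tabix index
and VCF header to answer region queries by decompressing only the chunks
the index selects — the whole-genome file is never read in full.
"""

from __future__ import annotations

import os
import re
import time
import urllib.error
import urllib.request
import warnings
from dataclasses import dataclass

from . import bgzf, tabix, vcf
from .errors import ArgumentError, FormatError, UnsupportedServerError, VariomeError

MAX_CONTIG_SPAN = tabix.MAX_COORD  # whole-contig queries span [1, 2^29]

#: In-session decompressed-block cache budget (bytes of payload).
BLOCK_CACHE_LIMIT = 32 * 1024 * 1024


@dataclass(frozen=True)
class Region:
    """1-based inclusive genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ArgumentError(f"invalid region {self.contig}:{self.start}-{self.end}")

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


_REGION_RE = re.compile(
    r"^(?P<contig>[^:]+?)(?::(?P<start>[\d,]+)(?:-(?P<end>[\d,]+))?)?$"
)


def parse_region_string(text: str) -> Region:
    """Parse ``ctg``, ``ctg:pos`` or ``ctg:start-end`` (commas allowed)."""
    m = _REGION_RE.match(text.strip())
    if not m or not m.group("contig"):
        raise ArgumentError(f"cannot parse region {text!r}")
    contig = m.group("contig")
    if m.group("start") is None:
        return Region(contig, 1, MAX_CONTIG_SPAN)
    try:
        start = int(m.group("start").replace(",", ""))
        end = int(m.group("end").replace(",", "")) if m.group("end") else start
    except ValueError as exc:
        raise ArgumentError(f"non-numeric coordinate in region {text!r}") from exc
    if start < 1 or end < start:
        raise ArgumentError(f"invalid coordinates in region {text!r} (start > end?)")
    return Region(contig, start, end)


class ByteRangeSource:
    """Contract: ``read(offset, length)``, ``size()``, ``bytes_fetched``."""

    bytes_fetched: int = 0

    def read(self, offset: int, length: int) -> bytes:
        raise NotImplementedError

    def size(self) -> int:
        raise NotImplementedError


class FileSource(ByteRangeSource):
    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        if not os.path.exists(self.path):
            raise FileNotFoundError(self.path)
        self._fh = open(self.path, "rb")
        self._size = os.path.getsize(self.path)
        self.bytes_fetched = 0

    def read(self, offset: int, length: int) -> bytes:
        self._fh.seek(offset)
        data = self._fh.read(length)
        self.bytes_fetched += len(data)
        return data

    def size(self) -> int:
        return self._size

    def close(self) -> None:
        self._fh.close()


class BytesSource(ByteRangeSource):
    """In-memory source, mainly for tests and index parsing."""

    def __init__(self, data: bytes):
        self._data = data
        self.bytes_fetched = 0

    def read(self, offset: int, length: int) -> bytes:
        data = self._data[offset : offset + length]
        self.bytes_fetched += len(data)
        return data

    def size(self) -> int:
        return len(self._data)


class HttpSource(ByteRangeSource):
    """HTTP(S) source using Range requests, with retry on 5xx/timeouts.

    The constructor probes the server with a 1-byte ranged read; a server
    replying 200 without honoring the range cannot support partial fetches
    and is rejected.
    """

    def __init__(self, url: str, retries: int = 3, timeout: float = 30.0):
        self.url = url
        self.retries = retries
        self.timeout = timeout
        self.bytes_fetched = 0
        self._size: int | None = None
        self._probe()

    def _request(self, offset: int, length: int) -> tuple[bytes, object]:
        req = urllib.request.Request(
            self.url, headers={"Range": f"bytes={offset}-{offset + length - 1}"}
        )
        last_exc: Exception | None = None
        for attempt in range(self.retries):
            try:
                with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                    return resp.read(), resp
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    raise FileNotFoundError(f"{self.url}: HTTP 404") from exc
                if exc.code == 416:  # range past EOF -> short read semantics
                    return b"", exc
                if 500 <= exc.code < 600 and attempt < self.retries - 1:
                    last_exc = exc
                    time.sleep(0.1 * 2**attempt)
                    continue
                raise
            except (urllib.error.URLError, TimeoutError) as exc:
                if attempt < self.retries - 1:
                    last_exc = exc
                    time.sleep(0.1 * 2**attempt)
                    continue
                raise
        raise VariomeError(f"HTTP request failed after {self.retries} attempts: {last_exc}")

    def _probe(self) -> None:
        data, resp = self._request(0, 1)
        status = getattr(resp, "status", getattr(resp, "code", None))
        if status != 206:
            raise UnsupportedServerError(
                f"{self.url}: server returned {status} for a Range request; "
                "an HTTP(S) server that supports serving file ranges is required"
            )
        content_range = resp.headers.get("Content-Range", "")
        m = re.match(r"bytes \d+-\d+/(\d+)", content_range)
        if m:
            self._size = int(m.group(1))

    def read(self, offset: int, length: int) -> bytes:
        if length <= 0:
            return b""
        data, _ = self._request(offset, length)
        if len(data) > length:  # server ignored the range after all
            raise UnsupportedServerError(
                f"{self.url}: server returned more bytes than the requested range"
            )
        self.bytes_fetched += len(data)
        return data

    def size(self) -> int:
        if self._size is None:
            data, resp = self._request(0, 1)
            m = re.match(r"bytes \d+-\d+/(\d+)", resp.headers.get("Content-Range", ""))
            if not m:
                raise UnsupportedServerError(f"{self.url}: no Content-Range in response")
            self._size = int(m.group(1))
        return self._size


def _toggle_chr(name: str) -> str:
    return name[3:] if name.startswith("chr") else "chr" + name


class GenomeSession:
    """An opened compressed+indexed VCF ready for region queries.

    The entire Tabix index (typically well under a megabyte) is held in
    memory; VCF bytes are fetched lazily per query through the block cache.
    """

    def __init__(self, source: ByteRangeSource, index: tabix.TabixIndex,
                 reference_assembly: str | None = None, check_crc: bool = True):
        self.source = source
        self.index = index
        self.reference_assembly = reference_assembly
        self.check_crc = check_crc
        self._block_cache: dict[int, tuple[bytes, int]] = {}
        self._cache_bytes = 0
        self.header = self._read_header()

    # -- opening ---------------------------------------------------------

    @classmethod
    def open_local(cls, vcf_path: str | os.PathLike, tbi_path=None, **kw) -> "GenomeSession":
        vcf_path = os.fspath(vcf_path)
        tbi_path = os.fspath(tbi_path) if tbi_path else vcf_path + ".tbi"
        if not os.path.exists(vcf_path):
            raise FileNotFoundError(f"VCF file not found: {vcf_path}")
        if not os.path.exists(tbi_path):
            raise FileNotFoundError(
                f"Tabix index not found: expected it at {tbi_path} "
                "(pass tbi_path explicitly if it lives elsewhere)"
            )
        source = FileSource(vcf_path)
        head = source.read(0, 64)
        if not bgzf.is_bgzf(head):
            if head[:2] == b"\x1f\x8b":
                raise FormatError(
                    f"{vcf_path} is plain gzip, not BGZF; recompress with bgzip "
                    "to enable random access"
                )
            raise FormatError(f"{vcf_path} is not BGZF-compressed")
        with open(tbi_path, "rb") as fh:
            index = tabix.parse_index(fh.read())
        return cls(source, index, **kw)

    @classmethod
    def open_url(cls, vcf_url: str, tbi_url: str | None = None, **kw) -> "GenomeSession":
        tbi_url = tbi_url or vcf_url + ".tbi"
        source = HttpSource(vcf_url)
        tbi_source = HttpSource(tbi_url)
        raw = tbi_source.read(0, tbi_source.size())
        index = tabix.parse_index(raw)
        return cls(source, index, **kw)

    @classmethod
    def open(cls, vcf_location: str, tbi_location: str | None = None, **kw) -> "GenomeSession":
        if re.match(r"^https?://", vcf_location):
            return cls.open_url(vcf_location, tbi_location, **kw)
        return cls.open_local(vcf_location, tbi_location, **kw)

    # -- internals -------------------------------------------------------

    def _cached_range(self, beg: int, end: int) -> bytes:
        data = bgzf.read_range(
            self.source, beg, end, check_crc=self.check_crc, block_cache=self._block_cache
        )
        # crude cache cap: drop everything once over budget
        total = sum(len(p) for p, _ in self._block_cache.values())
        if total > BLOCK_CACHE_LIMIT:
            self._block_cache.clear()
        return data

    def _read_header(self) -> vcf.VcfHeader:
        """Decompress leading blocks until the full header is in hand."""
        lines: list[str] = []
        pending = b""
        done = False
        for coff, block in bgzf.iter_blocks(self.source, check_crc=self.check_crc):
            self._block_cache[coff] = (block.payload, block.compressed_size)
            pending += block.payload
            *complete, pending = pending.split(b"\n")
            for raw in complete:
                if raw.startswith(b"#"):
                    lines.append(raw.decode("utf-8", "replace"))
                else:
                    done = True
                    break
            if done:
                break
        if not done and pending.startswith(b"#"):  # header-only, no final newline
            lines.append(pending.decode("utf-8", "replace"))
        return vcf.parse_header(lines)

    @property
    def sample_names(self) -> list[str]:
        return self.header.sample_names

    def resolve_contig(self, contig: str) -> str | None:
        """Map a query contig onto the index's naming ('chr' toggled if needed)."""
        if self.index.contig_id(contig) is not None:
            return contig
        alias = _toggle_chr(contig)
        if self.index.contig_id(alias) is not None:
            return alias
        return None

    # -- queries ---------------------------------------------------------

    def query_region(self, region: Region) -> list[vcf.VcfRecord]:
        """All records whose reference span intersects ``region``, file order.

        A contig absent from the index (after 'chr' aliasing) yields an empty
        list plus a warning, never an exception.
        """
        contig = self.resolve_contig(region.contig)
        if contig is None:
            warnings.warn(
                f"contig {region.contig!r} not present in the index "
                f"(known: {', '.join(self.index.names[:5])} ...)",
                stacklevel=2,
            )
            return []
        beg0 = region.start - 1
        end0 = min(region.end, tabix.MAX_COORD)
        chunks = tabix.query_chunks(self.index, contig, beg0, end0)
        if not chunks:
            return []
        results: list[vcf.VcfRecord] = []
        for chunk in chunks:
            text = self._cached_range(chunk.beg, chunk.end)
            for i, raw in enumerate(text.split(b"\n")):
                if not raw or raw.startswith(b"#"):
                    continue
                rec = vcf.parse_record(raw.decode(), self.header)
                if rec.contig != contig:
                    continue
                if rec.pos <= end0 and rec.end >= region.start:
                    results.append(rec)
        return results

    def query_position(self, contig: str, pos: int) -> list[vcf.VcfRecord]:
        return self.query_region(Region(contig, pos, pos))

    def query(self, region_text: str) -> list[vcf.VcfRecord]:
        return self.query_region(parse_region_string(region_text))


class SymbolResolver:
    """Offline symbol -> region resolver backed by a TSV table.

    Rows: ``symbol<TAB>contig<TAB>start<TAB>end`` (1-based inclusive); a
    symbol may occupy several rows (e.g. a gene on patches).
    """

    def __init__(self, table: dict[str, list[Region]], name: str = "offline table"):
        self._table = table
        self.name = name

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SymbolResolver":
        table: dict[str, list[Region]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                symbol, contig, start, end = line.split("\t")[:4]
                table.setdefault(symbol, []).append(Region(contig, int(start), int(end)))
        return cls(table, name=os.fspath(path))

    def resolve(self, symbol: str) -> list[Region]:
        if not symbol:
            raise ArgumentError("empty symbol")
        regions = self._table.get(symbol)
        if not regions:
            raise KeyError(f"symbol {symbol!r} not found by resolver {self.name}")
        return regions


def resolve_symbol(symbol: str, resolver: SymbolResolver) -> list[Region]:
    """Translate an rsID or gene symbol to genomic region(s)."""
    return resolver.resolve(symbol)
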