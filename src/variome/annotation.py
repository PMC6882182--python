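"""Site-level variant annotation with a hard privacy boundary.

Annotation is pluggable: an offline provider backed by a local TSV, or a
remote MyVariant.info-shaped client (opt-in, disabled by default).  The
privacy contract is enforced mechanically: every outbound payload passes
through :func:`privacy_guard`, which rejects anything that carries
genotypes — sample names, GT strings, zygosity labels, or dosage fields.
Only site-level data (position and alleles) may leave the process.
"""

from __future__ import annotations

import json
import re
import urllib.request
from dataclasses import dataclass, field

from .analyses import Site
from .errors import PrivacyError, VariomeError

#: Global switch: when True (default), remote providers refuse to run.
_block_third_party = True


def block_third_party_apis(block: bool = True) -> None:
    """Globally force the offline provider (\"block third-party APIs\")."""
    global _block_third_party
    _block_third_party = block


def third_party_blocked() -> bool:
    return _block_third_party


@dataclass
class AnnotationRecord:
    hgvs_g: str
    gene: str | None = None
    consequence: str | None = None
    population_frequency: float | None = None
    links: dict[str, str] = field(default_factory=dict)


def hgvs_g(site: Site) -> str:
    """HGVS genomic (g.) name of a normalized site, 'chr' prefix stripped.

    SNV -> ``7:g.141672604T>C``; deletion -> ``1:g.101del`` /
    ``1:g.101_102del``; insertion -> ``1:g.100_101insG``; other length
    changes -> delins.
    """
    contig = site.contig[3:] if site.contig.startswith("chr") else site.contig
    ref, alt, pos = site.ref, site.alt, site.pos
    if alt.startswith("<") or "[" in alt or "]" in alt:
        raise VariomeError(f"symbolic allele {alt!r} has no HGVS g. representation")
    if len(ref) == 1 and len(alt) == 1:
        return f"{contig}:g.{pos}{ref}>{alt}"
    if len(ref) > 1 and alt == ref[0]:  # pure deletion, anchor base retained
        start, end = pos + 1, pos + len(ref) - 1
        span = f"{start}" if start == end else f"{start}_{end}"
        return f"{contig}:g.{span}del"
    if len(alt) > 1 and ref == alt[0]:  # pure insertion after the anchor base
        return f"{contig}:g.{pos}_{pos + 1}ins{alt[1:]}"
    end = pos + len(ref) - 1
    span = f"{pos}" if end == pos else f"{pos}_{end}"
    return f"{contig}:g.{span}delins{alt}"


# --------------------------------------------------------------------------
# Privacy guard

_GT_TOKEN = re.compile(r"(?:^|[^\w])[\d.][/|][\d.](?:[^\w]|$)")
_ZYGOSITY_WORDS = re.compile(
    r"\b(hom_ref|hom_alt|het|hemizygous|heterozygous|homozygous|zygosity|genotype)\b",
    re.IGNORECASE,
)
_FORBIDDEN_KEYS = {
    "gt", "genotype", "genotypes", "zygosity", "dosage", "dosages",
    "sample", "samples", "sample_name", "sample_names",
}


def privacy_guard(payload, sample_names: tuple[str, ...] | list[str] = ()) -> object:
    """Verify an outbound payload carries only site-level data.

    Recursively scans dicts, lists and strings; raises :class:`PrivacyError`
    on any field that could carry a genotype: keys like ``genotype`` or
    ``sample``, GT strings (``0/1``, ``1|0``, ``./.``), zygosity vocabulary,
    or any of the session's sample names.  Returns the payload unchanged
    when clean.
    """
    names = tuple(n for n in sample_names if n)

    def scan(node, path="payload"):
        if isinstance(node, dict):
            for k, v in node.items():
                if str(k).lower() in _FORBIDDEN_KEYS:
                    raise PrivacyError(
                        f"{path}: key {k!r} would send genotype-level data"
                    )
                scan(k, f"{path}.{k}")
                scan(v, f"{path}.{k}")
        elif isinstance(node, (list, tuple, set)):
            for i, v in enumerate(node):
                scan(v, f"{path}[{i}]")
        elif isinstance(node, str):
            if _GT_TOKEN.search(node):
                raise PrivacyError(f"{path}: string {node!r} contains a GT call")
            if _ZYGOSITY_WORDS.search(node):
                raise PrivacyError(f"{path}: string {node!r} names a zygosity/genotype")
            for name in names:
                if name in node:
                    raise PrivacyError(f"{path}: string contains sample name {name!r}")
        # numbers/bools/None carry no alleles on their own

    scan(payload)
    return payload


# --------------------------------------------------------------------------
# Providers


class AnnotationProvider:
    """Contract: ``annotate(sites) -> dict[Site, AnnotationRecord]`` with
    absent sites simply absent from the result."""

    def annotate(self, sites: list[Site]) -> dict[Site, AnnotationRecord]:
        raise NotImplementedError


def _site_key(contig: str, pos: int, ref: str, alt: str) -> str:
    contig = contig[3:] if contig.startswith("chr") else contig
    return f"{contig}:{pos}:{ref}:{alt}"


class OfflineAnnotationProvider(AnnotationProvider):
    """Local TSV keyed by ``contig:pos:ref:alt`` ('chr' prefix ignored).

    Columns: key, gene, consequence, population_frequency, links
    (``db=id;db=id``); ``.`` marks an absent field.
    """

    def __init__(self, table: dict[str, AnnotationRecord]):
        self._table = table

    @classmethod
    def from_tsv(cls, path) -> "OfflineAnnotationProvider":
        table = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("key\t"):
                    continue
                key, gene, consequence, freq, links = (line.split("\t") + ["."] * 5)[:5]
                contig, pos, ref, alt = key.split(":")
                site = Site(contig, int(pos), ref, alt)
                key = _site_key(contig, int(pos), ref, alt)
                table[key] = AnnotationRecord(
                    hgvs_g=hgvs_g(site),
                    gene=None if gene == "." else gene,
                    consequence=None if consequence == "." else consequence,
                    population_frequency=None if freq == "." else float(freq),
                    links=dict(
                        kv.split("=", 1) for kv in links.split(";") if "=" in kv
                    ),
                )
        return cls(table)

    def annotate(self, sites: list[Site]) -> dict[Site, AnnotationRecord]:
        out = {}
        for site in sites:
            key = _site_key(site.contig, site.pos, site.ref, site.alt)
            if key in self._table:
                out[site] = self._table[key]
        return out


class RemoteAnnotationProvider(AnnotationProvider):
    """MyVariant.info-v1-shaped HTTPS client.  Opt-in only.

    Requests are batched HGVS g. identifiers; every payload passes the
    privacy guard before transmission.  A network failure fails the whole
    batch — no silent partial results.
    """

    def __init__(self, base_url: str, sample_names: tuple[str, ...] = (),
                 timeout: float = 30.0):
        self.base_url = base_url.rstrip("/")
        self.sample_names = sample_names
        self.timeout = timeout

    def annotate(self, sites: list[Site]) -> dict[Site, AnnotationRecord]:
        if third_party_blocked():
            raise VariomeError(
                "third-party annotation APIs are blocked; use the offline "
                "provider or call block_third_party_apis(False) to opt in"
            )
        if not sites:
            return {}
        ids = [hgvs_g(s) for s in sites]
        payload = {"ids": ids, "fields": "dbsnp,cadd,gnomad_genome.af"}
        privacy_guard(payload, self.sample_names)
        body = json.dumps(payload).encode()
        req = urllib.request.Request(
            f"{self.base_url}/variant",
            data=body,
            headers={"Content-Type": "application/json"},
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                hits = json.loads(resp.read())
        except Exception as exc:
            raise VariomeError(f"remote annotation batch failed: {exc}") from exc
        out = {}
        by_id = {h.get("query") or h.get("_id"): h for h in hits if isinstance(h, dict)}
        for site, ident in zip(sites, ids):
            hit = by_id.get(ident)
            if not hit or hit.get("notfound"):
                continue
            out[site] = AnnotationRecord(
                hgvs_g=ident,
                gene=(hit.get("dbsnp") or {}).get("gene", {}).get("symbol")
                if isinstance(hit.get("dbsnp"), dict)
                else None,
                population_frequency=(hit.get("gnomad_genome") or {}).get("af")
                if isinstance(hit.get("gnomad_genome"), dict)
                else None,
            )
        return out


def annotate(sites: list[Site], provider: AnnotationProvider) -> dict[Site, AnnotationRecord]:
    """Batch site-level annotation; absent keys are absent, not errors."""
    if not sites:
        return {}
    return provider.annotate(list(sites))
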