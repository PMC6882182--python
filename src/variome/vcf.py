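"""VCF parsing, genotypes/zygosity, and variant normalization.

Parses the VCF 4.1-4.3 text dialect into light-weight records with
per-sample genotype calls, and rewrites variants into canonical form:
bi-allelic (multi-allelic sites split per alternate allele), parsimonious
(shared prefix/suffix trimmed), and left-aligned against a reference
sequence when one is available.  Downstream analyses assume normalized
variants so that a site can be matched by (contig, pos, ref, alt).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import FormatError

_BASES = frozenset("ACGTN")

#: INFO flag recording that a genotype lost an allele in a multi-allelic split.
LOSSY_SPLIT_FLAG = "OLD_MULTIALLELIC"


class Zygosity(Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMIZYGOUS = "hemizygous"
    MISSING = "missing"

    def __str__(self) -> str:  # stable config-table key
        return self.value


@dataclass(frozen=True)
class Genotype:
    """One sample's call: allele indices (None = missing '.') and phasing."""

    allele_indices: tuple[int | None, ...]
    phased: bool = False

    @property
    def ploidy(self) -> int:
        return len(self.allele_indices)

    def __str__(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.allele_indices)


@dataclass
class VcfHeader:
    sample_names: list[str] = field(default_factory=list)
    contigs: list[str] = field(default_factory=list)
    meta: list[str] = field(default_factory=list)
    fileformat: str | None = None

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)


@dataclass
class VcfRecord:
    contig: str
    pos: int  # 1-based
    ids: list[str]
    ref: str
    alts: list[str]
    qual: float | None
    filters: list[str]
    info: dict[str, object]
    sample_names: list[str] = field(default_factory=list)
    genotypes: list[Genotype | None] = field(default_factory=list)
    line_number: int | None = None

    @property
    def end(self) -> int:
        """1-based inclusive end of the record's reference span.

        Uses the INFO END key when present (symbolic/structural alleles),
        otherwise pos + len(ref) - 1, matching the tabix VCF preset.
        """
        info_end = self.info.get("END")
        if info_end is not None:
            try:
                return max(int(info_end), self.pos)
            except (TypeError, ValueError):
                pass
        return self.pos + len(self.ref) - 1

    def genotype(self, sample: int | str = 0) -> Genotype | None:
        if isinstance(sample, str):
            sample = self.sample_names.index(sample)
        return self.genotypes[sample] if self.genotypes else None

    def is_symbolic(self) -> bool:
        return any(a.startswith("<") or "[" in a or "]" in a for a in self.alts)


def parse_header(lines: Iterable[str]) -> VcfHeader:
    """Parse the ## meta lines and #CHROM column line of a VCF header."""
    header = VcfHeader()
    saw_chrom = False
    for line in lines:
        line = line.rstrip("\r\n")
        if not line:
            continue
        if line.startswith("##"):
            header.meta.append(line)
            if line.startswith("##fileformat="):
                header.fileformat = line.split("=", 1)[1]
            elif line.startswith("##contig="):
                inner = line.split("<", 1)[-1].rstrip(">")
                for kv in inner.split(","):
                    if kv.startswith("ID="):
                        header.contigs.append(kv[3:])
        elif line.startswith("#CHROM"):
            cols = line.split("\t")
            if cols[:8] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]:
                raise FormatError(f"malformed #CHROM line: {line[:80]!r}")
            samples = cols[9:] if len(cols) > 9 else []
            if len(set(samples)) != len(samples):
                dupes = sorted({s for s in samples if samples.count(s) > 1})
                raise FormatError(f"duplicated sample name(s): {', '.join(dupes)}")
            header.sample_names = samples
            saw_chrom = True
        else:
            break
    if header.fileformat is None:
        raise FormatError("missing ##fileformat line; not a VCF header")
    if not saw_chrom:
        raise FormatError("missing #CHROM column line in VCF header")
    return header


def _parse_info(text: str) -> dict[str, object]:
    info: dict[str, object] = {}
    if text in (".", ""):
        return info
    for item in text.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            info[k] = v
        elif item:
            info[item] = True
    return info


def _parse_gt(gt: str, n_alts: int, line_number: int | None) -> Genotype:
    phased = "|" in gt
    fields = gt.replace("|", "/").split("/")
    if not 1 <= len(fields) <= 2:
        raise FormatError(
            f"line {line_number}: unsupported ploidy {len(fields)} in GT {gt!r} "
            "(only haploid and diploid calls are handled)"
        )
    indices: list[int | None] = []
    for f in fields:
        if f == ".":
            indices.append(None)
        else:
            try:
                idx = int(f)
            except ValueError as exc:
                raise FormatError(f"line {line_number}: bad GT allele {f!r}") from exc
            if idx > n_alts:
                raise FormatError(
                    f"line {line_number}: GT index {idx} exceeds {n_alts} alt allele(s)"
                )
            indices.append(idx)
    return Genotype(tuple(indices), phased)


def parse_record(line: str, header: VcfHeader, line_number: int | None = None) -> VcfRecord:
    """Parse one tab-delimited VCF data line against ``header``."""
    cols = line.rstrip("\r\n").split("\t")
    expected = 8 if header.n_samples == 0 else 9 + header.n_samples
    if header.n_samples == 0 and len(cols) == 9:
        expected = 9  # tolerate a dangling FORMAT column
    if len(cols) != expected:
        raise FormatError(
            f"line {line_number}: expected {expected} columns for "
            f"{header.n_samples} sample(s), found {len(cols)}"
        )
    try:
        pos = int(cols[1])
    except ValueError as exc:
        raise FormatError(f"line {line_number}: non-numeric POS {cols[1]!r}") from exc
    if pos < 1:
        raise FormatError(f"line {line_number}: POS must be >= 1, got {pos}")
    ids = [] if cols[2] == "." else cols[2].split(";")
    alts = [] if cols[4] == "." else cols[4].split(",")
    qual = None if cols[5] == "." else float(cols[5])
    filters = [] if cols[6] in (".", "") else cols[6].split(";")
    info = _parse_info(cols[7])

    genotypes: list[Genotype | None] = []
    if header.n_samples and len(cols) > 9:
        fmt_keys = cols[8].split(":")
        try:
            gt_pos = fmt_keys.index("GT")
        except ValueError:
            gt_pos = None  # site-only FORMAT: zygosity will be missing
        for sample_field in cols[9:]:
            if gt_pos is None:
                genotypes.append(None)
                continue
            parts = sample_field.split(":")
            gt = parts[gt_pos] if gt_pos < len(parts) else "."
            if gt in (".", ""):
                genotypes.append(None)
            else:
                genotypes.append(_parse_gt(gt, len(alts), line_number))
    elif header.n_samples:
        genotypes = [None] * header.n_samples

    return VcfRecord(
        contig=cols[0],
        pos=pos,
        ids=ids,
        ref=cols[3],
        alts=alts,
        qual=qual,
        filters=filters,
        info=info,
        sample_names=list(header.sample_names),
        genotypes=genotypes,
        line_number=line_number,
    )


def zygosity(genotype: Genotype | None, alt_index: int = 1) -> Zygosity:
    """Classify a genotype with respect to the alt allele ``alt_index`` (>= 1).

    Counts copies of the judged alt: 0 copies -> hom_ref, 1 -> het,
    2 -> hom_alt; a haploid call carrying the alt is hemizygous; any missing
    allele makes the whole call missing.  Total over all inputs.
    """
    if genotype is None:
        return Zygosity.MISSING
    indices = genotype.allele_indices
    if any(a is None for a in indices):
        return Zygosity.MISSING
    n_alt = sum(1 for a in indices if a == alt_index)
    if len(indices) == 1:
        return Zygosity.HEMIZYGOUS if n_alt == 1 else Zygosity.HOM_REF
    if n_alt == 0:
        return Zygosity.HOM_REF
    if n_alt == len(indices):
        return Zygosity.HOM_ALT
    return Zygosity.HET


def split_multiallelic(record: VcfRecord) -> list[VcfRecord]:
    """One bi-allelic record per alternate allele.

    Genotype indices are remapped per output record: the kept alt becomes 1
    and every other alt becomes 0 (reference).  That remap is lossy for
    samples that carried another alt; such records gain the INFO flag
    ``OLD_MULTIALLELIC`` with the original site as its value.
    """
    if len(record.alts) <= 1:
        return [record]
    out = []
    origin = f"{record.contig}:{record.pos}:{record.ref}:{','.join(record.alts)}"
    for alt_idx, alt in enumerate(record.alts, start=1):
        lossy = False
        new_gts: list[Genotype | None] = []
        for gt in record.genotypes:
            if gt is None:
                new_gts.append(None)
                continue
            remapped = []
            for a in gt.allele_indices:
                if a is None:
                    remapped.append(None)
                elif a == alt_idx:
                    remapped.append(1)
                else:
                    if a != 0:
                        lossy = True
                    remapped.append(0)
            new_gts.append(Genotype(tuple(remapped), gt.phased))
        info = dict(record.info)
        if lossy:
            info[LOSSY_SPLIT_FLAG] = origin
        out.append(
            replace(record, alts=[alt], genotypes=new_gts, info=info)
        )
    return out


def _trimmable(record: VcfRecord) -> bool:
    return (
        len(record.alts) == 1
        and not record.is_symbolic()
        and bool(record.alts[0])
        and set(record.ref.upper()) <= _BASES
    )


def trim(record: VcfRecord) -> VcfRecord:
    """Remove shared suffix then shared prefix; idempotent, position-adjusting."""
    if not _trimmable(record):
        return record
    ref, alt, pos = record.ref, record.alts[0], record.pos
    # shared suffix, keeping both alleles non-empty
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # shared prefix, keeping both alleles non-empty
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == record.ref and alt == record.alts[0]:
        return record
    return replace(record, pos=pos, ref=ref, alts=[alt])


class ReferenceLookup:
    """Adapt a reference source to ``base(contig, pos_1based) -> str``.

    Accepts a mapping of contig -> sequence string, or any object with a
    pyfaidx-style ``fetch``/``__getitem__`` interface.
    """

    def __init__(self, reference):
        self._ref = reference

    def has_contig(self, contig: str) -> bool:
        ref = self._ref
        if isinstance(ref, Mapping):
            return contig in ref
        try:
            return contig in ref  # pyfaidx.Fasta supports __contains__
        except TypeError:
            return True

    def base(self, contig: str, pos: int) -> str:
        ref = self._ref
        if isinstance(ref, Mapping):
            return ref[contig][pos - 1].upper()
        return str(ref[contig][pos - 1 : pos]).upper()


def left_align(record: VcfRecord, reference) -> VcfRecord:
    """Shift an indel to its left-most minimal representation.

    Classic normalization loop: while the two alleles end in the same base,
    drop it; whenever an allele empties, prepend the reference base at
    pos-1 and step left.  A final trim removes any shared prefix.  SNVs and
    symbolic alleles are returned unchanged; the result is idempotent and
    has the minimal position among all equivalent representations.
    """
    if not _trimmable(record):
        return record
    lookup = reference if isinstance(reference, ReferenceLookup) else ReferenceLookup(reference)
    if not lookup.has_contig(record.contig):
        raise FormatError(
            f"no reference sequence for contig {record.contig!r}; "
            "use trim-only normalization (reference=None)"
        )
    ref, alt, pos = record.ref.upper(), record.alts[0].upper(), record.pos
    if len(ref) == len(alt) == 1:
        return record
    while True:
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos == 1:
                # cannot extend past the contig start; re-anchor and stop
                base = lookup.base(record.contig, pos)
                ref, alt = base + ref, base + alt  # degenerate guard
                break
            pos -= 1
            base = lookup.base(record.contig, pos)
            ref, alt = base + ref, base + alt
        elif ref[-1] != alt[-1]:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(record, pos=pos, ref=ref, alts=[alt])


def normalize(record: VcfRecord, reference=None) -> list[VcfRecord]:
    """Split multi-allelic sites, then left-align (with reference) or trim."""
    out = []
    for rec in split_multiallelic(record):
        if rec.is_symbolic() or not rec.alts:
            out.append(rec)
        elif reference is not None:
            out.append(left_align(rec, reference))
        else:
            out.append(trim(rec))
    return out


def normalize_records(records: Sequence[VcfRecord], reference=None) -> list[VcfRecord]:
    return [out for rec in records for out in normalize(rec, reference)]


def is_normalized(record: VcfRecord, reference=None) -> bool:
    """True when the record is bi-allelic, trimmed, and (if a reference is
    given) left-aligned."""
    if len(record.alts) != 1:
        return False
    if record.is_symbolic():
        return True
    if trim(record).pos != record.pos or trim(record).ref != record.ref:
        return False
    if reference is not None:
        la = left_align(record, reference)
        return la.pos == record.pos and la.ref == record.ref and la.alts == record.alts
    return True


def format_record(record: VcfRecord) -> str:
    """Serialize a record back to a VCF data line (GT-only FORMAT)."""
    cols = [
        record.contig,
        str(record.pos),
        ";".join(record.ids) if record.ids else ".",
        record.ref,
        ",".join(record.alts) if record.alts else ".",
        "." if record.qual is None else f"{record.qual:g}",
        ";".join(record.filters) if record.filters else ".",
        ";".join(
            k if v is True else f"{k}={v}" for k, v in record.info.items()
        )
        or ".",
    ]
    if record.genotypes:
        cols.append("GT")
        cols.extend("./." if gt is None else str(gt) for gt in record.genotypes)
    return "\t".join(cols)
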