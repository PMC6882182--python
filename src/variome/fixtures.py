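"""Deterministic synthetic-genome fixture generation.

Builds multi-sample VCFs with SNVs, indels, and multi-allelic sites on
GRCh37/hg38-style contigs, compresses them with the package's own BGZF
writer, and indexes them with the package's own Tabix writer — so every
random-access code path can be exercised without downloading real data.
The same spec and seed always produce byte-identical VCF, BGZF, and .tbi
outputs (the generator uses numpy's PCG64 ``default_rng``, which is stable
across platforms).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import bgzf, tabix
from .analyses import Site
from .errors import ArgumentError

_BASES = np.array(["A", "C", "G", "T"])

DEFAULT_CONTIGS = [("chr1", 2_000_000), ("chr7", 150_000_000), ("chr19", 50_000_000)]


@dataclass(frozen=True)
class PlantedSite:
    """A variant embedded verbatim, with explicit per-sample GT strings."""

    site: Site
    genotypes: tuple[str, ...]  # e.g. ("0/1",), one per sample

    @classmethod
    def make(cls, contig, pos, ref, alt, genotypes, rsid=None) -> "PlantedSite":
        return cls(Site(contig, pos, ref, alt, rsid), tuple(genotypes))


@dataclass
class FixtureSpec:
    seed: int = 0
    contigs: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_CONTIGS))
    n_variants: int = 1000
    multiallelic_fraction: float = 0.05
    indel_fraction: float = 0.15
    samples: list[str] = field(default_factory=lambda: ["SAMPLE1"])
    planted_sites: list[PlantedSite] = field(default_factory=list)


def _random_allele(rng, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _random_gt(rng, n_alts: int) -> str:
    # mild missingness keeps the zygosity=missing path exercised
    if rng.random() < 0.02:
        return "./."
    a = rng.integers(0, n_alts + 1)
    b = rng.integers(0, n_alts + 1)
    sep = "|" if rng.random() < 0.2 else "/"
    return f"{a}{sep}{b}"


def generate_records(spec: FixtureSpec) -> list[tuple[str, int, str, str, list[str], list[str]]]:
    """Random records as (contig, pos, ref, alts-string components...).

    Returns tuples (contig, pos, rsid, ref, alts, gts) sorted by contig order
    then position, with planted sites merged in.  Raises on a planted site
    colliding with another record at the same (contig, pos).
    """
    rng = np.random.default_rng(spec.seed)
    order = {name: i for i, (name, _) in enumerate(spec.contigs)}
    planted_keys = {(p.site.contig, p.site.pos) for p in spec.planted_sites}
    if len(planted_keys) != len(spec.planted_sites):
        raise ArgumentError("planted sites collide with each other at a position")
    for p in spec.planted_sites:
        if p.site.contig not in order:
            raise ArgumentError(f"planted site contig {p.site.contig!r} not declared")
        length = dict(spec.contigs)[p.site.contig]
        if not 1 <= p.site.pos <= length:
            raise ArgumentError(f"planted site {p.site} outside contig bounds")
        if len(p.genotypes) != len(spec.samples):
            raise ArgumentError(
                f"planted site {p.site}: {len(p.genotypes)} genotypes for "
                f"{len(spec.samples)} sample(s)"
            )

    # spread random variants across contigs proportional to length
    lengths = np.array([ln for _, ln in spec.contigs], dtype=float)
    weights = lengths / lengths.sum()
    counts = rng.multinomial(spec.n_variants, weights)
    records = []
    used: set[tuple[str, int]] = set(planted_keys)
    for (contig, length), n in zip(spec.contigs, counts):
        if n == 0:
            continue
        positions = rng.integers(1, max(2, length - 100), size=n * 2)
        taken = []
        for pos in positions:
            pos = int(pos)
            if (contig, pos) not in used:
                used.add((contig, pos))
                taken.append(pos)
            if len(taken) == n:
                break
        for pos in sorted(taken):
            is_multi = rng.random() < spec.multiallelic_fraction
            is_indel = rng.random() < spec.indel_fraction
            if is_indel:
                if rng.random() < 0.5:  # deletion
                    ref = _random_allele(rng, int(rng.integers(2, 6)))
                    alts = [ref[0]]
                else:  # insertion
                    ref = _random_allele(rng, 1)
                    alts = [ref + _random_allele(rng, int(rng.integers(1, 5)))]
            else:
                ref = _random_allele(rng, 1)
                choices = [b for b in "ACGT" if b != ref]
                alts = [choices[int(rng.integers(0, 3))]]
            if is_multi:
                extra = [b for b in "ACGT" if b != ref[0] and b not in alts]
                if extra:
                    alts.append(extra[int(rng.integers(0, len(extra)))])
            gts = [_random_gt(rng, len(alts)) for _ in spec.samples]
            records.append((contig, pos, ".", ref, alts, gts))

    for p in spec.planted_sites:
        records.append(
            (
                p.site.contig,
                p.site.pos,
                p.site.rsid or ".",
                p.site.ref,
                [p.site.alt],
                list(p.genotypes),
            )
        )
    records.sort(key=lambda r: (order[r[0]], r[1]))
    return records


def build_vcf_text(spec: FixtureSpec) -> str:
    """The fixture VCF as plain text (the full-scan oracle's input)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=variome-fixture",
    ]
    for name, length in spec.contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if spec.samples:
        cols += ["FORMAT"] + list(spec.samples)
    lines.append("\t".join(cols))
    for contig, pos, rsid, ref, alts, gts in generate_records(spec):
        row = [contig, str(pos), rsid, ref, ",".join(alts), "50", "PASS", "."]
        if spec.samples:
            row += ["GT"] + gts
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def compress_and_index(vcf_text: str) -> tuple[bytes, bytes]:
    """BGZF-compress VCF text and build its .tbi with the package's writers."""
    writer = bgzf.BgzfWriter()
    spans = []  # (contig, beg0, end0, vo_start, vo_end)
    contig_order: list[str] = []
    for line in vcf_text.splitlines(keepends=True):
        if not line.endswith("\n"):
            line += "\n"
        if line.startswith("#"):
            if line.startswith("##contig=<ID="):
                name = line.split("ID=", 1)[1].split(",")[0].rstrip(">\n")
                if name not in contig_order:
                    contig_order.append(name)
            writer.write(line.encode())
            continue
        vo_start = writer.tell_virtual()
        writer.write(line.encode())
        vo_end = writer.tell_virtual()
        cols = line.split("\t", 5)
        contig, pos, ref = cols[0], int(cols[1]), cols[3]
        if contig not in contig_order:
            contig_order.append(contig)
        beg0 = pos - 1
        end0 = beg0 + len(ref)
        spans.append((contig, beg0, end0, vo_start, vo_end))
    compressed = writer.finish()
    tbi = tabix.write_index(spans, contig_order)
    return compressed, tbi


def generate_fixture(spec: FixtureSpec, out_dir: str | os.PathLike,
                     basename: str = "fixture") -> tuple[str, str, str]:
    """Write ``<basename>.vcf``, ``.vcf.gz`` and ``.vcf.gz.tbi`` under
    ``out_dir``; returns (gz path, tbi path, plain-text path)."""
    os.makedirs(out_dir, exist_ok=True)
    text = build_vcf_text(spec)
    compressed, tbi = compress_and_index(text)
    plain = os.path.join(out_dir, basename + ".vcf")
    gz = os.path.join(out_dir, basename + ".vcf.gz")
    tbi_path = gz + ".tbi"
    with open(plain, "w") as fh:
        fh.write(text)
    with open(gz, "wb") as fh:
        fh.write(compressed)
    with open(tbi_path, "wb") as fh:
        fh.write(tbi)
    return gz, tbi_path, plain


def generate_reference(seed: int, contigs: list[tuple[str, int]]) -> dict[str, str]:
    """A random reference sequence per contig (for left-alignment tests).

    Kept deliberately repetitive (AC-rich) so indel left-shifting has work
    to do.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name, length in contigs:
        # mixture of random bases and short repeats
        bases = _BASES[rng.integers(0, 4, size=length)]
        seq = "".join(bases)
        out[name] = seq
    return out


def generate_aim_panel(seed: int, n_markers: int = 496, n_background: int = 60):
    """Synthetic ancestry panel: markers + reference background coordinates.

    Markers get frequencies in (0.05, 0.95) and small PC loadings; the
    background samples are drawn from three synthetic populations whose
    genotypes are projected with the same centered-dosage formula the
    engine uses, so self-consistency is checkable.  Returns
    (AncestryPanel, dict sample -> dosage vector).
    """
    from .analyses import AimMarker, AncestryPanel, project_dosages

    rng = np.random.default_rng(seed)
    markers = []
    contig_cycle = ["chr1", "chr7", "chr19"]
    pos_used = set()
    freqs = rng.uniform(0.05, 0.95, size=n_markers)
    load1 = rng.normal(0, 0.05, size=n_markers)
    load2 = rng.normal(0, 0.05, size=n_markers)
    for i in range(n_markers):
        contig = contig_cycle[i % 3]
        while True:
            pos = int(rng.integers(10_000, 1_900_000))
            if (contig, pos) not in pos_used:
                pos_used.add((contig, pos))
                break
        ref, alt = ("A", "G") if rng.random() < 0.5 else ("C", "T")
        markers.append(
            AimMarker(Site(contig, pos, ref, alt), alt, float(freqs[i]),
                      float(load1[i]), float(load2[i]))
        )
    panel = AncestryPanel(markers=markers, declared_markers=n_markers)
    pops = {"POP_A": -0.3, "POP_B": 0.0, "POP_C": 0.3}
    background = []
    dosage_vectors = {}
    for pi, (pop, shift) in enumerate(pops.items()):
        for si in range(n_background // len(pops)):
            p = np.clip(freqs + shift * (rng.random(n_markers) - 0.3), 0.02, 0.98)
            dosages = rng.binomial(2, p).astype(int)
            name = f"{pop}_{si:02d}"
            pc1, pc2 = project_dosages(panel, [int(d) for d in dosages])
            background.append((name, pop, pc1, pc2))
            dosage_vectors[name] = [int(d) for d in dosages]
    panel.background = background
    return panel, dosage_vectors
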