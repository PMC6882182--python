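# Methods

This note documents the models and procedures `variome` implements, the
choices made where the design was genuinely open, and what the synthetic
test data does and does not establish about behaviour on real callsets.

## Random access: BGZF and Tabix

The package implements BGZF and the `.tbi` Tabix index natively rather than
wrapping htslib, because partial fetching over arbitrary byte-range sources
(local files, HTTP `Range` requests, in-memory buffers) is the core of the
artifact and needs an instrumented, transport-agnostic code path. htslib
(via `pysam` and the `bgzip`/`tabix` CLIs) is used in the test suite as an
independent oracle: indexes written by `variome` are read by htslib and vice
versa, and query results are compared.

Numerical/format choices:

- Block payload limit 65,280 bytes (htslib's convention), so a compressed
  block never exceeds 65,536 bytes even for incompressible input; a payload
  that inflates under deflate is re-encoded at compression level 0.
- CRC32 verification of every decompressed block is on by default and can be
  disabled (`check_crc=False`) for speed; on by default because remote
  fetches can be silently corrupted.
- Plain (non-blocked) gzip input is rejected with a message suggesting
  recompression with bgzip. Accepting it would silently forfeit random
  access, the module's whole contract.
- CSI indexes (contigs >2²⁹ bp) are rejected with a clear message; only
  `.tbi` is in scope.
- Binning uses the standard 5-level scheme (minimum interval 2¹⁴ bp, bins
  0…37448) and a 16-kb linear index. Query chunks are filtered by the linear
  index, sorted, and merged whenever the next chunk begins at or before the
  current chunk's end (packed virtual-offset comparison) — fewer, larger
  range requests beat many small ones on HTTP.
- All internal index arithmetic is 0-based half-open. User-facing regions
  are 1-based inclusive and converted exactly once, at the session boundary,
  to eliminate off-by-one drift.
- A record's indexed span is `pos … pos + len(ref) − 1`, extended by an
  `END` INFO key when present (symbolic alleles). Query overlap uses the
  same deletion-aware span, so a deletion covering a query point is
  returned.

## Sessions and transports

A `GenomeSession` holds the whole `.tbi` in memory (typically ≪1 MB), reads
the VCF header from the leading blocks, and serves queries by fetching only
the chunks the index selects. Decompressed blocks are cached per session
(32 MB budget, dropped wholesale when exceeded — a deliberate simplicity
over LRU given desk-scale workloads). The HTTP source probes the server
with a 1-byte ranged read at open; a server answering `200` without the
range is rejected immediately rather than downloading whole files. Requests
retry 3× with exponential backoff on 5xx/timeouts. Contig aliasing retries a
failed lookup with the `chr` prefix toggled; a contig absent after aliasing
yields an empty result plus a warning, not an exception, so `chrM` vs `MT`
mismatches do not crash batch analyses.

## Variant normalization

`normalize` = split multi-allelic sites per alternate allele, then left-align
(when a reference is available) or trim. The split remaps the kept alt to 1
and every other alt to 0; records where a genotype actually lost an allele
carry the `OLD_MULTIALLELIC` INFO flag naming the original site, keeping the
lossy step auditable. Trimming removes the shared suffix then prefix while
both alleles stay non-empty. Left-alignment runs the classic loop — drop
shared terminal bases; when an allele empties, prepend the reference base at
`pos−1` — and terminates at the unique minimal-position representation
(verified in tests against brute-force enumeration of all equivalent
representations within 50-bp windows). Symbolic alleles (`<DEL>`, breakends)
pass through untouched: trimming rules are undefined for them. Ploidy is
limited to 1 and 2 (human scope); higher ploidy is a parse error rather than
a silent misinterpretation.

Zygosity is alt-centric: the count of copies of the judged alternate allele
(0 → hom-ref, 1 → het, 2 → hom-alt; haploid carrier → hemizygous; any
missing allele → missing). This makes a diploid `0/2` genotype judged
against alt 1 homozygous-reference, consistent with the post-split remap.

## Interpretation analyses

All analyses are pure functions of (session genotypes, configuration
tables). The engine is code; the variant content is replaceable TSV/YAML
under `variome/data`, clearly marked non-diagnostic.

- **Missing ≠ hom-ref by default.** A site absent from a VCF without
  reference blocks is indistinguishable from no-coverage, and silently
  assuming hom-ref is the dangerous default. Every model can opt in to
  `absent_hom_ref` where its source data justify it.
- **Traits** are joint-zygosity table lookups with an optional default
  phenotype; an unmapped joint genotype with no default reports
  `undetermined`.
- **Risk** multiplies per-variant likelihood ratios (missing genotypes
  contribute a neutral LR of 1) and updates pre-test odds. The arithmetic is
  exact under `fractions.Fraction` inputs; configuration with nonpositive
  LRs or a pre-test probability outside (0,1) is rejected at load.
  The packaged Type 2 Diabetes table is synthetic: its LRs and pre-test
  probability illustrate the method only.
- **APOE** maps (rs429358, rs7412) allele pairs through the ε haplotype
  table (T,C→ε3; T,T→ε2; C,C→ε4; C,T→ε1). Exactly one of the nine biallelic
  genotype combinations — the double heterozygote — is phase-ambiguous; it
  is reported as ε2/ε4 (by far the likelier phasing) with a
  `phase-ambiguous` flag rather than guessing silently.
- **PGx** rules map a joint zygosity tuple over the rule's defining sites
  to a diplotype/phenotype/recommendation row. A combination absent from the
  table (e.g. >2 CYP2C9 variant alleles across *2/*3 sites) reports
  `uncallable`; missing genotypes report `undetermined` listing the missing
  sites.
- **Ancestry** projects centered dosages `x = d − 2f` onto PC1/PC2 loadings.
  Missing markers contribute 0 — mean imputation, the only choice that keeps
  the origin meaningful. Whether to scale by `√(2f(1−f))` before projection
  is not standardized across published panels; the default is unscaled with
  a `scale` switch.

## Privacy contract

`privacy_guard` recursively scans every outbound payload for forbidden keys
(`genotype`, `gt`, `zygosity`, `dosage`, `sample`…), GT-string patterns
(`0/1`, `1|0`, `./.`), zygosity vocabulary, and the session's sample names,
raising before any transmission. The remote annotation client
(MyVariant.info-shaped) is additionally disabled by a global switch that
defaults to blocked; the offline TSV provider is the default path and the
entire test suite runs with non-loopback networking disabled.

## Synthetic data: what it shows and what it does not

The fixture generator emulates single- and multi-sample VCF 4.2 callsets on
GRCh37/hg38-style contigs with SNVs, short indels (≤5 bp), multi-allelic
sites (default fractions 0.15 and 0.05 — typical of short-read germline
callsets), sporadic missing genotypes (2%), and verbatim planted sites for
analysis tests. Records are uniform over contigs proportional to length;
real callsets cluster variants, but clustering only makes partial fetching
*easier*, so the uniform layout is the conservative case for the index
tests. The generator does not emulate: reference blocks (gVCF), complex
INFO/FORMAT payloads, structural variants, or realistic linkage structure —
so passing tests establish engine correctness (indexing, parsing,
normalization, arithmetic), not population-genetic realism.

The packaged ancestry panel is **synthetic** (`aim_panel_synthetic.tsv`,
496 markers with plausible frequencies and small Gaussian loadings;
three synthetic background populations projected with the same formula the
engine uses). It demonstrates and tests the projection machinery; its
coordinates carry no ancestry information about real populations. To analyse
real data, replace it with a published AIM panel in the same TSV layout.

Determinism: all generation flows through numpy's seeded PCG64
(`default_rng`), so a spec + seed reproduces byte-identical VCF, BGZF and
`.tbi` outputs across platforms.

## Problem sizes

The acceptance checks run at desk scale by design: 50 random fixtures
(48 drawn between 50 and 2,500 variants, plus one at 20,000 and one at
100,000) × 500 random regions for index/full-scan equivalence; a
100,000-variant three-sample fixture for the HTTP partial-fetch measurement
(a point query fetches ≈3% of the file: one header block, the probe byte,
and the chunk blocks the index selects); 10,000 random variants for
normalization idempotence and 500 reference-consistent indels for
left-alignment minimality. These sizes exercise every boundary the format
has (block boundaries, 16-kb windows, bin levels) while keeping the full
suite fast enough to run on every change.

## Known limitations

- No CSI/BAI support; contigs are limited to 2²⁹ −1 bp (the `.tbi` format's
  ceiling).
- FORMAT fields other than GT are carried but not typed or validated against
  header declarations.
- Left-alignment requires an in-memory or FASTA reference; without one,
  normalization is trim-only (correct but not necessarily minimal-position).
- The remote annotation client ships disabled and untested against the live
  service by design; only its payload shape and privacy behaviour are
  tested.
- gene/rsID query resolution is offline-table-driven; no bundled genome-wide
  symbol table is provided.
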