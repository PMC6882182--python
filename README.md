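# variome

Desk-scale personal-genome analysis for education and exploration.

`variome` answers questions like *"what variant does this genome carry at
chr7:141672604, and what might it mean?"* against whole-genome-scale VCF
callsets **without ever reading the whole file**. It implements the two
random-access primitives of the htslib ecosystem from the ground up — BGZF
(blocked gzip) and the Tabix `.tbi` binning/linear index — over a byte-range
source abstraction that works identically on a local file and on any HTTP(S)
server that supports `Range` requests. On top of the query engine it provides
table-driven interpretation analyses: physical-trait prediction,
star-allele pharmacogenomics, likelihood-ratio polygenic disease risk, APOE
ε-genotype reporting, and PCA ancestry projection on ancestry-informative
markers (AIMs).

A strict privacy contract is enforced mechanically: only site-level data
(position and alleles) may leave the process; any outbound payload carrying a
sample name, GT string, zygosity label or dosage is rejected before
transmission. Third-party annotation APIs are blocked by default.

**None of the packaged analyses is diagnostic.** The configuration tables
shipped under `variome/data` are illustrative content for learning how such
analyses work; they are not clinically curated.

## The core machinery

*Random access.* A BGZF file is a series of ≤64 KiB independently
decompressible gzip members. A **virtual offset** packs a block's compressed
file offset `c` and an offset `u` into its decompressed payload as
`c·2¹⁶ + u`. The Tabix index assigns each VCF record to the smallest bin of a
5-level hierarchy (bin ids 0…37448, minimum interval 2¹⁴ bp) and keeps, per
bin, chunks `[beg, end)` of virtual offsets, plus a 16-kb linear index used
to discard chunks that end before a query's window. A region query touches
only the chunks `reg2bins(beg, end)` selects — a few KB of a multi-hundred-MB
file.

*Normalization.* Analyses match variants by `(contig, pos, ref, alt)`, so
records are rewritten to canonical form: multi-allelic sites split per
alternate allele (genotypes remapped, lossy remaps flagged
`OLD_MULTIALLELIC`), shared prefix/suffix trimmed, and indels left-aligned
against a reference to the unique minimal-position representation.

*Risk arithmetic.* Polygenic risk uses the likelihood-ratio update: with
pre-test probability *p*, odds *o = p/(1−p)* are multiplied by the product of
per-variant genotype likelihood ratios `LR(g) = P(g|disease)/P(g|healthy)`
(assumed independent), and the post-test probability is
*o·LR / (1 + o·LR)*.

*Ancestry.* For each panel marker with effect-allele frequency *f* and
loadings *(w₁, w₂)*, the centered dosage *x = d − 2f* contributes *wₖ·x* to
PCₖ; missing markers contribute 0 (mean imputation). The packaged panel is
synthetic (496 markers, self-declared in its header) — see
`docs/methods.md`.

## Worked example

Generate a deterministic synthetic genome with a planted heterozygous
`chr7:141672604 T>C` call and planted APOE sites, then query it:

```python
from variome.fixtures import FixtureSpec, PlantedSite, generate_fixture

spec = FixtureSpec(
    seed=42, n_variants=1000, samples=["NA12878"],
    planted_sites=[
        PlantedSite.make("chr7", 141672604, "T", "C", ["0/1"], "rs10246939"),
        PlantedSite.make("chr19", 45411941, "T", "C", ["0/1"], "rs429358"),
        PlantedSite.make("chr19", 45412079, "C", "T", ["0/0"], "rs7412"),
    ],
)
generate_fixture(spec, "demo", "genome")   # writes .vcf, .vcf.gz, .vcf.gz.tbi
```

```console
$ variome query --vcf demo/genome.vcf.gz --region chr7:141672604
chr7:141672604 T>C NA12878=0/1

$ variome apoe --vcf demo/genome.vcf.gz --assembly GRCh37
APOE ε3/ε4 (unambiguous): one ε4 allele: elevated Alzheimer disease risk relative to ε3/ε3

$ variome risk --vcf demo/genome.vcf.gz \
    --model src/variome/data/risk_t2d_synthetic_grch37.yaml
Type 2 Diabetes (synthetic example model): pre-test 0.250, combined LR 1.000, post-test 0.250
```

The query returned exactly one overlapping variant (HGVS
`7:g.141672604T>C`), heterozygous in NA12878. The APOE report combined the
two defining SNVs (rs429358 het, rs7412 hom-ref) into the ε3/ε4 diplotype.
The risk command found none of the model's variant genotypes carrying a
non-neutral likelihood ratio in this synthetic genome, so the combined LR is
1.0 and the post-test probability equals the pre-test 0.25. Interpretation
commands print a non-diagnostic warning on stderr.

The same commands accept a URL wherever they accept a path
(`--vcf https://host/genome.vcf.gz`), fetching only the index and the byte
ranges each query needs. Python API: `variome.GenomeSession.open(...)`,
`.query_region(...)`, and the functions in `variome.analyses`.

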