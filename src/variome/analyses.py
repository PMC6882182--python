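"""Interpretation analyses: traits, pharmacogenomics, likelihood-ratio
polygenic risk, APOE, and AIM-based ancestry projection.

Every analysis is a pure, table-driven function of the session's genotypes
and an editable configuration table: the engine knows how to look up a
genotype at a site, classify its zygosity, and map joint genotypes through
a table; the *content* of the tables (which variants define a trait, which
likelihood ratios a disease model uses) is replaceable data, not code.
Packaged default tables are illustrative and explicitly non-diagnostic.

None of these analyses is intended to diagnose, prevent or treat any
disease or condition, or to predict a person's response to medication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ArgumentError, ConfigError
from .source import GenomeSession
from .vcf import Zygosity, normalize, zygosity

#: Warning shown by every interpretation command.
NON_DIAGNOSTIC_WARNING = (
    "This analysis is for education and exploration only. It is not intended "
    "to diagnose, prevent or treat any disease or condition, or to predict a "
    "person's response to specific medications."
)


@dataclass(frozen=True)
class Site:
    """A normalized bi-allelic site key: contig, 1-based pos, ref, alt."""

    contig: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None

    def __str__(self) -> str:
        label = f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"
        return f"{label} ({self.rsid})" if self.rsid else label


def genotype_at(
    session: GenomeSession,
    site: Site,
    sample: int | str = 0,
    absent_hom_ref: bool = False,
) -> tuple[Zygosity, int | None]:
    """Zygosity and alt-allele dosage of ``sample`` at ``site``.

    Records overlapping the site are normalized (split + trimmed) before
    matching on (pos, ref, alt).  A site with no matching record is
    ``missing`` — unless ``absent_hom_ref`` is set, in which case absence is
    read as homozygous reference with dosage 0 (only sound for callsets
    that omit reference-matching positions).
    """
    records = session.query_position(site.contig, site.pos)
    for rec in records:
        for norm in normalize(rec):
            if norm.pos == site.pos and norm.ref == site.ref and norm.alts == [site.alt]:
                gt = norm.genotype(sample)
                z = zygosity(gt, 1)
                dosage = {
                    Zygosity.HOM_REF: 0,
                    Zygosity.HET: 1,
                    Zygosity.HOM_ALT: 2,
                    Zygosity.HEMIZYGOUS: 1,
                    Zygosity.MISSING: None,
                }[z]
                return z, dosage
    if absent_hom_ref:
        return Zygosity.HOM_REF, 0
    return Zygosity.MISSING, None


# --------------------------------------------------------------------------
# Physical traits


@dataclass
class TraitModel:
    """Joint-genotype -> phenotype lookup for a physical trait."""

    name: str
    variants: list[Site]
    phenotype_map: dict[tuple[str, ...], str]
    default_phenotype: str | None = None
    absent_hom_ref: bool = False

    UNDETERMINED = "undetermined"


@dataclass
class TraitReport:
    trait: str
    phenotype: str
    evidence: dict[str, str]  # site label -> zygosity name


def predict_trait(
    session: GenomeSession, model: TraitModel, sample: int | str = 0
) -> TraitReport:
    """Deterministic table lookup on the joint zygosity tuple."""
    calls = [
        genotype_at(session, site, sample, model.absent_hom_ref)[0]
        for site in model.variants
    ]
    key = tuple(z.value for z in calls)
    phenotype = model.phenotype_map.get(key)
    if phenotype is None:
        phenotype = (
            model.default_phenotype
            if model.default_phenotype is not None
            else TraitModel.UNDETERMINED
        )
    evidence = {str(site): z.value for site, z in zip(model.variants, calls)}
    return TraitReport(trait=model.name, phenotype=phenotype, evidence=evidence)


# --------------------------------------------------------------------------
# Likelihood-ratio polygenic risk


@dataclass
class RiskModel:
    """Per-variant genotype -> likelihood-ratio table with a pre-test
    probability.

    The likelihood ratio for a genotype g at a variant is
    P(g | disease) / P(g | no disease); assuming independent variants the
    joint LR is the product over variants, which updates pre-test odds to
    post-test odds.
    """

    disease: str
    pre_test_probability: float
    entries: dict[Site, dict[str, float]]  # zygosity value -> LR
    absent_hom_ref: bool = False

    def __post_init__(self):
        if not 0 < self.pre_test_probability < 1:
            raise ConfigError(
                f"pre-test probability must be in (0,1), got {self.pre_test_probability}"
            )
        for site, table in self.entries.items():
            for zyg, lr in table.items():
                if not lr > 0:
                    raise ConfigError(f"nonpositive LR {lr} for {site} / {zyg}")


def combined_lr(model: RiskModel, calls: Mapping[Site, Zygosity]) -> float:
    """Product of per-variant LRs for the observed zygosities.

    Missing calls (and zygosities without a configured LR) contribute a
    neutral LR of 1.
    """
    lr = 1.0
    for site, table in model.entries.items():
        z = calls.get(site, Zygosity.MISSING)
        lr *= table.get(z.value, 1.0)
    return lr


def post_test_probability(pre, lr):
    """Update a pre-test probability by a likelihood ratio via odds.

    odds = p/(1-p); post-odds = odds * LR; back-transform.  Exact under
    :class:`fractions.Fraction` inputs, strictly increasing in ``lr``.
    """
    if not 0 < pre < 1:
        raise ArgumentError(f"pre-test probability must be in (0,1), got {pre}")
    if not lr > 0:
        raise ArgumentError(f"likelihood ratio must be positive, got {lr}")
    odds = pre / (1 - pre)
    post_odds = odds * lr
    return post_odds / (1 + post_odds)


@dataclass
class RiskReport:
    disease: str
    pre_test_probability: float
    combined_lr: float
    post_test_probability: float
    evidence: dict[str, str]
    missing_sites: list[str]


def predict_risk(session: GenomeSession, model: RiskModel, sample: int | str = 0) -> RiskReport:
    calls = {
        site: genotype_at(session, site, sample, model.absent_hom_ref)[0]
        for site in model.entries
    }
    lr = combined_lr(model, calls)
    return RiskReport(
        disease=model.disease,
        pre_test_probability=model.pre_test_probability,
        combined_lr=lr,
        post_test_probability=post_test_probability(model.pre_test_probability, lr),
        evidence={str(s): z.value for s, z in calls.items()},
        missing_sites=[str(s) for s, z in calls.items() if z is Zygosity.MISSING],
    )


# --------------------------------------------------------------------------
# APOE


@dataclass
class ApoeDefinition:
    """Assembly-specific positions of rs429358 and rs7412 on chromosome 19.

    The epsilon haplotypes: (rs429358=T, rs7412=C) -> e3; (T, T) -> e2;
    (C, C) -> e4; (C, T) -> e1 (vanishingly rare).
    """

    rs429358: Site
    rs7412: Site


_EPS = {("T", "C"): "ε3", ("T", "T"): "ε2", ("C", "C"): "ε4", ("C", "T"): "ε1"}

#: GRCh37 and hg38 coordinates of the two defining SNVs.
APOE_DEFINITIONS = {
    "GRCh37": ApoeDefinition(
        rs429358=Site("19", 45411941, "T", "C", "rs429358"),
        rs7412=Site("19", 45412079, "C", "T", "rs7412"),
    ),
    "hg38": ApoeDefinition(
        rs429358=Site("19", 44908684, "T", "C", "rs429358"),
        rs7412=Site("19", 44908822, "C", "T", "rs7412"),
    ),
}
APOE_DEFINITIONS["hg19"] = APOE_DEFINITIONS["GRCh37"]
APOE_DEFINITIONS["GRCh38"] = APOE_DEFINITIONS["hg38"]

#: Informational annotations per genotype (educational, non-diagnostic).
_APOE_NOTES = {
    frozenset({"ε4"}): "two ε4 alleles: the strongest common genetic risk factor "
    "for late-onset Alzheimer disease",
    frozenset({"ε3", "ε4"}): "one ε4 allele: elevated Alzheimer disease risk "
    "relative to ε3/ε3",
    frozenset({"ε2", "ε4"}): "one ε2 and one ε4 allele: near-average Alzheimer "
    "disease risk",
    frozenset({"ε3"}): "the most common genotype; baseline Alzheimer disease risk",
    frozenset({"ε2", "ε3"}): "one ε2 allele: reduced Alzheimer disease risk",
    frozenset({"ε2"}): "two ε2 alleles: reduced Alzheimer disease risk; associated "
    "with type III hyperlipoproteinemia",
}


@dataclass
class ApoeReport:
    diplotype: str  # e.g. "ε3/ε4"
    note: str
    confidence: str  # "unambiguous" | "phase-ambiguous" | "undetermined"
    evidence: dict[str, str]


def _allele_pair(z: Zygosity, ref: str, alt: str) -> tuple[str, str] | None:
    return {
        Zygosity.HOM_REF: (ref, ref),
        Zygosity.HET: (ref, alt),
        Zygosity.HOM_ALT: (alt, alt),
        Zygosity.HEMIZYGOUS: (alt, alt),
    }.get(z)


def apoe_report(
    session: GenomeSession,
    sample: int | str = 0,
    assembly: str | None = None,
    definition: ApoeDefinition | None = None,
    absent_hom_ref: bool = False,
) -> ApoeReport:
    """APOE ε diplotype from the rs429358/rs7412 genotypes.

    Without phase, the rs429358 C/T + rs7412 C/T double heterozygote is
    consistent with both ε2/ε4 and ε1/ε3; it is reported as ε2/ε4 (by far
    the likelier pair) flagged phase-ambiguous.
    """
    if definition is None:
        key = assembly or session.reference_assembly or "GRCh37"
        if key not in APOE_DEFINITIONS:
            raise ConfigError(f"no APOE site definitions for assembly {key!r}")
        definition = APOE_DEFINITIONS[key]
    z1, _ = genotype_at(session, definition.rs429358, sample, absent_hom_ref)
    z2, _ = genotype_at(session, definition.rs7412, sample, absent_hom_ref)
    evidence = {str(definition.rs429358): z1.value, str(definition.rs7412): z2.value}
    p1 = _allele_pair(z1, definition.rs429358.ref, definition.rs429358.alt)
    p2 = _allele_pair(z2, definition.rs7412.ref, definition.rs7412.alt)
    if p1 is None or p2 is None:
        return ApoeReport("undetermined", "one or both APOE sites uncalled",
                          "undetermined", evidence)
    if z1 is Zygosity.HET and z2 is Zygosity.HET:
        return ApoeReport(
            "ε2/ε4",
            _APOE_NOTES[frozenset({"ε2", "ε4"})]
            + " (assuming the common phasing; ε1/ε3 cannot be excluded without phase)",
            "phase-ambiguous",
            evidence,
        )
    alleles = sorted(_EPS[(a1, a2)] for a1, a2 in zip(p1, p2))
    diplotype = "/".join(alleles)
    note = _APOE_NOTES.get(frozenset(alleles), "rare genotype; no annotation configured")
    return ApoeReport(diplotype, note, "unambiguous", evidence)


# --------------------------------------------------------------------------
# Pharmacogenomics


@dataclass
class PgxRule:
    """Star-allele pharmacogenomic rule for one drug.

    ``sites`` are the defining variants in a fixed order; the
    ``diplotype_table`` maps a joint zygosity tuple (one entry per site, in
    that order) to the reported diplotype, phenotype, recommendation, and
    its source (CPIC guideline or drug label).
    """

    drug: str
    gene: str
    sites: list[Site]
    diplotype_table: dict[tuple[str, ...], "PgxRow"]
    absent_hom_ref: bool = False


@dataclass(frozen=True)
class PgxRow:
    diplotype: str
    phenotype: str
    recommendation: str
    source: str = "CPIC"


@dataclass
class PgxReport:
    drug: str
    gene: str
    status: str  # "called" | "undetermined" | "uncallable"
    diplotype: str | None
    phenotype: str | None
    recommendation: str | None
    source: str | None
    evidence: dict[str, str]
    missing_sites: list[str]


def pgx_report(session: GenomeSession, rule: PgxRule, sample: int | str = 0) -> PgxReport:
    calls = [
        genotype_at(session, site, sample, rule.absent_hom_ref)[0] for site in rule.sites
    ]
    evidence = {str(s): z.value for s, z in zip(rule.sites, calls)}
    missing = [str(s) for s, z in zip(rule.sites, calls) if z is Zygosity.MISSING]
    if missing:
        return PgxReport(rule.drug, rule.gene, "undetermined", None, None, None, None,
                         evidence, missing)
    key = tuple(z.value for z in calls)
    row = rule.diplotype_table.get(key)
    if row is None:
        return PgxReport(rule.drug, rule.gene, "uncallable", None, None, None, None,
                         evidence, [])
    return PgxReport(rule.drug, rule.gene, "called", row.diplotype, row.phenotype,
                     row.recommendation, row.source, evidence, [])


# --------------------------------------------------------------------------
# Ancestry


@dataclass(frozen=True)
class AimMarker:
    site: Site
    effect_allele: str  # the allele whose dosage is counted (= site.alt)
    frequency: float  # effect-allele frequency in the reference panel
    loading_pc1: float
    loading_pc2: float


@dataclass
class AncestryPanel:
    """Ancestry-informative-marker panel with PC1/PC2 loadings.

    ``declared_markers`` is the count the panel claims for itself (496 for
    the published panel); ``background`` carries reference-sample PC
    coordinates for plotting context.
    """

    markers: list[AimMarker]
    declared_markers: int
    background: list[tuple[str, str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        for m in self.markers:
            if not 0 < m.frequency < 1:
                raise ConfigError(
                    f"marker {m.site}: effect-allele frequency must be in (0,1), "
                    f"got {m.frequency}"
                )


@dataclass
class AncestryResult:
    pc1: float
    pc2: float
    markers_used: int
    markers_total: int
    background: list[tuple[str, str, float, float]]


def project_dosages(
    panel: AncestryPanel, dosages: Sequence[int | None], scale: bool = False
) -> tuple[float, float]:
    """Project centered dosages onto the panel's PC1/PC2 loadings.

    x_i = dosage_i - 2 * frequency_i; missing dosages contribute 0 (mean
    imputation).  With ``scale`` the centered dosage is divided by
    sqrt(2 f (1-f)) before projection.
    """
    pc1 = pc2 = 0.0
    for m, d in zip(panel.markers, dosages):
        if d is None:
            continue
        x = d - 2.0 * m.frequency
        if scale:
            x /= math.sqrt(2.0 * m.frequency * (1.0 - m.frequency))
        pc1 += m.loading_pc1 * x
        pc2 += m.loading_pc2 * x
    return pc1, pc2


def ancestry_project(
    session: GenomeSession,
    panel: AncestryPanel,
    sample: int | str = 0,
    scale: bool = False,
    absent_hom_ref: bool = False,
) -> AncestryResult:
    """Place a sample on the panel's first two principal components."""
    dosages = [
        genotype_at(session, m.site, sample, absent_hom_ref)[1] for m in panel.markers
    ]
    used = sum(1 for d in dosages if d is not None)
    if used == 0:
        raise ArgumentError(
            "no panel marker could be resolved in this callset; "
            "check the reference assembly and contig naming"
        )
    pc1, pc2 = project_dosages(panel, dosages, scale=scale)
    return AncestryResult(pc1, pc2, used, len(panel.markers), panel.background)
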