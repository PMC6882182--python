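"""Interpretation analyses: traits, LR risk, APOE, PGx, ancestry."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from variome import analyses as an
from variome.analyses import (
    AncestryPanel,
    AimMarker,
    ApoeDefinition,
    PgxRow,
    PgxRule,
    RiskModel,
    Site,
    TraitModel,
    Zygosity,
    ancestry_project,
    apoe_report,
    combined_lr,
    genotype_at,
    pgx_report,
    post_test_probability,
    predict_trait,
    project_dosages,
)
from variome.errors import ArgumentError, ConfigError
from variome.fixtures import FixtureSpec, PlantedSite, generate_fixture
from variome.source import GenomeSession


def make_session(tmp_path, planted, samples=("S1",), name="fx", seed=5,
                 n_variants=50, contigs=None):
    spec = FixtureSpec(seed=seed, n_variants=n_variants, samples=list(samples),
                       planted_sites=planted)
    if contigs:
        spec.contigs = contigs
    gz, _, _ = generate_fixture(spec, tmp_path, name)
    return GenomeSession.open_local(gz)


class TestGenotypeAt:
    def test_het_site_with_dosage(self, trio_session):
        z, dosage = genotype_at(trio_session, Site("chr7", 141672604, "T", "C"),
                                sample="NA12878")
        assert z is Zygosity.HET and dosage == 1

    def test_absent_site_missing_by_default(self, trio_session):
        z, dosage = genotype_at(trio_session, Site("chr7", 999_983, "A", "G"))
        assert z is Zygosity.MISSING and dosage is None

    def test_absent_policy_reads_hom_ref(self, trio_session):
        z, dosage = genotype_at(trio_session, Site("chr7", 999_983, "A", "G"),
                                absent_hom_ref=True)
        assert z is Zygosity.HOM_REF and dosage == 0

    def test_alt_mismatch_is_missing(self, trio_session):
        z, _ = genotype_at(trio_session, Site("chr7", 141672604, "T", "G"))
        assert z is Zygosity.MISSING

    def test_contig_alias_applies(self, trio_session):
        z, _ = genotype_at(trio_session, Site("7", 141672604, "T", "C"),
                           sample="NA12878")
        assert z is Zygosity.HET

    def test_untrimmed_site_matched_after_normalization(self, tmp_path):
        session = make_session(
            tmp_path,
            [PlantedSite.make("chr1", 5000, "TAA", "TA", ["1/1"])],
            name="indel",
        )
        # engine matches the *normalized* form (trimmed: 5001 AA>A ~ 5000 TA>T)
        z, dosage = genotype_at(session, Site("chr1", 5000, "TA", "T"))
        assert z is Zygosity.HOM_ALT and dosage == 2


class TestTraits:
    def test_single_variant_lookup(self, trio_session):
        model = TraitModel(
            name="bitter tasting",
            variants=[Site("chr7", 141672604, "T", "C")],
            phenotype_map={("hom_ref",): "non-taster", ("het",): "taster",
                           ("hom_alt",): "taster"},
        )
        report = predict_trait(trio_session, model, sample="NA12878")
        assert report.phenotype == "taster"
        assert list(report.evidence.values()) == ["het"]

    def test_all_missing_no_default_is_undetermined(self, trio_session):
        model = TraitModel(name="x", variants=[Site("chr1", 1_999_499, "A", "C")],
                           phenotype_map={})
        assert predict_trait(trio_session, model).phenotype == "undetermined"

    def test_two_variant_joint_table_enumeration(self, tmp_path):
        """Every reachable joint tuple maps exactly per its table row."""
        gts = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
        combos = list(itertools.product(gts, repeat=2))
        table = {(a, b): f"pheno-{a}-{b}" for a, b in combos}
        for a, b in combos:
            session = make_session(
                tmp_path,
                [PlantedSite.make("chr1", 1000, "A", "G", [gts[a]]),
                 PlantedSite.make("chr1", 2000, "C", "T", [gts[b]])],
                name=f"t_{a}_{b}", n_variants=0,
            )
            model = TraitModel(
                name="joint", phenotype_map=table,
                variants=[Site("chr1", 1000, "A", "G"), Site("chr1", 2000, "C", "T")],
            )
            assert predict_trait(session, model).phenotype == f"pheno-{a}-{b}"


class TestLikelihoodRatioRisk:
    def _model(self, lrs, pre=0.25):
        entries = {
            Site("chr1", 1000 + i, "A", "G"): {"het": lr} for i, lr in enumerate(lrs)
        }
        return RiskModel(disease="d", pre_test_probability=pre, entries=entries)

    def test_all_ones_neutral(self):
        model = self._model([1.0, 1.0, 1.0])
        calls = {s: Zygosity.HET for s in model.entries}
        assert combined_lr(model, calls) == 1.0

    def test_exact_cancellation(self):
        model = self._model([2.0, 0.5])
        calls = {s: Zygosity.HET for s in model.entries}
        assert combined_lr(model, calls) == 1.0

    @given(lrs=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_product_matches_log_domain_oracle(self, lrs):
        model = self._model(lrs)
        calls = {s: Zygosity.HET for s in model.entries}
        got = combined_lr(model, calls)
        expected = math.exp(sum(math.log(x) for x in lrs))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariant_and_multiplicative(self):
        lrs = [1.5, 0.7, 2.2, 0.9]
        m_all = self._model(lrs)
        sites = list(m_all.entries)
        calls = {s: Zygosity.HET for s in sites}
        full = combined_lr(m_all, calls)
        # partition into two sub-models: product of parts == whole
        m_a = RiskModel("d", 0.25, {s: m_all.entries[s] for s in sites[:2]})
        m_b = RiskModel("d", 0.25, {s: m_all.entries[s] for s in sites[2:]})
        assert combined_lr(m_a, calls) * combined_lr(m_b, calls) == pytest.approx(full)
        # permutation of the entry order leaves the product unchanged
        m_rev = RiskModel("d", 0.25, dict(reversed(list(m_all.entries.items()))))
        assert combined_lr(m_rev, calls) == pytest.approx(full)

    def test_missing_call_contributes_neutral_lr(self):
        model = self._model([2.0, 3.0])
        first = list(model.entries)[0]
        assert combined_lr(model, {first: Zygosity.HET}) == 2.0

    def test_nonpositive_lr_is_config_error(self):
        with pytest.raises(ConfigError, match="nonpositive"):
            self._model([1.0, -0.5])

    def test_bad_pretest_is_config_error(self):
        with pytest.raises(ConfigError):
            self._model([1.0], pre=1.5)


class TestPostTestProbability:
    def test_neutral_lr_fixes_probability(self):
        assert post_test_probability(0.1, 1.0) == pytest.approx(0.1, abs=1e-15)

    def test_exact_rational_case(self):
        # odds 1/3 * 3 = 1 -> probability 1/2, exactly in rational arithmetic
        assert post_test_probability(Fraction(1, 4), Fraction(3)) == Fraction(1, 2)
        assert post_test_probability(0.25, 3.0) == pytest.approx(0.5, abs=1e-12)

    def test_small_lr_limit(self):
        assert post_test_probability(0.5, 1e-12) < 1e-11

    @pytest.mark.parametrize("pre,lr", [(0.0, 1.0), (1.0, 1.0), (0.5, 0.0), (0.5, -1.0)])
    def test_bounds_rejected(self, pre, lr):
        with pytest.raises(ArgumentError):
            post_test_probability(pre, lr)

    def test_strictly_increasing_in_lr_over_grid(self):
        for pre in (0.01, 0.25, 0.5, 0.9):
            values = [post_test_probability(pre, lr)
                      for lr in (0.1, 0.5, 1.0, 2.0, 10.0, 100.0)]
            assert all(a < b for a, b in zip(values, values[1:]))
            assert post_test_probability(pre, 1.0) == pytest.approx(pre)


class TestApoe:
    GTS = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}

    def _session(self, tmp_path, z1, z2, name):
        return make_session(
            tmp_path,
            [PlantedSite.make("chr19", 45411941, "T", "C", [self.GTS[z1]]),
             PlantedSite.make("chr19", 45412079, "C", "T", [self.GTS[z2]])],
            name=name, n_variants=0,
        )

    @pytest.mark.parametrize("z1,z2,expected,confidence", [
        ("hom_ref", "hom_ref", "ε3/ε3", "unambiguous"),
        ("hom_alt", "hom_ref", "ε4/ε4", "unambiguous"),
        ("hom_ref", "hom_alt", "ε2/ε2", "unambiguous"),
        ("het", "hom_ref", "ε3/ε4", "unambiguous"),
        ("hom_ref", "het", "ε2/ε3", "unambiguous"),
        ("het", "het", "ε2/ε4", "phase-ambiguous"),
        ("hom_alt", "het", "ε1/ε4", "unambiguous"),
        ("het", "hom_alt", "ε1/ε2", "unambiguous"),
        ("hom_alt", "hom_alt", "ε1/ε1", "unambiguous"),
    ])
    def test_all_nine_biallelic_combinations(self, tmp_path, z1, z2, expected, confidence):
        session = self._session(tmp_path, z1, z2, f"apoe_{z1}_{z2}")
        report = apoe_report(session, assembly="GRCh37")
        assert report.diplotype == expected
        assert report.confidence == confidence

    def test_exactly_one_combination_is_phase_ambiguous(self, tmp_path):
        ambiguous = 0
        for z1, z2 in itertools.product(self.GTS, repeat=2):
            session = self._session(tmp_path, z1, z2, f"amb_{z1}_{z2}")
            if apoe_report(session, assembly="GRCh37").confidence == "phase-ambiguous":
                ambiguous += 1
        assert ambiguous == 1

    def test_missing_site_undetermined(self, tmp_path):
        session = make_session(
            tmp_path,
            [PlantedSite.make("chr19", 45411941, "T", "C", ["0/1"])],
            name="apoe_partial", n_variants=0,
        )
        report = apoe_report(session, assembly="GRCh37")
        assert report.confidence == "undetermined"

    def test_unknown_assembly_is_config_error(self, trio_session):
        with pytest.raises(ConfigError, match="assembly"):
            apoe_report(trio_session, assembly="T2T")


class TestPgx:
    def _rule(self):
        site = Site("chr12", 21331549, "T", "C", "rs4149056")
        table = {
            ("hom_ref",): PgxRow("*1/*1", "Normal function", "Standard dosing."),
            ("het",): PgxRow("*1/*5", "Intermediate function", "Lower dose."),
            ("hom_alt",): PgxRow("*5/*5", "Low function", "Alternative statin."),
        }
        return PgxRule(drug="Simvastatin", gene="SLCO1B1", sites=[site],
                       diplotype_table=table)

    def test_hom_ref_row(self, tmp_path):
        session = make_session(
            tmp_path, [PlantedSite.make("chr12", 21331549, "T", "C", ["0/0"])],
            name="pgx0", n_variants=0, contigs=[("chr12", 30_000_000)])
        report = pgx_report(session, self._rule())
        assert report.status == "called"
        assert report.diplotype == "*1/*1"
        assert report.evidence == {"chr12:21331549:T:C (rs4149056)": "hom_ref"}

    def test_missing_sites_listed_when_undetermined(self, tmp_path):
        session = make_session(tmp_path, [], name="pgx_missing", n_variants=0,
                               contigs=[("chr12", 30_000_000)])
        report = pgx_report(session, self._rule())
        assert report.status == "undetermined"
        assert report.missing_sites == ["chr12:21331549:T:C (rs4149056)"]

    def test_exhaustive_joint_coverage_hits_each_row_once(self, tmp_path):
        """Each configured diplotype row is reached by exactly one joint
        genotype combination."""
        gts = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1"}
        rule = self._rule()
        hits = []
        for z, gt in gts.items():
            session = make_session(
                tmp_path, [PlantedSite.make("chr12", 21331549, "T", "C", [gt])],
                name=f"pgx_{z}", n_variants=0, contigs=[("chr12", 30_000_000)])
            report = pgx_report(session, rule)
            assert report.status == "called"
            hits.append(report.diplotype)
        assert sorted(hits) == sorted(r.diplotype for r in rule.diplotype_table.values())

    def test_unconfigured_combination_uncallable(self, tmp_path):
        rule = self._rule()
        del rule.diplotype_table[("het",)]
        session = make_session(
            tmp_path, [PlantedSite.make("chr12", 21331549, "T", "C", ["0/1"])],
            name="pgx_unc", n_variants=0, contigs=[("chr12", 30_000_000)])
        assert pgx_report(session, rule).status == "uncallable"


class TestAncestry:
    def _panel(self, markers):
        return AncestryPanel(markers=markers, declared_markers=len(markers))

    def test_mirror_pair_panel_projects_to_origin(self, tmp_path):
        """Two markers with opposite loadings and equal centered dosages
        cancel exactly: the projection is (0, 0) by construction."""
        m1 = AimMarker(Site("chr1", 1000, "A", "G"), "G", 0.5, 0.7, -0.2)
        m2 = AimMarker(Site("chr1", 2000, "C", "T"), "T", 0.5, -0.7, 0.2)
        session = make_session(
            tmp_path,
            [PlantedSite.make("chr1", 1000, "A", "G", ["0/1"]),
             PlantedSite.make("chr1", 2000, "C", "T", ["0/1"])],
            name="mirror", n_variants=0)
        result = ancestry_project(session, self._panel([m1, m2]))
        assert result.pc1 == pytest.approx(0.0, abs=1e-12)
        assert result.pc2 == pytest.approx(0.0, abs=1e-12)
        assert result.markers_used == 2

    def test_two_marker_hand_arithmetic(self, tmp_path):
        m1 = AimMarker(Site("chr1", 1000, "A", "G"), "G", 0.2, 0.5, 1.0)
        m2 = AimMarker(Site("chr1", 2000, "C", "T"), "T", 0.8, -1.0, 0.25)
        session = make_session(
            tmp_path,
            [PlantedSite.make("chr1", 1000, "A", "G", ["1/1"]),   # dosage 2
             PlantedSite.make("chr1", 2000, "C", "T", ["0/1"])],  # dosage 1
            name="hand", n_variants=0)
        result = ancestry_project(session, self._panel([m1, m2]))
        # x1 = 2 - 0.4 = 1.6 ; x2 = 1 - 1.6 = -0.6
        assert result.pc1 == pytest.approx(0.5 * 1.6 + (-1.0) * (-0.6))
        assert result.pc2 == pytest.approx(1.0 * 1.6 + 0.25 * (-0.6))

    def test_missing_marker_contributes_zero(self, tmp_path):
        m1 = AimMarker(Site("chr1", 1000, "A", "G"), "G", 0.2, 0.5, 1.0)
        m2 = AimMarker(Site("chr1", 777_331, "C", "T"), "T", 0.8, -1.0, 0.25)
        session = make_session(
            tmp_path, [PlantedSite.make("chr1", 1000, "A", "G", ["1/1"])],
            name="partial", n_variants=0)
        result = ancestry_project(session, self._panel([m1, m2]))
        assert result.markers_used == 1
        assert result.pc1 == pytest.approx(0.5 * 1.6)

    def test_zero_resolvable_markers_is_error(self, tmp_path):
        m = AimMarker(Site("chr1", 999_999, "A", "G"), "G", 0.5, 1.0, 1.0)
        session = make_session(tmp_path, [], name="none", n_variants=0)
        with pytest.raises(ArgumentError):
            ancestry_project(session, self._panel([m]))

    def test_projection_linear_in_centered_dosages(self):
        rng = np.random.default_rng(0)
        from variome.fixtures import generate_aim_panel

        panel, _ = generate_aim_panel(seed=3, n_markers=40, n_background=6)
        d1 = [int(x) for x in rng.integers(0, 3, 40)]
        d2 = [int(x) for x in rng.integers(0, 3, 40)]
        p1 = np.array(project_dosages(panel, d1))
        p2 = np.array(project_dosages(panel, d2))
        # sum of centered vectors: dosage d1+d2 centered by 2*(2f) — emulate
        # by projecting (d1 + d2) against a doubled-frequency panel
        doubled = AncestryPanel(
            markers=[AimMarker(m.site, m.effect_allele, min(m.frequency, 0.49999),
                               m.loading_pc1, m.loading_pc2) for m in panel.markers],
            declared_markers=panel.declared_markers)
        summed = [a + b for a, b in zip(d1, d2)]
        got = np.array(project_dosages(doubled, summed)) - np.array(
            project_dosages(doubled, [0] * 40))
        want = (np.array(project_dosages(doubled, d1)) +
                np.array(project_dosages(doubled, d2)) -
                2 * np.array(project_dosages(doubled, [0] * 40)))
        assert np.allclose(got, want, atol=1e-9)

    def test_background_self_consistency(self, tmp_path):
        """A sample rebuilt from a reference individual's genotypes lands on
        that individual's background coordinates."""
        from variome.fixtures import generate_aim_panel

        panel, dosage_vectors = generate_aim_panel(seed=12, n_markers=30,
                                                   n_background=6)
        name, dosages = next(iter(dosage_vectors.items()))
        gt = {0: "0/0", 1: "0/1", 2: "1/1"}
        planted = [
            PlantedSite.make(m.site.contig, m.site.pos, m.site.ref, m.site.alt,
                             [gt[d]])
            for m, d in zip(panel.markers, dosages)
        ]
        session = make_session(tmp_path, planted, name="selfcons", n_variants=0)
        result = ancestry_project(session, panel)
        expected = next(b for b in panel.background if b[0] == name)
        assert result.pc1 == pytest.approx(expected[2], abs=1e-9)
        assert result.pc2 == pytest.approx(expected[3], abs=1e-9)
        assert result.markers_used == 30

    def test_scale_switch_divides_by_sd(self):
        m = AimMarker(Site("chr1", 10, "A", "G"), "G", 0.2, 1.0, 0.0)
        panel = self._panel([m])
        raw, _ = project_dosages(panel, [2])
        scaled, _ = project_dosages(panel, [2], scale=True)
        assert scaled == pytest.approx(raw / math.sqrt(2 * 0.2 * 0.8))

    def test_bad_frequency_rejected(self):
        with pytest.raises(ConfigError):
            self._panel([AimMarker(Site("chr1", 10, "A", "G"), "G", 1.0, 0.1, 0.1)])


def test_analyses_deterministic_repeat(trio_session):
    """Analyses are pure functions of genotypes + tables: repeated calls
    produce identical output."""
    model = TraitModel(
        name="t", variants=[Site("chr7", 141672604, "T", "C")],
        phenotype_map={("het",): "yes"}, default_phenotype="no")
    a = predict_trait(trio_session, model, "NA12878")
    b = predict_trait(trio_session, model, "NA12878")
    assert a == b
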