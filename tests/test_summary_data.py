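"""Reading, validating, selecting and harmonizing summary associations."""

import math

import pytest

from ironmr import datasets
from ironmr.estimators import wald_ratio
from ironmr.summary_data import (
    HarmonizedPair,
    InstrumentTable,
    ValidationError,
    VariantAssociation,
    Z_95,
    backfill_from_ratio,
    harmonize,
    read_association_table,
    select_instruments,
)

HEADER = "variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\ttrait\n"


def make_table(trait, rows):
    return InstrumentTable(
        trait_id=trait,
        records=tuple(VariantAssociation(trait_id=trait, **row) for row in rows),
    )


class TestReadAssociationTable:
    def test_reads_bundled_serum_iron_values(self, exposure_tables):
        table = exposure_tables["serum_iron"]
        assert len(table) == 5
        rec = table.get("rs1800562")
        assert (rec.beta, rec.se, rec.eaf, rec.effect_allele) == (0.328, 0.016, 0.07, "A")
        assert exposure_tables["serum_iron"].get("rs855791").beta == 0.181
        assert exposure_tables["serum_iron"].get("rs855791").se == 0.007

    def test_bundled_table_sizes_and_variance_explained(self, exposure_tables):
        sizes = {trait: len(table) for trait, table in exposure_tables.items()}
        assert sizes == {
            "serum_iron": 5,
            "transferrin_saturation": 5,
            "log10_ferritin": 6,
            "transferrin": 8,
        }
        assert exposure_tables["serum_iron"].variance_explained == 0.034
        assert exposure_tables["transferrin"].get("rs8177240").beta == 0.380

    def test_underflowing_pvalue_is_clamped_positive(self, exposure_tables):
        p = exposure_tables["transferrin"].get("rs8177240").pvalue
        assert 0.0 < p < 1e-300

    def test_empty_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(HEADER)
        table = read_association_table(path, trait_id="t")
        assert len(table) == 0

    def test_zero_se_is_rejected_with_row_reference(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(HEADER + "rs1\tA\tG\t0.2\t0.1\t0\t0.5\tt\n")
        with pytest.raises(ValidationError, match="rs1"):
            read_association_table(path, trait_id="t")

    def test_missing_beta_rejected_unless_permissive(self, tmp_path):
        path = tmp_path / "missing.tsv"
        path.write_text(HEADER + "rs1\tA\tG\t0.2\t\t0.01\t0.5\tt\nrs2\tA\tG\t0.2\t0.1\t0.01\t0.5\tt\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_association_table(path, trait_id="t")
        table = read_association_table(path, trait_id="t", permissive=True)
        assert table.variant_ids == ("rs2",)

    def test_duplicate_variant_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text(HEADER + "rs1\tA\tG\t0.2\t0.1\t0.01\t0.5\tt\nrs1\tA\tG\t0.2\t0.2\t0.01\t0.5\tt\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_association_table(path, trait_id="t")

    def test_comma_dialect_via_suffix(self, tmp_path):
        path = tmp_path / "assoc.csv"
        path.write_text(HEADER.replace("\t", ",") + "rs1,A,G,0.2,0.1,0.01,0.5,t\n")
        assert read_association_table(path, trait_id="t").get("rs1").beta == 0.1

    def test_missing_file_and_missing_column(self, tmp_path):
        with pytest.raises(ValidationError, match="no such file"):
            read_association_table(tmp_path / "nope.tsv", trait_id="t")
        path = tmp_path / "nocol.tsv"
        path.write_text("variant_id\tbeta\nrs1\t0.1\n")
        with pytest.raises(ValidationError, match="se"):
            read_association_table(path, trait_id="t")


class TestSelectInstruments:
    def test_defaults_keep_all_genomewide_significant_iron_snps(self, exposure_tables):
        table = exposure_tables["serum_iron"]
        assert select_instruments(table).variant_ids == table.variant_ids

    def test_extreme_threshold_keeps_only_strongest_hit(self, exposure_tables):
        kept = select_instruments(exposure_tables["transferrin_saturation"], p_threshold=1e-200)
        assert kept.variant_ids == ("rs1800562",)

    def test_correlated_pair_keeps_smaller_p(self):
        table = make_table(
            "t",
            [
                {"variant_id": "rsA", "beta": 0.1, "se": 0.01, "pvalue": 1e-9},
                {"variant_id": "rsB", "beta": 0.1, "se": 0.01, "pvalue": 1e-10},
            ],
        )
        kept = select_instruments(table, correlations={("rsA", "rsB"): 1.0})
        assert kept.variant_ids == ("rsB",)

    def test_missing_correlation_pair_is_an_error(self):
        table = make_table(
            "t",
            [
                {"variant_id": "rsA", "beta": 0.1, "se": 0.01, "pvalue": 1e-9},
                {"variant_id": "rsB", "beta": 0.1, "se": 0.01, "pvalue": 1e-10},
            ],
        )
        with pytest.raises(ValidationError, match="correlation"):
            select_instruments(table, correlations={})

    def test_output_is_subset_and_stable_under_loose_thresholds(self, exposure_tables):
        for table in exposure_tables.values():
            kept = select_instruments(table)
            assert set(kept.variant_ids) <= set(table.variant_ids)
            loose = select_instruments(table, p_threshold=0.9999999, r2_threshold=1.01)
            assert loose.variant_ids == table.variant_ids


def assoc(trait, ea, oa, beta, eaf=None, vid="rs1", se=0.02):
    return make_table(
        trait,
        [{"variant_id": vid, "effect_allele": ea, "other_allele": oa, "beta": beta, "se": se, "eaf": eaf}],
    )


class TestHarmonize:
    def test_opposite_effect_alleles_flip_outcome_sign(self):
        hset = harmonize(assoc("x", "A", "G", 0.328), assoc("y", "G", "A", 0.5))
        pair = hset.pairs[0]
        assert pair.flipped and pair.beta_outcome == -0.5 and pair.beta_exposure == 0.328

    def test_identical_orientation_is_identity(self):
        hset = harmonize(assoc("x", "A", "G", 0.328), assoc("y", "A", "G", 0.5))
        assert not hset.pairs[0].flipped
        assert hset.pairs[0].beta_outcome == 0.5

    def test_strand_complement_is_matched(self):
        # outcome reported on the other strand: A/G on + is T/C on -
        hset = harmonize(assoc("x", "A", "G", 0.3), assoc("y", "T", "C", 0.5))
        assert not hset.pairs[0].flipped
        flipped = harmonize(assoc("x", "A", "G", 0.3), assoc("y", "C", "T", 0.5))
        assert flipped.pairs[0].flipped

    def test_incompatible_alleles_name_the_variant(self):
        with pytest.raises(ValidationError, match="rs1"):
            harmonize(assoc("x", "A", "G", 0.3), assoc("y", "A", "C", 0.5))

    def test_palindromic_eaf_policy_keeps_informative_variant(self):
        exposure = assoc("x", "C", "G", 0.189, eaf=0.15, vid="rs1799945")
        outcome = assoc("y", "C", "G", 0.4, eaf=0.14, vid="rs1799945")
        hset = harmonize(exposure, outcome, palindromic_policy="eaf", eaf_window=0.08)
        assert len(hset) == 1 and not hset.pairs[0].flipped

    def test_palindromic_opposite_eaf_sides_flip(self):
        exposure = assoc("x", "A", "T", 0.2, eaf=0.2)
        outcome = assoc("y", "A", "T", 0.4, eaf=0.8)
        assert harmonize(exposure, outcome).pairs[0].flipped

    def test_palindromic_near_half_eaf_excluded_and_strict_raises(self):
        exposure = assoc("x", "A", "T", 0.2, eaf=0.48)
        outcome = assoc("y", "A", "T", 0.4, eaf=0.52)
        assert len(harmonize(exposure, outcome).pairs) == 0
        with pytest.raises(ValidationError, match="palindromic"):
            harmonize(exposure, outcome, palindromic_policy="strict")
        assert len(harmonize(exposure, outcome, palindromic_policy="drop").pairs) == 0

    def test_harmonize_is_idempotent(self):
        exposure = assoc("x", "A", "G", 0.3)
        outcome = assoc("y", "G", "A", 0.5)
        once = harmonize(exposure, outcome)
        # re-express the harmonized outcome in exposure orientation and redo
        realigned = assoc("y", "A", "G", once.pairs[0].beta_outcome)
        twice = harmonize(exposure, realigned)
        assert not twice.pairs[0].flipped
        assert twice.pairs[0].beta_outcome == once.pairs[0].beta_outcome

    def test_double_allele_flip_is_identity(self):
        plain = harmonize(assoc("x", "A", "G", 0.3), assoc("y", "G", "A", 0.5))
        both_flipped = harmonize(assoc("x", "G", "A", -0.3), assoc("y", "A", "G", -0.5))
        a, b = plain.pairs[0], both_flipped.pairs[0]
        assert a.beta_exposure == -b.beta_exposure  # orientation differs ...
        assert a.beta_outcome == -b.beta_outcome
        assert wald_ratio(a).theta == pytest.approx(wald_ratio(b).theta)  # ... estimate does not

    def test_preserves_exposure_order_and_intersects(self, exposure_tables):
        exposure = exposure_tables["serum_iron"]
        outcome = make_table(
            "y",
            [
                {"variant_id": "rs855791", "effect_allele": "G", "beta": 0.1, "se": 0.02},
                {"variant_id": "rs1800562", "effect_allele": "A", "beta": 0.2, "se": 0.02},
            ],
        )
        hset = harmonize(exposure, outcome)
        assert hset.variant_ids == ("rs1800562", "rs855791")


class TestBackfillFromRatio:
    @pytest.mark.parametrize(
        "or_point, lo, hi, beta, theta, se_theta",
        [
            (6.65, 2.78, 15.9, 0.328, 1.8946, 0.4449),
            (0.27, 0.15, 0.50, -0.479, -1.3093, 0.3071),
        ],
    )
    def test_known_inversions(self, or_point, lo, hi, beta, theta, se_theta):
        gamma, se_gamma = backfill_from_ratio(or_point, lo, hi, beta)
        assert gamma == pytest.approx(theta * beta, rel=1e-3)
        assert se_gamma == pytest.approx(se_theta * abs(beta), rel=1e-3)

    def test_degenerate_and_disordered_cis_are_errors(self):
        with pytest.raises(ValidationError):
            backfill_from_ratio(1.0, 1.0, 1.0, 0.328)
        with pytest.raises(ValidationError):
            backfill_from_ratio(1.0, 1.2, 0.9, 0.328)
        with pytest.raises(ValidationError):
            backfill_from_ratio(1.0, 0.5, 2.0, 0.0)

    def test_round_trip_through_wald_ratio(self, harmonized_sets):
        ratios = datasets.outcome_ratios()
        for row in ratios.itertuples():
            hset = harmonized_sets[(row.exposure, row.outcome)]
            pair = next(p for p in hset if p.variant_id == row.variant_id)
            est = wald_ratio(pair)
            assert est.theta == pytest.approx(math.log(row.or_point), rel=5e-3, abs=1e-9)
            width = est.ci_high - est.ci_low
            assert width == pytest.approx(math.log(row.ci_high) - math.log(row.ci_low), rel=5e-3)


class TestBundledHarmonizedSets:
    def test_eight_sets_of_three_primary_variants(self, harmonized_sets):
        assert len(harmonized_sets) == 8
        for (exposure, outcome), hset in harmonized_sets.items():
            assert hset.variant_ids == datasets.PRIMARY_VARIANTS
            assert exposure in datasets.EXPOSURES and outcome in datasets.OUTCOMES

    def test_liver_transferrin_ratios_all_protective(self, liver_transferrin):
        # all three per-variant ORs are below 1 (negative log-OR per SD)
        for pair in liver_transferrin:
            assert wald_ratio(pair).theta < 0
            assert pair.beta_exposure < 0  # transferrin betas are negative
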