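"""Closed-form neutrality probabilities against frozen enumeration values.

The frozen expected values were computed with the brute-force enumerator in
conftest (every breakpoint combination through classify_event) and, for the
large genome, cross-checked by Monte-Carlo breakpoint sampling.
"""

import math

import pytest

from genomeflux import (
    ArchitectureError,
    GenomeArchitecture,
    MutationEvent,
    MutationRates,
    MutationType,
    classify_event,
    mean_neutral_size,
    neutral_prob,
    neutral_prob_deletion,
    neutral_prob_duplication,
    neutral_prob_extended,
    neutral_prob_given_size,
)


@pytest.fixture
def big_arch():
    return GenomeArchitecture(g=2000, zc=10**6, znc=10**6)


class TestClosedForms:
    def test_deletion_toy_genome(self, toy_arch):
        # 6 of the 100 (start,size) deletions are neutral
        assert neutral_prob_deletion(toy_arch) == pytest.approx(0.06, abs=1e-15)

    def test_deletion_zero_noncoding(self):
        arch = GenomeArchitecture(g=3, zc=9, znc=0)
        assert neutral_prob_deletion(arch) == 0.0

    def test_deletion_large_genome(self, big_arch):
        assert neutral_prob_deletion(big_arch) == pytest.approx(6.2625e-5, rel=1e-12)

    def test_duplication_toy_genome(self, toy_arch):
        # 120 of the 1000 (start,size,insertion) triples are neutral
        assert neutral_prob_duplication(toy_arch) == pytest.approx(0.12, abs=1e-15)

    def test_duplication_all_promoters(self):
        arch = GenomeArchitecture(g=2, zc=2, znc=0)
        assert neutral_prob_duplication(arch) == 0.0

    def test_duplication_large_genome(self, big_arch):
        assert neutral_prob_duplication(big_arch) == pytest.approx(
            1.2512475e-4, rel=1e-12
        )

    def test_deletion_duplication_ratio_identity(self, big_arch):
        ratio = neutral_prob_deletion(big_arch) / neutral_prob_duplication(big_arch)
        expected = big_arch.znc / (big_arch.znc + big_arch.zc - big_arch.g)
        assert ratio == pytest.approx(expected, rel=1e-14)
        assert ratio <= 1.0

    def test_monotone_in_noncoding_size(self, rates6):
        prev = {t: -1.0 for t in MutationType}
        for znc in (0, 2, 4, 10, 40):
            arch = GenomeArchitecture(g=2, zc=6, znc=znc)
            for t in MutationType:
                val = neutral_prob(arch, rates6, t)
                assert val >= prev[t]
                prev[t] = val


class TestSizeConditional:
    def test_deletion_above_cutoff_is_impossible(self, toy_arch):
        k = toy_arch.intergene_len + 1
        assert neutral_prob_given_size(toy_arch, MutationType.DELETION, k) == 0.0

    def test_deletion_single_base(self, toy_arch):
        # 4 of 10 start positions begin a neutral 1-bp deletion
        assert neutral_prob_given_size(toy_arch, MutationType.DELETION, 1) == pytest.approx(0.4)

    def test_duplication_size_four(self, toy_arch):
        assert neutral_prob_given_size(
            toy_arch, MutationType.DUPLICATION, 4
        ) == pytest.approx(2 * (5 - 4) * 6 / 100)

    def test_duplication_above_period_cutoff(self, toy_arch):
        assert neutral_prob_given_size(
            toy_arch, MutationType.DUPLICATION, toy_arch.period
        ) == 0.0

    @pytest.mark.parametrize("mtype", [MutationType.DELETION, MutationType.DUPLICATION])
    def test_size_sum_recovers_total(self, toy_arch, rates2, mtype):
        """Averaging the per-size neutrality over the uniform size measure
        (sizes 1..L) recovers the type's total closed form."""
        L = int(toy_arch.L)
        total = sum(
            neutral_prob_given_size(toy_arch, mtype, k) for k in range(1, L + 1)
        ) / L
        assert total == pytest.approx(neutral_prob(toy_arch, rates2, mtype), rel=1e-14)

    def test_rejects_nonpositive_size(self, toy_arch):
        with pytest.raises(ArchitectureError):
            neutral_prob_given_size(toy_arch, MutationType.DELETION, 0)


class TestExtendedTypes:
    def test_point_fully_coding(self, rates6):
        arch = GenomeArchitecture(g=3, zc=9, znc=0)
        assert neutral_prob_extended(arch, rates6, MutationType.POINT) == 0.0

    def test_insertion_junction_count(self, toy_arch, rates6):
        # 6 of 10 junctions lie outside genes
        assert neutral_prob_extended(
            toy_arch, rates6, MutationType.INDEL_PLUS
        ) == pytest.approx(0.6)

    def test_small_deletion_averages_sizes(self, toy_arch, rates6):
        # lm=2: (0.4 + 0.2)/2
        assert neutral_prob_extended(
            toy_arch, rates6, MutationType.INDEL_MINUS
        ) == pytest.approx(0.3)

    def test_inversion_squares_junction_fraction(self, toy_arch, rates6):
        assert neutral_prob_extended(
            toy_arch, rates6, MutationType.INVERSION
        ) == pytest.approx(0.36)


class TestMeanNeutralSize:
    def test_deletion_toy_value(self, toy_arch):
        # per tract: sizes (1,1,2) -> mean 4/3
        assert mean_neutral_size(toy_arch, MutationType.DELETION) == pytest.approx(4 / 3)

    def test_duplications_larger_than_deletions(self):
        for g, zc, znc in [(2, 6, 4), (3, 12, 9), (2000, 10**6, 10**6)]:
            arch = GenomeArchitecture(g=g, zc=zc, znc=znc)
            assert mean_neutral_size(arch, MutationType.DUPLICATION) > mean_neutral_size(
                arch, MutationType.DELETION
            )

    def test_unit_tract_forces_single_base(self):
        arch = GenomeArchitecture(g=2, zc=6, znc=2)
        assert mean_neutral_size(arch, MutationType.DELETION) == pytest.approx(1.0)

    def test_zero_neutral_mass_is_an_error(self):
        arch = GenomeArchitecture(g=2, zc=6, znc=0)
        with pytest.raises(ArchitectureError):
            mean_neutral_size(arch, MutationType.DELETION)


class TestClassifyEvent:
    def test_deletion_inside_tract_is_neutral(self, toy_arch):
        # unit layout: bases 0-2 gene, 3-4 intergene (period 5)
        ev = MutationEvent(MutationType.DELETION, start=3, size=2)
        assert classify_event(toy_arch, ev)

    def test_deletion_touching_gene_is_lethal(self, toy_arch):
        ev = MutationEvent(MutationType.DELETION, start=4, size=2)
        assert not classify_event(toy_arch, ev)

    def test_duplicating_a_promoter_is_lethal(self, toy_arch):
        ev = MutationEvent(MutationType.DUPLICATION, start=0, size=1, insertion_point=4)
        assert not classify_event(toy_arch, ev)

    def test_promoter_free_copy_into_tract_is_neutral(self, toy_arch):
        ev = MutationEvent(MutationType.DUPLICATION, start=1, size=3, insertion_point=4)
        assert classify_event(toy_arch, ev)

    def test_insertion_between_intergenic_bases_is_neutral(self, toy_arch):
        ev = MutationEvent(MutationType.INDEL_PLUS, start=4, size=1)
        assert classify_event(toy_arch, ev)

    def test_insertion_inside_gene_is_lethal(self, toy_arch):
        ev = MutationEvent(MutationType.INDEL_PLUS, start=1, size=1)
        assert not classify_event(toy_arch, ev)

    def test_out_of_range_coordinates_rejected(self, toy_arch):
        with pytest.raises(ArchitectureError):
            classify_event(toy_arch, MutationEvent(MutationType.POINT, start=10))
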