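"""Per-type fluxes and the bias B against enumeration and closed limits."""

import numpy as np
import pytest

from genomeflux import (
    ArchitectureError,
    GenomeArchitecture,
    MutationRates,
    MutationType,
    PopulationParams,
    bias,
    delta_deletion,
    delta_duplication,
    delta_indels,
    enumerate_neutrality,
)


@pytest.fixture
def pop1():
    return PopulationParams(N=1)


class TestDeltasAtNeutralLimit:
    """At N=1 every mutant fixes, so each delta must equal the mean neutral
    length mass from exhaustive enumeration."""

    def test_duplication_flux_matches_enumeration(self, toy_arch, rates2, pop1):
        rep = enumerate_neutrality(toy_arch, MutationType.DUPLICATION)
        L = int(toy_arch.L)
        oracle = sum(k * c for k, c in rep.size_histogram.items()) / L**3
        assert delta_duplication(toy_arch, rates2, pop1) == pytest.approx(
            oracle, rel=1e-12
        )

    def test_deletion_flux_matches_enumeration(self, toy_arch, rates2, pop1):
        rep = enumerate_neutrality(toy_arch, MutationType.DELETION)
        L = int(toy_arch.L)
        oracle = sum(k * c for k, c in rep.size_histogram.items()) / L**2
        assert delta_deletion(toy_arch, rates2, pop1) == pytest.approx(oracle, rel=1e-12)

    def test_single_size_indels(self, toy_arch, pop1):
        rates = MutationRates(
            mu=1e-3, lambda_indel_plus=1, lambda_indel_minus=1, lm=1
        )
        d_plus, d_minus = delta_indels(toy_arch, rates, pop1)
        assert d_plus == pytest.approx((toy_arch.znc + toy_arch.g) / toy_arch.L)
        assert d_minus == pytest.approx(toy_arch.znc / toy_arch.L)


class TestDegenerateArchitectures:
    def test_no_noncoding_means_no_deletion_flux(self, rates2, pop1):
        arch = GenomeArchitecture(g=2, zc=6, znc=0)
        assert delta_deletion(arch, rates2, pop1) == 0.0

    def test_all_promoters_means_no_duplication_flux(self, rates2, pop1):
        arch = GenomeArchitecture(g=2, zc=2, znc=0)
        assert delta_duplication(arch, rates2, pop1) == 0.0

    def test_no_noncoding_means_no_indel_deletions(self, pop1):
        arch = GenomeArchitecture(g=2, zc=6, znc=0)
        rates = MutationRates(mu=1e-3, lambda_indel_plus=1, lambda_indel_minus=1, lm=2)
        _, d_minus = delta_indels(arch, rates, pop1)
        assert d_minus == 0.0


class TestSelectionEffects:
    def test_duplication_flux_shrinks_with_population_size(self):
        arch = GenomeArchitecture(g=2000, zc=10**6, znc=10**6)
        rates = MutationRates(mu=1e-10)
        deltas = [
            delta_duplication(arch, rates, PopulationParams(N=n)) * n
            for n in (10**6, 10**7, 10**8)
        ]
        # per-copy fixed flux (delta * N removes the neutral 1/N factor)
        assert deltas[0] > deltas[1] > deltas[2]

    def test_insertion_indels_beat_deletion_indels_everywhere(self):
        """Small indels alone favor growth across the whole explored grid."""
        rates = MutationRates(
            mu=1e-10, lambda_dupl=0, lambda_del=0,
            lambda_indel_plus=1, lambda_indel_minus=1, lm=50,
        )
        pop = PopulationParams(N=10**8)
        for znc in np.logspace(3, 9, 7):
            arch = GenomeArchitecture(g=2000, zc=10**6, znc=float(znc))
            d_plus, d_minus = delta_indels(arch, rates, pop)
            assert d_plus > d_minus


class TestBias:
    def test_crosses_one_exactly_once(self):
        rates = MutationRates(mu=1e-10)
        pop = PopulationParams(N=10**8)
        signs = []
        for znc in np.logspace(3, 9, 13):
            arch = GenomeArchitecture(g=2000, zc=10**6, znc=float(znc))
            signs.append(bias(arch, rates, pop, model="structural_only").bias_B > 1)
        flips = sum(a != b for a, b in zip(signs, signs[1:]))
        assert flips == 1
        assert not signs[0] and signs[-1]

    def test_below_one_at_small_above_one_at_large_noncoding(self):
        rates = MutationRates(mu=1e-10)
        for N in (10**6, 10**7, 10**8, 10**9):
            pop = PopulationParams(N=N)
            lo = bias(
                GenomeArchitecture(g=2000, zc=10**6, znc=10**3), rates, pop,
                model="structural_only",
            ).bias_B
            hi = bias(
                GenomeArchitecture(g=2000, zc=10**6, znc=10**9), rates, pop,
                model="structural_only",
            ).bias_B
            assert lo < 1 < hi

    def test_indel_only_never_reaches_one(self):
        rates = MutationRates(
            mu=1e-10, lambda_dupl=0, lambda_del=0,
            lambda_indel_plus=1, lambda_indel_minus=1, lm=50,
        )
        pop = PopulationParams(N=10**8)
        for znc in np.logspace(3, 9, 13):
            arch = GenomeArchitecture(g=2000, zc=10**6, znc=float(znc))
            assert bias(arch, rates, pop, model="indel_only").bias_B < 1

    def test_neutral_limit_favors_duplications(self, pop1):
        """At N=1 the bias is the pure neutral flux ratio, below one whenever
        genes are much longer than one base."""
        rates = MutationRates(mu=1e-10)
        for znc in (10**4, 10**6, 10**8):
            arch = GenomeArchitecture(g=2000, zc=10**6, znc=znc)
            assert bias(arch, rates, pop1, model="structural_only").bias_B < 1

    def test_compound_parameter_invariance(self):
        """B at (N, mu) and (c*N, mu/c) agree to 1e-6 relative for mu << 1."""
        arch = GenomeArchitecture(g=2000, zc=10**6, znc=10**5)
        base = bias(
            arch, MutationRates(mu=1e-9), PopulationParams(N=10**6),
            model="structural_only",
        ).bias_B
        for c in (10, 100):
            scaled = bias(
                arch, MutationRates(mu=1e-9 / c), PopulationParams(N=10**6 * c),
                model="structural_only",
            ).bias_B
            assert scaled == pytest.approx(base, rel=1e-6)

    def test_zero_insertion_flux_rejected(self, pop1):
        arch = GenomeArchitecture(g=2, zc=2, znc=0)
        rates = MutationRates(mu=1e-3)
        with pytest.raises(ArchitectureError):
            bias(arch, rates, pop1, model="structural_only")

    def test_expanded_weights_by_rate_multipliers(self, pop1):
        """Doubling the deletion-side multipliers doubles B in the neutral
        limit (deltas themselves are rate-free there)."""
        arch = GenomeArchitecture(g=20, zc=10**4, znc=10**4)
        r1 = MutationRates(
            mu=1e-6, lambda_indel_plus=1, lambda_indel_minus=1, lm=10
        )
        r2 = MutationRates(
            mu=1e-6, lambda_del=2, lambda_indel_minus=2,
            lambda_indel_plus=1, lm=10,
        )
        b1 = bias(arch, r1, pop1, model="expanded").bias_B
        b2 = bias(arch, r2, pop1, model="expanded").bias_B
        assert b2 == pytest.approx(2 * b1, rel=1e-12)
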