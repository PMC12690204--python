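"""Effective fitness: exact product, decimal reference, approximations."""

import math
from fractions import Fraction

import numpy as np
import pytest

from genomeflux import (
    ArchitectureError,
    GenomeArchitecture,
    MutationRates,
    MutationType,
    effective_fitness,
    effective_fitness_approx,
    effective_fitness_decimal,
    enumerate_neutrality,
    log_fitness_ratio,
    selection_coefficient,
    selection_coefficient_approx,
)
from genomeflux.fitness import (
    _log_fitness_ratio_exact,
    _log_fitness_ratio_series,
    _resolve_types,
)

#: fixed grid for the 50-digit decimal agreement contract
DECIMAL_GRID = [
    (2, 6, 4, 1e-3),
    (3, 9, 6, 1e-2),
    (2, 8, 10, 1e-4),
    (5, 20, 30, 1e-3),
    (4, 400, 200, 1e-5),
]


class TestEffectiveFitness:
    def test_no_mutations_means_perfect_robustness(self, toy_arch):
        assert effective_fitness(toy_arch, MutationRates(mu=0.0)).fe == 1.0

    @pytest.mark.parametrize("g,zc,znc,mu", DECIMAL_GRID)
    def test_agrees_with_decimal_reference(self, g, zc, znc, mu):
        arch = GenomeArchitecture(g=g, zc=zc, znc=znc)
        rates = MutationRates(
            mu=mu, lambda_inv=1, lambda_pm=1, lambda_indel_plus=1,
            lambda_indel_minus=1, lm=3,
        )
        fe = effective_fitness(arch, rates).fe
        ref = float(effective_fitness_decimal(arch, rates))
        assert fe == pytest.approx(ref, rel=1e-12)

    def test_matches_enumeration_expectation(self, toy_arch, rates2):
        """The product form equals the offspring-viability expectation built
        from exhaustively enumerated per-type neutral fractions."""
        mu = rates2.mu
        # independent reconstruction: per-position neutrality of a deletion
        # starting at i is r_i/L; enumerate r_i directly from the layout
        L = int(toy_arch.L)
        fe_ref = 1.0
        runs = []
        for i in range(L):
            o = i % int(toy_arch.period)
            runs.append(0 if o < toy_arch.gene_len else int(toy_arch.period) - o)
        for r in runs:  # deletions
            fe_ref *= (1 - mu) + mu * r / L
        for i in range(L):  # duplications
            o = i % int(toy_arch.period)
            d = 0 if o == 0 else int(toy_arch.period) - o
            fe_ref *= (1 - mu) + mu * (d / L) * ((toy_arch.znc + toy_arch.g) / L)
        assert effective_fitness(toy_arch, rates2).fe == pytest.approx(fe_ref, rel=1e-12)

    def test_decreasing_in_noncoding_size_and_rate(self):
        vals = []
        for znc in (4, 8, 40):
            arch = GenomeArchitecture(g=2, zc=6, znc=znc)
            vals.append(effective_fitness(arch, MutationRates(mu=1e-3)).fe)
        assert vals[0] > vals[1] > vals[2]
        arch = GenomeArchitecture(g=2, zc=6, znc=4)
        fes = [effective_fitness(arch, MutationRates(mu=m)).fe for m in (1e-4, 1e-3, 1e-2)]
        assert fes[0] > fes[1] > fes[2]

    def test_per_type_terms_sum_to_log_fe(self, toy_arch, rates6):
        res = effective_fitness(toy_arch, rates6)
        assert math.fsum(res.per_type_log_terms.values()) == pytest.approx(
            res.log_fe, abs=1e-15
        )

    def test_rate_at_or_above_one_rejected(self, toy_arch):
        rates = MutationRates(mu=0.5, lambda_dupl=2.0)
        with pytest.raises(ArchitectureError):
            effective_fitness(toy_arch, rates)


class TestApproximation:
    def test_two_type_exponential_form(self):
        arch = GenomeArchitecture(g=2000, zc=10**6, znc=10**6)
        rates = MutationRates(mu=1e-10)
        res = effective_fitness_approx(arch, rates)
        assert res.fe == pytest.approx(math.exp(-4e-4), rel=1e-15)
        exact = effective_fitness(arch, rates)
        assert res.fe == pytest.approx(exact.fe, rel=1e-6)

    def test_mu_zero_limit(self, toy_arch):
        assert effective_fitness_approx(toy_arch, MutationRates(mu=0.0)).fe == 1.0

    def test_ratio_tends_to_exp_2k_mu(self):
        arch = GenomeArchitecture(g=2000, zc=10**6, znc=10**6)
        rates = MutationRates(mu=1e-10)
        k = 1000
        D = log_fitness_ratio(arch, rates, k)  # log fe(znc) - log fe(znc+k)
        assert D == pytest.approx(2 * k * rates.mu, rel=1e-3)


class TestLogFitnessRatio:
    @pytest.mark.parametrize("k", [2, -2, 10, -4])
    def test_series_matches_exact_pairing(self, toy_arch, rates2, k):
        types = _resolve_types(rates2, None)
        exact = _log_fitness_ratio_exact(toy_arch, rates2, k, types)
        series = float(
            _log_fitness_ratio_series(toy_arch, rates2, np.asarray([float(k)]), types)[0]
        )
        assert series == pytest.approx(exact, rel=1e-8)

    def test_series_matches_exact_at_scale(self):
        arch = GenomeArchitecture(g=2000, zc=10**6, znc=10**7)
        rates = MutationRates(mu=1e-8)
        types = _resolve_types(rates, None)
        for k in (1, 500, -500, 4000):
            exact = _log_fitness_ratio_exact(arch, rates, k, types)
            series = float(
                _log_fitness_ratio_series(arch, rates, np.asarray([float(k)]), types)[0]
            )
            assert series == pytest.approx(exact, rel=1e-9)

    def test_exact_matches_decimal_log_ratio(self, toy_arch, rates2):
        from decimal import localcontext

        fe0 = effective_fitness_decimal(toy_arch, rates2)
        fek = effective_fitness_decimal(toy_arch.with_znc(8), rates2)
        with localcontext() as ctx:
            ctx.prec = 50
            ref = float((fe0 / fek).ln())
        assert log_fitness_ratio(toy_arch, rates2, 4) == pytest.approx(ref, rel=1e-12)

    def test_deleting_below_zero_noncoding_rejected(self, toy_arch, rates2):
        with pytest.raises(ArchitectureError):
            log_fitness_ratio(toy_arch, rates2, -5)


class TestSelectionCoefficient:
    def test_zero_size_change_is_neutral(self, toy_arch, rates2):
        assert selection_coefficient(toy_arch, rates2, 0) == 0.0

    def test_deletions_increase_robustness(self, toy_arch, rates2):
        assert selection_coefficient(toy_arch, rates2, -2) > 0
        assert selection_coefficient(toy_arch, rates2, 2) < 0

    def test_small_mu_approximation(self):
        arch = GenomeArchitecture(g=2000, zc=10**6, znc=10**6)
        rates = MutationRates(mu=1e-10)
        s = selection_coefficient(arch, rates, 1000)
        assert s == pytest.approx(-2e-7, rel=1e-2)
        assert selection_coefficient_approx(rates, 1000) == pytest.approx(-2e-7)
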