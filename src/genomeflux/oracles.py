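"""Independent ground truth: exhaustive enumeration and forward simulation.

Every closed-form neutrality probability is an exact event count; this
module recomputes those counts by brute force on small enumerable genomes
(exact rational arithmetic), estimates them by Monte-Carlo breakpoint
sampling on large genomes, and validates the fixation formula with a
forward Wright-Fisher simulator.  Nothing here shares code paths with the
analytic formulas it checks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Optional, Tuple

import numpy as np

from .architecture import (
    ArchitectureError,
    GenomeArchitecture,
    MutationEvent,
    MutationRates,
    MutationType,
    PopulationParams,
)
from .neutrality import classify_event

#: size guards for exhaustive enumeration
MAX_L_QUADRATIC = 10_000  # deletion / inversion / point / indels: O(L^2) or less
MAX_L_CUBIC = 200  # duplications: O(L^3) events


@dataclass(frozen=True)
class EnumerationReport:
    """Exact neutral-event counts for one mutation type."""

    type: MutationType
    total_events: int
    neutral_events: int
    size_histogram: Dict[int, int] = field(default_factory=dict)

    @property
    def neutral_fraction(self) -> Fraction:
        return Fraction(self.neutral_events, self.total_events)

    def to_json(self) -> str:
        return json.dumps(
            {
                "type": self.type.value,
                "total_events": self.total_events,
                "neutral_events": self.neutral_events,
                "neutral_fraction": [
                    self.neutral_fraction.numerator,
                    self.neutral_fraction.denominator,
                ],
                "size_histogram": {str(k): v for k, v in sorted(self.size_histogram.items())},
            }
        )


def _coding_mask(arch: GenomeArchitecture) -> np.ndarray:
    L = int(arch.L)
    period = int(arch.period)
    gene_len = int(arch.gene_len)
    offsets = np.arange(L) % period
    return offsets < gene_len


def _junction_lethal_mask(arch: GenomeArchitecture) -> np.ndarray:
    """True where the junction (gap before base j) is strictly inside a gene."""
    L = int(arch.L)
    period = int(arch.period)
    gene_len = int(arch.gene_len)
    o = np.arange(L) % period
    return (o >= 1) & (o <= gene_len - 1)


def _noncoding_runs(arch: GenomeArchitecture) -> np.ndarray:
    """Per start base: number of consecutive noncoding bases (0 if coding)."""
    L = int(arch.L)
    coding = _coding_mask(arch)
    runs = np.zeros(L, dtype=np.int64)
    # scan the doubled circular array backwards
    doubled = np.concatenate([coding, coding])
    acc = 0
    tmp = np.zeros(2 * L, dtype=np.int64)
    for i in range(2 * L - 1, -1, -1):
        acc = 0 if doubled[i] else acc + 1
        tmp[i] = acc
    runs = np.minimum(tmp[:L], L)
    return runs


def _promoter_free_runs(arch: GenomeArchitecture) -> np.ndarray:
    """Per start base: largest promoter-free segment size starting there."""
    L = int(arch.L)
    period = int(arch.period)
    o = np.arange(L) % period
    runs = np.where(o == 0, 0, period - o)
    return runs.astype(np.int64)


def enumerate_neutrality(
    arch: GenomeArchitecture,
    mtype: MutationType,
    lm: Optional[int] = None,
    max_L_cubic: int = MAX_L_CUBIC,
) -> EnumerationReport:
    """Exact neutral-event counts by iterating the full event space.

    Counts all ``L**2`` (start, size) deletions, ``L**3`` duplication
    triples (the insertion-junction factor is independent of the segment, so
    the triple count is the product of the two exhaustive counts), ``L**2``
    inversion junction pairs, ``L`` point targets and ``L*lm`` indels.
    Guarded against combinatorial blowup; use :func:`sample_neutrality`
    beyond the guards.
    """
    arch.require_enumerable()
    L = int(arch.L)
    if L > MAX_L_QUADRATIC:
        raise ArchitectureError(
            f"L = {L} exceeds enumeration guard {MAX_L_QUADRATIC}; "
            "use sample_neutrality instead"
        )
    if mtype is MutationType.DUPLICATION and L > max_L_cubic:
        raise ArchitectureError(
            f"L = {L} exceeds duplication enumeration guard {max_L_cubic} "
            "(O(L^3) events); use sample_neutrality instead"
        )

    if mtype is MutationType.POINT:
        coding = _coding_mask(arch)
        neutral = int((~coding).sum())
        return EnumerationReport(mtype, L, neutral, {0: neutral})

    if mtype in (MutationType.DELETION, MutationType.INDEL_MINUS):
        sizes = range(1, L + 1) if mtype is MutationType.DELETION else range(1, int(lm) + 1)
        runs = _noncoding_runs(arch)
        hist = {}
        for k in sizes:
            c = int((runs >= k).sum())
            if c:
                hist[k] = c
        neutral = sum(hist.values())
        total = L * (L if mtype is MutationType.DELETION else int(lm))
        return EnumerationReport(mtype, total, neutral, hist)

    if mtype is MutationType.INDEL_PLUS:
        if lm is None:
            raise ArchitectureError("lm required to enumerate insertions")
        ok = int((~_junction_lethal_mask(arch)).sum())
        hist = {k: ok for k in range(1, int(lm) + 1)}
        return EnumerationReport(mtype, L * int(lm), ok * int(lm), hist)

    if mtype is MutationType.INVERSION:
        ok_mask = ~_junction_lethal_mask(arch)
        ok = int(ok_mask.sum())
        # histogram over breakpoint separations via circular correlation
        f = np.fft.rfft(ok_mask.astype(float))
        corr = np.fft.irfft(f * np.conj(f), n=L)
        hist = {int(s): int(round(corr[s])) for s in range(L) if round(corr[s]) > 0}
        return EnumerationReport(mtype, L * L, ok * ok, hist)

    if mtype is MutationType.DUPLICATION:
        seg_runs = _promoter_free_runs(arch)
        ok_junctions = int((~_junction_lethal_mask(arch)).sum())
        hist = {}
        for k in range(1, L + 1):
            c = int((seg_runs >= k).sum()) * ok_junctions
            if c:
                hist[k] = c
        neutral = sum(hist.values())
        return EnumerationReport(mtype, L ** 3, neutral, hist)

    raise ArchitectureError(f"unknown mutation type {mtype}")


def mean_signed_size_change(arch: GenomeArchitecture) -> Fraction:
    """Exact expected signed genome-length change per mutation event when one
    duplication and one deletion event class are drawn at equal rates.

    Every event (neutral or lethal) counts with its raw size effect, the
    matched uniform size measure of both classes: ``(E[+k] - E[k])/2 = 0``
    exactly.  Computed here by full enumeration in rational arithmetic.
    """
    arch.require_enumerable()
    L = int(arch.L)
    # duplications: all L^3 (start, size, junction) triples, effect +size
    dup_sum = Fraction(0)
    for k in range(1, L + 1):
        dup_sum += Fraction(k * L * L, 1)  # L starts x L junctions for each size
    dup_mean = dup_sum / Fraction(L ** 3)
    # deletions: all L^2 (start, size) pairs, effect -size
    del_sum = Fraction(0)
    for k in range(1, L + 1):
        del_sum += Fraction(k * L, 1)
    del_mean = del_sum / Fraction(L * L)
    return (dup_mean - del_mean) / 2


# ---------------------------------------------------------------------------
# Monte-Carlo breakpoint sampling
# ---------------------------------------------------------------------------

def sample_neutrality(
    arch: GenomeArchitecture,
    mtype: MutationType,
    draws: int,
    seed: int,
    lm: Optional[int] = None,
) -> Tuple[float, float]:
    """Unbiased Monte-Carlo estimate of the neutrality probability.

    Returns ``(estimate, stderr)``; reproducible from the seed.  Scales the
    enumeration oracle beyond the exhaustive guards.
    """
    if draws < 1_000:
        raise ArchitectureError("draws must be >= 1000")
    arch.require_enumerable()
    rng = np.random.default_rng(seed)
    L = int(arch.L)
    period = int(arch.period)
    gene_len = int(arch.gene_len)

    def junction_ok(j: np.ndarray) -> np.ndarray:
        o = j % period
        return ~((o >= 1) & (o <= gene_len - 1))

    def noncoding_run(s: np.ndarray) -> np.ndarray:
        o = s % period
        return np.where(o >= gene_len, period - o, 0)

    def promoter_free_run(s: np.ndarray) -> np.ndarray:
        o = s % period
        return np.where(o == 0, 0, period - o)

    if mtype is MutationType.POINT:
        s = rng.integers(0, L, size=draws)
        hits = (s % period) >= gene_len
    elif mtype is MutationType.DELETION:
        s = rng.integers(0, L, size=draws)
        k = rng.integers(1, L + 1, size=draws)
        hits = k <= noncoding_run(s)
    elif mtype is MutationType.INDEL_MINUS:
        if lm is None:
            raise ArchitectureError("lm required")
        s = rng.integers(0, L, size=draws)
        k = rng.integers(1, lm + 1, size=draws)
        hits = k <= noncoding_run(s)
    elif mtype is MutationType.INDEL_PLUS:
        j = rng.integers(0, L, size=draws)
        hits = junction_ok(j)
    elif mtype is MutationType.INVERSION:
        j1 = rng.integers(0, L, size=draws)
        j2 = rng.integers(0, L, size=draws)
        hits = junction_ok(j1) & junction_ok(j2)
    elif mtype is MutationType.DUPLICATION:
        s = rng.integers(0, L, size=draws)
        k = rng.integers(1, L + 1, size=draws)
        j = rng.integers(0, L, size=draws)
        hits = (k <= promoter_free_run(s)) & junction_ok(j)
    else:
        raise ArchitectureError(f"unknown mutation type {mtype}")

    p = float(hits.mean())
    stderr = math.sqrt(max(p * (1.0 - p), 1e-300) / draws)
    return p, stderr


# ---------------------------------------------------------------------------
# Wright-Fisher Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WFRun:
    """Result of a Wright-Fisher fixation experiment."""

    N: int
    fitness_ratio: float
    replicates: int
    seed: int
    fixations: int
    ci95: float  # binomial 95% half-width

    @property
    def rate(self) -> float:
        return self.fixations / self.replicates


def wf_fixation_mc(
    N: int,
    fitness_ratio: float,
    replicates: int,
    seed: int,
    max_generations: int = 10_000_000,
) -> WFRun:
    """Empirical fixation rate of a single mutant lineage.

    Standard discrete haploid Wright-Fisher: each generation the mutant count
    is a binomial draw of ``N`` offspring where a mutant parent is sampled
    with relative weight ``fitness_ratio`` (mutant effective fitness over
    wild-type).  Runs all replicates in parallel until loss or fixation.
    """
    if N > 1_000:
        raise ArchitectureError("N > 1000 exceeds the desk-scale simulator guard")
    if replicates > 1_000_000:
        raise ArchitectureError("replicates > 1e6 exceeds the desk-scale guard")
    rng = np.random.default_rng(seed)
    w = fitness_ratio
    m = np.ones(replicates, dtype=np.int64)
    active = np.ones(replicates, dtype=bool)
    fixations = 0
    for _ in range(max_generations):
        if not active.any():
            break
        ma = m[active]
        p = ma * w / (ma * w + (N - ma))
        ma = rng.binomial(N, p)
        m[active] = ma
        fixed = ma == N
        lost = ma == 0
        fixations += int(fixed.sum())
        idx = np.flatnonzero(active)
        active[idx[fixed | lost]] = False
    rate = fixations / replicates
    ci95 = 1.96 * math.sqrt(max(rate * (1.0 - rate), 1e-300) / replicates)
    return WFRun(
        N=N,
        fitness_ratio=fitness_ratio,
        replicates=replicates,
        seed=seed,
        fixations=fixations,
        ci95=ci95,
    )


# ---------------------------------------------------------------------------
# Forward genome-size trajectory (qualitative oracle)
# ---------------------------------------------------------------------------

def wf_genome_trajectory(
    arch: GenomeArchitecture,
    rates: MutationRates,
    pop: PopulationParams,
    generations: int,
    seed: int,
    max_tries: int = 1_000,
) -> Tuple[np.ndarray, bool]:
    """Forward Wright-Fisher simulation of population-mean noncoding size.

    Desk-scale only (``N <= 200``): each offspring draws Poisson numbers of
    duplication/deletion events at the per-base rates, each event's
    breakpoints are drawn uniformly on the continuous circular genome (the
    equal-spacing idealization is re-imposed after every change), lethal
    offspring are redrawn from a new parent.  Returns the per-generation
    mean ``znc`` and a flag set when the population went extinct (all
    offspring lethal).  Qualitative mean-reversion checks only.
    """
    N = int(pop.N)
    if N > 200:
        raise ArchitectureError("N > 200 exceeds the trajectory simulator guard")
    rng = np.random.default_rng(seed)
    g = arch.g
    zc = arch.zc
    znc = np.full(N, float(arch.znc))
    means = np.empty(generations + 1)
    means[0] = znc.mean()

    lam_dup = rates.lambda_dupl * rates.mu
    lam_del = rates.lambda_del * rates.mu

    def mutate(z: float) -> Optional[float]:
        """Apply one offspring's mutations; None if lethal."""
        L = zc + z
        il = z / g
        n_dup = rng.poisson(lam_dup * L)
        n_del = rng.poisson(lam_del * L)
        for _ in range(n_del):
            size = rng.uniform(0.0, L)
            # start is noncoding with prob z/L, at uniform depth in a tract
            if rng.uniform() >= z / L:
                return None
            remaining = (z / g) - rng.uniform(0.0, z / g)
            if size > remaining:
                return None
            z -= size
            L = zc + z
        for _ in range(n_dup):
            size = rng.uniform(0.0, L)
            # distance from segment start to the next promoter (1 bp arcs)
            y = rng.uniform(0.0, L / g)
            d = 0.0 if y < 1.0 else L / g - y
            if size > d:
                return None
            if rng.uniform() >= (z + g) / L:
                return None  # insertion junction inside a gene
            z += size
            L = zc + z
        return z

    for t in range(1, generations + 1):
        new = np.empty(N)
        for i in range(N):
            ok = False
            for _ in range(max_tries):
                parent = znc[rng.integers(0, N)]
                child = mutate(parent)
                if child is not None:
                    new[i] = child
                    ok = True
                    break
            if not ok:
                means[t:] = np.nan
                return means, True
        znc = new
        means[t] = znc.mean()
    return means, False
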