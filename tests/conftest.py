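"""Shared fixtures and brute-force oracles.

The brute-force enumerators here iterate every event coordinate explicitly
through ``classify_event`` (no run-length shortcuts), so they are fully
independent of both the closed forms and the package's own enumeration
module.
"""

from __future__ import annotations

from fractions import Fraction

import pytest

from genomeflux import (
    GenomeArchitecture,
    MutationEvent,
    MutationRates,
    MutationType,
    classify_event,
)


@pytest.fixture
def toy_arch() -> GenomeArchitecture:
    """The L=10 toy genome: 2 genes of 3 bp, 2 intergenic tracts of 2 bp."""
    return GenomeArchitecture(g=2, zc=6, znc=4)


@pytest.fixture
def rates2() -> MutationRates:
    """Two-type structural model at mu = 1e-3."""
    return MutationRates(mu=1e-3)


@pytest.fixture
def rates6() -> MutationRates:
    """All six mutation types at unit multipliers, lm = 2."""
    return MutationRates(
        mu=1e-3,
        lambda_inv=1.0,
        lambda_pm=1.0,
        lambda_indel_plus=1.0,
        lambda_indel_minus=1.0,
        lm=2,
    )


def brute_force_count(
    arch: GenomeArchitecture, mtype: MutationType, lm: int | None = None
) -> tuple[int, int]:
    """(neutral, total) by looping every coordinate through classify_event."""
    L = int(arch.L)
    neutral = 0
    total = 0
    if mtype is MutationType.POINT:
        for s in range(L):
            total += 1
            neutral += classify_event(arch, MutationEvent(mtype, start=s))
    elif mtype in (MutationType.DELETION, MutationType.INDEL_MINUS):
        sizes = range(1, L + 1) if mtype is MutationType.DELETION else range(1, lm + 1)
        for s in range(L):
            for k in sizes:
                total += 1
                neutral += classify_event(arch, MutationEvent(mtype, start=s, size=k))
    elif mtype is MutationType.INDEL_PLUS:
        for j in range(L):
            for k in range(1, lm + 1):
                total += 1
                neutral += classify_event(arch, MutationEvent(mtype, start=j, size=k))
    elif mtype is MutationType.INVERSION:
        for j1 in range(L):
            for sep in range(L):
                total += 1
                neutral += classify_event(
                    arch, MutationEvent(mtype, start=j1, size=sep)
                )
    elif mtype is MutationType.DUPLICATION:
        for s in range(L):
            for k in range(1, L + 1):
                for j in range(L):
                    total += 1
                    neutral += classify_event(
                        arch,
                        MutationEvent(mtype, start=s, size=k, insertion_point=j),
                    )
    else:  # pragma: no cover
        raise AssertionError(mtype)
    return neutral, total


def brute_force_fraction(
    arch: GenomeArchitecture, mtype: MutationType, lm: int | None = None
) -> Fraction:
    n, d = brute_force_count(arch, mtype, lm)
    return Fraction(n, d)
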