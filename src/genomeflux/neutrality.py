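"""Exact neutrality probabilities under uniform-breakpoint counting.

A mutation is *neutral* when it leaves every coding base and every promoter
intact and inserts nothing inside a gene; every other mutation is lethal
(binary fitness).  All breakpoints are uniform over the genome, which fixes
the event measure:

* a deletion is an ordered pair ``(start, size)``, start uniform over the
  ``L`` bases and size uniform over ``1..L`` — ``L**2`` equiprobable events;
* a duplication adds an independent uniform insertion junction — ``L**3``
  events;
* an inversion is an ordered pair of junctions — ``L**2`` events;
* a point mutation is a single base — ``L`` events;
* an indel is ``(position, size)`` with size uniform on ``1..lm`` —
  ``L*lm`` events.

Junctions are the ``L`` inter-base positions; a junction is *inside a gene*
iff both flanking bases belong to the same gene, so exactly ``zc - g``
junctions are lethal insertion/breakpoint sites and ``znc + g`` are neutral.

The closed forms below are polynomials in ``(g, zc, znc)`` and are the exact
event counts divided by the total number of events on any enumerable
architecture; on analytic (real-valued ``znc``) architectures they are the
natural polynomial continuation.
"""

from __future__ import annotations

import math
from typing import Optional

from .architecture import (
    ArchitectureError,
    GenomeArchitecture,
    MutationEvent,
    MutationRates,
    MutationType,
)


def neutral_prob_deletion(arch: GenomeArchitecture) -> float:
    """Probability that a uniform deletion is neutral.

    ``nu_del = znc (znc + g) / (2 g L^2)``: a deletion is neutral iff it is
    entirely contained in one intergenic tract.
    """
    L = arch.L
    return arch.znc * (arch.znc + arch.g) / (2.0 * arch.g * L * L)


def neutral_prob_duplication(arch: GenomeArchitecture) -> float:
    """Probability that a uniform duplication is neutral.

    ``nu_dupl = (znc + zc - g)(znc + g) / (2 g L^2)``: the copied segment
    must avoid all promoters and the insertion junction must lie outside
    genes.  The ratio ``nu_del/nu_dupl = znc/(znc + zc - g) <= 1`` whenever
    ``zc > g``: duplications are more often neutral than deletions.
    """
    L = arch.L
    return (
        (arch.znc + arch.zc - arch.g)
        * (arch.znc + arch.g)
        / (2.0 * arch.g * L * L)
    )


def neutral_junction_count(arch: GenomeArchitecture) -> float:
    """Number of junctions not strictly inside a gene: ``znc + g``."""
    return arch.znc + arch.g


def neutral_prob_given_size(
    arch: GenomeArchitecture, mtype: MutationType, k: float
) -> float:
    """Probability that a mutation of type ``mtype`` and size ``k`` is neutral.

    For deletions this is over the ``L`` start positions,
    ``g * max(intergene_len - k + 1, 0) / L``; for duplications over start and
    insertion positions, ``g * max(period - k, 0) * (znc + g) / L**2``.  Above
    the architectural cutoffs (``intergene_len`` for deletions, ``period - 1``
    for duplications) no mutation of that size can be neutral.
    """
    if k < 1:
        raise ArchitectureError(f"mutation size must be >= 1, got {k}")
    L = arch.L
    if mtype is MutationType.DELETION:
        return arch.g * max(arch.intergene_len - k + 1.0, 0.0) / L
    if mtype is MutationType.DUPLICATION:
        return arch.g * max(arch.period - k, 0.0) * (arch.znc + arch.g) / (L * L)
    if mtype is MutationType.INDEL_MINUS:
        return arch.g * max(arch.intergene_len - k + 1.0, 0.0) / L
    if mtype is MutationType.INDEL_PLUS:
        return (arch.znc + arch.g) / L
    raise ArchitectureError(f"size-conditional neutrality undefined for {mtype}")


def neutral_prob_extended(
    arch: GenomeArchitecture, rates: MutationRates, mtype: MutationType
) -> float:
    """Neutrality probability for point mutations, inversions and indels.

    * point: ``znc / L`` (the hit base must be noncoding);
    * inversion: ``((znc + g)/L)**2`` (both breakpoint junctions outside
      genes);
    * indel+: ``(znc + g)/L`` (only the insertion junction matters, small
      insertions are never architecturally blocked);
    * indel-: ``(1/lm) * sum_{j=1..lm} g * max(intergene_len - j + 1, 0)/L``.
    """
    L = arch.L
    if mtype is MutationType.POINT:
        return arch.znc / L
    if mtype is MutationType.INVERSION:
        q = (arch.znc + arch.g) / L
        return q * q
    if mtype is MutationType.INDEL_PLUS:
        return (arch.znc + arch.g) / L
    if mtype is MutationType.INDEL_MINUS:
        lm = rates.lm
        total = sum(
            max(arch.intergene_len - j + 1.0, 0.0) for j in range(1, lm + 1)
        )
        return arch.g * total / (L * lm)
    raise ArchitectureError(f"not an extended mutation type: {mtype}")


def neutral_prob(
    arch: GenomeArchitecture, rates: MutationRates, mtype: MutationType
) -> float:
    """Total neutrality probability for any of the six mutation types."""
    if mtype is MutationType.DELETION:
        return neutral_prob_deletion(arch)
    if mtype is MutationType.DUPLICATION:
        return neutral_prob_duplication(arch)
    return neutral_prob_extended(arch, rates, mtype)


def mean_neutral_size(
    arch: GenomeArchitecture, mtype: MutationType, lm: Optional[int] = None
) -> float:
    """Expected size (bp) of a neutral event of the given type.

    The expectation is over the conditional distribution of neutral events
    under the uniform event measure.  Closed forms follow from the per-size
    neutral counts: ``(intergene_len + 2)/3`` for deletions and
    ``(period + 1)/3`` for duplications, so neutral duplications are on
    average larger than neutral deletions whenever genes are longer than one
    base (``zc > g``).
    """
    il = arch.intergene_len
    if mtype is MutationType.DELETION:
        if il <= 0:
            raise ArchitectureError("no neutral deletions exist (znc = 0)")
        return (il + 2.0) / 3.0
    if mtype is MutationType.DUPLICATION:
        if arch.period <= 1:
            raise ArchitectureError("no neutral duplications exist (period <= 1)")
        return (arch.period + 1.0) / 3.0
    if mtype is MutationType.INDEL_PLUS:
        if lm is None:
            raise ArchitectureError("lm required for indel mean size")
        return (lm + 1.0) / 2.0
    if mtype is MutationType.INDEL_MINUS:
        if lm is None:
            raise ArchitectureError("lm required for indel mean size")
        if il <= 0:
            raise ArchitectureError("no neutral indel deletions exist (znc = 0)")
        # weights (il - j + 1) for j = 1..min(lm, ceil(il))
        num = 0.0
        den = 0.0
        j = 1
        while j <= lm and il - j + 1.0 > 0.0:
            w = il - j + 1.0
            num += w * j
            den += w
            j += 1
        return num / den
    raise ArchitectureError(f"mean neutral size undefined for {mtype}")


# ---------------------------------------------------------------------------
# Discrete event classification (enumerable architectures)
# ---------------------------------------------------------------------------

def _unit_offset(arch: GenomeArchitecture, pos: int) -> int:
    """Offset of base ``pos`` within its gene+intergene unit."""
    return pos % int(arch.period)


def is_coding(arch: GenomeArchitecture, pos: int) -> bool:
    """True iff base ``pos`` is coding (genes occupy the first ``gene_len``
    bases of each unit, promoter at offset 0)."""
    arch.require_enumerable()
    return _unit_offset(arch, pos) < int(arch.gene_len)


def is_promoter(arch: GenomeArchitecture, pos: int) -> bool:
    arch.require_enumerable()
    return _unit_offset(arch, pos) == 0


def junction_inside_gene(arch: GenomeArchitecture, j: int) -> bool:
    """True iff junction ``j`` (the gap before base ``j``) lies strictly
    inside a gene, i.e. both flanking bases belong to the same gene."""
    arch.require_enumerable()
    o = _unit_offset(arch, j)
    return 1 <= o <= int(arch.gene_len) - 1


def _promoter_free_run(arch: GenomeArchitecture, start: int) -> int:
    """Largest segment size starting at ``start`` that contains no promoter."""
    o = _unit_offset(arch, start)
    period = int(arch.period)
    return 0 if o == 0 else period - o


def _noncoding_run(arch: GenomeArchitecture, start: int) -> int:
    """Number of consecutive noncoding bases starting at ``start`` (0 if the
    start base is coding)."""
    o = _unit_offset(arch, start)
    gene_len = int(arch.gene_len)
    if o < gene_len:
        return 0
    return int(arch.period) - o


def classify_event(arch: GenomeArchitecture, event: MutationEvent) -> bool:
    """Deterministic lethal/neutral classification of a concrete event.

    Deletions are lethal iff any removed base is coding; duplications iff the
    copied segment contains a promoter or the insertion junction lies
    strictly inside a gene; insertions iff the junction is strictly inside a
    gene; point mutations iff the target base is coding; inversions iff
    either breakpoint junction is strictly inside a gene (genes inside a
    neutral inverted segment are assumed re-orientable without effect).
    """
    arch.require_enumerable()
    L = int(arch.L)
    if not 0 <= event.start < L:
        raise ArchitectureError(f"start {event.start} out of range [0, {L})")

    t = event.type
    if t is MutationType.POINT:
        return not is_coding(arch, event.start)

    if t in (MutationType.DELETION, MutationType.INDEL_MINUS):
        if not 1 <= event.size <= L:
            raise ArchitectureError(f"deletion size {event.size} out of range")
        return event.size <= _noncoding_run(arch, event.start)

    if t is MutationType.INDEL_PLUS:
        return not junction_inside_gene(arch, event.start)

    if t is MutationType.INVERSION:
        j2 = (event.start + event.size) % L
        return not junction_inside_gene(arch, event.start) and not junction_inside_gene(
            arch, j2
        )

    if t is MutationType.DUPLICATION:
        if event.insertion_point is None:
            raise ArchitectureError("duplication requires an insertion_point")
        if not 0 <= event.insertion_point < L:
            raise ArchitectureError(
                f"insertion_point {event.insertion_point} out of range [0, {L})"
            )
        if not 1 <= event.size <= L:
            raise ArchitectureError(f"duplication size {event.size} out of range")
        segment_ok = event.size <= _promoter_free_run(arch, event.start)
        junction_ok = not junction_inside_gene(arch, event.insertion_point)
        return segment_ok and junction_ok

    raise ArchitectureError(f"unknown mutation type: {t}")
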