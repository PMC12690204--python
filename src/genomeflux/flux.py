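"""Expected fixed-length fluxes and the duplication/deletion bias B.

Under the origination-fixation approximation (one mutant at a time, no
clonal interference), each mutation type contributes an expected number of
fixed base pairs per generation per mutation event::

    delta_dupl = g (znc+g)/L^3 * sum_{j=1..period-1} (period - j) * j * Pfix(+j)
    delta_del  = g/L^2         * sum_{j=1..il}       (il - j + 1)  * j * Pfix(-j)
    delta_ind+ = (znc+g)/(L lm) * sum_{j=1..lm}                    j * Pfix(+j)
    delta_ind- = g/(L lm)      * sum_{j=1..min(lm,il)} (il - j + 1) * j * Pfix(-j)

with ``il = znc/g`` the intergenic tract length.  The bias towards shrinking
is the ratio of deletion to insertion flux, weighted by the per-type
origination rates (the common ``mu L N`` factors cancel)::

    B = (lambda_del delta_del + lambda_ind- delta_ind-)
        / (lambda_dupl delta_dupl + lambda_ind+ delta_ind+)

``B > 1`` means the noncoding genome shrinks, ``B < 1`` that it grows;
``B = 1`` defines the equilibrium noncoding size.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .architecture import (
    ArchitectureError,
    GenomeArchitecture,
    MutationRates,
    MutationType,
    PopulationParams,
)
from . import fitness as _fitness


class ModelVariant(str, enum.Enum):
    """Which size-changing mutation types enter the flux balance."""

    STRUCTURAL_ONLY = "structural_only"
    EXPANDED = "expanded"
    INDEL_ONLY = "indel_only"
    AUTO = "auto"


def _variant_types(
    variant: ModelVariant, rates: MutationRates
) -> Tuple[MutationType, ...]:
    """Mutation types active in the effective fitness for a model variant."""
    if variant is ModelVariant.STRUCTURAL_ONLY:
        return (MutationType.DUPLICATION, MutationType.DELETION)
    if variant is ModelVariant.INDEL_ONLY:
        return (MutationType.INDEL_PLUS, MutationType.INDEL_MINUS)
    if variant is ModelVariant.EXPANDED:
        return tuple(MutationType)
    return rates.active_types()


def _flux_types(
    variant: ModelVariant, rates: MutationRates
) -> Tuple[MutationType, ...]:
    """Size-changing types whose deltas enter B."""
    fe_types = _variant_types(variant, rates)
    size_changing = (
        MutationType.DUPLICATION,
        MutationType.DELETION,
        MutationType.INDEL_PLUS,
        MutationType.INDEL_MINUS,
    )
    return tuple(t for t in size_changing if t in fe_types and rates.lam(t) > 0)


@dataclass(frozen=True)
class FluxResult:
    """Per-type fixed-length fluxes, the bias B and its regime."""

    delta_dupl: float
    delta_del: float
    delta_indel_plus: float
    delta_indel_minus: float
    bias_B: float
    regime: str  # growing | shrinking | at_equilibrium

    @staticmethod
    def classify_regime(B: float, tol: float = 1e-9) -> str:
        if abs(B - 1.0) <= tol:
            return "at_equilibrium"
        return "shrinking" if B > 1.0 else "growing"


def _auto_pfix_method(arch: GenomeArchitecture, n_j: int) -> str:
    # exact per-j pairing is O(n_j * (il + period)); fall back to the series
    # engine (relative error O((lambda*mu)^3)) beyond desk scale
    return "exact" if n_j * (arch.intergene_len + arch.period) <= 2e5 else "series"


#: block size for the j-sums; keeps memory bounded at very large genomes
_CHUNK = 1 << 22


def _weighted_pfix_sum(
    arch: GenomeArchitecture,
    rates: MutationRates,
    pop: PopulationParams,
    jmax: int,
    sign: float,
    weight_fn,
    fe_types: Sequence[MutationType],
    method: Optional[str],
) -> float:
    """``sum_{j=1..jmax} weight(j) * j * Pfix(sign*j)`` evaluated in blocks."""
    if method is None or method == "auto":
        method = _auto_pfix_method(arch, jmax)
    total = 0.0
    for lo in range(1, jmax + 1, _CHUNK):
        j = np.arange(lo, min(lo + _CHUNK, jmax + 1), dtype=float)
        w = weight_fn(j)
        pf = _fitness.fixation_probabilities(
            arch, rates, pop, sign * j, types=fe_types, method=method
        )
        total += float(np.sum(w * j * pf))
    return total


def _pfix(
    arch: GenomeArchitecture,
    rates: MutationRates,
    pop: PopulationParams,
    ks: np.ndarray,
    fe_types: Sequence[MutationType],
    method: Optional[str],
) -> np.ndarray:
    if method is None or method == "auto":
        method = _auto_pfix_method(arch, len(ks))
    return _fitness.fixation_probabilities(
        arch, rates, pop, ks, types=fe_types, method=method
    )


def delta_duplication(
    arch: GenomeArchitecture,
    rates: MutationRates,
    pop: PopulationParams,
    fe_types: Optional[Sequence[MutationType]] = None,
    pfix_method: Optional[str] = "auto",
) -> float:
    """Expected fixed bp per generation per mutation event for duplications."""
    P = arch.period
    if P <= 1:
        return 0.0
    jmax = math.ceil(P) - 1
    if fe_types is None:
        fe_types = rates.active_types()
    s = _weighted_pfix_sum(
        arch, rates, pop, jmax, +1.0,
        lambda j: np.clip(P - j, 0.0, None), fe_types, pfix_method,
    )
    L = arch.L
    return arch.g * (arch.znc + arch.g) / (L ** 3) * s


def delta_deletion(
    arch: GenomeArchitecture,
    rates: MutationRates,
    pop: PopulationParams,
    fe_types: Optional[Sequence[MutationType]] = None,
    pfix_method: Optional[str] = "auto",
) -> float:
    """Expected fixed bp per generation per mutation event for deletions."""
    il = arch.intergene_len
    if il <= 0:
        return 0.0
    jmax = math.ceil(il)
    if fe_types is None:
        fe_types = rates.active_types()
    s = _weighted_pfix_sum(
        arch, rates, pop, jmax, -1.0,
        lambda j: np.clip(il - j + 1.0, 0.0, None), fe_types, pfix_method,
    )
    L = arch.L
    return arch.g / (L ** 2) * s


def delta_indels(
    arch: GenomeArchitecture,
    rates: MutationRates,
    pop: PopulationParams,
    fe_types: Optional[Sequence[MutationType]] = None,
    pfix_method: Optional[str] = "auto",
) -> Tuple[float, float]:
    """Expected fixed bp fluxes ``(delta_indel+, delta_indel-)``."""
    lm = rates.lm
    L = arch.L
    il = arch.intergene_len
    if fe_types is None:
        fe_types = rates.active_types()

    j_plus = np.arange(1, lm + 1, dtype=float)
    pf_plus = _pfix(arch, rates, pop, j_plus, fe_types, pfix_method)
    d_plus = float((arch.znc + arch.g) / (L * lm) * np.sum(j_plus * pf_plus))

    if il <= 0:
        return d_plus, 0.0
    jmax = math.ceil(min(float(lm), il))
    j_minus = np.arange(1, jmax + 1, dtype=float)
    w = np.clip(il - j_minus + 1.0, 0.0, None)
    pf_minus = _pfix(arch, rates, pop, -j_minus, fe_types, pfix_method)
    d_minus = float(arch.g / (L * lm) * np.sum(w * j_minus * pf_minus))
    return d_plus, d_minus


def bias(
    arch: GenomeArchitecture,
    rates: MutationRates,
    pop: PopulationParams,
    model: ModelVariant | str = ModelVariant.AUTO,
    pfix_method: Optional[str] = "auto",
    regime_tol: float = 1e-9,
) -> FluxResult:
    """Bias ``B`` = rate-weighted deletion flux over insertion flux.

    ``model`` selects which size-changing types enter both the flux balance
    and the effective fitness: ``structural_only`` (duplications/deletions),
    ``indel_only``, ``expanded`` (all six types), or ``auto`` (every type
    with a nonzero rate multiplier).  The ``mu L N`` origination factors
    cancel between numerator and denominator.
    """
    variant = ModelVariant(model)
    fe_types = _variant_types(variant, rates)
    flux_types = _flux_types(variant, rates)
    if not flux_types:
        raise ArchitectureError(f"no active size-changing mutation types for {variant}")

    d_dupl = d_del = d_plus = d_minus = 0.0
    if MutationType.DUPLICATION in flux_types:
        d_dupl = delta_duplication(arch, rates, pop, fe_types, pfix_method)
    if MutationType.DELETION in flux_types:
        d_del = delta_deletion(arch, rates, pop, fe_types, pfix_method)
    if MutationType.INDEL_PLUS in flux_types or MutationType.INDEL_MINUS in flux_types:
        d_plus, d_minus = delta_indels(arch, rates, pop, fe_types, pfix_method)
        if MutationType.INDEL_PLUS not in flux_types:
            d_plus = 0.0
        if MutationType.INDEL_MINUS not in flux_types:
            d_minus = 0.0

    num = 0.0
    den = 0.0
    if MutationType.DELETION in flux_types:
        num += rates.lambda_del * d_del
    if MutationType.INDEL_MINUS in flux_types:
        num += rates.lambda_indel_minus * d_minus
    if MutationType.DUPLICATION in flux_types:
        den += rates.lambda_dupl * d_dupl
    if MutationType.INDEL_PLUS in flux_types:
        den += rates.lambda_indel_plus * d_plus
    if den <= 0.0:
        raise ArchitectureError(
            "insertion flux is zero: bias undefined (no possible insertions)"
        )
    B = num / den
    return FluxResult(
        delta_dupl=d_dupl,
        delta_del=d_del,
        delta_indel_plus=d_plus,
        delta_indel_minus=d_minus,
        bias_B=B,
        regime=FluxResult.classify_regime(B, regime_tol),
    )
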