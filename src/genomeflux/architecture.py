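"""Idealized circular genome architecture and mutation-rate parameters.

The genome model is a circular haploid chromosome of length ``L = zc + znc``
base pairs carrying ``g`` identical, equally spaced genes.  Each gene occupies
``zc/g`` contiguous bases, starts with a one-base promoter, and is followed by
an intergenic (noncoding) tract of ``znc/g`` bases.  The repeating
gene+intergene unit has length ``period = L/g``.  Only the three integers
(or, in analytic mode, reals) ``g``, ``zc``, ``znc`` are needed to describe a
genome; there are no nucleotides, only segment arithmetic.

Two usage modes coexist:

* *enumerable* mode — ``g`` divides ``zc`` and ``znc`` exactly and every
  length is an integer, so mutation events can be enumerated exhaustively;
* *analytic* mode — ``znc`` may be any nonnegative real, and the closed-form
  neutrality/flux polynomials are evaluated directly (the continuous
  continuation of the integer counting formulas).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Optional


class MutationType(str, enum.Enum):
    """The six mutation types of the model.

    Duplications, deletions and inversions are structural: their breakpoints
    are uniform over the genome, so their size scales with genome length.
    Small insertions/deletions (indels) have size uniform on ``1..lm``.
    Point mutations hit a single base.
    """

    DUPLICATION = "duplication"
    DELETION = "deletion"
    INVERSION = "inversion"
    POINT = "point"
    INDEL_PLUS = "indel_plus"
    INDEL_MINUS = "indel_minus"


#: Mutation types that change the noncoding size.
SIZE_CHANGING_TYPES = (
    MutationType.DUPLICATION,
    MutationType.DELETION,
    MutationType.INDEL_PLUS,
    MutationType.INDEL_MINUS,
)

STRUCTURAL_TYPES = (MutationType.DUPLICATION, MutationType.DELETION)
INDEL_TYPES = (MutationType.INDEL_PLUS, MutationType.INDEL_MINUS)


class ArchitectureError(ValueError):
    """Raised for an invalid genome architecture or rate configuration."""


@dataclass(frozen=True)
class GenomeArchitecture:
    """Coding/noncoding layout of the idealized circular genome.

    Parameters
    ----------
    g : int
        Number of genes (and of intergenic tracts), ``g >= 1``.
    zc : float
        Total coding length in bp; ``zc >= g`` so each gene holds at least
        its promoter base.
    znc : float
        Total noncoding length in bp, ``znc >= 0``.  May be non-integer in
        analytic mode.
    """

    g: int
    zc: float
    znc: float

    def __post_init__(self) -> None:
        if self.g < 1 or int(self.g) != self.g:
            raise ArchitectureError(f"g must be a positive integer, got {self.g}")
        if self.zc < self.g:
            raise ArchitectureError(
                f"zc must be >= g (one promoter base per gene), got zc={self.zc}, g={self.g}"
            )
        if self.znc < 0:
            raise ArchitectureError(f"znc must be nonnegative, got {self.znc}")

    @property
    def L(self) -> float:
        """Total genome length ``zc + znc`` (bp)."""
        return self.zc + self.znc

    @property
    def period(self) -> float:
        """Length ``L/g`` of one gene+intergene repeating unit (bp)."""
        return self.L / self.g

    @property
    def gene_len(self) -> float:
        """Length ``zc/g`` of one gene (bp)."""
        return self.zc / self.g

    @property
    def intergene_len(self) -> float:
        """Length ``znc/g`` of one intergenic tract (bp)."""
        return self.znc / self.g

    @property
    def enumerable(self) -> bool:
        """True when all segment lengths are integers (g | zc and g | znc)."""
        return (
            float(self.zc).is_integer()
            and float(self.znc).is_integer()
            and int(self.zc) % self.g == 0
            and int(self.znc) % self.g == 0
        )

    def require_enumerable(self) -> None:
        if not self.enumerable:
            raise ArchitectureError(
                f"architecture (g={self.g}, zc={self.zc}, znc={self.znc}) is not "
                "enumerable: g must divide zc and znc exactly"
            )

    def with_znc(self, znc: float) -> "GenomeArchitecture":
        """Return a copy with a different noncoding size (coding layout fixed)."""
        return replace(self, znc=znc)

    @property
    def noncoding_fraction(self) -> float:
        """``znc / L``."""
        return self.znc / self.L


@dataclass(frozen=True)
class MutationRates:
    """Per-base, per-type mutation rates.

    ``mu`` is the basal per-base per-generation probability that a mutation of
    a given type initiates at a base; type ``i`` occurs at rate
    ``lambda_i * mu``.  Types with ``lambda_i == 0`` are absent from the
    model.  The default configuration is the two-type structural model
    (duplications and deletions at equal rate, nothing else).

    ``lm`` is the maximum indel size: indel sizes are uniform on ``1..lm``.
    """

    mu: float
    lambda_dupl: float = 1.0
    lambda_del: float = 1.0
    lambda_inv: float = 0.0
    lambda_pm: float = 0.0
    lambda_indel_plus: float = 0.0
    lambda_indel_minus: float = 0.0
    lm: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu < 1.0:
            raise ArchitectureError(f"mu must satisfy 0 <= mu < 1, got {self.mu}")
        for name in (
            "lambda_dupl",
            "lambda_del",
            "lambda_inv",
            "lambda_pm",
            "lambda_indel_plus",
            "lambda_indel_minus",
        ):
            if getattr(self, name) < 0:
                raise ArchitectureError(f"{name} must be nonnegative")
        if self.lm < 1:
            raise ArchitectureError(f"lm must be >= 1, got {self.lm}")

    @classmethod
    def from_kappa(
        cls,
        mu: float,
        kappa: float,
        lm: int = 50,
        lambda_pm: float = 1.0,
        lambda_inv: float = 1.0,
    ) -> "MutationRates":
        """Build the six-type rate set from the deletion bias ``kappa``.

        The deletion bias is ``kappa = lambda_del/lambda_dupl =
        lambda_indel-/lambda_indel+`` with ``lambda_del = lambda_indel-``,
        ``lambda_dupl = lambda_indel+`` and the four size-changing multipliers
        summing to 4, so::

            lambda_del = lambda_indel- = 2*kappa / (1 + kappa)
            lambda_dupl = lambda_indel+ = 2 / (1 + kappa)
        """
        if kappa <= 0:
            raise ArchitectureError(f"kappa must be positive, got {kappa}")
        lam_minus = 2.0 * kappa / (1.0 + kappa)
        lam_plus = 2.0 / (1.0 + kappa)
        return cls(
            mu=mu,
            lambda_dupl=lam_plus,
            lambda_del=lam_minus,
            lambda_inv=lambda_inv,
            lambda_pm=lambda_pm,
            lambda_indel_plus=lam_plus,
            lambda_indel_minus=lam_minus,
            lm=lm,
        )

    def lam(self, mtype: MutationType) -> float:
        """Rate multiplier for a mutation type."""
        return {
            MutationType.DUPLICATION: self.lambda_dupl,
            MutationType.DELETION: self.lambda_del,
            MutationType.INVERSION: self.lambda_inv,
            MutationType.POINT: self.lambda_pm,
            MutationType.INDEL_PLUS: self.lambda_indel_plus,
            MutationType.INDEL_MINUS: self.lambda_indel_minus,
        }[mtype]

    @property
    def kappa(self) -> float:
        """Deletion bias ``lambda_del / lambda_dupl``."""
        if self.lambda_dupl == 0:
            raise ArchitectureError("kappa undefined: lambda_dupl is zero")
        return self.lambda_del / self.lambda_dupl

    def active_types(self) -> tuple[MutationType, ...]:
        """Mutation types with a nonzero rate multiplier."""
        return tuple(t for t in MutationType if self.lam(t) > 0)


@dataclass(frozen=True)
class PopulationParams:
    """Population size for the Wright-Fisher fixation calculation.

    ``N`` may be real-valued in analytic formulas; simulation code requires an
    integer.  The compound parameter ``N*mu`` is the main driver of the
    equilibrium noncoding fraction.
    """

    N: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ArchitectureError(f"N must be >= 1, got {self.N}")


@dataclass(frozen=True)
class MutationEvent:
    """A concrete mutation event on an enumerable architecture.

    Coordinates are 0-based on the circular genome.  ``start`` is a base
    index for deletions, point mutations and indel deletions, the first base
    of the copied segment for duplications, and the first breakpoint junction
    for inversions.  Junctions are identified with the ``L`` inter-base
    positions: junction ``j`` sits immediately before base ``j``.

    ``size`` is 0 for point mutations; the signed effect on ``znc`` of a
    neutral event is ``+size`` for duplications/insertions and ``-size`` for
    deletions.  Inversions use ``size`` to locate the second breakpoint at
    ``(start + size) mod L``.
    """

    type: MutationType
    start: int
    size: int = 0
    insertion_point: Optional[int] = None

    def signed_size_effect(self) -> int:
        """Signed change in znc if this event is neutral."""
        if self.type in (MutationType.DUPLICATION, MutationType.INDEL_PLUS):
            return self.size
        if self.type in (MutationType.DELETION, MutationType.INDEL_MINUS):
            return -self.size
        return 0
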