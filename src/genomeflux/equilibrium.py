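"""Equilibrium noncoding genome size: the root of B(znc) = 1.

The bias B is monotone nondecreasing in the noncoding size over the search
bracket (small genomes grow, large genomes shrink), so the equilibrium is
found by bisection on ``log10(znc)``.  The default bracket ``[1e3, 1e9]``
covers the parameter sweeps of the two-type and six-type analyses; it can be
widened, or expanded automatically, for extreme deletion biases or very
small ``N*mu``.

When no sign change exists in the bracket — notably in the indel-only model,
whose bias stays below 1 for every noncoding size — the solver reports a
non-converged result rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .architecture import (
    ArchitectureError,
    GenomeArchitecture,
    MutationRates,
    PopulationParams,
)
from .flux import ModelVariant, bias

#: Column order of the tabular outputs.
TABLE_COLUMNS = (
    "N",
    "mu",
    "N_mu",
    "kappa",
    "g",
    "zc",
    "znc_star",
    "fraction_star",
    "bias_residual",
    "converged",
)


@dataclass(frozen=True)
class EquilibriumResult:
    """Equilibrium noncoding size with solver diagnostics."""

    znc_star: Optional[float]
    fraction_star: Optional[float]
    bias_at_root: Optional[float]
    iterations: int
    bracket: Tuple[float, float]
    converged: bool
    message: str = ""


def _bias_value(
    zc: float,
    g: int,
    rates: MutationRates,
    pop: PopulationParams,
    znc: float,
    model: ModelVariant | str,
    pfix_method: Optional[str],
) -> float:
    arch = GenomeArchitecture(g=g, zc=zc, znc=znc)
    return bias(arch, rates, pop, model=model, pfix_method=pfix_method).bias_B


def equilibrium_noncoding(
    zc: float,
    g: int,
    rates: MutationRates,
    pop: PopulationParams,
    model: ModelVariant | str = ModelVariant.AUTO,
    bracket: Tuple[float, float] = (1e3, 1e9),
    tolerance: float = 1e-6,
    pfix_method: Optional[str] = "auto",
    expand_bracket: bool = False,
    max_bracket: Tuple[float, float] = (1e0, 1e11),
    check_monotone: bool = True,
    monotone_points: int = 5,
) -> EquilibriumResult:
    """Solve ``B(znc) = 1`` by bisection on ``log10(znc)``.

    ``tolerance`` is relative on ``znc``.  A sign change of ``B - 1`` across
    the bracket is verified before iterating; with ``expand_bracket`` the
    bracket is widened geometrically (up to ``max_bracket``) until a sign
    change appears.  Absent a sign change the result reports
    ``converged=False`` with the boundary biases in ``message``.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ArchitectureError(f"invalid bracket {bracket}")

    def h(z: float) -> float:
        return _bias_value(zc, g, rates, pop, z, model, pfix_method) - 1.0

    h_lo, h_hi = h(lo), h(hi)
    evals = 2
    while h_lo * h_hi > 0 and expand_bracket:
        grew = False
        if h_lo > 0 and lo > max_bracket[0]:  # root below bracket
            lo = max(lo / 100.0, max_bracket[0])
            h_lo = h(lo)
            evals += 1
            grew = True
        elif h_hi < 0 and hi < max_bracket[1]:  # root above bracket
            hi = min(hi * 100.0, max_bracket[1])
            h_hi = h(hi)
            evals += 1
            grew = True
        if not grew:
            break

    if h_lo * h_hi > 0:
        return EquilibriumResult(
            znc_star=None,
            fraction_star=None,
            bias_at_root=None,
            iterations=evals,
            bracket=(lo, hi),
            converged=False,
            message=(
                "no equilibrium in bracket: "
                f"B({lo:.6g}) = {h_lo + 1.0:.6g}, B({hi:.6g}) = {h_hi + 1.0:.6g}"
            ),
        )

    if check_monotone:
        grid = np.logspace(math.log10(lo), math.log10(hi), monotone_points)
        vals = [h(z) for z in grid]
        evals += monotone_points
        diffs = np.diff(vals)
        if np.any(diffs < -1e-9 * np.maximum(1.0, np.abs(np.array(vals)[:-1]))):
            raise ArchitectureError(
                "bias is not monotone nondecreasing over the bracket; "
                "bisection is not applicable"
            )

    # bisection on log10(znc)
    llo, lhi = math.log10(lo), math.log10(hi)
    iterations = 0
    while 10.0 ** lhi / 10.0 ** llo - 1.0 > tolerance:
        mid = 0.5 * (llo + lhi)
        hm = h(10.0 ** mid)
        iterations += 1
        if hm * h_lo <= 0:
            lhi = mid
        else:
            llo = mid
            h_lo = hm
        if iterations > 200:
            break
    znc_star = 10.0 ** (0.5 * (llo + lhi))
    B_root = h(znc_star) + 1.0
    return EquilibriumResult(
        znc_star=znc_star,
        fraction_star=znc_star / (znc_star + zc),
        bias_at_root=B_root,
        iterations=iterations,
        bracket=(lo, hi),
        converged=True,
        message="",
    )


def equilibrium_curve(
    zc: float,
    g: int,
    n_mu_values: Sequence[float],
    kappas: Sequence[float],
    mu_ref: float = 1e-9,
    lm: int = 50,
    lambda_pm: float = 1.0,
    lambda_inv: float = 1.0,
    model: ModelVariant | str = ModelVariant.EXPANDED,
    bracket: Tuple[float, float] = (1e3, 1e9),
    tolerance: float = 1e-6,
    expand_bracket: bool = True,
) -> pd.DataFrame:
    """Equilibrium noncoding fraction over a grid of ``N*mu`` and ``kappa``.

    Each compound value is realised as ``mu = mu_ref`` and ``N = N_mu /
    mu_ref`` (B depends on N and mu essentially through their product).  One
    row per (N*mu, kappa); solver failures are recorded per row, not fatal.
    """
    rows = []
    for kappa in kappas:
        rates = MutationRates.from_kappa(
            mu=mu_ref, kappa=kappa, lm=lm, lambda_pm=lambda_pm, lambda_inv=lambda_inv
        )
        for n_mu in n_mu_values:
            N = max(n_mu / mu_ref, 1.0)
            pop = PopulationParams(N=N)
            res = equilibrium_noncoding(
                zc,
                g,
                rates,
                pop,
                model=model,
                bracket=bracket,
                tolerance=tolerance,
                expand_bracket=expand_bracket,
            )
            rows.append(
                {
                    "N": N,
                    "mu": mu_ref,
                    "N_mu": n_mu,
                    "kappa": kappa,
                    "g": g,
                    "zc": zc,
                    "znc_star": res.znc_star if res.converged else float("nan"),
                    "fraction_star": res.fraction_star if res.converged else float("nan"),
                    "bias_residual": (res.bias_at_root - 1.0) if res.converged else float("nan"),
                    "converged": res.converged,
                }
            )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def gene_number_sensitivity(
    gene_len: float,
    g_values: Sequence[int],
    rates: MutationRates,
    pop: PopulationParams,
    model: ModelVariant | str = ModelVariant.AUTO,
    bracket: Tuple[float, float] = (1e3, 1e9),
    tolerance: float = 1e-6,
    expand_bracket: bool = True,
) -> Tuple[pd.DataFrame, float]:
    """Equilibrium fraction for several gene numbers at fixed gene length.

    ``g`` and ``zc = g * gene_len`` are covaried so the coding architecture
    keeps a constant gene size.  Returns the per-``g`` table and the maximum
    relative spread of the equilibrium fraction across the grid.
    """
    rows = []
    for g in g_values:
        zc = g * gene_len
        res = equilibrium_noncoding(
            zc,
            g,
            rates,
            pop,
            model=model,
            bracket=bracket,
            tolerance=tolerance,
            expand_bracket=expand_bracket,
        )
        rows.append(
            {
                "N": pop.N,
                "mu": rates.mu,
                "N_mu": pop.N * rates.mu,
                "kappa": rates.kappa if rates.lambda_dupl > 0 else float("nan"),
                "g": g,
                "zc": zc,
                "znc_star": res.znc_star if res.converged else float("nan"),
                "fraction_star": res.fraction_star if res.converged else float("nan"),
                "bias_residual": (res.bias_at_root - 1.0) if res.converged else float("nan"),
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    fracs = table["fraction_star"].dropna()
    if len(fracs) <= 1:
        spread = 0.0
    else:
        spread = float((fracs.max() - fracs.min()) / fracs.mean())
    return table, spread
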