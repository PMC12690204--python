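"""Species tables: observed noncoding fractions vs model predictions.

The model predicts that the equilibrium noncoding fraction of a species is a
function of ``Ne * mu`` (with ``mu`` the structural mutation rate), the
deletion bias ``kappa`` and the coding architecture.  This module reads a
tab-separated species table (species, Ne, mu, noncoding_fraction, optionally
zc and g), overlays the model prediction at each species' compound
parameter, and synthesizes realistic fixture tables so no external data
download is ever needed.

Structural mutation rates are unobservable in practice; following the
standard convention the per-base structural rate is taken as a fixed ratio
(default 1:1) of the substitution rate reported in the table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .architecture import ArchitectureError, MutationRates, PopulationParams
from .equilibrium import equilibrium_noncoding
from .flux import ModelVariant

REQUIRED_COLUMNS = ("species", "Ne", "mu", "noncoding_fraction")
OPTIONAL_COLUMNS = ("zc", "g")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species' population-genetic summary."""

    species: str
    Ne: float
    mu: float
    noncoding_fraction: float
    zc: Optional[float] = None
    g: Optional[int] = None

    def __post_init__(self) -> None:
        if self.Ne <= 0:
            raise ArchitectureError(f"{self.species}: Ne must be positive")
        if self.mu <= 0:
            raise ArchitectureError(f"{self.species}: mu must be positive")
        if not 0.0 <= self.noncoding_fraction <= 1.0:
            raise ArchitectureError(
                f"{self.species}: noncoding_fraction must be in [0, 1]"
            )


class SpeciesTableError(ValueError):
    """Malformed species table, with row-level diagnostics."""


def read_species_table(path: str | Path) -> List[SpeciesRecord]:
    """Read a tab-separated species table with a header row.

    Required columns: species, Ne, mu, noncoding_fraction; optional: zc, g.
    Malformed rows raise :class:`SpeciesTableError` with the line number.
    """
    path = Path(path)
    lines = [
        ln
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise SpeciesTableError(f"{path}: empty table")
    header = lines[0].split("\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SpeciesTableError(f"{path}: missing required columns {missing}")
    idx = {c: header.index(c) for c in header}
    records = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise SpeciesTableError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        try:
            rec = SpeciesRecord(
                species=cells[idx["species"]],
                Ne=float(cells[idx["Ne"]]),
                mu=float(cells[idx["mu"]]),
                noncoding_fraction=float(cells[idx["noncoding_fraction"]]),
                zc=float(cells[idx["zc"]]) if "zc" in idx and cells[idx["zc"]] else None,
                g=int(cells[idx["g"]]) if "g" in idx and cells[idx["g"]] else None,
            )
        except (ValueError, ArchitectureError) as exc:
            raise SpeciesTableError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_species_table(records: Sequence[SpeciesRecord], path: str | Path) -> None:
    """Write records as TSV (lossless round-trip with the reader)."""
    path = Path(path)
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    out = ["\t".join(cols)]
    for r in records:
        out.append(
            "\t".join(
                [
                    r.species,
                    repr(r.Ne),
                    repr(r.mu),
                    repr(r.noncoding_fraction),
                    "" if r.zc is None else repr(r.zc),
                    "" if r.g is None else str(r.g),
                ]
            )
        )
    path.write_text("\n".join(out) + "\n")


def predict_fraction(
    n_mu: float,
    kappa: float = 1.0,
    zc: float = 1e6,
    g: int = 2000,
    lm: int = 50,
    mu_ref: float = 1e-9,
    tolerance: float = 1e-6,
) -> float:
    """Equilibrium noncoding fraction of the six-type model at ``Ne*mu``."""
    rates = MutationRates.from_kappa(mu=mu_ref, kappa=kappa, lm=lm)
    pop = PopulationParams(N=max(n_mu / mu_ref, 1.0))
    res = equilibrium_noncoding(
        zc,
        g,
        rates,
        pop,
        model=ModelVariant.EXPANDED,
        tolerance=tolerance,
        expand_bracket=True,
    )
    if not res.converged:
        raise ArchitectureError(f"no equilibrium at N*mu = {n_mu}: {res.message}")
    return res.fraction_star


def predict_overlay(
    records: Sequence[SpeciesRecord],
    kappa: float = 1.0,
    structural_point_ratio: float = 1.0,
    zc_default: float = 1e6,
    g_default: int = 2000,
    lm: int = 50,
    tolerance: float = 1e-6,
) -> pd.DataFrame:
    """Observed vs predicted noncoding fraction per species.

    The structural per-base rate is ``structural_point_ratio`` times the
    tabulated substitution rate (default 1:1).  Species-specific coding
    architecture columns are used when present, the configured defaults
    otherwise.
    """
    rows = []
    for r in records:
        n_mu = r.Ne * r.mu * structural_point_ratio
        pred = predict_fraction(
            n_mu,
            kappa=kappa,
            zc=r.zc if r.zc is not None else zc_default,
            g=r.g if r.g is not None else g_default,
            lm=lm,
            tolerance=tolerance,
        )
        rows.append(
            {
                "species": r.species,
                "Ne": r.Ne,
                "mu": r.mu,
                "N_mu": n_mu,
                "observed_fraction": r.noncoding_fraction,
                "predicted_fraction": pred,
            }
        )
    return pd.DataFrame(rows)


def generate_fixture_table(
    n_species: int,
    seed: int,
    noise: float = 0.3,
    kappa: float = 1.0,
    n_mu_range: tuple[float, float] = (1e-5, 1e-1),
    ne_range: tuple[float, float] = (1e4, 1e9),
    path: Optional[str | Path] = None,
) -> List[SpeciesRecord]:
    """Synthesize a species table around the model's own predictions.

    ``(Ne, mu)`` pairs are drawn log-uniformly so the compound ``Ne*mu``
    spans the explored range; the observed fraction is the model prediction
    perturbed by Gaussian noise of scale ``noise`` on the logit scale (so it
    stays a fraction; ``noise = 0`` reproduces the prediction exactly).
    Reproducible from the seed; optionally written to ``path``.
    """
    if n_species < 1:
        raise ArchitectureError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_species):
        n_mu = 10.0 ** rng.uniform(math.log10(n_mu_range[0]), math.log10(n_mu_range[1]))
        Ne = 10.0 ** rng.uniform(math.log10(ne_range[0]), math.log10(ne_range[1]))
        mu = n_mu / Ne
        pred = predict_fraction(n_mu, kappa=kappa)
        pred = min(max(pred, 1e-12), 1.0 - 1e-12)
        logit = math.log(pred / (1.0 - pred)) + noise * rng.standard_normal()
        obs = 1.0 / (1.0 + math.exp(-logit))
        records.append(
            SpeciesRecord(
                species=f"synthetic_{i:03d}",
                Ne=Ne,
                mu=mu,
                noncoding_fraction=obs,
            )
        )
    if path is not None:
        write_species_table(records, path)
    return records
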