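"""Run configuration: validated, serializable, hashable.

A run is fully reproducible from its configuration plus seed; every tabular
output carries the configuration hash in a leading comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .architecture import ArchitectureError, MutationRates


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a model run.

    Rates can be given either explicitly (the ``lambda_*`` fields) or in
    kappa mode (``kappa`` set), in which case the four size-changing
    multipliers are derived from the deletion bias and sum to 4.
    Defaults mirror the standard six-type parameter choice: ``g = 2000``,
    ``zc = 1e6``, ``lambda_pm = lambda_inv = 1``, ``lm = 50``.
    """

    model: str = "auto"
    g: int = 2000
    zc: float = 1e6
    znc: Optional[float] = None
    mu: float = 1e-10
    N: float = 1e8
    kappa: Optional[float] = None
    lambda_dupl: float = 1.0
    lambda_del: float = 1.0
    lambda_inv: float = 0.0
    lambda_pm: float = 0.0
    lambda_indel_plus: float = 0.0
    lambda_indel_minus: float = 0.0
    lm: int = 50
    bracket: Tuple[float, float] = (1e3, 1e9)
    tolerance: float = 1e-6
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.verbosity not in ("quiet", "info", "debug"):
            raise ArchitectureError(f"unknown verbosity {self.verbosity!r}")
        lo, hi = self.bracket
        if not 0 < lo < hi:
            raise ArchitectureError(f"invalid bracket {self.bracket}")
        self.rates()  # validate rate parameters eagerly

    def rates(self) -> MutationRates:
        if self.kappa is not None:
            return MutationRates.from_kappa(
                mu=self.mu,
                kappa=self.kappa,
                lm=self.lm,
                lambda_pm=self.lambda_pm,
                lambda_inv=self.lambda_inv,
            )
        return MutationRates(
            mu=self.mu,
            lambda_dupl=self.lambda_dupl,
            lambda_del=self.lambda_del,
            lambda_inv=self.lambda_inv,
            lambda_pm=self.lambda_pm,
            lambda_indel_plus=self.lambda_indel_plus,
            lambda_indel_minus=self.lambda_indel_minus,
            lm=self.lm,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bracket"] = list(self.bracket)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "bracket" in d:
            d["bracket"] = tuple(d["bracket"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ArchitectureError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a YAML (or JSON, a YAML subset) key/value file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ArchitectureError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Short sha256 of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)
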