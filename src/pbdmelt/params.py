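"""Model parameters for the Peyrard-Bishop-Dauxois (PBD) Hamiltonian.

The PBD model describes a DNA duplex as a 1-D chain of base-pair
stretching coordinates ``y_n`` (angstroms).  Each pair sits in an on-site
Morse well whose depth depends on the pair class (AT vs GC), and adjacent
pairs interact through an anharmonic stacking potential.  All energies
are in eV, lengths in angstroms, temperatures in kelvin.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

#: Boltzmann constant in eV/K; fixed so every module shares one unit system.
KB = 8.617333e-5


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the crowder-modified PBD model.

    Attributes
    ----------
    D_AT, D_GC : float
        Morse well depths (eV) for AT and GC base pairs.  GC pairs have
        three hydrogen bonds and are the deeper well.
    a_AT, a_GC : float
        Inverse widths of the Morse wells (1/angstrom).
    kappa : float
        Harmonic stacking stiffness (eV/angstrom^2), one value for every
        step along the chain.
    rho, b : float
        Amplitude (dimensionless) and range (1/angstrom) of the stacking
        anharmonicity ``[1 + rho * exp(-b (y_n + y_{n-1}))]`` that
        stiffens closed regions and produces sharp cooperative melting.
    m : float
        Reduced base-pair mass (amu); enters only the analytic momentum
        factor of the free energy.
    k_B : float
        Boltzmann constant (eV/K).
    y_min, y_max : float
        Integration cutoffs (angstrom) for the configurational partition
        function, which diverges on an unbounded domain.
    n_grid : int
        Number of Gauss-Legendre quadrature nodes on [y_min, y_max].
    y0 : float
        Displacement threshold (angstrom) separating closed (y < y0)
        from open (y >= y0) base pairs.
    """

    D_AT: float = 0.0395
    D_GC: float = 0.059
    a_AT: float = 4.2
    a_GC: float = 6.3
    kappa: float = 0.03
    rho: float = 2.0
    b: float = 0.35
    m: float = 300.0
    k_B: float = KB
    y_min: float = -5.0
    y_max: float = 200.0
    n_grid: int = 900
    y0: float = 2.0

    def __post_init__(self) -> None:
        for name in ("D_AT", "D_GC", "a_AT", "a_GC", "kappa", "m", "k_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (self.y_min < 0 < self.y0 < self.y_max):
            raise ValueError(
                "require y_min < 0 < y0 < y_max, got "
                f"y_min={self.y_min}, y0={self.y0}, y_max={self.y_max}"
            )
        if self.n_grid < 2:
            raise ValueError("n_grid must be >= 2")

    def depth(self, pair_class: str) -> float:
        """Unscaled Morse depth D0 (eV) for a pair class ('AT' or 'GC')."""
        return {"AT": self.D_AT, "GC": self.D_GC}[pair_class]

    def width(self, pair_class: str) -> float:
        """Morse inverse width a (1/angstrom) for a pair class."""
        return {"AT": self.a_AT, "GC": self.a_GC}[pair_class]

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short deterministic hash of the parameter set, for output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load parameters from YAML or JSON, overriding any subset of defaults."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
        return cls(**data)
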