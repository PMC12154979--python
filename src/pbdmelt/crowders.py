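"""Molecular crowders as local Morse-depth modifiers.

An inert crowder near base pair ``i`` restricts its thermal fluctuation
and stabilizes the hydrogen bond; the model represents this by scaling
the Morse depth at that site, ``D_i = alpha * D0_i`` with alpha > 1.
Crowders carry no geometry of their own — a configuration is just a list
of ``(site, alpha)`` assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement
from pathlib import Path

import numpy as np
import yaml

from .params import ModelParams
from .sequences import Duplex


@dataclass(frozen=True)
class CrowderConfig:
    """A multiset of crowder placements on a duplex.

    Parameters
    ----------
    assignments : tuple of (site, alpha)
        1-based site indices with their depth scale factors (alpha > 0;
        alpha > 1 stabilizes, alpha = 1 is a no-op).
    multiplicity_rule : {"product", "single"}
        How several crowders on one site combine: ``product`` multiplies
        their alphas (two 1.5-crowders act as 2.25); ``single`` keeps a
        single alpha per site (duplicates collapse).
    """

    assignments: tuple[tuple[int, float], ...] = ()
    multiplicity_rule: str = "product"

    def __post_init__(self) -> None:
        if self.multiplicity_rule not in ("product", "single"):
            raise ValueError(f"unknown multiplicity_rule {self.multiplicity_rule!r}")
        for site, alpha in self.assignments:
            if site < 1:
                raise ValueError(f"sites are 1-based; got {site}")
            if alpha <= 0:
                raise ValueError(f"alpha must be > 0; got {alpha} at site {site}")

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(s for s, _ in self.assignments)

    def validate(self, N: int) -> None:
        for site, _ in self.assignments:
            if site > N:
                raise ValueError(f"crowder site {site} exceeds chain length {N}")

    def effective_alphas(self, N: int) -> np.ndarray:
        """Per-site effective scale factor, length N (1.0 where uncrowded)."""
        self.validate(N)
        alphas = np.ones(N)
        if self.multiplicity_rule == "product":
            for site, alpha in self.assignments:
                alphas[site - 1] *= alpha
        else:  # single: last assignment wins; duplicates collapse to one alpha
            for site, alpha in self.assignments:
                alphas[site - 1] = alpha
        return alphas

    def describe(self) -> str:
        if not self.assignments:
            return "no crowders"
        return ",".join(f"{s}:{a:g}" for s, a in self.assignments)


def parse_crowder_spec(spec: str, multiplicity_rule: str = "product") -> CrowderConfig:
    """Parse the CLI syntax ``site:alpha[,site:alpha...]``."""
    if not spec.strip():
        return CrowderConfig()
    assignments = []
    for i, token in enumerate(spec.split(","), start=1):
        try:
            site_str, alpha_str = token.split(":")
            assignments.append((int(site_str), float(alpha_str)))
        except ValueError:
            raise ValueError(
                f"bad crowder token {token!r} (entry {i}); expected site:alpha"
            ) from None
    return CrowderConfig(tuple(assignments), multiplicity_rule=multiplicity_rule)


def load_crowder_config(path: str | Path) -> CrowderConfig:
    """Read a crowder configuration from YAML/JSON.

    Expected layout::

        crowders:
          - {site: 2, alpha: 1.5}
          - {site: 7, alpha: 1.5}
        multiplicity_rule: product   # optional
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "crowders" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'crowders' list")
    assignments = tuple(
        (int(entry["site"]), float(entry["alpha"])) for entry in data["crowders"]
    )
    rule = data.get("multiplicity_rule", "product")
    return CrowderConfig(assignments, multiplicity_rule=rule)


def save_crowder_config(config: CrowderConfig, path: str | Path) -> None:
    data = {
        "crowders": [{"site": s, "alpha": a} for s, a in config.assignments],
        "multiplicity_rule": config.multiplicity_rule,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def enumerate_crowder_configs(
    N: int, k: int, alpha: float = 1.5, allow_repeats: bool = False
) -> list[CrowderConfig]:
    """All distinct placements of ``k`` identical crowders on ``N`` sites.

    Identical crowders make placements unordered, so without repeats the
    configurations are the k-element site subsets (``C(N, k)`` of them;
    56 for k=3 on an 8-mer) and with repeats the k-multisets.  The list
    is lexicographically ordered by site tuple and duplicate-free.
    """
    if N < 1 or k < 1:
        raise ValueError("need N >= 1 and k >= 1")
    if not allow_repeats and k > N:
        raise ValueError(f"cannot place {k} crowders on {N} sites without repeats")
    chooser = combinations_with_replacement if allow_repeats else combinations
    return [
        CrowderConfig(tuple((site, alpha) for site in sites))
        for sites in chooser(range(1, N + 1), k)
    ]


def effective_depths(
    duplex: Duplex, crowders: CrowderConfig, params: ModelParams
) -> np.ndarray:
    """Per-site Morse depths (eV) after crowder scaling.

    Site ``i`` gets ``alpha_eff(i) * D0(class_i)`` where ``alpha_eff`` is
    1 at uncrowded sites.
    """
    base = np.array([params.depth(p) for p in duplex.pairs])
    return crowders.effective_alphas(duplex.N) * base


def site_widths(duplex: Duplex, params: ModelParams) -> np.ndarray:
    """Per-site Morse inverse widths (1/angstrom); crowders do not alter them."""
    return np.array([params.width(p) for p in duplex.pairs])
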