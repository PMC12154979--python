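"""Reference duplexes and long-chain crowding scenarios.

The two 8-bp duplexes (shorthand alphabet: G = GC pair, A = AT pair)
come from published UV-melting experiments on short duplexes in
PEG-crowded solution:

* chain-A: 5'-GGGAGAAG-3'
* chain-B: 5'-GGAAGAGG-3'

The long-chain scenarios model a cell-like environment: five crowders
of graded strength (alpha = 5..9) at fixed positions on 50-, 100- and
300-bp chains, giving crowded-site fractions of 10%, 5% and ~1.7%.
The underlying heteropolymer sequences are not part of the published
record, so each scenario carries a reproducible random sequence at 50%
GC content generated from a fixed package-level seed.
"""

from __future__ import annotations

from pathlib import Path

from .crowders import CrowderConfig, save_crowder_config
from .sequences import Duplex, generate_random_duplex, parse_duplex, write_fasta_duplex

CHAIN_A = "GGGAGAAG"
CHAIN_B = "GGAAGAGG"

#: Crowder placements for the long chains: (site, alpha) with alpha
#: 5, 6, 7, 8, 9 assigned to the listed positions in order.
LONG_CHAIN_CROWDERS: dict[int, tuple[tuple[int, int], ...]] = {
    50: ((33, 5), (36, 6), (27, 7), (15, 8), (43, 9)),
    100: ((83, 5), (86, 6), (77, 7), (15, 8), (93, 9)),
    300: ((283, 5), (286, 6), (177, 7), (115, 8), (293, 9)),
}

#: Fixed seed for the scenario sequences, so the shipped fixtures are
#: identical across installations.
SCENARIO_SEED = 1234

#: GC content of the scenario sequences.
SCENARIO_GC_FRACTION = 0.5


def chain_a() -> Duplex:
    return parse_duplex(CHAIN_A, alphabet="shorthand", label="chain-A")


def chain_b() -> Duplex:
    return parse_duplex(CHAIN_B, alphabet="shorthand", label="chain-B")


def long_chain_scenario(length: int) -> tuple[Duplex, CrowderConfig]:
    """Duplex + crowder configuration for a 50/100/300-bp scenario."""
    if length not in LONG_CHAIN_CROWDERS:
        raise ValueError(
            f"no scenario for length {length}; choose from "
            f"{sorted(LONG_CHAIN_CROWDERS)}"
        )
    duplex = generate_random_duplex(
        length, SCENARIO_GC_FRACTION, SCENARIO_SEED, label=f"scenario-{length}bp"
    )
    crowders = CrowderConfig(
        tuple((site, float(alpha)) for site, alpha in LONG_CHAIN_CROWDERS[length])
    )
    return duplex, crowders


def crowded_fraction(length: int) -> float:
    """Fraction of crowded sites in a long-chain scenario."""
    return len(LONG_CHAIN_CROWDERS[length]) / length


def write_fixtures(outdir: str | Path) -> list[Path]:
    """Write chain-A/B FASTA and the three scenario files to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for duplex in (chain_a(), chain_b()):
        path = outdir / f"{duplex.label}.fasta"
        write_fasta_duplex(duplex, path)
        written.append(path)
    for length in sorted(LONG_CHAIN_CROWDERS):
        duplex, crowders = long_chain_scenario(length)
        fasta = outdir / f"{duplex.label}.fasta"
        write_fasta_duplex(duplex, fasta)
        written.append(fasta)
        cfg = outdir / f"{duplex.label}-crowders.yaml"
        save_crowder_config(crowders, cfg)
        written.append(cfg)
    return written
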