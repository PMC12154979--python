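"""DNA duplex sequences as ordered lists of base-pair classes.

A duplex is reduced to the information the PBD model uses: for each
position along the chain, whether the pair is AT/TA or GC/CG.  Two input
alphabets are supported: the two-letter shorthand in which ``G`` means a
GC-class pair and ``A`` an AT-class pair, and the literal nucleotide
alphabet in which G/C map to the GC class and A/T to the AT class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

#: Valid pair classes, in the order used for display.
PAIR_CLASSES = ("AT", "GC")

_SHORTHAND = {"G": "GC", "A": "AT"}
_LITERAL = {"G": "GC", "C": "GC", "A": "AT", "T": "AT"}


class SequenceParseError(ValueError):
    """Raised when a sequence string contains an unknown character."""


@dataclass(frozen=True)
class Duplex:
    """An N-base-pair duplex, stored 5'->3' along one strand.

    ``pairs[i]`` is the class of pair ``i+1`` (sites are 1-based in all
    user-facing I/O, matching the field's convention for crowder
    positions such as "(2, 7, 8)").
    """

    pairs: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("a duplex needs at least one base pair")
        bad = [p for p in self.pairs if p not in PAIR_CLASSES]
        if bad:
            raise ValueError(f"invalid pair class(es): {sorted(set(bad))}")

    @property
    def N(self) -> int:
        return len(self.pairs)

    def gc_count(self) -> int:
        return sum(p == "GC" for p in self.pairs)

    def reversed(self) -> "Duplex":
        """The same duplex read from the other end."""
        return Duplex(tuple(reversed(self.pairs)), label=self.label)


def parse_duplex(text: str, alphabet: str = "shorthand", label: str = "") -> Duplex:
    """Parse a sequence string into a :class:`Duplex`.

    Parameters
    ----------
    text : str
        The sequence, read 5'->3' on one strand.
    alphabet : {"shorthand", "literal"}
        ``shorthand``: G = GC-class pair, A = AT-class pair.
        ``literal``: G/C -> GC class, A/T -> AT class.
    """
    if alphabet == "shorthand":
        table = _SHORTHAND
    elif alphabet == "literal":
        table = _LITERAL
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if not text:
        raise SequenceParseError("empty sequence string")
    pairs = []
    for pos, ch in enumerate(text.upper(), start=1):
        try:
            pairs.append(table[ch])
        except KeyError:
            raise SequenceParseError(
                f"unknown character {ch!r} at position {pos} "
                f"(alphabet={alphabet})"
            ) from None
    return Duplex(tuple(pairs), label=label)


def format_duplex(duplex: Duplex) -> str:
    """Render a duplex in the shorthand alphabet (inverse of parsing)."""
    return "".join("G" if p == "GC" else "A" for p in duplex.pairs)


def read_fasta_duplex(path: str | Path, alphabet: str = "literal") -> Duplex:
    """Read a single-record FASTA file into a Duplex."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]
    return parse_duplex(str(rec.seq), alphabet=alphabet, label=rec.id)


def write_fasta_duplex(duplex: Duplex, path: str | Path) -> None:
    """Write a duplex as shorthand FASTA (one record)."""
    name = duplex.label or "duplex"
    Path(path).write_text(f">{name}\n{format_duplex(duplex)}\n")


def generate_random_duplex(N: int, gc_fraction: float, seed: int, label: str = "") -> Duplex:
    """Random heteropolymer duplex with an exact GC count.

    Exactly ``floor(N * gc_fraction)`` sites are GC, placed uniformly at
    random without replacement, so the realized composition is fixed and
    only the arrangement is random.  Deterministic for a fixed seed.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    n_gc = int(np.floor(N * gc_fraction))
    gc_sites = rng.choice(N, size=n_gc, replace=False)
    pairs = np.array(["AT"] * N, dtype=object)
    pairs[gc_sites] = "GC"
    return Duplex(tuple(pairs), label=label or f"random-{N}bp-gc{gc_fraction:g}-seed{seed}")
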