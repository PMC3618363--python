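"""Small shared helpers: rounding convention and FASTA I/O."""

from __future__ import annotations

import math
from typing import Iterable


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding).

    This is the convention used for every reported percentage and mean:
    100 * 1656 / 31662 -> 5.23, 1621208 / 14813 -> 109.
    """
    factor = 10.0 ** decimals
    scaled = x * factor
    # nudge by an epsilon-free construction: floor(|x|+0.5) with sign restored
    rounded = math.floor(abs(scaled) + 0.5)
    return math.copysign(rounded, x) / factor


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) pairs, preserving order."""
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i : i + width] + "\n")
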