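"""Concatenation of family alignments and strict gap-column filtering.

Per-family alignments are joined column-wise into one "super-gene" matrix
with recorded per-family column spans; filtering then removes every column
in which any species holds '-', mirroring the strictest no-gaps setting of
block-filtering tools. 'X' is retained and treated as missing data by the
likelihood machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .util import round_half_away, write_fasta


class MatrixError(ValueError):
    pass


@dataclass(frozen=True)
class FamilyAlignment:
    family_id: str
    rows: Mapping[str, str]

    def __post_init__(self):
        widths = {len(s) for s in self.rows.values()}
        if len(widths) > 1:
            raise MatrixError(f"family {self.family_id!r}: rows differ in length")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class SuperMatrix:
    species_order: list[str]
    rows: list[str]                       # aligned to species_order
    spans: list[tuple[str, int, int]]     # (family_id, start, end) 1-based incl.

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row_map(self) -> dict[str, str]:
        return dict(zip(self.species_order, self.rows))

    def extract(self, family_id: str) -> FamilyAlignment:
        for fam, start, end in self.spans:
            if fam == family_id:
                return FamilyAlignment(
                    family_id,
                    {
                        sp: row[start - 1 : end]
                        for sp, row in zip(self.species_order, self.rows)
                    },
                )
        raise MatrixError(f"family {family_id!r} not in matrix spans")


def concatenate(
    families: Sequence[FamilyAlignment], species_order: Sequence[str]
) -> SuperMatrix:
    """Join family alignments column-wise in the given species order."""
    species_order = list(species_order)
    parts: dict[str, list[str]] = {sp: [] for sp in species_order}
    spans = []
    cursor = 1
    for fam in families:
        missing = set(species_order) - set(fam.rows)
        if missing:
            raise MatrixError(
                f"family {fam.family_id!r} lacks species {sorted(missing)}"
            )
        for sp in species_order:
            parts[sp].append(fam.rows[sp])
        spans.append((fam.family_id, cursor, cursor + fam.width - 1))
        cursor += fam.width
    return SuperMatrix(
        species_order=species_order,
        rows=["".join(parts[sp]) for sp in species_order],
        spans=spans,
    )


def strip_gap_columns(m: SuperMatrix) -> tuple[SuperMatrix, dict]:
    """Drop every column holding '-' in any row; remap spans.

    Returns the filtered matrix and a report with the retained fraction
    (percentage rounded half away from zero to 1 decimal). Families may
    shrink to zero width, leaving an empty span (start, start-1).
    """
    if not m.rows:
        return m, {"original_width": 0, "retained_width": 0,
                   "retained_fraction": 1.0, "retained_pct": 100.0}
    arr = np.array([list(r) for r in m.rows])
    keep = ~(arr == "-").any(axis=0)
    filtered = ["".join(row[keep]) for row in arr]
    new_spans = []
    cursor = 1
    for fam, start, end in m.spans:
        surv = int(keep[start - 1 : end].sum())
        new_spans.append((fam, cursor, cursor + surv - 1))
        cursor += surv
    original = m.width
    retained = int(keep.sum())
    frac = retained / original if original else 1.0
    report = {
        "original_width": original,
        "retained_width": retained,
        "retained_fraction": frac,
        "retained_pct": round_half_away(100.0 * frac, 1),
    }
    return SuperMatrix(list(m.species_order), filtered, new_spans), report


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta_matrix(path, m: SuperMatrix) -> None:
    write_fasta(path, zip(m.species_order, m.rows))


def write_phylip(path, m: SuperMatrix) -> None:
    """Relaxed PHYLIP: names of any length, separated by whitespace."""
    with open(path, "w") as fh:
        fh.write(f"{len(m.species_order)} {m.width}\n")
        for sp, row in zip(m.species_order, m.rows):
            fh.write(f"{sp}  {row}\n")


def write_spans(path, m: SuperMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tstart\tend\n")
        for fam, start, end in m.spans:
            fh.write(f"{fam}\t{start}\t{end}\n")
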