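"""Six-frame translation and single-product ORF selection.

Each contig is translated in all six reading frames under the standard
genetic code. Two candidate sets compete for the contig's protein product:

* set A — complete ORFs, running from an in-frame ATG to the next in-frame
  stop codon;
* set B — 5'-truncated fragments: the prefix of a frame up to its first
  stop codon, eligible only when no in-frame ATG precedes that stop (the
  start codon is presumed lost upstream of the contig).

The longest set-A candidate wins unless the longest set-B fragment is
strictly longer. Contigs shorter than 10 nt yield no product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Data import CodonTable

from .util import round_half_away

STOP = "*"
MIN_CONTIG_NT = 10
FRAMES = (1, 2, 3, -1, -2, -3)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_TO_AA[_stop] = STOP
_VALID_NT = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


class InvalidAlphabetError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str

    def __post_init__(self):
        seq = self.sequence.upper()
        if not seq:
            raise InvalidAlphabetError(f"contig {self.id!r} is empty")
        bad = set(seq) - _VALID_NT
        if bad:
            raise InvalidAlphabetError(
                f"contig {self.id!r} has characters outside ACGTN: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class TranslatedORF:
    contig_id: str
    frame: int            # one of +1,+2,+3,-1,-2,-3
    protein: str          # residues only, no stop symbol
    has_start: bool
    has_stop: bool
    nt_start: int         # 1-based inclusive, forward strand
    nt_end: int


def _translate_codon(codon: str) -> str:
    # any N makes the codon ambiguous: X, which is never a start or a stop
    if "N" in codon:
        return "X"
    return _CODON_TO_AA[codon]


def _frame_codons(seq: str, frame: int) -> list[str]:
    s = seq if frame > 0 else revcomp(seq)
    off = abs(frame) - 1
    usable = s[off:]
    return [usable[i : i + 3] for i in range(0, len(usable) - 2, 3)]


def six_frame_translate(contig: Contig) -> dict[int, str]:
    """Raw translation of all six frames; stops appear as '*'.

    Frames too short for a full codon give empty strings; trailing 1-2 nt
    are dropped.
    """
    return {
        frame: "".join(_translate_codon(c) for c in _frame_codons(contig.sequence, frame))
        for frame in FRAMES
    }


def _forward_span(n: int, frame: int, codon_start: int, n_codons: int) -> tuple[int, int]:
    """Map a codon run in a frame onto 1-based forward-strand coordinates."""
    off = abs(frame) - 1
    first = off + 3 * codon_start + 1          # on the frame's own strand
    last = off + 3 * (codon_start + n_codons)  # inclusive end
    if frame > 0:
        return first, last
    return n - last + 1, n - first + 1


def _candidates(contig: Contig):
    """Yield (set_tag, frame, protein, codon_start, n_codons_incl_stop)."""
    seq = contig.sequence
    for frame in FRAMES:
        codons = _frame_codons(seq, frame)
        aa = [_translate_codon(c) for c in codons]
        stops = [i for i, a in enumerate(aa) if a == STOP]
        starts = [i for i, c in enumerate(codons) if c == "ATG"]
        # set A: every in-frame ATG running to the next in-frame stop
        for s in starts:
            nxt = next((i for i in stops if i >= s), None)
            if nxt is not None and nxt > s:
                protein = "".join(aa[s:nxt])
                yield "A", frame, protein, s, nxt - s + 1
        # set B: prefix to the first stop, with no upstream in-frame start
        if stops:
            first_stop = stops[0]
            if first_stop > 0 and not any(s < first_stop for s in starts):
                protein = "".join(aa[:first_stop])
                yield "B", frame, protein, 0, first_stop + 1


_FRAME_RANK = {f: i for i, f in enumerate(FRAMES)}


def select_orf(contig: Contig, min_nt: int = MIN_CONTIG_NT) -> Optional[TranslatedORF]:
    """Pick the contig's single protein product, or None.

    Ties between equal-length candidates break by set A over set B, forward
    strand over reverse, lower frame number, then smaller forward-strand
    start coordinate.
    """
    if len(contig.sequence) < min_nt:
        return None
    n = len(contig.sequence)
    best = None
    best_key = None
    for tag, frame, protein, cstart, ncod in _candidates(contig):
        if not protein:
            continue
        nt_start, nt_end = _forward_span(n, frame, cstart, ncod)
        key = (-len(protein), 0 if tag == "A" else 1, _FRAME_RANK[frame], nt_start)
        if best_key is None or key < best_key:
            best_key = key
            best = TranslatedORF(
                contig_id=contig.id,
                frame=frame,
                protein=protein,
                has_start=(tag == "A"),
                has_stop=True,
                nt_start=nt_start,
                nt_end=nt_end,
            )
    if best is None:
        return None
    # winner maximality rule: B only beats A by strict length inequality,
    # which the sort key already encodes (A ranks first within a length).
    return best


def translate_set(
    contigs: Iterable[Contig], min_nt: int = MIN_CONTIG_NT
) -> tuple[list[TranslatedORF], dict]:
    """Translate a contig collection; returns products and a length summary.

    The mean length is total residues / product count, rounded half away
    from zero to whole residues.
    """
    products = []
    for contig in contigs:
        orf = select_orf(contig, min_nt=min_nt)
        if orf is not None:
            products.append(orf)
    if not products:
        return [], {"count": 0, "total_aa": 0, "mean_aa": None,
                    "min_aa": None, "max_aa": None}
    lengths = [len(p.protein) for p in products]
    total = sum(lengths)
    summary = {
        "count": len(products),
        "total_aa": total,
        "mean_aa": int(round_half_away(total / len(products), 0)),
        "min_aa": min(lengths),
        "max_aa": max(lengths),
    }
    return products, summary


def read_contigs(path) -> list[Contig]:
    from .util import read_fasta

    return [Contig(name, seq) for name, seq in read_fasta(path)]


def write_orfs(path, orfs: Iterable[TranslatedORF]) -> None:
    from .util import write_fasta

    write_fasta(
        path,
        (
            (
                f"{o.contig_id} frame={o.frame:+d} start={int(o.has_start)} "
                f"stop={int(o.has_stop)} span={o.nt_start}-{o.nt_end}",
                o.protein,
            )
            for o in orfs
        ),
    )
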