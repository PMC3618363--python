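"""One-to-one reciprocal-best-hit ortholog detection.

Similarity is the exact Smith–Waterman local-alignment score under BLOSUM62
with affine gaps (open 11, extend 1 — i.e. a gap of length k costs 11 + k),
computed with Biopython's PairwiseAligner. A pair (s, r) is an ortholog
candidate iff r is s's best hit in the reference proteome and s is r's best
hit in the species proteome; groups keep only reference genes with a
reciprocal partner in every species.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence

DEFAULT_MIN_SCORE = 40
ProteinRecord = tuple[str, str]  # (gene id, sequence)


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: int


@dataclass(frozen=True)
class OrthologGroup:
    reference_gene: str
    members: Mapping[str, str]  # species label -> gene id (reference included)


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # BLAST convention: gap of length k costs open + k*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Optimal Smith–Waterman local score; 0 for the empty local alignment."""
    if not a or not b:
        raise AlignmentError("sequences must be non-empty")
    aligner = _aligner(matrix, gap_open, gap_extend)
    return int(max(0.0, aligner.score(a, b)))


def best_hit(
    query: ProteinRecord,
    proteome: Sequence[ProteinRecord],
    min_score: int = DEFAULT_MIN_SCORE,
    **align_kwargs,
) -> Optional[SimilarityHit]:
    """Highest-scoring subject for a query; ties break toward the
    lexicographically smaller subject id; None below `min_score`."""
    if not proteome:
        raise AlignmentError("proteome must be non-empty")
    qid, qseq = query
    best: Optional[SimilarityHit] = None
    for sid, sseq in proteome:
        if sid == qid:
            continue
        score = local_align_score(qseq, sseq, **align_kwargs)
        if best is None or score > best.score or (
            score == best.score and sid < best.subject_id
        ):
            best = SimilarityHit(qid, sid, score)
    if best is None or best.score < min_score:
        return None
    return best


def _best_per_row(ids_a, ids_b, scores, min_score):
    """Best subject (column) per query (row) with lexicographic ties."""
    out = {}
    for i, qid in enumerate(ids_a):
        best_j = None
        for j, sid in enumerate(ids_b):
            if sid == qid:
                continue
            if (
                best_j is None
                or scores[i][j] > scores[i][best_j]
                or (scores[i][j] == scores[i][best_j] and sid < ids_b[best_j])
            ):
                best_j = j
        if best_j is not None and scores[i][best_j] >= min_score:
            out[qid] = ids_b[best_j]
    return out


def reciprocal_best_hits(
    species_proteome: Sequence[ProteinRecord],
    reference_proteome: Sequence[ProteinRecord],
    min_score: int = DEFAULT_MIN_SCORE,
    **align_kwargs,
) -> set[tuple[str, str]]:
    """(species_gene, reference_gene) pairs that are mutual best hits."""
    if not species_proteome or not reference_proteome:
        raise AlignmentError("both proteomes must be non-empty")
    ids_s = [gid for gid, _ in species_proteome]
    ids_r = [gid for gid, _ in reference_proteome]
    scores = [
        [local_align_score(sseq, rseq, **align_kwargs) for _, rseq in reference_proteome]
        for _, sseq in species_proteome
    ]
    fwd = _best_per_row(ids_s, ids_r, scores, min_score)
    rev_scores = [[scores[i][j] for i in range(len(ids_s))] for j in range(len(ids_r))]
    rev = _best_per_row(ids_r, ids_s, rev_scores, min_score)
    return {
        (s, r) for s, r in fwd.items() if rev.get(r) == s
    }


def build_groups(
    rbh_maps: Mapping[str, set[tuple[str, str]]],
    species: Sequence[str],
    reference: str,
) -> list[OrthologGroup]:
    """Group reference genes having a reciprocal partner in every species.

    `rbh_maps` maps each non-reference species label to its RBH pair set.
    Reference genes missing a partner in any species are dropped.
    """
    if reference not in species:
        raise AlignmentError("reference species must be in the species list")
    others = [sp for sp in species if sp != reference]
    by_ref: dict[str, dict[str, str]] = {}
    for sp in others:
        pairs = rbh_maps.get(sp, set())
        for sgene, rgene in pairs:
            by_ref.setdefault(rgene, {})[sp] = sgene
    groups = []
    for rgene in sorted(by_ref):
        members = by_ref[rgene]
        if len(members) == len(others):
            full = dict(members)
            full[reference] = rgene
            groups.append(OrthologGroup(reference_gene=rgene, members=full))
    return groups
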