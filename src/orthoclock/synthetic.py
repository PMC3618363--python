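"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: an ultrametric
pure-birth species tree, gap-free protein family alignments evolved under an
empirical amino-acid model (with an optional rate multiplier on one focal
terminal branch), nucleotide contigs that embed those proteins behind
untranslated flanks, per-species proteomes with decoy paralogs and missing
copies, and a small GO ontology with planted enriched/diminished terms.

All randomness flows through numpy Generators seeded from the scenario, so
identical scenarios produce byte-identical FASTA/OBO/Newick outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .phylo import AA_ORDER, SubstitutionModel, load_model
from .util import write_fasta

_STANDARD_NAMESPACES = (
    "biological_process",
    "cellular_component",
    "molecular_function",
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scenario and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimScenario:
    """Study design for one synthetic run.

    Defaults describe a desk-scale counterpart of a multi-species ortholog
    study: 5 taxa, 50 single-copy families of 200 residues on a Yule tree of
    height 0.5 substitutions/site, no paralogs or missing copies.
    """

    n_taxa: int = 5
    birth_rate: float = 1.0
    n_families: int = 50
    sites_per_family: int = 200
    focal_taxon: str = "sp2"
    reference_taxon: str = "sp1"
    rate_multiplier: float = 1.0
    shifted_fraction: float = 0.0  # fraction of families given the multiplier
    paralog_rate: float = 0.0
    missing_rate: float = 0.0
    paralog_branch: float = 0.6
    tree_height: float = 0.5
    model_name: str = "WAG"
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise SimulationError("n_taxa must be at least 3")
        if self.rate_multiplier <= 0 or self.birth_rate <= 0:
            raise SimulationError("rates must be positive")
        for p in (self.paralog_rate, self.missing_rate, self.shifted_fraction):
            if not 0.0 <= p <= 1.0:
                raise SimulationError("probabilities must lie in [0, 1]")
        if self.focal_taxon not in self.species or self.reference_taxon not in self.species:
            raise SimulationError("focal and reference taxa must be among the species")

    @property
    def species(self) -> list[str]:
        return [f"sp{i}" for i in range(1, self.n_taxa + 1)]


@dataclass
class ContigTruth:
    contig_id: str
    source_id: str
    protein: str            # the protein select_orf should recover
    has_start: bool
    has_stop: bool
    nt_start: int           # 1-based inclusive, forward strand
    nt_end: int
    strand: str             # '+' or '-'
    is_decoy: bool = False  # <10 nt decoy with no recoverable product


@dataclass
class ProteomeTruth:
    tree: dendropy.Tree
    species: list[str]
    reference: str
    focal: str
    ortholog_pairs: set
    family_alignments: dict
    family_rate_class: dict
    deletions: set
    paralogs: set

    @property
    def complete_families(self) -> list[str]:
        missing = {fam for fam, _ in self.deletions}
        return [f for f in self.family_alignments if f not in missing]


@dataclass
class GoFixture:
    obo_text: str
    annotations: dict            # gene -> set of direct term ids
    study_genes: list[str]
    planted: dict                # term id -> (direction, odds)
    term_levels: dict            # truth: term id -> shortest-path level
    term_parents: dict           # truth: term id -> tuple of parents
    namespaces: dict             # term id -> namespace
    alt_ids: dict                # alt id -> primary id
    obsolete_ids: list[str]
    genes: list = None           # gene order matching study_weights
    study_weights: "np.ndarray" = None  # planted-odds sampling weights

    def draw_study(self, size: int, rng: np.random.Generator) -> list[str]:
        """Redraw a study set under the fixture's planted-odds weighting."""
        idx = rng.choice(len(self.genes), size=min(size, len(self.genes)),
                         replace=False, p=self.study_weights)
        return sorted(self.genes[i] for i in idx)

    def write(self, obo_path, annotations_path) -> None:
        with open(obo_path, "w") as fh:
            fh.write(self.obo_text)
        with open(annotations_path, "w") as fh:
            fh.write("gene_id\tgo_id\n")
            for gene in sorted(self.annotations):
                for term in sorted(self.annotations[gene]):
                    fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def sample_tree(
    n_taxa: int,
    birth_rate: float,
    seed: int,
    labels: Optional[Sequence[str]] = None,
) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric tree with positive branch lengths.

    Waiting times between the k-th and (k+1)-th birth are Exp(k * birth_rate);
    a final Exp(n * birth_rate) segment after the last split keeps every
    terminal branch strictly positive.
    """
    if n_taxa < 2:
        raise SimulationError("n_taxa must be at least 2")
    if birth_rate <= 0:
        raise SimulationError("birth_rate must be positive")
    if labels is None:
        labels = [f"sp{i}" for i in range(1, n_taxa + 1)]
    if len(set(labels)) != n_taxa:
        raise SimulationError("labels must be unique and match n_taxa")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        active.append((root.new_child(), 0.0))
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t - born
        active.insert(idx, (node.new_child(), t))
        active.insert(idx + 1, (node.new_child(), t))
    t += rng.exponential(1.0 / (n_taxa * birth_rate))
    for (node, born), lbl in zip(active, labels):
        node.edge.length = t - born
        node.taxon = tns.get_taxon(lbl)
    return tree


def tree_height(tree: dendropy.Tree) -> float:
    return max(lf.distance_from_root() for lf in tree.leaf_node_iter())


def rescale_tree(tree: dendropy.Tree, height: float) -> dendropy.Tree:
    current = tree_height(tree)
    if current <= 0:
        raise SimulationError("tree has zero height")
    factor = height / current
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _sample_states(p_rows: np.ndarray, parent: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(p_rows[parent], axis=1)
    u = rng.random(parent.shape[0])
    child = (u[:, None] > cum).sum(axis=1)
    return np.minimum(child, p_rows.shape[0] - 1)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(AA_ORDER[c] for c in codes)


def evolve_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    rate_multiplier: float = 1.0,
    focal_taxon: Optional[str] = None,
    seed: int = 0,
    return_root: bool = False,
):
    """Simulate a gap-free alignment down a tree under `model`.

    The root sequence is drawn from the equilibrium frequencies; each branch
    applies the model's transition probabilities at its length, with the
    focal terminal branch scaled by `rate_multiplier`.
    """
    if rate_multiplier <= 0:
        raise SimulationError("rate_multiplier must be positive")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if focal_taxon is not None and focal_taxon not in leaf_labels:
        raise SimulationError(f"focal taxon {focal_taxon!r} is not a leaf")
    rng = np.random.default_rng(seed)
    root_states = rng.choice(len(AA_ORDER), size=n_sites, p=model.frequencies)
    states = {id(tree.seed_node): root_states}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        blen = node.edge.length or 0.0
        label = node.taxon.label if node.is_leaf() else None
        if label is not None and label == focal_taxon:
            blen *= rate_multiplier
        if blen == 0.0:
            child_states = states[id(node.parent_node)].copy()
        else:
            p = model.transition_matrix(blen)
            child_states = _sample_states(p, states[id(node.parent_node)], rng)
        states[id(node)] = child_states
        if label is not None:
            out[label] = _codes_to_str(child_states)
    if return_root:
        return out, _codes_to_str(root_states)
    return out


def _evolve_branch(seq: str, model: SubstitutionModel, t: float,
                   rng: np.random.Generator) -> str:
    codes = np.array([AA_ORDER.index(c) for c in seq])
    if t > 0:
        codes = _sample_states(model.transition_matrix(t), codes, rng)
    return _codes_to_str(codes)


# ---------------------------------------------------------------------------
# contigs
# ---------------------------------------------------------------------------

def _codon_tables():
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa in by_aa:
        by_aa[aa].sort()
    return by_aa, sorted(table.stop_codons)


_BY_AA, _STOP_CODONS = _codon_tables()
_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _BY_AA.get(aa)
        if not options:
            raise SimulationError(f"cannot reverse-translate residue {aa!r}")
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _ct_utr(length: int, rng: np.random.Generator) -> str:
    # {C,T} flanks contain no start or stop codon on either strand
    return "".join("CT"[b] for b in rng.integers(0, 2, size=length))


def make_contigs(
    proteins: Sequence[tuple[str, str]],
    seed: int,
    truncated_start_frac: float = 0.0,
    short_decoy_frac: float = 0.0,
    utr_range: tuple[int, int] = (0, 30),
    max_attempts: int = 60,
    min_fragment_aa: int = 15,
) -> tuple[list[tuple[str, str]], dict[str, ContigTruth]]:
    """Embed proteins into nucleotide contigs with known recoverable ORFs.

    Each protein is reverse-translated (uniform synonymous codons, standard
    code), given a start codon, a stop codon, and untranslated {C,T} flanks,
    and emitted on a random strand. A `truncated_start_frac` fraction loses
    its start codon (and 5' flank), so only the stop-terminated fragment is
    recoverable. Construction is verified against the ORF-selection rule and
    re-drawn until the planted product is the unique winner, so the truth
    table is exact by construction.
    """
    from . import orf as orf_mod

    if not proteins:
        raise SimulationError("proteins must be non-empty")
    rng = np.random.default_rng(seed)
    contigs: list[tuple[str, str]] = []
    truth: dict[str, ContigTruth] = {}
    counter = 0

    for source_id, protein in proteins:
        counter += 1
        cid = f"contig_{counter:05d}"
        encoded = protein if protein.startswith("M") else "M" + protein
        # a 5'-truncated contig keeps the tail after the last methionine, so
        # the stop-terminated start-less fragment really is the product the
        # selection rule should return; too-short tails stay intact
        frag_start = encoded.rfind("M") + 1
        fragment = encoded[frag_start:]
        truncated = (
            rng.random() < truncated_start_frac
            and len(fragment) >= min_fragment_aa
        )
        if truncated:
            expected, exp_start, skip_codons = fragment, False, frag_start
        else:
            expected, exp_start, skip_codons = encoded, True, 0
        placed = None
        for _ in range(max_attempts):
            body = _reverse_translate(encoded, rng)[3 * skip_codons:]
            stop = _STOP_CODONS[rng.integers(len(_STOP_CODONS))]
            if truncated:
                utr5 = ""
            else:
                utr5 = _ct_utr(int(rng.integers(utr_range[0], utr_range[1] + 1)), rng)
            utr3 = _ct_utr(int(rng.integers(utr_range[0], utr_range[1] + 1)), rng)
            fwd = utr5 + body + stop + utr3
            minus = rng.random() < 0.5
            seq = revcomp(fwd) if minus else fwd
            span_start = len(utr5) + 1
            span_end = len(utr5) + len(body) + 3
            if minus:
                span_start, span_end = (
                    len(fwd) - span_end + 1,
                    len(fwd) - span_start + 1,
                )
            if len(fwd) < 10:
                # below the translation cutoff: emit with planted truth but
                # no recoverable product to verify against
                placed = (seq, span_start, span_end, "-" if minus else "+")
                break
            got = orf_mod.select_orf(orf_mod.Contig(cid, seq))
            if (
                got is not None
                and got.protein == expected
                and got.has_start is exp_start
                and got.has_stop
                and got.nt_start == span_start
                and got.nt_end == span_end
            ):
                placed = (seq, span_start, span_end, "-" if minus else "+")
                break
        if placed is None:
            raise SimulationError(
                f"could not place protein {source_id!r} as the unique ORF winner"
            )
        seq, s0, s1, strand = placed
        contigs.append((cid, seq))
        truth[cid] = ContigTruth(
            contig_id=cid, source_id=source_id, protein=expected,
            has_start=exp_start, has_stop=True,
            nt_start=s0, nt_end=s1, strand=strand,
        )

    n_decoys = int(round(short_decoy_frac * len(proteins)))
    for _ in range(n_decoys):
        counter += 1
        cid = f"contig_{counter:05d}"
        length = int(rng.integers(1, 10))
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=length))
        contigs.append((cid, seq))
        truth[cid] = ContigTruth(
            contig_id=cid, source_id="", protein="", has_start=False,
            has_stop=False, nt_start=0, nt_end=0, strand="+", is_decoy=True,
        )
    return contigs, truth


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------

def make_proteomes(
    scenario: SimScenario,
) -> tuple[dict[str, list[tuple[str, str]]], ProteomeTruth]:
    """Simulate per-species proteomes of single-copy ortholog families.

    Families evolve on one shared species tree. With probability
    `paralog_rate` a species gains a decoy duplicate that diverged on an
    extra branch placed before the family root; with probability
    `missing_rate` a non-reference species loses its copy. A
    `shifted_fraction` of families evolves the focal terminal branch at
    `rate_multiplier` times the clock rate.
    """
    sc = scenario
    species = sc.species
    tree = sample_tree(sc.n_taxa, sc.birth_rate, sc.seed, labels=species)
    rescale_tree(tree, sc.tree_height)
    model = load_model(sc.model_name)
    rng = np.random.default_rng(sc.seed + 1)

    n_shifted = int(round(sc.shifted_fraction * sc.n_families))
    shifted = set(rng.choice(sc.n_families, size=n_shifted, replace=False)) \
        if n_shifted else set()
    if sc.rate_multiplier > 1:
        shifted_class = "accelerated"
    elif sc.rate_multiplier < 1:
        shifted_class = "decreased"
    else:
        shifted_class = "clock-like"

    root_dist = {
        lf.taxon.label: sum(e.length or 0.0 for e in _path_edges(lf))
        for lf in tree.leaf_node_iter()
    }

    proteomes: dict[str, list[tuple[str, str]]] = {sp: [] for sp in species}
    pairs: set = set()
    alignments: dict[str, dict[str, str]] = {}
    rate_class: dict[str, str] = {}
    deletions: set = set()
    paralogs: set = set()

    for fi in range(sc.n_families):
        fam = f"fam{fi:04d}"
        r = sc.rate_multiplier if fi in shifted else 1.0
        fam_seed = int(rng.integers(2**31))
        rows, root_seq = evolve_alignment(
            tree, model, sc.sites_per_family, rate_multiplier=r,
            focal_taxon=sc.focal_taxon, seed=fam_seed, return_root=True,
        )
        alignments[fam] = rows
        rate_class[fam] = shifted_class if fi in shifted else "clock-like"
        for sp in species:
            gene = f"{sp}_{fam}"
            deleted = sp != sc.reference_taxon and rng.random() < sc.missing_rate
            if deleted:
                deletions.add((fam, sp))
            else:
                proteomes[sp].append((gene, rows[sp]))
                if sp != sc.reference_taxon:
                    pairs.add((gene, f"{sc.reference_taxon}_{fam}"))
            if rng.random() < sc.paralog_rate:
                dup_seq = _evolve_branch(
                    root_seq, model, sc.paralog_branch + root_dist[sp], rng
                )
                dup = f"{sp}_{fam}_dup"
                proteomes[sp].append((dup, dup_seq))
                paralogs.add(dup)

    truth = ProteomeTruth(
        tree=tree, species=species, reference=sc.reference_taxon,
        focal=sc.focal_taxon, ortholog_pairs=pairs,
        family_alignments=alignments, family_rate_class=rate_class,
        deletions=deletions, paralogs=paralogs,
    )
    return proteomes, truth


def _path_edges(node):
    edges = []
    while node.parent_node is not None:
        edges.append(node.edge)
        node = node.parent_node
    return edges


def write_proteomes(proteomes: Mapping[str, list], outdir) -> dict[str, str]:
    """One FASTA per species; returns species -> path."""
    import os

    paths = {}
    for sp, records in proteomes.items():
        path = os.path.join(str(outdir), f"{sp}.faa")
        write_fasta(path, records)
        paths[sp] = path
    return paths


def inject_gaps(rows: Mapping[str, str], column_fraction: float,
                seed: int) -> dict[str, str]:
    """Replace residues by '-' in a random fraction of columns (for testing
    the gap-column filter; true alignments are generated gap-free)."""
    rng = np.random.default_rng(seed)
    taxa = list(rows)
    width = len(next(iter(rows.values())))
    n_cols = int(round(column_fraction * width))
    cols = rng.choice(width, size=n_cols, replace=False) if n_cols else []
    out = {t: list(rows[t]) for t in taxa}
    for c in cols:
        hit = [t for t in taxa if rng.random() < 0.5]
        if not hit:
            hit = [taxa[rng.integers(len(taxa))]]
        for t in hit:
            out[t][c] = "-"
    return {t: "".join(v) for t, v in out.items()}


# ---------------------------------------------------------------------------
# GO fixture
# ---------------------------------------------------------------------------

def make_go_fixture(
    n_terms: int = 60,
    max_depth: int = 5,
    n_genes: int = 500,
    planted_terms: Optional[Sequence[tuple[str, float]]] = None,
    seed: int = 0,
    study_size: int = 200,
    terms_per_gene: tuple[int, int] = (1, 6),
) -> GoFixture:
    """A rooted three-namespace GO DAG with annotations and a study subset.

    `planted_terms` is a list of (direction, odds) requests; the generator
    picks a distinct mid-frequency term for each and biases the study-set
    draw so genes carrying an 'enriched' term are `odds` times more likely
    to enter the study (and 1/odds for 'diminished').
    """
    if max_depth < 3:
        raise SimulationError("max_depth must be at least 3 so levels 3-4 exist")
    if n_terms < 3 * max_depth:
        raise SimulationError("n_terms too small for three namespaces")
    rng = np.random.default_rng(seed)
    planted_terms = list(planted_terms or [])

    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    namespaces: dict[str, str] = {}
    parents: dict[str, tuple[str, ...]] = {}
    levels: dict[str, int] = {}
    roots = ids[:3]
    for ns, root in zip(_STANDARD_NAMESPACES, roots):
        namespaces[root] = ns
        parents[root] = ()
        levels[root] = 1
    per_ns: dict[str, list[str]] = {r: [r] for r in roots}

    # guarantee a chain to max_depth under each root, then attach the rest
    chain_len = max_depth - 1
    cursor = 3
    for root in roots:
        prev = root
        for _ in range(chain_len):
            tid = ids[cursor]
            cursor += 1
            namespaces[tid] = namespaces[root]
            parents[tid] = (prev,)
            levels[tid] = levels[prev] + 1
            per_ns[root].append(tid)
            prev = tid
    for tid in ids[cursor:]:
        root = roots[rng.integers(3)]
        pool = [t for t in per_ns[root] if levels[t] < max_depth]
        first = pool[rng.integers(len(pool))]
        pset = [first]
        if rng.random() < 0.25:
            extra_pool = [t for t in per_ns[root]
                          if levels[t] < max_depth and t != first]
            if extra_pool:
                pset.append(extra_pool[rng.integers(len(extra_pool))])
        namespaces[tid] = namespaces[root]
        parents[tid] = tuple(pset)
        levels[tid] = 1 + min(levels[p] for p in pset)
        per_ns[root].append(tid)

    ancestors: dict[str, frozenset[str]] = {}

    def _anc(tid: str) -> frozenset:
        if tid not in ancestors:
            acc = {tid}
            for p in parents[tid]:
                acc |= _anc(p)
            ancestors[tid] = frozenset(acc)
        return ancestors[tid]

    for tid in ids:
        _anc(tid)

    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    non_roots = [t for t in ids if t not in roots]
    lo, hi = terms_per_gene
    annotations: dict[str, set[str]] = {}
    propagated: dict[str, set[str]] = {}
    for g in genes:
        k = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(non_roots), size=min(k, len(non_roots)),
                            replace=False)
        direct = {non_roots[i] for i in chosen}
        annotations[g] = direct
        prop = set()
        for t in direct:
            prop |= ancestors[t]
        propagated[g] = prop

    planted: dict[str, tuple[str, float]] = {}
    if planted_terms:
        freq = {
            t: sum(1 for g in genes if t in propagated[g]) / n_genes
            for t in non_roots
        }
        candidates = [t for t in non_roots
                      if levels[t] >= 3 and 0.08 <= freq[t] <= 0.35]
        candidates.sort(key=lambda t: abs(freq[t] - 0.2))
        if len(candidates) < len(planted_terms):
            raise SimulationError("not enough mid-frequency terms to plant")
        for (direction, odds), term in zip(planted_terms, candidates):
            if direction not in ("enriched", "diminished"):
                raise SimulationError(f"unknown direction {direction!r}")
            planted[term] = (direction, float(odds))

    weights = np.ones(n_genes)
    for gi, g in enumerate(genes):
        for term, (direction, odds) in planted.items():
            if term in propagated[g]:
                weights[gi] *= odds if direction == "enriched" else 1.0 / odds
    weights /= weights.sum()
    study_idx = rng.choice(n_genes, size=min(study_size, n_genes),
                           replace=False, p=weights)
    study_genes = sorted(genes[i] for i in study_idx)

    # a couple of obsolete terms and one alt_id exercise the parser
    obsolete_ids = [f"GO:{n_terms + 1:07d}", f"GO:{n_terms + 2:07d}"]
    alt_ids = {f"GO:{n_terms + 3:07d}": ids[3]}

    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    alt_by_primary: dict[str, list[str]] = {}
    for alt, primary in alt_ids.items():
        alt_by_primary.setdefault(primary, []).append(alt)
    for tid in ids:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: synthetic term {tid[3:].lstrip('0')}")
        lines.append(f"namespace: {namespaces[tid]}")
        for alt in alt_by_primary.get(tid, []):
            lines.append(f"alt_id: {alt}")
        for p in parents[tid]:
            lines.append(f"is_a: {p} ! synthetic term {p[3:].lstrip('0')}")
        lines.append("")
    for tid in obsolete_ids:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: obsolete synthetic term {tid[3:].lstrip('0')}")
        lines.append(f"namespace: {_STANDARD_NAMESPACES[0]}")
        lines.append("is_obsolete: true")
        lines.append("")

    return GoFixture(
        obo_text="\n".join(lines),
        annotations=annotations,
        study_genes=study_genes,
        planted=planted,
        term_levels=levels,
        term_parents=parents,
        namespaces=namespaces,
        alt_ids=alt_ids,
        obsolete_ids=obsolete_ids,
        genes=genes,
        study_weights=weights,
    )
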