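"""Amino-acid phylogenetics engine.

Implements reversible empirical substitution models (WAG, JTT, LG, Dayhoff,
Blosum62) with optional invariant-sites and discrete-gamma rate mixtures,
Felsenstein-pruning log-likelihoods with site-pattern compression,
Poisson-corrected protein distances, neighbor joining, coordinate-wise
branch-length optimization, AIC model selection, and a Metropolis–Hastings
MCMC over unrooted topologies with majority-rule consensus summaries.

Trees are dendropy objects throughout; leaves are matched to alignment rows
by taxon label.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist
from scipy.optimize import minimize_scalar

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20
MISSING_CODE = 20  # 'X': fully missing data

_CHAR_CODES = np.full(256, -1, dtype=np.int16)
for _i, _a in enumerate(AA_ORDER):
    _CHAR_CODES[ord(_a)] = _i
    _CHAR_CODES[ord(_a.lower())] = _i
_CHAR_CODES[ord("X")] = MISSING_CODE
_CHAR_CODES[ord("x")] = MISSING_CODE
_CHAR_CODES[ord("?")] = MISSING_CODE

#: model names shipped as PAML-layout .dat files under orthoclock/data
BUILTIN_MODELS = ("WAG", "JTT", "LG", "Dayhoff", "Blosum62")


class PhyloError(ValueError):
    pass


# ---------------------------------------------------------------------------
# substitution models
# ---------------------------------------------------------------------------

def _load_dat(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-layout .dat file: 19 lower-triangle rows then frequencies."""
    ref = importlib.resources.files("orthoclock") / "data" / f"{name.lower()}.dat"
    tokens: list[float] = []
    for line in ref.read_text().splitlines():
        tokens.extend(float(t) for t in line.split())
    if len(tokens) < 190 + 20:
        raise PhyloError(f"model file for {name} is truncated")
    tri = tokens[:190]
    freqs = np.asarray(tokens[190:210])
    s = np.zeros((N_STATES, N_STATES))
    idx = 0
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = tri[idx]
            idx += 1
    return s, freqs / freqs.sum()


def discrete_gamma_rates(alpha: float, n_categories: int) -> np.ndarray:
    """Mean rates of equal-probability discrete-gamma categories (mean 1).

    Category boundaries are the i/k quantiles of Gamma(alpha, rate=alpha);
    each category's rate is its conditional mean, so the discretized
    distribution preserves the unit mean exactly.
    """
    if alpha <= 0:
        raise PhyloError("gamma shape must be positive")
    k = n_categories
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    cuts = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X · 1{X<=q}] for X~Gamma(a, rate=a) equals gammainc(a+1, a q)
    upper = np.where(np.isinf(cuts[1:]), 1.0, gammainc(alpha + 1.0, alpha * cuts[1:]))
    lower = gammainc(alpha + 1.0, alpha * cuts[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean() * 1.0


@dataclass
class SubstitutionModel:
    """A reversible 20-state amino-acid model with optional +I / +G / +F.

    The rate matrix is Q[i,j] = s[i,j] * pi[j], rescaled so the expected
    rate at stationarity is one substitution per site.
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: Optional[float] = None
    p_inv: Optional[float] = None
    n_categories: int = 4
    empirical_freqs: bool = False  # True if frequencies came from the data (+F)

    def __post_init__(self):
        s = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if s.shape != (N_STATES, N_STATES) or not np.allclose(s, s.T):
            raise PhyloError("exchangeabilities must be a symmetric 20x20 table")
        if np.any(s < 0) or np.any(pi < 0):
            raise PhyloError("model entries must be nonnegative")
        if abs(pi.sum() - 1.0) > 1e-6:
            raise PhyloError("frequencies must sum to 1")
        pi = pi / pi.sum()
        if self.p_inv is not None and not (0.0 <= self.p_inv < 1.0):
            raise PhyloError("p_inv must lie in [0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise PhyloError("alpha must be positive")
        self.exchangeabilities = s
        self.frequencies = pi
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        q /= mu
        self.rate_matrix = q
        # symmetrized eigendecomposition: exact and stable for reversible Q
        sq = np.sqrt(pi)
        b = (q * sq[:, None]) / sq[None, :]
        eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
        self._eigval = eigval
        self._left = eigvec / sq[:, None]        # D^-1/2 U
        self._right = eigvec.T * sq[None, :]     # U^T D^1/2

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); negative round-off entries are clipped to 0."""
        if t < 0:
            raise PhyloError("branch length must be nonnegative")
        p = (self._left * np.exp(self._eigval * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        return p

    def rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the site-rate mixture, renormalized to mean 1."""
        if self.alpha is not None:
            rates = discrete_gamma_rates(self.alpha, self.n_categories)
            weights = np.full(self.n_categories, 1.0 / self.n_categories)
        else:
            rates = np.array([1.0])
            weights = np.array([1.0])
        if self.p_inv is not None and self.p_inv > 0:
            pi0 = self.p_inv
            rates = np.concatenate([[0.0], rates / (1.0 - pi0)])
            weights = np.concatenate([[pi0], weights * (1.0 - pi0)])
        return rates, weights

    @property
    def n_free_params(self) -> int:
        k = 0
        if self.alpha is not None:
            k += 1
        if self.p_inv is not None:
            k += 1
        if self.empirical_freqs:
            k += N_STATES - 1
        return k

    def with_rates(self, alpha=None, p_inv=None) -> "SubstitutionModel":
        """Copy sharing the eigendecomposition, with new mixture parameters."""
        m = object.__new__(SubstitutionModel)
        m.__dict__.update(self.__dict__)
        m.alpha = alpha
        m.p_inv = p_inv
        return m

    @property
    def label(self) -> str:
        tag = self.name
        if self.p_inv is not None:
            tag += "+I"
        if self.alpha is not None:
            tag += "+G"
        if self.empirical_freqs:
            tag += "+F"
        return tag


def load_model(
    name: str,
    alpha: Optional[float] = None,
    p_inv: Optional[float] = None,
    frequencies: Optional[np.ndarray] = None,
    n_categories: int = 4,
) -> SubstitutionModel:
    """Load a built-in empirical model, optionally with +I/+G/+F settings."""
    canonical = {m.lower(): m for m in BUILTIN_MODELS}
    if name.lower() not in canonical:
        raise PhyloError(f"unknown model {name!r}; available: {BUILTIN_MODELS}")
    s, default_freqs = _load_dat(name)
    freqs = default_freqs if frequencies is None else np.asarray(frequencies, float)
    return SubstitutionModel(
        name=canonical[name.lower()],
        exchangeabilities=s,
        frequencies=freqs,
        alpha=alpha,
        p_inv=p_inv,
        n_categories=n_categories,
        empirical_freqs=frequencies is not None,
    )


def empirical_frequencies(rows: Mapping[str, str]) -> np.ndarray:
    """Observed residue frequencies across an alignment (X ignored)."""
    counts = np.zeros(N_STATES)
    for seq in rows.values():
        codes = _encode_row(seq)
        valid = codes[codes < N_STATES]
        counts += np.bincount(valid, minlength=N_STATES)
    if counts.sum() == 0:
        raise PhyloError("no unambiguous residues in alignment")
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# alignment encoding and pruning likelihood
# ---------------------------------------------------------------------------

def _encode_row(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CHAR_CODES[raw]
    if np.any(codes < 0):
        bad = sorted({chr(c) for c in raw[codes < 0]})
        if "-" in bad:
            raise PhyloError("alignment contains gaps; strip gap columns first")
        raise PhyloError(f"invalid residue characters: {bad}")
    return codes.astype(np.int64)


def _as_rows(alignment) -> dict[str, str]:
    if hasattr(alignment, "rows") and hasattr(alignment, "species_order"):
        return {sp: row for sp, row in zip(alignment.species_order, alignment.rows)}
    return dict(alignment)


def compress_patterns(rows: Mapping[str, str]) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Column-compress an alignment into unique site patterns with counts."""
    taxa = list(rows)
    lengths = {len(rows[t]) for t in taxa}
    if len(lengths) != 1:
        raise PhyloError("alignment rows differ in length")
    width = lengths.pop()
    if width == 0:
        return taxa, np.zeros((len(taxa), 0), dtype=np.int64), np.zeros(0)
    mat = np.stack([_encode_row(rows[t]) for t in taxa])
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return taxa, patterns, counts.astype(float)


class PreparedAlignment:
    """Pattern-compressed alignment with cached leaf partials.

    Optimizers and the MCMC evaluate the likelihood thousands of times on
    the same data; preparing once avoids recompressing per call.
    """

    def __init__(self, rows: Mapping[str, str]):
        self.rows = dict(rows)
        taxa, patterns, counts = compress_patterns(self.rows)
        self.taxa = taxa
        self.taxon_index = {t: i for i, t in enumerate(taxa)}
        self.patterns = patterns
        self.counts = counts
        self.leaf_partials = _leaf_partials(patterns)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]


def _leaf_partials(patterns: np.ndarray) -> np.ndarray:
    """(n_taxa, n_patterns, 20) one-hot partials; X rows are all-ones."""
    n_taxa, n_pat = patterns.shape
    out = np.zeros((n_taxa, n_pat, N_STATES))
    missing = patterns == MISSING_CODE
    out[missing] = 1.0
    idx_t, idx_p = np.nonzero(~missing)
    out[idx_t, idx_p, patterns[idx_t, idx_p]] = 1.0
    return out


def _site_loglik_one_rate(tree, leaf_partials, taxon_index, model, rate) -> np.ndarray:
    """Per-pattern log-likelihood under a single relative rate."""
    n_pat = leaf_partials.shape[1]
    if rate == 0.0:
        # invariant category: site likelihood is pi[state] if all observed
        # states agree, else 0 (missing leaves impose no constraint)
        lik = np.ones(n_pat)
        partial = np.ones((n_pat, N_STATES))
        for leaf in tree.leaf_node_iter():
            partial *= leaf_partials[taxon_index[leaf.taxon.label]]
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(partial @ model.frequencies, 0.0))
    logscale = np.zeros(n_pat)
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            partials[id(node)] = leaf_partials[taxon_index[node.taxon.label]]
            continue
        acc = np.ones((n_pat, N_STATES))
        for child in node.child_nodes():
            blen = child.edge.length or 0.0
            p = model.transition_matrix(blen * rate)
            acc *= partials.pop(id(child)) @ p.T
        scale = acc.max(axis=1)
        scale[scale == 0.0] = 1.0
        acc /= scale[:, None]
        logscale += np.log(scale)
        partials[id(node)] = acc
    root = tree.seed_node
    lik = partials[id(root)] @ model.frequencies
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def log_likelihood(alignment, tree: dendropy.Tree, model: SubstitutionModel) -> float:
    """Felsenstein-pruning log-likelihood of an ungapped amino-acid alignment.

    The site-rate mixture (invariant class and/or discrete gamma) is summed
    per site in log space; 'X' residues contribute all-ones partials.
    """
    prep = alignment if isinstance(alignment, PreparedAlignment) \
        else PreparedAlignment(_as_rows(alignment))
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaf_labels != set(prep.taxa):
        raise PhyloError(
            f"tree leaves {sorted(leaf_labels)} != alignment taxa {sorted(prep.taxa)}"
        )
    if prep.n_patterns == 0:
        return 0.0
    rates, weights = model.rate_mixture()
    per_cat = np.stack(
        [_site_loglik_one_rate(tree, prep.leaf_partials, prep.taxon_index, model, r)
         for r in rates]
    )
    site_ll = logsumexp(per_cat, axis=0, b=weights[:, None])
    return float(np.dot(prep.counts, site_ll))


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------

P_CLAMP = 0.95  # Poisson correction saturates at d = -ln(0.05)


def protein_distance(a: str, b: str) -> float:
    """Poisson-corrected distance -ln(1-p) over unambiguous aligned sites."""
    if len(a) != len(b) or len(a) == 0:
        raise PhyloError("rows must be nonempty and equal length")
    ca, cb = _encode_row(a), _encode_row(b)
    ok = (ca < N_STATES) & (cb < N_STATES)
    n = int(ok.sum())
    if n == 0:
        raise PhyloError("no comparable (unambiguous) sites")
    p = float((ca[ok] != cb[ok]).sum()) / n
    p = min(p, P_CLAMP)
    return -math.log(1.0 - p)


def distance_matrix(rows: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(rows)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = protein_distance(rows[labels[i]], rows[labels[j]])
    return labels, d


def neighbor_joining(labels: Sequence[str], d: np.ndarray) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; negative branch estimates clamped to 0."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise PhyloError("distance table must be square and match labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise PhyloError("distance table must be symmetric with zero diagonal")
    if len(labels) < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    tree = nj(DistanceMatrix(d, ids=list(labels)))
    buf = StringIO()
    tree.write(buf)
    dtree = parse_newick(buf.getvalue())
    for edge in dtree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return dtree


def parse_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick", unquoted_underscores=True, suppress_rooting=True
    ).strip()


def split_set(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """Non-trivial unrooted splits, each normalized to exclude the anchor
    (lexicographically smallest) taxon, as a hashable topology key."""
    taxa = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(taxa)
    splits = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if anchor in side:
            side = taxa - side
        if 2 <= len(side) <= len(taxa) - 2:
            splits.add(side)
    return frozenset(splits)


# ---------------------------------------------------------------------------
# branch-length optimization and model selection
# ---------------------------------------------------------------------------

MAX_BRANCH = 20.0


@dataclass
class PhyloModelFit:
    tree: dendropy.Tree
    model: SubstitutionModel
    lnL: float
    n_free_params: int

    @property
    def aic(self) -> float:
        return -2.0 * self.lnL + 2.0 * self.n_free_params


def optimize_branch_lengths(
    alignment,
    topology: dendropy.Tree,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 10,
) -> PhyloModelFit:
    """Coordinate-wise Brent optimization of each branch on [0, 20],
    cycling until the round improves lnL by less than `tol`."""
    tree = topology.clone(depth=1)
    rows = alignment if isinstance(alignment, PreparedAlignment) \
        else PreparedAlignment(_as_rows(alignment))
    edges = [nd.edge for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    for e in edges:
        if e.length is None or e.length < 0:
            e.length = 0.1
    current = log_likelihood(rows, tree, model)
    for _ in range(max_rounds):
        round_start = current
        for e in edges:
            def neg(b, _e=e):
                _e.length = b
                return -log_likelihood(rows, tree, model)

            res = minimize_scalar(
                neg, bounds=(0.0, MAX_BRANCH), method="bounded",
                options={"xatol": 1e-4},
            )
            if -res.fun >= current:
                e.length = float(res.x)
                current = -res.fun
            else:  # keep previous value if Brent failed to improve
                neg(e.length)
        if current - round_start < tol:
            break
    n_edges = len(edges)
    return PhyloModelFit(tree, model, current, n_edges + model.n_free_params)


def _fit_candidate(rows, topology, base: SubstitutionModel, use_inv, use_gamma,
                   n_categories=4, outer_cycles=2) -> PhyloModelFit:
    alpha = 0.7 if use_gamma else None
    p_inv = 0.1 if use_inv else None
    model = base.with_rates(alpha=alpha, p_inv=p_inv)
    model.n_categories = n_categories
    fit = optimize_branch_lengths(rows, topology, model)
    for _ in range(outer_cycles if (use_inv or use_gamma) else 0):
        tree = fit.tree
        if use_gamma:
            def neg_a(log_a):
                m = model.with_rates(alpha=math.exp(log_a), p_inv=model.p_inv)
                return -log_likelihood(rows, tree, m)

            res = minimize_scalar(neg_a, bounds=(math.log(0.02), math.log(50.0)),
                                  method="bounded", options={"xatol": 1e-3})
            alpha = math.exp(float(res.x))
        if use_inv:
            def neg_p(p):
                m = model.with_rates(alpha=alpha, p_inv=p)
                return -log_likelihood(rows, tree, m)

            res = minimize_scalar(neg_p, bounds=(1e-6, 0.9), method="bounded",
                                  options={"xatol": 1e-3})
            p_inv = float(res.x)
        model = model.with_rates(alpha=alpha, p_inv=p_inv)
        fit = optimize_branch_lengths(rows, fit.tree, model)
    return fit


def select_model(
    alignment,
    topology: dendropy.Tree,
    candidates: Optional[Iterable[tuple[str, bool, bool, bool]]] = None,
    n_categories: int = 4,
) -> list[PhyloModelFit]:
    """Fit candidate models on a fixed topology and rank by AIC (ascending).

    Candidates are (matrix_name, +I, +G, +F) tuples; the default grid is the
    five built-in matrices crossed with {plain, +I, +G, +I+G} at default
    frequencies. AIC counts branch lengths plus model free parameters
    (alpha, p_inv, and 19 for empirical +F frequencies).
    """
    rows = alignment if isinstance(alignment, PreparedAlignment) \
        else PreparedAlignment(_as_rows(alignment))
    if candidates is None:
        candidates = [
            (name, inv, gam, False)
            for name in BUILTIN_MODELS
            for inv in (False, True)
            for gam in (False, True)
        ]
    candidates = list(candidates)
    if not candidates:
        raise PhyloError("at least one candidate model is required")
    fits = []
    for name, use_inv, use_gamma, use_f in candidates:
        freqs = empirical_frequencies(rows.rows) if use_f else None
        base = load_model(name, frequencies=freqs, n_categories=n_categories)
        fits.append(_fit_candidate(rows, topology, base, use_inv, use_gamma,
                                   n_categories=n_categories))
    return sorted(fits, key=lambda f: f.aic)


# ---------------------------------------------------------------------------
# Bayesian MCMC over topologies
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSample:
    topology_freqs: dict
    clade_posteriors: dict
    consensus_splits: frozenset
    n_samples: int
    n_burnin: int
    settings: dict = field(default_factory=dict)
    acceptance_rate: float = 0.0
    trace: list = field(default_factory=list)


def random_topology(taxa: Sequence[str], rng: np.random.Generator,
                    branch_mean: float = 0.1) -> dendropy.Tree:
    """Uniform-ish random unrooted topology by sequential random attachment."""
    taxa = list(taxa)
    if len(taxa) < 3:
        raise PhyloError("need at least 3 taxa")
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    for lbl in taxa[:3]:
        child = tree.seed_node.new_child()
        child.taxon = tns.get_taxon(lbl)
        child.edge.length = float(rng.exponential(branch_mean))
    for lbl in taxa[3:]:
        edges = [nd.edge for nd in tree.preorder_node_iter()
                 if nd.parent_node is not None]
        target = edges[rng.integers(len(edges))]
        child_node = target.head_node
        parent = child_node.parent_node
        mid = dendropy.Node()
        parent.remove_child(child_node)
        parent.add_child(mid)
        mid.add_child(child_node)
        old = target.length
        mid.edge.length = old / 2.0
        child_node.edge.length = old / 2.0
        leaf = mid.new_child()
        leaf.taxon = tns.get_taxon(lbl)
        leaf.edge.length = float(rng.exponential(branch_mean))
    return tree


def _internal_edges(tree: dendropy.Tree) -> list:
    return [
        nd.edge
        for nd in tree.preorder_internal_node_iter()
        if nd.parent_node is not None
    ]


def _nni_swap(edge, pick_child: int, pick_sib: int):
    """Swap a child of edge.head_node with a sibling subtree; returns the
    (x, y) pair so the caller can undo by swapping back."""
    c = edge.head_node
    p = edge.tail_node
    kids = c.child_nodes()
    sibs = [n for n in p.child_nodes() if n is not c]
    x = kids[pick_child % len(kids)]
    y = sibs[pick_sib % len(sibs)]
    c.remove_child(x)
    p.remove_child(y)
    c.add_child(y)
    p.add_child(x)
    return x, y


def _undo_nni(edge, x, y):
    c = edge.head_node
    p = edge.tail_node
    c.remove_child(y)
    p.remove_child(x)
    c.add_child(x)
    p.add_child(y)


def mcmc_sample(
    alignment,
    model: SubstitutionModel,
    n_generations: int,
    sample_freq: int,
    seed: int,
    burnin_frac: float = 0.25,
    start_tree: Optional[dendropy.Tree] = None,
    branch_prior_mean: float = 0.1,
    alpha_window: float = 10.0,
    pinv_window: float = 0.2,
) -> PosteriorSample:
    """Single-chain Metropolis–Hastings sampler over unrooted topologies.

    Moves: NNI on a random internal edge, branch-length multiplier, and
    sliding windows on the gamma shape (prior Uniform(0,200)) and invariant
    proportion (prior Uniform(0,1)) when the model carries them. Topologies
    are a priori equiprobable; branch lengths have an Exponential prior.
    """
    if n_generations < sample_freq:
        raise PhyloError("n_generations must be at least sample_freq")
    rows = alignment if isinstance(alignment, PreparedAlignment) \
        else PreparedAlignment(_as_rows(alignment))
    taxa = sorted(rows.taxa)
    if len(taxa) < 4:
        raise PhyloError("topology sampling needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    if start_tree is None:
        tree = random_topology(taxa, rng, branch_prior_mean)
    else:
        tree = start_tree.clone(depth=1)
        if not tree.seed_node.is_internal() or len(tree.seed_node.child_nodes()) < 3:
            # re-root as an unrooted (trifurcating) representation
            tree.deroot()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and (nd.edge.length is None or nd.edge.length <= 0):
            nd.edge.length = branch_prior_mean

    alpha = model.alpha
    p_inv = model.p_inv
    prior_rate = 1.0 / branch_prior_mean

    def log_prior_branches() -> float:
        return -prior_rate * sum(
            nd.edge.length for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    def lnL() -> float:
        return log_likelihood(rows, tree, model.with_rates(alpha=alpha, p_inv=p_inv))

    cur_lnl = lnL()
    cur_prior = log_prior_branches()
    moves = ["nni", "brlen"]
    if alpha is not None:
        moves.append("alpha")
    if p_inv is not None:
        moves.append("pinv")

    split_counts: dict[frozenset, int] = {}
    topo_counts: dict[frozenset, int] = {}
    trace = []
    n_samples = 0
    accepted = 0
    total_moves = 0
    n_planned = n_generations // sample_freq
    burn = int(math.floor(burnin_frac * n_planned))

    for gen in range(1, n_generations + 1):
        move = moves[rng.integers(len(moves))]
        total_moves += 1
        if move == "nni":
            internals = _internal_edges(tree)
            if internals:
                edge = internals[rng.integers(len(internals))]
                x, y = _nni_swap(edge, int(rng.integers(2)), int(rng.integers(2)))
                new_lnl = lnL()
                if math.log(rng.random()) < new_lnl - cur_lnl:
                    cur_lnl = new_lnl
                    accepted += 1
                else:
                    _undo_nni(edge, x, y)
        elif move == "brlen":
            edges = [nd.edge for nd in tree.preorder_node_iter()
                     if nd.parent_node is not None]
            edge = edges[rng.integers(len(edges))]
            old = edge.length
            m = math.exp(1.0 * (rng.random() - 0.5))
            edge.length = old * m
            new_lnl = lnL()
            new_prior = cur_prior - prior_rate * (edge.length - old)
            log_ratio = (new_lnl + new_prior) - (cur_lnl + cur_prior) + math.log(m)
            if math.log(rng.random()) < log_ratio:
                cur_lnl, cur_prior = new_lnl, new_prior
                accepted += 1
            else:
                edge.length = old
        elif move == "alpha":
            prop = alpha + (rng.random() - 0.5) * alpha_window
            # reflect into the Uniform(0, 200) prior support
            while prop <= 0.0 or prop >= 200.0:
                prop = -prop if prop <= 0 else 400.0 - prop
            old_alpha, alpha = alpha, prop
            new_lnl = lnL()
            if math.log(rng.random()) < new_lnl - cur_lnl:
                cur_lnl = new_lnl
                accepted += 1
            else:
                alpha = old_alpha
        else:  # pinv
            prop = p_inv + (rng.random() - 0.5) * pinv_window
            while prop < 0.0 or prop >= 1.0:
                prop = -prop if prop < 0 else 2.0 - prop
            old_p, p_inv = p_inv, prop
            new_lnl = lnL()
            if math.log(rng.random()) < new_lnl - cur_lnl:
                cur_lnl = new_lnl
                accepted += 1
            else:
                p_inv = old_p

        if gen % sample_freq == 0:
            n_samples += 1
            if n_samples > burn:
                splits = split_set(tree)
                topo_counts[splits] = topo_counts.get(splits, 0) + 1
                for s in splits:
                    split_counts[s] = split_counts.get(s, 0) + 1
                trace.append({"gen": gen, "lnL": cur_lnl,
                              "alpha": alpha, "p_inv": p_inv})

    kept = n_samples - burn
    topo_freqs = {k: v / kept for k, v in topo_counts.items()}
    clade_post = {k: v / kept for k, v in split_counts.items()}
    consensus = frozenset(s for s, f in clade_post.items() if f > 0.5)
    return PosteriorSample(
        topology_freqs=topo_freqs,
        clade_posteriors=clade_post,
        consensus_splits=consensus,
        n_samples=kept,
        n_burnin=burn,
        settings={
            "n_generations": n_generations,
            "sample_freq": sample_freq,
            "burnin_frac": burnin_frac,
            "seed": seed,
        },
        acceptance_rate=accepted / max(total_moves, 1),
        trace=trace,
    )
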