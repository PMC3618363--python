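"""Global-clock vs local-clock likelihood ratio tests per gene family.

Both fits constrain the rooted topology to be ultrametric in time: the root
age is fixed at 1, each non-root internal node has a free age below its
parent's, and a free overall rate converts ages into expected substitutions
per site. The local model adds one free multiplier r on the focal species'
terminal branch. The test statistic D = -2 (lnL_G - lnL_L) is referred to a
chi-squared distribution with df = 1 (e.g. 11 local vs 10 global free
parameters on an 11-taxon tree); per-gene significance uses a Bonferroni
threshold alpha / m over the m families tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .phylo import PhyloError, PreparedAlignment, SubstitutionModel, log_likelihood
from .util import round_half_away


class ClockError(ValueError):
    pass


@dataclass
class ClockFit:
    tree: dendropy.Tree            # branch lengths in expected subs/site
    ages: dict                     # internal-node key -> age (root = 1.0)
    scale: float                   # substitutions per site per unit age
    rate_multiplier: float         # r on the focal terminal branch (global: 1)
    lnL: float
    n_free_params: int
    mode: str
    focal_taxon: Optional[str]
    x: np.ndarray = None           # optimizer solution, for warm starts


@dataclass(frozen=True)
class ClockTestResult:
    gene_id: str
    lnL_G: float
    lnL_L: float
    D: float
    df: int
    p_raw: float
    alpha_bonf: float
    significant: bool
    r_hat: float
    rate_class: str  # accelerated | decreased | clock-like


def _check_rooted_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_internal_node_iter():
        if len(node.child_nodes()) != 2:
            raise ClockError(
                "clock fits need a rooted binary topology "
                "(root the tree on an outgroup first)"
            )


def clock_free_params(tree: dendropy.Tree, mode: str) -> int:
    """Free parameters of a clock fit: (n_internal - 1) node ages + 1 rate
    scale, plus 1 for the local multiplier."""
    _check_rooted_binary(tree)
    n_internal = sum(1 for _ in tree.preorder_internal_node_iter())
    base = (n_internal - 1) + 1
    return base + (1 if mode == "local" else 0)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _init_fractions(internal_nonroot, depth_below) -> list[float]:
    fracs = []
    for node in internal_nonroot:
        parent_h = depth_below[id(node.parent_node)]
        fracs.append(depth_below[id(node)] / (parent_h + 1e-9))
    return fracs


def fit_clock(
    alignment,
    rooted_topology: dendropy.Tree,
    model: SubstitutionModel,
    mode: str = "global",
    focal_taxon: Optional[str] = None,
    init: Optional["ClockFit"] = None,
    maxiter: int = 300,
) -> ClockFit:
    """Maximum-likelihood clock fit on a fixed rooted binary topology.

    mode="global": one rate everywhere. mode="local": the focal terminal
    branch gets its own multiplier r. Node ages are parameterized as
    fractions of the parent age (logit-transformed), which enforces
    ultrametry without explicit constraints.
    """
    if mode not in ("global", "local"):
        raise ClockError(f"unknown mode {mode!r}")
    tree = rooted_topology.clone(depth=1)
    _check_rooted_binary(tree)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if mode == "local":
        if focal_taxon is None or focal_taxon not in leaves:
            raise ClockError("local mode needs a focal taxon that is a leaf")
    prep = alignment if isinstance(alignment, PreparedAlignment) \
        else PreparedAlignment(dict(alignment))

    internal = list(tree.preorder_internal_node_iter())
    internal_nonroot = [nd for nd in internal if nd.parent_node is not None]
    n_ages = len(internal_nonroot)

    # levels-below heuristic gives a feasible, roughly even age ladder
    depth_below = {}
    for node in tree.postorder_node_iter():
        depth_below[id(node)] = (
            0 if node.is_leaf()
            else 1 + max(depth_below[id(c)] for c in node.child_nodes())
        )

    def unpack(x):
        ages = {id(tree.seed_node): 1.0}
        for node, xi in zip(internal_nonroot, x[:n_ages]):
            ages[id(node)] = ages[id(node.parent_node)] * _sigmoid(xi)
        scale = math.exp(x[n_ages])
        r = math.exp(x[n_ages + 1]) if mode == "local" else 1.0
        return ages, scale, r

    def apply_lengths(ages, scale, r):
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            child_age = ages.get(id(node), 0.0)
            duration = ages[id(node.parent_node)] - child_age
            blen = scale * duration
            if mode == "local" and node.is_leaf() and node.taxon.label == focal_taxon:
                blen *= r
            node.edge.length = blen

    def neg_loglik(x):
        ages, scale, r = unpack(x)
        apply_lengths(ages, scale, r)
        return -log_likelihood(prep, tree, model)

    if init is not None and init.x is not None:
        x0 = list(init.x[: n_ages + 1])
    else:
        fracs = _init_fractions(internal_nonroot, depth_below)
        x0 = [math.log(f / (1 - f)) if 0 < f < 1 else 0.0 for f in fracs]
        x0.append(math.log(_initial_scale(prep)))
    if mode == "local":
        x0.append(0.0)  # r = 1
    x0 = np.asarray(x0, dtype=float)

    res = minimize(neg_loglik, x0, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-10})
    x_best = res.x if res.fun <= neg_loglik(x0) else x0
    ages, scale, r = unpack(x_best)
    apply_lengths(ages, scale, r)
    lnl = -neg_loglik(x_best)
    return ClockFit(
        tree=tree,
        ages={i: a for i, a in ages.items()},
        scale=scale,
        rate_multiplier=r,
        lnL=lnl,
        n_free_params=clock_free_params(tree, mode),
        mode=mode,
        focal_taxon=focal_taxon,
        x=np.asarray(x_best, dtype=float),
    )


def _initial_scale(prep: PreparedAlignment) -> float:
    from .phylo import protein_distance

    rows = prep.rows
    taxa = list(rows)
    dists = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            try:
                dists.append(protein_distance(rows[taxa[i]], rows[taxa[j]]))
            except PhyloError:
                continue
    mean = float(np.mean(dists)) if dists else 0.2
    return max(mean / 2.0, 1e-3)


def clock_lrt(lnl_g: float, lnl_l: float, df: int = 1) -> tuple[float, float]:
    """D = -2 (lnL_G - lnL_L), clamped at 0; chi-squared upper-tail p."""
    if not (math.isfinite(lnl_g) and math.isfinite(lnl_l)):
        raise ClockError("log-likelihoods must be finite")
    d = max(0.0, -2.0 * (lnl_g - lnl_l))
    return d, float(chi2.sf(d, df))


def bonferroni_threshold(alpha: float, m: int) -> float:
    if m < 1:
        raise ClockError("m must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ClockError("alpha must lie in (0, 1)")
    return alpha / m


def rate_scan(
    families: Mapping[str, Mapping[str, str]],
    rooted_topology: dendropy.Tree,
    model: SubstitutionModel,
    focal_taxon: str,
    alpha: float = 0.05,
) -> tuple[list[ClockTestResult], dict]:
    """Per-family global-vs-local clock LRT with Bonferroni correction.

    The local fit is warm-started from the global optimum (at r = 1), so
    lnL_L >= lnL_G holds by construction up to optimizer tolerance.
    Families whose focal rate is significantly above 1 are 'accelerated',
    below 1 'decreased', otherwise 'clock-like'.
    """
    fam_ids = list(families)
    m = len(fam_ids)
    if m == 0:
        return [], {"n_tested": 0, "n_raw_significant": 0,
                    "n_bonferroni_significant": 0, "n_accelerated": 0,
                    "n_decreased": 0, "alpha": alpha, "alpha_bonf": None,
                    "pct_raw_significant": None}
    thr = bonferroni_threshold(alpha, m)
    results = []
    for fam in fam_ids:
        prep = PreparedAlignment(dict(families[fam]))
        g = fit_clock(prep, rooted_topology, model, mode="global",
                      focal_taxon=focal_taxon)
        l = fit_clock(prep, rooted_topology, model, mode="local",
                      focal_taxon=focal_taxon, init=g)
        d, p = clock_lrt(g.lnL, l.lnL)
        sig = p < thr
        if sig and l.rate_multiplier > 1.0:
            cls = "accelerated"
        elif sig and l.rate_multiplier < 1.0:
            cls = "decreased"
        else:
            cls = "clock-like"
        results.append(ClockTestResult(
            gene_id=fam, lnL_G=g.lnL, lnL_L=l.lnL, D=d, df=1, p_raw=p,
            alpha_bonf=thr, significant=sig, r_hat=l.rate_multiplier,
            rate_class=cls,
        ))
    n_raw = sum(1 for r in results if r.p_raw < alpha)
    n_bonf = sum(1 for r in results if r.significant)
    summary = {
        "n_tested": m,
        "n_raw_significant": n_raw,
        "n_bonferroni_significant": n_bonf,
        "n_accelerated": sum(1 for r in results if r.rate_class == "accelerated"),
        "n_decreased": sum(1 for r in results if r.rate_class == "decreased"),
        "alpha": alpha,
        "alpha_bonf": thr,
        "pct_raw_significant": round_half_away(100.0 * n_raw / m, 1),
    }
    return results, summary


def write_results_tsv(path, results: Sequence[ClockTestResult]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlnL_G\tlnL_L\tD\tdf\tp_raw\talpha_bonf\t"
                 "significant\tr_hat\trate_class\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.lnL_G:.6f}\t{r.lnL_L:.6f}\t{r.D:.6f}\t{r.df}\t"
                f"{r.p_raw:.6g}\t{r.alpha_bonf:.6g}\t{int(r.significant)}\t"
                f"{r.r_hat:.6g}\t{r.rate_class}\n"
            )
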