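"""GO DAG handling, level distributions and hypergeometric enrichment.

The ontology is a directed acyclic graph over three namespaces; a term's
level is 1 + the length of its shortest is_a path to the namespace root
(roots are level 1). Gene annotations propagate upward through is_a, so a
gene annotated to a child also counts toward every ancestor. Over- and
under-representation of a term in a study set against a background are two
one-sided hypergeometric tail tests, corrected jointly by the
Benjamini–Yekutieli step-up procedure, which controls the FDR under
arbitrary dependency among tests (as GO term counts certainly are).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom

from .util import round_half_away


class OntologyError(ValueError):
    pass


@dataclass
class GoDag:
    terms: dict                  # id -> {"name", "namespace", "parents": tuple}
    roots: dict                  # namespace -> root term id
    alt_ids: dict = field(default_factory=dict)
    _levels: dict = field(default_factory=dict, repr=False)
    _ancestors: dict = field(default_factory=dict, repr=False)

    def canonical(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.canonical(term) in self.terms

    def ancestors(self, term: str) -> frozenset:
        """The term itself plus all is_a ancestors."""
        term = self.canonical(term)
        if term not in self.terms:
            raise OntologyError(f"unknown GO term {term!r}")
        cached = self._ancestors.get(term)
        if cached is None:
            acc = {term}
            for p in self.terms[term]["parents"]:
                acc |= self.ancestors(p)
            cached = frozenset(acc)
            self._ancestors[term] = cached
        return cached


def parse_obo(path) -> GoDag:
    """Minimal OBO 1.2 reader: id, name, namespace, is_a, alt_id,
    is_obsolete. Obsolete terms are dropped; alt_ids map to their primary."""
    graph = _read_obo_graph(path)
    if not nx.is_directed_acyclic_graph(graph):
        raise OntologyError("is_a relationships contain a cycle")
    terms = {}
    alt_ids = {}
    for node, data in graph.nodes(data=True):
        parents = tuple(sorted(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        ))
        terms[node] = {
            "name": data.get("name", node),
            "namespace": data.get("namespace", ""),
            "parents": parents,
        }
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    roots = {}
    for tid, info in terms.items():
        if not info["parents"]:
            ns = info["namespace"]
            if ns in roots:
                raise OntologyError(f"namespace {ns!r} has multiple roots")
            roots[ns] = tid
    return GoDag(terms=terms, roots=roots, alt_ids=alt_ids)


def _read_obo_graph(path) -> nx.MultiDiGraph:
    import obonet

    return obonet.read_obo(str(path), ignore_obsolete=True)


def term_level(dag: GoDag, term: str) -> int:
    """1 + shortest is_a path length to the namespace root; roots are 1."""
    term = dag.canonical(term)
    if term not in dag.terms:
        raise OntologyError(f"unknown GO term {term!r}")
    if not dag._levels:
        _compute_levels(dag)
    return dag._levels[term]


def _compute_levels(dag: GoDag) -> None:
    from collections import deque

    levels = {}
    queue = deque()
    children: dict[str, list[str]] = {t: [] for t in dag.terms}
    for tid, info in dag.terms.items():
        for p in info["parents"]:
            children[p].append(tid)
    for root in dag.roots.values():
        levels[root] = 1
        queue.append(root)
    while queue:
        cur = queue.popleft()
        for child in children[cur]:
            if child not in levels:
                levels[child] = levels[cur] + 1
                queue.append(child)
    orphans = set(dag.terms) - set(levels)
    if orphans:
        raise OntologyError(f"terms unreachable from any root: {sorted(orphans)[:5]}")
    dag._levels = levels


@dataclass
class AnnotationSet:
    direct: dict  # gene id -> frozenset of direct term ids

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]], dag: GoDag) -> "AnnotationSet":
        out: dict[str, set] = {}
        for gene, term in pairs:
            canon = dag.canonical(term)
            if canon not in dag.terms:
                raise OntologyError(f"annotation uses unknown term {term!r}")
            out.setdefault(gene, set()).add(canon)
        return cls({g: frozenset(ts) for g, ts in out.items()})

    @classmethod
    def read_tsv(cls, path, dag: GoDag) -> "AnnotationSet":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                gene, term = line.split("\t")[:2]
                if gene == "gene_id":
                    continue
                pairs.append((gene, term))
        return cls.from_pairs(pairs, dag)

    def stats(self) -> dict:
        per_gene = [len(ts) for ts in self.direct.values()]
        total = sum(per_gene)
        unique = len(set().union(*self.direct.values())) if self.direct else 0
        return {
            "genes_annotated": len(self.direct),
            "total_mappings": total,
            "unique_terms": unique,
            "mean_per_gene": round_half_away(total / len(per_gene), 1)
            if per_gene else None,
            "min_per_gene": min(per_gene) if per_gene else None,
            "max_per_gene": max(per_gene) if per_gene else None,
        }

    def propagated(self, dag: GoDag) -> dict:
        """gene -> set of terms after upward is_a propagation."""
        cache: dict[frozenset, frozenset] = {}
        out = {}
        for gene, terms in self.direct.items():
            if terms not in cache:
                acc = set()
                for t in terms:
                    acc |= dag.ancestors(t)
                cache[terms] = frozenset(acc)
            out[gene] = cache[terms]
        return out


def level_distribution(
    dag: GoDag, annotations: AnnotationSet, level: int
) -> list[dict]:
    """Percentage of annotated genes mapping to each level-`level` term.

    A gene counts toward a term if any of its direct annotations is the term
    or one of its descendants. Denominators are namespace-specific: the
    number of genes with at least one propagated term in that namespace.
    """
    if level < 1:
        raise OntologyError("level must be >= 1")
    prop = annotations.propagated(dag)
    ns_of = {t: dag.terms[t]["namespace"] for t in dag.terms}
    ns_denoms: dict[str, int] = {ns: 0 for ns in dag.roots}
    for terms in prop.values():
        seen = {ns_of[t] for t in terms}
        for ns in seen:
            ns_denoms[ns] += 1
    counts: dict[str, int] = {}
    for terms in prop.values():
        for t in terms:
            if term_level(dag, t) == level:
                counts[t] = counts.get(t, 0) + 1
    rows = []
    for t, k in counts.items():
        ns = ns_of[t]
        denom = ns_denoms[ns]
        rows.append({
            "term": t,
            "name": dag.terms[t]["name"],
            "namespace": ns,
            "level": level,
            "genes": k,
            "denominator": denom,
            "pct": round_half_away(100.0 * k / denom, 1) if denom else None,
        })
    rows.sort(key=lambda r: (-r["genes"], r["term"]))
    return rows


def hypergeom_test(k: int, n: int, K: int, N: int, direction: str) -> float:
    """Tail probability of Hypergeometric(N, K, n) at the observed k.

    direction='enriched': P(X >= k); 'diminished': P(X <= k).
    """
    if not (0 <= k <= n <= N) or not (0 <= K <= N) or k > K:
        raise OntologyError(
            f"inconsistent counts k={k}, n={n}, K={K}, N={N}"
        )
    if direction == "enriched":
        return float(hypergeom.sf(k - 1, N, K, n))
    if direction == "diminished":
        return float(hypergeom.cdf(k, N, K, n))
    raise OntologyError(f"unknown direction {direction!r}")


def by_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up adjusted values (original order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise OntologyError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, adj, _, _ = multipletests(p, method="fdr_by")
    return adj


@dataclass(frozen=True)
class EnrichmentRecord:
    term: str
    name: str
    namespace: str
    level: int
    direction: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float
    significant: bool


def enrichment_scan(
    dag: GoDag,
    study: AnnotationSet,
    background: AnnotationSet,
    level_filter: Optional[int] = None,
    fdr_level: float = 0.05,
) -> list[EnrichmentRecord]:
    """Two one-sided hypergeometric tests per background term, BY-corrected
    jointly over all (term, direction) tests."""
    if not background.direct:
        raise OntologyError("background annotation set is empty")
    study_prop = study.propagated(dag)
    bg_prop = background.propagated(dag)
    n = len(study_prop)
    N = len(bg_prop)
    bg_counts: dict[str, int] = {}
    for terms in bg_prop.values():
        for t in terms:
            bg_counts[t] = bg_counts.get(t, 0) + 1
    study_counts: dict[str, int] = {}
    for terms in study_prop.values():
        for t in terms:
            study_counts[t] = study_counts.get(t, 0) + 1
    tests = []
    for t, K in sorted(bg_counts.items()):
        lvl = term_level(dag, t)
        if level_filter is not None and lvl != level_filter:
            continue
        k = min(study_counts.get(t, 0), K)
        for direction in ("enriched", "diminished"):
            p = hypergeom_test(k, n, K, N, direction)
            tests.append((t, lvl, direction, k, K, p))
    qs = by_fdr([t[-1] for t in tests])
    records = []
    for (t, lvl, direction, k, K, p), q in zip(tests, qs):
        records.append(EnrichmentRecord(
            term=t, name=dag.terms[t]["name"],
            namespace=dag.terms[t]["namespace"], level=lvl,
            direction=direction, k=k, n=n, K=K, N=N,
            p=p, q=float(q), significant=bool(q < fdr_level),
        ))
    records.sort(key=lambda r: (r.q, r.p, r.term, r.direction))
    return records


def write_enrichment_tsv(path, records: Sequence[EnrichmentRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("term\tname\tnamespace\tlevel\tdirection\tk\tn\tK\tN\tp\tq\t"
                 "significant\n")
        for r in records:
            fh.write(
                f"{r.term}\t{r.name}\t{r.namespace}\t{r.level}\t{r.direction}\t"
                f"{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p:.6g}\t{r.q:.6g}\t"
                f"{int(r.significant)}\n"
            )
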