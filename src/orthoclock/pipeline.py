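"""End-to-end orchestration on synthetic or on-disk inputs.

Stages run in order: simulate -> translate -> orthologs -> supermatrix ->
tree -> (modelselect) -> (mcmc) -> ratescan -> go. Each stage writes its
artifacts under the run directory and later stages reload them from disk
when their producing stage is toggled off, so runs can be resumed. The
run report collects the per-stage counts and every derived percentage or
mean, computed with the global rounding convention (ties away from zero).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

from . import clock, go, orf, orthology, phylo, supermatrix, synthetic
from .util import read_fasta, round_half_away, write_fasta

log = logging.getLogger("orthoclock")


class PipelineError(RuntimeError):
    pass


def summarize_counts(
    numerator: float, denominator: float, decimals: int, mode: str = "percentage"
) -> float:
    """Reported percentage (100*num/den) or mean (num/den), rounded half
    away from zero to `decimals`."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    value = numerator / denominator
    if mode == "percentage":
        value *= 100.0
    elif mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    return round_half_away(value, decimals)


ALL_STAGES = (
    "simulate", "translate", "orthologs", "supermatrix", "tree",
    "modelselect", "mcmc", "ratescan", "go",
)
DEFAULT_STAGES = (
    "simulate", "translate", "orthologs", "supermatrix", "tree",
    "ratescan", "go",
)


@dataclass
class RunConfig:
    outdir: str
    scenario: synthetic.SimScenario = field(default_factory=synthetic.SimScenario)
    stages: Sequence[str] = DEFAULT_STAGES
    alpha: float = 0.05
    fdr_level: float = 0.05
    min_score: int = orthology.DEFAULT_MIN_SCORE
    model_name: str = "WAG"
    mcmc_generations: int = 4000
    mcmc_sample_freq: int = 10
    burnin_frac: float = 0.25
    go_n_terms: int = 60
    go_max_depth: int = 5
    go_n_genes: int = 400
    go_study_size: int = 150
    go_planted: Sequence[tuple[str, float]] = ()

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")

    def path(self, *parts) -> str:
        return os.path.join(self.outdir, *parts)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["go_planted"] = [list(p) for p in self.go_planted]
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)

    def percentage(self, key: str, numerator: int, denominator: int,
                   decimals: int = 1) -> None:
        self.derived[key] = {
            "numerator": numerator,
            "denominator": denominator,
            "value": summarize_counts(numerator, denominator, decimals),
        }

    def mean(self, key: str, numerator: float, denominator: float,
             decimals: int = 1) -> None:
        self.derived[key] = {
            "numerator": numerator,
            "denominator": denominator,
            "value": summarize_counts(numerator, denominator, decimals, "mean"),
        }

    def to_json(self) -> str:
        return json.dumps({"counts": self.counts, "derived": self.derived},
                          indent=2, sort_keys=True)


def _stage(name, config):
    if name not in ALL_STAGES:
        raise PipelineError(f"unknown stage {name}")
    return name in config.stages


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages; returns the run report.

    Any stage failure raises PipelineError labeled with the stage; artifacts
    written before the failure are left in place.
    """
    os.makedirs(config.outdir, exist_ok=True)
    os.makedirs(config.path("proteomes"), exist_ok=True)
    os.makedirs(config.path("families"), exist_ok=True)
    with open(config.path("config.json"), "w") as fh:
        fh.write(config.to_json())
    report = RunReport()
    model = phylo.load_model(config.model_name)
    try:
        truth = _run_simulate(config, report) if _stage("simulate", config) else None
        _run_translate(config, report)
        groups = _run_orthologs(config, report)
        matrix = _run_supermatrix(config, report, groups, truth)
        topo = _run_tree(config, report, matrix)
        if _stage("modelselect", config):
            _run_modelselect(config, report, matrix, topo)
        if _stage("mcmc", config):
            _run_mcmc(config, report, matrix, model)
        _run_ratescan(config, report, model)
        _run_go(config, report)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - label with the failing stage
        raise PipelineError(f"pipeline failed: {exc}") from exc
    with open(config.path("report.json"), "w") as fh:
        fh.write(report.to_json())
    return report


def _run_simulate(config: RunConfig, report: RunReport):
    sc = config.scenario
    log.info("simulate: %d taxa, %d families", sc.n_taxa, sc.n_families)
    proteomes, truth = synthetic.make_proteomes(sc)
    synthetic.write_proteomes(proteomes, config.path("proteomes"))
    with open(config.path("species_tree.nwk"), "w") as fh:
        fh.write(phylo.to_newick(truth.tree) + "\n")
    contigs, contig_truth = synthetic.make_contigs(
        proteomes[sc.focal_taxon], seed=sc.seed + 101,
        truncated_start_frac=0.1, short_decoy_frac=0.05,
    )
    write_fasta(config.path("contigs.fna"), contigs)
    for fam, rows in truth.family_alignments.items():
        write_fasta(config.path("families", f"{fam}.faa"), sorted(rows.items()))
    fixture = synthetic.make_go_fixture(
        n_terms=config.go_n_terms, max_depth=config.go_max_depth,
        n_genes=config.go_n_genes, planted_terms=list(config.go_planted),
        seed=sc.seed + 202, study_size=config.go_study_size,
    )
    fixture.write(config.path("ontology.obo"), config.path("annotations.tsv"))
    with open(config.path("study_genes.txt"), "w") as fh:
        fh.write("\n".join(fixture.study_genes) + "\n")
    with open(config.path("truth.json"), "w") as fh:
        json.dump({
            "ortholog_pairs": sorted(map(list, truth.ortholog_pairs)),
            "complete_families": truth.complete_families,
            "family_rate_class": truth.family_rate_class,
            "planted_go": {t: list(v) for t, v in fixture.planted.items()},
            "n_planted_contigs": sum(
                0 if t.is_decoy else 1 for t in contig_truth.values()
            ),
        }, fh, indent=2, sort_keys=True)
    report.counts["n_species"] = sc.n_taxa
    report.counts["n_families_simulated"] = sc.n_families
    report.counts["n_contigs"] = len(contigs)
    return truth


def _run_translate(config: RunConfig, report: RunReport):
    if not _stage("translate", config):
        return
    contigs = orf.read_contigs(config.path("contigs.fna"))
    products, summary = orf.translate_set(contigs)
    orf.write_orfs(config.path("orfs.faa"), products)
    with open(config.path("orf_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    report.counts["n_contigs_translated"] = summary["count"]
    report.counts["orf_total_aa"] = summary["total_aa"]
    if summary["count"]:
        report.mean("mean_orf_length_aa", summary["total_aa"], summary["count"], 0)


def _load_proteomes(config: RunConfig) -> dict[str, list[tuple[str, str]]]:
    out = {}
    for sp in config.scenario.species:
        path = config.path("proteomes", f"{sp}.faa")
        if not os.path.exists(path):
            raise PipelineError(f"orthologs: missing proteome {path}")
        out[sp] = read_fasta(path)
    return out


def _run_orthologs(config: RunConfig, report: RunReport):
    groups_path = config.path("groups.tsv")
    if not _stage("orthologs", config):
        return _read_groups(groups_path) if os.path.exists(groups_path) else None
    sc = config.scenario
    proteomes = _load_proteomes(config)
    reference = sc.reference_taxon
    rbh_maps = {}
    with open(config.path("rbh_pairs.tsv"), "w") as fh:
        fh.write("species\tspecies_gene\treference_gene\n")
        for sp in sc.species:
            if sp == reference:
                continue
            pairs = orthology.reciprocal_best_hits(
                proteomes[sp], proteomes[reference], min_score=config.min_score
            )
            rbh_maps[sp] = pairs
            for sgene, rgene in sorted(pairs):
                fh.write(f"{sp}\t{sgene}\t{rgene}\n")
    groups = orthology.build_groups(rbh_maps, sc.species, reference)
    with open(groups_path, "w") as fh:
        fh.write("reference_gene\tspecies\tgene_id\n")
        for g in groups:
            for sp in sc.species:
                fh.write(f"{g.reference_gene}\t{sp}\t{g.members[sp]}\n")
    report.counts["n_rbh_pairs"] = sum(len(p) for p in rbh_maps.values())
    report.counts["n_ortholog_groups"] = len(groups)
    return groups


def _read_groups(path) -> list[orthology.OrthologGroup]:
    by_ref: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            rgene, sp, gene = line.rstrip("\n").split("\t")
            by_ref.setdefault(rgene, {})[sp] = gene
    return [
        orthology.OrthologGroup(reference_gene=r, members=m)
        for r, m in sorted(by_ref.items())
    ]


def _family_of_reference_gene(rgene: str) -> str:
    # synthetic gene ids are "<species>_<family>"
    return rgene.split("_", 1)[1]


def _run_supermatrix(config: RunConfig, report: RunReport, groups, truth):
    fasta_path = config.path("supermatrix.fasta")
    if not _stage("supermatrix", config):
        if os.path.exists(fasta_path):
            rows = dict(read_fasta(fasta_path))
            return supermatrix.SuperMatrix(
                species_order=list(rows), rows=list(rows.values()),
                spans=[("all", 1, len(next(iter(rows.values()))))],
            )
        return None
    sc = config.scenario
    if groups is None:
        raise PipelineError("supermatrix: no ortholog groups available")
    fams = []
    for g in groups:
        fam_id = _family_of_reference_gene(g.reference_gene)
        path = config.path("families", f"{fam_id}.faa")
        if not os.path.exists(path):
            raise PipelineError(f"supermatrix: missing family alignment {path}")
        fams.append(supermatrix.FamilyAlignment(fam_id, dict(read_fasta(path))))
    matrix = supermatrix.concatenate(fams, sc.species)
    filtered, rep = supermatrix.strip_gap_columns(matrix)
    supermatrix.write_fasta_matrix(fasta_path, filtered)
    supermatrix.write_phylip(config.path("supermatrix.phy"), filtered)
    supermatrix.write_spans(config.path("spans.tsv"), filtered)
    report.counts["supermatrix_width_before"] = rep["original_width"]
    report.counts["supermatrix_width_after"] = rep["retained_width"]
    if rep["original_width"]:
        report.percentage("pct_columns_retained", rep["retained_width"],
                          rep["original_width"], 1)
    return filtered


def _run_tree(config: RunConfig, report: RunReport, matrix):
    path = config.path("nj_tree.nwk")
    if not _stage("tree", config):
        return phylo.parse_newick(open(path).read()) if os.path.exists(path) else None
    if matrix is None or matrix.width == 0:
        raise PipelineError("tree: no supermatrix available")
    labels, d = phylo.distance_matrix(matrix.row_map())
    tree = phylo.neighbor_joining(labels, d)
    with open(path, "w") as fh:
        fh.write(phylo.to_newick(tree) + "\n")
    report.counts["nj_tree_taxa"] = len(labels)
    return tree


def _run_modelselect(config: RunConfig, report: RunReport, matrix, topo):
    if matrix is None or topo is None:
        raise PipelineError("modelselect: needs supermatrix and topology")
    candidates = [(name, False, False, False) for name in phylo.BUILTIN_MODELS]
    fits = phylo.select_model(matrix.row_map(), topo, candidates=candidates)
    with open(config.path("modelselect.tsv"), "w") as fh:
        fh.write("model\tlnL\tk\tAIC\n")
        for f in fits:
            fh.write(f"{f.model.label}\t{f.lnL:.4f}\t{f.n_free_params}\t{f.aic:.4f}\n")
    report.counts["best_model"] = fits[0].model.label
    return fits


def _run_mcmc(config: RunConfig, report: RunReport, matrix, model):
    if matrix is None:
        raise PipelineError("mcmc: needs a supermatrix")
    rows = matrix.row_map()
    labels, d = phylo.distance_matrix(rows)
    start = phylo.neighbor_joining(labels, d)
    post = phylo.mcmc_sample(
        rows, model, n_generations=config.mcmc_generations,
        sample_freq=config.mcmc_sample_freq, seed=config.scenario.seed + 303,
        burnin_frac=config.burnin_frac, start_tree=start,
    )
    payload = {
        "n_samples": post.n_samples,
        "n_burnin": post.n_burnin,
        "acceptance_rate": post.acceptance_rate,
        "consensus_splits": [sorted(s) for s in sorted(post.consensus_splits,
                                                       key=sorted)],
        "clade_posteriors": {
            "|".join(sorted(s)): f for s, f in sorted(
                post.clade_posteriors.items(), key=lambda kv: sorted(kv[0])
            )
        },
    }
    with open(config.path("mcmc_posterior.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    report.counts["mcmc_samples"] = post.n_samples
    report.counts["mcmc_min_clade_posterior"] = (
        min(post.clade_posteriors[s] for s in post.consensus_splits)
        if post.consensus_splits else None
    )
    return post


def _run_ratescan(config: RunConfig, report: RunReport, model):
    if not _stage("ratescan", config):
        return None
    sc = config.scenario
    tree = phylo.parse_newick(open(config.path("species_tree.nwk")).read())
    groups_path = config.path("groups.tsv")
    fam_ids = sorted({
        _family_of_reference_gene(r)
        for r in (g.reference_gene for g in _read_groups(groups_path))
    }) if os.path.exists(groups_path) else []
    families = {}
    for fam in fam_ids:
        rows = dict(read_fasta(config.path("families", f"{fam}.faa")))
        families[fam] = rows
    results, summary = clock.rate_scan(
        families, tree, model, focal_taxon=sc.focal_taxon, alpha=config.alpha
    )
    clock.write_results_tsv(config.path("ratescan.tsv"), results)
    with open(config.path("ratescan_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    report.counts["n_rate_tested"] = summary["n_tested"]
    report.counts["n_raw_significant"] = summary["n_raw_significant"]
    report.counts["n_bonferroni_significant"] = summary["n_bonferroni_significant"]
    report.counts["n_accelerated"] = summary["n_accelerated"]
    report.counts["n_decreased"] = summary["n_decreased"]
    if summary["n_tested"]:
        report.percentage("pct_raw_significant", summary["n_raw_significant"],
                          summary["n_tested"], 1)
    return results


def _run_go(config: RunConfig, report: RunReport):
    if not _stage("go", config):
        return None
    dag = go.parse_obo(config.path("ontology.obo"))
    background = go.AnnotationSet.read_tsv(config.path("annotations.tsv"), dag)
    with open(config.path("study_genes.txt")) as fh:
        study_genes = [line.strip() for line in fh if line.strip()]
    study = go.AnnotationSet(
        {g: background.direct[g] for g in study_genes if g in background.direct}
    )
    stats = background.stats()
    report.counts["go_genes_annotated"] = stats["genes_annotated"]
    report.counts["go_total_mappings"] = stats["total_mappings"]
    report.counts["go_unique_terms"] = stats["unique_terms"]
    report.mean("mean_go_terms_per_gene", stats["total_mappings"],
                stats["genes_annotated"], 1)
    for level in (3, 4):
        rows = go.level_distribution(dag, background, level)
        with open(config.path(f"go_level{level}.tsv"), "w") as fh:
            fh.write("term\tname\tnamespace\tgenes\tdenominator\tpct\n")
            for r in rows:
                fh.write(f"{r['term']}\t{r['name']}\t{r['namespace']}\t"
                         f"{r['genes']}\t{r['denominator']}\t{r['pct']}\n")
    records = go.enrichment_scan(dag, study, background,
                                 fdr_level=config.fdr_level)
    go.write_enrichment_tsv(config.path("go_enrichment.tsv"), records)
    report.counts["go_tests"] = len(records)
    report.counts["go_significant"] = sum(1 for r in records if r.significant)
    return records
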