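"""Synthetic benchmark cohorts with the statistical structure the
pipeline assumes.

The generator emulates, at desk scale, the inputs of a spike-in
benchmark: a rooted phenotype DAG, a disease catalog annotating each
disease to a handful of terms and linking it to one or more genes
(genetic heterogeneity), noisy patient term queries (dropout plus
unrelated noise terms), gestalt similarity vectors in which the true
syndrome's score is shifted upward by a tunable signal, per-ethnicity
background exome score maps, and causal-variant deleteriousness draws.

Every stage is deterministic under the config seed, with one RNG stream
per purpose (ontology, catalog, each case), so adding cases does not
perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .data_model import CaseRecord, Cohort, save_cohort
from .hpo_similarity import (
    DiseaseAnnotationCatalog,
    ICMap,
    OntologyGraph,
    compute_ic,
    score_all_diseases,
    write_annotation_catalog,
    write_obo,
)
from .syndrome_gene_mapping import (
    GenePhenotypeMap,
    map_scores_to_genes,
    write_gene_map,
)
from .variant_scores import GeneMaxScoreMap, spike_in
from .classifier import assemble_case_table

ROOT_TERM = "HP:0000001"


@dataclass
class SyntheticConfig:
    """Shape and noise parameters of a generated cohort.

    Ontology: ``n_terms`` terms in a rooted DAG; each non-root term
    attaches to a parent with at most ``dag_branching`` children (when
    available) and gains a second parent with probability
    ``multi_parent_prob``.

    Catalog: ``n_diseases`` diseases, each annotated to
    ``terms_per_disease`` non-root terms and linked to
    ``genes_per_disease`` genes drawn from a shared pool sized so some
    genes serve several diseases (heterogeneity).

    Queries: each annotation term is dropped with probability
    ``term_dropout_rate`` (at least one is always retained) and
    ``Binomial(|annotation|, noise_term_rate)`` unrelated terms are
    added.

    Gestalt: per syndrome an exponential noise baseline (scale
    ``gestalt_noise_scale``); the true syndrome's entry is shifted up by
    ``gestalt_signal``.

    Exomes: per ethnicity tag, ``n_background_genes`` genes survive
    filtering; their scores follow ``background_score_distribution``
    (default Beta(2,5) scaled to [0,40]: right-skewed, most genes
    low-scoring) and the causal variant follows
    ``causal_score_distribution`` (default Normal(28,4) truncated at 0).
    These are plausible CADD-PHRED shapes chosen once for the benchmark.
    """

    n_terms: int = 60
    dag_branching: int = 3
    multi_parent_prob: float = 0.15
    n_diseases: int = 20
    genes_per_disease: int = 2
    terms_per_disease: int = 6
    term_dropout_rate: float = 0.2
    noise_term_rate: float = 0.1
    gestalt_signal: float = 0.5
    gestalt_noise_scale: float = 0.1
    n_background_genes: dict[str, int] = field(
        default_factory=lambda: {"EUR": 60, "EAS": 60, "AFR": 90}
    )
    background_score_distribution: dict = field(
        default_factory=lambda: {"name": "beta_scaled", "a": 2.0, "b": 5.0, "scale": 40.0}
    )
    causal_score_distribution: dict = field(
        default_factory=lambda: {"name": "truncnorm", "mean": 28.0, "sd": 4.0}
    )
    n_cases: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("multi_parent_prob", "term_dropout_rate", "noise_term_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_diseases < 2:
            raise ValueError("n_diseases must be >= 2")
        if self.genes_per_disease < 1:
            raise ValueError("genes_per_disease must be >= 1")
        if self.terms_per_disease > self.n_terms - 1:
            raise ValueError("terms_per_disease exceeds available non-root terms")
        if self.gestalt_signal < 0:
            raise ValueError("gestalt_signal must be >= 0")


def _draw(dist: Mapping, rng: np.random.Generator, size: int | None = None):
    """Draw from a named nonnegative distribution."""
    name = dist["name"]
    if name == "beta_scaled":
        return dist["scale"] * rng.beta(dist["a"], dist["b"], size=size)
    if name == "truncnorm":
        x = rng.normal(dist["mean"], dist["sd"], size=size)
        return np.maximum(x, 0.0)
    if name == "uniform":
        return rng.uniform(dist["low"], dist["high"], size=size)
    raise ValueError(f"unknown distribution {name!r}")


def _rng(config_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, *stream]))


def _term_id(i: int) -> str:
    return f"HP:{i + 1:07d}"


def make_ontology_and_catalog(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[OntologyGraph, DiseaseAnnotationCatalog, GenePhenotypeMap]:
    """Generate the rooted DAG, the disease annotations, and the
    syndrome<->gene map; deterministic given the seed."""
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 1)

    terms = [_term_id(i) for i in range(config.n_terms)]
    edges: dict[str, set[str]] = {t: set() for t in terms}
    child_count = {t: 0 for t in terms}
    for i in range(1, config.n_terms):
        open_parents = [t for t in terms[:i] if child_count[t] < config.dag_branching]
        pool = open_parents or terms[:i]
        parent = pool[rng.integers(len(pool))]
        edges[terms[i]].add(parent)
        child_count[parent] += 1
        if i >= 2 and rng.random() < config.multi_parent_prob:
            others = [t for t in terms[:i] if t != parent]
            extra = others[rng.integers(len(others))]
            edges[terms[i]].add(extra)
    ontology = OntologyGraph(terms=set(terms), is_a_edges=edges, root=terms[0])

    non_root = terms[1:]
    annotations: dict[str, set[str]] = {}
    for d in range(config.n_diseases):
        picked = rng.choice(len(non_root), size=config.terms_per_disease, replace=False)
        annotations[f"OMIM:{600001 + d}"] = {non_root[j] for j in picked}
    catalog = DiseaseAnnotationCatalog(annotations)

    # gene pool ~15% smaller than diseases x genes_per_disease so some
    # genes are shared across syndromes (heterogeneity)
    n_slots = config.n_diseases * config.genes_per_disease
    pool_size = max(config.genes_per_disease, int(round(n_slots * 0.85)))
    pool = [f"GENE{i + 1:04d}" for i in range(pool_size)]
    gmap = GenePhenotypeMap()
    for d in sorted(annotations):
        picked = rng.choice(pool_size, size=config.genes_per_disease, replace=False)
        for j in picked:
            gmap.add(d, pool[j])
    return ontology, catalog, gmap


def simulate_case(
    disease_id: str,
    catalog: DiseaseAnnotationCatalog,
    gmap: GenePhenotypeMap,
    config: SyntheticConfig,
    rng: np.random.Generator,
    ontology: OntologyGraph,
    case_id: str = "case",
) -> CaseRecord:
    """One noisy patient record for a given disease.

    The HPO query is the disease annotation after dropout draws (never
    emptied: one annotation term is retained if all were dropped) plus
    noise-term draws from the rest of the ontology; the gestalt vector
    is exponential baseline noise with the signal added to the true
    syndrome's entry; the causal gene is uniform over the disease's
    genes.
    """
    annotation = sorted(catalog.annotations[disease_id])
    kept = [t for t in annotation if rng.random() >= config.term_dropout_rate]
    if not kept:
        kept = [annotation[rng.integers(len(annotation))]]
    n_noise = rng.binomial(len(annotation), config.noise_term_rate)
    if n_noise:
        outside = sorted(ontology.terms - set(annotation) - {ontology.root})
        picked = rng.choice(len(outside), size=min(n_noise, len(outside)), replace=False)
        kept.extend(outside[j] for j in picked)

    gestalt = {}
    for syndrome in sorted(catalog.annotations):
        score = rng.exponential(config.gestalt_noise_scale)
        if syndrome == disease_id:
            score += config.gestalt_signal
        gestalt[syndrome] = max(score, 0.0)

    genes = sorted(gmap.syndrome_to_genes[disease_id])
    causal_gene = genes[rng.integers(len(genes))]
    causal_score = float(_draw(config.causal_score_distribution, rng))
    tags = sorted(config.n_background_genes)
    ethnicity = tags[rng.integers(len(tags))]
    return CaseRecord(
        case_id=case_id,
        hpo_terms=set(kept),
        diagnosis_id=disease_id,
        causal_gene=causal_gene,
        causal_variant_score=causal_score,
        gestalt_scores=gestalt,
        ethnicity=ethnicity,
    )


def _background_exome(
    config: SyntheticConfig,
    gene_universe: list[str],
    ethnicity: str,
    rng: np.random.Generator,
) -> GeneMaxScoreMap:
    n = min(config.n_background_genes[ethnicity], len(gene_universe))
    picked = rng.choice(len(gene_universe), size=n, replace=False)
    scores = _draw(config.background_score_distribution, rng, size=n)
    return GeneMaxScoreMap(
        {gene_universe[j]: float(s) for j, s in zip(picked, scores)}
    )


@dataclass
class GeneratedCohort:
    """A cohort plus the fixtures it was generated from."""

    cohort: Cohort
    ontology: OntologyGraph
    catalog: DiseaseAnnotationCatalog
    gmap: GenePhenotypeMap
    ic_map: ICMap
    gestalt_by_gene: dict[str, dict[str, float]]


def generate_cohort(config: SyntheticConfig, with_fixtures: bool = False):
    """Generate ``n_cases`` cases cycling over the diseases, with
    assembled five-score tables.

    Per case: a background exome is sampled for the case's ethnicity,
    the causal variant spiked in, the three semantic scores computed
    from the noisy query and mapped to genes, the gestalt vector mapped
    to genes, and the table assembled over the exome's candidate genes.
    """
    ontology, catalog, gmap = make_ontology_and_catalog(config)
    ic_map = compute_ic(ontology, catalog)
    diseases = sorted(catalog.annotations)
    mapped_genes = sorted(gmap.gene_to_syndromes)
    # background pool: every disease gene plus enough unmapped genes that
    # the largest per-ethnicity exome still subsamples the universe
    n_extra = max(
        3 * len(mapped_genes),
        2 * max(config.n_background_genes.values()) - len(mapped_genes),
    )
    gene_universe = mapped_genes + [f"BG{i + 1:04d}" for i in range(n_extra)]

    cases, tables = [], {}
    gestalt_by_gene: dict[str, dict[str, float]] = {}
    for i in range(config.n_cases):
        rng = _rng(config.seed, 2, i)
        disease = diseases[i % len(diseases)]
        case = simulate_case(
            disease, catalog, gmap, config, rng, ontology, case_id=f"case{i + 1:04d}"
        )
        background = _background_exome(config, gene_universe, case.ethnicity, rng)
        exome = spike_in(background, case.causal_gene, case.causal_variant_score)
        triples = score_all_diseases(case.hpo_terms, catalog, ontology, ic_map)
        fm = map_scores_to_genes({d: v[0] for d, v in triples.items()}, gmap)
        phen = map_scores_to_genes({d: v[1] for d, v in triples.items()}, gmap)
        boqa = map_scores_to_genes({d: v[2] for d, v in triples.items()}, gmap)
        gestalt = map_scores_to_genes(case.gestalt_scores, gmap)
        gestalt_by_gene[case.case_id] = gestalt
        tables[case.case_id] = assemble_case_table(
            case, exome, gestalt, fm, phen, boqa, fill=0.0
        )
        cases.append(case)
    cohort = Cohort(cases=cases, tables=tables)
    if with_fixtures:
        return GeneratedCohort(cohort, ontology, catalog, gmap, ic_map, gestalt_by_gene)
    return cohort


def export_inputs(generated: GeneratedCohort, directory: str | Path) -> None:
    """Write the generated cohort in the same dialects the pipeline
    reads back (case JSONs, OBO ontology, annotation TSV, morbidmap
    TSV) — the parsers are exercised on generator output."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_cohort(generated.cohort, directory / "cases")
    write_obo(generated.ontology, directory / "ontology.obo")
    write_annotation_catalog(generated.catalog, directory / "annotations.tsv")
    write_gene_map(
        generated.gmap, directory / "morbidmap.tsv", directory / "mim2gene.tsv"
    )
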