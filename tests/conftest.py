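import numpy as np
import pytest

from pediascore.hpo_similarity import (
    DiseaseAnnotationCatalog,
    OntologyGraph,
    compute_ic,
)
from pediascore.synthetic_cohort import SyntheticConfig, generate_cohort


def random_dag(rng: np.random.Generator, n_terms: int, multi_parent_prob: float = 0.3):
    """Rooted random DAG over HP:-style term ids (edges point to earlier terms)."""
    terms = [f"HP:{i + 1:07d}" for i in range(n_terms)]
    edges = {t: set() for t in terms}
    for i in range(1, n_terms):
        edges[terms[i]].add(terms[rng.integers(i)])
        if i >= 2 and rng.random() < multi_parent_prob:
            edges[terms[i]].add(terms[rng.integers(i)])
    return OntologyGraph(terms=set(terms), is_a_edges=edges, root=terms[0])


def random_catalog(rng: np.random.Generator, ontology: OntologyGraph, n_diseases: int,
                   terms_per_disease: int = 4) -> DiseaseAnnotationCatalog:
    non_root = sorted(ontology.terms - {ontology.root})
    return DiseaseAnnotationCatalog(
        {
            f"OMIM:{600001 + d}": {
                non_root[j]
                for j in rng.choice(
                    len(non_root),
                    size=min(terms_per_disease, len(non_root)),
                    replace=False,
                )
            }
            for d in range(n_diseases)
        }
    )


@pytest.fixture
def toy_ontology():
    """Diamond DAG: root A; B,C -> A; D -> B,C; E -> D; F -> C."""
    edges = {
        "A": set(),
        "B": {"A"},
        "C": {"A"},
        "D": {"B", "C"},
        "E": {"D"},
        "F": {"C"},
    }
    return OntologyGraph(terms=set(edges), is_a_edges=edges, root="A")


@pytest.fixture
def toy_catalog(toy_ontology):
    return DiseaseAnnotationCatalog(
        {"OMIM:1": {"E"}, "OMIM:2": {"B", "F"}, "OMIM:3": {"C"}}
    )


@pytest.fixture
def toy_ic(toy_ontology, toy_catalog):
    return compute_ic(toy_ontology, toy_catalog)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-case cohort with assembled tables, shared across tests."""
    cfg = SyntheticConfig(n_cases=40, n_diseases=10, seed=7)
    return generate_cohort(cfg, with_fixtures=True)
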