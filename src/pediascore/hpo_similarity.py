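"""HPO-based semantic similarity between a patient's terms and diseases.

Three scorers stand in for the external phenotype tools the pipeline
integrates:

* :func:`symmetric_bma_score` — Phenomizer-style symmetric Resnik
  best-match-average over information content (IC);
* :func:`boqa_score` — exact-enumeration Bayesian ontology query: a
  posterior over diseases given the observed term closure under
  false-positive rate ``alpha`` and false-negative rate ``beta``;
* :func:`feature_match_score` — ancestor-closure Jaccard overlap, a
  pluggable stand-in for proprietary clinical-feature matchers.

IC is Resnik-style corpus IC in natural-log units: ``ic(t) =
-ln(n_t / N)`` where ``n_t`` counts diseases annotated to ``t`` directly
or through a descendant and ``N`` is the catalog size, so ``ic(root)=0``
and IC is non-decreasing from parent to child.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import obonet


class OntologyFormatError(ValueError):
    """OBO file is not a rooted DAG of is_a edges."""


@dataclass
class OntologyGraph:
    """A rooted DAG of ontology terms connected by is_a edges.

    ``is_a_edges`` maps each child to its set of parents; multiple
    inheritance is fully supported.  Obsolete terms are recorded but are
    not part of the DAG.
    """

    terms: set[str]
    is_a_edges: dict[str, set[str]]
    root: str
    obsolete: set[str] = field(default_factory=set)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyFormatError("is_a closure contains a cycle")
        for t in self.terms:
            if t != self.root and not self.is_a_edges.get(t):
                raise OntologyFormatError(
                    f"term {t} does not reach the root via is_a edges"
                )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parents in self.is_a_edges.items():
            for p in parents:
                g.add_edge(child, p)
        return g

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of *term* including the term itself."""
        if term not in self.terms:
            raise KeyError(f"term {term!r} not in ontology")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        for p in self.is_a_edges.get(term, ()):
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    def closure(self, terms: Iterable[str]) -> frozenset[str]:
        """Ancestor closure of a term set (union of per-term ancestors)."""
        out: set[str] = set()
        for t in terms:
            out |= self.ancestors(t)
        return frozenset(out)


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2 flat file into an :class:`OntologyGraph`.

    Only ``[Term]`` stanzas with ``id``, ``is_a`` and ``is_obsolete``
    tags are interpreted.  Obsolete terms are excluded from the DAG but
    listed in ``obsolete``.
    """
    g = obonet.read_obo(str(path), ignore_obsolete=False)
    obsolete = {
        n for n, d in g.nodes(data=True)
        if str(d.get("is_obsolete", "")).lower() == "true"
    }
    terms = set(g.nodes) - obsolete
    edges: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent, key in g.edges(keys=True):
        if key != "is_a" or child in obsolete or parent in obsolete:
            continue
        edges[child].add(parent)
    roots = sorted(t for t in terms if not edges[t])
    if not roots:
        raise OntologyFormatError(f"{path}: no root term found")
    if len(roots) > 1:
        raise OntologyFormatError(f"{path}: multiple roots: {roots}")
    return OntologyGraph(terms=terms, is_a_edges=edges, root=roots[0], obsolete=obsolete)


def write_obo(ontology: OntologyGraph, path: str | Path) -> None:
    """Write an :class:`OntologyGraph` back to minimal OBO 1.2."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(ontology.terms | ontology.obsolete):
            fh.write(f"\n[Term]\nid: {t}\nname: {t}\n")
            if t in ontology.obsolete:
                fh.write("is_obsolete: true\n")
                continue
            for p in sorted(ontology.is_a_edges.get(t, ())):
                fh.write(f"is_a: {p}\n")


@dataclass
class DiseaseAnnotationCatalog:
    """disease_id -> set of annotated ontology terms."""

    annotations: dict[str, set[str]]

    def validate(self, ontology: OntologyGraph) -> None:
        for d, ts in self.annotations.items():
            if not ts:
                raise ValueError(f"disease {d} has an empty annotation set")
            missing = ts - ontology.terms
            if missing:
                raise ValueError(
                    f"disease {d} annotated to unknown term(s) {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.annotations)


def read_annotation_catalog(path: str | Path) -> DiseaseAnnotationCatalog:
    """Read ``disease_id<TAB>term_id`` pairs (phenotype.hpoa-like minimal dialect)."""
    annotations: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected disease<TAB>term")
            annotations.setdefault(parts[0], set()).add(parts[1])
    return DiseaseAnnotationCatalog(annotations)


def write_annotation_catalog(catalog: DiseaseAnnotationCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for d in sorted(catalog.annotations):
            for t in sorted(catalog.annotations[d]):
                fh.write(f"{d}\t{t}\n")


@dataclass
class ICMap:
    """Term information content in natural-log units."""

    ic: dict[str, float]

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise KeyError(f"no IC for term {term!r}") from None


def compute_ic(ontology: OntologyGraph, catalog: DiseaseAnnotationCatalog) -> ICMap:
    """Corpus information content from annotation frequency.

    ``n_t`` is the number of diseases whose annotation closure contains
    ``t``.  Terms no disease reaches (zero frequency) fall back to
    ``max_catalog_ic + ln 2``, i.e. they are treated as strictly more
    informative than any observed term, which preserves parent-to-child
    monotonicity.
    """
    catalog.validate(ontology)
    n = len(catalog)
    counts: dict[str, int] = {t: 0 for t in ontology.terms}
    for terms in catalog.annotations.values():
        for t in ontology.closure(terms):
            counts[t] += 1
    observed = [c for c in counts.values() if c > 0]
    max_ic = -math.log(min(observed) / n) if observed else 0.0
    fallback = max_ic + math.log(2.0)
    ic = {
        t: (-math.log(c / n) if c > 0 else fallback)
        for t, c in counts.items()
    }
    return ICMap(ic)


def resnik_term_sim(t1: str, t2: str, ontology: OntologyGraph, ic_map: ICMap) -> float:
    """Max IC over common ancestors of two terms (each its own ancestor)."""
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    return max(ic_map[t] for t in common)


def symmetric_bma_score(
    query_terms: Iterable[str],
    disease_id: str,
    catalog: DiseaseAnnotationCatalog,
    ontology: OntologyGraph,
    ic_map: ICMap,
) -> float:
    """Symmetric Resnik best-match-average between query and disease annotation.

    Mean over query terms of their best match in the disease annotation,
    averaged with the mean over annotation terms of their best match in
    the query.
    """
    query = list(query_terms)
    if not query:
        raise ValueError("query_terms must be nonempty")
    disease_terms = list(catalog.annotations[disease_id])
    sims = [
        [resnik_term_sim(q, d, ontology, ic_map) for d in disease_terms]
        for q in query
    ]
    q_side = sum(max(row) for row in sims) / len(query)
    d_side = sum(max(sims[i][j] for i in range(len(query))) for j in range(len(disease_terms)))
    d_side /= len(disease_terms)
    return 0.5 * (q_side + d_side)


@dataclass
class BoqaParams:
    """Noise model of the Bayesian ontology query.

    ``alpha`` — probability that an observed term is a false positive;
    ``beta`` — probability that a disease-annotation term is missed;
    ``prior`` — disease prior (None = uniform over the catalog).
    """

    alpha: float = 0.001
    beta: float = 0.1
    prior: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0) or not (0.0 < self.beta < 1.0):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.prior is not None:
            total = sum(self.prior.values())
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"prior must sum to 1, sums to {total}")


def boqa_score(
    query_terms: Iterable[str],
    catalog: DiseaseAnnotationCatalog,
    ontology: OntologyGraph,
    params: BoqaParams | None = None,
) -> dict[str, float]:
    """Posterior over diseases given the observed term closure.

    With query closure Q, disease annotation closure A and term universe
    T, the likelihood is ``alpha^|Q\\A| (1-alpha)^|T\\(Q u A)|
    beta^|A\\Q| (1-beta)^|A n Q|``; posteriors are prior-weighted and
    normalized over the catalog.  Computed exactly in log space.
    """
    params = params or BoqaParams()
    q = ontology.closure(query_terms)
    n_terms = len(ontology.terms)
    la, l1a = math.log(params.alpha), math.log1p(-params.alpha)
    lb, l1b = math.log(params.beta), math.log1p(-params.beta)
    diseases = sorted(catalog.annotations)
    if params.prior is None:
        log_prior = {d: -math.log(len(diseases)) for d in diseases}
    else:
        log_prior = {
            d: (math.log(params.prior[d]) if params.prior.get(d, 0) > 0 else -math.inf)
            for d in diseases
        }
    log_post = {}
    for d in diseases:
        a = ontology.closure(catalog.annotations[d])
        n_qa = len(q & a)
        n_q_only = len(q) - n_qa
        n_a_only = len(a) - n_qa
        n_neither = n_terms - len(q | a)
        log_post[d] = (
            log_prior[d] + n_q_only * la + n_neither * l1a + n_a_only * lb + n_qa * l1b
        )
    m = max(log_post.values())
    unnorm = {d: math.exp(v - m) for d, v in log_post.items()}
    z = sum(unnorm.values())
    return {d: v / z for d, v in unnorm.items()}


def feature_match_score(
    query_terms: Iterable[str],
    disease_id: str,
    catalog: DiseaseAnnotationCatalog,
    ontology: OntologyGraph,
) -> float:
    """Ancestor-closure Jaccard overlap between query and disease annotation."""
    q = ontology.closure(query_terms)
    if not q:
        raise ValueError("query_terms must be nonempty")
    a = ontology.closure(catalog.annotations[disease_id])
    return len(q & a) / len(q | a)


FeatureMatcher = Callable[
    [Iterable[str], str, DiseaseAnnotationCatalog, OntologyGraph], float
]


def score_all_diseases(
    query_terms: Iterable[str],
    catalog: DiseaseAnnotationCatalog,
    ontology: OntologyGraph,
    ic_map: ICMap,
    boqa_params: BoqaParams | None = None,
    feature_matcher: FeatureMatcher = feature_match_score,
) -> dict[str, tuple[float, float, float]]:
    """(feature_match, phenomizer, boqa) triple per catalog disease.

    The feature matcher is pluggable so externally exported
    clinical-feature scores can replace the built-in Jaccard stand-in.
    BOQA posteriors sum to 1 across the returned map.
    """
    if not catalog.annotations:
        raise ValueError("catalog must be nonempty")
    query = sorted(set(query_terms))
    posteriors = boqa_score(query, catalog, ontology, boqa_params)
    out = {}
    for d in sorted(catalog.annotations):
        fm = feature_matcher(query, d, catalog, ontology)
        phen = symmetric_bma_score(query, d, catalog, ontology, ic_map)
        out[d] = (fm, phen, posteriors[d])
    return out
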