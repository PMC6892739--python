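"""Benchmark harness: gene-disjoint cross-validation, top-k accuracy,
rank-sensitivity curves, score-combination ablations, and the
score-borrowing transfer experiment.

Folds are *gene-disjoint*: every case sharing a causal gene is assigned
to the same fold, so a model is never trained and tested on the same
disease gene — this prevents leakage when the same pathogenic variant
occurs in two individuals.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .data_model import SCORE_COLUMNS, CaseRecord, Cohort, GeneScoreTable
from .classifier import (
    ClassifierConfig,
    PediaRanker,
    rank_genes,
    train_model,
)

DEFAULT_TOPK = (1, 10)


@dataclass
class FoldAssignment:
    """case_id -> fold index in 0..k-1, with all cases of one causal gene
    in a single fold."""

    folds: dict[str, int]
    k: int

    def cases_in_fold(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.folds.items() if f == fold)


@dataclass
class EvaluationReport:
    """Per-case causal-gene ranks plus the derived accuracy readouts."""

    per_case_rank: dict[str, int]
    topk: dict[int, float]
    curve: list[tuple[int, float]]
    combo_label: str = "cadd+gestalt+feature_match+phenomizer+boqa"

    def to_dict(self) -> dict:
        return {
            "combo": self.combo_label,
            "per_case_rank": dict(sorted(self.per_case_rank.items())),
            "topk": {str(k): v for k, v in sorted(self.topk.items())},
            "curve": [[r, s] for r, s in self.curve],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def gene_disjoint_folds(cohort: Cohort, k: int, seed: int) -> FoldAssignment:
    """Partition cases into k folds without splitting any causal gene.

    Cases are grouped by causal gene; gene-groups are shuffled (seeded),
    then assigned largest-first to the currently smallest fold, which
    balances *case* counts across folds while keeping the disjointness
    constraint exact.
    """
    by_gene: dict[str, list[str]] = {}
    for case in cohort.cases:
        by_gene.setdefault(case.causal_gene, []).append(case.case_id)
    if len(by_gene) < k:
        raise ValueError(
            f"need >= {k} distinct causal genes for {k} folds, got {len(by_gene)}"
        )
    groups = sorted(by_gene.items())
    rng = random.Random(seed)
    rng.shuffle(groups)
    # stable sort: equal-size groups stay in shuffled order
    groups.sort(key=lambda kv: -len(kv[1]))
    loads = [0] * k
    folds: dict[str, int] = {}
    for _gene, case_ids in groups:
        target = loads.index(min(loads))
        for cid in case_ids:
            folds[cid] = target
        loads[target] += len(case_ids)
    return FoldAssignment(folds=folds, k=k)


def topk_accuracy(per_case_rank: Mapping[str, int], k: int) -> float:
    """Fraction of cases whose causal gene ranks within the top k."""
    if not per_case_rank:
        raise ValueError("per_case_rank is empty")
    ranks = list(per_case_rank.values())
    return sum(r <= k for r in ranks) / len(ranks)


def rank_sensitivity_curve(
    per_case_rank: Mapping[str, int], max_rank: int
) -> list[tuple[int, float]]:
    """Sensitivity as a function of the number of top genes considered.

    Point r is the top-r accuracy, for r = 1..max_rank; the curve is
    non-decreasing and its first point is the top-1 accuracy.
    """
    if max_rank < 1:
        raise ValueError("max_rank must be >= 1")
    return [(r, topk_accuracy(per_case_rank, r)) for r in range(1, max_rank + 1)]


def _combo_label(columns: Sequence[str]) -> str:
    return "+".join(columns)


def cross_validate(
    cohort: Cohort,
    classifier_config: ClassifierConfig,
    k: int = 10,
    seed: int = 0,
    columns: Sequence[str] = SCORE_COLUMNS,
    assignment: FoldAssignment | None = None,
    topk: Sequence[int] = DEFAULT_TOPK,
    max_rank: int = 100,
) -> EvaluationReport:
    """Gene-disjoint k-fold cross-validation of the ranking pipeline.

    Per fold: C is selected and the model trained on the other folds'
    tables, then every held-out case's genes are ranked.  Each case is
    held out exactly once.  Deterministic given the seed.
    """
    if cohort.tables is None:
        raise ValueError("cohort has no assembled score tables")
    if assignment is None:
        assignment = gene_disjoint_folds(cohort, k, seed)
    tables = cohort.tables
    per_case_rank: dict[str, int] = {}
    for fold in range(assignment.k):
        test_ids = assignment.cases_in_fold(fold)
        if not test_ids:
            continue
        train_ids = [
            c.case_id for c in cohort.cases if assignment.folds[c.case_id] != fold
        ]
        model = train_model(
            [tables[cid] for cid in train_ids], classifier_config, columns
        )
        for cid in test_ids:
            per_case_rank[cid] = rank_genes(model, tables[cid]).causal_rank
    cap = min(max_rank, max(max(per_case_rank.values()), max(topk)))
    return EvaluationReport(
        per_case_rank=per_case_rank,
        topk={kk: topk_accuracy(per_case_rank, kk) for kk in topk},
        curve=rank_sensitivity_curve(per_case_rank, cap),
        combo_label=_combo_label(columns),
    )


def ablation_grid(
    cohort: Cohort,
    combos: Sequence[Sequence[str]],
    classifier_config: ClassifierConfig,
    k: int = 10,
    seed: int = 0,
    topk: Sequence[int] = DEFAULT_TOPK,
) -> dict[str, EvaluationReport]:
    """Cross-validate every score combination on shared folds.

    Inactive columns are removed from the feature vector (the model
    dimension shrinks), so a single-score combo reduces exactly to
    sorting genes by that score.  All combos share one fold assignment
    and seed, making reports directly comparable.
    """
    for combo in combos:
        if not combo:
            raise ValueError("combos must be nonempty subsets of the score columns")
    assignment = gene_disjoint_folds(cohort, k, seed)
    out: dict[str, EvaluationReport] = {}
    for combo in combos:
        combo = tuple(combo)
        out[_combo_label(combo)] = cross_validate(
            cohort,
            classifier_config,
            k=k,
            seed=seed,
            columns=combo,
            assignment=assignment,
            topk=topk,
        )
    return out


def _borrow_table(
    test_case: CaseRecord,
    donor_table: GeneScoreTable,
    gestalt_by_gene: Mapping[str, float],
    fill: float,
) -> GeneScoreTable:
    """Donor's molecular + feature columns with the test case's own gestalt.

    The donor's exome serves as the background; the test case's causal
    variant is spiked into the borrowed deleteriousness column so the
    causal gene is always a candidate (the donor may carry a different
    disease gene of the same syndrome).
    """
    from .classifier import assemble_case_table
    from .variant_scores import GeneMaxScoreMap, spike_in

    cadd = GeneMaxScoreMap({r.gene: r.cadd for r in donor_table.rows})
    cadd = spike_in(cadd, test_case.causal_gene, test_case.causal_variant_score)
    fm = {r.gene: r.feature_match for r in donor_table.rows}
    phen = {r.gene: r.phenomizer for r in donor_table.rows}
    boqa = {r.gene: r.boqa for r in donor_table.rows}
    return assemble_case_table(
        test_case, cadd, gestalt_by_gene, fm, phen, boqa, fill=fill
    )


def transfer_augment_evaluate(
    train_cohort: Cohort,
    phenotype_only_cases: Sequence[CaseRecord],
    gestalt_by_gene_per_case: Mapping[str, Mapping[str, float]],
    classifier_config: ClassifierConfig,
    repeats: int = 10,
    seed: int = 0,
    topk: Sequence[int] = DEFAULT_TOPK,
) -> dict[int, tuple[float, float]]:
    """Score-borrowing transfer experiment for photo-only cases.

    Each phenotype-only case (gestalt vector but no exome) borrows the
    molecular and feature score columns from a uniformly sampled cohort
    donor with the same diagnosis; its own gestalt scores, mapped to
    genes, replace the gestalt column.  Training cases carrying the same
    pathogenic variant as the donor — identified by the (causal gene,
    causal variant score) pair — are excluded from the training set.
    Repeated ``repeats`` times with fresh donor draws; returns
    ``{k: (mean, sd)}`` of the top-k accuracies over repeats (SD = 0 by
    convention for a single repeat).
    """
    if train_cohort.tables is None:
        raise ValueError("train cohort has no assembled score tables")
    donors_by_dx: dict[str, list[CaseRecord]] = {}
    for c in train_cohort.cases:
        donors_by_dx.setdefault(c.diagnosis_id, []).append(c)
    missing = sorted(
        {c.diagnosis_id for c in phenotype_only_cases} - set(donors_by_dx)
    )
    if missing:
        raise ValueError(f"no cohort donor for diagnosis id(s): {missing}")

    rng = random.Random(seed)
    accs: dict[int, list[float]] = {kk: [] for kk in topk}
    for _ in range(repeats):
        per_case_rank: dict[str, int] = {}
        excluded: set[str] = set()
        borrowed: list[tuple[CaseRecord, GeneScoreTable]] = []
        for case in phenotype_only_cases:
            donor = rng.choice(
                sorted(donors_by_dx[case.diagnosis_id], key=lambda c: c.case_id)
            )
            excluded.add(donor.case_id)
            # drop training cases carrying the test case's pathogenic
            # variant (identified by the gene/score pair)
            for c in train_cohort.cases:
                if (
                    c.causal_gene == case.causal_gene
                    and c.causal_variant_score == case.causal_variant_score
                ):
                    excluded.add(c.case_id)
            table = _borrow_table(
                case,
                train_cohort.tables[donor.case_id],
                gestalt_by_gene_per_case[case.case_id],
                fill=classifier_config.missing_fill,
            )
            borrowed.append((case, table))
        training_tables = [
            train_cohort.tables[c.case_id]
            for c in train_cohort.cases
            if c.case_id not in excluded
        ]
        model = train_model(training_tables, classifier_config)
        for case, table in borrowed:
            per_case_rank[case.case_id] = rank_genes(model, table).causal_rank
        for kk in topk:
            accs[kk].append(topk_accuracy(per_case_rank, kk))
    # SD is exactly 0 for a single repeat or identical repeats (avoids
    # float residue from the mean subtraction)
    return {
        kk: (
            float(np.mean(v)),
            float(np.std(v)) if len(v) > 1 and max(v) > min(v) else 0.0,
        )
        for kk, v in accs.items()
    }


def write_ablation_tsv(reports: Mapping[str, EvaluationReport], path: str | Path) -> None:
    """combo / top-1 / top-10 summary table."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("combo\ttop1\ttop10\n")
        for label, rep in reports.items():
            fh.write(f"{label}\t{rep.topk.get(1, float('nan'))!r}\t"
                     f"{rep.topk.get(10, float('nan'))!r}\n")


def write_curve_tsv(report: EvaluationReport, path: str | Path) -> None:
    """Two-column rank/sensitivity TSV for plotting."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("max_rank\tsensitivity\n")
        for r, s in report.curve:
            fh.write(f"{r}\t{s!r}\n")
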