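"""Linear-SVM integration of the five evidence scores into one ranking.

Each candidate gene of a case is a point in the five-dimensional score
space (cadd, gestalt, feature_match, phenomizer, boqa).  A soft-margin
linear SVM is trained on the pooled rows of the training cases to
separate causal from non-causal genes; the signed distance of a gene to
the hyperplane — the PEDIA score — ranks the genes of a held-out case.

Features are standardized (location/scale fitted on training rows only)
because SVM margins are scale-sensitive and raw deleteriousness
(~0-40) would otherwise dominate posterior-scale features (~0-1).  The
extreme class imbalance (one causal gene per case against thousands of
candidates) is handled with inverse-frequency class weighting on the
loss rather than subsampling, which keeps training deterministic and
uses every row.

The regularization strength C is selected per training set by internal
k-fold cross-validation over cases, maximizing top-1 accuracy; ties go
to the smallest C.

:class:`PediaSVM` is a scikit-learn compatible estimator (``fit`` /
``decision_function`` on arrays); :class:`PediaRanker` adds the
case-table plumbing and C selection.  The module-level functions are
thin wrappers over the two.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .data_model import SCORE_COLUMNS, CaseRecord, GeneScoreRow, GeneScoreTable
from .variant_scores import GeneMaxScoreMap

DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-6, 13))


@dataclass
class ClassifierConfig:
    """Training configuration.

    ``c_grid`` defaults to all integer powers of two in [2^-6, 2^12];
    ``internal_folds`` is the k of the internal case-level CV that
    selects C; ``missing_fill`` replaces phenotype scores of genes the
    mapping never scored (0 = "no similarity", the natural floor of
    nonnegative similarity scores).
    """

    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    internal_folds: int = 5
    missing_fill: float = 0.0
    class_weighting: str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_grid = tuple(float(c) for c in self.c_grid)
        if not self.c_grid:
            raise ValueError("c_grid must be nonempty")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("c_grid values must be positive")
        if list(self.c_grid) != sorted(set(self.c_grid)):
            raise ValueError("c_grid must be strictly increasing")
        if self.internal_folds < 2:
            raise ValueError("internal_folds must be >= 2")


def _linear_svc(C: float, class_weight: str | None, n_samples: int) -> LinearSVC:
    # primal squared-hinge: deterministic (no random_state dependence).
    # C is divided by n_samples so the data term is a mean, making the
    # fit invariant to duplicating the training rows.
    return LinearSVC(
        C=C / n_samples,
        class_weight=class_weight,
        dual=False,
        tol=1e-6,
        max_iter=20000,
    )


class PediaSVM(BaseEstimator, ClassifierMixin):
    """Standardizing soft-margin linear SVM over gene score rows.

    Thin scikit-learn estimator: ``fit(X, y)`` fits a per-feature
    location/scale on X, then a linear SVM (primal squared-hinge,
    deterministic) with class weighting; ``decision_function(X)``
    returns the unnormalized signed margin w.x + b in standardized
    coordinates — monotone in geometric hyperplane distance, so
    rankings are identical.

    Fitted attributes: ``scaler_``, ``svm_``, ``coef_`` (1-d weight
    vector), ``intercept_``.
    """

    def __init__(self, C: float = 1.0, class_weight: str | None = "balanced"):
        self.C = C
        self.class_weight = class_weight

    def fit(self, X, y) -> "PediaSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.scaler_ = StandardScaler().fit(X)
        self.svm_ = _linear_svc(self.C, self.class_weight, len(y)).fit(
            self.scaler_.transform(X), y
        )
        self.coef_ = self.svm_.coef_.ravel()
        self.intercept_ = float(self.svm_.intercept_[0])
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.scaler_.transform(X) @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


@dataclass
class TrainedModel:
    """Frozen linear model: weights over the active score columns, bias,
    the selected C, and the standardizer parameters."""

    weights: np.ndarray
    bias: float
    selected_C: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    columns: tuple[str, ...] = SCORE_COLUMNS

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=float)
        self.scaler_scale = np.asarray(self.scaler_scale, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(self.scaler_scale <= 0):
            raise ValueError("scaler scales must be positive")

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return Xs @ self.weights + self.bias

    def to_json(self, path: str | Path) -> None:
        payload = {
            "columns": list(self.columns),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "selected_C": self.selected_C,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            weights=np.array(d["weights"]),
            bias=float(d["bias"]),
            selected_C=float(d["selected_C"]),
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_scale=np.array(d["scaler_scale"]),
            columns=tuple(d["columns"]),
        )


@dataclass
class RankedEntry:
    gene: str
    pedia_score: float
    rank: int
    scores: tuple[float, ...]


@dataclass
class RankedResult:
    """Genes of one case ordered by decreasing PEDIA score (ranks 1..N,
    exact ties broken lexicographically by gene symbol)."""

    case_id: str
    entries: list[RankedEntry]
    causal_rank: int


def assemble_case_table(
    case: CaseRecord,
    gene_scores: GeneMaxScoreMap | Mapping[str, float],
    gestalt_by_gene: Mapping[str, float],
    fm_by_gene: Mapping[str, float],
    phen_by_gene: Mapping[str, float],
    boqa_by_gene: Mapping[str, float],
    fill: float = 0.0,
) -> GeneScoreTable:
    """Build the per-case gene/score table.

    The candidate-gene universe is the exome-derived score map (the
    spike-in guarantees the causal gene is present).  Phenotype columns
    take the gene-mapped value or ``fill`` for genes the mapping never
    scored.
    """
    scores = gene_scores.scores if isinstance(gene_scores, GeneMaxScoreMap) else gene_scores
    if case.causal_gene not in scores:
        raise ValueError(
            f"case {case.case_id}: causal gene {case.causal_gene!r} absent "
            "from the candidate-gene score map (spike-in missing?)"
        )
    rows = [
        GeneScoreRow(
            gene=g,
            cadd=scores[g],
            gestalt=gestalt_by_gene.get(g, fill),
            feature_match=fm_by_gene.get(g, fill),
            phenomizer=phen_by_gene.get(g, fill),
            boqa=boqa_by_gene.get(g, fill),
            label=(g == case.causal_gene),
        )
        for g in sorted(scores)
    ]
    return GeneScoreTable(case_id=case.case_id, rows=rows)


def _column_indices(columns: Sequence[str]) -> list[int]:
    unknown = set(columns) - set(SCORE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown score column(s): {sorted(unknown)}")
    if not columns:
        raise ValueError("need at least one score column")
    return [SCORE_COLUMNS.index(c) for c in columns]


def table_matrix(
    table: GeneScoreTable, columns: Sequence[str] = SCORE_COLUMNS
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(X, y, genes) arrays of one table restricted to *columns*."""
    idx = _column_indices(columns)
    X = np.array([[r.scores()[i] for i in idx] for r in table.rows], dtype=float)
    y = np.array([int(r.label) for r in table.rows])
    return X, y, [r.gene for r in table.rows]


def pooled_matrix(
    tables: Iterable[GeneScoreTable], columns: Sequence[str] = SCORE_COLUMNS
) -> tuple[np.ndarray, np.ndarray]:
    Xs, ys = [], []
    for t in tables:
        X, y, _ = table_matrix(t, columns)
        Xs.append(X)
        ys.append(y)
    return np.vstack(Xs), np.concatenate(ys)


class PediaRanker(BaseEstimator):
    """End-to-end ranker over case tables with internal C selection.

    ``fit(tables)`` selects C by internal case-level k-fold CV
    (maximizing mean top-1 accuracy, ties to the smallest C), then fits
    the final scaler + SVM on all pooled rows.  ``rank(table)`` returns
    the ordered gene list of one case.

    Parameters mirror :class:`ClassifierConfig`; ``columns`` restricts
    the feature space for ablation runs.
    """

    def __init__(
        self,
        c_grid: Sequence[float] = DEFAULT_C_GRID,
        internal_folds: int = 5,
        missing_fill: float = 0.0,
        class_weighting: str = "balanced",
        seed: int = 0,
        columns: Sequence[str] = SCORE_COLUMNS,
    ):
        self.c_grid = tuple(c_grid)
        self.internal_folds = internal_folds
        self.missing_fill = missing_fill
        self.class_weighting = class_weighting
        self.seed = seed
        self.columns = tuple(columns)

    @classmethod
    def from_config(
        cls, config: ClassifierConfig, columns: Sequence[str] = SCORE_COLUMNS
    ) -> "PediaRanker":
        return cls(
            c_grid=config.c_grid,
            internal_folds=config.internal_folds,
            missing_fill=config.missing_fill,
            class_weighting=config.class_weighting,
            seed=config.seed,
            columns=columns,
        )

    def _config(self) -> ClassifierConfig:
        return ClassifierConfig(
            c_grid=self.c_grid,
            internal_folds=self.internal_folds,
            missing_fill=self.missing_fill,
            class_weighting=self.class_weighting,
            seed=self.seed,
        )

    def select_C(self, tables: Sequence[GeneScoreTable]) -> float:
        """Internal k-fold CV over cases; argmax of mean top-1 accuracy."""
        cfg = self._config()
        if len(tables) < cfg.internal_folds:
            raise ValueError(
                f"need >= {cfg.internal_folds} training cases, got {len(tables)}"
            )
        if len(self.c_grid) == 1:
            return self.c_grid[0]
        mats = [table_matrix(t, self.columns) for t in tables]
        kf = KFold(n_splits=cfg.internal_folds, shuffle=True, random_state=cfg.seed)
        hits = {C: 0 for C in self.c_grid}
        n_val_cases = 0
        for train_idx, val_idx in kf.split(np.arange(len(tables))):
            Xtr = np.vstack([mats[i][0] for i in train_idx])
            ytr = np.concatenate([mats[i][1] for i in train_idx])
            scaler = StandardScaler().fit(Xtr)  # shared across the C grid
            Xtr_s = scaler.transform(Xtr)
            val = [
                (scaler.transform(mats[i][0]), mats[i][1], mats[i][2])
                for i in val_idx
            ]
            n_val_cases += len(val)
            for C in self.c_grid:
                svc = _linear_svc(C, self.class_weighting, len(ytr)).fit(Xtr_s, ytr)
                w, b = svc.coef_.ravel(), float(svc.intercept_[0])
                for Xv, yv, genes in val:
                    scores = Xv @ w + b
                    best = min(range(len(genes)), key=lambda j: (-scores[j], genes[j]))
                    hits[C] += int(yv[best])
        # grid is increasing, so ties keep the smallest C
        best_c, best_hits = None, -1
        for C in self.c_grid:
            if hits[C] > best_hits:
                best_c, best_hits = C, hits[C]
        return best_c

    def fit(self, tables: Sequence[GeneScoreTable]) -> "PediaRanker":
        self.selected_C_ = self.select_C(tables)
        X, y = pooled_matrix(tables, self.columns)
        svm = PediaSVM(C=self.selected_C_, class_weight=self.class_weighting).fit(X, y)
        self.model_ = _frozen(svm, self.selected_C_, self.columns)
        return self

    def rank(self, table: GeneScoreTable) -> RankedResult:
        return rank_genes(self.model_, table)

    def decision_scores(self, table: GeneScoreTable) -> dict[str, float]:
        return pedia_scores(self.model_, table)


def _frozen(svm: PediaSVM, C: float, columns: Sequence[str]) -> TrainedModel:
    return TrainedModel(
        weights=svm.coef_,
        bias=svm.intercept_,
        selected_C=C,
        scaler_mean=svm.scaler_.mean_,
        scaler_scale=svm.scaler_.scale_,
        columns=tuple(columns),
    )


def select_hyperparameter(
    training_tables: Sequence[GeneScoreTable],
    config: ClassifierConfig,
    columns: Sequence[str] = SCORE_COLUMNS,
) -> float:
    """Pick C from the grid by internal k-fold CV on top-1 accuracy."""
    return PediaRanker.from_config(config, columns).select_C(training_tables)


def train_model(
    training_tables: Sequence[GeneScoreTable],
    config: ClassifierConfig,
    columns: Sequence[str] = SCORE_COLUMNS,
    selected_C: float | None = None,
) -> TrainedModel:
    """Select C (unless given) and fit the final scaler + linear SVM."""
    ranker = PediaRanker.from_config(config, columns)
    if selected_C is None:
        selected_C = ranker.select_C(training_tables)
    X, y = pooled_matrix(training_tables, columns)
    svm = PediaSVM(C=selected_C, class_weight=config.class_weighting).fit(X, y)
    return _frozen(svm, selected_C, columns)


def pedia_scores(model: TrainedModel, table: GeneScoreTable) -> dict[str, float]:
    """Signed hyperplane margin per gene of one case."""
    X, _, genes = table_matrix(table, model.columns)
    bad = [g for g, row in zip(genes, X) if not np.all(np.isfinite(row))]
    if bad:
        raise ValueError(f"non-finite feature(s) for gene(s): {bad}")
    return dict(zip(genes, model.decision(X)))


def rank_genes(model: TrainedModel, table: GeneScoreTable) -> RankedResult:
    """Order a case's genes by decreasing PEDIA score.

    Exact score ties are broken lexicographically by gene symbol, so the
    ranking is deterministic; ``causal_rank`` is the 1-based position of
    the labelled gene.
    """
    scores = pedia_scores(model, table)
    rows = {r.gene: r for r in table.rows}
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [
        RankedEntry(gene=g, pedia_score=s, rank=i + 1, scores=rows[g].scores())
        for i, (g, s) in enumerate(ordered)
    ]
    causal = [e.rank for e in entries if rows[e.gene].label]
    if len(causal) != 1:
        raise ValueError("table must contain exactly one causal label")
    return RankedResult(case_id=table.case_id, entries=entries, causal_rank=causal[0])


def weight_contributions(model: TrainedModel) -> dict[str, float]:
    """Relative evidence contributions |w_i| / sum|w_j|, grouped.

    Returns the variant-level share (cadd), the combined share of the
    three HPO feature-based scores, and the gestalt share; the three sum
    to 1.  Only defined for models trained on all five columns.
    """
    if tuple(model.columns) != SCORE_COLUMNS:
        raise ValueError("weight_contributions requires the full five-score model")
    total = float(np.sum(np.abs(model.weights)))
    if total == 0:
        raise ValueError("all weights are zero; contributions undefined")
    share = {c: float(abs(w)) / total for c, w in zip(model.columns, model.weights)}
    return {
        "variant": share["cadd"],
        "features": share["feature_match"] + share["phenomizer"] + share["boqa"],
        "gestalt": share["gestalt"],
    }
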