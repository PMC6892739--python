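"""Table assembly, C selection, SVM training and gene ranking."""

import numpy as np
import pytest

from pediascore.data_model import SCORE_COLUMNS, CaseRecord, GeneScoreRow, GeneScoreTable
from pediascore.classifier import (
    ClassifierConfig,
    PediaRanker,
    PediaSVM,
    TrainedModel,
    assemble_case_table,
    pedia_scores,
    rank_genes,
    select_hyperparameter,
    train_model,
    weight_contributions,
)
from pediascore.variant_scores import GeneMaxScoreMap


def _case(causal="G1"):
    return CaseRecord(
        case_id="c1",
        hpo_terms={"HP:0000002"},
        diagnosis_id="OMIM:600001",
        causal_gene=causal,
        causal_variant_score=30.0,
        gestalt_scores={},
    )


def test_assemble_fill_rule_and_row_count():
    exome = GeneMaxScoreMap({"G1": 30.0, "G2": 5.0, "G3": 12.0})
    table = assemble_case_table(
        _case(), exome, gestalt_by_gene={"G1": 0.8}, fm_by_gene={}, phen_by_gene={},
        boqa_by_gene={"G2": 0.4}, fill=0.0,
    )
    assert len(table.rows) == len(exome.scores)
    by_gene = {r.gene: r for r in table.rows}
    assert by_gene["G2"].gestalt == 0.0  # unscored -> fill
    assert by_gene["G1"].gestalt == 0.8
    assert by_gene["G2"].boqa == 0.4
    assert [r.label for r in table.rows].count(True) == 1
    assert by_gene["G1"].label


def test_assemble_missing_causal_gene_raises():
    with pytest.raises(ValueError, match="causal gene"):
        assemble_case_table(_case("G9"), GeneMaxScoreMap({"G1": 1.0}), {}, {}, {}, {})


def test_assemble_columns_equal_lookups():
    rng = np.random.default_rng(0)
    genes = [f"G{i}" for i in range(20)]
    exome = GeneMaxScoreMap({g: float(rng.uniform(0, 40)) for g in genes})
    maps = [
        {g: float(rng.random()) for g in genes if rng.random() < 0.6}
        for _ in range(4)
    ]
    table = assemble_case_table(_case("G0"), exome, *maps, fill=-1.0)
    for r in table.rows:
        assert r.cadd == exome.scores[r.gene]
        for col, m in zip(("gestalt", "feature_match", "phenomizer", "boqa"), maps):
            assert getattr(r, col) == m.get(r.gene, -1.0)


def _synthetic_tables(rng, n_cases=20, n_genes=15, shift=3.0):
    """Tables where the causal gene is shifted up on cadd and gestalt."""
    tables = []
    for i in range(n_cases):
        causal = int(rng.integers(n_genes))
        rows = []
        for g in range(n_genes):
            x = rng.normal(size=5) + (shift if g == causal else 0.0) * np.array(
                [1, 1, 0, 0, 0], dtype=float
            )
            rows.append(
                GeneScoreRow(
                    gene=f"G{g:02d}",
                    cadd=float(x[0]),
                    gestalt=float(x[1]),
                    feature_match=float(x[2]),
                    phenomizer=float(x[3]),
                    boqa=float(x[4]),
                    label=(g == causal),
                )
            )
        tables.append(GeneScoreTable(f"case{i}", rows))
    return tables


def test_config_validation():
    with pytest.raises(ValueError):
        ClassifierConfig(c_grid=())
    with pytest.raises(ValueError):
        ClassifierConfig(c_grid=(1.0, 0.5))
    with pytest.raises(ValueError):
        ClassifierConfig(internal_folds=1)


def test_single_value_grid_returned_directly():
    tables = _synthetic_tables(np.random.default_rng(1), n_cases=6)
    cfg = ClassifierConfig(c_grid=(0.5,), internal_folds=3)
    assert select_hyperparameter(tables, cfg) == 0.5


def test_separable_cohort_ties_break_to_smallest_c():
    tables = _synthetic_tables(np.random.default_rng(2), n_cases=15, shift=20.0)
    cfg = ClassifierConfig(c_grid=(0.25, 1.0, 4.0), internal_folds=5)
    assert select_hyperparameter(tables, cfg) == 0.25


def test_selection_matches_independent_grid_loop():
    """Re-run C selection with an independently scripted loop over the
    same folds and assert the same argmax."""
    from sklearn.model_selection import KFold
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVC

    rng = np.random.default_rng(3)
    tables = _synthetic_tables(rng, n_cases=12, shift=1.0)
    grid = (0.03125, 1.0, 32.0)
    cfg = ClassifierConfig(c_grid=grid, internal_folds=4, seed=9)

    accs = {}
    kf = KFold(n_splits=4, shuffle=True, random_state=9)
    for C in grid:
        hits = total = 0
        for tr, va in kf.split(np.arange(len(tables))):
            X = np.vstack([[r.scores() for r in tables[i].rows] for i in tr])
            y = np.concatenate([[r.label for r in tables[i].rows] for i in tr]).astype(int)
            sc = StandardScaler().fit(X)
            svc = LinearSVC(C=C / len(y), class_weight="balanced", dual=False,
                            tol=1e-6, max_iter=20000).fit(sc.transform(X), y)
            for i in va:
                rows = tables[i].rows
                scores = sc.transform([r.scores() for r in rows]) @ svc.coef_.ravel() \
                    + svc.intercept_[0]
                best = min(range(len(rows)), key=lambda j: (-scores[j], rows[j].gene))
                hits += rows[best].label
                total += 1
        accs[C] = hits / total
    expected = max(grid, key=lambda C: (accs[C], -C))
    assert select_hyperparameter(tables, cfg) == expected


def test_svm_separates_separable_toy():
    rng = np.random.default_rng(4)
    X = np.zeros((40, 5))
    y = np.array([0, 1] * 20)
    X[:, 0] = rng.normal(size=40) + 10 * y
    X[:, 1] = rng.normal(size=40) - 10 * y
    X[:, 2:] = 1.0 + rng.normal(scale=1e-9, size=(40, 3))
    svm = PediaSVM(C=1.0).fit(X, y)
    assert (svm.predict(X) == y).all()


def test_single_class_training_rejected():
    with pytest.raises(ValueError, match="both classes"):
        PediaSVM().fit(np.zeros((5, 5)), np.zeros(5))


def test_training_deterministic_and_duplication_invariant():
    tables = _synthetic_tables(np.random.default_rng(5), n_cases=10)
    cfg = ClassifierConfig(c_grid=(1.0,), seed=3)
    m1 = train_model(tables, cfg)
    m2 = train_model(tables, cfg)
    assert m1.weights.tobytes() == m2.weights.tobytes()
    assert m1.bias == m2.bias
    # duplicating every training row leaves the decision function unchanged
    doubled = tables + tables
    for t in doubled[len(tables):]:
        t.case_id += "_dup"
    m3 = train_model(doubled, cfg)
    X = np.vstack([[r.scores() for r in tables[0].rows]])
    np.testing.assert_allclose(m1.decision(X), m3.decision(X), atol=1e-6)


def test_pedia_score_is_margin_arithmetic():
    model = TrainedModel(
        weights=np.array([1.0, -2.0, 0.5, 0.0, 3.0]),
        bias=0.25,
        selected_C=1.0,
        scaler_mean=np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
        scaler_scale=np.array([2.0, 1.0, 1.0, 0.5, 1.0]),
    )
    rng = np.random.default_rng(6)
    rows = [
        GeneScoreRow(f"G{i}", *map(float, rng.normal(size=5)), label=(i == 0))
        for i in range(8)
    ]
    table = GeneScoreTable("c", rows)
    scores = pedia_scores(model, table)
    for r in rows:
        x = (np.array(r.scores()) - model.scaler_mean) / model.scaler_scale
        assert scores[r.gene] == pytest.approx(float(x @ model.weights + 0.25))


def test_centered_row_scores_zero():
    model = TrainedModel(
        weights=np.ones(5), bias=0.0, selected_C=1.0,
        scaler_mean=np.full(5, 2.0), scaler_scale=np.ones(5),
    )
    table = GeneScoreTable(
        "c", [GeneScoreRow("G1", 2.0, 2.0, 2.0, 2.0, 2.0, label=True)]
    )
    assert pedia_scores(model, table)["G1"] == 0.0


def test_nonfinite_feature_names_gene():
    model = TrainedModel(
        weights=np.ones(5), bias=0.0, selected_C=1.0,
        scaler_mean=np.zeros(5), scaler_scale=np.ones(5),
    )
    table = GeneScoreTable(
        "c",
        [
            GeneScoreRow("GOOD", 1, 1, 1, 1, 1, label=True),
            GeneScoreRow("BAD", float("nan"), 1, 1, 1, 1, label=False),
        ],
    )
    with pytest.raises(ValueError, match="BAD"):
        pedia_scores(model, table)


def _identity_model(n=5):
    return TrainedModel(
        weights=np.array([1.0] + [0.0] * (n - 1)), bias=0.0, selected_C=1.0,
        scaler_mean=np.zeros(n), scaler_scale=np.ones(n),
    )


def test_rank_genes_basic_and_causal_rank():
    table = GeneScoreTable(
        "c",
        [
            GeneScoreRow("G1", 2.0, 0, 0, 0, 0, label=True),
            GeneScoreRow("G2", 1.0, 0, 0, 0, 0, label=False),
        ],
    )
    result = rank_genes(_identity_model(), table)
    assert [e.gene for e in result.entries] == ["G1", "G2"]
    assert [e.rank for e in result.entries] == [1, 2]
    assert result.causal_rank == 1


def test_rank_ties_break_lexicographically():
    table = GeneScoreTable(
        "c",
        [
            GeneScoreRow("G_b", 1.0, 0, 0, 0, 0, label=True),
            GeneScoreRow("G_a", 1.0, 0, 0, 0, 0, label=False),
        ],
    )
    result = rank_genes(_identity_model(), table)
    assert [e.gene for e in result.entries] == ["G_a", "G_b"]


def test_ranking_matches_reference_sort():
    rng = np.random.default_rng(7)
    rows = [
        GeneScoreRow(f"G{i:02d}", float(rng.normal()), 0, 0, 0, 0, label=(i == 0))
        for i in range(30)
    ]
    table = GeneScoreTable("c", rows)
    result = rank_genes(_identity_model(), table)
    expected = sorted(rows, key=lambda r: (-r.cadd, r.gene))
    assert [e.gene for e in result.entries] == [r.gene for r in expected]
    # invariant to strictly increasing transforms of the score
    scaled = _identity_model()
    scaled.weights = scaled.weights * 7.0
    scaled.bias = 3.0
    assert [e.gene for e in rank_genes(scaled, table).entries] == [
        r.gene for r in expected
    ]


def test_weight_contributions_equal_weights():
    model = TrainedModel(
        weights=np.ones(5), bias=0.0, selected_C=1.0,
        scaler_mean=np.zeros(5), scaler_scale=np.ones(5),
    )
    contrib = weight_contributions(model)
    assert contrib == pytest.approx({"variant": 0.2, "features": 0.6, "gestalt": 0.2})


def test_weight_contributions_single_nonzero_and_normalization():
    model = TrainedModel(
        weights=np.array([2.5, 0, 0, 0, 0]), bias=0.0, selected_C=1.0,
        scaler_mean=np.zeros(5), scaler_scale=np.ones(5),
    )
    assert weight_contributions(model) == {"variant": 1.0, "features": 0.0, "gestalt": 0.0}
    rng = np.random.default_rng(8)
    for _ in range(20):
        w = rng.normal(size=5)
        model = TrainedModel(
            weights=w, bias=0.0, selected_C=1.0,
            scaler_mean=np.zeros(5), scaler_scale=np.ones(5),
        )
        contrib = weight_contributions(model)
        assert sum(contrib.values()) == pytest.approx(1.0, abs=1e-12)
        total = np.abs(w).sum()
        assert contrib["gestalt"] == pytest.approx(abs(w[1]) / total)


def test_zero_weights_rejected():
    model = TrainedModel(
        weights=np.zeros(5), bias=0.0, selected_C=1.0,
        scaler_mean=np.zeros(5), scaler_scale=np.ones(5),
    )
    with pytest.raises(ValueError):
        weight_contributions(model)


def test_model_json_round_trip(tmp_path):
    tables = _synthetic_tables(np.random.default_rng(9), n_cases=8)
    model = train_model(tables, ClassifierConfig(c_grid=(1.0,)))
    model.to_json(tmp_path / "m.json")
    back = TrainedModel.from_json(tmp_path / "m.json")
    assert back.weights.tobytes() == model.weights.tobytes()
    assert back.bias == model.bias
    assert back.columns == SCORE_COLUMNS


def test_single_informative_feature_reduces_to_feature_sort(small_cohort):
    """With only the cadd column active, the learned ranking equals
    sorting by cadd (up to the shared lexicographic tie-break)."""
    tables = list(small_cohort.cohort.tables.values())
    ranker = PediaRanker(c_grid=(1.0,), columns=("cadd",)).fit(tables)
    for table in tables[:10]:
        got = [e.gene for e in ranker.rank(table).entries]
        expected = [
            r.gene for r in sorted(table.rows, key=lambda r: (-r.cadd, r.gene))
        ]
        assert got == expected
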