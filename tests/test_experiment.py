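import numpy as np
import pandas as pd
import pytest

from simpredict import (
    AUPRC,
    AUROC,
    ConfigError,
    GeneratorConfig,
    MetricSummary,
    PatientVector,
    SweepConfig,
    SweepResult,
    compare_conditions,
    death_count_risk,
    default_n_grid,
    find_peak,
    fit_local_logistic,
    fit_scaler,
    generate_cohort,
    mean_ci,
    predict_fold,
    rank_neighbors,
    run_benchmarks,
    run_sweep,
    stratified_folds,
)


def split(cohort, n_test):
    ids = list(cohort.ids)
    return cohort.subset(ids[n_test:]), cohort.subset(ids[:n_test])


# ---------------------------------------------------------------------------
# sweep mechanics
# ---------------------------------------------------------------------------

def test_sweep_shape_contract(small_generated):
    cohort = small_generated.cohort.subset(list(small_generated.cohort.ids)[:300])
    result = run_sweep(cohort, SweepConfig("death_count", (10, 20), k_folds=3, seed=5))
    frame = result.to_frame()
    assert len(frame) == 4  # 2 N values x 2 metrics
    assert set(frame["metric"]) == {AUROC, AUPRC}
    for metric in (AUROC, AUPRC):
        for n in (10, 20):
            s = result.summary(metric, n)
            assert len(s.fold_values) == 3
            assert s.ci_low <= s.mean <= s.ci_high
            assert all(0.0 <= v <= 1.0 for v in s.fold_values)


def test_sweep_is_deterministic(small_generated):
    cohort = small_generated.cohort
    config = SweepConfig("death_count", (10, 30, 50), k_folds=4, seed=2)
    a = run_sweep(cohort, config)
    b = run_sweep(cohort, config)
    assert a.to_frame().equals(b.to_frame())


def test_sweep_config_validation(small_generated):
    with pytest.raises(ConfigError):
        SweepConfig("death_count", ())
    with pytest.raises(ConfigError):
        SweepConfig("death_count", (20, 10))
    with pytest.raises(ConfigError):
        SweepConfig("logistic", (100,))  # below logistic minimum 5000
    with pytest.raises(ConfigError, match="smallest training-fold"):
        run_sweep(
            small_generated.cohort,  # 400 patients, k=4 -> train 300
            SweepConfig("death_count", (10, 350), k_folds=4, seed=0),
        )


def test_default_grids():
    assert default_n_grid("death_count", 10_000) == tuple(range(10, 501, 10))
    grid = default_n_grid("logistic", 15_649)
    assert grid[0] == 5000 and grid[-1] == 15_649
    assert default_n_grid("tree", 4000) == (2000, 3000, 4000)
    with pytest.raises(ConfigError):
        default_n_grid("logistic", 4000)


# ---------------------------------------------------------------------------
# per-fold prediction against an end-to-end oracle
# ---------------------------------------------------------------------------

def test_death_count_fold_matches_brute_force_oracle(small_generated):
    cohort = small_generated.cohort.subset(list(small_generated.cohort.ids)[:220])
    train, test = split(cohort, 20)
    preds = {p.patient_id: p.risk for p in
             predict_fold(train, test, "death_count", n=10)}

    scaler = fit_scaler(train)
    outcomes = dict(zip(train.ids, train.outcomes))
    cat_cols = list(cohort.schema.categorical_features)

    def vector(c, pid):
        row = c.table.loc[pid]
        cont = scaler.transform(
            row[list(c.schema.continuous_features)].to_numpy(float)
        )
        return PatientVector(pid, cont, tuple(row[cat_cols]))

    candidates = [vector(train, pid) for pid in train.ids]
    for pid in test.ids:
        ranking = rank_neighbors(vector(test, pid), candidates)
        oracle = death_count_risk(ranking, outcomes, 10)
        assert preds[pid] == pytest.approx(oracle.risk, abs=1e-12)


def test_identical_patient_ranks_first_with_psm_one(small_generated):
    cohort = small_generated.cohort
    train, test = split(cohort, 10)
    twin_id = list(train.ids)[0]
    row = train.table.loc[[twin_id]].rename(index={twin_id: "zz_twin"})
    test_twin = type(test)(test.schema, pd.concat([test.table, row]).sort_index())
    scaler = fit_scaler(train)
    cat_cols = list(cohort.schema.categorical_features)

    def vector(c, pid):
        r = c.table.loc[pid]
        cont = scaler.transform(r[list(c.schema.continuous_features)].to_numpy(float))
        return PatientVector(pid, cont, tuple(r[cat_cols]))

    ranking = rank_neighbors(
        vector(test_twin, "zz_twin"), [vector(train, i) for i in train.ids]
    )
    assert ranking.entries[0] == (twin_id, 1.0)


def test_neighborhood_nesting(small_generated):
    cohort = small_generated.cohort
    train, test = split(cohort, 5)
    scaler = fit_scaler(train)
    cat_cols = list(cohort.schema.categorical_features)

    def vector(c, pid):
        r = c.table.loc[pid]
        return PatientVector(
            pid,
            scaler.transform(r[list(c.schema.continuous_features)].to_numpy(float)),
            tuple(r[cat_cols]),
        )

    ranking = rank_neighbors(vector(test, list(test.ids)[0]),
                             [vector(train, i) for i in train.ids])
    for n, m in [(5, 20), (20, 100)]:
        assert set(ranking.top_ids(n)) <= set(ranking.top_ids(m))


def test_personalized_logistic_degenerate_limit():
    g = generate_cohort(GeneratorConfig(n_patients=400, seed=13))
    train, test = split(g.cohort, 80)
    preds = predict_fold(train, test, "logistic", n=train.n)
    global_model = fit_local_logistic(train)
    expected = global_model.predict_risk_values(test.table)
    got = np.array([p.risk for p in preds])
    assert np.max(np.abs(got - expected)) < 1e-8


def test_single_class_neighborhood_falls_back_to_death_count(caplog):
    # a tiny N makes some neighborhoods single-class; fallback must log
    g = generate_cohort(GeneratorConfig(n_patients=300, seed=3))
    train, test = split(g.cohort, 30)
    with caplog.at_level("WARNING", logger="simpredict"):
        preds = predict_fold(train, test, "logistic", n=5)
    assert len(preds) == 30
    assert all(0 <= p.risk <= 1 for p in preds)
    assert any("fell back" in r.message for r in caplog.records)
    from simpredict import SingleClassError

    with pytest.raises(SingleClassError):
        predict_fold(train, test, "logistic", n=5, fallback="error")


def test_predict_fold_rejects_overlapping_cohorts(small_generated):
    cohort = small_generated.cohort
    train, test = split(cohort, 10)
    with pytest.raises(ValueError, match="share"):
        predict_fold(train, train, "death_count", n=10)


# ---------------------------------------------------------------------------
# peak finding and comparisons
# ---------------------------------------------------------------------------

def _fake_result(means, fold_sd=0.0, k=5):
    grid = tuple(sorted(means))
    summaries = {AUROC: {}, AUPRC: {}}
    for metric in (AUROC, AUPRC):
        for n in grid:
            values = [means[n] + fold_sd * i for i in range(k)]
            summaries[metric][n] = mean_ci(values, metric_name=metric)
    config = SweepConfig("death_count", grid, k_folds=k, seed=0)
    folds = stratified_folds(
        pd.Series([0, 1] * (5 * k), index=[f"p{i}" for i in range(10 * k)]), k, 0
    )
    return SweepResult(config=config, folds=folds, summaries=summaries)


def test_find_peak_and_tie_rule():
    result = _fake_result({50: 0.78, 100: 0.797, 150: 0.78})
    n_star, summary = find_peak(result, AUROC)
    assert n_star == 100 and summary.mean == pytest.approx(0.797)
    tied = _fake_result({50: 0.797, 100: 0.797, 150: 0.78})
    assert find_peak(tied, AUROC)[0] == 50  # smaller N wins ties
    single = _fake_result({100: 0.8})
    assert find_peak(single, AUROC)[0] == 100


def test_compare_conditions_peak_equals_max_n():
    result = _fake_result({100: 0.8}, fold_sd=0.01)
    table = compare_conditions(result)
    row = table[(table.metric == AUROC)].iloc[0]
    assert row.p_value == pytest.approx(1.0)
    assert not row.significant


def test_compare_conditions_benchmark_and_fold_mismatch():
    result = _fake_result({50: 0.80, 100: 0.72}, fold_sd=0.005)
    benchmarks = {"saps": {AUROC: [0.55, 0.56, 0.54, 0.55, 0.56],
                           AUPRC: [0.2, 0.21, 0.2, 0.22, 0.2]}}
    table = compare_conditions(result, benchmarks)
    saps_row = table[(table.metric == AUROC) &
                     (table.comparison == "peak_vs_saps")].iloc[0]
    assert saps_row.p_value < 0.05 and saps_row.significant
    with pytest.raises(ValueError, match="fold values"):
        compare_conditions(result, {"saps": {AUROC: [0.5, 0.5], AUPRC: [0.2, 0.2]}})


# ---------------------------------------------------------------------------
# benchmarks
# ---------------------------------------------------------------------------

def test_benchmarks_share_fold_assignment(small_generated):
    cohort = small_generated.cohort
    folds = stratified_folds(
        pd.Series(cohort.outcomes, index=list(cohort.ids)), 4, seed=9
    )
    results = run_benchmarks(cohort, folds)
    assert set(results) == {"saps", "sofa"}
    for metrics in results.values():
        assert len(metrics[AUROC].fold_values) == 4
        assert 0.5 < metrics[AUROC].mean < 0.9  # scores are informative


def test_uninformative_benchmark_score_is_random():
    rng = np.random.default_rng(31)
    g = generate_cohort(GeneratorConfig(n_patients=2000, seed=8))
    cohort = g.cohort
    cohort.table["saps"] = rng.normal(size=cohort.n)  # sever score-outcome link
    folds = stratified_folds(
        pd.Series(cohort.outcomes, index=list(cohort.ids)), 5, seed=1
    )
    s = run_benchmarks(cohort, folds)["saps"][AUROC]
    assert s.ci_low <= 0.5 <= s.ci_high or abs(s.mean - 0.5) < 0.05
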