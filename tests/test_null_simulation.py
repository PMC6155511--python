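import numpy as np
import pytest
from scipy.special import expit, logit

import repenroll as rp
from repenroll.null_simulation import (
    _score_matrix,
    build_intermediate_matrix,
    discretized_correlation,
    nearest_positive_definite,
)


def _binary_model(p=0.3, completion=None):
    sch = [
        rp.FieldSchema(name="a", categories=(0, 1), weights={0: 0, 1: 1}),
        rp.FieldSchema(name="b", categories=(0, 1), weights={0: 0, 1: 1}),
    ]
    return rp.NullModel(
        schemas=sch,
        marginals=[np.array([1 - p, p]), np.array([0.5, 0.5])],
        target_corr=np.eye(2),
        cutoff=0.0,
        completion_coefs=completion or {},
    )


# -- estimation ------------------------------------------------------------

def test_estimate_marginals_by_counting(tiny_schemas):
    sch = [rp.FieldSchema(name="x", categories=(0, 1)),
           rp.FieldSchema(name="y", categories=(0, 1))]
    rng = np.random.default_rng(0)
    x = np.zeros(100)
    x[:30] = 1
    y = rng.integers(0, 2, 100).astype(float)
    pool = rp.SurveyMatrix(np.column_stack([rng.permutation(x), y]), sch)
    nm = rp.estimate_null_model(pool, np.ones(100, bool), cutoff=-np.inf,
                                completion_covariates=[])
    np.testing.assert_allclose(nm.marginals[0], [0.7, 0.3])


def test_estimate_rejects_single_category_field():
    sch = [rp.FieldSchema(name="x", categories=(0, 1)),
           rp.FieldSchema(name="y", categories=(0, 1))]
    vals = np.column_stack([np.zeros(50), np.r_[np.zeros(25), np.ones(25)]])
    pool = rp.SurveyMatrix(vals, sch)
    with pytest.raises(ValueError, match="single observed category"):
        rp.estimate_null_model(pool, np.ones(50, bool), cutoff=-np.inf)


def test_intercept_only_completion_recovers_rate():
    sch = [rp.FieldSchema(name="x", categories=(0, 1))]
    rng = np.random.default_rng(1)
    vals = rng.integers(0, 2, (200, 1)).astype(float)
    completed = np.zeros(200, bool)
    completed[:130] = True
    pool = rp.SurveyMatrix(vals, sch)
    nm = rp.estimate_null_model(pool, rng.permutation(completed), cutoff=-np.inf,
                                completion_covariates=[])
    assert nm.completion_coefs["intercept"] == pytest.approx(logit(0.65), abs=1e-6)


def test_independent_fields_give_near_zero_target_corr(null_model):
    sim = rp.simulate_ordinal(_binary_model(), 5000, seed=3)
    nm = rp.estimate_null_model(sim, np.ones(sim.n, bool), cutoff=-np.inf,
                                completion_covariates=[])
    assert abs(nm.target_corr[0, 1]) < 0.05


# -- intermediate correlation ---------------------------------------------

def test_intermediate_correlation_zero_is_zero():
    assert rp.intermediate_correlation([0.5, 0.5], [0.5, 0.5], 0.0) == 0.0


def test_median_dichotomized_closed_form():
    # for p = 0.5 binaries, rho_point = (2/pi) * arcsin(rho_z)
    target = 0.5
    rho_z = rp.intermediate_correlation([0.5, 0.5], [0.5, 0.5], target,
                                        codes_i=[0, 1], codes_j=[0, 1])
    assert rho_z == pytest.approx(np.sin(np.pi * target / 2), abs=1e-3)


def test_discretized_correlation_matches_arcsine_law():
    for rho_z in (-0.6, 0.2, 0.9):
        got = discretized_correlation([0.5, 0.5], [0.5, 0.5], rho_z)
        assert got == pytest.approx(2 / np.pi * np.arcsin(rho_z), abs=1e-6)


def test_intermediate_correlation_monotone_in_target():
    probs = [0.2, 0.5, 0.3]
    vals = [rp.intermediate_correlation(probs, [0.4, 0.6], t)
            for t in (-0.5, -0.2, 0.1, 0.4, 0.65)]
    assert (np.diff(vals) > 0).all()


def test_unattainable_target_reports_range():
    # Bernoulli(0.9) vs Bernoulli(0.1): max attainable Pearson corr is 1/9
    with pytest.raises(ValueError, match="attainable range"):
        rp.intermediate_correlation([0.1, 0.9], [0.9, 0.1], 0.5)


def test_build_intermediate_identity_target():
    m = _binary_model()
    build_intermediate_matrix(m)
    np.testing.assert_allclose(m.intermediate_corr, np.eye(2), atol=1e-12)
    assert m.repair_delta == 0.0


def test_build_intermediate_matches_scalar_result():
    sch = [rp.FieldSchema(name="a", categories=(1, 2, 3)),
           rp.FieldSchema(name="b", categories=(1, 2))]
    marg = [np.array([0.3, 0.4, 0.3]), np.array([0.6, 0.4])]
    tc = np.array([[1.0, 0.35], [0.35, 1.0]])
    m = rp.NullModel(schemas=sch, marginals=marg, target_corr=tc, cutoff=0)
    build_intermediate_matrix(m)
    scalar = rp.intermediate_correlation(marg[0], marg[1], 0.35,
                                         codes_i=(1, 2, 3), codes_j=(1, 2))
    assert m.intermediate_corr[0, 1] == pytest.approx(scalar, abs=1e-10)


def test_nearest_positive_definite_repair():
    bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    assert np.linalg.eigvalsh(bad).min() < 0
    fixed, delta = nearest_positive_definite(bad)
    assert delta > 0
    assert np.linalg.eigvalsh(fixed).min() > 0
    np.testing.assert_allclose(np.diag(fixed), 1.0, atol=1e-12)
    np.testing.assert_allclose(fixed, fixed.T)


# -- simulation ------------------------------------------------------------

def test_simulate_ordinal_marginal_recovery():
    m = _binary_model(p=0.3)
    sim = rp.simulate_ordinal(m, 50_000, seed=7)
    assert sim.column("a").mean() == pytest.approx(0.3, abs=0.01)


def test_simulate_ordinal_same_seed_identical():
    m = _binary_model()
    a = rp.simulate_ordinal(m, 500, seed=5)
    b = rp.simulate_ordinal(m, 500, seed=5)
    np.testing.assert_array_equal(a.values, b.values)


def test_simulate_identity_corr_independent():
    m = _binary_model()
    sim = rp.simulate_ordinal(m, 50_000, seed=9)
    assert abs(np.corrcoef(sim.values.T)[0, 1]) < 0.02


# -- scoring and rejection sampling ---------------------------------------

def test_score_examples(null_model):
    schemas = null_model.schemas
    zero_row = [s.categories[0] for s in schemas]
    s, eligible = rp.score(zero_row, schemas, cutoff=27)
    assert s == 0 and not eligible
    max_row = [s.categories[-1] for s in schemas]
    s, eligible = rp.score(max_row, schemas, cutoff=27)
    assert s == 89 and eligible


def test_score_cutoff_is_non_strict(tiny_schemas):
    row = [5, 5, 20]  # weights 4 + 8; age carries no weight
    s, eligible = rp.score(row, tiny_schemas, cutoff=12)
    assert s == 12 and eligible


def test_score_missing_level_errors():
    sch = [rp.FieldSchema(name="x", categories=(1, 2), weights={1: 0, 2: 5})]
    with pytest.raises(ValueError, match="missing from weight map"):
        _score_matrix(np.array([[3.0]]), sch)


def test_rejection_sample_contract(null_model):
    cohort = rp.rejection_sample_cohort(null_model, 300, seed=13)
    m = cohort.matrix
    assert m.n == 300
    scores = _score_matrix(m.values[:, :-1], null_model.schemas)
    assert (scores >= null_model.cutoff).all()
    # appended order is a permutation of 1..N
    np.testing.assert_array_equal(np.sort(m.column("order")), np.arange(1, 301))


def test_rejection_acceptance_near_one_without_screens():
    m = _binary_model(completion=None)  # cutoff 0, no completion model
    cohort = rp.rejection_sample_cohort(m, 200, seed=4)
    assert cohort.acceptance_rate == pytest.approx(1.0)


def test_rejection_acceptance_matches_brute_force(null_model):
    # brute-force: simulate unscreened respondents, average the acceptance prob
    sim = rp.simulate_ordinal(null_model, 20_000, seed=17)
    scores = _score_matrix(sim.values, null_model.schemas)
    p_complete = null_model.completion_probability(sim.values)
    expected = np.mean((scores >= null_model.cutoff) * p_complete)
    cohort = rp.rejection_sample_cohort(null_model, 3000, seed=18)
    assert cohort.acceptance_rate == pytest.approx(expected, abs=0.02)


def test_screened_population_enriched_for_risk(null_model):
    pool = rp.simulate_ordinal(null_model, 20_000, seed=19)
    scores = _score_matrix(pool.values, null_model.schemas)
    kept = pool.values[scores >= null_model.cutoff]
    # positive weights: eligible respondents sit higher on every weighted item
    for j, sch in enumerate(null_model.schemas):
        if sch.weights:
            assert kept[:, j].mean() > pool.values[:, j].mean()


def test_permuted_order_uncorrelated_with_fields(null_model):
    cohort = rp.rejection_sample_cohort(null_model, 3000, seed=23)
    order = cohort.matrix.column("order")
    for j in range(len(null_model.schemas)):
        r = np.corrcoef(order, cohort.matrix.values[:, j])[0, 1]
        assert abs(r) < 0.05


def test_null_model_json_round_trip(null_model, tmp_path):
    path = tmp_path / "model.json"
    null_model.to_json(path)
    again = rp.NullModel.from_json(path)
    np.testing.assert_allclose(again.target_corr, null_model.target_corr)
    np.testing.assert_allclose(again.intermediate_corr, null_model.intermediate_corr)
    assert again.cutoff == null_model.cutoff
    assert again.field_names == null_model.field_names
    assert again.schemas[0].weights == null_model.schemas[0].weights
    assert again.completion_coefs == null_model.completion_coefs
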