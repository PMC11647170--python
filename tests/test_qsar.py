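"""OLS fitting, validation statistics, GA selection, and the frozen model."""

import numpy as np
import pandas as pd
import pytest

from bitterqsar.qsar import (
    GAConfig,
    QsarModel,
    RankDeficientError,
    SplitSpec,
    fit_ols,
    ga_evolve,
    loo_q2,
    published_model,
    published_model_predict,
    r_squared,
    split_train_test,
)
from bitterqsar.synth import PlantedModelSpec, gen_descriptor_table
from bitterqsar.topo import DescriptorTable


def make_table(X, y, names=None):
    names = names or [f"x{k}" for k in range(X.shape[1])]
    ids = [f"c{k}" for k in range(X.shape[0])]
    df = pd.DataFrame(X, index=pd.Index(ids, name="compound_id"), columns=names)
    return DescriptorTable(df, pd.Series(y, index=df.index, name="S"))


def brute_force_loo_q2(X, y):
    """Independent oracle: refit OLS n times, one observation out."""
    n = len(y)
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        Xa = np.column_stack([np.ones(n - 1), X[keep]])
        beta, *_ = np.linalg.lstsq(Xa, y[keep], rcond=None)
        yhat = beta[0] + X[i] @ beta[1:]
        press += (y[i] - yhat) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)


# ---------------------------------------------------------------------------
# splitting

def test_split_490_at_080_gives_392_98():
    ids = [f"c{k}" for k in range(490)]
    train, test = split_train_test(ids, SplitSpec(seed=0, train_fraction=0.8))
    assert (len(train), len(test)) == (392, 98)
    assert set(train) | set(test) == set(ids)
    assert set(train) & set(test) == set()


def test_split_small_and_deterministic():
    ids = [f"c{k}" for k in range(10)]
    a = split_train_test(ids, SplitSpec(seed=5, train_fraction=0.8))
    b = split_train_test(ids, SplitSpec(seed=5, train_fraction=0.8))
    assert a == b
    assert (len(a[0]), len(a[1])) == (8, 2)
    c = split_train_test(ids, SplitSpec(seed=6, train_fraction=0.8))
    assert c != a  # different seed, different partition (w.h.p.)


def test_split_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        split_train_test(["only"], SplitSpec(seed=0))
    with pytest.raises(ValueError):
        split_train_test(["a", "a", "b"], SplitSpec(seed=0))
    with pytest.raises(ValueError):
        SplitSpec(seed=0, train_fraction=1.0)


# ---------------------------------------------------------------------------
# OLS and validation statistics

def test_fit_ols_exact_interpolation():
    x = np.linspace(0, 10, 20)
    table = make_table(x[:, None], 2.0 * x - 3.0)
    model = fit_ols(table, ["x0"])
    assert model.intercept == pytest.approx(-3.0, abs=1e-10)
    assert model.coefficients["x0"] == pytest.approx(2.0, abs=1e-10)
    assert model.stats["r2"] == pytest.approx(1.0, abs=1e-12)


def test_fit_ols_constant_response_convention():
    table = make_table(np.random.default_rng(0).normal(size=(10, 2)), np.full(10, 3.3))
    model = fit_ols(table, ["x0", "x1"])
    assert model.stats["r2"] == 0.0
    assert all(v == 0.0 for v in model.coefficients.values())


def test_fit_ols_collinear_columns_named():
    rng = np.random.default_rng(1)
    x = rng.normal(size=20)
    X = np.column_stack([x, 2 * x, rng.normal(size=20)])
    table = make_table(X, rng.normal(size=20))
    with pytest.raises(RankDeficientError, match="x0|x1"):
        fit_ols(table, ["x0", "x1", "x2"])


def test_fit_ols_recovers_planted_coefficients_within_error():
    spec = PlantedModelSpec(seed=4)
    table = gen_descriptor_table(spec)
    model = fit_ols(table, ["vsurf_S", "wienerPath"])
    X = table.restrict(["vsurf_S", "wienerPath"]).to_numpy()
    Xa = np.column_stack([np.ones(len(X)), X])
    resid = table.response.to_numpy() - model.predict(table).to_numpy()
    sigma2 = resid @ resid / (len(X) - 3)
    cov = sigma2 * np.linalg.inv(Xa.T @ Xa)
    se = np.sqrt(np.diag(cov))
    planted = [spec.intercept, spec.coefficients["vsurf_S"], spec.coefficients["wienerPath"]]
    fitted = [model.intercept, model.coefficients["vsurf_S"], model.coefficients["wienerPath"]]
    for f, p, s in zip(fitted, planted, se):
        assert abs(f - p) < 3 * s


def test_fit_ols_invariant_to_column_rescaling():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 2))
    y = 1.5 * X[:, 0] - 0.5 * X[:, 1] + rng.normal(0, 0.1, 30)
    t1 = make_table(X.copy(), y)
    X2 = X.copy()
    X2[:, 0] = 10.0 * X2[:, 0] + 3.0  # affine rescale of one column
    t2 = make_table(X2, y)
    m1 = fit_ols(t1, ["x0", "x1"])
    m2 = fit_ols(t2, ["x0", "x1"])
    np.testing.assert_allclose(
        m1.predict(t1).to_numpy(), m2.predict(t2).to_numpy(), atol=1e-9
    )
    assert m2.coefficients["x0"] == pytest.approx(m1.coefficients["x0"] / 10.0)


def test_r_squared_conventions():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(25, 1))
    y = 2 * X[:, 0] + 1
    table = make_table(X, y)
    model = fit_ols(table, ["x0"])
    assert r_squared(model, table) == pytest.approx(1.0, abs=1e-12)
    mean_model = QsarModel(intercept=float(y.mean()), coefficients={"x0": 0.0})
    assert r_squared(mean_model, table) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        r_squared(model, make_table(X, np.full(25, 1.0)))


def test_sample_r2_close_to_population_r2_at_study_size():
    vals = []
    for seed in range(8):
        table = gen_descriptor_table(PlantedModelSpec(seed=seed))
        model = fit_ols(table, ["vsurf_S", "wienerPath"])
        vals.append(model.stats["r2"])
    assert all(abs(v - 0.93) < 0.05 for v in vals)


def test_loo_q2_matches_brute_force_oracle():
    rng = np.random.default_rng(9)
    for trial in range(20):
        X = rng.normal(size=(50, 2)) * rng.uniform(0.5, 20.0)
        y = X @ rng.normal(size=2) + rng.normal(0, rng.uniform(0.1, 2.0), 50)
        table = make_table(X, y)
        fast = loo_q2(table, subset=["x0", "x1"])
        slow = brute_force_loo_q2(X, y)
        assert fast == pytest.approx(slow, abs=1e-10)


def test_loo_q2_near_one_for_noiseless_data():
    x = np.linspace(0, 5, 40)
    table = make_table(x[:, None], 3.0 * x + 1.0)
    assert loo_q2(table, subset=["x0"]) == pytest.approx(1.0, abs=1e-10)


def test_loo_q2_y_scrambling_control():
    rng = np.random.default_rng(21)
    table = gen_descriptor_table(PlantedModelSpec(n=200, pool_width=5, seed=21))
    y = table.response.to_numpy().copy()
    q2s = []
    for _ in range(10):
        rng.shuffle(y)
        scrambled = DescriptorTable(
            table.data, pd.Series(y.copy(), index=table.data.index)
        )
        q2s.append(loo_q2(scrambled, subset=["vsurf_S", "wienerPath"]))
    assert np.mean(q2s) <= 0.1


def test_loo_q2_not_above_r2():
    for seed in range(6):
        table = gen_descriptor_table(PlantedModelSpec(n=120, pool_width=8, seed=seed))
        model = fit_ols(table, ["vsurf_S", "wienerPath"])
        q2 = loo_q2(table, subset=["vsurf_S", "wienerPath"])
        assert q2 <= model.stats["r2"]


# ---------------------------------------------------------------------------
# genetic algorithm

def test_ga_two_column_pool_equals_direct_fit():
    table = gen_descriptor_table(PlantedModelSpec(n=60, pool_width=2, seed=2))
    ga = GAConfig(seed=2, generations=10, population_size=10, max_descriptors=2)
    model = ga_evolve(table, ga=ga, split=SplitSpec(seed=2))
    assert sorted(model.descriptor_names) == ["vsurf_S", "wienerPath"]
    train, _ = split_train_test(table.compound_ids, SplitSpec(seed=2))
    direct = fit_ols(
        DescriptorTable(table.data.loc[train], table.response.loc[train]),
        model.descriptor_names,
    )
    assert model.intercept == pytest.approx(direct.intercept)
    for k in model.coefficients:
        assert model.coefficients[k] == pytest.approx(direct.coefficients[k])


def test_ga_deterministic_per_seed():
    table = gen_descriptor_table(PlantedModelSpec(n=100, pool_width=30, seed=5))
    ga = GAConfig(seed=5, generations=25, population_size=20)
    m1 = ga_evolve(table, ga=ga, split=SplitSpec(seed=5))
    m2 = ga_evolve(table, ga=ga, split=SplitSpec(seed=5))
    assert m1.to_json() == m2.to_json()


def test_ga_rejects_all_constant_pool():
    df = pd.DataFrame(
        np.ones((20, 4)),
        index=pd.Index([f"c{k}" for k in range(20)], name="compound_id"),
        columns=list("abcd"),
    )
    table = DescriptorTable(df, pd.Series(np.arange(20.0), index=df.index))
    with pytest.raises(ValueError, match="constant"):
        ga_evolve(table, ga=GAConfig(seed=0, generations=2, population_size=4))


def test_ga_finds_planted_pair_in_modest_pool():
    table = gen_descriptor_table(PlantedModelSpec(n=200, pool_width=40, seed=8))
    model = ga_evolve(
        table,
        ga=GAConfig(seed=8, generations=60, population_size=40),
        split=SplitSpec(seed=8),
    )
    assert sorted(model.descriptor_names) == ["vsurf_S", "wienerPath"]
    assert model.stats["q2"] <= model.stats["r2_all"] + 1e-9
    assert model.stats["n_train"] + model.stats["n_test"] == 200


# ---------------------------------------------------------------------------
# frozen published model

def test_published_model_constants():
    assert published_model_predict(0.0, 0.0) == pytest.approx(-1.26777, abs=1e-12)
    assert published_model_predict(100.0, 1000.0) == pytest.approx(-2.35877, abs=1e-10)


def test_published_model_monotone_in_surface_area():
    s1 = published_model_predict(200.0, 500.0)
    s2 = published_model_predict(300.0, 500.0)
    assert s2 < s1  # larger interaction surface -> stronger predicted binding


def test_published_model_rejects_non_finite():
    with pytest.raises(ValueError):
        published_model_predict(float("nan"), 0.0)


def test_model_json_round_trip(tmp_path):
    model = published_model()
    path = tmp_path / "model.json"
    model.to_json(path)
    back = QsarModel.from_json(path)
    assert back.intercept == model.intercept == -1.26777
    assert back.coefficients == model.coefficients
    assert back.stats == model.stats


def test_model_predict_missing_column_errors():
    model = published_model()
    df = pd.DataFrame({"vsurf_S": [1.0]}, index=pd.Index(["a"], name="compound_id"))
    with pytest.raises(KeyError, match="wienerPath"):
        model.predict(df)
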