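"""PLS fitting, LOO cross-validation, statistics panel, external validation."""

import numpy as np
import pytest

from fieldsar import qsar, synthgen, fields
from fieldsar.qsar import (PLSModel, fit_pls, field_contributions,
                           loo_cross_validate, loo_prediction_matrix,
                           make_fold_preprocessor, model_statistics,
                           predict_and_validate, scramble_q2,
                           select_components)


def _random_xy(n=24, p=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 1.5 + noise * rng.normal(size=n)
    return X, y, beta


# ------------------------------------------------------------- fitting

def test_exact_fit_single_informative_column():
    rng = np.random.default_rng(2)
    x = rng.normal(size=40)
    X = x[:, None]
    y = 2.0 * x + 3.0
    model = fit_pls(X, y, 1)
    stats = model_statistics(model, X, y)
    assert stats["r2"] == pytest.approx(1.0, abs=1e-9)


def test_full_rank_pls_equals_ols():
    X, y, _ = _random_xy(30, 5, seed=1, noise=0.3)
    model = fit_pls(X, y, 5)
    Xc = X - X.mean(axis=0)
    beta_ols, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
    assert np.abs(model.coef_ - beta_ols).max() < 1e-8


def test_nipals_matches_sklearn_pls():
    sklearn_pls = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
    X, y, _ = _random_xy(40, 12, seed=3, noise=0.5)
    for k in (1, 3, 6):
        ours = fit_pls(X, y, k)
        ref = sklearn_pls(n_components=k, scale=False).fit(X, y)
        assert np.abs(ours.coef_ - ref.coef_.ravel()).max() < 1e-8


def test_noise_free_planted_design_coefficients_recovered():
    """On a well-conditioned full-rank design (where the coefficient vector
    is identifiable) PLS at full rank recovers the planted β exactly."""
    X, y, beta = _random_xy(50, 8, seed=5, noise=0.0)
    model = fit_pls(X, y, 8)
    assert np.corrcoef(model.coef_, beta)[0, 1] > 0.999
    assert np.abs(model.coef_ - beta).max() < 1e-8


def test_planted_field_signal_recovered_noiselessly():
    """σ = 0 planted set: the field->PLS chain reproduces the activity to
    r² >= 0.999 and near-perfect prediction correlation."""
    spec = synthgen.QsarPlantSpec(n_molecules=60, n_train=50, n_test=10,
                                  seed=2, sigma=0.0, randomize_pose=False)
    recs, truth = synthgen.gen_qsar_set(spec)
    g = truth["grid"]
    grid = fields.GridSpec(origin=tuple(g["origin"]), spacing=g["spacing"],
                           dims=tuple(g["dims"]))
    fs = fields.compute_comfa_set(recs, grid)
    y = np.array([r.activity for r in recs])
    res = qsar.build_qsar_model(fs, y, max_components=15)
    assert res.stats["r2"] >= 0.999
    assert np.corrcoef(res.model.predict(res.X), y)[0, 1] > 0.999


def test_rank_deficient_fit_warns_and_truncates():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(20, 2))
    X = np.hstack([base, base @ rng.normal(size=(2, 3))])  # rank 2
    y = X[:, 0] - X[:, 1]
    model = fit_pls(X, y, 5)
    assert model.n_components <= 3


# ------------------------------------------------------------------ LOO

def test_loo_matches_naive_refit_loop(small_qsar):
    """Vectorized LOO equals a literal leave-one-out re-fit loop to 1e-10,
    including per-fold refiltering of the design."""
    fs = small_qsar["fs_train"]
    y = small_qsar["y_train"]
    fold = make_fold_preprocessor(fs, sigma_min=2.0)
    n_comp = 4
    q2, see_cv, preds = loo_cross_validate(None, y, n_comp, fold)
    naive = np.empty(len(y))
    idx = np.arange(len(y))
    for i in range(len(y)):
        tr = idx[idx != i]
        asm = fields.DesignAssembler(sigma_min=2.0).fit(fs.subset(tr))
        Xtr = asm.transform(fs.subset(tr))
        Xte = asm.transform(fs.subset(np.array([i])))
        model = fit_pls(Xtr, y[tr], n_comp)
        naive[i] = model.predict(Xte)[0]
    assert np.abs(preds - naive).max() < 1e-10
    press = ((y - naive) ** 2).sum()
    q2_naive = 1 - press / ((y - y.mean()) ** 2).sum()
    assert q2 == pytest.approx(q2_naive, abs=1e-10)


def test_loo_perfect_linear_model():
    X, y, _ = _random_xy(25, 3, seed=7, noise=0.0)
    q2, _, _ = loo_cross_validate(X, y, 3)
    assert q2 >= 0.999


def test_loo_constant_activity_error():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError, match="zero activity variance"):
        loo_cross_validate(X, np.ones(10), 2)


def test_loo_too_few_samples_error():
    with pytest.raises(ValueError):
        loo_prediction_matrix(np.zeros((2, 2)), np.array([1.0, 2.0]), 1)


# -------------------------------------------------------- model choice

def test_single_latent_direction_selects_one_component():
    rng = np.random.default_rng(1)
    t = rng.normal(size=30)
    X = np.outer(t, rng.normal(size=10))  # exactly rank one
    y = 2 * t
    n_opt, _ = select_components(X, y, 5)
    assert n_opt == 1


def test_two_latent_planted_set_selects_two():
    rng = np.random.default_rng(4)
    t1, t2 = rng.normal(size=(2, 40))
    P = rng.normal(size=(2, 12))
    X = np.outer(t1, P[0]) + np.outer(t2, P[1])
    y = t1 - 0.7 * t2
    n_opt, q2 = select_components(X, y, 6)
    assert n_opt == 2
    assert q2[1] > 0.999


def test_monotone_profile_selects_max():
    X, y, _ = _random_xy(30, 6, seed=9, noise=0.0)
    n_opt, q2 = select_components(X, y, 6)
    # noiseless full-rank linear model: q² improves up to the true rank
    assert n_opt == int(np.argmax(q2)) + 1


# ------------------------------------------------------------ statistics

def test_f_statistic_arithmetic():
    # n=10, N=2, r²=0.9 -> F = (0.9/2)/(0.1/7) = 31.5
    y = np.arange(10.0)
    y = y - y.mean()
    ss_tot = (y ** 2).sum()
    # craft predictions with SS_res = 0.1 * SS_tot
    resid = y / np.sqrt(ss_tot) * np.sqrt(0.1 * ss_tot)
    yhat = y - resid
    model = PLSModel(n_components=2, coef_=np.array([1.0]),
                     x_mean=np.zeros(1), y_mean=0.0,
                     weights=np.empty(0), x_loadings=np.empty(0),
                     y_loadings=np.empty(0), n_samples=10)
    X = yhat[:, None]
    stats = model_statistics(model, X, y)
    assert stats["r2"] == pytest.approx(0.9, abs=1e-12)
    assert stats["F"] == pytest.approx(31.5, abs=1e-9)


def test_perfect_fit_reports_infinite_f():
    y = np.arange(8.0)
    model = PLSModel(n_components=1, coef_=np.array([1.0]),
                     x_mean=np.zeros(1), y_mean=0.0,
                     weights=np.empty(0), x_loadings=np.empty(0),
                     y_loadings=np.empty(0), n_samples=8)
    stats = model_statistics(model, y[:, None], y)
    assert stats["r2"] == 1.0
    assert np.isinf(stats["F"])


def test_statistics_panel_matches_residual_recompute(small_qsar_result, small_qsar):
    res = small_qsar_result
    y = small_qsar["y_train"]
    yhat = res.model.predict(res.X)
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    n, N = len(y), res.stats["N"]
    assert res.stats["r2"] == pytest.approx(1 - ss_res / ss_tot, abs=1e-10)
    assert res.stats["see_ncv"] == pytest.approx(
        np.sqrt(ss_res / (n - N - 1)), abs=1e-10)
    assert res.stats["F"] == pytest.approx(
        (res.stats["r2"] / N) / ((1 - res.stats["r2"]) / (n - N - 1)), rel=1e-10)
    press = ((y - res.loo_predictions) ** 2).sum()
    assert res.stats["q2"] == pytest.approx(1 - press / ss_tot, abs=1e-10)


def test_too_few_dof_error():
    y = np.arange(3.0)
    model = PLSModel(n_components=2, coef_=np.array([1.0]),
                     x_mean=np.zeros(1), y_mean=0.0,
                     weights=np.empty(0), x_loadings=np.empty(0),
                     y_loadings=np.empty(0), n_samples=3)
    with pytest.raises(ValueError):
        model_statistics(model, y[:, None], y)


# ---------------------------------------------------- field contributions

def test_single_field_gets_full_contribution():
    X = np.random.default_rng(0).normal(size=(20, 4))
    model = PLSModel(n_components=1, coef_=np.array([1.0, 0.5, 0.0, 0.0]),
                     x_mean=X.mean(axis=0), y_mean=0.0,
                     weights=np.empty(0), x_loadings=np.empty(0),
                     y_loadings=np.empty(0), n_samples=20)
    cmap = [("S", 0), ("S", 1), ("E", 2), ("E", 3)]
    contrib = field_contributions(model, X, cmap)
    assert contrib["S"] == pytest.approx(1.0, abs=1e-12)
    assert contrib["E"] == pytest.approx(0.0, abs=1e-12)


def test_duplicated_blocks_split_evenly():
    rng = np.random.default_rng(1)
    half = rng.normal(size=(25, 3))
    X = np.hstack([half, half])
    coef = np.array([0.3, -0.2, 0.7, 0.3, -0.2, 0.7])
    model = PLSModel(n_components=1, coef_=coef, x_mean=X.mean(axis=0),
                     y_mean=0.0, weights=np.empty(0), x_loadings=np.empty(0),
                     y_loadings=np.empty(0), n_samples=25)
    cmap = [("S", j) for j in range(3)] + [("E", j) for j in range(3)]
    contrib = field_contributions(model, X, cmap)
    assert contrib["S"] == pytest.approx(0.5, abs=1e-12)
    assert contrib["E"] == pytest.approx(0.5, abs=1e-12)


def test_contributions_sum_to_one(small_qsar_result):
    contrib = small_qsar_result.stats["field_contributions"]
    assert sum(contrib.values()) == pytest.approx(1.0, abs=1e-6)
    assert all(v >= 0 for v in contrib.values())


# ------------------------------------------------------------ validation

def _trivial_model(y_train_mean=0.0):
    return PLSModel(n_components=1, coef_=np.array([1.0]), x_mean=np.zeros(1),
                    y_mean=y_train_mean, weights=np.empty(0),
                    x_loadings=np.empty(0), y_loadings=np.empty(0), n_samples=5)


def test_r2_pred_limits_and_arithmetic():
    model = _trivial_model()
    y = np.array([1.0, 2.0, 3.0])
    # Press = 0: model predicts exactly
    rep = predict_and_validate(model, y[:, None], y)
    assert rep.r2_pred == pytest.approx(1.0, abs=1e-12)
    # Press = SD: predict the training mean everywhere
    rep = predict_and_validate(model, np.zeros((3, 1)), y)
    assert rep.r2_pred == pytest.approx(0.0, abs=1e-12)
    # SD = 4, Press = 1 -> 0.75
    y1 = np.array([2.0])
    rep = predict_and_validate(model, np.array([[1.0]]), y1)
    assert rep.sd == pytest.approx(4.0)
    assert rep.press == pytest.approx(1.0)
    assert rep.r2_pred == pytest.approx(0.75, abs=1e-12)
    assert rep.see_pred == pytest.approx(1.0)


def test_r2_pred_identity_holds(small_qsar_result, small_qsar):
    res = small_qsar_result
    X_test = res.assembler.transform(small_qsar["fs_test"])
    rep = predict_and_validate(res.model, X_test, small_qsar["y_test"])
    assert rep.r2_pred == pytest.approx((rep.sd - rep.press) / rep.sd, abs=1e-12)
    assert rep.r2_pred <= 1.0


def test_empty_test_set_error():
    with pytest.raises(ValueError):
        predict_and_validate(_trivial_model(), np.zeros((0, 1)), np.array([]))


# ----------------------------------------------------- negative control

def test_y_scrambling_collapses_q2(small_qsar, small_qsar_result):
    fs = small_qsar["fs_train"]
    y = small_qsar["y_train"]
    fold = make_fold_preprocessor(fs, sigma_min=2.0)
    q2s = scramble_q2(None, y, small_qsar_result.stats["N"], n_scrambles=20,
                      seed=0, fold_preprocess=fold)
    assert np.median(q2s) <= 0.0


def test_zero_variance_column_changes_nothing(small_qsar):
    fs = small_qsar["fs_train"]
    y = small_qsar["y_train"]
    X, _, _ = fields.assemble_design_matrix(fs, sigma_min=2.0)
    m1 = fit_pls(X, y, 3)
    X_aug = np.hstack([X, np.full((X.shape[0], 1), 7.0)])
    m2 = fit_pls(X_aug, y, 3)
    assert np.abs(m2.predict(X_aug) - m1.predict(X)).max() < 1e-9
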