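"""Proportional-odds engine: closed forms, oracle agreement, invariances."""

import numpy as np
import pytest
from scipy.special import expit, logit

from polydif.ordinal import (
    LRTest,
    NotNestedError,
    ProportionalOdds,
    fit_proportional_odds,
    lr_statistic,
)

from _oracles import grid_search_polr, polr_loglik


def test_intercept_only_cutpoints_are_cumulative_logits():
    y = np.array([0] * 10 + [1] * 25 + [2] * 15)
    fit = ProportionalOdds().fit(None, y)
    expected = logit(np.array([10, 35]) / 50)
    np.testing.assert_allclose(fit.cutpoints_, expected, atol=1e-6)
    # loglik equals multinomial loglik of the observed proportions
    ll = 10 * np.log(0.2) + 25 * np.log(0.5) + 15 * np.log(0.3)
    assert fit.loglik_ == pytest.approx(ll, abs=1e-8)


@pytest.mark.parametrize("seed,n,ncat", [(42, 60, 3), (7, 50, 4), (19, 80, 3)])
def test_matches_grid_search_oracle(seed, n, ncat):
    """ML solution agrees with a dense grid-search maximizer to 1e-4."""
    r = np.random.default_rng(seed)
    x = r.normal(size=n)
    cuts_true = np.linspace(-1, 1, ncat - 1)
    cum = expit(cuts_true[None, :] - (0.8 * x)[:, None])
    cum = np.hstack([np.zeros((n, 1)), cum, np.ones((n, 1))])
    y = np.array([r.choice(ncat, p=p) for p in np.diff(cum, axis=1)])
    if np.unique(y).size < ncat:  # keep the fixture simple: all cats present
        pytest.skip("degenerate draw")
    fit = ProportionalOdds().fit(x[:, None], y)
    _, ll_oracle = grid_search_polr(y, x[:, None], n_cut=ncat - 1)
    assert fit.loglik_ == pytest.approx(ll_oracle, abs=1e-4)
    # and never below it (ours is the maximizer)
    assert fit.loglik_ >= ll_oracle - 1e-6


def test_duplicating_rows_doubles_loglik(ordinal_fixture):
    y, X = ordinal_fixture
    f1 = ProportionalOdds().fit(X, y)
    f2 = ProportionalOdds().fit(np.vstack([X, X]), np.concatenate([y, y]))
    np.testing.assert_allclose(f2.cutpoints_, f1.cutpoints_, atol=1e-4)
    np.testing.assert_allclose(f2.coef_, f1.coef_, atol=1e-4)
    assert f2.loglik_ == pytest.approx(2 * f1.loglik_, abs=1e-5)


def test_monotone_loglik_under_nesting():
    """Adding a predictor column never decreases the maximized loglik."""
    r = np.random.default_rng(0)
    for _ in range(8):
        n = 80
        X = r.normal(size=(n, 2))
        y = r.integers(0, 4, size=n)
        if np.unique(y).size < 2:
            continue
        f0 = ProportionalOdds(compute_se=False).fit(X[:, :1], y)
        f1 = ProportionalOdds(compute_se=False).fit(X, y)
        assert f1.loglik_ >= f0.loglik_ - 1e-7


def test_recentering_predictor_shifts_cutpoints_only(ordinal_fixture):
    y, X = ordinal_fixture
    f = ProportionalOdds().fit(X, y)
    g = ProportionalOdds().fit(X + 2.5, y)
    np.testing.assert_allclose(g.coef_, f.coef_, atol=1e-5)
    np.testing.assert_allclose(
        g.cutpoints_, f.cutpoints_ + 2.5 * f.coef_[0], atol=1e-5
    )
    assert g.loglik_ == pytest.approx(f.loglik_, abs=1e-7)


def test_agrees_with_statsmodels(ordinal_fixture):
    sm = pytest.importorskip("statsmodels.miscmodels.ordinal_model")
    y, X = ordinal_fixture
    ours = ProportionalOdds().fit(X, y)
    theirs = sm.OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
    assert ours.loglik_ == pytest.approx(theirs.llf, abs=1e-6)
    assert ours.coef_[0] == pytest.approx(theirs.params[0], abs=1e-4)
    assert ours.bse_coef_[0] == pytest.approx(theirs.bse[0], rel=1e-3)


def test_loglik_never_positive(ordinal_fixture):
    y, X = ordinal_fixture
    assert ProportionalOdds().fit(X, y).loglik_ <= 0


def test_cutpoints_strictly_increasing(small_study_data):
    data, bank, _ = small_study_data
    fit = ProportionalOdds().fit(
        data.total_score()[:, None].astype(float), data.responses[:, 0]
    )
    assert np.all(np.diff(fit.cutpoints_) > 0)


def test_unobserved_categories_are_collapsed():
    y = np.array([0, 0, 4, 4, 2, 2, 0, 4, 2, 0])  # categories 1, 3 missing
    fit = ProportionalOdds().fit(None, y)
    assert list(fit.categories_) == [0, 2, 4]
    assert fit.cutpoints_.size == 2


def test_single_category_raises():
    with pytest.raises(ValueError, match="categor"):
        ProportionalOdds().fit(None, np.zeros(20, int))


def test_lr_statistic_closed_form(ordinal_fixture):
    y, X = ordinal_fixture
    f1 = ProportionalOdds().fit(X, y)
    f0 = ProportionalOdds().fit(None if X.shape[1] == 1 else X[:, :0], y)
    # identity comparison
    same = lr_statistic(f1, f1)
    assert same == LRTest(0.0, 0, 1.0)
    # chi-square(2) survival has closed form exp(-x/2)
    lr = lr_statistic(f1, f0)

    class Fake:
        pass

    fa, fb = Fake(), Fake()
    for src, dst in ((f1, fa), (f0, fb)):
        dst.n_obs_ = src.n_obs_
        dst.response_hash_ = src.response_hash_
        dst.converged_ = True
    fa.n_params_, fb.n_params_ = 4, 2
    fa.loglik_, fb.loglik_ = -10.0, -13.0
    out = lr_statistic(fa, fb)
    assert out.chi_square == pytest.approx(6.0)
    assert out.df == 2
    assert out.p_value == pytest.approx(np.exp(-3.0), rel=1e-10)


def test_lr_statistic_rejects_mismatched_data(ordinal_fixture):
    y, X = ordinal_fixture
    f1 = ProportionalOdds().fit(X, y)
    y2 = y.copy()
    y2[0] = (y2[0] + 1) % 3
    f2 = ProportionalOdds().fit(X, y2)
    with pytest.raises(NotNestedError):
        lr_statistic(f1, f2)


def test_nonconverged_fit_flags_test(ordinal_fixture):
    y, X = ordinal_fixture
    f1 = fit_proportional_odds(y, X)
    f0 = fit_proportional_odds(y, None)
    f0.converged_ = False
    out = lr_statistic(f1, f0)
    assert not out.valid


def test_oracle_loglik_function_consistency(ordinal_fixture):
    """Package loglik_at equals the independent direct formula."""
    y, X = ordinal_fixture
    f = ProportionalOdds().fit(X, y)
    assert f.loglik_at(f.cutpoints_, f.coef_) == pytest.approx(
        polr_loglik(y, X, f.cutpoints_, f.coef_), abs=1e-9
    )


def test_predict_proba_rows_sum_to_one(ordinal_fixture):
    y, X = ordinal_fixture
    f = ProportionalOdds().fit(X, y)
    p = f.predict_proba(X)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(p >= 0)


def test_sklearn_get_set_params_roundtrip():
    est = ProportionalOdds(compute_se=False, maxiter=50)
    params = est.get_params()
    est2 = ProportionalOdds().set_params(**params)
    assert est2.get_params() == params
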