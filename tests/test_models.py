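"""Spatial regression (loess + CV span selection) and the remap logistic model."""

import numpy as np
import pandas as pd
import pytest

from placeburst.models import (
    RemapLogit,
    SpatialRateRegression,
    fit_remap_logistic,
    percent_variance_explained,
    select_span_cv,
)

from conftest import gaussian_map, make_map


@pytest.mark.parametrize(
    "resid_scale, expected",
    [(0.0, 100.0), (1.0, 0.0), (0.5, 75.0)],
)
def test_pve_constructed_residual_cases(resid_scale, expected):
    """pve is 100 for a perfect fit, 0 for a mean-only fit, 75 when the
    residual SD is half the total SD."""
    rng = np.random.default_rng(0)
    y = rng.normal(3.0, 1.0, 500)
    resid = (y - y.mean()) * resid_scale
    pred = y - resid
    assert percent_variance_explained(y, pred) == pytest.approx(expected, abs=1e-9)


def test_pve_shift_and_scale_invariance():
    rng = np.random.default_rng(1)
    y = rng.normal(0, 1, 300)
    pred = y + rng.normal(0, 0.5, 300)
    base = percent_variance_explained(y, pred)
    assert percent_variance_explained(y + 7.0, pred + 7.0) == pytest.approx(base)
    assert percent_variance_explained(3.0 * y, 3.0 * pred) == pytest.approx(base)


def test_single_element_span_grid():
    rm = gaussian_map(noise_sd=0.3, seed=2)
    assert select_span_cv(rm, span_grid=[0.3], seed=0) == 0.3


def test_cv_prefers_small_span_on_smooth_field():
    """On a noiseless smooth field the chosen span beats any span >= 4x larger."""
    rm = gaussian_map(width=4.0)
    model = SpatialRateRegression(rm)
    grid = [0.05, 0.1, 0.2, 0.5, 1.0]
    errs = dict(zip(grid, model.cv_errors(grid, seed=0)))
    chosen = model.select_span(grid, seed=0)
    for span in grid:
        if span >= 4.0 * chosen:
            assert errs[chosen] < errs[span]


def test_cv_on_noise_map_still_returns_unique_span():
    rng = np.random.default_rng(3)
    rm = make_map(lambda cx, cy: rng.uniform(0, 5, cx.shape))
    span = select_span_cv(rm, span_grid=[0.2, 0.5, 1.0], seed=0)
    assert span in (0.2, 0.5, 1.0)


def test_noiseless_smooth_field_high_pve():
    rm = gaussian_map(width=4.0)
    model = SpatialRateRegression(rm)
    res = model.fit(model.select_span(seed=0))
    assert res.pve >= 95.0


def test_span_one_linear_ramp_exact():
    """A plane is reproduced exactly by a degree-1 local fit at any span."""
    rm = make_map(lambda cx, cy: 1.0 + 0.2 * cx + 0.1 * cy)
    res = SpatialRateRegression(rm).fit(1.0)
    assert res.pve == pytest.approx(100.0, abs=1.0)
    np.testing.assert_allclose(res.predicted, res.observed, atol=1e-8)


def wls_plane_oracle(xy, y, xy_eval, span):
    """Direct normal-equation weighted plane fit per eval point (independent
    of the lstsq-based implementation path)."""
    n = len(xy)
    m = min(n, max(3, int(np.ceil(span * n))))
    out = np.empty(len(xy_eval))
    for k, p in enumerate(xy_eval):
        d = np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1])
        nb = np.sort(np.argsort(d, kind="stable")[:m])
        dn = d[nb]
        dmax = dn.max() * (1.0 + 1e-12)
        w = np.maximum((1.0 - (dn / dmax) ** 3) ** 3, 1e-12)
        X = np.column_stack([np.ones(len(nb)), xy[nb, 0] - p[0], xy[nb, 1] - p[1]])
        XtW = X.T * w
        beta = np.linalg.solve(XtW @ X, XtW @ y[nb])
        out[k] = beta[0]
    return out


@pytest.mark.parametrize("seed", range(5))
def test_full_span_matches_normal_equation_oracle(seed):
    rng = np.random.default_rng(seed)
    rm = gaussian_map(center=(rng.uniform(-5, 5), rng.uniform(-5, 5)), noise_sd=0.5, seed=seed, arena_radius=6.0)
    model = SpatialRateRegression(rm)
    res = model.fit(1.0)
    oracle = wls_plane_oracle(model.xy, model.y, model.xy, 1.0)
    assert np.max(np.abs(res.predicted - oracle)) < 1e-8


def simulate_remap_table(rng, n=1000, a=( -1.0, 0.2, 0.0, 0.0, 0.0)):
    x = rng.normal(3.0, 1.0, n)
    g = rng.integers(0, 2, n).astype(float)
    s2 = rng.integers(0, 2, n).astype(float)
    s3 = (1 - s2) * rng.integers(0, 2, n)
    eta = a[0] + a[1] * x + a[2] * g + a[3] * s2 + a[4] * s3
    y = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return pd.DataFrame(dict(remap=y, isi_peak=x, group=g, session2=s2, session3=s3))


def test_logistic_null_coefficients_near_zero():
    """With the outcome independent of the predictors, non-intercept |z| < 2
    in at least 90% of replicates."""
    ok = np.zeros(4)
    reps = 60
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        df = simulate_remap_table(rng, n=600, a=(-0.5, 0.0, 0.0, 0.0, 0.0))
        res = fit_remap_logistic(df)
        ok += (np.abs(res.zvalues[1:]) < 2.0).astype(int)
    assert np.all(ok / reps >= 0.9)


def test_logistic_reduced_model_columns():
    rng = np.random.default_rng(7)
    df = simulate_remap_table(rng)
    res = fit_remap_logistic(df, columns=("group", "session2", "session3"))
    assert res.exog_names == ["intercept", "group", "session2", "session3"]
    assert res.converged


def test_logistic_single_class_errors():
    df = pd.DataFrame(dict(remap=np.ones(20), isi_peak=np.arange(20.0), group=0.0, session2=0.0, session3=0.0))
    with pytest.raises(ValueError):
        fit_remap_logistic(df)


def test_logistic_perfect_separation_flagged():
    x = np.concatenate([np.full(20, -2.0), np.full(20, 2.0)])
    y = (x > 0).astype(float)
    model = RemapLogit(y, np.column_stack([np.ones(40), x]), ["intercept", "x"])
    with pytest.warns(UserWarning):
        res = model.fit()
    assert not res.converged
    assert res.diagnostic != ""


def test_logistic_deviance_monotone_and_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(11)
    df = simulate_remap_table(rng)
    res = fit_remap_logistic(df)
    assert all(np.diff(res.deviance_path) <= 1e-10)
    X = np.column_stack(
        [np.ones(len(df)), df["isi_peak"], df["group"], df["session2"], df["session3"]]
    )
    ref = sm.Logit(df["remap"].to_numpy(), X).fit(disp=0)
    np.testing.assert_allclose(res.params, ref.params, atol=1e-6)
    np.testing.assert_allclose(res.bse, ref.bse, atol=1e-6)
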