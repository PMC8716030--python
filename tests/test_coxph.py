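import warnings

import numpy as np
import pandas as pd
import pytest

from ocumsm.coxph import (
    breslow_baseline,
    fit_cox,
    nelson_aalen,
    score_max_norm,
)
from ocumsm.event_history import COVARIATE_NAMES, to_counting_process
from ocumsm.simulate import default_params, simulate_cohort


def _rows(entry, exit_, status, x, name="x"):
    return pd.DataFrame(
        {
            "patient_id": np.arange(len(entry)),
            "from_state": 0,
            "to_state": 1,
            "entry": np.asarray(entry, dtype=float),
            "exit": np.asarray(exit_, dtype=float),
            "status": status,
            name: np.asarray(x, dtype=float),
        }
    )


def _toy_loglik(beta, entry, exit_, status, x):
    """Hand-written Breslow partial likelihood for one binary covariate."""
    ll = 0.0
    for t in sorted(set(e for e, s in zip(exit_, status) if s)):
        at_risk = [i for i in range(len(x)) if entry[i] < t <= exit_[i]]
        dead = [i for i in at_risk if exit_[i] == t and status[i]]
        denom = sum(np.exp(beta * x[i]) for i in at_risk)
        for i in dead:
            ll += beta * x[i] - np.log(denom)
    return ll


def test_toy_fit_matches_grid_search_maximizer():
    """Four subjects, two events: the fit equals the dense-grid maximizer of
    the explicit one-dimensional partial likelihood."""
    entry = [0, 0, 0, 0]
    exit_ = [2.0, 4.0, 5.0, 6.0]
    status = [1, 1, 0, 0]
    x = [1.0, 0.0, 1.0, 0.0]
    rows = _rows(entry, exit_, status, x)
    fit = fit_cox(rows, (0, 1), covariate_names=("x",))
    grid = np.linspace(-4, 4, 200001)
    lls = [_toy_loglik(b, entry, exit_, status, x) for b in grid]
    b_star = grid[int(np.argmax(lls))]
    assert fit.converged
    assert fit.beta[0] == pytest.approx(b_star, abs=5e-5)
    assert fit.log_partial_likelihood == pytest.approx(max(lls), abs=1e-8)


def test_relabeling_symmetry():
    """Recoding a binary covariate as 1-x flips the sign of its coefficient."""
    rng = np.random.default_rng(5)
    n = 120
    x = rng.binomial(1, 0.5, n).astype(float)
    t = rng.exponential(1 / np.exp(0.8 * x))
    c = rng.exponential(1.5, n)
    rows_a = _rows(np.zeros(n), np.minimum(t, c), (t <= c).astype(int), x)
    rows_b = _rows(np.zeros(n), np.minimum(t, c), (t <= c).astype(int), 1 - x)
    fa = fit_cox(rows_a, (0, 1), covariate_names=("x",))
    fb = fit_cox(rows_b, (0, 1), covariate_names=("x",))
    assert fa.beta[0] == pytest.approx(-fb.beta[0], abs=1e-8)
    assert fa.se[0] == pytest.approx(fb.se[0], abs=1e-8)


def test_agrees_with_lifelines_on_delayed_entry_data():
    """Coefficients match an independent survival implementation to 1e-6 on
    tie-free left-truncated data."""
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(1)
    n = 300
    x1 = rng.binomial(1, 0.4, n).astype(float)
    x2 = rng.normal(0, 1, n)
    entry = rng.uniform(0, 0.5, n)
    T = entry + rng.exponential(1 / np.exp(0.7 * x1 - 0.4 * x2), n)
    C = entry + rng.exponential(2.0, n)
    df = pd.DataFrame(
        dict(
            patient_id=np.arange(n),
            from_state=0,
            to_state=1,
            entry=entry,
            exit=np.minimum(T, C),
            status=(T <= C).astype(int),
            a=x1,
            b=x2,
        )
    )
    fit = fit_cox(df, (0, 1), covariate_names=("a", "b"))
    cph = lifelines.CoxPHFitter()
    cph.fit(
        df[["entry", "exit", "status", "a", "b"]],
        duration_col="exit",
        event_col="status",
        entry_col="entry",
    )
    assert np.abs(fit.beta - cph.params_.values).max() < 1e-6
    assert np.abs(fit.se - cph.standard_errors_.values).max() < 1e-6


def test_breslow_and_efron_agree_without_ties():
    cohort = simulate_cohort(default_params(n=250, seed=11))
    rows, _ = to_counting_process(cohort)
    fb = fit_cox(rows, (0, 1), ties="breslow")
    fe = fit_cox(rows, (0, 1), ties="efron")
    assert np.allclose(fb.beta, fe.beta, atol=1e-8, equal_nan=True)


def test_score_vanishes_at_optimum(study_fits, cp_rows):
    for fit in study_fits.values():
        assert fit.converged
        assert score_max_norm(fit, cp_rows) <= 1e-6


def test_wald_inference_shape(study_fits):
    for fit in study_fits.values():
        cov = fit.covariance
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-10)
        ok = ~np.isnan(fit.beta)
        assert np.all(fit.ci_lower[ok] < fit.hr[ok])
        assert np.all(fit.hr[ok] < fit.ci_upper[ok])
        assert np.all((fit.p_values[ok] > 0) & (fit.p_values[ok] <= 1))


def test_zero_events_rejected():
    rows = _rows([0, 0], [3.0, 4.0], [0, 0], [0.0, 1.0])
    with pytest.raises(ValueError, match="no events"):
        fit_cox(rows, (0, 1), covariate_names=("x",))


def test_constant_covariate_dropped_with_warning():
    rng = np.random.default_rng(2)
    n = 80
    t = rng.exponential(1, n)
    rows = _rows(np.zeros(n), t, np.ones(n, dtype=int), np.ones(n))
    rows["y"] = rng.normal(size=n)
    with pytest.warns(UserWarning, match="constant"):
        fit = fit_cox(rows, (0, 1), covariate_names=("x", "y"))
    assert np.isnan(fit.beta[0])
    assert np.isfinite(fit.beta[1])


def test_monotone_likelihood_flagged():
    """Perfect separation (events only among exposed) yields a divergence
    flag rather than a silent bogus estimate."""
    rows = _rows(
        [0] * 8,
        [1.0, 2.0, 3.0, 4.0, 9.0, 9.5, 10.0, 11.0],
        [1, 1, 1, 1, 0, 0, 0, 0],
        [1, 1, 1, 1, 0, 0, 0, 0],
    )
    with pytest.warns(UserWarning, match="monotone"):
        fit = fit_cox(rows, (0, 1), covariate_names=("x",))
    assert not fit.converged
    assert fit.beta[0] > 0  # direction of divergence


def test_nelson_aalen_definitional_increment():
    """Three subjects at risk, one event at t=2: increment 1/3."""
    rows = _rows([0, 0, 0], [2.0, 5.0, 7.0], [1, 0, 0], [0, 0, 0])
    ch = nelson_aalen(rows, (0, 1))
    assert list(ch.times) == [2.0]
    assert ch.increments[0] == pytest.approx(1 / 3)
    assert ch(1.9) == 0.0
    assert ch(2.0) == pytest.approx(1 / 3)


def test_nelson_aalen_no_events_flat():
    rows = _rows([0, 0], [2.0, 5.0], [0, 0], [0, 0])
    ch = nelson_aalen(rows, (0, 1))
    assert len(ch.times) == 0
    assert np.all(ch(np.linspace(0, 10, 5)) == 0)


def test_nelson_aalen_recovers_exponential_rate():
    """Large-sample cumulative hazard tracks rate * t for exponential data."""
    rng = np.random.default_rng(4)
    n, rate = 4000, 0.3
    t = rng.exponential(1 / rate, n)
    c = np.full(n, 8.0)
    rows = _rows(np.zeros(n), np.minimum(t, c), (t <= c).astype(int), np.zeros(n))
    ch = nelson_aalen(rows, (0, 1))
    for tt in [1.0, 3.0, 6.0]:
        assert ch(tt) == pytest.approx(rate * tt, rel=0.1)


def test_breslow_baseline_reduces_to_nelson_aalen(study_fits, cp_rows):
    """With all coefficients forced to zero the Breslow baseline is exactly
    the Nelson-Aalen estimator."""
    fit = study_fits[(0, 1)]
    saved = fit.beta.copy()
    try:
        fit.beta = np.zeros_like(saved)
        base = breslow_baseline(fit, cp_rows)
    finally:
        fit.beta = saved
    na = nelson_aalen(cp_rows, (0, 1))
    assert np.allclose(base.times, na.times)
    assert np.allclose(base.increments, na.increments, atol=1e-12)


def test_breslow_baseline_hand_computed():
    """Toy data with one binary covariate: increments d / sum(exp(beta x))."""
    rows = _rows([0, 0, 0, 0], [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1], [1, 0, 1, 0])
    fit = fit_cox(rows, (0, 1), covariate_names=("x",))
    b = fit.beta[0]
    base = fit.baseline_cumhaz
    expected = [
        1 / (2 * np.exp(b) + 2),
        1 / (np.exp(b) + 2),
        1 / 1.0,
    ]
    assert np.allclose(base.increments, expected, atol=1e-10)


def test_single_subject_single_event_increment_one():
    rows = _rows([0], [2.0], [1], [0.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_cox(rows, (0, 1), covariate_names=("x",))
    assert fit.baseline_cumhaz.increments[0] == pytest.approx(1.0)


def test_parameter_recovery_moderate_n():
    """Estimates at n=2000 lie within 3 Monte-Carlo SEs of the generating
    log hazard ratios on the none->mild transition."""
    reps = 12
    betas = []
    for rep in range(reps):
        cohort = simulate_cohort(default_params(n=2000, seed=300 + rep))
        rows, _ = to_counting_process(cohort)
        fit = fit_cox(rows, (0, 1))
        betas.append(fit.beta)
    betas = np.array(betas)
    true = default_params().beta[(0, 1)]
    mean = betas.mean(axis=0)
    se = betas.std(axis=0, ddof=1) / np.sqrt(reps)
    assert np.all(np.abs(mean - true) <= 3.5 * se + 0.02)
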