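"""Bayesian machinery: HDI, ROPE, Savage-Dickey, pMAP, diagnostics, and
mixed-model parameter recovery against closed forms and brute force."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from turngait import bayes


# ---------------------------------------------------------------------------
# HDI
# ---------------------------------------------------------------------------

def hdi_brute_force(samples, mass=0.95):
    """Independent oracle: scan every window of ceil(mass*n) sorted samples."""
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    best = (np.inf, None)
    for i in range(n - k):
        width = x[i + k] - x[i]
        if width < best[0]:
            best = (width, (float(x[i]), float(x[i + k])))
    return best[1]


def test_hdi_degenerate_and_gaussian():
    assert bayes.hdi([3.0] * 50) == (3.0, 3.0)
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 200_000)
    lo, hi = bayes.hdi(x)
    assert lo == pytest.approx(-1.96, abs=0.03)
    assert hi == pytest.approx(1.96, abs=0.03)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(5, 400), st.integers(0, 10_000),
       st.sampled_from([0.5, 0.8, 0.95]))
def test_hdi_equals_brute_force_oracle(n, seed, mass):
    rng = np.random.default_rng(seed)
    x = rng.gamma(2.0, 1.5, n)  # skewed, so the shortest window is off-center
    assert bayes.hdi(x, mass) == hdi_brute_force(x, mass)


# ---------------------------------------------------------------------------
# ROPE
# ---------------------------------------------------------------------------

def test_rope_decision_point_masses():
    pct, dec = bayes.rope_decision(np.zeros(100), 0.2)
    assert dec == "practically_equivalent" and pct == 100.0
    pct, dec = bayes.rope_decision(np.full(100, 2.0), 0.2)
    assert dec == "different" and pct == 0.0


def test_rope_gaussian_fraction_matches_phi():
    """Standard-normal effect posterior, ROPE +-0.2: the in-ROPE mass is
    Phi(0.2) - Phi(-0.2) ~ 15.85%, and the decision is undecided."""
    rng = np.random.default_rng(1)
    d = rng.normal(0, 1, 300_000)
    pct, dec = bayes.rope_decision(d, 0.2)
    expected = 100 * (stats.norm.cdf(0.2) - stats.norm.cdf(-0.2))
    assert pct == pytest.approx(expected, abs=0.4)
    assert dec == "undecided"


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.floats(0.5, 20.0), st.integers(0, 1000))
def test_rope_halfwidth_scales_with_data(scale, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, 200)
    base = bayes.rope_halfwidth(x)
    assert bayes.rope_halfwidth(x * scale) == pytest.approx(base * scale, rel=1e-9)
    assert base == pytest.approx(0.2 * np.std(x), rel=1e-12)


# ---------------------------------------------------------------------------
# Savage-Dickey, robustness, pMAP
# ---------------------------------------------------------------------------

def test_savage_dickey_posterior_equals_prior_gives_bf_one():
    rng = np.random.default_rng(2)
    d = rng.normal(0, 1.6, 100_000)
    assert bayes.bayes_factor_savage_dickey(d) == pytest.approx(1.0, rel=0.05)


def test_savage_dickey_matches_conjugate_closed_form():
    """Normal prior N(0, 1.6^2), known-sigma normal likelihood: BF from the
    exact posterior samples must match the marginal-likelihood ratio."""
    prior_sd, sigma, n, ybar = 1.6, 1.0, 25, 0.4
    post_var = 1.0 / (1.0 / prior_sd**2 + n / sigma**2)
    post_mean = post_var * n * ybar / sigma**2
    rng = np.random.default_rng(3)
    d = rng.normal(post_mean, np.sqrt(post_var), 200_000)
    bf10_kde = bayes.bayes_factor_savage_dickey(d, prior_sd)
    # oracle: BF01 = p(y|H0) / p(y|H1) with ybar ~ N(0, prior^2 + sigma^2/n)
    m0 = stats.norm.pdf(ybar, 0, sigma / np.sqrt(n))
    m1 = stats.norm.pdf(ybar, 0, np.sqrt(prior_sd**2 + sigma**2 / n))
    assert bf10_kde == pytest.approx(m1 / m0, rel=0.10)


def test_savage_dickey_large_effect_gives_large_bf():
    rng = np.random.default_rng(4)
    d = rng.normal(5.0, 0.3, 50_000)
    assert bayes.bayes_factor_savage_dickey(d) > 100.0


def test_bf_robustness_monotone_for_null_posterior():
    """Posterior symmetric at 0: BF01 grows with the prior SD (the prior
    density at 0 shrinks), so BF10 falls monotonically."""
    rng = np.random.default_rng(5)
    d = rng.normal(0, 0.5, 100_000)
    grid = [0.5, 1.0, 1.6, 2.5, 4.0]
    curve = bayes.bf_robustness(grid, d)
    assert list(curve["prior_sd"]) == grid
    assert curve["bf10"].is_monotonic_decreasing
    single = bayes.bf_robustness([1.6], d)
    assert single["bf10"][0] == pytest.approx(
        bayes.bayes_factor_savage_dickey(d), rel=1e-12)


def test_p_map_closed_form():
    rng = np.random.default_rng(6)
    assert bayes.p_map(rng.normal(0, 1, 50_000)) == pytest.approx(1.0, abs=0.05)
    assert bayes.p_map(rng.normal(8, 0.5, 50_000)) == pytest.approx(0.0, abs=1e-6)
    mu, sd = 1.3, 0.8
    got = bayes.p_map(rng.normal(mu, sd, 200_000))
    assert got == pytest.approx(np.exp(-mu**2 / (2 * sd**2)), abs=0.02)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_diagnostics_iid_and_ar1():
    rng = np.random.default_rng(7)
    n = 20_000
    iid = rng.normal(size=(2, n))
    out = bayes.diagnostics({"x": iid})
    assert out["rhat"]["x"] == pytest.approx(1.0, abs=0.01)
    assert out["ess"]["x"] == pytest.approx(2 * n, rel=0.10)
    phi = 0.9
    ar = np.empty((2, n))
    for c in range(2):
        e = rng.normal(size=n)
        ar[c, 0] = e[0]
        for i in range(1, n):
            ar[c, i] = phi * ar[c, i - 1] + e[i]
    out = bayes.diagnostics({"x": ar})
    expected = 2 * n * (1 - phi) / (1 + phi)
    assert out["ess"]["x"] == pytest.approx(expected, rel=0.20)


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def simulate_table(effect=0.0, n_subjects=10, subj_sd=1.0, resid_sd=1.0,
                   seed=0, base=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        us = rng.normal(0, subj_sd)
        for speed in bayes.SPEED_LEVELS:
            for amp in bayes.AMPLITUDE_LEVELS:
                mu = base + (effect if speed == "slow" else 0.0)
                rows.append(dict(subject=s, speed=speed, amplitude=amp,
                                 value=mu + us + rng.normal(0, resid_sd)))
    return pd.DataFrame(rows)


def fast_spec(seed=0, **kw):
    kw.setdefault("chains", 2)
    kw.setdefault("warmup", 200)
    kw.setdefault("draws", 800)
    return bayes.ModelSpec(response="x", seed=seed, **kw)


def test_fit_recovers_known_speed_effect():
    """Speed effect -20 units, zero interaction: posterior means inside
    2 posterior SDs of the truth."""
    table = simulate_table(effect=-20.0, subj_sd=2.5, resid_sd=1.0, base=113.0,
                           seed=8)
    post = bayes.fit_model(table, fast_spec(seed=1, draws=1500))
    c = bayes.speed_contrast()
    raw = bayes.contrast_samples(post, c) * post.scale
    assert abs(raw.mean() - (-20.0)) < 2 * raw.std()
    inter = bayes.contrast_samples(post, bayes.design_row("slow", 360)
                                   - bayes.design_row("slow", 90)
                                   - bayes.design_row("normal", 360)
                                   + bayes.design_row("normal", 90)) * post.scale
    assert abs(inter.mean()) < 3 * inter.std()


def test_fit_zero_response_concentrates_at_zero():
    table = simulate_table(effect=0.0, subj_sd=0.0, resid_sd=0.0)
    table["value"] = 0.0
    post = bayes.fit_model(table, fast_spec(seed=2))
    raw = bayes.contrast_samples(post, bayes.speed_contrast()) * post.scale
    assert abs(raw.mean()) < 0.05 and raw.std() < 0.2


def test_fit_deterministic_given_seed():
    table = simulate_table(effect=-1.0, seed=9)
    a = bayes.fit_model(table, fast_spec(seed=3))
    b = bayes.fit_model(table, fast_spec(seed=3))
    np.testing.assert_array_equal(a.beta, b.beta)


def test_cohens_d_zero_contrast_and_scale_invariance():
    table = simulate_table(effect=-2.4, resid_sd=1.0, subj_sd=0.5, seed=10)
    post = bayes.fit_model(table, fast_spec(seed=4, draws=1500))
    zero = bayes.cohens_d(post, np.zeros(6))
    assert np.all(zero == 0)
    d1 = bayes.cohens_d(post, bayes.speed_contrast())
    table2 = table.assign(value=table["value"] * 2.0)
    post2 = bayes.fit_model(table2, fast_spec(seed=4, draws=1500))
    d2 = bayes.cohens_d(post2, bayes.speed_contrast())
    assert d1.mean() == pytest.approx(d2.mean(), rel=0.05)  # scale-free
    # recovery of the simulated standardized magnitude
    assert abs(d1.mean() - (-2.4)) < 2 * d1.std() + 0.3


def test_eta_squared_bounds_and_single_factor():
    table = simulate_table(effect=-5.0, subj_sd=0.1, resid_sd=0.3, seed=11)
    post = bayes.fit_model(table, fast_spec(seed=5))
    for factor in ("speed", "amplitude"):
        e2 = bayes.eta_squared(post, factor)
        assert np.all((e2 >= 0) & (e2 <= 1))
    assert bayes.eta_squared(post, "speed").mean() > 0.9
    assert bayes.eta_squared(post, "amplitude").mean() < 0.1


def test_nonconvergence_is_flagged_not_silent():
    table = simulate_table(effect=-1.0, seed=12)
    spec = fast_spec(seed=6, draws=40, warmup=5)
    with pytest.warns(RuntimeWarning, match="effective sample size"):
        bayes.fit_model(table, spec)
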