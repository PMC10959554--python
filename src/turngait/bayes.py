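"""Bayesian repeated-measures inference with HDI+ROPE decisions.

The model is a linear mixed model for one response parameter (its
per-subject condition mean, or its within-subject SD) over a 2 x 3
repeated-measures design:

    y_{s,ij} = mu + speed_i + amplitude_j + (speed x amplitude)_{ij}
               + u_s + eps,   u_s ~ N(0, sigma_u^2),  eps ~ N(0, sigma^2)

The response is standardized by the SD of all its subject-condition values
before fitting, so fixed-effect coefficients live on the standardized-
effect scale where the N(0, 1.6) prior applies (that prior puts ~80% mass
on effect sizes between -2 and 2).  Variance components get half-Cauchy
priors via the usual inverse-gamma scale-mixture, which keeps the sampler
a pure Gibbs scheme: every full conditional is normal or inverse gamma.

Decisions use the 95% highest-density interval against a region of
practical equivalence of +-0.2 standardized units (a "small" effect):
"different" when the HDI and ROPE are disjoint, "practically equivalent"
when the HDI lies inside the ROPE, "undecided" otherwise.  Bayes factors
come from the Savage-Dickey density ratio under the N(0, 1.6) prior, and
pMAP is the posterior-density ratio at zero versus the mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PRIOR_EFFECT_SD = 1.6     # N(0, 1.6) prior on standardized effects
ROPE_SMALL_EFFECT = 0.2   # ROPE half-width: 0.2 standardized units
VARIANCE_PRIOR_SCALE = 2.5  # half-Cauchy scale for SD components (standardized data)
ESS_MINIMUM = 10_000      # per-parameter effective-sample-size floor

SPEED_LEVELS = ("normal", "slow")
AMPLITUDE_LEVELS = (90, 180, 360)

Decision = Literal["different", "practically_equivalent", "undecided"]


@dataclass
class ModelSpec:
    """Sampler settings and priors for one response parameter."""

    response: str
    prior_effect_sd: float = PRIOR_EFFECT_SD
    chains: int = 4
    warmup: int = 500
    draws: int = 5000
    seed: int | None = None
    #: run split-R-hat / ESS checks after sampling (skip for bulk
    #: short-chain simulation studies)
    check_diagnostics: bool = True

    def __post_init__(self) -> None:
        if self.prior_effect_sd <= 0:
            raise ValueError("prior SD must be positive")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-R-hat")


@dataclass
class PosteriorSamples:
    """MCMC output of :func:`fit_model`.

    ``beta`` has one column per fixed-effect coefficient (intercept, slow,
    amp180, amp360, slow:amp180, slow:amp360) on the standardized response
    scale; ``scale`` is the SD used to standardize, so raw-unit quantities
    are ``standardized * scale``.
    """

    beta: np.ndarray          # (chains, draws, 6)
    sigma: np.ndarray         # (chains, draws) residual SD (standardized)
    sigma_u: np.ndarray       # (chains, draws) subject SD (standardized)
    scale: float
    coef_names: tuple[str, ...]
    seed: int | None

    def flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(-1, *arr.shape[2:])

    def cell_mean(self, speed: str, amplitude: int) -> np.ndarray:
        """Posterior draws of one cell mean (standardized units)."""
        x = design_row(speed, amplitude)
        return self.flat(self.beta) @ x


def design_row(speed: str, amplitude: int) -> np.ndarray:
    """Treatment-coded design row: intercept, slow, amp180, amp360,
    slow:amp180, slow:amp360."""
    s = 1.0 if speed == "slow" else 0.0
    a180 = 1.0 if amplitude == 180 else 0.0
    a360 = 1.0 if amplitude == 360 else 0.0
    return np.array([1.0, s, a180, a360, s * a180, s * a360])


COEF_NAMES = ("intercept", "slow", "amp180", "amp360", "slow:amp180", "slow:amp360")


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([design_row(r.speed, int(r.amplitude)) for r in table.itertuples()])
    subjects, subj_idx = np.unique(table["subject"].to_numpy(), return_inverse=True)
    y = table["value"].to_numpy(float)
    return X, y, subj_idx


def fit_model(table: pd.DataFrame, spec: ModelSpec) -> PosteriorSamples:
    """Gibbs sampler for the random-intercept model.

    ``table`` needs columns subject, speed, amplitude, value with one row
    per subject x condition cell (a complete or near-complete 2 x 3 table).
    The response is standardized by the SD of all its values; a constant
    response keeps scale 1.  Raises a warning (never silently) when any
    split-R-hat exceeds 1.01 or any ESS falls below the floor.
    """
    for col in ("subject", "speed", "amplitude", "value"):
        if col not in table.columns:
            raise ValueError(f"summary table lacks required column {col!r}")
    X, y_raw, subj_idx = _design(table)
    scale = float(np.std(y_raw))
    if not np.isfinite(scale) or scale == 0.0:
        scale = 1.0
    y = y_raw / scale
    n, p = X.shape
    n_subj = subj_idx.max() + 1
    # joint design [X | Z]: sampling beta and u as one Gaussian block avoids
    # the slow mixing of intercept vs mean subject effect
    Z = np.zeros((n, n_subj))
    Z[np.arange(n), subj_idx] = 1.0
    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    q = p + n_subj

    # N(0, prior_sd^2) on non-intercept effects, vague N(0, 10^2) intercept
    fixed_prec = np.array([1.0 / 10.0 ** 2]
                          + [1.0 / spec.prior_effect_sd ** 2] * (p - 1))
    A2 = VARIANCE_PRIOR_SCALE ** 2

    root = np.random.SeedSequence(spec.seed)
    chains_beta, chains_sigma, chains_sigma_u = [], [], []
    for seq in root.spawn(spec.chains):
        rng = np.random.default_rng(seq)
        theta = np.zeros(q)
        sig2, sig2_u = 1.0, 0.5
        a_sig = a_u = 1.0
        keep_b = np.empty((spec.draws, p))
        keep_s = np.empty(spec.draws)
        keep_su = np.empty(spec.draws)
        for it in range(spec.warmup + spec.draws):
            # joint (beta, u) block
            prior_diag = np.concatenate([fixed_prec,
                                         np.full(n_subj, 1.0 / sig2_u)])
            prec = WtW / sig2 + np.diag(prior_diag)
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, Wty / sig2)
            z = rng.standard_normal(q)
            theta = mean + np.linalg.solve(chol.T, z)
            beta, u = theta[:p], theta[p:]
            # residual variance (half-Cauchy via IG mixture)
            rss = float(np.sum((y - W @ theta) ** 2))
            sig2 = 1.0 / rng.gamma((n + 1) / 2.0, 1.0 / (1.0 / a_sig + rss / 2.0))
            sig2 = max(sig2, 1e-12)  # keep degenerate (constant) data finite
            a_sig = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A2 + 1.0 / sig2))
            # subject variance
            ssu = float(np.sum(u ** 2))
            sig2_u = 1.0 / rng.gamma((n_subj + 1) / 2.0,
                                     1.0 / (1.0 / a_u + ssu / 2.0))
            sig2_u = max(sig2_u, 1e-12)
            a_u = 1.0 / rng.gamma(1.0, 1.0 / (1.0 / A2 + 1.0 / sig2_u))
            if it >= spec.warmup:
                j = it - spec.warmup
                keep_b[j] = beta
                keep_s[j] = np.sqrt(sig2)
                keep_su[j] = np.sqrt(sig2_u)
        chains_beta.append(keep_b)
        chains_sigma.append(keep_s)
        chains_sigma_u.append(keep_su)

    post = PosteriorSamples(
        beta=np.stack(chains_beta), sigma=np.stack(chains_sigma),
        sigma_u=np.stack(chains_sigma_u), scale=scale,
        coef_names=COEF_NAMES, seed=spec.seed)
    if not spec.check_diagnostics:
        return post
    diag = diagnostics({"beta": post.beta, "sigma": post.sigma[..., None]})
    bad_rhat = {k: v for k, v in diag["rhat"].items() if v > 1.01}
    if bad_rhat:
        warnings.warn(f"MCMC convergence flagged: split-R-hat > 1.01 for {bad_rhat}",
                      RuntimeWarning, stacklevel=2)
    low_ess = {k: v for k, v in diag["ess"].items() if v < ESS_MINIMUM}
    if low_ess:
        warnings.warn(
            f"effective sample size below {ESS_MINIMUM} for {low_ess}; "
            "increase draws or chains", RuntimeWarning, stacklevel=2)
    return post


# ---------------------------------------------------------------------------
# posterior functionals
# ---------------------------------------------------------------------------

def contrast_samples(post: PosteriorSamples, contrast: np.ndarray) -> np.ndarray:
    """Posterior draws of a linear contrast of the 6 fixed-effect
    coefficients (standardized units)."""
    return post.flat(post.beta) @ np.asarray(contrast, float)


def speed_contrast(amplitude: int | None = None) -> np.ndarray:
    """slow - normal, at one amplitude or averaged over all three."""
    if amplitude is not None:
        return design_row("slow", amplitude) - design_row("normal", amplitude)
    rows = [design_row("slow", a) - design_row("normal", a) for a in AMPLITUDE_LEVELS]
    return np.mean(rows, axis=0)


def amplitude_contrast(a2: int, a1: int, speed: str | None = None) -> np.ndarray:
    """amplitude a2 - amplitude a1, within one speed or averaged."""
    if speed is not None:
        return design_row(speed, a2) - design_row(speed, a1)
    rows = [design_row(s, a2) - design_row(s, a1) for s in SPEED_LEVELS]
    return np.mean(rows, axis=0)


def cohens_d(post: PosteriorSamples, contrast: np.ndarray) -> np.ndarray:
    """Posterior of Cohen's d: contrast / residual SD, samplewise.
    Scale-invariant because both live on the standardized response scale."""
    return contrast_samples(post, contrast) / post.flat(post.sigma)


def hdi(samples: Sequence[float], mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[:n - k]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k])


def rope_halfwidth(all_values: Sequence[float],
                   small_effect: float = ROPE_SMALL_EFFECT) -> float:
    """ROPE half-width in raw units: ``small_effect`` x the SD pooled over
    every subject-condition value of the parameter."""
    return small_effect * float(np.std(np.asarray(all_values, float)))


def rope_decision(d_samples: Sequence[float], rope_hw: float,
                  mass: float = 0.95) -> tuple[float, Decision]:
    """(% of posterior mass inside the ROPE, three-way HDI+ROPE decision)."""
    d = np.asarray(d_samples, float)
    lo, hi = hdi(d, mass)
    pct_in = 100.0 * float(np.mean(np.abs(d) <= rope_hw))
    if hi < -rope_hw or lo > rope_hw:
        return pct_in, "different"
    if lo >= -rope_hw and hi <= rope_hw:
        return pct_in, "practically_equivalent"
    return pct_in, "undecided"


def _kde_density(samples: np.ndarray, at: float) -> float:
    if np.ptp(samples) < 1e-12:  # degenerate posterior
        return np.inf if abs(at - samples[0]) < 1e-12 else 0.0
    kde = stats.gaussian_kde(samples)  # Silverman bandwidth
    return float(kde(at)[0])


def bayes_factor_savage_dickey(d_samples: Sequence[float],
                               prior_sd: float = PRIOR_EFFECT_SD,
                               null_value: float = 0.0) -> float:
    """BF10 by the Savage-Dickey density ratio: prior density at the null
    over the kernel-density posterior estimate at the null."""
    d = np.asarray(d_samples, float)
    post_at_null = _kde_density(d, null_value)
    prior_at_null = float(stats.norm.pdf(null_value, 0.0, prior_sd))
    if post_at_null == 0.0:
        return np.inf
    return prior_at_null / post_at_null


def bf_robustness(prior_sds: Sequence[float],
                  d_samples: Sequence[float]) -> pd.DataFrame:
    """BF10 over a grid of prior SDs (same posterior draws re-evaluated;
    a density-ratio approximation appropriate when the likelihood dominates
    the prior)."""
    rows = [{"prior_sd": float(s),
             "bf10": bayes_factor_savage_dickey(d_samples, prior_sd=float(s))}
            for s in prior_sds]
    return pd.DataFrame(rows)


def p_map(d_samples: Sequence[float], null_value: float = 0.0) -> float:
    """MAP-based p-value: posterior density at the null over the density at
    the posterior mode, clipped to [0, 1]."""
    d = np.asarray(d_samples, float)
    if np.ptp(d) < 1e-12:
        return 1.0 if abs(null_value - d[0]) < 1e-12 else 0.0
    kde = stats.gaussian_kde(d)
    grid = np.linspace(d.min(), d.max(), 512)
    mode_density = float(kde(grid).max())
    return float(np.clip(kde(null_value)[0] / mode_density, 0.0, 1.0))


def eta_squared(post: PosteriorSamples, factor: Literal["speed", "amplitude"]
                ) -> np.ndarray:
    """Posterior of eta squared: the factor's share of the between-cell sum
    of squares, computed samplewise from the 6 posterior cell means."""
    cells = np.stack([[post.cell_mean(s, a) for a in AMPLITUDE_LEVELS]
                      for s in SPEED_LEVELS])          # (2, 3, ndraws)
    grand = cells.mean(axis=(0, 1))
    m_speed = cells.mean(axis=1) - grand               # (2, ndraws)
    m_amp = cells.mean(axis=0) - grand                 # (3, ndraws)
    inter = cells - grand - m_speed[:, None, :] - m_amp[None, :, :]
    ss_speed = 3.0 * np.sum(m_speed ** 2, axis=0)
    ss_amp = 2.0 * np.sum(m_amp ** 2, axis=0)
    ss_inter = np.sum(inter ** 2, axis=(0, 1))
    ss_tot = ss_speed + ss_amp + ss_inter
    ss_factor = ss_speed if factor == "speed" else ss_amp
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ss_tot > 0, ss_factor / ss_tot, 0.0)
    return out


def diagnostics(chain_sets: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Split-R-hat and autocorrelation-based ESS per parameter.

    ``chain_sets`` maps a name to an array of shape (chains, draws) or
    (chains, draws, k).  Returns {"rhat": {...}, "ess": {...}} keyed by
    name (suffixed ``[i]`` for vector parameters).
    """
    import arviz as az

    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    for name, arr in chain_sets.items():
        arr = np.asarray(arr, float)
        if arr.ndim == 2:
            arr = arr[..., None]
        for i in range(arr.shape[-1]):
            key = name if arr.shape[-1] == 1 else f"{name}[{i}]"
            data = arr[..., i]
            rhat[key] = float(az.rhat(az.convert_to_dataset(data)).x)
            ess[key] = float(az.ess(az.convert_to_dataset(data)).x)
    return {"rhat": rhat, "ess": ess}


# ---------------------------------------------------------------------------
# effect reports
# ---------------------------------------------------------------------------

DECISION_GLYPHS = {"different": "><", "practically_equivalent": "=",
                   "undecided": "?"}


@dataclass
class EffectEstimate:
    """Posterior summary for one contrast of one response parameter."""

    response: str
    contrast: str
    mean_diff: float                  # raw response units
    ci_low: float
    ci_high: float
    d_mean: float
    d_hdi_low: float
    d_hdi_high: float
    eta_squared_mean: float | None
    bf10: float
    p_map: float
    rope_halfwidth: float
    pct_in_rope: float
    decision: Decision
    diagnostics: dict = field(default_factory=dict)

    @property
    def glyph(self) -> str:
        if self.decision == "different":
            return ">" if self.mean_diff > 0 else "<"
        return DECISION_GLYPHS[self.decision]

    def to_row(self) -> dict:
        row = {k: getattr(self, k) for k in (
            "response", "contrast", "mean_diff", "ci_low", "ci_high",
            "d_mean", "d_hdi_low", "d_hdi_high", "eta_squared_mean", "bf10",
            "p_map", "rope_halfwidth", "pct_in_rope", "decision")}
        row["glyph"] = self.glyph
        return row


def standard_contrasts() -> dict[str, np.ndarray]:
    """The contrasts reported for every parameter: speed effect per
    amplitude, and amplitude pairs within each speed."""
    out: dict[str, np.ndarray] = {}
    for a in AMPLITUDE_LEVELS:
        out[f"slow_vs_normal@{a}"] = speed_contrast(a)
    for s in SPEED_LEVELS:
        for a1, a2 in ((90, 180), (90, 360), (180, 360)):
            out[f"{s}:{a2}_vs_{a1}"] = amplitude_contrast(a2, a1, s)
    return out


def analyze_parameter(table: pd.DataFrame, spec: ModelSpec,
                      contrasts: dict[str, np.ndarray] | None = None
                      ) -> list[EffectEstimate]:
    """Fit the mixed model for one response and summarize every contrast."""
    post = fit_model(table, spec)
    if contrasts is None:
        contrasts = standard_contrasts()
    diag = diagnostics({"beta": post.beta, "sigma": post.sigma[..., None]})
    out: list[EffectEstimate] = []
    for name, cvec in contrasts.items():
        std = contrast_samples(post, cvec)   # units: SD of all parameter data
        raw = std * post.scale
        d = cohens_d(post, cvec)
        d_lo, d_hi = hdi(d)
        ci_lo, ci_hi = hdi(raw)
        # ROPE, Savage-Dickey prior and pMAP all live on the scale the
        # response was standardized to (SD of all parameter data)
        pct, decision = rope_decision(std, ROPE_SMALL_EFFECT)
        factor = "speed" if name.startswith("slow_vs_normal") else "amplitude"
        out.append(EffectEstimate(
            response=spec.response, contrast=name,
            mean_diff=float(np.mean(raw)), ci_low=ci_lo, ci_high=ci_hi,
            d_mean=float(np.mean(d)), d_hdi_low=d_lo, d_hdi_high=d_hi,
            eta_squared_mean=float(np.mean(eta_squared(post, factor))),
            bf10=bayes_factor_savage_dickey(std, spec.prior_effect_sd),
            p_map=p_map(std),
            rope_halfwidth=ROPE_SMALL_EFFECT, pct_in_rope=pct,
            decision=decision, diagnostics=diag))
    return out
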