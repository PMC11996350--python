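"""Group-level statistics.

* Hierarchical Bayesian random-intercept / random-slope regression of
  trial-level affective arousal on a physiological predictor, fit by a
  conjugate Gibbs sampler (4 chains x 5000 draws, 2500 warm-up), with
  split-Rhat convergence checks (analysis proceeds only when all
  Rhat <= 1.01) and posterior-mean / 95% credible-interval summaries.
* Default-prior (JZS) Bayes factors: one-sample/paired t and
  single-predictor regression, via adaptive numerical quadrature over
  the Cauchy prior's scale-mixture representation.
* Canonical Bayes-factor interpretation labels.
* Pearson correlation of per-participant HEP effect magnitudes with
  anxiety composites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.stats

__all__ = [
    "HierarchicalFit", "BayesFactorResult", "CorrelationResult",
    "fit_random_slope_model", "rhat", "zscore_within",
    "jzs_bf_one_sample", "jzs_bf_regression", "interpret_bf",
    "correlate_effect_with_anxiety",
]

DEFAULT_CAUCHY_SCALE = math.sqrt(2) / 2


class ConvergenceError(RuntimeError):
    """Raised when posterior summaries are requested from a non-converged fit."""


@dataclass
class HierarchicalFit:
    """Posterior draws and summaries of the random-slope model.

    ``draws`` maps parameter name -> (n_chains, n_draws) post-warmup
    array for: ``beta0``, ``beta1`` (group intercept/slope), ``sigma``
    (residual sd), ``tau0``, ``tau1`` (random-effect sds) and ``rho``
    (random-effect correlation).
    """

    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    n_chains: int
    n_draws: int
    n_warmup: int
    participant_ids: list
    b_means: np.ndarray  # posterior mean of (b0_i, b1_i), (n_participants, 2)
    converged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.converged = all(v <= 1.01 for v in self.rhat.values())

    def _summary_table(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, d in self.draws.items():
            flat = d.ravel()
            lo, hi = np.percentile(flat, [2.5, 97.5])
            out[name] = {
                "mean": float(flat.mean()), "ci_low": float(lo),
                "ci_high": float(hi), "rhat": self.rhat[name],
            }
        return out

    def summary(self, force: bool = False) -> dict[str, dict[str, float]]:
        """Posterior means and 95% credible intervals per parameter.

        Withheld (raises) when any Rhat exceeds 1.01, unless ``force``.
        """
        if not self.converged and not force:
            bad = {k: v for k, v in self.rhat.items() if v > 1.01}
            raise ConvergenceError(f"fit not converged: Rhat {bad}")
        return self._summary_table()

    def slope_excludes_zero(self) -> bool:
        s = self.summary()["beta1"]
        return not (s["ci_low"] <= 0.0 <= s["ci_high"])


def zscore_within(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Z-score ``values`` within each group (participant)."""
    values = np.asarray(values, dtype=float)
    out = np.empty_like(values)
    for g in np.unique(groups):
        m = groups == g
        sd = values[m].std(ddof=0)
        if sd == 0:
            raise ValueError(f"group {g!r} has zero variance; cannot z-score")
        out[m] = (values[m] - values[m].mean()) / sd
    return out


def _sample_invwishart(nu: float, scale: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Inverse-Wishart draw via the Bartlett decomposition (2x2 here)."""
    p = scale.shape[0]
    chol_inv = np.linalg.cholesky(np.linalg.inv(scale))
    a = np.zeros((p, p))
    for i in range(p):
        a[i, i] = math.sqrt(rng.chisquare(nu - i))
        for j in range(i):
            a[i, j] = rng.standard_normal()
    l = chol_inv @ a
    w = l @ l.T  # Wishart(nu, scale^{-1})
    return np.linalg.inv(w)


def _inv2(m: np.ndarray) -> np.ndarray:
    """Batched closed-form inverse of symmetric 2x2 matrices (..., 2, 2)."""
    a, b, c = m[..., 0, 0], m[..., 0, 1], m[..., 1, 1]
    det = a * c - b * b
    out = np.empty_like(m)
    out[..., 0, 0] = c / det
    out[..., 1, 1] = a / det
    out[..., 0, 1] = out[..., 1, 0] = -b / det
    return out


def _chol2(m: np.ndarray) -> np.ndarray:
    """Batched closed-form Cholesky of symmetric PD 2x2 matrices."""
    a, b, c = m[..., 0, 0], m[..., 0, 1], m[..., 1, 1]
    l11 = np.sqrt(a)
    l21 = b / l11
    l22 = np.sqrt(np.clip(c - l21**2, 1e-300, None))
    out = np.zeros_like(m)
    out[..., 0, 0] = l11
    out[..., 1, 0] = l21
    out[..., 1, 1] = l22
    return out


def _gibbs_chain(x, y, groups_idx, n_groups, n_iter, init_scale,
                 priors, rng):
    n = len(y)
    z = np.column_stack([np.ones(n), x])
    ztz = z.T @ z
    # per-group sufficient statistics: counts, sum x, sum x^2
    cnt = np.bincount(groups_idx, minlength=n_groups).astype(float)
    sx = np.bincount(groups_idx, weights=x, minlength=n_groups)
    sxx = np.bincount(groups_idx, weights=x * x, minlength=n_groups)
    ztz_g = np.empty((n_groups, 2, 2))
    ztz_g[:, 0, 0] = cnt
    ztz_g[:, 0, 1] = ztz_g[:, 1, 0] = sx
    ztz_g[:, 1, 1] = sxx

    beta = priors["beta_sd"] * rng.standard_normal(2) * init_scale
    b = np.zeros((n_groups, 2))
    sigma2 = float(np.var(y)) * (0.5 + rng.uniform())
    cov_b = np.diag(priors["s0_diag"]).astype(float)

    v0_inv = np.diag(1.0 / priors["beta_sd"] ** 2)
    out = {k: np.empty(n_iter) for k in
           ("beta0", "beta1", "sigma", "tau0", "tau1", "rho")}
    b_sum = np.zeros((n_groups, 2))

    zty = np.stack([
        np.bincount(groups_idx, weights=y, minlength=n_groups),
        np.bincount(groups_idx, weights=y * x, minlength=n_groups),
    ], axis=1)  # (G, 2)

    for it in range(n_iter):
        # beta | sigma2, cov_b with b marginalized out (collapsed step):
        # per group, Z'V^{-1}Z = A - A (cov_b^{-1} + A)^{-1} A via Woodbury,
        # with A = Z_g'Z_g / sigma2 -- all 2x2 blocks.
        cov_b_inv = _inv2(cov_b)
        a_g = ztz_g / sigma2
        m_g = _inv2(cov_b_inv[None] + a_g)
        am = np.einsum("gij,gjk->gik", a_g, m_g)
        p_beta = (a_g - np.einsum("gij,gjk->gik", am, a_g)).sum(0) + v0_inv
        u_g = zty / sigma2
        r_beta = (u_g - np.einsum("gij,gj->gi", am, u_g)).sum(0)
        cov = _inv2(p_beta)
        beta = cov @ r_beta + _chol2(cov) @ rng.standard_normal(2)

        # b_i | beta, sigma2, cov_b  (vectorized across participants)
        resid_f = y - z @ beta
        rhs = np.stack([
            np.bincount(groups_idx, weights=resid_f, minlength=n_groups),
            np.bincount(groups_idx, weights=resid_f * x, minlength=n_groups),
        ], axis=1) / sigma2  # (G, 2)
        prec_g = ztz_g / sigma2 + cov_b_inv[None]
        cov_g = _inv2(prec_g)
        mean_g = np.einsum("gij,gj->gi", cov_g, rhs)
        b = mean_g + np.einsum("gij,gj->gi", _chol2(cov_g),
                               rng.standard_normal((n_groups, 2)))

        # sigma2 | beta, b
        resid = resid_f - b[groups_idx, 0] - b[groups_idx, 1] * x
        a_post = priors["a0"] + n / 2
        b_post = priors["b0"] + 0.5 * resid @ resid
        sigma2 = b_post / rng.gamma(a_post)

        # cov_b | b
        nu_post = priors["nu0"] + n_groups
        s_post = np.diag(priors["s0_diag"]) + b.T @ b
        cov_b = _sample_invwishart(nu_post, s_post, rng)

        out["beta0"][it] = beta[0]
        out["beta1"][it] = beta[1]
        out["sigma"][it] = math.sqrt(sigma2)
        out["tau0"][it] = math.sqrt(cov_b[0, 0])
        out["tau1"][it] = math.sqrt(cov_b[1, 1])
        out["rho"][it] = cov_b[0, 1] / math.sqrt(cov_b[0, 0] * cov_b[1, 1])
        b_sum += b
    return out, b_sum / n_iter


def fit_random_slope_model(x: np.ndarray, y: np.ndarray, participant: np.ndarray,
                           n_chains: int = 4, n_draws: int = 5000,
                           n_warmup: int = 2500,
                           seed: int | None = None) -> HierarchicalFit:
    """Fit ``y ~ x`` with random intercepts and slopes grouped by participant.

    Gaussian likelihood with conjugate weakly-informative priors scaled
    to the data: fixed effects ~ Normal(0, (10 sd(y)/sd(x_col))^2),
    residual variance ~ InvGamma(2, var(y)), random-effect covariance ~
    InvWishart(4, diag scaled to 0.5 var(y)). ``n_draws`` includes the
    ``n_warmup`` draws that are discarded. ``y`` should already be
    z-scored within participant (and log-transformed predictors
    log-transformed) by the caller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    participant = np.asarray(participant)
    ids, groups_idx = np.unique(participant, return_inverse=True)
    if len(ids) < 2:
        raise ValueError("need >= 2 participants")
    counts = np.bincount(groups_idx)
    if counts.min() < 3:
        raise ValueError("each participant needs >= 3 trials")
    if np.std(x) == 0:
        raise ValueError("predictor has zero variance")
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    if n_warmup >= n_draws:
        raise ValueError("n_draws must exceed n_warmup")

    sd_y = max(float(np.std(y)), 1e-12)
    sd_x = float(np.std(x))
    priors = {
        "beta_sd": np.array([10.0 * sd_y, 10.0 * sd_y / sd_x]),
        "a0": 2.0, "b0": float(np.var(y)),
        "nu0": 4.0,
        "s0_diag": np.array([0.5 * sd_y**2, 0.5 * (sd_y / sd_x) ** 2]),
    }
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(n_chains)
    kept = n_draws - n_warmup
    draws = {k: np.empty((n_chains, kept)) for k in
             ("beta0", "beta1", "sigma", "tau0", "tau1", "rho")}
    b_means = np.zeros((len(ids), 2))
    for c in range(n_chains):
        rng = np.random.default_rng(child[c])
        chain, b_mean = _gibbs_chain(x, y, groups_idx, len(ids), n_draws,
                                     init_scale=0.5 + c * 0.5, priors=priors,
                                     rng=rng)
        for k in draws:
            draws[k][c] = chain[k][n_warmup:]
        b_means += b_mean / n_chains
    rhats = {k: rhat(v) for k, v in draws.items()}
    return HierarchicalFit(draws=draws, rhat=rhats, n_chains=n_chains,
                           n_draws=n_draws, n_warmup=n_warmup,
                           participant_ids=list(ids), b_means=b_means)


def rhat(chains: np.ndarray) -> float:
    """Split-Rhat (Gelman-Rubin) for one parameter.

    ``chains`` is (n_chains, n_draws); each chain is split in half, so m
    = 2 x n_chains sequences enter the between/within variance ratio.
    Rank normalization is not applied. Constant chains return 1.0 with a
    warning rather than failing.
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.shape[0] < 2:
        raise ValueError("Rhat requires >= 2 chains")
    if chains.shape[1] < 4:
        raise ValueError("Rhat requires >= 4 draws per chain")
    half = chains.shape[1] // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    n = split.shape[1]
    w = split.var(axis=1, ddof=1).mean()
    b = n * split.mean(axis=1).var(ddof=1)
    if w <= 1e-300:
        warnings.warn("zero within-chain variance; Rhat undefined, returning 1.0")
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def _log_quad(log_f, lo: float = -40.0, hi: float = 40.0) -> float:
    """log of the integral of exp(log_f(u)) du, stably via max-shift."""
    grid = np.linspace(lo, hi, 400)
    log_vals = np.array([log_f(u) for u in grid])
    m = float(log_vals.max())
    val, _ = scipy.integrate.quad(lambda u: math.exp(log_f(u) - m), lo, hi,
                                  limit=200)
    return m + math.log(val)


@dataclass
class BayesFactorResult:
    bf10: float
    bf01: float
    cauchy_scale: float
    method: str = "numerical-integration"

    @property
    def interpretation(self) -> str:
        return interpret_bf(max(self.bf10, self.bf01))


def jzs_bf_one_sample(t_stat: float, n: int,
                      cauchy_scale: float = DEFAULT_CAUCHY_SCALE) -> BayesFactorResult:
    """JZS Bayes factor for a one-sample (or paired) t-test.

    Cauchy(0, r) prior on the standardized effect size, expressed as the
    scale mixture delta | g ~ N(0, g), g ~ InvGamma(1/2, r^2/2), and
    integrated over g by adaptive quadrature.
    """
    if not np.isfinite(t_stat):
        raise ValueError("t statistic must be finite")
    if n < 2:
        raise ValueError("need n >= 2")
    t2 = t_stat**2
    nu = n - 1
    r = cauchy_scale
    log_null = -(nu + 1) / 2 * math.log1p(t2 / nu)

    def log_integrand(u):  # u = log g; includes the dg = g du Jacobian
        g = math.exp(u)
        return (
            -0.5 * math.log1p(n * g)
            - (nu + 1) / 2 * math.log1p(t2 / ((1 + n * g) * nu))
            + math.log(r) - 0.5 * math.log(2 * math.pi)
            - 1.5 * u - r**2 / (2 * g) + u
        )

    log_bf10 = _log_quad(log_integrand) - log_null
    bf10 = math.exp(log_bf10) if log_bf10 < 700 else math.inf
    return BayesFactorResult(bf10=float(bf10),
                             bf01=float(1 / bf10) if bf10 > 0 else math.inf,
                             cauchy_scale=r)


def jzs_bf_regression(x: np.ndarray, y: np.ndarray,
                      cauchy_scale: float = DEFAULT_CAUCHY_SCALE) -> BayesFactorResult:
    """Default-prior Bayes factor: single-predictor linear model vs intercept.

    Zellner-Siow setup: g-prior on the standardized coefficient with
    g ~ InvGamma(1/2, n r^2 / 2) (a Cauchy(0, r) on the effect), which
    gives BF10 as a one-dimensional integral in n and R^2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    r_corr = np.corrcoef(x, y)[0, 1]
    r2 = r_corr**2
    if r2 >= 1.0 - 1e-14:
        return BayesFactorResult(bf10=np.inf, bf01=0.0, cauchy_scale=cauchy_scale)
    p = 1
    s = cauchy_scale

    def log_integrand(u):  # u = log g; includes the dg = g du Jacobian
        g = math.exp(u)
        return (
            (n - p - 1) / 2 * math.log1p(g)
            - (n - 1) / 2 * math.log1p(g * (1 - r2))
            + 0.5 * math.log(n * s**2 / 2) - math.lgamma(0.5)
            - 1.5 * u - n * s**2 / (2 * g) + u
        )

    log_bf10 = _log_quad(log_integrand)
    bf10 = math.exp(log_bf10) if log_bf10 < 700 else math.inf
    return BayesFactorResult(bf10=float(bf10),
                             bf01=float(1 / bf10) if bf10 > 0 else math.inf,
                             cauchy_scale=s)


def interpret_bf(bf: float) -> str:
    """Canonical evidence label for a Bayes factor.

    < 3 anecdotal; 3-10 substantial; 10-31.6 strong; 31.6-100 very
    strong; > 100 decisive.
    """
    if not bf > 0:
        raise ValueError("Bayes factor must be positive")
    if bf < 3:
        return "anecdotal"
    if bf < 10:
        return "substantial"
    if bf < 31.6:
        return "strong"
    if bf < 100:
        return "very strong"
    return "decisive"


@dataclass
class CorrelationResult:
    r: float
    n: int
    df: int
    p: float


def correlate_effect_with_anxiety(effects: np.ndarray,
                                  anxiety: np.ndarray) -> CorrelationResult:
    """Pearson correlation of HEP effect magnitudes with anxiety scores.

    Pairs with missing anxiety are dropped (state-anxiety composites may
    exist for only a subset of participants). Two-tailed t-based p.
    """
    effects = np.asarray(effects, dtype=float)
    anxiety = np.asarray(anxiety, dtype=float)
    mask = np.isfinite(effects) & np.isfinite(anxiety)
    e, a = effects[mask], anxiety[mask]
    if len(e) < 4:
        raise ValueError("need >= 4 complete pairs")
    if np.std(e) == 0 or np.std(a) == 0:
        raise ValueError("zero variance in effects or anxiety")
    res = scipy.stats.pearsonr(e, a)
    return CorrelationResult(r=float(res.statistic), n=len(e), df=len(e) - 2,
                             p=float(res.pvalue))
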