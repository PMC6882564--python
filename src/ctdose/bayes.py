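"""Bayesian normal location-scale model with uniform priors.

The observable (required contrast volume per kg, or raw enhancement in
HU) is modelled as i.i.d. normal(μ, σ²).  The prior is uniform (flat)
on (μ, σ) inside wide finite bounds, so the posterior is

    p(μ, σ | y) ∝ σ^{-n} exp(-S(μ) / (2σ²)),   S(μ) = Σ (y_i − μ)²

restricted to the prior box.  When the bounds are wide this posterior
has closed-form marginals, implemented in :class:`AnalyticPosterior` and
used as an exact oracle for the sampler:

* μ | y  =  ȳ + s·√((n−1)/(n−2)) / √n · T,  T ~ Student-t(n−2)
* σ² | y =  (n−1)·s² / X,                   X ~ χ²(n−2)

with ȳ the sample mean and s the n−1 sample SD.  Sampling uses a
two-block Gibbs scheme on the exact conditionals

* μ  | σ², y ~ normal(ȳ, σ²/n)
* σ² | μ,  y ~ Inv-Gamma((n−1)/2, S(μ)/2)

with rejection of draws falling outside the prior box; a random-walk
Metropolis sampler targeting the same posterior is available to
demonstrate sampler independence.

Two per-draw derived quantities drive the study conclusions:

* exceedance probability  p_k = Φ((L − μ_k)/σ_k): the modelled fraction
  of patients whose required volume does not exceed the administered
  dose L — equivalently, the probability of attaining diagnostic
  enhancement at that dose;
* coverage dose  q_k = μ_k + z(c)·σ_k: the dose at which a target
  fraction c of patients attain diagnostic enhancement (z is the
  standard-normal quantile; z(0.95) ≈ 1.6449).

Summaries are reported as the mean ± SD of the per-draw values, plus a
central 95% credible interval, the split-chain Gelman–Rubin R-hat and
an effective sample size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import McmcError, UndefinedMomentsError

__all__ = [
    "McmcConfig",
    "PosteriorDraws",
    "ParamSummary",
    "PosteriorSummary",
    "AnalyticPosterior",
    "sample_posterior",
    "analytic_posterior",
    "exceedance_probability",
    "coverage_dose",
    "gelman_rubin",
    "split_rhat",
    "effective_sample_size",
    "delta_method_sd",
    "summarize_posterior",
    "export_draws_csv",
    "read_draws_csv",
]

#: Default uniform prior box in required-volume space (mL/kg).
DEFAULT_MU_BOUNDS = (0.0, 10.0)
DEFAULT_SIGMA_BOUNDS = (1e-6, 5.0)

#: Wide prior box for fits in enhancement space (HU).
HU_MU_BOUNDS = (0.0, 1000.0)
HU_SIGMA_BOUNDS = (1e-6, 500.0)


@dataclass(frozen=True)
class McmcConfig:
    """MCMC run configuration.

    Defaults follow the study design: five chains of 21,000 draws with
    the first 1,000 discarded as burn-in, retaining 100,000 draws total.
    """

    n_chains: int = 5
    draws_per_chain: int = 21_000
    burn_in: int = 1_000
    mu_bounds: tuple[float, float] = DEFAULT_MU_BOUNDS
    sigma_bounds: tuple[float, float] = DEFAULT_SIGMA_BOUNDS
    seed: int = 0
    sampler: str = "gibbs"

    def __post_init__(self):
        if self.n_chains < 1:
            raise McmcError(f"n_chains must be >= 1, got {self.n_chains}")
        if self.burn_in < 0 or self.burn_in >= self.draws_per_chain:
            raise McmcError(
                f"burn_in must be in [0, draws_per_chain), got {self.burn_in}"
            )
        lo, hi = self.mu_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise McmcError(f"mu_bounds must be finite and ordered, got {self.mu_bounds}")
        slo, shi = self.sigma_bounds
        if not (np.isfinite(slo) and np.isfinite(shi) and 0 < slo < shi):
            raise McmcError(
                f"sigma_bounds must be finite with 0 < lo < hi, got {self.sigma_bounds}"
            )
        if self.sampler not in ("gibbs", "metropolis"):
            raise McmcError(f"sampler must be 'gibbs' or 'metropolis', got {self.sampler!r}")

    @property
    def retained_per_chain(self) -> int:
        return self.draws_per_chain - self.burn_in

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mu_bounds"] = list(self.mu_bounds)
        d["sigma_bounds"] = list(self.sigma_bounds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "McmcConfig":
        d = dict(d)
        for key in ("mu_bounds", "sigma_bounds"):
            if key in d:
                d[key] = tuple(float(v) for v in d[key])
        return cls(**d)


@dataclass(frozen=True)
class PosteriorDraws:
    """Chain-indexed MCMC draws of (μ, σ) plus the data summary they
    were conditioned on.  Arrays have shape (n_chains, retained)."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int
    sample_mean: float
    sample_sd: float
    config: McmcConfig

    def __post_init__(self):
        if self.mu.shape != self.sigma.shape or self.mu.ndim != 2:
            raise McmcError("mu and sigma must be 2-D arrays of identical shape")
        if (self.sigma <= 0).any():
            raise McmcError("all sigma draws must be positive")

    @property
    def n_chains(self) -> int:
        return self.mu.shape[0]

    @property
    def retained_per_chain(self) -> int:
        return self.mu.shape[1]

    def flat(self, param: str) -> np.ndarray:
        return getattr(self, param).reshape(-1)


def _draw_truncated_normal(rng, loc, scale, lo, hi):
    x = rng.normal(loc, scale)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = rng.normal(loc[bad] if np.ndim(loc) else loc, scale[bad])
        bad = (x < lo) | (x > hi)
    return x


def _draw_truncated_invgamma(rng, shape, scale_b, lo, hi):
    # Inv-Gamma(a, b) as b / Gamma(a); reject outside [lo, hi]
    x = scale_b / rng.gamma(shape, size=scale_b.shape)
    bad = (x < lo) | (x > hi)
    while bad.any():
        x[bad] = scale_b[bad] / rng.gamma(shape, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return x


def _validate_data(data: Sequence[float], config: McmcConfig):
    y = np.asarray(data, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise McmcError(f"need a 1-D sample with n >= 3, got n = {y.size}")
    if not np.isfinite(y).all():
        raise McmcError("data contain non-finite values")
    ybar = float(y.mean())
    s = float(y.std(ddof=1))
    if s == 0:
        raise McmcError("data have zero variance; the scale is not identifiable")
    lo, hi = config.mu_bounds
    if not lo <= ybar <= hi:
        raise McmcError(
            f"prior mu bounds {config.mu_bounds} exclude the sample mean {ybar:.4g}"
        )
    return y, ybar, s


def sample_posterior(data: Sequence[float], config: McmcConfig | None = None) -> PosteriorDraws:
    """Draw from the flat-prior normal-model posterior by MCMC.

    The Gibbs sampler alternates the exact conditionals and is therefore
    effectively uncorrelated after one step; the Metropolis variant is a
    tuned random walk on (μ, σ).  Runs are reproducible given
    ``config.seed``.
    """
    if config is None:
        config = McmcConfig()
    y, ybar, s = _validate_data(data, config)
    n = y.size
    if config.sampler == "gibbs":
        mu, sigma = _gibbs(n, ybar, s, config)
    else:
        mu, sigma = _metropolis(n, ybar, s, config)
    return PosteriorDraws(
        mu=mu, sigma=sigma, n=n, sample_mean=ybar, sample_sd=s, config=config
    )


def _gibbs(n, ybar, s, config):
    rng = np.random.default_rng(config.seed)
    m = config.n_chains
    mu_lo, mu_hi = config.mu_bounds
    sg_lo, sg_hi = config.sigma_bounds
    s2_lo, s2_hi = sg_lo**2, sg_hi**2
    ss = (n - 1) * s * s
    shape = 0.5 * (n - 1)

    # overdispersed start: chains begin spread around the sample mean
    start_scale = max(s / np.sqrt(n), 1e-12)
    mu = np.clip(ybar + 2.0 * start_scale * rng.standard_normal(m), mu_lo, mu_hi)
    sig2 = np.full(m, float(np.clip(s * s, s2_lo, s2_hi)))

    kept = config.retained_per_chain
    mu_out = np.empty((m, kept))
    sig_out = np.empty((m, kept))
    for t in range(config.draws_per_chain):
        mu = _draw_truncated_normal(rng, ybar, np.sqrt(sig2 / n), mu_lo, mu_hi)
        b = 0.5 * (ss + n * (mu - ybar) ** 2)
        sig2 = _draw_truncated_invgamma(rng, shape, b, s2_lo, s2_hi)
        if t >= config.burn_in:
            j = t - config.burn_in
            mu_out[:, j] = mu
            sig_out[:, j] = np.sqrt(sig2)
    return mu_out, sig_out


def _metropolis(n, ybar, s, config):
    rng = np.random.default_rng(config.seed)
    m = config.n_chains
    mu_lo, mu_hi = config.mu_bounds
    sg_lo, sg_hi = config.sigma_bounds
    ss = (n - 1) * s * s

    def logpost(mu, sigma):
        lp = -n * np.log(sigma) - (ss + n * (mu - ybar) ** 2) / (2 * sigma**2)
        out = np.where(
            (mu >= mu_lo) & (mu <= mu_hi) & (sigma >= sg_lo) & (sigma <= sg_hi),
            lp,
            -np.inf,
        )
        return out

    prop_mu = 2.4 * s / np.sqrt(n)
    prop_sg = 2.4 * s / np.sqrt(2 * n)
    mu = np.clip(ybar + prop_mu * rng.standard_normal(m), mu_lo, mu_hi)
    sigma = np.full(m, float(np.clip(s, sg_lo, sg_hi)))
    lp = logpost(mu, sigma)

    kept = config.retained_per_chain
    mu_out = np.empty((m, kept))
    sig_out = np.empty((m, kept))
    for t in range(config.draws_per_chain):
        mu_new = mu + prop_mu * rng.standard_normal(m)
        sg_new = sigma + prop_sg * rng.standard_normal(m)
        lp_new = logpost(mu_new, sg_new)
        accept = np.log(rng.random(m)) < (lp_new - lp)
        mu = np.where(accept, mu_new, mu)
        sigma = np.where(accept, sg_new, sigma)
        lp = np.where(accept, lp_new, lp)
        if t >= config.burn_in:
            j = t - config.burn_in
            mu_out[:, j] = mu
            sig_out[:, j] = sigma
    return mu_out, sig_out


@dataclass(frozen=True)
class AnalyticPosterior:
    """Closed-form flat-prior posterior for the normal model.

    Valid when the uniform prior box is wide enough to be effectively
    unbounded; serves as the exact oracle against which the MCMC sampler
    is tested.  Requires n >= 4 so that the marginals are proper with
    at least two t degrees of freedom.
    """

    n: int
    sample_mean: float
    sample_sd: float

    def __post_init__(self):
        if self.n < 4:
            raise UndefinedMomentsError(
                f"closed-form posterior requires n >= 4, got n = {self.n}"
            )
        if self.sample_sd <= 0:
            raise UndefinedMomentsError("sample_sd must be > 0")

    # ---- marginal of mu: shifted/scaled Student-t(n - 2) ----

    @property
    def nu(self) -> int:
        return self.n - 2

    @property
    def mu_scale(self) -> float:
        n, s = self.n, self.sample_sd
        return s * np.sqrt((n - 1) / (n - 2)) / np.sqrt(n)

    def mu_mean(self) -> float:
        return self.sample_mean

    def mu_sd(self) -> float:
        n, s = self.n, self.sample_sd
        if n <= 4:
            raise UndefinedMomentsError("SD of mu requires n > 4")
        return (s / np.sqrt(n)) * np.sqrt((n - 1) / (n - 4))

    def mu_ppf(self, q) -> np.ndarray | float:
        return self.sample_mean + self.mu_scale * stats.t.ppf(q, self.nu)

    def mu_pdf(self, x) -> np.ndarray | float:
        return stats.t.pdf((x - self.sample_mean) / self.mu_scale, self.nu) / self.mu_scale

    # ---- marginal of sigma^2: (n-1) s^2 / chi2(n - 2) ----

    @property
    def _invgamma_ab(self) -> tuple[float, float]:
        n, s = self.n, self.sample_sd
        return (n - 2) / 2.0, (n - 1) * s * s / 2.0

    def sigma2_mean(self) -> float:
        n, s = self.n, self.sample_sd
        if n <= 4:
            raise UndefinedMomentsError("mean of sigma^2 requires n > 4")
        return (n - 1) * s * s / (n - 4)

    def sigma_mean(self) -> float:
        a, b = self._invgamma_ab
        if a <= 0.5:
            raise UndefinedMomentsError("mean of sigma requires n > 3")
        return float(np.sqrt(b) * np.exp(gammaln(a - 0.5) - gammaln(a)))

    def sigma_sd(self) -> float:
        return float(np.sqrt(self.sigma2_mean() - self.sigma_mean() ** 2))

    def sigma_ppf(self, q) -> np.ndarray | float:
        n, s = self.n, self.sample_sd
        # sigma is decreasing in the chi2 variate, hence the 1 - q flip
        return np.sqrt((n - 1) * s * s / stats.chi2.ppf(1.0 - np.asarray(q, float), self.nu))

    def sigma_pdf(self, x) -> np.ndarray | float:
        a, b = self._invgamma_ab
        x = np.asarray(x, float)
        # density of sigma = sqrt(tau), tau ~ Inv-Gamma(a, b)
        return stats.invgamma.pdf(x**2, a, scale=b) * 2 * x


def analytic_posterior(n: int, sample_mean: float, sample_sd: float) -> AnalyticPosterior:
    """Closed-form flat-prior posterior description; see
    :class:`AnalyticPosterior`."""
    return AnalyticPosterior(n=int(n), sample_mean=float(sample_mean), sample_sd=float(sample_sd))


# ---------------------------------------------------------------------------
# derived quantities


@dataclass(frozen=True)
class ParamSummary:
    """Posterior mean ± SD and central 95% credible interval of one
    scalar quantity; ``values`` optionally carries the per-draw array."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    values: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.ci_low > self.ci_high:
            raise ValueError("credible interval bounds out of order")

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _summarize_values(values: np.ndarray, keep_values: bool = True) -> ParamSummary:
    lo, hi = np.percentile(values, [2.5, 97.5])
    return ParamSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        values=values if keep_values else None,
    )


def exceedance_probability(
    draws: PosteriorDraws, dose_limit: float, upper: bool = False
) -> ParamSummary:
    """Per-draw attainment probability and its posterior summary.

    For each retained draw, p_k = Φ((dose_limit − μ_k)/σ_k): the
    modelled fraction of patients whose required volume does not exceed
    ``dose_limit``.  With ``upper=True`` the complementary tail
    P(X > dose_limit) is returned instead — the natural direction when
    the model is fitted in enhancement (HU) space and the limit is the
    diagnostic threshold.
    """
    if dose_limit <= 0:
        raise ValueError(f"dose_limit must be > 0, got {dose_limit}")
    z = (dose_limit - draws.flat("mu")) / draws.flat("sigma")
    p = stats.norm.sf(z) if upper else stats.norm.cdf(z)
    return _summarize_values(p)


def coverage_dose(draws: PosteriorDraws, coverage: float) -> ParamSummary:
    """Per-draw dose q_k = μ_k + z(coverage)·σ_k achieving diagnostic
    enhancement for the target fraction of patients, and its summary."""
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must be in (0, 1), got {coverage}")
    z = stats.norm.ppf(coverage)
    q = draws.flat("mu") + z * draws.flat("sigma")
    return _summarize_values(q)


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman–Rubin).

    Each chain is split in half; R-hat compares the between-half-chain
    variance of the means to the mean within-half-chain variance.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an array of shape (n_chains, n_draws)")
    m, n = x.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain to split")
    half = n // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    w = halves.var(axis=1, ddof=1).mean()
    b = half * halves.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def gelman_rubin(draws: PosteriorDraws) -> dict[str, float]:
    """Split R-hat for μ and σ; requires at least two chains and ten
    retained draws per chain."""
    if draws.n_chains < 2:
        raise McmcError("Gelman-Rubin diagnostic requires at least 2 chains")
    if draws.retained_per_chain < 10:
        raise McmcError("Gelman-Rubin diagnostic requires >= 10 retained draws per chain")
    return {"mu": split_rhat(draws.mu), "sigma": split_rhat(draws.sigma)}


def effective_sample_size(draws: PosteriorDraws) -> dict[str, float]:
    """Bulk effective sample size for μ and σ (via ArviZ)."""
    import arviz as az

    return {
        "mu": float(az.ess(np.asarray(draws.mu))),
        "sigma": float(az.ess(np.asarray(draws.sigma))),
    }


def delta_method_sd(n: int, mean: float, sd: float, dose_limit: float) -> float:
    """First-order approximation to the posterior SD of the attainment
    probability p = Φ((L − μ)/σ).

    With z = (L − mean)/sd the sampling variability of (μ, σ) propagates
    to SD(p) ≈ φ(z)·√((1 + z²/2)/n); used to cross-check MCMC output.
    """
    if n < 4:
        raise UndefinedMomentsError(f"delta-method SD requires n >= 4, got {n}")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    z = (dose_limit - mean) / sd
    return float(stats.norm.pdf(z) * np.sqrt((1.0 + z * z / 2.0) / n))


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior summaries for (μ, σ) and the derived attainment
    probability and coverage dose, with convergence diagnostics."""

    mu: ParamSummary
    sigma: ParamSummary
    p: ParamSummary
    q: ParamSummary
    rhat: dict[str, float]
    ess: dict[str, float]
    dose_limit: float
    coverage: float
    n: int
    sample_mean: float
    sample_sd: float

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.to_dict(),
            "sigma": self.sigma.to_dict(),
            "p": self.p.to_dict(),
            "q": self.q.to_dict(),
            "rhat": dict(self.rhat),
            "ess": dict(self.ess),
            "dose_limit": self.dose_limit,
            "coverage": self.coverage,
            "n": self.n,
            "sample_mean": self.sample_mean,
            "sample_sd": self.sample_sd,
        }


def summarize_posterior(
    draws: PosteriorDraws,
    dose_limit: float,
    coverage: float = 0.95,
    compute_ess: bool = True,
) -> PosteriorSummary:
    """Full posterior summary: μ, σ, attainment probability at
    ``dose_limit`` and the ``coverage`` dose, with diagnostics."""
    mu = _summarize_values(draws.flat("mu"))
    sigma = _summarize_values(draws.flat("sigma"))
    p = exceedance_probability(draws, dose_limit)
    q = coverage_dose(draws, coverage)
    rhat = gelman_rubin(draws) if draws.n_chains >= 2 else {}
    ess = effective_sample_size(draws) if compute_ess else {}
    return PosteriorSummary(
        mu=mu, sigma=sigma, p=p, q=q, rhat=rhat, ess=ess,
        dose_limit=dose_limit, coverage=coverage,
        n=draws.n, sample_mean=draws.sample_mean, sample_sd=draws.sample_sd,
    )


def export_draws_csv(
    draws: PosteriorDraws,
    path: str | Path,
    dose_limit: float | None = None,
    coverage: float | None = None,
) -> None:
    """Write draws as CSV with columns chain,iteration,mu,sigma[,p,q]."""
    m, k = draws.mu.shape
    frame = pd.DataFrame(
        {
            "chain": np.repeat(np.arange(1, m + 1), k),
            "iteration": np.tile(np.arange(1, k + 1), m),
            "mu": draws.mu.reshape(-1),
            "sigma": draws.sigma.reshape(-1),
        }
    )
    if dose_limit is not None:
        frame["p"] = stats.norm.cdf((dose_limit - frame["mu"]) / frame["sigma"])
    if coverage is not None:
        frame["q"] = frame["mu"] + stats.norm.ppf(coverage) * frame["sigma"]
    frame.to_csv(path, index=False)


def read_draws_csv(path: str | Path) -> PosteriorDraws:
    """Read a draws CSV written by :func:`export_draws_csv`.

    The data summary is not stored in the CSV, so the returned object
    carries placeholder values (n=0, NaN moments); derived-quantity
    computations do not need them.
    """
    frame = pd.read_csv(path)
    chains = sorted(frame["chain"].unique())
    mu = np.stack([frame.loc[frame["chain"] == c, "mu"].to_numpy() for c in chains])
    sigma = np.stack([frame.loc[frame["chain"] == c, "sigma"].to_numpy() for c in chains])
    config = McmcConfig(
        n_chains=len(chains),
        draws_per_chain=mu.shape[1],
        burn_in=0,
        mu_bounds=(min(0.0, float(mu.min())), float(mu.max()) * 2 + 1),
        sigma_bounds=(1e-12, float(sigma.max()) * 2 + 1),
    )
    return PosteriorDraws(
        mu=mu, sigma=sigma, n=0, sample_mean=float("nan"), sample_sd=float("nan"),
        config=config,
    )
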