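"""Gibbs samplers, truncated-normal liability draws and MCMC diagnostics.

The Gaussian sampler alternates single-site normal updates of every
location effect (fixed, additive genetic, permanent environment) with
scaled-inverse-chi-square draws of the three variance components; the
quadratic form for the additive variance is u' A-inverse u.  Priors default
to the flat limit (nu = -2, scale = 0) commonly used as the non-informative
setting in animal-breeding Gibbs software, and are configurable.

A bivariate extension (used by the penalized threshold model) lives in
:mod:`daysopen.censoring`; this module provides the shared machinery:
the location sweep, the truncated-normal liability sampler, the Geweke
convergence z-score and the autocorrelation function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from . import _kernel
from .model_build import DesignSystem, VarianceComponents, heritability


class SamplerError(RuntimeError):
    pass


@dataclass
class VariancePrior:
    """Scaled-inverse-chi-square prior; nu = -2, scale = 0 is the flat limit."""

    nu: float = -2.0
    scale: float = 0.0


@dataclass
class ChainConfig:
    """Gibbs chain settings.

    The defaults (20,000 iterations, 4,000 burn-in, thin 10) are a
    desk-scale chain adequate for the simulated datasets in this package;
    production-scale settings of 500,000 / 100,000 / 50 are available by
    passing them explicitly.
    """

    n_iter: int = 20_000
    burn_in: int = 4_000
    thin: int = 10
    seed: int = 0
    priors: dict = field(default_factory=dict)  # name -> VariancePrior

    def validate(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def prior(self, name: str) -> VariancePrior:
        return self.priors.get(name, VariancePrior())


@dataclass
class PosteriorChain:
    """Thinned Gibbs draws plus effect-vector summaries."""

    draws: dict                      # name -> 1-d array of stored draws
    config: ChainConfig
    effect_mean: dict = field(default_factory=dict)   # block -> mean vector
    effect_sd: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out = {}
        for name, x in self.draws.items():
            out[name] = {
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)),
                "geweke_z": float(geweke_z(x)) if x.size >= 100 else float("nan"),
                "lag1_autocorr": float(autocorrelation(x, 1)[1]) if x.size > 2 else float("nan"),
            }
        return out

    def to_frame(self):
        """Flat long-format draws: iteration, parameter, value."""
        import pandas as pd

        frames = []
        for name, x in self.draws.items():
            frames.append(
                pd.DataFrame(
                    {"iteration": np.arange(1, x.size + 1), "parameter": name, "value": x}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def posterior_vc(self) -> VarianceComponents:
        return VarianceComponents(
            sigma_u2=float(np.mean(self.draws["sigma_u2"])),
            sigma_pe2=float(np.mean(self.draws["sigma_pe2"])),
            sigma_e2=float(np.mean(self.draws["sigma_e2"])),
        )


def truncated_normal(mean, sd, rng, *, above_zero) -> np.ndarray:
    """Draw from N(mean, sd^2) truncated to (0, inf) or (-inf, 0].

    Inverse-CDF sampling carried out in log space (log_ndtr / ndtri_exp)
    so that means tens of standard deviations beyond the truncation point
    still yield finite, correctly signed draws.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    above = np.broadcast_to(np.asarray(above_zero, dtype=bool), mean.shape)
    a = -mean / np.where(sd > 0, sd, 1.0)  # standardized truncation point
    u = rng.uniform(size=mean.shape)
    logu = np.log(u)
    out = np.empty(mean.shape)
    # above zero: standardized draw in (a, inf):  -ndtri_exp(log u + log Phi(-a))
    x_hi = -special.ndtri_exp(logu + special.log_ndtr(-a))
    # below zero: standardized draw in (-inf, a]:  ndtri_exp(log u + log Phi(a))
    x_lo = special.ndtri_exp(logu + special.log_ndtr(a))
    out = np.where(above, x_hi, x_lo)
    return mean + sd * out


def sample_liability(binary_status, linear_predictor, residual_sd, rng) -> np.ndarray:
    """Liability draw under the threshold link with T = 0.

    Records with binary status 1 (censored) draw from the normal full
    conditional truncated to (0, inf); status 0 to (-inf, 0].
    """
    status = np.asarray(binary_status)
    return truncated_normal(
        np.asarray(linear_predictor, dtype=float),
        residual_sd,
        rng,
        above_zero=status == 1,
    )


def _draw_variance(quad: float, df_data: float, prior: VariancePrior, rng) -> float:
    """sigma^2 | rest  ~  (quad + nu*scale) / chi2(df_data + nu)."""
    df = df_data + prior.nu
    if df <= 0:
        raise SamplerError(f"non-positive posterior degrees of freedom ({df})")
    return (quad + prior.nu * prior.scale) / rng.chisquare(df)


def _csr_parts(A):
    return A.indptr, A.indices, A.data.astype(np.float64)


def gibbs_gaussian(
    design: DesignSystem,
    config: ChainConfig,
    y: np.ndarray | None = None,
    fixed_variances: VarianceComponents | None = None,
    start: VarianceComponents | None = None,
    store_effects: bool = True,
    store_effect_draws: bool = False,
    rng: np.random.Generator | None = None,
) -> PosteriorChain:
    """Single-chain Gibbs sampler for the Gaussian repeatability animal model.

    With ``fixed_variances`` the variance draws are skipped (degenerate
    priors), which makes the posterior mean of the location effects the
    BLUP solution of the mixed-model equations - the oracle used in tests.
    """
    config.validate()
    y = design.y if y is None else np.asarray(y, dtype=float)
    n = y.size
    rng = np.random.default_rng(config.seed) if rng is None else rng

    M = (design.T.T @ design.T).tocsr()
    M.sum_duplicates()
    mp, mi, mx = _csr_parts(M)
    ap, ai, ax = _csr_parts(design.Ainv)
    s = design.slices
    u_start, q = s["u"].start, design.n_animals
    pe_start, n_pe = s["pe"].start, design.n_cows
    n_eff = design.n_effects
    Tt_y = (design.T.T @ y).reshape(n_eff, 1)

    if fixed_variances is not None:
        vc = fixed_variances
    elif start is not None:
        vc = start
    else:
        vy = float(np.var(y)) or 1.0
        vc = VarianceComponents(0.15 * vy, 0.15 * vy, 0.7 * vy)
    vc.validate()

    theta = np.zeros((n_eff, 1))
    n_stored = config.n_stored
    draws = {k: np.empty(n_stored) for k in ("sigma_u2", "sigma_pe2", "sigma_e2", "h2")}
    eff_sum = np.zeros(n_eff)
    eff_sq = np.zeros(n_eff)
    eff_draws = np.empty((n_stored, n_eff)) if store_effect_draws else None
    kept = 0
    vmax = 1e12 * (float(np.var(y)) + 1.0)

    for it in range(config.n_iter):
        z = rng.standard_normal((n_eff, 1))
        Rinv = np.array([[1.0 / vc.sigma_e2]])
        Ginv = np.array([[1.0 / vc.sigma_u2]])
        Pinv = np.array([[1.0 / vc.sigma_pe2]])
        _kernel.location_sweep(
            theta, mp, mi, mx, Tt_y, ap, ai, ax,
            u_start, q, pe_start, n_pe, Rinv, Ginv, Pinv, z,
        )
        if fixed_variances is None:
            u = theta[u_start:u_start + q, 0]
            pe = theta[pe_start:pe_start + n_pe, 0]
            e = y - design.T @ theta[:, 0]
            quad_u = float(u @ (design.Ainv @ u))
            vc = VarianceComponents(
                sigma_u2=_draw_variance(quad_u, q, config.prior("sigma_u2"), rng),
                sigma_pe2=_draw_variance(float(pe @ pe), n_pe, config.prior("sigma_pe2"), rng),
                sigma_e2=_draw_variance(float(e @ e), n, config.prior("sigma_e2"), rng),
            )
            if not np.isfinite(vc.total) or vc.total > vmax:
                raise SamplerError(f"divergent variance draw at iteration {it}")
        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            draws["sigma_u2"][kept] = vc.sigma_u2
            draws["sigma_pe2"][kept] = vc.sigma_pe2
            draws["sigma_e2"][kept] = vc.sigma_e2
            draws["h2"][kept] = heritability(vc)
            if store_effects:
                eff_sum += theta[:, 0]
                eff_sq += theta[:, 0] ** 2
            if eff_draws is not None:
                eff_draws[kept] = theta[:, 0]
            kept += 1

    chain = PosteriorChain(draws={k: v[:kept] for k, v in draws.items()}, config=config)
    if eff_draws is not None:
        chain.extras["effect_draws"] = eff_draws[:kept]
    if store_effects and kept:
        mean = eff_sum / kept
        var = np.maximum(eff_sq / kept - mean**2, 0.0)
        for block, sl in s.items():
            chain.effect_mean[block] = mean[sl]
            chain.effect_sd[block] = np.sqrt(var[sl])
    return chain


def _spectral_density_zero(x: np.ndarray) -> float:
    """Bartlett-windowed estimate of the spectral density at frequency 0."""
    n = x.size
    xc = x - x.mean()
    lmax = max(1, int(round(n ** (1.0 / 3.0))))
    s = float(xc @ xc) / n
    for k in range(1, min(lmax, n - 1) + 1):
        gamma = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (lmax + 1.0)) * gamma
    return max(s, 0.0)


def geweke_z(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence diagnostic.

    Compares the mean of the first ``first`` fraction of the chain against
    the last ``last`` fraction, with spectral-density variance estimates.
    A constant chain returns 0 by convention.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError("geweke_z needs >= 100 draws")
    if np.ptp(x) == 0:
        return 0.0
    a = x[: int(first * x.size)]
    b = x[-int(last * x.size):]
    var = _spectral_density_zero(a) / a.size + _spectral_density_zero(b) / b.size
    if var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation function at lags 0..max_lag."""
    x = np.asarray(chain, dtype=float)
    if x.size < 2 * max_lag:
        raise ValueError("chain too short for requested max_lag")
    from statsmodels.tsa.stattools import acf

    return acf(x, nlags=max_lag, fft=True)
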