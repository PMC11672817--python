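"""The three censoring treatments for days open: LM, PLM and PTM.

* LM: drop every censored record and fit the Gaussian animal model.
* PLM: impute each censored record as the maximum uncensored DO of its
  herd-year-season contemporary group plus a penalty of 21 days (one
  estrous cycle: a cow not yet confirmed pregnant is assumed to conceive
  given one more cycle), then fit the same Gaussian model.
* PTM: a bivariate threshold-linear model; trait 1 is DO (observed records
  plus the PLM-style penalty-imputed ones), trait 2 is a censorship
  liability whose sign relative to the threshold T = 0 reproduces the
  binary censoring status.  Liabilities are redrawn from their truncated
  normal full conditionals at every Gibbs iteration; 2x2 genetic and
  permanent-environment covariance matrices get inverse-Wishart updates and
  the residual liability variance is fixed at 1 for identifiability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernel
from .model_build import DesignSystem, VarianceComponents, build_design, heritability
from .pedigree import Pedigree
from .samplers import (
    ChainConfig,
    PosteriorChain,
    SamplerError,
    _csr_parts,
    _draw_variance,
    sample_liability,
)

log = logging.getLogger(__name__)

#: penalty added to the contemporary-group maximum: one estrous cycle, days
DEFAULT_PENALTY = 21.0


class CensoringError(ValueError):
    pass


def impute_penalty(
    records: pd.DataFrame, penalty: float = DEFAULT_PENALTY
) -> pd.DataFrame:
    """Penalty imputation of censored DO records.

    Each censored record receives ``imputed_do`` = (maximum uncensored DO in
    its HYS contemporary group) + ``penalty``.  A group in which every
    record is censored (an extreme-class group) falls back to the maximum
    uncensored DO of the whole dataset, with a logged warning.  Adds
    ``do_complete`` (observed or imputed DO), ``imputed_do`` (censored rows
    only) and the binary censorship trait ``cens01``.
    """
    if penalty < 0:
        raise CensoringError("penalty must be >= 0")
    if "hys" not in records.columns:
        raise CensoringError("records need a 'hys' column (run edit_records first)")
    df = records.copy()
    cens = df["censored"].astype(bool)
    if (~cens).sum() == 0:
        raise CensoringError("no uncensored record anywhere; cannot impute")
    group_max = (
        df.loc[~cens].groupby("hys")["do"].max()
    )
    global_max = float(df.loc[~cens, "do"].max())
    gm = df["hys"].map(group_max)
    fallback = cens & gm.isna()
    if fallback.any():
        bad = sorted(df.loc[fallback, "hys"].unique())
        msg = (
            f"{len(bad)} extreme-class contemporary group(s) contain only "
            f"censored records; falling back to the dataset-wide maximum "
            f"uncensored DO ({global_max:g})"
        )
        log.warning(msg)
        warnings.warn(msg)
    gm = gm.fillna(global_max)
    df["imputed_do"] = np.where(cens, gm + penalty, np.nan)
    df["do_complete"] = np.where(cens, gm + penalty, df["do"])
    df["cens01"] = cens.astype(int)
    return df


@dataclass
class FitResult:
    """Posterior chain plus per-animal EBV table for one censoring model."""

    model: str
    chain: PosteriorChain
    ebv: pd.DataFrame           # animal_id (external), ebv, posterior_sd
    design: DesignSystem
    vc_mean: VarianceComponents
    h2_mean: float
    extras: dict = field(default_factory=dict)

    def vc_summary(self) -> dict:
        """Variance-component summary (posterior mean and SD per parameter)."""
        out = {}
        for name, x in self.chain.draws.items():
            out[name] = {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
        return out


def _ebv_table(design: DesignSystem, ped: Pedigree, chain: PosteriorChain, model: str) -> pd.DataFrame:
    mean = chain.effect_mean["u"]
    sd = chain.effect_sd["u"]
    return pd.DataFrame(
        {
            "animal_id": ped.to_external(range(1, ped.n + 1)),
            "model": model,
            "ebv": mean,
            "posterior_sd": sd,
        }
    )


def _finish(model, design, ped, chain, extras=None) -> FitResult:
    vc = chain.posterior_vc()
    return FitResult(
        model=model,
        chain=chain,
        ebv=_ebv_table(design, ped, chain, model),
        design=design,
        vc_mean=vc,
        h2_mean=float(np.mean(chain.draws["h2"])),
        extras=extras or {},
    )


def fit_lm(
    records: pd.DataFrame,
    ped: Pedigree,
    config: ChainConfig,
    **gibbs_kwargs,
) -> FitResult:
    """Gaussian animal model on uncensored records only (censored dropped)."""
    from .samplers import gibbs_gaussian

    kept = records.loc[~records["censored"].astype(bool)]
    if len(kept) == 0:
        raise CensoringError("no data after omission of censored records")
    design = build_design(kept, ped, response="do")
    chain = gibbs_gaussian(design, config, **gibbs_kwargs)
    return _finish("LM", design, ped, chain)


def fit_plm(
    records: pd.DataFrame,
    ped: Pedigree,
    config: ChainConfig,
    penalty: float = DEFAULT_PENALTY,
    **gibbs_kwargs,
) -> FitResult:
    """Penalty model: impute censored DO (group max + penalty), fit Gaussian model."""
    from .samplers import gibbs_gaussian

    aug = impute_penalty(records, penalty)
    design = build_design(aug, ped, response="do_complete")
    chain = gibbs_gaussian(design, config, **gibbs_kwargs)
    return _finish("PLM", design, ped, chain, extras={"augmented": aug})


def fit_ptm(
    records: pd.DataFrame,
    ped: Pedigree,
    config: ChainConfig,
    penalty: float = DEFAULT_PENALTY,
    start_h2: float = 0.1,
    store_liabilities: bool = False,
) -> FitResult:
    """Bivariate threshold-linear model with penalty (PTM).

    Trait 1 is DO with censored records held at their penalty-imputed
    values; trait 2 is the censorship liability (residual variance fixed at
    1, threshold 0).  Both traits share the fixed/random incidence
    structure.  Returns DO-scale EBVs; liability-trait EBVs are exported in
    ``extras['ebv_liability']`` and are auxiliary.
    """
    cens = records["censored"].astype(bool)
    if cens.all() or (~cens).all():
        raise CensoringError(
            "censorship status is degenerate (all censored or all uncensored); "
            "use fit_lm / fit_plm instead"
        )
    config.validate()
    aug = impute_penalty(records, penalty)
    design = build_design(aug, ped, response="do_complete")
    y = design.y
    status = aug["cens01"].to_numpy()
    n = y.size
    rng = np.random.default_rng(config.seed)

    M = (design.T.T @ design.T).tocsr()
    M.sum_duplicates()
    mp, mi, mx = _csr_parts(M)
    ap, ai, ax = _csr_parts(design.Ainv)
    s = design.slices
    u_start, q = s["u"].start, design.n_animals
    pe_start, n_pe = s["pe"].start, design.n_cows
    n_eff = design.n_effects

    # starting covariance matrices: modest h2, zero cross-trait covariance
    vy = float(np.var(y)) or 1.0
    G0 = np.diag([start_h2 * vy, 0.05])
    P0 = np.diag([0.15 * vy, 0.05])
    R0 = np.array([[0.75 * vy, 0.0], [0.0, 1.0]])

    theta = np.zeros((n_eff, 2))
    liab = sample_liability(status, np.zeros(n), 1.0, rng)

    n_stored = config.n_stored
    names = [
        "sigma_u2", "sigma_pe2", "sigma_e2", "h2",
        "sigma_u2_liab", "gen_corr", "res_cov", "h2_liab",
    ]
    draws = {k: np.empty(n_stored) for k in names}
    eff_sum = np.zeros((n_eff, 2))
    eff_sq = np.zeros((n_eff, 2))
    sign_ok = np.empty(n_stored, dtype=bool)
    stored_liab = [] if store_liabilities else None
    kept = 0
    rhs = np.empty((n_eff, 2))
    rhs[:, 0] = design.T.T @ y
    vmax = 1e12 * (vy + 1.0)

    for it in range(config.n_iter):
        # liability full conditional given the DO-trait residual
        eta = design.T @ theta
        e1 = y - eta[:, 0]
        cond_mean = eta[:, 1] + (R0[0, 1] / R0[0, 0]) * e1
        cond_var = R0[1, 1] - R0[0, 1] ** 2 / R0[0, 0]
        liab = sample_liability(status, cond_mean, np.sqrt(max(cond_var, 1e-12)), rng)
        rhs[:, 1] = design.T.T @ liab

        z = rng.standard_normal((n_eff, 2))
        Rinv = np.linalg.inv(R0)
        Ginv = np.linalg.inv(G0)
        Pinv = np.linalg.inv(P0)
        _kernel.location_sweep(
            theta, mp, mi, mx, rhs, ap, ai, ax,
            u_start, q, pe_start, n_pe, Rinv, Ginv, Pinv, z,
        )

        # covariance updates (flat priors: inverse Wishart with df = n - p - 1)
        U = theta[u_start:u_start + q, :]
        Pe = theta[pe_start:pe_start + n_pe, :]
        Su = _kernel.quad_form_ainv(ap, ai, ax, U)
        G0 = stats.invwishart.rvs(df=q - 3, scale=_nearpd(Su), random_state=rng)
        P0 = stats.invwishart.rvs(df=n_pe - 3, scale=_nearpd(Pe.T @ Pe), random_state=rng)
        E = np.column_stack([y - design.T @ theta[:, 0], liab - design.T @ theta[:, 1]])
        R0 = stats.invwishart.rvs(df=n - 3, scale=_nearpd(E.T @ E), random_state=rng)

        # identification: rescale the liability axis so R0[1,1] = 1
        c = np.sqrt(R0[1, 1])
        D = np.array([1.0, 1.0 / c])
        R0 = R0 * np.outer(D, D)
        G0 = G0 * np.outer(D, D)
        P0 = P0 * np.outer(D, D)
        theta[:, 1] /= c
        liab /= c
        if not np.isfinite(G0[0, 0] + P0[0, 0] + R0[0, 0]) or R0[0, 0] > vmax:
            raise SamplerError(f"divergent covariance draw at iteration {it}")

        if it >= config.burn_in and (it - config.burn_in) % config.thin == config.thin - 1:
            vc = VarianceComponents(G0[0, 0], P0[0, 0], R0[0, 0])
            draws["sigma_u2"][kept] = vc.sigma_u2
            draws["sigma_pe2"][kept] = vc.sigma_pe2
            draws["sigma_e2"][kept] = vc.sigma_e2
            draws["h2"][kept] = heritability(vc)
            draws["sigma_u2_liab"][kept] = G0[1, 1]
            draws["gen_corr"][kept] = G0[0, 1] / np.sqrt(G0[0, 0] * G0[1, 1])
            draws["res_cov"][kept] = R0[0, 1]
            draws["h2_liab"][kept] = G0[1, 1] / (G0[1, 1] + P0[1, 1] + R0[1, 1])
            sign_ok[kept] = bool(
                np.all((liab > 0) == (status == 1))
            )
            if stored_liab is not None:
                stored_liab.append(liab.copy())
            eff_sum += theta
            eff_sq += theta**2
            kept += 1

    chain = PosteriorChain(draws={k: v[:kept] for k, v in draws.items()}, config=config)
    mean = eff_sum / max(kept, 1)
    var = np.maximum(eff_sq / max(kept, 1) - mean**2, 0.0)
    for block, sl in s.items():
        chain.effect_mean[block] = mean[sl, 0]
        chain.effect_sd[block] = np.sqrt(var[sl, 0])
    chain.extras["liability_sign_ok"] = sign_ok[:kept]
    if stored_liab is not None:
        chain.extras["liabilities"] = np.array(stored_liab)

    ebv_liab = pd.DataFrame(
        {
            "animal_id": ped.to_external(range(1, ped.n + 1)),
            "model": "PTM-liability",
            "ebv": mean[s["u"], 1],
            "posterior_sd": np.sqrt(var[s["u"], 1]),
        }
    )
    res = _finish("PTM", design, ped, chain, extras={"augmented": aug, "ebv_liability": ebv_liab})
    return res


def _nearpd(S: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Guard an inverse-Wishart scale matrix against numerical indefiniteness."""
    S = 0.5 * (S + S.T)
    jitter = eps * max(np.trace(S), 1.0)
    return S + jitter * np.eye(S.shape[0])


FIT_FUNCTIONS = {"LM": fit_lm, "PLM": fit_plm, "PTM": fit_ptm}


def fit_model(variant: str, records, ped, config, **kw) -> FitResult:
    """Dispatch to fit_lm / fit_plm / fit_ptm by variant name."""
    try:
        fn = FIT_FUNCTIONS[variant.upper()]
    except KeyError:
        raise CensoringError(f"unknown model variant {variant!r}") from None
    return fn(records, ped, config, **kw)
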