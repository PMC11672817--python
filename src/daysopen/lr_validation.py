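"""LR-method validation of breeding values (whole vs. partial evaluation).

The LR method compares EBVs of a validation cohort (young phenotyped
animals) estimated from the whole dataset (u_w) against EBVs from a partial
dataset with the cohort's phenotypes removed (u_p):

  accuracy   = sqrt( cov(u_w, u_p) / ((1 - F_bar) * sigma_a2) )
  bias       = mean(u_p) - mean(u_w)          (days)
  dispersion = cov(u_w, u_p) / var(u_p)       (regression slope of u_w on u_p)

where F_bar is the mean inbreeding of the validation cohort and sigma_a2
the genetic variance estimated by the model under validation.  Model
agreement is summarized by Spearman rank correlations and the percentage of
common animals in the top fraction (lowest EBV = best: shorter days open is
the favourable direction for a fertility trait; flip with ``best_is_low``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ValidationError(ValueError):
    pass


@dataclass
class ValidationSplit:
    """Whole/partial phenotype split for LR validation."""

    whole: pd.DataFrame
    partial: pd.DataFrame
    validation_cows: list  # external cow ids, phenotyped, born >= cutoff
    cutoff: pd.Timestamp

    @property
    def validation_fraction(self) -> float:
        return len(self.validation_cows) / self.whole["cow_id"].nunique()


def _as_cutoff(cutoff) -> pd.Timestamp:
    if isinstance(cutoff, (int, np.integer)):
        return pd.Timestamp(year=int(cutoff), month=1, day=1)
    return pd.Timestamp(cutoff)


def make_split(records: pd.DataFrame, cutoff=2020) -> ValidationSplit:
    """Remove the phenotypes of cows born on/after the cutoff.

    ``cutoff`` is a calendar year or an ISO date.  Only phenotyped cows
    enter the validation set; the pedigree (and hence relationship
    information) is untouched - only phenotype rows are dropped.
    """
    ts = _as_cutoff(cutoff)
    young = records["birth_date"] >= ts
    cows = sorted(records.loc[young, "cow_id"].unique())
    if not cows:
        raise ValidationError(f"no phenotyped animal born on/after {ts.date()}")
    partial = records.loc[~records["cow_id"].isin(cows)].reset_index(drop=True)
    if len(partial) == 0:
        raise ValidationError("cutoff removes every phenotype; nothing to fit on")
    return ValidationSplit(
        whole=records.reset_index(drop=True),
        partial=partial,
        validation_cows=cows,
        cutoff=ts,
    )


def cutoff_for_fraction(records: pd.DataFrame, fraction: float = 0.30) -> pd.Timestamp:
    """Birth-date cutoff that puts ~``fraction`` of phenotyped cows in validation."""
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    births = records.groupby("cow_id")["birth_date"].min().sort_values()
    k = int(np.ceil(fraction * len(births)))
    return births.iloc[len(births) - k]


def acc_lr(ebv_whole, ebv_partial, F_bar: float, sigma_a2: float) -> float:
    """LR accuracy: sqrt(cov(u_w, u_p) / ((1 - F_bar) sigma_a2)).

    Returns NaN (with a warning) when the EBV covariance is negative, where
    the accuracy is undefined.
    """
    if sigma_a2 <= 0:
        raise ValidationError("sigma_a2 must be positive")
    if not 0 <= F_bar < 1:
        raise ValidationError("F_bar must be in [0, 1)")
    ratio = acc_lr_squared(ebv_whole, ebv_partial, F_bar, sigma_a2)
    if ratio < 0:
        warnings.warn("negative EBV covariance; LR accuracy undefined (NaN)")
        return float("nan")
    return float(np.sqrt(ratio))


def acc_lr_squared(ebv_whole, ebv_partial, F_bar: float, sigma_a2: float) -> float:
    """Unrooted variant cov(u_w, u_p) / ((1 - F_bar) sigma_a2) for comparison."""
    w = np.asarray(ebv_whole, dtype=float)
    p = np.asarray(ebv_partial, dtype=float)
    cov = float(np.cov(w, p, ddof=1)[0, 1])
    return cov / ((1.0 - F_bar) * sigma_a2)


def bias_lr(ebv_whole, ebv_partial) -> float:
    """mean(u_p) - mean(u_w) over the validation animals (days)."""
    return float(np.mean(ebv_partial) - np.mean(ebv_whole))


def dispersion_lr(ebv_whole, ebv_partial) -> float:
    """Regression slope of u_w on u_p: cov(u_w, u_p) / var(u_p)."""
    p = np.asarray(ebv_partial, dtype=float)
    vp = float(np.var(p, ddof=1))
    if vp == 0:
        raise ValidationError("partial EBVs are constant; slope undefined")
    cov = float(np.cov(np.asarray(ebv_whole, dtype=float), p, ddof=1)[0, 1])
    return cov / vp


def rank_agreement(
    ebv_a,
    ebv_b,
    ids=None,
    top_fraction: float = 0.20,
    best_is_low: bool = True,
) -> tuple[float, float]:
    """Spearman correlation and top-fraction overlap between two EBV vectors.

    ``top`` means lowest EBV when ``best_is_low`` (the default for days
    open).  Top-k size is ceil(fraction * n); boundary ties are broken by
    id order (stable sort) for determinism.  Returns (spearman, overlap %).
    """
    a = np.asarray(ebv_a, dtype=float)
    b = np.asarray(ebv_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("EBV vectors differ in length")
    n = a.size
    rho = float(stats.spearmanr(a, b).statistic) if n > 1 else 1.0
    k = int(np.ceil(top_fraction * n))
    sgn = 1.0 if best_is_low else -1.0
    order_a = np.argsort(sgn * a, kind="stable")[:k]
    order_b = np.argsort(sgn * b, kind="stable")[:k]
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    overlap = len(set(ids[order_a]) & set(ids[order_b])) / k * 100.0
    return rho, overlap


@dataclass
class LRReport:
    """Per-model LR statistics plus cross-model agreement matrices."""

    acc: dict
    acc_squared: dict
    bias: dict
    dispersion: dict
    spearman: pd.DataFrame
    overlap: pd.DataFrame
    F_bar: float
    sigma_a2: dict
    n_validation: int
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "acc_lr": self.acc,
            "acc_lr_squared": self.acc_squared,
            "bias_lr": self.bias,
            "dispersion_lr": self.dispersion,
            "spearman": self.spearman.to_dict(),
            "top_overlap_pct": self.overlap.to_dict(),
            "F_bar": self.F_bar,
            "sigma_a2": self.sigma_a2,
            "n_validation": self.n_validation,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> pd.DataFrame:
        """Compact table: acc/bias/dispersion rows, then the agreement matrix
        (Spearman above the diagonal, top-overlap % below)."""
        models = list(self.spearman.columns)
        rows = [
            ["acc_lr"] + [self.acc[m] for m in models],
            ["bias_lr"] + [self.bias[m] for m in models],
            ["dispersion_lr"] + [self.dispersion[m] for m in models],
        ]
        for i, mi in enumerate(models):
            row = [mi]
            for j, mj in enumerate(models):
                if i < j:
                    row.append(self.spearman.loc[mi, mj])
                elif i > j:
                    row.append(self.overlap.loc[mi, mj])
                else:
                    row.append("")
            rows.append(row)
        return pd.DataFrame(rows, columns=["quantity"] + models)


def lr_report(
    ebv_whole: dict,
    ebv_partial: dict,
    validation_ids,
    F_bar: float,
    sigma_a2: dict,
    top_fraction: float = 0.20,
    best_is_low: bool = True,
) -> LRReport:
    """Assemble an :class:`LRReport` from per-model EBV tables.

    ``ebv_whole`` / ``ebv_partial`` map model name -> DataFrame with columns
    ``animal_id`` and ``ebv``; ``sigma_a2`` maps model name -> that model's
    own posterior-mean genetic variance (each model is judged on its own
    scale).
    """
    models = list(ebv_whole)
    vids = list(validation_ids)

    def vec(table):
        s = table.set_index("animal_id")["ebv"]
        missing = [v for v in vids if v not in s.index]
        if missing:
            raise ValidationError(f"EBVs missing for validation animals {missing[:5]}")
        return s.loc[vids].to_numpy(dtype=float)

    acc, acc2, bias, disp = {}, {}, {}, {}
    w_vecs, p_vecs = {}, {}
    for m in models:
        w_vecs[m] = vec(ebv_whole[m])
        p_vecs[m] = vec(ebv_partial[m])
        acc[m] = acc_lr(w_vecs[m], p_vecs[m], F_bar, sigma_a2[m])
        acc2[m] = acc_lr_squared(w_vecs[m], p_vecs[m], F_bar, sigma_a2[m])
        bias[m] = bias_lr(w_vecs[m], p_vecs[m])
        disp[m] = dispersion_lr(w_vecs[m], p_vecs[m])

    spearman = pd.DataFrame(np.eye(len(models)), index=models, columns=models)
    overlap = pd.DataFrame(100.0 * np.ones((len(models), len(models))),
                           index=models, columns=models)
    for i, mi in enumerate(models):
        for j, mj in enumerate(models):
            if i == j:
                continue
            rho, ov = rank_agreement(
                p_vecs[mi], p_vecs[mj], ids=vids,
                top_fraction=top_fraction, best_is_low=best_is_low,
            )
            spearman.loc[mi, mj] = rho
            overlap.loc[mi, mj] = ov
    return LRReport(
        acc=acc, acc_squared=acc2, bias=bias, dispersion=disp,
        spearman=spearman, overlap=overlap,
        F_bar=F_bar, sigma_a2=sigma_a2, n_validation=len(vids),
    )


def run_validation(
    records: pd.DataFrame,
    ped,
    config,
    variants=("LM", "PLM", "PTM"),
    cutoff=2020,
    top_fraction: float = 0.20,
    best_is_low: bool = True,
    penalty: float | None = None,
) -> LRReport:
    """Fit each censoring model on the whole and the partial dataset and
    assemble the LR report.

    ``sigma_a2`` for each model's accuracy is that model's own
    posterior-mean additive variance from the whole-data fit.  The partial
    fit uses a shifted chain seed so whole and partial chains are
    independent.
    """
    from dataclasses import replace

    from .censoring import DEFAULT_PENALTY, fit_model
    from .pedigree import inbreeding, mean_inbreeding

    penalty = DEFAULT_PENALTY if penalty is None else penalty
    split = make_split(records, cutoff)
    F = inbreeding(ped)
    vids_internal = ped.to_internal(split.validation_cows)
    F_bar = mean_inbreeding(ped, vids_internal, F=F)

    kw = {}
    ebv_w, ebv_p, sigma_a2 = {}, {}, {}
    fits = {}
    for k, variant in enumerate(variants):
        if variant.upper() != "LM":
            kw = {"penalty": penalty}
        else:
            kw = {}
        fw = fit_model(variant, split.whole, ped, replace(config, seed=config.seed + 2 * k), **kw)
        fp = fit_model(variant, split.partial, ped, replace(config, seed=config.seed + 2 * k + 1), **kw)
        ebv_w[fw.model] = fw.ebv
        ebv_p[fp.model] = fp.ebv
        sigma_a2[fw.model] = fw.vc_mean.sigma_u2
        fits[fw.model] = (fw, fp)

    report = lr_report(
        ebv_w, ebv_p, split.validation_cows, F_bar, sigma_a2,
        top_fraction=top_fraction, best_is_low=best_is_low,
    )
    report.extras["fits"] = fits
    report.extras["split"] = split
    return report
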