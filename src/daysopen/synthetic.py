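"""Synthetic pedigree + censored days-open datasets with known ground truth.

The generator emulates the statistical structure the censoring models
assume: a multi-generation pedigree under random mating, breeding values
drawn recursively with inbreeding-shrunk Mendelian-sampling variances,
repeated lactation records (up to three parities) with herd-year-season
contemporary groups and two linear covariates, and right-censoring of each
cow's final record (a later calving confirms pregnancy, so only a cow's
last record can be censored at data retrieval).

Default true variance components (437.64, 705.76, 11932.0 days^2, h2 ~
0.033) and the 14.51% censoring target are typical of days open in a
small intensively managed Holstein population; the default scale (~1,000
founder animals, ~2,000 records) keeps a full three-model fit plus
validation in the minutes range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_editing import assign_season, flag_censored
from .pedigree import Pedigree, from_triples, inbreeding, mendelian_variances

MECHANISMS = ("random", "value_dependent", "liability_correlated")


@dataclass
class SimulationConfig:
    n_founders: int = 1000
    n_generations: int = 4            # founders + 3 descendant generations
    progeny_per_dam: int = 2
    n_herds: int = 4
    base_birth_year: int = 2015
    generation_interval_years: int = 2
    retrieval_date: str = "2023-12-31"
    # true variance components (days^2)
    sigma_u2: float = 437.64
    sigma_pe2: float = 705.76
    sigma_e2: float = 11932.0
    # fixed-effect truth
    intercept: float = 155.0
    hys_sd: float = 15.0
    parity_effects: tuple = (0.0, 1.1, 4.2)
    slope_dim_first_ai: float = 0.5   # days DO per day of delayed first AI
    slope_age_at_calving: float = 0.01
    # lactation-career probabilities
    p_parity2: float = 0.62
    p_parity3_given_2: float = 0.45
    # censoring
    censoring_mechanism: str = "value_dependent"
    censoring_rate: float = 0.1451
    liability_gen_corr: float = 0.5   # liability_correlated mechanism only
    liability_h2: float = 0.10
    residual_distribution: str = "gaussian"   # or "lognormal" (stress test)
    do_floor: float = 20.0
    seed: int = 0

    def validate(self):
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if not -1 < self.liability_gen_corr < 1:
            raise ValueError("liability_gen_corr must be in (-1, 1)")
        if min(self.sigma_u2, self.sigma_pe2, self.sigma_e2) <= 0:
            raise ValueError("true variances must be positive")
        if self.censoring_mechanism not in MECHANISMS:
            raise ValueError(f"censoring mechanism must be one of {MECHANISMS}")


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated dataset."""

    animals: pd.DataFrame         # animal_id, sex, generation, birth_date, u, (u_liab), pe
    records: pd.DataFrame         # cow_id, parity, latent_do, censored
    params: dict = field(default_factory=dict)


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Non-overlapping generations under random mating.

    Sexes alternate deterministically within each generation so the animal
    count follows closed-form bookkeeping:
    n_founders + (gens - 1) * floor(n_founders/2) * progeny_per_dam when
    every generation keeps the founder cohort's female count (the default
    progeny_per_dam = 2 with balanced sexes does exactly that).

    Returns (Pedigree, meta DataFrame with sex/generation/birth_date).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    triples = []
    meta_rows = []
    next_id = 1

    def add_animal(sire, dam, gen, idx_in_gen):
        nonlocal next_id
        aid = next_id
        next_id += 1
        sex = "M" if idx_in_gen % 2 == 0 else "F"
        year0 = config.base_birth_year + gen * config.generation_interval_years
        day = int(rng.integers(0, 365 * config.generation_interval_years))
        birth = pd.Timestamp(year=year0, month=1, day=1) + pd.Timedelta(days=day)
        triples.append((aid, sire, dam))
        meta_rows.append((aid, sex, gen, birth))
        return aid, sex

    males, females = [], []
    for i in range(config.n_founders):
        aid, sex = add_animal(0, 0, 0, i)
        (males if sex == "M" else females).append(aid)

    for gen in range(1, config.n_generations):
        new_m, new_f = [], []
        idx = 0
        for dam in females:
            sire = int(males[rng.integers(0, len(males))])
            for _ in range(config.progeny_per_dam):
                aid, sex = add_animal(sire, dam, gen, idx)
                idx += 1
                (new_m if sex == "M" else new_f).append(aid)
        males, females = new_m, new_f

    ped = from_triples(triples)
    meta = pd.DataFrame(meta_rows, columns=["animal_id", "sex", "generation", "birth_date"])
    return ped, meta


def _simulate_breeding_values(ped: Pedigree, G0: np.ndarray, rng) -> np.ndarray:
    """Recursive BV simulation: u_i = parent average + Mendelian deviation.

    The Mendelian-sampling (co)variance is d_i * G0 with d_i shrunk by
    parental inbreeding; G0 may be 1x1 (one trait) or 2x2.
    """
    nt = G0.shape[0]
    F = inbreeding(ped)
    d = mendelian_variances(ped, F)
    L = np.linalg.cholesky(G0)
    u = np.zeros((ped.n + 1, nt))
    z = rng.standard_normal((ped.n, nt))
    for i in range(1, ped.n + 1):
        s, dm = ped.sire[i], ped.dam[i]
        pa = 0.5 * (u[s] + u[dm])  # row 0 is the zero vector (unknown parent)
        u[i] = pa + np.sqrt(d[i - 1]) * (L @ z[i - 1])
    return u[1:]


def simulate_phenotypes(ped: Pedigree, meta: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None):
    """Simulate lactation records for non-founder females.

    Returns (records DataFrame in the phenotype-file dialect, SyntheticTruth).
    Only a cow's final record is eligible for censoring; the per-record
    probabilities are scaled so the expected *overall* censored fraction
    matches ``config.censoring_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    retrieval = pd.Timestamp(config.retrieval_date)

    bivariate = config.censoring_mechanism == "liability_correlated"
    if bivariate:
        su, sl = config.sigma_u2, config.liability_h2
        rho = config.liability_gen_corr
        G0 = np.array([[su, rho * np.sqrt(su * sl)], [rho * np.sqrt(su * sl), sl]])
    else:
        G0 = np.array([[config.sigma_u2]])
    u = _simulate_breeding_values(ped, G0, rng)

    meta = meta.set_index("animal_id")
    cows = meta[(meta["sex"] == "F") & (meta["generation"] > 0)].index.to_numpy()
    pe = rng.normal(0.0, np.sqrt(config.sigma_pe2), size=cows.size)
    pe_by_cow = dict(zip(cows, pe))
    herd_by_cow = dict(zip(cows, rng.integers(1, config.n_herds + 1, size=cows.size)))

    hys_effects: dict = {}
    rows = []
    for cow in cows:
        birth = meta.loc[cow, "birth_date"]
        ages = [float(np.clip(rng.normal(771.75, 77.81), 540, 1100))]
        if rng.uniform() < config.p_parity2:
            ages.append(ages[0] + max(300.0, rng.normal(429.5, 80.0)))
            if rng.uniform() < config.p_parity3_given_2:
                ages.append(ages[1] + max(300.0, rng.normal(427.0, 90.0)))
        for parity, age in enumerate(ages, start=1):
            calving = birth + pd.Timedelta(days=round(age))
            if calving > retrieval:
                break
            dim = float(np.clip(rng.normal(76.0, 25.0), 20, 250))
            rows.append((cow, herd_by_cow[cow], calving, birth, parity, round(age), round(dim)))

    rec = pd.DataFrame(rows, columns=[
        "cow_id", "herd", "calving_date", "birth_date", "parity",
        "age_at_calving", "dim_first_ai",
    ])
    season = rec["calving_date"].map(assign_season)
    rec["hys"] = (rec["herd"].astype(str) + ":"
                  + rec["calving_date"].dt.year.astype(str) + ":" + season)
    for h in pd.unique(rec["hys"]):
        hys_effects[h] = rng.normal(0.0, config.hys_sd)

    internal = ped.to_internal(rec["cow_id"].tolist())
    u_do = u[internal - 1, 0]
    if config.residual_distribution == "lognormal":
        # right-skewed residual with matching first two moments (stress test)
        se = np.sqrt(config.sigma_e2)
        sigma_ln = np.sqrt(np.log(1 + 1.0))  # cv = 1
        mu_ln = np.log(se) - sigma_ln**2 / 2
        e = rng.lognormal(mu_ln, sigma_ln, size=len(rec)) - se
    else:
        e = rng.normal(0.0, np.sqrt(config.sigma_e2), size=len(rec))
    latent = (
        config.intercept
        + rec["hys"].map(hys_effects).to_numpy()
        + np.array(config.parity_effects)[rec["parity"].to_numpy() - 1]
        + config.slope_dim_first_ai * (rec["dim_first_ai"].to_numpy() - 76.0)
        + config.slope_age_at_calving * (rec["age_at_calving"].to_numpy() - 1000.0)
        + u_do
        + np.array([pe_by_cow[c] for c in rec["cow_id"]])
        + e
    )
    latent = np.maximum(latent, config.do_floor)
    latent = np.round(latent)

    censored = _censor(rec, latent, u, internal, config, rng)

    obs = latent.copy()
    obs[censored] = np.maximum(
        config.do_floor, np.round(latent[censored] * rng.uniform(0.4, 0.9, censored.sum()))
    )
    rec["do"] = obs
    rec["conception_date"] = rec["calving_date"] + pd.to_timedelta(obs, unit="D")
    rec.loc[censored, "conception_date"] = pd.NaT

    truth_animals = meta.reset_index()[["animal_id", "sex", "generation", "birth_date"]].copy()
    truth_animals["u"] = u[:, 0][ped.to_internal(truth_animals["animal_id"].tolist()) - 1]
    if bivariate:
        truth_animals["u_liab"] = u[:, 1][ped.to_internal(truth_animals["animal_id"].tolist()) - 1]
    truth_animals["pe"] = truth_animals["animal_id"].map(pe_by_cow)
    truth_records = pd.DataFrame({
        "cow_id": rec["cow_id"], "parity": rec["parity"],
        "latent_do": latent, "censored": censored,
    })
    truth = SyntheticTruth(
        animals=truth_animals,
        records=truth_records,
        params={
            "sigma_u2": config.sigma_u2, "sigma_pe2": config.sigma_pe2,
            "sigma_e2": config.sigma_e2,
            "h2": config.sigma_u2 / (config.sigma_u2 + config.sigma_pe2 + config.sigma_e2),
            "hys_effects": hys_effects,
            "realized_var_e": float(np.var(e, ddof=1)),
            "realized_censoring_rate": float(np.mean(censored)),
            "mechanism": config.censoring_mechanism,
        },
    )
    out = rec.drop(columns=["hys"])
    out = flag_censored(out)
    return out, truth


def _censor(rec, latent, u, internal, config: SimulationConfig, rng) -> np.ndarray:
    """Censoring indicator; only each cow's final record is eligible."""
    n = len(rec)
    is_last = ~rec.duplicated(subset="cow_id", keep="last").to_numpy()
    n_elig = int(is_last.sum())
    target = config.censoring_rate * n / max(n_elig, 1)  # rate among eligible
    target = min(target, 0.999)
    censored = np.zeros(n, dtype=bool)
    if config.censoring_rate == 0:
        return censored
    mech = config.censoring_mechanism
    if mech == "random":
        censored[is_last] = rng.uniform(size=n_elig) < target
    elif mech == "value_dependent":
        # long DO (top 15% within HYS) censored with 4x elevated probability
        s = pd.Series(latent)
        q85 = s.groupby(rec["hys"].to_numpy()).transform(lambda x: x.quantile(0.85))
        high = (s > q85).to_numpy()
        # calibrate to the realized high-fraction among eligible records so
        # small contemporary groups do not inflate the overall rate
        f_high = float(high[is_last].mean())
        p_low = target / ((1.0 - f_high) + 4.0 * f_high)
        p_high = 4.0 * p_low
        if p_high > 1.0:
            p_high = 1.0
            p_low = max((target - f_high) / (1.0 - f_high), 0.0)
        p = np.where(high, p_high, p_low)
        censored[is_last] = rng.uniform(size=n_elig) < p[is_last]
    else:  # liability_correlated
        u_l = u[internal - 1, 1]
        e_l = rng.normal(0.0, np.sqrt(1.0 - config.liability_h2), size=n)
        liab = u_l + e_l
        thresh = stats.norm.ppf(1.0 - target)
        censored[is_last] = liab[is_last] > thresh
    return censored


def simulate_dataset(config: SimulationConfig):
    """Pedigree + phenotypes + truth in one call (single seed)."""
    rng = np.random.default_rng(config.seed)
    ped, meta = simulate_pedigree(config, rng)
    records, truth = simulate_phenotypes(ped, meta, config, rng)
    return ped, records, truth


def realized_h2(truth: SyntheticTruth) -> float:
    """Realized variance-decomposition h2 of one simulated dataset.

    Uses the founder breeding values (mutually unrelated, so their sample
    variance estimates sigma_u2 without covariance bias), the cow pe draws
    and the record-level residual implied by latent - (systematic + u + pe).
    """
    founders = truth.animals[truth.animals["generation"] == 0]
    vu = float(founders["u"].var(ddof=1))
    vpe = float(truth.animals["pe"].dropna().var(ddof=1))
    ve = truth.params["realized_var_e"]
    return vu / (vu + vpe + ve)


def write_fixture(records: pd.DataFrame, ped: Pedigree, truth: SyntheticTruth, outdir):
    """Write pedigree / phenotype / truth files, re-readable and seed-stable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped_path = outdir / "pedigree.txt"
    with open(ped_path, "w") as fh:
        for i in range(1, ped.n + 1):
            s, d = ped.sire[i], ped.dam[i]
            fh.write(
                f"{ped.original_ids[i - 1]} "
                f"{ped.original_ids[s - 1] if s else 0} "
                f"{ped.original_ids[d - 1] if d else 0}\n"
            )
    pheno = records.copy()
    for col in ("calving_date", "birth_date", "conception_date"):
        pheno[col] = pd.to_datetime(pheno[col]).dt.strftime("%Y-%m-%d")
    pheno_path = outdir / "phenotypes.csv"
    pheno.to_csv(pheno_path, index=False)
    truth.animals.assign(
        birth_date=pd.to_datetime(truth.animals["birth_date"]).dt.strftime("%Y-%m-%d")
    ).to_csv(outdir / "truth_animals.csv", index=False)
    truth.records.to_csv(outdir / "truth_records.csv", index=False)
    return {"pedigree": ped_path, "phenotypes": pheno_path,
            "truth_animals": outdir / "truth_animals.csv",
            "truth_records": outdir / "truth_records.csv"}
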