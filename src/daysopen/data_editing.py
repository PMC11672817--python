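"""Phenotype editing: filters, censorship flagging, contemporary groups.

Records are lactations of dairy cows with the fertility trait *days open*
(DO: days from calving to the next conception).  Editing keeps the first
three parities, removes implausible ages and covariate outliers, applies
DO range filters to uncensored records only, and builds herd x calving-year
x calving-season (HYS) contemporary groups, dropping groups with fewer than
three records.  Every rule reports how many records it removed so the edit
is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: columns a phenotype table must carry
REQUIRED_COLUMNS = (
    "cow_id", "herd", "calving_date", "birth_date", "parity",
    "age_at_calving", "dim_first_ai", "do",
)

_SEASON_BY_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


class EditingError(ValueError):
    pass


def parse_dates(series: pd.Series) -> pd.Series:
    """Strict ISO-8601 (YYYY-MM-DD) date parsing; empty -> NaT, else hard error."""
    return pd.to_datetime(series, format="%Y-%m-%d", errors="raise")


def assign_season(calving_date) -> str | pd.Series:
    """Season of calving: Dec-Feb winter, Mar-May spring, Jun-Aug summer,
    Sep-Nov fall.  Accepts a scalar date or a datetime Series.

    The HYS key always uses the calendar year of calving, so a December
    calving is 'winter' of its own year, not of the following one.
    """
    if isinstance(calving_date, pd.Series):
        return calving_date.dt.month.map(_SEASON_BY_MONTH)
    return _SEASON_BY_MONTH[pd.Timestamp(calving_date).month]


def hys_key(df: pd.DataFrame) -> pd.Series:
    """Herd-year-season contemporary-group label per record."""
    year = df["calving_date"].dt.year.astype(str)
    season = assign_season(df["calving_date"])
    return df["herd"].astype(str) + ":" + year + ":" + season


def flag_censored(df: pd.DataFrame) -> pd.DataFrame:
    """Mark records censored when no pregnancy was confirmed.

    A record is uncensored if it has a conception date, or if the same cow
    has a later calving (a subsequent calving confirms the pregnancy even
    when the conception date was not recorded).  Otherwise the recorded DO
    is only a lower bound and the record is flagged censored.
    """
    df = df.copy()
    has_conception = (
        df["conception_date"].notna()
        if "conception_date" in df.columns
        else pd.Series(False, index=df.index)
    )
    last_calving = df.groupby("cow_id")["calving_date"].transform("max")
    has_later_calving = df["calving_date"] < last_calving
    df["censored"] = ~(has_conception | has_later_calving)
    return df


@dataclass
class EditReport:
    """Per-rule removal counts, in application order."""

    removed: dict = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule": list(self.removed), "removed_count": list(self.removed.values())}
        )


@dataclass
class EditConfig:
    parities: tuple = (1, 2, 3)
    min_first_calving_age: float = 530.0
    covariate_sd_mult: float = 3.0
    covariate_filter_within_parity: bool = False
    do_min: float = 20.0
    do_sd_mult: float = 3.0
    min_group_size: int = 3


def edit_records(
    df: pd.DataFrame, config: EditConfig | None = None
) -> tuple[pd.DataFrame, EditReport]:
    """Apply the editing pipeline in a fixed, audited order.

    Order: parity window -> missing/duplicate calving dates -> early first
    calving -> covariate outliers (mean + 3 SD, computed once on the data
    entering that rule) -> uncensored DO < 20 d -> uncensored DO outside
    mean +/- 3 SD within parity -> HYS groups smaller than 3.  Censored
    records are exempt from the two DO filters: their DO is a lower bound,
    not an observation, and the censoring models re-impute it.

    Returns the surviving records (with a ``hys`` column) and an
    :class:`EditReport` whose counts sum to ``n_in - n_out``.
    """
    cfg = config or EditConfig()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EditingError(f"phenotype table missing columns: {missing}")
    df = df.copy()
    if not pd.api.types.is_datetime64_any_dtype(df["calving_date"]):
        df["calving_date"] = parse_dates(df["calving_date"])
    if not pd.api.types.is_datetime64_any_dtype(df["birth_date"]):
        df["birth_date"] = parse_dates(df["birth_date"])
    if "censored" not in df.columns:
        df = flag_censored(df)

    report = EditReport(n_in=len(df))

    def apply_rule(name, keep_mask):
        nonlocal df
        keep_mask = keep_mask.fillna(False) if keep_mask.dtype == object else keep_mask
        report.removed[name] = int((~keep_mask).sum())
        df = df[keep_mask]

    apply_rule("parity", df["parity"].isin(cfg.parities))
    apply_rule(
        "calving_date",
        df["calving_date"].notna()
        & ~df.duplicated(subset=["cow_id", "calving_date"], keep="first"),
    )

    early = df.loc[
        (df["parity"] == 1) & (df["age_at_calving"] < cfg.min_first_calving_age),
        "cow_id",
    ].unique()
    apply_rule("early_first_calving", ~df["cow_id"].isin(early))

    # covariate outliers: thresholds frozen on the data entering this rule
    def cov_keep(col):
        if cfg.covariate_filter_within_parity:
            mu = df.groupby("parity")[col].transform("mean")
            sd = df.groupby("parity")[col].transform("std")
        else:
            mu, sd = df[col].mean(), df[col].std()
        return df[col] <= mu + cfg.covariate_sd_mult * sd

    apply_rule("covariate_outlier", cov_keep("age_at_calving") & cov_keep("dim_first_ai"))

    cens = df["censored"].astype(bool)
    apply_rule("do_min", cens | (df["do"] >= cfg.do_min))

    mu = df.groupby("parity")["do"].transform(lambda s: s[~cens.loc[s.index]].mean())
    sd = df.groupby("parity")["do"].transform(lambda s: s[~cens.loc[s.index]].std())
    cens = df["censored"].astype(bool)
    in_range = (df["do"] >= mu - cfg.do_sd_mult * sd) & (df["do"] <= mu + cfg.do_sd_mult * sd)
    apply_rule("do_range", cens | in_range)

    df["hys"] = hys_key(df)
    sizes = df.groupby("hys")["hys"].transform("size")
    apply_rule("small_cg", sizes >= cfg.min_group_size)

    report.n_out = len(df)
    if report.n_out == 0:
        raise EditingError("no records survive editing")
    return df.reset_index(drop=True), report


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype CSV with named header columns and ISO dates."""
    df = pd.read_csv(path)
    for col in ("calving_date", "birth_date", "conception_date"):
        if col in df.columns:
            df[col] = parse_dates(df[col])
    return df
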