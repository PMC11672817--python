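"""LR-method statistics: accuracy, bias, dispersion, rank agreement, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import daysopen as d
from daysopen.lr_validation import ValidationError

vectors = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False), min_size=3, max_size=40
).filter(lambda xs: np.std(xs) > 1e-6)


class TestIdentities:
    @given(vectors)
    @settings(max_examples=50, deadline=None)
    def test_self_comparison(self, xs):
        x = np.array(xs)
        assert d.bias_lr(x, x) == 0.0
        assert d.dispersion_lr(x, x) == pytest.approx(1.0)
        rho, overlap = d.rank_agreement(x, x)
        assert rho == pytest.approx(1.0)
        assert overlap == 100.0

    def test_shifted_bias(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert d.bias_lr(x, x + 3.0) == pytest.approx(3.0)

    def test_halved_dispersion(self):
        p = np.array([2.0, 4.0, 8.0, 16.0])
        assert d.dispersion_lr(0.5 * p, p) == pytest.approx(0.5)

    def test_constant_partial_is_error(self):
        with pytest.raises(ValidationError, match="slope"):
            d.dispersion_lr(np.array([1.0, 2.0]), np.array([5.0, 5.0]))

    def test_shift_invariance_where_mathematically_true(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=50)
        p = w + 0.5 * rng.normal(size=50)  # positively related, cov > 0
        assert d.acc_lr(w + 7, p + 7, 0.01, 1.0) == pytest.approx(d.acc_lr(w, p, 0.01, 1.0))
        assert d.dispersion_lr(w + 7, p + 7) == pytest.approx(d.dispersion_lr(w, p))
        # bias is NOT shift invariant:
        assert d.bias_lr(w, p + 7) == pytest.approx(d.bias_lr(w, p) + 7)


class TestAccuracy:
    def test_self_consistency_limit(self):
        rng = np.random.default_rng(1)
        F_bar, sigma_a2 = 0.009, 437.64
        u = rng.normal(size=20000) * np.sqrt((1 - F_bar) * sigma_a2)
        # scale to the exact sample variance
        u *= np.sqrt((1 - F_bar) * sigma_a2 / np.var(u, ddof=1))
        assert d.acc_lr(u, u, F_bar, sigma_a2) == pytest.approx(1.0, abs=1e-9)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(2)
        w, p = rng.normal(size=100_000), rng.normal(size=100_000)
        assert abs(d.acc_lr_squared(w, p, 0.0, 1.0)) < 0.02

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        w, p = rng.normal(size=200), rng.normal(size=200)
        F_bar, sa2 = 0.009, 400.0
        expected = np.sqrt(np.cov(w, p)[0, 1] / ((1 - F_bar) * sa2))
        assert d.acc_lr(w, p, F_bar, sa2) == pytest.approx(expected)

    def test_negative_covariance_gives_nan_with_warning(self):
        w = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="negative"):
            out = d.acc_lr(w, -w, 0.0, 1.0)
        assert np.isnan(out)

    def test_parameter_validation(self):
        w = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            d.acc_lr(w, w, 0.0, -1.0)
        with pytest.raises(ValidationError):
            d.acc_lr(w, w, 1.5, 1.0)


class TestRankAgreement:
    def test_reversed_ranks_pigeonhole(self):
        n, frac = 10, 0.2
        x = np.arange(float(n))
        rho, overlap = d.rank_agreement(x, -x, top_fraction=frac)
        k = int(np.ceil(frac * n))
        assert rho == pytest.approx(-1.0)
        assert overlap == pytest.approx(max(0, 2 * k - n) / k * 100)

    def test_random_vectors_expectations(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        rho, overlap = d.rank_agreement(a, b)
        assert abs(rho) < 0.1
        assert 12 < overlap < 28  # expectation 20% under independence

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=100), rng.normal(size=100)
        base = d.rank_agreement(a, b)
        assert d.rank_agreement(np.exp(a), b) == base
        assert d.rank_agreement(a, 3 * b + 2) == base

    def test_dispersion_matches_regression_oracle(self):
        rng = np.random.default_rng(6)
        p = rng.normal(size=300)
        w = 0.8 * p + rng.normal(size=300) * 0.3
        slope = stats.linregress(p, w).slope
        assert d.dispersion_lr(w, p) == pytest.approx(slope)


class TestMakeSplit:
    def test_empty_validation_is_error(self, small_sim):
        with pytest.raises(ValidationError):
            d.make_split(small_sim["edited"], cutoff=2050)

    def test_partial_plus_removed_is_whole(self, small_sim):
        split = d.make_split(small_sim["edited"], cutoff=2020)
        removed = split.whole[split.whole["cow_id"].isin(split.validation_cows)]
        assert len(split.partial) + len(removed) == len(split.whole)
        assert not set(split.partial["cow_id"]) & set(split.validation_cows)

    def test_only_phenotyped_animals_in_validation(self, small_sim):
        split = d.make_split(small_sim["edited"], cutoff=2020)
        phenotyped = set(small_sim["edited"]["cow_id"])
        assert set(split.validation_cows) <= phenotyped

    def test_cutoff_for_fraction_hits_target(self, small_sim):
        cutoff = d.cutoff_for_fraction(small_sim["edited"], 0.30)
        split = d.make_split(small_sim["edited"], cutoff=cutoff)
        assert split.validation_fraction == pytest.approx(0.30, abs=0.05)


def test_lr_report_self_consistency(small_sim):
    """Report values must equal direct recomputation from the EBV tables."""
    rng = np.random.default_rng(7)
    ids = sorted(small_sim["edited"]["cow_id"].unique())
    tables_w, tables_p = {}, {}
    for m in ("LM", "PLM"):
        tables_w[m] = pd.DataFrame({"animal_id": ids, "ebv": rng.normal(size=len(ids))})
        tables_p[m] = pd.DataFrame({"animal_id": ids, "ebv": rng.normal(size=len(ids))})
    vids = ids[: len(ids) // 3]
    report = d.lr_report(tables_w, tables_p, vids, F_bar=0.01,
                         sigma_a2={"LM": 100.0, "PLM": 120.0})
    w = tables_w["LM"].set_index("animal_id").loc[vids, "ebv"].to_numpy()
    p = tables_p["LM"].set_index("animal_id").loc[vids, "ebv"].to_numpy()
    assert report.bias["LM"] == pytest.approx(d.bias_lr(w, p))
    assert report.dispersion["LM"] == pytest.approx(d.dispersion_lr(w, p))
    assert np.isnan(report.acc["LM"]) or report.acc["LM"] == pytest.approx(
        d.acc_lr(w, p, 0.01, 100.0), nan_ok=True
    )
    assert (np.diag(report.spearman) == 1.0).all()
    assert (np.diag(report.overlap) == 100.0).all()
    # table shape: 3 statistic rows + one row per model
    table = report.to_table()
    assert len(table) == 3 + 2
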