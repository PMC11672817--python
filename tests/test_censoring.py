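"""Penalty imputation and the three censoring treatments (LM / PLM / PTM)."""

import numpy as np
import pandas as pd
import pytest

import daysopen as d

from .conftest import uncensor


def _group_records():
    """One HYS group with DO {100, 150} observed and one censored record."""
    return pd.DataFrame(
        {
            "cow_id": [1, 2, 3],
            "hys": ["1:2020:winter"] * 3,
            "do": [100.0, 150.0, 80.0],
            "censored": [False, False, True],
        }
    )


class TestImputePenalty:
    def test_group_max_plus_21(self):
        out = d.impute_penalty(_group_records())
        assert out.loc[out["censored"], "imputed_do"].item() == 171.0
        assert out.loc[out["censored"], "do_complete"].item() == 171.0
        assert out["cens01"].tolist() == [0, 0, 1]

    def test_no_censored_is_identity(self):
        df = _group_records()
        df["censored"] = False
        out = d.impute_penalty(df)
        assert out["imputed_do"].isna().all()
        np.testing.assert_array_equal(out["do_complete"], df["do"])

    def test_uncensored_rows_untouched(self):
        out = d.impute_penalty(_group_records())
        np.testing.assert_array_equal(
            out.loc[~out["censored"], "do_complete"],
            out.loc[~out["censored"], "do"],
        )

    def test_extreme_class_group_falls_back_to_global_max(self):
        df = _group_records()
        extra = pd.DataFrame(
            {
                "cow_id": [4, 5],
                "hys": ["2:2021:summer"] * 2,
                "do": [60.0, 55.0],
                "censored": [True, True],
            }
        )
        df = pd.concat([df, extra], ignore_index=True)
        df.loc[df["do"] == 100.0, "do"] = 300.0  # dataset-wide max uncensored
        with pytest.warns(UserWarning, match="extreme-class"):
            out = d.impute_penalty(df)
        assert (out.loc[out["hys"] == "2:2021:summer", "imputed_do"] == 321.0).all()

    def test_imputed_never_below_group_max(self, small_sim):
        out = d.impute_penalty(small_sim["edited"])
        cens = out["censored"].astype(bool)
        gmax = out.loc[~cens].groupby("hys")["do"].max()
        have = out.loc[cens & out["hys"].isin(gmax.index)]
        assert (have["imputed_do"].to_numpy()
                >= gmax.loc[have["hys"]].to_numpy()).all()

    def test_negative_penalty_rejected(self):
        with pytest.raises(d.CensoringError):
            d.impute_penalty(_group_records(), penalty=-1)

    def test_all_censored_everywhere_is_error(self):
        df = _group_records()
        df["censored"] = True
        with pytest.raises(d.CensoringError, match="no uncensored"):
            d.impute_penalty(df)


class TestFitVariants:
    def test_lm_equals_plm_without_censoring(self, tiny_sim, short_chain):
        rec = uncensor(tiny_sim["edited"])
        lm = d.fit_lm(rec, tiny_sim["ped"], short_chain)
        plm = d.fit_plm(rec, tiny_sim["ped"], short_chain)
        for name in lm.chain.draws:
            np.testing.assert_array_equal(lm.chain.draws[name], plm.chain.draws[name])
        np.testing.assert_array_equal(lm.ebv["ebv"], plm.ebv["ebv"])

    def test_plm_keeps_all_rows(self, tiny_sim, short_chain):
        plm = d.fit_plm(tiny_sim["edited"], tiny_sim["ped"], short_chain)
        assert plm.design.T.shape[0] == len(tiny_sim["edited"])

    def test_lm_drops_censored_rows(self, tiny_sim, short_chain):
        lm = d.fit_lm(tiny_sim["edited"], tiny_sim["ped"], short_chain)
        n_unc = (~tiny_sim["edited"]["censored"].astype(bool)).sum()
        assert lm.design.T.shape[0] == n_unc

    def test_lm_all_censored_is_error(self, tiny_sim, short_chain):
        rec = tiny_sim["edited"].copy()
        rec["censored"] = True
        with pytest.raises(d.CensoringError, match="no data"):
            d.fit_lm(rec, tiny_sim["ped"], short_chain)

    def test_ptm_needs_both_statuses(self, tiny_sim, short_chain):
        rec = uncensor(tiny_sim["edited"])
        with pytest.raises(d.CensoringError, match="degenerate"):
            d.fit_ptm(rec, tiny_sim["ped"], short_chain)

    def test_unknown_variant(self, tiny_sim, short_chain):
        with pytest.raises(d.CensoringError, match="unknown"):
            d.fit_model("XYZ", tiny_sim["edited"], tiny_sim["ped"], short_chain)

    def test_ptm_liability_signs_match_status(self, tiny_sim, short_chain):
        fit = d.fit_ptm(tiny_sim["edited"], tiny_sim["ped"], short_chain,
                        store_liabilities=True)
        assert fit.chain.extras["liability_sign_ok"].all()
        liab = fit.chain.extras["liabilities"]
        status = fit.extras["augmented"]["cens01"].to_numpy()
        assert ((liab > 0) == (status == 1)).all()

    def test_ptm_reports_bivariate_parameters(self, tiny_sim, short_chain):
        fit = d.fit_ptm(tiny_sim["edited"], tiny_sim["ped"], short_chain)
        for name in ("gen_corr", "res_cov", "sigma_u2_liab", "h2_liab"):
            assert name in fit.chain.draws
        assert (np.abs(fit.chain.draws["gen_corr"]) < 1).all()
        assert len(fit.extras["ebv_liability"]) == tiny_sim["ped"].n

    def test_plm_residual_variance_not_below_lm(self):
        """The penalty pushes imputed values into the upper tail, so PLM's
        residual variance should exceed LM's on average (direction only)."""
        diffs = []
        for seed in (31, 32):
            cfg = d.SimulationConfig(seed=seed)
            ped, rec, _ = d.simulate_dataset(cfg)
            edited, _ = d.edit_records(rec)
            cc = d.ChainConfig(n_iter=6000, burn_in=1500, thin=5, seed=seed)
            lm = d.fit_lm(edited, ped, cc)
            plm = d.fit_plm(edited, ped, cc)
            diffs.append(plm.vc_mean.sigma_e2 - lm.vc_mean.sigma_e2)
        assert np.mean(diffs) > 0

    def test_ptm_h2_agrees_with_plm_when_uncorrelated(self, short_chain):
        """With censoring independent of the trait's genetics, the DO-trait
        heritability from PTM should agree with PLM within MC error."""
        cfg = d.SimulationConfig(seed=55, n_founders=200, n_generations=3,
                                 censoring_mechanism="random")
        ped, rec, _ = d.simulate_dataset(cfg)
        edited, _ = d.edit_records(rec)
        plm = d.fit_plm(edited, ped, short_chain)
        ptm = d.fit_ptm(edited, ped, short_chain)
        sd = np.hypot(np.std(plm.chain.draws["h2"], ddof=1),
                      np.std(ptm.chain.draws["h2"], ddof=1))
        assert abs(ptm.h2_mean - plm.h2_mean) < 3 * sd


def test_ptm_recovers_positive_genetic_correlation():
    """Simulated genetic correlation of 0.5 between DO and the censorship
    liability: the posterior correlation should come out positive in most
    replicates."""
    positive = 0
    n_rep = 3
    for seed in range(n_rep):
        cfg = d.SimulationConfig(
            seed=200 + seed,
            censoring_mechanism="liability_correlated", liability_gen_corr=0.5,
            censoring_rate=0.25,
        )
        ped, rec, _ = d.simulate_dataset(cfg)
        edited, _ = d.edit_records(rec)
        cc = d.ChainConfig(n_iter=4000, burn_in=1000, thin=5, seed=seed)
        fit = d.fit_ptm(edited, ped, cc)
        positive += float(np.mean(fit.chain.draws["gen_corr"])) > 0
    assert positive >= n_rep - 1
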