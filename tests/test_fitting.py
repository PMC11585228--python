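"""Person-period construction, stabilized weights, Cox/logistic fits, bootstrap."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import msmsim as ms
from msmsim.fitting import Z975
from conftest import make_k1_config


def _tiny_batch(t_obs, event):
    """Hand-built two-individual batch for row-expansion tests."""
    n, K = len(t_obs), 9
    return ms.TrajectoryBatch(
        x=np.zeros((n, 2)), b=np.zeros((n, 2)),
        l=np.tile(np.arange(K + 1, dtype=float)[None, :, None], (n, 1, 2)),
        a=np.tile(np.arange(K + 1, dtype=float)[None, :], (n, 1)),
        y=np.ones((n, K + 1), dtype=np.int8),
        t_fail=np.where(np.asarray(event) == 1, np.asarray(t_obs), np.inf),
        n_visits=np.full(n, K + 1), K=K,
        x_names=("x1", "x2"), b_names=("b1", "b2"), l_names=("l1", "l2"),
        t_cens=np.full(n, np.inf), t_obs=np.asarray(t_obs, dtype=float),
        event=np.asarray(event, dtype=np.int8),
    )


class TestBuildPersonPeriod:
    def test_event_mid_interval(self):
        df = ms.build_person_period(_tiny_batch([2.4], [1]), observed_b=("b1",))
        assert df[["tstart", "tstop", "event"]].values.tolist() == [
            [0.0, 1.0, 0], [1.0, 2.0, 0], [2.0, 2.4, 1]
        ]
        assert df["k"].tolist() == [0, 1, 2]
        assert df["a"].tolist() == [0.0, 1.0, 2.0]
        assert df["a_lag"].tolist() == [0.0, 0.0, 1.0]

    def test_administrative_censoring_full_rows(self):
        df = ms.build_person_period(_tiny_batch([10.0], [0]), observed_b=("b1",))
        assert len(df) == 10
        assert df["event"].sum() == 0
        assert df["tstop"].iloc[-1] == 10.0

    def test_row_count_is_sum_of_ceilings(self, study_pp_high):
        msm, dgp, df = study_pp_high
        counts = df.groupby("id").size()
        tobs = df.groupby("id")["tstop"].max()
        assert (counts == np.ceil(tobs)).all()

    def test_requires_censoring_first(self, k1_config):
        msm, dgp = k1_config
        batch = ms.simulate_batch_exact(msm, dgp, 50, np.random.default_rng(0))
        with pytest.raises(ValueError, match="apply_censoring"):
            ms.build_person_period(batch)


class TestStabilizedWeights:
    def test_hand_fit_saturated_logistic(self):
        # one visit, binary x1 and l1 with an interaction: the fits are
        # saturated, predicted probabilities are cell frequencies, and the
        # weight is the x1-cell treatment share over the (x1, l1) share
        rows = []
        # (x1, l1) -> (count a=0, count a=1), all cells non-empty
        cells = {(0, 0): (4, 1), (0, 1): (2, 3), (1, 0): (3, 2), (1, 1): (1, 4)}
        i = 0
        for (x1, l1), (n0, n1) in cells.items():
            for a in [0] * n0 + [1] * n1:
                rows.append((i, 0, 0.0, 1.0, 0, float(x1), float(l1), float(a), 0.0))
                i += 1
        df = pd.DataFrame(
            rows, columns=["id", "k", "tstart", "tstop", "event", "x1", "l1", "a", "a_lag"]
        )
        df["x1l1"] = df["x1"] * df["l1"]
        sw = ms.stabilized_weights(
            df, denominator_cols=("x1", "l1", "x1l1"), numerator_cols=("x1",)
        )
        for (x1, l1), (n0, n1) in cells.items():
            other = cells[(x1, 1 - l1)]
            p_num = (n1 + other[1]) / (n0 + n1 + sum(other))
            p_den = n1 / (n0 + n1)
            sel = (df.x1 == x1) & (df.l1 == l1)
            np.testing.assert_allclose(
                sw[sel & (df.a == 1)], p_num / p_den, rtol=1e-4
            )
            np.testing.assert_allclose(
                sw[sel & (df.a == 0)], (1 - p_num) / (1 - p_den), rtol=1e-4
            )

    def test_weights_near_one_when_numerator_equals_denominator_model(self):
        # treatment depending only on (X, A_lag): the extra denominator
        # covariates have true coefficient zero, so weights converge to 1
        msm, dgp = ms.study_config("low", "low", m=200)

        def a_only_x(rng, k, x, b, l, a_prev):
            from scipy.special import expit
            ap = 0.0 if a_prev is None else a_prev
            p = expit(-1 + 0.3 * x[:, 0] + ap)
            return (rng.random(x.shape[0]) < p).astype(float)

        dgp.sample_a = a_only_x
        rng = np.random.default_rng(30)
        batch = ms.apply_censoring(
            ms.simulate_batch_extended(msm, dgp, 4000, rng), dgp, rng
        )
        df = ms.build_person_period(batch, observed_b=dgp.observed_b)
        sw = ms.stabilized_weights(df)
        assert abs(np.mean(sw) - 1) < 0.02
        assert np.std(sw) < 0.12

    def test_mean_weight_near_one_per_visit_low_confounding(self):
        # correctly specified stabilized weights average to one at every visit
        # (survivor selection is negligible under weak confounding)
        msm, dgp = ms.study_config("low", "low", m=300)
        rng = np.random.default_rng(40)
        batch = ms.apply_censoring(
            ms.simulate_batch_extended(msm, dgp, 3000, rng), dgp, rng
        )
        df = ms.build_person_period(batch, observed_b=dgp.observed_b)
        means = pd.Series(ms.stabilized_weights(df)).groupby(df["k"].values).mean()
        assert ((means > 0.9) & (means < 1.1)).all()

    def test_estimated_weights_track_true_denominator_weights(self, study_pp_high):
        # oracle check: plug the known treatment-model probabilities into the
        # denominator and compare with the fully estimated weights
        from scipy.special import expit

        msm, dgp, df = study_pp_high
        sw = ms.stabilized_weights(df)
        delta = np.asarray(dgp.manifest["delta"])
        p_den = expit(-1 + delta[0] * df.x1 + delta[1] * df.x2 + delta[2] * df.b1
                      + delta[3] * df.l1 + delta[4] * df.l2 + df.a_lag)
        lik_den = np.where(df.a == 1, p_den, 1 - p_den)
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=np.inf, max_iter=1000).fit(
            df[["x1", "x2", "a_lag"]], df.a
        )
        p_num = clf.predict_proba(df[["x1", "x2", "a_lag"]])[:, 1]
        lik_num = np.where(df.a == 1, p_num, 1 - p_num)
        logr = np.log(lik_num / lik_den)
        ids = df["id"].to_numpy()
        cs = np.cumsum(logr)
        starts = np.r_[0, np.flatnonzero(np.diff(ids) != 0) + 1]
        counts = np.diff(np.r_[starts, len(ids)])
        offset = np.repeat(np.r_[0.0, cs[starts[1:] - 1]], counts)
        sw_true = np.exp(cs - offset)
        assert np.corrcoef(sw, sw_true)[0, 1] > 0.98
        assert np.abs(sw - sw_true).mean() < 0.1

    def test_cumulative_product_structure(self, study_pp_high):
        msm, dgp, df = study_pp_high
        sw = ms.stabilized_weights(df)
        first_rows = np.flatnonzero(~df["id"].duplicated().values)
        # visit-0 weights are a single probability ratio: positive, bounded
        assert np.all(sw > 0)
        assert np.all(sw[first_rows] < 50)

    def test_requires_binary_treatment(self, study_pp_high):
        _, _, df = study_pp_high
        bad = df.copy()
        bad.loc[bad.index[0], "a"] = 0.5
        with pytest.raises(ValueError, match="binary"):
            ms.stabilized_weights(bad)


class TestFitCoxMsm:
    def test_all_weights_one_equals_unweighted(self, study_pp_high):
        msm, dgp, df = study_pp_high
        f0 = ms.fit_cox_msm(df, msm.design_fn, variance="model")
        f1 = ms.fit_cox_msm(df, msm.design_fn, weights=np.ones(len(df)), variance="model")
        np.testing.assert_allclose(f0.params.values, f1.params.values, rtol=1e-8)

    def test_matches_lifelines_unweighted(self, study_pp_high):
        msm, dgp, df = study_pp_high
        mine = ms.fit_cox_msm(df, msm.design_fn, variance="model")
        from lifelines import CoxTimeVaryingFitter

        ldf = df[["id", "tstart", "tstop", "event"]].join(msm.design_fn(df))
        ctv = CoxTimeVaryingFitter()
        ctv.fit(ldf, id_col="id", event_col="event", start_col="tstart",
                stop_col="tstop", formula="x1+x2+a+x1_a+x2_a")
        np.testing.assert_allclose(mine.params.values, ctv.params_.values, atol=1e-6)
        np.testing.assert_allclose(mine.se.values, ctv.standard_errors_.values, atol=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_weighted_sandwich_matches_R_survival(self, study_pp_high, tmp_path):
        # independent oracle for the clustered simple-sandwich variance
        msm, dgp, df = study_pp_high
        sub = df[df["id"] < 300].copy()
        sub["sw"] = ms.stabilized_weights(df)[: len(sub)]
        mine = ms.fit_cox_msm(sub, msm.design_fn, weights="sw", variance="sandwich")
        csv = tmp_path / "pp.csv"
        pd.concat([sub, msm.design_fn(sub)[["x1_a", "x2_a"]]], axis=1).to_csv(csv, index=False)
        script = (
            f'd <- read.csv("{csv}"); library(survival); '
            "f <- coxph(Surv(tstart,tstop,event)~x1+x2+a+x1_a+x2_a+cluster(id),"
            ' data=d, weights=sw, ties="breslow"); '
            'cat(coef(f), sqrt(diag(f$var)), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(mine.params.values, vals[:5], atol=1e-6)
        np.testing.assert_allclose(mine.se.values, vals[5:], atol=1e-6)

    def test_recovers_truth_without_confounding(self):
        # randomized treatment (delta = 0) makes the naive fit consistent
        msm, dgp = ms.study_config("low", "high", m=500)

        def randomized(rng, k, x, b, l, a_prev):
            from scipy.special import expit
            ap = 0.0 if a_prev is None else a_prev
            return (rng.random(x.shape[0]) < expit(-1 + ap)).astype(float)

        dgp.sample_a = randomized
        rng = np.random.default_rng(31)
        batch = ms.apply_censoring(
            ms.simulate_batch_extended(msm, dgp, 12_000, rng), dgp, rng
        )
        df = ms.build_person_period(batch, observed_b=dgp.observed_b)
        fit = ms.fit_cox_msm(df, msm.design_fn, variance="model")
        for est, se, truth in zip(fit.params, fit.se, msm.beta):
            assert abs(est - truth) < 3 * se

    def test_invariant_to_row_order_and_id_labels(self, study_pp_high):
        msm, dgp, df = study_pp_high
        base = ms.fit_cox_msm(df, msm.design_fn, variance="model")
        shuffled = df.sample(frac=1.0, random_state=1).copy()
        shuffled["id"] = shuffled["id"] + 10_000
        other = ms.fit_cox_msm(shuffled, msm.design_fn, variance="model")
        np.testing.assert_allclose(base.params.values, other.params.values, atol=1e-8)

    def test_ci_width_decreases_with_n(self):
        msm, dgp = ms.study_config("low", "low", m=200)
        widths = []
        for n in (250, 1000):
            rng = np.random.default_rng(np.random.SeedSequence([32, n]))
            batch = ms.apply_censoring(
                ms.simulate_batch_extended(msm, dgp, n, rng), dgp, rng
            )
            df = ms.build_person_period(batch, observed_b=dgp.observed_b)
            fit = ms.fit_cox_msm(df, msm.design_fn, variance="model")
            widths.append(float((fit.ci_upper - fit.ci_lower).mean()))
        assert widths[1] < widths[0]

    def test_sandwich_diagonal_nonnegative(self, study_pp_high):
        msm, dgp, df = study_pp_high
        sw = ms.stabilized_weights(df)
        fit = ms.fit_cox_msm(df, msm.design_fn, weights=sw, variance="sandwich")
        assert (np.diag(fit.vcov.values) >= 0).all()
        assert np.allclose(
            fit.ci_upper.values - fit.params.values, Z975 * fit.se.values
        )


class TestFitDiscreteMsm:
    def test_recovers_logistic_msm_without_confounding(self):
        msm, dgp = make_k1_config(rho=0.0)  # rho=0: outcome ⊥ history given (X, Ā)
        batch = ms.simulate_batch_exact(msm, dgp, 40_000, np.random.default_rng(33))
        batch = ms.apply_censoring(batch, dgp, np.random.default_rng(34))
        df = ms.build_person_period(batch)
        fit = ms.fit_discrete_msm(df, ["x1", "a"])
        truth = {"const": -2.0, "x1": 0.8, "a": -0.7}
        for name, val in truth.items():
            assert abs(fit.params[name] - val) < 3 * fit.se[name]

    def test_weights_one_equals_unweighted(self):
        msm, dgp = make_k1_config(rho=0.0)
        batch = ms.simulate_batch_exact(msm, dgp, 3000, np.random.default_rng(35))
        batch = ms.apply_censoring(batch, dgp, np.random.default_rng(36))
        df = ms.build_person_period(batch)
        f0 = ms.fit_discrete_msm(df, ["x1", "a"])
        f1 = ms.fit_discrete_msm(df, ["x1", "a"], weights=np.ones(len(df)))
        np.testing.assert_allclose(f0.params.values, f1.params.values, rtol=1e-6)

    def test_no_events_raises(self):
        df = pd.DataFrame(
            {"id": [0, 1], "event": [0, 0], "x1": [0.0, 1.0], "a": [0.0, 1.0]}
        )
        with pytest.raises(ValueError, match="no events"):
            ms.fit_discrete_msm(df, ["x1", "a"])


class TestBootstrapCI:
    def test_contains_point_estimate_and_is_deterministic(self, study_pp_high):
        msm, dgp, df = study_pp_high
        sub = df[df["id"] < 400]
        f1 = ms.bootstrap_ci(sub, msm.design_fn, n_boot=40, rng=np.random.default_rng(37))
        f2 = ms.bootstrap_ci(sub, msm.design_fn, n_boot=40, rng=np.random.default_rng(37))
        assert np.all(f1.ci_lower.values <= f1.params.values)
        assert np.all(f1.params.values <= f1.ci_upper.values)
        np.testing.assert_allclose(f1.ci_lower.values, f2.ci_lower.values)

    def test_rejects_tiny_n_boot(self, study_pp_high):
        msm, dgp, df = study_pp_high
        with pytest.raises(ValueError):
            ms.bootstrap_ci(df, msm.design_fn, n_boot=1, rng=np.random.default_rng(38))
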