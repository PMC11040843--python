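"""Reliability, repeated-measures correlation, mixed models, composite bins."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fatiguebci import SimulationConfig, gen_cohort
from fatiguebci.stats import (
    assign_age_groups,
    composite_bins,
    fit_lmm,
    holm_adjust,
    mdc_from_sem,
    rmcorr,
    sem_from_pairs,
)
from fatiguebci.study import records_to_long


class TestReliability:
    def test_constant_differences_give_zero_sem(self):
        r = sem_from_pairs([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert r.sem == 0.0 and r.mdc95 == 0.0

    def test_sd_sqrt2_differences_give_unit_sem(self, rng):
        d = rng.normal(0, 1, size=5000) * np.sqrt(2)
        d = (d - d.mean()) / d.std(ddof=1) * np.sqrt(2)  # exact SD sqrt(2)
        r = sem_from_pairs(d, np.zeros_like(d))
        assert r.sem == pytest.approx(1.0, abs=1e-9)

    def test_mdc_arithmetic(self):
        """MDC95 = 1.96·√2·SEM: SEM 5.0 maps to ≈13.86."""
        assert mdc_from_sem(5.0) == pytest.approx(13.859, abs=0.01)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            sem_from_pairs([1, 2], [1, 2, 3])

    def test_units_scale_linearly(self, rng):
        a = rng.normal(5, 2, 30)
        b = rng.normal(5, 2, 30)
        r1 = sem_from_pairs(a, b)
        rk = sem_from_pairs(10 * a, 10 * b)
        assert rk.sem == pytest.approx(10 * r1.sem)
        assert rk.mdc95 == pytest.approx(10 * r1.mdc95)


def _ancova_rmcorr_oracle(df, x, y, participant="participant"):
    """Independent sums-of-squares oracle: full dummy-coded ANCOVA by lstsq."""
    parts = sorted(df[participant].unique())
    D = np.column_stack([(df[participant] == p).to_numpy(float) for p in parts])
    X_full = np.column_stack([D, df[x].to_numpy()])
    beta, *_ = np.linalg.lstsq(X_full, df[y].to_numpy(), rcond=None)
    resid_full = df[y].to_numpy() - X_full @ beta
    beta0, *_ = np.linalg.lstsq(D, df[y].to_numpy(), rcond=None)
    resid_red = df[y].to_numpy() - D @ beta0
    ss_err = resid_full @ resid_full
    ss_reg = resid_red @ resid_red - ss_err
    r = np.sqrt(ss_reg / (ss_reg + ss_err))
    return np.sign(beta[-1]) * r


class TestRmcorr:
    @staticmethod
    def _data(rng, n_part=12, n_obs=5, slope=0.7, noise=1.0):
        rows = []
        for p in range(n_part):
            offset = rng.normal(0, 5)
            x = rng.normal(0, 2, n_obs)
            y = slope * x + offset + rng.normal(0, noise, n_obs)
            for xi, yi in zip(x, y):
                rows.append({"participant": f"p{p}", "x": xi, "y": yi})
        return pd.DataFrame(rows)

    def test_perfect_common_slope_gives_r_one(self, rng):
        df = self._data(rng, noise=0.0)
        res = rmcorr(df, "x", "y")
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_matches_ancova_oracle(self, rng):
        df = self._data(rng)
        res = rmcorr(df, "x", "y")
        assert res.r == pytest.approx(_ancova_rmcorr_oracle(df, "x", "y"), abs=1e-8)

    def test_matches_pingouin(self, rng):
        """Cross-check against pingouin's independent implementation."""
        pg = pytest.importorskip("pingouin")
        df = self._data(rng)
        res = rmcorr(df, "x", "y")
        ref = pg.rm_corr(data=df, x="x", y="y", subject="participant")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert res.dof == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_independent_data_near_zero(self, rng):
        df = self._data(rng, n_part=30, n_obs=10, slope=0.0, noise=3.0)
        res = rmcorr(df, "x", "y")
        assert abs(res.r) < 0.15

    def test_invariant_to_participant_offsets(self, rng):
        df = self._data(rng)
        res = rmcorr(df, "x", "y")
        shifted = df.copy()
        offsets = {p: i * 13.0 for i, p in enumerate(shifted["participant"].unique())}
        shifted["y"] = shifted["y"] + shifted["participant"].map(offsets)
        res2 = rmcorr(shifted, "x", "y")
        assert res2.r == pytest.approx(res.r, abs=1e-10)

    def test_dof_formula(self, rng):
        df = self._data(rng, n_part=10, n_obs=4)
        assert rmcorr(df, "x", "y").dof == 40 - 10 - 1

    def test_sparse_participants_dropped_with_warning(self, rng, caplog):
        df = self._data(rng, n_part=5, n_obs=3)
        extra = pd.DataFrame([{"participant": "lonely", "x": 1.0, "y": 2.0}])
        with caplog.at_level("WARNING"):
            res = rmcorr(pd.concat([df, extra]), "x", "y")
        assert res.n_participants == 5
        assert "lonely" in caplog.text

    def test_all_dropped_rejected(self):
        df = pd.DataFrame({"participant": ["a", "b"], "x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError):
            rmcorr(df, "x", "y")


class TestFitLmm:
    def test_time_effect_parameter_recovery(self):
        """A simulated 1.2-point pre/post shift is recovered by the REML fit."""
        # low noise keeps the 0-10 scale truncation from biasing the shift
        cfg = SimulationConfig(seed=31, n_participants=200, pre_post_shift=1.2,
                               vasf_between_sd=0.8, vasf_resid_sd=0.4)
        long = records_to_long(gen_cohort(cfg))
        res = fit_lmm(long, "vasf", ("session", "time"), interaction=False)
        assert res.coef("[T.post]") == pytest.approx(1.2, abs=0.1)

    def test_balanced_two_level_matches_paired_anova_oracle(self, rng):
        """With one two-level factor and balanced data, the mixed-model F for
        the factor equals the paired-samples F (t²)."""
        from scipy import stats as spstats

        n = 40
        pre = rng.normal(5, 1.5, n)
        post = pre + 1.0 + rng.normal(0, 1.0, n)
        rows = []
        for i in range(n):
            rows.append({"participant": f"p{i}", "time": "pre", "y": pre[i]})
            rows.append({"participant": f"p{i}", "time": "post", "y": post[i]})
        df = pd.DataFrame(rows)
        res = fit_lmm(df, "y", ("time",))
        t, _ = spstats.ttest_rel(post, pre)
        assert res.term_f("time") == pytest.approx(t**2, rel=0.02)

    def test_emm_equals_cell_means_on_balanced_data(self, rng):
        cfg = SimulationConfig(seed=32, n_participants=60)
        long = records_to_long(gen_cohort(cfg))
        res = fit_lmm(long, "vasf", ("session", "time"))
        for (session, time), cell in res.emm.items():
            observed = long.query("session == @session and time == @time")["vasf"].mean()
            assert cell["mean"] == pytest.approx(observed, abs=0.02)
            assert cell["ci_low"] <= cell["mean"] <= cell["ci_high"]

    def test_posthoc_holm_dominates_raw(self):
        cfg = SimulationConfig(seed=33, n_participants=40)
        long = records_to_long(gen_cohort(cfg))
        res = fit_lmm(long, "vasf", ("session", "time"))
        assert len(res.posthoc) == 15  # C(6,2) cell pairs
        assert (res.posthoc["p_holm"] >= res.posthoc["p_raw"] - 1e-12).all()

    def test_aic_reported_finite(self):
        cfg = SimulationConfig(seed=34, n_participants=30)
        long = records_to_long(gen_cohort(cfg))
        res = fit_lmm(long, "vasf", ("session", "time"))
        assert np.isfinite(res.aic)


class TestHolm:
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_dominate_raw_and_monotone(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCompositeBins:
    @staticmethod
    def _df(**over):
        base = {"motivation_total": 30.0, "workload_total": 50.0, "pain": 1}
        base.update(over)
        return pd.DataFrame([base])

    @pytest.mark.parametrize("value,group", [(29.3, "lower"), (41.0, "higher"),
                                             (35.9, "lower"), (36.0, "higher")])
    def test_motivation_split(self, value, group):
        out = composite_bins(self._df(motivation_total=value))
        assert out["motivation_group"].iloc[0] == group

    @pytest.mark.parametrize("value,label", [(0.0, "0-24"), (41.4, "25-49"),
                                             (50.0, "50-74"), (100.0, "75-100")])
    def test_workload_quartile_bins(self, value, label):
        out = composite_bins(self._df(workload_total=value))
        assert out["workload_group"].iloc[0] == label

    @pytest.mark.parametrize("value,group", [(0, "low/no"), (2, "low/no"),
                                             (3, "higher"), (5, "higher")])
    def test_pain_split(self, value, group):
        out = composite_bins(self._df(pain=value))
        assert out["pain_group"].iloc[0] == group

    def test_out_of_range_names_field(self):
        with pytest.raises(ValueError, match="workload_total"):
            composite_bins(self._df(workload_total=130.0))

    def test_age_median_split(self):
        df = pd.DataFrame({
            "participant": ["a", "a", "b", "c", "d"],
            "age": [7.0, 7.0, 9.0, 12.0, 15.0],
        })
        out = assign_age_groups(df)
        groups = out.drop_duplicates("participant").set_index("participant")["age_group"]
        assert groups["a"] == "younger" and groups["d"] == "older"
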