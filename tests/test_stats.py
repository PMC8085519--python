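"""Standardised regressions, Tukey contrasts and report summaries."""

import numpy as np
import pandas as pd
import pytest

from cannuskill.stats import (
    PROCESS_METRICS,
    RegressionResult,
    SkillAssociationModel,
    fit_indicator_regressions,
    indicators_from_meta,
    summarize,
    transform_standardize,
    tukey_pairwise,
)
from cannuskill.io import GRS_CATEGORIES, TrialMeta


def _metrics_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "T_s": rng.uniform(2, 12, n),
            "PL_mm": rng.uniform(20, 200, n),
            "Pks": rng.integers(0, 15, n),
            "LDLJ": rng.uniform(-20, -7, n),
            "SPARC": rng.uniform(-8, -1.2, n),
        }
    )


class TestTransformStandardize:
    def test_columns_are_zero_mean_unit_sd(self):
        out = transform_standardize(_metrics_frame())
        assert np.allclose(out.mean(), 0, atol=1e-10)
        assert np.allclose(out.std(ddof=1), 1, atol=1e-10)

    def test_ldlj_passes_through_as_pure_zscore(self):
        frame = _metrics_frame()
        out = transform_standardize(frame)
        raw = frame["LDLJ"].to_numpy()
        expected = (raw - raw.mean()) / raw.std(ddof=1)
        np.testing.assert_allclose(out["LDLJ"], expected, atol=1e-12)

    def test_scaling_pl_changes_nothing(self):
        frame = _metrics_frame()
        out1 = transform_standardize(frame)
        frame2 = frame.assign(PL_mm=frame["PL_mm"] * 2.0)
        out2 = transform_standardize(frame2)
        np.testing.assert_allclose(out1["PL"], out2["PL"], atol=1e-12)

    def test_zero_variance_column_named_in_error(self):
        frame = _metrics_frame().assign(T_s=5.0)
        with pytest.raises(ValueError, match="T"):
            transform_standardize(frame)

    def test_nonnegative_sparc_rejected(self):
        frame = _metrics_frame()
        frame.loc[0, "SPARC"] = 0.5
        with pytest.raises(ValueError):
            transform_standardize(frame)


class TestRegressions:
    def _tables(self, n=40, seed=1):
        rng = np.random.default_rng(seed)
        predictors = pd.DataFrame(
            {m: rng.standard_normal(n) for m in PROCESS_METRICS}
        )
        predictors = (predictors - predictors.mean()) / predictors.std(ddof=1)
        indicators = pd.DataFrame(
            {
                "FR": rng.uniform(0, 1, n),
                "GRS": rng.integers(16, 29, n).astype(float),
                "Exp": rng.uniform(0, 38, n),
            }
        )
        return indicators, predictors

    def test_agrees_with_closed_form_ols_oracle(self):
        for seed in (1, 2, 3):
            indicators, predictors = self._tables(seed=seed)
            results = fit_indicator_regressions(indicators, predictors, 5)
            for res in results:
                x = predictors[res.metric].to_numpy()
                y = indicators[res.indicator].to_numpy()
                n = len(x)
                sxx = ((x - x.mean()) ** 2).sum()
                slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
                resid = y - y.mean() - slope * (x - x.mean())
                se = np.sqrt(resid @ resid / (n - 2) / sxx)
                r = np.corrcoef(x, y)[0, 1]
                assert res.slope == pytest.approx(slope, abs=1e-10)
                assert res.se == pytest.approx(se, abs=1e-10)
                assert res.r2 == pytest.approx(r**2, abs=1e-10)
                # slope on a standardised predictor equals r·SD(indicator)
                assert res.slope == pytest.approx(r * y.std(ddof=1), abs=1e-10)
                assert res.r2 == pytest.approx(res.r**2, abs=1e-10)

    def test_perfect_linear_indicator(self):
        _, predictors = self._tables()
        indicators = pd.DataFrame(
            {"FR": 3.0 * predictors["LDLJ"] + 1.0,
             "GRS": np.random.default_rng(0).normal(size=len(predictors)),
             "Exp": np.random.default_rng(1).normal(size=len(predictors))}
        )
        results = fit_indicator_regressions(indicators, predictors, 5)
        res = next(r for r in results if (r.indicator, r.metric) == ("FR", "LDLJ"))
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.se <= 1e-8

    def test_too_few_observations(self):
        indicators, predictors = self._tables(n=2)
        with pytest.raises(ValueError):
            fit_indicator_regressions(indicators.iloc[:2], predictors.iloc[:2], 5)


def _fake_results(slopes, se=0.05, n=779, indicator="FR", spans=None):
    out = []
    for i, b in enumerate(slopes):
        out.append(
            RegressionResult(
                indicator=indicator,
                metric=PROCESS_METRICS[i % 5],
                window_span=spans[i] if spans else 5,
                slope=b, se=se, r2=0.1, r=0.3, n=n, resid_var=se**2 * (n - 1),
            )
        )
    return out


class TestTukey:
    def test_identical_groups_not_significant(self):
        cmps = tukey_pairwise(_fake_results([0.2, 0.2]))
        assert cmps[0].estimate == 0.0
        assert not cmps[0].significant
        assert cmps[0].lower < 0 < cmps[0].upper

    def test_five_groups_give_ten_comparisons(self):
        cmps = tukey_pairwise(_fake_results([0.1, 0.2, 0.3, 0.4, 0.5]))
        assert len(cmps) == 10

    def test_mismatched_n_rejected(self):
        results = _fake_results([0.1, 0.2])
        results[1].n = 500
        with pytest.raises(ValueError, match="balanced"):
            tukey_pairwise(results)

    def test_ci_width_shrinks_like_root_n(self):
        widths = {}
        for n in (100, 400, 1600):
            se = 1.0 / np.sqrt(n - 1)
            cmps = tukey_pairwise(_fake_results([0.0] * 5, se=se, n=n))
            widths[n] = cmps[0].half_width
        assert widths[100] / widths[400] == pytest.approx(2.0, rel=0.1)
        assert widths[400] / widths[1600] == pytest.approx(2.0, rel=0.1)


class TestSummaries:
    def _results_grid(self):
        out = []
        rng = np.random.default_rng(0)
        for ind in ("FR", "GRS", "Exp"):
            for span in (5, 25, 51, 101, 201):
                for met in PROCESS_METRICS:
                    out.append(
                        RegressionResult(ind, met, span, 0.1, 0.01,
                                         float(rng.uniform(0, 0.4)), 0.2, 779, 1.0)
                    )
        return out

    def test_r2_table_shape_and_mean_consistency(self):
        tables = summarize(self._results_grid())
        assert tables["r2_by_span"].shape == (3, 5)
        recomputed = tables["r2_by_span"].mean(axis=1)
        assert np.allclose(recomputed, tables["r2_mean"], atol=1e-12)


def test_model_fits_end_to_end(small_cohort):
    from cannuskill import compute_all, segment_task
    from cannuskill.io import write_metrics_table, read_metrics_table
    import tempfile, os

    rows = []
    for series, meta in small_cohort.trials:
        seg = segment_task(series, meta)
        rows.extend(compute_all(seg, meta, spans=(5, 25)))
    with tempfile.TemporaryDirectory() as tmp:
        path = os.path.join(tmp, "m.csv")
        write_metrics_table(rows, path)
        metrics = read_metrics_table(path)
    indicators = indicators_from_meta(meta for _, meta in small_cohort.trials)
    res = SkillAssociationModel(metrics, indicators).fit()
    assert set(res.r2_mean.index) == {"FR", "GRS", "Exp"}
    assert ((res.regressions["r2"] >= 0) & (res.regressions["r2"] <= 1)).all()
    # both Tukey families produce full tables with finite intervals
    tables = res.tukey_tables()
    assert len(tables["metric_contrasts"]) == 3 * 2 * 10
    assert np.isfinite(tables["metric_contrasts"]["estimate"]).all()
    assert (tables["span_contrasts"]["pair"] == "5-25").all()
    text = res.summary()
    assert "Mean R^2" in text


def test_indicator_table_from_meta_sums_four_subscores():
    meta = TrialMeta(
        participant_id="P9", trial_id="T1", fistula_id=1, skin_z=0.0, fs=100.0,
        years_experience=12.0,
        grs={"palpation": 7, "needle_holding": 4, "needle_movement": 5,
             "flashback_quality": 6, "overall_quality": 3},
    )
    table = indicators_from_meta([meta])
    assert table.loc["P9", "GRS"] == 4 + 5 + 6 + 3  # palpation excluded
    assert table.loc["P9", "Exp"] == 12.0
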