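"""Skill-association statistics: standardised regressions and Tukey contrasts.

The scientific question: which skill indicator — the objective outcome
metric FR, the observer rating GRS, or years of experience — do the
process metrics account for best, and does the degree of smoothing (SG
window span) change a metric's association with skill?

The analysis, per window span:

1. transform each process metric so larger = better and the skew is tamed:
   natural log for T, PL, Pks and |SPARC|, pass-through for LDLJ (already a
   log), sign flips for T, PL, Pks; then z-score each predictor;
2. simple OLS of each indicator on each standardised predictor, one model
   per (indicator, metric, span), pooling all trials with participant-level
   indicators broadcast to their trials;
3. pairwise contrasts of the standardised slopes with Tukey's
   multiple-comparison adjustment (studentized-range critical value
   ``q_{α; r, n−r}``), in two families: metrics compared within an
   indicator × span, and spans compared within an indicator × smoothness
   metric.

The broadcast of participant-level indicators over trials repeats the
emulated study's design (n = all viable trials); the resulting independence
violation is documented, not corrected.

Exposed both as plain functions and as a model/results pair:
:class:`SkillAssociationModel` holds the data and options, ``fit()`` returns
a :class:`SkillAssociationResults` carrying the regression table, R²
summaries, correlation grid, Tukey contrast tables and a text ``summary()``.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range

__all__ = [
    "RegressionResult",
    "TukeyComparison",
    "PROCESS_METRICS",
    "INDICATORS",
    "DEFAULT_GRS_SUBSCORES",
    "transform_standardize",
    "fit_indicator_regressions",
    "tukey_pairwise",
    "summarize",
    "indicators_from_meta",
    "SkillAssociationModel",
    "SkillAssociationResults",
]

PROCESS_METRICS = ("T", "PL", "Pks", "LDLJ", "SPARC")
INDICATORS = ("FR", "GRS", "Exp")

#: Subscores summed into the GRS indicator; palpation is excluded by default
#: because it does not reflect needle motion.
DEFAULT_GRS_SUBSCORES = (
    "needle_holding",
    "needle_movement",
    "flashback_quality",
    "overall_quality",
)

_RAW_COLUMN = {"T": "T_s", "PL": "PL_mm", "Pks": "Pks", "LDLJ": "LDLJ", "SPARC": "SPARC"}


@dataclasses.dataclass
class RegressionResult:
    """One simple OLS fit of a skill indicator on a standardised metric."""

    indicator: str
    metric: str
    window_span: int
    slope: float
    se: float
    r2: float
    r: float
    n: int
    resid_var: float  # σ̂²_ε = SSR / (n − 2)

    @property
    def group(self) -> str:
        return self.metric


@dataclasses.dataclass
class TukeyComparison:
    """One pairwise slope contrast with a Tukey-adjusted confidence interval."""

    group_i: str
    group_j: str
    estimate: float
    half_width: float
    alpha: float
    q_crit: float
    n: int
    r: int

    @property
    def lower(self) -> float:
        return self.estimate - self.half_width

    @property
    def upper(self) -> float:
        return self.estimate + self.half_width

    @property
    def significant(self) -> bool:
        return not (self.lower <= 0.0 <= self.upper)


# ---------------------------------------------------------------------------
# transforms


def transform_standardize(
    metrics: pd.DataFrame,
    pks_offset: float = 1.0,
    log_sparc: bool = True,
) -> pd.DataFrame:
    """Transform and z-score process-metric columns into predictors.

    T, PL and Pks are log-transformed and negated (smaller raw value =
    better performance, so the standardised predictor points the same way
    for every metric: larger = smoother/better).  LDLJ is already on a log
    scale and passes through.  SPARC is negative; ``−log(−SPARC)`` is
    monotone increasing in SPARC and is used by default (``log_sparc=False``
    passes SPARC through untransformed).  ``Pks`` may be 0, where the log is
    undefined; ``log(Pks + pks_offset)`` with offset 1 is the documented
    default.  Each predictor is then standardised to zero mean, unit
    (sample) variance.

    Raises
    ------
    ValueError
        On non-positive T/PL, non-negative SPARC, or a zero-variance column
        (named in the message).
    """
    if len(metrics) == 0:
        raise ValueError("empty metrics table")
    cols = {}
    T = metrics[_RAW_COLUMN["T"]].to_numpy(dtype=float)
    PL = metrics[_RAW_COLUMN["PL"]].to_numpy(dtype=float)
    Pks = metrics[_RAW_COLUMN["Pks"]].to_numpy(dtype=float)
    LDLJ = metrics[_RAW_COLUMN["LDLJ"]].to_numpy(dtype=float)
    SPARC = metrics[_RAW_COLUMN["SPARC"]].to_numpy(dtype=float)
    if not (T > 0).all():
        raise ValueError("T must be positive for the log transform")
    if not (PL > 0).all():
        raise ValueError("PL must be positive for the log transform")
    if (Pks < 0).any():
        raise ValueError("Pks must be nonnegative")
    if not (SPARC < 0).all():
        raise ValueError("SPARC must be negative")
    cols["T"] = -np.log(T)
    cols["PL"] = -np.log(PL)
    cols["Pks"] = -np.log(Pks + pks_offset)
    cols["LDLJ"] = LDLJ
    cols["SPARC"] = -np.log(-SPARC) if log_sparc else SPARC
    out = {}
    for name, values in cols.items():
        sd = values.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"predictor column {name!r} has zero variance")
        out[name] = (values - values.mean()) / sd
    return pd.DataFrame(out, index=metrics.index)


# ---------------------------------------------------------------------------
# regressions


def fit_indicator_regressions(
    indicators: pd.DataFrame,
    predictors: pd.DataFrame,
    window_span: int,
    indicator_names: Sequence[str] = INDICATORS,
    metric_names: Sequence[str] = PROCESS_METRICS,
) -> list[RegressionResult]:
    """One simple OLS per (indicator, metric) on aligned trial rows.

    ``indicators`` and ``predictors`` must share an index (one row per
    trial, participant-level indicators already broadcast).
    """
    if len(indicators) != len(predictors):
        raise ValueError("indicator and predictor tables must align row-wise")
    n = len(predictors)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    results = []
    for ind in indicator_names:
        y = indicators[ind].to_numpy(dtype=float)
        for met in metric_names:
            x = predictors[met].to_numpy(dtype=float)
            fit = sm.OLS(y, sm.add_constant(x)).fit()
            slope = float(fit.params[1])
            resid_var = float(fit.ssr / (n - 2))
            sy = y.std(ddof=1)
            r = slope / sy if sy > 0 else np.nan  # β₁ = r·SD(y) for z-scored x
            results.append(
                RegressionResult(
                    indicator=ind,
                    metric=met,
                    window_span=int(window_span),
                    slope=slope,
                    se=float(fit.bse[1]),
                    r2=float(fit.rsquared),
                    r=float(r),
                    n=n,
                    resid_var=resid_var,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Tukey pairwise contrasts


@functools.lru_cache(maxsize=128)
def _q_crit(alpha: float, r: int, df: int) -> float:
    """Studentized-range quantile q_{alpha; r, df} (cached: ppf is costly)."""
    return float(studentized_range.ppf(1.0 - alpha, r, df))


def tukey_pairwise(
    results: Sequence[RegressionResult],
    alpha: float = 0.05,
    variance: str = "pooled",
    labels: Sequence[str] | None = None,
) -> list[TukeyComparison]:
    """All pairwise slope contrasts with a Tukey-adjusted CI.

    The r slopes being compared (one per group: per metric, or per window
    span) come from regressions on the same n observations.  The critical
    value is the studentized-range quantile ``q_{α; r, n−r}``; each CI is

        (β̂ᵢ − β̂ⱼ) ± q·SE,

    where SE is the pooled slope standard error
    ``sqrt(mean(SE₁², …, SE_r²))`` (``variance="pooled"``, the default: the
    residual variance is pooled across the r compared regressions) or the
    pair-specific ``sqrt((SEᵢ² + SEⱼ²)/2)`` (``variance="per_pair"``).  The
    two coincide for a balanced design with equal residual variances; the
    construction reduces to the classic Tukey HSD when the slopes behave as
    r independent estimates with common variance.

    Raises
    ------
    ValueError
        If fewer than 2 groups, mismatched n across groups (the design must
        be balanced), or an unknown ``variance`` option.
    """
    results = list(results)
    r = len(results)
    if r < 2:
        raise ValueError("need at least 2 groups to compare")
    ns = {res.n for res in results}
    if len(ns) != 1:
        raise ValueError(f"groups have mismatched n: {sorted(ns)}; design must be balanced")
    if variance not in ("pooled", "per_pair"):
        raise ValueError(f"unknown variance option {variance!r}")
    n = ns.pop()
    df = n - r
    if df < 1:
        raise ValueError("nonpositive degrees of freedom")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    q = _q_crit(alpha, r, df)
    if labels is None:
        labels = [res.group for res in results]
    pooled_se = float(np.sqrt(np.mean([res.se**2 for res in results])))
    comparisons = []
    for i, j in itertools.combinations(range(r), 2):
        if variance == "pooled":
            se = pooled_se
        else:
            se = float(np.sqrt((results[i].se**2 + results[j].se**2) / 2.0))
        comparisons.append(
            TukeyComparison(
                group_i=str(labels[i]),
                group_j=str(labels[j]),
                estimate=results[i].slope - results[j].slope,
                half_width=q * se,
                alpha=alpha,
                q_crit=q,
                n=n,
                r=r,
            )
        )
    return comparisons


# ---------------------------------------------------------------------------
# summaries


def _results_frame(results: Iterable[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(res) for res in results]
    )


def summarize(results: Iterable[RegressionResult]) -> dict:
    """Tidy report tables from a batch of regression results.

    Returns a dict with ``regressions`` (the long table), ``r2_by_span``
    (indicator × span, R² averaged over metrics), ``r2_mean`` (per
    indicator, averaged over spans), and ``correlations`` (|r| per metric ×
    indicator × span).
    """
    frame = _results_frame(results)
    if frame.empty:
        raise ValueError("no regression results to summarise")
    r2_by_span = (
        frame.pivot_table(index="indicator", columns="window_span", values="r2",
                          aggfunc="mean")
        .sort_index()
    )
    r2_mean = r2_by_span.mean(axis=1).rename("mean_r2")
    correlations = frame.assign(abs_r=frame["r"].abs())[
        ["indicator", "metric", "window_span", "abs_r"]
    ]
    return {
        "regressions": frame,
        "r2_by_span": r2_by_span,
        "r2_mean": r2_mean,
        "correlations": correlations,
    }


def indicators_from_meta(
    metas: Iterable,
    grs_subscores: Sequence[str] = DEFAULT_GRS_SUBSCORES,
) -> pd.DataFrame:
    """Participant-level indicator table (GRS sum, Exp) from trial metadata.

    The GRS indicator is the sum of the configured subscores (default: the
    four needle-motion-related categories).  One row per participant.
    """
    rows = {}
    for meta in metas:
        grs_sum = int(sum(meta.grs[c] for c in grs_subscores))
        rows[meta.participant_id] = {
            "participant_id": meta.participant_id,
            "GRS": grs_sum,
            "Exp": float(meta.years_experience),
        }
    if not rows:
        raise ValueError("no trial metadata supplied")
    return pd.DataFrame(rows.values()).set_index("participant_id")


# ---------------------------------------------------------------------------
# model / results objects


class SkillAssociationModel:
    """Association of process metrics with skill indicators across spans.

    Parameters
    ----------
    metrics : DataFrame
        Tidy long metrics table (one row per trial × window span) with
        columns ``participant_id, trial_id, window_span, T_s, PL_mm, Pks,
        LDLJ, SPARC, FR`` and optionally ``missing_reason``.
    participant_indicators : DataFrame
        Indexed by participant_id with columns ``GRS`` and ``Exp``;
        broadcast to trials at fit time.  FR comes from the metrics table.
    spans : sequence of int, optional
        Window spans to analyse (default: all spans present).
    alpha : float
        Significance level for the Tukey contrasts.
    """

    def __init__(
        self,
        metrics: pd.DataFrame,
        participant_indicators: pd.DataFrame,
        spans: Sequence[int] | None = None,
        alpha: float = 0.05,
        pks_offset: float = 1.0,
        log_sparc: bool = True,
        tukey_variance: str = "pooled",
    ):
        required = {"participant_id", "trial_id", "window_span", "FR"} | set(
            _RAW_COLUMN.values()
        )
        missing = required - set(metrics.columns)
        if missing:
            raise ValueError(f"metrics table missing columns: {sorted(missing)}")
        for col in ("GRS", "Exp"):
            if col not in participant_indicators.columns:
                raise ValueError(f"participant indicator table missing column {col!r}")
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.metrics = metrics
        self.participant_indicators = participant_indicators
        self.spans = (
            sorted(int(s) for s in spans)
            if spans is not None
            else sorted(metrics["window_span"].unique())
        )
        self.alpha = alpha
        self.pks_offset = pks_offset
        self.log_sparc = log_sparc
        self.tukey_variance = tukey_variance

    @classmethod
    def from_cohort(cls, cohort, metrics: pd.DataFrame, **kwargs):
        """Build from a synthetic :class:`~cannuskill.synthetic.Cohort`."""
        from .stats import indicators_from_meta  # self-import keeps mypy quiet

        indicators = indicators_from_meta(meta for _, meta in cohort.trials)
        return cls(metrics, indicators, **kwargs)

    def _usable(self, span: int) -> pd.DataFrame:
        rows = self.metrics[self.metrics["window_span"] == span]
        if "missing_reason" in rows.columns:
            rows = rows[rows["missing_reason"].fillna("") == ""]
        rows = rows.dropna(subset=list(_RAW_COLUMN.values()) + ["FR"])
        return rows

    def _fit_span(self, span: int, rows: pd.DataFrame) -> list[RegressionResult]:
        predictors = transform_standardize(
            rows, pks_offset=self.pks_offset, log_sparc=self.log_sparc
        )
        broadcast = self.participant_indicators.reindex(rows["participant_id"])
        if broadcast[["GRS", "Exp"]].isna().any().any():
            unknown = sorted(
                set(rows["participant_id"]) - set(self.participant_indicators.index)
            )
            raise ValueError(f"participants missing from indicator table: {unknown}")
        indicators = pd.DataFrame(
            {
                "FR": rows["FR"].to_numpy(dtype=float),
                "GRS": broadcast["GRS"].to_numpy(dtype=float),
                "Exp": broadcast["Exp"].to_numpy(dtype=float),
            },
            index=rows.index,
        )
        return fit_indicator_regressions(indicators, predictors, span)

    def fit(self) -> "SkillAssociationResults":
        """Fit every (indicator, metric, span) regression and package results."""
        all_results: list[RegressionResult] = []
        span_rows: dict[int, pd.DataFrame] = {}
        for span in self.spans:
            rows = self._usable(span)
            if len(rows) < 3:
                continue
            span_rows[span] = rows
            all_results.extend(self._fit_span(span, rows))
        if not all_results:
            raise ValueError("no span had enough usable rows to fit")
        return SkillAssociationResults(self, all_results, span_rows)


class SkillAssociationResults:
    """Fitted results: regression table, summaries, contrasts, plots."""

    def __init__(self, model, results, span_rows):
        self.model = model
        self.results = results
        self._span_rows = span_rows
        tables = summarize(results)
        self.regressions: pd.DataFrame = tables["regressions"]
        self.r2_by_span: pd.DataFrame = tables["r2_by_span"]
        self.r2_mean: pd.Series = tables["r2_mean"]
        self.correlations: pd.DataFrame = tables["correlations"]

    # -- contrasts ---------------------------------------------------------

    def _select(self, **match) -> list[RegressionResult]:
        out = [
            res
            for res in self.results
            if all(getattr(res, k) == v for k, v in match.items())
        ]
        return out

    def tukey_metrics(self, indicator: str, span: int) -> list[TukeyComparison]:
        """Compare the five process metrics' slopes within one indicator × span."""
        group = self._select(indicator=indicator, window_span=int(span))
        group.sort(key=lambda res: PROCESS_METRICS.index(res.metric))
        return tukey_pairwise(
            group, alpha=self.model.alpha, variance=self.model.tukey_variance
        )

    def tukey_spans(self, indicator: str, metric: str) -> list[TukeyComparison]:
        """Compare window spans' slopes within one indicator × smoothness metric.

        Balanced design required: refits on the trials available at *every*
        span so each group shares the same n.
        """
        spans = sorted(self._span_rows)
        keys = [
            set(zip(rows["participant_id"], rows["trial_id"]))
            for rows in self._span_rows.values()
        ]
        common = set.intersection(*keys)
        group = []
        for span in spans:
            rows = self._span_rows[span]
            mask = [
                (p, t) in common
                for p, t in zip(rows["participant_id"], rows["trial_id"])
            ]
            sub = rows[np.asarray(mask)]
            fits = {
                (res.indicator, res.metric): res
                for res in self.model._fit_span(span, sub)
            }
            group.append(fits[(indicator, metric)])
        return tukey_pairwise(
            group,
            alpha=self.model.alpha,
            variance=self.model.tukey_variance,
            labels=[str(res.window_span) for res in group],
        )

    # -- reporting ---------------------------------------------------------

    def tukey_tables(self) -> dict:
        """Both contrast families as tidy DataFrames."""
        metric_rows = []
        for ind in INDICATORS:
            for span in sorted(self._span_rows):
                for cmp_ in self.tukey_metrics(ind, span):
                    metric_rows.append(
                        {
                            "indicator": ind,
                            "window_span": span,
                            "pair": f"{cmp_.group_i}-{cmp_.group_j}",
                            "estimate": cmp_.estimate,
                            "lower": cmp_.lower,
                            "upper": cmp_.upper,
                            "significant": cmp_.significant,
                        }
                    )
        span_rows = []
        if len(self._span_rows) >= 2:
            for ind in INDICATORS:
                for met in ("LDLJ", "SPARC"):
                    for cmp_ in self.tukey_spans(ind, met):
                        span_rows.append(
                            {
                                "indicator": ind,
                                "metric": met,
                                "pair": f"{cmp_.group_i}-{cmp_.group_j}",
                                "estimate": cmp_.estimate,
                                "lower": cmp_.lower,
                                "upper": cmp_.upper,
                                "significant": cmp_.significant,
                            }
                        )
        return {
            "metric_contrasts": pd.DataFrame(metric_rows),
            "span_contrasts": pd.DataFrame(span_rows),
        }

    def summary(self) -> str:
        """Human-readable overview: mean R² per indicator and R² by span."""
        lines = ["Skill-indicator association summary", "=" * 36]
        lines.append("Mean R^2 across spans and metrics:")
        for ind, val in self.r2_mean.items():
            lines.append(f"  {ind:>4}: {val:.4f} ({100 * val:.1f}%)")
        lines.append("")
        lines.append("R^2 by window span (averaged over metrics):")
        lines.append(self.r2_by_span.round(4).to_string())
        lines.append("")
        n_by_span = {s: len(rows) for s, rows in self._span_rows.items()}
        lines.append(f"Usable trials per span: {n_by_span}")
        return "\n".join(lines)

    def save_report(self, out_dir) -> None:
        """Write the report tables (CSV + JSON summary) into a directory."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.regressions.to_csv(out / "regressions.csv", index=False)
        self.r2_by_span.to_csv(out / "r2_by_span.csv")
        self.correlations.to_csv(out / "correlations.csv", index=False)
        tables = self.tukey_tables()
        tables["metric_contrasts"].to_csv(out / "tukey_metrics.csv", index=False)
        tables["span_contrasts"].to_csv(out / "tukey_spans.csv", index=False)
        payload = {
            "mean_r2": {k: float(v) for k, v in self.r2_mean.items()},
            "spans": [int(s) for s in sorted(self._span_rows)],
            "n_by_span": {str(s): int(len(r)) for s, r in self._span_rows.items()},
            "alpha": self.model.alpha,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def plot_r2(self, ax=None):
        """R² against window span, one line per indicator."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for ind in self.r2_by_span.index:
            ax.plot(self.r2_by_span.columns, self.r2_by_span.loc[ind],
                    marker="o", label=ind)
        ax.set_xlabel("SG window span (samples)")
        ax.set_ylabel(r"$R^2$")
        ax.legend()
        return ax
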