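"""Cohort statistics: logit transform, group summaries, one-way ANOVA, and
Tukey-Kramer all-pairs comparisons on per-section slide metrics.

Proportion-valued metrics (relative number / relative area) are analyzed on
the logit scale, logit(p) = ln(p / (1 - p)); raw counts are analyzed as-is
(the logit domain excludes values >= 1). Tukey-Kramer standard errors use
the unequal-n form SE = sqrt(MSW/2 * (1/n_i + 1/n_j)) and adjusted p-values
come from the studentized-range distribution with (k, N - k).

The packaged 23-patient cohort table ships as a CSV fixture; see
``load_cohort_fixture``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._studentized_range import studentized_range_sf
from .errors import DegenerateDataError, ParameterError

GROUPS = ("Healthy", "Myocarditis", "ICM", "DCM")

#: Metric-name suffixes whose values live strictly in (0, 1).
RATIO_SUFFIXES = ("relative_number", "relative_area")

REQUIRED_COLUMNS = ("patient_id", "group", "biopsy_location", "metric_name", "value")


def is_ratio_metric(metric_name: str) -> bool:
    return metric_name.endswith(RATIO_SUFFIXES)


def logit(p):
    """Natural-log logit, ln(p / (1 - p)); domain (0, 1) strictly."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("logit requires values strictly inside (0, 1)")
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def inverse_logit(x):
    arr = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(-arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class CohortTable:
    """Long-format per-patient metric table.

    One row per (patient, metric); ratio metrics must lie strictly in (0, 1).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ParameterError(f"cohort table missing columns {missing}")
        if df.duplicated(subset=["patient_id", "metric_name"]).any():
            raise ParameterError("duplicate (patient_id, metric_name) rows")
        for name, sub in df.groupby("metric_name"):
            if is_ratio_metric(str(name)):
                vals = sub["value"].to_numpy(dtype=float)
                if np.any(vals <= 0) or np.any(vals >= 1):
                    raise ParameterError(
                        f"ratio metric {name!r} has values outside (0, 1)"
                    )
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def metrics(self) -> list[str]:
        return sorted(self.data["metric_name"].unique())

    @property
    def groups(self) -> list[str]:
        """Group labels, canonical cohort order first, then alphabetical."""
        present = list(dict.fromkeys(self.data["group"]))
        known = [g for g in GROUPS if g in present]
        return known + sorted(g for g in present if g not in GROUPS)

    def metric_values(self, metric_name: str) -> dict[str, np.ndarray]:
        sub = self.data[self.data["metric_name"] == metric_name]
        if sub.empty:
            raise ParameterError(f"metric {metric_name!r} not present in the table")
        return {
            g: sub.loc[sub["group"] == g, "value"].to_numpy(dtype=float)
            for g in self.groups
            if (sub["group"] == g).any()
        }

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))


def load_cohort_fixture() -> CohortTable:
    """The packaged 23-patient cohort table (4 groups, 4 metrics)."""
    with resources.files("cpcquant.data").joinpath("cohort23.csv").open() as fh:
        table = CohortTable(pd.read_csv(fh))
    unknown = set(table.data["group"]) - set(GROUPS)
    if unknown:
        raise ParameterError(f"fixture has unexpected groups {unknown}")
    return table


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float
    scale: str  # "raw" | "logit"


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    ms_within: float


@dataclass(frozen=True)
class TukeyComparison:
    group_a: str
    group_b: str
    mean_diff: float
    standard_error: float
    q_statistic: float
    adjusted_p: float
    significant: bool


def _summaries(values: dict[str, np.ndarray], scale: str) -> list[GroupSummary]:
    out = []
    for g, vals in values.items():
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out.append(GroupSummary(g, int(vals.size), float(vals.mean()), sd, scale))
    return out


def group_summary(
    table: CohortTable, metric_name: str, scale: str = "raw"
) -> list[GroupSummary]:
    """Per-group n / mean / sample sd on the requested scale."""
    if scale not in ("raw", "logit"):
        raise ParameterError(f"unknown scale {scale!r}")
    values = table.metric_values(metric_name)
    if scale == "logit":
        if not is_ratio_metric(metric_name):
            raise ParameterError(f"metric {metric_name!r} is not a (0,1) ratio")
        values = {g: logit(v) for g, v in values.items()}
    return _summaries(values, scale)


def anova_oneway(values: dict[str, np.ndarray]) -> AnovaResult:
    """Classical one-way fixed-effects decomposition; p from the F upper tail."""
    groups = [np.asarray(v, dtype=float) for v in values.values() if len(v)]
    k = len(groups)
    if k < 2:
        raise ParameterError("ANOVA needs at least 2 groups")
    n_total = sum(len(g) for g in groups)
    if n_total <= k:
        raise ParameterError("ANOVA needs more observations than groups")
    grand = np.concatenate(groups).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ssw <= 0:
        raise DegenerateDataError("within-group variance is zero")
    msb, msw = ssb / df_b, ssw / df_w
    f = msb / msw
    return AnovaResult(
        F=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=float(sps.f.sf(f, df_b, df_w)),
        ms_within=float(msw),
    )


def tukey_kramer(
    values: dict[str, np.ndarray], alpha: float = 0.05
) -> list[TukeyComparison]:
    """All-pairs comparisons with studentized-range adjusted p-values.

    Valid for unequal group sizes via the Kramer standard error
    sqrt(MSW/2 * (1/n_i + 1/n_j)).
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must lie in (0, 1)")
    anova = anova_oneway(values)
    labels = [g for g, v in values.items() if len(v)]
    k = len(labels)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = labels[i], labels[j]
            va, vb = values[a], values[b]
            diff = float(np.mean(va) - np.mean(vb))
            se = float(np.sqrt(anova.ms_within / 2.0 * (1.0 / len(va) + 1.0 / len(vb))))
            q = abs(diff) / se
            p = studentized_range_sf(q, k, anova.df_within)
            out.append(
                TukeyComparison(
                    group_a=a,
                    group_b=b,
                    mean_diff=diff,
                    standard_error=se,
                    q_statistic=q,
                    adjusted_p=p,
                    significant=bool(p < alpha),
                )
            )
    return out


@dataclass(frozen=True)
class StatsReport:
    """Full per-metric analysis: summaries on both scales, ANOVA, post-hoc."""

    metric_name: str
    analysis_scale: str
    alpha: float
    summaries_raw: list[GroupSummary]
    summaries_analysis: list[GroupSummary]
    anova: AnovaResult
    comparisons: list[TukeyComparison]
    provenance: dict = field(default_factory=dict)

    def comparison(self, group_a: str, group_b: str) -> TukeyComparison:
        for c in self.comparisons:
            if {c.group_a, c.group_b} == {group_a, group_b}:
                return c
        raise KeyError(f"no comparison for ({group_a}, {group_b})")

    def to_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "analysis_scale": self.analysis_scale,
            "alpha": self.alpha,
            "summaries_raw": [vars(s) for s in self.summaries_raw],
            "summaries_analysis": [vars(s) for s in self.summaries_analysis],
            "anova": vars(self.anova),
            "comparisons": [vars(c) for c in self.comparisons],
            "provenance": self.provenance,
        }

    def to_text(self) -> str:
        lines = [
            f"Metric: {self.metric_name}  (analysis scale: {self.analysis_scale}, "
            f"alpha={self.alpha})",
            "",
            f"{'group':<14}{'n':>4}{'mean(raw)':>16}{'sd(raw)':>14}",
        ]
        for s in self.summaries_raw:
            lines.append(f"{s.group:<14}{s.n:>4}{s.mean:>16.8g}{s.sd:>14.6g}")
        a = self.anova
        lines += [
            "",
            f"ANOVA: F({a.df_between}, {a.df_within}) = {a.F:.4f}, "
            f"p = {a.p_value:.4g}",
            "",
            f"{'pair':<28}{'diff':>10}{'SE':>9}{'q':>8}{'adj p':>10}  sig",
        ]
        for c in self.comparisons:
            lines.append(
                f"{c.group_a + ' vs ' + c.group_b:<28}{c.mean_diff:>10.4f}"
                f"{c.standard_error:>9.4f}{c.q_statistic:>8.3f}"
                f"{c.adjusted_p:>10.4g}  {'*' if c.significant else ''}"
            )
        return "\n".join(lines)


def analyze_cohort(
    table: CohortTable, metric_name: str, alpha: float = 0.05
) -> StatsReport:
    """Logit-transform ratio metrics, then summarize + ANOVA + Tukey-Kramer."""
    raw = table.metric_values(metric_name)
    if len(raw) < 2:
        raise ParameterError("cohort analysis needs at least 2 groups")
    use_logit = is_ratio_metric(metric_name)
    analysis = {g: logit(v) for g, v in raw.items()} if use_logit else raw
    scale = "logit" if use_logit else "raw"
    return StatsReport(
        metric_name=metric_name,
        analysis_scale=scale,
        alpha=alpha,
        summaries_raw=_summaries(raw, "raw"),
        summaries_analysis=_summaries(analysis, scale),
        anova=anova_oneway(analysis),
        comparisons=tukey_kramer(analysis, alpha=alpha),
    )
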