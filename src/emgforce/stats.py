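"""Method-comparison statistics: the Shapiro-Wilk-gated testing ladder.

Per metric, across recordings (rows) and methods (columns):

1. Shapiro-Wilk normality test per method.
2. If no method rejects normality (alpha = 0.05): one-way repeated-measures
   ANOVA omnibus, then paired t-tests for all method pairs.
   If any method rejects: Friedman omnibus, then Wilcoxon signed-rank tests.
3. All pairwise post hoc p-values are Bonferroni-corrected (x number of
   pairs, clamped at 1).

Summary statistic: the mean per method on the parametric branch, the median
on the non-parametric branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["PairResult", "StatsReport", "compare_methods"]

ALPHA = 0.05


@dataclass(frozen=True)
class PairResult:
    method_a: str
    method_b: str
    statistic: float
    p_raw: float
    p_corrected: float

    @property
    def significant(self) -> bool:
        return self.p_corrected < ALPHA


@dataclass
class StatsReport:
    metric: str
    normality_p: dict[str, float]
    parametric: bool
    omnibus_test: str
    omnibus_statistic: float
    omnibus_p: float
    posthoc_test: str
    pairs: list[PairResult]
    summary_statistic: str
    summary: dict[str, float]

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [(p.method_a, p.method_b) for p in self.pairs if p.significant]

    def to_text(self) -> str:
        lines = [
            f"Metric: {self.metric}",
            "Shapiro-Wilk normality p-values: "
            + ", ".join(f"{m}={p:.3g}" for m, p in self.normality_p.items()),
            f"Branch: {'parametric' if self.parametric else 'non-parametric'}",
            f"Omnibus {self.omnibus_test}: stat={self.omnibus_statistic:.4g}, "
            f"p={self.omnibus_p:.3g}",
            f"Per-method {self.summary_statistic}: "
            + ", ".join(f"{m}={v:.4g}" for m, v in self.summary.items()),
            f"Post hoc ({self.posthoc_test}, Bonferroni-corrected):",
        ]
        for p in self.pairs:
            flag = " *" if p.significant else ""
            lines.append(
                f"  {p.method_a} vs {p.method_b}: p={p.p_corrected:.3g}{flag}"
            )
        return "\n".join(lines)


def _rm_anova(table: pd.DataFrame) -> tuple[float, float]:
    """One-way repeated-measures ANOVA (subjects = rows, condition = columns)."""
    from statsmodels.stats.anova import AnovaRM

    long = table.reset_index(names="subject").melt(
        id_vars="subject", var_name="method", value_name="value"
    )
    res = AnovaRM(long, depvar="value", subject="subject", within=["method"]).fit()
    row = res.anova_table.iloc[0]
    return float(row["F Value"]), float(row["Pr > F"])


def compare_methods(table: pd.DataFrame, metric: str = "rmse") -> StatsReport:
    """Run the full testing ladder on a recordings x methods metric table."""
    if table.shape[0] < 3:
        raise ValueError("need at least 3 recordings for method comparison")
    if table.shape[1] < 2:
        raise ValueError("need at least 2 methods to compare")
    methods = list(table.columns)
    cols = {m: np.asarray(table[m], dtype=float) for m in methods}

    normality = {m: float(sps.shapiro(v).pvalue) for m, v in cols.items()}
    parametric = all(p > ALPHA for p in normality.values())

    if parametric:
        omnibus_name, posthoc_name = "repeated-measures ANOVA", "paired t-test"
        stat, p = _rm_anova(table)
    else:
        omnibus_name, posthoc_name = "Friedman", "Wilcoxon signed-rank"
        stat, p = sps.friedmanchisquare(*cols.values())
        stat, p = float(stat), float(p)

    pair_list = list(combinations(methods, 2))
    n_pairs = len(pair_list)
    pairs = []
    for a, b in pair_list:
        if parametric:
            r = sps.ttest_rel(cols[a], cols[b])
        else:
            # exact null distribution when the tie structure allows, else
            # the normal approximation (scipy decides via method="auto")
            r = sps.wilcoxon(cols[a], cols[b], method="auto")
        p_raw = float(r.pvalue)
        pairs.append(
            PairResult(
                method_a=a,
                method_b=b,
                statistic=float(r.statistic),
                p_raw=p_raw,
                p_corrected=min(1.0, p_raw * n_pairs),
            )
        )

    summary_stat = "mean" if parametric else "median"
    reduce = np.mean if parametric else np.median
    summary = {m: float(reduce(v)) for m, v in cols.items()}
    return StatsReport(
        metric=metric,
        normality_p=normality,
        parametric=parametric,
        omnibus_test=omnibus_name,
        omnibus_statistic=stat,
        omnibus_p=p,
        posthoc_test=posthoc_name,
        pairs=pairs,
        summary_statistic=summary_stat,
        summary=summary,
    )
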