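"""Group comparisons and summary tables for per-cell metrics.

Standard plumbing mirroring how bead/spreading experiments are reported:
mean ± SEM per group, one- or two-way ANOVA, and Sidak or Dunnett post hoc
comparisons with star annotations (* 0.01 < p < 0.05, ** 0.001 < p < 0.01,
*** p < 0.001, **** p < 0.0001).  The observational unit is the cell.
"""

from __future__ import annotations

from itertools import combinations
from typing import Literal, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps


class StatsError(ValueError):
    """Raised for degenerate designs (too few groups or observations)."""


class ComparisonDesign(BaseModel):
    """Which test to run and how to adjust the pairwise comparisons."""

    factors: tuple[str, ...] = ("condition",)
    test: Literal["one_way_anova", "two_way_anova"] = "one_way_anova"
    posthoc: Literal["sidak", "dunnett"] = "sidak"
    reference_level: Optional[str] = None
    alpha: float = Field(0.05, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "ComparisonDesign":
        if self.test == "two_way_anova" and len(self.factors) != 2:
            raise ValueError("two-way ANOVA needs exactly two factors")
        if self.test == "one_way_anova" and len(self.factors) != 1:
            raise ValueError("one-way ANOVA needs exactly one factor")
        if self.posthoc == "dunnett" and self.reference_level is None:
            raise ValueError("Dunnett post hoc needs a reference_level")
        return self


def stars(p: float, alpha: float = 0.05) -> str:
    """Significance annotation using the conventional p-value bands."""
    if np.isnan(p) or p >= alpha:
        return "ns"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    return "*"


def sidak_adjust(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Sidak family-wise adjustment: ``1 - (1 - p)^m`` (identity at m=1)."""
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def summarize(records: pd.DataFrame, group_keys: list[str], metric: str) -> pd.DataFrame:
    """Per-group n, mean and SEM (= sd/sqrt(n)) of one metric.

    A group with a single observation has SEM NaN and is flagged.
    """
    if records.empty:
        raise StatsError("no records to summarize")
    rows = []
    for keys, sub in records.groupby(group_keys, dropna=False):
        vals = sub[metric].dropna().to_numpy(dtype=float)
        n = len(vals)
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            dict(zip(group_keys, keys))
            | {
                "n": n,
                "mean": vals.mean() if n else np.nan,
                "sem": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "qc": "" if n > 1 else "sem_undefined",
            }
        )
    return pd.DataFrame(rows)


def _group_samples(df: pd.DataFrame, factor: str, metric: str):
    levels = list(pd.unique(df[factor]))
    samples = {lev: df.loc[df[factor] == lev, metric].dropna().to_numpy() for lev in levels}
    if len(samples) < 2:
        raise StatsError("need at least 2 groups")
    for lev, vals in samples.items():
        if len(vals) < 2:
            raise StatsError(f"group {lev!r} has fewer than 2 observations")
    return levels, samples


def compare_groups(
    records: pd.DataFrame, metric: str, design: ComparisonDesign
) -> dict[str, pd.DataFrame]:
    """ANOVA plus post hoc contrasts for one metric.

    Returns ``{"anova": F-table, "posthoc": contrast table}`` where the
    post hoc table has raw and adjusted p-values (Sidak: ``1-(1-p)^m``
    over the m comparisons; Dunnett: multivariate-t many-to-one test
    against the reference level) and star annotations.
    """
    df = records.dropna(subset=[metric]).copy()
    primary = design.factors[0]
    levels, samples = _group_samples(df, primary, metric)

    terms = " + ".join(f"C(Q('{f}'))" for f in design.factors)
    if design.test == "two_way_anova":
        terms += f" + C(Q('{design.factors[0]}')):C(Q('{design.factors[1]}'))"
    model = smf.ols(f"Q('{metric}') ~ {terms}", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    if design.posthoc == "dunnett":
        ref = design.reference_level
        if ref not in samples:
            raise StatsError(f"reference level {ref!r} not among groups {levels}")
        others = [lev for lev in levels if lev != ref]
        res = sps.dunnett(*(samples[lev] for lev in others), control=samples[ref])
        posthoc = pd.DataFrame(
            {
                "contrast": [f"{lev} vs {ref}" for lev in others],
                "statistic": res.statistic,
                "p_raw": res.pvalue,
                "p_adj": res.pvalue,  # Dunnett p-values are family-wise already
            }
        )
    else:
        pairs = list(combinations(levels, 2))
        raw = [
            sps.ttest_ind(samples[a], samples[b]).pvalue for a, b in pairs
        ]
        posthoc = pd.DataFrame(
            {
                "contrast": [f"{a} vs {b}" for a, b in pairs],
                "p_raw": raw,
                "p_adj": np.minimum(sidak_adjust(np.array(raw), len(pairs)), 1.0),
            }
        )
    posthoc["stars"] = [stars(p, design.alpha) for p in posthoc["p_adj"]]
    return {"anova": anova, "posthoc": posthoc}
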