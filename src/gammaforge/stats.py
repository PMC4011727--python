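"""Group-comparison harness for pipeline outputs.

Mirrors the classical two-genotype workflow: per-group Shapiro–Wilk
normality check, unpaired two-sided t-test (pooled variance by default,
Welch by flag) with optional Bonferroni correction, and a two-factor
(group x pulse) ANOVA for repetitive-stimulation experiments.
Normality failure is reported, never silently switched to another test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = ["GroupComparison", "compare_groups", "train_anova"]

ALPHA = 0.05


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    test_name: str
    statistic: float
    p_value: float
    p_corrected: float
    normality_p: tuple[float, float]
    correction: str
    m_comparisons: int
    significant: bool


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    m: int = 1,
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-sided t-test with Shapiro–Wilk and Bonferroni.

    ``m`` is the number of comparisons in the family; the corrected
    p-value is min(1, m x p).  Significance is declared at corrected
    p < 0.05.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each group needs n >= 3")
    if m < 1:
        raise ValueError("m must be >= 1")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance in both groups: t-test undefined")
    sw_a = float(sst.shapiro(x).pvalue)
    sw_b = float(sst.shapiro(y).pvalue)
    res = sst.ttest_ind(x, y, equal_var=not welch)
    p_corr = min(1.0, m * float(res.pvalue))
    return GroupComparison(
        mean_a=float(np.mean(x)), sem_a=float(sst.sem(x)), n_a=int(x.size),
        mean_b=float(np.mean(y)), sem_b=float(sst.sem(y)), n_b=int(y.size),
        test_name="welch t" if welch else "unpaired t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        p_corrected=p_corr,
        normality_p=(sw_a, sw_b),
        correction="bonferroni" if m > 1 else "none",
        m_comparisons=int(m),
        significant=bool(p_corr < ALPHA),
    )


def train_anova(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Two-factor (group x pulse) ANOVA of normalised train responses.

    ``groups`` maps a group label to a (sweeps x pulses) array of
    normalised responses; pulse counts must match across groups.  Returns
    the type-II ANOVA table with F and p for group, pulse and their
    interaction.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    n_pulses = {np.asarray(v).shape[1] for v in groups.values()}
    if len(n_pulses) != 1:
        raise ValueError("pulse count must be balanced across groups")
    rows = []
    for label, arr in groups.items():
        arr = np.asarray(arr, dtype=float)
        for sweep in range(arr.shape[0]):
            for pulse in range(arr.shape[1]):
                rows.append((label, pulse + 1, arr[sweep, pulse]))
    df = pd.DataFrame(rows, columns=["group", "pulse", "response"])
    model = ols("response ~ C(group) * C(pulse)", data=df).fit()
    return sm.stats.anova_lm(model, typ=2)
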