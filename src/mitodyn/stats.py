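"""Group summaries (mean ± SEM) and two-group t-tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSummary:
    """Mean ± SEM of one metric in one group; sem uses the n-1 denominator."""

    mean: float
    sem: float
    n: int
    single_value: bool = False   # n == 1: sem reported as 0 with this flag

    def __str__(self) -> str:
        return f"{self.mean:.4g} ± {self.sem:.2g} (n={self.n})"


@dataclass
class TTestResult:
    t: float
    p: float
    variant: str
    n_a: int
    n_b: int


def group_summary(values) -> GroupSummary:
    """Arithmetic mean and standard error (sample sd over sqrt(n))."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("group_summary requires at least one value")
    if values.size == 1:
        return GroupSummary(mean=float(values[0]), sem=0.0, n=1, single_value=True)
    sd = float(values.std(ddof=1))
    return GroupSummary(mean=float(values.mean()),
                        sem=sd / np.sqrt(values.size), n=int(values.size))


def two_group_t(values_a, values_b, variant: str = "student") -> TTestResult:
    """Two-sided two-sample t-test; 'student' (pooled variance) or 'welch'."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError("variant must be 'student' or 'welch'")
    res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       variant=variant, n_a=int(a.size), n_b=int(b.size))
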