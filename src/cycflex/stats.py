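"""Statistical primitives: Cohen's d with pooled s, two-sample t, Pearson r."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


@dataclass(frozen=True)
class EffectSizeReport:
    """Cohen's d of group 1 vs group 2 with all ingredients.

    ``d = (mean1 - mean2) / pooled_sd`` with
    ``pooled_sd = sqrt(((n1-1)*sd1^2 + (n2-1)*sd2^2) / (n1+n2-2))``;
    sample sds use n-1 denominators.  ``t``/``p`` are the pooled-variance
    two-sided t-test, consistent with the pooled s in d.
    """

    d: float
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    pooled_sd: float
    n1: int
    n2: int
    t: float
    p: float

    def to_dict(self) -> dict:
        return {
            "d": self.d, "mean1": self.mean1, "mean2": self.mean2,
            "sd1": self.sd1, "sd2": self.sd2, "pooled_sd": self.pooled_sd,
            "n1": self.n1, "n2": self.n2, "t": self.t, "p": self.p,
        }


def cohens_d(x1, x2) -> EffectSizeReport:
    """Cohen's d effect size of ``x1`` vs ``x2`` (positive ⇒ x1 larger)."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("non-finite values in input")
    m1, m2 = float(x1.mean()), float(x2.mean())
    s1, s2 = float(x1.std(ddof=1)), float(x2.std(ddof=1))
    pooled = float(np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2)
                           / (n1 + n2 - 2)))
    if pooled == 0.0:
        raise UndefinedStatisticError("pooled standard deviation is zero")
    d = (m1 - m2) / pooled
    t = d * np.sqrt(n1 * n2 / (n1 + n2))
    p = float(2.0 * sps.t.sf(abs(t), df=n1 + n2 - 2))
    return EffectSizeReport(d=float(d), mean1=m1, mean2=m2, sd1=s1, sd2=s2,
                            pooled_sd=pooled, n1=n1, n2=n2, t=float(t), p=p)


def two_sample_t(x1, x2, flavor: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test; ``flavor`` is 'welch' or 'pooled'."""
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("both groups need n >= 2")
    if flavor not in ("welch", "pooled"):
        raise ValueError(f"unknown flavor {flavor!r}")
    if x1.std(ddof=1) == 0.0 and x2.std(ddof=1) == 0.0:
        if x1.mean() == x2.mean():
            return 0.0, 1.0  # degenerate: identical constants
        raise UndefinedStatisticError("zero variance in both groups")
    res = sps.ttest_ind(x1, x2, equal_var=(flavor == "pooled"))
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedStatisticError("zero variance input")
    return float(sps.pearsonr(x, y).statistic)
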