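"""Behavioural statistics: RAU transform, paired t-tests, Cohen's d.

Listening accuracy (proportion of sentence-final words repeated correctly) is
variance-stabilised with Studebaker's rationalized arcsine unit (RAU)
transform before testing, to reduce clustering near ceiling. Program effects
on per-participant means are tested with paired-samples t-tests, and the
paired-design standardized effect size is d = |t| / sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def rau_transform(x_correct, n_items) -> np.ndarray | float:
    """Rationalized arcsine units from a correct count out of ``n_items``.

    t = asin(sqrt(x/(n+1))) + asin(sqrt((x+1)/(n+1))); RAU = (146/pi)*t - 23.
    Monotone in x with limits -23 (x=0) and 123 (x=n) as n grows.
    """
    x = np.asarray(x_correct, dtype=float)
    n = np.asarray(n_items, dtype=float)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("correct count must satisfy 0 <= x <= n")
    t = np.arcsin(np.sqrt(x / (n + 1.0))) + np.arcsin(np.sqrt((x + 1.0) / (n + 1.0)))
    rau = (146.0 / np.pi) * t - 23.0
    return float(rau) if rau.ndim == 0 else rau


@dataclass
class PairedTestResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    diff: float
    ci95: tuple
    df: int
    t: float
    p: float
    d: float

    def summary_row(self, label_a: str = "a", label_b: str = "b") -> dict:
        return {
            "group_a": label_a,
            "group_b": label_b,
            "M_a": self.mean_a,
            "SD_a": self.sd_a,
            "M_b": self.mean_b,
            "SD_b": self.sd_b,
            "Diff": self.diff,
            "CI95_low": self.ci95[0],
            "CI95_high": self.ci95[1],
            "df": self.df,
            "t": self.t,
            "p": self.p,
            "d": self.d,
        }


def cohens_d_paired(t: float, n: int) -> float:
    """Paired-design Cohen's d from the t statistic: d = |t| / sqrt(n)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return float(abs(t) / np.sqrt(n))


def paired_ci_from_summary(diff: float, t: float, n: int, level: float = 0.95) -> tuple:
    """Reconstruct the paired-test CI on the mean difference from (diff, t, n).

    The standard error is diff/t and the interval uses the t quantile on
    n - 1 degrees of freedom, as in a reported summary table.
    """
    if t == 0:
        raise ValueError("cannot reconstruct a CI from t = 0")
    se = diff / t
    tcrit = stats.t.ppf(0.5 + level / 2, n - 1)
    return (diff - tcrit * se, diff + tcrit * se)


def paired_t(a, b) -> PairedTestResult:
    """Two-sided paired-samples t-test of a - b with a 95% CI on the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be paired 1-D samples of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    diffs = a - b
    sd_diff = diffs.std(ddof=1)
    df = n - 1
    if sd_diff == 0:
        if diffs.mean() == 0:  # identical samples: no effect, not an error
            return PairedTestResult(
                mean_a=float(a.mean()), mean_b=float(b.mean()),
                sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
                diff=0.0, ci95=(0.0, 0.0), df=df, t=0.0, p=1.0, d=0.0,
            )
        raise ValueError("zero variance of paired differences")
    se = sd_diff / np.sqrt(n)
    t_stat = diffs.mean() / se
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    tcrit = stats.t.ppf(0.975, df)
    ci = (diffs.mean() - tcrit * se, diffs.mean() + tcrit * se)
    return PairedTestResult(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        diff=float(diffs.mean()),
        ci95=(float(ci[0]), float(ci[1])),
        df=df,
        t=float(t_stat),
        p=float(p),
        d=cohens_d_paired(t_stat, n),
    )
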