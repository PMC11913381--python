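"""Statistical tests and fits used across the pipeline.

Three procedures: chi-square goodness of fit of observed bin counts
against composition-based expectations (df = bins - 1, since expected
totals are constrained to observed); ordinary least-squares regression of
nine-bin mutation counts on mean replication time with the Pearson
correlation and its t-based two-sided p-value; and the Wilcoxon
matched-pairs signed-rank test for per-chromosome observed vs expected
percentages (exact null for n <= 25 informative pairs, normal
approximation above, no continuity correction, zero differences dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DomainError, NoInformationError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    estimates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.statistic):
            raise DomainError("non-finite test statistic")
        if not (0 < self.p_value <= 1):
            # p-values of exactly 0 only arise from floating underflow in
            # extreme fits; clamp to the smallest positive float
            if self.p_value == 0:
                self.p_value = np.nextafter(0, 1)
            else:
                raise DomainError(f"p-value {self.p_value} outside (0, 1]")


def chisq_gof(observed, expected) -> TestResult:
    """Chi-square goodness of fit: statistic = sum (O-E)^2/E, df = k-1."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.ndim != 1:
        raise DomainError("observed and expected must be equal-length vectors")
    if len(observed) < 2:
        raise DomainError("need >= 2 bins (df would be 0)")
    if np.any(expected <= 0):
        raise DomainError("all expected counts must be positive")
    if observed.sum() <= 0:
        raise DomainError("observed total must be positive")
    stat, p = sps.chisquare(observed, expected)
    return TestResult(float(stat), float(p), "chi-square GOF", df=len(observed) - 1)


def ninebin_regression(bin_counts, bin_mean_times) -> TestResult:
    """OLS of per-bin mutation counts on mean replication time.

    Returns slope, intercept and Pearson r; the two-sided p-value comes
    from t = r sqrt(n-2)/sqrt(1-r^2) with df = n-2.
    """
    y = np.asarray(bin_counts, dtype=float)
    x = np.asarray(bin_mean_times, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise DomainError("need >= 3 paired (time, count) points")
    if np.all(x == x[0]):
        raise DomainError("abscissa is constant")
    if np.all(y == y[0]):
        raise DomainError("constant counts: correlation undefined")
    fit = sps.linregress(x, y)
    return TestResult(
        float(fit.rvalue),
        float(fit.pvalue),
        "nine-bin OLS regression",
        df=len(x) - 2,
        estimates={
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
            "r": float(fit.rvalue),
        },
    )


def wilcoxon_matched_pairs(
    observed_pct, expected_pct, alternative: str = "two_sided"
) -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on per-chromosome paired
    percentages.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 informative pairs and the normal approximation (without
    continuity correction) above.
    """
    obs = np.asarray(observed_pct, dtype=float)
    exp = np.asarray(expected_pct, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise DomainError("paired vectors must have equal length")
    diffs = obs - exp
    informative = diffs[diffs != 0]
    if len(informative) == 0:
        raise NoInformationError("all paired differences are zero")
    if len(informative) < 5:
        raise DomainError(f"need >= 5 informative pairs, have {len(informative)}")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}.get(
        alternative
    )
    if alt is None:
        raise DomainError(f"unknown alternative {alternative!r}")
    method = "exact" if len(informative) <= 25 else "approx"
    res = sps.wilcoxon(
        informative,
        zero_method="wilcox",
        alternative=alt,
        correction=False,
        method=method,
    )
    return TestResult(
        float(res.statistic),
        float(res.pvalue),
        f"Wilcoxon signed-rank ({method})",
        estimates={"n_informative": float(len(informative))},
    )
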