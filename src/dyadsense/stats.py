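"""Effect sizes, t-tests with CIs, FDR adjustment, and post hoc power.

The battery applied to collaboration features:

* Cohen's d for paired and independent designs, with the conventional
  interpretation bands |d| < 0.2 negligible, < 0.5 small, < 0.8 medium,
  else large.  Independent d pools standard deviations with n-1 weights;
  paired d standardizes the mean difference by the SD of differences.
  Hedges' small-sample correction is available but off by default.
* Paired/independent t-tests (delegated to scipy) with 95% confidence
  intervals of the mean difference.
* Benjamini–Hochberg step-up adjustment: sort p ascending, q_(i) =
  p_(i) * m / i, enforce monotonicity from the largest rank down, cap at 1,
  report in input order.
* Post hoc power from the noncentral t distribution: for a paired or
  one-sample design the noncentrality is d * sqrt(n) with df = n - 1; for
  two equal groups it is d * sqrt(n/2) with df = 2n - 2.  Two-sided power
  is P(T' > t_crit) + P(T' < -t_crit) under the noncentral law, so power
  equals alpha when d = 0 and grows monotonically in n, |d| and alpha.

Hierarchical models (linear mixed effects) and MANOVA are standard fits
and are passed through to statsmodels rather than re-implemented; see
:func:`fit_mixed_model` and :func:`fit_manova`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectSize",
    "TestResult",
    "PowerResult",
    "cohens_d",
    "t_test",
    "benjamini_hochberg",
    "posthoc_power",
    "run_battery",
    "fit_mixed_model",
    "fit_manova",
]

_BANDS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def effect_band(d: float) -> str:
    """Interpretation band on |d| with thresholds 0.2 / 0.5 / 0.8."""
    for cut, name in _BANDS:
        if abs(d) < cut:
            return name
    return "large"


@dataclass(frozen=True)
class EffectSize:
    d: float
    design: str
    band: str


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_raw: float
    ci95: tuple[float, float]
    p_adjusted: float | None = None


@dataclass(frozen=True)
class PowerResult:
    power: float
    design: str
    d: float
    n: int
    alpha: float
    sidedness: str


def _check_samples(a, b, design):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if design not in ("paired", "independent"):
        raise ValueError(f"unknown design {design!r}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    if design == "paired" and len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    return a, b


def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float],
             design: str = "independent", hedges: bool = False) -> EffectSize:
    """Standardized mean difference of a over b."""
    a, b = _check_samples(sample_a, sample_b, design)
    if design == "paired":
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance of differences: d undefined")
        d = diff.mean() / sd
        m = len(a) - 1
    else:
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                         / (na + nb - 2))
        if pooled == 0:
            raise ValueError("zero pooled variance: d undefined")
        d = (a.mean() - b.mean()) / pooled
        m = na + nb - 2
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * m - 1.0)
    return EffectSize(float(d), design, effect_band(d))


def t_test(sample_a: Sequence[float], sample_b: Sequence[float],
           design: str = "independent",
           sidedness: str = "two-sided") -> TestResult:
    """t statistic, p value and 95% CI of the mean difference (a - b)."""
    a, b = _check_samples(sample_a, sample_b, design)
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if design == "paired":
        if (a - b).std(ddof=1) == 0:
            raise ValueError("zero variance of differences")
        res = sps.ttest_rel(a, b, alternative=sidedness)
        df = len(a) - 1
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("zero variance in both samples")
        res = sps.ttest_ind(a, b, alternative=sidedness)
        df = len(a) + len(b) - 2
    lo, hi = res.confidence_interval(0.95)
    return TestResult(float(res.statistic), float(df), float(res.pvalue),
                      (float(lo), float(hi)))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR-adjusted p values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]   # monotone from largest rank down
    q = np.minimum(q, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = q
    return out


def posthoc_power(d: float, n: int, alpha: float = 0.05,
                  design: str = "independent",
                  sidedness: str = "two-sided") -> PowerResult:
    """Power of a t-test at observed effect size d via the noncentral t.

    ``n`` is the number of pairs (paired design) or per-group size
    (independent design, equal groups).
    """
    if design not in ("paired", "independent"):
        raise ValueError(f"unknown design {design!r}")
    if sidedness not in ("two-sided", "one-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    if n < 2:
        raise ValueError("n must be at least 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if design == "paired":
        df = n - 1
        ncp = d * np.sqrt(n)
    else:
        df = 2 * n - 2
        ncp = d * np.sqrt(n / 2.0)
    if sidedness == "two-sided":
        tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
        upper = sps.nct.sf(tcrit, df, ncp)
        lower = sps.nct.cdf(-tcrit, df, ncp)
        # the far tail can underflow to nan at large df; it is then negligible
        power = (upper if np.isfinite(upper) else 0.0) + \
                (lower if np.isfinite(lower) else 0.0)
    else:
        tcrit = sps.t.ppf(1.0 - alpha, df)
        power = sps.nct.sf(tcrit, df, abs(ncp))
    return PowerResult(float(power), design, float(d), int(n), float(alpha),
                       sidedness)


def run_battery(comparisons: dict[str, tuple[Sequence[float], Sequence[float], str]],
                 alpha: float = 0.05):
    """Run the full battery over named (sample_a, sample_b, design) triples.

    Returns a tidy DataFrame with one row per comparison: t, df, raw and
    BH-adjusted p, 95% CI, Cohen's d with band, and post hoc power at the
    observed d.
    """
    import pandas as pd

    rows = []
    for name, (a, b, design) in comparisons.items():
        tr = t_test(a, b, design)
        es = cohens_d(a, b, design)
        n = len(a) if design == "paired" else min(len(a), len(b))
        pw = posthoc_power(es.d, n, alpha, design)
        rows.append({"comparison": name, "design": design,
                     "t": tr.statistic, "df": tr.df, "p_raw": tr.p_raw,
                     "ci95_low": tr.ci95[0], "ci95_high": tr.ci95[1],
                     "d": es.d, "band": es.band, "power": pw.power})
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adj"] = benjamini_hochberg(frame["p_raw"].to_numpy())
    return frame


# --- pass-throughs for standard hierarchical/multivariate fits -------------

def fit_mixed_model(data, formula: str, groups: str, **kwargs):
    """Linear mixed-effects fit, delegated to statsmodels MixedLM."""
    import statsmodels.formula.api as smf

    return smf.mixedlm(formula, data, groups=data[groups], **kwargs).fit()


def fit_manova(data, formula: str):
    """Multivariate analysis of variance, delegated to statsmodels MANOVA."""
    from statsmodels.multivariate.manova import MANOVA

    return MANOVA.from_formula(formula, data)
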