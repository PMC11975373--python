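"""Shared statistics: bootstrap CIs, t-tests, effect sizes, mixed models.

The bootstrap resamples *participants* with replacement (the unit of
inference everywhere in this package) and reports the percentile
interval of the mean. Mixed models delegate to statsmodels ``MixedLM``;
on convergence failure random slopes are dropped one at a time, last
first, until the fit converges, and every reduction step is logged on
the returned object.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapCI:
    low: float
    high: float
    n_boot: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must not exceed high")


@dataclass(frozen=True)
class EffectReport:
    """One test result: statistic, df, two-sided p, Cohen's d."""

    name: str
    statistic: float
    df: float
    p: float
    effect_size: float
    mean: float
    ci: BootstrapCI | None = None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "effect_size": self.effect_size,
            "mean": self.mean,
        }
        if self.ci is not None:
            d["ci_low"], d["ci_high"] = self.ci.low, self.ci.high
        return d


def bootstrap_ci(
    values, n_boot: int = 10_000, seed: int | None = None, level: float = 0.95
) -> BootstrapCI:
    """Percentile bootstrap CI of the mean, resampling participants."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 participants")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return BootstrapCI(low=float(lo), high=float(hi), n_boot=n_boot, level=level)


def _check_sample(values: np.ndarray) -> None:
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    if np.std(values, ddof=1) == 0:
        raise ValueError("zero-variance sample: t statistic undefined")


def one_sample_t(values, mu0: float = 0.0, name: str = "one_sample_t") -> EffectReport:
    """Two-sided one-sample t-test with d = (mean - mu0) / SD."""
    values = np.asarray(values, dtype=float)
    _check_sample(values)
    t, p = scipy.stats.ttest_1samp(values, mu0)
    d = (values.mean() - mu0) / values.std(ddof=1)
    return EffectReport(
        name=name, statistic=float(t), df=len(values) - 1, p=float(p),
        effect_size=float(d), mean=float(values.mean()),
    )


def paired_t(a, b, name: str = "paired_t") -> EffectReport:
    """Two-sided paired t-test with d = mean(a-b) / SD(a-b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    diff = a - b
    _check_sample(diff)
    t, p = scipy.stats.ttest_rel(a, b)
    d = diff.mean() / diff.std(ddof=1)
    return EffectReport(
        name=name, statistic=float(t), df=len(diff) - 1, p=float(p),
        effect_size=float(d), mean=float(diff.mean()),
    )


def cohens_d_one_sample(values, mu0: float = 0.0) -> float:
    values = np.asarray(values, dtype=float)
    _check_sample(values)
    return float((values.mean() - mu0) / values.std(ddof=1))


def cohens_d_paired(a, b) -> float:
    return cohens_d_one_sample(np.asarray(a, float) - np.asarray(b, float))


@dataclass
class LmmFit:
    """Coefficient table of a converged linear mixed-effects fit.

    ``coefficients`` has one row per fixed-effect term with columns
    beta, se, t, p. ``re_formula`` is the random structure that actually
    converged; ``reduction_log`` records any slopes dropped on the way.
    """

    coefficients: pd.DataFrame
    re_formula: str
    converged: bool
    reduction_log: list[str] = field(default_factory=list)
    result: object = None

    def beta(self, term: str) -> float:
        return float(self.coefficients.loc[term, "beta"])

    def p(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


def _re_terms(re_formula: str | None) -> list[str]:
    if not re_formula:
        return []
    rhs = re_formula.lstrip("~").strip()
    return [t.strip() for t in rhs.split("+") if t.strip() not in ("", "1")]


def _try_fit(formula: str, data: pd.DataFrame, groups, re_formula: str | None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=groups, re_formula=re_formula)
        result = model.fit(reml=True, method=["lbfgs", "bfgs"], maxiter=500)
        ok = bool(result.converged) and bool(np.all(np.isfinite(result.bse_fe)))
    return result, ok


def fit_lmm(
    formula: str,
    data: pd.DataFrame,
    groups: str = "participant",
    re_formula: str | None = None,
) -> LmmFit:
    """Linear mixed-effects fit with automatic random-slope reduction.

    Fits ``formula`` with a by-group random intercept plus the slopes in
    ``re_formula``. If the fit fails to converge (or yields non-finite
    standard errors), slopes are removed one at a time in reverse of the
    listed order; as a last resort the model keeps only the random
    intercept. The reduction path is deterministic and logged.
    """
    if groups not in data.columns:
        raise ValueError(f"grouping column {groups!r} missing from data")
    slopes = _re_terms(re_formula)
    log: list[str] = []
    attempts = [slopes[:k] for k in range(len(slopes), -1, -1)]
    result, ok, used = None, False, None
    for terms in attempts:
        rf = "~" + " + ".join(["1"] + terms) if terms else None
        try:
            result, ok = _try_fit(formula, data, data[groups], rf)
        except Exception as exc:  # singular design, LinAlgError, ...
            result, ok = None, False
            log.append(f"random structure {rf or '~1'} failed: {type(exc).__name__}")
        if ok:
            used = rf or "~1"
            break
        if result is not None:
            log.append(f"random structure {rf or '~1'} did not converge; reducing")
    if result is None:
        raise RuntimeError("mixed model failed even with intercept-only random effects")
    if not ok:
        used = "~1"
        log.append("no structure converged cleanly; reporting intercept-only fit")
    for line in log:
        logger.info("fit_lmm: %s", line)
    fe = result.fe_params.index
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # se of a pinned variance component
        table = pd.DataFrame(
            {
                "beta": result.fe_params,
                "se": result.bse[fe],
                "t": result.tvalues[fe],
                "p": result.pvalues[fe],
            }
        )
    table.index.name = "term"
    return LmmFit(
        coefficients=table,
        re_formula=used,
        converged=bool(result.converged),
        reduction_log=log,
        result=result,
    )
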