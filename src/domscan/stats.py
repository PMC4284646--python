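"""Shared association statistics.

Implements the 1-df dominance (carrier vs non-carrier) chi-square
genotypic test, two-sample t-tests (pooled or Welch), least-squares
covariate residualization for quantitative phenotypes, and Bonferroni
accounting of per-experiment significance thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .datamodel import DomscanError

_P_FLOOR = 5e-324  # smallest subnormal double; p-values are never reported as 0


@dataclass
class AssocResult:
    """One test's statistic, p-value and the Bonferroni context it sits in."""

    test: str
    statistic: float
    df: float
    p_value: float
    n_tests_in_experiment: int = 1
    alpha: float = 0.05
    uninformative: bool = False

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_tests_in_experiment

    @property
    def significant(self) -> bool:
        return not self.uninformative and self.p_value < self.bonferroni_threshold


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = phenotype class, columns = carrier/non-carrier:

    ===========  ========  ============
    .            carrier   non-carrier
    affected        a           b
    unaffected      c           d
    ===========  ========  ============
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def dominance_chi2(
    table: ContingencyTable2x2,
    continuity_correction: bool = False,
    exact: bool = False,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> AssocResult:
    """Genotypic test assuming dominance: 1-df chi-square on the
    carrier x phenotype 2x2 table.

    statistic = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).

    ``exact`` switches to Fisher's exact test (two-sided), useful for
    small cells; ``continuity_correction`` applies Yates' correction to
    the chi-square. A zero margin makes the test uninformative (p = 1).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    margins = ((a + b), (c + d), (a + c), (b + d))
    if 0 in margins:
        return AssocResult("dominance_chi2", 0.0, 1, 1.0, n_tests, alpha, uninformative=True)
    if exact:
        res = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return AssocResult("dominance_fisher_exact", float(res.statistic), 1,
                           max(float(res.pvalue), _P_FLOOR), n_tests, alpha)
    diff = abs(a * d - b * c)
    if continuity_correction:
        diff = max(diff - n / 2.0, 0.0)
    stat = n * diff**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = max(float(sps.chi2.sf(stat, df=1)), _P_FLOOR)
    return AssocResult("dominance_chi2", float(stat), 1, p, n_tests, alpha)


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    variant: str = "pooled",
    alpha: float = 0.05,
    n_tests: int = 1,
) -> AssocResult:
    """Two-sided two-sample t-test, pooled-variance or Welch."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DomscanError("two_sample_t requires at least 2 observations per group")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        # degenerate: no within-group variation
        if x.mean() == y.mean():
            return AssocResult(f"t_{variant}", 0.0, len(x) + len(y) - 2, 1.0, n_tests, alpha)
        sign = math.copysign(1.0, x.mean() - y.mean())
        return AssocResult(f"t_{variant}", sign * np.inf, len(x) + len(y) - 2,
                           _P_FLOOR, n_tests, alpha)
    import warnings

    with warnings.catch_warnings():
        # near-constant groups trip scipy's precision-loss warning; the
        # zero-variance degenerate cases are handled explicitly above
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return AssocResult(
        f"t_{variant}", float(res.statistic), float(res.df),
        max(float(res.pvalue), _P_FLOOR), n_tests, alpha,
    )


def residualize(y: Sequence[float], covariates: pd.DataFrame) -> np.ndarray:
    """Residuals of ``y`` after an ordinary least-squares fit on the
    covariate design (intercept always included).

    Categorical columns are one-hot encoded with the reference (first)
    level dropped. The design must be full rank after encoding; a rank
    deficiency raises an error naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(covariates):
        raise ValueError("y and covariate table lengths differ")
    design = _encode_design(covariates)
    if len(y) <= design.shape[1]:
        raise DomscanError(
            f"need more observations ({len(y)}) than design columns ({design.shape[1]})"
        )
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_columns(design)
        raise DomscanError(f"rank-deficient design; collinear columns: {collinear}")
    fit = sm.OLS(y, design.to_numpy()).fit()
    return np.asarray(fit.resid)


def _encode_design(covariates: pd.DataFrame) -> pd.DataFrame:
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        series = covariates[col]
        if series.nunique(dropna=False) <= 1:
            continue  # constant factors are absorbed by the intercept
        if pd.api.types.is_numeric_dtype(series):
            parts.append(series.astype(float))
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Greedy scan for columns that do not increase the design rank."""
    kept: list[int] = []
    collinear: list[str] = []
    arr = design.to_numpy()
    for j in range(arr.shape[1]):
        cand = arr[:, kept + [j]]
        if np.linalg.matrix_rank(cand) > len(kept):
            kept.append(j)
        else:
            collinear.append(str(design.columns[j]))
    return collinear


def bonferroni(alpha: float, m: int) -> float:
    """Per-experiment significance threshold alpha / m."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if m < 1:
        raise DomscanError("number of tests m must be >= 1")
    return alpha / m


def format_threshold(threshold: float, sig_figs: int = 3) -> str:
    """Display form at 3 significant figures, e.g. ``7.96e-08``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return f"{threshold:.{sig_figs - 1}e}"
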