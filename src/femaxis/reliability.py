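"""Reliability statistics for repeated DBHF measurements.

Implements the intraclass correlation coefficient in its two-way random,
absolute-agreement, single-measure form, ICC(2,1):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with MSR/MSC/MSE the subject, column (rater or repetition) and residual
mean squares of the two-way layout, and the 95% confidence interval via
the F-distribution bounds for this estimator.  Gender x side effects on
DBHF are compared by a two-way ANOVA with type-II sums of squares (the
conventional choice for mildly unbalanced cohorts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DesignError, UndefinedICCError


@dataclass(frozen=True)
class ICCResult:
    """ICC point estimate, 95% CI and the underlying mean squares."""

    icc: float
    ci_low: float
    ci_high: float
    model: str
    msr: float
    msc: float
    mse: float
    n_subjects: int
    k: int

    def summary(self) -> str:
        return (
            f"{self.model}\n"
            f"subjects n = {self.n_subjects}, columns k = {self.k}\n"
            f"MSR = {self.msr:.6g}, MSC = {self.msc:.6g}, MSE = {self.mse:.6g}\n"
            f"ICC = {self.icc:.3f}  95% CI {self.ci_low:.3f}-{self.ci_high:.3f}"
        )


def _as_grid(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        grid = table.to_numpy(dtype=float)
    else:
        grid = np.asarray(table, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise DesignError("measurement table needs >= 2 subjects and >= 2 columns")
    if not np.all(np.isfinite(grid)):
        raise DesignError("measurement table has missing or non-finite cells")
    return grid


def icc(table, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with a 95% (or 1-alpha) confidence interval.

    ``table`` is a subjects x columns grid (ndarray or DataFrame): columns
    are repetitions for intra-observer reliability, raters for
    inter-observer reliability.
    """
    x = _as_grid(table)
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand, atol=1e-12 * max(1.0, abs(grand))):
        raise UndefinedICCError("zero total variance; ICC is undefined")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_total = np.sum((x - grand) ** 2)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise UndefinedICCError("degenerate mean squares; ICC is undefined")
    est = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        lo = hi = est  # perfectly reproducible table; interval degenerates
    else:
        # Satterthwaite df for the F bounds of ICC(A,1)
        a = k * est / (n * (1.0 - est)) if est < 1 else np.inf
        b = 1.0 + k * est * (n - 1.0) / (n * (1.0 - est)) if est < 1 else np.inf
        if np.isfinite(a) and (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
        else:
            v = (n - 1) * (k - 1)
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        lo, hi = min(lo, est), max(hi, est)

    return ICCResult(
        icc=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        model="ICC(2,1) two-way random, absolute agreement, single measure",
        msr=float(msr),
        msc=float(msc),
        mse=float(mse),
        n_subjects=n,
        k=k,
    )


@dataclass(frozen=True)
class AnovaResult:
    """Per-term sums of squares, F and p for a two-factor design."""

    table: pd.DataFrame  # index: factor_a, factor_b, interaction, residual
    factor_a: str
    factor_b: str
    alpha: float = 0.05

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def summary(self) -> str:
        lines = [
            f"Two-way ANOVA (type II SS), alpha = {self.alpha}",
            self.table.to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)


def two_way_anova(
    data: pd.DataFrame,
    value: str = "dbhf",
    factor_a: str = "gender",
    factor_b: str = "side",
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way ANOVA with interaction on a long-form table.

    Each row is one femur; ``factor_a`` / ``factor_b`` are categorical
    columns (e.g. gender and side).  Unbalanced designs are handled with
    type-II sums of squares.  Every cell must contain at least two
    observations for the interaction term to be estimable.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    for col in (value, factor_a, factor_b):
        if col not in data.columns:
            raise DesignError(f"column {col!r} missing from the table")
    counts = data.groupby([factor_a, factor_b], observed=True).size().unstack()
    if counts.isna().any().any() or (counts < 2).any().any():
        raise DesignError(
            "every factor_a x factor_b cell needs >= 2 observations:\n"
            f"{counts}"
        )

    df = data.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    fit = smf.ols("_y ~ C(_a) * C(_b)", data=df).fit()
    raw = anova_lm(fit, typ=2)

    ss = raw["sum_sq"].to_numpy()
    dfree = raw["df"].to_numpy()
    ms = ss / dfree
    ss_scale = max(float(np.sum(ss)), 1e-300)
    ms_err, df_err = ms[-1], dfree[-1]
    out = []
    for i, term in enumerate(("factor_a", "factor_b", "interaction")):
        ss_i = max(ss[i], 0.0)
        if ss_i / ss_scale < 1e-12:
            ss_i = 0.0
        if ms_err / ss_scale < 1e-15:  # zero residual variance, exact design
            f = np.inf if ss_i > 0 else 0.0
            p = 0.0 if ss_i > 0 else 1.0
        else:
            f = (ss_i / dfree[i]) / ms_err
            p = float(sps.f.sf(f, dfree[i], df_err))
        out.append({"term": term, "ss": ss_i, "df": dfree[i], "ms": ss_i / dfree[i],
                    "F": f, "p": p})
    out.append(
        {"term": "residual", "ss": ss[-1], "df": df_err, "ms": ms_err,
         "F": np.nan, "p": np.nan}
    )
    table = pd.DataFrame(out).set_index("term")
    table.index = pd.Index(
        [factor_a, factor_b, f"{factor_a}:{factor_b}", "residual"], name="term"
    )
    return AnovaResult(table=table, factor_a=factor_a, factor_b=factor_b, alpha=alpha)
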