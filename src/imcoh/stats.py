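"""Group-level inference for the subject metrics table.

Implements the study-style inference layer: pooled-variance two-sample t-test
with Cohen's d, Box-Cox normalization of the (often skewed, sometimes zero)
coherence volumes, 2 (limb) x 2 (muscle pair) ANCOVAs with four covariates
(window mean angle, window mean velocity, age, antagonist co-contraction)
using Type-III sums of squares and sum-to-zero factor coding, and a partial
Spearman correlation with an optional +/- 2-residual-SE outlier rule.

The ANCOVA significance level is Bonferroni-style corrected to alpha = 0.017
(three limb contrasts); each contrast is a separate fit on the two limbs it
compares, not one three-limb model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

ANCOVA_ALPHA = 0.017
COVARIATES = ("mean_angle", "mean_velocity", "age", "cocontraction")


@dataclass
class StatResult:
    """One inferential result: test statistic, p, effect size and metadata."""

    name: str
    statistic: float
    df: float
    p: float
    effect: float = float("nan")
    effect_name: str = ""
    ci: tuple[float, float] | None = None
    df2: float | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# t-test and Box-Cox


def two_sample_t(a, b) -> StatResult:
    """Pooled-variance two-sample t-test with Cohen's d and its 95 % CI.

    df = n1 + n2 - 2; d uses the pooled SD; the CI uses the standard
    normal-approximation standard error of d.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return StatResult("t", 0.0, n1 + n2 - 2, 1.0, 0.0, "cohen_d", (0.0, 0.0))
        raise ValueError("zero pooled variance with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2 - 2)))
    ci = (d - 1.96 * se_d, d + 1.96 * se_d)
    return StatResult(
        "t", float(t), n1 + n2 - 2, float(p), float(d), "cohen_d", ci,
        extra={"ci_method": "normal-approximation SE of d"},
    )


def boxcox(values, offset: float | None = None) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with profile-ML lambda.

    ``y(lambda) = (y**lambda - 1)/lambda`` (log for lambda = 0).  Coherence
    volumes can be exactly zero (no significant cells), so when non-positive
    values are present an offset of half the smallest positive value is added
    first (recorded in the returned metadata).  Returns
    ``(transformed, lambda, offset)``.
    """
    y = np.asarray(values, dtype=float)
    if offset is None:
        if np.any(y <= 0):
            positive = y[y > 0]
            if positive.size == 0:
                raise ValueError("Box-Cox needs at least one positive value")
            offset = float(positive.min() / 2)
        else:
            offset = 0.0
    y = y + offset
    if np.any(y <= 0):
        raise ValueError("non-positive values remain after offset")
    transformed, lam = sps.boxcox(y)
    return transformed, float(lam), offset


# ---------------------------------------------------------------------------
# ANCOVA


def check_balanced(table: pd.DataFrame, factors: tuple[str, str] = ("limb", "muscle_pair")) -> None:
    counts = table.groupby(list(factors), observed=True).size()
    if counts.nunique() != 1:
        raise ValueError(f"unbalanced design; cell counts:\n{counts}")


def ancova_limb_by_pair(
    table: pd.DataFrame,
    limbs: tuple[str, str],
    response: str = "imc_volume",
    alpha: float = ANCOVA_ALPHA,
    transform: bool = True,
    covariates: tuple[str, ...] = COVARIATES,
) -> dict[str, StatResult]:
    """2 (limb) x 2 (muscle pair) ANCOVA on Box-Cox-transformed volumes.

    The model contains limb, muscle pair, their interaction and the four
    covariates; per-term F, p and partial eta^2 are computed from Type-III
    sums of squares with sum-to-zero factor coding.  The design must be
    balanced across the limb x pair cells.  Terms are flagged significant at
    the corrected ``alpha``.
    """
    sub = table[table["limb"].isin(limbs)].copy()
    if sub.empty or sub["limb"].nunique() != 2:
        raise ValueError(f"table does not contain both limbs {limbs}")
    check_balanced(sub)
    meta: dict = {}
    if transform:
        sub["_y"], lam, off = boxcox(sub[response].to_numpy())
        meta = {"boxcox_lambda": lam, "boxcox_offset": off}
    else:
        sub["_y"] = sub[response]
    formula = "_y ~ C(limb, Sum) * C(muscle_pair, Sum)"
    if covariates:
        formula += " + " + " + ".join(covariates)
    model = smf.ols(formula, data=sub).fit()
    tab = anova_lm(model, typ=3)
    ss_err = float(tab.loc["Residual", "sum_sq"])
    df_err = float(tab.loc["Residual", "df"])
    rename = {
        "C(limb, Sum)": "limb",
        "C(muscle_pair, Sum)": "muscle_pair",
        "C(limb, Sum):C(muscle_pair, Sum)": "limb:muscle_pair",
    }
    out: dict[str, StatResult] = {}
    for row in tab.index:
        if row in ("Intercept", "Residual"):
            continue
        name = rename.get(row, row)
        ss = float(tab.loc[row, "sum_sq"])
        out[name] = StatResult(
            name=name,
            statistic=float(tab.loc[row, "F"]),
            df=float(tab.loc[row, "df"]),
            df2=df_err,
            p=float(tab.loc[row, "PR(>F)"]),
            effect=ss / (ss + ss_err),
            effect_name="partial_eta2",
            extra={
                "significant": bool(tab.loc[row, "PR(>F)"] < alpha),
                "alpha": alpha,
                "ss_type": "III (sum-to-zero coding)",
                **meta,
            },
        )
    return out


# ---------------------------------------------------------------------------
# partial Spearman


def partial_spearman(
    x,
    y,
    covariates=None,
    drop_outliers: bool = False,
    outlier_on: str = "either",
) -> StatResult:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    All variables are rank-transformed; the ranks of ``x`` and ``y`` are each
    regressed on the covariate ranks (plus intercept) and the Pearson
    correlation of the two residual vectors is the partial rho.  p comes from
    the t distribution with ``n - 2 - k`` df and the 95 % CI from the Fisher
    z transform.  With ``drop_outliers`` points whose residual magnitude
    exceeds two residual standard errors in the x-model, the y-model or
    either (``outlier_on``) are removed and the correlation recomputed; the
    dropped indices are reported in ``extra["outliers"]``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y lengths differ")
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("covariate rows must match len(x)")
    k = Z.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > k + 3 observations (n={n}, k={k})")

    def ranks(v: np.ndarray) -> np.ndarray:
        r = sps.rankdata(v)
        if np.ptp(r) == 0:
            raise ValueError("constant ranks")
        return r

    rx, ry = ranks(x), ranks(y)
    rz = np.column_stack([ranks(Z[:, j]) for j in range(k)]) if k else np.empty((n, 0))
    design = np.column_stack([np.ones(n), rz])

    def residuals(v: np.ndarray) -> np.ndarray:
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    ex, ey = residuals(rx), residuals(ry)

    keep = np.ones(n, dtype=bool)
    outliers: list[int] = []
    if drop_outliers:
        dof = n - (k + 1)
        se_x = np.sqrt(np.sum(ex**2) / dof)
        se_y = np.sqrt(np.sum(ey**2) / dof)
        out_x = np.abs(ex) > 2 * se_x
        out_y = np.abs(ey) > 2 * se_y
        flag = {"either": out_x | out_y, "x": out_x, "y": out_y}.get(outlier_on)
        if flag is None:
            raise ValueError(f"unknown outlier rule {outlier_on!r}")
        outliers = list(np.flatnonzero(flag))
        if outliers:
            keep = ~flag
            return_res = partial_spearman(x[keep], y[keep],
                                          Z[keep] if k else None, drop_outliers=False)
            return_res.extra.update({"outliers": outliers, "n_used": int(keep.sum())})
            return return_res

    denom = np.sqrt(np.sum(ex**2) * np.sum(ey**2))
    if denom == 0:
        raise ValueError("degenerate residuals")
    rho = float(np.clip(np.sum(ex * ey) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    if abs(rho) < 1.0 and n > k + 3:
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - k - 3)
        ci = (float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se)))
    else:
        ci = (rho, rho)
    return StatResult(
        "partial_spearman_rho", rho, df, p, rho, "rho", ci,
        extra={"n_used": n, "outliers": outliers, "k_covariates": k},
    )


# ---------------------------------------------------------------------------
# demographics


def demographics_summary(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) per numeric column, with printed-style ints.

    Clinical demographic tables conventionally print integer summaries; the
    ``printed_mean``/``printed_sd`` columns use truncation toward zero, the
    convention this package adopts for such tables.  Single-value columns
    raise (SD undefined).
    """
    if columns is None:
        columns = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if not columns:
        raise ValueError("no numeric columns")
    rows = []
    for c in columns:
        v = table[c].dropna().to_numpy(dtype=float)
        if v.size == 0:
            raise ValueError(f"column {c!r} is empty")
        if v.size < 2:
            raise ValueError(f"column {c!r} has a single value: SD undefined")
        mean, sd = v.mean(), v.std(ddof=1)
        rows.append(
            dict(column=c, n=v.size, mean=mean, sd=sd,
                 printed_mean=int(mean), printed_sd=int(sd))
        )
    return pd.DataFrame(rows).set_index("column")
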