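"""Group-level statistics for ISC, SSVEP, and spectrum summaries.

Procedures: Pearson age correlations with Benjamini–Hochberg FDR control
across the stimulus family; a young/old median split (with an optional fixed
age boundary for replication runs); two-way main-effects ANOVA with Type II
sums of squares for unbalanced designs; Tukey–Kramer post hoc pairwise
comparisons; and residualization of ISC on SSVEP amplitude to control for
evoked-response strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .io_core import ValidationError


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    fdr_significant: bool | None = None


def correlate_with_age(
    values: np.ndarray,
    ages: np.ndarray,
    fdr_q: float = 0.05,
    family: list[float] | None = None,
) -> CorrelationResult:
    """Pearson correlation of a per-subject measure with age.

    When ``family`` (the p-values of the sibling tests across stimuli,
    including this one's) is given, the FDR flag reports whether this test
    survives Benjamini–Hochberg at ``fdr_q`` within that family.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.ndim != 1:
        raise ValidationError("values and ages must be equal-length vectors")
    if len(values) < 3:
        raise ValidationError("need at least 3 paired observations")
    if np.std(values) == 0 or np.std(ages) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = sps.pearsonr(values, ages)
    fdr_flag = None
    if family is not None:
        fam = np.asarray(list(family), dtype=float)
        if not np.any(np.isclose(fam, p)):
            fam = np.append(fam, p)  # the family must contain this test
        reject = benjamini_hochberg(fam, fdr_q)
        own = int(np.argmin(np.abs(fam - p)))
        fdr_flag = bool(reject[own])
    return CorrelationResult(r=float(r), p=float(p), n=len(values), fdr_significant=fdr_flag)


def benjamini_hochberg(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """BH step-up rejection decisions for a family of p-values."""
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


def median_split(
    table: pd.DataFrame,
    fixed_boundary: float | None = None,
    column: str = "age_group",
) -> pd.DataFrame:
    """Label subjects young/old at the cohort median age (or a fixed age).

    Ages at or below the boundary are "young", above it "old".  With
    ``fixed_boundary`` the split reproduces a previously chosen boundary
    (e.g. 14 yr) instead of this cohort's median.
    """
    if len(table) < 2:
        raise ValidationError("need at least 2 subjects to split")
    boundary = fixed_boundary if fixed_boundary is not None else float(
        table["age"].median()
    )
    out = table.copy()
    out[column] = np.where(out["age"] <= boundary, "young", "old")
    if (out[column] == "young").all() or (out[column] == "old").all():
        warnings.warn("median split produced a single group (degenerate ages)")
    return out


def two_way_anova(
    values: np.ndarray,
    factor_a: list[str],
    factor_b: list[str],
) -> dict:
    """Additive two-way ANOVA (main effects only), Type II sums of squares.

    Returns F, p, and degrees of freedom for each factor.  Type II SS keeps
    the main-effect tests meaningful for the unbalanced group sizes an
    observational cohort produces.
    """
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": factor_a, "b": factor_b}
    )
    for name in ("a", "b"):
        if df[name].nunique() < 2:
            raise ValidationError(f"factor {name!r} needs at least 2 levels")
    cells = df.groupby(["a", "b"], observed=True).size()
    full = df["a"].nunique() * df["b"].nunique()
    if len(cells) < full:
        present = set(cells.index)
        missing = [
            (a, b)
            for a in df["a"].unique()
            for b in df["b"].unique()
            if (a, b) not in present
        ]
        raise ValidationError(f"empty design cells: {missing}")
    model = smf.ols("y ~ C(a) + C(b)", data=df).fit()
    table = anova_lm(model, typ=2)
    return {
        "F_a": float(table.loc["C(a)", "F"]),
        "p_a": float(table.loc["C(a)", "PR(>F)"]),
        "F_b": float(table.loc["C(b)", "F"]),
        "p_b": float(table.loc["C(b)", "PR(>F)"]),
        "df_a": float(table.loc["C(a)", "df"]),
        "df_b": float(table.loc["C(b)", "df"]),
        "df_resid": float(table.loc["Residual", "df"]),
    }


def tukey_hsd(
    values: np.ndarray,
    labels: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey–Kramer pairwise comparisons (valid for unequal group sizes).

    Groups of size 1 are excluded with a warning — they carry no
    within-group variance.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    singles = counts[counts < 2].index.tolist()
    if singles:
        warnings.warn(f"excluding size-1 groups from Tukey HSD: {singles}")
        keep = ~np.isin(labels, singles)
        values, labels = values[keep], labels[keep]
    if pd.Series(labels).nunique() < 2:
        raise ValidationError("need at least 2 groups of size >= 2")
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    frame["p-adj"] = res.pvalues  # full precision, not the rounded summary
    return frame


def residualize_isc(
    isc: pd.Series | np.ndarray,
    ssvep: pd.Series | np.ndarray,
) -> np.ndarray:
    """Residual ISC after regressing out SSVEP amplitude (OLS with intercept).

    Pandas inputs are inner-joined on their index (subject id); arrays are
    assumed aligned.  Residuals are mean zero and orthogonal to SSVEP.
    """
    if isinstance(isc, pd.Series) and isinstance(ssvep, pd.Series):
        joined = pd.concat({"isc": isc, "ssvep": ssvep}, axis=1, join="inner")
        y = joined["isc"].to_numpy(dtype=float)
        x = joined["ssvep"].to_numpy(dtype=float)
    else:
        y = np.asarray(isc, dtype=float)
        x = np.asarray(ssvep, dtype=float)
        if y.shape != x.shape:
            raise ValidationError("unaligned ISC and SSVEP vectors")
    if len(y) < 3:
        raise ValidationError("need at least 3 paired subjects")
    design = sm.add_constant(x)
    return np.asarray(sm.OLS(y, design).fit().resid)
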