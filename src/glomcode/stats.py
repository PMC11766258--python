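"""Shared statistical machinery for the odour-coding pipeline.

Provides the small set of procedures every analysis stage relies on:
a Kolmogorov-Smirnov normality check (advisory, attached to downstream
results rather than gating them), n-way fixed-effects ANOVA with
configurable interaction order, Benjamini-Hochberg FDR adjustment, and
FDR-corrected families of two-sample contrasts on marginal means.

ANOVA uses partial (Type-II-style) sums of squares so that unbalanced
designs -- e.g. glomeruli missing in some flies -- are handled without
order dependence.  Post-hoc contrasts are pooled-variance two-sample
t-tests on the relevant marginal means, adjusted within an explicitly
declared family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KSNormalityResult",
    "ks_normality",
    "nway_anova",
    "fdr_adjust",
    "group_contrasts",
    "pairwise_contrasts",
]


@dataclass(frozen=True)
class KSNormalityResult:
    """One-sample KS test of a sample against a normal with its own mean/sd."""

    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False

    @property
    def normal_at(self) -> float:
        return self.pvalue


def ks_normality(sample) -> KSNormalityResult:
    """Kolmogorov-Smirnov check of approximate normality.

    The reference distribution is a normal parameterised by the sample
    mean and standard deviation.  The result is advisory: it is recorded
    alongside ANOVA output, it does not switch the analysis.

    Parameters
    ----------
    sample : array-like, n >= 5

    Returns
    -------
    KSNormalityResult
        ``degenerate`` is set (with NaN statistic) for constant samples,
        for which the test is undefined.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError(f"need at least 5 finite observations, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0.0:
        return KSNormalityResult(np.nan, np.nan, x.size, degenerate=True)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return KSNormalityResult(float(stat), float(p), x.size)


def _term_label(combo: tuple[str, ...]) -> str:
    return ":".join(combo)


def nway_anova(
    table: pd.DataFrame,
    response: str,
    factors: list[str] | tuple[str, ...],
    max_order: int = 2,
) -> pd.DataFrame:
    """Fixed-effects n-way ANOVA with interactions up to ``max_order``.

    Partial (Type-II) sums of squares are used, so term tests do not
    depend on factor order in unbalanced designs.  On balanced designs
    this coincides with the textbook decomposition.

    Parameters
    ----------
    table : DataFrame containing ``response`` and all ``factors``.
    response : name of the (finite, numeric) response column.
    factors : categorical factor columns.
    max_order : highest interaction order to include (1 = main effects only).

    Returns
    -------
    DataFrame with columns ``term, df, sum_sq, F, p`` (residual row
    included, F and p NaN there).  A ``rank_deficient`` attribute in
    ``DataFrame.attrs`` lists aliased terms if the design matrix is
    singular; they are reported, never silently dropped.
    """
    if not factors:
        raise ValueError("at least one factor required")
    missing = [c for c in (response, *factors) if c not in table.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    y = pd.to_numeric(table[response], errors="raise")
    if not np.isfinite(y.to_numpy(dtype=float)).all():
        raise ValueError(f"non-finite values in response {response!r}")
    dropped = [f for f in factors if table[f].nunique() < 2]
    factors = [f for f in factors if f not in dropped]
    if not factors:
        raise ValueError("no factor has at least two levels")

    max_order = min(max_order, len(factors))
    terms: list[tuple[str, ...]] = []
    for order in range(1, max_order + 1):
        terms.extend(itertools.combinations(factors, order))
    rhs = " + ".join(
        ":".join(f"C(Q('{f}'))" for f in combo) for combo in terms
    )
    model = ols(f"Q('{response}') ~ {rhs}", data=table).fit()

    aliased: list[str] = []
    rank = np.linalg.matrix_rank(model.model.exog)
    if rank < model.model.exog.shape[1]:
        aliased = ["<design matrix rank-deficient: some terms aliased>"]

    aov = anova_lm(model, typ=2)
    out = aov.reset_index().rename(
        columns={"index": "term", "PR(>F)": "p", "sum_sq": "sum_sq", "F": "F"}
    )

    def clean(name: str) -> str:
        return name.replace("C(Q('", "").replace("'))", "")

    out["term"] = out["term"].map(clean)
    out = out[["term", "df", "sum_sq", "F", "p"]]
    # a term explaining (numerically) zero variance has no effect by convention
    y_arr = y.to_numpy(dtype=float)
    total_ss = float(((y_arr - y_arr.mean()) ** 2).sum())
    tol = max(total_ss, 1.0) * 1e-12
    zero = (out["sum_sq"] <= tol) & (out["term"] != "Residual")
    out.loc[zero, "F"] = 0.0
    out.loc[zero, "p"] = 1.0
    out.attrs["rank_deficient"] = aliased
    out.attrs["dropped_factors"] = dropped  # single-level factors, untestable
    out.attrs["n_obs"] = int(model.nobs)
    if aliased:
        out.attrs["warning"] = "aliased terms present; interpret with care"
    return out


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone in the ranks and independent of the input ordering.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-sample pooled-variance t-test; returns (t, df, p)."""
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    if se == 0.0:
        t = 0.0 if a.mean() == b.mean() else np.inf * np.sign(a.mean() - b.mean())
    else:
        t = (a.mean() - b.mean()) / se
    p = 2 * sps.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    return float(t), float(df), float(p)


def group_contrasts(
    table: pd.DataFrame,
    value: str,
    group: str,
    between: str,
    alpha: float = 0.05,
    groups: list | None = None,
) -> pd.DataFrame:
    """Per-group two-level contrasts with FDR adjustment across the family.

    For each level of ``group`` (e.g. each glomerulus), the two levels of
    ``between`` (e.g. the two species) are compared with a pooled-variance
    t-test on the marginal observations; p-values are BH-adjusted across
    all groups, which constitute one declared family.

    Returns a DataFrame with per-group means, difference, t, p, adjusted
    p, significance flag at ``alpha`` and effect direction (the level of
    ``between`` with the larger mean; empty string for exact ties).
    """
    levels = sorted(table[between].unique())
    if len(levels) != 2:
        raise ValueError(f"{between!r} must have exactly 2 levels, got {levels}")
    la, lb = levels
    present = list(pd.unique(table[group]))
    if groups is None:
        groups = present
    else:
        unknown = [g for g in groups if g not in present]
        if unknown:
            raise ValueError(f"unknown {group!r} levels requested: {unknown}")

    rows = []
    for g in groups:
        sub = table[table[group] == g]
        a = sub.loc[sub[between] == la, value].to_numpy(dtype=float)
        b = sub.loc[sub[between] == lb, value].to_numpy(dtype=float)
        t, df, p = _pooled_t(a, b)
        rows.append(
            {
                group: g,
                f"mean_{la}": a.mean(),
                f"mean_{lb}": b.mean(),
                "diff": a.mean() - b.mean(),
                "t": t,
                "df": df,
                "p": p,
                "n_a": a.size,
                "n_b": b.size,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    out["direction"] = np.where(
        out["diff"] > 0, la, np.where(out["diff"] < 0, lb, "")
    )
    out.attrs["family"] = f"{group} contrasts ({len(out)} tests), BH at {alpha}"
    return out


def pairwise_contrasts(
    table: pd.DataFrame,
    value: str,
    category: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All unordered pairwise contrasts among the levels of ``category``.

    Pooled-variance t-tests on the marginal observations of each pair;
    BH adjustment across the full set of pairs (one family).
    """
    levels = list(pd.unique(table[category]))
    if len(levels) < 2:
        raise ValueError("need at least two category levels")
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        a = table.loc[table[category] == la, value].to_numpy(dtype=float)
        b = table.loc[table[category] == lb, value].to_numpy(dtype=float)
        t, df, p = _pooled_t(a, b)
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "diff": a.mean() - b.mean(),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_adjust(out["p"].to_numpy())
    out["significant"] = out["p_fdr"] < alpha
    return out
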