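"""Four-choice trap-assay analysis.

Groups of flies choose among four baited traps (bait 1, bait 2, a
paraffin-oil control and an empty control) or remain on the release
platform.  Preference is quantified as the proportion of recovered
flies per trap; by default the denominator includes platform flies
(flies lost between release and counting are ignored, never imputed).

Within one bait-1 family (all conditions sharing the same reference
odour), the bait-2 trap proportion is analysed with a two-way ANOVA
(factors: bait-2 identity and species), preceded by an advisory KS
normality check, followed by FDR-corrected pairwise comparisons among
trap categories within each species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from . import stats

__all__ = ["TRAP_CATEGORIES", "proportions", "BehaviourTestResult", "behaviour_test"]

TRAP_CATEGORIES = ("bait1", "bait2", "oil", "empty")


def proportions(
    counts: pd.DataFrame,
    include_platform: bool = True,
) -> pd.DataFrame:
    """Per-replicate trap proportions in %.

    The denominator is the sum of the four trap counts plus, when
    ``include_platform`` (default), the platform count.  Replicates with
    zero recovered flies are excluded with a warning.  Returns a long
    table with one row per (replicate, category); per-replicate
    percentages sum to 100 over the included categories.
    """
    cats = list(TRAP_CATEGORIES) + (["platform"] if include_platform else [])
    missing = [c for c in cats if c not in counts.columns]
    if missing:
        raise ValueError(f"count columns missing: {missing}")
    if (counts[cats] < 0).any().any():
        raise ValueError("counts must be non-negative")
    df = counts.copy()
    total = df[cats].sum(axis=1)
    zero = total == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} replicate(s) with zero recovered flies excluded",
            stacklevel=2,
        )
        df = df[~zero]
        total = total[~zero]
    id_cols = [c for c in df.columns if c not in cats]
    long = df.melt(
        id_vars=id_cols, value_vars=cats, var_name="category", value_name="count"
    )
    denom = long[id_cols].merge(
        df[id_cols].assign(total=total), on=id_cols, how="left"
    )["total"]
    long["pct"] = 100.0 * long["count"] / denom.to_numpy()
    long.attrs["denominator"] = (
        "four traps + platform" if include_platform else "four traps"
    )
    return long


@dataclass
class BehaviourTestResult:
    """ANOVA and post-hoc contrasts for one bait-1 family."""

    bait1: str
    anova: pd.DataFrame
    posthoc: dict[str, pd.DataFrame]  # species -> pairwise category contrasts
    normality: stats.KSNormalityResult
    n_replicates: pd.DataFrame


def behaviour_test(
    prop: pd.DataFrame,
    bait1: str,
    alpha: float = 0.05,
) -> BehaviourTestResult:
    """Two-way ANOVA (bait-2 identity x species) within one bait-1 family.

    The response is the bait-2 trap proportion per replicate.  Post-hoc:
    within each species and condition, FDR-corrected pairwise
    pooled-variance comparisons among the trap categories (one BH family
    per species).  Raw proportions are analysed directly, with a KS
    normality check attached as advisory metadata.
    """
    fam = prop[prop["bait1_odour"] == bait1]
    if fam.empty:
        raise ValueError(f"no conditions with bait1 {bait1!r}")
    b2 = fam[fam["category"] == "bait2"]
    cell_n = (
        b2.groupby(["species", "bait2_odour"], observed=True)
        .size()
        .reset_index(name="n")
    )
    if (cell_n["n"] < 2).any():
        raise ValueError("need >= 2 replicates per (species, bait2) cell")
    aov = stats.nway_anova(b2, "pct", ["bait2_odour", "species"], max_order=2)
    ks = stats.ks_normality(b2["pct"])

    posthoc: dict[str, pd.DataFrame] = {}
    for sp in sorted(fam["species"].unique()):
        sub = fam[(fam["species"] == sp) & fam["category"].isin(TRAP_CATEGORIES)]
        pieces = []
        for cond, cond_sub in sub.groupby("condition", observed=True):
            pc = stats.pairwise_contrasts(cond_sub, "pct", "category", alpha)
            pc.insert(0, "condition", cond)
            pieces.append(pc)
        combined = pd.concat(pieces, ignore_index=True)
        # one FDR family per species, across all conditions and pairs
        combined["p_fdr"] = stats.fdr_adjust(combined["p"].to_numpy())
        combined["significant"] = combined["p_fdr"] < alpha
        posthoc[sp] = combined
    return BehaviourTestResult(bait1, aov, posthoc, ks, cell_n)
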