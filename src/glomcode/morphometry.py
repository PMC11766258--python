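"""Glomerular volume morphometry and species comparison.

One species' antennal lobe can be globally larger (a pure scale
difference), so individual glomeruli are compared on their *relative*
volume, each glomerulus as a percentage of the total AL volume of that
fly (and side).  Relative volumes are invariant under any per-fly
global scaling, so a pure AL-size difference produces no species main
effect after normalization; genuine reallocations of volume between
glomeruli survive as species-glomerulus interactions.

By default the "total" is the sum of the listed (identified) glomeruli;
a separately measured whole-AL total can be supplied instead, in which
case per-fly relative volumes sum to less than 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import stats

__all__ = ["relative_volumes", "VolumeTestResult", "volume_species_test"]


def relative_volumes(
    volumes: pd.DataFrame,
    total_mode: str = "sum",
    totals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Relative glomerular volumes in % of the total AL volume.

    Parameters
    ----------
    volumes : rows (species, fly, side, glomerulus) with ``volume_um3``.
    total_mode : ``"sum"`` (total = sum of listed glomeruli per fly/side)
        or ``"supplied"`` (join per-(species, fly, side) totals).
    totals : required for ``"supplied"``; columns (species, fly, side,
        total_um3).

    Returns the input with an added ``relative_pct`` column and a
    ``total_mode`` entry in ``DataFrame.attrs``.
    """
    if (volumes["volume_um3"] <= 0).any():
        raise ValueError("volumes must be positive")
    out = volumes.copy()
    keys = ["species", "fly", "side"]
    if total_mode == "sum":
        tot = out.groupby(keys, observed=True)["volume_um3"].transform("sum")
    elif total_mode == "supplied":
        if totals is None:
            raise ValueError("totals table required for total_mode='supplied'")
        merged = out.merge(totals, on=keys, how="left", validate="many_to_one")
        if merged["total_um3"].isna().any():
            missing = merged.loc[merged["total_um3"].isna(), keys].drop_duplicates()
            raise ValueError(f"no supplied total for:\n{missing}")
        tot = merged["total_um3"].to_numpy()
    else:
        raise ValueError(f"unknown total_mode {total_mode!r}")
    out["relative_pct"] = 100.0 * out["volume_um3"] / tot
    out.attrs["total_mode"] = total_mode
    return out


@dataclass
class VolumeTestResult:
    """Two-way ANOVA on relative volume plus per-glomerulus contrasts."""

    anova: pd.DataFrame
    contrasts: pd.DataFrame
    normality: stats.KSNormalityResult

    @property
    def significant(self) -> pd.DataFrame:
        return self.contrasts[self.contrasts["significant"]]


def volume_species_test(
    relative: pd.DataFrame, alpha: float = 0.05
) -> VolumeTestResult:
    """Species x glomerulus ANOVA on relative volumes, with FDR post-hoc.

    The ANOVA (partial SS, species and glomerulus main effects plus
    their interaction) tests whether the relative-volume normalization
    removed the general species dependence and whether volume is
    reallocated between glomeruli across species; per-glomerulus species
    contrasts (pooled-variance t, BH-adjusted across the glomerulus
    family) localise the interaction and report effect direction.
    """
    if "relative_pct" not in relative.columns:
        raise ValueError("run relative_volumes() first")
    counts = relative.groupby("species", observed=True)["fly"].nunique()
    if (counts < 2).any():
        raise ValueError("need >= 2 flies per species")
    aov = stats.nway_anova(
        relative, "relative_pct", ["species", "glomerulus"], max_order=2
    )
    contrasts = stats.group_contrasts(
        relative, "relative_pct", "glomerulus", "species", alpha
    )
    ks = stats.ks_normality(relative["relative_pct"])
    return VolumeTestResult(aov, contrasts, ks)
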