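"""From fluorescence movies and traces to response-amplitude tables.

The chain implemented here is the standard calcium-imaging one: mean
region fluorescence per frame, relative change dF/F(t) = (F(t) - Fb)/Fb
against the mean pre-stimulus baseline Fb, averaging over repeated
stimulus trials, the mean dF/F during the stimulus window as the scalar
response amplitude, a cross-species rescaling that equalises the grand
mean amplitude of the two species, and pooling of left/right brain
sides when no side effect is detectable.

Missing (fly, glomerulus) combinations remain explicit missing rows;
nothing is imputed.  Downstream coding-space operations use complete
cases only and report how many entered each comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GlomerulusMask, StimulusProtocol
from . import stats

__all__ = [
    "TraceSet",
    "extract_traces",
    "dff",
    "trial_average",
    "amplitude",
    "amplitude_table",
    "cross_species_normalize",
    "SideTestResult",
    "side_effect_test",
    "pool_sides",
]

KEY_COLUMNS = ("species", "fly", "side", "plane", "glomerulus", "odour", "trial")


@dataclass
class TraceSet:
    """Stimulus-locked fluorescence traces with their identifying keys.

    ``values`` is (n_traces, n_frames) raw fluorescence; ``keys`` holds
    one row per trace with columns ``species, fly, side, plane,
    glomerulus, odour, trial``.
    """

    values: np.ndarray
    keys: pd.DataFrame
    protocol: StimulusProtocol

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_traces, n_frames)")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite trace values")
        if self.values.shape[1] != self.protocol.n_frames:
            raise ValueError(
                f"trace length {self.values.shape[1]} != protocol "
                f"n_frames {self.protocol.n_frames}"
            )
        missing = [c for c in KEY_COLUMNS if c not in self.keys.columns]
        if missing:
            raise ValueError(f"key columns missing: {missing}")
        if len(self.keys) != self.values.shape[0]:
            raise ValueError("keys and values row counts differ")
        if self.keys.duplicated(subset=list(KEY_COLUMNS)).any():
            raise ValueError("duplicate trace keys")

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_long(self) -> pd.DataFrame:
        """Long-format table, one row per (trace, frame)."""
        n_tr, n_fr = self.values.shape
        rep = self.keys.loc[self.keys.index.repeat(n_fr)].reset_index(drop=True)
        rep["frame"] = np.tile(np.arange(n_fr), n_tr)
        rep["value"] = self.values.reshape(-1)
        return rep

    @classmethod
    def from_long(cls, df: pd.DataFrame, protocol: StimulusProtocol) -> "TraceSet":
        keycols = list(KEY_COLUMNS)
        df = df.sort_values(keycols + ["frame"], kind="stable")
        grouped = df.groupby(keycols, sort=True, observed=True)
        keys = []
        rows = []
        for key, sub in grouped:
            if len(sub) != protocol.n_frames:
                raise ValueError(
                    f"trace {key} has {len(sub)} frames, expected {protocol.n_frames}"
                )
            keys.append(key)
            rows.append(sub["value"].to_numpy())
        return cls(np.asarray(rows), pd.DataFrame(keys, columns=keycols), protocol)


def extract_traces(
    movie: np.ndarray,
    mask: GlomerulusMask,
) -> tuple[np.ndarray, list[str]]:
    """Mean fluorescence per labelled region per frame.

    Parameters
    ----------
    movie : (n_frames, H, W) image stack.
    mask : label image matching the frame shape.

    Returns
    -------
    traces : (n_regions, n_frames) array, rows ordered by ascending label.
    names : glomerulus name per row.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3:
        raise ValueError("movie must be (n_frames, H, W)")
    if movie.shape[1:] != mask.labels.shape:
        raise ValueError(
            f"mask shape {mask.labels.shape} != frame shape {movie.shape[1:]}"
        )
    flat = movie.reshape(movie.shape[0], -1)
    lab = mask.labels.reshape(-1)
    traces = []
    names = []
    for label in mask.sorted_labels:
        idx = np.flatnonzero(lab == label)
        if idx.size == 0:
            raise ValueError(f"empty region for label {label}")
        traces.append(flat[:, idx].mean(axis=1))
        names.append(mask.names[label])
    return np.asarray(traces), names


def dff(
    trace: np.ndarray,
    protocol: StimulusProtocol | None = None,
    baseline: tuple[int, int] | None = None,
) -> np.ndarray:
    """Relative fluorescence change (F(t) - Fb)/Fb.

    Fb is the mean over the pre-stimulus baseline window, by default all
    frames from trace start to stimulus onset; ``baseline`` overrides it
    as a half-open (start, end) frame window.  Works on a single trace
    or a (n_traces, n_frames) stack.  dff is invariant under positive
    rescaling of F.
    """
    x = np.asarray(trace, dtype=float)
    one = x.ndim == 1
    if one:
        x = x[None]
    if baseline is None:
        if protocol is None:
            raise ValueError("need a protocol or an explicit baseline window")
        baseline = (0, protocol.stim_onset)
    b0, b1 = baseline
    if not (0 <= b0 < b1 <= x.shape[1]):
        raise ValueError(f"empty or out-of-range baseline window {baseline}")
    if protocol is not None and b1 > protocol.stim_onset:
        raise ValueError("baseline window must precede stimulus onset")
    fb = x[:, b0:b1].mean(axis=1)
    if np.any(fb <= 0):
        bad = np.flatnonzero(fb <= 0)[:5]
        raise ValueError(f"non-positive baseline Fb in traces {list(bad)}")
    out = (x - fb[:, None]) / fb[:, None]
    return out[0] if one else out


def trial_average(trials: np.ndarray) -> tuple[np.ndarray, int]:
    """Pointwise mean over trials; returns (mean course, n contributing)."""
    x = np.asarray(trials, dtype=float)
    if x.ndim == 1:
        x = x[None]
    if x.shape[0] < 1:
        raise ValueError("need at least one trial")
    return x.mean(axis=0), x.shape[0]


def amplitude(course: np.ndarray, protocol: StimulusProtocol) -> float:
    """Mean dF/F over the half-open stimulus window [onset, offset)."""
    x = np.asarray(course, dtype=float)
    if x.ndim != 1:
        raise ValueError("amplitude expects a single time course")
    if protocol.stim_offset > x.size:
        raise ValueError("stimulus window extends past trace end")
    return float(x[protocol.stim_slice].mean())


def amplitude_table(
    traces: TraceSet,
    baseline: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per-(species, fly, side, glomerulus, odour) mean stimulus amplitude.

    Computes dF/F per trace, the stimulus-window mean per trial, then the
    mean over trials (identical, by linearity, to the stimulus-window
    mean of the trial-averaged course).  The number of trials entering
    each cell is recorded; provenance is marked ``raw``.
    """
    rel = dff(traces.values, traces.protocol, baseline)
    amp = rel[:, traces.protocol.stim_slice].mean(axis=1)
    df = traces.keys.copy()
    df["amplitude"] = amp
    grouped = (
        df.groupby(["species", "fly", "side", "glomerulus", "odour"], observed=True)
        .agg(amplitude=("amplitude", "mean"), n_trials=("amplitude", "size"))
        .reset_index()
    )
    grouped["provenance"] = "raw"
    return grouped


def cross_species_normalize(amps: pd.DataFrame) -> pd.DataFrame:
    """Rescale each species so both grand-mean amplitudes are equal.

    Each species' amplitudes are multiplied by (mean of the two species
    means) / (that species' mean over all stimuli, glomeruli and flies).
    Within-species amplitude ratios are unchanged and the operation is
    idempotent.
    """
    species = sorted(amps["species"].unique())
    if len(species) != 2:
        raise ValueError(f"need exactly two species, got {species}")
    means = amps.groupby("species", observed=True)["amplitude"].mean()
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"non-positive species mean amplitude for {bad}")
    grand = means.mean()
    out = amps.copy()
    scale = out["species"].map(grand / means)
    out["amplitude"] = out["amplitude"] * scale
    out["provenance"] = "normalized"
    return out


@dataclass(frozen=True)
class SideTestResult:
    """ANOVA terms involving brain side, FDR-adjusted within that family."""

    table: pd.DataFrame
    poolable: bool
    alpha: float


def side_effect_test(amps: pd.DataFrame, alpha: float = 0.05) -> SideTestResult:
    """Test whether left/right brain sides can be pooled.

    Runs the four-factor ANOVA (species, odour, glomerulus, side; two-way
    interactions) and BH-adjusts the p-values of the side main effect and
    all side interactions as one family.  Pooling is allowed when none is
    significant at ``alpha``.
    """
    if amps["side"].nunique() < 2:
        raise ValueError("side factor must have two levels to test")
    aov = stats.nway_anova(
        amps, "amplitude", ["species", "odour", "glomerulus", "side"], max_order=2
    )
    side_terms = aov[aov["term"].str.contains("side")].copy()
    side_terms["p_fdr"] = stats.fdr_adjust(side_terms["p"].to_numpy())
    poolable = bool((side_terms["p_fdr"] >= alpha).all())
    return SideTestResult(side_terms.reset_index(drop=True), poolable, alpha)


def pool_sides(
    amps: pd.DataFrame,
    side_test: SideTestResult | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Average amplitudes over brain side if no side effect is detectable.

    If the side family (main effect + interactions) shows any FDR-significant
    term, the table is returned unchanged with a warning.
    """
    if amps["side"].nunique() < 2:
        return amps.copy()
    if side_test is None:
        side_test = side_effect_test(amps, alpha)
    if not side_test.poolable:
        warnings.warn(
            "significant brain-side effect detected; sides kept separate",
            stacklevel=2,
        )
        return amps.copy()
    pooled = (
        amps.groupby(["species", "fly", "glomerulus", "odour"], observed=True)
        .agg(amplitude=("amplitude", "mean"), n_trials=("n_trials", "sum"))
        .reset_index()
    )
    pooled["side"] = "pooled"
    pooled["provenance"] = amps["provenance"].iloc[0] if "provenance" in amps else "raw"
    cols = ["species", "fly", "side", "glomerulus", "odour", "amplitude", "n_trials", "provenance"]
    return pooled[cols]
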