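"""Multi-glomerular odour-code analysis.

An odour's code is the vector of response amplitudes across glomeruli
(optionally time-resolved).  This module provides:

* a shared-basis PCA: one transformation fitted on the pooled
  subject-averaged responses of both species and applied identically to
  each, so trajectory differences in PC space reflect coding
  differences, not basis differences;
* Euclidean distances between per-fly coding vectors, partitioned into
  within-species and between-species fly pairs, with a rank-based test
  and a fly-label permutation test (the robust default, since pair
  distances sharing a fly are not independent);
* agglomerative clustering of subject-averaged odour codes with Ward's
  minimum-variance criterion, cut at 70 % of the maximum merge height;
* FDR-corrected species contrasts of response amplitudes per glomerulus
  (averaged over odours) and per odour (averaged over glomeruli).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from . import stats
from .extraction import TraceSet, dff

__all__ = [
    "coding_vectors",
    "time_resolved_codes",
    "SharedPCA",
    "fit_shared_pca",
    "ed",
    "WithinBetweenTest",
    "DistanceSummary",
    "within_between",
    "distance_summaries",
    "ClusterResult",
    "hca",
    "AmplitudeContrasts",
    "compare_amplitudes",
]


def coding_vectors(
    amps: pd.DataFrame,
    glomeruli: list[str] | None = None,
) -> pd.DataFrame:
    """Per-(species, fly, odour) coding vectors over glomeruli.

    Pivots an amplitude table into rows indexed by (species, fly, odour)
    with one column per glomerulus.  Missing combinations stay NaN;
    complete-case selection happens at the point of each comparison.
    """
    wide = amps.pivot_table(
        index=["species", "fly", "odour"],
        columns="glomerulus",
        values="amplitude",
        aggfunc="mean",
    )
    if glomeruli is not None:
        missing = [g for g in glomeruli if g not in wide.columns]
        if missing:
            raise ValueError(f"glomeruli absent from table: {missing}")
        wide = wide[glomeruli]
    wide.columns.name = "glomerulus"
    return wide


def time_resolved_codes(
    traces: TraceSet,
    baseline: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Subject-averaged dF/F time courses as (species, odour, frame) x glomerulus.

    Averages dF/F over trials and flies; the post-stimulus tail is kept,
    since response dynamics range from phasic to tonic and the decay
    carries coding information.
    """
    rel = dff(traces.values, traces.protocol, baseline)
    keys = traces.keys[["species", "odour", "glomerulus"]]
    codes, group_keys = [], []
    for key, idx in keys.groupby(
        ["species", "odour", "glomerulus"], observed=True, sort=True
    ).indices.items():
        group_keys.append(key)
        codes.append(rel[idx].mean(axis=0))
    n_frames = traces.protocol.n_frames
    long = pd.DataFrame(group_keys, columns=["species", "odour", "glomerulus"])
    long = long.loc[long.index.repeat(n_frames)].reset_index(drop=True)
    long["frame"] = np.tile(np.arange(n_frames), len(group_keys))
    long["value"] = np.asarray(codes).reshape(-1)
    wide = long.pivot_table(
        index=["species", "odour", "frame"], columns="glomerulus", values="value"
    )
    return wide


@dataclass
class SharedPCA:
    """One PCA basis shared by both species.

    Fitted on the pooled (column-mean-centred) data matrix; projection is
    ``(X - mean_) @ components_.T`` and is applied through the very same
    routine to any subset, so re-projecting one species alone reproduces
    its joint-call coordinates bitwise.
    """

    mean_: np.ndarray
    components_: np.ndarray
    explained_variance_ratio_: np.ndarray
    n_nonzero: int
    columns: tuple

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T


def fit_shared_pca(
    responses: pd.DataFrame,
    k: int = 3,
) -> tuple[SharedPCA, pd.DataFrame]:
    """Fit one PCA on pooled responses and project both species with it.

    Parameters
    ----------
    responses : wide table indexed by (species, odour, frame) with one
        column per glomerulus (complete cases only).
    k : number of components to retain (default 3).

    Returns
    -------
    (SharedPCA, trajectories) where trajectories is a tidy frame with
    columns ``species, odour, frame, pc1..pck``.  If the pooled matrix
    has rank below ``k``, the trailing components carry (numerically)
    zero variance and ``n_nonzero`` reports the effective count.
    """
    if responses.isna().any().any():
        bad = list(responses.columns[responses.isna().any()])
        raise ValueError(f"incomplete response matrix; NaN in columns {bad}")
    X = responses.to_numpy(dtype=float)
    n, G = X.shape
    if k > G:
        raise ValueError(f"k={k} exceeds {G} glomerular dimensions")
    mean_ = X.mean(axis=0)
    Xc = X - mean_
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    total = (s**2).sum()
    evr = s**2 / total if total > 0 else np.zeros_like(s)
    tol = s[0] * max(n, G) * np.finfo(float).eps if s.size else 0.0
    n_nonzero = int((s > tol).sum())
    pca = SharedPCA(mean_, Vt[:k], evr[:k], min(n_nonzero, k), tuple(responses.columns))

    frames = []
    idx = responses.index.to_frame(index=False)
    for sp in idx["species"].unique():
        rows = (idx["species"] == sp).to_numpy()
        proj = pca.project(X[rows])
        block = idx.loc[rows].reset_index(drop=True)
        for c in range(k):
            block[f"pc{c + 1}"] = proj[:, c]
        frames.append(block)
    trajectories = pd.concat(frames, ignore_index=True)
    return pca, trajectories


def ed(u: np.ndarray, v: np.ndarray) -> float:
    """Euclidean distance between two coding vectors.

    NaN entries mark absent glomeruli; the distance is computed on the
    intersection of present components, which must be non-empty.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("coding vectors differ in length")
    both = np.isfinite(u) & np.isfinite(v)
    if not both.any():
        raise ValueError("no shared glomeruli between vectors")
    d = u[both] - v[both]
    return float(np.sqrt((d * d).sum()))


@dataclass(frozen=True)
class WithinBetweenTest:
    statistic: float
    pvalue: float
    direction: str  # "within_smaller" | "within_larger" | "equal"

    def significantly_below(self, alpha: float = 0.05) -> bool:
        return self.pvalue < alpha and self.direction == "within_smaller"


@dataclass
class DistanceSummary:
    """Pairwise Euclidean distances for one odour, partitioned by species."""

    odour: str
    species: tuple[str, str]
    within: dict[str, np.ndarray]
    between: np.ndarray
    tests: dict[str, WithinBetweenTest]
    method: str
    n_glomeruli: int


def _pair_masks(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    return same, iu[0], iu[1]


def within_between(
    vectors_by_species: dict[str, np.ndarray],
    odour: str = "",
    method: str = "permutation",
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    n_glomeruli: int | None = None,
) -> DistanceSummary:
    """Within- vs between-species Euclidean distances for one odour.

    All unordered fly pairs are split into within-species-A,
    within-species-B and between-species sets.  For each species the
    within distances are compared against the between distances:

    * ``method="permutation"`` (default): two-sided fly-label
      permutation test of T = mean(within) - mean(between); exact under
      exchangeability of flies across species and robust to the
      non-independence of pair distances.
    * ``method="ranksum"``: two-sided Wilcoxon rank-sum on the two
      distance lists.
    """
    if len(vectors_by_species) != 2:
        raise ValueError("need exactly two species")
    (sp_a, A), (sp_b, B) = vectors_by_species.items()
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    for sp, M in ((sp_a, A), (sp_b, B)):
        if M.ndim != 2 or M.shape[0] < 2:
            raise ValueError(f"need >= 2 complete flies for species {sp!r}")
    if A.shape[1] != B.shape[1]:
        raise ValueError("species coding vectors differ in dimension")

    X = np.vstack([A, B])
    labels = np.concatenate([np.zeros(A.shape[0], int), np.ones(B.shape[0], int)])
    from scipy.spatial.distance import pdist
    D = squareform(pdist(X))
    same, iu, ju = _pair_masks(labels)
    within_a = D[iu, ju][(labels[iu] == 0) & (labels[ju] == 0)]
    within_b = D[iu, ju][(labels[iu] == 1) & (labels[ju] == 1)]
    between = D[iu, ju][labels[iu] != labels[ju]]

    tests: dict[str, WithinBetweenTest] = {}
    if method == "ranksum":
        for sp, w in ((sp_a, within_a), (sp_b, within_b)):
            stat, p = sps.mannwhitneyu(w, between, alternative="two-sided")
            tests[sp] = WithinBetweenTest(
                float(stat), float(p), _direction(w, between)
            )
    elif method == "permutation":
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        elif rng is None:
            rng = np.random.default_rng(0)
        n = labels.size
        perms = rng.permuted(np.tile(labels, (n_perm, 1)), axis=1)
        for sp_idx, (sp, w_obs) in enumerate(((sp_a, within_a), (sp_b, within_b))):
            P = (perms == sp_idx).astype(float)
            Q = 1.0 - P
            n_s = int((labels == sp_idx).sum())
            n_o = n - n_s
            w_sum = np.einsum("pi,ij,pj->p", P, D, P) / 2.0
            b_sum = np.einsum("pi,ij,pj->p", P, D, Q)
            t_perm = w_sum / (n_s * (n_s - 1) / 2) - b_sum / (n_s * n_o)
            t_obs = w_obs.mean() - between.mean()
            p = (1 + np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12)) / (n_perm + 1)
            tests[sp] = WithinBetweenTest(float(t_obs), float(p), _direction(w_obs, between))
    else:
        raise ValueError(f"unknown method {method!r}")

    return DistanceSummary(
        odour=odour,
        species=(sp_a, sp_b),
        within={sp_a: within_a, sp_b: within_b},
        between=between,
        tests=tests,
        method=method,
        n_glomeruli=n_glomeruli if n_glomeruli is not None else X.shape[1],
    )


def _direction(within: np.ndarray, between: np.ndarray) -> str:
    wm, bm = within.mean(), between.mean()
    if wm < bm:
        return "within_smaller"
    if wm > bm:
        return "within_larger"
    return "equal"


def distance_summaries(
    vectors: pd.DataFrame,
    method: str = "permutation",
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> list[DistanceSummary]:
    """Within/between distance analysis for every odour in a vector table.

    ``vectors`` is the output of :func:`coding_vectors`.  For each odour,
    only flies with complete vectors over the configured glomerulus set
    enter the comparison; the number used is carried in the summary.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    elif rng is None:
        rng = np.random.default_rng(0)
    species = sorted(vectors.index.get_level_values("species").unique())
    if len(species) != 2:
        raise ValueError("need exactly two species")
    out = []
    for odour in vectors.index.get_level_values("odour").unique():
        sub = vectors.xs(odour, level="odour")
        sub = sub.dropna(axis=0, how="any")
        by_sp = {
            sp: sub.xs(sp, level="species").to_numpy(dtype=float)
            for sp in species
        }
        out.append(
            within_between(
                by_sp, odour=odour, method=method, n_perm=n_perm, rng=rng,
                n_glomeruli=sub.shape[1],
            )
        )
    return out


@dataclass
class ClusterResult:
    """Ward linkage with a flat cut at a fraction of the maximum height."""

    linkage: np.ndarray
    threshold: float
    labels: pd.Series
    threshold_frac: float

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def hca(
    codes: pd.DataFrame,
    threshold_frac: float = 0.70,
) -> ClusterResult:
    """Ward's minimum-variance clustering of subject-averaged odour codes.

    ``codes`` is (odours x glomeruli), complete.  Merge heights are the
    standard Ward/Euclidean linkage distances; flat clusters are formed
    by cutting where the merge height reaches ``threshold_frac`` times
    the maximum height (the dendrogram colour-threshold convention).
    Labels are renumbered by first occurrence in input row order, so the
    assignment is deterministic with ties broken by lowest odour index.
    """
    if codes.shape[0] < 2:
        raise ValueError("need at least two odours to cluster")
    if codes.isna().any().any():
        raise ValueError("incomplete odour codes")
    X = codes.to_numpy(dtype=float)
    Z = linkage(X, method="ward")
    hmax = Z[:, 2].max()
    threshold = threshold_frac * hmax
    raw = fcluster(Z, t=threshold, criterion="distance")
    remap: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in remap:
            remap[r] = len(remap) + 1
        labels.append(remap[r])
    return ClusterResult(
        Z, float(threshold), pd.Series(labels, index=codes.index, name="cluster"),
        threshold_frac,
    )


@dataclass
class AmplitudeContrasts:
    """FDR-corrected species contrasts of normalized response amplitudes."""

    per_glomerulus: pd.DataFrame
    per_odour: pd.DataFrame


def compare_amplitudes(amps: pd.DataFrame, alpha: float = 0.05) -> AmplitudeContrasts:
    """Species contrasts per glomerulus (odour-averaged) and per odour
    (glomerulus-averaged).

    Fly-level marginal means are compared between species with
    pooled-variance t-tests; the per-glomerulus contrasts form one BH
    family and the per-odour contrasts another.  Expects the
    cross-species-normalized table (warns otherwise).
    """
    if "provenance" in amps.columns and not (amps["provenance"] == "normalized").all():
        warnings.warn("amplitude table is not cross-species normalized", stacklevel=2)
    per_glom_means = (
        amps.groupby(["species", "fly", "glomerulus"], observed=True)["amplitude"]
        .mean()
        .reset_index()
    )
    per_odour_means = (
        amps.groupby(["species", "fly", "odour"], observed=True)["amplitude"]
        .mean()
        .reset_index()
    )
    return AmplitudeContrasts(
        per_glomerulus=stats.group_contrasts(
            per_glom_means, "amplitude", "glomerulus", "species", alpha
        ),
        per_odour=stats.group_contrasts(
            per_odour_means, "amplitude", "odour", "species", alpha
        ),
    )
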