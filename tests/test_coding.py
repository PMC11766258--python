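"""Coding-space operations: shared PCA, distances, permutation test, Ward HCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glomcode import coding, extraction, synthetic
from glomcode.coding import (coding_vectors, compare_amplitudes,
                             distance_summaries, ed, fit_shared_pca, hca,
                             time_resolved_codes, within_between)


# ---------------------------------------------------------------------------
# Coding vectors


def _amp_table(tiny_config):
    ts = synthetic.gen_traces(tiny_config)
    return extraction.cross_species_normalize(extraction.amplitude_table(ts))


def test_coding_vectors_pivot_matches_source(tiny_config):
    amps = _amp_table(tiny_config)
    vec = coding_vectors(amps)
    row = amps.iloc[37]
    assert vec.loc[
        (row["species"], row["fly"], row["odour"]), row["glomerulus"]
    ] == pytest.approx(row["amplitude"])
    assert vec.shape == (
        2 * tiny_config.n_flies_per_species * len(tiny_config.odour_panel),
        tiny_config.n_glomeruli,
    )


def test_coding_vectors_missing_cells_stay_nan(tiny_config):
    amps = _amp_table(tiny_config)
    drop = (amps["fly"] == "mel-01") & (amps["glomerulus"] == amps["glomerulus"].iloc[0])
    vec = coding_vectors(amps[~drop])
    assert vec.loc[("melanogaster", "mel-01")].isna().any().any()
    with pytest.raises(ValueError, match="absent"):
        coding_vectors(amps, glomeruli=["nonexistent"])


# ---------------------------------------------------------------------------
# Euclidean distance


def test_ed_hand_examples():
    assert ed([0, 0], [3, 4]) == pytest.approx(5.0)
    assert ed([1, 2, 3], [1, 2, 3]) == 0.0


def test_ed_matches_naive_loop(rng):
    for _ in range(50):
        u = rng.standard_normal(12)
        v = rng.standard_normal(12)
        naive = sum((a - b) ** 2 for a, b in zip(u, v)) ** 0.5
        assert ed(u, v) == pytest.approx(naive, rel=1e-12)


def test_ed_uses_shared_components_only():
    u = np.array([1.0, np.nan, 3.0])
    v = np.array([1.0, 5.0, 7.0])
    assert ed(u, v) == pytest.approx(4.0)
    with pytest.raises(ValueError, match="no shared"):
        ed([np.nan, 1.0], [2.0, np.nan])
    with pytest.raises(ValueError, match="length"):
        ed([1.0], [1.0, 2.0])


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_ed_is_a_metric_on_random_triples(seed):
    rng = np.random.default_rng(seed)
    x, y, z = rng.standard_normal((3, 6))
    assert ed(x, y) == pytest.approx(ed(y, x))
    assert ed(x, z) <= ed(x, y) + ed(y, z) + 1e-9
    assert ed(x, x) == 0.0


# ---------------------------------------------------------------------------
# Within/between distances and permutation test


def brute_force_within_between(A, B):
    """All unordered pair distances by explicit loops."""
    X = np.vstack([A, B])
    lab = [0] * len(A) + [1] * len(B)
    within_a, within_b, between = [], [], []
    for i, j in itertools.combinations(range(len(X)), 2):
        d = ed(X[i], X[j])
        if lab[i] == lab[j] == 0:
            within_a.append(d)
        elif lab[i] == lab[j] == 1:
            within_b.append(d)
        else:
            between.append(d)
    return np.array(within_a), np.array(within_b), np.array(between)


def test_distance_partition_matches_brute_force(rng):
    A = rng.standard_normal((4, 5))
    B = rng.standard_normal((3, 5))
    res = within_between({"a": A, "b": B}, n_perm=10)
    wa, wb, bt = brute_force_within_between(A, B)
    np.testing.assert_allclose(np.sort(res.within["a"]), np.sort(wa), atol=1e-12)
    np.testing.assert_allclose(np.sort(res.within["b"]), np.sort(wb), atol=1e-12)
    np.testing.assert_allclose(np.sort(res.between), np.sort(bt), atol=1e-12)


def exact_permutation_p(A, B, species_idx):
    """Enumerate all label assignments of the 3+3 flies for the exact
    two-sided p-value of T = mean(within) - mean(between)."""
    X = np.vstack([A, B])
    n = len(X)
    n_s = len(A) if species_idx == 0 else len(B)
    D = np.array([[ed(X[i], X[j]) for j in range(n)] for i in range(n)])

    def t_for(members):
        members = set(members)
        others = set(range(n)) - members
        w = [D[i, j] for i, j in itertools.combinations(sorted(members), 2)]
        b = [D[i, j] for i in members for j in others]
        return np.mean(w) - np.mean(b)

    obs_members = range(0, len(A)) if species_idx == 0 else range(len(A), n)
    t_obs = t_for(obs_members)
    ts = [t_for(c) for c in itertools.combinations(range(n), n_s)]
    return t_obs, np.mean([abs(t) >= abs(t_obs) - 1e-12 for t in ts])


def test_permutation_p_matches_exact_enumeration(rng):
    """With all C(6,3)=20 assignments sampled exhaustively many times, the
    Monte-Carlo p (with +1 correction) converges to the exact p."""
    A = rng.standard_normal((3, 4))
    B = rng.standard_normal((3, 4)) + 0.5
    for sp_idx, sp in [(0, "a"), (1, "b")]:
        t_obs, p_exact = exact_permutation_p(A, B, sp_idx)
        res = within_between(
            {"a": A, "b": B}, n_perm=40_000, rng=np.random.default_rng(9)
        )
        test = res.tests[sp]
        assert test.statistic == pytest.approx(t_obs, rel=1e-9)
        assert test.pvalue == pytest.approx(p_exact, abs=0.01)


def test_tight_cluster_detected_as_within_smaller(rng):
    A = rng.standard_normal((8, 6)) * 0.05          # tight species
    B = rng.standard_normal((8, 6)) * 1.0 + 3.0     # loose, displaced species
    res = within_between({"a": A, "b": B}, rng=1)
    assert res.tests["a"].direction == "within_smaller"
    assert res.tests["a"].significantly_below(0.05)


def test_exchangeable_null_is_uniformish():
    """Type-I: pooled flies from one distribution, p < .05 rarely."""
    hits = 0
    n_rep = 100
    for seed in range(n_rep):
        rng = np.random.default_rng(10_000 + seed)
        A = rng.standard_normal((5, 4))
        B = rng.standard_normal((5, 4))
        res = within_between({"a": A, "b": B}, n_perm=400, rng=rng)
        hits += res.tests["a"].pvalue < 0.05
    assert hits / n_rep <= 0.10


def test_ranksum_method_agrees_with_scipy(rng):
    from scipy.stats import mannwhitneyu
    A = rng.standard_normal((4, 5))
    B = rng.standard_normal((4, 5)) + 1.0
    res = within_between({"a": A, "b": B}, method="ranksum")
    wa, _, bt = brute_force_within_between(A, B)
    stat, p = mannwhitneyu(wa, bt, alternative="two-sided")
    assert res.tests["a"].statistic == pytest.approx(stat)
    assert res.tests["a"].pvalue == pytest.approx(p)


def test_within_between_input_validation(rng):
    with pytest.raises(ValueError, match="two species"):
        within_between({"a": rng.standard_normal((3, 2))})
    with pytest.raises(ValueError, match=">= 2 complete flies"):
        within_between({"a": rng.standard_normal((1, 2)),
                        "b": rng.standard_normal((3, 2))})
    with pytest.raises(ValueError, match="dimension"):
        within_between({"a": rng.standard_normal((3, 2)),
                        "b": rng.standard_normal((3, 3))})
    with pytest.raises(ValueError, match="unknown method"):
        within_between({"a": rng.standard_normal((3, 2)),
                        "b": rng.standard_normal((3, 2))}, method="bogus")


def test_distance_summaries_per_odour_complete_cases(tiny_config):
    amps = _amp_table(tiny_config)
    # knock one fly's glomerulus out for one odour
    odour = amps["odour"].iloc[0]
    drop = ((amps["fly"] == "mel-01") & (amps["odour"] == odour)
            & (amps["glomerulus"] == amps["glomerulus"].iloc[0]))
    vec = coding_vectors(amps[~drop])
    sums = distance_summaries(vec, n_perm=200, rng=3)
    assert len(sums) == len(tiny_config.odour_panel)
    by_odour = {s.odour: s for s in sums}
    # dropped fly removed only from the affected odour
    n_mel_pairs = len(by_odour[odour].within["melanogaster"])
    assert n_mel_pairs == 1  # C(2,2) pairs from the remaining 2 flies
    other = next(o for o in by_odour if o != odour)
    assert len(by_odour[other].within["melanogaster"]) == 3  # C(3,2)


# ---------------------------------------------------------------------------
# Shared PCA


def test_pca_recovers_planted_two_dim_structure(rng):
    n = 40
    basis = np.linalg.qr(rng.standard_normal((6, 6)))[0][:2]
    scores = rng.standard_normal((n, 2)) * [5.0, 2.0]
    X = scores @ basis
    idx = pd.MultiIndex.from_product(
        [["a", "b"], ["o"], range(n // 2)], names=["species", "odour", "frame"]
    )
    df = pd.DataFrame(X, index=idx, columns=[f"g{i}" for i in range(6)])
    pca, traj = fit_shared_pca(df, k=3)
    assert pca.n_nonzero == 2
    assert pca.explained_variance_ratio_[:2].sum() == pytest.approx(1.0)
    # component span matches planted basis
    proj = pca.components_[:2] @ basis.T
    np.testing.assert_allclose(np.abs(np.linalg.det(proj)), 1.0, atol=1e-9)


def test_pca_projection_is_shared_bitwise(tiny_config):
    ts = synthetic.gen_traces(tiny_config)
    codes = time_resolved_codes(ts)
    pca, traj = fit_shared_pca(codes, k=3)
    # re-projecting one species alone through the same routine is bitwise equal
    one = codes.xs("suzukii", level="species", drop_level=False)
    re_proj = pca.project(one.to_numpy(dtype=float))
    got = traj[traj.species == "suzukii"][["pc1", "pc2", "pc3"]].to_numpy()
    assert np.array_equal(re_proj, got)


def test_pca_variance_ratios_match_svd_oracle(tiny_config):
    ts = synthetic.gen_traces(tiny_config)
    codes = time_resolved_codes(ts)
    X = codes.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    pca, _ = fit_shared_pca(codes, k=3)
    np.testing.assert_allclose(
        pca.explained_variance_ratio_, (s**2 / (s**2).sum())[:3], rtol=1e-10
    )


def test_pca_sign_convention_is_deterministic(tiny_config):
    ts = synthetic.gen_traces(tiny_config)
    codes = time_resolved_codes(ts)
    p1, _ = fit_shared_pca(codes)
    p2, _ = fit_shared_pca(codes)
    np.testing.assert_array_equal(p1.components_, p2.components_)
    for row in p1.components_:
        assert row[np.argmax(np.abs(row))] > 0


def test_pca_rejects_nan_and_excess_k(tiny_config):
    ts = synthetic.gen_traces(tiny_config)
    codes = time_resolved_codes(ts)
    with pytest.raises(ValueError, match="exceeds"):
        fit_shared_pca(codes, k=codes.shape[1] + 1)
    bad = codes.copy()
    bad.iloc[0, 0] = np.nan
    with pytest.raises(ValueError, match="incomplete"):
        fit_shared_pca(bad)


# ---------------------------------------------------------------------------
# Ward clustering


def brute_force_ward(X):
    """Agglomerative Ward from the ESS definition.

    Clusters merge to minimise the increase in total within-cluster sum
    of squares; the reported height is sqrt(2 * delta-ESS), matching the
    Lance-Williams/SciPy convention.
    """
    clusters = {i: [i] for i in range(len(X))}
    merges = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ia, ib = clusters[a], clusters[b]
            ca, cb = X[ia].mean(axis=0), X[ib].mean(axis=0)
            na, nb = len(ia), len(ib)
            d_ess = na * nb / (na + nb) * ((ca - cb) ** 2).sum()
            if best is None or d_ess < best[0] - 1e-12:
                best = (d_ess, a, b)
        d_ess, a, b = best
        merges.append((a, b, np.sqrt(2 * d_ess), len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def test_ward_heights_match_ess_oracle(rng):
    X = rng.standard_normal((7, 4))
    codes = pd.DataFrame(X, index=[f"o{i}" for i in range(7)])
    res = hca(codes)
    oracle = brute_force_ward(X)
    np.testing.assert_allclose(res.linkage[:, 2], [m[2] for m in oracle], rtol=1e-9)
    np.testing.assert_array_equal(res.linkage[:, 3], [m[3] for m in oracle])


def test_cluster_cut_on_separated_blobs(rng):
    centres = np.array([[0, 0], [10, 0], [0, 10]])
    X = np.vstack([c + 0.1 * rng.standard_normal((4, 2)) for c in centres])
    codes = pd.DataFrame(X, index=[f"o{i}" for i in range(12)])
    res = hca(codes, threshold_frac=0.70)
    assert res.n_clusters == 3
    lab = res.labels.to_numpy()
    for k in range(3):
        assert len(set(lab[4 * k: 4 * k + 4])) == 1
    # deterministic first-occurrence numbering
    assert lab[0] == 1 and lab[4] == 2 and lab[8] == 3


def test_cluster_threshold_fraction_of_max_height(rng):
    X = rng.standard_normal((6, 3))
    codes = pd.DataFrame(X, index=list("abcdef"))
    res = hca(codes, threshold_frac=0.5)
    assert res.threshold == pytest.approx(0.5 * res.linkage[:, 2].max())


def test_cluster_input_validation():
    with pytest.raises(ValueError, match="at least two"):
        hca(pd.DataFrame([[1.0, 2.0]], index=["only"]))
    bad = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["a", "b"])
    with pytest.raises(ValueError, match="incomplete"):
        hca(bad)


# ---------------------------------------------------------------------------
# Amplitude contrasts


def test_compare_amplitudes_families_and_warning(tiny_config):
    amps = _amp_table(tiny_config)
    res = compare_amplitudes(amps)
    assert len(res.per_glomerulus) == tiny_config.n_glomeruli
    assert len(res.per_odour) == len(tiny_config.odour_panel)
    # marginal means oracle for one glomerulus
    g = res.per_glomerulus["glomerulus"].iloc[0]
    marg = (amps[amps.glomerulus == g]
            .groupby(["species", "fly"])["amplitude"].mean())
    row = res.per_glomerulus.iloc[0]
    assert row["mean_melanogaster"] == pytest.approx(marg["melanogaster"].mean())
    assert row["mean_suzukii"] == pytest.approx(marg["suzukii"].mean())
    raw = amps.assign(provenance="raw")
    with pytest.warns(UserWarning, match="not cross-species normalized"):
        compare_amplitudes(raw)
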