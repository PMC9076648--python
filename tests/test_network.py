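"""Signed adjacency, scale-free fit, module detection and eigengenes,
each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domnet.network import (
    GREY,
    ModuleSet,
    NetworkParams,
    connectivity,
    correlation_matrix,
    detect_modules,
    export_network,
    module_eigenvalues,
    scale_free_fit,
    scale_free_fit_from_connectivity,
    signed_adjacency,
)
from domnet.synthetic import PlantedStructure, generate_feature_matrix, planted_recovery_ari


def frame(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"f{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=ids, columns=[f"s{j}" for j in range(values.shape[1])])


# ------------------------------------------------------------- correlation

def test_duplicated_feature_r_is_one():
    m = frame([[1, 2, 3, 4], [1, 2, 3, 4], [4, 1, 3, 2]])
    cor = correlation_matrix(m)
    assert cor.loc["f0", "f1"] == pytest.approx(1.0)


def test_negated_feature_r_is_minus_one():
    x = np.array([1.0, 2.0, 5.0, 3.0])
    m = frame([x, 2 * x.mean() - x])
    cor = correlation_matrix(m)
    assert cor.loc["f0", "f1"] == pytest.approx(-1.0)


def test_correlation_matches_hand_computed_covariance_formula():
    """Brute-force r = cov(x,y) / (sd(x) sd(y)) on a 5 x 4 table."""
    values = np.array(
        [
            [2.0, 4.0, 4.0, 6.0],
            [1.0, 3.0, 5.0, 7.0],
            [9.0, 2.0, 6.0, 4.0],
            [3.0, 3.0, 1.0, 9.0],
            [5.0, 8.0, 2.0, 2.0],
        ]
    )
    cor = correlation_matrix(frame(values))
    for i in range(5):
        for j in range(5):
            x, y = values[i], values[j]
            cov = ((x - x.mean()) * (y - y.mean())).mean()
            r = cov / (x.std() * y.std())
            assert cor.iloc[i, j] == pytest.approx(r, abs=1e-12)


def test_zero_variance_feature_excluded_with_warning():
    m = frame([[1, 1, 1, 1], [1, 2, 3, 4]])
    with pytest.warns(UserWarning, match="zero-variance"):
        cor = correlation_matrix(m)
    assert list(cor.index) == ["f1"]


def test_too_few_samples_rejected():
    with pytest.raises(ValueError, match="3 samples"):
        correlation_matrix(frame([[1, 2], [3, 4]]))


# --------------------------------------------------------------- adjacency

def test_adjacency_endpoint_values():
    cor = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]])
    adj = signed_adjacency(cor, power=9)
    assert adj.iloc[0, 0] == pytest.approx(1.0, abs=1e-12)
    assert adj.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_adjacency_at_zero_correlation():
    adj = signed_adjacency(pd.DataFrame([[0.0]]), power=9)
    assert adj.iloc[0, 0] == pytest.approx(0.5**9, abs=1e-15)
    assert adj.iloc[0, 0] == pytest.approx(0.001953125, abs=1e-15)


@settings(derandomize=True, max_examples=50)
@given(st.floats(-1, 1), st.floats(-1, 1))
def test_adjacency_monotone_in_correlation(a, b):
    lo, hi = sorted([a, b])
    adj = signed_adjacency(pd.DataFrame([[lo, hi]]), power=9).to_numpy()[0]
    assert adj[0] <= adj[1]


def test_increasing_power_never_increases_adjacency():
    cor = pd.DataFrame([[0.99, -0.3, 0.5]])
    a9 = signed_adjacency(cor, power=9).to_numpy()
    a12 = signed_adjacency(cor, power=12).to_numpy()
    assert (a12 <= a9 + 1e-15).all()


def test_invalid_power_rejected():
    with pytest.raises(ValueError, match="power"):
        signed_adjacency(pd.DataFrame([[0.5]]), power=0)


def test_out_of_range_correlations_rejected():
    with pytest.raises(ValueError, match=r"\[-1, 1\]"):
        signed_adjacency(pd.DataFrame([[1.5]]), power=9)


# ------------------------------------------------------------- scale-free

def test_planted_power_law_fits_perfectly():
    # connectivities at 1, 2, 4, 8 with counts proportional to k^-1:
    # binned log-log relation is exactly linear
    k = np.repeat([1.0, 2.0, 4.0, 8.0], [8, 4, 2, 1])
    fit = scale_free_fit_from_connectivity(k, n_bins=8)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
    assert fit.slope == pytest.approx(-1.0, abs=1e-6)


def test_fit_equals_brute_force_regression():
    rng = np.random.default_rng(0)
    k = rng.pareto(2.0, size=500) + 1.0
    fit = scale_free_fit_from_connectivity(k, n_bins=10)
    # independent binning + closed-form least squares
    edges = np.linspace(k.min(), k.max(), 11)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
    xs, ys = [], []
    for b in range(10):
        mask = which == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum() / k.size))
    xs, ys = np.array(xs), np.array(ys)
    slope = ((xs - xs.mean()) * (ys - ys.mean())).sum() / ((xs - xs.mean()) ** 2).sum()
    r = ((xs - xs.mean()) * (ys - ys.mean())).sum() / np.sqrt(
        ((xs - xs.mean()) ** 2).sum() * ((ys - ys.mean()) ** 2).sum()
    )
    assert fit.slope == pytest.approx(slope, abs=1e-12)
    assert fit.r_squared == pytest.approx(r**2, abs=1e-12)


def test_degenerate_connectivities_rejected():
    with pytest.raises(ValueError, match="undefined"):
        scale_free_fit_from_connectivity(np.full(10, 3.0))
    with pytest.raises(ValueError, match="3 non-empty"):
        scale_free_fit_from_connectivity(np.array([1.0, 1.0, 8.0]), n_bins=2)


def test_connectivity_excludes_diagonal():
    adj = pd.DataFrame(np.array([[1.0, 0.5], [0.5, 1.0]]), index=["a", "b"], columns=["a", "b"])
    k = connectivity(adj)
    assert k.tolist() == [0.5, 0.5]


# ---------------------------------------------------------------- modules

def planted_adjacency(rng, n_blocks=3, block_size=40):
    """Block-diagonal high correlation, near-zero elsewhere."""
    n = n_blocks * block_size
    cor = rng.uniform(-0.05, 0.05, size=(n, n))
    cor = (cor + cor.T) / 2
    for b in range(n_blocks):
        s = slice(b * block_size, (b + 1) * block_size)
        cor[s, s] = rng.uniform(0.93, 0.97, size=(block_size, block_size))
    cor = np.clip((cor + cor.T) / 2, -1, 1)
    np.fill_diagonal(cor, 1.0)
    ids = [f"f{i}" for i in range(n)]
    truth = pd.Series([f"block{i // block_size}" for i in range(n)], index=ids)
    return pd.DataFrame(cor, index=ids, columns=ids), truth


def test_three_planted_blocks_recovered_exactly(rng):
    cor, truth = planted_adjacency(rng)
    adj = signed_adjacency(cor, power=9)
    modules = detect_modules(adj)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth, modules.labels) == pytest.approx(1.0)
    assert modules.colors == ["turquoise", "blue", "brown"]


def test_identical_features_single_module():
    n = 40
    adj = pd.DataFrame(np.ones((n, n)), index=[f"f{i}" for i in range(n)], columns=[f"f{i}" for i in range(n)])
    modules = detect_modules(adj)
    assert set(modules.labels) == {"turquoise"}


def test_min_module_size_larger_than_n_all_grey():
    adj = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
    with pytest.warns(UserWarning, match="all grey"):
        modules = detect_modules(adj, NetworkParams(min_module_size=10))
    assert set(modules.labels) == {GREY}


def test_module_labels_invariant_under_permutation(rng):
    cor, truth = planted_adjacency(rng, n_blocks=2, block_size=35)
    adj = signed_adjacency(cor, power=9)
    base = detect_modules(adj)
    perm = rng.permutation(len(adj))
    shuffled = adj.iloc[perm, perm]
    permuted = detect_modules(shuffled)
    # same partition up to relabelling
    from sklearn.metrics import adjusted_rand_score

    joint = pd.DataFrame({"a": base.labels, "b": permuted.labels.reindex(base.labels.index)})
    assert adjusted_rand_score(joint["a"], joint["b"]) == pytest.approx(1.0)


def test_default_synthetic_recovery(default_run, noise_free_run):
    for run, minimum in ((noise_free_run, 1.0), (default_run, 0.9)):
        matrix, _, truth = run
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cor = correlation_matrix(matrix)
        adj = signed_adjacency(cor, power=9)
        modules = detect_modules(adj)
        assert planted_recovery_ari(truth, modules.labels) >= minimum


def test_tom_dissimilarity_also_recovers_blocks(rng):
    cor, truth = planted_adjacency(rng)
    adj = signed_adjacency(cor, power=9)
    modules = detect_modules(adj, NetworkParams(dissimilarity="tom", cut_height_fraction=0.95))
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(truth, modules.labels) == pytest.approx(1.0)


# -------------------------------------------------------------- eigengenes

def standardize(x):
    return (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)


def test_identical_features_eigenvalue_is_standardized_profile():
    profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
    m = frame(np.tile(profile, (4, 1)))
    modules = ModuleSet(labels=pd.Series("turquoise", index=m.index))
    eig = module_eigenvalues(m, modules)
    expected = (profile - profile.mean()) / profile.std()
    np.testing.assert_allclose(eig.scores.loc["turquoise"], expected, atol=1e-10)
    assert eig.variance_explained["turquoise"] == pytest.approx(1.0)


def test_eigenvalues_match_svd_oracle(rng):
    values = rng.normal(size=(10, 6))
    m = frame(values)
    modules = ModuleSet(labels=pd.Series("turquoise", index=m.index))
    eig = module_eigenvalues(m, modules)
    z = standardize(values)
    _, s, vt = np.linalg.svd(z)
    oracle = np.sqrt(6) * vt[0]
    if np.dot(oracle, z.mean(axis=0)) < 0:
        oracle = -oracle
    np.testing.assert_allclose(eig.scores.loc["turquoise"], oracle, atol=1e-8)
    assert eig.variance_explained["turquoise"] == pytest.approx(s[0] ** 2 / (s**2).sum())


def test_eigengene_maximizes_explained_variance(rng):
    """PC1 scores explain at least as much variance as random unit-norm
    combinations of the module's standardized features."""
    values = rng.normal(size=(8, 12))
    z = standardize(values)
    m = frame(values)
    modules = ModuleSet(labels=pd.Series("turquoise", index=m.index))
    eig = module_eigenvalues(m, modules)
    # captured energy of PC1, reconstructed from the variance explained
    pc1_energy = eig.variance_explained["turquoise"] * (z**2).sum()
    for _ in range(20):
        w = rng.normal(size=8)
        w /= np.linalg.norm(w)
        assert ((w @ z) ** 2).sum() <= pc1_energy + 1e-9


def test_orientation_positive_on_default_run(default_run):
    matrix, _, _ = default_run
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cor = correlation_matrix(matrix)
    adj = signed_adjacency(cor, power=9)
    modules = detect_modules(adj)
    eig = module_eigenvalues(matrix.loc[adj.index], modules)
    for color in modules.colors:
        block = standardize(matrix.loc[modules.members(color)].to_numpy())
        r = np.corrcoef(eig.scores.loc[color], block.mean(axis=0))[0, 1]
        assert r >= 0


def test_eigenvalues_invariant_to_feature_permutation(rng):
    values = rng.normal(size=(9, 7))
    m = frame(values)
    labels = pd.Series("turquoise", index=m.index)
    eig_a = module_eigenvalues(m, ModuleSet(labels=labels))
    perm = rng.permutation(len(m))
    eig_b = module_eigenvalues(m.iloc[perm], ModuleSet(labels=labels.iloc[perm]))
    np.testing.assert_allclose(
        eig_a.scores.loc["turquoise"], eig_b.scores.loc["turquoise"], atol=1e-10
    )


def test_single_feature_module_warns(default_run):
    m = frame(np.random.default_rng(0).normal(size=(1, 5)))
    modules = ModuleSet(labels=pd.Series("turquoise", index=m.index))
    with pytest.warns(UserWarning, match="single feature"):
        eig = module_eigenvalues(m, modules)
    assert eig.variance_explained["turquoise"] == 1.0


# ----------------------------------------------------------------- export

def test_threshold_zero_gives_complete_graph(rng):
    n = 8
    cor = np.clip(rng.uniform(-0.5, 0.5, (n, n)), -1, 1)
    cor = (cor + cor.T) / 2
    np.fill_diagonal(cor, 1.0)
    adj = signed_adjacency(pd.DataFrame(cor, index=[f"f{i}" for i in range(n)], columns=[f"f{i}" for i in range(n)]), 9)
    g = export_network(adj, edge_threshold=0.0)
    assert g.number_of_nodes() == n
    assert g.number_of_edges() == n * (n - 1) // 2


def test_graphml_roundtrip(tmp_path, rng):
    import networkx as nx

    n = 6
    cor = rng.uniform(0.2, 0.9, (n, n))
    cor = (cor + cor.T) / 2
    np.fill_diagonal(cor, 1.0)
    ids = [f"f{i}" for i in range(n)]
    adj = signed_adjacency(pd.DataFrame(cor, index=ids, columns=ids), 9)
    path = tmp_path / "net.graphml"
    g = export_network(adj, edge_threshold=0.1, path=str(path))
    g2 = nx.read_graphml(path)
    assert set(g2.nodes) == set(g.nodes)
    for u, v, data in g.edges(data=True):
        assert g2[u][v]["weight"] == pytest.approx(data["weight"])


def test_invalid_threshold_rejected(rng):
    adj = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
    with pytest.raises(ValueError, match="threshold"):
        export_network(adj, edge_threshold=1.5)
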