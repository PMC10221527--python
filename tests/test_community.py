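"""Community-module contracts: rarefaction depth conservation, the
abundance/prevalence filter, diversity formulas, Bray-Curtis, PCoA
round-trips, and ANOSIM against a brute-force enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from gutlink.community import (anosim, bray_curtis, filter_taxa,
                               observed_features, pcoa, rarefy, shannon)
from gutlink.containers import TaxaTable


# ---------------------------------------------------------------- rarefy

def test_rarefy_conserves_depth_and_zeros(count_table):
    depth = int(count_table.data.sum(axis=1).min())
    out = rarefy(count_table, depth, seed=1)
    assert (out.data.sum(axis=1) == depth).all()
    # a taxon never observed stays at zero everywhere
    assert (out.data["t7"] == 0).all()
    # rarefaction never creates taxa
    assert ((out.data > 0) <= (count_table.data > 0)).all().all()


def test_rarefy_at_exact_total_is_identity(count_table):
    row = count_table.data.iloc[[0]]
    single = TaxaTable(row, location="faeces")
    out = rarefy(single, int(row.sum(axis=1).iloc[0]), seed=0)
    pd.testing.assert_frame_equal(out.data, row)


def test_rarefy_reports_shallow_samples(count_table):
    with pytest.raises(ValueError, match="fewer than"):
        rarefy(count_table, int(count_table.data.sum(axis=1).max()) + 1)


def test_observed_features_never_increase_after_rarefaction(count_table):
    depth = int(count_table.data.sum(axis=1).min())
    out = rarefy(count_table, depth, seed=3)
    before = [observed_features(r) for r in count_table.data.to_numpy()]
    after = [observed_features(r) for r in out.data.to_numpy()]
    assert all(a <= b for a, b in zip(after, before))


# ----------------------------------------------------------- filter_taxa

def test_filter_taxa_hand_enumerated_toy():
    # 10 samples x 6 taxa built so exactly t0, t1, t2 pass both rules:
    # t3 fails prevalence (4/10 <= 0.4? uses >5%: 4/10 passes 5% -- make it 0/10 except
    # abundant in none), t4 fails mean abundance, t5 fails both.
    data = pd.DataFrame(0.0, index=[f"s{i}" for i in range(10)],
                        columns=[f"t{j}" for j in range(6)])
    data["t0"] = 10.0              # everywhere, abundant
    data["t1"] = [5.0] * 9 + [0.0]  # 90% prevalence, abundant
    data["t2"] = [2.0] * 6 + [0.0] * 4
    data.loc["s0", "t3"] = 8.0      # 10% prevalence? 1/10 = 0.1 > 0.05 -> passes prev
    data["t4"] = 0.001              # everywhere but mean relabund ~6e-5 < 5e-4
    data.loc["s0", "t5"] = 0.0001   # rare and sparse
    rel = data.div(data.sum(axis=1), axis=0)
    expect = [t for t in data.columns
              if rel[t].mean() > 0.0005 and (data[t] > 0).mean() > 0.05]
    table = TaxaTable(data, location="cecum")
    out = filter_taxa(table)
    assert list(out.data.columns) == expect
    assert "t4" not in out.data.columns and "t0" in out.data.columns


def test_filter_prevalence_is_strictly_greater_than():
    # nonzero in 4 of 100 samples = 4% <= 5% -> removed; 6% -> kept
    data = pd.DataFrame(0.0, index=range(100), columns=["rare", "ok"])
    data.loc[:3, "rare"] = 1.0
    data.loc[:5, "ok"] = 1.0
    data["anchor"] = 1.0
    out = filter_taxa(TaxaTable(data, location="cecum"), min_mean_relabund=0.0)
    assert "rare" not in out.data.columns
    assert "ok" in out.data.columns


def test_filter_taxa_idempotent(count_table):
    once = filter_taxa(count_table)
    twice = filter_taxa(once)
    pd.testing.assert_frame_equal(once.data, twice.data)


def test_filter_taxa_empty_result_warns():
    data = pd.DataFrame([[1.0], [1.0]], columns=["t"])
    with pytest.warns(UserWarning):
        out = filter_taxa(TaxaTable(data, location="cecum"), min_prevalence=1.0)
    assert out.n_taxa == 0


# ------------------------------------------------------------- diversity

@pytest.mark.parametrize("counts,expected", [
    ((1, 1, 1, 1), 2.0),           # uniform over 4 taxa
    ((5, 0, 0), 0.0),              # single taxon
    ((1, 1, 2), 1.5),              # worked example in bits
])
def test_shannon_bits(counts, expected):
    assert shannon(counts) == pytest.approx(expected)


def test_shannon_all_zero_errors():
    with pytest.raises(ValueError):
        shannon((0, 0, 0))


def test_observed_features_counts_nonzero():
    assert observed_features((1, 1, 2, 0)) == 3
    assert observed_features((0, 0)) == 0


# ----------------------------------------------------------- bray-curtis

def test_bray_curtis_values():
    data = pd.DataFrame([[1.0, 1.0], [1.0, 3.0], [1.0, 1.0], [0.0, 5.0]],
                        index=list("abcd"), columns=["t1", "t2"])
    dm = bray_curtis(TaxaTable(data, location="cecum"))
    assert dm.loc["a", "b"] == pytest.approx(1 / 3)   # 2/6
    assert dm.loc["a", "c"] == 0.0                    # identical samples
    disjoint = pd.DataFrame([[1.0, 0.0], [0.0, 2.0]], columns=["t1", "t2"])
    dm2 = bray_curtis(TaxaTable(disjoint, location="cecum"))
    assert dm2.iloc[0, 1] == pytest.approx(1.0)
    assert np.allclose(dm, dm.T) and (np.diag(dm) == 0).all()


def test_bray_curtis_two_empty_samples_error():
    data = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]], columns=["a", "b"])
    with pytest.raises(ValueError, match="all-zero"):
        bray_curtis(TaxaTable(data, location="cecum"))


# ------------------------------------------------------------------ pcoa

def test_pcoa_roundtrip_recovers_euclidean_distances():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(9, 4))
    d = pd.DataFrame(squareform(pdist(x)))
    coords, explained, eigvals = pcoa(d, k=9)
    d2 = squareform(pdist(coords.to_numpy()))
    np.testing.assert_allclose(d2, d.to_numpy(), atol=1e-8)
    assert np.all(np.diff(eigvals) <= 1e-9)  # descending
    assert explained.sum() == pytest.approx(1.0)


def test_pcoa_collinear_points_single_axis():
    pts = np.array([[0.0], [1.0], [2.5], [4.0]])
    d = pd.DataFrame(squareform(pdist(pts)))
    coords, explained, _ = pcoa(d, k=3)
    assert coords.shape[1] == 1
    assert explained[0] == pytest.approx(1.0)


def test_pcoa_rejects_asymmetric_input():
    bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValueError):
        pcoa(bad)


def test_pcoa_matches_skbio_on_bray_curtis():
    pytest.importorskip("skbio")
    from skbio.stats.ordination import pcoa as sk_pcoa
    rng = np.random.default_rng(1)
    data = pd.DataFrame(rng.random((10, 6)))
    dm = bray_curtis(TaxaTable(data, location="cecum"))
    ours, _, our_eig = pcoa(dm, k=2)
    theirs = sk_pcoa(dm.to_numpy(), number_of_dimensions=2)
    np.testing.assert_allclose(np.abs(ours.to_numpy()),
                               np.abs(theirs.samples.to_numpy()[:, :2]),
                               atol=1e-8)


# ---------------------------------------------------------------- anosim

def _naive_anosim_r(d, groups):
    """Independent oracle: direct rank formula over all pairs."""
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([d[i, j] for i, j in pairs])
    within = [k for k, (i, j) in enumerate(pairs) if groups[i] == groups[j]]
    between = [k for k in range(len(pairs)) if k not in within]
    m = len(pairs)
    return (np.mean(ranks[between]) - np.mean(ranks[within])) / (m / 2)


def test_anosim_perfect_separation_gives_r_one():
    d = np.full((6, 6), 10.0)
    np.fill_diagonal(d, 0.0)
    for i, j in itertools.combinations(range(3), 2):
        d[i, j] = d[j, i] = 1.0
        d[i + 3, j + 3] = d[j + 3, i + 3] = 1.0
    r, p = anosim(pd.DataFrame(d), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
    assert r == pytest.approx(1.0)
    assert 0 < p <= 1


def test_anosim_exact_p_matches_brute_force_enumeration():
    rng = np.random.default_rng(7)
    x = rng.normal(size=(6, 3))
    d = squareform(pdist(x))
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    r_obs, p_exact = anosim(pd.DataFrame(d), groups, n_perm="exact")
    # oracle: enumerate all distinct labelings via positions of group "a"
    rs = [_naive_anosim_r(d, _assign(pos)) for pos in
          itertools.combinations(range(6), 3)]
    assert r_obs == pytest.approx(_naive_anosim_r(d, groups))
    expect = np.mean([rv >= r_obs - 1e-12 for rv in rs])
    assert p_exact == pytest.approx(expect)


def _assign(positions):
    g = np.array(["b"] * 6, dtype=object)
    g[list(positions)] = "a"
    return g


def test_anosim_matches_skbio_r_statistic():
    pytest.importorskip("skbio")
    from skbio import DistanceMatrix
    from skbio.stats.distance import anosim as sk_anosim
    rng = np.random.default_rng(12)
    x = rng.normal(size=(12, 4))
    d = squareform(pdist(x))
    groups = ["a"] * 6 + ["b"] * 6
    ours, _ = anosim(pd.DataFrame(d), groups, n_perm=9, seed=0)
    theirs = sk_anosim(DistanceMatrix(d), np.asarray(groups), permutations=9)
    assert ours == pytest.approx(theirs["test statistic"])


def test_anosim_null_rejection_rate_calibrated():
    rng = np.random.default_rng(9)
    rejections = 0
    n_sims = 300
    for _ in range(n_sims):
        x = rng.normal(size=(10, 3))
        d = squareform(pdist(x))
        groups = rng.permutation(["a"] * 5 + ["b"] * 5)
        _, p = anosim(pd.DataFrame(d), groups, n_perm=99,
                      seed=int(rng.integers(2**31)))
        rejections += p <= 0.05
    assert 0.02 <= rejections / n_sims <= 0.08


def test_anosim_rejects_singleton_group():
    d = pd.DataFrame(np.zeros((3, 3)))
    with pytest.raises(ValueError):
        anosim(d, ["a", "b", "b"])
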