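"""Two-part engine contracts: residualization exactness, sub-test
calibration and power, Stouffer combination closed forms, BH against a
hand step-up oracle, partial Spearman against pingouin, and scan
invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gutlink.association import (ScanPolicy, bh_adjust, binary_part,
                                 meta_unweighted_z, quant_part, residualize,
                                 run_association_scan, spearman_partial,
                                 validate_with_spearman)


# ----------------------------------------------------------- residualize

def test_residualize_removes_covariate_signal_exactly():
    rng = np.random.default_rng(0)
    n = 200
    sex = rng.integers(0, 2, n)
    batch = rng.integers(0, 4, n)
    cov = pd.DataFrame({"sex": np.where(sex == 1, "M", "F"),
                        "batch": [f"b{b}" for b in batch]})
    y = 1.0 * sex + 0.5 * batch + rng.normal(size=n)
    resid = residualize(y, cov)
    assert abs(resid.mean()) < 1e-10
    # residual orthogonal to the sex indicator: t-statistic ~ 0
    r = np.corrcoef(resid, sex)[0, 1]
    assert abs(r) < 1e-8


def test_residualize_exact_linear_function_gives_zero():
    batch = np.repeat([0, 1, 2], 10)
    cov = pd.DataFrame({"batch": [f"b{b}" for b in batch]})
    y = 2.0 + 3.0 * (batch == 1) - 1.0 * (batch == 2)
    resid = residualize(y, cov)
    np.testing.assert_allclose(resid, 0.0, atol=1e-10)


# ------------------------------------------------------------- sub-tests

def test_binary_part_null_calibration():
    rng = np.random.default_rng(1)
    n, sims = 300, 1000
    presence = rng.random(n) < 0.4
    hits = 0
    for _ in range(sims):
        y = rng.normal(size=n)
        z, _ = binary_part(y - y.mean(), presence)
        hits += abs(z) > 1.96
    assert 0.03 <= hits / sims <= 0.07


def test_binary_part_strong_shift_gives_large_z():
    rng = np.random.default_rng(2)
    n = 300
    presence = rng.random(n) < 0.5
    y = presence * 1.0 + rng.normal(0, 1, n)
    z, beta = binary_part(y - y.mean(), presence)
    # closed form: E|z| ~ delta * sqrt(n p (1-p)) = sqrt(75) ~ 8.7
    assert abs(z) > 7 and beta > 0.8


def test_binary_part_error_paths():
    with pytest.raises(ValueError):
        binary_part(np.zeros(10), np.ones(10))          # one class absent
    with pytest.raises(ValueError):
        binary_part(np.zeros(10), np.r_[np.ones(5), np.zeros(5)])  # constant y


def test_quant_part_noncentrality_matches_closed_form():
    # slope 0.5 sd per sd with 200 present samples: E|z| ~ 0.5 * sqrt(200)
    rng = np.random.default_rng(3)
    zs = []
    for _ in range(200):
        x = rng.lognormal(0, 1, 220)
        present = np.ones(220, bool)
        xs = (np.log10(x) - np.log10(x).mean()) / np.log10(x).std()
        y = 0.5 * xs + rng.normal(size=220)
        z, _ = quant_part(y - y.mean(), x, present)
        zs.append(abs(z))
    assert np.mean(zs) == pytest.approx(0.5 * np.sqrt(220), rel=0.08)


def test_quant_part_null_z_is_standard_normal():
    rng = np.random.default_rng(4)
    zs = []
    for _ in range(2000):
        x = rng.lognormal(0, 1, 60)
        y = rng.normal(size=60)
        z, _ = quant_part(y - y.mean(), x, np.ones(60, bool))
        zs.append(z)
    assert stats.kstest(zs, "norm").pvalue > 0.01


def test_quant_part_thresholds():
    with pytest.raises(ValueError):
        quant_part(np.zeros(20), np.ones(20), np.r_[np.ones(5, bool),
                                                    np.zeros(15, bool)])
    with pytest.raises(ValueError):  # constant abundance among present
        quant_part(np.random.default_rng(0).normal(size=20),
                   np.ones(20), np.ones(20, bool))


# ----------------------------------------------------------- stouffer

def test_meta_z_closed_forms():
    z, p = meta_unweighted_z(1.96, 1.96)
    assert z == pytest.approx(2.77186, abs=1e-4)
    assert p == pytest.approx(0.0055737, abs=2e-6)
    assert meta_unweighted_z(0.0, 0.0) == (0.0, 1.0)
    z, p = meta_unweighted_z(2.5, -2.5)
    assert z == 0.0 and p == 1.0
    # single-part reduction
    z, p = meta_unweighted_z(1.5, None)
    assert z == pytest.approx(1.5)
    with pytest.raises(ValueError):
        meta_unweighted_z(None, None)


# ------------------------------------------------------------------- bh

def _bh_oracle(p):
    """Exhaustive step-up: q_i = min over j>=i of p_(j) * m / j."""
    p = np.asarray(p, float)
    order = np.argsort(p)
    m = len(p)
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def test_bh_worked_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])
    np.testing.assert_allclose(bh_adjust([0.2]), [0.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                max_size=20))
def test_bh_matches_exhaustive_oracle(pvals):
    np.testing.assert_allclose(bh_adjust(pvals), _bh_oracle(pvals), atol=1e-12)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_adjust([0.0, 0.5])


# ------------------------------------------------------ partial spearman

def test_spearman_monotone_relations():
    x = np.array([0.5, 1.2, 2.0, 3.3, 4.8, 6.0])
    rho, _ = spearman_partial(x, x)
    assert rho == pytest.approx(1.0)
    rho, _ = spearman_partial(x, -x**2)
    assert rho == pytest.approx(-1.0)


def test_spearman_hand_case_with_tie():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 5.0])
    rho, p = spearman_partial(x, y)
    ref_rho, ref_p = stats.spearmanr(x, y)
    assert rho == pytest.approx(ref_rho)
    assert p == pytest.approx(ref_p, rel=1e-6)


def test_spearman_partial_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    n = 40
    z = rng.normal(size=n)
    x = z + rng.normal(size=n)
    y = -z + rng.normal(size=n)
    df = pd.DataFrame({"x": x, "y": y, "z": z})
    ours_rho, ours_p = spearman_partial(x, y, df[["z"]])
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["z"],
                                method="spearman")
    assert ours_rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


def test_spearman_constant_vector_errors():
    with pytest.raises(ValueError):
        spearman_partial(np.ones(10), np.arange(10.0))


# ------------------------------------------------------------------ scan

def test_scan_refuses_too_few_samples(null_cohort):
    taxa, metab, meta = null_cohort
    small = taxa.with_data(taxa.data.iloc[:10])
    with pytest.raises(ValueError, match="overlapping samples"):
        run_association_scan(small, metab, meta)


def test_scan_duplicated_metabolite_gives_identical_rows(null_cohort):
    taxa, metab, meta = null_cohort
    data = metab.test_data().copy()
    data["dup"] = data[data.columns[0]]
    res = run_association_scan(taxa, data, meta)
    a = res[res.metabolite_id == data.columns[0]].set_index("taxon_id")
    b = res[res.metabolite_id == "dup"].set_index("taxon_id")
    np.testing.assert_allclose(a["z_meta"], b.loc[a.index, "z_meta"])


def test_scan_invariant_to_sample_order_and_monotone_rescale(null_cohort):
    taxa, metab, meta = null_cohort
    res1 = run_association_scan(taxa, metab, meta)
    perm = np.random.default_rng(0).permutation(taxa.data.index)
    taxa2 = taxa.with_data(taxa.data.loc[perm])
    rescaled = metab.test_data() * 1000.0   # the transform absorbs scaling
    res2 = run_association_scan(taxa2, rescaled, meta)
    key = ["taxon_id", "metabolite_id"]
    m = res1.set_index(key).sort_index()
    m2 = res2.set_index(key).sort_index()
    np.testing.assert_allclose(m["z_meta"], m2["z_meta"], atol=1e-9)


def test_scan_parts_policy_prevalence_regimes(effect_cohort):
    taxa, metab, meta, _ = effect_cohort
    res = run_association_scan(taxa, metab, meta,
                               policy=ScanPolicy(quant_only_prevalence=0.95))
    by_taxon = res.groupby("taxon_id").agg(prev=("prevalence", "first"),
                                           parts=("parts_run", "first"))
    high = by_taxon[by_taxon.prev >= 0.95]
    assert (high.parts == "quant_only").all()
    mid = by_taxon[(by_taxon.prev < 0.95) & (by_taxon.prev * 300 >= 10)]
    assert (mid.parts == "both").all()


def test_scan_recovers_implanted_effects(effect_cohort):
    taxa, metab, meta, truth = effect_cohort
    res = run_association_scan(taxa, metab, meta)
    sig = set(zip(res.loc[res.q_value < 0.05, "taxon_id"],
                  res.loc[res.q_value < 0.05, "metabolite_id"]))
    for eff in truth:
        pair = (f"taxon{eff.taxon:03d}", f"feat{eff.metabolite:04d}")
        assert pair in sig
        row = res[(res.taxon_id == pair[0]) & (res.metabolite_id == pair[1])]
        expected = "+" if eff.binary_effect > 0 else "-"
        assert row["direction"].iloc[0] == expected


def test_spearman_validation_on_effect_cohort(effect_cohort):
    taxa, metab, meta, truth = effect_cohort
    res = run_association_scan(taxa, metab, meta)
    rep = validate_with_spearman(res, taxa, metab, meta)
    assert rep["n_significant"] >= len(truth)
    assert rep["replication_fraction"] >= 0.8


def test_spearman_validation_null_is_empty(null_cohort):
    taxa, metab, meta = null_cohort
    res = run_association_scan(taxa, metab, meta)
    rep = validate_with_spearman(res, taxa, metab, meta)
    assert rep["n_significant"] <= 1
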