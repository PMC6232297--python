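"""Resemblance, ordination and permutation tests against independent oracles.

Closed-form oracles: classical one-way ANOVA F (PERMANOVA on Euclidean
distances of univariate data), classical regression F (DistLM likewise),
brute-force label enumeration, hand-expanded SIMPER sums; cross-
implementation oracles: scikit-bio (PERMANOVA/ANOSIM statistics) and
scikit-learn (non-metric MDS stress).
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reservoirnet.containers import SQRT_RELATIVE, EnvTable, RelAbundanceTable
from reservoirnet.resemblance import (
    EUCLIDEAN,
    ResemblanceMatrix,
    anosim,
    bioenv_best,
    bray_curtis,
    distlm_forward,
    distlm_marginal,
    euclidean,
    nmds,
    permanova,
    pseudo_f_from_prop,
    relate,
    simper,
)
from tests.conftest import euclid_matrix


def _sqrt_rel(values, columns=None):
    values = np.atleast_2d(values)
    columns = columns or [f"o{i}" for i in range(values.shape[1])]
    return RelAbundanceTable(
        pd.DataFrame(values, index=[f"s{i}" for i in range(values.shape[0])],
                     columns=columns),
        SQRT_RELATIVE,
    )


# ---------------------------------------------------------------------------
# resemblance construction


def test_bray_curtis_values():
    rel = _sqrt_rel([[0.1, 0.3], [0.1, 0.3], [0.3, 0.1], [0.5, 0.0]])
    sim = bray_curtis(rel).values
    assert sim[0, 1] == pytest.approx(100.0)          # identical samples
    # x=[.1,.3] vs y=[.3,.1]: 100*(1 - 0.4/0.8) = 50 (ratio as [1,3] vs [3,1])
    assert sim[0, 2] == pytest.approx(50.0)
    rel2 = _sqrt_rel([[0.5, 0.0], [0.0, 0.5]])
    assert bray_curtis(rel2).values[0, 1] == pytest.approx(0.0)  # disjoint


def test_bray_curtis_requires_sqrt_tag():
    raw = RelAbundanceTable(pd.DataFrame([[0.5, 0.5]], index=["s0"],
                                         columns=["a", "b"]))
    with pytest.raises(ValueError, match="sqrt"):
        bray_curtis(raw)


def test_euclidean_values_and_missing_rescaling():
    env = EnvTable(pd.DataFrame(
        {"a": [0.0, 3.0, 3.0], "b": [0.0, 4.0, np.nan]},
        index=["s1", "s2", "s3"]))
    d = euclidean(env).values
    assert d[0, 0] == 0.0
    assert d[0, 1] == pytest.approx(5.0)  # 3-4-5 triangle
    # s1 vs s3: only 'a' shared, diff 3, rescaled by sqrt(2/1) -> 3*sqrt(2)
    assert d[0, 2] == pytest.approx(3 * np.sqrt(2))


def test_euclidean_no_shared_variables_rejected():
    env = EnvTable(pd.DataFrame(
        {"a": [1.0, np.nan], "b": [np.nan, 2.0]}, index=["s1", "s2"]))
    with pytest.raises(ValueError, match="share no observed"):
        euclidean(env)


# ---------------------------------------------------------------------------
# nMDS


def test_nmds_exact_for_three_points():
    pts = np.array([[0.0, 0.0], [1.0, 0.2], [0.3, 2.0]])
    res = nmds(euclid_matrix(pts), k=2, n_restarts=3, seed=0)
    assert res.stress <= 1e-6


def test_nmds_recovers_planar_configuration():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(6, 2))
    res = nmds(euclid_matrix(pts), k=2, n_restarts=5, seed=0)
    assert res.stress < 0.01
    assert res.coordinates.shape == (6, 2)


def test_nmds_stress_close_to_sklearn_reference():
    from sklearn.manifold import MDS

    rng = np.random.default_rng(7)
    pts = rng.normal(size=(5, 3))
    mat = euclid_matrix(pts)
    mine = nmds(mat, k=2, n_restarts=20, seed=0)
    ref = MDS(n_components=2, metric=False, dissimilarity="precomputed",
              n_init=20, normalized_stress=True, random_state=0,
              max_iter=500, eps=1e-9)
    ref.fit(mat.values)
    assert mine.stress <= ref.stress_ + 0.005


def test_nmds_needs_enough_samples():
    with pytest.raises(ValueError):
        nmds(euclid_matrix(np.zeros((2, 2))), k=2)


# ---------------------------------------------------------------------------
# PERMANOVA


def _univariate_matrix(values):
    return euclid_matrix(np.asarray(values, dtype=float)[:, None])


def test_permanova_equals_anova_f_closed_form():
    res = permanova(_univariate_matrix([0, 1, 10, 11]), ["A", "A", "B", "B"],
                    n_perm=99, seed=0)
    assert res.statistic == pytest.approx(200.0)  # SSB=100 df1, SSW=1 df2


def test_permanova_exact_enumeration_p():
    res = permanova(_univariate_matrix([0, 1, 10, 11]), ["A", "A", "B", "B"],
                    method="exact")
    assert res.n_perm == 24
    assert res.p_perm == pytest.approx(8 / 24)


def test_permanova_label_symmetry():
    mat = _univariate_matrix([0.0, 2.0, 5.0, 9.0])
    f1 = permanova(mat, ["A", "A", "B", "B"], n_perm=9, seed=0).statistic
    f2 = permanova(mat, ["B", "B", "A", "A"], n_perm=9, seed=0).statistic
    assert f1 == pytest.approx(f2)


@pytest.mark.parametrize("seed", range(5))
def test_permanova_matches_classical_anova_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=12)
    groups = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
    f_mine = permanova(_univariate_matrix(y), groups, n_perm=9, seed=0).statistic
    f_ref = stats.f_oneway(y[:4], y[4:8], y[8:]).statistic
    assert f_mine == pytest.approx(f_ref)


def test_permanova_statistic_matches_scikit_bio():
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as sk_permanova

    rng = np.random.default_rng(3)
    pts = rng.normal(size=(9, 4))
    mat = euclid_matrix(pts)
    groups = ["a", "a", "a", "b", "b", "b", "c", "c", "c"]
    mine = permanova(mat, groups, n_perm=99, seed=0)
    ref = sk_permanova(DistanceMatrix(mat.values, ids=mat.ids), groups,
                       permutations=99)
    assert mine.statistic == pytest.approx(ref["test statistic"])


# ---------------------------------------------------------------------------
# ANOSIM


def test_anosim_complete_separation_r_is_one():
    d = np.array([[0, 1, 9, 8], [1, 0, 9, 9], [9, 9, 0, 1], [8, 9, 1, 0]],
                 dtype=float)
    mat = ResemblanceMatrix(list("abcd"), d, EUCLIDEAN)
    res = anosim(mat, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
    assert res.statistic == pytest.approx(1.0)


def test_anosim_hand_computation():
    # distances (ab, ac, ad, bc, bd, cd) = (1, 2, 3, 4, 5, 6), groups AABB:
    # ranks are the values themselves; within = {ab=1, cd=6}, between =
    # {2,3,4,5}; R = (3.5 - 3.5) / (6/2) = 0
    d = np.zeros((4, 4))
    vals = {(0, 1): 1, (0, 2): 2, (0, 3): 3, (1, 2): 4, (1, 3): 5, (2, 3): 6}
    for (i, j), v in vals.items():
        d[i, j] = d[j, i] = v
    mat = ResemblanceMatrix(list("abcd"), d, EUCLIDEAN)
    res = anosim(mat, ["A", "A", "B", "B"], n_perm=9, seed=0)
    assert res.statistic == pytest.approx(0.0)


def test_anosim_statistic_matches_scikit_bio():
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import anosim as sk_anosim

    rng = np.random.default_rng(5)
    pts = rng.normal(size=(8, 3))
    pts[4:] += 1.5
    mat = euclid_matrix(pts)
    groups = ["a"] * 4 + ["b"] * 4
    mine = anosim(mat, groups, n_perm=99, seed=0)
    ref = sk_anosim(DistanceMatrix(mat.values, ids=mat.ids), groups,
                    permutations=99)
    assert mine.statistic == pytest.approx(ref["test statistic"])


# ---------------------------------------------------------------------------
# SIMPER


def test_simper_single_differing_otu_contributes_all():
    rel = _sqrt_rel([[0.2, 0.3], [0.2, 0.7]])
    table = simper(rel, ["a", "b"])
    assert table.loc["o1", "percent"] == pytest.approx(100.0)
    assert table.loc["o0", "percent"] == pytest.approx(0.0)


def test_simper_symmetric_differences_split_evenly():
    rel = _sqrt_rel([[0.4, 0.2], [0.2, 0.4]])
    table = simper(rel, ["a", "b"])
    assert table["percent"].tolist() == pytest.approx([50.0, 50.0])


def test_simper_matches_hand_expanded_pairs():
    # groups {s0,s1} vs {s2,s3}; contribution of each OTU is the average of
    # 100*|x-y|/sum(x+y) over the 4 between pairs, expanded by hand below
    x = np.array([[0.1, 0.5], [0.2, 0.4], [0.4, 0.1], [0.3, 0.3]])
    rel = _sqrt_rel(x)
    pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
    expected = np.zeros(2)
    for i, j in pairs:
        expected += 100 * np.abs(x[i] - x[j]) / (x[i] + x[j]).sum()
    expected /= len(pairs)
    table = simper(rel, ["a", "a", "b", "b"])
    for otu, val in zip(["o0", "o1"], expected):
        assert table.loc[otu, "average_contribution"] == pytest.approx(val)
    assert table["percent"].sum() == pytest.approx(100.0)
    assert table["cumulative_percent"].iloc[-1] == pytest.approx(100.0)


def test_simper_requires_two_groups():
    rel = _sqrt_rel([[0.5, 0.5], [0.4, 0.6], [0.3, 0.7]])
    with pytest.raises(ValueError, match="2 groups"):
        simper(rel, ["a", "b", "c"])


# ---------------------------------------------------------------------------
# DistLM


def _env(columns: dict, index=None):
    df = pd.DataFrame(columns, dtype=float)
    df.index = index or [f"s{i}" for i in range(len(df))]
    return EnvTable(df)


def test_distlm_marginal_equals_classical_regression_f():
    mat = _univariate_matrix([1.0, 2.0, 3.0, 4.0])
    env = _env({"x": [1, 2, 3, 5]})
    table = distlm_marginal(mat, env, n_perm=99, seed=0)
    lr = stats.linregress([1, 2, 3, 5], [1, 2, 3, 4])
    y = np.array([1, 2, 3, 4.0])
    ss_total = np.sum((y - y.mean()) ** 2)
    ss_reg = lr.rvalue**2 * ss_total
    f_ref = ss_reg / ((ss_total - ss_reg) / 2)
    assert table.loc["x", "pseudo_f"] == pytest.approx(f_ref)
    assert table.loc["x", "prop"] == pytest.approx(lr.rvalue**2)
    assert table.loc["x", "ss_total"] == pytest.approx(ss_total)


@pytest.mark.parametrize("seed", range(4))
def test_distlm_marginal_matches_regression_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    y = rng.normal(size=10)
    x = rng.normal(size=10)
    table = distlm_marginal(_univariate_matrix(y), _env({"x": x}),
                            n_perm=9, seed=0)
    r2 = stats.pearsonr(x, y).statistic ** 2
    f_ref = r2 / ((1 - r2) / 8)
    assert table.loc["x", "pseudo_f"] == pytest.approx(f_ref)


def test_distlm_orthogonal_predictor_explains_nothing():
    # G of univariate Euclidean distances is the centered Gram matrix of y,
    # so x'Gx = (x . y_centered)^2 = 0 for an orthogonal predictor
    mat = _univariate_matrix([1.0, 2.0, 3.0, 4.0])
    env = _env({"x": [1, -1, -1, 1]})
    table = distlm_marginal(mat, env, n_perm=9, seed=0)
    assert table.loc["x", "prop"] == pytest.approx(0.0, abs=1e-12)
    assert table.loc["x", "pseudo_f"] == pytest.approx(0.0, abs=1e-12)


def test_distlm_constant_predictor_rejected():
    mat = _univariate_matrix([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="constant"):
        distlm_marginal(mat, _env({"x": [2, 2, 2]}), n_perm=9)


def test_distlm_missing_values_reduce_effective_n():
    mat = _univariate_matrix([1.0, 2.0, 3.0, 4.0, 5.0])
    env = _env({"x": [1, 2.2, np.nan, 3.1, 5.5]})
    table = distlm_marginal(mat, env, n_perm=9, seed=0)
    assert table.loc["x", "n_eff"] == 4


def test_pseudo_f_prop_identity():
    # F = prop (n-2)/(1-prop): single-predictor identity used to audit
    # printed DistLM tables for internal consistency
    assert pseudo_f_from_prop(0.5, 10) == pytest.approx(10.0)
    assert pseudo_f_from_prop(0.0, 21) == 0.0
    with pytest.raises(ValueError):
        pseudo_f_from_prop(1.0, 21)


def test_distlm_forward_selects_planted_gradient_first():
    rng = np.random.default_rng(2)
    gradient = np.linspace(-2, 2, 16)
    y = np.column_stack([gradient, gradient**2]) + rng.normal(scale=0.1,
                                                              size=(16, 2))
    mat = euclid_matrix(y)
    env = _env({"signal": gradient,
                "noise1": rng.normal(size=16),
                "noise2": rng.normal(size=16)})
    sel = distlm_forward(mat, env, entry_alpha=0.05, n_perm=199, seed=0)
    assert sel.selected[0] == "signal"


def test_distlm_forward_zero_alpha_selects_nothing():
    mat = _univariate_matrix([1.0, 2.0, 3.0, 4.0, 5.0])
    env = _env({"x": [1, 2, 3, 4, 5]})
    sel = distlm_forward(mat, env, entry_alpha=0.0, n_perm=99, seed=0)
    assert sel.selected == []


def test_distlm_forward_skips_duplicate_variable():
    rng = np.random.default_rng(4)
    gradient = np.linspace(0, 1, 14)
    y = gradient[:, None] + rng.normal(scale=0.05, size=(14, 1))
    mat = euclid_matrix(y)
    env = _env({"a": gradient, "a_copy": gradient})
    sel = distlm_forward(mat, env, entry_alpha=0.05, n_perm=199, seed=0)
    assert len(sel.selected) == 1


# ---------------------------------------------------------------------------
# RELATE / BEST


def test_relate_self_and_reversed():
    rng = np.random.default_rng(6)
    mat = euclid_matrix(rng.normal(size=(5, 3)))
    assert relate(mat, mat, n_perm=49, seed=0).statistic == pytest.approx(1.0)
    reversed_vals = mat.values.max() + 1.0 - mat.values
    np.fill_diagonal(reversed_vals, 0.0)
    rev = ResemblanceMatrix(mat.ids, reversed_vals, EUCLIDEAN)
    assert relate(mat, rev, n_perm=49, seed=0).statistic == pytest.approx(-1.0)


def test_relate_matches_scipy_spearman_on_fixture():
    d1 = np.zeros((4, 4))
    d2 = np.zeros((4, 4))
    v1 = [1, 2, 3, 4, 5, 6]
    v2 = [2, 1, 4, 3, 6, 5]
    iu = np.triu_indices(4, k=1)
    d1[iu] = v1
    d2[iu] = v2
    d1 += d1.T
    d2 += d2.T
    m1 = ResemblanceMatrix(list("abcd"), d1, EUCLIDEAN)
    m2 = ResemblanceMatrix(list("abcd"), d2, EUCLIDEAN)
    rho = relate(m1, m2, n_perm=9, seed=0).statistic
    assert rho == pytest.approx(stats.spearmanr(v1, v2).statistic)


def test_relate_id_mismatch_rejected():
    mat = euclid_matrix(np.zeros((3, 2)))
    other = ResemblanceMatrix(["x", "y", "z"], mat.values, EUCLIDEAN)
    with pytest.raises(ValueError, match="ids"):
        relate(mat, other)


def test_bioenv_best_finds_planted_gradient():
    rng = np.random.default_rng(8)
    gradient = np.linspace(-1, 1, 12)
    bio = euclid_matrix(gradient[:, None])
    env = _env({"driver": gradient,
                "junk1": rng.normal(size=12),
                "junk2": rng.normal(size=12)})
    res = bioenv_best(bio, env, max_subset=2)
    assert res.selected == ("driver",)
    assert res.rho == pytest.approx(res.table["rho"].max())


def test_bioenv_best_subset_counts():
    rng = np.random.default_rng(9)
    bio = euclid_matrix(rng.normal(size=(6, 2)))
    env = _env({f"v{i}": rng.normal(size=6) for i in range(4)})
    res = bioenv_best(bio, env, max_subset=4)
    assert len(res.table) == 15  # 2^4 - 1 nonempty subsets
    single = bioenv_best(bio, _env({"only": rng.normal(size=6)}), max_subset=1)
    assert single.selected == ("only",)


def test_bioenv_best_invalid_max_subset():
    bio = euclid_matrix(np.zeros((3, 1)))
    with pytest.raises(ValueError):
        bioenv_best(bio, _env({"v": [1.0, 2.0, 3.0]}), max_subset=0)
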