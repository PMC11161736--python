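import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from proteosub import (
    DEPENDENCY_PRESET,
    KinaseSubstrateMap,
    OmicsMatrix,
    activity_ksea,
    activity_mean_fd,
    activity_mlr,
    detect_outlier_kinases,
    differential_activity_votes,
    inka_score,
    normalize_sites_by_protein,
    plant_outlier,
    site_log2fc,
    subset_specific_hits,
)


def _pp(values, rows, cols):
    return OmicsMatrix("PP", pd.DataFrame(np.asarray(values, float), index=rows, columns=cols))


def _stats_frame(fcs, sites=None):
    sites = sites or [f"X_S{i + 1}" for i in range(len(fcs))]
    return pd.DataFrame({"log2fc": np.asarray(fcs, float), "p": 0.01}, index=sites)


# ---------------------------------------------------------------- site stats

def test_site_log2fc_trivials_and_welch_oracle():
    rng = np.random.default_rng(0)
    X = rng.normal(20, 1, size=(50, 12))
    cols = [f"S{i}" for i in range(12)]
    m = _pp(X, [f"X_S{i + 1}" for i in range(50)], cols)
    same = site_log2fc(m, cols[:6], cols[:6])
    np.testing.assert_allclose(same["log2fc"], 0.0)
    shifted = _pp(np.column_stack([X[:, :6] + 1.0, X[:, 6:]]),
                  [f"X_S{i + 1}" for i in range(50)], cols)
    res = site_log2fc(shifted, cols[:6], cols[6:])
    # oracle: textbook Welch t-test per site
    for i in [0, 17, 42]:
        t, p = sps.ttest_ind(X[i, :6] + 1.0, X[i, 6:], equal_var=False)
        assert res["p"].iloc[i] == pytest.approx(p, abs=1e-12)
        assert res["log2fc"].iloc[i] == pytest.approx(
            (X[i, :6] + 1).mean() - X[i, 6:].mean())


def test_site_log2fc_single_sample_group_flagged():
    m = _pp([[1.0, 2.0, 3.0]], ["X_S1"], ["A", "B", "C"])
    res = site_log2fc(m, ["A"], ["B", "C"])
    assert np.isnan(res["p"].iloc[0]) and res["flagged"].iloc[0]


# ---------------------------------------------------------------- mean FD

def test_mean_fd_trivials_and_hand_mean():
    ks = KinaseSubstrateMap(substrates={"K": {f"X_S{i + 1}" for i in range(5)}})
    res = activity_mean_fd(_stats_frame([1.0, 1.0, 1.0, 0.5, 0.5]), ks)
    assert res.loc["K", "log2fc"] == pytest.approx(0.8)
    sym = activity_mean_fd(_stats_frame([1.0, -1.0, 2.0, -2.0, 0.0]), ks)
    assert sym.loc["K", "log2fc"] == pytest.approx(0.0)
    # below min_substrates the kinase is omitted
    few = KinaseSubstrateMap(substrates={"K": {"X_S1", "X_S2"}})
    assert len(activity_mean_fd(_stats_frame([1.0, 1.0]), few)) == 0


# ---------------------------------------------------------------- KSEA

def test_ksea_plug_in_values():
    # background mean 0 sd 1, m=4 substrates with mean 1 -> z = 2
    rng = np.random.default_rng(1)
    bg = rng.normal(size=400)
    bg = (bg - bg.mean()) / bg.std(ddof=1)
    fcs = np.concatenate([np.full(4, 1.0), bg])
    sites = [f"K_S{i + 1}" for i in range(4)] + [f"B_S{i + 1}" for i in range(400)]
    stats = _stats_frame(fcs, sites)
    ks = KinaseSubstrateMap(substrates={"K": set(sites[:4])})
    res = activity_ksea(stats, ks)
    mu, sd = fcs.mean(), fcs.std(ddof=1)
    expected = (1.0 - mu) * 2.0 / sd
    assert res.loc["K", "activity"] == pytest.approx(expected, abs=1e-12)
    # zero-enrichment kinase -> z = 0
    ks0 = KinaseSubstrateMap(substrates={"Z": set(sites)})
    res0 = activity_ksea(stats, ks0)
    assert res0.loc["Z", "activity"] == pytest.approx(0.0, abs=1e-12)


def test_ksea_matches_brute_force_formula_on_random_toys():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = 200
        sites = [f"P{i + 1}_S1" for i in range(n)]
        fcs = rng.normal(scale=2.0, size=n)
        stats = _stats_frame(fcs, sites)
        m = int(rng.integers(3, 30))
        subs = set(rng.choice(sites, size=m, replace=False))
        ks = KinaseSubstrateMap(substrates={"K": subs})
        res = activity_ksea(stats, ks)
        mean_sub = np.mean([fcs[sites.index(s)] for s in subs])
        z = (mean_sub - fcs.mean()) * np.sqrt(m) / fcs.std(ddof=1)
        assert res.loc["K", "activity"] == pytest.approx(z, abs=1e-9)
        assert res.loc["K", "p"] == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-9)


# ---------------------------------------------------------------- MLR

def test_mlr_single_kinase_constant_sites():
    sites = [f"X_S{i + 1}" for i in range(6)]
    ks = KinaseSubstrateMap(substrates={"K": set(sites)})
    res = activity_mlr(_stats_frame([2.5] * 6, sites), ks, ridge=1e-10)
    assert res.loc["K", "activity"] == pytest.approx(2.5, abs=1e-6)


def test_mlr_disjoint_substrates_equal_per_kinase_means():
    rng = np.random.default_rng(3)
    sites_a = [f"A_S{i + 1}" for i in range(8)]
    sites_b = [f"B_S{i + 1}" for i in range(5)]
    fc_a, fc_b = rng.normal(size=8), rng.normal(size=5) + 2
    stats = _stats_frame(np.concatenate([fc_a, fc_b]), sites_a + sites_b)
    ks = KinaseSubstrateMap(substrates={"KA": set(sites_a), "KB": set(sites_b)})
    res = activity_mlr(stats, ks, ridge=1e-12)
    assert res.loc["KA", "activity"] == pytest.approx(fc_a.mean(), abs=1e-6)
    assert res.loc["KB", "activity"] == pytest.approx(fc_b.mean(), abs=1e-6)


def test_mlr_shared_substrates_match_normal_equation_oracle():
    rng = np.random.default_rng(4)
    sites = [f"P{i + 1}_S1" for i in range(12)]
    ks = KinaseSubstrateMap(substrates={
        "K1": set(sites[:8]), "K2": set(sites[4:]),
    })
    y = rng.normal(size=12)
    stats = _stats_frame(y, sites)
    lam = 0.01
    res = activity_mlr(stats, ks, ridge=lam)
    X = np.zeros((12, 2))
    X[:8, 0] = 1.0
    X[4:, 1] = 1.0
    beta = np.linalg.solve(X.T @ X + lam * np.eye(2), X.T @ y)
    assert res.loc["K1", "activity"] == pytest.approx(beta[0], abs=1e-9)
    assert res.loc["K2", "activity"] == pytest.approx(beta[1], abs=1e-9)


# ---------------------------------------------------------------- voting

def _two_group_matrices(delta, n_subs=10, noise=0.1, seed=0):
    """Raw + normalized PP with one kinase's substrates shifted by delta."""
    rng = np.random.default_rng(seed)
    cols = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
    subs = [f"S{i}_S1" for i in range(n_subs)]
    bg = [f"N{i}_S1" for i in range(60)]
    X = rng.normal(20, 1, size=(n_subs + 60, 8))
    X[:n_subs, :4] += delta
    X += rng.normal(0, noise, X.shape)
    raw = _pp(X, subs + bg, cols)
    norm = _pp(X - 18.0, subs + bg, cols)
    ks = KinaseSubstrateMap(substrates={"K": set(subs)})
    return raw, norm, cols[:4], cols[4:], ks


def test_votes_all_six_for_strongly_shifted_kinase():
    raw, norm, ga, gb, ks = _two_group_matrices(delta=3.0)
    votes = differential_activity_votes(raw, norm, ga, gb, ks)
    assert votes.loc["K", "votes_s1"] == 6
    assert votes.loc["K", "votes_s2"] == 0


def test_votes_direction_flips_with_sign():
    raw, norm, ga, gb, ks = _two_group_matrices(delta=-3.0)
    votes = differential_activity_votes(raw, norm, ga, gb, ks)
    assert votes.loc["K", "votes_s2"] == 6


def test_no_vote_below_fold_change_threshold():
    # significant but |log2FC| < 1 -> abstain everywhere
    raw, norm, ga, gb, ks = _two_group_matrices(delta=0.9, noise=0.01)
    votes = differential_activity_votes(raw, norm, ga, gb, ks)
    assert votes.loc["K", "votes_total"] == 0


def test_planted_kinases_recovered_from_panel(panel):
    ga, gb = panel.super_group_samples()
    norm_pp, _ = normalize_sites_by_protein(panel.pp, panel.wp)
    votes = differential_activity_votes(panel.pp, norm_pp, ga, gb, panel.ks_map)
    for kin, favored in panel.planted_active_kinases.items():
        col = "votes_s1" if favored == 0 else "votes_s2"
        assert votes.loc[kin, col] >= 5


# ---------------------------------------------------------------- INKA

def test_inka_geometric_mean_and_zero_arm():
    data = pd.DataFrame(
        {"A": [2.0, np.log2(9.0)], "B": [2.0, np.nan]},
        index=["K1_Y10", "SUB_Y5"],
    )
    yp = OmicsMatrix("YP", data)
    ks = KinaseSubstrateMap(substrates={"K1": {"SUB_Y5"}}, own_sites={"K1": {"K1_Y10"}})
    scores, top = inka_score(yp, ks)
    assert scores.loc["A", "K1"] == pytest.approx(6.0)  # sqrt(4 * 9)
    assert scores.loc["B", "K1"] == pytest.approx(0.0)  # substrate arm silent
    assert top["A"] == ["K1"]
    assert top["B"] == []


def test_inka_monotone_in_either_arm_and_sample_order_invariant():
    rng = np.random.default_rng(0)
    rows = ["K1_Y1", "K1_Y2", "S1_Y1", "S2_Y1"]
    X = rng.normal(10, 1, size=(4, 3))
    yp = OmicsMatrix("YP", pd.DataFrame(X, index=rows, columns=["A", "B", "C"]))
    ks = KinaseSubstrateMap(substrates={"K1": {"S1_Y1", "S2_Y1"}},
                            own_sites={"K1": {"K1_Y1", "K1_Y2"}})
    base, _ = inka_score(yp, ks)
    boosted, _ = inka_score(
        OmicsMatrix("YP", yp.data + pd.DataFrame(
            [[1.0] * 3] + [[0.0] * 3] * 3, index=rows, columns=["A", "B", "C"])), ks)
    assert (boosted["K1"] > base["K1"]).all()
    shuffled, _ = inka_score(yp.copy(data=yp.data[["C", "A", "B"]]), ks)
    np.testing.assert_allclose(shuffled.loc[["A", "B", "C"], "K1"],
                               base.loc[["A", "B", "C"], "K1"])


def test_inka_ranks_planted_hyperactive_kinase_first(panel):
    yp = panel.yp
    kin = panel.ks_map.kinases[0]
    line_samples = [s for s in yp.sample_ids if s.startswith("L05")]
    boosted = yp
    own = sorted(panel.ks_map.own_sites[kin] & set(yp.feature_keys))
    subs = sorted(panel.ks_map.substrates[kin] & set(yp.feature_keys))
    for f in own + subs:
        for s in line_samples:
            boosted = plant_outlier(boosted, f, s, 6.0)
    _, top = inka_score(boosted, panel.ks_map)
    for s in line_samples:
        assert top[s][0] == kin


# ---------------------------------------------------------------- outliers

def test_planted_entry_level_outlier_is_flagged(toy_wp):
    planted = plant_outlier(toy_wp, "P012", "S1", 8.0)
    flags = detect_outlier_kinases({"WP": planted}, {"WP": {"P012": "KIN1"}},
                                   top_frac=0.05)
    assert (("KIN1" == flags["kinase"]) & (flags["sample"] == "S1")
            & (flags["feature"] == "P012")).any()


def test_constant_matrix_yields_no_flags():
    m = OmicsMatrix("WP", pd.DataFrame(np.ones((10, 4)),
                                       index=[f"P{i}" for i in range(10)],
                                       columns=list("ABCD")))
    flags = detect_outlier_kinases({"WP": m}, {"WP": {f"P{i}": "K" for i in range(10)}})
    assert flags.empty


def test_top_frac_flags_about_five_percent_of_entries():
    rng = np.random.default_rng(1)
    m = OmicsMatrix("WP", pd.DataFrame(rng.normal(size=(500, 20)),
                                       index=[f"P{i}" for i in range(500)],
                                       columns=[f"S{j}" for j in range(20)]))
    fmap = {"WP": {f"P{i}": f"K{i}" for i in range(500)}}
    flags = detect_outlier_kinases({"WP": m}, fmap, top_frac=0.05)
    assert len(flags) == pytest.approx(500 * 20 * 0.05, rel=0.15)
    with pytest.raises(ValueError):
        detect_outlier_kinases({"WP": m}, fmap, top_frac=1.5)


# ---------------------------------------------------------------- hits

def test_subset_specific_hits_presets_and_edges():
    rng = np.random.default_rng(5)
    cols = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)]
    X = rng.normal(0, 0.05, size=(3, 8))
    X[1, :4] += 2.5   # dependency preset: p << 0.1 and |fc| > 2 -> specific
    X[2, :4] += 1.5   # |fc| < 2 -> equal under dependency preset
    tab = pd.DataFrame(X, index=["flat", "strong", "mild"], columns=cols)
    res = subset_specific_hits(tab, cols[:4], cols[4:], *DEPENDENCY_PRESET)
    assert res.loc["flat", "call"] == "equal"
    assert res.loc["strong", "call"] == "S1-specific"
    assert res.loc["mild", "call"] == "equal"
    # identical groups -> all equal under any preset
    same = subset_specific_hits(tab, cols[:4], cols[:4])
    assert (same["call"] == "equal").all()
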