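"""Focus matching checked against planted ground truth and a brute-force
maximum-cardinality matching oracle, plus histogram and chi-squared forms."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from teloscreen import (
    FociSimConfig,
    cofoci_histogram,
    generate_foci,
    group_ratio_summary,
    match_foci,
    match_foci_table,
    positive_fraction_test,
)
from teloscreen.foci import coloc_results_frame


def brute_force_max_matching(a, b, threshold):
    """Maximum-cardinality matching on the distance-thresholded bipartite
    graph — an upper bound for any one-to-one matching rule."""
    g = nx.Graph()
    g.add_nodes_from((0, i) for i in range(len(a)))
    g.add_nodes_from((1, j) for j in range(len(b)))
    d = cdist(a, b)
    for i in range(len(a)):
        for j in range(len(b)):
            if d[i, j] <= threshold:
                g.add_edge((0, i), (1, j))
    return len(nx.bipartite.maximum_matching(g, top_nodes=[(0, i) for i in range(len(a))])) // 2


def test_coincident_pair_matches():
    res = match_foci({"A": np.array([[1.0, 1.0]]), "B": np.array([[1.0, 1.0]])}, 0.5)
    assert res.n_coloc == 1 and res.ratio == 1.0


def test_distant_pair_does_not_match():
    res = match_foci({"A": np.array([[0.0, 0.0]]), "B": np.array([[10.0, 0.0]])}, 1.0)
    assert res.n_coloc == 0 and res.ratio == 0.0


def test_matching_validation():
    foci = {"A": np.zeros((1, 2)), "B": np.zeros((1, 2))}
    with pytest.raises(ValueError):
        match_foci(foci, threshold=0.0)
    with pytest.raises(ValueError):
        match_foci(foci, 1.0, channels=["A", "C"])
    with pytest.raises(ValueError):
        match_foci(foci, 1.0, reference="Z")


def test_ratio_undefined_when_reference_empty():
    res = match_foci(
        {"A": np.array([[0.0, 0.0]]), "B": np.zeros((0, 2))}, 1.0, reference="B"
    )
    assert res.n_coloc == 0 and res.ratio is None


def _min_spacing(points_by_channel):
    pools = [np.asarray(p) for p in points_by_channel.values()]
    best = math.inf
    for i, a in enumerate(pools):
        for b in pools[i + 1:]:
            if len(a) and len(b):
                d = cdist(a, b)
                d = d[d > 1e-12]
                if d.size:
                    best = min(best, d.min())
    return best


def test_jitter_free_planted_recovery_any_valid_threshold():
    cfg = FociSimConfig(
        n_nuclei=8, foci_per_channel={"A": 10, "B": 10},
        colocalized_fraction=0.4, jitter_sd=0.0, seed=6,
    )
    table, truth = generate_foci(cfg)
    results = match_foci_table(table, ("A", "B"), threshold=1e-6)
    for r, expected in zip(results, truth["n_coloc_true"]):
        assert r.n_coloc >= expected  # uniform foci can add chance matches
    # thresholds strictly below the minimum non-planted spacing recover
    # the planted count exactly
    for nucleus_id, sub in table.groupby("nucleus_id", sort=False):
        pts = {ch: sub[sub["channel"] == ch][["x", "y"]].to_numpy() for ch in ("A", "B")}
        spacing = _min_spacing(pts)
        for thr in (spacing * 0.5, spacing * 0.99):
            res = match_foci(pts, thr)
            expected = int(truth.loc[truth["nucleus_id"] == nucleus_id, "n_coloc_true"].iloc[0])
            assert res.n_coloc == expected
            assert res.n_coloc == brute_force_max_matching(pts["A"], pts["B"], thr)


def test_monotone_in_threshold(rng):
    a = rng.uniform(0, 10, size=(12, 2))
    b = rng.uniform(0, 10, size=(12, 2))
    counts = [match_foci({"A": a, "B": b}, t).n_coloc for t in (0.1, 0.5, 1, 2, 5, 20)]
    assert counts == sorted(counts)


def test_symmetry_and_rigid_motion_invariance(rng):
    a = rng.uniform(0, 10, size=(7, 2))
    b = rng.uniform(0, 10, size=(9, 2))
    base = match_foci({"A": a, "B": b}, 1.5).n_coloc
    assert match_foci({"B": b, "A": a}, 1.5, channels=["B", "A"]).n_coloc == base
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shift = np.array([100.0, -40.0])
    moved = match_foci({"A": a @ rot.T + shift, "B": b @ rot.T + shift}, 1.5).n_coloc
    assert moved == base


def test_mutual_nn_bounded_by_max_matching(rng):
    for _ in range(25):
        na, nb = rng.integers(1, 9, size=2)
        a = rng.uniform(0, 5, size=(na, 2))
        b = rng.uniform(0, 5, size=(nb, 2))
        thr = float(rng.uniform(0.2, 3.0))
        mine = match_foci({"A": a, "B": b}, thr).n_coloc
        assert mine <= brute_force_max_matching(a, b, thr)


def test_triple_channel_recovers_planted_anchors():
    cfg = FociSimConfig(
        n_nuclei=6, foci_per_channel={"A": 8, "B": 8, "C": 8},
        channels=("A", "B", "C"), colocalized_fraction=0.5, jitter_sd=0.0, seed=13,
    )
    table, truth = generate_foci(cfg)
    for nucleus_id, sub in table.groupby("nucleus_id", sort=False):
        pts = {ch: sub[sub["channel"] == ch][["x", "y"]].to_numpy() for ch in ("A", "B", "C")}
        thr = 0.99 * _min_spacing(pts)
        res = match_foci(pts, thr, channels=("A", "B", "C"))
        expected = int(truth.loc[truth["nucleus_id"] == nucleus_id, "n_coloc_true"].iloc[0])
        assert res.n_coloc == expected


def test_zero_colocalization_gives_near_zero_matches():
    cfg = FociSimConfig(
        n_nuclei=30, foci_per_channel={"A": 10, "B": 10},
        colocalized_fraction=0.0, jitter_sd=0.0, field_size=100.0, seed=3,
    )
    table, _ = generate_foci(cfg)
    results = match_foci_table(table, ("A", "B"), threshold=0.5)
    # chance matching only: expected pairs per nucleus ~ n^2 * pi r^2 / A ~ 0.008
    assert sum(r.n_coloc for r in results) <= 2


def test_histogram_spec_cases():
    assert cofoci_histogram([6] * 10) == {"0": 0, "1-4": 0, "5-8": 1.0, "9-10": 0, ">10": 0}
    h = cofoci_histogram([0, 0, 11, 11])
    assert h["0"] == 0.5 and h[">10"] == 0.5
    assert sum(h.values()) == pytest.approx(1.0)


def test_histogram_matches_direct_tabulation(rng):
    counts = rng.integers(0, 15, size=200)
    h = cofoci_histogram(list(counts))
    assert h["5-8"] == np.isin(counts, [5, 6, 7, 8]).mean()
    assert h[">10"] == (counts > 10).mean()
    assert sum(h.values()) == pytest.approx(1.0)


def test_histogram_rejects_overlapping_bins_and_empty():
    with pytest.raises(ValueError):
        cofoci_histogram([1, 2], bins=[("a", 0, 5), ("b", 3, 8)])
    with pytest.raises(ValueError):
        cofoci_histogram([])


def test_chi2_closed_form():
    # hand oracle: chi2 = n (ad - bc)^2 / (r1 r2 c1 c2)
    def hand(a, na, b, nb):
        t = np.array([[a, na - a], [b, nb - b]], dtype=float)
        n = t.sum()
        return n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2 / (
            t.sum(1).prod() * t.sum(0).prod()
        )

    res = positive_fraction_test(90, 100, 40, 100)
    assert res["chi2"] == pytest.approx(hand(90, 100, 40, 100))
    assert res["chi2"] == pytest.approx(54.95, abs=0.005)
    assert res["p_value"] < 0.001
    res2 = positive_fraction_test(0, 10, 10, 10)
    assert res2["chi2"] == pytest.approx(20.0)
    assert res2["p_value"] < 0.001
    same = positive_fraction_test(50, 100, 50, 100)
    assert same["chi2"] == 0.0 and same["p_value"] == pytest.approx(1.0)


def test_chi2_validation():
    with pytest.raises(ValueError):
        positive_fraction_test(5, 4, 1, 10)
    with pytest.raises(ValueError):
        positive_fraction_test(0, 10, 0, 10)  # zero positive margin


def test_group_ratio_summary_identical_and_errors():
    res = group_ratio_summary({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]})
    assert res["comparison"]["p_value"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        group_ratio_summary({"a": [0.1, 0.2]})
    with pytest.raises(ValueError):
        group_ratio_summary({"a": [0.1], "b": [0.1, 0.2]})


def test_group_ratio_summary_recovers_planted_fold_change():
    tables = {}
    for group, frac, seed in [("WT", 0.2, 1), ("KO", 0.4, 2)]:
        table, _ = generate_foci(
            FociSimConfig(
                n_nuclei=40, foci_per_channel={"DAMAGE": 10, "TEL": 10},
                colocalized_fraction=frac, jitter_sd=0.2, field_size=100.0,
                seed=seed,
            )
        )
        tables[group] = match_foci_table(table, ("DAMAGE", "TEL"), 1.5, reference="TEL")
    res = group_ratio_summary(tables)
    fold = res["group_means"]["KO"] / res["group_means"]["WT"]
    assert fold == pytest.approx(2.0, rel=0.15)
    assert res["comparison"]["p_value"] < 0.001


def test_coloc_results_frame_shape():
    res = match_foci({"A": np.zeros((2, 2)), "B": np.zeros((3, 2))}, 1.0, nucleus_id="n1")
    df = coloc_results_frame([res])
    assert set(df.columns) >= {"nucleus_id", "n_A", "n_B", "n_coloc", "ratio"}
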