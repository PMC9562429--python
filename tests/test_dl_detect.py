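"""Differential localization: robust distances, two-stage detection."""

import itertools

import numpy as np
import pandas as pd
import pytest

import spatmap as sm
from _utils import build_cmap, classify_both, prep_experiment
from spatmap.dl_detect import (
    CompartmentStats,
    DistanceProfileSet,
    closest_compartment,
    collate_dl,
    compartment_stats,
    distance_profile,
    merge_nuclear,
    qualitative_dl,
    run_dl_analysis,
)
from spatmap.dl_detect import test_dl as dl_distance_test
from spatmap.io_preprocess import ProfileMatrix


def _stats(center, cov):
    center = np.asarray(center, dtype=float)
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    return CompartmentStats(
        compartment="c", center=center, covariance=cov,
        precision=np.linalg.inv(cov), n_members=10,
    )


class TestMergeNuclear:
    def test_eleven_to_ten_classes(self, big_classified):
        merged = merge_nuclear(big_classified["A"])
        assert len(merged.taxonomy) == 10
        assert "nucleus" in merged.taxonomy
        assert "nucleus_chromatin" not in merged.taxonomy

    def test_idempotent(self, big_classified):
        once = merge_nuclear(big_classified["A"])
        twice = merge_nuclear(once)
        pd.testing.assert_frame_equal(once.assignments, twice.assignments)
        assert once.taxonomy == twice.taxonomy

    def test_marker_counts_conserved(self, big_classified):
        cm = big_classified["A"]
        markers = cm.assignments[cm.assignments["is_marker"]]
        n_nuc = markers["predicted"].isin(
            ["nucleus_chromatin", "nucleus_nonchromatin"]
        ).sum()
        merged = merge_nuclear(cm)
        m_markers = merged.assignments[merged.assignments["is_marker"]]
        assert (m_markers["predicted"] == "nucleus").sum() == n_nuc
        assert len(m_markers) == len(markers)


class TestDistanceOracles:
    def test_identity_covariance_reduces_to_euclidean(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(size=6)
        x = rng.normal(size=6)
        d = distance_profile(x, {"c": _stats(mu, np.eye(6))}, reduce=False)
        assert d["c"] == pytest.approx(np.linalg.norm(x - mu))

    def test_distance_at_center_is_zero(self):
        mu = np.array([0.2, 0.5, 0.3])
        d = distance_profile(mu, {"c": _stats(mu, np.eye(3))}, reduce=False)
        assert d["c"] == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_hand_case(self):
        # variance 4, offset 2 -> distance 1
        d = distance_profile([2.0], {"c": _stats([0.0], [[4.0]])}, reduce=False)
        assert d["c"] == pytest.approx(1.0)

    def test_affine_invariance_with_empirical_covariance(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 5)), index=[f"P{i}" for i in range(40)])
        A = rng.normal(size=(5, 5)) + 5 * np.eye(5)  # invertible
        XA = pd.DataFrame(X.to_numpy() @ A.T, index=X.index)
        members = X.index[:25]
        s1 = compartment_stats(X, members, estimator="empirical", reduce=False)
        s2 = compartment_stats(XA, members, estimator="empirical", reduce=False)
        for i in range(25, 40):
            d1 = distance_profile(X.iloc[i].to_numpy(), {"c": s1}, reduce=False)
            d2 = distance_profile(XA.iloc[i].to_numpy(), {"c": s2}, reduce=False)
            assert d1["c"] == pytest.approx(d2["c"], abs=1e-7)


class TestClosest:
    def test_argmin_by_label(self):
        d = pd.Series({"cytosol": 3.0, "ER": 1.0, "Golgi": 2.0})
        assert closest_compartment(d, ("cytosol", "ER", "Golgi")) == "ER"

    def test_tie_broken_by_taxonomy_order(self):
        d = pd.Series({"Golgi": 1.0, "ER": 1.0, "cytosol": 5.0})
        assert closest_compartment(d, ("cytosol", "ER", "Golgi")) == "ER"
        all_equal = pd.Series({"cytosol": 2.0, "ER": 2.0})
        assert closest_compartment(all_equal, ("cytosol", "ER")) == "cytosol"

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            closest_compartment(pd.Series({"ER": np.inf}))


class TestCompartmentStats:
    def test_identical_members_degenerate_to_ridge(self):
        data = pd.DataFrame(
            np.tile([0.5, 0.3, 0.2], (8, 1)), index=[f"P{i}" for i in range(8)]
        )
        st = compartment_stats(data, data.index, estimator="empirical", reduce=False)
        np.testing.assert_allclose(st.center, [0.5, 0.3, 0.2])
        assert np.linalg.eigvalsh(st.covariance).min() > 0

    def test_mcd_agrees_with_brute_force_subset_search(self):
        rng = np.random.default_rng(3)
        inliers = rng.normal(0, 0.5, size=(10, 2))
        outliers = np.array([[25.0, 25.0], [-30.0, 28.0]])
        X = np.vstack([inliers, outliers])
        n, p = X.shape
        h = (n + p + 1) // 2
        best_det, best_subset = np.inf, None
        for subset in itertools.combinations(range(n), h):
            c = np.cov(X[list(subset)], rowvar=False, bias=True)
            det = np.linalg.det(c)
            if det < best_det:
                best_det, best_subset = det, subset
        assert set(best_subset).isdisjoint({10, 11})  # oracle excludes outliers
        brute_center = X[list(best_subset)].mean(axis=0)
        df = pd.DataFrame(X, index=[f"P{i}" for i in range(n)])
        st = compartment_stats(df, df.index, estimator="mcd", reduce=False, seed=0)
        # both land on the inlier cloud, far from the contaminated mean
        assert np.linalg.norm(st.center - brute_center) < 0.5
        assert np.linalg.norm(X.mean(axis=0) - brute_center) > 3.0

    def test_mcd_center_resists_gross_outliers(self):
        rng = np.random.default_rng(4)
        inliers = rng.normal(0, 1, size=(40, 3))
        outliers = rng.normal(50, 1, size=(10, 3))
        X = pd.DataFrame(np.vstack([inliers, outliers]),
                         index=[f"P{i}" for i in range(50)])
        st = compartment_stats(X, X.index, estimator="mcd", reduce=False, seed=0)
        inlier_mean = inliers.mean(axis=0)
        plain_mean = X.to_numpy().mean(axis=0)
        assert np.linalg.norm(st.center - inlier_mean) < np.linalg.norm(
            plain_mean - inlier_mean
        )

    def test_too_few_members_error_names_compartment(self):
        data = pd.DataFrame(np.random.default_rng(0).random((4, 5)),
                            index=list("abcd"))
        with pytest.raises(ValueError, match="lysosome"):
            compartment_stats(data, data.index, compartment="lysosome", reduce=False)


class TestQualitative:
    def test_differing_confident_labels_listed(self):
        a = build_cmap({"P1": ("ER", 0.9, False), "P2": ("ER", 0.9, False)})
        b = build_cmap({"P1": ("Golgi", 0.9, False), "P2": ("ER", 0.9, False)})
        assert qualitative_dl(a, b) == ["P1"]

    def test_unknown_in_either_map_not_listed(self):
        a = build_cmap({"P1": ("ER", 0.9, False)})
        b = build_cmap({"P1": ("unknown", 0.3, False)})
        assert qualitative_dl(a, b) == []

    def test_identical_maps_empty(self):
        a = build_cmap({"P1": ("ER", 0.9, False)})
        assert qualitative_dl(a, a) == []


def _dps(values, condition, comps=("ER", "PM")):
    """values: {acc: {comp: [replicate distances]}}"""
    rows, idx = [], []
    for acc, by_comp in values.items():
        n_rep = len(next(iter(by_comp.values())))
        for r in range(1, n_rep + 1):
            rows.append([by_comp[c][r - 1] for c in comps])
            idx.append((acc, r))
    df = pd.DataFrame(
        rows, columns=list(comps),
        index=pd.MultiIndex.from_tuples(idx, names=["accession", "replicate"]),
    )
    return DistanceProfileSet(df, condition, tuple(comps))


class TestTestDl:
    def test_identical_distances_yield_no_calls(self):
        vals = {"P1": {"ER": [1, 1.1, 0.9], "PM": [5, 5.2, 4.8]}}
        a = _dps(vals, "A")
        b = _dps(vals, "B")
        closest = pd.Series({"P1": "ER"})
        res = dl_distance_test(a, b, closest, closest)
        assert not res["is_DL"].any()

    def test_zero_variance_handling(self, caplog):
        vals_a = {"P1": {"ER": [1.0, 1.0, 1.0], "PM": [5.0, 5.0, 5.0]}}
        vals_b_same = {"P1": {"ER": [1.0, 1.0, 1.0], "PM": [5.0, 5.0, 5.0]}}
        res = dl_distance_test(_dps(vals_a, "A"), _dps(vals_b_same, "B"),
                      pd.Series({"P1": "ER"}), pd.Series({"P1": "ER"}))
        assert res.attrs["p_values"].loc["P1"].tolist() == [1.0, 1.0]

        vals_b_diff = {"P1": {"ER": [9.0, 9.0, 9.0], "PM": [0.5, 0.5, 0.5]}}
        res2 = dl_distance_test(_dps(vals_a, "A"), _dps(vals_b_diff, "B"),
                       pd.Series({"P1": "ER"}), pd.Series({"P1": "PM"}))
        assert res2.loc["P1", "is_DL"]

    def test_requires_two_replicates(self):
        vals = {"P1": {"ER": [1.0], "PM": [2.0]}}
        with pytest.raises(ValueError, match="replicates"):
            dl_distance_test(_dps(vals, "A"), _dps(vals, "B"),
                    pd.Series({"P1": "ER"}), pd.Series({"P1": "ER"}))


class TestCollate:
    def test_union_and_stage_tags(self):
        quant = pd.DataFrame(
            {
                "closest_A": ["ER", "ER", "Golgi"],
                "closest_B": ["PM", "ER", "PM"],
                "q_A": [0.01, 0.9, 0.01],
                "q_B": [0.01, 0.9, 0.02],
                "is_DL": [True, False, True],
            },
            index=["P1", "P2", "P3"],
        )
        out = collate_dl(["P1", "P4"], quant)
        assert sorted(out.index) == ["P1", "P3", "P4"]
        assert out.loc["P1", "stage"] == "qualitative+quantitative"
        assert out.loc["P3", "stage"] == "quantitative"
        assert out.loc["P4", "stage"] == "qualitative"

    def test_empty_inputs_empty_table(self):
        empty = pd.DataFrame(
            columns=["closest_A", "closest_B", "q_A", "q_B", "is_DL"]
        )
        assert len(collate_dl([], empty)) == 0


def test_planted_translocators_recovered_end_to_end(planted_experiment):
    truth, reps, combined, marker_set = planted_experiment
    cms = classify_both(combined, marker_set)
    res = run_dl_analysis(cms["A"], cms["B"], reps["A"], reps["B"], seed=1)
    planted = truth.table.loc[
        truth.table.compartment_A != truth.table.compartment_B, "accession"
    ]
    quant = res["quantitative"]
    hits = quant.loc[quant.index.intersection(planted)]
    correct = (
        hits["is_DL"] & (hits["closest_A"] == "ER") & (hits["closest_B"] == "PM")
    )
    assert correct.sum() >= 9
    # false calls stay rare
    others = quant.loc[~quant.index.isin(planted), "is_DL"]
    assert others.mean() <= 0.01


def test_predicted_compartment_is_closest_on_clean_data():
    cfg = sm.SimulationConfig(
        n_proteins=440, marker_fraction=0.5, noise_sd=0.0,
        organelle_shift_sd=0.0, seed=29,
    )
    truth, reps, combined, marker_set = prep_experiment(cfg)
    cms = classify_both(combined, marker_set, threshold=0.0)
    res = run_dl_analysis(cms["A"], cms["B"], reps["A"], reps["B"], seed=0)
    merged = merge_nuclear(cms["A"])
    closest = res["closest"]["A"]
    predicted = merged.predicted.loc[closest.index]
    agree = (closest == predicted).mean()
    assert agree == pytest.approx(1.0)
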