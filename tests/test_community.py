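"""Community analyses: Bray-Curtis, PERMANOVA, NMDS, SIMPER, trajectories."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

import riverbaci as rb
from conftest import random_response_table


def dist_from_points(points, labels):
    D = squareform(pdist(np.asarray(points, dtype=float)))
    return pd.DataFrame(D, index=labels, columns=labels)


@pytest.fixture(scope="module")
def community_data(strong_experiment):
    X, meta = rb.abundance_matrix(strong_experiment.abundance.counts)
    T = rb.transform_abundance(X)
    return T, rb.bray_curtis_matrix(T), meta


class TestTransform:
    def test_fourth_root_values(self):
        X = pd.DataFrame({"a": [16.0, 0.0], "b": [81.0, 1.0]})
        out = rb.transform_abundance(X)
        assert out["a"].tolist() == [2.0, 0.0]
        assert out["b"].tolist() == [3.0, 1.0]
        assert np.allclose(out.to_numpy() ** 4, X.to_numpy(), atol=1e-10)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            rb.transform_abundance(pd.DataFrame({"a": [-1.0]}))


class TestBrayCurtis:
    def test_hand_value_and_bounds(self):
        X = pd.DataFrame([[1.0, 2.0, 0.0], [0.0, 2.0, 4.0]], index=["u", "v"])
        D = rb.bray_curtis_matrix(X)
        assert D.loc["u", "v"] == pytest.approx(100 * 5 / 9)
        assert D.loc["u", "u"] == 0.0
        assert D.equals(D.T)

    def test_identical_and_disjoint(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [0.0, 3.0]],
                         index=["a", "b", "c"], columns=["t1", "t2"])
        D = rb.bray_curtis_matrix(X)
        assert D.loc["a", "b"] == 0.0
        disjoint = pd.DataFrame([[5.0, 0.0], [0.0, 7.0]], index=["a", "b"])
        assert rb.bray_curtis_matrix(disjoint).loc["a", "b"] == 100.0

    def test_all_zero_pair_is_missing_with_warning(self):
        X = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]],
                         index=["z1", "z2", "ok"])
        with pytest.warns(UserWarning, match="all-zero"):
            D = rb.bray_curtis_matrix(X)
        assert np.isnan(D.loc["z1", "z2"])

    def test_taxon_order_invariance(self, community_data):
        T, D, _ = community_data
        shuffled = T[list(T.columns[::-1])]
        D2 = rb.bray_curtis_matrix(shuffled)
        assert np.allclose(D.to_numpy(), D2.to_numpy(), atol=1e-10)


class TestPermanova:
    def test_df_column_matches_design(self, community_data):
        _, D, meta = community_data
        table = rb.permanova(D, meta, n_perm=99, seed=0)
        assert table["df"].tolist() == [5, 1, 5, 24, 1, 1, 5, 5, 24]
        assert table["source"].tolist() == list(rb.community.PERMANOVA_SOURCES)

    def test_ss_additivity_against_total(self, community_data):
        _, D, meta = community_data
        table = rb.permanova(D, meta, n_perm=99, seed=0)
        G = rb.community._gower(D.to_numpy())
        assert table["SS"].sum() == pytest.approx(np.trace(G), rel=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_euclidean_special_case_equals_anova(self, seed):
        rng = np.random.default_rng(seed)
        data = random_response_table(rng, r=3, s=3, effect=rng.normal(0, 3))
        an = rb.fit_baci_anova(data, transform="none")
        labels = data["river"] + "|" + data["site"] + "|" + data["period"]
        D = dist_from_points(data[["value"]].to_numpy(), labels)
        meta = data.set_index(labels)
        table = rb.permanova(D, meta, n_perm=99, seed=0).set_index("source")
        uni = an.table.set_index("source")
        pairs = {
            "River": "River", "Treatment": "Treatment",
            "River x Treatment": "Treatment x River",
            "Time": "Time", "Time x Treatment": "Time x Treatment",
            "Time x River": "Time x River",
            "Time x River x Treatment": "Time x Treatment x River",
        }
        for multi, single in pairs.items():
            assert table.loc[multi, "pseudo_F"] == pytest.approx(
                uni.loc[single, "F"], rel=1e-6
            )

    def test_strong_treatment_interaction_detected(self, community_data):
        _, D, meta = community_data
        table = rb.permanova(D, meta, n_perm=199, seed=1).set_index("source")
        assert table.loc["Time x Treatment", "P_perm"] <= 0.01
        assert (table["P_perm"].dropna() > 0).all()
        assert (table["P_perm"].dropna() <= 1).all()

    def test_label_mismatch_rejected(self, community_data):
        _, D, meta = community_data
        with pytest.raises(ValueError, match="labels"):
            rb.permanova(D.iloc[::-1], meta, n_perm=99, seed=0)


class TestPairwise:
    def test_t_squared_is_two_group_pseudo_f(self, community_data):
        # cross-check against an independent one-way implementation
        _, D, meta = community_data
        after = meta.index[meta["period"] == "after"]
        sub = D.loc[after, after]
        t, p = rb.pairwise_permanova(sub, meta.loc[after, "treatment"],
                                     n_perm=499, seed=0)
        dm = DistanceMatrix(sub.to_numpy() / 100.0, ids=list(range(len(sub))))
        ref = skbio_permanova(dm, grouping=meta.loc[after, "treatment"].to_numpy(),
                              permutations=99)
        assert t**2 == pytest.approx(ref["test statistic"], rel=1e-10)
        assert p <= 0.01

    def test_identical_groups_not_separated(self):
        points = [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]] * 2
        labels = [f"s{i}" for i in range(8)]
        D = dist_from_points(points, labels)
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=labels)
        # group b replicates group a exactly
        t, p = rb.pairwise_permanova(D, groups, n_perm=199, seed=0)
        assert p > 0.5

    def test_tiny_group_rejected(self, community_data):
        _, D, meta = community_data
        labels = list(D.index[:5])
        groups = pd.Series(["a"] * 4 + ["b"], index=labels)
        with pytest.raises(ValueError, match="at least two"):
            rb.pairwise_permanova(D.loc[labels, labels], groups, n_perm=99)


class TestNmds:
    def test_exactly_embeddable_configuration(self):
        points = [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.2, 1.1], [0.5, 2.0]]
        D = dist_from_points(points, [f"p{i}" for i in range(5)])
        res = rb.nmds(D, n_restarts=10, seed=0)
        assert res.stress < 0.01

    def test_stress_monotone_within_run(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(12, 4))
        D = dist_from_points(points, [f"p{i}" for i in range(12)])
        res = rb.nmds(D, n_restarts=3, seed=1)
        h = np.array(res.stress_history)
        assert (np.diff(h) <= 1e-8).all()

    def test_rank_agreement_on_low_noise_fixture(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        points = rng.normal(size=(15, 2))
        D = dist_from_points(points, [f"p{i}" for i in range(15)])
        res = rb.nmds(D, n_restarts=10, seed=2)
        out = pdist(res.coords.to_numpy())
        rho = spearmanr(squareform(D.to_numpy(), checks=False), out).statistic
        assert rho > 0.95

    def test_too_few_samples_rejected(self):
        D = dist_from_points([[0.0], [1.0], [2.0]], ["a", "b", "c"])
        with pytest.raises(ValueError, match="four"):
            rb.nmds(D)


class TestSimper:
    def test_single_differing_taxon_takes_all_contribution(self):
        X = pd.DataFrame(
            {"t1": [1.0, 1.0, 1.0, 1.0], "t2": [0.0, 0.0, 2.0, 2.0]},
            index=["a1", "a2", "b1", "b2"],
        )
        groups = pd.Series(["A", "A", "B", "B"], index=X.index)
        res = rb.simper(X, groups)
        assert res.table.loc["t2", "cum_pct"] == pytest.approx(100.0)
        assert res.table.loc["t1", "average_contribution"] == 0.0

    def test_contributions_sum_to_average_dissimilarity(self, community_data):
        T, D, meta = community_data
        after = meta.index[meta["period"] == "after"]
        res = rb.simper(T.loc[after], meta.loc[after, "treatment"])
        total = res.table["average_contribution"].sum()
        assert total == pytest.approx(res.average_dissimilarity, rel=1e-8)
        # and the average dissimilarity matches the Bray-Curtis matrix
        ctl = [i for i in after if meta.loc[i, "treatment"] == "control"]
        man = [i for i in after if meta.loc[i, "treatment"] == "manipulation"]
        assert res.average_dissimilarity == pytest.approx(
            D.loc[ctl, man].to_numpy().mean(), rel=1e-8
        )

    def test_matches_brute_force_decomposition(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.uniform(0, 5, size=(6, 5)),
                         index=[f"s{i}" for i in range(6)],
                         columns=[f"t{j}" for j in range(5)])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=X.index)
        res = rb.simper(X, groups)
        expected = np.zeros(5)
        n_pairs = 0
        for i in range(3):
            for j in range(3, 6):
                xi, xj = X.iloc[i].to_numpy(), X.iloc[j].to_numpy()
                expected += 100 * np.abs(xi - xj) / (xi + xj).sum()
                n_pairs += 1
        expected /= n_pairs
        got = res.table["average_contribution"].reindex(X.columns).to_numpy()
        assert np.allclose(got, expected, rtol=1e-10)


class TestTrajectories:
    def test_stationary_community_zero_arrow(self):
        coords = pd.DataFrame(
            {"NMDS1": [1.0, 1.0, 2.0, 2.0], "NMDS2": [0.0, 0.0, 1.0, 1.0]},
            index=["a", "b", "c", "d"],
        )
        meta = pd.DataFrame(
            {"river": ["R1"] * 4, "treatment": ["control"] * 2 + ["manipulation"] * 2,
             "period": ["before", "after"] * 2},
            index=coords.index,
        )
        out = rb.centroid_trajectories(coords, meta)
        assert np.allclose(out["displacement"], 0.0)
        # single-sample groups: centroid is the point itself
        row = out[out["treatment"] == "control"].iloc[0]
        assert (row["NMDS1_before"], row["NMDS2_before"]) == (1.0, 0.0)

    def test_displacement_invariant_to_rotation(self, community_data):
        _, D, meta = community_data
        res = rb.nmds(D, n_restarts=3, seed=5)
        base = rb.centroid_trajectories(res.coords, meta)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rotated = pd.DataFrame(res.coords.to_numpy() @ R.T,
                               index=res.coords.index, columns=res.coords.columns)
        rot = rb.centroid_trajectories(rotated, meta)
        merged = base.merge(rot, on=["river", "treatment"], suffixes=("", "_rot"))
        assert np.allclose(merged["displacement"],
                           merged["displacement_rot"], atol=1e-10)
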