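import numpy as np
import pandas as pd
import pytest

import commstruct as cs
from commstruct.beta_structure import BetaStructureError

from conftest import dnn_oracle, dpw_oracle, random_community, random_distance_matrix


class TestDpw:
    def test_single_term(self):
        d = pd.DataFrame([[0.0, 6.0], [6.0, 0.0]], index=list("AB"),
                         columns=list("AB"))
        assert cs.dpw(pd.Series({"A": 1.0}), pd.Series({"B": 1.0}), d) == 6.0

    def test_hand_value_two_species(self, abc_dist):
        k1 = pd.Series({"A": 1.0})
        k2 = pd.Series({"B": 0.5, "C": 0.5})
        assert cs.dpw(k1, k2, abc_dist) == pytest.approx(3.0)

    def test_identical_single_species_zero(self, abc_dist):
        k = pd.Series({"A": 1.0})
        assert cs.dpw(k, k, abc_dist) == 0.0

    def test_missing_species_named(self, abc_dist):
        with pytest.raises(BetaStructureError, match="Z"):
            cs.dpw(pd.Series({"Z": 1.0}), pd.Series({"A": 1.0}), abc_dist)


class TestDnn:
    def test_single_pair_both_conventions(self):
        d = pd.DataFrame([[0.0, 6.0], [6.0, 0.0]], index=list("AB"),
                         columns=list("AB"))
        k1, k2 = pd.Series({"A": 1.0}), pd.Series({"B": 1.0})
        assert cs.dnn(k1, k2, d, convention="literal") == 12.0
        assert cs.dnn(k1, k2, d, convention="halved") == 6.0

    def test_hand_value(self, abc_dist):
        k1 = pd.Series({"A": 1.0})
        k2 = pd.Series({"B": 0.5, "C": 0.5})
        assert cs.dnn(k1, k2, abc_dist) == pytest.approx(5.0)

    def test_self_comparison_zero(self, abc_dist):
        k = pd.Series({"A": 2.0, "B": 1.0})
        assert cs.dnn(k, k, abc_dist, convention="literal") == 0.0
        assert cs.dnn(k, k, abc_dist, convention="halved") == 0.0


class TestBetaProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_equivalence_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        labels = [f"s{i}" for i in range(rng.integers(4, 12))]
        dist = random_distance_matrix(rng, labels)
        k1 = random_community(rng, labels)
        k2 = random_community(rng, labels)
        assert cs.dpw(k1, k2, dist) == pytest.approx(
            dpw_oracle(k1, k2, dist), abs=1e-12)
        assert cs.dpw(k1, k2, dist) == pytest.approx(
            cs.dpw(k2, k1, dist), abs=1e-12)
        for conv in ("literal", "halved"):
            assert cs.dnn(k1, k2, dist, conv) == pytest.approx(
                dnn_oracle(k1, k2, dist, conv), abs=1e-12)
            assert cs.dnn(k1, k2, dist, conv) == pytest.approx(
                cs.dnn(k2, k1, dist, conv), abs=1e-12)

    def test_literal_is_twice_halved(self, abc_dist):
        k1 = pd.Series({"A": 2.0, "B": 1.0})
        k2 = pd.Series({"B": 1.0, "C": 3.0})
        assert cs.dnn(k1, k2, abc_dist, "literal") == pytest.approx(
            2 * cs.dnn(k1, k2, abc_dist, "halved"))

    def test_linear_scaling(self, abc_dist):
        k1 = pd.Series({"A": 2.0, "B": 1.0})
        k2 = pd.Series({"B": 1.0, "C": 3.0})
        assert cs.dpw(k1, k2, abc_dist * 2.5) == pytest.approx(
            2.5 * cs.dpw(k1, k2, abc_dist))
        assert cs.dnn(k1, k2, abc_dist * 2.5) == pytest.approx(
            2.5 * cs.dnn(k1, k2, abc_dist))

    def test_beta_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(17)
        labels = [f"s{i}" for i in range(10)]
        dist = random_distance_matrix(rng, labels)
        comm = pd.DataFrame([random_community(rng, labels) for _ in range(6)],
                            index=[f"site{i}" for i in range(6)])
        for metric, fn in [("Dpw", cs.dpw), ("Dnn", cs.dnn)]:
            mat = cs.beta_matrix(comm, dist, metric)
            for a in comm.index:
                for b in comm.index:
                    assert mat.loc[a, b] == pytest.approx(
                        fn(comm.loc[a], comm.loc[b], dist), abs=1e-10)

    def test_trait_dpw_on_gower_stays_in_unit_scale(self):
        rng = np.random.default_rng(18)
        traits = pd.DataFrame(rng.random((8, 4)) + 0.5,
                              index=[f"s{i}" for i in range(8)],
                              columns=list("wbtm"))
        g = cs.gower_matrix(traits)
        comm = pd.DataFrame([random_community(rng, list(traits.index))
                             for _ in range(5)],
                            index=[f"site{i}" for i in range(5)])
        mat = cs.beta_matrix(comm, g, "traitDpw")
        assert (mat.to_numpy() >= 0).all() and (mat.to_numpy() <= 1).all()


class TestBetaNullStandardize:
    def test_exchangeable_distances_flagged(self):
        labels = list("abcd")
        d = pd.DataFrame(1.0, index=labels, columns=labels)
        np.fill_diagonal(d.to_numpy(), 0)
        d = pd.DataFrame(np.where(np.eye(4), 0.0, 1.0), index=labels,
                         columns=labels)
        comm = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1.0]],
                            index=["x", "y"], columns=labels)
        res = cs.beta_null_standardize(comm, d, "Dpw", n_null=19, seed=0)
        assert res.null_sd.loc["x", "y"] == 0
        assert np.isnan(res.ses.loc["x", "y"])

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(19)
        labels = [f"s{i}" for i in range(12)]
        dist = random_distance_matrix(rng, labels)
        comm = pd.DataFrame([random_community(rng, labels) for _ in range(5)],
                            index=[f"site{i}" for i in range(5)])
        a = cs.beta_null_standardize(comm, dist, "Dnn", n_null=49, seed=3)
        b = cs.beta_null_standardize(comm, dist, "Dnn", n_null=49, seed=3)
        pd.testing.assert_frame_equal(a.ses, b.ses)

    def test_n_null_must_be_positive(self, abc_dist):
        comm = pd.DataFrame([[1, 1, 0], [0, 1, 1.0]], index=["x", "y"],
                            columns=list("ABC"))
        with pytest.raises(BetaStructureError):
            cs.beta_null_standardize(comm, abc_dist, "Dpw", n_null=0)

    def test_null_self_calibration(self):
        # communities of random pool draws: per-pair SES centered near 0
        rng = np.random.default_rng(20)
        tree = cs.simulate_tree(25, rng)
        dist = cs.cophenetic_matrix(tree)
        labels = list(tree.tips)
        comm = pd.DataFrame([random_community(rng, labels, k=int(rng.integers(5, 15)))
                             for _ in range(30)],
                            index=[f"site{i}" for i in range(30)])
        res = cs.beta_null_standardize(comm, dist, "Dpw", n_null=99, seed=4)
        iu = np.triu_indices(30, k=1)
        mean_ses = np.nanmean(res.ses.to_numpy()[iu])
        assert -0.2 < mean_ses < 0.2


class TestRegionContrast:
    def _setup(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        sites = [f"s{i}" for i in range(12)]
        regions = pd.Series(["west"] * 6 + ["east"] * 6, index=sites)
        base = rng.normal(10, 1, size=(12, 12))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0)
        m[:6, :6] += shift    # shift within-west pairs
        m = (m + m.T) / 2
        return pd.DataFrame(m, index=sites, columns=sites), regions

    def test_identical_values_no_difference(self):
        sites = [f"s{i}" for i in range(8)]
        regions = pd.Series(["west"] * 4 + ["east"] * 4, index=sites)
        m = pd.DataFrame(np.where(np.eye(8), 0.0, 5.0), index=sites,
                         columns=sites)
        tab = cs.region_contrast(m, regions)
        assert (tab["p_adj"] > 0.9).all()

    def test_large_shift_detected(self):
        beta, regions = self._setup(shift=30.0)
        tab = cs.region_contrast(beta, regions)
        ww = tab[(tab["group1"] == "east-east") & (tab["group2"] == "west-west")]
        assert (ww["p_adj"] < 0.001).all()

    def test_single_region_error(self):
        sites = ["a", "b", "c"]
        regions = pd.Series(["west"] * 3, index=sites)
        m = pd.DataFrame(np.ones((3, 3)) - np.eye(3), index=sites, columns=sites)
        with pytest.raises(BetaStructureError):
            cs.region_contrast(m, regions)


class TestPartialMantel:
    def test_self_correlation(self):
        rng = np.random.default_rng(21)
        m = random_distance_matrix(rng, [f"s{i}" for i in range(10)])
        r, p = cs.partial_mantel(m, m, n_perm=199, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_control_equal_to_m2_kills_correlation(self):
        rng = np.random.default_rng(22)
        m1 = random_distance_matrix(rng, [f"s{i}" for i in range(10)])
        m2 = random_distance_matrix(rng, [f"s{i}" for i in range(10)])
        # residualizing m2 on itself leaves only numerical noise, so the
        # partial correlation collapses to ~0
        r, _ = cs.partial_mantel(m1, m2, control=m2, n_perm=99, seed=0)
        assert abs(r) < 0.01

    def test_size_mismatch_error(self):
        a = pd.DataFrame(np.zeros((3, 3)))
        b = pd.DataFrame(np.zeros((4, 4)))
        with pytest.raises(BetaStructureError):
            cs.partial_mantel(a, b)

    def test_agrees_with_skbio_simple_mantel(self):
        # independent reference implementation for the no-control case
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(23)
        labels = [f"s{i}" for i in range(12)]
        m1 = random_distance_matrix(rng, labels)
        m2 = random_distance_matrix(rng, labels)
        r, _ = cs.partial_mantel(m1, m2, n_perm=99, seed=0)
        r_ref, _, _ = mantel(DistanceMatrix(m1.to_numpy(), labels),
                             DistanceMatrix(m2.to_numpy(), labels),
                             permutations=0)
        assert r == pytest.approx(r_ref, abs=1e-10)
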