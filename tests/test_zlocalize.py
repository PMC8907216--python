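import itertools

import numpy as np
import pandas as pd
import pytest

from nanotopo.loc_io import LocalizationTable
from nanotopo.zlocalize import (AlignmentError, _mutual_nn_pairs, assign_z,
                                correct_refractive_index,
                                estimate_channel_transform, pair_localizations)


def table(frame, x, y, intensity=None, **kw):
    n = len(x)
    return LocalizationTable.from_arrays(
        frame, x, y, intensity if intensity is not None else np.full(n, 1000.0),
        **kw)


def random_table(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return table(rng.integers(0, 20, n), rng.uniform(0, 2e4, n),
                 rng.uniform(0, 2e4, n), rng.uniform(500, 3000, n))


class TestChannelTransform:
    def test_recovers_translation(self):
        t1 = random_table(seed=1)
        t2 = table(t1.df["frame"], t1.df["x"] + 100.0, t1.df["y"] - 50.0)
        tf = estimate_channel_transform(t1, t2)
        mapped = tf.apply(t2.df[["x", "y"]].to_numpy())
        np.testing.assert_allclose(mapped, t1.df[["x", "y"]].to_numpy(),
                                   atol=1.0)
        assert tf.rms_residual < 1.0

    def test_identity_for_identical_tables(self):
        t1 = random_table(seed=2)
        tf = estimate_channel_transform(t1, t1)
        np.testing.assert_allclose(tf.transform.params, np.eye(3), atol=1e-6)

    def test_recovers_rotation_and_scale(self):
        t1 = random_table(seed=3)
        theta, scale = 0.01, 1.002
        rot = scale * np.array([[np.cos(theta), -np.sin(theta)],
                                [np.sin(theta), np.cos(theta)]])
        xy2 = t1.df[["x", "y"]].to_numpy() @ rot.T + [40.0, -30.0]
        t2 = table(t1.df["frame"], xy2[:, 0], xy2[:, 1])
        tf = estimate_channel_transform(t2, t1)  # map t1 onto t2
        mapped = tf.apply(t1.df[["x", "y"]].to_numpy())
        np.testing.assert_allclose(mapped, xy2, atol=1.0)

    def test_disjoint_point_sets_fail(self):
        rng = np.random.default_rng(4)
        t1 = table(np.zeros(20, int), rng.uniform(0, 1e3, 20),
                   rng.uniform(0, 1e3, 20))
        t2 = table(np.ones(20, int), rng.uniform(5e5, 6e5, 20),
                   rng.uniform(5e5, 6e5, 20))
        with pytest.raises(AlignmentError):
            estimate_channel_transform(t1, t2)


class TestPairing:
    def test_single_pair_within_threshold(self):
        t1 = table([0], [0.0], [0.0])
        t2 = table([0], [100.0], [0.0])
        pairs, rep = pair_localizations(t1, t2, None, max_dist=500)
        assert rep.n_pairs == 1 and len(pairs) == 1

    def test_beyond_threshold_unpaired(self):
        t1 = table([0], [0.0], [0.0])
        t2 = table([0], [600.0], [0.0])
        pairs, rep = pair_localizations(t1, t2, None, max_dist=500)
        assert rep.n_pairs == 0
        assert rep.n_unpaired_1 == 1 and rep.n_unpaired_2 == 1

    def test_different_frames_never_pair(self):
        t1 = table([0], [0.0], [0.0])
        t2 = table([1], [0.0], [0.0])
        _, rep = pair_localizations(t1, t2, None)
        assert rep.n_pairs == 0

    def test_ascending_distance_matching(self):
        # distances: a1-b1 = 50, a2-b2 = 60, a1-b2 = 310, a2-b1 = 300;
        # brute force over one-to-one matchings confirms {a1-b1, a2-b2}
        t1 = table([0, 0], [0.0, 360.0], [0.0, 0.0])
        t2 = table([0, 0], [50.0, 300.0], [0.0, 0.0])
        pairs, rep = pair_localizations(t1, t2, None, max_dist=500)
        assert rep.n_pairs == 2
        assert sorted(zip(pairs["x"], pairs["I2"])) == [(0.0, 1000.0),
                                                        (360.0, 1000.0)]
        xy1 = t1.df[["x", "y"]].to_numpy()
        xy2 = t2.df[["x", "y"]].to_numpy()
        best = min(itertools.permutations(range(2)),
                   key=lambda p: sum(np.linalg.norm(xy1[i] - xy2[p[i]])
                                     for i in range(2)))
        assert best == (0, 1)

    def test_matches_greedy_brute_force(self):
        """Greedy ascending-distance matching agrees with an independent
        brute-force greedy enumeration on random frames."""
        rng = np.random.default_rng(7)
        xy1 = rng.uniform(0, 2000, (8, 2))
        xy2 = rng.uniform(0, 2000, (9, 2))
        mi, mj, _ = _mutual_nn_pairs(xy1, xy2, max_dist=800)
        # oracle: repeatedly take the globally closest unused pair
        d = np.linalg.norm(xy1[:, None] - xy2[None, :], axis=2)
        expected = set()
        dd = d.copy()
        while True:
            i, j = np.unravel_index(np.argmin(dd), dd.shape)
            if dd[i, j] > 800:
                break
            expected.add((i, j))
            dd[i, :] = np.inf
            dd[:, j] = np.inf
        assert set(zip(mi.tolist(), mj.tolist())) == expected

    def test_injective_on_random_inputs(self):
        t1 = random_table(300, seed=8)
        t2 = random_table(300, seed=9)
        pairs, _ = pair_localizations(t1, t2, None, max_dist=2000)
        assert pairs.duplicated(["frame", "x", "y"]).sum() == 0

    def test_symmetric_under_channel_swap(self):
        t1 = random_table(200, seed=10)
        t2 = random_table(200, seed=11)
        p12, r12 = pair_localizations(t1, t2, None, max_dist=2000)
        p21, r21 = pair_localizations(t2, t1, None, max_dist=2000)
        assert r12.n_pairs == r21.n_pairs
        a = set(zip(p12["frame"], np.round(p12["I1"], 6), np.round(p12["I2"], 6)))
        b = set(zip(p21["frame"], np.round(p21["I2"], 6), np.round(p21["I1"], 6)))
        assert a == b


class TestAssignZ:
    def make_pairs(self, gammas):
        g = np.asarray(gammas, float)
        i1 = 1000.0 * (1 - g)
        i2 = 1000.0 * (1 + g)
        return pd.DataFrame({"frame": np.zeros(len(g), int),
                             "x": np.zeros(len(g)), "y": np.zeros(len(g)),
                             "I1": i1, "I2": i2, "gamma": g})

    def test_gamma_at_node_returns_node_z(self, noiseless_lut):
        g = float(noiseless_lut.gamma_nodes[500])
        out, dropped = assign_z(self.make_pairs([g]), noiseless_lut)
        assert dropped == 0
        assert out.loc[0, "z_raw"] == pytest.approx(
            noiseless_lut.z_nodes[500], abs=1e-9)

    def test_midway_gamma_interpolates_linearly(self, noiseless_lut):
        g = 0.5 * (noiseless_lut.gamma_nodes[500] + noiseless_lut.gamma_nodes[501])
        out, _ = assign_z(self.make_pairs([g]), noiseless_lut)
        z_mid = 0.5 * (noiseless_lut.z_nodes[500] + noiseless_lut.z_nodes[501])
        assert out.loc[0, "z_raw"] == pytest.approx(z_mid, abs=1e-6)

    def test_out_of_range_gamma_dropped(self, noiseless_lut):
        out, dropped = assign_z(self.make_pairs([0.0, 0.9999]), noiseless_lut)
        assert dropped == 1 and len(out) == 1

    def test_inverts_forward_model(self, optical_model, noiseless_lut):
        g = optical_model.gamma(137.0)
        out, _ = assign_z(self.make_pairs([g]), noiseless_lut)
        assert out.loc[0, "z_raw"] == pytest.approx(137.0, abs=2.0)


class TestRefractiveIndex:
    def test_scaling_and_identity(self, noiseless_lut):
        pairs = pd.DataFrame({"z_raw": [100.0, -50.0, 0.0]})
        same = correct_refractive_index(pairs, 1.0)
        np.testing.assert_array_equal(same["z"], pairs["z_raw"])
        scaled = correct_refractive_index(pairs, 0.8)
        np.testing.assert_allclose(scaled["z"], [80.0, -40.0, 0.0])

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        pairs = pd.DataFrame({"z_raw": rng.normal(0, 100, 50)})
        out = correct_refractive_index(pairs, 0.79)
        assert (np.argsort(out["z"]) == np.argsort(pairs["z_raw"])).all()

    def test_non_positive_factor_rejected(self):
        with pytest.raises(ValueError):
            correct_refractive_index(pd.DataFrame({"z_raw": [1.0]}), 0.0)
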