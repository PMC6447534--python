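import numpy as np
import pandas as pd
import pytest

from spatcorr import (
    IsletSet,
    StraussParams,
    TranscriptTable,
    Window,
    count_pairs,
    fit_per_islet,
    fit_pseudolikelihood,
    geometry_robustness,
    log_density_unnormalized,
    simulate_multitype_strauss,
)
from spatcorr.islets import Islet
from spatcorr.strauss import PointPattern
from spatcorr.synthetic import GeneSpec, TissueSpec, make_tissue


def brute_force_pairs(xy, types, type_set, r):
    """O(n^2) oracle for unordered within-radius pair counts."""
    idx = {t: k for k, t in enumerate(type_set)}
    s = np.zeros((len(type_set), len(type_set)), dtype=int)
    for a in range(len(xy)):
        for b in range(a + 1, len(xy)):
            if np.hypot(*(xy[a] - xy[b])) <= r:
                i, j = idx[types[a]], idx[types[b]]
                s[i, j] += 1
                if i != j:
                    s[j, i] += 1
    return s


def _pattern(xy, types, window=None, type_set=()):
    window = window or Window.square(0.0, 0.0, 1000.0)
    return PointPattern(
        np.asarray(xy, float), np.asarray(types, object), window, type_set
    )


class TestCountPairs:
    def test_three_point_example(self):
        pat = _pattern([[0, 0], [10, 0], [5, 0]], ["A", "A", "B"])
        pc = count_pairs(pat, r=6.0)
        a, b = pat.type_set.index("A"), pat.type_set.index("B")
        assert pc.n[a] == 2 and pc.n[b] == 1
        assert pc.s[a, b] == 2
        assert pc.s[a, a] == 0 and pc.s[b, b] == 0

    def test_single_point_no_pairs(self):
        pat = _pattern([[0, 0]], ["A"])
        assert count_pairs(pat, 10.0).s.sum() == 0

    def test_boundary_distance_inclusive(self):
        pat = _pattern([[0, 0], [0, 10]], ["A", "A"])
        assert count_pairs(pat, 10.0).s[0, 0] == 1

    def test_matches_bruteforce_on_random_patterns(self):
        rng = np.random.default_rng(11)
        win = Window.square(0.0, 0.0, 200.0)
        for trial in range(20):
            n = int(rng.integers(2, 120))
            xy = win.sample_uniform(n, rng)
            types = rng.choice(["A", "B", "C"], size=n).astype(object)
            pat = PointPattern(xy, types, win, ("A", "B", "C"))
            r = float(rng.uniform(5, 60))
            pc = count_pairs(pat, r)
            assert (pc.s == brute_force_pairs(xy, types, pat.type_set, r)).all()


class TestLogDensity:
    def test_poisson_reduction_when_gamma_one(self):
        rng = np.random.default_rng(3)
        win = Window.circle(0, 0, 100.0)
        xy = win.sample_uniform(60, rng)
        types = rng.choice(["A", "B"], size=60).astype(object)
        pat = PointPattern(xy, types, win, ("A", "B"))
        beta = np.array([0.002, 0.005])
        params = StraussParams(("A", "B"), beta, np.ones((2, 2)), 20.0)
        n = pat.counts().to_numpy()
        assert log_density_unnormalized(pat, params) == pytest.approx(
            float(n @ np.log(beta)), abs=1e-9
        )

    def test_hand_computed_three_point_example(self):
        pat = _pattern([[0, 0], [10, 0], [5, 0]], ["A", "A", "B"])
        params = StraussParams(
            ("A", "B"),
            np.array([2.0, 3.0]),
            np.array([[1.0, 0.5], [0.5, 1.0]]),
            6.0,
        )
        # 2 ln 2 + 1 ln 3 + 2 ln 0.5
        assert log_density_unnormalized(pat, params) == pytest.approx(
            2 * np.log(2) + np.log(3) + 2 * np.log(0.5), abs=1e-6
        )

    def test_hard_core_violation_is_minus_inf(self):
        pat = _pattern([[0, 0], [10, 0], [5, 0]], ["A", "A", "B"])
        params = StraussParams(
            ("A", "B"),
            np.array([2.0, 3.0]),
            np.array([[1.0, 0.0], [0.0, 1.0]]),
            6.0,
        )
        assert log_density_unnormalized(pat, params) == -np.inf

    def test_unknown_type_rejected(self):
        pat = _pattern([[0, 0]], ["Z"])
        params = StraussParams(("A",), np.array([1.0]), np.ones((1, 1)), 5.0)
        with pytest.raises(ValueError):
            log_density_unnormalized(pat, params)


class TestFit:
    def test_null_gamma_within_3se_of_one(self, null_pattern):
        res = fit_pseudolikelihood(null_pattern, r=20.0, seed=0)
        g = res.gamma.loc["A", "B"]
        se = res.gamma_se.loc["A", "B"]
        assert abs(g - 1.0) < 3 * se

    def test_beta_matches_poisson_mle_within_10pct(self, null_pattern):
        res = fit_pseudolikelihood(null_pattern, r=20.0, seed=1)
        area = null_pattern.window.area
        for t in ("A", "B"):
            assert res.beta[t] == pytest.approx(500 / area, rel=0.35)
        # geometric-mean check is tighter: beta trades off with gamma
        gm = np.sqrt(res.beta["A"] * res.beta["B"])
        assert gm == pytest.approx(500 / area, rel=0.15)

    def test_relabeling_invariance(self, null_pattern):
        res = fit_pseudolikelihood(null_pattern, r=20.0, seed=5)
        swapped = PointPattern(
            null_pattern.xy,
            np.where(null_pattern.types == "A", "B", "A").astype(object),
            null_pattern.window,
        )
        res2 = fit_pseudolikelihood(swapped, r=20.0, seed=5)
        assert res2.gamma.loc["A", "B"] == pytest.approx(
            res.gamma.loc["A", "B"], rel=1e-6
        )
        assert res2.beta["B"] == pytest.approx(res.beta["A"], rel=1e-6)

    def test_summary_lists_pairs(self, null_pattern):
        res = fit_pseudolikelihood(null_pattern, r=20.0, seed=0)
        text = res.summary()
        assert "A ~ B" in text and "gamma" in text


class TestSimulation:
    WIN = Window.circle(0.0, 0.0, 250.0)

    def test_gamma_one_acceptance_is_exactly_one(self):
        params = StraussParams(
            ("A", "B"), np.array([0.001, 0.001]), np.ones((2, 2)), 10.0
        )
        pat, acc = simulate_multitype_strauss(
            params, self.WIN, {"A": 50, "B": 50}, steps=2000, seed=0,
            return_acceptance=True,
        )
        assert acc == 1.0
        assert len(pat) == 100

    def test_gamma_one_matches_uniform_nn_distances(self):
        # mean nearest-neighbor distance of the chain's output vs direct
        # uniform sampling, averaged over seeds
        from scipy.spatial import cKDTree

        params = StraussParams(("A",), np.array([0.001]), np.ones((1, 1)), 10.0)
        sim_means, unif_means = [], []
        for seed in range(5):
            pat = simulate_multitype_strauss(
                params, self.WIN, {"A": 200}, steps=2000, seed=seed
            )
            d, _ = cKDTree(pat.xy).query(pat.xy, k=2)
            sim_means.append(d[:, 1].mean())
            rng = np.random.default_rng(100 + seed)
            u = self.WIN.sample_uniform(200, rng)
            du, _ = cKDTree(u).query(u, k=2)
            unif_means.append(du[:, 1].mean())
        assert np.mean(sim_means) == pytest.approx(np.mean(unif_means), rel=0.10)

    def test_hard_core_output_has_no_close_same_type_pairs(self):
        win = Window.circle(0.0, 0.0, 500.0)
        params = StraussParams(
            ("A",), np.array([0.0001]), np.zeros((1, 1)), 10.0
        )
        pat = simulate_multitype_strauss(params, win, {"A": 20}, seed=2)
        assert count_pairs(pat, 10.0).s[0, 0] == 0

    def test_inhibition_reduces_cross_pairs(self):
        beta = np.array([0.002, 0.002])
        inhib = StraussParams(
            ("A", "B"), beta, np.array([[1.0, 0.5], [0.5, 1.0]]), 20.0
        )
        nullp = StraussParams(("A", "B"), beta, np.ones((2, 2)), 20.0)
        win = Window.circle(0.0, 0.0, 150.0)
        s_inhib, s_null = [], []
        for seed in range(6):
            a = simulate_multitype_strauss(
                inhib, win, {"A": 150, "B": 150}, steps=15_000, seed=seed
            )
            b = simulate_multitype_strauss(
                nullp, win, {"A": 150, "B": 150}, steps=15_000, seed=seed
            )
            ia = a.type_set.index("A")
            ib = a.type_set.index("B")
            s_inhib.append(count_pairs(a, 20.0).s[ia, ib])
            s_null.append(count_pairs(b, 20.0).s[ia, ib])
        assert np.mean(s_inhib) < np.mean(s_null)

    def test_same_seed_reproducible(self):
        params = StraussParams(
            ("A", "B"), np.array([0.001, 0.001]),
            np.array([[1.0, 0.8], [0.8, 1.0]]), 15.0,
        )
        a = simulate_multitype_strauss(params, self.WIN, {"A": 40, "B": 40},
                                       steps=3000, seed=9)
        b = simulate_multitype_strauss(params, self.WIN, {"A": 40, "B": 40},
                                       steps=3000, seed=9)
        assert np.array_equal(a.xy, b.xy)
        assert np.array_equal(a.types, b.types)


def _independent_islet_tissue(n_islets=12, per_type=60, seed=21):
    """Tissue whose islets contain two independent uniform gene types."""
    rng = np.random.default_rng(seed)
    islets, frames = [], []
    grid = np.arange(n_islets)
    for k in grid:
        cx, cy = 400.0 * (k % 4), 400.0 * (k // 4)
        r = 75.0
        islets.append(Islet(cx, cy, r, per_type * 2))
        for gene in ("G1", "G2"):
            rad = r * np.sqrt(rng.uniform(size=per_type))
            th = rng.uniform(0, 2 * np.pi, per_type)
            frames.append(
                pd.DataFrame(
                    {
                        "x": cx + rad * np.cos(th),
                        "y": cy + rad * np.sin(th),
                        "gene": gene,
                        "quality": 1.0,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    table = TranscriptTable(df, ("G1", "G2"))
    return table, IsletSet(tuple(islets), ("G1",))


class TestPerIsletFit:
    def test_independent_types_give_mean_gamma_near_one(self):
        table, islets = _independent_islet_tissue()
        res = fit_per_islet(table, islets, r=20.0, min_count=100, seed=0)
        g = res.gamma_mean.loc["G1", "G2"]
        assert 0.95 < g < 1.05
        assert res.windows_used.loc["G1", "G2"] == len(islets)
        assert res.gamma_std.loc["G1", "G2"] >= 0

    def test_single_islet_std_is_zero(self):
        table, islets = _independent_islet_tissue(n_islets=1)
        res = fit_per_islet(table, islets, r=20.0, min_count=50, seed=0)
        assert res.gamma_std.loc["G1", "G2"] == 0.0
        assert res.windows_used.loc["G1", "G2"] == 1

    def test_gate_excludes_scarce_genes(self):
        table, islets = _independent_islet_tissue()
        with pytest.raises(ValueError):
            fit_per_islet(table, islets, r=20.0, min_count=10**6)


class TestGeometryRobustness:
    def test_square_side_preserves_area(self):
        r = 73.0
        win = Window.square(0.0, 0.0, r * np.sqrt(np.pi))
        assert win.area == pytest.approx(np.pi * r**2)

    def test_null_fits_agree_across_geometry(self):
        table, islets = _independent_islet_tissue()
        out = geometry_robustness(table, islets, r=20.0, min_count=100, seed=3)
        assert out["abs_difference"].loc["G1", "G2"] < 0.1

    def test_deterministic_given_seed(self):
        table, islets = _independent_islet_tissue(n_islets=4)
        a = geometry_robustness(table, islets, r=20.0, min_count=100, seed=5)
        b = geometry_robustness(table, islets, r=20.0, min_count=100, seed=5)
        pd.testing.assert_frame_equal(
            a["circle"].gamma_mean, b["circle"].gamma_mean
        )
        pd.testing.assert_frame_equal(
            a["square"].gamma_mean, b["square"].gamma_mean
        )
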