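"""Expression preprocessing, PLS1, spin permutation, bootstrap gene Z and
FDR gene sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hemispan import synthdata as sd
from hemispan import transcriptomics as tx


def make_probe_table(expr: dict, genes: dict, flags: dict | None = None):
    e = pd.DataFrame(expr).T
    e.columns = [f"s{i}" for i in range(e.shape[1])]
    f = (
        pd.DataFrame(flags).T.set_axis(e.columns, axis=1)
        if flags is not None
        else pd.DataFrame(True, index=e.index, columns=e.columns)
    )
    return tx.ProbeTable(expression=e, probe_gene=pd.Series(genes), flags=f)


class TestFilterProbes:
    def test_boundary_and_hand_counted_survivors(self):
        # five probes with printed flag patterns over 4 samples
        flags = {
            "p1": [1, 1, 1, 1],  # keep
            "p2": [1, 1, 0, 0],  # exactly 50% above background: keep
            "p3": [1, 0, 0, 0],  # drop
            "p4": [0, 0, 0, 0],  # drop
            "p5": [1, 1, 1, 0],  # keep
        }
        t = make_probe_table(
            {k: [1.0, 2.0, 3.0, 4.0] for k in flags},
            {k: "G" for k in flags},
            {k: list(map(bool, v)) for k, v in flags.items()},
        )
        out = tx.filter_probes(t)
        assert sorted(out.expression.index) == ["p1", "p2", "p5"]

    def test_no_survivors_rejected(self):
        t = make_probe_table(
            {"p1": [1.0, 2.0]}, {"p1": "G"}, {"p1": [False, False]}
        )
        with pytest.raises(ValueError, match="survive"):
            tx.filter_probes(t)


class TestRepresentativeProbe:
    regions = pd.Series({"s0": 1, "s1": 1, "s2": 2, "s3": 2, "s4": 3, "s5": 3})

    def test_singleton_gene_passes_through(self):
        t = make_probe_table({"p1": [1, 2, 3, 4, 5, 6.0]}, {"p1": "G1"})
        _, mapping = tx.select_representative_probe(t, self.regions)
        assert mapping["G1"] == "p1"

    def test_identical_probes_tie_to_smallest_id(self):
        t = make_probe_table(
            {"pB": [1, 2, 3, 4, 5, 6.0], "pA": [1, 2, 3, 4, 5, 6.0]},
            {"pB": "G1", "pA": "G1"},
        )
        _, mapping = tx.select_representative_probe(t, self.regions)
        assert mapping["G1"] == "pA"

    def test_concordant_pair_beats_anticorrelated_probe(self):
        up = [1, 1, 2, 2, 3, 3.0]
        down = [3, 3, 2, 2, 1, 1.0]
        t = make_probe_table(
            {"p1": up, "p2": [x + 0.1 for x in up], "p3": down},
            {"p1": "G1", "p2": "G1", "p3": "G1"},
        )
        reduced, mapping = tx.select_representative_probe(t, self.regions)
        assert mapping["G1"] in ("p1", "p2")
        assert len(reduced.expression) == 1


class TestAssignSamples:
    atlas = np.zeros((4, 4, 4), dtype=int)
    atlas[0, 0, 0] = 1
    atlas[2, 0, 0] = 2
    affine = np.eye(4)

    def test_sample_inside_labelled_voxel(self):
        out = tx.assign_samples(np.array([[0.0, 0.0, 0.0]]), self.atlas, self.affine)
        assert out[0] == 1

    def test_far_sample_unassigned_at_two_mm(self):
        out = tx.assign_samples(np.array([[0.0, 3.5, 0.0]]), self.atlas, self.affine)
        assert out[0] == 0

    def test_nearby_sample_snaps_to_nearest_label(self):
        out = tx.assign_samples(np.array([[2.0, 1.5, 0.0]]), self.atlas, self.affine)
        assert out[0] == 2

    def test_equidistant_tie_takes_smaller_label(self):
        # exactly midway between the voxel centers of labels 1 and 2
        out = tx.assign_samples(np.array([[1.0, 0.9, 0.0]]), self.atlas, self.affine)
        assert out[0] == 1


class TestSrsNormalize:
    def test_closed_form_on_printed_values(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        # median 3, IQR 2 -> sigmoid((x-3)/2), then min-max
        s = 1.0 / (1.0 + np.exp(-(x - 3.0) / 2.0))
        want = (s - s.min()) / (s.max() - s.min())
        assert np.allclose(tx.srs_normalize(x), want, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_unit_interval_and_rank_preservation(self, seed):
        x = np.random.default_rng(seed).normal(10, 3, 20)
        out = tx.srs_normalize(x)
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.array_equal(np.argsort(x), np.argsort(out))

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError, match="IQR|distinct"):
            tx.srs_normalize(np.array([1.0, 1.0, 1.0, 1.0, 9.0]))


class TestPls1:
    def test_single_informative_gene_explains_everything(self, rng):
        y = rng.standard_normal(20)
        X = pd.DataFrame({"g": y})
        fit = tx.pls1_fit(X, y)
        assert fit.explained_variance == pytest.approx(1.0)
        assert abs(np.corrcoef(fit.scores, y)[0, 1]) == pytest.approx(1.0)

    def test_explained_variance_identity(self, rng):
        for _ in range(10):
            X = rng.standard_normal((30, 40))
            y = rng.standard_normal(30)
            fit = tx.pls1_fit(pd.DataFrame(X), y)
            r = np.corrcoef(fit.scores, y)[0, 1]
            assert fit.explained_variance == pytest.approx(r**2, abs=1e-9)
            assert r >= 0  # sign convention

    def test_weights_match_sklearn_first_component(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((25, 8))
        y = rng.standard_normal(25)
        fit = tx.pls1_fit(pd.DataFrame(X), y)
        ref = PLSRegression(n_components=1, scale=True).fit(X, y)
        w = ref.x_weights_[:, 0]
        w = w if np.corrcoef(ref.x_scores_[:, 0], y)[0, 1] >= 0 else -w
        assert np.allclose(fit.weights.to_numpy(), w, atol=1e-8)

    def test_covariance_maximization_against_random_search(self, rng):
        # 5-region, 3-gene toy: no random unit vector beats the PLS1 weights
        X = rng.standard_normal((5, 3))
        y = rng.standard_normal(5)
        fit = tx.pls1_fit(pd.DataFrame(X), y, standardize=True)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        best = np.abs(Xs @ fit.weights.to_numpy() @ yc)
        for _ in range(20_000):
            w = rng.standard_normal(3)
            w /= np.linalg.norm(w)
            assert np.abs((Xs @ w) @ yc) <= best + 1e-9

    def test_too_few_regions_rejected(self, rng):
        with pytest.raises(ValueError, match="region"):
            tx.pls1_fit(pd.DataFrame(rng.standard_normal((2, 4))), rng.standard_normal(2))


class TestSpinNull:
    def test_identity_rotation_gives_identity_assignment(self, rng):
        cents = rng.standard_normal((12, 3)) * 20
        null = tx.build_spin_null(
            cents, n=3, seed=0, rotations=np.array([np.eye(3)] * 3)
        )
        for p in null.perms:
            assert np.array_equal(p, np.arange(12))

    def test_every_spin_is_a_bijection(self, rng):
        cents = rng.standard_normal((15, 3)) * 20
        null = tx.build_spin_null(cents, n=200, seed=1)
        ref = np.arange(15)
        for p in null.perms:
            assert np.array_equal(np.sort(p), ref)

    def test_spun_map_preserves_multiset_and_centres_nulls(self, rng):
        cents = rng.standard_normal((30, 3)) * 20
        null = tx.build_spin_null(cents, n=500, seed=2)
        m = rng.standard_normal(30)
        rs = []
        for p in null.perms:
            spun = m[p]
            assert np.array_equal(np.sort(spun), np.sort(m))
            rs.append(np.corrcoef(m, spun)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_coplanar_centroids_fall_back_with_warning(self, rng):
        cents = np.c_[rng.standard_normal((10, 2)), np.zeros(10)]
        with pytest.warns(UserWarning, match="coplanar"):
            null = tx.build_spin_null(cents, n=10, seed=0)
        assert null.method == "label_permutation"

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError, match="4"):
            tx.build_spin_null(np.zeros((3, 3)), n=10, seed=0)


class TestSpinTest:
    def test_extreme_observation_attains_minimum_p(self, rng):
        cents = rng.standard_normal((10, 3)) * 10
        null = tx.build_spin_null(cents, n=500, seed=0)
        m = rng.standard_normal(10)
        p = tx.spin_test(lambda s: 0.0, observed=1.0, null=null, regional_map=m)
        assert p == pytest.approx(1.0 / 501)

    def test_calibrated_under_exchangeable_null(self):
        # statistic of a spun map against an independent reference:
        # p should be near-uniform over repeats
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            cents = rng.standard_normal((20, 3)) * 10
            null = tx.build_spin_null(cents, n=99, seed=seed)
            ref = rng.standard_normal(20)
            m = rng.standard_normal(20)
            stat = lambda s: float(np.corrcoef(ref, s)[0, 1])
            ps.append(tx.spin_test(stat, stat(m), null, m))
        ps = np.array(ps)
        assert abs(ps.mean() - 0.5) < 0.08
        assert abs(np.mean(ps < 0.25) - 0.25) < 0.1

    def test_power_for_planted_coupling(self):
        # explained variance of PLS1 on coupled expression beats the spin
        # null in >= 90% of seeded runs (coupling r = 0.8)
        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(45)
            X, _ = sd.make_expression_table(45, 200, y, 10, 0.8, seed=seed)
            cents = rng.standard_normal((45, 3)) * 30
            null = tx.build_spin_null(cents, n=500, seed=seed)
            fit = tx.pls1_fit(X, y)
            stat = lambda ys: tx.pls1_fit(X, ys).explained_variance
            p = tx.spin_test(stat, fit.explained_variance, null, y)
            hits += p < 0.05
        assert hits / n_runs >= 0.9


class TestBootstrapZ:
    def test_informative_gene_attains_largest_z(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(40)
            X = pd.DataFrame(rng.standard_normal((40, 30)))
            X[0] = y + 0.05 * rng.standard_normal(40)
            z = tx.bootstrap_gene_z(X, y, n_boot=300, seed=seed)
            assert z.abs().idxmax() == 0

    def test_duplicated_genes_get_equal_z(self, rng):
        y = rng.standard_normal(30)
        g = 0.5 * y + rng.standard_normal(30)
        X = pd.DataFrame({"a": g, "b": g, "c": rng.standard_normal(30)})
        z = tx.bootstrap_gene_z(X, y, n_boot=2000, seed=0)
        assert z["a"] == pytest.approx(z["b"], abs=0.05)

    def test_fixed_seed_reproducible(self, rng):
        y = rng.standard_normal(20)
        X = pd.DataFrame(rng.standard_normal((20, 10)))
        z1 = tx.bootstrap_gene_z(X, y, n_boot=200, seed=3)
        z2 = tx.bootstrap_gene_z(X, y, n_boot=200, seed=3)
        assert np.array_equal(z1.to_numpy(), z2.to_numpy())

    def test_null_z_roughly_standard_normal(self, rng):
        y = rng.standard_normal(45)
        X = pd.DataFrame(rng.standard_normal((45, 300)))
        z = tx.bootstrap_gene_z(X, y, n_boot=500, seed=0)
        assert 0.7 < z.std() < 1.3


class TestFdrGeneSets:
    def test_all_zero_gives_empty_sets(self):
        plus, minus, cuts = tx.fdr_gene_sets(pd.Series(np.zeros(10)))
        assert plus == [] and minus == []
        assert cuts == (None, None)

    def test_hand_worked_bh_on_four_p_values(self):
        z = pd.Series({"a": 5.0, "b": -5.0, "c": 0.1, "d": -0.1})
        plus, minus, cuts = tx.fdr_gene_sets(z, q=0.05)
        assert plus == ["a"] and minus == ["b"]
        assert cuts[0] == pytest.approx(5.0)
        assert cuts[1] == pytest.approx(-5.0)

    def test_bh_monotone_in_q(self, rng):
        z = pd.Series(rng.standard_normal(200) * 2)
        small = tx.fdr_gene_sets(z, q=0.01)
        large = tx.fdr_gene_sets(z, q=0.20)
        assert set(small[0]) <= set(large[0])
        assert set(small[1]) <= set(large[1])

    def test_planted_recovery_recall_and_fdp(self):
        # 45 regions, 500 genes, 10 coupled at r=0.8; n_boot scaled to 1000
        recalls, fdps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.standard_normal(45)
            X, truth = sd.make_expression_table(45, 500, y, 10, 0.8, seed=seed + 1000)
            z = tx.bootstrap_gene_z(X, y, n_boot=1000, seed=seed)
            plus, _, _ = tx.fdr_gene_sets(z)
            hits = set(plus) & set(truth)
            recalls.append(len(hits) / len(truth))
            fdps.append((len(plus) - len(hits)) / max(len(plus), 1))
        assert np.median(recalls) >= 0.7
        assert np.median(fdps) <= 0.2
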