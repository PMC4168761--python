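import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from conftest import euclidean_dm
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix

from cophylospace import (
    adjusted_r2,
    dbrda,
    explanatory_axes,
    forward_select_mems,
    mem_basis,
    pcoa,
    variance_partition,
)

# four points that satisfy the triangle inequality but admit no Euclidean
# embedding: C and D are both forced onto the midpoint of AB yet kept apart
NON_EUCLIDEAN = DistanceMatrix(
    np.array(
        [
            [0, 2, 1, 1],
            [2, 0, 1, 1],
            [1, 1, 0, 1],
            [1, 1, 1, 0],
        ],
        dtype=float,
    ),
    ["A", "B", "C", "D"],
)


def reconstructed(dm_coords):
    diff = dm_coords[:, None, :] - dm_coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


class TestPCoA:
    def test_two_points_forced_configuration(self):
        dm = DistanceMatrix([[0, 2.0], [2.0, 0]], ["a", "b"])
        fit = pcoa(dm)
        assert fit.coordinates_.shape == (2, 1)
        assert fit.eigenvalues_[0] == pytest.approx(2.0)
        np.testing.assert_allclose(sorted(fit.coordinates_[:, 0]), [-1.0, 1.0], atol=1e-12)

    def test_euclidean_isometry(self, rng):
        pts = rng.normal(size=(20, 2))
        fit = pcoa(euclidean_dm(pts))
        np.testing.assert_allclose(
            reconstructed(fit.coordinates_), euclidean_dm(pts).data, atol=1e-8
        )

    def test_axes_centered_and_orthogonal(self, rng):
        fit = pcoa(euclidean_dm(rng.normal(size=(12, 3))))
        coords = fit.coordinates_
        np.testing.assert_allclose(coords.mean(axis=0), 0, atol=1e-10)
        gram = coords.T @ coords
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_non_euclidean_matrix_reports_negative_eigenvalues(self):
        fit = pcoa(NON_EUCLIDEAN)
        assert fit.n_negative_ >= 1
        # negative axes excluded from coordinates
        assert fit.coordinates_.shape[1] < 4

    @pytest.mark.parametrize("correction", ["lingoes", "cailliez"])
    def test_corrections_remove_negative_eigenvalues(self, correction):
        fit = pcoa(NON_EUCLIDEAN, correction=correction)
        tol = 1e-8 * fit.eigenvalues_[0]
        assert fit.eigenvalues_.min() >= -tol

    def test_single_specimen_rejected(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix(np.zeros((1, 1)), ["a"]))


class TestMEM:
    def transect(self, n=10, spacing=1.0):
        pts = np.column_stack([np.arange(n) * spacing, np.zeros(n)])
        return euclidean_dm(pts)

    def test_count_bound(self):
        basis = mem_basis(self.transect(3))
        assert basis.vectors_.shape[1] <= 2

    def test_brute_force_oracle_transect(self):
        """Truncate-center-eigendecompose by hand and compare up to sign."""
        dm = self.transect(10)
        basis = mem_basis(dm)
        # independent implementation
        d = dm.data.copy()
        t = 1.0  # max MST edge on a unit transect
        dstar = np.where(d <= t, d, 4.0 * t)
        np.fill_diagonal(dstar, 0.0)
        a = -0.5 * dstar**2
        n = len(dstar)
        j = np.eye(n) - np.ones((n, n)) / n
        g = j @ a @ j
        vals, vecs = np.linalg.eigh(g)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        keep = vals > 1e-10 * vals[0]
        assert basis.truncation_ == pytest.approx(t)
        np.testing.assert_allclose(basis.eigenvalues_, vals[keep], atol=1e-8)
        for col, ref in zip(basis.vectors_.T, vecs[:, keep].T):
            assert min(np.abs(col - ref).max(), np.abs(col + ref).max()) < 1e-8

    def test_small_truncation_equals_constant_matrix_case(self):
        dm = self.transect(6)
        t = 0.5  # below the minimum inter-point distance
        basis = mem_basis(dm, truncation=t)
        constant = DistanceMatrix(
            4.0 * t * (1 - np.eye(6)), list(dm.ids)
        )
        ref = pcoa(constant)
        np.testing.assert_allclose(
            basis.eigenvalues_, ref.eigenvalues_[: len(basis.eigenvalues_)], atol=1e-8
        )

    def test_vectors_orthonormal_centered(self, rng):
        dm = euclidean_dm(rng.uniform(0, 100, size=(15, 2)))
        basis = mem_basis(dm)
        v = basis.vectors_
        np.testing.assert_allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-8)
        np.testing.assert_allclose(v.mean(axis=0), 0, atol=1e-10)

    def test_coincident_points_rejected(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"))
        with pytest.raises(ValueError, match="coincident"):
            mem_basis(dm)

    def test_moran_i_nonincreasing_on_transect(self):
        """MEM 1 is the broadest scale: Moran's I decreases with index."""
        dm = self.transect(12)
        basis = mem_basis(dm)
        w = (dm.data <= basis.truncation_ + 1e-12) & ~np.eye(12, dtype=bool)
        w = w.astype(float)

        def morans_i(z):
            z = z - z.mean()
            return len(z) * (w * np.outer(z, z)).sum() / (w.sum() * (z @ z))

        ivals = [morans_i(v) for v in basis.vectors_.T]
        assert all(ivals[i] >= ivals[i + 1] - 1e-9 for i in range(len(ivals) - 1))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_vegan_pcnm(self, tmp_path):
        dm = self.transect(10)
        vals_csv = tmp_path / "vals.csv"
        vecs_csv = tmp_path / "vecs.csv"
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(vegan))\n"
            "xy <- cbind(seq(0, 9), rep(0, 10))\n"
            "p <- pcnm(dist(xy))\n"
            f"write.csv(p$values, '{vals_csv}', row.names=FALSE)\n"
            f"write.csv(p$vectors, '{vecs_csv}', row.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], capture_output=True, check=True)
        ref_vals = pd.read_csv(vals_csv).to_numpy().ravel()
        ref_vecs = pd.read_csv(vecs_csv).to_numpy()
        basis = mem_basis(dm)
        m = basis.vectors_.shape[1]
        assert ref_vecs.shape[1] == m
        np.testing.assert_allclose(basis.eigenvalues_, ref_vals[:m], atol=1e-6)
        for col, ref in zip(basis.vectors_.T, ref_vecs.T):
            assert min(np.abs(col - ref).max(), np.abs(col + ref).max()) < 1e-6


class TestExplanatoryAxes:
    def test_planar_configuration_gives_two_axes(self, rng):
        x = explanatory_axes(euclidean_dm(rng.normal(size=(10, 2))))
        assert x.shape == (10, 2)

    def test_self_explanation_r2_is_one(self, rng):
        dm = euclidean_dm(rng.normal(size=(12, 3)))
        x = explanatory_axes(dm)
        fit = dbrda(dm, x, n_permutations=0)
        assert fit.r2_ == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize(
        "shares,expected",
        [((0.6, 0.3, 0.1), 3), ((0.7, 0.3), 2)],
    )
    def test_cum95_rule(self, shares, expected):
        # orthogonal coordinates with prescribed inertia shares
        n = 8
        basis, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(n, len(shares))))
        basis -= basis.mean(axis=0, keepdims=True)
        basis, _ = np.linalg.qr(basis)
        coords = basis * np.sqrt(np.array(shares))
        dm = euclidean_dm(coords)
        assert explanatory_axes(dm, rule="cum95").shape[1] == expected

    def test_first_k_rule(self, rng):
        dm = euclidean_dm(rng.normal(size=(10, 4)))
        assert explanatory_axes(dm, rule=2).shape[1] == 2

    def test_bad_rule_rejected(self, rng):
        dm = euclidean_dm(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            explanatory_axes(dm, rule="most")
        with pytest.raises(ValueError):
            explanatory_axes(dm, rule=0)


class TestDbRDA:
    def test_univariate_matches_ols(self, rng):
        n = 25
        x = rng.normal(size=n)
        y = 2.0 * x + rng.normal(scale=0.5, size=n)
        dm = euclidean_dm(y[:, None])
        fit = dbrda(dm, x[:, None], n_permutations=0)
        yc = y - y.mean()
        xc = x - x.mean()
        ols_r2 = (xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc))
        assert fit.r2_ == pytest.approx(ols_r2, abs=1e-8)
        assert fit.adj_r2_ == pytest.approx(adjusted_r2(ols_r2, n, 1), abs=1e-8)

    def test_rotation_invariance_of_predictors(self, rng):
        dm = euclidean_dm(rng.normal(size=(15, 2)))
        x = rng.normal(size=(15, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        f1 = dbrda(dm, x, n_permutations=0)
        f2 = dbrda(dm, x @ q, n_permutations=0)
        assert f1.r2_ == pytest.approx(f2.r2_, abs=1e-10)

    def test_relabeling_invariance(self, rng):
        pts = rng.normal(size=(12, 2))
        x = rng.normal(size=(12, 2))
        dm = euclidean_dm(pts)
        perm = rng.permutation(12)
        dm_p = dm.filter([f"s{i}" for i in perm])
        f1 = dbrda(dm, x, n_permutations=0)
        f2 = dbrda(dm_p, x[perm], n_permutations=0)
        assert f1.r2_ == pytest.approx(f2.r2_, abs=1e-10)

    def test_collinear_columns_dropped_with_warning(self, rng):
        dm = euclidean_dm(rng.normal(size=(10, 2)))
        x = rng.normal(size=(10, 2))
        x = np.hstack([x, x[:, [0]] * 2.0])
        with pytest.warns(UserWarning, match="collinear"):
            fit = dbrda(dm, x, n_permutations=0)
        assert fit.n_features_ == 2

    def test_saturated_model_rejected(self, rng):
        dm = euclidean_dm(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError, match="saturated"):
            dbrda(dm, rng.normal(size=(6, 5)), n_permutations=0)

    def test_permutation_p_detects_signal(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.2, size=30)
        fit = dbrda(euclidean_dm(y[:, None]), x[:, None], n_permutations=199, seed=1)
        assert fit.p_value_ == pytest.approx(1 / 200)

    def test_permutation_p_null_moderate(self, rng):
        pvals = []
        for i in range(40):
            y = rng.normal(size=(20, 1))
            x = rng.normal(size=(20, 2))
            pvals.append(dbrda(euclidean_dm(y), x, n_permutations=99, seed=i).p_value_)
        assert 0.2 < np.mean(pvals) < 0.8  # light null check; full one in acceptance


class TestAdjustedR2:
    def test_hand_computed(self):
        assert adjusted_r2(0.5, 21, 5) == pytest.approx(1 - 0.5 * 20 / 15)

    def test_no_predictors_no_penalty(self):
        assert adjusted_r2(0.37, 10, 0) == 0.37

    def test_perfect_fit_stays_one(self):
        assert adjusted_r2(1.0, 21, 5) == pytest.approx(1.0)

    def test_undefined_when_saturated(self):
        with pytest.raises(ValueError):
            adjusted_r2(0.5, 6, 5)


class TestForwardSelection:
    def test_alpha_zero_selects_nothing(self, rng):
        dm = euclidean_dm(rng.uniform(0, 10, size=(12, 2)))
        basis = mem_basis(dm)
        resp = euclidean_dm(rng.normal(size=(12, 1)), ids=list(dm.ids))
        assert forward_select_mems(resp, basis, alpha=0.0, n_permutations=49) == []

    def test_planted_mem_recovered_first(self, rng):
        geo = euclidean_dm(np.column_stack([np.arange(14.0), np.zeros(14)]))
        basis = mem_basis(geo)
        signal = basis.vectors_[:, 1]  # plant MEM 2
        resp = euclidean_dm(signal[:, None] + rng.normal(scale=0.01, size=(14, 1)),
                            ids=list(geo.ids))
        selected = forward_select_mems(resp, basis, alpha=0.05,
                                       n_permutations=199, seed=7)
        assert selected and selected[0] == 2

    def test_label_mismatch_rejected(self, rng):
        geo = euclidean_dm(rng.uniform(0, 5, (8, 2)))
        basis = mem_basis(geo)
        resp = euclidean_dm(rng.normal(size=(8, 1)), ids=[f"x{i}" for i in range(8)])
        with pytest.raises(KeyError):
            forward_select_mems(resp, basis)

    def test_deterministic_given_seed(self, rng):
        geo = euclidean_dm(rng.uniform(0, 5, (12, 2)))
        basis = mem_basis(geo)
        resp = euclidean_dm(basis.vectors_[:, :2] @ np.array([[1.0], [0.5]])
                            + rng.normal(scale=0.05, size=(12, 1)),
                            ids=list(geo.ids))
        a = forward_select_mems(resp, basis, n_permutations=99, seed=5)
        b = forward_select_mems(resp, basis, n_permutations=99, seed=5)
        assert a == b


class TestVariancePartition:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_fractions_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        dm = euclidean_dm(r.normal(size=(12, 2)))
        vp = variance_partition(dm, r.normal(size=(12, 2)), r.normal(size=(12, 2)))
        assert vp.a + vp.b + vp.c + vp.d == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_blocks_unadjusted_share_zero(self, rng):
        # exactly orthogonal predictor blocks explain disjoint parts of
        # the response, so the raw (unadjusted) shared fraction
        # A + B - AB vanishes; the adjusted b then differs from zero only
        # by the Ezekiel penalty terms
        n = 40
        q, _ = np.linalg.qr(rng.normal(size=(n, 4)))
        q -= q.mean(axis=0, keepdims=True)
        q, _ = np.linalg.qr(q)
        block1, block2 = q[:, :2], q[:, 2:]
        y = block1 @ rng.normal(size=(2, 1)) + block2 @ rng.normal(size=(2, 1))
        dm = euclidean_dm(y)
        r2_a = dbrda(dm, block1, n_permutations=0).r2_
        r2_b = dbrda(dm, block2, n_permutations=0).r2_
        r2_ab = dbrda(dm, np.hstack([block1, block2]), n_permutations=0).r2_
        assert abs(r2_a + r2_b - r2_ab) < 1e-6
        vp = variance_partition(dm, block1, block2)
        expected_b = (
            adjusted_r2(r2_a, n, 2) + adjusted_r2(r2_b, n, 2) - adjusted_r2(r2_ab, n, 4)
        )
        assert vp.b == pytest.approx(expected_b, abs=1e-9)

    def test_empty_space_reduces_to_single_adjusted_r2(self, rng):
        dm = euclidean_dm(rng.normal(size=(15, 2)))
        x = rng.normal(size=(15, 3))
        vp = variance_partition(dm, x, None)
        assert not vp.has_space and vp.b == 0.0 and vp.c == 0.0
        assert vp.a == pytest.approx(dbrda(dm, x, n_permutations=0).adj_r2_)
        assert vp.d == pytest.approx(1 - vp.a)

    def test_clamped_view_never_negative(self, rng):
        dm = euclidean_dm(rng.normal(size=(10, 2)))
        vp = variance_partition(dm, rng.normal(size=(10, 2)), rng.normal(size=(10, 2)))
        assert all(v >= 0 for v in vp.clamped()[:3])
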