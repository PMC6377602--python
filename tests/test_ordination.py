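import numpy as np
import pandas as pd
import pytest

from cooccur import ordination as orde


class TestHellinger:
    def test_equal_row(self):
        out = orde.hellinger(np.array([[1.0, 1.0, 1.0, 1.0]]))
        assert np.allclose(out, 0.5)

    def test_single_species_row(self):
        out = orde.hellinger(np.array([[4.0, 0.0, 0.0]]))
        assert out.tolist() == [[1.0, 0.0, 0.0]]

    def test_rows_unit_norm(self, rng):
        y = rng.uniform(0, 50, size=(20, 4))
        out = orde.hellinger(y)
        assert np.allclose(np.linalg.norm(out, axis=1), 1.0)

    def test_zero_rows_warn(self):
        with pytest.warns(UserWarning):
            out = orde.hellinger(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert np.allclose(out[0], 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            orde.hellinger(np.array([[-1.0, 2.0]]))


class TestRda:
    def test_exact_fit(self, rng):
        x = rng.standard_normal((30, 3))
        b = rng.standard_normal((3, 2))
        y = x @ b
        res = orde.rda(y, x)
        assert res.r2 == pytest.approx(1.0)
        assert np.max(np.abs(res.residuals)) < 1e-9

    def test_orthogonal_predictor_r2_zero(self, rng):
        y = rng.standard_normal((50, 2))
        x = np.ones((50, 1)) * 0 + rng.standard_normal((50, 1))
        x -= x.mean()
        # project y to be exactly orthogonal to x
        y = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
        res = orde.rda(y, x)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_r2_matches_columnwise_oracle(self, rng):
        y = rng.standard_normal((30, 3))
        x = rng.standard_normal((30, 4))
        res = orde.rda(y, x)
        yc = y - y.mean(0)
        xc = x - x.mean(0)
        ss_fit = 0.0
        for j in range(3):
            b, *_ = np.linalg.lstsq(xc, yc[:, j], rcond=None)
            ss_fit += float(((xc @ b) ** 2).sum())
        assert res.r2 == pytest.approx(ss_fit / float((yc ** 2).sum()), abs=1e-10)

    def test_single_response_equals_ols_r2(self, rng):
        y = rng.standard_normal(40)
        x = rng.standard_normal((40, 2))
        res = orde.rda(y, x)
        yc = y - y.mean()
        xc = x - x.mean(0)
        b, *_ = np.linalg.lstsq(xc, yc, rcond=None)
        r2 = ((xc @ b) ** 2).sum() / (yc ** 2).sum()
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_decomposition_exact(self, rng):
        y = rng.standard_normal((25, 3))
        x = rng.standard_normal((25, 2))
        res = orde.rda(y, x)
        yc = y - y.mean(0)
        assert np.allclose(res.fitted + res.residuals, yc, atol=1e-10)

    def test_monotone_in_predictors(self, rng):
        y = rng.standard_normal((40, 2))
        x = rng.standard_normal((40, 5))
        r2s = [orde.rda(y, x[:, :k]).r2 for k in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_aliased_predictors_rejected(self, rng):
        x = rng.standard_normal((20, 2))
        x = np.column_stack([x, x[:, 0] * 2])
        with pytest.raises(ValueError, match="alias"):
            orde.rda(rng.standard_normal((20, 2)), x)

    def test_permutation_p_detects_signal(self, rng):
        x = rng.standard_normal((60, 2))
        y = x @ rng.standard_normal((2, 2)) + 0.3 * rng.standard_normal((60, 2))
        res = orde.rda(y, x, n_perm=99, rng_seed=0)
        assert res.permutation_p <= 0.05


class TestAdjustedR2:
    def test_values(self):
        assert orde.adjusted_r2(1.0, 50, 3) == pytest.approx(1.0)
        assert orde.adjusted_r2(0.5, 11, 5) == pytest.approx(0.0)
        assert orde.adjusted_r2(0.42, 100, 0) == pytest.approx(0.42)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            orde.adjusted_r2(0.5, 5, 5)


class TestVariancePartition:
    def test_pure_abiotic_signal(self, rng):
        xa = rng.standard_normal((60, 2))
        xb = rng.standard_normal((60, 2))
        xs = rng.standard_normal((60, 2))
        y = xa @ rng.standard_normal((2, 3))
        vp = orde.variance_partition(y, xa, xb, xs)
        assert vp.unique["abiotic"] == pytest.approx(vp.total_explained, abs=0.05)
        assert abs(vp.unique["biotic"]) < 0.05
        assert abs(vp.unique["spatial"]) < 0.05

    def test_orthogonal_sets_additive(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            r = np.random.default_rng(seed)
            q, _ = np.linalg.qr(r.standard_normal((90, 6)))
            xa, xb, xs = q[:, 0:2], q[:, 2:4], q[:, 4:6]
            y = (2 * xa[:, :1] + 1.5 * xb[:, :1] + xs[:, :1]
                 + 0.1 * r.standard_normal((90, 1)))
            vp = orde.variance_partition(y, xa, xb, xs)
            # adjusted R2 breaks exact additivity by O(m / (n - m)); allow that
            assert vp.unique["abiotic"] == pytest.approx(vp.marginal["abiotic"], abs=0.06)
            assert vp.unique["biotic"] == pytest.approx(vp.marginal["biotic"], abs=0.06)
            assert abs(vp.shared_triple) < 0.06

    def test_fractions_sum_to_one(self, rng):
        y = rng.standard_normal((40, 3))
        xa = rng.standard_normal((40, 3))
        xb = rng.standard_normal((40, 2))
        xs = rng.standard_normal((40, 4))
        vp = orde.variance_partition(y, xa, xb, xs)
        total = sum(vp.unique.values()) + sum(vp.shared_pairwise.values()) \
            + vp.shared_triple + vp.residual
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_set_warns(self, rng):
        y = rng.standard_normal((30, 2))
        with pytest.warns(UserWarning, match="spatial"):
            vp = orde.variance_partition(y, rng.standard_normal((30, 2)),
                                         rng.standard_normal((30, 2)), None)
        assert vp.unique["spatial"] == pytest.approx(0.0, abs=1e-12)


class TestResidualCorrelations:
    def test_identical_and_orthogonal_columns(self):
        a = np.array([1.0, -1.0, 2.0, -2.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        frame = pd.DataFrame({"s1": a, "s2": a, "s3": b})
        out = orde.residual_correlations(frame)
        r = {(row.pair_a, row.pair_b): row.r for row in out.itertuples()}
        assert r[("s1", "s2")] == pytest.approx(1.0)
        assert abs(r[("s1", "s3")]) < 1e-12

    def test_zero_variance_sentinel(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 0.0, 0.0]})
        out = orde.residual_correlations(frame)
        assert np.isnan(out["r"].iloc[0])

    def test_planted_negative_interaction_recovered(self):
        """RDA residuals show the planted negative association in most runs."""
        from cooccur.ordination import hellinger, rda, residual_correlations
        from cooccur.synthetic import generate_landscape, mdv_like_config
        neg = 0
        n_runs = 8
        for s in range(n_runs):
            land = generate_landscape(mdv_like_config(seed=500 + s))
            keep = land.presence.occupancy.sum(1) > 0
            hel = hellinger(land.community.abundance.loc[keep].to_numpy())
            x = land.gradients.loc[keep].to_numpy()
            res = rda(hel, x, species=land.presence.species)
            out = residual_correlations(res)
            row = out[(out.pair_a == "Scottnema") & (out.pair_b == "Plectus")]
            neg += int(row["r"].iloc[0] < 0)
        assert neg >= int(0.9 * n_runs)
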