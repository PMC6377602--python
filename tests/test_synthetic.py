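import numpy as np
import pytest
from scipy import stats

from cooccur import synthetic as syn
from cooccur.community import cooccurrence_counts


class TestSites:
    def test_reproducible_and_bounded(self):
        cfg = syn.mdv_like_config(seed=3)
        a = syn.sample_sites(cfg)
        b = syn.sample_sites(cfg)
        assert np.array_equal(a, b)
        assert a.shape == (314, 2)
        assert np.all(a[:, 0] >= 0) and np.all(a[:, 0] <= cfg.extent[0])
        assert np.all(a[:, 1] >= 0) and np.all(a[:, 1] <= cfg.extent[1])

    def test_min_sites_enforced(self):
        with pytest.raises(ValueError):
            syn.SyntheticConfig(n_sites=5)


class TestGaussianField:
    def test_short_range_limit_iid(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 10_000, size=(400, 2))
        vals = syn.gaussian_field(coords, range_=1e-3, seed=1)
        _, p = stats.kstest(vals, "norm")
        assert p > 0.01

    def test_variogram_recovers_range(self):
        """Spherical variogram fit recovers the generating range.

        A single realization's empirical variogram can fluctuate (the
        domain holds only ~4x4 correlation patches), so the check is on
        the median relative error over several independent fields.
        """
        from cooccur.glmm import _fit_spherical_variogram
        from cooccur.spatial import pairwise_distances
        true_range = 5000.0
        errs = []
        for s in range(5):
            rng = np.random.default_rng(2 + s)
            coords = rng.uniform(0, 20_000, size=(2000, 2))
            vals = syn.gaussian_field(coords, range_=true_range, seed=3 + s)
            model = _fit_spherical_variogram(vals, pairwise_distances(coords))
            assert model is not None
            errs.append(abs(model.range - true_range) / true_range)
        assert np.median(errs) < 0.25

    def test_deterministic(self):
        coords = np.random.default_rng(1).uniform(0, 100, size=(50, 2))
        a = syn.gaussian_field(coords, 50.0, seed=9)
        b = syn.gaussian_field(coords, 50.0, seed=9)
        assert np.array_equal(a, b)

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            syn.gaussian_field(np.zeros((5, 2)), range_=-1.0)


class TestOccupancy:
    def _flat_cfg(self, seed=0):
        cfg = syn.null_config(seed)
        for sp in cfg.species:
            sp.coefficients = {}
            sp.target_occupancy = None
            sp.intercept = 0.0
        return cfg

    def test_zero_model_half_occupancy(self):
        cfg = self._flat_cfg()
        cfg.n_sites = 2000
        land = syn.generate_landscape(cfg)
        occ = land.presence.occupancy_counts() / cfg.n_sites
        # binomial 99.9% CI around 0.5 at n=2000
        assert np.all(np.abs(occ - 0.5) < 0.04)

    def test_hard_exclusion(self):
        cfg = syn.mdv_like_config(seed=4)
        cfg.interactions = {("Scottnema", "Plectus"): -30.0}
        for sp in cfg.species:
            if sp.name == "Plectus":
                # fix the intercept: occupancy calibration would otherwise
                # push it up to compensate for the exclusion
                sp.target_occupancy = None
                sp.intercept = 0.0
        land = syn.generate_landscape(cfg)
        from cooccur.community import filter_occupied_sites
        s = cooccurrence_counts(filter_occupied_sites(land.presence))
        assert s.pair_cooccurrence[("Scottnema", "Plectus")] == 0
        assert land.presence.occupancy["Plectus"].sum() > 0

    def test_cyclic_conditioning_rejected(self):
        cfg = syn.mdv_like_config(seed=0)
        with pytest.raises(ValueError, match="DAG"):
            syn.SyntheticConfig(fields=cfg.fields, species=cfg.species,
                                interactions={("Plectus", "Scottnema"): -1.0})

    def test_calibrated_occupancies_near_targets(self, mdv_landscape):
        occ = mdv_landscape.presence.occupancy_counts()
        assert abs(occ["Scottnema"] - 289) < 30
        assert abs(occ["Eudorylaimus"] - 222) < 35
        assert abs(occ["Plectus"] - 50) < 25


class TestAbundance:
    def test_absent_means_zero(self, mdv_landscape):
        ab = mdv_landscape.community.values
        occ = mdv_landscape.presence.values
        assert np.all(ab[occ == 0] == 0)

    @staticmethod
    def _abundance_draws(k, log_mean, n=50_000, seed=5):
        """Abundance draws at fully occupied sites, single species."""
        cfg = syn.SyntheticConfig(
            n_sites=n, fields=[],
            species=[syn.SpeciesSpec("sp", intercept=30.0, log_mean=log_mean,
                                     dispersion=k)],
            seed=seed)
        import pandas as pd
        fields = pd.DataFrame(index=[f"S{i}" for i in range(n)])
        pm = syn.simulate_occupancy(fields, cfg, np.random.default_rng(seed))
        cm = syn.simulate_abundance(pm, fields, cfg, np.random.default_rng(seed + 1))
        return cm.values.ravel()

    @staticmethod
    def _truncated_nb_moments(k, mu, upper=10_000):
        x = np.arange(1, upper)
        pmf = stats.nbinom.pmf(x, k, k / (k + mu))
        pmf = pmf / pmf.sum()
        mean = float((x * pmf).sum())
        var = float(((x - mean) ** 2 * pmf).sum())
        return mean, var

    def test_large_dispersion_poisson_limit(self):
        """k -> infinity: variance approaches the (truncated) Poisson mean."""
        mu = 7.0
        draws = self._abundance_draws(1e6, np.log(mu))
        mean, var = self._truncated_nb_moments(1e6, mu)
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.var() == pytest.approx(var, rel=0.05)
        assert draws.var() == pytest.approx(draws.mean(), rel=0.05)

    def test_nb_moments_match_parameterization(self):
        k, mu = 1.5, 40.0
        draws = self._abundance_draws(k, np.log(mu), seed=6)
        mean, var = self._truncated_nb_moments(k, mu)
        assert draws.min() >= 1  # zero-truncated where present
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.var() == pytest.approx(var, rel=0.05)

    def test_invalid_dispersion(self):
        cfg = syn.mdv_like_config(seed=0)
        cfg.species[0].dispersion = 0.0
        with pytest.raises(ValueError, match="dispersion"):
            syn.generate_landscape(cfg)


class TestLandscape:
    def test_full_determinism(self):
        a = syn.generate_landscape(syn.mdv_like_config(seed=77))
        b = syn.generate_landscape(syn.mdv_like_config(seed=77))
        assert np.array_equal(a.coords, b.coords)
        assert a.community.abundance.equals(b.community.abundance)
        assert a.presence.occupancy.equals(b.presence.occupancy)
        assert a.truth == b.truth

    def test_views_consistent(self, mdv_landscape):
        land = mdv_landscape
        assert (land.presence.values == (land.community.values > 0)).all()
        assert land.sites.site_ids == land.community.sites

    def test_planted_segregation_detected(self):
        """SIM9 SES for the Sc-Pl pair is positive under mdv_like."""
        from cooccur import nullmodels as nm
        from cooccur.community import filter_occupied_sites
        hits = 0
        n_runs = 10
        for s in range(n_runs):
            land = syn.generate_landscape(syn.mdv_like_config(seed=200 + s))
            pm = filter_occupied_sites(land.presence)
            res = nm.pairwise_tests(pm, n_iter=400, burn_in=10_000,
                                    rng_seed=s)
            by = {r.pair: r for r in res}
            hits += int(by[("Scottnema", "Plectus")].ses > 0)
        assert hits >= 9

    def test_unknown_preset(self):
        with pytest.raises(KeyError):
            syn.preset_config("nope")


class TestReconstruction:
    def test_cell_counts_match_published_statistics(self):
        pm = syn.mdv_occupancy_from_counts()
        s = cooccurrence_counts(pm)
        assert s.n_sites == 314
        assert s.species_occupancy == {
            "Scottnema": 289, "Eudorylaimus": 222, "Plectus": 50}
        assert s.pair_cooccurrence[("Scottnema", "Eudorylaimus")] == 204
        assert s.pair_cooccurrence[("Scottnema", "Plectus")] == 32
        assert s.pair_cooccurrence[("Eudorylaimus", "Plectus")] == 41
        assert s.n_sites_two_plus == 217
        assert s.n_sites_all == 30
        assert s.richness_histogram[0] == 0
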