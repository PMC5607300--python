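import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neodem.mcspd import (
    InsufficientDataError,
    NullModel,
    envelope_and_regions,
    fit_null,
    global_pvalue,
    run_mcspd,
    sample_exponential_ages,
    simulate_ensemble,
)
from neodem.spd import GrowthFit, SPDResult
from neodem.synth import toy_curve


def meso_dates(n, rng, window=(11_800.0, 9_200.0)):
    ages = rng.uniform(window[1], window[0], n)
    return pd.DataFrame(
        {
            "lab_code": [f"M{i}" for i in range(n)],
            "cra": ages,  # toy curve is near-identity; close enough for binning
            "sigma_lab": rng.uniform(30, 90, n),
            "site": [f"s{i}" for i in range(n)],
            "lon": [10.0] * n,
            "lat": [45.0] * n,
            "period": ["Mesolithic"] * n,
            "culture": [None] * n,
        }
    )


def null_model(rate, window):
    return NullModel(
        growth=GrowthFit(rate=rate, se=1e-9, window=window, corrected=False,
                         amplitude=1.0),
        window=window,
        n_bins=50,
    )


def spd_from(density, window):
    old, young = window
    grid = np.arange(young, old + 1.0)
    return SPDResult(grid=grid, density=density, scale="raw", window=window,
                     n_bins=100)


class TestFitNull:
    def test_no_mesolithic_dates_raises(self):
        df = meso_dates(5, np.random.default_rng(0))
        df["period"] = "Neolithic"
        with pytest.raises(InsufficientDataError):
            fit_null(df, 9_000.0, toy_curve())

    def test_too_few_bins_raises_with_count(self):
        df = meso_dates(4, np.random.default_rng(0))
        with pytest.raises(InsufficientDataError) as err:
            fit_null(df, 9_000.0, toy_curve())
        assert err.value.count == 4

    def test_neolithic_dates_are_ignored(self):
        rng = np.random.default_rng(1)
        meso = meso_dates(40, rng)
        neo = meso_dates(20, rng, window=(8_500.0, 7_000.0))
        neo["period"] = "Neolithic"
        neo["lab_code"] = "N" + neo["lab_code"]
        a = fit_null(meso, 9_000.0, toy_curve(), n_boot=0)
        b = fit_null(pd.concat([meso, neo], ignore_index=True), 9_000.0,
                     toy_curve(), n_boot=0)
        assert a.growth.rate == b.growth.rate
        assert a.n_bins == b.n_bins


class TestSampling:
    def test_zero_rate_is_uniform(self):
        rng = np.random.default_rng(0)
        ages = sample_exponential_ages(0.0, (9_000.0, 6_000.0), 20_000, rng)
        assert ages.min() >= 6_000 and ages.max() <= 9_000
        assert stats.kstest(ages, "uniform", args=(6_000, 3_000)).pvalue > 0.01

    def test_exponential_density_shape(self):
        rng = np.random.default_rng(0)
        r = 5e-4
        ages = sample_exponential_ages(r, (9_000.0, 6_000.0), 50_000, rng)
        # truncated-exponential CDF as the reference distribution
        ea, eb = np.exp(-r * 6_000), np.exp(-r * 9_000)
        cdf = lambda t: (ea - np.exp(-r * t)) / (ea - eb)
        assert stats.kstest(ages, cdf).pvalue > 0.01


class TestEnsemble:
    def test_identical_seeds_bitwise_identical(self):
        model = null_model(1e-4, (9_000.0, 6_000.0))
        pool = np.array([40.0, 60.0])
        a = simulate_ensemble(model, 30, pool, toy_curve(), (9_000.0, 6_000.0),
                              n_sim=20, seed=5)
        b = simulate_ensemble(model, 30, pool, toy_curve(), (9_000.0, 6_000.0),
                              n_sim=20, seed=5)
        assert np.array_equal(a, b)

    def test_zero_rate_ensemble_mean_is_flat(self):
        model = null_model(0.0, (9_000.0, 6_000.0))
        ens = simulate_ensemble(model, 200, np.array([30.0]), toy_curve(),
                                (9_000.0, 6_000.0), n_sim=300, seed=0)
        mean = ens.mean(axis=0)
        # ignore edge roll-off where sampled ages stop contributing mass
        inner = mean[300:-300]
        assert inner.std() / inner.mean() < 0.05

    def test_ensemble_mean_converges_with_n_sim(self):
        window = (9_000.0, 6_500.0)
        model = null_model(3e-4, window)
        pool = np.array([50.0])
        big = simulate_ensemble(model, 100, pool, toy_curve(), window,
                                n_sim=1_000, seed=1).mean(axis=0)
        small = simulate_ensemble(model, 100, pool, toy_curve(), window,
                                  n_sim=100, seed=2).mean(axis=0)
        mid = simulate_ensemble(model, 100, pool, toy_curve(), window,
                                n_sim=1_000, seed=3).mean(axis=0)
        assert np.abs(mid - big).max() < np.abs(small - big).max()


class TestEnvelope:
    def test_observed_at_ensemble_mean_has_no_excursions(self):
        window = (9_000.0, 6_000.0)
        model = null_model(1e-4, window)
        ens = simulate_ensemble(model, 80, np.array([50.0]), toy_curve(), window,
                                n_sim=200, seed=3)
        obs = spd_from(ens.mean(axis=0), window)
        res = envelope_and_regions(obs, ens)
        assert res.sig_regions == []
        assert np.all(res.envelope_lo <= res.envelope_hi)

    def test_constructed_excursion_found_with_direction_and_extent(self):
        window = (9_000.0, 6_000.0)
        model = null_model(1e-4, window)
        ens = simulate_ensemble(model, 80, np.array([50.0]), toy_curve(), window,
                                n_sim=200, seed=3)
        base = ens.mean(axis=0)
        obs_d = base.copy()
        grid = np.arange(6_000.0, 9_001.0)
        block = (grid >= 7_200) & (grid <= 7_700)
        hi = np.percentile(ens * (base.sum() / ens.sum(1, keepdims=True)), 97.5, axis=0)
        obs_d[block] = 1.5 * hi[block]
        res = envelope_and_regions(spd_from(obs_d, window), ens)
        above = [r for r in res.sig_regions if r[2] == "above"]
        assert len(above) == 1
        old, young, _ = above[0]
        assert old == pytest.approx(7_700, abs=30)
        assert young == pytest.approx(7_200, abs=30)

    def test_grid_mismatch_raises(self):
        window = (9_000.0, 6_000.0)
        model = null_model(1e-4, window)
        ens = simulate_ensemble(model, 20, np.array([50.0]), toy_curve(), window,
                                n_sim=20, seed=0)
        with pytest.raises(ValueError):
            envelope_and_regions(spd_from(np.ones(100), (8_000.0, 7_901.0)), ens)


class TestGlobalP:
    def test_observed_equal_to_mean_gives_p_one(self):
        window = (9_000.0, 6_000.0)
        model = null_model(1e-4, window)
        ens = simulate_ensemble(model, 60, np.array([50.0]), toy_curve(), window,
                                n_sim=100, seed=4)
        obs = spd_from(ens.mean(axis=0), window)
        assert global_pvalue(obs, ens) == pytest.approx(1.0)

    def test_enlarging_excursion_never_increases_p(self):
        window = (9_000.0, 6_000.0)
        model = null_model(1e-4, window)
        ens = simulate_ensemble(model, 60, np.array([50.0]), toy_curve(), window,
                                n_sim=200, seed=4)
        base = ens.mean(axis=0)
        grid = np.arange(6_000.0, 9_001.0)
        block = (grid >= 7_300) & (grid <= 7_800)
        last_p = 1.1
        for bump in (1.0, 1.3, 1.8, 2.5, 4.0):
            d = base.copy()
            d[block] *= bump
            p = global_pvalue(spd_from(d, window), ens)
            assert p <= last_p + 1e-12
            last_p = p

    def test_p_uniform_under_null(self):
        """A held-out null simulation, tested against the ensemble, must give
        p-values indistinguishable from uniform."""
        window = (8_200.0, 6_500.0)
        model = null_model(1e-4, window)
        curve = toy_curve()
        rng = np.random.default_rng(6)
        pvals = []
        for _ in range(100):
            ens = simulate_ensemble(model, 50, np.array([40.0, 80.0]), curve,
                                    window, n_sim=100, seed=rng)
            obs = spd_from(ens[0], window)
            pvals.append(global_pvalue(obs, ens[1:]))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_power_against_synthetic_boom(self):
        """A x3 boom over 400 years on >= 100 bins is detected (p < 0.05) in
        at least 80% of replicates — the regime-2 detection mechanism."""
        window = (9_000.0, 6_000.0)
        rate = 1e-4
        curve = toy_curve()
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            n_bins = 120
            ages = sample_exponential_ages(rate, window, n_bins, rng)
            boom = rng.random(n_bins) < 0.5
            ages[boom] = np.where(
                rng.random(boom.sum()) < 0.35,
                rng.uniform(7_200, 7_600, boom.sum()),
                ages[boom],
            )
            sigs = rng.uniform(30, 90, n_bins)
            from neodem.calcurve import sum_calibrated, uncalibrate

            cras = uncalibrate(ages, curve, sigs, rng)
            grid = np.arange(window[1], window[0] + 1.0)
            obs = spd_from(sum_calibrated(cras, sigs, curve, grid), window)
            model = null_model(rate, window)
            ens = simulate_ensemble(model, n_bins, sigs, curve, window,
                                    n_sim=200, seed=rng)
            if global_pvalue(obs, ens) < 0.05:
                hits += 1
        assert hits / n_rep >= 0.8

    def test_run_mcspd_reproducible_and_consistent(self):
        window = (9_000.0, 6_000.0)
        model = null_model(2e-4, window)
        rng = np.random.default_rng(9)
        ages = sample_exponential_ages(2e-4, window, 60, rng)
        sigs = rng.uniform(30, 90, 60)
        from neodem.calcurve import sum_calibrated, uncalibrate

        curve = toy_curve()
        cras = uncalibrate(ages, curve, sigs, rng)
        grid = np.arange(window[1], window[0] + 1.0)
        obs = spd_from(sum_calibrated(cras, sigs, curve, grid), window)
        obs.n_bins = 60
        r1 = run_mcspd(obs, model, sigs, curve, n_sim=100, seed=11)
        r2 = run_mcspd(obs, model, sigs, curve, n_sim=100, seed=11)
        assert r1.global_p == r2.global_p
        assert np.array_equal(r1.envelope_hi, r2.envelope_hi)
        assert 1 / 101 <= r1.global_p <= 1.0
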