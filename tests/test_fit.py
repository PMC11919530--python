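"""χ² definitions, forward-model composition, and the multi-contrast MCMC fit."""

import warnings

import numpy as np
import pytest

from mononr.contrast import ContrastScheme, sld_from_nd, smear_profile
from mononr.fit import (
    DEFAULT_BOUNDS,
    FitParameters,
    MCMCSettings,
    PriorSet,
    _CachedModel,
    fit_contrasts,
    forward_model,
    reduced_chi2,
    total_chi2,
)
from mononr.reflect import ReflectivityCurve, apply_scale_background, reflectivity
from mononr.synth import gen_reflectivity_data

QUICK_MCMC = MCMCSettings(n_draws=2000, n_walkers=12, summary_draws=400)


def curve(q, R, dR=None):
    return ReflectivityCurve(np.asarray(q, float), np.asarray(R, float),
                             None if dR is None else np.asarray(dR, float))


class TestReducedChi2:
    def test_perfect_model_gives_zero(self):
        q = np.geomspace(0.01, 0.5, 10)
        R = np.geomspace(1, 1e-4, 10)
        assert reduced_chi2(curve(q, R, 0.1 * R), curve(q, R), 6) == 0.0

    def test_unit_residuals_forced_value(self):
        """N = 3 points, each residual equal to its δR, P = 1 → 3/2."""
        q = [0.1, 0.2, 0.3]
        exp = curve(q, [1.0, 0.5, 0.2], dR=[0.1, 0.05, 0.02])
        model = curve(q, [1.1, 0.55, 0.22])
        assert reduced_chi2(exp, model, 1) == pytest.approx(1.5, rel=1e-14)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(8)
        q = np.sort(rng.uniform(0.01, 0.6, 40))
        Re = rng.uniform(0.1, 1.0, 40)
        Rm = rng.uniform(0.1, 1.0, 40)
        dR = rng.uniform(0.01, 0.1, 40)
        total = 0.0
        for a, b, s in zip(Re, Rm, dR):
            total += (a - b) ** 2 / s**2
        expected = total / (40 - 6)
        got = reduced_chi2(curve(q, Re, dR), curve(q, Rm), 6)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_scales_inverse_square_with_errors(self):
        rng = np.random.default_rng(9)
        q = np.sort(rng.uniform(0.01, 0.6, 20))
        Re, Rm = rng.uniform(0.1, 1, 20), rng.uniform(0.1, 1, 20)
        dR = rng.uniform(0.01, 0.1, 20)
        base = reduced_chi2(curve(q, Re, dR), curve(q, Rm), 6)
        scaled = reduced_chi2(curve(q, Re, 3.0 * dR), curve(q, Rm), 6)
        assert scaled == pytest.approx(base / 9.0, rel=1e-12)

    def test_errors(self):
        q = np.geomspace(0.01, 0.5, 5)
        good = curve(q, np.ones(5), 0.1 * np.ones(5))
        with pytest.raises(ValueError, match="q grids"):
            reduced_chi2(good, curve(q * 1.1, np.ones(5)), 1)
        with pytest.raises(ValueError, match="N > P"):
            reduced_chi2(good, curve(q, np.ones(5)), 5)
        with pytest.raises(ValueError, match="δR"):
            reduced_chi2(curve(q, np.ones(5)), curve(q, np.ones(5)), 1)


class TestTotalChi2:
    def test_sum_and_degenerate_cases(self):
        assert total_chi2([0.0, 0.0, 0.0]) == 0.0
        assert total_chi2([1.5, 2.5]) == 4.0
        with pytest.raises(ValueError, match="empty"):
            total_chi2([])
        with pytest.raises(ValueError, match="non-negative"):
            total_chi2([1.0, -0.5])


class TestForwardModel:
    def test_identity_composition(self, monolayer_profile, q_grid):
        """σ→0, scale 1, background 0 reduces to the bare reflectivity."""
        scheme = ContrastScheme("D70-D2O", False, True, "D2O")
        params = FitParameters(0.0, 1.0, 0.0, 0.0, 6.36e-6, 0.0)
        got = forward_model(monolayer_profile, scheme, params, q_grid)
        sld = sld_from_nd(monolayer_profile, scheme, solvent_sld=6.36e-6)
        assert np.allclose(got.R, reflectivity(sld, q_grid).R, rtol=1e-12)

    def test_solvent_isolation(self, monolayer_profile, q_grid):
        """Schemes differing only in solvent differ only via SLD/background."""
        params = FitParameters(2.0, 0.95, 4e-6, 4e-6, 1e-7, 1e-7)
        d2o = forward_model(monolayer_profile,
                            ContrastScheme("D70-D2O", False, True, "D2O"),
                            params, q_grid)
        acmw = forward_model(monolayer_profile,
                             ContrastScheme("D70-ACMW", False, True, "ACMW"),
                             params, q_grid)
        # equal solvent SLDs and backgrounds → identical curves
        assert np.allclose(d2o.R, acmw.R, rtol=1e-12)

    def test_matches_manual_pipeline(self, monolayer_profile, q_grid, true_params):
        """Composition equals the explicit SLD → smear → reflect → scale chain."""
        scheme = ContrastScheme("D13-ACMW", True, False, "ACMW")
        got = forward_model(monolayer_profile, scheme, true_params, q_grid)
        sld = sld_from_nd(monolayer_profile, scheme,
                          solvent_sld=true_params.sld_ACMW)
        sld = smear_profile(sld, true_params.roughness)
        manual = apply_scale_background(
            reflectivity(sld, q_grid), true_params.scale,
            true_params.background_ACMW,
        )
        assert np.allclose(got.R, manual.R, rtol=1e-12)

    def test_cached_model_agrees_with_public_composition(
        self, monolayer_profile, q_grid, true_params, noisy_datasets
    ):
        """The fit's fast path reproduces forward_model to ~machine level."""
        cache = _CachedModel(monolayer_profile, list(noisy_datasets),
                             noisy_datasets, None)
        for scheme, fast in zip(cache.schemes, cache.model_curves(true_params)):
            ref = forward_model(monolayer_profile, scheme, true_params, q_grid)
            assert np.allclose(fast.R, ref.R, rtol=1e-9, atol=1e-30)


class TestParameters:
    def test_validation(self):
        with pytest.raises(ValueError, match="roughness"):
            FitParameters(-1.0, 1.0, 0.0, 0.0, 6e-6, 0.0)
        with pytest.raises(ValueError, match="scale"):
            FitParameters(1.0, 0.0, 0.0, 0.0, 6e-6, 0.0)
        with pytest.raises(ValueError, match="backgrounds"):
            FitParameters(1.0, 1.0, -1e-9, 0.0, 6e-6, 0.0)

    def test_array_round_trip(self, true_params):
        assert FitParameters.from_array(true_params.to_array()) == true_params

    def test_prior_validation(self):
        with pytest.raises(ValueError, match="missing bounds"):
            PriorSet({"roughness": (1.0, 10.0)})
        bad = dict(DEFAULT_BOUNDS)
        bad["scale"] = (1.5, 0.5)
        with pytest.raises(ValueError, match="lower bound"):
            PriorSet(bad)


class TestMCMCSettings:
    def test_summary_window_tracks_short_chains(self):
        """The summary window never includes more than a fifth of the chain."""
        default = MCMCSettings()
        assert default.n_steps * default.n_walkers >= 50_000
        assert default.summary_steps * default.n_walkers <= 10_000 + default.n_walkers
        short = MCMCSettings(n_draws=5000, n_walkers=16)
        # at least the first fifth of a short chain is always discarded
        assert short.summary_steps <= 0.8 * short.n_steps + 1


class TestFitContrasts:
    def test_same_seed_is_bit_reproducible(self, monolayer_profile, noisy_datasets):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_contrasts(monolayer_profile, noisy_datasets,
                              mcmc=QUICK_MCMC, seed=5)
            b = fit_contrasts(monolayer_profile, noisy_datasets,
                              mcmc=QUICK_MCMC, seed=5)
        assert a.modes == b.modes
        assert a.chi2_total == b.chi2_total
        assert np.array_equal(a.chain, b.chain)

    def test_likelihood_invariant_under_contrast_relabeling(
        self, monolayer_profile, noisy_datasets, true_params
    ):
        items = list(noisy_datasets.items())
        shuffled = dict(reversed(items))
        a = _CachedModel(monolayer_profile, list(noisy_datasets), noisy_datasets, None)
        b = _CachedModel(monolayer_profile, list(shuffled), shuffled, None)
        x = true_params.to_array()
        assert a.chi2_unreduced(x) == pytest.approx(b.chi2_unreduced(x), rel=1e-12)

    def test_noise_free_data_recovered_to_machine_level(
        self, monolayer_profile, q_grid, true_params
    ):
        """Perfect-data limit: best-fit χ² collapses toward zero."""
        data = gen_reflectivity_data(monolayer_profile, noise_rel=0.0,
                                     q_grid=q_grid, seed=3,
                                     true_params=true_params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = fit_contrasts(monolayer_profile, data,
                                    mcmc=QUICK_MCMC, seed=4)
        assert summary.chi2_total_map < 1e-6

    def test_mode_beats_coarse_lattice(self, monolayer_profile, noisy_datasets):
        """χ² at the reported best fit ≤ χ² at seeded prior-space probes."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = fit_contrasts(monolayer_profile, noisy_datasets,
                                    mcmc=QUICK_MCMC, seed=6)
        cache = _CachedModel(monolayer_profile, list(noisy_datasets),
                             noisy_datasets, None)
        best = cache.chi2_unreduced(summary.map_params.to_array())
        priors = PriorSet()
        rng = np.random.default_rng(7)
        probes = priors.lower + rng.uniform(0, 1, (64, 6)) * (priors.upper - priors.lower)
        assert all(best <= cache.chi2_unreduced(p) + 1e-9 for p in probes)

    def test_scale_roughness_posterior_correlation(
        self, monolayer_profile, noisy_datasets
    ):
        """Scale and roughness marginals are positively correlated, the
        well-known degeneracy of air–water monolayer reflectivity."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = fit_contrasts(
                monolayer_profile, noisy_datasets,
                mcmc=MCMCSettings(n_draws=5000, n_walkers=16), seed=8,
            )
        chain = summary.chain
        corr = np.corrcoef(chain[:, 0], chain[:, 1])[0, 1]  # roughness, scale
        assert corr > 0.2

    def test_missing_errors_rejected(self, monolayer_profile, q_grid):
        scheme = ContrastScheme("H-D2O", False, False, "D2O")
        bad = {scheme: ReflectivityCurve(q_grid, np.geomspace(1, 1e-6, len(q_grid)))}
        with pytest.raises(ValueError, match="δR"):
            fit_contrasts(monolayer_profile, bad, mcmc=QUICK_MCMC, seed=0)

    def test_empty_datasets_rejected(self, monolayer_profile):
        with pytest.raises(ValueError, match="at least one"):
            fit_contrasts(monolayer_profile, {}, mcmc=QUICK_MCMC, seed=0)

    def test_posterior_summary_export(self, monolayer_profile, noisy_datasets, tmp_path):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = fit_contrasts(monolayer_profile, noisy_datasets,
                                    mcmc=QUICK_MCMC, seed=9)
        summary.write_json(tmp_path / "fit.json")
        summary.export_chain(tmp_path / "chain.txt")
        import json

        blob = json.loads((tmp_path / "fit.json").read_text())
        assert set(blob["modes"]) == {
            "roughness", "scale", "background_D2O", "background_ACMW",
            "sld_D2O", "sld_ACMW",
        }
        assert len(blob["chi2_per_contrast"]) == 7
        chain = np.loadtxt(tmp_path / "chain.txt")
        assert chain.shape[1] == 6
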