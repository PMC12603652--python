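"""Seed extraction, interaction construction, design assembly, GLM fitting."""

import numpy as np
import pytest
from scipy.stats import kstest

from ppikit import (
    BasisSet,
    DegenerateInputError,
    GroundTruth,
    InvalidArgumentError,
    NeuronalSeed,
    PipelineConfig,
    PpiDesign,
    PsychRegressor,
    RankDeficiencyError,
    RoiMatrix,
    TimeSeries,
    assemble_ppi_design,
    build_interaction,
    dct_highpass_basis,
    extract_seed,
    first_eigenvariate,
    fit_glm_prewhitened,
    run_ppi_subject,
    simulate_subject,
)
from ppikit.hemodynamics import default_operator, fast_ridge_deconvolve
from ppikit.ppi_design import PIPELINE_FLAGS, _extract_seed_impl
from ppikit.synthetic_data import _ar1_series, make_block_design


@pytest.fixture
def block_psy():
    return make_block_design(0.9, 200, 18.0)


class TestPipelineConfig:
    def test_pipeline_flag_mapping_roundtrips(self):
        for pid, (mc, wi) in PIPELINE_FLAGS.items():
            cfg = PipelineConfig.from_pipeline(pid)
            assert (cfg.mean_center, cfg.whitening_inversion) == (mc, wi)
            assert cfg.pipeline_id == pid

    def test_unknown_pipeline_rejected(self):
        with pytest.raises(InvalidArgumentError):
            PipelineConfig.from_pipeline(5)


class TestExtractSeed:
    def test_inversion_is_noop_when_rho_forced_zero(self, rng):
        roi = RoiMatrix(rng.normal(size=(100, 6)), tr=0.9)
        with_inv = extract_seed(roi, None, PipelineConfig(True, True), force_rho=0.0)
        without = extract_seed(roi, None, PipelineConfig(True, False), force_rho=0.0)
        assert np.max(np.abs(with_inv.values - without.values)) < 1e-12

    def test_reduces_to_plain_eigenvariate(self, rng):
        # no confounds, infinite cutoff, rho forced 0: every stage is identity
        roi = RoiMatrix(rng.normal(size=(80, 5)), tr=0.9)
        cfg = PipelineConfig(True, False, highpass_cutoff=np.inf)
        seed = extract_seed(roi, None, cfg, force_rho=0.0)
        assert np.max(np.abs(seed.values - first_eigenvariate(roi).values)) < 1e-12

    def test_whitening_inversion_restores_latent_structure(self):
        """On an autocorrelated rank-1 ROI the inverted extraction tracks
        the latent series better than the still-whitened one."""
        rng = np.random.default_rng(5)
        op = default_operator(0.9, 200)
        latent = op.entries @ (
            make_block_design(0.9, 200, 18.0).values + _ar1_series(rng, 200, 0.5, 1.0)
        )
        noise = np.column_stack([_ar1_series(rng, 200, 0.5, 0.7) for _ in range(8)])
        roi = RoiMatrix(latent[:, None] + noise, tr=0.9)
        corr = {}
        for wi in (False, True):
            seed = extract_seed(roi, None, PipelineConfig(True, wi))
            corr[wi] = abs(np.corrcoef(seed.values, latent)[0, 1])
        assert corr[True] > corr[False]

    def test_degenerate_roi_propagates(self):
        roi = RoiMatrix(np.zeros((50, 3)) + 1e-15, tr=0.9)
        with pytest.raises(DegenerateInputError):
            extract_seed(roi, None, PipelineConfig(True, True))


class TestBuildInteraction:
    def test_balanced_boxcar_centered_product_is_half_xn(self, rng, block_psy):
        xn = NeuronalSeed(rng.normal(size=200))
        op = default_operator(0.9, 200)
        out = build_interaction(xn, block_psy, True, op)
        product = np.where(block_psy.values > 0, 0.5, -0.5) * xn.values
        assert np.max(np.abs(out.values - op.entries @ product)) < 1e-12

    def test_uncentered_product_vanishes_at_baseline(self, rng, block_psy):
        from ppikit import convolution_matrix

        xn = NeuronalSeed(rng.normal(size=200))
        identity = convolution_matrix(np.array([1.0]), 200)
        out = build_interaction(xn, block_psy, False, identity)
        assert np.all(out.values[block_psy.values == 0] == 0)
        assert np.allclose(out.values[block_psy.values == 1],
                           xn.values[block_psy.values == 1])

    def test_zero_mean_task_coding_makes_flag_irrelevant(self, rng):
        psy = PsychRegressor(np.tile([0.5, -0.5], 100))
        xn = NeuronalSeed(rng.normal(size=200))
        op = default_operator(0.9, 200)
        on = build_interaction(xn, psy, True, op).values
        off = build_interaction(xn, psy, False, op).values
        assert np.max(np.abs(on - off)) < 1e-12


class TestAssembleDesign:
    def test_column_order_and_count_without_confounds(self, rng, block_psy):
        op = default_operator(0.9, 200)
        inter = build_interaction(NeuronalSeed(rng.normal(size=200)), block_psy, True, op)
        design = assemble_ppi_design(inter, TimeSeries(rng.normal(size=200), 0.9),
                                     block_psy, op)
        assert design.labels == ["interaction", "seed", "psych", "intercept"]
        assert design.columns.shape == (200, 4)

    def test_psych_column_matches_convolution_oracle(self, rng, block_psy):
        op = default_operator(0.9, 200)
        inter = build_interaction(NeuronalSeed(rng.normal(size=200)), block_psy, True, op)
        design = assemble_ppi_design(inter, TimeSeries(rng.normal(size=200), 0.9),
                                     block_psy, op)
        kernel = op.entries[:, 0]
        expected = np.convolve(block_psy.values, kernel)[:200]
        expected -= expected.mean()
        assert np.max(np.abs(design.column("psych") - expected)) < 1e-12

    def test_constant_confound_rejected(self, rng, block_psy):
        op = default_operator(0.9, 200)
        inter = build_interaction(NeuronalSeed(rng.normal(size=200)), block_psy, True, op)
        confounds = BasisSet(np.ones((200, 1)), ["const"])
        with pytest.raises(InvalidArgumentError):
            assemble_ppi_design(inter, TimeSeries(rng.normal(size=200), 0.9),
                                block_psy, op, confounds)


class TestFitGlm:
    def _design(self, rng, n=200):
        psy = make_block_design(0.9, n, 18.0)
        op = default_operator(0.9, n)
        inter = build_interaction(NeuronalSeed(rng.normal(size=n)), psy, True, op)
        return assemble_ppi_design(
            inter, TimeSeries(rng.normal(size=n), 0.9), psy, op,
            dct_highpass_basis(n, 0.9, 128.0),
        )

    def test_noise_free_recovery_is_exact(self, rng):
        design = self._design(rng)
        beta_true = rng.normal(size=design.columns.shape[1])
        fit = fit_glm_prewhitened(design.columns @ beta_true, design, force_rho=0.0)
        assert np.max(np.abs(fit.beta - beta_true)) < 1e-8

    def test_intercept_only_fits_the_mean(self, rng):
        y = rng.normal(loc=3.0, size=50)
        design = PpiDesign(np.ones((50, 1)), ["intercept"])
        fit = fit_glm_prewhitened(y, design, force_rho=0.0)
        assert fit.coef("intercept").beta == pytest.approx(y.mean())

    def test_rank_deficiency_names_collinear_columns(self, rng):
        x = rng.normal(size=(60, 2))
        design = PpiDesign(
            np.column_stack([x, x[:, 0] + x[:, 1], np.ones(60)]),
            ["a", "b", "a_plus_b", "intercept"],
        )
        with pytest.raises(RankDeficiencyError, match="a_plus_b"):
            fit_glm_prewhitened(rng.normal(size=60), design, force_rho=0.0)

    def test_zero_interaction_column_aborts(self, rng):
        design = PpiDesign(
            np.column_stack([np.zeros(50), rng.normal(size=50), np.ones(50)]),
            ["interaction", "seed", "intercept"],
        )
        with pytest.raises(DegenerateInputError):
            fit_glm_prewhitened(rng.normal(size=50), design, force_rho=0.0)

    def test_dof_and_pvalue_bounds(self, rng):
        design = self._design(rng)
        fit = fit_glm_prewhitened(rng.normal(size=200), design)
        assert fit.dof == 200 - design.columns.shape[1]
        assert np.all((fit.p >= 0) & (fit.p <= 1))


class TestRunSubject:
    def test_pipeline3_equals_pipeline4_when_rho_forced_zero(self):
        truth = GroundTruth(beta_ppi=0.3)
        data = simulate_subject(truth, 21)
        f3 = run_ppi_subject(data, PipelineConfig.from_pipeline(3), force_rho=0.0)
        f4 = run_ppi_subject(data, PipelineConfig.from_pipeline(4), force_rho=0.0)
        for name in f3:
            assert np.allclose(f3[name].beta, f4[name].beta)
            assert np.allclose(f3[name].t, f4[name].t, equal_nan=True)

    def test_bold_level_variant_runs_without_deconvolution(self):
        truth = GroundTruth(beta_ppi=0.3)
        data = simulate_subject(truth, 22)
        cfg = PipelineConfig(mean_center=True, whitening_inversion=True, deconvolve=False)
        fits = run_ppi_subject(data, cfg)
        assert set(fits) == {"target", "seed"}
        assert np.isfinite(fits["target"].coef("interaction").t)

    def test_high_snr_interaction_recovery(self):
        truth = GroundTruth(beta_ppi=0.5, sigma_noise=0.0, voxel_noise_sd=0.0,
                            target_latent_sd=0.0)
        data = simulate_subject(truth, 23)
        fit = run_ppi_subject(data, PipelineConfig.from_pipeline(4),
                              include_seed_target=False)["target"]
        assert fit.coef("interaction").beta == pytest.approx(0.5, rel=0.15)


class TestMisspecificationMechanics:
    def test_mean_centering_decorrelates_interaction_from_seed(self):
        """Without centering the interaction regressor carries the seed
        main effect; centering removes that shared variance (median over
        100 replicates)."""
        op = default_operator(0.9, 200)
        psy = make_block_design(0.9, 200, 18.0)
        diffs = []
        for r in range(100):
            g = np.random.default_rng(300 + r)
            z = psy.values + _ar1_series(g, 200, 0.5, 1.0)
            bold = op.entries @ z + _ar1_series(g, 200, 0.4, 0.5)
            xn = NeuronalSeed(fast_ridge_deconvolve(bold, 0.9))
            centered = build_interaction(xn, psy, True, op).values
            plain = build_interaction(xn, psy, False, op).values
            seed_c = bold - bold.mean()
            diffs.append(
                abs(np.corrcoef(centered, seed_c)[0, 1])
                - abs(np.corrcoef(plain, seed_c)[0, 1])
            )
        assert np.median(diffs) < 0

    def test_double_prewhitening_distorts_seed_regressor(self):
        """Without inversion, the regressor entering the whitened fit has
        been whitened twice and tracks the latent seed BOLD less well."""
        rng = np.random.default_rng(17)
        op = default_operator(0.9, 200)
        latent = op.entries @ (
            make_block_design(0.9, 200, 18.0).values + _ar1_series(rng, 200, 0.5, 1.0)
        )
        noise = np.column_stack([_ar1_series(rng, 200, 0.5, 0.7) for _ in range(8)])
        roi = RoiMatrix(latent[:, None] + noise, tr=0.9)
        regs = {}
        for wi in (False, True):
            seed, rho = _extract_seed_impl(roi, None, PipelineConfig(True, wi), None)
            # the fitting stage whitens the design once more
            from ppikit.whitening import apply_whitening, build_whitening_matrix

            w2 = build_whitening_matrix(rho, 200)
            regs[wi] = apply_whitening(w2, seed.values)
        target = latent  # what the seed regressor is meant to represent
        assert abs(np.corrcoef(regs[False], target)[0, 1]) < abs(
            np.corrcoef(regs[True], target)[0, 1]
        )

    def test_null_pvalues_uniform(self, null_pipeline4_stats):
        """Under the correctly specified null, Pipeline-4 interaction
        p-values are uniform (Kolmogorov-Smirnov over 1,000 replicates)."""
        _, pvals = null_pipeline4_stats
        assert kstest(pvals, "uniform").statistic < 0.05
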