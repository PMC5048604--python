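"""Reads-fraction-on-GC regression, z scores, CV and outlier flagging."""

import numpy as np
import pytest
import statsmodels.api as sm

from adaptnipt.gc_correction import ChromosomeProfile, PanelProfiles, normalize_panel
from adaptnipt.scoring import (
    DegeneratePanelError,
    fit_regression,
    flag_outliers,
    moderated_z,
    panel_cv,
    predicted_rf,
    z_score,
)

from conftest import make_profiles


def _panel(rf, gc):
    return PanelProfiles(make_profiles(rf, gc))


class TestFitRegression:
    def test_exact_line_recovered(self):
        gc = np.array([0.41, 0.42, 0.43, 0.44])
        panel = _panel(0.01 + 0.5 * gc, gc)
        fit = fit_regression(panel, 21)
        assert fit.alpha == pytest.approx(0.01, abs=1e-12)
        assert fit.beta == pytest.approx(0.5, abs=1e-10)
        assert fit.residuals == pytest.approx(0.0, abs=1e-14)
        assert fit.resid_sd == 0.0

    def test_flat_data_gives_mean_intercept(self):
        rng = np.random.default_rng(0)
        rf = rng.normal(0.013, 1e-4, 30)
        gc = rng.uniform(0.41, 0.45, 30)
        # no true slope: alpha + beta*mean(gc) equals mean(rf) regardless
        fit = fit_regression(_panel(rf, gc), 21)
        assert predicted_rf(fit, gc.mean()) == pytest.approx(rf.mean(), abs=1e-12)

    def test_matches_statsmodels_ols(self):
        """Closed-form fit agrees with the statsmodels OLS oracle."""
        rng = np.random.default_rng(1)
        for _ in range(5):
            gc = rng.uniform(0.40, 0.51, 50)
            rf = 0.004 + 0.02 * gc + rng.normal(0, 2e-4, 50)
            fit = fit_regression(_panel(rf, gc), 21)
            ols = sm.OLS(rf, sm.add_constant(gc)).fit()
            assert fit.alpha == pytest.approx(ols.params[0], abs=1e-12)
            assert fit.beta == pytest.approx(ols.params[1], abs=1e-10)
            assert fit.residuals == pytest.approx(ols.resid, abs=1e-12)

    def test_residuals_centred_and_orthogonal_to_gc(self):
        rng = np.random.default_rng(2)
        gc = rng.uniform(0.40, 0.51, 200)
        rf = 0.01 + 0.03 * gc + rng.normal(0, 3e-4, 200)
        fit = fit_regression(_panel(rf, gc), 21)
        assert abs(fit.resid_mean) < 1e-10 * np.std(rf)
        assert abs(fit.residuals @ (gc - gc.mean())) < 1e-12

    def test_degenerate_gc_rejected(self):
        with pytest.raises(DegeneratePanelError, match="21"):
            fit_regression(_panel([0.01, 0.011, 0.012], [0.43, 0.43, 0.43]), 21)

    def test_subset_refit(self):
        rng = np.random.default_rng(3)
        gc = rng.uniform(0.40, 0.51, 40)
        rf = 0.01 + 0.03 * gc + rng.normal(0, 3e-4, 40)
        panel = _panel(rf, gc)
        mask = np.zeros(40, dtype=bool)
        mask[:20] = True
        fit = fit_regression(panel, 21, mask)
        direct = fit_regression(_panel(rf[:20], gc[:20]), 21)
        assert fit.beta == pytest.approx(direct.beta)
        assert fit.resid_sd == pytest.approx(direct.resid_sd)


class TestZScore:
    def _fit(self, resid_sd=0.001, alpha=0.01, beta=0.0):
        from adaptnipt.scoring import RegressionFit

        return RegressionFit(
            chrom=21,
            alpha=alpha,
            beta=beta,
            residuals=np.zeros(10),
            resid_mean=0.0,
            resid_sd=resid_sd,
            n=10,
        )

    def test_arithmetic(self):
        test = make_profiles([0.014], [0.43], prefix="T")[0]
        # residual 0.014 - 0.01 = 0.004, sd 0.001 -> z = 4
        assert z_score(test, self._fit(), 21) == pytest.approx(4.0)

    def test_zero_residual_gives_zero(self):
        test = make_profiles([0.01], [0.43], prefix="T")[0]
        assert z_score(test, self._fit(), 21) == 0.0

    def test_degenerate_sd_rejected(self):
        test = make_profiles([0.014], [0.43], prefix="T")[0]
        with pytest.raises(DegeneratePanelError):
            z_score(test, self._fit(resid_sd=0.0), 21)

    def test_invariant_under_common_rescaling(self):
        """Multiplying every reads fraction by a common factor leaves z
        unchanged (the panel normalisation scale does not matter)."""
        rng = np.random.default_rng(4)
        gc = rng.uniform(0.40, 0.51, 60)
        rf = 0.01 + 0.02 * gc + rng.normal(0, 2e-4, 60)
        t_rf, t_gc = 0.01 + 0.02 * 0.45 + 6e-4, 0.45
        z1 = z_score(
            make_profiles([t_rf], [t_gc])[0], fit_regression(_panel(rf, gc), 21), 21
        )
        c = 7.3
        z2 = z_score(
            make_profiles([c * t_rf], [t_gc])[0],
            fit_regression(_panel(c * rf, gc), 21),
            21,
        )
        assert z1 == pytest.approx(z2, rel=1e-9)

    def test_null_samples_standard_normal(self):
        """Test samples drawn from the panel distribution score ~N(0,1)."""
        rng = np.random.default_rng(5)
        means, sds = [], []
        for _ in range(20):
            gc = rng.uniform(0.40, 0.51, 396)
            rf = 0.005 + 0.02 * gc + rng.normal(0, 2e-4, 396)
            fit = fit_regression(_panel(rf, gc), 21)
            tg = rng.uniform(0.40, 0.51, 50)
            tr = 0.005 + 0.02 * tg + rng.normal(0, 2e-4, 50)
            zs = [
                z_score(make_profiles([r], [g])[0], fit, 21)
                for r, g in zip(tr, tg)
            ]
            means.append(np.mean(zs))
            sds.append(np.std(zs))
        assert abs(np.mean(means)) < 0.1
        assert np.mean(sds) == pytest.approx(1.0, abs=0.05)

    def test_moderation_reduces_to_plain_z_on_full_panel(self):
        rng = np.random.default_rng(6)
        gc = rng.uniform(0.40, 0.51, 100)
        rf = 0.005 + 0.02 * gc + rng.normal(0, 2e-4, 100)
        fit = fit_regression(_panel(rf, gc), 21)
        test = make_profiles([0.015], [0.45], prefix="T")[0]
        assert moderated_z(test, fit, fit, 21, 60) == pytest.approx(
            z_score(test, fit, 21), abs=1e-12
        )

    def test_moderation_shrinks_toward_prior_sd(self):
        rng = np.random.default_rng(7)
        gc = rng.uniform(0.40, 0.51, 30)
        rf = 0.005 + 0.02 * gc + rng.normal(0, 1e-4, 30)
        small = fit_regression(_panel(rf, gc), 21)
        prior = fit_regression(
            _panel(0.005 + 0.02 * gc, gc + 1e-6), 21
        )  # zero-noise prior; sd 0
        prior.resid_sd = 10 * small.resid_sd
        test = make_profiles([0.02], [0.45], prefix="T")[0]
        z_plain = z_score(test, small, 21)
        z_mod = moderated_z(test, small, prior, 21, 60)
        assert abs(z_mod) < abs(z_plain)


class TestPanelCv:
    def test_identical_values_zero(self):
        cv = panel_cv(_panel([0.013] * 5, np.linspace(0.41, 0.45, 5)), 21)
        assert cv == pytest.approx(0.0, abs=1e-14)

    def test_two_point_arithmetic(self):
        cv = panel_cv(_panel([0.9, 1.1], [0.42, 0.44]), 21)
        assert cv == pytest.approx(0.1 * np.sqrt(2), rel=1e-12)

    def test_gc_matched_subset_beats_heterogeneous_panel(self):
        """A GC-matched half of a panel whose rf tracks GC has lower CV
        than the mixed panel."""
        rng = np.random.default_rng(8)
        gc = np.r_[rng.normal(0.42, 0.002, 100), rng.normal(0.46, 0.002, 100)]
        rf = 0.013 * (1 + 2.0 * (gc - 0.44)) + rng.normal(0, 5e-5, 200)
        panel = _panel(rf, gc)
        full = panel_cv(panel, 21)
        matched = panel_cv(panel, 21, members=np.arange(200) < 100)
        assert matched < full


class TestFlagOutliers:
    def _panel22(self, rng, n=50):
        profs = []
        for i in range(n):
            rf = rng.normal(1 / 22, 1e-3, 22)
            profs.append(
                ChromosomeProfile(
                    f"S{i:03d}", np.arange(1, 23), rf, rf, rng.uniform(0.4, 0.5, 22)
                )
            )
        return PanelProfiles(profs)

    def test_homogeneous_panel_flags_at_most_chance_level(self):
        panel = self._panel22(np.random.default_rng(9))
        # 50 samples x 22 chromosomes at |robust z| > 3: a handful of
        # false positives is expected by chance, not more
        assert len(flag_outliers(panel, threshold=3.0)) <= 8

    def test_shifted_sample_flagged(self):
        rng = np.random.default_rng(10)
        panel = self._panel22(rng)
        j = panel.col(21)
        sd = panel.rf[:, j].std()
        panel.rf[7, j] += 10 * sd
        assert "S007" in flag_outliers(panel, threshold=3.0)

    def test_infinite_threshold_flags_nothing(self):
        panel = self._panel22(np.random.default_rng(11))
        assert flag_outliers(panel, threshold=np.inf) == []

    def test_zero_mad_chromosome_skipped(self):
        rng = np.random.default_rng(12)
        panel = self._panel22(rng)
        panel.rf[:, 0] = 0.05  # constant -> MAD 0
        with pytest.warns(UserWarning, match="MAD"):
            flag_outliers(panel, threshold=3.0)
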