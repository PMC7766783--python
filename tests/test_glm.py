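"""Design construction, HRF, and AR(1) whitened fitting."""

import numpy as np
import pytest

from stopbayes import (
    HrfSpec,
    RaceParams,
    SessionDesign,
    build_design,
    canonical_hrf,
    contrast_vector,
    fit_glm_ar1,
    generate_voxel_bold,
    simulate_session,
)
from stopbayes.observer import ObserverParams, pstop_sequence


@pytest.fixture(scope="module")
def glm_session():
    trials = simulate_session(SessionDesign(n_trials=100), RaceParams(), seed=404)
    pstop = pstop_sequence([1 if t.category == "stop" else 0 for t in trials], ObserverParams())
    return trials, pstop


@pytest.fixture(scope="module")
def design1(glm_session):
    trials, _ = glm_session
    return build_design(trials, model="GLM1", n_scans=305, tr_s=2.0)


class TestHrf:
    def test_peak_location(self):
        spec = HrfSpec()
        h, _ = canonical_hrf(spec)
        t_peak = np.argmax(h) * spec.dt_s
        assert 4.0 <= t_peak <= 7.0

    def test_derivative_integrates_to_zero_once_decayed(self):
        spec = HrfSpec(kernel_length_s=64.0)
        h, dh = canonical_hrf(spec)
        assert abs(dh.sum() * spec.dt_s) < 1e-6 * np.max(np.abs(h))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            HrfSpec(peak_dispersion_s=-1.0)
        with pytest.raises(ValueError):
            HrfSpec(dt_s=0.3)  # does not divide the kernel length


class TestBuildDesign:
    def test_column_layout_and_order(self, design1):
        names = design1.names
        # modulators follow conditions, in the stated order
        i_rt, i_ss, i_se = names.index("GSxRT"), names.index("SSxSSD"), names.index("SExSSD")
        assert i_rt < i_ss < i_se
        assert names[-1] == "constant"
        assert any(n.startswith("drift") for n in names)
        assert design1.n_scans == 300  # 305 minus 5 discarded volumes

    def test_absent_condition_has_no_columns(self, glm_session):
        trials, _ = glm_session
        kept = [t for t in trials if t.outcome != "GE"]
        design = build_design(kept, model="GLM1", n_scans=305)
        assert not any(n.startswith("GE") for n in design.names)

    def test_glm2_modulator_order(self, glm_session):
        trials, pstop = glm_session
        design = build_design(trials, model="GLM2", pstop=pstop, n_scans=305)
        mods = [n for n in design.names if "x" in n]
        assert mods == ["GSxpstop", "SSxSSD", "SSxpstop", "SExSSD", "SExpstop"]

    def test_zero_variance_modulator_omitted(self, glm_session):
        trials, _ = glm_session
        with pytest.warns(UserWarning, match="zero variance"):
            design = build_design(trials, model="GLM2", pstop=[0.25] * len(trials), n_scans=305)
        assert "GSxpstop" not in design.names and "SSxSSD" in design.names

    def test_reproducible_bit_identical(self, glm_session, design1):
        trials, _ = glm_session
        again = build_design(trials, model="GLM1", n_scans=305, tr_s=2.0)
        assert again.frame.equals(design1.frame)

    def test_events_past_scan_end_clipped_with_warning(self, glm_session):
        trials, _ = glm_session
        with pytest.warns(UserWarning, match="clipped"):
            short = build_design(trials, model="GLM1", n_scans=100)
        assert short.n_scans == 95

    def test_glm2_requires_pstop(self, glm_session):
        with pytest.raises(ValueError, match="pstop"):
            build_design(glm_session[0], model="GLM2", n_scans=305)


class TestFit:
    def test_noiseless_recovery_is_exact(self, design1):
        beta_true = np.zeros(len(design1.names))
        beta_true[design1.names.index("GS")] = 1.0
        beta_true[design1.names.index("GSxRT")] = 0.5
        Y = generate_voxel_bold(design1, beta_true, noise_sd=0.0, seed=0)
        fit = fit_glm_ar1(Y, design1)
        assert np.allclose(fit.betas.to_numpy().ravel(), beta_true, atol=1e-8)

    def test_contrast_scale_invariance(self, design1, glm_session):
        """Scaling the HRF kernel rescales betas but leaves t statistics
        unchanged (linearity)."""
        trials, _ = glm_session
        scaled_frame = design1.frame.copy()
        for c in ("GS", "SS", "GE", "SE"):
            if c in scaled_frame:
                scaled_frame[c] *= 3.0
        import dataclasses

        scaled = dataclasses.replace(design1, frame=scaled_frame)
        rng = np.random.default_rng(5)
        beta = np.zeros(len(design1.names))
        beta[design1.names.index("SS")] = 2.0
        Y = generate_voxel_bold(design1, beta, noise_sd=1.0, seed=9)
        t1 = fit_glm_ar1(Y, design1).contrast({"SS": 1.0, "GS": -1.0})["t"][0]
        t2 = fit_glm_ar1(Y, scaled).contrast({"SS": 1.0 / 3.0, "GS": -1.0 / 3.0})["t"][0]
        assert t1 == pytest.approx(t2, rel=1e-8)

    def test_rho_recovery(self, design1):
        beta = np.zeros(len(design1.names))
        Y0 = generate_voxel_bold(design1, beta, ar1_rho=0.0, noise_sd=1.0, seed=2, n_voxels=50)
        fit0 = fit_glm_ar1(Y0, design1)
        assert abs(fit0.ar1_rho.mean()) < 0.05
        # residual-based rho estimates run low when smooth drift regressors
        # absorb part of the low-frequency noise; the estimate must still
        # clearly separate rho = 0.4 noise from white noise
        Y4 = generate_voxel_bold(design1, beta, ar1_rho=0.4, noise_sd=1.0, seed=3, n_voxels=50)
        fit4 = fit_glm_ar1(Y4, design1)
        assert 0.25 < fit4.ar1_rho.mean() < 0.45

    def test_whitened_ols_equals_gls_oracle(self, rng):
        """On a small instance, AR(1)-whitened OLS must equal the direct
        GLS solve with the implied covariance."""
        from stopbayes.glm import _whiten

        n, p, rho = 40, 3, 0.35
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        bw, *_ = np.linalg.lstsq(_whiten(X, rho), _whiten(y, rho), rcond=None)
        # AR(1) covariance: V_ij = rho^|i-j| / (1 - rho^2)
        V = rho ** np.abs(np.subtract.outer(np.arange(n), np.arange(n))) / (1 - rho**2)
        Vi = np.linalg.inv(V)
        b_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(bw, b_gls, atol=1e-8)

    def test_drift_columns_leave_clean_contrasts_unchanged(self, glm_session):
        trials, _ = glm_session
        d_with = build_design(trials, model="GLM1", n_scans=305, hp_cutoff_s=128.0)
        beta = np.zeros(len(d_with.names))
        beta[d_with.names.index("SS")] = 1.5
        Y = generate_voxel_bold(d_with, beta, noise_sd=0.0, seed=1)
        est = fit_glm_ar1(Y, d_with).contrast({"SS": 1.0, "GS": -1.0})["estimate"][0]
        assert est == pytest.approx(1.5, abs=1e-8)

    def test_null_contrast_centered_at_zero(self, design1):
        """Equal SS and GS amplitudes: the SS > GS contrast distribution is
        centered at zero across noise realizations."""
        beta = np.zeros(len(design1.names))
        beta[design1.names.index("SS")] = 1.0
        beta[design1.names.index("GS")] = 1.0
        Y = generate_voxel_bold(design1, beta, noise_sd=1.0, seed=8, n_voxels=100)
        con = fit_glm_ar1(Y, design1).contrast({"SS": 1.0, "GS": -1.0})
        assert abs(con["estimate"].mean()) < 3.0 * con["estimate"].std() / 10.0 + 0.05

    def test_rank_deficient_design_rejected(self, design1):
        import dataclasses

        frame = design1.frame.copy()
        frame["dup"] = frame["GS"]
        bad = dataclasses.replace(design1, frame=frame)
        with pytest.raises(np.linalg.LinAlgError):
            fit_glm_ar1(np.zeros(bad.n_scans), bad)

    def test_contrast_vector_unknown_name(self, design1):
        with pytest.raises(KeyError):
            contrast_vector(design1, {"nope": 1.0})
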