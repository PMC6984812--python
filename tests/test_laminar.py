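"""Depth grids, depth sampling, contrasts and the laminar shape GLM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from lamfmri.laminar import (CONTRASTS, ContrastSpec, blockwise_contrast,
                             centered_depth_regressor, compute_contrast,
                             equivolume_depth_fractions, fit_laminar_glm,
                             roi_depth_profile, sample_along_normal)
from lamfmri.synth import make_beta_labels


class TestEquivolume:
    def test_flat_cortex_reduces_to_equidistant(self):
        rho = equivolume_depth_fractions(1.0, 2.0, 2.0, n=6)
        assert np.allclose(rho, (np.arange(1, 7) - 0.5) / 6)

    def test_matches_numeric_quadrature(self):
        # Volume between WM and rho with linearly interpolated area must be
        # alpha_k of the total; verify against brute-force integration.
        a_in, a_out = 1.0, 3.0
        area = lambda r: a_in + (a_out - a_in) * r
        total, _ = integrate.quad(area, 0.0, 1.0)
        rho = equivolume_depth_fractions(1.0, a_in, a_out, n=6)
        for k, r in enumerate(rho, start=1):
            vol, _ = integrate.quad(area, 0.0, r)
            assert vol / total == pytest.approx((k - 0.5) / 6, abs=1e-10)

    def test_single_depth_is_volume_midpoint(self):
        a_in, a_out = 1.0, 3.0
        rho = equivolume_depth_fractions(1.0, a_in, a_out, n=1)
        area = lambda r: a_in + (a_out - a_in) * r
        half = integrate.quad(area, 0, 1)[0] / 2
        vol = integrate.quad(area, 0, float(rho[0]))[0]
        assert vol == pytest.approx(half, abs=1e-10)

    def test_converges_to_equidistant_as_areas_equalise(self):
        equi = (np.arange(1, 7) - 0.5) / 6
        dev_prev = np.inf
        for contrast in (2.0, 1.0, 0.5, 0.1):
            rho = equivolume_depth_fractions(1.0, 1.0, 1.0 + contrast, n=6)
            dev = np.max(np.abs(rho - equi))
            assert dev < dev_prev
            dev_prev = dev

    def test_vectorised_over_vertices_and_validates(self):
        rho = equivolume_depth_fractions(np.ones(5), np.ones(5),
                                         np.linspace(1, 3, 5), n=6)
        assert rho.shape == (5, 6)
        assert np.all(np.diff(rho, axis=1) > 0)
        with pytest.raises(ValueError):
            equivolume_depth_fractions(1.0, -1.0, 2.0)


class TestNormalSampling:
    def test_exact_for_linear_field(self):
        # Trilinear interpolation reproduces a linear field exactly.
        z = np.arange(10, dtype=float)
        vol = np.broadcast_to(z, (10, 10, 10)).copy()
        depths = np.array([1.0, 2.5, 4.75, 8.2])
        prof = sample_along_normal(vol, [0.0, 0.0, 0.0], [0.0, 0.0, 1.0], depths)
        assert np.allclose(prof, depths)

    def test_constant_volume_gives_constant_profile(self):
        vol = np.full((5, 5, 5), 7.0)
        prof = sample_along_normal(vol, [2, 2, 0], [0, 0, 1], np.linspace(0, 4, 6))
        assert np.allclose(prof, 7.0)

    def test_matches_eight_corner_oracle(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(size=(6, 6, 6))
        pt = np.array([1.3, 2.7, 0.4])
        nrm = np.array([0.5, 0.2, 0.84])
        nrm = nrm / np.linalg.norm(nrm)
        depths = np.array([0.3, 1.1, 2.2])
        prof = sample_along_normal(vol, pt, nrm, depths)

        def trilinear(p):
            i0 = np.floor(p).astype(int)
            f = p - i0
            val = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((f[0] if dx else 1 - f[0])
                             * (f[1] if dy else 1 - f[1])
                             * (f[2] if dz else 1 - f[2]))
                        val += w * vol[i0[0] + dx, i0[1] + dy, i0[2] + dz]
            return val

        oracle = [trilinear(pt + d * nrm) for d in depths]
        assert np.allclose(prof, oracle)

    def test_outside_points_flagged_missing(self):
        vol = np.zeros((4, 4, 4))
        prof = sample_along_normal(vol, [2.5, 0, 0], [1, 0, 0], np.array([0.0, 1.0]))
        assert np.isnan(prof[1]) and np.isfinite(prof[0])


class TestROIProfile:
    def test_constant_vertices_give_constant_profile(self):
        betas = np.full((10, 6), 3.0)
        assert np.allclose(roi_depth_profile(betas), 3.0)

    def test_median_resists_skew(self):
        betas = np.array([[1.0] * 6, [1.0] * 6, [100.0] * 6])
        assert np.allclose(roi_depth_profile(betas), 1.0)   # not the mean 34

    def test_vertices_with_missing_depths_excluded(self):
        betas = np.ones((4, 6))
        betas[0, 3] = np.nan
        assert np.allclose(roi_depth_profile(betas), 1.0)
        with pytest.raises(ValueError):
            roi_depth_profile(np.full((2, 6), np.nan))

    def test_72_profiles_per_subject(self, noisy_dataset):
        prof = roi_depth_profile(noisy_dataset.roi_betas("A1"))
        assert prof.shape == (6, 72)


class TestContrasts:
    def test_unisensory_formula(self):
        spec = CONTRASTS["V-Fix"]
        assert compute_contrast({"V_AttA": 2.0, "V_AttV": 4.0}, spec) == 3.0

    def test_all_equal_conditions_null_difference_contrasts(self):
        vals = {c: 5.0 for c in CONTRASTS["AttA-AttV"].weights}
        for name in ("AV-A", "AV-V", "AttA-AttV", "AttV-AttA"):
            assert compute_contrast(vals, CONTRASTS[name]) == pytest.approx(0.0)

    def test_attention_contrast_divides_by_three(self):
        vals = {f"{s}_AttA": 1.0 for s in ("A", "V", "AV")}
        vals.update({f"{s}_AttV": 0.0 for s in ("A", "V", "AV")})
        assert compute_contrast(vals, CONTRASTS["AttA-AttV"]) == pytest.approx(1.0)
        vals["A_AttA"] = 4.0     # single-condition change contributes /3
        assert compute_contrast(vals, CONTRASTS["AttA-AttV"]) == pytest.approx(2.0)

    def test_missing_condition_named_in_error(self):
        with pytest.raises(KeyError, match="V_AttV"):
            compute_contrast({"V_AttA": 1.0}, CONTRASTS["V-Fix"])

    def test_blockwise_yields_twelve_estimates(self, default_design):
        labels = make_beta_labels(default_design)
        rng = np.random.default_rng(0)
        betas = rng.normal(size=(5, 6, 72))
        con, cells = blockwise_contrast(betas, labels, CONTRASTS["AV-A"])
        assert con.shape == (5, 6, 12)
        assert len(cells) == 12
        # spot-check one cell against the printed formula
        sub = labels[(labels["block"] == 2) & (labels["run"] == 3)]
        idx = {r.condition: i for i, r in zip(sub.index, sub.itertuples())}
        k = cells.index[(cells["block"] == 2) & (cells["run"] == 3)][0]
        expected = 0.5 * ((betas[..., idx["AV_AttA"]] - betas[..., idx["A_AttA"]])
                          + (betas[..., idx["AV_AttV"]] - betas[..., idx["A_AttV"]]))
        assert np.allclose(con[..., k], expected)

    def test_invalid_condition_label_rejected(self):
        with pytest.raises(ValueError):
            ContrastSpec("bad", {"X_AttA": 1.0})


class TestShapeGLM:
    def test_constant_profile(self):
        p = fit_laminar_glm(np.full(6, 4.2))
        assert p.C == pytest.approx(4.2) and p.L == pytest.approx(0.0)

    def test_exact_line(self):
        p = fit_laminar_glm(np.arange(6.0))
        assert p.C == pytest.approx(2.5) and p.L == pytest.approx(1.0)

    def test_matches_normal_equations_oracle_in_bulk(self):
        # closed-form OLS on [1, x]: C = mean, L = sum(x*y)/sum(x^2)
        rng = np.random.default_rng(42)
        y = rng.normal(size=(10_000, 6))
        p = fit_laminar_glm(y)
        x = centered_depth_regressor()
        oracle_C = y.mean(axis=1)
        oracle_L = (y * x).sum(axis=1) / (x**2).sum()
        assert np.array_equal(p.C, oracle_C)
        assert np.array_equal(p.L, oracle_L)
        # and against an independent lstsq solve on a few rows
        X = np.column_stack([np.ones(6), x])
        for i in range(25):
            beta, *_ = np.linalg.lstsq(X, y[i], rcond=None)
            assert np.allclose(beta, [p.C[i], p.L[i]])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6),
           st.floats(-5, 5), st.floats(-50, 50))
    def test_affine_equivariance(self, profile, a, b):
        y = np.asarray(profile)
        p0 = fit_laminar_glm(y)
        p1 = fit_laminar_glm(a * y + b)
        assert p1.C == pytest.approx(a * p0.C + b, rel=1e-9, abs=1e-9)
        assert p1.L == pytest.approx(a * p0.L, rel=1e-9, abs=1e-9)

    def test_regressor_orthogonality_decouples_C_and_L(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=6)
        x = centered_depth_regressor()
        p0 = fit_laminar_glm(y)
        p1 = fit_laminar_glm(y + 3.0 * x)     # add pure linear component
        assert p1.C == pytest.approx(p0.C)
        assert p1.L == pytest.approx(p0.L + 3.0)
        p2 = fit_laminar_glm(y + 5.0)         # add pure constant
        assert p2.L == pytest.approx(p0.L)

    def test_non_finite_profile_rejected(self):
        with pytest.raises(ValueError):
            fit_laminar_glm([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
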