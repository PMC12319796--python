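"""Gamma transit-time distribution and the OEF integral."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from capox import (
    HemodynamicSummary,
    TransitTimeDistribution,
    add_model_oef,
    gamma_from_moments,
    gamma_pdf,
    limit_extraction,
    oef,
    oef_map,
    single_capillary_extraction,
)
from capox.transit_distribution import OefLookup, oef_nifti, oef_vector
from capox.oxygen_transport import extraction_profile


def riemann_oef(summary, constants, n_steps=100_000):
    """Brute-force midpoint Riemann sum over the truncated gamma support."""
    dist = gamma_from_moments(summary)
    q = dist.quantile(1 - 1e-7)
    tau = (np.arange(n_steps) + 0.5) * q / n_steps
    profile = extraction_profile(constants)
    dens = gamma_dist.pdf(tau, dist.alpha, scale=dist.beta)
    return float(np.sum(dens * profile(constants.k * tau)) * q / n_steps)


class TestMomentsParameterization:
    def test_exponential_case(self):
        d = gamma_from_moments(HemodynamicSummary(1.0, 1.0))
        assert d.alpha == pytest.approx(1.0) and d.beta == pytest.approx(1.0)

    def test_published_nawm_moments(self):
        d = gamma_from_moments(HemodynamicSummary(4.52, 5.45))
        assert d.alpha == pytest.approx((4.52 / 5.45) ** 2)
        assert d.beta == pytest.approx(5.45**2 / 4.52)

    @given(
        mtt=st.floats(min_value=0.1, max_value=60.0),
        cth=st.floats(min_value=0.05, max_value=60.0),
    )
    def test_moment_round_trip(self, mtt, cth):
        d = gamma_from_moments(HemodynamicSummary(mtt, cth))
        assert d.mean == pytest.approx(mtt, rel=1e-12)
        assert d.std == pytest.approx(cth, rel=1e-12)

    def test_degenerate_cth_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_moments(HemodynamicSummary(1.0, 0.0))

    def test_invalid_summary_rejected(self):
        with pytest.raises(ValueError):
            HemodynamicSummary(0.0, 1.0)
        with pytest.raises(ValueError):
            HemodynamicSummary(1.0, -1.0)


class TestGammaPdf:
    def test_exponential_density_at_zero(self):
        assert gamma_pdf(0.0, TransitTimeDistribution(1.0, 1.0)) == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha,beta", [(0.5, 2.0), (1.0, 1.0), (2.5, 3.0)])
    def test_normalization(self, alpha, beta):
        d = TransitTimeDistribution(alpha, beta)
        total, _ = quad(lambda t: gamma_pdf(t, d), 0, d.quantile(1 - 1e-12), limit=200)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_mode_matches_closed_form(self):
        d = TransitTimeDistribution(2.0, 1.0)
        tau = np.linspace(0.01, 10, 5000)
        assert tau[np.argmax(gamma_pdf(tau, d))] == pytest.approx(1.0, abs=0.01)


class TestOefIntegral:
    def test_delta_distribution_collapse(self, constants):
        q = single_capillary_extraction(4.52, constants)
        assert oef(HemodynamicSummary(4.52, 0.0), constants) == pytest.approx(q, abs=1e-6)
        # small cth converges to the same value
        assert oef(HemodynamicSummary(4.52, 1e-4), constants) == pytest.approx(q, abs=1e-5)

    def test_bounded_by_extraction_ceiling(self, constants):
        ceiling = limit_extraction(constants.PtO2, constants)
        for mtt in (0.5, 3.4, 10.0):
            for cth in (0.5, 4.0, 12.0):
                val = oef(HemodynamicSummary(mtt, cth), constants)
                assert 0 < val < ceiling

    @pytest.mark.parametrize("k", [22.0, 68.0, 175.0])
    @pytest.mark.parametrize("mtt", [3.14, 4.52, 6.42])
    @pytest.mark.parametrize("cth", [2.85, 5.45, 8.31])
    def test_quadrature_against_riemann_oracle(self, constants, mtt, cth, k):
        s = HemodynamicSummary(mtt, cth)
        c = constants.with_(k=k)
        assert oef(s, c) == pytest.approx(riemann_oef(s, c), abs=1e-4)

    def test_truncation_error_bound(self, constants, nawm):
        import capox.transit_distribution as td

        loose = oef(nawm, constants)
        orig = td.TAIL_PROB
        try:
            td.TAIL_PROB = 1e-10
            tight = oef(nawm, constants, n_nodes=512)
        finally:
            td.TAIL_PROB = orig
        assert loose == pytest.approx(tight, abs=1e-5)

    def test_decreasing_in_cth_over_observed_range(self, constants):
        # empirical property on the published parameter box
        for mtt in (3.14, 4.52, 6.42):
            cths = np.linspace(2.85, 8.31, 8)
            vals = [oef(HemodynamicSummary(mtt, c), constants) for c in cths]
            assert np.all(np.diff(vals) < 0), mtt

    def test_increasing_in_k_and_mtt(self, constants, nawm):
        vals_k = [
            oef(nawm, constants.with_(k=k)) for k in (10.0, 30.0, 68.0, 200.0, 1000.0)
        ]
        assert np.all(np.diff(vals_k) > 0)
        ratio = nawm.cth / nawm.mtt
        vals_m = [
            oef(HemodynamicSummary(m, ratio * m), constants) for m in (1.0, 2.0, 4.52, 9.0)
        ]
        assert np.all(np.diff(vals_m) > 0)


class TestOefMap:
    def test_matches_per_voxel_scalar_calls(self, constants, rng):
        mtt = rng.uniform(2.0, 7.0, size=(2, 2, 2))
        cth = rng.uniform(2.0, 9.0, size=(2, 2, 2))
        out = oef_map(mtt, cth, constants)
        for idx in np.ndindex(mtt.shape):
            expected = oef(HemodynamicSummary(mtt[idx], cth[idx]), constants)
            assert out[idx] == pytest.approx(expected, abs=1e-6)

    def test_uniform_map_broadcasts_scalar(self, constants, nawm):
        mtt = np.full((3, 3), nawm.mtt)
        cth = np.full((3, 3), nawm.cth)
        out = oef_map(mtt, cth, constants)
        assert np.allclose(out, oef(nawm, constants))

    def test_masked_and_invalid_voxels_are_nan(self, constants):
        mtt = np.full((2, 2), 4.52)
        cth = np.full((2, 2), 5.45)
        mask = np.ones((2, 2), bool)
        mask[0, 0] = False
        mtt[1, 1] = np.nan
        out = oef_map(mtt, cth, constants, mask)
        assert np.isnan(out[0, 0]) and np.isnan(out[1, 1])
        assert np.isfinite(out[0, 1]) and np.isfinite(out[1, 0])

    def test_shape_mismatch_rejected(self, constants):
        with pytest.raises(ValueError):
            oef_map(np.ones((2, 2)), np.ones((3, 2)), constants)

    def test_lookup_grid_accuracy(self, constants, rng):
        lookup = OefLookup(constants, (2.0, 8.0), (2.0, 10.0), n_grid=48)
        mtt = rng.uniform(2.2, 7.5, size=50)
        cth = rng.uniform(2.2, 9.5, size=50)
        exact = oef_vector(mtt, cth, constants)
        assert np.max(np.abs(lookup(mtt, cth) - exact)) <= 1e-3

    def test_nifti_round_trip(self, constants, rng, tmp_path):
        import nibabel as nib

        shape = (3, 3, 2)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        mtt = rng.uniform(3.0, 6.0, shape)
        cth = rng.uniform(3.0, 8.0, shape)
        nib.save(nib.Nifti1Image(mtt, affine), tmp_path / "mtt.nii")
        nib.save(nib.Nifti1Image(cth, affine), tmp_path / "cth.nii")
        oef_nifti(
            tmp_path / "mtt.nii",
            tmp_path / "cth.nii",
            tmp_path / "oef.nii",
            constants,
            lookup=False,
        )
        img = nib.load(tmp_path / "oef.nii")
        assert np.allclose(img.affine, affine)
        expected = oef_map(mtt, cth, constants)
        assert np.allclose(np.asarray(img.get_fdata()), expected, atol=1e-6)


def test_add_model_oef_table(constants):
    import pandas as pd

    table = pd.DataFrame(
        {
            "subject_id": ["s1", "s2"],
            "roi": ["NAWM", "GM"],
            "mtt_s": [4.52, 3.40],
            "cth_s": [5.45, 4.08],
        }
    )
    out = add_model_oef(table, constants)
    assert "oef_mri" in out.columns
    assert out.loc[0, "oef_mri"] == pytest.approx(
        oef(HemodynamicSummary(4.52, 5.45), constants)
    )
    with pytest.raises(KeyError):
        add_model_oef(table.drop(columns=["cth_s"]), constants)
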