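"""Vergence primitives and the Castrop closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from castrop.exceptions import BiometryDomainError, VergenceSingularityError
from castrop.model_eye import CastropConstants, ModelEye
from castrop.optics import (
    castrop_iol_power,
    castrop_predicted_refraction,
    corneal_surface_powers,
    derive_posterior_corneal_radius,
    effective_lens_position,
    paraxial_trace_refraction,
    vergence_refract,
    vergence_translate,
)

from conftest import MEAN_ARGS, MEAN_EYE, STUDY_CONSTANTS, random_valid_records


class TestPosteriorRadius:
    def test_fixed_ratio(self):
        assert derive_posterior_corneal_radius(7.77) == pytest.approx(6.4, abs=1e-12)

    def test_mean_eye_value(self):
        assert derive_posterior_corneal_radius(7.668) == pytest.approx(
            7.668 * 6.4 / 7.77, rel=1e-12
        )

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_degenerate_radius(self, bad):
        with pytest.raises(BiometryDomainError):
            derive_posterior_corneal_radius(bad)


class TestCornealPowers:
    def test_front_power(self):
        pca, _ = corneal_surface_powers(7.77, 6.4)
        assert pca == pytest.approx(0.376 / 0.00777, rel=1e-12)

    def test_back_power_is_negative(self):
        _, pcp = corneal_surface_powers(7.77, 6.4)
        assert pcp == pytest.approx((1.336 - 1.376) / 0.0064, rel=1e-12)
        assert pcp < 0

    def test_flat_surface_limit(self):
        pca, pcp = corneal_surface_powers(1e12, 1e12)
        assert abs(pca) < 1e-6 and abs(pcp) < 1e-6


class TestEffectiveLensPosition:
    def test_mean_eye_study_constants(self):
        elp = effective_lens_position(3.099, 4.608, CastropConstants(0.424, -0.312))
        assert elp == pytest.approx(4.740792, abs=1e-9)

    def test_offsets_vanish(self):
        assert effective_lens_position(3.0, 4.5, CastropConstants(0.0, 0.0)) == 3.0

    def test_linear_in_h(self):
        assert effective_lens_position(3.0, 0.0, CastropConstants(0.4, 0.1)) == pytest.approx(3.1)

    def test_affine_slopes(self):
        k = CastropConstants(0.41, 0.2)
        base = effective_lens_position(3.0, 4.5, k)
        assert effective_lens_position(3.5, 4.5, k) - base == pytest.approx(0.5)
        assert effective_lens_position(3.0, 5.5, k) - base == pytest.approx(0.41)

    def test_iol_in_front_of_cornea(self):
        with pytest.raises(BiometryDomainError):
            effective_lens_position(0.3, 0.0, CastropConstants(0.4, -0.5))


class TestVergencePrimitives:
    def test_refraction_from_infinity(self):
        assert vergence_refract(0.0, 48.391) == 48.391

    def test_refract_identity_and_cancellation(self):
        assert vergence_refract(5.0, 0.0) == 5.0
        assert vergence_refract(-6.25, 6.25) == 0.0

    def test_zero_vergence_stays_zero(self):
        assert vergence_translate(0.0, 250.0, 1.336) == 0.0

    def test_zero_distance_identity(self):
        assert vergence_translate(12.5, 0.0) == 12.5

    def test_reciprocal_form(self):
        # 1/V' = 1/V - d/n
        v2 = vergence_translate(8.0, 20.0, 1.336)
        assert 1.0 / v2 == pytest.approx(1.0 / 8.0 - 0.020 / 1.336, rel=1e-12)

    def test_focal_plane_singularity(self):
        with pytest.raises(VergenceSingularityError):
            vergence_translate(10.0, 100.0, 1.0)


class TestCastropClosedForms:
    def test_matches_trace_on_mean_eye(self):
        p = castrop_iol_power(*MEAN_ARGS, constants=STUDY_CONSTANTS, target_se=0.0)
        closed = castrop_predicted_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, p_iol=p
        )
        traced = paraxial_trace_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, p_iol=p
        )
        assert closed == pytest.approx(traced, abs=1e-9)

    def test_oracle_equivalence_randomized(self):
        rng = np.random.default_rng(99)
        recs = random_valid_records(rng, 1000)
        k = CastropConstants(
            rng.uniform(0.35, 0.45), rng.uniform(-0.5, 0.5), rng.uniform(-0.5, 0.5)
        )
        p_iol = rng.uniform(5.0, 32.0, len(recs))
        closed = castrop_predicted_refraction(
            recs.AL, recs.ACD, recs.LT, recs.RCA, k, p_iol=p_iol
        )
        traced = paraxial_trace_refraction(
            recs.AL, recs.ACD, recs.LT, recs.RCA, k, p_iol=p_iol
        )
        assert np.max(np.abs(closed - traced)) < 1e-9

    @pytest.mark.parametrize("target", [-3.0, 0.0, 2.0])
    def test_round_trip(self, target):
        p = castrop_iol_power(*MEAN_ARGS, constants=STUDY_CONSTANTS, target_se=target)
        back = castrop_predicted_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, p_iol=p
        )
        assert back == pytest.approx(target, abs=1e-9)

    def test_inverse_identity_target_grid(self):
        targets = np.linspace(-10.0, 10.0, 41)
        p = castrop_iol_power(*MEAN_ARGS, constants=STUDY_CONSTANTS, target_se=targets)
        back = castrop_predicted_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, p_iol=p
        )
        assert np.max(np.abs(back - targets)) < 1e-9

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        al=st.floats(21.0, 28.5),
        acd=st.floats(2.2, 4.2),
        lt=st.floats(3.4, 5.7),
        rca=st.floats(6.8, 8.6),
        c=st.floats(0.35, 0.45),
        h=st.floats(-0.6, 0.6),
        r=st.floats(-0.6, 0.6),
        t=st.floats(-10.0, 10.0),
    )
    def test_inverse_identity_property(self, al, acd, lt, rca, c, h, r, t):
        k = CastropConstants(c, h, r)
        p = castrop_iol_power(al, acd, lt, rca, k, target_se=t)
        assert castrop_predicted_refraction(al, acd, lt, rca, k, p_iol=p) == pytest.approx(
            t, abs=1e-9
        )

    def test_myopic_target_needs_stronger_iol(self):
        p0 = castrop_iol_power(*MEAN_ARGS, constants=STUDY_CONSTANTS, target_se=0.0)
        pm = castrop_iol_power(*MEAN_ARGS, constants=STUDY_CONSTANTS, target_se=-1.0)
        assert pm > p0

    def test_power_decreases_with_axial_length(self):
        eyes = dict(MEAN_EYE)
        p1 = castrop_iol_power(*[eyes[k] for k in ("AL","ACD","LT","RCA")], constants=STUDY_CONSTANTS)
        eyes["AL"] = MEAN_EYE["AL"] + 0.5
        p2 = castrop_iol_power(*[eyes[k] for k in ("AL","ACD","LT","RCA")], constants=STUDY_CONSTANTS)
        assert p2 < p1

    def test_r_offset_is_additive_on_refraction(self):
        delta = 0.3
        k1 = STUDY_CONSTANTS
        k2 = CastropConstants(k1.c, k1.h, k1.r + delta)
        se1 = castrop_predicted_refraction(*MEAN_ARGS, constants=k1, p_iol=21.5)
        se2 = castrop_predicted_refraction(*MEAN_ARGS, constants=k2, p_iol=21.5)
        assert se2 - se1 == pytest.approx(delta, abs=1e-12)

    def test_scalar_and_vector_paths_agree(self):
        rng = np.random.default_rng(5)
        recs = random_valid_records(rng, 20)
        batch = castrop_predicted_refraction(
            recs.AL, recs.ACD, recs.LT, recs.RCA, STUDY_CONSTANTS, p_iol=21.0
        )
        single = [
            castrop_predicted_refraction(
                row.AL, row.ACD, row.LT, row.RCA, STUDY_CONSTANTS, p_iol=21.0
            )
            for row in recs.itertuples()
        ]
        np.testing.assert_allclose(batch, single, rtol=0, atol=1e-12)

    def test_al_shorter_than_elp_rejected(self):
        with pytest.raises(BiometryDomainError):
            castrop_iol_power(4.0, 3.1, 4.6, 7.7, STUDY_CONSTANTS)

    def test_measured_corneal_geometry_used_when_present(self):
        with_fallback = castrop_predicted_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, p_iol=21.5
        )
        measured = castrop_predicted_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, p_iol=21.5, rcp=6.0, dc=0.6
        )
        assert with_fallback != measured
        # NaN entries fall back to the model eye
        nan_geom = castrop_predicted_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, p_iol=21.5,
            rcp=np.nan, dc=np.nan,
        )
        assert nan_geom == pytest.approx(with_fallback, abs=1e-12)


class TestTraceLimits:
    def test_zero_vertex_distance_removes_spectacle_term(self):
        eye0 = ModelEye(vertex_distance=0.0)
        closed = castrop_predicted_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, eye=eye0, p_iol=21.5
        )
        traced = paraxial_trace_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, eye=eye0, p_iol=21.5
        )
        assert closed == pytest.approx(traced, abs=1e-12)
        # with dVD = 0 the spectacle- and corneal-plane refractions coincide:
        # shifting R by delta still shifts predSE by exactly delta
        k2 = CastropConstants(STUDY_CONSTANTS.c, STUDY_CONSTANTS.h, STUDY_CONSTANTS.r + 0.25)
        shifted = castrop_predicted_refraction(
            *MEAN_ARGS, constants=k2, eye=eye0, p_iol=21.5
        )
        assert shifted - closed == pytest.approx(0.25, abs=1e-12)

    def test_thin_cornea_degenerates_to_three_surfaces(self):
        # zero corneal thickness and a flat back surface: only the front
        # surface power remains, i.e. a thin-cornea vergence model
        thin = castrop_predicted_refraction(
            *MEAN_ARGS, constants=STUDY_CONSTANTS, p_iol=21.5, rcp=1e12, dc=1e-9
        )
        pca, _ = corneal_surface_powers(MEAN_EYE["RCA"], 1e12)
        elp = effective_lens_position(
            MEAN_EYE["ACD"], MEAN_EYE["LT"], STUDY_CONSTANTS
        )
        n = 1.336
        v = n / ((MEAN_EYE["AL"] - elp) * 1e-3) - 21.5
        v = v / (1 + v * elp * 1e-3 / n)
        v = v - pca
        v = v / (1 + v * 0.012)
        assert thin == pytest.approx(v + STUDY_CONSTANTS.r, abs=1e-6)
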