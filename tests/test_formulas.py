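"""Classical comparator formulae and the shared estimator interface."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from castrop.exceptions import BiometryDomainError
from castrop.formulas import (
    FORMULA_REGISTRY,
    CastropFormula,
    HaigisFormula,
    _hofferq_elp,
    _holladay1_elp,
    _srkt_elp_and_lopt,
    haigis_elp,
    make_formula,
    predicted_refraction,
)
from castrop.optics import vergence_refract, vergence_translate

from conftest import MEAN_EYE

STUDY_FORMULAE = {
    "srkt": {"a_constant": 119.011},
    "hofferq": {"pacd": 5.606},
    "holladay1": {"sf": 1.824},
    "haigis": {"a0": 1.446},
    "haigis3": {"a0": 1.565, "a1": 0.443, "a2": 0.089},
    "castrop": {"c": 0.424, "h": -0.312, "r": 0.077},
}


def mean_eye_frame(p_iol=21.5):
    return pd.DataFrame({**{k: [v] for k, v in MEAN_EYE.items()}, "PIOL": [p_iol]})


class TestHaigisELP:
    def test_standard_constants_mean_eye(self):
        d = haigis_elp(3.099, 23.497, a0=1.446, a1=0.4, a2=0.1)
        assert d == pytest.approx(1.446 + 0.4 * 3.099 + 0.1 * 23.497, abs=1e-12)
        assert d == pytest.approx(5.0353, abs=1e-4)

    def test_constant_mode(self):
        assert haigis_elp(3.0, 24.0, a0=1.2, a1=0.0, a2=0.0) == 1.2

    def test_acd_identity(self):
        assert haigis_elp(3.3, 24.0, a0=0.0, a1=1.0, a2=0.0) == pytest.approx(3.3)

    def test_lens_behind_retina_rejected(self):
        with pytest.raises(BiometryDomainError):
            haigis_elp(3.0, 10.0, a0=9.0, a1=0.4, a2=0.1)


class TestInverseIdentity:
    @pytest.mark.parametrize("tag", sorted(STUDY_FORMULAE))
    @pytest.mark.parametrize("target", [-3.0, -0.5, 0.0, 2.0])
    def test_power_refraction_round_trip(self, tag, target):
        est = make_formula(tag, **STUDY_FORMULAE[tag])
        X = mean_eye_frame()
        p = est.iol_power(X, target_se=target)
        X2 = X.assign(PIOL=p)
        assert est.predict_refraction(X2)[0] == pytest.approx(target, abs=1e-9)

    def test_round_trip_on_scattered_biometry(self):
        # ranges kept inside every formula's validity domain (the SRK/T
        # corneal-height term fails for very long eyes with steep corneas)
        rng = np.random.default_rng(31)
        X = pd.DataFrame(
            {
                "AL": rng.uniform(21.5, 26.0, 50),
                "ACD": rng.uniform(2.4, 4.0, 50),
                "LT": rng.uniform(3.6, 5.5, 50),
                "RCA": rng.uniform(7.2, 8.4, 50),
            }
        )
        for tag, consts in STUDY_FORMULAE.items():
            est = make_formula(tag, **consts)
            p = est.iol_power(X, target_se=-0.75)
            back = est.predict_refraction(X.assign(PIOL=p))
            np.testing.assert_allclose(back, -0.75, rtol=0, atol=1e-9)


class TestHaigisVergenceOracle:
    def test_triplet_matches_primitive_trace(self):
        """Independent re-derivation of the Haigis two-surface vergence chain
        using the generic refract/translate primitives."""
        a0, a1, a2 = 1.565, 0.443, 0.089
        al, acd, rca = MEAN_EYE["AL"], MEAN_EYE["ACD"], MEAN_EYE["RCA"]
        p_iol = 21.5
        d = a0 + a1 * acd + a2 * al
        dc_power = 331.5 / rca
        n = 1.336
        # back-propagate the retinal vergence requirement to the spectacle plane
        v = (n * 1000.0) / (al - d) - p_iol
        v = vergence_translate(v, -d, n)          # IOL plane -> cornea
        v = vergence_refract(v, -dc_power)        # remove thin cornea
        v = vergence_translate(v, -12.0, 1.0)     # cornea -> spectacle plane
        est = HaigisFormula(a0=a0, a1=a1, a2=a2, mode="triplet")
        assert est.predict_refraction(mean_eye_frame(p_iol))[0] == pytest.approx(
            v, abs=1e-9
        )

    def test_simple_mode_equals_triplet_at_standard_a1_a2(self):
        X = mean_eye_frame()
        simple = HaigisFormula(a0=1.446, mode="simple").predict_refraction(X)
        triplet = HaigisFormula(a0=1.446, a1=0.4, a2=0.1, mode="triplet").predict_refraction(X)
        assert simple[0] == pytest.approx(triplet[0], abs=1e-12)


class TestSRKT:
    def test_emmetropic_power_monotone_in_a_constant(self):
        X = mean_eye_frame()
        powers = [
            make_formula("srkt", a_constant=a).iol_power(X, target_se=0.0)[0]
            for a in (117.0, 118.0, 119.0, 120.0)
        ]
        assert np.all(np.diff(powers) > 0)

    def test_retinal_thickness_and_long_eye_correction(self):
        elp_a, lopt = _srkt_elp_and_lopt(23.497, 7.668, 119.0)
        assert lopt == pytest.approx(23.497 + 0.65696 - 0.02029 * 23.497, abs=1e-9)
        # the long-eye correction takes over above 24.2 mm and is nearly
        # continuous there (the published quadratic meets the identity to
        # within a couple of microns)
        e1, _ = _srkt_elp_and_lopt(24.2, 7.668, 119.0)
        e2, _ = _srkt_elp_and_lopt(24.2 + 1e-9, 7.668, 119.0)
        assert e1 == pytest.approx(e2, abs=5e-3)

    def test_corneal_height_domain_error(self):
        with pytest.raises(BiometryDomainError):
            _srkt_elp_and_lopt(30.0, 6.8, 119.0)


class TestHofferQ:
    def test_axial_length_clamped_in_acd_prediction(self):
        e31, _ = _hofferq_elp(31.0, 7.668, 5.606)
        e35, _ = _hofferq_elp(35.0, 7.668, 5.606)
        assert e31 == pytest.approx(e35, abs=1e-12)

    def test_short_long_eye_branch_switch(self):
        # M/G switch at 23 mm: both branches finite and ACD increasing in AL
        # through the switch region
        elps = [_hofferq_elp(al, 7.668, 5.606)[0] for al in (22.0, 23.0, 23.01, 24.0)]
        assert np.all(np.isfinite(elps))
        assert elps[-1] > elps[0]


class TestHolladay1:
    def test_anterior_segment_cap(self):
        # AG caps at 13.5 mm for long eyes: predicted chamber depth saturates
        e26 = _holladay1_elp(26.0, 7.668, 1.824)
        e28 = _holladay1_elp(28.0, 7.668, 1.824)
        assert e26 == pytest.approx(e28, abs=1e-12)

    def test_steep_small_cornea_clamped_to_7mm(self):
        assert _holladay1_elp(23.0, 6.5, 0.0) == pytest.approx(
            _holladay1_elp(23.0, 7.0, 0.0), abs=1e-12
        )


class TestMeanEyeSanity:
    @pytest.mark.parametrize("tag", sorted(STUDY_FORMULAE))
    def test_emmetropic_power_plausible(self, tag):
        """Every formula with its lens-specific constants lands near the
        population's implanted power for the population-mean eye."""
        est = make_formula(tag, **STUDY_FORMULAE[tag])
        p = est.iol_power(mean_eye_frame(), target_se=-0.5)[0]
        assert 20.0 <= p <= 23.0


class TestEstimatorInterface:
    def test_get_set_params_and_clone(self):
        est = CastropFormula(c=0.41, h=0.1, r=-0.05)
        params = est.get_params()
        assert params["c"] == 0.41
        est2 = clone(est)
        assert est2.get_params()["h"] == 0.1
        est2.set_params(h=0.3)
        assert est2.h == 0.3 and est.h == 0.1

    def test_fit_sets_trailing_underscore_attributes(self, clean_dataset):
        est = CastropFormula().fit(clean_dataset, clean_dataset["SE"])
        assert hasattr(est, "constants_")
        assert est.c_ == pytest.approx(est.constants_[0])
        assert est.converged_by_ in {"step", "ftol", "max_iter"}

    def test_predict_uses_fitted_constants(self, clean_dataset):
        est = CastropFormula(c=0.40).fit(clean_dataset, clean_dataset["SE"])
        manual = CastropFormula(c=est.c_, h=est.h_, r=est.r_)
        np.testing.assert_allclose(
            est.predict(clean_dataset), manual.predict(clean_dataset), atol=1e-12
        )

    def test_functional_dispatch_matches_estimator(self):
        X = mean_eye_frame()
        a = predicted_refraction(X, "castrop", c=0.424, h=-0.312, r=0.077)
        b = CastropFormula(c=0.424, h=-0.312, r=0.077).predict_refraction(X)
        assert a[0] == b[0]

    def test_unknown_formula_tag(self):
        with pytest.raises(ValueError, match="unknown formula"):
            make_formula("barrett")

    def test_registry_covers_six_formulae(self):
        assert set(FORMULA_REGISTRY) == {
            "srkt", "hofferq", "holladay1", "haigis", "haigis3", "castrop",
        }
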