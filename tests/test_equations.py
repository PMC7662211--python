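"""Unit and property tests for the five body-fat estimation equations."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bfagree.equations import (
    AnthropometricRecord,
    Sex,
    compute_bmi,
    compute_panel,
    cun_bae,
    deurenberg,
    ecore_bf,
    palafolls,
    rfm,
    sex_code,
)

ages = st.floats(min_value=18, max_value=65)
bmis = st.floats(min_value=15, max_value=45)
heights = st.floats(min_value=140, max_value=200)
wcs = st.floats(min_value=55, max_value=140)


class TestComputeBmi:
    @pytest.mark.parametrize(
        "weight, height, expected",
        [(81.3, 174.4, 26.73), (65.8, 161.7, 25.17), (50.0, 100.0, 50.0)],
    )
    def test_known_values(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("weight, height", [(0, 170), (-1, 170), (70, 0), (70, -5)])
    def test_rejects_nonpositive(self, weight, height):
        with pytest.raises(ValueError):
            compute_bmi(weight, height)


class TestSexCode:
    @pytest.mark.parametrize(
        "equation, sex, expected",
        [
            ("cun_bae", Sex.female, 1),
            ("cun_bae", Sex.male, 0),
            ("ecore_bf", Sex.female, 1),
            ("rfm", Sex.male, 0),
            ("palafolls", Sex.female, 1),
            ("deurenberg", Sex.female, 0),  # reversed coding
            ("deurenberg", Sex.male, 1),
        ],
    )
    def test_coding(self, equation, sex, expected):
        assert sex_code(equation, sex) == expected

    def test_unknown_equation(self):
        with pytest.raises(KeyError):
            sex_code("siri", Sex.female)


class TestEquationValues:
    """Frozen hand-evaluations of each published formula."""

    @pytest.mark.parametrize(
        "fn, args, expected",
        [
            (cun_bae, (40, Sex.female, 25), 35.521),
            (cun_bae, (40, Sex.male, 25), 23.432),
            (ecore_bf, (40, Sex.female, 25), 35.466),
            (ecore_bf, (40, Sex.male, 25), 23.566),
            (ecore_bf, (0, Sex.male, 1), -97.102),
            (rfm, (160, 80, Sex.female), 36.0),
            (rfm, (160, 80, Sex.male), 24.0),
            (rfm, (161.7, 75.9, Sex.female), 33.39),
            (palafolls, (25, 100, Sex.male), 27.5),
            (palafolls, (25, 100, Sex.female), 37.5),
            (palafolls, (26.7, 88.7, Sex.male), 29.71),
            (deurenberg, (25.2, 39.4, Sex.female), 33.902),
            (deurenberg, (26.7, 40.4, Sex.male), 25.132),
            (deurenberg, (25, 40, Sex.male), 23.0),
        ],
    )
    def test_point_values(self, fn, args, expected):
        assert fn(*args) == pytest.approx(expected, abs=0.005)

    def test_cun_bae_constant_term(self):
        # age 0, bmi -> 0 leaves only the intercept
        assert cun_bae(0, Sex.male, 1e-12) == pytest.approx(-44.988, abs=1e-6)

    def test_log_domain_and_division_guards(self):
        with pytest.raises(ValueError):
            ecore_bf(40, Sex.male, 0)
        with pytest.raises(ValueError):
            rfm(160, 0, Sex.male)
        with pytest.raises(ValueError):
            palafolls(25, 0, Sex.male)
        with pytest.raises(ValueError):
            cun_bae(float("nan"), Sex.male, 25)

    def test_vectorised_matches_scalar(self):
        age = np.array([20.0, 40.0, 60.0])
        bmi = np.array([20.0, 25.0, 35.0])
        sex = np.array(["female", "male", "female"], dtype=object)
        vec = cun_bae(age, sex, bmi)
        scal = [cun_bae(a, Sex(s), b) for a, s, b in zip(age, sex, bmi)]
        np.testing.assert_allclose(vec, scal, rtol=0, atol=0)


class TestSexOffsets:
    """Per-equation female-minus-male offsets at identical covariates."""

    @settings(max_examples=50, deadline=None)
    @given(age=ages, bmi=bmis, height=heights, wc=wcs)
    def test_offsets_equal_coefficients(self, age, bmi, height, wc):
        assert ecore_bf(age, Sex.female, bmi) - ecore_bf(age, Sex.male, bmi) == pytest.approx(11.900)
        assert rfm(height, wc, Sex.female) - rfm(height, wc, Sex.male) == pytest.approx(12.0)
        assert palafolls(bmi, wc, Sex.female) - palafolls(bmi, wc, Sex.male) == pytest.approx(10.0)
        # reversed coding: women minus men is +10.8
        assert deurenberg(bmi, age, Sex.female) - deurenberg(bmi, age, Sex.male) == pytest.approx(10.8)


class TestMonotonicity:
    @settings(max_examples=100, deadline=None)
    @given(
        age=ages,
        sex=st.sampled_from([Sex.female, Sex.male]),
        b=st.tuples(bmis, bmis).filter(lambda t: abs(t[0] - t[1]) > 1e-6),
        wc=wcs,
    )
    def test_bmi_equations_increase_in_bmi(self, age, sex, b, wc):
        lo, hi = sorted(b)
        assert cun_bae(age, sex, hi) > cun_bae(age, sex, lo)
        assert ecore_bf(age, sex, hi) > ecore_bf(age, sex, lo)
        assert palafolls(hi, wc, sex) > palafolls(lo, wc, sex)
        assert deurenberg(hi, age, sex) > deurenberg(lo, age, sex)

    @settings(max_examples=100, deadline=None)
    @given(
        sex=st.sampled_from([Sex.female, Sex.male]),
        height=heights,
        w=st.tuples(wcs, wcs).filter(lambda t: abs(t[0] - t[1]) > 1e-6),
    )
    def test_rfm_monotone_in_wc_and_height(self, sex, height, w):
        lo, hi = sorted(w)
        assert rfm(height, hi, sex) > rfm(height, lo, sex)
        assert rfm(height + 1, lo, sex) < rfm(height, lo, sex)


class TestRecordAndPanel:
    def _record(self, **kw):
        base = dict(id="r1", sex=Sex.female, age_years=40.0, weight_kg=65.0, height_cm=161.2, wc_cm=76.0)
        base.update(kw)
        return AnthropometricRecord(**base)

    def test_bmi_always_recomputed(self, caplog):
        rec = self._record()
        assert rec.bmi == pytest.approx(65.0 / 1.612**2)
        with caplog.at_level(logging.WARNING):
            rec2 = self._record(bmi=30.0)
        assert rec2.bmi == pytest.approx(rec.bmi)
        assert "disagrees" in caplog.text

    def test_protocol_flag(self):
        assert self._record(age_years=40).in_protocol
        assert not self._record(age_years=17).in_protocol
        assert not self._record(age_years=70).in_protocol

    def test_rejects_nonpositive_measurements(self):
        for field in ("weight_kg", "height_cm", "wc_cm"):
            with pytest.raises(Exception):
                self._record(**{field: 0})

    def test_panel_matches_single_equations(self):
        rec = self._record()
        panel = compute_panel(rec)
        assert panel.cun_bae_pct == cun_bae(rec.age_years, rec.sex, rec.bmi)
        assert panel.ecore_bf_pct == ecore_bf(rec.age_years, rec.sex, rec.bmi)
        assert panel.rfm_pct == rfm(rec.height_cm, rec.wc_cm, rec.sex)
        assert panel.palafolls_pct == palafolls(rec.bmi, rec.wc_cm, rec.sex)
        assert panel.deurenberg_pct == deurenberg(rec.bmi, rec.age_years, rec.sex)

    def test_panel_deterministic(self):
        a, b = compute_panel(self._record()), compute_panel(self._record())
        assert a == b

    def test_panel_error_names_failing_equations(self):
        rec = self._record().model_copy(update={"wc_cm": 0.0})
        with pytest.raises(ValueError) as exc:
            compute_panel(rec)
        assert "rfm" in str(exc.value) and "palafolls" in str(exc.value)

    def test_sex_swap_changes_panel_by_offsets(self):
        f = compute_panel(self._record(sex=Sex.female))
        m = compute_panel(self._record(sex=Sex.male))
        assert f.ecore_bf_pct - m.ecore_bf_pct == pytest.approx(11.900)
        assert f.rfm_pct - m.rfm_pct == pytest.approx(12.0)
        assert f.palafolls_pct - m.palafolls_pct == pytest.approx(10.0)
        assert f.deurenberg_pct - m.deurenberg_pct == pytest.approx(10.8)


def test_deurenberg_linearity_mean_identity(small_cohort):
    """A linear formula evaluated at the means equals the mean of its values."""
    for sex in ("female", "male"):
        sub = small_cohort[small_cohort["sex"] == sex]
        at_means = deurenberg(sub["bmi"].mean(), sub["age_years"].mean(), Sex(sex))
        assert at_means == pytest.approx(sub["deurenberg"].mean(), abs=1e-9)
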