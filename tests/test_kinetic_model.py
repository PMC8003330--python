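"""Rate-law algebra: Hill fractions, saturation limits, unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import glyatkin as gk
from glyatkin import HillBisubstrateParams, ValidationError


def _hill_oracle(vmax, s05, h, S):
    """Plain-float evaluation of the Hill rate, independent of the package's
    vectorised implementation."""
    if S == 0:
        return 0.0
    x = math.exp(h * math.log(S / s05))
    return vmax * x / (1.0 + x)


class TestBisubstrateRate:
    def test_zero_substrate_annihilates(self, ref_params):
        assert gk.rate_bisubstrate(ref_params, 0.0, 50.0) == 0.0
        assert gk.rate_bisubstrate(ref_params, 10.0, 0.0) == 0.0

    def test_reference_point_matches_hand_arithmetic(self, ref_params):
        expected = (_hill_oracle(1, 23, 1.6, 20)
                    * _hill_oracle(1, 97, 2.1, 80) * 0.85)
        got = gk.rate_bisubstrate(ref_params, 20.0, 80.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.151146, rel=1e-4)

    def test_saturation_limit_is_vf(self, ref_params):
        assert gk.saturation_rate(ref_params) == 0.85
        # analytic limit dominates every finite evaluation
        assert gk.rate_bisubstrate(ref_params, 1e6, 1e6) < 0.85

    def test_negative_concentration_rejected(self, ref_params):
        with pytest.raises(ValidationError):
            gk.rate_bisubstrate(ref_params, -1.0, 50.0)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(g1=st.floats(0.1, 500), g2=st.floats(0.1, 500),
           b1=st.floats(0.5, 500), b2=st.floats(0.5, 500))
    def test_separability(self, g1, g2, b1, b2):
        """The rate law factorises: v(G1,B1) v(G2,B2) = v(G1,B2) v(G2,B1)."""
        p = gk.REFERENCE_156SER
        r = gk.rate_bisubstrate
        lhs = r(p, g1, b1) * r(p, g2, b2)
        rhs = r(p, g1, b2) * r(p, g2, b1)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    @pytest.mark.parametrize("benz", [20.0, 80.0, 200.0])
    def test_half_saturation_identity(self, ref_params, benz):
        """Rate at G = s05_gly is exactly half the G->inf limit at any B."""
        at_half = gk.rate_bisubstrate(ref_params, ref_params.s05_gly, benz)
        at_inf = ref_params.vf * gk.hill_fraction(
            benz, ref_params.s05_benz, ref_params.h_benz)
        assert at_half / at_inf == pytest.approx(0.5, abs=1e-12)

    def test_strictly_increasing_in_each_substrate(self, ref_params):
        gly = np.geomspace(0.5, 400, 25)
        rates = gk.rate_bisubstrate(ref_params, gly, 80.0)
        assert np.all(np.diff(rates) > 0)
        benz = np.geomspace(5, 400, 25)
        rates = gk.rate_bisubstrate(ref_params, 50.0, benz)
        assert np.all(np.diff(rates) > 0)
        assert np.all(rates < ref_params.vf)

    def test_h1_reduces_to_michaelis_menten_product(self):
        p = HillBisubstrateParams(label="mm", vf=1.2, s05_gly=15.0, h_gly=1.0,
                                  s05_benz=70.0, h_benz=1.0)
        for g in (1.0, 15.0, 120.0):
            for b in (10.0, 70.0, 300.0):
                mm = 1.2 * (g / (15.0 + g)) * (b / (70.0 + b))
                assert gk.rate_bisubstrate(p, g, b) == pytest.approx(
                    mm, rel=1e-12)


class TestUnisubstrateRate:
    @pytest.mark.parametrize("vmax, s05, h, S, expected", [
        (1.0, 10.0, 2.0, 10.0, 0.5),          # half saturation by definition
        (1.0, 10.0, 1.0, 30.0, 0.75),         # Michaelis-Menten limit
        (0.85, 23.0, 1.6, 200.0, None),       # checked against the oracle
    ])
    def test_values(self, vmax, s05, h, S, expected):
        got = gk.rate_unisubstrate(vmax, s05, h, S)
        if expected is None:
            expected = _hill_oracle(vmax, s05, h, S)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_substrate(self):
        assert gk.rate_unisubstrate(1.0, 10.0, 0.7, 0.0) == 0.0


class TestRelativeActivity:
    def test_identity(self, ref_params):
        assert gk.relative_activity(ref_params, ref_params, 20, 80) == 100.0

    def test_rare_variant_vs_reference_at_assay_point(self, ref_params,
                                                      rc_params):
        # model-side prediction at 20 mM glycine / 80 uM benzoyl-CoA
        expected = 100.0 * (
            0.083 * _hill_oracle(1, 30, 1.4, 20) * _hill_oracle(1, 61, 3.5, 80)
        ) / (
            0.85 * _hill_oracle(1, 23, 1.6, 20) * _hill_oracle(1, 97, 2.1, 80)
        )
        got = gk.relative_activity(rc_params, ref_params, 20.0, 80.0)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(14.3, abs=0.1)

    def test_double_variant_at_saturation(self, ref_params, tt_params):
        assert gk.relative_activity(tt_params, ref_params) == pytest.approx(
            73.0, abs=0.5)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(g=st.floats(1.0, 200.0), b=st.floats(5.0, 400.0))
    def test_inversion_product(self, g, b):
        a, c = gk.REFERENCE_156SER, gk.HAPLOTYPE_156SER_199CYS
        fwd = gk.relative_activity(a, c, g, b)
        rev = gk.relative_activity(c, a, g, b)
        assert fwd * rev == pytest.approx(10_000.0, rel=1e-10)

    def test_zero_reference_raises(self, ref_params):
        dead = HillBisubstrateParams(label="dead", vf=0.0, s05_gly=1.0,
                                     h_gly=1.0, s05_benz=1.0, h_benz=1.0)
        with pytest.raises(ZeroDivisionError):
            gk.relative_activity(ref_params, dead)


class TestKcatConversion:
    def test_reference_pair(self):
        assert gk.specific_activity_to_kcat(0.85, 33_880.0) == pytest.approx(
            0.480, abs=5e-4)

    def test_invalid_input(self):
        with pytest.raises(ValidationError):
            gk.specific_activity_to_kcat(0.0)
        with pytest.raises(ValidationError):
            gk.kcat_to_specific_activity(-1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(kcat=st.floats(1e-4, 1e3), mass=st.floats(5e3, 2e5))
    def test_roundtrip_exact(self, kcat, mass):
        back = gk.specific_activity_to_kcat(
            gk.kcat_to_specific_activity(kcat, mass), mass)
        assert back == pytest.approx(kcat, rel=1e-12)

    def test_single_molar_mass_reconciles_all_haplotypes(self):
        """One subunit mass maps every published Vf to its kcat within 2%."""
        for p in gk.CHARACTERISED_HAPLOTYPES.values():
            derived = gk.specific_activity_to_kcat(p.vf, gk.DEFAULT_MOLAR_MASS)
            assert derived == pytest.approx(p.kcat, rel=0.02)


class TestParamsValidation:
    def test_bad_values_rejected(self):
        good = dict(label="x", vf=1.0, s05_gly=10.0, h_gly=1.5,
                    s05_benz=50.0, h_benz=2.0)
        for key, bad in [("vf", -1.0), ("s05_gly", 0.0), ("h_gly", 0.2),
                         ("h_benz", 7.0), ("s05_benz", float("nan"))]:
            with pytest.raises(ValidationError):
                HillBisubstrateParams(**{**good, key: bad})

    def test_inconsistent_kcat_rejected(self):
        with pytest.raises(ValidationError):
            HillBisubstrateParams(label="x", vf=0.85, kcat=0.9,
                                  s05_gly=23, h_gly=1.6,
                                  s05_benz=97, h_benz=2.1)

    def test_enzyme_amount_single_interpretation(self):
        with pytest.raises(ValidationError):
            gk.EnzymeAmount(e_total_uM=1.0, mass_ug=2.0, volume_uL=200.0)
        with pytest.raises(ValidationError):
            gk.EnzymeAmount(mass_ug=2.0)  # volume missing
        amt = gk.EnzymeAmount(mass_ug=2.0, volume_uL=200.0)
        # 1 umol/min/mg * 0.002 mg / 0.0002 L = 10 uM/min
        assert amt.well_rate_uM_per_min(1.0) == pytest.approx(10.0)


class TestSerialisation:
    def test_ini_roundtrip(self, tmp_path, ref_params, rc_params):
        path = tmp_path / "params.ini"
        gk.write_params_ini([ref_params, rc_params], path)
        loaded = gk.read_params_ini(path)
        assert set(loaded) == {ref_params.label, rc_params.label}
        assert loaded[ref_params.label] == ref_params

    def test_packaged_fixture_matches_constants(self):
        table = gk.load_characterised_haplotypes()
        assert table == gk.CHARACTERISED_HAPLOTYPES

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.ini"
        path.write_text("[h1]\nvf = 1.0\nwibble = 2\n")
        with pytest.raises(ValidationError):
            gk.read_params_ini(path)
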