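"""Binding-curve models: exact depletion isotherm and Hill equation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import qmc

import bindprof as bp

NM = 1e-9


def bisect_complex(kd, atot, btot, tol=1e-14):
    """Independent oracle: root of (Atot-AB)(Btot-AB) = KD*AB by bisection."""
    if atot == 0 or btot == 0:
        return 0.0
    lo, hi = 0.0, min(atot, btot)

    def g(ab):
        return (atot - ab) * (btot - ab) - kd * ab

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * min(atot, btot):
            break
    return 0.5 * (lo + hi)


@pytest.mark.parametrize(
    "kd, atot, btot, expected",
    [
        (10 * NM, 0.0, 10 * NM, 0.0),  # no titrant, no complex
        (0.0, 20 * NM, 10 * NM, 10 * NM),  # infinite affinity: min(Atot, Btot)
        (10 * NM, 10 * NM, 10 * NM, 3.8196601125e-9),  # frozen from the oracle
    ],
)
def test_complex_concentration_examples(kd, atot, btot, expected):
    assert bp.complex_concentration(kd, atot, btot) == pytest.approx(
        expected, rel=1e-9, abs=1e-30
    )


def test_complex_concentration_matches_bisection_oracle():
    """Stable quadratic root vs bisection on 1000 quasi-random triples."""
    sampler = qmc.Halton(d=3, scramble=True, seed=42)
    # span picomolar..millimolar on a log scale
    triples = 10.0 ** (-12 + 9 * sampler.random(1000))
    for kd, atot, btot in triples:
        ab = bp.complex_concentration(kd, atot, btot)
        oracle = bisect_complex(kd, atot, btot)
        assert ab == pytest.approx(oracle, rel=1e-8)


def test_complex_concentration_negative_input_names_argument():
    with pytest.raises(ValueError, match="Atot"):
        bp.complex_concentration(1e-9, -1e-9, 1e-9)
    with pytest.raises(ValueError, match="KD"):
        bp.complex_concentration(-1e-9, 1e-9, 1e-9)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    kd=st.floats(1e-12, 1e-3),
    atot=st.floats(0, 1e-3),
    btot=st.floats(1e-12, 1e-3),
)
def test_complex_concentration_properties(kd, atot, btot):
    """0 <= AB <= min(Atot, Btot) and the mass-action quadratic holds."""
    ab = bp.complex_concentration(kd, atot, btot)
    assert 0.0 <= ab <= min(atot, btot) * (1 + 1e-12)
    residual = (atot - ab) * (btot - ab) - kd * ab
    scale = max(kd * ab, atot * btot, 1e-300)
    assert abs(residual) <= 1e-10 * scale


def test_dilute_probe_limit_reduces_to_hyperbola():
    """Btot << KD and << Atot: bound fraction ~ Atot / (KD + Atot)."""
    kd = 10 * NM
    btot = 1e-3 * kd
    for atot in [1 * NM, 10 * NM, 100 * NM, 1000 * NM]:
        if btot > 1e-3 * atot:
            continue
        frac = bp.complex_concentration(kd, atot, btot) / btot
        assert frac == pytest.approx(atot / (kd + atot), rel=1e-2)


def test_complex_concentration_monotonicity_grid():
    grid = 10.0 ** np.linspace(-11, -6, 12)
    for btot in (1 * NM, 50 * NM):
        ab_in_atot = [bp.complex_concentration(10 * NM, a, btot) for a in grid]
        assert np.all(np.diff(ab_in_atot) >= -1e-25)
        ab_in_kd = [bp.complex_concentration(k, 20 * NM, btot) for k in grid]
        assert np.all(np.diff(ab_in_kd) <= 1e-25)
    ab_in_btot = [bp.complex_concentration(10 * NM, 20 * NM, b) for b in grid]
    assert np.all(np.diff(ab_in_btot) >= -1e-25)


class TestMstResponse:
    shared = bp.SharedBindingParams(KD=10 * NM)
    rep = bp.MstReplicateParams(Btot=10 * NM, Fn_B=0.0, Fn_AB=1.0)

    def test_zero_dose_gives_free_partner_signal(self):
        assert bp.mst_response(self.shared, self.rep, 0.0) == 0.0

    def test_saturation_approaches_complex_signal(self):
        assert bp.mst_response(self.shared, self.rep, 1e6 * 10 * NM) == pytest.approx(
            1.0, abs=1e-4
        )

    def test_midpoint_value_from_oracle(self):
        # AB/Btot at Atot = Btot = KD, frozen from the bisection oracle
        assert bp.mst_response(self.shared, self.rep, 10 * NM) == pytest.approx(
            0.38196601, rel=1e-6
        )

    def test_monotone_and_bounded(self):
        doses = np.geomspace(1e-12, 1e-4, 50)
        vals = np.array([bp.mst_response(self.shared, self.rep, d) for d in doses])
        assert np.all(np.diff(vals) >= 0)
        assert np.all((vals >= 0.0) & (vals <= 1.0))

    def test_flat_amplitudes_warn(self):
        with pytest.warns(UserWarning, match="identifiable"):
            bp.MstReplicateParams(Btot=10 * NM, Fn_B=1.0, Fn_AB=1.0)


class TestHillResponse:
    rep = bp.HillReplicateParams(F0=1.0, Fmax=2.0)

    @pytest.mark.parametrize(
        "ec50, n, c, expected",
        [
            (150e-6, 1.5, 150e-6, 2.0),  # midpoint F0 + Fmax/2
            (150e-6, 1.5, 0.0, 1.0),  # zero-dose limit is F0
            (150e-6, 1.0, 50e-6, 1.5),  # 1 + 2/(1+3)
        ],
    )
    def test_examples(self, ec50, n, c, expected):
        shared = bp.SharedBindingParams(EC50=ec50, n=n)
        assert bp.hill_response(shared, self.rep, c) == pytest.approx(expected)

    def test_saturation_limit(self):
        shared = bp.SharedBindingParams(EC50=150e-6, n=2.0)
        assert bp.hill_response(shared, self.rep, 1e3) == pytest.approx(3.0, rel=1e-6)

    def test_unit_hill_coefficient_is_one_site_saturation(self):
        shared = bp.SharedBindingParams(EC50=150e-6, n=1.0)
        for c in np.geomspace(1e-7, 1e-2, 20):
            expected = self.rep.F0 + self.rep.Fmax * c / (shared.EC50 + c)
            assert bp.hill_response(shared, self.rep, c) == pytest.approx(expected)

    def test_monotone_in_dose(self):
        shared = bp.SharedBindingParams(EC50=150e-6, n=1.7)
        doses = np.geomspace(1e-8, 1e-1, 60)
        vals = np.array([bp.hill_response(shared, self.rep, c) for c in doses])
        assert np.all(np.diff(vals) >= 0)


def test_parameter_validation():
    with pytest.raises(ValueError):
        bp.SharedBindingParams(KD=0.0)
    with pytest.raises(ValueError):
        bp.SharedBindingParams(EC50=150e-6, n=-1.0)
    with pytest.raises(ValueError):
        bp.MstReplicateParams(Btot=0.0, Fn_B=0.0, Fn_AB=1.0)
    with pytest.raises(ValueError):
        bp.HillReplicateParams(F0=np.inf, Fmax=1.0)
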