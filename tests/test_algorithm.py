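"""Quadratic inversion, the parametric N_app algorithm, and SN lookup."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nsensor as ns
from nsensor.algorithm import SNAnchor, SNLookupTable, si_max

BOOTING_Q = ns.QuadraticResponse(a0=0.542, a1=0.003, a2=-0.0006)
BOOTING_B = ns.LinearSIMap(b0=-0.608, b1=1.616)

concave = st.tuples(
    st.floats(min_value=0.1, max_value=1.0),     # a0
    st.floats(min_value=0.0, max_value=0.01),    # a1
    st.floats(min_value=-1e-3, max_value=-1e-5),  # a2
)


class TestNrateMax:
    def test_booting_vertex_rate(self):
        assert ns.nrate_max(BOOTING_Q) == pytest.approx(2.5)

    @given(k=st.floats(min_value=0.0, max_value=500.0),
           a2=st.floats(min_value=-1e-2, max_value=-1e-6))
    def test_vertex_identity(self, k, a2):
        q = ns.QuadraticResponse(a0=0.5, a1=2 * k * abs(a2), a2=a2)
        assert ns.nrate_max(q) == pytest.approx(k, rel=1e-9, abs=1e-9)

    def test_convex_response_rejected(self):
        with pytest.raises(ns.NonConcaveError):
            ns.nrate_max(ns.QuadraticResponse(a0=0.5, a1=1.0, a2=0.1))


class TestNrateForSI:
    def test_zero_n_plot_lies_at_zero_rate(self):
        assert ns.nrate_for_si(BOOTING_Q, BOOTING_Q.a0) == pytest.approx(0.0, abs=1e-9)

    def test_vertex_si_gives_vertex_rate(self):
        assert ns.nrate_for_si(BOOTING_Q, si_max(BOOTING_Q)) == pytest.approx(2.5)

    def test_unit_rate_recovered_from_its_si(self):
        si_at_1 = BOOTING_Q.predict(1.0)  # 0.5444
        assert ns.nrate_for_si(BOOTING_Q, si_at_1) == pytest.approx(1.0, rel=1e-9)

    def test_matches_brute_force_scan(self):
        """Grid-scan oracle: the returned rate's SI matches the input SI."""
        grid = np.linspace(0.0, ns.nrate_max(BOOTING_Q), 200_001)
        si_target = BOOTING_Q.predict(1.7)
        best = grid[np.argmin(np.abs(BOOTING_Q.predict(grid) - si_target))]
        assert ns.nrate_for_si(BOOTING_Q, si_target) == pytest.approx(best, abs=1e-4)

    def test_si_above_maximum_clamps_to_vertex_with_warning(self):
        with pytest.warns(UserWarning, match="achievable maximum"):
            rate = ns.nrate_for_si(BOOTING_Q, si_max(BOOTING_Q) + 0.1)
        assert rate == pytest.approx(2.5)

    @given(abc=concave, frac=st.floats(min_value=0.0, max_value=1.0))
    def test_inversion_is_identity_on_ascending_branch(self, abc, frac):
        q = ns.QuadraticResponse(*abc)
        n_star = frac * ns.nrate_max(q)
        recovered = ns.nrate_for_si(q, q.predict(n_star))
        assert recovered == pytest.approx(n_star, rel=1e-9, abs=1e-4)


class TestNappFromSISpad:
    def test_zero_at_maximum_si(self):
        assert ns.napp_from_si_spad(BOOTING_Q, si_max(BOOTING_Q)) == pytest.approx(0.0)

    def test_full_vertex_rate_for_zero_n_plot(self):
        assert ns.napp_from_si_spad(BOOTING_Q, BOOTING_Q.a0) == pytest.approx(2.5)

    @given(abc=concave, frac=st.floats(min_value=0.0, max_value=1.0))
    def test_closed_form_square_root_identity(self, abc, frac):
        q = ns.QuadraticResponse(*abc)
        si = q.a0 + frac * (si_max(q) - q.a0)
        expected = math.sqrt((si_max(q) - si) / abs(q.a2))
        # abs floor ~R*sqrt(eps): epsilon-scale cancellation at the vertex
        assert ns.napp_from_si_spad(q, si) == pytest.approx(expected, rel=1e-9, abs=1e-4)


class TestDeriveParametric:
    def test_booting_r_constant_matches_published(self):
        alg = ns.derive_parametric(BOOTING_Q, BOOTING_B, "booting")
        assert alg.R == pytest.approx(math.sqrt(1.616 / 0.0006), rel=1e-12)
        assert alg.R == pytest.approx(51.89, abs=0.05)
        assert alg.provenance == "derived"

    def test_booting_derived_sufficiency_threshold(self):
        alg = ns.derive_parametric(BOOTING_Q, BOOTING_B, "booting")
        assert alg.SI_R == pytest.approx(0.714, abs=5e-4)

    def test_unit_case(self):
        q = ns.QuadraticResponse(a0=1.0, a1=0.0, a2=-1.0)
        m = ns.LinearSIMap(b0=0.0, b1=1.0)
        alg = ns.derive_parametric(q, m, "booting")
        assert alg.R == pytest.approx(1.0)
        assert alg.SI_R == pytest.approx(1.0)

    def test_non_concave_or_flat_bridge_rejected(self):
        with pytest.raises(ns.DerivationError):
            ns.derive_parametric(
                ns.QuadraticResponse(a0=0.5, a1=0.01, a2=0.001), BOOTING_B, "booting"
            )
        with pytest.raises(ns.DerivationError):
            ns.derive_parametric(BOOTING_Q, ns.LinearSIMap(b0=0.0, b1=-1.0), "booting")


class TestNapp:
    def test_zero_at_sufficiency_threshold(self):
        alg = ns.published_algorithm("tillering")
        assert ns.napp(alg, alg.SI_R) == 0.0
        assert ns.napp(alg, 1.35) == 0.0

    def test_published_booting_full_unit_deficit(self):
        alg = ns.published_algorithm("booting")
        assert ns.napp(alg, 0.33) == pytest.approx(51.89)

    @given(si=st.floats(min_value=0.0, max_value=3.0),
           delta=st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_non_increasing_and_non_negative(self, si, delta):
        alg = ns.published_algorithm("booting")
        lo, hi = ns.napp(alg, si + delta), ns.napp(alg, si)
        assert lo <= hi
        assert lo >= 0.0

    def test_negative_sensor_si_rejected(self):
        with pytest.raises(ns.ValidationError):
            ns.napp(ns.published_algorithm("booting"), -0.1)


def test_published_algorithm_fixtures():
    till = ns.published_algorithm("tillering")
    assert (till.R, till.SI_R) == (87.17, 1.35)
    boot = ns.published_algorithm("booting")
    assert (boot.R, boot.SI_R) == (51.89, 1.33)
    assert boot.provenance == "published"
    with pytest.raises(ns.ValidationError):
        ns.published_algorithm("ear_emergence")


bridge_sets = st.tuples(
    st.floats(min_value=-1.0, max_value=0.25),  # b0
    st.floats(min_value=0.5, max_value=2.0),    # b1
)


@given(abc=concave, b=bridge_sets, frac=st.floats(min_value=0.0, max_value=1.0))
def test_path_equivalence_of_composed_and_parametric_routes(abc, b, frac):
    """N_app via quadratic inversion + bridge equals R*sqrt(SI_R - SI)."""
    q = ns.QuadraticResponse(*abc)
    m = ns.LinearSIMap(*b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alg = ns.derive_parametric(q, m, "booting")
        # sample sensor SI so the mapped SPAD SI spans [a0, SI_max]:
        # both routes defined, no clamping
        si_spad = q.a0 + frac * (si_max(q) - q.a0)
        si_sensor = m.invert(si_spad)
        composed = ns.napp_from_si_spad(q, m.predict(si_sensor))
        parametric = alg.R * math.sqrt(max(alg.SI_R - si_sensor, 0.0))
    # abs floor ~R*sqrt(eps): epsilon-scale cancellation at the vertex
    assert parametric == pytest.approx(composed, rel=1e-9, abs=1e-4)


class TestSNLookup:
    @pytest.mark.parametrize(
        "stage, sn, expected",
        [
            ("tillering", 9.0, 75.0),
            ("tillering", 35.0, 45.0),
            ("booting", 20.0, 40.0),
            ("booting", 80.0, 25.0),
        ],
    )
    def test_published_anchor_ranges(self, stage, sn, expected):
        table = ns.published_sn_table(stage)
        assert ns.recommend_from_sn(table, sn) == expected

    def test_between_ranges_interpolates_on_midpoints(self):
        table = ns.published_sn_table("tillering")
        mid = 0.5 * (9.0 + 35.05)  # halfway between anchor midpoints
        assert ns.recommend_from_sn(table, mid) == pytest.approx(60.0)

    def test_outside_table_extrapolates_with_warning(self):
        table = ns.published_sn_table("booting")
        with pytest.warns(UserWarning, match="below the table"):
            assert ns.recommend_from_sn(table, 2.0) == 40.0
        with pytest.warns(UserWarning, match="above the table"):
            assert ns.recommend_from_sn(table, 95.0) == 25.0

    @pytest.mark.parametrize("stage", ["tillering", "booting"])
    def test_monotone_non_increasing_over_sn(self, stage):
        table = ns.published_sn_table(stage)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rates = [ns.recommend_from_sn(table, s) for s in np.linspace(0, 100, 401)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_table_invariants_enforced(self):
        with pytest.raises(ns.ValidationError):
            SNLookupTable(stage="x", anchors=())
        with pytest.raises(ns.ValidationError):  # overlapping ranges
            SNLookupTable(
                stage="x",
                anchors=(SNAnchor(0, 10, 50), SNAnchor(5, 20, 40)),
            )
        with pytest.raises(ns.ValidationError):  # rate increases with SN
            SNLookupTable(
                stage="x",
                anchors=(SNAnchor(0, 10, 50), SNAnchor(20, 30, 60)),
            )
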