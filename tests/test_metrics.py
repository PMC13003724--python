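import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aawss.metrics import (CycleSpec, clamp_for_report, compute_ecap,
                           compute_fields, compute_osi, compute_rrt,
                           compute_tawss, extract_cycle, mean_wss_vector)
from aawss.waveform import make_waveform
from conftest import series_from_signal

# closed-form cycle averages for the 0.5 + sin(2*pi*t) carrier
TAWSS_CARRIER = (np.pi + 2 * (np.sqrt(3) - np.pi / 3)) / (2 * np.pi)  # 0.71800
OSI_CARRIER = 0.5 * (1 - 0.5 / TAWSS_CARRIER)                        # 0.15181


class TestExtractCycle:
    def test_third_cycle_of_three_spans_2_to_3_seconds(self, tiny_mesh):
        t = np.arange(300) * 0.01
        s = series_from_signal(tiny_mesh, t, np.sin(2 * np.pi * t))
        cyc = extract_cycle(s, CycleSpec(cycle_index=3))
        assert len(cyc.times) == 101
        assert cyc.times[0] == pytest.approx(2.0)
        assert cyc.times[-1] == pytest.approx(3.0)
        # periodic closure: final sample equals the cycle-start sample
        assert np.array_equal(cyc.tau[-1], cyc.tau[0])

    def test_single_cycle_identity(self, tiny_mesh, closed_cycle_times):
        t = closed_cycle_times
        s = series_from_signal(tiny_mesh, t, np.cos(2 * np.pi * t))
        cyc = extract_cycle(s, CycleSpec(cycle_index=1))
        assert np.array_equal(cyc.tau, s.tau)

    def test_cycle_beyond_series_rejected(self, tiny_mesh):
        t = np.arange(300) * 0.01
        s = series_from_signal(tiny_mesh, t, np.ones_like(t))
        with pytest.raises(ValueError, match="cycle 4"):
            extract_cycle(s, CycleSpec(cycle_index=4))


class TestAnalyticSignals:
    def test_constant_vector_tawss_osi_rrt(self, tiny_mesh, closed_cycle_times):
        t = closed_cycle_times
        s = series_from_signal(tiny_mesh, t, np.full_like(t, 0.3))
        tawss = compute_tawss(s)
        osi, undef = compute_osi(s, tawss)
        rrt, inf_rrt = compute_rrt(s, tawss, osi)
        assert tawss == pytest.approx(0.3, rel=1e-12)
        assert osi == pytest.approx(0.0, abs=1e-12)
        assert not undef.any()
        assert rrt == pytest.approx(1 / 0.3, rel=1e-12)
        assert not inf_rrt.any()

    def test_zero_mean_sinusoid_tawss_two_over_pi(self, tiny_mesh,
                                                  closed_cycle_times):
        t = closed_cycle_times
        s = series_from_signal(tiny_mesh, t, np.sin(2 * np.pi * t))
        assert compute_tawss(s) == pytest.approx(2 / np.pi, abs=1e-3)

    def test_zero_mean_sinusoid_osi_half_rrt_infinite(self, tiny_mesh,
                                                      closed_cycle_times):
        t = closed_cycle_times
        s = series_from_signal(tiny_mesh, t, np.sin(2 * np.pi * t))
        tawss = compute_tawss(s)
        osi, _ = compute_osi(s, tawss)
        assert osi == pytest.approx(0.5, abs=1e-6)
        rrt, inf_rrt = compute_rrt(s, tawss, osi)
        assert inf_rrt.all()
        assert np.isinf(rrt).all()

    def test_offset_sinusoid_reproduces_closed_form_quadruple(
            self, tiny_mesh, closed_cycle_times):
        """tau_x = 0.5 + sin(2*pi*t): TAWSS 0.71800 Pa, OSI 0.15181,
        ECAP 0.21143 1/Pa, RRT 2.0."""
        t = closed_cycle_times
        s = series_from_signal(tiny_mesh, t, 0.5 + np.sin(2 * np.pi * t))
        tawss = compute_tawss(s)
        osi, _ = compute_osi(s, tawss)
        ecap, _ = compute_ecap(tawss, osi)
        rrt, _ = compute_rrt(s, tawss, osi)
        assert tawss == pytest.approx(TAWSS_CARRIER, abs=1e-3)
        assert osi == pytest.approx(OSI_CARRIER, abs=1e-3)
        assert ecap == pytest.approx(OSI_CARRIER / TAWSS_CARRIER, abs=2e-3)
        assert rrt == pytest.approx(2.0, abs=1e-3)

    def test_trapezoid_error_halves_quadratically(self, tiny_mesh):
        errs = []
        for dt in (0.01, 0.005):
            t = np.arange(0, 1 + dt / 2, dt)
            s = series_from_signal(tiny_mesh, t, np.sin(2 * np.pi * t))
            errs.append(abs(compute_tawss(s)[0] - 2 / np.pi))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)


class TestDegenerateNodes:
    def test_zero_shear_node_flagged_undefined(self, tiny_mesh,
                                               closed_cycle_times):
        t = closed_cycle_times
        s = series_from_signal(tiny_mesh, t, np.zeros_like(t))
        tawss = compute_tawss(s)
        osi, undef = compute_osi(s, tawss)
        assert undef.all()
        assert (osi == 0).all()
        ecap, undef_e = compute_ecap(tawss, osi)
        assert undef_e.all()

    def test_ecap_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            compute_ecap(np.ones(3), np.ones(4))

    def test_clamp_for_report_caps_display_only(self, tiny_mesh,
                                                closed_cycle_times):
        t = closed_cycle_times
        s = series_from_signal(tiny_mesh, t, np.full_like(t, 0.025))
        fields = compute_fields(
            series_from_signal(tiny_mesh, t, np.full_like(t, 0.025)),
            CycleSpec(cycle_index=1))
        assert fields.rrt[0] == pytest.approx(40.0)
        disp = clamp_for_report(fields)
        assert disp.rrt[0] == 30.0
        assert fields.rrt[0] == pytest.approx(40.0)  # raw untouched
        assert disp.tawss[0] == fields.tawss[0]  # in-range values unchanged

    def test_clamp_handles_infinite_rrt(self, tiny_mesh, closed_cycle_times):
        t = closed_cycle_times
        fields = compute_fields(
            series_from_signal(tiny_mesh, t, np.sin(2 * np.pi * t)),
            CycleSpec(cycle_index=1))
        disp = clamp_for_report(fields)
        assert (disp.rrt == 30.0).all()
        assert disp.infinite_rrt.all()


@settings(deadline=None, derandomize=True, max_examples=25)
@given(coeffs=st.lists(st.tuples(st.floats(-2, 2), st.floats(-2, 2),
                                 st.integers(1, 4)),
                       min_size=1, max_size=3),
       offset=st.tuples(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)))
def test_osi_bounds_and_mean_vector_identity(coeffs, offset):
    """For arbitrary harmonic WSS signals: 0 <= OSI <= 0.5, and
    (1 - 2*OSI)*TAWSS equals the cycle-mean vector magnitude (the identity
    tying the two RRT forms together)."""
    from aawss.mesh import cylinder_profile, make_vessel_mesh
    mesh = make_vessel_mesh(cylinder_profile(0.01), 0.1, 8, 8)
    t = np.linspace(0, 1, 101)
    tau = np.zeros((101, mesh.n_nodes, 3))
    for k, (a, b, m) in enumerate(coeffs):
        tau[:, :, k % 3] += (a * np.sin(2 * np.pi * m * t)
                             + b * np.cos(2 * np.pi * m * t))[:, None]
    tau += np.asarray(offset)[None, None, :]
    from aawss.metrics import WssSeries
    s = WssSeries(mesh=mesh, times=t, tau=tau)
    tawss = compute_tawss(s)
    osi, undef = compute_osi(s, tawss)
    assert np.all(osi >= 0) and np.all(osi <= 0.5)
    mean_mag = np.linalg.norm(mean_wss_vector(s), axis=1)
    ok = tawss > 1e-12
    np.testing.assert_allclose(((1 - 2 * osi) * tawss)[ok], mean_mag[ok],
                               rtol=1e-9, atol=1e-12)
    # compute_rrt's internal Eq-16/Eq-17 cross-check must accept the result
    compute_rrt(s, tawss, osi)
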