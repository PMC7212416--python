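"""The continuous affinity-competition switch and its coupling to the core."""

import math

import numpy as np
import pytest

from tcellnet.hybrid import (
    HybridConfigError,
    HybridSpec,
    discretize,
    hybrid_simulate,
    integrate_logistic,
    logistic_rhs,
    logistic_value,
)
from tcellnet.network import parse_rules

MARKERS = ("IL2G", "AP1", "NFAT", "NFKB")


class TestLogistic:
    def test_half_decay_is_exactly_half(self):
        for spec in (HybridSpec(), HybridSpec(beta=3, t_d=4.5), HybridSpec(beta=500)):
            assert logistic_value(spec.t_d, spec) == pytest.approx(0.5, abs=1e-15)

    def test_sigmoid_limits_and_overflow_safety(self):
        spec = HybridSpec(beta=50, t_d=10)
        assert logistic_value(-1e6, spec) == 1.0
        assert logistic_value(1e6, spec) == 0.0
        assert logistic_value(9, spec) == pytest.approx(1.0, abs=1e-15)

    def test_strictly_decreasing(self):
        spec = HybridSpec(beta=2, t_d=5)
        ts = np.linspace(-5, 15, 200)
        vs = [logistic_value(t, spec) for t in ts]
        assert all(a > b for a, b in zip(vs, vs[1:]))

    def test_rhs_values(self):
        spec = HybridSpec(beta=50)
        assert logistic_rhs(0.0, spec) == 0.0
        assert logistic_rhs(1.0, spec) == 0.0
        assert logistic_rhs(0.5, spec) == -12.5
        assert logistic_rhs(0.5, spec, printed_sign=True) == 12.5
        with pytest.raises(ValueError):
            logistic_rhs(1.5, spec)

    @pytest.mark.parametrize(
        "beta,t_d,t0,t_max",
        [
            (2, 10, 0.0, 20.0),   # full sigmoid at a moderate rate
            (50, 10, 10.0, 5.0),  # steep tail, starting from c(t_d) = 1/2
        ],
    )
    def test_rk4_matches_closed_form(self, beta, t_d, t0, t_max):
        """Integrating the decaying ODE reproduces the closed-form sigmoid to
        1e-6 (started where c0 is exactly representable: near c = 1 the
        unstable direction amplifies the float truncation of 1 - epsilon
        beyond any integrator's control, so the steep case starts at the
        half-decay point)."""
        spec = HybridSpec(beta=beta, t_d=t_d)
        c0 = logistic_value(t0, spec)
        ts, cs = integrate_logistic(c0, spec, t_max=t_max, dt=1e-4)
        exact = np.array([logistic_value(t0 + t, spec) for t in ts])
        assert np.max(np.abs(cs - exact)) < 1e-6

    def test_step_like_at_large_rate(self):
        """At beta >> 1 the discretized integer-grid trace is the indicator
        t < t_d (a non-integer t_d avoids the tie at the half-decay point)."""
        spec = HybridSpec(beta=500, t_d=9.5)
        for t in range(21):
            assert discretize(logistic_value(t, spec), spec.theta) == int(t < spec.t_d)

    def test_continuous_trace_is_steplike_at_default_rate(self):
        spec = HybridSpec(beta=50, t_d=10)
        for t in range(26):
            c = logistic_value(t, spec)
            if 0.01 < c < 0.99:
                assert abs(t - spec.t_d) <= 0.2


class TestDiscretize:
    def test_tie_goes_to_one(self):
        assert discretize(0.5, 0.5) == 1

    def test_below_threshold(self):
        assert discretize(0.4999, 0.5) == 0

    def test_saturated(self):
        assert discretize(1.0, 0.99) == 1


class TestSpecValidation:
    @pytest.mark.parametrize("kw", [{"beta": 0}, {"beta": -1}, {"theta": 0},
                                    {"theta": 1}, {"t_d": -1}])
    def test_invalid_parameters(self, kw):
        with pytest.raises(HybridConfigError):
            HybridSpec(**kw)

    def test_missing_hybrid_node(self):
        net = parse_rules("A <- A")
        with pytest.raises(HybridConfigError):
            hybrid_simulate(net, {"A": 0})


class TestHybridRun:
    def _run(self, core, spec=None, ampk=0, **kw):
        init = {n: 0 for n in core.names}
        init.update(TCR=1, CD8086=1, AMPK=ampk)
        return hybrid_simulate(core, init, spec=spec, **kw)

    def test_checkpoint_shutdown_shape(self, core):
        """Full activation before the affinity switch, then monotone loss:
        no activation marker reactivates after the switch, and the run ends
        in the arrest state with everything off."""
        traj, trace, t_ac = self._run(core)
        assert traj.converged
        assert t_ac is not None and t_ac <= 10
        switch = next(t for t, d in zip(trace.times, trace.cd8086_discrete) if d == 0)
        seen_off = {m: False for m in MARKERS}
        for t, state in enumerate(traj.states):
            for m in MARKERS:
                if t >= switch and not state[m]:
                    seen_off[m] = True
                if seen_off[m]:
                    assert not state[m], f"{m} reactivated after the switch"
        final = traj.final
        assert all(final[m] == 0 for m in MARKERS)
        assert final["TCR"] == 0 and final["CD28"] == 0

    def test_anticorrelation_identity(self, core):
        _, trace, _ = self._run(core)
        for c, g in zip(trace.cd8086_continuous, trace.ctla4dim_strength):
            assert c + g == pytest.approx(1.0, abs=1e-12)
        for c, d in zip(trace.cd8086_continuous, trace.cd8086_discrete):
            assert d == (1 if c >= 0.5 else 0)

    def test_decay_disabled_equals_clamped_run(self, core):
        """With the half-decay time at infinity the hybrid run is the plain
        synchronous trajectory with the ligand clamped on."""
        from tcellnet.network import simulate

        spec = HybridSpec(beta=50, t_d=math.inf)
        traj, trace, _ = self._run(core, spec=spec)
        init = {n: 0 for n in core.names}
        init.update(TCR=1, CD8086=1)
        plain = simulate(core, init)
        assert traj.converged and plain.converged
        assert traj.final == plain.final
        assert set(trace.cd8086_discrete) == {1}

    def test_warns_when_decay_precedes_activation(self, core):
        """t_d just below the measured activation-completion time: activation
        still completes (the marker layer lags the switch by one step), so
        the t_d >= t_ac constraint check fires."""
        with pytest.warns(UserWarning, match="t_ac"):
            self._run(core, spec=HybridSpec(beta=50, t_d=7.5))

    def test_ctla4_gate_never_fires_when_ligand_holds(self, core):
        """In ctla4-gated mode the clock waits for CTLA-4 dimers; the bundled
        rules keep dimers off while the ligand is bound, so the run settles in
        the activation state."""
        traj, trace, t_ac = self._run(core, gate="ctla4")
        assert traj.converged
        assert all(d == 1 for d in trace.cd8086_discrete)
        assert all(traj.final[m] == 1 for m in MARKERS)
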