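"""Single-neuron dynamics against closed forms and fine-step reference
integrations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thalcort.model import (
    CorticalParams,
    CorticalPopulationState,
    ThalamicParams,
    ThalamicPopulationState,
    decay_conductance,
    step_cortical,
    step_thalamic,
    t_current,
    update_h,
)


# --- T current --------------------------------------------------------------


class TestTCurrent:
    def test_zero_when_deinactivated(self, sp_params):
        assert t_current(-65.0, 0.0, sp_params) == 0.0

    def test_zero_below_switch_threshold(self, sp_params):
        assert t_current(-70.0, 1.0, sp_params) == 0.0

    def test_direct_evaluation(self, sp_params):
        # g_T * m * h * (V - E_T) = 0.07 * 0.5 * (-60 - 120)
        val = t_current(-60.0, 0.5, sp_params)
        assert val == pytest.approx(-6.3)
        # inserted with a minus sign in dV/dt, this depolarizes
        assert -val > 0

    def test_rejects_bad_input(self, sp_params):
        with pytest.raises(ValueError):
            t_current(np.nan, 0.5, sp_params)
        with pytest.raises(ValueError):
            t_current(-60.0, 1.5, sp_params)

    def test_piecewise_zero_property(self, sp_params):
        rng = np.random.default_rng(0)
        V = rng.uniform(-90, -30, 200)
        h = rng.uniform(0, 1, 200)
        out = np.asarray(t_current(V, h, sp_params))
        off = (V < sp_params.V_h) | (h == 0)
        assert np.all(out[off] == 0.0)


# --- h dynamics -------------------------------------------------------------


class TestUpdateH:
    def test_recovery_matches_closed_form(self, sp_params):
        # one recovery time constant: h -> 1 - e^-1
        h = 0.0
        for _ in range(100):
            h = update_h(h, -80.0, 1.0, sp_params)
        assert h == pytest.approx(1.0 - np.exp(-1.0), rel=0.01)

    def test_decay_matches_closed_form(self, sp_params):
        h = 1.0
        for _ in range(20):
            h = update_h(h, -50.0, 1.0, sp_params)
        assert h == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_absorbing_at_zero_when_depolarized(self, sp_params):
        assert update_h(0.0, -50.0, 1.0, sp_params) == 0.0

    def test_rejects_nonpositive_dt(self, sp_params):
        with pytest.raises(ValueError):
            update_h(0.5, -65.0, 0.0, sp_params)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(voltages=st.lists(st.floats(-120, 0), min_size=1, max_size=100),
           h0=st.floats(0.0, 1.0))
    def test_h_stays_in_unit_interval(self, sp_params, voltages, h0):
        h = h0
        for v in voltages:
            h = update_h(h, v, 1.0, sp_params)
            assert 0.0 <= float(h) <= 1.0


# --- synaptic decay ---------------------------------------------------------


class TestDecayConductance:
    def test_exponential_decay(self):
        g = 1.0
        for _ in range(10):
            g = decay_conductance(g, tau_s=10.0, gain=1.0, weighted_spike_sum=0.0, dt=1.0)
        assert g == pytest.approx(np.exp(-1.0), rel=0.01)

    def test_single_spike_increment(self):
        # one presynaptic spike through the relay->reticular weight
        g = decay_conductance(0.0, tau_s=10.0, gain=1.0, weighted_spike_sum=0.018, dt=1.0)
        assert g == pytest.approx(0.018)

    def test_zero_stays_zero(self):
        assert decay_conductance(0.0, 10.0, 1.0, 0.0, 1.0) == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            decay_conductance(0.0, 10.0, 1.0, -0.5, 1.0)


# --- thalamic population step ----------------------------------------------


def _resting_state(n, params, V=None, h=None):
    st_ = ThalamicPopulationState.resting(n, params)
    if V is not None:
        st_.V[:] = V
    if h is not None:
        st_.h[:] = h
    return st_


class TestStepThalamic:
    def test_leak_equilibrium(self, sp_params):
        state = _resting_state(5, sp_params)
        new, spikes = step_thalamic(state, sp_params)
        assert np.allclose(new.V, sp_params.V_L)
        assert not spikes.any()

    def test_spike_and_reset(self, sp_params):
        state = _resting_state(1, sp_params, V=-34.0)
        state.g_E[:] = 10.0  # strong drive keeps V above threshold
        new, spikes = step_thalamic(state, sp_params)
        assert spikes.all()
        assert np.allclose(new.V, sp_params.V_reset)

    def test_monotone_relaxation_to_leak(self):
        # with the T current removed (g_T = 0) and no synaptic input, V must
        # relax monotonically to the leak reversal from either side
        sp_params = ThalamicParams(g_T=0.0)
        for v0 in (-90.0, -40.0):
            state = _resting_state(1, sp_params, V=v0, h=0.0)
            prev_gap = abs(v0 - sp_params.V_L)
            for _ in range(400):
                state, _ = step_thalamic(state, sp_params)
                gap = abs(float(state.V[0]) - sp_params.V_L)
                assert gap <= prev_gap + 1e-12
                prev_gap = gap
            assert prev_gap < 0.5

    def test_rebound_burst_matches_reference(self, sp_params):
        """Release from 200 ms hyperpolarization triggers an LTS burst whose
        spike count agrees with a 0.01 ms reference integration within 1.

        The coarse path goes through the population stepper; the reference
        is an independent scalar integration of the same equations.
        """

        def simulate_module(params):
            state = _resting_state(1, params)
            spike_times = []
            for t in range(500):
                state.g_I[:] = 0.2 if t < 200 else 0.0
                state, spikes = step_thalamic(state, params, dt=1.0)
                if spikes[0]:
                    spike_times.append(t)
            isis = np.diff(spike_times)
            return len(spike_times), isis

        def simulate(dt):
            V, h, n_spikes = sp_params.V_L, 0.0, 0
            g_I = 0.2
            isis, last = [], None
            t, t_end = 0.0, 500.0
            while t < t_end:
                release = t >= 200.0
                gI = 0.0 if release else g_I
                m = 1.0 if V > sp_params.V_h else 0.0
                I_T = sp_params.g_T * m * h * (V - sp_params.E_T)
                dV = (
                    -sp_params.g_L * (V - sp_params.V_L)
                    - gI * (V - sp_params.V_I)
                    - I_T
                ) * (dt / sp_params.C)
                V_new = V + dV
                if V > sp_params.V_h:
                    h = h * np.exp(-dt / sp_params.tau_h_minus)
                else:
                    h = 1.0 - (1.0 - h) * np.exp(-dt / sp_params.tau_h_plus)
                if V_new >= sp_params.V_0:
                    V_new = sp_params.V_reset
                    n_spikes += 1
                    if last is not None:
                        isis.append(t - last)
                    last = t
                V = V_new
                t += dt
            return n_spikes, isis

        n_euler, isis = simulate_module(sp_params)
        n_ref, _ = simulate(0.01)
        assert n_euler >= 2
        assert all(isi < 20.0 for isi in isis)
        assert abs(n_euler - n_ref) <= 1


# --- cortical cells ---------------------------------------------------------


def _single_rs(I=0.0):
    params = CorticalParams.build(1, 0, rng=np.random.default_rng(0))
    params.r[:] = 0.0
    params.c[:] = -65.0
    params.d[:] = 8.0
    params.I_intrinsic[:] = I
    return params


class TestStepCortical:
    def test_quadratic_fixed_points(self):
        """At I = 0 the membrane equation (with u at its nullcline value for
        b = 0.2) has a stable rest at -70 mV and a threshold at -50 mV."""
        roots = np.sort(np.roots([0.04, 5 - 0.2, 140]))
        assert roots == pytest.approx([-70.0, -50.0])

        params = _single_rs(I=0.0)
        state = CorticalPopulationState.resting(params)
        state.v[:] = -70.0
        state.u[:] = 0.2 * -70.0
        for _ in range(1000):
            state, spikes = step_cortical(state, params)
            assert not spikes.any()
        assert abs(float(state.v[0]) + 70.0) < 0.5

    def test_spike_reset_rule(self):
        params = _single_rs()
        state = CorticalPopulationState.resting(params)
        state.v[:] = 30.1
        u0 = float(state.u[0])
        state, spikes = step_cortical(state, params)
        assert spikes.all()
        assert float(state.v[0]) == -65.0
        assert float(state.u[0]) == pytest.approx(u0 + 8.0, abs=1.5)  # u also advances dt*a(bv-u)

    def test_repetitive_spiking_matches_reference(self):
        """A regular-spiking cell at the published excitatory intrinsic drive
        (I = 6.7) fires repetitively; the 1 ms two-half-step scheme agrees
        with an independent 0.01 ms reference on the 1 s spike count within
        10%."""
        params = _single_rs(I=6.7)
        state = CorticalPopulationState.resting(params)
        n_euler = 0
        for _ in range(1000):
            state, spikes = step_cortical(state, params)
            n_euler += int(spikes[0])

        def reference(dt=0.01, T=1000.0):
            v, u, n = -65.0, -13.0, 0
            for _ in range(int(round(T / dt))):
                for _ in range(2):
                    v = min(v + 0.5 * dt * (0.04 * v * v + 5 * v + 140 - u + 6.7), 30.0)
                u += dt * 0.02 * (0.2 * v - u)
                if v >= 30.0:
                    v, u, n = -65.0, u + 8.0, n + 1
            return n

        n_ref = reference()
        assert n_euler > 0
        assert abs(n_euler - n_ref) <= max(0.1 * n_ref, 1.0)

    def test_zero_input_rest_is_stable(self):
        params = _single_rs(I=0.0)
        state = CorticalPopulationState.resting(params)
        state.v[:] = -70.0
        state.u[:] = -14.0
        for _ in range(2000):
            state, spikes = step_cortical(state, params)
        assert abs(float(state.v[0]) + 70.0) < 0.5
        assert not spikes.any()

    def test_heterogeneity_layout(self):
        rng = np.random.default_rng(3)
        p = CorticalParams.build(800, 200, rng=rng)
        r_e, r_i = p.r[:800], p.r[800:]
        assert np.allclose(p.c[:800], -65 + 15 * r_e**2)
        assert np.allclose(p.d[:800], 8 - 6 * r_e**2)
        assert np.allclose(p.a[800:], 0.02 + 0.08 * r_i)
        assert np.allclose(p.b[800:], 0.25 - 0.05 * r_i)
        assert p.n == 1000
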