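"""Single-timestep dynamics of the two cell classes in the network.

Thalamic relay/reticular neurons follow the integrate-and-fire-or-burst
(IFB) scheme: a conductance-based leaky integrate-and-fire cell augmented
with a slow de-inactivation variable ``h`` gating a low-threshold T-type
calcium current.  Under sustained hyperpolarisation below the switch
threshold ``V_h``, ``h`` recovers toward 1; upon release the calcium current
produces a low-threshold spike crowned by a burst of fast spikes.

Cortical cells are quadratic integrate-and-fire neurons with a recovery
variable (regular-spiking parameters for the excitatory 80%, fast-spiking
for the inhibitory 20%, with per-neuron uniform(0,1) heterogeneity ``r``).

Membrane equations are integrated by forward Euler at 1 ms (cortical ``v``
uses two 0.5 ms half-steps, standard for the quadratic model's stiffness).
The linear subsystems — the h-dynamics and the synaptic decays — use the
exact exponential update, which is unconditionally stable and accurate at
the 1 ms step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ThalamicParams",
    "ThalamicPopulationState",
    "CorticalParams",
    "CorticalPopulationState",
    "t_current",
    "update_h",
    "decay_conductance",
    "step_thalamic",
    "step_cortical",
]


@dataclass(frozen=True)
class ThalamicParams:
    """IFB parameters for one thalamic nucleus (arrays broadcast per neuron).

    ``V_h`` is the T-channel activation/inactivation switch threshold (−66 mV
    for SP/NSP, −64 mV for TRN) used both by the Heaviside activation
    ``m_inf`` and by the branch condition of the h-dynamics.  ``E_T`` is the
    calcium driving reversal (+120 mV), well above threshold, so the T
    current is depolarizing whenever it is active.
    """

    C: float = 2.0            # membrane capacitance, uF/cm^2
    g_L: float = 0.035        # leak conductance, mS/cm^2
    V_L: float = -65.0        # leak reversal, mV
    g_T: float = 0.07         # T-channel conductance, mS/cm^2
    V_h: float | np.ndarray = -66.0   # activation/inactivation switch, mV
    E_T: float | np.ndarray = 120.0   # calcium driving reversal, mV
    V_0: float = -35.0        # spike threshold, mV
    V_reset: float = -50.0    # post-spike reset, mV
    V_E: float = 0.0          # excitatory synaptic reversal, mV
    V_I: float = -85.0        # inhibitory synaptic reversal, mV
    tau_h_minus: float | np.ndarray = 20.0  # h decay (depolarised), ms
    tau_h_plus: float | np.ndarray = 100.0  # h recovery (hyperpolarised), ms
    k_E: float = 1.0          # excitatory synaptic gain
    k_I: float = 0.1          # inhibitory synaptic gain

    def __post_init__(self) -> None:
        if self.g_L < 0 or self.g_T < 0:
            raise ValueError("conductances must be non-negative")
        if self.V_reset >= self.V_0:
            raise ValueError("V_reset must lie below the spike threshold V_0")
        if np.any(np.asarray(self.tau_h_minus) <= 0) or np.any(
            np.asarray(self.tau_h_plus) <= 0
        ):
            raise ValueError("h time constants must be positive")
        if not (self.V_I < self.V_L < self.V_E):
            raise ValueError("require V_I < V_L < V_E")


@dataclass
class ThalamicPopulationState:
    """Per-neuron state of one thalamic nucleus."""

    V: np.ndarray            # membrane potential, mV
    h: np.ndarray            # T-channel de-inactivation, in [0, 1]
    g_E: np.ndarray          # summed excitatory conductance, mS
    g_I: np.ndarray          # summed inhibitory conductance, mS
    spike_flags: np.ndarray  # bool, spikes emitted this step

    @classmethod
    def resting(cls, n: int, params: ThalamicParams) -> "ThalamicPopulationState":
        return cls(
            V=np.full(n, params.V_L),
            h=np.zeros(n),
            g_E=np.zeros(n),
            g_I=np.zeros(n),
            spike_flags=np.zeros(n, dtype=bool),
        )

    def validate(self) -> None:
        n = self.V.shape[0]
        for name in ("h", "g_E", "g_I", "spike_flags"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.h < 0) or np.any(self.h > 1):
            raise ValueError("h out of [0, 1]")
        if np.any(self.g_E < 0) or np.any(self.g_I < 0):
            raise ValueError("negative synaptic conductance")


@dataclass
class CorticalParams:
    """Quadratic integrate-and-fire parameters, per neuron.

    Excitatory (regular-spiking) cells: a=0.02, b=0.2, c=−65+15r²,
    d=8−6r².  Inhibitory (fast-spiking) cells: a=0.02+0.08r, b=0.25−0.05r,
    c=−65, d=2.  Intrinsic drives I_E=6.7 and I_I=2.7 place the excitatory
    population in a slow repetitive-firing regime whose population rhythm
    sits in the alpha range.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    I_intrinsic: np.ndarray
    r: np.ndarray
    n_exc: int
    spike_cutoff: float = 30.0

    I_E: float = 6.7
    I_I: float = 2.7

    @classmethod
    def build(
        cls,
        n_exc: int = 800,
        n_inh: int = 200,
        rng: np.random.Generator | None = None,
        I_E: float = 6.7,
        I_I: float = 2.7,
    ) -> "CorticalParams":
        rng = np.random.default_rng() if rng is None else rng
        r = rng.random(n_exc + n_inh)
        re, ri = r[:n_exc], r[n_exc:]
        a = np.concatenate([np.full(n_exc, 0.02), 0.02 + 0.08 * ri])
        b = np.concatenate([np.full(n_exc, 0.2), 0.25 - 0.05 * ri])
        c = np.concatenate([-65.0 + 15.0 * re**2, np.full(n_inh, -65.0)])
        d = np.concatenate([8.0 - 6.0 * re**2, np.full(n_inh, 2.0)])
        I = np.concatenate([np.full(n_exc, I_E), np.full(n_inh, I_I)])
        return cls(a=a, b=b, c=c, d=d, I_intrinsic=I, r=r, n_exc=n_exc, I_E=I_E, I_I=I_I)

    @property
    def n(self) -> int:
        return self.a.shape[0]


@dataclass
class CorticalPopulationState:
    """Per-neuron state of the cortical sheet (excitatory block first)."""

    v: np.ndarray                # membrane potential, mV
    u: np.ndarray                # recovery variable
    I_syn_decaying: np.ndarray   # decaying current from thalamic afferents
    I_pulse: np.ndarray          # instantaneous cortico-cortical input, cleared each step
    spike_flags: np.ndarray

    @classmethod
    def resting(cls, params: CorticalParams) -> "CorticalPopulationState":
        v = np.full(params.n, -65.0)
        return cls(
            v=v,
            u=params.b * v,
            I_syn_decaying=np.zeros(params.n),
            I_pulse=np.zeros(params.n),
            spike_flags=np.zeros(params.n, dtype=bool),
        )


def t_current(V, h, params: ThalamicParams):
    """Low-threshold T-type calcium current.

    ``I_T = g_T · m_inf(V) · h · (V − E_T)`` with ``m_inf`` a Heaviside step
    at ``V_h``.  The term enters the membrane equation with a minus sign, so
    for V < E_T (always, physiologically) an active current depolarizes.
    Identically zero when ``h = 0`` or ``V < V_h``.
    """
    V = np.asarray(V, dtype=float)
    h = np.asarray(h, dtype=float)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(h))):
        raise ValueError("non-finite membrane potential or h")
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("h out of [0, 1]")
    m_inf = (V > np.asarray(params.V_h)).astype(float)
    return params.g_T * m_inf * h * (V - params.E_T)


def update_h(h, V, dt: float, params: ThalamicParams):
    """Advance the T-channel de-inactivation variable by ``dt``.

    Two linear branches: above ``V_h`` h decays to 0 with ``tau_h_minus``;
    below, it recovers to 1 with ``tau_h_plus``.  Each branch is advanced
    with its exact exponential solution and the result clamped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    h = np.asarray(h, dtype=float)
    V = np.asarray(V, dtype=float)
    depol = V > np.asarray(params.V_h)
    decay = h * np.exp(-dt / np.asarray(params.tau_h_minus, dtype=float))
    recover = 1.0 - (1.0 - h) * np.exp(-dt / np.asarray(params.tau_h_plus, dtype=float))
    return np.clip(np.where(depol, decay, recover), 0.0, 1.0)


def decay_conductance(g, tau_s: float, gain: float, weighted_spike_sum, dt: float):
    """One synaptic-conductance step: exponential decay plus spike increment.

    ``g' = g·exp(−dt/τ_s) + gain · Σ_j W_ij s_j`` where the sum is over
    presynaptic spikes arriving this step (already delayed and weighted).
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = np.asarray(g, dtype=float)
    out = g * np.exp(-dt / tau_s) + gain * np.asarray(weighted_spike_sum, dtype=float)
    if np.any(out < 0):
        raise ValueError("negative conductance; check projection weights")
    return out


def step_thalamic(
    state: ThalamicPopulationState,
    params: ThalamicParams,
    dt: float = 1.0,
) -> tuple[ThalamicPopulationState, np.ndarray]:
    """Advance a thalamic population one step (synaptic conductances are
    updated externally by the network engine before this call).

    Membrane: C dV/dt = −g_L(V−V_L) − g_E(V−V_E) − g_I(V−V_I) − I_T.
    Spikes at V ≥ V_0 reset V to V_reset.  h follows its own two-branch
    dynamics evaluated at the pre-update V.
    """
    V, h = state.V, state.h
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite thalamic membrane potential")
    I_T = t_current(V, h, params)
    dV = (
        -params.g_L * (V - params.V_L)
        - state.g_E * (V - params.V_E)
        - state.g_I * (V - params.V_I)
        - I_T
    ) * (dt / params.C)
    V_new = V + dV
    spikes = V_new >= params.V_0
    V_new = np.where(spikes, params.V_reset, V_new)
    h_new = update_h(h, V, dt, params)
    new = ThalamicPopulationState(
        V=V_new, h=h_new, g_E=state.g_E, g_I=state.g_I, spike_flags=spikes
    )
    return new, spikes


def step_cortical(
    state: CorticalPopulationState,
    params: CorticalParams,
    dt: float = 1.0,
    I_extra: np.ndarray | float = 0.0,
) -> tuple[CorticalPopulationState, np.ndarray]:
    """Advance the cortical population one step.

    Total drive I = intrinsic + decaying thalamic afferent current +
    instantaneous cortico-cortical pulses + ``I_extra`` (e.g. the post-lesion
    GABA current).  ``v`` is advanced in two half-steps with the membrane
    clamped at the 30 mV peak (the quadratic diverges in finite time, so the
    peak is truncated as in the model's reference implementations); cells at
    the peak spike and reset v ← c, u ← u + d.  ``I_pulse`` is cleared on
    return.
    """
    v, u = state.v, state.u
    if not np.all(np.isfinite(v)):
        raise FloatingPointError("non-finite cortical membrane potential")
    I = params.I_intrinsic + state.I_syn_decaying + state.I_pulse + I_extra
    half = 0.5 * dt
    v = np.minimum(v + half * (0.04 * v**2 + 5.0 * v + 140.0 - u + I), params.spike_cutoff)
    v = np.minimum(v + half * (0.04 * v**2 + 5.0 * v + 140.0 - u + I), params.spike_cutoff)
    u = u + dt * params.a * (params.b * v - u)
    spikes = v >= params.spike_cutoff
    v = np.where(spikes, params.c, v)
    u = np.where(spikes, u + params.d, u)
    new = CorticalPopulationState(
        v=v,
        u=u,
        I_syn_decaying=state.I_syn_decaying,
        I_pulse=np.zeros_like(state.I_pulse),
        spike_flags=spikes,
    )
    return new, spikes
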