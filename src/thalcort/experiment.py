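"""The stroke-lesion simulation protocol and its analyses.

A run simulates the full thalamo-cortical module for 20 s of model time at a
1 ms step.  At t = 10 s a structural cortical lesion is applied by
deafferenting a contiguous block of 30% of the excitatory and inhibitory
cortical cells — every synapse to and from these neurons is removed, while
peripheral Poisson drives to the thalamus are untouched.  Population LFPs
(mean membrane potential over intact neurons) are recorded every step, and
spike rasters per population.

Cohort protocol: 40 runs with seeds base+i, each with freshly randomised
connectivity and cortical heterogeneity.  Runs whose pre-lesion cortical
dominant peak falls outside the healthy alpha range (8.3–11.9 Hz) are
omitted, mirroring the noise constraint applied against the control group's
EEG peak range.

An optional variant adds a tonic inhibitory current to all intact cortical
cells post-lesion with a slow linear onset, emulating the neuroprotective
rise of extrasynaptic GABA during ischaemia.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    CorticalParams,
    CorticalPopulationState,
    ThalamicParams,
    ThalamicPopulationState,
    step_cortical,
    step_thalamic,
)
from .network import NetworkTopology, RealizedProjection, build_network
from .spectral import PowerSpectrum, WaveletBank, dominant_peak, tf_power

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "IsiSummary",
    "CohortResult",
    "apply_lesion",
    "gaba_current",
    "run_simulation",
    "run_cohort",
    "lesion_sweep",
    "isi_statistics",
    "model_wavelet_bank",
]

#: Healthy pre-lesion peak bounds for the run-omission rule (Hz): the
#: control group's minimum and maximum dominant alpha frequencies.
OMISSION_BOUNDS = (8.3, 11.9)

#: Search window for cortical dominant peaks (Hz).
PEAK_WINDOW = (6.0, 13.0)

#: Search window for the thalamic low-frequency peak (Hz).
THAL_PEAK_WINDOW = (1.0, 13.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol parameters for one run (times in ms unless noted)."""

    duration: float = 20_000.0
    dt: float = 1.0
    lesion_time: float = 10_000.0
    lesion_fraction: float = 0.30
    lesion_anchor: int = 0           # start index of the excitatory lesion block
    gaba_enabled: bool = True
    gaba_amplitude: float | None = None  # plateau; None => gaba_per_fraction * lesion_fraction
    gaba_per_fraction: float = 5.0 / 3.0  # calibrated GABA current per unit lesion fraction
    gaba_ramp: float = 1000.0        # onset ramp duration, ms
    seed: int = 0
    n_runs: int = 40
    settle: float = 1000.0           # transient excluded from spectral windows
    record_rasters: bool = True
    crx_random_weights: bool = True  # per-edge U(0,1) scaling of cortico-cortical weights
    cortical_noise_sigma: float = 3.0  # Gaussian jitter on cortical drive, per step
    cortical_drive_exc: float = 4.1  # network-calibrated intrinsic drive, excitatory cells
    cortical_drive_inh: float = 2.7  # intrinsic drive, inhibitory cells
    record_thalamic_v: bool = False  # keep the full per-neuron thalamic V trace
    calcium_reversal: float = 120.0      # E_T of the thalamic T current, mV

    def __post_init__(self) -> None:
        if not 0.0 <= self.lesion_fraction < 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1)")
        if self.lesion_time >= self.duration:
            raise ValueError("lesion_time must precede the end of the run")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def gaba_plateau(self) -> float:
        """Plateau of the tonic inhibitory current: the explicit amplitude
        if given, otherwise scaled to the lesion extent."""
        if self.gaba_amplitude is not None:
            return self.gaba_amplitude
        return self.gaba_per_fraction * self.lesion_fraction

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def lesion_step(self) -> int:
        return int(round(self.lesion_time / self.dt))


@dataclass
class SimulationResult:
    """Rasters, LFPs and provenance of one run."""

    rasters: dict[str, tuple[np.ndarray, np.ndarray]]  # pop -> (times ms, neuron ids)
    lfp: dict[str, np.ndarray]                         # pop -> (n_steps,) mean V, mV
    lesion_mask: np.ndarray                            # per-CRX-neuron bool
    config: SimulationConfig
    seed: int
    provenance: dict = field(default_factory=dict)


@dataclass
class IsiSummary:
    """Inter-spike-interval statistics of one population within a window."""

    isis: dict[int, np.ndarray]          # neuron id -> consecutive ISIs, ms
    burst_fraction: float | None         # pooled share of ISIs < 20 ms; None if no ISIs
    neuron_class: dict[int, str]         # "burst" | "tonic" per neuron with >= 2 spikes
    window: tuple[float, float]

    def pooled(self) -> np.ndarray:
        if not self.isis:
            return np.empty(0)
        return np.concatenate(list(self.isis.values()))


BURST_ISI_MS = 20.0


def isi_statistics(
    raster: tuple[np.ndarray, np.ndarray],
    window: tuple[float, float],
) -> IsiSummary:
    """Per-neuron consecutive inter-spike intervals within ``window``.

    ``burst_fraction`` is the pooled share of ISIs below 20 ms (intra-burst
    spikes); a neuron is classed "burst" when the majority of its own ISIs
    fall below that bound.  An empty window yields ``burst_fraction=None``.
    """
    times, ids = raster
    lo, hi = window
    sel = (times >= lo) & (times < hi)
    times, ids = times[sel], ids[sel]
    isis: dict[int, np.ndarray] = {}
    classes: dict[int, str] = {}
    for nid in np.unique(ids):
        t = np.sort(times[ids == nid])
        if t.size < 2:
            continue
        d = np.diff(t)
        isis[int(nid)] = d
        classes[int(nid)] = "burst" if np.mean(d < BURST_ISI_MS) > 0.5 else "tonic"
    pooled = np.concatenate(list(isis.values())) if isis else np.empty(0)
    bf = float(np.mean(pooled < BURST_ISI_MS)) if pooled.size else None
    return IsiSummary(isis=isis, burst_fraction=bf, neuron_class=classes, window=window)


def apply_lesion(
    topology: NetworkTopology,
    fraction: float,
    anchor: int = 0,
) -> NetworkTopology:
    """Deafferent a contiguous block of cortical neurons.

    ``floor(fraction * 800)`` excitatory cells starting at ``anchor`` and the
    aligned block of ``floor(fraction * 200)`` inhibitory cells lose every
    afferent and efferent synapse.  Edges among intact neurons are preserved
    exactly; peripheral drives are untouched.  Returns a new topology whose
    ``lesion_mask`` (length n_E + n_I, excitatory block first) marks the
    lesioned cells.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    n_e, n_i = topology.populations["E"], topology.populations["I"]
    n_les_e = int(np.floor(fraction * n_e))
    n_les_i = int(np.floor(fraction * n_i))
    anchor_i = anchor * n_i // n_e  # aligned inhibitory block start
    if anchor + n_les_e > n_e or anchor_i + n_les_i > n_i:
        raise ValueError("lesion block exceeds the cortical population")

    mask = np.zeros(n_e + n_i, dtype=bool)
    mask[anchor : anchor + n_les_e] = True
    mask[n_e + anchor_i : n_e + anchor_i + n_les_i] = True

    def lesioned(pop: str, idx: np.ndarray) -> np.ndarray:
        if pop == "E":
            return mask[idx]
        if pop == "I":
            return mask[n_e + idx]
        if pop == "CRX":
            return mask[idx]
        return np.zeros(idx.shape, dtype=bool)

    new_projs = []
    for proj in topology.projections:
        drop = lesioned(proj.spec.source, proj.src) | lesioned(proj.spec.target, proj.tgt)
        keep = ~drop
        new_projs.append(RealizedProjection(proj.spec, proj.src[keep], proj.tgt[keep]))

    return NetworkTopology(
        populations=dict(topology.populations),
        projections=new_projs,
        drives=topology.drives,
        rng_seed=topology.rng_seed,
        lesion_mask=mask,
        provenance={**topology.provenance, "lesion_fraction": fraction, "lesion_anchor": anchor},
    )


def gaba_current(t: float, config: SimulationConfig) -> float:
    """Tonic inhibitory current (negative) at time ``t`` ms.

    Zero before the lesion; ramps linearly to ``-gaba_amplitude`` over
    ``gaba_ramp`` ms after the lesion, then stays constant.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    if not config.gaba_enabled or t < config.lesion_time:
        return 0.0
    frac = min((t - config.lesion_time) / config.gaba_ramp, 1.0)
    return -config.gaba_plateau * frac


# --- engine internals -------------------------------------------------------

_THAL_SLICES = {"SP": slice(0, 100), "NSP": slice(100, 200), "TRN": slice(200, 300)}


class _Synapse:
    """Per-projection conductance/current accumulator with its dense weights."""

    __slots__ = ("W", "g", "decay", "gain", "delay", "src", "tgt_slice", "kind")

    def __init__(self, proj: RealizedProjection, sizes: dict[str, int], k_E: float, k_I: float):
        spec = proj.spec
        self.src = spec.source
        n_s = _source_size(spec.source, sizes)
        n_t = sizes[spec.target]
        self.W = proj.weight_matrix(n_t, n_s)
        self.g = np.zeros(n_t)
        tau = spec.tau_s or np.inf
        self.decay = float(np.exp(-1.0 / tau))
        self.delay = max(proj.delay_steps, 1)  # zero-delay arrives next step
        if spec.target in _THAL_SLICES:
            self.kind = "thal_I" if spec.polarity == "inhibitory" else "thal_E"
            self.gain = k_I if spec.polarity == "inhibitory" else k_E
            self.tgt_slice = _THAL_SLICES[spec.target]
        else:  # current-based decaying drive onto cortical excitatory cells
            self.kind = "crx"
            self.gain = 1.0
            self.tgt_slice = None

    def step(self, delayed_spikes: np.ndarray) -> None:
        self.g *= self.decay
        idx = np.flatnonzero(delayed_spikes)
        if idx.size:
            self.g += self.gain * self.W[:, idx].sum(axis=1)

    def relesion(self, proj: RealizedProjection) -> None:
        n_t, n_s = self.W.shape
        self.W = proj.weight_matrix(n_t, n_s)


def _source_size(name: str, sizes: dict[str, int]) -> int:
    return sizes[name.removeprefix("INPUT_")] if name.startswith("INPUT_") else sizes[name]


def run_simulation(
    config: SimulationConfig,
    topology: NetworkTopology | None = None,
    seed: int | None = None,
    _step_hook=None,
) -> SimulationResult:
    """Run the full 20 s protocol once; deterministic given config and seed.

    ``topology`` defaults to a fresh build seeded identically to the run.
    The lesion is applied mid-run by swapping in the deafferented weight
    matrices from :func:`apply_lesion`; lesioned cortical cells lose their
    intrinsic drive as well and fall silent (they are disconnected from every
    observable either way).
    """
    seed = config.seed if seed is None else seed
    if topology is None:
        topology = build_network(seed=seed)
    rng = np.random.default_rng(seed)
    sizes = topology.populations
    n_e, n_i = sizes["E"], sizes["I"]
    n_crx = n_e + n_i
    n_thal = sizes["SP"] + sizes["NSP"] + sizes["TRN"]
    dt = config.dt
    n_steps = config.n_steps
    lesion_step = config.lesion_step

    # thalamic parameters: SP/NSP share V_h=-66, tau_h-=20; TRN uses -64/40
    V_h = np.concatenate([np.full(200, -66.0), np.full(100, -64.0)])
    tau_hm = np.concatenate([np.full(200, 20.0), np.full(100, 40.0)])
    th_params = ThalamicParams(V_h=V_h, tau_h_minus=tau_hm, E_T=config.calcium_reversal)
    th_state = ThalamicPopulationState.resting(n_thal, th_params)

    cx_params = CorticalParams.build(
        n_e, n_i, rng=rng, I_E=config.cortical_drive_exc, I_I=config.cortical_drive_inh
    )
    cx_state = CorticalPopulationState.resting(cx_params)
    I_intrinsic = cx_params.I_intrinsic.copy()

    lesioned_topo = apply_lesion(topology, config.lesion_fraction, config.lesion_anchor)
    lesion_mask = lesioned_topo.lesion_mask
    alive = ~lesion_mask

    # synapse bookkeeping; cortico-cortical all-to-all handled by pulse sums
    pre_syn, post_syn = {}, {}
    for pre_p, post_p in zip(topology.projections, lesioned_topo.projections):
        if pre_p.spec.pattern == "all_to_all":
            continue
        pre_syn[pre_p.spec.name] = _Synapse(pre_p, sizes, th_params.k_E, th_params.k_I)
        post_syn[post_p.spec.name] = post_p
    w_ee = topology.projection("E->E/I").spec.g_s
    w_ii = topology.projection("I->I/E").spec.g_s
    # cortico-cortical coupling: uniform weights admit an O(n) pulse sum;
    # per-edge random scaling (the default) needs the dense matrices
    if config.crx_random_weights:
        W_EC = w_ee * rng.random((n_crx, n_e))
        W_IC = w_ii * rng.random((n_crx, n_i))
        W_EC[np.arange(n_e), np.arange(n_e)] = 0.0
        W_IC[n_e + np.arange(n_i), np.arange(n_i)] = 0.0
        W_EC, W_IC = np.asfortranarray(W_EC), np.asfortranarray(W_IC)
    else:
        W_EC = W_IC = None
    noise_sigma = config.cortical_noise_sigma

    drive_specs = {d.target: d for d in topology.drives}
    # spike histories: index by step modulo buffer length
    L = max(max(p.delay_steps for p in topology.projections) + 1, 2)
    thal_hist = np.zeros((L, n_thal), dtype=bool)
    crx_hist = np.zeros((L, n_crx), dtype=bool)

    lfp = {p: np.empty(n_steps) for p in ("SP", "NSP", "TRN", "CRX")}
    v_trace = np.empty((n_steps, n_thal), dtype=np.float32) if config.record_thalamic_v else None
    rasters: dict[str, list[tuple[int, np.ndarray]]] = {p: [] for p in ("SP", "NSP", "TRN", "CRX")}
    crx_alive = np.ones(n_crx, dtype=bool)

    sp_sl, nsp_sl, trn_sl = (_THAL_SLICES[k] for k in ("SP", "NSP", "TRN"))
    gaba_on = config.gaba_enabled

    # per-line input weights from the Input->SP/NSP projection rows
    in_sp = pre_syn.pop("Input-SP->SP")
    in_nsp = pre_syn.pop("Input-NSP->NSP")
    w_in_sp = in_sp.W.diagonal().copy()
    w_in_nsp = in_nsp.W.diagonal().copy()
    cx_params_step = cx_params

    for t in range(n_steps):
        if t == lesion_step and config.lesion_fraction > 0:
            crx_alive = alive
            I_intrinsic = np.where(alive, cx_params.I_intrinsic, 0.0)
            cx_params_step = replace_intrinsic(cx_params, I_intrinsic)
            for name, syn in pre_syn.items():
                syn.relesion(post_syn[name])
            if W_EC is not None:
                W_EC[lesion_mask, :] = 0.0
                W_IC[lesion_mask, :] = 0.0
                W_EC[:, lesion_mask[:n_e]] = 0.0
                W_IC[:, lesion_mask[n_e:]] = 0.0

        # peripheral Poisson drives (fresh Bernoulli draws each step)
        sp_drive = rng.random(sizes["SP"]) < drive_specs["SP"].P
        nsp_drive = rng.random(sizes["NSP"]) < drive_specs["NSP"].P
        in_sp.g = in_sp.g * in_sp.decay + in_sp.gain * w_in_sp * sp_drive
        in_nsp.g = in_nsp.g * in_nsp.decay + in_nsp.gain * w_in_nsp * nsp_drive

        # synaptic updates from delayed presynaptic spikes
        for syn in pre_syn.values():
            row = (t - syn.delay) % L
            if syn.src in _THAL_SLICES:
                s = thal_hist[row, _THAL_SLICES[syn.src]]
            elif syn.src == "E":
                s = crx_hist[row, :n_e]
            else:
                s = crx_hist[row, n_e:]
            syn.step(s)

        # thalamic totals and step
        g_E = np.zeros(n_thal)
        g_I = np.zeros(n_thal)
        g_E[sp_sl] += in_sp.g
        g_E[nsp_sl] += in_nsp.g
        for syn in pre_syn.values():
            if syn.kind == "thal_E":
                g_E[syn.tgt_slice] += syn.g
            elif syn.kind == "thal_I":
                g_I[syn.tgt_slice] += syn.g
        th_state.g_E, th_state.g_I = g_E, g_I
        try:
            th_state, th_spikes = step_thalamic(th_state, th_params, dt)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"thalamic integration diverged at step {t} ({t * dt:.0f} ms)"
            ) from err

        # cortical input: decaying thalamic afferent currents, instantaneous
        # cortico-cortical pulses from last step's spikes, optional GABA
        I_syn = np.zeros(n_crx)
        for syn in pre_syn.values():
            if syn.kind == "crx":
                I_syn[:n_e] += syn.g
        prev = crx_hist[(t - 1) % L]
        e_spk = prev[:n_e]
        i_spk = prev[n_e:]
        if W_EC is not None:
            ei = np.flatnonzero(e_spk)
            ii = np.flatnonzero(i_spk)
            pulse = np.zeros(n_crx)
            if ei.size:
                pulse += W_EC[:, ei].sum(axis=1)
            if ii.size:
                pulse -= W_IC[:, ii].sum(axis=1)
        else:
            n_es, n_is = int(e_spk.sum()), int(i_spk.sum())
            pulse = np.full(n_crx, w_ee * n_es - w_ii * n_is)
            if n_es:
                pulse[:n_e][e_spk] -= w_ee
            if n_is:
                pulse[n_e:][i_spk] += w_ii
            if config.lesion_fraction > 0 and t >= lesion_step:
                pulse[lesion_mask] = 0.0
        I_extra = 0.0
        if noise_sigma:
            I_extra = noise_sigma * rng.standard_normal(n_crx)
        if gaba_on:
            g_now = gaba_current(t * dt, config)
            if g_now:
                I_extra = I_extra + np.where(crx_alive, g_now, 0.0)
        cx_state.I_syn_decaying = I_syn
        cx_state.I_pulse = pulse
        try:
            cx_state, cx_spikes = step_cortical(cx_state, cx_params_step, dt, I_extra=I_extra)
        except FloatingPointError as err:
            raise FloatingPointError(
                f"cortical integration diverged at step {t} ({t * dt:.0f} ms)"
            ) from err

        if _step_hook is not None:
            _step_hook(t, th_state, cx_state)

        row = t % L
        thal_hist[row] = th_spikes
        crx_hist[row] = cx_spikes & crx_alive

        # record
        V = th_state.V
        if v_trace is not None:
            v_trace[t] = V
        lfp["SP"][t] = V[sp_sl].mean()
        lfp["NSP"][t] = V[nsp_sl].mean()
        lfp["TRN"][t] = V[trn_sl].mean()
        lfp["CRX"][t] = np.minimum(cx_state.v[crx_alive], 30.0).mean()
        if config.record_rasters:
            for pop, sl, spk in (
                ("SP", sp_sl, th_spikes),
                ("NSP", nsp_sl, th_spikes),
                ("TRN", trn_sl, th_spikes),
            ):
                idx = np.flatnonzero(spk[sl])
                if idx.size:
                    rasters[pop].append((t, idx))
            idx = np.flatnonzero(cx_spikes & crx_alive)
            if idx.size:
                rasters["CRX"].append((t, idx))

    out_rasters = {}
    for pop, events in rasters.items():
        if events:
            times = np.concatenate([np.full(ix.size, step * dt) for step, ix in events])
            ids = np.concatenate([ix for _, ix in events])
        else:
            times, ids = np.empty(0), np.empty(0, dtype=int)
        out_rasters[pop] = (times, ids)

    return SimulationResult(
        rasters=out_rasters,
        lfp=lfp,
        lesion_mask=lesion_mask,
        config=config,
        seed=seed,
        provenance={
            "topology_seed": topology.rng_seed,
            "run_seed": seed,
            "thalamic_v": v_trace,
        },
    )


def replace_intrinsic(params: CorticalParams, I: np.ndarray) -> CorticalParams:
    if I is params.I_intrinsic:
        return params
    return CorticalParams(
        a=params.a, b=params.b, c=params.c, d=params.d,
        I_intrinsic=I, r=params.r, n_exc=params.n_exc,
        spike_cutoff=params.spike_cutoff, I_E=params.I_E, I_I=params.I_I,
    )


def model_wavelet_bank(fs: float = 1000.0) -> WaveletBank:
    """Default wavelet bank for model LFPs: log-spaced 1–80 Hz."""
    return WaveletBank.log_spaced(1.0, 80.0, fs=fs)


def window_spectrum(
    lfp: np.ndarray,
    window: tuple[float, float],
    bank: WaveletBank,
    dt: float = 1.0,
) -> PowerSpectrum:
    """Time-averaged wavelet spectrum of an LFP segment (window in ms)."""
    lo, hi = int(round(window[0] / dt)), int(round(window[1] / dt))
    return tf_power(lfp[lo:hi], bank).time_average()


@dataclass
class RunSummary:
    seed: int
    pre_peak: float
    post_peak: float
    retained: bool
    spectra: dict[str, PowerSpectrum]           # "{pop}_{pre|post}"
    burst_fractions: dict[str, float | None]    # "{pop}_{pre|post}"
    nsp_post_peak: float
    mean_nsp_v: dict[str, float]                # pre/post mean NSP potential
    median_isis: dict[str, float | None] = field(default_factory=dict)


@dataclass
class CohortResult:
    runs: list[RunSummary]
    config: SimulationConfig
    bank: WaveletBank

    @property
    def retained(self) -> list[RunSummary]:
        return [r for r in self.runs if r.retained]

    def omitted_seeds(self) -> list[int]:
        return [r.seed for r in self.runs if not r.retained]

    def mean_peaks(self) -> tuple[float, float]:
        pre = float(np.mean([r.pre_peak for r in self.retained]))
        post = float(np.mean([r.post_peak for r in self.retained]))
        return pre, post

    def sem_peaks(self) -> tuple[float, float]:
        from scipy.stats import sem

        pre = float(sem([r.pre_peak for r in self.retained]))
        post = float(sem([r.post_peak for r in self.retained]))
        return pre, post


def summarize_run(
    result: SimulationResult,
    bank: WaveletBank,
    bounds: tuple[float, float] = OMISSION_BOUNDS,
) -> RunSummary:
    """Spectral and ISI summaries of one run, plus the omission decision."""
    cfg = result.config
    pre_win = (cfg.settle, cfg.lesion_time)
    post_win = (cfg.lesion_time + cfg.settle, cfg.duration)
    spectra = {}
    for pop in ("SP", "NSP", "TRN", "CRX"):
        spectra[f"{pop}_pre"] = window_spectrum(result.lfp[pop], pre_win, bank, cfg.dt)
        spectra[f"{pop}_post"] = window_spectrum(result.lfp[pop], post_win, bank, cfg.dt)
    pre_peak = dominant_peak(spectra["CRX_pre"], PEAK_WINDOW)
    post_peak = dominant_peak(spectra["CRX_post"], PEAK_WINDOW)
    nsp_post_peak = dominant_peak(spectra["NSP_post"], THAL_PEAK_WINDOW)
    retained = bounds[0] <= pre_peak <= bounds[1]

    bf, med = {}, {}
    for pop in ("SP", "NSP", "TRN"):
        for tag, win in (("pre", pre_win), ("post", post_win)):
            key = f"{pop}_{tag}"
            if result.rasters[pop][0].size:
                summary = isi_statistics(result.rasters[pop], win)
                bf[key] = summary.burst_fraction
                pooled = summary.pooled()
                med[key] = float(np.median(pooled)) if pooled.size else None
            else:
                bf[key] = med[key] = None

    n_pre = int(round(cfg.lesion_time / cfg.dt))
    mean_nsp = {
        "pre": float(result.lfp["NSP"][int(cfg.settle) : n_pre].mean()),
        "post": float(result.lfp["NSP"][n_pre + int(cfg.settle) :].mean()),
    }
    return RunSummary(
        seed=result.seed,
        pre_peak=pre_peak,
        post_peak=post_peak,
        retained=retained,
        spectra=spectra,
        burst_fractions=bf,
        nsp_post_peak=nsp_post_peak,
        mean_nsp_v=mean_nsp,
        median_isis=med,
    )


def run_cohort(config: SimulationConfig, bank: WaveletBank | None = None) -> CohortResult:
    """Run ``config.n_runs`` seeded simulations and apply the omission rule.

    Run i uses seed ``config.seed + i`` for both its topology and its
    dynamics.  Runs whose pre-lesion cortical dominant peak (6–13 Hz search)
    falls outside the healthy bounds are flagged omitted and excluded from
    cohort means; the omission log is retained for inspection.
    """
    if config.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    bank = bank or model_wavelet_bank(1000.0 / config.dt)
    runs = []
    for i in range(config.n_runs):
        run_seed = config.seed + i
        cfg = replace_cfg(config, seed=run_seed)
        result = run_simulation(cfg)
        summary = summarize_run(result, bank)
        if not summary.retained:
            logger.info(
                "run %d omitted: pre-lesion peak %.2f Hz outside [%.1f, %.1f]",
                run_seed, summary.pre_peak, *OMISSION_BOUNDS,
            )
        runs.append(summary)
    return CohortResult(runs=runs, config=config, bank=bank)


def replace_cfg(config: SimulationConfig, **kw) -> SimulationConfig:
    from dataclasses import replace as _replace

    return _replace(config, **kw)


def gaba_compare(
    config: SimulationConfig | None = None,
    n_runs: int = 5,
    bank: WaveletBank | None = None,
) -> pd.DataFrame:
    """Post-lesion cortical spectra with and without the tonic GABA current.

    Runs ``n_runs`` seed-matched pairs (lesion-only vs lesion+GABA) and
    returns the grand-mean post-lesion cortical power spectrum of each
    variant on the model frequency grid.  The neuroprotective GABA rise is
    expected to suppress power in the upper beta/gamma range relative to the
    lesion-only variant.
    """
    config = config or SimulationConfig()
    bank = bank or model_wavelet_bank(1000.0 / config.dt)
    post_win = (config.lesion_time + config.settle, config.duration)
    acc = {"lesion_only": [], "with_gaba": []}
    for k in range(n_runs):
        for label, gaba in (("lesion_only", False), ("with_gaba", True)):
            cfg = replace_cfg(
                config, seed=config.seed + k, gaba_enabled=gaba, record_rasters=False
            )
            res = run_simulation(cfg)
            acc[label].append(window_spectrum(res.lfp["CRX"], post_win, bank, cfg.dt).power)
    return pd.DataFrame(
        {
            "freq_hz": bank.freqs,
            "lesion_only": np.mean(acc["lesion_only"], axis=0),
            "with_gaba": np.mean(acc["with_gaba"], axis=0),
        }
    )


def lesion_sweep(
    sizes: list[float] | None = None,
    reps: int = 10,
    config: SimulationConfig | None = None,
    bank: WaveletBank | None = None,
) -> pd.DataFrame:
    """Mean post-lesion dominant peak as a function of lesion fraction.

    For each fraction, ``reps`` seeded runs; returns a table with mean and
    s.e.m. of the post-lesion cortical peak (and the pre-lesion mean as a
    reference).  Seeds are ``config.seed + k`` for rep k, shared across
    fractions so the comparison is paired.
    """
    from scipy.stats import sem

    sizes = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5] if sizes is None else sorted(sizes)
    config = config or SimulationConfig()
    bank = bank or model_wavelet_bank(1000.0 / config.dt)
    rows = []
    for frac in sizes:
        pre, post = [], []
        for k in range(reps):
            cfg = replace_cfg(
                config, lesion_fraction=frac, seed=config.seed + k, record_rasters=False
            )
            summary = summarize_run(run_simulation(cfg), bank)
            pre.append(summary.pre_peak)
            post.append(summary.post_peak)
        rows.append(
            {
                "lesion_fraction": frac,
                "mean_pre_peak": float(np.mean(pre)),
                "mean_post_peak": float(np.mean(post)),
                "sem_post_peak": float(sem(post)) if reps > 1 else np.nan,
                "n": reps,
            }
        )
    return pd.DataFrame(rows)
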