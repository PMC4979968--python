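# Methods

`thalcort` couples a spiking model of a generic thalamo-cortical module to a
wavelet-based spectral pipeline, so that the same analysis can be applied to
the model's simulated field potentials and to (synthetic or real)
multichannel resting-state EEG. This note documents the model equations, the
numerical scheme, the calibration choices that were genuinely open, what the
synthetic-EEG generator does and does not emulate, and the known limitations.

## The thalamo-cortical module

Five neuron groups are simulated: a specific relay nucleus (SP, 100 cells,
the model analogue of a primary sensory relay such as the ventral posterior
complex), a non-specific/intralaminar-like nucleus (NSP, 100), the
inhibitory thalamic reticular nucleus (TRN, 100), and a cortical sheet of
800 excitatory and 200 inhibitory cells.

### Thalamic cells: integrate-and-fire-or-burst

Thalamic neurons are single-compartment, conductance-based
integrate-and-fire cells augmented with a low-threshold T-type calcium
current gated by a slow de-inactivation variable `h`:

    C dV/dt = -g_L (V - V_L) - g_E (V - V_E) - g_I (V - V_I) - I_T
    I_T     = g_T · m∞(V) · h · (V - E_T),   m∞(V) = H(V - V_h)
    dh/dt   = -h / τh⁻           if V > V_h
            = (1 - h) / τh⁺      if V < V_h

with a spike emitted and `V ← V_reset` when `V ≥ V_0`. Under sustained
hyperpolarization below `V_h`, `h` recovers toward 1; on release the T
current ignites a low-threshold calcium spike crowned by a fast burst
(inter-spike intervals < 20 ms), the cellular signature of thalamo-cortical
dysrhythmia. Parameters (per nucleus): C = 2 µF/cm², g_L = 0.035 mS/cm²,
V_L = −65 mV, g_T = 0.07 mS/cm², V_0 = −35 mV, V_reset = −50 mV, V_E = 0,
V_I = −85 mV, k_E = 1, k_I = 0.1, τh⁺ = 100 ms; V_h = −66 mV and τh⁻ = 20 ms
for SP/NSP, −64 mV and 40 ms for TRN.

Two conventions in this formulation deserve comment. First, the threshold
`V_h` serves both as the Heaviside activation point of `m∞` and as the
branch condition of the h-dynamics; the calcium driving reversal `E_T`
(default +120 mV, configurable) is a separate parameter — with the driving
term evaluated at the threshold voltage itself the current would be
hyperpolarizing, which contradicts its physiological role. Second, synaptic
input is implemented in the conventional conductance form shown above, in
which excitatory conductances pull the membrane toward `V_E` and inhibitory
ones toward `V_I`.

### Cortical cells: quadratic integrate-and-fire

Cortical cells follow the two-variable quadratic model

    dv/dt = 0.04 v² + 5v + 140 - u + I
    du/dt = a (b v - u)

with spike cutoff at +30 mV and reset `v ← c`, `u ← u + d`. Excitatory
cells are regular-spiking (a = 0.02, b = 0.2, c = −65 + 15r², d = 8 − 6r²)
and inhibitory cells fast-spiking (a = 0.02 + 0.08r, b = 0.25 − 0.05r,
c = −65, d = 2), with `r ~ U(0,1)` drawn per neuron. The quadratic equation
diverges in finite time, so `v` is clamped at the 30 mV peak within the
step; without the clamp the post-threshold overshoot feeds a spurious extra
increment into `u` through the recovery equation.

### Connectivity

Thirteen projections connect the groups (weights g_s in mS, decay constants
τ_s in ms, integer conduction delays in ms):

| projection | polarity | g_s | pattern | τ_s | delay |
|---|---|---|---|---|---|
| Input→SP | exc | 0.005 | 1-to-1 | 10 | 0 |
| Input→NSP | exc | 0.005 | 1-to-1 | 10 | 0 |
| SP→TRN | exc | 0.018 | 1-to-1 | 10 | 3 |
| TRN→SP | inh | 0.35 | 1-to-1 | 75 | 3 |
| TRN→NSP | inh | 0.18 | 1-to-many (0.15) | 75 | 3 |
| NSP→TRN | exc | 0.015 | 1-to-many (0.15) | 10 | 3 |
| E→TRN | exc | 0.02 | 8-to-1 | 7 | 7 |
| E→SP | exc | 0.007 | 8-to-1 | 7 | 7 |
| E→NSP | exc | 0.02 | 8-to-1 | 7 | 7 |
| SP→E | exc | 0.002 | 1-to-8 | 7 | 7 |
| NSP→E | exc | 0.8 | 1-to-many (0.03) | 7 | 7 |
| E→E/I | exc | 0.3 | all-to-all | — | — |
| I→I/E | inh | 1.0 | all-to-all | — | — |

The 8↔1 cortico-thalamic mappings are contiguous and topographic, so a
contiguous cortical lesion deafferents a contiguous thalamic zone.
Projections onto thalamic targets are conductance-based (the increment per
presynaptic spike is `k_{E/I} · g_s`, decaying exponentially with τ_s);
projections onto cortical targets are current-based decaying inputs; the
cortico-cortical "all-to-all" rows are instantaneous current pulses with no
decay and no conduction delay (effectively one 1 ms step), excluding
self-connections. Peripheral drive is an independent Bernoulli spike train
per relay cell with per-step probability P_SP = 0.5 and P_NSP = 0.35 through
the Input rows above — values that keep the relay nuclei firing in a
physiological range with peripheral input dominating the SP.

Two cortical-coupling choices were genuinely open and are set as follows:

- **Per-edge weight scaling.** Cortico-cortical weights are scaled per edge
  by independent U(0,1) factors (the convention of the cortical model this
  sheet derives from). With strictly uniform weights the all-to-all coupling
  is all-or-none: any coincidence ignites the entire sheet into 800-cell
  one-millisecond volleys, which drives the TRN into permanent bursting and
  collapses the healthy baseline.
- **Gaussian drive jitter.** A zero-mean Gaussian current (σ = 3, redrawn
  per cell per step) is added to the cortical drive, for the same reason:
  it keeps the sheet in an asynchronous-irregular regime. Both options are
  exposed in `SimulationConfig`.

### Calibration of the cortical drive

The intrinsic cortical drives (I_E, I_I) are the model's calibration
parameters for the healthy alpha rhythm: they were chosen by searching the
parameter space until the pre-lesion cortical spectrum shows a dominant peak
inside the healthy alpha range, reproducing spectra comparable to healthy
EEG. For this implementation (exact-exponential synaptic updates, peak
clamping, random edge scaling) that search lands at **I_E = 4.1, I_I = 2.7**.
The drives sit in the slow repetitive-firing regime of the regular-spiking
cell (an isolated cell at this drive fires ≈9 Hz), and the resulting network
rhythm places the pre-lesion dominant peak at ≈9.8 Hz.

## Numerical scheme

The membrane equations use forward Euler at the model's 1 ms step (cortical
`v` in two 0.5 ms half-steps, standard for the quadratic model's stiffness;
`u` full-step). The linear subsystems — `h` and every synaptic
conductance/current decay — use the exact exponential update of the linear
ODE, which is unconditionally stable and eliminates the few-percent decay
error plain Euler commits at τ as short as 10 ms. Unit tests pin the 1 ms
scheme against closed forms and against 0.01 ms reference integrations
(spike counts within 10%, rebound-burst spike count within ±1). Delays are
integer-step ring buffers; a "—" delay means the spike acts on the next
step. All randomness flows from a single `numpy` generator seeded per run,
making every run bit-reproducible.

## Lesion protocol

Each run simulates 20 s. At t = 10 s a structural lesion deafferents a
contiguous block of ⌊0.30·800⌋ = 240 excitatory plus the aligned
⌊0.30·200⌋ = 60 inhibitory cortical cells: every synapse to and from these
neurons is removed (edges among intact neurons are preserved exactly;
peripheral thalamic drives are untouched). Lesioned cells also lose their
intrinsic drive and fall silent — being disconnected, their residual firing
could not influence any observable, and silencing them keeps rasters
interpretable. They are excluded from LFPs and all spectra.

**Extrasynaptic GABA.** Acute ischaemia raises extrasynaptic GABA as a
neuroprotective response, inhibiting all cortical activity. The model
represents this as a tonic negative current applied to all intact cortical
cells, ramping linearly over 1 s from lesion onset to a plateau that scales
with lesion extent (default 5/3 per unit lesion fraction, i.e. 0.5 at the
reference 30% lesion — a calibration; no magnitude is published). It is on
by default, as part of the modelled acute-stroke condition: with it the
30% lesion slows the cortical dominant peak from ≈9.8 to ≈9.4 Hz and the
lesion-size sweep is monotone with zero shift at zero lesion; the
`gaba-compare` experiment isolates its spectral effect (suppression of the
upper beta/gamma range from ≈23 Hz) against a lesion-only variant.

**Cohort and omission rule.** Cohorts run n seeded repetitions (seed base+i;
fresh connectivity, heterogeneity and drives per run). Runs whose pre-lesion
cortical dominant peak (6–13 Hz search) falls outside 8.3–11.9 Hz — the
healthy control group's alpha range — are omitted from cohort statistics,
mirroring the noise constraint of the original protocol.

**LFPs and spectral windows.** The population LFP is the per-step mean
membrane potential over intact neurons (cortical contributions clipped at
the 30 mV peak). Spectral windows exclude the first second after run start
and after lesion onset as transients: pre-lesion 1–10 s, post-lesion
11–20 s.

## Spectral analysis

Complex Morlet wavelets on a log-spaced grid (50 points per decade: 1–35 Hz
for EEG, 1–80 Hz for model LFPs), each normalised by its maximum value, with
cycles increasing linearly from 3 at the lowest to 10 at the highest center
frequency. Power is computed by frequency-domain convolution; at each
time-frequency point the power is the square of the *real part* of the
analytic signal (the squared-magnitude alternative is available but off by
default), then averaged over time with samples inside half a wavelet support
of either signal edge excluded. Band energies (MSE) average power over grid
frequencies inside δ 1.0–4.0, θ 4.2–7.9, α 8.3–11.9, β 12.4–30.6 (and γ
30.7–80 for the model). Note two consequences of this (deliberately
literal) estimator: the band partition has gaps (a 4.1 Hz line belongs to
no band), and max-normalised wavelets carry more energy at low frequencies,
so band energies of a flat spectrum are not flat — comparisons are always
within-band across conditions, never across bands. Dominant peaks are the
grid argmax within a search window (6–13 Hz for cortical/EEG alpha, 1–13 Hz
for the thalamic low-frequency peak), ties broken toward the lower
frequency.

## EEG pipeline

Fixed order, enforced by the orchestrator: (1) 0.5–35 Hz 2nd-order
Butterworth bandpass (12 dB/octave), applied forward-backward for zero
phase — which doubles the effective roll-off, a deliberate deviation in
favour of epoch integrity; (2) common-average re-referencing; (3) the first
45 non-overlapping 2048 ms epochs containing no sample beyond ±75 µV
(the sole artifact criterion); (4) Morlet spectra. Epochs are concatenated
per channel before convolution because the lowest-frequency wavelets are
longer than a single epoch; only global edges are excluded. Group
statistics use the two-sided Wilcoxon rank-sum (Mann–Whitney) test — exact
null distribution for small tie-free samples, tie-corrected normal
approximation otherwise — on per-subject band energies and dominant alpha
peaks. For topographic maps, all non-midline electrodes of left-lesion
subjects are mirrored so the map's right side is always ipsi-lesional.

## Synthetic EEG generator

Per electrode: frequency-domain-shaped Gaussian noise (1/f^χ, χ = 1,
background RMS 10 µV) with per-band multiplicative power gains; an
independent narrowband-noise alpha oscillator (±0.5 Hz around the subject's
alpha frequency, RMS 8 µV, posterior-weighted topography); optional 200 ms,
150 µV bipolar transients at Poisson times (1/min default) on single
electrodes. Patient-like cohorts draw alpha frequencies from N(7.9, 1.0²)
clipped to [6.1, 10.4] Hz and use band gains δ 2.2, θ 1.8, α 1.0, β 0.55
with an extra ×1.5 delta/theta gain on ipsi-lesional lateral electrodes
(F8/C4/T4/T6 or mirrored); control-like cohorts draw from N(9.7, 1.0²)
clipped to [8.3, 11.9] with unit gains. The group means and ranges are the
published clinical values; the subject-level s.d. of 1 Hz, the amplitudes
and the band-gain magnitudes are generator assumptions chosen to produce
realistic-looking traces with unambiguous group structure.

What passing recovery tests on this generator shows: that the pipeline's
filtering, referencing, rejection, spectral estimation and statistics
correctly recover the spectral structure they target, at clinical cohort
sizes. What it does not show: anything about volume conduction, spatial
covariance, non-stationarity, or artifact diversity of real scalp EEG —
the generator's electrodes are statistically independent apart from their
shared gain structure, and its only artifact class is the one the rejection
rule is defined by.

## Known limitations

- The pre-lesion network state and the published 9.9 → 9.2 Hz slowing are
  reproduced, but in this re-derivation the post-lesion slowing is carried
  by the lesion-scaled GABA current; with GABA disabled the post-lesion
  cortical peak drifts slightly upward instead. The de-novo switch of the
  whole NSP/TRN to synchronized theta bursting is only partial here:
  bursting appears in, and stays largely confined to, the deafferented
  thalamic zone, the post-lesion NSP spectrum gains low-frequency (≲5 Hz)
  rather than 6–8 Hz power, and pooled post-lesion burst fractions stay
  well below one half. Correspondingly, the deafferented NSP zone
  hyperpolarizes relative to the intact zone (and the deafferented TRN zone
  absolutely), but the NSP population mean does not drop.
- Problem sizes in the test suite are chosen for fast feedback: reference
  integrations run 0.5–1 s of model time, behavioural simulations 6–10 s;
  the acceptance protocols use the full 20 s × 40-run cohort.
- Neurons are single-compartment with Heaviside T-channel activation; no
  plasticity, no spatial embedding, no conduction-distance delays.
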