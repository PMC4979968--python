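"""Topology of the thalamo-cortical module and its peripheral drives.

Five neuron groups: the specific relay nucleus (SP, 100 cells), the
non-specific/intralaminar nucleus (NSP, 100), the inhibitory reticular
nucleus (TRN, 100), and a cortical sheet of 800 excitatory (E) and 200
inhibitory (I) quadratic integrate-and-fire cells.  Thirteen projections
connect them; each is defined by a polarity, a uniform synaptic weight, a
connectivity pattern, a synaptic decay constant and an integer conduction
delay.  SP and NSP additionally receive independent Poisson spike-train
drives standing in for peripheral sensory and brainstem input.

Connectivity patterns
---------------------
``one_to_one``      index-aligned pairing (requires equal sizes)
``one_to_many(p)``  each (i, j) pair connected independently with prob. p
``eight_to_one``    contiguous source blocks [8k, 8k+7] converge on target k
``one_to_eight``    the transpose (divergence to a contiguous block)
``all_to_all``      complete bipartite minus cortical self-edges

The 8↔1 mappings are topographic: a contiguous cortical lesion therefore
deafferents a contiguous zone of each thalamic nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProjectionSpec",
    "RealizedProjection",
    "NetworkTopology",
    "PoissonDriveSpec",
    "TopologyError",
    "DEFAULT_POPULATIONS",
    "default_projection_table",
    "build_projection",
    "build_network",
    "poisson_drive",
]


class TopologyError(ValueError):
    """Raised when a projection spec is inconsistent with population sizes."""


DEFAULT_POPULATIONS: dict[str, int] = {
    "SP": 100,
    "NSP": 100,
    "TRN": 100,
    "E": 800,
    "I": 200,
}

PATTERNS = ("one_to_one", "one_to_many", "eight_to_one", "one_to_eight", "all_to_all")


@dataclass(frozen=True)
class ProjectionSpec:
    """One row of the connectivity table (weights in mS, delays in ms)."""

    name: str
    source: str
    target: str
    polarity: str                 # "excitatory" | "inhibitory"
    g_s: float
    pattern: str
    p: float | None = None        # connection probability for one_to_many
    tau_s: float | None = None    # None => instantaneous pulse coupling
    delay: int | None = None      # None => zero-delay

    def __post_init__(self) -> None:
        if self.polarity not in ("excitatory", "inhibitory"):
            raise TopologyError(f"{self.name}: bad polarity {self.polarity!r}")
        if self.pattern not in PATTERNS:
            raise TopologyError(f"{self.name}: unknown pattern {self.pattern!r}")
        if self.pattern == "one_to_many" and not (self.p and 0 < self.p <= 1):
            raise TopologyError(f"{self.name}: one_to_many needs p in (0, 1]")
        if self.g_s < 0:
            raise TopologyError(f"{self.name}: weight magnitude must be >= 0")


@dataclass
class RealizedProjection:
    """A projection instantiated as an explicit edge set."""

    spec: ProjectionSpec
    src: np.ndarray   # presynaptic indices within source population
    tgt: np.ndarray   # postsynaptic indices within target population

    @property
    def signed_weight(self) -> float:
        return -self.spec.g_s if self.spec.polarity == "inhibitory" else self.spec.g_s

    @property
    def delay_steps(self) -> int:
        return int(self.spec.delay or 0)

    def n_edges(self) -> int:
        return int(self.src.size)

    def weight_matrix(self, n_target: int, n_source: int) -> np.ndarray:
        """Dense (n_target, n_source) matrix of weight magnitudes."""
        W = np.zeros((n_target, n_source), order="F")
        np.add.at(W, (self.tgt, self.src), self.spec.g_s)
        return W


def default_projection_table() -> list[ProjectionSpec]:
    """The thirteen projections of the module, with their weights (mS),
    decay constants tau_s (ms) and conduction delays (ms)."""
    P = ProjectionSpec
    return [
        P("Input-SP->SP", "INPUT_SP", "SP", "excitatory", 0.005, "one_to_one", tau_s=10, delay=0),
        P("Input-NSP->NSP", "INPUT_NSP", "NSP", "excitatory", 0.005, "one_to_one", tau_s=10, delay=0),
        P("SP->TRN", "SP", "TRN", "excitatory", 0.018, "one_to_one", tau_s=10, delay=3),
        P("TRN->SP", "TRN", "SP", "inhibitory", 0.35, "one_to_one", tau_s=75, delay=3),
        P("TRN->NSP", "TRN", "NSP", "inhibitory", 0.18, "one_to_many", p=0.15, tau_s=75, delay=3),
        P("NSP->TRN", "NSP", "TRN", "excitatory", 0.015, "one_to_many", p=0.15, tau_s=10, delay=3),
        P("E->TRN", "E", "TRN", "excitatory", 0.02, "eight_to_one", tau_s=7, delay=7),
        P("E->SP", "E", "SP", "excitatory", 0.007, "eight_to_one", tau_s=7, delay=7),
        P("E->NSP", "E", "NSP", "excitatory", 0.02, "eight_to_one", tau_s=7, delay=7),
        P("SP->E", "SP", "E", "excitatory", 0.002, "one_to_eight", tau_s=7, delay=7),
        P("NSP->E", "NSP", "E", "excitatory", 0.8, "one_to_many", p=0.03, tau_s=7, delay=7),
        P("E->E/I", "E", "CRX", "excitatory", 0.3, "all_to_all"),
        P("I->I/E", "I", "CRX", "inhibitory", 1.0, "all_to_all"),
    ]


@dataclass(frozen=True)
class PoissonDriveSpec:
    """Independent Bernoulli spike lines, one per target neuron.

    P is the per-1 ms-step spike probability; the tuned defaults keep the
    relay nuclei firing in a physiological range while preserving the SP's
    dominance of peripheral input (P_SP = 0.5, P_NSP = 0.35).
    """

    target: str
    P: float
    weight: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must lie in [0, 1]")


DEFAULT_DRIVES = (
    PoissonDriveSpec("SP", 0.5),
    PoissonDriveSpec("NSP", 0.35),
)


def _crx_size(sizes: dict[str, int]) -> int:
    return sizes["E"] + sizes["I"]


def _pop_size(name: str, sizes: dict[str, int]) -> int:
    if name == "CRX":
        return _crx_size(sizes)
    if name.startswith("INPUT_"):
        return sizes[name.removeprefix("INPUT_")]
    return sizes[name]


def build_projection(
    spec: ProjectionSpec,
    sizes: dict[str, int],
    rng: np.random.Generator,
) -> RealizedProjection:
    """Realize one projection as (src, tgt) index arrays.

    Deterministic given the generator state; only ``one_to_many`` consumes
    randomness.  All-to-all cortical projections exclude self-edges (a
    cortical cell never pulses itself).
    """
    n_s = _pop_size(spec.source, sizes)
    n_t = _pop_size(spec.target, sizes)

    if spec.pattern == "one_to_one":
        if n_s != n_t:
            raise TopologyError(f"{spec.name}: one_to_one needs equal sizes ({n_s} vs {n_t})")
        idx = np.arange(n_s)
        return RealizedProjection(spec, idx, idx.copy())

    if spec.pattern == "one_to_many":
        mask = rng.random((n_s, n_t)) < spec.p
        src, tgt = np.nonzero(mask)
        return RealizedProjection(spec, src, tgt)

    if spec.pattern == "eight_to_one":
        if n_s != 8 * n_t:
            raise TopologyError(f"{spec.name}: eight_to_one needs source = 8 x target")
        src = np.arange(n_s)
        return RealizedProjection(spec, src, src // 8)

    if spec.pattern == "one_to_eight":
        if n_t != 8 * n_s:
            raise TopologyError(f"{spec.name}: one_to_eight needs target = 8 x source")
        tgt = np.arange(n_t)
        return RealizedProjection(spec, tgt // 8, tgt)

    # all_to_all within cortex, minus self-edges
    src_grid, tgt_grid = np.meshgrid(np.arange(n_s), np.arange(n_t), indexing="ij")
    src, tgt = src_grid.ravel(), tgt_grid.ravel()
    if spec.target == "CRX" and spec.source in ("E", "I"):
        offset = 0 if spec.source == "E" else sizes["E"]
        keep = tgt != src + offset
        src, tgt = src[keep], tgt[keep]
    return RealizedProjection(spec, src, tgt)


@dataclass
class NetworkTopology:
    """All realized projections plus population bookkeeping."""

    populations: dict[str, int]
    projections: list[RealizedProjection]
    drives: tuple[PoissonDriveSpec, ...]
    rng_seed: int
    lesion_mask: np.ndarray | None = None  # per-CRX-neuron bool, True = lesioned
    provenance: dict = field(default_factory=dict)

    @property
    def n_crx(self) -> int:
        return _crx_size(self.populations)

    def projection(self, name: str) -> RealizedProjection:
        for proj in self.projections:
            if proj.spec.name == name:
                return proj
        raise KeyError(name)

    def edge_table(self) -> pd.DataFrame:
        """Signed edge list (source, target, weight, delay, projection)."""
        frames = []
        for proj in self.projections:
            frames.append(
                pd.DataFrame(
                    {
                        "projection": proj.spec.name,
                        "source_pop": proj.spec.source,
                        "target_pop": proj.spec.target,
                        "source": proj.src,
                        "target": proj.tgt,
                        "weight": proj.signed_weight,
                        "delay_ms": proj.delay_steps,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def validate(self) -> None:
        for proj in self.projections:
            sign_ok = (
                proj.signed_weight <= 0
                if proj.spec.polarity == "inhibitory"
                else proj.signed_weight >= 0
            )
            if not sign_ok:
                raise TopologyError(f"{proj.spec.name}: weight sign mismatch")
            if proj.delay_steps < 0:
                raise TopologyError(f"{proj.spec.name}: negative delay")


def build_network(
    config: list[ProjectionSpec] | None = None,
    seed: int = 0,
    populations: dict[str, int] | None = None,
    drives: tuple[PoissonDriveSpec, ...] = DEFAULT_DRIVES,
) -> NetworkTopology:
    """Instantiate the full module topology, deterministically from ``seed``.

    ``config`` defaults to the thirteen-row projection table; passing a
    partial list raises, since the module's dynamics depend on every
    pathway being present.
    """
    sizes = dict(populations or DEFAULT_POPULATIONS)
    specs = default_projection_table() if config is None else list(config)
    required = {s.name for s in default_projection_table()}
    if config is not None:
        missing = required - {s.name for s in specs}
        if missing:
            raise TopologyError(f"missing projections: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    projections = [build_projection(s, sizes, rng) for s in specs]
    topo = NetworkTopology(
        populations=sizes,
        projections=projections,
        drives=drives,
        rng_seed=seed,
        provenance={"seed": seed},
    )
    topo.validate()
    return topo


def poisson_drive(
    spec: PoissonDriveSpec,
    n_neurons: int,
    n_steps: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Independent Bernoulli(P) spike trains, shape (n_steps, n_neurons)."""
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.random((n_steps, n_neurons)) < spec.P
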