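"""Neural-mass circuit model of the cortico-basal-ganglia-thalamocortical loop.

The motor loop is modelled as six interacting sources: motor cortex,
striatum, external and internal globus pallidus (GPe, GPi), subthalamic
nucleus (STN) and thalamus.  Cortex is a three-population layered ensemble
(spiny-stellate input cells, pyramidal projection cells, inhibitory
interneurons); each subcortical nucleus is a single excitatory or
inhibitory cell mass.  Every population carries two second-order synaptic
channels (excitatory and inhibitory alpha kernels); coupling between
populations is a gain factor mapping presynaptic firing rate to
postsynaptic drive, with an axonal conduction delay.

Connection signs are not free parameters: a GABAergic presynaptic
population inhibits, a glutamatergic one excites.
"""

from __future__ import annotations

import importlib.resources
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

# ---------------------------------------------------------------------------
# Sources and population kinds
# ---------------------------------------------------------------------------

CORTEX = "cortex"
STRIATUM = "striatum"
GPE = "gpe"
STN = "stn"
GPI = "gpi"
THALAMUS = "thalamus"

SOURCES = (CORTEX, STRIATUM, GPE, STN, GPI, THALAMUS)

SPINY_STELLATE = "spiny_stellate_input"
PYRAMIDAL = "pyramidal"
INTERNEURON = "inhibitory_interneuron"
EXC_MASS = "excitatory_mass"
INH_MASS = "inhibitory_mass"

#: population kinds that release glutamate (everything else is GABAergic)
EXCITATORY_KINDS = frozenset({SPINY_STELLATE, PYRAMIDAL, EXC_MASS})

#: number of state variables per population: (v_e, z_e, v_i, z_i)
STATES_PER_POP = 4


@dataclass(frozen=True)
class SubpopulationParams:
    """Synaptic kernel and activation-function constants shared by all populations.

    ``He``/``Hi`` are the maximal excitatory/inhibitory postsynaptic
    amplitudes (mV), ``kappa_e``/``kappa_i`` the corresponding rate
    constants (1/s; the alpha kernel ``H*kappa*t*exp(-kappa*t)`` peaks at
    ``t = 1/kappa``).  ``rho1`` (1/mV) and ``rho2`` (mV) set the slope and
    offset of the centred sigmoid converting depolarisation to firing.
    """

    He: float = 4.0
    Hi: float = 32.0
    kappa_e: float = 250.0
    kappa_i: float = 62.5
    rho1: float = 2.0
    rho2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("He", "Hi", "kappa_e", "kappa_i", "rho1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class Population:
    source: str
    kind: str

    @property
    def excitatory(self) -> bool:
        return self.kind in EXCITATORY_KINDS

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.source}/{self.kind}"


@dataclass(frozen=True)
class Connection:
    """A gain-factor coupling from one population's firing to another's drive."""

    source_from: str
    kind_from: str
    source_to: str
    kind_to: str
    gain: float
    delay: float  # seconds
    scope: str  # "extrinsic" | "intrinsic"
    name: str

    @property
    def sign(self) -> int:
        """+1 for glutamatergic (excitatory), -1 for GABAergic presynaptic cells."""
        return 1 if self.kind_from in EXCITATORY_KINDS else -1

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("connection gain must be non-negative")
        if self.delay < 0:
            raise ValueError("connection delay must be non-negative")
        if self.scope == "extrinsic" and self.source_from == self.source_to:
            raise ValueError("extrinsic connections must couple distinct sources")
        if self.scope not in ("extrinsic", "intrinsic"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class CircuitModel:
    """A wired architecture: populations, connections and observation mapping.

    ``observation_map`` sends each recorded channel label to the population
    whose membrane potential it reads out (through an estimable log gain).
    ``innovation_sites`` lists the populations receiving endogenous
    (neuronal-noise) input.
    """

    populations: tuple[Population, ...]
    connections: tuple[Connection, ...]
    observation_map: tuple[tuple[str, Population], ...]
    innovation_sites: tuple[Population, ...]
    params: SubpopulationParams = field(default_factory=SubpopulationParams)
    name: str = "standard"

    # -- structure ----------------------------------------------------------

    @property
    def sources(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p.source, None)
        return tuple(seen)

    @property
    def n_states(self) -> int:
        return STATES_PER_POP * len(self.populations)

    @property
    def extrinsic(self) -> tuple[Connection, ...]:
        return tuple(c for c in self.connections if c.scope == "extrinsic")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.observation_map)

    @property
    def observed_sources(self) -> tuple[str, ...]:
        return tuple(pop.source for _, pop in self.observation_map)

    @property
    def hidden_sources(self) -> tuple[str, ...]:
        observed = set(self.observed_sources)
        return tuple(s for s in self.sources if s not in observed)

    def population_index(self, source: str, kind: str | None = None) -> int:
        for i, p in enumerate(self.populations):
            if p.source == source and (kind is None or p.kind == kind):
                return i
        raise KeyError(f"no population {source}/{kind}")

    def connection_index(self, name: str) -> int:
        for i, c in enumerate(self.connections):
            if c.name == name:
                return i
        raise KeyError(f"no connection named {name!r}")

    def principal_population(self, source: str) -> Population:
        """The population whose potential stands for the source's signal."""
        kind = PYRAMIDAL if source == CORTEX else None
        return self.populations[self.population_index(source, kind)]

    def without_source(self, source: str) -> "CircuitModel":
        """Remove a source and every connection or channel touching it."""
        pops = tuple(p for p in self.populations if p.source != source)
        if len(pops) == len(self.populations):
            raise KeyError(f"source {source!r} not in circuit")
        conns = tuple(
            c for c in self.connections
            if c.source_from != source and c.source_to != source
        )
        obs = tuple((l, p) for l, p in self.observation_map if p.source != source)
        innov = tuple(p for p in self.innovation_sites if p.source != source)
        return replace(self, populations=pops, connections=conns,
                       observation_map=obs, innovation_sites=innov,
                       name=f"{self.name}-minus-{source}")

    def with_gains(self, gains: Mapping[str, float]) -> "CircuitModel":
        """Return a copy with the named connections' gains replaced."""
        unknown = set(gains) - {c.name for c in self.connections}
        if unknown:
            raise KeyError(f"unknown connections {sorted(unknown)}")
        conns = tuple(
            replace(c, gain=float(gains[c.name])) if c.name in gains else c
            for c in self.connections
        )
        return replace(self, connections=conns)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "bgdcm-circuit",
            "version": 1,
            "name": self.name,
            "params": {k: getattr(self.params, k)
                       for k in ("He", "Hi", "kappa_e", "kappa_i", "rho1", "rho2")},
            "populations": [[p.source, p.kind] for p in self.populations],
            "connections": [
                {"name": c.name, "from": [c.source_from, c.kind_from],
                 "to": [c.source_to, c.kind_to], "gain": c.gain,
                 "delay": c.delay, "scope": c.scope, "sign": c.sign}
                for c in self.connections
            ],
            "observation_map": [[l, [p.source, p.kind]]
                                for l, p in self.observation_map],
            "innovation_sites": [[p.source, p.kind] for p in self.innovation_sites],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitModel":
        if d.get("format") != "bgdcm-circuit":
            raise ValueError("not a circuit document")
        if d.get("version") != 1:
            raise ValueError(f"unsupported circuit document version {d.get('version')!r}")
        params = SubpopulationParams(**d["params"])
        pops = tuple(Population(s, k) for s, k in d["populations"])
        conns = tuple(
            Connection(c["from"][0], c["from"][1], c["to"][0], c["to"][1],
                       c["gain"], c["delay"], c["scope"], c["name"])
            for c in d["connections"]
        )
        obs = tuple((l, Population(s, k)) for l, (s, k) in d["observation_map"])
        innov = tuple(Population(s, k) for s, k in d["innovation_sites"])
        return cls(pops, conns, obs, innov, params, d.get("name", "standard"))

    @classmethod
    def from_json(cls, path) -> "CircuitModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Default priors (single config document)
# ---------------------------------------------------------------------------

def load_config(path=None) -> dict:
    """Load the model configuration (priors, gains, delays, noise levels).

    With no argument the packaged defaults are returned.  The numeric values
    are reconstructed defaults in the spirit of published DCM studies of
    this circuit, not authoritative constants; every one can be overridden
    by pointing ``path`` at a YAML file of the same shape.
    """
    if path is None:
        ref = importlib.resources.files("bgdcm").joinpath("default_priors.yaml")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def _conn(src_f, kind_f, src_t, kind_t, gain, delay, scope, name) -> Connection:
    return Connection(src_f, kind_f, src_t, kind_t, float(gain), float(delay),
                      scope, name)


def _cortex_populations() -> tuple[Population, ...]:
    return (
        Population(CORTEX, SPINY_STELLATE),
        Population(CORTEX, PYRAMIDAL),
        Population(CORTEX, INTERNEURON),
    )


def _mass(source: str) -> Population:
    kind = EXC_MASS if source in (STN, THALAMUS) else INH_MASS
    return Population(source, kind)


def build_standard_circuit(config: dict | None = None) -> CircuitModel:
    """The six-source loop with direct, indirect and hyperdirect pathways.

    Nine extrinsic connections: cortex excites striatum and STN
    (hyperdirect); the striatal mass inhibits GPe (indirect) and GPi
    (direct); GPe and STN are reciprocally coupled; STN excites GPi; GPi
    inhibits thalamus, which closes the loop by exciting the cortical
    input layer.  Channels are recorded from cortex (EEG), STN and GPi;
    striatum and thalamus are hidden.
    """
    cfg = config if config is not None else load_config()
    params = SubpopulationParams(**cfg["subpopulation"])
    d_ext = cfg["delays"]["extrinsic_ms"] * 1e-3
    d_int = cfg["delays"]["intrinsic_ms"] * 1e-3
    g_int = cfg["intrinsic_gains"]
    g_ext = cfg["extrinsic_gains"]

    pops = _cortex_populations() + tuple(
        _mass(s) for s in (STRIATUM, GPE, STN, GPI, THALAMUS))

    intrinsic = (
        _conn(CORTEX, SPINY_STELLATE, CORTEX, PYRAMIDAL,
              g_int["input_to_pyramidal"], d_int, "intrinsic", "in_py"),
        _conn(CORTEX, SPINY_STELLATE, CORTEX, INTERNEURON,
              g_int["input_to_interneuron"], d_int, "intrinsic", "in_ii"),
        _conn(CORTEX, PYRAMIDAL, CORTEX, SPINY_STELLATE,
              g_int["pyramidal_to_input"], d_int, "intrinsic", "py_in"),
        _conn(CORTEX, PYRAMIDAL, CORTEX, INTERNEURON,
              g_int["pyramidal_to_interneuron"], d_int, "intrinsic", "py_ii"),
        _conn(CORTEX, INTERNEURON, CORTEX, PYRAMIDAL,
              g_int["interneuron_to_pyramidal"], d_int, "intrinsic", "ii_py"),
    )
    extrinsic = (
        _conn(CORTEX, PYRAMIDAL, STRIATUM, INH_MASS,
              g_ext["ctx_str"], d_ext, "extrinsic", "ctx_str"),
        _conn(CORTEX, PYRAMIDAL, STN, EXC_MASS,
              g_ext["ctx_stn"], d_ext, "extrinsic", "ctx_stn"),
        _conn(STRIATUM, INH_MASS, GPE, INH_MASS,
              g_ext["str_gpe"], d_ext, "extrinsic", "str_gpe"),
        _conn(STRIATUM, INH_MASS, GPI, INH_MASS,
              g_ext["str_gpi"], d_ext, "extrinsic", "str_gpi"),
        _conn(GPE, INH_MASS, STN, EXC_MASS,
              g_ext["gpe_stn"], d_ext, "extrinsic", "gpe_stn"),
        _conn(STN, EXC_MASS, GPE, INH_MASS,
              g_ext["stn_gpe"], d_ext, "extrinsic", "stn_gpe"),
        _conn(STN, EXC_MASS, GPI, INH_MASS,
              g_ext["stn_gpi"], d_ext, "extrinsic", "stn_gpi"),
        _conn(GPI, INH_MASS, THALAMUS, EXC_MASS,
              g_ext["gpi_tha"], d_ext, "extrinsic", "gpi_tha"),
        _conn(THALAMUS, EXC_MASS, CORTEX, SPINY_STELLATE,
              g_ext["tha_ctx"], d_ext, "extrinsic", "tha_ctx"),
    )
    obs = (
        ("ctx", Population(CORTEX, PYRAMIDAL)),
        ("stn", Population(STN, EXC_MASS)),
        ("gpi", Population(GPI, INH_MASS)),
    )
    innov = (
        Population(CORTEX, SPINY_STELLATE),
        Population(STRIATUM, INH_MASS),
        Population(STN, EXC_MASS),
    )
    return CircuitModel(pops, intrinsic + extrinsic, obs, innov, params,
                        name="standard")


VARIANTS = ("gpe_gpi", "gpe_striatum", "pallidal_channel_to_gpe")


def build_variant(which: str, config: dict | None = None) -> CircuitModel:
    """Candidate alternatives to the standard architecture.

    ``gpe_gpi`` and ``gpe_striatum`` add one extra inhibitory pallidofugal
    connection; ``pallidal_channel_to_gpe`` keeps the standard wiring but
    assumes the pallidal electrode actually recorded GPe, leaving GPi
    hidden.
    """
    cfg = config if config is not None else load_config()
    base = build_standard_circuit(cfg)
    d_ext = cfg["delays"]["extrinsic_ms"] * 1e-3
    g_extra = cfg["variant_gains"]
    if which == "gpe_gpi":
        extra = _conn(GPE, INH_MASS, GPI, INH_MASS,
                      g_extra["gpe_gpi"], d_ext, "extrinsic", "gpe_gpi")
        return replace(base, connections=base.connections + (extra,),
                       name="gpe_gpi")
    if which == "gpe_striatum":
        extra = _conn(GPE, INH_MASS, STRIATUM, INH_MASS,
                      g_extra["gpe_str"], d_ext, "extrinsic", "gpe_str")
        return replace(base, connections=base.connections + (extra,),
                       name="gpe_striatum")
    if which == "pallidal_channel_to_gpe":
        obs = tuple(
            (label, Population(GPE, INH_MASS) if label == "gpi" else pop)
            for label, pop in base.observation_map
        )
        return replace(base, observation_map=obs,
                       name="pallidal_channel_to_gpe")
    raise ValueError(f"unknown variant {which!r}; expected one of {VARIANTS}")


def all_architectures(config: dict | None = None) -> dict[str, CircuitModel]:
    cfg = config if config is not None else load_config()
    out = {"standard": build_standard_circuit(cfg)}
    for v in VARIANTS:
        out[v] = build_variant(v, cfg)
    return out


# ---------------------------------------------------------------------------
# Activation function and state equations
# ---------------------------------------------------------------------------

def sigmoid_firing(v, params: SubpopulationParams):
    """Centred sigmoid rate function: zero deviation at baseline potential.

    ``S(v) = expit(rho1*(v - rho2)) - expit(-rho1*rho2)`` so that S(0) = 0,
    S is bounded and monotone, and its slope at baseline is
    ``rho1 * sig * (1 - sig)`` with ``sig = expit(-rho1*rho2)``.
    """
    from scipy.special import expit

    return expit(params.rho1 * (np.asarray(v, float) - params.rho2)) \
        - expit(-params.rho1 * params.rho2)


def sigmoid_slope_at_baseline(params: SubpopulationParams) -> float:
    s = 1.0 / (1.0 + math.exp(params.rho1 * params.rho2))
    return params.rho1 * s * (1.0 - s)


def _population_potentials(circuit: CircuitModel, x: np.ndarray) -> np.ndarray:
    """Membrane potential of each population: v = v_e - v_i."""
    xr = np.asarray(x).reshape(len(circuit.populations), STATES_PER_POP)
    return xr[:, 0] - xr[:, 2]


def state_derivative(
    circuit: CircuitModel,
    x: np.ndarray,
    u: np.ndarray | float,
    gains: np.ndarray | None = None,
    x_delayed: np.ndarray | None = None,
) -> np.ndarray:
    """Right-hand side of the neural-mass ODE system.

    Each synaptic channel obeys the second-order alpha-kernel dynamics
    ``v' = z``, ``z' = kappa*H*(drive) - 2*kappa*z - kappa^2*v`` where the
    drive collects signed, gain-weighted presynaptic firing plus exogenous
    input ``u`` at the innovation sites.  ``x_delayed`` supplies the state
    from which presynaptic firing is read (defaults to ``x``; conduction
    delays are otherwise handled exactly in the frequency domain).
    ``gains`` optionally overrides the connections' stored gains (aligned
    with ``circuit.connections``).
    """
    x = np.asarray(x, float)
    if x.shape != (circuit.n_states,):
        raise ValueError(
            f"state dimension {x.shape} != ({circuit.n_states},)")
    p = circuit.params
    n_pop = len(circuit.populations)
    xr = x.reshape(n_pop, STATES_PER_POP)
    v_pre = _population_potentials(circuit, x if x_delayed is None else x_delayed)
    firing = sigmoid_firing(v_pre, p)

    if gains is None:
        gains = np.array([c.gain for c in circuit.connections])
    else:
        gains = np.asarray(gains, float)
        if gains.shape != (len(circuit.connections),):
            raise ValueError("gains must align with circuit.connections")

    drive_e = np.zeros(n_pop)
    drive_i = np.zeros(n_pop)
    for g, c in zip(gains, circuit.connections):
        i_from = circuit.population_index(c.source_from, c.kind_from)
        i_to = circuit.population_index(c.source_to, c.kind_to)
        if c.sign > 0:
            drive_e[i_to] += g * firing[i_from]
        else:
            drive_i[i_to] += g * firing[i_from]

    u_arr = np.broadcast_to(np.asarray(u, float), (len(circuit.innovation_sites),))
    for uk, pop in zip(u_arr, circuit.innovation_sites):
        drive_e[circuit.population_index(pop.source, pop.kind)] += uk

    dx = np.empty_like(xr)
    dx[:, 0] = xr[:, 1]
    dx[:, 1] = p.kappa_e * p.He * drive_e - 2 * p.kappa_e * xr[:, 1] \
        - p.kappa_e ** 2 * xr[:, 0]
    dx[:, 2] = xr[:, 3]
    dx[:, 3] = p.kappa_i * p.Hi * drive_i - 2 * p.kappa_i * xr[:, 3] \
        - p.kappa_i ** 2 * xr[:, 2]
    return dx.ravel()


def find_fixed_point(
    circuit: CircuitModel,
    u0: float | np.ndarray = 0.0,
    gains: np.ndarray | None = None,
    tol: float = 1e-8,
    x_init: np.ndarray | None = None,
) -> np.ndarray:
    """Equilibrium of the state equations under constant input ``u0``.

    With the centred sigmoid and zero input the origin is an exact fixed
    point; for non-zero tonic input the root is found numerically.  Raises
    ``UnstableModelError`` if no root with residual below ``tol`` is found.
    """
    from scipy.optimize import root

    if np.all(np.asarray(u0) == 0.0) and x_init is None:
        x0 = np.zeros(circuit.n_states)
        # exact by construction: S(0) = 0 kills every coupling term
        return x0
    x_start = np.zeros(circuit.n_states) if x_init is None else np.asarray(x_init)
    sol = root(lambda x: state_derivative(circuit, x, u0, gains=gains),
               x_start, method="hybr", tol=1e-12)
    resid = np.linalg.norm(state_derivative(circuit, sol.x, u0, gains=gains))
    if not sol.success or resid > tol:
        raise UnstableModelError(
            f"fixed-point search failed (residual {resid:.2e})")
    return sol.x


class UnstableModelError(RuntimeError):
    """Raised when a parameterization yields an unstable or divergent system."""


# ---------------------------------------------------------------------------
# Estimable parameters (log-deviation parameterization)
# ---------------------------------------------------------------------------

@dataclass
class ThetaVector:
    """All estimable parameters, as log-deviations from their prior means.

    * ``log_gain`` — one entry per extrinsic connection: log of the ratio
      between the (condition-ON) gain and its prior mean.
    * ``log_mod`` — one entry per extrinsic connection: the condition
      modulator, log of the OFF/ON gain ratio (0 means no drug effect).
    * ``log_he``, ``log_kappa``, ``log_delay`` — global log-scalings of the
      synaptic amplitudes, rate constants and conduction delays.
    * ``log_obs`` — per-channel observation log-gain deviations.
    * ``log_innov_white``, ``log_innov_pink`` — neuronal innovation
      spectrum amplitudes (white and 1/f components, shared across sites).
    * ``log_chan_white`` — per-channel white measurement-noise amplitude
      (sensor floors differ between scalp EEG and depth contacts);
      ``log_chan_pink`` — the 1/f measurement component, shared.
    """

    log_gain: np.ndarray
    log_mod: np.ndarray
    log_he: float = 0.0
    log_kappa: float = 0.0
    log_delay: float = 0.0
    log_obs: np.ndarray = None  # type: ignore[assignment]
    log_innov_white: float = 0.0
    log_innov_pink: float = 0.0
    log_chan_white: np.ndarray = None  # type: ignore[assignment]
    log_chan_pink: float = 0.0

    @classmethod
    def zeros(cls, circuit: CircuitModel) -> "ThetaVector":
        n_ext = len(circuit.extrinsic)
        n_ch = len(circuit.observation_map)
        return cls(log_gain=np.zeros(n_ext), log_mod=np.zeros(n_ext),
                   log_obs=np.zeros(n_ch), log_chan_white=np.zeros(n_ch))

    def copy(self) -> "ThetaVector":
        return ThetaVector(self.log_gain.copy(), self.log_mod.copy(),
                           self.log_he, self.log_kappa, self.log_delay,
                           self.log_obs.copy(),
                           self.log_innov_white, self.log_innov_pink,
                           np.asarray(self.log_chan_white, float).copy(),
                           self.log_chan_pink)

    def pack(self) -> np.ndarray:
        return np.concatenate([
            self.log_gain, self.log_mod,
            [getattr(self, k) for k in ("log_he", "log_kappa", "log_delay")],
            self.log_obs,
            [self.log_innov_white, self.log_innov_pink],
            np.atleast_1d(self.log_chan_white),
            [self.log_chan_pink],
        ])

    @classmethod
    def unpack(cls, vec: np.ndarray, circuit: CircuitModel) -> "ThetaVector":
        vec = np.asarray(vec, float)
        n_ext = len(circuit.extrinsic)
        n_ch = len(circuit.observation_map)
        i = 0
        log_gain = vec[i:i + n_ext]; i += n_ext
        log_mod = vec[i:i + n_ext]; i += n_ext
        log_he, log_kappa, log_delay = vec[i:i + 3]; i += 3
        log_obs = vec[i:i + n_ch]; i += n_ch
        liw, lip = vec[i:i + 2]; i += 2
        lcw = vec[i:i + n_ch]; i += n_ch
        lcp = vec[i]; i += 1
        if i != vec.size:
            raise ValueError("theta vector length mismatch")
        return cls(log_gain.copy(), log_mod.copy(), float(log_he),
                   float(log_kappa), float(log_delay), log_obs.copy(),
                   float(liw), float(lip), lcw.copy(), float(lcp))

    def names(self, circuit: CircuitModel) -> list[str]:
        ext = [c.name for c in circuit.extrinsic]
        return (
            [f"gain:{n}" for n in ext]
            + [f"mod:{n}" for n in ext]
            + ["he", "kappa", "delay"]
            + [f"obs:{l}" for l in circuit.channel_labels]
            + ["innov_white", "innov_pink"]
            + [f"chan_white:{l}" for l in circuit.channel_labels]
            + ["chan_pink"]
        )

    def modulator_slice(self, circuit: CircuitModel) -> slice:
        n_ext = len(circuit.extrinsic)
        return slice(n_ext, 2 * n_ext)

    def size(self) -> int:
        return self.pack().size


def effective_gains(
    circuit: CircuitModel, theta: ThetaVector, condition: str
) -> np.ndarray:
    """Connection gains (aligned with ``circuit.connections``) in a condition.

    ON gains are prior mean x exp(log_gain); OFF additionally multiplies by
    the per-connection modulator exp(log_mod).  Intrinsic gains are shared
    across conditions and not modulated.
    """
    if condition not in ("on", "off"):
        raise ValueError("condition must be 'on' or 'off'")
    gains = np.array([c.gain for c in circuit.connections])
    ext_names = {c.name: i for i, c in enumerate(circuit.extrinsic)}
    for j, c in enumerate(circuit.connections):
        if c.scope != "extrinsic":
            continue
        k = ext_names[c.name]
        scale = math.exp(theta.log_gain[k])
        if condition == "off":
            scale *= math.exp(theta.log_mod[k])
        gains[j] *= scale
    return gains


# ---------------------------------------------------------------------------
# Pathway checks (graph utilities)
# ---------------------------------------------------------------------------

def has_directed_walk(circuit: CircuitModel, path_sources: Iterable[str]) -> bool:
    """True if consecutive sources in ``path_sources`` are linked by
    extrinsic connections (any subpopulations)."""
    seq = list(path_sources)
    edges = {(c.source_from, c.source_to) for c in circuit.extrinsic}
    return all((a, b) in edges for a, b in zip(seq, seq[1:]))
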