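"""Spectral forward model: from circuit parameters to predicted cross-spectra.

The nonlinear state equations are linearized at their fixed point; with
conduction delays kept as exact phase factors the linear stochastic system

    dx/dt = A0 x(t) + sum_d A_d x(t - d) + B u(t)
    y(t)  = C x(t) + e(t)

has transfer matrix ``T(w) = C (iwI - A0 - sum_d A_d exp(-iwd))^{-1} B``
and predicted channel cross-spectral density

    S(w) = T(w) G_u(w) T(w)^H + G_e(w)

where ``G_u`` is the (diagonal) innovation spectrum at the sites receiving
neuronal noise and ``G_e`` the channel measurement-noise spectrum.  Both
noise spectra are white + 1/f mixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .circuit import (
    STATES_PER_POP,
    CircuitModel,
    SubpopulationParams,
    ThetaVector,
    UnstableModelError,
    effective_gains,
    load_config,
    sigmoid_slope_at_baseline,
    state_derivative,
)

#: below this frequency the 1/f noise components are clamped, emulating the
#: 1 Hz analogue high-pass applied to the recordings
PINK_FLOOR_HZ = 1.0

DEFAULT_BAND = (13.0, 35.0)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpace:
    """Linearized (delay-differential) system matrices.

    ``A0`` holds the instantaneous dynamics; ``delay_blocks`` maps each
    distinct conduction delay (s) to the Jacobian block of terms arriving
    with that delay.  ``B`` injects innovations, ``C`` reads out channels.
    """

    A0: np.ndarray
    delay_blocks: tuple[tuple[float, np.ndarray], ...]
    B: np.ndarray
    C: np.ndarray
    #: original state indices retained after pruning undriven channels
    keep: np.ndarray | None = None

    @property
    def aggregate(self) -> np.ndarray:
        """Zero-delay aggregate Jacobian A0 + sum_d A_d."""
        A = self.A0.copy()
        for _, Ad in self.delay_blocks:
            A = A + Ad
        return A

    def is_stable(self) -> bool:
        return bool(np.max(np.linalg.eigvals(self.aggregate).real) < 0)


@dataclass
class NoiseSpectrumParams:
    """White + 1/f spectral mixtures for neuronal and channel noise."""

    innovation_white: float
    innovation_pink: float
    channel_white: float
    channel_pink: float
    exponent: float = 1.0
    #: fixed relative innovation amplitude per site (None = all equal)
    site_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        for k in ("innovation_white", "innovation_pink",
                  "channel_white", "channel_pink"):
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be strictly positive")
        if self.site_weights is not None:
            self.site_weights = np.asarray(self.site_weights, float)

    @classmethod
    def from_config(cls, config: dict | None = None) -> "NoiseSpectrumParams":
        cfg = config if config is not None else load_config()
        n = cfg["noise"]
        return cls(n["innovation_white"], n["innovation_pink"],
                   n["channel_white"], n["channel_pink"], n["exponent"],
                   n.get("site_weights"))

    #: source order the configured site weights refer to
    SITE_ORDER = ("cortex", "striatum", "stn")

    def weights_for(self, sites) -> np.ndarray:
        """Innovation weights for a circuit's (possibly reduced) site list.

        ``sites`` is either a site count (weights assigned positionally)
        or the circuit's innovation populations (weights looked up by
        source, so removing a source removes its weight).
        """
        if isinstance(sites, int):
            n = sites
            if self.site_weights is None:
                return np.ones(n)
            if self.site_weights.size != n:
                raise ValueError(
                    f"{self.site_weights.size} site weights for {n} sites")
            return self.site_weights
        if self.site_weights is None:
            return np.ones(len(sites))
        lookup = dict(zip(self.SITE_ORDER, self.site_weights))
        return np.array([lookup.get(pop.source, 1.0) for pop in sites])

    def innovation_spectrum(self, freqs: np.ndarray,
                            theta: ThetaVector | None = None) -> np.ndarray:
        w, p = self.innovation_white, self.innovation_pink
        if theta is not None:
            w *= math.exp(theta.log_innov_white)
            p *= math.exp(theta.log_innov_pink)
        f = np.maximum(np.asarray(freqs, float), PINK_FLOOR_HZ)
        return w + p / f ** self.exponent

    def channel_spectrum(self, freqs: np.ndarray,
                         theta: ThetaVector | None = None,
                         n_channels: int = 1) -> np.ndarray:
        """Measurement-noise spectra, shape (n_freqs, n_channels)."""
        f = np.maximum(np.asarray(freqs, float), PINK_FLOOR_HZ)
        w = np.full(n_channels, self.channel_white)
        p = self.channel_pink
        if theta is not None:
            lcw = np.atleast_1d(np.asarray(theta.log_chan_white, float))
            if lcw.size == 1:
                lcw = np.repeat(lcw, n_channels)
            w = w * np.exp(lcw)
            p *= math.exp(theta.log_chan_pink)
        return w[None, :] + (p / f ** self.exponent)[:, None]


@dataclass
class CrossSpectralData:
    """Complex Hermitian channel-by-channel spectral matrices on a grid.

    ``S`` has shape (n_freqs, n_channels, n_channels); ``band`` is the
    frequency window of interest (Hz) used for band masks and band power.
    """

    freqs: np.ndarray
    S: np.ndarray
    labels: tuple[str, ...]
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.S = np.asarray(self.S, complex)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.S.shape != (self.freqs.size, n, n):
            raise ValueError(
                f"S shape {self.S.shape} does not match grid/labels")

    @property
    def band_mask(self) -> np.ndarray:
        lo, hi = self.band
        return (self.freqs >= lo) & (self.freqs <= hi)

    def in_band(self) -> "CrossSpectralData":
        m = self.band_mask
        return CrossSpectralData(self.freqs[m], self.S[m], self.labels,
                                 self.band)

    def auto_spectra(self) -> np.ndarray:
        """Real diagonal (n_freqs, n_channels)."""
        return np.real(np.einsum("fii->fi", self.S))

    def band_power(self) -> np.ndarray:
        """Per-channel power integrated over the band (trapezoid rule)."""
        m = self.band_mask
        return np.trapezoid(self.auto_spectra()[m], self.freqs[m], axis=0)

    def is_hermitian(self, tol: float = 0.0) -> bool:
        H = np.conj(np.swapaxes(self.S, 1, 2))
        return bool(np.max(np.abs(self.S - H)) <= tol)

    # -- IO -----------------------------------------------------------------

    def to_hdf5(self, target) -> None:
        """Write to an h5py File/Group or a path."""
        if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
            with h5py.File(target, "w") as fh:
                self.to_hdf5(fh)
            return
        g = target
        g.attrs["format"] = "bgdcm-csd"
        g.attrs["version"] = 1
        g.create_dataset("freqs", data=self.freqs)
        g.create_dataset("S_re", data=self.S.real)
        g.create_dataset("S_im", data=self.S.imag)
        g.create_dataset("labels",
                         data=np.array(self.labels, dtype=h5py.string_dtype()))
        g.create_dataset("band", data=np.asarray(self.band))

    @classmethod
    def from_hdf5(cls, source) -> "CrossSpectralData":
        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
            with h5py.File(source, "r") as fh:
                return cls.from_hdf5(fh)
        g = source
        if g.attrs.get("format") != "bgdcm-csd":
            raise ValueError("not a cross-spectral-density container")
        labels = tuple(s.decode() if isinstance(s, bytes) else str(s)
                       for s in g["labels"][()])
        return cls(g["freqs"][()], g["S_re"][()] + 1j * g["S_im"][()],
                   labels, tuple(g["band"][()]))

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (f, chan_i, chan_j)."""
        rows = []
        for fi, f in enumerate(self.freqs):
            for i, li in enumerate(self.labels):
                for j, lj in enumerate(self.labels):
                    rows.append((f, li, lj, self.S[fi, i, j].real,
                                 self.S[fi, i, j].imag))
        return pd.DataFrame(rows, columns=["f", "chan_i", "chan_j", "re", "im"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Linearization
# ---------------------------------------------------------------------------

def _scaled_params(params: SubpopulationParams,
                   theta: ThetaVector) -> SubpopulationParams:
    return SubpopulationParams(
        He=params.He * math.exp(theta.log_he),
        Hi=params.Hi * math.exp(theta.log_he),
        kappa_e=params.kappa_e * math.exp(theta.log_kappa),
        kappa_i=params.kappa_i * math.exp(theta.log_kappa),
        rho1=params.rho1, rho2=params.rho2,
    )


def linearize(
    circuit: CircuitModel,
    theta: ThetaVector | None = None,
    x0: np.ndarray | None = None,
    condition: str = "on",
    config: dict | None = None,
    check_stability: bool = True,
) -> StateSpace:
    """Jacobian of the state equations at a fixed point, by delay block.

    Coupling terms are differentiated analytically: a connection of gain
    ``c`` contributes ``kappa*H*c*S'(v_pre)`` to the z-equation of its
    target channel, with columns on the presynaptic potential states
    (+v_e, -v_i).  Terms are grouped by the conduction delay they carry so
    the frequency response can apply exact phase factors.
    """
    cfg = config if config is not None else load_config()
    if theta is None:
        theta = ThetaVector.zeros(circuit)
    p = _scaled_params(circuit.params, theta)
    n = circuit.n_states
    n_pop = len(circuit.populations)
    gains = effective_gains(circuit, theta, condition)
    delay_scale = math.exp(theta.log_delay)

    if x0 is None:
        x0 = np.zeros(n)
    xr = np.asarray(x0, float).reshape(n_pop, STATES_PER_POP)
    v0 = xr[:, 0] - xr[:, 2]
    # slope of the centred sigmoid at the linearization potential
    from scipy.special import expit

    z = p.rho1 * (v0 - p.rho2)
    sig = expit(z)
    slope = p.rho1 * sig * (1.0 - sig)

    A0 = np.zeros((n, n))
    for i in range(n_pop):
        b = STATES_PER_POP * i
        A0[b + 0, b + 1] = 1.0
        A0[b + 1, b + 0] = -p.kappa_e ** 2
        A0[b + 1, b + 1] = -2.0 * p.kappa_e
        A0[b + 2, b + 3] = 1.0
        A0[b + 3, b + 2] = -p.kappa_i ** 2
        A0[b + 3, b + 3] = -2.0 * p.kappa_i

    blocks: dict[float, np.ndarray] = {}
    for g, c in zip(gains, circuit.connections):
        i_from = circuit.population_index(c.source_from, c.kind_from)
        i_to = circuit.population_index(c.source_to, c.kind_to)
        if c.sign > 0:
            row = STATES_PER_POP * i_to + 1
            w = p.kappa_e * p.He * g * slope[i_from]
        else:
            row = STATES_PER_POP * i_to + 3
            w = p.kappa_i * p.Hi * g * slope[i_from]
        d = c.delay * delay_scale
        Ad = blocks.setdefault(d, np.zeros((n, n)))
        Ad[row, STATES_PER_POP * i_from + 0] += w
        Ad[row, STATES_PER_POP * i_from + 2] -= w

    if 0.0 in blocks:  # zero-delay couplings belong in A0
        A0 = A0 + blocks.pop(0.0)

    B = np.zeros((n, len(circuit.innovation_sites)))
    for k, pop in enumerate(circuit.innovation_sites):
        i = circuit.population_index(pop.source, pop.kind)
        B[STATES_PER_POP * i + 1, k] = p.kappa_e * p.He

    obs_gain = cfg["observation_gain"]
    C = np.zeros((len(circuit.observation_map), n))
    for ch, (_, pop) in enumerate(circuit.observation_map):
        i = circuit.population_index(pop.source, pop.kind)
        g = obs_gain * math.exp(theta.log_obs[ch])
        C[ch, STATES_PER_POP * i + 0] = g
        C[ch, STATES_PER_POP * i + 2] = -g

    # prune synaptic channels that receive no coupling or innovation:
    # their states are identically zero in the linear system
    driven = np.zeros(n, bool)
    for Ad in blocks.values():
        driven |= np.abs(Ad).sum(axis=1) > 0
    off_kernel = np.abs(A0.copy())
    for i in range(n // 2):  # blank each channel's own kernel entries
        b = 2 * i
        off_kernel[b:b + 2, b:b + 2] = 0.0
    driven |= off_kernel.sum(axis=1) > 0
    driven |= np.abs(B).sum(axis=1) > 0
    keep_ch = np.zeros(n, bool)
    for i in range(2 * n_pop):  # channel index: 2 per population
        b = 2 * i
        if driven[b] or driven[b + 1]:
            keep_ch[b] = keep_ch[b + 1] = True
    keep = np.where(keep_ch)[0]
    if keep.size < n:
        A0 = A0[np.ix_(keep, keep)]
        blocks = {d: Ad[np.ix_(keep, keep)] for d, Ad in blocks.items()}
        B = B[keep]
        C = C[:, keep]

    ss = StateSpace(A0, tuple(sorted(blocks.items())), B, C, keep)
    if check_stability and not ss.is_stable():
        raise UnstableModelError(
            "linearization unstable: zero-delay aggregate Jacobian has an "
            "eigenvalue with non-negative real part")
    return ss


# ---------------------------------------------------------------------------
# Frequency response
# ---------------------------------------------------------------------------

def _resolvent(ss: StateSpace, omega: np.ndarray) -> np.ndarray:
    """(iwI - A0 - sum_d A_d e^{-iwd}) for a vector of angular frequencies."""
    omega = np.atleast_1d(np.asarray(omega, float))
    n = ss.A0.shape[0]
    M = np.zeros((omega.size, n, n), complex)
    M += 1j * omega[:, None, None] * np.eye(n)
    M -= ss.A0
    for d, Ad in ss.delay_blocks:
        M -= np.exp(-1j * omega * d)[:, None, None] * Ad
    return M


def transfer_matrix(ss: StateSpace, omega) -> np.ndarray:
    """Channel-by-innovation transfer function ``T(w) = C M(w)^{-1} B``.

    ``omega`` is in rad/s; scalar input returns a (channels, innovations)
    matrix, vector input a stacked (n_omega, channels, innovations) array.
    """
    scalar = np.isscalar(omega) or np.asarray(omega).ndim == 0
    M = _resolvent(ss, omega)
    try:
        X = np.linalg.solve(M, np.broadcast_to(ss.B, (M.shape[0],) + ss.B.shape))
    except np.linalg.LinAlgError as err:
        raise UnstableModelError(
            f"singular frequency response at omega={omega}") from err
    T = ss.C @ X
    return T[0] if scalar else T


def state_transfer(ss: StateSpace, omega) -> np.ndarray:
    """Transfer from innovations to the full state vector, ``M(w)^{-1} B``."""
    M = _resolvent(ss, np.atleast_1d(omega))
    return np.linalg.solve(M, np.broadcast_to(ss.B, (M.shape[0],) + ss.B.shape))


def predict_csd(
    circuit: CircuitModel,
    theta: ThetaVector | None = None,
    freqs: np.ndarray | None = None,
    condition: str = "on",
    noise: NoiseSpectrumParams | None = None,
    config: dict | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> CrossSpectralData:
    """Predicted channel cross-spectral density matrices.

    Computed as ``S = W W^H + diag(channel noise)`` with
    ``W = T(w) sqrt(G_u(w))``, which is Hermitian positive semidefinite by
    construction (to the last floating-point bit).
    """
    cfg = config if config is not None else load_config()
    if theta is None:
        theta = ThetaVector.zeros(circuit)
    if freqs is None:
        freqs = default_band_grid(cfg)
    if noise is None:
        noise = NoiseSpectrumParams.from_config(cfg)
    freqs = np.asarray(freqs, float)

    ss = linearize(circuit, theta, condition=condition, config=cfg)
    T = transfer_matrix(ss, 2.0 * np.pi * freqs)
    gu = noise.innovation_spectrum(freqs, theta)          # (nf,)
    wts = noise.weights_for(circuit.innovation_sites)
    W = T * np.sqrt(gu)[:, None, None] * wts[None, None, :]
    S = W @ np.conj(np.swapaxes(W, 1, 2))
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))  # exact Hermitian
    nc = T.shape[1]
    ge = noise.channel_spectrum(freqs, theta, nc)         # (nf, nc)
    S = S + ge[:, :, None] * np.eye(nc)[None, :, :]
    return CrossSpectralData(freqs, S, circuit.channel_labels, band)


def source_potential_csd(
    circuit: CircuitModel,
    theta: ThetaVector | None = None,
    freqs: np.ndarray | None = None,
    condition: str = "on",
    noise: NoiseSpectrumParams | None = None,
    config: dict | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> CrossSpectralData:
    """Cross-spectra of each source's principal-population potential.

    Unlike :func:`predict_csd` this covers hidden sources too, uses unit
    read-out gain and adds no measurement noise; it is the quantity the
    perturbation analyses integrate over the beta band.
    """
    cfg = config if config is not None else load_config()
    if theta is None:
        theta = ThetaVector.zeros(circuit)
    if freqs is None:
        freqs = default_band_grid(cfg)
    if noise is None:
        noise = NoiseSpectrumParams.from_config(cfg)
    freqs = np.asarray(freqs, float)

    ss = linearize(circuit, theta, condition=condition, config=cfg)
    X = state_transfer(ss, 2.0 * np.pi * freqs)           # (nf, n_kept, k)
    n = circuit.n_states
    sources = circuit.sources
    Csrc = np.zeros((len(sources), n))
    for r, s in enumerate(sources):
        pop = circuit.principal_population(s)
        i = circuit.population_index(pop.source, pop.kind)
        Csrc[r, STATES_PER_POP * i + 0] = 1.0
        Csrc[r, STATES_PER_POP * i + 2] = -1.0
    if ss.keep is not None:
        Csrc = Csrc[:, ss.keep]
    T = Csrc @ X
    gu = noise.innovation_spectrum(freqs, theta)
    wts = noise.weights_for(circuit.innovation_sites)
    W = T * np.sqrt(gu)[:, None, None] * wts[None, None, :]
    S = W @ np.conj(np.swapaxes(W, 1, 2))
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))  # exact Hermitian
    return CrossSpectralData(freqs, S, sources, band)


def default_band_grid(config: dict | None = None) -> np.ndarray:
    """The inversion frequency grid: the beta window at 1 Hz steps."""
    cfg = config if config is not None else load_config()
    lo, hi = cfg["band"]
    return np.arange(lo, hi + 0.5, 1.0)
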