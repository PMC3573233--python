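"""Synthetic cohorts emulating paired OFF/ON resting-state recordings.

Each synthetic subject is a draw of the circuit's parameters around the
prior mean; the untreated (OFF) state multiplies a configurable subset of
extrinsic gains — by default the hyperdirect cortex->STN, the pallido-
subthalamic GPe->STN and the subthalamo-pallidal STN->GPi connections, each
by 1.5.  At these settings the OFF circuit expresses a pronounced beta-band
(13-35 Hz) resonance in every auto- and cross-spectrum that is attenuated
in the ON state, mirroring the qualitative contrast the pipeline is meant
to recover.

Recordings are synthesized in the frequency domain: independent complex
Gaussian Fourier coefficients with per-bin covariance equal to the model's
predicted source cross-spectrum give a stationary Gaussian series whose
expected periodogram equals the prediction exactly.  Deep sources are then
mixed into three bipolar contact channels through a decaying loading
vector plus independent sensor noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import circuit as circ
from .circuit import CircuitModel, ThetaVector, UnstableModelError
from .features import SegmentRecording
from .forward import (
    CrossSpectralData,
    NoiseSpectrumParams,
    linearize,
    predict_csd,
    state_transfer,
)

#: default OFF/ON gain ratios defining the untreated state
DEFAULT_OFF_RATIOS = {"ctx_stn": 1.5, "gpe_stn": 1.5, "stn_gpi": 1.5}

#: log-normal jitter SD of subject-level gains around the prior mean
SUBJECT_JITTER_SD = 0.1

#: additional segment-to-segment jitter (shared by the OFF/ON pair)
SEGMENT_JITTER_SD = 0.05

#: bipolar contact loading of each deep source (geometric decay)
CONTACT_LOADINGS = (1.0, 0.7, 0.4)

#: sensor-noise variance as a fraction of each contact's signal variance
#: (averaged over the OFF/ON pair: hardware noise does not follow drug state)
SENSOR_NOISE_FRACTION = 0.1

#: required decay margin (s^-1) of the slowest eigenmode when drawing
#: subjects: rejects near-critical draws whose resonance would be
#: pathologically sharp rather than data-like
STABILITY_MARGIN = 4.0

#: phenotype inclusion band: the predicted STN beta band-power ratio
#: OFF/ON must fall in this range, mirroring a cohort in which every
#: patient expresses a clear but finite untreated beta exaggeration
CONTRAST_BOUNDS = (2.5, 50.0)

_COHORT_VERSION = 1


@dataclass
class SegmentPair:
    """Ground truth for one paired OFF/ON segment of one subject.

    ``theta`` holds the segment's parameters: ``log_gain`` carries the
    subject+segment jitter (shared across conditions) and ``log_mod`` the
    true OFF/ON log-ratios.  ``seed_off``/``seed_on`` drive the recording
    synthesis.
    """

    subject: str
    pair_id: str
    theta: ThetaVector
    seed_off: int
    seed_on: int


@dataclass
class SegmentPairSet:
    """A cohort of paired segments with their generating parameters."""

    pairs: list[SegmentPair]
    off_ratios: dict[str, float]
    seed: int
    circuit_name: str = "standard"

    @property
    def subjects(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.subject, None)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Ground-truth generation
# ---------------------------------------------------------------------------

def make_ground_truth(
    n_subjects: int = 5,
    segments_per_condition: int = 3,
    off_ratios: dict[str, float] | None = None,
    seed: int = 0,
    circuit: CircuitModel | None = None,
    config: dict | None = None,
) -> SegmentPairSet:
    """Draw a cohort of subject/segment parameter sets with known truth.

    Subject base gains are log-normal jitters (SD 0.1) of the prior means;
    each segment pair adds a smaller shared jitter (SD 0.05); the OFF
    condition multiplies the gains named in ``off_ratios``.  Draws that are unstable, too close to instability, or outside the
    phenotype contrast band are redrawn (at most 30 times each) before
    failing.  Fully determined by ``seed``.
    """
    if off_ratios is None:
        off_ratios = dict(DEFAULT_OFF_RATIOS)
    if any(r <= 0 for r in off_ratios.values()):
        raise ValueError("off ratios must be strictly positive")
    cfg = config if config is not None else circ.load_config()
    cm = circuit if circuit is not None else circ.build_standard_circuit(cfg)
    ext_names = [c.name for c in cm.extrinsic]
    unknown = set(off_ratios) - set(ext_names)
    if unknown:
        raise KeyError(f"off_ratios name unknown connections {sorted(unknown)}")
    log_mod = np.zeros(len(ext_names))
    for name, r in off_ratios.items():
        log_mod[ext_names.index(name)] = math.log(r)

    rng = np.random.default_rng(seed)
    pairs: list[SegmentPair] = []
    for s in range(n_subjects):
        subject = f"s{s}"
        base = None
        for _ in range(30):
            cand = rng.normal(0.0, SUBJECT_JITTER_SD, len(ext_names))
            if _stable(cm, cand, log_mod, cfg):
                base = cand
                break
        if base is None:
            raise UnstableModelError(
                f"could not draw an admissible subject after 30 attempts ({subject})")
        for g in range(segments_per_condition):
            theta = None
            for _ in range(30):
                jit = base + rng.normal(0.0, SEGMENT_JITTER_SD, len(ext_names))
                if _stable(cm, jit, log_mod, cfg):
                    theta = ThetaVector.zeros(cm)
                    theta.log_gain[:] = jit
                    theta.log_mod[:] = log_mod
                    break
            if theta is None:
                raise UnstableModelError(
                    f"could not draw an admissible segment after 30 attempts "
                    f"({subject}/pair{g})")
            seed_off = int(rng.integers(0, 2 ** 31 - 1))
            seed_on = int(rng.integers(0, 2 ** 31 - 1))
            pairs.append(SegmentPair(subject, f"{subject}_p{g}", theta,
                                     seed_off, seed_on))
    return SegmentPairSet(pairs, dict(off_ratios), seed, cm.name)


def _stable(cm: CircuitModel, log_gain: np.ndarray, log_mod: np.ndarray,
            cfg: dict) -> bool:
    """Admissibility of a draw: stable with margin, phenotype expressed.

    Besides dynamical stability, the draw must predict a clear but finite
    untreated beta exaggeration on the STN channel (the cohort emulates
    patients in whom the phenotype is present in every recording).
    """
    th = ThetaVector.zeros(cm)
    th.log_gain[:] = log_gain
    th.log_mod[:] = log_mod
    try:
        for cond in ("off", "on"):
            ss = linearize(cm, th, condition=cond, config=cfg)
            if np.max(np.linalg.eigvals(ss.aggregate).real) > -STABILITY_MARGIN:
                return False
        freqs = np.arange(13.0, 35.5, 1.0)
        bp = {cond: predict_csd(cm, th, freqs, cond,
                                config=cfg).band_power()
              for cond in ("off", "on")}
    except UnstableModelError:
        return False
    if np.any(log_mod != 0) and "stn" in cm.channel_labels:
        # the contrast band only constrains cohorts with a drug effect
        stn = cm.channel_labels.index("stn")
        contrast = bp["off"][stn] / bp["on"][stn]
        if not (CONTRAST_BOUNDS[0] <= contrast <= CONTRAST_BOUNDS[1]):
            return False
    return True


# ---------------------------------------------------------------------------
# Recording synthesis
# ---------------------------------------------------------------------------

def _observed_signal_csd(cm: CircuitModel, theta: ThetaVector,
                         condition: str, freqs: np.ndarray,
                         cfg: dict) -> np.ndarray:
    """Cross-spectrum of the observed channels' noiseless signals."""
    csd = predict_csd(cm, theta, freqs, condition, config=cfg)
    noise = NoiseSpectrumParams.from_config(cfg)
    nc = len(csd.labels)
    ge = noise.channel_spectrum(freqs, theta, nc)
    S = csd.S - ge[:, :, None] * np.eye(nc)[None, :, :]
    return S


def _synthesize_gaussian(S_interp: np.ndarray, n: int, fs: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Real multichannel series whose expected one-sided periodogram
    (density convention) equals the supplied per-bin spectra.

    ``S_interp`` has shape (n_bins, k, k) on the rfft grid of an n-sample
    series; bin 0 (DC) and the Nyquist bin are zeroed.
    """
    n_bins, k, _ = S_interp.shape
    # eigen square root per bin (Hermitian PSD by construction upstream)
    w, V = np.linalg.eigh(S_interp)
    L = V * np.sqrt(np.maximum(w, 0.0))[:, None, :]
    xi = rng.standard_normal((n_bins, k)) + 1j * rng.standard_normal((n_bins, k))
    X = np.einsum("fij,fj->fi", L, xi) * math.sqrt(n * fs / 4.0)
    X[0] = 0.0
    if n % 2 == 0:
        X[-1] = 0.0
    return np.fft.irfft(X, n=n, axis=0).T  # (k, n)


def simulate_recording(
    theta: ThetaVector,
    condition: str,
    duration: float = 50.0,
    fs: float = 1000.0,
    seed: int = 0,
    circuit: CircuitModel | None = None,
    config: dict | None = None,
    subject: str = "s0",
    segment: str = "seg0",
    interp_points: int = 2048,
    sensor_fraction: float = SENSOR_NOISE_FRACTION,
    loadings: tuple[float, ...] = CONTACT_LOADINGS,
) -> SegmentRecording:
    """Synthesize one multichannel segment from the linearized circuit.

    The three observed-source signals are generated jointly from their
    predicted cross-spectrum (computed on a coarse grid and interpolated to
    the FFT bins); each deep source is mixed into three bipolar contact
    channels through the loading vector (1.0, 0.7, 0.4) and every channel
    receives independent white sensor noise at 10% of its signal variance.
    Bit-reproducible given ``seed``.
    """
    cfg = config if config is not None else circ.load_config()
    cm = circuit if circuit is not None else circ.build_standard_circuit(cfg)
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)

    grid = np.linspace(0.25, fs / 2.0, interp_points)
    S_grid = _observed_signal_csd(cm, theta, condition, grid, cfg)
    # condition-independent sensor-noise levels: a fraction of the signal
    # variance predicted for this parameter set in the quieter (ON) state,
    # so the same hardware floor applies to both recordings of a pair
    # without burying the weaker one
    var_conds = []
    for cond in ("off", "on"):
        Sc = S_grid if cond == condition else \
            _observed_signal_csd(cm, theta, cond, grid, cfg)
        var_conds.append(np.trapezoid(
            np.real(np.einsum("fii->fi", Sc)), grid, axis=0))
    sensor_var = sensor_fraction * np.minimum(*var_conds)
    bin_freqs = np.fft.rfftfreq(n, 1.0 / fs)
    k = S_grid.shape[1]
    S_bins = np.empty((bin_freqs.size, k, k), complex)
    for i in range(k):
        for j in range(k):
            S_bins[:, i, j] = (
                np.interp(bin_freqs, grid, S_grid[:, i, j].real)
                + 1j * np.interp(bin_freqs, grid, S_grid[:, i, j].imag)
            )
    # re-Hermitianize after componentwise interpolation
    S_bins = 0.5 * (S_bins + np.conj(np.swapaxes(S_bins, 1, 2)))
    sources = _synthesize_gaussian(S_bins, n, fs, rng)  # (3, n): ctx, stn, gpi

    labels: list[str] = []
    rows: list[np.ndarray] = []
    loads = np.asarray(loadings)
    for ch, label in enumerate(("ctx", "stn", "gpi")):
        if label == "ctx":
            noise = rng.standard_normal(n) * math.sqrt(sensor_var[ch])
            rows.append(sources[ch] + noise)
            labels.append("ctx")
        else:
            for ci, l in enumerate(loads):
                noise = rng.standard_normal(n) * math.sqrt(
                    l ** 2 * sensor_var[ch])
                rows.append(l * sources[ch] + noise)
                labels.append(f"{label}_{ci}{ci + 1}")
    return SegmentRecording(np.vstack(rows), tuple(labels), fs, condition,
                            subject, segment)


def simulate_pair(pair: SegmentPair, duration: float = 50.0,
                  fs: float = 1000.0, circuit: CircuitModel | None = None,
                  config: dict | None = None
                  ) -> tuple[SegmentRecording, SegmentRecording]:
    """OFF and ON recordings for one ground-truth segment pair."""
    off = simulate_recording(pair.theta, "off", duration, fs, pair.seed_off,
                             circuit, config, pair.subject, pair.pair_id)
    on = simulate_recording(pair.theta, "on", duration, fs, pair.seed_on,
                            circuit, config, pair.subject, pair.pair_id)
    return off, on


# ---------------------------------------------------------------------------
# Time-domain backend (independent of the spectral synthesis path)
# ---------------------------------------------------------------------------

def _colored_noise(spectrum_fn, n: int, fs: float,
                   rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Independent real series with the given one-sided density spectrum."""
    bin_freqs = np.fft.rfftfreq(n, 1.0 / fs)
    g = spectrum_fn(bin_freqs)  # (n_bins,)
    amp = np.sqrt(np.maximum(g, 0.0) * n * fs / 4.0)
    xi = rng.standard_normal(shape + (bin_freqs.size,)) \
        + 1j * rng.standard_normal(shape + (bin_freqs.size,))
    X = amp * xi
    X[..., 0] = 0.0
    if n % 2 == 0:
        X[..., -1] = 0.0
    return np.fft.irfft(X, n=n, axis=-1)


def simulate_channels_timedomain(
    theta: ThetaVector,
    condition: str,
    duration: float = 200.0,
    fs: float = 1000.0,
    seed: int = 0,
    circuit: CircuitModel | None = None,
    config: dict | None = None,
    oversample: int = 4,
    include_channel_noise: bool = True,
) -> tuple[np.ndarray, float]:
    """Integrate the linearized delay system through time (Heun scheme).

    This backend shares nothing with the frequency-domain synthesis beyond
    the linearization itself: states are stepped at ``oversample * fs``
    with conduction delays as sample shifts, driven by white + 1/f
    innovations, then the observation matrix and (optionally) measurement
    noise produce the channel series, decimated back to ``fs``.  Returns
    ``(channels, fs)`` with channels shaped (n_channels, n_samples).
    """
    cfg = config if config is not None else circ.load_config()
    cm = circuit if circuit is not None else circ.build_standard_circuit(cfg)
    ss = linearize(cm, theta, condition=condition, config=cfg)
    noise = NoiseSpectrumParams.from_config(cfg)
    dt = 1.0 / (fs * oversample)
    n_hi = int(round(duration * fs)) * oversample
    rng = np.random.default_rng(seed)

    n_sites = len(cm.innovation_sites)
    wts = noise.weights_for(n_sites)
    u = _colored_noise(lambda f: noise.innovation_spectrum(f, theta),
                       n_hi, fs * oversample, rng, (n_sites,))
    u *= wts[:, None]
    # innovations are defined per unit bandwidth at the analysis rate; the
    # white part extends to the simulation Nyquist unchanged, which is what
    # the flat spectrum above already gives.

    delays = [max(1, int(round(d / dt))) for d, _ in ss.delay_blocks]
    blocks = [Ad for _, Ad in ss.delay_blocks]
    max_lag = max(delays, default=0)
    nst = ss.A0.shape[0]
    hist = np.zeros((max_lag + 1, nst))  # ring buffer of past states
    Bu = ss.B @ u  # (nst, n_hi)

    out = np.empty((n_hi, ss.C.shape[0]))
    x = np.zeros(nst)
    head = 0
    for t in range(n_hi):
        lagged = np.zeros(nst)
        for lag, Ad in zip(delays, blocks):
            lagged += Ad @ hist[(head - lag) % (max_lag + 1)]
        f1 = ss.A0 @ x + lagged + Bu[:, t]
        x_pred = x + dt * f1
        f2 = ss.A0 @ x_pred + lagged + Bu[:, t]
        x = x + 0.5 * dt * (f1 + f2)
        head = (head + 1) % (max_lag + 1)
        hist[head] = x
        out[t] = ss.C @ x

    y = out[::oversample].T  # (n_channels, n_samples)
    if include_channel_noise:
        n = y.shape[1]
        nc = y.shape[0]
        for c in range(nc):
            e = _colored_noise(
                lambda f: noise.channel_spectrum(f, theta, nc)[:, c],
                n, fs, rng, ())
            y[c] += e
    return y, fs


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

def write_cohort(cohort: SegmentPairSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "bgdcm-cohort"
        fh.attrs["version"] = _COHORT_VERSION
        fh.attrs["seed"] = cohort.seed
        fh.attrs["circuit_name"] = cohort.circuit_name
        names = sorted(cohort.off_ratios)
        fh.create_dataset("off_ratio_names",
                          data=np.array(names, dtype=h5py.string_dtype()))
        fh.create_dataset("off_ratio_values",
                          data=np.array([cohort.off_ratios[n] for n in names]))
        for i, p in enumerate(cohort.pairs):
            g = fh.create_group(f"pair{i:03d}")
            g.attrs["subject"] = p.subject
            g.attrs["pair_id"] = p.pair_id
            g.attrs["seed_off"] = p.seed_off
            g.attrs["seed_on"] = p.seed_on
            g.create_dataset("theta", data=p.theta.pack())


def read_cohort(path, circuit: CircuitModel | None = None) -> SegmentPairSet:
    cm = circuit if circuit is not None else circ.build_standard_circuit()
    try:
        fh = h5py.File(path, "r")
    except OSError as err:
        raise ValueError(f"unreadable cohort container: {err}") from err
    with fh:
        if fh.attrs.get("format") != "bgdcm-cohort":
            raise ValueError("not a cohort container")
        if int(fh.attrs.get("version", -1)) != _COHORT_VERSION:
            raise ValueError(
                f"incompatible cohort version {fh.attrs.get('version')!r} "
                f"(expected {_COHORT_VERSION})")
        names = [s.decode() if isinstance(s, bytes) else str(s)
                 for s in fh["off_ratio_names"][()]]
        ratios = dict(zip(names, fh["off_ratio_values"][()].tolist()))
        pairs = []
        for key in sorted(k for k in fh.keys() if k.startswith("pair")):
            g = fh[key]
            pairs.append(SegmentPair(
                str(g.attrs["subject"]), str(g.attrs["pair_id"]),
                ThetaVector.unpack(g["theta"][()], cm),
                int(g.attrs["seed_off"]), int(g.attrs["seed_on"])))
        return SegmentPairSet(pairs, ratios, int(fh.attrs["seed"]),
                              str(fh.attrs["circuit_name"]))
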