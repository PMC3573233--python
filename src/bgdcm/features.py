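"""Data features: from raw multichannel segments to cross-spectral densities.

The fitted data features are not raw periodograms but parametric spectra:
each deep site's three bipolar contacts are reduced to their first
principal component (leading eigenvariate), the cortical EEG channel plus
the two eigenvariates form a three-channel series, a vector autoregression
of order 8 is fitted with zero-mean shrinkage (ridge) priors on the
coefficients, and the VAR model is transformed analytically to
cross-spectral density matrices

    H(w) = (I - sum_k A_k exp(-i w k / fs))^{-1},   S(w) = H E H*

restricted to the 13-35 Hz window.  The normalization is fixed by the
white-noise identity: with all A_k = 0 the spectrum equals the innovation
covariance E.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import DEFAULT_BAND, CrossSpectralData

#: bipolar contact channels per deep site
CONTACTS_PER_SITE = 3

#: default ridge penalty on VAR coefficients (precision of the zero-mean
#: Gaussian shrinkage prior, in units of the innovation precision)
DEFAULT_RIDGE = 1.0

DEFAULT_VAR_ORDER = 8


# ---------------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------------

@dataclass
class SegmentRecording:
    """One resting-state segment: labelled channel-by-sample matrix.

    Channel layout follows the recording montage: one bipolar EEG channel
    (``ctx``) and three bipolar contacts for each deep site
    (``stn_01 stn_12 stn_23 gpi_01 gpi_12 gpi_23``).
    """

    channels: np.ndarray
    labels: tuple[str, ...]
    fs: float = 1000.0
    condition: str = "off"
    subject: str = "s0"
    segment: str = "seg0"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, float)
        self.labels = tuple(self.labels)
        if self.channels.ndim != 2 or self.channels.shape[0] != len(self.labels):
            raise ValueError("channels must be (n_channels, n_samples) "
                             "matching labels")
        if self.condition not in ("off", "on"):
            raise ValueError("condition must be 'off' or 'on'")
        if self.duration < 10.0:
            raise ValueError(
                f"segment too short ({self.duration:.1f} s < 10 s)")
        for site in ("stn", "gpi"):
            if len(self.site_channels(site)) != CONTACTS_PER_SITE:
                raise ValueError(f"{site} must contribute exactly "
                                 f"{CONTACTS_PER_SITE} bipolar channels")
        if "ctx" not in self.labels:
            raise ValueError("missing cortical channel 'ctx'")

    @property
    def duration(self) -> float:
        return self.channels.shape[1] / self.fs

    def site_channels(self, site: str) -> list[int]:
        return [i for i, l in enumerate(self.labels)
                if l.startswith(site + "_")]

    def site_matrix(self, site: str) -> np.ndarray:
        return self.channels[self.site_channels(site)]

    # -- IO -----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """CSV matrix of samples plus a JSON sidecar with the metadata."""
        path = Path(path)
        pd.DataFrame(self.channels.T, columns=list(self.labels)).to_csv(
            path, index=False)
        sidecar = {"fs": self.fs, "condition": self.condition,
                   "subject": self.subject, "segment": self.segment,
                   "labels": list(self.labels)}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path) -> "SegmentRecording":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path)
        return cls(df[meta["labels"]].to_numpy().T, tuple(meta["labels"]),
                   meta["fs"], meta["condition"], meta["subject"],
                   meta["segment"])

    def to_hdf5(self, target) -> None:
        if isinstance(target, (str, bytes)) or hasattr(target, "__fspath__"):
            with h5py.File(target, "w") as fh:
                self.to_hdf5(fh)
            return
        g = target
        g.attrs["format"] = "bgdcm-recording"
        g.attrs["version"] = 1
        g.attrs["fs"] = self.fs
        g.attrs["condition"] = self.condition
        g.attrs["subject"] = self.subject
        g.attrs["segment"] = self.segment
        g.create_dataset("channels", data=self.channels)
        g.create_dataset("labels",
                         data=np.array(self.labels, dtype=h5py.string_dtype()))

    @classmethod
    def from_hdf5(cls, source) -> "SegmentRecording":
        if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
            with h5py.File(source, "r") as fh:
                return cls.from_hdf5(fh)
        g = source
        if g.attrs.get("format") != "bgdcm-recording":
            raise ValueError("not a recording container")
        labels = tuple(s.decode() if isinstance(s, bytes) else str(s)
                       for s in g["labels"][()])
        return cls(g["channels"][()], labels, float(g.attrs["fs"]),
                   str(g.attrs["condition"]), str(g.attrs["subject"]),
                   str(g.attrs["segment"]))


def read_edf(path, **kwargs) -> SegmentRecording:  # pragma: no cover
    """Optional EDF import (requires the ``mne`` package)."""
    try:
        import mne
    except ImportError as err:
        raise ImportError("EDF support requires the optional 'mne' "
                          "package") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return SegmentRecording(raw.get_data(), tuple(raw.ch_names),
                            raw.info["sfreq"], **kwargs)


# ---------------------------------------------------------------------------
# PCA eigenvariate
# ---------------------------------------------------------------------------

def first_principal_component(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvariate of a contacts-by-samples matrix.

    Channels are mean-centred (no variance normalization: bipolar contacts
    share units) and the SVD's first left singular vector defines the
    component; its sign is fixed so the largest-magnitude loading is
    positive.  Returns the component time series and the fraction of total
    variance it explains.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (channels >= 2, samples) matrix")
    if X.shape[1] <= X.shape[0]:
        raise ValueError("need more samples than channels")
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = Xc.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant channel: principal component undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    u1 = U[:, 0]
    if u1[np.argmax(np.abs(u1))] < 0:
        u1 = -u1
    series = u1 @ Xc
    variance_fraction = float(s[0] ** 2 / np.sum(s ** 2))
    return series, variance_fraction


# ---------------------------------------------------------------------------
# Bayesian (shrinkage) VAR
# ---------------------------------------------------------------------------

@dataclass
class VarModel:
    """Vector autoregression: coefficients ``A`` (order, k, k) and
    innovation covariance ``E`` (k, k)."""

    A: np.ndarray
    E: np.ndarray
    labels: tuple[str, ...] = ()
    fs: float = 1000.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, float)
        self.E = np.asarray(self.E, float)
        if self.A.ndim != 3 or self.A.shape[1] != self.A.shape[2]:
            raise ValueError("A must have shape (order, k, k)")
        if self.A.shape[0] < 1:
            raise ValueError("order must be >= 1")
        if self.E.shape != self.A.shape[1:]:
            raise ValueError("E must be (k, k)")
        if not self.labels:
            self.labels = tuple(f"ch{i}" for i in range(self.A.shape[1]))
        if not np.allclose(self.E, self.E.T):
            raise ValueError("E must be symmetric")
        if np.min(np.linalg.eigvalsh((self.E + self.E.T) / 2)) < -1e-10:
            raise ValueError("E must be positive semidefinite")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    @property
    def n_channels(self) -> int:
        return self.A.shape[1]


def fit_var(Y: np.ndarray, order: int = DEFAULT_VAR_ORDER,
            ridge: float = DEFAULT_RIDGE, labels: tuple[str, ...] = (),
            fs: float = 1000.0) -> VarModel:
    """Conditional-mean VAR estimate under a zero-mean shrinkage prior.

    The coefficient prior is an isotropic zero-mean Gaussian whose
    precision, relative to the innovation precision, is ``ridge``; the
    posterior mean is then the ridge-regularized least-squares solution,
    computed per equation on the lagged design matrix.  ``E`` is the
    residual covariance.  Deterministic given ``Y``.
    """
    Y = np.asarray(Y, float)
    if Y.ndim != 2:
        raise ValueError("Y must be (channels, samples)")
    k, T = Y.shape
    if T <= 10 * order * k:
        raise ValueError(f"series too short (T={T}) for order {order}")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    # standardize per channel so the shrinkage prior is scale-free; the
    # coefficients and innovation covariance are mapped back afterwards
    sd = Yc.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant channel")
    Ys = Yc / sd[:, None]

    # design: Z[t] = [y(t-1); ...; y(t-p)], target y(t)
    p = order
    rows = [Ys[:, p - l:T - l] for l in range(1, p + 1)]
    Z = np.concatenate(rows, axis=0)              # (k*p, T-p)
    Yt = Ys[:, p:]                                # (k, T-p)
    G = Z @ Z.T
    Greg = G + ridge * np.eye(G.shape[0])
    if np.linalg.matrix_rank(Greg) < G.shape[0]:
        raise ValueError("rank-deficient regressors")
    B = np.linalg.solve(Greg, Z @ Yt.T).T         # (k, k*p)
    resid = Yt - B @ Z
    E = resid @ resid.T / resid.shape[1]
    A = B.reshape(k, p, k).transpose(1, 0, 2)
    A = A * (sd[None, :, None] / sd[None, None, :])
    E = E * np.outer(sd, sd)
    if not labels:
        labels = tuple(f"ch{i}" for i in range(k))
    return VarModel(A, (E + E.T) / 2, tuple(labels), fs)


def var_from_spectrum(freqs: np.ndarray, S: np.ndarray, fs: float,
                      order: int = DEFAULT_VAR_ORDER) -> VarModel:
    """Project an arbitrary spectral density onto the VAR(p) family.

    Computes the process autocovariances ``C(l)`` by numerically
    integrating the one-sided cross-spectrum over [0, fs/2] and solves the
    multivariate Yule-Walker equations for the best order-``p``
    autoregression.  This is the population analogue of fitting a VAR to a
    long sample of the process: pushing model predictions through it puts
    them behind the same parametric lens as VAR-estimated data features.
    """
    freqs = np.asarray(freqs, float)
    S = np.asarray(S, complex)
    k = S.shape[1]
    # C(l) = (2/fs) int_0^{fs/2} Re[S(f) exp(i 2 pi f l / fs)] df
    lags = np.arange(order + 1)
    phase = np.exp(1j * 2 * np.pi * freqs[:, None] * lags[None, :] / fs)
    C = np.empty((order + 1, k, k))
    for l in lags:
        integrand = np.real(S * phase[:, l, None, None])
        C[l] = np.trapezoid(integrand, freqs, axis=0) * 2.0 / fs
    # block-Toeplitz Yule-Walker, solved for B = [A_1^T; ...; A_p^T]:
    # C(l)^T = sum_j C(l-j)^T A_j^T, with C(-m) = C(m)^T
    R = np.empty((order * k, order * k))
    for i in range(1, order + 1):
        for j in range(1, order + 1):
            l = i - j
            blk = C[l].T if l >= 0 else C[-l]
            R[(i - 1) * k:i * k, (j - 1) * k:j * k] = blk
    r = np.concatenate([C[l].T for l in range(1, order + 1)], axis=0)
    try:
        B = np.linalg.solve(R, r)
    except np.linalg.LinAlgError as err:
        raise ValueError("degenerate autocovariance sequence") from err
    A = np.stack([B[l * k:(l + 1) * k].T for l in range(order)])
    E = C[0] - sum(A[l] @ C[l + 1].T for l in range(order))
    E = (E + E.T) / 2
    # guard tiny negative eigenvalues from quadrature error
    w, V = np.linalg.eigh(E)
    E = V @ np.diag(np.maximum(w, 1e-300)) @ V.T
    return VarModel(A, (E + E.T) / 2, tuple(f"ch{i}" for i in range(k)), fs)


def var_csd(model: VarModel, freqs: np.ndarray, fs: float | None = None,
            band: tuple[float, float] = DEFAULT_BAND) -> CrossSpectralData:
    """Analytic cross-spectral density of a fitted VAR model.

    Uses the standard spectral factorization of a VAR process,
    ``S(w) = H(w) E H(w)*`` with ``H = (I - sum_k A_k z^{-k})^{-1}``,
    normalized so a pure white-noise model returns S = E at every
    frequency.  Frequencies where the AR polynomial is near-singular are
    reported in the raised error.
    """
    if fs is None:
        fs = model.fs
    freqs = np.asarray(freqs, float)
    k = model.n_channels
    z = np.exp(-1j * 2 * np.pi * freqs[:, None] / fs
               * np.arange(1, model.order + 1)[None, :])  # (nf, p)
    Apoly = np.eye(k) - np.einsum("fp,pij->fij", z, model.A)
    cond = np.linalg.cond(Apoly)
    bad = np.where(cond > 1e12)[0]
    if bad.size:
        raise ValueError(
            f"AR polynomial near-singular at frequencies {freqs[bad]}")
    H = np.linalg.inv(Apoly)
    # exact-Hermitian construction via the matrix square root of E
    w_eig, V = np.linalg.eigh((model.E + model.E.T) / 2)
    Esqrt = V @ np.diag(np.sqrt(np.maximum(w_eig, 0.0))) @ V.T
    W = H @ Esqrt
    S = W @ np.conj(np.swapaxes(W, 1, 2))
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))  # exact Hermitian
    return CrossSpectralData(freqs, S, model.labels, band)


# ---------------------------------------------------------------------------
# Full feature pipeline
# ---------------------------------------------------------------------------

#: decimation factor applied before the VAR stage (1 kHz -> 200 Hz): a
#: fixed-order VAR's spectral resolution is set by its lag depth, and
#: eight lags at the recording rate span only 8 ms — too short to resolve
#: a beta-band peak.  At 200 Hz the same order spans 40 ms.
DEFAULT_DECIMATE = 5


def extract_features(
    segment: SegmentRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_VAR_ORDER,
    ridge: float = DEFAULT_RIDGE,
    freq_step: float = 1.0,
    decimate: int = DEFAULT_DECIMATE,
) -> CrossSpectralData:
    """Segment -> band-limited cross-spectral data features.

    Pipeline: first principal component per deep site, assembly of the
    (cortex, STN, GPi) three-channel series, zero-phase anti-aliased
    decimation, shrinkage VAR(``order``) fit, analytic spectral transform,
    band mask.  Deterministic.
    """
    from scipy.signal import decimate as _decimate

    ctx = segment.channels[segment.labels.index("ctx")]
    stn, _ = first_principal_component(segment.site_matrix("stn"))
    gpi, _ = first_principal_component(segment.site_matrix("gpi"))
    Y = np.vstack([ctx, stn, gpi])
    fs = segment.fs
    if decimate > 1:
        Y = _decimate(Y, decimate, axis=1, zero_phase=True)
        fs = fs / decimate
    model = fit_var(Y, order=order, ridge=ridge,
                    labels=("ctx", "stn", "gpi"), fs=fs)
    freqs = np.arange(band[0], band[1] + freq_step / 2, freq_step)
    return var_csd(model, freqs, fs, band)


def debias(csd: CrossSpectralData, bias: CrossSpectralData
           ) -> CrossSpectralData:
    """Subtract a bootstrap-estimated estimation bias from data features."""
    if csd.S.shape != bias.S.shape:
        raise ValueError("bias container shape mismatch")
    return CrossSpectralData(csd.freqs, csd.S - bias.S, csd.labels, csd.band)


def simulate_var(model: VarModel, T: int, seed: int = 0,
                 burn: int = 500) -> np.ndarray:
    """Sample a (channels, T) series from a fitted VAR model."""
    rng = np.random.default_rng(seed)
    k, p = model.n_channels, model.order
    L = np.linalg.cholesky(model.E + 1e-12 * np.trace(model.E) / k * np.eye(k))
    e = rng.standard_normal((T + burn, k)) @ L.T
    y = np.zeros((T + burn, k))
    A = model.A
    for t in range(p, T + burn):
        acc = e[t].copy()
        for l in range(p):
            acc += A[l] @ y[t - 1 - l]
        y[t] = acc
    return y[burn:].T


def feature_noise(
    segment: SegmentRecording,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_VAR_ORDER,
    ridge: float = DEFAULT_RIDGE,
    freq_step: float = 1.0,
    decimate: int = DEFAULT_DECIMATE,
    n_boot: int = 6,
    seed: int = 0,
) -> CrossSpectralData:
    """Parametric-bootstrap estimate of feature sampling variance and bias.

    Surrogate series of the segment's length are simulated from the VAR
    model fitted to the segment itself, the feature pipeline's VAR stage
    is re-run on each, and the surrogate features' empirical variance and
    mean offset estimate the sampling variance and the finite-sample
    estimation bias of the data features.  Deterministic given ``seed``.
    Returns ``(variance, bias)`` containers; variance entries hold the
    variance of the real part in their real part and of the imaginary
    part in their imaginary part.
    """
    from scipy.signal import decimate as _decimate

    ctx = segment.channels[segment.labels.index("ctx")]
    stn, _ = first_principal_component(segment.site_matrix("stn"))
    gpi, _ = first_principal_component(segment.site_matrix("gpi"))
    Y = np.vstack([ctx, stn, gpi])
    fs = segment.fs
    if decimate > 1:
        Y = _decimate(Y, decimate, axis=1, zero_phase=True)
        fs = fs / decimate
    model = fit_var(Y, order=order, ridge=ridge,
                    labels=("ctx", "stn", "gpi"), fs=fs)
    freqs = np.arange(band[0], band[1] + freq_step / 2, freq_step)
    T = Y.shape[1]
    stack = []
    for b in range(n_boot):
        Yb = simulate_var(model, T, seed=seed + b)
        mb = fit_var(Yb, order=order, ridge=ridge,
                     labels=model.labels, fs=fs)
        stack.append(var_csd(mb, freqs, fs, band).S)
    A = np.stack(stack)
    var = A.real.var(axis=0, ddof=1) + 1j * A.imag.var(axis=0, ddof=1)
    bias = A.mean(axis=0) - var_csd(model, freqs, fs, band).S
    return CrossSpectralData(freqs, var, model.labels, band), \
        CrossSpectralData(freqs, bias, model.labels, band)
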