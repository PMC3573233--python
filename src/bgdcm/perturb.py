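"""Contribution and lesion analyses on fitted or synthetic parameter sets.

Contribution analysis quantifies each connection's beta-promoting potency
as the sensitivity dbeta/dc of band-limited (13-35 Hz) oscillatory power
beta, summed over every source in the circuit (hidden sources included
through their state spectra), to a small change in that connection's gain
c.  Small perturbations probe the operating circuit without reconfiguring
it to a different steady state.

Lesion analysis removes the subthalamic nucleus either by zeroing all of
its afferent and efferent connection gains or by deleting the source from
the model; the two are equivalent for every quantity expressed over the
remaining sources.  Partial lesions reset a single connection to its
treated (ON) strength while the rest of the circuit stays in the
untreated (OFF) configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .circuit import (
    STN,
    CircuitModel,
    ThetaVector,
    UnstableModelError,
    effective_gains,
)
from .forward import DEFAULT_BAND, CrossSpectralData, source_potential_csd

#: default relative finite-difference step on a connection gain
DEFAULT_REL_STEP = 1e-3

#: frequency resolution (Hz) of the band grid used for beta integrals
BETA_GRID_STEP = 0.25


def _band_grid(band: tuple[float, float]) -> np.ndarray:
    return np.arange(band[0], band[1] + BETA_GRID_STEP / 2, BETA_GRID_STEP)


@dataclass
class BetaSummary:
    """Band-limited oscillatory power by source and in total."""

    per_source: "pd.Series"
    beta: float
    band: tuple[float, float]
    condition: str

    @classmethod
    def from_csd(cls, csd: CrossSpectralData, condition: str) -> "BetaSummary":
        powers = csd.band_power()
        per_source = pd.Series(powers, index=list(csd.labels))
        return cls(per_source, float(powers.sum()), csd.band, condition)


def beta_power(
    circuit: CircuitModel,
    theta: ThetaVector,
    condition: str = "off",
    config: dict | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    gains: np.ndarray | None = None,
) -> BetaSummary:
    """Network beta power: band-integrated source spectra, all sources.

    Hidden sources contribute through their state spectra — the summary
    covers the whole circuit, not only the recorded channels.  ``gains``
    optionally overrides the effective connection gains (used by the
    finite-difference and lesion machinery).
    """
    csd = _source_csd(circuit, theta, condition, config, band, gains)
    return BetaSummary.from_csd(csd, condition)


def _source_csd(circuit, theta, condition, config, band, gains=None
                ) -> CrossSpectralData:
    if gains is None:
        return source_potential_csd(circuit, theta, _band_grid(band),
                                    condition, config=config, band=band)
    # route an explicit gain vector through a gain-carrying circuit copy
    mod = circuit.with_gains({c.name: g for c, g in
                              zip(circuit.connections, gains)})
    th = theta.copy()
    th.log_gain[:] = 0.0
    th.log_mod[:] = 0.0
    return source_potential_csd(mod, th, _band_grid(band), condition,
                                config=config, band=band)


def contribution(
    circuit: CircuitModel,
    theta: ThetaVector,
    connection: str,
    condition: str = "off",
    rel_step: float = DEFAULT_REL_STEP,
    config: dict | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Sensitivity of beta activity to one connection's gain.

    Central finite difference of the source spectra with respect to the
    connection gain, evaluated at the condition's effective gains.
    Returns ``(dbeta_dc, freqs, profile)``: the frequency profile is the
    per-frequency derivative averaged (unweighted) over sources, and the
    scalar is its average over the band.  If the stencil leaves the
    stable region the step is shrunk once (by 10x) before failing.
    """
    j = circuit.connection_index(connection)
    gains = effective_gains(circuit, theta, condition)
    c0 = gains[j]
    if c0 <= 0:
        raise ValueError(f"connection {connection!r} has zero gain; "
                         "contribution undefined")
    step = rel_step
    for attempt in range(2):
        delta = step * c0
        try:
            up = gains.copy(); up[j] = c0 + delta
            dn = gains.copy(); dn[j] = c0 - delta
            csd_up = _source_csd(circuit, theta, condition, config, band, up)
            csd_dn = _source_csd(circuit, theta, condition, config, band, dn)
        except UnstableModelError:
            if attempt == 0:
                step = step / 10.0
                continue
            raise
        break
    freqs = csd_up.freqs
    d_auto = (csd_up.auto_spectra() - csd_dn.auto_spectra()) / (2.0 * delta)
    profile = d_auto.mean(axis=1)  # unweighted mean over sources
    dbeta_dc = float(profile.mean())
    return dbeta_dc, freqs, profile


def contribution_table(
    circuit: CircuitModel,
    theta: ThetaVector,
    config: dict | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Per-connection contribution in both conditions, with differences."""
    rows = []
    for c in circuit.extrinsic:
        vals = {}
        for cond in ("off", "on"):
            vals[cond], _, _ = contribution(circuit, theta, c.name, cond,
                                            config=config, band=band)
        rows.append((c.name, vals["on"], vals["off"],
                     vals["off"] - vals["on"]))
    return pd.DataFrame(rows, columns=["connection", "contribution_on",
                                       "contribution_off", "difference"])


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------

def _restrict_theta(circuit: CircuitModel, sub: CircuitModel,
                    theta: ThetaVector) -> ThetaVector:
    """Map a parameter vector onto a circuit with sources removed."""
    ext_old = {c.name: k for k, c in enumerate(circuit.extrinsic)}
    th = ThetaVector.zeros(sub)
    for k, c in enumerate(sub.extrinsic):
        th.log_gain[k] = theta.log_gain[ext_old[c.name]]
        th.log_mod[k] = theta.log_mod[ext_old[c.name]]
    old_ch = {l: i for i, l in enumerate(circuit.channel_labels)}
    for i, l in enumerate(sub.channel_labels):
        th.log_obs[i] = theta.log_obs[old_ch[l]]
        th.log_chan_white[i] = np.atleast_1d(theta.log_chan_white)[old_ch[l]]
    for k in ("log_he", "log_kappa", "log_delay", "log_innov_white",
              "log_innov_pink", "log_chan_pink"):
        setattr(th, k, getattr(theta, k))
    return th


def lesion_stn(
    circuit: CircuitModel,
    theta: ThetaVector,
    mode: str = "zero_connections",
    condition: str = "off",
    config: dict | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> tuple[CrossSpectralData, BetaSummary]:
    """Simulated subthalamotomy: silence every connection to and from STN.

    ``zero_connections`` keeps the source but sets the gains of all its
    afferent and efferent extrinsic connections to zero;
    ``remove_node`` deletes the source (and its channel) from the model.
    Both return the source-potential spectra and network beta of the
    lesioned circuit; over the surviving sources the two modes are
    equivalent.
    """
    if mode == "zero_connections":
        gains = effective_gains(circuit, theta, condition)
        for k, c in enumerate(circuit.connections):
            if STN in (c.source_from, c.source_to):
                gains[k] = 0.0
        csd = _source_csd(circuit, theta, condition, config, band, gains)
        return csd, BetaSummary.from_csd(csd, condition)
    if mode == "remove_node":
        sub = circuit.without_source(STN)
        th = _restrict_theta(circuit, sub, theta)
        csd = _source_csd(sub, th, condition, config, band)
        return csd, BetaSummary.from_csd(csd, condition)
    raise ValueError(f"unknown lesion mode {mode!r}")


STN_CONNECTIONS = ("ctx_stn", "gpe_stn", "stn_gpe", "stn_gpi")


def partial_lesion(
    circuit: CircuitModel,
    theta: ThetaVector,
    connections: "str | tuple[str, ...]",
    config: dict | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> BetaSummary:
    """Reset selected connections to their treated (ON) strength.

    The returned summary is the beta power of the hybrid parameter set:
    every other connection keeps its untreated (OFF) gain, while the
    named ones have their condition modulators removed (gain ratio 1).
    """
    if isinstance(connections, str):
        connections = (connections,)
    names = {c.name for c in circuit.extrinsic}
    unknown = set(connections) - names
    if unknown:
        raise KeyError(f"unknown connections {sorted(unknown)}")
    th = theta.copy()
    ext = [c.name for c in circuit.extrinsic]
    for name in connections:
        th.log_mod[ext.index(name)] = 0.0
    return beta_power(circuit, th, "off", config, band)


def partial_lesion_batch(
    circuit: CircuitModel,
    theta: ThetaVector,
    config: dict | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Partial-lesion sweep over the four STN-linked connections."""
    full_off = beta_power(circuit, theta, "off", config, band).beta
    rows = [("none (full OFF)", full_off)]
    for name in STN_CONNECTIONS:
        rows.append((name, partial_lesion(circuit, theta, name, config,
                                          band).beta))
    rows.append(("all four", partial_lesion(circuit, theta, STN_CONNECTIONS,
                                            config, band).beta))
    return pd.DataFrame(rows, columns=["reset_to_on", "network_beta"])
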