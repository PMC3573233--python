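"""Group-level inference over per-segment posteriors.

Per-segment inversions yield Gaussian posteriors over each connection's
log OFF/ON gain ratio.  The group summary follows the averaging
convention of pooling the conditional means and their confidence
intervals directly (a simple average of bounds, not a precision-weighted
combination); a connection's drug effect is declared significant only
when two criteria hold together:

(i)  more than 95% of the group-pooled posterior mass lies on one side
     of ratio 1, and
(ii) the same one-sided 95% posterior-mass criterion holds in at least
     half of the individual segment pairs, in the same direction.

A precision-weighted Bayesian pooling is also computed for comparison
(``pooled_precision_weighted``).  The module also provides the Wilcoxon
signed-rank test used by the perturbation analyses, with an exact
enumeration null for small samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .circuit import CircuitModel, ThetaVector
from .inversion import PosteriorDensity

#: one-sided posterior-mass threshold of the significance criteria
MASS_THRESHOLD = 0.95

#: fraction of segment pairs that must individually reach the criterion
SEGMENT_FRACTION = 0.5

#: largest sample size for which the exact signed-rank null is enumerated
EXACT_WILCOXON_MAX_N = 25


def _modulator_table(posteriors: list[PosteriorDensity],
                     circuit: CircuitModel) -> tuple[np.ndarray, np.ndarray,
                                                     list[str]]:
    if not posteriors:
        raise ValueError("no posteriors to pool")
    sl = ThetaVector.zeros(circuit).modulator_slice(circuit)
    names = [c.name for c in circuit.extrinsic]
    M = np.array([p.mean[sl] for p in posteriors])
    SD = np.array([p.marginal_sd()[sl] for p in posteriors])
    return M, SD, names


def pool_posteriors(posteriors: list[PosteriorDensity],
                    circuit: CircuitModel,
                    ci: float = 0.95) -> pd.DataFrame:
    """Group mean and 95% interval per modulator, by CI averaging.

    The group mean is the arithmetic mean of the per-segment conditional
    means; the group interval bounds are the means of the per-segment
    interval bounds.  A precision-weighted pooled mean/sd is reported
    alongside.
    """
    M, SD, names = _modulator_table(posteriors, circuit)
    z = norm.ppf(0.5 + ci / 2.0)
    lo = (M - z * SD).mean(axis=0)
    hi = (M + z * SD).mean(axis=0)
    w = 1.0 / SD ** 2
    pw_mean = (M * w).sum(axis=0) / w.sum(axis=0)
    pw_sd = np.sqrt(1.0 / w.sum(axis=0))
    return pd.DataFrame({
        "connection": names,
        "group_log_ratio": M.mean(axis=0),
        "group_ci_low": lo,
        "group_ci_high": hi,
        "group_ratio": np.exp(M.mean(axis=0)),
        "pooled_precision_weighted": pw_mean,
        "pooled_precision_weighted_sd": pw_sd,
        "n_segments": len(posteriors),
    })


def significance_flags(posteriors: list[PosteriorDensity],
                       circuit: CircuitModel,
                       mass_threshold: float = MASS_THRESHOLD,
                       segment_fraction: float = SEGMENT_FRACTION
                       ) -> pd.DataFrame:
    """Apply the two-part significance criteria per extrinsic connection.

    Returns a frame with the group posterior mass above ratio 1, the
    per-segment counts, and a flag in {"increase", "decrease", "ns"}.
    """
    if len(posteriors) < 2:
        raise ValueError("need at least two posteriors for group criteria")
    M, SD, names = _modulator_table(posteriors, circuit)
    n_seg = M.shape[0]
    z_seg = norm.ppf(mass_threshold)
    # group density by the CI-averaging convention: mean of means and
    # mean of per-segment sds
    g_mean = M.mean(axis=0)
    g_sd = SD.mean(axis=0)
    mass_up = norm.cdf(g_mean / g_sd)
    seg_up = (M / SD > z_seg).sum(axis=0)
    seg_dn = (M / SD < -z_seg).sum(axis=0)
    flags = []
    need = segment_fraction * n_seg
    for k in range(len(names)):
        if mass_up[k] > mass_threshold and seg_up[k] >= need:
            flags.append("increase")
        elif (1.0 - mass_up[k]) > mass_threshold and seg_dn[k] >= need:
            flags.append("decrease")
        else:
            flags.append("ns")
    return pd.DataFrame({
        "connection": names,
        "group_log_ratio": g_mean,
        "group_sd": g_sd,
        "mass_above_one": mass_up,
        "segments_up": seg_up,
        "segments_down": seg_dn,
        "n_segments": n_seg,
        "flag": flags,
    })


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n: int
    method: str


def wilcoxon_signed_rank(x, y=None, zero_method: str = "wilcox"
                         ) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of paired differences.

    ``x`` may be the differences directly or the first member of a pair
    with ``y``.  Zeros are dropped (``wilcox``) or kept with the Pratt
    rule (``pratt``); ties receive mid-ranks.  For n <= 25 the p-value is
    computed from the exact null by enumerating all sign assignments;
    beyond that a normal approximation with tie correction is used.
    """
    d = np.asarray(x, float)
    if y is not None:
        d = d - np.asarray(y, float)
    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            raise ValueError("all paired differences are zero")
        ranks = _midranks(np.abs(d))
    elif zero_method == "pratt":
        if np.all(d == 0):
            raise ValueError("all paired differences are zero")
        ranks = _midranks(np.abs(d))
        keep = d != 0
        ranks = ranks[keep]
        d = d[keep]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = d.size
    if n < 5:
        raise ValueError(f"need at least 5 non-zero differences, got {n}")
    W = float(np.sum(ranks[d > 0]))
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_p(ranks, W)
        method = "exact"
    else:
        mu = np.sum(ranks) / 2.0
        # tie-corrected null variance of the signed-rank sum
        sigma2 = np.sum(ranks ** 2) / 4.0
        z = (W - mu) / math.sqrt(sigma2)
        p = 2.0 * norm.sf(abs(z))
        method = "normal"
    return WilcoxonResult(W, min(p, 1.0), n, method)


def _midranks(a: np.ndarray) -> np.ndarray:
    order = np.argsort(a, kind="stable")
    ranks = np.empty(a.size)
    sa = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_p(ranks: np.ndarray, W: float) -> float:
    """Exact two-sided p by dynamic programming over sign assignments.

    The null distribution of the positive-rank sum is built by convolving
    each rank's two equiprobable contributions (0 or r).  Mid-ranks are
    doubled first so all contributions are integers.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[:total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    W2 = int(round(W * 2))
    lo = dist[:min(W2, total - W2) + 1].sum()
    hi = dist[max(W2, total - W2):].sum()
    return float(min(1.0, lo + hi))


def wilcoxon_exact_enumeration(d: np.ndarray) -> float:
    """Brute-force exact two-sided p over all 2^n sign assignments.

    Exponential-time reference implementation for validating the test on
    small samples; use :func:`wilcoxon_signed_rank` for real work.
    """
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    if n > 20:
        raise ValueError("enumeration limited to n <= 20")
    ranks = _midranks(np.abs(d))
    W_obs = float(np.sum(ranks[d > 0]))
    total = float(np.sum(ranks))
    dev_obs = abs(W_obs - total / 2.0)
    count = 0
    for mask in range(1 << n):
        W = 0.0
        for i in range(n):
            if mask >> i & 1:
                W += ranks[i]
        if abs(W - total / 2.0) >= dev_obs - 1e-12:
            count += 1
    return count / (1 << n)
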