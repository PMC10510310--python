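"""Combination of IP and AP data into IPAP subspectra.

The sum (IP + k·AP) and difference (IP − k·AP) of matched in-phase and
anti-phase spectra separate the α and β ¹⁹F spin-state components of every
multiplet into two subspectra.  Because anti-phase coherences relax faster
than in-phase ones, the AP amplitudes are attenuated by a factor ρ ≤ 1, and
an AP scaling factor k (ideally 1/ρ) must be applied before combining to
suppress cross-talk — the residue of the unwanted spin-state component.

``optimize_k`` determines k numerically from the observation that
cross-talk-free subspectra are congruent up to the J displacement: it
minimizes, over k, the best-shift least-squares residual between the two
subspectra.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import correlate

from ._shift import fractional_shift
from .spin_model import Spectrum1D

__all__ = [
    "IPAPPair",
    "Subspectra",
    "KOptResult",
    "InterleaveLayout",
    "demultiplex_interleaved",
    "combine",
    "optimize_k",
]

logger = logging.getLogger(__name__)


@dataclass
class IPAPPair:
    """Matched IP and AP spectra acquired under identical conditions."""

    ip: Spectrum1D
    ap: Spectrum1D
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.ip.grid != self.ap.grid:
            raise ValueError("IP and AP spectra must share an identical grid")
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass
class Subspectra:
    """The two IPAP subspectra: sum (IP + k·AP) and difference (IP − k·AP)."""

    sum_spec: Spectrum1D
    diff_spec: Spectrum1D
    k_used: float


@dataclass
class KOptResult:
    """Outcome of numerical optimization of the AP scaling factor."""

    k_opt: float
    displacement_at_opt: float
    residual: float
    n_evaluations: int


class InterleaveLayout(str, Enum):
    """Ordering of IP- and AP-tagged scans in an interleaved acquisition."""

    IP_AP_alternating = "IP_AP_alternating"
    blocks = "blocks"


def demultiplex_interleaved(
    scans: Sequence[Spectrum1D], layout: InterleaveLayout | str = InterleaveLayout.IP_AP_alternating
) -> IPAPPair:
    """Average interleaved IP/AP scans into one :class:`IPAPPair`.

    ``IP_AP_alternating``: scans alternate IP, AP, IP, AP, …
    ``blocks``: the first half of the scans is IP, the second half AP.
    """
    layout = InterleaveLayout(layout)
    n = len(scans)
    if n == 0 or n % 2:
        raise ValueError("an even, nonzero number of scans is required")
    grid = scans[0].grid
    if any(s.grid != grid for s in scans):
        raise ValueError("all scans must share an identical grid")
    if layout is InterleaveLayout.IP_AP_alternating:
        ip_scans, ap_scans = scans[0::2], scans[1::2]
    else:
        ip_scans, ap_scans = scans[: n // 2], scans[n // 2 :]
    ip = scans[0].copy_with(np.mean([s.intensities for s in ip_scans], axis=0))
    ap = scans[0].copy_with(np.mean([s.intensities for s in ap_scans], axis=0))
    ip.metadata["mode"], ap.metadata["mode"] = "IP", "AP"
    return IPAPPair(ip=ip, ap=ap)


def combine(pair: IPAPPair, k: float | None = None) -> Subspectra:
    """Form the IP ± k·AP subspectra (pointwise; grids must match)."""
    if k is None:
        k = pair.k
    if k <= 0:
        raise ValueError("k must be positive")
    if pair.ip.grid != pair.ap.grid:
        raise ValueError("grid mismatch between IP and AP spectra")
    s = pair.ip.copy_with(pair.ip.intensities + k * pair.ap.intensities)
    d = pair.ip.copy_with(pair.ip.intensities - k * pair.ap.intensities)
    s.metadata["subspectrum"], d.metadata["subspectrum"] = "sum", "diff"
    return Subspectra(sum_spec=s, diff_spec=d, k_used=k)


# ---------------------------------------------------------------------------
# best-shift residual machinery (shared with the displacement fit)


def _integer_lag_objective(
    s_full: np.ndarray, d_full: np.ndarray, a: int, b: int, lag_lo: int, lag_hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares misfit Σ_[a,b) (s[i] − d[i−L])² at every integer lag L.

    Computed exactly in O(n log n) from a cross-correlation and a cumulative
    sum of squares.  Lags are clipped so that the shifted window stays inside
    ``d_full``.  Returns ``(lags, objective)``.
    """
    n = d_full.size
    m = b - a
    lag_lo = max(lag_lo, b - n)
    lag_hi = min(lag_hi, a)
    if lag_hi < lag_lo:
        raise ValueError("search window exceeds available padding")
    s = s_full[a:b]
    ss = float(np.dot(s, s))
    # c[j] = Σ_i d_full[j+i]·s[i]  →  cross term at lag L is c[a−L]
    c = correlate(d_full, s, mode="valid", method="fft")
    csq = np.concatenate([[0.0], np.cumsum(d_full * d_full)])
    lags = np.arange(lag_lo, lag_hi + 1)
    dd = csq[b - lags] - csq[a - lags]
    cross = c[a - lags]
    return lags, ss + dd - 2.0 * cross


def _continuous_objective(
    s_full: np.ndarray, d_full: np.ndarray, a: int, b: int, step: float
):
    """Return f(δ) = Σ_[a,b) (s[i] − shift(d, δ)[i])² with δ in Hz."""
    s = s_full[a:b]

    def f(delta: float) -> float:
        d_shift = fractional_shift(d_full, delta / step)[a:b]
        r = s - d_shift
        return float(np.dot(r, r))

    return f


def best_shift_residual(
    sum_y: np.ndarray,
    diff_y: np.ndarray,
    step: float,
    a: int,
    b: int,
    search: tuple[float, float],
    xatol: float = 1e-3,
) -> tuple[float, float, int]:
    """Find the displacement δ (Hz) minimizing the subspectrum misfit.

    Exhaustive integer-lag search at grid resolution followed by bounded
    golden-section/parabolic refinement with band-limited shifting.  Returns
    ``(delta_opt, residual_at_opt, n_evaluations)``.
    """
    lag_lo = int(np.floor(search[0] / step))
    lag_hi = int(np.ceil(search[1] / step))
    # zero-pad when the search reaches past the sampled window (tails ~ 0)
    n = diff_y.size
    need_left = max(0, lag_hi - a)
    need_right = max(0, b - lag_lo - n)
    if need_left or need_right:
        diff_y = np.pad(diff_y, (need_left, need_right))
        sum_y = np.pad(sum_y, (need_left, need_right))
        a += need_left
        b += need_left
    lags, obj = _integer_lag_objective(sum_y, diff_y, a, b, lag_lo, lag_hi)
    i_best = int(np.argmin(obj))
    n_eval = lags.size
    f = _continuous_objective(sum_y, diff_y, a, b, step)
    lo = max(search[0], (lags[i_best] - 2) * step)
    hi = min(search[1], (lags[i_best] + 2) * step)
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": xatol})
    n_eval += int(res.nfev)
    if res.fun <= obj[i_best]:
        return float(res.x), float(res.fun), n_eval
    return float(lags[i_best] * step), float(obj[i_best]), n_eval


def _region_indices(spec: Spectrum1D, region: tuple[float, float] | None) -> tuple[int, int]:
    freqs = spec.frequencies
    if region is None:
        n = freqs.size
        return n // 8, n - n // 8  # leave padding for shifts at the edges
    lo, hi = region
    if not (freqs[0] <= lo < hi <= freqs[-1]):
        raise ValueError("region must lie within the frequency grid")
    a = int(np.searchsorted(freqs, lo))
    b = int(np.searchsorted(freqs, hi, side="right"))
    if b - a < 4:
        raise ValueError("region too narrow")
    return a, b


def optimize_k(
    pair: IPAPPair,
    bounds: tuple[float, float] = (0.5, 2.0),
    region: tuple[float, float] | None = None,
    search: tuple[float, float] = (-80.0, 80.0),
    coarse_points: int = 31,
) -> KOptResult:
    """Numerically optimize the AP scaling factor k.

    Minimizes over k the best-shift least-squares residual between the
    IP + k·AP and IP − k·AP subspectra: when cross-talk vanishes the two
    subspectra are identical up to the J displacement, so the residual is a
    direct cross-talk meter.  The result is invariant to an overall
    intensity rescaling of the pair.

    Parameters
    ----------
    bounds : (k_lo, k_hi)
        Search interval; relaxation losses make k ≥ 1 typical.
    region : (lo, hi) in Hz, optional
        Restrict the objective to one multiplet, mirroring per-multiplet
        optimization; default uses the whole spectrum minus edge padding.
    """
    k_lo, k_hi = bounds
    if not (0 < k_lo < k_hi):
        raise ValueError("require 0 < k_lo < k_hi")
    scale = float(np.max(np.abs(pair.ip.intensities)))
    if scale == 0:
        raise ValueError("k unidentifiable: IP spectrum is empty")
    if np.max(np.abs(pair.ap.intensities)) < 1e-12 * scale:
        raise ValueError("k unidentifiable: AP spectrum is zero (flat objective)")
    step = pair.ip.grid.step
    a, b = _region_indices(pair.ip, region)
    # slice a padded window around the region so each objective evaluation
    # works on a small array
    pad = int(np.ceil(max(abs(search[0]), abs(search[1])) / step)) + 8
    w0 = max(0, a - pad)
    w1 = min(pair.ip.grid.npoints, b + pad)
    ip_y = pair.ip.intensities[w0:w1] / scale
    ap_y = pair.ap.intensities[w0:w1] / scale
    a, b = a - w0, b - w0
    n_eval_total = 0
    delta_holder = {"delta": 0.0}

    first_eval = {"done": False}

    def objective(k: float) -> float:
        nonlocal n_eval_total
        sum_y = ip_y + k * ap_y
        diff_y = ip_y - k * ap_y
        if first_eval["done"]:
            # the displacement barely moves with k; search near the last one
            d0 = delta_holder["delta"]
            local = (max(search[0], d0 - 2.0), min(search[1], d0 + 2.0))
        else:
            local = search
        delta, resid, n_eval = best_shift_residual(
            sum_y, diff_y, step, a, b, local, xatol=1e-2
        )
        first_eval["done"] = True
        n_eval_total += n_eval
        delta_holder["delta"] = delta
        return resid

    ks = np.linspace(k_lo, k_hi, coarse_points)
    vals = np.array([objective(k) for k in ks])
    if np.ptp(vals) < 1e-14 * max(vals.max(), 1.0):
        raise ValueError("k unidentifiable: objective is flat over the bounds")
    i = int(np.argmin(vals))
    lo = ks[max(i - 1, 0)]
    hi = ks[min(i + 1, coarse_points - 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-5})
    k_opt = float(res.x)
    resid = float(res.fun)
    logger.info("optimize_k: k=%.4f residual=%.3g (%d objective evaluations)", k_opt, resid, n_eval_total)
    return KOptResult(
        k_opt=k_opt,
        displacement_at_opt=float(delta_holder["delta"]),
        residual=resid,
        n_evaluations=n_eval_total,
    )
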