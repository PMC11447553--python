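"""Lamellar-spacing arithmetic and 1D SAXD peak fitting.

Diffraction peak positions q_n (nm^-1) of a lamellar phase of repeat
distance d satisfy q_n = 2 pi n / d for order n; an isolated reflection at
position q corresponds to a spacing 2 pi / q.  Peaks are located by
least-squares fitting of Pearson VII profiles

    I(q) = A [1 + ((q - q0)/w)^2 (2^(1/m) - 1)]^(-m) + background

parameterized by the half-width-at-half-maximum w and shape exponent m
(m = 1: Lorentzian; m -> inf: Gaussian).  Phase assignment searches
candidate repeat distances from every peak/order combination and reports a
phase when at least two orders match, allowing peaks to be shared between
phases (overlapping orders).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

TWO_PI = 2.0 * np.pi


def spacing_from_q(q: float) -> float:
    """Spacing (nm) of a reflection at position q (nm^-1): 2 pi / q."""
    if q <= 0:
        raise ValueError("q must be positive")
    return TWO_PI / q


def repeat_distance(q_n: float, n: int) -> float:
    """Lamellar repeat distance d = 2 n pi / q_n for diffraction order n."""
    if q_n <= 0:
        raise ValueError("q must be positive")
    if n < 1:
        raise ValueError("order must be >= 1")
    return TWO_PI * n / q_n


def pearson_vii(q, q0, amplitude, w, m):
    """Pearson VII profile with half-width-at-half-maximum w and exponent m."""
    q = np.asarray(q, dtype=float)
    return amplitude * (
        1.0 + ((q - q0) / w) ** 2 * (2.0 ** (1.0 / m) - 1.0)
    ) ** (-m)


@dataclass
class PeakFit:
    q0: float
    amplitude: float
    w: float
    m: float
    background: float
    converged: bool = True

    @property
    def spacing(self) -> float:
        return spacing_from_q(self.q0)


def fit_pearson_vii(q, intensity, initial_peaks, background: float = None):
    """Least-squares multi-peak Pearson VII fit with a constant background.

    ``initial_peaks`` is a list of (q0, amplitude, w, m) starting values.
    Returns a list of :class:`PeakFit` (non-convergence is flagged on each
    fit, carrying the last iterate).
    """
    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(q) != len(intensity):
        raise ValueError("q and intensity lengths differ")
    if len(q) < 5 * len(initial_peaks):
        raise ValueError("need >= 5 points per peak")
    if background is None:
        background = float(np.percentile(intensity, 5))
    p0 = [background]
    lo, hi = [-np.inf], [np.inf]
    for q0, amp, w, m in initial_peaks:
        p0 += [q0, amp, w, m]
        lo += [q.min(), 0.0, 1e-6, 0.51]
        hi += [q.max(), np.inf, np.inf, 500.0]

    def model(p):
        y = np.full_like(q, p[0])
        for k in range(len(initial_peaks)):
            q0, amp, w, m = p[1 + 4 * k: 5 + 4 * k]
            y = y + pearson_vii(q, q0, amp, w, m)
        return y

    res = least_squares(
        lambda p: model(p) - intensity, p0, bounds=(lo, hi),
        ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=500 * (1 + 4 * len(initial_peaks)),
    )
    converged = bool(res.status > 0)
    fits = []
    for k in range(len(initial_peaks)):
        q0, amp, w, m = res.x[1 + 4 * k: 5 + 4 * k]
        fits.append(PeakFit(float(q0), float(amp), float(w), float(m),
                            float(res.x[0]), converged))
    return fits


def find_initial_peaks(q, intensity, prominence_frac: float = 0.05):
    """Rough (q0, A, w, m) starting values via scipy peak detection."""
    from scipy.signal import find_peaks, peak_widths

    q = np.asarray(q, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    baseline = np.percentile(intensity, 5)
    span = intensity.max() - baseline
    idx, _ = find_peaks(intensity, prominence=prominence_frac * span)
    widths = peak_widths(intensity, idx, rel_height=0.5)[0]
    dq = np.median(np.diff(q))
    return [
        (float(q[i]), float(intensity[i] - baseline),
         max(float(0.5 * widths[k] * dq), 2 * dq), 1.5)
        for k, i in enumerate(idx)
    ]


@dataclass
class LamellarAssignment:
    """One lamellar phase: repeat distance and its matched orders."""

    d: float
    orders: dict  # order n -> peak q
    sse: float

    @property
    def n_orders(self) -> int:
        return len(self.orders)


@dataclass
class PhaseTable:
    phases: list
    unassigned: list  # peak q values not in any phase

    @property
    def unknown_spacings(self) -> list:
        return [spacing_from_q(q) for q in self.unassigned]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "phase": f"lamellar_{i + 1}",
                "repeat_distance_nm": round(p.d, 1),
                "orders": ",".join(str(n) for n in sorted(p.orders)),
                "spacing_nm": np.nan,
            }
            for i, p in enumerate(self.phases)
        ]
        rows += [
            {
                "phase": "unknown",
                "repeat_distance_nm": np.nan,
                "orders": "",
                "spacing_nm": round(s, 1),
            }
            for s in self.unknown_spacings
        ]
        return pd.DataFrame(rows)


def _match_orders(peaks, d, tol, max_order):
    """Best peak per order n within tol of 2 pi n / d."""
    orders = {}
    for n in range(1, max_order + 1):
        q_exp = TWO_PI * n / d
        if q_exp > max(peaks) + tol:
            break
        diffs = np.abs(np.asarray(peaks) - q_exp)
        j = int(np.argmin(diffs))
        if diffs[j] <= tol:
            orders[n] = peaks[j]
    return orders


def _refine_d(orders) -> float:
    """Least-squares d over matched orders: min_d sum (q_n - 2 pi n/d)^2."""
    ns = np.array(sorted(orders), dtype=float)
    qs = np.array([orders[int(n)] for n in ns])
    return float(TWO_PI * (ns**2).sum() / (ns * qs).sum())


def assign_lamellar_phases(peak_qs, tol: float = 0.02,
                           max_order: int = 4) -> PhaseTable:
    """Greedy lamellar-phase assignment from fitted peak positions.

    Candidate repeat distances come from every (peak, order) combination; a
    candidate is accepted when its first order lies on an observed peak and
    at least two orders match within ``tol`` (peaks may be shared between
    phases, as with overlapping diffraction orders).  Remaining peaks are
    reported as unknown-phase spacings 2 pi / q.
    """
    peaks = sorted(float(q) for q in peak_qs)
    if not peaks:
        raise ValueError("need >= 1 peak")
    accepted = []
    seen = set()
    candidates = []
    for q in peaks:
        for n in range(1, max_order + 1):
            d = repeat_distance(q, n)
            orders = _match_orders(peaks, d, tol, max_order)
            if len(orders) < 2 or 1 not in orders:
                continue
            d_ref = _refine_d(orders)
            orders = _match_orders(peaks, d_ref, tol, max_order)
            if len(orders) < 2 or 1 not in orders:
                continue
            d_ref = _refine_d(orders)
            key = tuple(sorted(orders.items()))
            if key in seen:
                continue
            seen.add(key)
            sse = sum(
                (qn - TWO_PI * n_ / d_ref) ** 2 for n_, qn in orders.items()
            )
            candidates.append(LamellarAssignment(d_ref, orders, sse))
    # greedy: most explained peaks first, then lowest SSE
    candidates.sort(key=lambda c: (-c.n_orders, c.sse))
    used_d = []
    for c in candidates:
        if any(abs(c.d - d) < 0.05 for d in used_d):
            continue
        accepted.append(c)
        used_d.append(c.d)
    member = {q for p in accepted for q in p.orders.values()}
    unassigned = [q for q in peaks if q not in member]
    return PhaseTable(accepted, unassigned)


def load_profile(path) -> tuple:
    """Two-column (q, intensity) CSV/TSV -> arrays; q must be ascending."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    q = df.iloc[:, 0].to_numpy(dtype=float)
    intensity = df.iloc[:, 1].to_numpy(dtype=float)
    if (np.diff(q) <= 0).any():
        raise ValueError("q must be strictly increasing")
    return q, intensity
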