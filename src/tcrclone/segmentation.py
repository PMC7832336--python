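"""Piecewise-constant fitting (PCF) of 1-D coverage signals.

The signal — typically a binned, depth-normalized log2 tumor/normal ratio —
is first winsorized against a running median/MAD band to tame outlier bins,
then partitioned into segments by minimizing

    sum_bins (value - segment_mean)^2  +  gamma * sigma2 * (#breakpoints)

subject to a minimum segment length of ``kmin`` bins.  ``sigma2`` is a
robust noise-variance estimate from the MAD of lag-1 differences, which
makes ``gamma`` scale-free: the same penalty works at 5x and at 90x depth.

Two solvers are provided.  :func:`segment_pcf` is the production solver, a
numpy-vectorized O(n^2) dynamic program that is exact.  For verification,
:func:`segment_pcf_exact` solves the identical objective with an
independently coded, deliberately plain dynamic program; the two must agree
on the attained objective for any input on which both run.

Ties (equal objective) are broken toward fewer breakpoints, then toward the
leftmost breakpoint placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_NOISE_VAR = 1e-12  # floor so noiseless signals keep a positive penalty
_TIE_TOL = 1e-9


@dataclass
class Signal:
    """Regularly binned 1-D signal (positions are 0-based bin starts)."""

    positions: np.ndarray
    values: np.ndarray
    bin_size: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values length mismatch")
        if len(self.values) == 0:
            raise ValueError("empty signal")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if len(self.positions) > 1:
            d = np.diff(self.positions)
            if np.any(d != self.bin_size):
                raise ValueError("positions must increase by exactly bin_size")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Segment:
    """One piecewise-constant piece of a segmentation (bins half-open)."""

    start_bin: int
    end_bin: int
    start_bp: int
    end_bp: int
    mean_value: float
    n_bins: int

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp


def winsorize(signal: Signal, tau: float = 2.5, half_window: int = 25) -> Signal:
    """Clip outliers to a running median +/- tau * MAD band.

    For each bin, the window is the bin plus ``half_window`` neighbours on
    each side (truncated at the edges).  The MAD is scaled by 1.4826 so tau
    is in normal-sigma units.  Values inside the band are untouched; a
    window whose values are all equal trivially clips nothing.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    n = len(signal)
    if n <= 2 * half_window:
        raise ValueError(
            f"signal length {n} must exceed 2*half_window = {2 * half_window}"
        )
    v = signal.values
    out = v.copy()
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n, i + half_window + 1)
        w = v[lo:hi]
        med = np.median(w)
        mad = 1.4826 * np.median(np.abs(w - med))
        lo_b, hi_b = med - tau * mad, med + tau * mad
        if v[i] < lo_b:
            out[i] = lo_b
        elif v[i] > hi_b:
            out[i] = hi_b
    return Signal(signal.positions, out, signal.bin_size)


_NOISE_WINDOW = 50  # bins per local MAD window
_NOISE_QUANTILE = 0.9


def noise_variance(values: np.ndarray) -> float:
    """Robust per-bin noise variance via MAD of lag-1 differences.

    Differencing removes the piecewise-constant mean (except at the few
    breakpoints, which the median absorbs); /sqrt(2) undoes the variance
    doubling of differencing.  For count-derived coverage signals the
    noise is heteroscedastic — quiet inside deletions, loud on neutral
    ground — and a single global MAD would be dragged down by a broad
    deletion and over-segment the neutral regions.  The estimate is
    therefore an upper envelope: the 90th percentile of MADs over
    non-overlapping 50-bin windows (reducing to the global MAD for short
    or homoscedastic signals).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return MIN_NOISE_VAR
    d = np.diff(values)
    if len(d) < 2 * _NOISE_WINDOW:
        mad = float(np.median(np.abs(d - np.median(d))))
    else:
        n_win = len(d) // _NOISE_WINDOW
        chunks = d[: n_win * _NOISE_WINDOW].reshape(n_win, _NOISE_WINDOW)
        meds = np.median(chunks, axis=1, keepdims=True)
        mads = np.median(np.abs(chunks - meds), axis=1)
        mad = float(np.quantile(mads, _NOISE_QUANTILE))
    sigma = 1.4826 * mad / np.sqrt(2.0)
    return max(float(sigma) ** 2, MIN_NOISE_VAR)


def _segments_from_breaks(signal: Signal, bounds: list[int]) -> list[Segment]:
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segs.append(
            Segment(
                start_bin=a,
                end_bin=b,
                start_bp=int(signal.positions[a]),
                end_bp=int(signal.positions[b - 1]) + signal.bin_size,
                mean_value=float(np.mean(signal.values[a:b])),
                n_bins=b - a,
            )
        )
    return segs


def segment_pcf(signal: Signal, gamma: float = 40.0, kmin: int = 5) -> list[Segment]:
    """Optimal PCF segmentation (vectorized exact dynamic program)."""
    _check_args(signal, gamma, kmin)
    n = len(signal)
    v = signal.values
    beta = gamma * noise_variance(v)

    cs = np.concatenate([[0.0], np.cumsum(v)])
    css = np.concatenate([[0.0], np.cumsum(v * v)])

    inf = np.inf
    F = np.full(n + 1, inf)
    nseg = np.zeros(n + 1, dtype=np.int64)
    prev = np.full(n + 1, -1, dtype=np.int64)
    F[0] = 0.0

    for j in range(kmin, n + 1):
        # valid last-segment starts: t = 0 or kmin <= t <= j - kmin
        if j - kmin >= kmin:
            ts = np.concatenate([[0], np.arange(kmin, j - kmin + 1)])
        else:
            ts = np.array([0])
        lens = j - ts
        sse = css[j] - css[ts] - (cs[j] - cs[ts]) ** 2 / lens
        np.clip(sse, 0.0, None, out=sse)
        costs = F[ts] + sse + beta
        m = np.min(costs)
        tol = _TIE_TOL * (1.0 + abs(m))
        cand = ts[costs <= m + tol]
        # ties: fewer segments first, then leftmost last-breakpoint
        best = min(cand, key=lambda t: (nseg[t], t))
        F[j] = m
        nseg[j] = nseg[best] + 1
        prev[j] = best

    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(int(prev[bounds[-1]]))
    bounds.reverse()
    return _segments_from_breaks(signal, bounds)


def segment_pcf_exact(
    signal: Signal, gamma: float = 40.0, kmin: int = 5
) -> list[Segment]:
    """Reference PCF solver: exhaustive O(n^2) dynamic program.

    Deliberately plain (scalar loops over all admissible previous
    breakpoints) so it can serve as an independent oracle for
    :func:`segment_pcf`.  Limited to signals of at most 5000 bins.
    """
    _check_args(signal, gamma, kmin)
    n = len(signal)
    if n > 5000:
        raise ValueError("exact reference solver limited to 5000 bins")
    v = [float(x) for x in signal.values]
    beta = gamma * noise_variance(signal.values)

    cs = [0.0]
    css = [0.0]
    for x in v:
        cs.append(cs[-1] + x)
        css.append(css[-1] + x * x)

    INF = float("inf")
    F = [INF] * (n + 1)
    nseg = [0] * (n + 1)
    prev = [-1] * (n + 1)
    F[0] = 0.0
    for j in range(kmin, n + 1):
        best_cost, best_t, best_nseg = INF, -1, 0
        for t in range(0, j - kmin + 1):
            if t != 0 and t < kmin:
                continue
            if F[t] == INF:
                continue
            length = j - t
            sse = css[j] - css[t] - (cs[j] - cs[t]) ** 2 / length
            if sse < 0.0:
                sse = 0.0
            cost = F[t] + sse + beta
            tol = _TIE_TOL * (1.0 + abs(best_cost if best_cost < INF else 0.0))
            if cost < best_cost - tol:
                best_cost, best_t, best_nseg = cost, t, nseg[t] + 1
            elif cost <= best_cost + tol and (nseg[t] + 1, t) < (best_nseg, best_t):
                best_cost, best_t, best_nseg = min(cost, best_cost), t, nseg[t] + 1
        F[j] = best_cost
        prev[j] = best_t
        nseg[j] = best_nseg

    bounds = [n]
    while bounds[-1] > 0:
        bounds.append(prev[bounds[-1]])
    bounds.reverse()
    return _segments_from_breaks(signal, bounds)


def segmentation_objective(
    signal: Signal, segments: list[Segment], gamma: float
) -> float:
    """Objective value of a tiling: total SSE + gamma*sigma2*(#breakpoints)."""
    beta = gamma * noise_variance(signal.values)
    sse = 0.0
    for seg in segments:
        chunk = signal.values[seg.start_bin : seg.end_bin]
        sse += float(np.sum((chunk - np.mean(chunk)) ** 2))
    return sse + beta * (len(segments) - 1)


def _check_args(signal: Signal, gamma: float, kmin: int) -> None:
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if len(signal) < kmin:
        raise ValueError(f"signal length {len(signal)} < kmin {kmin}")
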