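"""Penalized-contrast segmentation of an FPT series.

The series is modeled as piecewise-constant in the mean with homoscedastic
noise. For each candidate segment count K the within-segment sum of squared
deviations (the contrast) is minimized exactly by dynamic programming under
a minimum segment length; K is then chosen by the standard elbow criterion
on the normalized contrast decrease (second-difference threshold rho).
"""

from __future__ import annotations

import numpy as np

from .fpt import FptProfile

__all__ = [
    "Segmentation",
    "segment_series",
    "DEFAULT_LMIN",
    "DEFAULT_KMAX",
    "DEFAULT_RHO",
]

DEFAULT_LMIN = 10
DEFAULT_KMAX = 20
DEFAULT_RHO = 0.75


class Segmentation:
    """Breakpoint partition of a (trimmed) FPT series.

    ``breakpoints`` are start indices of segments 2..K relative to the
    trimmed series; ``offset`` maps trimmed indices back to fix indices of
    the caribou-year (trimmed index + offset = fix index). ``contrast_curve``
    holds the minimized contrast J(K) for K = 1..Kmax.
    """

    def __init__(self, breakpoints, segment_means, K, contrast_curve, n, offset=0):
        self.breakpoints = np.asarray(breakpoints, dtype=int)
        self.segment_means = np.asarray(segment_means, dtype=float)
        self.K = int(K)
        self.contrast_curve = np.asarray(contrast_curve, dtype=float)
        self.n = int(n)
        self.offset = int(offset)
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.breakpoints) != self.K - 1:
            raise ValueError("breakpoint count must be K-1")

    @property
    def bounds(self) -> np.ndarray:
        """Segment boundaries [0, b1, ..., n] in trimmed coordinates."""
        return np.concatenate([[0], self.breakpoints, [self.n]])

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.diff(self.bounds)

    def fix_bounds(self) -> np.ndarray:
        """Segment boundaries in fix-index coordinates of the caribou-year."""
        return self.bounds + self.offset

    def labels(self) -> np.ndarray:
        """Per-sample segment id (0-based) for the trimmed series."""
        return np.repeat(np.arange(self.K), self.segment_lengths)


def _prepare_series(fpt: FptProfile) -> tuple[np.ndarray, int]:
    """Trim undefined ends; bridge interior gaps linearly (contrast only)."""
    v = np.asarray(fpt.values, dtype=float)
    ok = np.isfinite(v)
    if not ok.any():
        raise ValueError("FPT series is entirely undefined")
    first, last = int(np.argmax(ok)), len(v) - 1 - int(np.argmax(ok[::-1]))
    v = v[first : last + 1].copy()
    miss = ~np.isfinite(v)
    if miss.any():
        idx = np.arange(len(v))
        v[miss] = np.interp(idx[miss], idx[~miss], v[~miss])
    return v, first


def _segment_costs(y: np.ndarray, lmin: int) -> np.ndarray:
    """cost[i, j] = SSE of y[i..j] inclusive; +inf where j-i+1 < lmin."""
    n = len(y)
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y * y)])
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = (j - i + 1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sums = s1[j + 1] - s1[i]
        cost = (s2[j + 1] - s2[i]) - sums * sums / np.maximum(length, 1.0)
    cost[length < lmin] = np.inf
    return np.where(np.isfinite(cost), np.maximum(cost, 0.0), np.inf)


def _dp(y: np.ndarray, lmin: int, kmax: int):
    """Exact DP over breakpoints honoring the minimum segment length.

    Returns (J, back): J[k-1] = minimal contrast with k segments over the
    whole series; back[k-1][j] = optimal start of the last segment ending
    at j when k segments are used.
    """
    n = len(y)
    cost = _segment_costs(y, lmin)
    J = np.full((kmax, n), np.inf)
    back = np.zeros((kmax, n), dtype=int)
    J[0] = cost[0]
    for k in range(1, kmax):
        # last segment starts at i in 1..n-1: J[k-1, i-1] + cost[i, j]
        tot = J[k - 1][:-1][:, None] + cost[1:, :]
        back[k] = np.argmin(tot, axis=0) + 1
        J[k] = np.min(tot, axis=0)
    return J[:, -1], back


def _choose_k(J: np.ndarray, rho: float, n: int | None = None,
              support_factor: float = 3.0) -> int:
    """Elbow rule: largest K whose normalized second difference of the
    contrast exceeds rho; K=1 for flat or degenerate curves.

    A candidate K must also be *supported*: its marginal contrast drop has
    to exceed roughly what overfitting pure noise buys (about the residual
    variance times ln n per spurious breakpoint), otherwise shallow noise
    curves get inflated by the normalization and trip the elbow.
    """
    finite = np.flatnonzero(np.isfinite(J))
    if len(finite) == 0:
        return 1
    kmax = int(finite[-1]) + 1
    J = J[:kmax]
    if kmax <= 2 or not J[0] - J[-1] > 0:
        return 1
    Jn = (J - J[-1]) / (J[0] - J[-1]) * (kmax - 1) + 1
    d2 = Jn[:-2] - 2.0 * Jn[1:-1] + Jn[2:]  # evaluated at K = 2..kmax-1
    good = d2 > rho
    if n is not None and n > kmax:
        sigma2 = J[-1] / (n - kmax)
        min_drop = support_factor * sigma2 * np.log(n)
        drops = J[:-1] - J[1:]  # drop achieved by moving to K = 2..kmax
        good = good & (drops[: len(good)] >= min_drop)
    idx = np.flatnonzero(good)
    if len(idx) == 0:
        return 1
    return int(idx[-1]) + 2


def segment_series(
    fpt: FptProfile,
    lmin: int = DEFAULT_LMIN,
    kmax: int = DEFAULT_KMAX,
    rho: float = DEFAULT_RHO,
) -> Segmentation:
    """Segment an FPT series into homogeneous-mean pieces.

    Undefined values at the ends are trimmed (``offset`` records the shift);
    interior gaps are linearly bridged for the contrast only. ``kmax`` is
    clipped to what the minimum segment length allows.
    """
    y, offset = _prepare_series(fpt)
    n = len(y)
    if n < 2 * lmin:
        raise ValueError(f"series too short ({n}) for lmin={lmin}")
    kmax_eff = max(1, min(kmax, n // lmin))
    J, back = _dp(y, lmin, kmax_eff)
    K = _choose_k(J, rho, n=n)
    bps = []
    j = n - 1
    for k in range(K - 1, 0, -1):
        i = int(back[k, j])
        bps.append(i)
        j = i - 1
    bps = np.array(sorted(bps), dtype=int)
    bounds = np.concatenate([[0], bps, [n]])
    means = np.array([y[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    return Segmentation(
        breakpoints=bps, segment_means=means, K=K, contrast_curve=J,
        n=n, offset=offset,
    )
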