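"""Changepoint detection on the ranked activity curve.

Regions are ranked by log2(RPP+1) and segmented by minimising

    sum over segments of  n_s * (log(2*pi) + log(sigma_s^2) + 1)  +  beta * K

i.e. twice the Gaussian negative log-likelihood with segment-specific mean
and variance, plus a penalty beta per changepoint. Three solvers share the
cost: an exact O(n^2) dynamic program, PELT (exact with pruning), and binary
segmentation (greedy). The activity threshold theta is the curve value at
the right-most (highest-valued) changepoint, transformed back to RPP scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MIN_SEGMENT = 2  # a variance needs two points
_VAR_FLOOR = 1e-8
# Segment variances are floored at this fraction of the overall curve
# variance: without it the Gaussian mean+variance likelihood diverges on
# near-duplicate point pairs and every solver overfits them.
VAR_FLOOR_FRACTION = 1e-2


@dataclass(frozen=True)
class ThresholdResult:
    changepoint_indices: list[int]
    theta: float
    theta_log2: float
    method: str
    penalty: float
    n_points: int = 0
    subsampled: bool = False


class _SegmentCost:
    """O(1) Gaussian mean+variance segment cost from prefix sums."""

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        self.c1 = np.concatenate(([0.0], np.cumsum(x)))
        self.c2 = np.concatenate(([0.0], np.cumsum(x * x)))
        self.floor = max(_VAR_FLOOR, VAR_FLOOR_FRACTION * float(np.var(x)))

    def __call__(self, i: int, j: int) -> float:
        """Cost of the segment x[i:j]."""
        n = j - i
        s1 = self.c1[j] - self.c1[i]
        s2 = self.c2[j] - self.c2[i]
        var = max(s2 / n - (s1 / n) ** 2, self.floor)
        return n * (math.log(2.0 * math.pi) + math.log(var) + 1.0)


def penalty_value(penalty: float | str, n: int) -> float:
    """Resolve a penalty spec: a number, 'bic' (2 log n) or 'mbic' (3 log n,
    the default, in the spirit of the modified BIC)."""
    if isinstance(penalty, str):
        name = penalty.lower()
        if name == "bic":
            return 2.0 * math.log(n)
        if name == "mbic":
            return 3.0 * math.log(n)
        raise ValueError(f"unknown penalty {penalty!r}")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    return float(penalty)


def _exact_dp(x: np.ndarray, beta: float) -> list[int]:
    n = len(x)
    cost = _SegmentCost(x)
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=int)
    for t in range(MIN_SEGMENT, n + 1):
        best, arg = np.inf, 0
        for s in range(0, t - MIN_SEGMENT + 1):
            if not (s == 0 or s >= MIN_SEGMENT):
                continue
            val = F[s] + cost(s, t) + beta
            if val < best:
                best, arg = val, s
        F[t] = best
        prev[t] = arg
    bps: list[int] = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            bps.append(s)
        t = s
    return sorted(bps)


def _pelt(x: np.ndarray, beta: float) -> list[int]:
    n = len(x)
    cost = _SegmentCost(x)
    F = np.full(n + 1, np.inf)
    F[0] = -beta
    prev = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(MIN_SEGMENT, n + 1):
        best, arg = np.inf, 0
        vals = {}
        for s in candidates:
            if t - s < MIN_SEGMENT:
                continue
            c = F[s] + cost(s, t)
            vals[s] = c
            if c + beta < best:
                best, arg = c + beta, s
        F[t] = best
        prev[t] = arg
        # prune: s stays a candidate only if it could still win later
        candidates = [s for s in candidates if s not in vals or vals[s] <= F[t]]
        if t <= n - MIN_SEGMENT:
            candidates.append(t)
    bps: list[int] = []
    t = n
    while t > 0:
        s = prev[t]
        if s > 0:
            bps.append(s)
        t = s
    return sorted(bps)


def _binseg(x: np.ndarray, beta: float) -> list[int]:
    cost = _SegmentCost(x)
    bps: list[int] = []

    def recurse(i: int, j: int) -> None:
        base = cost(i, j)
        best, arg = np.inf, -1
        for m in range(i + MIN_SEGMENT, j - MIN_SEGMENT + 1):
            c = cost(i, m) + cost(m, j)
            if c < best:
                best, arg = c, m
        if arg >= 0 and best + beta < base:
            recurse(i, arg)
            bps.append(arg)
            recurse(arg, j)

    recurse(0, len(x))
    return sorted(bps)


def _amoc(x: np.ndarray, beta: float) -> list[int]:
    """At-most-one-changepoint: the best single split, kept if its cost
    reduction exceeds the penalty."""
    n = len(x)
    cost = _SegmentCost(x)
    best_b, best_c = -1, np.inf
    for b in range(MIN_SEGMENT, n - MIN_SEGMENT + 1):
        c = cost(0, b) + cost(b, n)
        if c < best_c:
            best_c, best_b = c, b
    if best_b > 0 and cost(0, n) - best_c > beta:
        return [best_b]
    return []


_METHODS = {"exact_dp": _exact_dp, "pelt": _pelt, "binseg": _binseg, "amoc": _amoc}


def detect_changepoints(
    values: np.ndarray, method: str = "pelt", penalty: float | str = "mbic"
) -> list[int]:
    """Segment boundaries of ``values``; boundary b means segments split
    between indices b-1 and b. A constant curve yields no changepoints."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2 * MIN_SEGMENT:
        raise ValueError("need a 1-D curve with at least 4 points")
    if not np.isfinite(x).all():
        raise ValueError("curve values must be finite")
    if np.ptp(x) == 0:
        return []
    beta = penalty_value(penalty, len(x))
    if method not in _METHODS:
        raise ValueError(f"method must be one of {sorted(_METHODS)}")
    return [int(b) for b in _METHODS[method](x, beta)]


def select_theta(
    values_log2: np.ndarray,
    changepoints: list[int],
    method: str = "",
    penalty: float = 0.0,
) -> ThresholdResult:
    """Pick theta from a segmented ascending ranked curve.

    The threshold is the curve value at the changepoint with the greatest
    value — on an ascending curve, the right-most boundary — back-transformed
    from log2(RPP+1) to the RPP scale.
    """
    if not changepoints:
        raise ValueError(
            "no changepoints detected; supply a manual threshold instead"
        )
    x = np.asarray(values_log2, dtype=float)
    b = max(changepoints, key=lambda i: (x[i], i))
    theta_log2 = float(x[b])
    return ThresholdResult(
        changepoint_indices=sorted(changepoints),
        theta=float(2.0**theta_log2 - 1.0),
        theta_log2=theta_log2,
        method=method,
        penalty=penalty,
        n_points=len(x),
    )


def find_threshold(
    rpp_values: np.ndarray,
    method: str = "amoc",
    penalty: float | str = "mbic",
    max_points: int = 50_000,
) -> ThresholdResult:
    """Ranked-curve thresholding of raw RPP values.

    Values are sorted ascending on log2(RPP+1); for very large inputs an
    even rank-subsample of ``max_points`` is segmented instead (theta is a
    value, not an index, so subsampling is safe). The default detection mode
    is 'amoc' (single best mean+variance split): ranked curves of continuous
    values are order statistics, which full segmentation keeps subdividing
    into near-penalty-sized pieces, so the right-most changepoint of a
    multi-changepoint fit tracks the top of the curve rather than the
    boundary between the inactive mass and the active tail.
    """
    rpp = np.asarray(rpp_values, dtype=float)
    rpp = rpp[np.isfinite(rpp)]
    if (rpp < 0).any():
        raise ValueError("RPP values must be non-negative")
    curve = np.sort(np.log2(rpp + 1.0))
    subsampled = False
    if len(curve) > max_points:
        idx = np.linspace(0, len(curve) - 1, max_points).round().astype(int)
        curve = curve[idx]
        subsampled = True
    beta = penalty_value(penalty, len(curve))
    cps = detect_changepoints(curve, method=method, penalty=beta)
    res = select_theta(curve, cps, method=method, penalty=beta)
    return ThresholdResult(
        res.changepoint_indices,
        res.theta,
        res.theta_log2,
        method,
        beta,
        n_points=len(curve),
        subsampled=subsampled,
    )
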