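"""Piecewise-linear regression of the winding profile.

On a protein with one LRR domain the cumulative winding number is flat,
then climbs linearly at one turn per repeat period, then goes flat again.
The domain boundaries are therefore estimated by least-squares fits of
discontinuous piecewise-linear models to w:

* two breakpoints (flat - sloped - flat, a "clipped ReLU" that need not be
  continuous at the breakpoints) for the generic case;
* four breakpoints (flat - sloped - flat - sloped - flat) when the sloped
  residuals have high standard deviation, registering a short non-coiling
  stretch (hairpin, insertion, mis-folding) as the short middle flat piece.

Breakpoints are integer positions on the residue-index axis; segments are
half-open index ranges [prev, b).  Within a fixed breakpoint configuration,
flat segments take their mean and sloped segments their OLS line; the
configuration itself is optimized exhaustively (two breakpoints) or by
dynamic programming over per-segment least-squares costs (four breakpoints),
ties broken toward smaller breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .geometry import WindingProfile


@dataclass(frozen=True)
class PiecewiseFit:
    """Breakpoints and per-segment lines of one piecewise-linear fit.

    ``segments[k]`` is (slope, intercept) with the line evaluated as
    slope*t + intercept on the global index axis; flat segments have slope
    exactly 0.  ``sloped_residual_sd`` is the population standard deviation
    of residuals restricted to the sloped segment(s).
    """

    breakpoints: tuple[int, ...]
    segments: tuple[tuple[float, float], ...]
    rss: float
    sloped_residual_sd: float
    n: int

    def __post_init__(self) -> None:
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.segments) != len(self.breakpoints) + 1:
            raise ValueError("segment count must be breakpoints + 1")

    def segment_bounds(self) -> list[tuple[int, int]]:
        edges = [0, *self.breakpoints, self.n]
        return list(zip(edges[:-1], edges[1:]))

    def predict(self) -> np.ndarray:
        out = np.empty(self.n)
        for (lo, hi), (slope, intercept) in zip(self.segment_bounds(), self.segments):
            t = np.arange(lo, hi)
            out[lo:hi] = slope * t + intercept
        return out


@dataclass
class LRRAnnotation:
    """Selected-model annotation: LRR span, optional anomaly, repeat starts.

    All positions are 0-based indices into the winding profile; mapping to
    author residue numbering happens when records are emitted.
    """

    model_used: str  # "two_breakpoint" | "four_breakpoint" | "none"
    lrr_start: Optional[int] = None
    lrr_end: Optional[int] = None  # inclusive
    anomaly_interval: Optional[tuple[int, int]] = None  # inclusive
    repeat_unit_starts: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.model_used != "none":
            if self.lrr_start is None or self.lrr_end is None:
                raise ValueError("lrr_start/lrr_end required when a model is selected")
            if self.lrr_start >= self.lrr_end:
                raise ValueError("lrr_start must be < lrr_end")
            if self.anomaly_interval is not None:
                a, b = self.anomaly_interval
                if not (self.lrr_start < a <= b < self.lrr_end):
                    raise ValueError("anomaly interval must lie strictly inside the LRR")


def _as_array(w: WindingProfile | np.ndarray) -> np.ndarray:
    return np.asarray(w.w if hasattr(w, "w") else w, dtype=float)


class _SegmentCosts:
    """Prefix-sum machinery for O(1) flat / sloped segment least squares."""

    def __init__(self, w: np.ndarray) -> None:
        n = len(w)
        t = np.arange(n, dtype=float)
        z = np.zeros(1)
        self.n = n
        self.Pw = np.concatenate([z, np.cumsum(w)])
        self.Pw2 = np.concatenate([z, np.cumsum(w * w)])
        self.Pt = np.concatenate([z, np.cumsum(t)])
        self.Pt2 = np.concatenate([z, np.cumsum(t * t)])
        self.Ptw = np.concatenate([z, np.cumsum(t * w)])

    def flat(self, i, j):
        """SSE of the best constant on [i, j); empty segments cost 0."""
        i, j = np.asarray(i), np.asarray(j)
        cnt = (j - i).astype(float)
        sw = self.Pw[j] - self.Pw[i]
        sw2 = self.Pw2[j] - self.Pw2[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            sse = sw2 - np.where(cnt > 0, sw * sw / np.maximum(cnt, 1), 0.0)
        return np.maximum(sse, 0.0)

    def flat_params(self, i: int, j: int) -> tuple[float, float]:
        cnt = j - i
        mean = (self.Pw[j] - self.Pw[i]) / cnt if cnt else 0.0
        return 0.0, float(mean)

    def sloped(self, i, j):
        """SSE of the best line on [i, j); segments shorter than 2 cost 0."""
        i, j = np.asarray(i), np.asarray(j)
        cnt = (j - i).astype(float)
        st = self.Pt[j] - self.Pt[i]
        st2 = self.Pt2[j] - self.Pt2[i]
        sw = self.Pw[j] - self.Pw[i]
        sw2 = self.Pw2[j] - self.Pw2[i]
        stw = self.Ptw[j] - self.Ptw[i]
        det = cnt * st2 - st * st
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(det > 0, (cnt * stw - st * sw) / np.where(det > 0, det, 1), 0.0)
            intercept = np.where(cnt > 0, (sw - slope * st) / np.maximum(cnt, 1), 0.0)
        sse = sw2 - intercept * sw - slope * stw
        return np.maximum(np.where(cnt >= 2, sse, 0.0), 0.0)

    def sloped_params(self, i: int, j: int) -> tuple[float, float]:
        cnt = j - i
        if cnt == 0:
            return 0.0, 0.0
        if cnt == 1:
            return 0.0, float(self.Pw[j] - self.Pw[i])
        st = self.Pt[j] - self.Pt[i]
        st2 = self.Pt2[j] - self.Pt2[i]
        sw = self.Pw[j] - self.Pw[i]
        stw = self.Ptw[j] - self.Ptw[i]
        det = cnt * st2 - st * st
        slope = (cnt * stw - st * sw) / det
        intercept = (sw - slope * st) / cnt
        return float(slope), float(intercept)


def _finalize(
    w: np.ndarray,
    breakpoints: tuple[int, ...],
    sloped_segments: Sequence[int],
    costs: _SegmentCosts,
) -> PiecewiseFit:
    n = len(w)
    edges = [0, *breakpoints, n]
    segments: list[tuple[float, float]] = []
    rss = 0.0
    sloped_res: list[np.ndarray] = []
    for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        if k in sloped_segments:
            slope, intercept = costs.sloped_params(lo, hi)
        else:
            slope, intercept = costs.flat_params(lo, hi)
        segments.append((slope, intercept))
        t = np.arange(lo, hi)
        res = w[lo:hi] - (slope * t + intercept)
        rss += float(np.dot(res, res))
        if k in sloped_segments:
            sloped_res.append(res)
    pooled = np.concatenate(sloped_res) if sloped_res else np.zeros(0)
    sd = float(np.std(pooled)) if pooled.size else 0.0
    return PiecewiseFit(
        breakpoints=tuple(int(b) for b in breakpoints),
        segments=tuple(segments),
        rss=rss,
        sloped_residual_sd=sd,
        n=n,
    )


def fit_two_breakpoint(
    w: WindingProfile | np.ndarray, min_sloped_len: int = 48
) -> PiecewiseFit:
    """Globally optimal flat - sloped - flat fit (clipped ReLU, discontinuities
    allowed).

    Exhaustive search over breakpoint pairs (b1, b2) with b2 - b1 >=
    ``min_sloped_len``; flanking flats may be empty.  Ties go to the smaller
    b1, then the smaller b2.
    """
    arr = _as_array(w)
    n = len(arr)
    if min_sloped_len < 1:
        raise ValueError("min_sloped_len must be positive")
    if n < min_sloped_len + 2:
        raise ValueError(
            f"profile of length {n} too short for min_sloped_len={min_sloped_len}"
        )
    costs = _SegmentCosts(arr)
    b2_all = np.arange(n + 1)
    flat_suffix = costs.flat(b2_all, np.full(n + 1, n))
    best = (np.inf, -1, -1)
    for b1 in range(0, n - min_sloped_len + 1):
        head = float(costs.flat(0, b1))
        b2 = np.arange(b1 + min_sloped_len, n + 1)
        total = head + costs.sloped(np.full(len(b2), b1), b2) + flat_suffix[b2]
        k = int(np.argmin(total))
        if total[k] < best[0] - 1e-12:
            best = (float(total[k]), b1, int(b2[k]))
    _, b1, b2 = best
    return _finalize(arr, (b1, b2), sloped_segments=[1], costs=costs)


def fit_four_breakpoint(
    w: WindingProfile | np.ndarray, min_seg_len: int = 5
) -> PiecewiseFit:
    """Optimal flat - sloped - flat - sloped - flat fit by dynamic programming.

    The interior three segments (sloped, middle flat, sloped) must each span
    at least ``min_seg_len`` positions; the outer flats may be empty.  The
    two sloped segments are fit independently.  Per-segment least-squares
    costs come from prefix sums; the stage-wise DP minimum is exact, with
    ties resolved toward smaller indices at each stage.
    """
    arr = _as_array(w)
    n = len(arr)
    m = int(min_seg_len)
    if m < 1:
        raise ValueError("min_seg_len must be positive")
    if n < 4 * m + 1:
        raise ValueError(f"profile of length {n} too short for min_seg_len={m}")
    costs = _SegmentCosts(arr)
    idx = np.arange(n + 1)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    F = costs.flat(ii, jj)
    L = costs.sloped(ii, jj)
    invalid_interior = (jj - ii) < m
    F_int = np.where(invalid_interior, np.inf, F)
    L_int = np.where(invalid_interior, np.inf, L)

    A1 = F[0, :]  # leading flat [0, b1), may be empty
    C2 = A1[:, None] + L_int
    A2, arg2 = C2.min(axis=0), C2.argmin(axis=0)
    C3 = A2[:, None] + F_int
    A3, arg3 = C3.min(axis=0), C3.argmin(axis=0)
    C4 = A3[:, None] + L_int
    A4, arg4 = C4.min(axis=0), C4.argmin(axis=0)
    total = A4 + F[:, n]  # trailing flat [b4, n), may be empty
    b4 = int(np.argmin(total))
    if not np.isfinite(total[b4]):
        raise ValueError("no feasible four-breakpoint configuration")
    b3 = int(arg4[b4])
    b2 = int(arg3[b3])
    b1 = int(arg2[b2])
    return _finalize(arr, (b1, b2, b3, b4), sloped_segments=[1, 3], costs=costs)


def select_model(
    fit2: PiecewiseFit,
    fit4: PiecewiseFit,
    sd_threshold: float = 0.15,
    slope_floor: float = 1.0 / 60.0,
) -> LRRAnnotation:
    """Choose between the two fits and emit the LRR annotation.

    The two-breakpoint model is kept when its sloped residual sd is at most
    ``sd_threshold`` (winding units); otherwise the four-breakpoint model is
    used and its middle flat piece becomes the anomaly interval.  If the
    selected model's (length-weighted) sloped slope falls below
    ``slope_floor`` turns/residue, no LRR is declared.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    if fit2.sloped_residual_sd <= sd_threshold:
        b1, b2 = fit2.breakpoints
        slope = fit2.segments[1][0]
        if slope < slope_floor:
            return LRRAnnotation(model_used="none")
        return LRRAnnotation(
            model_used="two_breakpoint", lrr_start=b1, lrr_end=b2 - 1
        )
    b1, b2, b3, b4 = fit4.breakpoints
    len1, len3 = b2 - b1, b4 - b3
    s1, s3 = fit4.segments[1][0], fit4.segments[3][0]
    slope = (len1 * s1 + len3 * s3) / max(len1 + len3, 1)
    if slope < slope_floor:
        return LRRAnnotation(model_used="none")
    return LRRAnnotation(
        model_used="four_breakpoint",
        lrr_start=b1,
        lrr_end=b4 - 1,
        anomaly_interval=(b2, b3 - 1),
    )


def repeat_units_from_winding(
    w: WindingProfile | np.ndarray, annotation: LRRAnnotation
) -> np.ndarray:
    """Residue indices where the winding crosses successive integers in the LRR.

    The profile is re-anchored at the LRR start; for each integer
    m = 1 .. floor(w[end] - w[start]) the first index s with w[s] >= m is
    recorded.  Each crossing marks the completion of one coil turn, i.e. the
    boundary of a tandem repeat unit.
    """
    if annotation.model_used == "none":
        raise ValueError("no LRR selected; repeat units undefined")
    arr = _as_array(w)
    lo, hi = annotation.lrr_start, annotation.lrr_end
    v = arr[lo : hi + 1] - arr[lo]
    total = int(np.floor(v[-1] + 1e-9))
    starts = []
    for mth in range(1, total + 1):
        hits = np.nonzero(v >= mth - 1e-9)[0]
        starts.append(lo + int(hits[0]))
    return np.asarray(starts, dtype=int)
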