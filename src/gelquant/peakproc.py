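"""Chromatography-style processing of lane densitograms.

A densitogram is treated exactly like a chromatogram: a baseline is drawn under
the profile and subtracted, band peaks are located as local maxima, bounded
valley-to-valley, and integrated by the trapezoid rule.  Peak area ``S`` (in
arbitrary units x rows) is the quantification currency that feeds the
area-to-mass calibration.

Diffuse, polydisperse smears — typical of mechanically degraded protein — defeat
automatic valley detection, so `integrate_region` offers manual integration
bounds; unwanted bands are excluded simply by not declaring regions for them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

from .errors import BoundsError, ParameterError, StateError
from .gelimage import Densitogram

__all__ = [
    "Peak",
    "PeakTable",
    "subtract_baseline",
    "detect_peaks",
    "integrate_peak",
    "integrate_region",
]


@dataclass
class Peak:
    """One integrated band: half-open row interval, apex, height and area S."""

    lane_id: int
    apex_row: int
    start_row: int
    end_row: int
    area: float
    height: float
    saturated: bool = False

    def __post_init__(self) -> None:
        if not self.start_row <= self.apex_row < self.end_row:
            raise BoundsError(
                f"apex {self.apex_row} outside peak rows "
                f"[{self.start_row}, {self.end_row})"
            )
        if self.area < 0:
            raise BoundsError(f"negative peak area {self.area}")


@dataclass
class PeakTable:
    """Peaks of one or more lanes; intervals within a lane are disjoint and sorted."""

    peaks: list[Peak]
    profile_length: int

    def __post_init__(self) -> None:
        by_lane: dict[int, list[Peak]] = {}
        for p in self.peaks:
            by_lane.setdefault(p.lane_id, []).append(p)
        for lane_id, ps in by_lane.items():
            ps_sorted = sorted(ps, key=lambda p: p.start_row)
            for a, b in zip(ps_sorted, ps_sorted[1:]):
                if a.end_row > b.start_row:
                    raise BoundsError(
                        f"lane {lane_id}: overlapping peaks "
                        f"[{a.start_row},{a.end_row}) and [{b.start_row},{b.end_row})"
                    )

    def for_lane(self, lane_id: int) -> list[Peak]:
        return sorted(
            (p for p in self.peaks if p.lane_id == lane_id),
            key=lambda p: p.start_row,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = ["lane_id", "apex_row", "start_row", "end_row", "height", "area", "saturated"]
        return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in self.peaks], columns=cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _cumulative_trapezoid(values: np.ndarray) -> np.ndarray:
    """F[i] = trapezoidal integral of the profile from sample 0 to sample i."""
    return np.concatenate([[0.0], np.cumsum((values[1:] + values[:-1]) / 2.0)])


def _check_bounds(n: int, start_row: int, end_row: int) -> None:
    if not 0 <= start_row < end_row <= n:
        raise BoundsError(
            f"integration bounds [{start_row}, {end_row}) invalid for profile of length {n}"
        )


def integrate_peak(d: Densitogram, start_row: int, end_row: int) -> float:
    """Trapezoidal area of the baseline-corrected profile over ``[start_row, end_row)``.

    The area is the integral of the piecewise-linear interpolant from sample
    ``start_row`` to sample ``min(end_row, n-1)``, so areas over a contiguous
    partition of an interval add up exactly to the whole-interval area.
    """
    if not d.baseline_subtracted:
        raise StateError("integrate on a baseline-subtracted densitogram")
    _check_bounds(len(d), start_row, end_row)
    F = _cumulative_trapezoid(d.values)
    return float(F[min(end_row, len(d) - 1)] - F[start_row])


def integrate_region(
    d: Densitogram,
    start_row: int,
    end_row: int,
    saturated: bool = False,
) -> Peak:
    """Integrate a manually declared band region (for diffuse smears).

    Returns a `Peak` carrying the user's bounds; the apex is the maximum row
    within the region (earliest row on ties).
    """
    area = integrate_peak(d, start_row, end_row)
    seg = d.values[start_row:end_row]
    apex = start_row + int(np.argmax(seg))
    return Peak(
        lane_id=d.lane_id,
        apex_row=apex,
        start_row=start_row,
        end_row=end_row,
        area=area,
        height=float(seg.max()),
        saturated=saturated,
    )


def subtract_baseline(d: Densitogram, method: str = "valley_chords") -> Densitogram:
    """Draw and subtract a baseline under the densitogram.

    ``valley_chords`` connects consecutive valleys (local minima of the lightly
    smoothed profile, plus the endpoints) by straight chords — the classical
    chromatographic construction.  ``smooth_floor`` iteratively clips the
    profile against its own running mean, converging to a smooth lower
    envelope that tracks broad background but not bands.  Both leave the
    output non-negative.
    """
    if d.baseline_subtracted:
        raise StateError("densitogram is already baseline-subtracted")
    v = d.values
    n = v.size
    if method == "valley_chords":
        # valleys on a strongly smoothed copy (noise minima are not valleys);
        # knot heights as local medians of the raw profile, so chords anchor on
        # the true floor rather than on the deepest noise excursions
        smooth_w = max(5, n // 20)
        s = ndimage.uniform_filter1d(v, size=smooth_w, mode="nearest")
        # valleys = prominent minima of the smoothed profile; the prominence
        # floor rejects noise ripples riding on band tops and on the baseline
        span = s.max() - s.min()
        mins, _ = sps.find_peaks(-s, prominence=max(0.02 * span, 1e-12))
        knots = np.concatenate([[0], mins, [n - 1]]).astype(int)
        knot_vals = np.array([np.median(v[max(0, k - 2) : k + 3]) for k in knots])
        baseline = np.interp(np.arange(n), knots, knot_vals)
    elif method == "smooth_floor":
        w = max(5, n // 10)
        baseline = v.copy()
        for _ in range(60):
            sm = ndimage.uniform_filter1d(baseline, size=w, mode="nearest")
            baseline = np.minimum(baseline, sm)
        baseline = np.minimum(baseline, v)
    else:
        raise ParameterError(
            f"method must be 'valley_chords' or 'smooth_floor', got {method!r}"
        )
    return dataclasses.replace(
        d, values=np.clip(v - baseline, 0.0, None), baseline_subtracted=True
    )


def detect_peaks(
    d: Densitogram,
    min_height_frac: float = 0.05,
    min_width_rows: int = 3,
    saturation_fraction: np.ndarray | None = None,
) -> PeakTable:
    """Find band peaks on a baseline-subtracted densitogram.

    Local maxima above ``min_height_frac`` of the profile maximum with width
    at least ``min_width_rows`` become peaks.  Boundaries follow the
    chromatographic valley-to-valley rule: between adjacent peaks the deepest
    point, and on the outer flanks the first point falling below 5% of the
    peak height.  Plateau apexes resolve to the earliest row.

    ``saturation_fraction`` (per-row fraction of saturated source pixels, from
    the gel image) flags any peak whose support is more than 1% saturated.
    An empty table is a valid result.
    """
    if not d.baseline_subtracted:
        raise StateError("detect_peaks needs a baseline-subtracted densitogram")
    if not 0.0 < min_height_frac < 1.0:
        raise ParameterError(f"min_height_frac must be in (0, 1), got {min_height_frac}")
    if min_width_rows < 1:
        raise ParameterError(f"min_width_rows must be >= 1, got {min_width_rows}")

    v = d.values
    n = v.size
    # locate apexes and valleys on a lightly smoothed copy: on a noisy profile
    # the raw apex has only noise-scale prominence and every width test fails
    s = ndimage.gaussian_filter1d(v, sigma=max(1.0, min_width_rows / 2.0))
    smax = s.max()
    if smax <= 0:
        return PeakTable(peaks=[], profile_length=n)

    apexes, _ = sps.find_peaks(s, height=min_height_frac * smax, width=min_width_rows)
    if apexes.size == 0:
        return PeakTable(peaks=[], profile_length=n)

    floor_frac = 0.05
    bounds: list[tuple[int, int]] = []
    for k, apex in enumerate(apexes):
        height = s[apex]
        # left bound
        if k == 0:
            left = apex
            while left > 0 and s[left - 1] > floor_frac * height:
                left -= 1
        else:
            left = int(apexes[k - 1] + np.argmin(s[apexes[k - 1] : apex + 1]))
        # right bound (exclusive)
        if k == len(apexes) - 1:
            right = apex
            while right < n - 1 and s[right + 1] > floor_frac * height:
                right += 1
            right += 1
        else:
            right = int(apex + np.argmin(s[apex : apexes[k + 1] + 1]))
        bounds.append((left, max(right, apex + 1)))

    # valley shared by two peaks belongs to the right peak's start; keep disjoint
    for k in range(1, len(bounds)):
        prev_l, prev_r = bounds[k - 1]
        cur_l, cur_r = bounds[k]
        if cur_l < prev_r:
            bounds[k] = (prev_r, cur_r)

    peaks = []
    for _, (left, right) in zip(apexes, bounds):
        # apex on the raw profile within the bounds; argmax takes the earliest
        # row of an equal-height plateau
        apex = left + int(np.argmax(v[left:right]))
        saturated = False
        if saturation_fraction is not None:
            saturated = float(np.mean(saturation_fraction[left:right])) > 0.01
        peaks.append(
            Peak(
                lane_id=d.lane_id,
                apex_row=int(apex),
                start_row=int(left),
                end_row=int(right),
                area=integrate_peak(d, int(left), int(right)),
                height=float(v[apex]),
                saturated=saturated,
            )
        )
    return PeakTable(peaks=peaks, profile_length=n)
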