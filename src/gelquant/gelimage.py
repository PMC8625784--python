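"""Gel photographs to lane densitograms.

A stained gel photograph is turned into an oriented *optical signal* matrix
(`GelImage`): darker Coomassie staining means more protein, so the source
luminance is inverted once — ``signal = white_reference - luminance`` — and the
result is non-negative with row 0 at the well end and migration increasing down
the rows.  Lanes are vertical tracks; each lane collapses to a 1-D signal vs.
migration profile (`Densitogram`) that downstream code treats like a
chromatogram.

The default inversion is linear, following the colorimetric premise that
staining intensity is directly proportional to protein content; a logarithmic
optical-density mode is available via ``mode="od"``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import (
    BoundsError,
    DegenerateInputError,
    InputError,
    LaneDetectionError,
    ParameterError,
)

__all__ = [
    "GelImage",
    "LaneRegion",
    "Densitogram",
    "load_gel_image",
    "flatten_background",
    "detect_lanes",
    "lane_profile",
]

#: ITU-R BT.709 luma weights used to collapse RGB photographs to grey tone.
_LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

LANE_ROLES = ("sample", "calibration", "marker", "blank")


@dataclass
class GelImage:
    """Oriented optical-signal matrix derived from a gel photograph.

    ``signal`` is non-negative and increases where the stained band is darker
    in the source photo; row 0 is the well end and migration increases with the
    row index.  ``saturated_mask`` marks source pixels that sat at the
    full-scale code value of the camera (their signal is a lower bound, so
    peaks supported on them must be flagged, never silently quantified).
    """

    signal: np.ndarray
    bit_depth: int
    saturated_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise DegenerateInputError("signal must be a 2-D matrix")
        if self.saturated_mask is None:
            self.saturated_mask = np.zeros(self.signal.shape, dtype=bool)
        self.saturated_mask = np.asarray(self.saturated_mask, dtype=bool)
        if self.saturated_mask.shape != self.signal.shape:
            raise DegenerateInputError(
                "saturated_mask shape "
                f"{self.saturated_mask.shape} != signal shape {self.signal.shape}"
            )
        if not np.isfinite(self.signal).all():
            raise DegenerateInputError("signal contains non-finite values")
        if (self.signal < 0).any():
            raise DegenerateInputError("signal must be non-negative")

    @property
    def n_rows(self) -> int:
        return self.signal.shape[0]

    @property
    def n_cols(self) -> int:
        return self.signal.shape[1]

    def scaled(self, c: float) -> "GelImage":
        """Return a copy with the signal scaled by ``c >= 0``."""
        return dataclasses.replace(self, signal=self.signal * float(c))


@dataclass(frozen=True)
class LaneRegion:
    """Half-open column interval ``[col_start, col_end)`` holding one lane."""

    lane_id: int
    col_start: int
    col_end: int
    role: str = "sample"

    def __post_init__(self) -> None:
        if self.lane_id < 1:
            raise ParameterError(f"lane_id must be >= 1, got {self.lane_id}")
        if not 0 <= self.col_start < self.col_end:
            raise BoundsError(
                f"lane {self.lane_id}: need 0 <= col_start < col_end, "
                f"got [{self.col_start}, {self.col_end})"
            )
        if self.role not in LANE_ROLES:
            raise ParameterError(
                f"lane {self.lane_id}: role {self.role!r} not in {LANE_ROLES}"
            )

    @property
    def width(self) -> int:
        return self.col_end - self.col_start


@dataclass
class Densitogram:
    """One lane's optical signal versus migration distance.

    ``values[i]`` is the mean signal of the lane at gel row ``row_origin + i``.
    ``baseline_subtracted`` records whether a baseline correction has been
    applied, so peak integration cannot silently run on raw profiles twice.
    """

    lane_id: int
    values: np.ndarray
    row_origin: int = 0
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise DegenerateInputError("densitogram needs >= 2 values")
        if not np.isfinite(self.values).all():
            raise DegenerateInputError("densitogram values must be finite")

    def __len__(self) -> int:
        return self.values.size


def _luminance(arr: np.ndarray) -> np.ndarray:
    """Collapse an image array to scalar luminance in source code values."""
    if arr.ndim == 2:
        return arr.astype(float)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3].astype(float) @ _LUMA_WEIGHTS
    raise InputError(f"unsupported image shape {arr.shape}")


def load_gel_image(
    path,
    white_reference: float | None = None,
    mode: str = "linear",
) -> GelImage:
    """Read a gel photograph and convert it to an optical-signal matrix.

    Parameters
    ----------
    path : str or PathLike
        PNG/TIFF/JPEG file, 8- or 16-bit, greyscale or RGB.
    white_reference : float, optional
        Luminance of unstained gel.  Defaults to the 99.5th percentile of the
        luminance — the bright background of a dark-bands-on-light photo.  (The
        histogram mode underestimates the white point when the background is
        graded, and the subsequent clip at zero then eats band tails.)
    mode : {"linear", "od"}
        ``linear`` (default): ``signal = white_reference - luminance`` clipped
        at 0, consistent with stain intensity proportional to protein.
        ``od``: decadic optical density ``log10(white_reference / luminance)``.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise InputError(f"image file not found: {path}") from None
    except Exception as exc:  # codec errors vary by backend
        raise InputError(f"cannot read image {path}: {exc}") from exc

    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise InputError(
            f"image {path} has dtype {arr.dtype}; only 8- or 16-bit rasters supported"
        )
    full_scale = 2**bit_depth - 1

    lum = _luminance(arr)
    if lum.shape[0] < 16 or lum.shape[1] < 16:
        raise DegenerateInputError(
            f"image {path} is {lum.shape[0]}x{lum.shape[1]}; need at least 16x16"
        )

    if arr.ndim == 2:
        saturated = arr == full_scale
    else:
        saturated = (arr[..., :3] == full_scale).any(axis=-1)

    if white_reference is None:
        white_reference = float(np.percentile(lum, 99.5))

    if mode == "linear":
        signal = np.clip(white_reference - lum, 0.0, None)
    elif mode == "od":
        signal = np.log10(white_reference / np.clip(lum, 1.0, None))
        signal = np.clip(signal, 0.0, None)
    else:
        raise ParameterError(f"mode must be 'linear' or 'od', got {mode!r}")

    return GelImage(signal=signal, bit_depth=bit_depth, saturated_mask=saturated)


def flatten_background(img: GelImage, window_rows: int | None = None, q: float = 0.10) -> GelImage:
    """Remove smooth background staining / illumination gradients per column.

    The background under each column is estimated with a quantile opening: a
    moving ``q``-quantile followed by a moving ``1-q`` quantile over the same
    ``window_rows`` window.  The pair is exact on linear ramps (the down-shift
    of the first pass is undone by the second) while bands much narrower than
    the window are rejected from the estimate.  The estimate, capped at the
    observed signal, is subtracted.

    ``window_rows`` defaults to 25% of ``n_rows``.
    """
    if window_rows is None:
        window_rows = max(3, img.n_rows // 4)
    if not 3 <= window_rows < img.n_rows:
        raise ParameterError(
            f"window_rows must be in [3, {img.n_rows}), got {window_rows}"
        )
    s = img.signal
    bg = _quantile_opening(s, window_rows, q)
    # bands cast a "shadow" on a sloped background (rows just past a band see
    # an elevated quantile); re-estimate with band rows bridged by straight
    # interpolation between the flanking background
    resid = s - bg
    sigma = 1.4826 * np.median(np.abs(resid - np.median(resid, axis=0)), axis=0)
    band_mask = resid > 3.0 * sigma + 1e-12
    band_mask = ndimage.binary_dilation(band_mask, np.ones((7, 1), dtype=bool))
    rows = np.arange(img.n_rows)
    bridged = s.copy()
    for c in range(img.n_cols):
        m = band_mask[:, c]
        if m.any() and not m.all():
            bridged[m, c] = np.interp(rows[m], rows[~m], s[~m, c])
    bg = np.minimum(_quantile_opening(bridged, window_rows, q), s)
    return dataclasses.replace(img, signal=s - bg)


def _quantile_opening(s: np.ndarray, window_rows: int, q: float) -> np.ndarray:
    """Moving q-quantile then (1-q)-quantile along rows; exact on linear ramps.

    Edges are padded by odd (point) reflection, which continues gradients, so
    the opening stays exact on ramps right up to the first and last row.
    """
    pct = 100.0 * q
    size = (window_rows, 1)
    pad = window_rows
    top = 2.0 * s[:1] - s[pad:0:-1]
    bottom = 2.0 * s[-1:] - s[-2 : -pad - 2 : -1]
    padded = np.concatenate([top, s, bottom], axis=0)
    bg = ndimage.percentile_filter(padded, pct, size=size, mode="nearest")
    bg = ndimage.percentile_filter(bg, 100.0 - pct, size=size, mode="nearest")
    return bg[pad : pad + s.shape[0]]


def _split_run_at_minima(colmean: np.ndarray, start: int, stop: int) -> list[tuple[int, int]]:
    """Split a supra-threshold run at interior valleys separating two maxima."""
    seg = colmean[start:stop]
    if seg.size < 5:
        return [(start, stop)]
    interior = np.arange(1, seg.size - 1)
    is_min = (seg[interior] < seg[interior - 1]) & (seg[interior] <= seg[interior + 1])
    cuts = []
    for i in interior[is_min]:
        left_max = seg[:i].max()
        right_max = seg[i + 1 :].max()
        if seg[i] < 0.5 * min(left_max, right_max):
            cuts.append(start + int(i))
    if not cuts:
        return [(start, stop)]
    edges = [start] + cuts + [stop]
    return [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]


def detect_lanes(img: GelImage, expected_n: int | None = None) -> list[LaneRegion]:
    """Locate lanes from the smoothed column-wise mean signal.

    Contiguous column runs above 20% of the 95th percentile of the smoothed
    column mean become lanes, numbered left to right from 1.  Runs containing
    two clearly separated maxima (touching lanes) are split at the valley.
    If ``expected_n`` is given and the detected count differs, an error is
    raised rather than silently merging or splitting lanes.
    """
    if img.signal.size == 0:
        raise DegenerateInputError("empty image")
    colmean = img.signal.mean(axis=0)
    smooth_w = max(3, img.n_cols // 64)
    smoothed = ndimage.uniform_filter1d(colmean, size=smooth_w, mode="nearest")
    robust_max = np.percentile(smoothed, 95)
    threshold = 0.2 * robust_max
    above = smoothed > threshold
    if robust_max <= 0 or not above.any():
        raise LaneDetectionError("no lanes found: column signal never exceeds threshold")

    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for c in range(img.n_cols):
        if above[c] and not in_run:
            in_run, start = True, c
        elif not above[c] and in_run:
            in_run = False
            runs.append((start, c))
    if in_run:
        runs.append((start, img.n_cols))

    split_runs: list[tuple[int, int]] = []
    for s, e in runs:
        split_runs.extend(_split_run_at_minima(smoothed, s, e))

    lanes = [
        LaneRegion(lane_id=i + 1, col_start=s, col_end=e)
        for i, (s, e) in enumerate(split_runs)
    ]
    if expected_n is not None and len(lanes) != expected_n:
        raise LaneDetectionError(
            f"detected {len(lanes)} lanes but expected {expected_n}"
        )
    return lanes


def lane_profile(img: GelImage, lane: LaneRegion) -> Densitogram:
    """Average the signal across a lane's columns into a densitogram."""
    if lane.col_end > img.n_cols:
        raise BoundsError(
            f"lane {lane.lane_id} columns [{lane.col_start}, {lane.col_end}) "
            f"outside image with {img.n_cols} columns"
        )
    values = img.signal[:, lane.col_start : lane.col_end].mean(axis=1)
    return Densitogram(lane_id=lane.lane_id, values=values, row_origin=0)


def lane_saturation_fraction(img: GelImage, lane: LaneRegion) -> np.ndarray:
    """Per-row fraction of saturated source pixels within a lane."""
    if lane.col_end > img.n_cols:
        raise BoundsError(f"lane {lane.lane_id} outside image")
    return img.saturated_mask[:, lane.col_start : lane.col_end].mean(axis=1)
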