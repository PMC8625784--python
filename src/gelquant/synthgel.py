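"""Synthetic gel photographs with exact ground truth.

Renders Coomassie-style gels — dark bands on a light background, smooth
illumination gradients, Gaussian sensor noise, 8/16-bit quantisation — from a
declarative spec, and emits a ground-truth table (band centres, deposited
signal, masses, true degradation degrees) so the whole pipeline can be tested
against known answers without any real photographs.

Model: each band is a Gaussian along the migration axis and uniform across its
lane's width ("top-hat"), discretely normalised so that the deposited
integrated signal equals ``mass_ug * response`` exactly before noise and
quantisation.  Band centres follow the classic electrophoretic mobility law
``rf = intercept + slope * log10(mw)`` unless an explicit ``center_row`` is
given.  Rendering is bit-exact reproducible for a fixed seed.

Two presets mirror common experimental layouts: a twofold serial-dilution
calibration gel with a 14.4–116 kDa marker lane, and a degradation series in
which treated lanes retain a declared fraction of the native band, the balance
optionally smeared into a broad diffuse tail of degradation products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SpecError
from .gelimage import LaneRegion

__all__ = [
    "BandSpec",
    "SyntheticGelSpec",
    "render_gel",
    "make_calibration_gel",
    "make_degradation_gel",
    "write_gel",
    "DEFAULT_MARKER_MASSES_KDA",
]

#: A conventional unstained-ladder composition spanning 14.4–116 kDa.
DEFAULT_MARKER_MASSES_KDA = (116.0, 85.0, 66.2, 45.0, 35.0, 25.0, 18.4, 14.4)

#: Default mobility law rf = intercept + slope*log10(mw), placing 116 kDa near
#: the well and 14.4 kDa near the front.
DEFAULT_MOBILITY = (-0.94, 2.04)


@dataclass
class BandSpec:
    """One band: protein mass, stain response, position and sharpness.

    ``response`` converts mass to deposited optical signal (signal counts per
    µg, summed over all band pixels).  Large ``sigma_rows`` model diffuse,
    polydisperse smears of degraded protein.  Position comes from ``mw`` via
    the gel's mobility law, or from an explicit ``center_row``.
    """

    lane_id: int
    mass_ug: float
    response: float
    sigma_rows: float
    mw: float | None = None
    center_row: float | None = None
    kind: str = "native"  # native | smear | marker

    def __post_init__(self) -> None:
        if self.mass_ug <= 0 or self.response <= 0 or self.sigma_rows <= 0:
            raise SpecError(
                f"band in lane {self.lane_id}: mass_ug, response and sigma_rows "
                "must be positive"
            )
        if self.mw is None and self.center_row is None:
            raise SpecError(f"band in lane {self.lane_id}: give mw or center_row")


@dataclass
class SyntheticGelSpec:
    """Complete declarative description of one synthetic gel photograph."""

    n_rows: int
    n_cols: int
    lanes: list[LaneRegion]
    bands: list[BandSpec]
    mobility: tuple[float, float] = DEFAULT_MOBILITY
    front_row: int | None = None
    background: tuple[float, float, float] = (200.0, 300.0, 150.0)
    noise_sd: float = 0.0
    bit_depth: int = 16
    seed: int = 0
    white_level: float | None = None
    true_alpha_pct: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise SpecError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")
        if self.front_row is None:
            self.front_row = int(round(0.93 * self.n_rows))
        if self.white_level is None:
            # integer white level keeps quantisation unbiased for clean gels
            self.white_level = float(round(0.95 * (2**self.bit_depth - 1)))

    def band_center(self, band: BandSpec) -> float:
        if band.center_row is not None:
            return float(band.center_row)
        slope, intercept = self.mobility
        rf = intercept + slope * np.log10(band.mw)
        return float(rf * self.front_row)

    def lane_by_id(self, lane_id: int) -> LaneRegion:
        for ln in self.lanes:
            if ln.lane_id == lane_id:
                return ln
        raise SpecError(f"band references unknown lane {lane_id}")


def render_gel(spec: SyntheticGelSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a spec to a quantised image and its ground-truth table.

    Returns ``(image, truth)`` where ``image`` is uint8/uint16 with dark bands
    on a light background and ``truth`` has one row per band with its exact
    centre, deposited integrated signal (total over pixels) and the
    lane-mean-profile area ``mass*response/width`` the densitometry pipeline
    should recover.
    """
    nr, nc = spec.n_rows, spec.n_cols
    signal = np.zeros((nr, nc), dtype=float)
    rows = np.arange(nr, dtype=float)
    records = []
    for i, band in enumerate(spec.bands):
        lane = spec.lane_by_id(band.lane_id)
        if lane.col_end > nc:
            raise SpecError(f"lane {lane.lane_id} outside gel with {nc} columns")
        center = spec.band_center(band)
        if not 0 <= center < spec.front_row:
            raise SpecError(
                f"band in lane {band.lane_id}: center row {center:.1f} outside "
                f"[0, front_row={spec.front_row})"
            )
        profile = np.exp(-((rows - center) ** 2) / (2.0 * band.sigma_rows**2))
        total = band.mass_ug * band.response
        width = lane.width
        profile *= (total / width) / profile.sum()  # exact discrete deposition
        signal[:, lane.col_start : lane.col_end] += profile[:, None]
        records.append(
            {
                "band_id": i,
                "lane_id": band.lane_id,
                "kind": band.kind,
                "center_row": center,
                "sigma_rows": band.sigma_rows,
                "mass_ug": band.mass_ug,
                "mw_kda": band.mw if band.mw is not None else np.nan,
                "integrated_signal": total,
                "profile_area": total / width,
                "true_alpha_pct": spec.true_alpha_pct.get(band.lane_id, np.nan),
            }
        )

    base, row_grad, col_grad = spec.background
    bg = (
        base
        + row_grad * (rows[:, None] / max(nr - 1, 1))
        + col_grad * (np.arange(nc)[None, :] / max(nc - 1, 1))
    )
    luminance = spec.white_level - signal - bg
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        luminance = luminance + rng.normal(0.0, spec.noise_sd, size=luminance.shape)
    full = 2**spec.bit_depth - 1
    image = np.clip(np.round(luminance), 0, full).astype(
        np.uint8 if spec.bit_depth == 8 else np.uint16
    )
    truth = pd.DataFrame.from_records(records)
    return image, truth


def write_gel(spec: SyntheticGelSpec, image_path, truth_path=None, spec_path=None):
    """Render and write the image (PNG or 16-bit TIFF by extension), the
    ground-truth CSV and the generating spec as a flat key=value text file."""
    import imageio.v3 as iio
    import tifffile

    image, truth = render_gel(spec)
    image_path = str(image_path)
    if image_path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(image_path, image)
    else:
        iio.imwrite(image_path, image)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)
    if spec_path is not None:
        with open(spec_path, "w") as fh:
            for key, val in _flatten_spec(spec).items():
                fh.write(f"{key} = {val}\n")
    return image, truth


def _flatten_spec(spec: SyntheticGelSpec) -> dict:
    flat = {
        "n_rows": spec.n_rows,
        "n_cols": spec.n_cols,
        "mobility_slope": spec.mobility[0],
        "mobility_intercept": spec.mobility[1],
        "front_row": spec.front_row,
        "background_base": spec.background[0],
        "background_row_grad": spec.background[1],
        "background_col_grad": spec.background[2],
        "noise_sd": spec.noise_sd,
        "bit_depth": spec.bit_depth,
        "seed": spec.seed,
        "white_level": spec.white_level,
        "n_lanes": len(spec.lanes),
        "n_bands": len(spec.bands),
    }
    for ln in spec.lanes:
        flat[f"lane{ln.lane_id}"] = f"{ln.col_start}:{ln.col_end}:{ln.role}"
    for i, b in enumerate(spec.bands):
        flat[f"band{i}"] = (
            f"lane={b.lane_id},mass_ug={b.mass_ug},response={b.response},"
            f"sigma={b.sigma_rows},mw={b.mw},center={b.center_row},kind={b.kind}"
        )
    return flat


def _layout_lanes(n_lanes: int, lane_width: int, lane_gap: int, margin: int, roles):
    lanes = []
    for k in range(n_lanes):
        start = margin + k * (lane_width + lane_gap)
        lanes.append(
            LaneRegion(
                lane_id=k + 1,
                col_start=start,
                col_end=start + lane_width,
                role=roles[k],
            )
        )
    n_cols = 2 * margin + n_lanes * lane_width + (n_lanes - 1) * lane_gap
    return lanes, n_cols


def serial_dilution_masses(
    top_conc_mg_ml: float, volume_ul: float, n_levels: int
) -> list[float]:
    """Loaded masses (µg) of a twofold serial dilution: top*volume / 2^(k-1)."""
    if top_conc_mg_ml <= 0 or volume_ul <= 0 or n_levels < 1:
        raise SpecError("top concentration, volume and n_levels must be positive")
    top_mass = top_conc_mg_ml * volume_ul  # mg/mL * µL = µg
    return [top_mass / 2**k for k in range(n_levels)]


def make_calibration_gel(
    top_conc_mg_ml: float = 0.2,
    n_levels: int = 5,
    volume_ul: float = 10.0,
    calibrant_mw: float = 66.0,
    extra_sample_masses: tuple[float, ...] = (),
    marker_masses: tuple[float, ...] = DEFAULT_MARKER_MASSES_KDA,
    marker_mass_ug: float = 0.3,
    n_rows: int = 600,
    lane_width: int = 36,
    lane_gap: int = 14,
    margin: int = 20,
    sigma_rows: float = 5.0,
    response: float = 1.0e6,
    noise_sd: float = 5.0,
    seed: int = 0,
    bit_depth: int = 16,
) -> SyntheticGelSpec:
    """Serial-dilution calibration gel plus a molecular-weight marker lane.

    Lane k (k = 1..n_levels) carries ``top_conc_mg_ml * volume_ul / 2**(k-1)``
    µg of a single calibrant band; optional ``extra_sample_masses`` add
    unknown-sample lanes, and a marker lane with ``marker_masses`` (spanning
    14.4–116 kDa by default) is appended last.
    """
    if n_levels < 1:
        raise SpecError(f"n_levels must be >= 1, got {n_levels}")
    masses = serial_dilution_masses(top_conc_mg_ml, volume_ul, n_levels)
    roles = (
        ["calibration"] * n_levels
        + ["sample"] * len(extra_sample_masses)
        + ["marker"]
    )
    lanes, n_cols = _layout_lanes(len(roles), lane_width, lane_gap, margin, roles)
    bands = [
        BandSpec(
            lane_id=k + 1,
            mass_ug=m,
            response=response,
            sigma_rows=sigma_rows,
            mw=calibrant_mw,
        )
        for k, m in enumerate(masses)
    ]
    for j, m in enumerate(extra_sample_masses):
        bands.append(
            BandSpec(
                lane_id=n_levels + j + 1,
                mass_ug=m,
                response=response,
                sigma_rows=sigma_rows,
                mw=calibrant_mw,
            )
        )
    marker_lane = len(roles)
    for mw in marker_masses:
        bands.append(
            BandSpec(
                lane_id=marker_lane,
                mass_ug=marker_mass_ug,
                response=response,
                sigma_rows=max(2.5, sigma_rows * 0.6),
                mw=mw,
                kind="marker",
            )
        )
    return SyntheticGelSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        lanes=lanes,
        bands=bands,
        noise_sd=noise_sd,
        seed=seed,
        bit_depth=bit_depth,
    )


def make_degradation_gel(
    control_mass_ug: float = 2.0,
    retained_fractions: tuple[float, ...] = (0.8, 0.5, 0.2, 0.08),
    smear: bool = True,
    native_mw: float = 66.0,
    smear_offset_rows: float = 150.0,
    smear_sigma_rows: float = 60.0,
    include_marker: bool = True,
    marker_masses: tuple[float, ...] = DEFAULT_MARKER_MASSES_KDA,
    marker_mass_ug: float = 0.3,
    n_rows: int = 600,
    lane_width: int = 36,
    lane_gap: int = 14,
    margin: int = 20,
    sigma_rows: float = 5.0,
    response: float = 1.0e6,
    noise_sd: float = 5.0,
    seed: int = 0,
    bit_depth: int = 16,
) -> SyntheticGelSpec:
    """Degradation series: untreated control, then lanes retaining a fraction
    of the native band, the removed mass optionally redistributed into a broad
    diffuse smear of lower-mobility degradation products.

    Ground truth records each treated lane's true degradation degree
    ``alpha = 100 * (1 - fraction)``; with ``smear=True`` total deposited
    signal per lane is conserved exactly.
    """
    if control_mass_ug <= 0:
        raise SpecError("control_mass_ug must be positive")
    for f in retained_fractions:
        if not 0.0 <= f <= 1.0:
            raise SpecError(f"retained fraction {f} outside [0, 1]")
    n_sample = 1 + len(retained_fractions)
    roles = ["sample"] * n_sample + (["marker"] if include_marker else [])
    lanes, n_cols = _layout_lanes(len(roles), lane_width, lane_gap, margin, roles)
    spec = SyntheticGelSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        lanes=lanes,
        bands=[],
        noise_sd=noise_sd,
        seed=seed,
        bit_depth=bit_depth,
    )
    slope, intercept = spec.mobility
    native_center = (intercept + slope * np.log10(native_mw)) * spec.front_row
    bands = [
        BandSpec(
            lane_id=1,
            mass_ug=control_mass_ug,
            response=response,
            sigma_rows=sigma_rows,
            mw=native_mw,
        )
    ]
    alpha = {1: 0.0}
    for k, f in enumerate(retained_fractions):
        lane_id = k + 2
        alpha[lane_id] = 100.0 * (1.0 - f)
        if f > 0:
            bands.append(
                BandSpec(
                    lane_id=lane_id,
                    mass_ug=f * control_mass_ug,
                    response=response,
                    sigma_rows=sigma_rows,
                    mw=native_mw,
                )
            )
        if smear and f < 1:
            bands.append(
                BandSpec(
                    lane_id=lane_id,
                    mass_ug=(1.0 - f) * control_mass_ug,
                    response=response,
                    sigma_rows=smear_sigma_rows,
                    center_row=native_center + smear_offset_rows,
                    kind="smear",
                )
            )
    if include_marker:
        for mw in marker_masses:
            bands.append(
                BandSpec(
                    lane_id=len(roles),
                    mass_ug=marker_mass_ug,
                    response=response,
                    sigma_rows=max(2.5, sigma_rows * 0.6),
                    mw=mw,
                    kind="marker",
                )
            )
    spec.bands = bands
    spec.true_alpha_pct = alpha
    return spec
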