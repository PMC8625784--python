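"""Quantitative models: calibration, molecular weight, degradation degree.

Three pieces of arithmetic sit downstream of peak integration:

* **Area-to-mass calibration.**  Serial-dilution lanes of known loaded mass Q
  (micrograms) and measured peak area S fit a quadratic through the origin,

      Q = a * S**2 + b * S,

  the standard response for planar chromatography and stained gels (no
  intercept: zero protein gives zero stain).  The fit quality is summarised by
  the *relative deviation*, the mean absolute relative residual in percent.
  Because a calibration typically spans a 16-fold dilution, the default
  residual weighting is 1/Q^2 (relative-error weighting) so the most loaded
  lane does not dominate; unweighted and 1/Q modes are also available.

* **Molecular-weight ladder.**  Marker bands of known mass anchor a map from
  relative mobility Rf = apex_row / front_row to log10(MW/kDa), either as one
  least-squares line (``loglinear``) or as monotone log-linear interpolation
  between anchors (``piecewise``, exact at every anchor).

* **Degradation degree.**  alpha = (S0 - St)/S0 * 100, the percent loss of the
  native-protein band's area after a treatment; unit-free, so it can be read
  off raw areas without calibration.

`QuadraticCalibration` and `MolecularWeightLadder` are scikit-learn style
estimators (``fit``/``predict``, ``get_params``/``set_params``, fitted
attributes with trailing underscores); the module-level functions are thin
wrappers over them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, FitError, InputError
from .peakproc import Peak

__all__ = [
    "CalibrationPoint",
    "QuadraticCalibration",
    "MolecularWeightLadder",
    "DegradationResult",
    "fit_calibration",
    "predict_content",
    "invert_calibration",
    "fit_ladder",
    "estimate_mw",
    "degradation_degree",
]

WEIGHTINGS = ("none", "inverse_Q", "inverse_Q2")


class CalibrationPoint(NamedTuple):
    """One calibration lane: measured peak area S and loaded protein mass Q (µg)."""

    S: float
    Q: float


class QuadraticCalibration(RegressorMixin, BaseEstimator):
    """Quadratic-through-origin calibration Q = a·S² + b·S.

    Parameters
    ----------
    weighting : {"inverse_Q2", "inverse_Q", "none"}
        Residual weighting of the least-squares fit.  ``inverse_Q2`` weights
        residuals by 1/Q², i.e. minimises relative error — appropriate when the
        calibration spans a wide dilution series.
    deviation : {"mean", "max"}
        Whether ``relative_deviation_pct_`` reports the mean or the maximum
        absolute relative residual.

    Attributes
    ----------
    a_ : float
        Quadratic coefficient (µg per squared area unit).
    b_ : float
        Linear coefficient (µg per area unit).
    relative_deviation_pct_ : float
        Summary of relative residuals over the calibration points, percent.
    residuals_pct_ : ndarray
        Signed per-point relative residuals (predicted − Q)/Q × 100.
    """

    def __init__(self, weighting: str = "inverse_Q2", deviation: str = "mean"):
        self.weighting = weighting
        self.deviation = deviation

    def _validate(self, S, Q):
        S = np.asarray(S, dtype=float).ravel()
        Q = np.asarray(Q, dtype=float).ravel()
        if S.shape != Q.shape:
            raise FitError(f"S and Q lengths differ: {S.size} vs {Q.size}")
        if np.unique(S).size < 3:
            raise FitError(
                f"need >= 3 calibration points with distinct areas, got {np.unique(S).size}"
            )
        if (S < 0).any():
            raise FitError("peak areas S must be non-negative")
        if (Q <= 0).any():
            raise FitError("loaded masses Q must be positive")
        if self.weighting not in WEIGHTINGS:
            raise FitError(f"weighting must be one of {WEIGHTINGS}, got {self.weighting!r}")
        if self.deviation not in ("mean", "max"):
            raise FitError(f"deviation must be 'mean' or 'max', got {self.deviation!r}")
        return S, Q

    @classmethod
    def from_coefficients(cls, a: float, b: float) -> "QuadraticCalibration":
        """Calibration with externally given coefficients (e.g. a published
        curve) for forward evaluation; carries no fit diagnostics."""
        return _FrozenCalibration(a, b)

    def fit(self, S, Q):
        """Weighted least-squares fit of Q = a·S² + b·S on areas S, masses Q."""
        S, Q = self._validate(S, Q)
        if self.weighting == "none":
            w = np.ones_like(Q)
        elif self.weighting == "inverse_Q":
            w = 1.0 / Q
        else:
            w = 1.0 / Q**2
        X = np.column_stack([S**2, S])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], Q * sw, rcond=None)
        if not np.isfinite(coef).all():
            raise FitError("degenerate calibration system")
        self.a_, self.b_ = float(coef[0]), float(coef[1])
        pred = self.a_ * S**2 + self.b_ * S
        self.residuals_pct_ = (pred - Q) / Q * 100.0
        agg = np.mean if self.deviation == "mean" else np.max
        self.relative_deviation_pct_ = float(agg(np.abs(self.residuals_pct_)))
        self.n_points_ = S.size
        return self

    def predict(self, S):
        """Protein mass (µg) at peak area(s) S ≥ 0."""
        S_arr = np.asarray(S, dtype=float)
        if (S_arr < 0).any():
            raise DomainError("peak area S must be non-negative")
        out = self.a_ * S_arr**2 + self.b_ * S_arr
        return float(out) if np.isscalar(S) or S_arr.ndim == 0 else out

    def inverse(self, Q):
        """Unique non-negative root S of a·S² + b·S − Q = 0."""
        if Q < 0:
            raise DomainError("protein mass Q must be non-negative")
        a, b = self.a_, self.b_
        if a < 0 or b < 0 or (a == 0 and b == 0):
            raise DomainError(
                f"inverse requires a >= 0, b >= 0, not both zero (a={a}, b={b})"
            )
        if Q == 0:
            return 0.0
        if a == 0:
            return float(Q / b)
        # citardauq form: stable when 4aQ << b^2, reduces to Q/b as a -> 0
        return float(2.0 * Q / (b + np.sqrt(b * b + 4.0 * a * Q)))


class _FrozenCalibration(QuadraticCalibration):
    """A calibration with externally supplied coefficients (no fit)."""

    def __init__(self, a: float, b: float):
        super().__init__()
        self.a_, self.b_ = float(a), float(b)
        self.relative_deviation_pct_ = float("nan")
        self.residuals_pct_ = np.array([])
        self.n_points_ = 0


class MolecularWeightLadder(BaseEstimator):
    """Rf → molecular-weight map anchored on a marker lane.

    Parameters
    ----------
    mode : {"piecewise", "loglinear"}
        ``piecewise``: monotone log-linear interpolation between anchors,
        exact at every anchor; segments are extended for out-of-range queries,
        which are flagged.  ``loglinear``: one least-squares line
        log10(MW) = intercept + slope·Rf.

    Attributes
    ----------
    anchors_ : list of (mw_kda, rf)
        Marker bands sorted by increasing Rf (decreasing mass).
    slope_, intercept_ : float
        Global log-linear fit (slope < 0), kept in both modes for reporting.
    """

    def __init__(self, mode: str = "piecewise"):
        self.mode = mode

    def fit(self, apex_rows: Sequence[int], mws_kda: Sequence[float], front_row: int):
        if self.mode not in ("piecewise", "loglinear"):
            raise InputError(f"mode must be 'piecewise' or 'loglinear', got {self.mode!r}")
        apex_rows = np.asarray(apex_rows, dtype=float).ravel()
        mws = np.asarray(mws_kda, dtype=float).ravel()
        if apex_rows.size != mws.size:
            raise InputError(
                f"{apex_rows.size} marker peaks but {mws.size} masses"
            )
        if apex_rows.size < 2:
            raise InputError("need at least 2 marker bands")
        if (mws <= 0).any():
            raise InputError("marker masses must be positive (kDa)")
        if front_row <= apex_rows.max():
            raise InputError(
                f"front_row {front_row} must lie beyond every marker apex "
                f"(max apex {apex_rows.max():.0f})"
            )
        order = np.argsort(apex_rows)
        apex_rows, mws = apex_rows[order], mws[order]
        if not (np.diff(mws) < 0).all():
            raise InputError("marker masses must strictly decrease with migration")
        rf = apex_rows / float(front_row)
        self.front_row_ = int(front_row)
        self.anchors_ = list(zip(mws.tolist(), rf.tolist()))
        self._rf = rf
        self._logmw = np.log10(mws)
        slope, intercept = np.polyfit(rf, self._logmw, 1)
        self.slope_, self.intercept_ = float(slope), float(intercept)
        return self

    def predict(self, rf):
        """Molecular weight (kDa) at relative mobility rf ∈ (0, 1]."""
        mw, _ = self.predict_with_flags(rf)
        return mw

    def predict_with_flags(self, rf):
        """Return (mw_kda, extrapolated); flags queries outside the anchor range."""
        rf_arr = np.atleast_1d(np.asarray(rf, dtype=float))
        if ((rf_arr <= 0) | (rf_arr > 1)).any():
            raise DomainError(f"relative mobility must be in (0, 1], got {rf!r}")
        extrapolated = (rf_arr < self._rf[0]) | (rf_arr > self._rf[-1])
        if self.mode == "loglinear":
            logmw = self.intercept_ + self.slope_ * rf_arr
        else:
            logmw = np.interp(rf_arr, self._rf, self._logmw)
            # extend the terminal segments instead of clamping
            lo, hi = extrapolated & (rf_arr < self._rf[0]), extrapolated & (rf_arr > self._rf[-1])
            if lo.any():
                s = (self._logmw[1] - self._logmw[0]) / (self._rf[1] - self._rf[0])
                logmw[lo] = self._logmw[0] + s * (rf_arr[lo] - self._rf[0])
            if hi.any():
                s = (self._logmw[-1] - self._logmw[-2]) / (self._rf[-1] - self._rf[-2])
                logmw[hi] = self._logmw[-1] + s * (rf_arr[hi] - self._rf[-1])
        mw = 10.0**logmw
        if np.isscalar(rf) or np.asarray(rf).ndim == 0:
            return float(mw[0]), bool(extrapolated[0])
        return mw, extrapolated


@dataclass(frozen=True)
class DegradationResult:
    """Degradation degree alpha = (S0 − St)/S0 × 100 from native-band areas."""

    S0: float
    St: float
    alpha_pct: float


def degradation_degree(S0: float, St: float) -> DegradationResult:
    """Percent loss of the native-protein band area after treatment.

    ``St > S0`` (apparent gain) yields a negative alpha and a warning, not an
    error: it happens with noisy areas near zero degradation.
    """
    if S0 <= 0:
        raise DomainError(f"untreated band area S0 must be positive, got {S0}")
    if St < 0:
        raise DomainError(f"treated band area St must be non-negative, got {St}")
    if St > S0:
        warnings.warn(
            f"treated area St={St} exceeds untreated S0={S0}: apparent gain, "
            "alpha is negative",
            stacklevel=2,
        )
    return DegradationResult(S0=float(S0), St=float(St), alpha_pct=(S0 - St) / S0 * 100.0)


# ---------------------------------------------------------------------------
# Thin functional wrappers over the estimators


def fit_calibration(
    points: Iterable[CalibrationPoint | tuple], weighting: str = "inverse_Q2"
) -> QuadraticCalibration:
    pts = [CalibrationPoint(*p) for p in points]
    S = [p.S for p in pts]
    Q = [p.Q for p in pts]
    return QuadraticCalibration(weighting=weighting).fit(S, Q)


def predict_content(model: QuadraticCalibration, S: float) -> float:
    return model.predict(S)


def invert_calibration(model: QuadraticCalibration, Q: float) -> float:
    return model.inverse(Q)


def fit_ladder(
    marker_peaks: Sequence[Peak],
    marker_mws: Sequence[float],
    front_row: int,
    mode: str = "piecewise",
) -> MolecularWeightLadder:
    apexes = [p.apex_row for p in marker_peaks]
    return MolecularWeightLadder(mode=mode).fit(apexes, marker_mws, front_row)


def estimate_mw(ladder: MolecularWeightLadder, apex_row: int, front_row: int | None = None):
    """Molecular weight at a band apex; returns (mw_kda, extrapolated_flag)."""
    if front_row is None:
        front_row = ladder.front_row_
    if not 0 < apex_row <= front_row:
        raise DomainError(
            f"apex_row {apex_row} must be in (0, front_row={front_row}]"
        )
    return ladder.predict_with_flags(apex_row / float(front_row))
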