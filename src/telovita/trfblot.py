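"""Mean TRF length from a 1-D densitometric lane profile.

A Southern-blot telomere smear is summarised by the intensity-corrected
mean fragment length

    mean TRF = sum_i OD_i / sum_i (OD_i / L_i)

where OD_i is the background-subtracted optical density of bin i and L_i
the fragment length assigned to that bin by a molecular-weight ladder
calibration.  The correction divides each bin's signal by its length
because hybridisation signal scales with the amount of telomeric repeat,
i.e. with fragment length: OD/L counts molecules.  A plain length-weighted
mean sum(OD*L)/sum(OD) is available behind the ``formula`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import LadderCalibrationError, MeasurementError, TelovitaError

#: default analysis window, bp (span of the lambda HindIII/EcoRI ladder
#: restricted to the telomere-relevant range)
DEFAULT_WINDOW = (1500.0, 21226.0)


@dataclass
class LaneProfile:
    """Densitometric trace: migration position (mm, increasing away from
    the well) against optical density per bin."""

    positions: np.ndarray
    od: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.positions.size != self.od.size:
            raise TelovitaError("positions and od must have equal length")
        if self.positions.size < 10:
            raise TelovitaError("a lane profile needs at least 10 bins")
        if not np.all(np.diff(self.positions) > 0):
            raise TelovitaError("positions must be strictly increasing")


@dataclass
class LadderLane:
    """Observed ladder band sizes (bp) and migration positions (mm)."""

    sizes: np.ndarray
    positions: np.ndarray


@dataclass
class LadderCalibration:
    """Monotone position -> size map, piecewise linear in log10(size).

    Node positions reproduce their band sizes exactly; positions beyond the
    terminal bands continue the terminal segment (extrapolation is flagged
    by :meth:`in_range`).
    """

    band_sizes: np.ndarray
    band_positions: np.ndarray
    _log_sizes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.band_sizes = np.asarray(self.band_sizes, dtype=float)
        self.band_positions = np.asarray(self.band_positions, dtype=float)
        self._log_sizes = np.log10(self.band_sizes)

    def size_at(self, position_mm):
        position_mm = np.asarray(position_mm, dtype=float)
        logsz = np.interp(position_mm, self.band_positions, self._log_sizes)
        # np.interp clamps; continue the terminal segments instead
        for edge, seg in ((0, slice(0, 2)), (-1, slice(-2, None))):
            p = self.band_positions[seg]
            s = self._log_sizes[seg]
            slope = (s[1] - s[0]) / (p[1] - p[0])
            mask = (
                position_mm < self.band_positions[0]
                if edge == 0
                else position_mm > self.band_positions[-1]
            )
            logsz = np.where(mask, s[0 if edge == 0 else 1] + slope * (position_mm - p[0 if edge == 0 else 1]), logsz)
        return 10.0**logsz

    def position_at(self, size_bp):
        size_bp = np.asarray(size_bp, dtype=float)
        # positions increase as size decreases: interpolate on reversed axes
        return np.interp(
            -np.log10(size_bp), -self._log_sizes, self.band_positions
        )

    def in_range(self, position_mm):
        position_mm = np.asarray(position_mm, dtype=float)
        return (position_mm >= self.band_positions[0]) & (
            position_mm <= self.band_positions[-1]
        )


def calibrate_ladder(band_sizes, band_positions):
    """Build a :class:`LadderCalibration` from observed ladder bands.

    Bands may be given in any order; they are sorted by position.  Sizes
    must then be strictly decreasing (larger fragments migrate less), and
    at least 3 bands are required.
    """
    sizes = np.asarray(band_sizes, dtype=float)
    positions = np.asarray(band_positions, dtype=float)
    if sizes.size != positions.size:
        raise LadderCalibrationError("sizes and positions must pair up")
    if sizes.size < 3:
        raise LadderCalibrationError("need at least 3 ladder bands")
    order = np.argsort(positions)
    sizes, positions = sizes[order], positions[order]
    if np.any(np.diff(positions) <= 0):
        raise LadderCalibrationError("ladder band positions must be distinct")
    diffs = np.diff(sizes)
    if np.any(diffs >= 0):
        k = int(np.argmax(diffs >= 0))
        raise LadderCalibrationError(
            f"ladder not monotone: band of {sizes[k + 1]:.0f} bp at "
            f"{positions[k + 1]:.2f} mm should be smaller than the "
            f"{sizes[k]:.0f} bp band above it"
        )
    return LadderCalibration(band_sizes=sizes, band_positions=positions)


def subtract_background(profile, method="rolling_min", window=51):
    """Background-subtract a lane profile.

    ``rolling_min`` subtracts a running minimum over ``window`` bins;
    ``linear`` subtracts the straight line through the first and last bins.
    Negative residuals are clipped at zero.
    """
    od = profile.od
    if method == "rolling_min":
        if window > od.size:
            raise TelovitaError(
                f"background window ({window} bins) exceeds profile length "
                f"({od.size} bins)"
            )
        from scipy.ndimage import minimum_filter1d

        baseline = minimum_filter1d(od, size=int(window), mode="nearest")
    elif method == "linear":
        baseline = np.linspace(od[0], od[-1], od.size)
    else:
        raise TelovitaError(f"unknown background method {method!r}")
    out = LaneProfile(positions=profile.positions, od=np.clip(od - baseline, 0, None))
    out.background_method = method
    return out


def mean_trf(profile, calibration, window=DEFAULT_WINDOW, formula="intensity_corrected"):
    """Mean TRF length (bp) of a lane inside a bp analysis window.

    ``intensity_corrected`` (default): sum(OD) / sum(OD / L).
    ``weighted``: sum(OD * L) / sum(OD).
    """
    lengths = calibration.size_at(profile.positions)
    lo, hi = min(window), max(window)
    mask = (lengths >= lo) & (lengths <= hi)
    if not mask.any():
        raise MeasurementError("analysis window does not overlap the profile")
    od = profile.od[mask]
    L = lengths[mask]
    total = od.sum()
    if total <= 0:
        raise MeasurementError("zero total optical density in the analysis window")
    if not calibration.in_range(profile.positions[mask]).all():
        warnings.warn("analysis window extends beyond the ladder; extrapolating",
                      stacklevel=2)
    if formula == "intensity_corrected":
        return float(total / np.sum(od / L))
    if formula == "weighted":
        return float(np.sum(od * L) / total)
    raise TelovitaError(f"unknown formula {formula!r}")
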