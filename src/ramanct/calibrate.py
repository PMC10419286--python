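"""Wavenumber-axis calibration against a 4-acetamidophenol reference.

Dispersive Raman spectrometers drift by a wavenumber offset (and a mild
dispersion nonlinearity) between acquisition days. The standard remedy is
to record a reference substance with sharp, well-catalogued bands —
4-acetamidophenol (paracetamol) here — once per day, locate its peaks, and
fit a low-order polynomial mapping the measured peak positions onto the
literature positions. Applying that polynomial to the axis of every
spectrum of the day, then resampling onto a common grid, puts all batches
on one calibrated axis.

The literature band list ships as an editable CSV (ASTM E1840 values); no
positions are hard-coded in logic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectralDataset, resample_to_axis, validate_axis


@dataclass
class ReferencePeakSet:
    """Literature band positions (cm^-1) of a calibration standard."""

    name: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.size < 3:
            raise ValueError("a reference peak set needs >= 3 positions")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("reference positions must be strictly increasing")


def load_reference_peaks(path=None) -> ReferencePeakSet:
    """Load a peak-position CSV; defaults to the shipped acetaminophen set."""
    if path is None:
        ref = importlib.resources.files("ramanct.data") / "acetaminophen_peaks.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, comment="#")
        name = "4-acetamidophenol"
    else:
        table = pd.read_csv(path, comment="#")
        name = str(path)
    return ReferencePeakSet(name, table["position"].to_numpy(dtype=float))


def _refine_centroid(axis: np.ndarray, y: np.ndarray, i: int) -> float:
    """Parabolic (3-point) refinement of a local-max position."""
    if i <= 0 or i >= y.size - 1:
        return float(axis[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not a proper local max in this triplet
        return float(axis[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    # local spacing may be non-uniform; use the nearer interval
    step = axis[i + 1] - axis[i] if delta >= 0 else axis[i] - axis[i - 1]
    return float(axis[i] + delta * step)


class WavenumberCalibrator(BaseEstimator):
    """Polynomial measured->true wavenumber correction fitted on a reference.

    Parameters
    ----------
    peaks : ReferencePeakSet, optional
        Literature positions; defaults to the shipped 4-acetamidophenol set.
    poly_degree : int
        Degree of the correction polynomial (2 corrects offset plus mild
        dispersion nonlinearity without overfitting a short peak list).
    search_window : float
        Half-width (cm^-1) of the window around each literature position
        searched for a measured peak.
    min_snr : float
        A located maximum must exceed the in-window median by this many
        robust sigmas to count as a detected peak.

    Fitted attributes
    -----------------
    coefficients_ : ndarray
        Polynomial coefficients, lowest order first.
    fit_rmse_ : float
        RMS residual of the peak fit in cm^-1.
    n_peaks_used_ : int
        Number of matched reference peaks.
    """

    def __init__(self, peaks: ReferencePeakSet | None = None, poly_degree: int = 2,
                 search_window: float = 10.0, min_snr: float = 5.0):
        self.peaks = peaks
        self.poly_degree = poly_degree
        self.search_window = search_window
        self.min_snr = min_snr

    # -- fitting -------------------------------------------------------------
    def fit(self, axis: np.ndarray, intensities: np.ndarray):
        """Fit on a (despiked, baseline-corrected) reference spectrum."""
        axis = validate_axis(np.asarray(axis, dtype=float))
        y = np.asarray(intensities, dtype=float).ravel()
        if y.size != axis.size:
            raise ValueError("reference spectrum length does not match its axis")
        peaks = self.peaks or load_reference_peaks()
        measured, literature = [], []
        for pos in peaks.positions:
            got = self._locate(axis, y, pos)
            if got is not None:
                measured.append(got)
                literature.append(pos)
        if len(measured) < self.poly_degree + 1:
            raise ValueError(
                f"only {len(measured)} reference peaks detected; "
                f"degree {self.poly_degree} needs >= {self.poly_degree + 1}"
            )
        coefs = np.polynomial.polynomial.polyfit(measured, literature,
                                                 self.poly_degree)
        fitted = np.polynomial.polynomial.polyval(np.asarray(measured), coefs)
        self.coefficients_ = coefs
        self.fit_rmse_ = float(np.sqrt(np.mean((fitted - np.asarray(literature)) ** 2)))
        self.n_peaks_used_ = len(measured)
        self.matched_peaks_ = pd.DataFrame(
            {"measured": measured, "literature": literature})
        return self

    def _locate(self, axis: np.ndarray, y: np.ndarray, pos: float) -> float | None:
        sel = np.flatnonzero(np.abs(axis - pos) <= self.search_window)
        if sel.size < 3:
            return None
        win = y[sel]
        med = np.median(win)
        mad = np.median(np.abs(win - med)) * 1.4826
        j = int(np.argmax(win))
        if j == 0 or j == sel.size - 1:  # maximum at window edge: unreliable
            return None
        if mad > 0 and (win[j] - med) / mad < self.min_snr:
            return None
        if mad == 0 and win[j] <= med:
            return None
        return _refine_centroid(axis[sel], win, j)

    # -- application ---------------------------------------------------------
    def correct_axis(self, axis: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "coefficients_")
        corrected = np.polynomial.polynomial.polyval(
            np.asarray(axis, dtype=float), self.coefficients_)
        if np.any(np.diff(corrected) <= 0):
            raise ValueError("calibration polynomial folds the axis back on itself")
        return corrected

    def transform(self, ds: SpectralDataset,
                  target: np.ndarray | None = None) -> SpectralDataset:
        return apply_calibration(ds, self, target)


def fit_calibration(axis: np.ndarray, intensities: np.ndarray,
                    peaks: ReferencePeakSet | None = None,
                    poly_degree: int = 2) -> WavenumberCalibrator:
    """Convenience wrapper returning a fitted :class:`WavenumberCalibrator`."""
    return WavenumberCalibrator(peaks=peaks, poly_degree=poly_degree).fit(
        axis, intensities)


def apply_calibration(ds: SpectralDataset, model: WavenumberCalibrator,
                      target: np.ndarray | None = None) -> SpectralDataset:
    """Correct the dataset axis and resample onto ``target``.

    Default target: the original axis restricted to the corrected hull, so
    no extrapolation occurs.
    """
    corrected = model.correct_axis(ds.axis)
    shifted = SpectralDataset(corrected, ds.intensities, ds.meta,
                              list(ds.provenance))
    if target is None:
        inside = (ds.axis >= corrected[0]) & (ds.axis <= corrected[-1])
        if not inside.any():
            raise ValueError("corrected axis does not overlap the original grid")
        target = ds.axis[inside]
    out = resample_to_axis(shifted, target)
    out.log(f"apply_calibration: degree {len(model.coefficients_) - 1}, "
            f"rmse {model.fit_rmse_:.3f} cm-1, {model.n_peaks_used_} peaks")
    return out
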