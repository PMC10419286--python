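"""Spectral preprocessing: cosmic-spike removal, SNIP background
subtraction, vector normalization, and range clipping.

The chain applied by :func:`preprocess_pipeline` is the one standard for
dispersive Raman microspectroscopy of cells:

1. despike — cosmic-ray events hit single CCD channels (occasionally two)
   and tower over the local noise; they are detected as narrow outliers
   against a running median and repaired by linear interpolation.
2. SNIP baseline — the fluorescence/background continuum is estimated by
   Sensitive Nonlinear Iterative Peak clipping in the compressed
   log-log-sqrt (LLS) domain with a decreasing clipping window, and
   subtracted.
3. wavenumber calibration (optional, see :mod:`ramanct.calibrate`).
4. clipping to the informative ranges — by default the fingerprint region
   400-1800 cm^-1 and the CH-stretching region 2800-3050 cm^-1; the nearly
   band-free "silent" region 1800-2800 cm^-1 and everything above
   3050 cm^-1 are discarded.
5. vector (L2) normalization over the retained channels, removing overall
   intensity differences between cells.

All transformers follow the scikit-learn estimator protocol and operate on
``(n_spectra, n_channels)`` arrays; dataset-level wrappers handle the
:class:`~ramanct.dataset.SpectralDataset` bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import SpectralDataset

DEFAULT_KEEP_RANGES = ((400.0, 1800.0), (2800.0, 3050.0))


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    Attributes
    ----------
    despike_zscore_threshold : float
        Robust z-score (residual / MAD) above which a channel is a spike
        candidate.
    despike_max_width : int
        Candidate runs wider than this many channels are left alone —
        genuine Raman bands are broad, cosmic spikes are not.
    despike_max_repairs : int
        Per-spectrum cap on repaired channels; beyond it only the
        largest-amplitude candidates are repaired.
    despike_method : str
        "mad" (threshold detector, default) or "kmeans" (2-means clustering
        of candidate-run features; the high-amplitude cluster is labelled
        spike).
    snip_max_halfwidth : int
        Largest clipping half-window m of the SNIP iteration, in channels.
    snip_decreasing : bool
        Iterate the window m..1 (low-artifact variant) instead of 1..m.
    snip_lls : bool
        Run the clipping in the compressed log-log-sqrt domain.
    clip_keep_ranges : sequence of (low, high)
        Wavenumber intervals (cm^-1, inclusive) retained after clipping.
    normalization : str
        Only "vector" (unit Euclidean norm) is supported.
    """

    despike_zscore_threshold: float = 8.0
    despike_max_width: int = 2
    despike_max_repairs: int = 10
    despike_method: str = "mad"
    snip_max_halfwidth: int = 60
    snip_decreasing: bool = True
    snip_lls: bool = True
    clip_keep_ranges: tuple = DEFAULT_KEEP_RANGES
    normalization: str = "vector"

    def __post_init__(self) -> None:
        if self.snip_max_halfwidth < 1:
            raise ValueError("snip_max_halfwidth must be >= 1")
        if self.despike_zscore_threshold <= 0:
            raise ValueError("despike_zscore_threshold must be positive")
        if self.normalization != "vector":
            raise ValueError("only vector normalization is supported")
        if self.despike_method not in ("mad", "kmeans"):
            raise ValueError("despike_method must be 'mad' or 'kmeans'")
        ranges = [tuple(map(float, r)) for r in self.clip_keep_ranges]
        for lo, hi in ranges:
            if hi <= lo:
                raise ValueError(f"clip interval ({lo}, {hi}) is not increasing")
        for (_, hi), (lo2, _) in zip(ranges, ranges[1:]):
            if lo2 <= hi:
                raise ValueError("clip intervals must be non-overlapping, increasing")
        self.clip_keep_ranges = tuple(ranges)


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

_MEDFILT_WIDTH = 5
_MAD_SCALE = 1.4826  # MAD -> sigma for a Gaussian


def _candidate_runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b]) + 1) for a, b in zip(starts, stops)]


class Despiker(BaseEstimator, TransformerMixin):
    """Cosmic-spike detector and repairer.

    Channels whose residual from a 5-channel running median exceeds
    ``zscore_threshold`` robust sigmas are grouped into runs; runs no wider
    than ``max_width`` channels are treated as spikes and replaced by
    linear interpolation across the flanking clean channels. Unflagged
    channels are returned bit-identical.

    With ``method="kmeans"`` the candidate runs (at a permissive threshold
    of half the configured one) are instead partitioned by 2-means on
    (peak robust z, run width); the cluster with the higher mean amplitude
    is labelled spike, still subject to the width cap.
    """

    def __init__(self, zscore_threshold: float = 8.0, max_width: int = 2,
                 max_repairs: int = 10, method: str = "mad"):
        self.zscore_threshold = zscore_threshold
        self.max_width = max_width
        self.max_repairs = max_repairs
        self.method = method

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=_MEDFILT_WIDTH)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        out, _ = self.transform_with_report(X)
        return out

    def transform_with_report(self, X) -> tuple[np.ndarray, pd.DataFrame]:
        """Repair spikes; also return a report of (spectrum, channel) repairs."""
        check_is_fitted(self)
        X = check_array(X, ensure_min_features=_MEDFILT_WIDTH)
        if X.shape[1] < 16:
            raise ValueError("despiking needs spectra with >= 16 channels")
        out = X.copy()
        records: list[tuple[int, int]] = []
        for i in range(X.shape[0]):
            repaired = self._despike_one(out[i])
            records.extend((i, ch) for ch in repaired)
        report = pd.DataFrame(records, columns=["spectrum_index", "channel"])
        return out, report

    def _spike_channels(self, y: np.ndarray) -> list[int]:
        med = median_filter(y, size=_MEDFILT_WIDTH, mode="nearest")
        resid = y - med
        mad = np.median(np.abs(resid - np.median(resid))) * _MAD_SCALE
        if mad == 0:
            return []
        z = np.abs(resid) / mad
        if self.method == "kmeans":
            cand = _candidate_runs(z > self.zscore_threshold / 2)
            if len(cand) < 2:
                spike_runs = [r for r in cand if z[r[0]:r[1]].max() > self.zscore_threshold]
            else:
                feats = np.array([[z[a:b].max(), b - a] for a, b in cand])
                km = KMeans(n_clusters=2, n_init=5, random_state=0).fit(
                    (feats - feats.mean(0)) / (feats.std(0) + 1e-12))
                hi = int(np.argmax([feats[km.labels_ == c, 0].mean() for c in (0, 1)]))
                spike_runs = [r for r, lab, f in zip(cand, km.labels_, feats)
                              if lab == hi or f[0] > self.zscore_threshold]
        else:
            spike_runs = _candidate_runs(z > self.zscore_threshold)
        chans = [ch for a, b in spike_runs if b - a <= self.max_width
                 for ch in range(a, b)]
        if len(chans) > self.max_repairs:
            chans = sorted(chans, key=lambda c: -z[c])[: self.max_repairs]
        return sorted(chans)

    def _despike_one(self, y: np.ndarray) -> list[int]:
        chans = self._spike_channels(y)
        if chans:
            idx = np.arange(y.size)
            good = np.setdiff1d(idx, chans)
            y[chans] = np.interp(chans, good, y[good])
        return chans


# ---------------------------------------------------------------------------
# SNIP baseline
# ---------------------------------------------------------------------------

def _lls(v: np.ndarray) -> np.ndarray:
    return np.log(np.log(np.sqrt(v + 1.0) + 1.0) + 1.0)


def _lls_inv(v: np.ndarray) -> np.ndarray:
    return (np.exp(np.exp(v) - 1.0) - 1.0) ** 2 - 1.0


def snip_baseline(y: np.ndarray, max_halfwidth: int = 60, decreasing: bool = True,
                  lls: bool = True, pedestal: float = 2.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """SNIP background estimate of one or many spectra.

    The input (rows = spectra) is anchored at its per-spectrum minimum,
    optionally compressed through the log-log-sqrt transform, and clipped
    iteratively: at half-window p every interior channel is replaced by the
    minimum of itself and the mean of its p-distant neighbours. Anchoring at
    the minimum makes the estimate exactly equivariant under adding a
    constant offset and keeps the compression defined for negative counts.

    ``pedestal`` (in units of the per-spectrum dynamic range) is added
    before the LLS compression and removed after; it keeps the compression
    away from its strongly curved region near zero, where straight
    baselines would otherwise be eroded by the clipping.

    Returns ``(baseline, corrected)`` with ``corrected = y - baseline`` and
    ``baseline <= y`` channelwise.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if not np.all(np.isfinite(y)):
        raise ValueError("SNIP requires finite intensities")
    if max_halfwidth < 1:
        raise ValueError("max_halfwidth must be >= 1")
    offset = y.min(axis=1, keepdims=True)
    ped = pedestal * np.ptp(y, axis=1, keepdims=True) if lls else 0.0
    v = y - offset + ped
    if lls:
        v = _lls(v)
    n = v.shape[1]
    widths = range(max_halfwidth, 0, -1) if decreasing else range(1, max_halfwidth + 1)
    for p in widths:
        if 2 * p >= n:
            continue
        mid = 0.5 * (v[:, : -2 * p] + v[:, 2 * p:])
        v[:, p:-p] = np.minimum(v[:, p:-p], mid)
    base = _lls_inv(v) if lls else v
    base = np.minimum(base - ped, y - offset) + offset  # guard fp overshoot
    corrected = y - base
    return base, corrected


class SnipBaseline(BaseEstimator, TransformerMixin):
    """Transformer subtracting the SNIP background from each spectrum."""

    def __init__(self, max_halfwidth: int = 60, decreasing: bool = True,
                 lls: bool = True):
        self.max_halfwidth = max_halfwidth
        self.decreasing = decreasing
        self.lls = lls

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        _, corrected = snip_baseline(X, self.max_halfwidth, self.decreasing, self.lls)
        return corrected


# ---------------------------------------------------------------------------
# normalization and clipping
# ---------------------------------------------------------------------------

def vector_normalize(y: np.ndarray) -> np.ndarray:
    """Scale each spectrum to unit Euclidean norm (direction preserved)."""
    y = np.asarray(y, dtype=float)
    one = y.ndim == 1
    y = np.atleast_2d(y)
    norms = np.linalg.norm(y, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("cannot vector-normalize a zero spectrum")
    out = y / norms
    return out[0] if one else out


class VectorNormalizer(BaseEstimator, TransformerMixin):
    """L2 normalization of each row (sklearn-protocol wrapper)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return vector_normalize(check_array(X))


def keep_mask(axis: np.ndarray, keep_ranges) -> np.ndarray:
    """Boolean mask of channels inside any keep interval (inclusive ends)."""
    axis = np.asarray(axis, dtype=float)
    mask = np.zeros(axis.size, dtype=bool)
    for lo, hi in keep_ranges:
        mask |= (axis >= lo) & (axis <= hi)
    return mask


class RangeClipper(BaseEstimator, TransformerMixin):
    """Retain only channels whose wavenumber falls in a keep interval.

    The wavenumber axis is a constructor parameter so the transformer can
    sit inside a plain sklearn pipeline operating on intensity matrices.
    """

    def __init__(self, wavenumbers=None, keep_ranges=DEFAULT_KEEP_RANGES):
        self.wavenumbers = wavenumbers
        self.keep_ranges = keep_ranges

    def fit(self, X, y=None):
        X = check_array(X)
        if self.wavenumbers is None:
            raise ValueError("RangeClipper requires the wavenumbers array")
        axis = np.asarray(self.wavenumbers, dtype=float)
        if axis.size != X.shape[1]:
            raise ValueError("wavenumbers length does not match channel count")
        self.mask_ = keep_mask(axis, self.keep_ranges)
        if not self.mask_.any():
            raise ValueError("clipping would leave no channels")
        self.axis_ = axis[self.mask_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return X[:, self.mask_]


# ---------------------------------------------------------------------------
# dataset-level wrappers
# ---------------------------------------------------------------------------

def despike(ds: SpectralDataset, cfg: PreprocessConfig | None = None
            ) -> tuple[SpectralDataset, pd.DataFrame]:
    """Despike every spectrum; return the new dataset and a spike report.

    The report has columns ``spectrum_id, channel, wavenumber``.
    """
    cfg = cfg or PreprocessConfig()
    est = Despiker(cfg.despike_zscore_threshold, cfg.despike_max_width,
                   cfg.despike_max_repairs, cfg.despike_method).fit(ds.intensities)
    cleaned, rep = est.transform_with_report(ds.intensities)
    report = pd.DataFrame({
        "spectrum_id": ds.meta["spectrum_id"].to_numpy()[rep["spectrum_index"]],
        "channel": rep["channel"],
        "wavenumber": ds.axis[rep["channel"]] if len(rep) else rep["channel"],
    })
    out = ds.with_intensities(cleaned,
                              note=f"despike: method={cfg.despike_method}, "
                                   f"z>{cfg.despike_zscore_threshold}, "
                                   f"{len(report)} channels repaired")
    return out, report


def subtract_baseline(ds: SpectralDataset, cfg: PreprocessConfig | None = None
                      ) -> SpectralDataset:
    cfg = cfg or PreprocessConfig()
    _, corrected = snip_baseline(ds.intensities, cfg.snip_max_halfwidth,
                                 cfg.snip_decreasing, cfg.snip_lls)
    return ds.with_intensities(corrected,
                               note=f"snip_baseline: m={cfg.snip_max_halfwidth}, "
                                    f"decreasing={cfg.snip_decreasing}, lls={cfg.snip_lls}")


def clip_ranges(ds: SpectralDataset, cfg: PreprocessConfig | None = None
                ) -> SpectralDataset:
    cfg = cfg or PreprocessConfig()
    mask = keep_mask(ds.axis, cfg.clip_keep_ranges)
    if not mask.any():
        raise ValueError("clipping would leave an empty axis")
    return ds.with_axis(ds.axis[mask], ds.intensities[:, mask],
                        note=f"clip_ranges: keep {cfg.clip_keep_ranges}")


def normalize(ds: SpectralDataset) -> SpectralDataset:
    return ds.with_intensities(vector_normalize(ds.intensities),
                               note="vector_normalize: L2 over retained channels")


def preprocess_pipeline(ds: SpectralDataset, cfg: PreprocessConfig | None = None,
                        calibration=None, *, do_despike: bool = True,
                        do_baseline: bool = True
                        ) -> tuple[SpectralDataset, pd.DataFrame]:
    """Full chain: despike -> SNIP -> (calibrate) -> clip -> normalize.

    ``calibration`` is an optional fitted
    :class:`~ramanct.calibrate.WavenumberCalibrator`; when given, the axis
    is corrected and the spectra resampled before clipping.

    Returns the processed dataset and the spike report (empty when
    despiking is disabled).
    """
    cfg = cfg or PreprocessConfig()
    report = pd.DataFrame(columns=["spectrum_id", "channel", "wavenumber"])
    if do_despike:
        ds, report = despike(ds, cfg)
    if do_baseline:
        ds = subtract_baseline(ds, cfg)
    if calibration is not None:
        from .calibrate import apply_calibration
        ds = apply_calibration(ds, calibration)
    ds = clip_ranges(ds, cfg)
    ds = normalize(ds)
    return ds, report
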