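"""Group mean spectra, difference spectra, and band assignment.

Subtracting the mean spectrum of a control group from that of a diseased
group exposes which vibrational bands gain or lose intensity with disease:
positive excursions are enriched in the first group, negative ones in the
second. Detected extrema are annotated against a catalogue of tentative
band assignments (nucleic acids, proteins, lipids, amino acids) shipped as
an editable CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .dataset import SpectralDataset


# ---------------------------------------------------------------------------
# band catalogue
# ---------------------------------------------------------------------------

@dataclass
class BandTable:
    """Catalogue mapping wavenumber positions/ranges to biochemical classes.

    ``entries`` has columns ``low, high, category``; single positions have
    low == high. Positions are tentative literature assignments and the
    table is meant to be user-editable.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.entries)
        for col in ("low", "high", "category"):
            if col not in df.columns:
                raise ValueError(f"band table needs column {col!r}")
        df = df.astype({"low": float, "high": float})
        if ((df["low"] < 400) | (df["high"] > 3100)).any():
            raise ValueError("band positions must lie within 400-3100 cm^-1")
        if (df["high"] < df["low"]).any():
            raise ValueError("band ranges must have high >= low")
        self.entries = df.reset_index(drop=True)

    def match(self, position: float, tolerance: float = 5.0) -> list[str]:
        """Categories whose band (range widened by ``tolerance``) covers
        ``position``; a single position counts as a zero-width range."""
        e = self.entries
        hit = (e["low"] - tolerance <= position) & (position <= e["high"] + tolerance)
        return list(dict.fromkeys(e.loc[hit, "category"]))


def load_band_table(path=None) -> BandTable:
    """Load a band-assignment CSV; defaults to the shipped catalogue."""
    if path is None:
        ref = importlib.resources.files("ramanct.data") / "band_assignments.csv"
        with importlib.resources.as_file(ref) as p:
            return BandTable(pd.read_csv(p, comment="#"))
    return BandTable(pd.read_csv(path, comment="#"))


# ---------------------------------------------------------------------------
# mean and difference spectra
# ---------------------------------------------------------------------------

def mean_spectrum(ds: SpectralDataset, selector) -> tuple[np.ndarray, np.ndarray]:
    """Channelwise mean and standard deviation over the selected spectra."""
    sub = ds.select(selector)
    return sub.intensities.mean(axis=0), sub.intensities.std(axis=0)


@dataclass
class DifferenceSpectrum:
    """mean(group A) - mean(group B) with its detected, annotated extrema."""

    axis: np.ndarray
    values: np.ndarray
    label_a: str
    label_b: str
    peaks: pd.DataFrame  # position, amplitude, prominence, sign, categories


def _noise_scale(values: np.ndarray) -> float:
    """Robust noise from the median absolute channel-to-channel increment.

    For white noise of sd s the first difference has sd s*sqrt(2); the MAD
    of the increments scaled by 1.4826/sqrt(2) therefore estimates s while
    ignoring the smooth band structure.
    """
    inc = np.diff(values)
    return float(np.median(np.abs(inc - np.median(inc))) * 1.4826 / np.sqrt(2))


def detect_peaks(axis: np.ndarray, values: np.ndarray,
                 prominence_factor: float = 3.0) -> pd.DataFrame:
    """Local extrema of both signs with prominence >= factor x noise scale."""
    noise = _noise_scale(values)
    floor = prominence_factor * noise if noise > 0 else np.inf
    rows = []
    for sign, v in ((+1, values), (-1, -values)):
        idx, props = find_peaks(v, prominence=floor)
        for i, prom in zip(idx, props["prominences"]):
            rows.append({"position": float(axis[i]),
                         "amplitude": float(values[i]),
                         "prominence": float(prom) * 1.0,
                         "sign": sign})
    df = pd.DataFrame(rows, columns=["position", "amplitude", "prominence", "sign"])
    return df.sort_values("position").reset_index(drop=True)


def difference_spectrum(ds: SpectralDataset, group_a, group_b,
                        prominence_factor: float = 3.0,
                        band_table: BandTable | None = None,
                        tolerance: float = 5.0) -> DifferenceSpectrum:
    """Difference of the two selections' mean spectra, with annotated peaks."""
    mean_a, _ = mean_spectrum(ds, group_a)
    mean_b, _ = mean_spectrum(ds, group_b)
    values = mean_a - mean_b
    peaks = detect_peaks(ds.axis, values, prominence_factor)
    table = band_table or load_band_table()
    peaks = assign_bands(peaks, table, tolerance)
    return DifferenceSpectrum(ds.axis.copy(), values,
                              label_a=repr(group_a), label_b=repr(group_b),
                              peaks=peaks)


def assign_bands(peaks: pd.DataFrame, table: BandTable,
                 tolerance: float = 5.0) -> pd.DataFrame:
    """Annotate each detected peak with the matching band categories.

    A peak matches a single-position band within ``tolerance`` cm^-1 and a
    range band if it falls inside the range widened by ``tolerance``;
    tolerance 0 therefore assigns only exact containment. Peaks matching
    nothing are labelled ``unassigned``; overlapping categories are all
    reported, separated by ``;``.
    """
    out = peaks.copy()
    cats = []
    for pos in out["position"]:
        hit = table.match(float(pos), tolerance)
        cats.append(";".join(hit) if hit else "unassigned")
    out["categories"] = cats
    return out
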