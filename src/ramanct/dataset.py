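"""In-memory container for collections of single-cell Raman spectra.

A :class:`SpectralDataset` holds a shared wavenumber axis (cm^-1), an
``(n_spectra, n_channels)`` intensity matrix, and a per-spectrum metadata
table with the hierarchical labels of the experiment: acquisition batch,
animal, disease group (``sham`` vs ``sick``), disease model (``PCI`` vs
``LPS``), and cell. All downstream stages (preprocessing, calibration,
chemometrics, difference spectra) operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("sham", "sick")
MODELS = ("PCI", "LPS")

#: Metadata columns every dataset carries, in canonical order.
META_COLUMNS = ("spectrum_id", "batch_id", "mouse_id", "group", "model", "cell_id")


def validate_axis(axis: np.ndarray) -> np.ndarray:
    """Validate a wavenumber axis: finite, positive, strictly increasing."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size == 0:
        raise ValueError("wavenumber axis must be a non-empty 1-D array")
    if not np.all(np.isfinite(axis)):
        raise ValueError("wavenumber axis contains non-finite values")
    if np.any(axis <= 0):
        raise ValueError("wavenumber axis must be strictly positive (cm^-1)")
    if np.any(np.diff(axis) <= 0):
        raise ValueError("wavenumber axis must be strictly increasing")
    return axis


@dataclass
class SpectralDataset:
    """Aligned spectra on one wavenumber axis with hierarchical metadata.

    Parameters
    ----------
    axis : ndarray of shape (n_channels,)
        Shared wavenumber axis in cm^-1, strictly increasing.
    intensities : ndarray of shape (n_spectra, n_channels)
        Intensity matrix in arbitrary counts; row i belongs to ``meta`` row i.
    meta : DataFrame
        One row per spectrum with columns ``spectrum_id, batch_id, mouse_id,
        group, model, cell_id``. ``spectrum_id`` values must be unique.
    provenance : list of str
        Free-text log of processing steps already applied, oldest first.
    """

    axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.axis.size:
            raise ValueError(
                f"intensity matrix has {self.intensities.shape[1]} channels, "
                f"axis has {self.axis.size}"
            )
        meta = pd.DataFrame(self.meta).reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if len(meta) != self.intensities.shape[0]:
            raise ValueError(
                f"{len(meta)} metadata rows for {self.intensities.shape[0]} spectra"
            )
        if meta["spectrum_id"].duplicated().any():
            dupes = meta.loc[meta["spectrum_id"].duplicated(), "spectrum_id"].tolist()
            raise ValueError(f"duplicate spectrum_id values: {dupes[:5]}")
        bad_group = set(meta["group"]) - set(GROUPS)
        if bad_group:
            raise ValueError(f"group labels outside {GROUPS}: {sorted(bad_group)}")
        bad_model = set(meta["model"]) - set(MODELS)
        if bad_model:
            raise ValueError(f"model labels outside {MODELS}: {sorted(bad_model)}")
        self.meta = meta[list(META_COLUMNS)].copy()

    # -- basic introspection -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.axis.size

    def __len__(self) -> int:
        return self.n_spectra

    # -- derivation helpers --------------------------------------------------
    def with_intensities(self, intensities: np.ndarray, note: str | None = None) -> "SpectralDataset":
        """Copy of the dataset with a new intensity matrix (same axis/meta)."""
        prov = list(self.provenance) + ([note] if note else [])
        return SpectralDataset(self.axis.copy(), np.asarray(intensities, float),
                               self.meta.copy(), prov)

    def with_axis(self, axis: np.ndarray, intensities: np.ndarray,
                  note: str | None = None) -> "SpectralDataset":
        """Copy with a new axis and matching intensity matrix."""
        prov = list(self.provenance) + ([note] if note else [])
        return SpectralDataset(np.asarray(axis, float), np.asarray(intensities, float),
                               self.meta.copy(), prov)

    def select(self, predicate: Mapping[str, object] | Callable[[pd.DataFrame], np.ndarray]) -> "SpectralDataset":
        """Subset by metadata.

        ``predicate`` is either a mapping of column -> required value
        (e.g. ``{"group": "sick", "model": "PCI"}``) or a callable taking the
        metadata frame and returning a boolean mask.
        """
        mask = self.mask(predicate)
        if not mask.any():
            raise ValueError(f"selection matched no spectra: {predicate!r}")
        return SpectralDataset(self.axis.copy(), self.intensities[mask],
                               self.meta.loc[mask].reset_index(drop=True),
                               list(self.provenance))

    def mask(self, predicate: Mapping[str, object] | Callable[[pd.DataFrame], np.ndarray]) -> np.ndarray:
        if callable(predicate):
            mask = np.asarray(predicate(self.meta), dtype=bool)
        else:
            mask = np.ones(len(self.meta), dtype=bool)
            for col, val in predicate.items():
                if col not in self.meta.columns:
                    raise KeyError(f"unknown metadata column {col!r}")
                mask &= (self.meta[col] == val).to_numpy()
        if mask.shape != (self.n_spectra,):
            raise ValueError("predicate mask has wrong length")
        return mask

    def log(self, note: str) -> None:
        self.provenance.append(note)


def resample_to_axis(ds: SpectralDataset, target: np.ndarray) -> SpectralDataset:
    """Linearly interpolate every spectrum onto ``target``.

    ``target`` must lie within the convex hull of the source axis;
    extrapolation is refused.
    """
    target = validate_axis(np.asarray(target, dtype=float))
    if target[0] < ds.axis[0] - 1e-9 or target[-1] > ds.axis[-1] + 1e-9:
        raise ValueError(
            f"target axis [{target[0]:.2f}, {target[-1]:.2f}] extends past source "
            f"[{ds.axis[0]:.2f}, {ds.axis[-1]:.2f}]; extrapolation not supported"
        )
    out = np.empty((ds.n_spectra, target.size))
    for i in range(ds.n_spectra):
        out[i] = np.interp(target, ds.axis, ds.intensities[i])
    return ds.with_axis(target, out,
                        note=f"resample_to_axis: {target.size} channels "
                             f"[{target[0]:.1f}, {target[-1]:.1f}] cm-1")


def uniform_axis(low: float, high: float, step: float = 1.0) -> np.ndarray:
    """Uniform wavenumber grid ``low, low+step, ... <= high`` (cm^-1)."""
    n = int(np.floor((high - low) / step + 1e-9)) + 1
    return validate_axis(low + step * np.arange(n))
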