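"""Reading and writing spectral tables as plain delimited text.

Two dialects are supported:

* **wide** — one CSV whose first column is the wavenumber axis and each
  further column one spectrum (header = spectrum_id), plus a sidecar
  metadata CSV ``<stem>.meta.csv``.
* **long** — a tidy CSV with columns ``spectrum_id, wavenumber, intensity``
  plus the same sidecar metadata CSV keyed by ``spectrum_id``.

The sidecar carries ``spectrum_id, batch_id, mouse_id, group, model,
cell_id``. Spectra with no metadata row are rejected with a report naming
the missing ids.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS, SpectralDataset, validate_axis

_FORMATS = ("wide", "long")


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.csv")


def read_spectra(path: str | os.PathLike, format: str = "wide") -> SpectralDataset:
    """Read a spectral table plus its metadata sidecar into a dataset.

    Raises
    ------
    ValueError
        If the axis is non-monotone, spectra have mismatched lengths, or
        any spectrum lacks a metadata row (the error names the missing ids).
    """
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = pd.read_csv(_meta_path(path), dtype=str)
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata sidecar missing columns: {missing_cols}")

    if format == "wide":
        table = pd.read_csv(path)
        axis = validate_axis(table.iloc[:, 0].to_numpy(dtype=float))
        ids = [str(c) for c in table.columns[1:]]
        intens = table.iloc[:, 1:].to_numpy(dtype=float).T
    else:
        table = pd.read_csv(path, dtype={"spectrum_id": str})
        for col in ("spectrum_id", "wavenumber", "intensity"):
            if col not in table.columns:
                raise ValueError(f"long format requires column {col!r}")
        ids = list(dict.fromkeys(table["spectrum_id"]))  # preserve file order
        groups = {sid: g for sid, g in table.groupby("spectrum_id", sort=False)}
        axis = validate_axis(groups[ids[0]]["wavenumber"].to_numpy(dtype=float))
        rows = []
        for sid in ids:
            g = groups[sid]
            w = g["wavenumber"].to_numpy(dtype=float)
            if w.shape != axis.shape or not np.allclose(w, axis):
                raise ValueError(
                    f"spectrum {sid!r} is not on the shared wavenumber axis"
                )
            rows.append(g["intensity"].to_numpy(dtype=float))
        intens = np.vstack(rows)

    known = set(meta["spectrum_id"])
    orphans = [sid for sid in ids if sid not in known]
    if orphans:
        raise ValueError(
            f"{len(orphans)} spectra lack metadata entries: {orphans[:10]}"
        )
    meta = meta.set_index("spectrum_id").loc[ids].reset_index()
    ds = SpectralDataset(axis, intens, meta)
    ds.log(f"read_spectra: {path.name} ({format}, {len(ids)} spectra)")
    return ds


def write_spectra(ds: SpectralDataset, path: str | os.PathLike,
                  format: str = "wide") -> None:
    """Write the dataset and its metadata sidecar; inverse of read_spectra."""
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {_FORMATS}, got {format!r}")
    if ds.n_spectra == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    if format == "wide":
        table = pd.DataFrame({"wavenumber": ds.axis})
        for i, sid in enumerate(ds.meta["spectrum_id"]):
            table[sid] = ds.intensities[i]
        table.to_csv(path, index=False)
    else:
        n = ds.n_channels
        table = pd.DataFrame({
            "spectrum_id": np.repeat(ds.meta["spectrum_id"].to_numpy(), n),
            "wavenumber": np.tile(ds.axis, ds.n_spectra),
            "intensity": ds.intensities.ravel(),
        })
        table.to_csv(path, index=False)
    ds.meta.to_csv(_meta_path(path), index=False)
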