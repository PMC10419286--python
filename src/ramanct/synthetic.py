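"""Synthetic single-cell Raman data with known ground truth.

The generator emulates the hierarchical structure of a two-arm murine
immune-profiling experiment — acquisition batches, sham and sick animals
within each batch, cells per animal, spectra per cell — and the spectral
phenomenology that the analysis pipeline must cope with:

* Gaussian Raman bands at catalogue positions (fingerprint bands ~10 cm^-1
  FWHM, CH-stretch bands 25-40 cm^-1);
* class-dependent multiplicative band effects (nucleic-acid bands 785,
  1094 and 1334 cm^-1 elevated in sick animals; amino-acid bands 527 and
  641 cm^-1 and the lipid ester band 1754 cm^-1 elevated in sham), scaled
  globally by ``effect_scale`` (0 = null data);
* log-normal per-animal band jitter and gain (biological heterogeneity),
  log-normal per-batch gain and baseline variation (acquisition drift);
* a smooth polynomial + broad-hump fluorescence baseline, additive
  Gaussian noise, and Poisson-placed single-channel cosmic spikes;
* an optional constant wavenumber miscalibration (``axis_shift``) applied
  to both the cell spectra and the companion calibration-reference
  spectrum.

Everything stochastic flows from one seed; the returned ground truth
carries the clean (band-signal-only) spectra, the class templates, and
every injected spike, so each pipeline stage can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SpectralDataset, uniform_axis

# (center cm^-1, FWHM cm^-1, base amplitude) — positions follow the shipped
# band catalogue; amplitudes are generic cell-spectrum proportions.
DEFAULT_BANDS: tuple = (
    (527.0, 10.0, 0.30),   # amino acids
    (554.0, 10.0, 0.20),
    (596.0, 9.0, 0.15),
    (641.0, 10.0, 0.28),   # amino acids
    (695.0, 10.0, 0.15),
    (743.0, 10.0, 0.18),
    (785.0, 10.0, 0.55),   # nucleic acids (O-P-O backbone / pyrimidine)
    (852.0, 10.0, 0.25),
    (1004.0, 6.0, 0.50),   # phenylalanine
    (1094.0, 12.0, 0.45),  # nucleic acids (PO2-)
    (1127.0, 10.0, 0.25),
    (1254.0, 15.0, 0.35),
    (1334.0, 12.0, 0.40),  # nucleic acids
    (1449.0, 14.0, 0.60),  # CH deformation
    (1576.0, 11.0, 0.30),
    (1654.0, 18.0, 0.70),  # amide I
    (1754.0, 12.0, 0.18),  # lipid C=O ester
    (2849.0, 25.0, 0.50),  # lipid CH2
    (2885.0, 28.0, 0.70),
    (2936.0, 32.0, 1.60),  # CH3 stretch
    (3011.0, 25.0, 0.25),  # =C-H unsaturated lipid
)

#: sick / sham intensity ratio per band center (exponentiated by effect_scale)
DEFAULT_CLASS_EFFECTS: dict = {
    785.0: 1.30, 1094.0: 1.30, 1334.0: 1.25,   # up in sick
    527.0: 0.78, 641.0: 0.78, 1754.0: 0.75,    # up in sham
}

DEFAULT_REFERENCE_PEAKS: tuple = (
    390.9, 465.1, 504.0, 651.6, 710.8, 797.2, 834.5, 857.9, 968.7,
    1105.5, 1168.5, 1236.8, 1278.5, 1323.9, 1371.5, 1515.1, 1561.6,
    1648.4, 2931.1, 3064.6,
)


@dataclass
class SyntheticConfig:
    """Full description of the generative model; defaults give a clearly
    separable sepsis-like experiment of 4 batches x 4 mice/group x 50 cells."""

    bands: tuple = DEFAULT_BANDS
    class_effects: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS))
    effect_scale: float = 1.0
    n_batches: int = 4
    mice_per_group_per_batch: int = 4
    cells_per_mouse: int = 50
    spectra_per_cell: int = 1
    baseline_scale: float = 5.0
    baseline_poly: tuple = (0.5, 0.4, 0.3)   # coefficients in normalized axis
    hump_center: float = 1400.0              # broad fluorescence hump (cm^-1)
    hump_sigma: float = 1800.0
    hump_weight: float = 0.5
    noise_sd: float = 0.02
    spike_rate: float = 0.0
    spikes_per_spectrum: int | None = None
    spike_amplitude: float = 30.0  # multiple of noise_sd
    batch_effect_sd: float = 0.03
    mouse_gain_sd: float = 0.03
    mouse_band_jitter_sd: float = 0.01
    cell_gain_sd: float = 0.03
    axis_start: float = 350.0
    axis_stop: float = 3100.0
    axis_step: float = 1.0
    axis_shift: float = 0.0
    model: str = "PCI"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_batches", "mice_per_group_per_batch", "cells_per_mouse",
                     "spectra_per_cell"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ValueError("noise_sd and spike_rate must be >= 0")
        if self.model not in ("PCI", "LPS"):
            raise ValueError("model must be 'PCI' or 'LPS'")

    def axis(self) -> np.ndarray:
        return uniform_axis(self.axis_start, self.axis_stop, self.axis_step)


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    clean: np.ndarray               # (n_spectra, n_channels) band signal only
    templates: dict                 # class -> population clean template
    spikes: pd.DataFrame            # spectrum_index, channel, amplitude
    config: SyntheticConfig


_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _band_profiles(true_w: np.ndarray, bands) -> np.ndarray:
    """(n_bands, n_channels) unit-amplitude Gaussian profiles."""
    centers = np.array([b[0] for b in bands])
    sigmas = np.array([b[1] for b in bands]) * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((true_w[None, :] - centers[:, None]) / sigmas[:, None]) ** 2)


def _class_factors(cfg: SyntheticConfig, group: str) -> np.ndarray:
    amps = np.array([b[2] for b in cfg.bands])
    if group == "sham":
        return amps
    ratios = np.array([cfg.class_effects.get(b[0], 1.0) for b in cfg.bands])
    return amps * ratios ** cfg.effect_scale


def class_template(cfg: SyntheticConfig, group: str) -> np.ndarray:
    """Population-level clean band signal of a class on the recorded axis."""
    true_w = cfg.axis() - cfg.axis_shift
    return _class_factors(cfg, group) @ _band_profiles(true_w, cfg.bands)


def _baseline(cfg: SyntheticConfig, axis: np.ndarray, scale: float) -> np.ndarray:
    x = (axis - cfg.axis_start) / (cfg.axis_stop - cfg.axis_start)
    poly = sum(c * x**k for k, c in enumerate(cfg.baseline_poly))
    hump = cfg.hump_weight * np.exp(-(((axis - cfg.hump_center) / cfg.hump_sigma) ** 2))
    return cfg.baseline_scale * scale * (poly + hump)


def generate_dataset(cfg: SyntheticConfig) -> tuple[SpectralDataset, GroundTruth]:
    """Draw a full hierarchical dataset plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis()
    true_w = axis - cfg.axis_shift
    profiles = _band_profiles(true_w, cfg.bands)
    n_bands = len(cfg.bands)

    spectra, clean_rows, meta_rows, spike_rows = [], [], [], []
    idx = 0
    for b in range(1, cfg.n_batches + 1):
        batch_gain = rng.lognormal(0.0, cfg.batch_effect_sd)
        batch_base = rng.lognormal(0.0, cfg.batch_effect_sd)
        for group in ("sham", "sick"):
            factors = _class_factors(cfg, group)
            for m in range(1, cfg.mice_per_group_per_batch + 1):
                mouse_id = f"b{b}_{group}_m{m}"
                mouse_gain = rng.lognormal(0.0, cfg.mouse_gain_sd)
                jitter = rng.lognormal(0.0, cfg.mouse_band_jitter_sd, size=n_bands)
                mouse_factors = factors * jitter * mouse_gain * batch_gain
                for c in range(1, cfg.cells_per_mouse + 1):
                    cell_gain = rng.lognormal(0.0, cfg.cell_gain_sd)
                    for s in range(1, cfg.spectra_per_cell + 1):
                        clean = (mouse_factors * cell_gain) @ profiles
                        y = clean + _baseline(cfg, axis, batch_base)
                        y = y + rng.normal(0.0, cfg.noise_sd, size=axis.size)
                        n_spikes = (cfg.spikes_per_spectrum
                                    if cfg.spikes_per_spectrum is not None
                                    else rng.poisson(cfg.spike_rate))
                        for _ in range(n_spikes):
                            ch = int(rng.integers(2, axis.size - 2))
                            amp = (cfg.spike_amplitude * cfg.noise_sd
                                   * rng.uniform(0.8, 1.2))
                            y[ch] += amp
                            spike_rows.append({"spectrum_index": idx,
                                               "channel": ch, "amplitude": amp})
                        spectra.append(y)
                        clean_rows.append(clean)
                        meta_rows.append({
                            "spectrum_id": f"{mouse_id}_c{c}_s{s}",
                            "batch_id": f"batch{b}",
                            "mouse_id": mouse_id,
                            "group": group,
                            "model": cfg.model,
                            "cell_id": f"{mouse_id}_c{c}",
                        })
                        idx += 1
    ds = SpectralDataset(axis, np.vstack(spectra), pd.DataFrame(meta_rows))
    ds.log(f"generate_dataset: seed={cfg.seed}, effect_scale={cfg.effect_scale}, "
           f"{idx} spectra, axis_shift={cfg.axis_shift}")
    truth = GroundTruth(
        clean=np.vstack(clean_rows),
        templates={g: class_template(cfg, g) for g in ("sham", "sick")},
        spikes=pd.DataFrame(spike_rows,
                            columns=["spectrum_index", "channel", "amplitude"]),
        config=cfg,
    )
    return ds, truth


def generate_reference(cfg: SyntheticConfig,
                       peak_positions=DEFAULT_REFERENCE_PEAKS,
                       peak_fwhm: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Sharp-band calibration-standard spectrum on the (mis)recorded axis.

    Returns ``(axis, intensities)``; with ``axis_shift`` s each catalogue
    peak appears at its literature position + s on the recorded axis.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    axis = cfg.axis()
    true_w = axis - cfg.axis_shift
    sigma = peak_fwhm * _FWHM_TO_SIGMA
    y = np.zeros_like(axis)
    for i, pos in enumerate(peak_positions):
        amp = 0.6 + 0.4 * ((i * 7919) % 11) / 10.0  # fixed, varied amplitudes
        y += amp * np.exp(-0.5 * ((true_w - pos) / sigma) ** 2)
    y += rng.normal(0.0, cfg.noise_sd, size=axis.size)
    return axis, y
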