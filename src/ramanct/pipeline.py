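"""Single-config orchestration of the full analysis.

``run_pipeline`` drives synth/ingest -> preprocess -> calibrate ->
aggregate -> model (k-fold and batchwise CV) -> majority vote -> difference
spectrum from one dictionary config, writing every stage product plus a
provenance log into a run directory. Rerunning the same config reproduces
the metrics bit for bit: every random operation draws from the single
top-level seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .calibrate import fit_calibration
from .chemometrics import (AggregationSpec, aggregate_spectra, batchwise_cv,
                           fit_model, kfold_cv)
from .dataset import SpectralDataset
from .difference import difference_spectrum
from .preprocess import PreprocessConfig, preprocess_pipeline, snip_baseline
from .synthetic import SyntheticConfig, generate_dataset, generate_reference

_ALLOWED_TOP = {"seed", "synthetic", "input", "preprocess", "calibrate",
                "aggregation", "model", "difference"}


def validate_config(cfg: dict) -> dict:
    """Check the run config; a missing seed is a hard error."""
    unknown = set(cfg) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    if "seed" not in cfg:
        raise ValueError("config must set an explicit top-level seed")
    if "synthetic" not in cfg and "input" not in cfg:
        raise ValueError("config needs either a 'synthetic' or an 'input' section")
    return cfg


def _parse_predicate(spec) -> dict:
    """'group=sick,model=PCI' or a mapping -> selector dict."""
    if isinstance(spec, dict):
        return spec
    out = {}
    for part in str(spec).split(","):
        key, _, val = part.partition("=")
        if not _:
            raise ValueError(f"predicate term {part!r} is not key=value")
        out[key.strip()] = val.strip()
    return out


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute all stages; return the metrics dict written to metrics.json."""
    cfg = validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    log: list[str] = [f"run_pipeline: seed={seed}"]

    # --- data ---------------------------------------------------------------
    if "synthetic" in cfg:
        syn = SyntheticConfig(**{**cfg.get("synthetic", {}), "seed": seed})
        ds, truth = generate_dataset(syn)
        log.append(f"synthetic: {ds.n_spectra} spectra, "
                   f"effect_scale={syn.effect_scale}, axis_shift={syn.axis_shift}")
    else:
        inp = cfg["input"]
        ds = io.read_spectra(inp["path"], inp.get("format", "long"))
        syn = None
        log.append(f"input: {inp['path']} ({ds.n_spectra} spectra)")

    # --- calibration --------------------------------------------------------
    calibrator = None
    cal_cfg = cfg.get("calibrate", {})
    want_cal = cal_cfg.get("enabled", syn is not None and syn.axis_shift != 0)
    if want_cal:
        if syn is not None:
            axis, ref = generate_reference(syn)
        else:
            ref_ds = io.read_spectra(cal_cfg["reference"], cal_cfg.get("format", "wide"))
            axis, ref = ref_ds.axis, ref_ds.intensities[0]
        _, ref_corr = snip_baseline(ref)
        calibrator = fit_calibration(axis, ref_corr,
                                     poly_degree=int(cal_cfg.get("poly_degree", 2)))
        log.append(f"calibrate: {calibrator.n_peaks_used_} peaks, "
                   f"rmse={calibrator.fit_rmse_:.4f} cm-1")

    # --- preprocessing ------------------------------------------------------
    pp_cfg = PreprocessConfig(**cfg.get("preprocess", {}))
    proc, spikes = preprocess_pipeline(ds, pp_cfg, calibration=calibrator)
    spikes.to_csv(out / "spike_report.csv", index=False)
    log.append(f"preprocess: {len(spikes)} spike channels repaired; "
               f"{proc.n_channels} channels retained")

    # --- aggregation + models ----------------------------------------------
    agg_kwargs = dict(cfg.get("aggregation", {}))
    agg_kwargs.setdefault("seed", seed)
    agg = aggregate_spectra(proc, AggregationSpec(**agg_kwargs))
    log.append(f"aggregate: {agg.n_spectra} aggregates "
               f"(group_size={agg_kwargs.get('group_size', 10)})")
    mdl = cfg.get("model", {})
    n_pcs = int(mdl.get("n_pcs", 5))
    classifier = str(mdl.get("classifier", "lda"))
    k = int(mdl.get("k", 10))

    metrics: dict = {"seed": seed, "n_spectra": ds.n_spectra,
                     "n_aggregates": agg.n_spectra,
                     "n_pcs": n_pcs, "classifier": classifier}
    res_k = kfold_cv(agg, k=k, n_pcs=n_pcs, classifier=classifier, seed=seed)
    metrics["kfold"] = res_k.summary()
    res_b = batchwise_cv(agg, n_pcs=n_pcs, classifier=classifier, seed=seed)
    metrics["batchwise"] = res_b.summary()
    res_k.predictions.to_csv(out / "kfold_predictions.csv", index=False)
    res_k.vote_table.to_csv(out / "kfold_votes.csv", index=False)
    res_b.predictions.to_csv(out / "batchwise_predictions.csv", index=False)
    res_b.vote_table.to_csv(out / "batchwise_votes.csv", index=False)
    log.append(f"kfold_cv: BA={res_k.balanced_accuracy:.4f} "
               f"kappa={res_k.cohens_kappa:.4f}")
    log.append(f"batchwise_cv: BA={res_b.balanced_accuracy:.4f} "
               f"kappa={res_b.cohens_kappa:.4f}")

    final = fit_model(agg, n_pcs=n_pcs, classifier=classifier, seed=seed)
    if classifier == "lda":
        pd.DataFrame({"wavenumber": agg.axis,
                      "ld_loading": final.ld_loading()}
                     ).to_csv(out / "ld_loading.csv", index=False)

    # --- difference spectrum ------------------------------------------------
    dcfg = cfg.get("difference", {"group_a": "group=sick", "group_b": "group=sham"})
    diff = difference_spectrum(proc, _parse_predicate(dcfg["group_a"]),
                               _parse_predicate(dcfg["group_b"]))
    pd.DataFrame({"wavenumber": diff.axis, "difference": diff.values}
                 ).to_csv(out / "difference_spectrum.csv", index=False)
    diff.peaks.to_csv(out / "difference_peaks.csv", index=False)
    log.append(f"difference: {len(diff.peaks)} annotated peaks")

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    with open(out / "provenance.log", "w") as fh:
        fh.write("\n".join(log + list(proc.provenance)) + "\n")
    return metrics
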