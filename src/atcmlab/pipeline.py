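"""End-to-end orchestration: simulate -> extract -> WED -> noise -> fit.

A run is described by a single YAML/JSON-style mapping with one entry per
acquisition (phantom, direction, protocol, pitch, seed, ...). Outputs per
acquisition are CSV curves, optional rendered DICOM fixtures, a JSON fit
report and a figure overlaying dose, WED and noise versus table position;
a run-level summary table mirrors the acquisition matrix (ID, phantom,
direction, protocol, pitch, mean CTDIvol, DLP). Every output file is listed
in a manifest and runs are resumable: completed acquisitions are skipped
when their declared outputs already exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from . import __version__
from .atcm_sim import (PROTOCOLS, ModulationCurve, Protocol, dlp,
                       render_series, simulate_axial, simulate_modulation)
from .curves_io import curve_to_csv, profile_to_csv, write_series
from .fitting import fit_model
from .noise import (CTDI_T_BODY_ROI, CTDI_T_HEAD_ROI, PMMA_VALIDITY,
                    ROIConfig, noise_curve, noise_to_frame)
from .phantoms import PHANTOM_NAMES, analytic_wed_profile, build_phantom
from .wed import wed_series

log = logging.getLogger("atcmlab")


class ConfigError(ValueError):
    pass


_ACQ_KEYS = {"id", "phantom", "direction", "protocol", "pitch", "seed",
             "mode", "lookahead_mm", "weights", "fit", "render",
             "write_dicom", "d_max", "step_mm"}
_TOP_KEYS = {"out_dir", "acquisitions", "profile_dz", "profile_margin_mm",
             "scan_margin_mm", "noise_sigma_ref", "pixel_size", "matrix"}


def validate_config(config: dict) -> None:
    """Schema check; raises ConfigError naming every offending key."""
    errors = []
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for key in set(config) - _TOP_KEYS:
        errors.append(f"unknown top-level key: {key!r}")
    acqs = config.get("acquisitions")
    if not isinstance(acqs, list) or not acqs:
        errors.append("'acquisitions' must be a non-empty list")
        acqs = []
    for i, acq in enumerate(acqs):
        where = f"acquisitions[{i}]"
        if not isinstance(acq, dict):
            errors.append(f"{where}: must be a mapping")
            continue
        for key in set(acq) - _ACQ_KEYS:
            errors.append(f"{where}: unknown key {key!r}")
        phantom = acq.get("phantom")
        if phantom not in PHANTOM_NAMES:
            errors.append(f"{where}: 'phantom' must be one of"
                          f" {PHANTOM_NAMES}, got {phantom!r}")
        if acq.get("direction", "HF") not in ("HF", "FH"):
            errors.append(f"{where}: 'direction' must be HF or FH")
        proto = acq.get("protocol", "thorax")
        if not (isinstance(proto, dict) or proto in PROTOCOLS):
            errors.append(f"{where}: 'protocol' must be one of"
                          f" {sorted(PROTOCOLS)} or a mapping")
        if "seed" in acq and not isinstance(acq["seed"], int):
            errors.append(f"{where}: 'seed' must be an integer")
    if errors:
        raise ConfigError("invalid pipeline config:\n  " +
                          "\n  ".join(errors))


def _protocol_for(acq: dict) -> Protocol:
    proto = acq.get("protocol", "thorax")
    if isinstance(proto, dict):
        protocol = Protocol(**proto)
    else:
        protocol = PROTOCOLS[proto]
    if "pitch" in acq:
        protocol = replace(protocol, pitch=float(acq["pitch"]))
    if acq.get("mode"):
        protocol = replace(protocol, mode=acq["mode"])
    return protocol


def _default_roi(phantom_name: str) -> list[ROIConfig]:
    if phantom_name == "ctdi_t":
        return [CTDI_T_HEAD_ROI, CTDI_T_BODY_ROI]
    if phantom_name.startswith("ctdi"):
        return [ROIConfig(validity_range=PMMA_VALIDITY)]
    return [ROIConfig()]


def _plot_overlay(path: Path, curve: ModulationCurve, profile,
                  noise_df: pd.DataFrame | None,
                  fit_curve: np.ndarray | None) -> None:
    fig = Figure(figsize=(8, 4.5))
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    ax.plot(curve.z, curve.ctdi_vol, "b.-", ms=2, lw=0.8,
            label=f"CTDIvol ({curve.direction})")
    if fit_curve is not None:
        ax.plot(curve.z, fit_curve, "r-", lw=1.0, label="fitted model")
    ax.set_xlabel("table position (mm), Head at positive values")
    ax.set_ylabel("CTDIvol (mGy)")
    ax2 = ax.twinx()
    ax2.plot(profile.z, profile.wed, "g-", lw=1.0, label="WED")
    ax2.set_ylabel("WED (mm)")
    if noise_df is not None:
        valid = noise_df[noise_df["valid"]]
        ax3 = ax.twinx()
        ax3.spines.right.set_position(("outward", 45))
        ax3.plot(valid["table_position_mm"], valid["sd_hu"], "k.", ms=2,
                 label="SD (valid)")
        ax3.set_ylabel("SD (HU)")
    ax.invert_xaxis()  # scan direction reading order: Head on the left
    handles, labels = ax.get_legend_handles_labels()
    ax.legend(handles, labels, loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)


def run_pipeline(config, out_dir=None, resume: bool = False) -> Path:
    """Run the full analysis described by ``config``.

    ``config`` may be a mapping or a path to a YAML file. Returns the run
    directory containing per-acquisition outputs, ``summary.csv`` and
    ``manifest.json``. Deterministic given the per-acquisition seeds.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    validate_config(config)
    run_dir = Path(out_dir or config.get("out_dir", "atcmlab_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()
    log.info("run dir %s, config hash %s, atcmlab %s", run_dir,
             cfg_hash[:12], __version__)

    manifest_path = run_dir / "manifest.json"
    manifest = {"config_hash": cfg_hash, "version": __version__,
                "acquisitions": {}, "files": []}
    if resume and manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash:
            manifest = old

    dz = float(config.get("profile_dz", 2.0))
    margin = float(config.get("profile_margin_mm", 60.0))
    scan_margin = float(config.get("scan_margin_mm", 40.0))
    rows = []
    for acq in config["acquisitions"]:
        acq_id = str(acq.get("id", len(rows) + 1))
        acq_dir = run_dir / f"acq_{acq_id}"
        done = manifest["acquisitions"].get(acq_id)
        if resume and done and all(Path(p).exists() for p in done["files"]):
            log.info("acquisition %s already complete; skipping", acq_id)
            rows.append(done["summary"])
            continue
        acq_dir.mkdir(parents=True, exist_ok=True)
        files: list[str] = []

        phantom = build_phantom(acq["phantom"])
        protocol = _protocol_for(acq)
        direction = acq.get("direction", "HF")
        seed = int(acq.get("seed", 0))
        profile = analytic_wed_profile(phantom, dz=dz, margin=margin)
        kwargs = dict(direction=direction,
                      lookahead_mm=acq.get("lookahead_mm"),
                      seed=seed, scan_margin_mm=scan_margin)
        if acq.get("weights"):
            kwargs["weights"] = tuple(acq["weights"])
        if protocol.mode == "axial":
            curve = simulate_axial(profile, protocol,
                                   step_mm=acq.get("step_mm"), **kwargs)
        else:
            curve = simulate_modulation(profile, protocol, **kwargs)

        curve_path = acq_dir / "curve.csv"
        curve_to_csv(curve, curve_path)
        files.append(str(curve_path))
        wed_path = acq_dir / "wed_analytic.csv"
        profile_to_csv(profile, wed_path)
        files.append(str(wed_path))

        noise_df = None
        if acq.get("render", False):
            records = render_series(
                curve, phantom, seed=seed,
                noise_sigma_ref=float(config.get("noise_sigma_ref", 12.0)),
                pixel_size=float(config.get("pixel_size", 3.0)),
                matrix=int(config.get("matrix", 128)))
            measured = wed_series(records)
            profile_to_csv(measured, acq_dir / "wed_measured.csv")
            files.append(str(acq_dir / "wed_measured.csv"))
            samples = []
            for roi in _default_roi(acq["phantom"]):
                samples.extend(noise_curve(records, roi))
            noise_df = noise_to_frame(samples)
            noise_df.to_csv(acq_dir / "noise.csv", index=False)
            files.append(str(acq_dir / "noise.csv"))
            if acq.get("write_dicom", False):
                paths = write_series(records, acq_dir / "dicom", protocol,
                                     direction, acq["phantom"])
                files.extend(str(p) for p in paths)

        fit_curve_vals = None
        if acq.get("fit", False):
            d_max = int(acq.get("d_max", 40))
            result = fit_model([(curve, profile)],
                               d_candidates=range(1, d_max + 1))
            report = {
                "a": result.params.a, "b": result.params.b,
                "c": result.params.c, "d": result.params.d,
                "weights": list(result.params.weights),
                "rmse": result.rmse, "r2": result.r2,
                "d_grid_profile": {str(k): v for k, v in
                                   sorted(result.d_grid_profile.items())},
            }
            (acq_dir / "fit.json").write_text(json.dumps(report, indent=2))
            files.append(str(acq_dir / "fit.json"))
            fit_curve_vals = curve.ctdi_vol - result.per_curve_residuals[0]

        plot_path = acq_dir / "overlay.png"
        _plot_overlay(plot_path, curve, profile, noise_df, fit_curve_vals)
        files.append(str(plot_path))

        summary = {
            "id": acq_id, "phantom": acq["phantom"],
            "direction": direction, "protocol": protocol.name,
            "pitch": protocol.pitch,
            "mean_ctdi_vol_mGy": float(np.mean(curve.ctdi_vol)),
            "dlp_mGycm": dlp(curve),
        }
        rows.append(summary)
        manifest["acquisitions"][acq_id] = {"files": files,
                                            "summary": summary}
        manifest["files"].extend(files)
        manifest_path.write_text(json.dumps(manifest, indent=2))

    summary_df = pd.DataFrame(rows)
    summary_df.to_csv(run_dir / "summary.csv", index=False)
    manifest["files"].append(str(run_dir / "summary.csv"))
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return run_dir
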