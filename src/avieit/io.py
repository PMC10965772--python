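"""File formats, pipeline configuration and orchestration.

Artefacts are single self-describing HDF5 containers carrying a
``avi-eit-schema`` version attribute: voltage recordings (with optional
simulation ground truth), phantoms and reconstruction models.  A CSV
fallback exists for recordings.  ``run_pipeline`` ties the stages together:
reconstruct -> global curve -> cardiac filter -> breath detection/selection
-> ventilation variables -> breathing-pattern labels -> report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import breaths as br
from . import brp as brp_mod
from . import ventilation as vent
from .forward import StimulationPattern, VoltageRecording
from .geometry import ContourSet, Phantom, PixelGrid, make_pixel_mask
from .greit import ImageStream, ReconstructionModel, reconstruct

__all__ = [
    "SCHEMA",
    "read_recording",
    "write_recording",
    "write_recording_csv",
    "read_recording_csv",
    "write_phantom",
    "read_phantom",
    "write_model",
    "read_model",
    "PipelineConfig",
    "run_pipeline",
]

SCHEMA = 1
log = logging.getLogger("avieit")


def _pattern_to_group(g: h5py.Group, pat: StimulationPattern) -> None:
    g.create_dataset("injections", data=pat.injections)
    g.create_dataset("channel_injection", data=pat.channel_injection)
    g.create_dataset("meas_plus", data=pat.meas_plus)
    g.create_dataset("meas_minus", data=pat.meas_minus)
    g.attrs["n_electrodes"] = pat.n_electrodes
    g.attrs["skip"] = pat.skip


def _pattern_from_group(g: h5py.Group) -> StimulationPattern:
    return StimulationPattern(
        n_electrodes=int(g.attrs["n_electrodes"]),
        skip=int(g.attrs["skip"]),
        injections=g["injections"][...],
        channel_injection=g["channel_injection"][...],
        meas_plus=g["meas_plus"][...],
        meas_minus=g["meas_minus"][...],
    )


def write_recording(rec: VoltageRecording, path, truth=None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["avi-eit-schema"] = SCHEMA
        f.create_dataset("voltages", data=rec.voltages)
        f.create_dataset("time", data=rec.time)
        f.attrs["fps"] = rec.fps
        f.attrs["n_electrodes"] = rec.pattern.n_electrodes
        f.attrs["skip"] = rec.pattern.skip
        f.attrs["current_A"] = rec.current_a
        f.attrs["carrier_hz"] = rec.carrier_hz
        f.attrs["ref_frame"] = rec.ref_frame
        for k, v in rec.meta.items():
            f.attrs[f"meta_{k}"] = v
        _pattern_to_group(f.create_group("pattern"), rec.pattern)
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("volume", data=truth.volume_curve)
            g.create_dataset("breaths", data=np.asarray(truth.breaths, dtype=int))
            g.create_dataset("airsac_gain", data=truth.airsac_gain)
            g.attrs["brp"] = truth.brp
            g.attrs["shift"] = truth.shift
            g.attrs["ref_frame"] = truth.ref_frame


def read_recording(path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        for name in ("voltages", "time"):
            if name not in f:
                raise KeyError(f"required dataset /{name} not found in {path}")
        if "pattern" not in f:
            raise KeyError(f"pattern not found in {path}")
        fps = float(f.attrs["fps"])
        time = f["time"][...]
        if len(time) > 1:
            spacing = float(np.median(np.diff(time)))
            if spacing > 0 and abs(spacing - 1.0 / fps) > 0.01 / fps:
                log.warning("frame spacing drifts >1%% from declared fps in %s", path)
        meta = {
            k[5:]: (v.item() if hasattr(v, "item") else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        return VoltageRecording(
            voltages=f["voltages"][...],
            time=time,
            fps=fps,
            pattern=_pattern_from_group(f["pattern"]),
            current_a=float(f.attrs.get("current_A", 5e-3)),
            carrier_hz=float(f.attrs.get("carrier_hz", 192e3)),
            ref_frame=int(f.attrs.get("ref_frame", 0)),
            meta=meta,
        )


def write_recording_csv(rec: VoltageRecording, path) -> None:
    """One row per frame, channels in pattern order; first column is time."""
    arr = np.column_stack([rec.time, rec.voltages])
    header = "time_s," + ",".join(f"ch{i}" for i in range(rec.voltages.shape[1]))
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.17g")


def read_recording_csv(path, pattern: StimulationPattern, fps: float,
                       **kwargs) -> VoltageRecording:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return VoltageRecording(
        voltages=arr[:, 1:], time=arr[:, 0], fps=fps, pattern=pattern, **kwargs
    )


def write_phantom(p: Phantom, path) -> None:
    from .geometry import save_contours  # local import avoids cycle at module load

    with h5py.File(path, "w") as f:
        f.attrs["avi-eit-schema"] = SCHEMA
        f.create_dataset("nodes", data=p.nodes)
        f.create_dataset("elements", data=p.elements)
        f.create_dataset("electrode_nodes", data=p.electrode_nodes)
        f.create_dataset("element_labels", data=p.element_labels)
        f.create_dataset("mask", data=p.grid.mask)
        f.attrs["grid_origin"] = p.grid.origin
        f.attrs["grid_pixel_size"] = p.grid.pixel_size
        c = p.contours
        payload = {
            "subject_id": c.subject_id,
            "units": "mm",
            "contours": {
                "outer": c.outer.points.tolist(),
                "lung_r": c.lung_r.points.tolist(),
                "lung_l": c.lung_l.points.tolist(),
                "cardiac": c.cardiac.points.tolist(),
            },
        }
        f.attrs["contours_json"] = json.dumps(payload)


def read_phantom(path) -> Phantom:
    from .geometry import Contour

    with h5py.File(path, "r") as f:
        payload = json.loads(f.attrs["contours_json"])
        c = payload["contours"]
        cs = ContourSet(
            outer=Contour(np.asarray(c["outer"]), "outer"),
            lung_r=Contour(np.asarray(c["lung_r"]), "lung_r"),
            lung_l=Contour(np.asarray(c["lung_l"]), "lung_l"),
            cardiac=Contour(np.asarray(c["cardiac"]), "cardiac"),
            subject_id=payload.get("subject_id", ""),
        )
        p = Phantom(
            nodes=f["nodes"][...],
            elements=f["elements"][...],
            electrode_nodes=f["electrode_nodes"][...],
            element_labels=f["element_labels"][...],
            grid=PixelGrid(
                mask=f["mask"][...].astype(bool),
                origin=np.asarray(f.attrs["grid_origin"]),
                pixel_size=float(f.attrs["grid_pixel_size"]),
            ),
            pixel_elements=[],
            contours=cs,
        )
        _, p.pixel_elements = make_pixel_mask(p)
        return p


def write_model(m: ReconstructionModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["avi-eit-schema"] = SCHEMA
        f.create_dataset("R", data=m.R)
        f.create_dataset("mask", data=m.mask)
        for k, v in m.training_meta.items():
            f.attrs[k] = v


def read_model(path) -> ReconstructionModel:
    with h5py.File(path, "r") as f:
        mask = f["mask"][...].astype(bool)
        return ReconstructionModel(
            R=f["R"][...],
            mask=mask,
            shape=mask.shape,
            training_meta={k: v for k, v in f.attrs.items() if k != "avi-eit-schema"},
        )


@dataclass
class PipelineConfig:
    """Serialisable configuration for the analysis pipeline."""

    recording: str = ""
    model: str = ""
    phantom: str = ""
    out_dir: str = "results"
    cutoff_hz: float = 1.5
    prominence_frac: float = 0.2
    min_breaths: int = 6
    max_breaths: int = 10
    artefact_tol_frac: float = 0.5
    min_pause_s: float = 0.3
    pause_slope_frac: float = 0.1
    uniform_frac: float = 0.95
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def analyse_images(images: ImageStream, cfg: PipelineConfig | None = None):
    """Images -> breath table (+labels) and per-recording summary dict."""
    cfg = cfg or PipelineConfig()
    curve = br.global_curve(images)
    filtered = br.remove_cardiac(curve, cutoff_hz=cfg.cutoff_hz)
    all_breaths = br.detect_breaths(filtered, prominence_frac=cfg.prominence_frac)
    selected = br.select_artefact_free(
        all_breaths,
        min_n=cfg.min_breaths,
        max_n=cfg.max_breaths,
        tol_frac=cfg.artefact_tol_frac,
        fps=curve.fps,
    )
    table, means = vent.variables_for_breaths(images, selected)
    labels = []
    for b in selected:
        e = brp_mod.extract_expiration(filtered, b)
        pause = brp_mod.detect_pause(
            e, min_pause_s=cfg.min_pause_s, slope_frac=cfg.pause_slope_frac
        )
        labels.append(brp_mod.classify_breath(e, pause))
    table = table.assign(brp=[l.value for l in labels])
    rec_label = brp_mod.classify_recording(labels, uniform_frac=cfg.uniform_frac)
    rr = len(all_breaths) / (len(curve.z) / curve.fps) * 60.0
    summary = {
        "n_breaths_detected": len(all_breaths),
        "n_breaths_analysed": len(selected),
        "respiratory_rate_per_min": rr,
        "brp": rec_label.value,
        "brp_pause_level": rec_label.pause_level,
        **{k: float(v) for k, v in means.items()},
    }
    return table, summary, rec_label


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full analysis for one recording; returns the results directory.

    Every stage's output is persisted (breath CSV, summary JSON, config and
    log); reruns with the same config and inputs are byte-stable.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        rec = read_recording(cfg.recording)
        model = read_model(cfg.model)
        stream = reconstruct(
            model, rec.voltages[rec.ref_frame], rec.voltages, fps=rec.fps
        )
        table, summary, _ = analyse_images(stream, cfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {type(exc).__name__}: {exc}") from exc
    table.to_csv(out / "breaths.csv", index=False)
    if "recumbency" in rec.meta:
        summary["recumbency"] = rec.meta["recumbency"]
    summary["schema"] = SCHEMA
    summary["seed"] = cfg.seed
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    cfg.to_json(out / "pipeline_config.json")
    log.info("pipeline complete: %s", out)
    return out
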