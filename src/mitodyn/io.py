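"""Reading and writing the pipeline's on-disk formats.

Movies are multi-page TIFF; ground-truth tracks and ROIs are JSON sidecars;
flux traces are plain CSV with columns time_s, ocr_pmol_min, ecar_mph_min,
phase_label.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .bioenergetics import FluxTrace
from .tracks import ParticleTrack


def write_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(str(path), movie)


def read_movie(path) -> np.ndarray:
    movie = tifffile.imread(str(path))
    if movie.ndim == 2:
        movie = movie[None]
    return movie


def write_tracks_json(path, tracks: list[ParticleTrack], pixel_size: float,
                      frame_interval: float) -> None:
    """Ground-truth sidecar: per-track [frame, x_px, y_px] plus truth labels."""
    payload = {
        "pixel_size_um": pixel_size,
        "frame_interval_s": frame_interval,
        "tracks": [],
    }
    for tr in tracks:
        frames = (tr.frames if tr.frames is not None
                  else np.round(tr.times / frame_interval).astype(int))
        ys = tr.y_px if tr.y_px is not None else np.zeros(len(tr))
        payload["tracks"].append({
            "particle_id": tr.particle_id,
            "cargo_kind": tr.cargo_kind,
            "truth_mobile": tr.truth_mobile,
            "truth_speed": tr.truth_speed,
            "points": [[int(f), float(x / pixel_size), float(y)]
                       for f, x, y in zip(frames, tr.positions, ys)],
        })
    Path(path).write_text(json.dumps(payload))


def read_tracks_json(path) -> list[ParticleTrack]:
    payload = json.loads(Path(path).read_text())
    px = payload["pixel_size_um"]
    dt = payload["frame_interval_s"]
    tracks = []
    for t in payload["tracks"]:
        pts = np.asarray(t["points"], dtype=float)
        tracks.append(ParticleTrack(
            particle_id=int(t["particle_id"]),
            positions=pts[:, 1] * px,
            times=pts[:, 0] * dt,
            frames=pts[:, 0].astype(int),
            y_px=pts[:, 2],
            cargo_kind=t.get("cargo_kind", "mitochondrion"),
            truth_mobile=t.get("truth_mobile"),
            truth_speed=t.get("truth_speed")))
    return tracks


def write_flux_csv(path, trace: FluxTrace) -> None:
    pd.DataFrame({
        "time_s": trace.times_min * 60.0,
        "ocr_pmol_min": trace.ocr,
        "ecar_mph_min": trace.ecar,
        "phase_label": trace.phase_labels,
    }).to_csv(path, index=False, float_format="%.6g")


def read_flux_csv(path, well_id: str = "A1", protein_ug: float | None = None,
                  column_map: dict[str, str] | None = None) -> FluxTrace:
    """Load a flux trace; ``column_map`` maps our names to the file's columns."""
    df = pd.read_csv(path)
    cm = {"time_s": "time_s", "ocr_pmol_min": "ocr_pmol_min",
          "ecar_mph_min": "ecar_mph_min", "phase_label": "phase_label"}
    cm.update(column_map or {})
    return FluxTrace(times_min=df[cm["time_s"]].to_numpy() / 60.0,
                     ocr=df[cm["ocr_pmol_min"]].to_numpy(),
                     ecar=df[cm["ecar_mph_min"]].to_numpy(),
                     phase_labels=list(df[cm["phase_label"]]),
                     well_id=well_id, protein_ug=protein_ug)


def write_rois_json(path, rois: list[dict]) -> None:
    Path(path).write_text(json.dumps(rois))


def read_rois_json(path) -> list[dict]:
    return json.loads(Path(path).read_text())
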