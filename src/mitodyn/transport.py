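"""Kymographs, puncta detection/linking, and axonal-transport statistics.

Velocities are computed from linked 2D detections projected onto the axon
path; the kymograph is a visualization and cross-check of the same motion
(stationary organelles appear as vertical lines, moving ones as diagonals).

Definitions used throughout:

* overall velocity — |position(last) - position(first)| / elapsed time,
  i.e. net displacement over the recording, pauses included;
* mobile — overall velocity at or above 0.005 μm/s (boundary inclusive);
* instantaneous velocity — mean frame-to-frame speed of a mobile track with
  sub-threshold (paused) intervals excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .presets import MOBILITY_THRESHOLD_UM_S
from .stats import group_summary
from .tracks import ParticleTrack

# ---------------------------------------------------------------------------
# kymographs
# ---------------------------------------------------------------------------


@dataclass
class Kymograph:
    """Distance x time intensity matrix built by max-projection over a path."""

    matrix: np.ndarray         # (n_frames, n_path_positions)
    line_width: int
    frame_interval: float      # s
    pixel_size: float          # μm/px
    path: np.ndarray           # (n_vertices, 2) px, columns (x, y)

    def __post_init__(self) -> None:
        if self.line_width < 1 or self.line_width % 2 == 0:
            raise ValueError("line_width must be odd and >= 1")


def _resample_path(path: np.ndarray):
    """Unit-spaced points and unit normals along a polyline (px)."""
    path = np.asarray(path, dtype=float)
    seg = np.diff(path, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = seglen.sum()
    s = np.arange(0.0, total + 1e-9, 1.0)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    pts = np.empty((s.size, 2))
    tans = np.empty((s.size, 2))
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / np.where(seglen[idx] > 0, seglen[idx], 1.0)
    pts = path[idx] + frac[:, None] * seg[idx]
    tans = seg[idx] / seglen[idx, None]
    normals = np.stack([-tans[:, 1], tans[:, 0]], axis=1)
    return pts, normals


def build_kymograph(movie: np.ndarray, path, line_width: int = 5,
                    frame_interval: float = 3.0, pixel_size: float = 0.1) -> Kymograph:
    """Max-project a ``line_width``-pixel-wide band along ``path`` per frame.

    For each position along the path and each frame, the kymograph value is
    the maximum intensity over ``line_width`` pixels perpendicular to the
    path at that position — the wide line ensures organelles slightly off
    the drawn line are still recorded.
    """
    if line_width < 1 or line_width % 2 == 0:
        raise ValueError("line_width must be odd and >= 1")
    movie = np.asarray(movie)
    if movie.ndim != 3:
        raise ValueError("movie must be a (frames, H, W) stack")
    h, w = movie.shape[1:]
    path = np.asarray(path, dtype=float)
    for vx, vy in path:
        if not (0 <= vx <= w - 1 and 0 <= vy <= h - 1):
            raise ValueError(f"path vertex ({vx}, {vy}) lies outside the "
                             f"{w}x{h} image")
    pts, normals = _resample_path(path)
    half = line_width // 2
    offsets = np.arange(-half, half + 1)
    # sample coordinates: (n_offsets, n_positions, 2)
    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    xs = np.clip(coords[..., 0], 0, w - 1)
    ys = np.clip(coords[..., 1], 0, h - 1)
    n_frames = movie.shape[0]
    matrix = np.empty((n_frames, pts.shape[0]), dtype=float)
    for f in range(n_frames):
        samples = ndimage.map_coordinates(movie[f].astype(float),
                                          [ys.ravel(), xs.ravel()], order=1)
        matrix[f] = samples.reshape(offsets.size, -1).max(axis=0)
    return Kymograph(matrix=matrix, line_width=line_width,
                     frame_interval=frame_interval, pixel_size=pixel_size,
                     path=path)


# ---------------------------------------------------------------------------
# detection and linking
# ---------------------------------------------------------------------------


def detect_puncta(frame: np.ndarray, min_sigma: float = 1.0,
                  max_sigma: float = 3.0, threshold: float | None = None,
                  return_intensity: bool = False) -> np.ndarray:
    """Detect fluorescent puncta in one frame; returns (n, 2) of (x, y) px.

    Band-pass (difference of Gaussians) followed by local-maximum picking and
    intensity-weighted sub-pixel centroid refinement on the band-passed
    image.  ``threshold`` is an absolute cut on the band-pass response; when
    None it is set to 5 robust standard deviations of the response.  With
    ``return_intensity`` a third column holds the integrated band-pass mass
    of each punctum (useful as an identity feature when linking).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    dog = (ndimage.gaussian_filter(frame, min_sigma)
           - ndimage.gaussian_filter(frame, max_sigma))
    if threshold is None:
        mad = np.median(np.abs(dog - np.median(dog)))
        threshold = 5.0 * 1.4826 * max(mad, 1e-12)
    maxima = (dog == ndimage.maximum_filter(dog, size=5)) & (dog > threshold)
    ys, xs = np.nonzero(maxima)
    ncol = 3 if return_intensity else 2
    if ys.size == 0:
        return np.empty((0, ncol))
    h, w = frame.shape
    r = 3
    rows = []
    for y, x in zip(ys, xs):
        y0, y1 = max(y - r, 0), min(y + r + 1, h)
        x0, x1 = max(x - r, 0), min(x + r + 1, w)
        win = np.clip(dog[y0:y1, x0:x1], 0, None)
        tot = win.sum()
        yy, xx = np.mgrid[y0:y1, x0:x1]
        row = [(xx * win).sum() / tot, (yy * win).sum() / tot]
        if return_intensity:
            row.append(tot)
        rows.append(row)
    return np.asarray(rows)


def link_tracks(detections, *, frame_interval: float, pixel_size: float,
                max_step: float, max_gap: int = 2, min_length: int = 5,
                intensity_weight: float = 0.0) -> list[ParticleTrack]:
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    ``detections`` is a sequence (one entry per frame, in order) of (n, 2)
    arrays of (x, y) pixel centroids, or (n, 3) with a punctum-intensity
    column.  Candidate links within the displacement gate (``max_step`` μm
    per elapsed frame; gap-closing over up to ``max_gap`` skipped frames
    scales the gate) are assigned globally in order of increasing cost, ties
    broken by lowest track index — deterministic across runs.

    The cost is the distance to the track's constant-velocity predicted
    position, plus ``intensity_weight`` (px per unit relative difference)
    times the relative intensity mismatch when intensities are available —
    brightness is a persistent identity feature that disambiguates two
    organelles passing each other on the axon.  When puncta merge into a
    single detection during such a crossing, the losing track coasts on the
    merged detection with frozen velocity and identity features, so both
    identities survive the occlusion.  Tracks shorter than ``min_length``
    observations are discarded.  Positions are the x coordinates projected
    onto the (horizontal) axon path axis, in μm.
    """
    active: list[dict] = []
    finished: list[dict] = []
    next_id = 0

    def _advance(tr: dict, f: int, det: np.ndarray, shared: bool = False) -> None:
        gap = f - tr["last_frame"]
        xy = det[:2]
        tr["prev_vel"] = tr["vel"].copy()
        # A shared (merged-blob) observation sits off the true punctum, so
        # freeze the velocity and intensity features through the occlusion.
        if not shared:
            tr["vel"] = 0.5 * tr["vel"] + 0.5 * (xy - tr["xy"]) / gap
            if det.size > 2 and tr["intensity"] is not None:
                tr["intensity"] = 0.7 * tr["intensity"] + 0.3 * det[2]
        tr["obs"].append((f, xy[0], xy[1]))
        tr["last_frame"] = f
        tr["xy"] = xy.copy()

    for f, dets in enumerate(detections):
        dets = np.asarray(dets, dtype=float)
        if dets.size == 0:
            dets = dets.reshape(0, 2)
        has_int = dets.shape[1] > 2
        still = []
        for tr in active:
            (finished if f - tr["last_frame"] > max_gap + 1 else still).append(tr)
        active = still
        pairs = []
        for ti, tr in enumerate(active):
            gap = f - tr["last_frame"]
            gate = max_step * gap / pixel_size     # px
            pred = tr["xy"] + tr["vel"] * gap      # constant-velocity prediction
            d = np.hypot(dets[:, 0] - pred[0], dets[:, 1] - pred[1])
            d_last = np.hypot(dets[:, 0] - tr["xy"][0], dets[:, 1] - tr["xy"][1])
            cost = d.copy()
            if has_int and tr["intensity"] is not None:
                rel = np.abs(dets[:, 2] - tr["intensity"]) / \
                    (dets[:, 2] + tr["intensity"])
                cost = d + intensity_weight * rel
            for di in np.nonzero(d <= gate)[0]:
                pairs.append((cost[di], ti, int(di),
                              min(d[di], d_last[di])))
        pairs.sort(key=lambda p: (p[0], p[1]))
        used_t, used_d = set(), set()
        winner_of: dict[int, int] = {}
        for _, ti, di, _d in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            winner_of[di] = ti
            _advance(active[ti], f, dets[di])
        # occlusion pass: two puncta passing each other merge into a single
        # detection for a few frames; let the track that lost the contest
        # share a *nearby* merged detection rather than fragment.  The
        # detection is then known to be a blend, so the winner's velocity
        # update is rolled back too — both identities coast through the
        # occlusion with their pre-merge velocities, which is what separates
        # them correctly when the puncta split again.
        occl_px = 8.0
        for _, ti, di, d_px in pairs:
            if ti in used_t or d_px > occl_px:
                continue
            used_t.add(ti)
            used_d.add(di)
            _advance(active[ti], f, dets[di], shared=True)
            wi = winner_of.get(di)
            if wi is not None:
                active[wi]["vel"] = active[wi]["prev_vel"].copy()
        for di in range(dets.shape[0]):
            if di not in used_d:
                active.append({
                    "id": next_id, "obs": [(f, dets[di, 0], dets[di, 1])],
                    "last_frame": f, "xy": dets[di, :2].copy(),
                    "vel": np.zeros(2), "prev_vel": np.zeros(2),
                    "intensity": dets[di, 2] if has_int else None})
                next_id += 1
    finished.extend(active)
    finished.sort(key=lambda tr: tr["id"])
    tracks = []
    for tr in finished:
        if len(tr["obs"]) < min_length:
            continue
        obs = np.asarray(tr["obs"], dtype=float)
        tracks.append(ParticleTrack(
            particle_id=tr["id"],
            positions=obs[:, 1] * pixel_size,
            times=obs[:, 0] * frame_interval,
            frames=obs[:, 0].astype(int),
            y_px=obs[:, 2]))
    return tracks


# ---------------------------------------------------------------------------
# velocity statistics
# ---------------------------------------------------------------------------


def overall_velocity(track: ParticleTrack) -> float:
    """Net displacement between first and last positions over elapsed time (μm/s)."""
    if len(track) < 2:
        raise ValueError("track needs at least 2 points")
    if track.elapsed <= 0:
        raise ValueError("zero elapsed time")
    return abs(track.net_displacement) / track.elapsed


def classify_mobility(velocity: float,
                      threshold: float = MOBILITY_THRESHOLD_UM_S) -> str:
    """'mobile' iff overall velocity >= threshold (boundary inclusive)."""
    if velocity < 0:
        raise ValueError("velocity must be non-negative")
    return "mobile" if velocity >= threshold else "stationary"


def instantaneous_velocity(track: ParticleTrack,
                           threshold: float = MOBILITY_THRESHOLD_UM_S) -> float:
    """Mean frame-to-frame speed with paused intervals excluded (μm/s).

    Only defined for mobile tracks; an interval counts as paused when its
    speed falls below the mobility threshold.
    """
    v = overall_velocity(track)
    if classify_mobility(v, threshold) != "mobile":
        raise ValueError("instantaneous velocity is defined for mobile tracks; "
                         "filter with classify_mobility first")
    speeds = np.abs(np.diff(track.positions)) / np.diff(track.times)
    moving = speeds >= threshold
    if not moving.any():      # cannot happen if overall >= threshold, kept defensive
        return 0.0
    return float(speeds[moving].mean())


def direction_of(track: ParticleTrack, soma_end: str = "left",
                 threshold: float = MOBILITY_THRESHOLD_UM_S) -> str:
    """'anterograde' (away from soma), 'retrograde' (toward), or 'none'."""
    if soma_end not in ("left", "right"):
        raise ValueError("soma_end must be 'left' or 'right'")
    if classify_mobility(overall_velocity(track), threshold) != "mobile":
        return "none"
    away = track.net_displacement > 0
    if soma_end == "right":
        away = not away
    return "anterograde" if away else "retrograde"


@dataclass
class TransportStats:
    """Cohort transport statistics (mean ± SEM convention)."""

    per_particle: pd.DataFrame
    n: int
    mean_velocity: float
    sem_velocity: float
    mobile_fraction_pct: float
    n_mobile: int
    mean_instantaneous: float     # over mobile tracks only; NaN if none
    sem_instantaneous: float


def summarize_transport(tracks: list[ParticleTrack], soma_end: str = "left",
                        threshold: float = MOBILITY_THRESHOLD_UM_S) -> TransportStats:
    """Per-particle velocities, mobility classes and cohort summaries."""
    if not tracks:
        raise ValueError("no tracks to summarize")
    rows = []
    for tr in tracks:
        v = overall_velocity(tr)
        mob = classify_mobility(v, threshold)
        rows.append({
            "particle_id": tr.particle_id,
            "overall_velocity": v,
            "mobile": mob == "mobile",
            "direction": direction_of(tr, soma_end, threshold),
            "instantaneous_velocity": (instantaneous_velocity(tr, threshold)
                                       if mob == "mobile" else np.nan),
            "n_frames": len(tr),
        })
    df = pd.DataFrame(rows)
    overall = group_summary(df["overall_velocity"].to_numpy())
    mob_df = df[df["mobile"]]
    if len(mob_df):
        inst = group_summary(mob_df["instantaneous_velocity"].to_numpy())
        mean_inst, sem_inst = inst.mean, inst.sem
    else:
        mean_inst, sem_inst = float("nan"), float("nan")
    return TransportStats(
        per_particle=df, n=len(df),
        mean_velocity=overall.mean, sem_velocity=overall.sem,
        mobile_fraction_pct=100.0 * len(mob_df) / len(df),
        n_mobile=len(mob_df),
        mean_instantaneous=mean_inst, sem_instantaneous=sem_inst)


def match_to_truth(recovered: list[ParticleTrack], truth: list[ParticleTrack],
                   tol_um: float = 3.0) -> list[tuple[ParticleTrack, ParticleTrack]]:
    """Greedily pair recovered tracks with ground-truth tracks by mean position."""
    pairs = []
    cand = []
    for ri, rt in enumerate(recovered):
        for ti, tt in enumerate(truth):
            d = abs(rt.mean_position - tt.mean_position)
            if d <= tol_um:
                cand.append((d, ri, ti))
    cand.sort()
    used_r, used_t = set(), set()
    for d, ri, ti in cand:
        if ri in used_r or ti in used_t:
            continue
        used_r.add(ri)
        used_t.add(ti)
        pairs.append((recovered[ri], truth[ti]))
    return pairs


def recover_tracks(movie: np.ndarray, *, pixel_size: float, frame_interval: float,
                   psf_sigma: float = 1.5, max_step: float = 2.0,
                   max_gap: int = 2, min_length: int = 5) -> list[ParticleTrack]:
    """Detection + linking for one movie stack.

    ``max_step`` (μm per frame interval) must comfortably exceed the fastest
    expected per-frame displacement; when analyzing a movie generated from a
    preset use :func:`max_step_for_preset`.
    """
    detections = [detect_puncta(movie[f], min_sigma=psf_sigma,
                                max_sigma=2.5 * psf_sigma)
                  for f in range(movie.shape[0])]
    return link_tracks(detections, frame_interval=frame_interval,
                       pixel_size=pixel_size, max_step=max_step,
                       max_gap=max_gap, min_length=min_length)


def max_step_for_preset(preset) -> float:
    """Linking gate (μm per frame) covering the preset's fastest run speed."""
    return preset.max_run_speed * preset.frame_interval + 1.0


def analyze_movie(movie: np.ndarray, *, pixel_size: float, frame_interval: float,
                  psf_sigma: float = 1.5, max_step: float = 2.0,
                  max_gap: int = 2, min_length: int = 5,
                  threshold: float = MOBILITY_THRESHOLD_UM_S) -> TransportStats:
    """Full detection -> linking -> summary pipeline for one movie stack."""
    tracks = recover_tracks(movie, pixel_size=pixel_size,
                            frame_interval=frame_interval, psf_sigma=psf_sigma,
                            max_step=max_step, max_gap=max_gap,
                            min_length=min_length)
    return summarize_transport(tracks, threshold=threshold)
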