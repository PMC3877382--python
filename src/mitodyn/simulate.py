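"""Synthetic time-lapse movies, morphology fields, soma fields and flux traces.

Every generator takes an explicit preset (or parameters) carrying its own
seed, and the same seed + preset reproduce bit-identical output.  Ground
truth is returned alongside each artifact so downstream measurements can be
validated against construction.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, stats

from .bioenergetics import FluxTrace
from .presets import (AXON_MARGIN_UM, FluxPreset, MorphologyPreset,
                      TransportPreset)
from .tracks import ParticleTrack

# ---------------------------------------------------------------------------
# axonal transport movies
# ---------------------------------------------------------------------------


def _place_with_separation(rng, intervals, min_sep, max_tries=500):
    """Sample one coordinate per (lo, hi) interval, pairwise >= min_sep apart.

    Raises RuntimeError when an interval cannot be satisfied; intervals are
    processed in the order given (most constrained first helps feasibility).
    """
    placed: list[float] = []
    for lo, hi in intervals:
        if hi <= lo:
            raise RuntimeError(
                f"placement interval [{lo:.2f}, {hi:.2f}] is empty; axon too "
                "short for the requested speeds")
        for _ in range(max_tries):
            x = rng.uniform(lo, hi)
            if all(abs(x - q) >= min_sep for q in placed):
                placed.append(x)
                break
        else:
            raise RuntimeError(
                f"could not place a particle with min separation {min_sep} μm "
                f"after {max_tries} tries; reduce density or lengthen the axon")
    return placed


def simulate_transport_tracks(preset: TransportPreset,
                              rng: np.random.Generator | None = None,
                              min_separation: float = 1.0) -> list[ParticleTrack]:
    """Generate ground-truth run/pause tracks for one movie (no rendering).

    Mobile particles draw a constant run speed from a truncated normal on
    [preset.min_run_speed, preset.max_run_speed], move by speed*frame_interval in their fixed
    direction on each non-paused interval, and are given enough runway that
    the full pause-free excursion stays inside the axon.  Stationary
    particles wobble around their anchor with sub-pixel Gaussian jitter.
    """
    if rng is None:
        rng = np.random.default_rng(preset.seed)
    n = preset.n_particles
    # Bernoulli mobile/stationary assignment: the mobile count varies
    # binomially between movies, as it would between biological fields.
    n_mob = int(np.sum(rng.random(n) < preset.mobile_fraction))
    dt = preset.frame_interval
    times = np.arange(preset.n_frames) * dt
    margin = AXON_MARGIN_UM

    loc, sd = preset.speed_mean, preset.speed_sd
    a = (preset.min_run_speed - loc) / sd
    b = (preset.max_run_speed - loc) / sd
    speeds = stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=n_mob, random_state=rng)
    retro = rng.random(n_mob) < preset.retrograde_fraction

    # Mobile particles first: their start intervals are the constrained ones.
    intervals = []
    for v, r in zip(speeds, retro):
        travel = v * preset.duration
        if r:
            intervals.append((margin + travel, preset.axon_length - margin))
        else:
            intervals.append((margin, preset.axon_length - margin - travel))
    intervals += [(margin, preset.axon_length - margin)] * (n - n_mob)
    starts = _place_with_separation(rng, intervals, min_separation)

    jitter_um = preset.stationary_jitter_px * preset.pixel_size
    tracks: list[ParticleTrack] = []
    for i in range(n):
        x0 = starts[i]
        if i < n_mob:
            direction = -1.0 if retro[i] else 1.0
            moving = rng.random(preset.n_frames - 1) >= preset.pause_prob_per_frame
            steps = direction * speeds[i] * dt * moving
            pos = x0 + np.concatenate([[0.0], np.cumsum(steps)])
            mobile, v = True, float(speeds[i])
        else:
            pos = x0 + rng.normal(0.0, jitter_um, preset.n_frames)
            mobile, v = False, 0.0
        y = (preset.height_px / 2.0 + rng.uniform(-1.5, 1.5)
             + rng.normal(0.0, preset.stationary_jitter_px, preset.n_frames))
        tracks.append(ParticleTrack(
            particle_id=i, positions=pos, times=times.copy(),
            frames=np.arange(preset.n_frames), y_px=y,
            cargo_kind=preset.cargo_kind, truth_mobile=mobile, truth_speed=v))
    return tracks


def _draw_punctum(frame: np.ndarray, x: float, y: float, amp: float, sigma: float) -> None:
    """Accumulate a 2D Gaussian punctum into ``frame`` (in place)."""
    h, w = frame.shape
    r = int(math.ceil(4 * sigma))
    x0, x1 = int(math.floor(x)) - r, int(math.floor(x)) + r + 1
    y0, y1 = int(math.floor(y)) - r, int(math.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma ** 2))
    frame[y0c:y1c, x0c:x1c] += amp * g


def render_transport_movie(tracks: list[ParticleTrack], preset: TransportPreset,
                           rng: np.random.Generator) -> np.ndarray:
    """Render tracks as a (n_frames, H, W) uint16 stack with Gaussian noise."""
    width = int(round(preset.axon_length / preset.pixel_size))
    shape = (preset.n_frames, preset.height_px, width)
    amps = preset.amplitude * rng.uniform(0.75, 1.25, size=len(tracks))
    movie = np.full(shape, preset.background, dtype=float)
    for tr, amp in zip(tracks, amps):
        xs_px = tr.positions / preset.pixel_size
        ys_px = tr.y_px if tr.y_px is not None else np.full(len(tr), preset.height_px / 2)
        for f in range(preset.n_frames):
            _draw_punctum(movie[f], xs_px[f], ys_px[f], amp, preset.psf_sigma)
    if preset.noise_sd > 0:
        movie += rng.normal(0.0, preset.noise_sd, size=shape)
    return np.clip(np.round(movie), 0, 65535).astype(np.uint16)


def simulate_transport_movie(preset: TransportPreset):
    """Simulate one axonal-transport movie.

    Returns ``(movie, tracks)``: a (n_frames, H, W) uint16 stack rendering a
    straight horizontal axon (soma at x = 0, so anterograde = increasing
    coordinate) and the ground-truth :class:`ParticleTrack` list.
    """
    rng = np.random.default_rng(preset.seed)
    tracks = simulate_transport_tracks(preset, rng)
    movie = render_transport_movie(tracks, preset, rng)
    return movie, tracks


# ---------------------------------------------------------------------------
# morphology fields
# ---------------------------------------------------------------------------


def _ellipse_mask(shape, cx, cy, a_px, b_px, theta):
    """Boolean mask of a filled rotated ellipse (semi-axes in px)."""
    h, w = shape
    r = int(math.ceil(max(a_px, b_px))) + 2
    y0, y1 = max(int(cy) - r, 0), min(int(cy) + r + 1, h)
    x0, x1 = max(int(cx) - r, 0), min(int(cx) + r + 1, w)
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = inside
    return mask


def simulate_morphology_image(preset: MorphologyPreset):
    """Render a field of ellipse-like mitochondria with known shape truth.

    Returns ``(image, truth)`` where truth is a list of dicts with center
    (px), full major/minor axes (μm), orientation (rad) and a ``touching``
    flag for the deliberately overlapping pairs
    (``floor(overlap_fraction * n_objects / 2)`` of them).
    """
    rng = np.random.default_rng(preset.seed)
    n = preset.n_objects
    px = preset.pixel_size
    size = preset.field_size
    field_um = size * px

    n_pairs = int(preset.overlap_fraction * n / 2)
    majors = stats.truncnorm.rvs(
        (preset.min_major_axis - preset.major_axis_mean) / preset.major_axis_sd,
        np.inf, loc=preset.major_axis_mean, scale=preset.major_axis_sd,
        size=n, random_state=rng)
    aspects = stats.truncnorm.rvs(
        (1.05 - preset.aspect_ratio_mean) / preset.aspect_ratio_sd, np.inf,
        loc=preset.aspect_ratio_mean, scale=preset.aspect_ratio_sd,
        size=n, random_state=rng)
    minors = majors / aspects
    thetas = rng.uniform(0, math.pi, size=n)

    margin = majors.max() / 2 + 0.5 if n else 0.0
    if n and field_um <= 2 * margin:
        raise RuntimeError("field too small for the largest object")

    centers: list[tuple[float, float]] = []   # μm
    touching = np.zeros(n, dtype=bool)

    def _clear(cx, cy, idx) -> bool:
        for j, (qx, qy) in enumerate(centers):
            req = (majors[idx] + majors[j]) / 2 + preset.min_separation
            if (cx - qx) ** 2 + (cy - qy) ** 2 < req ** 2:
                return False
        return True

    def _sample_center(idx, tries=500):
        for _ in range(tries):
            cx = rng.uniform(margin, field_um - margin)
            cy = rng.uniform(margin, field_um - margin)
            if _clear(cx, cy, idx):
                return cx, cy
        raise RuntimeError(
            f"could not place object {idx} with min_separation="
            f"{preset.min_separation} μm in a {field_um:.0f} μm field")

    i = 0
    for _ in range(n_pairs):
        cx, cy = _sample_center(i)
        centers.append((cx, cy))
        ang = rng.uniform(0, 2 * math.pi)
        d = 0.35 * (minors[i] + minors[i + 1])   # < sum of semi-minors -> overlap
        centers.append((cx + d * math.cos(ang), cy + d * math.sin(ang)))
        touching[i] = touching[i + 1] = True
        i += 2
    while i < n:
        centers.append(_sample_center(i))
        i += 1

    image = np.zeros((size, size), dtype=float)
    truth = []
    for k, (cx, cy) in enumerate(centers):
        mask = _ellipse_mask((size, size), cx / px, cy / px,
                             majors[k] / 2 / px, minors[k] / 2 / px, thetas[k])
        image = np.maximum(image, preset.amplitude * mask)
        truth.append({
            "object_id": k, "center_x_px": cx / px, "center_y_px": cy / px,
            "major_um": float(majors[k]), "minor_um": float(minors[k]),
            "orientation_rad": float(thetas[k]), "touching": bool(touching[k]),
        })
    if preset.psf_sigma > 0:
        image = ndimage.gaussian_filter(image, preset.psf_sigma)
    image += preset.background
    if preset.noise_sd > 0:
        image += rng.normal(0.0, preset.noise_sd, size=image.shape)
    return np.clip(np.round(image), 0, 65535).astype(np.uint16), truth


# ---------------------------------------------------------------------------
# soma fields (membrane-potential dye proxy)
# ---------------------------------------------------------------------------


def simulate_soma_field(n_cells: int, intensity_mean: float, intensity_sd: float,
                        seed: int, noise_sd: float = 2.0, field_size: int = 512,
                        background: float = 10.0, radius_px: tuple[float, float] = (15, 25)):
    """Render disc-shaped somata with group-dependent dye intensity.

    Returns ``(image, rois)``; each ROI dict holds the cell id, a polygon
    strictly inside the disc, and the cell's quantized truth intensity.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = np.random.default_rng(seed)
    image = np.full((field_size, field_size), float(background))
    rois = []
    placed: list[tuple[float, float, float]] = []
    for cid in range(n_cells):
        r = rng.uniform(*radius_px)
        for _ in range(1000):
            cx = rng.uniform(r + 2, field_size - r - 2)
            cy = rng.uniform(r + 2, field_size - r - 2)
            if all((cx - qx) ** 2 + (cy - qy) ** 2 >= (r + qr + 4) ** 2
                   for qx, qy, qr in placed):
                break
        else:
            raise RuntimeError(f"could not place {n_cells} somata in the field")
        placed.append((cx, cy, r))
        level = round(max(rng.normal(intensity_mean, intensity_sd)
                          if intensity_sd > 0 else intensity_mean, 0.0))
        ys, xs = np.mgrid[0:field_size, 0:field_size]
        disc = (xs - cx) ** 2 + (ys - cy) ** 2 <= r ** 2
        image[disc] = level
        ang = np.linspace(0, 2 * math.pi, 48, endpoint=False)
        poly = np.stack([cx + (r - 1.5) * np.cos(ang),
                         cy + (r - 1.5) * np.sin(ang)], axis=1)
        rois.append({"cell_id": cid, "polygon": poly.tolist(),
                     "truth_intensity": float(level)})
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=image.shape)
    return np.clip(np.round(image), 0, 65535).astype(np.uint16), rois


# ---------------------------------------------------------------------------
# extracellular flux traces
# ---------------------------------------------------------------------------

_ALLOWED_COMPOUNDS = ("oligomycin", "FCCP", "rotenone", "antimycin")
MITO_STRESS_SCHEDULE = ("oligomycin", "FCCP", "rotenone+antimycin")
ROT_ANT_SCHEDULE = ("rotenone+antimycin",)


def _parse_injection(entry: str) -> str:
    parts = frozenset(p.strip().lower() for p in entry.split("+"))
    allowed = {c.lower() for c in _ALLOWED_COMPOUNDS}
    unknown = parts - allowed
    if unknown:
        raise ValueError(
            f"unknown compound label(s) {sorted(unknown)}; allowed: "
            f"{list(_ALLOWED_COMPOUNDS)}")
    if parts == {"oligomycin"}:
        return "post_oligomycin"
    if parts == {"fccp"}:
        return "post_fccp"
    if parts == {"rotenone", "antimycin"}:
        return "post_rot_ant"
    raise ValueError(f"unsupported injection {entry!r}; use oligomycin, FCCP "
                     "or rotenone+antimycin")


def simulate_flux_trace(preset: FluxPreset, schedule=MITO_STRESS_SCHEDULE,
                        well_id: str = "A1") -> FluxTrace:
    """Generate a Seahorse-style OCR/ECAR trace from ground-truth components.

    OCR phase levels: baseline = mito + non-mito; post-oligomycin = proton
    leak + non-mito; post-FCCP = the preset's FCCP plateau; post-rotenone/
    antimycin = non-mito.  ECAR sits at its basal level before oligomycin
    and rises afterwards (glycolytic compensation).  Gaussian measurement
    noise is added to every reading.
    """
    phases = [_parse_injection(e) for e in schedule]
    if phases not in (["post_oligomycin", "post_fccp", "post_rot_ant"],
                      ["post_rot_ant"]):
        raise ValueError(
            "schedule must be oligomycin -> FCCP -> rotenone+antimycin, or "
            "rotenone+antimycin alone")
    rng = np.random.default_rng(preset.seed)
    ocr_level = {
        "baseline": preset.basal_ocr,
        "post_oligomycin": preset.proton_leak + preset.non_mito,
        "post_fccp": preset.fccp_response,
        "post_rot_ant": preset.non_mito,
    }
    labels = (["baseline"] * preset.n_baseline
              + [ph for ph in phases for _ in range(preset.n_per_injection)])
    times = 1.3 + 6.5 * np.arange(len(labels))
    ocr = np.array([ocr_level[lb] for lb in labels], dtype=float)
    oligo_seen = np.array([ph != "baseline" for ph in labels]) & ("post_oligomycin" in phases)
    ecar = np.where(oligo_seen, 1.4 * preset.ecar_basal, preset.ecar_basal).astype(float)
    if preset.measurement_noise_sd > 0:
        ocr += rng.normal(0.0, preset.measurement_noise_sd, size=ocr.shape)
        ecar += rng.normal(0.0, 0.25 * preset.measurement_noise_sd, size=ecar.shape)
    return FluxTrace(times_min=times, ocr=ocr, ecar=ecar, phase_labels=labels,
                     well_id=well_id, protein_ug=preset.protein_ug)
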