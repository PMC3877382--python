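"""Named synthetic-data presets emulating the wt / A53T / rapamycin study arms.

Each transport preset is calibrated so that the *expected* cohort mean of
net-displacement / elapsed-time over all generated particles (mobile plus
stationary) equals the target overall velocity for that condition, while the
mean of the run-speed distribution equals the target instantaneous velocity.
Under the two-state run/pause model a mobile particle with run speed v and
per-frame pause probability p has expected overall velocity v*(1-p), so the
cohort mean is  (n_mobile/n) * E[v] * (1-p)  and the calibration solves for
the location of the truncated-normal run-speed distribution that yields the
required E[v].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import optimize, stats

#: Mobility threshold (μm/s): particles moving at or above this are mobile.
MOBILITY_THRESHOLD_UM_S = 0.005

#: Margin (μm) kept between any particle and the ends of the rendered axon.
AXON_MARGIN_UM = 2.0


@dataclass(frozen=True)
class TransportPreset:
    """Parameters for one synthetic axonal-transport movie."""

    name: str
    n_particles: int
    mobile_fraction: float
    speed_mean: float          # location (μm/s) of the truncated-normal run speed
    speed_sd: float            # scale (μm/s) of the run-speed distribution
    pause_prob_per_frame: float
    retrograde_fraction: float
    frame_interval: float = 3.0    # s
    n_frames: int = 101            # 5 min at 3 s
    pixel_size: float = 0.1        # μm/px
    axon_length: float = 200.0     # μm
    psf_sigma: float = 1.5         # px
    background: float = 100.0      # a.u.
    noise_sd: float = 20.0         # a.u.
    amplitude: float = 400.0       # punctum peak above background, a.u.
    height_px: int = 24
    stationary_jitter_px: float = 0.1
    cargo_kind: str = "mitochondrion"
    min_run_speed: float = 0.0     # μm/s lower bound of the run-speed draw
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("mobile_fraction", "pause_prob_per_frame", "retrograde_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr}={v} must lie in [0, 1]")
        if self.n_particles < 0:
            raise ValueError("n_particles must be non-negative")
        if self.n_frames <= 1:
            raise ValueError("n_frames must exceed 1")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be positive")
        if self.speed_sd <= 0:
            raise ValueError("speed_sd must be positive")
        if self.axon_length <= 4 * AXON_MARGIN_UM:
            raise ValueError("axon_length too short for the placement margins")

    @property
    def duration(self) -> float:
        """Elapsed time (s) between the first and last frame."""
        return (self.n_frames - 1) * self.frame_interval

    @property
    def max_run_speed(self) -> float:
        """Largest admissible run speed (μm/s) given the axon runway."""
        return (self.axon_length - 3 * AXON_MARGIN_UM) / self.duration

    @property
    def n_mobile(self) -> int:
        return int(round(self.mobile_fraction * self.n_particles))


@dataclass(frozen=True)
class MorphologyPreset:
    """Parameters for one synthetic field of ellipse-like mitochondria."""

    name: str
    n_objects: int
    major_axis_mean: float      # μm (full major axis = length)
    major_axis_sd: float        # μm
    aspect_ratio_mean: float
    aspect_ratio_sd: float
    min_separation: float = 0.6     # μm of clearance between object extents
    overlap_fraction: float = 0.0   # fraction of objects in deliberately touching pairs
    field_size: int = 512           # px (square)
    pixel_size: float = 0.1         # μm/px
    psf_sigma: float = 1.0          # px
    noise_sd: float = 10.0          # a.u.
    background: float = 50.0        # a.u.
    amplitude: float = 300.0        # a.u.
    min_major_axis: float = 0.4     # μm, lower truncation of the length distribution
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aspect_ratio_mean < 1.0:
            raise ValueError("aspect_ratio_mean must be >= 1 (major >= minor)")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.n_objects < 0:
            raise ValueError("n_objects must be non-negative")


@dataclass(frozen=True)
class FluxPreset:
    """Ground-truth bioenergetic components for one synthetic flux trace.

    The identity mito_respiration = atp_linked + proton_leak is structural:
    the preset stores the two addends and derives the total.
    """

    name: str
    atp_linked: float           # pmol/min
    proton_leak: float          # pmol/min
    non_mito: float             # pmol/min
    fccp_response: float        # OCR plateau after FCCP, pmol/min
    ecar_basal: float           # mpH/min
    measurement_noise_sd: float = 0.0   # pmol/min
    n_baseline: int = 4
    n_per_injection: int = 3
    protein_ug: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("atp_linked", "proton_leak", "non_mito", "fccp_response", "ecar_basal"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if self.n_baseline < 1 or self.n_per_injection < 1:
            raise ValueError("reading counts must be >= 1")

    @property
    def mito_respiration(self) -> float:
        return self.atp_linked + self.proton_leak

    @property
    def basal_ocr(self) -> float:
        return self.mito_respiration + self.non_mito


def truncnorm_location(target_mean: float, sd: float, lower: float = 0.0,
                       upper: float = math.inf) -> float:
    """Location μ of a Normal(μ, sd) truncated to [lower, upper] with the given mean."""
    if not lower < target_mean < upper:
        raise ValueError("target mean must lie strictly inside the truncation interval")

    def _mean(loc: float) -> float:
        a = (lower - loc) / sd
        b = (upper - loc) / sd if math.isfinite(upper) else math.inf
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd)

    lo = lower - 30.0 * sd
    hi = upper if math.isfinite(upper) else target_mean + 30.0 * sd
    return float(optimize.brentq(lambda m: _mean(m) - target_mean, lo, hi, xtol=1e-12))


def calibrated_transport_preset(
    name: str,
    n_particles: int,
    overall_velocity: float,
    mobile_fraction: float,
    pause_prob: float,
    speed_sd: float,
    **kwargs,
) -> TransportPreset:
    """Build a preset whose expected cohort overall velocity equals the target.

    The run-speed distribution location is solved so that E[cohort mean of
    |net displacement| / elapsed time] equals ``overall_velocity`` exactly
    (mobility is assigned per particle with probability ``mobile_fraction``).
    """
    draft = TransportPreset(
        name=name, n_particles=n_particles, mobile_fraction=mobile_fraction,
        speed_mean=overall_velocity, speed_sd=speed_sd,
        pause_prob_per_frame=pause_prob, retrograde_fraction=kwargs.pop(
            "retrograde_fraction", 0.4), **kwargs,
    )
    if mobile_fraction == 0:
        return draft if overall_velocity == 0 else _raise_uncalibratable(name)
    required_ev = overall_velocity / (mobile_fraction * (1.0 - pause_prob))
    # Run speeds are bounded away from the mobility threshold so that every
    # mobile particle is classifiable as mobile (its expected overall
    # velocity is at least twice the threshold); the printed instantaneous
    # velocities are conditional on the mobile classification, so the
    # distribution mean is only their calibration target when essentially
    # all mobile particles clear the threshold.
    v_lo = 2.0 * MOBILITY_THRESHOLD_UM_S / (1.0 - pause_prob)
    loc = truncnorm_location(required_ev, speed_sd, lower=v_lo,
                             upper=draft.max_run_speed)
    return replace(draft, speed_mean=loc, min_run_speed=v_lo)


def _raise_uncalibratable(name: str):
    raise ValueError(f"preset {name!r}: cannot reach a non-zero cohort mean with no mobile particles")


def _transport_registry() -> dict[str, TransportPreset]:
    mk = calibrated_transport_preset
    return {
        # Fig 1E/G/H arm, 7 DIV: cohort 0.021 μm/s (n=94), instantaneous 0.051,
        # mobile fraction > 30%.
        "wt_7div": mk("wt_7div", 94, 0.021, 0.45, 0.085, 0.051,
                      pixel_size=0.1, axon_length=200.0),
        # Fig 1E arm: 0.003 μm/s (n=53), ~8% mobile.
        "a53t_7div": mk("a53t_7div", 53, 0.003, 0.08, 0.085, 0.012,
                        pixel_size=0.1, axon_length=120.0),
        # Fig 1F arm, 14 DIV: 0.190 μm/s (n=85), instantaneous 0.504.
        "wt_14div": mk("wt_14div", 85, 0.190, 0.412, 0.085, 0.63,
                       pixel_size=0.2, axon_length=650.0),
        "a53t_14div": mk("a53t_14div", 107, 0.008, 0.08, 0.085, 0.06,
                         pixel_size=0.1, axon_length=200.0),
        # Fig 2E autophagosome arms: mostly mobile, predominantly retrograde,
        # progressive run-pause motion.
        "wt_autophagosome": mk("wt_autophagosome", 103, 0.16, 0.97, 0.084, 0.07,
                               retrograde_fraction=0.9, pixel_size=0.2,
                               axon_length=500.0, cargo_kind="autophagosome"),
        "a53t_autophagosome": mk("a53t_autophagosome", 103, 0.28, 0.97, 0.038, 0.12,
                                 retrograde_fraction=0.9, pixel_size=0.2,
                                 axon_length=500.0, cargo_kind="autophagosome"),
        # Fig 6 rapamycin experiment arms: wt 0.050 (n=58), A53T 0.021 (n=130),
        # A53T + rapamycin 0.075 (n=130).  Broad speed distributions reproduce
        # the large per-particle spread behind the printed SEMs.
        "wt_rapa_expt": mk("wt_rapa_expt", 58, 0.050, 0.45, 0.085, 0.085,
                           pixel_size=0.1, axon_length=160.0),
        "a53t_rapa_expt": mk("a53t_rapa_expt", 130, 0.021, 0.10, 0.085, 0.35,
                             pixel_size=0.2, axon_length=340.0),
        "a53t_rapamycin": mk("a53t_rapamycin", 130, 0.075, 0.40, 0.085, 0.424,
                             pixel_size=0.2, axon_length=620.0),
    }


_MORPHOLOGY_PRESETS = {
    # Fig 3D length arms: wt 1.96 μm vs A53T 1.32 μm (6-7 DIV), unchanged
    # aspect ratio.
    "wt_len": MorphologyPreset("wt_len", n_objects=40, major_axis_mean=1.96,
                               major_axis_sd=0.55, aspect_ratio_mean=3.0,
                               aspect_ratio_sd=0.6),
    "a53t_len": MorphologyPreset("a53t_len", n_objects=40, major_axis_mean=1.32,
                                 major_axis_sd=0.40, aspect_ratio_mean=3.0,
                                 aspect_ratio_sd=0.6),
}

_FLUX_PRESETS = {
    # Basal OCR 160.3 (wt) vs 169.1 (A53T) pmol/min/40,000 cells; A53T has
    # lower ATP-linked and maximal respiration, higher non-mitochondrial OCR,
    # similar proton leak, and is more glycolytic (higher ECAR).
    "wt_flux": FluxPreset("wt_flux", atp_linked=107.0, proton_leak=25.3,
                          non_mito=28.0, fccp_response=300.0, ecar_basal=25.0,
                          measurement_noise_sd=4.0),
    "a53t_flux": FluxPreset("a53t_flux", atp_linked=101.0, proton_leak=26.1,
                            non_mito=42.0, fccp_response=230.0, ecar_basal=32.0,
                            measurement_noise_sd=4.0),
}


def transport_preset(name: str, seed: int = 0, **overrides) -> TransportPreset:
    """Look up a named, calibrated transport preset (with a fresh seed)."""
    try:
        base = _transport_registry()[name]
    except KeyError:
        raise KeyError(f"unknown transport preset {name!r}; known: "
                       f"{sorted(_transport_registry())}") from None
    return replace(base, seed=seed, **overrides)


def morphology_preset(name: str, seed: int = 0, **overrides) -> MorphologyPreset:
    try:
        base = _MORPHOLOGY_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown morphology preset {name!r}; known: "
                       f"{sorted(_MORPHOLOGY_PRESETS)}") from None
    return replace(base, seed=seed, **overrides)


def flux_preset(name: str, seed: int = 0, **overrides) -> FluxPreset:
    try:
        base = _FLUX_PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown flux preset {name!r}; known: "
                       f"{sorted(_FLUX_PRESETS)}") from None
    return replace(base, seed=seed, **overrides)


TRANSPORT_PRESET_NAMES = tuple(sorted(_transport_registry()))
MORPHOLOGY_PRESET_NAMES = tuple(sorted(_MORPHOLOGY_PRESETS))
FLUX_PRESET_NAMES = tuple(sorted(_FLUX_PRESETS))
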