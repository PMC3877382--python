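"""Extracellular-flux (OCR/ECAR) bioenergetic decomposition.

With phase means B (baseline), O (post-oligomycin), F (post-FCCP) and R
(post-rotenone/antimycin), the operational definitions are:

    non-mitochondrial respiration  = R
    mitochondrial respiration      = B - R
    ATP-linked respiration         = B - O
    proton leak                    = O - R
    maximal respiratory capacity   = F - R

so mitochondrial respiration = ATP-linked + proton leak holds as an exact
algebraic identity, (B - O) + (O - R) = B - R.  Phase summaries are the
arithmetic mean of that phase's readings.  Negative derived values, which
can occur under measurement noise, are reported as-is with a QC warning
flag rather than clipped, to preserve the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHASES = ("baseline", "post_oligomycin", "post_fccp", "post_rot_ant")


@dataclass
class FluxTrace:
    """Ordered OCR/ECAR measurements with an injection schedule."""

    times_min: np.ndarray
    ocr: np.ndarray                 # pmol/min
    ecar: np.ndarray                # mpH/min
    phase_labels: list[str]
    well_id: str = "A1"
    protein_ug: float | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        n = len(self.phase_labels)
        if not (self.times_min.size == self.ocr.size == self.ecar.size == n):
            raise ValueError("times, ocr, ecar and phase_labels must align")
        unknown = set(self.phase_labels) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phase labels {sorted(unknown)}")
        if not np.all(np.isfinite(self.ocr)):
            raise ValueError("OCR values must be finite")
        # phases must appear in schedule order
        order = [PHASES.index(p) for p in self.phase_labels]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("phases out of schedule order")

    def phase_mean(self, phase: str) -> float | None:
        """Mean OCR of one phase, or None if that phase is absent."""
        sel = [p == phase for p in self.phase_labels]
        if not any(sel):
            return None
        return float(self.ocr[np.asarray(sel)].mean())


@dataclass
class BioenergeticProfile:
    """Derived decomposition of one flux trace; absent phases leave None."""

    well_id: str
    basal_ocr: float
    ocr_ecar_ratio: float | None
    mito_respiration: float | None
    atp_linked: float | None
    proton_leak: float | None
    non_mito: float | None
    max_capacity: float | None
    basal_per_protein: float | None = None
    warnings: list[str] = field(default_factory=list)


def basal_ocr(trace: FluxTrace) -> float:
    """Mean OCR over the baseline readings (taken before any injection)."""
    b = trace.phase_mean("baseline")
    if b is None:
        raise ValueError("trace has no baseline phase")
    return b


def ocr_ecar_ratio(trace: FluxTrace) -> float:
    """Basal OCR divided by basal ECAR (an oxidative-vs-glycolytic index)."""
    sel = np.asarray([p == "baseline" for p in trace.phase_labels])
    if not sel.any():
        raise ValueError("trace has no baseline phase")
    ecar = float(trace.ecar[sel].mean())
    if ecar == 0:
        raise ValueError("basal ECAR is zero; ratio undefined")
    return basal_ocr(trace) / ecar


def derive_profile(trace: FluxTrace) -> BioenergeticProfile:
    """Decompose a trace into the standard mito-stress-test parameters.

    Missing phases yield a partial profile (fields left None); with the
    rotenone/antimycin-only schedule just non-mitochondrial and
    mitochondrial respiration are defined.
    """
    b = basal_ocr(trace)
    o = trace.phase_mean("post_oligomycin")
    f = trace.phase_mean("post_fccp")
    r = trace.phase_mean("post_rot_ant")
    for name, val in (("post_oligomycin", o), ("post_fccp", f), ("post_rot_ant", r)):
        if val is not None and not np.isfinite(val):
            raise ValueError(f"non-finite phase mean for {name}")

    non_mito = r
    mito = b - r if r is not None else None
    atp = b - o if o is not None else None
    leak = o - r if (o is not None and r is not None) else None
    max_cap = f - r if (f is not None and r is not None) else None

    try:
        ratio = ocr_ecar_ratio(trace)
    except ValueError:
        ratio = None

    warnings = [f"negative {k}" for k, v in
                [("mito_respiration", mito), ("atp_linked", atp),
                 ("proton_leak", leak), ("non_mito", non_mito),
                 ("max_capacity", max_cap)]
                if v is not None and v < 0]
    return BioenergeticProfile(
        well_id=trace.well_id, basal_ocr=b, ocr_ecar_ratio=ratio,
        mito_respiration=mito, atp_linked=atp, proton_leak=leak,
        non_mito=non_mito, max_capacity=max_cap, warnings=warnings)


def normalize_per_protein(profile: BioenergeticProfile,
                          protein_ug: float) -> BioenergeticProfile:
    """Attach basal OCR per μg protein (BCA-style normalization)."""
    if protein_ug <= 0:
        raise ValueError("protein_ug must be positive")
    profile.basal_per_protein = profile.basal_ocr / protein_ug
    return profile
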