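"""Flux-trace decomposition: definitions, identities, degenerate cases."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodyn import bioenergetics as B
from mitodyn import presets, simulate


def _trace(b, o=None, f=None, r=None, ecar=40.0, nb=4, ni=3):
    ocr, labels = [b] * nb, ["baseline"] * nb
    for val, lab in ((o, "post_oligomycin"), (f, "post_fccp"), (r, "post_rot_ant")):
        if val is not None:
            ocr += [val] * ni
            labels += [lab] * ni
    n = len(ocr)
    return B.FluxTrace(times_min=np.arange(n) * 6.5, ocr=np.array(ocr, float),
                       ecar=np.full(n, ecar), phase_labels=labels)


class TestBasalOcr:
    def test_mean_of_baseline_readings(self):
        tr = _trace(0.0)
        tr.ocr[:4] = [160, 162, 158, 160]
        assert B.basal_ocr(tr) == 160.0

    def test_noise_free_preset_baselines(self):
        a53t = simulate.simulate_flux_trace(
            presets.flux_preset("a53t_flux", measurement_noise_sd=0.0))
        assert np.all(a53t.ocr[:4] == a53t.ocr[0])
        assert B.basal_ocr(a53t) == pytest.approx(169.1)
        wt = simulate.simulate_flux_trace(
            presets.flux_preset("wt_flux", measurement_noise_sd=0.0))
        assert B.basal_ocr(wt) == pytest.approx(160.3)

    def test_missing_baseline_rejected(self):
        tr = _trace(100.0, o=60.0)
        tr.phase_labels = ["post_oligomycin"] * len(tr.phase_labels)
        with pytest.raises(ValueError):
            B.basal_ocr(tr)


class TestOcrEcarRatio:
    def test_ratio_and_homogeneity(self):
        tr = _trace(160.0, ecar=40.0)
        assert B.ocr_ecar_ratio(tr) == pytest.approx(4.0)
        tr2 = _trace(160.0, ecar=80.0)
        assert B.ocr_ecar_ratio(tr2) == pytest.approx(2.0)

    def test_zero_ecar_rejected(self):
        with pytest.raises(ValueError):
            B.ocr_ecar_ratio(_trace(160.0, ecar=0.0))

    def test_a53t_more_glycolytic_than_wt(self):
        r = {}
        for name in ("wt_flux", "a53t_flux"):
            tr = simulate.simulate_flux_trace(
                presets.flux_preset(name, measurement_noise_sd=0.0))
            r[name] = B.ocr_ecar_ratio(tr)
        assert r["a53t_flux"] < r["wt_flux"]


class TestDeriveProfile:
    def test_worked_decomposition(self):
        """(B,O,F,R) = (160,70,200,30) -> mito 130, ATP 90, leak 40,
        non-mito 30, max capacity 170."""
        p = B.derive_profile(_trace(160.0, 70.0, 200.0, 30.0))
        assert (p.mito_respiration, p.atp_linked, p.proton_leak,
                p.non_mito, p.max_capacity) == (130.0, 90.0, 40.0, 30.0, 170.0)

    def test_oligomycin_noop_degenerate(self):
        p = B.derive_profile(_trace(160.0, 160.0, 200.0, 30.0))
        assert p.atp_linked == 0.0
        assert p.proton_leak == p.mito_respiration

    def test_zero_non_mito(self):
        p = B.derive_profile(_trace(160.0, 70.0, 200.0, 0.0))
        assert p.mito_respiration == p.basal_ocr

    def test_partial_profile_for_rot_ant_only(self):
        p = B.derive_profile(_trace(160.0, r=30.0))
        assert p.non_mito == 30.0 and p.mito_respiration == 130.0
        assert p.atp_linked is None and p.proton_leak is None
        assert p.max_capacity is None

    def test_negative_values_flagged_not_clipped(self):
        p = B.derive_profile(_trace(100.0, 120.0, 200.0, 30.0))
        assert p.atp_linked == -20.0
        assert any("atp_linked" in w for w in p.warnings)
        # identity still exact
        assert p.atp_linked + p.proton_leak == p.mito_respiration

    @given(st.floats(0, 300), st.floats(0, 300), st.floats(0, 400),
           st.floats(0, 100), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_identity_exact_for_arbitrary_traces(self, b, o, f, r, seed):
        noise = np.random.default_rng(seed).normal(0, 5, 13)
        tr = _trace(b, o, f, r)
        tr.ocr = tr.ocr + noise
        p = B.derive_profile(tr)
        assert p.atp_linked + p.proton_leak == pytest.approx(
            p.mito_respiration, abs=1e-9)
        assert p.max_capacity - p.proton_leak == pytest.approx(
            tr.phase_mean("post_fccp") - tr.phase_mean("post_oligomycin"),
            abs=1e-9)

    def test_noise_free_recovery_equals_preset_truth(self):
        p = presets.flux_preset("a53t_flux", measurement_noise_sd=0.0)
        prof = B.derive_profile(simulate.simulate_flux_trace(p))
        assert prof.mito_respiration == pytest.approx(p.mito_respiration)
        assert prof.atp_linked == pytest.approx(p.atp_linked)
        assert prof.proton_leak == pytest.approx(p.proton_leak)
        assert prof.non_mito == pytest.approx(p.non_mito)
        assert prof.max_capacity == pytest.approx(p.fccp_response - p.non_mito)

    def test_noisy_recovery_error_scales_with_noise(self):
        errs = []
        for seed in range(30):
            p = presets.flux_preset("wt_flux", measurement_noise_sd=4.0, seed=seed)
            prof = B.derive_profile(simulate.simulate_flux_trace(p))
            errs.append(prof.atp_linked - p.atp_linked)
        # atp_linked = B - O: sd ~ sqrt(4^2/4 + 4^2/3) = 3.06
        assert np.std(errs) < 3 * 3.06

    def test_group_direction_over_seeds(self):
        """A53T vs wt over 20 seeds: lower mito/ATP/max-capacity, higher
        non-mito, similar proton leak."""
        prof = {"wt_flux": [], "a53t_flux": []}
        for name in prof:
            for seed in range(20):
                p = presets.flux_preset(name, seed=seed)
                prof[name].append(B.derive_profile(simulate.simulate_flux_trace(p)))
        mean = lambda n, k: np.mean([getattr(x, k) for x in prof[n]])
        assert mean("a53t_flux", "mito_respiration") < mean("wt_flux", "mito_respiration")
        assert mean("a53t_flux", "atp_linked") < mean("wt_flux", "atp_linked")
        assert mean("a53t_flux", "max_capacity") < mean("wt_flux", "max_capacity")
        assert mean("a53t_flux", "non_mito") > mean("wt_flux", "non_mito")
        assert abs(mean("a53t_flux", "proton_leak")
                   - mean("wt_flux", "proton_leak")) < 3.0


class TestProteinNormalization:
    def test_per_protein(self):
        p = B.derive_profile(_trace(160.0, 70.0, 200.0, 30.0))
        assert B.normalize_per_protein(p, 8.0).basal_per_protein == 20.0
        assert B.normalize_per_protein(p, 16.0).basal_per_protein == 10.0

    def test_non_positive_protein_rejected(self):
        p = B.derive_profile(_trace(160.0, 70.0, 200.0, 30.0))
        with pytest.raises(ValueError):
            B.normalize_per_protein(p, 0.0)


class TestFluxTraceValidation:
    def test_out_of_order_phases_rejected(self):
        with pytest.raises(ValueError):
            B.FluxTrace(times_min=[0, 1, 2], ocr=[1, 2, 3], ecar=[1, 1, 1],
                        phase_labels=["post_fccp", "baseline", "baseline"])

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            B.FluxTrace(times_min=[0], ocr=[1], ecar=[1], phase_labels=["x"])

    def test_non_finite_ocr_rejected(self):
        with pytest.raises(ValueError):
            B.FluxTrace(times_min=[0], ocr=[np.nan], ecar=[1],
                        phase_labels=["baseline"])
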