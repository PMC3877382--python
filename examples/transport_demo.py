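"""Axonal mitochondrial transport: simulate wt and A53T movies, recover tracks.

Builds one synthetic time-lapse per condition (5 min at 3 s intervals),
runs detection + linking, and prints the three cohort statistics the
analysis produces: overall velocity (net displacement / elapsed time over
all organelles), percent mobile (>= 0.005 μm/s), and instantaneous
velocity (pause-excluded frame-to-frame speed of mobile organelles).
"""

import mitodyn as md

for name in ("wt_7div", "a53t_7div"):
    preset = md.transport_preset(name, seed=1)
    movie, truth = md.simulate_transport_movie(preset)
    tracks = md.recover_tracks(
        movie, pixel_size=preset.pixel_size,
        frame_interval=preset.frame_interval, psf_sigma=preset.psf_sigma,
        max_step=md.max_step_for_preset(preset))
    st = md.summarize_transport(tracks)
    print(f"{name}: n={st.n} tracks")
    print(f"  overall velocity      {st.mean_velocity:.4f} ± {st.sem_velocity:.4f} μm/s")
    print(f"  mobile fraction       {st.mobile_fraction_pct:.1f} %")
    print(f"  instantaneous (mobile) {st.mean_instantaneous:.4f} ± {st.sem_instantaneous:.4f} μm/s")

print("\nA wild-type cohort sits near 0.021 μm/s with >30% mobile organelles;")
print("the A53T α-synuclein cohort is an order of magnitude slower with ~8% mobile,")
print("the transport deficit the analysis is built to quantify.")
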