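"""Kymograph construction: distance-time view of axonal transport.

Builds a synthetic movie, compiles the kymograph by taking the maximum
pixel value over a five-pixel-wide line along the axon, and reports how
stationary vs mobile organelles appear in it.
"""

import numpy as np

import mitodyn as md

preset = md.transport_preset("wt_7div", seed=2)
movie, truth = md.simulate_transport_movie(preset)
mid = preset.height_px / 2
kymo = md.build_kymograph(movie, [(0, mid), (movie.shape[2] - 1, mid)],
                          line_width=5, frame_interval=preset.frame_interval,
                          pixel_size=preset.pixel_size)
print(f"kymograph: {kymo.matrix.shape[0]} time rows x "
      f"{kymo.matrix.shape[1]} path positions")

# a stationary organelle leaves a vertical line: its per-row argmax is fixed
stationary = next(t for t in truth if not t.truth_mobile)
mobile = max((t for t in truth if t.truth_mobile), key=lambda t: t.truth_speed)
for label, t in (("stationary", stationary), ("mobile", mobile)):
    cols = []
    for f in range(0, preset.n_frames, 20):
        x = int(round(t.positions[f] / preset.pixel_size))
        lo = max(x - 4, 0)
        cols.append(lo + int(kymo.matrix[f, lo:x + 5].argmax()))
    drift = np.ptp(cols) * preset.pixel_size
    print(f"  {label} organelle: bright-column drift {drift:.2f} μm over the movie "
          f"(truth run speed {t.truth_speed:.3f} μm/s)")
print("Vertical lines (no drift) are stationary mitochondria; diagonals are "
      "moving ones — the same classification the track statistics quantify.")
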