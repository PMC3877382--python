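"""Kymographs, detection, linking and velocity statistics."""

import numpy as np
import pytest

import mitodyn as md
from mitodyn import simulate, transport
from mitodyn.tracks import ParticleTrack

from conftest import sparse_preset


def _track(positions, dt=3.0, pid=0):
    positions = np.asarray(positions, dtype=float)
    return ParticleTrack(particle_id=pid, positions=positions,
                         times=np.arange(positions.size) * dt)


def _punctum_movie(xs, ys, shape=(30, 120), amp=300.0, sigma=1.5, bg=50.0):
    """Render one punctum per frame at (xs[f], ys[f]) with no noise."""
    movie = np.full((len(xs),) + shape, bg)
    for f, (x, y) in enumerate(zip(xs, ys)):
        simulate._draw_punctum(movie[f], x, y, amp, sigma)
    return movie.astype(np.uint16)


class TestKymograph:
    def test_stationary_punctum_is_bright_vertical_line(self):
        xs = np.full(40, 50.0)
        movie = _punctum_movie(xs, np.full(40, 15.0))
        k = transport.build_kymograph(movie, [(0, 15), (119, 15)])
        assert np.all(k.matrix.argmax(axis=1) == 50)

    def test_moving_punctum_argmax_advances(self):
        xs = 20.0 + 0.5 * np.arange(60)
        movie = _punctum_movie(xs, np.full(60, 15.0))
        k = transport.build_kymograph(movie, [(0, 15), (119, 15)])
        am = k.matrix.argmax(axis=1)
        assert np.all(np.abs(am - xs) <= 0.5 + 1e-9)

    def test_line_width_five_captures_offset_punctum(self):
        """A punctum 3 px off the path survives a 5-px line, not a 1-px one."""
        movie = _punctum_movie(np.full(10, 60.0), np.full(10, 18.0))
        on = transport.build_kymograph(movie, [(0, 15), (119, 15)], line_width=5)
        off = transport.build_kymograph(movie, [(0, 15), (119, 15)], line_width=1)
        bg = 50
        assert on.matrix[:, 60].min() > bg + 100
        assert off.matrix[:, 60].max() < bg + 100

    def test_path_outside_bounds_reports_vertex(self):
        movie = _punctum_movie([50.0], [15.0])
        with pytest.raises(ValueError, match="500"):
            transport.build_kymograph(movie, [(0, 15), (500, 15)])

    def test_even_line_width_rejected(self):
        movie = _punctum_movie([50.0], [15.0])
        with pytest.raises(ValueError):
            transport.build_kymograph(movie, [(0, 15), (119, 15)], line_width=4)

    def test_argmax_tracks_ground_truth_within_one_pixel(self):
        """Kymograph columns and ground-truth positions agree for isolated
        particles (the cross-check the kymograph exists for)."""
        p = sparse_preset(seed=3, n_particles=6, noise_sd=5.0)
        movie, tracks = simulate.simulate_transport_movie(p)
        mid = p.height_px / 2
        k = transport.build_kymograph(movie, [(0, mid), (movie.shape[2] - 1, mid)],
                                      pixel_size=p.pixel_size,
                                      frame_interval=p.frame_interval)
        for t in tracks:
            for f in range(0, p.n_frames, 10):
                x_px = t.positions[f] / p.pixel_size
                others = [u for u in tracks if u is not t]
                if min(abs(u.positions[f] - t.positions[f]) for u in others) < 2.0:
                    continue  # only isolated particles have a unique local max
                lo = max(int(x_px) - 4, 0)
                hi = min(int(x_px) + 5, k.matrix.shape[1])
                local_am = lo + k.matrix[f, lo:hi].argmax()
                assert abs(local_am - x_px) <= 1.0


class TestDetection:
    def test_blank_frame_gives_empty_list(self):
        frame = np.full((30, 60), 100.0)
        assert transport.detect_puncta(frame).shape == (0, 2)

    def test_subpixel_centroid_accuracy(self):
        movie = _punctum_movie([30.25], [14.0])
        det = transport.detect_puncta(movie[0], min_sigma=1.5, max_sigma=3.5)
        assert det.shape == (1, 2)
        assert abs(det[0, 0] - 30.25) <= 0.25
        assert abs(det[0, 1] - 14.0) <= 0.25

    def test_two_puncta_ten_pixels_apart_resolved(self):
        frame = np.full((30, 120), 50.0)
        simulate._draw_punctum(frame, 40.0, 15.0, 300, 1.5)
        simulate._draw_punctum(frame, 50.0, 15.0, 300, 1.5)
        det = transport.detect_puncta(frame.astype(np.uint16),
                                      min_sigma=1.5, max_sigma=3.5)
        assert det.shape[0] == 2


class TestLinking:
    def test_single_particle_single_track(self):
        dets = [np.array([[10.0 + 0.3 * f, 15.0]]) for f in range(20)]
        tracks = transport.link_tracks(dets, frame_interval=3.0, pixel_size=0.1,
                                       max_step=1.0)
        assert len(tracks) == 1
        assert len(tracks[0]) == 20

    def test_distant_stationary_particles_not_swapped(self):
        """Two stationary particles 20 μm apart with a 2 μm gate stay two
        clean tracks."""
        dets = [np.array([[100.0, 15.0], [300.0, 15.0]]) for _ in range(20)]
        tracks = transport.link_tracks(dets, frame_interval=3.0, pixel_size=0.1,
                                       max_step=2.0)
        assert len(tracks) == 2
        for t in tracks:
            assert np.ptp(t.positions) == 0.0

    def test_short_tracks_discarded(self):
        dets = [np.array([[10.0, 15.0]])] * 3 + [np.empty((0, 2))] * 10
        tracks = transport.link_tracks(dets, frame_interval=3.0, pixel_size=0.1,
                                       max_step=1.0, min_length=5)
        assert tracks == []

    def test_ground_truth_recovery_on_wt_movie(self):
        """>= 90% of ground-truth tracks recovered with the correct
        mobile/stationary label from a rendered wt movie."""
        p = md.transport_preset("wt_7div", seed=1)
        movie, truth = simulate.simulate_transport_movie(p)
        rec = transport.recover_tracks(
            movie, pixel_size=p.pixel_size, frame_interval=p.frame_interval,
            psf_sigma=p.psf_sigma, max_step=transport.max_step_for_preset(p))
        pairs = transport.match_to_truth(rec, truth)
        correct = sum(
            (transport.classify_mobility(transport.overall_velocity(r)) == "mobile")
            == bool(t.truth_mobile) for r, t in pairs)
        assert correct / len(truth) >= 0.90


class TestVelocityStatistics:
    def test_overall_velocity_arithmetic(self):
        t = _track([10.0, 12.0, 16.0], dt=150.0)   # 6 um over 300 s
        assert transport.overall_velocity(t) == pytest.approx(0.02)

    def test_round_trip_excursion_has_zero_overall_velocity(self):
        t = _track([10.0, 12.5, 15.0, 12.5, 10.0])
        assert transport.overall_velocity(t) == 0.0

    def test_overall_velocity_needs_two_points(self):
        with pytest.raises(ValueError):
            transport.overall_velocity(_track([10.0]))

    def test_mobility_threshold_boundary_inclusive(self):
        assert transport.classify_mobility(0.005) == "mobile"
        assert transport.classify_mobility(0.0049) == "stationary"
        with pytest.raises(ValueError):
            transport.classify_mobility(-0.001)

    def test_classify_is_idempotent_and_monotone(self):
        vs = np.linspace(0, 0.02, 41)
        labels = [transport.classify_mobility(v) for v in vs]
        flips = sum(a != b for a, b in zip(labels, labels[1:]))
        assert flips == 1  # single stationary->mobile transition
        assert labels == [transport.classify_mobility(v) for v in vs]

    def test_instantaneous_constant_speed(self):
        t = _track(10.0 + 0.3 * np.arange(20))     # 0.1 um/s at 3 s intervals
        assert transport.instantaneous_velocity(t) == pytest.approx(0.1)

    def test_instantaneous_excludes_pauses(self):
        """0.2 μm/s for half the intervals, paused otherwise -> 0.2 μm/s."""
        steps = np.tile([0.6, 0.0], 10)
        t = _track(np.concatenate([[5.0], 5.0 + np.cumsum(steps)]))
        assert transport.instantaneous_velocity(t) == pytest.approx(0.2)

    def test_instantaneous_rejects_stationary_track(self):
        t = _track(np.full(10, 20.0))
        with pytest.raises(ValueError):
            transport.instantaneous_velocity(t)

    def test_instantaneous_at_least_overall_for_mobile_tracks(self, rng):
        """Path-integrated motion can never be below net displacement."""
        for _ in range(50):
            steps = rng.choice([0.0, 0.3, -0.3], size=30, p=[0.3, 0.5, 0.2])
            t = _track(np.concatenate([[50.0], 50.0 + np.cumsum(steps)]))
            v = transport.overall_velocity(t)
            if transport.classify_mobility(v) == "mobile":
                assert transport.instantaneous_velocity(t) >= v - 1e-12

    def test_direction_classification(self):
        ante = _track(np.linspace(10, 16, 11))
        retro = _track(np.linspace(16, 10, 11))
        still = _track(np.full(11, 10.0))
        assert transport.direction_of(ante, "left") == "anterograde"
        assert transport.direction_of(retro, "left") == "retrograde"
        assert transport.direction_of(still, "left") == "none"
        assert transport.direction_of(ante, "right") == "retrograde"


class TestSummaries:
    def test_identical_tracks_zero_sem(self):
        tracks = [_track(10.0 + 0.06 * np.arange(11), dt=3.0, pid=i)
                  for i in range(10)]
        st = transport.summarize_transport(tracks)
        assert st.mean_velocity == pytest.approx(0.02)
        assert st.sem_velocity == pytest.approx(0.0)
        assert st.mobile_fraction_pct == 100.0

    def test_manual_three_track_oracle(self):
        """Spreadsheet-style check: velocities 0.02, 0.0, 0.05 -> mean
        0.023333, 1/3 of tracks below threshold."""
        tracks = [
            _track([10.0, 13.0, 16.0], dt=150.0, pid=0),    # 0.02
            _track([40.0, 40.0, 40.0], dt=150.0, pid=1),    # 0.0
            _track([80.0, 72.5, 65.0], dt=150.0, pid=2),    # 0.05 retrograde
        ]
        st = transport.summarize_transport(tracks)
        vals = np.array([0.02, 0.0, 0.05])
        assert st.mean_velocity == pytest.approx(vals.mean())
        assert st.sem_velocity == pytest.approx(
            vals.std(ddof=1) / np.sqrt(3))
        assert st.mobile_fraction_pct == pytest.approx(200 / 3)
        assert list(st.per_particle["direction"]) == \
            ["anterograde", "none", "retrograde"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            transport.summarize_transport([])


def test_mobile_fraction_recovery_within_binomial_interval():
    """Pooled over 20 seeds, the pipeline-recovered mobile fraction lies in
    the exact binomial 95% interval of the preset's mobile fraction."""
    from scipy.stats import binom
    n_mobile = 0
    n_total = 0
    for seed in range(1, 21):
        p = sparse_preset(seed=seed)
        movie, _ = simulate.simulate_transport_movie(p)
        rec = transport.recover_tracks(
            movie, pixel_size=p.pixel_size, frame_interval=p.frame_interval,
            psf_sigma=p.psf_sigma, max_step=transport.max_step_for_preset(p))
        st = transport.summarize_transport(rec)
        n_mobile += st.n_mobile
        n_total += st.n
    lo = binom.ppf(0.025, n_total, 0.5)
    hi = binom.ppf(0.975, n_total, 0.5)
    assert lo <= n_mobile <= hi
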