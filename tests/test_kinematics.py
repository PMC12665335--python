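"""Kinematic conditioning: smoothing, body frame, hand selection, mirroring."""

import numpy as np
import pytest

from costructure import kinematics as kin
from costructure.kinematics import KinematicFeatures

RATE = 60.0


def make_features(hand, head, rate=RATE, side="left", mirrored=False, ratio=2.0):
    hv, ha = kin.derive_kinematics(hand, rate)
    dv, da = kin.derive_kinematics(head, rate)
    return KinematicFeatures(
        hand_pos=hand, head_pos=head, hand_vel=hv, head_vel=dv,
        hand_acc=ha, head_acc=da, rate=rate, dominant_side=side,
        mirrored=mirrored, energy_ratio=ratio,
    )


class TestSavgol:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(100) / RATE
        x = 1.5 - 2.0 * t + 0.8 * t**2
        out = kin.smooth_savgol(x, RATE)
        assert np.allclose(out, x, atol=1e-10)

    def test_constant_unchanged(self):
        x = np.full((50, 3), 2.2)
        assert np.allclose(kin.smooth_savgol(x, RATE), x)

    def test_noise_variance_reduced(self, rng):
        t = np.arange(600) / RATE
        clean = np.sin(2 * np.pi * 1.0 * t)
        noisy = clean + rng.normal(0, 0.2, len(t))
        out = kin.smooth_savgol(noisy, RATE)
        assert np.var(out - clean) < np.var(noisy - clean)

    def test_window_is_seven_samples_at_60hz(self):
        # 125 ms * 60 Hz = 7.5 -> nearest odd, favouring detail: 7
        with pytest.raises(ValueError, match="7-sample"):
            kin.smooth_savgol(np.zeros(6), RATE)

    def test_short_series_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            kin.smooth_savgol(np.zeros(3), RATE)


def reference_posture(n=50):
    """Aligned posture: shoulders on x, pelvis at origin, hands moving."""
    t = np.linspace(0, 1, n)
    return {
        "shoulder_L": {"pos": np.tile([0.2, 0.0, 0.5], (n, 1))},
        "shoulder_R": {"pos": np.tile([-0.2, 0.0, 0.5], (n, 1))},
        "pelvis": {"pos": np.zeros((n, 3))},
        "hand_L": {"pos": np.stack([0.3 + 0.1 * np.sin(6 * t), 0.2 * t, 0.1 + 0 * t], axis=1)},
        "head": {"pos": np.tile([0.0, 0.0, 0.7], (n, 1))},
    }


def rigid(segments, yaw, shift):
    c, s = np.cos(yaw), np.sin(yaw)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    return {k: {"pos": d["pos"] @ R.T + shift} for k, d in segments.items()}


class TestBodyFrame:
    def test_aligned_input_identity(self):
        segs = reference_posture()
        frame, out = kin.to_body_frame(segs)
        assert np.allclose(frame.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(frame.origin, 0.0, atol=1e-12)
        assert np.allclose(out["hand_L"]["pos"], segs["hand_L"]["pos"])

    def test_recovers_random_rigid_transform(self, rng):
        segs = reference_posture()
        moved = rigid(segs, yaw=float(rng.uniform(-np.pi, np.pi)), shift=rng.normal(size=3))
        _, out = kin.to_body_frame(moved)
        for seg in segs:
            assert np.allclose(out[seg]["pos"], segs[seg]["pos"], atol=1e-9)
        sl = out["shoulder_L"]["pos"].mean(axis=0)
        sr = out["shoulder_R"]["pos"].mean(axis=0)
        assert abs((sl - sr)[1]) < 1e-9  # no front-back shoulder component

    def test_idempotent(self, rng):
        moved = rigid(reference_posture(), 1.2, np.array([0.5, -0.3, 0.1]))
        _, once = kin.to_body_frame(moved)
        _, twice = kin.to_body_frame(once)
        for seg in once:
            assert np.allclose(once[seg]["pos"], twice[seg]["pos"], atol=1e-12)

    def test_norms_preserved_for_vectors(self, rng):
        segs = reference_posture()
        vel = rng.normal(size=(50, 3))
        segs["hand_L"]["vel"] = vel
        moved = rigid(segs, 0.7, np.array([1.0, 2.0, 0.0]))
        moved["hand_L"]["vel"] = vel @ np.array(
            [[np.cos(0.7), -np.sin(0.7), 0], [np.sin(0.7), np.cos(0.7), 0], [0, 0, 1.0]]
        ).T
        _, out = kin.to_body_frame(moved)
        assert np.allclose(
            np.linalg.norm(out["hand_L"]["vel"], axis=1), np.linalg.norm(vel, axis=1), atol=1e-9
        )

    def test_degenerate_shoulders_error(self):
        segs = reference_posture()
        segs["shoulder_R"]["pos"] = segs["shoulder_L"]["pos"].copy()
        with pytest.raises(ValueError, match="degenerate"):
            kin.to_body_frame(segs)


class TestDominantHand:
    def test_speed_two_vs_one_gives_ratio_four(self):
        left = np.full((30, 3), [2.0, 0.0, 0.0])
        right = np.full((30, 3), [0.0, 1.0, 0.0])
        side, ratio = kin.select_dominant_hand(left, right)
        assert side == "left"
        assert ratio == pytest.approx(4.0)

    def test_exact_tie_goes_left_with_warning(self):
        v = np.ones((10, 3))
        with pytest.warns(UserWarning, match="tie"):
            side, ratio = kin.select_dominant_hand(v, v.copy())
        assert side == "left" and ratio == 1.0

    def test_matches_bruteforce_energy(self, rng):
        left = rng.normal(size=(40, 3))
        right = rng.normal(size=(40, 3))
        ke = []
        for v in (left, right):
            total = 0.0
            for frame in v:  # independent loop-based oracle
                total += 0.5 * (frame[0] ** 2 + frame[1] ** 2 + frame[2] ** 2)
            ke.append(total)
        side, ratio = kin.select_dominant_hand(left, right)
        assert side == ("left" if ke[0] > ke[1] else "right")
        assert ratio == pytest.approx(max(ke) / min(ke))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            kin.select_dominant_hand(np.zeros((0, 3)), np.zeros((5, 3)))


class TestMirror:
    def _features(self, rng, side):
        hand = rng.normal(size=(40, 3))
        head = rng.normal(size=(40, 3))
        return make_features(hand, head, side=side)

    def test_right_dominant_flips_x_everywhere(self, rng):
        f = self._features(rng, "right")
        m = kin.mirror_x(f)
        for name in ("hand_pos", "head_pos", "hand_vel", "head_vel", "hand_acc", "head_acc"):
            a, b = getattr(f, name), getattr(m, name)
            assert np.allclose(b[:, 0], -a[:, 0])
            assert np.allclose(b[:, 1:], a[:, 1:])
        assert m.mirrored and m.in_left_hand_space

    def test_left_dominant_identity(self, rng):
        f = self._features(rng, "left")
        m = kin.mirror_x(f)
        assert m is f

    def test_involution(self, rng):
        f = self._features(rng, "right")
        mm = kin.mirror_x(kin.mirror_x(f))
        assert np.allclose(mm.hand_pos, f.hand_pos)
        assert mm.mirrored == f.mirrored

    def test_norms_invariant(self, rng):
        f = self._features(rng, "right")
        m = kin.mirror_x(f)
        assert np.allclose(
            np.linalg.norm(m.hand_vel, axis=1), np.linalg.norm(f.hand_vel, axis=1)
        )


class TestDeriveKinematics:
    def test_linear_position(self):
        t = np.arange(50)[:, None] / RATE
        pos = t * np.array([1.0, -2.0, 0.5])
        vel, acc = kin.derive_kinematics(pos, RATE)
        assert np.allclose(vel, [1.0, -2.0, 0.5], atol=1e-9)
        assert np.allclose(acc, 0.0, atol=1e-6)

    def test_quadratic_acceleration(self):
        a = 3.0
        t = np.arange(100) / RATE
        pos = np.stack([0.5 * a * t**2, np.zeros_like(t), np.zeros_like(t)], axis=1)
        _, acc = kin.derive_kinematics(pos, RATE)
        assert np.allclose(acc[2:-2, 0], a, atol=1e-6)

    def test_sinusoid_second_order_accuracy(self):
        t = np.arange(200) / RATE
        pos = np.stack([np.sin(2 * np.pi * t), np.zeros_like(t), np.zeros_like(t)], axis=1)
        vel, _ = kin.derive_kinematics(pos, RATE)
        expected = 2 * np.pi * np.cos(2 * np.pi * t)
        dt = 1 / RATE
        assert np.max(np.abs(vel[1:-1, 0] - expected[1:-1])) < (2 * np.pi) ** 3 * dt**2

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            kin.derive_kinematics(np.zeros((2, 3)), RATE)


class TestFullChain:
    def test_chain_is_deterministic_and_mirrors_right(self, rng):
        segs = reference_posture(n=60)
        # make the right hand the energetic one
        t = np.linspace(0, 1, 60)
        segs["hand_R"] = {"pos": np.stack([-0.3 + 0.3 * np.sin(12 * t), 0.2 * t, 0.1 + 0 * t], axis=1)}
        moved = rigid(segs, 0.9, np.array([0.2, 0.1, 0.0]))
        f1 = kin.compute_kinematic_features(moved, RATE)
        f2 = kin.compute_kinematic_features(moved, RATE)
        assert f1.dominant_side == "right"
        assert f1.mirrored and f1.in_left_hand_space
        assert np.array_equal(f1.hand_pos, f2.hand_pos)
        assert f1.energy_ratio > 1.0
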