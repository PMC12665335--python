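"""Per-motif kinematic conditioning: smoothing, body frame, hand selection.

The transform chain is fixed and deterministic:

1. Savitzky–Golay smoothing (order 2, 125 ms window) of every ingested
   series, per axis.
2. Rotation about the vertical axis so the time-averaged shoulder-to-
   shoulder line is parallel to the mediolateral x-axis, and translation
   putting the time-averaged pelvis centroid at the origin.  One rigid
   transform per motif; rotation only is applied to velocities and
   accelerations.
3. Dominant-hand selection by kinetic energy KE = Σ_t ½·m·‖v_t‖² with the
   two hands' masses assumed equal (m = 1); ties go to the left hand.
4. Mirroring of the x-axis for right-dominant motifs so all gestures live
   in a common "left-hand space".  Head series are never mirrored.

Axis convention: x mediolateral (left shoulder toward +x), y antero-
posterior, z vertical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "KinematicFeatures",
    "BodyFrame",
    "smooth_savgol",
    "body_frame_from_posture",
    "to_body_frame",
    "select_dominant_hand",
    "kinetic_energy",
    "mirror_x",
    "derive_kinematics",
    "compute_kinematic_features",
]

DEFAULT_RATE_HZ = 60.0
SAVGOL_WINDOW_S = 0.125
SAVGOL_ORDER = 2


@dataclass
class KinematicFeatures:
    """Six conditioned 3-D series for one motif on a shared time base."""

    hand_pos: np.ndarray
    head_pos: np.ndarray
    hand_vel: np.ndarray
    head_vel: np.ndarray
    hand_acc: np.ndarray
    head_acc: np.ndarray
    rate: float
    dominant_side: str
    mirrored: bool
    energy_ratio: float

    def __post_init__(self) -> None:
        n = self.hand_pos.shape[0]
        for name in ("head_pos", "hand_vel", "head_vel", "hand_acc", "head_acc"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise ValueError(f"kinematic series {name!r} must have shape ({n}, 3)")
        if self.dominant_side not in ("left", "right"):
            raise ValueError(f"dominant_side must be left/right, got {self.dominant_side!r}")
        if self.energy_ratio < 1.0:
            raise ValueError("energy_ratio is max/min and must be >= 1")

    @property
    def in_left_hand_space(self) -> bool:
        """True once right-dominant motifs have been mirrored (pipeline output)."""
        return self.dominant_side == "left" or self.mirrored

    def __len__(self) -> int:
        return self.hand_pos.shape[0]


@dataclass(frozen=True)
class BodyFrame:
    """Yaw rotation + translation mapping world coordinates to body frame."""

    rotation: np.ndarray  # (3, 3), rotation about z
    origin: np.ndarray    # (3,), world position of the pelvis centroid

    def apply_position(self, pos: np.ndarray) -> np.ndarray:
        return (pos - self.origin) @ self.rotation.T

    def apply_vector(self, vec: np.ndarray) -> np.ndarray:
        return vec @ self.rotation.T


def smooth_savgol(
    series: np.ndarray,
    rate: float,
    window_s: float = SAVGOL_WINDOW_S,
    order: int = SAVGOL_ORDER,
) -> np.ndarray:
    """Per-axis Savitzky–Golay smoothing.

    The window in samples is the nearest odd integer to ``window_s * rate``
    (rounding down on ties, favouring detail retention: 125 ms at 60 Hz →
    7 samples).  Polynomials of degree ≤ ``order`` pass through unchanged.
    """
    series = np.asarray(series, dtype=np.float64)
    w = int(round(window_s * rate))
    if w % 2 == 0:
        w -= 1
    min_w = order + 1 if (order + 1) % 2 == 1 else order + 2  # smallest odd > order
    w = max(w, min_w)
    if series.shape[0] < w:
        raise ValueError(
            f"series of {series.shape[0]} samples shorter than the "
            f"{w}-sample smoothing window"
        )
    return savgol_filter(series, w, order, axis=0, mode="interp")


def body_frame_from_posture(
    shoulder_l: np.ndarray, shoulder_r: np.ndarray, pelvis: np.ndarray
) -> BodyFrame:
    """Rigid body-frame transform from time-averaged landmark positions.

    The yaw angle aligns the mean left→right shoulder line with the x-axis
    (left shoulder toward +x); the mean pelvis position becomes the origin.
    """
    sl = np.atleast_2d(shoulder_l).mean(axis=0)
    sr = np.atleast_2d(shoulder_r).mean(axis=0)
    pe = np.atleast_2d(pelvis).mean(axis=0)
    s = sl - sr
    if np.hypot(s[0], s[1]) < 1e-12:
        raise ValueError("degenerate (vertical or zero-length) shoulder vector")
    yaw = np.arctan2(s[1], s[0])
    c, sn = np.cos(-yaw), np.sin(-yaw)
    rot = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
    return BodyFrame(rotation=rot, origin=np.asarray(pe, dtype=np.float64))


def to_body_frame(
    segments: dict[str, dict[str, np.ndarray]]
) -> tuple[BodyFrame, dict[str, dict[str, np.ndarray]]]:
    """Apply one motif-level body-frame transform to all segments.

    ``segments`` maps segment name → ``{"pos": (n,3), "vel": (n,3), "acc": (n,3)}``
    (vel/acc optional).  Positions are rotated and translated; velocities
    and accelerations are rotated only, so speeds and acceleration
    magnitudes are preserved.
    """
    for need in ("shoulder_L", "shoulder_R", "pelvis"):
        if need not in segments:
            raise ValueError(f"body frame needs segment {need!r}")
    frame = body_frame_from_posture(
        segments["shoulder_L"]["pos"], segments["shoulder_R"]["pos"], segments["pelvis"]["pos"]
    )
    out: dict[str, dict[str, np.ndarray]] = {}
    for seg, d in segments.items():
        nd = {"pos": frame.apply_position(d["pos"])}
        for key in ("vel", "acc"):
            if key in d:
                nd[key] = frame.apply_vector(d[key])
        if "t" in d:
            nd["t"] = d["t"]
        out[seg] = nd
    return frame, out


def kinetic_energy(vel: np.ndarray, mass: float = 1.0) -> float:
    """Total kinetic energy Σ_t ½·m·‖v_t‖² over a motif."""
    vel = np.asarray(vel, dtype=np.float64)
    return float(0.5 * mass * np.sum(vel**2))


def select_dominant_hand(
    left_vel: np.ndarray, right_vel: np.ndarray, mass: float = 1.0
) -> tuple[str, float]:
    """Pick the hand with more kinetic energy; ties go to the left hand.

    Returns ``(side, energy_ratio)`` with ``energy_ratio = max/min`` (1.0
    on an exact tie, +inf when only one hand moved at all).
    """
    if len(left_vel) == 0 or len(right_vel) == 0:
        raise ValueError("empty velocity series")
    ke_l = kinetic_energy(left_vel, mass)
    ke_r = kinetic_energy(right_vel, mass)
    if ke_l == ke_r:
        warnings.warn("exact kinetic-energy tie; choosing left hand", stacklevel=2)
        return "left", 1.0
    hi, lo = max(ke_l, ke_r), min(ke_l, ke_r)
    ratio = float("inf") if lo == 0 else hi / lo
    return ("left", ratio) if ke_l > ke_r else ("right", ratio)


def mirror_x(features: KinematicFeatures) -> KinematicFeatures:
    """Negate the x-components of right-dominant motifs (involution).

    Applying the operation to an already-mirrored right-dominant motif
    restores the original orientation; left-dominant motifs pass through.
    """
    if features.dominant_side == "left":
        return features
    flip = np.array([-1.0, 1.0, 1.0])

    def m(a: np.ndarray) -> np.ndarray:
        return a * flip

    return replace(
        features,
        hand_pos=m(features.hand_pos),
        head_pos=m(features.head_pos),
        hand_vel=m(features.hand_vel),
        head_vel=m(features.head_vel),
        hand_acc=m(features.hand_acc),
        head_acc=m(features.head_acc),
        mirrored=not features.mirrored,
    )


def derive_kinematics(pos: np.ndarray, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration by central differences (one-sided at ends)."""
    pos = np.asarray(pos, dtype=np.float64)
    if pos.shape[0] < 3:
        raise ValueError("need at least 3 frames to differentiate")
    vel = np.gradient(pos, 1.0 / rate, axis=0)
    acc = np.gradient(vel, 1.0 / rate, axis=0)
    return vel, acc


def compute_kinematic_features(
    segments: dict[str, dict[str, np.ndarray]],
    rate: float = DEFAULT_RATE_HZ,
    window_s: float = SAVGOL_WINDOW_S,
    order: int = SAVGOL_ORDER,
    smooth: bool = True,
    in_body_frame: bool = False,
) -> KinematicFeatures:
    """Full conditioning chain for one motif.

    ``segments`` must contain ``hand_L``, ``hand_R``, ``head`` and — unless
    ``in_body_frame`` — ``shoulder_L``, ``shoulder_R``, ``pelvis``, each as
    ``{"pos": (n,3)}`` with optional tracker-native ``vel``/``acc`` (derived
    by central differences when absent).
    """
    work: dict[str, dict[str, np.ndarray]] = {}
    for seg, d in segments.items():
        nd = {}
        for key in ("pos", "vel", "acc"):
            if key in d:
                arr = np.asarray(d[key], dtype=np.float64)
                nd[key] = smooth_savgol(arr, rate, window_s, order) if smooth else arr
        work[seg] = nd
    for seg in ("hand_L", "hand_R", "head"):
        if seg not in work:
            raise ValueError(f"missing segment {seg!r}")
        if "vel" not in work[seg] or "acc" not in work[seg]:
            vel, acc = derive_kinematics(work[seg]["pos"], rate)
            work[seg].setdefault("vel", vel)
            work[seg].setdefault("acc", acc)
    if not in_body_frame:
        _, work = to_body_frame(work)
    side, ratio = select_dominant_hand(work["hand_L"]["vel"], work["hand_R"]["vel"])
    hand = work["hand_L"] if side == "left" else work["hand_R"]
    feats = KinematicFeatures(
        hand_pos=hand["pos"],
        head_pos=work["head"]["pos"],
        hand_vel=hand["vel"],
        head_vel=work["head"]["vel"],
        hand_acc=hand["acc"],
        head_acc=work["head"]["acc"],
        rate=rate,
        dominant_side=side,
        mirrored=False,
        energy_ratio=ratio if np.isfinite(ratio) else 1e9,
    )
    return mirror_x(feats)
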