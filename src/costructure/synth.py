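"""Synthetic multimodal motif datasets with tunable gesture-vocal coupling.

The generator emulates the statistical structure of segmented vocal
performances with synchronized motion tracking:

* motifs are drawn from a small number of **latent melodic classes**; each
  class owns smooth prototype curves for f0 (Hz), loudness (dB re max) and
  spectral centroid (Hz) on a unit time axis;
* each motif instance applies a random **monotone time warp** of bounded
  derivative to its class prototype, samples it at a variable duration
  (≥ 1.5 s), and adds noise — exactly the distortion DTW is built to
  absorb;
* the **kinematic trajectories** are a mixture
  ``λ · (rotation of the class prototype's (f0, loudness, centroid) values
  into 3-D position) + (1 − λ) · (independent smooth trajectory)``,
  sharing the motif's warp, so λ = 1 makes gesture shape a deterministic
  function of melodic class and λ = 0 makes it independent; velocity- and
  acceleration-level coupling is inherited through differentiation;
* the rotation is drawn once per (performer, segment), so each
  pseudo-performer couples sound to movement through their own mix of
  sonic dimensions, each dimension keeping an equal variance share;
* the dominant hand carries ``hand_dominance_ratio`` times the kinetic
  energy of the nondominant hand (exact on noise-free runs); velocity and
  acceleration are central differences of position.

Noise scales: ``sonic_noise_sd`` is in Hz on f0 and is rescaled for the
other sonic features by the ratio of their prototype amplitudes;
``kinematic_noise_sd`` is in meters.

A small harmonic synthesizer (:func:`synthesize_audio`) renders f0/envelope
contours to audio for testing the sonic feature extractors; it makes no
attempt at vocal timbre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import ingest
from .ingest import MotifRecord
from .kinematics import (
    KinematicFeatures,
    derive_kinematics,
    kinetic_energy,
    mirror_x,
    select_dominant_hand,
    smooth_savgol,
)
from .sonic import SonicFeatures, delta_f0, smooth_gaussian

__all__ = ["SynthConfig", "SynthDataset", "generate_dataset", "synthesize_audio", "write_dataset"]

_PROTO_N = 512          # samples of the unit-time class prototypes
_F0_BASE, _F0_AMP = 180.0, 40.0          # Hz
_LOUD_BASE, _LOUD_AMP = -18.0, 5.0       # dB re max
_CENT_BASE, _CENT_AMP = 1500.0, 350.0    # Hz
_GESTURE_SD_M = 0.08                     # per-axis amplitude of gesture curves
_P_LEFT_DOMINANT = 0.89                  # per-performer probability of a left dominant hand


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition knobs for the generator.

    ``coupling`` is λ ∈ [0, 1]: 0 = gesture independent of melody,
    1 = gesture a deterministic function of melodic class.
    """

    n_performers: int = 3
    motifs_per_performer: int = 40
    n_classes: int = 6
    coupling: float = 0.8
    sonic_noise_sd: float = 2.0
    kinematic_noise_sd: float = 0.005
    warp_strength: float = 0.3
    duration_range_s: tuple[float, float] = (1.5, 4.0)
    sonic_rate_hz: float = 100.0
    kinematic_rate_hz: float = 60.0
    hand_dominance_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling λ must be in [0, 1], got {self.coupling}")
        lo, hi = self.duration_range_s
        if lo < 1.5 or hi < lo:
            raise ValueError(f"duration range must satisfy 1.5 <= min <= max, got {self.duration_range_s}")
        if self.sonic_rate_hz <= 0 or self.kinematic_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.sonic_noise_sd < 0 or self.kinematic_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.warp_strength < 0:
            raise ValueError("warp_strength must be >= 0")
        if self.hand_dominance_ratio <= 1.0:
            raise ValueError("hand_dominance_ratio must be > 1")
        if self.n_performers < 1 or self.motifs_per_performer < 1 or self.n_classes < 1:
            raise ValueError("counts must be positive")


@dataclass
class SynthDataset:
    """Generated motifs with ground-truth latent classes."""

    motif_table: list[MotifRecord]
    sonic: dict[str, SonicFeatures]
    kinematic: dict[str, KinematicFeatures]
    class_labels: dict[str, int]
    config: SynthConfig

    def motif_frame(self) -> pd.DataFrame:
        return ingest.motif_frame(self.motif_table)


def _smooth_curve(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Standardized smoothed Gaussian random walk on n samples."""
    c = gaussian_filter1d(rng.standard_normal(n), sigma, mode="reflect")
    c = c - c.mean()
    sd = c.std()
    return c / sd if sd > 0 else c


def _monotone_warp(rng: np.random.Generator, strength: float, n_knots: int = 64) -> np.ndarray:
    """Random monotone diffeomorphism of [0, 1] with bounded derivative.

    Returned as the warp evaluated on a dense knot grid; interpolate to
    apply.  ``strength`` = 0 gives the identity.
    """
    g = gaussian_filter1d(rng.standard_normal(n_knots), 6.0, mode="reflect")
    dens = np.exp(strength * g)
    cdf = np.concatenate([[0.0], np.cumsum(dens)])
    return cdf / cdf[-1]


def _apply_warp(u: np.ndarray, warp_knots: np.ndarray) -> np.ndarray:
    knots = np.linspace(0.0, 1.0, len(warp_knots))
    return np.interp(u, knots, warp_knots)


def _sample_proto(proto: np.ndarray, u: np.ndarray) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, len(proto))
    return np.interp(u, grid, proto)


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate a fully reproducible synthetic dataset under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_cls = config.n_classes
    proto_sigma = _PROTO_N / 14.0  # ~0.5-2 Hz gestural wiggles over a 1.5-4 s motif

    # class sonic prototypes and their standardized derivative stacks
    protos = []
    for _ in range(n_cls):
        f0c = _F0_BASE + _F0_AMP * _smooth_curve(rng, _PROTO_N, proto_sigma)
        loudc = np.minimum(_LOUD_BASE + _LOUD_AMP * _smooth_curve(rng, _PROTO_N, proto_sigma), -0.5)
        centc = np.maximum(_CENT_BASE + _CENT_AMP * _smooth_curve(rng, _PROTO_N, proto_sigma), 100.0)
        stack = []
        for curve in (f0c, loudc, centc):
            z = (curve - curve.mean()) / max(curve.std(), 1e-12)
            stack.append(z)
        protos.append({"f0": f0c, "loud": loudc, "cent": centc, "stack": np.stack(stack, axis=1)})

    records: list[MotifRecord] = []
    sonic: dict[str, SonicFeatures] = {}
    kinematic: dict[str, KinematicFeatures] = {}
    labels: dict[str, int] = {}

    noise_f0 = config.sonic_noise_sd
    noise_loud = config.sonic_noise_sd * (_LOUD_AMP / _F0_AMP)
    noise_cent = config.sonic_noise_sd * (_CENT_AMP / _F0_AMP)
    lam = config.coupling

    for p in range(config.n_performers):
        performer = f"P{p + 1}"
        dominant = "left" if rng.random() < _P_LEFT_DOMINANT else "right"
        # per-(performer, segment) sonic->3D coupling maps: a random rotation
        # of (f0, loudness, centroid) prototype values into gesture space, so
        # each performer couples through their own dimension mix while every
        # sonic channel keeps an equal share of the gesture variance
        def _coupling_map() -> np.ndarray:
            q, r = np.linalg.qr(rng.standard_normal((3, 3)))
            return q * np.sign(np.diag(r))

        maps = {"hand": _coupling_map(), "head": _coupling_map()}
        offsets = {
            "hand_L": np.array([0.25, 0.20, 0.10]),
            "hand_R": np.array([-0.25, 0.20, 0.10]),
            "head": np.array([0.0, 0.05, 0.60]),
        }
        t_cursor = 1.0
        for k in range(config.motifs_per_performer):
            motif_id = f"{performer}_M{k:03d}"
            cls = int(rng.integers(n_cls))
            proto = protos[cls]
            dur = float(rng.uniform(*config.duration_range_s))
            ns = max(3, int(round(dur * config.sonic_rate_hz)))
            nk = max(5, int(round(dur * config.kinematic_rate_hz)))
            warp = _monotone_warp(rng, config.warp_strength)

            u_s = _apply_warp(np.linspace(0.0, 1.0, ns), warp)
            # emit *conditioned* sonic series: the same Gaussian smoothing the
            # feature pipeline applies to real tracks
            f0 = smooth_gaussian(_sample_proto(proto["f0"], u_s) + rng.normal(0, noise_f0, ns))
            loud = np.minimum(
                smooth_gaussian(_sample_proto(proto["loud"], u_s) + rng.normal(0, noise_loud, ns)), 0.0
            )
            cent = np.maximum(
                smooth_gaussian(_sample_proto(proto["cent"], u_s) + rng.normal(0, noise_cent, ns)), 0.0
            )
            f0 = np.maximum(f0, 30.0)
            sonic[motif_id] = SonicFeatures(
                f0=f0,
                delta_f0=delta_f0(f0),
                loudness=loud,
                spectral_centroid=cent,
                rate=config.sonic_rate_hz,
                voiced_mask=np.ones(ns, dtype=bool),
            )

            u_k = _apply_warp(np.linspace(0.0, 1.0, nk), warp)
            stack = np.stack([_sample_proto(proto["stack"][:, c], u_k) for c in range(3)], axis=1)

            # independent movement has fixed spectral content in absolute time
            # (~0.25 s smoothness), so its DTW distances carry no duration
            # signature that could leak sonic information at λ = 0
            indep_sigma = 0.25 * config.kinematic_rate_hz

            def gesture(segment: str) -> np.ndarray:
                coupled = stack @ maps[segment].T
                coupled = coupled / max(coupled.std(), 1e-12) * _GESTURE_SD_M
                indep = np.stack(
                    [_GESTURE_SD_M * _smooth_curve(rng, nk, indep_sigma) for _ in range(3)], axis=1
                )
                return lam * coupled + (1.0 - lam) * indep

            dom_traj = gesture("hand")
            head_traj = gesture("head")
            # nondominant hand: independent movement scaled to the target KE ratio
            nd_traj = np.stack(
                [_GESTURE_SD_M * _smooth_curve(rng, nk, indep_sigma) for _ in range(3)], axis=1
            )
            ke_dom = kinetic_energy(
                derive_kinematics(smooth_savgol(dom_traj, config.kinematic_rate_hz), config.kinematic_rate_hz)[0]
            )
            ke_nd = kinetic_energy(
                derive_kinematics(smooth_savgol(nd_traj, config.kinematic_rate_hz), config.kinematic_rate_hz)[0]
            )
            if ke_nd > 0 and ke_dom > 0:
                nd_traj = nd_traj * np.sqrt(ke_dom / (config.hand_dominance_ratio * ke_nd))

            hands = {
                ("left" if dominant == "left" else "right"): dom_traj,
                ("right" if dominant == "left" else "left"): nd_traj,
            }
            pos = {
                "hand_L": hands["left"] + offsets["hand_L"],
                "hand_R": hands["right"] + offsets["hand_R"],
                "head": 0.5 * head_traj + offsets["head"],
            }
            if config.kinematic_noise_sd > 0:
                # band-limited tracking jitter (~50 ms correlation), the error
                # profile of an IMU-fusion suit; per-frame white noise would
                # dominate the derived velocity/acceleration channels at 60 Hz
                for seg in pos:
                    jit = gaussian_filter1d(
                        rng.normal(0, 1.0, (nk, 3)), 3.0, axis=0, mode="reflect"
                    )
                    sd = jit.std()
                    if sd > 0:
                        jit *= config.kinematic_noise_sd / sd
                    pos[seg] = pos[seg] + jit

            vel = {}
            acc = {}
            for seg in pos:
                # conditioned positions: the pipeline's Savitzky-Golay filter
                pos[seg] = smooth_savgol(pos[seg], config.kinematic_rate_hz)
                vel[seg], acc[seg] = derive_kinematics(pos[seg], config.kinematic_rate_hz)
            side, ratio = select_dominant_hand(vel["hand_L"], vel["hand_R"])
            hand_seg = "hand_L" if side == "left" else "hand_R"
            feats = KinematicFeatures(
                hand_pos=pos[hand_seg],
                head_pos=pos["head"],
                hand_vel=vel[hand_seg],
                head_vel=vel["head"],
                hand_acc=acc[hand_seg],
                head_acc=acc["head"],
                rate=config.kinematic_rate_hz,
                dominant_side=side,
                mirrored=False,
                energy_ratio=ratio if np.isfinite(ratio) else 1e9,
            )
            kinematic[motif_id] = mirror_x(feats)

            records.append(
                MotifRecord(
                    motif_id=motif_id,
                    performance_id=f"{performer}_perf1",
                    performer_id=performer,
                    start_s=t_cursor,
                    end_s=t_cursor + dur,
                )
            )
            labels[motif_id] = cls
            t_cursor += dur + 0.5

    return SynthDataset(records, sonic, kinematic, labels, config)


def synthesize_audio(
    f0_contour: np.ndarray,
    amp_envelope: np.ndarray,
    sample_rate: int = 48_000,
    frame_rate: float = 100.0,
    n_harmonics: int = 8,
) -> np.ndarray:
    """Phase-continuous harmonic tone following an f0/amplitude contour.

    ``f0_contour`` (Hz, NaN or <= 0 = unvoiced) and ``amp_envelope``
    ([0, 1]) are frame series at ``frame_rate``; unvoiced frames render as
    silence with the oscillator phase held.
    """
    f0_contour = np.asarray(f0_contour, dtype=np.float64)
    amp_envelope = np.asarray(amp_envelope, dtype=np.float64)
    if f0_contour.size == 0:
        raise ValueError("empty f0 contour")
    if f0_contour.shape != amp_envelope.shape:
        raise ValueError("contour and envelope must have equal length")
    if np.nanmax(amp_envelope) > 1.0 + 1e-9 or np.nanmin(amp_envelope) < 0.0:
        raise ValueError("envelope must lie in [0, 1]")
    n = int(round(len(f0_contour) / frame_rate * sample_rate))
    t_frames = np.arange(len(f0_contour)) / frame_rate
    t = np.arange(n) / sample_rate
    voiced_f = np.isfinite(f0_contour) & (f0_contour > 0)
    f0_s = np.interp(t, t_frames[voiced_f], f0_contour[voiced_f]) if voiced_f.any() else np.zeros(n)
    amp_s = np.interp(t, t_frames, np.where(voiced_f, amp_envelope, 0.0))
    phase = 2.0 * np.pi * np.cumsum(f0_s) / sample_rate
    out = np.zeros(n)
    for h in range(1, n_harmonics + 1):
        out += np.sin(h * phase) / h
    out *= amp_s
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> None:
    """Persist a dataset in the CSV layouts the ingest module consumes.

    Writes ``motif_table.csv`` plus, per performance, per-frame kinematic
    CSVs (all six tracked segments, in a world frame offset from the body
    frame by a random-looking per-performance yaw and translation derived
    from the seed) and per-performance sonic track CSVs (f0, loudness,
    centroid) with unvoiced silence between motifs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    ingest.write_motif_table(dataset.motif_table, outdir / "motif_table.csv")
    rng = np.random.default_rng(cfg.seed + 1)

    by_perf: dict[str, list[MotifRecord]] = {}
    for rec in dataset.motif_table:
        by_perf.setdefault(rec.performance_id, []).append(rec)

    for perf, recs in by_perf.items():
        recs = sorted(recs, key=lambda r: r.start_s)
        t_end = recs[-1].end_s + 1.0
        nk = int(round(t_end * cfg.kinematic_rate_hz))
        ns = int(round(t_end * cfg.sonic_rate_hz))
        tk = np.arange(nk) / cfg.kinematic_rate_hz
        ts = np.arange(ns) / cfg.sonic_rate_hz

        yaw = rng.uniform(-np.pi, np.pi)
        shift = rng.uniform(-1.0, 1.0, 3)
        c, s = np.cos(yaw), np.sin(yaw)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

        segs: dict[str, dict[str, np.ndarray]] = {}
        base = {
            "pelvis": np.zeros(3),
            "shoulder_L": np.array([0.18, 0.0, 0.45]),
            "shoulder_R": np.array([-0.18, 0.0, 0.45]),
            "hand_L": np.array([0.25, 0.20, 0.10]),
            "hand_R": np.array([-0.25, 0.20, 0.10]),
            "head": np.array([0.0, 0.05, 0.60]),
        }
        for seg, b in base.items():
            segs[seg] = {"t": tk, "pos": np.tile(b, (nk, 1)).astype(float)}
        f0_track = np.full(ns, np.nan)
        loud_track = np.full(ns, -80.0)
        cent_track = np.zeros(ns)

        for rec in recs:
            sf = dataset.sonic[rec.motif_id]
            kf = dataset.kinematic[rec.motif_id]
            i0 = int(np.floor(rec.start_s * cfg.sonic_rate_hz + 0.5))
            n_m = len(sf.f0)
            f0_track[i0:i0 + n_m] = sf.f0
            loud_track[i0:i0 + n_m] = sf.loudness
            cent_track[i0:i0 + n_m] = sf.spectral_centroid
            k0 = int(np.floor(rec.start_s * cfg.kinematic_rate_hz + 0.5))
            n_k = len(kf)
            # undo mirroring so the on-disk hands are anatomical
            kf_raw = mirror_x(kf) if kf.mirrored else kf
            hand_seg = "hand_L" if kf.dominant_side == "left" else "hand_R"
            segs[hand_seg]["pos"][k0:k0 + n_k] = kf_raw.hand_pos
            segs["head"]["pos"][k0:k0 + n_k] = kf_raw.head_pos

        for seg in segs:
            world = segs[seg]["pos"] @ rot.T + shift
            vel, acc = derive_kinematics(world, cfg.kinematic_rate_hz)
            segs[seg] = {"t": tk, "pos": world, "vel": vel, "acc": acc}
        ingest.write_kinematics(segs, outdir / f"{perf}_kin.csv")
        ingest.write_feature_series(ts, f0_track, outdir / f"{perf}_f0.csv", "f0")
        ingest.write_feature_series(ts, loud_track, outdir / f"{perf}_loudness.csv", "loudness")
        ingest.write_feature_series(ts, cent_track, outdir / f"{perf}_centroid.csv", "centroid")
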