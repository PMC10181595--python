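"""Synthetic gait cohort generator.

Emulates a treadmill-speed walking cohort of adults with knee osteoarthritis:
slow self-selected speed, body mass ~80 kg, ~100 gait cycles per subject.
The generator produces, for each cycle, joint-angle waveforms, a consistent
distal-limb kinematic chain, per-foot ground reaction forces (double-hump
vertical profile, braking/propulsion anterior-posterior S-curve), a
heel-to-toe centre-of-pressure path, and ground reaction moments about the
lab origin computed exactly from the generated force and COP.

The statistical structure is deliberately low-rank: a small set of smooth
latent modes perturbs the kinematic and force channels *jointly*, so the
kinematics carry information about the forces — exactly the assumption a
probabilistic-PCA force estimator relies on.  Subject individuality enters
as (a) anthropometric scaling and (b) a per-subject random smooth template
offset applied to both channel groups, which makes leave-one-subject-out
validation strictly harder than leave-one-cycle-out.  Noise levels,
variability amplitudes and mode shapes are generator design constants, not
quantities taken from any measured cohort.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gaitwrench.core import (
    GRAVITY,
    GaitEvent,
    GaitTrial,
    NormalizedCycle,
    SubjectModel,
    scale_subject,
    time_normalize,
)

# fixed design constants for the latent-mode bank (independent of user seed)
_MODE_SEED = 20230777
_N_OFFSET_HARMONICS = 3

ANGLE_CHANNELS = (
    "hip_flexion_r", "hip_flexion_l",
    "hip_adduction_r", "hip_adduction_l",
    "knee_flexion_r", "knee_flexion_l",
    "ankle_flexion_r", "ankle_flexion_l",
)


@dataclass
class GeneratorConfig:
    """Cohort and variability parameters of the synthetic generator.

    Demographic defaults (mass 80.5 +/- 15.3 kg, height 1.65 +/- 0.12 m,
    speed 0.75 +/- 0.23 m/s, 18 subjects x ~100 cycles) emulate a slow-walking
    knee-osteoarthritis cohort.  Variability magnitudes (latent mode
    amplitudes, subject offsets, noise) are the generator's own choices.
    """

    n_subjects: int = 18
    cycles_per_subject: int = 99
    mass_mean: float = 80.5   # kg
    mass_sd: float = 15.3
    height_mean: float = 1.65  # m
    height_sd: float = 0.12
    speed_mean: float = 0.75   # m/s
    speed_sd: float = 0.23
    latent_rank: int = 5
    latent_sd: tuple[float, ...] | None = None  # default: 0.06 * 0.75**k
    noise_sd_grf: float = 0.02   # BW, white, tapered to zero at stance edges
    noise_sd_kin: float = 0.01   # rad, white
    subject_offset_sd_grf: float = 0.03  # BW
    subject_offset_sd_kin: float = 0.02  # rad
    stance_fraction: float = 0.60
    sample_rate: float = 100.0   # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0,1)")
        for name in ("mass_sd", "height_sd", "speed_sd", "noise_sd_grf", "noise_sd_kin",
                     "subject_offset_sd_grf", "subject_offset_sd_kin"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.latent_sd is None:
            self.latent_sd = tuple(0.06 * 0.75 ** k for k in range(self.latent_rank))
        if len(self.latent_sd) != self.latent_rank:
            raise ValueError("latent_sd length must equal latent_rank")


# ---------------------------------------------------------------------------
# deterministic templates
# ---------------------------------------------------------------------------

def _stance_window(s: np.ndarray) -> np.ndarray:
    """Smooth taper, zero at stance boundaries (s in [0,1], 0 outside)."""
    s = np.clip(s, 0.0, 1.0)
    return np.sin(np.pi * s) ** 0.7


def _vertical_shape(s: np.ndarray) -> np.ndarray:
    """Unnormalized double-hump vertical GRF shape over stance fraction s.

    Tuned so that after the whole-cycle mean normalization (both feet
    average 1 BW) the two humps land near 1.1 BW with a mid-stance valley.
    """
    g = lambda c, w: np.exp(-0.5 * ((s - c) / w) ** 2)
    win = np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 0.25
    return (1.15 * g(0.25, 0.16) + 1.10 * g(0.75, 0.16) + 0.90 * g(0.50, 0.35)) * win


def _ap_shape(s: np.ndarray, speed: float) -> np.ndarray:
    """Braking (negative) then propulsive (positive) AP force, BW."""
    return -0.17 * np.sqrt(max(speed, 0.05) / 0.75) * np.sin(2 * np.pi * np.clip(s, 0, 1)) * _stance_window(s)


def _ml_shape(s: np.ndarray, side_sign: float) -> np.ndarray:
    """Small medio-lateral force; opposite sign per foot."""
    return -0.05 * side_sign * np.sin(np.pi * np.clip(s, 0, 1)) * _stance_window(s)


def _angle_templates(p: np.ndarray, speed: float) -> dict[str, np.ndarray]:
    """Joint-angle templates (rad) over cycle fraction p for the right leg;
    left leg is the right template shifted by half a cycle."""
    amp = (max(speed, 0.05) / 0.75) ** 0.3
    out = {}
    for side, shift in (("r", 0.0), ("l", 0.5)):
        q = (p + shift) % 1.0
        out[f"hip_flexion_{side}"] = 0.12 + 0.35 * amp * np.cos(2 * np.pi * q)
        out[f"hip_adduction_{side}"] = 0.08 * np.sin(2 * np.pi * q)
        out[f"knee_flexion_{side}"] = (
            0.08
            + 0.25 * np.exp(-0.5 * ((q - 0.15) / 0.09) ** 2)
            + 1.00 * amp * np.exp(-0.5 * ((q - 0.72) / 0.09) ** 2)
        )
        out[f"ankle_flexion_{side}"] = -0.05 + 0.18 * np.sin(2 * np.pi * q + 0.9) * amp
    return out


def _mode_bank(latent_rank: int) -> list[dict]:
    """Fixed smooth latent modes coupling kinematic and force channels.

    Mode k carries: stance-domain waveforms for the vertical/AP/ML force
    channels and cycle-domain harmonics (random but fixed amplitude/phase)
    for each joint-angle channel.  The bank is a design constant.
    """
    rng = np.random.default_rng(_MODE_SEED)
    bank = []
    for k in range(latent_rank):
        entry = {
            "grf_y": (k + 1, 0.0, 1.0),          # sin((k+1) pi s) * window
            "grf_x": (k + 1, np.pi / 2, 0.4),    # phase-shifted, smaller
            "grf_z": (k + 1, 0.0, 0.1),
            "angles": {
                ch: (float(rng.uniform(0.7, 1.5)) * 1.5, float(rng.uniform(0, 2 * np.pi)))
                for ch in ANGLE_CHANNELS
            },
        }
        bank.append(entry)
    return bank


# ---------------------------------------------------------------------------
# per-subject hidden parameters
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated to mean +/- 3 sd (resampling)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= 3 * sd:
            return float(x)
    return mean


def _subject_index(subject: SubjectModel) -> int:
    sid = subject.subject_id
    if sid.startswith("S") and sid[1:].isdigit():
        return int(sid[1:])
    return zlib.crc32(sid.encode()) % (2 ** 20)


def _subject_hidden(config: GeneratorConfig, index: int) -> dict:
    """Deterministic per-subject parameters: demographics, speed, offsets."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101, index]))
    mass = _truncated_normal(rng, config.mass_mean, config.mass_sd)
    height = _truncated_normal(rng, config.height_mean, config.height_sd)
    speed = max(_truncated_normal(rng, config.speed_mean, config.speed_sd), 0.2)
    nh = _N_OFFSET_HARMONICS
    off = {
        "grf": rng.normal(0.0, config.subject_offset_sd_grf / np.sqrt(nh), size=(3, nh)),
        "angles": {
            ch: (
                rng.normal(0.0, config.subject_offset_sd_kin / np.sqrt(nh), size=nh),
                rng.uniform(0, 2 * np.pi, size=nh),
            )
            for ch in ANGLE_CHANNELS
        },
    }
    return {"mass": max(mass, 30.0), "height": max(height, 1.2), "speed": speed, "offsets": off}


def generate_subject(config: GeneratorConfig, index: int) -> SubjectModel:
    """Sample one subject of the synthetic cohort.

    Mass and height are Normal draws truncated to the mean +/- 3 sd,
    deterministic given ``(config.seed, index)``.
    """
    if index < 0 or index >= config.n_subjects:
        raise ValueError(f"index {index} out of range for {config.n_subjects} subjects")
    h = _subject_hidden(config, index)
    return scale_subject(h["mass"], h["height"], subject_id=f"S{index:03d}")


# ---------------------------------------------------------------------------
# cycle generation
# ---------------------------------------------------------------------------

def _grf_waveforms(
    s: np.ndarray,
    in_stance: np.ndarray,
    speed: float,
    side_sign: float,
    z: np.ndarray,
    bank: list[dict],
    offsets: np.ndarray,
    noise: np.ndarray | None,
) -> np.ndarray:
    """Per-foot GRF (n x 3, BW) before mean normalization; zero outside stance."""
    n = len(s)
    out = np.zeros((n, 3))
    w = np.where(in_stance, _stance_window(s), 0.0)
    sv = np.where(in_stance, s, 0.0)
    base = np.stack(
        [
            np.where(in_stance, _ap_shape(sv, speed), 0.0),
            np.where(in_stance, _vertical_shape(sv), 0.0),
            np.where(in_stance, _ml_shape(sv, side_sign), 0.0),
        ],
        axis=1,
    )
    out += base
    # latent modes (shared with kinematics)
    for k, mode in enumerate(bank):
        for j, key in enumerate(("grf_x", "grf_y", "grf_z")):
            harm, phase, gain = mode[key]
            out[:, j] += z[k] * gain * np.sin(harm * np.pi * sv + phase) * w
    # subject offset: smooth stance-domain harmonics per component
    for j in range(3):
        for h in range(offsets.shape[1]):
            out[:, j] += offsets[j, h] * np.sin((h + 1) * np.pi * sv) * w
    if noise is not None:
        out += noise * w[:, None]
    out[~in_stance] = 0.0
    return out


def _normalize_vertical(grf: np.ndarray, in_stance: np.ndarray, s: np.ndarray, target_mean: float) -> np.ndarray:
    """Linearly project the vertical component so its cycle mean is exact.

    Subtracts a multiple of the deterministic vertical template, which is
    zero outside stance, so the correction preserves the stance support and
    keeps the map from latent variables to waveforms linear.
    """
    tmpl = np.where(in_stance, _vertical_shape(np.where(in_stance, s, 0.0)), 0.0)
    m_t = tmpl.mean()
    if m_t <= 0:
        return grf
    grf = grf.copy()
    grf[:, 1] = grf[:, 1] - (grf[:, 1].mean() - target_mean) / m_t * tmpl
    return grf


def generate_cycle(
    subject: SubjectModel,
    config: GeneratorConfig,
    cycle_index: int,
    subject_index: int | None = None,
) -> GaitTrial:
    """Generate one gait cycle (right heel strike to right heel strike).

    The trial contains joint angles, a consistent distal kinematic chain
    (knee/ankle/foot positions and segment orientation angles for both
    legs), per-foot GRF in BW and GRM in Nm/kg about the lab origin, the
    generating COP paths, COM acceleration consistent with the total force,
    and the gait events.  The whole-cycle mean of the summed vertical GRF
    is exactly 1 BW.  Deterministic given (config.seed, subject, cycle_index).
    """
    sidx = _subject_index(subject) if subject_index is None else subject_index
    hidden = _subject_hidden(config, sidx)
    speed = hidden["speed"]
    sf = config.stance_fraction
    fs = config.sample_rate

    T_target = 1.4 * (0.75 / speed) ** 0.3
    n = max(int(round(T_target * fs)), 20)
    dt = 1.0 / fs
    T = n * dt
    t = np.arange(n + 1) * dt
    p = t / T  # cycle fraction 0..1

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202, sidx, cycle_index]))
    bank = _mode_bank(config.latent_rank)
    z = rng.normal(0.0, np.asarray(config.latent_sd))

    # --- stance phasing -------------------------------------------------
    # right foot: stance [0, sf*T]; left foot: stance [0.5T, (0.5+sf)T] wrapped
    s_r = t / (sf * T)
    in_r = s_r <= 1.0 + 1e-12
    s_l = ((p - 0.5) % 1.0) / sf
    in_l = s_l <= 1.0 + 1e-12

    # --- forces ----------------------------------------------------------
    noise_r = rng.normal(0.0, config.noise_sd_grf, size=(n + 1, 3)) if config.noise_sd_grf > 0 else None
    noise_l = rng.normal(0.0, config.noise_sd_grf, size=(n + 1, 3)) if config.noise_sd_grf > 0 else None
    grf_r = _grf_waveforms(s_r, in_r, speed, +1.0, z, bank, hidden["offsets"]["grf"], noise_r)
    grf_l = _grf_waveforms(s_l, in_l, speed, -1.0, z, bank, hidden["offsets"]["grf"], noise_l)
    grf_r = _normalize_vertical(grf_r, in_r, s_r, 0.5)
    grf_l = _normalize_vertical(grf_l, in_l, s_l, 0.5)

    # --- COP paths and moments about the lab origin ----------------------
    # Plant (calcaneus) positions follow the *nominal* stance-ankle path of
    # the template kinematics, so force and kinematic chain are
    # geometrically consistent while the moments stay linear in the latent
    # variables (the plant does not depend on the latent draw).
    nominal_chain = _limb_chain(_angle_templates(p, speed), p, speed, T, subject)
    plant_r = np.array([float(np.mean(nominal_chain["r_ankle_x"][in_r])) - 0.07, +0.09])
    cop_r = _cop_path(s_r, in_r, plant_r, side_sign=+1.0)
    # left stance consists of the tail of the previous step and a new plant
    cop_l = np.full((n + 1, 2), np.nan)
    old = in_l & (p <= 0.5)
    new = in_l & (p > 0.5)
    ank_l = nominal_chain["l_ankle_x"]
    plant_l_old = np.array([float(np.mean(ank_l[old])) - 0.07 if old.any() else plant_r[0] - 0.5 * speed * T, -0.09])
    plant_l_new = np.array([float(np.mean(ank_l[new])) - 0.07 if new.any() else plant_r[0] + 0.5 * speed * T, -0.09])
    cop_l[old] = _cop_path(s_l[old], np.ones(old.sum(), bool), plant_l_old, -1.0)
    cop_l[new] = _cop_path(s_l[new], np.ones(new.sum(), bool), plant_l_new, -1.0)

    grm_r = _moments_from_cop(grf_r, cop_r, in_r)
    grm_l = _moments_from_cop(grf_l, cop_l, in_l)
    # hold the nearest in-stance value through swing so the COP channels
    # interpolate cleanly when the cycle is time-normalized
    cop_r = _fill_nan_nearest(cop_r)
    cop_l = _fill_nan_nearest(cop_l)

    # --- kinematics -------------------------------------------------------
    angles = _angle_templates(p, speed)
    for k, mode in enumerate(bank):
        for ch, (amp, phase) in mode["angles"].items():
            angles[ch] = angles[ch] + z[k] * amp * np.cos(2 * np.pi * (k + 1) * p + phase)
    for ch, (coef, phases) in hidden["offsets"]["angles"].items():
        for h in range(len(coef)):
            angles[ch] = angles[ch] + coef[h] * np.cos(2 * np.pi * (h + 1) * p + phases[h])
    if config.noise_sd_kin > 0:
        for ch in angles:
            angles[ch] = angles[ch] + rng.normal(0.0, config.noise_sd_kin, size=n + 1)

    chain = _limb_chain(angles, p, speed, T, subject)
    kin = pd.DataFrame({**angles, **chain})

    # --- COM acceleration consistent with total force ---------------------
    total_bw = grf_r + grf_l
    g_vec = np.array([0.0, -GRAVITY, 0.0])
    com_accel = GRAVITY * total_bw + g_vec

    events = [
        GaitEvent("heel_strike", "right", 0.0),
        GaitEvent("toe_off", "right", sf * T),
        GaitEvent("heel_strike", "right", T),
        GaitEvent("toe_off", "left", (sf - 0.5) * T),
        GaitEvent("heel_strike", "left", 0.5 * T),
    ]

    return GaitTrial(
        time=t,
        kinematics=kin,
        grf={"right": grf_r, "left": grf_l},
        grm={"right": grm_r, "left": grm_l},
        cop={"right": cop_r, "left": cop_l},
        com_accel=com_accel,
        events=events,
        body_weight=subject.mass * GRAVITY,
    )


def _fill_nan_nearest(mat: np.ndarray) -> np.ndarray:
    out = mat.copy()
    idx = np.arange(len(mat))
    for j in range(mat.shape[1]):
        ok = np.isfinite(mat[:, j])
        if ok.any() and not ok.all():
            out[~ok, j] = np.interp(idx[~ok], idx[ok], mat[ok, j])
    return out


def _cop_path(s: np.ndarray, valid: np.ndarray, plant: np.ndarray, side_sign: float) -> np.ndarray:
    """Heel-to-toe COP progression from the plant (calcaneus) position, m."""
    s = np.clip(s, 0.0, 1.0)
    prog = s * s * (3 - 2 * s)  # smoothstep 0..1
    out = np.full((len(s), 2), np.nan)
    out[valid, 0] = plant[0] + 0.18 * prog[valid]
    out[valid, 1] = plant[1] - side_sign * 0.015 * np.sin(np.pi * s[valid])
    return out


def _moments_from_cop(grf_bw: np.ndarray, cop: np.ndarray, in_stance: np.ndarray) -> np.ndarray:
    """GRM (Nm/kg) about the lab origin from force (BW) and ground-plane COP."""
    n = grf_bw.shape[0]
    grm = np.zeros((n, 3))
    r = np.zeros((n, 3))
    r[in_stance, 0] = cop[in_stance, 0]
    r[in_stance, 2] = cop[in_stance, 1]
    grm[in_stance] = GRAVITY * np.cross(r[in_stance], grf_bw[in_stance])
    return grm


def _limb_chain(
    angles: dict[str, np.ndarray],
    p: np.ndarray,
    speed: float,
    T: float,
    subject: SubjectModel,
) -> dict[str, np.ndarray]:
    """Forward kinematics of hip->knee->ankle->foot for both legs.

    Produces knee/ankle/foot-COM/shank-COM position channels (m) and
    sagittal/frontal orientation-angle channels for shank and foot, all in
    the lab frame.  The chain is driven by the joint angles so positions
    and angles are mutually consistent.
    """
    L_th = subject.segment("thigh_r").length
    L_sh = subject.segment("shank_r").length
    L_ft = subject.segment("foot_r").length
    com_sh = subject.segment("shank_r").com_fraction
    com_ft = subject.segment("foot_r").com_fraction
    t = p * T
    hip_y = 0.08 + (L_th + L_sh) * 0.98 + 0.015 * np.sin(4 * np.pi * p)
    hip_x = speed * t + 0.02 * np.sin(2 * np.pi * p)
    out: dict[str, np.ndarray] = {}
    for side, zoff in (("r", +0.09), ("l", -0.09)):
        th = angles[f"hip_flexion_{side}"]
        kf = angles[f"knee_flexion_{side}"]
        ad = angles[f"hip_adduction_{side}"] * (1 if side == "r" else -1)
        af = angles[f"ankle_flexion_{side}"]
        th_sag = th                 # thigh global sagittal lean (forward +)
        sh_sag = th - kf            # shank global sagittal lean
        ft_sag = sh_sag + af        # foot long-axis angle from horizontal
        # thigh direction hip->knee
        dth = np.stack([np.sin(th_sag), -np.cos(th_sag), np.sin(ad) * np.ones_like(th)], axis=1)
        dth /= np.linalg.norm(dth, axis=1, keepdims=True)
        dsh = np.stack([np.sin(sh_sag), -np.cos(sh_sag), np.sin(ad)], axis=1)
        dsh /= np.linalg.norm(dsh, axis=1, keepdims=True)
        hip = np.stack([hip_x, hip_y, np.full_like(hip_x, zoff)], axis=1)
        knee = hip + L_th * dth
        ankle = knee + L_sh * dsh
        dft = np.stack([np.cos(ft_sag), -np.sin(ft_sag), np.zeros_like(ft_sag)], axis=1)
        foot_com = ankle + com_ft * L_ft * dft
        shank_com = knee + com_sh * L_sh * dsh
        for label, mat in (("knee", knee), ("ankle", ankle), ("foot_com", foot_com), ("shank_com", shank_com)):
            for j, ax in enumerate("xyz"):
                out[f"{side}_{label}_{ax}"] = mat[:, j]
        out[f"{side}_shank_rx"] = ad
        out[f"{side}_shank_ry"] = np.zeros_like(ad)
        out[f"{side}_shank_rz"] = sh_sag
        out[f"{side}_foot_rx"] = ad
        out[f"{side}_foot_ry"] = np.zeros_like(ad)
        out[f"{side}_foot_rz"] = ft_sag
    return out


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Cycles grouped by subject, with the generating subject models."""

    config: GeneratorConfig
    subjects: list[SubjectModel]
    trials: dict[str, list[GaitTrial]] = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return sum(len(v) for v in self.trials.values())

    def subject(self, subject_id: str) -> SubjectModel:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the full cohort: n_subjects x cycles_per_subject cycles,
    reproducible from ``config.seed``."""
    subjects = [generate_subject(config, i) for i in range(config.n_subjects)]
    trials: dict[str, list[GaitTrial]] = {}
    for i, subj in enumerate(subjects):
        trials[subj.subject_id] = [
            generate_cycle(subj, config, c, subject_index=i) for c in range(config.cycles_per_subject)
        ]
    return SyntheticDataset(config=config, subjects=subjects, trials=trials)


def normalized_cycles(dataset: SyntheticDataset, side: str = "right") -> dict[str, list[NormalizedCycle]]:
    """Time-normalize every generated cycle to the 101-point base."""
    out: dict[str, list[NormalizedCycle]] = {}
    for sid, trials in dataset.trials.items():
        cycles = []
        for trial in trials:
            hs = [e.time for e in trial.events_of(side, "heel_strike")]
            cycles.append(time_normalize(trial, hs[0], hs[1], side=side, subject_id=sid))
        out[sid] = cycles
    return out
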