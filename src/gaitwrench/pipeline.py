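"""End-to-end inertial-capture workflow: kinematics in, knee loading out.

Per gait cycle: time-normalize -> PPCA inference of per-foot GRFM ->
zero-moment-point COP with polynomial endpoint repair -> bottom-up external
knee moments -> (optionally) a clearly-labelled frontal-plane proxy for the
medial/lateral contact-force split.

The contact-force stage is a static frontal-plane balance about the two
condylar contact points, NOT a musculoskeletal contact simulation: it
ignores muscle co-contraction and so underestimates absolute compartment
loads.  Every output file it produces is suffixed ``_proxy``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gaitwrench.core import GRAVITY, GaitTrial, NormalizedCycle, SubjectModel, scale_subject, time_normalize
from gaitwrench.cop import CopTrajectory, cop_from_grfm, repair_cop
from gaitwrench.dynamics import GroundWrench, KneeMoments, knee_moments
from gaitwrench.metrics import extract_features
from gaitwrench.ppca import N_POINTS, GrfmPrediction, PPCAModel, infer_grfm

logger = logging.getLogger("gaitwrench.pipeline")


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run."""

    model_path: str | None = None
    event_threshold: float = 20.0       # N
    fz_threshold: float = 20.0          # N, ZMP validity cutoff
    calcaneus_origin: tuple[float, float] | None = None  # m; None = from ankle channel
    proxy_kcf: bool = True
    intercondylar_distance: float = 0.045  # m
    side: str = "right"
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_threshold <= 0 or self.fz_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0.02 < self.intercondylar_distance < 0.10:
            raise ValueError("intercondylar_distance outside plausible (0.02, 0.10) m")


@dataclass
class KcfProxy:
    """Frontal-plane compartmental force split (BW), with clamp flags."""

    medial: np.ndarray
    lateral: np.ndarray
    total: np.ndarray
    clamp_flag: np.ndarray

    def __post_init__(self) -> None:
        free = ~self.clamp_flag
        if np.any(self.medial[free] + self.lateral[free] - self.total[free] > 1e-9):
            raise ValueError("medial + lateral must equal total where unclamped")


def proxy_kcf(moments: KneeMoments, axial_force: np.ndarray, d: float = 0.045) -> KcfProxy:
    """Medial/lateral split of an axial knee load from the adduction moment.

    Static frontal-plane balance about two condylar contact points a
    distance ``d`` apart: ``medial - lateral = 2 KAM / (d g)`` (waveforms
    in BW, KAM in Nm/kg) and ``medial + lateral = axial``.  A negative
    compartment force is clamped to zero with the other side taking the
    whole axial load, flagged per sample.  This is a proxy for — not a
    reimplementation of — musculoskeletal contact modelling.
    """
    if d <= 0:
        raise ValueError("intercondylar distance must be > 0")
    axial = np.asarray(axial_force, dtype=float)
    if axial.shape != moments.kam.shape:
        raise ValueError("axial force and moments must be aligned")
    delta = 2.0 * moments.kam / (d * GRAVITY)  # BW
    medial = axial / 2.0 + delta / 2.0
    lateral = axial / 2.0 - delta / 2.0
    clamp = (medial < 0) | (lateral < 0)
    med = np.where(lateral < 0, axial, np.where(medial < 0, 0.0, medial))
    lat = np.where(medial < 0, axial, np.where(lateral < 0, 0.0, lateral))
    return KcfProxy(medial=med, lateral=lat, total=axial.copy(), clamp_flag=clamp)


@dataclass
class CycleResult:
    """All derived quantities of one gait cycle."""

    cycle: NormalizedCycle
    prediction: GrfmPrediction
    cop: CopTrajectory
    cop_cycle_grid: np.ndarray  # (101, 2), NaN in swing
    moments: KneeMoments
    kcf: KcfProxy | None


@dataclass
class PipelineResult:
    cycles: list[CycleResult] = field(default_factory=list)
    report: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _stance_grid_cop(raw_cop: np.ndarray, valid: np.ndarray, percent: np.ndarray, sf: float) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate cycle-grid raw COP onto the 101-point stance grid."""
    stance_pct_cycle = percent / (sf * 100.0) * 100.0
    mask = (percent <= sf * 100.0 + 1e-9) & valid
    grid = np.linspace(0.0, 100.0, N_POINTS)
    out = np.full((N_POINTS, 2), np.nan)
    ok = np.zeros(N_POINTS, dtype=bool)
    if mask.sum() >= 2:
        lo, hi = stance_pct_cycle[mask].min(), stance_pct_cycle[mask].max()
        inside = (grid >= lo) & (grid <= hi)
        for j in range(2):
            out[inside, j] = np.interp(grid[inside], stance_pct_cycle[mask], raw_cop[mask, j])
        ok = inside
    return out, ok


def _cycle_grid_cop(cop: CopTrajectory, percent: np.ndarray, sf: float) -> np.ndarray:
    """Map a repaired stance-grid COP back onto the cycle grid (NaN in swing)."""
    out = np.full((len(percent), 2), np.nan)
    stance = percent <= sf * 100.0 + 1e-9
    sp = percent[stance] / (sf * 100.0) * 100.0
    out[stance, 0] = np.interp(sp, cop.stance_percent, cop.x_ap)
    out[stance, 1] = np.interp(sp, cop.stance_percent, cop.y_ml)
    return out


def process_cycle(
    cycle: NormalizedCycle,
    model: PPCAModel,
    subject: SubjectModel,
    config: PipelineConfig,
) -> CycleResult:
    """Run inference, COP estimation and inverse dynamics for one cycle."""
    side = config.side
    s = side[0]
    pred = infer_grfm(model, cycle)
    percent = pred.percent
    sf = cycle.stance_fraction

    force_bw = np.stack([pred.channels[f"grf_{s}_{ax}"] for ax in "xyz"], axis=1)
    moment_nmkg = np.stack([pred.channels[f"grm_{s}_{ax}"] for ax in "xyz"], axis=1)
    wrench = GroundWrench(force=force_bw, moment=moment_nmkg, reference_point="lab_origin",
                          side=side, units="normalized")
    raw_cop, valid = cop_from_grfm(wrench, fz_threshold=config.fz_threshold, mass=subject.mass)
    stance_cop, _ = _stance_grid_cop(raw_cop, valid, percent, sf)

    if config.calcaneus_origin is not None:
        calc = config.calcaneus_origin
    else:  # heel position proxy: ankle channel at heel strike, slightly posterior
        calc = (float(cycle.channel(f"{s}_ankle_x")[0]) - 0.05, float(cycle.channel(f"{s}_ankle_z")[0]))
    cop_traj = repair_cop(stance_cop, calc)
    cop_cycle = _cycle_grid_cop(cop_traj, percent, sf)

    cop3 = np.stack([cop_cycle[:, 0], np.zeros(len(percent)), cop_cycle[:, 1]], axis=1)
    at_cop = GroundWrench(force=force_bw, moment=np.zeros_like(force_bw), reference_point="cop",
                          side=side, units="normalized", point=np.where(np.isfinite(cop3), cop3, 0.0))
    km = knee_moments(cycle, at_cop, cop_cycle, subject, side=side)

    kcf = proxy_kcf(km, force_bw[:, 1], config.intercondylar_distance) if config.proxy_kcf else None
    return CycleResult(cycle=cycle, prediction=pred, cop=cop_traj, cop_cycle_grid=cop_cycle,
                       moments=km, kcf=kcf)


def run_pipeline(
    trial: GaitTrial,
    model: PPCAModel,
    config: PipelineConfig,
    subject: SubjectModel | None = None,
) -> PipelineResult:
    """Run the full workflow on a trial of kinematics + events.

    Cycles are delimited by consecutive ipsilateral heel strikes in
    ``trial.events``; each is normalized, GRFM inferred, COP estimated and
    knee moments computed.  Outputs are written to ``config.output_dir``
    when set.  Deterministic given inputs and config.
    """
    side = config.side
    hs = [e.time for e in trial.events_of(side, "heel_strike")]
    if len(hs) < 2:
        raise ValueError(f"no complete {side} gait cycle: need two {side} heel_strike events")
    if subject is None:
        if not np.isfinite(trial.body_weight):
            raise ValueError("subject model or trial body_weight required")
        subject = scale_subject(trial.body_weight / GRAVITY, 1.70)

    results = []
    for i, (a, b) in enumerate(zip(hs, hs[1:])):
        cycle = time_normalize(trial, a, b, side=side)
        res = process_cycle(cycle, model, subject, config)
        results.append(res)
        logger.info("cycle %d: [%0.3f, %0.3f] s processed", i, a, b)

    rows = []
    for i, res in enumerate(results):
        s = side[0]
        feats = extract_features(res.prediction.channels[f"grf_{s}_y"],
                                 res.cycle.stance_fraction, res.cycle.cycle_duration)
        rows.append({
            "cycle": i,
            "stance_fraction": res.cycle.stance_fraction,
            "grf_peak1_bw": feats.peak1,
            "grf_peak2_bw": feats.peak2,
            "grf_impulse_bws": feats.impulse,
            "kam_peak_nmkg": float(np.nanmax(res.moments.kam)),
            "kfm_peak_nmkg": float(np.nanmax(res.moments.kfm)),
        })
    report = pd.DataFrame(rows)

    out = PipelineResult(cycles=results, report=report)
    if config.output_dir:
        _write_outputs(out, model, config, side)
    return out


def _provenance(model: PPCAModel, config: PipelineConfig) -> dict:
    import gaitwrench

    # hash only the scientific knobs, not where the outputs happen to go
    cfg_fields = {k: str(v) for k, v in vars(config).items() if k not in ("output_dir", "model_path")}
    cfg_hash = hashlib.sha256(json.dumps(cfg_fields, sort_keys=True).encode()).hexdigest()[:12]
    model_hash = hashlib.sha256(model.mu.tobytes() + model.W.tobytes()).hexdigest()[:12]
    return {"package_version": gaitwrench.__version__, "config_hash": cfg_hash, "model_hash": model_hash}


def _write_outputs(result: PipelineResult, model: PPCAModel, config: PipelineConfig, side: str) -> None:
    from gaitwrench.io import write_sto

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = _provenance(model, config)
    s = side[0]
    for i, res in enumerate(result.cycles):
        pct = res.prediction.percent
        grfm = pd.DataFrame({"time": pct, **{ch: v for ch, v in res.prediction.channels.items()}})
        write_sto(outdir / f"grfm_cycle{i:02d}.sto", grfm, name="grfm_estimate", header_meta=meta)
        cop = pd.DataFrame({
            "time": res.cop.stance_percent,
            "cop_x_ap": res.cop.x_ap,
            "cop_z_ml": res.cop.y_ml,
            "fitted": (res.cop.source_flag == "polynomial_fitted").astype(float),
        })
        write_sto(outdir / f"cop_cycle{i:02d}.sto", cop, name="cop_zmp", header_meta=meta)
        km = pd.DataFrame({"time": pct, "kfm": res.moments.kfm, "kam": res.moments.kam, "krm": res.moments.krm})
        write_sto(outdir / f"knee_moments_cycle{i:02d}.sto", km, name="knee_moments", header_meta=meta)
        if res.kcf is not None:
            kcf = pd.DataFrame({
                "time": pct,
                "medial_bw": res.kcf.medial,
                "lateral_bw": res.kcf.lateral,
                "total_bw": res.kcf.total,
                "clamped": res.kcf.clamp_flag.astype(float),
            })
            write_sto(outdir / f"kcf_cycle{i:02d}_proxy.sto", kcf, name="kcf_frontal_plane_proxy",
                      header_meta=meta)
    result.report.to_csv(outdir / "report.csv", index=False, float_format="%.10g")
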