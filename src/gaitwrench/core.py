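"""Canonical gait data model, event handling, time normalization and subject scaling.

All trials live in a right-handed lab frame: X anterior, Y vertical (up),
Z to the subject's right.  Ground reaction forces are stored in body-weight
units (BW) and ground reaction moments in Nm/kg about the lab origin, so
that waveforms from subjects of different size are directly comparable.
Gait cycles are resampled to the conventional 101 points (0..100% of the
cycle, heel strike to ipsilateral heel strike).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRAVITY = 9.81
"""Gravitational acceleration in m/s^2, used for all BW conversions."""

SIDES = ("left", "right")
EVENT_KINDS = ("heel_strike", "toe_off")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentParams:
    """Anthropometric parameters of one body segment.

    Fractions follow the body-segment-parameter table convention: segment
    mass as a fraction of body mass, segment length as a fraction of
    stature, centre of mass measured from the proximal end as a fraction
    of segment length, and radius of gyration about the COM as a fraction
    of segment length.
    """

    name: str
    mass_fraction: float
    length: float  # m, already scaled to the subject
    com_fraction: float
    gyration_fraction: float

    @property
    def mass(self) -> float:  # set by SubjectModel scaling
        raise AttributeError("use SubjectModel.segment_mass(name)")


@dataclass
class SubjectModel:
    """A subject with scaled segment parameters.

    Parameters
    ----------
    subject_id : str
    mass : float
        Body mass in kg, > 0.
    height : float
        Stature in m, > 0.
    segments : list of SegmentParams
        Full-body segment set; mass fractions must sum to 1.
    """

    subject_id: str
    mass: float
    height: float
    segments: list[SegmentParams] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValueError(f"mass must be > 0, got {self.mass}")
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")
        for seg in self.segments:
            if not 0 < seg.mass_fraction < 1:
                raise ValueError(f"segment {seg.name}: mass_fraction {seg.mass_fraction} not in (0,1)")
            if not 0 < seg.com_fraction < 1:
                raise ValueError(f"segment {seg.name}: com_fraction not in (0,1)")
            if not 0 < seg.gyration_fraction < 1:
                raise ValueError(f"segment {seg.name}: gyration_fraction not in (0,1)")
        if self.segments:
            total = sum(s.mass_fraction for s in self.segments)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"full-body mass fractions sum to {total}, expected 1")

    @property
    def body_weight(self) -> float:
        """Body weight in N (mass * g)."""
        return self.mass * GRAVITY

    def segment(self, name: str) -> SegmentParams:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(f"no segment named {name!r}")

    def segment_mass(self, name: str) -> float:
        return self.segment(name).mass_fraction * self.mass

    def segment_inertia(self, name: str) -> float:
        """Moment of inertia about the segment COM (kg m^2), isotropic model."""
        seg = self.segment(name)
        return self.segment_mass(name) * (seg.gyration_fraction * seg.length) ** 2


@dataclass(frozen=True)
class GaitEvent:
    kind: str  # heel_strike | toe_off
    side: str  # left | right
    time: float  # s

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class GaitTrial:
    """A synchronized gait recording.

    Attributes
    ----------
    time : (n,) array, s, strictly increasing with uniform step.
    kinematics : DataFrame (n x DOF), joint angles in radians plus any
        segment-position channels (m); column names identify channels.
    grf : dict side -> (n, 3) array in BW (X anterior, Y vertical, Z right).
    grm : dict side -> (n, 3) array in Nm/kg about the lab origin.
    cop : dict side -> (n, 2) array in m, columns (x_ap, z_ml); optional.
    com_accel : (n, 3) array in m/s^2, optional.
    events : list of GaitEvent.
    body_weight : float, N.
    """

    time: np.ndarray
    kinematics: pd.DataFrame
    grf: dict[str, np.ndarray] = field(default_factory=dict)
    grm: dict[str, np.ndarray] = field(default_factory=dict)
    cop: dict[str, np.ndarray] | None = None
    com_accel: np.ndarray | None = None
    events: list[GaitEvent] = field(default_factory=list)
    body_weight: float = np.nan

    @property
    def mass(self) -> float:
        return self.body_weight / GRAVITY

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def events_of(self, side: str, kind: str | None = None) -> list[GaitEvent]:
        evs = sorted((e for e in self.events if e.side == side), key=lambda e: e.time)
        if kind is not None:
            evs = [e for e in evs if e.kind == kind]
        return evs

    def stance_intervals(self, side: str) -> list[tuple[float, float]]:
        """Foot-on-ground intervals, closed, clipped to the trial time range.

        A leading toe_off opens an interval at the trial start; a trailing
        heel_strike closes one at the trial end (cycles may begin or end
        mid-stance of the contralateral foot).
        """
        evs = self.events_of(side)
        intervals: list[tuple[float, float]] = []
        t0, t1 = float(self.time[0]), float(self.time[-1])
        open_at: float | None = None
        for i, ev in enumerate(evs):
            if ev.kind == "heel_strike":
                open_at = ev.time
            else:  # toe_off
                start = open_at if open_at is not None else t0
                intervals.append((start, ev.time))
                open_at = None
        if open_at is not None:
            intervals.append((open_at, t1))
        return intervals

    def validate(self, atol: float = 1e-9) -> None:
        """Check the trial invariants; raise ValueError on violation."""
        n = len(self.time)
        steps = np.diff(self.time)
        if not np.all(steps > 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("time step must be uniform")
        if len(self.kinematics) != n:
            raise ValueError("kinematics length mismatch")
        for name, mat in list(self.grf.items()) + list(self.grm.items()):
            if mat.shape[0] != n:
                raise ValueError(f"{name} channel length mismatch")
        # events alternate per side
        for side in SIDES:
            kinds = [e.kind for e in self.events_of(side)]
            for a, b in zip(kinds, kinds[1:]):
                if a == b:
                    raise ValueError(f"{side} events do not alternate")
        # forces exactly zero outside stance
        for side, f in self.grf.items():
            in_stance = np.zeros(n, dtype=bool)
            for a, b in self.stance_intervals(side):
                in_stance |= (self.time >= a - atol) & (self.time <= b + atol)
            for name, mat in ((f"grf[{side}]", f), (f"grm[{side}]", self.grm.get(side))):
                if mat is None:
                    continue
                if np.any(np.abs(mat[~in_stance]) > atol):
                    raise ValueError(f"{name} nonzero outside stance")


@dataclass
class NormalizedCycle:
    """One gait cycle resampled to 101 points (0..100% of the cycle)."""

    percent: np.ndarray  # 101 values 0..100
    channels: dict[str, np.ndarray]  # each 101 samples
    stance_fraction: float
    cycle_duration: float  # s
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.percent) != 101 or self.percent[0] != 0 or self.percent[-1] != 100:
            raise ValueError("percent must span 0..100 with 101 samples")
        for name, ch in self.channels.items():
            if len(ch) != 101:
                raise ValueError(f"channel {name!r} has {len(ch)} samples, expected 101")
        if not 0 < self.stance_fraction < 1:
            raise ValueError(f"stance_fraction {self.stance_fraction} not in (0,1)")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"cycle has no channel {name!r}") from None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def detect_events(
    vertical_grf: np.ndarray,
    time: np.ndarray,
    threshold: float = 20.0,
    side: str = "right",
) -> list[GaitEvent]:
    """Detect heel strikes and toe offs by threshold crossing of vertical GRF.

    A heel strike is recorded at each upward crossing of ``threshold`` and a
    toe off at each downward crossing; the crossing time is found by linear
    interpolation between the bracketing samples.

    Parameters
    ----------
    vertical_grf : (n,) array in N (or any unit consistent with threshold).
    time : (n,) array, s, uniformly sampled.
    threshold : float, > 0.  Default 20 N, a common force-plate convention.

    Raises
    ------
    ValueError
        If the signal never rises above the threshold ("no stance detected")
        or never falls below it ("no swing detected").
    """
    f = np.asarray(vertical_grf, dtype=float)
    t = np.asarray(time, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    above = f >= threshold
    if not above.any():
        raise ValueError("no stance detected: signal never crosses threshold")
    if above.all():
        raise ValueError("no swing detected: signal always above threshold")

    events: list[GaitEvent] = []
    idx = np.flatnonzero(above[1:] != above[:-1])
    for i in idx:
        f0, f1 = f[i], f[i + 1]
        tc = t[i] + (threshold - f0) / (f1 - f0) * (t[i + 1] - t[i])
        kind = "heel_strike" if f1 > f0 else "toe_off"
        events.append(GaitEvent(kind=kind, side=side, time=float(tc)))
    return events


def _trial_channels(trial: GaitTrial) -> dict[str, np.ndarray]:
    """Flatten all trial time series into named 1-D channels."""
    channels: dict[str, np.ndarray] = {
        name: trial.kinematics[name].to_numpy(dtype=float) for name in trial.kinematics.columns
    }
    axes3 = "xyz"
    for side, mat in trial.grf.items():
        for j, ax in enumerate(axes3):
            channels[f"grf_{side[0]}_{ax}"] = mat[:, j]
    for side, mat in trial.grm.items():
        for j, ax in enumerate(axes3):
            channels[f"grm_{side[0]}_{ax}"] = mat[:, j]
    if trial.cop:
        for side, mat in trial.cop.items():
            channels[f"cop_{side[0]}_x"] = mat[:, 0]
            channels[f"cop_{side[0]}_ml"] = mat[:, 1]
    if trial.com_accel is not None:
        for j, ax in enumerate(axes3):
            channels[f"com_accel_{ax}"] = trial.com_accel[:, j]
    return channels


def time_normalize(
    trial: GaitTrial,
    hs_start: float,
    hs_end: float,
    side: str = "right",
    kind: str = "linear",
    subject_id: str | None = None,
) -> NormalizedCycle:
    """Resample one gait cycle onto the 101-point normalized time base.

    The cycle spans two consecutive ipsilateral heel strikes
    ``[hs_start, hs_end]``.  Every channel of the trial (kinematics, GRF,
    GRM, COP, COM acceleration) is interpolated onto 101 equally spaced
    points; endpoint values are preserved.  The stance fraction is the
    position of the ipsilateral toe off within the cycle.

    ``kind`` selects the interpolant: "linear" (default) or "cubic".
    """
    t = trial.time
    if hs_start < t[0] - 1e-9 or hs_end > t[-1] + 1e-9 or hs_end <= hs_start:
        raise ValueError("cycle bounds outside trial time range")
    inside = (t >= hs_start) & (t <= hs_end)
    if inside.sum() < 2:
        raise ValueError("fewer than 2 samples inside cycle")

    toe_offs = [e.time for e in trial.events_of(side, "toe_off") if hs_start < e.time < hs_end]
    if not toe_offs:
        raise ValueError(f"no {side} toe_off inside cycle [{hs_start}, {hs_end}]")
    duration = hs_end - hs_start
    stance_fraction = (toe_offs[0] - hs_start) / duration

    t_new = hs_start + np.linspace(0.0, 1.0, 101) * duration
    channels: dict[str, np.ndarray] = {}
    if kind == "linear":
        for name, ch in _trial_channels(trial).items():
            channels[name] = np.interp(t_new, t, ch)
    elif kind == "cubic":
        from scipy.interpolate import interp1d

        for name, ch in _trial_channels(trial).items():
            channels[name] = interp1d(t, ch, kind="cubic")(t_new)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")

    return NormalizedCycle(
        percent=np.linspace(0.0, 100.0, 101),
        channels=channels,
        stance_fraction=float(stance_fraction),
        cycle_duration=float(duration),
        subject_id=subject_id,
    )


def load_segment_table(table_id: str = "winter") -> pd.DataFrame:
    """Load a bundled body-segment-parameter table.

    Currently the classic Winter (2009) full-body fractions table is
    bundled under the id ``"winter"``.
    """
    if table_id != "winter":
        raise ValueError(f"unknown anthropometric table {table_id!r}")
    with importlib.resources.files("gaitwrench.data").joinpath("winter_segments.csv").open() as fh:
        return pd.read_csv(fh)


def scale_subject(
    mass: float,
    height: float,
    table_id: str = "winter",
    subject_id: str = "subject",
) -> SubjectModel:
    """Build a subject model by scaling a body-segment-parameter table.

    Segment masses are ``mass_fraction * mass`` and segment lengths
    ``length_fraction * height``; centre-of-mass and radius-of-gyration
    fractions are carried through unchanged.
    """
    if mass <= 0 or height <= 0:
        raise ValueError("mass and height must be > 0")
    table = load_segment_table(table_id)
    segments = []
    for _, row in table.iterrows():
        name = row["segment"] if row["side"] == "center" else f"{row['segment']}_{row['side'][0]}"
        segments.append(
            SegmentParams(
                name=name,
                mass_fraction=float(row["mass_fraction"]),
                length=float(row["length_fraction"]) * height,
                com_fraction=float(row["com_fraction"]),
                gyration_fraction=float(row["gyration_fraction"]),
            )
        )
    return SubjectModel(subject_id=subject_id, mass=mass, height=height, segments=segments)
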