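"""Link-segment Newton-Euler computations.

Two uses: the whole-body external wrench implied by centre-of-mass
acceleration (a consistency feature for the force estimator), and
bottom-up external knee moments (flexion, adduction, rotation) from ground
reaction force, centre of pressure and distal-limb kinematics.

The knee chain is deliberately short — foot and shank only — because the
external knee moment depends only on the distal free body.  Segment
inertia uses an isotropic radius-of-gyration model; segment angular
velocity is the time derivative of the segment orientation-angle channels
(exact for planar motion, first-order for small out-of-plane angles).
Accelerations come from 5-point central finite differences with one-sided
stencils at the endpoints.

External-moment sign convention: the moment of the ground wrench about the
knee joint centre, resolved in the shank anatomical frame.  Flexion is
positive about the frame's medio-lateral (+Z') axis; adduction positive
drives the knee into varus (about +X' on the right side, -X' on the left);
internal rotation positive (about -Y' on the right, +Y' on the left).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gaitwrench.core import GRAVITY, NormalizedCycle, SubjectModel

G_VEC = np.array([0.0, -GRAVITY, 0.0])


@dataclass
class GroundWrench:
    """A ground reaction force/moment pair with an explicit reference point.

    ``units`` is "SI" (N, Nm) or "normalized" (BW, Nm/kg).  ``point`` holds
    the reference-point coordinates: a (3,) vector for a fixed point such
    as the lab origin, or an (n, 3) array for a moving point such as the COP.
    """

    force: np.ndarray   # (n, 3)
    moment: np.ndarray  # (n, 3)
    reference_point: str = "lab_origin"  # lab_origin | cop
    side: str = "total"  # left | right | total
    units: str = "SI"
    point: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        self.moment = np.atleast_2d(np.asarray(self.moment, dtype=float))
        if self.force.shape != self.moment.shape or self.force.shape[1] != 3:
            raise ValueError("force and moment must both be (n, 3)")
        if self.point is None:
            self.point = np.zeros(3)

    @property
    def n(self) -> int:
        return self.force.shape[0]

    def to_si(self, mass: float) -> "GroundWrench":
        """Convert BW / Nm-per-kg to N / Nm using the subject mass."""
        if self.units == "SI":
            return self
        return GroundWrench(
            force=self.force * mass * GRAVITY,
            moment=self.moment * mass,
            reference_point=self.reference_point,
            side=self.side,
            units="SI",
            point=self.point,
        )


def transport_wrench(wrench: GroundWrench, new_point: np.ndarray, label: str = "custom") -> GroundWrench:
    """Re-express a wrench about a new reference point.

    The force is unchanged; the moment transforms as
    ``M' = M + (p_old - p_new) x F``.  ``new_point`` may be a (3,) fixed
    point or an (n, 3) per-sample path.
    """
    new_point = np.asarray(new_point, dtype=float)
    old = np.broadcast_to(np.atleast_2d(wrench.point), wrench.force.shape)
    new = np.broadcast_to(np.atleast_2d(new_point), wrench.force.shape)
    moment = wrench.moment + np.cross(old - new, wrench.force)
    return GroundWrench(
        force=wrench.force.copy(),
        moment=moment,
        reference_point=label,
        side=wrench.side,
        units=wrench.units,
        point=new_point,
    )


@dataclass
class KneeMoments:
    """External knee moments over the 101-point gait cycle, Nm/kg."""

    kfm: np.ndarray  # flexion +
    kam: np.ndarray  # adduction +
    krm: np.ndarray  # internal rotation +
    percent: np.ndarray

    def __post_init__(self) -> None:
        for name in ("kfm", "kam", "krm"):
            v = np.asarray(getattr(self, name), dtype=float)
            if len(v) != len(self.percent):
                raise ValueError(f"{name} length mismatch")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, v)


# ---------------------------------------------------------------------------
# finite differences (5-point interior stencil, one-sided endpoints)
# ---------------------------------------------------------------------------

def first_derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """dy/dt, 4th-order central in the interior, 2nd-order one-sided edges."""
    y = np.asarray(y, dtype=float)
    d = np.empty_like(y)
    d[2:-2] = (y[:-4] - 8 * y[1:-3] + 8 * y[3:-1] - y[4:]) / (12 * dt)
    d[0] = (-3 * y[0] + 4 * y[1] - y[2]) / (2 * dt)
    d[1] = (-3 * y[1] + 4 * y[2] - y[3]) / (2 * dt)
    d[-1] = (3 * y[-1] - 4 * y[-2] + y[-3]) / (2 * dt)
    d[-2] = (3 * y[-2] - 4 * y[-3] + y[-4]) / (2 * dt)
    return d


def second_derivative(y: np.ndarray, dt: float) -> np.ndarray:
    """d2y/dt2, 4th-order central in the interior, 2nd-order one-sided edges."""
    y = np.asarray(y, dtype=float)
    d = np.empty_like(y)
    d[2:-2] = (-y[:-4] + 16 * y[1:-3] - 30 * y[2:-2] + 16 * y[3:-1] - y[4:]) / (12 * dt**2)
    d[0] = (2 * y[0] - 5 * y[1] + 4 * y[2] - y[3]) / dt**2
    d[1] = (2 * y[1] - 5 * y[2] + 4 * y[3] - y[4]) / dt**2
    d[-1] = (2 * y[-1] - 5 * y[-2] + 4 * y[-3] - y[-4]) / dt**2
    d[-2] = (2 * y[-2] - 5 * y[-3] + 4 * y[-4] - y[-5]) / dt**2
    return d


def _column_derivatives(mat: np.ndarray, dt: float, order: int) -> np.ndarray:
    fn = first_derivative if order == 1 else second_derivative
    return np.stack([fn(mat[:, j], dt) for j in range(mat.shape[1])], axis=1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def whole_body_wrench(com_accel: np.ndarray, subject: SubjectModel) -> GroundWrench:
    """Total external ground force implied by COM acceleration.

    ``F = m (a_com - g_vec)``, returned in BW.  The moment channel is zero
    (angular momentum about the lab origin is not tracked at whole-body
    level).
    """
    a = np.atleast_2d(np.asarray(com_accel, dtype=float))
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite COM acceleration")
    force_bw = (a - G_VEC) / GRAVITY
    return GroundWrench(
        force=force_bw,
        moment=np.zeros_like(force_bw),
        reference_point="lab_origin",
        side="total",
        units="normalized",
    )


def _rotation_zx(rz: float, rx: float, ry: float = 0.0) -> np.ndarray:
    """Segment orientation matrix R = Rz(rz) @ Rx(rx) @ Ry(ry)."""
    cz, sz = np.cos(rz), np.sin(rz)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return Rz @ Rx @ Ry


def _cycle_vec(cycle: NormalizedCycle, prefix: str, axes: str = "xyz") -> np.ndarray:
    return np.stack([cycle.channel(f"{prefix}_{ax}") for ax in axes], axis=1)


def knee_moments(
    cycle: NormalizedCycle,
    grf: GroundWrench,
    cop: np.ndarray,
    subject: SubjectModel,
    side: str = "right",
    foot_mass: float | None = None,
    shank_mass: float | None = None,
) -> KneeMoments:
    """Bottom-up external knee moments from GRF + COP + distal kinematics.

    Parameters
    ----------
    cycle : NormalizedCycle
        Must provide, for the chosen side prefix (``r``/``l``), position
        channels ``{s}_knee_*``, ``{s}_ankle_*``, ``{s}_foot_com_*``,
        ``{s}_shank_com_*`` (m) and orientation channels ``{s}_foot_r[xyz]``,
        ``{s}_shank_r[xyz]`` (rad).
    grf : GroundWrench
        Ground wrench expressed at the COP (``reference_point == "cop"``);
        its moment channel is the free moment.  SI or normalized units.
    cop : (101, 3) or (101, 2) array
        COP path in lab coordinates, m.  A two-column input is taken as
        (x_ap, z_ml) on the ground plane.  May be NaN during swing; NaN
        during stance (nonzero GRF) is an error.
    foot_mass, shank_mass : float, optional
        Override the table-scaled segment masses (0 gives the quasi-static
        massless chain used by analytic checks).

    Returns
    -------
    KneeMoments with flexion/adduction/rotation components in Nm/kg.
    """
    if grf.reference_point != "cop":
        raise ValueError("grf must be expressed at the COP")
    s = side[0]
    n = len(cycle.percent)
    dt = cycle.cycle_duration / (n - 1)
    wr = grf.to_si(subject.mass)
    F = wr.force
    M_free = wr.moment
    if F.shape[0] != n:
        raise ValueError("grf length does not match cycle")

    cop = np.asarray(cop, dtype=float)
    if cop.shape[1] == 2:
        cop = np.stack([cop[:, 0], np.zeros(len(cop)), cop[:, 1]], axis=1)
    loaded = np.linalg.norm(F, axis=1) > 1e-12
    if np.any(loaded & ~np.all(np.isfinite(cop), axis=1)):
        raise ValueError("COP absent during stance")
    cop = np.where(np.all(np.isfinite(cop), axis=1)[:, None], cop, 0.0)

    knee = _cycle_vec(cycle, f"{s}_knee")
    ankle = _cycle_vec(cycle, f"{s}_ankle")
    com_f = _cycle_vec(cycle, f"{s}_foot_com")
    com_s = _cycle_vec(cycle, f"{s}_shank_com")
    ang_f = np.stack([cycle.channel(f"{s}_foot_r{ax}") for ax in "xyz"], axis=1)
    ang_s = np.stack([cycle.channel(f"{s}_shank_r{ax}") for ax in "xyz"], axis=1)

    m_f = subject.segment_mass(f"foot_{s}") if foot_mass is None else foot_mass
    m_s = subject.segment_mass(f"shank_{s}") if shank_mass is None else shank_mass
    I_f = m_f * (subject.segment(f"foot_{s}").gyration_fraction * subject.segment(f"foot_{s}").length) ** 2
    I_s = m_s * (subject.segment(f"shank_{s}").gyration_fraction * subject.segment(f"shank_{s}").length) ** 2

    a_f = _column_derivatives(com_f, dt, 2)
    a_s = _column_derivatives(com_s, dt, 2)
    w_f = _column_derivatives(ang_f, dt, 1)
    al_f = _column_derivatives(ang_f, dt, 2)
    w_s = _column_derivatives(ang_s, dt, 1)
    al_s = _column_derivatives(ang_s, dt, 2)

    # foot free body: reaction at the ankle
    R_a = m_f * (a_f - G_VEC) - F
    M_a = (
        I_f * al_f
        + np.cross(w_f, I_f * w_f)
        - np.cross(cop - com_f, F)
        - M_free
        - np.cross(ankle - com_f, R_a)
    )
    # shank free body: reaction at the knee
    R_k = m_s * (a_s - G_VEC) + R_a
    M_k = (
        I_s * al_s
        + np.cross(w_s, I_s * w_s)
        + M_a
        + np.cross(ankle - com_s, R_a)
        - np.cross(knee - com_s, R_k)
    )
    M_ext = -M_k  # external convention: ground wrench moment about the knee

    # resolve in the shank anatomical frame
    M_local = np.empty_like(M_ext)
    for i in range(n):
        R = _rotation_zx(ang_s[i, 2], ang_s[i, 0], ang_s[i, 1])
        M_local[i] = R.T @ M_ext[i]

    sign = 1.0 if s == "r" else -1.0
    return KneeMoments(
        kfm=M_local[:, 2] / subject.mass,
        kam=sign * M_local[:, 0] / subject.mass,
        krm=-sign * M_local[:, 1] / subject.mass,
        percent=cycle.percent.copy(),
    )
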