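"""Centre-of-pressure estimation by the zero-moment-point method, with
polynomial repair of the near-heel-strike / near-toe-off regions.

The ZMP identity: with the ground wrench (F, M) expressed about the lab
origin and the COP constrained to the ground plane y = 0, the point
r = (x, 0, z) satisfying M = r x F (no horizontal couple) is

    x_ap = M_z / F_y        z_ml = -M_x / F_y

(lab frame X anterior, Y up, Z right).  Worked sign example: F = (0, 700, 0) N
with M = (-35, 0, 70) Nm gives COP (x_ap, z_ml) = (0.10, 0.05) m.

Near heel strike and toe off the vertical force approaches zero and the
ratio blows up, so the first and last 15% of stance are replaced by a
10th-order polynomial fitted to the trustworthy 15-85% core and anchored
at the calcaneus origin at 0% and 100% of stance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import chebyshev

from gaitwrench.core import GRAVITY
from gaitwrench.dynamics import GroundWrench

POLY_DEGREE = 10
CORE_LO, CORE_HI = 15.0, 85.0  # % of stance kept raw
BLEND_WIDTH = 2.0              # % of stance used to blend fit into raw
FOOTPRINT_BOUND = 0.40         # m, |COP - calcaneus| sanity bound


@dataclass
class CopTrajectory:
    """Stance-normalized COP path with raw/repaired provenance flags."""

    stance_percent: np.ndarray        # 0..100 grid
    x_ap: np.ndarray                  # m, anterior-posterior
    y_ml: np.ndarray                  # m, medio-lateral (lab Z)
    source_flag: np.ndarray           # "raw_zmp" | "polynomial_fitted"
    calcaneus_origin: tuple[float, float]

    def __post_init__(self) -> None:
        n = len(self.stance_percent)
        if not (len(self.x_ap) == len(self.y_ml) == len(self.source_flag) == n):
            raise ValueError("COP channel length mismatch")

    def as_points(self, ground_y: float = 0.0) -> np.ndarray:
        """(n, 3) lab-frame points on the ground plane."""
        return np.stack([self.x_ap, np.full_like(self.x_ap, ground_y), self.y_ml], axis=1)


def cop_from_grfm(
    wrench: GroundWrench,
    fz_threshold: float = 20.0,
    mass: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw ZMP centre of pressure from a lab-origin ground wrench.

    Returns ``(cop, valid)`` where ``cop`` is (n, 2) with columns
    (x_ap, z_ml) in metres (NaN where invalid) and ``valid`` marks samples
    whose vertical force reaches ``fz_threshold`` (N).  For a wrench in
    normalized units the subject ``mass`` (kg) is required to convert.

    Raises ValueError if no sample reaches the threshold ("no stance").
    """
    if wrench.reference_point != "lab_origin":
        raise ValueError("wrench must be expressed about the lab origin")
    if wrench.units == "normalized":
        if mass is None:
            raise ValueError("mass required to convert a normalized wrench")
        F = wrench.force * mass * GRAVITY
        M = wrench.moment * mass
    else:
        F = wrench.force
        M = wrench.moment
    f_vert = F[:, 1]
    valid = f_vert >= fz_threshold
    if not valid.any():
        raise ValueError("no stance: vertical force never reaches threshold")
    cop = np.full((len(f_vert), 2), np.nan)
    cop[valid, 0] = M[valid, 2] / f_vert[valid]
    cop[valid, 1] = -M[valid, 0] / f_vert[valid]
    return cop, valid


def _anchored_chebfit(s: np.ndarray, y: np.ndarray, anchors_s: np.ndarray, anchors_y: np.ndarray):
    """Least-squares degree-10 Chebyshev fit with exact-interpolation
    anchors, solved as an equality-constrained least-squares (KKT) system.

    The stance axis is mapped to [-1, 1]; the anchor rows are enforced
    exactly, which realises the hard calcaneus anchoring at 0% and 100%.
    """
    x = 2.0 * s / 100.0 - 1.0
    xa = 2.0 * anchors_s / 100.0 - 1.0
    A = chebyshev.chebvander(x, POLY_DEGREE)
    B = chebyshev.chebvander(xa, POLY_DEGREE)
    p = POLY_DEGREE + 1
    m = len(xa)
    K = np.zeros((p + m, p + m))
    K[:p, :p] = 2.0 * A.T @ A
    K[:p, p:] = B.T
    K[p:, :p] = B
    rhs = np.concatenate([2.0 * A.T @ y, anchors_y])
    sol = np.linalg.solve(K, rhs)
    coef = sol[:p]
    return lambda ss: chebyshev.chebval(2.0 * np.asarray(ss) / 100.0 - 1.0, coef)


def repair_cop(
    raw: np.ndarray,
    calcaneus_origin: tuple[float, float],
    stance_percent: np.ndarray | None = None,
    valid: np.ndarray | None = None,
) -> CopTrajectory:
    """Repair the COP endpoints with an anchored 10th-order polynomial.

    ``raw`` is (n, 2) on a 0..100% stance grid (NaN where the ZMP ratio was
    undefined).  Per coordinate, a degree-10 polynomial is fitted by least
    squares to the valid 15-85% core samples, constrained to pass through
    the calcaneus origin at 0% and 100% of stance.  The output equals the
    raw samples over the 15-85% core; in the end regions it is the
    polynomial, linearly blended into the raw value over a 2% window inside
    each end region so the junctions are continuous.

    Raises ValueError when fewer than 12 valid core samples are available
    (a degree-10 fit would be underdetermined).
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    s = np.linspace(0.0, 100.0, n) if stance_percent is None else np.asarray(stance_percent, dtype=float)
    if valid is None:
        valid = np.all(np.isfinite(raw), axis=1)
    core = (s >= CORE_LO) & (s <= CORE_HI)
    usable = core & valid
    if usable.sum() < POLY_DEGREE + 2:
        raise ValueError(
            f"only {int(usable.sum())} valid core samples; degree-{POLY_DEGREE} fit underdetermined"
        )

    calc = np.asarray(calcaneus_origin, dtype=float)
    out = raw.copy()
    flags = np.where(core, "raw_zmp", "polynomial_fitted").astype(object)
    anchors_s = np.array([0.0, 100.0])
    core_idx = np.flatnonzero(usable)
    i_lo, i_hi = core_idx[0], core_idx[-1]  # junction samples nearest 15% / 85%
    for j in range(2):
        fit = _anchored_chebfit(s[usable], raw[usable, j], anchors_s, np.array([calc[j], calc[j]]))
        lo_region = s < s[i_lo]
        hi_region = s > s[i_hi]
        out[lo_region, j] = fit(s[lo_region])
        out[hi_region, j] = fit(s[hi_region])
        # rare invalid samples inside the core are filled from the fit too
        gaps = core & ~valid
        out[gaps, j] = fit(s[gaps])
        flags[gaps] = "polynomial_fitted"
        # blend the fit into the raw junction value over a 2% window so the
        # repaired curve is continuous at 15% and 85% by construction
        lo_blend = lo_region & (s >= s[i_lo] - BLEND_WIDTH)
        alpha = (s[lo_blend] - (s[i_lo] - BLEND_WIDTH)) / BLEND_WIDTH
        out[lo_blend, j] += alpha * (raw[i_lo, j] - fit(s[i_lo]))
        hi_blend = hi_region & (s <= s[i_hi] + BLEND_WIDTH)
        beta = ((s[i_hi] + BLEND_WIDTH) - s[hi_blend]) / BLEND_WIDTH
        out[hi_blend, j] += beta * (raw[i_hi, j] - fit(s[i_hi]))

    return CopTrajectory(
        stance_percent=s,
        x_ap=out[:, 0],
        y_ml=out[:, 1],
        source_flag=flags,
        calcaneus_origin=(float(calc[0]), float(calc[1])),
    )
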