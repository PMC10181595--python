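"""Newton-Euler computations: whole-body wrench, transport, knee moments."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gaitwrench.core import GRAVITY, NormalizedCycle
from gaitwrench.dynamics import (
    GroundWrench,
    first_derivative,
    knee_moments,
    second_derivative,
    transport_wrench,
    whole_body_wrench,
)
from gaitwrench.synth import GeneratorConfig, generate_cycle, generate_subject, normalized_cycles, generate_dataset

G_VEC = np.array([0.0, -GRAVITY, 0.0])


class TestWholeBodyWrench:
    def test_static_standing_is_one_bw(self, subject80):
        a = np.zeros((5, 3))
        w = whole_body_wrench(a, subject80)
        assert np.allclose(w.force, [0.0, 1.0, 0.0])

    def test_free_fall_gives_zero_force(self, subject80):
        a = np.tile(G_VEC, (4, 1))
        w = whole_body_wrench(a, subject80)
        assert np.allclose(w.force, 0.0)

    def test_upward_acceleration_adds_to_weight(self, subject80):
        w = whole_body_wrench(np.array([[0.0, 1.0, 0.0]]), subject80)
        # F_y = m (1 + g) N -> (1 + g)/g BW; for 80 kg that is 864.8 N
        assert w.force[0, 1] * 80.0 * GRAVITY == pytest.approx(80.0 * (1.0 + GRAVITY))


class TestTransport:
    def test_roundtrip_identity(self, rng):
        F = rng.normal(size=(50, 3))
        M = rng.normal(size=(50, 3))
        w = GroundWrench(force=F, moment=M, reference_point="lab_origin")
        cop_path = rng.normal(size=(50, 3))
        back = transport_wrench(transport_wrench(w, cop_path, "cop"), np.zeros(3), "lab_origin")
        assert np.allclose(back.moment, M, atol=1e-12)

    def test_transport_matches_cross_product_definition(self, rng):
        F = rng.normal(size=(1, 3))
        M = rng.normal(size=(1, 3))
        p = rng.normal(size=3)
        w = GroundWrench(force=F, moment=M)
        moved = transport_wrench(w, p)
        assert np.allclose(moved.moment[0], M[0] + np.cross(-p, F[0]))


def _static_cycle(knee, ankle, subject, duration=1.0):
    """A motionless cycle with all distal-chain channels constant."""
    n = 101
    ch = {}
    positions = {
        "r_knee": knee, "r_ankle": ankle,
        "r_foot_com": (ankle[0] + 0.07, ankle[1] - 0.03, ankle[2]),
        "r_shank_com": ((knee[0] + ankle[0]) / 2, (knee[1] + ankle[1]) / 2, knee[2]),
    }
    for name, vec in positions.items():
        for j, ax in enumerate("xyz"):
            ch[f"{name}_{ax}"] = np.full(n, float(vec[j]))
    for seg in ("foot", "shank"):
        for ax in "xyz":
            ch[f"r_{seg}_r{ax}"] = np.zeros(n)
    return NormalizedCycle(
        percent=np.linspace(0, 100, n), channels=ch,
        stance_fraction=0.999, cycle_duration=duration,
    )


class TestKneeMomentsStatic:
    def test_vertical_force_with_anterior_lever_gives_35_newton_metres(self, subject80):
        knee = (0.0, 0.5, 0.09)
        cyc = _static_cycle(knee, (0.0, 0.08, 0.09), subject80)
        n = 101
        F = np.tile([0.0, 700.0, 0.0], (n, 1))
        cop = np.tile([knee[0] + 0.05, 0.0, knee[2]], (n, 1))
        wrench = GroundWrench(force=F, moment=np.zeros_like(F), reference_point="cop",
                              units="SI", point=cop)
        km = knee_moments(cyc, wrench, cop, subject80, side="right",
                          foot_mass=0.0, shank_mass=0.0)
        assert np.allclose(km.kfm * subject80.mass, 35.0, atol=1e-10)
        assert np.allclose(km.kam, 0.0, atol=1e-10)
        assert np.allclose(km.krm, 0.0, atol=1e-10)

    def test_force_line_through_knee_gives_zero_moments(self, subject80):
        knee = (0.1, 0.5, 0.0)
        cyc = _static_cycle(knee, (0.1, 0.08, 0.0), subject80)
        n = 101
        F = np.tile([0.0, 650.0, 0.0], (n, 1))
        cop = np.tile([knee[0], 0.0, knee[2]], (n, 1))  # directly below the knee
        wrench = GroundWrench(force=F, moment=np.zeros_like(F), reference_point="cop",
                              units="SI", point=cop)
        km = knee_moments(cyc, wrench, cop, subject80, side="right",
                          foot_mass=0.0, shank_mass=0.0)
        for comp in (km.kfm, km.kam, km.krm):
            assert np.allclose(comp, 0.0, atol=1e-12)

    def test_linearity_in_grf_for_massless_static_chain(self, subject80, rng):
        knee = (0.0, 0.5, 0.09)
        cyc = _static_cycle(knee, (0.02, 0.08, 0.09), subject80)
        n = 101
        cop = np.tile([0.06, 0.0, 0.07], (n, 1))
        F1 = rng.normal(size=(n, 3)) * 100
        F2 = rng.normal(size=(n, 3)) * 100

        def km_of(F):
            w = GroundWrench(force=F, moment=np.zeros_like(F), reference_point="cop",
                             units="SI", point=cop)
            return knee_moments(cyc, w, cop, subject80, side="right",
                                foot_mass=0.0, shank_mass=0.0)

        a, b = 2.0, -0.7
        combo = km_of(a * F1 + b * F2)
        k1, k2 = km_of(F1), km_of(F2)
        assert np.allclose(combo.kfm, a * k1.kfm + b * k2.kfm, atol=1e-9)
        assert np.allclose(combo.kam, a * k1.kam + b * k2.kam, atol=1e-9)

    def test_wrench_at_lab_origin_rejected(self, subject80):
        cyc = _static_cycle((0, 0.5, 0), (0, 0.1, 0), subject80)
        w = GroundWrench(force=np.zeros((101, 3)), moment=np.zeros((101, 3)))
        with pytest.raises(ValueError, match="COP"):
            knee_moments(cyc, w, np.zeros((101, 3)), subject80)


def _oracle_knee_moments(cycle, wrench, cop, subject, side="right"):
    """System-level oracle: moment balance of the combined foot+shank free
    body taken directly about the knee joint centre (a different assembly
    than the segment-by-segment recursion in the implementation)."""
    s = side[0]
    n = len(cycle.percent)
    dt = cycle.cycle_duration / (n - 1)
    wr = wrench.to_si(subject.mass)
    cop = np.asarray(cop, dtype=float)
    if cop.shape[1] == 2:
        cop = np.stack([cop[:, 0], np.zeros(len(cop)), cop[:, 1]], axis=1)
    cop = np.where(np.all(np.isfinite(cop), axis=1)[:, None], cop, 0.0)

    def vec(prefix):
        return np.stack([cycle.channel(f"{prefix}_{ax}") for ax in "xyz"], axis=1)

    knee = vec(f"{s}_knee")
    segs = []
    for seg, compref in (("foot", f"{s}_foot_com"), ("shank", f"{s}_shank_com")):
        m = subject.segment_mass(f"{seg}_{s}")
        gy = subject.segment(f"{seg}_{s}")
        inertia = m * (gy.gyration_fraction * gy.length) ** 2
        com = vec(compref)
        ang = np.stack([cycle.channel(f"{s}_{seg}_r{ax}") for ax in "xyz"], axis=1)
        segs.append((m, inertia, com, ang))

    M_k = np.zeros((n, 3))
    for m, inertia, com, ang in segs:
        a = np.stack([second_derivative(com[:, j], dt) for j in range(3)], axis=1)
        w = np.stack([first_derivative(ang[:, j], dt) for j in range(3)], axis=1)
        al = np.stack([second_derivative(ang[:, j], dt) for j in range(3)], axis=1)
        for i in range(n):
            M_k[i] += inertia * al[i] + np.cross(w[i], inertia * w[i])
            M_k[i] += np.cross(com[i] - knee[i], m * (a[i] - G_VEC))
    for i in range(n):
        M_k[i] -= np.cross(cop[i] - knee[i], wr.force[i]) + wr.moment[i]
    M_ext = -M_k

    ang_s = np.stack([cycle.channel(f"{s}_shank_r{ax}") for ax in "xyz"], axis=1)
    out = np.empty_like(M_ext)
    for i in range(n):
        R = Rotation.from_euler("ZXY", [ang_s[i, 2], ang_s[i, 0], ang_s[i, 1]]).as_matrix()
        out[i] = R.T @ M_ext[i]
    sign = 1.0 if s == "r" else -1.0
    return (out[:, 2] / subject.mass, sign * out[:, 0] / subject.mass, -sign * out[:, 1] / subject.mass)


class TestKneeMomentsDynamic:
    def test_full_dynamic_case_matches_system_level_oracle(self):
        cfg = GeneratorConfig(n_subjects=1, cycles_per_subject=1, seed=21)
        ds = generate_dataset(cfg)
        subj = ds.subjects[0]
        cyc = normalized_cycles(ds)["S000"][0]
        cop = np.stack([cyc.channel("cop_r_x"), cyc.channel("cop_r_ml")], axis=1)
        F = np.stack([cyc.channel(f"grf_r_{ax}") for ax in "xyz"], axis=1)
        cop3 = np.stack([cop[:, 0], np.zeros(101), cop[:, 1]], axis=1)
        wrench = GroundWrench(force=F, moment=np.zeros_like(F), reference_point="cop",
                              units="normalized", point=cop3)
        km = knee_moments(cyc, wrench, cop, subj, side="right")
        kfm_o, kam_o, krm_o = _oracle_knee_moments(cyc, wrench, cop, subj, side="right")
        assert np.allclose(km.kfm, kfm_o, atol=1e-8 / subj.mass)
        assert np.allclose(km.kam, kam_o, atol=1e-8 / subj.mass)
        assert np.allclose(km.krm, krm_o, atol=1e-8 / subj.mass)

    def test_left_side_sign_convention_mirrors_right(self):
        cfg = GeneratorConfig(n_subjects=1, cycles_per_subject=1, seed=22,
                              noise_sd_kin=0.0, noise_sd_grf=0.0)
        ds = generate_dataset(cfg)
        subj = ds.subjects[0]
        cyc = normalized_cycles(ds)["S000"][0]
        for s, side in (("r", "right"), ("l", "left")):
            cop = np.stack([cyc.channel(f"cop_{s}_x"), cyc.channel(f"cop_{s}_ml")], axis=1)
            F = np.stack([cyc.channel(f"grf_{s}_{ax}") for ax in "xyz"], axis=1)
            cop3 = np.stack([cop[:, 0], np.zeros(101), cop[:, 1]], axis=1)
            wrench = GroundWrench(force=F, moment=np.zeros_like(F), reference_point="cop",
                                  units="normalized", point=cop3)
            km = knee_moments(cyc, wrench, cop, subj, side=side)
            # stance adduction moment loads the medial compartment on both sides
            stance = cyc.percent <= cyc.stance_fraction * 100
            if s == "l":
                stance = (cyc.percent >= 50) | (cyc.percent <= 10)
            assert np.max(km.kam[stance]) > 0
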