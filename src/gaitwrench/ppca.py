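"""Probabilistic PCA over stacked gait-cycle waveforms, with conditional
(missing-block) inference of ground reaction forces and moments.

Model: x = W z + mu + eps with z ~ N(0, I_q) and eps ~ N(0, sigma2 I_D),
fitted in closed form by eigendecomposition (maximum likelihood).  The
stacked feature vector x concatenates, per gait cycle, the 101-point
kinematic waveforms, the stance fraction (the stance-timing scalar that
resolves the double-support indeterminacy), and the 101-point per-foot
GRFM waveforms.  Prediction conditions the joint Gaussian on the kinematic
block and reads off the GRFM block; all conditioning runs through the
q-dimensional latent posterior, never a dense D x D covariance.

Channels are standardized by a per-channel scale (one scalar per channel,
the pooled standard deviation over the training set) so radian, BW and
Nm/kg channels are commensurable; the scales are stored in the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from gaitwrench.core import NormalizedCycle

N_POINTS = 101
STANCE_FEATURE = "stance_fraction"

DEFAULT_GRFM_CHANNELS = ("grf_r_x", "grf_r_y", "grf_r_z", "grm_r_x", "grm_r_y", "grm_r_z")


# ---------------------------------------------------------------------------
# feature layout
# ---------------------------------------------------------------------------

@dataclass
class FeatureLayout:
    """Maps named channel blocks onto index ranges of the stacked vector.

    Each channel occupies 101 consecutive indices except the special
    ``stance_fraction`` channel, which is a single scalar.  Blocks
    partition ``0..D-1``; observed and target blocks are disjoint.
    """

    blocks: dict[str, list[str]]
    observed_blocks: frozenset[str]
    target_blocks: frozenset[str]

    def __post_init__(self) -> None:
        self.observed_blocks = frozenset(self.observed_blocks)
        self.target_blocks = frozenset(self.target_blocks)
        if self.observed_blocks & self.target_blocks:
            raise ValueError("observed and target blocks overlap")
        unknown = (self.observed_blocks | self.target_blocks) - set(self.blocks)
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")

    @staticmethod
    def _width(channel: str) -> int:
        return 1 if channel == STANCE_FEATURE else N_POINTS

    @property
    def D(self) -> int:
        return sum(self._width(ch) for chs in self.blocks.values() for ch in chs)

    def channel_slices(self) -> dict[tuple[str, str], slice]:
        out = {}
        pos = 0
        for block, chs in self.blocks.items():
            for ch in chs:
                w = self._width(ch)
                out[(block, ch)] = slice(pos, pos + w)
                pos += w
        return out

    def block_indices(self, names: frozenset[str] | set[str]) -> np.ndarray:
        idx = []
        for (block, _), sl in self.channel_slices().items():
            if block in names:
                idx.extend(range(sl.start, sl.stop))
        return np.asarray(idx, dtype=int)

    def channels_of(self, names: frozenset[str] | set[str]) -> list[str]:
        return [ch for block, chs in self.blocks.items() if block in names for ch in chs]

    @classmethod
    def default(
        cls,
        kin_channels: list[str] | tuple[str, ...],
        grfm_channels: tuple[str, ...] = DEFAULT_GRFM_CHANNELS,
        include_wrench: bool = False,
        wrench_channels: tuple[str, ...] = ("com_accel_x", "com_accel_y", "com_accel_z"),
    ) -> "FeatureLayout":
        """Observed = joint angles + stance fraction (+ optional whole-body
        wrench features); target = per-foot GRFM waveforms."""
        obs = list(kin_channels) + ([*wrench_channels] if include_wrench else []) + [STANCE_FEATURE]
        return cls(
            blocks={"kinematics": obs, "grfm": list(grfm_channels)},
            observed_blocks=frozenset({"kinematics"}),
            target_blocks=frozenset({"grfm"}),
        )

    def to_dict(self) -> dict:
        return {
            "blocks": self.blocks,
            "observed_blocks": sorted(self.observed_blocks),
            "target_blocks": sorted(self.target_blocks),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureLayout":
        return cls(
            blocks={k: list(v) for k, v in d["blocks"].items()},
            observed_blocks=frozenset(d["observed_blocks"]),
            target_blocks=frozenset(d["target_blocks"]),
        )


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def compute_scales(cycles: list[NormalizedCycle], layout: FeatureLayout) -> dict[str, float]:
    """Per-channel standardization scale: pooled sd over cycles and time.

    A channel that is (numerically) constant gets a unit-order scale
    instead, so float jitter in a degenerate channel is not amplified.
    """
    scales: dict[str, float] = {}
    for block, chs in layout.blocks.items():
        for ch in chs:
            if ch == STANCE_FEATURE:
                vals = np.array([c.stance_fraction for c in cycles])
            else:
                vals = np.concatenate([c.channel(ch) for c in cycles])
            sd = float(np.std(vals))
            level = max(1.0, float(np.abs(vals).max(initial=0.0)))
            scales[ch] = sd if sd > 1e-8 * level else level
    return scales


def build_features(
    cycles: list[NormalizedCycle],
    layout: FeatureLayout,
    scales: dict[str, float] | None = None,
    blocks: frozenset[str] | set[str] | None = None,
) -> np.ndarray:
    """Stack cycles into an (n, D) feature matrix in layout order.

    ``blocks`` restricts the output to a subset of blocks (e.g. only the
    observed block at prediction time); by default all blocks are stacked.
    Each channel is divided by its training-set scale when ``scales`` is
    given.  A cycle missing a required channel raises KeyError naming it.
    """
    use = set(layout.blocks) if blocks is None else set(blocks)
    slices = [(block, ch) for block, chs in layout.blocks.items() for ch in chs if block in use]
    rows = []
    for cyc in cycles:
        parts = []
        for block, ch in slices:
            if ch == STANCE_FEATURE:
                v = np.array([cyc.stance_fraction])
            else:
                v = np.asarray(cyc.channel(ch), dtype=float)
                if len(v) != N_POINTS:
                    raise ValueError(f"channel {ch!r} is not {N_POINTS}-point")
            if scales is not None:
                v = v / scales[ch]
            parts.append(v)
        rows.append(np.concatenate(parts))
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class PPCAModel:
    """Maximum-likelihood PPCA fit.

    Implied covariance C = W W^T + sigma2 I.  ``mu``, ``W`` and ``sigma2``
    live in standardized feature space; ``scales`` maps back to physical
    units.
    """

    mu: np.ndarray
    W: np.ndarray
    sigma2: float
    q: int
    layout: FeatureLayout | None = None
    scales: dict[str, float] | None = None
    eigenvalues: np.ndarray | None = None
    training_meta: dict = field(default_factory=dict)

    FORMAT_VERSION = 1

    @property
    def D(self) -> int:
        return len(self.mu)

    def save(self, path) -> None:
        obj = {
            "format_version": self.FORMAT_VERSION,
            "mu": self.mu.tolist(),
            "W": self.W.tolist(),
            "sigma2": self.sigma2,
            "q": self.q,
            "layout": self.layout.to_dict() if self.layout else None,
            "scales": self.scales,
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def load(cls, path) -> "PPCAModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {obj.get('format_version')}")
        return cls(
            mu=np.asarray(obj["mu"]),
            W=np.asarray(obj["W"]),
            sigma2=float(obj["sigma2"]),
            q=int(obj["q"]),
            layout=FeatureLayout.from_dict(obj["layout"]) if obj["layout"] else None,
            scales=obj["scales"],
            training_meta=obj.get("training_meta", {}),
        )


def _sample_eigendecomposition(Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of the sample covariance S = Xc^T Xc / n, descending.

    Uses the n x n Gram matrix when n < D (the usual waveform regime), so
    only min(n, D) pairs are returned — the rest of the spectrum is zero.
    """
    n, D = Xc.shape
    if D <= n:
        S = Xc.T @ Xc / n
        lam, U = np.linalg.eigh(S)
        order = np.argsort(lam)[::-1]
        return lam[order], U[:, order]
    G = Xc @ Xc.T / n
    lam, V = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    pos = lam > 1e-14 * max(lam[0], 1.0)
    U = np.zeros((D, len(lam)))
    U[:, pos] = Xc.T @ (V[:, pos] / np.sqrt(n * lam[pos]))
    return lam, U


def train_ppca(
    X: np.ndarray,
    q: int,
    layout: FeatureLayout | None = None,
    scales: dict[str, float] | None = None,
    training_meta: dict | None = None,
) -> PPCAModel:
    """Closed-form maximum-likelihood PPCA fit.

    ``sigma2`` is the mean of the discarded sample-covariance eigenvalues;
    when n <= D the average runs over the min(n-1, D) - q nonzero discarded
    eigenvalues (the deficient tail of the spectrum carries no information).
    ``W = U_q (Lambda_q - sigma2 I)^{1/2}``.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in X")
    n, D = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 1 <= q < min(n, D):
        raise ValueError(f"q={q} must satisfy 1 <= q < min(n, D) = {min(n, D)}")
    mu = X.mean(axis=0)
    lam, U = _sample_eigendecomposition(X - mu)
    lam = np.clip(lam, 0.0, None)
    r = min(n - 1, D)
    if q > r:
        raise ValueError(f"q={q} exceeds the data rank bound {r}")
    discarded = lam[q:r]
    sigma2 = float(discarded.mean()) if len(discarded) else 0.0
    if sigma2 < 1e-12 * max(lam[0], 1.0):
        sigma2 = max(sigma2, 0.0)
    W = U[:, :q] * np.sqrt(np.clip(lam[:q] - sigma2, 0.0, None))
    return PPCAModel(
        mu=mu, W=W, sigma2=sigma2, q=q, layout=layout, scales=scales,
        eigenvalues=lam[:r],
        training_meta={"n_cycles": n, **(training_meta or {})},
    )


def choose_q(eigenvalues: np.ndarray, explained: float = 0.95, q_max: int | None = None) -> int:
    """Smallest q whose leading eigenvalues explain ``explained`` of the
    total variance (default 95%)."""
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    frac = np.cumsum(lam) / lam.sum()
    q = int(np.searchsorted(frac, explained) + 1)
    hi = len(lam) - 1 if q_max is None else min(q_max, len(lam) - 1)
    return max(1, min(q, hi))


def fit_model(
    cycles: list[NormalizedCycle],
    layout: FeatureLayout,
    q: int | str = "auto",
    explained: float = 0.95,
) -> PPCAModel:
    """Standardize, stack and fit in one call (training entry point)."""
    scales = compute_scales(cycles, layout)
    X = build_features(cycles, layout, scales)
    if q == "auto":
        mu = X.mean(axis=0)
        lam, _ = _sample_eigendecomposition(X - mu)
        q = choose_q(np.clip(lam, 0, None)[: min(len(cycles) - 1, X.shape[1])], explained)
    model = train_ppca(X, int(q), layout=layout, scales=scales)
    subj = {c.subject_id for c in cycles if c.subject_id}
    model.training_meta["n_subjects"] = len(subj)
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass
class GrfmPrediction:
    """Predicted per-foot GRFM waveforms with per-sample posterior sd.

    Channels are in physical units (BW / Nm-per-kg) on the 101-point cycle
    grid, masked to zero outside the stance window implied by
    ``stance_fraction``.
    """

    channels: dict[str, np.ndarray]
    posterior_sd: dict[str, np.ndarray]
    stance_fraction: float
    percent: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 100.0, N_POINTS))


def _conditional(model: PPCAModel, obs_idx: np.ndarray, x_obs_std: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian conditional (mean, variance diagonal) of the complement of
    obs_idx given the observed coordinates, via the latent posterior."""
    D = model.D
    tgt_idx = np.setdiff1d(np.arange(D), obs_idx)
    W_o, W_t = model.W[obs_idx], model.W[tgt_idx]
    d = x_obs_std - model.mu[obs_idx]
    s2 = model.sigma2
    if s2 > 0:
        M = W_o.T @ W_o + s2 * np.eye(model.q)
        Minv = np.linalg.inv(M)
        z = Minv @ (W_o.T @ d)
        var = s2 + s2 * np.einsum("ij,jk,ik->i", W_t, Minv, W_t)
    else:
        z, *_ = np.linalg.lstsq(W_o, d, rcond=None)
        var = np.zeros(len(tgt_idx))
    mean = model.mu[tgt_idx] + W_t @ z
    return mean, var


def infer_grfm(
    model: PPCAModel,
    observed: np.ndarray | dict[str, np.ndarray] | NormalizedCycle,
    stance_fraction: float | None = None,
) -> GrfmPrediction:
    """Predict the GRFM block from the kinematic block by conditioning.

    ``observed`` may be a NormalizedCycle (channels and stance fraction
    taken from it), a dict of raw channel waveforms, or the raw stacked
    observed vector *without* the stance-fraction entry (in which case
    ``stance_fraction`` must be given).  The conditional mean and the
    diagonal of the conditional covariance are computed through the latent
    posterior, de-standardized and masked to the stance window.
    """
    if model.layout is None or model.scales is None:
        raise ValueError("model carries no layout/scales; train with fit_model")
    layout, scales = model.layout, model.scales
    obs_channels = layout.channels_of(layout.observed_blocks)

    if isinstance(observed, NormalizedCycle):
        stance_fraction = observed.stance_fraction
        observed = {ch: observed.channel(ch) for ch in obs_channels if ch != STANCE_FEATURE}
    if stance_fraction is None:
        raise ValueError("stance_fraction required")
    if isinstance(observed, dict):
        parts = []
        for ch in obs_channels:
            if ch == STANCE_FEATURE:
                parts.append(np.array([stance_fraction]))
            else:
                if ch not in observed:
                    raise KeyError(f"observed channels missing {ch!r}")
                parts.append(np.asarray(observed[ch], dtype=float))
        x_obs_raw = np.concatenate(parts)
    else:
        x_obs_raw = np.concatenate([np.asarray(observed, dtype=float), [stance_fraction]])

    obs_scales = np.concatenate(
        [np.full(FeatureLayout._width(ch), scales[ch]) for ch in obs_channels]
    )
    obs_idx = layout.block_indices(layout.observed_blocks)
    if len(x_obs_raw) != len(obs_idx):
        raise ValueError(f"observed vector has length {len(x_obs_raw)}, layout expects {len(obs_idx)}")
    mean_std, var_std = _conditional(model, obs_idx, x_obs_raw / obs_scales)

    tgt_channels = layout.channels_of(layout.target_blocks)
    percent = np.linspace(0.0, 100.0, N_POINTS)
    swing = percent > stance_fraction * 100.0 + 1e-9
    channels: dict[str, np.ndarray] = {}
    sds: dict[str, np.ndarray] = {}
    pos = 0
    for ch in tgt_channels:
        w = FeatureLayout._width(ch)
        vals = mean_std[pos : pos + w] * scales[ch]
        sd = np.sqrt(np.clip(var_std[pos : pos + w], 0.0, None)) * scales[ch]
        pos += w
        if w == N_POINTS:
            vals = vals.copy()
            vals[swing] = 0.0
        channels[ch] = vals
        sds[ch] = sd
    return GrfmPrediction(channels=channels, posterior_sd=sds, stance_fraction=float(stance_fraction))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-fold and pooled agreement of predicted vs measured GRFM."""

    per_cycle: "object"  # pandas DataFrame: fold, subject, channel, rmse, r2
    pooled: dict[str, dict[str, float]]  # channel -> {rmse_mean, rmse_sd, r2_mean, r2_sd}


def _score_fold(model: PPCAModel, test_cycles: list[NormalizedCycle], rows: list, fold: str) -> None:
    from gaitwrench.metrics import agreement

    tgt_channels = model.layout.channels_of(model.layout.target_blocks)
    for cyc in test_cycles:
        pred = infer_grfm(model, cyc)
        for ch in tgt_channels:
            if ch == STANCE_FEATURE:
                continue
            ref = np.asarray(cyc.channel(ch), dtype=float)
            rmse, r2 = agreement(ref, pred.channels[ch])
            rows.append({"fold": fold, "subject": cyc.subject_id, "channel": ch, "rmse": rmse, "r2": r2})


def _pool(rows: list) -> CvResult:
    import pandas as pd

    df = pd.DataFrame(rows)
    pooled = {}
    for ch, grp in df.groupby("channel"):
        pooled[ch] = {
            "rmse_mean": float(grp["rmse"].mean()),
            "rmse_sd": float(grp["rmse"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "r2_mean": float(grp["r2"].mean()),
            "r2_sd": float(grp["r2"].std(ddof=1)) if len(grp) > 1 else 0.0,
        }
    return CvResult(per_cycle=df, pooled=pooled)


def loso_cv(
    cycles_by_subject: dict[str, list[NormalizedCycle]],
    layout: FeatureLayout,
    q: int | str = "auto",
) -> CvResult:
    """Leave-one-subject-out cross-validation.

    For each subject, a model is fitted on all other subjects' cycles
    (standardization scales recomputed per fold) and that subject's GRFM
    is predicted from kinematics and scored per cycle and channel.
    """
    subjects = list(cycles_by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    for sid, cycs in cycles_by_subject.items():
        if not cycs:
            raise ValueError(f"subject {sid} has zero cycles")
    rows: list = []
    for sid in subjects:
        train = [c for other, cycs in cycles_by_subject.items() if other != sid for c in cycs]
        model = fit_model(train, layout, q=q)
        _score_fold(model, cycles_by_subject[sid], rows, fold=sid)
    return _pool(rows)


def loco_cv(
    cycles_by_subject: dict[str, list[NormalizedCycle]],
    layout: FeatureLayout,
    q: int | str = "auto",
    n_folds: int = 10,
    seed: int = 0,
) -> CvResult:
    """Cross-cycle validation: grouped K-fold over cycles with every
    subject represented in training (the leave-cycles-out counterpart of
    LOSO; fold assignment is random but seeded)."""
    all_cycles = [c for cycs in cycles_by_subject.values() for c in cycs]
    rng = np.random.default_rng(seed)
    assignment = rng.integers(0, n_folds, size=len(all_cycles))
    rows: list = []
    for k in range(n_folds):
        test = [c for c, a in zip(all_cycles, assignment) if a == k]
        train = [c for c, a in zip(all_cycles, assignment) if a != k]
        if not test or len(train) < 2:
            continue
        model = fit_model(train, layout, q=q)
        _score_fold(model, test, rows, fold=f"fold{k}")
    return _pool(rows)


def ppca_loglik(X: np.ndarray, q: int) -> float:
    """Average per-sample log-likelihood of X under the ML PPCA fit with q
    components (used to check monotonicity of the ML path in q)."""
    X = np.asarray(X, dtype=float)
    n, D = X.shape
    mu = X.mean(axis=0)
    lam, _ = _sample_eigendecomposition(X - mu)
    lam = np.clip(lam, 0.0, None)
    r = min(n - 1, D)
    sigma2 = float(lam[q:r].mean()) if r > q else 0.0
    if sigma2 <= 0:
        raise ValueError("degenerate fit: sigma2 = 0")
    logdet = float(np.sum(np.log(lam[:q]))) + (D - q) * np.log(sigma2)
    trace = q + float(lam[q:r].sum()) / sigma2
    return -0.5 * (D * np.log(2 * np.pi) + logdet + trace)
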