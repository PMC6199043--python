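"""Relative accessible surface area prediction.

A segment-template similarity engine (cosine match of profile windows
against a pool harvested from solved tracks) fused with an
epsilon-insensitive kernel regression engine by an explicit knowledge
rule: confident template matches override the learned model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.svm import SVR

from .errors import (
    ConfigError,
    InputError,
    TrainingError,
    UndefinedCorrelationError,
)
from .propensity import PropensityTrack, window_feature_matrix
from .seqio import AA_INDEX, Profile, SequenceRecord, scale_profile
from .tmh import Topology


@dataclass
class RasaTrack:
    """Per-residue relative accessibility in percent, clamped to [0,100]."""

    record_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("rasa track must be 1-D")
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise InputError("rasa values outside [0,100]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TemplatePool:
    """Unit-normalized segment windows with their central-residue rasa."""

    features: np.ndarray  # (n, segment_length*20), rows unit-norm
    rasa: np.ndarray  # (n,)
    source_ids: list[str]
    segment_length: int = 15

    def __post_init__(self):
        if len(self.features) != len(self.rasa):
            raise InputError("pool features and rasa lengths disagree")
        if np.any(self.rasa < 0) or np.any(self.rasa > 100):
            raise InputError("pool rasa values outside [0,100]")

    def __len__(self) -> int:
        return len(self.rasa)

    def save(self, path) -> None:
        np.savez(path, features=self.features, rasa=self.rasa,
                 source_ids=np.array(self.source_ids),
                 segment_length=self.segment_length)

    @classmethod
    def load(cls, path) -> "TemplatePool":
        with np.load(path, allow_pickle=False) as z:
            return cls(features=z["features"], rasa=z["rasa"],
                       source_ids=[str(s) for s in z["source_ids"]],
                       segment_length=int(z["segment_length"]))


@dataclass
class RasaFusionConfig:
    similarity_threshold: float = 0.9
    top_t: int = 3
    blend: str = "hard_switch"  # or "similarity_blend"

    def __post_init__(self):
        if not 0.0 < self.similarity_threshold <= 1.0:
            raise ConfigError("similarity_threshold outside (0,1]")
        if self.top_t < 1:
            raise ConfigError("top_t must be >= 1")
        if self.blend not in ("hard_switch", "similarity_blend"):
            raise ConfigError(f"unknown blend rule '{self.blend}'")


# ---------------------------------------------------------------------------
# template engine
# ---------------------------------------------------------------------------

def _unit_rows(M: np.ndarray) -> np.ndarray:
    """Mean-center each row, then scale to unit Euclidean norm.

    Centering is essential: scaled profiles share a large constant
    offset, and without it every window pair has cosine ~1, collapsing
    the similarity signal the knowledge rule depends on.  Constant
    windows map to the zero vector (cosine 0 against everything).
    """
    M = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(M, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M / norms


def _segment_windows(profile: Profile, segment_length: int) -> tuple[np.ndarray, np.ndarray]:
    """Full-length flattened windows and the 0-based centers they serve."""
    L = profile.length
    half = (segment_length - 1) // 2
    centers = np.arange(half, L - half)
    if len(centers) == 0:
        return np.empty((0, segment_length * 20)), centers
    view = np.lib.stride_tricks.sliding_window_view(
        profile.scaled, (segment_length, 20)
    )[:, 0]
    return view.reshape(len(centers), -1).copy(), centers


def build_template_pool(
    corpus: list[tuple[Profile, RasaTrack]],
    segment_length: int = 15,
    max_entries: int | None = None,
    seed: int = 0,
) -> TemplatePool:
    """One entry per residue with a full-length window; truncated termini
    are skipped.  Feature vectors are unit-normalized."""
    if segment_length % 2 == 0 or segment_length < 3:
        raise ConfigError(f"segment_length {segment_length} must be odd and >= 3")
    if not corpus:
        raise TrainingError("empty template corpus")
    feats, rasa, src = [], [], []
    for profile, track in corpus:
        if profile.length != len(track):
            raise InputError(
                f"profile/track length mismatch for '{profile.record_id}'"
            )
        windows, centers = _segment_windows(profile, segment_length)
        if len(centers) == 0:
            continue
        feats.append(windows)
        rasa.append(track.values[centers])
        src.extend([profile.record_id] * len(centers))
    if not feats:
        raise TrainingError("no sequence long enough for the segment length")
    F = _unit_rows(np.vstack(feats))
    R = np.concatenate(rasa)
    if max_entries is not None and len(R) > max_entries:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(R), size=max_entries, replace=False))
        F, R = F[keep], R[keep]
        src = [src[i] for i in keep]
    return TemplatePool(features=F, rasa=R, source_ids=src,
                        segment_length=segment_length)


def template_predict(
    profile: Profile,
    pool: TemplatePool,
    config: RasaFusionConfig | None = None,
) -> tuple[RasaTrack, np.ndarray]:
    """Per-residue template prediction plus best-similarity track.

    Similarity is the cosine between unit windows mapped to [0,1] via
    (s+1)/2; the prediction is the mean central rasa of the ``top_t``
    most similar pool entries.  Positions without a full window get
    similarity 0 and fall back to the pool mean.
    """
    config = config or RasaFusionConfig()
    if len(pool) == 0:
        raise InputError("empty template pool")
    L = profile.length
    values = np.full(L, float(np.mean(pool.rasa)))
    best_sim = np.zeros(L)
    windows, centers = _segment_windows(profile, pool.segment_length)
    if len(centers):
        Q = _unit_rows(windows)
        sims = Q @ pool.features.T  # cosine, in [-1, 1]
        t = min(config.top_t, len(pool))
        top_idx = np.argpartition(-sims, t - 1, axis=1)[:, :t]
        values[centers] = np.mean(pool.rasa[top_idx], axis=1)
        best_sim[centers] = (np.max(sims, axis=1) + 1.0) / 2.0
    return (
        RasaTrack(record_id=profile.record_id, values=np.clip(values, 0, 100)),
        best_sim,
    )


# ---------------------------------------------------------------------------
# regression engine
# ---------------------------------------------------------------------------

from .synthetic import KD_VECTOR  # hydropathy in PSSM column order

RASA_WINDOW = 9


def rasa_features(
    record: SequenceRecord,
    profile: Profile,
    topology: Topology | None = None,
    propensity: PropensityTrack | None = None,
    window: int = RASA_WINDOW,
) -> np.ndarray:
    """Six-block per-residue feature matrix (L rows).

    Blocks: scaled-profile window; hydropathy window; one-hot residue
    identity; helix-propensity window (a smoothed-hydropathy logistic
    surrogate when no track is supplied); relative position within the
    containing helix (0 outside); normalized distance to the nearer
    terminus.
    """
    L = profile.length
    if len(record) != L:
        raise InputError("record/profile length mismatch")
    half = (window - 1) // 2

    block1 = window_feature_matrix(profile, window)  # (L, window*20)

    kd = np.array([0.0 if c == "X" else KD_VECTOR[AA_INDEX[c]]
                   for c in record.residues])
    kd_scaled = (kd + 4.5) / 9.0  # map [-4.5, 4.5] -> [0, 1]
    padded = np.concatenate([np.full(half, 0.5), kd_scaled, np.full(half, 0.5)])
    block2 = np.lib.stride_tricks.sliding_window_view(padded, window).copy()

    block3 = np.zeros((L, 20))
    for i, c in enumerate(record.residues):
        if c != "X":
            block3[i, AA_INDEX[c]] = 1.0

    if propensity is not None:
        if len(propensity) != L:
            raise InputError("propensity track length mismatch")
        prop = propensity.values
    else:
        # surrogate: logistic of the mean hydropathy over the window
        kd_mean = np.convolve(kd, np.ones(window) / window, mode="same")
        prop = scale_profile(kd_mean.reshape(1, -1)).ravel()
    padded_p = np.concatenate([np.full(half, 0.5), prop, np.full(half, 0.5)])
    block4 = np.lib.stride_tricks.sliding_window_view(padded_p, window).copy()

    block5 = np.zeros((L, 1))
    if topology is not None:
        for seg in topology.segments:
            idx = np.arange(seg.start - 1, seg.end)
            if seg.length == 1:
                block5[idx, 0] = 0.5
            else:
                block5[idx, 0] = (idx - (seg.start - 1)) / (seg.length - 1)

    pos = np.arange(L)
    block6 = (np.minimum(pos, L - 1 - pos) / max(L - 1, 1)).reshape(L, 1)

    return np.hstack([block1, block2, block3, block4, block5, block6])


@dataclass
class RasaRegressor:
    """SVR wrapper: clamps to [0,100], degrades to a constant predictor."""

    model: SVR | None
    constant: float | None = None
    n_features: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.constant is not None:
            return np.full(len(X), self.constant)
        return np.clip(self.model.predict(X), 0.0, 100.0)


def train_rasa_regressor(
    features: np.ndarray,
    targets: np.ndarray,
    max_samples: int = 4000,
    seed: int = 0,
    C: float = 10.0,
    epsilon: float = 2.0,
) -> RasaRegressor:
    """Epsilon-insensitive RBF regression on (subsampled) residues."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if len(X) == 0:
        raise TrainingError("empty regression corpus")
    if len(X) != len(y):
        raise InputError("features/targets length mismatch")
    if np.ptp(y) == 0.0:
        import warnings

        warnings.warn("constant-target corpus; fitting a constant predictor",
                      stacklevel=2)
        return RasaRegressor(model=None, constant=float(y[0]),
                             n_features=X.shape[1])
    if len(X) > max_samples:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(X), size=max_samples, replace=False)
        X, y = X[keep], y[keep]
    svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma="scale")
    svr.fit(X, y)
    return RasaRegressor(model=svr, n_features=X.shape[1])


# ---------------------------------------------------------------------------
# fusion and evaluation
# ---------------------------------------------------------------------------

def fuse_rasa(
    template_track: RasaTrack,
    similarity_track: np.ndarray,
    regression_track: RasaTrack,
    config: RasaFusionConfig | None = None,
) -> tuple[RasaTrack, np.ndarray]:
    """Knowledge-rule fusion; returns the fused track and, per position,
    which engine supplied the value ('template'/'regression'/'blend')."""
    config = config or RasaFusionConfig()
    sim = np.asarray(similarity_track, dtype=float)
    if not (len(template_track) == len(sim) == len(regression_track)):
        raise InputError("fusion inputs differ in length")
    t = template_track.values
    r = regression_track.values
    if config.blend == "hard_switch":
        use_template = sim >= config.similarity_threshold
        fused = np.where(use_template, t, r)
        engine = np.where(use_template, "template", "regression")
    else:
        fused = sim * t + (1.0 - sim) * r
        engine = np.full(len(sim), "blend")
    track = RasaTrack(record_id=template_track.record_id,
                      values=np.clip(fused, 0, 100))
    return track, engine


def evaluate_rasa(predicted: RasaTrack, observed: RasaTrack) -> tuple[float, float]:
    """(Pearson r, mean absolute error in percent)."""
    p = predicted.values
    o = observed.values
    if len(p) != len(o):
        raise InputError("track lengths differ")
    if len(p) < 2:
        raise InputError("need at least 2 residues")
    mae = float(np.mean(np.abs(p - o)))
    if np.ptp(o) == 0.0:
        raise UndefinedCorrelationError(
            "observed track is constant; correlation undefined", mae=mae
        )
    if np.ptp(p) == 0.0:
        return 0.0, mae
    r = float(pearsonr(p, o)[0])
    return r, mae


def evaluate_rasa_pooled(pairs: list[tuple[RasaTrack, RasaTrack]]) -> tuple[float, float]:
    """Corpus-level r and MAE over the concatenation of all residues."""
    pred = np.concatenate([p.values for p, _ in pairs])
    obs = np.concatenate([o.values for _, o in pairs])
    return evaluate_rasa(RasaTrack(record_id="pooled", values=pred),
                         RasaTrack(record_id="pooled", values=obs))
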