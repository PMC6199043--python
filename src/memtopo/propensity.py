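"""Per-residue helix propensity via multi-scale windows and an
evidence-theoretic K-nearest-neighbor classifier.

Each of the k nearest reference vectors contributes a basic belief
assignment with mass ``alpha0 * exp(-gamma_q * d^2)`` on its own class
and the remainder on the full frame; the k assignments are combined by
Dempster's rule and read out as the pignistic probability of the helix
class.  The "optimized" step refines the two per-class gamma scale
parameters by a leave-one-out coordinate search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, InputError, TrainingError
from .seqio import Profile


@dataclass
class WindowConfig:
    """Sliding-window widths fused by the multi-scale model."""

    sizes: tuple[int, ...] = (13, 15)
    padding: float = 0.5  # neutral value for rows outside [1, L]

    def __post_init__(self):
        for w in self.sizes:
            if w % 2 == 0 or w < 3:
                raise ConfigError(f"window size {w} must be odd and >= 3")


@dataclass(frozen=True)
class MassAssignment:
    """Two-class basic belief assignment over {TMH, non-TMH, Theta}."""

    m_tmh: float
    m_non: float
    m_theta: float

    def __post_init__(self):
        total = self.m_tmh + self.m_non + self.m_theta
        if min(self.m_tmh, self.m_non, self.m_theta) < -1e-12 or abs(total - 1.0) > 1e-12:
            raise InputError(f"invalid mass assignment ({self.m_tmh}, {self.m_non}, {self.m_theta})")


def combine_masses(masses: list[MassAssignment]) -> MassAssignment:
    """Dempster's rule (conflict-normalized) folded left over ``masses``."""
    mt, mn, mth = 0.0, 0.0, 1.0  # identity element: vacuous assignment
    for m in masses:
        new_t = mt * m.m_tmh + mt * m.m_theta + mth * m.m_tmh
        new_n = mn * m.m_non + mn * m.m_theta + mth * m.m_non
        new_th = mth * m.m_theta
        conflict = mt * m.m_non + mn * m.m_tmh
        norm = 1.0 - conflict
        if norm <= 0.0:
            raise InputError("total conflict in Dempster combination")
        mt, mn, mth = new_t / norm, new_n / norm, new_th / norm
    return MassAssignment(m_tmh=mt, m_non=mn, m_theta=mth)


def pignistic_tmh(m: MassAssignment) -> float:
    """Point probability of the helix class: bel({TMH}) + m(Theta)/2."""
    return m.m_tmh + 0.5 * m.m_theta


@dataclass
class OetknnModel:
    """Instance store plus the evidence-theoretic scale parameters."""

    reference_vectors: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) in {0, 1}; 1 = TMH
    k: int = 11
    alpha0: float = 0.95
    gamma_tmh: float = 1.0
    gamma_non: float = 1.0
    window_size: int | None = None

    def __post_init__(self):
        self.reference_vectors = np.asarray(self.reference_vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.reference_vectors.ndim != 2:
            raise InputError("reference_vectors must be a 2-D array")
        if len(self.labels) != len(self.reference_vectors):
            raise InputError("labels and reference_vectors disagree in length")
        if self.k > len(self.reference_vectors):
            raise ConfigError(f"k={self.k} exceeds reference set size {len(self.labels)}")
        if not 0.0 < self.alpha0 < 1.0:
            raise ConfigError(f"alpha0 must be in (0,1), got {self.alpha0}")
        if self.gamma_tmh <= 0 or self.gamma_non <= 0:
            raise ConfigError("gamma parameters must be positive")

    @property
    def n_features(self) -> int:
        return self.reference_vectors.shape[1]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            reference_vectors=self.reference_vectors,
            labels=self.labels,
            k=self.k,
            alpha0=self.alpha0,
            gamma_tmh=self.gamma_tmh,
            gamma_non=self.gamma_non,
            window_size=-1 if self.window_size is None else self.window_size,
        )

    @classmethod
    def load(cls, path: str | Path) -> "OetknnModel":
        with np.load(path) as z:
            w = int(z["window_size"])
            return cls(
                reference_vectors=z["reference_vectors"],
                labels=z["labels"],
                k=int(z["k"]),
                alpha0=float(z["alpha0"]),
                gamma_tmh=float(z["gamma_tmh"]),
                gamma_non=float(z["gamma_non"]),
                window_size=None if w < 0 else w,
            )


@dataclass
class PropensityTrack:
    record_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InputError("propensity track must be 1-D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise InputError("propensity values outside [0,1]")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def window_features(profile: Profile, i: int, W: int, padding: float = 0.5) -> np.ndarray:
    """Concatenated scaled-profile rows centered at 1-based position i.

    Rows outside [1, L] contribute an all-``padding`` neutral row so the
    feature length is always W*20.
    """
    if W % 2 == 0 or W < 3:
        raise ConfigError(f"window size {W} must be odd and >= 3")
    L = profile.length
    if not 1 <= i <= L:
        raise InputError(f"position {i} outside [1, {L}]")
    half = (W - 1) // 2
    out = np.full((W, 20), padding, dtype=float)
    lo = max(1, i - half)
    hi = min(L, i + half)
    out[lo - (i - half) : hi - (i - half) + 1] = profile.scaled[lo - 1 : hi]
    return out.ravel()


def window_feature_matrix(profile: Profile, W: int, padding: float = 0.5) -> np.ndarray:
    """All L window features at once (rows match 1-based positions)."""
    if W % 2 == 0 or W < 3:
        raise ConfigError(f"window size {W} must be odd and >= 3")
    L = profile.length
    half = (W - 1) // 2
    padded = np.full((L + 2 * half, 20), padding, dtype=float)
    padded[half : half + L] = profile.scaled
    view = np.lib.stride_tricks.sliding_window_view(padded, (W, 20))[:, 0]
    return view.reshape(L, W * 20).copy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _mean_squared_pairwise_distance(X: np.ndarray) -> float:
    # identity: mean_{i!=j} ||xi-xj||^2 = 2 * n/(n-1) * sum_d var_d(biased)
    n = len(X)
    if n < 2:
        return 1.0
    return float(2.0 * n / (n - 1) * np.sum(np.var(X, axis=0)))


def _loo_neighbors(X, y, sample_idx, k, chunk=512):
    """k-nearest (self excluded, distance ties included) for LOO points.

    Returns per-point arrays of neighbor squared distances and labels,
    as ragged lists (tie inclusion can exceed k).
    """
    sq_ref = np.einsum("ij,ij->i", X, X)
    d2_list, lab_list = [], []
    for s in range(0, len(sample_idx), chunk):
        idx = sample_idx[s : s + chunk]
        Q = X[idx]
        d2 = sq_ref[None, :] + np.einsum("ij,ij->i", Q, Q)[:, None] - 2.0 * Q @ X.T
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(len(idx)), idx] = np.inf  # exclude self
        for r in range(len(idx)):
            row = d2[r]
            kth = np.partition(row, k - 1)[k - 1]
            sel = np.flatnonzero(row <= kth)
            d2_list.append(row[sel])
            lab_list.append(y[sel])
    return d2_list, lab_list


def _combine_closed_form(d2, labels, alpha0, gamma_tmh, gamma_non):
    """Pignistic TMH probability for one query from its neighbor set.

    Uses the product form of Dempster's rule for simple support
    functions on a two-class frame.
    """
    d2 = np.asarray(d2, dtype=float)
    labels = np.asarray(labels)
    a = alpha0 * np.exp(-gamma_tmh * d2[labels == 1])
    b = alpha0 * np.exp(-gamma_non * d2[labels == 0])
    prod_a = np.prod(1.0 - a)  # residual frame mass from TMH neighbors
    prod_b = np.prod(1.0 - b)
    m_t = (1.0 - prod_a) * prod_b
    m_n = (1.0 - prod_b) * prod_a
    m_th = prod_a * prod_b
    total = m_t + m_n + m_th
    if total <= 0.0:
        return 0.5
    return (m_t + 0.5 * m_th) / total


def _loo_error(d2_list, lab_list, true_labels, alpha0, gamma_tmh, gamma_non):
    wrong = 0
    for d2, labs, truth in zip(d2_list, lab_list, true_labels):
        p = _combine_closed_form(d2, labs, alpha0, gamma_tmh, gamma_non)
        if (p >= 0.5) != bool(truth):
            wrong += 1
    return wrong / len(true_labels)


def train_oetknn(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 11,
    alpha0: float = 0.95,
    window_size: int | None = None,
    max_refs: int = 20_000,
    loo_sample: int = 1_000,
    seed: int = 0,
) -> OetknnModel:
    """Fit the instance store and refine the per-class gamma scales.

    gamma_q starts at 1 / (mean squared pairwise distance within class
    q) and both gammas are then refined by a multiplicative coordinate
    search that only ever accepts leave-one-out improvements.  The LOO
    objective is evaluated on a seeded stratified subsample of at most
    ``loo_sample`` reference points (the neighbor sets are fixed, so
    the search itself is cheap).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise InputError("features must be (n, d) with matching labels")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("training corpus contains a single class")
    if counts.min() < k:
        raise TrainingError(f"need >= k={k} examples per class, got {counts.min()}")

    rng = np.random.default_rng(seed)
    if len(X) > max_refs:
        keep = []
        for c in classes:
            idx = np.flatnonzero(y == c)
            n_c = max(k, int(round(max_refs * len(idx) / len(X))))
            keep.append(rng.choice(idx, size=min(n_c, len(idx)), replace=False))
        keep = np.sort(np.concatenate(keep))
        X, y = X[keep], y[keep]

    g_tmh = 1.0 / max(_mean_squared_pairwise_distance(X[y == 1]), 1e-12)
    g_non = 1.0 / max(_mean_squared_pairwise_distance(X[y == 0]), 1e-12)

    n_loo = min(loo_sample, len(X))
    sample_idx = rng.choice(len(X), size=n_loo, replace=False) if n_loo < len(X) else np.arange(len(X))
    d2_list, lab_list = _loo_neighbors(X, y, sample_idx, k)
    truth = y[sample_idx]

    best_err = _loo_error(d2_list, lab_list, truth, alpha0, g_tmh, g_non)
    gammas = [g_tmh, g_non]
    factors = (4.0, 2.0, 1.414)
    for _sweep in range(6):
        improved = False
        for gi in (0, 1):
            for f in factors:
                for cand in (gammas[gi] * f, gammas[gi] / f):
                    trial = gammas.copy()
                    trial[gi] = cand
                    err = _loo_error(d2_list, lab_list, truth, alpha0, trial[0], trial[1])
                    if err < best_err:
                        best_err = err
                        gammas = trial
                        improved = True
        if not improved:
            break

    return OetknnModel(
        reference_vectors=X,
        labels=y,
        k=k,
        alpha0=alpha0,
        gamma_tmh=gammas[0],
        gamma_non=gammas[1],
        window_size=window_size,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _neighbor_sets(model: OetknnModel, X: np.ndarray, chunk: int = 1024):
    """Yield (d2, labels) of the k nearest references (ties included)."""
    R = model.reference_vectors
    sq_ref = np.einsum("ij,ij->i", R, R)
    k = model.k
    for s in range(0, len(X), chunk):
        Q = X[s : s + chunk]
        d2 = sq_ref[None, :] + np.einsum("ij,ij->i", Q, Q)[:, None] - 2.0 * Q @ R.T
        np.maximum(d2, 0.0, out=d2)
        for r in range(len(Q)):
            row = d2[r]
            kth = np.partition(row, k - 1)[k - 1]
            sel = np.flatnonzero(row <= kth)
            yield row[sel], model.labels[sel]


def classify(model: OetknnModel, x: np.ndarray) -> float:
    """Helix propensity of a single feature vector, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != model.n_features:
        raise InputError(
            f"feature length {x.shape} does not match model ({model.n_features})"
        )
    return classify_batch(model, x[None, :])[0]


def classify_batch(model: OetknnModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise InputError(
            f"feature matrix shape {X.shape} does not match model "
            f"({model.n_features} features)"
        )
    out = np.empty(len(X))
    for i, (d2, labs) in enumerate(_neighbor_sets(model, X)):
        out[i] = _combine_closed_form(d2, labs, model.alpha0,
                                      model.gamma_tmh, model.gamma_non)
    return np.clip(out, 0.0, 1.0)


def predict_propensity(
    profile: Profile,
    models: dict[int, OetknnModel],
    window_config: WindowConfig | None = None,
) -> PropensityTrack:
    """Mean of the per-window-size propensity tracks."""
    cfg = window_config or WindowConfig()
    missing = [w for w in cfg.sizes if w not in models]
    if missing:
        raise ConfigError(f"no model supplied for window size(s) {missing}")
    tracks = []
    for w in cfg.sizes:
        feats = window_feature_matrix(profile, w, padding=cfg.padding)
        tracks.append(classify_batch(models[w], feats))
    values = np.mean(tracks, axis=0)
    return PropensityTrack(record_id=profile.record_id, values=values)


def build_training_set(corpus, windows=(13, 15), pssm_lookup=None):
    """Window features + binary helix labels for every corpus residue.

    ``corpus`` is a list of (SequenceRecord, Topology); profiles come
    from ``pssm_lookup`` (record_id -> Profile) or pseudo-profiles.
    Returns {W: (features, labels)}.
    """
    from .seqio import pseudo_profile

    out = {}
    for w in windows:
        feats, labels = [], []
        for record, topo in corpus:
            if pssm_lookup and record.id in pssm_lookup:
                profile = pssm_lookup[record.id]
            else:
                profile = pseudo_profile(record)
            feats.append(window_feature_matrix(profile, w))
            lab = np.zeros(len(record), dtype=int)
            for seg in topo.segments:
                lab[seg.start - 1 : seg.end] = 1
            labels.append(lab)
        out[w] = (np.vstack(feats), np.concatenate(labels))
    return out
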