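"""Helix-helix residue contact prediction.

Two engines fused by rank averaging: an unsupervised coevolution engine
(sequence-weighted indicator covariance, shrinkage, L1-penalized sparse
precision, average-product correction) and a supervised ensemble of
evidence-theoretic KNN classifiers trained on random under-samplings of
the non-contact majority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.covariance import graphical_lasso

from .errors import (
    ConfigError,
    InputError,
    InsufficientAlignmentError,
    TrainingError,
)
from .propensity import OetknnModel, classify_batch, train_oetknn, window_features
from .seqio import AA_INDEX, MsaBlock, Profile
from .tmh import Topology

DEFAULT_MIN_SEPARATION = 5


@dataclass
class ContactMap:
    """Symmetric L x L score matrix with masking and optional truth layer.

    The diagonal and pairs closer than ``min_separation`` in sequence are
    always masked; an optional ``tmh_mask`` additionally restricts
    rankings to inter-helix pairs.
    """

    record_id: str
    scores: np.ndarray
    truth: np.ndarray | None = None
    tmh_mask: np.ndarray | None = None
    min_separation: int = DEFAULT_MIN_SEPARATION
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        L = self.scores.shape[0]
        if self.scores.shape != (L, L):
            raise InputError("contact scores must be square")
        if not np.allclose(self.scores, self.scores.T, atol=1e-8, equal_nan=True):
            raise InputError("contact scores must be symmetric")
        if self.truth is not None:
            self.truth = np.asarray(self.truth)
            if self.truth.shape != (L, L):
                raise InputError("truth layer shape mismatch")
            if not np.array_equal(self.truth, self.truth.T):
                raise InputError("truth layer must be symmetric")
            uniq = np.unique(self.truth)
            if not np.all(np.isin(uniq, (0, 1))):
                raise InputError("truth layer must be binary")
        if self.tmh_mask is not None:
            self.tmh_mask = np.asarray(self.tmh_mask, dtype=bool)
            if self.tmh_mask.shape != (L, L):
                raise InputError("tmh_mask shape mismatch")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    def unmasked(self) -> np.ndarray:
        """Boolean matrix of pairs eligible for ranking (both triangles)."""
        L = self.length
        i, j = np.indices((L, L))
        ok = np.abs(i - j) >= self.min_separation
        if self.tmh_mask is not None:
            ok &= self.tmh_mask
        return ok

    def is_masked(self, i: int, j: int) -> bool:
        """0-based pair masked from ranking?"""
        return not self.unmasked()[i, j]


def tmh_pair_mask(topology: Topology, L: int) -> np.ndarray:
    """True where residues i and j lie in two *different* helices."""
    helix_of = np.full(L, -1, dtype=int)
    for hi, seg in enumerate(topology.segments):
        helix_of[seg.start - 1 : seg.end] = hi
    in_helix = helix_of >= 0
    different = helix_of[:, None] != helix_of[None, :]
    return in_helix[:, None] & in_helix[None, :] & different


@dataclass
class CoevolutionConfig:
    shrinkage_lambda: float = 0.1
    sparsity_rho: float = 0.005
    seq_weight_identity: float = 0.8
    apc: bool = True
    pseudocount: float = 1.0
    max_iter: int = 50
    tol: float = 1e-3

    def __post_init__(self):
        if not 0.0 <= self.shrinkage_lambda <= 1.0:
            raise ConfigError("shrinkage_lambda outside [0,1]")
        if self.sparsity_rho <= 0:
            raise ConfigError("sparsity_rho must be > 0")
        if not 0.0 < self.seq_weight_identity < 1.0:
            raise ConfigError("seq_weight_identity outside (0,1)")


def _encode_msa(msa: MsaBlock) -> np.ndarray:
    """Rows as integer states: 0..19 amino acids, 20 = gap/unknown."""
    lut = np.full(128, 20, dtype=np.int8)
    for aa, idx in AA_INDEX.items():
        lut[ord(aa)] = idx
    mat = np.frombuffer("".join(msa.rows).encode(), dtype=np.uint8)
    return lut[mat].reshape(msa.depth, msa.width)


def sequence_weights(encoded: np.ndarray, identity: float = 0.8) -> np.ndarray:
    """1 / (number of rows within ``identity`` fractional identity)."""
    n, L = encoded.shape
    counts = np.ones(n)
    for i in range(n):
        same = (encoded == encoded[i]).mean(axis=1)
        counts[i] = np.sum(same >= identity)
    return 1.0 / counts


def apply_apc(scores: np.ndarray, unmasked: np.ndarray) -> np.ndarray:
    """Average-product correction over the unmasked pairs."""
    s = np.where(unmasked, scores, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(s, axis=1)
        total_mean = np.nanmean(s)
    row_mean = np.nan_to_num(row_mean)
    if total_mean == 0 or not np.isfinite(total_mean):
        return np.where(unmasked, scores, 0.0)
    corrected = scores - np.outer(row_mean, row_mean) / total_mean
    return np.where(unmasked, corrected, 0.0)


def coevolution_scores(
    msa: MsaBlock,
    config: CoevolutionConfig | None = None,
    record_id: str | None = None,
) -> ContactMap:
    """Sparse-inverse-covariance coevolution scores from an alignment.

    Pipeline: sequence weighting -> pseudocounted weighted frequencies
    over 21 states -> 20L x 20L indicator covariance (gap dropped as the
    reference category) -> shrinkage toward the diagonal -> graphical
    lasso -> L1 norm of each 20 x 20 precision block -> optional APC.
    """
    config = config or CoevolutionConfig()
    if msa.depth < 2:
        raise InsufficientAlignmentError(f"alignment depth {msa.depth} < 2")
    enc = _encode_msa(msa)
    n, L = enc.shape
    w = sequence_weights(enc, config.seq_weight_identity)
    w_eff = w.sum()
    pc = config.pseudocount

    # one-hot over 21 states, weighted; the gap state is dropped as the
    # indicator reference category before the covariance
    q = 21
    onehot = np.zeros((n, L, q))
    rows = np.repeat(np.arange(n), L)
    cols = np.tile(np.arange(L), n)
    onehot[rows, cols, enc.ravel()] = 1.0

    # pseudocounted frequencies (reported in metadata); the covariance
    # itself is the pure weighted empirical one so that an alignment
    # with no variation yields an exactly-zero signal
    f1 = (pc / q + np.einsum("s,sia->ia", w, onehot)) / (pc + w_eff)

    X = onehot[:, :, :20].reshape(n, L * 20)
    wf = w[:, None] * X
    f2_emp = (X.T @ wf) / w_eff
    mean_emp = (w @ X) / w_eff
    C = f2_emp - np.outer(mean_emp, mean_emp)

    lam = config.shrinkage_lambda
    C = (1.0 - lam) * C + lam * np.diag(np.diag(C))
    ridge = 1e-6 * (1.0 + float(np.mean(np.diag(C))))
    C[np.diag_indices_from(C)] += ridge

    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _, precision = graphical_lasso(
                C, alpha=config.sparsity_rho, max_iter=config.max_iter,
                tol=config.tol, enet_tol=1e-4,
            )
        if any("did not converge" in str(w.message) for w in caught):
            converged = False
    except FloatingPointError:
        converged = False
        precision = np.linalg.pinv(C)
    if not converged:
        warnings.warn("sparse precision estimation stopped before full "
                      "convergence; returning the best iterate", stacklevel=2)

    blocks = np.abs(precision).reshape(L, 20, L, 20)
    raw = blocks.sum(axis=(1, 3))
    raw = 0.5 * (raw + raw.T)
    np.fill_diagonal(raw, 0.0)

    cmap = ContactMap(
        record_id=record_id or (msa.ids[0] if msa.ids else "msa"),
        scores=raw,
        metadata={"converged": converged, "apc": config.apc,
                  "effective_depth": float(w_eff),
                  "frequencies": f1},
    )
    if config.apc:
        corrected = apply_apc(raw, cmap.unmasked())
        corrected = 0.5 * (corrected + corrected.T)
        cmap.scores = corrected
    else:
        cmap.scores = np.where(cmap.unmasked(), raw, 0.0)
    return cmap


# ---------------------------------------------------------------------------
# supervised engine
# ---------------------------------------------------------------------------

PAIR_WINDOW = 7


def _helix_relative_position(topology: Topology | None, pos: int) -> float:
    """Relative position in [0,1] within the helix containing 1-based pos."""
    if topology is None:
        return 0.0
    for seg in topology.segments:
        if seg.start <= pos <= seg.end:
            if seg.length == 1:
                return 0.5
            return (pos - seg.start) / (seg.length - 1)
    return 0.0


def _helix_index(topology: Topology | None, pos: int) -> int:
    if topology is None:
        return -1
    for hi, seg in enumerate(topology.segments):
        if seg.start <= pos <= seg.end:
            return hi
    return -1


def pair_features(
    profile: Profile,
    i: int,
    j: int,
    topology: Topology | None = None,
) -> np.ndarray:
    """Symmetric feature vector for a 1-based residue pair (i, j).

    Two W=7 scaled-profile windows (canonically ordered so that
    (i,j) and (j,i) are identical), the sequence separation, and the two
    within-helix relative positions (0 when no topology is supplied).
    """
    if i == j:
        raise InputError("pair features need two distinct residues")
    a, b = (i, j) if i < j else (j, i)
    if topology is not None:
        ha, hb = _helix_index(topology, a), _helix_index(topology, b)
        if ha >= 0 and ha == hb:
            raise InputError(f"pair ({a},{b}) lies within a single helix")
    wa = window_features(profile, a, PAIR_WINDOW)
    wb = window_features(profile, b, PAIR_WINDOW)
    # sequence separation scaled by L so it cannot swamp the window
    # blocks in the instance-based Euclidean metric
    extras = np.array([
        float(b - a) / profile.length,
        _helix_relative_position(topology, a),
        _helix_relative_position(topology, b),
    ])
    return np.concatenate([wa, wb, extras])


@dataclass
class ContactEnsemble:
    """Mean of OET-KNN members, each trained on an under-sampled draw."""

    members: list[OetknnModel]

    def score(self, X: np.ndarray) -> np.ndarray:
        return np.mean([classify_batch(m, X) for m in self.members], axis=0)


def train_contact_ensemble(
    features: np.ndarray,
    labels: np.ndarray,
    n_models: int = 10,
    undersample_ratio: float = 1.0,
    seed: int = 0,
    k: int = 11,
    alpha0: float = 0.95,
) -> ContactEnsemble:
    """All positives + an independent seeded negative draw per member."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0:
        raise TrainingError("no positive contact pairs in the training data")
    if len(neg) == 0:
        raise TrainingError("no negative contact pairs in the training data")
    rng = np.random.default_rng(seed)
    n_neg = max(1, int(round(len(pos) * undersample_ratio)))
    members = []
    for m in range(n_models):
        draw = rng.choice(neg, size=min(n_neg, len(neg)),
                          replace=n_neg > len(neg))
        idx = np.concatenate([pos, draw])
        k_m = min(k, len(pos), len(draw))
        members.append(
            train_oetknn(X[idx], y[idx], k=k_m, alpha0=alpha0,
                         seed=int(rng.integers(2**31)))
        )
    return ContactEnsemble(members=members)


def ml_contact_map(
    profile: Profile,
    ensemble: ContactEnsemble,
    topology: Topology | None = None,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    record_id: str | None = None,
) -> ContactMap:
    """Score every unmasked pair of a sequence with the trained ensemble."""
    L = profile.length
    tmask = tmh_pair_mask(topology, L) if topology is not None else None
    scores = np.zeros((L, L))
    pairs, feats = [], []
    for a in range(1, L + 1):
        for b in range(a + min_separation, L + 1):
            if tmask is not None and not tmask[a - 1, b - 1]:
                continue
            pairs.append((a, b))
            feats.append(pair_features(profile, a, b, topology))
    if pairs:
        vals = ensemble.score(np.asarray(feats))
        for (a, b), v in zip(pairs, vals):
            scores[a - 1, b - 1] = scores[b - 1, a - 1] = v
    return ContactMap(
        record_id=record_id or profile.record_id,
        scores=scores,
        tmh_mask=tmask,
        min_separation=min_separation,
    )


# ---------------------------------------------------------------------------
# fusion and evaluation
# ---------------------------------------------------------------------------

def _rank_normalize(scores: np.ndarray, unmasked: np.ndarray) -> np.ndarray:
    iu = np.triu_indices_from(scores, k=1)
    sel = unmasked[iu]
    vals = scores[iu][sel]
    out = np.zeros_like(scores)
    if len(vals) == 0:
        return out
    r = rankdata(vals, method="average")
    r = (r - 1.0) / (len(vals) - 1.0) if len(vals) > 1 else np.ones_like(r)
    flat = np.zeros(len(sel))
    flat[sel] = r
    out[iu] = flat
    out = out + out.T
    return out


def fuse_contact_maps(coevo: ContactMap, ml: ContactMap, weight: float = 0.5) -> ContactMap:
    """Weighted average of the two rank-normalized score matrices."""
    if not 0.0 <= weight <= 1.0:
        raise InputError(f"fusion weight {weight} outside [0,1]")
    if coevo.length != ml.length:
        raise InputError("contact maps differ in length")
    if not np.array_equal(coevo.unmasked(), ml.unmasked()):
        raise InputError("contact maps differ in masking")
    unm = coevo.unmasked()
    fused = weight * _rank_normalize(coevo.scores, unm) \
        + (1.0 - weight) * _rank_normalize(ml.scores, unm)
    return ContactMap(
        record_id=coevo.record_id,
        scores=np.where(unm, fused, 0.0),
        truth=coevo.truth if coevo.truth is not None else ml.truth,
        tmh_mask=coevo.tmh_mask,
        min_separation=coevo.min_separation,
        metadata={"fusion_weight": weight},
    )


def ranked_pairs(cmap: ContactMap) -> list[tuple[int, int, float]]:
    """Unmasked upper-triangle pairs sorted by descending score, ties
    broken lexicographically by (i, j); 0-based indices."""
    unm = cmap.unmasked()
    iu = np.triu_indices_from(cmap.scores, k=1)
    out = [
        (int(i), int(j), float(cmap.scores[i, j]))
        for i, j in zip(*iu)
        if unm[i, j]
    ]
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def top_k_accuracy(cmap: ContactMap, k: int) -> float:
    """Precision among the k highest-scoring unmasked pairs."""
    if cmap.truth is None:
        raise InputError("contact map has no truth layer")
    if k < 1:
        raise InputError("k must be >= 1")
    top = ranked_pairs(cmap)[:k]
    if not top:
        raise InputError("no unmasked pairs to rank")
    hits = sum(int(cmap.truth[i, j]) for i, j, _ in top)
    return hits / len(top)
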