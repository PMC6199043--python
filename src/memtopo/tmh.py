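"""Propensity track -> helix topology: median smoothing, dynamic-threshold
segmentation, and the four segment-level evaluation metrics."""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .errors import ConfigError, InputError
from .propensity import PropensityTrack


@dataclass(frozen=True, order=True)
class TmhSegment:
    """1-based inclusive residue interval."""

    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise InputError(f"invalid segment ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "TmhSegment") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class Topology:
    """Ordered, pairwise-disjoint helix intervals over one sequence."""

    record_id: str
    segments: list[TmhSegment]

    def __post_init__(self):
        segs = sorted(self.segments)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end + 1:
                # require >= 1 residue gap between consecutive helices
                raise InputError(
                    f"'{self.record_id}': segments ({a.start},{a.end}) and "
                    f"({b.start},{b.end}) overlap or touch"
                )
        self.segments = segs

    def __len__(self) -> int:
        return len(self.segments)

    def residue_labels(self, L: int) -> np.ndarray:
        lab = np.zeros(L, dtype=int)
        for seg in self.segments:
            lab[seg.start - 1 : seg.end] = 1
        return lab


@dataclass
class SegmenterConfig:
    initial_threshold: float = 0.4
    step: float = 0.05
    max_threshold: float = 0.95
    min_tmh_length: int = 5
    median_window: int = 5
    split_valley_depth: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.initial_threshold < self.max_threshold <= 1.0:
            raise ConfigError(
                f"need 0 < T0 < max_threshold <= 1, got "
                f"({self.initial_threshold}, {self.max_threshold})"
            )
        if self.step <= 0:
            raise ConfigError("step must be positive")
        if self.median_window % 2 == 0:
            raise ConfigError("median_window must be odd")
        if self.min_tmh_length < 1:
            raise ConfigError("min_tmh_length must be >= 1")


@dataclass
class TmhEvalResult:
    a_tmh: float
    a_p: float
    n_score_mean: float
    n_score_sd: float
    c_score_mean: float
    c_score_sd: float
    n_observed: int = 0
    n_predicted: int = 0
    n_matched: int = 0


def median_filter(track: PropensityTrack, window: int = 5) -> PropensityTrack:
    """Running median with windows shrunk at the termini (no fabricated
    values); idempotent on constant tracks."""
    if window % 2 == 0:
        raise ConfigError(f"median window must be odd, got {window}")
    v = track.values
    L = len(v)
    half = (window - 1) // 2
    out = np.empty(L)
    for i in range(L):
        lo = max(0, i - half)
        hi = min(L, i + half + 1)
        out[i] = np.median(v[lo:hi])
    return PropensityTrack(record_id=track.record_id, values=out)


def threshold_segments(track: PropensityTrack, T: float) -> list[TmhSegment]:
    """Maximal runs of positions with value >= T (inclusive comparison)."""
    if not 0.0 < T < 1.0:
        raise InputError(f"threshold {T} outside (0,1)")
    above = track.values >= T
    segments = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append(TmhSegment(start=start + 1, end=i))
            start = None
    if start is not None:
        segments.append(TmhSegment(start=start + 1, end=len(above)))
    return segments


def _subtrack(track: PropensityTrack, seg: TmhSegment) -> PropensityTrack:
    return PropensityTrack(record_id=track.record_id,
                           values=track.values[seg.start - 1 : seg.end])


def dynamic_split(
    segment: TmhSegment,
    track: PropensityTrack,
    config: SegmenterConfig,
) -> list[TmhSegment]:
    """Recursively split a merged segment at an interior propensity valley.

    The threshold is raised from T0 in ``step`` increments; the first
    level at which the segment separates into >= 2 pieces, each at
    least ``min_tmh_length`` long, with the interior minimum lying at
    least ``split_valley_depth`` below that level, is accepted and the
    pieces are recursed on.  If no level qualifies the segment is
    returned unchanged.
    """
    values = track.values[segment.start - 1 : segment.end]
    interior_min = float(values.min())
    level = config.initial_threshold + config.step
    sub = _subtrack(track, segment)
    while level <= config.max_threshold + 1e-9:
        T = min(level, 1.0 - 1e-12)
        pieces = threshold_segments(sub, T)
        if (
            len(pieces) >= 2
            and all(p.length >= config.min_tmh_length for p in pieces)
            and interior_min < level - config.split_valley_depth
        ):
            out = []
            for p in pieces:
                shifted = TmhSegment(start=segment.start + p.start - 1,
                                     end=segment.start + p.end - 1)
                out.extend(dynamic_split(shifted, track, config))
            return out
        level += config.step
    return [segment]


def segment_track(track: PropensityTrack, config: SegmenterConfig | None = None) -> Topology:
    """Full segmentation: initial threshold, dynamic split, length filter."""
    config = config or SegmenterConfig()
    initial = threshold_segments(track, config.initial_threshold)
    segments: list[TmhSegment] = []
    for seg in initial:
        segments.extend(dynamic_split(seg, track, config))
    segments = [s for s in segments if s.length >= config.min_tmh_length]
    return Topology(record_id=track.record_id, segments=segments)


def _match_pairs(predicted: Topology, observed: Topology):
    """Greedy one-to-one matching in sequence order.

    An observed helix matches a predicted one when they overlap by at
    least min(5, ceil(len_observed / 2)) residues.
    """
    used_pred: set[int] = set()
    pairs = []
    for obs in observed.segments:
        need = min(5, ceil(obs.length / 2))
        for pi, pred in enumerate(predicted.segments):
            if pi in used_pred:
                continue
            if pred.overlap(obs) >= need:
                used_pred.add(pi)
                pairs.append((pred, obs))
                break
    return pairs


def evaluate_topology(predicted: Topology, observed: Topology) -> TmhEvalResult:
    """Segment-level accuracy and end-placement scores for one protein."""
    if predicted.record_id != observed.record_id:
        raise InputError(
            f"record mismatch: '{predicted.record_id}' vs '{observed.record_id}'"
        )
    pairs = _match_pairs(predicted, observed)
    n_obs = len(observed.segments)
    n_pred = len(predicted.segments)
    n_matched = len(pairs)
    a_tmh = n_matched / n_obs if n_obs else 1.0
    protein_correct = (n_matched == n_obs) and (n_pred == n_obs)
    n_offsets = np.array([abs(p.start - o.start) for p, o in pairs], dtype=float)
    c_offsets = np.array([abs(p.end - o.end) for p, o in pairs], dtype=float)

    def _stats(x):
        if len(x) == 0:
            return 0.0, 0.0
        return float(np.mean(x)), float(np.std(x))

    n_mean, n_sd = _stats(n_offsets)
    c_mean, c_sd = _stats(c_offsets)
    return TmhEvalResult(
        a_tmh=a_tmh,
        a_p=1.0 if protein_correct else 0.0,
        n_score_mean=n_mean,
        n_score_sd=n_sd,
        c_score_mean=c_mean,
        c_score_sd=c_sd,
        n_observed=n_obs,
        n_predicted=n_pred,
        n_matched=n_matched,
    )


def evaluate_topologies(pairs: list[tuple[Topology, Topology]]) -> TmhEvalResult:
    """Corpus-level aggregation of (predicted, observed) topology pairs."""
    if not pairs:
        raise InputError("no topology pairs to evaluate")
    total_obs = total_pred = total_matched = correct_proteins = 0
    n_offsets: list[float] = []
    c_offsets: list[float] = []
    for predicted, observed in pairs:
        matched = _match_pairs(predicted, observed)
        total_obs += len(observed.segments)
        total_pred += len(predicted.segments)
        total_matched += len(matched)
        if len(matched) == len(observed.segments) == len(predicted.segments):
            correct_proteins += 1
        n_offsets.extend(abs(p.start - o.start) for p, o in matched)
        c_offsets.extend(abs(p.end - o.end) for p, o in matched)
    n_off = np.asarray(n_offsets, dtype=float)
    c_off = np.asarray(c_offsets, dtype=float)
    return TmhEvalResult(
        a_tmh=total_matched / total_obs if total_obs else 1.0,
        a_p=correct_proteins / len(pairs),
        n_score_mean=float(np.mean(n_off)) if len(n_off) else 0.0,
        n_score_sd=float(np.std(n_off)) if len(n_off) else 0.0,
        c_score_mean=float(np.mean(c_off)) if len(c_off) else 0.0,
        c_score_sd=float(np.std(c_off)) if len(c_off) else 0.0,
        n_observed=total_obs,
        n_predicted=total_pred,
        n_matched=total_matched,
    )
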