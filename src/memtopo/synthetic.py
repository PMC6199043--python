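"""Seeded synthetic corpora with the statistical structure each engine assumes.

Three generators: membrane-protein sequences with known helix topology,
alignments with planted covarying column pairs, and per-residue relative
accessibility tracks with helical periodicity.  Every label returned is
the generative truth, never re-derived from the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .seqio import AA_ORDER, MsaBlock, SequenceRecord
from .tmh import TmhSegment, Topology

#: Kyte-Doolittle hydropathy scale, keyed in PSSM column order.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
KD_VECTOR = np.array([KYTE_DOOLITTLE[a] for a in AA_ORDER])

#: Background amino-acid composition used for unplanted MSA columns.
from .seqio import BACKGROUND_FREQUENCIES as BACKGROUND_COMPOSITION

#: Sidechain-compatible residue pairs used to plant covariation.
COMPATIBLE_STATES = [
    ("A", "L"), ("I", "V"), ("F", "W"), ("K", "E"),
    ("D", "R"), ("S", "T"), ("G", "N"), ("Y", "H"),
]

_TMH_WEIGHTS = np.exp(KD_VECTOR / 2.0)
_TMH_WEIGHTS /= _TMH_WEIGHTS.sum()
_LOOP_WEIGHTS = np.exp(-KD_VECTOR / 2.0)
_LOOP_WEIGHTS /= _LOOP_WEIGHTS.sum()

_AA = np.array(list(AA_ORDER))


@dataclass
class TopologyGeneratorConfig:
    """Knobs for the membrane-protein corpus generator."""

    n_proteins: int = 100
    loop_length_range: tuple[int, int] = (1, 30)
    tmh_length_core: tuple[int, int] = (17, 28)
    p_half_tmh: float = 0.1
    p_long_tmh: float = 0.05
    half_tmh_range: tuple[int, int] = (8, 12)
    long_tmh_range: tuple[int, int] = (36, 45)
    n_tmh_range: tuple[int, int] = (1, 7)
    seed: int = 0

    def __post_init__(self):
        for name in ("loop_length_range", "tmh_length_core", "half_tmh_range",
                     "long_tmh_range", "n_tmh_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ConfigError(f"{name}: empty or negative interval ({lo},{hi})")
        if self.loop_length_range[0] < 1:
            raise ConfigError("loop_length_range minimum must be >= 1")
        for name in ("p_half_tmh", "p_long_tmh"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}: probability {p} outside [0,1]")
        if self.p_half_tmh + self.p_long_tmh > 1.0:
            raise ConfigError("p_half_tmh + p_long_tmh exceeds 1")
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be positive")
        if self.n_tmh_range[0] < 1:
            raise ConfigError("n_tmh_range minimum must be >= 1")


def _draw_tmh_length(rng: np.random.Generator, cfg: TopologyGeneratorConfig) -> int:
    u = rng.random()
    if u < cfg.p_half_tmh:
        lo, hi = cfg.half_tmh_range
    elif u < cfg.p_half_tmh + cfg.p_long_tmh:
        lo, hi = cfg.long_tmh_range
    else:
        lo, hi = cfg.tmh_length_core
    return int(rng.integers(lo, hi + 1))


def generate_membrane_protein_corpus(
    cfg: TopologyGeneratorConfig,
) -> list[tuple[SequenceRecord, Topology]]:
    """Alternating loop/helix architectures with composition-coded helices.

    Helix residues are drawn with weights proportional to exp(KD/2) over
    the Kyte-Doolittle scale, loops from the complementary exp(-KD/2)
    distribution, so helices are recoverable from local composition —
    the signal the propensity classifier exploits.
    """
    rng = np.random.default_rng(cfg.seed)
    corpus = []
    for n in range(cfg.n_proteins):
        n_tmh = int(rng.integers(cfg.n_tmh_range[0], cfg.n_tmh_range[1] + 1))
        parts: list[str] = []
        segments: list[TmhSegment] = []
        pos = 0

        def _loop_len() -> int:
            return int(rng.integers(cfg.loop_length_range[0],
                                    cfg.loop_length_range[1] + 1))

        loop0 = _loop_len()
        parts.append("".join(rng.choice(_AA, size=loop0, p=_LOOP_WEIGHTS)))
        pos += loop0
        for h in range(n_tmh):
            tl = _draw_tmh_length(rng, cfg)
            parts.append("".join(rng.choice(_AA, size=tl, p=_TMH_WEIGHTS)))
            segments.append(TmhSegment(start=pos + 1, end=pos + tl))
            pos += tl
            ll = _loop_len()
            parts.append("".join(rng.choice(_AA, size=ll, p=_LOOP_WEIGHTS)))
            pos += ll
        record = SequenceRecord(id=f"syn{n:05d}", residues="".join(parts))
        corpus.append((record, Topology(record_id=record.id, segments=segments)))
    return corpus


def generate_planted_contact_msa(
    L: int,
    depth: int,
    n_pairs: int,
    coupling: float,
    seed: int,
    gap_rate: float = 0.0,
    min_separation: int = 5,
) -> tuple[MsaBlock, set[tuple[int, int]]]:
    """Alignment with ``n_pairs`` covarying column pairs planted in it.

    Unplanted columns are i.i.d. from the background composition.  For a
    planted pair, each row's two residues are drawn jointly from a fixed
    8-entry compatible-state list with probability ``coupling`` (both
    orientations equally likely), otherwise independently from the
    background.  Pair columns are returned 0-based, i < j.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ConfigError(f"coupling {coupling} outside [0,1]")
    if n_pairs > L // 2:
        raise ConfigError(f"n_pairs={n_pairs} exceeds L/2={L // 2}")
    if not 0.0 <= gap_rate < 1.0:
        raise ConfigError(f"gap_rate {gap_rate} outside [0,1)")
    rng = np.random.default_rng(seed)

    # sample disjoint column pairs with the required sequence separation
    pairs: set[tuple[int, int]] = set()
    used: set[int] = set()
    attempts = 0
    while len(pairs) < n_pairs:
        attempts += 1
        if attempts > 10_000 * n_pairs:
            raise ConfigError(
                "could not place the requested planted pairs; "
                "relax n_pairs or min_separation"
            )
        i, j = sorted(int(v) for v in rng.choice(L, size=2, replace=False))
        if j - i < min_separation or i in used or j in used:
            continue
        pairs.add((i, j))
        used.update((i, j))

    aln = rng.choice(_AA, size=(depth, L), p=BACKGROUND_COMPOSITION)
    state_idx = {a: k for k, a in enumerate(AA_ORDER)}
    for (i, j) in pairs:
        coupled = rng.random(depth) < coupling
        which = rng.integers(0, len(COMPATIBLE_STATES), size=depth)
        flip = rng.random(depth) < 0.5
        for r in np.flatnonzero(coupled):
            a, b = COMPATIBLE_STATES[which[r]]
            if flip[r]:
                a, b = b, a
            aln[r, i] = a
            aln[r, j] = b
        # uncoupled rows keep their independent background draws
    if gap_rate > 0:
        gaps = rng.random(aln.shape) < gap_rate
        aln[gaps] = "-"
    rows = ["".join(row) for row in aln]
    ids = [f"row{r:04d}" for r in range(depth)]
    return MsaBlock(ids=ids, rows=rows), pairs


HELIX_PERIOD = 3.6  # residues per alpha-helical turn


def generate_rasa_corpus(
    corpus: list[tuple[SequenceRecord, Topology]],
    noise_sd: float,
    seed: int,
):
    """Ground-truth accessibility tracks for a generated corpus.

    Helix residues follow a clamped sinusoid with the alpha-helical
    period (lipid-facing vs. buried faces), a random phase per helix and
    Gaussian noise; loop residues sit at a high exposed baseline.
    """
    from .rasa import RasaTrack  # deferred: rasa imports nothing from here

    if noise_sd < 0:
        raise ConfigError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = np.random.default_rng(seed)
    tracks = []
    for record, topo in corpus:
        L = len(record)
        values = 70.0 + rng.normal(0.0, noise_sd, size=L) if noise_sd > 0 else np.full(L, 70.0)
        for seg in topo.segments:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            idx = np.arange(seg.start, seg.end + 1)
            helix = 45.0 + 35.0 * np.sin(2.0 * np.pi * idx / HELIX_PERIOD + phase)
            if noise_sd > 0:
                helix = helix + rng.normal(0.0, noise_sd, size=len(idx))
            values[seg.start - 1 : seg.end] = helix
        values = np.clip(values, 0.0, 100.0)
        tracks.append(RasaTrack(record_id=record.id, values=values))
    return tracks
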