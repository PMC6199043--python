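"""Readers and writers for every on-disk format the toolkit touches.

No science lives here: only faithful parsing, validation and
serialization.  All on-disk coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO as _BioSeqIO

from .errors import (
    EmptyInputError,
    InputError,
    InsufficientAlignmentError,
    ParseError,
)

#: Fixed column order of the PSSM dialect.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
#: Residue alphabet accepted in sequences ('X' = unknown).
ALPHABET = set(AA_ORDER) | {"X"}
#: Alignment alphabet (adds the gap character).
MSA_ALPHABET = ALPHABET | {"-"}

#: Background amino-acid composition (Robinson & Robinson), PSSM column order.
BACKGROUND_FREQUENCIES = np.array([
    0.0780, 0.0512, 0.0448, 0.0536, 0.0192, 0.0426, 0.0629, 0.0738, 0.0219,
    0.0514, 0.0901, 0.0574, 0.0224, 0.0385, 0.0520, 0.0712, 0.0584, 0.0132,
    0.0321, 0.0644,
])
BACKGROUND_FREQUENCIES = BACKGROUND_FREQUENCIES / BACKGROUND_FREQUENCIES.sum()


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence over the 20-letter alphabet plus 'X'."""

    id: str
    residues: str

    def __post_init__(self):
        bad = [i for i, c in enumerate(self.residues) if c not in ALPHABET]
        if bad:
            raise ParseError(
                f"record '{self.id}': illegal residue "
                f"'{self.residues[bad[0]]}' at position {bad[0] + 1}"
            )
        if not self.residues:
            raise ParseError(f"record '{self.id}': empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Profile:
    """Per-sequence L x 20 evolutionary scoring matrix.

    ``raw`` holds log-odds scores (or pseudo-probabilities); ``scaled``
    is the elementwise logistic map of ``raw`` into (0, 1).  Column
    order is :data:`AA_ORDER`.
    """

    record_id: str
    raw: np.ndarray
    source: str = "pssm_file"
    scaled: np.ndarray = field(init=False)

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != 20:
            raise InputError(
                f"profile for '{self.record_id}': expected L x 20 matrix, "
                f"got shape {self.raw.shape}"
            )
        if not np.all(np.isfinite(self.raw)):
            raise InputError(f"profile for '{self.record_id}': non-finite entry")
        self.scaled = scale_profile(self.raw)

    @property
    def length(self) -> int:
        return self.raw.shape[0]


@dataclass
class MsaBlock:
    """An aligned FASTA block: equal-length gapped rows, query first."""

    ids: list[str]
    rows: list[str]

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into validated records, in file order."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for rec in _BioSeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper().replace(" ", "")
            records.append(SequenceRecord(id=rec.id, residues=seq))
    if not records:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def scale_profile(raw: np.ndarray) -> np.ndarray:
    """Elementwise logistic map x -> 1/(1+exp(-x)); strictly monotone."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise InputError("scale_profile: non-finite entry in raw matrix")
    # expit without importing scipy here; overflow-safe piecewise form
    out = np.empty_like(raw)
    pos = raw >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-raw[pos]))
    ex = np.exp(raw[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def pseudo_profile(record: SequenceRecord, weight: float = 0.9) -> Profile:
    """Fallback profile when no PSSM is available (degraded mode).

    Row i puts mass ``weight`` on the observed residue and spreads the
    remainder uniformly over the other 19 columns; 'X' rows are uniform.
    The point-mass rows are stored in ``raw`` (and therefore logistic-
    scaled like any other profile downstream).
    """
    if not 0.0 < weight < 1.0:
        raise InputError(f"pseudo-profile weight must be in (0,1), got {weight}")
    L = len(record)
    raw = np.full((L, 20), (1.0 - weight) / 19.0)
    for i, c in enumerate(record.residues):
        if c == "X":
            raw[i, :] = 1.0 / 20.0
        else:
            raw[i, AA_INDEX[c]] = weight
    return Profile(record_id=record.id, raw=raw, source="pseudo")


def read_pssm(path: str | Path, record: SequenceRecord | None = None) -> Profile:
    """Parse a PSI-BLAST ASCII PSSM (log-odds block only).

    Only the first 20 numeric columns of each row are consumed; the
    optional percentage block and trailing statistics are ignored.  If
    ``record`` is given, row letters are cross-checked against it.
    """
    path = Path(path)
    rows: list[list[float]] = []
    letters: list[str] = []
    record_id = record.id if record is not None else path.stem
    n_tok: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if len(tok) < 22:
                continue
            if not tok[0].isdigit():
                continue
            # rows must agree in token count; a short row (e.g. 19
            # log-odds columns) would otherwise swallow trailing
            # statistics silently
            if n_tok is None:
                n_tok = len(tok)
            elif len(tok) != n_tok:
                raise ParseError(
                    f"inconsistent column count ({len(tok)} tokens, "
                    f"expected {n_tok})",
                    path=str(path),
                    line=lineno,
                )
            pos = int(tok[0])
            letter = tok[1]
            if len(letter) != 1 or letter.upper() not in MSA_ALPHABET:
                continue
            cells = tok[2:22]
            try:
                values = [float(c) for c in cells]
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric PSSM cell ({exc})", path=str(path), line=lineno
                ) from None
            if pos != len(rows) + 1:
                raise ParseError(
                    f"unexpected position index {pos} (expected {len(rows) + 1})",
                    path=str(path),
                    line=lineno,
                )
            # a short row would have swallowed trailing statistics columns;
            # detect by checking the tail really had 20 numerics
            if len(values) != 20:
                raise ParseError(
                    f"expected 20 log-odds columns, found {len(values)}",
                    path=str(path),
                    line=lineno,
                )
            rows.append(values)
            letters.append(letter.upper())
    if not rows:
        raise ParseError("no PSSM rows found", path=str(path))
    if record is not None:
        if len(rows) != len(record):
            raise ParseError(
                f"PSSM has {len(rows)} rows but sequence '{record.id}' has "
                f"{len(record)} residues",
                path=str(path),
            )
        for i, (a, b) in enumerate(zip(letters, record.residues)):
            if a != b and a != "X" and b != "X":
                raise ParseError(
                    f"PSSM residue '{a}' at position {i + 1} disagrees with "
                    f"sequence residue '{b}'",
                    path=str(path),
                )
    return Profile(record_id=record_id, raw=np.array(rows), source="pssm_file")


def write_pssm(profile: Profile, record: SequenceRecord, path: str | Path) -> None:
    """Write a profile in the ASCII PSSM layout accepted by :func:`read_pssm`."""
    if profile.length != len(record):
        raise InputError("profile length does not match record length")
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(AA_ORDER) + "\n")
        for i, (row, letter) in enumerate(zip(profile.raw, record.residues), start=1):
            cells = " ".join(f"{v:7.3f}" for v in row)
            # two trailing statistics columns, ignored by the reader
            fh.write(f"{i:5d} {letter} {cells}   0.00 0.00\n")


def read_msa(path: str | Path) -> MsaBlock:
    """Read an aligned FASTA block; all rows must share one width."""
    path = Path(path)
    ids, rows = [], []
    with open(path) as fh:
        for rec in _BioSeqIO.parse(fh, "fasta"):
            row = str(rec.seq).upper()
            bad = [c for c in row if c not in MSA_ALPHABET]
            if bad:
                raise ParseError(
                    f"row '{rec.id}': illegal alignment character '{bad[0]}'",
                    path=str(path),
                )
            ids.append(rec.id)
            rows.append(row)
    if not rows:
        raise EmptyInputError(f"{path}: no alignment rows found")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ParseError(
            f"unequal alignment row lengths {sorted(widths)}", path=str(path)
        )
    if len(rows) < 2:
        raise InsufficientAlignmentError(
            f"{path}: alignment depth {len(rows)} < 2"
        )
    return MsaBlock(ids=ids, rows=rows)


def write_msa(block: MsaBlock, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(block.ids, block.rows):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# prediction tables (TSV)
# ---------------------------------------------------------------------------

def write_propensity_tsv(
    record: SequenceRecord,
    raw_values: Sequence[float],
    smoothed_values: Sequence[float],
    labels: Sequence[int],
    path: str | Path,
) -> None:
    """Per-residue table: position, residue, propensity, smoothed, label."""
    L = len(record)
    if not (len(raw_values) == len(smoothed_values) == len(labels) == L):
        raise InputError("track lengths do not match sequence length")
    with open(path, "w") as fh:
        fh.write("position\tresidue\tpropensity\tsmoothed\tlabel\n")
        for i in range(L):
            fh.write(
                f"{i + 1}\t{record.residues[i]}\t{raw_values[i]:.6f}\t"
                f"{smoothed_values[i]:.6f}\t{int(labels[i])}\n"
            )


def read_propensity_tsv(path: str | Path) -> dict[str, np.ndarray]:
    data = np.genfromtxt(path, delimiter="\t", names=True, dtype=None, encoding=None)
    data = np.atleast_1d(data)
    return {
        "position": data["position"].astype(int),
        "residue": data["residue"].astype(str),
        "propensity": data["propensity"].astype(float),
        "smoothed": data["smoothed"].astype(float),
        "label": data["label"].astype(int),
    }


def write_intervals_tsv(topologies, path: str | Path) -> None:
    """Interval list: record id, start, end (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("record_id\tstart\tend\n")
        for topo in topologies:
            for seg in topo.segments:
                fh.write(f"{topo.record_id}\t{seg.start}\t{seg.end}\n")


def read_intervals_tsv(path: str | Path):
    """Read an interval list back into Topology objects (file order)."""
    from .tmh import TmhSegment, Topology  # local import avoids cycle at module load

    per_record: dict[str, list[TmhSegment]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("record_id"):
            raise ParseError("missing interval header", path=str(path), line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            tok = line.rstrip("\n").split("\t")
            if len(tok) != 3:
                raise ParseError("expected 3 columns", path=str(path), line=lineno)
            rid, start, end = tok[0], int(tok[1]), int(tok[2])
            if rid not in per_record:
                per_record[rid] = []
                order.append(rid)
            per_record[rid].append(TmhSegment(start=start, end=end))
    return [Topology(record_id=rid, segments=per_record[rid]) for rid in order]


def write_contacts_tsv(contact_map, path: str | Path) -> None:
    """Upper-triangle contact scores, descending: i, j, score with i<j."""
    scores = contact_map.scores
    L = scores.shape[0]
    pairs = []
    for i in range(L):
        for j in range(i + 1, L):
            if contact_map.is_masked(i, j):
                continue
            pairs.append((i + 1, j + 1, scores[i, j]))
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("i\tj\tscore\n")
        for i, j, s in pairs:
            fh.write(f"{i}\t{j}\t{s:.6g}\n")


def read_contacts_tsv(path: str | Path) -> list[tuple[int, int, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("i\t"):
            raise ParseError("missing contact header", path=str(path), line=1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            tok = line.rstrip("\n").split("\t")
            if len(tok) != 3:
                raise ParseError("expected 3 columns", path=str(path), line=lineno)
            i, j, s = int(tok[0]), int(tok[1]), float(tok[2])
            if i >= j:
                raise ParseError(f"expected i<j, got ({i},{j})", path=str(path), line=lineno)
            out.append((i, j, s))
    return out


def write_rasa_tsv(record: SequenceRecord, values: Sequence[float], path: str | Path,
                   engine_used: Sequence[str] | None = None,
                   similarity: Sequence[float] | None = None) -> None:
    L = len(record)
    if len(values) != L:
        raise InputError("rasa track length does not match sequence length")
    with open(path, "w") as fh:
        cols = ["position", "residue", "rasa"]
        if engine_used is not None:
            cols += ["engine", "similarity"]
        fh.write("\t".join(cols) + "\n")
        for i in range(L):
            row = f"{i + 1}\t{record.residues[i]}\t{values[i]:.4f}"
            if engine_used is not None:
                row += f"\t{engine_used[i]}\t{similarity[i]:.4f}"
            fh.write(row + "\n")


def read_rasa_tsv(path: str | Path) -> np.ndarray:
    vals = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("position"):
            raise ParseError("missing rasa header", path=str(path), line=1)
        for line in fh:
            if line.strip():
                vals.append(float(line.split("\t")[2]))
    return np.array(vals)


def profile_from_msa(block: MsaBlock, record_id: str | None = None,
                     pseudocount: float = 1.0) -> Profile:
    """Column log-odds (vs. background composition) of an alignment.

    Pseudocounted per-column frequencies are converted to log2 odds
    against :data:`BACKGROUND_FREQUENCIES`, mirroring the PSSM layout
    consumed everywhere else.  Gaps and unknowns are excluded from the
    per-column counts.
    """
    L = block.width
    counts = np.zeros((L, 20))
    for row in block.rows:
        for i, c in enumerate(row):
            k = AA_INDEX.get(c)
            if k is not None:
                counts[i, k] += 1.0
    totals = counts.sum(axis=1, keepdims=True)
    freq = (counts + pseudocount / 20.0) / (totals + pseudocount)
    raw = np.log2(freq / BACKGROUND_FREQUENCIES)
    rid = record_id or (block.ids[0] if block.ids else "msa")
    return Profile(record_id=rid, raw=raw, source="pseudo")


def profile_for(record: SequenceRecord, pssm_path: str | Path | None) -> Profile:
    """Load the record's PSSM if given, else fall back to a pseudo-profile."""
    if pssm_path is not None:
        return read_pssm(pssm_path, record=record)
    warnings.warn(
        f"no PSSM supplied for '{record.id}'; using pseudo-profile "
        "(degraded mode)",
        stacklevel=2,
    )
    return pseudo_profile(record)
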