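"""Position frequency matrices and log-odds scanning.

A transcription factor's binding preference is represented as a position
frequency matrix: one probability distribution over {A, C, G, T} per position
of the site.  Scores are log2 odds against an iid GC-content background, the
same scale used for border checks in the spatial scrambler and for score
density profiles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
# A=0, C=1, G=2, T=3, anything else (N, masked fill) = 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)

MAX_WIDTH = 30
DEFAULT_PSEUDOCOUNT = 1e-4


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def reverse_complement(seq: str) -> str:
    return decode(COMPLEMENT[encode(seq)[::-1]])


@dataclass(frozen=True)
class BackgroundModel:
    """iid background over {A,C,G,T} parameterised by GC fraction.

    A and T each get (1-gc)/2; C and G each get gc/2.  The default of 0.38
    matches the yeast intergenic GC content used throughout.
    """

    gc: float = 0.38

    def __post_init__(self):
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"gc must be in (0, 1), got {self.gc}")

    @property
    def probs(self) -> np.ndarray:
        at = (1.0 - self.gc) / 2.0
        cg = self.gc / 2.0
        return np.array([at, cg, cg, at])

    @property
    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position base distribution of a motif of width ``w``.

    ``probs`` has shape (w, 4); every row sums to one and is strictly
    positive (a pseudocount is applied at construction time).
    """

    probs: np.ndarray
    name: str = ""
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if not 1 <= p.shape[0] <= MAX_WIDTH:
            raise ValueError(f"width must be in [1, {MAX_WIDTH}], got {p.shape[0]}")
        if np.any(p < 0):
            raise ValueError("negative probabilities")
        sums = p.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("zero-sum matrix row")
        p = p / sums[:, None]
        p = p + self.pseudocount
        p = p / p.sum(axis=1)[:, None]
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)

    def reverse_complement(self) -> "FrequencyMatrix":
        return FrequencyMatrix(self.probs[::-1, ::-1], name=self.name + "_rc",
                               pseudocount=0.0)

    @classmethod
    def from_counts(cls, counts, name: str = "", pseudocount: float = 1.0
                    ) -> "FrequencyMatrix":
        """Build from a count table, adding ``pseudocount`` to every cell."""
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(c / c.sum(axis=1)[:, None], name=name, pseudocount=0.0)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))


def consensus_matrix(bases: str, strength: float = 0.88,
                     name: str = "") -> FrequencyMatrix:
    """Matrix concentrated on a consensus: ``strength`` at each consensus
    base, the remainder spread evenly over the other three."""
    w = len(bases)
    codes = encode(bases)
    if np.any(codes >= 4):
        raise ValueError("consensus must be unambiguous ACGT")
    probs = np.full((w, 4), (1.0 - strength) / 3.0)
    probs[np.arange(w), codes] = strength
    return FrequencyMatrix(probs, name=name or bases, pseudocount=0.0)


class MatrixParseError(ValueError):
    pass


def load_frequency_matrix(source, name: str = "",
                          pseudocount: float = DEFAULT_PSEUDOCOUNT
                          ) -> FrequencyMatrix:
    """Parse a whitespace table (one row per position, columns A C G T).

    Accepts either probabilities or counts; rows whose sums are far from one
    are treated as counts (normalised with a pseudocount of one per cell),
    probability rows get a small pseudocount to keep log-odds finite.
    ``source`` may be a path, a file object, or the table text itself.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        if "\n" in s or s.strip() == "":
            text = s
        else:
            try:
                with open(s) as fh:
                    text = fh.read()
            except OSError:
                text = s
    rows = []
    for lineno, line in enumerate(io.StringIO(text), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if all(f.upper() in ("A", "C", "G", "T", "POS", "PO") for f in fields):
            continue  # header row
        if len(fields) == 5 and all(_is_number(f) for f in fields[1:]):
            fields = fields[1:]  # leading position label
        if len(fields) != 4:
            raise MatrixParseError(
                f"line {lineno}: expected 4 columns (A C G T), got {len(fields)}")
        try:
            vals = [float(f) for f in fields]
        except ValueError as exc:
            raise MatrixParseError(f"line {lineno}: {exc}") from None
        if any(v < 0 for v in vals):
            raise MatrixParseError(f"line {lineno}: negative entry")
        if sum(vals) <= 0:
            raise MatrixParseError(f"line {lineno}: zero-sum row")
        rows.append(vals)
    if not rows:
        raise MatrixParseError("no matrix rows found")
    arr = np.array(rows)
    if np.all(np.abs(arr.sum(axis=1) - 1.0) < 0.05):
        return FrequencyMatrix(arr, name=name, pseudocount=pseudocount)
    return FrequencyMatrix.from_counts(arr, name=name, pseudocount=1.0)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_frequency_matrix(matrix: FrequencyMatrix, path) -> None:
    header = "A C G T\n"
    body = "\n".join(" ".join(f"{v:.6f}" for v in row) for row in matrix.probs)
    with open(path, "w") as fh:
        fh.write(header + body + "\n")


def _score_tables(matrix: FrequencyMatrix, bg: BackgroundModel,
                  base: float = 2.0, invalid: float = 0.0):
    """Per-position, per-base log-odds lookup tables for both orientations.

    Returns (fwd, rev) of shape (w, 5); column 4 is the contribution of an
    ambiguous base (0 for scanning, -inf when used to forbid site placement).
    """
    lm = matrix.log_probs / np.log(base)
    lbg = bg.log_probs / np.log(base)
    w = matrix.width
    fwd = np.full((w, 5), invalid)
    rev = np.full((w, 5), invalid)
    fwd[:, :4] = lm - lbg[None, :]
    # reverse-orientation site: position k emits the complement of matrix
    # position w-1-k
    rev[:, :4] = lm[::-1, ::-1] - lbg[None, :]
    return fwd, rev


def log_odds_score(matrix: FrequencyMatrix, bg: BackgroundModel, subseq: str,
                   strand: str = "+") -> float:
    """log2-odds of ``subseq`` under the matrix versus the background.

    ``strand='-'`` scores the site in reverse orientation (equivalently, the
    reverse complement of ``subseq`` against the matrix).  Ambiguous bases
    contribute zero.
    """
    codes = encode(subseq)
    if codes.size != matrix.width:
        raise ValueError(
            f"subsequence length {codes.size} != matrix width {matrix.width}")
    fwd, rev = _score_tables(matrix, bg)
    tab = fwd if strand in ("+", "fwd") else rev
    return float(tab[np.arange(matrix.width), codes].sum())


def motif_information(matrix: FrequencyMatrix, bg: BackgroundModel) -> float:
    """Information content of the motif in nats.

    Sum over positions of the KL divergence between the position's base
    distribution and the background: sum_i sum_b m[i][b] ln(m[i][b]/bg[b]).
    """
    m = matrix.probs
    return float(np.sum(m * (np.log(m) - bg.log_probs[None, :])))


def scan_scores(matrix: FrequencyMatrix, bg: BackgroundModel, seq: str
                ) -> np.ndarray:
    """Score every site placement on both strands.

    Returns an array of shape (L - w + 1, 2) of log2-odds scores; column 0 is
    the forward orientation, column 1 the reverse.  Sequences shorter than the
    matrix yield an empty (0, 2) track.
    """
    codes = encode(seq)
    return scan_scores_codes(matrix, bg, codes)


def scan_scores_codes(matrix: FrequencyMatrix, bg: BackgroundModel,
                      codes: np.ndarray) -> np.ndarray:
    w = matrix.width
    L = codes.size
    if L < w:
        return np.zeros((0, 2))
    fwd, rev = _score_tables(matrix, bg)
    n = L - w + 1
    out = np.zeros((n, 2))
    for k in range(w):
        window = codes[k:k + n]
        out[:, 0] += fwd[k, window]
        out[:, 1] += rev[k, window]
    return out


def write_score_track(path, promoter_id: str, scores: np.ndarray) -> None:
    """Write a scan track as BED-like TSV (id, 0-based start, strand, score)."""
    with open(path, "w") as fh:
        fh.write("promoter\tstart\tstrand\tscore\n")
        for i in range(scores.shape[0]):
            fh.write(f"{promoter_id}\t{i}\t+\t{scores[i, 0]:.4f}\n")
            fh.write(f"{promoter_id}\t{i}\t-\t{scores[i, 1]:.4f}\n")
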