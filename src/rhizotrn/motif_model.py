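"""Position-specific scoring matrices: log-odds scoring and exact score p-values.

A motif is represented by a count matrix over the DNA alphabet (rows A, C, G, T)
with an identifier of the form ``<gene>_m<k>``: the gene whose upstream region
the motif was discovered in, and the matrix index (a gene carries one to five
conserved motifs).  Scores are additive log\\ :sub:`2` odds against an i.i.d.
background; the tail probability of a score under that background (the site
*p*-value) is computed exactly by dynamic programming over a discretised score
lattice, the standard approach for PSSM *p*-values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
from Bio import motifs as _bio_motifs

__all__ = [
    "ALPHABET",
    "PSSM",
    "ScoreDistribution",
    "FormatError",
    "parse_matrix_id",
    "log_odds",
    "score_sequence",
    "score_distribution",
    "exact_pvalue",
    "significance",
    "reverse_complement",
    "read_transfac",
    "write_transfac",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: default pseudocount, distributed proportionally to the background
DEFAULT_PSEUDOCOUNT = 1.0
#: default width of one cell of the discretised score lattice, in bits
DEFAULT_GRANULARITY = 0.01

_MATRIX_ID_RE = re.compile(r"^(?P<gene>.+)_m(?P<index>\d+)$")


class FormatError(ValueError):
    """Raised for malformed matrix identifiers or matrix files."""


def parse_matrix_id(matrix_id: str) -> tuple[str, int]:
    """Split ``<gene>_m<k>`` into the source gene and the matrix index.

    >>> parse_matrix_id("RHE_RS13345_m5")
    ('RHE_RS13345', 5)
    """
    m = _MATRIX_ID_RE.match(matrix_id)
    if m is None:
        raise FormatError(f"malformed matrix identifier: {matrix_id!r}")
    return m.group("gene"), int(m.group("index"))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PSSM:
    """A gene-associated motif count matrix.

    Parameters
    ----------
    matrix_id:
        Identifier of the form ``<gene>_m<k>``.
    counts:
        4 x w non-negative count matrix, rows in A, C, G, T order.  Real
        counts are accepted (some motif pipelines emit weighted counts).
    background:
        Background base probabilities (A, C, G, T), summing to one.
    pseudocount:
        Total pseudocount per column, split proportionally to the background.
    """

    matrix_id: str
    counts: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "background", background)
        parse_matrix_id(self.matrix_id)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix (rows A,C,G,T)")
        if counts.shape[1] < 1:
            raise ValueError("matrix must have at least one column")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if background.shape != (4,) or abs(background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 probabilities summing to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if np.any(counts.sum(axis=0) + self.pseudocount <= 0):
            raise ValueError("every column must have positive total count")

    @property
    def source_gene(self) -> str:
        return parse_matrix_id(self.matrix_id)[0]

    @property
    def index(self) -> int:
        return parse_matrix_id(self.matrix_id)[1]

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    def probabilities(self) -> np.ndarray:
        """Pseudocount-regularised probability matrix; columns sum to one."""
        reg = self.counts + self.pseudocount * self.background[:, None]
        return reg / reg.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.counts, axis=0))


def log_odds(pssm: PSSM) -> np.ndarray:
    """4 x w log2-odds matrix of the regularised probabilities vs background."""
    if np.any(pssm.background <= 0):
        raise ValueError("background probabilities must be strictly positive")
    return np.log2(pssm.probabilities() / pssm.background[:, None])


def encode(seq: str) -> np.ndarray:
    """Map an ACGT string to integer indices; rejects other letters."""
    try:
        return np.fromiter(
            (_BASE_INDEX[b] for b in seq.upper()), dtype=np.intp, count=len(seq)
        )
    except KeyError as exc:
        raise ValueError(f"non-ACGT letter in sequence: {exc.args[0]!r}") from None


def score_sequence(pssm: PSSM, seq: str, strand: str = "D") -> float:
    """Log-odds weight of one site.  Strand ``R`` scores the reverse complement."""
    if strand not in ("D", "R"):
        raise ValueError("strand must be 'D' or 'R'")
    if len(seq) != pssm.width:
        raise ValueError(
            f"sequence length {len(seq)} does not match matrix width {pssm.width}"
        )
    if strand == "R":
        seq = reverse_complement(seq)
    idx = encode(seq)
    lod = log_odds(pssm)
    return float(lod[idx, np.arange(pssm.width)].sum())


@dataclass(frozen=True)
class ScoreDistribution:
    """Exact null distribution of a PSSM score on the discretised lattice.

    ``grid`` holds the achievable lattice scores in ascending order (in the
    same bit units as the weights); ``tail_prob[i]`` is P(score >= grid[i])
    for a random background sequence of the matrix width.
    """

    grid: np.ndarray
    tail_prob: np.ndarray
    granularity: float

    def pvalue(self, threshold: float) -> float:
        """P(score >= threshold); thresholds are snapped to the lattice."""
        if math.isinf(threshold) and threshold < 0:
            return 1.0
        t = round(threshold / self.granularity)
        i = np.searchsorted(np.round(self.grid / self.granularity), t, side="left")
        if i >= len(self.grid):
            return 0.0
        return float(self.tail_prob[i])

    def pvalues(self, thresholds: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`pvalue`."""
        t = np.round(np.asarray(thresholds) / self.granularity)
        lattice = np.round(self.grid / self.granularity)
        i = np.searchsorted(lattice, t, side="left")
        out = np.zeros(len(t))
        ok = i < len(self.grid)
        out[ok] = self.tail_prob[i[ok]]
        return out


def score_distribution(
    pssm: PSSM, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact tail probabilities of the PSSM score under the background model.

    Column-wise dynamic programming: log-odds entries are rounded to the
    nearest multiple of ``granularity`` (bits) and the distribution of their
    sum is convolved one column at a time.  The null is single-strand i.i.d.
    background of the matrix width; both-strand scanning handles strands by
    scoring each orientation against this same null.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    lod = log_odds(pssm)
    scaled = np.round(lod / granularity).astype(np.int64)  # 4 x w
    first = {}
    for b in range(4):
        first[int(scaled[b, 0])] = first.get(int(scaled[b, 0]), 0.0) + float(
            pssm.background[b]
        )
    base = min(first)
    cur_arr = np.zeros(max(first) - base + 1)
    for s, p in first.items():
        cur_arr[s - base] = p
    for j in range(1, pssm.width):
        col = scaled[:, j]
        new_base = base + int(col.min())
        new_len = len(cur_arr) + int(col.max() - col.min())
        new_arr = np.zeros(new_len)
        for b in range(4):
            shift = int(col[b] - col.min())
            new_arr[shift : shift + len(cur_arr)] += pssm.background[b] * cur_arr
        base, cur_arr = new_base, new_arr
    support = np.nonzero(cur_arr > 0)[0]
    grid = (base + support) * granularity
    p = cur_arr[support]
    tail = np.cumsum(p[::-1])[::-1]
    tail = np.minimum(tail, 1.0)  # guard accumulated round-off
    return ScoreDistribution(grid=grid, tail_prob=tail, granularity=granularity)


def exact_pvalue(
    pssm: PSSM, threshold: float, granularity: float = DEFAULT_GRANULARITY
) -> float:
    """P(score of a random background sequence >= threshold).

    Convenience wrapper building the score distribution on the fly; scanning
    code builds :func:`score_distribution` once per matrix instead.
    """
    if math.isnan(threshold):
        raise ValueError("threshold must be a number")
    return score_distribution(pssm, granularity).pvalue(threshold)


def significance(p: float) -> float:
    """The Significance column: -log10 of the site p-value."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return -math.log10(p)


# ---------------------------------------------------------------------------
# TRANSFAC-format matrix files
# ---------------------------------------------------------------------------

def write_transfac(pssms: Iterable[PSSM], handle: TextIO) -> None:
    """Write count matrices in TRANSFAC format (ID, P0 header, counts, //)."""
    for pssm in pssms:
        handle.write(f"ID  {pssm.matrix_id}\n")
        handle.write("P0      A      C      G      T\n")
        for j in range(pssm.width):
            cells = []
            for b in range(4):
                v = pssm.counts[b, j]
                cells.append(f"{v:g}")
            handle.write(f"{j + 1:02d}  " + "  ".join(f"{c:>6}" for c in cells) + "\n")
        handle.write("XX\n//\n")


def read_transfac(
    handle: TextIO,
    background: np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[PSSM]:
    """Read TRANSFAC count matrices (integer or real counts) into PSSMs."""
    try:
        records = _bio_motifs.parse(handle, "transfac", strict=False)
    except Exception as exc:  # Bio raises bare ValueError with a line excerpt
        raise FormatError(f"unreadable TRANSFAC input: {exc}") from exc
    out = []
    for rec in records:
        matrix_id = rec.get("ID") or rec.get("AC")
        if not matrix_id:
            raise FormatError("TRANSFAC record without an ID line")
        counts = np.array([list(rec.counts[b]) for b in ALPHABET], dtype=float)
        kwargs = {} if background is None else {"background": background}
        out.append(
            PSSM(
                matrix_id=matrix_id,
                counts=counts,
                pseudocount=pseudocount,
                **kwargs,
            )
        )
    return out
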