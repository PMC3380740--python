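"""PWM scanning with exact p-values by dynamic programming.

A position frequency matrix (PFM) is smoothed against a background model and
turned into a log-likelihood-ratio (LLR) scoring matrix in bits.  Window
scores are converted to p-values with the classic lattice dynamic program:
per-column scores are discretized onto an integer grid, the exact score
distribution of a random background word is convolved column by column, and
p(s) = Pr[score >= s] is read off the survival function.  Scanning evaluates
both strands (the reverse strand scores the reverse-complement window) and
emits hits below a p-value threshold; Benjamini-Hochberg q-values are
attached over the number of scanned positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

ALPHABET = "ACGT"
UNIFORM_BACKGROUND = np.full(4, 0.25)

# byte -> code; A/C/G/T -> 0..3, anything else -> 4 (treated as N)
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i


class MotifError(ValueError):
    pass


@dataclass
class MotifMatrix:
    """A position frequency matrix: one row of A/C/G/T weights per position.

    Rows may be raw observation counts (JASPAR, TRANSFAC) or probabilities
    (MEME); :attr:`probs` row-normalizes either.
    """

    name: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise MotifError(f"{self.name}: counts must be (width, 4)")
        if self.counts.shape[0] < 1:
            raise MotifError(f"{self.name}: zero-width motif")
        if (self.counts < 0).any():
            raise MotifError(f"{self.name}: negative matrix entries")
        if (self.counts.sum(axis=1) == 0).any():
            raise MotifError(f"{self.name}: all-zero matrix row")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(self.name, self.counts[::-1, ::-1].copy())

    @classmethod
    def from_consensus(cls, name: str, consensus: str, strength: float = 100.0) -> "MotifMatrix":
        """Build a near-deterministic PFM from a consensus string."""
        idx = [ALPHABET.index(c) for c in consensus.upper()]
        counts = np.ones((len(idx), 4))
        counts[np.arange(len(idx)), idx] = strength
        return cls(name, counts)


@dataclass
class ScoringMatrix:
    """LLR scores in bits plus the integer discretization used for p-values."""

    name: str
    llr: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.llr.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.llr.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.llr.min(axis=1).sum())


def make_scoring_matrix(
    motif: MotifMatrix,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.1,
    prob_floor: float = 1e-6,
) -> ScoringMatrix:
    """Convert a PFM to a log2 likelihood-ratio matrix.

    Smoothed probability at position i for base b is
    ``(counts[i,b] + pseudocount*bg[b]) / (rowsum + pseudocount)``; zero
    probabilities surviving a zero pseudocount are floored at ``prob_floor``
    so every score is finite.
    """
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1) > 1e-6:
        raise MotifError("background must be 4 strictly positive probabilities summing to 1")
    rowsum = motif.counts.sum(axis=1, keepdims=True)
    p = (motif.counts + pseudocount * bg) / (rowsum + pseudocount)
    p = np.maximum(p, prob_floor)
    return ScoringMatrix(motif.name, np.log2(p / bg), bg.copy(), pseudocount)


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order base composition of the scanned sequences (N excluded)."""
    counts = np.zeros(4)
    for seq in sequences:
        codes = encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return UNIFORM_BACKGROUND.copy()
    return counts / counts.sum()


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class ScorePValueFunction:
    """Monotone map from window score to p-value for one scoring matrix.

    Per-column scores are shifted to be non-negative and rounded to an
    integer grid with ``granularity`` bins spanning the matrix score range;
    the exact distribution of the integer total under the background model
    is built by convolution.  ``pvalue(s)`` is non-increasing in s and 1 at
    (or below) the minimum achievable score.  Window p-values during
    scanning use the same integer scores, so scan p-values are exactly the
    lattice tail probabilities.
    """

    def __init__(
        self,
        sm: ScoringMatrix,
        background: Sequence[float] | None = None,
        granularity: int = 1000,
    ) -> None:
        if granularity < 100:
            raise MotifError("granularity must be >= 100")
        self.granularity = granularity
        bg = sm.background if background is None else np.asarray(background, dtype=float)
        llr = sm.llr
        col_min = llr.min(axis=1)
        span = float((llr.max(axis=1) - col_min).sum())
        self.offset = float(col_min.sum())
        self.scale = granularity / span if span > 0 else 1.0
        self.bin_width = 1.0 / self.scale
        self.imat = np.rint((llr - col_min[:, None]) * self.scale).astype(np.int64)
        self.sf = self._survival(self.imat, bg)
        self.max_int = self.imat.max(axis=1).sum()

    @staticmethod
    def _survival(imat: np.ndarray, bg: np.ndarray) -> np.ndarray:
        pmf = np.array([1.0])
        for row in imat:
            top = int(row.max())
            new = np.zeros(len(pmf) + top)
            for b in range(4):
                new[row[b] : row[b] + len(pmf)] += bg[b] * pmf
            pmf = new
        return np.minimum(1.0, pmf[::-1].cumsum()[::-1])

    def int_score(self, scores: np.ndarray | float) -> np.ndarray:
        k = np.rint((np.asarray(scores, dtype=float) - self.offset) * self.scale).astype(np.int64)
        return np.clip(k, 0, self.max_int)

    def pvalue_int(self, k: np.ndarray) -> np.ndarray:
        return self.sf[k]

    def pvalue(self, score) -> np.ndarray | float:
        p = self.sf[self.int_score(score)]
        return float(p) if np.isscalar(score) or np.ndim(score) == 0 else p


def score_pvalue_function(
    sm: ScoringMatrix,
    background: Sequence[float] | None = None,
    granularity: int = 1000,
) -> ScorePValueFunction:
    return ScorePValueFunction(sm, background, granularity)


@dataclass
class MotifHit:
    motif: str
    region_id: str
    offset: int
    strand: str
    score: float
    p_value: float
    q_value: float | None = None


def _window_int_scores(codes: np.ndarray, imat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores and a validity mask (False where a window has N)."""
    w = imat.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    total = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for i in range(w):
        c = codes[i : i + n]
        bad = c >= 4
        valid &= ~bad
        total += imat[i, np.where(bad, 0, c)]
    return total, valid


def scan_regions(
    sm: ScoringMatrix,
    sequences: Mapping[str, str],
    p_threshold: float,
    pv: ScorePValueFunction | None = None,
    granularity: int = 1000,
) -> list[MotifHit]:
    """Scan both strands of every sequence, emitting hits with p <= threshold.

    The reverse strand scores the reverse-complement of each window; hit
    offsets are forward-strand window starts on both strands.  Windows
    containing N never match.  Output is sorted by ascending p-value
    (ties by region, offset, strand).
    """
    if not (0 < p_threshold <= 1):
        raise MotifError(f"p_threshold must be in (0, 1], got {p_threshold}")
    if pv is None:
        pv = ScorePValueFunction(sm, granularity=granularity)
    # reverse-complement matrix shares the forward grid: columns reversed both ways
    imat_fwd = pv.imat
    imat_rev = imat_fwd[::-1, ::-1]
    sym = np.allclose(sm.background, sm.background[::-1])
    # with equal granularity the reverse grid coincides with the forward one
    # (column spans and minima are permutation-invariant)
    pv_rev = pv if sym else ScorePValueFunction(
        ScoringMatrix(sm.name, sm.llr[::-1, ::-1], sm.background, sm.pseudocount),
        granularity=pv.granularity,
    )
    hits: list[MotifHit] = []
    for region_id, seq in sequences.items():
        codes = encode(seq)
        for strand, imat, table in (("+", imat_fwd, pv), ("-", imat_rev, pv_rev)):
            ints, valid = _window_int_scores(codes, imat)
            if ints.size == 0:
                continue
            ps = table.pvalue_int(np.clip(ints, 0, table.max_int))
            keep = valid & (ps <= p_threshold)
            for off in np.flatnonzero(keep):
                score = ints[off] * pv.bin_width + pv.offset
                hits.append(
                    MotifHit(sm.name, region_id, int(off), strand, float(score), float(ps[off]))
                )
    hits.sort(key=lambda h: (h.p_value, h.region_id, h.offset, h.strand))
    return hits


def n_scanned_positions(sequences: Mapping[str, str], width: int) -> int:
    """Number of scored windows over both strands: 2 * sum(len - w + 1)."""
    return 2 * sum(max(0, len(s) - width + 1) for s in sequences.values())


def attach_qvalues(hits: list[MotifHit], n_tests: int) -> list[MotifHit]:
    """Benjamini-Hochberg q-values over ``n_tests`` scanned positions, in place."""
    if n_tests < len(hits):
        raise MotifError(f"n_tests={n_tests} smaller than number of hits {len(hits)}")
    if not hits:
        return hits
    order = sorted(range(len(hits)), key=lambda i: hits[i].p_value)
    q = 1.0
    for rank in range(len(order), 0, -1):
        i = order[rank - 1]
        q = min(q, hits[i].p_value * n_tests / rank)
        hits[i].q_value = q
    return hits


def hit_region_ids(hits: Iterable[MotifHit]) -> set[str]:
    return {h.region_id for h in hits}


def count_region_hits(hits: Sequence[MotifHit], regions) -> tuple[int, int]:
    """(total hit positions, regions with at least one hit on either strand)."""
    known = set(regions.ids)
    covered = set()
    for h in hits:
        if h.region_id not in known:
            raise MotifError(f"hit references unknown region {h.region_id!r}")
        covered.add(h.region_id)
    return len(hits), len(covered)
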