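"""Information-weighted PWM scanning with rate-calibrated thresholds.

A position weight matrix is scored against a sequence window with the
matrix-similarity statistic of the MatInspector family: each position
contributes its base frequency weighted by the column's information
content ci in [0, 100] (0 for a uniform column, 100 for an invariant
one), normalized by the best attainable weighted sum, so the consensus
always scores 1.  Detection thresholds are calibrated empirically by
allowing one hit per 10 kb of background sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position frequency matrix over {A, C, G, T}.

    ``frequencies`` has shape (L, 4) in A, C, G, T order; each row sums
    to 1.  Build from counts with :meth:`from_counts`.
    """

    id: str
    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise ValueError("frequencies must have shape (L, 4)")
        if f.shape[0] < 3:
            raise ValueError("PWM must span at least 3 positions")
        if (f < 0).any():
            raise ValueError("frequencies must be non-negative")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's frequencies must sum to 1")
        object.__setattr__(self, "frequencies", f)

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    @classmethod
    def from_counts(
        cls, id: str, counts: np.ndarray, pseudocount: float = 0.0
    ) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        totals = c.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("a PWM column has zero total count")
        return cls(id, c / totals)

    def consensus(self) -> str:
        """Highest-frequency base per position (ties: first in ACGT order)."""
        return "".join(ALPHABET[i] for i in self.frequencies.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based, forward-strand coordinates
    strand: str  # '+' or '-'
    score: float
    pwm_id: str


def information_weights(pwm: PWM) -> np.ndarray:
    """Per-position information weight ci in [0, 100].

    ci(l) = (100 / ln 4) * sum_b f(b,l) ln f(b,l) + 100, with
    0 * ln 0 := 0.  Uniform column -> 0; single-base column -> 100.
    """
    f = pwm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log(f), 0.0)
    return (100.0 / np.log(4.0)) * term.sum(axis=1) + 100.0


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes; anything outside ACGT becomes 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)
    for base, i in _INDEX.items():
        codes[arr == ord(base)] = i
    return codes


def matrix_similarity(pwm: PWM, window: str, weights: np.ndarray | None = None) -> float:
    """Matrix similarity of one window against the PWM.

    score = sum_l ci(l) f(b_l, l) / sum_l ci(l) f_max(l); an N (or any
    non-ACGT symbol) contributes 0 at its position.  Equals 1 iff every
    base attains its column maximum.
    """
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != PWM length {pwm.length}"
        )
    if weights is None:
        weights = information_weights(pwm)
    codes = _encode(window)
    f = pwm.frequencies
    num = 0.0
    for l, c in enumerate(codes):
        if c < 4:
            num += weights[l] * f[l, c]
    denom = float((weights * f.max(axis=1)).sum())
    if denom == 0.0:
        return 0.0
    return min(num / denom, 1.0)


def window_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Similarity scores of every window on the forward and reverse
    strand (both reported against forward-strand start coordinates)."""
    L = pwm.length
    n = len(seq) - L + 1
    if n < 1:
        return np.empty(0), np.empty(0)
    weights = information_weights(pwm)
    f = pwm.frequencies
    denom = float((weights * f.max(axis=1)).sum())

    def _scores(codes: np.ndarray) -> np.ndarray:
        # weight lookup table with a zero row for non-ACGT codes
        table = np.concatenate(
            [weights[:, None] * f, np.zeros((L, 1))], axis=1
        )  # shape (L, 5): table[l, code], code 4 = non-ACGT contributes 0
        out = np.zeros(n)
        for l in range(L):
            out += table[l, codes[l : l + n]]
        return np.minimum(out / denom, 1.0) if denom else np.zeros(n)

    fwd = _scores(_encode(seq))
    rc = _scores(_encode(reverse_complement(seq)))
    # reverse-strand window starting at i (forward coords) corresponds to
    # window n-1-i on the reverse complement
    rev = rc[::-1]
    return fwd, rev


def scan(
    seq: str,
    pwm: PWM,
    threshold: float,
    sequence_id: str = "seq",
) -> list[MotifHit]:
    """All windows on both strands scoring >= threshold, reported in
    forward-strand coordinates."""
    fwd, rev = window_scores(pwm, seq)
    hits = [
        MotifHit(sequence_id, int(i), "+", float(s), pwm.id)
        for i, s in enumerate(fwd)
        if s >= threshold
    ] + [
        MotifHit(sequence_id, int(i), "-", float(s), pwm.id)
        for i, s in enumerate(rev)
        if s >= threshold
    ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def calibrate_threshold(
    pwm: PWM,
    background: str,
    target_rate: float = 1.0 / 10_000.0,
    min_length: int = 100_000,
) -> tuple[float, bool]:
    """Smallest score t at which hits (both strands, score >= t) on the
    background occur at <= ``target_rate`` per base.

    Returns (threshold, achieved).  ``achieved`` is False for degenerate
    matrices where even t = 1.0 exceeds the target rate (e.g. a PWM
    matching everything equally); the threshold is then reported as 1.0.
    """
    if len(background) < min_length:
        raise ValueError(
            f"background of {len(background)} bp is shorter than the "
            f"required {min_length} bp"
        )
    fwd, rev = window_scores(pwm, background)
    scores = np.sort(np.concatenate([fwd, rev]))  # ascending
    allowed = int(np.floor(target_rate * len(background)))
    candidates = np.unique(scores)  # ascending unique scores
    # count(scores >= t) is non-increasing in t: take the smallest t
    # at which the background hit count drops to the allowance
    counts = scores.size - np.searchsorted(scores, candidates, side="left")
    ok = np.flatnonzero(counts <= allowed)
    if ok.size:
        return float(candidates[ok[0]]), True
    return 1.0, False


def hits_to_bed(hits: list[MotifHit], pwm_lengths: dict[str, int]) -> pd.DataFrame:
    """BED6 frame: chrom, start, end, name, score (x1000 rounded), strand."""
    rows = [
        (
            h.sequence_id,
            h.start,
            h.start + pwm_lengths[h.pwm_id],
            h.pwm_id,
            int(round(h.score * 1000)),
            h.strand,
        )
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def tss_relative_label(start: int, region_length: int) -> int:
    """Promoter coordinate of a hit start relative to the TSS, for a
    region spanning [-region_length, -1]."""
    return start - region_length


def random_background(
    length: int, gc_fraction: float = 0.5, seed: int | None = None
) -> str:
    """IID background sequence at the given GC content, for threshold
    calibration when no coding FASTA is supplied."""
    rng = np.random.default_rng(seed)
    gc, at = gc_fraction / 2.0, (1.0 - gc_fraction) / 2.0
    return "".join(
        rng.choice(list(ALPHABET), size=length, p=[at, gc, gc, at])
    )
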