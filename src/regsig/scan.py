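"""Genome scanning with log-odds profiles and exact score p-values.

A window of length L is scored as sum_j log2(p(b_j, j) / q(b_j)) over the
unmasked columns; N contributes the background-weighted mean of the four
column log-odds, and masked columns contribute exactly 0.  Both strands are
always scanned (orientation is a post-processing question), and minus-strand
hits are reported in top-strand coordinates.

The p-value of a score threshold t is the exact probability that a random
L-mer drawn from the background distribution scores >= t.  It is computed by
column-wise convolution of the per-column score distributions after rounding
every per-column log-odds to a fixed granularity (default 0.001 bits), so the
total discretization error of any word's score is at most L·granularity/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._dna import encode, revcomp
from .errors import ConfigurationError
from .motifs import Profile

#: sort order of strands within one start coordinate
_STRAND_ORDER = {"+": 0, "-": 1}


@dataclass(frozen=True)
class Hit:
    """A scored profile match on a genome (top-strand, 0-based half-open)."""

    genome_id: str
    start: int
    end: int
    strand: str
    score: float
    pvalue: float
    profile_name: str

    def sort_key(self) -> tuple:
        return (self.start, _STRAND_ORDER[self.strand], self.end)


def log_odds_matrix(profile: Profile) -> np.ndarray:
    """L x 5 log2-odds matrix over (A, C, G, T, N); masked columns are 0.

    Zero-probability cells (possible at pseudocount 0) map to -inf, so any
    window crossing them can never reach a finite cutoff.
    """
    p = profile.matrix
    q = profile.background
    with np.errstate(divide="ignore"):
        lo = np.log2(p) - np.log2(q)[None, :]
    n_col = np.where(np.isfinite(lo), lo, 0.0) @ q  # E_q[log-odds], -inf -> ?
    # If any base has -inf log-odds the background mean is still finite only
    # when that base has background weight 0 -- background is all-positive,
    # so propagate -inf explicitly.
    neg = np.isneginf(lo).any(axis=1)
    n_col = np.where(neg, -np.inf, n_col)
    m = np.concatenate([lo, n_col[:, None]], axis=1)
    if profile.masked_columns:
        m[list(profile.masked_columns)] = 0.0
    return m


def score_window(profile: Profile, window: str) -> float:
    """Score one window of exactly profile.length bases (bits)."""
    if len(window) != profile.length:
        raise ValueError(
            f"window length {len(window)} != profile length {profile.length}"
        )
    m = log_odds_matrix(profile)
    idx = encode(window.upper())
    return float(m[np.arange(len(idx)), idx].sum())


class ScoreDistribution:
    """Exact distribution of the profile score of a random background L-mer.

    Per-column log-odds are rounded to integer multiples of ``granularity``
    bits and convolved column by column.  Words containing a zero-probability
    base (score -inf) are tracked as a separate mass that can never satisfy a
    finite threshold.
    """

    def __init__(self, profile: Profile, granularity: float = 0.001):
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        self.granularity = float(granularity)
        m = log_odds_matrix(profile)[:, :4]
        q = profile.background
        probs = np.array([1.0])
        offset = 0  # integer grid value of probs[0]
        dead = 0.0  # mass of -inf words
        for j in range(profile.length):
            finite = np.isfinite(m[j])
            live_q = q[finite]
            dead += probs.sum() * q[~finite].sum()
            if not live_q.size:
                probs = np.array([])
                break
            steps = np.rint(m[j, finite] / self.granularity).astype(np.int64)
            lo, hi = steps.min(), steps.max()
            new = np.zeros(len(probs) + (hi - lo), dtype=float)
            for s, qb in zip(steps, live_q):
                new[s - lo : s - lo + len(probs)] += qb * probs
            probs = new
            offset += lo
        self._probs = probs
        self._offset = offset
        self._dead = dead
        # survival[i] = P(grid score >= offset + i)
        self._survival = probs[::-1].cumsum()[::-1] if probs.size else np.array([])

    def survival(self, threshold_bits: float) -> float:
        """P(score >= threshold) for a background-random word."""
        if threshold_bits == -np.inf:
            return 1.0
        if not self._survival.size:
            return 0.0
        k = int(np.ceil(threshold_bits / self.granularity - 1e-9))
        i = k - self._offset
        if i <= 0:
            return float(self._survival[0] + 0.0)  # all finite mass qualifies
        if i >= len(self._survival):
            return 0.0
        return float(self._survival[i])

    def pvalue_of_score(self, score_bits: float) -> float:
        """Exact p-value of an attained score (P of scoring at least it)."""
        if score_bits == -np.inf:
            return 1.0
        if not self._survival.size:
            return 1.0
        k = int(np.rint(score_bits / self.granularity))
        i = min(max(k - self._offset, 0), len(self._survival) - 1)
        return float(max(self._survival[i], 0.0)) or float(self._survival[-1])

    def score_at_pvalue(self, pvalue: float) -> float:
        """Smallest grid score whose survival probability is <= pvalue."""
        if not self._survival.size:
            return -np.inf
        idx = np.searchsorted(-self._survival, -pvalue, side="left")
        if idx >= len(self._survival):
            return np.inf
        return (self._offset + idx) * self.granularity


def score_pvalue(
    profile: Profile, threshold: float, granularity: float = 0.001
) -> float:
    """Exact P(random background L-mer scores >= threshold), in (0, 1]."""
    return ScoreDistribution(profile, granularity).survival(threshold)


def _window_scores(m: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores of every window via per-column vectorized adds."""
    L = m.shape[0]
    n = len(codes) - L + 1
    out = np.zeros(n)
    for j in range(L):
        out += m[j, codes[j : j + n]]
    return out


def scan_genome(
    profile: Profile,
    record: "GenomeRecord",
    mode: str = "score",
    cutoff: Optional[float] = None,
    granularity: float = 0.001,
) -> list[Hit]:
    """Scan both strands of a replicon, returning cutoff-passing hits.

    ``mode`` is "score" (cutoff in bits; defaults to the profile's gathering
    cutoff) or "pvalue" (cutoff on the exact p-value).  Hits are sorted by
    start, then strand (+ before -), ties at the cutoff are kept.  Circular
    replicons are scanned without wrapping the origin.
    """
    if mode not in ("score", "pvalue"):
        raise ValueError(f"unknown scan mode {mode!r}")
    L = profile.length
    seq = record.sequence.upper()
    if len(seq) < L:
        warnings.warn(
            f"sequence {record.id!r} shorter than profile ({len(seq)} < {L})",
            stacklevel=2,
        )
        return []
    dist = ScoreDistribution(profile, granularity)
    if mode == "score":
        if cutoff is None:
            cutoff = profile.cutoffs.gathering
        if cutoff is None:
            raise ConfigurationError(
                f"profile {profile.name!r} has no gathering cutoff and no scan "
                "cutoff was supplied"
            )
        score_cut = float(cutoff)
    else:
        if cutoff is None:
            raise ConfigurationError("p-value scan mode requires a cutoff")
        if not (0.0 < cutoff <= 1.0):
            raise ValueError("p-value cutoff must be in (0, 1]")
        score_cut = dist.score_at_pvalue(float(cutoff)) - 0.5 * granularity

    m = log_odds_matrix(profile)
    hits = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        scores = _window_scores(m, encode(s))
        for i in np.nonzero(scores >= score_cut - 1e-12)[0]:
            sc = float(scores[i])
            if strand == "+":
                start = int(i)
            else:
                start = n - int(i) - L
            hits.append(
                Hit(
                    genome_id=record.id,
                    start=start,
                    end=start + L,
                    strand=strand,
                    score=sc,
                    pvalue=dist.pvalue_of_score(sc),
                    profile_name=profile.name,
                )
            )
    hits.sort(key=Hit.sort_key)
    return hits


# ---------------------------------------------------------------------------
# Exports


def hits_to_bed(hits: list[Hit]) -> str:
    """BED6: chrom, start, end, name=profile, score=bits*100 rounded, strand."""
    lines = [
        f"{h.genome_id}\t{h.start}\t{h.end}\t{h.profile_name}"
        f"\t{round(h.score * 100)}\t{h.strand}"
        for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_table(hits: list[Hit]) -> str:
    """Tab-separated hit table with scores and exact p-values."""
    lines = ["genome\tstart\tend\tstrand\tscore_bits\tpvalue\tprofile"]
    for h in hits:
        lines.append(
            f"{h.genome_id}\t{h.start}\t{h.end}\t{h.strand}"
            f"\t{h.score:.4f}\t{h.pvalue:.6g}\t{h.profile_name}"
        )
    return "\n".join(lines) + "\n"


def hits_from_table(text: str) -> list[Hit]:
    """Inverse of :func:`hits_to_table` (used by the CLI filter command)."""
    hits = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        g, s, e, st, sc, pv, prof = line.split("\t")
        hits.append(Hit(g, int(s), int(e), st, float(sc), float(pv), prof))
    return hits
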