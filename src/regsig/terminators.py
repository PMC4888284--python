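"""Intrinsic (rho-independent) transcription terminator detection.

An intrinsic terminator is a GC-rich RNA hairpin (stem-loop) immediately
followed by a U-rich tract.  The detector enumerates stem-loop
decompositions on both strands, scores the hairpin by summed base-pair
scores (G:C +3, A:T +2, G·U wobble +1, mismatch -3) minus a loop-length
penalty of 0.5 per nt, scores the poly-U tail with positionally decaying
weights, and maps the two onto a 0-100 confidence through a logistic:

    confidence = 100 / (1 + exp(-0.35 * (hairpin + 3*tail - 18)))

The constants are this package's own surrogate scoring, chosen so that a
canonical terminator (>= 6 bp clean stem + 8-nt U tail) comfortably exceeds
the default confidence cutoff of 70 while hairpin-free sequence never
reaches it.  The detector is annotation-agnostic: whether a candidate is in
a sensible place relative to genes is decided downstream (regulon module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from ._dna import encode, revcomp

# pair scores indexed by (base1, base2) codes 0..4 (ACGTN)
_MISMATCH = -3.0


def _pair_matrix(allow_GU: bool) -> np.ndarray:
    m = np.full((5, 5), _MISMATCH)
    A, C, G, T = 0, 1, 2, 3
    m[G, C] = m[C, G] = 3.0
    m[A, T] = m[T, A] = 2.0
    if allow_GU:
        m[G, T] = m[T, G] = 1.0  # rU·rG wobble, written in DNA
    return m


@dataclass
class TerminatorParams:
    """Detector settings (stem/loop bounds, tail length, confidence cutoff)."""

    stem_min: int = 4
    stem_max: int = 20
    loop_min: int = 3
    loop_max: int = 10
    tail_len: int = 8
    allow_GU: bool = True
    max_mismatches: int = 1
    min_confidence: float = 70.0
    min_tail_score: float = 0.0  # extra U-tail gate for high-specificity scans
    loop_penalty: float = 0.5  # per loop nt
    logistic_slope: float = 0.35
    logistic_midpoint: float = 18.0
    tail_weight_start: float = 1.0
    tail_weight_step: float = 0.1
    tail_weight_floor: float = 0.1

    def __post_init__(self):
        if self.stem_min > self.stem_max or self.stem_min < 1:
            raise ValueError("need 1 <= stem_min <= stem_max")
        if self.loop_min > self.loop_max or self.loop_min < 0:
            raise ValueError("need 0 <= loop_min <= loop_max")
        if self.tail_len < 1:
            raise ValueError("tail_len must be >= 1")

    def tail_weights(self) -> np.ndarray:
        w = self.tail_weight_start - self.tail_weight_step * np.arange(self.tail_len)
        return np.maximum(w, self.tail_weight_floor)


@dataclass(frozen=True)
class TerminatorCandidate:
    """A stem-loop candidate; ``start``..``end`` spans stem1 through stem2."""

    start: int
    end: int
    strand: str
    stem_len: int
    loop_len: int
    mismatches: int
    hairpin_score: float
    tail_score: float = 0.0
    confidence: float = 0.0


def high_specificity_params() -> TerminatorParams:
    """Settings for genome-wide scans that feed operon inference.

    Random DNA contains hairpins that clear the default confidence cutoff;
    when terminator calls delimit transcription units, a false call is much
    costlier than a missed weak terminator, so the confidence gate is raised
    and a strong U-tail is required outright.
    """
    return TerminatorParams(min_confidence=99.0, min_tail_score=4.0)


def find_hairpins(seq: str, params: TerminatorParams | None = None) -> list[TerminatorCandidate]:
    """Enumerate stem-loop candidates on the given (single-strand) sequence.

    All (stem length, loop length, position) decompositions within the
    parameter bounds and with at most ``max_mismatches`` unpaired stem
    positions are generated; candidates with overlapping loop regions then
    collapse to the highest-scoring one.  Tail and confidence are left at 0.
    """
    params = params or TerminatorParams()
    codes = encode(seq.upper())
    n = len(codes)
    pair = _pair_matrix(params.allow_GU)
    raw: list[tuple] = []  # (loop_start, loop_end, candidate)
    for s in range(params.stem_min, params.stem_max + 1):
        for l in range(params.loop_min, params.loop_max + 1):
            width = 2 * s + l
            npos = n - width + 1
            if npos <= 0:
                continue
            idx = np.arange(npos)
            total = np.zeros(npos)
            mism = np.zeros(npos, dtype=int)
            for k in range(s):
                sc = pair[codes[idx + k], codes[idx + width - 1 - k]]
                total += sc
                mism += sc < 0
            ok = np.nonzero(mism <= params.max_mismatches)[0]
            for i in ok:
                score = float(total[i]) - params.loop_penalty * l
                cand = TerminatorCandidate(
                    start=int(i),
                    end=int(i) + width,
                    strand="+",
                    stem_len=s,
                    loop_len=l,
                    mismatches=int(mism[i]),
                    hairpin_score=score,
                )
                raw.append((int(i) + s, int(i) + s + l, cand))
    if not raw:
        return []
    # greedy non-maximum suppression: a candidate is dropped when its loop
    # overlaps the loop of an already-kept, better-scoring candidate
    raw.sort(
        key=lambda t: (-t[2].hairpin_score, t[2].mismatches, -t[2].stem_len, t[2].start)
    )
    covered = np.zeros(n, dtype=bool)
    out = []
    for lo, hi, cand in raw:
        if covered[lo:hi].any():
            continue
        covered[lo:hi] = True
        out.append(cand)
    out.sort(key=lambda c: c.start)
    return out


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def score_tail(
    seq: str, cand: TerminatorCandidate, params: TerminatorParams | None = None
) -> TerminatorCandidate:
    """Score the poly-U (poly-T in DNA) tract after the hairpin.

    tail_score = sum of decaying weights over tail positions that are T;
    a tail truncated by the contig end is scored over the available bases.
    Sets ``tail_score`` and ``confidence`` on a copy of the candidate.
    """
    params = params or TerminatorParams()
    weights = params.tail_weights()
    tail = seq[cand.end : cand.end + params.tail_len].upper()
    tail_score = float(
        sum(w for w, b in zip(weights, tail) if b == "T")
    )
    x = params.logistic_slope * (
        cand.hairpin_score + 3.0 * tail_score - params.logistic_midpoint
    )
    return replace(
        cand, tail_score=tail_score, confidence=100.0 * _logistic(x)
    )


def _min_useful_hairpin(params: TerminatorParams) -> float:
    """Exact pruning bound: weakest hairpin that could still pass the cutoff."""
    p = min(max(params.min_confidence / 100.0, 0.0), 1.0)
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    logit = math.log(p / (1.0 - p))
    max_tail = float(params.tail_weights().sum())
    return logit / params.logistic_slope + params.logistic_midpoint - 3.0 * max_tail


def find_terminators(
    record: "GenomeRecord", params: TerminatorParams | None = None
) -> list[TerminatorCandidate]:
    """Detect intrinsic terminators on both strands of a replicon.

    Minus-strand candidates are found on the reverse complement and
    reported in top-strand coordinates.  Only candidates with confidence >=
    ``params.min_confidence`` are returned, sorted by start then strand.
    """
    params = params or TerminatorParams()
    seq = record.sequence.upper()
    n = len(seq)
    min_h = _min_useful_hairpin(params)
    out: list[TerminatorCandidate] = []
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for cand in find_hairpins(s, params):
            if cand.hairpin_score < min_h - 1e-9:
                continue
            cand = score_tail(s, cand, params)
            if cand.confidence < params.min_confidence:
                continue
            if cand.tail_score < params.min_tail_score:
                continue
            if strand == "-":
                cand = replace(
                    cand, start=n - cand.end, end=n - cand.start, strand="-"
                )
            out.append(cand)
    out.sort(key=lambda c: (c.start, c.strand, c.end))
    return out


def terminators_to_bed(cands: list[TerminatorCandidate], chrom: str) -> str:
    """BED6 export (name=terminator, score=confidence rounded)."""
    lines = [
        f"{chrom}\t{c.start}\t{c.end}\tterminator\t{round(c.confidence)}\t{c.strand}"
        for c in cands
    ]
    return "\n".join(lines) + ("\n" if lines else "")
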