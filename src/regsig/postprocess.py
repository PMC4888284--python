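"""Context-aware filtering of raw scan hits against the genome annotation.

Raw hits from both strands are reduced to the biologically plausible set:
palindromic double-reports are collapsed, and every remaining hit is
classified by where it sits relative to the annotated genes:

- ``intragenic``      -- overlaps a gene/CDS;
- ``converging-region`` -- strictly between the 3' ends of two adjacent
  convergently transcribed genes (a region that cannot be upstream of
  anything);
- ``upstream-ok``     -- the nearest same-strand gene start downstream of the
  hit lies within a configurable window of the hit's 3' edge;
- ``wrong-orientation`` -- everything else.

Precedence: intragenic > converging-region > upstream-ok.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import AnnotationMissingError
from .genome_io import GenomeRecord
from .scan import Hit

UPSTREAM_OK = "upstream-ok"
WRONG_ORIENTATION = "wrong-orientation"
CONVERGING_REGION = "converging-region"
INTRAGENIC = "intragenic"
PALINDROMIC_DUPLICATE = "palindromic-duplicate"

CATEGORIES = (
    UPSTREAM_OK,
    WRONG_ORIENTATION,
    CONVERGING_REGION,
    INTRAGENIC,
    PALINDROMIC_DUPLICATE,
)

#: feature kinds treated as genes for context classification
GENE_KINDS = ("gene", "CDS")


@dataclass
class FilterConfig:
    """Settings of the post-scan context filter."""

    max_upstream: int = 300
    min_upstream: int = 0
    drop_intragenic: bool = True
    palindromic: bool = False
    overlap_fraction: float = 0.5

    def __post_init__(self):
        if self.min_upstream > self.max_upstream:
            raise ValueError("min_upstream must be <= max_upstream")
        if not (0.0 < self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in (0, 1]")


def _gene_intervals(record: GenomeRecord) -> list[tuple[int, int, Optional[str]]]:
    seen = set()
    out = []
    for f in record.features_of_kind(*GENE_KINDS):
        key = (f.start, f.end, f.strand)
        if key not in seen:
            seen.add(key)
            out.append(key)
    out.sort()
    return out


def dedupe_palindromic(hits: list[Hit], cfg: FilterConfig) -> list[Hit]:
    """Collapse the strand double-report of palindromic sites.

    Opposite-strand hits whose intervals reciprocally overlap by at least
    ``cfg.overlap_fraction`` are linked; each connected component keeps its
    highest-scoring hit (plus strand wins exact score ties).  With
    ``cfg.palindromic`` false this is the identity.
    """
    if not cfg.palindromic or not hits:
        return sorted(hits, key=Hit.sort_key)
    n = len(hits)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    order = sorted(range(n), key=lambda i: hits[i].start)
    for a_pos, i in enumerate(order):
        hi = hits[i]
        for j in order[a_pos + 1 :]:
            hj = hits[j]
            if hj.start >= hi.end:
                break
            if hi.strand == hj.strand:
                continue
            ov = min(hi.end, hj.end) - max(hi.start, hj.start)
            if (
                ov / (hi.end - hi.start) >= cfg.overlap_fraction
                and ov / (hj.end - hj.start) >= cfg.overlap_fraction
            ):
                union(i, j)
    best: dict[int, Hit] = {}
    for i, h in enumerate(hits):
        r = find(i)
        cur = best.get(r)
        if cur is None or _dedupe_rank(h) < _dedupe_rank(cur):
            best[r] = h
    return sorted(best.values(), key=Hit.sort_key)


def _dedupe_rank(h: Hit) -> tuple:
    return (-h.score, 0 if h.strand == "+" else 1, h.start)


def classify_context(hit: Hit, record: GenomeRecord, cfg: FilterConfig) -> str:
    """Classify one hit against the gene annotation (see module docstring)."""
    genes = _gene_intervals(record)
    if not genes:
        raise AnnotationMissingError(
            f"record {record.id!r} has no gene/CDS features to filter against"
        )
    for g_start, g_end, _ in genes:
        if hit.start < g_end and g_start < hit.end:
            return INTRAGENIC
    for (a_start, a_end, a_strand), (b_start, b_end, b_strand) in zip(
        genes, genes[1:]
    ):
        if (
            a_strand == "+"
            and b_strand == "-"
            and a_end <= hit.start
            and hit.end <= b_start
        ):
            return CONVERGING_REGION
    if hit.strand == "+":
        downstream = [s for s, _, st in genes if st == "+" and s >= hit.end]
        dist = min(downstream) - hit.end if downstream else None
    else:
        downstream = [e for _, e, st in genes if st == "-" and e <= hit.start]
        dist = hit.start - max(downstream) if downstream else None
    if dist is not None and cfg.min_upstream <= dist <= cfg.max_upstream:
        return UPSTREAM_OK
    return WRONG_ORIENTATION


@dataclass
class FilterReport:
    """Per-category hit counts; categories partition the input exactly."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CATEGORIES}
    )

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_text(self) -> str:
        lines = [f"{cat}\t{self.counts[cat]}" for cat in CATEGORIES]
        lines.append(f"total\t{self.total}")
        return "\n".join(lines) + "\n"


def filter_hits(
    hits: list[Hit], record: GenomeRecord, cfg: FilterConfig
) -> tuple[list[Hit], FilterReport]:
    """Dedupe then drop contextually implausible hits.

    Wrong-orientation and converging-region hits are always dropped;
    intragenic hits only when ``cfg.drop_intragenic``.  The report counts
    every input hit exactly once (palindromic duplicates included).
    """
    report = FilterReport()
    deduped = dedupe_palindromic(hits, cfg)
    report.counts[PALINDROMIC_DUPLICATE] = len(hits) - len(deduped)
    kept = []
    for h in deduped:
        cat = classify_context(h, record, cfg)
        report.counts[cat] += 1
        if cat == UPSTREAM_OK or (cat == INTRAGENIC and not cfg.drop_intragenic):
            kept.append(h)
    return kept, report
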