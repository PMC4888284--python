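"""Iterative cross-genome profile optimisation.

Starting from a seed alignment of known sites, the loop scans a set of
target genomes, retains context-plausible hits above a retention score,
rebuilds the probability matrix from the retained sites, probes the
alignment boundaries for additional conserved columns (kept when their
information content clears a threshold), and repeats until the retained
site set and the profile width stop changing.  The final profile is
calibrated in the trusted/noise/gathering convention: trusted = weakest
retained-site score, noise = strongest rejected hit.

Curator judgement about which extra sites are biologically plausible is
operationalised as an explicit ``target_regions`` allowlist; sites matching
the seed alignment's own genomic intervals are always retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from ._dna import revcomp
from .errors import OptimizationCollapseError
from .genome_io import GenomeRecord
from .motifs import (
    Profile,
    Provenance,
    Site,
    SiteAlignment,
    build_profile,
    calibrate,
    extend_alignment,
    information_content,
    slice_alignment,
)
from .postprocess import FilterConfig, filter_hits
from .scan import scan_genome

logger = logging.getLogger(__name__)


@dataclass
class OptimizeConfig:
    """Settings of the optimisation loop."""

    max_iterations: int = 5
    retain_score: Union[float, str] = "noise-cutoff"  # bits, or the profile's noise
    extension_probe: int = 5  # nt probed on each side per round
    column_keep_ic: float = 0.3  # bits; flank columns below this are rejected
    target_regions: Optional[dict[str, list[tuple[int, int]]]] = None
    seed: int = 0

    def __post_init__(self):
        if self.extension_probe < 0:
            raise ValueError("extension_probe must be >= 0")
        if not (0.0 <= self.column_keep_ic <= 2.0):
            raise ValueError("column_keep_ic must be in [0, 2]")


@dataclass
class OptimizeResult:
    """Outcome of :func:`optimize_profile`."""

    profile: Profile
    alignment: SiteAlignment
    rounds: int
    converged: bool
    history: list[dict] = field(default_factory=list)


def _retention_cutoff(profile: Profile, cfg: OptimizeConfig) -> float:
    if cfg.retain_score == "noise-cutoff":
        if profile.cutoffs.noise is None:
            raise ValueError(
                "retain_score is 'noise-cutoff' but the profile has no noise cutoff"
            )
        return float(profile.cutoffs.noise)
    return float(cfg.retain_score)


def _overlaps_any(start, end, intervals) -> bool:
    return any(start < b and a < end for a, b in intervals)


def collect_candidate_sites(
    profile: Profile,
    genomes: Sequence[GenomeRecord],
    cfg: OptimizeConfig,
    filter_cfg: Optional[FilterConfig] = None,
    seed_sites: Optional[Sequence[Provenance]] = None,
) -> SiteAlignment:
    """Scan the target genomes and assemble the retained-site alignment.

    Hits must score at least the retention cutoff.  Hits overlapping a seed
    site's genomic interval count as re-found seed sites and are always
    included; other hits must additionally pass the context filter and, when
    ``cfg.target_regions`` is given, fall inside an allowed region.
    """
    if not genomes:
        raise ValueError("empty genome list")
    retain = _retention_cutoff(profile, cfg)
    seed_by_genome: dict[str, list[tuple[int, int]]] = {}
    for p in seed_sites or ():
        seed_by_genome.setdefault(p.genome, []).append((p.start, p.end))
    sites: list[Site] = []
    counter = 0
    for rec in genomes:
        hits = scan_genome(profile, rec, mode="score", cutoff=retain)
        if filter_cfg is not None:
            kept, _ = filter_hits(hits, rec, filter_cfg)
        else:
            kept = hits
        kept_set = {(h.start, h.end, h.strand) for h in kept}
        seed_ivals = seed_by_genome.get(rec.id, [])
        regions = (cfg.target_regions or {}).get(rec.id)
        for h in hits:
            is_seed = _overlaps_any(h.start, h.end, seed_ivals)
            if not is_seed:
                if (h.start, h.end, h.strand) not in kept_set:
                    continue
                if regions is not None and not _overlaps_any(h.start, h.end, regions):
                    continue
            chunk = rec.sequence[h.start : h.end].upper()
            if h.strand == "-":
                chunk = revcomp(chunk)
            sites.append(
                Site(
                    f"{rec.id}_{counter:04d}",
                    chunk,
                    Provenance(rec.id, h.start, h.end, h.strand),
                )
            )
            counter += 1
    if not sites:
        raise OptimizationCollapseError(
            f"no sites retained at cutoff {retain:.2f} bits", round_number=0
        )
    return SiteAlignment(profile.name, sites, profile.masked_columns)


def refine_boundaries(
    aln: SiteAlignment,
    genomes: Sequence[GenomeRecord] | dict[str, GenomeRecord],
    cfg: OptimizeConfig,
) -> SiteAlignment:
    """Probe alignment flanks and keep conserved columns; trim weak edges.

    Each side is extended by ``cfg.extension_probe`` columns re-extracted
    from the source genomes; the maximal contiguous run of probe columns
    with per-column information content >= ``cfg.column_keep_ic`` (measured
    without pseudocount) is kept.  Edge columns of the original core below
    the threshold are trimmed symmetrically.  Deterministic.
    """
    if not isinstance(genomes, dict):
        genomes = {g.id: g for g in genomes}
    probe = cfg.extension_probe
    if probe == 0:
        ext = aln
    else:
        ext = extend_alignment(aln, genomes, probe, probe)
    core_L = aln.length
    ic, _ = information_content(build_profile(ext, pseudocount=0.0))
    thr = cfg.column_keep_ic

    lo = probe
    while lo > 0 and ic[lo - 1] >= thr:
        lo -= 1
    hi = probe + core_L
    while hi < ext.length and ic[hi] >= thr:
        hi += 1
    if lo == probe:  # no left flank kept: trim weak core edge columns
        while lo < probe + core_L - 1 and ic[lo] < thr:
            lo += 1
    if hi == probe + core_L:
        while hi > lo + 1 and ic[hi - 1] < thr:
            hi -= 1
    return slice_alignment(ext, [(lo, hi)])


def optimize_profile(
    seed_aln: SiteAlignment,
    genomes: Sequence[GenomeRecord],
    cfg: OptimizeConfig | None = None,
    filter_cfg: Optional[FilterConfig] = None,
) -> OptimizeResult:
    """Run the collect → rebuild → refine loop to convergence and calibrate.

    Convergence: the (site set, width) pair is unchanged between two
    successive rounds.  The final profile's trusted cutoff is the weakest
    retained-site score; the noise cutoff the strongest rejected hit (the
    best-scoring hit not in the final site set), gathering their mean.
    """
    cfg = cfg or OptimizeConfig()
    if not genomes:
        raise ValueError("empty genome list")
    genome_map = {g.id: g for g in genomes}
    seed_prov = [s.provenance for s in seed_aln.sites if s.provenance is not None]
    aln = seed_aln
    state = (frozenset(seed_prov), aln.length)
    converged = False
    history = []
    rounds = 0
    for r in range(1, cfg.max_iterations + 1):
        rounds = r
        profile = build_profile(aln, name=seed_aln.name)
        try:
            collected = collect_candidate_sites(
                profile, genomes, cfg, filter_cfg, seed_sites=seed_prov
            )
        except OptimizationCollapseError as e:
            raise OptimizationCollapseError(str(e), round_number=r) from None
        refined = refine_boundaries(collected, genome_map, cfg)
        new_state = (
            frozenset(s.provenance for s in refined.sites),
            refined.length,
        )
        history.append(
            {
                "round": r,
                "sites": refined.nsites,
                "width": refined.length,
            }
        )
        logger.info(
            "round %d: %d sites retained, width %d", r, refined.nsites, refined.length
        )
        aln = refined
        if new_state == state:
            converged = True
            break
        state = new_state

    final_profile = build_profile(aln, name=seed_aln.name)
    training = [
        _self_score(final_profile, s.seq) for s in aln.sites
    ]
    decoys = _rejected_scores(final_profile, genomes, aln)
    calibrated = calibrate(final_profile, training, decoys[:50])
    logger.info(
        "calibrated: trusted %.2f noise %.2f gathering %.2f",
        calibrated.cutoffs.trusted,
        calibrated.cutoffs.noise,
        calibrated.cutoffs.gathering,
    )
    return OptimizeResult(calibrated, aln, rounds, converged, history)


def _self_score(profile: Profile, seq: str) -> float:
    from .scan import score_window

    return score_window(profile, seq)


def _rejected_scores(
    profile: Profile, genomes: Sequence[GenomeRecord], aln: SiteAlignment
) -> list[float]:
    """Best-scoring hits that are not part of the final alignment."""
    final_ivals: dict[str, list[tuple[int, int]]] = {}
    for s in aln.sites:
        p = s.provenance
        if p is not None:
            final_ivals.setdefault(p.genome, []).append((p.start, p.end))
    scores: list[float] = []
    for rec in genomes:
        for h in scan_genome(profile, rec, mode="score", cutoff=0.0):
            if not _overlaps_any(h.start, h.end, final_ivals.get(rec.id, [])):
                scores.append(h.score)
    scores.sort(reverse=True)
    return scores
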