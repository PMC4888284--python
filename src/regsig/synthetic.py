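"""Synthetic annotated genomes with planted regulatory signals.

The generator lays operons alternately on both strands along a random
(i.i.d., GC-controlled) background sequence.  Each selected operon gets one
motif instance planted a short, configurable distance upstream of its first
gene; a configurable fraction of operons end in a canonical intrinsic
terminator (8-bp perfect GC stem, 4-nt loop, 8-nt T tail).  Decoy motif
copies are planted inside genes and between converging gene pairs, so the
intragenic and converging-region context filters are exercised by
construction.  Everything is deterministic for a fixed seed, and a
:class:`TruthTable` records planted coordinates, operon memberships and the
expected transcription-unit end reasons for oracle-style tests.

When the motif is given as a consensus string, planted instances are exact
consensus copies (so every planted site scores at the profile maximum); a
:class:`~regsig.motifs.Profile` motif is sampled column by column instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from ._dna import BASES, revcomp
from .errors import LayoutError
from .genome_io import Feature, GenomeRecord
from .motifs import Profile, Provenance, Site, SiteAlignment

#: default 20-bp planted motif consensus
DEFAULT_MOTIF = "ATTGACCGGTACGATCGCAT"

#: canonical planted terminator hairpin: 8-bp perfect stem, 4-nt loop
TERMINATOR_STEM = "GGCTAGCC"
TERMINATOR_LOOP = "TTCA"

REGULATORY = "regulatory"
INTRAGENIC_DECOY = "intragenic-decoy"
CONVERGING_DECOY = "converging-decoy"


@dataclass
class SimConfig:
    """Study conditions of a simulated genome (all lengths in nt)."""

    length: int = 50_000
    gc_content: float = 0.5
    n_operons: int = 10
    genes_per_operon: tuple[int, int] = (2, 4)
    gene_len: tuple[int, int] = (300, 900)
    intra_operon_gap: tuple[int, int] = (20, 120)  # below regulon max_gap
    inter_operon_gap: tuple[int, int] = (450, 650)  # above it
    motif: Union[str, Profile] = DEFAULT_MOTIF
    motif_name: str = "RegA"
    sites_per_motif: Optional[int] = None  # default: one per operon
    site_upstream_offset: tuple[int, int] = (20, 100)
    terminator_fraction: float = 0.5
    decoy_intragenic_sites: int = 3
    decoy_converging_sites: int = 2
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (
            self.genes_per_operon,
            self.gene_len,
            self.intra_operon_gap,
            self.inter_operon_gap,
            self.site_upstream_offset,
        ):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must be non-negative with lo <= hi")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        if not (0.0 <= self.terminator_fraction <= 1.0):
            raise ValueError("terminator_fraction must be in [0, 1]")


@dataclass(frozen=True)
class PlantedSite:
    start: int
    end: int
    strand: str
    motif: str
    category: str = REGULATORY
    operon: Optional[int] = None


@dataclass(frozen=True)
class PlantedTerminator:
    start: int  # hairpin span (stem1..stem2), excluding the tail
    end: int
    strand: str
    operon: int


@dataclass
class PlantedOperon:
    index: int
    strand: str
    locus_tags: list[str]  # transcription order
    gene_intervals: list[tuple[int, int]]  # transcription order
    site: Optional[PlantedSite]
    terminator: Optional[PlantedTerminator]
    expected_end_reason: str


@dataclass
class TruthTable:
    """Ground truth of one simulated genome."""

    sites: list[PlantedSite] = field(default_factory=list)
    decoys: list[PlantedSite] = field(default_factory=list)
    terminators: list[PlantedTerminator] = field(default_factory=list)
    operons: list[PlantedOperon] = field(default_factory=list)

    def all_planted_intervals(self) -> list[tuple[int, int]]:
        out = [(s.start, s.end) for s in self.sites + self.decoys]
        out += [(t.start, t.end) for t in self.terminators]
        return out


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _motif_instance(rng: np.random.Generator, motif: Union[str, Profile]) -> str:
    if isinstance(motif, str):
        return motif.upper()
    cols = [rng.choice(4, p=motif.matrix[j]) for j in range(motif.length)]
    return "".join(BASES[c] for c in cols)


def _motif_len(motif: Union[str, Profile]) -> int:
    return len(motif) if isinstance(motif, str) else motif.length


def _paste(seq: np.ndarray, start: int, text: str) -> None:
    seq[start : start + len(text)] = np.frombuffer(text.encode(), dtype="S1")


def simulate_genome(cfg: SimConfig | None = None) -> tuple[GenomeRecord, TruthTable]:
    """Generate one annotated replicon plus its ground truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    seq = _random_sequence(rng, cfg.length, cfg.gc_content)
    truth = TruthTable()
    features: list[Feature] = []
    record_id = f"synth{cfg.seed}"

    if cfg.n_operons == 0:
        record = GenomeRecord(record_id, b"".join(seq).decode(), [])
        return record, truth

    W = _motif_len(cfg.motif)
    n_sites = cfg.n_operons if cfg.sites_per_motif is None else min(
        cfg.sites_per_motif, cfg.n_operons
    )
    site_ops = set(sorted(rng.permutation(cfg.n_operons)[:n_sites].tolist()))
    n_terms = int(round(cfg.terminator_fraction * cfg.n_operons))
    term_ops = set(sorted(rng.permutation(cfg.n_operons)[:n_terms].tolist()))

    def draw(rg: tuple[int, int]) -> int:
        return int(rng.integers(rg[0], rg[1] + 1))

    pos = draw(cfg.inter_operon_gap)
    locus_counter = 0
    block_bounds: list[tuple[int, int]] = []  # occupied span of each operon block
    pending_terms: list[tuple[int, str, int]] = []  # (hairpin start, strand, operon)

    for i in range(cfg.n_operons):
        strand = "+" if i % 2 == 0 else "-"
        block_start = pos
        n_genes = draw(cfg.genes_per_operon)
        glens = [draw(cfg.gene_len) for _ in range(n_genes)]
        ggaps = [draw(cfg.intra_operon_gap) for _ in range(n_genes - 1)]
        has_site = i in site_ops
        has_term = i in term_ops
        offset = draw(cfg.site_upstream_offset)
        term_gap = int(rng.integers(15, 41))
        site_span = None
        term_info = None
        gene_intervals: list[tuple[int, int]] = []

        if strand == "+":
            if has_site:
                site_span = (pos, pos + W)
                pos = pos + W + offset
            for k, gl in enumerate(glens):
                gene_intervals.append((pos, pos + gl))
                pos += gl
                if k < n_genes - 1:
                    pos += ggaps[k]
            if has_term:
                pos += term_gap
                term_info = (pos, "+")  # hairpin [pos, pos+20), tail follows
                pos += 28
        else:
            if has_term:
                term_info = (pos + 8, "-")  # top-strand: 8-nt tail first
                pos += 28
                pos += term_gap
            for k in range(n_genes - 1, -1, -1):
                gene_intervals.append((pos, pos + glens[k]))
                pos += glens[k]
                if k > 0:
                    pos += ggaps[k - 1]
            if has_site:
                pos += offset
                site_span = (pos, pos + W)
                pos += W

        if pos >= cfg.length:
            raise LayoutError(
                f"operon layout exceeds genome length at operon {i} "
                f"(needs > {pos} nt, have {cfg.length})"
            )

        # features + truth bookkeeping (transcription order for truth)
        tags = []
        for a, b in gene_intervals:
            tag = f"SYN_{locus_counter:04d}"
            locus_counter += 1
            for kind in ("gene", "CDS"):
                quals = {"locus_tag": [tag]}
                if kind == "CDS":
                    quals["product"] = ["hypothetical protein"]
                features.append(Feature(kind, a, b, strand, quals))
            tags.append(tag)
        if strand == "-":
            tags = tags[::-1]
            gene_order = gene_intervals[::-1]
        else:
            gene_order = list(gene_intervals)

        planted_site = None
        if site_span is not None:
            instance = _motif_instance(rng, cfg.motif)
            _paste(seq, site_span[0], instance if strand == "+" else revcomp(instance))
            planted_site = PlantedSite(
                site_span[0], site_span[1], strand, cfg.motif_name, REGULATORY, i
            )
            truth.sites.append(planted_site)

        planted_term = None
        if term_info is not None:
            h_start, t_strand = term_info
            # fixed canonical cassette: the CC guard blocks accidental stem
            # extension into flanking sequence (two outward mismatches exceed
            # the default budget), and the mixed-base stem has no equal-scoring
            # shifted pairing register, so detection lands on the exact span
            stem1, loop = TERMINATOR_STEM, TERMINATOR_LOOP
            term_seq = "CC" + stem1 + loop + revcomp(stem1) + "T" * 8
            if t_strand == "+":
                _paste(seq, h_start - 2, term_seq)
            else:
                _paste(seq, h_start - 8, revcomp(term_seq))
            planted_term = PlantedTerminator(h_start, h_start + 20, t_strand, i)
            truth.terminators.append(planted_term)
            pending_terms.append((h_start, t_strand, i))

        truth.operons.append(
            PlantedOperon(
                index=i,
                strand=strand,
                locus_tags=tags,
                gene_intervals=gene_order,
                site=planted_site,
                terminator=planted_term,
                expected_end_reason="",  # filled in below
            )
        )
        block_bounds.append((block_start, pos))
        pos += draw(cfg.inter_operon_gap)

    # expected end reasons: terminator if planted; else gap when any gene
    # lies further along the direction of transcription, else contig-end
    all_gene_spans = sorted(
        (f.start, f.end) for f in features if f.kind == "gene"
    )
    for op in truth.operons:
        if op.terminator is not None:
            op.expected_end_reason = "terminator"
            continue
        if op.strand == "+":
            last_end = op.gene_intervals[-1][1]
            beyond = any(s >= last_end for s, _ in all_gene_spans)
        else:
            first_start = op.gene_intervals[-1][0]
            beyond = any(e <= first_start for _, e in all_gene_spans)
        op.expected_end_reason = "gap" if beyond else "contig-end"

    # decoy sites inside genes
    genes_flat = [
        (a, b)
        for op in truth.operons
        for (a, b) in op.gene_intervals
        if b - a >= W + 40
    ]
    rng.shuffle(genes_flat)
    for a, b in genes_flat[: cfg.decoy_intragenic_sites]:
        s = int(rng.integers(a + 10, b - W - 10))
        instance = _motif_instance(rng, cfg.motif)
        d_strand = "+" if rng.integers(2) == 0 else "-"
        _paste(seq, s, instance if d_strand == "+" else revcomp(instance))
        truth.decoys.append(
            PlantedSite(s, s + W, d_strand, cfg.motif_name, INTRAGENIC_DECOY)
        )

    # decoy sites between converging operon pairs (+ block followed by - block)
    conv_pairs = [
        i
        for i in range(cfg.n_operons - 1)
        if truth.operons[i].strand == "+" and truth.operons[i + 1].strand == "-"
    ]
    planted_conv = 0
    for i in conv_pairs:
        if planted_conv >= cfg.decoy_converging_sites:
            break
        lo = block_bounds[i][1] + 10
        hi = block_bounds[i + 1][0] - 10 - W
        if hi <= lo:
            continue
        s = int(rng.integers(lo, hi + 1))
        instance = _motif_instance(rng, cfg.motif)
        d_strand = "+" if rng.integers(2) == 0 else "-"
        _paste(seq, s, instance if d_strand == "+" else revcomp(instance))
        truth.decoys.append(
            PlantedSite(s, s + W, d_strand, cfg.motif_name, CONVERGING_DECOY)
        )
        planted_conv += 1

    record = GenomeRecord(
        record_id,
        b"".join(seq).decode(),
        features,
        topology="linear",
        description="synthetic genome with planted regulatory signals",
    )
    return record, truth


def truth_sites_bed(truth: TruthTable, chrom: str) -> str:
    """Planted regulatory sites and decoys as BED6 (decoys named by category)."""
    lines = []
    for s in truth.sites + truth.decoys:
        name = s.motif if s.category == REGULATORY else s.category
        lines.append(f"{chrom}\t{s.start}\t{s.end}\t{name}\t0\t{s.strand}")
    return "\n".join(lines) + ("\n" if lines else "")


def truth_terminators_bed(truth: TruthTable, chrom: str) -> str:
    lines = [
        f"{chrom}\t{t.start}\t{t.end}\tterminator\t0\t{t.strand}"
        for t in truth.terminators
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_truth(truth: TruthTable, directory, chrom: str) -> None:
    """Write ground truth as BED6 files plus a structured-text manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "sites.bed").write_text(truth_sites_bed(truth, chrom))
    (directory / "terminators.bed").write_text(truth_terminators_bed(truth, chrom))
    manifest = {
        "operons": [
            {
                "index": op.index,
                "strand": op.strand,
                "locus_tags": op.locus_tags,
                "expected_end_reason": op.expected_end_reason,
                "has_site": op.site is not None,
                "has_terminator": op.terminator is not None,
            }
            for op in truth.operons
        ]
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


# ---------------------------------------------------------------------------
# Cross-genome ortholog sets for the profile-optimisation loop


@dataclass
class OrthologSet:
    """Planted ortholog fixture: genomes, a seed alignment, and full truth."""

    genomes: list[GenomeRecord]
    seed_alignment: SiteAlignment
    full_motif: str
    planted: dict[str, list[tuple[int, int]]]  # genome id -> full-width spans


def simulate_ortholog_set(
    n_genomes: int = 4,
    sites_per_genome: int = 12,
    core_motif: str = "TTGACGGCTAGGTCCTAC",
    flank_left: str = "G",
    flank_right: str = "C",
    spacing: int = 1200,
    seed: int = 0,
) -> OrthologSet:
    """Plant a motif (conserved flanks included) across several genomes.

    The planted instances carry ``flank_left + core + flank_right``; the seed
    alignment covers only the core, so boundary refinement should recover
    exactly ``len(flank_left) + len(flank_right)`` extra columns.  Every site
    has a downstream same-strand gene inside the default upstream window, so
    the context filter keeps it.
    """
    rng = np.random.default_rng(seed)
    full = (flank_left + core_motif + flank_right).upper()
    W = len(full)
    fl = len(flank_left)
    genomes = []
    planted: dict[str, list[tuple[int, int]]] = {}
    seed_sites = []
    for g in range(n_genomes):
        length = sites_per_genome * spacing + 800
        seq = _random_sequence(rng, length, 0.5)
        gid = f"ortho{g}"
        feats = []
        spans = []
        for k in range(sites_per_genome):
            p = 300 + k * spacing + int(rng.integers(0, 120))
            _paste(seq, p, full)
            spans.append((p, p + W))
            gene_start = p + W + int(rng.integers(30, 81))
            gene_end = gene_start + 400
            tag = f"{gid.upper()}_{k:03d}"
            feats.append(Feature("gene", gene_start, gene_end, "+", {"locus_tag": [tag]}))
            feats.append(
                Feature(
                    "CDS",
                    gene_start,
                    gene_end,
                    "+",
                    {"locus_tag": [tag], "product": ["hypothetical protein"]},
                )
            )
            if g == 0:
                seed_sites.append(
                    Site(
                        f"seed_{k:03d}",
                        full[fl : fl + len(core_motif)],
                        Provenance(gid, p + fl, p + fl + len(core_motif), "+"),
                    )
                )
        genomes.append(GenomeRecord(gid, b"".join(seq).decode(), feats))
        planted[gid] = spans
    seed_aln = SiteAlignment("ortholog-seed", seed_sites)
    return OrthologSet(genomes, seed_aln, full, planted)
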