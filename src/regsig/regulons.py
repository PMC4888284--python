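"""Transcription-unit (regulon) inference from annotated regulatory sites.

Every annotated TFBS (``protein_bind``) or promoter feature is treated as
the potential start of a transcription unit: the first gene on the unit
strand whose start falls inside a configurable downstream window anchors the
unit, which then extends over successive co-oriented genes until a
same-strand terminator, a large non-coding gap (or an intervening
opposite-strand gene), or the replicon end.

TFBS features are orientation-free — a protein bound between two divergently
transcribed operons can regulate both — so both directions are attempted,
and the two resulting units can be merged into a single *divergon* unit.
Promoter features direct RNA polymerase and use their annotated strand only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .genome_io import Feature, GenomeRecord

END_TERMINATOR = "terminator"
END_GAP = "gap"
END_CONTIG = "contig-end"

_GENE_KINDS = ("gene", "CDS")
_SITE_KINDS = ("promoter", "protein_bind")


@dataclass
class RegulonConfig:
    """Settings of the transcription-unit listing."""

    site_to_start_min: int = 0
    site_to_start_max: int = 300
    max_gap: int = 200
    list_divergons: bool = True
    regulator_filter: Optional[str] = None

    def __post_init__(self):
        if self.site_to_start_min > self.site_to_start_max:
            raise ValueError("site_to_start_min must be <= site_to_start_max")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


@dataclass
class TranscriptionUnit:
    """A regulator-anchored run of co-oriented genes.

    ``genes`` are ordered along the direction of transcription.  For a
    divergon, ``partner`` holds the oppositely directed arm and the unit is
    counted once.
    """

    regulator: str
    site: Feature
    strand: str
    genes: list[Feature]
    end_reason: str
    divergon: bool = False
    partner: Optional["TranscriptionUnit"] = None

    def gene_names(self) -> list[str]:
        out = []
        for g in self.genes:
            out.append(
                g.qualifier("locus_tag")
                or g.qualifier("gene")
                or f"{g.start}-{g.end}"
            )
        return out


def regulator_of_site(site: Feature) -> str:
    """Regulator name of a site feature (bound_moiety, or the note prefix)."""
    if site.kind == "protein_bind":
        return site.qualifier("bound_moiety") or "unknown"
    note = site.qualifier("note") or ""
    if " promoter" in note:
        return note.split(" promoter")[0]
    return note or "unknown"


def _unique_genes(record: GenomeRecord) -> list[Feature]:
    """One feature per (start, end, strand); gene preferred over CDS."""
    chosen: dict[tuple, Feature] = {}
    for f in record.features_of_kind(*_GENE_KINDS):
        key = (f.start, f.end, f.strand)
        if key not in chosen or (f.kind == "gene" and chosen[key].kind == "CDS"):
            chosen[key] = f
    return sorted(chosen.values(), key=lambda f: (f.start, f.end))


def infer_unit(
    record: GenomeRecord,
    site: Feature,
    direction: str,
    cfg: RegulonConfig | None = None,
) -> Optional[TranscriptionUnit]:
    """Infer the transcription unit started by ``site`` in ``direction``.

    Returns None when no same-strand gene start lies inside the
    site-to-start window.  Extension past a gene stops at a same-strand
    terminator (checked first), at a non-coding gap >= max_gap or an
    intervening opposite-strand gene, or at the replicon end.
    """
    cfg = cfg or RegulonConfig()
    if site not in record.features:
        raise ValueError("site is not a feature of the record")
    genes = _unique_genes(record)
    terms = [f for f in record.features_of_kind("terminator") if f.strand == direction]

    if direction == "+":
        cands = [
            g
            for g in genes
            if g.strand == "+"
            and cfg.site_to_start_min <= g.start - site.end <= cfg.site_to_start_max
        ]
        first = min(cands, key=lambda g: g.start) if cands else None
    else:
        cands = [
            g
            for g in genes
            if g.strand == "-"
            and cfg.site_to_start_min <= site.start - g.end <= cfg.site_to_start_max
        ]
        first = max(cands, key=lambda g: g.end) if cands else None
    if first is None:
        return None

    def term_between(a: int, b: int) -> bool:
        return any(a <= t.start and t.end <= b for t in terms)

    unit_genes = [first]
    end_reason = END_CONTIG
    if direction == "+":
        following = [g for g in genes if g.start >= first.end]
        following.sort(key=lambda g: (g.start, g.end))
        cur_end = first.end
        for g in following:
            if term_between(cur_end, g.start):
                end_reason = END_TERMINATOR
                break
            if g.strand != "+" or g.start - cur_end >= cfg.max_gap:
                end_reason = END_GAP
                break
            unit_genes.append(g)
            cur_end = max(cur_end, g.end)
        else:
            end_reason = (
                END_TERMINATOR if term_between(cur_end, len(record)) else END_CONTIG
            )
    else:
        preceding = [g for g in genes if g.end <= first.start]
        preceding.sort(key=lambda g: (-g.end, -g.start))
        cur_start = first.start
        for g in preceding:
            if term_between(g.end, cur_start):
                end_reason = END_TERMINATOR
                break
            if g.strand != "-" or cur_start - g.end >= cfg.max_gap:
                end_reason = END_GAP
                break
            unit_genes.append(g)
            cur_start = min(cur_start, g.start)
        else:
            end_reason = END_TERMINATOR if term_between(0, cur_start) else END_CONTIG

    return TranscriptionUnit(
        regulator=regulator_of_site(site),
        site=site,
        strand=direction,
        genes=unit_genes,
        end_reason=end_reason,
    )


def list_regulons(
    record: GenomeRecord, cfg: RegulonConfig | None = None
) -> tuple[list[TranscriptionUnit], dict[str, int]]:
    """List putative transcription units for every annotated regulatory site.

    Orientation-free sites (all ``protein_bind`` features) try both
    directions; promoters use their annotated strand (both when unstranded).
    When both directions yield units and ``cfg.list_divergons`` is set, they
    merge into one divergon unit, counted once.  Returns the units and
    per-regulator unit counts.
    """
    cfg = cfg or RegulonConfig()
    units: list[TranscriptionUnit] = []
    for site in record.features_of_kind(*_SITE_KINDS):
        regulator = regulator_of_site(site)
        if cfg.regulator_filter and regulator != cfg.regulator_filter:
            continue
        if site.kind == "protein_bind" or site.strand is None:
            directions = ("+", "-")
        else:
            directions = (site.strand,)
        found = {
            d: u
            for d in directions
            if (u := infer_unit(record, site, d, cfg)) is not None
        }
        if len(found) == 2 and cfg.list_divergons:
            plus, minus = found["+"], found["-"]
            plus.divergon = True
            plus.partner = minus
            minus.divergon = True
            units.append(plus)
        else:
            units.extend(found.values())
    counts = dict(Counter(u.regulator for u in units))
    return units, counts


def units_to_table(units: list[TranscriptionUnit]) -> str:
    """Tab-separated unit table (one row per unit; divergon arms joined)."""
    lines = ["regulator\tsite_start\tsite_end\tstrand\tgenes\tend_reason\tdivergon"]
    for u in units:
        genes = ",".join(u.gene_names())
        reason = u.end_reason
        strand = u.strand
        if u.partner is not None:
            genes += "|" + ",".join(u.partner.gene_names())
            reason += "|" + u.partner.end_reason
            strand = "+-"
        lines.append(
            f"{u.regulator}\t{u.site.start}\t{u.site.end}\t{strand}"
            f"\t{genes}\t{reason}\t{str(u.divergon).lower()}"
        )
    return "\n".join(lines) + "\n"


def counts_to_table(counts: dict[str, int]) -> str:
    lines = ["regulator\tunits"]
    for reg in sorted(counts):
        lines.append(f"{reg}\t{counts[reg]}")
    return "\n".join(lines) + "\n"
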