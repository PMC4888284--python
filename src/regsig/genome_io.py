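"""Annotated-genome I/O: GenBank flat files, feature editing, coverage tracks.

In memory, every location is 0-based half-open on the top strand; the
GenBank convention (1-based inclusive, ``complement()`` for the bottom
strand) exists only at the file boundary.  ``join()`` locations are kept as
their enclosing span with the original location string preserved verbatim in
a ``location_raw`` qualifier, so writing reproduces the compound location.

Reading and writing go through Biopython's SeqIO; this module is the thin,
typed surface the rest of the package uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import BiopythonParserWarning, SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import Location, SeqFeature, SimpleLocation
from Bio.SeqIO.InsdcIO import _insdc_location_string
from Bio.SeqRecord import SeqRecord

from .errors import GenBankFormatError, SelectorError, TrackError

RAW_LOCATION_QUALIFIER = "location_raw"

# fixed so that identical inputs produce byte-identical GenBank output
_DEFAULT_DATE = "01-JAN-1980"


@dataclass
class Feature:
    """A typed, stranded genome feature with an ordered qualifier map."""

    kind: str
    start: int
    end: int
    strand: Optional[str] = None  # "+", "-" or None (unstranded)
    qualifiers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.kind:
            raise ValueError("feature kind must be non-empty")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid feature interval [{self.start}, {self.end})"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def qualifier(self, key: str) -> Optional[str]:
        vals = self.qualifiers.get(key)
        return vals[0] if vals else None

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class GenomeRecord:
    """One replicon: sequence plus coordinate-sorted features."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    topology: str = "linear"
    description: str = ""

    def __post_init__(self):
        self.sort_features()

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end, f.kind))

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CoverageTrack:
    """A per-coordinate data track (e.g. read depth); 1-based coordinates."""

    points: list[tuple[int, float]]
    label: str = ""

    def __post_init__(self):
        prev = 0
        for i, (coord, value) in enumerate(self.points):
            if coord <= prev:
                raise TrackError("coordinates must be strictly increasing", i + 1)
            if value < 0:
                raise TrackError("values must be non-negative", i + 1)
            prev = coord


_STRAND_IN = {1: "+", -1: "-", None: None, 0: None}


def _feature_from_seqfeature(sf: SeqFeature, seq_len: int) -> Optional[Feature]:
    quals = {k: [str(x) for x in v] for k, v in sf.qualifiers.items()}
    loc = sf.location
    if loc is None:
        warnings.warn(
            f"feature {sf.type} has an unparsable location; keeping raw string",
            stacklevel=2,
        )
        quals.setdefault(RAW_LOCATION_QUALIFIER, [str(sf.qualifiers)])
        return Feature(sf.type, 0, seq_len, None, quals)
    start, end = int(loc.start), int(loc.end)
    if len(getattr(loc, "parts", [loc])) > 1:
        quals[RAW_LOCATION_QUALIFIER] = [_insdc_location_string(loc, seq_len)]
    return Feature(sf.type, start, end, _STRAND_IN.get(loc.strand), quals)


def read_genbank(path) -> list[GenomeRecord]:
    """Read a GenBank flat file into :class:`GenomeRecord` objects."""
    path = Path(path)
    records = []
    with warnings.catch_warnings():
        warnings.simplefilter("default", BiopythonParserWarning)
        try:
            parsed = list(SeqIO.parse(str(path), "genbank"))
        except ValueError as e:
            raise GenBankFormatError(f"cannot parse {path.name}: {e}") from e
        for rec in parsed:
            try:
                sequence = str(rec.seq).upper()
            except UndefinedSequenceError:
                raise GenBankFormatError(
                    f"record {rec.id!r} in {path.name} has no ORIGIN sequence"
                )
            if not sequence:
                raise GenBankFormatError(
                    f"record {rec.id!r} in {path.name} has an empty sequence"
                )
            feats = []
            for sf in rec.features:
                if sf.type == "source":
                    continue
                f = _feature_from_seqfeature(sf, len(sequence))
                if f is not None:
                    feats.append(f)
            records.append(
                GenomeRecord(
                    id=rec.id if rec.id != "<unknown id>" else rec.name,
                    sequence=sequence,
                    features=feats,
                    topology=rec.annotations.get("topology", "linear"),
                    description=rec.description,
                )
            )
    if not records:
        raise GenBankFormatError(f"no GenBank records in {path}")
    return records


_STRAND_OUT = {"+": 1, "-": -1, None: None}


def _seqfeature_from_feature(f: Feature, seq_len: int) -> SeqFeature:
    quals = {k: list(v) for k, v in f.qualifiers.items()}
    raw = quals.pop(RAW_LOCATION_QUALIFIER, None)
    if raw:
        try:
            loc = Location.fromstring(raw[0], length=seq_len)
        except Exception:
            loc = SimpleLocation(f.start, f.end, _STRAND_OUT[f.strand])
    else:
        loc = SimpleLocation(f.start, f.end, _STRAND_OUT[f.strand])
    return SeqFeature(location=loc, type=f.kind, qualifiers=quals)


def write_genbank(records: Iterable[GenomeRecord] | GenomeRecord, path) -> None:
    """Write records as a standard GenBank flat file (features in order)."""
    if isinstance(records, GenomeRecord):
        records = [records]
    seq_records = []
    for rec in records:
        rec.sort_features()
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.id,
            name=rec.id.split(".")[0][:16],
            description=rec.description,
            annotations={
                "molecule_type": "DNA",
                "topology": rec.topology,
                "date": _DEFAULT_DATE,
                "data_file_division": "BCT",
            },
        )
        sr.features = [_seqfeature_from_feature(f, len(rec)) for f in rec.features]
        seq_records.append(sr)
    SeqIO.write(seq_records, str(path), "genbank")


# ---------------------------------------------------------------------------
# Annotation of scan / terminator results


def _feature_key(f: Feature) -> tuple:
    return (f.kind, f.start, f.end, f.strand, f.qualifier("bound_moiety"))


def annotate_sites(
    record: GenomeRecord,
    hits: Sequence["Hit"],
    regulator: str,
    is_promoter: bool = False,
) -> GenomeRecord:
    """Add hits as ``promoter`` / ``protein_bind`` features (idempotent).

    A hit already present as a feature with the same kind, interval, strand
    and bound moiety is not added again, so repeated genome scans are safe.
    Hits outside the sequence raise after the valid ones are applied.
    """
    existing = {_feature_key(f) for f in record.features}
    new_features = list(record.features)
    bad = []
    for h in hits:
        if h.start < 0 or h.end > len(record):
            bad.append(h)
            continue
        if is_promoter:
            f = Feature(
                "promoter",
                h.start,
                h.end,
                h.strand,
                {"note": [f"{regulator} promoter, score {h.score:.2f}"]},
            )
        else:
            f = Feature(
                "protein_bind",
                h.start,
                h.end,
                h.strand,
                {
                    "bound_moiety": [regulator],
                    "note": [f"score {h.score:.2f}, p-value {h.pvalue:.3g}"],
                },
            )
        key = _feature_key(f)
        if key in existing:
            continue
        existing.add(key)
        new_features.append(f)
    if bad:
        warnings.warn(
            f"{len(bad)} hit(s) outside sequence bounds skipped: "
            + ", ".join(f"[{h.start},{h.end})" for h in bad),
            stacklevel=2,
        )
    return GenomeRecord(
        record.id, record.sequence, new_features, record.topology, record.description
    )


def annotate_terminators(
    record: GenomeRecord, candidates: Sequence["TerminatorCandidate"]
) -> GenomeRecord:
    """Add terminator candidates as ``terminator`` features (idempotent)."""
    existing = {_feature_key(f) for f in record.features}
    new_features = list(record.features)
    for c in candidates:
        f = Feature(
            "terminator",
            c.start,
            c.end,
            c.strand,
            {"note": [f"intrinsic terminator, confidence {c.confidence:.0f}"]},
        )
        key = _feature_key(f)
        if key in existing:
            continue
        existing.add(key)
        new_features.append(f)
    return GenomeRecord(
        record.id, record.sequence, new_features, record.topology, record.description
    )


def edit_feature(
    record: GenomeRecord,
    selector: tuple[str, int, int, Optional[str]],
    updates: dict[str, str | list[str]],
    rename_gene: Optional[str] = None,
) -> GenomeRecord:
    """Replace/add qualifiers on the single feature matching ``selector``.

    ``selector`` is (kind, start, end, strand).  ``rename_gene`` also updates
    the ``gene`` qualifier on the gene/CDS partner sharing the interval.
    """
    kind, start, end, strand = selector
    matches = [
        i
        for i, f in enumerate(record.features)
        if f.kind == kind and f.start == start and f.end == end and f.strand == strand
    ]
    if len(matches) != 1:
        raise SelectorError(
            f"selector {selector!r} matched {len(matches)} features (need exactly 1)",
            len(matches),
        )
    features = [replace(f, qualifiers={k: list(v) for k, v in f.qualifiers.items()})
                for f in record.features]
    target = features[matches[0]]
    for key, value in updates.items():
        target.qualifiers[key] = [value] if isinstance(value, str) else list(value)
    if rename_gene is not None:
        target.qualifiers["gene"] = [rename_gene]
        partner_kinds = {"gene", "CDS"} - {kind}
        for f in features:
            if (
                f.kind in partner_kinds
                and f.start == start
                and f.end == end
                and f.strand == strand
            ):
                f.qualifiers["gene"] = [rename_gene]
    return GenomeRecord(
        record.id, record.sequence, features, record.topology, record.description
    )


# ---------------------------------------------------------------------------
# Coverage tracks


def read_coverage_track(path, label: Optional[str] = None) -> CoverageTrack:
    """Read a tab-separated coverage track.

    Accepts two dialects, auto-detected per file: 2 columns
    (coordinate, value) and 3 columns (reference, coordinate, value) as
    produced by per-base depth tools.
    """
    path = Path(path)
    points: list[tuple[int, float]] = []
    prev = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                coord_s, value_s = fields
            elif len(fields) == 3:
                _, coord_s, value_s = fields
            else:
                raise TrackError(
                    f"expected 2 or 3 tab-separated fields, got {len(fields)}", lineno
                )
            try:
                coord = int(coord_s)
                value = float(value_s)
            except ValueError:
                raise TrackError(f"non-numeric field in {fields!r}", lineno)
            if coord <= prev:
                raise TrackError(
                    f"coordinate {coord} not greater than previous {prev}", lineno
                )
            points.append((coord, value))
            prev = coord
    return CoverageTrack(points, label or path.stem)
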