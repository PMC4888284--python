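"""Binding-site alignments and scoring profiles.

A transcription-factor binding site (TFBS) or promoter class is represented
by a gapless multiple alignment of equal-length DNA sites
(:class:`SiteAlignment`) and by the probability matrix built from it
(:class:`Profile`).  The profile is the scannable unit: per-column base
probabilities p(b, j) with a background distribution q(b), scored as log2
odds (bits).  Profiles carry calibration cutoffs in the trusted / noise /
gathering convention: *trusted* is the weakest score among known true sites,
*noise* the strongest score of a known false hit, and *gathering* — the
operational default threshold for genome scans — their arithmetic mean.

Coordinates are 0-based half-open throughout; strand "+" is the top
(annotated) strand of the genome.  Alignment columns may be masked: masked
columns contribute zero bits to information content and zero to window
scores, which lets low-information stretches inside a site (e.g. spacers of
sigma-factor promoters) be excluded without re-cutting the alignment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import yaml
from Bio import SeqIO

from ._dna import BASES, revcomp
from .errors import (
    AlignmentContentError,
    AlignmentShapeError,
    FlankBoundaryError,
    ProfileParseError,
    ProvenanceError,
)

_VALID_CHARS = set("ACGTN")
_GAP_CHARS = set(".-~")


class Provenance(NamedTuple):
    """Genomic origin of one aligned site (0-based half-open, top strand)."""

    genome: str
    start: int
    end: int
    strand: str  # "+" or "-"


@dataclass(frozen=True)
class Site:
    """One sequence of a site alignment."""

    id: str
    seq: str
    provenance: Optional[Provenance] = None


@dataclass
class SiteAlignment:
    """Gapless, equal-length alignment of binding-site/promoter sequences."""

    name: str
    sites: list[Site]
    mask: frozenset[int] = frozenset()

    def __post_init__(self):
        if not self.sites:
            raise AlignmentShapeError(f"alignment {self.name!r} has no sequences")
        L = len(self.sites[0].seq)
        for s in self.sites:
            if len(s.seq) != L:
                raise AlignmentShapeError(
                    f"record {s.id!r}: length {len(s.seq)} != {L}"
                )
            bad = set(s.seq) - _VALID_CHARS
            if bad & _GAP_CHARS:
                raise AlignmentContentError(f"record {s.id!r} contains gap characters")
            if bad:
                raise AlignmentContentError(
                    f"record {s.id!r} contains non-DNA characters: {sorted(bad)}"
                )
            if s.provenance is not None and s.provenance.end - s.provenance.start != L:
                raise ProvenanceError(
                    f"record {s.id!r}: provenance span != alignment length"
                )
        self.mask = frozenset(self.mask)
        if any(j < 0 or j >= L for j in self.mask):
            raise IndexError(f"mask index outside [0, {L})")

    @property
    def length(self) -> int:
        return len(self.sites[0].seq)

    @property
    def nsites(self) -> int:
        return len(self.sites)

    @property
    def sequences(self) -> list[str]:
        return [s.seq for s in self.sites]

    def to_fasta(self, path) -> None:
        """Write the alignment as FASTA, encoding provenance in headers."""
        with open(path, "w") as fh:
            for s in self.sites:
                header = s.id
                if s.provenance is not None:
                    p = s.provenance
                    header = f"{s.id}:{p.genome}:{p.start}-{p.end}:{p.strand}"
                fh.write(f">{header}\n{s.seq}\n")


def load_alignment(path, name: Optional[str] = None) -> SiteAlignment:
    """Load a gapless FASTA alignment of binding sites.

    Headers of the form ``id:genome:start-end:strand`` yield per-sequence
    provenance (0-based half-open, top strand); any other header is kept as
    an opaque id.
    """
    path = Path(path)
    sites = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        prov = None
        parts = rec.id.split(":")
        if len(parts) == 4 and parts[3] in "+-":
            span = parts[2].split("-")
            try:
                prov = Provenance(parts[1], int(span[0]), int(span[1]), parts[3])
                parts = parts[:1]
            except (ValueError, IndexError):
                prov = None
        sites.append(Site(parts[0], seq, prov))
    if not sites:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    return SiteAlignment(name or path.stem, sites)


def _check_ranges(ranges, L):
    if not ranges:
        raise ValueError("empty range list")
    norm = sorted((int(a), int(b)) for a, b in ranges)
    for a, b in norm:
        if a < 0 or b > L or a >= b:
            raise IndexError(f"range [{a}, {b}) outside alignment of length {L}")
    for (_, b0), (a1, _) in zip(norm, norm[1:]):
        if a1 < b0:
            raise ValueError("ranges overlap")
    return norm


def slice_alignment(aln: SiteAlignment, ranges: Sequence[tuple[int, int]]) -> SiteAlignment:
    """Keep only the given column intervals (concatenated in genomic order).

    Provenance survives only a single contiguous range (coordinates are
    shifted); multiple ranges break genomic contiguity, so it is dropped.
    """
    L = aln.length
    norm = _check_ranges(ranges, L)
    cols = [j for a, b in norm for j in range(a, b)]
    col_map = {j: i for i, j in enumerate(cols)}
    single = len(norm) == 1
    new_sites = []
    for s in aln.sites:
        seq = "".join(s.seq[j] for j in cols)
        prov = None
        if single and s.provenance is not None:
            a, b = norm[0]
            p = s.provenance
            if p.strand == "+":
                prov = Provenance(p.genome, p.start + a, p.start + b, "+")
            else:
                # column j is genomic position end-1-j on the minus strand
                prov = Provenance(p.genome, p.end - b, p.end - a, "-")
        new_sites.append(Site(s.id, seq, prov))
    new_mask = frozenset(col_map[j] for j in aln.mask if j in col_map)
    return SiteAlignment(aln.name, new_sites, new_mask)


def mask_columns(aln: SiteAlignment, ranges: Sequence[tuple[int, int]]) -> SiteAlignment:
    """Return a copy with the given column intervals added to the mask."""
    if not ranges:
        return SiteAlignment(aln.name, list(aln.sites), aln.mask)
    norm = []
    for a, b in ranges:
        a, b = int(a), int(b)
        if a < 0 or b > aln.length or a > b:
            raise IndexError(f"mask range [{a}, {b}) outside [0, {aln.length})")
        norm.append((a, b))
    extra = {j for a, b in norm for j in range(a, b)}
    return SiteAlignment(aln.name, list(aln.sites), aln.mask | extra)


def extend_alignment(
    aln: SiteAlignment,
    genomes: Mapping[str, "GenomeRecord"],
    left: int,
    right: int,
    drop_on_error: bool = False,
) -> SiteAlignment:
    """Re-extract every site from its source genome with extra flanks.

    ``left``/``right`` are counted 5'/3' on the site's own strand, so a
    minus-strand site grows toward higher top-strand coordinates on its
    ``left``.  Requires provenance for every sequence.
    """
    if left < 0 or right < 0:
        raise ValueError("flank lengths must be non-negative")
    if left == 0 and right == 0:
        return SiteAlignment(aln.name, list(aln.sites), aln.mask)
    new_sites = []
    failed = []
    for s in aln.sites:
        p = s.provenance
        if p is None:
            raise ProvenanceError(f"record {s.id!r} has no provenance")
        if p.genome not in genomes:
            raise ProvenanceError(f"record {s.id!r}: genome {p.genome!r} not supplied")
        genome_seq = genomes[p.genome].sequence
        if p.strand == "+":
            a, b = p.start - left, p.end + right
        else:
            a, b = p.start - right, p.end + left
        if a < 0 or b > len(genome_seq):
            failed.append(s.id)
            continue
        chunk = genome_seq[a:b].upper()
        if p.strand == "-":
            chunk = revcomp(chunk)
        new_sites.append(Site(s.id, chunk, Provenance(p.genome, a, b, p.strand)))
    if failed and not drop_on_error:
        raise FlankBoundaryError(
            f"flank extension beyond contig end for: {', '.join(failed)}", failed
        )
    if not new_sites:
        raise FlankBoundaryError("every sequence was dropped during extension", failed)
    new_mask = frozenset(j + left for j in aln.mask)
    return SiteAlignment(aln.name, new_sites, new_mask)


# ---------------------------------------------------------------------------
# Profiles


@dataclass
class Cutoffs:
    """Calibration cutoffs in bits (all optional until calibrated)."""

    trusted: Optional[float] = None
    noise: Optional[float] = None
    gathering: Optional[float] = None
    noise_provisional: bool = False


@dataclass
class FilterDefaults:
    """Per-profile defaults for the context filter applied after scanning."""

    max_upstream: int = 300
    min_upstream: int = 0
    allow_intragenic: bool = False


@dataclass
class Profile:
    """Per-column base-probability matrix plus scan/filter metadata.

    ``matrix`` is L x 4 over (A, C, G, T); every row sums to 1.  ``background``
    is the null base distribution used for log-odds scoring and p-values.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.5
    masked_columns: frozenset[int] = frozenset()
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    palindromic: bool = False
    filter_defaults: FilterDefaults = field(default_factory=FilterDefaults)
    description: str = ""
    nsites: int = 0
    is_promoter: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("profile matrix must be L x 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must each sum to 1")
        if self.background.shape != (4,) or not math.isclose(
            self.background.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError("background must be 4 probabilities summing to 1")
        if np.any(self.background <= 0):
            raise ValueError("background probabilities must all be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        self.masked_columns = frozenset(self.masked_columns)
        if any(j < 0 or j >= self.length for j in self.masked_columns):
            raise IndexError("masked column outside profile width")
        c = self.cutoffs
        if (
            c.trusted is not None
            and c.noise is not None
            and c.noise >= c.trusted
        ):
            warnings.warn(
                f"profile {self.name!r}: noise cutoff >= trusted cutoff "
                "(non-canonical ordering kept)",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return self.matrix.shape[0]


def build_profile(
    aln: SiteAlignment,
    pseudocount: float = 0.5,
    background: Optional[Sequence[float]] = None,
    name: Optional[str] = None,
) -> Profile:
    """Count-based probability matrix: p(b,j) = (n_bj + a) / (n + 4a).

    An N in the input contributes 1/4 of a count to each base.  The
    alignment mask is copied into the profile's masked columns; cutoffs are
    left unset (see :func:`calibrate`).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    L, n = aln.length, aln.nsites
    counts = np.zeros((L, 4))
    for s in aln.sites:
        for j, b in enumerate(s.seq):
            if b == "N":
                counts[j] += 0.25
            else:
                counts[j, BASES.index(b)] += 1.0
    matrix = (counts + pseudocount) / (n + 4.0 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return Profile(
        name=name or aln.name,
        matrix=matrix,
        background=bg,
        pseudocount=pseudocount,
        masked_columns=aln.mask,
        nsites=n,
    )


def information_content(
    profile: Profile, small_sample_correction: bool = False
) -> tuple[np.ndarray, float]:
    """Per-column and total information content in bits.

    Uses the uniform-background definition IC_j = 2 + sum_b p log2 p, with
    0·log 0 = 0; masked columns report 0.  The optional small-sample
    correction subtracts the expected entropy excess 3 / (2 ln2 · n) per
    column (clipped at zero); it is off by default.
    """
    p = profile.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    if small_sample_correction:
        if profile.nsites <= 0:
            raise ValueError("small-sample correction requires a positive nsites")
        ic = np.clip(ic - 3.0 / (2.0 * math.log(2.0) * profile.nsites), 0.0, None)
    if profile.masked_columns:
        ic[list(profile.masked_columns)] = 0.0
    ic = np.clip(ic, 0.0, 2.0)
    return ic, float(ic.sum())


def logo_matrix(profile: Profile) -> np.ndarray:
    """Sequence-logo letter heights: height(b,j) = p(b,j) * IC_j (L x 4)."""
    ic, _ = information_content(profile)
    return profile.matrix * ic[:, None]


def calibrate(
    profile: Profile,
    training_scores: Iterable[float],
    decoy_scores: Iterable[float] = (),
) -> Profile:
    """Set trusted / noise / gathering cutoffs from observed scores.

    trusted = min(training), noise = max(decoys), gathering = their mean.
    With no decoys the noise cutoff falls back to trusted − 0.5·|trusted|
    and is flagged provisional.  noise >= trusted warns but is stored (the
    orderings found in practice are not always canonical).
    """
    training = [float(x) for x in training_scores]
    decoys = [float(x) for x in decoy_scores]
    if not training:
        raise ValueError("training_scores must be non-empty")
    trusted = min(training)
    if decoys:
        noise = max(decoys)
        provisional = False
    else:
        noise = trusted - 0.5 * abs(trusted)
        provisional = True
        warnings.warn(
            f"profile {profile.name!r}: no decoy scores; noise cutoff is provisional",
            stacklevel=2,
        )
    gathering = (trusted + noise) / 2.0
    cut = Cutoffs(trusted, noise, gathering, provisional)
    if noise >= trusted:
        warnings.warn(
            f"profile {profile.name!r}: noise cutoff ({noise:.3g}) >= trusted "
            f"({trusted:.3g})",
            stacklevel=2,
        )
    return replace(profile, cutoffs=cut)


# ---------------------------------------------------------------------------
# MEME motif format v4 + structured-text side-car

_SIDECAR_SUFFIX = ".yaml"


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(_SIDECAR_SUFFIX)


def write_profile(profile: Profile, path) -> None:
    """Serialize as a MEME v4 motif file plus a YAML side-car.

    The MEME file holds the letter-probability matrix and background; the
    side-car (same basename, ``.yaml``) holds everything MEME cannot:
    cutoffs, mask, pseudocount, filter defaults, description.
    """
    path = Path(path)
    bg = profile.background
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(BASES)),
        "",
        f"MOTIF {profile.name}",
        (
            f"letter-probability matrix: alength= 4 w= {profile.length} "
            f"nsites= {max(profile.nsites, 1)} E= 0"
        ),
    ]
    for row in profile.matrix:
        lines.append(" " + " ".join(f"{x:.6f}" for x in row))
    lines.append("")
    path.write_text("\n".join(lines))

    c = profile.cutoffs
    meta = {
        "name": profile.name,
        "description": profile.description,
        "pseudocount": float(profile.pseudocount),
        "masked_columns": sorted(profile.masked_columns),
        "palindromic": bool(profile.palindromic),
        "is_promoter": bool(profile.is_promoter),
        "cutoffs": {
            "trusted": c.trusted,
            "noise": c.noise,
            "gathering": c.gathering,
            "noise_provisional": bool(c.noise_provisional),
        },
        "filter": {
            "max_upstream": int(profile.filter_defaults.max_upstream),
            "min_upstream": int(profile.filter_defaults.min_upstream),
            "allow_intragenic": bool(profile.filter_defaults.allow_intragenic),
        },
    }
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_profile(path) -> Profile:
    """Read a MEME v4 motif file (+ side-car if present) back to a Profile."""
    path = Path(path)
    name = path.stem
    background = np.full(4, 0.25)
    matrix_rows: list[list[float]] = []
    width = None
    nsites = 1
    in_matrix = False
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        lineno = i + 1
        if line.startswith("Background letter frequencies"):
            i += 1
            if i >= len(lines):
                raise ProfileParseError("truncated background block", lineno)
            toks = lines[i].split()
            try:
                freqs = {toks[k]: float(toks[k + 1]) for k in range(0, len(toks), 2)}
                background = np.array([freqs[b] for b in BASES])
            except (KeyError, ValueError, IndexError):
                raise ProfileParseError("malformed background frequencies", i + 1)
        elif line.startswith("MOTIF"):
            toks = line.split()
            if len(toks) > 1:
                name = toks[1]
        elif line.startswith("letter-probability matrix:"):
            kv = {}
            toks = line.split(":", 1)[1].split()
            for k in range(0, len(toks) - 1, 2):
                if toks[k].endswith("="):
                    kv[toks[k][:-1]] = toks[k + 1]
            try:
                alength = int(kv.get("alength", 4))
                width = int(kv["w"])
                nsites = int(float(kv.get("nsites", 1)))
            except (KeyError, ValueError):
                raise ProfileParseError("malformed matrix header", lineno)
            if alength != 4:
                raise ProfileParseError(
                    f"alength= {alength} unsupported (DNA profiles need 4)", lineno
                )
            in_matrix = True
        elif in_matrix and line:
            try:
                row = [float(x) for x in line.split()]
            except ValueError:
                raise ProfileParseError("non-numeric matrix entry", lineno)
            if len(row) != 4:
                raise ProfileParseError(
                    f"matrix row has {len(row)} values, expected 4", lineno
                )
            matrix_rows.append(row)
        elif in_matrix and not line:
            in_matrix = False
        i += 1
    if width is None:
        raise ProfileParseError("no letter-probability matrix block found")
    if len(matrix_rows) != width:
        raise ProfileParseError(
            f"matrix has {len(matrix_rows)} rows but header says w= {width}"
        )
    matrix = np.array(matrix_rows)
    # guard against rounding drift from the 6-decimal serialization
    matrix = matrix / matrix.sum(axis=1, keepdims=True)
    background = background / background.sum()

    sc = sidecar_path(path)
    cutoffs = Cutoffs()
    masked: frozenset[int] = frozenset()
    pseudocount = 0.5
    palindromic = False
    is_promoter = False
    description = ""
    fdef = FilterDefaults()
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
        name = meta.get("name", name)
        description = meta.get("description", "")
        pseudocount = float(meta.get("pseudocount", 0.5))
        masked = frozenset(int(j) for j in meta.get("masked_columns", []))
        palindromic = bool(meta.get("palindromic", False))
        is_promoter = bool(meta.get("is_promoter", False))
        c = meta.get("cutoffs", {}) or {}
        cutoffs = Cutoffs(
            c.get("trusted"),
            c.get("noise"),
            c.get("gathering"),
            bool(c.get("noise_provisional", False)),
        )
        f = meta.get("filter", {}) or {}
        fdef = FilterDefaults(
            int(f.get("max_upstream", 300)),
            int(f.get("min_upstream", 0)),
            bool(f.get("allow_intragenic", False)),
        )
    else:
        warnings.warn(
            f"no side-car metadata for {path.name}; cutoffs left unset", stacklevel=2
        )
    return Profile(
        name=name,
        matrix=matrix,
        background=background,
        pseudocount=pseudocount,
        masked_columns=masked,
        cutoffs=cutoffs,
        palindromic=palindromic,
        filter_defaults=fdef,
        description=description,
        nsites=nsites,
        is_promoter=is_promoter,
    )
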