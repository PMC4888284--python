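"""GenBank round trips, annotation operations, coverage tracks."""

import numpy as np
import pytest

from regsig import (
    Feature,
    GenomeRecord,
    annotate_sites,
    annotate_terminators,
    edit_feature,
    read_coverage_track,
    read_genbank,
    write_genbank,
)
from regsig.errors import GenBankFormatError, SelectorError, TrackError
from regsig.scan import Hit
from regsig.terminators import TerminatorCandidate

GB_MINIMAL = """\
LOCUS       toyrec                  1000 bp    DNA     linear   BCT 01-JAN-1980
DEFINITION  toy record.
ACCESSION   toyrec
FEATURES             Location/Qualifiers
     CDS             101..400
                     /locus_tag="g1"
                     /product="hypothetical protein"
     CDS             complement(601..900)
                     /locus_tag="g2"
     CDS             join(12..78,134..202)
                     /locus_tag="g3"
ORIGIN
{origin}
//
"""


def _origin_block(seq):
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        groups = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i+1:>9} {groups}")
    return "\n".join(lines)


@pytest.fixture
def gb_file(tmp_path):
    seq = "".join(np.random.default_rng(2).choice(list("acgt"), size=1000))
    f = tmp_path / "toy.gb"
    f.write_text(GB_MINIMAL.format(origin=_origin_block(seq)))
    return f


class TestReadGenBank:
    def test_coordinate_convention(self, gb_file):
        rec = read_genbank(gb_file)[0]
        cds = [f for f in rec.features if f.qualifier("locus_tag") == "g1"][0]
        assert (cds.kind, cds.start, cds.end, cds.strand) == ("CDS", 100, 400, "+")

    def test_complement_is_minus_strand(self, gb_file):
        rec = read_genbank(gb_file)[0]
        cds = [f for f in rec.features if f.qualifier("locus_tag") == "g2"][0]
        assert (cds.start, cds.end, cds.strand) == (600, 900, "-")

    def test_join_kept_as_enclosing_span_with_raw_location(self, gb_file):
        rec = read_genbank(gb_file)[0]
        cds = [f for f in rec.features if f.qualifier("locus_tag") == "g3"][0]
        assert (cds.start, cds.end) == (11, 202)
        assert "join" in cds.qualifier("location_raw")

    def test_missing_origin_is_format_error(self, tmp_path):
        f = tmp_path / "noseq.gb"
        f.write_text(
            "LOCUS       x                         10 bp    DNA     linear   BCT 01-JAN-1980\n"
            "FEATURES             Location/Qualifiers\n"
            "     gene            1..5\n"
            "ORIGIN\n"
            "//\n"
        )
        with pytest.raises(GenBankFormatError):
            read_genbank(f)


class TestRoundTrip:
    def test_semantic_round_trip(self, gb_file, tmp_path):
        recs = read_genbank(gb_file)
        out = tmp_path / "out.gb"
        write_genbank(recs, out)
        recs2 = read_genbank(out)
        assert len(recs2) == 1
        a, b = recs[0], recs2[0]
        assert a.sequence == b.sequence
        assert len(a.features) == len(b.features)
        for fa, fb in zip(a.features, b.features):
            assert (fa.kind, fa.start, fa.end, fa.strand) == (
                fb.kind,
                fb.start,
                fb.end,
                fb.strand,
            )
            assert fa.qualifiers == fb.qualifiers

    def test_round_trip_synthetic_genome(self, sim_default, tmp_path):
        rec, _ = sim_default
        write_genbank(rec, tmp_path / "syn.gb")
        rec2 = read_genbank(tmp_path / "syn.gb")[0]
        assert rec2.sequence == rec.sequence
        assert [
            (f.kind, f.start, f.end, f.strand, f.qualifier("locus_tag"))
            for f in rec2.features
        ] == [
            (f.kind, f.start, f.end, f.strand, f.qualifier("locus_tag"))
            for f in rec.features
        ]


class TestAnnotate:
    def _hit(self, start=100, end=118, strand="+"):
        return Hit("toy", start, end, strand, 12.5, 1e-5, "Fur")

    def test_empty_hits_unchanged(self, toy_record):
        out = annotate_sites(toy_record, [], "Fur")
        assert [f.kind for f in out.features] == [f.kind for f in toy_record.features]

    def test_tfbs_feature_written_one_based(self, toy_record, tmp_path):
        out = annotate_sites(toy_record, [self._hit()], "Fur")
        pb = out.features_of_kind("protein_bind")[0]
        assert (pb.start, pb.end, pb.strand) == (100, 118, "+")
        assert pb.qualifier("bound_moiety") == "Fur"
        write_genbank(out, tmp_path / "o.gb")
        assert "101..118" in (tmp_path / "o.gb").read_text()

    def test_promoter_feature_kind_and_note(self, toy_record):
        out = annotate_sites(toy_record, [self._hit()], "RpoS", is_promoter=True)
        prom = out.features_of_kind("promoter")[0]
        assert "RpoS promoter" in prom.qualifier("note")

    def test_idempotent(self, toy_record):
        hits = [self._hit(), self._hit(500, 518, "-")]
        once = annotate_sites(toy_record, hits, "Fur")
        twice = annotate_sites(once, hits, "Fur")
        assert len(twice.features) == len(once.features)

    def test_out_of_bounds_hit_warned_rest_applied(self, toy_record):
        hits = [self._hit(), self._hit(990, 1008, "+")]
        with pytest.warns(UserWarning, match="outside"):
            out = annotate_sites(toy_record, hits, "Fur")
        assert len(out.features_of_kind("protein_bind")) == 1

    def test_sequence_never_modified(self, toy_record):
        out = annotate_sites(toy_record, [self._hit()], "Fur")
        assert out.sequence == toy_record.sequence

    def test_annotate_terminators_idempotent(self, toy_record):
        cands = [
            TerminatorCandidate(450, 470, "+", 8, 4, 0, 22.0, 5.2, 99.5),
        ]
        once = annotate_terminators(toy_record, cands)
        twice = annotate_terminators(once, cands)
        term = once.features_of_kind("terminator")[0]
        assert "confidence" in term.qualifier("note")
        assert len(twice.features) == len(once.features)


class TestEditFeature:
    def test_product_update(self, toy_record):
        out = edit_feature(
            toy_record,
            ("CDS", 100, 400, "+"),
            {"product": "cellobiose-specific PTS system subunit IIB"},
        )
        cds = [f for f in out.features_of_kind("CDS") if f.start == 100][0]
        assert cds.qualifier("product").startswith("cellobiose")
        # original untouched
        orig = [f for f in toy_record.features_of_kind("CDS") if f.start == 100][0]
        assert orig.qualifier("product") is None

    def test_empty_updates_unchanged(self, toy_record):
        out = edit_feature(toy_record, ("CDS", 100, 400, "+"), {})
        assert out.features == toy_record.features

    def test_rename_gene_updates_partner(self, toy_record):
        out = edit_feature(toy_record, ("CDS", 100, 400, "+"), {}, rename_gene="celB")
        for kind in ("gene", "CDS"):
            f = [x for x in out.features_of_kind(kind) if x.start == 100][0]
            assert f.qualifier("gene") == "celB"

    def test_ambiguous_selector_errors(self, toy_record):
        dup = GenomeRecord(
            "d",
            toy_record.sequence,
            toy_record.features + [Feature("CDS", 100, 400, "+")],
        )
        with pytest.raises(SelectorError) as exc:
            edit_feature(dup, ("CDS", 100, 400, "+"), {"product": "x"})
        assert exc.value.n_matches == 2
        with pytest.raises(SelectorError):
            edit_feature(toy_record, ("CDS", 1, 2, "+"), {"product": "x"})


class TestCoverageTrack:
    def test_two_column(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("1\t10\n2\t12\n")
        track = read_coverage_track(f)
        assert track.points == [(1, 10.0), (2, 12.0)]

    def test_three_column_samtools_depth_dialect(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("chr1\t1\t10\n")
        assert read_coverage_track(f, "depth").points == [(1, 10.0)]

    def test_non_numeric_reports_line(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("1\t10\nx\t12\n")
        with pytest.raises(TrackError) as exc:
            read_coverage_track(f)
        assert exc.value.line == 2

    def test_decreasing_coordinates_rejected(self, tmp_path):
        f = tmp_path / "t.tsv"
        f.write_text("2\t5\n1\t7\n")
        with pytest.raises(TrackError):
            read_coverage_track(f)
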