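"""Site alignments, profile construction, information content, calibration."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regsig import (
    GenomeRecord,
    Provenance,
    Site,
    SiteAlignment,
    build_profile,
    calibrate,
    extend_alignment,
    information_content,
    load_alignment,
    logo_matrix,
    mask_columns,
    slice_alignment,
)
from regsig.errors import (
    AlignmentContentError,
    AlignmentShapeError,
    FlankBoundaryError,
    ProvenanceError,
)


def write_fasta(path, records):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in records))


class TestLoadAlignment:
    def test_identity_case(self, tmp_path):
        f = tmp_path / "a.fa"
        write_fasta(f, [("r1", "ACGT"), ("r2", "ACGT")])
        aln = load_alignment(f)
        assert aln.length == 4 and aln.nsites == 2
        assert aln.sequences == ["ACGT", "ACGT"]

    def test_lowercase_upcased_and_provenance_parsed(self, tmp_path):
        f = tmp_path / "a.fa"
        write_fasta(f, [("s1:genomeA:100-118:+", "acgtacgtacgtacgtac")])
        aln = load_alignment(f)
        assert aln.sequences[0] == "ACGTACGTACGTACGTAC"
        assert aln.sites[0].provenance == Provenance("genomeA", 100, 118, "+")

    def test_unequal_lengths_name_offender(self, tmp_path):
        f = tmp_path / "a.fa"
        write_fasta(f, [("r1", "ACGT"), ("bad", "ACG")])
        with pytest.raises(AlignmentShapeError, match="bad"):
            load_alignment(f)

    def test_gap_characters_rejected(self, tmp_path):
        f = tmp_path / "a.fa"
        write_fasta(f, [("r1", "AC-T")])
        with pytest.raises(AlignmentContentError, match="gap"):
            load_alignment(f)

    def test_non_dna_rejected(self, tmp_path):
        f = tmp_path / "a.fa"
        write_fasta(f, [("r1", "ACQT")])
        with pytest.raises(AlignmentContentError):
            load_alignment(f)

    def test_tfbs_scale_alignment(self, tmp_path):
        # 24 sites of length 18: the shape of a typical ArgR-like input
        rng = np.random.default_rng(3)
        f = tmp_path / "argr.fa"
        write_fasta(
            f,
            [
                (f"s{i}", "".join(rng.choice(list("ACGT"), size=18)))
                for i in range(24)
            ],
        )
        aln = load_alignment(f)
        assert (aln.length, aln.nsites) == (18, 24)


class TestSliceMask:
    def test_middle_slice(self):
        aln = SiteAlignment("t", [Site("a", "ACGTACGTAC")])
        out = slice_alignment(aln, [(2, 6)])
        assert out.sequences == ["GTAC"] and out.length == 4

    def test_full_slice_is_identity(self):
        aln = SiteAlignment("t", [Site("a", "ACGTACGTAC")])
        assert slice_alignment(aln, [(0, 10)]).sequences == aln.sequences

    def test_multi_range_concatenation(self):
        aln = SiteAlignment("t", [Site("a", "ACGTACGTAC")])
        out = slice_alignment(aln, [(0, 3), (7, 10)])
        assert out.sequences == ["ACGTAC"]

    def test_multi_range_drops_provenance_single_shifts(self):
        prov = Provenance("g", 100, 110, "+")
        aln = SiteAlignment("t", [Site("a", "ACGTACGTAC", prov)])
        assert slice_alignment(aln, [(0, 3), (7, 10)]).sites[0].provenance is None
        shifted = slice_alignment(aln, [(2, 6)]).sites[0].provenance
        assert shifted == Provenance("g", 102, 106, "+")

    def test_minus_strand_provenance_shift(self):
        prov = Provenance("g", 100, 110, "-")
        aln = SiteAlignment("t", [Site("a", "ACGTACGTAC", prov)])
        # columns [2,6) are genomic [end-6, end-2) on the minus strand
        assert slice_alignment(aln, [(2, 6)]).sites[0].provenance == Provenance(
            "g", 104, 108, "-"
        )

    def test_empty_ranges_error(self):
        aln = SiteAlignment("t", [Site("a", "ACGT")])
        with pytest.raises(ValueError):
            slice_alignment(aln, [])

    def test_out_of_bounds_error(self):
        aln = SiteAlignment("t", [Site("a", "ACGT")])
        with pytest.raises(IndexError):
            slice_alignment(aln, [(2, 9)])

    def test_mask_ranges(self):
        aln = SiteAlignment("t", [Site("a", "A" * 20)])
        assert mask_columns(aln, [(5, 8)]).mask == {5, 6, 7}

    def test_mask_empty_is_identity(self):
        aln = SiteAlignment("t", [Site("a", "ACGT")])
        assert mask_columns(aln, []).mask == set()

    def test_full_mask_zeroes_information(self):
        aln = SiteAlignment("t", [Site("a", "ACGT"), Site("b", "ACGT")])
        masked = mask_columns(aln, [(0, 4)])
        _, total = information_content(build_profile(masked, pseudocount=0.0))
        assert total == 0.0


class TestExtendAlignment:
    def _genome(self):
        #            0         1         2
        #            0123456789012345678901234567890
        return GenomeRecord("g", "ATGCATGCATGCATGCATGCATGCATGCAT")

    def test_zero_extension_is_identity(self):
        aln = SiteAlignment(
            "t", [Site("a", "GCAT", Provenance("g", 2, 6, "+"))]
        )
        out = extend_alignment(aln, {"g": self._genome()}, 0, 0)
        assert out.sequences == aln.sequences

    def test_plus_strand_coordinates(self):
        g = self._genome()
        aln = SiteAlignment("t", [Site("a", g.sequence[10:14], Provenance("g", 10, 14, "+"))])
        out = extend_alignment(aln, {"g": g}, 2, 3)
        s = out.sites[0]
        assert s.provenance == Provenance("g", 8, 17, "+")
        assert s.seq == g.sequence[8:17]

    def test_minus_strand_left_is_five_prime(self):
        # toy genome, site on the minus strand: "left" bases must come from
        # higher top-strand coordinates, reverse-complemented
        from regsig._dna import revcomp

        g = self._genome()
        site_seq = revcomp(g.sequence[10:14])
        aln = SiteAlignment("t", [Site("a", site_seq, Provenance("g", 10, 14, "-"))])
        out = extend_alignment(aln, {"g": g}, 2, 1)
        s = out.sites[0]
        assert s.provenance == Provenance("g", 9, 16, "-")
        assert s.seq == revcomp(g.sequence[9:16])
        # manual check: 5' flank of the site as read on its own strand
        assert s.seq[:2] == revcomp(g.sequence[14:16])

    def test_missing_provenance_error(self):
        aln = SiteAlignment("t", [Site("a", "ACGT")])
        with pytest.raises(ProvenanceError):
            extend_alignment(aln, {}, 1, 1)

    def test_flank_past_contig_end(self):
        g = self._genome()
        aln = SiteAlignment("t", [Site("a", g.sequence[0:4], Provenance("g", 0, 4, "+"))])
        with pytest.raises(FlankBoundaryError, match="a"):
            extend_alignment(aln, {"g": g}, 2, 0)
        # with the drop flag the offending sequence is dropped, not fatal
        aln2 = SiteAlignment(
            "t",
            [
                Site("a", g.sequence[0:4], Provenance("g", 0, 4, "+")),
                Site("b", g.sequence[10:14], Provenance("g", 10, 14, "+")),
            ],
        )
        out = extend_alignment(aln2, {"g": g}, 2, 0, drop_on_error=True)
        assert [s.id for s in out.sites] == ["b"]


class TestBuildProfile:
    def test_pure_column(self):
        aln = SiteAlignment("t", [Site("a", "ACGT"), Site("b", "ACGT")])
        p = build_profile(aln, pseudocount=0.0)
        assert np.allclose(p.matrix[0], [1, 0, 0, 0])

    def test_split_column(self):
        aln = SiteAlignment("t", [Site("a", "AA"), Site("b", "AT")])
        p = build_profile(aln, pseudocount=0.0)
        assert np.allclose(p.matrix[1], [0.5, 0, 0, 0.5])

    def test_pseudocount_arithmetic(self):
        aln = SiteAlignment("t", [Site("a", "A"), Site("b", "A"), Site("c", "C")])
        p = build_profile(aln, pseudocount=0.5)
        assert np.allclose(p.matrix[0], [2.5 / 5, 1.5 / 5, 0.5 / 5, 0.5 / 5])

    def test_n_contributes_quarter_counts(self):
        aln = SiteAlignment("t", [Site("a", "N"), Site("b", "A")])
        p = build_profile(aln, pseudocount=0.0)
        assert np.allclose(p.matrix[0], [1.25 / 2, 0.25 / 2, 0.25 / 2, 0.25 / 2])

    @given(
        st.integers(1, 12),
        st.integers(1, 30),
        st.floats(0.0, 5.0, allow_nan=False),
        st.integers(0, 2**31 - 1),
    )
    def test_columns_normalized_for_any_pseudocount(self, L, n, pc, seed):
        rng = np.random.default_rng(seed)
        sites = [
            Site(f"s{i}", "".join(rng.choice(list("ACGTN"), size=L)))
            for i in range(n)
        ]
        p = build_profile(SiteAlignment("t", sites), pseudocount=pc)
        assert np.allclose(p.matrix.sum(axis=1), 1.0, atol=1e-9)


class TestInformationContent:
    def test_pure_column_two_bits(self, acgt_profile):
        ic, total = information_content(acgt_profile)
        assert np.allclose(ic, 2.0) and total == pytest.approx(8.0)

    def test_uniform_column_zero_bits(self):
        from regsig.motifs import Profile

        p = Profile("u", np.full((1, 4), 0.25))
        ic, total = information_content(p)
        assert ic[0] == pytest.approx(0.0) and total == pytest.approx(0.0)

    def test_two_thirds_column(self):
        from regsig.motifs import Profile

        p = Profile("x", np.array([[2 / 3, 0, 0, 1 / 3]]))
        ic, _ = information_content(p)
        assert ic[0] == pytest.approx(2 - 0.9183, abs=1e-4)

    def test_masked_columns_report_zero(self):
        aln = SiteAlignment("t", [Site("a", "ACGT")], mask={1, 2})
        p = build_profile(aln, pseudocount=0.0)
        ic, total = information_content(p)
        assert list(ic) == [2.0, 0.0, 0.0, 2.0] and total == 4.0

    @given(st.integers(1, 10), st.integers(0, 2**31 - 1))
    def test_bounds_and_mask_budget(self, L, seed):
        from conftest import random_profile

        rng = np.random.default_rng(seed)
        p = random_profile(rng, L)
        k = int(rng.integers(0, L + 1))
        p.masked_columns = frozenset(range(k))
        ic, total = information_content(p)
        assert np.all(ic >= 0) and np.all(ic <= 2)
        assert total <= 2 * (L - k) + 1e-9


class TestLogoMatrix:
    def test_heights(self):
        from regsig.motifs import Profile

        p = Profile("x", np.array([[1.0, 0, 0, 0], [2 / 3, 0, 0, 1 / 3]]))
        h = logo_matrix(p)
        assert np.allclose(h[0], [2, 0, 0, 0])
        assert h[1, 0] == pytest.approx(0.7211, abs=1e-4)
        assert h[1, 3] == pytest.approx(0.3606, abs=1e-4)
        ic, _ = information_content(p)
        assert np.allclose(h.sum(axis=1), ic)


class TestCalibrate:
    def test_quoted_rule(self, acgt_profile):
        p = calibrate(acgt_profile, [10.2, 12.5, 15.1], [8.0, 7.1])
        c = p.cutoffs
        assert (c.trusted, c.noise) == (10.2, 8.0)
        assert c.gathering == pytest.approx(9.1)
        assert not c.noise_provisional

    def test_degenerate_equality_warns(self, acgt_profile):
        with pytest.warns(UserWarning, match="noise"):
            p = calibrate(acgt_profile, [5.0], [5.0])
        c = p.cutoffs
        assert (c.trusted, c.noise, c.gathering) == (5.0, 5.0, 5.0)

    def test_no_decoys_provisional_fallback(self, acgt_profile):
        with pytest.warns(UserWarning, match="provisional"):
            p = calibrate(acgt_profile, [10.0, 12.0])
        assert p.cutoffs.noise == pytest.approx(10.0 - 5.0)
        assert p.cutoffs.noise_provisional

    def test_empty_training_error(self, acgt_profile):
        with pytest.raises(ValueError):
            calibrate(acgt_profile, [])

    @given(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=20),
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=20),
        st.randoms(use_true_random=False),
    )
    def test_order_invariance_and_exact_mean(self, training, decoys, rnd):
        from regsig.motifs import Profile

        prof = Profile("x", np.full((2, 4), 0.25))
        shuffled_t, shuffled_d = list(training), list(decoys)
        rnd.shuffle(shuffled_t)
        rnd.shuffle(shuffled_d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = calibrate(prof, training, decoys).cutoffs
            b = calibrate(prof, shuffled_t, shuffled_d).cutoffs
        assert (a.trusted, a.noise, a.gathering) == (b.trusted, b.noise, b.gathering)
        assert a.trusted == min(training) and a.noise == max(decoys)
        assert a.gathering == pytest.approx((a.trusted + a.noise) / 2, abs=1e-12)
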