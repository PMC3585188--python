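import numpy as np
import pytest

from sawyerflow import (
    AlignedSeqSet,
    classify_shared_private,
    collapse_haplotypes,
    read_alignment,
    screen_numts,
    variability_summary,
)
from sawyerflow.errors import AlignmentError, PopmapError
from sawyerflow.seqio import HaplotypeTable, write_fasta, write_popmap

from conftest import make_alignment


class TestReadAlignment:
    def test_roundtrip_well_formed(self, tmp_path):
        fasta = tmp_path / "a.fa"
        fasta.write_text(">i1\nACGTACGTACGT\n>i2\nACGTACGTACGA\n>i3\nACGTACGTACGC\n")
        popmap = tmp_path / "p.tsv"
        popmap.write_text("i1\tX\ni2\tX\ni3\tY\n")
        seqs = read_alignment(fasta, popmap)
        assert seqs.length == 12
        assert seqs.populations == ["X", "Y"]
        assert [r[0] for r in seqs.records] == ["i1", "i2", "i3"]

    def test_length_mismatch_names_record(self, tmp_path):
        fasta = tmp_path / "a.fa"
        fasta.write_text(">i1\nACGTACGTACGT\n>i2\nACGTACGTACG\n")
        popmap = tmp_path / "p.tsv"
        popmap.write_text("i1\tX\ni2\tX\n")
        with pytest.raises(AlignmentError, match="i2"):
            read_alignment(fasta, popmap)

    def test_unknown_individual_rejected(self, tmp_path):
        fasta = tmp_path / "a.fa"
        fasta.write_text(">i1\nACGT\n>mystery\nACGT\n")
        popmap = tmp_path / "p.tsv"
        popmap.write_text("i1\tX\n")
        with pytest.raises(PopmapError, match="mystery"):
            read_alignment(fasta, popmap)

    def test_survey_shape(self, tmp_path, survey_sim):
        seqs, _, _ = survey_sim
        write_fasta(seqs, tmp_path / "s.fa")
        write_popmap(seqs, tmp_path / "s.tsv")
        back = read_alignment(tmp_path / "s.fa", tmp_path / "s.tsv")
        assert len(back.populations) == 14
        assert all(len(back.indices_of(p)) == 10 for p in back.populations)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            AlignedSeqSet([("i1", "X", "ACGT"), ("i1", "X", "ACGT")])


class TestScreenNumts:
    def test_internal_stop_flagged(self):
        # TAA in frame 0 mid-sequence under the invertebrate mito code
        seqs = make_alignment({"X": ["ATGTAAATGGGA", "ATGGCAATGGGA"]})
        assert screen_numts(seqs) == ["X_1"]

    def test_clean_coding_alignment(self):
        seqs = make_alignment({"X": ["ATGGCAATGGGA", "ATGGCCATGGGA"]})
        assert screen_numts(seqs) == []

    def test_indel_flagged(self):
        seqs = make_alignment({"X": ["ATGGC-ATGGGA", "ATGGCCATGGGA"]})
        assert screen_numts(seqs) == ["X_1"]

    def test_frame_shifts_stop_out_of_frame(self):
        # leading TAA is a stop in frame 0 but invisible in frame 1
        seqs = make_alignment({"X": ["TAAGCATGGGAT"]})
        assert screen_numts(seqs, frame=0) == ["X_1"]
        assert screen_numts(seqs, frame=1) == []


class TestCollapse:
    def test_identical_sequences_one_shared_haplotype(self):
        seqs = make_alignment({"X": ["ACGT", "ACGT"], "Y": ["ACGT", "ACGT"]})
        t = collapse_haplotypes(seqs)
        assert t.n_haplotypes == 1
        assert t.shared_flag("H1")
        assert t.counts[("X", "H1")] == 2 and t.counts[("Y", "H1")] == 2

    def test_distinct_sequences_private(self):
        seqs = make_alignment({"X": ["ACGT", "ACGA", "ACGC"]})
        t = collapse_haplotypes(seqs)
        assert t.n_haplotypes == 3
        assert classify_shared_private(t, "X") == (0, 3)

    def test_ambiguity_is_distinct_state(self):
        seqs = make_alignment({"X": ["ACGT", "ACGN"]})
        assert collapse_haplotypes(seqs).n_haplotypes == 2

    def test_idempotent(self, small_sim):
        seqs, _, _ = small_sim
        t = collapse_haplotypes(seqs)
        again = AlignedSeqSet(
            [(h, "one", s) for h, s in t.haplotypes], populations=["one"]
        )
        t2 = collapse_haplotypes(again)
        assert [s for _, s in t2.haplotypes] == [s for _, s in t.haplotypes]

    def test_haplotype_count_bounds(self, small_sim):
        seqs, _, _ = small_sim
        t = collapse_haplotypes(seqs)
        assert t.n_haplotypes <= seqs.n
        assert sum(t.counts.values()) == seqs.n

    def test_matches_ground_truth(self, small_sim):
        seqs, _, truth = small_sim
        t = collapse_haplotypes(seqs)
        assert t.n_haplotypes == len(set(truth.haplotype_of.values()))


class TestSharedPrivate:
    def test_published_rows(self, published_tables):
        table, _ = published_tables
        assert classify_shared_private(table, "HB") == (3, 6)
        assert classify_shared_private(table, "HA") == (2, 0)
        assert classify_shared_private(table, "GX") == (0, 3)

    def test_incidence_partition_is_exhaustive(self, published_tables):
        # every (population, haplotype) pair is counted exactly once
        table, _ = published_tables
        total = sum(
            sum(classify_shared_private(table, p)) for p in table.populations
        )
        assert total == sum(len(v) for v in table.incidence.values())

    def test_unknown_population(self, published_tables):
        table, _ = published_tables
        with pytest.raises(PopmapError):
            classify_shared_private(table, "XX")

    def test_tsv_roundtrip(self, tmp_path, published_tables):
        table, _ = published_tables
        table.to_tsv(tmp_path / "t.tsv")
        back = HaplotypeTable.from_tsv(tmp_path / "t.tsv")
        assert back.populations == table.populations
        assert {h: back.incidence[h] for h, _ in back.haplotypes} == table.incidence


class TestVariability:
    def test_identical_pair_all_zero(self):
        vs = variability_summary(make_alignment({"X": ["ACGT", "ACGT"]}))
        assert vs.n_polymorphic == 0
        assert vs.n_parsimony_informative == 0
        assert sum(vs.substitution_counts.values()) == 0

    def test_hand_enumerated_sites(self):
        # site 2: A/A/G/G (informative AG transition); site 3: A/A/A/T (singleton transversion)
        seqs = make_alignment({"X": ["CAAA", "CAAA", "CGGA", "CGAT"]})
        vs = variability_summary(seqs)
        assert vs.n_polymorphic == 3
        assert vs.n_parsimony_informative == 1
        assert vs.substitution_counts == {"CT": 0, "AG": 2, "TV": 1}

    def test_planted_class_proportions(self):
        # 40 C/T sites, 20 A/G sites, 5 A/T sites segregating in a 4-seq alignment
        L = 200
        base = ["A"] * L
        rows = [base[:], base[:], base[:], base[:]]
        pos = iter(range(L))
        for pair, k in (("CT", 40), ("AG", 20), ("AT", 5)):
            for _ in range(k):
                j = next(pos)
                rows[0][j], rows[1][j] = pair[0], pair[0]
                rows[2][j], rows[3][j] = pair[1], pair[1]
        seqs = make_alignment({"X": ["".join(r) for r in rows]})
        vs = variability_summary(seqs)
        assert vs.n_polymorphic == 65
        c = vs.substitution_counts
        assert (c["CT"], c["AG"], c["TV"]) == (40, 20, 5)
        total = sum(c.values())
        assert [round(100 * c[k] / total, 1) for k in ("CT", "AG", "TV")] == [61.5, 30.8, 7.7]

    def test_order_invariance(self, small_sim):
        seqs, _, _ = small_sim
        rng = np.random.default_rng(0)
        perm = rng.permutation(seqs.n)
        shuffled = AlignedSeqSet([seqs.records[i] for i in perm])
        a, b = variability_summary(seqs), variability_summary(shuffled)
        assert (a.n_polymorphic, a.n_parsimony_informative) == \
               (b.n_polymorphic, b.n_parsimony_informative)
        assert a.substitution_counts == b.substitution_counts

    def test_composition_sums_to_one(self, small_sim):
        seqs, _, _ = small_sim
        vs = variability_summary(seqs)
        assert abs(sum(vs.nucleotide_composition.values()) - 1.0) < 1e-9
        assert vs.n_parsimony_informative <= vs.n_polymorphic <= seqs.length

    def test_gap_columns_excluded(self):
        seqs = make_alignment({"X": ["A-GT", "ACGA"]})
        vs = variability_summary(seqs)
        assert vs.n_sites == 3
        assert vs.n_polymorphic == 1
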