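"""Trim, merge, align, event calling and haplotype classification."""

import math
import random

import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from betle.amplicon_analysis import (
    AlignScoring,
    AnalysisWindow,
    EmptyTableError,
    align_to_reference,
    analyze_amplicon,
    call_events,
    classify_reads,
    merge_pairs,
    quality_trim,
    windowed_read_seq,
)
from betle.editing_simulator import (
    IndelSpectrum,
    ReadSimParams,
    simulate_amplicon_reads,
    simulate_sorted_molecules,
)
from betle.reporter_model import EditEvent, FrameClass, revcomp

NEG_INF = float("-inf")


def gotoh_oracle(ref, read, match=2.0, mismatch=-3.0, open_=-6.0, ext=-1.0):
    """Independent affine-gap DP (Gotoh), free end gaps on the reference.

    Returns the optimal score; a gap of length L costs open_ + L*ext.
    """
    n, m = len(ref), len(read)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in read (deletion)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in ref (insertion)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # reference prefix skipped for free
    for j in range(1, m + 1):
        Y[0][j] = open_ + ext * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == read[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + open_ + ext, X[i - 1][j] + ext, Y[i - 1][j] + open_ + ext
            )
            Y[i][j] = max(
                M[i][j - 1] + open_ + ext, Y[i][j - 1] + ext, X[i][j - 1] + open_ + ext
            )
    return max(max(M[i][m], X[i][m], Y[i][m]) for i in range(n + 1))


def fastq_record(name, seq, quals):
    rec = BioSeqRecord(Seq(seq), id=name, description="")
    rec.letter_annotations["phred_quality"] = quals
    return rec


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestQualityTrim:
    def test_high_quality_reads_unchanged(self):
        reads = [fastq_record("r", "ACGT" * 20, [30] * 80)]
        out = quality_trim(reads, min_q=20, window=4)
        assert str(out[0].seq) == "ACGT" * 20

    def test_low_quality_tail_removed(self):
        seq = "ACGT" * 20
        quals = [38] * 60 + [2] * 20
        out = quality_trim([fastq_record("r", seq, quals)], min_q=20, window=4)
        assert len(out[0]) == 60

    def test_idempotent(self):
        rng = random.Random(1)
        reads = [
            fastq_record(
                f"r{i}",
                _random_seq(rng, 100),
                [rng.choice([2, 11, 25, 38]) for _ in range(100)],
            )
            for i in range(50)
        ]
        once = quality_trim(reads)
        twice = quality_trim(once)
        assert [str(r.seq) for r in once] == [str(r.seq) for r in twice]

    def test_short_survivors_dropped(self):
        reads = [fastq_record("r", "ACGT" * 20, [2] * 80)]
        assert quality_trim(reads) == []


class TestMergePairs:
    def _pair_from_amplicon(self, amplicon, read_len=250, q=30):
        r1 = amplicon[:read_len]
        r2 = revcomp(amplicon)[:read_len]
        return (
            fastq_record("p", r1, [q] * len(r1)),
            fastq_record("p", r2, [q] * len(r2)),
        )

    def test_400nt_amplicon_merges_to_400(self):
        rng = random.Random(2)
        amplicon = _random_seq(rng, 400)
        r1, r2 = self._pair_from_amplicon(amplicon)
        res = merge_pairs([r1], [r2])
        assert len(res.merged) == 1
        assert str(res.merged[0].seq) == amplicon

    def test_no_overlap_stays_unmerged(self):
        rng = random.Random(3)
        amplicon = _random_seq(rng, 600)
        r1, r2 = self._pair_from_amplicon(amplicon)
        res = merge_pairs([r1], [r2])
        assert res.merged == [] and len(res.unmerged) == 1

    def test_conflict_resolved_by_quality(self):
        rng = random.Random(4)
        amplicon = _random_seq(rng, 400)
        r1s = amplicon[:250]
        # corrupt one base inside the overlap (amplicon[150:250]) on R2 and
        # give R2 low quality there: R1's Q40 base must win
        rc2 = amplicon[150:400]
        idx = 50  # amplicon coordinate 200, inside the overlap
        wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[rc2[idx]]
        rc2 = rc2[:idx] + wrong + rc2[idx + 1 :]
        r1 = fastq_record("p", r1s, [40] * 250)
        r2 = fastq_record("p", revcomp(rc2), [10] * 250)
        res = merge_pairs([r1], [r2])
        assert str(res.merged[0].seq) == amplicon

    def test_mate_count_mismatch(self):
        r = fastq_record("p", "A" * 60, [30] * 60)
        with pytest.raises(Exception):
            merge_pairs([r, r], [r])


class TestAlignment:
    def test_identity_alignment(self):
        rng = random.Random(5)
        ref = _random_seq(rng, 300)
        aln = align_to_reference(ref[100:200], ref)
        assert aln.ops == [("M", 100)]
        assert aln.ref_start == 100

    def test_two_nt_deletion_called_once(self):
        rng = random.Random(6)
        ref = _random_seq(rng, 300)
        read = ref[50:150] + ref[152:250]
        aln = align_to_reference(read, ref)
        dels = [(op, n) for op, n in aln.ops if op == "D"]
        assert dels == [("D", 2)]

    def test_39nt_insertion_called_once(self, reporter):
        read = reporter.repaired_record.seq[
            reporter.hdr_junction - 120 : reporter.hdr_junction + 120 + 39
        ]
        aln = align_to_reference(read, reporter.reference)
        assert [(op, n) for op, n in aln.ops if op == "I"] == [("I", 39)]

    def test_score_matches_gotoh_oracle_on_random_pairs(self):
        """Biopython-backed glocal affine alignment reproduces an
        independently coded Gotoh DP on random short sequences."""
        rng = random.Random(7)
        for _ in range(100):
            ref = _random_seq(rng, rng.randint(40, 60))
            if rng.random() < 0.5:
                # related read: mutated window of the reference
                s = rng.randint(0, 10)
                read = list(ref[s : s + rng.randint(30, 45)])
                for _ in range(rng.randint(0, 4)):
                    k = rng.randrange(len(read))
                    read[k] = rng.choice("ACGT")
                read = "".join(read)
            else:
                read = _random_seq(rng, rng.randint(30, 60))
            aln = align_to_reference(read, ref, min_score_frac=-100.0)
            assert aln is not None
            assert math.isclose(aln.score, gotoh_oracle(ref, read), abs_tol=1e-6)


class TestCallEvents:
    def test_all_match_yields_no_events(self):
        rng = random.Random(8)
        ref = _random_seq(rng, 200)
        aln = align_to_reference(ref[20:180], ref)
        assert call_events(aln, AnalysisWindow("w", 50, 150), ref) == []

    def test_single_deletion_event_net_minus_one(self):
        rng = random.Random(9)
        ref = _random_seq(rng, 200)
        read = ref[20:100] + ref[101:180]
        aln = align_to_reference(read, ref)
        events = call_events(aln, AnalysisWindow("w", 50, 150), ref)
        assert len(events) == 1 and events[0].net == -1

    def test_homopolymer_deletion_left_aligned(self):
        """Within a homopolymer run every deletion placement is equivalent;
        the reported position must equal the leftmost (checked by shifting
        exhaustively)."""
        ref = "ACGTACGTCC" + "AAAAAA" + "GCGCTTGCAGCATCGATCAGCTAGCTTACGATCGTT"
        run_start = 10
        for cut in range(run_start, run_start + 6):  # delete one A anywhere
            read = ref[:cut] + ref[cut + 1 :]
            aln = align_to_reference(read[:40], ref)
            events = call_events(aln, AnalysisWindow("w", 0, 40), ref)
            assert len(events) == 1
            equivalents = [
                p
                for p in range(len(ref) - 1)
                if ref[:p] + ref[p + 1 :] == read
            ]
            assert events[0].position == min(equivalents)

    def test_window_not_covered_raises(self):
        rng = random.Random(10)
        ref = _random_seq(rng, 200)
        aln = align_to_reference(ref[100:180], ref)
        with pytest.raises(ValueError):
            call_events(aln, AnalysisWindow("w", 50, 150), ref)


class TestClassification:
    def test_reference_reads_all_unedited(self):
        rng = random.Random(11)
        ref = _random_seq(rng, 300)
        window = AnalysisWindow("w", 100, 200)
        table = classify_reads([ref[50:250]] * 10, ref, window)
        assert table.class_fractions()[FrameClass.UNEDITED] == 1.0

    def test_even_mixture_recovers_exact_fractions(self):
        rng = random.Random(12)
        ref = _random_seq(rng, 300)
        window = AnalysisWindow("w", 100, 200)
        unedited = ref[50:250]
        deleted = (ref[:150] + ref[152:])[50:248]
        table = classify_reads([unedited] * 20 + [deleted] * 20, ref, window)
        fr = table.class_fractions()
        assert fr[FrameClass.UNEDITED] == 0.5
        assert fr[FrameClass.N2] == 0.5  # net −2 deletion

    def test_fractions_sum_to_one(self, reporter):
        mols = simulate_sorted_molecules(
            reporter.cassette, reporter.guide, IndelSpectrum.default(),
            {FrameClass.N1: 0.5, FrameClass.N2: 0.3, FrameClass.UNEDITED: 0.2},
            300, seed=13,
        )
        params = ReadSimParams(coverage=300, seed=14)
        r1s, r2s = simulate_amplicon_reads(mols, reporter.primers, params)
        table = analyze_amplicon(r1s, r2s, reporter.reference, reporter.window)
        assert math.isclose(sum(table.class_fractions().values()), 1.0, abs_tol=1e-9)

    def test_substitution_errors_never_create_indel_calls(self, reporter):
        """At error 0.005 with no true indels, ≥99.9% of reads classify
        UNEDITED or SUBSTITUTION_ONLY."""
        params = ReadSimParams(substitution_error=0.005, coverage=2000, seed=15)
        r1s, r2s = simulate_amplicon_reads([reporter.reference], reporter.primers, params)
        table = analyze_amplicon(r1s, r2s, reporter.reference, reporter.window)
        fr = table.class_fractions()
        clean = fr[FrameClass.UNEDITED] + fr[FrameClass.SUBSTITUTION_ONLY]
        assert clean >= 0.999

    def test_zero_reads_rejected(self):
        with pytest.raises(EmptyTableError):
            classify_reads([], "ACGT" * 100, AnalysisWindow("w", 10, 40))

    def test_end_to_end_mixture_within_3sd(self, reporter):
        """Known class mixture recovered from reads at error 0.001."""
        truth = {FrameClass.N1: 0.2, FrameClass.N2: 0.5, FrameClass.UNEDITED: 0.3}
        n = 2500
        mols = simulate_sorted_molecules(
            reporter.cassette, reporter.guide, IndelSpectrum.default(), truth, n, seed=16
        )
        params = ReadSimParams(substitution_error=0.001, coverage=n, seed=17)
        r1s, r2s = simulate_amplicon_reads(mols, reporter.primers, params)
        table = analyze_amplicon(r1s, r2s, reporter.reference, reporter.window)
        fr = table.class_fractions()
        for cls, p in truth.items():
            observed = fr[cls]
            if cls == FrameClass.UNEDITED:
                observed += fr[FrameClass.SUBSTITUTION_ONLY]
            sd = math.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * sd, cls


class TestHdrClassification:
    def test_hdr_reads_classify_hdr(self, reporter):
        read = reporter.repaired_record.seq[
            reporter.cut_site - 150 : reporter.cut_site + 189
        ]
        table = classify_reads(
            [read] * 5, reporter.reference, reporter.window, reporter.repaired_record.seq
        )
        assert table.class_fractions()[FrameClass.HDR] == 1.0

    def test_hdr_requires_repaired_reference(self, reporter):
        """Without the repaired reference, a restored molecule reads as an
        in-frame 39-nt insertion."""
        read = reporter.repaired_record.seq[
            reporter.cut_site - 150 : reporter.cut_site + 189
        ]
        table = classify_reads([read] * 5, reporter.reference, reporter.window)
        assert table.class_fractions()[FrameClass.N3_INFRAME] == 1.0
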