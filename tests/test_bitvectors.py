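"""Bit-vector conversion from SAM and the four quality filters."""

import numpy as np
import pytest

from dmsensemble.bitvectors import (
    MATCH,
    MUTATION,
    UNINFORMATIVE,
    deduplicate,
    filter_bitvectors,
    reads_from_sam,
    sam_to_bitmatrix,
)
from dmsensemble.reference import ReferenceWindow
from tests.conftest import matrix_from_strings

REF = "ACGAGACCGCAATTGACCGA"  # DNA on disk; window covers it all


@pytest.fixture
def window():
    return ReferenceWindow("toy", REF, 1, 20)


def write_sam(tmp_path, records, ref_len=20, name="toy"):
    lines = ["@HD\tVN:1.6", f"@SQ\tSN:{name}\tLN:{ref_len}"]
    lines += records
    path = tmp_path / "reads.sam"
    path.write_text("\n".join(lines) + "\n")
    return path


def rec(qname, pos, cigar, seq, qual, flag=0, ref="toy"):
    return f"{qname}\t{flag}\t{ref}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}"


class TestMakeBitvector:
    def test_perfect_match_all_match(self, tmp_path, window):
        sam = write_sam(tmp_path, [rec("r1", 1, "20M", REF, "I" * 20)])
        matrix, _ = sam_to_bitmatrix(sam, window, min_read_length=10)
        assert (matrix.codes == MATCH).all()

    def test_single_q30_mismatch(self, tmp_path, window):
        seq = REF[:6] + "A" + REF[7:]  # position 7 is C in the reference
        sam = write_sam(tmp_path, [rec("r1", 1, "20M", seq, "I" * 20)])
        matrix, _ = sam_to_bitmatrix(sam, window, min_read_length=10)
        assert matrix.codes[0, 6] == MUTATION
        assert (np.delete(matrix.codes[0], 6) == MATCH).all()

    def test_low_quality_call_uninformative(self, tmp_path, window):
        sam = write_sam(tmp_path, [rec("r1", 1, "20M", REF, "I" * 5 + "#" + "I" * 14)])
        matrix, _ = sam_to_bitmatrix(sam, window, min_read_length=10)
        assert matrix.codes[0, 5] == UNINFORMATIVE

    def test_literal_phred_rule_inverts(self, tmp_path, window):
        sam = write_sam(tmp_path, [rec("r1", 1, "20M", REF, "I" * 20)])
        matrix, _ = sam_to_bitmatrix(
            sam, window, min_read_length=10, literal_phred_rule=True
        )
        # every call is Q40 > 20, hence uninformative under the literal rule
        assert (matrix.codes == UNINFORMATIVE).all()

    def test_two_nt_deletion_marks_both_then_filtered(self, tmp_path, window):
        # CIGAR 3M2D15M: reference positions 4 and 5 deleted
        seq = REF[:3] + REF[5:]
        sam = write_sam(tmp_path, [rec("r1", 1, "3M2D15M", seq, "I" * 18)])
        matrix, _ = sam_to_bitmatrix(sam, window, min_read_length=10)
        assert matrix.codes[0, 3] == MUTATION and matrix.codes[0, 4] == MUTATION
        _, report = filter_bitvectors(matrix)
        assert report.close_mutations == 1 and report.retained == 0

    def test_positions_outside_read_uninformative(self, tmp_path, window):
        sam = write_sam(tmp_path, [rec("r1", 5, "10M", REF[4:14], "I" * 10)])
        matrix, _ = sam_to_bitmatrix(sam, window, min_read_length=5)
        codes = matrix.codes[0]
        assert (codes[:4] == UNINFORMATIVE).all()
        assert (codes[14:] == UNINFORMATIVE).all()
        assert (codes[4:14] == MATCH).all()

    def test_insertion_carries_no_reference_position(self, tmp_path, window):
        seq = REF[:10] + "GG" + REF[10:]
        sam = write_sam(tmp_path, [rec("r1", 1, "10M2I10M", seq, "I" * 22)])
        matrix, _ = sam_to_bitmatrix(sam, window, min_read_length=10)
        assert (matrix.codes[0] == MATCH).all()


class TestMatePairs:
    def test_overlap_agreement_merged_once(self, tmp_path, window):
        sam = write_sam(
            tmp_path,
            [
                rec("p1", 1, "12M", REF[:12], "I" * 12, flag=99),
                rec("p1", 9, "12M", REF[8:20], "I" * 12, flag=147),
            ],
        )
        obs, n_short = reads_from_sam(sam, window, min_read_length=10)
        assert len(obs) == 1 and obs[0].footprint == 20
        matrix, _ = sam_to_bitmatrix(sam, window, min_read_length=10)
        assert (matrix.codes[0] == MATCH).all()

    def test_overlap_disagreement_uninformative(self, tmp_path, window):
        # mates disagree at reference position 10 (one has a mismatch)
        mate2 = "G" + REF[9:20][1:]
        assert mate2[0] != REF[9]
        sam = write_sam(
            tmp_path,
            [
                rec("p1", 1, "12M", REF[:12], "I" * 12, flag=99),
                rec("p1", 10, "11M", mate2, "I" * 11, flag=147),
            ],
        )
        matrix, _ = sam_to_bitmatrix(sam, window, min_read_length=10)
        assert matrix.codes[0, 9] == UNINFORMATIVE
        assert (np.delete(matrix.codes[0], 9) == MATCH).all()

    def test_short_footprint_dropped_and_counted(self, tmp_path, window):
        sam = write_sam(
            tmp_path,
            [rec("s1", 1, "6M", REF[:6], "I" * 6), rec("r1", 1, "20M", REF, "I" * 20)],
        )
        obs, n_short = reads_from_sam(sam, window, min_read_length=10)
        assert n_short == 1 and len(obs) == 1

    def test_reference_id_mismatch_rejected(self, tmp_path, window):
        sam = write_sam(tmp_path, [rec("r1", 1, "20M", REF, "I" * 20)], name="other")
        with pytest.raises(ValueError):
            reads_from_sam(sam, window)


def brute_force_filter(codes, max_uninf=0.5, max_mutfrac=0.10, min_gap=4, adj=True):
    """Independent re-check of the four rules, one read at a time."""
    keep = []
    for row in codes:
        mut = [i for i, c in enumerate(row) if c == 1]
        uninf = [i for i, c in enumerate(row) if c == 2]
        n_inf = len(row) - len(uninf)
        ok = True
        if len(uninf) / len(row) >= max_uninf:
            ok = False
        if ok and n_inf > 0 and len(mut) / n_inf > max_mutfrac:
            ok = False
        if ok and any(b - a < min_gap for a, b in zip(mut, mut[1:])):
            ok = False
        if ok and adj and any(
            (i - 1 in uninf) or (i + 1 in uninf) for i in mut
        ):
            ok = False
        keep.append(ok)
    return np.array(keep)


class TestFilters:
    @pytest.fixture
    def wide_window(self):
        return ReferenceWindow("w30", "ACGAGACCGC" * 3, 1, 30)

    def test_close_mutations_discarded(self, wide_window):
        # mutations at positions 5 and 7: distance 2 < 4; fraction 2/30 is
        # below the 10% rule, so attribution lands on the close-pair rule
        m = matrix_from_strings(wide_window, ["0000101000" + "0" * 20])
        kept, report = filter_bitvectors(m)
        assert len(kept) == 0 and report.close_mutations == 1

    def test_all_match_retained(self, small_window):
        m = matrix_from_strings(small_window, ["0" * 10])
        kept, report = filter_bitvectors(m)
        assert len(kept) == 1 and report.retained == 1

    def test_half_uninformative_discarded(self, small_window):
        m = matrix_from_strings(small_window, ["?????00000"])  # exactly 50%
        kept, report = filter_bitvectors(m)
        assert len(kept) == 0 and report.too_uninformative == 1

    def test_mutation_adjacent_uninformative(self, wide_window):
        m = matrix_from_strings(wide_window, ["001?000000" + "0" * 20])
        kept, report = filter_bitvectors(m)
        assert len(kept) == 0 and report.mutation_adjacent_uninformative == 1
        kept2, _ = filter_bitvectors(m, drop_adjacent_to_uninformative=False)
        assert len(kept2) == 1

    def test_mutation_fraction_uses_informative_count(self, small_window):
        # 1 mutation of 6 informative = 16.7% > 10%, though 10% of width
        m = matrix_from_strings(small_window, ["1?0?0?0?00"])
        with np.errstate(all="ignore"):
            kept, report = filter_bitvectors(m, drop_adjacent_to_uninformative=False)
        assert report.high_mutation_fraction == 1

    def test_report_reconciles(self, small_window):
        rows = ["0" * 10, "0000101000", "?????00000", "001?000000"]
        _, report = filter_bitvectors(matrix_from_strings(small_window, rows))
        assert report.discarded + report.retained == len(rows)

    def test_matches_brute_force_on_random_vectors(self, small_window):
        rng = np.random.default_rng(42)
        codes = rng.choice([0, 1, 2], size=(2000, 10), p=[0.82, 0.08, 0.10]).astype(
            np.int8
        )
        m = matrix_from_strings(
            small_window, ["".join("01?"[c] for c in row) for row in codes]
        )
        kept, report = filter_bitvectors(m)
        expected = brute_force_filter(codes)
        assert report.retained == int(expected.sum())
        assert {tuple(r) for r in kept.codes} <= {
            tuple(r) for r in codes[expected]
        }

    def test_retained_set_order_independent(self, small_window):
        # rules are conjunctive: disabling attribution order cannot change
        # the retained vectors, only the per-rule counts
        rng = np.random.default_rng(7)
        codes = rng.choice([0, 1, 2], size=(500, 10), p=[0.8, 0.1, 0.1]).astype(np.int8)
        rows = ["".join("01?"[c] for c in row) for row in codes]
        kept, _ = filter_bitvectors(matrix_from_strings(small_window, rows))
        expected = brute_force_filter(codes)
        assert len(kept) == int(expected.sum())


class TestDeduplicate:
    def test_copies_collapse_with_weight(self, small_window):
        m = matrix_from_strings(small_window, ["0010000000"] * 1000)
        d = deduplicate(m)
        assert len(d) == 1 and d.weights[0] == 1000 and d.n_reads == 1000

    def test_distinct_vectors_unchanged(self, small_window):
        rows = ["0000000000", "1000000000", "0000000001"]
        d = deduplicate(matrix_from_strings(small_window, rows))
        assert len(d) == 3 and (d.weights == 1).all()

    def test_mixture_loglik_invariant(self, small_window):
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1], size=(400, 10), p=[0.9, 0.1]).astype(np.int8)
        rows = ["".join("01"[c] for c in row) for row in codes]
        m = matrix_from_strings(small_window, rows)
        d = deduplicate(m)
        # fixed-parameter weighted log-likelihood identical on raw vs dedup
        mu = rng.uniform(0.02, 0.3, size=(2, 10))
        pi = np.array([0.6, 0.4])

        def loglik(mat):
            mut = (mat.codes == 1).astype(float)
            match = (mat.codes == 0).astype(float)
            logb = mut @ np.log(mu).T + match @ np.log1p(-mu).T
            from scipy.special import logsumexp

            return float(
                (mat.weights * logsumexp(logb + np.log(pi), axis=1)).sum()
            )

        assert abs(loglik(m) - loglik(d)) < 1e-9
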