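"""Alignment engines and hit-selection rules."""

import numpy as np
import pytest

from htt import align, seqio, simulate
from htt.align import AlignParams
from htt.seqio import Hit, SeqRecord


@pytest.fixture(scope="module")
def target():
    rng = np.random.default_rng(17)
    return SeqRecord("t", simulate.random_dna(10_000, rng))


class TestLocalAlign:
    def test_exact_substring(self, target):
        q = SeqRecord("q", target.seq[500:700])
        (h,) = align.local_align([q], [target])
        assert (h.pct_identity, h.aln_len, h.t_start, h.t_end, h.strand) == (
            100.0, 200, 501, 700, "+",
        )

    def test_reverse_complement_found(self, target):
        q = SeqRecord("q", seqio.revcomp(target.seq[800:1000]))
        (h,) = align.local_align([q], [target])
        assert (h.t_start, h.t_end, h.strand) == (801, 1000, "-")
        assert h.pct_identity == 100.0

    def test_three_substitutions_identity(self, target):
        mut = simulate.mutate(target.seq[100:250], 2.0, seed=5)  # 3 of 150
        (h,) = align.local_align([SeqRecord("q", mut.seq)], [target])
        assert h.pct_identity == pytest.approx(98.0)
        assert h.aln_len == 150

    def test_self_alignment_full_length(self):
        rng = np.random.default_rng(3)
        s = SeqRecord("s", simulate.random_dna(300, rng))
        hits = [h for h in align.local_align([s], [s]) if h.strand == "+"]
        assert hits[0].pct_identity == 100.0
        assert hits[0].aln_len == 300

    def test_identity_recomputable_from_alignment(self, target):
        mut = simulate.mutate(target.seq[2000:2150], 4.0, seed=8)
        (h,) = align.local_align([SeqRecord("q", mut.seq)], [target])
        q_sub = mut.seq[h.q_start - 1: h.q_end]
        t_sub = target.seq[h.t_start - 1: h.t_end]
        matches = sum(a == b for a, b in zip(q_sub, t_sub))
        assert h.pct_identity == pytest.approx(100.0 * matches / h.aln_len, abs=1e-9)

    def test_deletion_in_query_handled_gapped(self, target):
        frag = target.seq[3000:3200]
        q = SeqRecord("q", frag[:100] + frag[103:])  # 3-bp deletion
        (h,) = align.local_align([SeqRecord("q", q.seq)], [target])
        assert h.t_start <= 3010 and h.t_end >= 3190
        assert h.aln_len >= 197  # spans the gap columns

    def test_score_and_evalue_thresholds(self, target):
        q = SeqRecord("q", target.seq[600:655])  # 55 bp: score 55 <= 60
        assert align.local_align([q], [target]) == []

    def test_empty_inputs_warn(self, target):
        with pytest.warns(UserWarning):
            assert align.local_align([], [target]) == []


class TestMapKMismatch:
    def test_identity_floor_is_94(self, target):
        frag = simulate.mutate(target.seq[400:450], 6.0, seed=2)  # 3 mismatches
        (h,) = align.map_kmismatch([SeqRecord("r", frag.seq)], target, 3)
        assert h.pct_identity == 94.0

    def test_four_mismatches_not_placed(self, target):
        frag = simulate.mutate(target.seq[400:450], 8.0, seed=2)  # 4 mismatches
        assert align.map_kmismatch([SeqRecord("r", frag.seq)], target, 3) == []

    def test_k0_equals_exact_search(self, target):
        r = SeqRecord("r", target.seq[700:750])
        hits = align.map_kmismatch([r], target, 0)
        # every exact occurrence, either strand
        expected = {
            i + 1
            for i in range(len(target) - 50 + 1)
            if target.seq[i: i + 50] == r.seq
        }
        assert {h.t_start for h in hits if h.strand == "+"} == expected

    def test_brute_force_oracle_equivalence(self, target):
        rng = np.random.default_rng(5)
        reads = []
        for i in range(20):
            s = int(rng.integers(0, len(target) - 50))
            frag = simulate.mutate(target.seq[s: s + 50], float(rng.integers(0, 9)), seed=i)
            seq = frag.seq if rng.random() < 0.5 else seqio.revcomp(frag.seq)
            reads.append(SeqRecord(f"r{i}", seq))
        got = {
            (h.query_id, h.t_start, h.strand)
            for h in align.map_kmismatch(reads, target, 3)
        }
        t_codes = seqio.encode(target.seq).astype(np.int16)
        t_codes[t_codes == 4] = 5
        oracle = set()
        for r in reads:
            for strand in "+-":
                seq = r.seq if strand == "+" else seqio.revcomp(r.seq)
                codes = seqio.encode(seq).astype(np.int16)
                for s in range(len(target) - 50 + 1):
                    if np.count_nonzero(t_codes[s: s + 50] != codes) <= 3:
                        oracle.add((r.id, s + 1, strand))
        assert got == oracle


def _mkhit(qid, t_start, t_end, score):
    return Hit(
        query_id=qid, target_id="t", pct_identity=99.0,
        aln_len=t_end - t_start + 1, q_start=1, q_end=t_end - t_start + 1,
        t_start=t_start, t_end=t_end, score=score,
    )


class TestBestNonoverlapping:
    def test_overlap_above_limit_drops_lower_scorer(self):
        a = _mkhit("a", 1, 150, 140)
        b = _mkhit("b", 71, 220, 120)  # 80 bp overlap with a
        assert align.select_best_nonoverlapping([a, b]) == [a]

    def test_boundary_overlap_inclusive(self):
        a = _mkhit("a", 1, 150, 140)
        b = _mkhit("b", 76, 225, 120)  # exactly 75 bp overlap
        assert align.select_best_nonoverlapping([a, b]) == [a, b]

    def test_min_len_enforced(self):
        short = _mkhit("s", 1, 99, 200)
        assert align.select_best_nonoverlapping([short]) == []

    def test_multiple_targets_rejected(self):
        a = _mkhit("a", 1, 150, 10)
        b = _mkhit("b", 1, 150, 10)
        b.target_id = "other"
        with pytest.raises(ValueError):
            align.select_best_nonoverlapping([a, b])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_greedy(self, seed):
        rng = np.random.default_rng(seed)
        hits = [
            _mkhit(f"h{i}", s := int(rng.integers(1, 2000)),
                   s + int(rng.integers(50, 400)), float(rng.integers(40, 400)))
            for i in range(50)
        ]
        got = align.select_best_nonoverlapping(hits, 100, 75)
        # independent reimplementation of the stated greedy contract
        order = sorted(hits, key=lambda h: (-h.score, -h.aln_len, h.t_start, h.query_id))
        accepted = []
        for h in order:
            if h.aln_len < 100:
                continue
            if all(
                min(h.t_end, a.t_end) - max(h.t_start, a.t_start) + 1 <= 75
                for a in accepted
            ):
                accepted.append(h)
        assert got == sorted(accepted, key=lambda h: h.t_start)
        # invariants: pairwise overlaps bounded, lengths floored
        for i, a in enumerate(got):
            assert a.aln_len >= 100
            for b in got[i + 1:]:
                assert min(a.t_end, b.t_end) - max(a.t_start, b.t_start) + 1 <= 75


class TestFullSpanIdentity:
    def test_extends_trimmed_hit_to_read_ends(self):
        rng = np.random.default_rng(2)
        t = SeqRecord("t", simulate.random_dna(2000, rng))
        # read with mismatches clustered at the ends: local HSP trims them
        frag = list(t.seq[500:650])
        for i in (0, 2, 4, 145, 147, 149):
            frag[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[i]]
        q = SeqRecord("q", "".join(frag))
        (h,) = align.local_align([q], [t])
        full = align.full_span_identity(h, q, t)
        assert full == pytest.approx(100.0 * 144 / 150)
        assert h.pct_identity > full  # the trimmed segment looks cleaner
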