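"""Built-in alignment engines and hit-selection rules.

Three engines cover the pipeline's needs without an external aligner:

* :func:`local_align` — seed-and-extend local alignment for 100–151-bp
  sample reads (and longer queries) against contigs.  Exact word-size seeds
  are grouped by diagonal band; each band is extended ungapped by a
  maximum-scoring-segment pass, with a gapped refinement (full local DP on
  the candidate subwindow) when the ungapped extension is fragmentary or
  the seeds betray an indel.  Statistics follow Karlin–Altschul with the
  effective search space frozen to the supplied target set.
* :func:`map_kmismatch` — end-to-end ungapped placement of fixed-length
  short reads with at most ``k`` mismatches (the 94%-identity pass for
  50-bp reads at k=3), reporting every qualifying placement on both strands.
* :func:`select_best_nonoverlapping` — the best-nonoverlapping-hit rule:
  greedy by descending score, accepting a hit only if it is long enough and
  overlaps every already-accepted hit by at most ``max_overlap`` bases
  (boundary inclusive: an overlap of exactly ``max_overlap`` passes).

Scoring defaults (+1 match, −2 mismatch, −5 gap open, −2 gap extend) make a
score of 60 correspond to roughly 60 bp of matched sequence, consistent
with the 100–140 bp match-length floors used downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import Align as _BioAlign
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .seqio import Hit, SeqRecord, encode, revcomp

__all__ = ["AlignParams", "local_align", "map_kmismatch",
           "select_best_nonoverlapping", "full_span_identity"]


@dataclass
class AlignParams:
    word_size: int = 11
    min_score: float = 60.0
    max_evalue: float = 1e-8
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    single_hsp: bool = True

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.min_score <= 0:
            raise ValueError("min_score must be > 0")


@lru_cache(maxsize=8)
def _karlin_lambda(match: int, mismatch: int) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1, p uniform."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


# Conventional ungapped K for small-alphabet scoring; the e-value threshold
# is orders of magnitude away from accepted scores, so its precision is not
# load-bearing.
_KARLIN_K = 0.3


def _evalue(score: float, qlen: int, search_space: int, params: AlignParams) -> float:
    lam = _karlin_lambda(params.match, params.mismatch)
    return _KARLIN_K * qlen * search_space * math.exp(-lam * score)


@lru_cache(maxsize=4)
def _gapped_aligner(match: int, mismatch: int, gap_open: int, gap_extend: int):
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = match if (a == b and a != "N") else mismatch
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    # first gap base costs open+extend (BLAST-style affine: open + g*extend)
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def _index_kmers(seq: str, w: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        kmer = seq[i: i + w]
        if "N" in kmer:
            continue
        idx.setdefault(kmer, []).append(i)
    return idx


def _ungapped_hsp(
    q_codes: np.ndarray, t_codes: np.ndarray, diag: int
) -> tuple[float, int, int, int] | None:
    """Best-scoring ungapped segment on one diagonal (Kadane on +1/-2).

    Returns (score, q_start0, q_end0_exclusive, matches) or None.
    """
    i0 = max(0, -diag)
    i1 = min(len(q_codes), len(t_codes) - diag)
    if i1 - i0 < 1:
        return None
    q_sub = q_codes[i0:i1]
    t_sub = t_codes[i0 + diag: i1 + diag]
    is_match = (q_sub == t_sub) & (q_sub < 4)
    scores = np.where(is_match, 1.0, -2.0)
    prefix = np.concatenate(([0.0], np.cumsum(scores)))
    runmin = np.minimum.accumulate(prefix[:-1])
    vals = prefix[1:] - runmin
    e = int(np.argmax(vals))
    score = float(vals[e])
    if score <= 0:
        return None
    s = int(np.argmin(prefix[: e + 1]))
    mcum = np.concatenate(([0], np.cumsum(is_match)))
    matches = int(mcum[e + 1] - mcum[s])
    return score, i0 + s, i0 + e + 1, matches


def _gapped_hsp(
    aligner, q_seq: str, t_seq: str, t_off: int
) -> tuple[float, int, int, int, int, int, int] | None:
    """Best gapped local alignment of query vs a target subwindow.

    Returns (score, q_start0, q_end0_excl, t_start0, t_end0_excl, matches,
    columns), target coordinates already shifted by ``t_off``.
    """
    alns = aligner.align(t_seq, q_seq)
    try:
        aln = alns[0]
    except IndexError:
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)
        for a, b in zip(t_seq[ts:te], q_seq[qs:qe]):
            if a == b and a != "N":
                matches += 1
        columns += te - ts
        prev_t, prev_q = te, qe
    return (
        float(aln.score),
        int(q_blocks[0][0]),
        int(q_blocks[-1][1]),
        t_off + int(t_blocks[0][0]),
        t_off + int(t_blocks[-1][1]),
        matches,
        columns,
    )


def _collect_bands(
    q_seq: str, idx: dict[str, list[int]], w: int, band_merge: int = 16
) -> list[tuple[list[int], int, int]]:
    """Seed diagonals grouped into bands.

    Returns a list of (diagonals, t_min, t_max) with diagonals sorted and
    seed-count-ordered; t_min/t_max bound seed positions in the band.
    """
    diag_seeds: dict[int, list[int]] = {}
    for qpos in range(0, len(q_seq) - w + 1):
        hits = idx.get(q_seq[qpos: qpos + w])
        if hits:
            for tpos in hits:
                diag_seeds.setdefault(tpos - qpos, []).append(tpos)
    if not diag_seeds:
        return []
    bands = []
    cur: list[int] = []
    for d in sorted(diag_seeds):
        if cur and d - cur[-1] > band_merge:
            bands.append(cur)
            cur = []
        cur.append(d)
    bands.append(cur)
    out = []
    for diags in bands:
        positions = [p for d in diags for p in diag_seeds[d]]
        diags_by_support = sorted(diags, key=lambda d: -len(diag_seeds[d]))
        out.append((diags_by_support, min(positions), max(positions)))
    return out


def local_align(
    queries: Sequence[SeqRecord],
    targets: Sequence[SeqRecord],
    params: AlignParams | None = None,
) -> list[Hit]:
    """Seed-and-extend local alignment of every query against every target.

    Both strands are searched.  With ``params.single_hsp`` (the default) at
    most one HSP — the highest-scoring — is reported per query–target pair;
    otherwise each distinct band contributes its best HSP.  Hits with score
    not exceeding ``min_score`` or e-value not below ``max_evalue`` are
    dropped.
    """
    params = params or AlignParams()
    if not queries or not targets:
        warnings.warn("local_align called with empty queries or targets", stacklevel=2)
        return []
    w = params.word_size
    search_space = sum(len(t) for t in targets)
    aligner = _gapped_aligner(params.match, params.mismatch, params.gap_open,
                              params.gap_extend)
    all_hits: list[Hit] = []
    for target in targets:
        idx = _index_kmers(target.seq, w)
        t_codes = encode(target.seq)
        for query in queries:
            pair_hits: list[Hit] = []
            for strand in "+-":
                q_seq = query.seq if strand == "+" else revcomp(query.seq)
                q_codes = encode(q_seq)
                qlen = len(q_seq)
                for diags, t_min, t_max in _collect_bands(q_seq, idx, w):
                    # seeds on one diagonal: exact ungapped extension; seeds
                    # straddling diagonals betray an indel, so run the full
                    # gapped local DP on the candidate subwindow instead
                    if max(diags) == min(diags):
                        ug = _ungapped_hsp(q_codes, t_codes, diags[0])
                        if ug is None:
                            continue
                        score, qs, qe, matches = ug
                        d = diags[0]
                        hsp = (score, qs, qe, qs + d, qe + d, matches, qe - qs)
                    else:
                        t_lo = max(0, t_min - qlen - 16)
                        t_hi = min(len(target.seq), t_max + w + qlen + 16)
                        hsp = _gapped_hsp(aligner, q_seq,
                                          target.seq[t_lo:t_hi], t_lo)
                    if hsp is None:
                        continue
                    score, qs, qe, ts, te, matches, columns = hsp
                    if columns < 1 or score <= params.min_score:
                        continue
                    ev = _evalue(score, qlen, search_space, params)
                    if ev >= params.max_evalue:
                        continue
                    if strand == "+":
                        q_start, q_end = qs + 1, qe
                    else:
                        q_start, q_end = qlen - qe + 1, qlen - qs
                    pair_hits.append(
                        Hit(
                            query_id=query.id,
                            target_id=target.id,
                            pct_identity=100.0 * matches / columns,
                            aln_len=columns,
                            q_start=q_start,
                            q_end=q_end,
                            t_start=ts + 1,
                            t_end=te,
                            score=score,
                            evalue=ev,
                            strand=strand,
                        )
                    )
            if not pair_hits:
                continue
            pair_hits.sort(key=lambda h: (-h.score, -h.aln_len, h.t_start))
            if params.single_hsp:
                all_hits.append(pair_hits[0])
            else:
                kept: list[Hit] = []
                for h in pair_hits:
                    if all(
                        min(h.t_end, k.t_end) - max(h.t_start, k.t_start)
                        < 0.5 * min(h.aln_len, k.aln_len)
                        for k in kept
                    ):
                        kept.append(h)
                all_hits.extend(kept)
    return all_hits


def map_kmismatch(
    reads: Sequence[SeqRecord],
    target: SeqRecord,
    k: int = 3,
) -> list[Hit]:
    """End-to-end ungapped placement of fixed-length reads, <= k mismatches.

    All qualifying placements on both strands are reported;
    ``pct_identity = 100 * (len - mismatches) / len``, so 50-bp reads at
    k=3 have an identity floor of exactly 94.0%.  Seeding uses the
    pigeonhole principle: the read is cut into ``k + 1`` pieces and every
    exact piece match anchors a candidate placement.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not reads:
        return []
    read_len = len(reads[0])
    if any(len(r) != read_len for r in reads):
        raise ValueError("map_kmismatch requires fixed-length reads")
    piece = read_len // (k + 1)
    if piece < 4:
        raise ValueError("reads too short for this k (seed pieces < 4 bp)")
    t_seq = target.seq
    t_codes = encode(t_seq)
    # read N and target N get distinct codes so N never matches anything
    t_cmp = t_codes.astype(np.int16)
    t_cmp[t_cmp == 4] = 5
    idx = _index_kmers(t_seq, piece)
    hits: list[Hit] = []
    t_len = len(t_seq)
    for read in reads:
        seen: set[tuple[int, str]] = set()
        for strand in "+-":
            r_seq = read.seq if strand == "+" else revcomp(read.seq)
            r_cmp = encode(r_seq).astype(np.int16)
            starts: set[int] = set()
            for j in range(k + 1):
                off = j * piece
                for tpos in idx.get(r_seq[off: off + piece], ()):
                    s = tpos - off
                    if 0 <= s <= t_len - read_len:
                        starts.add(s)
            for s in starts:
                if (s, strand) in seen:
                    continue
                mm = int(np.count_nonzero(t_cmp[s: s + read_len] != r_cmp))
                if mm <= k:
                    seen.add((s, strand))
                    matches = read_len - mm
                    hits.append(
                        Hit(
                            query_id=read.id,
                            target_id=target.id,
                            pct_identity=100.0 * matches / read_len,
                            aln_len=read_len,
                            q_start=1,
                            q_end=read_len,
                            t_start=s + 1,
                            t_end=s + read_len,
                            score=float(matches - 2 * mm),
                            strand=strand,
                        )
                    )
    return hits


def full_span_identity(hit: Hit, query: SeqRecord, target: SeqRecord) -> float:
    """Identity of the whole query at the hit's placement.

    Local alignment reports the maximal-scoring segment, which trims
    mismatch-dense read ends and so overstates identity by a few points on
    diverged sequence; for divergence estimation the identity over the full
    read span is the right quantity.  The hit's diagonal placement is
    extended ungapped to the read ends (clipped at the target bounds);
    gapped hits fall back to the reported hit identity.
    """
    qlen = len(query)
    qspan = hit.q_end - hit.q_start + 1
    tspan = hit.t_end - hit.t_start + 1
    if hit.aln_len != qspan or qspan != tspan:
        return hit.pct_identity
    q_seq = query.seq if hit.strand == "+" else revcomp(query.seq)
    q_s0 = (hit.q_start - 1) if hit.strand == "+" else (qlen - hit.q_end)
    diag = (hit.t_start - 1) - q_s0
    lo_q = max(0, -diag)
    hi_q = min(qlen, len(target) - diag)
    if hi_q <= lo_q:
        return hit.pct_identity
    q_codes = encode(q_seq)[lo_q:hi_q]
    t_codes = encode(target.seq)[lo_q + diag: hi_q + diag]
    matches = int(np.count_nonzero((q_codes == t_codes) & (q_codes < 4)))
    return 100.0 * matches / (hi_q - lo_q)


def select_best_nonoverlapping(
    hits: Iterable[Hit],
    min_len: int = 100,
    max_overlap: int = 75,
) -> list[Hit]:
    """Greedy best-nonoverlapping-hit selection on one target contig.

    Hits are taken in order of descending score (ties: longer alignment,
    then smaller target start, then query id); a hit is accepted iff its
    alignment length is at least ``min_len`` and its target-interval
    overlap with every already-accepted hit is at most ``max_overlap``
    (inclusive boundary).  Output is sorted by target start.
    """
    hits = list(hits)
    if len({h.target_id for h in hits}) > 1:
        raise ValueError("select_best_nonoverlapping expects hits on one target")
    order = sorted(hits, key=lambda h: (-h.score, -h.aln_len, h.t_start, h.query_id))
    accepted: list[Hit] = []
    for h in order:
        if h.aln_len < min_len:
            continue
        ok = True
        for a in accepted:
            ov = min(h.t_end, a.t_end) - max(h.t_start, a.t_start) + 1
            if ov > max_overlap:
                ok = False
                break
        if ok:
            accepted.append(h)
    return sorted(accepted, key=lambda h: h.t_start)
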