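"""The two HT-detection procedures: targeted (RT-seeded, element-delimited)
and nontargeted (dense-region), plus exclusion filters and the
identity-threshold sweep.

Targeted path, per cluster-representative RT sequence: find its genomic
homologies (top 3 per genome at > 85% identity over >= 140 bp), cut a
10-kb-flanked window around each, map all sample reads onto the window,
prune to best-nonoverlapping hits (>= 100 bp matched, <= 75 bp overlap),
annotate the element structurally, and call a horizontal transfer iff at
least 10 distinct reads hit within the element at an unweighted mean
identity above 97%.  Hits beyond the element ends must not show elevated
identity — a window that does is flagged, since a real HT moves the
element alone, not its flanks.

Nontargeted path: shred sample reads to 50 bp, map end-to-end with at most
3 mismatches (a 94% identity floor), merge densely mapped target intervals
(> 500 bp covered, gaps < 150 bp), re-map the full-length reads onto each
20-kb-flanked candidate window, and call a transfer iff reads above the
identity threshold cover > 500 bp.  Candidate regions matching organelle /
rRNA / conserved-gene exclusion sets or low-complexity sequence are
removed before calling.

All inequality boundaries follow the source criteria literally: > 500 bp,
< 150 bp, > 97.0%, >= 10 hits, >= 140 bp, > 85%.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import align as _align
from . import domains as _domains
from .seqio import Hit, Interval, SeqRecord, encode

__all__ = [
    "Region",
    "HTCall",
    "targeted_scan",
    "homolog_search",
    "merge_dense_regions",
    "nontargeted_scan",
    "apply_filters",
    "threshold_sweep",
]


@dataclass
class Region:
    """A merged interval on a target contig densely covered by mapped reads."""

    target_id: str
    start: int
    end: int
    mapped_bp: int          # union of read intervals (covered bases)
    n_hits: int
    mean_identity: float
    filter_reason: str = ""

    def __post_init__(self) -> None:
        if self.mapped_bp > self.end - self.start + 1:
            raise ValueError("mapped_bp cannot exceed the region span")
        if not 0.0 <= self.mean_identity <= 100.0:
            raise ValueError("mean_identity must be in [0, 100]")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class HTCall:
    """One putative horizontally transferred element."""

    donor_taxon: str
    recipient_genome: str
    element_interval: Interval
    n_support_hits: int
    mean_identity: float
    mode: str  # targeted | nontargeted
    te_class: str | None = None
    cluster_id: str = ""
    flags: list[str] = field(default_factory=list)
    support_hits: list[Hit] = field(default_factory=list, repr=False)
    provenance: dict = field(default_factory=dict)


def _union_bp(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_s = cur_e = None
    for s, e in sorted(intervals):
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def _extract_window(
    genome: SeqRecord, start: int, end: int, flank: int
) -> tuple[SeqRecord, int]:
    """Window [start-flank, end+flank] (clipped); returns (record, offset)
    where offset converts window coords to genome coords (genome = window +
    offset)."""
    lo = max(1, start - flank)
    hi = min(len(genome), end + flank)
    if lo > start - flank or hi < end + flank:
        warnings.warn(
            f"window around {genome.id}:{start}-{end} truncated at a contig edge",
            stacklevel=3,
        )
    rec = SeqRecord(
        id=f"{genome.id}:{lo}-{hi}", seq=genome.seq[lo - 1: hi], taxon=genome.taxon
    )
    return rec, lo - 1


def targeted_scan(
    rt_clusters: Mapping[str, SeqRecord],
    target_genomes: Sequence[SeqRecord],
    sample_reads: Sequence[SeqRecord],
    params: _align.AlignParams | None = None,
    domain_profiles: Mapping[str, _domains.Profile] | None = None,
    *,
    top_n: int = 3,
    rt_min_identity: float = 85.0,
    rt_min_len: int = 140,
    flank: int = 10_000,
    min_len: int = 100,
    max_overlap: int = 75,
    min_hits: int = 10,
    identity_threshold: float = 97.0,
) -> list[HTCall]:
    """RT-seeded, element-delimited HT detection.

    ``rt_clusters`` maps cluster id -> representative RT sequence (from
    :func:`htt.cluster_events.cluster_sequences` over RT-carrying reads).
    Support hits are counted as distinct read ids falling entirely within
    the annotated element; their unweighted mean identity must exceed
    ``identity_threshold``.
    """
    params = params or _align.AlignParams()
    domain_profiles = domain_profiles or _domains.default_profiles()
    multi_params = _align.AlignParams(
        word_size=params.word_size, min_score=params.min_score,
        max_evalue=params.max_evalue, single_hsp=False,
    )
    genomes_by_id = {g.id: g for g in target_genomes}
    # top-N qualifying homologies per representative per genome ...
    seeds: list[tuple[str, Hit]] = []
    for cluster_id, rep in sorted(rt_clusters.items()):
        genome_hits = _align.local_align([rep], list(target_genomes), multi_params)
        by_genome: dict[str, list[Hit]] = {}
        for h in genome_hits:
            if h.pct_identity > rt_min_identity and h.aln_len >= rt_min_len:
                by_genome.setdefault(h.target_id, []).append(h)
        for genome_id, hits in sorted(by_genome.items()):
            top = sorted(hits, key=lambda h: (-h.score, h.t_start))[:top_n]
            seeds.extend((cluster_id, h) for h in top)
    # ... but each genomic locus is examined once, seeded by its best hit
    # (representatives of overlapping clusters share the same element)
    distinct: list[tuple[str, Hit]] = []
    for cluster_id, h in sorted(seeds, key=lambda s: -s[1].score):
        if any(
            k.target_id == h.target_id
            and min(k.t_end, h.t_end) - max(k.t_start, h.t_start) > -2000
            for _, k in distinct
        ):
            continue
        distinct.append((cluster_id, h))
    calls: list[HTCall] = []
    for cluster_id, seed_hit in distinct:
        call = _examine_window(
            seed_hit, genomes_by_id[seed_hit.target_id], sample_reads, params,
            domain_profiles, cluster_id, flank, min_len, max_overlap,
            min_hits, identity_threshold,
        )
        if call is not None:
            calls.append(call)
    return _dedup_calls(calls)


def _examine_window(
    seed_hit: Hit,
    genome: SeqRecord,
    sample_reads: Sequence[SeqRecord],
    params: _align.AlignParams,
    domain_profiles,
    cluster_id: str,
    flank: int,
    min_len: int,
    max_overlap: int,
    min_hits: int,
    identity_threshold: float,
) -> HTCall | None:
    window, offset = _extract_window(genome, seed_hit.t_start, seed_hit.t_end, flank)
    read_hits = _align.local_align(list(sample_reads), [window], params)
    retained = _align.select_best_nonoverlapping(read_hits, min_len, max_overlap)
    annot = _domains.annotate_te(window, dict(domain_profiles))
    elements = [iv for iv in annot if iv.kind == "TE"]
    if not elements:
        return None
    # the element containing (or nearest to) the seeding RT hit
    seed_mid_w = (seed_hit.t_start + seed_hit.t_end) // 2 - offset
    elements.sort(
        key=lambda iv: 0 if iv.start <= seed_mid_w <= iv.end
        else min(abs(iv.start - seed_mid_w), abs(iv.end - seed_mid_w))
    )
    element = elements[0]
    inside = [
        h for h in retained
        if element.start <= h.t_start and h.t_end <= element.end
    ]
    distinct_ids = {h.query_id for h in inside}
    if len(distinct_ids) < min_hits:
        return None
    mean_identity = float(np.mean([h.pct_identity for h in inside]))
    weighted = float(
        np.average([h.pct_identity for h in inside],
                   weights=[h.aln_len for h in inside])
    )
    if mean_identity <= identity_threshold:
        return None
    flags = []
    if "incomplete" in element.label:
        flags.append("element_incomplete")
    flank_hits = [
        h for h in retained
        if h.t_end < element.start or h.t_start > element.end
    ]
    high_flank = [h for h in flank_hits if h.pct_identity > identity_threshold]
    if len(high_flank) >= 5 and len(high_flank) > 0.2 * len(flank_hits):
        flags.append("elevated_flank_identity")
    donors = Counter(r.taxon for r in sample_reads if r.taxon)
    donor = donors.most_common(1)[0][0] if donors else "unknown"
    return HTCall(
        donor_taxon=donor,
        recipient_genome=genome.id,
        element_interval=Interval(
            genome.id, element.start + offset, element.end + offset, "TE",
            element.label,
        ),
        n_support_hits=len(distinct_ids),
        mean_identity=mean_identity,
        mode="targeted",
        cluster_id=cluster_id,
        flags=flags,
        support_hits=inside,
        provenance={
            "min_hits": min_hits,
            "identity_threshold": identity_threshold,
            "min_len": min_len,
            "max_overlap": max_overlap,
            "flank": flank,
            "mean_identity_length_weighted": weighted,
            "window": window.id,
        },
    )


def _dedup_calls(calls: list[HTCall]) -> list[HTCall]:
    """Collapse calls whose element intervals overlap on the same genome."""
    kept: list[HTCall] = []
    for call in sorted(calls, key=lambda c: (-c.mean_identity, -c.n_support_hits)):
        iv = call.element_interval
        if any(
            k.recipient_genome == call.recipient_genome
            and k.element_interval.overlap(iv.start, iv.end) > 0
            for k in kept
        ):
            continue
        kept.append(call)
    return sorted(kept, key=lambda c: (c.recipient_genome, c.element_interval.start))


def homolog_search(
    ht_rt_seq: SeqRecord,
    genome: SeqRecord,
    params: _align.AlignParams | None = None,
    min_identity: float = 85.0,
) -> list[Hit]:
    """Homologous copies of a confirmed HT element's RT in a genome.

    A hit counts as a homolog iff its matched length exceeds half the query
    RT (strictly) at identity strictly above ``min_identity``; the identity
    list feeds the per-genome homolog histograms.
    """
    params = params or _align.AlignParams(single_hsp=False)
    if params.single_hsp:
        params = _align.AlignParams(
            word_size=params.word_size, min_score=params.min_score,
            max_evalue=params.max_evalue, single_hsp=False,
        )
    hits = _align.local_align([ht_rt_seq], [genome], params)
    half = len(ht_rt_seq) / 2.0
    return sorted(
        (h for h in hits if h.aln_len > half and h.pct_identity > min_identity),
        key=lambda h: h.t_start,
    )


def merge_dense_regions(
    kmismatch_hits: Sequence[Hit],
    min_region_len: int = 500,
    max_gap: int = 150,
) -> list[Region]:
    """Chain mapped short-read intervals into densely mapped regions.

    Intervals whose gap is strictly less than ``max_gap`` chain together;
    a chain survives iff the union of its mapped bases strictly exceeds
    ``min_region_len``.  ``mapped_bp`` counts covered bases (interval
    union), not the chain span; both are available (span via start/end).
    """
    regions: list[Region] = []
    by_target: dict[str, list[Hit]] = {}
    for h in kmismatch_hits:
        by_target.setdefault(h.target_id, []).append(h)
    for target_id in sorted(by_target):
        hits = sorted(by_target[target_id], key=lambda h: (h.t_start, h.t_end))
        chain: list[Hit] = []
        chain_end = None
        for h in hits + [None]:
            if h is not None and (chain_end is None or h.t_start - chain_end - 1 < max_gap):
                chain.append(h)
                chain_end = max(chain_end or 0, h.t_end)
            else:
                if chain:
                    mapped = _union_bp((c.t_start, c.t_end) for c in chain)
                    if mapped > min_region_len:
                        regions.append(
                            Region(
                                target_id=target_id,
                                start=min(c.t_start for c in chain),
                                end=max(c.t_end for c in chain),
                                mapped_bp=mapped,
                                n_hits=len(chain),
                                mean_identity=float(
                                    np.mean([c.pct_identity for c in chain])
                                ),
                            )
                        )
                if h is not None:
                    chain = [h]
                    chain_end = h.t_end
    return regions


# ---------------------------------------------------------------------------
# Exclusion filters


def _low_complexity_fraction(seq: str, window: int = 50) -> float:
    """Fraction of windows with low mono- or dinucleotide entropy."""
    if len(seq) < window:
        window = len(seq)
    codes = encode(seq)
    n_low = 0
    n_win = 0
    for s in range(0, len(codes) - window + 1, window):
        sub = codes[s: s + window]
        mono = np.bincount(sub, minlength=5)[:4]
        p = mono[mono > 0] / mono.sum() if mono.sum() else np.array([1.0])
        h1 = -np.sum(p * np.log2(p))
        di = sub[:-1] * 5 + sub[1:]
        counts = np.bincount(di, minlength=25)
        q = counts[counts > 0] / counts.sum()
        h2 = -np.sum(q * np.log2(q))
        n_win += 1
        if h1 < 1.5 or h2 < 2.5:
            n_low += 1
    return n_low / n_win if n_win else 0.0


def apply_filters(
    regions: Sequence[Region],
    exclusion_sets: Mapping[str, Sequence[SeqRecord]] | None,
    genome: SeqRecord,
    min_exclusion_identity: float = 85.0,
    max_exclusion_frac: float = 0.5,
    max_low_complexity: float = 0.5,
    params: _align.AlignParams | None = None,
) -> list[Region]:
    """Drop candidate regions explained by non-HT homology.

    A region is removed iff >= ``max_exclusion_frac`` of its bases align to
    any named exclusion set (organelle, rRNA, conserved genes, ...) at
    identity > ``min_exclusion_identity``, or its low-complexity window
    fraction reaches ``max_low_complexity``.  Removed regions keep a
    ``filter_reason``; the returned list holds the survivors.
    """
    params = params or _align.AlignParams(min_score=40.0, single_hsp=False)
    kept: list[Region] = []
    for region in regions:
        seq = genome.seq[region.start - 1: region.end]
        rec = SeqRecord(id="region", seq=seq)
        reason = ""
        if _low_complexity_fraction(seq) >= max_low_complexity:
            reason = "simple_repeat"
        if not reason and exclusion_sets:
            for name, refs in exclusion_sets.items():
                hits = _align.local_align([rec], list(refs), params)
                covered = _union_bp(
                    (h.q_start, h.q_end)
                    for h in hits
                    if h.pct_identity > min_exclusion_identity
                )
                if covered >= max_exclusion_frac * len(seq):
                    reason = name
                    break
        if reason:
            region.filter_reason = reason
        else:
            kept.append(region)
    return kept


# ---------------------------------------------------------------------------
# Nontargeted scan


def _shred_to_pieces(reads: Sequence[SeqRecord], piece_len: int) -> list[SeqRecord]:
    """Deterministically chop reads into consecutive fixed-length pieces."""
    pieces = []
    for r in reads:
        for k in range(len(r) // piece_len):
            pieces.append(
                SeqRecord(
                    id=f"{r.id}.p{k}",
                    seq=r.seq[k * piece_len: (k + 1) * piece_len],
                    taxon=r.taxon,
                )
            )
    return pieces


def nontargeted_scan(
    sample_reads: Sequence[SeqRecord],
    target_genome: SeqRecord,
    filters: Mapping[str, Sequence[SeqRecord]] | None = None,
    params: _align.AlignParams | None = None,
    *,
    piece_len: int = 50,
    k_mismatch: int = 3,
    min_region_len: int = 500,
    max_gap: int = 150,
    flank: int = 20_000,
    identity_threshold: float = 97.0,
    min_covered: int = 500,
) -> list[HTCall]:
    """Dense-region HT detection without an RT seed.

    Reads are shredded to ``piece_len`` bp and placed end-to-end with at
    most ``k_mismatch`` mismatches (the loose, 94%-floor pass); densely
    mapped regions are filtered against the exclusion sets, then the
    full-length reads are re-mapped onto each flanked candidate window and
    a call is made iff reads above ``identity_threshold`` cover more than
    ``min_covered`` bp.  With no filter sets the scan still runs but every
    call is flagged unfiltered.
    """
    params = params or _align.AlignParams()
    # multi-HSP mapping: a read matching several element copies in one
    # window contributes coverage to each copy's candidate region
    params = _align.AlignParams(
        word_size=params.word_size, min_score=params.min_score,
        max_evalue=params.max_evalue, single_hsp=False,
    )
    pieces = _shred_to_pieces(sample_reads, piece_len)
    kmis_hits = _align.map_kmismatch(pieces, target_genome, k_mismatch)
    regions = merge_dense_regions(kmis_hits, min_region_len, max_gap)
    unfiltered = filters is None
    if unfiltered:
        warnings.warn(
            "no exclusion sets supplied; nontargeted calls are unfiltered",
            stacklevel=2,
        )
    else:
        regions = apply_filters(regions, filters, target_genome)
    donors = Counter(r.taxon for r in sample_reads if r.taxon)
    donor = donors.most_common(1)[0][0] if donors else "unknown"
    calls: list[HTCall] = []
    reads_by_id = {r.id: r for r in sample_reads}
    for region in regions:
        window, offset = _extract_window(target_genome, region.start, region.end, flank)
        read_hits = _align.local_align(list(sample_reads), [window], params)
        # identity over the full read span, not the trimmed local segment:
        # the threshold screens divergence since transfer, and segment
        # trimming overstates identity by a couple of points on diverged
        # sequence
        read_hits = [
            dataclasses.replace(
                h,
                pct_identity=_align.full_span_identity(
                    h, reads_by_id[h.query_id], window
                ),
            )
            for h in read_hits
        ]
        # hits accrue to this region's candidate locus, not to unrelated
        # high-identity sequence elsewhere in the re-mapping window
        lo = region.start - offset - 2000
        hi = region.end - offset + 2000
        above = [
            h for h in read_hits
            if h.pct_identity > identity_threshold
            and h.t_end >= lo and h.t_start <= hi
        ]
        covered = _union_bp((h.t_start, h.t_end) for h in above)
        if covered <= min_covered:
            continue
        flags = ["unfiltered"] if unfiltered else []
        calls.append(
            HTCall(
                donor_taxon=donor,
                recipient_genome=target_genome.id,
                element_interval=Interval(
                    target_genome.id,
                    min(h.t_start for h in above) + offset,
                    max(h.t_end for h in above) + offset,
                    "region",
                    "nontargeted_candidate",
                ),
                n_support_hits=len({h.query_id for h in above}),
                mean_identity=float(np.mean([h.pct_identity for h in above])),
                mode="nontargeted",
                flags=flags,
                support_hits=above,
                provenance={
                    "piece_len": piece_len,
                    "k_mismatch": k_mismatch,
                    "min_region_len": min_region_len,
                    "max_gap": max_gap,
                    "flank": flank,
                    "identity_threshold": identity_threshold,
                    "min_covered": min_covered,
                    "covered_bp": covered,
                    "seed_region": (region.start, region.end),
                },
            )
        )
    return _dedup_calls(calls)


def threshold_sweep(
    calls_raw: Sequence[HTCall],
    thresholds: Sequence[float] = (94.0, 97.0, 100.0),
) -> dict[float, int]:
    """Call counts at increasing identity thresholds.

    ``calls_raw`` are calls computed once at the loosest threshold with
    per-call mean identities retained; the count at ``t`` is the number of
    calls with mean identity >= t, so counts are nonincreasing in t.
    """
    return {
        float(t): sum(1 for c in calls_raw if c.mean_identity >= t)
        for t in thresholds
    }
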