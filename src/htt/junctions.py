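"""Insertion verification at element junctions.

A genuine LTR-retrotransposon integration leaves three marks that vertical
homology cannot fake: the element begins ``TG`` and ends ``CA`` (the LTR
terminal motif), the integrase duplicates 4–6 bp of host sequence on both
sides (the target-site duplication, TSD), and reads from the recipient
span the native/foreign junctions.  Comparing the insertion window against
orthologous regions of related genomes then shows the element as present
or absent between conserved flanks, dating the transfer against the
recipient phylogeny.  The TSD is assigned to the flanks, not the element:
junction coordinates are the element's outer LTR edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from . import align as _align
from .seqio import Hit, Interval, SeqRecord, revcomp

__all__ = [
    "JunctionReport",
    "refine_element_boundaries",
    "check_terminal_motifs",
    "detect_tsd",
    "junction_support",
    "ortholog_presence",
    "junction_report",
]


@dataclass
class JunctionReport:
    element: Interval
    ltr5_motif_ok: bool
    ltr3_motif_ok: bool
    tsd_seq: str
    left_support: int
    right_support: int
    orthologs: dict[str, str] = field(default_factory=dict)

    @property
    def tsd_len(self) -> int:
        return len(self.tsd_seq)


def check_terminal_motifs(
    contig: SeqRecord, element: Interval
) -> tuple[bool, bool]:
    """TG…CA terminal-motif flags for an element (outer LTR boundaries).

    Both strands are checked and the better orientation reported, so a
    minus-strand element scores the same as a plus-strand one.  A solo LTR
    is a single TG…CA unit and passes the same check.
    """
    if element.start < 1 or element.end > len(contig):
        raise ValueError("element outside contig")
    seq = contig.seq[element.start - 1: element.end]
    fwd = (seq.startswith("TG"), seq.endswith("CA"))
    rc = revcomp(seq)
    rev = (rc.startswith("TG"), rc.endswith("CA"))
    return fwd if sum(fwd) >= sum(rev) else rev


def detect_tsd(
    contig: SeqRecord,
    element: Interval,
    min_len: int = 4,
    max_len: int = 6,
) -> str:
    """Target-site duplication anchored at the element junctions.

    The longest exact match between the ``max_len`` bases immediately 5'
    of the element and those immediately 3' of it, required to touch both
    junctions; the empty string if the best anchored match is shorter than
    ``min_len``.
    """
    if element.start - 1 < max_len or len(contig) - element.end < max_len:
        raise ValueError("element needs >= max_len bp of flank on each side")
    left = contig.seq[element.start - 1 - max_len: element.start - 1]
    right = contig.seq[element.end: element.end + max_len]
    for length in range(max_len, min_len - 1, -1):
        if left[-length:] == right[:length]:
            return right[:length]
    return ""


def junction_support(
    reads: Sequence[SeqRecord],
    contig: SeqRecord,
    element: Interval,
    min_anchor: int = 20,
    params: _align.AlignParams | None = None,
) -> tuple[int, int]:
    """Reads spanning the left and right element junctions.

    A read supports a junction iff its alignment covers at least
    ``min_anchor`` bases on each side of it.  Returns (left, right) counts.
    """
    if reads and min(len(r) for r in reads) < 2 * min_anchor:
        raise ValueError("reads must be >= 2 * min_anchor bp")
    params = params or _align.AlignParams()
    hits = _align.local_align(list(reads), [contig], params)
    left_edge = element.start - 1   # between positions start-1 and start
    right_edge = element.end        # between positions end and end+1
    left = sum(
        1 for h in hits
        if h.t_start <= left_edge - min_anchor + 1 and h.t_end >= left_edge + min_anchor
    )
    right = sum(
        1 for h in hits
        if h.t_start <= right_edge - min_anchor + 1 and h.t_end >= right_edge + min_anchor
    )
    return left, right


def ortholog_presence(
    window: SeqRecord,
    element: Interval,
    other_genomes: Sequence[SeqRecord],
    anchor_len: int = 1000,
    anchor_min_identity: float = 80.0,
    element_min_identity: float = 85.0,
    element_min_cov: float = 0.5,
    absent_max_frac: float = 0.1,
    params: _align.AlignParams | None = None,
) -> dict[str, str]:
    """Presence/absence of the element in orthologous regions.

    The element's flanks (``anchor_len`` bp each side, > ``anchor_min_identity``
    % identity required) locate the orthologous locus in each genome;
    the element is *present* iff its sequence aligns between the anchors at
    > ``element_min_identity`` % identity over > ``element_min_cov`` of its
    length, *absent* iff the anchors adjoin with less than
    ``absent_max_frac`` of the element length between them, and
    *unresolved* otherwise (including unalignable flanks).
    """
    params = params or _align.AlignParams(single_hsp=False)
    if element.start - 1 < anchor_len or len(window) - element.end < anchor_len:
        raise ValueError("window must hold >= anchor_len bp on each side")
    left = SeqRecord(id="left_anchor",
                     seq=window.seq[element.start - 1 - anchor_len: element.start - 1])
    right = SeqRecord(id="right_anchor",
                      seq=window.seq[element.end: element.end + anchor_len])
    elem = SeqRecord(id="element",
                     seq=window.seq[element.start - 1: element.end])
    verdicts: dict[str, str] = {}
    for genome in other_genomes:
        anchor_hits = _align.local_align([left, right], [genome], params)
        best: dict[str, Hit] = {}
        for h in anchor_hits:
            if h.pct_identity > anchor_min_identity and h.aln_len >= 0.5 * anchor_len:
                if h.query_id not in best or h.score > best[h.query_id].score:
                    best[h.query_id] = h
        if "left_anchor" not in best or "right_anchor" not in best:
            verdicts[genome.id] = "unresolved"
            continue
        lh, rh = best["left_anchor"], best["right_anchor"]
        if lh.strand != rh.strand:
            verdicts[genome.id] = "unresolved"
            continue
        if lh.strand == "+":
            inner_lo, inner_hi = lh.t_end, rh.t_start
        else:
            inner_lo, inner_hi = rh.t_end, lh.t_start
        gap = inner_hi - inner_lo - 1
        # anchors may overlap slightly (e.g. both cover the single target
        # site where the recipient carries a TSD); a large overlap means
        # the locus is rearranged
        if gap < -50:
            verdicts[genome.id] = "unresolved"
            continue
        elem_hits = [
            h for h in _align.local_align([elem], [genome], params)
            if h.pct_identity > element_min_identity
            and h.t_start >= inner_lo - 100 and h.t_end <= inner_hi + 100
            and h.aln_len > element_min_cov * len(elem)
        ]
        if elem_hits:
            verdicts[genome.id] = "present"
        elif gap < absent_max_frac * len(elem):
            verdicts[genome.id] = "absent"
        else:
            verdicts[genome.id] = "unresolved"
    return verdicts


def refine_element_boundaries(
    contig: SeqRecord,
    element: Interval,
    max_shift: int = 10,
    min_tsd: int = 4,
    max_tsd: int = 6,
) -> Interval:
    """Snap approximate element boundaries to the motif/TSD-consistent ones.

    Structural annotation delimits an element to within a few bases; the
    junction evidence itself (``TG``/``CA`` termini, flanking target-site
    duplication) pins the exact edges.  Candidate boundaries within
    ``max_shift`` bp are scored by the junction marks they exhibit — an
    anchored TSD of at least ``min_tsd`` bp (the sharpest signal, so it
    carries the most weight) plus each intact terminal motif — with ties
    going to the smallest displacement then the longer TSD.  Either mark
    may be absent (both decay by mutation); with no scoring candidate the
    input is returned unchanged.
    """
    best = None
    for d5 in range(-max_shift, max_shift + 1):
        s = element.start + d5
        if s < max_tsd + 1:
            continue
        motif5 = contig.seq[s - 1: s + 1] == "TG"
        for d3 in range(-max_shift, max_shift + 1):
            e = element.end + d3
            if e > len(contig) - max_tsd or e <= s:
                continue
            motif3 = contig.seq[e - 2: e] == "CA"
            cand = Interval(element.target_id, s, e, element.kind, element.label)
            tsd = detect_tsd(contig, cand, min_tsd, max_tsd)
            score = 3 * bool(tsd) + motif5 + motif3
            if score == 0:
                continue
            key = (-score, abs(d5) + abs(d3), -len(tsd), d5, d3)
            if best is None or key < best[0]:
                best = (key, cand)
    return best[1] if best is not None else element


def junction_report(
    contig: SeqRecord,
    element: Interval,
    reads: Sequence[SeqRecord] = (),
    other_genomes: Sequence[SeqRecord] = (),
    window_flank: int = 10_000,
    refine: bool = True,
) -> JunctionReport:
    """Bundle all junction evidence for one element.

    With ``refine`` (the default) the element boundaries are first snapped
    to the nearest motif/TSD-consistent edges (annotation places them only
    to within a few bases).
    """
    if refine:
        element = refine_element_boundaries(contig, element)
    ltr5, ltr3 = check_terminal_motifs(contig, element)
    tsd = detect_tsd(contig, element)
    left = right = 0
    if reads:
        left, right = junction_support(reads, contig, element)
    orthologs: dict[str, str] = {}
    if other_genomes:
        lo = max(1, element.start - window_flank)
        hi = min(len(contig), element.end + window_flank)
        window = SeqRecord(id="window", seq=contig.seq[lo - 1: hi])
        shifted = Interval(
            "window", element.start - lo + 1, element.end - lo + 1,
            element.kind, element.label,
        )
        orthologs = ortholog_presence(window, shifted, other_genomes)
    return JunctionReport(
        element=element,
        ltr5_motif_ok=ltr5,
        ltr3_motif_ok=ltr3,
        tsd_seq=tsd,
        left_support=left,
        right_support=right,
        orthologs=orthologs,
    )
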