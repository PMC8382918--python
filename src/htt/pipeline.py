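"""End-to-end orchestration of the published two-track analysis.

The targeted track mirrors the RT-seeded screen: isolate RT-carrying
sample reads with the domain profile, cluster them, then run the
element-delimited window scan per cluster representative.  The
nontargeted track runs the dense-region scan directly.  The calibration
track maps the sample reads onto a reference CDS set to place the
vertical-divergence peak and check that the HT identity threshold clears
it.  Each function is a thin composition of the library modules so the
command-line interface, the test-suite and user scripts all execute the
same code path.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Mapping, Sequence

from . import align as _align
from . import calibrate as _calibrate
from . import cluster_events as _cluster
from . import domains as _domains
from . import htscan as _htscan
from .seqio import Hit, SeqRecord

__all__ = [
    "stage_seed",
    "isolate_rt_reads",
    "rt_cluster_representatives",
    "run_targeted",
    "run_nontargeted",
    "run_calibration",
]


def stage_seed(seed: int, stage: str) -> int:
    """Fan a global seed out to a stable per-stage seed (< 2**31)."""
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def isolate_rt_reads(
    reads: Sequence[SeqRecord],
    rt_profile: _domains.Profile | None = None,
) -> list[SeqRecord]:
    """Sample reads carrying a reverse-transcriptase domain."""
    rt_profile = rt_profile or _domains.default_profiles()["RT"]
    detected = _domains.scan_reads(reads, rt_profile)
    ids = {read_id for read_id, _, _ in detected}
    return [r for r in reads if r.id in ids]


def rt_cluster_representatives(
    rt_reads: Sequence[SeqRecord],
    min_identity: float = 90.0,
    min_cov: float = 0.55,
) -> dict[str, SeqRecord]:
    """Cluster RT reads and pick one representative per cluster.

    The representative is the longest member (ties: smallest id), since
    downstream homology seeding imposes a matched-length floor; singleton
    RT reads seed their own pseudo-cluster so low-copy elements are still
    screened.
    """
    if not rt_reads:
        return {}
    by_id = {r.id: r for r in rt_reads}
    clusters, singletons = _cluster.cluster_sequences(
        list(rt_reads), min_identity, min_cov
    )
    reps = {
        c.id: max((by_id[m] for m in c.members), key=lambda r: (len(r), r.id))
        for c in clusters
    }
    for i, sid in enumerate(singletons):
        reps[f"SG{i + 1:03d}"] = by_id[sid]
    return reps


def run_targeted(
    sample_reads: Sequence[SeqRecord],
    target_genomes: Sequence[SeqRecord],
    domain_profiles: Mapping[str, _domains.Profile] | None = None,
    params: _align.AlignParams | None = None,
    **scan_kwargs,
) -> dict:
    """Full targeted track: RT isolation -> clustering -> window scan."""
    profiles = dict(domain_profiles or _domains.default_profiles())
    rt_reads = isolate_rt_reads(sample_reads, profiles["RT"])
    reps = rt_cluster_representatives(rt_reads)
    calls = _htscan.targeted_scan(
        reps, list(target_genomes), list(sample_reads),
        params=params, domain_profiles=profiles, **scan_kwargs,
    )
    return {
        "rt_reads": rt_reads,
        "cluster_representatives": reps,
        "calls": calls,
    }


def run_nontargeted(
    sample_reads: Sequence[SeqRecord],
    target_genome: SeqRecord,
    filters: Mapping[str, Sequence[SeqRecord]] | None = None,
    **scan_kwargs,
) -> list[_htscan.HTCall]:
    return _htscan.nontargeted_scan(
        list(sample_reads), target_genome, filters, **scan_kwargs
    )


def run_calibration(
    sample_reads: Sequence[SeqRecord],
    cds_records: Sequence[SeqRecord],
    threshold: float = 97.0,
    params: _align.AlignParams | None = None,
    min_len: int = 100,
    max_overlap: int = 75,
) -> dict:
    """CDS-identity calibration of the HT threshold.

    Best-nonoverlapping sample-read hits per CDS feed the identity
    histogram; the report carries the modal peak, the tail fraction above
    the threshold and the pass/fail verdict.  Computed over CDS-mapped
    best hits only (unmapped reads carry no identity information).  Each
    retained hit contributes its identity over the full read span
    (:func:`htt.align.full_span_identity`): the maximal-scoring segment
    alone overstates identity on diverged sequence, which would bias the
    divergence peak upward.
    """
    params = params or _align.AlignParams()
    hits = _align.local_align(list(sample_reads), list(cds_records), params)
    by_cds: dict[str, list[Hit]] = {}
    for h in hits:
        by_cds.setdefault(h.target_id, []).append(h)
    retained: list[Hit] = []
    for cds_id in sorted(by_cds):
        retained.extend(
            _align.select_best_nonoverlapping(by_cds[cds_id], min_len, max_overlap)
        )
    reads_by_id = {r.id: r for r in sample_reads}
    cds_by_id = {c.id: c for c in cds_records}
    retained = [
        dataclasses.replace(
            h,
            pct_identity=_align.full_span_identity(
                h, reads_by_id[h.query_id], cds_by_id[h.target_id]
            ),
        )
        for h in retained
    ]
    hist = _calibrate.cds_identity_histogram(retained)
    report = _calibrate.validate_threshold(hist, threshold)
    return {"histogram": hist, "report": report, "retained_hits": retained}
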