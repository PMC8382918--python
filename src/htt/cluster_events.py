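"""Similarity clustering of detected elements and HT-event inference.

Clustering is explicit single-linkage over identity/coverage edges (an edge
joins two sequences aligning at >= ``min_identity`` % over >= ``min_cov``
of the shorter one); connected components of size >= 2 are clusters,
everything else is a singleton.  This is a declared stand-in for
graph-layout read clustering pipelines, with the similarity defaults (90%
identity over 55% coverage) mirroring their documented settings.

Event inference then answers "how many independent transfers explain these
calls?": calls in the same cluster collapse into one event when they share
a donor taxon and their recipients group in one clade of the cluster tree,
or share a recipient taxon and their donors form one clade — the pattern
left by a single transfer into a common ancestor (or out of one donor
lineage) followed by amplification.  Without tree evidence the rule
degrades to same-cluster + shared-taxon and the event is flagged
unverified.  The minimum event count is one event per HT cluster plus one
per singleton, since each cluster requires at least one transfer.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import networkx as nx
import pandas as pd

from . import align as _align
from .phylo import taxa_form_clade
from .seqio import SeqRecord

__all__ = [
    "Cluster",
    "CallRecord",
    "HTEvent",
    "cluster_sequences",
    "merge_calls_to_events",
    "minimum_event_count",
    "partition_accounting",
    "per_recipient_tally",
]


@dataclass
class Cluster:
    """A similarity cluster of >= 2 sequences; singletons are not Clusters."""

    id: str
    members: list[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a Cluster has >= 2 members; track singletons separately")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CallRecord:
    """Minimal donor/recipient/cluster view of an HT call for event merging."""

    donor: str
    recipient: str
    cluster: str
    identity: float | None = None


@dataclass
class HTEvent:
    id: str
    donor_taxa: set[str]
    recipient_taxa: set[str]
    cluster_id: str
    member_calls: list[CallRecord]
    verified_by_phylogeny: bool = True

    def __post_init__(self) -> None:
        if not self.member_calls:
            raise ValueError("an event needs >= 1 member call")
        if self.donor_taxa & self.recipient_taxa:
            raise ValueError("donor and recipient taxon sets must be disjoint")


def cluster_sequences(
    seqs: Sequence[SeqRecord],
    min_identity: float = 90.0,
    min_cov: float = 0.55,
    params: _align.AlignParams | None = None,
) -> tuple[list[Cluster], list[str]]:
    """Single-linkage clustering over pairwise local-alignment edges.

    An edge joins i and j iff their best local alignment reaches
    ``min_identity`` % identity over at least ``min_cov`` of the shorter
    sequence.  Components of size >= 2 become clusters named ``CLxxx`` by
    descending size (ties by smallest member id); the rest are singletons.
    The output partitions the input: every id lands in exactly one cluster
    or the singleton list.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    params = params or _align.AlignParams(min_score=25.0, max_evalue=1e-4)
    lengths = {s.id: len(s) for s in seqs}
    g = nx.Graph()
    g.add_nodes_from(lengths)
    hits = _align.local_align(seqs, seqs, params) if len(seqs) > 1 else []
    for h in hits:
        if h.query_id == h.target_id:
            continue
        shorter = min(lengths[h.query_id], lengths[h.target_id])
        if h.pct_identity >= min_identity and h.aln_len >= min_cov * shorter:
            g.add_edge(h.query_id, h.target_id)
    comps = [sorted(c) for c in nx.connected_components(g)]
    multi = sorted(
        (c for c in comps if len(c) >= 2), key=lambda c: (-len(c), c[0])
    )
    clusters = [
        Cluster(id=f"CL{i + 1:03d}", members=c) for i, c in enumerate(multi)
    ]
    singletons = sorted(
        itertools.chain.from_iterable(c for c in comps if len(c) == 1)
    )
    return clusters, singletons


def merge_calls_to_events(
    calls: Sequence[CallRecord],
    clusters: Mapping[str, Cluster] | None = None,
    trees: Mapping[str, dendropy.Tree] | None = None,
) -> list[HTEvent]:
    """Collapse HT calls into independent transfer events.

    Two calls merge iff they sit in the same cluster AND either share the
    donor taxon with their recipients grouped in one clade of the cluster
    tree, or share the recipient taxon with their donors forming one clade.
    A clade is any bipartition side whose taxa are exactly the focal pair
    (root-agnostic, so recipients nested inside the donors' subtree still
    leave the donor pair as the complement side).  The merge relation is
    closed transitively.  Clusters without a tree fall back to
    same-cluster + shared-taxon and their events are flagged as unverified
    by phylogeny; a call without a cluster assignment becomes its own
    singleton event with a warning.
    """
    trees = trees or {}
    calls = list(calls)
    for c in calls:
        if not c.cluster:
            warnings.warn(
                f"call {c.donor}->{c.recipient} has no cluster; treated as singleton",
                stacklevel=2,
            )
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i, j in itertools.combinations(range(len(calls)), 2):
        a, b = calls[i], calls[j]
        if not a.cluster or a.cluster != b.cluster:
            continue
        tree = trees.get(a.cluster)
        if tree is None:
            if a.donor == b.donor or a.recipient == b.recipient:
                g.add_edge(i, j)
            continue
        if a.donor == b.donor and taxa_form_clade(
            tree, {a.recipient, b.recipient}
        ):
            g.add_edge(i, j)
        elif a.recipient == b.recipient and taxa_form_clade(
            tree, {a.donor, b.donor}
        ):
            g.add_edge(i, j)
    events: list[HTEvent] = []
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: c[0],
    )
    for k, comp in enumerate(comps):
        members = [calls[i] for i in comp]
        cluster_id = members[0].cluster or f"singleton_{k}"
        events.append(
            HTEvent(
                id=f"EV{k + 1:03d}",
                donor_taxa={m.donor for m in members},
                recipient_taxa={m.recipient for m in members},
                cluster_id=cluster_id,
                member_calls=members,
                verified_by_phylogeny=members[0].cluster in trees,
            )
        )
    return events


def minimum_event_count(clusters_with_ht, ht_singletons) -> int:
    """Minimum number of HT events: one per HT cluster plus one per
    singleton horizontally transferred element.

    Accepts counts or collections for either argument.
    """
    n_clusters = clusters_with_ht if isinstance(clusters_with_ht, int) else len(clusters_with_ht)
    n_singletons = ht_singletons if isinstance(ht_singletons, int) else len(ht_singletons)
    if n_clusters < 0 or n_singletons < 0:
        raise ValueError("counts must be >= 0")
    return n_clusters + n_singletons


def partition_accounting(
    clusters: Sequence[Cluster], singletons: Sequence[str]
) -> dict:
    """Bookkeeping for a clustering partition of detected elements."""
    n_clustered = sum(c.size for c in clusters)
    return {
        "n_clusters": len(clusters),
        "n_clustered_elements": n_clustered,
        "n_singletons": len(singletons),
        "n_total": n_clustered + len(singletons),
        "min_events": minimum_event_count(len(clusters), len(singletons)),
    }


def per_recipient_tally(events: Sequence[HTEvent]) -> pd.DataFrame:
    """Events per recipient taxon; multi-recipient events count once per
    recipient and are flagged shared."""
    rows = []
    for ev in events:
        shared = len(ev.recipient_taxa) > 1
        for taxon in sorted(ev.recipient_taxa):
            rows.append({"recipient": taxon, "event_id": ev.id, "shared": shared})
    if not rows:
        return pd.DataFrame(columns=["recipient", "n_events", "n_shared"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("recipient")
        .agg(n_events=("event_id", "nunique"), n_shared=("shared", "sum"))
        .reset_index()
    )
    out["n_shared"] = out["n_shared"].astype(int)
    return out
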