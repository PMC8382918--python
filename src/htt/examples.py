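"""Worked example: LTR-retrotransposon transfers between panicoid grasses
and *Oryza* species.

A published targeted screen of panicoid sample sequences against ten
*Oryza* genomes yielded 15 candidate (donor, recipient, cluster) records,
which the merge rule collapses into 12 independent transfer events: the
CL025 and CL102 shared-donor candidates merge because their recipients
group in one clade of the cluster tree, and the CL148 shared-recipient
candidates merge because their donors form one clade (the recipient's
copies nest inside it).  The per-cluster trees below encode exactly that
evidence; the third CL102 record keeps its own event because its donor
does not group with the other CL102 donor.

These records double as the inventory for the minimum-event counting
rule: the same survey's nontargeted screen found 165 transferred elements
falling into 30 multi-member HT clusters (147 elements) plus 18
singletons, a minimum of 48 events; 19 clusters and 8 singletons unique
to one recipient give a minimum of 27.
"""

from __future__ import annotations

import dendropy

from .cluster_events import CallRecord, Cluster

__all__ = [
    "GRASS_HT_CALLS",
    "grass_cluster_trees",
    "make_cluster_inventory",
]

# 15 candidate records from the targeted screen (donor, recipient, cluster,
# mean identity of supporting sample-sequence hits, %).
GRASS_HT_CALLS: list[CallRecord] = [
    CallRecord("Echinochloa haploclada", "Oryza punctata", "CL010", 98.7),
    CallRecord("Zuloagaea bulbosa", "Oryza brachyantha", "CL010", 98.9),
    CallRecord("Melinis ambigua", "Oryza nivara", "CL129", 97.8),
    CallRecord("Zuloagaea bulbosa", "Oryza rufipogon", "CL129", 99.1),
    CallRecord("Eriochloa meyeriana", "Oryza sativa", "CL129", 98.6),
    CallRecord("Echinochloa haploclada", "Oryza brachyantha", "CL212", 99.3),
    CallRecord("Cymbopogon citratus", "Oryza sativa", "CL025", 99.3),
    CallRecord("Cymbopogon citratus", "Oryza nivara", "CL025", 99.3),
    CallRecord("Echinochloa haploclada", "Oryza glumaepatula", "CL112", 97.3),
    CallRecord("Echinochloa pyramidalis", "Oryza punctata", "CL148", 98.4),
    CallRecord("Echinochloa haploclada", "Oryza punctata", "CL148", 98.1),
    CallRecord("Iseilema membranaceum", "Oryza rufipogon", "CL102", 97.0),
    CallRecord("Iseilema membranaceum", "Oryza sativa", "CL102", 97.8),
    CallRecord("Cenchrus pilosus", "Oryza sativa", "CL102", 97.3),
    CallRecord("Cenchrus setigerus", "Oryza nivara", "CL329", 97.1),
]

# Newick encodings of the phylogenetic evidence for the three clusters whose
# candidates merge (leaf labels are "taxon|copy").
_CLUSTER_TREES = {
    # recipients' RTs group in one clade nested in the donor's diversity
    "CL025": (
        "(('Cymbopogon citratus|1','Cymbopogon citratus|2'),"
        "('Oryza sativa|1','Oryza nivara|1'));"
    ),
    # the two shared-donor recipients group; the third donor does not join
    "CL102": (
        "(('Iseilema membranaceum|1',('Oryza sativa|1','Oryza rufipogon|1')),"
        "('Cenchrus pilosus|1','Oryza sativa|2'));"
    ),
    # the recipient's copies nest inside the clade of the two donors
    "CL148": (
        "(('Echinochloa pyramidalis|1',('Oryza punctata|1','Oryza punctata|2')),"
        "'Echinochloa haploclada|1');"
    ),
}


def grass_cluster_trees() -> dict[str, dendropy.Tree]:
    return {
        cid: dendropy.Tree.get(data=nwk, schema="newick")
        for cid, nwk in _CLUSTER_TREES.items()
    }


def make_cluster_inventory(
    n_clusters: int,
    n_singletons: int,
    mean_cluster_size: int = 5,
    n_clustered_elements: int | None = None,
) -> tuple[list[Cluster], list[str]]:
    """A synthetic cluster/singleton inventory with the given shape.

    Used to exercise the minimum-event counting rule on stated inventories
    (e.g. 30 clusters + 18 singletons) without the underlying reads.  With
    ``n_clustered_elements`` the cluster sizes are adjusted to sum to that
    many members (each cluster keeps >= 2).
    """
    if n_clustered_elements is None:
        sizes = [2 + (i * 7) % (2 * mean_cluster_size - 3) for i in range(n_clusters)]
    else:
        if n_clustered_elements < 2 * n_clusters:
            raise ValueError("need >= 2 members per cluster")
        base = n_clustered_elements // n_clusters
        sizes = [base] * n_clusters
        for i in range(n_clustered_elements - base * n_clusters):
            sizes[i] += 1
    clusters = [
        Cluster(
            id=f"HT{i + 1:03d}",
            members=[f"ht_el_{i:03d}_{j}" for j in range(size)],
        )
        for i, size in enumerate(sizes)
    ]
    singletons = [f"ht_singleton_{i:03d}" for i in range(n_singletons)]
    return clusters, singletons
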