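"""Dereplication and greedy identity clustering of oriented reads.

Oriented reads are collapsed to unique sequences with abundances, sorted
most-abundant-first, and scanned greedily: each unique sequence joins the
first cluster whose founding sequence (centroid) it matches at or above the
minimum identity, or founds a new cluster.  Identity is matches over
alignment columns of a global, end-to-end alignment, so length differences
are penalized.  Comparison is plus/plus only — upstream orientation has
already put every enrichment primer on the plus strand.

The sequence carried forward into classification is not the centroid but the
longest member read of each cluster, the cluster-representative consensus
read (crCCS read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .seqcore import NucSequence, global_identity


@dataclass
class UniqueSeq:
    """One distinct sequence string and the reads that carry it."""

    bases: str
    member_ids: list[str]

    @property
    def abundance(self) -> int:
        return len(self.member_ids)


@dataclass
class Cluster:
    """A centroid-founded cluster; identity of members is to the centroid."""

    cluster_id: int
    centroid: UniqueSeq
    members: list[UniqueSeq] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)

    @property
    def read_count(self) -> int:
        return sum(u.abundance for u in self.members)

    def member_read_ids(self) -> list[str]:
        return [rid for u in self.members for rid in u.member_ids]


def dereplicate(reads: Sequence[NucSequence]) -> list[UniqueSeq]:
    """Exact-string grouping, sorted by descending abundance.

    Ties are broken by descending length, then by the smallest member read
    id, making the downstream greedy scan deterministic.
    """
    groups: dict[str, list[str]] = {}
    for read in reads:
        groups.setdefault(read.bases, []).append(read.id)
    uniques = [UniqueSeq(bases, sorted(ids)) for bases, ids in groups.items()]
    uniques.sort(key=lambda u: (-u.abundance, -len(u.bases), u.member_ids[0]))
    return uniques


def greedy_cluster(
    uniques: Sequence[UniqueSeq], min_identity: float = 0.97
) -> list[Cluster]:
    """Greedy centroid clustering at a minimum global identity.

    The input must already be sorted as :func:`dereplicate` produces it; the
    result is then deterministic.  ``min_identity = 1.0`` yields one cluster
    per unique sequence.
    """
    clusters: list[Cluster] = []
    for unique in uniques:
        placed = False
        for cluster in clusters:
            a, b = unique.bases, cluster.centroid.bases
            # A length difference alone bounds identity from above; skip the
            # alignment when even a perfect overlap could not reach the bar.
            if min(len(a), len(b)) < min_identity * max(len(a), len(b)):
                continue
            ident = global_identity(a, b)
            if ident >= min_identity:
                cluster.members.append(unique)
                cluster.identities.append(ident)
                placed = True
                break
        if not placed:
            cluster = Cluster(cluster_id=len(clusters) + 1, centroid=unique)
            cluster.members.append(unique)
            cluster.identities.append(1.0)
            clusters.append(cluster)
    return clusters


def representative(
    cluster: Cluster, reads_by_id: Mapping[str, NucSequence]
) -> NucSequence:
    """The longest member read of a cluster (smallest id on ties) — the crCCS read."""
    if not cluster.members:
        raise ValueError("empty cluster has no representative")
    ids = cluster.member_read_ids()
    best_id = min(ids, key=lambda rid: (-len(reads_by_id[rid]), rid))
    return reads_by_id[best_id]


def membership_table(
    clusters: Iterable[Cluster], reads_by_id: Mapping[str, NucSequence]
) -> str:
    """TSV of cluster membership with roles and identities to the centroid."""
    lines = ["cluster_id\tread_id\trole\tidentity_to_centroid"]
    for cluster in clusters:
        rep_id = representative(cluster, reads_by_id).id
        for unique, ident in zip(cluster.members, cluster.identities):
            for rid in unique.member_ids:
                roles = []
                if unique is cluster.centroid:
                    roles.append("centroid")
                if rid == rep_id:
                    roles.append("representative")
                if not roles:
                    roles.append("member")
                lines.append(f"{cluster.cluster_id}\t{rid}\t{','.join(roles)}\t{ident:.4f}")
    return "\n".join(lines) + "\n"
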