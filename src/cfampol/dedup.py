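"""Sequence clustering and nonredundant genome selection.

Two genomes collapse into one only when they encode the same number of
C-family polymerases and those polymerases can be matched one-to-one at
>90% identity; genomes with differing polymerase counts are always both
kept.  Multi-way redundancy is resolved through connected components of
the pairwise-equivalence graph, with the lexicographically smallest
genome id surviving.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GenomeRecord, ProteinRecord
from .profiles import kmer_identity_screen, pairwise_identity


@dataclass(frozen=True)
class ClusterAssignment:
    representative_id: str
    member_ids: tuple[str, ...]
    identity_threshold: float

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("representative must be a member of its cluster")


def cluster_sequences(
    seqs: Mapping[str, str], threshold: float = 0.90
) -> list[ClusterAssignment]:
    """Greedy incremental identity clustering (CD-HIT style).

    Sequences are processed longest first (ties broken by id); each joins
    the first existing cluster whose representative it matches at strictly
    greater than ``threshold`` identity, otherwise it founds a new cluster.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for sid in order:
        placed = False
        for rep in reps:
            if not kmer_identity_screen(seqs[sid], seqs[rep]):
                continue
            if pairwise_identity(seqs[sid], seqs[rep]) > threshold:
                members[rep].append(sid)
                placed = True
                break
        if not placed:
            reps.append(sid)
            members[sid] = [sid]
    return [
        ClusterAssignment(rep, tuple(members[rep]), threshold) for rep in reps
    ]


def _genomes_equivalent(
    pols_a: Sequence[ProteinRecord],
    pols_b: Sequence[ProteinRecord],
    threshold: float,
) -> bool:
    """Count-preserving greedy best-identity matching, all pairs > threshold."""
    if len(pols_a) != len(pols_b):
        return False
    if not pols_a:
        return True
    pairs: list[tuple[float, int, int]] = []
    for i, a in enumerate(pols_a):
        for j, b in enumerate(pols_b):
            if not kmer_identity_screen(a.sequence, b.sequence):
                continue
            pairs.append((pairwise_identity(a.sequence, b.sequence), i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = 0
    for ident, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        if ident <= threshold:
            break
        used_a.add(i)
        used_b.add(j)
        matched += 1
    return matched == len(pols_a)


def select_nonredundant_genomes(
    genomes: Iterable[GenomeRecord],
    pols: Mapping[str, Sequence[ProteinRecord]],
    threshold: float = 0.90,
) -> list[str]:
    """Pick the nonredundant genome set.

    Returns the surviving genome ids in ascending order.  Equivalence is
    evaluated pairwise over genomes with equal polymerase counts; collapse
    groups are the connected components of the equivalence graph and the
    lexicographically smallest member survives.
    """
    recs = {g.genome_id: g for g in genomes}
    for gid in pols:
        if gid not in recs:
            raise KeyError(f"genome id {gid!r} in polymerase map but not in genome set")
    ids = sorted(recs)
    parent = {gid: gid for gid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            if ry < rx:
                rx, ry = ry, rx
            parent[ry] = rx

    by_count: dict[int, list[str]] = {}
    for gid in ids:
        by_count.setdefault(len(pols.get(gid, ())), []).append(gid)
    for _, group in sorted(by_count.items()):
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if find(a) == find(b):
                    continue
                if _genomes_equivalent(pols.get(a, ()), pols.get(b, ()), threshold):
                    union(a, b)
    survivors = sorted({find(gid) for gid in ids})
    return survivors


def dedup_report(
    genomes: Iterable[GenomeRecord],
    pols: Mapping[str, Sequence[ProteinRecord]],
    path: str | Path | None = None,
    threshold: float = 0.90,
) -> pd.DataFrame:
    """TSV-ready report: genome_id, kept flag, representative genome id."""
    recs = sorted(g.genome_id for g in genomes)
    genomes = list(genomes)
    survivors = set(select_nonredundant_genomes(genomes, pols, threshold))
    rep_of: dict[str, str] = {}
    # recompute components to attribute members to their representative
    remaining = {g.genome_id: g for g in genomes}
    for gid in recs:
        if gid in survivors:
            rep_of[gid] = gid
    for gid in recs:
        if gid in rep_of:
            continue
        for rep in sorted(survivors):
            if len(pols.get(gid, ())) == len(pols.get(rep, ())) and _genomes_equivalent(
                pols.get(gid, ()), pols.get(rep, ()), threshold
            ):
                rep_of[gid] = rep
                break
        else:
            rep_of[gid] = gid
    df = pd.DataFrame(
        {
            "genome_id": recs,
            "kept": [gid in survivors for gid in recs],
            "representative": [rep_of[gid] for gid in recs],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
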