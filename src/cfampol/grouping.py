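"""Polymerase group classification and the phylogenetic tie-breaker.

Each polymerase is classified into PolC, DnaE1, DnaE2, DnaE3 or the
DnaEX fallback from its feature vector.  Architecture has precedence
(PolC is architecture-defined: OB upstream of PHP, an NTD, or the Exo
insertion); the DnaE groups are separated by the C-terminal domain, the
beta-clamp motif class, the PHP metal-site state and the DnaE2 tail
motif.  Ambiguous sequences fall back to DnaEX and can be resolved by
their placement relative to anchor sequences in a neighbor-joining tree
with bootstrap supports: the smallest clade with >50% support and
unanimous anchors decides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .motifs import MotifReport

GROUPS = ("PolC", "DnaE1", "DnaE2", "DnaE3", "DnaEX")
OB_POSITIONS = ("upstream_of_PHP", "downstream_of_HhH", "absent")

#: Kimura's protein-distance correction diverges as p approaches ~0.8541;
#: larger observed differences are clamped to this distance.
_MAX_DISTANCE = 10.0


@dataclass(frozen=True)
class FeatureVector:
    has_NTD: bool
    has_CTD: bool
    exo_inserted: bool
    exo_nterminal: bool
    ob_position: str
    clamp_class: str
    php_intact: bool
    ctail_motif: bool
    core_length: int
    core_pI: float

    def __post_init__(self) -> None:
        if self.ob_position not in OB_POSITIONS:
            raise ValueError(f"unknown OB position {self.ob_position!r}")


@dataclass(frozen=True)
class GroupCall:
    label: str
    confidence: str  # rule | clade | fallback
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.label not in GROUPS:
            raise ValueError(f"unknown group {self.label!r}")
        if self.confidence not in ("rule", "clade", "fallback"):
            raise ValueError(f"unknown confidence {self.confidence!r}")
        if not self.evidence:
            raise ValueError("evidence must be non-empty")


def extract_features(
    arch, motif_report: MotifReport, core_length: int, core_pI: float
) -> FeatureVector:
    """Package upstream annotations into the classification features."""
    domains = [h.domain for h in arch.hits if not h.nested_in]
    starts: dict[str, int] = {}
    for h in arch.hits:
        starts[h.domain] = min(starts.get(h.domain, h.start), h.start)
    exo_inserted = any(h.domain == "Exo" and h.nested_in == "PHP" for h in arch.hits)
    exo_nterminal = (
        "Exo" in starts
        and not exo_inserted
        and "PHP" in starts
        and starts["Exo"] < starts["PHP"]
    )
    ob_position = "absent"
    if "OB" in starts:
        if "PHP" in starts and starts["OB"] < starts["PHP"]:
            ob_position = "upstream_of_PHP"
        else:
            ob_position = "downstream_of_HhH"
    return FeatureVector(
        has_NTD="NTD" in domains,
        has_CTD="CTD" in domains,
        exo_inserted=exo_inserted,
        exo_nterminal=exo_nterminal,
        ob_position=ob_position,
        clamp_class=motif_report.clamp_class,
        php_intact=motif_report.php_intact,
        ctail_motif=motif_report.ctail_motif,
        core_length=core_length,
        core_pI=core_pI,
    )


def classify_group(f: FeatureVector) -> GroupCall:
    """Rule-based group call; total and deterministic.

    Ordered rules: (1) PolC architecture marks; (2) missing CTD plus a
    DnaE2 hallmark (tail motif or proline-type clamp motif); (3) intact
    PHP metal site plus a canonical clamp motif, or the
    disrupted-PHP-but-strong-motif DnaE1 exception seen in
    proteobacteria-like sequences; (4) disrupted PHP with a weak or
    absent clamp motif; (5) DnaEX fallback for conflicting evidence,
    resolvable by clade assignment when a tree is available.
    """
    if f.ob_position == "upstream_of_PHP" or f.has_NTD or f.exo_inserted:
        return GroupCall("PolC", "rule", ("polc_architecture",))
    if not f.has_CTD and (f.ctail_motif or f.clamp_class == "dnae2_type"):
        ev = ["no_ctd"]
        if f.ctail_motif:
            ev.append("srdf_tail")
        if f.clamp_class == "dnae2_type":
            ev.append("dnae2_clamp_motif")
        return GroupCall("DnaE2", "rule", tuple(ev))
    if f.php_intact and f.clamp_class in ("canonical", "canonical_strong"):
        return GroupCall("DnaE1", "rule", ("php_intact", "canonical_clamp"))
    if not f.php_intact and f.clamp_class == "canonical_strong" and f.has_CTD:
        return GroupCall(
            "DnaE1", "rule", ("php_disrupted_exception", "strong_clamp", "ctd")
        )
    if not f.php_intact and f.clamp_class in ("weak", "none"):
        return GroupCall("DnaE3", "rule", ("php_disrupted", "weak_or_absent_clamp"))
    return GroupCall("DnaEX", "fallback", ("no_rule_fired",))


def nj_tree(distances: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths clamped to zero."""
    if not isinstance(distances, DistanceMatrix):
        distances = np.asarray(distances, dtype=float)
        if (
            distances.ndim != 2
            or distances.shape[0] != distances.shape[1]
            or not np.allclose(distances, distances.T)
            or not np.allclose(np.diag(distances), 0.0)
        ):
            raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
        distances = DistanceMatrix(distances, ids=ids)
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    tree = nj(distances)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def kimura_distance_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Kimura-corrected protein distances from an aligned sequence set."""
    ids = list(alignment)
    n = len(ids)
    encoded = np.array([list(alignment[i]) for i in ids])
    valid = encoded != "-"
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            if total == 0:
                d = _MAX_DISTANCE
            else:
                p = float((encoded[i][both] != encoded[j][both]).mean())
                d = _kimura(p)
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=ids)


def _kimura(p: float) -> float:
    arg = 1.0 - p - 0.2 * p * p
    if arg <= np.exp(-_MAX_DISTANCE):
        return _MAX_DISTANCE
    return float(-np.log(arg))


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions; zero-length internal edges are
    treated as unresolved (collapsed) and contribute no split."""
    leaves = frozenset(leaf.name for leaf in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        if (node.length or 0.0) <= 1e-12:
            continue
        clade = frozenset(leaf.name for leaf in node.tips())
        if 1 < len(clade) < len(leaves) - 1:
            # canonicalise: store the side not containing the alphabetical
            # minimum so each split has one representation
            other = leaves - clade
            parts.add(clade if min(clade) > min(other) else other)
    return parts


def _clade_key(node: TreeNode, all_leaves: frozenset[str]) -> frozenset[str]:
    clade = frozenset(leaf.name for leaf in node.tips())
    other = all_leaves - clade
    return clade if min(clade) > min(other) else other


def bootstrap_support(
    core_alignment: Mapping[str, str],
    n_reps: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with bootstrap clade supports.

    Columns are resampled with replacement; distances use the Kimura
    protein correction; each internal edge's support is the fraction of
    replicate trees containing the same leaf bipartition, stored on the
    node as ``node.support`` in [0, 1].  Deterministic per seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ids = list(core_alignment)
    length = len(next(iter(core_alignment.values())))
    if any(len(core_alignment[i]) != length for i in ids):
        raise ValueError("core alignment sequences must have equal length")
    tree = nj_tree(kimura_distance_matrix(core_alignment))
    rng = np.random.default_rng(seed)
    matrix = np.array([list(core_alignment[i]) for i in ids])
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = {ids[k]: "".join(matrix[k][cols]) for k in range(len(ids))}
        try:
            rep_tree = nj_tree(kimura_distance_matrix(resampled))
        except ValueError:
            continue
        for part in _bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    all_leaves = frozenset(ids)
    for node in tree.non_tips(include_self=False):
        if (node.length or 0.0) <= 1e-12:
            node.support = 0.0
            continue
        key = _clade_key(node, all_leaves)
        node.support = counts.get(key, 0) / n_reps
    return tree


def assign_by_clade(
    tree: TreeNode, anchors: Mapping[str, str], query: str
) -> str | None:
    """Group of the smallest supported clade containing the query.

    Clades are evaluated as bipartitions, so the (arbitrary) rooting of
    the NJ tree does not matter: among all splits with bootstrap support
    > 0.5, the smallest side that contains the query together with at
    least one anchor decides — its group if the contained anchors are
    unanimous, otherwise no assignment.  Anchor-free sides are skipped.
    """
    leaves = frozenset(tip.name for tip in tree.tips())
    if query not in leaves:
        raise KeyError(f"query {query!r} not in tree")
    candidates: list[tuple[int, tuple[str, ...], set[str]]] = []
    for node in tree.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is None or support <= 0.5:
            continue
        clade = frozenset(tip.name for tip in node.tips())
        side = clade if query in clade else leaves - clade
        labels = {anchors[name] for name in side if name in anchors}
        if not labels:
            continue
        candidates.append((len(side), tuple(sorted(side)), labels))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1]))
    labels = candidates[0][2]
    return labels.pop() if len(labels) == 1 else None


def tree_to_newick(tree: TreeNode) -> str:
    """Newick string with bootstrap supports as internal node labels."""
    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None:
            node.name = f"{support:.2f}"
    return str(clone)
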