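"""Per-genome polymerase combinations and cohort statistics.

Combination labels follow the canonical group order (PolC, DnaE1, DnaE3,
DnaE2, DnaEX) with multiplicity rendered as "2x"; cohort tabulations
report one-decimal percentages (round half up, matching the printed
style of published combination tables).  Trait-binned fractions and
Spearman rank correlations connect polymerase repertoires to genome
size, GC content and oxygen use.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io import GenomeRecord

COMBINATION_ORDER = ("PolC", "DnaE1", "DnaE3", "DnaE2", "DnaEX")

#: collapsed classes used for trait-binned fraction plots
COMBINATION_CLASSES = (
    "DnaE1 only",
    "DnaE1 + DnaE2",
    "PolC + DnaE3",
    "PolC + DnaE1",
    "other",
)


@dataclass(frozen=True)
class GenomeProfile:
    genome_id: str
    group_counts: Mapping[str, int]

    @property
    def combination_label(self) -> str:
        return combination_label(self.group_counts)


@dataclass(frozen=True)
class StatsResult:
    rho: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("rho outside [-1, 1]")


def combination_label(group_counts: Mapping[str, int]) -> str:
    """Canonical combination string, e.g. ``"DnaE1 + 2xDnaE2"``."""
    parts = []
    for group in COMBINATION_ORDER:
        count = int(group_counts.get(group, 0))
        if count < 0:
            raise ValueError("group counts must be >= 0")
        if count == 1:
            parts.append(group)
        elif count > 1:
            parts.append(f"{count}x{group}")
    return " + ".join(parts) if parts else "none"


def round_half_up(value: float, decimals: int = 1) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def tabulate_combinations(profiles: Iterable[GenomeProfile]) -> pd.DataFrame:
    """Count and percentage per combination label, most frequent first."""
    labels = [p.combination_label for p in profiles]
    if not labels:
        raise ValueError("at least one genome profile is required")
    series = pd.Series(labels).value_counts()
    total = len(labels)
    return pd.DataFrame(
        {
            "combination": series.index,
            "count": series.values,
            "percent": [round_half_up(100.0 * c / total) for c in series.values],
        }
    )


def collapse_combination(label: str) -> str:
    """Map a combination label to the coarse class used in trait plots."""
    if label == "DnaE1":
        return "DnaE1 only"
    groups = {part.split("x")[-1] for part in label.split(" + ")}
    if groups == {"DnaE1", "DnaE2"}:
        return "DnaE1 + DnaE2"
    if groups == {"PolC", "DnaE3"}:
        return "PolC + DnaE3"
    if groups == {"PolC", "DnaE1"}:
        return "PolC + DnaE1"
    return "other"


def binned_fractions(
    genomes: Mapping[str, GenomeRecord],
    profiles: Iterable[GenomeProfile],
    trait: str,
    edges: Sequence[float],
) -> pd.DataFrame:
    """Per-bin fractions of collapsed combination classes along a trait.

    ``trait`` is ``size_bp`` or ``gc_percent``; ``edges`` are strictly
    increasing bin edges.  Fractions in occupied bins sum to 1; empty
    bins are flagged and carry NaN fractions.
    """
    if trait not in ("size_bp", "gc_percent"):
        raise ValueError("trait must be size_bp or gc_percent")
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])) or len(edges) < 2:
        raise ValueError("edges must be strictly increasing, at least two")
    rows = []
    classes = {
        p.genome_id: collapse_combination(p.combination_label) for p in profiles
    }
    values = {gid: getattr(genomes[gid], trait) for gid in classes if gid in genomes}
    for lo, hi in zip(edges, edges[1:]):
        members = [gid for gid, v in values.items() if lo <= v < hi]
        row: dict[str, object] = {
            "bin_left": lo,
            "bin_right": hi,
            "n": len(members),
            "empty": not members,
        }
        for cls in COMBINATION_CLASSES:
            if members:
                row[cls] = sum(1 for gid in members if classes[gid] == cls) / len(members)
            else:
                row[cls] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def oxygen_breakdown(
    genomes: Mapping[str, GenomeRecord], profiles: Iterable[GenomeProfile]
) -> pd.DataFrame:
    """Per-combination-class fractions of oxygen-using vs anaerobic genomes.

    Aerobes, facultative aerobes and microaerophiles count as oxygen
    using; unannotated genomes are reported separately.
    """

    def category(oxygen_class: str) -> str:
        if oxygen_class in ("aerobe", "facultative", "microaerophile"):
            return "oxygen_using"
        if oxygen_class == "anaerobe":
            return "anaerobe"
        return "unknown"

    rows: dict[str, dict[str, int]] = {}
    for p in profiles:
        genome = genomes.get(p.genome_id)
        if genome is None:
            continue
        cls = collapse_combination(p.combination_label)
        rows.setdefault(cls, {"oxygen_using": 0, "anaerobe": 0, "unknown": 0})
        rows[cls][category(genome.oxygen_class)] += 1
    out = []
    for cls, counts in rows.items():
        total = sum(counts.values())
        out.append(
            {
                "combination_class": cls,
                "n": total,
                "oxygen_using": counts["oxygen_using"] / total,
                "anaerobe": counts["anaerobe"] / total,
                "unknown": counts["unknown"] / total,
            }
        )
    return pd.DataFrame(out)


def spearman(x: Sequence[float], y: Sequence[float]) -> StatsResult:
    """Tie-corrected Spearman rank correlation (average ranks)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 observations required")
    rho = float(sp_stats.spearmanr(x, y).statistic)
    return StatsResult(rho=rho, n=int(x.size))
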