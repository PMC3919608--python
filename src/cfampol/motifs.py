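"""Functional motif extraction and classification.

Covered motifs: the polymerase active-site aspartate triad (reference
columns corresponding to E. coli D401/D403/D555), the nine
metal-coordinating positions of the PHP domain, the beta-clamp binding
pentapeptide downstream of the (HhH)2 motif (consensus QL[S/D]LF), and
the DnaE2-specific SRDF[H/R] tail at the extreme C-terminus.  Logo-style
position frequency matrices are emitted as plain tables.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import CoreMap, DomainArchitecture
from .io import AMINO_ACIDS, ProteinRecord

CLAMP_CLASSES = ("canonical_strong", "canonical", "weak", "dnae2_type", "none")

#: ranking used when several window pentapeptides classify differently
_CLASS_PRIORITY = {
    "canonical_strong": 4,
    "canonical": 3,
    "dnae2_type": 2,
    "weak": 1,
    "none": 0,
}

CLAMP_WINDOW_CAP = 200
CTAIL_WINDOW = 15

_CTAIL_RE = re.compile(r"SRDF[HR]")


@dataclass(frozen=True)
class SiteConfig:
    """Reference-column configuration for the active site and PHP metal site.

    Columns are 1-based positions on the reference core.  The per-group
    consensus maps each group label to the set of residues accepted at
    each of the nine PHP metal-coordinating positions.
    """

    active_site_columns: tuple[int, int, int]
    php_site_columns: tuple[int, ...]
    php_consensus: Mapping[str, tuple[frozenset[str], ...]]

    def __post_init__(self) -> None:
        if list(self.active_site_columns) != sorted(self.active_site_columns):
            raise ValueError("active-site columns must be strictly increasing")
        if list(self.php_site_columns) != sorted(self.php_site_columns):
            raise ValueError("PHP site columns must be strictly increasing")
        if len(self.php_site_columns) != 9:
            raise ValueError("exactly nine PHP metal-site columns are required")
        for group, sets in self.php_consensus.items():
            if len(sets) != 9 or any(not s for s in sets):
                raise ValueError(f"group {group!r}: nine non-empty consensus sets required")

    def to_json(self) -> str:
        return json.dumps(
            {
                "active_site_columns": list(self.active_site_columns),
                "php_site_columns": list(self.php_site_columns),
                "php_consensus": {
                    g: ["".join(sorted(s)) for s in sets]
                    for g, sets in self.php_consensus.items()
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SiteConfig":
        data = json.loads(text)
        return cls(
            active_site_columns=tuple(data["active_site_columns"]),
            php_site_columns=tuple(data["php_site_columns"]),
            php_consensus={
                g: tuple(frozenset(s) for s in sets)
                for g, sets in data["php_consensus"].items()
            },
        )


@dataclass(frozen=True)
class MotifReport:
    protein_id: str
    clamp_motif: str | None
    clamp_class: str
    clamp_position: tuple[int, int] | None
    clamp_window_fallback: bool
    hda_like: bool
    php_score: int
    php_intact: bool
    active_site_intact: bool
    ctail_motif: bool

    def __post_init__(self) -> None:
        if self.clamp_class not in CLAMP_CLASSES:
            raise ValueError(f"unknown clamp class {self.clamp_class!r}")
        if not 0 <= self.php_score <= 9:
            raise ValueError("php_score must be within 0..9")


def check_active_site(core_map: CoreMap, rec: ProteinRecord, cfg: SiteConfig) -> bool:
    """True iff all three active-site columns map to aspartate.

    An unmapped column (deleted in the protein) counts as absent.
    """
    for col in cfg.active_site_columns:
        pos = core_map.column_map.get(col)
        if pos is None or rec.sequence[pos] != "D":
            return False
    return True


def score_php_site(
    core_map: CoreMap,
    rec: ProteinRecord,
    cfg: SiteConfig,
    group_consensus: str = "canonical",
) -> tuple[int, bool]:
    """Count PHP metal-site positions matching the group consensus.

    The site is considered intact when at least eight of the nine
    positions carry a consensus residue.
    """
    sets = cfg.php_consensus.get(group_consensus)
    if sets is None:
        raise KeyError(f"no consensus configured for group {group_consensus!r}")
    score = 0
    for col, allowed in zip(cfg.php_site_columns, sets):
        pos = core_map.column_map.get(col)
        if pos is not None and rec.sequence[pos] in allowed:
            score += 1
    return score, score >= 8


def classify_clamp_motif(pentapeptide: str) -> str:
    """Classify a pentapeptide into the beta-clamp motif classes.

    Positions 4 and 5 must be L and F/L for any motif class; position 1
    then separates canonical (Q) from the proline-marked DnaE2 type, with
    S/D at position 3 upgrading canonical to canonical_strong.
    """
    p = pentapeptide.upper()
    if len(p) != 5:
        raise ValueError("pentapeptide must have length 5")
    if p[3] != "L" or p[4] not in "FL":
        return "none"
    if p[0] == "Q":
        return "canonical_strong" if p[2] in "SD" else "canonical"
    if p[0] == "P" or p[2] == "P":
        return "dnae2_type"
    return "weak"


def _pfm_log_score(penta: str, pfm: pd.DataFrame) -> float:
    score = 0.0
    for i, aa in enumerate(penta):
        freq = float(pfm.iloc[i].get(aa, 0.0)) if aa in pfm.columns else 0.0
        score += np.log2(max(freq, 1e-3) / 0.05)
    return score


def find_clamp_motif(
    rec: ProteinRecord,
    arch: DomainArchitecture,
    class_pfms: Mapping[str, pd.DataFrame] | None = None,
) -> tuple[str, str, tuple[int, int], bool, bool] | None:
    """Locate the best beta-clamp binding pentapeptide.

    The search window runs from the end of the (HhH)2 hit to the start of
    the next assigned domain (or the sequence end), capped at 200
    residues.  Without an HhH hit the final 200 residues are searched and
    the report is flagged as a fallback.  Returns ``(pentapeptide,
    class, (start, end), fallback_flag, hda_like_flag)`` or ``None``.
    """
    seq = rec.sequence
    fallback = False
    hhh = next((h for h in arch.hits if h.domain == "HhH"), None)
    if hhh is None:
        w_start = max(0, len(seq) - CLAMP_WINDOW_CAP)
        w_end = len(seq)
        fallback = True
    else:
        w_start = hhh.end
        nxt = min(
            (h.start for h in arch.hits if h.start >= hhh.end and h.domain != "HhH"),
            default=len(seq),
        )
        w_end = min(nxt, w_start + CLAMP_WINDOW_CAP)
    best: tuple[int, float, int, str, str] | None = None
    for i in range(w_start, w_end - 4):
        penta = seq[i : i + 5]
        cls = classify_clamp_motif(penta)
        if cls == "none":
            continue
        pfm_score = 0.0
        if class_pfms and cls in class_pfms:
            pfm_score = _pfm_log_score(penta, class_pfms[cls])
        key = (_CLASS_PRIORITY[cls], pfm_score, -i, penta, cls)
        if best is None or key > best:
            best = key
    if best is None:
        return None
    _, _, neg_i, penta, cls = best
    i = -neg_i
    hda_like = penta.startswith("QLPL") and i + 5 < len(seq) and seq[i + 5] == "L"
    return penta, cls, (i, i + 5), fallback, hda_like


def find_ctail_motif(rec: ProteinRecord | str) -> bool:
    """True iff SRDF[H/R] occurs entirely within the final 15 residues."""
    seq = rec.sequence if isinstance(rec, ProteinRecord) else rec
    return bool(_CTAIL_RE.search(seq[-CTAIL_WINDOW:]))


def position_frequency_matrix(
    instances: Sequence[str], allow_gap: bool = False
) -> pd.DataFrame:
    """Per-position residue frequencies of equal-length motif instances.

    Rows are motif positions; columns are the 20 amino acids plus the gap
    character.  Every row sums to 1 (including the gap fraction).
    """
    if not instances:
        raise ValueError("at least one motif instance is required")
    length = len(instances[0])
    if any(len(s) != length for s in instances):
        raise ValueError("motif instances must have equal length")
    columns = list(AMINO_ACIDS) + ["-"]
    counts = np.zeros((length, len(columns)))
    index = {c: i for i, c in enumerate(columns)}
    for s in instances:
        for pos, c in enumerate(s.upper()):
            if c == "-" and not allow_gap:
                raise ValueError("gap characters present but allow_gap is False")
            counts[pos, index.get(c, index["-"])] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freqs, columns=columns, index=range(1, length + 1))


def build_motif_report(
    rec: ProteinRecord,
    arch: DomainArchitecture,
    core_map: CoreMap,
    cfg: SiteConfig,
    group_consensus: str = "canonical",
    class_pfms: Mapping[str, pd.DataFrame] | None = None,
) -> MotifReport:
    """Assemble the per-protein motif summary used for group classification."""
    clamp = find_clamp_motif(rec, arch, class_pfms)
    if clamp is None:
        motif, cls, pos, fallback, hda = None, "none", None, False, False
    else:
        motif, cls, pos, fallback, hda = clamp
    php_score, php_intact = score_php_site(core_map, rec, cfg, group_consensus)
    return MotifReport(
        protein_id=rec.protein_id,
        clamp_motif=motif,
        clamp_class=cls,
        clamp_position=pos,
        clamp_window_fallback=fallback,
        hda_like=hda,
        php_score=php_score,
        php_intact=php_intact,
        active_site_intact=check_active_site(core_map, rec, cfg),
        ctail_motif=find_ctail_motif(rec),
    )


def motif_reports_to_tsv(reports: Iterable[MotifReport], path) -> None:
    rows = []
    for r in reports:
        rows.append(
            {
                "protein_id": r.protein_id,
                "clamp_motif": r.clamp_motif or "",
                "clamp_class": r.clamp_class,
                "clamp_start": r.clamp_position[0] if r.clamp_position else "",
                "clamp_end": r.clamp_position[1] if r.clamp_position else "",
                "hda_like": r.hda_like,
                "php_score": r.php_score,
                "php_intact": r.php_intact,
                "active_site_intact": r.active_site_intact,
                "ctail_motif": r.ctail_motif,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
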