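"""Structural-domain assignment and architecture strings.

Each protein is scanned with per-domain profiles (PHP, Pol3, HhH, OB,
CTD, NTD, Exo, UDG, Lar).  Overlapping hits are resolved by bit score,
except the PolC hallmark of an exonuclease domain nested inside the PHP
span, which is rendered as an insertion ("PHP(Exo)").  Poorly conserved
terminal domains missed by the direct scan are recovered by a gradual
extension of a terminal query fragment, accepted only when the
calibrated assignment probability is >= 0.90 for one domain and <= 0.30
for all others.  The universally conserved PHP-Pol3-(HhH)2 core is
extracted through a column-level coordinate map onto the reference core.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import ProteinRecord
from .profiles import (
    ProfileCalibration,
    ProfileHit,
    ProfileMatrix,
    calibrate_profile,
    scan_sequence,
)

DOMAIN_TYPES = ("PHP", "Pol3", "HhH", "OB", "CTD", "NTD", "Exo", "UDG", "Lar")

#: fraction of the shorter hit two hits may overlap before conflicting
OVERLAP_TOLERANCE = 0.30
#: maximal linker between an N-terminal Exo hit and the PHP start
EXO_NTERM_MAX_GAP = 100
#: unassigned spans at least this long are reported
MIN_UNASSIGNED_SPAN = 50

# logistic calibration of the terminal-scan assignment probability:
# probability = sigmoid((z - _PROB_Z0) / _PROB_SCALE) on the null z-score,
# chosen so random terminal spans score < 0.05 while genuinely homologous
# (if diverged) domains saturate towards 1.
_PROB_Z0 = 8.0
_PROB_SCALE = 1.2


@dataclass(frozen=True)
class DomainHit:
    domain: str
    start: int
    end: int
    bit_score: float
    empirical_p: float
    assignment_prob: float = float("nan")
    nested_in: str | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_TYPES:
            raise ValueError(f"unknown domain {self.domain!r}")
        if not self.start < self.end:
            raise ValueError("domain hit start must be < end")


@dataclass(frozen=True)
class DomainArchitecture:
    protein_id: str
    tokens: tuple[str, ...]
    hits: tuple[DomainHit, ...]
    unassigned_spans: tuple[tuple[int, int], ...] = ()

    @property
    def string(self) -> str:
        return "-".join(self.tokens) if self.tokens else "(none)"

    def domain_set(self) -> set[str]:
        out: set[str] = set()
        for tok in self.tokens:
            out.add(tok.split("(")[0])
            if "(" in tok:
                out.add(tok[tok.index("(") + 1 : tok.index(")")])
        return out


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _nested(inner: DomainHit, outer: DomainHit, containment: float = 0.9) -> bool:
    """True when at least ``containment`` of the inner hit lies inside the outer."""
    return _overlap(inner, outer) >= containment * (inner.end - inner.start)


def assign_domains(
    rec: ProteinRecord,
    domain_profiles: Mapping[str, ProfileMatrix],
    p_threshold: float = 1e-3,
    min_identity: float = 0.10,
    calibrations: Mapping[str, ProfileCalibration] | None = None,
    seed: int = 0,
) -> list[DomainHit]:
    """Scan all domain profiles and resolve overlaps.

    Hits must be significant at ``p_threshold`` and show at least
    ``min_identity`` identity to the profile consensus over the aligned
    columns.  Non-nested overlaps exceeding 30% of the shorter hit keep
    only the higher-scoring hit; an Exo hit nested within a PHP hit is
    retained and flagged as an insertion.
    """
    if calibrations is None:
        calibrations = {
            name: calibrate_profile(prof, seed=seed)
            for name, prof in domain_profiles.items()
        }
    raw: list[DomainHit] = []
    for name, prof in domain_profiles.items():
        cal = calibrations[name]
        # iterative masked re-scanning so repeated copies of a domain
        # (tandem duplications, concatenated architectures) are all found
        masked = rec.sequence
        for _ in range(5):
            hit = scan_sequence(prof, masked)
            if hit is None:
                break
            p = cal.pvalue(hit.bit_score, len(rec.sequence))
            if p > p_threshold:
                break
            masked = masked[: hit.start] + "X" * (hit.end - hit.start) + masked[hit.end :]
            if np.isfinite(hit.identity) and hit.identity < min_identity:
                continue
            raw.append(
                DomainHit(
                    domain=name,
                    start=hit.start,
                    end=hit.end,
                    bit_score=hit.bit_score,
                    empirical_p=p,
                )
            )
    raw.sort(key=lambda h: -h.bit_score)
    kept: list[DomainHit] = []
    for cand in raw:
        conflict = False
        for prev in kept:
            ov = _overlap(cand, prev)
            if ov == 0:
                continue
            pair = {cand.domain, prev.domain}
            if pair == {"Exo", "PHP"}:
                inner, outer = (cand, prev) if cand.domain == "Exo" else (prev, cand)
                if _nested(inner, outer):
                    continue
            if ov > OVERLAP_TOLERANCE * min(cand.end - cand.start, prev.end - prev.start):
                conflict = True
                break
        if not conflict:
            kept.append(cand)
    # flag the PolC-style exonuclease insertion after conflict resolution
    php_hits = [h for h in kept if h.domain == "PHP"]
    for i, h in enumerate(kept):
        if h.domain == "Exo" and any(_nested(h, php) for php in php_hits):
            kept[i] = DomainHit(
                domain=h.domain,
                start=h.start,
                end=h.end,
                bit_score=h.bit_score,
                empirical_p=h.empirical_p,
                nested_in="PHP",
            )
    kept.sort(key=lambda h: h.start)
    return kept


def terminal_extension_scan(
    rec: ProteinRecord,
    unassigned_terminal_span: tuple[int, int],
    candidate_profiles: Mapping[str, ProfileMatrix],
    calibrations: Mapping[str, ProfileCalibration] | None = None,
    initial: int = 50,
    step: int = 25,
    accept_prob: float = 0.90,
    reject_prob: float = 0.30,
    seed: int = 0,
) -> DomainHit | None:
    """Recover a diverged terminal domain by gradual query extension.

    Starting from the terminal ``initial`` residues of the unassigned
    span (the whole span if shorter) the query grows inward in ``step``
    increments up to the span boundary.  At each length the assignment
    probability of every candidate profile is evaluated; a hit is
    accepted only when exactly one domain reaches ``accept_prob`` while
    all other candidates stay at or below ``reject_prob``.
    """
    start, end = unassigned_terminal_span
    n = len(rec.sequence)
    if not (0 <= start < end <= n):
        raise ValueError("span out of range")
    if start != 0 and end != n:
        raise ValueError("span must touch a sequence terminus")
    if calibrations is None:
        calibrations = {
            name: calibrate_profile(prof, seed=seed)
            for name, prof in candidate_profiles.items()
        }
    n_span = end - start
    at_nterm = start == 0
    length = min(initial, n_span)
    while True:
        if at_nterm:
            q_start, q_end = end - length, end
        else:
            q_start, q_end = start, start + length
        query = rec.sequence[q_start:q_end]
        scored: list[tuple[float, str, ProfileHit | None]] = []
        for name, prof in candidate_profiles.items():
            hit = scan_sequence(prof, query)
            prob = (
                assignment_probability(hit.bit_score, len(query), calibrations[name])
                if hit is not None
                else 0.0
            )
            scored.append((prob, name, hit))
        scored.sort(key=lambda t: -t[0])
        prob, name, hit = scored[0]
        runner_up = scored[1][0] if len(scored) > 1 else 0.0
        if hit is not None and prob >= accept_prob and runner_up <= reject_prob:
            return DomainHit(
                domain=name,
                start=q_start + hit.start,
                end=q_start + hit.end,
                bit_score=hit.bit_score,
                empirical_p=hit.empirical_p,
                assignment_prob=prob,
            )
        if length >= n_span:
            return None
        length = min(length + step, n_span)


def assignment_probability(
    bit_score: float, query_length: int, calibration: ProfileCalibration
) -> float:
    """Logistic transform of the calibrated null z-score into [0, 1]."""
    z = calibration.zscore(bit_score, query_length)
    return float(1.0 / (1.0 + np.exp(-(z - _PROB_Z0) / _PROB_SCALE)))


def resolve_architecture(
    hits: Sequence[DomainHit], protein_length: int, protein_id: str = ""
) -> DomainArchitecture:
    """Render resolved hits as a canonical ordered architecture string.

    Nested hits become insertions ("PHP(Exo)").  Unassigned spans of at
    least 50 residues between or outside domains are recorded.
    """
    ordered = sorted(hits, key=lambda h: h.start)
    nested = [h for h in ordered if h.nested_in]
    top = [h for h in ordered if not h.nested_in]
    for i, a in enumerate(top):
        for b in top[i + 1 :]:
            ov = _overlap(a, b)
            if ov and ov > OVERLAP_TOLERANCE * min(a.end - a.start, b.end - b.start):
                raise ValueError(
                    f"{protein_id}: overlapping non-nested hits {a.domain}/{b.domain}"
                )
    tokens: list[str] = []
    for h in top:
        inner = [x.domain for x in nested if _nested(x, h)]
        tokens.append(f"{h.domain}({','.join(inner)})" if inner else h.domain)
    spans: list[tuple[int, int]] = []
    cursor = 0
    for h in top:
        if h.start - cursor >= MIN_UNASSIGNED_SPAN:
            spans.append((cursor, h.start))
        cursor = max(cursor, h.end)
    if protein_length - cursor >= MIN_UNASSIGNED_SPAN:
        spans.append((cursor, protein_length))
    return DomainArchitecture(
        protein_id=protein_id,
        tokens=tuple(tokens),
        hits=tuple(ordered),
        unassigned_spans=tuple(spans),
    )


@dataclass(frozen=True)
class CoreMap:
    """The conserved PHP-Pol3-(HhH)2 core of a protein mapped to reference columns.

    ``column_map`` maps 1-based reference columns to 0-based protein
    positions for every aligned column; ``sequence`` is the protein
    subsequence aligned to the reference span, in protein order.
    """

    protein_id: str
    sequence: str
    column_map: dict[int, int]

    @property
    def length(self) -> int:
        return len(self.sequence)


class CoreUnmappableError(ValueError):
    pass


def extract_core(
    rec: ProteinRecord,
    core_profile: ProfileMatrix,
    calibration: ProfileCalibration | None = None,
    p_threshold: float = 1e-3,
    seed: int = 0,
) -> CoreMap:
    """Map a polymerase onto the reference core columns.

    Raises :class:`CoreUnmappableError` when the protein has no
    significant core hit.
    """
    if calibration is None:
        calibration = calibrate_profile(core_profile, seed=seed)
    result = scan_sequence(core_profile, rec, with_alignment=True)
    hit, cols, poss = result
    if hit is None:
        raise CoreUnmappableError(f"{rec.protein_id}: core unmappable")
    p = calibration.pvalue(hit.bit_score, len(rec.sequence))
    if p > p_threshold:
        raise CoreUnmappableError(
            f"{rec.protein_id}: core unmappable (p = {p:.3g})"
        )
    column_map = {int(c) + 1: int(p_) for c, p_ in zip(cols, poss)}
    seq = "".join(rec.sequence[p_] for p_ in sorted(column_map.values()))
    return CoreMap(protein_id=rec.protein_id, sequence=seq, column_map=column_map)


def architectures_to_tsv(archs: Iterable[DomainArchitecture], path) -> None:
    import pandas as pd

    rows = []
    for arch in archs:
        rows.append(
            {
                "protein_id": arch.protein_id,
                "architecture": arch.string,
                "domains": ";".join(
                    f"{h.domain}:{h.start}-{h.end}" for h in arch.hits
                ),
                "unassigned": ";".join(f"{s}-{e}" for s, e in arch.unassigned_spans),
            }
        )
    pd.DataFrame(rows, columns=["protein_id", "architecture", "domains", "unassigned"]).to_csv(
        path, sep="\t", index=False
    )
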