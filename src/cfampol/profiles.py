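"""Log-odds profiles and proteome scanning.

A :class:`ProfileMatrix` is a per-column log-odds model over the 20 amino
acids built from a reference multiple alignment (columns with >= 50% gaps
are dropped, mirroring the trimming applied before phylogenetic analysis).
Profiles are scanned against proteins with local Smith-Waterman alignment
and affine gaps; candidate C-family polymerases are those whose best hit
is significant at p <= 1e-3 with at least 40% of profile columns covered.

Two significance routes exist.  ``empirical_pvalue`` is the exact
plus-one-rule shuffle test on the target sequence itself.  For cohort
scale work, :class:`ProfileCalibration` fits an extreme-value (Gumbel)
null to seeded random-sequence scores once per profile and evaluates the
same threshold analytically; the two routes agree on accept/reject far
from the threshold and the empirical route remains the reference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._align import X_INDEX, encode_sequence, sw_best_score, sw_traceback
from .io import AMINO_ACIDS, ProteinRecord

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

_GAP_CHARS = frozenset("-.")

_EULER_GAMMA = 0.5772156649015329


@dataclass
class ProfileMatrix:
    """Position-specific log-odds scores (bits) over the amino-acid alphabet."""

    name: str
    scores: np.ndarray  # (n_columns, 20) float
    background: np.ndarray  # (20,) frequencies summing to 1
    consensus: str = ""
    n_seqs: int = 0
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    source_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be (n_columns, 20)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("profile scores must be finite")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    def __len__(self) -> int:
        return self.scores.shape[0]

    @property
    def scan_matrix(self) -> np.ndarray:
        """(n_columns, 21) float32 matrix with X scored as background (0 bits)."""
        cached = getattr(self, "_scan_matrix", None)
        if cached is None:
            cached = np.zeros((len(self), 21), dtype=np.float32)
            cached[:, :20] = self.scores
            cached[:, X_INDEX] = 0.0
            self._scan_matrix = cached
        return cached


@dataclass(frozen=True)
class ProfileHit:
    """A scored local match of a profile on a protein."""

    profile_name: str
    protein_id: str
    start: int
    end: int
    bit_score: float
    empirical_p: float
    coverage: float
    column_start: int = 0
    column_end: int = 0
    identity: float = float("nan")

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("hit start must be < end")
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must be in (0, 1]")
        if not 0.0 < self.empirical_p <= 1.0:
            raise ValueError("empirical_p must be in (0, 1]")


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def build_profile(
    alignment: Sequence[str],
    name: str = "profile",
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    source_span: tuple[int, int] | None = None,
) -> ProfileMatrix:
    """Build a log-odds profile from an aligned set of sequences.

    Columns with at least 50% gap characters are dropped.  Per-column
    scores are ``log2((f + w * bg) / (1 + w) / bg)`` where ``f`` is the
    observed residue fraction, ``w`` the pseudocount weight and ``bg`` the
    background frequency.  ``X`` is ignored when counting.
    """
    seqs = [s.upper() for s in alignment]
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if length == 0 or any(len(s) != length for s in seqs):
        raise ValueError("alignment sequences must be non-empty and equal length")
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be >= 0")
    bg = uniform_background() if background is None else np.asarray(background, float)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    n = len(seqs)
    kept_scores: list[np.ndarray] = []
    consensus: list[str] = []
    tiny = 1e-12  # avoids log(0) when a pseudocount of exactly 0 is requested
    for col in range(length):
        letters = [s[col] for s in seqs]
        n_gap = sum(1 for c in letters if c in _GAP_CHARS)
        if n_gap * 2 >= n:
            continue
        counts = np.zeros(20)
        for c in letters:
            idx = aa_index.get(c)
            if idx is not None:
                counts[idx] += 1
        total = counts.sum()
        freq = counts / total if total else bg.copy()
        num = (freq + pseudocount_weight * bg) / (1.0 + pseudocount_weight)
        kept_scores.append(np.log2(np.maximum(num, tiny) / bg))
        consensus.append(AMINO_ACIDS[int(np.argmax(counts))] if total else "X")
    if not kept_scores:
        raise ValueError("all alignment columns were >= 50% gaps")
    return ProfileMatrix(
        name=name,
        scores=np.vstack(kept_scores),
        background=bg,
        consensus="".join(consensus),
        n_seqs=n,
        gap_open=gap_open,
        gap_extend=gap_extend,
        source_span=source_span,
    )


def _as_sequence(rec: ProteinRecord | str) -> tuple[str, str]:
    if isinstance(rec, ProteinRecord):
        return rec.sequence, rec.protein_id
    return rec, "query"


def scan_sequence(
    profile: ProfileMatrix,
    rec: ProteinRecord | str,
    with_alignment: bool = False,
):
    """Best local alignment of a profile on a protein, if score > 0.

    Returns a :class:`ProfileHit` (p-value left at 1.0; significance is
    assigned by the caller), or ``None`` when no positive-scoring local
    alignment exists.  With ``with_alignment=True`` returns
    ``(hit, columns, positions)`` giving the matched column/position pairs.
    """
    seq, pid = _as_sequence(rec)
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    encoded = encode_sequence(seq)
    score, c0, c1, p0, p1, cols, poss = sw_traceback(
        profile.scan_matrix, encoded, np.float32(profile.gap_open), np.float32(profile.gap_extend)
    )
    if score <= 0.0 or len(cols) == 0:
        return (None, None, None) if with_alignment else None
    consensus = profile.consensus
    if consensus:
        ident = float(np.mean([seq[p] == consensus[c] for c, p in zip(cols, poss)]))
    else:
        ident = float("nan")
    hit = ProfileHit(
        profile_name=profile.name,
        protein_id=pid,
        start=int(p0),
        end=int(p1),
        bit_score=float(score),
        empirical_p=1.0,
        coverage=(int(c1) - int(c0)) / len(profile),
        column_start=int(c0),
        column_end=int(c1),
        identity=ident,
    )
    if with_alignment:
        return hit, np.asarray(cols), np.asarray(poss)
    return hit


def scan_score(profile: ProfileMatrix, seq: str) -> float:
    """Score-only scan (no traceback); used for null distributions."""
    return float(
        sw_best_score(
            profile.scan_matrix,
            encode_sequence(seq),
            np.float32(profile.gap_open),
            np.float32(profile.gap_extend),
        )
    )


def empirical_pvalue(
    profile: ProfileMatrix,
    rec: ProteinRecord | str,
    n_shuffles: int = 99,
    seed: int = 0,
    observed: float | None = None,
) -> float:
    """Shuffle p-value with the plus-one rule.

    ``p = (1 + #{shuffled scores >= observed}) / (n_shuffles + 1)`` where
    the null is residue-shuffled copies of the target sequence itself.
    Deterministic for a fixed seed.
    """
    if n_shuffles < 19:
        raise ValueError("n_shuffles must be >= 19")
    seq, _ = _as_sequence(rec)
    if not seq:
        raise ValueError("cannot scan an empty sequence")
    if observed is None:
        observed = scan_score(profile, seq)
    rng = np.random.default_rng(seed)
    encoded = encode_sequence(seq)
    matrix = profile.scan_matrix
    go = np.float32(profile.gap_open)
    ge = np.float32(profile.gap_extend)
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = rng.permutation(encoded)
        if float(sw_best_score(matrix, shuffled, go, ge)) >= observed:
            exceed += 1
    return (1 + exceed) / (n_shuffles + 1)


@dataclass
class ProfileCalibration:
    """Gumbel null for a profile, fitted once from seeded random sequences.

    Location/scale are moment-matched to maximal local alignment scores of
    random sequences of length ``ref_length`` drawn from the profile
    background; the location shifts with ``log(L / ref_length)`` for other
    sequence lengths (Karlin-Altschul style length scaling).
    """

    mu: float
    beta: float
    ref_length: int
    n_samples: int

    @property
    def null_sd(self) -> float:
        return self.beta * math.pi / math.sqrt(6.0)

    def location(self, length: int) -> float:
        return self.mu + self.beta * math.log(max(length, 2) / self.ref_length)

    def pvalue(self, score: float, length: int) -> float:
        z = (score - self.location(length)) / self.beta
        # 1 - exp(-exp(-z)), stable for large z
        if z > 30:
            return max(math.exp(-z), 5e-324)
        return max(-math.expm1(-math.exp(-z)), 5e-324)

    def zscore(self, score: float, length: int) -> float:
        loc = self.location(length)
        mean = loc + _EULER_GAMMA * self.beta
        return (score - mean) / self.null_sd


def calibrate_profile(
    profile: ProfileMatrix,
    seed: int = 0,
    n_samples: int = 80,
    length: int = 400,
) -> ProfileCalibration:
    """Fit the Gumbel null for a profile from random background sequences."""
    rng = np.random.default_rng(seed)
    matrix = profile.scan_matrix
    go = np.float32(profile.gap_open)
    ge = np.float32(profile.gap_extend)
    maxima = np.empty(n_samples)
    for k in range(n_samples):
        seq = rng.choice(20, size=length, p=profile.background).astype(np.int8)
        maxima[k] = sw_best_score(matrix, seq, go, ge)
    sd = float(np.std(maxima, ddof=1))
    beta = max(sd * math.sqrt(6.0) / math.pi, 1e-6)
    mu = float(np.mean(maxima)) - _EULER_GAMMA * beta
    return ProfileCalibration(mu=mu, beta=beta, ref_length=length, n_samples=n_samples)


def detect_polymerases(
    proteome: Iterable[ProteinRecord],
    core_profile: ProfileMatrix,
    p_threshold: float = 1e-3,
    min_coverage: float = 0.4,
    calibration: ProfileCalibration | None = None,
    significance: str = "calibrated",
    n_shuffles: int = 999,
    seed: int = 0,
) -> list[ProfileHit]:
    """Detect candidate C-family polymerases in a proteome.

    One best hit per protein; a hit is reported when its p-value is at or
    below ``p_threshold`` and it covers at least ``min_coverage`` of the
    profile columns.  ``significance`` selects the analytic calibrated
    null (default) or the exact per-sequence shuffle test.
    """
    if significance not in ("calibrated", "empirical"):
        raise ValueError(f"unknown significance mode {significance!r}")
    if significance == "calibrated" and calibration is None:
        calibration = calibrate_profile(core_profile, seed=seed)
    hits: list[ProfileHit] = []
    for rec in proteome:
        hit = scan_sequence(core_profile, rec)
        if hit is None or hit.coverage < min_coverage:
            continue
        if significance == "calibrated":
            p = calibration.pvalue(hit.bit_score, len(rec.sequence))
        else:
            p = empirical_pvalue(
                core_profile, rec, n_shuffles=n_shuffles, seed=seed, observed=hit.bit_score
            )
        if p <= p_threshold:
            hits.append(
                ProfileHit(
                    profile_name=hit.profile_name,
                    protein_id=hit.protein_id,
                    start=hit.start,
                    end=hit.end,
                    bit_score=hit.bit_score,
                    empirical_p=p,
                    coverage=hit.coverage,
                    column_start=hit.column_start,
                    column_end=hit.column_end,
                    identity=hit.identity,
                )
            )
    return hits


_ALIGNER: Align.PairwiseAligner | None = None


def _global_aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _ALIGNER = aligner
    return _ALIGNER


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity, normalised by the shorter sequence.

    The clustering-tool convention: identical aligned pairs divided by the
    length of the shorter sequence.  Symmetric by construction (the pair
    is canonicalised before alignment).
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    x, y = (a, b) if a <= b else (b, a)
    # X is outside BLOSUM62's core alphabet handling for some versions;
    # substitute by a neutral residue for alignment purposes only
    alignment = _global_aligner().align(x.replace("X", "A"), y.replace("X", "A"))[0]
    identical = 0
    aligned_x, aligned_y = alignment.aligned
    for (xs, xe), (ys, _) in zip(aligned_x, aligned_y):
        for off in range(xe - xs):
            if x[xs + off] == y[ys + off]:
                identical += 1
    return identical / min(len(x), len(y))


def kmer_identity_screen(a: str, b: str, k: int = 8, threshold: float = 0.2) -> bool:
    """Cheap pre-screen: True when the pair could plausibly be >= ~90% identical.

    Sequences >= 90% identical share ~0.9^8 = 43% of their 8-mers, while
    pairs at <= 80% identity fall below ~17%; the 0.2 default separates
    the two regimes with margin on both sides.
    """
    if min(len(a), len(b)) <= k:
        return True
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    kmers = {long_[i : i + k] for i in range(len(long_) - k + 1)}
    shared = sum(1 for i in range(len(short) - k + 1) if short[i : i + k] in kmers)
    return shared / (len(short) - k + 1) >= threshold


def profile_to_json(profile: ProfileMatrix) -> str:
    """Serialise a profile to the documented JSON layout."""
    payload = {
        "name": profile.name,
        "alphabet": AMINO_ACIDS,
        "scores": profile.scores.tolist(),
        "background": profile.background.tolist(),
        "consensus": profile.consensus,
        "n_seqs": profile.n_seqs,
        "gap_open": profile.gap_open,
        "gap_extend": profile.gap_extend,
        "source_span": list(profile.source_span) if profile.source_span else None,
    }
    return json.dumps(payload)


def profile_from_json(text: str) -> ProfileMatrix:
    payload = json.loads(text)
    return ProfileMatrix(
        name=payload["name"],
        scores=np.asarray(payload["scores"]),
        background=np.asarray(payload["background"]),
        consensus=payload.get("consensus", ""),
        n_seqs=payload.get("n_seqs", 0),
        gap_open=payload.get("gap_open", DEFAULT_GAP_OPEN),
        gap_extend=payload.get("gap_extend", DEFAULT_GAP_EXTEND),
        source_span=tuple(payload["source_span"]) if payload.get("source_span") else None,
    )


def hits_to_tsv(hits: Iterable[ProfileHit], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "protein_id": h.protein_id,
            "profile": h.profile_name,
            "start": h.start,
            "end": h.end,
            "bit_score": round(h.bit_score, 4),
            "p": h.empirical_p,
            "coverage": round(h.coverage, 4),
        }
        for h in hits
    ]
    pd.DataFrame(
        rows, columns=["protein_id", "profile", "start", "end", "bit_score", "p", "coverage"]
    ).to_csv(path, sep="\t", index=False)
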