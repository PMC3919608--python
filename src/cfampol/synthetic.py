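"""Synthetic proteome cohorts with planted polymerases and full truth tables.

The generator emulates the statistical structure the analysis assumes:
group-typical domain architectures concatenated in canonical order with
short linkers, group-specific motifs (active-site aspartates, PHP
metal-site state, beta-clamp pentapeptide class, DnaE2 SRDF tail),
point-mutational divergence that spares planted motif columns, decoy
proteins, and genome metadata in which DnaE2 presence is coupled to GC
content, genome size and oxygen use through a logistic model.  The core
length of DnaE2 polymerases is coupled to genomic GC through a variable
deletion in the polymerase 'thumb' region whose slope and noise are
solved from the requested Spearman target.

Every emitted polymerase carries complete truth annotations (group,
architecture, motif classes, core span), so each pipeline stage can be
scored against planted truth without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, GenomeRecord, ProteinRecord, write_fasta, write_genome_table
from .motifs import SiteConfig
from .profiles import ProfileMatrix, build_profile, pairwise_identity
from .stats import combination_label

DEFAULT_DOMAIN_LENGTHS: dict[str, int] = {
    "PHP": 270,
    "Pol3": 460,
    "HhH": 100,
    "OB": 100,
    "CTD": 120,
    "NTD": 210,
    "Exo": 180,
    "UDG": 160,
    "Lar": 70,
}

#: core layout: PHP + 10-residue linker + Pol3 + 10-residue linker + HhH
CORE_LINKER = 10

#: relative positions of the nine metal-coordinating residues within PHP
_PHP_SITE_FRACTIONS = (0.03, 0.09, 0.22, 0.35, 0.48, 0.60, 0.73, 0.85, 0.97)
#: canonical residues at the nine PHP metal-site positions
PHP_CANONICAL = "HHDHEHDHD"
#: relative position of the first active-site aspartate within Pol3 (the
#: second sits two residues downstream, the third near the block's end)
_ACTIVE_SITE_FRACTIONS = (0.215, 0.93)
#: relative start of the deletion window emulating 'thumb' reduction
_THUMB_FRACTION = 0.33
THUMB_WINDOW_MAX = 180


def _php_site_positions(php_length: int) -> tuple[int, ...]:
    """1-based metal-site positions scaled to the PHP block length."""
    positions = sorted({max(1, round(f * php_length)) for f in _PHP_SITE_FRACTIONS})
    if len(positions) != 9:
        raise ValueError(f"PHP block of {php_length} residues cannot host nine distinct sites")
    return tuple(positions)


def _active_site_positions(pol3_length: int) -> tuple[int, int, int]:
    """1-based positions of the three catalytic aspartates within Pol3."""
    first = max(1, round(_ACTIVE_SITE_FRACTIONS[0] * pol3_length))
    third = min(pol3_length, round(_ACTIVE_SITE_FRACTIONS[1] * pol3_length))
    if third <= first + 2:
        raise ValueError(f"Pol3 block of {pol3_length} residues too short for the active site")
    return (first, first + 2, third)

_SCENARIOS = ("DnaE1", "PolC+DnaE3", "PolC+DnaE1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for cohort generation."""

    seed: int = 0
    n_genomes: int = 100
    divergence: float = 0.15
    decoys_per_genome: int = 3
    scenario_weights: tuple[float, float, float] = (0.766, 0.150, 0.084)
    #: intercept, standardized GC, standardized log-size, oxygen-using flag
    dnae2_logit: tuple[float, float, float, float] = (-0.8, 1.1, 0.7, 0.9)
    #: P(1, 2, 3 DnaE2 copies | present)
    dnae2_count_probs: tuple[float, float, float] = (0.855, 0.121, 0.024)
    rho_target: float = 0.6
    ctail_prob: float = 0.77
    gc_range: tuple[float, float] = (25.0, 75.0)
    size_range_mb: tuple[float, float] = (0.5, 10.0)
    group_divergence: float = 0.12
    ref_divergence: float = 0.10
    n_ref: int = 8
    domain_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_LENGTHS)
    )
    corrupt_motifs: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence < 0.5:
            raise ValueError("divergence must be in [0, 0.5)")
        if abs(sum(self.scenario_weights) - 1.0) > 1e-9:
            raise ValueError("scenario weights must sum to 1")
        if any(v <= 0 for v in self.domain_lengths.values()):
            raise ValueError("domain lengths must be positive")


@dataclass
class DomainLibrary:
    """Reference domain blocks, alignments and derived planting metadata."""

    seed: int
    lengths: dict[str, int]
    consensus: dict[str, str]
    alignments: dict[str, list[str]]
    core_alignment: list[str]
    detection_alignment: list[str]
    group_templates: dict[str, dict[str, str]]
    site_config: SiteConfig
    core_length: int
    core_linkers: tuple[str, str] = ("", "")
    php_site_positions: tuple[int, ...] = ()
    active_site_positions: tuple[int, int, int] = (0, 0, 0)
    thumb_start: int = 0
    thumb_max_deletion: int = 0

    def build_profiles(self, pseudocount: float = 0.5) -> dict[str, ProfileMatrix]:
        profiles = {
            name: build_profile(aln, name=name, pseudocount_weight=pseudocount)
            for name, aln in self.alignments.items()
        }
        profiles["core"] = build_profile(
            self.core_alignment, name="core", pseudocount_weight=pseudocount
        )
        profiles["detection"] = build_profile(
            self.detection_alignment, name="detection", pseudocount_weight=pseudocount
        )
        return profiles

    def group_core(self, group: str) -> str:
        """The group template's core sequence, aligned to the reference columns."""
        t = self.group_templates[group]
        l1, l2 = self.core_linkers
        return t["PHP"] + l1 + t["Pol3"] + l2 + t["HhH"]

    def anchor_cores(
        self, n_per_group: int = 3, divergence: float = 0.08
    ) -> tuple[dict[str, str], dict[str, str]]:
        """Column-aligned anchor core sequences for clade assignment.

        Returns ``(alignment_rows, anchor_groups)``; anchors are
        substitution-only mutants of each group's core template, so they
        stay trivially aligned to the reference columns.  Deterministic
        for the library seed.
        """
        rng = np.random.default_rng(self.seed + 104729)
        rows: dict[str, str] = {}
        labels: dict[str, str] = {}
        for group in ("PolC", "DnaE1", "DnaE2", "DnaE3"):
            core = self.group_core(group)
            for i in range(n_per_group):
                name = f"anchor_{group}_{i}"
                rows[name] = _mutate(rng, core, divergence)
                labels[name] = group
        return rows, labels


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def ungapped_identity(a: str, b: str) -> float:
    """Positionwise identity over the shorter length, no alignment.

    Used for the library dissimilarity criterion: the gapped
    shorter-length-normalised identity sits at 0.3-0.4 for unrelated
    sequences of very different lengths (the alignment cherry-picks
    matches), so chance-level dissimilarity is certified ungapped, where
    the chance level is 1/20.
    """
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("empty sequence")
    return sum(1 for x, y in zip(a, b) if x == y) / n


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Point substitutions at the given per-residue rate, sparing protected 0-based positions."""
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            out[i] = AMINO_ACIDS[int(rng.integers(0, 20))]
    return "".join(out)


def make_domain_library(
    seed: int,
    lengths: Mapping[str, int] | None = None,
    n_ref: int = 8,
    ref_divergence: float = 0.10,
    group_divergence: float = 0.12,
    max_retries: int = 200,
    max_identity: float = 0.20,
) -> DomainLibrary:
    """Generate mutually dissimilar reference domain blocks.

    Consensus blocks are redrawn until every pair stays below the
    ``max_identity`` ceiling of ungapped positionwise identity (chance
    level 1/20), i.e. the blocks share no detectable homology.  Reference alignments hold ``n_ref`` sequences mutated at
    ``ref_divergence`` from the consensus (motif columns spared); group
    templates diverge from the consensus at ``group_divergence``.
    Deterministic for a fixed seed.
    """
    lengths = dict(lengths or DEFAULT_DOMAIN_LENGTHS)
    for name, value in lengths.items():
        if value <= 0:
            raise ValueError(f"domain {name}: requested length must be positive")
    rng = np.random.default_rng(seed)
    php_positions = _php_site_positions(lengths["PHP"])
    active_positions = _active_site_positions(lengths["Pol3"])
    thumb_start = max(1, round(_THUMB_FRACTION * lengths["Pol3"]))
    # the deletion window must never reach the distal catalytic aspartate
    thumb_max_deletion = max(0, min(THUMB_WINDOW_MAX, active_positions[2] - thumb_start - 1))
    protected: dict[str, frozenset[int]] = {
        name: frozenset() for name in lengths
    }
    protected["PHP"] = frozenset(p - 1 for p in php_positions)
    protected["Pol3"] = frozenset(p - 1 for p in active_positions)

    def plant(name: str, seq: str) -> str:
        out = list(seq)
        if name == "PHP":
            for pos, aa in zip(php_positions, PHP_CANONICAL):
                out[pos - 1] = aa
        elif name == "Pol3":
            for pos in active_positions:
                out[pos - 1] = "D"
        return "".join(out)

    names = list(lengths)
    consensus: dict[str, str] = {}
    for name in names:
        for _ in range(max_retries):
            cand = plant(name, _random_sequence(rng, lengths[name]))
            if all(ungapped_identity(cand, other) < max_identity for other in consensus.values()):
                consensus[name] = cand
                break
        else:
            raise RuntimeError(f"could not generate a dissimilar block for {name}")

    alignments = {
        name: [
            _mutate(rng, consensus[name], ref_divergence, protected[name])
            for _ in range(n_ref)
        ]
        for name in names
    }
    linker1 = _random_sequence(rng, CORE_LINKER)
    linker2 = _random_sequence(rng, CORE_LINKER)
    core_alignment = [
        alignments["PHP"][i] + linker1 + alignments["Pol3"][i] + linker2 + alignments["HhH"][i]
        for i in range(n_ref)
    ]
    detection_alignment = list(alignments["Pol3"])

    group_templates: dict[str, dict[str, str]] = {}
    for group in ("PolC", "DnaE1", "DnaE2", "DnaE3"):
        group_templates[group] = {
            name: _mutate(rng, consensus[name], group_divergence, protected[name])
            for name in names
        }

    php_offset = 0
    pol3_offset = lengths["PHP"] + CORE_LINKER
    active_cols = tuple(pol3_offset + p for p in active_positions)
    php_cols = tuple(php_offset + p for p in php_positions)
    canonical_sets = tuple(frozenset(aa) for aa in PHP_CANONICAL)
    site_config = SiteConfig(
        active_site_columns=active_cols,
        php_site_columns=php_cols,
        php_consensus={
            "canonical": canonical_sets,
            "PolC": canonical_sets,
            "DnaE1": canonical_sets,
            "DnaE2": canonical_sets,
            "DnaE3": canonical_sets,
        },
    )
    core_length = lengths["PHP"] + CORE_LINKER + lengths["Pol3"] + CORE_LINKER + lengths["HhH"]
    return DomainLibrary(
        seed=seed,
        lengths=lengths,
        consensus=consensus,
        alignments=alignments,
        core_alignment=core_alignment,
        detection_alignment=detection_alignment,
        group_templates=group_templates,
        site_config=site_config,
        core_length=core_length,
        core_linkers=(linker1, linker2),
        php_site_positions=php_positions,
        active_site_positions=active_positions,
        thumb_start=thumb_start,
        thumb_max_deletion=thumb_max_deletion,
    )


def _sample_clamp(group: str, rng: np.random.Generator) -> tuple[str | None, str]:
    """Sample a beta-clamp pentapeptide and its class for a group."""

    def rand_aa(exclude: str = "") -> str:
        while True:
            aa = AMINO_ACIDS[int(rng.integers(0, 20))]
            if aa not in exclude:
                return aa

    u = rng.random()
    if group == "PolC":
        return ("QLSLF", "canonical_strong") if u < 0.98 else (None, "none")
    if group == "DnaE1":
        if u < 0.60:
            return "Q" + rand_aa() + ("S" if rng.random() < 0.5 else "D") + "LF", "canonical_strong"
        if u < 0.99:
            return "Q" + rand_aa() + rand_aa("SDP") + "LF", "canonical"
        return None, "none"
    if group == "DnaE2":
        if u < 0.75:
            if rng.random() < 0.5:
                return "PLPLF", "dnae2_type"
            return rand_aa("QP") + "LPLF", "dnae2_type"
        if u < 0.85:
            return rand_aa("QP") + rand_aa() + rand_aa("SDP") + "LL", "weak"
        return None, "none"
    if group == "DnaE3":
        if u < 0.61:
            return rand_aa("QP") + rand_aa() + rand_aa("SDP") + "L" + (
                "F" if rng.random() < 0.5 else "L"
            ), "weak"
        if u < 0.75:
            return "QM" + rand_aa("SDP") + "LF", "canonical"
        return None, "none"
    raise ValueError(f"unknown group {group!r}")


def _thumb_deletion(
    group: str,
    gc: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    max_deletion: int = THUMB_WINDOW_MAX,
) -> int:
    """Deletion length (residues) removed from the Pol3 'thumb' window."""
    if group in ("PolC", "DnaE1"):
        return 0
    if group == "DnaE3":
        return int(rng.integers(0, min(100, max_deletion) + 1))
    # DnaE2: linear-in-GC deletion; slope fixed, noise solved from the
    # Spearman target via the bivariate-normal relation rho = (6/pi) asin(r/2)
    slope = 1.2
    r = 2.0 * math.sin(math.pi * cfg.rho_target / 6.0)
    gc_sd = (cfg.gc_range[1] - cfg.gc_range[0]) / math.sqrt(12.0)
    signal_sd = slope * gc_sd
    noise_sd = signal_sd * math.sqrt(max(1.0 / (r * r) - 1.0, 0.0)) if r > 0 else 1e6
    mid = 0.5 * (cfg.gc_range[0] + cfg.gc_range[1])
    raw = 70.0 - slope * (gc - mid) + rng.normal(0.0, noise_sd)
    return int(np.clip(round(raw), 0, max_deletion))


@dataclass(frozen=True)
class PlantedPolymerase:
    record: ProteinRecord
    truth: dict


def make_polymerase(
    group: str,
    cfg: GeneratorConfig,
    library: DomainLibrary,
    rng: np.random.Generator,
    protein_id: str = "p1",
    genome_id: str = "G0000",
    gc: float = 50.0,
) -> PlantedPolymerase:
    """Assemble one polymerase of a given group with full truth annotation."""
    if group not in ("PolC", "DnaE1", "DnaE2", "DnaE3"):
        raise ValueError(f"unknown group {group!r}")
    template = library.group_templates[group]
    lengths = library.lengths

    def linker() -> str:
        return _random_sequence(rng, int(rng.integers(5, 21)))

    php_intact_prob = {"PolC": 1.0, "DnaE1": 0.7, "DnaE2": 0.10, "DnaE3": 0.0}[group]
    php_intact = rng.random() < php_intact_prob
    php = template["PHP"]
    if not php_intact:
        chars = list(php)
        for pos in library.php_site_positions:
            chars[pos - 1] = AMINO_ACIDS[int(rng.integers(0, 20))]
        php = "".join(chars)

    pol3 = template["Pol3"]
    deletion = _thumb_deletion(group, gc, cfg, rng, library.thumb_max_deletion)
    if deletion:
        start = library.thumb_start - 1
        pol3 = pol3[:start] + pol3[start + deletion :]

    clamp_motif, clamp_class = _sample_clamp(group, rng)

    # architecture variant sampling
    u = rng.random()
    if group == "PolC":
        exo_inserted = u < 0.94
        variant = "typical" if exo_inserted else "no_exo"
    elif group == "DnaE1":
        if u < 0.93:
            variant = "typical"
        elif u < 0.97:
            variant = "no_ctd"
        else:
            variant = "exo_nterm"
    elif group == "DnaE2":
        variant = "typical" if u < 0.90 else "no_ob"
    else:  # DnaE3
        if u < 0.70:
            variant = "typical"
        elif u < 0.90:
            variant = "no_ctd"
        else:
            variant = "no_ob_no_ctd"

    pieces: list[tuple[str, str]] = []  # (label, sequence)

    def add(label: str, seq: str) -> None:
        pieces.append((label, seq))

    clamp_segment = (
        _random_sequence(rng, int(rng.integers(3, 9)))
        + (clamp_motif or "")
        + _random_sequence(rng, int(rng.integers(2, 7)))
    )

    if group == "PolC":
        add("NTD", template["NTD"])
        add("linker", linker())
        add("OB", template["OB"])
        add("linker", linker())
        if variant == "typical":
            split = lengths["PHP"] // 2
            add("PHP_a", php[:split])
            add("Exo", template["Exo"])
            add("PHP_b", php[split:])
        else:
            add("PHP", php)
        add("linker", linker())
        add("Pol3", pol3)
        add("linker", linker())
        add("HhH", template["HhH"])
        add("clamp", clamp_segment)
        arch_truth = (
            "NTD-OB-PHP(Exo)-Pol3-HhH" if variant == "typical" else "NTD-OB-PHP-Pol3-HhH"
        )
    else:
        if group == "DnaE1" and variant == "exo_nterm":
            add("Exo", template["Exo"])
            add("linker", _random_sequence(rng, 60))
        add("PHP", php)
        add("linker", linker())
        add("Pol3", pol3)
        add("linker", linker())
        add("HhH", template["HhH"])
        add("clamp", clamp_segment)
        if group == "DnaE2":
            has_ob = variant == "typical"
            has_ctd = False
        else:  # DnaE1 / DnaE3
            has_ob = variant in ("typical", "no_ctd", "exo_nterm")
            has_ctd = variant in ("typical", "exo_nterm")
        if has_ob:
            add("OB", template["OB"])
        if has_ctd:
            add("linker", linker())
            add("CTD", template["CTD"])
        tokens = []
        if group == "DnaE1" and variant == "exo_nterm":
            tokens.append("Exo")
        tokens += ["PHP", "Pol3", "HhH"]
        if has_ob:
            tokens.append("OB")
        if has_ctd:
            tokens.append("CTD")
        arch_truth = "-".join(tokens)

    ctail = False
    if group == "DnaE2":
        ctail = rng.random() < cfg.ctail_prob
        tail = _random_sequence(rng, int(rng.integers(10, 21)))
        if ctail:
            tail += "SRDF" + ("H" if rng.random() < 0.5 else "R")
            tail += _random_sequence(rng, int(rng.integers(0, 6)))
        add("tail", tail)

    # assemble, tracking protected positions and landmark coordinates
    seq_parts: list[str] = []
    protected: set[int] = set()
    coords: dict[str, tuple[int, int]] = {}
    offset = 0
    for label, part in pieces:
        span = (offset, offset + len(part))
        base = label.split("_")[0]
        if base in lengths or base in ("PHP",):
            prev = coords.get(base)
            coords[base] = (prev[0], span[1]) if prev else span
        seq_parts.append(part)
        offset = span[1]
    sequence = "".join(seq_parts)

    # protected positions: active-site aspartates, intact PHP site,
    # clamp pentapeptide, SRDF tail
    if not cfg.corrupt_motifs:
        php_start = coords["PHP"][0]
        pol3_start = coords["Pol3"][0]
        if group == "PolC" and variant == "typical":
            # Exo insertion shifts the second half of PHP
            split = lengths["PHP"] // 2
            exo_len = len(template["Exo"])
            for pos in library.php_site_positions:
                p0 = pos - 1
                absolute = php_start + (p0 if p0 < split else p0 + exo_len)
                protected.add(absolute)
        else:
            for pos in library.php_site_positions:
                protected.add(php_start + pos - 1)
        for pos in library.active_site_positions:
            p0 = pos - 1
            if deletion and p0 >= library.thumb_start - 1:
                p0 -= deletion
            protected.add(pol3_start + p0)
        if clamp_motif:
            idx = sequence.find(clamp_motif)
            if idx >= 0:
                protected.update(range(idx, idx + len(clamp_motif)))
        if ctail:
            idx = sequence.rfind("SRDF")
            protected.update(range(idx, idx + 5))

    mutated = _mutate(rng, sequence, cfg.divergence, frozenset(protected))

    core_start = coords["PHP"][0]
    core_end = coords["HhH"][1]
    record = ProteinRecord(
        protein_id=protein_id,
        genome_id=genome_id,
        sequence=mutated,
        description=f"{protein_id} genome={genome_id} planted={group}",
    )
    truth = {
        "protein_id": protein_id,
        "genome_id": genome_id,
        "group": group,
        "variant": variant,
        "architecture": arch_truth,
        "core_start": core_start,
        "core_end": core_end,
        "core_length": library.core_length - deletion,
        "thumb_deletion": deletion,
        "php_intact": php_intact,
        "clamp_class": clamp_class,
        "clamp_motif": clamp_motif or "",
        "ctail_motif": ctail,
    }
    return PlantedPolymerase(record=record, truth=truth)


@dataclass
class Cohort:
    config: GeneratorConfig
    library: DomainLibrary
    genomes: dict[str, GenomeRecord]
    proteomes: dict[str, list[ProteinRecord]]
    polymerase_truth: pd.DataFrame
    genome_truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gid, records in sorted(self.proteomes.items()):
            write_fasta(records, out / f"{gid}.faa")
        write_genome_table(self.genomes, out / "genomes.tsv")
        self.polymerase_truth.to_csv(out / "truth_polymerases.tsv", sep="\t", index=False)
        self.genome_truth.to_csv(out / "truth_genomes.tsv", sep="\t", index=False)


def _sample_oxygen(scenario: str, rng: np.random.Generator) -> str:
    u = rng.random()
    if scenario == "PolC+DnaE1":
        if u < 0.85:
            return "anaerobe"
        return "facultative" if u < 0.93 else "unknown"
    if scenario == "PolC+DnaE3":
        if u < 0.50:
            return "aerobe"
        if u < 0.75:
            return "facultative"
        if u < 0.85:
            return "anaerobe"
        return "microaerophile" if u < 0.92 else "unknown"
    # DnaE1-based genomes
    if u < 0.40:
        return "aerobe"
    if u < 0.60:
        return "facultative"
    if u < 0.65:
        return "microaerophile"
    if u < 0.90:
        return "anaerobe"
    return "unknown"


def make_cohort(cfg: GeneratorConfig) -> Cohort:
    """Generate a full cohort: proteomes, metadata and truth tables."""
    # the cohort stream must be decorrelated from the library stream: with
    # a shared integer seed the two PCG64 streams are identical and linker
    # draws can replay consensus-block draws, planting phantom homology
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x9E3779B9]))
    library = make_domain_library(
        cfg.seed,
        lengths=cfg.domain_lengths,
        n_ref=cfg.n_ref,
        ref_divergence=cfg.ref_divergence,
        group_divergence=cfg.group_divergence,
    )
    genomes: dict[str, GenomeRecord] = {}
    proteomes: dict[str, list[ProteinRecord]] = {}
    pol_rows: list[dict] = []
    genome_rows: list[dict] = []
    phylum_of = {"DnaE1": "Proteobacteria", "PolC+DnaE3": "Firmicutes", "PolC+DnaE1": "Firmicutes"}
    class_of = {"DnaE1": "Gammaproteobacteria", "PolC+DnaE3": "Bacilli", "PolC+DnaE1": "Clostridia"}
    weights = np.asarray(cfg.scenario_weights)
    for i in range(cfg.n_genomes):
        gid = f"G{i:04d}"
        scenario = _SCENARIOS[int(rng.choice(len(_SCENARIOS), p=weights))]
        gc = float(rng.uniform(*cfg.gc_range))
        log_lo, log_hi = (math.log(m * 1e6) for m in cfg.size_range_mb)
        size = int(round(math.exp(rng.uniform(log_lo, log_hi))))
        oxygen = _sample_oxygen(scenario, rng)
        groups: list[str] = []
        if scenario == "DnaE1":
            groups.append("DnaE1")
            b0, b_gc, b_size, b_oxy = cfg.dnae2_logit
            gc_std = (gc - np.mean(cfg.gc_range)) / (
                (cfg.gc_range[1] - cfg.gc_range[0]) / math.sqrt(12.0)
            )
            size_std = (math.log(size) - 0.5 * (log_lo + log_hi)) / (
                (log_hi - log_lo) / math.sqrt(12.0)
            )
            oxy = 1.0 if oxygen in ("aerobe", "facultative", "microaerophile") else 0.0
            logit = b0 + b_gc * gc_std + b_size * size_std + b_oxy * oxy
            if rng.random() < 1.0 / (1.0 + math.exp(-logit)):
                n_e2 = 1 + int(rng.choice(3, p=np.asarray(cfg.dnae2_count_probs)))
                groups.extend(["DnaE2"] * n_e2)
        elif scenario == "PolC+DnaE3":
            groups.extend(["PolC", "DnaE3"])
        else:
            groups.extend(["PolC", "DnaE1"])
        genomes[gid] = GenomeRecord(
            genome_id=gid,
            size_bp=size,
            gc_percent=round(gc, 2),
            oxygen_class=oxygen,
            phylum=phylum_of[scenario],
            class_name=class_of[scenario],
        )
        records: list[ProteinRecord] = []
        for k, group in enumerate(groups):
            planted = make_polymerase(
                group,
                cfg,
                library,
                rng,
                protein_id=f"{gid}_p{k}",
                genome_id=gid,
                gc=gc,
            )
            records.append(planted.record)
            pol_rows.append(planted.truth)
        for d in range(cfg.decoys_per_genome):
            length = int(rng.integers(120, 601))
            records.append(
                ProteinRecord(
                    protein_id=f"{gid}_d{d}",
                    genome_id=gid,
                    sequence=_random_sequence(rng, length),
                    description=f"{gid}_d{d} genome={gid} decoy",
                )
            )
        proteomes[gid] = records
        counts = {g: groups.count(g) for g in set(groups)}
        genome_rows.append(
            {
                "genome_id": gid,
                "scenario": scenario,
                "combination": combination_label(counts),
                "n_polymerases": len(groups),
                "size_bp": size,
                "gc_percent": round(gc, 2),
                "oxygen_class": oxygen,
            }
        )
    return Cohort(
        config=cfg,
        library=library,
        genomes=genomes,
        proteomes=proteomes,
        polymerase_truth=pd.DataFrame(pol_rows),
        genome_truth=pd.DataFrame(genome_rows),
    )
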