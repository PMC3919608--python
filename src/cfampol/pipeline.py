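"""End-to-end analysis chain over a cohort of proteomes.

Stages: candidate detection with the conserved polymerase-region
profile, nonredundant genome selection, domain-architecture annotation
(including terminal-extension recovery), core extraction, motif and
physico-chemical feature analysis, rule-based group classification with
an optional NJ+bootstrap clade tie-breaker, and genome-level
combination/trait statistics.  All randomness derives from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dedup import select_nonredundant_genomes
from .domains import (
    CoreUnmappableError,
    assign_domains,
    extract_core,
    resolve_architecture,
    terminal_extension_scan,
    DOMAIN_TYPES,
)
from .grouping import (
    assign_by_clade,
    bootstrap_support,
    classify_group,
    extract_features,
    tree_to_newick,
    GroupCall,
)
from .io import GenomeRecord, ProteinRecord
from .motifs import SiteConfig, build_motif_report
from .physchem import isoelectric_point
from .profiles import ProfileMatrix, calibrate_profile, detect_polymerases
from .stats import (
    GenomeProfile,
    StatsResult,
    binned_fractions,
    oxygen_breakdown,
    spearman,
    tabulate_combinations,
)
from .synthetic import Cohort

DEFAULT_SIZE_EDGES = [i * 1_000_000 for i in range(0, 11)]
DEFAULT_GC_EDGES = list(range(20, 85, 5))


@dataclass
class PipelineResult:
    kept_genomes: list[str]
    annotations: pd.DataFrame
    genome_profiles: list[GenomeProfile]
    combination_table: pd.DataFrame
    size_fractions: pd.DataFrame
    gc_fractions: pd.DataFrame
    oxygen_table: pd.DataFrame
    dnae2_core_gc: StatsResult | None
    tree_newick: str | None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        self.combination_table.to_csv(out / "combinations.tsv", sep="\t", index=False)
        self.size_fractions.to_csv(out / "size_fractions.tsv", sep="\t", index=False)
        self.gc_fractions.to_csv(out / "gc_fractions.tsv", sep="\t", index=False)
        self.oxygen_table.to_csv(out / "oxygen.tsv", sep="\t", index=False)
        if self.tree_newick:
            (out / "clade_tree.nwk").write_text(self.tree_newick)
        stats = {
            "n_genomes_kept": len(self.kept_genomes),
            "n_polymerases": int(len(self.annotations)),
        }
        if self.dnae2_core_gc is not None:
            stats["dnae2_core_length_vs_gc_spearman"] = self.dnae2_core_gc.rho
            stats["dnae2_core_length_vs_gc_n"] = self.dnae2_core_gc.n
        import json

        (out / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    genomes: Mapping[str, GenomeRecord],
    proteomes: Mapping[str, Sequence[ProteinRecord]],
    profiles: Mapping[str, ProfileMatrix],
    site_config: SiteConfig,
    seed: int = 0,
    p_threshold: float = 1e-3,
    anchor_alignment: Mapping[str, str] | None = None,
    anchor_groups: Mapping[str, str] | None = None,
    bootstrap_reps: int = 100,
    dedup: bool = True,
) -> PipelineResult:
    """Run the full analysis chain and return all per-stage outputs.

    ``profiles`` must contain a ``detection`` profile (the conserved
    polymerase region), a ``core`` profile (the PHP-Pol3-(HhH)2
    reference span) and one profile per structural domain.  When anchor
    core sequences with known groups are supplied, DnaEX fallbacks are
    re-examined against the bootstrap NJ tree.
    """
    rng = np.random.default_rng(seed)
    calib_seeds = {name: int(rng.integers(0, 2**31 - 1)) for name in sorted(profiles)}
    calibrations = {
        name: calibrate_profile(profiles[name], seed=calib_seeds[name])
        for name in sorted(profiles)
    }
    domain_profiles = {n: profiles[n] for n in DOMAIN_TYPES if n in profiles}
    domain_calibrations = {n: calibrations[n] for n in domain_profiles}

    detections: dict[str, list] = {}
    for gid in sorted(proteomes):
        detections[gid] = detect_polymerases(
            proteomes[gid],
            profiles["detection"],
            p_threshold=p_threshold,
            calibration=calibrations["detection"],
        )

    records_by_id = {
        rec.protein_id: rec for recs in proteomes.values() for rec in recs
    }
    if dedup:
        pols_by_genome = {
            gid: [records_by_id[h.protein_id] for h in hits]
            for gid, hits in detections.items()
        }
        kept = select_nonredundant_genomes(genomes.values(), pols_by_genome)
    else:
        kept = sorted(genomes)

    rows: list[dict] = []
    core_rows: dict[str, dict[int, int]] = {}
    for gid in kept:
        for hit in detections[gid]:
            rec = records_by_id[hit.protein_id]
            hits = assign_domains(
                rec,
                domain_profiles,
                p_threshold=p_threshold,
                calibrations=domain_calibrations,
            )
            arch = resolve_architecture(hits, len(rec.sequence), rec.protein_id)
            recovered = []
            for span in arch.unassigned_spans:
                if span[0] == 0 or span[1] == len(rec.sequence):
                    extra = terminal_extension_scan(
                        rec, span, domain_profiles, calibrations=domain_calibrations
                    )
                    if extra is not None:
                        recovered.append(extra)
            if recovered:
                arch = resolve_architecture(
                    list(hits) + recovered, len(rec.sequence), rec.protein_id
                )
            try:
                core_map = extract_core(
                    rec, profiles["core"], calibration=calibrations["core"]
                )
            except CoreUnmappableError:
                continue
            motif_report = build_motif_report(rec, arch, core_map, site_config)
            if not motif_report.active_site_intact:
                continue
            core_pi = isoelectric_point(core_map.sequence)
            features = extract_features(
                arch, motif_report, core_map.length, core_pi
            )
            call = classify_group(features)
            core_rows[rec.protein_id] = core_map.column_map
            rows.append(
                {
                    "protein_id": rec.protein_id,
                    "genome_id": gid,
                    "architecture": arch.string,
                    "clamp_motif": motif_report.clamp_motif or "",
                    "clamp_class": motif_report.clamp_class,
                    "php_score": motif_report.php_score,
                    "php_intact": motif_report.php_intact,
                    "ctail_motif": motif_report.ctail_motif,
                    "core_length": core_map.length,
                    "core_pI": round(core_pi, 3),
                    "group": call.label,
                    "confidence": call.confidence,
                    "evidence": ";".join(call.evidence),
                }
            )

    annotations = pd.DataFrame(rows)
    tree_newick = None
    if (
        anchor_alignment
        and anchor_groups
        and len(annotations)
        and (annotations["group"] == "DnaEX").any()
    ):
        n_cols = len(next(iter(anchor_alignment.values())))
        alignment = dict(anchor_alignment)
        queries = annotations.loc[annotations["group"] == "DnaEX", "protein_id"]
        for pid in queries:
            cmap = core_rows[pid]
            rec = records_by_id[pid]
            alignment[pid] = "".join(
                rec.sequence[cmap[c]] if c in cmap else "-" for c in range(1, n_cols + 1)
            )
        tree = bootstrap_support(
            alignment, n_reps=bootstrap_reps, seed=int(rng.integers(0, 2**31 - 1))
        )
        tree_newick = tree_to_newick(tree)
        for idx, pid in queries.items():
            group = assign_by_clade(tree, anchor_groups, pid)
            if group is not None:
                annotations.loc[idx, "group"] = group
                annotations.loc[idx, "confidence"] = "clade"
                annotations.loc[idx, "evidence"] = "clade_assignment"

    genome_profiles = []
    for gid in kept:
        sub = annotations[annotations["genome_id"] == gid] if len(annotations) else annotations
        counts = sub["group"].value_counts().to_dict() if len(sub) else {}
        genome_profiles.append(GenomeProfile(genome_id=gid, group_counts=counts))

    combination_table = tabulate_combinations(genome_profiles)
    size_fractions = binned_fractions(genomes, genome_profiles, "size_bp", DEFAULT_SIZE_EDGES)
    gc_fractions = binned_fractions(genomes, genome_profiles, "gc_percent", DEFAULT_GC_EDGES)
    oxygen_table = oxygen_breakdown(genomes, genome_profiles)

    dnae2_stat = None
    if len(annotations):
        dnae2 = annotations[annotations["group"] == "DnaE2"]
        if len(dnae2) >= 3:
            gcs = [genomes[g].gc_percent for g in dnae2["genome_id"]]
            dnae2_stat = spearman(dnae2["core_length"].tolist(), gcs)

    return PipelineResult(
        kept_genomes=list(kept),
        annotations=annotations,
        genome_profiles=genome_profiles,
        combination_table=combination_table,
        size_fractions=size_fractions,
        gc_fractions=gc_fractions,
        oxygen_table=oxygen_table,
        dnae2_core_gc=dnae2_stat,
        tree_newick=tree_newick,
    )


def run_cohort_pipeline(
    cohort: Cohort,
    seed: int = 0,
    p_threshold: float = 1e-3,
    use_tree: bool = True,
    bootstrap_reps: int = 100,
    dedup: bool = True,
) -> PipelineResult:
    """Convenience wrapper running the chain on a synthetic cohort."""
    profiles = cohort.library.build_profiles()
    anchors, anchor_groups = (
        cohort.library.anchor_cores() if use_tree else ({}, {})
    )
    return run_pipeline(
        cohort.genomes,
        cohort.proteomes,
        profiles,
        cohort.library.site_config,
        seed=seed,
        p_threshold=p_threshold,
        anchor_alignment=anchors or None,
        anchor_groups=anchor_groups or None,
        bootstrap_reps=bootstrap_reps,
        dedup=dedup,
    )


def recovery_rates(cohort: Cohort, result: PipelineResult) -> dict[str, float]:
    """Fraction of polymerases / genomes whose labels match planted truth."""
    truth = cohort.polymerase_truth.set_index("protein_id")
    ann = result.annotations.set_index("protein_id") if len(result.annotations) else None
    if ann is None or not len(truth):
        return {"polymerase_recovery": 0.0, "combination_recovery": 0.0}
    matched = 0
    for pid, row in truth.iterrows():
        if pid in ann.index and ann.loc[pid, "group"] == row["group"]:
            matched += 1
    pol_rate = matched / len(truth)
    genome_truth = cohort.genome_truth.set_index("genome_id")["combination"]
    labels = {p.genome_id: p.combination_label for p in result.genome_profiles}
    genome_matched = sum(
        1 for gid, combo in genome_truth.items() if labels.get(gid) == combo
    )
    return {
        "polymerase_recovery": pol_rate,
        "combination_recovery": genome_matched / len(genome_truth),
    }
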