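"""End-to-end pipeline orchestration: simulate -> map -> call -> filter /
consensus -> heteroplasmy -> evaluate, reproducible from one seed.

`run_sim_pipeline` is the in-memory engine used by the benchmark designs;
`run_pipeline` materializes a full run directory (FASTQ, SAM, VCF, consensus
FASTA, truth and report tables, log); `replicate_study` sweeps a
contamination-rate grid with replicates and returns a simulation-benchmark
table (simulated CR, tested CR, AF design, confusion counts, metrics).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cns
from . import evaluation as ev
from .calling import VariantCall, apply_call_filters, build_pileup, call_variants
from .consensus import FilterPattern, apply_pattern, build_consensus
from .heteroplasmy import af_bin_profile, select_heteroplasmy_sites
from .mapping import (
    ReadIndex,
    deduplicate,
    estimate_damage_profile,
    filter_ambiguous,
    map_reads,
    rescale_qualities,
    write_sam,
)
from .reference import CircularReference, MtVariant, load_reference, packaged_reference
from .simulate import (
    DamageParams,
    SimulationConfig,
    SimulationResult,
    random_snp_set,
    simulate_dataset,
    write_fastq,
    write_truth,
)

logger = logging.getLogger("paleomito")

# the four variant positions the benchmark treats as never-reported rare
# reference polymorphisms, plus the N-placeholder artifact site
RARE_POLYMORPHISM_SITES = (1189, 4769, 7028, 8860)


@dataclass
class PipelineResult:
    """All intermediates of one in-memory pipeline run."""

    sim: SimulationResult
    alignments: list
    kept_alignments: list
    removed: list
    rejected: list
    damage_profile: object
    pileup: object
    calls: list[VariantCall]
    retained: list[VariantCall]
    consensus: cns.ConsensusSequence
    tested_cr: float
    pattern: FilterPattern


def run_sim_pipeline(
    config: SimulationConfig,
    tested_cr: float,
    pattern: FilterPattern | None = None,
    rescale: bool = True,
    min_bq: int = 20,
    min_mq: int = 30,
    delta: int = 0,
) -> PipelineResult:
    """Simulate a library and push it through mapping, calling and filtering.

    ``tested_cr`` plays the role of the externally estimated contamination
    rate handed to the call filters (in simulation mode the true rate is
    also known and may be passed here for correct-CR experiments).
    """
    pattern = pattern or FilterPattern(cr_mode="mean", min_ad=10, min_af_pct=50)
    t0 = time.perf_counter()
    sim = simulate_dataset(config)
    index = ReadIndex(config.reference, sim.decoys)
    alignments, rejected = map_reads(sim.reads, index)
    alignments = deduplicate(alignments, sim.reads)
    nondup = [a for a in alignments if not a.duplicate]
    profile = estimate_damage_profile(nondup, sim.reads, config.reference)
    reads = (
        rescale_qualities(nondup, sim.reads, config.reference, profile)
        if rescale
        else sim.reads
    )
    kept, removed = filter_ambiguous(nondup, delta=delta, min_mapq=min_mq)
    pileup = build_pileup(kept, reads, config.reference, min_bq=min_bq, min_mq=min_mq)
    calls = call_variants(pileup)
    calls = apply_call_filters(calls, cr=tested_cr)
    retained = apply_pattern(calls, pattern, cr_mean=tested_cr, cr_high=tested_cr)
    consensus_seq = build_consensus(config.reference, retained, pileup.depth_map())
    logger.info(
        "pipeline: %d reads, %d mapped, %d kept, %d calls, %d retained (%.2fs)",
        len(sim.reads),
        len(alignments),
        len(kept),
        len(calls),
        len(retained),
        time.perf_counter() - t0,
    )
    return PipelineResult(
        sim=sim,
        alignments=alignments,
        kept_alignments=kept,
        removed=removed,
        rejected=rejected,
        damage_profile=profile,
        pileup=pileup,
        calls=calls,
        retained=retained,
        consensus=consensus_seq,
        tested_cr=tested_cr,
        pattern=pattern,
    )


# ---------------------------------------------------------------------------
# Benchmark designs


def homoplasmic_design(
    ref: CircularReference,
    seed: int,
    contamination_rate: float = 0.02,
    coverage: float = 100.0,
    n_variants: int = 36,
    damage: DamageParams | None = None,
) -> SimulationConfig:
    """The homoplasmic benchmark: an endogenous haplotype differing from the
    reference at 36 SNPs (four placed at the rare-polymorphism positions the
    evaluation excludes), damage on, undamaged contaminant identical to the
    reference."""
    variants = random_snp_set(
        ref, n=n_variants, seed=seed, include_positions=RARE_POLYMORPHISM_SITES
    )
    return SimulationConfig(
        reference=ref,
        endogenous_variants=variants,
        endogenous_coverage=coverage,
        contamination_rate=contamination_rate,
        damage=damage if damage is not None else DamageParams(),
        seed=seed,
    )


def mixture_design(
    ref: CircularReference,
    seed: int,
    contamination_rate: float = 0.02,
    coverage: float = 100.0,
    mutant_fraction: float = 0.30,
    n_variants: int = 36,
    damage: DamageParams | None = None,
) -> SimulationConfig:
    """The heteroplasmy benchmark: reference-identical haplotype A mixed with
    a 36-SNP mutant haplotype B at 30% of the endogenous coverage, so sites
    where the haplotypes differ carry an expected AF of 0.30*(1-CR).

    Damage defaults to off in this design: with the strict <2-mismatch
    mapping-quality convention, terminal damage preferentially removes
    variant-carrying reads and biases the measured minor-allele fraction
    downward (see the methods note)."""
    variants = random_snp_set(
        ref, n=n_variants, seed=seed, include_positions=RARE_POLYMORPHISM_SITES
    )
    return SimulationConfig(
        reference=ref,
        endogenous_variants=(),
        mixture=(variants, mutant_fraction),
        endogenous_coverage=coverage,
        contamination_rate=contamination_rate,
        damage=damage if damage is not None else DamageParams.none(),
        seed=seed,
    )


def evaluate_run(
    result: PipelineResult,
    exclusions: ev.ExclusionLists | None = None,
    exclude_reference: bool = False,
) -> tuple[ev.ConfusionCounts, ev.Metrics]:
    """Score retained calls against the simulation truth set.

    Default convention matches the simulation benchmark: excluded positions
    are removed from the test set only, so never-reported truth variants
    count as FN."""
    exclusions = exclusions or ev.ExclusionLists()
    truth = [e.variant for e in result.sim.truth.entries]
    counts, _ = ev.classify_calls(
        result.retained,
        truth,
        exclusions=exclusions,
        genome_length=result.sim.config.reference.length,
        exclude_reference=exclude_reference,
    )
    return counts, ev.compute_metrics(counts)


def replicate_study(
    ref: CircularReference,
    cr_grid=(0.02, 0.1, 0.2, 0.3, 0.4),
    n_replicates: int = 1,
    design: str = "homoplasmic",
    tested_cr: float | None = None,
    base_seed: int = 1,
    pattern: FilterPattern | None = None,
) -> pd.DataFrame:
    """Sweep simulated contamination rates with replicates.

    ``tested_cr`` defaults to the simulated (correct) rate; pass a scalar to
    reproduce wrongly-estimated-CR experiments.  Returns one row per
    (simulated CR, replicate) in the simulation-benchmark layout.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for cr in cr_grid:
        for rep in range(n_replicates):
            seed = (base_seed + 7919 * rep + int(round(cr * 1000))) % (2**31)
            if design == "homoplasmic":
                config = homoplasmic_design(ref, seed=seed, contamination_rate=cr)
                af_design = 100
            elif design == "mixture":
                config = mixture_design(ref, seed=seed, contamination_rate=cr)
                af_design = 30
            else:
                raise ValueError(f"unknown design {design!r}")
            used_cr = cr if tested_cr is None else tested_cr
            result = run_sim_pipeline(config, tested_cr=used_cr, pattern=pattern)
            counts, metrics = evaluate_run(result)
            row = {
                "simulated_cr_pct": 100 * cr,
                "tested_cr_pct": 100 * used_cr,
                "af_design_pct": af_design,
                "replicate": rep,
                "TP": counts.tp,
                "TN": counts.tn,
                "FP": counts.fp,
                "FN": counts.fn,
            }
            row.update({k.rstrip("_").upper(): v for k, v in metrics.as_dict().items()})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run directory orchestration


@dataclass
class RunConfig:
    """Configuration for a materialized end-to-end run."""

    output_dir: Path
    reference_path: Path | None = None  # None -> packaged synthetic reference
    seed: int = 1
    design: str = "homoplasmic"  # or "mixture"
    contamination_rate: float = 0.02
    tested_cr: float | None = None
    coverage: float = 100.0
    pattern: str = "AD10,AF50,CR=mean"
    blacklist: tuple[int, ...] = tuple(sorted(ev.DEFAULT_BLACKLIST))
    rcrs_rare: tuple[int, ...] = tuple(sorted(ev.DEFAULT_RCRS_RARE))
    write_sam_file: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        data["output_dir"] = Path(data["output_dir"])
        if data.get("reference_path"):
            data["reference_path"] = Path(data["reference_path"])
        for key in ("blacklist", "rcrs_rare"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write all artifacts into the run directory.

    Identical config + seed yields identical artifacts and report JSON.
    Returns the report dictionary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    ref = (
        load_reference(config.reference_path)
        if config.reference_path
        else packaged_reference()
    )
    if config.design == "homoplasmic":
        sim_config = homoplasmic_design(
            ref, seed=config.seed, contamination_rate=config.contamination_rate,
            coverage=config.coverage,
        )
    elif config.design == "mixture":
        sim_config = mixture_design(
            ref, seed=config.seed, contamination_rate=config.contamination_rate,
            coverage=config.coverage,
        )
    else:
        raise ValueError(f"unknown design {config.design!r}")
    tested_cr = (
        config.tested_cr if config.tested_cr is not None else config.contamination_rate
    )
    pattern = FilterPattern.parse(config.pattern)
    result = run_sim_pipeline(sim_config, tested_cr=tested_cr, pattern=pattern)

    write_fastq(result.sim.reads, out / "reads.fastq")
    write_truth(result.sim.truth, out / "truth.tsv")
    if config.write_sam_file:
        write_sam(
            result.kept_alignments, result.sim.reads, ref, result.sim.decoys,
            out / "alignments.sam",
        )
    from .vcfio import write_vcf

    write_vcf(result.calls, "sim", out / "calls.vcf", ref=ref)
    result.consensus.write("consensus", out / "consensus.fasta")

    exclusions = ev.ExclusionLists(
        blacklist=frozenset(config.blacklist), rcrs_rare=frozenset(config.rcrs_rare)
    )
    counts, metrics = evaluate_run(result, exclusions=exclusions)
    het = af_bin_profile(select_heteroplasmy_sites(result.calls), sample="sim")
    report = {
        "seed": config.seed,
        "design": config.design,
        "contamination_rate": config.contamination_rate,
        "tested_cr": tested_cr,
        "pattern": pattern.label(),
        "n_reads": len(result.sim.reads),
        "n_mapped": len(result.alignments),
        "n_kept": len(result.kept_alignments),
        "n_calls": len(result.calls),
        "n_retained": len(result.retained),
        "consensus_coverage_pct": result.consensus.coverage_pct,
        "consensus_mean_depth": result.consensus.mean_depth,
        "confusion": {"TP": counts.tp, "TN": counts.tn, "FP": counts.fp, "FN": counts.fn},
        "metrics": {k: v for k, v in metrics.as_dict().items()},
        "heteroplasmy_bins": het.bin_counts,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
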