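"""End-to-end orchestration of the two-arm concordance study.

One "arm" is a sampling method applied to the 14 study individuals:
simulated multiplexed reads -> demultiplexing -> (optional contaminant
screen) -> de novo reference from the arm's own reads -> read mapping and
genotype-likelihood calling -> SNP filter cascade -> Gibbs admixture genotype
probabilities.  The study runs two arms that share genotypes and compares
their PCA ordinations by symmetric Procrustes, optionally also after mapping
both arms to a shared control reference built from a third read pool.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import concord, io
from .admixture import GenoProbMatrix, MCMCConfig, genotype_probabilities
from .demux import DemuxReport, SampleReadSet, demultiplex, screen_contaminants
from .errors import ConfigError
from .genolik import SNPTable, genotype_all
from .refbuild import ContigSet, build_reference
from .simulate import (
    MethodProfile,
    MultiplexedReads,
    SimConfig,
    TruthSet,
    config_from_dict,
    config_to_dict,
    simulate_method_reads,
    simulate_truth,
)
from .snpfilter import FilterLedger, FilterParams, apply_cascade


@dataclass
class PipelineParams:
    """Every tunable stage parameter with its field-standard default."""

    max_barcode_mismatches: int = 0
    min_contaminant_identity: float = 0.9
    ref_min_copies: int = 4
    ref_min_individuals: int = 4
    cluster_identity: float = 0.80
    map_min_identity: float = 0.9
    min_allele_count: int = 2
    gl_error_rate: float = 0.01
    filters: FilterParams = field(default_factory=FilterParams)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    rhat_threshold: float = 1.2
    rhat_strict: bool = False  # warn-and-proceed by default; see docs/methods.md
    n_axes: int = 2
    concordance_threshold: float = 0.95

    def validate(self) -> None:
        if not (0.0 < self.filters.min_maf <= 0.5):
            raise ConfigError("min_maf must be in (0, 0.5]")
        if not (0.0 < self.filters.min_presence <= 1.0):
            raise ConfigError("min_presence must be in (0, 1]")
        if not (0.5 <= self.cluster_identity <= 1.0):
            raise ConfigError("cluster_identity must be in [0.5, 1]")
        if not (0.5 <= self.map_min_identity <= 1.0):
            raise ConfigError("map_min_identity must be in [0.5, 1]")
        if not (0.0 < self.gl_error_rate < 0.5):
            raise ConfigError("gl_error_rate must be in (0, 0.5)")
        self.mcmc.validate()


@dataclass
class ArmResult:
    """Everything one arm's analysis produced."""

    label: str
    design: str  # "own" or "control"
    sample_ids: list[str]
    read_counts: dict[str, int]
    demux_report: DemuxReport
    contigs: ContigSet
    snp_table_raw: SNPTable
    snp_table: SNPTable
    ledger: FilterLedger
    gprobs: GenoProbMatrix


@dataclass
class StudyResult:
    truth: TruthSet
    arms: dict[str, ArmResult]  # keyed "label:design"
    concordance: concord.ConcordanceResult


def analyse_arm(
    samples: dict[str, SampleReadSet],
    contigs: ContigSet,
    label: str,
    design: str,
    read_counts: dict[str, int],
    demux_report: DemuxReport,
    params: PipelineParams,
    seed: int,
) -> ArmResult:
    """Genotype, filter, and compute genotype probabilities against a reference."""
    table_raw, _ = genotype_all(
        samples,
        contigs,
        min_identity=params.map_min_identity,
        min_allele_count=params.min_allele_count,
        error_rate=params.gl_error_rate,
        method="auto",
    )
    filters = dataclasses.replace(params.filters, thin_seed=seed)
    table, ledger = apply_cascade(table_raw, filters)
    mcmc = dataclasses.replace(params.mcmc, seed=seed)
    site_labels = [f"{c}:{p}" for c, p in zip(table.contig_ids, table.positions)]
    gprobs = genotype_probabilities(
        table.gl,
        mcmc,
        sample_ids=table.sample_ids,
        site_labels=site_labels,
        rhat_threshold=params.rhat_threshold,
        override=not params.rhat_strict,
    )
    return ArmResult(
        label=label,
        design=design,
        sample_ids=list(samples),
        read_counts=read_counts,
        demux_report=demux_report,
        contigs=contigs,
        snp_table_raw=table_raw,
        snp_table=table,
        ledger=ledger,
        gprobs=gprobs,
    )


def run_arm(
    truth: TruthSet,
    profile: MethodProfile,
    label: str,
    seed: int,
    params: PipelineParams | None = None,
    contaminants: list[str] | None = None,
    reference: ContigSet | None = None,
) -> tuple[ArmResult, MultiplexedReads]:
    """Simulate and analyse one arm.

    With ``reference=None`` the arm is analysed against a de novo reference
    built from its own reads ("own" design); otherwise against the given
    (control) reference.
    """
    params = params or PipelineParams()
    params.validate()
    pool = simulate_method_reads(truth, profile, seed=seed, arm=label)
    from .demux import BarcodeMap

    samples, report = demultiplex(
        pool, BarcodeMap(pool.barcode_map), max_mismatches=params.max_barcode_mismatches
    )
    if contaminants:
        for sid in samples:
            samples[sid], _ = screen_contaminants(
                samples[sid], contaminants, params.min_contaminant_identity
            )
    if reference is None:
        contigs, _ = build_reference(
            samples,
            min_copies=params.ref_min_copies,
            min_individuals=params.ref_min_individuals,
            identity_threshold=params.cluster_identity,
            label=f"{label}-only",
        )
        design = "own"
    else:
        contigs, design = reference, "control"
    arm = analyse_arm(
        samples, contigs, label, design, pool.per_individual_reads, report, params, seed
    )
    return arm, pool


def run_study(
    sim_config: SimConfig | None = None,
    params: PipelineParams | None = None,
    seed: int | None = None,
    designs: tuple[str, ...] = ("own",),
    arm_labels: tuple[str, str] = ("tissue", "swab"),
) -> StudyResult:
    """Run the full two-arm study and produce the concordance report.

    ``designs`` selects which Procrustes comparisons to run: "own" (each arm
    mapped to its own de novo reference) and/or "control" (both arms mapped to
    a shared reference built from a control read pool).
    """
    sim_config = sim_config or SimConfig()
    params = params or PipelineParams()
    params.validate()
    sim_config.validate()
    if seed is not None:
        sim_config = dataclasses.replace(sim_config, seed=seed)
    truth = simulate_truth(sim_config)
    base = np.random.SeedSequence(sim_config.seed).generate_state(4) % (2**31 - 1)
    arms: dict[str, ArmResult] = {}
    a_label, b_label = arm_labels
    arm_a, _ = run_arm(truth, sim_config.profiles[a_label], a_label, int(base[0]), params)
    arm_b, _ = run_arm(truth, sim_config.profiles[b_label], b_label, int(base[1]), params)
    arms[f"{a_label}:own"] = arm_a
    arms[f"{b_label}:own"] = arm_b
    arm_a_ctrl = arm_b_ctrl = None
    if "control" in designs:
        control_pool = simulate_method_reads(
            truth, sim_config.profiles["control"], seed=int(base[2]), arm="control"
        )
        from .demux import BarcodeMap

        control_samples, _ = demultiplex(control_pool, BarcodeMap(control_pool.barcode_map))
        control_ref, _ = build_reference(
            control_samples,
            min_copies=params.ref_min_copies,
            min_individuals=params.ref_min_individuals,
            identity_threshold=params.cluster_identity,
            label="control",
        )
        arm_a_ctrl, _ = run_arm(
            truth, sim_config.profiles[a_label], a_label, int(base[0]), params,
            reference=control_ref,
        )
        arm_b_ctrl, _ = run_arm(
            truth, sim_config.profiles[b_label], b_label, int(base[1]), params,
            reference=control_ref,
        )
        arms[f"{a_label}:control"] = arm_a_ctrl
        arms[f"{b_label}:control"] = arm_b_ctrl
    report = concord.concordance_report(
        arm_a,
        arm_b,
        arm_a_control=arm_a_ctrl,
        arm_b_control=arm_b_ctrl,
        n_axes=params.n_axes,
        threshold=params.concordance_threshold,
    )
    return StudyResult(truth=truth, arms=arms, concordance=report)


def load_config(path: str | Path) -> tuple[SimConfig, PipelineParams, dict]:
    """Load a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_top = {"simulation", "pipeline", "designs", "output"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    sim = config_from_dict(raw.get("simulation", {}))
    pdict = dict(raw.get("pipeline", {}))
    known = {f.name for f in dataclasses.fields(PipelineParams)}
    unknown = set(pdict) - known
    if unknown:
        raise ConfigError(f"unknown pipeline keys: {sorted(unknown)}")
    if "filters" in pdict:
        fknown = {f.name for f in dataclasses.fields(FilterParams)}
        funknown = set(pdict["filters"]) - fknown
        if funknown:
            raise ConfigError(f"unknown filter keys: {sorted(funknown)}")
        pdict["filters"] = FilterParams(**pdict["filters"])
    if "mcmc" in pdict:
        m = dict(pdict["mcmc"])
        preset = m.pop("preset", None)
        if preset:
            pdict["mcmc"] = MCMCConfig.preset(preset, **m)
        else:
            pdict["mcmc"] = MCMCConfig(**m)
    params = PipelineParams(**pdict)
    params.validate()
    extras = {"designs": tuple(raw.get("designs", ["own"])), "output": raw.get("output")}
    return sim, params, extras


def write_study_artifacts(result: StudyResult, outdir: str | Path, seed: int | None = None) -> None:
    """Write TSV/VCF/FASTA/JSON artifacts plus a reproducibility manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_truth_tables(result.truth, outdir / "truth")
    for key, arm in result.arms.items():
        tag = key.replace(":", "_")
        arm.contigs.to_fasta(outdir / f"{tag}_reference.fasta")
        io.write_vcf(arm.snp_table, outdir / f"{tag}_filtered.vcf")
        arm.ledger.to_tsv(outdir / f"{tag}_filter_ledger.tsv")
        io.write_gprobs_tsv(arm.gprobs, outdir / f"{tag}_gprobs.tsv")
        arm.demux_report.to_tsv(outdir / f"{tag}_demux.tsv")
    io.write_manifest(
        outdir / "manifest.json",
        seed=seed if seed is not None else result.truth.config.seed,
        simulation=config_to_dict(result.truth.config),
        concordance=result.concordance.to_dict(),
    )
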