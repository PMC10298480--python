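"""The SNP filter cascade and its per-stage ledger.

Stages, in order: biallelic -> presence (>= 80% of individuals with data) ->
depth floor (summed site depth >= 2n) -> paralog depth (site mean depth above
assembly-wide mean + 2 SD) -> mapping quality (site MQ >= 30) -> allele
quality rank tests (Mann-Whitney U on base and mapping qualities of
reference- vs alternative-allele reads, |z| > 1.96 removes) -> minor allele
frequency (>= 0.05) -> random thinning to one SNP per contig.  Every stage
appends a ledger row with sites in, removed, and out, and the ledger is
conservation-checked.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError
from .genolik import SNPTable, estimate_allele_freqs


@dataclass
class FilterStage:
    name: str
    params: dict
    sites_in: int
    sites_removed: int
    sites_out: int


@dataclass
class FilterLedger:
    stages: list[FilterStage] = field(default_factory=list)

    def append(self, stage: FilterStage) -> None:
        if stage.sites_in != stage.sites_removed + stage.sites_out:
            raise InputError(f"ledger conservation violated at stage {stage.name!r}")
        if self.stages and self.stages[-1].sites_out != stage.sites_in:
            raise InputError(
                f"stage {stage.name!r} input ({stage.sites_in}) does not match previous "
                f"stage output ({self.stages[-1].sites_out})"
            )
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "params": ";".join(f"{k}={v}" for k, v in s.params.items()),
                    "sites_in": s.sites_in,
                    "sites_removed": s.sites_removed,
                    "sites_out": s.sites_out,
                }
                for s in self.stages
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _stage(table: SNPTable, keep: np.ndarray, name: str, params: dict) -> tuple[SNPTable, FilterStage]:
    keep = np.asarray(keep, dtype=bool)
    st = FilterStage(name, params, table.n_sites, int((~keep).sum()), int(keep.sum()))
    return table.subset(keep), st


def biallelic_filter(table: SNPTable) -> tuple[SNPTable, FilterStage]:
    """Keep sites flagged biallelic at discovery (no third allele at count)."""
    return _stage(table, table.biallelic, "biallelic", {})


def presence_filter(table: SNPTable, min_fraction: float = 0.8) -> tuple[SNPTable, FilterStage]:
    """Keep sites with data in at least ceil(min_fraction * n) individuals.

    "At least 80%" rounds up: with n = 14 a site must be present in 12
    individuals (ceil(11.2)), so presence in 11 is removed.
    """
    n = table.n_individuals
    need = math.ceil(min_fraction * n)
    present = (table.total_depth >= 1).sum(axis=1)
    return _stage(table, present >= need, "presence", {"min_fraction": min_fraction, "need": need})


def depth_floor_filter(
    table: SNPTable, per_individual: float = 2.0, n: int | None = None
) -> tuple[SNPTable, FilterStage]:
    """Keep sites whose summed depth over individuals is >= 2n (inclusive).

    Equivalent to a mean per-individual depth of at least ``per_individual``.
    """
    if n is None:
        n = table.n_individuals
    floor = per_individual * n
    total = table.total_depth.sum(axis=1)
    return _stage(table, total >= floor, "depth_floor", {"min_total_depth": floor})


def paralog_depth_filter(table: SNPTable, n_sd: float = 2.0) -> tuple[SNPTable, FilterStage]:
    """Remove sites with exceptionally high depth (collapsed-paralog signature).

    A site's mean per-individual depth must not exceed the assembly-wide mean
    plus ``n_sd`` standard deviations of the per-site means, computed once
    before any removal (single pass; strict >).  With fewer than two sites the
    SD is undefined and the stage passes everything through with a warning.
    """
    if table.n_sites < 2:
        if table.n_sites:
            warnings.warn("paralog depth filter skipped: fewer than 2 sites", stacklevel=2)
        return _stage(table, np.ones(table.n_sites, dtype=bool), "paralog_depth", {"n_sd": n_sd})
    site_mean = table.total_depth.mean(axis=1)
    cutoff = site_mean.mean() + n_sd * site_mean.std(ddof=0)
    return _stage(table, ~(site_mean > cutoff), "paralog_depth", {"n_sd": n_sd, "cutoff": round(float(cutoff), 3)})


def mapping_quality_filter(table: SNPTable, min_mq: float = 30.0) -> tuple[SNPTable, FilterStage]:
    """Keep sites with site mapping quality >= min_mq (kept at exactly 30)."""
    return _stage(table, table.site_mq >= min_mq, "mapping_quality", {"min_mq": min_mq})


def mann_whitney_z(values_ref, values_alt, continuity: bool = False) -> float:
    """Mann-Whitney U z-score for the reference- vs alternative-allele group.

    Midrank tie handling with the tie-corrected normal-approximation variance
    sigma^2 = n1*n2/12 * ((n+1) - sum(t^3 - t)/(n*(n-1))).  U is counted for
    the reference group; all-tied input gives z = 0.  ``continuity`` applies
    the 0.5 continuity correction toward zero.
    """
    x = np.asarray(values_ref, dtype=float)
    y = np.asarray(values_alt, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = rankdata(np.concatenate([x, y]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, t = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 0.0
    d = u1 - mu
    if continuity and d != 0:
        d -= 0.5 * np.sign(d)
    return float(d / math.sqrt(sigma2))


def allele_quality_filter(
    table: SNPTable, z_cutoff: float = 1.96, continuity: bool = False
) -> tuple[SNPTable, FilterStage]:
    """Remove sites where ref- and alt-allele reads differ in base or mapping
    quality (|z| > z_cutoff on either Mann-Whitney test, strict).

    A site with an empty allele group skips that test (treated as a pass).
    """
    keep = np.ones(table.n_sites, dtype=bool)
    for s in range(table.n_sites):
        for ref_vals, alt_vals in ((table.bq_ref[s], table.bq_alt[s]), (table.mq_ref[s], table.mq_alt[s])):
            if len(ref_vals) == 0 or len(alt_vals) == 0:
                continue
            z = mann_whitney_z(ref_vals, alt_vals, continuity=continuity)
            if abs(z) > z_cutoff:
                keep[s] = False
                break
    return _stage(table, keep, "allele_quality_mw", {"z_cutoff": z_cutoff})


def maf_filter(
    table: SNPTable, min_maf: float = 0.05, error_rate: float = 0.01
) -> tuple[SNPTable, FilterStage]:
    """Keep sites with minor allele frequency >= min_maf (kept at exactly 0.05).

    Frequencies come from the EM maximum-likelihood estimates over genotype
    likelihoods; they are computed here if not already present.
    """
    if np.isnan(table.allele_freq).any():
        estimate_allele_freqs(table, error_rate)
    maf = np.minimum(table.allele_freq, 1.0 - table.allele_freq)
    return _stage(table, maf >= min_maf, "maf", {"min_maf": min_maf})


def _contig_rng(seed: int, contig_id: str) -> np.random.Generator:
    digest = hashlib.blake2b(f"{seed}|{contig_id}".encode(), digest_size=8).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))


def thin_one_per_contig(table: SNPTable, seed: int = 0) -> tuple[SNPTable, FilterStage]:
    """Keep one uniformly random SNP per contig (linkage thinning).

    The per-contig choice is seeded by hashing the contig id with the global
    seed, so survivorship is stable under contig reordering.  Output is sorted
    by (contig, position).
    """
    keep = np.zeros(table.n_sites, dtype=bool)
    by_contig: dict[str, list[int]] = {}
    for s, cid in enumerate(table.contig_ids):
        by_contig.setdefault(cid, []).append(s)
    for cid, sites in by_contig.items():
        sites = sorted(sites, key=lambda s: table.positions[s])
        pick = sites[int(_contig_rng(seed, cid).integers(len(sites)))]
        keep[pick] = True
    out, st = _stage(table, keep, "thin_one_per_contig", {"seed": seed})
    order = np.lexsort((out.positions, out.contig_ids.astype(str)))
    return out.subset(order), st


@dataclass
class FilterParams:
    """Thresholds of the cascade, with their field-standard defaults."""

    min_presence: float = 0.8
    depth_floor_per_individual: float = 2.0
    paralog_n_sd: float = 2.0
    min_mq: float = 30.0
    mw_z_cutoff: float = 1.96
    mw_continuity: bool = False
    min_maf: float = 0.05
    error_rate: float = 0.01
    thin_seed: int = 0


def apply_cascade(table: SNPTable, params: FilterParams | None = None) -> tuple[SNPTable, FilterLedger]:
    """Run the full cascade in its fixed order and return the survivors + ledger."""
    params = params or FilterParams()
    ledger = FilterLedger()
    table, st = biallelic_filter(table)
    ledger.append(st)
    table, st = presence_filter(table, params.min_presence)
    ledger.append(st)
    table, st = depth_floor_filter(table, params.depth_floor_per_individual)
    ledger.append(st)
    table, st = paralog_depth_filter(table, params.paralog_n_sd)
    ledger.append(st)
    table, st = mapping_quality_filter(table, params.min_mq)
    ledger.append(st)
    table, st = allele_quality_filter(table, params.mw_z_cutoff, params.mw_continuity)
    ledger.append(st)
    table, st = maf_filter(table, params.min_maf, params.error_rate)
    ledger.append(st)
    table, st = thin_one_per_contig(table, params.thin_seed)
    ledger.append(st)
    return table, ledger
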