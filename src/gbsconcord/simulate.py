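"""Synthetic genotyping-by-sequencing (GBS) data with known ground truth.

The generator emulates a two-arm replicate design: the same diploid
individuals are "sampled" twice, once under a tissue-biopsy-like sequencing
profile (high read yield, broad locus capture, low per-locus depth) and once
under a visceral-swab-like profile (low yield, narrow capture, high per-locus
depth).  Genotypes are drawn once per individual and shared by both arms, so
downstream concordance between arms can be evaluated against a known truth.

Model
-----
* Loci are independent random fragments of 84-86 bp (the post-trim read
  length of EcoRI/MseI GBS libraries; the underlying 300-400 bp fragment
  size is carried as metadata only).
* Each locus carries a fixed number of biallelic variant sites with minor
  allele frequency drawn uniformly on a configurable range; haplotypes are
  drawn independently per allele copy, i.e. genotypes are Hardy-Weinberg.
* Individuals belong to two collection sites that are labels only: allele
  frequencies are shared between sites unless ``site_divergence`` is raised.
* Per-individual read totals are normal draws (truncated at zero) so that
  mean +/- SD yield profiles are directly representable.
* Reads are allocated to the arm's capturable loci by a Dirichlet-multinomial;
  ``depth_overdispersion`` is the Dirichlet concentration, so small values
  concentrate reads on few loci (depth at the cost of breadth).
* Each read is ``barcode + locus haplotype`` with independent per-base
  substitution errors; base qualities come from a two-component model (high
  for correct bases, low for error bases) so quality-based filters downstream
  have signal to act on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._seq import decode, phred_to_ascii
from .errors import ConfigError

#: Desk-scale method profiles: per-individual read yields representative of
#: field data (tissue 1,608,863 +/- 307,130; swab 518,985 +/- 238,072) scaled
#: by 1/100, preserving the ~3.1x yield ratio, combined with the breadth/depth
#: contrast that distinguishes the two sampling methods.
TISSUE_LIKE: "MethodProfile"
SWAB_LIKE: "MethodProfile"
CONTROL_LIKE: "MethodProfile"


@dataclass(frozen=True)
class MethodProfile:
    """Sequencing-yield profile of one sampling method.

    Parameters
    ----------
    mean_reads, sd_reads:
        Mean and SD of the per-individual total read count (truncated normal).
    capture_breadth:
        Fraction of loci that receive any reads under this method, in (0, 1].
        The capturable subset is drawn once per arm and shared by all
        individuals (capture is a property of the fragment, not the animal).
    depth_overdispersion:
        Dirichlet concentration for allocating an individual's reads across
        the capturable loci; lower values mean more uneven (overdispersed)
        per-locus depth.
    """

    mean_reads: float
    sd_reads: float
    capture_breadth: float
    depth_overdispersion: float = 10.0

    def validate(self) -> None:
        if self.mean_reads <= 0:
            raise ConfigError("mean_reads must be positive")
        if self.sd_reads < 0:
            raise ConfigError("sd_reads must be non-negative")
        if not (0.0 < self.capture_breadth <= 1.0):
            raise ConfigError("capture_breadth must be in (0, 1]")
        if self.depth_overdispersion <= 0:
            raise ConfigError("depth_overdispersion must be positive")


TISSUE_LIKE = MethodProfile(mean_reads=16089, sd_reads=3071, capture_breadth=0.90)
SWAB_LIKE = MethodProfile(mean_reads=5190, sd_reads=2381, capture_breadth=0.15)
CONTROL_LIKE = MethodProfile(mean_reads=16089, sd_reads=3071, capture_breadth=0.98)


@dataclass
class SimConfig:
    """Configuration of the synthetic study."""

    n_individuals: int = 14
    n_loci: int = 2000
    locus_length_range: tuple[int, int] = (84, 86)
    n_variable_sites_per_locus: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    fragment_size_range: tuple[int, int] = (300, 400)  # metadata only
    base_error_rate: float = 0.005
    barcode_length_range: tuple[int, int] = (10, 14)
    n_collection_sites: int = 2
    site_divergence: float = 0.0
    correct_base_quality: tuple[float, float] = (38.0, 2.0)  # mean, sd
    error_base_quality: tuple[float, float] = (15.0, 3.0)
    profiles: dict[str, MethodProfile] = field(
        default_factory=lambda: {
            "tissue": TISSUE_LIKE,
            "swab": SWAB_LIKE,
            "control": CONTROL_LIKE,
        }
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ConfigError("n_individuals must be >= 0")
        if self.n_loci < 0:
            raise ConfigError("n_loci must be >= 0")
        lo, hi = self.locus_length_range
        if not (0 < lo <= hi):
            raise ConfigError("locus_length_range must satisfy 0 < lo <= hi")
        if self.n_variable_sites_per_locus < 0:
            raise ConfigError("n_variable_sites_per_locus must be >= 0")
        if self.n_variable_sites_per_locus > lo:
            raise ConfigError("n_variable_sites_per_locus exceeds locus_length_range")
        flo, fhi = self.maf_range
        if not (0.0 <= flo <= fhi <= 0.5):
            raise ConfigError("maf_range must lie within [0, 0.5]")
        if not (0.0 <= self.base_error_rate < 0.5):
            raise ConfigError("base_error_rate must be in [0, 0.5)")
        blo, bhi = self.barcode_length_range
        if not (1 <= blo <= bhi):
            raise ConfigError("barcode_length_range must satisfy 1 <= lo <= hi")
        if self.n_collection_sites < 1:
            raise ConfigError("n_collection_sites must be >= 1")
        if self.site_divergence < 0:
            raise ConfigError("site_divergence must be >= 0")
        for name, prof in self.profiles.items():
            try:
                prof.validate()
            except ConfigError as exc:
                raise ConfigError(f"profile {name!r}: {exc}") from exc


@dataclass
class TruthSet:
    """Ground truth of a simulated study.

    ``haplotypes[j]`` is an (n_individuals, 2, n_var_sites_j) array of alt
    indicators; genotype dosage is the sum over the two allele copies.
    Both method arms of the same individual share these genotypes.
    """

    config: SimConfig
    sample_ids: list[str]
    collection_site: np.ndarray  # (n_individuals,) site labels
    barcodes: dict[str, str]
    locus_ids: list[str]
    locus_seqs: list[str]
    variant_positions: list[np.ndarray]
    variant_ref: list[list[str]]
    variant_alt: list[list[str]]
    allele_freqs: list[np.ndarray]  # true alt-allele frequency per site
    haplotypes: list[np.ndarray]

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_seqs)

    def dosage_matrix(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """True genotype dosages (n_individuals x total variant sites).

        Returns the matrix and a list of (locus_id, position) column labels.
        """
        cols, labels = [], []
        for j, hap in enumerate(self.haplotypes):
            if hap.shape[2] == 0:
                continue
            cols.append(hap.sum(axis=1))
            labels.extend((self.locus_ids[j], int(p)) for p in self.variant_positions[j])
        if not cols:
            return np.zeros((self.n_individuals, 0), dtype=np.int64), []
        return np.concatenate(cols, axis=1), labels


@dataclass
class MultiplexedReads:
    """A simulated multiplexed FASTQ-equivalent read pool for one arm."""

    arm: str
    names: list[str]
    sequences: list[str]
    qualities: list[str]
    barcode_map: dict[str, str]
    per_individual_reads: dict[str, int]
    capturable_loci: np.ndarray  # bool mask over truth loci
    profile: MethodProfile

    @property
    def n_reads(self) -> int:
        return len(self.sequences)


def _random_barcodes(rng: np.random.Generator, n: int, length_range: tuple[int, int]) -> list[str]:
    """Draw ``n`` unique, mutually prefix-free barcodes."""
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 1000 * (n + 1):
            raise ConfigError("could not draw prefix-free barcodes; widen barcode_length_range")
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        cand = decode(rng.integers(0, 4, size=length).astype(np.uint8))
        if any(cand.startswith(b) or b.startswith(cand) for b in barcodes):
            continue
        barcodes.append(cand)
    return barcodes


def simulate_truth(config: SimConfig) -> TruthSet:
    """Draw locus sequences, variant sites, allele frequencies and genotypes.

    Deterministic given ``config.seed``.  Every variant site is biallelic with
    true minor allele frequency inside ``config.maf_range``; genotypes are
    Hardy-Weinberg draws at that frequency, shared by both method arms.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    sample_ids = [f"ind{i + 1:02d}" for i in range(n)]
    collection_site = np.array(
        [f"site{1 + (i * config.n_collection_sites) // max(n, 1)}" for i in range(n)]
    )
    barcodes = dict(zip(sample_ids, _random_barcodes(rng, n, config.barcode_length_range)))

    locus_ids, locus_seqs = [], []
    variant_positions, variant_ref, variant_alt = [], [], []
    allele_freqs, haplotypes = [], []
    lo, hi = config.locus_length_range
    for j in range(config.n_loci):
        length = int(rng.integers(lo, hi + 1))
        enc = rng.integers(0, 4, size=length).astype(np.uint8)
        nv = config.n_variable_sites_per_locus
        pos = np.sort(rng.choice(length, size=nv, replace=False)) if nv else np.array([], dtype=int)
        refs = [decode(enc[p : p + 1]) for p in pos]
        alts = [decode(np.array([(enc[p] + rng.integers(1, 4)) % 4], dtype=np.uint8)) for p in pos]
        freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=nv)
        # optional allele-frequency divergence between collection sites
        site_shift = (
            rng.normal(0.0, config.site_divergence, size=nv) if config.site_divergence > 0 else 0.0
        )
        site_idx = (collection_site != collection_site[0]).astype(float) if n else np.array([])
        per_ind_freq = np.clip(freqs[None, :] + np.outer(site_idx, np.atleast_1d(site_shift)), 0, 1)
        hap = (rng.random((n, 2, nv)) < per_ind_freq[:, None, :]).astype(np.uint8)
        locus_ids.append(f"locus{j + 1:05d}")
        locus_seqs.append(decode(enc))
        variant_positions.append(pos.astype(int))
        variant_ref.append(refs)
        variant_alt.append(alts)
        allele_freqs.append(freqs)
        haplotypes.append(hap)
    return TruthSet(
        config=config,
        sample_ids=sample_ids,
        collection_site=collection_site,
        barcodes=barcodes,
        locus_ids=locus_ids,
        locus_seqs=locus_seqs,
        variant_positions=variant_positions,
        variant_ref=variant_ref,
        variant_alt=variant_alt,
        allele_freqs=allele_freqs,
        haplotypes=haplotypes,
    )


def _haplotype_sequence(truth: TruthSet, locus: int, allele_vec: np.ndarray) -> np.ndarray:
    from ._seq import encode

    enc = encode(truth.locus_seqs[locus]).copy()
    for p, a, alt in zip(truth.variant_positions[locus], allele_vec, truth.variant_alt[locus]):
        if a:
            enc[p] = encode(alt)[0]
    return enc


def simulate_method_reads(
    truth: TruthSet, profile: MethodProfile, seed: int, arm: str = "arm"
) -> MultiplexedReads:
    """Simulate one arm's multiplexed read pool under a method profile.

    Per-individual totals are truncated-normal draws; reads land on the arm's
    capturable loci via Dirichlet-multinomial allocation; each read is
    barcode + one of the individual's two locus haplotypes, with per-base
    substitution errors at ``base_error_rate`` and Phred+33 qualities from the
    two-component quality model.  Reads are emitted in shuffled (multiplexed)
    order.  Deterministic given (truth, profile, seed).
    """
    profile.validate()
    cfg = truth.config
    rng = np.random.default_rng(seed)
    capturable = rng.random(truth.n_loci) < profile.capture_breadth
    cap_idx = np.flatnonzero(capturable)
    q_hi_mu, q_hi_sd = cfg.correct_base_quality
    q_lo_mu, q_lo_sd = cfg.error_base_quality

    names: list[str] = []
    seqs: list[str] = []
    quals: list[str] = []
    per_ind: dict[str, int] = {}
    hap_cache: dict[tuple[int, tuple[int, ...]], np.ndarray] = {}

    for i, sid in enumerate(truth.sample_ids):
        total = max(0, int(round(rng.normal(profile.mean_reads, profile.sd_reads))))
        per_ind[sid] = total
        if total == 0 or len(cap_idx) == 0:
            if total and len(cap_idx) == 0:
                per_ind[sid] = 0
            continue
        weights = rng.dirichlet(np.full(len(cap_idx), profile.depth_overdispersion))
        counts = rng.multinomial(total, weights)
        bc_enc = np.frombuffer(truth.barcodes[sid].encode(), dtype=np.uint8)
        from ._seq import _ENCODE

        bc_enc = _ENCODE[bc_enc]
        for k in np.flatnonzero(counts):
            locus = int(cap_idx[k])
            c = int(counts[k])
            copies = rng.integers(0, 2, size=c)
            for copy_choice in (0, 1):
                n_c = int((copies == copy_choice).sum())
                if n_c == 0:
                    continue
                allele_vec = truth.haplotypes[locus][i, copy_choice]
                key = (locus, tuple(int(a) for a in allele_vec))
                hap_enc = hap_cache.get(key)
                if hap_enc is None:
                    hap_enc = _haplotype_sequence(truth, locus, allele_vec)
                    hap_cache[key] = hap_enc
                read = np.concatenate([bc_enc, hap_enc])
                mat = np.tile(read, (n_c, 1))
                if cfg.base_error_rate > 0:
                    err = rng.random(mat.shape) < cfg.base_error_rate
                    if err.any():
                        mat[err] = (mat[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
                else:
                    err = np.zeros(mat.shape, dtype=bool)
                q = rng.normal(q_hi_mu, q_hi_sd, size=mat.shape)
                if err.any():
                    q[err] = rng.normal(q_lo_mu, q_lo_sd, size=int(err.sum()))
                q = np.clip(np.rint(q), 2, 40).astype(np.uint8)
                for r in range(n_c):
                    seqs.append(decode(mat[r]))
                    quals.append(phred_to_ascii(q[r]))
    order = rng.permutation(len(seqs))
    seqs = [seqs[o] for o in order]
    quals = [quals[o] for o in order]
    names = [f"{arm}_read{r + 1:07d}" for r in range(len(seqs))]
    return MultiplexedReads(
        arm=arm,
        names=names,
        sequences=seqs,
        qualities=quals,
        barcode_map=dict(truth.barcodes),
        per_individual_reads=per_ind,
        capturable_loci=capturable,
        profile=profile,
    )


def config_to_dict(config: SimConfig) -> dict:
    """JSON/YAML-friendly representation of a :class:`SimConfig`."""
    d = dataclasses.asdict(config)
    d["profiles"] = {k: dataclasses.asdict(v) for k, v in config.profiles.items()}
    return d


def config_from_dict(d: dict) -> SimConfig:
    """Inverse of :func:`config_to_dict`; unknown keys are rejected."""
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    if "profiles" in d:
        profs = {}
        for k, v in d["profiles"].items():
            pknown = {f.name for f in dataclasses.fields(MethodProfile)}
            punknown = set(v) - pknown
            if punknown:
                raise ConfigError(f"unknown profile keys for {k!r}: {sorted(punknown)}")
            profs[k] = MethodProfile(**v)
        d["profiles"] = profs
    for key in ("locus_length_range", "maf_range", "fragment_size_range",
                "barcode_length_range", "correct_base_quality", "error_base_quality"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg
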