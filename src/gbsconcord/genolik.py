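"""Read mapping, site discovery, genotype likelihoods, allele frequencies.

The mapper is a deliberately simple substitute for a full short-read aligner:
each read is placed at its best ungapped offset on its best-identity contig,
with a mapping-quality surrogate derived from the ambiguity between the best
and second-best contig.  Candidate variant sites are pileup columns with two
alleles each supported by a minimum read count; the genotype-likelihood model
is the standard symmetric-error biallelic model, where a read supports the
alternative allele with probability g/2*(1-eps) + (1-g/2)*eps for dosage g.
Population allele frequencies are maximum-likelihood estimates via EM over
genotype posteriors under Hardy-Weinberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import KmerIndex, ascii_to_phred, batch_best_identity, encode, pad_matrix
from .demux import SampleReadSet
from .errors import InputError, ParameterError
from .refbuild import ContigSet

MAX_MAPQ = 60


@dataclass
class AlignmentSet:
    """Per-read placements for one sample, parallel to the read set order.

    ``contig_idx`` is -1 for unmapped reads (below identity, or tied between
    contigs); ``offset`` is the read start on the contig (may be negative when
    the read overhangs); ``mapq`` is the ambiguity-based surrogate.
    """

    sample_id: str
    contig_idx: np.ndarray
    offset: np.ndarray
    mapq: np.ndarray

    @property
    def n_mapped(self) -> int:
        return int((self.contig_idx >= 0).sum())


def _mapq_from_gap(match_gap: int) -> int:
    """round(-10*log10 p_err) with p_err = 1/(1+10^gap), capped at 60.

    ``match_gap`` is the match-count difference between the best and
    second-best contig; a gap of zero is a tie and the read stays unmapped.
    """
    if match_gap >= 7:
        return MAX_MAPQ
    return min(MAX_MAPQ, int(round(10.0 * math.log10(1.0 + 10.0**match_gap))))


def map_reads(
    readset: SampleReadSet,
    contigs: ContigSet,
    min_identity: float = 0.9,
    method: str = "auto",
    seed_k: int = 16,
) -> AlignmentSet:
    """Assign each read to its best-identity contig at the best ungapped offset.

    Reads whose best identity is below ``min_identity``, or that tie between
    two or more contigs at the best identity, are left unmapped.

    ``method``: "full" scans every contig for every read (the exact,
    brute-force behaviour); "kmer" shortlists contigs sharing a ``seed_k``-mer
    with the read (fast, seeded-alignment heuristic); "auto" picks "full" for
    small problems and "kmer" for large ones.
    """
    n_contigs = len(contigs)
    n_reads = readset.n_reads
    out_contig = np.full(n_reads, -1, dtype=np.int64)
    out_offset = np.zeros(n_reads, dtype=np.int64)
    out_mapq = np.zeros(n_reads, dtype=np.int64)
    if n_contigs == 0 or n_reads == 0:
        return AlignmentSet(readset.sample_id, out_contig, out_offset, out_mapq)

    if method == "auto":
        method = "full" if n_reads * n_contigs <= 2_000_000 else "kmer"
    ref_mat, ref_lens = pad_matrix([encode(s) for s in contigs.sequences])
    index = None
    if method == "kmer":
        index = KmerIndex(k=seed_k)
        for ci, s in enumerate(contigs.sequences):
            index.add(ci, s)

    # map unique read sequences once, then broadcast to read positions
    uniq: dict[str, list[int]] = {}
    for r, seq in enumerate(readset.sequences):
        uniq.setdefault(seq, []).append(r)
    for seq, positions in uniq.items():
        enc = encode(seq)
        if index is not None:
            cand = sorted(index.candidates(seq))
            if not cand:
                continue
            cand_idx = np.asarray(cand, dtype=np.int64)
            matches, offsets = batch_best_identity(enc, ref_mat[cand_idx], ref_lens[cand_idx])
            lens = ref_lens[cand_idx]
        else:
            cand_idx = np.arange(n_contigs)
            matches, offsets = batch_best_identity(enc, ref_mat, ref_lens)
            lens = ref_lens
        ident = matches / np.maximum(len(enc), lens)
        best = int(np.argmax(ident))
        if ident[best] < min_identity:
            continue
        best_ident = ident[best]
        ties = np.flatnonzero(ident == best_ident)
        if ties.size > 1:
            continue  # ambiguous between contigs
        if ident.size > 1:
            second_m = int(np.partition(matches, -2)[-2])
            gap = int(matches[best]) - second_m
            mapq = _mapq_from_gap(max(gap, 1))
        else:
            mapq = MAX_MAPQ
        for r in positions:
            out_contig[r] = cand_idx[best]
            out_offset[r] = offsets[best]
            out_mapq[r] = mapq
    return AlignmentSet(readset.sample_id, out_contig, out_offset, out_mapq)


@dataclass
class SNPTable:
    """Biallelic candidate sites with per-individual depths and quality context.

    The substrate of the filter cascade.  Per-site pooled base-quality and
    mapping-quality lists are kept separately for reads carrying the reference
    and the alternative allele, so allele-quality rank tests can act on them.
    ``gl`` holds natural-log genotype likelihoods (site x individual x dosage)
    once :func:`build_gl_matrix` has run; ``allele_freq`` holds EM estimates
    once :func:`estimate_allele_freqs` has run.
    """

    sample_ids: list[str]
    contig_ids: np.ndarray  # (S,) str
    positions: np.ndarray  # (S,) int, 0-based
    ref: np.ndarray  # (S,) str
    alt: np.ndarray  # (S,) str
    biallelic: np.ndarray  # (S,) bool
    ref_depth: np.ndarray  # (S, N) int
    alt_depth: np.ndarray  # (S, N) int
    site_mq: np.ndarray  # (S,) float
    bq_ref: list  # (S) of int arrays
    bq_alt: list
    mq_ref: list
    mq_alt: list
    allele_freq: np.ndarray = field(default=None)  # (S,) float, NaN until estimated
    gl: np.ndarray = field(default=None)  # (S, N, 3) natural-log likelihoods

    def __post_init__(self):
        if self.allele_freq is None:
            self.allele_freq = np.full(self.n_sites, np.nan)

    @property
    def n_sites(self) -> int:
        return len(self.contig_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def total_depth(self) -> np.ndarray:
        """(S, N) depth counting only reads carrying the ref or alt allele."""
        return self.ref_depth + self.alt_depth

    def subset(self, mask) -> "SNPTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SNPTable(
            sample_ids=self.sample_ids,
            contig_ids=self.contig_ids[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            biallelic=self.biallelic[idx],
            ref_depth=self.ref_depth[idx],
            alt_depth=self.alt_depth[idx],
            site_mq=self.site_mq[idx],
            bq_ref=[self.bq_ref[i] for i in idx],
            bq_alt=[self.bq_alt[i] for i in idx],
            mq_ref=[self.mq_ref[i] for i in idx],
            mq_alt=[self.mq_alt[i] for i in idx],
            allele_freq=self.allele_freq[idx],
            gl=self.gl[idx] if self.gl is not None else None,
        )


def _empty_snp_table(sample_ids: list[str]) -> SNPTable:
    z = np.zeros(0, dtype=np.int64)
    return SNPTable(
        sample_ids=sample_ids,
        contig_ids=np.array([], dtype=object),
        positions=z.copy(),
        ref=np.array([], dtype=object),
        alt=np.array([], dtype=object),
        biallelic=np.zeros(0, dtype=bool),
        ref_depth=np.zeros((0, len(sample_ids)), dtype=np.int64),
        alt_depth=np.zeros((0, len(sample_ids)), dtype=np.int64),
        site_mq=np.zeros(0),
        bq_ref=[],
        bq_alt=[],
        mq_ref=[],
        mq_alt=[],
    )


def call_sites(
    samples: dict[str, SampleReadSet],
    alignments: dict[str, AlignmentSet],
    contigs: ContigSet,
    min_allele_count: int = 2,
) -> SNPTable:
    """Pile up mapped reads per contig and emit candidate variant sites.

    A column is a candidate when at least two distinct alleles are each seen
    ``min_allele_count`` times pooled over individuals; sites where a third
    allele also reaches that count are flagged non-biallelic (removed by the
    first cascade stage).  The reference allele is the pooled major allele
    (ties break lexicographically); the site mapping quality is the
    root-mean-square of the mapping qualities of covering reads.
    """
    sample_ids = list(samples)
    n_ind = len(sample_ids)
    contig_lens = [len(s) for s in contigs.sequences]
    # bucket reads by contig: (sample_idx, enc_seq, quals, offset, mapq)
    buckets: dict[int, list] = {}
    for si, sid in enumerate(sample_ids):
        rs, al = samples[sid], alignments[sid]
        for r in np.flatnonzero(al.contig_idx >= 0):
            ci = int(al.contig_idx[r])
            buckets.setdefault(ci, []).append(
                (si, rs.sequences[r], rs.qualities[r], int(al.offset[r]), int(al.mapq[r]))
            )

    rows = {
        "contig": [], "pos": [], "ref": [], "alt": [], "biallelic": [],
        "site_mq": [], "rd": [], "ad": [], "bqr": [], "bqa": [], "mqr": [], "mqa": [],
    }
    for ci in sorted(buckets):
        reads = buckets[ci]
        lc = contig_lens[ci]
        n_r = len(reads)
        base = np.full((n_r, lc), 255, dtype=np.uint8)
        qual = np.zeros((n_r, lc), dtype=np.int16)
        samp = np.zeros(n_r, dtype=np.int64)
        mapq = np.zeros(n_r, dtype=np.int64)
        for r, (si, seq, q, off, mq) in enumerate(reads):
            enc = encode(seq)
            ph = ascii_to_phred(q)
            # clip read to the contig window
            rs_, re_ = max(0, -off), min(len(enc), lc - off)
            cs = off + rs_
            base[r, cs : cs + (re_ - rs_)] = enc[rs_:re_]
            qual[r, cs : cs + (re_ - rs_)] = ph[rs_:re_]
            samp[r] = si
            mapq[r] = mq
        counts = np.stack([(base == b).sum(axis=0) for b in range(4)])  # (4, lc)
        order = np.argsort(-counts, axis=0, kind="stable")
        top1 = np.take_along_axis(counts, order[:1], axis=0)[0]
        top2 = np.take_along_axis(counts, order[1:2], axis=0)[0]
        top3 = np.take_along_axis(counts, order[2:3], axis=0)[0]
        variable = (top2 >= min_allele_count) & (top1 >= min_allele_count)
        for col in np.flatnonzero(variable):
            # pooled-major reference; argsort is stable so ties break toward
            # the lexicographically smaller base (A<C<G<T by encoding)
            ref_b, alt_b = int(order[0, col]), int(order[1, col])
            covered = base[:, col] < 4
            is_ref = base[:, col] == ref_b
            is_alt = base[:, col] == alt_b
            rd = np.bincount(samp[is_ref], minlength=n_ind)
            ad = np.bincount(samp[is_alt], minlength=n_ind)
            rows["contig"].append(contigs.ids[ci])
            rows["pos"].append(int(col))
            rows["ref"].append("ACGT"[ref_b])
            rows["alt"].append("ACGT"[alt_b])
            rows["biallelic"].append(bool(top3[col] < min_allele_count))
            rows["site_mq"].append(
                float(np.sqrt(np.mean(mapq[covered].astype(float) ** 2))) if covered.any() else 0.0
            )
            rows["rd"].append(rd)
            rows["ad"].append(ad)
            rows["bqr"].append(qual[is_ref, col].astype(np.int64))
            rows["bqa"].append(qual[is_alt, col].astype(np.int64))
            rows["mqr"].append(mapq[is_ref])
            rows["mqa"].append(mapq[is_alt])
    if not rows["contig"]:
        return _empty_snp_table(sample_ids)
    return SNPTable(
        sample_ids=sample_ids,
        contig_ids=np.array(rows["contig"], dtype=object),
        positions=np.array(rows["pos"], dtype=np.int64),
        ref=np.array(rows["ref"], dtype=object),
        alt=np.array(rows["alt"], dtype=object),
        biallelic=np.array(rows["biallelic"], dtype=bool),
        ref_depth=np.stack(rows["rd"]),
        alt_depth=np.stack(rows["ad"]),
        site_mq=np.array(rows["site_mq"]),
        bq_ref=rows["bqr"],
        bq_alt=rows["bqa"],
        mq_ref=rows["mqr"],
        mq_alt=rows["mqa"],
    )


def genotype_likelihood(ref_depth, alt_depth, error_rate: float = 0.01) -> np.ndarray:
    """Natural-log likelihood triplet L(g) for dosages g = 0, 1, 2.

    Under the symmetric-error model a read shows the alternative allele with
    probability ``g/2*(1-e) + (1-g/2)*e``.  Inputs broadcast; the trailing
    axis of the result indexes dosage.  Zero total depth yields a flat
    (all-zero log) triplet.
    """
    if not (0.0 < error_rate < 0.5):
        raise ParameterError(f"error_rate must be in (0, 0.5), got {error_rate}")
    rd = np.asarray(ref_depth, dtype=float)
    ad = np.asarray(alt_depth, dtype=float)
    if (rd < 0).any() or (ad < 0).any():
        raise ParameterError("depths must be non-negative")
    g = np.arange(3, dtype=float)
    p_alt = g / 2.0 * (1.0 - error_rate) + (1.0 - g / 2.0) * error_rate
    out = rd[..., None] * np.log(1.0 - p_alt) + ad[..., None] * np.log(p_alt)
    return out


def build_gl_matrix(table: SNPTable, error_rate: float = 0.01) -> SNPTable:
    """Fill ``table.gl`` with the (S, N, 3) natural-log likelihood matrix."""
    table.gl = genotype_likelihood(table.ref_depth, table.alt_depth, error_rate)
    return table


@dataclass(frozen=True)
class AlleleFreqEstimate:
    freq: float
    converged: bool
    no_data: bool


def estimate_allele_freq(
    gl: np.ndarray, max_iter: int = 200, tol: float = 1e-8
) -> AlleleFreqEstimate:
    """Maximum-likelihood alternative-allele frequency from per-individual GLs.

    EM under Hardy-Weinberg: the E-step forms genotype posteriors at the
    current frequency, the M-step sets f to the posterior mean dosage over
    2N.  ``gl`` is (N, 3) natural-log likelihoods.  All-flat input (no data)
    returns 0.5 with ``no_data=True``.
    """
    gl = np.asarray(gl, dtype=float)
    if gl.ndim != 2 or gl.shape[1] != 3:
        raise InputError("gl must be an (N, 3) array")
    lik = np.exp(gl - gl.max(axis=1, keepdims=True))
    informative = ~np.all(np.isclose(lik, lik[:, :1]), axis=1)
    n_inf = int(informative.sum())
    if n_inf == 0:
        return AlleleFreqEstimate(0.5, True, True)
    lik = lik[informative]
    n = lik.shape[0]
    f = 0.5
    converged = False
    for _ in range(max_iter):
        prior = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        post = lik * prior
        post /= post.sum(axis=1, keepdims=True)
        f_new = float((post @ np.array([0.0, 1.0, 2.0])).sum() / (2 * n))
        if abs(f_new - f) < tol:
            f = f_new
            converged = True
            break
        f = f_new
    return AlleleFreqEstimate(float(np.clip(f, 0.0, 1.0)), converged, False)


def estimate_allele_freqs(table: SNPTable, error_rate: float = 0.01) -> SNPTable:
    """EM allele frequency for every site; fills ``table.allele_freq``."""
    if table.gl is None:
        build_gl_matrix(table, error_rate)
    freqs = np.empty(table.n_sites)
    for s in range(table.n_sites):
        freqs[s] = estimate_allele_freq(table.gl[s]).freq
    table.allele_freq = freqs
    return table


def genotype_all(
    samples: dict[str, SampleReadSet],
    contigs: ContigSet,
    min_identity: float = 0.9,
    min_allele_count: int = 2,
    error_rate: float = 0.01,
    method: str = "auto",
) -> tuple[SNPTable, dict[str, AlignmentSet]]:
    """Convenience: map all samples, call sites, build GLs and allele frequencies."""
    alignments = {
        sid: map_reads(rs, contigs, min_identity=min_identity, method=method)
        for sid, rs in samples.items()
    }
    table = call_sites(samples, alignments, contigs, min_allele_count=min_allele_count)
    build_gl_matrix(table, error_rate)
    estimate_allele_freqs(table, error_rate)
    return table, alignments
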