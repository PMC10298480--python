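"""Shared fixtures: small simulated studies and truth-matching helpers."""

from __future__ import annotations

import numpy as np
import pytest

import gbsconcord as gc


@pytest.fixture(scope="session")
def tiny_truth():
    """8 individuals, 120 loci — enough for every stage to have work to do."""
    cfg = gc.SimConfig(n_individuals=8, n_loci=120, seed=3)
    return gc.simulate_truth(cfg)


@pytest.fixture(scope="session")
def tiny_pool(tiny_truth):
    profile = gc.MethodProfile(mean_reads=2000, sd_reads=200, capture_breadth=0.9)
    return gc.simulate_method_reads(tiny_truth, profile, seed=11, arm="tissue")


@pytest.fixture(scope="session")
def tiny_samples(tiny_pool):
    samples, report = gc.demultiplex(tiny_pool, gc.BarcodeMap(tiny_pool.barcode_map))
    return samples, report


@pytest.fixture(scope="session")
def tiny_reference(tiny_samples):
    samples, _ = tiny_samples
    contigs, _ = gc.build_reference(samples, label="tissue-only")
    return contigs


@pytest.fixture(scope="session")
def tiny_snp_table(tiny_samples, tiny_reference):
    samples, _ = tiny_samples
    table, _ = gc.genotype_all(samples, tiny_reference)
    return table


def make_snp_table(
    sample_ids,
    contig_ids,
    positions,
    ref_depth,
    alt_depth,
    site_mq=None,
    biallelic=None,
    bq_ref=None,
    bq_alt=None,
    mq_ref=None,
    mq_alt=None,
):
    """Build an SNPTable directly from arrays (test scaffolding)."""
    ref_depth = np.asarray(ref_depth, dtype=np.int64)
    alt_depth = np.asarray(alt_depth, dtype=np.int64)
    s = ref_depth.shape[0]
    if site_mq is None:
        site_mq = np.full(s, 60.0)
    if biallelic is None:
        biallelic = np.ones(s, dtype=bool)

    def _default_quals(depths):
        return [np.full(int(d.sum()), 38, dtype=np.int64) for d in depths]

    return gc.SNPTable(
        sample_ids=list(sample_ids),
        contig_ids=np.array(contig_ids, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(["A"] * s, dtype=object),
        alt=np.array(["G"] * s, dtype=object),
        biallelic=np.asarray(biallelic, dtype=bool),
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        site_mq=np.asarray(site_mq, dtype=float),
        bq_ref=bq_ref if bq_ref is not None else _default_quals(ref_depth),
        bq_alt=bq_alt if bq_alt is not None else _default_quals(alt_depth),
        mq_ref=mq_ref if mq_ref is not None else _default_quals(ref_depth),
        mq_alt=mq_alt if mq_alt is not None else _default_quals(alt_depth),
    )


def match_sites_to_truth(table, contigs, truth):
    """Map each site of an SNPTable back to its true locus/variant.

    Contigs are matched to loci by best ungapped identity; a site matches a
    truth variant when positions coincide and its {ref, alt} pair equals the
    truth {ref, alt} pair.  Returns a list of (site_index, truth_dosages,
    flipped) where ``flipped`` marks sites whose contig representative carries
    the alternative allele (so dosage orientation is reversed).
    """
    from gbsconcord._seq import best_ungapped_identity

    contig_to_locus = {}
    for ci, seq in enumerate(contigs.sequences):
        best, best_j = -1.0, None
        for j, locus in enumerate(truth.locus_seqs):
            hit = best_ungapped_identity(seq, locus)
            if hit.identity > best:
                best, best_j = hit.identity, j
        if best >= 0.9:
            contig_to_locus[contigs.ids[ci]] = best_j
    matched = []
    for s in range(table.n_sites):
        j = contig_to_locus.get(table.contig_ids[s])
        if j is None:
            continue
        pos = int(table.positions[s])
        hits = np.flatnonzero(truth.variant_positions[j] == pos)
        if hits.size != 1:
            continue
        v = int(hits[0])
        truth_ref, truth_alt = truth.variant_ref[j][v], truth.variant_alt[j][v]
        pair = {table.ref[s], table.alt[s]}
        if pair != {truth_ref, truth_alt}:
            continue
        dosage = truth.haplotypes[j][:, :, v].sum(axis=1)
        flipped = table.ref[s] == truth_alt
        matched.append((s, dosage, flipped))
    return matched
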