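"""Readers and writers for the pipeline's on-disk formats.

FASTQ is Phred+33 single-end; FASTA holds reference contigs; the variant
table round-trips through a GT-free VCF 4.2 with per-individual depths (DP),
allele depths (AD) and log10-scaled genotype likelihoods (GL), plus site-level
INFO: site mapping quality (MQ), EM allele frequency (AF), a biallelic flag
(BI) and the pooled per-allele base/mapping-quality lists (BQR/BQA/MQR/MQA)
the allele-quality rank tests need.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .admixture import GenoProbMatrix
from .demux import SampleReadSet
from .errors import InputError
from .genolik import SNPTable
from .refbuild import Contig, ContigSet

LOG10 = np.log(10.0)


def write_fastq(path: str | Path, names, sequences, qualities) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in zip(names, sequences, qualities):
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> tuple[list[str], list[str], list[str]]:
    names, seqs, quals = [], [], []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            names.append(rec.name)
            seqs.append(rec.sequence)
            quals.append(rec.quality)
    return names, seqs, quals


def write_sample_fastq(path: str | Path, readset: SampleReadSet) -> None:
    names = [f"{readset.sample_id}_r{i + 1:07d}" for i in range(readset.n_reads)]
    write_fastq(path, names, readset.sequences, readset.qualities)


def read_sample_fastq(path: str | Path, sample_id: str) -> SampleReadSet:
    _, seqs, quals = read_fastq(path)
    return SampleReadSet(sample_id, seqs, quals)


def read_fasta(path: str | Path) -> ContigSet:
    contigs = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            members, label = 1, "control"
            if rec.comment:
                for tok in rec.comment.split():
                    if tok.startswith("members="):
                        members = int(tok.split("=", 1)[1])
                    elif tok.startswith("label="):
                        label = tok.split("=", 1)[1]
            contigs.append(Contig(rec.name, rec.sequence, members, label))
    label = contigs[0].label if contigs else "control"
    return ContigSet(contigs=contigs, label=label)


def _fmt_list(values) -> str:
    return ",".join(str(int(v)) for v in values) if len(values) else "."


def write_vcf(table: SNPTable, path: str | Path) -> None:
    """Write a GT-free VCF 4.2 carrying everything the filter cascade needs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gbsconcord\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Site RMS mapping quality">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="EM alternative allele frequency">\n')
        fh.write('##INFO=<ID=BI,Number=1,Type=Integer,Description="1 if biallelic at discovery">\n')
        for tag, desc in (
            ("BQR", "Pooled base qualities of reference-allele reads"),
            ("BQA", "Pooled base qualities of alternative-allele reads"),
            ("MQR", "Pooled mapping qualities of reference-allele reads"),
            ("MQA", "Pooled mapping qualities of alternative-allele reads"),
        ):
            fh.write(f'##INFO=<ID={tag},Number=.,Type=Integer,Description="{desc}">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Ref+alt read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods">\n')
        seen = []
        for cid in table.contig_ids:
            if cid not in seen:
                seen.append(cid)
        for cid in seen:
            fh.write(f"##contig=<ID={cid}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        gl10 = table.gl / LOG10 if table.gl is not None else None
        for s in range(table.n_sites):
            af = table.allele_freq[s]
            info = (
                f"MQ={table.site_mq[s]:.2f};AF={af if not np.isnan(af) else 0.5:.6f};"
                f"BI={int(table.biallelic[s])};"
                f"BQR={_fmt_list(table.bq_ref[s])};BQA={_fmt_list(table.bq_alt[s])};"
                f"MQR={_fmt_list(table.mq_ref[s])};MQA={_fmt_list(table.mq_alt[s])}"
            )
            cells = []
            for i in range(table.n_individuals):
                rd, ad = int(table.ref_depth[s, i]), int(table.alt_depth[s, i])
                if gl10 is not None:
                    g = gl10[s, i]
                    gl_txt = f"{g[0]:.4f},{g[1]:.4f},{g[2]:.4f}"
                else:
                    gl_txt = "0,0,0"
                cells.append(f"{rd + ad}:{rd},{ad}:{gl_txt}")
            fh.write(
                f"{table.contig_ids[s]}\t{table.positions[s] + 1}\t.\t{table.ref[s]}\t"
                f"{table.alt[s]}\t.\t.\t{info}\tDP:AD:GL\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path: str | Path) -> SNPTable:
    """Read a VCF written by :func:`write_vcf` back into an SNPTable."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    sample_ids = list(vcf.samples)
    rows = {k: [] for k in ("cid", "pos", "ref", "alt", "bi", "mq", "af",
                            "rd", "ad", "bqr", "bqa", "mqr", "mqa", "gl")}
    for var in vcf:
        rows["cid"].append(var.CHROM)
        rows["pos"].append(var.POS - 1)
        rows["ref"].append(var.REF)
        rows["alt"].append(var.ALT[0] if var.ALT else "N")
        rows["bi"].append(bool(var.INFO.get("BI", 1)))
        rows["mq"].append(float(var.INFO.get("MQ", 0.0)))
        rows["af"].append(float(var.INFO.get("AF", np.nan)))
        ad = var.format("AD")
        rows["rd"].append(ad[:, 0].astype(np.int64))
        rows["ad"].append(ad[:, 1].astype(np.int64))
        gl = var.format("GL")
        rows["gl"].append(np.asarray(gl, dtype=float) * LOG10)
        for tag, key in (("BQR", "bqr"), ("BQA", "bqa"), ("MQR", "mqr"), ("MQA", "mqa")):
            val = var.INFO.get(tag)
            if val is None:
                arr = np.array([], dtype=np.int64)
            elif isinstance(val, tuple):
                arr = np.array(val, dtype=np.int64)
            else:
                arr = np.array([int(val)], dtype=np.int64)
            rows[key].append(arr)
    vcf.close()
    n_sites = len(rows["cid"])
    n = len(sample_ids)
    return SNPTable(
        sample_ids=sample_ids,
        contig_ids=np.array(rows["cid"], dtype=object),
        positions=np.array(rows["pos"], dtype=np.int64),
        ref=np.array(rows["ref"], dtype=object),
        alt=np.array(rows["alt"], dtype=object),
        biallelic=np.array(rows["bi"], dtype=bool),
        ref_depth=np.stack(rows["rd"]) if n_sites else np.zeros((0, n), dtype=np.int64),
        alt_depth=np.stack(rows["ad"]) if n_sites else np.zeros((0, n), dtype=np.int64),
        site_mq=np.array(rows["mq"]),
        bq_ref=rows["bqr"],
        bq_alt=rows["bqa"],
        mq_ref=rows["mqr"],
        mq_alt=rows["mqa"],
        allele_freq=np.array(rows["af"]) if n_sites else None,
        gl=np.stack(rows["gl"]) if n_sites else None,
    )


def write_gprobs_tsv(gprobs: GenoProbMatrix, path: str | Path) -> None:
    """Posterior mean dosage matrix (individuals x SNPs) as TSV."""
    gprobs.dosage_frame().to_csv(path, sep="\t", index_label="sample_id")


def write_truth_tables(truth, outdir: str | Path) -> None:
    """Ground-truth genotype dosages and allele frequencies as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dosage, labels = truth.dosage_matrix()
    cols = [f"{cid}:{pos}" for cid, pos in labels]
    pd.DataFrame(dosage, index=truth.sample_ids, columns=cols).to_csv(
        outdir / "true_genotypes.tsv", sep="\t", index_label="sample_id"
    )
    freq_rows = []
    for j, cid in enumerate(truth.locus_ids):
        for p, f in zip(truth.variant_positions[j], truth.allele_freqs[j]):
            freq_rows.append({"locus": cid, "position": int(p), "alt_freq": float(f)})
    pd.DataFrame(freq_rows).to_csv(outdir / "true_allele_freqs.tsv", sep="\t", index=False)


def write_manifest(path: str | Path, **entries) -> None:
    """Reproducibility manifest: seeds, parameters, artifact paths."""
    payload = {}
    for k, v in entries.items():
        try:
            json.dumps(v)
            payload[k] = v
        except TypeError:
            payload[k] = str(v)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_contaminants(path: str | Path | None) -> list[str]:
    if path is None:
        return []
    seqs = []
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            seqs.append(rec.sequence)
    if not seqs:
        raise InputError(f"no sequences in contaminant FASTA {path}")
    return seqs
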