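"""De novo reference construction from per-sample GBS reads.

Two steps, mirroring the reduced-representation convention: (1) a retention
filter over the unique-read table keeps sequences seen in at least
``min_copies`` total copies AND shared by at least ``min_individuals``
individuals; (2) greedy incremental identity clustering of the survivors
(most abundant first) at an 80% identity threshold, with cluster
representatives becoming the reference contigs.  The comparator is the
best-ungapped-offset identity of :mod:`gbsconcord._seq` — adequate for
near-identical 84-86 bp read stacks, where gapped alignment adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import batch_best_identity, encode_strict, pad_matrix
from .demux import SampleReadSet
from .errors import InputError


def unique_read_table(samples: dict[str, SampleReadSet]) -> pd.DataFrame:
    """Tabulate unique read sequences across samples.

    Returns a DataFrame indexed by sequence with columns ``total_copies``
    (copies summed over all samples) and ``n_individuals_sharing``.
    """
    totals: dict[str, int] = {}
    sharing: dict[str, int] = {}
    for rs in samples.values():
        counts: dict[str, int] = {}
        for seq in rs.sequences:
            counts[seq] = counts.get(seq, 0) + 1
        for seq, c in counts.items():
            totals[seq] = totals.get(seq, 0) + c
            sharing[seq] = sharing.get(seq, 0) + 1
    df = pd.DataFrame(
        {
            "total_copies": pd.Series(totals, dtype=np.int64),
            "n_individuals_sharing": pd.Series(sharing, dtype=np.int64),
        }
    )
    df.index.name = "sequence"
    return df


def retention_filter(
    table: pd.DataFrame, min_copies: int = 4, min_individuals: int = 4
) -> pd.DataFrame:
    """Keep sequences with total_copies >= min_copies AND shared by >= min_individuals.

    The conjunctive >= reading at the boundary of 4/4 follows the dDocent
    convention for this style of filter.
    """
    keep = (table["total_copies"] >= min_copies) & (
        table["n_individuals_sharing"] >= min_individuals
    )
    return table.loc[keep]


@dataclass
class Contig:
    contig_id: str
    sequence: str
    member_count: int
    label: str = "control"


@dataclass
class ContigSet:
    """A de novo reference: cluster-representative contigs plus membership."""

    contigs: list[Contig]
    label: str = "control"
    membership: dict[str, str] = field(default_factory=dict)  # input sequence -> contig_id

    def __len__(self) -> int:
        return len(self.contigs)

    @property
    def sequences(self) -> list[str]:
        return [c.sequence for c in self.contigs]

    @property
    def ids(self) -> list[str]:
        return [c.contig_id for c in self.contigs]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.contigs:
                fh.write(f">{c.contig_id} members={c.member_count} label={c.label}\n")
                fh.write(c.sequence + "\n")

    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence": list(self.membership), "contig_id": list(self.membership.values())}
        )


def greedy_cluster(
    sequences,
    abundances=None,
    identity_threshold: float = 0.80,
    label: str = "control",
) -> ContigSet:
    """Greedy incremental identity clustering, CD-HIT style.

    Sequences are processed in descending (abundance, length, lexicographic-
    ascending) order; each joins the *first-founded* existing cluster whose
    representative reaches ``identity_threshold`` under the best-ungapped-
    offset comparator, else founds a new cluster.  Representatives (the
    founding, most-abundant sequences) are returned as contigs; any two
    representatives are guaranteed below the threshold pairwise.
    """
    sequences = list(sequences)
    if abundances is None:
        abundances = [1] * len(sequences)
    abundances = [int(a) for a in abundances]
    if len(abundances) != len(sequences):
        raise InputError("abundances must match sequences in length")
    # aggregate duplicates so identical sequences always co-cluster
    agg: dict[str, int] = {}
    for seq, ab in zip(sequences, abundances):
        agg[seq] = agg.get(seq, 0) + ab
    encoded = {seq: encode_strict(seq) for seq in agg}
    order = sorted(agg, key=lambda s: (-agg[s], -len(s), s))

    contigs: list[Contig] = []
    membership: dict[str, str] = {}
    rep_mat = None
    rep_lens = None
    n_reps = 0
    cap = max(16, len(order))
    width = max((len(s) for s in order), default=0)
    rep_mat = np.full((cap, width), 255, dtype=np.uint8)
    rep_lens = np.zeros(cap, dtype=np.int64)
    for seq in order:
        enc = encoded[seq]
        joined = None
        if n_reps:
            matches, _ = batch_best_identity(enc, rep_mat[:n_reps], rep_lens[:n_reps])
            ident = matches / np.maximum(len(enc), rep_lens[:n_reps])
            hits = np.flatnonzero(ident >= identity_threshold)
            if hits.size:
                joined = int(hits[0])  # first-founded representative
        if joined is None:
            cid = f"{label}_contig{len(contigs) + 1:05d}"
            contigs.append(Contig(cid, seq, agg[seq], label))
            rep_mat[n_reps, : len(enc)] = enc
            rep_lens[n_reps] = len(enc)
            n_reps += 1
            membership[seq] = cid
        else:
            contigs[joined].member_count += agg[seq]
            membership[seq] = contigs[joined].contig_id
    return ContigSet(contigs=contigs, label=label, membership=membership)


def build_reference(
    samples: dict[str, SampleReadSet],
    min_copies: int = 4,
    min_individuals: int = 4,
    identity_threshold: float = 0.80,
    label: str = "control",
) -> tuple[ContigSet, pd.DataFrame]:
    """Unique-read tabulation -> retention filter -> greedy clustering.

    Returns the contig set and the retained unique-read table.
    """
    table = retention_filter(unique_read_table(samples), min_copies, min_individuals)
    contigs = greedy_cluster(
        table.index.tolist(),
        abundances=table["total_copies"].tolist(),
        identity_threshold=identity_threshold,
        label=label,
    )
    return contigs, table
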