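"""Demultiplexing and contaminant screening of multiplexed GBS reads.

Reads are assigned to samples by matching their prefix against a map of
multiplex identifier (MID) barcodes of 10-20 bp, the barcode is stripped, and
an optional trailing adapter stub is trimmed.  A separate screen removes reads
matching a contaminant reference (a PhiX-style sequencing control) by ungapped
sliding-window identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import KmerIndex, encode
from .errors import ConfigError, InputError


@dataclass
class BarcodeMap:
    """sample_id -> barcode, validated to be unique and mutually prefix-free."""

    barcodes: dict[str, str]

    def __post_init__(self):
        self.validate()

    def validate(self, max_mismatches: int = 0) -> None:
        items = list(self.barcodes.items())
        seen: dict[str, str] = {}
        for sid, bc in items:
            if not bc or set(bc) - set("ACGT"):
                raise ConfigError(f"barcode for {sid!r} is not a non-empty ACGT string: {bc!r}")
            if bc in seen:
                raise ConfigError(f"duplicate barcode {bc!r} ({seen[bc]!r} and {sid!r})")
            seen[bc] = sid
        for i, (sa, a) in enumerate(items):
            for sb, b in items[i + 1 :]:
                short, long_ = (a, b) if len(a) <= len(b) else (b, a)
                dist = sum(x != y for x, y in zip(short, long_))
                if dist <= 2 * max_mismatches:
                    raise ConfigError(
                        f"barcodes for {sa!r} and {sb!r} are not separable at "
                        f"max_mismatches={max_mismatches}"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "barcode"} <= set(df.columns):
            raise InputError(f"barcode map {path} must have sample_id and barcode columns")
        return cls(dict(zip(df["sample_id"], df["barcode"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.barcodes), "barcode": list(self.barcodes.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class SampleReadSet:
    """Per-sample trimmed reads: parallel lists of sequence and quality strings."""

    sample_id: str
    sequences: list[str] = field(default_factory=list)
    qualities: list[str] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.sequences)


@dataclass
class DemuxReport:
    """Per-sample assignment counts plus the unassigned remainder."""

    per_sample: dict[str, int]
    unassigned: int
    total: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample_id": s, "reads": c} for s, c in self.per_sample.items()]
        rows.append({"sample_id": "__unassigned__", "reads": self.unassigned})
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _trim_adapter(seq: str, qual: str, adapter: str, min_overlap: int = 5) -> tuple[str, str]:
    """Trim a 3' adapter: full occurrences, else a terminal adapter prefix."""
    idx = seq.find(adapter)
    if idx >= 0:
        return seq[:idx], qual[:idx]
    for ov in range(min(len(adapter), len(seq)) - 1, min_overlap - 1, -1):
        if seq.endswith(adapter[:ov]):
            return seq[: len(seq) - ov], qual[: len(qual) - ov]
    return seq, qual


def demultiplex(
    reads,
    barcode_map: BarcodeMap,
    max_mismatches: int = 0,
    adapter: str | None = None,
) -> tuple[dict[str, SampleReadSet], DemuxReport]:
    """Assign reads to samples by barcode prefix and strip the barcode.

    Parameters
    ----------
    reads:
        Iterable of ``(sequence, quality)`` pairs, or an object with
        ``sequences``/``qualities`` attributes (e.g. ``MultiplexedReads``).
    max_mismatches:
        Allowed mismatches in the barcode prefix (0 by default; the barcode
        map is re-validated for separability at the requested radius).
    adapter:
        Optional 3' adapter whose full occurrence (or terminal stub) is
        trimmed after barcode removal.

    Returns the per-sample read sets and a report whose counts satisfy
    ``sum(per_sample) + unassigned == total``.
    """
    if hasattr(reads, "sequences"):
        pairs = list(zip(reads.sequences, reads.qualities))
    else:
        pairs = list(reads)
    barcode_map.validate(max_mismatches=max_mismatches)
    items = list(barcode_map.barcodes.items())
    out = {sid: SampleReadSet(sid) for sid, _ in items}
    exact = {bc: sid for sid, bc in items}
    lengths = sorted({len(bc) for _, bc in items})
    unassigned = 0
    for seq, qual in pairs:
        hit_sid, hit_len = None, 0
        if max_mismatches == 0:
            for ln in lengths:
                sid = exact.get(seq[:ln])
                if sid is not None:
                    hit_sid, hit_len = sid, ln
                    break
        else:
            matches = []
            for sid, bc in items:
                prefix = seq[: len(bc)]
                if len(prefix) == len(bc):
                    mm = sum(x != y for x, y in zip(prefix, bc))
                    if mm <= max_mismatches:
                        matches.append((sid, len(bc)))
            if len(matches) == 1:
                hit_sid, hit_len = matches[0]
        if hit_sid is None:
            unassigned += 1
            continue
        tseq, tqual = seq[hit_len:], qual[hit_len:]
        if adapter:
            tseq, tqual = _trim_adapter(tseq, tqual, adapter)
        rs = out[hit_sid]
        rs.sequences.append(tseq)
        rs.qualities.append(tqual)
    report = DemuxReport(
        per_sample={sid: rs.n_reads for sid, rs in out.items()},
        unassigned=unassigned,
        total=len(pairs),
    )
    return out, report


def _screen_read(read_enc: np.ndarray, cont_enc: np.ndarray, min_identity: float) -> bool:
    """True if the read matches the contaminant at >= min_identity over its full length."""
    lr, lc = len(read_enc), len(cont_enc)
    if lr == 0 or lc < lr:
        return False
    need = int(np.ceil(min_identity * lr))
    for off in range(lc - lr + 1):
        if int((read_enc == cont_enc[off : off + lr]).sum()) >= need:
            return True
    return False


def screen_contaminants(
    readset: SampleReadSet,
    contaminants,
    min_identity: float = 0.9,
    prefilter_k: int = 12,
) -> tuple[SampleReadSet, int]:
    """Remove reads whose best ungapped alignment to any contaminant reaches
    ``min_identity`` over the full read length.

    ``contaminants`` is a list of sequences (or ``None``/empty, in which case
    the input is returned unchanged).  Order of surviving reads is preserved.
    A shared-k-mer prefilter (k=``prefilter_k``) shortlists reads for the exact
    sliding-window scan; reads sharing no k-mer with any contaminant are kept
    without scanning (seeded-alignment heuristic: a borderline-identity read
    with mismatches spread pathologically evenly could slip past the seed).
    """
    if not contaminants:
        return readset, 0
    cont_enc = [encode(c) for c in contaminants]
    index = KmerIndex(k=prefilter_k)
    for ci, c in enumerate(contaminants):
        index.add(ci, c)
    keep_seq, keep_qual = [], []
    removed = 0
    for seq, qual in zip(readset.sequences, readset.qualities):
        cands = index.candidates(seq) if len(seq) >= prefilter_k else range(len(cont_enc))
        renc = encode(seq)
        if any(_screen_read(renc, cont_enc[ci], min_identity) for ci in cands):
            removed += 1
        else:
            keep_seq.append(seq)
            keep_qual.append(qual)
    return SampleReadSet(readset.sample_id, keep_seq, keep_qual), removed
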