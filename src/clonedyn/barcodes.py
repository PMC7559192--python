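"""ClonTracer-style barcode extraction, error merging, and frequency tables.

Barcodes follow the semi-random (WS)^15 design (W = A/T, S = C/G) flanked by
constant anchor sequences. Reads failing the anchor match or the
weak/strong alternation are discarded and tallied in a QC report.
Sequencing-error collapse is a greedy single pass in descending abundance:
any barcode within a Hamming radius of a more abundant one is absorbed.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "BarcodePattern",
    "ExtractResult",
    "extract_barcodes",
    "merge_barcodes",
    "counts_to_frequencies",
    "hamming",
]

WEAK = frozenset("AT")
STRONG = frozenset("CG")


@dataclass(frozen=True)
class BarcodePattern:
    """The semi-random barcode design: (WS)^(length/2) between two anchors."""

    length: int = 30
    flank_5p: str = "ACTGACTG"
    flank_3p: str = "CAGTCAGT"

    def __post_init__(self) -> None:
        if self.length <= 0 or self.length % 2:
            raise ValueError("barcode length must be a positive even number")
        if not self.flank_5p or not self.flank_3p:
            raise ValueError("both anchor sequences are required")

    def is_valid(self, seq: str) -> bool:
        """True if ``seq`` matches the alternating weak/strong rule."""
        if len(seq) != self.length:
            return False
        return all(
            c in (WEAK if i % 2 == 0 else STRONG) for i, c in enumerate(seq)
        )


@dataclass
class ExtractResult:
    """Single-sample barcode counts plus read-level QC tallies."""

    counts: pd.Series  # barcode -> reads
    qc: dict[str, int] = field(default_factory=dict)


def extract_barcodes(
    reads: str | Path | IO[str] | Iterable,
    pattern: BarcodePattern | None = None,
) -> ExtractResult:
    """Count valid barcodes in a FASTQ stream (one sample).

    Each read contributes at most one count. A read fails QC as
    ``anchor_fail`` if the 5' anchor is absent or the 3' anchor does not sit
    immediately after the barcode window, and as ``pattern_fail`` if the
    window violates the weak/strong alternation.
    """
    pattern = pattern or BarcodePattern()
    qc = {"reads": 0, "valid": 0, "anchor_fail": 0, "pattern_fail": 0}
    counts: dict[str, int] = {}
    handle = None
    if isinstance(reads, (str, Path)):
        if str(reads).endswith(".gz"):
            handle = gzip.open(reads, "rt")
        else:
            handle = open(reads)
        records = SeqIO.parse(handle, "fastq")
    elif hasattr(reads, "read"):
        records = SeqIO.parse(reads, "fastq")
    else:
        records = reads  # pre-parsed SeqRecords
    for rec in records:
        qc["reads"] += 1
        seq = str(rec.seq).upper()
        start = seq.find(pattern.flank_5p)
        if start < 0:
            qc["anchor_fail"] += 1
            continue
        lo = start + len(pattern.flank_5p)
        hi = lo + pattern.length
        tail = seq[hi : hi + len(pattern.flank_3p)]
        if len(seq) < hi + len(pattern.flank_3p) or tail != pattern.flank_3p:
            qc["anchor_fail"] += 1
            continue
        bc = seq[lo:hi]
        if not pattern.is_valid(bc):
            qc["pattern_fail"] += 1
            continue
        qc["valid"] += 1
        counts[bc] = counts.get(bc, 0) + 1
    if handle is not None:
        handle.close()
    if qc["reads"] == 0:
        warnings.warn("empty FASTQ input: returning an empty count table")
    series = pd.Series(counts, dtype=int).sort_values(ascending=False)
    series.index.name = "barcode"
    return ExtractResult(counts=series, qc=qc)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


def merge_barcodes(
    counts: pd.Series | pd.DataFrame, max_hamming: int = 2
) -> pd.Series | pd.DataFrame:
    """Absorb likely sequencing-error barcodes into more abundant ones.

    Barcodes are visited once in descending total abundance (ties broken
    lexicographically). A barcode within ``max_hamming`` of an already-kept,
    more abundant barcode is merged into the closest such keeper (ties to
    the more abundant, then lexicographically smaller keeper). Total counts
    are conserved.
    """
    if max_hamming < 0:
        raise ValueError("max_hamming must be non-negative")
    df = counts.to_frame() if isinstance(counts, pd.Series) else counts
    if df.empty or max_hamming == 0:
        return counts.copy()
    lengths = {len(b) for b in df.index}
    if len(lengths) > 1:
        raise ValueError(f"mixed barcode lengths: {sorted(lengths)}")

    totals = df.sum(axis=1)
    order = sorted(df.index, key=lambda b: (-totals[b], b))
    seqs = np.array([list(b) for b in order])
    target: dict[str, str] = {}
    kept_idx: list[int] = []
    for i, bc in enumerate(order):
        if kept_idx:
            dists = (seqs[kept_idx] != seqs[i]).sum(axis=1)
            j = int(np.argmin(dists))  # keepers ordered by abundance: first min
            if dists[j] <= max_hamming:
                target[bc] = order[kept_idx[j]]
                continue
        kept_idx.append(i)
        target[bc] = bc

    grouped = df.groupby([target[b] for b in df.index]).sum()
    grouped = grouped.loc[[b for b in order if target[b] == b]]
    grouped.index.name = df.index.name
    if isinstance(counts, pd.Series):
        out = grouped.iloc[:, 0]
        out.name = counts.name
        return out
    return grouped


def counts_to_frequencies(
    counts: pd.DataFrame | pd.Series, min_reads: int = 10
) -> pd.DataFrame | pd.Series:
    """Filter low-count barcodes per sample and renormalize to frequencies.

    A barcode with fewer than ``min_reads`` reads in a sample is set to zero
    frequency there; the remainder are renormalized so that each sample sums
    to one. Raises if a sample retains no reads.
    """
    was_series = isinstance(counts, pd.Series)
    df = counts.to_frame() if was_series else counts
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    kept = df.where(df >= min_reads, 0).astype(float)
    totals = kept.sum(axis=0)
    dead = totals[totals == 0].index.tolist()
    if dead:
        raise ValueError(
            f"sample(s) with zero total reads after min_reads={min_reads} "
            f"filter: {dead}"
        )
    freq = kept / totals
    return freq.iloc[:, 0] if was_series else freq
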