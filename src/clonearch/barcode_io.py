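"""Barcode extraction from amplicon reads and count-table I/O.

Lentiviral lineage barcodes (BC14-spacer-BC30 style cassettes) are amplified
from genomic or supernatant DNA and sequenced as short amplicons with fixed
flanking sequences.  Because the cassette is fixed-length and indel-free,
reads are assigned by locating the 5' flank with a bounded Hamming mismatch
budget and matching the fixed-length insert against the barcode library at a
bounded Hamming distance; ambiguous and unmatched reads are tallied with
reasons.  The module also owns the canonical long-format count-table TSV
(barcode_id, replicate, timepoint_day, phase, count).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

__all__ = [
    "BarcodeLibrary",
    "ExtractionResult",
    "extract_barcodes",
    "read_count_table",
    "write_count_table",
    "read_library_fasta",
]

COUNT_COLUMNS = ["barcode_id", "replicate", "timepoint_day", "phase", "count"]
VALID_PHASES = {"parental", "drug", "regrowth"}
_BASES = set("ACGT")


@dataclass
class BarcodeLibrary:
    """Known barcode sequences plus the fixed amplicon flanks."""

    barcodes: dict[str, str]
    flank_5prime: str
    flank_3prime: str = ""

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("barcode library is empty")
        lengths = {len(s) for s in self.barcodes.values()}
        if len(lengths) != 1:
            raise ValueError("all barcode sequences must have the same length")
        for name, seq in self.barcodes.items():
            if not set(seq) <= _BASES:
                raise ValueError(f"barcode {name!r} has non-ACGT characters")
        for flank in (self.flank_5prime, self.flank_3prime):
            if flank and not set(flank) <= _BASES:
                raise ValueError("flanks must be over ACGT")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes.values())))


@dataclass
class ExtractionResult:
    counts: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=dict)
    n_reads: int = 0


def _seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _find_flank(read: np.ndarray, flank: np.ndarray, max_mm: int) -> int:
    """Leftmost offset where the flank matches within max_mm mismatches, or -1."""
    n, m = len(read), len(flank)
    for pos in range(0, n - m + 1):
        if int(np.count_nonzero(read[pos : pos + m] != flank)) <= max_mm:
            return pos
    return -1


def _iter_fastq(path: str | Path) -> Iterator:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from SeqIO.parse(fh, "fastq")
    else:
        with open(path) as fh:
            yield from SeqIO.parse(fh, "fastq")


def extract_barcodes(
    reads: str | Path | Iterable[str],
    lib: BarcodeLibrary,
    max_mismatch_flank: int = 1,
    max_mismatch_barcode: int = 1,
    both_strands: bool = False,
    replicate: str = "R1",
    timepoint_day: float = 0.0,
    phase: str = "parental",
) -> ExtractionResult:
    """Assign amplicon reads to library barcodes by Hamming matching.

    ``reads`` is a FASTQ path (plain or gzip) or an iterable of raw read
    strings.  For each read the 5' flank is located (leftmost hit within
    ``max_mismatch_flank``), the fixed-length insert downstream is compared
    against every library barcode, and the read is assigned to the unique
    barcode at minimal Hamming distance within ``max_mismatch_barcode``.
    Failures are tallied as ``no_flank``, ``truncated``, ``no_match`` or
    ``ambiguous``; assigned + unassigned always equals the number of reads.
    """
    ids = list(lib.barcodes)
    L = lib.barcode_length
    lib_mat = np.vstack([_seq_to_u8(lib.barcodes[i]) for i in ids])
    flank = _seq_to_u8(lib.flank_5prime)

    if isinstance(reads, (str, Path)):
        seq_iter: Iterable[str] = (str(rec.seq) for rec in _iter_fastq_checked(reads))
    else:
        seq_iter = reads

    counts = dict.fromkeys(ids, 0)
    unassigned = {"no_flank": 0, "truncated": 0, "no_match": 0, "ambiguous": 0}
    n_reads = 0
    for seq in seq_iter:
        n_reads += 1
        seq = seq.upper()
        attempts = [seq, reverse_complement(seq)] if both_strands else [seq]
        assigned = False
        reason = "no_flank"
        for attempt in attempts:
            arr = _seq_to_u8(attempt)
            pos = _find_flank(arr, flank, max_mismatch_flank)
            if pos < 0:
                continue
            start = pos + len(flank)
            if start + L > len(arr):
                reason = "truncated"
                continue
            insert = arr[start : start + L]
            dists = np.count_nonzero(lib_mat != insert[None, :], axis=1)
            best = int(dists.min())
            if best > max_mismatch_barcode:
                reason = "no_match"
                continue
            hits = np.flatnonzero(dists == best)
            if len(hits) > 1:
                reason = "ambiguous"
                continue
            counts[ids[hits[0]]] += 1
            assigned = True
            break
        if not assigned:
            unassigned[reason] += 1

    table = pd.DataFrame(
        {
            "barcode_id": ids,
            "replicate": replicate,
            "timepoint_day": float(timepoint_day),
            "phase": phase,
            "count": [counts[i] for i in ids],
        }
    )
    return ExtractionResult(counts=table, unassigned=unassigned, n_reads=n_reads)


def _iter_fastq_checked(path: str | Path) -> Iterator:
    idx = 0
    try:
        for rec in _iter_fastq(path):
            yield rec
            idx += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc


def read_library_fasta(path: str | Path, flank_5prime: str,
                       flank_3prime: str = "") -> BarcodeLibrary:
    """Load a barcode library from FASTA (record id = barcode id)."""
    barcodes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return BarcodeLibrary(barcodes, flank_5prime.upper(), flank_3prime.upper())


# ---------------------------------------------------------------------------
# count-table TSV


def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical count table as TSV (lossless round-trip)."""
    _validate_count_table(table)
    table[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a count-table TSV."""
    df = pd.read_csv(
        path, sep="\t",
        dtype={"barcode_id": str, "replicate": str, "phase": str},
    )
    _validate_count_table(df)
    df["count"] = df["count"].astype(np.int64)
    df["timepoint_day"] = df["timepoint_day"].astype(float)
    return df[COUNT_COLUMNS]


def _validate_count_table(df: pd.DataFrame) -> None:
    for col in COUNT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"count table is missing column {col!r}")
    counts = df["count"]
    if not np.issubdtype(np.asarray(counts).dtype, np.number):
        raise ValueError("column 'count' must be numeric")
    if (np.asarray(counts) % 1 != 0).any():
        raise ValueError("column 'count' must contain integers")
    if (np.asarray(counts) < 0).any():
        raise ValueError("column 'count' contains negative values")
    bad_phase = set(df["phase"].unique()) - VALID_PHASES
    if bad_phase:
        raise ValueError(f"column 'phase' has unknown labels: {sorted(bad_phase)}")
    dup = df.duplicated(subset=["barcode_id", "replicate", "timepoint_day"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate (barcode_id, replicate, timepoint_day) row: "
            f"{first['barcode_id']}/{first['replicate']}/{first['timepoint_day']}"
        )
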