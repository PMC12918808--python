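"""Barcode counting from FASTQ reads.

Reads carry a reporter barcode between two constant flanks.  Counting is a
two-step per-read decision: locate the 5' flank (the anchor) allowing a small
number of substitutions, then assign the following fixed-width window to a
library barcode by Hamming distance.  Ambiguous windows (more than one library
barcode within the mismatch budget) are dropped rather than fractionally
assigned.  The QC tally partitions every read into exactly one of
assigned / ambiguous / unmatched / no_anchor.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass
from itertools import combinations, product
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import GuideLibrary, LibraryRecord

_BASES = "ACGT"


@dataclass(frozen=True)
class ReadLayout:
    """Geometry of a barcode read: 5' flank, barcode window, 3' flank."""

    flank5: str = "ACCGGTAG"
    flank3: str = "CTGCAGGT"
    barcode_length: int = 12
    max_flank_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.barcode_length < 6:
            raise ValueError("barcode_length must be >= 6")
        if not self.flank5 or not self.flank3:
            raise ValueError("flanks must be non-empty")
        if self.max_flank_mismatch < 0:
            raise ValueError("max_flank_mismatch must be >= 0")

    @property
    def read_length(self) -> int:
        return len(self.flank5) + self.barcode_length + len(self.flank3)


@dataclass
class QCStats:
    """Per-run read accounting; the four categories partition reads_total."""

    reads_total: int = 0
    reads_assigned: int = 0
    reads_ambiguous: int = 0
    reads_unmatched: int = 0
    reads_no_anchor: int = 0

    def to_dict(self) -> dict[str, int]:
        return asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def extract_barcode(read_sequence: str, layout: ReadLayout) -> str | None:
    """Return the barcode window after the leftmost acceptable 5'-flank hit.

    The anchor may carry up to ``layout.max_flank_mismatch`` substitutions;
    among acceptable positions the leftmost wins.  Returns None when no anchor
    fits or the read is too short to hold flank + barcode.
    """
    seq = read_sequence.upper()
    flank = layout.flank5
    flen = len(flank)
    blen = layout.barcode_length
    last = len(seq) - flen - blen
    if last < 0:
        return None
    max_mm = layout.max_flank_mismatch
    # exact hit bounds the scan: the leftmost approximate hit is at or before it
    exact = seq.find(flank, 0, last + flen)
    if exact == 0 or max_mm == 0:
        if exact == -1:
            return None
        return seq[exact + flen : exact + flen + blen]
    stop = exact if exact != -1 else last
    for pos in range(stop + 1):
        mm = 0
        window = seq[pos : pos + flen]
        for a, b in zip(flank, window):
            if a != b:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            return seq[pos + flen : pos + flen + blen]
    if exact != -1:
        return seq[exact + flen : exact + flen + blen]
    return None


def _neighbors(seq: str, max_mismatch: int) -> Iterator[str]:
    """All sequences within Hamming distance max_mismatch of seq (A/C/G/T)."""
    yield seq
    if max_mismatch >= 1:
        for i in range(len(seq)):
            for b in _BASES:
                if b != seq[i]:
                    yield seq[:i] + b + seq[i + 1 :]
    if max_mismatch >= 2:
        for i, j in combinations(range(len(seq)), 2):
            for bi, bj in product(_BASES, _BASES):
                if bi != seq[i] and bj != seq[j]:
                    yield seq[:i] + bi + seq[i + 1 : j] + bj + seq[j + 1 :]


def _match_status(
    seq: str, library: GuideLibrary, max_mismatch: int
) -> tuple[LibraryRecord | None, str]:
    if len(seq) != library.barcode_length:
        raise ValueError(
            f"query length {len(seq)} != library barcode length "
            f"{library.barcode_length}"
        )
    hits: set[str] = set()
    if max_mismatch <= 2:
        for variant in _neighbors(seq, max_mismatch):
            if variant in library:
                hits.add(variant)
    else:
        for bc in library.barcodes:
            if hamming(seq, bc) <= max_mismatch:
                hits.add(bc)
    if len(hits) == 1:
        return library.get(hits.pop()), "assigned"
    if not hits:
        return None, "unmatched"
    return None, "ambiguous"


def match_barcode(
    seq: str, library: GuideLibrary, max_mismatch: int = 1
) -> LibraryRecord | None:
    """Unique library record within ``max_mismatch`` of seq, else None.

    The uniqueness rule is strict: if two or more library barcodes fall inside
    the budget the call is ambiguous and None is returned.  On libraries built
    with pairwise distance >= 3 this cannot trigger at max_mismatch=1.
    """
    record, _ = _match_status(seq, library, max_mismatch)
    return record


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_reads(source) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a FASTQ path/handle or (id, seq) pairs."""
    if isinstance(source, (str, Path)):
        with _open_maybe_gzip(source) as handle:
            yield from _iter_fastq(handle)
        return
    if hasattr(source, "read"):
        yield from _iter_fastq(source)
        return
    for item in source:
        rid, seq = item[0], item[1]
        yield rid, seq


def _iter_fastq(handle) -> Iterator[tuple[str, str]]:
    iterator = FastqGeneralIterator(handle)
    n = 0
    while True:
        try:
            title, seq, _qual = next(iterator)
        except StopIteration:
            return
        except ValueError as exc:
            raise ValueError(f"truncated or malformed FASTQ record {n + 1}: {exc}")
        n += 1
        yield title.split()[0], seq


def count_barcodes(
    reads,
    library: GuideLibrary,
    layout: ReadLayout,
    max_mismatch: int = 1,
) -> tuple[pd.Series, QCStats]:
    """Stream reads into a per-barcode count column plus QC tally.

    ``reads`` may be a FASTQ path (optionally .gz), an open text handle, or an
    iterable of (read_id, sequence) pairs.  Memory use is constant in the
    number of reads.
    """
    if layout.barcode_length != library.barcode_length:
        raise ValueError(
            f"layout barcode_length {layout.barcode_length} != library "
            f"barcode length {library.barcode_length}"
        )
    counts = dict.fromkeys(library.barcodes, 0)
    qc = QCStats()
    # for small mismatch budgets, precompute variant -> barcode once; identical
    # semantics to _match_status, one dict probe per read
    table: dict[str, str | None] | None = None
    if max_mismatch <= 1:
        table = {}
        for bc in library.barcodes:
            for variant in _neighbors(bc, max_mismatch):
                prior = table.get(variant, "")
                if prior == "":
                    table[variant] = bc
                elif prior != bc:
                    table[variant] = None  # >= 2 barcodes qualify: ambiguous
    for _rid, seq in _iter_reads(reads):
        qc.reads_total += 1
        window = extract_barcode(seq, layout)
        if window is None:
            qc.reads_no_anchor += 1
            continue
        if table is not None and set(window) <= set(_BASES):
            hit = table.get(window, "")
            if hit == "":
                qc.reads_unmatched += 1
            elif hit is None:
                qc.reads_ambiguous += 1
            else:
                counts[hit] += 1
                qc.reads_assigned += 1
            continue
        record, status = _match_status(window, library, max_mismatch)
        if status == "assigned":
            assert record is not None
            counts[record.barcode] += 1
            qc.reads_assigned += 1
        elif status == "ambiguous":
            qc.reads_ambiguous += 1
        else:
            qc.reads_unmatched += 1
    column = pd.Series(counts, name="count")
    column.index.name = "barcode"
    return column, qc
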