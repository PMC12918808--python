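"""Guide-library table: the barcode -> guide RNA -> gene map of a pooled screen.

Pooled CRISPRi reporter screens measure genetic perturbations through short
DNA barcodes embedded in the reporter 3'UTR.  Each guide RNA targets one gene
and carries one or more unique barcodes; the library table is the contract
between read counting and gene-level scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

LIBRARY_COLUMNS = ("barcode", "guide_id", "gene", "is_control")

_VALID_BASES = frozenset("ACGT")
_BOOL_STRINGS = {"true": True, "false": False, "1": True, "0": False}


@dataclass(frozen=True)
class LibraryRecord:
    barcode: str
    guide_id: str
    gene: str
    is_control: bool


class GuideLibrary:
    """Validated, immutable set of (barcode, guide, gene, is_control) records.

    Invariants enforced at construction: barcodes are unique and of one common
    length, every guide maps to exactly one gene, and barcodes are plain
    A/C/G/T strings.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"library table missing columns: {missing}")
        frame = frame.loc[:, list(LIBRARY_COLUMNS)].reset_index(drop=True)
        if frame.empty:
            raise ValueError("library table has no records")
        dup = frame["barcode"][frame["barcode"].duplicated()]
        if not dup.empty:
            raise ValueError(f"duplicate barcode {dup.iloc[0]!r} in library")
        lengths = frame["barcode"].str.len().unique()
        if len(lengths) != 1:
            raise ValueError(
                f"barcodes must share one length, found lengths {sorted(lengths)}"
            )
        bad = frame["barcode"][
            ~frame["barcode"].map(lambda b: set(b) <= _VALID_BASES)
        ]
        if not bad.empty:
            raise ValueError(f"barcode {bad.iloc[0]!r} contains non-ACGT characters")
        genes_per_guide = frame.groupby("guide_id")["gene"].nunique()
        conflicted = genes_per_guide[genes_per_guide > 1]
        if not conflicted.empty:
            raise ValueError(
                f"guide {conflicted.index[0]!r} maps to more than one gene"
            )
        frame["is_control"] = frame["is_control"].astype(bool)
        self._frame = frame
        self._index = {bc: i for i, bc in enumerate(frame["barcode"])}

    # -- accessors ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[LibraryRecord]:
        for row in self._frame.itertuples(index=False):
            yield LibraryRecord(row.barcode, row.guide_id, row.gene, row.is_control)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def barcodes(self) -> list[str]:
        return list(self._frame["barcode"])

    @property
    def barcode_length(self) -> int:
        return len(self._frame["barcode"].iloc[0])

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self._frame["gene"]))

    @property
    def n_guides(self) -> int:
        return self._frame["guide_id"].nunique()

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._index

    def get(self, barcode: str) -> LibraryRecord | None:
        i = self._index.get(barcode)
        if i is None:
            return None
        row = self._frame.iloc[i]
        return LibraryRecord(row.barcode, row.guide_id, row.gene, bool(row.is_control))


def parse_library_table(path: str | Path) -> GuideLibrary:
    """Read a TSV with header ``barcode guide_id gene is_control``.

    Malformed rows are reported with their 1-based file line number; duplicate
    barcodes are reported by sequence.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in LIBRARY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"library table {path}: missing columns {missing}")
    for col in LIBRARY_COLUMNS:
        na = frame[col].isna()
        if na.any():
            line = int(na.idxmax()) + 2  # +1 header, +1 one-based
            raise ValueError(f"library table {path}: malformed row at line {line}")
    flags = []
    for i, raw in enumerate(frame["is_control"]):
        flag = _BOOL_STRINGS.get(str(raw).strip().lower())
        if flag is None:
            raise ValueError(
                f"library table {path}: bad is_control value {raw!r} at line {i + 2}"
            )
        flags.append(flag)
    frame["is_control"] = flags
    return GuideLibrary(frame)


def write_library_table(library: GuideLibrary, path: str | Path) -> None:
    frame = library.frame
    frame["is_control"] = frame["is_control"].map({True: "true", False: "false"})
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
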