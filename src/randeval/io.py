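"""CSV import/export of allocation sequences and assessment tables."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .assess import AssessmentSummary
from .sequences import AllocationSequence

__all__ = [
    "export_sequences_csv",
    "import_sequences_csv",
    "summaries_to_frame",
    "export_summaries_csv",
]


def export_sequences_csv(sequences, path, labels: bool = False) -> None:
    """Write sequences to CSV with header ``seq_id,pos_1,...,pos_N``.

    Values are 0/1 by default, or ``E``/``C`` with ``labels=True``. UTF-8,
    LF line endings; round-trips losslessly with
    :func:`import_sequences_csv`.
    """
    sequences = [
        s if isinstance(s, AllocationSequence) else AllocationSequence(s) for s in sequences
    ]
    if not sequences:
        raise ValueError("no sequences to export")
    n = sequences[0].n
    if any(s.n != n for s in sequences):
        raise ValueError("all sequences must have the same length")
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["seq_id"] + [f"pos_{i}" for i in range(1, n + 1)])
        for k, s in enumerate(sequences, start=1):
            row = s.to_labels() if labels else [int(x) for x in s.assignments]
            writer.writerow([k] + row)


def import_sequences_csv(path) -> list[AllocationSequence]:
    """Read sequences written by :func:`export_sequences_csv` (0/1 or E/C)."""
    path = Path(path)
    out: list[AllocationSequence] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[0] != "seq_id":
            raise ValueError(f"{path}: expected header starting with 'seq_id'")
        for row in reader:
            if not row:
                continue
            out.append(AllocationSequence.from_labels(row[1:]))
    if not out:
        raise ValueError(f"{path}: no sequences found")
    return out


def summaries_to_frame(summaries: Iterable[AssessmentSummary]) -> pd.DataFrame:
    """Assessment summaries as a tidy DataFrame (one procedure/cell per row)."""
    return pd.DataFrame([s.to_row() for s in summaries])


def export_summaries_csv(summaries: Sequence[AssessmentSummary], path) -> None:
    """Write assessment summaries as a CSV results table."""
    summaries_to_frame(summaries).to_csv(path, index=False, lineterminator="\n")
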