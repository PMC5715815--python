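"""Allocation sequences for two-arm trials.

A sequence records, for each of N sequentially enrolled patients, whether the
patient was allocated to the experimental arm E (coded 1) or the control arm C
(coded 0). Position 1 is the first enrolled patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True, eq=False)
class AllocationSequence:
    """An allocation vector T in {0,1}^N (1 = experimental, 0 = control).

    Parameters
    ----------
    assignments
        Length-N integer vector over {0, 1}.
    """

    assignments: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.assignments, dtype=np.int8)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("assignments must be a non-empty 1-D vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("assignments must contain only 0 (C) and 1 (E)")
        arr.setflags(write=False)
        object.__setattr__(self, "assignments", arr)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AllocationSequence):
            return NotImplemented
        return np.array_equal(self.assignments, other.assignments)

    def __hash__(self) -> int:
        return hash(self.assignments.tobytes())

    @property
    def n(self) -> int:
        """Total sample size N."""
        return int(self.assignments.size)

    @property
    def n_e(self) -> int:
        """Final count on the experimental arm."""
        return int(self.assignments.sum())

    @property
    def n_c(self) -> int:
        """Final count on the control arm."""
        return self.n - self.n_e

    def counts_before(self) -> tuple[np.ndarray, np.ndarray]:
        """(N_E(i-1), N_C(i-1)) for i = 1..N: arm counts before each allocation."""
        ne = np.concatenate(([0], np.cumsum(self.assignments)[:-1]))
        idx = np.arange(self.n)
        return ne, idx - ne

    def imbalance_profile(self) -> np.ndarray:
        """D(i) = N_E(i) - N_C(i) after each allocation, i = 1..N."""
        return imbalance_profile(self.assignments)

    def complement(self) -> "AllocationSequence":
        """The sequence with arms relabelled (E <-> C)."""
        return AllocationSequence(1 - self.assignments)

    def to_labels(self) -> list[str]:
        """Render as 'E'/'C' labels."""
        return ["E" if t else "C" for t in self.assignments]

    @classmethod
    def from_labels(cls, labels) -> "AllocationSequence":
        """Build from an iterable (or string) of 'E'/'C' labels."""
        mapping = {"E": 1, "C": 0, "1": 1, "0": 0}
        try:
            return cls([mapping[str(x).strip().upper()] for x in labels])
        except KeyError as exc:
            raise ValueError(f"unknown arm label {exc.args[0]!r}") from exc

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return self.n

    def __str__(self) -> str:
        return "".join(self.to_labels())


def imbalance_profile(assignments) -> np.ndarray:
    """Signed imbalance D(i) = N_E(i) - N_C(i) along a 0/1 allocation vector."""
    arr = np.asarray(assignments, dtype=np.int64)
    return np.cumsum(2 * arr - 1)


def as_matrix(sequences) -> np.ndarray:
    """Stack sequences (AllocationSequence or 0/1 vectors) into an (r, N) array."""
    rows = [
        s.assignments if isinstance(s, AllocationSequence) else np.asarray(s, dtype=np.int8)
        for s in sequences
    ]
    return np.vstack(rows).astype(np.int8)
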