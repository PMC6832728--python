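"""Discrete categorical datasets.

Every learner in this package consumes a :class:`CategoricalDataset`: N complete
records over P categorical variables, each variable taking values coded as
integers ``0 .. arity-1``. Variable order is fixed and shared with every graph
defined over the same variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CategoricalDataset:
    """Complete categorical data with known per-variable arities.

    Parameters
    ----------
    variable_names
        Ordered identifiers for the P variables.
    arities
        Number of categories per variable; each must be >= 2.
    records
        Integer array of shape (N, P); cell (n, i) holds the category index of
        variable i in record n, in ``0 .. arities[i]-1``. Missing values are
        not representable.
    levels
        Optional per-variable category labels (index -> label), preserved so a
        dataset read from CSV round-trips losslessly.
    """

    variable_names: tuple[str, ...]
    arities: tuple[int, ...]
    records: np.ndarray
    levels: tuple[tuple[str, ...], ...] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        records = np.ascontiguousarray(self.records, dtype=np.int64)
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        object.__setattr__(self, "arities", tuple(int(r) for r in self.arities))
        p = len(self.variable_names)
        if p < 1:
            raise ValueError("dataset needs at least one variable")
        if len(self.arities) != p:
            raise ValueError("arities length must match variable_names")
        if any(r < 2 for r in self.arities):
            raise ValueError("every arity must be >= 2")
        if records.ndim != 2 or records.shape[1] != p:
            raise ValueError(f"records must be an N x {p} array")
        if records.shape[0]:
            lo = records.min(axis=0)
            hi = records.max(axis=0)
            if (lo < 0).any() or (hi >= np.asarray(self.arities)).any():
                bad = int(np.argmax((lo < 0) | (hi >= np.asarray(self.arities))))
                raise ValueError(
                    f"values of variable {self.variable_names[bad]!r} fall outside "
                    f"0..{self.arities[bad] - 1}"
                )

    @property
    def n(self) -> int:
        """Number of records N."""
        return int(self.records.shape[0])

    @property
    def p(self) -> int:
        """Number of variables P."""
        return len(self.variable_names)

    def head(self, n: int) -> "CategoricalDataset":
        """Leading-prefix slice of the first ``n`` records (shares storage)."""
        if n < 0 or n > self.n:
            raise ValueError(f"cannot take {n} leading records from {self.n}")
        return CategoricalDataset(
            self.variable_names, self.arities, self.records[:n], self.levels
        )

    def rows(self, start: int, stop: int) -> "CategoricalDataset":
        """Contiguous row block ``[start, stop)`` as a dataset."""
        if not (0 <= start <= stop <= self.n):
            raise ValueError(f"invalid row block [{start}, {stop}) for N={self.n}")
        return CategoricalDataset(
            self.variable_names, self.arities, self.records[start:stop], self.levels
        )
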