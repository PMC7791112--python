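"""Core in-memory containers: the expression matrix and the two-group design.

The expression matrix is a thin wrapper over a genes x samples
:class:`pandas.DataFrame` carrying a ``scale`` tag so downstream stages can
refuse inputs on the wrong scale (raw FPKM vs log2 vs quantile-normalized
log2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, DesignError, StateError

SCALE_FPKM = "fpkm"
SCALE_LOG2 = "log2"
SCALE_LOG2_QNORM = "log2_qnorm"
VALID_SCALES = (SCALE_FPKM, SCALE_LOG2, SCALE_LOG2_QNORM)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a scale tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample id.
    scale
        One of ``fpkm``, ``log2`` or ``log2_qnorm``. FPKM-scale values must
        be non-negative; all values must be finite.
    """

    data: pd.DataFrame
    scale: str = SCALE_FPKM

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise StateError(f"unknown scale tag {self.scale!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise DataError("expression values must be finite")
        if self.scale == SCALE_FPKM and values.size and (values < 0).any():
            raise DataError("FPKM values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def require_scale(self, *scales: str) -> None:
        if self.scale not in scales:
            raise StateError(
                f"matrix is on {self.scale!r} scale; expected one of {scales}"
            )


@dataclass
class GroupDesign:
    """Assignment of every sample to one of exactly two groups.

    ``reference`` names the baseline group (the wild type in a knockout
    comparison); fold changes are reported as test minus reference.
    """

    groups: Mapping[str, str]
    reference: str
    _labels: tuple[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.groups = dict(self.groups)
        labels = sorted(set(self.groups.values()))
        if len(labels) != 2:
            raise DesignError(f"need exactly two groups, got {labels}")
        if self.reference not in labels:
            raise DesignError(
                f"reference group {self.reference!r} not among {labels}"
            )
        for label in labels:
            n = sum(1 for g in self.groups.values() if g == label)
            if n < 2:
                raise DesignError(f"group {label!r} has {n} samples; need >= 2")
        self._labels = (labels[0], labels[1])

    @property
    def labels(self) -> tuple[str, str]:
        return self._labels

    @property
    def test_group(self) -> str:
        a, b = self._labels
        return b if a == self.reference else a

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    def indices(self, sample_ids: Iterable[str], label: str) -> np.ndarray:
        """Positions of the samples of ``label`` within ``sample_ids``."""
        ids = list(sample_ids)
        missing = [s for s in self.groups if s not in ids]
        if missing:
            raise DesignError(f"design samples {missing} absent from matrix")
        return np.array(
            [i for i, s in enumerate(ids) if self.groups.get(s) == label],
            dtype=int,
        )
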