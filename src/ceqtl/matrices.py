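"""Marker-by-clone dosage and gene-by-clone expression containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

RAW = "raw"
SMOOTHED = "smoothed"
NORMALIZED = "normalized"
BINNED = "binned"
_STATES = (RAW, SMOOTHED, NORMALIZED, BINNED)


@dataclass
class DosageMatrix:
    """Copy-number log10 ratios, rows = markers, columns = clones.

    ``state`` tracks the processing stage (raw / smoothed / normalized /
    binned); binned values are restricted to {0, 1}.
    """

    values: np.ndarray
    marker_ids: List[str]
    chrom: np.ndarray
    position: np.ndarray
    chrom_class: np.ndarray  # "autosome" | "sex" per marker
    clone_ids: List[str]
    state: str = RAW
    mask: Optional[np.ndarray] = None  # True where value missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.position = np.asarray(self.position, dtype=np.int64)
        self.chrom = np.asarray(self.chrom)
        self.chrom_class = np.asarray(self.chrom_class)
        n, m = self.values.shape
        if not (len(self.marker_ids) == len(self.chrom) == len(self.position) == n):
            raise ValueError("marker annotation length does not match value rows")
        if len(self.clone_ids) != m:
            raise ValueError("clone id count does not match value columns")
        if len(set(self.marker_ids)) != n:
            raise ValueError("duplicated marker ids")
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        for c in np.unique(self.chrom):
            pos = self.position[self.chrom == c]
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not sorted within chromosome {c}")
        if self.state == BINNED and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("binned state requires values in {0, 1}")

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_clones(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, state: str) -> "DosageMatrix":
        return replace(self, values=np.asarray(values, dtype=float), state=state)

    def chromosome_slices(self):
        """Yield ``(chrom, row-index array)`` in row order, one per chromosome run."""
        for c in dict.fromkeys(self.chrom.tolist()):
            yield c, np.flatnonzero(self.chrom == c)


@dataclass
class ExpressionMatrix:
    """Expression log10 ratios, rows = genes, columns = clones."""

    values: np.ndarray
    gene_ids: List[str]
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    clone_ids: List[str]
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        n, m = self.values.shape
        if not (len(self.gene_ids) == len(self.chrom) == len(self.start) == len(self.end) == n):
            raise ValueError("gene annotation length does not match value rows")
        if len(self.clone_ids) != m:
            raise ValueError("clone id count does not match value columns")
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicated gene ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_clones(self) -> int:
        return self.values.shape[1]
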