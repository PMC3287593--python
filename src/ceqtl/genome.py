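"""Genome coordinate bookkeeping shared by the simulator and the analysis.

Coordinates are 0-based, half-open throughout; BED dialect on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

AUTOSOME = "autosome"
SEX = "sex"


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene interval (0-based, half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )


@dataclass
class GenomeDefinition:
    """Chromosome sizes, marker grid, gene annotation and the selectable locus.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp, chrom_class)`` triples; class is ``"autosome"``
        or ``"sex"``.
    marker_positions
        Mapping chromosome -> strictly increasing marker positions (bp).
    genes
        Gene interval records.
    selectable_locus
        ``(chrom, position)`` of the locus every clone must retain.
    centromeres
        Optional mapping chromosome -> (start, end) centromere interval.
    """

    chromosomes: List[Tuple[str, int, str]]
    marker_positions: Dict[str, np.ndarray]
    genes: List[GeneRecord]
    selectable_locus: Tuple[str, int]
    centromeres: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = self.chrom_lengths
        for name, length, cls in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name}: nonpositive length {length}")
            if cls not in (AUTOSOME, SEX):
                raise ValueError(f"chromosome {name}: unknown class {cls!r}")
        for chrom, pos in self.marker_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.marker_positions[chrom] = pos
            if chrom not in lengths:
                raise ValueError(f"markers on undefined chromosome {chrom}")
            if pos.size and (pos.min() < 0 or pos.max() >= lengths[chrom]):
                raise ValueError(f"marker position outside chromosome {chrom}")
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"marker positions not strictly increasing on {chrom}")
        for g in self.genes:
            if g.chrom not in lengths:
                raise ValueError(f"gene {g.gene_id} on undefined chromosome {g.chrom}")
            if g.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")
        sel_chrom, sel_pos = self.selectable_locus
        if sel_chrom not in lengths:
            raise ValueError(f"selectable locus on undefined chromosome {sel_chrom}")
        if not (0 <= sel_pos < lengths[sel_chrom]):
            raise ValueError("selectable locus position outside chromosome")
        for chrom, (s, e) in self.centromeres.items():
            if chrom not in lengths or not (0 <= s < e <= lengths[chrom]):
                raise ValueError(f"bad centromere interval on {chrom}")

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: length for name, length, _ in self.chromosomes}

    @property
    def chrom_classes(self) -> Dict[str, str]:
        return {name: cls for name, _, cls in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(length for _, length, _ in self.chromosomes)

    @property
    def n_markers(self) -> int:
        return sum(len(p) for p in self.marker_positions.values())

    def marker_table(self) -> Tuple[List[str], np.ndarray, np.ndarray, np.ndarray]:
        """Flattened marker grid in chromosome order.

        Returns ``(ids, chroms, positions, classes)`` with one entry per marker.
        """
        ids: List[str] = []
        chroms: List[str] = []
        pos: List[int] = []
        cls: List[str] = []
        classes = self.chrom_classes
        for name, _, _ in self.chromosomes:
            p = self.marker_positions.get(name)
            if p is None:
                continue
            for j, x in enumerate(p):
                ids.append(f"{name}:{int(x)}")
                chroms.append(name)
                pos.append(int(x))
                cls.append(classes[name])
        return ids, np.array(chroms), np.array(pos, dtype=np.int64), np.array(cls)

    def nearest_marker_index(self, chrom: str, position: int) -> int:
        """Index into the flattened marker table of the marker nearest a point."""
        ids, chroms, positions, _ = self.marker_table()
        on = np.flatnonzero(chroms == chrom)
        if on.size == 0:
            raise ValueError(f"no markers on chromosome {chrom}")
        return int(on[np.argmin(np.abs(positions[on] - position))])


def uniform_genome(
    chrom_specs: Sequence[Tuple[str, int, str]],
    marker_spacing: int,
    n_genes: int,
    selectable_locus: Optional[Tuple[str, int]] = None,
    centromeres: Optional[Dict[str, Tuple[int, int]]] = None,
    gene_length: int = 20_000,
    seed: int = 0,
) -> GenomeDefinition:
    """Build a regular test genome: evenly spaced markers, random gene starts.

    Convenience constructor used by tests and the CLI `simulate` defaults.
    """
    rng = np.random.default_rng(seed)
    markers = {
        name: np.arange(marker_spacing // 2, length, marker_spacing, dtype=np.int64)
        for name, length, _ in chrom_specs
    }
    total = sum(length for _, length, _ in chrom_specs)
    genes: List[GeneRecord] = []
    for i in range(n_genes):
        # genes proportional to chromosome length
        u = rng.uniform(0, total)
        acc = 0
        for name, length, _ in chrom_specs:
            if u < acc + length:
                start = int(min(u - acc, length - gene_length - 1))
                start = max(start, 0)
                genes.append(GeneRecord(f"gene{i:05d}", name, start, start + gene_length))
                break
            acc += length
    if selectable_locus is None:
        name0, length0, _ = chrom_specs[0]
        selectable_locus = (name0, length0 // 2)
    return GenomeDefinition(
        chromosomes=list(chrom_specs),
        marker_positions=markers,
        genes=genes,
        selectable_locus=selectable_locus,
        centromeres=dict(centromeres or {}),
    )
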