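"""Genetic map: SNP chromosome assignments and base-pair positions.

Recombination follows Haldane's model at 1 cM per Mb, so a ~100 Mb
chromosome is ~1 Morgan long and crossover counts per meiosis are Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GeneticMap", "CM_PER_MB"]

CM_PER_MB = 1.0  # map density: 1 cM per Mb (Haldane, no interference)


@dataclass
class GeneticMap:
    """Globally ordered SNP map.

    Loci are 0-based and ordered by (chromosome, position); positions are
    1-based base pairs, strictly increasing within a chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    snp_id: np.ndarray | None = None
    _slices: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.snp_id is None:
            self.snp_id = np.array([f"snp{i}" for i in range(len(self.pos))])
        else:
            self.snp_id = np.asarray(self.snp_id)
        if len(self.chrom) != len(self.pos):
            raise ValueError("chrom and pos lengths differ")
        if len(self.chrom) == 0:
            raise ValueError("empty genetic map")
        if np.any(self.pos <= 0):
            raise ValueError("positions must be positive (1-based bp)")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("loci must be ordered by (chromosome, position)")
        self._slices = {}
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            if np.any(np.diff(self.pos[idx]) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}")
            self._slices[int(c)] = slice(int(idx[0]), int(idx[-1]) + 1)

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self._slices)

    def chrom_slice(self, c: int) -> slice:
        """Global locus-index slice covering chromosome ``c``."""
        return self._slices[int(c)]

    def chrom_length_bp(self, c: int) -> int:
        s = self._slices[int(c)]
        return int(self.pos[s.stop - 1])

    def chrom_morgans(self, c: int) -> float:
        """Map length of chromosome ``c`` in Morgans (span * 1 cM/Mb)."""
        s = self._slices[int(c)]
        span_bp = float(self.pos[s.stop - 1] - self.pos[s.start])
        return span_bp / 1e6 * CM_PER_MB / 100.0
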