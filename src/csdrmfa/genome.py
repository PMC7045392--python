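"""Circular chromosome coordinate system and genome landmarks.

All internal coordinates are 1-based and inclusive on a circular
chromosome. Readers for 0-based half-open formats (bedGraph/BED) convert
at the boundary. Positions recentered on *oriC* are signed base-pair
offsets in ``(-L/2, +L/2]``, positive clockwise (increasing genome
coordinate away from *oriC*, wrapping at the end of the sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "ChromosomeMap",
    "GeneRecord",
    "ECOLI_K12",
    "RRN_OPERONS",
    "circular_distance",
]


@dataclass(frozen=True)
class ChromosomeMap:
    """A circular chromosome with replication landmarks.

    Parameters
    ----------
    name : str
        Sequence name (e.g. ``"NC_000913.3"``).
    length : int
        Chromosome length in bp.
    oriC_position : int
        1-based position of the canonical replication origin.
    dif_position : int
        1-based position of the *dif* replication-terminus locus.
    ter_region : tuple of int
        Half-open interval ``[start, end)`` (1-based start) of the
        terminus region bounded by Tus-bound Ter sites. Must contain
        ``dif_position``.
    circular : bool
        Only circular chromosomes are supported by the pipeline.
    """

    name: str
    length: int
    oriC_position: int
    dif_position: int
    ter_region: tuple[int, int]
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("chromosome length must be positive")
        for label, pos in (("oriC", self.oriC_position), ("dif", self.dif_position)):
            if not 1 <= pos <= self.length:
                raise ValueError(f"{label} position {pos} outside [1, {self.length}]")
        if not self.contains_ter(self.dif_position):
            raise ValueError("ter_region must contain the dif position")

    # -- circular arithmetic -------------------------------------------------

    def wrap(self, position: int | np.ndarray) -> int | np.ndarray:
        """Map any integer position onto [1, length] (circular)."""
        return (np.asarray(position) - 1) % self.length + 1 if isinstance(
            position, np.ndarray
        ) else (position - 1) % self.length + 1

    def distance(self, a, b):
        """Shortest circular distance between positions ``a`` and ``b``."""
        return circular_distance(a, b, self.length)

    def recenter(self, positions):
        """Signed offset from oriC in ``(-L/2, +L/2]``, positive clockwise."""
        pos = np.asarray(positions, dtype=float)
        d = np.mod(pos - self.oriC_position, self.length)
        out = np.where(d > self.length / 2, d - self.length, d)
        if np.isscalar(positions) or np.ndim(positions) == 0:
            return float(out)
        return out

    def uncenter(self, offsets):
        """Inverse of :meth:`recenter`: signed offset back to genome coords."""
        off = np.asarray(offsets, dtype=float)
        pos = np.mod(self.oriC_position + off - 1, self.length) + 1
        if np.isscalar(offsets) or np.ndim(offsets) == 0:
            return float(pos)
        return pos

    def contains_ter(self, position: int) -> bool:
        """Whether ``position`` lies in ter_region (handles wrap)."""
        start, end = self.ter_region
        p = (position - 1) % self.length + 1
        if start <= end:
            return start <= p < end
        return p >= start or p < end  # ter spans the origin of coordinates

    def antipode(self, position: int) -> int:
        """Position diametrically opposite ``position`` on the circle."""
        return int((position - 1 + self.length // 2) % self.length + 1)


def circular_distance(a, b, length: int):
    """Shortest distance between coordinates on a circle of ``length`` bp."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), length)
    out = np.minimum(d, length - d)
    if np.ndim(out) == 0:
        return float(out)
    return out


@dataclass
class GeneRecord:
    """A gene with strand and functional class.

    ``gene_class`` is one of ``{"mRNA", "rRNA", "tRNA", "other"}``;
    ``essential`` is an optional annotation used by the collision-score
    gene filters.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    gene_class: str = "mRNA"
    essential: bool = False
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# E. coli K-12 MG1655 (NC_000913.3) landmarks. dif at 1,588,800; the
# terminus region defaults to dif +/- 400 kb, wide enough to cover the
# innermost Ter sites while leaving the 4.3-4.6 Mb oriK45 region intact.
ECOLI_K12 = ChromosomeMap(
    name="NC_000913.3",
    length=4_641_652,
    oriC_position=3_925_744,
    dif_position=1_588_800,
    ter_region=(1_188_800, 1_988_800),
)

# rRNA operon anchor coordinates (bp) on NC_000913.3 as used for
# inversion-end bookkeeping; strand is the direction of transcription.
RRN_OPERONS: dict[str, tuple[int, str]] = {
    "rrnH": (223_000, "+"),
    "rrnG": (2_729_000, "-"),
    "rrnD": (3_420_000, "-"),
    "rrnC": (3_940_000, "+"),
    "rrnA": (4_035_000, "+"),
    "rrnB": (4_166_000, "+"),
    "rrnE": (4_200_000, "+"),
}
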