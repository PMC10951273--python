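"""Genetic map container (marker, chromosome, centimorgan position)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "haldane_recomb_fraction"]


def haldane_recomb_fraction(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM under Haldane's
    no-interference model: c = (1 - exp(-2 d / 100)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map.

    Parameters
    ----------
    marker_id : sequence of str
        Unique marker names, ordered by chromosome then position.
    chromosome : sequence of str
        Chromosome label per marker.
    position_cm : sequence of float
        Map position in centimorgans, strictly increasing within chromosome.
    """

    marker_id: tuple[str, ...]
    chromosome: tuple[str, ...]
    position_cm: tuple[float, ...]
    _chrom_slices: dict[str, slice] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if len(self.marker_id) == 0:
            raise ValueError("genetic map is empty")
        if not (len(self.marker_id) == len(self.chromosome) == len(self.position_cm)):
            raise ValueError("map columns have unequal lengths")
        if len(set(self.marker_id)) != len(self.marker_id):
            raise ValueError("duplicate marker ids in map")
        slices: dict[str, slice] = {}
        start = 0
        for i in range(1, len(self.chromosome) + 1):
            if i == len(self.chromosome) or self.chromosome[i] != self.chromosome[start]:
                chrom = self.chromosome[start]
                if chrom in slices:
                    raise ValueError(f"chromosome {chrom!r} is not contiguous in the map")
                pos = self.position_cm[start:i]
                if any(b <= a for a, b in zip(pos, pos[1:])):
                    raise ValueError(f"positions not strictly increasing on {chrom!r}")
                if pos[0] < 0:
                    raise ValueError("negative cM position")
                slices[chrom] = slice(start, i)
                start = i
        object.__setattr__(self, "_chrom_slices", slices)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        return self._chrom_slices[chrom]

    def recomb_fractions(self, chrom: str) -> np.ndarray:
        """Adjacent-interval recombination fractions on one chromosome."""
        sl = self._chrom_slices[chrom]
        pos = np.asarray(self.position_cm[sl], dtype=float)
        return haldane_recomb_fraction(np.diff(pos))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": list(self.marker_id),
                "chrom": list(self.chromosome),
                "cM": list(self.position_cm),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        return cls(
            tuple(str(m) for m in df["marker"]),
            tuple(str(c) for c in df["chrom"]),
            tuple(float(p) for p in df["cM"]),
        )

    @classmethod
    def uniform(cls, n_markers: int, n_chrom: int = 7, length_cm: float = 100.0) -> "GeneticMap":
        """Evenly spaced map: ``n_markers`` split across ``n_chrom`` chromosomes."""
        if n_markers < n_chrom:
            n_chrom = max(1, n_markers)
        base, extra = divmod(n_markers, n_chrom)
        ids, chroms, pos = [], [], []
        k = 0
        for c in range(n_chrom):
            m = base + (1 if c < extra else 0)
            spacing = length_cm / m
            for j in range(m):
                ids.append(f"M{k:05d}")
                chroms.append(f"chr{c + 1}")
                pos.append(round(j * spacing, 6))
                k += 1
        return cls(tuple(ids), tuple(chroms), tuple(pos))
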