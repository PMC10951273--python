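"""Pedigree records (parent-offspring trios with birth years).

The pedigree is the genealogical backbone for the numerator relationship
matrix and for birth-year time series of breeding values. Unknown parents are
coded as ``None`` internally; "0" or the empty string on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "PedigreeError"]


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Validated, topologically sorted pedigree.

    Construct with :meth:`from_frame`; rows may arrive in any order and are
    re-sorted so every parent precedes its offspring.
    """

    ids: list[str]
    sire: list[str | None]
    dam: list[str | None]
    birth_year: list[float]  # NaN when unknown

    @classmethod
    def from_frame(cls, df: pd.DataFrame, strict_years: bool = False) -> "Pedigree":
        ids = [str(x) for x in df["id"]]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
            raise PedigreeError(f"duplicate id in pedigree: {dup!r}")

        def _clean(col):
            out = []
            for v in col:
                if pd.isna(v) or str(v).strip() in ("", "0", "0.0"):
                    out.append(None)
                else:
                    out.append(str(v).strip())
            return out

        sire = _clean(df["sire"])
        dam = _clean(df["dam"])
        if "birth_year" in df.columns:
            year = [float(v) if not pd.isna(v) else float("nan") for v in df["birth_year"]]
        else:
            year = [float("nan")] * len(ids)

        for i, d, s in zip(ids, dam, sire):
            if i == d or i == s:
                raise PedigreeError(f"individual {i!r} listed as its own parent")
        known = set(ids)
        for p in sire + dam:
            if p is not None and p not in known:
                raise PedigreeError(f"parent {p!r} has no pedigree record")

        order = cls._toposort(ids, sire, dam)
        idx = {v: k for k, v in enumerate(ids)}
        perm = [idx[i] for i in order]
        ped = cls(
            [ids[k] for k in perm],
            [sire[k] for k in perm],
            [dam[k] for k in perm],
            [year[k] for k in perm],
        )
        ped._check_years(strict=strict_years)
        return ped

    @staticmethod
    def _toposort(ids, sire, dam) -> list[str]:
        """Kahn's algorithm; raises naming a cycle member if one exists."""
        children: dict[str, list[str]] = {i: [] for i in ids}
        indeg = {i: 0 for i in ids}
        for child, s, d in zip(ids, sire, dam):
            for p in {s, d} - {None}:
                children[p].append(child)
                indeg[child] += 1
        queue = [i for i in ids if indeg[i] == 0]
        out: list[str] = []
        while queue:
            nxt = queue.pop(0)
            out.append(nxt)
            for c in children[nxt]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(out) != len(ids):
            cyclic = sorted(i for i in ids if indeg[i] > 0)
            raise PedigreeError(f"pedigree contains a cycle involving: {cyclic[:10]}")
        return out

    def _check_years(self, strict: bool):
        year = dict(zip(self.ids, self.birth_year))
        for i, s, d in zip(self.ids, self.sire, self.dam):
            for p in (s, d):
                if p is None:
                    continue
                if not (np.isnan(year[p]) or np.isnan(year[i])) and year[p] >= year[i]:
                    msg = f"parent {p!r} (year {year[p]:.0f}) not older than {i!r} ({year[i]:.0f})"
                    if strict:
                        raise PedigreeError(msg)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def founders(self) -> list[str]:
        return [i for i, s, d in zip(self.ids, self.sire, self.dam) if s is None and d is None]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) into the sorted order; -1 for unknown."""
        pos = {v: k for k, v in enumerate(self.ids)}
        s = np.array([pos[p] if p is not None else -1 for p in self.sire], dtype=np.int64)
        d = np.array([pos[p] if p is not None else -1 for p in self.dam], dtype=np.int64)
        return s, d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": ["0" if p is None else p for p in self.sire],
                "dam": ["0" if p is None else p for p in self.dam],
                "birth_year": self.birth_year,
            }
        )
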