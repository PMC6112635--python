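"""Phecode map: ICD-9 → phecode grouping with hierarchy and exclusion ranges.

Phecodes aggregate ICD-9 billing codes into clinically meaningful
phenotypes arranged by string prefix: ``250.2`` (type 2 diabetes) is the
parent of ``250.21`` … ``250.25``. Each phecode carries numeric exclusion
intervals; patients whose only related codes fall inside those intervals
are removed from that phenotype's control pool.

The bundled miniature map covers the diabetes family (type 1 and the six
type 2 phecodes), ischemic heart disease (411.*) and chronic kidney
disease (585.3x) — a deliberately small synthetic subset of a full map; a
complete external map in the same two-file CSV schema can be loaded with
:meth:`PhecodeMap.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["PhecodeMap", "T2DM_PHECODES"]

#: The six type-2-diabetes phecodes screened in the discovery phase.
T2DM_PHECODES = ["250.2", "250.21", "250.22", "250.23", "250.24", "250.25"]


def _is_descendant(phecode: str, ancestor: str) -> bool:
    """Prefix hierarchy: 250.21 descends from 250.2, which descends from 250."""
    if phecode == ancestor:
        return True
    if not phecode.startswith(ancestor):
        return False
    rest = phecode[len(ancestor):]
    return rest.isdigit() or (rest.startswith(".") and rest[1:].isdigit())


@dataclass(frozen=True)
class PhecodeMap:
    """ICD-9 → phecode rows plus per-phecode exclusion intervals."""

    icd9_to_phecode: pd.DataFrame  # columns icd9, phecode
    exclusions: pd.DataFrame  # columns phecode, exclude_low, exclude_high
    _by_icd9: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for col in ("icd9", "phecode"):
            if col not in self.icd9_to_phecode.columns:
                raise ValueError(f"phecode map: missing column {col!r}")
        for col in ("phecode", "exclude_low", "exclude_high"):
            if col not in self.exclusions.columns:
                raise ValueError(f"phecode exclusions: missing column {col!r}")
        bad = self.exclusions["exclude_low"] > self.exclusions["exclude_high"]
        if bad.any():
            raise ValueError("phecode exclusions: intervals must satisfy low <= high")
        mapped = set(self.icd9_to_phecode["phecode"].astype(str))
        listed = set(self.exclusions["phecode"].astype(str))
        missing = mapped - listed
        if missing:
            raise ValueError(
                f"phecode exclusions: no entry (even empty) for phecodes {sorted(missing)}"
            )
        object.__setattr__(
            self,
            "_by_icd9",
            self.icd9_to_phecode.groupby("icd9")["phecode"].apply(list).to_dict(),
        )

    @classmethod
    def bundled(cls) -> "PhecodeMap":
        """The miniature map shipped with the package."""
        pkg = resources.files("ldlt2dm.data")
        return cls.from_csv(pkg / "phecode_icd9.csv", pkg / "phecode_exclusions.csv")

    @classmethod
    def from_csv(cls, map_path, exclusions_path) -> "PhecodeMap":
        with resources.as_file(map_path) if not isinstance(map_path, (str, Path)) else _noop(map_path) as p1:
            m = pd.read_csv(p1, dtype={"icd9": str, "phecode": str})
        with resources.as_file(exclusions_path) if not isinstance(exclusions_path, (str, Path)) else _noop(exclusions_path) as p2:
            e = pd.read_csv(p2, dtype={"phecode": str})
        return cls(m, e)

    @property
    def phecodes(self) -> list[str]:
        return sorted(set(self.icd9_to_phecode["phecode"]))

    def contains(self, phenotype_id: str) -> bool:
        return phenotype_id in set(self.icd9_to_phecode["phecode"])

    def phecodes_for(self, icd9: str) -> list[str]:
        return self._by_icd9.get(icd9, [])

    def icd9_for(self, phenotype_id: str, include_descendants: bool = True) -> set[str]:
        """All ICD-9 codes mapping to a phecode (and, by default, its children)."""
        m = self.icd9_to_phecode
        if include_descendants:
            mask = m["phecode"].map(lambda p: _is_descendant(p, phenotype_id))
        else:
            mask = m["phecode"] == phenotype_id
        return set(m.loc[mask, "icd9"])

    def exclusion_intervals(self, phenotype_id: str) -> list[tuple[float, float]]:
        e = self.exclusions[self.exclusions["phecode"] == phenotype_id]
        return [
            (float(lo), float(hi))
            for lo, hi in zip(e["exclude_low"], e["exclude_high"])
        ]

    def in_exclusion_range(self, phenotype_id: str, icd9: str) -> bool:
        """Whether an ICD-9 code maps to a phecode inside the exclusion ranges."""
        intervals = self.exclusion_intervals(phenotype_id)
        if not intervals:
            return False
        for phe in self.phecodes_for(icd9):
            try:
                v = float(phe)
            except ValueError:  # non-numeric phecode (none in ICD-9 maps)
                continue
            if any(lo <= v <= hi for lo, hi in intervals):
                return True
        return False


class _noop:
    """Context manager passthrough for plain filesystem paths."""

    def __init__(self, path):
        self.path = path

    def __enter__(self):
        return self.path

    def __exit__(self, *exc):
        return False
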