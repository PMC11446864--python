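"""Fragment registry with field-collection provenance and triage grouping.

Field collection labels every fragment with the grid sector and bag it
came from; before any matching, fragments below the minimum-length rule
are excluded and the rest are sorted by bone type (diaphysis, flat bone,
epiphysis/short bones), then anatomical region, then — where the operator
could tell — the bone itself.  Candidate match pairs may only be drawn
from within the same innermost non-empty group.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .ct import MIN_FRAGMENT_LENGTH_MM

__all__ = ["FragmentRecord", "read_registry", "write_registry", "triage"]

BONE_TYPES = ("diaphysis", "flat_bone", "epiphysis_short")
REGIONS = ("head", "trunk", "upper_limb", "lower_limb")


@dataclasses.dataclass
class FragmentRecord:
    """One collected fragment and its operator-supplied classification."""

    fragment_id: str
    source_file: str
    sector: str
    bag: str
    bone_type: str
    region: str
    length_mm: float
    bone_name: Optional[str] = None
    retained: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.bone_type not in BONE_TYPES:
            raise ValueError(
                f"record {self.fragment_id}: unknown bone_type {self.bone_type!r} "
                f"(expected one of {BONE_TYPES})"
            )
        if self.region not in REGIONS:
            raise ValueError(
                f"record {self.fragment_id}: unknown region {self.region!r} "
                f"(expected one of {REGIONS})"
            )
        derived = self.length_mm >= MIN_FRAGMENT_LENGTH_MM
        if self.retained is None:
            self.retained = derived
        elif self.retained != derived:
            raise ValueError(
                f"record {self.fragment_id}: retained={self.retained} inconsistent "
                f"with length {self.length_mm} mm at threshold {MIN_FRAGMENT_LENGTH_MM} mm"
            )


_CSV_COLUMNS = [
    "fragment_id",
    "source_file",
    "sector",
    "bag",
    "bone_type",
    "region",
    "bone_name",
    "length_mm",
    "retained",
]


def read_registry(path: str | Path) -> list[FragmentRecord]:
    df = pd.read_csv(path, dtype={"fragment_id": str, "sector": str, "bag": str})
    records = []
    for row in df.itertuples(index=False):
        bone_name = getattr(row, "bone_name", None)
        if pd.isna(bone_name):
            bone_name = None
        records.append(
            FragmentRecord(
                fragment_id=str(row.fragment_id),
                source_file=str(row.source_file),
                sector=str(row.sector),
                bag=str(row.bag),
                bone_type=str(row.bone_type),
                region=str(row.region),
                bone_name=bone_name,
                length_mm=float(row.length_mm),
            )
        )
    ids = [r.fragment_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fragment IDs in registry")
    return records


def write_registry(records: Sequence[FragmentRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)


def triage(records: Sequence[FragmentRecord]) -> dict[tuple[str, str, str], list[str]]:
    """Group retained fragments into candidate pools for matching.

    Returns ``{(bone_type, region, bone_name-or-''): [fragment_id, ...]}``
    with IDs sorted, so the grouping is independent of registry row order.
    Pools partition the retained set: match plans should only pair
    fragments within one pool.
    """
    ids = [r.fragment_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fragment IDs in registry")
    pools: dict[tuple[str, str, str], list[str]] = {}
    for r in records:
        if not r.retained:
            continue
        key = (r.bone_type, r.region, r.bone_name or "")
        pools.setdefault(key, []).append(r.fragment_id)
    return {key: sorted(members) for key, members in sorted(pools.items())}
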