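"""Dataclass view of one family's members and phenotypes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Member", "FamilyRecord", "families_from_frame"]


@dataclass
class Member:
    role: str
    sex: str
    age: dict = field(default_factory=dict)  # wave -> years
    life_events: dict = field(default_factory=dict)
    anx_dep: dict = field(default_factory=dict)
    wellbeing: dict = field(default_factory=dict)
    pgs_wb: float = np.nan
    pgs_res: float = np.nan
    pcs: tuple = ()
    platform: str = ""


@dataclass
class FamilyRecord:
    """One family: exactly two twins (possibly with missing phenotypes)
    plus up to two non-twin siblings."""

    family_id: int
    zygosity: str
    members: list[Member]

    def __post_init__(self):
        twins = [m for m in self.members if m.role in ("twin1", "twin2")]
        sibs = [m for m in self.members if m.role == "sibling"]
        if len(twins) != 2:
            raise ValueError(f"family {self.family_id}: expected 2 twins, got {len(twins)}")
        if len(sibs) > 2:
            raise ValueError(f"family {self.family_id}: more than 2 siblings")
        t1, t2 = twins
        if self.zygosity in ("MZM", "MZF") and t1.sex != t2.sex:
            raise ValueError(f"family {self.family_id}: MZ twins must share sex")
        if self.zygosity == "DOS" and t1.sex == t2.sex:
            raise ValueError(f"family {self.family_id}: DOS twins must have opposite sexes")
        for m in self.members:
            for w, v in m.life_events.items():
                if np.isfinite(v) and v < 0:
                    raise ValueError(f"family {self.family_id}: negative life events at {w}")


def families_from_frame(frame: pd.DataFrame) -> list[FamilyRecord]:
    """Convert a phenotype table (one row per individual) to records."""
    out = []
    pc_cols = [f"pc{i}" for i in range(1, 11) if f"pc{i}" in frame.columns]
    for fid, fam in frame.groupby("family_id"):
        members = []
        for _, row in fam.iterrows():
            members.append(
                Member(
                    role=row["role"],
                    sex=row["sex"],
                    age={w: row.get(f"age_{w}", np.nan) for w in ("t1", "t2")},
                    life_events={w: row.get(f"life_events_{w}", np.nan) for w in ("t1", "t2")},
                    anx_dep={w: row.get(f"anxdep_{w}", np.nan) for w in ("t1", "t2")},
                    wellbeing={w: row.get(f"wellbeing_{w}", np.nan) for w in ("t1", "t2")},
                    pgs_wb=row.get("pgs_wb", np.nan),
                    pgs_res=row.get("pgs_res", np.nan),
                    pcs=tuple(row[c] for c in pc_cols),
                    platform=row.get("platform", ""),
                )
            )
        out.append(FamilyRecord(family_id=fid, zygosity=fam["zygosity"].iloc[0], members=members))
    return out
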