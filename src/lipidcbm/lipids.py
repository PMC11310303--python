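"""Lipid variable annotation: the unit record of a shotgun (DI-MS) dataset.

A direct-infusion measurement identifies species by accurate mass alone, so a
variable is a *sum composition* — e.g. PC(38:6) is a phosphatidylcholine with
38 acyl carbons and 6 double bonds in total, without knowing the individual
fatty acids.  The (class, carbons, double_bonds, mode) tuple is the unique key
of a variable within a theoretical library.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

LIPID_CLASSES = ("PC", "PE", "PC-O", "LPC", "LPE", "LPS", "CL", "TG", "DG", "SM", "other")

MZ_MIN = 150.0
MZ_MAX = 1200.0

Mode = Literal["positive", "negative"]


@dataclass(frozen=True)
class LipidVariable:
    variable_id: str
    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    mode: Mode
    theoretical_mz: float

    def __post_init__(self) -> None:
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(f"unknown lipid class {self.lipid_class!r}")
        if self.total_carbons < 0 or self.total_double_bonds < 0:
            raise ValueError("carbons and double bonds must be non-negative")
        if not MZ_MIN <= self.theoretical_mz <= MZ_MAX:
            raise ValueError(
                f"theoretical m/z {self.theoretical_mz} outside [{MZ_MIN}, {MZ_MAX}] Da"
            )

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.lipid_class, self.total_carbons, self.total_double_bonds, self.mode)

    @property
    def name(self) -> str:
        return f"{self.lipid_class}({self.total_carbons}:{self.total_double_bonds})"


def check_unique_keys(library: Iterable[LipidVariable]) -> None:
    """Reject duplicate (class, carbons, double_bonds, mode) keys."""
    seen: set[tuple] = set()
    for var in library:
        if var.key in seen:
            raise ValueError(f"duplicate lipid species key {var.key}")
        seen.add(var.key)


def library_frame(library: Iterable[LipidVariable]) -> pd.DataFrame:
    """Library as a DataFrame indexed by variable_id (CSV-ready)."""
    rows = [
        {
            "variable_id": v.variable_id,
            "name": v.name,
            "lipid_class": v.lipid_class,
            "total_carbons": v.total_carbons,
            "total_double_bonds": v.total_double_bonds,
            "mode": v.mode,
            "theoretical_mz": v.theoretical_mz,
        }
        for v in library
    ]
    return pd.DataFrame(rows).set_index("variable_id")


def library_from_frame(frame: pd.DataFrame) -> list[LipidVariable]:
    if "variable_id" in frame.columns:
        frame = frame.set_index("variable_id")
    out = [
        LipidVariable(
            variable_id=str(idx),
            lipid_class=row["lipid_class"],
            total_carbons=int(row["total_carbons"]),
            total_double_bonds=int(row["total_double_bonds"]),
            mode=row["mode"],
            theoretical_mz=float(row["theoretical_mz"]),
        )
        for idx, row in frame.iterrows()
    ]
    check_unique_keys(out)
    return out
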