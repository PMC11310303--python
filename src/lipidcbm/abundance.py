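"""Per-mille normalization and grouped-abundance aggregation.

Because direct-infusion intensities have no absolute scale, each biological
sample's retained signals are expressed relative to that sample's total: each
value is divided by the sample sum and multiplied by 1000 (per mille, ‰).
Missing values stay missing and are excluded from the denominator.

Aggregations over the per-mille table serve the grouped analyses: whole lipid
classes, unsaturation bands of PC/PE (three or fewer vs four or more double
bonds), LC-PUFA content (compositional rules for TG/DG, curated species sets
for PC), and arbitrary curated species sets such as ARA- or DHA-containing
PC/PE lists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipids import LipidVariable
from .qc import SignalTable

PER_MILLE_TOTAL = 1000.0


@dataclass
class AbundanceTable:
    """Per-mille relative abundances over retained variables (biological
    samples only; non-missing values in each row sum to 1000)."""

    mode: str
    samples: pd.DataFrame
    values: pd.DataFrame
    library: list[LipidVariable] = field(default_factory=list)

    def variable_ids(self) -> list[str]:
        return list(self.values.columns)


def to_per_mille(table: SignalTable) -> AbundanceTable:
    """Normalize a retained signal table to per-mille relative abundance.

    QC samples are dropped (the scale is defined over biological signal);
    zeros are treated as not measured.  A sample with no measured signal at
    all cannot be normalized and raises, naming the sample.
    """
    bio = table.biological.astype(float).replace(0.0, np.nan)
    totals = bio.sum(axis=1, skipna=True)
    empty = totals[bio.notna().sum(axis=1) == 0]
    if len(empty):
        raise ValueError(f"sample(s) with all values missing: {list(empty.index)}")
    values = bio.div(totals, axis=0) * PER_MILLE_TOTAL
    samples = table.samples.loc[values.index]
    return AbundanceTable(mode=table.mode, samples=samples, values=values,
                          library=list(table.library))


# --------------------------------------------------------------------------
# grouping rules
# --------------------------------------------------------------------------

UNSATURATION_SPLIT = 4  # >= 4 double bonds is the high-unsaturation band


def band_by_unsaturation(library: list[LipidVariable]) -> dict[str, str]:
    """Partition PC/PE variables into '<=3 double bonds' / '>=4 double bonds'."""
    out = {}
    for v in library:
        if v.lipid_class not in ("PC", "PE"):
            raise ValueError(f"unsaturation bands are defined for PC/PE, got {v.lipid_class}")
        out[v.variable_id] = (">=4 double bonds"
                              if v.total_double_bonds >= UNSATURATION_SPLIT
                              else "<=3 double bonds")
    return out


@dataclass
class SpeciesGroupDefinition:
    """A curated species set (e.g. ARA-containing PC), supplied as input:
    sum compositions alone cannot identify the fatty acids, so membership
    comes from targeted fragmentation data."""

    group_name: str
    members: list[str]
    provenance: str = ""


def check_disjoint(groups: list[SpeciesGroupDefinition]) -> None:
    seen: dict[str, str] = {}
    for g in groups:
        for m in g.members:
            if m in seen:
                raise ValueError(
                    f"variable {m!r} in both {seen[m]!r} and {g.group_name!r}")
            seen[m] = g.group_name


# LC-PUFA compositional rules: a glyceride is expected to contain a
# long-chain PUFA when its sum composition is large and unsaturated enough.
LCPUFA_RULES = {"TG": (54, 5), "DG": (38, 5)}


def classify_lcpufa(variable: LipidVariable,
                    curated_sets: list[SpeciesGroupDefinition] | None = None) -> bool:
    """Is this TG/DG/PC variable expected to contain a LC-PUFA?

    TG: >=54 carbons and >=5 double bonds.  DG: >=38 carbons and >=5 double
    bonds.  PC: membership in a curated LC-PUFA set (required — the sum
    composition cannot identify fatty acids).
    """
    cls = variable.lipid_class
    if cls in LCPUFA_RULES:
        min_c, min_db = LCPUFA_RULES[cls]
        return variable.total_carbons >= min_c and variable.total_double_bonds >= min_db
    if cls == "PC":
        if not curated_sets:
            raise ValueError(
                "PC LC-PUFA status requires a curated species set "
                "(cannot be inferred from the sum composition)")
        members = {m for g in curated_sets for m in g.members}
        return variable.variable_id in members or variable.name in members
    raise ValueError(f"LC-PUFA classification is defined for TG/DG/PC, got {cls}")


def group_by_class(library: list[LipidVariable]) -> dict[str, str]:
    return {v.variable_id: v.lipid_class for v in library}


def group_by_lcpufa(library: list[LipidVariable],
                    curated_sets: list[SpeciesGroupDefinition] | None = None,
                    classes=("TG", "DG", "PC")) -> dict[str, str]:
    """Map each TG/DG/PC variable to '<class> LC-PUFA' or '<class> non-LC-PUFA'."""
    out = {}
    for v in library:
        if v.lipid_class not in classes:
            continue
        flag = classify_lcpufa(v, curated_sets)
        out[v.variable_id] = f"{v.lipid_class} {'LC-PUFA' if flag else 'non-LC-PUFA'}"
    return out


def aggregate(abundance: AbundanceTable, grouping: dict[str, str],
              kind: str = "custom") -> pd.DataFrame:
    """Sum per-mille abundances over group members, per sample.

    ``grouping`` maps variable_id -> group name (each variable in at most one
    group).  Missing values count as zero in the sum so group totals are
    always defined.  Returns a long-format frame (sample_id, group_id,
    grouping, group_name, abundance_permille).
    """
    unknown = set(grouping) - set(abundance.values.columns)
    if unknown:
        raise ValueError(f"grouping covers unretained variables: {sorted(unknown)}")
    names = sorted(set(grouping.values()))
    rows = []
    for name in names:
        members = [v for v, g in grouping.items() if g == name]
        if not members:
            warnings.warn(f"empty group {name!r}")
        summed = abundance.values[members].fillna(0.0).sum(axis=1)
        for sid, val in summed.items():
            rows.append({"sample_id": sid,
                         "group_id": abundance.samples.loc[sid, "group_id"],
                         "grouping": kind, "group_name": name,
                         "abundance_permille": float(val)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# isoform assignment
# --------------------------------------------------------------------------

def assign_isoform(candidates: list[tuple[str, float]]):
    """Choose the most abundant sn-1/sn-2 isoform from fragmentation evidence.

    ``candidates`` are (composition, share-of-total-signal) pairs.  Returns
    a dict with the chosen isoform, its share (as a percentage), and an
    ``ambiguous`` flag set when the maximum is tied (ties break to the
    lexicographically first composition).  An empty candidate list yields an
    'undetermined' assignment.
    """
    if not candidates:
        return {"isoform": "undetermined", "share": np.nan, "ambiguous": False}
    if any(share < 0 for _, share in candidates):
        raise ValueError("isoform shares must be non-negative")
    best = max(s for _, s in candidates)
    winners = sorted(name for name, s in candidates if s == best)
    return {"isoform": winners[0], "share": float(best), "ambiguous": len(winners) > 1}
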