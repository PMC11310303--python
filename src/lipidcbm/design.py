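"""Cohort design: experimental groups and genotype-matched replicate comparisons.

The study layout this package targets is an eight-group mouse cohort in which
virgin and pregnant dams are compared while holding the maternal *Dlk1*
genotype fixed, and DLK1-manipulated pregnant groups are compared while
holding either the fetal or the maternal source of DLK1 fixed.  The unit of
replication for biomarker discovery is the *genotype-matched comparison*: a
candidate biomarker must reproduce across at least two such comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

Genotype = Literal["WT", "Mat", "null"]
FetalDlk1 = Literal["present", "absent", "n/a"]
ComparisonKind = Literal["virgin_vs_pregnant", "fetal_effect", "maternal_effect"]


@dataclass(frozen=True)
class Group:
    group_id: int
    pregnant: bool
    maternal_genotype: Genotype
    fetal_dlk1: FetalDlk1

    def __post_init__(self) -> None:
        if not 1 <= self.group_id <= 8:
            raise ValueError(f"group_id must be 1..8, got {self.group_id}")
        if not self.pregnant and self.fetal_dlk1 != "n/a":
            raise ValueError("virgin groups carry no fetal DLK1 status")


@dataclass(frozen=True)
class Comparison:
    """A two-group contrast; ``group_b`` is the 'treated' side (pregnant, or
    DLK1-deficient), so a positive direction means higher in ``group_b``."""

    name: str
    group_a: int
    group_b: int
    kind: ComparisonKind
    replicate_set_id: str


@dataclass
class StudyDesign:
    groups: list[Group] = field(default_factory=list)
    comparisons: list[Comparison] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {g.group_id for g in self.groups}
        if len(ids) != len(self.groups):
            raise ValueError("duplicate group ids in design")
        for c in self.comparisons:
            for gid in (c.group_a, c.group_b):
                if gid not in ids:
                    raise ValueError(
                        f"comparison {c.name!r} references missing group {gid}"
                    )
        for rid in {c.replicate_set_id for c in self.comparisons}:
            if len(self.replicate_set(rid)) < 2:
                raise ValueError(f"replicate set {rid!r} has fewer than 2 comparisons")

    def group(self, group_id: int) -> Group:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    def replicate_set(self, replicate_set_id: str) -> list[Comparison]:
        return [c for c in self.comparisons if c.replicate_set_id == replicate_set_id]

    @property
    def replicate_set_ids(self) -> list[str]:
        seen: list[str] = []
        for c in self.comparisons:
            if c.replicate_set_id not in seen:
                seen.append(c.replicate_set_id)
        return seen


def default_design() -> StudyDesign:
    """The eight-group cohort with its three replicate comparison sets.

    Virgin-vs-pregnant pairs share a maternal genotype (1v2 WT, 6v8 Mat,
    3v5 null).  Fetal-effect pairs contrast pregnant dams with and without a
    functional fetal *Dlk1* copy at matched maternal genotype (8v7, 5v4);
    maternal-effect pairs contrast maternal genotypes at matched fetal DLK1
    (8v5, 7v4).
    """
    groups = [
        Group(1, False, "WT", "n/a"),
        Group(2, True, "WT", "present"),
        Group(3, False, "null", "n/a"),
        Group(4, True, "null", "absent"),
        Group(5, True, "null", "present"),
        Group(6, False, "Mat", "n/a"),
        Group(7, True, "Mat", "absent"),
        Group(8, True, "Mat", "present"),
    ]
    comparisons = [
        Comparison("1v2", 1, 2, "virgin_vs_pregnant", "pregnancy"),
        Comparison("6v8", 6, 8, "virgin_vs_pregnant", "pregnancy"),
        Comparison("3v5", 3, 5, "virgin_vs_pregnant", "pregnancy"),
        Comparison("8v7", 8, 7, "fetal_effect", "fetal_effect"),
        Comparison("5v4", 5, 4, "fetal_effect", "fetal_effect"),
        Comparison("8v5", 8, 5, "maternal_effect", "maternal_effect"),
        Comparison("7v4", 7, 4, "maternal_effect", "maternal_effect"),
    ]
    return StudyDesign(groups=groups, comparisons=comparisons)
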