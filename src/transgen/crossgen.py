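"""Cross-generation effect classification and identifier-set partitioning.

Generation F1 carries direct effects, F2 intergenerational effects and F3
transgenerational effects.  Differential-call identifier sets from the
three generations are partitioned into the seven exclusive Venn regions;
"inherited" sets are the plain F1-intersections regardless of third-set
membership.  Direction concordance flags identifiers whose up/down call
differs between the generations in which they appear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

GENERATIONS = ("F1", "F2", "F3")

EFFECT_CLASS = {
    "F1": "direct",
    "F2": "intergenerational",
    "F3": "transgenerational",
}

REGION_LABELS = (
    "F1only", "F2only", "F3only",
    "F1F2only", "F1F3only", "F2F3only",
    "F1F2F3",
)


@dataclass(frozen=True)
class VennPartition:
    region_sets: Mapping[str, frozenset]
    inherited_F2: frozenset  # F1 & F2, any F3 status
    inherited_F3: frozenset  # F1 & F3, any F2 status

    def union(self) -> frozenset:
        out: frozenset = frozenset()
        for s in self.region_sets.values():
            out |= s
        return out


@dataclass(frozen=True)
class ConcordanceRecord:
    id: str
    directions: Mapping[str, str]
    concordant: bool


@dataclass(frozen=True)
class EffectClass:
    generation: str
    label: str


def venn_partition(set_f1: Iterable, set_f2: Iterable, set_f3: Iterable) -> VennPartition:
    """Exact three-set partition into the seven exclusive Venn regions."""
    s1, s2, s3 = frozenset(set_f1), frozenset(set_f2), frozenset(set_f3)
    regions = {
        "F1only": s1 - s2 - s3,
        "F2only": s2 - s1 - s3,
        "F3only": s3 - s1 - s2,
        "F1F2only": (s1 & s2) - s3,
        "F1F3only": (s1 & s3) - s2,
        "F2F3only": (s2 & s3) - s1,
        "F1F2F3": s1 & s2 & s3,
    }
    return VennPartition(
        region_sets=regions,
        inherited_F2=s1 & s2,
        inherited_F3=s1 & s3,
    )


def direction_concordance(
    records: Mapping[str, Iterable[tuple[str, str]]],
) -> list[ConcordanceRecord]:
    """Per-id direction agreement across generations.

    ``records`` maps generation label -> iterable of ``(id, direction)``.
    Ids present in fewer than two generations are excluded.  A duplicated
    id with contradictory directions within one generation raises, naming
    the id.
    """
    by_gen: dict[str, dict[str, str]] = {}
    for gen, pairs in records.items():
        table: dict[str, str] = {}
        for ident, direction in pairs:
            if ident in table and table[ident] != direction:
                raise ValueError(
                    f"contradictory directions for id {ident!r} in generation {gen!r}"
                )
            table[ident] = direction
        by_gen[gen] = table
    all_ids = sorted({i for t in by_gen.values() for i in t})
    out = []
    for ident in all_ids:
        dirs = {g: t[ident] for g, t in by_gen.items() if ident in t}
        if len(dirs) < 2:
            continue
        out.append(
            ConcordanceRecord(
                id=ident,
                directions=dirs,
                concordant=len(set(dirs.values())) == 1,
            )
        )
    return out


def classify_effect(generation: str) -> EffectClass:
    """Fixed mapping F1 -> direct, F2 -> intergenerational, F3 -> transgenerational."""
    if generation not in EFFECT_CLASS:
        raise ValueError(f"unknown generation {generation!r}")
    return EffectClass(generation=generation, label=EFFECT_CLASS[generation])
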