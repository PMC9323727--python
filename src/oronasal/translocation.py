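"""Rule-based screen for bacteria translocating between the oral and nasal niches.

A genus is called an oral-to-nasal translocator (for a given case group vs the
healthy group of the same age class) when it meets three conditions on
group-mean relative abundances, with M(group, niche) the per-genus mean of
per-sample fractions:

  c1  the genus is a reported high-rate colonizer of the source niche
      (reference list), is absent (mean <= detection_floor, default 0) from the
      target niche of the healthy group, and present (> detection_floor) in the
      target niche of the case group;
  c2  its healthy-group content is < 0.01% in the target niche but > 0.01% in
      the source niche;
  c3  it is non-dominant (< 1%) in the healthy target niche but dominant
      (> 1%) in the case target niche.

The nasal-to-oral screen mirrors every condition with the niches swapped.
"Time-stable" translocators are the intersection of the oral-to-nasal sets
across cohort comparisons (CP children, CP adolescents, postoperative
adolescents). The module is fully deterministic.

The strict reading of "not found" (detection_floor = 0, literal absence) and a
relaxed reading (detection_floor = minor_threshold, since conditions c1 and c3
otherwise conflict for genera present at trace level) are both supported and
reported side by side by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .tables import AbundanceTable, Stratum, group_mean_relative

__all__ = [
    "TranslocationCriteria",
    "TranslocationReport",
    "TSIntersection",
    "default_reference_list",
    "screen_translocation",
    "intersect_ts",
    "ts_abundance_profile",
    "ORAL_TO_NASAL",
    "NASAL_TO_ORAL",
]

ORAL_TO_NASAL = "oral_to_nasal"
NASAL_TO_ORAL = "nasal_to_oral"


def default_reference_list(direction: str = ORAL_TO_NASAL) -> frozenset[str]:
    """Reference colonizer genera for the source niche, from the packaged lists."""
    name = "oral_colonizers.txt" if direction == ORAL_TO_NASAL else "nasal_colonizers.txt"
    text = resources.files("oronasal.data").joinpath(name).read_text(encoding="utf-8")
    genera = [line.strip() for line in text.splitlines()]
    return frozenset(g for g in genera if g and not g.startswith("#"))


@dataclass(frozen=True)
class TranslocationCriteria:
    detection_floor: float = 0.0  # fraction; 0 means literal absence
    minor_threshold: float = 1e-4  # 0.01%
    dominance_threshold: float = 1e-2  # 1%
    combination_mode: str = "all"  # conjunctive; "any" for sensitivity analysis
    reference_list: frozenset[str] = field(default_factory=lambda: default_reference_list())

    def __post_init__(self) -> None:
        if not (self.detection_floor <= self.minor_threshold < self.dominance_threshold):
            raise ValueError(
                "criteria must satisfy detection_floor <= minor_threshold < dominance_threshold"
            )
        if self.combination_mode not in ("all", "any"):
            raise ValueError("combination_mode must be 'all' or 'any'")

    def relaxed(self) -> "TranslocationCriteria":
        """Variant with detection_floor raised to the minor threshold."""
        return replace(self, detection_floor=self.minor_threshold)


@dataclass
class TranslocationReport:
    direction: str
    healthy_group: str
    case_group: str
    age_class: str | None
    criteria: TranslocationCriteria
    records: pd.DataFrame  # per-genus condition outcomes and the means behind them
    selected: frozenset[str]

    def to_tsv(self, path) -> None:
        out = self.records.copy()
        out.insert(1, "direction", self.direction)
        out.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def screen_translocation(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    case_group: str,
    age_class: str | None = None,
    direction: str = ORAL_TO_NASAL,
    criteria: TranslocationCriteria | None = None,
    healthy_group: str = "healthy",
) -> TranslocationReport:
    """Evaluate the three-condition translocation rule for every genus."""
    if direction not in (ORAL_TO_NASAL, NASAL_TO_ORAL):
        raise ValueError(f"unknown direction {direction!r}")
    if criteria is None:
        criteria = TranslocationCriteria(reference_list=default_reference_list(direction))
    source, target = ("oral", "nasal") if direction == ORAL_TO_NASAL else ("nasal", "oral")

    m_h_target = group_mean_relative(table, metadata, healthy_group, target, age_class=age_class)
    m_h_source = group_mean_relative(table, metadata, healthy_group, source, age_class=age_class)
    m_c_target = group_mean_relative(table, metadata, case_group, target, age_class=age_class)

    rows = []
    selected = []
    for genus in table.taxa:
        ht, hs, ct = float(m_h_target[genus]), float(m_h_source[genus]), float(m_c_target[genus])
        c1 = (
            genus in criteria.reference_list
            and ht <= criteria.detection_floor
            and ct > criteria.detection_floor
        )
        c2 = ht < criteria.minor_threshold and hs > criteria.minor_threshold
        c3 = ht < criteria.dominance_threshold and ct > criteria.dominance_threshold
        if criteria.combination_mode == "all":
            keep = c1 and c2 and c3
        else:
            keep = c1 or c2 or c3
        if keep:
            selected.append(genus)
        rows.append(
            {
                "genus": genus,
                "M_healthy_source": hs,
                "M_healthy_target": ht,
                "M_case_target": ct,
                "c1": c1,
                "c2": c2,
                "c3": c3,
                "selected": keep,
            }
        )
    return TranslocationReport(
        direction=direction,
        healthy_group=healthy_group,
        case_group=case_group,
        age_class=age_class,
        criteria=criteria,
        records=pd.DataFrame(rows),
        selected=frozenset(selected),
    )


@dataclass
class TSIntersection:
    """Intersection of translocator sets across cohorts, with Venn support."""

    intersection: frozenset[str]
    set_sizes: dict[str, int]
    pairwise_sizes: dict[tuple[str, str], int]

    def to_json_dict(self) -> dict:
        return {
            "intersection": sorted(self.intersection),
            "set_sizes": dict(sorted(self.set_sizes.items())),
            "pairwise_sizes": {
                f"{a}&{b}": n for (a, b), n in sorted(self.pairwise_sizes.items())
            },
        }


def intersect_ts(named_sets: Mapping[str, Iterable[str]]) -> TSIntersection:
    """Intersect named translocator sets; also report all pairwise overlap sizes."""
    if len(named_sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    sets = {name: frozenset(s) for name, s in named_sets.items()}
    names = list(sets)
    inter = frozenset.intersection(*sets.values())
    pairwise = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    return TSIntersection(
        intersection=inter,
        set_sizes={name: len(s) for name, s in sets.items()},
        pairwise_sizes=pairwise,
    )


def ts_abundance_profile(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    ts_set: Iterable[str],
    strata: Sequence[Stratum],
) -> pd.DataFrame:
    """Group-mean relative abundance of each TS genus, one column per stratum."""
    genera = sorted(set(ts_set))
    if not genera:
        raise ValueError("ts_set is empty")
    columns = {}
    for stratum in strata:
        means = group_mean_relative(
            table, metadata, stratum.group, stratum.niche, age_class=stratum.age_class
        )
        columns[stratum.label()] = means
    profile = pd.DataFrame(index=pd.Index(genera, name="genus"))
    for label, means in columns.items():
        values = []
        for genus in genera:
            if genus in means.index:
                values.append(float(means[genus]))
            else:
                warnings.warn(f"genus {genus!r} absent from table; zero-filled")
                values.append(0.0)
        profile[label] = values
    return profile
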