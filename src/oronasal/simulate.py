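"""Synthetic paired oral/nasal cohorts with planted ground truth.

The generator emulates the statistical structure the analysis assumes, not any
particular sequencing run: each subject contributes one oral and one nasal
sample; oral communities are dominated by a stable set of oral-colonizer
genera; nasal communities by a different dominant set; and the case groups
(unrepaired and postoperative cleft palate) leak a chosen subset of
oral-dominant genera into their nasal communities, raising nasal diversity.

Per sample, genus proportions are drawn from a Dirichlet whose mean is the
stratum profile (concentration 200 by default, i.e. roughly 40% CV for a genus
at a few percent) and counts from a multinomial at the configured read depth.
Case-group nasal mean profiles are the healthy nasal profile plus
``leakage`` x oral mean for the translocator genera, renormalized; the
``diversity_shift`` fraction is then mixed toward a uniform profile over the
nasal-resident genera, which strictly raises expected nasal diversity.
Translocator genera are exactly absent from healthy nasal profiles, so the
strict "not found" reading of the screen is satisfiable.

Everything is driven by one seeded generator; the same seed reproduces the
same cohort byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    COUNTS,
    RELATIVE,
    AbundanceTable,
    Stratum,
    load_table,
    write_metadata,
    write_table,
)

__all__ = [
    "ORAL_PROFILE",
    "NASAL_PROFILE",
    "BACKGROUND_GENERA",
    "DEFAULT_TRANSLOCATORS",
    "CohortConfig",
    "GroundTruth",
    "stratum_profile",
    "simulate_cohort",
    "write_fixture",
    "load_fixture",
    "simulate_two_group",
]

# Oral-colonizer mean fractions (healthy and case oral communities alike; the
# saliva is only weakly perturbed by cleft palate).
ORAL_PROFILE: dict[str, float] = {
    "Streptococcus": 0.15,
    "Neisseria": 0.08,
    "Veillonella": 0.07,
    "Prevotella": 0.06,
    "Haemophilus": 0.06,
    "Rothia": 0.05,
    "Gemella": 0.04,
    "Alloprevotella": 0.04,
    "Actinomyces": 0.04,
    "Granulicatella": 0.03,
    "Atopobium": 0.02,
    "Porphyromonas": 0.02,
}

# Nasal-dominant mean fractions per age class.
NASAL_PROFILE: dict[str, dict[str, float]] = {
    "child": {
        "Pseudomonas": 0.32,
        "Dolosigranulum": 0.20,
        "Moraxella": 0.14,
        "Serratia": 0.08,
        "Staphylococcus": 0.06,
        "Corynebacterium": 0.04,
        "Stenotrophomonas": 0.02,
        "Achromobacter": 0.02,
    },
    "adolescent": {
        "Pseudomonas": 0.30,
        "Serratia": 0.18,
        "Stenotrophomonas": 0.10,
        "Achromobacter": 0.08,
        "Staphylococcus": 0.07,
        "Corynebacterium": 0.05,
        "Moraxella": 0.04,
        "Dolosigranulum": 0.03,
    },
}

# Low-abundance genera shared by both niches.
BACKGROUND_GENERA: tuple[str, ...] = (
    "Acinetobacter", "Lactobacillus", "Fusobacterium", "Leptotrichia",
    "Capnocytophaga", "Campylobacter", "Selenomonas", "Megasphaera",
    "Dialister", "Oribacterium", "Parvimonas", "Peptostreptococcus",
    "Catonella", "Solobacterium", "Stomatobaculum", "Tannerella",
    "Treponema", "Bergeyella", "Kingella", "Eikenella",
    "Cardiobacterium", "Lautropia", "Abiotrophia", "Mogibacterium",
    "Filifactor", "Centipeda", "Bacteroides", "Paludibacter",
    "Sphingomonas", "Methylobacterium", "Ralstonia", "Delftia",
    "Comamonas", "Brevundimonas", "Ochrobactrum", "Rhizobium",
    "Bradyrhizobium", "Enhydrobacter", "Micrococcus", "Kocuria",
)

DEFAULT_TRANSLOCATORS: tuple[str, ...] = (
    "Streptococcus", "Gemella", "Alloprevotella", "Neisseria",
    "Rothia", "Actinomyces", "Veillonella",
)

_DEFAULT_STRATA: tuple[tuple[tuple[str, str], int], ...] = (
    (("healthy", "child"), 10),
    (("CP", "child"), 10),
    (("healthy", "adolescent"), 10),
    (("CP", "adolescent"), 5),
    (("postoperative", "adolescent"), 10),
)

_CASE_GROUPS = ("CP", "postoperative")


@dataclass
class CohortConfig:
    n_per_stratum: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(_DEFAULT_STRATA)
    )
    reads_per_sample: int = 5000
    concentration: float = 200.0  # Dirichlet total concentration (overdispersion)
    leakage: float = 1.0  # lambda: fraction of the oral mean added to case nasal
    diversity_shift: float = 0.05  # mix toward uniform over nasal residents in case nasal
    translocators: tuple[str, ...] = DEFAULT_TRANSLOCATORS
    correlation_blocks: tuple[tuple[str, ...], ...] = ()
    correlation_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leakage < 0:
            raise ValueError("leakage must be >= 0")
        if not (0.0 <= self.diversity_shift < 1.0):
            raise ValueError("diversity_shift must be in [0, 1)")
        unknown = sorted(set(self.translocators) - set(ORAL_PROFILE))
        if unknown:
            raise ValueError(f"translocators must be oral-dominant genera; unknown {unknown}")
        for key, n in self.n_per_stratum.items():
            if n < 3:
                raise ValueError(f"stratum {key} has {n} subjects; need >= 3")

    @property
    def genera(self) -> list[str]:
        return list(ORAL_PROFILE) + list(NASAL_PROFILE["child"]) + list(BACKGROUND_GENERA)


@dataclass
class GroundTruth:
    translocators: tuple[str, ...]
    biomarkers: dict[str, tuple[str, ...]]  # comparison label -> planted nasal biomarkers
    dominant_genera: dict[str, tuple[str, ...]]  # stratum label -> top genera by mean
    correlation_blocks: tuple[tuple[str, ...], ...]

    def to_json_dict(self) -> dict:
        return {
            "translocators": sorted(self.translocators),
            "biomarkers": {k: sorted(v) for k, v in sorted(self.biomarkers.items())},
            "dominant_genera": {k: list(v) for k, v in sorted(self.dominant_genera.items())},
            "correlation_blocks": [sorted(b) for b in self.correlation_blocks],
        }


def stratum_profile(config: CohortConfig, group: str, age_class: str, niche: str) -> pd.Series:
    """Expected genus fractions for one stratum (sums to 1)."""
    genera = config.genera
    profile = pd.Series(0.0, index=genera)
    if niche == "oral":
        for genus, frac in ORAL_PROFILE.items():
            profile[genus] = frac
        remainder = 1.0 - sum(ORAL_PROFILE.values())
        profile[list(BACKGROUND_GENERA)] = remainder / len(BACKGROUND_GENERA)
        return profile
    base = NASAL_PROFILE[age_class]
    for genus, frac in base.items():
        profile[genus] = frac
    remainder = 1.0 - sum(base.values())
    profile[list(BACKGROUND_GENERA)] = remainder / len(BACKGROUND_GENERA)
    if group in _CASE_GROUPS:
        for genus in config.translocators:
            profile[genus] += config.leakage * ORAL_PROFILE[genus]
        profile /= profile.sum()
        if config.diversity_shift > 0:
            residents = list(base) + list(BACKGROUND_GENERA)
            uniform = pd.Series(0.0, index=genera)
            uniform[residents] = 1.0 / len(residents)
            profile = (1.0 - config.diversity_shift) * profile + config.diversity_shift * uniform
    return profile


def _draw_sample(
    rng: np.random.Generator, profile: np.ndarray, config: CohortConfig, block_index: list[np.ndarray]
) -> np.ndarray:
    support = profile > 0
    alpha = profile[support] * config.concentration
    proportions = np.zeros_like(profile)
    proportions[support] = rng.dirichlet(alpha)
    for idx in block_index:
        factor = float(np.exp(config.correlation_strength * rng.normal()))
        proportions[idx] *= factor
        proportions /= proportions.sum()
    return rng.multinomial(config.reads_per_sample, proportions)


def simulate_cohort(
    config: CohortConfig | None = None,
) -> tuple[AbundanceTable, pd.DataFrame, GroundTruth]:
    """Draw the full paired-cohort table, its metadata, and the planted truth."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    genera = config.genera
    block_index = [
        np.array([genera.index(g) for g in block]) for block in config.correlation_blocks
    ]

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    dominants: dict[str, tuple[str, ...]] = {}
    for (group, age_class), n_subjects in config.n_per_stratum.items():
        for niche in ("oral", "nasal"):
            profile = stratum_profile(config, group, age_class, niche).to_numpy()
            label = Stratum(group, niche, age_class).label()
            order = np.argsort(-profile, kind="stable")
            dominants[label] = tuple(genera[i] for i in order[:3])
            for subject in range(1, n_subjects + 1):
                subject_id = f"{group}_{age_class}_{subject:02d}"
                sample_id = f"{subject_id}_{niche}"
                columns[sample_id] = _draw_sample(rng, profile, config, block_index)
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "subject_id": subject_id,
                        "group": group,
                        "niche": niche,
                        "age_class": age_class,
                    }
                )
    data = pd.DataFrame(columns, index=pd.Index(genera, name="taxon"), dtype=np.int64)
    metadata = pd.DataFrame(meta_rows)
    planted = tuple(config.translocators) if config.leakage > 0 else ()
    biomarkers = {
        f"{case}_{age}_nasal_vs_healthy": planted
        for (case, age) in config.n_per_stratum
        if case in _CASE_GROUPS
    }
    truth = GroundTruth(
        translocators=planted,
        biomarkers=biomarkers,
        dominant_genera=dominants,
        correlation_blocks=config.correlation_blocks,
    )
    return AbundanceTable(data, COUNTS), metadata, truth


def write_fixture(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    truth: GroundTruth,
    directory: str | Path,
    seed: int | None = None,
) -> dict[str, Path]:
    """Emit table.tsv, metadata.tsv and truth.json with stable filenames."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": directory / "table.tsv",
        "metadata": directory / "metadata.tsv",
        "truth": directory / "truth.json",
    }
    write_table(table, paths["table"])
    write_metadata(metadata, paths["metadata"])
    doc = truth.to_json_dict()
    if seed is not None:
        doc["seed"] = seed
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def load_fixture(directory: str | Path) -> tuple[AbundanceTable, pd.DataFrame, dict]:
    directory = Path(directory)
    from .tables import load_metadata

    table = load_table(directory / "table.tsv")
    metadata = load_metadata(directory / "metadata.tsv")
    with open(directory / "truth.json", "r", encoding="utf-8") as fh:
        truth = json.load(fh)
    return table, metadata, truth


def simulate_two_group(
    n_per_group: int = 10,
    n_features: int = 60,
    n_planted: int = 5,
    fold: float = 10.0,
    planted_abundance: float = 0.005,
    noise_cv: float = 0.003,
    seed: int = 0,
) -> tuple[AbundanceTable, pd.DataFrame, tuple[str, ...]]:
    """Two-group biomarker fixture: planted fold shifts on a uniform background.

    Planted features sit at ``planted_abundance`` in the enriched (case) group
    and ``planted_abundance / fold`` in the control group; the background
    features share the rest of the composition equally. Within-group
    variability is multiplicative log-normal with coefficient of variation
    ``noise_cv`` — deliberately far below the effect sizes of interest, so
    recovery and specificity reflect the decision rule rather than sampling
    noise (see the methods note). ``fold=1`` gives an exchangeable null.

    Returns a relative-mode table, metadata casting the two groups as healthy
    vs CP child nasal strata, and the planted feature names.
    """
    if n_planted > n_features:
        raise ValueError("n_planted must be <= n_features")
    rng = np.random.default_rng(seed)
    planted = tuple(f"Planted{i + 1:02d}" for i in range(n_planted))
    background = tuple(f"Background{i + 1:03d}" for i in range(n_features - n_planted))
    features = list(planted) + list(background)

    control_mean = np.empty(n_features)
    case_mean = np.empty(n_features)
    control_mean[:n_planted] = planted_abundance / fold
    case_mean[:n_planted] = planted_abundance
    bg_control = (1.0 - control_mean[:n_planted].sum()) / len(background)
    bg_case = (1.0 - case_mean[:n_planted].sum()) / len(background)
    control_mean[n_planted:] = bg_control
    case_mean[n_planted:] = bg_case

    sigma = float(np.sqrt(np.log(1.0 + noise_cv**2)))
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for group, mean in (("healthy", control_mean), ("CP", case_mean)):
        for i in range(1, n_per_group + 1):
            noise = np.exp(rng.normal(0.0, sigma, size=n_features) - sigma**2 / 2.0)
            values = mean * noise
            values /= values.sum()
            sample_id = f"{group}_{i:02d}_nasal"
            columns[sample_id] = values
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "subject_id": f"{group}_{i:02d}",
                    "group": group,
                    "niche": "nasal",
                    "age_class": "child",
                }
            )
    data = pd.DataFrame(columns, index=pd.Index(features, name="taxon"))
    return AbundanceTable(data, RELATIVE), pd.DataFrame(meta_rows), planted
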