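"""End-to-end study analysis: diversity -> ordination -> biomarkers -> screens -> networks.

``run_study`` executes, for a genus table plus metadata covering the five
paired strata (healthy/CP children; healthy/CP/postoperative adolescents):

* per-sample alpha diversity with the study's group tests (Welch t for the
  two child groups, one-way ANOVA for the three adolescent groups);
* Bray-Curtis distances and PCoA per niche and age class;
* pairwise LEfSe biomarker scans per niche;
* the oral-to-nasal and nasal-to-oral translocation screens for each case
  cohort, in both the strict (detection floor 0) and relaxed (floor = 0.01%)
  modes, with the time-stable intersection across the oral-to-nasal sets;
* per-stratum nasal co-occurrence networks with hub centralities.

All stage outputs land under one run directory together with a JSON report and
a manifest (input checksums, parameters, seed, output paths). Outputs are pure
functions of (inputs, parameters, seed): replaying a manifest reproduces them
byte for byte. A missing stratum skips the affected comparison with a recorded
warning rather than failing the run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import alpha_diversity, bray_curtis, compare_alpha, pcoa
from .lefse import LefseParams, records_to_frame, run_lefse
from .network import spearman_edges, write_graphml
from .tables import (
    AbundanceTable,
    Stratum,
    check_linkage,
    select_samples,
    top_n_genera,
    validate_metadata,
)
from .translocation import (
    ORAL_TO_NASAL,
    NASAL_TO_ORAL,
    TranslocationCriteria,
    default_reference_list,
    intersect_ts,
    screen_translocation,
    ts_abundance_profile,
)

__all__ = ["StudyParams", "run_study"]

# (case group, age class) cohort comparisons, in study order.
DEFAULT_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("CP", "child"),
    ("CP", "adolescent"),
    ("postoperative", "adolescent"),
)


@dataclass
class StudyParams:
    lefse: LefseParams = field(default_factory=LefseParams)
    rho_min: float = 0.6
    network_alpha: float = 0.05
    prevalence_min: float = 0.2
    top_n: int = 15
    pcoa_axes: int = 2
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_COMPARISONS

    def to_json_dict(self) -> dict:
        doc = asdict(self)
        doc["comparisons"] = [list(c) for c in self.comparisons]
        return doc


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode("utf-8")).hexdigest()


def _has_stratum(metadata: pd.DataFrame, group: str, niche: str, age_class: str) -> bool:
    return len(select_samples(metadata, group, niche, age_class)) > 0


def _write_json(doc: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_study(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    outdir: str | Path,
    params: StudyParams | None = None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Run every stage over a table/metadata pair; returns (manifest, report)."""
    params = params or StudyParams()
    validate_metadata(metadata)
    check_linkage(table, metadata)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {"warnings": []}
    outputs: dict[str, str] = {}
    seed_root = np.random.SeedSequence(seed)

    groups_present = {
        (g, a)
        for g in metadata["group"].unique()
        for a in metadata.loc[metadata["group"] == g, "age_class"].unique()
    }
    age_groups: dict[str, list[str]] = {}
    for age in ("child", "adolescent"):
        age_groups[age] = sorted(g for (g, a) in groups_present if a == age)

    # ---- alpha diversity + group tests --------------------------------------
    alpha = alpha_diversity(table)
    alpha = alpha.join(metadata.set_index("sample_id")[["group", "niche", "age_class"]])
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", lineterminator="\n", float_format="%.10g")
    outputs["alpha_diversity"] = "alpha_diversity.tsv"
    alpha_tests: dict = {}
    stratum_means: dict = {}
    for age, groups in age_groups.items():
        for niche in ("oral", "nasal"):
            for index in ("shannon", "chao1", "ace"):
                values = {
                    g: alpha.loc[
                        (alpha["group"] == g) & (alpha["niche"] == niche) & (alpha["age_class"] == age),
                        index,
                    ].to_numpy()
                    for g in groups
                }
                values = {g: v for g, v in values.items() if v.size >= 2}
                for g, v in values.items():
                    stratum_means[f"{g}_{age}_{niche}_{index}"] = float(v.mean())
                if len(values) < 2:
                    report["warnings"].append(
                        f"alpha comparison skipped for {age}/{niche}/{index}: <2 groups"
                    )
                    continue
                stat, p = compare_alpha(values)
                alpha_tests[f"{age}_{niche}_{index}"] = {
                    "design": "two_group_t" if len(values) == 2 else "anova",
                    "groups": sorted(values),
                    "statistic": stat,
                    "p": p,
                }
    report["alpha_tests"] = alpha_tests
    report["alpha_stratum_means"] = stratum_means

    # ---- composition summaries ----------------------------------------------
    top_genera: dict = {}
    for (group, age) in sorted(groups_present):
        for niche in ("oral", "nasal"):
            if not _has_stratum(metadata, group, niche, age):
                continue
            label = Stratum(group, niche, age).label()
            top = top_n_genera(table, metadata, group, niche, params.top_n, age_class=age)
            top_genera[label] = [[g, float(v)] for g, v in top]
    report["top_genera"] = top_genera

    # ---- ordination ----------------------------------------------------------
    ordinations: dict = {}
    for age in age_groups:
        for niche in ("oral", "nasal"):
            ids = [
                s
                for s in select_samples(metadata, niche=niche, age_class=age)
                if s in table.data.columns
            ]
            if len(ids) < 3:
                report["warnings"].append(f"ordination skipped for {age}/{niche}: <3 samples")
                continue
            dm = bray_curtis(table.subset_samples(ids))
            ordination = pcoa(dm, k=params.pcoa_axes)
            name = f"pcoa_{age}_{niche}.tsv"
            ordination.to_tsv(outdir / name)
            outputs[f"pcoa_{age}_{niche}"] = name
            ordinations[f"{age}_{niche}"] = {
                "proportion_explained": [float(v) for v in ordination.proportion_explained],
                "n_negative_eigenvalues": ordination.n_negative_eigenvalues,
            }
    report["ordination"] = ordinations

    # ---- pairwise biomarker scans --------------------------------------------
    lefse_runs: dict = {}
    pair_labels = []
    for age, groups in age_groups.items():
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                for niche in ("oral", "nasal"):
                    pair_labels.append((ga, gb, age, niche))
    children = seed_root.spawn(len(pair_labels) + 1)
    for child_seq, (ga, gb, age, niche) in zip(children, pair_labels):
        label = f"{ga}_vs_{gb}_{age}_{niche}"
        sa, sb = Stratum(ga, niche, age), Stratum(gb, niche, age)
        try:
            lefse_params = LefseParams(
                alpha=params.lefse.alpha,
                lda_min=params.lefse.lda_min,
                scale=params.lefse.scale,
                n_boot=params.lefse.n_boot,
                boot_fraction=params.lefse.boot_fraction,
                shrink=params.lefse.shrink,
                seed=int(child_seq.generate_state(1)[0] % (2**31)),
            )
            records = run_lefse(table, metadata, sa, sb, lefse_params)
        except ValueError as err:
            report["warnings"].append(f"lefse skipped for {label}: {err}")
            continue
        frame = records_to_frame(records)
        name = f"lefse_{label}.tsv"
        frame.to_csv(outdir / name, sep="\t", index=False, lineterminator="\n", float_format="%.10g")
        outputs[f"lefse_{label}"] = name
        passing = frame.loc[frame["passes"]]
        lefse_runs[label] = {
            "n_biomarkers": int(passing.shape[0]),
            "biomarkers": {
                row["genus"]: row["enriched_group"] for _, row in passing.iterrows()
            },
            "seed": lefse_params.seed,
        }
    report["lefse"] = lefse_runs

    # ---- translocation screens ----------------------------------------------
    screens: dict = {}
    on_sets: dict[str, dict[str, frozenset[str]]] = {"strict": {}, "relaxed": {}}
    for direction in (ORAL_TO_NASAL, NASAL_TO_ORAL):
        strict = TranslocationCriteria(reference_list=default_reference_list(direction))
        for mode_name, criteria in (("strict", strict), ("relaxed", strict.relaxed())):
            for case_group, age in params.comparisons:
                label = f"{direction}_{case_group}_{age}_{mode_name}"
                needed = [
                    ("healthy", "oral", age), ("healthy", "nasal", age),
                    (case_group, "oral", age), (case_group, "nasal", age),
                ]
                if not all(_has_stratum(metadata, *s) for s in needed):
                    report["warnings"].append(f"screen skipped for {label}: missing stratum")
                    continue
                screen = screen_translocation(
                    table, metadata, case_group, age_class=age, direction=direction,
                    criteria=criteria,
                )
                name = f"screen_{label}.tsv"
                screen.to_tsv(outdir / name)
                outputs[f"screen_{label}"] = name
                screens[label] = sorted(screen.selected)
                if direction == ORAL_TO_NASAL:
                    on_sets[mode_name][f"{case_group}_{age}"] = screen.selected
    report["screens"] = screens

    ts_results: dict = {}
    for mode_name, sets in on_sets.items():
        if len(sets) < 2:
            report["warnings"].append(f"TS intersection skipped ({mode_name}): <2 screens ran")
            continue
        ts = intersect_ts(sets)
        ts_results[mode_name] = ts.to_json_dict()
        if ts.intersection:
            strata = [
                Stratum(g, "nasal", a)
                for (g, a) in sorted(
                    {(g, a) for (g, a) in (tuple(k.rsplit("_", 1)) for k in sets)}
                    | {("healthy", "child"), ("healthy", "adolescent")}
                )
                if _has_stratum(metadata, g, "nasal", a)
            ]
            profile = ts_abundance_profile(table, metadata, ts.intersection, strata)
            name = f"ts_profile_{mode_name}.tsv"
            profile.to_csv(outdir / name, sep="\t", lineterminator="\n", float_format="%.10g")
            outputs[f"ts_profile_{mode_name}"] = name
    report["ts_intersection"] = ts_results
    _write_json(ts_results, outdir / "ts_intersection.json")
    outputs["ts_intersection"] = "ts_intersection.json"

    # ---- co-occurrence networks ----------------------------------------------
    networks: dict = {}
    for (group, age) in sorted(groups_present):
        stratum = Stratum(group, "nasal", age)
        ids = select_samples(metadata, group, "nasal", age)
        if len(ids) < 5:
            report["warnings"].append(f"network skipped for {stratum.label()}: <5 samples")
            continue
        net = spearman_edges(
            table, metadata, stratum,
            rho_min=params.rho_min, alpha=params.network_alpha,
            prevalence_min=params.prevalence_min,
        )
        base = f"network_{stratum.label()}"
        net.write_edges(outdir / f"{base}_edges.tsv")
        net.write_nodes(outdir / f"{base}_nodes.tsv")
        write_graphml(net, outdir / f"{base}.graphml")
        outputs[base] = f"{base}_edges.tsv"
        hubs = net.nodes.sort_values(["betweenness", "degree", "genus"], ascending=[False, False, True])
        networks[stratum.label()] = {
            "n_nodes": int(net.nodes.shape[0]),
            "n_edges": int(net.edges.shape[0]),
            "hubs": hubs["genus"].head(5).tolist(),
        }
    report["networks"] = networks

    # ---- report + manifest ----------------------------------------------------
    _write_json(report, outdir / "report.json")
    outputs["report"] = "report.json"
    manifest = {
        "tool": "oronasal",
        "version": __version__,
        "seed": seed,
        "params": params.to_json_dict(),
        "inputs": {
            "table_sha256": _sha256(table.data.to_csv(sep="\t", lineterminator="\n")),
            "metadata_sha256": _sha256(metadata.to_csv(sep="\t", index=False, lineterminator="\n")),
            "n_taxa": table.shape[0],
            "n_samples": table.shape[1],
        },
        "outputs": dict(sorted(outputs.items())),
    }
    _write_json(manifest, outdir / "manifest.json")
    return manifest, report
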