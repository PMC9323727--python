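"""Biomarker discovery: Kruskal-Wallis screen plus bootstrapped LDA effect size.

The procedure mirrors the conventional two-stage biomarker scan used on genus
tables: per-genus abundances are total-sum-scaled to 10^6 per sample, screened
with a Kruskal-Wallis test at alpha = 0.05, and the survivors are scored with a
bootstrapped two-class linear discriminant effect size reported as
log10(1 + effect); a genus is called a biomarker when its score exceeds 2.

Effect-size definition (per bootstrap subsample of 2/3 of the samples, 30
bootstraps): fit a two-class LDA with the pooled within-class covariance shrunk
toward its diagonal, take the unit-norm discriminant axis w, and score feature
f as the mean of (i) |w_f * (w . (m1 - m2))|, the feature's share of the
projected class-mean separation, and (ii) |m1_f - m2_f|, the raw class-mean
difference. No subclass (within-group Wilcoxon) stage and no multiple-testing
correction are applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import AbundanceTable, SCALED, Stratum, select_samples

__all__ = [
    "LefseParams",
    "BiomarkerRecord",
    "normalize_tss",
    "kruskal_wallis",
    "lda_effect_size",
    "run_lefse",
    "records_to_frame",
]


@dataclass
class LefseParams:
    alpha: float = 0.05
    lda_min: float = 2.0
    scale: float = 1e6
    n_boot: int = 30
    boot_fraction: float = 2.0 / 3.0
    shrink: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.boot_fraction <= 1.0):
            raise ValueError("boot_fraction must be in (0, 1]")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class BiomarkerRecord:
    genus: str
    enriched_group: str
    kw_statistic: float
    kw_p: float
    lda_score: float  # log10 scale; NaN when the genus never reached the LDA stage
    passes: bool


def normalize_tss(table: AbundanceTable, scale: float = 1e6) -> AbundanceTable:
    """Rescale every sample column to sum to ``scale`` (total-sum scaling)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    sums = table.data.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total abundance")
    return AbundanceTable((table.data / sums * scale).astype(float), SCALED)


def kruskal_wallis(
    values_by_group: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    method: str = "chi2",
) -> tuple[float, float]:
    """Kruskal-Wallis H with average ranks and tie correction.

    ``method="chi2"`` (default) takes p from the chi-square approximation with
    g-1 degrees of freedom; ``method="exact"`` enumerates every assignment of
    the pooled values to the group sizes (small samples only) and reports the
    fraction of assignments with H at least as large as observed.

    Groups whose pooled values are all identical give (H=0, p=1).
    """
    if isinstance(values_by_group, Mapping):
        groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    else:
        groups = [np.asarray(v, dtype=float) for v in values_by_group]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    if method == "chi2":
        stat, p = stats.kruskal(*groups)
        return float(stat), float(p)
    if method == "exact":
        return _kruskal_exact(groups)
    raise ValueError(f"unknown method {method!r}")


def _h_statistic(pooled_ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    n = pooled_ranks.size
    start, h = 0, 0.0
    for size in sizes:
        r = pooled_ranks[start : start + size]
        h += r.sum() ** 2 / size
        start += size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _kruskal_exact(groups: list[np.ndarray]) -> tuple[float, float]:
    pooled = np.concatenate(groups)
    n = pooled.size
    if n > 12:
        raise ValueError("exact method only supported for <= 12 total observations")
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    sizes = [g.size for g in groups]
    h_obs = _h_statistic(ranks, sizes, tie_term)
    count = total = 0
    indices = set(range(n))

    def recurse(remaining: frozenset, size_idx: int, chosen: list[np.ndarray]) -> None:
        nonlocal count, total
        if size_idx == len(sizes) - 1:
            last = np.fromiter(remaining, dtype=int)
            arrangement = np.concatenate(chosen + [ranks[last]])
            h = _h_statistic(arrangement, sizes, tie_term)
            total += 1
            if h >= h_obs - 1e-12:
                count += 1
            return
        for combo in combinations(sorted(remaining), sizes[size_idx]):
            recurse(remaining - set(combo), size_idx + 1, chosen + [ranks[list(combo)]])

    recurse(frozenset(indices), 0, [])
    return float(h_obs), count / total


def lda_effect_size(
    features: pd.DataFrame,
    labels: Sequence[str],
    params: LefseParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Bootstrapped two-class LDA effect size per feature (log10 scale).

    ``features`` is features x samples (TSS-scaled); ``labels`` assigns each
    sample column to one of exactly two classes.
    """
    params = params or LefseParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly 2 classes required, got {list(classes)}")
    x = features.to_numpy(dtype=float)
    n_features, n_samples = x.shape
    m = max(int(math.ceil(params.boot_fraction * n_samples)), 4)
    m = min(m, n_samples)
    acc = np.zeros(n_features)
    for _ in range(params.n_boot):
        for attempt in range(100):
            idx = rng.choice(n_samples, size=m, replace=False)
            ys = labels[idx]
            if (ys == classes[0]).sum() >= 2 and (ys == classes[1]).sum() >= 2:
                break
        else:
            raise RuntimeError("could not draw a bootstrap subsample with both classes")
        xs = x[:, idx]
        m1 = xs[:, ys == classes[0]].mean(axis=1)
        m2 = xs[:, ys == classes[1]].mean(axis=1)
        centered = xs.copy()
        centered[:, ys == classes[0]] -= m1[:, None]
        centered[:, ys == classes[1]] -= m2[:, None]
        cov = centered @ centered.T / max(m - 2, 1)
        cov = (1.0 - params.shrink) * cov + params.shrink * np.diag(np.diag(cov))
        # tiny ridge keeps the solve defined even with zero variance everywhere
        ridge = 1e-10 * max(np.trace(cov) / n_features, 1e-12)
        cov[np.diag_indices_from(cov)] += ridge
        delta = m1 - m2
        try:
            w = np.linalg.solve(cov, delta)
        except np.linalg.LinAlgError:
            w = delta.copy()
        norm = np.linalg.norm(w)
        if norm == 0.0:
            acc += np.abs(delta) / 2.0
            continue
        w /= norm
        projected = float(w @ delta)
        acc += (np.abs(w * projected) + np.abs(delta)) / 2.0
    effect = acc / params.n_boot
    return pd.Series(np.log10(1.0 + effect), index=features.index, name="lda_score")


def run_lefse(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    stratum_a: Stratum,
    stratum_b: Stratum,
    params: LefseParams | None = None,
) -> list[BiomarkerRecord]:
    """Two-stratum biomarker scan: TSS -> per-genus KW -> LDA effect size.

    Returns one record per genus; ``passes`` is True iff kw_p < alpha and
    lda_score > lda_min. Multi-group designs are handled upstream as all
    pairwise runs.
    """
    params = params or LefseParams()
    ids_a = [s for s in select_samples(metadata, stratum_a.group, stratum_a.niche, stratum_a.age_class) if s in table.data.columns]
    ids_b = [s for s in select_samples(metadata, stratum_b.group, stratum_b.niche, stratum_b.age_class) if s in table.data.columns]
    for label, ids in ((stratum_a.label(), ids_a), (stratum_b.label(), ids_b)):
        if len(ids) < 3:
            raise ValueError(f"stratum {label!r} has {len(ids)} samples; need >= 3")
    scaled = normalize_tss(table.subset_samples(ids_a + ids_b), scale=params.scale)
    name_a, name_b = stratum_a.label(), stratum_b.label()
    labels = np.array([name_a] * len(ids_a) + [name_b] * len(ids_b))

    kw_stats: dict[str, tuple[float, float]] = {}
    for genus in scaled.taxa:
        row = scaled.data.loc[genus]
        kw_stats[genus] = kruskal_wallis(
            {name_a: row[ids_a].to_numpy(), name_b: row[ids_b].to_numpy()}
        )
    passing = [g for g, (_, p) in kw_stats.items() if p < params.alpha]
    scores = pd.Series(np.nan, index=scaled.data.index, name="lda_score")
    if passing:
        scores.loc[passing] = lda_effect_size(scaled.data.loc[passing], labels, params)

    records = []
    mean_a = scaled.data[ids_a].mean(axis=1)
    mean_b = scaled.data[ids_b].mean(axis=1)
    for genus in scaled.taxa:
        h, p = kw_stats[genus]
        score = float(scores[genus])
        enriched = name_a if mean_a[genus] >= mean_b[genus] else name_b
        passes = bool(p < params.alpha and not np.isnan(score) and score > params.lda_min)
        records.append(BiomarkerRecord(genus, enriched, h, p, score, passes))
    return records


def records_to_frame(records: Sequence[BiomarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genus": r.genus,
                "enriched_group": r.enriched_group,
                "kw_statistic": r.kw_statistic,
                "kw_p": r.kw_p,
                "lda_score": r.lda_score,
                "passes": r.passes,
            }
            for r in records
        ]
    )
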