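"""Alpha diversity estimators, group comparisons, Bray-Curtis distances, PCoA.

Shannon is reported in natural-log units by default (the 2-4 range typical of
genus-level 16S communities); Chao1 uses the bias-corrected form so that
doubleton-free samples are defined; ACE uses the conventional rare cutoff of 10
and falls back to Chao1 when its sample-coverage estimate degenerates
(C_ace = 0 or N_rare <= 1). Indices are computed on raw counts; no rarefaction
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from .tables import COUNTS, RELATIVE, AbundanceTable, to_relative

__all__ = [
    "shannon",
    "chao1",
    "ace",
    "ace_with_fallback",
    "alpha_diversity",
    "compare_alpha",
    "bray_curtis",
    "pcoa",
    "Ordination",
]


def _as_counts(v: Sequence[float]) -> np.ndarray:
    x = np.asarray(v, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    if x.sum() <= 0:
        raise ValueError("all-zero count vector")
    return x


def shannon(v: Sequence[float], base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero taxa (default base e)."""
    x = _as_counts(v)
    p = x[x > 0] / x.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= float(np.log(base))
    return h


def _freq_counts(x: np.ndarray) -> tuple[int, int, int]:
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs, f1, f2


def chao1(v: Sequence[float], bias_corrected: bool = True) -> float:
    """Chao1 richness; bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default."""
    x = _as_counts(v)
    s_obs, f1, f2 = _freq_counts(x)
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ValueError("classic Chao1 undefined with no doubletons; use bias_corrected=True")
    return s_obs + f1 * f1 / (2.0 * f2)


def ace_with_fallback(v: Sequence[float], rare_cutoff: int = 10) -> tuple[float, bool]:
    """ACE richness estimate and a flag marking the Chao1 fallback.

    Rare genera are those with 1 <= count <= ``rare_cutoff``. With
    C_ace = 1 - F1/N_rare, the estimate is
    S_abund + S_rare/C_ace + (F1/C_ace) * gamma^2 where gamma^2 is the
    (clamped at zero) rare-class coefficient of variation. When the coverage
    estimate degenerates (C_ace == 0 or N_rare <= 1) the bias-corrected Chao1
    value is returned with the flag set.
    """
    x = _as_counts(v)
    counts = x[x > 0]
    rare = counts[counts <= rare_cutoff]
    s_abund = int((counts > rare_cutoff).sum())
    s_rare = int(rare.size)
    if s_rare == 0:
        return float(s_abund), False
    n_rare = float(rare.sum())
    f1 = float((rare == 1).sum())
    if n_rare <= 1:
        return chao1(x), True
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(x), True
    top = sum(i * (i - 1) * float((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma_sq = max((s_rare / c_ace) * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return float(s_abund + s_rare / c_ace + (f1 / c_ace) * gamma_sq), False


def ace(v: Sequence[float], rare_cutoff: int = 10) -> float:
    return ace_with_fallback(v, rare_cutoff=rare_cutoff)[0]


def alpha_diversity(table: AbundanceTable, rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-sample Shannon, Chao1 and ACE for a counts-mode table."""
    if table.mode != COUNTS:
        raise ValueError("alpha diversity requires a counts-mode table")
    rows = {}
    for sample in table.samples:
        x = table.data[sample].to_numpy(dtype=float)
        a, flag = ace_with_fallback(x, rare_cutoff=rare_cutoff)
        rows[sample] = {
            "shannon": shannon(x),
            "chao1": chao1(x),
            "ace": a,
            "ace_fallback": flag,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


def compare_alpha(
    values_by_group: Mapping[str, Sequence[float]],
    design: str = "auto",
) -> tuple[float, float]:
    """Two-sided Welch t (two groups) or one-way ANOVA F (three or more).

    ``design`` may be ``"two_group_t"``, ``"anova"``, or ``"auto"`` (choose by
    group count). Each group needs at least two values.
    """
    groups = {name: np.asarray(v, dtype=float) for name, v in values_by_group.items()}
    for name, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    if design == "auto":
        design = "two_group_t" if len(groups) == 2 else "anova"
    arrays = list(groups.values())
    if design == "two_group_t":
        if len(arrays) != 2:
            raise ValueError("two_group_t requires exactly 2 groups")
        stat, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
    elif design == "anova":
        if len(arrays) < 2:
            raise ValueError("anova requires >= 2 groups")
        stat, p = stats.f_oneway(*arrays)
    else:
        raise ValueError(f"unknown design {design!r}")
    if np.isnan(stat):  # identical constant groups
        stat, p = 0.0, 1.0
    return float(stat), float(p)


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis dissimilarity d = sum|x-y| / sum(x+y) on samples."""
    if len(table.samples) < 2:
        raise ValueError("need at least 2 samples")
    x = table.data.to_numpy(dtype=float)
    zero_cols = np.where(x.sum(axis=0) == 0)[0]
    if zero_cols.size >= 2:
        names = [table.samples[j] for j in zero_cols]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples {names}")
    dist = squareform(pdist(x.T, metric="braycurtis"))
    return DistanceMatrix(dist, ids=table.samples)


@dataclass
class Ordination:
    """PCoA result: sample coordinates on the positive-eigenvalue axes."""

    coordinates: pd.DataFrame  # samples x axes, axis i scaled by sqrt(eigenvalue_i)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray  # fraction of positive-eigenvalue variance
    n_negative_eigenvalues: int
    truncated: bool  # True when fewer axes were available than requested

    def to_tsv(self, path) -> None:
        self.coordinates.to_csv(path, sep="\t", index_label="sample_id", lineterminator="\n")


def pcoa(dm: DistanceMatrix, k: int = 2, tol: float = 1e-9) -> Ordination:
    """Principal coordinates analysis by Gower double-centering.

    B = -1/2 J D^2 J is eigendecomposed; axes come from positive eigenvalues
    (descending) scaled by sqrt(eigenvalue). Negative eigenvalues are discarded
    and counted (no Lingoes/Cailliez correction). If ``k`` exceeds the number
    of positive eigenvalues all available axes are returned with
    ``truncated=True``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = tol * max(abs(eigvals[0]), 1.0)
    n_negative = int((eigvals < -scale).sum())
    positive = eigvals > scale
    pos_vals = eigvals[positive]
    pos_vecs = eigvecs[:, positive]
    n_axes = min(k, pos_vals.size)
    truncated = k > pos_vals.size
    coords = pos_vecs[:, :n_axes] * np.sqrt(pos_vals[:n_axes])
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i + 1}" for i in range(n_axes)]
    )
    total = pos_vals.sum() if pos_vals.size else 1.0
    return Ordination(
        coordinates=frame,
        eigenvalues=pos_vals,
        proportion_explained=pos_vals[:n_axes] / total,
        n_negative_eigenvalues=n_negative,
        truncated=truncated,
    )
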