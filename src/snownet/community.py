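"""Community-level statistics: alpha diversity, composition tests, richness contrasts.

Shannon diversity uses the natural logarithm.  Community dissimilarity is
Bray–Curtis, and differences between sample groups are tested with a
permutational ANOVA (pseudo-F on the distance decomposition, free
permutation of sample labels).  Per-phylum richness contrasts between
snow-free and snow-covered samples use Kruskal–Wallis, with Dunn's post-hoc
test (Holm-adjusted) after a significant omnibus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

from .tables import (
    CONDITIONS,
    SNOW_COVERED,
    SNOW_FREE,
    AsvTable,
    SampleMetadata,
    Taxonomy,
    ValidationError,
)

logger = logging.getLogger(__name__)


def alpha_diversity(table: AsvTable) -> pd.DataFrame:
    """Per-sample richness (# detected ASVs) and Shannon index (natural log)."""
    depths = table.depths()
    if (depths == 0).any():
        raise ValidationError(f"zero-depth sample(s): {list(depths.index[depths == 0])}")
    counts = table.counts.to_numpy(dtype=float)
    richness = (counts > 0).sum(axis=1)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity, d = 1 − 2·Σ min(a,b) / Σ (a+b)."""
    values = np.asarray(matrix, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two samples")
    dm = squareform(pdist(values, metric="braycurtis"))
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(values.shape[0])
    return pd.DataFrame(dm, index=index, columns=index)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


def permanova(
    dist: pd.DataFrame | np.ndarray,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-factor permutational ANOVA on a distance matrix.

    ``R² = SS_between / SS_total`` from the distance decomposition
    (SS_total = Σ_{i<j} d²_ij / n; SS_within summed per group); the p-value
    uses the add-one permutation formula.
    """
    d2 = np.asarray(dist, dtype=float) ** 2
    labels = np.asarray(labels)
    n = d2.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match the distance matrix")
    if n_permutations < 1:
        raise ValueError("n_permutations must be ≥ 1")
    levels, group_idx = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("labels must have at least two levels")
    counts = np.bincount(group_idx)
    if (counts < 2).any():
        raise ValueError("every group needs at least two samples")
    k = len(levels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def ss_within(gidx: np.ndarray) -> float:
        total = 0.0
        for g in range(k):
            members = np.flatnonzero(gidx == g)
            sub = d2[np.ix_(members, members)]
            total += sub[np.triu_indices(len(members), 1)].sum() / len(members)
        return total

    def pseudo_f(ssw: float) -> float:
        if ssw <= 0:
            return 0.0 if ss_total <= ssw else math.inf
        return ((ss_total - ssw) / (k - 1)) / (ssw / (n - k))

    if ss_total <= 0:  # all samples identical: nothing to decompose
        return PermanovaResult(pseudo_f=0.0, r2=0.0, p_value=1.0,
                               n_permutations=n_permutations)
    ssw_obs = ss_within(group_idx)
    f_obs = pseudo_f(ssw_obs)
    r2 = 1.0 - ssw_obs / ss_total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if pseudo_f(ss_within(rng.permutation(group_idx))) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(pseudo_f=f_obs, r2=r2, p_value=p, n_permutations=n_permutations)


def phylum_richness_contrast(
    table: AsvTable,
    taxonomy: Taxonomy,
    meta: SampleMetadata,
    min_asvs: int | float = 10,
) -> pd.DataFrame:
    """Per-phylum richness medians by condition with a Kruskal–Wallis p-value.

    Phyla whose total ASV count is ≤ ``min_asvs`` are excluded, mirroring the
    convention of only reporting phyla with more than ten ASVs.  ASVs without
    phylum annotation are pooled as ``"unknown"``.
    """
    meta.validate_covers(table)
    phyla = pd.Series(
        [taxonomy.phylum(a) for a in table.asv_ids], index=table.counts.columns
    )
    presence = table.counts > 0
    cond = meta.condition_of().loc[table.sample_ids]
    rows = []
    for phylum, asvs in phyla.groupby(phyla).groups.items():
        if len(asvs) <= min_asvs:
            continue
        richness = presence[list(asvs)].sum(axis=1)
        by_cond = {c: richness[cond == c].to_numpy() for c in CONDITIONS}
        groups = [v for v in by_cond.values() if len(v)]
        if len(groups) == 2 and (np.ptp(np.concatenate(groups)) > 0):
            p = stats.kruskal(*groups).pvalue
        else:
            p = np.nan
        def _median(v):
            return float(np.median(v)) if len(v) else float("nan")

        rows.append(
            {
                "phylum": phylum,
                "n_asvs": len(asvs),
                "median_snow_free": _median(by_cond[SNOW_FREE]),
                "median_snow_covered": _median(by_cond[SNOW_COVERED]),
                "p_kruskal": p,
            }
        )
    return pd.DataFrame(rows, columns=[
        "phylum", "n_asvs", "median_snow_free", "median_snow_covered", "p_kruskal",
    ])


@dataclass
class KruskalDunnResult:
    omnibus_h: float
    omnibus_p: float
    dunn: pd.DataFrame | None  # pairwise table, None when omnibus not significant


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests on rank sums with tie correction, Holm-adjusted."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    levels = np.unique(groups)
    mean_ranks = {g: ranks[groups == g].mean() for g in levels}
    sizes = {g: int((groups == g).sum()) for g in levels}
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
            )
            z = (mean_ranks[a] - mean_ranks[b]) / se
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p_raw": 2 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def groupwise_kruskal_dunn(
    values: pd.Series,
    meta: SampleMetadata,
    factor: str = "location",
    alpha: float = 0.05,
) -> KruskalDunnResult:
    """Kruskal–Wallis omnibus across the levels of ``factor`` (``"location"``
    or ``"condition"``), followed by Dunn's pairwise tests (Holm-adjusted)
    only when the omnibus is significant at ``alpha``."""
    fac = meta.table.loc[values.index, factor]
    levels = fac.unique()
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs ≥ 2 levels")
    groups = [values[fac == g].to_numpy() for g in levels]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    h, p = stats.kruskal(*groups)
    dunn = None
    if p <= alpha:
        dunn = _dunn_pairwise(values.to_numpy(), fac.to_numpy())
    return KruskalDunnResult(omnibus_h=float(h), omnibus_p=float(p), dunn=dunn)
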