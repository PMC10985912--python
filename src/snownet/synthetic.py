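"""Synthetic paired fungal/bacterial ASV datasets with planted associations.

The generator emulates the structure of a two-season (snow-free vs
snow-covered), three-location soil amplicon study: 79 samples split into the
study's six location × condition groups, a fungal table with shallow depth
(~6,500 reads) and a much richer bacterial table with deep sequencing
(~60,000 reads), heavy-tailed per-ASV occupancy (the median ASV occurs in a
small fraction of samples) and a small "core" of ASVs detected in every
location.

Cross-kingdom dependence is planted through a latent Gaussian copula: every
ASV has a standard-normal latent variable, and each planted association is a
correlation ρ (signed) between one fungal and one bacterial latent, switched
on only in samples of the edge's condition ("both" edges are always on).
Latents are pushed through per-ASV log-normal abundance profiles, masked by
a per-ASV occupancy draw, and realized as counts by multinomial sampling at
a truncated-normal sequencing depth.  The planted edges form the ground
truth against which network recovery is scored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import (
    BACTERIA,
    CONDITIONS,
    FUNGI,
    SNOW_COVERED,
    SNOW_FREE,
    AsvTable,
    SampleMetadata,
    Taxonomy,
    normalize_condition,
)

logger = logging.getLogger(__name__)

BOTH = "both"

#: per-group sample counts of the field design being emulated
DEFAULT_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("Kuehtai", SNOW_FREE): 13,
    ("Kuehtai", SNOW_COVERED): 12,
    ("Patscherkofel", SNOW_FREE): 19,
    ("Patscherkofel", SNOW_COVERED): 14,
    ("Praxmar", SNOW_FREE): 13,
    ("Praxmar", SNOW_COVERED): 8,
}

_FUNGAL_PHYLA = (
    "Ascomycota", "Basidiomycota", "Mortierellomycota", "Mucoromycota", "Chytridiomycota",
)
_BACTERIAL_PHYLA = (
    "Proteobacteria", "Acidobacteriota", "Actinobacteriota",
    "Bacteroidota", "Verrucomicrobiota", "Planctomycetota",
)
_FUNGAL_GENERA = (
    "Mortierella", "Russula", "Basidioascus", "Umbelopsis", "Cladophialophora",
    "Solicoccozyma", "Rhizopogon", "Pseudotomentella", "Mucor", "Nadsonia",
)
_BACTERIAL_GENERA = (
    "Mycobacterium", "Acidothermus", "Bryobacter", "Granulicella", "Mucilaginibacter",
    "Conexibacter", "Acidibacter", "Methylocella", "Aquisphaera", "Psychrobacillus",
)


@dataclass(frozen=True)
class PlantedEdge:
    """A ground-truth fungal–bacterial association.

    ``fungal_idx``/``bacterial_idx`` index into the generated ASV panels,
    ``sign`` is +1 or −1, ``condition`` is ``"snow-free"``, ``"snow-covered"``
    or ``"both"`` and ``rho`` the latent correlation magnitude.
    """

    fungal_idx: int
    bacterial_idx: int
    sign: int
    condition: str
    rho: float = 0.7

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError(f"sign must be ±1, got {self.sign}")
        if not 0 < self.rho < 1:
            raise ValueError(f"|rho| must be in (0,1), got {self.rho}")
        cond = self.condition if self.condition == BOTH else normalize_condition(self.condition)
        object.__setattr__(self, "condition", cond)


def default_planted_edges(n_edges: int = 10, rho: float = 0.7) -> tuple[PlantedEdge, ...]:
    """Default truth: ``n_edges`` fungal–bacterial edges on the first core
    ASVs of each kingdom, a mix of season-independent and season-specific
    edges, mostly positive (as observed for soil fb associations)."""
    conditions = [BOTH, BOTH, BOTH, BOTH, SNOW_FREE, SNOW_FREE, SNOW_FREE,
                  SNOW_COVERED, SNOW_COVERED, SNOW_COVERED]
    signs = [1, 1, -1, 1, 1, -1, 1, 1, -1, 1]
    edges = []
    for i in range(n_edges):
        edges.append(
            PlantedEdge(
                fungal_idx=i,
                bacterial_idx=i,
                sign=signs[i % len(signs)],
                condition=conditions[i % len(conditions)],
                rho=rho,
            )
        )
    return tuple(edges)


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the emulated study design: 79 samples in six
    location × condition groups, fungal depth 6,500 ± 2,320 and bacterial
    depth 60,000 ± 16,000 reads, and a scaled-down ASV richness (150 fungal,
    600 bacterial) that preserves the fungi ≪ bacteria asymmetry.
    """

    group_sizes: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_fungi: int = 150
    n_bacteria: int = 600
    fungal_depth: tuple[float, float] = (6500.0, 2320.0)
    bacterial_depth: tuple[float, float] = (60000.0, 16000.0)
    depth_floor: int = 100
    n_core_fungi: int = 15
    n_core_bacteria: int = 60
    planted_edges: Sequence[PlantedEdge] | None = None  # None → default_planted_edges()
    occupancy_decay: float = 0.25
    lognormal_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for group, size in self.group_sizes.items():
            if size < 1:
                raise ValueError(f"group {group} has size {size} < 1")
        if self.n_core_fungi > self.n_fungi or self.n_core_bacteria > self.n_bacteria:
            raise ValueError("n_core may not exceed the kingdom's ASV count")
        edges = self.planted_edges
        if edges is None:
            edges = default_planted_edges()
        for e in edges:
            if not (0 <= e.fungal_idx < self.n_fungi and 0 <= e.bacterial_idx < self.n_bacteria):
                raise ValueError(f"planted edge endpoint out of range: {e}")
        self.planted_edges = tuple(edges)

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes.values())


@dataclass
class TruthEdge:
    fungal_id: str
    bacterial_id: str
    sign: int
    condition: str
    rho: float
    weakly_identifiable: bool = False


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset."""

    edges: list[TruthEdge]
    core_fungi: list[str]
    core_bacteria: list[str]


def truth_edge_set(truth: SyntheticTruth, condition: str) -> set[frozenset[str]]:
    """Unordered ASV-id pairs planted as active in ``condition``.

    Edges planted under ``"both"`` belong to every condition's set.
    """
    cond = normalize_condition(condition)
    return {
        frozenset((e.fungal_id, e.bacterial_id))
        for e in truth.edges
        if e.condition in (cond, BOTH)
    }


def _make_taxonomy(fungal_ids, bacterial_ids) -> Taxonomy:
    rows = {}
    for ids, phyla, genera in (
        (fungal_ids, _FUNGAL_PHYLA, _FUNGAL_GENERA),
        (bacterial_ids, _BACTERIAL_PHYLA, _BACTERIAL_GENERA),
    ):
        for i, asv in enumerate(ids):
            genus = genera[i % len(genera)] if i % 10 < 7 else pd.NA  # ~70% annotated
            rows[asv] = {
                "phylum": phyla[i % len(phyla)],
                "class": pd.NA,
                "order": pd.NA,
                "family": pd.NA,
                "genus": genus,
                "species": pd.NA,
            }
    return Taxonomy(pd.DataFrame.from_dict(rows, orient="index"))


def _occupancy(rng, n_asvs, n_samples, decay, core_idx, planted_idx, location_slices):
    """Per-ASV Bernoulli occupancy mask, heavy-tailed toward rare ASVs."""
    q = rng.beta(decay, 1.0, size=n_asvs)
    # core ASVs are prevalent; planted endpoints are always-detected taxa —
    # inferred associations in real data are between prevalent ASVs, and an
    # absence decouples the pair from its latent correlation
    q[core_idx] = np.maximum(q[core_idx], rng.uniform(0.35, 0.95, size=len(core_idx)))
    q[planted_idx] = 1.0
    mask = rng.random((n_samples, n_asvs)) < q[None, :]
    # every ASV detected somewhere (real tables contain only detected ASVs)
    empty = ~mask.any(axis=0)
    if empty.any():
        rows = rng.integers(0, n_samples, size=int(empty.sum()))
        mask[rows, np.flatnonzero(empty)] = True
    # core forcing: at least one sample per location
    for sl in location_slices:
        loc_empty = ~mask[sl].any(axis=0)
        fix = np.array([j for j in core_idx if loc_empty[j]], dtype=int)
        if len(fix):
            rows = rng.integers(sl.start, sl.stop, size=len(fix))
            mask[rows, fix] = True
    return mask, q


def _condition_correlation(n_total, n_fungi, edges, condition):
    """Latent correlation matrix for samples of one condition."""
    corr = np.eye(n_total)
    for e in edges:
        if e.condition not in (condition, BOTH):
            continue
        i, j = e.fungal_idx, n_fungi + e.bacterial_idx
        corr[i, j] = corr[j, i] = e.sign * e.rho
    return corr


def _nearest_pd_cholesky(corr):
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # overlapping planted edges can break positive definiteness; clip spectrum
        w, v = np.linalg.eigh(corr)
        w = np.clip(w, 1e-6, None)
        fixed = v @ np.diag(w) @ v.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        return np.linalg.cholesky(fixed)


def generate_dataset(
    config: SimConfig,
) -> tuple[AsvTable, AsvTable, Taxonomy, SampleMetadata, SyntheticTruth]:
    """Draw one synthetic paired dataset.

    Returns ``(fungal table, bacterial table, taxonomy, metadata, truth)``.
    The same config (including seed) always yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    nF, nB = config.n_fungi, config.n_bacteria
    p = nF + nB

    fungal_ids = [f"fASV_{i + 1:04d}" for i in range(nF)]
    bacterial_ids = [f"bASV_{i + 1:04d}" for i in range(nB)]

    # --- samples -----------------------------------------------------------
    sample_ids, locations, conditions = [], [], []
    loc_codes = {}
    for (loc, cond) in sorted(config.group_sizes):
        loc_codes.setdefault(loc, loc[:2].upper())
    for (loc, cond), size in sorted(config.group_sizes.items()):
        tag = "sf" if cond == SNOW_FREE else "sc"
        for i in range(size):
            sample_ids.append(f"{loc_codes[loc]}-{tag}-{i + 1:02d}")
            locations.append(loc)
            conditions.append(cond)
    meta = SampleMetadata(
        pd.DataFrame(
            {"location": locations, "condition": conditions},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    n = len(sample_ids)
    loc_arr = np.asarray(locations)
    cond_arr = np.asarray(conditions)

    # contiguous sample blocks per location (samples were built sorted by group)
    location_slices = []
    for loc in sorted(set(locations)):
        idx = np.flatnonzero(loc_arr == loc)
        location_slices.append(slice(int(idx.min()), int(idx.max()) + 1))

    # --- occupancy ---------------------------------------------------------
    core_f = np.arange(config.n_core_fungi)
    core_b = np.arange(config.n_core_bacteria)
    planted_f = sorted({e.fungal_idx for e in config.planted_edges})
    planted_b = sorted({e.bacterial_idx for e in config.planted_edges})
    mask_f, _ = _occupancy(
        rng, nF, n, config.occupancy_decay, core_f, np.asarray(planted_f, dtype=int),
        location_slices,
    )
    mask_b, _ = _occupancy(
        rng, nB, n, config.occupancy_decay, core_b, np.asarray(planted_b, dtype=int),
        location_slices,
    )
    mask = np.hstack([mask_f, mask_b])

    # --- latent copula -----------------------------------------------------
    z = np.empty((n, p))
    for cond in CONDITIONS:
        rows = np.flatnonzero(cond_arr == cond)
        if len(rows) == 0:
            continue
        corr = _condition_correlation(p, nF, config.planted_edges, cond)
        chol = _nearest_pd_cholesky(corr)
        z[rows] = rng.standard_normal((len(rows), p)) @ chol.T

    # --- abundance profiles ------------------------------------------------
    # prevalent ASVs tend to be abundant; base log-mean rises with occupancy
    occ_frac_f = mask_f.mean(axis=0)
    occ_frac_b = mask_b.mean(axis=0)
    mu = np.concatenate(
        [rng.normal(0.0, 1.0, nF) + 1.5 * occ_frac_f,
         rng.normal(0.0, 1.0, nB) + 1.5 * occ_frac_b]
    )
    intensity = np.exp(mu[None, :] + config.lognormal_sigma * z) * mask

    # --- counts ------------------------------------------------------------
    def draw_counts(weights, depth_mean, depth_sd, ids):
        depths = np.round(rng.normal(depth_mean, depth_sd, size=n))
        depths = np.maximum(depths, config.depth_floor).astype(int)
        counts = np.zeros((n, weights.shape[1]), dtype=np.int64)
        for s in range(n):
            w = weights[s]
            total = w.sum()
            if total <= 0:  # sample with no present ASVs: fall back to uniform
                w = np.ones_like(w)
                total = w.sum()
            counts[s] = rng.multinomial(depths[s], w / total)
        return pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=ids)

    def enforce_core(counts: pd.DataFrame, core_ids: list[str]) -> None:
        # multinomial sampling can zero out a masked-present core ASV; move one
        # read from the sample's top ASV so the core stays detected per
        # location while keeping the drawn depth exact
        for sl in location_slices:
            block = counts.iloc[sl]
            missing = [a for a in core_ids if a in counts.columns and block[a].sum() == 0]
            for asv in missing:
                s = block.index[int(rng.integers(0, len(block)))]
                donor = counts.loc[s].idxmax()
                if counts.at[s, donor] < 2:
                    continue
                counts.at[s, donor] -= 1
                counts.at[s, asv] += 1

    fungal_counts = draw_counts(intensity[:, :nF], *config.fungal_depth, fungal_ids)
    bacterial_counts = draw_counts(intensity[:, nF:], *config.bacterial_depth, bacterial_ids)
    enforce_core(fungal_counts, [fungal_ids[i] for i in core_f])
    enforce_core(bacterial_counts, [bacterial_ids[i] for i in core_b])
    fungal = AsvTable(fungal_counts, FUNGI)
    bacterial = AsvTable(bacterial_counts, BACTERIA)

    taxonomy = _make_taxonomy(fungal_ids, bacterial_ids)

    # --- truth with identifiability annotation -----------------------------
    truth_edges = []
    for e in config.planted_edges:
        active = (
            np.ones(n, dtype=bool) if e.condition == BOTH else cond_arr == e.condition
        )
        co_occ = int((mask_f[active, e.fungal_idx] & mask_b[active, e.bacterial_idx]).sum())
        weak = co_occ == 0
        if weak:
            warnings.warn(
                f"planted edge {fungal_ids[e.fungal_idx]}–{bacterial_ids[e.bacterial_idx]} "
                f"({e.condition}) never co-occurs; marked weakly identifiable",
                stacklevel=2,
            )
        truth_edges.append(
            TruthEdge(
                fungal_id=fungal_ids[e.fungal_idx],
                bacterial_id=bacterial_ids[e.bacterial_idx],
                sign=e.sign,
                condition=e.condition,
                rho=e.rho,
                weakly_identifiable=weak,
            )
        )
    truth = SyntheticTruth(
        edges=truth_edges,
        core_fungi=[fungal_ids[i] for i in core_f],
        core_bacteria=[bacterial_ids[i] for i in core_b],
    )
    return fungal, bacterial, taxonomy, meta, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "fungal_id": e.fungal_id,
                "bacterial_id": e.bacterial_id,
                "sign": e.sign,
                "condition": e.condition,
                "rho": e.rho,
                "weakly_identifiable": e.weakly_identifiable,
            }
            for e in truth.edges
        ]
    ).to_csv(path, sep="\t", index=False)


def load_truth(path: str | Path, core_fungi=(), core_bacteria=()) -> SyntheticTruth:
    df = pd.read_csv(path, sep="\t")
    edges = [
        TruthEdge(
            fungal_id=r.fungal_id,
            bacterial_id=r.bacterial_id,
            sign=int(r.sign),
            condition=r.condition,
            rho=float(r.rho),
            weakly_identifiable=bool(r.weakly_identifiable),
        )
        for r in df.itertuples()
    ]
    return SyntheticTruth(edges=edges, core_fungi=list(core_fungi), core_bacteria=list(core_bacteria))
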