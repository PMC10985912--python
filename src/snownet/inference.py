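"""Sparse cross-kingdom association networks from paired count tables.

The estimator is neighborhood selection (Meinshausen–Bühlmann) on
centred-log-ratio (CLR) transformed counts of the *joint* fungal+bacterial
table: each CLR feature is lasso-regressed on all others, and an edge is
kept when either direction's coefficient is non-zero (OR rule).  The lasso
penalty λ is chosen by StARS stability selection: the neighborhood graphs
are re-estimated on random subsamples and the densest λ whose average
edge-selection instability stays below a threshold (default 0.05) is kept.
Edge weights are the larger-magnitude member of the two directional
coefficients at the selected λ, masked by the refitted adjacency; the edge
sign is the weight's sign.  Nodes left without any edge (orphans) are
removed.

One network is inferred per (filtered table pair, condition); weights are
penalized-regression coefficients and are not comparable to correlation
coefficients.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._lasso import NeighborhoodState, neighborhood_paths
from ._utils import derive_seed
from .filtering import FilteredPairTable, FilterPair
from .tables import BACTERIA, CONDITIONS, FUNGI, AsvTable, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class ClrMatrix:
    """CLR-transformed samples × features matrix with per-feature kingdom tags."""

    values: pd.DataFrame
    kingdoms: np.ndarray  # one tag per feature/column

    def __post_init__(self) -> None:
        if len(self.kingdoms) != self.values.shape[1]:
            raise ValueError("one kingdom tag per feature required")
        row_sums = self.values.to_numpy().sum(axis=1)
        if not np.allclose(row_sums, 0.0, atol=1e-8):
            raise ValueError("CLR rows must sum to zero")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def joint_clr(
    fungal_counts: pd.DataFrame,
    bacterial_counts: pd.DataFrame,
    pseudocount: float = 1.0,
    per_kingdom: bool = False,
) -> ClrMatrix:
    """CLR transform of the concatenated fungal+bacterial count table.

    Per sample, ``x_i = ln(c_i + pseudocount) − mean_j ln(c_j + pseudocount)``
    with the mean taken over the joint feature vector, so fungal and
    bacterial abundances share one geometric-mean reference.  With
    ``per_kingdom=True`` each kingdom is centred on its own geometric mean
    instead (the rows then still sum to zero within each kingdom block).
    """
    if list(fungal_counts.index) != list(bacterial_counts.index):
        raise ValueError("fungal and bacterial tables must share samples in the same order")
    overlap = set(fungal_counts.columns) & set(bacterial_counts.columns)
    if overlap:
        raise ValueError(f"ASV ids shared across kingdoms: {sorted(overlap)[:5]}")

    def _clr(block: np.ndarray) -> np.ndarray:
        logs = np.log(block + pseudocount)
        return logs - logs.mean(axis=1, keepdims=True)

    f = fungal_counts.to_numpy(dtype=float)
    b = bacterial_counts.to_numpy(dtype=float)
    if per_kingdom:
        data = np.hstack([_clr(f), _clr(b)])
    else:
        data = _clr(np.hstack([f, b]))
    values = pd.DataFrame(
        data,
        index=fungal_counts.index,
        columns=list(fungal_counts.columns) + list(bacterial_counts.columns),
    )
    kingdoms = np.array([FUNGI] * fungal_counts.shape[1] + [BACTERIA] * bacterial_counts.shape[1])
    return ClrMatrix(values=values, kingdoms=kingdoms)


# ---------------------------------------------------------------------------
# neighborhood selection


def _standardize(x: np.ndarray) -> np.ndarray:
    """Column z-scores; constant columns become all-zero (they carry no signal)."""
    mean = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd


def lambda_max(clr_values: np.ndarray) -> float:
    """Smallest penalty that zeroes every neighborhood: the largest absolute
    pairwise correlation between standardized features."""
    z = _standardize(np.asarray(clr_values, dtype=float))
    n = z.shape[0]
    c = np.abs(z.T @ z) / n
    np.fill_diagonal(c, 0.0)
    return float(c.max()) if c.size else 0.0


def make_lambda_path(lmax: float, n_lambda: int = 20, min_ratio: float = 0.01) -> np.ndarray:
    """Descending log-spaced penalty path from λ_max to min_ratio·λ_max."""
    if lmax <= 0:
        return np.full(n_lambda, 1e-12)
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def _neighborhood_paths(z: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Directed coefficient matrices B(λ) for every λ on the path.

    ``z`` must be standardized.  Returns an array of shape
    (n_lambda, p, p) with B[l, i, j] the coefficient of feature i in the
    lasso regression of feature j; diagonals are zero.  The lasso objective
    is ``1/(2n)·‖y − Xb‖² + λ‖b‖₁``, matching the λ_max scale above.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda path must be descending")
    if np.any(lambdas < 0):
        raise ValueError("lambda must be ≥ 0")
    n, p = z.shape
    if p < 2 or n < 3:
        return np.zeros((len(lambdas), p, p))
    return neighborhood_paths(z, lambdas)


def mb_fit(clr: ClrMatrix | np.ndarray, lam: float) -> np.ndarray:
    """Directed neighborhood coefficients B(λ) at a single penalty."""
    if lam < 0:
        raise ValueError("lambda must be ≥ 0")
    values = clr.values.to_numpy() if isinstance(clr, ClrMatrix) else np.asarray(clr, float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    z = _standardize(values)
    return _neighborhood_paths(z, np.array([lam]))[0]


def default_subsample_size(n: int) -> int:
    """StARS subsample size: min(⌊n/2⌋, ⌊10√n⌋).

    Half-sampling (the complementary-pairs convention of stability
    selection) keeps subsamples dissimilar enough that sampling-noise edges
    register as unstable even at the small per-condition sample sizes of a
    field study; for n ≥ 400 the ⌊10√n⌋ rate takes over.
    """
    return max(3, int(min(math.floor(0.5 * n), math.floor(10.0 * math.sqrt(n)))))


@dataclass
class StarsSettings:
    """StARS stability-selection settings (conventional defaults)."""

    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    n_subsamples: int = 20
    subsample_size: int | None = None  # None → default_subsample_size(n)
    beta_threshold: float = 0.05
    pseudocount: float = 1.0
    per_kingdom_clr: bool = False
    symmetrize: str = "max"  # "max" (larger-magnitude coefficient) or "mean"


@dataclass
class StarsResult:
    lambda_selected: float
    instability_path: list[tuple[float, float]]  # (λ, mean instability), λ descending


def stars_select(
    clr: ClrMatrix,
    lambda_path: Sequence[float] | None = None,
    n_subsamples: int = 20,
    subsample_size: int | None = None,
    beta_threshold: float = 0.05,
    seed: int | None = None,
) -> StarsResult:
    """Select the lasso penalty by subsampling stability.

    For every λ on the (descending) path, each feature pair's selection
    frequency θ̂ over ``n_subsamples`` subsamples (drawn without replacement)
    gives an instability contribution 2θ̂(1−θ̂); D(λ) is the average over all
    pairs.  Walking from λ_max downward, the running supremum of D is
    monotone non-decreasing, and the smallest λ for which it still satisfies
    ``D̄ ≤ beta_threshold`` is selected — the densest sufficiently-stable
    graph.  If even λ_max is unstable, λ_max is returned with a warning.
    """
    if n_subsamples < 2:
        raise ValueError("n_subsamples must be ≥ 2")
    values = clr.values.to_numpy(dtype=float)
    n, p = values.shape
    if lambda_path is None:
        lambda_path = make_lambda_path(lambda_max(values))
    lambdas = np.asarray(lambda_path, dtype=float)
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda path must be descending")
    b = subsample_size if subsample_size is not None else default_subsample_size(n)
    if b > n:
        raise ValueError(f"subsample size {b} exceeds n={n}")
    rng = np.random.default_rng(seed)
    states = [
        NeighborhoodState(_standardize(values[rng.choice(n, size=b, replace=False)]))
        for _ in range(n_subsamples)
    ]
    iu = np.triu_indices(p, 1)
    n_pairs = max(len(iu[0]), 1)
    instability: list[float] = []
    running_sup = 0.0
    # walk the path from sparse to dense; once the running-sup instability
    # exceeds β no smaller λ can be selected, so the dense end is skipped
    for lam in lambdas:
        counts = np.zeros((p, p), dtype=np.int32)
        for state in states:
            state.step(float(lam))
            counts += state.support()
        theta = counts[iu].astype(float) / n_subsamples
        d = float((2.0 * theta * (1.0 - theta)).sum() / n_pairs)
        instability.append(d)
        running_sup = max(running_sup, d)
        if running_sup > beta_threshold:
            break
    sup_path = np.maximum.accumulate(instability)
    ok = sup_path <= beta_threshold
    if ok.any():
        lam_sel = float(lambdas[np.flatnonzero(ok)[-1]])
    else:
        logger.warning(
            "instability exceeds %.3g already at λ_max (D=%.3g); selecting λ_max",
            beta_threshold, instability[0],
        )
        lam_sel = float(lambdas[0])
    return StarsResult(
        lambda_selected=lam_sel,
        instability_path=list(zip(lambdas[: len(instability)].tolist(), instability)),
    )


# ---------------------------------------------------------------------------
# network construction


@dataclass
class AssociationNetwork:
    """Undirected signed association network for one (filter pair, condition).

    ``graph`` nodes carry a ``kingdom`` attribute; edges carry ``weight``
    (signed, penalized-regression scale) and ``sign`` (+1/−1).
    ``dataset_nodes`` records every ASV that entered inference (also the
    orphans), per kingdom — the node pool null models draw from.
    """

    graph: nx.Graph
    condition: str | None = None
    pair: FilterPair | None = None
    lambda_selected: float | None = None
    instability_path: list[tuple[float, float]] = field(default_factory=list)
    dataset_nodes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def kingdom_of(self, node: str) -> str:
        return self.graph.nodes[node]["kingdom"]

    def edge_sign(self, a: str, b: str) -> int:
        return self.graph.edges[a, b]["sign"]

    def label(self) -> str:
        pair = self.pair or FilterPair(0, 0)
        return f"{self.condition}_tF{pair.t_f}_tB{pair.t_b}"


def refit_and_weight(
    clr: ClrMatrix,
    lambda_selected: float,
    symmetrize: str = "max",
    condition: str | None = None,
    pair: FilterPair | None = None,
    instability_path: list[tuple[float, float]] | None = None,
) -> AssociationNetwork:
    """Refit neighborhoods at the selected λ and build the weighted network.

    Adjacency uses the OR rule (an edge exists when either directional
    coefficient is non-zero); the symmetrized coefficient is the
    larger-magnitude member of {B_ij, B_ji} (``symmetrize="max"``) or their
    mean (``"mean"``); the weight is the symmetrized coefficient on the
    refitted adjacency, and orphan nodes are dropped.
    """
    if symmetrize not in ("max", "mean"):
        raise ValueError("symmetrize must be 'max' or 'mean'")
    values = clr.values.to_numpy(dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    # warm-started descent from λ_max keeps the refit cheap and well-conditioned
    state = NeighborhoodState(_standardize(values))
    for lam in make_lambda_path(lambda_max(values)):
        if lam <= lambda_selected:
            break
        state.step(float(lam))
    B = state.step(float(lambda_selected)).T
    support = (B != 0) | (B.T != 0)
    if symmetrize == "max":
        beta_sym = np.where(np.abs(B) >= np.abs(B.T), B, B.T)
    else:
        beta_sym = (B + B.T) / 2.0
    weights = beta_sym * support
    ids = clr.feature_ids
    graph = nx.Graph()
    iu, ju = np.nonzero(np.triu(support, 1))
    for i, j in zip(iu, ju):
        w = float(weights[i, j])
        if w == 0.0:  # opposite-signed coefficients can cancel under "mean"
            continue
        for k in (i, j):
            if ids[k] not in graph:
                graph.add_node(ids[k], kingdom=str(clr.kingdoms[k]))
        graph.add_edge(ids[i], ids[j], weight=w, sign=1 if w > 0 else -1)
    return AssociationNetwork(
        graph=graph,
        condition=condition,
        pair=pair,
        lambda_selected=float(lambda_selected),
        instability_path=list(instability_path or []),
        dataset_nodes={
            FUNGI: [f for f, k in zip(ids, clr.kingdoms) if k == FUNGI],
            BACTERIA: [f for f, k in zip(ids, clr.kingdoms) if k == BACTERIA],
        },
    )


def infer_network(
    fungal_counts: pd.DataFrame,
    bacterial_counts: pd.DataFrame,
    settings: StarsSettings | None = None,
    seed: int | None = None,
    condition: str | None = None,
    pair: FilterPair | None = None,
) -> AssociationNetwork:
    """CLR → StARS-selected neighborhood selection → weighted network."""
    settings = settings or StarsSettings()
    clr = joint_clr(
        fungal_counts, bacterial_counts,
        pseudocount=settings.pseudocount, per_kingdom=settings.per_kingdom_clr,
    )
    path = make_lambda_path(
        lambda_max(clr.values.to_numpy()), settings.n_lambda, settings.lambda_min_ratio
    )
    stars = stars_select(
        clr,
        lambda_path=path,
        n_subsamples=settings.n_subsamples,
        subsample_size=settings.subsample_size,
        beta_threshold=settings.beta_threshold,
        seed=seed,
    )
    return refit_and_weight(
        clr,
        stars.lambda_selected,
        symmetrize=settings.symmetrize,
        condition=condition,
        pair=pair,
        instability_path=stars.instability_path,
    )


def infer_condition_networks(
    filtered: FilteredPairTable,
    meta: SampleMetadata,
    settings: StarsSettings | None = None,
    seed: int = 0,
) -> tuple[AssociationNetwork, AssociationNetwork]:
    """One network per condition from a filtered table pair.

    Samples are split by snow-cover condition; ASVs with zero occurrence
    within a condition's subset are dropped from that condition's input.
    Returns ``(snow-free network, snow-covered network)``.
    """
    nets = []
    for condition in CONDITIONS:
        samples = [s for s in filtered.fungal.sample_ids if s in set(meta.samples_for(condition))]
        if len(samples) < 4:
            raise ValueError(f"condition {condition!r} has {len(samples)} samples; need ≥ 4")
        f_sub = filtered.fungal.counts.loc[samples]
        b_sub = filtered.bacterial.counts.loc[samples]
        for name, block in (("fungal", f_sub), ("bacterial", b_sub)):
            gone = block.columns[(block > 0).sum(axis=0) == 0]
            if len(gone):
                logger.info(
                    "%s: dropping %d %s ASV(s) absent from all %s samples",
                    filtered.pair, len(gone), name, condition,
                )
        f_sub = f_sub.loc[:, (f_sub > 0).any(axis=0)]
        b_sub = b_sub.loc[:, (b_sub > 0).any(axis=0)]
        nets.append(
            infer_network(
                f_sub,
                b_sub,
                settings=settings,
                seed=derive_seed(seed, "network", condition, filtered.pair.t_f, filtered.pair.t_b),
                condition=condition,
                pair=filtered.pair,
            )
        )
    return nets[0], nets[1]
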