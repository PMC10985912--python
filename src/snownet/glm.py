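"""GLMs on network ensembles: sign odds and per-phylum association frequency.

Two models mirror the two ecological questions.  A binomial GLM (logit
link) models the per-network counts of positive vs negative associations as
a function of snow-cover condition — its fitted values are the odds of a
positive association in each season.  Per filter pair, a Poisson GLM (log
link) models how often each fungal phylum associates to any bacterium,
with candidate terms {phylum, condition, phylum × condition}; the final
model is chosen by bidirectional stepwise AIC starting from the
main-effects model, with ties resolved toward the smaller model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .inference import AssociationNetwork
from .metrics import edge_type_partition
from .tables import CONDITIONS, FUNGI, SNOW_COVERED, SNOW_FREE, Taxonomy

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# record builders


def build_sign_records(networks: list[AssociationNetwork]) -> pd.DataFrame:
    """Per-network counts of positive and negative associations."""
    rows = []
    for net in networks:
        signs = [d["sign"] for _, _, d in net.graph.edges(data=True)]
        rows.append(
            {
                "network_id": net.label(),
                "condition": net.condition,
                "n_pos": sum(1 for s in signs if s > 0),
                "n_neg": sum(1 for s in signs if s < 0),
            }
        )
    return pd.DataFrame(rows)


def build_phylum_records(
    networks: list[AssociationNetwork], taxonomy: Taxonomy
) -> pd.DataFrame:
    """Fungal-phylum × condition fb-association counts, one block per filter pair.

    Every fb edge is attributed to the phylum of its fungal partner; phyla
    are zero-filled within each filter pair so both conditions contribute a
    count for every phylum seen in that pair.
    """
    rows = []
    for net in networks:
        fb = edge_type_partition(net)["fb"]
        tally: dict[str, int] = {}
        for edge in fb:
            a, b = tuple(edge)
            fungal = a if net.kingdom_of(a) == FUNGI else b
            phylum = taxonomy.phylum(fungal)
            tally[phylum] = tally.get(phylum, 0) + 1
        for phylum, count in tally.items():
            rows.append(
                {
                    "t_f": net.pair.t_f if net.pair else 0,
                    "t_b": net.pair.t_b if net.pair else 0,
                    "condition": net.condition,
                    "phylum": phylum,
                    "n_fb": count,
                }
            )
    df = pd.DataFrame(rows, columns=["t_f", "t_b", "condition", "phylum", "n_fb"])
    if df.empty:
        return df
    filled = []
    for (t_f, t_b), block in df.groupby(["t_f", "t_b"]):
        phyla = sorted(block["phylum"].unique())
        full = pd.MultiIndex.from_product(
            [phyla, list(CONDITIONS)], names=["phylum", "condition"]
        ).to_frame(index=False)
        merged = full.merge(block, on=["phylum", "condition"], how="left")
        merged["n_fb"] = merged["n_fb"].fillna(0).astype(int)
        merged["t_f"], merged["t_b"] = t_f, t_b
        filled.append(merged)
    return pd.concat(filled, ignore_index=True)[["t_f", "t_b", "condition", "phylum", "n_fb"]]


# ---------------------------------------------------------------------------
# stepwise AIC


@dataclass
class StepwiseResult:
    terms: tuple[str, ...]
    formula: str
    result: object  # fitted statsmodels results
    aic_trace: list[tuple[str, float]]


def _formula(response: str, terms: tuple[str, ...]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _hierarchy_ok(terms: set[str]) -> bool:
    for t in terms:
        if ":" in t:
            if not set(t.split(":")) <= terms:
                return False
    return True


def stepwise_aic(
    data: pd.DataFrame,
    response: str,
    start_terms: tuple[str, ...],
    scope_terms: tuple[str, ...],
    family: sm.families.Family,
) -> StepwiseResult:
    """Bidirectional AIC stepping over a hierarchical term space.

    From the starting model, each iteration evaluates every single-term
    addition (from ``scope_terms``) and deletion that keeps the model
    hierarchical (interactions require their main effects).  The move with
    the lowest AIC wins if it improves on the current model; on AIC ties the
    smaller model is preferred.  Stops when no move lowers the AIC.
    """
    def fit(terms: tuple[str, ...]):
        import warnings as _warnings

        with _warnings.catch_warnings():
            # zero cells under a log link predict rate→0; harmless here
            _warnings.simplefilter("ignore")
            return smf.glm(_formula(response, terms), data=data, family=family).fit()

    current = tuple(start_terms)
    if not _hierarchy_ok(set(current)):
        raise ValueError(f"starting terms {current} violate hierarchy")
    current_fit = fit(current)
    trace = [(_formula(response, current), float(current_fit.aic))]
    while True:
        candidates: list[tuple[float, int, tuple[str, ...]]] = []
        cur_set = set(current)
        for term in scope_terms:
            if term not in cur_set and _hierarchy_ok(cur_set | {term}):
                candidates.append(tuple(sorted(cur_set | {term})))
        for term in current:
            if _hierarchy_ok(cur_set - {term}):
                candidates.append(tuple(sorted(cur_set - {term})))
        best = None
        for terms in candidates:
            try:
                res = fit(terms)
            except Exception as exc:  # singular designs etc. are simply not eligible
                logger.debug("candidate %s failed: %s", terms, exc)
                continue
            key = (round(float(res.aic), 10), len(terms))
            if best is None or key < best[0]:
                best = (key, terms, res)
        if best is None:
            break
        (best_aic, _), best_terms, best_res = best
        cur_key = (round(float(current_fit.aic), 10), len(current))
        if (best_aic, len(best_terms)) < cur_key:
            current, current_fit = best_terms, best_res
            trace.append((_formula(response, current), float(current_fit.aic)))
        else:
            break
    return StepwiseResult(
        terms=current,
        formula=_formula(response, current),
        result=current_fit,
        aic_trace=trace,
    )


# ---------------------------------------------------------------------------
# the two models


@dataclass
class BinomialSignFit:
    params: pd.Series
    pvalues: pd.Series
    odds_by_condition: dict[str, float]
    odds_ratio_covered_vs_free: float
    separation_flag: bool
    n_networks: int
    result: object


def fit_sign_binomial(records: pd.DataFrame) -> BinomialSignFit:
    """Binomial GLM of (n_pos, n_neg) per network on snow-cover condition.

    ``records`` needs columns condition, n_pos, n_neg.  Networks with no
    edges are excluded.  Reports the fitted odds of a positive association
    per condition and the covered-vs-free odds ratio.  Under complete
    separation (a condition with only positive or only negative edges) the
    fit is flagged and refit with a Haldane–Anscombe 0.5 correction.
    """
    df = records.copy()
    df = df[(df["n_pos"] + df["n_neg"]) > 0]
    present = set(df["condition"])
    if not {SNOW_FREE, SNOW_COVERED} <= present:
        raise ValueError(f"both conditions required, got {sorted(present)}")

    def _fit(frame):
        frame = frame.copy()
        frame["covered"] = (frame["condition"] == SNOW_COVERED).astype(float)
        endog = frame[["n_pos", "n_neg"]].to_numpy(dtype=float)
        exog = sm.add_constant(frame[["covered"]].to_numpy(dtype=float))
        return sm.GLM(endog, exog, family=sm.families.Binomial()).fit()

    res = _fit(df)
    separation = bool(np.any(np.abs(res.params) > 15) or not np.all(np.isfinite(res.bse)))
    if separation:
        logger.warning("quasi-separation in sign model; refitting with +0.5 counts")
        adj = df.copy()
        adj[["n_pos", "n_neg"]] = adj[["n_pos", "n_neg"]] + 0.5
        res = _fit(adj)
    intercept, covered_coef = res.params
    odds = {
        SNOW_FREE: float(np.exp(intercept)),
        SNOW_COVERED: float(np.exp(intercept + covered_coef)),
    }
    return BinomialSignFit(
        params=pd.Series(res.params, index=["intercept", "covered"]),
        pvalues=pd.Series(res.pvalues, index=["intercept", "covered"]),
        odds_by_condition=odds,
        odds_ratio_covered_vs_free=float(np.exp(covered_coef)),
        separation_flag=separation,
        n_networks=len(df),
        result=res,
    )


@dataclass
class PoissonPhylumFit:
    pair: tuple[int, int]
    selected: StepwiseResult
    estimates: pd.DataFrame  # phylum × condition fitted rates


def fit_phylum_poisson(records: pd.DataFrame) -> PoissonPhylumFit:
    """Stepwise-selected Poisson GLM of fb counts on phylum and condition,
    for the records of a single filter pair.

    Phyla with zero fb edges in both conditions are dropped (log-link
    degeneracy).  Returns the per-phylum fitted association frequency under
    each condition from the selected model.
    """
    pairs = records[["t_f", "t_b"]].drop_duplicates()
    if len(pairs) != 1:
        raise ValueError("fit_phylum_poisson expects records of exactly one filter pair")
    df = records.copy()
    totals = df.groupby("phylum")["n_fb"].sum()
    keep = totals[totals > 0].index
    df = df[df["phylum"].isin(keep)]
    if df.empty or df["n_fb"].sum() == 0:
        raise ValueError("all-zero fb counts")
    if df["phylum"].nunique() < 2:
        raise ValueError("need at least two fungal phyla")
    if df["condition"].nunique() < 2:
        raise ValueError("need both conditions for a condition contrast")
    selected = stepwise_aic(
        df,
        response="n_fb",
        start_terms=("phylum", "condition"),
        scope_terms=("phylum", "condition", "condition:phylum"),
        family=sm.families.Poisson(),
    )
    grid = pd.MultiIndex.from_product(
        [sorted(df["phylum"].unique()), list(CONDITIONS)], names=["phylum", "condition"]
    ).to_frame(index=False)
    grid["rate"] = selected.result.predict(grid)
    pair = (int(pairs.iloc[0]["t_f"]), int(pairs.iloc[0]["t_b"]))
    return PoissonPhylumFit(pair=pair, selected=selected, estimates=grid)


def fit_phylum_poisson_grid(records: pd.DataFrame) -> list[PoissonPhylumFit]:
    """Run the per-pair Poisson model for every filter pair in ``records``."""
    fits = []
    for _, block in records.groupby(["t_f", "t_b"]):
        try:
            fits.append(fit_phylum_poisson(block))
        except ValueError as exc:
            logger.warning("phylum model skipped for pair %s: %s",
                           block[["t_f", "t_b"]].iloc[0].tolist(), exc)
    return fits
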