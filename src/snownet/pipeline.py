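"""End-to-end orchestration: data → composition stats → grid → networks →
nulls → consensus → GLMs, with a provenance manifest.

Each stage is a pure function of (inputs, config, master seed); per-stage
and per-network random streams are derived from the master seed by hashing
stage names and network identities, so a rerun with the same configuration
is bit-identical for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from . import community, ensemble, filtering, glm, graph_io, metrics, nulls
from .inference import AssociationNetwork, StarsSettings, infer_condition_networks
from .synthetic import SimConfig, SyntheticTruth, generate_dataset, write_truth
from .tables import (
    AsvTable,
    SampleMetadata,
    Taxonomy,
    BACTERIA,
    FUNGI,
    core_asvs,
    condition_exclusive_core,
    load_asv_table,
    load_metadata,
    load_taxonomy,
    write_asv_table,
    write_metadata,
    write_taxonomy,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With ``fungal_table``/``bacterial_table`` unset, a synthetic dataset is
    generated from ``sim`` (the generator's defaults are the emulated study
    design).  Defaults follow the study wherever it states a value: the two
    threshold vectors, 999 null replicates, and frequent associations in
    more than five networks.
    """

    outdir: str = "snownet_run"
    fungal_table: str | None = None
    bacterial_table: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    fungal_thresholds: tuple[int, ...] = filtering.DEFAULT_FUNGAL_THRESHOLDS
    bacterial_thresholds: tuple[int, ...] = filtering.DEFAULT_BACTERIAL_THRESHOLDS
    stars: StarsSettings = field(default_factory=StarsSettings)
    null_replicates: int = 999
    min_networks: int = ensemble.DEFAULT_MIN_NETWORKS
    permanova_permutations: int = 999
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {})) if "sim" in raw else SimConfig()
        stars = StarsSettings(**raw.pop("stars", {})) if "stars" in raw else StarsSettings()
        cfg = cls(sim=sim, stars=stars, **raw)
        cfg.fungal_thresholds = tuple(cfg.fungal_thresholds)
        cfg.bacterial_thresholds = tuple(cfg.bacterial_thresholds)
        return cfg


def _jsonable(obj):
    """Recursively coerce a config structure into JSON-safe types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Manifest:
    """Run inventory: files with hashes, stage seeds, failures."""

    def __init__(self, outdir: Path, config: RunConfig):
        self.outdir = outdir
        self.data = {
            "snownet_version": __version__,
            "config": _jsonable(asdict(config)),
            "files": {},
            "seeds": {},
            "failures": [],
        }

    def record(self, path: Path) -> Path:
        self.data["files"][str(path.relative_to(self.outdir))] = _sha256(path)
        return path

    def record_seed(self, stage: str, seed: int) -> int:
        self.data["seeds"][stage] = seed
        return seed

    def fail(self, stage: str, error: Exception) -> None:
        self.data["failures"].append({"stage": stage, "error": repr(error)})

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=1, sort_keys=True))
        return path


@dataclass
class PipelineData:
    fungal: AsvTable
    bacterial: AsvTable
    taxonomy: Taxonomy
    meta: SampleMetadata
    truth: SyntheticTruth | None = None


def load_or_simulate(config: RunConfig) -> PipelineData:
    if config.fungal_table:
        for name in ("bacterial_table", "taxonomy", "metadata"):
            if getattr(config, name) is None:
                raise FileNotFoundError(f"input mode requires --{name.replace('_', '-')}")
        return PipelineData(
            fungal=load_asv_table(config.fungal_table, FUNGI),
            bacterial=load_asv_table(config.bacterial_table, BACTERIA),
            taxonomy=load_taxonomy(config.taxonomy),
            meta=load_metadata(config.metadata),
        )
    sim = replace(config.sim, seed=derive_seed(config.seed, "simulate", config.sim.seed))
    fungal, bacterial, taxonomy, meta, truth = generate_dataset(sim)
    return PipelineData(fungal=fungal, bacterial=bacterial, taxonomy=taxonomy, meta=meta, truth=truth)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(data: PipelineData, outdir: Path, manifest: Manifest) -> None:
    write_asv_table(data.fungal, outdir / "fungal_counts.tsv")
    write_asv_table(data.bacterial, outdir / "bacterial_counts.tsv")
    write_taxonomy(data.taxonomy, outdir / "taxonomy.tsv")
    write_metadata(data.meta, outdir / "metadata.tsv")
    for name in ("fungal_counts.tsv", "bacterial_counts.tsv", "taxonomy.tsv", "metadata.tsv"):
        manifest.record(outdir / name)
    if data.truth is not None:
        write_truth(data.truth, outdir / "truth.tsv")
        manifest.record(outdir / "truth.tsv")


def stage_composition(
    data: PipelineData, outdir: Path, manifest: Manifest, config: RunConfig
) -> None:
    rows = []
    for table in (data.fungal, data.bacterial):
        alpha = community.alpha_diversity(table)
        alpha.insert(0, "kingdom", table.kingdom)
        rows.append(alpha)
    pd.concat(rows).to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    manifest.record(outdir / "alpha_diversity.tsv")

    test_rows = []
    for table in (data.fungal, data.bacterial):
        from .tables import relative_abundance

        dist = community.bray_curtis(relative_abundance(table))
        for factor in ("condition", "location"):
            labels = data.meta.table.loc[table.sample_ids, factor]
            seed = derive_seed(config.seed, "permanova", table.kingdom, factor)
            res = community.permanova(
                dist, labels, n_permutations=config.permanova_permutations, seed=seed
            )
            test_rows.append(
                {
                    "kingdom": table.kingdom,
                    "factor": factor,
                    "pseudo_F": res.pseudo_f,
                    "R2": res.r2,
                    "p": res.p_value,
                }
            )
    pd.DataFrame(test_rows).to_csv(outdir / "permanova.tsv", sep="\t", index=False)
    manifest.record(outdir / "permanova.tsv")

    # core ASVs and their condition exclusivity
    core_rows = []
    for table in (data.fungal, data.bacterial):
        core = core_asvs(table, data.meta)
        part = condition_exclusive_core(table, data.meta, core)
        part.insert(0, "kingdom", table.kingdom)
        core_rows.append(part)
    pd.concat(core_rows).to_csv(outdir / "core_asvs.tsv", sep="\t")
    manifest.record(outdir / "core_asvs.tsv")

    contrasts = []
    for table in (data.fungal, data.bacterial):
        c = community.phylum_richness_contrast(table, data.taxonomy, data.meta)
        c.insert(0, "kingdom", table.kingdom)
        contrasts.append(c)
    pd.concat(contrasts).to_csv(outdir / "phylum_richness.tsv", sep="\t", index=False)
    manifest.record(outdir / "phylum_richness.tsv")


def stage_grid(data: PipelineData, config: RunConfig) -> list[filtering.FilteredPairTable]:
    return filtering.build_grid(
        data.fungal, data.bacterial, config.fungal_thresholds, config.bacterial_thresholds
    )


def stage_networks(
    grid: list[filtering.FilteredPairTable],
    data: PipelineData,
    outdir: Path,
    manifest: Manifest,
    config: RunConfig,
) -> list[AssociationNetwork]:
    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    networks = []
    for filtered in grid:
        t0 = time.time()
        free, covered = infer_condition_networks(
            filtered, data.meta, settings=config.stars, seed=config.seed
        )
        for net in (free, covered):
            networks.append(net)
            manifest.record(graph_io.write_network(net, netdir / f"{net.label()}.tsv"))
            manifest.record(netdir / f"{net.label()}.tsv.json")
        logger.info("pair %s: %d + %d edges (%.1fs)",
                    filtered.pair, free.n_edges, covered.n_edges, time.time() - t0)
    props = metrics.properties_table(networks)
    props.to_csv(outdir / "network_properties.tsv", sep="\t", index=False)
    manifest.record(outdir / "network_properties.tsv")
    comparison = metrics.paired_comparison_table(props)
    comparison.to_csv(outdir / "paired_comparison.tsv", sep="\t", index=False)
    manifest.record(outdir / "paired_comparison.tsv")
    return networks


def stage_nulls(
    networks: list[AssociationNetwork], outdir: Path, manifest: Manifest, config: RunConfig
) -> pd.DataFrame:
    dists = []
    for net in networks:
        if net.n_edges == 0:
            logger.warning("network %s has no edges; null model skipped", net.label())
            continue
        seed = derive_seed(config.seed, "null-edge-type", net.label())
        dists.extend(nulls.edge_type_null(net, n_replicates=config.null_replicates, seed=seed))
    by_pair: dict[tuple, dict[str, AssociationNetwork]] = {}
    for net in networks:
        by_pair.setdefault((net.pair.t_f, net.pair.t_b), {})[net.condition] = net
    for pair, conds in sorted(by_pair.items()):
        if len(conds) != 2:
            continue
        free, covered = conds["snow-free"], conds["snow-covered"]
        for fb_restricted in (False, True):
            seed = derive_seed(config.seed, "null-shared", pair, fb_restricted)
            try:
                dists.append(
                    nulls.shared_null(
                        free, covered, n_replicates=config.null_replicates,
                        seed=seed, fb_restricted=fb_restricted,
                    )
                )
            except ValueError as exc:
                logger.warning("shared null skipped for %s: %s", pair, exc)
    summary = nulls.null_summary_table(dists)
    summary.to_csv(outdir / "null_summaries.tsv", sep="\t", index=False)
    manifest.record(outdir / "null_summaries.tsv")
    return summary


def stage_consensus(
    networks: list[AssociationNetwork],
    data: PipelineData,
    outdir: Path,
    manifest: Manifest,
    config: RunConfig,
) -> list[ensemble.AssociationRecord]:
    records = ensemble.frequent_associations(networks, min_networks=config.min_networks)
    table = ensemble.records_table(records, data.taxonomy)
    table.to_csv(outdir / "frequent_associations.tsv", sep="\t", index=False)
    manifest.record(outdir / "frequent_associations.tsv")
    genus = ensemble.genus_summary(
        records, data.taxonomy, min_networks=config.min_networks
    )
    genus.to_csv(outdir / "genus_summary.tsv", sep="\t", index=False)
    manifest.record(outdir / "genus_summary.tsv")
    if data.truth is not None:
        scores = ensemble.recovery_score(records, data.truth, min_networks=config.min_networks)
        pd.DataFrame([vars(s) for s in scores.values()]).to_csv(
            outdir / "recovery.tsv", sep="\t", index=False
        )
        manifest.record(outdir / "recovery.tsv")
    return records


def stage_glm(
    networks: list[AssociationNetwork],
    data: PipelineData,
    outdir: Path,
    manifest: Manifest,
) -> None:
    sign_records = glm.build_sign_records(networks)
    sign_records.to_csv(outdir / "sign_counts.tsv", sep="\t", index=False)
    manifest.record(outdir / "sign_counts.tsv")
    try:
        fit = glm.fit_sign_binomial(sign_records)
        json_out = {
            "params": fit.params.to_dict(),
            "pvalues": fit.pvalues.to_dict(),
            "odds_by_condition": fit.odds_by_condition,
            "odds_ratio_covered_vs_free": fit.odds_ratio_covered_vs_free,
            "separation_flag": fit.separation_flag,
            "n_networks": fit.n_networks,
        }
        (outdir / "sign_binomial.json").write_text(json.dumps(json_out, indent=1))
        manifest.record(outdir / "sign_binomial.json")
    except ValueError as exc:
        logger.warning("sign model skipped: %s", exc)

    phylum_records = glm.build_phylum_records(networks, data.taxonomy)
    phylum_records.to_csv(outdir / "phylum_fb_counts.tsv", sep="\t", index=False)
    manifest.record(outdir / "phylum_fb_counts.tsv")
    fits = glm.fit_phylum_poisson_grid(phylum_records)
    rows = []
    for f in fits:
        est = f.estimates.copy()
        est.insert(0, "t_f", f.pair[0])
        est.insert(1, "t_b", f.pair[1])
        est["formula"] = f.selected.formula
        rows.append(est)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(
            outdir / "phylum_poisson_estimates.tsv", sep="\t", index=False
        )
        manifest.record(outdir / "phylum_poisson_estimates.tsv")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the path of the manifest JSON."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    networks: list[AssociationNetwork] = []
    try:
        data = load_or_simulate(config)
        stage_simulate(data, outdir, manifest)
        stage_composition(data, outdir, manifest, config)
        grid = stage_grid(data, config)
        networks = stage_networks(grid, data, outdir, manifest, config)
        stage_nulls(networks, outdir, manifest, config)
        stage_consensus(networks, data, outdir, manifest, config)
        stage_glm(networks, data, outdir, manifest)
    except Exception as exc:
        manifest.fail("pipeline", exc)
        manifest.write()
        raise
    return manifest.write()
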