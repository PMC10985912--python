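"""ASV tables, taxonomy and sample metadata.

The central container is :class:`AsvTable`, a samples × ASVs count matrix for
one kingdom (fungi or bacteria).  Alongside it live the per-ASV taxonomic
annotations (:class:`Taxonomy`) and the per-sample design
(:class:`SampleMetadata`: location and snow-cover condition).

"Detected" throughout means a count of at least one read; no abundance floor
is applied.  Core ASVs are those detected in at least one sample from every
sampled location, i.e. taxa typical for the habitat rather than for a single
site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FUNGI = "fungi"
BACTERIA = "bacteria"
KINGDOMS = (FUNGI, BACTERIA)

SNOW_FREE = "snow-free"
SNOW_COVERED = "snow-covered"
CONDITIONS = (SNOW_FREE, SNOW_COVERED)

TAXONOMIC_RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: accepted spellings in input files, normalized on load
_CONDITION_ALIASES = {
    "snow-free": SNOW_FREE,
    "snow_free": SNOW_FREE,
    "snow free": SNOW_FREE,
    "snow-covered": SNOW_COVERED,
    "snow_covered": SNOW_COVERED,
    "snow covered": SNOW_COVERED,
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def normalize_condition(value: str) -> str:
    key = str(value).strip().lower()
    if key not in _CONDITION_ALIASES:
        raise ValidationError(
            f"unknown condition {value!r}; expected one of {sorted(set(_CONDITION_ALIASES))}"
        )
    return _CONDITION_ALIASES[key]


@dataclass
class AsvTable:
    """Samples × ASVs count matrix for a single kingdom.

    Parameters
    ----------
    counts
        Integer DataFrame with sample ids as index and ASV ids as columns.
        All-zero ASV columns are dropped on construction (with a warning),
        so every retained ASV is detected in at least one sample.
    kingdom
        ``"fungi"`` or ``"bacteria"``.
    """

    counts: pd.DataFrame
    kingdom: str

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValidationError(f"kingdom must be one of {KINGDOMS}, got {self.kingdom!r}")
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ValidationError("empty ASV table")
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dup}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate ASV ids: {dup}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (values < 0).any():
            raise ValidationError("negative counts in ASV table")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("non-integer counts in ASV table")
        self.counts = self.counts.astype(np.int64)
        zero = self.counts.sum(axis=0) == 0
        if zero.any():
            dropped = self.counts.columns[zero].tolist()
            logger.warning(
                "dropping %d all-zero ASV column(s) from %s table: %s",
                len(dropped), self.kingdom, dropped[:10],
            )
            self.counts = self.counts.loc[:, ~zero]
        if self.counts.shape[1] == 0:
            raise ValidationError("ASV table has no non-zero ASVs")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Total read count per sample."""
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str], drop_empty_asvs: bool = False) -> "AsvTable":
        sub = self.counts.loc[list(sample_ids)]
        if drop_empty_asvs:
            sub = sub.loc[:, sub.sum(axis=0) > 0]
        return AsvTable(sub.copy(), self.kingdom)

    def subset_asvs(self, asv_ids: Iterable[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[:, list(asv_ids)].copy(), self.kingdom)


def load_asv_table(path: str | Path, kingdom: str, orientation: str = "samples_by_asvs") -> AsvTable:
    """Read a TSV count table.

    ``orientation`` is ``"samples_by_asvs"`` (rows are samples; the default
    on-disk layout), ``"asvs_by_samples"`` (transposed), or ``"auto"`` which
    guesses from the shape and warns rather than deciding silently.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty table in {path}")
    if orientation == "auto":
        # Heuristic only: amplicon tables almost always have more ASVs than samples.
        if df.shape[0] > df.shape[1]:
            logger.warning(
                "orientation='auto': %s has more rows (%d) than columns (%d); "
                "assuming rows are ASVs and transposing", path, df.shape[0], df.shape[1],
            )
            df = df.T
        else:
            logger.warning("orientation='auto': assuming rows of %s are samples", path)
    elif orientation == "asvs_by_samples":
        df = df.T
    elif orientation != "samples_by_asvs":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = "sample_id"
    df.columns.name = None
    return AsvTable(df, kingdom)


def write_asv_table(table: AsvTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class Taxonomy:
    """Per-ASV rank annotations (phylum … species); missing ranks are NA."""

    assignments: pd.DataFrame

    def __post_init__(self) -> None:
        if self.assignments.index.duplicated().any():
            raise ValidationError("duplicate ASV ids in taxonomy")
        for rank in TAXONOMIC_RANKS:
            if rank not in self.assignments.columns:
                self.assignments[rank] = pd.NA
        self.assignments = self.assignments[list(TAXONOMIC_RANKS)]
        # empty strings are not a valid missing marker
        self.assignments = self.assignments.replace("", pd.NA)

    def rank(self, asv_id: str, rank: str, default=None):
        if asv_id not in self.assignments.index:
            return default
        value = self.assignments.at[asv_id, rank]
        return default if pd.isna(value) else value

    def phylum(self, asv_id: str, default: str = "unknown") -> str:
        return self.rank(asv_id, "phylum", default=default)

    def genus(self, asv_id: str, default=None):
        return self.rank(asv_id, "genus", default=default)


def load_taxonomy(path: str | Path) -> Taxonomy:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return Taxonomy(df)


def write_taxonomy(tax: Taxonomy, path: str | Path) -> None:
    tax.assignments.to_csv(path, sep="\t", index_label="asv_id", na_rep="NA")


@dataclass
class SampleMetadata:
    """Sample → (location, condition) design table."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"location", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")
        self.table = self.table.copy()
        self.table["condition"] = [normalize_condition(c) for c in self.table["condition"]]
        self.table["location"] = self.table["location"].astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def locations(self) -> list[str]:
        return sorted(self.table["location"].unique())

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def condition_of(self) -> pd.Series:
        return self.table["condition"]

    def location_of(self) -> pd.Series:
        return self.table["location"]

    def samples_for(self, condition: str | None = None, location: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == normalize_condition(condition)
        if location is not None:
            mask &= self.table["location"] == location
        return list(self.table.index[mask])

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """(location, condition) → sample ids."""
        out: dict[tuple[str, str], list[str]] = {}
        for (loc, cond), sub in self.table.groupby(["location", "condition"], sort=True):
            out[(loc, cond)] = list(sub.index)
        return out

    def validate_covers(self, table: AsvTable) -> None:
        missing = set(table.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(f"samples missing from metadata: {sorted(missing)[:10]}")


def load_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# derived quantities


def core_asvs(table: AsvTable, meta: SampleMetadata) -> set[str]:
    """ASVs detected (count ≥ 1) in at least one sample from every location."""
    meta.validate_covers(table)
    locations = meta.locations
    if len(locations) < 2:
        raise ValidationError("core ASVs are undefined with a single location")
    present_everywhere = np.ones(table.n_asvs, dtype=bool)
    for loc in locations:
        samples = [s for s in meta.samples_for(location=loc) if s in table.counts.index]
        if not samples:
            raise ValidationError(f"no samples for location {loc!r} in the ASV table")
        present_everywhere &= (table.counts.loc[samples] > 0).any(axis=0).to_numpy()
    return set(np.asarray(table.asv_ids)[present_everywhere])


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Per-sample read proportions; rows sum to one."""
    depths = table.depths()
    zero = depths[depths == 0]
    if len(zero):
        raise ValidationError(f"zero-depth sample(s): {list(zero.index)}")
    return table.counts.div(depths, axis=0)


def abundant_asvs_per_group(
    table: AsvTable, meta: SampleMetadata, threshold: float
) -> dict[tuple[str, str], list[str]]:
    """ASVs whose mean relative abundance within a (location, condition) group
    is at least ``threshold``."""
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    rel = relative_abundance(table)
    out: dict[tuple[str, str], list[str]] = {}
    for group, samples in meta.groups().items():
        samples = [s for s in samples if s in rel.index]
        if not samples:
            logger.warning("empty sample group %s skipped", group)
            continue
        means = rel.loc[samples].mean(axis=0)
        out[group] = list(means.index[means >= threshold]) if threshold > 0 else list(means.index)
    return out


def condition_exclusive_core(
    table: AsvTable, meta: SampleMetadata, core: set[str]
) -> pd.DataFrame:
    """Partition core ASVs by condition exclusivity.

    Returns a frame indexed by ASV id with the number of samples each core
    ASV occurs in per condition and a ``category`` column:
    ``snow-free-only``, ``snow-covered-only`` or ``both``.
    """
    unknown = core - set(table.asv_ids)
    if unknown:
        raise ValidationError(f"core ids not in table: {sorted(unknown)[:10]}")
    meta.validate_covers(table)
    core_sorted = sorted(core)
    rows = []
    for cond in CONDITIONS:
        samples = [s for s in meta.samples_for(condition=cond) if s in table.counts.index]
        occ = (table.counts.loc[samples, core_sorted] > 0).sum(axis=0)
        rows.append(occ)
    occ_free, occ_cov = rows
    category = np.where(
        (occ_free > 0) & (occ_cov > 0), "both",
        np.where(occ_free > 0, "snow-free-only", "snow-covered-only"),
    )
    return pd.DataFrame(
        {
            "n_samples_snow_free": occ_free,
            "n_samples_snow_covered": occ_cov,
            "category": category,
        },
        index=pd.Index(core_sorted, name="asv_id"),
    )
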