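"""Data model and I/O for functional-trait tables and colonization abundance tables.

The containers here mirror the two kinds of raw data in a trait-based
succession study of sessile-surface colonists:

* a species x trait table of discrete *modalities* (scoring levels), with
  trait definitions that declare each trait as ordered or categorical and
  give the level order;
* a sample x species count table, one row per colonization surface
  ("sandwich" or basalt "block"), with per-surface metadata (months since
  the eruption at recovery, recovery temperature, deployment duration,
  pre/post-eruption epoch).

Downstream analyses work on counts pooled over all surfaces recovered at the
same time point, and on per-trait modality abundances (the total number of
individuals expressing each modality).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("venttraits")

MISSING = None  # sentinel in public APIs; stored as NaN in DataFrames

#: ambient deep-sea temperature at the study depth, degrees C
AMBIENT_TEMP_C = 1.8


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSpec:
    """Definition of a single trait: its kind and ordered list of modality levels.

    ``kind`` is ``"ordered"`` when the levels form a gradient (e.g. maximum
    adult body size from small to very large) and ``"categorical"`` otherwise.
    Level order is meaningful only for ordered traits.
    """

    name: str
    kind: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("ordered", "categorical"):
            raise DataError(f"trait {self.name!r}: kind must be 'ordered' or "
                            f"'categorical', got {self.kind!r}")
        if len(self.levels) == 0:
            raise DataError(f"trait {self.name!r}: empty level list")
        if len(set(self.levels)) != len(self.levels):
            raise DataError(f"trait {self.name!r}: duplicate modality labels")
        if self.kind == "ordered" and len(self.levels) < 2:
            raise DataError(f"trait {self.name!r}: ordered trait needs >=2 levels")

    def rank_of(self, level: str) -> int:
        return self.levels.index(level)


class TraitTable:
    """Species x trait modality assignments, with missing values allowed.

    Stored as a pandas DataFrame (index = species, columns = traits, values =
    modality label strings or NaN). Every non-missing label must belong to the
    declared levels of its trait, and every species must carry at least one
    non-missing trait.
    """

    def __init__(self, data: pd.DataFrame, specs: Sequence[TraitSpec]):
        specs = list(specs)
        by_name = {s.name: s for s in specs}
        if set(data.columns) - set(by_name):
            extra = sorted(set(data.columns) - set(by_name))
            raise DataError(f"traits without definitions: {extra}")
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].tolist()
            raise DataError(f"duplicate species rows: {dups}")
        if len(data) == 0:
            raise DataError("no species in trait table")
        # validate labels against declared levels
        for trait in data.columns:
            spec = by_name[trait]
            col = data[trait].dropna()
            bad = col[~col.isin(spec.levels)]
            if len(bad):
                sp, lab = bad.index[0], bad.iloc[0]
                raise DataError(
                    f"species {sp!r}, trait {trait!r}: modality {lab!r} "
                    f"not among declared levels {list(spec.levels)}")
        if (data.notna().sum(axis=1) == 0).any():
            empty = data.index[data.notna().sum(axis=1) == 0].tolist()
            raise DataError(f"species with no non-missing trait: {empty}")
        self.data = data
        self.specs = [by_name[c] for c in data.columns]

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def modality(self, species: str, trait: str):
        v = self.data.at[species, trait]
        return None if pd.isna(v) else v

    def __eq__(self, other) -> bool:
        return (isinstance(other, TraitTable)
                and self.data.equals(other.data)
                and self.specs == other.specs)

    def __repr__(self) -> str:
        return (f"TraitTable({len(self.data)} species x "
                f"{len(self.data.columns)} traits)")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one colonization surface.

    ``time_months`` is months since the eruption at recovery for post-eruption
    samples; pre-eruption samples carry ``None`` (they are a mature-community
    reference, not a point on the post-eruption clock).
    """

    sample_id: str
    surface_kind: str  # "sandwich" | "block"
    epoch: str  # "pre_eruption" | "post_eruption"
    time_months: float | None
    recovery_temp_C: float
    deployment_months: float | None = None

    def __post_init__(self) -> None:
        if self.surface_kind not in ("sandwich", "block"):
            raise DataError(f"{self.sample_id}: bad surface_kind {self.surface_kind!r}")
        if self.epoch not in ("pre_eruption", "post_eruption"):
            raise DataError(f"{self.sample_id}: bad epoch {self.epoch!r}")
        if self.epoch == "post_eruption":
            if self.time_months is None or self.time_months < 0:
                raise DataError(f"{self.sample_id}: post-eruption sample needs "
                                f"time_months >= 0")
        if self.recovery_temp_C < AMBIENT_TEMP_C:
            raise DataError(f"{self.sample_id}: recovery temperature "
                            f"{self.recovery_temp_C} below ambient ({AMBIENT_TEMP_C})")


class AbundanceTable:
    """Per-surface species counts plus sample metadata.

    ``counts`` is a DataFrame (index = sample_id, columns = taxa) of
    non-negative integers; ``samples`` holds one :class:`SampleRecord` per row
    in the same order.
    """

    def __init__(self, samples: Sequence[SampleRecord], counts: pd.DataFrame):
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate sample ids")
        if list(counts.index) != ids:
            raise DataError("counts rows do not match sample records")
        if counts.columns.duplicated().any():
            raise DataError("duplicate taxa columns")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DataError("non-integer counts")
            counts = counts.round().astype(int)
            arr = counts.to_numpy()
        if (arr < 0).any():
            raise DataError("negative counts")
        self.samples = list(samples)
        self.counts = counts

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def record(self, sample_id: str) -> SampleRecord:
        return self.samples[self.sample_ids.index(sample_id)]

    def subset_samples(self, keep: Sequence[str]) -> "AbundanceTable":
        keep = list(keep)
        recs = [s for s in self.samples if s.sample_id in set(keep)]
        return AbundanceTable(recs, self.counts.loc[[r.sample_id for r in recs]])

    def __eq__(self, other) -> bool:
        return (isinstance(other, AbundanceTable)
                and self.samples == other.samples
                and self.counts.equals(other.counts))

    def __repr__(self) -> str:
        return f"AbundanceTable({len(self.samples)} samples x {len(self.taxa)} taxa)"


@dataclass
class PooledSeries:
    """Counts pooled over all surfaces recovered at the same post-eruption time.

    ``counts`` is indexed by post-eruption month; ``pre_counts`` (optional)
    pools the pre-eruption reference surfaces.
    """

    counts: pd.DataFrame  # index: time_months (sorted), columns: taxa
    pre_counts: pd.Series | None = None  # same taxa, or None

    @property
    def times(self) -> np.ndarray:
        return self.counts.index.to_numpy(dtype=float)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class ModalityAbundance:
    """Individuals per modality per time point for one trait.

    Row totals equal the pooled abundance of species with a non-missing
    modality for the trait; species missing the trait contribute nowhere.
    """

    trait: TraitSpec
    table: pd.DataFrame  # index: time_months, columns: trait levels
    pre_row: pd.Series | None = None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_trait_table(definitions_file, modalities_file) -> tuple[list[TraitSpec], TraitTable]:
    """Read trait definitions and species modality assignments from CSV.

    The definitions file is long-form with columns ``trait, trait_type,
    modality``; row order within a trait gives the level order. The
    modalities file is either long-form (``species, trait, modality``; an
    empty modality cell means missing) or wide (first column = species,
    remaining columns = traits).
    """
    defs = pd.read_csv(definitions_file, dtype=str)
    need = {"trait", "trait_type", "modality"}
    if not need <= set(defs.columns):
        raise DataError(f"definitions file must have columns {sorted(need)}, "
                        f"got {list(defs.columns)}")
    specs: list[TraitSpec] = []
    for trait, grp in defs.groupby("trait", sort=False):
        kinds = grp["trait_type"].unique()
        if len(kinds) != 1:
            raise DataError(f"trait {trait!r}: conflicting trait_type entries")
        specs.append(TraitSpec(trait, kinds[0], tuple(grp["modality"])))

    mods = pd.read_csv(modalities_file, dtype=str)
    if {"species", "trait", "modality"} <= set(mods.columns):
        if len(mods) == 0:
            raise DataError("no species in modalities file")
        if mods.duplicated(["species", "trait"]).any():
            dup = mods[mods.duplicated(["species", "trait"])].iloc[0]
            raise DataError(f"duplicate assignment for species {dup['species']!r}, "
                            f"trait {dup['trait']!r}")
        wide = mods.pivot(index="species", columns="trait", values="modality")
        wide = wide.reindex(index=pd.unique(mods["species"]))
    else:
        sp_col = mods.columns[0]
        if mods[sp_col].duplicated().any():
            raise DataError("duplicate species row in modalities file")
        wide = mods.set_index(sp_col)
    if len(wide) == 0:
        raise DataError("no species in modalities file")
    # order columns as in definitions; drop all-missing declared traits absent
    cols = [s.name for s in specs if s.name in wide.columns]
    unknown = set(wide.columns) - {s.name for s in specs}
    if unknown:
        raise DataError(f"modalities file has undeclared traits: {sorted(unknown)}")
    table = TraitTable(wide[cols], specs)
    return specs, table


def _metadata_frame(metadata) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        md = metadata.copy()
    else:
        md = pd.read_csv(metadata, float_precision="round_trip")
    if "sample_id" not in md.columns:
        raise DataError("metadata needs a sample_id column")
    md["sample_id"] = md["sample_id"].astype(str)
    return md.set_index("sample_id")


def read_abundance(counts_file, metadata) -> AbundanceTable:
    """Read per-surface species counts (wide or long CSV) plus sample metadata.

    Long form has columns ``sample, species, count``; anything else is treated
    as wide (first column = sample id, remaining columns = taxa). ``metadata``
    is a CSV path or DataFrame with columns ``sample_id, surface_kind, epoch,
    time_months, recovery_temp_C[, deployment_months]``.
    """
    raw = pd.read_csv(counts_file, float_precision="round_trip")
    if {"sample", "species", "count"} <= set(raw.columns):
        if raw.duplicated(["sample", "species"]).any():
            dup = raw[raw.duplicated(["sample", "species"])].iloc[0]
            raise DataError(f"duplicate (sample, species) pair: "
                            f"({dup['sample']!r}, {dup['species']!r})")
        wide = (raw.assign(sample=raw["sample"].astype(str))
                .pivot(index="sample", columns="species", values="count")
                .reindex(index=pd.unique(raw["sample"].astype(str)))
                .fillna(0))
        wide = wide[pd.unique(raw["species"])]
    else:
        sp_col = raw.columns[0]
        wide = raw.assign(**{sp_col: raw[sp_col].astype(str)}).set_index(sp_col)
    arr = wide.to_numpy()
    if not np.allclose(arr, np.round(arr)):
        raise DataError("non-integer counts in counts file")
    if (arr < 0).any():
        raise DataError("negative counts in counts file")
    wide = wide.round().astype(int)

    md = _metadata_frame(metadata)
    missing = set(wide.index) - set(md.index)
    if missing:
        raise DataError(f"samples without metadata: {sorted(missing)}")
    records = []
    for sid in wide.index:
        row = md.loc[sid]
        t = row.get("time_months")
        t = None if pd.isna(t) else float(t)
        dep = row.get("deployment_months")
        dep = None if dep is None or pd.isna(dep) else float(dep)
        records.append(SampleRecord(
            sample_id=str(sid),
            surface_kind=str(row["surface_kind"]),
            epoch=str(row["epoch"]),
            time_months=t,
            recovery_temp_C=float(row["recovery_temp_C"]),
            deployment_months=dep,
        ))
    return AbundanceTable(records, wide)


# ---------------------------------------------------------------------------
# Filtering, pooling, aggregation
# ---------------------------------------------------------------------------


def filter_samples(table: AbundanceTable, temp_min: float, temp_max: float) -> AbundanceTable:
    """Keep surfaces with recovery temperature in [temp_min, temp_max] (inclusive).

    The window restricts analysis to the thermal range sampled throughout the
    observation period; both bounds are inclusive. Order is preserved.
    """
    if temp_min > temp_max:
        raise DataError("temp_min > temp_max")
    keep = [s.sample_id for s in table.samples
            if temp_min <= s.recovery_temp_C <= temp_max]
    dropped = len(table.samples) - len(keep)
    if not keep:
        warnings.warn("temperature filter removed all samples")
    logger.info("temperature filter [%g, %g] degC: kept %d of %d samples",
                temp_min, temp_max, len(keep), len(table.samples))
    if dropped == 0:
        return table
    return table.subset_samples(keep)


def retain_species(table: AbundanceTable, traits: TraitTable) -> AbundanceTable:
    """Drop taxa that have no trait data; log what was dropped and its counts."""
    keep = [t for t in table.taxa if t in set(traits.species)]
    dropped = [t for t in table.taxa if t not in set(traits.species)]
    if dropped:
        totals = table.counts[dropped].sum()
        for t in dropped:
            logger.info("dropping taxon %r (no trait data; %d individuals)",
                        t, int(totals[t]))
    if not keep:
        warnings.warn("no taxa retained: trait table covers none of the counts")
    return AbundanceTable(table.samples, table.counts[keep])


def pool_by_time(table: AbundanceTable) -> PooledSeries:
    """Sum counts over all surfaces recovered at the same post-eruption time.

    Pre-eruption surfaces are pooled separately into the reference row.
    Total individuals are conserved.
    """
    post = [s for s in table.samples if s.epoch == "post_eruption"]
    pre = [s for s in table.samples if s.epoch == "pre_eruption"]
    times = sorted({s.time_months for s in post})
    rows = {}
    for t in times:
        ids = [s.sample_id for s in post if s.time_months == t]
        rows[t] = table.counts.loc[ids].sum()
    pooled = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=table.taxa)
    pooled.index.name = "time_months"
    pre_counts = None
    if pre:
        pre_counts = table.counts.loc[[s.sample_id for s in pre]].sum()
    return PooledSeries(counts=pooled.astype(int), pre_counts=pre_counts)


def modality_abundance(series: PooledSeries, traits: TraitTable,
                       trait: TraitSpec) -> ModalityAbundance:
    """Total individuals expressing each modality of ``trait``, per time point.

    Species with a missing value for the trait contribute to no modality, so
    each row total equals the pooled abundance of species scored for the trait.
    """
    col = traits.data[trait.name]
    groups = {m: [sp for sp in series.taxa
                  if sp in col.index and col.get(sp) == m]
              for m in trait.levels}

    def aggregate(row: pd.Series) -> pd.Series:
        return pd.Series({m: int(row[members].sum()) if members else 0
                          for m, members in groups.items()})

    table = series.counts.apply(aggregate, axis=1)
    table = table[list(trait.levels)]
    pre_row = aggregate(series.pre_counts) if series.pre_counts is not None else None
    return ModalityAbundance(trait=trait, table=table, pre_row=pre_row)


def per_sample_modality_counts(table: AbundanceTable, traits: TraitTable,
                               trait: TraitSpec) -> pd.DataFrame:
    """Modality counts per surface (sample x modality), for permutation tests.

    Randomization operates at the surface level, so trait trend tests need
    modality counts before pooling.
    """
    col = traits.data[trait.name]
    out = {}
    for m in trait.levels:
        members = [sp for sp in table.taxa if sp in col.index and col.get(sp) == m]
        out[m] = table.counts[members].sum(axis=1) if members else pd.Series(0, index=table.counts.index)
    return pd.DataFrame(out)
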